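"""Region summaries and candidate-gene annotation for significant SNPs.

Significant loci are grouped into chromosome regions anchored at the most
significant ("top") SNP: any significant SNP within 40 kb of a region's top
SNP joins it, and the reported range is top +/- 20 kb in Mb, rounded to the
nearest 0.01 Mb.  Candidate genes are those whose interval overlaps the
closed window [top - 20 kb, top + 20 kb] (a gene touching the boundary is
included).  BED inputs (0-based half-open) are converted to the internal
1-based closed convention; GFF3 is read as 1-based closed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "SignificantRegion",
    "regionize",
    "genes_in_window",
    "annotate_regions",
    "read_bed",
    "read_gff3",
    "region_report",
    "WINDOW_BP",
]

WINDOW_BP = 20_000


@dataclass
class SignificantRegion:
    contig: str
    start_mb: float
    end_mb: float
    n_snps: int
    top_pos: int
    top_stat: float  # p-value (single-locus) or LOD (multi-locus)
    member_pos: list = field(default_factory=list)
    genes: list = field(default_factory=list)

    @property
    def range_label(self) -> str:
        return f"{self.start_mb:.2f}-{self.end_mb:.2f}"


def regionize(
    results: pd.DataFrame,
    stat_col: str = "p_value",
    ascending: bool = True,
    merge_bp: int = 2 * WINDOW_BP,
    window_bp: int = WINDOW_BP,
) -> list[SignificantRegion]:
    """Group significant SNPs into top-SNP-anchored regions.

    ``results`` needs columns contig, pos and ``stat_col``; rows are the
    already-significant loci.  SNPs are taken in order of significance
    (ascending p or descending LOD, ties broken by position, so the output
    is independent of input order); each SNP joins the first existing
    region on its contig whose top SNP lies within ``merge_bp``, otherwise
    it founds a region.  The reported range is top +/- ``window_bp`` in
    Mb rounded to the nearest 0.01.
    """
    regions: list[SignificantRegion] = []
    if results.empty:
        return regions
    df = results.sort_values(
        [stat_col, "contig", "pos"], ascending=[ascending, True, True], kind="mergesort"
    )
    for row in df.itertuples(index=False):
        contig, pos = str(row.contig), int(row.pos)
        stat = float(getattr(row, stat_col))
        home = None
        for reg in regions:
            if reg.contig == contig and abs(reg.top_pos - pos) <= merge_bp:
                home = reg
                break
        if home is None:
            regions.append(
                SignificantRegion(
                    contig=contig,
                    start_mb=round((pos - window_bp) / 1e6, 2),
                    end_mb=round((pos + window_bp) / 1e6, 2),
                    n_snps=1,
                    top_pos=pos,
                    top_stat=stat,
                    member_pos=[pos],
                )
            )
        else:
            home.n_snps += 1
            home.member_pos.append(pos)
    regions.sort(key=lambda r: (_contig_key(r.contig), r.top_pos))
    return regions


def _contig_key(c: str):
    return (0, int(c)) if c.isdigit() else (1, c)


def genes_in_window(
    contig: str, pos: int, genes: pd.DataFrame, window_bp: int = WINDOW_BP
) -> list[str]:
    """Gene names whose 1-based closed interval overlaps pos +/- window.

    Overlap is any shared base with the closed window (a gene ending
    exactly ``window_bp`` before the SNP is included).  A contig present
    in results but absent from the annotation is a hard error so that
    assembly mismatches never pass silently.
    """
    known = set(genes["contig"].astype(str))
    if str(contig) not in known:
        raise ValueError(
            f"contig {contig!r} absent from gene annotation (knowns e.g. {sorted(known)[:5]})"
        )
    lo, hi = pos - window_bp, pos + window_bp
    g = genes[genes["contig"].astype(str) == str(contig)]
    hit = g[(g["end"] >= lo) & (g["start"] <= hi)]
    return list(dict.fromkeys(hit["name"]))


def annotate_regions(
    regions: list[SignificantRegion], genes: pd.DataFrame, window_bp: int = WINDOW_BP
) -> list[SignificantRegion]:
    """Attach candidate genes (top SNP +/- window) to each region."""
    for reg in regions:
        reg.genes = genes_in_window(reg.contig, reg.top_pos, genes, window_bp)
    return regions


def read_bed(path) -> pd.DataFrame:
    """Read a BED file of gene intervals -> 1-based closed (contig, start,
    end, name)."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype={0: str})
    if df.shape[1] < 3:
        raise ValueError("BED needs at least contig,start,end columns")
    out = pd.DataFrame(
        {
            "contig": df[0].astype(str),
            "start": df[1].astype(int) + 1,  # half-open 0-based -> closed 1-based
            "end": df[2].astype(int),
            "name": df[3].astype(str) if df.shape[1] > 3
            else [f"interval{i}" for i in range(len(df))],
        }
    )
    return out


def read_gff3(path, feature_types: tuple = ("gene",)) -> pd.DataFrame:
    """Read gene features from GFF3 (already 1-based closed).

    Gene names are taken from the Name= attribute, falling back to ID=.
    """
    rows = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 9 or parts[2] not in feature_types:
                continue
            attrs = dict(
                kv.split("=", 1) for kv in parts[8].split(";") if "=" in kv
            )
            name = attrs.get("Name") or attrs.get("ID") or f"{parts[0]}:{parts[3]}"
            rows.append((parts[0], int(parts[3]), int(parts[4]), name))
    if not rows:
        raise ValueError(f"{path}: no features of type {feature_types}")
    return pd.DataFrame(rows, columns=["contig", "start", "end", "name"])


def region_report(regions: list[SignificantRegion], trait: str, stat_name: str = "p_value"
                  ) -> pd.DataFrame:
    """Tabular report: trait, chr, range, SNP count, top SNP, genes, stat."""
    rows = [
        {
            "trait": trait,
            "chr": r.contig,
            "range_mb": r.range_label,
            "n_snps": r.n_snps,
            "top_pos": r.top_pos,
            "candidate_genes": "/".join(r.genes) if r.genes else "",
            stat_name: r.top_stat,
        }
        for r in regions
    ]
    return pd.DataFrame(
        rows, columns=["trait", "chr", "range_mb", "n_snps", "top_pos",
                       "candidate_genes", stat_name]
    )
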