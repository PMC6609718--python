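"""VCF genotype intake and quality control.

Filters mirror common re-sequencing practice for small pig cohorts:
autosomes only (sex chromosomes and unplaced scaffolds dropped), per-genotype
read depth, per-locus missingness, minor allele frequency, and an exact
Hardy-Weinberg test.  Rules are applied in a fixed order — contig whitelist,
depth-induced missingness, missingness, MAF, HWE — because missingness and
MAF are only well defined after low-depth genotypes are masked.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "QCThresholds",
    "GenotypeMatrix",
    "read_vcf",
    "hwe_exact_test",
    "apply_qc",
    "write_genotype_tables",
]

AUTOSOMES = tuple(str(i) for i in range(1, 19))  # Sscrofa autosomes 1..18


@dataclass
class QCThresholds:
    """Filter thresholds; defaults follow routine pig re-sequencing QC.

    ``maf_inclusive`` keeps loci with MAF exactly at ``maf_min`` (the
    convention adopted here; the strict alternative is available because
    the boundary is a genuine ambiguity in the field's reporting).
    """

    maf_min: float = 0.1
    miss_max: float = 0.1
    hwe_p_min: float = 1e-6
    depth_min: int = 6  # genotypes with DP <= depth_min are set missing
    autosomes: tuple = AUTOSOMES
    maf_inclusive: bool = True

    def __post_init__(self) -> None:
        if not 0 <= self.maf_min < 0.5:
            raise ValueError("maf_min must be in [0, 0.5)")
        if not 0 <= self.miss_max <= 1:
            raise ValueError("miss_max must be in [0, 1]")


@dataclass
class GenotypeMatrix:
    """Biallelic dosages (samples x loci) with locus metadata.

    ``dosages`` take values {0, 1, 2} with NaN for missing.  ``loci`` has
    columns contig, pos (1-based bp), ref, alt; MAF and missingness are
    derived properties.  ``depths`` (same shape) is optional per-genotype
    read depth.
    """

    dosages: np.ndarray
    loci: pd.DataFrame
    samples: list
    depths: np.ndarray | None = None
    planted_flaw: pd.Series | None = None  # set by the simulator; "" = clean

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=float)
        if self.dosages.shape != (len(self.samples), len(self.loci)):
            raise ValueError("dosage matrix shape must be (n_samples, n_loci)")
        for col in ("contig", "pos", "ref", "alt"):
            if col not in self.loci.columns:
                raise ValueError(f"loci table missing column {col!r}")
        pos = self.loci.groupby("contig", sort=False)["pos"]
        if (pos.diff().dropna() <= 0).any():
            raise ValueError("positions must be strictly increasing within each contig")

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    def alt_freq(self) -> np.ndarray:
        with np.errstate(invalid="ignore"):
            return np.nanmean(self.dosages, axis=0) / 2.0

    def maf(self) -> np.ndarray:
        p = self.alt_freq()
        return np.minimum(p, 1.0 - p)

    def missing_rate(self) -> np.ndarray:
        return np.isnan(self.dosages).mean(axis=0)

    def n_miss(self) -> np.ndarray:
        return np.isnan(self.dosages).sum(axis=0).astype(int)

    def genotype_counts(self) -> np.ndarray:
        """Per-locus (n_ref_hom, n_het, n_alt_hom) over non-missing calls."""
        out = np.zeros((self.n_loci, 3), dtype=int)
        for g in (0, 1, 2):
            out[:, g] = np.nansum(self.dosages == g, axis=0)
        return out

    def take_loci(self, mask_or_idx) -> "GenotypeMatrix":
        idx = np.asarray(mask_or_idx)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        return GenotypeMatrix(
            self.dosages[:, idx],
            self.loci.iloc[idx].reset_index(drop=True),
            list(self.samples),
            None if self.depths is None else self.depths[:, idx],
            None if self.planted_flaw is None else self.planted_flaw.iloc[idx].reset_index(drop=True),
        )

    def locus_table(self) -> pd.DataFrame:
        tab = self.loci.copy()
        tab["maf"] = self.maf()
        tab["n_miss"] = self.n_miss()
        return tab


def read_vcf(path, skip_multiallelic: bool = True) -> GenotypeMatrix:
    """Read a VCF (v4.x, GT required, per-genotype DP kept if present).

    Multiallelic records are skipped by default (counted in the returned
    matrix's ``loci`` attrs).  No filtering happens here; depth masking is
    part of :func:`apply_qc` so that the raw matrix stays inspectable.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path), gts012=True)
    samples = list(vcf.samples)
    if not samples:
        raise ValueError(f"{path}: VCF has no sample columns")
    dosage_rows, depth_rows, meta = [], [], []
    n_multi = 0
    has_depth = False
    for var in vcf:
        if len(var.ALT) != 1:
            if skip_multiallelic:
                n_multi += 1
                continue
            raise ValueError(f"multiallelic record at {var.CHROM}:{var.POS}")
        gt = np.asarray(var.gt_types, dtype=float)  # 0/1/2, 3 = missing
        gt[gt == 3] = np.nan
        dosage_rows.append(gt)
        try:
            dp = var.format("DP")
        except KeyError:
            dp = None
        if dp is not None:
            dp = np.asarray(dp, dtype=float).reshape(-1)[: len(samples)]
            dp[dp < 0] = np.nan
            has_depth = True
            depth_rows.append(dp)
        else:
            depth_rows.append(np.full(len(samples), np.nan))
        meta.append((var.CHROM, var.POS, var.REF, var.ALT[0]))
    if not meta:
        raise ValueError(f"{path}: no usable biallelic records")
    loci = pd.DataFrame(meta, columns=["contig", "pos", "ref", "alt"])
    loci.attrs["n_multiallelic_skipped"] = n_multi
    depths = np.array(depth_rows).T if has_depth else None
    return GenotypeMatrix(np.array(dosage_rows).T, loci, samples, depths)


def hwe_exact_test(n_hom1: int, n_het: int, n_hom2: int) -> float:
    """Exact Hardy-Weinberg test on the heterozygote count.

    Two-sided exact conditional test: given allele counts, sums the
    probabilities of all heterozygote counts no more probable than the
    observed one.  Symmetric in the two homozygote classes and under
    allele relabelling.  Monomorphic loci return 1.
    """
    if min(n_hom1, n_het, n_hom2) < 0:
        raise ValueError("negative genotype counts")
    n = n_hom1 + n_het + n_hom2
    if n == 0:
        raise ValueError("no genotypes")
    n_rare = 2 * min(n_hom1, n_hom2) + n_het
    if n_rare == 0 or n_rare == 2 * n:
        return 1.0
    # log-probability of each feasible het count conditional on allele counts
    hets = np.arange(n_rare % 2, n_rare + 1, 2)
    homr = (n_rare - hets) // 2
    homc = n - hets - homr
    lg = math.lgamma
    logp = np.array(
        [
            hets_i * math.log(2.0)
            + lg(n + 1) - lg(h_i + 1) - lg(r_i + 1) - lg(c_i + 1)
            for hets_i, h_i, r_i, c_i in zip(hets, hets, homr, homc)
        ]
    )
    logp -= logp.max()
    prob = np.exp(logp)
    prob /= prob.sum()
    p_obs = prob[hets == n_het][0]
    return float(min(1.0, prob[prob <= p_obs * (1 + 1e-12)].sum()))


@dataclass
class QCReport:
    """Removal counts per rule, in application order."""

    n_input: int = 0
    removed_contig: int = 0
    removed_miss: int = 0
    removed_maf: int = 0
    removed_hwe: int = 0
    n_pass: int = 0
    n_genotypes_masked_depth: int = 0
    notes: list = field(default_factory=list)

    def as_frame(self) -> pd.DataFrame:
        rows = [
            ("input", self.n_input),
            ("removed_non_autosome", self.removed_contig),
            ("removed_missingness", self.removed_miss),
            ("removed_maf", self.removed_maf),
            ("removed_hwe", self.removed_hwe),
            ("passed", self.n_pass),
        ]
        return pd.DataFrame(rows, columns=["rule", "count"])


def apply_qc(matrix: GenotypeMatrix, thresholds: QCThresholds | None = None):
    """Filter a genotype matrix; returns (filtered matrix, QCReport).

    Order: contig whitelist -> depth masking (DP <= depth_min becomes a
    missing genotype) -> missingness -> MAF -> exact HWE.  Idempotent.
    """
    th = thresholds or QCThresholds()
    rep = QCReport(n_input=matrix.n_loci)

    contigs = matrix.loci["contig"].astype(str)
    keep = contigs.isin(th.autosomes).to_numpy()
    rep.removed_contig = int((~keep).sum())
    m = matrix.take_loci(keep)

    if m.depths is not None:
        low = np.nan_to_num(m.depths, nan=np.inf) <= th.depth_min
        rep.n_genotypes_masked_depth = int((low & ~np.isnan(m.dosages)).sum())
        dosages = m.dosages.copy()
        dosages[low] = np.nan
        m = GenotypeMatrix(dosages, m.loci, m.samples, m.depths, m.planted_flaw)

    keep = m.missing_rate() < th.miss_max
    rep.removed_miss = int((~keep).sum())
    m = m.take_loci(keep)

    maf = m.maf()
    keep = (maf >= th.maf_min) if th.maf_inclusive else (maf > th.maf_min)
    keep &= maf > 0  # monomorphic never informative
    rep.removed_maf = int((~keep).sum())
    m = m.take_loci(keep)

    counts = m.genotype_counts()
    pvals = np.array([hwe_exact_test(*c) for c in counts])
    keep = pvals >= th.hwe_p_min
    rep.removed_hwe = int((~keep).sum())
    m = m.take_loci(keep)

    rep.n_pass = m.n_loci
    if rep.n_pass == 0:
        rep.notes.append("no locus survived QC")
    return m, rep


def write_genotype_tables(matrix: GenotypeMatrix, dosage_path, loci_path) -> None:
    """Persist a filtered matrix as two TSVs (dosages, locus metadata)."""
    pd.DataFrame(matrix.dosages, index=matrix.samples).to_csv(
        dosage_path, sep="\t", float_format="%g"
    )
    matrix.locus_table().to_csv(loci_path, sep="\t", index=False)
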