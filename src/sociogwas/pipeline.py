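"""End-to-end orchestration: simulate -> traits -> REML -> scans -> regions.

One call produces, for each trait, the fitted variance-component summary,
DGE/SGE pseudo-phenotypes for the genotyped pens, QC'd genotypes, single-
and multi-locus association tables, and region reports with candidate
genes.  Every output file carries the seed and a configuration hash in a
comment header, so a run is reproducible and checkable from its artefacts.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import pandas as pd

from . import annotate as ann
from .genoqc import QCThresholds, apply_qc
from .multi_locus import LOD_MIN, STAGE1_P, multi_locus_scan
from .relatedness import genomic_relationship, numerator_relationship
from .simulate import SimulationConfig, simulate_genotypes, simulate_growth_records, write_genes_bed
from .single_locus import GENOME_WIDE_P, SUGGESTIVE_P, classify, fit_null_lmm, scan
from .social_model import (
    SocialModelSpec, derive_summaries, fit_social_model, pseudo_phenotypes,
)
from .traits import compute_trait_table

log = logging.getLogger("sociogwas")

TRAITS = ("adg", "d100", "b100", "adfi", "fcr", "rfi")


@dataclass
class PipelineConfig:
    outdir: str = "sociogwas_run"
    seed: int = 0
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    qc: QCThresholds = field(default_factory=QCThresholds)
    genome_wide_p: float = GENOME_WIDE_P
    suggestive_p: float = SUGGESTIVE_P
    stage1_p: float = STAGE1_P
    lod_min: float = LOD_MIN
    include_social: bool = True
    kinship: str = "genomic"  # or "pedigree"
    traits: tuple = TRAITS

    def digest(self) -> str:
        d = asdict(self)
        d.pop("outdir", None)  # identical analyses hash alike wherever written
        blob = json.dumps(d, sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the full study on simulated data; returns a manifest of outputs.

    Deterministic given ``config.seed``.  Any stage failure aborts with the
    stage name in the raised error's message.
    """
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"outputs": [], "seed": config.seed, "config_hash": config.digest()}
    sim_cfg = replace(config.simulation, seed=config.seed)

    def _stage(name):
        log.info("stage %s", name)
        manifest.setdefault("stages", []).append(name)

    def _write(df: pd.DataFrame, name: str):
        path = out / name
        with open(path, "w") as fh:
            fh.write(f"# sociogwas seed={config.seed} config={manifest['config_hash']}\n")
            df.to_csv(fh, sep="\t", index=False)
        manifest["outputs"].append(str(path))
        return path

    try:
        _stage("simulate")
        records, studies = simulate_growth_records(sim_cfg)
        adg_study = studies["adg"]
        _write(records, "growth_records.tsv")

        _stage("traits")
        trait_tab = compute_trait_table(records, adg_unit="kg")
        _write(trait_tab, "trait_table.tsv")
        manifest["n_phenotyped"] = len(trait_tab)

        _stage("genotypes+qc")
        simulate_genotypes(adg_study, sim_cfg)
        raw = adg_study.genotypes
        gm, qc_rep = apply_qc(raw, config.qc)
        _write(qc_rep.as_frame(), "qc_report.tsv")
        _write(gm.locus_table(), "qc_passed_loci.tsv")
        manifest["n_snps_input"] = raw.n_loci
        manifest["n_snps_pass"] = gm.n_loci
        genes = write_genes_bed(out / "genes.bed", seed=config.seed)
        manifest["outputs"].append(str(out / "genes.bed"))

        _stage("fit")
        base = adg_study.phenotypes.data.set_index("animal_id")
        ped = adg_study.pedigree
        A = numerator_relationship(ped)
        if config.kinship == "genomic":
            K = genomic_relationship(gm.dosages, gm.samples)
        else:
            K = A.submatrix(gm.samples)
        summaries = []
        scan_index = []
        for trait in config.traits:
            pheno = adg_study.phenotypes
            df = pheno.data[["animal_id", "sex", "yearmonth", "litter", "pen"]].copy()
            df[trait] = trait_tab.set_index("animal_id")[trait].loc[df["animal_id"]].to_numpy()
            df = df.dropna(subset=[trait])
            from .social_model import GroupedPhenotypes

            gp = GroupedPhenotypes(df, trait=trait)
            spec = SocialModelSpec(trait=trait, include_social=config.include_social)
            fit = fit_social_model(gp, A, spec)
            summ = derive_summaries(fit, sim_cfg.pen_size)
            comp = fit.components
            summaries.append(
                {"trait": trait, **comp.as_dict(),
                 **{f"se_{k}": v for k, v in comp.se.items()},
                 **summ, "converged": comp.converged, "n_iter": comp.n_iter}
            )
            for which in ("dge", "sge") if config.include_social else ("dge",):
                y = pseudo_phenotypes(fit, which, gm.samples)
                null = fit_null_lmm(y.to_numpy(), K)
                single = classify(scan(y.to_numpy(), gm, null),
                                  config.genome_wide_p, config.suggestive_p)
                _write(single, f"scan_single_{which}_{trait}.tsv")
                multi = multi_locus_scan(y.to_numpy(), gm, null,
                                         config.stage1_p, config.lod_min)
                _write(multi, f"scan_multi_{which}_{trait}.tsv")
                scan_index.append((trait, which, single, multi))

        _stage("summaries")
        _write(pd.DataFrame(summaries), "variance_components.tsv")

        _stage("annotate")
        region_rows = []
        for trait, which, single, multi in scan_index:
            sig = single[single["tier"] != "none"]
            regs = ann.regionize(sig, "p_value", ascending=True)
            ann.annotate_regions(regs, genes)
            rep = ann.region_report(regs, f"{which}{trait.upper()}")
            if not rep.empty:
                region_rows.append(rep)
            qtn = multi[multi["retained"]]
            regs_m = ann.regionize(qtn, "lod", ascending=False)
            ann.annotate_regions(regs_m, genes)
            rep_m = ann.region_report(regs_m, f"{which}{trait.upper()}", "lod")
            if not rep_m.empty:
                region_rows.append(rep_m.rename(columns={"lod": "p_value"}))
        regions = (pd.concat(region_rows, ignore_index=True)
                   if region_rows else pd.DataFrame(
                       columns=["trait", "chr", "range_mb", "n_snps", "top_pos",
                                "candidate_genes", "p_value"]))
        _write(regions, "significant_regions.tsv")
    except Exception as e:
        stage = manifest.get("stages", ["?"])[-1]
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {e}") from e

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest
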