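"""Synthetic pedigreed populations with direct and social genetic effects.

The generator emulates a performance-tested pig herd: a multi-generation
pedigree, litters of full sibs, animals housed in pens of a fixed size, a
small subset of pens whole-genome genotyped, and phenotypes built from the
direct + social decomposition

    P_i = fixed effects + A_D,i + sum_{j in pen(i), j != i} A_S,j
          + litter + pen + residual,

with (A_D, A_S) sampled jointly along the pedigree so that their covariance
is G0 (x) A.  Everything is driven by one integer seed and is byte-identical
across re-runs.

The genotype simulator draws independent loci (no LD) for the genotyped
pens, with allele frequencies from a configured range, and can plant loci
that violate each genotype-QC rule (out-of-whitelist contigs, low read
depth, high missingness, low MAF, Hardy-Weinberg departures) as well as
causal loci whose dosages feed additively into direct and/or social
breeding values.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .genoqc import GenotypeMatrix
from .relatedness import Pedigree, numerator_relationship
from .social_model import GroupedPhenotypes

__all__ = [
    "SimulationConfig",
    "SimulatedStudy",
    "simulate_pedigree",
    "simulate_breeding_values",
    "simulate_phenotypes",
    "simulate_genotypes",
    "simulate_study",
    "simulate_gwas_dataset",
    "simulate_growth_records",
    "write_pedigree_csv",
    "write_vcf",
    "write_genes_bed",
]

N_AUTOSOMES = 18
CONTIG_LENGTH = 150_000_000  # synthetic bp span per autosome


@dataclass
class SimulationConfig:
    """Study-design and variance parameters for one simulated trait.

    Defaults mirror the reference study design: pens of 10 animals, 4 pens
    genotyped, and RFI-scale variance components (trait-squared units)
    with a strong positive direct-social genetic correlation.
    """

    n_animals: int = 3276
    n_founders: int = 200
    pen_size: int = 10
    n_pens_genotyped: int = 4
    n_snps: int = 5000
    maf_range: tuple = (0.1, 0.5)
    var_direct: float = 11577.72
    var_social: float = 97.23
    cov_direct_social: float = 742.62  # r_ADS = 0.70 at the defaults
    var_litter: float = 1300.0
    var_group: float = 1300.0
    var_residual: float = 11815.46
    fixed_effect_levels: tuple = (2, 6)  # sex, tested year-month
    fixed_effect_sd: float | None = None  # None -> 0.25 * sqrt(var_direct + var_residual)
    n_generations: int = 3
    litter_size_range: tuple = (8, 12)
    mean_depth: float = 20.0
    frac_nonautosomal: float = 0.0
    frac_low_depth: float = 0.0
    frac_high_missing: float = 0.0
    frac_low_maf: float = 0.0
    frac_hwe_violators: float = 0.0
    low_maf_range: tuple = (0.01, 0.05)
    causal_loci: tuple = ()  # (effect_on_direct, effect_on_social) per causal locus
    seed: int = 0

    def __post_init__(self) -> None:
        if self.pen_size < 2:
            raise ValueError("pen_size must be >= 2")
        if self.n_founders < 2 or self.n_animals < self.n_founders:
            raise ValueError("need n_animals >= n_founders >= 2")
        if not (0 < self.maf_range[0] <= self.maf_range[1] <= 0.5):
            raise ValueError("maf_range must satisfy 0 < lo <= hi <= 0.5")
        for name in ("var_direct", "var_social", "var_litter", "var_group", "var_residual"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if not _is_psd(self.genetic_matrix()):
            raise ValueError("direct/social genetic (co)variance matrix is not PSD")

    def genetic_matrix(self) -> np.ndarray:
        return np.array(
            [[self.var_direct, self.cov_direct_social],
             [self.cov_direct_social, self.var_social]]
        )

    def resolved_fixed_sd(self) -> float:
        if self.fixed_effect_sd is not None:
            return self.fixed_effect_sd
        return 0.25 * float(np.sqrt(self.var_direct + self.var_residual))


def _is_psd(G: np.ndarray, rtol: float = 1e-9) -> bool:
    w = np.linalg.eigvalsh(G)
    return w.min() >= -rtol * max(w.max(), 1.0)


@dataclass
class SimulatedStudy:
    """One simulated dataset with its generating truth attached."""

    config: SimulationConfig
    pedigree: Pedigree
    phenotypes: GroupedPhenotypes | None
    true_direct_bv: pd.Series
    true_social_bv: pd.Series
    genotypes: GenotypeMatrix | None = None
    causal_loci: list = field(default_factory=list)  # (locus_index, beta_direct, beta_social)

    @property
    def genotyped_ids(self) -> list:
        return [] if self.genotypes is None else list(self.genotypes.samples)


# ---------------------------------------------------------------------------
# pedigree


def simulate_pedigree(config: SimulationConfig, rng: np.random.Generator | None = None) -> Pedigree:
    """Multi-generation pedigree with litters of full sibs and pens.

    Founders (generation 0, both sexes guaranteed) have unknown parents.
    Each later generation is produced by random sire x dam matings from the
    previous generation, litter sizes uniform on ``litter_size_range``.
    Non-founders are housed in pens of exactly ``pen_size`` within their
    generation; animals left over from pen filling stay unpenned (and are
    therefore not phenotyped).  Year-month labels are assigned per pen.
    """
    rng = rng or np.random.default_rng(config.seed)
    n_extra = config.n_animals - config.n_founders
    per_gen = -(-n_extra // config.n_generations) if n_extra else 0

    rows = []
    sex_codes = np.array(["male", "female"])
    founder_sex = np.array(["male"] * (config.n_founders // 2)
                           + ["female"] * (config.n_founders - config.n_founders // 2))
    rng.shuffle(founder_sex)
    for i in range(config.n_founders):
        rows.append((f"F{i + 1:04d}", "0", "0", founder_sex[i], "", 0))

    prev = [(r[0], r[3]) for r in rows]
    made = 0
    gen = 0
    litter_no = 0
    while made < n_extra:
        gen += 1
        sires = [a for a, s in prev if s == "male"]
        dams = [a for a, s in prev if s == "female"]
        if not sires or not dams:
            raise ValueError(
                f"generation {gen - 1} lacks a sire or dam; litters would need unborn parents"
            )
        cur = []
        quota = min(per_gen, n_extra - made)
        while quota > 0:
            sire = sires[rng.integers(len(sires))]
            dam = dams[rng.integers(len(dams))]
            size = int(rng.integers(config.litter_size_range[0], config.litter_size_range[1] + 1))
            size = min(size, quota)
            litter_no += 1
            lit = f"L{litter_no:04d}"
            for _ in range(size):
                made += 1
                sex = sex_codes[rng.integers(2)]
                aid = f"G{gen}A{made:05d}"
                rows.append((aid, sire, dam, sex, lit, gen))
                cur.append((aid, sex))
            quota -= size
        prev = cur

    df = pd.DataFrame(rows, columns=["id", "sire", "dam", "sex", "litter", "generation"])

    # pens within each non-founder generation, exactly pen_size members each
    df["pen"] = ""
    df["yearmonth"] = ""
    pen_no = 0
    n_ym = config.fixed_effect_levels[1]
    for g in sorted(df.loc[df["generation"] > 0, "generation"].unique()):
        members = df.index[df["generation"] == g].to_numpy()
        perm = rng.permutation(members)
        n_pens = len(perm) // config.pen_size
        for k in range(n_pens):
            pen_no += 1
            rows_k = perm[k * config.pen_size:(k + 1) * config.pen_size]
            df.loc[rows_k, "pen"] = f"P{pen_no:04d}"
            df.loc[rows_k, "yearmonth"] = f"ym{int(rng.integers(n_ym)) + 1}"
    return Pedigree(df)


# ---------------------------------------------------------------------------
# breeding values


def simulate_breeding_values(
    pedigree: Pedigree, config: SimulationConfig, rng: np.random.Generator | None = None
) -> tuple[pd.Series, pd.Series]:
    """Sample (A_D, A_S) jointly with covariance G0 (x) A along the pedigree.

    Founders draw from N(0, G0); an offspring is the parent average plus a
    Mendelian-sampling deviation with variance G0 * (1/2)(1 - (F_s + F_d)/2)
    (3/4 - F_known/4 with one known parent), so the pedigree-implied
    covariance structure holds exactly in expectation.
    """
    G = config.genetic_matrix()
    if not _is_psd(G):
        raise ValueError("genetic matrix must be PSD")
    rng = rng or np.random.default_rng(config.seed + 1)
    w, U = np.linalg.eigh(G)
    Gh = U @ np.diag(np.sqrt(np.maximum(w, 0.0))) @ U.T  # symmetric square root

    F = numerator_relationship(pedigree).inbreeding()
    sire, dam = pedigree.parent_rows()
    n = len(pedigree)
    bv = np.zeros((n, 2))
    z = rng.standard_normal((n, 2))
    for i in range(n):
        s, d = sire[i], dam[i]
        if s < 0 and d < 0:
            mean, scale = np.zeros(2), 1.0
        elif s >= 0 and d >= 0:
            mean = 0.5 * (bv[s] + bv[d])
            scale = 0.5 * (1.0 - 0.5 * (F[s] + F[d]))
        else:
            k = s if s >= 0 else d
            mean = 0.5 * bv[k]
            scale = 0.75 - 0.25 * F[k]
        bv[i] = mean + np.sqrt(scale) * (Gh @ z[i])
    if config.var_social == 0.0 and config.cov_direct_social == 0.0:
        bv[:, 1] = 0.0
    ids = pedigree.ids
    return pd.Series(bv[:, 0], index=ids, name="a_D"), pd.Series(bv[:, 1], index=ids, name="a_S")


# ---------------------------------------------------------------------------
# phenotypes


def simulate_phenotypes(
    pedigree: Pedigree,
    bvs: tuple[pd.Series, pd.Series],
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
    trait: str = "y",
) -> GroupedPhenotypes:
    """Phenotypes for all penned animals under the direct+social model.

    Each phenotype is fixed effects + own direct BV + sum of pen-mates'
    social BVs + litter effect + pen effect + residual.  All generating
    components are stored in ``truth`` for recovery tests.
    """
    rng = rng or np.random.default_rng(config.seed + 2)
    a_D, a_S = bvs
    df = pedigree.records
    if "pen" not in df.columns:
        raise ValueError("pedigree records carry no pen assignments")
    penned = df[df["pen"].astype(str) != ""].copy()
    if penned.empty:
        raise ValueError("no penned animals: nothing to phenotype")
    sizes = penned.groupby("pen")["id"].size()
    bad = sizes[sizes != config.pen_size]
    if len(bad):
        raise ValueError(f"pens with size != {config.pen_size}: {list(bad.index[:5])}")
    missing = [a for a in penned["id"] if a not in a_D.index]
    if missing:
        raise ValueError(f"animals without breeding values: {missing[:5]}")

    sd_fix = config.resolved_fixed_sd()
    sex_levels = ["male", "female"][: config.fixed_effect_levels[0]]
    sex_eff = dict(zip(sex_levels, rng.normal(0.0, sd_fix, len(sex_levels)) if sd_fix else
                       np.zeros(len(sex_levels))))
    ym_levels = sorted(penned["yearmonth"].unique())
    ym_eff = dict(zip(ym_levels, rng.normal(0.0, sd_fix, len(ym_levels)) if sd_fix else
                      np.zeros(len(ym_levels))))

    litters = sorted(penned["litter"].unique())
    lit_eff = dict(zip(litters, rng.normal(0.0, np.sqrt(config.var_litter), len(litters))))
    pens = sorted(penned["pen"].unique())
    pen_eff = dict(zip(pens, rng.normal(0.0, np.sqrt(config.var_group), len(pens))))
    resid = rng.normal(0.0, np.sqrt(config.var_residual), len(penned))

    aS_pen_total = (
        pd.Series(a_S.loc[penned["id"]].to_numpy(), index=penned.index)
        .groupby(penned["pen"]).transform("sum")
    )

    own_d = a_D.loc[penned["id"]].to_numpy()
    own_s = a_S.loc[penned["id"]].to_numpy()
    mates_s = aS_pen_total.to_numpy() - own_s  # self excluded
    fixed = np.array([sex_eff[s] for s in penned["sex"]]) \
        + np.array([ym_eff[m] for m in penned["yearmonth"]])
    lit = np.array([lit_eff[v] for v in penned["litter"]])
    grp = np.array([pen_eff[v] for v in penned["pen"]])
    y = fixed + own_d + mates_s + lit + grp + resid

    data = pd.DataFrame(
        {
            "animal_id": penned["id"].to_numpy(),
            trait: y,
            "sex": penned["sex"].to_numpy(),
            "yearmonth": penned["yearmonth"].to_numpy(),
            "litter": penned["litter"].to_numpy(),
            "pen": penned["pen"].to_numpy(),
        }
    )
    truth = {
        "fixed": fixed, "direct": own_d, "social_sum": mates_s,
        "litter": lit, "group": grp, "residual": resid,
        "sex_effects": sex_eff, "yearmonth_effects": ym_eff,
    }
    return GroupedPhenotypes(data, trait=trait, truth=truth)


# ---------------------------------------------------------------------------
# genotypes


def simulate_genotypes(
    study: SimulatedStudy, config: SimulationConfig | None = None,
    rng: np.random.Generator | None = None,
) -> GenotypeMatrix:
    """Genotypes for ``n_pens_genotyped`` complete pens, with planted flaws.

    Loci are independent; clean loci are autosomal, deeply covered, in HWE,
    with alt-allele frequency drawn from ``maf_range``.  Fractions of loci
    may instead be planted as non-autosomal (contig "X" or "scaffold_*"),
    low-depth (DP <= 6 at ~30% of genotypes), high-missingness (~30%
    missing), low-MAF, or Hardy-Weinberg violators (fully homozygous pens of
    alleles, i.e. maximal heterozygote deficit).  Causal loci (clean) add
    dosage * effect to the genotyped animals' direct/social breeding values
    in place, and are returned in ``study.causal_loci``.
    """
    config = config or study.config
    rng = rng or np.random.default_rng(config.seed + 3)
    if study.phenotypes is None:
        raise ValueError("phenotypes must exist before genotyping (pens define the sample)")
    pens = study.phenotypes.pen_members()
    pen_ids = sorted(pens)[: config.n_pens_genotyped]
    if len(pen_ids) < config.n_pens_genotyped:
        raise ValueError("fewer pens available than n_pens_genotyped")
    samples = [a for p in pen_ids for a in pens[p]]
    n, m = len(samples), config.n_snps

    # flaw assignment: each locus has at most one planted flaw
    flaw = np.array([""] * m, dtype=object)
    kinds = [
        ("nonautosomal", config.frac_nonautosomal),
        ("low_depth", config.frac_low_depth),
        ("high_missing", config.frac_high_missing),
        ("low_maf", config.frac_low_maf),
        ("hwe", config.frac_hwe_violators),
    ]
    order = rng.permutation(m)
    start = 0
    for name, frac in kinds:
        k = int(round(frac * m))
        flaw[order[start:start + k]] = name
        start += k

    freq = rng.uniform(config.maf_range[0], config.maf_range[1], m)
    low = flaw == "low_maf"
    freq[low] = rng.uniform(config.low_maf_range[0], config.low_maf_range[1], low.sum())

    hwe = flaw == "hwe"
    # violators sit at intermediate frequency so the heterozygote deficit is
    # unambiguous even in a small genotyped sample
    freq[hwe] = rng.uniform(0.3, 0.5, hwe.sum())
    dosages = rng.binomial(2, freq[None, :], size=(n, m)).astype(float)
    if hwe.any():  # fully homozygous loci: extreme heterozygote deficit
        dosages[:, hwe] = 2.0 * rng.binomial(1, freq[None, hwe], size=(n, hwe.sum()))

    depths = rng.poisson(config.mean_depth, size=(n, m)).astype(float)
    depths[depths < 7] = 7.0  # clean loci always pass the depth rule
    lowdp = flaw == "low_depth"
    if lowdp.any():
        mask = rng.random((n, lowdp.sum())) < 0.3
        sub = depths[:, lowdp]
        sub[mask] = rng.integers(1, 7, size=int(mask.sum()))
        depths[:, lowdp] = sub
    himiss = flaw == "high_missing"
    if himiss.any():
        mask = rng.random((n, himiss.sum())) < 0.3
        sub = dosages[:, himiss]
        sub[mask] = np.nan
        dosages[:, himiss] = sub

    # contigs and positions: clean loci spread over autosomes 1..18
    contig = np.empty(m, dtype=object)
    auto = flaw != "nonautosomal"
    n_auto = int(auto.sum())
    contig[auto] = [str(1 + (j % N_AUTOSOMES)) for j in range(n_auto)]
    k_bad = int((~auto).sum())
    decoys = ["X"] + [f"scaffold_{j + 1}" for j in range(max(k_bad - 1, 0))]
    contig[~auto] = decoys[:k_bad]
    pos = np.zeros(m, dtype=int)
    order_df = pd.DataFrame({"contig": contig})
    for ctg, grp in order_df.groupby("contig", sort=False):
        idx = grp.index.to_numpy()
        draw = np.unique(rng.integers(1, CONTIG_LENGTH, size=len(idx)))
        while len(draw) < len(idx):  # rare collision: top up
            extra = rng.integers(1, CONTIG_LENGTH, size=len(idx) - len(draw))
            draw = np.unique(np.concatenate([draw, extra]))
        pos[idx] = np.sort(draw)
    ref = np.array(list("ACGT"))[rng.integers(0, 4, m)]
    alt = np.array([_other_base(b, rng) for b in ref])

    loci = pd.DataFrame({"contig": contig, "pos": pos, "ref": ref, "alt": alt})
    sort_idx = loci.sort_values(["contig", "pos"], kind="mergesort").index.to_numpy()
    loci = loci.iloc[sort_idx].reset_index(drop=True)
    dosages = dosages[:, sort_idx]
    depths = depths[:, sort_idx]
    flaw = flaw[sort_idx]

    # causal loci: clean autosomal loci feeding the genetic effects
    study.causal_loci = []
    if config.causal_loci:
        clean = np.flatnonzero(flaw == "")
        picks = rng.choice(clean, size=len(config.causal_loci), replace=False)
        for j, (b_d, b_s) in zip(picks, config.causal_loci):
            centred = dosages[:, j] - np.nanmean(dosages[:, j])
            for sid, x in zip(samples, np.nan_to_num(centred)):
                study.true_direct_bv.loc[sid] += b_d * x
                study.true_social_bv.loc[sid] += b_s * x
            study.causal_loci.append((int(j), float(b_d), float(b_s)))

    gm = GenotypeMatrix(dosages, loci, samples, depths, pd.Series(flaw, name="planted_flaw"))
    study.genotypes = gm
    return gm


def _other_base(b: str, rng) -> str:
    others = [x for x in "ACGT" if x != b]
    return others[rng.integers(3)]


# ---------------------------------------------------------------------------
# orchestration


def simulate_study(config: SimulationConfig, with_genotypes: bool = True) -> SimulatedStudy:
    """Full study: pedigree -> breeding values -> genotypes -> phenotypes.

    Genotypes come before phenotypes so that causal-locus contributions to
    the genotyped animals' breeding values are reflected in the phenotypes.
    Deterministic in ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    ped = simulate_pedigree(config, rng)
    a_D, a_S = simulate_breeding_values(ped, config, rng)
    study = SimulatedStudy(config, ped, None, a_D, a_S)
    if with_genotypes:
        # phenotype container is needed to define pens; build a provisional
        # one only to identify the genotyped pens, then regenerate with the
        # final (causal-adjusted) breeding values from a fresh substream.
        pheno_rng_state = np.random.default_rng(config.seed + 2)
        provisional = simulate_phenotypes(ped, (a_D, a_S), config,
                                          np.random.default_rng(config.seed + 2))
        study.phenotypes = provisional
        simulate_genotypes(study, config, np.random.default_rng(config.seed + 3))
        study.phenotypes = simulate_phenotypes(
            ped, (study.true_direct_bv, study.true_social_bv), config, pheno_rng_state
        )
    else:
        study.phenotypes = simulate_phenotypes(ped, (a_D, a_S), config,
                                               np.random.default_rng(config.seed + 2))
    return study


def simulate_gwas_dataset(
    n_samples: int,
    n_snps: int,
    seed: int = 0,
    maf_range: tuple = (0.1, 0.5),
    causal: tuple = (),  # (locus_index, beta) pairs
    h2_poly: float = 0.0,
    noise_sd: float = 1.0,
):
    """Small unstructured cohort for genome-scan experiments.

    Returns (dosages, y, freq).  ``causal`` adds beta * dosage to y;
    ``h2_poly`` adds an aggregate polygenic term built from all loci.
    """
    rng = np.random.default_rng(seed)
    freq = rng.uniform(*maf_range, n_snps)
    X = rng.binomial(2, freq[None, :], size=(n_samples, n_snps)).astype(float)
    y = rng.normal(0.0, noise_sd, n_samples)
    if h2_poly > 0:
        w = rng.normal(0.0, 1.0, n_snps)
        g = (X - 2 * freq) @ w
        g *= np.sqrt(h2_poly / max(np.var(g), 1e-300)) * noise_sd / np.sqrt(max(1 - h2_poly, 1e-9))
        y = y + g
    for j, beta in causal:
        y = y + beta * X[:, j]
    return X, y, freq


# ---------------------------------------------------------------------------
# growth-record generation (ties the generator to the trait calculators)


def simulate_growth_records(
    config: SimulationConfig, seed: int | None = None
) -> tuple[pd.DataFrame, dict]:
    """Raw performance-test records whose derived traits carry the
    direct+social structure.

    Three latent record-level quantities — ADG (kg/day), ADFI (kg/day) and
    test backfat (mm) — are each simulated under the social decomposition
    (variances scaled from the RFI-magnitude defaults); the feeding trial
    runs from 65 kg to a fixed 110-kg test weight, so each animal's test
    length is 45 kg over its own ADG and the full six-trait table (ADG,
    D100, B100, ADFI, FCR, RFI) follows from the trait calculators.
    Returns (records, studies) where ``studies`` maps latent trait ->
    SimulatedStudy.
    """
    seed = config.seed if seed is None else seed
    latent = {
        # (mean, phenotypic SD on the record scale)
        "adg": (0.85, 0.073),   # kg/day
        "adfi": (2.30, 0.196),  # kg/day
        "bft": (12.0, 2.0),     # mm
    }
    base_var = (config.var_direct + config.var_social + config.var_litter
                + config.var_group + config.var_residual)
    studies = {}
    ped = None
    frames = {}
    for k, (name, (mu, sd)) in enumerate(latent.items()):
        scale = sd**2 / base_var
        cfg = replace(
            config,
            var_direct=config.var_direct * scale,
            var_social=config.var_social * scale,
            cov_direct_social=config.cov_direct_social * scale,
            var_litter=config.var_litter * scale,
            var_group=config.var_group * scale,
            var_residual=config.var_residual * scale,
            fixed_effect_sd=(config.fixed_effect_sd if config.fixed_effect_sd is not None
                             else 0.25 * sd),
            seed=seed if k == 0 else seed,  # same seed: identical pedigree/pens
        )
        if ped is None:
            rng = np.random.default_rng(cfg.seed)
            ped = simulate_pedigree(cfg, rng)
        bv_rng = np.random.default_rng(cfg.seed + 11 + k)
        a_D, a_S = simulate_breeding_values(ped, cfg, bv_rng)
        ph = simulate_phenotypes(ped, (a_D, a_S), cfg,
                                 np.random.default_rng(cfg.seed + 21 + k), trait=name)
        studies[name] = SimulatedStudy(cfg, ped, ph, a_D, a_S)
        frames[name] = ph.data.set_index("animal_id")[name] + mu

    ids = frames["adg"].index
    bw_start, bw_end = 65.0, 110.0  # the feeding-trial weight window
    adg = frames["adg"].clip(lower=0.3)
    test_days = ((bw_end - bw_start) / adg).clip(upper=200.0)  # days to finish
    records = pd.DataFrame(
        {
            "animal_id": ids,
            "sex": studies["adg"].phenotypes.data.set_index("animal_id")["sex"].loc[ids],
            "test_days": test_days,
            "bw_start": bw_start,
            "bw_end": bw_end,
            "test_weight": bw_end,
            "test_bft": frames["bft"].clip(lower=4.0),
            "adfi": frames["adfi"].clip(lower=0.8),
            "adg": adg,
        }
    ).reset_index(drop=True)
    records["total_feed"] = records["adfi"] * test_days.to_numpy()
    return records, studies


# ---------------------------------------------------------------------------
# plain-text writers (round-trip through the package's own readers)


def write_pedigree_csv(pedigree: Pedigree, path) -> None:
    cols = [c for c in ("id", "sire", "dam", "litter", "pen", "sex", "yearmonth")
            if c in pedigree.records.columns]
    pedigree.records[cols].to_csv(path, index=False)


def write_vcf(gm: GenotypeMatrix, path, assembly: str = "synthetic") -> None:
    """Write a VCF v4.2 with GT and per-genotype DP."""
    contigs = list(pd.unique(gm.loci["contig"]))
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##source=sociogwas-simulator assembly={assembly}\n")
        for c in contigs:
            fh.write(f"##contig=<ID={c},length={CONTIG_LENGTH}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(str(s) for s in gm.samples) + "\n")
        gt_map = {0.0: "0/0", 1.0: "0/1", 2.0: "1/1"}
        for j, loc in enumerate(gm.loci.itertuples(index=False)):
            cells = []
            for i in range(gm.n_samples):
                d = gm.dosages[i, j]
                gt = "./." if np.isnan(d) else gt_map[d]
                dp = "." if gm.depths is None or np.isnan(gm.depths[i, j]) \
                    else str(int(gm.depths[i, j]))
                cells.append(f"{gt}:{dp}")
            fh.write(f"{loc.contig}\t{loc.pos}\t.\t{loc.ref}\t{loc.alt}\t.\tPASS\t.\tGT:DP\t"
                     + "\t".join(cells) + "\n")


def write_genes_bed(path, n_genes_per_contig: int = 30, gene_length: int = 30_000,
                    seed: int = 0, contigs=None) -> pd.DataFrame:
    """Synthetic gene intervals (BED, 0-based half-open) for annotation tests."""
    rng = np.random.default_rng(seed)
    contigs = contigs or [str(i) for i in range(1, N_AUTOSOMES + 1)]
    rows = []
    g = 0
    for c in contigs:
        starts = np.unique(rng.integers(0, CONTIG_LENGTH - gene_length,
                                        size=n_genes_per_contig))
        while len(starts) < n_genes_per_contig:  # rare collision: top up
            extra = rng.integers(0, CONTIG_LENGTH - gene_length,
                                 size=n_genes_per_contig - len(starts))
            starts = np.unique(np.concatenate([starts, extra]))
        for s in starts:
            g += 1
            rows.append((c, int(s), int(s + gene_length), f"GENE{g:05d}"))
    df = pd.DataFrame(rows, columns=["contig", "start", "end", "name"])
    df.to_csv(path, sep="\t", header=False, index=False)
    return df
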