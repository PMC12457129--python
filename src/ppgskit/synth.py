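"""Synthetic structured-cohort generator with planted truth.

Emulates the statistical structure the association battery assumes, at
desk scale and with no external data:

* three populations whose allele frequencies diverge from a shared
  ancestral frequency under the Balding-Nichols model
  (p_pop ~ Beta(p(1-F)/F, (1-p)(1-F)/F), so E[p_pop] = p and
  Var[p_pop] = F p(1-p));
* Hardy-Weinberg genotypes within each population
  (dosage ~ Binomial(2, p_pop));
* a sparse 12-cluster weight table whose planted rows exceed the
  inclusion threshold and whose decoy rows do not, so the strict filter
  is exercised;
* T2D status from a logistic liability on the standardized cluster
  scores, with per-population case counts rebalanced toward the cohort
  shape of the study design (62/30, 63/30, 60/30 across the three
  populations);
* log-normal clinical traits with additive log-scale population and
  disease shifts, with weight derived from BMI and height so the derived
  phenotypes are self-consistent.

Population-level pPGS shifts arise from the frequency divergence itself;
``freq_bias`` on a population additionally shifts effect-allele
frequencies at weighted variants to guarantee a target shift size.

Everything is reproducible: each stage derives its generator from
``(seed, stage index)``, so identical configs give byte-identical VCF,
weight-table and phenotype outputs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from ppgskit.geno_io import GenotypeMatrix, VariantRecord, write_vcf
from ppgskit.ppgs import compute_ppgs, standardize_scores
from ppgskit.weights import (
    CLUSTER_NAMES,
    DEFAULT_WEIGHT_THRESHOLD,
    ClusterWeightTable,
    filter_weight_table,
    harmonize,
)

# Non-palindromic ref/alt pairs only: planted variants must survive
# harmonization's palindromic drop.
_ALLELE_PAIRS = [
    ("A", "G"), ("A", "C"), ("T", "G"), ("T", "C"),
    ("G", "A"), ("C", "A"), ("G", "T"), ("C", "T"),
]


@dataclass(frozen=True)
class PopulationConfig:
    """One population: label, cohort shape, divergence, optional bias.

    ``fst`` is the Balding-Nichols divergence F in (0,1); ``freq_bias``
    shifts the effect-allele frequency at weighted variants by a constant
    (clipped to [0.02, 0.98]) to plant a directional pPGS shift.
    """

    label: str
    n_healthy: int = 62
    n_t2d: int = 30
    fst: float = 0.1
    freq_bias: float = 0.0

    @property
    def n_total(self) -> int:
        return self.n_healthy + self.n_t2d


@dataclass(frozen=True)
class TraitModel:
    """Log-normal clinical trait: ln X ~ N(log_mean + shifts, log_sd)."""

    log_mean: float
    log_sd: float
    pop_shift: dict = field(default_factory=dict)
    t2d_shift: float = 0.0


def _default_populations() -> tuple[PopulationConfig, ...]:
    return (
        PopulationConfig("Yakut", 62, 30),
        PopulationConfig("Tatar", 63, 30),
        PopulationConfig("Chechen", 60, 30),
    )


def _default_clinical() -> dict:
    ln = math.log
    return {
        "height": TraitModel(ln(1.68), 0.05),
        "bmi": TraitModel(ln(26.0), 0.15, t2d_shift=0.08),
        "wc": TraitModel(ln(92.0), 0.10, t2d_shift=0.05),
        "hc": TraitModel(ln(100.0), 0.07),
        "sbp": TraitModel(ln(125.0), 0.10, t2d_shift=0.04),
        "dbp": TraitModel(ln(80.0), 0.10, t2d_shift=0.03),
        "tc": TraitModel(ln(5.0), 0.15),
        "ldl": TraitModel(ln(3.0), 0.20),
        "hdl": TraitModel(ln(1.3), 0.18, t2d_shift=-0.05),
        "tg": TraitModel(ln(1.4), 0.35, t2d_shift=0.15),
        "hba1c": TraitModel(ln(5.4), 0.07, t2d_shift=0.25),
    }


@dataclass
class SimulationConfig:
    """Full cohort-simulation configuration.

    Defaults reproduce the study conditions: 3 populations shaped
    62+30 / 63+30 / 60+30 (healthy + T2D), F = 0.1 divergence, sex drawn
    Bernoulli(0.585) for women, age uniform 30-70.  ``n_weighted``
    variants carry an above-threshold weight in one cluster (round-robin
    over the 12 names); an equal number of decoy rows stay below the
    threshold.  ``t2d_gamma`` maps cluster names to planted per-SD
    log-odds (unlisted clusters are 0).
    """

    populations: tuple[PopulationConfig, ...] = field(default_factory=_default_populations)
    n_variants: int = 1000
    n_weighted: int = 60
    weight_scale: float = 1.0
    weight_threshold: float = DEFAULT_WEIGHT_THRESHOLD
    ancestral_freq_range: tuple[float, float] = (0.1, 0.9)
    t2d_beta0: float = math.log(90 / 185)  # cohort prevalence 90/275
    t2d_gamma: dict = field(default_factory=dict)
    t2d_age_effect: float = 0.0
    t2d_sex_effect: float = 0.0
    rebalance: bool = True
    clinical: dict = field(default_factory=_default_clinical)
    missing_rate: float = 0.0
    dr2_absent_fraction: float = 0.1
    dr2_low_fraction: float = 0.15
    sex_female_prob: float = 0.585
    age_range: tuple[float, float] = (30.0, 70.0)
    seed: int = 0

    def __post_init__(self):
        if self.n_weighted > self.n_variants:
            raise ValueError("n_weighted must be <= n_variants")
        for pop in self.populations:
            if not 0.0 < pop.fst < 1.0:
                raise ValueError(f"fst must lie in (0,1), got {pop.fst} for {pop.label}")
        for name, tm in self.clinical.items():
            if tm.log_sd <= 0:
                raise ValueError(f"log_sd must be > 0 for trait {name}")
        lo, hi = self.ancestral_freq_range
        if not (0.05 <= lo < hi <= 0.95):
            raise ValueError("ancestral_freq_range must lie within (0.05, 0.95)")

    @property
    def n_samples(self) -> int:
        return sum(p.n_total for p in self.populations)

    def rng(self, stage: int) -> np.random.Generator:
        return np.random.default_rng([int(self.seed), stage])


# ---------------------------------------------------------------------------
# Variant metadata (shared by frequencies, genotypes and the weight table)


def make_variant_frame(cfg: SimulationConfig) -> pd.DataFrame:
    """Deterministic per-variant metadata: position, alleles, weighted flag.

    The first ``n_weighted`` variants are the planted (above-threshold)
    rows; the next ``n_weighted`` are below-threshold decoys.  Effect
    alleles of planted rows are ALT or REF at random, so harmonization
    flips are exercised.
    """
    rng = cfg.rng(0)
    pair_idx = rng.integers(0, len(_ALLELE_PAIRS), size=cfg.n_variants)
    ref = np.array([_ALLELE_PAIRS[i][0] for i in pair_idx])
    alt = np.array([_ALLELE_PAIRS[i][1] for i in pair_idx])
    weighted = np.zeros(cfg.n_variants, dtype=bool)
    weighted[: cfg.n_weighted] = True
    decoy = np.zeros(cfg.n_variants, dtype=bool)
    decoy[cfg.n_weighted : min(2 * cfg.n_weighted, cfg.n_variants)] = True
    effect_is_alt = rng.random(cfg.n_variants) < 0.5
    return pd.DataFrame(
        {
            "chrom": "1",
            "pos": 10_001 + 100 * np.arange(cfg.n_variants),
            "vid": [f"var{j:05d}" for j in range(cfg.n_variants)],
            "ref": ref,
            "alt": alt,
            "weighted": weighted,
            "decoy": decoy,
            "effect_is_alt": effect_is_alt,
        }
    )


# ---------------------------------------------------------------------------
# Stage operations


def simulate_frequencies(cfg: SimulationConfig) -> pd.DataFrame:
    """Balding-Nichols per-population ALT-allele frequencies.

    Ancestral p_j ~ Uniform(ancestral_freq_range); each population draws
    p_{j,pop} ~ Beta(p_j(1-F)/F, (1-p_j)(1-F)/F) independently.  A
    population's ``freq_bias`` is then applied to its weighted variants on
    the effect-allele scale.  Returns a DataFrame with column ``ancestral``
    plus one column per population label.
    """
    rng = cfg.rng(1)
    vf = make_variant_frame(cfg)
    p_anc = rng.uniform(*cfg.ancestral_freq_range, size=cfg.n_variants)
    out = {"ancestral": p_anc}
    for pop in cfg.populations:
        f = pop.fst
        a = p_anc * (1 - f) / f
        b = (1 - p_anc) * (1 - f) / f
        p = rng.beta(a, b)
        if pop.freq_bias:
            sign = np.where(vf["effect_is_alt"], 1.0, -1.0)  # bias on effect-allele scale
            p = np.where(vf["weighted"], p + pop.freq_bias * sign, p)
        out[pop.label] = np.clip(p, 0.02, 0.98)
    return pd.DataFrame(out)


def simulate_genotypes(
    freqs: pd.DataFrame, cfg: SimulationConfig
) -> tuple[GenotypeMatrix, pd.DataFrame]:
    """HWE genotypes plus a phenotype-table skeleton.

    Dosages are Binomial(2, p_{j,pop}) per sample; optional missingness at
    ``missing_rate`` and per-variant DR2 annotations (weighted/decoy rows
    always imputation-clean so the quality filter never removes planted
    signal; a configured fraction of the rest falls below 0.3 or carries
    no annotation).  The skeleton holds sample_id, population, age, sex.
    """
    rng = cfg.rng(2)
    vf = make_variant_frame(cfg)
    n = cfg.n_samples

    rows = []
    pop_of_sample = []
    for pop in cfg.populations:
        for i in range(pop.n_total):
            rows.append(f"{pop.label}_{i:04d}")
            pop_of_sample.append(pop.label)
    dosage = np.empty((n, cfg.n_variants), dtype=float)
    start = 0
    for pop in cfg.populations:
        p = freqs[pop.label].to_numpy()
        block = rng.binomial(2, p[None, :], size=(pop.n_total, cfg.n_variants))
        dosage[start : start + pop.n_total] = block
        start += pop.n_total

    missing = np.zeros_like(dosage, dtype=bool)
    if cfg.missing_rate > 0:
        missing = rng.random(dosage.shape) < cfg.missing_rate
        dosage[missing] = np.nan

    # DR2: in-table variants clean; others absent / low / passing.
    u = rng.random(cfg.n_variants)
    dr2_draw = rng.uniform(0.3, 1.0, size=cfg.n_variants)
    dr2_low = rng.uniform(0.0, 0.3, size=cfg.n_variants)
    in_table = (vf["weighted"] | vf["decoy"]).to_numpy()
    variants = []
    for j in range(cfg.n_variants):
        if in_table[j]:
            dr2 = float(rng.uniform(0.5, 1.0))
        elif u[j] < cfg.dr2_absent_fraction:
            dr2 = None
        elif u[j] < cfg.dr2_absent_fraction + cfg.dr2_low_fraction:
            dr2 = float(dr2_low[j])
        else:
            dr2 = float(dr2_draw[j])
        variants.append(
            VariantRecord(
                chrom=vf["chrom"].iat[j],
                pos=int(vf["pos"].iat[j]),
                vid=vf["vid"].iat[j],
                ref=vf["ref"].iat[j],
                alt=vf["alt"].iat[j],
                dr2=dr2,
            )
        )

    gm = GenotypeMatrix(samples=rows, variants=variants, dosage=dosage, missing_mask=missing)
    skeleton = pd.DataFrame(
        {
            "sample_id": rows,
            "population": pop_of_sample,
            "age": rng.uniform(*cfg.age_range, size=n).round(1),
            "sex": (rng.random(n) < cfg.sex_female_prob).astype(int),  # 1 = female
        }
    )
    return gm, skeleton


def plant_weights(cfg: SimulationConfig) -> ClusterWeightTable:
    """Sparse planted weight table over the 12 clusters.

    Each of the ``n_weighted`` planted variants receives one cluster
    (round-robin over the canonical cluster order) with weight
    threshold + U(0.05, 0.7) * weight_scale, always strictly above the
    inclusion threshold and monotone in ``weight_scale``.  Decoy rows get
    a single weight drawn strictly below the threshold, so filtering at
    the default threshold retains exactly the planted rows.
    """
    rng = cfg.rng(3)
    vf = make_variant_frame(cfg)
    rows = vf[vf["weighted"] | vf["decoy"]].reset_index(drop=True)
    w = np.zeros((len(rows), 12))
    planted_count = 0
    for i in range(len(rows)):
        if rows["weighted"].iat[i]:
            c = planted_count % 12
            w[i, c] = cfg.weight_threshold + rng.uniform(0.05, 0.7) * cfg.weight_scale
            planted_count += 1
        else:
            c = int(rng.integers(0, 12))
            w[i, c] = rng.uniform(0.01, cfg.weight_threshold * 0.95)
    effect = np.where(rows["effect_is_alt"], rows["alt"], rows["ref"])
    other = np.where(rows["effect_is_alt"], rows["ref"], rows["alt"])
    df = pd.DataFrame(
        {
            "chrom": rows["chrom"],
            "pos": rows["pos"].astype(int),
            "rsid": rows["vid"],
            "effect_allele": effect,
            "other_allele": other,
        }
    )
    for c, name in enumerate(CLUSTER_NAMES):
        df[name] = w[:, c]
    return ClusterWeightTable(rows=df, threshold=cfg.weight_threshold)


def _standardized_planted_scores(gm: GenotypeMatrix, weights: ClusterWeightTable, cfg):
    t = filter_weight_table(weights, cfg.weight_threshold)
    hmap = harmonize(t, gm, drop_palindromic=True)
    return standardize_scores(compute_ppgs(gm, t, hmap, missing_policy="mean_dosage"))


def simulate_t2d(
    gm: GenotypeMatrix,
    weights: ClusterWeightTable,
    skeleton: pd.DataFrame,
    cfg: SimulationConfig,
) -> pd.DataFrame:
    """Assign T2D status from a logistic liability on the cluster scores.

    P(T2D_i) = logistic(beta0 + sum_c gamma_c z_c(i) + age/sex terms).
    With ``rebalance`` the per-population case count is adjusted to the
    configured target by flipping the status of samples chosen with
    probability proportional to their liability (promoting the most
    liable controls, demoting the least liable cases), keeping the
    planted score-status association's direction intact.
    """
    rng = cfg.rng(4)
    if cfg.n_weighted > 0:
        psm = _standardized_planted_scores(gm, weights, cfg)
        z = psm.to_frame().loc[skeleton["sample_id"]]
        gamma = np.array([cfg.t2d_gamma.get(c, 0.0) for c in psm.cluster_names])
        score_term = z.to_numpy() @ gamma
    else:  # no planted architecture: liability from covariates only
        score_term = 0.0
    age = skeleton["age"].to_numpy(dtype=float)
    age_z = (age - age.mean()) / age.std() if age.std() > 0 else np.zeros_like(age)
    lin = (
        cfg.t2d_beta0
        + score_term
        + cfg.t2d_age_effect * age_z
        + cfg.t2d_sex_effect * skeleton["sex"].to_numpy()
    )
    prob = 1.0 / (1.0 + np.exp(-lin))
    status = (rng.random(len(prob)) < prob).astype(int)

    pt = skeleton.copy()
    pt["t2d"] = status
    if cfg.rebalance:
        for pop in cfg.populations:
            m = (pt["population"] == pop.label).to_numpy()
            idx = np.flatnonzero(m)
            cases = idx[pt.loc[idx, "t2d"] == 1]
            controls = idx[pt.loc[idx, "t2d"] == 0]
            excess = len(cases) - pop.n_t2d
            if excess > 0:
                wts = 1.0 - prob[cases]
                demote = rng.choice(cases, size=excess, replace=False, p=wts / wts.sum())
                pt.loc[demote, "t2d"] = 0
            elif excess < 0:
                need = min(-excess, len(controls))
                if need < -excess:
                    import logging

                    logging.getLogger(__name__).warning(
                        "population %s: target %d cases unreachable, achieved %d",
                        pop.label, pop.n_t2d, len(cases) + need,
                    )
                wts = prob[controls]
                promote = rng.choice(controls, size=need, replace=False, p=wts / wts.sum())
                pt.loc[promote, "t2d"] = 1
    return pt


def simulate_clinical(pt: pd.DataFrame, cfg: SimulationConfig) -> pd.DataFrame:
    """Draw log-normal clinical traits with population and T2D shifts.

    ``weight`` is derived as bmi * height^2 so BMI recomputes
    consistently; every measurement is strictly positive by construction.
    """
    rng = cfg.rng(5)
    out = pt.copy()
    n = len(out)
    pop = out["population"].to_numpy()
    t2d = out["t2d"].to_numpy(dtype=float)
    draws = {}
    for trait, tm in cfg.clinical.items():
        shift = np.array([tm.pop_shift.get(p, 0.0) for p in pop])
        mu = tm.log_mean + shift + tm.t2d_shift * t2d
        draws[trait] = np.exp(rng.normal(mu, tm.log_sd, size=n))
    bmi = draws.pop("bmi")
    height = draws.pop("height")
    out["height"] = height.round(3)
    out["weight"] = (bmi * height**2).round(2)
    for trait, vals in draws.items():
        out[trait] = vals.round(3)
    return out


# ---------------------------------------------------------------------------
# Orchestration and truth bookkeeping


@dataclass
class SyntheticCohort:
    """Everything one simulated cohort produced, plus its planted truth."""

    config: SimulationConfig
    genotypes: GenotypeMatrix
    weights: ClusterWeightTable
    phenotypes: pd.DataFrame
    frequencies: pd.DataFrame

    def truth_frame(self) -> pd.DataFrame:
        cfg = self.config
        rows = [
            {"parameter": "t2d_beta0", "scope": "cohort", "value": cfg.t2d_beta0},
            {"parameter": "t2d_age_effect", "scope": "cohort", "value": cfg.t2d_age_effect},
            {"parameter": "t2d_sex_effect", "scope": "cohort", "value": cfg.t2d_sex_effect},
        ]
        for c in CLUSTER_NAMES:
            rows.append({"parameter": "gamma", "scope": c, "value": cfg.t2d_gamma.get(c, 0.0)})
        for pop in cfg.populations:
            rows.append({"parameter": "fst", "scope": pop.label, "value": pop.fst})
            rows.append({"parameter": "freq_bias", "scope": pop.label, "value": pop.freq_bias})
        for trait, tm in cfg.clinical.items():
            rows.append({"parameter": f"{trait}_t2d_shift", "scope": "cohort", "value": tm.t2d_shift})
            for p, s in tm.pop_shift.items():
                rows.append({"parameter": f"{trait}_pop_shift", "scope": p, "value": s})
        return pd.DataFrame(rows)

    def write(self, out_dir: str) -> dict:
        """Write VCF (GT+DS+DR2), weight TSV, phenotype TSV and truth TSV."""
        import os

        os.makedirs(out_dir, exist_ok=True)
        paths = {
            "vcf": os.path.join(out_dir, "cohort.vcf"),
            "weights": os.path.join(out_dir, "weights.tsv"),
            "phenotypes": os.path.join(out_dir, "phenotypes.tsv"),
            "truth": os.path.join(out_dir, "truth.tsv"),
        }
        write_vcf(self.genotypes, paths["vcf"], write_ds=True)
        self.weights.to_tsv(paths["weights"])
        self.phenotypes.to_csv(paths["phenotypes"], sep="\t", index=False)
        self.truth_frame().to_csv(paths["truth"], sep="\t", index=False)
        return paths


def simulate_cohort(cfg: SimulationConfig) -> SyntheticCohort:
    """Run all simulation stages in order for one seeded cohort."""
    freqs = simulate_frequencies(cfg)
    gm, skeleton = simulate_genotypes(freqs, cfg)
    weights = plant_weights(cfg)
    pt = simulate_t2d(gm, weights, skeleton, cfg)
    pt = simulate_clinical(pt, cfg)
    return SyntheticCohort(
        config=cfg, genotypes=gm, weights=weights, phenotypes=pt, frequencies=freqs
    )


def hudson_fst(dosage_a: np.ndarray, dosage_b: np.ndarray) -> float:
    """Hudson FST estimator (ratio of averages) between two populations.

    Takes samples x variants dosage arrays; uses the unbiased per-variant
    numerator (p1-p2)^2 - p1(1-p1)/(n1-1) - p2(1-p2)/(n2-1) over
    denominator p1(1-p2) + p2(1-p1).  Between two populations each
    diverged at F from a shared ancestor this estimates F.
    """
    a = np.asarray(dosage_a, dtype=float)
    b = np.asarray(dosage_b, dtype=float)
    n1 = 2 * a.shape[0]
    n2 = 2 * b.shape[0]
    p1 = a.mean(axis=0) / 2
    p2 = b.mean(axis=0) / 2
    num = (p1 - p2) ** 2 - p1 * (1 - p1) / (n1 - 1) - p2 * (1 - p2) / (n2 - 1)
    den = p1 * (1 - p2) + p2 * (1 - p1)
    return float(num.sum() / den.sum())
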