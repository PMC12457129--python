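"""Association battery for ancestry-stratified T2D analyses.

Implements the statistical layer of the study design: derived
anthropometric phenotypes (BMI, WHR, atherogenic index), natural-log
transformation of right-skewed traits, standardized ordinary least
squares (betas in outcome SDs per predictor SD), population and
population x T2D interaction scans with dummy-coded ancestry against a
declared reference population, per-cluster logistic models of T2D on
standardized pPGS with Wald odds-ratio CIs under four covariate tiers,
Mann-Whitney group comparisons, Pearson correlation, Benjamini-Hochberg
step-up adjustment, and a per-SNP one-vs-rest population scan.

BH families are per scan table (the most conservative reading of
"correction for multiple comparisons"): one family for the phenotype
scan, one for the interaction scan, one across the 12 clusters of the
logistic battery, and one across SNPs within each population of the
per-SNP scan.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
import scipy.stats
import statsmodels.api as sm
from statsmodels.stats.multitest import multipletests
from statsmodels.tools.sm_exceptions import PerfectSeparationError

from ppgskit.geno_io import GenotypeMatrix
from ppgskit.ppgs import PartitionedScoreMatrix

logger = logging.getLogger(__name__)

#: Traits log-transformed by default before regression (LDL is analyzed
#: untransformed; configurable via the ``fields`` argument).
DEFAULT_LOG_FIELDS = (
    "bmi", "tg", "wc", "hc", "whr", "sbp", "dbp", "tc", "hdl", "aip", "hba1c",
)

COVARIATE_TIERS = ("none", "age_sex_bmi", "plus_ancestry_labels", "plus_10PCs")


@dataclass(frozen=True)
class AssociationResult:
    """One model term: effect estimate, 95% CI, raw and BH-adjusted p.

    ``estimate`` is a standardized beta for linear models and an odds
    ratio for logistic ones; ``separated`` flags logistic fits with
    (quasi-)complete separation, whose CI is infinite.
    """

    term: str
    estimate: float
    ci_low: float
    ci_high: float
    p_raw: float
    p_adj: float | None
    model: str
    n: int
    separated: bool = False


def results_to_frame(results: list[AssociationResult]) -> pd.DataFrame:
    return pd.DataFrame([r.__dict__ for r in results])


# ---------------------------------------------------------------------------
# Derived phenotypes and transformations


def compute_derived_phenotypes(pt: pd.DataFrame) -> pd.DataFrame:
    """Add bmi = weight/height^2, whr = wc/hc, aip = (tc - hdl)/hdl.

    Units: weight kg, height m, circumferences cm, lipids mmol/L.
    Nonpositive denominators yield a missing value for that sample plus a
    warning; inputs are untouched.
    """
    out = pt.copy()

    def _safe_div(num: pd.Series, den: pd.Series, name: str) -> pd.Series:
        bad = den <= 0
        if bad.any():
            logger.warning("%s: %d samples with nonpositive denominator set missing", name, int(bad.sum()))
        return num.where(~bad) / den.where(~bad)

    if {"weight", "height"} <= set(out.columns):
        out["bmi"] = _safe_div(out["weight"], out["height"] ** 2, "bmi")
    if {"wc", "hc"} <= set(out.columns):
        out["whr"] = _safe_div(out["wc"], out["hc"], "whr")
    if {"tc", "hdl"} <= set(out.columns):
        out["aip"] = _safe_div(out["tc"] - out["hdl"], out["hdl"], "aip")
    return out


def log_transform(pt: pd.DataFrame, fields: tuple[str, ...] = DEFAULT_LOG_FIELDS) -> pd.DataFrame:
    """Natural-log transform the listed fields (skipping absent columns).

    Raises naming the first offending sample and field if a value is
    nonpositive; missing values stay missing.
    """
    out = pt.copy()
    for f in fields:
        if f not in out.columns:
            continue
        col = out[f]
        bad = col.notna() & (col <= 0)
        if bad.any():
            idx = col.index[bad][0]
            raise ValueError(f"cannot log-transform {f!r}: nonpositive value at sample {idx!r}")
        out[f] = np.log(col)
    return out


def _zscore(x: np.ndarray) -> np.ndarray:
    sd = x.std(ddof=0)
    if sd == 0:
        raise ValueError("zero-variance column cannot be z-scored")
    return (x - x.mean()) / sd


def _is_binary(x: np.ndarray) -> bool:
    vals = np.unique(x[np.isfinite(x)])
    return vals.size <= 2 and np.all(np.isin(vals, (0.0, 1.0)))


# ---------------------------------------------------------------------------
# Linear models


def _build_design(
    pt: pd.DataFrame, terms: list[str], standardize: bool = True
) -> pd.DataFrame:
    """Design columns for the named terms; continuous terms z-scored,
    binary (0/1) terms left as-is."""
    cols = {}
    for t in terms:
        x = pt[t].to_numpy(dtype=float)
        cols[t] = x if (_is_binary(x) or not standardize) else _zscore(x)
    return pd.DataFrame(cols, index=pt.index)


def standardized_ols(
    outcome: str,
    predictor: str,
    covariates: list[str],
    pt: pd.DataFrame,
) -> AssociationResult:
    """OLS of z-scored outcome on z-scored predictor plus covariates.

    The reported beta is in outcome SDs per predictor SD (binary
    covariates enter as 0/1 and are not scaled); p-values are the standard
    two-tailed t-tests.  Raises on rank-deficient designs, listing the
    collinear terms.
    """
    data = pt[[outcome, predictor, *covariates]].dropna()
    y = _zscore(data[outcome].to_numpy(dtype=float))
    X = _build_design(data, [predictor, *covariates])
    X = sm.add_constant(X)
    if len(data) <= X.shape[1]:
        raise ValueError(f"n={len(data)} too small for {X.shape[1]} design columns")
    if np.linalg.matrix_rank(X.to_numpy()) < X.shape[1]:
        raise ValueError(f"rank-deficient design over terms {list(X.columns)}")
    fit = sm.OLS(y, X).fit()
    ci = fit.conf_int().loc[predictor]
    return AssociationResult(
        term=predictor,
        estimate=float(fit.params[predictor]),
        ci_low=float(ci[0]),
        ci_high=float(ci[1]),
        p_raw=float(fit.pvalues[predictor]),
        p_adj=None,
        model=f"ols: z({outcome}) ~ z({predictor}) + {' + '.join(covariates) or '1'}",
        n=len(data),
    )


def _population_dummies(pt: pd.DataFrame, reference_pop: str) -> pd.DataFrame:
    pops = pt["population"].astype(str)
    levels = sorted(pops.unique())
    if reference_pop not in levels:
        raise ValueError(f"reference population {reference_pop!r} absent; have {levels}")
    if len(levels) < 2:
        raise ValueError("at least 2 populations are required")
    dummies = pd.get_dummies(pops, prefix="pop", prefix_sep="=").astype(float)
    return dummies.drop(columns=f"pop={reference_pop}")


def _apply_bh(results: list[AssociationResult]) -> list[AssociationResult]:
    if not results:
        return results
    adj = bh_adjust(np.array([r.p_raw for r in results]))
    return [replace(r, p_adj=float(a)) for r, a in zip(results, adj)]


def population_phenotype_scan(
    pt: pd.DataFrame,
    reference_pop: str,
    phenotypes: list[str],
) -> list[AssociationResult]:
    """Effect of ancestry on each phenotype, adjusted for T2D, age, sex.

    Each phenotype is z-scored and regressed on population dummies (the
    reference category omitted) with T2D status, z(age) and sex as
    covariates; BH is applied across the whole scan (one family).
    """
    results: list[AssociationResult] = []
    for pheno in phenotypes:
        data = pt[[pheno, "population", "t2d", "age", "sex"]].dropna()
        y = _zscore(data[pheno].to_numpy(dtype=float))
        X = pd.concat(
            [_population_dummies(data, reference_pop), _build_design(data, ["t2d", "age", "sex"])],
            axis=1,
        )
        X = sm.add_constant(X)
        fit = sm.OLS(y, X).fit()
        for term in X.columns:
            if not term.startswith("pop="):
                continue
            ci = fit.conf_int().loc[term]
            results.append(
                AssociationResult(
                    term=f"{pheno}~{term}",
                    estimate=float(fit.params[term]),
                    ci_low=float(ci[0]),
                    ci_high=float(ci[1]),
                    p_raw=float(fit.pvalues[term]),
                    p_adj=None,
                    model=f"ols: z({pheno}) ~ population + t2d + z(age) + sex (ref={reference_pop})",
                    n=len(data),
                )
            )
    return _apply_bh(results)


def interaction_scan(
    pt: pd.DataFrame,
    reference_pop: str,
    phenotypes: list[str],
) -> list[AssociationResult]:
    """Population x T2D interaction effects on each phenotype.

    The model adds population:t2d product columns to the main-effect
    design; only the interaction terms are reported, BH-adjusted as one
    family.  Raises naming the cell if any population lacks T2D cases or
    controls.
    """
    cells = pt.groupby(["population", "t2d"], observed=True).size()
    for pop in pt["population"].unique():
        for status in (0, 1):
            if (pop, status) not in cells.index:
                raise ValueError(f"empty cell: population={pop!r}, t2d={status}")

    results: list[AssociationResult] = []
    for pheno in phenotypes:
        data = pt[[pheno, "population", "t2d", "age", "sex"]].dropna()
        y = _zscore(data[pheno].to_numpy(dtype=float))
        dummies = _population_dummies(data, reference_pop)
        t2d = data["t2d"].to_numpy(dtype=float)
        inter = dummies.mul(t2d, axis=0)
        inter.columns = [f"{c}:t2d" for c in dummies.columns]
        X = pd.concat([dummies, _build_design(data, ["t2d", "age", "sex"]), inter], axis=1)
        X = sm.add_constant(X)
        fit = sm.OLS(y, X).fit()
        for term in inter.columns:
            ci = fit.conf_int().loc[term]
            results.append(
                AssociationResult(
                    term=f"{pheno}~{term}",
                    estimate=float(fit.params[term]),
                    ci_low=float(ci[0]),
                    ci_high=float(ci[1]),
                    p_raw=float(fit.pvalues[term]),
                    p_adj=None,
                    model=f"ols: z({pheno}) ~ population * t2d + z(age) + sex (ref={reference_pop})",
                    n=len(data),
                )
            )
    return _apply_bh(results)


# ---------------------------------------------------------------------------
# Logistic models


def fit_logistic_term(
    y: np.ndarray, X: pd.DataFrame, term: str, model_desc: str
) -> AssociationResult:
    """Logistic fit reporting exp(beta) for ``term`` with Wald 95% CI.

    Complete separation is flagged (infinite CI), not raised.
    """
    n = len(y)
    try:
        fit = sm.Logit(y, X).fit(disp=0, maxiter=100)
        b = float(fit.params[term])
        se = float(fit.bse[term])
        separated = not np.isfinite(se) or se > 1e3 or not fit.mle_retvals.get("converged", True)
    except (PerfectSeparationError, np.linalg.LinAlgError):
        b, se, separated = np.nan, np.inf, True
    if separated:
        return AssociationResult(
            term=term, estimate=float(np.exp(b)) if np.isfinite(b) else np.inf,
            ci_low=0.0, ci_high=np.inf, p_raw=1.0, p_adj=None,
            model=model_desc, n=n, separated=True,
        )
    z = scipy.stats.norm.ppf(0.975)
    p = 2.0 * scipy.stats.norm.sf(abs(b / se))
    return AssociationResult(
        term=term,
        estimate=float(np.exp(b)),
        ci_low=float(np.exp(b - z * se)),
        ci_high=float(np.exp(b + z * se)),
        p_raw=float(p),
        p_adj=None,
        model=model_desc,
        n=n,
    )


def ppgs_t2d_logistic(
    psm: PartitionedScoreMatrix,
    pt: pd.DataFrame,
    covariate_tier: str = "age_sex_bmi",
    pcs: pd.DataFrame | None = None,
    reference_pop: str | None = None,
) -> list[AssociationResult]:
    """Logistic T2D models, one per cluster, on the standardized score.

    Covariate tiers: ``none``; ``age_sex_bmi`` (z(age), sex, z(bmi));
    ``plus_ancestry_labels`` additionally adds population dummies;
    ``plus_10PCs`` instead adds the first 10 genotype PCs (``pcs``
    required).  The odds ratio is exp(beta) per score SD with a Wald 95%
    CI; BH is applied across the 12 clusters.
    """
    if covariate_tier not in COVARIATE_TIERS:
        raise ValueError(f"unknown covariate tier {covariate_tier!r}")
    scores = psm.to_frame()
    data = pt.set_index("sample_id") if "sample_id" in pt.columns else pt
    data = data.loc[scores.index]
    y = data["t2d"].to_numpy(dtype=float)
    if len(np.unique(y)) < 2:
        raise ValueError("T2D status is constant in the analyzed set")

    cov = pd.DataFrame(index=scores.index)
    if covariate_tier != "none":
        cov = _build_design(data, ["age", "sex", "bmi"])
    if covariate_tier == "plus_ancestry_labels":
        ref = reference_pop or sorted(data["population"].astype(str).unique())[0]
        cov = pd.concat([cov, _population_dummies(data, ref)], axis=1)
    elif covariate_tier == "plus_10PCs":
        if pcs is None:
            raise ValueError("plus_10PCs tier requires the pcs coordinate table")
        pc_cols = [c for c in pcs.columns if c.upper().startswith("PC")][:10]
        cov = pd.concat([cov, pcs.loc[scores.index, pc_cols]], axis=1)

    results = []
    for cluster in psm.cluster_names:
        x = scores[cluster].to_numpy(dtype=float)
        x = x if psm.standardized else _zscore(x)
        X = pd.concat([pd.Series(x, index=scores.index, name="score"), cov], axis=1)
        X = sm.add_constant(X.astype(float))
        res = fit_logistic_term(
            y, X, "score", f"logit: t2d ~ z(pPGS[{cluster}]) + tier={covariate_tier}"
        )
        results.append(replace(res, term=cluster))
    return _apply_bh(results)


def per_snp_population_scan(
    gm: GenotypeMatrix, pt: pd.DataFrame
) -> list[AssociationResult]:
    """One-vs-rest logistic test of each SNP against each population.

    For every population the indicator (this population vs all others) is
    regressed on the ALT dosage, SNP by SNP; missing dosages are mean
    -imputed.  Monomorphic SNPs are skipped (reason-coded in the model
    string, never raised); BH runs across SNPs within each population.
    """
    pops = sorted(pt["population"].astype(str).unique())
    if len(pops) < 2:
        raise ValueError("at least 2 populations are required")
    order = pt.set_index("sample_id") if "sample_id" in pt.columns else pt
    order = order.loc[gm.samples]

    all_results: list[AssociationResult] = []
    d = np.where(gm.missing_mask, np.nan, gm.dosage)
    col_mean = np.nanmean(d, axis=0)
    d = np.where(np.isnan(d), col_mean[None, :], d)

    for pop in pops:
        y = (order["population"].astype(str) == pop).to_numpy(dtype=float)
        pop_results: list[AssociationResult] = []
        for j, v in enumerate(gm.variants):
            x = d[:, j]
            if np.all(x == x[0]):
                all_results.append(
                    AssociationResult(
                        term=f"{pop}~{v.key}", estimate=np.nan, ci_low=np.nan,
                        ci_high=np.nan, p_raw=np.nan, p_adj=None,
                        model="skipped: monomorphic", n=len(y),
                    )
                )
                continue
            X = sm.add_constant(pd.DataFrame({"dosage": x}))
            res = fit_logistic_term(y, X, "dosage", f"logit: I(pop={pop}) ~ dosage")
            pop_results.append(replace(res, term=f"{pop}~{v.key}"))
        all_results.extend(_apply_bh(pop_results))
    return all_results


# ---------------------------------------------------------------------------
# Nonparametric and adjustment primitives


def mann_whitney(a, b) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test; returns ``(U_a, p)``.

    Uses the exact null distribution when min(n_a, n_b) <= 8 and there
    are no ties across the pooled sample, else the tie-corrected normal
    approximation (no continuity correction, so U equal to its null mean
    gives p = 1 exactly).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([a, b])
    has_ties = np.unique(pooled).size < pooled.size
    exact = min(a.size, b.size) <= 8 and not has_ties
    res = scipy.stats.mannwhitneyu(
        a, b,
        alternative="two-sided",
        method="exact" if exact else "asymptotic",
        use_continuity=False,
    )
    return float(res.statistic), float(min(res.pvalue, 1.0))


def pearson_corr(x, y) -> float:
    """Sample Pearson correlation; requires equal length >= 3 and positive
    variance in both vectors."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("vectors must have equal length >= 3")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("zero-variance input")
    return float(scipy.stats.pearsonr(x, y).statistic)


def bh_adjust(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, capped at 1."""
    p = np.asarray(p, dtype=float)
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    if p.size == 0:
        return p.copy()
    return multipletests(p, method="fdr_bh")[1]
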