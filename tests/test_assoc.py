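"""The association battery: derived traits, regressions, nonparametrics, BH."""

import itertools

import numpy as np
import pandas as pd
import pytest
import scipy.stats

from ppgskit.assoc import (
    bh_adjust,
    compute_derived_phenotypes,
    fit_logistic_term,
    interaction_scan,
    log_transform,
    mann_whitney,
    pearson_corr,
    per_snp_population_scan,
    population_phenotype_scan,
    ppgs_t2d_logistic,
    standardized_ols,
)
from ppgskit.ppgs import PartitionedScoreMatrix
from ppgskit.weights import CLUSTER_NAMES

from conftest import make_gm


# ---------------------------------------------------------------------------
# Oracles used by several tests


def bh_stepup_oracle(p):
    """Direct Benjamini-Hochberg step-up: p_(i) * m / i with monotone
    enforcement from the largest rank down, capped at 1."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    adj = np.empty(m)
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, p[i] * m / rank)
        adj[i] = running
    return adj


def mw_exact_enumeration(a, b):
    """Two-sided exact Mann-Whitney p by full enumeration of group
    assignments of the pooled sample (no ties assumed)."""
    pooled = np.concatenate([a, b])
    n_a = len(a)
    ranks = scipy.stats.rankdata(pooled)
    u_obs = ranks[:n_a].sum() - n_a * (n_a + 1) / 2
    mean_u = n_a * len(b) / 2
    us = []
    for comb in itertools.combinations(range(len(pooled)), n_a):
        u = ranks[list(comb)].sum() - n_a * (n_a + 1) / 2
        us.append(u)
    us = np.array(us)
    # two-sided: as or more extreme in |U - mean|
    return float(np.mean(np.abs(us - mean_u) >= abs(u_obs - mean_u) - 1e-12))


# ---------------------------------------------------------------------------


class TestDerivedPhenotypes:
    def test_bmi_whr_aip_arithmetic(self):
        pt = pd.DataFrame(
            {"weight": [81.0], "height": [1.8], "wc": [90.0], "hc": [90.0],
             "tc": [5.0], "hdl": [1.0]}
        )
        out = compute_derived_phenotypes(pt)
        assert out["bmi"].iloc[0] == pytest.approx(25.0)
        assert out["whr"].iloc[0] == pytest.approx(1.0)
        assert out["aip"].iloc[0] == pytest.approx(4.0)
        assert "bmi" not in pt.columns  # input untouched

    def test_nonpositive_denominator_yields_missing(self, caplog):
        pt = pd.DataFrame({"wc": [90.0, 80.0], "hc": [0.0, 100.0]})
        with caplog.at_level("WARNING"):
            out = compute_derived_phenotypes(pt)
        assert np.isnan(out["whr"].iloc[0]) and out["whr"].iloc[1] == 0.8


class TestLogTransform:
    def test_unit_values(self):
        pt = pd.DataFrame({"bmi": [1.0, np.e]})
        out = log_transform(pt, ("bmi",))
        assert np.allclose(out["bmi"], [0.0, 1.0])

    def test_nonpositive_names_sample_and_field(self):
        pt = pd.DataFrame({"tg": [1.0, -2.0]}, index=["s0", "s1"])
        with pytest.raises(ValueError, match="tg.*s1"):
            log_transform(pt, ("tg",))

    def test_lognormal_becomes_normal(self):
        # ln of a lognormal(0, 0.5) sample passes Shapiro-Wilk at alpha=0.01
        passed = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            pt = pd.DataFrame({"tg": np.exp(rng.normal(0, 0.5, size=500))})
            out = log_transform(pt, ("tg",))
            if scipy.stats.shapiro(out["tg"]).pvalue > 0.01:
                passed += 1
        assert passed >= 19


class TestStandardizedOls:
    def test_identity_fit(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=50)
        pt = pd.DataFrame({"y": x, "x": x})
        res = standardized_ols("y", "x", [], pt)
        assert res.estimate == pytest.approx(1.0)
        assert res.p_raw < 1e-30

    def test_simple_beta_equals_pearson(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=80)
        y = 0.3 * x + rng.normal(size=80)
        pt = pd.DataFrame({"y": y, "x": x})
        res = standardized_ols("y", "x", [], pt)
        assert abs(res.estimate - pearson_corr(x, y)) < 1e-10

    def test_planted_effect_recovered(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=1000)
        y = 0.4 * x + rng.normal(size=1000) * np.sqrt(1 - 0.4**2)
        pt = pd.DataFrame({"y": y, "x": x, "sex": rng.integers(0, 2, 1000)})
        res = standardized_ols("y", "x", ["sex"], pt)
        se = (res.ci_high - res.ci_low) / (2 * 1.96)
        assert abs(res.estimate - 0.4) < 2 * se

    def test_rank_deficient_design_raises(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=30)
        pt = pd.DataFrame({"y": rng.normal(size=30), "x": x, "x2": 2 * x})
        with pytest.raises(ValueError, match="rank-deficient"):
            standardized_ols("y", "x", ["x2"], pt)


def _clinical_pt(rng, n_per_pop=90, bmi_shift_pop=None, shift=0.0,
                 hdl_t2d_interaction_pop=None, delta=0.0):
    """Minimal phenotype table: 3 populations, lognormal traits."""
    pops = np.repeat(["P1", "P2", "P3"], n_per_pop)
    n = len(pops)
    t2d = rng.integers(0, 2, n)
    log_bmi = rng.normal(np.log(26), 0.15, n)
    if bmi_shift_pop:
        log_bmi += np.where(pops == bmi_shift_pop, shift * 0.15, 0.0)
    log_hdl = rng.normal(np.log(1.3), 0.18, n)
    if hdl_t2d_interaction_pop:
        log_hdl += np.where((pops == hdl_t2d_interaction_pop) & (t2d == 1), delta * 0.18, 0.0)
    return pd.DataFrame(
        {
            "population": pops,
            "t2d": t2d,
            "age": rng.uniform(30, 70, n),
            "sex": rng.integers(0, 2, n),
            "bmi": np.exp(log_bmi),
            "hdl": np.exp(log_hdl),
        }
    )


class TestPopulationScan:
    def test_planted_bmi_shift_detected(self):
        detected = 0
        for seed in range(15):
            rng = np.random.default_rng(seed)
            pt = log_transform(_clinical_pt(rng, bmi_shift_pop="P3", shift=0.8),
                               ("bmi", "hdl"))
            res = population_phenotype_scan(pt, "P1", ["bmi", "hdl"])
            hit = [r for r in res if r.term == "bmi~pop=P3"]
            if hit[0].p_adj <= 0.05:
                detected += 1
        assert detected >= 13  # >= ~90% power at +0.8 SD

    def test_null_type_i_error_controlled(self):
        n_terms = sig = 0
        for seed in range(40):
            rng = np.random.default_rng(1000 + seed)
            pt = log_transform(_clinical_pt(rng), ("bmi", "hdl"))
            res = population_phenotype_scan(pt, "P1", ["bmi", "hdl"])
            n_terms += len(res)
            sig += sum(r.p_adj <= 0.05 for r in res)
        assert sig / n_terms <= 0.05

    def test_single_population_raises(self):
        rng = np.random.default_rng(0)
        pt = _clinical_pt(rng)
        pt["population"] = "P1"
        with pytest.raises(ValueError, match="2 populations"):
            population_phenotype_scan(log_transform(pt, ("bmi",)), "P1", ["bmi"])

    def test_missing_reference_raises(self):
        rng = np.random.default_rng(0)
        pt = log_transform(_clinical_pt(rng), ("bmi",))
        with pytest.raises(ValueError, match="reference"):
            population_phenotype_scan(pt, "Zulu", ["bmi"])


class TestInteractionScan:
    def test_three_populations_give_two_interaction_terms(self):
        rng = np.random.default_rng(4)
        pt = log_transform(_clinical_pt(rng), ("bmi", "hdl"))
        res = interaction_scan(pt, "P1", ["bmi"])
        assert sorted(r.term for r in res) == ["bmi~pop=P2:t2d", "bmi~pop=P3:t2d"]

    def test_planted_interaction_recovered(self):
        rng = np.random.default_rng(5)
        pt = log_transform(
            _clinical_pt(rng, n_per_pop=200, hdl_t2d_interaction_pop="P2", delta=0.5),
            ("bmi", "hdl"),
        )
        res = interaction_scan(pt, "P1", ["hdl"])
        hit = [r for r in res if r.term == "hdl~pop=P2:t2d"][0]
        se = (hit.ci_high - hit.ci_low) / (2 * 1.96)
        assert abs(hit.estimate - 0.5) < 2 * se

    def test_empty_cell_names_the_cell(self):
        rng = np.random.default_rng(6)
        pt = _clinical_pt(rng)
        pt.loc[pt["population"] == "P2", "t2d"] = 0
        with pytest.raises(ValueError, match="P2"):
            interaction_scan(log_transform(pt, ("bmi",)), "P1", ["bmi"])

    def test_null_interaction_type_i_error(self):
        n_terms = sig = 0
        for seed in range(40):
            rng = np.random.default_rng(2000 + seed)
            pt = log_transform(_clinical_pt(rng), ("bmi", "hdl"))
            res = interaction_scan(pt, "P1", ["bmi", "hdl"])
            n_terms += len(res)
            sig += sum(r.p_raw <= 0.05 for r in res)
        assert sig / n_terms <= 0.07


def _psm_from_scores(scores, standardized=True):
    n = scores.shape[0]
    return PartitionedScoreMatrix(
        samples=[f"s{i}" for i in range(n)],
        cluster_names=CLUSTER_NAMES,
        score=scores,
        n_variants_used=np.ones(12, dtype=int),
        standardized=standardized,
    )


class TestLogisticBattery:
    def test_contingency_table_odds_ratio(self):
        # exposed cases a=20, exposed controls b=80, unexposed cases c=10,
        # unexposed controls d=90 -> OR = ad/bc = 2.25
        y = np.concatenate([np.ones(20), np.zeros(80), np.ones(10), np.zeros(90)])
        x = np.concatenate([np.ones(100), np.zeros(100)])
        import statsmodels.api as sm

        X = sm.add_constant(pd.DataFrame({"x": x}))
        res = fit_logistic_term(y, X, "x", "logit: 2x2")
        assert abs(res.estimate - 2.25) < 1e-6

    def test_null_scores_give_or_near_one(self):
        rng = np.random.default_rng(7)
        scores = rng.normal(size=(600, 12))
        pt = pd.DataFrame(
            {"sample_id": [f"s{i}" for i in range(600)],
             "t2d": rng.integers(0, 2, 600)}
        )
        res = ppgs_t2d_logistic(_psm_from_scores(scores), pt, "none")
        assert sum(r.p_adj <= 0.05 for r in res) <= 1
        assert abs(np.median([np.log(r.estimate) for r in res])) < 0.1

    def test_planted_log_odds_recovered(self):
        rng = np.random.default_rng(8)
        scores = rng.normal(size=(2000, 12))
        eta = -0.7 + 0.6 * scores[:, 0]
        y = (rng.random(2000) < 1 / (1 + np.exp(-eta))).astype(int)
        pt = pd.DataFrame({"sample_id": [f"s{i}" for i in range(2000)], "t2d": y})
        res = ppgs_t2d_logistic(_psm_from_scores(scores), pt, "none")
        r = res[0]
        log_or = np.log(r.estimate)
        se = (np.log(r.ci_high) - np.log(r.ci_low)) / (2 * 1.96)
        assert abs(log_or - 0.6) < 2 * se

    def test_complete_separation_flagged_not_raised(self):
        scores = np.zeros((40, 12))
        scores[:, 0] = np.concatenate([np.full(20, -3.0), np.full(20, 3.0)])
        scores[:, 1:] = np.random.default_rng(9).normal(size=(40, 11))
        y = np.concatenate([np.zeros(20), np.ones(20)])
        pt = pd.DataFrame({"sample_id": [f"s{i}" for i in range(40)], "t2d": y})
        res = ppgs_t2d_logistic(_psm_from_scores(scores), pt, "none")
        assert res[0].separated and np.isinf(res[0].ci_high)

    def test_constant_status_raises(self):
        scores = np.random.default_rng(10).normal(size=(30, 12))
        pt = pd.DataFrame({"sample_id": [f"s{i}" for i in range(30)], "t2d": 1})
        with pytest.raises(ValueError, match="constant"):
            ppgs_t2d_logistic(_psm_from_scores(scores), pt, "none")

    def test_covariate_tiers_run(self, small_cohort):
        from ppgskit import ancestry
        from ppgskit.assoc import compute_derived_phenotypes, log_transform
        from ppgskit.ppgs import compute_ppgs, standardize_scores
        from ppgskit.weights import filter_weight_table, harmonize

        gm = small_cohort.genotypes
        t = filter_weight_table(small_cohort.weights)
        hmap = harmonize(t, gm)
        psm = standardize_scores(compute_ppgs(gm, t, hmap))
        pt = log_transform(compute_derived_phenotypes(small_cohort.phenotypes))
        pcs = ancestry.pca(gm, k=10).to_frame()
        for tier in ("none", "age_sex_bmi", "plus_ancestry_labels", "plus_10PCs"):
            res = ppgs_t2d_logistic(psm, pt, tier, pcs=pcs, reference_pop="Tatar")
            assert len(res) == 12
            assert all(r.p_adj >= r.p_raw - 1e-12 for r in res if not r.separated)


class TestMannWhitney:
    def test_small_exact_examples(self):
        u, p = mann_whitney([1, 2], [3, 4])
        assert u == 0 and p == pytest.approx(1 / 3)
        u, p = mann_whitney([1, 2, 3], [4, 5, 6])
        assert u == 0 and p == pytest.approx(0.1)

    def test_identical_groups_give_p_one(self):
        _, p = mann_whitney([1, 2, 3], [1, 2, 3])
        assert p == pytest.approx(1.0)

    def test_empty_group_raises(self):
        with pytest.raises(ValueError):
            mann_whitney([], [1.0])

    @pytest.mark.parametrize("na,nb", [(2, 2), (2, 3), (3, 3), (2, 4), (4, 4)])
    def test_exact_branch_matches_enumeration(self, na, nb):
        rng = np.random.default_rng(na * 10 + nb)
        a = rng.normal(size=na)
        b = rng.normal(size=nb)
        _, p = mann_whitney(a, b)
        assert p == pytest.approx(mw_exact_enumeration(a, b), abs=1e-12)


class TestPearson:
    def test_identity_and_antisymmetry(self):
        x = np.array([1.0, 2.0, 5.0, 3.0])
        assert pearson_corr(x, x) == pytest.approx(1.0)
        assert pearson_corr(x, -x) == pytest.approx(-1.0)

    def test_closed_form_half(self):
        assert pearson_corr([1, 2, 3], [1, 3, 2]) == pytest.approx(0.5)

    def test_errors(self):
        with pytest.raises(ValueError):
            pearson_corr([1, 2], [1, 2])
        with pytest.raises(ValueError):
            pearson_corr([1, 1, 1], [1, 2, 3])


class TestBhAdjust:
    def test_single_p_unchanged(self):
        assert bh_adjust([0.37])[0] == pytest.approx(0.37)

    def test_stepup_example(self):
        adj = bh_adjust([0.01, 0.02, 0.03, 0.5])
        assert np.allclose(adj, [0.04, 0.04, 0.04, 0.5])

    def test_all_ones_capped(self):
        assert np.all(bh_adjust([1.0, 1.0, 1.0]) == 1.0)

    def test_out_of_range_raises(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.2])

    def test_matches_stepup_oracle_on_random_vectors(self):
        rng = np.random.default_rng(11)
        for _ in range(100):
            p = rng.random(rng.integers(1, 40))
            assert np.allclose(bh_adjust(p), bh_stepup_oracle(p), atol=1e-12)


class TestPerSnpScan:
    def _pt(self, n):
        return pd.DataFrame(
            {"sample_id": [f"s{i}" for i in range(2 * n)],
             "population": ["A"] * n + ["B"] * n}
        )

    def test_planted_frequency_difference_detected(self):
        rng = np.random.default_rng(12)
        n = 150
        d = np.column_stack(
            [
                np.concatenate([rng.binomial(2, 0.2, n), rng.binomial(2, 0.6, n)]),
                np.concatenate([rng.binomial(2, 0.5, n), rng.binomial(2, 0.5, n)]),
            ]
        ).astype(float)
        gm = make_gm(d, samples=[f"s{i}" for i in range(2 * n)])
        res = per_snp_population_scan(gm, self._pt(n))
        hit = [r for r in res if r.term == f"A~{gm.variants[0].key}"][0]
        assert hit.p_adj <= 0.05

    def test_monomorphic_snp_skipped(self):
        rng = np.random.default_rng(13)
        n = 30
        d = np.column_stack(
            [np.zeros(2 * n), rng.binomial(2, 0.5, 2 * n)]
        ).astype(float)
        gm = make_gm(d, samples=[f"s{i}" for i in range(2 * n)])
        res = per_snp_population_scan(gm, self._pt(n))
        skipped = [r for r in res if "monomorphic" in r.model]
        assert len(skipped) == 2  # once per population

    def test_null_type_i_error(self):
        sig = total = 0
        for seed in range(30):
            rng = np.random.default_rng(3000 + seed)
            n = 60
            d = rng.binomial(2, 0.4, size=(2 * n, 4)).astype(float)
            gm = make_gm(d, samples=[f"s{i}" for i in range(2 * n)])
            res = per_snp_population_scan(gm, self._pt(n))
            tested = [r for r in res if "monomorphic" not in r.model]
            total += len(tested)
            sig += sum(r.p_adj <= 0.05 for r in tested)
        assert sig / total <= 0.05
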