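import numpy as np
import pandas as pd
import pytest

from gpcraxes.errors import DegenerateInputError
from gpcraxes.survival import (
    CombinatorialCoxResult,
    SurvivalDataset,
    axis_screen,
    coefficient_regression,
    combined_stratify,
    combinatorial_cox,
    cox_score_test,
    cox_univariate,
    km_logrank,
    median_stratify,
)


def logrank_oracle(time, event, groups):
    """Hypergeometric O-E / V log-rank computation, written out longhand."""
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    x = (np.asarray(groups) == "high").astype(int)
    O = E = V = 0.0
    for t in sorted(set(time[event == 1])):
        at_risk = time >= t
        n = at_risk.sum()
        n1 = x[at_risk].sum()
        d = int(((time == t) & (event == 1)).sum())
        d1 = int((x[(time == t) & (event == 1)]).sum())
        O += d1
        E += d * n1 / n
        if n > 1:
            V += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    return (O - E) ** 2 / V


def two_group_data(rng, n=400, hr=2.0, censor_scale=None, baseline=0.1):
    x = rng.integers(0, 2, size=n)
    lam = baseline * np.where(x == 1, hr, 1.0)
    t = rng.exponential(1 / lam)
    if censor_scale:
        c = rng.exponential(censor_scale, size=n)
        return np.minimum(t, c), (t <= c).astype(int), np.where(x == 1, "high", "low")
    return t, np.ones(n, dtype=int), np.where(x == 1, "high", "low")


class TestMedianStratify:
    def test_even_split(self):
        assert median_stratify([1, 2, 3, 4]).tolist() == ["low", "low", "high", "high"]

    def test_ties_go_low(self):
        assert median_stratify([1, 2, 2, 4]).tolist() == ["low", "low", "low", "high"]

    def test_constant_vector_errors(self):
        with pytest.raises(DegenerateInputError):
            median_stratify([3, 3, 3, 3])

    def test_too_few_patients(self):
        with pytest.raises(DegenerateInputError):
            median_stratify([1, 2, 3])


class TestCombinedStratify:
    def test_aligned_vectors(self):
        labels = combined_stratify([1, 2, 3, 4], [1, 2, 3, 4])
        assert labels.tolist() == ["low", "low", "high", "high"]

    def test_anti_ranked_gives_empty_groups(self):
        labels = combined_stratify([1, 2, 3, 4], [4, 3, 2, 1])
        assert (labels == "high").sum() == 0 and (labels == "low").sum() == 0
        assert (labels == "excluded").sum() == 4

    def test_matches_set_intersection_enumeration(self, rng):
        vr, vp = rng.normal(size=200), rng.normal(size=200)
        labels = combined_stratify(vr, vp)
        hi = {i for i in range(200) if vr[i] > np.median(vr)} & {
            i for i in range(200) if vp[i] > np.median(vp)
        }
        lo = {i for i in range(200) if vr[i] <= np.median(vr)} & {
            i for i in range(200) if vp[i] <= np.median(vp)
        }
        assert set(np.where(labels == "high")[0]) == hi
        assert set(np.where(labels == "low")[0]) == lo


class TestKmLogrank:
    def test_identical_groups_statistic_zero(self):
        time = np.array([1.0, 2, 3, 1, 2, 3])
        event = np.array([1, 1, 0, 1, 1, 0])
        groups = np.array(["high"] * 3 + ["low"] * 3)
        stat, p, tables = km_logrank(time, event, groups)
        assert stat == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)
        assert set(tables) == {"high", "low"}

    def test_small_example_matches_hand_computation(self):
        time = np.array([1.0, 2, 3, 4, 5, 6])
        event = np.array([1, 1, 1, 1, 1, 1])
        groups = np.array(["high", "high", "high", "low", "low", "low"])
        stat, _, _ = km_logrank(time, event, groups)
        assert stat == pytest.approx(logrank_oracle(time, event, groups))

    def test_power_at_hr3(self):
        hits = 0
        for seed in range(30):
            rng = np.random.default_rng(seed)
            t, e, g = two_group_data(rng, n=1000, hr=3.0)
            _, p, _ = km_logrank(t, e, g)
            hits += p < 0.001
        assert hits >= 29

    def test_empty_group_errors(self):
        with pytest.raises(DegenerateInputError):
            km_logrank(np.array([1.0, 2]), np.array([1, 1]), np.array(["high", "high"]))

    def test_km_table_columns(self):
        time = np.array([1.0, 2, 3, 4])
        event = np.array([1, 0, 1, 1])
        groups = np.array(["high", "high", "low", "low"])
        _, _, tables = km_logrank(time, event, groups)
        assert list(tables["high"].columns) == ["time", "n_at_risk", "n_events", "survival"]


class TestCoxUnivariate:
    def test_recovers_true_hr(self, rng):
        t, e, g = two_group_data(rng, n=2000, hr=2.0)
        res = cox_univariate(t, e, (g == "high").astype(float))
        assert abs(res.beta - np.log(2)) < 0.1
        assert res.hr == pytest.approx(np.exp(res.beta))

    def test_null_covariate_flat(self, rng):
        t = rng.exponential(10, size=2000)
        e = np.ones(2000, dtype=int)
        x = rng.integers(0, 2, size=2000).astype(float)
        res = cox_univariate(t, e, x)
        assert abs(res.beta) < 0.1

    def test_constant_covariate_errors(self):
        with pytest.raises(DegenerateInputError):
            cox_univariate(np.array([1.0, 2, 3, 4]), np.array([1, 1, 1, 1]), np.zeros(4))

    def test_relabeling_flips_beta_sign(self, rng):
        t, e, g = two_group_data(rng, n=300, hr=2.0, censor_scale=20)
        x = (g == "high").astype(float)
        b1 = cox_univariate(t, e, x).beta
        b2 = cox_univariate(t, e, 1 - x).beta
        assert abs(b1 + b2) < 1e-6

    def test_score_test_agrees_with_logrank(self, rng):
        t, e, g = two_group_data(rng, n=1000, hr=1.3, censor_scale=20)
        stat, p_score = cox_score_test(t, e, g)
        lr_stat, p_lr, _ = km_logrank(t, e, g)
        assert abs(p_score - p_lr) / p_lr < 0.10
        assert stat == pytest.approx(lr_stat, rel=1e-6)  # continuous times: exact


def make_dataset(rng, n=200, genes=("R1", "L1"), hazard_fn=None):
    expr = pd.DataFrame(rng.normal(size=(len(genes), n)), index=list(genes))
    lam = np.full(n, 0.1) if hazard_fn is None else hazard_fn(expr)
    t = rng.exponential(1 / lam)
    c = rng.exponential(1 / (0.45 * 0.1), size=n)
    return SurvivalDataset(
        time=np.minimum(t, c),
        event=(t <= c).astype(int),
        expression=expr,
        cohort="C",
    )


class TestAxisScreen:
    def test_filter_logic_on_synthetic_axis(self, rng):
        def hazard(expr):
            er, ep = expr.loc["R1"].to_numpy(), expr.loc["L1"].to_numpy()
            hh = (er > np.median(er)) & (ep > np.median(ep))
            return 0.1 * np.where(hh, 6.0, 1.0)

        ds = make_dataset(rng, n=400, hazard_fn=hazard)
        out = axis_screen(ds, [("R1", "L1", "ligand")])
        row = out.iloc[0]
        assert not row["missing"]
        assert row["hr_axis"] > row["hr_r"] and row["hr_axis"] > row["hr_p"]

    def test_missing_gene_propagates(self, rng):
        ds = make_dataset(rng)
        out = axis_screen(ds, [("R1", "ABSENT", "ligand")])
        assert bool(out.iloc[0]["missing"])

    def test_deterministic(self, rng):
        ds = make_dataset(rng, n=120)
        axes = [("R1", "L1", "ligand")]
        pd.testing.assert_frame_equal(axis_screen(ds, axes), axis_screen(ds, axes))


class TestCombinatorialCox:
    def test_predictor_arithmetic(self):
        # indicators (1, 0) with betas (0.5, -0.2) -> predictor 0.5
        assert 0.5 * 1 + (-0.2) * 0 == pytest.approx(0.5)

    def test_zero_betas_flagged_missing(self, rng):
        ds = make_dataset(rng, n=100)
        res = combinatorial_cox(ds, ("R1", "L1", "ligand"), beta_r=0.0, beta_p=0.0)
        assert res.missing

    def test_planted_synergy_recovered(self):
        """Additive planted log-hazards: combined model beats individuals."""
        wins = 0
        n_seeds = 25
        for seed in range(n_seeds):
            rng = np.random.default_rng(seed)

            def hazard(expr):
                er, ep = expr.loc["R1"].to_numpy(), expr.loc["L1"].to_numpy()
                ir = (er > np.median(er)).astype(float)
                ip = (ep > np.median(ep)).astype(float)
                return 0.1 * np.exp(np.log(2) * ir + np.log(2) * ip)

            ds = make_dataset(rng, n=400, hazard_fn=hazard)
            res = combinatorial_cox(ds, ("R1", "L1", "ligand"))
            if not res.missing and res.hr_c >= res.hr_r and res.hr_c >= res.hr_p:
                wins += 1
        assert wins / n_seeds >= 0.8


class TestCoefficientRegression:
    def _result(self, beta_r, beta_p, beta_c):
        return CombinatorialCoxResult(
            beta_r=beta_r, beta_p=beta_p, hr_r=np.exp(beta_r), hr_p=np.exp(beta_p),
            predictor=np.zeros(1), beta_c=beta_c, hr_c=np.exp(beta_c),
            logrank_p_c=0.01, selected=True,
        )

    def test_exact_linear_relation(self, rng):
        results = []
        for _ in range(20):
            br, bp = rng.normal(size=2)
            results.append(self._result(br, bp, 1.0 * br + 1.0 * bp))
        fit = coefficient_regression(results)
        assert fit["slope_beta_r"] == pytest.approx(1.0)
        assert fit["slope_beta_p"] == pytest.approx(1.0)
        assert fit["r_squared"] == pytest.approx(1.0)

    def test_null_relation_gives_small_slopes(self, rng):
        results = [self._result(*rng.normal(size=2), rng.normal()) for _ in range(200)]
        fit = coefficient_regression(results)
        assert abs(fit["slope_beta_r"]) < 0.3 and abs(fit["slope_beta_p"]) < 0.3

    def test_too_few_models_errors(self, rng):
        results = [self._result(0.1, 0.2, 0.3), self._result(0.2, 0.1, 0.3)]
        with pytest.raises(DegenerateInputError):
            coefficient_regression(results)
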