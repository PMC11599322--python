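"""GLMM battery, marginal effects, transitions, and the exact test."""

import itertools
import math
import subprocess
import sys
from fractions import Fraction

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from beegaze.metrics import FacingSummary, TransitionCounts
from beegaze.stats import (
    ChoiceRecord,
    ContingencyTable,
    TableTooLargeError,
    compare_groups,
    facing_effect_model,
    facing_time_difference_test,
    fit_binomial_glmm,
    freeman_halton_test,
    transition_frequency_test,
)
from beegaze.stats import test_vs_chance as chance_model


def _irls_logistic(y, n, X, tol=1e-12, max_iter=200):
    """Independent weighted-logistic oracle: textbook IRLS iterations."""
    beta = np.zeros(X.shape[1])
    for _ in range(max_iter):
        eta = X @ beta
        p = 1.0 / (1.0 + np.exp(-eta))
        W = n * p * (1 - p)
        z = eta + (y - n * p) / np.maximum(W, 1e-12)
        WX = X * W[:, None]
        beta_new = np.linalg.solve(X.T @ WX, X.T @ (W * z))
        if np.max(np.abs(beta_new - beta)) < tol:
            beta = beta_new
            break
        beta = beta_new
    cov = np.linalg.inv(X.T @ (X * (n * p * (1 - p))[:, None]))
    return beta, np.sqrt(np.diag(cov))


def _records(ys, n=10, group="Blue", colonies=("c1", "c2")):
    return [
        ChoiceRecord(bee_id=f"b{i}", group=group,
                     colony_id=colonies[i % len(colonies)],
                     n_choices=n, n_yellow=y,
                     first_choice="yellow" if y > n / 2 else "blue")
        for i, y in enumerate(ys)
    ]


class TestBinomialGlmm:
    def test_symmetric_data_gives_zero_intercept(self):
        res = fit_binomial_glmm(np.full(8, 5.0), np.full(8, 10.0),
                                np.ones((8, 1)), names=["int"])
        assert abs(res.coefficients["int"]) < 1e-6

    def test_matches_independent_irls_oracle(self):
        rng = np.random.default_rng(1)
        n = np.full(30, 12.0)
        X = np.column_stack([np.ones(30), rng.normal(0, 5, 30)])
        y = rng.binomial(12, 1 / (1 + np.exp(-(-0.5 + 0.1 * X[:, 1])))).astype(float)
        res = fit_binomial_glmm(y, n, X, names=["a", "b"])
        beta, se = _irls_logistic(y, n, X)
        assert res.coefficients["a"] == pytest.approx(beta[0], abs=1e-6)
        assert res.coefficients["b"] == pytest.approx(beta[1], abs=1e-6)
        assert res.standard_errors["a"] == pytest.approx(se[0], rel=1e-4)

    def test_boundary_variance_falls_back_to_glm(self):
        # no colony signal at all: variance estimates at the boundary
        rng = np.random.default_rng(2)
        y = rng.binomial(10, 0.4, 24).astype(float)
        groups = np.repeat(["c1", "c2", "c3"], 8)
        res = fit_binomial_glmm(y, np.full(24, 10.0), np.ones((24, 1)),
                                groups=groups, names=["int"])
        glm = fit_binomial_glmm(y, np.full(24, 10.0), np.ones((24, 1)),
                                names=["int"])
        if res.random_effects_dropped:
            assert res.coefficients["int"] == pytest.approx(
                glm.coefficients["int"], abs=1e-8)
        else:  # variance kept but tiny: fit must agree with the GLM anyway
            assert res.random_effect_variances["group"] < 0.05
            assert res.coefficients["int"] == pytest.approx(
                glm.coefficients["int"], abs=1e-3)

    def test_mixed_fit_matches_lme4(self, tmp_path):
        """Adaptive-quadrature fit against R lme4 glmer (nAGQ=25)."""
        rng = np.random.default_rng(123)
        colony = np.repeat([f"c{i}" for i in range(6)], 8)
        x = rng.normal(0, 10, 48)
        u = rng.normal(0, 1.0, 6)[np.repeat(np.arange(6), 8)]
        y = rng.binomial(20, 1 / (1 + np.exp(-(-1.0 + 0.06 * x + u))))
        csv = tmp_path / "d.csv"
        pd.DataFrame({"colony": colony, "x": x, "y": y, "n": 20}).to_csv(
            csv, index=False)
        rscript = tmp_path / "fit.R"
        rscript.write_text(
            "suppressMessages(library(lme4))\n"
            f"d <- read.csv('{csv}')\n"
            "m <- glmer(cbind(y, n-y) ~ x + (1|colony), data=d,"
            " family=binomial, nAGQ=25)\n"
            "cat(fixef(m), sqrt(diag(vcov(m))),"
            " as.data.frame(VarCorr(m))$vcov, sep='\\n')\n")
        out = subprocess.run(["Rscript", str(rscript)], capture_output=True,
                             text=True, timeout=300)
        assert out.returncode == 0, out.stderr
        ref = [float(v) for v in out.stdout.split()]
        res = fit_binomial_glmm(y.astype(float), np.full(48, 20.0),
                                np.column_stack([np.ones(48), x]),
                                groups=colony, names=["int", "x"])
        assert res.coefficients["int"] == pytest.approx(ref[0], abs=1e-3)
        assert res.coefficients["x"] == pytest.approx(ref[1], abs=1e-4)
        assert res.standard_errors["int"] == pytest.approx(ref[2], rel=1e-3)
        assert res.standard_errors["x"] == pytest.approx(ref[3], rel=1e-3)
        assert res.random_effect_variances["group"] == pytest.approx(
            ref[4], rel=1e-3)

    def test_ci_coverage_with_colony_intercepts(self):
        """Wald 95% CI covers the slope at a nominal-ish rate under colony
        heterogeneity (sigma = 1)."""
        rng = np.random.default_rng(3)
        beta_true = -1.5
        cover = 0
        reps = 60
        for _ in range(reps):
            colony = np.repeat(["c1", "c2", "c3"], 22)
            x = rng.normal(0, 1, 66)
            u = rng.normal(0, 1.0, 3)[np.repeat(np.arange(3), 22)]
            p = 1 / (1 + np.exp(-(0.3 + beta_true * x + u)))
            y = rng.binomial(10, p).astype(float)
            res = fit_binomial_glmm(y, np.full(66, 10.0),
                                    np.column_stack([np.ones(66), x]),
                                    groups=colony, names=["int", "b"])
            lo = res.coefficients["b"] - 1.96 * res.standard_errors["b"]
            hi = res.coefficients["b"] + 1.96 * res.standard_errors["b"]
            cover += lo <= beta_true <= hi
        assert 0.85 <= cover / reps <= 1.0


class TestVsChance:
    def test_all_blue_choices_give_negative_intercept(self):
        res = chance_model(_records([0] * 12))
        assert res.coefficients["intercept"] < -2
        assert res.p_values["intercept"] < 0.001

    def test_fifty_fifty_is_chance(self):
        res = chance_model(_records([5] * 40))
        assert abs(res.z_values["intercept"]) < 0.1
        assert res.p_values["intercept"] > 0.9

    def test_recovers_innate_bias_logit(self):
        rng = np.random.default_rng(4)
        alpha = -1.2
        errs = []
        for _ in range(40):
            y = rng.binomial(10, 1 / (1 + math.exp(-alpha)), 22)
            res = chance_model(_records(list(y)), use_random_effects=False)
            errs.append(res.coefficients["intercept"] - alpha)
        assert abs(np.median(errs)) < 0.3


class TestCompareGroups:
    def test_identical_groups_null_lrt(self):
        recs = (_records([5] * 10, group="Blue")
                + _records([5] * 10, group="Yellow"))
        lrt, contrasts = compare_groups(recs, use_random_effects=False)
        assert lrt.statistic == pytest.approx(0.0, abs=1e-6)
        assert lrt.p_value > 0.99
        assert len(contrasts) == 1

    def test_lrt_statistic_is_twice_loglik_gap(self):
        rng = np.random.default_rng(5)
        recs = (_records(list(rng.binomial(10, 0.3, 15)), group="Blue")
                + _records(list(rng.binomial(10, 0.6, 15)), group="Yellow"))
        lrt, _ = compare_groups(recs, use_random_effects=False)
        # independent refit through the plain GLM path
        df = pd.DataFrame({
            "y": [r.n_yellow for r in recs],
            "n": [r.n_choices for r in recs],
            "g": [r.group for r in recs]})
        X_full = np.column_stack([np.ones(len(df)),
                                  (df["g"] == "Yellow").to_numpy(float)])
        full = fit_binomial_glmm(df["y"], df["n"], X_full, names=["i", "g"])
        null = fit_binomial_glmm(df["y"], df["n"], np.ones((len(df), 1)),
                                 names=["i"])
        assert lrt.statistic == pytest.approx(
            2 * (full.loglik - null.loglik), abs=1e-6)

    def test_three_group_ordering_detected(self):
        rng = np.random.default_rng(6)
        logits = {"Blue": -1.5, "Control": -0.9, "Yellow": -0.3}
        sign_ok = 0
        for _ in range(30):
            recs = []
            for g, a in logits.items():
                y = rng.binomial(10, 1 / (1 + math.exp(-a)), 20)
                recs += _records(list(y), group=g)
            _, contrasts = compare_groups(recs, use_random_effects=False)
            yb = contrasts[contrasts["contrast"] == "Yellow - Blue"]
            sign_ok += float(yb["estimate"].iloc[0]) > 0
        assert sign_ok >= 27  # >= 90%

    def test_tukey_adjustment_not_smaller(self):
        rng = np.random.default_rng(7)
        recs = (_records(list(rng.binomial(10, 0.35, 15)), group="Blue")
                + _records(list(rng.binomial(10, 0.5, 15)), group="Control")
                + _records(list(rng.binomial(10, 0.6, 15)), group="Yellow"))
        _, plain = compare_groups(recs, use_random_effects=False)
        _, tukey = compare_groups(recs, adjust="tukey",
                                  use_random_effects=False)
        for p0, p1 in zip(plain["p_value"], tukey["p_value"]):
            assert p1 >= p0 - 1e-12


def _summary(bee, occ_r, un_r, occ_n, un_n, group="Blue", colony="c1"):
    other = 200.0 - (occ_r + un_r + occ_n + un_n)
    return FacingSummary(
        bee_id=bee, group=group, colony_id=colony,
        t_occ_reward=occ_r, t_unocc_reward=un_r,
        t_occ_nonreward=occ_n, t_unocc_nonreward=un_n,
        t_no_flower=max(other, 0.0), t_invalid=0.0, session_duration=200.0)


class TestFacingTimeDifference:
    def test_zero_differences_not_significant(self):
        summaries = [_summary(f"b{i}", 10, 10, 10, 10) for i in range(12)]
        res = facing_time_difference_test(summaries)
        assert res.p_values["intercept"] > 0.99

    def test_matches_one_sample_z_without_colony_variance(self):
        rng = np.random.default_rng(8)
        d = rng.normal(5, 4, 20)
        summaries = [_summary(f"b{i}", 10 + d[i], 10, 10, 10, colony="c1")
                     for i in range(20)]
        res = facing_time_difference_test(summaries)
        z_direct = d.mean() / (d.std(ddof=1) / math.sqrt(len(d)))
        assert res.z_values["intercept"] == pytest.approx(z_direct, rel=1e-9)

    def test_reward_biased_generator_positive(self):
        rng = np.random.default_rng(9)
        pos = 0
        for _ in range(40):
            summaries = [
                _summary(f"b{i}", rng.gamma(4, 6), rng.gamma(4, 3),
                         rng.gamma(4, 1), rng.gamma(4, 2),
                         colony="c1" if i % 2 else "c2")
                for i in range(20)
            ]
            res = facing_time_difference_test(summaries)
            pos += res.z_values["intercept"] > 0
        assert pos >= 38  # 3:1 reward bias: positive Z in >= 95% of reps


class TestFacingEffectModel:
    def _dataset(self, rng, beta_occ=0.06, beta_unn=-0.04, n_bees=22):
        summaries, records = [], []
        for i in range(n_bees):
            occ_r = rng.gamma(2, 10)
            un_r = rng.gamma(2, 6)
            occ_n = rng.gamma(2, 1)
            un_n = rng.gamma(2, 4)
            # innate blue bias +1.2 on the blue logit; facing effects on top
            eta = 1.2 + beta_occ * occ_r + beta_unn * un_n
            p_blue = 1 / (1 + math.exp(-eta))
            n_yellow = rng.binomial(10, 1 - p_blue)
            summaries.append(_summary(f"b{i}", occ_r, un_r, occ_n, un_n,
                                      colony=f"c{i % 2}"))
            records.append(ChoiceRecord(f"b{i}", "Blue", f"c{i % 2}", 10,
                                        int(n_yellow), "blue"))
        return summaries, records

    def test_trivial_ame_arithmetic(self):
        # beta = 0.10/s at p-hat 0.5 for every bee: AME = 0.10*0.25*100
        assert 100 * 0.10 * 0.5 * 0.5 == pytest.approx(2.5)
        rng = np.random.default_rng(10)
        summaries, records = self._dataset(rng)
        model, ame = facing_effect_model(summaries, records, "Blue",
                                         use_random_effects=False)
        row = ame[ame["predictor"] == "t_occ_reward"].iloc[0]
        eta = np.array([
            model.coefficients["intercept"]
            + sum(model.coefficients[c] * getattr(s, c)
                  for c in ("t_occ_reward", "t_unocc_reward",
                            "t_occ_nonreward", "t_unocc_nonreward"))
            for s in summaries])
        p = 1 / (1 + np.exp(-eta))
        expected = 100 * model.coefficients["t_occ_reward"] * np.mean(p * (1 - p))
        assert row["ame_pct_per_s"] == pytest.approx(expected, rel=1e-9)

    def test_ame_sign_equals_coefficient_sign(self):
        rng = np.random.default_rng(11)
        summaries, records = self._dataset(rng)
        model, ame = facing_effect_model(summaries, records, "Blue",
                                         use_random_effects=False)
        for _, row in ame.iterrows():
            assert np.sign(row["ame_pct_per_s"]) == np.sign(row["coefficient"])

    def test_sign_recovery(self):
        rng = np.random.default_rng(12)
        occ_pos = unn_neg = 0
        reps = 40
        for _ in range(reps):
            summaries, records = self._dataset(rng)
            _, ame = facing_effect_model(summaries, records, "Blue",
                                         use_random_effects=False)
            occ_pos += float(ame.loc[ame["predictor"] == "t_occ_reward",
                                     "coefficient"].iloc[0]) > 0
            unn_neg += float(ame.loc[ame["predictor"] == "t_unocc_nonreward",
                                     "coefficient"].iloc[0]) < 0
        assert occ_pos >= int(0.9 * reps)
        assert unn_neg >= int(0.9 * reps)

    def test_null_predictor_type_I_control(self):
        rng = np.random.default_rng(13)
        rejected = 0
        reps = 120
        for _ in range(reps):
            summaries, records = self._dataset(rng, beta_occ=0.0, beta_unn=0.0)
            _, ame = facing_effect_model(summaries, records, "Blue",
                                         use_random_effects=False)
            rejected += bool(ame.loc[ame["predictor"] == "t_occ_reward",
                                     "retained"].iloc[0])
        assert 0.005 <= rejected / reps <= 0.12  # ~5% within MC error


class TestTransitionFrequency:
    def _counts(self, pairs):
        return [TransitionCounts(f"b{i}", a, b, 0)
                for i, (a, b) in enumerate(pairs)]

    def test_all_nonreward_predecessors_positive(self):
        res = transition_frequency_test(self._counts([(6, 0)] * 10))
        assert res.z_values["intercept"] > 2
        assert res.p_values["intercept"] < 0.05

    def test_even_split_is_chance(self):
        res = transition_frequency_test(self._counts([(5, 5)] * 12))
        assert res.p_values["intercept"] > 0.9

    def test_double_rate_generator_positive(self):
        rng = np.random.default_rng(14)
        pos = 0
        for _ in range(40):
            pairs = []
            for _ in range(20):
                tot = rng.poisson(8) + 1
                a = rng.binomial(tot, 2 / 3)
                pairs.append((a, tot - a))
            res = transition_frequency_test(self._counts(pairs))
            pos += res.z_values["intercept"] > 0
        assert pos >= 36  # >= 90%

    def test_bees_without_qualifying_predecessors_drop_out(self):
        counts = self._counts([(3, 1), (0, 0), (2, 2)])
        res = transition_frequency_test(counts)
        assert res.n_obs == 2


def _fh_oracle(table):
    """Exact-rational brute force over the fixed-margin lattice."""
    table = np.asarray(table, dtype=int)
    rows = table.sum(axis=1)
    cols = table.sum(axis=0)
    n = int(table.sum())

    def prob(t):
        num = math.prod(math.factorial(int(r)) for r in rows) * \
            math.prod(math.factorial(int(c)) for c in cols)
        den = math.factorial(n) * math.prod(
            math.factorial(int(v)) for v in np.ravel(t))
        return Fraction(num, den)

    cells = []
    r, c = table.shape
    ranges = [range(min(rows[i], cols[j]) + 1)
              for i in range(r - 1) for j in range(c - 1)]
    p_obs = prob(table)
    total = Fraction(0)
    for free in itertools.product(*ranges):
        t = np.zeros((r, c), dtype=int)
        t[:r - 1, :c - 1] = np.array(free).reshape(r - 1, c - 1)
        t[:r - 1, c - 1] = rows[:r - 1] - t[:r - 1, :c - 1].sum(axis=1)
        t[r - 1, :] = cols - t[:r - 1, :].sum(axis=0)
        if (t < 0).any():
            continue
        if prob(t) <= p_obs:
            total += prob(t)
    del cells
    return float(total)


class TestFreemanHalton:
    def test_reduces_to_fisher_exact_2x2(self):
        for tbl in ([[3, 1], [1, 3]], [[8, 2], [1, 5]], [[5, 0], [0, 5]]):
            assert freeman_halton_test(np.array(tbl)) == pytest.approx(
                sps.fisher_exact(tbl)[1], abs=1e-12)

    def test_zero_row_gives_p_one(self):
        assert freeman_halton_test(np.array([[3, 4], [0, 0]])) == 1.0
        assert freeman_halton_test(np.array([[3, 0], [5, 0]])) == 1.0

    def test_matches_exact_fraction_enumeration(self):
        rng = np.random.default_rng(15)
        for _ in range(12):
            shape = (2, 3) if rng.random() < 0.5 else (3, 3)
            tbl = rng.integers(0, 9, size=shape)
            if tbl.sum() == 0:
                continue
            assert freeman_halton_test(tbl) == pytest.approx(
                _fh_oracle(tbl), abs=1e-12)

    def test_lattice_probabilities_sum_to_one(self):
        from beegaze.stats import _enumerate_cell_terms
        from scipy.special import gammaln, logsumexp

        tbl = np.array([[4, 2, 1], [1, 3, 5], [2, 2, 2]])
        rows = tuple(tbl.sum(axis=1))
        cols = tuple(tbl.sum(axis=0))
        log_margin = (sum(gammaln(r + 1) for r in rows)
                      + sum(gammaln(c + 1) for c in cols)
                      - gammaln(tbl.sum() + 1))
        logs = [log_margin - t for t in _enumerate_cell_terms(rows, cols)]
        assert math.exp(logsumexp(np.array(logs))) == pytest.approx(
            1.0, abs=1e-10)

    def test_contingency_table_validation(self):
        with pytest.raises(ValueError):
            ContingencyTable(("a",), ("x", "y"), np.array([[1, 2], [3, 4]]))
        with pytest.raises(TableTooLargeError):
            freeman_halton_test(np.ones((5, 2), dtype=int))
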