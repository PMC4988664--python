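import itertools

import numpy as np
import pandas as pd
import pytest

from disurv import (ValidationError, fit_cox, partial_loglik,
                    ph_assumption_test, stepwise_select)
from disurv.io_model import DiscreteHazardModel, SurvivalDataset, generate_cohort

from conftest import make_ds


# ------------------------------------------------------------------ oracles

def brute_breslow(time, status, x, beta):
    ll = 0.0
    w = np.exp(x * beta)
    for t in sorted(set(time[status == 1])):
        dead = (time == t) & (status == 1)
        risk = time >= t
        ll += np.sum(x[dead]) * beta - dead.sum() * np.log(np.sum(w[risk]))
    return ll


def brute_efron(time, status, x, beta):
    ll = 0.0
    w = np.exp(x * beta)
    for t in sorted(set(time[status == 1])):
        dead = np.nonzero((time == t) & (status == 1))[0]
        risk = np.sum(w[time >= t])
        wd = np.sum(w[dead])
        d = len(dead)
        ll += np.sum(x[dead]) * beta
        for el in range(d):
            ll -= np.log(risk - el / d * wd)
    return ll


def brute_exact(time, status, x, beta):
    ll = 0.0
    w = np.exp(x * beta)
    for t in sorted(set(time[status == 1])):
        dead = np.nonzero((time == t) & (status == 1))[0]
        risk = np.nonzero(time >= t)[0]
        d = len(dead)
        num = np.exp(np.sum(x[dead]) * beta)
        den = sum(np.prod(w[list(sub)])
                  for sub in itertools.combinations(risk, d))
        ll += np.log(num / den)
    return ll


def random_tied_dataset(rng, n):
    time = rng.integers(1, 4, size=n).astype(float)
    status = rng.integers(0, 2, size=n)
    if status.sum() == 0:
        status[0] = 1
    x = rng.normal(size=n).round(2)
    return time, status, x


# ------------------------------------------------------------ partial_loglik

class TestPartialLoglik:
    def test_two_subject_closed_form(self):
        ds = make_ds([1, 2], [1, 1], x=[1.0, 0.0])
        for beta in (-1.0, 0.0, 0.4, 2.5):
            assert partial_loglik(ds, ["x"], [beta]) == pytest.approx(
                beta - np.log(np.exp(beta) + 1) - 0.0, abs=1e-12)

    def test_beta_zero_equals_null_loglik(self):
        rng = np.random.default_rng(3)
        ds = make_ds(rng.integers(1, 10, 20), rng.integers(0, 2, 20),
                     x=rng.normal(size=20))
        fit = fit_cox(ds, ["x"])
        assert partial_loglik(ds, ["x"], [0.0]) == pytest.approx(
            fit.loglik_null, abs=1e-10)

    @pytest.mark.parametrize("ties,oracle", [
        ("breslow", brute_breslow), ("efron", brute_efron),
        ("exact", brute_exact)])
    def test_tie_likelihoods_match_brute_force(self, ties, oracle):
        """All tie corrections vs independent sums, small tied datasets."""
        rng = np.random.default_rng(17)
        for _ in range(25):
            time, status, x = random_tied_dataset(rng, 6)
            ds = make_ds(time, status, x=x)
            for beta in (-0.8, 0.0, 0.6):
                assert partial_loglik(ds, ["x"], [beta], ties=ties) == \
                    pytest.approx(oracle(time, status, x, beta), abs=1e-9)

    def test_fitted_beta_is_a_maximum(self):
        rng = np.random.default_rng(8)
        ds = make_ds(rng.integers(1, 12, 30), rng.integers(0, 2, 30),
                     x=rng.normal(size=30))
        fit = fit_cox(ds, ["x"])
        best = partial_loglik(ds, ["x"], fit.coefficients.to_numpy())
        for delta in (-0.1, 0.1):
            assert best >= partial_loglik(
                ds, ["x"], fit.coefficients.to_numpy() + delta)


# ------------------------------------------------------------------ fit_cox

class TestFitCox:
    def test_symmetric_groups_give_zero_coefficient(self):
        ds = make_ds([1, 2, 3, 1, 2, 3], [1, 0, 1, 1, 0, 1],
                     x=[0, 0, 0, 1, 1, 1])
        fit = fit_cox(ds, ["x"])
        assert fit.coefficients["x"] == pytest.approx(0.0, abs=1e-8)
        assert fit.hazard_ratios["x"] == pytest.approx(1.0, abs=1e-8)

    def test_grid_search_maximizer(self):
        ds = make_ds([1, 2, 3, 4, 5, 6], [1, 1, 0, 1, 1, 1],
                     x=[0.5, -0.2, 1.1, 0.0, -1.3, 0.7])
        fit = fit_cox(ds, ["x"], ties="efron")
        grid = np.linspace(-4, 4, 8001)
        lls = [partial_loglik(ds, ["x"], [b]) for b in grid]
        assert fit.coefficients["x"] == pytest.approx(
            grid[int(np.argmax(lls))], abs=1e-3)

    def test_tie_methods_coincide_without_ties(self):
        rng = np.random.default_rng(2)
        times = rng.permutation(np.arange(1, 16)).astype(float)
        ds = make_ds(times, rng.integers(0, 2, 15) | 1,
                     x=rng.normal(size=15))
        betas = [fit_cox(ds, ["x"], ties=t).coefficients["x"]
                 for t in ("breslow", "efron", "exact")]
        assert betas[0] == pytest.approx(betas[1], abs=1e-8)
        assert betas[0] == pytest.approx(betas[2], abs=1e-8)

    def test_score_vanishes_at_the_maximum(self):
        model = DiscreteHazardModel(baseline=[0.05] * 15,
                                    effects={"x": 0.5},
                                    covariate_dists={"x": ("bernoulli", 0.4)})
        ds, _ = generate_cohort(300, 15, model, censor_prob=0.02, seed=6)
        for ties in ("breslow", "efron"):
            fit = fit_cox(ds, ["x"], ties=ties)
            b = fit.coefficients.to_numpy()[0]
            eps = 1e-5
            score = (partial_loglik(ds, ["x"], [b + eps], ties=ties)
                     - partial_loglik(ds, ["x"], [b - eps], ties=ties)) / (2 * eps)
            assert abs(score) < 1e-4

    def test_matches_statsmodels_phreg(self):
        from statsmodels.duration.hazard_regression import PHReg
        model = DiscreteHazardModel(
            baseline=[0.06] * 12, effects={"x": 0.7, "z": -0.3},
            covariate_dists={"x": ("bernoulli", 0.5), "z": ("normal", 0, 1)})
        ds, _ = generate_cohort(400, 12, model, censor_prob=0.03, seed=13)
        for ties in ("breslow", "efron"):
            fit = fit_cox(ds, ["x", "z"], ties=ties)
            ref = PHReg(ds.time, ds.covariates.to_numpy(), status=ds.status,
                        ties=ties).fit()
            np.testing.assert_allclose(fit.coefficients.to_numpy(),
                                       ref.params, atol=1e-6)
            np.testing.assert_allclose(fit.se.to_numpy(),
                                       ref.bse, atol=1e-6)

    def test_matches_r_coxph_exact_ties(self, tmp_path):
        """The exact-tie fit against R survival's coxph on a tied fixture."""
        import shutil
        import subprocess
        if shutil.which("Rscript") is None:
            pytest.fail("Rscript is required for the exact-ties cross-check")
        time = [1, 1, 1, 2, 2, 3, 4, 4, 5, 6]
        status = [1, 1, 0, 1, 1, 1, 0, 1, 1, 0]
        x = [0.3, -1.2, 0.8, 1.5, -0.4, 0.0, 2.1, -0.9, 0.6, 1.1]
        ds = make_ds(time, status, x=x)
        fit = fit_cox(ds, ["x"], ties="exact")
        csv = tmp_path / "d.csv"
        ds.write_csv(csv)
        script = (
            f'suppressMessages(library(survival));'
            f'd <- read.csv("{csv.as_posix()}");'
            f'f <- coxph(Surv(time, status) ~ x, data=d, ties="exact");'
            f'cat(sprintf("%.10f", coef(f)))'
        )
        out = subprocess.run(["Rscript", "-e", script], capture_output=True,
                             text=True, check=True)
        assert fit.coefficients["x"] == pytest.approx(float(out.stdout),
                                                      abs=1e-6)

    def test_categorical_reference_coding(self):
        ds = make_ds([1, 2, 3, 4, 5, 6], [1, 1, 1, 1, 1, 1],
                     grp=["a", "b", "c", "a", "b", "c"])
        fit = fit_cox(ds, ["grp"])
        assert list(fit.coefficients.index) == ["grp[b]", "grp[c]"]

    def test_constant_covariate_rejected(self):
        ds = make_ds([1, 2, 3], [1, 1, 1], x=[2.0, 2.0, 2.0])
        with pytest.raises(ValidationError, match="x"):
            fit_cox(ds, ["x"])

    def test_monotone_likelihood_warns_and_caps(self):
        ds = make_ds([1, 2], [1, 1], x=[1.0, 0.0])
        with pytest.warns(UserWarning, match="monotone"):
            fit = fit_cox(ds, ["x"])
        assert np.isfinite(fit.coefficients["x"])

    def test_lrt_non_negative_and_consistent(self):
        rng = np.random.default_rng(21)
        ds = make_ds(rng.integers(1, 20, 50), rng.integers(0, 2, 50),
                     x=rng.normal(size=50))
        fit = fit_cox(ds, ["x"])
        stat, df, p = fit.lrt
        assert stat == pytest.approx(
            2 * (fit.loglik_fit - fit.loglik_null), abs=1e-10)
        assert stat >= 0 and df == 1 and 0 <= p <= 1

    def test_stratified_fit_uses_separate_risk_sets(self):
        """A stratified fit equals pooling the per-stratum log-likelihoods."""
        rng = np.random.default_rng(31)
        ds = make_ds(rng.integers(1, 10, 40), rng.integers(0, 2, 40) | 1,
                     x=rng.normal(size=40), site=list("AB") * 20)
        fit = fit_cox(ds, ["x"], strata="site")
        beta = fit.coefficients.to_numpy()
        parts = []
        for s in "AB":
            sub = ds.with_frame(ds.frame[ds.frame["site"] == s]
                                .reset_index(drop=True))
            parts.append(partial_loglik(sub, ["x"], beta))
        assert fit.loglik_fit == pytest.approx(sum(parts), abs=1e-8)


# ----------------------------------------------------------------- stepwise

@pytest.fixture(scope="module")
def signal_noise_cohort():
    model = DiscreteHazardModel(
        baseline=[0.05] * 15,
        effects={"x": 0.9},
        covariate_dists={"x": ("bernoulli", 0.5),
                         "noise": ("normal", 0, 1)})
    ds, _ = generate_cohort(500, 15, model, censor_prob=0.02, seed=19)
    return ds


class TestStepwise:

    def test_backward_retains_true_effect(self, signal_noise_cohort):
        fit = stepwise_select(signal_noise_cohort, ["x", "noise"],
                              direction="backward")
        assert "x" in fit.selected
        assert fit.coefficients["x"] == pytest.approx(0.9, abs=0.45)

    def test_forward_on_pure_noise_stays_near_null(self):
        model = DiscreteHazardModel(
            baseline=[0.05] * 15,
            covariate_dists={"n1": ("normal", 0, 1), "n2": ("normal", 0, 1)})
        ds, _ = generate_cohort(500, 15, model, censor_prob=0.02, seed=23)
        fit = stepwise_select(ds, ["n1", "n2"], direction="forward")
        null_aic = -2 * fit.loglik_null
        assert len(fit.selected) <= 1
        assert fit.aic <= null_aic + 2

    def test_both_direction_reaches_fixed_point(self, signal_noise_cohort):
        ds = signal_noise_cohort
        fit = stepwise_select(ds, ["x", "noise"], direction="both")
        selected = set(fit.selected)
        for cov in ["x", "noise"]:
            trial = (selected - {cov}) if cov in selected else (selected | {cov})
            if trial:
                other = fit_cox(ds, sorted(trial)).aic
            else:
                other = -2 * fit.loglik_null
            assert fit.aic <= other + 1e-9


# ------------------------------------------------------- PH assumption test

class TestPhAssumption:
    def test_single_covariate_global_equals_per_variable(self):
        model = DiscreteHazardModel(baseline=[0.06] * 12,
                                    effects={"x": 0.5},
                                    covariate_dists={"x": ("bernoulli", 0.5)})
        ds, _ = generate_cohort(400, 12, model, censor_prob=0.02, seed=29)
        table = ph_assumption_test(fit_cox(ds, ["x"]))
        assert table.loc["x", "chisq"] == pytest.approx(
            table.loc["GLOBAL", "chisq"], rel=1e-9)

    def test_null_rejection_rate_is_calibrated(self):
        """Proportional data: the global test rejects at ~ the nominal rate."""
        model = DiscreteHazardModel(baseline=[0.05] * 20,
                                    effects={"x": 0.6},
                                    covariate_dists={"x": ("bernoulli", 0.5)})
        rej = 0
        reps = 500
        for k in range(reps):
            ds, _ = generate_cohort(1000, 20, model, censor_prob=0.01,
                                    seed=1000 + k)
            table = ph_assumption_test(fit_cox(ds, ["x"]))
            rej += table.loc["GLOBAL", "p"] < 0.05
        assert 0.03 <= rej / reps <= 0.07

    def test_detects_reversing_effect(self):
        """A covariate whose effect flips sign mid-study is flagged."""
        rng = np.random.default_rng(41)
        half = [0.15] * 10 + [0.02] * 10
        flat = [0.06] * 20
        frames = []
        for hazards, xval, seed in [(half, 1.0, 1), (flat, 0.0, 2)]:
            model = DiscreteHazardModel(baseline=hazards)
            sub, _ = generate_cohort(500, 20, model, censor_prob=0.01,
                                     seed=seed)
            frame = sub.frame.copy()
            frame["x"] = xval
            frames.append(frame)
        ds = SurvivalDataset(pd.concat(frames, ignore_index=True),
                             "time", "status", ("x",))
        table = ph_assumption_test(fit_cox(ds, ["x"]))
        assert table.loc["x", "p"] < 0.01

    def test_too_few_events_rejected(self):
        ds = make_ds([1, 2, 3], [1, 0, 0], x=[0.0, 1.0, 2.0])
        with pytest.warns(UserWarning):
            fit = fit_cox(ds, ["x"])
        with pytest.raises(ValidationError):
            ph_assumption_test(fit)
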