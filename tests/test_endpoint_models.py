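import numpy as np
import pytest

import kinetrace as kt
from kinetrace.endpoint_models import (
    RateRow,
    RateTable,
    fit_logistic4,
    fit_michaelis_menten,
    hts_flag,
    subtract_blank_rates,
)


def _table(conc, rates, stderrs=None, labels=None):
    labels = labels if labels is not None else [f"s{i}" for i in range(len(conc))]
    return RateTable.from_arrays(labels, conc, rates, stderrs)


class TestMichaelisMenten:
    CONC = np.array([5.0, 10.0, 25.0, 50.0, 100.0, 320.0])

    def test_exact_hyperbola_recovered(self):
        v = 10.0 * self.CONC / (25.0 + self.CONC)
        fit = fit_michaelis_menten(_table(self.CONC, v))
        assert fit.vmax == pytest.approx(10.0, rel=1e-6)
        assert fit.km == pytest.approx(25.0, rel=1e-6)

    def test_zero_concentration_rows_excluded(self):
        v = 10.0 * self.CONC / (25.0 + self.CONC)
        with_blank = _table(
            np.concatenate([[0.0], self.CONC]), np.concatenate([[99.0], v])
        )
        fit = fit_michaelis_menten(with_blank)
        assert fit.km == pytest.approx(25.0, rel=1e-6)

    def test_matches_grid_search_oracle(self):
        # brute-force minimiser of the same weighted SSE on noisy rates
        rng = np.random.default_rng(11)
        conc = np.array([5.0, 10.0, 20.0, 40.0, 80.0, 160.0, 320.0])
        sd = 0.05 * np.ones_like(conc)
        v = 8.0 * conc / (60.0 + conc) + rng.normal(0.0, sd)
        fit = fit_michaelis_menten(_table(conc, v, sd))

        kms = np.linspace(30.0, 120.0, 400)
        vmaxs = np.linspace(6.0, 10.0, 400)
        km_g, vm_g = np.meshgrid(kms, vmaxs)
        sse = np.zeros_like(km_g)
        for c, vi, s in zip(conc, v, sd):
            sse += ((vi - vm_g * c / (km_g + c)) / s) ** 2
        i, j = np.unravel_index(np.argmin(sse), sse.shape)
        assert fit.km == pytest.approx(km_g[i, j], rel=0.005)
        assert fit.vmax == pytest.approx(vm_g[i, j], rel=0.005)
        fit_sse = np.sum(((v - fit.predict(conc)) / sd) ** 2)
        assert fit_sse <= sse[i, j] + 1e-9

    def test_large_stderr_row_is_downweighted(self):
        conc = self.CONC
        v = 10.0 * conc / (25.0 + conc)
        sd = np.full_like(conc, 0.01)
        base = fit_michaelis_menten(_table(conc, v, sd))
        v_bad = v.copy()
        v_bad[2] *= 3.0  # grossly perturb one point...
        sd_bad = sd.copy()
        sd_bad[2] *= 100.0  # ...but tell the fit not to trust it
        perturbed = fit_michaelis_menten(_table(conc, v_bad, sd_bad))
        assert perturbed.km == pytest.approx(base.km, rel=0.01)
        assert perturbed.vmax == pytest.approx(base.vmax, rel=0.01)

    def test_stderr_inflation_property(self):
        rng = np.random.default_rng(3)
        conc = self.CONC
        sd = np.full_like(conc, 0.05)
        v = 10.0 * conc / (25.0 + conc) + rng.normal(0.0, sd)
        a = fit_michaelis_menten(_table(conc, v, sd))
        b = fit_michaelis_menten(_table(conc, v, 10.0 * sd))
        assert b.km == pytest.approx(a.km, rel=1e-6)
        assert b.vmax == pytest.approx(a.vmax, rel=1e-6)
        assert b.stderr_km == pytest.approx(10.0 * a.stderr_km, rel=1e-4)

    def test_prediction_monotone_in_substrate(self):
        v = 7.0 * self.CONC / (40.0 + self.CONC)
        fit = fit_michaelis_menten(_table(self.CONC, v))
        s = np.linspace(0.1, 500.0, 200)
        assert np.all(np.diff(fit.predict(s)) > 0)

    def test_too_few_distinct_concentrations(self):
        with pytest.raises(ValueError, match="distinct"):
            fit_michaelis_menten(_table([5.0, 5.0, 10.0], [1.0, 1.1, 1.5]))


class TestLogistic4:
    X = np.linspace(-9.0, -3.0, 8)  # log10 molar
    Y = 100.0 / (1.0 + 10.0 ** (1.0 * (-6.0 - X)))

    def _tab(self):
        return _table(10.0**self.X, self.Y)

    def test_exact_recovery(self):
        fit = fit_logistic4(self._tab(), x_scale="log10")
        assert fit.bottom == pytest.approx(0.0, abs=1e-6)
        assert fit.top == pytest.approx(100.0, rel=1e-6)
        assert fit.hill == pytest.approx(1.0, rel=1e-6)
        assert fit.midpoint == pytest.approx(-6.0, rel=1e-6)

    def test_midpoint_predicts_half_response(self):
        fit = fit_logistic4(self._tab(), x_scale="log10")
        assert fit.predict(fit.midpoint) == pytest.approx((fit.top + fit.bottom) / 2.0, abs=1e-10)

    def test_fixed_hill_reproduces_free_fit_when_truth_has_hill_one(self):
        free = fit_logistic4(self._tab(), x_scale="log10")
        fixed = fit_logistic4(self._tab(), fixed={"hill": 1.0}, x_scale="log10")
        assert fixed.midpoint == pytest.approx(free.midpoint, abs=1e-6)
        assert fixed.stderr_hill == 0.0
        assert "hill" in fixed.fixed
        sse_free = np.sum((self.Y - free.predict(self.X)) ** 2)
        sse_fixed = np.sum((self.Y - fixed.predict(self.X)) ** 2)
        assert abs(sse_free - sse_fixed) < 1e-9

    def test_monotone_with_hill_sign(self):
        fit = fit_logistic4(self._tab(), x_scale="log10")
        x = np.linspace(-10.0, -2.0, 100)
        assert np.all(np.sign(np.diff(fit.predict(x))) == np.sign(fit.hill))

    def test_decreasing_dose_response(self):
        y_down = 100.0 - self.Y  # inhibitor: top at low dose
        fit = fit_logistic4(_table(10.0**self.X, y_down), x_scale="log10")
        assert fit.midpoint == pytest.approx(-6.0, rel=1e-5)

    def test_zero_concentration_dropped_on_log_axis_with_warning(self):
        conc = np.concatenate([[0.0], 10.0**self.X])
        y = np.concatenate([[0.0], self.Y])
        with pytest.warns(UserWarning, match="zero-concentration"):
            fit = fit_logistic4(_table(conc, y), x_scale="log10")
        assert fit.midpoint == pytest.approx(-6.0, rel=1e-5)

    def test_all_fixed_is_overconstrained(self):
        with pytest.raises(ValueError, match="fixed"):
            fit_logistic4(self._tab(), fixed={"top": 1, "bottom": 0, "hill": 1, "midpoint": -6})

    def test_flat_response_errors(self):
        with pytest.raises(RuntimeError, match="flat"):
            fit_logistic4(_table(10.0**self.X, np.full(8, 3.0)))


class TestHtsFlag:
    def test_hand_computed_example(self):
        # mean 3.25, sample SD 4.5; only the 10 exceeds mean + 1 SD
        res = hts_flag(_table([0] * 4, [1.0, 1.0, 1.0, 10.0], labels=list("abcd")), 1.0)
        assert res.mean_rate == pytest.approx(3.25)
        assert res.sd_rate == pytest.approx(4.5)
        assert res.flags == {"a": "none", "b": "none", "c": "none", "d": "above"}

    def test_equal_rates_flag_nothing(self):
        res = hts_flag(_table([0] * 3, [2.0, 2.0, 2.0]), 1.0)
        assert set(res.flags.values()) == {"none"}
        assert res.sd_rate == 0.0

    def test_threshold_is_strict(self):
        # rates 0,1,2: mean 1, sd 1; 0 and 2 sit exactly on the boundary
        res = hts_flag(_table([0] * 3, [0.0, 1.0, 2.0]), 1.0)
        assert set(res.flags.values()) == {"none"}

    def test_matches_zscore_oracle_on_random_tables(self):
        rng = np.random.default_rng(123)
        for _ in range(200):
            n = int(rng.integers(3, 40))
            rates = rng.normal(rng.uniform(-2, 2), rng.uniform(0.1, 3), n)
            k = float(rng.uniform(0.5, 3.0))
            res = hts_flag(_table([0] * n, rates), k)
            z = (rates - rates.mean()) / rates.std(ddof=1)
            expected = np.where(z > k, "above", np.where(z < -k, "below", "none"))
            assert list(res.flags.values()) == list(expected)


class TestSubtractBlankRates:
    def test_quadrature_combination(self):
        table = RateTable.from_arrays(["blank", "A"], [0.0, 10.0], [0.5, 2.0], [0.1, 0.2])
        out = subtract_blank_rates(table, "blank")
        assert out.rows[0].rate == pytest.approx(1.5)
        assert out.rows[0].stderr == pytest.approx(np.sqrt(0.04 + 0.01), rel=1e-12)
        assert out.labels == ("A",)

    def test_zero_blank_only_removes_row(self):
        table = RateTable.from_arrays(["b", "A"], [0.0, 10.0], [0.0, 2.0], [0.0, 0.2])
        out = subtract_blank_rates(table, "b")
        assert out.rows[0].rate == 2.0
        assert out.rows[0].stderr == 0.2

    def test_subtract_then_add_back_restores_rates(self):
        table = RateTable.from_arrays(
            ["b", "A", "B"], [0.0, 5.0, 10.0], [0.3, 1.0, 2.0], [0.05, 0.1, 0.1]
        )
        out = subtract_blank_rates(table, "b")
        restored = [r.rate + 0.3 for r in out.rows]
        assert restored == pytest.approx([1.0, 2.0])

    def test_missing_label_errors(self):
        table = RateTable.from_arrays(["A"], [1.0], [1.0])
        with pytest.raises(KeyError):
            subtract_blank_rates(table, "nope")
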