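import numpy as np
import pytest

from stau_rnaloc.binding import (
    BindingCurveFitter,
    BindingModelSelector,
    Sensorgram,
    SensorgramFitter,
    dissociation_rate,
    eval_hill,
    eval_one_site,
    eval_steady_state,
    eval_two_site,
    fit_sensorgram,
    fit_steady_state,
    select_model,
    simulate_sensorgram,
)
from stau_rnaloc.errors import (
    FitFailureError,
    InvalidParameterError,
    UnderDeterminedError,
)
from stau_rnaloc.synthetic import simulate_binding_curve

CONC_GRID = np.geomspace(0.5, 5000, 25)


class TestEvaluators:
    def test_one_site_midpoint_and_origin(self):
        assert eval_one_site(132.0, 132.0, 100.0) == pytest.approx(50.0)
        assert eval_one_site(0.0, 10.0, 100.0) == 0.0

    def test_two_site_saturation_and_midpoint(self):
        assert eval_two_site(1e12, 10.0, 100.0, 30.0, 70.0) == pytest.approx(
            100.0, rel=1e-9
        )
        assert eval_two_site(50.0, 50.0, 50.0, 30.0, 70.0) == pytest.approx(50.0)
        assert eval_two_site(100.0, 18.0, 2000.0, 50.0, 50.0) == pytest.approx(
            44.75, abs=0.005
        )

    def test_hill_midpoint_for_any_exponent(self):
        for n in (0.5, 1.0, 1.7, 3.0):
            assert eval_hill(357.0, 357.0, n, 100.0) == pytest.approx(50.0)

    def test_hill_reference_value(self):
        # 2^1.7 / (1 + 2^1.7) * 100
        assert eval_hill(714.0, 357.0, 1.7, 100.0) == pytest.approx(76.47, abs=0.005)

    def test_hill_with_n1_equals_one_site_everywhere(self):
        np.testing.assert_allclose(
            eval_hill(CONC_GRID, 650.0, 1.0, 80.0),
            eval_one_site(CONC_GRID, 650.0, 80.0),
            rtol=1e-12,
        )

    def test_two_site_with_equal_kds_equals_one_site(self):
        np.testing.assert_allclose(
            eval_two_site(CONC_GRID, 200.0, 200.0, 30.0, 70.0),
            eval_one_site(CONC_GRID, 200.0, 100.0),
            rtol=1e-12,
        )

    @pytest.mark.parametrize(
        "model,params",
        [
            ("one_site", dict(kd=100.0, rmax=80.0)),
            ("two_site", dict(kd1=10.0, kd2=500.0, rmax1=40.0, rmax2=60.0)),
            ("hill", dict(kd=300.0, n=1.7, rmax=90.0)),
        ],
    )
    def test_monotone_nondecreasing_and_bounded(self, model, params):
        r = eval_steady_state(model, CONC_GRID, params)
        assert np.all(np.diff(r) >= -1e-12)
        total = params.get("rmax", 0) + params.get("rmax1", 0) + params.get("rmax2", 0)
        assert np.all(r <= total + 1e-9)

    def test_invalid_parameters_raise(self):
        with pytest.raises(InvalidParameterError):
            eval_one_site(10.0, -1.0, 100.0)
        with pytest.raises(InvalidParameterError):
            eval_hill(10.0, 100.0, 0.0, 100.0)
        with pytest.raises(InvalidParameterError):
            eval_two_site(10.0, 10.0, 20.0, -5.0, 50.0)


TRUE_PARAMS = {
    "one_site": dict(kd=132.0, rmax=100.0),
    "two_site": dict(kd1=18.0, kd2=500.0, rmax1=50.0, rmax2=50.0),
    "hill": dict(kd=357.0, n=1.7, rmax=100.0),
}


class TestSteadyStateFitting:
    @pytest.mark.parametrize("model", ["one_site", "two_site", "hill"])
    def test_noiseless_round_trip_recovers_parameters(self, model):
        conc = np.geomspace(1, 3000, 12)
        curve = simulate_binding_curve(model, TRUE_PARAMS[model], conc)
        fit = fit_steady_state(curve, model, seed=0)
        for name, true in TRUE_PARAMS[model].items():
            assert fit.params_[name] == pytest.approx(true, rel=1e-3), name

    @pytest.mark.parametrize("model", ["one_site", "two_site", "hill"])
    def test_noisy_round_trip_median_error_within_10pct(self, model):
        # a dense titration: the low-affinity site of the two-site model
        # needs ~24 points for a well-conditioned fit at 1% response noise
        conc = np.geomspace(0.5, 20000, 24)
        rmax_total = sum(v for k, v in TRUE_PARAMS[model].items() if "rmax" in k)
        errs = {k: [] for k in TRUE_PARAMS[model]}
        for rep in range(20):
            curve = simulate_binding_curve(
                model, TRUE_PARAMS[model], conc,
                noise_sd=0.01 * rmax_total, seed=1000 + rep,
            )
            fit = fit_steady_state(curve, model, seed=rep)
            for name, true in TRUE_PARAMS[model].items():
                errs[name].append(abs(fit.params_[name] - true) / true)
        for name, e in errs.items():
            assert np.median(e) <= 0.10, (name, np.median(e))

    def test_kd_above_max_concentration_is_flagged_censored(self):
        conc = np.geomspace(1, 1000, 12)
        curve = simulate_binding_curve(
            "two_site", dict(kd1=18, kd2=2000, rmax1=50, rmax2=50), conc
        )
        fit = fit_steady_state(curve, "two_site", seed=0)
        assert fit.censored_ == {"kd1": False, "kd2": True}
        assert fit.censored_repr_["kd2"] == "> 1000 nM"

    def test_constant_zero_curve_never_crashes(self):
        import pandas as pd

        curve = pd.DataFrame(
            {"conc_nM": np.geomspace(1, 1000, 8), "response_RU": np.zeros(8)}
        )
        try:
            fit = fit_steady_state(curve, "one_site", seed=0)
        except FitFailureError:
            return
        assert fit.params_["rmax"] < 1e-3 or fit.censored_["kd"]

    def test_too_few_points_raises_underdetermined(self):
        import pandas as pd

        curve = pd.DataFrame({"conc_nM": [1.0, 10.0, 100.0], "response_RU": [1, 5, 20]})
        with pytest.raises(UnderDeterminedError):
            fit_steady_state(curve, "two_site")

    def test_sklearn_param_interface(self):
        est = BindingCurveFitter(model="hill", n_starts=8)
        assert est.get_params()["model"] == "hill"
        est.set_params(model="one_site")
        assert est.model == "one_site"


class TestModelSelection:
    def test_cooperative_data_selects_hill_over_one_site(self):
        conc = np.geomspace(10, 3000, 12)
        curve = simulate_binding_curve(
            "hill", dict(kd=357, n=1.7, rmax=100), conc, noise_sd=1.0, seed=5
        )
        sel = select_model(curve, candidates=("one_site", "hill"), seed=0)
        assert sel.best_model_ == "hill"
        assert set(sel.scores_) == {"one_site", "hill"}

    def test_noncooperative_data_does_not_select_hill(self):
        conc = np.geomspace(1, 1000, 12)
        curve = simulate_binding_curve(
            "one_site", dict(kd=132, rmax=100), conc, noise_sd=1.0, seed=6
        )
        sel = select_model(curve, candidates=("one_site", "hill"), seed=0)
        assert sel.best_model_ == "one_site"

    def test_single_candidate_matches_direct_fit(self):
        conc = np.geomspace(1, 1000, 12)
        curve = simulate_binding_curve(
            "one_site", dict(kd=132, rmax=100), conc, noise_sd=0.5, seed=7
        )
        sel = BindingModelSelector(candidates=("one_site",), random_state=0).fit(
            curve["conc_nM"], curve["response_RU"]
        )
        direct = fit_steady_state(curve, "one_site", seed=0)
        assert sel.best_.params_["kd"] == pytest.approx(direct.params_["kd"], rel=1e-9)


BIVALENT = dict(ka1=2e5, kd1=5e-3, ka2=1e-4, kd2=2e-3, lmax=100.0)
T_GRID = np.linspace(0.0, 900.0, 301)
T_ASSOC = 300.0


def langmuir_1to1(t, conc_nm, ka1, kd1, lmax, t_assoc):
    """Independent closed-form 1:1 association/dissociation curve."""
    c = conc_nm * 1e-9
    kobs = ka1 * c + kd1
    req = lmax * c / (kd1 / ka1 + c)
    r = np.where(
        t <= t_assoc,
        req * (1.0 - np.exp(-kobs * t)),
        req * (1.0 - np.exp(-kobs * t_assoc)) * np.exp(-kd1 * (t - t_assoc)),
    )
    return r


class TestSensorgrams:
    def test_monovalent_limit_matches_analytic_langmuir(self):
        params = dict(BIVALENT, ka2=0.0)
        s = simulate_sensorgram(params, 1000.0, T_GRID, T_ASSOC)
        analytic = langmuir_1to1(
            T_GRID, 1000.0, params["ka1"], params["kd1"], params["lmax"], T_ASSOC
        )
        assert np.max(np.abs(s.response - analytic)) <= 1e-3 * analytic.max()

    def test_association_plateau_equals_steady_state_isotherm(self):
        params = dict(BIVALENT, ka2=0.0)
        t = np.linspace(0, 20000, 200)
        s = simulate_sensorgram(params, 500.0, t, t_assoc=20000.0)
        kd_nm = params["kd1"] / params["ka1"] / 1e-9
        expected = eval_one_site(500.0, kd_nm, params["lmax"])
        assert s.response[-1] == pytest.approx(expected, rel=1e-4)

    def test_zero_concentration_stays_flat(self):
        s = simulate_sensorgram(BIVALENT, 0.0, T_GRID, T_ASSOC)
        np.testing.assert_allclose(s.response, 0.0, atol=1e-9)

    def test_noiseless_round_trip_within_one_percent(self):
        sgrams = [
            simulate_sensorgram(BIVALENT, c, T_GRID, T_ASSOC) for c in (250.0, 1000.0)
        ]
        fit = fit_sensorgram(sgrams, seed=0)
        assert fit.params_["ka1"] == pytest.approx(BIVALENT["ka1"], rel=0.01)
        assert fit.params_["kd1"] == pytest.approx(BIVALENT["kd1"], rel=0.01)

    def test_dissociation_rate_recovers_kd1(self):
        params = dict(BIVALENT, ka2=0.0)
        s = simulate_sensorgram(params, 1000.0, T_GRID, T_ASSOC)
        assert dissociation_rate(s) == pytest.approx(params["kd1"], rel=1e-3)

    def test_flat_zero_trace_raises_fit_failure(self):
        s = Sensorgram(T_GRID, np.zeros_like(T_GRID), 1000.0, T_ASSOC)
        with pytest.raises(FitFailureError):
            SensorgramFitter().fit([s])

    def test_nonmonotone_time_grid_rejected(self):
        with pytest.raises(InvalidParameterError):
            Sensorgram(np.array([0.0, 2.0, 1.0]), np.zeros(3), 100.0, 1.0)

    def test_invalid_rate_constants_rejected(self):
        with pytest.raises(InvalidParameterError):
            simulate_sensorgram(dict(BIVALENT, kd1=-1.0), 100.0, T_GRID, T_ASSOC)
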