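"""Equilibrium and kinetic binding models for SPR-style data.

Steady-state isotherms
----------------------
``one_site``  R = Rmax·C/(KD + C)
``two_site``  R = Rmax1·C/(KD1 + C) + Rmax2·C/(KD2 + C), KD1 <= KD2
``hill``      R = Rmax·C^n/(KD^n + C^n)

Bivalent-analyte kinetics (A + L <-> AL, AL + L <-> AL2)::

    d[AL]/dt  = ka1·C·Lfree − kd1·AL − ka2·AL·Lfree + kd2·AL2
    d[AL2]/dt = ka2·AL·Lfree − kd2·AL2
    Lfree     = Lmax − AL − 2·AL2,   R(t) = AL + AL2

with C set to zero after the association phase. The response weights
the singly and doubly tethered species equally and each second-step
event consumes one additional ligand site; this convention is fixed
and documented here.

Concentrations are handled internally in molar units; all public
interfaces accept and report nanomolar (the customary unit for these
affinities). Rate constants are ka1 [M^-1 s^-1], kd1/kd2 [s^-1],
ka2 [RU^-1 s^-1], Lmax/Rmax [RU].

Fitting is multi-start nonlinear least squares in log-parameter space
(all parameters are positive); the best start by residual sum of
squares wins. Dissociation constants that exceed the largest tested
concentration are flagged censored and additionally reported as
``"> <Cmax> nM"``, mirroring how unsaturated sites are tabulated.
Model selection uses the small-sample-corrected Akaike criterion.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp
from scipy.optimize import least_squares
from sklearn.base import BaseEstimator

from stau_rnaloc.errors import (
    FitFailureError,
    InvalidParameterError,
    UnderDeterminedError,
)

NM_TO_M = 1e-9

#: free parameters per steady-state model, in reporting order
MODEL_PARAMS: dict[str, tuple[str, ...]] = {
    "one_site": ("kd", "rmax"),
    "two_site": ("kd1", "kd2", "rmax1", "rmax2"),
    "hill": ("kd", "n", "rmax"),
}

_KD_NAMES = {"kd", "kd1", "kd2"}


# ---------------------------------------------------------------------------
# steady-state evaluators (unit-agnostic: C and KD in the same unit)
# ---------------------------------------------------------------------------


def eval_one_site(conc, kd, rmax):
    """First-order (1:1 Langmuir) isotherm."""
    conc = np.asarray(conc, dtype=float)
    if np.any(conc < 0):
        raise InvalidParameterError("concentrations must be >= 0")
    if kd <= 0:
        raise InvalidParameterError(f"KD must be positive, got {kd}")
    if rmax < 0:
        raise InvalidParameterError(f"Rmax must be >= 0, got {rmax}")
    return rmax * conc / (kd + conc)


def eval_two_site(conc, kd1, kd2, rmax1, rmax2):
    """Sum of two independent hyperbolic binding sites."""
    return eval_one_site(conc, kd1, rmax1) + eval_one_site(conc, kd2, rmax2)


def eval_hill(conc, kd, n, rmax):
    """Hill isotherm with cooperativity exponent ``n``."""
    conc = np.asarray(conc, dtype=float)
    if np.any(conc < 0):
        raise InvalidParameterError("concentrations must be >= 0")
    if kd <= 0:
        raise InvalidParameterError(f"KD must be positive, got {kd}")
    if n <= 0:
        raise InvalidParameterError(f"Hill coefficient must be positive, got {n}")
    if rmax < 0:
        raise InvalidParameterError(f"Rmax must be >= 0, got {rmax}")
    cn = np.power(conc, n)
    return rmax * cn / (kd**n + cn)


def eval_steady_state(model: str, conc, params: Mapping[str, float]):
    """Dispatch to the named steady-state evaluator."""
    if model == "one_site":
        return eval_one_site(conc, params["kd"], params["rmax"])
    if model == "two_site":
        return eval_two_site(
            conc, params["kd1"], params["kd2"], params["rmax1"], params["rmax2"]
        )
    if model == "hill":
        return eval_hill(conc, params["kd"], params["n"], params["rmax"])
    raise InvalidParameterError(f"unknown steady-state model {model!r}")


# ---------------------------------------------------------------------------
# steady-state fitting
# ---------------------------------------------------------------------------


class BindingCurveFitter(BaseEstimator):
    """Multi-start least-squares fit of one steady-state binding model.

    Parameters
    ----------
    model
        ``"one_site"``, ``"two_site"`` or ``"hill"``.
    n_starts
        Number of log-uniform random starts. KD draws span
        ``[max(C)/1e4, 100·max(C)]``, Hill ``n`` spans ``[0.2, 4]``;
        two-site fits have symmetric local minima, hence the default
        of 32 starts.
    shared_rmax
        Two-site only: constrain Rmax1 = Rmax2.
    random_state
        Seed for the start draws.

    Attributes (after :meth:`fit`)
    ------------------------------
    params_ : dict
        Fitted parameters; KDs in nM, Rmax in RU.
    se_ : dict
        Asymptotic standard errors (same units).
    rss_, aicc_, n_obs_ : float
    censored_ : dict
        Per-KD flag, True when the fitted KD exceeds max(C).
    censored_repr_ : dict
        ``"> <Cmax> nM"`` strings for censored KDs.
    """

    def __init__(
        self,
        model: str = "two_site",
        n_starts: int = 32,
        shared_rmax: bool = False,
        random_state: int | None = 0,
    ):
        self.model = model
        self.n_starts = n_starts
        self.shared_rmax = shared_rmax
        self.random_state = random_state

    # -- internal parametrisation ------------------------------------------

    def _free_names(self) -> tuple[str, ...]:
        if self.model == "two_site" and self.shared_rmax:
            return ("kd1", "kd2", "rmax")
        return MODEL_PARAMS[self.model]

    def _expand(self, values: Mapping[str, float]) -> dict[str, float]:
        if self.model == "two_site" and self.shared_rmax:
            return {
                "kd1": values["kd1"],
                "kd2": values["kd2"],
                "rmax1": values["rmax"],
                "rmax2": values["rmax"],
            }
        return dict(values)

    def _eval(self, conc_m: np.ndarray, theta_log: np.ndarray) -> np.ndarray:
        values = dict(zip(self._free_names(), np.exp(theta_log)))
        return eval_steady_state(self.model, conc_m, self._expand(values))

    # -- fitting -----------------------------------------------------------

    def fit(self, conc_nm, response, sample_weight=None):
        if self.model not in MODEL_PARAMS:
            raise InvalidParameterError(f"unknown steady-state model {self.model!r}")
        conc_nm = np.asarray(conc_nm, dtype=float).ravel()
        response = np.asarray(response, dtype=float).ravel()
        if conc_nm.shape != response.shape:
            raise InvalidParameterError("conc and response lengths differ")
        if np.any(conc_nm <= 0) or not np.all(np.isfinite(conc_nm)):
            raise InvalidParameterError("concentrations must be positive and finite")
        if not np.all(np.isfinite(response)):
            raise InvalidParameterError("responses must be finite")
        names = self._free_names()
        p = len(names)
        if len(np.unique(conc_nm)) < p + 1:
            raise UnderDeterminedError(
                f"{self.model} needs at least {p + 1} distinct concentrations, "
                f"got {len(np.unique(conc_nm))}"
            )

        conc_m = conc_nm * NM_TO_M
        max_c = conc_m.max()
        max_r = max(response.max(), 0.0)
        r_scale = max_r if max_r > 0 else 1.0
        rng = np.random.default_rng(self.random_state)

        lo, hi = [], []
        for name in names:
            if name in _KD_NAMES:
                lo.append(np.log(max_c) - 25.0)
                hi.append(np.log(max_c) + 25.0)
            elif name == "n":
                lo.append(np.log(0.05))
                hi.append(np.log(20.0))
            else:  # rmax-like
                lo.append(np.log(r_scale) - 30.0)
                hi.append(np.log(r_scale) + 10.0)
        lo, hi = np.array(lo), np.array(hi)

        def residual(theta_log):
            return self._eval(conc_m, theta_log) - response

        starts = []
        for _ in range(max(int(self.n_starts), 1)):
            draw = []
            for name in names:
                if name in _KD_NAMES:
                    draw.append(rng.uniform(np.log(max_c * 1e-4), np.log(max_c * 1e2)))
                elif name == "n":
                    draw.append(rng.uniform(np.log(0.2), np.log(4.0)))
                else:
                    draw.append(rng.uniform(np.log(r_scale * 0.2), np.log(r_scale * 5.0)))
            starts.append(self._project_rmax(np.array(draw), conc_m, response, names))

        best = None
        total = float(np.sum(response**2))
        for theta0 in starts:
            theta0 = np.clip(theta0, lo, hi)
            try:
                sol = least_squares(
                    residual, theta0, bounds=(lo, hi), xtol=1e-14, ftol=1e-14,
                    gtol=1e-14, max_nfev=2000,
                )
            except Exception:  # noqa: BLE001 - a single diverged start is fine
                continue
            if not np.all(np.isfinite(sol.x)):
                continue
            if best is None or sol.cost < best.cost:
                best = sol
            if best.cost <= max(1e-24 * max(total, 1.0), 1e-28):
                break
        if best is None:
            raise FitFailureError(
                f"all {self.n_starts} starts diverged for model {self.model} "
                f"(n={len(conc_nm)}, max(C)={conc_nm.max():g} nM)"
            )

        values = dict(zip(names, np.exp(best.x)))
        params_m = self._expand(values)
        if self.model == "two_site" and params_m["kd1"] > params_m["kd2"]:
            params_m = {
                "kd1": params_m["kd2"],
                "kd2": params_m["kd1"],
                "rmax1": params_m["rmax2"],
                "rmax2": params_m["rmax1"],
            }

        rss = float(np.sum((eval_steady_state(self.model, conc_m, params_m) - response) ** 2))
        se_m = _standard_errors(
            lambda pv: eval_steady_state(
                self.model, conc_m, dict(zip(MODEL_PARAMS[self.model], pv))
            ),
            np.array([params_m[k] for k in MODEL_PARAMS[self.model]]),
            response,
            rss,
        )
        se = dict(zip(MODEL_PARAMS[self.model], se_m))

        # report KDs in nM
        self.params_ = {
            k: (v / NM_TO_M if k in _KD_NAMES else v) for k, v in params_m.items()
        }
        self.se_ = {k: (v / NM_TO_M if k in _KD_NAMES else v) for k, v in se.items()}
        self.rss_ = rss
        self.n_obs_ = len(conc_nm)
        k_eff = p + 1  # + residual variance
        self.aicc_ = _aicc(rss, self.n_obs_, k_eff)
        max_c_nm = conc_nm.max()
        self.censored_ = {
            k: bool(self.params_[k] > max_c_nm) for k in self.params_ if k in _KD_NAMES
        }
        self.censored_repr_ = {
            k: f"> {max_c_nm:g} nM" for k, flag in self.censored_.items() if flag
        }
        self.max_conc_nm_ = float(max_c_nm)
        return self

    def _project_rmax(self, theta_log, conc_m, response, names):
        """Replace Rmax draws by their conditional linear least-squares optimum."""
        values = dict(zip(names, np.exp(theta_log)))
        try:
            if self.model == "one_site":
                basis = conc_m / (values["kd"] + conc_m)
                cols = ["rmax"]
                design = basis[:, None]
            elif self.model == "hill":
                cn = np.power(conc_m, values["n"])
                design = (cn / (values["kd"] ** values["n"] + cn))[:, None]
                cols = ["rmax"]
            elif self.shared_rmax:
                design = (
                    conc_m / (values["kd1"] + conc_m) + conc_m / (values["kd2"] + conc_m)
                )[:, None]
                cols = ["rmax"]
            else:
                design = np.column_stack(
                    [conc_m / (values["kd1"] + conc_m), conc_m / (values["kd2"] + conc_m)]
                )
                cols = ["rmax1", "rmax2"]
            from scipy.optimize import nnls

            coef, _ = nnls(design, np.maximum(response, 0.0))
            for name, c in zip(cols, coef):
                values[name] = max(c, 1e-12)
        except Exception:  # noqa: BLE001 - fall back to the raw draw
            pass
        return np.log(np.array([values[n] for n in names]))

    def predict(self, conc_nm):
        params_m = {
            k: (v * NM_TO_M if k in _KD_NAMES else v) for k, v in self.params_.items()
        }
        return eval_steady_state(
            self.model, np.asarray(conc_nm, dtype=float) * NM_TO_M, params_m
        )

    def result(self) -> dict:
        """JSON-ready summary of the fit."""
        return {
            "model": self.model,
            "params": self.params_,
            "se": self.se_,
            "rss": self.rss_,
            "aicc": self.aicc_,
            "n_obs": self.n_obs_,
            "censored": self.censored_,
            "censored_repr": self.censored_repr_,
            "max_conc_nM": self.max_conc_nm_,
        }


class BindingModelSelector(BaseEstimator):
    """Fit several candidate isotherms and keep the lowest-AICc one.

    The published criterion for calling a curve "best described by" a
    particular fit is informal; the corrected information criterion is
    the transparent stand-in used here. All per-candidate scores and
    any per-candidate failures are retained.
    """

    def __init__(
        self,
        candidates: Sequence[str] = ("one_site", "two_site", "hill"),
        n_starts: int = 32,
        random_state: int | None = 0,
    ):
        self.candidates = candidates
        self.n_starts = n_starts
        self.random_state = random_state

    def fit(self, conc_nm, response):
        if len(self.candidates) < 1:
            raise InvalidParameterError("need at least one candidate model")
        self.fits_ = {}
        self.scores_ = {}
        self.failures_ = {}
        for model in self.candidates:
            fitter = BindingCurveFitter(
                model=model, n_starts=self.n_starts, random_state=self.random_state
            )
            try:
                fitter.fit(conc_nm, response)
            except (FitFailureError, UnderDeterminedError) as exc:
                self.failures_[model] = str(exc)
                continue
            self.fits_[model] = fitter
            self.scores_[model] = fitter.aicc_
        if not self.fits_:
            raise FitFailureError(f"every candidate failed: {self.failures_}")
        self.best_model_ = min(self.scores_, key=self.scores_.get)
        self.best_ = self.fits_[self.best_model_]
        return self

    def predict(self, conc_nm):
        return self.best_.predict(conc_nm)

    def result(self) -> dict:
        out = self.best_.result()
        out["candidate_aicc"] = self.scores_
        out["candidate_failures"] = self.failures_
        return out


def _aicc(rss: float, n: int, k: int) -> float:
    rss = max(rss, n * 1e-300)
    aic = n * np.log(rss / n) + 2 * k
    if n - k - 1 > 0:
        aic += 2 * k * (k + 1) / (n - k - 1)
    else:
        aic = np.inf
    return float(aic)


def _standard_errors(model_fn, params, response, rss) -> np.ndarray:
    """Asymptotic SEs from a forward-difference Jacobian at the optimum."""
    n, p = len(response), len(params)
    if n <= p + 1:
        return np.full(p, np.nan)
    jac = np.empty((n, p))
    base = model_fn(params)
    for j in range(p):
        step = max(abs(params[j]) * 1e-6, 1e-12)
        shifted = params.copy()
        shifted[j] += step
        jac[:, j] = (model_fn(shifted) - base) / step
    s2 = rss / (n - p)
    try:
        cov = s2 * np.linalg.pinv(jac.T @ jac)
        return np.sqrt(np.clip(np.diag(cov), 0.0, np.inf))
    except np.linalg.LinAlgError:
        return np.full(p, np.nan)


# ---------------------------------------------------------------------------
# bivalent-analyte kinetics
# ---------------------------------------------------------------------------


@dataclass
class Sensorgram:
    """Time-resolved response at one analyte concentration."""

    time_s: np.ndarray
    response: np.ndarray
    conc_nm: float
    t_assoc: float

    def __post_init__(self) -> None:
        self.time_s = np.asarray(self.time_s, dtype=float)
        self.response = np.asarray(self.response, dtype=float)
        if self.time_s.shape != self.response.shape:
            raise InvalidParameterError("time and response lengths differ")
        if np.any(np.diff(self.time_s) <= 0):
            raise InvalidParameterError("time grid must be strictly increasing")
        if not (self.time_s[0] <= self.t_assoc <= self.time_s[-1]):
            raise InvalidParameterError("t_assoc must lie within the time grid")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time_s": self.time_s,
                "response_RU": self.response,
                "conc_nM": self.conc_nm,
            }
        )


BIVALENT_PARAMS = ("ka1", "kd1", "ka2", "kd2", "lmax")


def _validate_bivalent(params: Mapping[str, float]) -> dict[str, float]:
    out = {}
    for name in BIVALENT_PARAMS:
        v = float(params[name])
        if name == "ka2":
            if v < 0:
                raise InvalidParameterError("ka2 must be >= 0")
        elif v <= 0:
            raise InvalidParameterError(f"{name} must be positive, got {v}")
        out[name] = v
    return out


def _bivalent_rhs(t, y, ka1, kd1, ka2, kd2, lmax, conc_m):
    al, al2 = y
    lfree = lmax - al - 2.0 * al2
    d_al = ka1 * conc_m * lfree - kd1 * al - ka2 * al * lfree + kd2 * al2
    d_al2 = ka2 * al * lfree - kd2 * al2
    return (d_al, d_al2)


def simulate_sensorgram(
    params: Mapping[str, float],
    conc_nm: float,
    t: np.ndarray,
    t_assoc: float,
    noise_sd: float = 0.0,
    seed: int | None = None,
    rtol: float = 1e-9,
) -> Sensorgram:
    """Integrate the bivalent-analyte model over association/dissociation.

    ``params`` holds ka1 [M^-1 s^-1], kd1 [s^-1], ka2 [RU^-1 s^-1],
    kd2 [s^-1] and lmax [RU]; ``conc_nm`` is the analyte concentration
    held constant until ``t_assoc`` and zero afterwards.
    """
    p = _validate_bivalent(params)
    t = np.asarray(t, dtype=float)
    if np.any(np.diff(t) <= 0):
        raise InvalidParameterError("time grid must be strictly increasing")
    if conc_nm < 0:
        raise InvalidParameterError("concentration must be >= 0")
    conc_m = conc_nm * NM_TO_M
    args = (p["ka1"], p["kd1"], p["ka2"], p["kd2"], p["lmax"])
    atol = 1e-12 * max(p["lmax"], 1.0)

    t_a = t[t <= t_assoc]
    y_assoc = np.zeros((2, len(t_a)))
    y_edge = np.zeros(2)
    if t_assoc > t[0]:
        # one association solve yields both the sampled points and the
        # exact state at t_assoc for the dissociation start
        t_eval = t_a if (len(t_a) and t_a[-1] == t_assoc) else np.append(t_a, t_assoc)
        sol = solve_ivp(
            _bivalent_rhs, (t[0], t_assoc), np.zeros(2), t_eval=t_eval,
            args=args + (conc_m,), method="LSODA", rtol=rtol, atol=atol,
        )
        if not sol.success:
            raise FitFailureError(
                f"association integration failed ({sol.message}); params={p}, "
                f"C={conc_nm} nM"
            )
        y_assoc = sol.y[:, : len(t_a)]
        y_edge = sol.y[:, -1]

    t_d = t[t > t_assoc]
    if len(t_d):
        sol_d = solve_ivp(
            _bivalent_rhs, (t_assoc, t_d[-1]), y_edge, t_eval=t_d,
            args=args + (0.0,), method="LSODA", rtol=rtol, atol=atol,
        )
        if not sol_d.success:
            raise FitFailureError(
                f"dissociation integration failed ({sol_d.message}); params={p}"
            )
        y = np.concatenate([y_assoc, sol_d.y], axis=1)
    else:
        y = y_assoc
    response = y[0] + y[1]
    if noise_sd > 0:
        response = response + np.random.default_rng(seed).normal(
            0.0, noise_sd, size=len(response)
        )
    return Sensorgram(time_s=t, response=response, conc_nm=conc_nm, t_assoc=t_assoc)


def dissociation_rate(sgram: Sensorgram, window_frac: float = 0.3) -> float:
    """Mono-exponential off-rate from the log-linear early dissociation phase."""
    mask = sgram.time_s > sgram.t_assoc
    t, r = sgram.time_s[mask], sgram.response[mask]
    if len(t) < 3 or r[0] <= 0:
        raise InvalidParameterError("no usable dissociation phase")
    span = t[-1] - t[0]
    sel = (t - t[0]) <= max(window_frac * span, t[1] - t[0])
    sel &= r > max(1e-6 * r[0], 0.0)
    if sel.sum() < 2:
        raise InvalidParameterError("dissociation phase decays too fast to fit")
    slope = np.polyfit(t[sel], np.log(r[sel]), 1)[0]
    return float(-slope)


class SensorgramFitter(BaseEstimator):
    """Least-squares fit of the bivalent-analyte ODE model.

    Fits ka1, kd1, ka2, kd2 and Lmax jointly to one or more
    sensorgrams (log-parameter space; heuristic start from the
    dissociation tail and association rate, plus log-uniform random
    starts). A practically non-identifiable second step shows up as
    very wide standard errors on ka2/kd2 rather than failing silently.
    """

    def __init__(self, n_starts: int = 8, random_state: int | None = 0):
        self.n_starts = n_starts
        self.random_state = random_state

    def fit(self, sensorgrams: Sequence[Sensorgram], y=None):
        if isinstance(sensorgrams, Sensorgram):
            sensorgrams = [sensorgrams]
        if len(sensorgrams) < 1:
            raise InvalidParameterError("need at least one sensorgram")
        max_r = max(float(s.response.max(initial=0.0)) for s in sensorgrams)
        if max_r <= 0:
            raise FitFailureError("flat (all <= 0) sensorgrams cannot be fitted")
        rng = np.random.default_rng(self.random_state)

        def residual(theta_log):
            ka1, kd1, ka2, kd2, lmax = np.exp(theta_log)
            res = []
            for s in sensorgrams:
                try:
                    sim = simulate_sensorgram(
                        dict(ka1=ka1, kd1=kd1, ka2=ka2, kd2=kd2, lmax=lmax),
                        s.conc_nm, s.time_s, s.t_assoc, rtol=1e-8,
                    )
                    res.append(sim.response - s.response)
                except FitFailureError:
                    res.append(np.full_like(s.response, 1e3 * max_r))
            return np.concatenate(res)

        theta_h = self._heuristic_start(sensorgrams, max_r)
        starts = [theta_h]
        for _ in range(max(int(self.n_starts) - 1, 0)):
            starts.append(theta_h + rng.uniform(-2.3, 2.3, size=5))

        lo = np.log([1e1, 1e-6, 1e-12, 1e-6, max_r * 0.2])
        hi = np.log([1e10, 1e2, 1e1, 1e2, max_r * 1e3])
        total = float(sum(np.sum(s.response**2) for s in sensorgrams))
        best = None
        for theta0 in starts:
            theta0 = np.clip(theta0, lo, hi)
            try:
                sol = least_squares(
                    residual, theta0, bounds=(lo, hi), xtol=1e-12, ftol=1e-12,
                    gtol=1e-12, max_nfev=400,
                )
            except Exception:  # noqa: BLE001
                continue
            if not np.all(np.isfinite(sol.x)):
                continue
            if best is None or sol.cost < best.cost:
                best = sol
            if best.cost <= 1e-14 * max(total, 1.0):
                break
        if best is None:
            raise FitFailureError("all sensorgram fit starts diverged")

        params = dict(zip(BIVALENT_PARAMS, np.exp(best.x)))
        rss = float(2.0 * best.cost)
        n_obs = sum(len(s.response) for s in sensorgrams)

        def model_fn(pv):
            vals = dict(zip(BIVALENT_PARAMS, pv))
            out = []
            for s in sensorgrams:
                out.append(
                    simulate_sensorgram(vals, s.conc_nm, s.time_s, s.t_assoc, rtol=1e-8).response
                )
            return np.concatenate(out)

        flat_obs = np.concatenate([s.response for s in sensorgrams])
        se = _standard_errors(
            model_fn, np.array([params[k] for k in BIVALENT_PARAMS]), flat_obs, rss
        )
        self.params_ = params
        self.se_ = dict(zip(BIVALENT_PARAMS, se))
        self.rss_ = rss
        self.n_obs_ = n_obs
        self.aicc_ = _aicc(rss, n_obs, len(BIVALENT_PARAMS) + 1)
        return self

    def _heuristic_start(self, sensorgrams, max_r) -> np.ndarray:
        s = max(sensorgrams, key=lambda g: g.conc_nm)
        conc_m = max(s.conc_nm, 1e-3) * NM_TO_M
        try:
            kd1 = dissociation_rate(s)
        except InvalidParameterError:
            kd1 = 1e-2
        kd1 = float(np.clip(kd1, 1e-5, 10.0))
        # association pseudo-first-order rate from the 63% crossing
        mask = s.time_s <= s.t_assoc
        t_a, r_a = s.time_s[mask], s.response[mask]
        plateau = r_a.max() if len(r_a) else max_r
        kobs = kd1 * 2
        if len(r_a) and plateau > 0:
            above = np.nonzero(r_a >= (1 - np.exp(-1)) * plateau)[0]
            if len(above) and t_a[above[0]] > t_a[0]:
                kobs = 1.0 / (t_a[above[0]] - t_a[0])
        ka1 = max((kobs - kd1) / conc_m, 0.01 * kd1 / conc_m)
        return np.log(
            np.array([ka1, kd1, 1e-4, kd1, max(2.0 * max_r, 1e-6)])
        )

    def predict(self, sensorgrams: Sequence[Sensorgram]) -> list[np.ndarray]:
        if isinstance(sensorgrams, Sensorgram):
            sensorgrams = [sensorgrams]
        return [
            simulate_sensorgram(self.params_, s.conc_nm, s.time_s, s.t_assoc).response
            for s in sensorgrams
        ]

    def result(self) -> dict:
        return {
            "model": "bivalent",
            "params": self.params_,
            "se": self.se_,
            "rss": self.rss_,
            "aicc": self.aicc_,
            "n_obs": self.n_obs_,
        }


# ---------------------------------------------------------------------------
# thin functional wrappers
# ---------------------------------------------------------------------------


def fit_steady_state(
    curve: pd.DataFrame,
    model: str,
    n_starts: int = 32,
    seed: int | None = 0,
    shared_rmax: bool = False,
) -> BindingCurveFitter:
    """Fit one steady-state model to a ``conc_nM, response_RU`` table."""
    return BindingCurveFitter(
        model=model, n_starts=n_starts, shared_rmax=shared_rmax, random_state=seed
    ).fit(curve["conc_nM"], curve["response_RU"])


def select_model(
    curve: pd.DataFrame,
    candidates: Sequence[str] = ("one_site", "two_site", "hill"),
    n_starts: int = 32,
    seed: int | None = 0,
) -> BindingModelSelector:
    """Fit all candidates and select by corrected information criterion."""
    return BindingModelSelector(
        candidates=candidates, n_starts=n_starts, random_state=seed
    ).fit(curve["conc_nM"], curve["response_RU"])


def fit_sensorgram(
    sensorgrams: Sequence[Sensorgram],
    n_starts: int = 8,
    seed: int | None = 0,
) -> SensorgramFitter:
    """Fit the bivalent-analyte model to one or more sensorgrams."""
    return SensorgramFitter(n_starts=n_starts, random_state=seed).fit(sensorgrams)
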