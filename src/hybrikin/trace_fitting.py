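"""Rate and K_D extraction from fluorescence measurements.

Covers the three measurement analyses of a stopped-flow / melt workflow on
2-aminopurine-labelled oligonucleotides:

* trace normalization against the free-strand and pre-annealed-duplex
  controls,  bound/[T]_tot = (F_mix - F_TP) / (F_T - F_TP);
* bimolecular association fits on bound-fraction traces (the reversible
  two-species mass-action ODE has an exact closed-form solution, which the
  fit evaluates directly -- exact at any stiffness);
* two-state van't Hoff melting-curve fits with linear baselines, giving
  K_D extrapolated to 25 °C, aggregated over replicate curves as a
  lognormal mean/SD.

Model-vs-measurement agreement is summarized by R² and a percentage RMSE
defined as (100/m) * sum_i |ŷ_i - y_i| / y_i (a mean absolute percentage
deviation, implemented exactly as defined).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence as TSequence

import lmfit
import numpy as np

from .nn_thermo import R_KCAL, T0


@dataclass
class FluorescenceTrace:
    """A stopped-flow emission time series with its mixing concentrations."""

    time: np.ndarray  # s, strictly increasing
    signal: np.ndarray  # a.u.
    conc_a: float  # mol/L, 2Ap-bearing strand
    conc_b: float  # mol/L, complementary strand
    name: str = ""
    condition: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.signal = np.asarray(self.signal, dtype=float)
        if len(self.time) < 20:
            raise ValueError("need at least 20 points")
        if np.any(np.diff(self.time) <= 0):
            raise ValueError("time must be strictly increasing")


@dataclass
class MeltCurve:
    """Fluorescence vs temperature at fixed total strand concentrations."""

    temperature: np.ndarray  # °C, strictly increasing
    signal: np.ndarray
    conc_a: float
    conc_b: float
    name: str = ""
    ramp_rate: Optional[float] = None  # °C/min metadata

    def __post_init__(self) -> None:
        self.temperature = np.asarray(self.temperature, dtype=float)
        self.signal = np.asarray(self.signal, dtype=float)
        if len(self.temperature) < 20:
            raise ValueError("need at least 20 points")
        if np.any(np.diff(self.temperature) <= 0):
            raise ValueError("temperature must be strictly increasing")


@dataclass
class FitResult:
    params: dict  # name -> value
    stderr: dict  # name -> standard error (may be nan)
    residuals: np.ndarray
    r2: float
    rmse: float  # root-mean-square residual in data units
    n_points: int
    success: bool
    message: str = ""
    extra: dict = field(default_factory=dict)


def normalize_trace(f_mix, f_t, f_tp, orientation: str = "bound") -> np.ndarray:
    """Normalize a mixture trace against its controls.

    (F_mix - F_TP)/(F_T - F_TP), interpreted as the bound fraction by
    default (as the normalization is printed); ``orientation="free"``
    returns the complement for workflows that treat the quenched state as
    bound. Output is clipped to [-0.05, 1.05] with a warning.
    """
    f_mix = np.asarray(f_mix, dtype=float)
    f_t = np.asarray(f_t, dtype=float)
    f_tp = np.asarray(f_tp, dtype=float)
    if np.any(np.isclose(f_t, f_tp)):
        raise ValueError("F_T equals F_TP: no dynamic range to normalize against")
    frac = (f_mix - f_tp) / (f_t - f_tp)
    if orientation == "free":
        frac = 1.0 - frac
    elif orientation != "bound":
        raise ValueError("orientation must be 'bound' or 'free'")
    if np.any(frac < -0.05) or np.any(frac > 1.05):
        warnings.warn("normalized fraction outside [-0.05, 1.05]; clipping", stacklevel=2)
    return np.clip(frac, -0.05, 1.05)


def bimolecular_bound(
    t: np.ndarray, kon: float, koff: float, conc_a: float, conc_b: float
) -> np.ndarray:
    """Bound complex [AB](t), mol/L, for A + B <-> AB from [AB](0) = 0.

    Exact solution: with x' = kon(a0-x)(b0-x) - koff*x and roots x1 <= x2 of
    the quadratic, x(t) = x1*x2*(1-E)/(x2 - x1*E), E = exp(-kon*(x2-x1)*t).
    """
    t = np.asarray(t, dtype=float)
    s = conc_a + conc_b + koff / kon
    disc = math.sqrt(max(s * s - 4.0 * conc_a * conc_b, 0.0))
    x1 = (s - disc) / 2.0
    x2 = (s + disc) / 2.0
    if disc < 1e-12 * x2:
        # degenerate equal-root limit (koff = 0, a0 = b0)
        return x1 * x1 * kon * t / (1.0 + x1 * kon * t)
    e = np.exp(-kon * disc * t)
    return x1 * x2 * (1.0 - e) / (x2 - x1 * e)


def fit_bimolecular(
    trace: FluorescenceTrace,
    include_koff: Optional[bool] = None,
    dead_time: float = 0.0,
    n_starts: int = 5,
) -> FitResult:
    """Fit k_on (and optionally k_off) to a bound-fraction trace.

    ``trace.signal`` must already be a bound fraction of the limiting
    strand (see :func:`normalize_trace`). Multistart over k_on in
    [1e5, 1e9] M^-1 s^-1; ``include_koff=None`` auto-enables the reversible
    model when the trace plateaus below 95% bound. ``dead_time`` excludes
    early points (stopped-flow mixing artifacts; 0.05 s is typical).
    """
    mask = trace.time >= dead_time
    t = trace.time[mask]
    y = trace.signal[mask]
    if len(t) < 10:
        raise ValueError("too few points after dead-time exclusion")
    c_lim = min(trace.conc_a, trace.conc_b)
    if np.std(y) < 1e-12:
        raise ValueError("flat trace: no association signal to fit")
    if include_koff is None:
        include_koff = float(np.max(y[-max(3, len(y) // 10):].mean())) < 0.95

    def model(params, tt):
        kon = 10.0 ** params["log10_kon"].value
        koff = params["koff"].value if include_koff else 0.0
        return bimolecular_bound(tt, kon, koff, trace.conc_a, trace.conc_b) / c_lim

    best = None
    for log10_k0 in np.linspace(5, 9, n_starts):
        params = lmfit.Parameters()
        params.add("log10_kon", value=log10_k0, min=4.0, max=10.0)
        if include_koff:
            params.add("koff", value=1e-2, min=0.0, max=1e4)
        try:
            res = lmfit.minimize(
                lambda p: model(p, t) - y, params, method="leastsq", nan_policy="raise"
            )
        except Exception:
            continue
        if best is None or res.chisqr < best.chisqr:
            best = res
    if best is None:
        raise RuntimeError("no fit start converged")
    kon = 10.0 ** best.params["log10_kon"].value
    out_params = {"kon": kon}
    out_err = {}
    lk = best.params["log10_kon"]
    out_err["kon"] = kon * math.log(10) * lk.stderr if lk.stderr else float("nan")
    if include_koff:
        out_params["koff"] = best.params["koff"].value
        out_err["koff"] = best.params["koff"].stderr or float("nan")
    resid = np.asarray(best.residual)
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - float(np.sum(resid**2)) / ss_tot if ss_tot > 0 else float("nan")
    at_bound = abs(lk.value - lk.min) < 1e-6 or abs(lk.value - lk.max) < 1e-6
    return FitResult(
        out_params, out_err, resid, r2, float(np.sqrt(np.mean(resid**2))),
        len(t), success=not at_bound,
        message="k_on at search bound" if at_bound else "",
        extra={"include_koff": include_koff, "lmfit": best},
    )


def two_state_bound_fraction(
    temp_c: np.ndarray, dh: float, ds: float, conc_a: float, conc_b: float
) -> np.ndarray:
    """Bound fraction of the limiting strand vs temperature (two-state)."""
    temp_c = np.asarray(temp_c, dtype=float)
    t_k = temp_c + T0
    kd = np.exp((dh - t_k * ds / 1000.0) / (R_KCAL * t_k))
    s = conc_a + conc_b + kd
    x = (s - np.sqrt(s * s - 4.0 * conc_a * conc_b)) / 2.0
    return x / min(conc_a, conc_b)


def _fit_one_melt(curve: MeltCurve) -> FitResult:
    temp = curve.temperature
    y = curve.signal
    n_edge = max(3, len(y) // 10)
    lo_end = y[:n_edge].mean()  # low-temperature plateau (duplexed)
    hi_end = y[-n_edge:].mean()  # high-temperature plateau (single strands)
    # midpoint estimate for initializing (dH, dS)
    mid = 0.5 * (lo_end + hi_end)
    tm0 = float(temp[np.argmin(np.abs(y - mid))]) + T0
    rhs = max((curve.conc_a + curve.conc_b) / 4.0, 1e-30)
    dh0 = -85.0
    ds0 = 1000.0 * (dh0 / tm0 - R_KCAL * math.log(rhs))

    params = lmfit.Parameters()
    params.add("dh", value=dh0, min=-250.0, max=-5.0)
    params.add("ds", value=ds0, min=-800.0, max=-5.0)
    params.add("bound_0", value=lo_end)  # duplex baseline intercept
    params.add("bound_slope", value=0.0)
    params.add("free_0", value=hi_end)  # single-strand baseline intercept
    params.add("free_slope", value=0.0)

    def resid(p):
        f = two_state_bound_fraction(
            temp, p["dh"].value, p["ds"].value, curve.conc_a, curve.conc_b
        )
        t_rel = temp - temp.mean()
        s_bound = p["bound_0"].value + p["bound_slope"].value * t_rel
        s_free = p["free_0"].value + p["free_slope"].value * t_rel
        return s_bound * f + s_free * (1.0 - f) - y

    res = lmfit.minimize(resid, params, method="leastsq", nan_policy="raise")
    dh = res.params["dh"].value
    ds = res.params["ds"].value
    t25 = 25.0 + T0
    kd25 = math.exp((dh - t25 * ds / 1000.0) / (R_KCAL * t25))
    # transition must sit inside the scanned window
    f_curve = two_state_bound_fraction(temp, dh, ds, curve.conc_a, curve.conc_b)
    if not (f_curve.max() > 0.6 and f_curve.min() < 0.4):
        raise RuntimeError(
            f"melting transition outside the scanned window for {curve.name!r}"
        )
    resid_v = np.asarray(res.residual)
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    return FitResult(
        {"dh": dh, "ds": ds, "kd25": kd25},
        {
            "dh": res.params["dh"].stderr or float("nan"),
            "ds": res.params["ds"].stderr or float("nan"),
        },
        resid_v,
        1.0 - float(np.sum(resid_v**2)) / ss_tot if ss_tot > 0 else float("nan"),
        float(np.sqrt(np.mean(resid_v**2))),
        len(y),
        success=res.success,
        extra={"lmfit": res},
    )


def fit_melt(curves: TSequence[MeltCurve]) -> FitResult:
    """Per-curve van't Hoff fits plus a lognormal aggregate of K_D(25 °C).

    Curves whose transition falls outside the window are recorded as
    failures; the aggregate runs over the survivors. All-fail is an error.
    """
    if len(curves) < 1:
        raise ValueError("need at least one curve")
    per_curve = []
    failures = []
    for curve in curves:
        try:
            per_curve.append((curve.name, _fit_one_melt(curve)))
        except (RuntimeError, ValueError) as exc:
            failures.append((curve.name, str(exc)))
    if not per_curve:
        raise RuntimeError(f"all melt fits failed: {failures}")
    kds = np.array([fit.params["kd25"] for _, fit in per_curve])
    mu = float(np.mean(np.log(kds)))
    sigma = float(np.std(np.log(kds), ddof=1)) if len(kds) > 1 else 0.0
    mean_kd = math.exp(mu + sigma**2 / 2.0)
    sd_kd = mean_kd * math.sqrt(math.expm1(sigma**2))
    all_resid = np.concatenate([fit.residuals for _, fit in per_curve])
    return FitResult(
        {"kd25_mean": mean_kd, "kd25_sd": sd_kd, "kd25_log_mu": mu, "kd25_log_sigma": sigma},
        {},
        all_resid,
        float("nan"),
        float(np.sqrt(np.mean(all_resid**2))),
        int(sum(fit.n_points for _, fit in per_curve)),
        success=True,
        message=f"{len(per_curve)} curve(s) fit, {len(failures)} failed",
        extra={"per_curve": dict(per_curve), "failures": failures},
    )


def comparison_stats(predicted, measured) -> tuple[float, float]:
    """(R², RMSE %) for predicted vs measured vectors.

    RMSE follows the percentage definition (100/m) * sum |ŷ-y|/y; measured
    values must be nonzero.
    """
    yhat = np.asarray(predicted, dtype=float)
    y = np.asarray(measured, dtype=float)
    if yhat.shape != y.shape or y.ndim != 1 or len(y) < 2:
        raise ValueError("predicted and measured must be equal-length vectors (>= 2)")
    zeros = np.nonzero(y == 0)[0]
    if len(zeros):
        raise ValueError(f"measured value is zero at index {zeros[0]}: RMSE%% undefined")
    ss_res = float(np.sum((y - yhat) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else float("nan")
    rmse = float(100.0 / len(y) * np.sum(np.abs(yhat - y) / np.abs(y)))
    return r2, rmse
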