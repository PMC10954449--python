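"""Mass-action dynamics and equilibrium of probe/target/competitor mixtures.

Three strands compete: a probe P, its perfect complement T (target), and a
defect-bearing competitor C. Binding accuracy is

    theta(t) = [T:P] / ([T:P] + [C:P])

with theta_in its value just after mixing (set by the association-rate
partition k_on^TP / (k_on^TP + k_on^CP) at equimolar T and C) and theta_eq
its equilibrium value (set by the dissociation constants). The mixture
evolves by hybridization/dissociation mass action, optionally toehold-free
strand displacement (relevant for RNA, where bare dissociation is too slow),
and optionally pseudo-bimolecular extension/ligation channels that convert
bound duplexes into inert reacted species T^R, C^R (how transient mis-paired
duplexes become substrates for template copying chemistry).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp
from scipy.optimize import brentq


@dataclass(frozen=True)
class MixtureSystem:
    """Species inventory, rate constants and concentrations (mol/L, s)."""

    conc_T: float
    conc_C: float
    conc_P: float
    kon_TP: float
    koff_TP: float
    kon_CP: float
    koff_CP: float
    k_sd: Optional[float] = None  # C:P + T -> T:P + C, M^-1 s^-1 (None = off)
    k_ext_TP: float = 0.0  # pseudo-bimolecular reaction rate, M^-1 s^-1
    k_ext_CP: float = 0.0
    substrate_conc: float = 0.0
    substrate_depletion: bool = False
    temperature: float = 25.0

    def __post_init__(self) -> None:
        for name in ("conc_T", "conc_C", "conc_P"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in ("kon_TP", "kon_CP"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @property
    def kd_TP(self) -> float:
        return self.koff_TP / self.kon_TP

    @property
    def kd_CP(self) -> float:
        return self.koff_CP / self.kon_CP

    @property
    def k_sd_rev(self) -> float:
        """Reverse displacement rate, fixed by thermodynamic consistency:
        k_sd / k_sd_rev = K_D(C:P) / K_D(T:P)."""
        if self.k_sd is None:
            return 0.0
        if self.kd_CP == 0:
            return 0.0
        return self.k_sd * self.kd_TP / self.kd_CP


@dataclass
class TimeCourse:
    """Simulated trajectories; concentrations mol/L on ``time`` (s)."""

    time: np.ndarray
    species: pd.DataFrame  # columns T, C, P, TP, CP, TR, CR (+ S if depleting)
    theta: np.ndarray  # [TP]/([TP]+[CP]), nan where no probe is bound
    reacted_T: np.ndarray  # fraction of total T converted to T^R
    reacted_C: np.ndarray
    system: MixtureSystem

    def to_frame(self) -> pd.DataFrame:
        df = self.species.copy()
        df.insert(0, "time", self.time)
        df["theta"] = self.theta
        return df


def theta_in(kon_TP: float, kon_CP: float) -> float:
    """Initial binding accuracy from the kinetic partition of the probe.

    Valid for equimolar target and competitor when dissociation is slow on
    the mixing timescale; 0.5 at equal rates, -> 1 as kon_CP -> 0.
    """
    if kon_TP <= 0 or kon_CP < 0:
        raise ValueError("association rates must be positive (kon_CP >= 0)")
    return kon_TP / (kon_TP + kon_CP)


def equilibrium_accuracy(
    kd_TP: float,
    kd_CP: float,
    conc_T: float,
    conc_C: float,
    conc_P: float,
) -> tuple[float, dict]:
    """Exact two-K_D competitive binding equilibrium.

    Solves the scalar conservation equation for free probe p (monotone,
    bracketed on [0, conc_P]):

        p + conc_T * p/(K_TP + p) + conc_C * p/(K_CP + p) = conc_P

    and returns (theta_eq, species dict).
    """
    if kd_TP <= 0 or kd_CP <= 0:
        raise ValueError("dissociation constants must be positive")
    if min(conc_T, conc_C, conc_P) < 0:
        raise ValueError("concentrations must be >= 0")
    if conc_P == 0:
        # no probe: theta from the vanishing-probe limit
        num = conc_T / kd_TP
        den = num + conc_C / kd_CP
        return num / den, {"P": 0.0, "T": conc_T, "C": conc_C, "TP": 0.0, "CP": 0.0}

    def excess(p: float) -> float:
        return p + conc_T * p / (kd_TP + p) + conc_C * p / (kd_CP + p) - conc_P

    lo, hi = 0.0, conc_P
    f_lo, f_hi = excess(lo), excess(hi)
    if f_lo > 0 or f_hi < 0:
        raise RuntimeError(
            f"equilibrium bracket failure: f(0)={f_lo:.3g}, f(P_tot)={f_hi:.3g}"
        )
    p = brentq(excess, lo, hi, xtol=1e-30, rtol=1e-15)
    tp = conc_T * p / (kd_TP + p)
    cp = conc_C * p / (kd_CP + p)
    bound = tp + cp
    if bound > 0:
        theta = tp / bound
    else:
        theta = (conc_T / kd_TP) / (conc_T / kd_TP + conc_C / kd_CP)
    species = {"P": p, "T": conc_T - tp, "C": conc_C - cp, "TP": tp, "CP": cp}
    return float(theta), species


def _rhs(system: MixtureSystem):
    k_sd = system.k_sd or 0.0
    k_sd_rev = system.k_sd_rev
    deplete = system.substrate_depletion

    def rhs(_t, y):
        T, C, P, TP, CP, TR, CR, S = y
        sub = S if deplete else system.substrate_conc
        hyb_T = system.kon_TP * T * P - system.koff_TP * TP
        hyb_C = system.kon_CP * C * P - system.koff_CP * CP
        disp = k_sd * CP * T - k_sd_rev * TP * C  # C:P + T <-> T:P + C
        ext_T = system.k_ext_TP * TP * sub
        ext_C = system.k_ext_CP * CP * sub
        return (
            -hyb_T - disp,  # T
            -hyb_C + disp,  # C
            -hyb_T - hyb_C,  # P
            hyb_T + disp - ext_T,  # TP
            hyb_C - disp - ext_C,  # CP
            ext_T,  # TR (reacted target, probe-bound sink)
            ext_C,  # CR
            -(ext_T + ext_C) if deplete else 0.0,  # S
        )

    return rhs


def simulate_mixture(
    system: MixtureSystem,
    t_grid: np.ndarray,
    y0: Optional[dict] = None,
    rtol: float = 1e-10,
) -> TimeCourse:
    """Integrate the mixture ODEs on an increasing time grid from t=0.

    Initial state is all-single-strands unless ``y0`` overrides species.
    Conservation of each strand family holds to the integrator tolerance
    (checked; 1e-9 relative).
    """
    t_grid = np.asarray(t_grid, dtype=float)
    if t_grid[0] != 0.0 or np.any(np.diff(t_grid) <= 0):
        raise ValueError("t_grid must increase strictly from 0")
    names = ["T", "C", "P", "TP", "CP", "TR", "CR", "S"]
    start = {
        "T": system.conc_T, "C": system.conc_C, "P": system.conc_P,
        "TP": 0.0, "CP": 0.0, "TR": 0.0, "CR": 0.0, "S": system.substrate_conc,
    }
    if y0:
        start.update(y0)
    y_init = np.array([start[n] for n in names])
    scale = max(system.conc_T, system.conc_C, system.conc_P, 1e-12)
    sol = solve_ivp(
        _rhs(system), (0.0, float(t_grid[-1])), y_init, method="LSODA",
        t_eval=t_grid, rtol=rtol, atol=scale * 1e-14,
    )
    if not sol.success:
        raise RuntimeError(f"integrator failure: {sol.message}")
    y = sol.y
    if np.any(y[:7] < -scale * 1e-6):
        raise RuntimeError("negative concentrations beyond tolerance")
    y = np.clip(y, 0.0, None) if np.any(y < 0) else y
    df = pd.DataFrame(y.T, columns=names)
    tot_T = start["T"] + start["TP"] + start["TR"]
    tot_C = start["C"] + start["CP"] + start["CR"]
    for fam, cols in (("T", ["T", "TP", "TR"]), ("C", ["C", "CP", "CR"])):
        tot = df[cols].sum(axis=1).to_numpy()
        ref = tot[0]
        if ref > 0 and np.max(np.abs(tot - ref)) > 1e-9 * ref:
            raise RuntimeError(f"strand family {fam} not conserved to 1e-9 relative")
    bound = df["TP"] + df["CP"]
    with np.errstate(invalid="ignore", divide="ignore"):
        theta = np.where(bound > 0, df["TP"] / bound, np.nan)
    reacted_T = df["TR"].to_numpy() / tot_T if tot_T > 0 else np.zeros(len(df))
    reacted_C = df["CR"].to_numpy() / tot_C if tot_C > 0 else np.zeros(len(df))
    if not system.substrate_depletion:
        df = df.drop(columns=["S"])
    return TimeCourse(t_grid, df, theta, reacted_T, reacted_C, system)


def equilibration_halflife(tc: TimeCourse, cp_eq: Optional[float] = None) -> float:
    """Time for half the transient mis-paired duplex [C:P] to disappear.

    Measured from the early [C:P] maximum toward its equilibrium value, with
    linear interpolation on log time. Raises if there is no transient or the
    trajectory is too short to bracket the half point.
    """
    cp = tc.species["CP"].to_numpy()
    t = tc.time
    imax = int(np.argmax(cp))
    cp_max = cp[imax]
    if cp_eq is None:
        cp_eq = float(cp[-1])
    if cp_max <= 0 or (cp_max - cp_eq) <= 1e-6 * max(cp_max, 1e-300):
        raise ValueError("no transient excess of C:P to equilibrate (already at equilibrium?)")
    half = 0.5 * (cp_max + cp_eq)
    below = np.nonzero(cp[imax:] <= half)[0]
    if len(below) == 0:
        raise ValueError(
            "half point not reached; integrate to longer times "
            f"(final [C:P]={cp[-1]:.3g}, target {half:.3g})"
        )
    k = imax + below[0]
    if k == 0:
        return float(t[0])
    t0, t1 = t[k - 1], t[k]
    c0, c1 = cp[k - 1], cp[k]
    if t0 <= 0:
        return float(t1)
    frac = (c0 - half) / (c0 - c1)
    return float(math.exp(math.log(t0) + frac * (math.log(t1) - math.log(t0))))


def reaction_yields(system: MixtureSystem, t_grid: np.ndarray) -> TimeCourse:
    """Time course with the extension/ligation channel active.

    The competitor's reacted fraction is nondecreasing and plateaus once the
    transient C:P population is depleted by equilibration.
    """
    if system.substrate_conc <= 0 or (system.k_ext_TP == 0 and system.k_ext_CP == 0):
        raise ValueError("reaction channel requires substrate_conc and a rate constant")
    return simulate_mixture(system, t_grid)
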