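"""Stochastic double-ended zippering over in-register bound states.

The duplex is a Markov chain whose states are the contiguous bound intervals
[a, b] of its alignment (all m(m+1)/2 of them for alignment length m) plus
the dissociated state. Transitions add or remove one terminal pair.
Rates follow the Metropolis rule at a fixed attempt rate k_uni (default
4.2e8 s^-1): downhill moves run at k_uni, uphill at k_uni*exp(-dG/RT).
A move that forms (or, symmetrically, removes) a declared mismatched pair
carries an extra additive barrier (default 2.49 kcal/mol) implemented as a
transition-state energy G_ts = max(G_s, G_s') + barrier, which preserves
detailed balance edge by edge; bulge-crossing moves carry their own barrier
(default 0). State free energies come from the NN engine applied to the
corresponding sub-duplex.

Association rates are estimated by the first-step construction: trajectories
start from single-pair nucleation states at complementary positions and are
absorbed at full zippering (success) or detachment (failure); k_on combines
the bimolecular entry rate, the success probability, and the conditional
mean first-passage times. An exact absorbing-chain linear solve provides the
deterministic counterpart used for fitting.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Optional

import numpy as np
from scipy import optimize

from .nn_thermo import R_KCAL, ThermoParams, _range_dh_ds, dg_from_dh_ds
from .sequences import DuplexSpec

DISSOCIATED = None  # public name for the unbound state


@dataclass(frozen=True)
class KMCConfig:
    k_uni: float = 4.2e8  # s^-1, base-pair formation attempt rate
    mismatch_barrier: float = 2.49  # kcal/mol
    bulge_barrier: float = 0.0  # kcal/mol
    temperature: float = 25.0  # °C
    concentration: float = 1e-6  # mol/L
    n_trajectories: int = 10000
    seed: int = 0
    k_nuc_bi: float = 2.0e6  # M^-1 s^-1 bimolecular entry scale
    entry_mode: str = "total"  # "total": k_nuc_bi split over sites; "per_site"
    max_steps: int = 1_000_000

    def __post_init__(self) -> None:
        if self.k_uni <= 0:
            raise ValueError("k_uni must be positive")
        if self.n_trajectories < 1:
            raise ValueError("n_trajectories must be >= 1")
        if self.entry_mode not in ("total", "per_site"):
            raise ValueError("entry_mode must be 'total' or 'per_site'")

    @property
    def rt(self) -> float:
        return R_KCAL * (self.temperature + 273.15)


@dataclass
class ZipperChain:
    """State space, free energies and move topology for one duplex."""

    duplex: DuplexSpec
    m: int  # alignment length
    states: list  # index -> (a, b) 1-based inclusive, or None (dissociated)
    index: dict  # state -> index
    G: np.ndarray  # kcal/mol, G[dissociated] = 0
    # undirected moves (s_idx, t_idx, is_mismatch, crosses_bulge); t has one
    # pair more than s; barrier magnitudes are resolved from the config at
    # rate-evaluation time so a chain can be reused across barrier values
    edges: list
    nucleation_idx: np.ndarray  # single-pair states at complementary positions
    full_idx: int
    diss_idx: int

    def n_states(self) -> int:
        return len(self.states)


def build_chain(
    duplex: DuplexSpec,
    config: KMCConfig = KMCConfig(),
    thermo: Optional[ThermoParams] = None,
) -> ZipperChain:
    """Enumerate interval states, their NN free energies, and all moves."""
    if thermo is None:
        thermo = ThermoParams.for_alphabet(duplex.strand_a.alphabet)
    pairs = sorted(duplex.alignment, key=lambda p: p[1])
    m = len(pairs)
    if m < 1:
        raise ValueError("alignment must contain at least one pair")
    mm = duplex.mismatch_positions
    is_mismatch = [j in mm for (_, j) in pairs]
    # gap > 0 between consecutive pairs means a bulge is crossed
    crosses_bulge = [pairs[k + 1][1] - pairs[k][1] > 1 for k in range(m - 1)]

    states: list = [None]
    index = {None: 0}
    for a in range(1, m + 1):
        for b in range(a, m + 1):
            index[(a, b)] = len(states)
            states.append((a, b))
    G = np.zeros(len(states))
    for s, st in enumerate(states):
        if st is None:
            continue
        a, b = st
        dh, ds = _range_dh_ds(duplex, thermo, a - 1, b - 1)
        G[s] = dg_from_dh_ds(dh, ds, config.temperature)

    def move_kind(pair_idx: int, from_pair: Optional[int]) -> tuple[bool, bool]:
        """(is_mismatch, crosses_bulge) for the move adding pair `pair_idx`
        (1-based) extending from `from_pair` (terminal pair of the shorter
        interval; None when the move creates the first pair)."""
        mm = is_mismatch[pair_idx - 1]
        bulge = False
        if from_pair is not None:
            lo, _ = sorted((pair_idx, from_pair))
            bulge = crosses_bulge[lo - 1]
        return mm, bulge

    edges = []
    for st, s in index.items():
        if st is None:
            continue
        a, b = st
        # grow at the 5'-probe end
        if a > 1:
            t = index[(a - 1, b)]
            edges.append((s, t, *move_kind(a - 1, a)))
        # grow at the 3'-probe end
        if b < m:
            t = index[(a, b + 1)]
            edges.append((s, t, *move_kind(b + 1, b)))
        # single pair -> dissociated (reverse of nucleus formation)
        if a == b:
            edges.append((0, s, *move_kind(a, None)))

    nucleation = np.array(
        [index[(k, k)] for k in range(1, m + 1) if not is_mismatch[k - 1]], dtype=int
    )
    if len(nucleation) == 0:
        raise ValueError("duplex has no complementary positions to nucleate at")
    return ZipperChain(
        duplex, m, states, index, G, edges, nucleation, index[(1, m)], 0
    )


def _edge_rates(chain: ZipperChain, config: KMCConfig):
    """Directed rate list: for each undirected edge (s, t, barrier) with t
    one pair larger than s, Metropolis rates through G_ts = max(G)+barrier."""
    rt = config.rt
    rates: dict[int, list[tuple[int, float]]] = {i: [] for i in range(chain.n_states())}
    for s, t, mm, bulge in chain.edges:
        bar = mm * config.mismatch_barrier + bulge * config.bulge_barrier
        g_ts = max(chain.G[s], chain.G[t]) + bar
        rates[s].append((t, config.k_uni * math.exp(-(g_ts - chain.G[s]) / rt)))
        rates[t].append((s, config.k_uni * math.exp(-(g_ts - chain.G[t]) / rt)))
    return rates


def transition_rates(
    chain: ZipperChain, state, config: KMCConfig = KMCConfig()
) -> list[tuple[object, float]]:
    """Outgoing (state, rate s^-1) list from a state ((a, b) or None)."""
    if state not in chain.index:
        raise KeyError(f"unknown state {state!r}")
    s = chain.index[state]
    out = []
    rt = config.rt
    for s0, t0, mm, bulge in chain.edges:
        if s0 == s or t0 == s:
            other = t0 if s0 == s else s0
            bar = mm * config.mismatch_barrier + bulge * config.bulge_barrier
            g_ts = max(chain.G[s0], chain.G[t0]) + bar
            out.append(
                (chain.states[other], config.k_uni * math.exp(-(g_ts - chain.G[s]) / rt))
            )
    return out


@dataclass(frozen=True)
class RateEstimate:
    k_on: float  # M^-1 s^-1
    se: float
    success_probability: float
    t_success: float  # conditional mean first-passage time, s
    t_failure: float
    n_trajectories: int


def _assemble_kon(
    p: float, t_succ: float, t_fail: float, n_sites: int, config: KMCConfig
) -> float:
    """First-step estimator: expected number of entry attempts is 1/p, each
    preceded by a bimolecular waiting time and, if failed, a failure
    excursion; k_on = 1 / (c * total mean time per success)."""
    if p <= 0:
        return 0.0
    k_coll = config.k_nuc_bi if config.entry_mode == "total" else config.k_nuc_bi * n_sites
    c = config.concentration
    tau = 1.0 / (p * k_coll * c) + (1.0 - p) / p * t_fail + t_succ
    return 1.0 / (c * tau)


def simulate_first_step(
    chain: ZipperChain, config: KMCConfig = KMCConfig()
) -> RateEstimate:
    """Seeded Gillespie first-step estimate of k_on.

    Each trajectory starts in a uniformly chosen single-pair nucleation
    state and runs to full zippering or detachment. Per-trajectory RNG
    streams derive from (seed, trajectory index), so results are identical
    for any worker count or chunking.
    """
    if config.n_trajectories < 1:
        raise ValueError("need at least one trajectory")
    rates = _edge_rates(chain, config)
    targets = {}
    totals = {}
    cums = {}
    for s, lst in rates.items():
        if s in (chain.full_idx, chain.diss_idx):
            continue
        tg = np.array([t for t, _ in lst], dtype=int)
        rr = np.array([r for _, r in lst], dtype=float)
        targets[s] = tg
        totals[s] = rr.sum()
        cums[s] = np.cumsum(rr)
    n_sites = len(chain.nucleation_idx)
    successes = 0
    t_succ_sum = 0.0
    t_fail_sum = 0.0
    for traj in range(config.n_trajectories):
        rng = np.random.default_rng((config.seed, traj))
        s = int(chain.nucleation_idx[rng.integers(n_sites)])
        t = 0.0
        if s == chain.full_idx:  # 1-bp duplex: nucleation completes the zipper
            successes += 1
            continue
        for _ in range(config.max_steps):
            tot = totals[s]
            t += rng.exponential(1.0 / tot)
            u = rng.random() * tot
            s = int(targets[s][np.searchsorted(cums[s], u)])
            if s == chain.full_idx:
                successes += 1
                t_succ_sum += t
                break
            if s == chain.diss_idx:
                t_fail_sum += t
                break
        else:
            raise RuntimeError("trajectory exceeded max_steps without absorbing")
    n = config.n_trajectories
    p = successes / n
    t_succ = t_succ_sum / successes if successes else 0.0
    t_fail = t_fail_sum / (n - successes) if successes < n else 0.0
    se_p = math.sqrt(max(p * (1 - p), 1e-300) / n)
    k_on = _assemble_kon(p, t_succ, t_fail, n_sites, config)
    k_hi = _assemble_kon(min(p + se_p, 1.0), t_succ, t_fail, n_sites, config)
    k_lo = _assemble_kon(max(p - se_p, 0.0), t_succ, t_fail, n_sites, config)
    return RateEstimate(k_on, (k_hi - k_lo) / 2.0, p, t_succ, t_fail, n)


@dataclass(frozen=True)
class PassageResult:
    """Exact absorbing-chain absorption statistics per nucleation site."""

    sites: tuple  # (a, a) tuples in chain order
    success_probability: np.ndarray
    t_success: np.ndarray  # conditional MFPT given success
    t_failure: np.ndarray  # conditional MFPT given failure

    def pooled(self):
        """Uniform-entry pooled (p, t_success, t_failure)."""
        p = float(np.mean(self.success_probability))
        w = self.success_probability
        t_s = float(np.sum(w * self.t_success) / np.sum(w)) if np.sum(w) > 0 else 0.0
        wf = 1.0 - w
        t_f = float(np.sum(wf * self.t_failure) / np.sum(wf)) if np.sum(wf) > 0 else 0.0
        return p, t_s, t_f


def exact_passage(chain: ZipperChain, config: KMCConfig = KMCConfig()) -> PassageResult:
    """Absorption probabilities and conditional MFPTs by linear solve.

    Absorbing states: fully zipped (success) and dissociated (failure).
    For transient states with jump matrix P and exit rates R:
    h = P h (success boundary 1), w = P w + h / R, t_success = w / h.
    """
    n = chain.n_states()
    if n > 10_000:
        raise ValueError(f"state count {n} exceeds exact-solve guard of 10^4")
    rates = _edge_rates(chain, config)
    transient = [s for s in range(n) if s not in (chain.full_idx, chain.diss_idx)]
    pos = {s: k for k, s in enumerate(transient)}
    nt = len(transient)
    P = np.zeros((nt, nt))
    b_succ = np.zeros(nt)
    exit_rate = np.zeros(nt)
    for s in transient:
        lst = rates[s]
        tot = sum(r for _, r in lst)
        exit_rate[pos[s]] = tot
        for t, r in lst:
            if t == chain.full_idx:
                b_succ[pos[s]] += r / tot
            elif t == chain.diss_idx:
                pass
            else:
                P[pos[s], pos[t]] += r / tot
    A = np.eye(nt) - P
    try:
        h = np.linalg.solve(A, b_succ)
    except np.linalg.LinAlgError as exc:
        raise RuntimeError("singular absorbing-chain system (disconnected?)") from exc
    # E[time * 1_success]; time-to-jump is independent of the jump target
    w = np.linalg.solve(A, h / exit_rate)
    hf = 1.0 - h
    wf = np.linalg.solve(A, hf / exit_rate)
    h_sites, ts, tf = [], [], []
    for s in chain.nucleation_idx:
        if s == chain.full_idx:  # 1-bp duplex: nucleation is full zippering
            h_sites.append(1.0)
            ts.append(0.0)
            tf.append(0.0)
            continue
        k = pos[s]
        h_sites.append(h[k])
        ts.append(w[k] / h[k] if h[k] > 0 else 0.0)
        tf.append(wf[k] / (1 - h[k]) if h[k] < 1 else 0.0)
    h_sites, ts, tf = np.array(h_sites), np.array(ts), np.array(tf)
    sites = tuple(chain.states[s] for s in chain.nucleation_idx)
    return PassageResult(sites, h_sites, ts, tf)


def kon_exact(chain: ZipperChain, config: KMCConfig = KMCConfig()) -> float:
    """Deterministic first-step k_on from the exact linear solve."""
    p, t_s, t_f = exact_passage(chain, config).pooled()
    return _assemble_kon(p, t_s, t_f, len(chain.nucleation_idx), config)


def simulate_equilibrium(
    chain: ZipperChain,
    config: KMCConfig,
    n_jumps: int = 50_000,
    n_samples: int = 2000,
) -> dict:
    """Time-weighted occupancy of the ergodic bound-state chain.

    The dissociated state is excluded (no detachment move), making the chain
    ergodic over intervals; occupancy is sampled at uniform times and should
    match Boltzmann weights exp(-G/RT). Used by the detailed-balance tests.
    """
    rates = _edge_rates(chain, config)
    bound = [s for s in range(chain.n_states()) if s != chain.diss_idx]
    tables = {}
    for s in bound:
        lst = [(t, r) for (t, r) in rates[s] if t != chain.diss_idx]
        tg = np.array([t for t, _ in lst], dtype=int)
        rr = np.array([r for _, r in lst], dtype=float)
        tables[s] = (tg, rr.sum(), np.cumsum(rr))
    rng = np.random.default_rng(config.seed)
    s = int(chain.nucleation_idx[0])
    times = [0.0]
    visits = [s]
    t = 0.0
    for _ in range(n_jumps):
        tg, tot, cum = tables[s]
        t += rng.exponential(1.0 / tot)
        times.append(t)
        s = int(tg[np.searchsorted(cum, rng.random() * tot)])
        visits.append(s)
    times = np.asarray(times)
    visits = np.asarray(visits)
    sample_t = np.linspace(0.0, t, n_samples, endpoint=False)
    state_at = visits[np.searchsorted(times, sample_t, side="right") - 1]
    counts = np.bincount(state_at, minlength=chain.n_states()).astype(float)
    g = chain.G[bound]
    wts = np.exp(-(g - g.min()) / config.rt)
    expected = wts / wts.sum() * n_samples
    return {
        "counts": counts[bound],
        "expected": expected,
        "states": [chain.states[s] for s in bound],
    }


@dataclass(frozen=True)
class KMCFit:
    k_nuc_bi: float
    mismatch_barrier: Optional[float]
    barrier_identifiable: bool
    sse: float


def fit_kmc(
    records,
    config: KMCConfig = KMCConfig(),
    thermo: Optional[ThermoParams] = None,
) -> KMCFit:
    """Fit the bimolecular entry scale and the mismatch zippering barrier.

    Two-parameter least squares on log10 k_on using the exact linear solve
    (deterministic, no sampling noise). Mismatches are assumed to affect
    zippering only, not nucleus formation, so the entry scale is shared.
    With no mismatched duplex in the records the barrier is unidentifiable
    and reported as None.
    """
    records = list(records)
    chains = [build_chain(r.duplex, config, thermo) for r in records]
    y = np.log10([r.k_on for r in records])
    has_mismatch = any(len(r.duplex.mismatch_positions) > 0 for r in records)

    def log10_kon(chain, scale, barrier):
        cfg = replace(config, k_nuc_bi=scale, mismatch_barrier=barrier)
        k = kon_exact(chain, cfg)
        return math.log10(max(k, 1e-300))

    if not has_mismatch:
        # barrier plays no role; 1-D closed-form in log10 scale
        base = np.array([log10_kon(c, 1.0, config.mismatch_barrier) for c in chains])
        log10_scale = float(np.mean(y - base))
        sse = float(np.sum((y - base - log10_scale) ** 2))
        return KMCFit(10.0**log10_scale, None, False, sse)

    def objective(theta):
        scale = 10.0 ** theta[0]
        barrier = theta[1]
        if barrier < 0 or barrier > 15:
            return 1e6 + barrier**2
        pred = np.array([log10_kon(c, scale, barrier) for c in chains])
        return float(np.sum((y - pred) ** 2))

    res = optimize.minimize(
        objective,
        np.array([math.log10(config.k_nuc_bi), config.mismatch_barrier]),
        method="Nelder-Mead",
        options={"xatol": 1e-6, "fatol": 1e-12, "maxiter": 5000},
    )
    if not res.success and not np.isfinite(res.fun):
        raise RuntimeError(f"KMC fit did not converge: {res.message}; last {res.x}")
    return KMCFit(10.0 ** float(res.x[0]), float(res.x[1]), True, float(res.fun))
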