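"""Probability of off-target binding sites in random sequence.

How likely is a length-n probe to find at least one near-complementary site
in a pool of L uniform random nucleotides? A window "binds" if it is the
antiparallel complement of the probe within a defect budget: up to d_m
mismatches (Hamming distance on length-n windows) and/or a single-base
bulge (a length n-1 window equal to the complement with one probe base
skipped). The expected site count is an exact combinatorial sum; the
probability of at least one site uses a Poisson (independence)
approximation across windows, validated against a Monte Carlo scanner.

Only combinatorial complementarity is counted -- no thermodynamic
weighting -- matching the back-of-envelope character of the question.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np


@dataclass(frozen=True)
class OfftargetQuery:
    probe_length: int  # n
    pool_length: float  # L (float to allow 1e9 comfortably)
    max_mismatches: int = 0
    max_bulges: int = 0
    alphabet_size: int = 4
    both_strands: bool = False  # search both pool orientations (doubles L)

    def __post_init__(self) -> None:
        if self.probe_length < 1:
            raise ValueError("probe length must be >= 1")
        if self.pool_length < self.probe_length:
            raise ValueError("pool must be at least as long as the probe")
        if self.max_mismatches < 0 or self.max_bulges < 0:
            raise ValueError("defect budgets must be >= 0")
        if self.max_bulges > 1:
            raise ValueError("only single-bulge sites are modelled")

    @property
    def effective_pool(self) -> float:
        return 2.0 * self.pool_length if self.both_strands else self.pool_length


def _mismatch_window_probability(n: int, d_m: int, q: int = 4) -> float:
    """P(random n-window complements a fixed probe with <= d_m mismatches)."""
    total = 0.0
    for k in range(min(d_m, n) + 1):
        total += math.comb(n, k) * (q - 1) ** k
    return total / q**n


def expected_distinct_deletions(n: int) -> float:
    """Expected number of distinct interior single-deletion strings of a
    uniform random n-mer.

    Only interior deletions count: a bulge must be flanked by pairs on both
    sides, so the skipped probe base cannot be terminal. Deleting positions
    i < j gives the same string iff i..j is a single repeated base, so the
    distinct count is the number of runs intersecting positions 2..n-1:
    expectation [1 + (n-1) 3/4] - 3/4 - 3/4 = n - (n-1)/4 - 3/2 for n >= 3.
    """
    if n < 3:
        return 0.0
    return n - (n - 1) / 4.0 - 1.5


def expected_sites(query: OfftargetQuery) -> float:
    """Expected number of binding windows in the random pool (exact sum).

    Mismatch sites: (L-n+1) * sum_{k<=d_m} C(n,k) 3^k / 4^n.
    Bulge sites (budget >= 1): (L-n+2) windows of length n-1, each matching
    one of the probe's distinct single-deletion complements exactly.
    Mixed bulge+mismatch windows are not counted (documented convention).
    """
    n = query.probe_length
    L = query.effective_pool
    q = query.alphabet_size
    total = (L - n + 1) * _mismatch_window_probability(n, query.max_mismatches, q)
    if query.max_bulges >= 1 and n >= 3:
        total += (L - (n - 1) + 1) * expected_distinct_deletions(n) / q ** (n - 1)
    return total


def _distinct_deletion_pmf(n: int):
    """Distribution of the number of distinct interior-deletion strings D of
    a uniform random n-mer: D = 1 + Binomial(n-3, 3/4) exactly (the interior
    base-change indicators are i.i.d.)."""
    m = n - 3
    return [(1 + j, math.comb(m, j) * 0.75**j * 0.25 ** (m - j)) for j in range(m + 1)]


def site_probability(query: OfftargetQuery, exact: bool = False) -> float:
    """P(at least one binding site).

    Windows are treated as independent (Poisson by default; ``exact=True``
    uses the product form, preferable for small pools), but the bulge term
    is mixed over the exact per-probe distribution of distinct deletion
    patterns, which matters at desk scale. A per-window probability of 1
    gives exactly 1.
    """
    n = query.probe_length
    L = query.effective_pool
    q = query.alphabet_size
    p_mm = _mismatch_window_probability(n, query.max_mismatches, q)
    w_mm = L - n + 1
    if p_mm >= 1.0:
        return 1.0

    def log_miss_given(d: float) -> float:
        """log P(no site) given d distinct bulge patterns."""
        if exact:
            out = w_mm * math.log1p(-p_mm)
            if d > 0:
                p_bu = d / q ** (n - 1)
                out += (L - n + 2) * math.log1p(-min(p_bu, 1.0 - 1e-15))
            return out
        return -(w_mm * p_mm + (L - n + 2) * d / q ** (n - 1))

    if query.max_bulges >= 1 and n >= 3:
        miss = sum(w * math.exp(log_miss_given(d)) for d, w in _distinct_deletion_pmf(n))
        return 1.0 - miss
    return 1.0 - math.exp(log_miss_given(0.0))


_BASE_COMP = np.array([3, 2, 1, 0], dtype=np.uint8)  # A<->T, C<->G as 0..3


@dataclass(frozen=True)
class MCResult:
    probability: float
    se: float
    trials: int


def mc_validate(query: OfftargetQuery, trials: int, seed: int = 0) -> MCResult:
    """Monte Carlo estimate of the at-least-one-site probability.

    Each trial draws a fresh random probe and pool and scans every window
    with the same budgeted-Hamming / single-deletion rule the analytic form
    counts. Guarded at 1e10 window-base comparisons.
    """
    if trials < 1:
        raise ValueError("trials must be >= 1")
    n = query.probe_length
    L = int(query.pool_length)
    if float(n) * L * trials * (1 + (n if query.max_bulges else 0)) > 1e10:
        raise ValueError("requested Monte Carlo exceeds the 1e10 comparison guard")
    if query.alphabet_size != 4:
        raise ValueError("Monte Carlo validator supports the 4-letter alphabet only")
    rng = np.random.default_rng(seed)
    hits = 0
    from numpy.lib.stride_tricks import sliding_window_view

    n_orient = 2 if query.both_strands else 1
    for _ in range(trials):
        probe = rng.integers(0, 4, size=n, dtype=np.uint8)
        pool = rng.integers(0, 4, size=L, dtype=np.uint8)
        # antiparallel binding: window must equal revcomp(probe) within budget
        pattern = _BASE_COMP[probe][::-1]
        found = False
        for orient in range(n_orient):
            scan = pool if orient == 0 else _BASE_COMP[pool][::-1]
            win = sliding_window_view(scan, n)
            mism = np.count_nonzero(win != pattern, axis=1)
            if np.any(mism <= query.max_mismatches):
                found = True
                break
            if query.max_bulges >= 1 and n >= 3:
                # interior probe deletions only (bulges are flanked by pairs)
                dels = {bytes(np.delete(pattern, k)) for k in range(1, n - 1)}
                win1 = sliding_window_view(scan, n - 1)
                for d in dels:
                    dd = np.frombuffer(d, dtype=np.uint8)
                    if np.any(np.all(win1 == dd, axis=1)):
                        found = True
                        break
                if found:
                    break
        hits += found
    p = hits / trials
    se = math.sqrt(max(p * (1 - p), 1e-300) / trials)
    return MCResult(p, se, trials)
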