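"""Nearest-neighbor duplex thermodynamics with mismatches, bulges and 2Ap.

The engine sums tabulated dinucleotide ΔH/ΔS terms over an annotated duplex:
Watson-Crick stacks, internal-mismatch doublets, terminal-mismatch doublets,
single-nucleotide bulge-loop increments (closing stack retained), duplex
initiation and terminal A·T penalties, plus a 2-aminopurine destabilization
applied as a purely entropic ΔΔG(25 °C) so ΔH is untouched.

Parameter provenance: the unified DNA set (SantaLucia 2004) and its internal
and terminal mismatch extensions, and the RNA nearest-neighbor set, all taken
at run time from :mod:`Bio.SeqUtils.MeltingTemp`. Reference condition is
1 M NaCl; no salt correction is applied by default (a hook exists but is off).
The same engine prices the n-mer "mini-duplexes" used as nucleation segments
by the kinetic model (:func:`nucleation_dg`), including initiation terms.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Optional

from Bio.SeqUtils import MeltingTemp as _mt
from scipy.optimize import brentq

from .sequences import DuplexSpec, Sequence, SequenceError, annotate_duplex

#: Gas constant, kcal/(mol·K).
R_KCAL = 1.987204258640832e-3

#: Absolute temperature offset.
T0 = 273.15


class ThermoError(ValueError):
    """Raised when a pairing context cannot be resolved from the tables."""


def _celsius(t_c: float) -> float:
    return t_c + T0


@dataclass(frozen=True)
class ThermoParams:
    """A nearest-neighbor parameter set plus package-level conventions.

    Tables map doublet keys ``"XY/ZW"`` (X,Y read 5'->3'; Z under X, W under
    Y read 3'->5') to ``(ΔH kcal/mol, ΔS cal/(mol·K))``. RNA bases are
    T-normalized for lookup. ``ap2_ddg25`` is the 2-aminopurine penalty on
    ΔG at 25 °C (+0.9 kcal/mol in DNA, 0 in RNA), implemented entropically.
    """

    alphabet: str
    nn_table: dict
    imm_table: Optional[dict]
    tmm_table: Optional[dict]
    bulge_loop: dict  # loop length -> (dH, dS); closing stack retained
    ap2_ddg25: float
    rna_mismatch_loop: tuple[float, float] = (0.0, 0.0)
    salt_correction: Optional[Callable[[float, float], float]] = None  # off by default
    parameter_set: str = ""

    @staticmethod
    def dna() -> "ThermoParams":
        # single-nt bulge: ΔG37 = +4.0 kcal/mol, entropic
        return ThermoParams(
            alphabet="DNA",
            nn_table=_mt.DNA_NN4,
            imm_table=_mt.DNA_IMM1,
            tmm_table=_mt.DNA_TMM1,
            bulge_loop={1: (0.0, -4.0 * 1000.0 / 310.15)},
            ap2_ddg25=0.9,
            parameter_set="DNA unified NN (SantaLucia 2004) + mismatch tables",
        )

    @staticmethod
    def rna() -> "ThermoParams":
        # single-nt bulge: ΔG37 = +3.8 kcal/mol; internal mismatch as a
        # generic 1x1-loop penalty of +1.5 kcal/mol at 25 °C (no installed
        # source ships the full RNA 1x1 tables)
        return ThermoParams(
            alphabet="RNA",
            nn_table=_mt.RNA_NN3,
            imm_table=None,
            tmm_table=None,
            bulge_loop={1: (0.0, -3.8 * 1000.0 / 310.15)},
            ap2_ddg25=0.0,
            rna_mismatch_loop=(0.0, -1.5 * 1000.0 / 298.15),
            parameter_set="RNA NN (Turner-derived, Biopython RNA_NN3)",
        )

    @staticmethod
    def for_alphabet(alphabet: str) -> "ThermoParams":
        return ThermoParams.dna() if alphabet == "DNA" else ThermoParams.rna()


@dataclass(frozen=True)
class ThermoResult:
    """ΔH/ΔS/ΔG(T)/K_D(T)/Tm for a duplex under stated conditions."""

    dh: float  # kcal/mol
    ds: float  # cal/(mol·K)
    temperature: float  # °C
    dg: float  # kcal/mol at `temperature`
    kd: float  # mol/L at `temperature`
    tm: float  # °C at the stated concentrations
    conc_a: float
    conc_b: float
    salt: str = "1 M NaCl"


def _norm(base: str) -> str:
    return "T" if base == "U" else base


def _lookup(table: dict, key: str) -> Optional[tuple[float, float]]:
    """Doublet lookup trying both strand orientations."""
    if key in table:
        return table[key]
    top, bottom = key.split("/")
    alt = bottom[::-1] + "/" + top[::-1]
    return table.get(alt)


def _ladder(duplex: DuplexSpec):
    """Pairs along the probe (ascending j) with complementarity flags, plus
    the set of probe-bulge positions sitting between consecutive pairs."""
    mm = duplex.mismatch_positions
    pairs = []  # (i, j, is_complementary)
    for (i, j) in duplex.alignment:
        pairs.append((i, j, j not in mm))
    pairs.sort(key=lambda p: p[1])
    return pairs


def _range_dh_ds(
    duplex: DuplexSpec, params: ThermoParams, a: int, b: int
) -> tuple[float, float]:
    """ΔH, ΔS of the sub-duplex spanning pair indices ``a..b`` (0-based,
    inclusive) of the probe-ordered ladder. ``a == 0, b == m-1`` reproduces
    the full duplex."""
    pairs = _ladder(duplex)
    m = len(pairs)
    if not (0 <= a <= b < m):
        raise ValueError(f"pair range [{a}, {b}] outside [0, {m - 1}]")
    A, B = duplex.strand_a, duplex.strand_b
    bulges = duplex.bulge_positions
    dh, ds = params.nn_table["init"]
    pending_rna_mismatch = 0

    def doublet_key(p, q) -> str:
        (i1, j1, _), (i2, j2, _) = p, q
        return (
            f"{_norm(B.base(j1))}{_norm(B.base(j2))}/"
            f"{_norm(A.base(i1))}{_norm(A.base(i2))}"
        )

    for k in range(a, b):
        p, q = pairs[k], pairs[k + 1]
        comp_p, comp_q = p[2], q[2]
        gap = q[1] - p[1] - 1  # probe bases skipped (bulge loop length)
        if gap > 0:
            if not (comp_p and comp_q):
                raise ThermoError(
                    f"mismatch adjacent to bulge between probe positions {p[1]} and {q[1]}"
                )
            if gap not in params.bulge_loop:
                raise ThermoError(f"no bulge-loop parameters for loop length {gap}")
            lh, ls = params.bulge_loop[gap]
            dh += lh
            ds += ls
            stack = _lookup(params.nn_table, doublet_key(p, q))
            if stack is None:
                raise ThermoError(f"missing closing stack for bulge context {doublet_key(p, q)}")
            dh += stack[0]
            ds += stack[1]
            continue
        if comp_p and comp_q:
            stack = _lookup(params.nn_table, doublet_key(p, q))
            if stack is None:
                raise ThermoError(f"missing stack parameters for {doublet_key(p, q)}")
            dh += stack[0]
            ds += stack[1]
            continue
        if not comp_p and not comp_q:
            raise ThermoError(
                f"tandem mismatch at probe positions {p[1]},{q[1]} is not tabulated"
            )
        # exactly one mismatched pair in the doublet
        mismatch_is_terminal = (not comp_p and k == a) or (not comp_q and k + 1 == b)
        if mismatch_is_terminal:
            if params.tmm_table is not None:
                # orient so the mismatch sits second in the key
                if not comp_q:
                    key = doublet_key(p, q)
                else:  # mismatch at p: read along the other strand (5'->3')
                    (iq, jq, _), (ip, jp, _) = q, p
                    key = (
                        f"{_norm(A.base(iq))}{_norm(A.base(ip))}/"
                        f"{_norm(B.base(jq))}{_norm(B.base(jp))}"
                    )
                term = _lookup(params.tmm_table, key)
                if term is None:
                    raise ThermoError(f"missing terminal-mismatch parameters for {key}")
                dh += term[0]
                ds += term[1]
            # RNA (no table): terminal mismatch treated as a neutral
            # dangling-like end -- contributes nothing
        else:
            if params.imm_table is not None:
                term = _lookup(params.imm_table, doublet_key(p, q))
                if term is None:
                    raise ThermoError(
                        f"missing internal-mismatch parameters for {doublet_key(p, q)}"
                    )
                dh += term[0]
                ds += term[1]
            else:
                # generic 1x1 loop: flanking doublets contribute nothing; one
                # loop penalty per interior mismatch, counted at its left
                # doublet (added below)
                if not comp_q and k + 1 < b:
                    pending_rna_mismatch += 1

    lh, ls = params.rna_mismatch_loop
    dh += lh * pending_rna_mismatch
    ds += ls * pending_rna_mismatch

    # terminal A·T penalties on complementary ends
    at_key = "init_A/T"
    if at_key in params.nn_table:
        for end in (a, b):
            i, j, comp = pairs[end]
            if comp and _norm(B.base(j)) in "AT":
                th, ts = params.nn_table[at_key]
                dh += th
                ds += ts

    # symmetry correction for self-complementary duplexes
    sub_b = "".join(B.base(j) for (_, j, _) in pairs[a : b + 1])
    sub_a = "".join(A.base(i) for (i, _, _) in pairs[a : b + 1])
    if sub_a == sub_b and "sym" in params.nn_table:
        comp_map = {"A": "T", "T": "A", "C": "G", "G": "C"}
        rc = "".join(comp_map[_norm(c)] for c in reversed(sub_a))
        if rc == "".join(_norm(c) for c in sub_a):
            sh, ss = params.nn_table["sym"]
            dh += sh
            ds += ss

    # 2Ap penalty, entropic, once per marked position inside the range
    if params.ap2_ddg25 != 0.0:
        j_lo, j_hi = pairs[a][1], pairs[b][1]
        i_hi, i_lo = pairs[a][0], pairs[b][0]
        n_ap2 = sum(1 for p in B.ap2_positions if j_lo <= p <= j_hi) + sum(
            1 for p in A.ap2_positions if i_lo <= p <= i_hi
        )
        ds -= params.ap2_ddg25 * 1000.0 / _celsius(25.0) * n_ap2

    return dh, ds


def dg_from_dh_ds(dh: float, ds: float, temperature: float) -> float:
    """ΔG (kcal/mol) at a Celsius temperature from ΔH (kcal) and ΔS (cal)."""
    return dh - _celsius(temperature) * ds / 1000.0


def duplex_dh_ds(duplex: DuplexSpec, params: Optional[ThermoParams] = None):
    """Full-duplex ΔH, ΔS; the primitive the other routines build on."""
    if params is None:
        params = ThermoParams.for_alphabet(duplex.strand_a.alphabet)
    m = len(duplex.alignment)
    return _range_dh_ds(duplex, params, 0, m - 1)


def duplex_thermo(
    duplex: DuplexSpec,
    temperature: float = 25.0,
    params: Optional[ThermoParams] = None,
    conc_a: float = 1e-6,
    conc_b: float = 1e-6,
) -> ThermoResult:
    """Hybridization ΔH/ΔS/ΔG(T)/K_D(T)/Tm of an annotated duplex.

    ΔG < 0 means the duplex is stable; K_D = exp(ΔG/RT) in mol/L.
    """
    if not 0.0 <= temperature <= 100.0:
        raise ValueError(f"temperature {temperature} °C outside [0, 100]")
    if params is None:
        params = ThermoParams.for_alphabet(duplex.strand_a.alphabet)
    dh, ds = duplex_dh_ds(duplex, params)
    dg = dg_from_dh_ds(dh, ds, temperature)
    kd = math.exp(dg / (R_KCAL * _celsius(temperature)))
    tm = melting_temperature(duplex, conc_a, conc_b, params)
    return ThermoResult(dh, ds, temperature, dg, kd, tm, conc_a, conc_b)


def melting_temperature(
    duplex: DuplexSpec,
    conc_a: float = 1e-6,
    conc_b: float = 1e-6,
    params: Optional[ThermoParams] = None,
) -> float:
    """Two-state Tm (°C) for a non-self-complementary pair at given totals.

    Defined by K_D(Tm) = (c_a - x)(c_b - x)/x with x = min(c_a, c_b)/2,
    i.e. half of the limiting strand duplexed. Monotone increasing in both
    concentrations.
    """
    if conc_a <= 0 or conc_b <= 0:
        raise ValueError("concentrations must be positive")
    if params is None:
        params = ThermoParams.for_alphabet(duplex.strand_a.alphabet)
    dh, ds = duplex_dh_ds(duplex, params)
    x = min(conc_a, conc_b) / 2.0
    rhs = (conc_a - x) * (conc_b - x) / x

    def f(t_c: float) -> float:
        return dg_from_dh_ds(dh, ds, t_c) / (R_KCAL * _celsius(t_c)) - math.log(rhs)

    lo, hi = -80.0, 250.0
    f_lo, f_hi = f(lo), f(hi)
    if f_lo * f_hi > 0:
        raise ThermoError(
            f"Tm bracket failure on [{lo}, {hi}] °C: f({lo})={f_lo:.3g}, "
            f"f({hi})={f_hi:.3g} (ΔH={dh:.2f} kcal/mol, ΔS={ds:.2f} cal/mol/K)"
        )
    return float(brentq(f, lo, hi, xtol=1e-9))


def kd_at(
    duplex: DuplexSpec, temperature: float = 25.0, params: Optional[ThermoParams] = None
) -> float:
    """Equilibrium dissociation constant K_D = exp(ΔG/RT), mol/L."""
    if params is None:
        params = ThermoParams.for_alphabet(duplex.strand_a.alphabet)
    dh, ds = duplex_dh_ds(duplex, params)
    dg = dg_from_dh_ds(dh, ds, temperature)
    return math.exp(dg / (R_KCAL * _celsius(temperature)))


def nucleation_dg(
    strand_a: Sequence,
    i: int,
    strand_b: Sequence,
    j: int,
    n: int,
    temperature: float = 25.0,
    params: Optional[ThermoParams] = None,
) -> float:
    """Free energy (kcal/mol) of the (i, j) nucleation segment of length n.

    +infinity unless ``A[i..i+n-1]`` is fully antiparallel-complementary to
    ``B[j..j+n-1]`` (A[i+k] pairs B[j+n-1-k]); otherwise the NN mini-duplex
    hybridization free energy of the n-mer pair, including initiation terms.
    2Ap markers are ignored here: nucleation energetics use bases only.
    Symmetric under (A, i) <-> (B, j).
    """
    L_a, L_b = len(strand_a), len(strand_b)
    if not 1 <= i <= L_a - n + 1:
        raise ValueError(f"i={i} outside [1, {L_a - n + 1}]")
    if not 1 <= j <= L_b - n + 1:
        raise ValueError(f"j={j} outside [1, {L_b - n + 1}]")
    if params is None:
        params = ThermoParams.for_alphabet(strand_a.alphabet)
    from .sequences import is_complementary  # local to avoid cycle at import

    for k in range(n):
        if not is_complementary(
            strand_a.base(i + k), strand_b.base(j + n - 1 - k), strand_a.alphabet
        ):
            return math.inf
    sub_a = Sequence(strand_a.bases[i - 1 : i - 1 + n], strand_a.alphabet)
    sub_b = Sequence(strand_b.bases[j - 1 : j - 1 + n], strand_b.alphabet)
    mini = annotate_duplex(sub_a, sub_b)
    dh, ds = duplex_dh_ds(mini, params)
    return dg_from_dh_ds(dh, ds, temperature)
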