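"""Seeded generators emulating the wet-lab measurements.

Every generator is a deterministic function of (parameters, seed) and
returns both the noisy "measurement" and its ground truth, so fitters can
be validated by round-trip recovery. The emulated experiments:

* stopped-flow 2Ap quench traces of bimolecular association (strand
  concentrations of order 0.5-5 uM; free 2Ap bright, duplexed 2Ap dark);
* two-state melting curves at several concentrations with linear baselines;
* three-strand competition time courses (200 nM per strand by default);
* uniform-random nucleotide pools.

Noise is additive Gaussian with SD expressed as a fraction of the signal's
dynamic range (default 2%). ``paper_preset`` bundles the printed probe /
target pair with systematically generated mismatch and bulge competitor
panels, plus RNA twins.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .competition import MixtureSystem, TimeCourse, simulate_mixture
from .sequences import DefectSpec, DuplexSpec, Sequence, annotate_duplex, make_variant, parse_sequence
from .trace_fitting import (
    FluorescenceTrace,
    MeltCurve,
    bimolecular_bound,
    two_state_bound_fraction,
)

#: Signal levels of the emulated 2Ap reporter (arbitrary units).
F_FREE = 1.0  # single-stranded: maximal quantum yield
F_DUPLEX = 0.2  # duplexed: quenched

PROBE_SEQ = "CACGCATCACCA"
TARGET_SEQ = "TGGTGATGCGTG"


def gen_stopped_flow(
    k_on: float,
    k_off: float,
    conc_a: float,
    conc_b: float,
    noise_sd: float = 0.02,
    n_points: int = 200,
    t_max: Optional[float] = None,
    seed: int = 0,
) -> tuple[FluorescenceTrace, dict]:
    """Simulated 2Ap quench trace of A + B -> AB plus ground truth.

    The 2Ap-bearing strand is A; the signal relaxes from F_FREE toward
    F_DUPLEX as A is consumed. Returns (trace, truth) where truth carries
    the generating parameters and the clean bound-fraction curve.
    """
    if k_on <= 0 or k_off < 0 or conc_a <= 0 or conc_b <= 0:
        raise ValueError("invalid kinetic parameters")
    if t_max is None:
        t_max = 5.0 / (k_on * (conc_a + conc_b) / 2.0 + k_off)
    t = np.linspace(0.0, t_max, n_points)
    bound = bimolecular_bound(t, k_on, k_off, conc_a, conc_b)
    frac_a = bound / conc_a
    clean = F_FREE + (F_DUPLEX - F_FREE) * frac_a
    rng = np.random.default_rng(seed)
    signal = clean + rng.normal(0.0, noise_sd * (F_FREE - F_DUPLEX), size=len(t))
    trace = FluorescenceTrace(t, signal, conc_a, conc_b, name="stopped_flow")
    truth = {
        "k_on": k_on, "k_off": k_off, "bound_fraction": bound / min(conc_a, conc_b),
        "frac_a_bound": frac_a, "f_free": F_FREE, "f_duplex": F_DUPLEX,
        "noise_sd": noise_sd, "seed": seed,
    }
    return trace, truth


def gen_melt_curves(
    dh: float,
    ds: float,
    conc_list,
    noise_sd: float = 0.01,
    baselines: tuple = ((0.2, -0.0005), (1.0, -0.001)),
    temp_range: tuple = (5.0, 95.0),
    n_points: int = 181,
    seed: int = 0,
) -> tuple[list[MeltCurve], dict]:
    """Two-state melt curves at several 1:1 concentrations plus truth.

    ``baselines`` holds ((duplex intercept, slope), (free intercept, slope))
    about the window's midpoint temperature. Ground truth includes the
    generating K_D at 25 °C. Curves whose transition midpoint falls outside
    the window are still produced but flagged in the truth record.
    """
    from .nn_thermo import R_KCAL, T0

    t = np.linspace(*temp_range, n_points)
    rng = np.random.default_rng(seed)
    curves, flagged = [], []
    (b0, b1), (f0, f1) = baselines
    for idx, c in enumerate(conc_list):
        ca = cb = c  # c = concentration of each strand in a 1:1 mix
        f = two_state_bound_fraction(t, dh, ds, ca, cb)
        t_rel = t - t.mean()
        clean = (b0 + b1 * t_rel) * f + (f0 + f1 * t_rel) * (1.0 - f)
        dyn = abs(f0 - b0)
        sig = clean + rng.normal(0.0, noise_sd * dyn, size=len(t))
        curves.append(MeltCurve(t, sig, ca, cb, name=f"melt_{idx}"))
        if not (f.max() > 0.6 and f.min() < 0.4):
            flagged.append(idx)
    t25 = 25.0 + T0
    kd25 = float(np.exp((dh - t25 * ds / 1000.0) / (R_KCAL * t25)))
    truth = {"dh": dh, "ds": ds, "kd25": kd25, "seed": seed, "out_of_window": flagged}
    return curves, truth


def gen_competition_experiment(
    system: MixtureSystem,
    t_grid: np.ndarray,
    noise_sd: float = 0.02,
    seed: int = 0,
) -> tuple[FluorescenceTrace, TimeCourse]:
    """Noisy 2Ap trace of the target-bound fraction in a competition mix.

    The reporter sits on the target strand, so the clean signal tracks
    [T:P]/[T]_tot; ground truth is the full TimeCourse.
    """
    tc = simulate_mixture(system, t_grid)
    tot_t = system.conc_T
    frac = tc.species["TP"].to_numpy() / tot_t if tot_t > 0 else np.zeros(len(t_grid))
    clean = F_FREE + (F_DUPLEX - F_FREE) * frac
    rng = np.random.default_rng(seed)
    signal = clean + rng.normal(0.0, noise_sd * (F_FREE - F_DUPLEX), size=len(t_grid))
    trace = FluorescenceTrace(
        np.asarray(t_grid, dtype=float), signal, system.conc_T, system.conc_P,
        name="competition",
    )
    return trace, tc


def gen_random_pool(length: int, seed: int = 0, alphabet: str = "DNA") -> Sequence:
    """Uniform i.i.d. random sequence of the given length."""
    if length < 1:
        raise ValueError("length must be >= 1")
    rng = np.random.default_rng(seed)
    bases = "ACGT" if alphabet == "DNA" else "ACGU"
    return Sequence(
        "".join(np.array(list(bases))[rng.integers(0, 4, size=length)]),
        alphabet,
        name=f"pool_{length}",
    )


@dataclass
class PresetBundle:
    """The printed probe/target pair with generated competitor panels."""

    probe: Sequence
    target: Sequence
    variants: dict  # name -> Sequence (DNA)
    defects: dict  # name -> tuple[DefectSpec, ...]
    probe_rna: Sequence
    target_rna: Sequence
    variants_rna: dict

    def duplex(self, name: str, rna: bool = False) -> DuplexSpec:
        """Annotated duplex of a named competitor (or 'perfect') vs probe."""
        if name == "perfect":
            if rna:
                return annotate_duplex(self.target_rna, self.probe_rna)
            return annotate_duplex(self.target, self.probe)
        seq = (self.variants_rna if rna else self.variants)[name]
        probe = self.probe_rna if rna else self.probe
        return annotate_duplex(seq, probe, self.defects[name])

    def to_frame(self):
        """Variant table (name, bases, defect kinds, probe positions)."""
        import pandas as pd

        rows = []
        for name, seq in self.variants.items():
            defects = self.defects[name]
            rows.append({
                "name": name,
                "bases": seq.bases,
                "defect_kinds": ";".join(d.kind for d in defects),
                "probe_positions": ";".join(str(d.probe_position) for d in defects),
            })
        return pd.DataFrame(rows)


def paper_preset(seed: int = 0) -> PresetBundle:
    """Probe 5'-CACGCATCACCA-3', target 5'-TGGTGATGCGTG-3', and the
    systematic single-defect panels: mismatches m_1..m_12, interior bulges
    b_2..b_11, and the double mismatches m_4,9 and m_1,12; plus RNA twins
    (T -> U throughout)."""
    probe = parse_sequence(PROBE_SEQ, "DNA", name="P")
    target = parse_sequence(TARGET_SEQ, "DNA", name="12t")
    variants: dict = {}
    defects: dict = {}

    def add(defect_list):
        v = make_variant(target, probe, defect_list, seed=seed)
        variants[v.name] = v
        defects[v.name] = tuple(defect_list)

    for pos in range(1, 13):
        add([DefectSpec("mismatch", pos)])
    for pos in range(2, 12):
        add([DefectSpec("bulge", pos)])
    add([DefectSpec("mismatch", 4), DefectSpec("mismatch", 9)])
    add([DefectSpec("mismatch", 1), DefectSpec("mismatch", 12)])

    variants_rna = {name: seq.to_rna() for name, seq in variants.items()}
    return PresetBundle(
        probe, target, variants, defects, probe.to_rna(), target.to_rna(), variants_rna
    )
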