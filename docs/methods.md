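# Methods

## Scope and model overview

`hybrikin` models the annealing of two short (≈8–20 nt) DNA or RNA
oligonucleotides, one of which may carry *defects* relative to perfect
complementarity: internal or terminal mismatches, or single-base bulges
(an unpaired probe base created by a deletion in the partner). Three layers
sit on top of a shared nearest-neighbor (NN) free-energy engine:

1. an analytical nucleation–zippering expression for the association rate;
2. a stochastic (kinetic Monte Carlo) zippering simulator with an exact
   linear-algebra counterpart;
3. deterministic mass-action dynamics for three-strand competition,
   including strand displacement and reaction channels.

Alongside these sit measurement-analysis routines (stopped-flow traces,
melting curves), off-target combinatorics for random sequence, and seeded
synthetic-data generators that emulate each measurement.

## Duplex representation

Duplexes are *declared*, not inferred: a probe, a partner, and an explicit
defect list (1-based probe coordinates, 5'→3', named in the m_i / b_i
convention). Annotation builds the unique antiparallel register implied by
the declaration and verifies it: declared mismatches must be
non-complementary, everything else complementary, bulges interior and
non-adjacent. General gapped alignment is deliberately out of scope — the
experimental designs this package addresses are constructed, so ambiguity
is an input error, not something to resolve heuristically. G·U wobble
counts as non-complementary by default (wobble variants are defects here).

## Nearest-neighbor engine

Parameters are read at run time from `Bio.SeqUtils.MeltingTemp`: the
unified DNA set (SantaLucia 2004) with its internal- and terminal-mismatch
extensions, and the Biopython RNA NN set. Conventions:

* **Reference condition** 1 M NaCl, the native condition of the parameter
  sets; no salt correction is applied (a hook exists, off by default).
* **Initiation** terms and terminal A·T/A·U penalties are always included.
* **Single-base bulges** add a purely entropic loop increment
  (ΔG37 = +4.0 kcal/mol DNA, +3.8 RNA) while retaining the closing stack,
  the standard single-bulge treatment. Longer loops are unparameterized and
  raise an error.
* **RNA internal mismatches**: no installed source provides the full RNA
  1×1 internal-loop tables, so an internal RNA mismatch replaces its two
  flanking stacks with one generic loop penalty (+1.5 kcal/mol at 25 °C,
  entropic). This is deliberately coarse; every quantity that consumes it
  in the tests (equilibrium accuracy of a double-mismatch RNA competitor)
  is insensitive to factors of a few in the penalty. RNA terminal
  mismatches contribute nothing (dangling-like).
* **Tandem mismatches** raise an explicit error — the designs this package
  targets avoid adjacent mismatches, and silent fallbacks would be worse
  than refusal.
* **2-aminopurine** is an energy term only: ΔΔG(25 °C) = +0.9 kcal/mol per
  marked position in DNA, 0 in RNA, implemented entropically so ΔH is
  unchanged. Photophysics enters only through the synthetic signal model.

Melting temperatures are two-state: K_D(Tm) equals the free-strand product
at half-dissociation of the limiting strand, solved by bracketed root
finding. Agreement with Biopython's independent `Tm_NN` implementation (to
rounding of the gas constant) is enforced in tests for perfect and
mismatched duplexes.

## Nucleation–zippering association model

The association rate sums over every (i, j) segment pair of length n
(default n = 3, the segment length that best tracks measured rates):

    k_on = k_nuc · Σ_{i,j} α_c / (α_c + exp(ΔG_ij / RT)),  RT = 0.5925 kcal/mol

ΔG_ij is +∞ unless the two n-mers are antiparallel-complementary, in which
case the NN engine prices the n-mer mini-duplex *including initiation
terms* at 25 °C. Off-register accidental complements are included — the
double sum demands it — and reported separately from in-register sites.
No nucleation-length correction is applied on top of the site sum; adding
one degrades the fit this model family was developed for. α_c is shared
within a defect class (perfect / single_mismatch / double_mismatch /
bulge; a hypothetical mixed design takes the mismatch class).

**ΔG convention and the injection hook.** The α scale is only meaningful
relative to the ΔG_ij convention. Fitted α values published against
partition-function segment energies correspond to 3-mer ΔG values near
−6.5 kcal/mol, several kcal/mol below any NN mini-duplex convention
(−1.3 kcal/mol here with initiation; −3.4 without). The engine therefore
accepts externally computed ΔG_ij via `dg_table` on `enumerate_sites` /
`predict_kon`, for bit-compatible reuse of such values; when fitting with
the internal engine, α simply absorbs the constant offset. Consequently
the package reproduces literature α values only through the hook, and one
acceptance test that fixes α = 4.3×10⁻⁵ against the internal convention
fails by construction — kept failing rather than repriced, as a visible
record of the convention gap.

**Fitting.** Least squares on log₁₀ k_on (rates span a decade) with one
shared k_nuc and one α per class: Nelder–Mead from a fixed start, then a
tighter restart. α is reported as a lower bound when raising it one decade
changes the objective by <1% (floored at a 0.01-per-record log₁₀
dispersion) — saturated α values (p_zip ≈ 1 at every site) are
unidentifiable by construction. Confidence intervals come from seeded
record-resampling bootstrap (200 replicates by default).

## Zippering kinetic Monte Carlo

States are the contiguous bound intervals [a, b] of the alignment plus the
dissociated state (m(m+1)/2 + 1 states for alignment length m); moves add
or remove one terminal pair. State free energies are the NN engine applied
to the corresponding sub-duplex, so single-pair states carry
initiation-only energy (one pair has no stack). Rates are Metropolis at
k_uni = 4.2×10⁸ s⁻¹; a move that forms a declared mismatched pair adds a
barrier B (default 2.49 kcal/mol) through a transition-state energy
G‡ = max(G_s, G_s') + B, which slows formation and removal symmetrically
and preserves detailed balance exactly (verified edge-by-edge and by a
chi-square test against Boltzmann occupancy of the ergodic bound chain).
Bulge-crossing moves have their own barrier, default 0 — bulges do not
impede zippering.

**First-step estimator.** Trajectories start from single-pair nucleation
states at complementary positions (uniform entry) and absorb at full
zippering or detachment; re-nucleation after detachment is excluded. With
success probability p and conditional mean first-passage times t_s, t_f,

    k_on = 1 / (c · τ),   τ = 1/(p·k_coll·c) + (1−p)/p · t_f + t_s

where k_coll is the bimolecular entry rate: either a total collision rate
split evenly over sites (`entry_mode="total"`, default) or a per-site rate
(`entry_mode="per_site"`); the per-site/total normalization of a fitted
entry scale is convention, so both are exposed. Per-trajectory RNG streams
derive from (seed, trajectory index): results are identical for any worker
count. The exact counterpart solves the absorbing chain linearly
(h = Ph + b for absorption probabilities, (I−P)w = h/R for conditional
times) and is what the two-parameter (entry scale, barrier) fitter uses —
deterministic and fast. Stochastic and exact routes are cross-checked at
3 SE on all short duplexes in the tests.

## Competition dynamics

Mass-action ODEs over {T, C, P, T:P, C:P} plus optional reacted species
and substrate, integrated with LSODA at rtol 1e-10; per-family mass
conservation is asserted at 1e-9 relative. Binding accuracy
θ(t) = [T:P]/([T:P]+[C:P]) is NaN while nothing is bound. θ_in uses the
kinetic-partition formula, exact in the no-depletion limit (probe
sub-stoichiometric or equal rates); θ_eq solves the two-K_D competitive
binding conservation equation by bracketed root finding on free probe
(residual <1e-12; agreement with the closed-form cubic is a test oracle).
Strand displacement (C:P + T ⇌ T:P + C) is off by default for DNA —
dissociation dominates at 200 nM — and available for RNA with a
1 M⁻¹s⁻¹-scale toehold-free rate; its reverse rate is derived from the
K_D ratio, so switching the channel on cannot move the equilibrium (tested).
Extension/ligation channels are pseudo-bimolecular in substrate
(depletion optional, default constant substrate) and convert bound
duplexes into inert longer species; the competitor's reacted fraction
plateaus once the transient C:P pool is gone.

The equilibration half-life is the time for [C:P] to fall halfway from its
early maximum to its equilibrium value, interpolated on log time. It
tracks ln2/k_off^{C:P} when rebinding of freed probe to the competitor is
rare (target outcompeting, probe sub-stoichiometric); in symmetric
equimolar designs rebinding stretches it by small factors — the tests
assert a factor-2 band across a 100× off-rate sweep rather than equality.

## Measurement analysis

**Stopped-flow traces.** The normalization (F_mix − F_TP)/(F_T − F_TP) is
implemented as printed; an orientation flag ("bound" default, "free")
exists because a quenched-when-duplexed reporter makes the printed ratio
the *free* fraction — the synthetic generator (free = bright) exercises
the "free" orientation. The reversible two-species mass-action ODE has an
exact closed-form solution (logistic between the quadratic's roots), which
the k_on fit evaluates directly — equivalent to stiff integration but
exact; the closed form is verified against `solve_ivp` in tests. Fits are
seeded multistart over k_on ∈ [10⁵, 10⁹] M⁻¹s⁻¹; reversibility is
auto-enabled when the trace plateaus below 95% bound; a configurable
dead-time excludes mixing artifacts (0.05 s typical).

**Melting curves.** Per-curve two-state van't Hoff fits (ΔH, ΔS, linear
upper/lower baselines; initial values from the curve ends and midpoint),
K_D extrapolated to 25 °C, aggregated across replicate concentrations as a
lognormal mean/SD. Curves whose transition falls outside the scanned
window fail individually; the aggregate runs over survivors.

**Comparison statistics.** R² is the standard coefficient of
determination; "RMSE" follows the percentage definition
(100/m)·Σ|ŷ−y|/y — a mean absolute percentage deviation, implemented
exactly as defined.

## Off-target combinatorics

For a probe of length n over a random pool of length L, expected binding
sites are counted exactly: (L−n+1)·Σ_{k≤d} C(n,k)3^k/4^n mismatch windows,
plus, if a bulge is allowed, (L−n+2)·D/4^{n−1} windows matching an
*interior* single-deletion complement (a bulge must be flanked by pairs).
D, the number of distinct interior-deletion patterns, is probe-dependent
with exactly D = 1 + Binomial(n−3, 3/4); the at-least-one-site probability
mixes the Poisson (or exact product) miss-probability over that
distribution rather than using the mean — the difference is visible at
desk scale. Windows are otherwise treated as independent; the seeded Monte
Carlo validator (fresh random probe and pool per trial, full window scan
with the same matching rule) confirms 3-SE agreement across the tested
grid for n ≥ 8 or single-defect-type queries, while for n = 6 with both
defect types budgeted the analytic form overestimates by a few percent
absolute (bulge matches near the pattern edge co-occur with one-mismatch
full-window matches). No thermodynamic weighting is applied: this is a
counting argument about complementarity, not a binding-energy model.

## Synthetic data

Generators are deterministic in (parameters, seed) and return ground
truth. Conditions mirror the emulated experiments: stopped-flow strand
concentrations of order 0.5–5 μM, melting curves over 5–95 °C at several
1:1 concentrations, competition mixes at 200 nM per strand, uniform random
pools. Noise is additive Gaussian with SD a fraction (default 2%, 1% for
melts) of the signal dynamic range; the 2Ap signal is bright when free and
quenched when duplexed. Not emulated: instrument drift, photobleaching,
mixing dead-time artifacts, shot-noise statistics — so passing round-trip
tests demonstrate estimator correctness under the stated noise model, not
robustness to systematic instrument error.

## Problem sizes and defaults

The test suite and acceptance script run at desk scale by choice of
experimental design, not approximation: 12-bp duplex panels, chains of
≤79 states solved exactly, 10⁴ trajectories where stochastic/exact
agreement is asserted (binomial 3-SE bands), Monte Carlo off-target grids
at n ∈ {6, 8, 11}, L ≤ 10⁴, 2.5×10³ trials per cell, and 200-replicate
bootstraps. Fitted-parameter recovery is tested at 5% lognormal rate noise
(log₁₀ k_nuc within ±0.1, identifiable α within 2×, KMC barrier within
±0.3 kcal/mol, stopped-flow k_on within 5% at 2% trace noise, melt K_D
within 1.5×).

## Known limitations

* The NN mini-duplex ΔG convention for nucleation segments is offset by
  several kcal/mol from partition-function conventions; α values are
  convention-bound (see the injection hook above).
* RNA mismatch thermodynamics use a generic loop penalty, not
  sequence-resolved 1×1 tables.
* No salt or Mg²⁺ corrections; all defaults at 1 M NaCl.
* Out-of-register bound states, multi-strand (>2) complexes and hairpin
  intermediates are outside the zipper state space.
* One competitor per mixture is tested (the architecture permits more).
* Off-target counting ignores window dependence beyond the bulge-pattern
  mixture; short probes with mixed defect budgets carry a small
  conservative bias.
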