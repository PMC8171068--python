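# Methods

## Model

A commensurately modulated crystal is described in (3+1)D superspace. The
modulation wavevector **q** = (σ₁, σ₂, σ₃), in reciprocal-lattice units of
the basic cell, gives the offset of first-order satellite reflections from
their main reflections. When every σᵢ = pᵢ/Nᵢ is rational in lowest terms,
the structure is commensurate: the supercell contains Nᵢ basic cells along
axis i (N = N₁N₂N₃ in total) and indexes all reflections.

Every atomic parameter is governed by a periodic atomic modulation function
(AMF) of the superspace coordinate

    x4 = q · (x̄ + n) = q · x̄ + t,    t = frac(q · n),

where x̄ is the atom's average position in basic-cell fractional
coordinates and n the integer cell index vector. The N basic cells sample
each AMF at the N fractions t = k/N; sorting cells by t (the *superorder*)
lays those samples along one AMF period. t is computed from the basic-cell
corner as origin, and the fractional part is taken with floor so negative
x4 reduces correctly.

The pipeline: assign chains to cells → fold cells onto the first → match
chains across cells into tNCS families → average members per atom → record
per-member displacement from the average at that cell's t. Occupancy
modulation appears as members missing from some cells; the AMF has no value
there (a discontinuity), which the series represent with presence flags.

## Algorithms and numerical choices

**Rationalization.** The smallest-denominator fraction p/N with
N ≤ max_denominator and |p/N − σ| ≤ tolerance is found by scanning
denominators in ascending order with the nearest numerator at each — an
exact search equivalent to walking the Stern–Brocot tree, affordable
because max_denominator defaults to 50 (observed protein supercells are
≤ 9-fold). Default tolerance 1e-3. Components are reduced modulo 1 (q lives
on the reciprocal-space torus). No fraction within tolerance raises an
"irrational within bounds" error: the input is effectively incommensurate
at that bound.

**q estimation from intensities.** For each candidate period N (2 up to
max_denominator, requiring at least two full periods of indices), reflections
are binned by l mod N; the candidate is scored by (mean intensity of the
strongest class) / (mean of the rest) and accepted at contrast ≥ 3 (the
harmonic N′ = 2N of a true period scores lower because its "rest" classes
contain main reflections). The first-order satellite offset m is the
strongest non-main class, folded to min(m, N − m) — m and N − m describe the
same spacing, and the smaller is reported by convention (3/7, not 4/7). A
profile whose best satellite class is below 1e-6 of the main class is a pure
translational repeat ("no modulation detected"), and the mean-intensity
hierarchy mains ≥ first order ≥ second order is enforced.

**Superspace reindexing.** l = h₃N + h₄p has a one-parameter integer
solution family; h₄ ≡ l·p⁻¹ (mod N) picks the representative with minimal
|h₄|, breaking the ±h₄ tie toward positive order (a fixed convention; no
physical content).

**Patterson section.** P(w) = Σ I(hkl)·cos(2πlw) at (u, v) = (0, 0) on a
512-point grid, origin-normalized; all reflections contribute (any h, k
collapse onto the l-cosine on this section). Raw intensities are used — no
E-value sharpening. Amplitudes are squared on input. Peak detection keeps
local maxima ≥ 0.2 of the origin *and* ≥ 0.5 of the strongest non-origin
peak: tNCS repeat peaks are near origin height, while series-termination
ripple and minor interatomic-vector maxima are not, and the dominance filter
keeps the spacing estimate from being dragged by them. The mean
nearest-neighbour gap (including the gaps to w = 0 and 1, occupied by the
origin peak) is snapped to the nearest 1/N, N ≤ 24.

**Partitioning.** Chains are assigned whole, by center of mass:
nᵢ = floor(comᵢ·Nᵢ). The COM is the unweighted mean of all atom fractional
positions (not mass-weighted, not backbone-only) — a documented choice where
reasonable alternatives exist; rigid-chain displacements make them
equivalent on synthetic data. A COM within 1e-9 of a cell boundary goes to
the lower cell with a warning. Folding is xᵢ → xᵢNᵢ − nᵢ without
re-wrapping, so chains protruding past a cell face stay contiguous; the
basic cell is the supercell divided by the denominators (a ninefold 385.4 Å
axis folds to 42.82 Å — the division result is reported as is, not forced
to any rounded published value).

**Family matching.** Per cell, member chains are matched one-to-one to the
reference cell's chains by folded-COM distance using optimal assignment
(scipy's linear_sum_assignment). Distances use cell-edge scaling of
fractional offsets — exact for orthogonal cells, which all exemplars are.
Match tolerance 10 Å by default (modulation displacements are a few Å;
distinct chains sit ≥ 15 Å apart). Two chains within tolerance of one
reference raise an explicit ambiguity error asking for a chain map, which
can always be supplied instead of matching.

**Ordering arithmetic.** t values are exact `Fraction`s (so the multiset
{k/N} is exact and sorting has no float ties); ties between cells at equal
t — possible when two modulated axes share a denominator factor — break by
ascending cell index. Internal indices are 0-based; reports are 1-based,
with the flat cell numbering taking the last axis fastest so a purely-x₃
supercell numbers its cells 1..N along x₃.

**AMF series.** Displacements are reported both in basic-cell fractional
units and in Å (cell-edge scaling, exact for orthogonal cells) — plots of
either are meaningful and the choice is left to the reader. The sawtooth
reset is located as the largest negative cyclic jump between consecutive
samples and reported at the midpoint of the bracketing pair; N discrete
samples cannot localize it further. A smooth waveform also has a largest
negative jump (its descending flank), so the result carries a contrast value
(jump over mean other-step size) and is flagged below 2.0. Series
comparison interpolates linearly on the cyclic t domain (needed to overlay
7-sample against 9-sample series); `mirror_t` evaluates the partner at
(1 − t) mod 1. Frames for animation are the folded cells in superorder,
cyclic, with per-family COM arrows from the previous frame; arrow sums
close to zero around the cycle by construction.

## Synthetic generator

The generator emulates the structure of the two exemplar superstructures:
a basic cell of 146.29 × 146.29 × 42.65 Å (so the sevenfold supercell's c
axis is 298.55 Å and the ninefold stack uses the same footprint) containing
four Cα-trace chains of 20 residues, dart-thrown ≥ 15 Å apart and built as
seeded 3.8 Å random walks. Modulation displaces each chain rigidly by its
family's AMF evaluated at x4 = q·com + t: sinusoids A·sin(2π(x4 + φ)),
sawtooths rising −A → +A with a prescribed reset, amplitudes ≤ 0.05
fractional (defaults 0.008–0.015, i.e. a few Å — small against the cell, as
observed modulations are), and optional occupancy windows in t. The default
exemplar recipe gives the transverse axes mirror-paired sinusoids and the
stacking axis sawtooths with staggered resets — the qualitative features
reported for the real pair.

Diffraction is simulated on the 00l axis only with unit point scatterers
damped by the atomic Debye–Waller factor (B = 20 Ų default): real intensity
data decays with resolution, and omitting the falloff leaves unphysical
series-termination ripple in Patterson syntheses. Default index range
l = 0..126 (18 periods of the sevenfold case, 14 of the ninefold).

What the generator does *not* emulate: internal conformational modulation
(chains displace rigidly), full hkl diffraction, measurement noise, solvent
or anomalous scattering, and crystallographic symmetry beyond P1. Passing
tests therefore demonstrate the correctness of the bookkeeping, ordering,
estimation and detection machinery on cleanly modulated data — not
robustness to the disorder, noise and incompleteness of measured data.

Exact-recovery statements have one caveat worth knowing: the average
structure estimates the family mean, so recovered displacement samples
equal the generating displacements *centred on their per-family mean*. For
sinusoids sampled at N equispaced t values the mean is exactly zero and
recovery is literal; a sawtooth's sample mean is generally a small nonzero
constant absorbed into the average position.

## Design decisions where the design was open

- A Model/Results surface (`SuperspaceModel.fit() → SuperspaceResults`)
  wraps the functional pipeline: the decomposition is deterministic, so the
  Results object carries products and diagnostics rather than uncertainties.
- One CLI entry point with subcommands (rationalize/order/qscan/patterson/
  analyze/simulate) rather than separate executables.
- Orderings for multi-axis q use the same enumeration-and-sort as the axial
  case; the two-axis 5 × 7 (35-cell) configuration is covered by tests.
- Altloc policy on read: keep the highest-occupancy conformer. Negative
  measured intensities clamp to zero with a warning. Both are documented
  defaults, not knobs the science depends on.
- Tabular outputs are TSV; frames are multi-model PDB.

## Problem sizes

Tests and the acceptance script run entirely on generated data: supercells
of 28–36 chains (560–720 atoms), 127-point 00l intensity profiles, and
512-point Patterson grids — sizes at which every stage is exact or
machine-precision testable and the whole suite runs in seconds.

## Known limitations

- Single q vector ((3+1)D) only; no (3+2)D support.
- Chains straddling the *supercell* boundary (wrapped coordinates) are not
  unwrapped before COM computation; deposited supercell models place chains
  contiguously, and the generator guarantees it.
- Intensity averaging for the q-estimate profile is over all reflections at
  fixed l, with no resolution cutoff.
- No refinement against data anywhere: the package analyses models and
  intensities as given.
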