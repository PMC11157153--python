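# Methods

This note documents the models, defaults and numerical choices behind
`modshift`, and what the synthetic benchmarks do and do not demonstrate.

## Reference model of the unmodified protein

The elemental composition of the intact chain is the sum of residue
formulas plus one water (pyteomics). Its aggregated isotopic distribution
is computed by per-element convolution over the NIST isotope table:
each element's per-atom distribution, indexed by neutron count, is raised
to the atom count by exponentiation-by-squaring, elements are combined by
convolution, and each neutron bin keeps the abundance-weighted centroid
mass. This yields ~1 Da-spaced isotopologue peaks without enumerating
fine structure (which is infeasible at 40 kDa). Peaks below
`min_abundance` (default 1e-5) are pruned and the rest renormalized;
pruning at this level moves the distribution mean by well under 0.05 Da.

A three-parameter Gaussian least-squares fit (initialized at the apex,
with σ₀ = FWHM/2.355) to the (mass, abundance) points gives the constant
envelope width σ and the reference mass *m*₀. For human p53 (393 aa,
average mass 43652.79 Da) this yields σ = 5.58 Da and *m*₀ = 43652.48 Da.
σ grows with protein size (≈ √mass); the same σ is reused for every
modified species, because a few added PTM atoms change the envelope
width negligibly.

The fit of a *windowed* portion of the (slightly right-skewed) envelope
sits ~0.3 Da below the full-distribution fit; this small systematic
offset is shared by all species of one protein, so shift *differences*
are unaffected, and it is well inside the 20–36 ppm (0.9–1.6 Da)
tolerances used downstream.

## Mass-shift detection

Pipeline per sample: select the analysis mass range → normalize by the
window maximum (the maximum is kept so raw units can be restored) →
centroid (strict local maxima; plateaus at their midpoint; boundary
points never peaks) → noise level = ½ × population SD of all profile
intensities in the range → sliding-window fits → χ² filter → overlap
resolution → joint refinement → quantification.

Key parameters and defaults:

* **window_size** — the mass width of the reference distribution's peaks
  with abundance ≥ 2/3 of the apex ("upper third"), floored at 6 Da
  (9.0 Da for p53). This guarantees ≥ 5 peaks per window for proteins
  ≥ ~14 kDa.
* **step_size** — 1 Da.
* **min_peak_distance** (allowed overlap) — 2/3 × window_size.
* **pvalue_threshold** — 0.05.
* **min_signal_peaks** — 5; windows with fewer signal peaks (above the
  noise level) produce no candidate.

Within a window, only the mean and amplitude are free. The fit is solved
as profile least squares: for a candidate mean the optimal non-negative
amplitude is closed-form, and the mean is located by a coarse grid over
the window followed by bounded scalar minimization. This is
deterministic, exact to ~1e-8 Da, and fast enough for the 100-replicate
benchmark harnesses. A candidate whose optimal mean pins to the window
boundary (within `edge_margin` = 0.25 Da) is discarded: the window does
not bracket an envelope apex, and the neighbouring window captures the
species with an interior optimum. Without this rule every isolated
envelope spawns a ladder of spurious flank fits.

The χ² statistic, Σ(obs − exp)²/exp with dof = n − 2 − 1, is computed on
the **ion-count scale**: intensities of single-ion spectra are ion
counts, which is the scale on which the Pearson statistic is calibrated.
Operationally the normalized window data are rescaled by the window's
normalization factor (configurable via `count_scale`). On normalized
intensities the statistic is so small that every fit — including
background artifacts — gets p ≈ 1 and the significance filter is inert;
on count scale, misfitted valley/background candidates are rejected and
the p-value ordering between candidates becomes meaningful.

Overlap resolution is greedy best-first: candidates ordered by
decreasing p-value (ties by larger amplitude, then lower mean) are
accepted iff at least `min_peak_distance` from every accepted mean. The
survivor set is independent of input order.

**Joint refinement.** A single-window fit of a partially overlapping
envelope is biased toward its neighbour by the neighbour's tail inside
the window (0.5–1.6 Da at 10–16 Da separations — comparable to the
20 ppm tolerance). After overlap resolution, all survivors are therefore
refit together as a sum of constant-σ Gaussians over the union of their
signal peaks. Each mean is bounded within half the allowed overlap of
its window estimate and the component count never changes, so the
refinement cannot split anything the scan did not already resolve; it
only removes the neighbour-tail bias of resolved species. On isolated
species it is a no-op to within hundredths of a Dalton.

Abundance per species is the Gaussian area A = α·σ·√(2π), rescaled to
raw units; relative abundances are fractions of the summed detected
area. (The √(2π) constant is the exact Gaussian integral; relative
abundances are invariant to it.)

## Cross-sample alignment

Fitted means from all samples are sorted and binned greedily: a new bin
starts when a mean lies ≥ `bin_size` above the bin's smallest member.
This bounds each row's spread below `bin_size`, keeps every member
within `bin_size` of the row average, and provably minimizes the number
of rows (greedy interval covering). The default bin size is the ppm mass
tolerance of the reference mass, floored at 0.5 Da. The row's arithmetic
mean mass is the species mass used for inference and reporting. Binning
is idempotent for species separated by more than the bin — the intended
regime; for means packed denser than the bin size no once-averaging rule
can be simultaneously spread-bounded and idempotent, and the spread
bound wins.

## PTM-pattern inference

The three programs are integer linear programs (counts are integers)
solved with scipy's HiGHS backend. |**m**·**p** − obs| is linearized
with one auxiliary variable; ε_max is the ppm tolerance of the
*protein's reference mass* (not of the shift), since the error budget of
a fitted envelope mean scales with the protein mass. P_max defaults to
Σ ubᵢ.

Lap strictness: `min_ptm` adds P ≥ P_prev + 1. For `min_error` and
`min_both` the strict-improvement constraint is enforced on the *actual*
error (resp. actual combined score) with a big-M disjunction over the
sign of the error — constraining only the auxiliary variable would let
the solver pad it and return the previous pattern again. The margins
(`epsilon_step` = 1e-3 Da, `score_step` = 1e-4) sit far below any
chemically meaningful objective difference and far above the solver's
feasibility tolerance. Patterns whose objective ties the previous
optimum exactly (e.g. mass-degenerate methyl combinations: 1[Me1]+1[Me3]
vs 2[Me2]) are skipped by construction; an exhaustive enumerator over
the bounded integer box provides the independent optimum for testing.

The stock table ships nine PTM types with masses derived from elemental
composition (average-mass convention, since fitted envelope means track
average mass): phosphorylation, acetylation, mono/di/tri-methylation,
phosphate adduct, oxidation, cysteinylation, sodium adduct. Upper
bounds default to the maximal per-type multiplicities reported for
intact p53 below ~400 Da (Ph 2, Ac 1, Me1 1, Me2 2, Me3 2, Ph-OH 3,
Ox 1, Cys 3, Na 1); adducts and artifacts are kept at low multiplicity.
All of this is an editable CSV.

## Synthetic spectra and the noise model

Simulated profile spectra place each species' isotopic envelope (the
reference distribution shifted by **m**·**p**) on a 0.02 Da grid as
narrow Gaussian peaks (σ = 0.05 Da), scaled so the tallest peak is ~500
ions — a realistic single-ion accumulation, and the scale on which the
χ² filter operates. Envelope shape changes from the PTM atoms themselves
are neglected (a few added atoms at 40+ kDa shift the envelope far more
than they reshape it).

Noise channels (all beta-distributed, all seeded, each switchable off):

* **basal** — background peaks on a ~1 Da lattice, heights
  `0.10 × apex × Beta(0.3, 8)`: mostly near zero with occasional
  stray-ion spikes. With this (spiky) shape ≥ 99 % of background peaks
  stay below the estimated noise level in realistic analysis windows,
  and basal noise leaves multi-species detection counts unchanged.
* **vertical** — each peak's height multiplied by
  `1 + 0.10 × (2·Beta(2.5, 2.5) − 1)` (sd ≈ 4 %, consistent with
  counting statistics at a few hundred ions per peak). At this level
  isolated species are recovered within 20 ppm in 100 % of replicates.
* **horizontal** — peak-spacing deviations
  `0.06 × (2·Beta(2.5, 2.5) − 1)` Da accumulated peak-to-peak; the walk
  restarts across signal gaps > 3 Da (an empty region has no spacing to
  deviate from, and instrument calibration does not drift unboundedly
  across a spectrum).

The supplementary beta parameters fitted to instrument data are not
publicly tabulated; these defaults were fixed once from the qualitative
descriptions of the three channels and the documented operating regime
(background below the signal threshold; detection of well-separated
species robust to every channel), and are user-replaceable.

## Benchmarks: what passing shows

* **Overlap ladder** — two equal-abundance p53-sized envelopes at mean
  separations 2–16 Da, 100 noisy replicates each; a replicate is
  "separated" when both means are recovered within 20 ppm. The smallest
  separation separated in > 75 % of replicates is **10 Da** (98–100 %),
  with 12–16 Da at ~100 % and ≤ 8 Da essentially never separated. The
  10 Da limit is structural: two σ = 5.58 Da envelopes form a unimodal
  sum below 2σ ≈ 11.2 Da, and only the shoulder asymmetry lets the
  sliding-window fits split them at 10 Da. At 8 Da (1.4 σ) the blob is
  too deeply merged: 39/40 noisy replicates yield exactly one fit, so
  the resolved fraction at 8 Da is ~0–2 %. Control experiments with
  smaller proteins shift the whole ladder as expected (σ = 3.9 →
  transition between 6 and 8 Da; σ = 4.5 → 8 Da at ~95 %), i.e. a
  substantial-but-minority rate at 8 Da corresponds to a separation of
  ~1.6 σ and is not attainable for a 43.6 kDa protein.
* **Phosphorylation ladder** — seven species 0–6 phosphates apart
  (~80 Da spacing): detection 7/7 and abundance R² ≈ 0.997 under all
  noise channels combined.
* **Complex landscape** — 18 species over four PTM types spanning
  16–453 Da with ≥ 16 Da gaps: all 18 detected in > 75 % of noisy
  replicates at 36 ppm; correct-pattern counts satisfy
  min_both ≥ min_ptm and k = 3 ≥ k = 1. This fixture is a synthetic
  stand-in — absolute correctness counts depend on the exact pattern
  list and are not comparable across fixtures.

These simulations emulate envelope shape, count-scale noise and
background of single-ion spectra. They do **not** model contaminant
species (a contaminant above the noise level will be reported as a
modform — a known behaviour, not corrected), detector-specific ion
statistics, or envelope-shape changes from unusual elemental
compositions; performance on real spectra additionally depends on
calibration and the appropriateness of the user's PTM table.

## Degenerate inputs and edge cases

Empty mass windows, spectra with < 3 profile points, windows with < 5
signal peaks, empty detection results, infeasible inference instances
and empty alignment tables all return explicit empty/None results or
raise informative errors; the CLI maps stage failures to nonzero exit
status with the stage name. All randomness flows through explicit seeds
(`numpy.random.default_rng` / `SeedSequence.spawn`), and repeated runs
are byte-identical.
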