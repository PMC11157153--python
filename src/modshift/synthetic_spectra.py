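"""Simulation of true mass spectra from known PTM-pattern mixtures.

A modform spectrum is built by shifting the protein's aggregated isotopic
distribution by each pattern's mass, scaling by its relative abundance,
and rendering the resulting ~1 Da-spaced sticks as narrow profile peaks.
Three noise/error channels, each driven by a beta distribution, emulate
experimental single-ion spectra:

* basal noise      — background peaks at ~1 Da spacing across the range;
* vertical error   — multiplicative scatter of each peak's height
                     (the fit/peak height ratio);
* horizontal error — deviation of the peak spacing from 1 Da, applied
                     cumulatively from peak to peak.

Two benchmark harnesses rerun the full detection (and optionally
inference) pipeline over many noisy realizations: an overlap ladder of
two-species spectra at decreasing separation, and a pattern benchmark for
arbitrary mixtures.
"""

from __future__ import annotations

from dataclasses import dataclass, replace as _dc_replace

import numpy as np

from .mass_shift_detection import detect_mass_shifts
from .protein_reference import ProteinReference
from .ptm_inference import (
    InferenceConfig,
    PtmEntry,
    PtmTable,
    enumerate_k_solutions,
)
from .spectrum_io import RawSpectrum

__all__ = [
    "Species",
    "ModformSpec",
    "NoiseModel",
    "BenchmarkResult",
    "build_theoretical_spectrum",
    "apply_noise",
    "run_overlap_ladder",
    "run_pattern_benchmark",
    "phospho_ladder",
    "complex_landscape",
    "complex_landscape_table",
    "P53_SEQUENCE",
]

#: human cellular tumor antigen p53 (UniProt P04637), the study protein
#: used by the stock benchmark fixtures; ~43.65 kDa average mass.
P53_SEQUENCE = (
    "MEEPQSDPSVEPPLSQETFSDLWKLLPENNVLSPLPSQAMDDLMLSPDDIEQWFTEDPGP"
    "DEAPRMPEAAPPVAPAPAAPTPAAPAPAPSWPLSSSVPSQKTYQGSYGFRLGFLHSGTAK"
    "SVTCTYSPALNKMFCQLAKTCPVQLWVDSTPPPGTRVRAMAIYKQSQHMTEVVRRCPHHE"
    "RCSDSDGLAPPQHLIRVEGNLRVEYLDDRNTFRHSVVVPYEPPEVGSDCTTIHYNYMCNS"
    "SCMGGMNRRPILTIITLEDSSGNLLGRNSFEVRVCACPGRDRRTEEENLRKKGEPHHELP"
    "PGSTKRALPNNTSSSPQPKKKPLDGEYFTLQIRGRERFEMFRELNEALELKDAQAGKEPG"
    "GSRAHSSHLKSKKGQSTSRHKKLMFKTEGPDSD"
)


@dataclass
class Species:
    """One simulated species: a mass shift, its relative abundance and
    (when built from a PTM pattern) the ground-truth count vector."""

    shift: float
    abundance: float
    counts: tuple[int, ...] | None = None
    label: str = ""


@dataclass
class ModformSpec:
    """A simulated modform (PTM-pattern) distribution for one protein."""

    protein: ProteinReference
    species: list[Species]

    def __post_init__(self) -> None:
        total = sum(s.abundance for s in self.species)
        if not np.isclose(total, 1.0, atol=1e-9):
            raise ValueError(f"species abundances must sum to 1 (got {total})")
        if any(s.abundance <= 0 for s in self.species):
            raise ValueError("species abundances must be positive")

    @classmethod
    def from_shifts(cls, protein: ProteinReference, shifts_abundances) -> "ModformSpec":
        return cls(protein, [Species(float(s), float(a)) for s, a in shifts_abundances])

    @classmethod
    def from_patterns(cls, protein: ProteinReference, table: PtmTable, patterns) -> "ModformSpec":
        """``patterns``: iterable of (counts mapping or sequence, abundance)."""
        species = []
        for counts, abundance in patterns:
            if isinstance(counts, dict):
                vec = tuple(int(counts.get(n, 0)) for n in table.names)
            else:
                vec = tuple(int(c) for c in counts)
            shift = float(np.dot(table.masses, vec))
            label = "".join(f"{c}[{n}]" for c, n in zip(vec, table.names) if c) or "unmodified"
            species.append(Species(shift, float(abundance), vec, label))
        return cls(protein, species)

    def true_shifts(self) -> np.ndarray:
        return np.array([s.shift for s in self.species])

    def true_abundances(self) -> np.ndarray:
        return np.array([s.abundance for s in self.species])


@dataclass
class NoiseModel:
    """Beta-distributed noise channels of a simulated true mass spectrum.

    Each channel has a beta shape pair and an amplitude/width scale; a
    scale of zero switches the channel off.  ``seed`` makes the sampled
    spectrum fully reproducible.
    """

    basal_shape: tuple[float, float] = (0.3, 8.0)
    basal_scale: float = 0.10          # background peak height, fraction of max signal
    vertical_shape: tuple[float, float] = (2.5, 2.5)
    vertical_width: float = 0.10       # height ratio drawn from 1 +- width
    horizontal_shape: tuple[float, float] = (2.5, 2.5)
    horizontal_width: float = 0.06     # Da; spacing deviation drawn from +- width
    horizontal_reset_gap: float = 3.0  # Da; spacing walk restarts across signal gaps
    seed: int = 0

    def __post_init__(self) -> None:
        for a, b in (self.basal_shape, self.vertical_shape, self.horizontal_shape):
            if a <= 0 or b <= 0:
                raise ValueError("beta shape parameters must be positive")
        if min(self.basal_scale, self.vertical_width, self.horizontal_width) < 0:
            raise ValueError("channel scales must be >= 0")

    @classmethod
    def default(cls, seed: int = 0) -> "NoiseModel":
        return cls(seed=seed)

    @classmethod
    def zero(cls, seed: int = 0) -> "NoiseModel":
        return cls(basal_scale=0.0, vertical_width=0.0, horizontal_width=0.0, seed=seed)

    def with_seed(self, seed: int) -> "NoiseModel":
        return _dc_replace(self, seed=int(seed))


#: width of a rendered profile peak (Da); fine relative to the 1 Da
#: isotopologue spacing so that centroiding recovers the apexes.
PEAK_SIGMA = 0.05
GRID_STEP = 0.02

#: ion count at the tallest profile peak of a simulated spectrum.  Spectra
#: built from individual ions report counts, and the downstream chi-square
#: goodness-of-fit test is calibrated on that count scale; a few hundred
#: ions at the apex is a typical accumulation for an intact-protein run.
APEX_IONS = 500.0


def _render_sticks(grid: np.ndarray, masses, heights, peak_sigma: float = PEAK_SIGMA) -> np.ndarray:
    out = np.zeros_like(grid)
    step = grid[1] - grid[0]
    half = int(np.ceil(5 * peak_sigma / step))
    for m, h in zip(masses, heights):
        if h <= 0:
            continue
        center = int(round((m - grid[0]) / step))
        lo = max(center - half, 0)
        hi = min(center + half + 1, grid.size)
        if lo >= hi:
            continue
        x = grid[lo:hi]
        out[lo:hi] += h * np.exp(-((x - m) ** 2) / (2 * peak_sigma**2))
    return out


def build_theoretical_spectrum(
    spec: ModformSpec,
    grid_step: float = GRID_STEP,
    lo: float | None = None,
    hi: float | None = None,
    peak_sigma: float = PEAK_SIGMA,
    source_id: str = "simulated",
    apex_ions: float = APEX_IONS,
) -> RawSpectrum:
    """Render the noise-free profile spectrum of a modform mixture.

    Each species contributes the reference isotopic distribution shifted
    by its mass shift and scaled by its abundance; isotopologue sticks are
    drawn as narrow Gaussian profile peaks on a common grid.  Intensities
    are in ion counts: the tallest peak is scaled to ``apex_ions``.
    """
    dist = spec.protein.isotopic_distribution
    margin = 4 * spec.protein.sigma + 5.0
    if lo is None:
        lo = float(dist.masses.min() + min(s.shift for s in spec.species) - margin)
    if hi is None:
        hi = float(dist.masses.max() + max(s.shift for s in spec.species) + margin)
    grid = np.arange(lo, hi + grid_step, grid_step)
    profile = np.zeros_like(grid)
    for s in spec.species:
        profile += _render_sticks(
            grid, dist.masses + s.shift, dist.abundances * s.abundance, peak_sigma
        )
    peak = profile.max()
    if peak > 0 and apex_ions:
        profile *= apex_ions / peak
    return RawSpectrum(grid, profile, normalization_factor=1.0, source_id=source_id)


def _peak_segments(intensities: np.ndarray) -> list[tuple[int, int]]:
    """Split a profile into per-peak segments at (near-)zero troughs and
    interior local minima; returns half-open index ranges."""
    n = intensities.size
    nz = intensities > 0
    segments: list[tuple[int, int]] = []
    i = 0
    while i < n:
        if not nz[i]:
            i += 1
            continue
        j = i
        while j < n and nz[j]:
            j += 1
        # split the nonzero run at interior local minima
        run = intensities[i:j]
        if run.size > 2:
            interior = np.flatnonzero(
                (run[1:-1] < run[:-2]) & (run[1:-1] <= run[2:])
            ) + 1
            cuts = [0] + [int(k) for k in interior] + [run.size]
        else:
            cuts = [0, run.size]
        for a, b in zip(cuts[:-1], cuts[1:]):
            if b > a:
                segments.append((i + a, i + b))
        i = j
    return segments


def apply_noise(spec: RawSpectrum, model: NoiseModel) -> RawSpectrum:
    """Apply the three seeded noise channels to a profile spectrum.

    Vertical error multiplies each peak segment's height by a beta-drawn
    ratio; horizontal error shifts peak positions by cumulative beta-drawn
    spacing deviations; basal noise adds background peaks on a ~1 Da
    lattice.  With all channel scales zero the input is returned
    unchanged (up to a copy).
    """
    rng = np.random.default_rng(model.seed)
    grid = spec.masses
    if model.vertical_width == 0 and model.horizontal_width == 0:
        out = spec.intensities.copy()
    else:
        segments = _peak_segments(spec.intensities)
        out = np.zeros_like(spec.intensities)
        offset = 0.0
        prev_apex = None
        for a, b in segments:
            apex = grid[a + int(np.argmax(spec.intensities[a:b]))]
            ratio = 1.0
            if model.vertical_width > 0:
                va, vb = model.vertical_shape
                ratio = 1.0 + model.vertical_width * (2.0 * rng.beta(va, vb) - 1.0)
                ratio = max(ratio, 0.0)
            if model.horizontal_width > 0:
                ha, hb = model.horizontal_shape
                # spacing deviations accumulate from peak to peak; a gap in
                # the signal means there is no spacing to deviate from, so
                # the walk restarts at the next envelope
                if prev_apex is not None and apex - prev_apex > model.horizontal_reset_gap:
                    offset = 0.0
                offset += model.horizontal_width * (2.0 * rng.beta(ha, hb) - 1.0)
            prev_apex = apex
            seg_m = grid[a:b] + offset
            seg_y = spec.intensities[a:b] * ratio
            lo_idx = np.searchsorted(grid, seg_m[0]) - 1
            hi_idx = np.searchsorted(grid, seg_m[-1]) + 2
            lo_idx, hi_idx = max(lo_idx, 0), min(hi_idx, grid.size)
            out[lo_idx:hi_idx] += np.interp(grid[lo_idx:hi_idx], seg_m, seg_y, left=0.0, right=0.0)
    if model.basal_scale > 0:
        ba, bb = model.basal_shape
        phase = rng.uniform(0.0, 1.0)
        lattice = np.arange(grid[0] + phase, grid[-1], 1.0)
        heights = model.basal_scale * spec.intensities.max() * rng.beta(ba, bb, lattice.size)
        out += _render_sticks(grid, lattice, heights)
    return RawSpectrum(grid, out, spec.normalization_factor, spec.source_id)


@dataclass
class BenchmarkResult:
    """Aggregated performance over ``n_simulations`` noisy realizations."""

    detection_rate: np.ndarray
    abundance_r2: float | None
    pattern_accuracy: dict
    n_simulations: int
    joint_rate: float = float("nan")  # fraction of runs with every species recovered


def _spawn_seeds(seed: int, n: int) -> list[int]:
    ss = np.random.SeedSequence(seed)
    return [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(n)]


def _detect_on(spec: ModformSpec, model: NoiseModel, lo, hi, det_overrides) -> list:
    clean = build_theoretical_spectrum(spec, lo=lo, hi=hi)
    noisy = apply_noise(clean, model)
    return detect_mass_shifts(noisy, spec.protein, lo, hi, **det_overrides)


def run_overlap_ladder(
    protein: ProteinReference,
    separations,
    model: NoiseModel,
    n: int = 100,
    mass_tolerance_ppm: float = 20.0,
    seed: int | None = None,
    **det_overrides,
) -> dict[float, BenchmarkResult]:
    """Two equal-abundance species per spectrum, at each mean separation.

    A run counts as separated when each true mean is recovered by some
    detected mean within the ppm tolerance.  Returns one result per
    separation with per-species detection rates and the joint (separated)
    fraction.
    """
    base_seed = model.seed if seed is None else seed
    results: dict[float, BenchmarkResult] = {}
    for sep_i, sep in enumerate(separations):
        spec = ModformSpec.from_shifts(protein, [(0.0, 0.5), (float(sep), 0.5)])
        ref = protein.reference_mass
        truth = ref + spec.true_shifts()
        lo = truth.min() - 4 * protein.sigma - 12.0
        hi = truth.max() + 4 * protein.sigma + 12.0
        seeds = _spawn_seeds(base_seed + 7919 * sep_i, n)
        hits = np.zeros((n, truth.size), dtype=bool)
        for i in range(n):
            shifts = _detect_on(spec, model.with_seed(seeds[i]), lo, hi, det_overrides)
            means = np.array([s.mean for s in shifts])
            for j, t in enumerate(truth):
                tol = mass_tolerance_ppm * 1e-6 * t
                hits[i, j] = means.size > 0 and np.min(np.abs(means - t)) <= tol
        results[float(sep)] = BenchmarkResult(
            detection_rate=hits.mean(axis=0),
            abundance_r2=None,
            pattern_accuracy={},
            n_simulations=n,
            joint_rate=float(hits.all(axis=1).mean()),
        )
    return results


def _r_squared(true: np.ndarray, pred: np.ndarray) -> float:
    ss_res = float(np.sum((true - pred) ** 2))
    ss_tot = float(np.sum((true - true.mean()) ** 2))
    return 1.0 - ss_res / ss_tot if ss_tot > 0 else float("nan")


def run_pattern_benchmark(
    spec: ModformSpec,
    model: NoiseModel,
    n: int,
    table: PtmTable,
    inference: InferenceConfig,
    objectives=(("min_ptm", 1), ("min_both", 1)),
    seed: int | None = None,
    **det_overrides,
) -> BenchmarkResult:
    """Detection + inference benchmark on a known modform mixture.

    For every noisy realization the full pipeline runs; a species counts
    as detected when a mass shift lands within the inference tolerance of
    its true shift, and a pattern prediction as correct when the true
    count vector appears among the top-k solutions of the objective.
    ``pattern_accuracy`` maps ``"objective@k"`` to per-species fractions.
    """
    protein = spec.protein
    ref = protein.reference_mass
    truth = ref + spec.true_shifts()
    true_ab = spec.true_abundances()
    lo = truth.min() - 4 * protein.sigma - 12.0
    hi = truth.max() + 4 * protein.sigma + 12.0
    tol = inference.eps_max
    base_seed = model.seed if seed is None else seed
    seeds = _spawn_seeds(base_seed, n)

    n_species = len(spec.species)
    detected = np.zeros((n, n_species), dtype=bool)
    correct = {f"{obj}@k{k}": np.zeros((n, n_species), dtype=bool) for obj, k in objectives}
    r2s = []
    for i in range(n):
        shifts = _detect_on(spec, model.with_seed(seeds[i]), lo, hi, det_overrides)
        means = np.array([s.mean for s in shifts])
        rel = np.array([s.relative_abundance for s in shifts])
        matched_pred = np.full(n_species, np.nan)
        for j, t in enumerate(truth):
            if means.size == 0:
                continue
            d = np.abs(means - t)
            jm = int(np.argmin(d))
            if d[jm] <= tol:
                detected[i, j] = True
                matched_pred[j] = rel[jm]
                obs = means[jm] - ref
                for obj, k in objectives:
                    cfg = _dc_replace(inference, objective=obj, laps=k)
                    sols = enumerate_k_solutions(obs, table, cfg)
                    truth_counts = spec.species[j].counts
                    if truth_counts is not None and any(
                        s.counts == truth_counts for s in sols
                    ):
                        correct[f"{obj}@k{k}"][i, j] = True
        ok = ~np.isnan(matched_pred)
        if ok.sum() >= 2:
            r2s.append(_r_squared(true_ab[ok], matched_pred[ok]))
    return BenchmarkResult(
        detection_rate=detected.mean(axis=0),
        abundance_r2=float(np.mean(r2s)) if r2s else None,
        pattern_accuracy={k: v.mean(axis=0) for k, v in correct.items()},
        n_simulations=n,
        joint_rate=float(detected.all(axis=1).mean()),
    )


# ---------------------------------------------------------------------------
# stock benchmark fixtures (synthetic approximations of the study designs)

def phospho_ladder(protein: ProteinReference, table: PtmTable | None = None):
    """Phosphorylation ladder: the unmodified protein plus 0-6 phospho
    groups (mass shifts up to ~480 Da): a synthetic multi-phosphorylation
    benchmark mixture."""
    if table is None:
        table = PtmTable([PtmEntry("Ph", 79.9799, 6, {"H": 1, "P": 1, "O": 3})])
    abundances = [0.22, 0.18, 0.15, 0.13, 0.12, 0.11, 0.09]
    patterns = [({"Ph": k}, a) for k, a in enumerate(abundances)]
    return ModformSpec.from_patterns(protein, table, patterns), table


def complex_landscape_table() -> PtmTable:
    """Four PTM types used by the complex-landscape fixture."""
    from .ptm_inference import _composition_mass, _STOCK_COMPOSITIONS

    bounds = {"Ph": 6, "Ac": 3, "Ox": 3, "Cys": 4}
    return PtmTable(
        [
            PtmEntry(n, _composition_mass(_STOCK_COMPOSITIONS[n]), bounds[n],
                     dict(_STOCK_COMPOSITIONS[n]))
            for n in ("Ph", "Ac", "Ox", "Cys")
        ]
    )


def complex_landscape(protein: ProteinReference):
    """Synthetic complex modform landscape: 18 modified species built from
    four PTM types (Ph, Ac, Ox, Cys), spanning shifts of ~16-430 Da with
    pairwise separations above the resolvable limit: a synthetic stand-in
    for a complex endogenous modform landscape."""
    table = complex_landscape_table()
    patterns = [
        ({"Ox": 1}, 8),
        ({"Ac": 1}, 6),
        ({"Ph": 1}, 7),
        ({"Ph": 1, "Ox": 1}, 5),
        ({"Cys": 1}, 6),
        ({"Cys": 1, "Ox": 1}, 4),
        ({"Cys": 1, "Ac": 1, "Ox": 1}, 5),
        ({"Cys": 1, "Ph": 1}, 4),
        ({"Cys": 1, "Ph": 1, "Ox": 1}, 3),
        ({"Cys": 2}, 4),
        ({"Cys": 2, "Ox": 1}, 3),
        ({"Cys": 1, "Ph": 2}, 3),
        ({"Cys": 1, "Ph": 2, "Ox": 1}, 3),
        ({"Ph": 4}, 3),
        ({"Cys": 1, "Ph": 2, "Ac": 1, "Ox": 2}, 2),
        ({"Cys": 3, "Ox": 2}, 2),
        ({"Cys": 2, "Ph": 2, "Ox": 2}, 2),
        ({"Cys": 3, "Ph": 1, "Ox": 1}, 2),
    ]
    total = sum(a for _, a in patterns)
    patterns = [(c, a / total) for c, a in patterns]
    return ModformSpec.from_patterns(protein, table, patterns), table
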