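"""Sliding-window detection and quantification of mass shifts.

A window of fixed size slides across the centroided spectrum in 1 Da
steps.  Within each window a Gaussian with the protein's constant sigma is
fitted (only mean and amplitude are free), a chi-square goodness-of-fit
p-value is attached, poorly fitting and overlapping candidates are
discarded, and the survivors are converted into quantified mass shifts
relative to the unmodified protein's reference mass.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar
from scipy.stats import chi2

from .protein_reference import ProteinReference
from .spectrum_io import (
    CentroidPeakList,
    RawSpectrum,
    centroid_profile,
    estimate_noise_level,
    select_and_normalize,
)

__all__ = [
    "DetectionConfig",
    "GaussianFit",
    "MassShift",
    "fit_window_gaussian",
    "chi_square_goodness",
    "scan_spectrum",
    "resolve_overlaps",
    "refit_survivors",
    "quantify_and_shift",
    "detect_mass_shifts",
    "shifts_to_dataframe",
]

logger = logging.getLogger(__name__)

SQRT_2PI = math.sqrt(2.0 * math.pi)

#: points with a fitted expectation below this are excluded from chi-square
_EXPECTED_FLOOR = 1e-12


@dataclass
class DetectionConfig:
    """Tunables of the sliding-window scan.

    ``min_peak_distance`` (the allowed overlap between adjacent fitted
    means) defaults to two-thirds of the window size.  ``ddof_params`` is
    the number of fitted parameters subtracted from the chi-square degrees
    of freedom (mean and amplitude).

    ``count_scale`` restores the intensity scale of the chi-square test:
    single-ion spectra report ion counts, and the Pearson statistic is
    only calibrated on count-like data.  ``None`` (the default) means
    "use the window's normalization factor", i.e. test on the raw
    intensity scale; an explicit value rescales normalized intensities by
    that factor instead.
    """

    window_size: float
    step_size: float = 1.0
    min_peak_distance: float | None = None
    pvalue_threshold: float = 0.05
    noise_level: float = 0.0
    min_signal_peaks: int = 5
    ddof_params: int = 2
    edge_margin: float = 0.25
    count_scale: float | None = None
    refine_survivors: bool = True

    def __post_init__(self) -> None:
        if self.window_size <= 5.0:
            raise ValueError("window_size must be bigger than 5 Da")
        if self.step_size <= 0:
            raise ValueError("step_size must be positive")
        if self.min_peak_distance is None:
            self.min_peak_distance = (2.0 / 3.0) * self.window_size
        if not 0.0 < self.pvalue_threshold < 1.0:
            raise ValueError("pvalue_threshold must lie in (0, 1)")

    @classmethod
    def from_reference(cls, ref: ProteinReference, **overrides) -> "DetectionConfig":
        """Window sized to the upper third of the reference isotopic
        distribution (see :meth:`ProteinReference.default_window_size`)."""
        overrides.setdefault("window_size", ref.default_window_size())
        return cls(**overrides)


@dataclass
class GaussianFit:
    mean: float
    amplitude: float
    sigma: float
    chi_square: float
    pvalue: float
    window_start: float


@dataclass
class MassShift:
    shift: float
    mean: float
    abundance: float
    relative_abundance: float
    sample_id: str = ""
    pvalue: float = float("nan")


def chi_square_goodness(
    observed: np.ndarray, expected: np.ndarray, n_fitted: int = 2
) -> tuple[float, float]:
    """Pearson chi-square statistic and upper-tail p-value.

    ``statistic = sum((obs - exp)^2 / exp)``; degrees of freedom are
    ``n - n_fitted - 1``.  Points with (near-)zero expectation are excluded
    with a warning; fewer than 5 usable points is an error.  A high
    p-value indicates a good fit.
    """
    observed = np.asarray(observed, dtype=float)
    expected = np.asarray(expected, dtype=float)
    if observed.shape != expected.shape:
        raise ValueError("observed and expected must have the same length")
    usable = expected > _EXPECTED_FLOOR
    if not np.all(usable):
        logger.warning(
            "chi-square: excluding %d points with zero expectation",
            int((~usable).sum()),
        )
    obs, exp = observed[usable], expected[usable]
    if obs.size < 5:
        raise ValueError("need >= 5 usable points for the chi-square test")
    stat = float(np.sum((obs - exp) ** 2 / exp))
    dof = max(obs.size - n_fitted - 1, 1)
    return stat, float(chi2.sf(stat, dof))


def _profile_sse(mu: float, m: np.ndarray, y: np.ndarray, sigma: float) -> tuple[float, float]:
    """Least-squares objective profiled over the (non-negative) amplitude."""
    g = np.exp(-((m - mu) ** 2) / (2.0 * sigma**2))
    denom = float(g @ g)
    amp = max(float(y @ g) / denom, 0.0) if denom > 0 else 0.0
    resid = y - amp * g
    return float(resid @ resid), amp


def fit_window_gaussian(
    peaks: CentroidPeakList,
    window_start: float,
    sigma: float,
    config: DetectionConfig,
) -> GaussianFit | None:
    """Fit a constant-sigma Gaussian to the signal peaks of one window.

    Only the mean and amplitude are free; the mean is constrained inside
    the window and the amplitude is non-negative (solved in closed form
    given the mean, with a bounded search over the mean).  Returns ``None``
    when fewer than ``min_signal_peaks`` signal peaks lie in the window or
    the fit degenerates to zero amplitude.
    """
    window_end = window_start + config.window_size
    masses, intensities = peaks.signals()
    inside = (masses >= window_start) & (masses <= window_end)
    m, y = masses[inside], intensities[inside]
    if m.size < config.min_signal_peaks:
        return None

    # coarse grid over the window, then local refinement of the best mean
    grid = np.arange(window_start, window_end + 1e-9, 0.25)
    sse = np.array([_profile_sse(mu, m, y, sigma)[0] for mu in grid])
    best = int(np.argmin(sse))
    lo = grid[max(best - 1, 0)]
    hi = grid[min(best + 1, grid.size - 1)]
    res = minimize_scalar(
        lambda mu: _profile_sse(mu, m, y, sigma)[0],
        bounds=(lo, hi),
        method="bounded",
        options={"xatol": 1e-8},
    )
    mu = float(res.x)
    _, amp = _profile_sse(mu, m, y, sigma)
    if amp <= 0.0:
        logger.warning("window at %.1f Da: degenerate fit skipped", window_start)
        return None
    if (mu - window_start < config.edge_margin) or (window_end - mu < config.edge_margin):
        # the constrained optimum is pinned to the window boundary: the
        # window does not bracket an envelope apex; a neighbouring window
        # will capture this species with an interior optimum.
        return None
    expected = amp * np.exp(-((m - mu) ** 2) / (2.0 * sigma**2))
    kappa = config.count_scale if config.count_scale is not None else 1.0
    try:
        stat, pval = chi_square_goodness(
            kappa * y, kappa * expected, n_fitted=config.ddof_params
        )
    except ValueError:
        return None
    return GaussianFit(
        mean=mu,
        amplitude=amp,
        sigma=sigma,
        chi_square=stat,
        pvalue=pval,
        window_start=window_start,
    )


def resolve_overlaps(fits: list[GaussianFit], config: DetectionConfig) -> list[GaussianFit]:
    """Greedy best-first conflict resolution between overlapping fits.

    Candidates are taken in order of decreasing p-value (ties broken by
    larger amplitude, then lower mean); a candidate is accepted iff its
    mean is at least ``min_peak_distance`` from every accepted mean.  The
    result is independent of the input order.
    """
    ranked = sorted(fits, key=lambda f: (-f.pvalue, -f.amplitude, f.mean))
    accepted: list[GaussianFit] = []
    for cand in ranked:
        if all(abs(cand.mean - a.mean) >= config.min_peak_distance for a in accepted):
            accepted.append(cand)
    accepted.sort(key=lambda f: f.mean)
    return accepted


def refit_survivors(
    fits: list[GaussianFit],
    peaks: CentroidPeakList,
    sigma: float,
    config: DetectionConfig,
    span_sigmas: float = 3.0,
) -> list[GaussianFit]:
    """Joint constant-sigma multi-Gaussian refit of the surviving fits.

    A window fit of a partially overlapping envelope is biased by the
    neighbouring species' tail inside the window.  Once the sliding-window
    scan and overlap resolution have fixed *which* species are present,
    refitting all survivors together on the union of their signal peaks
    removes that bias.  The refinement never adds, removes or reorders
    components: each mean stays within half the allowed overlap of its
    window estimate, so nothing below the resolvable limit is split.
    """
    if len(fits) == 0:
        return fits
    masses, intensities = peaks.signals()
    means0 = np.array([f.mean for f in fits])
    amps0 = np.array([f.amplitude for f in fits])
    near = np.zeros(masses.size, dtype=bool)
    for mu in means0:
        near |= np.abs(masses - mu) <= span_sigmas * sigma
    m, y = masses[near], intensities[near]
    if m.size < 2 * len(fits) + 1:
        return fits
    k = len(fits)

    def model(x, *params):
        mus, amps = np.asarray(params[:k]), np.asarray(params[k:])
        return np.sum(
            amps[:, None] * np.exp(-((x[None, :] - mus[:, None]) ** 2) / (2 * sigma**2)),
            axis=0,
        )

    half = 0.5 * config.min_peak_distance
    lower = np.concatenate([means0 - half, np.zeros(k)])
    upper = np.concatenate([means0 + half, np.full(k, np.inf)])
    try:
        from scipy.optimize import curve_fit

        popt, _ = curve_fit(
            model, m, y, p0=np.concatenate([means0, amps0]),
            bounds=(lower, upper), maxfev=2000 * (k + 1),
        )
    except RuntimeError:
        logger.warning("joint refinement did not converge; keeping window fits")
        return fits
    refined = []
    for f, mu, amp in zip(fits, popt[:k], popt[k:]):
        refined.append(replace(f, mean=float(mu), amplitude=float(amp)))
    refined.sort(key=lambda f: f.mean)
    return refined


def scan_spectrum(
    peaks: CentroidPeakList,
    ref: ProteinReference,
    config: DetectionConfig,
    lo: float | None = None,
    hi: float | None = None,
) -> list[GaussianFit]:
    """Slide the window across the spectrum and return surviving fits.

    One candidate fit is attempted per window position (default step
    1 Da); candidates with a p-value below the significance level are
    removed, and overlaps are resolved best-p-value-first.
    """
    if len(peaks) == 0:
        return []
    if lo is None:
        lo = float(peaks.peak_masses.min())
    if hi is None:
        hi = float(peaks.peak_masses.max())
    candidates: list[GaussianFit] = []
    start = lo
    while start + config.window_size <= hi + 1e-9:
        fit = fit_window_gaussian(peaks, start, ref.sigma, config)
        if fit is not None and fit.pvalue >= config.pvalue_threshold:
            candidates.append(fit)
        start += config.step_size
    return resolve_overlaps(candidates, config)


def quantify_and_shift(
    fits: list[GaussianFit],
    ref: ProteinReference,
    normalization_factor: float = 1.0,
    sample_id: str = "",
) -> list[MassShift]:
    """Convert surviving fits into quantified mass shifts.

    Abundance is the area under the fitted Gaussian,
    ``amplitude * sigma * sqrt(2*pi)``, rescaled to raw units with the
    normalization factor; relative abundances are fractions of the total
    detected abundance in the sample.
    """
    if not fits:
        return []
    areas = np.array([f.amplitude * f.sigma * SQRT_2PI * normalization_factor for f in fits])
    total = areas.sum()
    return [
        MassShift(
            shift=f.mean - ref.reference_mass,
            mean=f.mean,
            abundance=float(a),
            relative_abundance=float(a / total),
            sample_id=sample_id,
            pvalue=f.pvalue,
        )
        for f, a in zip(fits, areas)
    ]


def detect_mass_shifts(
    spectrum: RawSpectrum,
    ref: ProteinReference,
    lo: float,
    hi: float,
    config: DetectionConfig | None = None,
    **config_overrides,
) -> list[MassShift]:
    """End-to-end detection for one sample.

    Normalizes the selected mass range, centroids, estimates the noise
    level, scans with constant-sigma Gaussian windows, and quantifies the
    surviving fits.
    """
    windowed = select_and_normalize(spectrum, lo, hi)
    peaks = centroid_profile(windowed)
    noise = estimate_noise_level(windowed)
    if config is None:
        config = DetectionConfig.from_reference(ref, noise_level=noise, **config_overrides)
    else:
        config = replace(config, noise_level=noise)
    if config.count_scale is None:
        # intensities of single-ion spectra are ion counts; the chi-square
        # test runs on the raw (count) scale of the selected window
        config = replace(config, count_scale=windowed.normalization_factor)
    peaks.noise_level = config.noise_level
    fits = scan_spectrum(peaks, ref, config, lo=lo, hi=hi)
    if config.refine_survivors:
        fits = refit_survivors(fits, peaks, ref.sigma, config)
    logger.info(
        "sample %s: %d peaks, %d signals, %d surviving fits",
        spectrum.source_id,
        len(peaks),
        int((peaks.peak_intensities > peaks.noise_level).sum()),
        len(fits),
    )
    return quantify_and_shift(
        fits, ref, normalization_factor=windowed.normalization_factor,
        sample_id=spectrum.source_id,
    )


def shifts_to_dataframe(shifts: list[MassShift]) -> pd.DataFrame:
    """Detected shifts as a table: sample, mean, shift, p-value, abundances."""
    return pd.DataFrame(
        [
            {
                "sample_id": s.sample_id,
                "mean_da": s.mean,
                "shift_da": s.shift,
                "pvalue": s.pvalue,
                "abundance": s.abundance,
                "relative_abundance": s.relative_abundance,
            }
            for s in shifts
        ],
        columns=[
            "sample_id",
            "mean_da",
            "shift_da",
            "pvalue",
            "abundance",
            "relative_abundance",
        ],
    )
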