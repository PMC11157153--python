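"""Reference model of the unmodified protein.

From the amino-acid sequence we derive the elemental composition, the
aggregated (1 Da-spaced) isotopic distribution, and — by fitting a single
Gaussian to that distribution — the constant envelope width sigma and the
reference mass.  The same sigma is reused unchanged for every modified
species during mass-shift detection: adding a few PTM atoms to a protein
of tens of kDa changes the envelope width by a negligible amount.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from Bio import SeqIO
from pyteomics import mass as _pmass
from scipy.optimize import curve_fit

__all__ = [
    "IsotopicDistribution",
    "ProteinReference",
    "parse_fasta",
    "elemental_composition",
    "isotopic_distribution",
    "fit_reference_sigma",
    "build_reference",
    "average_mass",
    "upper_third_window",
]

_AMINO_ACIDS = set("ACDEFGHIKLMNPQRSTVWY")


@dataclass
class IsotopicDistribution:
    """Aggregated isotopologue distribution: ~1 Da-spaced peaks.

    Fine structure is binned by neutron count; each bin's mass is the
    abundance-weighted centroid of its isotopologues.  Abundances sum to 1.
    """

    masses: np.ndarray
    abundances: np.ndarray

    def __post_init__(self) -> None:
        self.masses = np.asarray(self.masses, dtype=float)
        self.abundances = np.asarray(self.abundances, dtype=float)

    def __len__(self) -> int:
        return self.masses.size

    def mean(self) -> float:
        return float(np.dot(self.masses, self.abundances))

    def write_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("# mass_da\tabundance\n")
            for m, a in zip(self.masses, self.abundances):
                fh.write(f"{m:.6f}\t{a:.8g}\n")


@dataclass
class ProteinReference:
    """Everything detection needs to know about the unmodified protein."""

    sequence: str
    composition: dict
    isotopic_distribution: IsotopicDistribution
    sigma: float
    reference_mass: float
    average_mass: float

    def default_window_size(self, floor: float = 6.0) -> float:
        """Default sliding-window size: the mass width of the upper third
        of the isotopic distribution (peaks with abundance >= 2/3 of the
        apex), floored so the window always spans > 5 peaks."""
        return upper_third_window(self.isotopic_distribution, floor=floor)


def parse_fasta(path) -> str:
    """Return the first record's sequence, uppercased, whitespace stripped.

    Extra records trigger a warning; non-amino-acid letters are rejected
    with their position.
    """
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ValueError(f"no FASTA record in {path}")
    if len(records) > 1:
        warnings.warn(
            f"{path} contains {len(records)} records; using the first "
            f"({records[0].id})",
            stacklevel=2,
        )
    seq = "".join(str(records[0].seq).split()).upper()
    return _validate_sequence(seq)


def _validate_sequence(seq: str) -> str:
    for i, ch in enumerate(seq):
        if ch not in _AMINO_ACIDS:
            raise ValueError(f"non-amino-acid character {ch!r} at position {i}")
    return seq


def elemental_composition(sequence: str) -> dict:
    """Elemental composition of the intact chain: residue formulas plus one
    water for the termini.  The empty chain maps to plain water."""
    _validate_sequence(sequence)
    if not sequence:
        return {"H": 2, "O": 1}  # bare termini: one water
    comp = _pmass.Composition(sequence=sequence)
    return dict(comp)


def average_mass(composition: dict) -> float:
    """Abundance-weighted (average) mass of a composition in Da."""
    return float(_pmass.calculate_mass(composition=_pmass.Composition(composition), average=True))


def monoisotopic_mass(composition: dict) -> float:
    return float(_pmass.calculate_mass(composition=_pmass.Composition(composition)))


def _element_isotopes(element: str) -> list[tuple[int, float, float]]:
    """(mass number, mass, abundance) for naturally occurring isotopes."""
    try:
        data = _pmass.nist_mass[element]
    except KeyError:
        raise ValueError(f"no isotope data for element {element!r}") from None
    iso = [(k, m, ab) for k, (m, ab) in data.items() if k != 0 and ab > 0]
    if not iso:
        raise ValueError(f"no isotope abundance data for element {element!r}")
    iso.sort()
    return iso


def _atom_arrays(element: str) -> tuple[np.ndarray, np.ndarray]:
    """Per-atom probability and mass-moment arrays indexed by neutron offset."""
    iso = _element_isotopes(element)
    base = iso[0][0]
    size = iso[-1][0] - base + 1
    p = np.zeros(size)
    m1 = np.zeros(size)
    for k, m, ab in iso:
        p[k - base] = ab
        m1[k - base] = ab * m
    return p, m1


def _conv_pair(pa, ma, pb, mb, tail: float = 1e-16):
    """Convolve two (probability, first-moment) pairs of independent
    neutron-count distributions, truncating the negligible tail."""
    p = np.convolve(pa, pb)
    m1 = np.convolve(ma, pb) + np.convolve(pa, mb)
    keep = np.flatnonzero(p > p.max() * tail)
    hi = keep[-1] + 1
    return p[:hi], m1[:hi]


def _element_power(element: str, count: int):
    """Distribution of ``count`` i.i.d. atoms, by squaring."""
    p_atom, m_atom = _atom_arrays(element)
    result = None
    base_p, base_m = p_atom, m_atom
    k = count
    while k:
        if k & 1:
            if result is None:
                result = (base_p.copy(), base_m.copy())
            else:
                result = _conv_pair(*result, base_p, base_m)
        k >>= 1
        if k:
            base_p, base_m = _conv_pair(base_p, base_m, base_p, base_m)
    return result


def isotopic_distribution(composition: dict, min_abundance: float = 1e-5) -> IsotopicDistribution:
    """Aggregated isotopic distribution of a composition.

    Isotopologues are binned by total neutron count, giving ~1 Da-spaced
    peaks whose masses are per-bin abundance centroids.  Peaks below
    ``min_abundance`` are pruned and the rest renormalized.
    """
    items = [(el, n) for el, n in composition.items() if n]
    if not items:
        raise ValueError("empty composition")
    if any(n < 0 for _, n in items):
        raise ValueError("negative element counts are not supported here")
    total = None
    for el, n in items:
        part = _element_power(el, int(n))
        total = part if total is None else _conv_pair(*total, *part)
    p, m1 = total
    mask = p > 0
    masses = np.where(mask, m1 / np.where(mask, p, 1.0), 0.0)
    keep = (p >= min_abundance) & mask
    if not np.any(keep):
        raise ValueError("min_abundance prunes the whole distribution")
    masses = masses[keep]
    abundances = p[keep] / p[keep].sum()
    order = np.argsort(masses)
    return IsotopicDistribution(masses[order], abundances[order])


def _gaussian(x, mean, sigma, amplitude):
    return amplitude * np.exp(-((x - mean) ** 2) / (2.0 * sigma**2))


def fit_reference_sigma(dist: IsotopicDistribution) -> tuple[float, float]:
    """Least-squares Gaussian fit to the (mass, abundance) points.

    Returns ``(sigma, reference_mass)``.  Initialization: mean at the apex
    mass, amplitude at the apex abundance, sigma at FWHM/2.355 of the
    discrete distribution.
    """
    if len(dist) < 5:
        raise ValueError("need >= 5 isotopologue peaks to fit a Gaussian")
    x, y = dist.masses, dist.abundances
    apex = int(np.argmax(y))
    half = y[apex] / 2.0
    above = np.flatnonzero(y >= half)
    fwhm = max(x[above[-1]] - x[above[0]], 1.0)
    p0 = (x[apex], fwhm / 2.355, y[apex])
    try:
        popt, _ = curve_fit(_gaussian, x, y, p0=p0, maxfev=10000)
    except RuntimeError as exc:
        resid = float(np.linalg.norm(y - _gaussian(x, *p0)))
        raise RuntimeError(
            f"Gaussian fit did not converge (initial residual norm {resid:.3g})"
        ) from exc
    mean, sigma, _amp = popt
    return abs(float(sigma)), float(mean)


def upper_third_window(dist: IsotopicDistribution, floor: float = 6.0) -> float:
    """Mass width of the peaks with abundance >= 2/3 of the apex."""
    thresh = dist.abundances.max() * (2.0 / 3.0)
    idx = np.flatnonzero(dist.abundances >= thresh)
    width = float(dist.masses[idx[-1]] - dist.masses[idx[0]])
    return max(width, floor)


def build_reference(sequence_or_fasta, min_abundance: float = 1e-5) -> ProteinReference:
    """Build a :class:`ProteinReference` from a sequence string or a FASTA path."""
    seq = str(sequence_or_fasta)
    looks_like_path = (
        not seq
        or not set(seq) <= _AMINO_ACIDS
        or (len(seq) < 256 and Path(seq).exists())
    )
    if looks_like_path:
        seq = parse_fasta(sequence_or_fasta)
    comp = elemental_composition(seq)
    dist = isotopic_distribution(comp, min_abundance=min_abundance)
    sigma, ref_mass = fit_reference_sigma(dist)
    return ProteinReference(
        sequence=seq,
        composition=comp,
        isotopic_distribution=dist,
        sigma=sigma,
        reference_mass=ref_mass,
        average_mass=average_mass(comp),
    )
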