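"""Reading, windowing, normalization and centroiding of true mass spectra.

The spectra handled here are *true* (charge-free) intact-protein mass
spectra: the x axis is mass in Dalton, not m/z, so no charge-state
deconvolution is performed anywhere in this package.  Two on-disk formats
are supported: profile-mode mzML (read and written with a compact built-in
codec for the standard binary encodings) and a plain two-column
TSV dialect (``mass<TAB>intensity``, ``#`` comments) that is convenient
for tests and quick inspection.
"""

from __future__ import annotations

import base64
import struct
import xml.etree.ElementTree as ET
from dataclasses import dataclass
from pathlib import Path

import numpy as np

__all__ = [
    "RawSpectrum",
    "CentroidPeakList",
    "load_spectrum",
    "select_and_normalize",
    "centroid_profile",
    "estimate_noise_level",
    "write_tsv",
    "write_mzml_profile",
]


@dataclass
class RawSpectrum:
    """A profile spectrum over a mass axis in Dalton.

    ``normalization_factor`` is 1.0 for raw data; after
    :func:`select_and_normalize` it stores the original maximum intensity
    so intensities can be rescaled back to raw units after the analysis.
    """

    masses: np.ndarray
    intensities: np.ndarray
    normalization_factor: float = 1.0
    source_id: str = ""

    def __post_init__(self) -> None:
        self.masses = np.asarray(self.masses, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.masses.ndim != 1 or self.masses.shape != self.intensities.shape:
            raise ValueError("masses and intensities must be 1-D arrays of equal length")
        if np.any(self.intensities < 0):
            raise ValueError("intensities must be non-negative")

    def __len__(self) -> int:
        return self.masses.size

    def copy(self) -> "RawSpectrum":
        return RawSpectrum(
            self.masses.copy(),
            self.intensities.copy(),
            self.normalization_factor,
            self.source_id,
        )


@dataclass
class CentroidPeakList:
    """Local-maximum peaks of a profile spectrum.

    ``noise_level`` is 0 until :func:`estimate_noise_level` has been run on
    the parent profile; peaks with intensity strictly above the noise level
    are treated as signals downstream.
    """

    peak_masses: np.ndarray
    peak_intensities: np.ndarray
    noise_level: float = 0.0
    source_id: str = ""

    def __post_init__(self) -> None:
        self.peak_masses = np.asarray(self.peak_masses, dtype=float)
        self.peak_intensities = np.asarray(self.peak_intensities, dtype=float)

    def __len__(self) -> int:
        return self.peak_masses.size

    def signals(self) -> tuple[np.ndarray, np.ndarray]:
        """Peaks strictly above the noise level."""
        keep = self.peak_intensities > self.noise_level
        return self.peak_masses[keep], self.peak_intensities[keep]


def _validate_points(masses: np.ndarray, intensities: np.ndarray, path) -> None:
    if masses.size == 0:
        raise ValueError(f"no data points in {path}")
    bad = np.flatnonzero(~(np.isfinite(masses) & np.isfinite(intensities)))
    if bad.size:
        raise ValueError(f"non-finite value at data point index {bad[0]} in {path}")


def _load_tsv(path: Path) -> tuple[np.ndarray, np.ndarray]:
    masses, intensities = [], []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t") if "\t" in line else line.split()
            if len(parts) < 2:
                raise ValueError(f"{path}:{lineno}: expected two columns")
            try:
                masses.append(float(parts[0]))
                intensities.append(float(parts[1]))
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-numeric value") from exc
    return np.asarray(masses), np.asarray(intensities)


def _local(tag: str) -> str:
    return tag.rsplit("}", 1)[-1]


def _decode_binary_array(ba_elem) -> tuple[str | None, np.ndarray | None]:
    """Decode one mzML <binaryDataArray>: returns (kind, values) where kind
    is 'mz' or 'intensity'.  Supports 32/64-bit floats, raw or zlib."""
    import zlib

    dtype = np.float64
    compressed = False
    kind = None
    payload = ""
    for child in ba_elem:
        name = _local(child.tag)
        if name == "cvParam":
            acc = child.get("accession", "")
            if acc == "MS:1000521":
                dtype = np.float32
            elif acc == "MS:1000523":
                dtype = np.float64
            elif acc == "MS:1000574":
                compressed = True
            elif acc == "MS:1000514":
                kind = "mz"
            elif acc == "MS:1000515":
                kind = "intensity"
        elif name == "binary":
            payload = child.text or ""
    if kind is None:
        return None, None
    raw = base64.b64decode(payload)
    if compressed:
        raw = zlib.decompress(raw)
    return kind, np.frombuffer(raw, dtype=dtype).astype(np.float64)


def _load_mzml(path: Path) -> tuple[np.ndarray, np.ndarray]:
    """Minimal profile-mzML reader (mass and intensity arrays of the first
    non-empty spectrum); handles the standard binary encodings."""
    for _event, elem in ET.iterparse(str(path), events=("end",)):
        if _local(elem.tag) != "spectrum":
            continue
        arrays: dict[str, np.ndarray] = {}
        for ba in elem.iter():
            if _local(ba.tag) == "binaryDataArray":
                kind, values = _decode_binary_array(ba)
                if kind is not None and values is not None:
                    arrays[kind] = values
        if "mz" in arrays and "intensity" in arrays and arrays["mz"].size:
            return arrays["mz"], arrays["intensity"]
        elem.clear()
    raise ValueError(f"no data points in {path}")


def load_spectrum(path, fmt: str | None = None, source_id: str | None = None) -> RawSpectrum:
    """Load a profile spectrum from disk.

    Parameters
    ----------
    path : str or Path
        File to read.
    fmt : {"mzml_profile", "tsv"}, optional
        Inferred from the file extension when omitted.
    source_id : str, optional
        Sample label; defaults to the file stem.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"spectrum file not found: {path}")
    if fmt is None:
        fmt = "mzml_profile" if path.suffix.lower() == ".mzml" else "tsv"
    if fmt == "mzml_profile":
        masses, intensities = _load_mzml(path)
    elif fmt == "tsv":
        masses, intensities = _load_tsv(path)
    else:
        raise ValueError(f"unknown spectrum format: {fmt!r}")
    _validate_points(masses, intensities, path)
    order = np.argsort(masses, kind="stable")
    return RawSpectrum(
        masses[order],
        intensities[order],
        normalization_factor=1.0,
        source_id=source_id if source_id is not None else path.stem,
    )


def select_and_normalize(spec: RawSpectrum, lo: float, hi: float) -> RawSpectrum:
    """Restrict to ``lo <= mass <= hi`` and normalize by the window maximum.

    The original maximum is kept in ``normalization_factor`` so intensities
    can be rescaled to raw units after the analysis.
    """
    if not lo < hi:
        raise ValueError(f"invalid mass range: [{lo}, {hi}]")
    keep = (spec.masses >= lo) & (spec.masses <= hi)
    masses = spec.masses[keep]
    intensities = spec.intensities[keep]
    if masses.size == 0 or not np.any(intensities > 0):
        raise ValueError(f"no signal in mass range [{lo}, {hi}] Da")
    factor = float(intensities.max())
    return RawSpectrum(
        masses,
        intensities / factor,
        normalization_factor=factor * spec.normalization_factor,
        source_id=spec.source_id,
    )


def centroid_profile(spec: RawSpectrum) -> CentroidPeakList:
    """Keep only the apex of each profile peak (strict local maxima).

    A plateau (a run of equal values strictly above both neighbours)
    contributes a single centroid at its midpoint mass.  Boundary points
    are never peaks.
    """
    n = len(spec)
    if n < 3:
        raise ValueError("profile too short to centroid (need >= 3 points)")
    y = spec.intensities
    # run-length encode equal-value plateaus
    change = np.flatnonzero(np.diff(y) != 0)
    starts = np.concatenate(([0], change + 1))
    ends = np.concatenate((change, [n - 1]))  # inclusive
    peak_masses, peak_intensities = [], []
    for s, e in zip(starts, ends):
        if s == 0 or e == n - 1:
            continue  # touches a boundary: no neighbour on one side
        if y[s] > y[s - 1] and y[e] > y[e + 1]:
            peak_masses.append(0.5 * (spec.masses[s] + spec.masses[e]))
            peak_intensities.append(y[s])
    return CentroidPeakList(
        np.asarray(peak_masses),
        np.asarray(peak_intensities),
        noise_level=0.0,
        source_id=spec.source_id,
    )


def estimate_noise_level(spec: RawSpectrum, ddof: int = 0) -> float:
    """Signal/noise threshold: half the standard deviation of all profile
    intensities in the analysis mass range.

    Uses the population standard deviation by default (``ddof=0``): the
    window's intensities are treated as the full population.
    """
    if len(spec) < 2:
        raise ValueError("cannot estimate dispersion from a single point")
    return 0.5 * float(np.std(spec.intensities, ddof=ddof))


def write_tsv(spec: RawSpectrum, path) -> None:
    header = f"# source_id={spec.source_id} normalization_factor={spec.normalization_factor!r}\n"
    with open(path, "w") as fh:
        fh.write(header)
        for m, i in zip(spec.masses, spec.intensities):
            fh.write(f"{m:.6f}\t{i:.8g}\n")


def _b64_doubles(values: np.ndarray) -> str:
    raw = struct.pack(f"<{values.size}d", *values)
    return base64.b64encode(raw).decode("ascii")


def write_mzml_profile(spec: RawSpectrum, path) -> None:
    """Write a minimal profile-mode mzML file (64-bit floats, uncompressed).

    Only the elements needed for round-tripping through standard readers
    are emitted; the mass axis is stored in the m/z array slot, as true
    mass spectra conventionally are.
    """
    n = len(spec)
    mz_b64 = _b64_doubles(spec.masses)
    it_b64 = _b64_doubles(spec.intensities)

    def cv(parent, accession, name, value=""):
        ET.SubElement(
            parent, "cvParam",
            {"cvRef": "MS", "accession": accession, "name": name, "value": str(value)},
        )

    root = ET.Element("mzML", {"xmlns": "http://psi.hupo.org/ms/mzml", "version": "1.1.0"})
    run = ET.SubElement(root, "run", {"id": spec.source_id or "run1"})
    slist = ET.SubElement(run, "spectrumList", {"count": "1"})
    spectrum = ET.SubElement(
        slist, "spectrum", {"index": "0", "id": "scan=1", "defaultArrayLength": str(n)}
    )
    cv(spectrum, "MS:1000128", "profile spectrum")
    cv(spectrum, "MS:1000511", "ms level", 1)
    balist = ET.SubElement(spectrum, "binaryDataArrayList", {"count": "2"})
    for accession, name, payload in (
        ("MS:1000514", "m/z array", mz_b64),
        ("MS:1000515", "intensity array", it_b64),
    ):
        ba = ET.SubElement(balist, "binaryDataArray", {"encodedLength": str(len(payload))})
        cv(ba, "MS:1000523", "64-bit float")
        cv(ba, "MS:1000576", "no compression")
        cv(ba, accession, name)
        ET.SubElement(ba, "binary").text = payload
    ET.ElementTree(root).write(path, xml_declaration=True, encoding="utf-8")
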