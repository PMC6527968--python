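"""Raman spectrum containers and delimited-text I/O.

A spectrum is a pair of equal-length arrays: a strictly increasing Raman-shift
axis in cm^-1 and the detector counts per channel.  Files are plain two-column
delimited text (comma, tab or whitespace separated), ``#`` starts a comment.
A :class:`SpectrumSet` holds acquisition replicates that share one shift axis,
e.g. the points of a 5 x 5 raster map.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

__all__ = [
    "SpectrumError",
    "RamanSpectrum",
    "SpectrumSet",
    "read_spectrum",
    "write_spectrum",
    "read_spectrum_set",
    "write_spectrum_set",
    "resample_to_axis",
]

#: default excitation wavelength in nm (deep-UV NeCu laser line)
DEFAULT_EXCITATION_NM = 248.6


class SpectrumError(ValueError):
    """Raised for malformed spectral data or files."""


@dataclass
class RamanSpectrum:
    """A calibrated Raman spectrum.

    Parameters
    ----------
    shift : ndarray
        Raman shift axis in cm^-1, strictly increasing, length >= 2.
    intensity : ndarray
        Detector counts per channel; same length as ``shift``; finite.
    meta : dict
        Free-form acquisition metadata.  Recognised keys: ``label``,
        ``excitation_nm`` (default 248.6), ``laser_correction`` (dimensionless,
        default 1.0), plus whatever processing stages record.
    """

    shift: np.ndarray
    intensity: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.shift = np.asarray(self.shift, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.shift.ndim != 1 or self.intensity.ndim != 1:
            raise SpectrumError("shift and intensity must be 1-D arrays")
        if len(self.shift) != len(self.intensity):
            raise SpectrumError(
                f"length mismatch: {len(self.shift)} shifts vs "
                f"{len(self.intensity)} intensities"
            )
        if len(self.shift) < 2:
            raise SpectrumError("insufficient data: need at least 2 channels")
        d = np.diff(self.shift)
        if np.any(d == 0):
            raise SpectrumError("duplicate channel in shift axis")
        if np.any(d < 0):
            raise SpectrumError("shift axis must be strictly increasing")
        if not np.all(np.isfinite(self.shift)):
            raise SpectrumError("non-finite value in shift axis")
        if not np.all(np.isfinite(self.intensity)):
            raise SpectrumError("non-finite intensity value")
        self.meta.setdefault("excitation_nm", DEFAULT_EXCITATION_NM)
        self.meta.setdefault("laser_correction", 1.0)

    # -- conveniences -------------------------------------------------
    @property
    def n_channels(self) -> int:
        return len(self.shift)

    @property
    def label(self) -> str:
        return str(self.meta.get("label", ""))

    def channel_spacing(self) -> float:
        """Median channel spacing in cm^-1."""
        return float(np.median(np.diff(self.shift)))

    def copy(self, intensity: np.ndarray | None = None, shift: np.ndarray | None = None,
             **meta_updates) -> "RamanSpectrum":
        """Return a copy, optionally with replaced arrays / extra metadata."""
        meta = dict(self.meta)
        meta.update(meta_updates)
        return RamanSpectrum(
            shift=np.array(self.shift if shift is None else shift, dtype=float),
            intensity=np.array(self.intensity if intensity is None else intensity,
                               dtype=float),
            meta=meta,
        )

    def window_mask(self, lo: float, hi: float) -> np.ndarray:
        return (self.shift >= lo) & (self.shift <= hi)

    def integral(self, lo: float | None = None, hi: float | None = None) -> float:
        """Trapezoidal integral of the intensity, optionally over [lo, hi]."""
        if lo is None and hi is None:
            return float(np.trapezoid(self.intensity, self.shift))
        lo = self.shift[0] if lo is None else lo
        hi = self.shift[-1] if hi is None else hi
        m = self.window_mask(lo, hi)
        if m.sum() < 2:
            raise SpectrumError(f"window [{lo}, {hi}] covers <2 channels")
        return float(np.trapezoid(self.intensity[m], self.shift[m]))


@dataclass
class SpectrumSet:
    """Ordered replicate spectra sharing one shift axis."""

    replicates: list

    def __post_init__(self) -> None:
        if not self.replicates:
            raise SpectrumError("SpectrumSet must be non-empty")
        axis = self.replicates[0].shift
        for i, rep in enumerate(self.replicates):
            if rep.n_channels != len(axis) or not np.array_equal(rep.shift, axis):
                raise SpectrumError(f"axis mismatch: replicate {i} differs from replicate 0")

    @property
    def axis(self) -> np.ndarray:
        return self.replicates[0].shift

    @property
    def n_replicates(self) -> int:
        return len(self.replicates)

    def to_matrix(self) -> np.ndarray:
        """Stack intensities as an (n_replicates, n_channels) array."""
        return np.vstack([r.intensity for r in self.replicates])

    @classmethod
    def from_matrix(cls, axis: np.ndarray, matrix: np.ndarray,
                    meta: dict | None = None) -> "SpectrumSet":
        matrix = np.atleast_2d(np.asarray(matrix, dtype=float))
        reps = [
            RamanSpectrum(np.array(axis, dtype=float), row,
                          dict(meta or {}, replicate=i))
            for i, row in enumerate(matrix)
        ]
        return cls(reps)

    def with_matrix(self, matrix: np.ndarray) -> "SpectrumSet":
        """New set with the same axis/metadata but replaced intensities."""
        matrix = np.asarray(matrix, dtype=float)
        reps = [r.copy(intensity=row) for r, row in zip(self.replicates, matrix)]
        return SpectrumSet(reps)

    def with_axis(self, axis: np.ndarray) -> "SpectrumSet":
        reps = [r.copy(shift=axis) for r in self.replicates]
        return SpectrumSet(reps)


# ---------------------------------------------------------------------------
# file I/O
# ---------------------------------------------------------------------------

_DELIMS = (",", "\t", None)  # None = any whitespace


def _split_row(line: str, delimiter: str | None):
    if delimiter is None:
        # auto-detect per row: comma, then tab, then whitespace
        if "," in line:
            return [t.strip() for t in line.split(",")]
        if "\t" in line:
            return [t.strip() for t in line.split("\t")]
        return line.split()
    return [t.strip() for t in line.split(delimiter)]


def _parse_rows(text: str, path, delimiter: str | None):
    """Parse numeric rows; returns (array of rows, meta dict from # comments)."""
    rows = []
    meta: dict = {}
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if not line:
            continue
        if line.startswith("#"):
            m = re.match(r"#\s*(\w+)\s*[:=]\s*(.*)$", line)
            if m:
                key, val = m.group(1), m.group(2).strip()
                try:
                    meta[key] = float(val)
                except ValueError:
                    meta[key] = val
            continue
        tokens = _split_row(line, delimiter)
        if len(tokens) < 2:
            raise SpectrumError(f"{path}: line {lineno}: expected >=2 columns")
        try:
            rows.append([float(t) for t in tokens if t != ""])
        except ValueError:
            # a header row of column names is tolerated on the first data line
            if not rows and lineno <= 2:
                continue
            raise SpectrumError(
                f"{path}: parse error at line {lineno}: {line!r}"
            ) from None
    if len(rows) < 2:
        raise SpectrumError(f"{path}: insufficient data (<2 points)")
    width = min(len(r) for r in rows)
    return np.array([r[:width] for r in rows], dtype=float), meta


def read_spectrum(path, delimiter: str | None = None) -> RamanSpectrum:
    """Read a two-column (shift cm^-1, intensity) delimited-text spectrum.

    Rows are sorted ascending by shift; ``#`` comment lines are skipped, and
    ``# key: value`` comments populate the metadata.  The delimiter is
    auto-detected among comma / tab / whitespace unless given explicitly.
    """
    path = Path(path)
    data, meta = _parse_rows(path.read_text(), path, delimiter)
    order = np.argsort(data[:, 0], kind="stable")
    data = data[order]
    if np.any(np.diff(data[:, 0]) == 0):
        raise SpectrumError(f"{path}: duplicate channel in shift column")
    meta.setdefault("label", path.stem)
    return RamanSpectrum(shift=data[:, 0], intensity=data[:, 1], meta=meta)


def write_spectrum(spectrum: RamanSpectrum, path, delimiter: str = ",") -> None:
    """Write a spectrum as two-column delimited text with metadata comments.

    Round trip: :func:`read_spectrum` on the written file reproduces shift and
    intensity to full stored precision (``%.17g``) and the ``label`` metadata.
    """
    path = Path(path)
    lines = [f"# label: {spectrum.label}" if spectrum.label else "# label: spectrum"]
    for key in ("excitation_nm", "laser_correction"):
        lines.append(f"# {key}: {spectrum.meta[key]:.17g}")
    for s, y in zip(spectrum.shift, spectrum.intensity):
        lines.append(f"{s:.17g}{delimiter}{y:.17g}")
    path.write_text("\n".join(lines) + "\n")


def read_spectrum_set(source, delimiter: str | None = None) -> SpectrumSet:
    """Read replicates from a directory of per-point files or one multi-column file.

    Directory: every ``*.csv``/``*.tsv``/``*.txt``/``*.dat`` file is one
    replicate (sorted by name).  Single file: column 1 is the shared shift
    axis, columns 2..n the replicates.
    """
    source = Path(source)
    if source.is_dir():
        files = sorted(
            p for p in source.iterdir()
            if p.suffix.lower() in {".csv", ".tsv", ".txt", ".dat"}
        )
        if not files:
            raise SpectrumError(f"{source}: no spectrum files found")
        return SpectrumSet([read_spectrum(p, delimiter) for p in files])
    data, meta = _parse_rows(source.read_text(), source, delimiter)
    order = np.argsort(data[:, 0], kind="stable")
    data = data[order]
    if data.shape[1] < 2:
        raise SpectrumError(f"{source}: need >=2 columns")
    meta.setdefault("label", source.stem)
    return SpectrumSet.from_matrix(data[:, 0], data[:, 1:].T, meta)


def write_spectrum_set(spectrum_set: SpectrumSet, path, delimiter: str = ",") -> None:
    """Write a replicate set as one multi-column delimited-text file."""
    path = Path(path)
    mat = spectrum_set.to_matrix()
    lines = [f"# label: {spectrum_set.replicates[0].label or 'set'}"]
    for s, col in zip(spectrum_set.axis, mat.T):
        lines.append(delimiter.join([f"{s:.17g}"] + [f"{v:.17g}" for v in col]))
    path.write_text("\n".join(lines) + "\n")


def resample_to_axis(spectrum: RamanSpectrum, axis: Sequence[float]) -> RamanSpectrum:
    """Linearly interpolate a spectrum onto a target shift grid.

    Target channels outside the source support are dropped, never
    extrapolated.  Exact for affine intensity functions; the identity when the
    target equals the source axis.
    """
    axis = np.asarray(axis, dtype=float)
    inside = (axis >= spectrum.shift[0]) & (axis <= spectrum.shift[-1])
    if inside.sum() < 2:
        raise SpectrumError("disjoint axes: target grid does not overlap source")
    target = axis[inside]
    intensity = np.interp(target, spectrum.shift, spectrum.intensity)
    return spectrum.copy(shift=target, intensity=intensity)
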