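"""Molecular-standard peak tables, tiers, and standard-spectrum synthesis.

Deep-UV (248.6 nm) excitation resonantly enhances the aromatic ring modes of
eight molecules that dominate bacterial Raman spectra: the five nucleobases
(adenine, cytosine, guanine, thymine, uracil) and the three aromatic amino
acids (phenylalanine, tryptophan, tyrosine).  The nucleic-acid standards come
in three tiers of increasing structural complexity — free base, deoxy/ribo
nucleotide triphosphate, and single-stranded 10-mer oligomer — whose dominant
marker bands shift as the ribose-phosphate and stacking interactions perturb
the ring's pi-electron density.  The amino-acid standards are shared across
tiers and all cluster near the ~1600 cm^-1 benzene ring stretch.

Where measured standard spectra are unavailable, standards are synthesised
from their tabulated peak positions using pseudo-Voigt lines at the ~25 cm^-1
instrument resolution.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from .spectra import RamanSpectrum, SpectrumError

__all__ = [
    "PeakDescriptor",
    "MolecularStandard",
    "StandardLibrary",
    "NUCLEIC_ACIDS",
    "AMINO_ACIDS",
    "COMPONENTS",
    "NUCLEIC_TIERS",
    "builtin_peak_table",
    "dominant_mode_shift",
    "synthesize_standard",
    "prepare_measured_standard",
    "gaussian_line",
    "lorentzian_line",
    "pseudo_voigt_line",
]

NUCLEIC_ACIDS = ("adenine", "cytosine", "guanine", "thymine", "uracil")
AMINO_ACIDS = ("phenylalanine", "tryptophan", "tyrosine")
#: Canonical component order of the 8-term linear-combination model.
COMPONENTS = NUCLEIC_ACIDS + AMINO_ACIDS

NUCLEIC_TIERS = ("nucleobase", "dNTP", "ssDNA_10mer")
TIERS = NUCLEIC_TIERS + ("amino_acid",)

#: Instrument resolution: minimum peak-to-peak separation, used as default FWHM.
DEFAULT_FWHM = 25.0

# Dominant marker-band positions (cm^-1) per molecule and tier.  Assignments
# name the coupled bond vibrations, classed stretching (s) / bending (b).
_DOMINANT = {
    "adenine": {"nucleobase": 1291.0, "dNTP": 1322.0, "ssDNA_10mer": 1314.0,
                "assignment": "C8H (b), C8N7 (s)"},
    "cytosine": {"nucleobase": 1512.0, "dNTP": 1523.0, "ssDNA_10mer": 1508.0,
                 "assignment": "N3C4 (s)"},
    "guanine": {"nucleobase": 1440.0, "dNTP": 1474.0, "ssDNA_10mer": 1462.0,
                "assignment": "C8H (b), N9C8 (s)"},
    "thymine": {"nucleobase": 1647.0, "dNTP": 1651.0, "ssDNA_10mer": 1634.0,
                "assignment": "C4=O (s), C5C7 (s)"},
    "uracil": {"nucleobase": 1210.0, "dNTP": 1214.0, "ssDNA_10mer": 1203.0,
               "assignment": "C5H (b), N3C4 (s)"},
}
_AMINO_DOMINANT = {
    "phenylalanine": 1595.0,
    "tryptophan": 1610.0,
    "tyrosine": 1591.0,
}

# Optional secondary features transcribed from textual band descriptions of
# cellular spectra (heights are placeholders, 0.3x the dominant mode, not
# measured values): guanine composite 1540-1555, Phe/Tyr symmetric ring
# stretch just below 1000, cytosine shoulder ~1350, and the strong ssDNA
# cytosine mode ~1574 absent from the simpler tiers.
_EXTENDED = {
    ("guanine", "nucleobase"): [(1548.0, "N3C4 (s), C5C4/C4N3 (s)")],
    ("guanine", "dNTP"): [(1548.0, "N3C4 (s), C5C4/C4N3 (s)")],
    ("guanine", "ssDNA_10mer"): [(1548.0, "N3C4 (s), C5C4/C4N3 (s)")],
    ("cytosine", "nucleobase"): [(1350.0, "C2H, N9C8 (s) shoulder")],
    ("cytosine", "dNTP"): [(1350.0, "C2H, N9C8 (s) shoulder")],
    ("cytosine", "ssDNA_10mer"): [(1574.0, "ring (s), oligomer-specific")],
    ("phenylalanine", "amino_acid"): [(1000.0, "symmetric ring (s)")],
    ("tyrosine", "amino_acid"): [(1000.0, "symmetric ring (s)")],
}
_EXTENDED_HEIGHT = 0.3


@dataclass(frozen=True)
class PeakDescriptor:
    """One Raman band: position, relative height, width and assignment."""

    center: float
    relative_height: float = 1.0
    fwhm: float = DEFAULT_FWHM
    assignment: str = ""
    mode: str = "stretching"
    dominant: bool = False

    def __post_init__(self):
        if not 400.0 <= self.center <= 2500.0:
            raise ValueError(f"peak center {self.center} outside [400, 2500] cm^-1")
        if not 0.0 < self.relative_height <= 1.0:
            raise ValueError("relative_height must be in (0, 1]")
        if self.fwhm <= 0:
            raise ValueError("fwhm must be positive")
        if self.mode not in ("stretching", "bending"):
            raise ValueError(f"unknown mode class {self.mode!r}")


@dataclass
class MolecularStandard:
    """A molecular standard: molecule name, complexity tier, peak list."""

    molecule: str
    tier: str
    peaks: list
    spectrum: RamanSpectrum | None = None

    def __post_init__(self):
        if self.molecule not in COMPONENTS:
            raise ValueError(f"unknown molecule {self.molecule!r}")
        if self.tier not in TIERS:
            raise ValueError(f"unknown tier {self.tier!r}")
        if self.molecule in AMINO_ACIDS and self.tier != "amino_acid":
            raise ValueError("amino-acid standards exist only in tier 'amino_acid'")
        if self.molecule in NUCLEIC_ACIDS and self.tier == "amino_acid":
            raise ValueError(f"{self.molecule} is not an amino-acid standard")
        if sum(p.dominant for p in self.peaks) != 1:
            raise ValueError("exactly one dominant peak required per standard")

    @property
    def dominant_peak(self) -> PeakDescriptor:
        return next(p for p in self.peaks if p.dominant)


def _mode_class(assignment: str) -> str:
    return "bending" if assignment.lstrip().startswith(("C8H", "C5H")) else "stretching"


def builtin_peak_table(tier: str, extended: bool = False) -> list:
    """Built-in dominant-mode table for one tier.

    ``tier`` in {nucleobase, dNTP, ssDNA_10mer} returns the five nucleic-acid
    standards of that tier; ``amino_acid`` returns Phe/Trp/Tyr.  With
    ``extended=True``, secondary bands transcribed from band descriptions are
    added at 0.3x relative height (placeholder heights, not measured values).
    """
    if tier not in TIERS:
        raise ValueError(f"unknown tier {tier!r}; expected one of {TIERS}")
    out = []
    if tier == "amino_acid":
        for mol in AMINO_ACIDS:
            peaks = [PeakDescriptor(_AMINO_DOMINANT[mol], 1.0, DEFAULT_FWHM,
                                    "Benzene (s)", "stretching", dominant=True)]
            if extended:
                for c, a in _EXTENDED.get((mol, tier), []):
                    peaks.append(PeakDescriptor(c, _EXTENDED_HEIGHT, DEFAULT_FWHM,
                                                a, _mode_class(a)))
            out.append(MolecularStandard(mol, tier, peaks))
        return out
    for mol in NUCLEIC_ACIDS:
        row = _DOMINANT[mol]
        peaks = [PeakDescriptor(row[tier], 1.0, DEFAULT_FWHM, row["assignment"],
                                _mode_class(row["assignment"]), dominant=True)]
        if extended:
            for c, a in _EXTENDED.get((mol, tier), []):
                peaks.append(PeakDescriptor(c, _EXTENDED_HEIGHT, DEFAULT_FWHM,
                                            a, _mode_class(a)))
        out.append(MolecularStandard(mol, tier, peaks))
    return out


def dominant_mode_shift(molecule: str, tier_from: str, tier_to: str) -> float:
    """Signed dominant-band shift (cm^-1) of a nucleic-acid standard between tiers.

    E.g. adenine nucleobase -> dNTP is +31 cm^-1: the ribose-triphosphate
    redistributes pi-electron density on the purine ring.
    """
    if molecule in AMINO_ACIDS:
        raise ValueError("amino acids have a single tier; no cross-tier shift")
    if molecule not in NUCLEIC_ACIDS:
        raise ValueError(f"unknown molecule {molecule!r}")
    for t in (tier_from, tier_to):
        if t not in NUCLEIC_TIERS:
            raise ValueError(f"unknown nucleic-acid tier {t!r}")
    row = _DOMINANT[molecule]
    return float(row[tier_to] - row[tier_from])


# ---------------------------------------------------------------------------
# line shapes & synthesis
# ---------------------------------------------------------------------------

def gaussian_line(x: np.ndarray, center: float, fwhm: float) -> np.ndarray:
    """Unit-height Gaussian."""
    sigma = fwhm / (2.0 * np.sqrt(2.0 * np.log(2.0)))
    return np.exp(-0.5 * ((x - center) / sigma) ** 2)


def lorentzian_line(x: np.ndarray, center: float, fwhm: float) -> np.ndarray:
    """Unit-height Lorentzian."""
    hw = fwhm / 2.0
    return hw**2 / ((x - center) ** 2 + hw**2)


def pseudo_voigt_line(x: np.ndarray, center: float, fwhm: float,
                      eta: float = 0.5) -> np.ndarray:
    """Unit-height pseudo-Voigt: eta*Lorentzian + (1-eta)*Gaussian."""
    return (eta * lorentzian_line(x, center, fwhm)
            + (1.0 - eta) * gaussian_line(x, center, fwhm))


_LINESHAPES = {
    "gaussian": gaussian_line,
    "lorentzian": lorentzian_line,
    "pseudo_voigt": pseudo_voigt_line,
}


def synthesize_standard(standard: MolecularStandard, axis,
                        lineshape: str = "pseudo_voigt") -> RamanSpectrum:
    """Synthesise a standard spectrum from its peak table.

    Each band contributes a unit-height line shape scaled by its relative
    height, so the output maximum falls within a channel of the dominant band
    when peaks are well separated.  Synthesis is linear in the peak list.
    """
    if not standard.peaks:
        raise ValueError("empty peak list")
    try:
        shape = _LINESHAPES[lineshape]
    except KeyError:
        raise ValueError(f"unknown lineshape {lineshape!r}") from None
    axis = np.asarray(axis, dtype=float)
    y = np.zeros_like(axis)
    for p in standard.peaks:
        if not (axis[0] <= p.center <= axis[-1]):
            warnings.warn(
                f"{standard.molecule}: peak at {p.center} cm^-1 outside axis; truncated",
                stacklevel=2,
            )
        y += p.relative_height * shape(axis, p.center, p.fwhm)
    meta = {"label": f"{standard.molecule}:{standard.tier}", "lineshape": lineshape}
    return RamanSpectrum(shift=axis.copy(), intensity=y, meta=meta)


@dataclass
class StandardLibrary:
    """The eight-component standard set for one nucleic-acid tier.

    Members are the five nucleic-acid standards of ``tier`` plus the three
    aromatic amino acids, all on one shared shift axis — the component list of
    the scalable linear-combination model.
    """

    tier: str
    standards: dict
    axis: np.ndarray

    def __post_init__(self):
        if self.tier not in NUCLEIC_TIERS:
            raise ValueError(f"library tier must be one of {NUCLEIC_TIERS}")
        if tuple(self.standards) != COMPONENTS:
            raise ValueError(
                "library must hold exactly the 8 components "
                f"{COMPONENTS} in order; got {tuple(self.standards)}"
            )
        self.axis = np.asarray(self.axis, dtype=float)
        for name, spec in self.spectra.items():
            if not np.array_equal(spec.shift, self.axis):
                raise SpectrumError(f"standard {name} not on the library axis")

    @property
    def spectra(self) -> dict:
        return {name: std.spectrum for name, std in self.standards.items()}

    @property
    def components(self):
        return COMPONENTS

    def design_matrix(self) -> np.ndarray:
        """(n_channels, 8) matrix of component intensities, model design matrix."""
        return np.column_stack([self.spectra[c].intensity for c in COMPONENTS])

    @classmethod
    def from_tier(cls, tier: str, axis, lineshape: str = "pseudo_voigt",
                  extended: bool = False,
                  baseline: bool = False) -> "StandardLibrary":
        """Build a library by synthesising the built-in peak tables.

        With ``baseline=True`` each synthesised spectrum has its global OLS
        line subtracted over ``axis`` — matching the processing a measured
        standard receives, and required when fitting a target that went
        through the same baseline-subtraction stage.
        """
        axis = np.asarray(axis, dtype=float)
        standards: dict = {}
        for std in (builtin_peak_table(tier, extended=extended)
                    + builtin_peak_table("amino_acid", extended=extended)):
            spec = synthesize_standard(std, axis, lineshape)
            if baseline:
                slope, intercept = np.polyfit(axis, spec.intensity, 1)
                spec = spec.copy(intensity=spec.intensity
                                 - (slope * axis + intercept))
            standards[std.molecule] = replace_spectrum(std, spec)
        ordered = {c: standards[c] for c in COMPONENTS}
        return cls(tier=tier, standards=ordered, axis=axis)

    @classmethod
    def from_spectra(cls, tier: str, spectra: dict) -> "StandardLibrary":
        """Build a library from measured/loaded spectra keyed by component name."""
        missing = [c for c in COMPONENTS if c not in spectra]
        if missing:
            raise ValueError(f"missing standards: {missing}")
        axis = spectra[COMPONENTS[0]].shift
        standards = {}
        for c in COMPONENTS:
            t = tier if c in NUCLEIC_ACIDS else "amino_acid"
            peak = PeakDescriptor(
                float(spectra[c].shift[int(np.argmax(spectra[c].intensity))]),
                1.0, DEFAULT_FWHM, "measured", "stretching", dominant=True)
            standards[c] = MolecularStandard(c, t, [peak], spectrum=spectra[c])
        return cls(tier=tier, standards=standards, axis=axis)


def replace_spectrum(std: MolecularStandard, spectrum: RamanSpectrum) -> MolecularStandard:
    return MolecularStandard(std.molecule, std.tier, list(std.peaks), spectrum)


# ---------------------------------------------------------------------------
# measured-standard preparation (internal-standard anchoring)
# ---------------------------------------------------------------------------

def prepare_measured_standard(spectrum: RamanSpectrum,
                              sulfate_position: float = 981.0,
                              halfwidth: float = 40.0) -> RamanSpectrum:
    """Anchor a measured standard to its co-dissolved sulfate internal standard.

    The ~981 cm^-1 sulfate band is fitted (pseudo-Voigt plus linear offset);
    the spectrum is scaled so the fitted band area equals 1 — anchoring
    intensity to concentration regardless of laser power — and the fitted band
    is then subtracted.  If no sulfate band is found the spectrum is returned
    unscaled with ``meta['sulfate_flag'] = 'absent'``.
    """
    lo, hi = sulfate_position - halfwidth, sulfate_position + halfwidth
    m = spectrum.window_mask(lo, hi)
    if m.sum() < 7:
        return spectrum.copy(sulfate_flag="absent")
    fit = _fit_local_peak(spectrum.shift[m], spectrum.intensity[m],
                          sulfate_position)
    if fit is None or fit["area"] <= 0:
        return spectrum.copy(sulfate_flag="absent")
    # band must rise meaningfully above the local residual scatter
    if fit["height"] < 5.0 * fit["resid_sd"]:
        return spectrum.copy(sulfate_flag="absent")
    peak = fit["peak_on"](spectrum.shift)
    scaled = (spectrum.intensity - peak) / fit["area"]
    return spectrum.copy(intensity=scaled, sulfate_scale=1.0 / fit["area"],
                         sulfate_flag="anchored")


def _fit_local_peak(x: np.ndarray, y: np.ndarray, center: float,
                    fwhm_bounds=(10.0, 40.0), center_slack: float = 8.0):
    """Fit pseudo-Voigt + linear offset in a window; return band parameters.

    Shared by internal-standard anchoring here and atmospheric-line
    subtraction in :mod:`duvdecon.preprocess`.
    """
    from lmfit.models import LinearModel, PseudoVoigtModel

    peak = PseudoVoigtModel(prefix="p_")
    line = LinearModel(prefix="l_")
    model = peak + line
    params = model.make_params()
    span = x[-1] - x[0]
    baseline = np.median(y)
    amp0 = max(float(np.max(y) - baseline), 1e-12) * 25.0
    params["p_center"].set(value=center, min=center - center_slack,
                           max=center + center_slack)
    params["p_sigma"].set(value=12.5, min=fwhm_bounds[0] / 2.0,
                          max=fwhm_bounds[1] / 2.0)
    params["p_amplitude"].set(value=amp0, min=0.0)
    params["p_fraction"].set(value=0.5, min=0.0, max=1.0)
    params["l_slope"].set(value=0.0)
    params["l_intercept"].set(value=baseline)
    try:
        result = model.fit(y, params, x=x)
    except Exception:
        return None
    if not result.success:
        return None
    pars = result.params

    def peak_on(grid):
        return peak.eval(result.params, x=np.asarray(grid, dtype=float))

    return {
        "area": float(pars["p_amplitude"].value),
        "center": float(pars["p_center"].value),
        "fwhm": float(pars["p_fwhm"].value),
        "height": float(pars["p_height"].value),
        "resid_sd": float(np.std(result.residual)),
        "peak_on": peak_on,
    }
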