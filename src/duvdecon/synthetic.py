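"""Seeded generator of replicate Raman acquisitions with known ground truth.

Emulates the statistical structure the analysis assumes so that every stage
is testable without instrument data: a 25-point replicate array whose clean
signal is a known linear combination of standard spectra, an unmodelled
broad background (16% of fingerprint intensity for cell-like targets, none
for mixture-like ones), additive Gaussian detector noise, Poisson-count
cosmic-ray spikes, a rigid wavenumber miscalibration, and atmospheric N2
(2330 cm^-1, the calibration reference position) and O2 (~1550 cm^-1) lines.
Identical seeds give bit-identical output.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .spectra import (RamanSpectrum, SpectrumSet, write_spectrum)
from .standards import (COMPONENTS, StandardLibrary, gaussian_line,
                        pseudo_voigt_line)

__all__ = [
    "SyntheticConfig",
    "TruthRecord",
    "CELL_WEIGHTS",
    "generate_target",
    "generate_standard_files",
    "end_to_end_fixture",
]

#: Default cell-like true weights: the relative contributions of the eight
#: components in a bacterial fingerprint spectrum (guanine and adenine
#: dominant, modest pyrimidines, a small pooled amino-acid share).
CELL_WEIGHTS = {
    "adenine": 0.23, "cytosine": 0.14, "guanine": 0.34, "thymine": 0.06,
    "uracil": 0.06, "phenylalanine": 0.09, "tryptophan": 0.02,
    "tyrosine": 0.02,
}

#: Atmospheric line parameters: (position cm^-1, FWHM cm^-1, height relative
#: to the dominant signal peak).  N2 sits at the calibration reference.
ATMOSPHERIC_LINES = ((2330.0, 12.0, 0.5), (1550.0, 12.0, 0.15))


@dataclass
class SyntheticConfig:
    """Generator settings; defaults emulate a cell-like acquisition."""

    seed: int = 0
    axis_lo: float = 400.0
    axis_hi: float = 2400.0
    axis_step: float = 2.0
    tier: str = "dNTP"
    true_weights: dict = field(default_factory=lambda: dict(CELL_WEIGHTS))
    background_fraction: float = 0.16
    noise_sigma: float = 0.01  # fraction of the dominant-peak height
    cosmic_ray_rate: float = 0.2  # expected spikes per replicate
    n_replicates: int = 25
    axis_offset_cm1: float | None = None  # None -> drawn uniformly in +-12
    include_atmospheric: bool = True
    background_center: float = 1300.0
    background_fwhm: float = 600.0
    lineshape: str = "pseudo_voigt"
    cross_section: dict = field(default_factory=dict)  # hypochromism dials

    def __post_init__(self):
        if not 0.0 <= self.background_fraction < 1.0:
            raise ValueError("background_fraction must lie in [0, 1)")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        if self.cosmic_ray_rate < 0:
            raise ValueError("cosmic_ray_rate must be >= 0")

    def axis(self) -> np.ndarray:
        n = int(round((self.axis_hi - self.axis_lo) / self.axis_step)) + 1
        return self.axis_lo + self.axis_step * np.arange(n)

    @classmethod
    def cell_like(cls, seed: int = 0, **overrides) -> "SyntheticConfig":
        """Cell-like acquisition: 16% unmodelled background, 1% noise."""
        return cls(seed=seed, **overrides)

    @classmethod
    def mixture_like(cls, seed: int = 0, **overrides) -> "SyntheticConfig":
        """Artificial-mixture acquisition: no unmodelled background and the
        186:1 signal-to-noise ratio such dilute-standard spectra achieve."""
        overrides.setdefault("background_fraction", 0.0)
        overrides.setdefault("noise_sigma", 1.0 / 186.0)
        return cls(seed=seed, **overrides)


@dataclass
class TruthRecord:
    """Everything needed to verify recovery: the generator's ground truth."""

    weights: dict
    background_fraction: float
    axis_offset_cm1: float
    noise_sigma_abs: float
    spikes: list  # (replicate, channel, amplitude)
    truth: RamanSpectrum  # clean signal + background on the true axis
    signal: RamanSpectrum  # clean component sum only
    background: RamanSpectrum
    tier: str

    def to_json(self) -> str:
        d = {
            "weights": self.weights,
            "background_fraction": self.background_fraction,
            "axis_offset_cm1": self.axis_offset_cm1,
            "noise_sigma_abs": self.noise_sigma_abs,
            "spikes": [[int(r), int(c), float(a)] for r, c, a in self.spikes],
            "tier": self.tier,
        }
        return json.dumps(d, indent=2)


def _detrend(axis: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Subtract the global OLS line — the processing chain's baseline stage."""
    slope, intercept = np.polyfit(axis, y, 1)
    return y - (slope * axis + intercept)


def _background_bump(axis: np.ndarray, signal: np.ndarray,
                     config: SyntheticConfig, library: StandardLibrary,
                     lo: float = 800.0, hi: float = 1800.0) -> np.ndarray:
    """Broad featureless background carrying ``background_fraction`` of the
    processed fingerprint-range intensity.

    An "unmodelled" background is, operationally, whatever survives both the
    processing chain and the component fit: the chain removes a global OLS
    line from every spectrum, and the least-squares deconvolution removes
    anything the component standards can represent.  The generator therefore
    builds the background directly in that surviving domain: a broad
    Gaussian bump (supported on the fingerprint window, zero outside) made
    orthogonal — in the window's least-squares sense — to the affine
    baseline and to the span of the generating library's baseline-processed
    component spectra.  A short fixed-point iteration scales it so its
    absolute integral equals ``background_fraction`` of the absolute
    integral of the processed target over 800-1800 cm^-1, the quantity the
    residual-fraction statistic measures.
    """
    if config.background_fraction == 0.0:
        return np.zeros_like(axis)
    m = (axis >= lo) & (axis <= hi)
    x = axis[m]
    bump = gaussian_line(x, config.background_center, config.background_fwhm)
    # orthogonalize against {1, x} and the processed component spectra
    comps = np.column_stack([
        _detrend(x, library.spectra[c].intensity[m]) for c in COMPONENTS])
    basis = np.column_stack([np.ones_like(x), x, comps])
    coef, *_ = np.linalg.lstsq(basis, bump, rcond=None)
    shape = bump - basis @ coef
    shape_int = np.trapezoid(np.abs(shape), x)
    sig_proc = _detrend(x, signal[m])
    f = config.background_fraction
    scale = f / (1.0 - f) * np.trapezoid(np.abs(sig_proc), x) / shape_int
    for _ in range(20):  # pin |B| / |processed target| = f
        denom = np.trapezoid(np.abs(sig_proc + scale * shape), x)
        new_scale = f * denom / shape_int
        if abs(new_scale - scale) <= 1e-12 * scale:
            break
        scale = new_scale
    out = np.zeros_like(axis)
    out[m] = scale * shape
    return out


def generate_target(config: SyntheticConfig,
                    library: StandardLibrary | None = None):
    """Generate a replicate acquisition set plus its truth record.

    The clean truth is the weighted component sum plus the broad background;
    each replicate adds atmospheric lines, Gaussian noise and cosmic-ray
    spikes (uniform channel, amplitude 10-100x the noise sd); the recorded
    axis carries the rigid miscalibration offset.
    """
    rng = np.random.default_rng(config.seed)
    axis = config.axis()
    if library is None:
        library = StandardLibrary.from_tier(config.tier, axis, config.lineshape)
    elif not np.array_equal(library.axis, axis):
        raise ValueError("library axis does not match the configured axis")
    unknown = set(config.true_weights) - set(COMPONENTS)
    if unknown:
        raise ValueError(f"weights reference unknown components: {sorted(unknown)}")

    signal = np.zeros_like(axis)
    for name, w in config.true_weights.items():
        xs = config.cross_section.get(name, 1.0)
        signal = signal + w * xs * library.spectra[name].intensity
    background = _background_bump(axis, signal, config, library)
    truth = signal + background

    peak_height = float(np.max(truth)) if np.any(truth) else 1.0
    sigma_abs = config.noise_sigma * peak_height

    offset = (config.axis_offset_cm1 if config.axis_offset_cm1 is not None
              else float(rng.uniform(-12.0, 12.0)))

    atmos = np.zeros_like(axis)
    if config.include_atmospheric:
        for pos, fwhm, rel in ATMOSPHERIC_LINES:
            atmos = atmos + rel * peak_height * pseudo_voigt_line(axis, pos, fwhm)

    n_ch = len(axis)
    mat = np.empty((config.n_replicates, n_ch))
    spikes = []
    for rep in range(config.n_replicates):
        y = truth + atmos
        if sigma_abs > 0:
            y = y + rng.normal(0.0, sigma_abs, size=n_ch)
        n_spikes = rng.poisson(config.cosmic_ray_rate)
        for _ in range(n_spikes):
            ch = int(rng.integers(0, n_ch))
            amp = float(rng.uniform(10.0, 100.0)) * max(sigma_abs,
                                                        1e-3 * peak_height)
            y = y.copy()
            y[ch] += amp
            spikes.append((rep, ch, amp))
        mat[rep] = y

    observed_axis = axis + offset
    spectrum_set = SpectrumSet.from_matrix(
        observed_axis, mat,
        {"label": f"synthetic:{config.tier}", "seed": config.seed})
    record = TruthRecord(
        weights=dict(config.true_weights),
        background_fraction=config.background_fraction,
        axis_offset_cm1=offset,
        noise_sigma_abs=sigma_abs,
        spikes=spikes,
        truth=RamanSpectrum(axis.copy(), truth, {"label": "truth"}),
        signal=RamanSpectrum(axis.copy(), signal, {"label": "signal"}),
        background=RamanSpectrum(axis.copy(), background + 0.0,
                                 {"label": "background"})
        if np.any(background) else RamanSpectrum(axis.copy(),
                                                 np.zeros_like(axis),
                                                 {"label": "background"}),
        tier=config.tier,
    )
    return spectrum_set, record


def generate_standard_files(tier: str, out_dir,
                            config: SyntheticConfig | None = None) -> dict:
    """Write the eight synthesised standard spectra of a tier plus a manifest.

    Files are two-column delimited text readable by
    :func:`duvdecon.spectra.read_spectrum`; the manifest maps component name
    to file name and dominant-peak position.
    """
    config = config or SyntheticConfig(tier=tier)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    axis = config.axis()
    library = StandardLibrary.from_tier(tier, axis, config.lineshape)
    manifest = {"tier": tier, "files": {}}
    for name, std in library.standards.items():
        fname = f"{name}.csv"
        spec = std.spectrum.copy(label=name)
        write_spectrum(spec, out_dir / fname)
        manifest["files"][name] = {
            "file": fname,
            "dominant_center_cm1": std.dominant_peak.center,
        }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest


def end_to_end_fixture(config: SyntheticConfig | None = None,
                       out_dir=None):
    """One call producing everything the pipeline needs.

    Returns (raw SpectrumSet, StandardLibrary, TruthRecord); with ``out_dir``
    also writes the replicate files, standards and truth record to disk.
    """
    config = config or SyntheticConfig()
    axis = config.axis()
    library = StandardLibrary.from_tier(config.tier, axis, config.lineshape)
    spectrum_set, record = generate_target(config, library)
    if out_dir is not None:
        out_dir = Path(out_dir)
        (out_dir / "replicates").mkdir(parents=True, exist_ok=True)
        for i, rep in enumerate(spectrum_set.replicates):
            write_spectrum(rep.copy(label=f"point_{i:02d}"),
                           out_dir / "replicates" / f"point_{i:02d}.csv")
        generate_standard_files(config.tier, out_dir / "standards", config)
        (out_dir / "truth.json").write_text(record.to_json())
    return spectrum_set, library, record
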