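"""Raw-replicate processing chain: from detector counts to a calibrated,
background-subtracted, normalized fingerprint spectrum.

Stage order matters and is enforced by :func:`run_pipeline`:

1. cosmic-ray removal (per-channel outliers across replicates)
2. laser-intensity correction
3. rigid wavenumber recalibration to the atmospheric N2 line at 2330 cm^-1
4. atmospheric N2 / O2 line subtraction (fitted locally, before cropping —
   the N2 line lies outside the fingerprint window)
5. crop to the 800-1800 cm^-1 organic fingerprint range
6. linear baseline subtraction (single OLS line over the cropped range)
7. replicate averaging (mean + channelwise sd)
8. normalization to the guanine marker band near 1460 cm^-1
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from .spectra import RamanSpectrum, SpectrumSet, SpectrumError

__all__ = [
    "PreprocessConfig",
    "PipelineResult",
    "remove_cosmic_rays",
    "correct_laser_intensity",
    "recalibrate_shift",
    "subtract_atmospheric",
    "crop_fingerprint",
    "subtract_linear_baseline",
    "average_replicates",
    "normalize_to_guanine",
    "run_pipeline",
    "RamanPreprocessor",
]


@dataclass
class PreprocessConfig:
    """Tunable parameters of the processing chain (all in cm^-1 unless noted)."""

    n2_reference: float = 2330.0
    n2_search_halfwidth: float = 30.0
    o2_position: float = 1550.0
    atmospheric_halfwidth: float = 40.0
    fingerprint_lo: float = 800.0
    fingerprint_hi: float = 1800.0
    cosmic_ray_zmax: float = 5.0  # robust z-score threshold, dimensionless
    guanine_window: tuple = (1440.0, 1480.0)
    guanine_statistic: str = "max"  # "max" (band apex) or "mean" over window
    recalibrate: bool = True
    subtract_atmospheric_lines: bool = True

    def __post_init__(self):
        if self.fingerprint_lo >= self.fingerprint_hi:
            raise ValueError("fingerprint_lo must be < fingerprint_hi")
        for name in ("n2_search_halfwidth", "atmospheric_halfwidth",
                     "cosmic_ray_zmax"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.guanine_window[0] >= self.guanine_window[1]:
            raise ValueError("guanine_window must be an increasing interval")
        if self.guanine_statistic not in ("max", "mean"):
            raise ValueError("guanine_statistic must be 'max' or 'mean'")


# ---------------------------------------------------------------------------
# individual stages
# ---------------------------------------------------------------------------

def remove_cosmic_rays(spectrum_set: SpectrumSet, zmax: float = 5.0):
    """Remove single-exposure CCD spikes by cross-replicate outlier detection.

    Per channel, replicate intensities are scored with a robust z
    (0.6745 * |x - median| / MAD across replicates); cells exceeding ``zmax``
    are replaced by the mean of the two spectrally adjacent channels of the
    same replicate (one-sided at the boundaries).  Only flagged cells change.

    Returns
    -------
    (SpectrumSet, list of (replicate, channel) flagged)
    """
    if spectrum_set.n_replicates < 3:
        raise SpectrumError(
            "insufficient replicates for outlier detection (need >=3)")
    mat = spectrum_set.to_matrix()
    med = np.median(mat, axis=0)
    mad = np.median(np.abs(mat - med), axis=0)
    scale = np.where(mad > 0, mad / 0.6745, np.finfo(float).tiny)
    z = np.abs(mat - med) / scale
    flagged = np.argwhere(z > zmax)
    if len(flagged) == 0:
        return spectrum_set, []
    out = mat.copy()
    n_ch = mat.shape[1]
    for rep, ch in flagged:
        left = ch - 1 if ch > 0 else ch + 1
        right = ch + 1 if ch < n_ch - 1 else ch - 1
        out[rep, ch] = 0.5 * (mat[rep, left] + mat[rep, right])
    return spectrum_set.with_matrix(out), [tuple(rc) for rc in flagged]


def correct_laser_intensity(spectrum: RamanSpectrum, factor: float) -> RamanSpectrum:
    """Divide intensities by the normalized laser-intensity correction factor."""
    if factor <= 0:
        raise SpectrumError(f"invalid correction factor {factor}")
    return spectrum.copy(intensity=spectrum.intensity / factor,
                         laser_correction=factor)


def _detect_apex(spectrum: RamanSpectrum, reference: float,
                 halfwidth: float) -> float:
    """Apex of the local maximum near ``reference``, 3-point parabola refined."""
    lo, hi = reference - halfwidth, reference + halfwidth
    if spectrum.shift[0] > lo or spectrum.shift[-1] < hi:
        raise SpectrumError("N2 region absent: axis does not cover the search window")
    m = spectrum.window_mask(lo, hi)
    idx = np.flatnonzero(m)
    y = spectrum.intensity[idx]
    k = int(np.argmax(y))
    # require a real local maximum above the window's edge level
    edge = 0.5 * (y[0] + y[-1])
    if y[k] <= edge + 1e-12 * max(1.0, abs(edge)):
        raise SpectrumError("N2 peak not found: no local maximum above background")
    i = idx[k]
    if 0 < i < spectrum.n_channels - 1:
        y0, y1, y2 = spectrum.intensity[i - 1:i + 2]
        denom = y0 - 2.0 * y1 + y2
        if denom < 0:  # concave: refine sub-channel
            delta = 0.5 * (y0 - y2) / denom
            delta = float(np.clip(delta, -0.5, 0.5))
            spacing = spectrum.shift[i + 1] - spectrum.shift[i]
            return float(spectrum.shift[i] + delta * spacing)
    return float(spectrum.shift[i])


def recalibrate_shift(spectrum: RamanSpectrum, reference: float = 2330.0,
                      search_halfwidth: float = 30.0):
    """Rigidly shift the axis so the atmospheric N2 line sits at ``reference``.

    Returns (recalibrated spectrum, applied shift in cm^-1).
    """
    apex = _detect_apex(spectrum, reference, search_halfwidth)
    delta = reference - apex
    out = spectrum.copy(shift=spectrum.shift + delta, recalibration_shift=delta)
    return out, float(delta)


#: Fit-window offsets (cm^-1) around each atmospheric line.  The O2 window is
#: asymmetric: its low side stops short of the strong cytosine marker band
#: (1508-1523 cm^-1 depending on tier) that overlaps the O2 region in
#: cellular spectra and would otherwise bias the local background estimate.
ATMOSPHERIC_WINDOWS = {2330.0: (-40.0, 40.0), 1550.0: (-25.0, 35.0)}
#: Calibrated atmospheric line width (cm^-1): the narrow rovibrational band
#: envelopes of the diatomic gases, sharper than the ~25 cm^-1 molecular bands.
ATMOSPHERIC_LINE_FWHM = 12.0


def _fit_atmospheric_line(x: np.ndarray, y: np.ndarray, pos: float,
                          fwhm: float = ATMOSPHERIC_LINE_FWHM,
                          center_slack: float = 2.0):
    """Amplitude of a known-shape line over a cubic local background.

    The line center is scanned over ``pos +- center_slack`` (0.5 cm^-1 steps)
    and the width over {0.8, 1.0, 1.2}x the calibrated FWHM; for each shape
    the non-negative amplitude and the cubic background are solved jointly by
    linear least squares and the lowest-SSE candidate is kept.  Linear solves
    cannot diverge, so the stage has no convergence failure mode.
    """
    from .standards import pseudo_voigt_line

    t = (x - pos) / (x[-1] - x[0])
    basis = np.vander(t, 4)
    best = None
    for c in np.arange(pos - center_slack, pos + center_slack + 0.25, 0.5):
        for w in (0.8 * fwhm, fwhm, 1.2 * fwhm):
            line = pseudo_voigt_line(x, c, w)
            design = np.column_stack([line, basis])
            coef, *_ = np.linalg.lstsq(design, y, rcond=None)
            if coef[0] < 0:  # no line: background-only model
                bg, *_ = np.linalg.lstsq(basis, y, rcond=None)
                sse = float(np.sum((y - basis @ bg) ** 2))
                cand = (sse, 0.0, c, w)
            else:
                sse = float(np.sum((y - design @ coef) ** 2))
                cand = (sse, float(coef[0]), c, w)
            if best is None or cand[0] < best[0]:
                best = cand
    _, amplitude, center, width = best
    return amplitude, center, width


def subtract_atmospheric(spectrum: RamanSpectrum, positions=(2330.0, 1550.0),
                         halfwidth: float = 40.0,
                         line_fwhm: float = ATMOSPHERIC_LINE_FWHM):
    """Quantify and remove atmospheric N2/O2 lines at the requested positions.

    Each line is modelled as a pseudo-Voigt of the calibrated atmospheric
    width riding on a cubic local background; only the fitted line — never
    the background — is subtracted.  ``halfwidth`` is the default symmetric
    window; known positions use curated windows (:data:`ATMOSPHERIC_WINDOWS`)
    that avoid overlapping molecular marker bands.  A position without a
    detectable line yields amplitude ~0 and leaves the spectrum unchanged.
    """
    out = spectrum.copy()
    info = []
    for pos in positions:
        lo_off, hi_off = ATMOSPHERIC_WINDOWS.get(pos, (-halfwidth, halfwidth))
        m = out.window_mask(pos + lo_off, pos + hi_off)
        if m.sum() < 10:
            warnings.warn(f"atmospheric window at {pos} cm^-1 not covered; skipped",
                          stacklevel=2)
            info.append({"position": pos, "status": "window_absent",
                         "height": 0.0})
            continue
        amplitude, center, width = _fit_atmospheric_line(
            out.shift[m], out.intensity[m], pos, line_fwhm)
        if amplitude > 0:
            from .standards import pseudo_voigt_line
            line = amplitude * pseudo_voigt_line(out.shift, center, width)
            # confine the subtraction to the line's own neighbourhood so the
            # Lorentzian tail cannot perturb distant channels
            reach = np.abs(out.shift - center) <= 6.0 * width
            out = out.copy(intensity=out.intensity - np.where(reach, line, 0.0))
        info.append({"position": pos, "status": "subtracted",
                     "height": amplitude, "center": center, "fwhm": width})
    flags = [i["status"] for i in info if i["status"] != "subtracted"]
    if flags:
        out.meta["atmospheric_flag"] = ",".join(flags)
    return out, info


def crop_fingerprint(spectrum: RamanSpectrum, lo: float = 800.0,
                     hi: float = 1800.0) -> RamanSpectrum:
    """Restrict to the organic fingerprint range [lo, hi] (closed interval)."""
    m = spectrum.window_mask(lo, hi)
    if m.sum() < 2:
        raise SpectrumError(f"empty crop: [{lo}, {hi}] does not overlap the axis")
    return spectrum.copy(shift=spectrum.shift[m], intensity=spectrum.intensity[m])


def subtract_linear_baseline(spectrum: RamanSpectrum):
    """Subtract the ordinary-least-squares line fitted over the whole range.

    Idempotent to numerical precision; output may go negative.
    Returns (spectrum, (slope, intercept)).
    """
    if spectrum.n_channels < 3:
        raise SpectrumError("degenerate baseline: need >=3 channels")
    slope, intercept = np.polyfit(spectrum.shift, spectrum.intensity, 1)
    base = slope * spectrum.shift + intercept
    return spectrum.copy(intensity=spectrum.intensity - base), (float(slope),
                                                                float(intercept))


def average_replicates(spectrum_set: SpectrumSet):
    """Channelwise mean spectrum and sample standard deviation.

    Returns (mean RamanSpectrum, sd array).  The sd is the per-channel sample
    standard deviation across replicates (ddof=1 when n > 1), the input to
    downstream uncertainty propagation.
    """
    mat = spectrum_set.to_matrix()
    mean = mat.mean(axis=0)
    sd = mat.std(axis=0, ddof=1) if mat.shape[0] > 1 else np.zeros(mat.shape[1])
    spec = spectrum_set.replicates[0].copy(intensity=mean,
                                           n_replicates=mat.shape[0])
    return spec, sd


def normalize_to_guanine(spectrum: RamanSpectrum,
                         window: tuple = (1440.0, 1480.0),
                         statistic: str = "max"):
    """Scale the spectrum to unit intensity of the guanine marker band.

    The band statistic over ``window`` (apex by default, windowed mean as an
    alternative) becomes 1.0; the scale factor is recorded in metadata.
    Returns (spectrum, scale factor applied as divisor).
    """
    m = spectrum.window_mask(*window)
    if m.sum() == 0:
        raise SpectrumError(f"normalization window {window} outside the axis")
    ref = (float(np.max(spectrum.intensity[m])) if statistic == "max"
           else float(np.mean(spectrum.intensity[m])))
    if ref <= 0:
        raise SpectrumError("cannot normalize: nonpositive guanine-band intensity")
    return spectrum.copy(intensity=spectrum.intensity / ref,
                         normalization_factor=ref), ref


class PipelineResult(NamedTuple):
    """Output of the full chain: mean spectrum, channel sd, stage report."""

    spectrum: RamanSpectrum
    sd: np.ndarray
    report: dict


def run_pipeline(spectrum_set: SpectrumSet,
                 config: PreprocessConfig | None = None,
                 laser_factors=None) -> PipelineResult:
    """Run the full chain in the enforced order on a replicate set.

    The rigid recalibration shift is estimated once from the replicate mean
    (miscalibration is a property of the acquisition, shared by replicates),
    as are the atmospheric line fits; the fitted lines are subtracted from
    every replicate.  Cropping happens only after recalibration because the
    N2 reference at 2330 cm^-1 lies outside the fingerprint window.

    Returns a :class:`PipelineResult` whose report logs each stage's effect
    size (spikes replaced, shift applied, atmospheric areas, baseline slope,
    normalization factor).
    """
    config = config or PreprocessConfig()
    report: dict = {"n_replicates": spectrum_set.n_replicates}

    # 1. cosmic rays
    spectrum_set, flagged = remove_cosmic_rays(spectrum_set,
                                               config.cosmic_ray_zmax)
    report["cosmic_rays_replaced"] = len(flagged)
    report["cosmic_ray_cells"] = [list(map(int, rc)) for rc in flagged]

    # 2. laser-intensity correction
    if laser_factors is not None:
        if len(laser_factors) != spectrum_set.n_replicates:
            raise SpectrumError("one laser factor per replicate required")
        reps = [correct_laser_intensity(r, f)
                for r, f in zip(spectrum_set.replicates, laser_factors)]
        spectrum_set = SpectrumSet(reps)
        report["laser_factors"] = [float(f) for f in laser_factors]
    else:
        reps = [correct_laser_intensity(r, r.meta.get("laser_correction", 1.0))
                for r in spectrum_set.replicates]
        spectrum_set = SpectrumSet(reps)

    # 3. rigid recalibration from the replicate mean
    if config.recalibrate:
        mean_spec, _ = average_replicates(spectrum_set)
        _, delta = recalibrate_shift(mean_spec, config.n2_reference,
                                     config.n2_search_halfwidth)
        spectrum_set = spectrum_set.with_axis(spectrum_set.axis + delta)
        report["recalibration_shift_cm1"] = delta

    # 4. atmospheric subtraction (fit on the mean, subtract from each replicate)
    if config.subtract_atmospheric_lines:
        mean_spec, _ = average_replicates(spectrum_set)
        corrected, info = subtract_atmospheric(
            mean_spec, (config.n2_reference, config.o2_position),
            config.atmospheric_halfwidth)
        removed = mean_spec.intensity - corrected.intensity
        mat = spectrum_set.to_matrix() - removed
        spectrum_set = spectrum_set.with_matrix(mat)
        report["atmospheric"] = info

    # 5. crop to fingerprint
    mask = ((spectrum_set.axis >= config.fingerprint_lo)
            & (spectrum_set.axis <= config.fingerprint_hi))
    if mask.sum() < 3:
        raise SpectrumError("empty crop: fingerprint window not covered")
    axis = spectrum_set.axis[mask]
    mat = spectrum_set.to_matrix()[:, mask]
    spectrum_set = SpectrumSet.from_matrix(
        axis, mat, spectrum_set.replicates[0].meta)

    # 6. per-replicate linear baseline
    slopes = []
    rows = []
    for rep in spectrum_set.replicates:
        sub, (slope, _) = subtract_linear_baseline(rep)
        slopes.append(slope)
        rows.append(sub.intensity)
    spectrum_set = spectrum_set.with_matrix(np.vstack(rows))
    report["baseline_slope_mean"] = float(np.mean(slopes))

    # 7. average
    mean_spec, sd = average_replicates(spectrum_set)

    # 8. normalize to the guanine band
    mean_spec, factor = normalize_to_guanine(mean_spec, config.guanine_window,
                                             config.guanine_statistic)
    sd = sd / factor
    report["normalization_factor"] = factor

    return PipelineResult(mean_spec, sd, report)


class RamanPreprocessor(TransformerMixin, BaseEstimator):
    """sklearn-style transformer wrapping :func:`run_pipeline`.

    Operates on an ``(n_replicates, n_channels)`` intensity matrix with the
    shift axis given at construction.  ``transform`` returns the processed
    mean spectrum as a ``(1, n_out)`` array; the processed axis, channel sd
    and stage report are exposed as fitted attributes.
    """

    def __init__(self, wavenumbers=None, n2_reference=2330.0,
                 n2_search_halfwidth=30.0, o2_position=1550.0,
                 atmospheric_halfwidth=40.0, fingerprint_lo=800.0,
                 fingerprint_hi=1800.0, cosmic_ray_zmax=5.0,
                 guanine_window=(1440.0, 1480.0), guanine_statistic="max",
                 recalibrate=True, subtract_atmospheric_lines=True):
        self.wavenumbers = wavenumbers
        self.n2_reference = n2_reference
        self.n2_search_halfwidth = n2_search_halfwidth
        self.o2_position = o2_position
        self.atmospheric_halfwidth = atmospheric_halfwidth
        self.fingerprint_lo = fingerprint_lo
        self.fingerprint_hi = fingerprint_hi
        self.cosmic_ray_zmax = cosmic_ray_zmax
        self.guanine_window = guanine_window
        self.guanine_statistic = guanine_statistic
        self.recalibrate = recalibrate
        self.subtract_atmospheric_lines = subtract_atmospheric_lines

    def _config(self) -> PreprocessConfig:
        return PreprocessConfig(
            n2_reference=self.n2_reference,
            n2_search_halfwidth=self.n2_search_halfwidth,
            o2_position=self.o2_position,
            atmospheric_halfwidth=self.atmospheric_halfwidth,
            fingerprint_lo=self.fingerprint_lo,
            fingerprint_hi=self.fingerprint_hi,
            cosmic_ray_zmax=self.cosmic_ray_zmax,
            guanine_window=tuple(self.guanine_window),
            guanine_statistic=self.guanine_statistic,
            recalibrate=self.recalibrate,
            subtract_atmospheric_lines=self.subtract_atmospheric_lines,
        )

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        if X.ndim != 2:
            raise ValueError("X must be (n_replicates, n_channels)")
        if self.wavenumbers is None:
            raise ValueError("wavenumbers must be provided at construction")
        spectrum_set = SpectrumSet.from_matrix(np.asarray(self.wavenumbers,
                                                          dtype=float), X)
        result = run_pipeline(spectrum_set, self._config())
        self.wavenumbers_ = result.spectrum.shift
        self.sd_ = result.sd
        self.report_ = result.report
        self.spectrum_ = result.spectrum
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X):
        self.fit(X)
        return self.spectrum_.intensity[np.newaxis, :]
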