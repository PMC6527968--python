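# Methods

This note documents the models, numerical choices and known limitations of
`duvdecon`, in the package's own terms.  Empirical claims below are all
computed by the test suite or `scripts/acceptance.py`.

## The measurement model

A deep-UV (248.6 nm) resonance Raman spectrum of a cell is treated as

    I_obs(ν) = Σ_i c_i · S_i(ν) + B(ν) + artifacts + noise

where `S_i` are the spectra of the eight resonantly enhanced standards
(five nucleobases, three aromatic amino acids), `B` is a broad unexplained
background, and the artifacts are cosmic-ray spikes, a rigid wavenumber
miscalibration, laser-power variation, and atmospheric N₂/O₂ lines.  The
analysis estimates `c_i` by least squares over the 800–1800 cm⁻¹
fingerprint range and summarises `B` as the *residual fraction*
∫|residual| / ∫|target|.

## Processing chain

Order is fixed: cosmic rays → laser correction → recalibration →
atmospheric subtraction → crop → linear baseline → average → normalize.
Cropping must follow recalibration because the N₂ reference at 2330 cm⁻¹
lies outside the fingerprint window.

**Cosmic rays.** Spikes are single-channel, single-exposure events, so they
are detected *across* replicates: per channel, a robust z-score
(0.6745·|x−median|/MAD over the ≥3 replicates) above `zmax = 5` flags a
cell, which is replaced by the mean of the two spectrally adjacent channels
of the same replicate (one-sided at boundaries).  Median/MAD statistics are
immune to the spike itself; at 25 replicates the threshold gives measured
sensitivity ≥ 95% for spikes 10–100× the noise sd and a false-replacement
rate below 0.1% (both recomputed by the acceptance script).  Only flagged
cells are modified.

**Recalibration.** Wavenumber miscalibration is modelled as rigid (a
property of the acquisition, shared by all replicates), so a single shift is
estimated from the replicate mean: the apex of the N₂ line near 2330 cm⁻¹
is located by window maximum plus 3-point parabolic refinement (sub-channel
accuracy without assuming a line shape) and the whole axis is shifted so the
apex lands on the 2330 cm⁻¹ reference.

**Atmospheric lines.** N₂ (2330 cm⁻¹) and O₂ (~1550 cm⁻¹) are narrow
(≈12 cm⁻¹ FWHM) gas-phase band envelopes, sharper than the ~25 cm⁻¹
molecular bands.  Each is modelled as a pseudo-Voigt of that calibrated
width riding on a cubic local background and fitted *linearly*: the center
is scanned over ±2 cm⁻¹ (0.5 cm⁻¹ steps) and the width over ±20%, and for
each candidate shape the non-negative amplitude plus cubic background is a
closed-form least-squares solve; the lowest-SSE candidate wins.  An earlier
free nonlinear fit (center, width, amplitude and offset all floating) was
abandoned: in cellular spectra the O₂ line sits on the flank of the
cytosine marker band and the optimizer reliably collapsed into line-free
local minima or slid the "line" onto the molecular flank.  The grid +
linear-solve design has no convergence failure mode.  The O₂ fit window is
asymmetric (−25/+35 cm⁻¹) so its low edge stays clear of the cytosine band
apex (1508–1523 cm⁻¹ depending on tier); windows are exposed in
`preprocess.ATMOSPHERIC_WINDOWS`.  Only the fitted line — never the local
background — is subtracted, the subtraction is confined to ±6 widths of the
line center, and the fit is performed once on the replicate mean and
subtracted from every replicate.  A spectrum with no line yields amplitude
≈ 0 and passes through unchanged.

**Baseline.** A single global OLS line over the cropped range, per
replicate.  This is deliberately the simplest model consistent with the
chain's purpose; it is idempotent and exactly linear in the data, which the
unmixing step exploits (below).  No rolling-ball or polynomial variants.

**Normalization.** The spectrum is scaled so the guanine marker band
(window 1440–1480 cm⁻¹) has unit intensity.  The band statistic is the
window *maximum* (apex scaling, the common convention); a windowed-mean
alternative is selectable (`guanine_statistic="mean"`) since the phrase
"mean intensity of the band" is ambiguous in common usage.  The scale
factor is recorded and also applied to the channelwise sd.

## Unmixing

`SpectralUnmixer` solves min‖Xc − y‖² with c ≥ 0 by default
(`scipy.optimize.nnls`; physical scale factors cannot be negative) or
unconstrained (`numpy.linalg.lstsq`), in which case it agrees with the
normal-equations closed form to ~1e-14 relative on full-rank inputs.  χ² is
the raw unweighted sum of squared residuals; the reduced value χ²/dof is
reported alongside, with dof = channels − 8.

**Consistent processing of standards.** Because the baseline stage is
linear, baseline-subtracting each standard spectrum over the same window
(`StandardLibrary.from_tier(..., baseline=True)`) makes the fit of a
processed target *exact* for a background-free mixture: detrend(Σ w·S) =
Σ w·detrend(S).  Fitting raw standards to a processed target instead leaves
an un-representable affine mismatch that visibly distorts the coefficients;
the package therefore always pairs processed targets with processed
standards.  Relative intensities are defined with absolute-value integrals
(c_i·∫|S_i| / ∫|target|) because processed spectra oscillate around zero;
they need not sum to 1, and on cell-like targets the shortfall/overlap is
absorbed by the residual.

**Uncertainties.** Coefficient SE combines, in quadrature, (1) the
residual-variance-scaled covariance s²(XᵀX)⁻¹ of the least-squares solution
and (2) the propagated channelwise replicate sd of the target,
H·diag(sd²)·Hᵀ with H = (XᵀX)⁻¹Xᵀ.  Both terms are exposed separately
(`stderr_fit_`, `stderr_target_`).  The quadrature combination is a
documented package choice.  At 1% noise, true weights fall within 3
reported SE in ≥95% of seed × component cases (acceptance-verified).

**Correlation pooling.** The three aromatic amino acids share the
~1600 cm⁻¹ ring stretch and are near-collinear in any library; groups are
the connected components of the |r| > 0.9 graph on the coefficient
correlation matrix, reported with pooled (summed) coefficients.  Pooling is
diagnostic only — the fit itself is unchanged.

**Model ranking.** `compare_standard_sets` ranks tiers by ascending χ²;
ties within 1e-9 relative are broken by fewer nonzero components, then by
tier order nucleobase < dNTP < ssDNA_10mer (simpler first, for determinism).

## Synthetic data

The generator's defaults are the study conditions the package is tested
under: 25 replicates (a 5×5 raster), 2 cm⁻¹ channels over 400–2400 cm⁻¹,
1% Gaussian noise (fraction of the dominant peak; the mixture-like preset
uses 1/186 ≈ 0.54%, the signal-to-noise ratio dilute standard mixtures
achieve), 0.2 expected cosmic rays per replicate at 10–100× the noise sd,
a rigid axis offset drawn uniformly in ±12 cm⁻¹, atmospheric N₂/O₂ lines at
0.5×/0.15× the dominant peak, and a 16% unmodelled background for cell-like
targets (0 for mixture-like).  Default component weights (guanine 0.34,
adenine 0.23, cytosine 0.14, thymine/uracil 0.06, Phe 0.09, Trp/Tyr 0.02)
are a plausible bacterial fingerprint composition with the purine bands
dominant.  Standards are synthesised from the built-in dominant-band tables
as pseudo-Voigt lines (η = 0.5) at the 25 cm⁻¹ instrument resolution;
relative heights of optional minor bands are placeholders, not measured
values.

Two generator conventions deserve emphasis:

- **The N₂ line is placed at 2330 cm⁻¹ exactly** — the position the
  recalibration stage defines as reference — so the generator's truth axis
  and the recalibrated axis coincide and truth-recovery tests can compare
  channel by channel.  Physically the band sits ~1 cm⁻¹ higher; a constant
  offset of that size is absorbed into the calibration convention and has
  no effect on any statistic the package reports.
- **The background is built in the "surviving" domain.**  An unmodelled
  background is operationally whatever the processing chain and the
  component fit *cannot* remove: the chain subtracts a global line, and the
  fit subtracts anything in the component span.  The generator therefore
  takes a broad Gaussian bump (center 1300 cm⁻¹, FWHM 600 cm⁻¹, supported
  on the fingerprint window), projects out the affine baseline and the
  span of the processed component spectra, and scales the remainder — by a
  short fixed-point iteration — so its absolute integral is the configured
  fraction of the processed target's absolute integral.  With this
  construction the residual-fraction statistic recovers the configured
  fraction (slope ≈ 0.93 over {0, 0.08, 0.16, 0.24} at full default noise,
  with a ≈0.02 noise floor at zero background), and the fitted coefficients
  are unbiased by the background.  A naive positive bump would instead be
  partly destroyed by the baseline stage and partly absorbed into the
  coefficients, making the "fraction" ill-defined.

What the generator does **not** emulate: resonance Raman cross-section
physics (hypochromism is available only as per-component multipliers,
default off), Poisson shot noise (additive Gaussian only), instrument PSF
beyond the fixed line width, wavelength-dependent throughput, or real
minor-mode structure of the standards.  Passing tests therefore demonstrate
that the *algorithms* behave as specified under the assumed statistical
structure — not that the synthesised spectra match laboratory spectra of
these molecules.

## Composition budget

The built-in table gives, per average exponentially growing cell
(~1000 fg wet mass, 0.9 fL): protein 165 fg with 7.1 mol% aromatic
residues, RNA 60 fg, DNA 9 fg (two genome copies), and a free-metabolite
pool with per-species concentrations.  Two modes:

- `transcribed` (default): tabulated per-unit counts are taken as given —
  fidelity to the source table; summary figures (224 million total units,
  71/29 nucleotide/amino split, 77% of nucleobases in nucleic acids) follow
  by arithmetic and round-half-away-from-zero.
- `derived`: counts recomputed as n = (m/M_residue)·N_A·x for macromolecules
  and n = C·V·N_A for metabolites.  Mean residue masses (protein 108.2 Da,
  RNA 340 Da, DNA 327 Da) are back-calibrated so derived class totals match
  the tabulated ones, and are config-exposed.

Known inconsistencies in the source table are preserved and documented
rather than silently fixed: the tabulated metabolite subtotal (36.4×10⁶)
exceeds the per-unit sum (~35.0×10⁶); the metabolite counts imply a
conversion volume of ≈1.113 fL rather than the stated 0.9 fL (the package
defaults to the implied value, which reproduces the printed counts, with
the cell volume available separately); and the protein share of aromatic
amino acids computed from the table is 99.95%, not the sometimes-quoted
99.4%.  The mixture recipe allocates a 1.00 mM total across 13 components
(5 oligomer, 5 free-nucleotide, 3 amino acid) proportional to residue
counts, conserving the total to 1e-12 and scaling homogeneously.

## Problem sizes and determinism

All statistical checks run on 501-channel fingerprint spectra; the
acceptance script uses 20 seeds for weight recovery and cosmic-ray
accounting, 10 for tier selection, and 3 per setting for the background
dial — sizes at which every estimate above is stable to well inside its
acceptance band while the whole script completes in well under a minute.
Every random draw flows from `numpy.random.default_rng(seed)`; identical
seeds give bit-identical generated files.

## Limitations

- The unmixing assumes standards and target share one axis; resampling is
  linear interpolation only (justified by 25 cm⁻¹ resolution vs ~4 cm⁻¹
  accuracy — higher-order schemes would fit interpolation noise).
- χ² values depend on the normalization convention and channel count and
  are comparable only within one target.
- The atmospheric-line subtraction assumes the calibrated line width; a
  spectrometer with very different resolution requires overriding
  `ATMOSPHERIC_LINE_FWHM` and the fit windows.
- Sulfate internal-standard anchoring (`prepare_measured_standard`) is for
  measured standards only and is a free nonlinear fit (isolated 981 cm⁻¹
  region, where it is well-conditioned).
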