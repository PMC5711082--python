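# Methods

## Dose chain

The package computes CT patient dose in five stages, each behind its own
module.

1. **CTDI metrics** (`ctdose.ctdi`). CTDI100 is the integral of the
   single-rotation longitudinal dose profile over ±50 mm about the
   isocenter divided by min(N·T, 100) mm. The integral is evaluated by
   the trapezoidal rule on the supplied samples, with linear
   interpolation at the ±50 mm window boundaries. The profile's z = 0 is
   its declared isocenter, defaulting to the mid-span of the sampled
   range; no automatic peak-finding is performed, so asymmetric profiles
   are never silently re-centred. Relative CTDI versus collimation is an
   exact table lookup (collimations form a discrete scanner menu, so
   interpolation would invent settings the scanner does not have); the
   reference collimation (16 mm in the bundled generators) must carry a
   factor of exactly 1.0.

2. **Scanner matching** (`ctdose.matching`). The head and body ImPACT
   factors are fixed linear combinations of the centre/periphery-to-air
   CTDI ratios (coefficients 0.4738, 0.8045, intercept +0.0752 for the
   head phantom; 3.5842, 0.6328, −0.0902 for the body phantom). All CTDI
   inputs are normalised per 100 mAs before the ratios are formed. The
   matching rule used by the original worksheet is not published, so the
   match score here is the equally weighted sum of relative absolute
   differences of the head and body factors — symmetric, dimensionless,
   and isolated in a single function so it can be swapped. Matching is
   per kV; when the library lacks the requested kV the nearest available
   kV is used with a warning (equidistant ties resolve to the lower kV).

3. **Dose engine** (`ctdose.engine`). Positions are millimetres along
   the phantom axis, 0 at the head end, slab i occupying [5i, 5(i+1))
   (half-open). Coverage of a scan range is a per-slab weight: 1 for
   fully covered slabs, overlap/thickness for partial end slabs. The
   fractional weighting (rather than nearest-slab rounding) makes organ
   dose exactly additive over abutting ranges. The organ dose is
   CTDIair·(mAs_per_rotation/100)·RelCTDI·Σ coeff·w / p_eff, with
   p_eff = pitch for helical mode and 1 otherwise. Axial-contiguous mode
   tiles the range with collimation-wide rotation windows (warning if
   the range is not a whole number of windows; the last window then
   extends past the requested end, as the real rotation would).
   Volume-axial mode is one rotation whose beam window is centred on the
   requested range. Helical over-ranging is not modelled. The relative
   CTDI is applied multiplicatively to CTDIair; the alternative — a
   collimation-specific re-measurement of CTDIair — is representable by
   editing the scanner's measurement set instead.

4. **Phantom conversion** (`ctdose.conversion`). Conversion factors are
   per-organ ratios of voxel-phantom to stylised-phantom dose, keyed by
   one of 13 examination categories and sex. Organs without a factor are
   dropped from the converted result (with a warning) rather than passed
   through, since passing a stylised dose off as a voxel-phantom dose
   would silently mix phantoms. Male tables omit female-only organs and
   vice versa; the female breast factor is applied even though the
   stylised phantom has no female breasts — encoding that correction is
   the table's responsibility. No interpolation between categories is
   attempted for nonstandard ranges.

5. **Effective dose** (`ctdose.effective`). H_T = D_T·w_R with w_R = 1
   for photons (the single mGy→mSv conversion point). ED is the
   ICRP 103 weighted sum; the weights ship as a versioned JSON file
   validated at load against Σw_T = 1 (to 1e-9). The remainder weight
   (0.12) multiplies the arithmetic mean of the remainder tissues that
   are actually present in the dose map; absent remainder tissues are
   excluded from the mean, with a warning, because slab datasets rarely
   score all of them and counting absences as zeros would bias ED
   downward silently. Sex averaging is tissue-wise: tissues present in
   both sexes average normally, sex-specific tissues (testes/ovaries
   within the gonad entry, prostate, uterus-cervix) enter at half
   weight. An ICRP 60 scheme slot exists in the API but ships no data.

## Synthetic data

Real per-slab Monte Carlo coefficient sets and published conversion
factors are proprietary, so `ctdose.synthetic` generates stand-ins:

- dose profiles sampled at 1 mm over ±150 mm (Gaussian, box, or
  primary-plus-scatter mixture) with a sidecar carrying the closed-form
  window integral, so the trapezoidal path has an exact oracle;
- coefficient matrices with one smooth Gaussian longitudinal profile per
  organ (centre slab distinct per organ, σ of 2–8 slabs, support
  truncated at 4σ, peak coefficients 0.3–1.5), mimicking the localized
  profiles of real datasets but not their anatomy or values;
- scanner measurement sets with head-phantom ratios near unity and much
  lower body-centre ratios, CTDIair growing ∝ kV^2.5 (defaults: 80, 100,
  120, 135 kV; 2–160 mm collimation menu, reference 16 mm);
- conversion-factor tables for all 13 categories × both sexes, factors
  uniform in [0.3, 2.0], plus identity tables;
- reference libraries with one planted entry within 1% of the target's
  factors and all decoys at least 5% away, so the correct winner is
  known by construction.

Every generator is a pure function of its seed. Dataset manifests
(exact organ doses for a protocol catalogue) are computed by
straight-line Python loops that import nothing from the dose engine,
making them independent oracles. Because the coefficients are not
anatomically calibrated, passing tests demonstrate the correctness of
the accumulation, conversion, and weighting arithmetic — not agreement
with any measured patient dose.

## Numerical choices

- Trapezoidal integration is exact for piecewise-linear profiles and
  within 0.1% of the Gaussian closed form at 1 mm sampling; box-profile
  oracles place edges outside the ±50 mm window (or on sample points) so
  the interpolant's closed form is exact.
- Organ doses computed by matrix product agree with the loop-based
  manifests only to floating-point summation order (≲1e-13 relative);
  tests assert at 1e-12.
- Match-score ties break by library order; kV fallback ties break toward
  the lower kV.
- Degenerate inputs (empty libraries, non-overlapping ranges, zero
  stylised doses under a ratio, unlisted collimations) raise
  `ValidationError` with the offending value named.

## Problem sizes

The test suite and acceptance script use 208-slab phantoms with up to 26
organs, libraries of 10–30 entries (50–100 replicates), 100-dataset /
200-protocol sweeps for the engine laws, and 100–500 random maps for the
conversion and weighting oracles; the full run completes in a few
seconds.

## Limitations

Tube-current modulation (AEC), ECG gating, helical over-ranging,
contrast timing, chamber calibration and measurement uncertainty are out
of scope. Conversion factors are only as transferable as the scanner
they were derived on; the package applies whatever table it is given and
cannot correct for effective-energy differences between scanners.
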