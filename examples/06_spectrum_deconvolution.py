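"""19F spectrum synthesis, processing and deconvolution into state
populations.

Generates a two-state spectrum (resonances 400 Hz apart, the scale that
separates inactive from intermediate conformations), adds noise, and
deconvolves it; then demonstrates that 15 Hz exponential apodization adds
exactly 15 Hz to a fitted Lorentzian linewidth."""

from gpcrkit.nmr import (SyntheticSpectrumSpec, apodize_exponential,
                         fid_to_spectrum, fit_lorentzians, make_fid,
                         make_spectrum)

spec = SyntheticSpectrumSpec(components=((-200.0, 60.0, 0.7),
                                         (200.0, 40.0, 0.3)),
                             noise_sd=0.05)
report = fit_lorentzians(make_spectrum(spec, seed=7), 2)
for i, c in enumerate(report.components):
    print(f"state {i}: center {c.center:7.1f} Hz, FWHM {c.fwhm:5.1f} Hz, "
          f"population {c.area_fraction:.3f} +- {c.sd_area_fraction:.3f}")
print("true populations were 0.70 / 0.30")

fid = make_fid([(1000.0, 30.0, 1.0)], dwell=1 / 15_000.0, n_points=4_096)
plain = fit_lorentzians(fid_to_spectrum(fid, 2), 1).components[0].fwhm
broad = fit_lorentzians(fid_to_spectrum(apodize_exponential(fid, 15.0), 2),
                        1).components[0].fwhm
print(f"\nfitted FWHM without apodization: {plain:.1f} Hz; "
      f"with 15 Hz line broadening: {broad:.1f} Hz "
      f"(added {broad - plain:.1f} Hz)")
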