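"""Simulate oocyte concentration-response data and fit the Hill equation.

Generates two synthetic genotypes (wild-type-like EC50 18 µM and a
mutant-like 768 µM), normalizes each oocyte to its own maximal response,
fits I/Imax = A^nH/(A^nH + EC50^nH), and reports the fold-shift.
"""

from pentasite import (DRSimConfig, ec50_fold_change, fit_hill, format_fold,
                       gen_dose_response, normalize_per_oocyte)

fits = {}
for label, ec50, seed in [("wild-type", 18e-6, 1), ("double-mutant", 768e-6, 2)]:
    cfg = DRSimConfig(ec50=ec50, nh=1.2, sigma=0.1, n_oocytes=6)
    data, truth = gen_dose_response(cfg, seed=seed)
    fit = fit_hill(normalize_per_oocyte(data))
    fits[label] = fit
    print(f"{label}: fitted EC50 = {fit.ec50 * 1e6:.1f} uM "
          f"(planted {truth['ec50'] * 1e6:.0f} uM), nH = {fit.nh:.2f}, "
          f"converged = {fit.converged}")

fold = ec50_fold_change(fits["double-mutant"], fits["wild-type"])
print(f"EC50 shift: {format_fold(fold)} ({fold:.1f}x)")
print()
print("With 10% multiplicative noise and 6 oocytes the fitted EC50s land")
print("within a few percent of the planted values, and the fold-shift is")
print("recovered close to the planted ~43x.")
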