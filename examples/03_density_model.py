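"""Fit the log-linear ONL density model and back-transform with smearing.

ONL nuclei density (cells/mm) is modelled as 10*log10(CD) = A + B*ORr by
OLS in dB space.  The fold-scale diagnostics are the multiplicative RMSE
factor F = 10^(RMSE/10) and Duan's smearing factor S (mean back-transformed
residual), which corrects the naive back-transform toward the conditional
mean.
"""

import numpy as np

from orrquant import SectionSpec, fit_log_linear, generate_section, predict_density

orr, counts = [], []
for seed in range(8):
    _, truth = generate_section(
        SectionSpec(length_um=6000.0, condition="treated", seed=seed),
        render=False)
    keep = truth.regions["onl_per_mm"] > 0
    orr.extend(truth.regions.loc[keep, "orr_true"])
    counts.extend(truth.regions.loc[keep, "onl_per_mm"])

fit = fit_log_linear(orr, counts)
print(f"n = {fit.n} regions")
print(f"10*log10(CD_ONL) = {fit.A:.2f} + {fit.B:.2f} * ORr")
print(f"R2_dB = {fit.r2_db:.3f}, RMSE = {fit.rmse_db:.2f} dB")
print(f"F = {fit.F:.2f}x (fold error), S = {fit.S:.3f} (Duan smearing)")
for v in (0.2, 0.44, 0.6):
    print(f"  ORr {v:.2f}: median-style {predict_density(fit, v):7.1f}, "
          f"smeared mean {predict_density(fit, v, smeared=True):7.1f} cells/mm")
print("\nThe smeared prediction exceeds the median-style back-transform by")
print("the factor S, as expected for log-symmetric residuals.")
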