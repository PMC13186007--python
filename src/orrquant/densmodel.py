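"""Log-linear ONL cell-density model with dB diagnostics and Duan smearing.

ONL nuclei density (cells per mm of retina) is modelled against ORr in
decibel space:

    10 * log10(CD_ONL) = A + B * ORr + eps

fitted by ordinary least squares on the dB-transformed densities.  Fit
quality is reported in the transformed space (R², RMSE in dB) together
with two fold-scale diagnostics:

* ``F = 10**(rmse_db / 10)`` — the multiplicative RMSE factor, the typical
  fold-error of a back-transformed prediction;
* ``S = mean(10**(r / 10))`` over residuals ``r`` — Duan's smearing factor,
  which multiplies the naive back-transform ``10**((A + B*ORr)/10)`` to
  estimate the conditional *mean* density rather than its median.  For any
  least-squares fit with an intercept the residuals are mean-zero, so
  S >= 1 by Jensen's inequality; for Gaussian residuals of SD sigma dB,
  S -> exp((sigma * ln(10) / 10)**2 / 2) as n grows.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from typing import Iterable

import numpy as np

DB_PER_DECADE = 10.0  # power-style dB convention: 10*log10, not 20*log10


@dataclass(frozen=True)
class DensityFit:
    """OLS fit of dB ONL density on ORr, with dB-space diagnostics."""

    A: float            # intercept, dB of cells/mm
    B: float            # slope, dB per unit ORr
    r2_db: float        # coefficient of determination, dB space
    rmse_db: float      # root mean square residual, dB
    F: float            # multiplicative RMSE factor, fold
    S: float            # Duan smearing factor, fold
    n: int

    def to_dict(self) -> dict:
        return asdict(self)


def smearing_factor(residuals_db: Iterable[float]) -> float:
    """Duan smearing factor: mean back-transform of dB residuals."""
    r = np.asarray(list(residuals_db), dtype=float)
    if r.size == 0:
        raise ValueError("no residuals")
    return float(np.mean(10.0 ** (r / DB_PER_DECADE)))


def fit_log_linear(
    orr: Iterable[float],
    density: Iterable[float],
    *,
    rmse_ddof: int = 0,
) -> DensityFit:
    """Fit ``10*log10(density) = A + B*orr`` by ordinary least squares.

    Parameters
    ----------
    orr, density
        Paired observations; densities must be strictly positive (regions
        with an uncountable ONL are excluded upstream).
    rmse_ddof
        Denominator adjustment for the RMSE: 0 (default) divides by n,
        2 divides by n - 2 (residual degrees of freedom).

    Raises
    ------
    ValueError
        On non-positive densities (reported with their indices), fewer
        than 3 observations, or zero ORr variance (slope unidentifiable).
    """
    x = np.asarray(list(orr), dtype=float)
    d = np.asarray(list(density), dtype=float)
    if x.shape != d.shape or x.ndim != 1:
        raise ValueError("orr and density must be 1-D and paired")
    bad = np.nonzero(~(d > 0))[0]
    if bad.size:
        raise ValueError(f"non-positive density at indices {bad.tolist()}")
    if x.size < 3:
        raise ValueError("need at least 3 observations")
    if np.ptp(x) == 0:
        raise ValueError("zero ORr variance: slope unidentifiable")

    y = DB_PER_DECADE * np.log10(d)
    X = np.column_stack([np.ones_like(x), x])
    (a, b), *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - (a + b * x)
    sse = float(resid @ resid)
    sst = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - sse / sst if sst > 0 else float("nan")
    denom = x.size - rmse_ddof
    if denom <= 0:
        raise ValueError("rmse_ddof leaves no residual degrees of freedom")
    rmse = float(np.sqrt(sse / denom))
    return DensityFit(
        A=float(a),
        B=float(b),
        r2_db=float(r2),
        rmse_db=rmse,
        F=float(10.0 ** (rmse / DB_PER_DECADE)),
        S=smearing_factor(resid),
        n=int(x.size),
    )


def predict_density(
    fit: DensityFit, orr: float | np.ndarray, smeared: bool = False
) -> float | np.ndarray:
    """Back-transformed density prediction at ``orr`` (cells per mm).

    The unsmeared prediction ``10**((A + B*orr)/10)`` estimates the
    conditional median under symmetric dB residuals; with ``smeared=True``
    it is multiplied by the Duan factor S to target the conditional mean.
    """
    orr_arr = np.asarray(orr, dtype=float)
    if np.any((orr_arr < 0) | (orr_arr > 1)):
        raise ValueError("orr must lie in [0, 1]")
    pred = 10.0 ** ((fit.A + fit.B * orr_arr) / DB_PER_DECADE)
    if smeared:
        pred = pred * fit.S
    return float(pred) if np.isscalar(orr) or orr_arr.ndim == 0 else pred
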