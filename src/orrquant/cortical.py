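"""Cortical activation thresholds and d' spatial selectivity.

For each stimulating electrode, multi-channel cortical spike counts are
recorded at increasing stimulus currents.  The per-channel *threshold* is
the injected current eliciting 50% of the channel's maximum spike count in
the 3–20 ms post-stimulus window; the electrode's *best threshold* is the
minimum finite channel threshold across both hemispheres.  Spatial
selectivity d' is the rate of reduction of max-normalised firing with
Euclidean distance (mm) from the best channel, computed within the best
channel's hemisphere: the negative least-squares slope of normalised firing
versus distance.  Both metrics are invariant to uniform scaling of spike
counts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

DEFAULT_NOISE_FLOOR = 5.0  # spikes: channels never exceeding this are unresponsive

#: Sentinel for channels/electrodes with no measurable response.
NO_RESPONSE = float("nan")


@dataclass
class CorticalResponse:
    """Spike counts versus stimulus current for one stimulating electrode.

    ``table`` columns: channel, hemisphere ('ipsi'|'contra'), x_mm, y_mm,
    current_uA, spikes.  Currents must be strictly increasing within each
    channel and spike counts non-negative.
    """

    stim_electrode_id: str
    table: pd.DataFrame = field(repr=False)

    REQUIRED = ("channel", "hemisphere", "x_mm", "y_mm", "current_uA", "spikes")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.table.columns]
        if missing:
            raise ValueError(f"spike table missing columns: {missing}")
        if (self.table["spikes"] < 0).any():
            raise ValueError("spike counts must be non-negative")
        for ch, sub in self.table.groupby("channel"):
            cur = sub["current_uA"].to_numpy()
            if np.any(np.diff(cur) <= 0):
                raise ValueError(f"currents not strictly increasing on channel {ch}")

    def channels(self) -> list:
        return list(self.table["channel"].unique())

    def channel_data(self, channel) -> tuple[np.ndarray, np.ndarray]:
        sub = self.table[self.table["channel"] == channel]
        return sub["current_uA"].to_numpy(float), sub["spikes"].to_numpy(float)

    def channel_info(self, channel) -> pd.Series:
        return self.table[self.table["channel"] == channel].iloc[0]


@dataclass(frozen=True)
class SelectivityEstimate:
    """d' spatial selectivity of one electrode's cortical activation map."""

    d_prime: float          # reduction in normalised firing per mm
    best_channel_id: object
    n_channels_used: int


def _logistic(i, m, t, s):
    from scipy.special import expit

    return m * expit((i - t) / s)


def _interp_threshold(currents: np.ndarray, counts: np.ndarray) -> float:
    """Current at the first crossing of 50% of the empirical maximum."""
    half = counts.max() / 2.0
    idx = np.nonzero(counts >= half)[0][0]
    if idx == 0 or counts[idx] == half:
        return float(currents[idx])
    c0, c1 = counts[idx - 1], counts[idx]
    i0, i1 = currents[idx - 1], currents[idx]
    return float(i0 + (half - c0) / (c1 - c0) * (i1 - i0))


def channel_threshold(
    currents: np.ndarray,
    spike_counts: np.ndarray,
    *,
    method: str = "sigmoid",
    noise_floor: float = DEFAULT_NOISE_FLOOR,
) -> float:
    """Current (uA) eliciting 50% of a channel's maximum spike count.

    ``method="sigmoid"`` (default) least-squares fits a monotone logistic
    with floor 0 and fitted ceiling and returns its midpoint (the current
    at 50% of the fitted maximum), falling back to linear interpolation
    between the bracketing current levels when the fit fails;
    ``method="interp"`` uses interpolation directly.  Channels whose
    maximum count stays below ``noise_floor`` return the NO_RESPONSE
    sentinel (NaN).  The result is invariant to scaling the counts (the
    floor scales with them).
    """
    currents = np.asarray(currents, dtype=float)
    counts = np.asarray(spike_counts, dtype=float)
    if currents.size != counts.size or currents.size < 3:
        raise ValueError("need >= 3 paired current levels")
    if np.any(np.diff(currents) <= 0):
        raise ValueError("currents must be strictly increasing")
    if np.any(counts < 0):
        raise ValueError("spike counts must be non-negative")
    if counts.max() <= 0 or counts.max() < noise_floor:
        return NO_RESPONSE

    if method == "interp":
        return _interp_threshold(currents, counts)
    if method != "sigmoid":
        raise ValueError(f"unknown method {method!r}")

    m0 = counts.max()
    t0 = _interp_threshold(currents, counts)
    s0 = max(np.ptp(currents) / 10.0, 1.0)
    try:
        popt, _ = curve_fit(
            _logistic,
            currents,
            counts,
            p0=[m0, t0, s0],
            bounds=([0, currents.min(), 1e-6], [10 * m0, currents.max(), np.ptp(currents)]),
            maxfev=5000,
        )
    except (RuntimeError, ValueError):
        return _interp_threshold(currents, counts)
    m, t, _s = popt
    if m < noise_floor:
        return NO_RESPONSE
    return float(t)


def best_threshold(
    response: CorticalResponse,
    *,
    method: str = "sigmoid",
    noise_floor: float = DEFAULT_NOISE_FLOOR,
) -> float:
    """Minimum finite channel threshold across both hemispheres (uA)."""
    best = np.inf
    for ch in response.channels():
        cur, cnt = response.channel_data(ch)
        thr = channel_threshold(cur, cnt, method=method, noise_floor=noise_floor)
        if np.isfinite(thr) and thr < best:
            best = thr
    return float(best) if np.isfinite(best) else NO_RESPONSE


def firing_falloff_slope(
    distances_mm: np.ndarray, normalized_firing: np.ndarray
) -> float:
    """d' from a firing map: negative LS slope of normalised firing vs distance."""
    d = np.asarray(distances_mm, dtype=float)
    f = np.asarray(normalized_firing, dtype=float)
    if d.size != f.size or d.size < 3:
        raise ValueError("need >= 3 channels for a falloff slope")
    if np.ptp(d) == 0:
        return 0.0
    slope = np.polyfit(d, f, 1)[0]
    return float(-slope)


def _firing_at(currents: np.ndarray, counts: np.ndarray, current: float) -> float:
    """Spike count at an arbitrary current by linear interpolation."""
    return float(np.interp(current, currents, counts))


def dprime_selectivity(
    response: CorticalResponse,
    evaluation_current: float | None = None,
    *,
    method: str = "sigmoid",
    noise_floor: float = DEFAULT_NOISE_FLOOR,
) -> SelectivityEstimate:
    """d' selectivity: falloff of normalised firing with distance from the
    best channel, within the best channel's hemisphere.

    Firing is read at ``evaluation_current`` (default: twice the best
    threshold, clipped to the measured range) on every channel of that
    hemisphere, normalised to the best channel's firing, and regressed on
    Euclidean distance (mm) from the best channel; d' is the negative
    slope.  Spatially uniform firing gives d' = 0; scaling all counts by a
    positive constant leaves d' unchanged.
    """
    thresholds = {}
    for ch in response.channels():
        cur, cnt = response.channel_data(ch)
        thr = channel_threshold(cur, cnt, method=method, noise_floor=noise_floor)
        if np.isfinite(thr):
            thresholds[ch] = thr
    if not thresholds:
        raise ValueError("no responsive channel")
    best_ch = min(thresholds, key=thresholds.get)
    info = response.channel_info(best_ch)
    hemi = info["hemisphere"]
    bx, by = float(info["x_mm"]), float(info["y_mm"])

    hemi_channels = [
        ch for ch in response.channels()
        if response.channel_info(ch)["hemisphere"] == hemi
    ]
    if len(hemi_channels) < 3:
        raise ValueError("need >= 3 channels in the best hemisphere")

    cur_b, cnt_b = response.channel_data(best_ch)
    if evaluation_current is None:
        evaluation_current = 2.0 * thresholds[best_ch]
    evaluation_current = float(np.clip(evaluation_current, cur_b.min(), cur_b.max()))
    f_best = _firing_at(cur_b, cnt_b, evaluation_current)
    if f_best <= 0:
        raise ValueError("best channel fires zero spikes at the evaluation current")

    dists, firing = [], []
    for ch in hemi_channels:
        cur, cnt = response.channel_data(ch)
        info_c = response.channel_info(ch)
        dists.append(np.hypot(float(info_c["x_mm"]) - bx, float(info_c["y_mm"]) - by))
        firing.append(_firing_at(cur, cnt, evaluation_current) / f_best)
    d_prime = firing_falloff_slope(np.asarray(dists), np.asarray(firing))
    return SelectivityEstimate(
        d_prime=d_prime, best_channel_id=best_ch, n_channels_used=len(hemi_channels)
    )
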