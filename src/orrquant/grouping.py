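"""Normative ORr threshold and degeneration-group assignment.

Control eyes define a normative band of ORr values; the classification
threshold is the control mean minus two standard deviations.  Every region
of a treated eye is then graded:

====== ============ =========================================
group  name         rule (mean ORr)
====== ============ =========================================
0      control      condition is control, regardless of ORr
1      none         >= threshold
2      mild         threshold > ORr >= 0.35
3      moderate     0.35 > ORr >= 0.2
4      severe       ORr < 0.2
====== ============ =========================================

Lower bounds are closed.  The mild/moderate (0.35) and moderate/severe
(0.2) cutoffs are configuration, defaulting to the conventional values.
Regions whose layers could not be delineated (unmeasurable) receive the
sentinel "indeterminate" label and are excluded from group statistics.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .geometry import RegionMeasurement

GROUP_NAMES = {0: "control", 1: "none", 2: "mild", 3: "moderate", 4: "severe"}

DEFAULT_CUTOFFS = (0.35, 0.2)  # (mild/moderate, moderate/severe)
DEFAULT_SD_MULTIPLIER = 2.0


@dataclass(frozen=True)
class NormativeModel:
    """Control-eye ORr summary defining the classification threshold."""

    mu_control: float
    sigma_control: float
    threshold: float
    n_control: int

    def __post_init__(self) -> None:
        recomputed = self.mu_control - DEFAULT_SD_MULTIPLIER * self.sigma_control
        # threshold may use a non-default multiplier; only sanity-check order
        if self.sigma_control > 0 and self.threshold >= self.mu_control:
            raise ValueError("threshold must lie below the control mean")
        del recomputed


@dataclass(frozen=True)
class GroupLabel:
    """Degeneration group of one region; ``value`` is None when indeterminate."""

    value: int | None
    name: str

    def __int__(self) -> int:
        if self.value is None:
            raise ValueError("indeterminate group has no integer value")
        return self.value


INDETERMINATE = GroupLabel(None, "indeterminate")


def fit_normative(
    control_orr: Iterable[float],
    sd_multiplier: float = DEFAULT_SD_MULTIPLIER,
) -> NormativeModel:
    """Fit the normative model from pooled control-region mean ORr values.

    The threshold is ``mean - sd_multiplier * SD`` with the sample (n-1)
    standard deviation.  Values must lie in [0, 1].
    """
    vals = np.asarray(list(control_orr), dtype=float)
    if vals.size < 2:
        raise ValueError("need at least 2 control ORr values")
    if np.any((vals < 0) | (vals > 1) | ~np.isfinite(vals)):
        raise ValueError("control ORr values must lie in [0, 1]")
    mu = float(np.mean(vals))
    sigma = float(np.std(vals, ddof=1))
    return NormativeModel(
        mu_control=mu,
        sigma_control=sigma,
        threshold=mu - sd_multiplier * sigma,
        n_control=int(vals.size),
    )


def normative_percentile(model: NormativeModel) -> float:
    """Percentile of the threshold under a normal model of the controls.

    For the default mean − 2 SD threshold this is 100·Φ(−2) ≈ 2.275,
    conventionally reported as the 2.3rd percentile.
    """
    if model.sigma_control <= 0:
        raise ValueError("percentile undefined for zero control SD")
    z = (model.threshold - model.mu_control) / model.sigma_control
    return float(100.0 * sps.norm.cdf(z))


def classify_orr(
    mean_orr: float,
    condition: str,
    model: NormativeModel,
    cutoffs: Sequence[float] = DEFAULT_CUTOFFS,
) -> GroupLabel:
    """Group label for a single mean ORr value (see module table)."""
    if condition == "control":
        return GroupLabel(0, GROUP_NAMES[0])
    if not np.isfinite(mean_orr):
        return INDETERMINATE
    mild, severe = cutoffs
    if not (model.threshold > mild > severe):
        raise ValueError(
            "cutoffs must decrease strictly below the normative threshold"
        )
    if mean_orr >= model.threshold:
        value = 1
    elif mean_orr >= mild:
        value = 2
    elif mean_orr >= severe:
        value = 3
    else:
        value = 4
    return GroupLabel(value, GROUP_NAMES[value])


def classify_region(
    measurement: RegionMeasurement,
    model: NormativeModel,
    cutoffs: Sequence[float] = DEFAULT_CUTOFFS,
) -> GroupLabel:
    """Group label for a measured region; unmeasurable → indeterminate."""
    if not measurement.measurable:
        return INDETERMINATE
    if measurement.condition is None:
        raise ValueError(f"region {measurement.region_id} has no condition")
    return classify_orr(measurement.mean_orr, measurement.condition, model, cutoffs)


def group_distribution(
    labels: Sequence[GroupLabel],
    eye_ids: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Per-eye and pooled group counts and proportions.

    Indeterminate regions are excluded from the table (their count is
    logged by the pipeline).  Returns a tidy frame with columns
    ``(eye_id, group, count, proportion)`` including a pooled ``"all"``
    eye; proportions sum to 1 within each eye.
    """
    if not labels:
        raise ValueError("no labels to summarise")
    per_eye = eye_ids is not None
    if eye_ids is None:
        eye_ids = ["all"] * len(labels)
    rows = [
        {"eye_id": e, "group": lab.value}
        for e, lab in zip(eye_ids, labels)
        if lab.value is not None
    ]
    if not rows:
        raise ValueError("all labels indeterminate")
    df = pd.DataFrame(rows)
    frames = []
    scopes = [("all", df)]
    if per_eye:
        scopes += [(e, g) for e, g in df.groupby("eye_id")]
    for scope, sub in scopes:
        counts = sub.groupby("group").size()
        frames.append(
            pd.DataFrame(
                {
                    "eye_id": scope,
                    "group": counts.index,
                    "count": counts.values,
                    "proportion": counts.values / counts.values.sum(),
                }
            )
        )
    out = pd.concat(frames, ignore_index=True)
    return out.sort_values(["eye_id", "group"]).reset_index(drop=True)
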