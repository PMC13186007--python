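"""Retinal layer geometry: boundary profiles, region windows, and the ORr.

The Outer Retina ratio (ORr) is the thickness of the outer retina — outer
segments (OS), inner segments (IS), outer nuclear layer (ONL) and outer
plexiform layer (OPL) — divided by the total retinal thickness from the
inner limiting membrane (ILM) to the outer edge of the OS.  Because it is a
ratio of nested extents measured along the same image column, it is
invariant to uniform scaling of thicknesses, which makes it robust to
oblique sectioning and to normal thickness variation with eccentricity.

Conventions
-----------
* Image orientation: row 0 is the vitread (ILM) side; depth increases
  toward the sclera.  Columns run along the section (lateral axis).
* All lateral positions and depths are in microns.  The ILM is treated as
  the inner bounding surface and contributes no thickness band of its own.
* Thickness is measured along the image column (vertical), not the local
  surface normal; the ratio absorbs minor obliqueness.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

logger = logging.getLogger(__name__)

#: Boundary surfaces in anatomical order, vitread to sclerad.
BOUNDARY_NAMES: tuple[str, ...] = (
    "ILM",
    "GCL/IPL",
    "IPL/INL",
    "INL/OPL",
    "OPL/ONL",
    "ONL/IS",
    "IS/OS",
    "OS/edge",
)

#: Layer bands delimited by consecutive boundaries, vitread to sclerad.
LAYER_NAMES: tuple[str, ...] = ("GCL", "IPL", "INL", "OPL", "ONL", "IS", "OS")

#: Bands whose summed thickness defines the outer retina.
OUTER_LAYERS: tuple[str, ...] = ("OPL", "ONL", "IS", "OS")

#: Integer labels used in label-mask images (0 = background).
LAYER_LABELS: dict[str, int] = {name: i + 1 for i, name in enumerate(LAYER_NAMES)}

DEFAULT_REGION_LENGTH_UM = 250.0
DEFAULT_SAMPLE_INTERVAL_UM = 50.0


class ProfileError(ValueError):
    """Raised when layer boundaries are inconsistent (crossing, negative)."""


@dataclass(frozen=True)
class LayerProfile:
    """Named layer-boundary curves of one retinal cross-section.

    Parameters
    ----------
    x : ndarray, shape (n,)
        Strictly increasing lateral sample positions, microns.
    depths : ndarray, shape (8, n)
        Depth of each boundary in :data:`BOUNDARY_NAMES` order at each
        ``x``, microns from the image's vitread reference.  Rows must be
        non-decreasing down the array (boundaries must not cross).
    px_per_um : float
        Pixel calibration of the source image (pixels per micron).
    """

    x: np.ndarray
    depths: np.ndarray
    px_per_um: float = 1.0

    def __post_init__(self) -> None:
        x = np.asarray(self.x, dtype=float)
        depths = np.asarray(self.depths, dtype=float)
        object.__setattr__(self, "x", x)
        object.__setattr__(self, "depths", depths)
        if x.ndim != 1 or x.size < 2:
            raise ProfileError("profile needs >= 2 lateral samples")
        if np.any(np.diff(x) <= 0):
            raise ProfileError("lateral positions must be strictly increasing")
        if depths.shape != (len(BOUNDARY_NAMES), x.size):
            raise ProfileError(
                f"depths must have shape ({len(BOUNDARY_NAMES)}, {x.size})"
            )
        if self.px_per_um <= 0:
            raise ProfileError("px_per_um must be positive")
        bad = np.diff(depths, axis=0) < 0
        if np.any(bad):
            i, j = np.argwhere(bad)[0]
            raise ProfileError(
                f"boundaries cross: {BOUNDARY_NAMES[i + 1]} rises above "
                f"{BOUNDARY_NAMES[i]} near x={x[j]:.1f} um"
            )

    @property
    def extent(self) -> tuple[float, float]:
        """Lateral extent ``(x_min, x_max)`` in microns."""
        return float(self.x[0]), float(self.x[-1])

    def boundary_depths(self, x: float | np.ndarray) -> np.ndarray:
        """Linearly interpolated depth of every boundary at ``x`` (microns)."""
        x = np.asarray(x, dtype=float)
        lo, hi = self.extent
        if np.any(x < lo) or np.any(x > hi):
            raise ValueError(f"x outside profile extent [{lo}, {hi}] um")
        return np.stack([np.interp(x, self.x, d) for d in self.depths])

    @classmethod
    def from_label_mask(
        cls, mask: np.ndarray, px_per_um: float = 1.0
    ) -> "LayerProfile":
        """Build boundary curves from an integer label mask.

        Each column is scanned for the extremal rows of every layer label
        (values of :data:`LAYER_LABELS`); boundaries are placed at band
        edges.  Columns missing any band are excluded from the profile.
        """
        mask = np.asarray(mask)
        if mask.ndim != 2:
            raise ProfileError("label mask must be 2-D")
        ncols = mask.shape[1]
        xs: list[float] = []
        cols: list[list[float]] = []
        for c in range(ncols):
            col = mask[:, c]
            tops: list[float] = []
            bottom = None
            ok = True
            for name in LAYER_NAMES:
                rows = np.nonzero(col == LAYER_LABELS[name])[0]
                if rows.size == 0:
                    ok = False
                    break
                tops.append(rows[0] / px_per_um)
                bottom = (rows[-1] + 1) / px_per_um
            if not ok:
                continue
            xs.append((c + 0.5) / px_per_um)
            cols.append(tops + [bottom])
        if len(xs) < 2:
            raise ProfileError("label mask yields fewer than 2 usable columns")
        return cls(np.asarray(xs), np.asarray(cols).T, px_per_um=px_per_um)

    @classmethod
    def from_polylines(cls, data: dict, px_per_um: float = 1.0) -> "LayerProfile":
        """Build a profile from a polyline JSON dict.

        ``data`` maps each boundary name to ``{"x": [...], "depth": [...]}``
        in microns; curves are resampled onto the common overlapping grid.
        """
        missing = [n for n in BOUNDARY_NAMES if n not in data]
        if missing:
            raise ProfileError(f"polyline input missing boundaries: {missing}")
        lo = max(min(data[n]["x"]) for n in BOUNDARY_NAMES)
        hi = min(max(data[n]["x"]) for n in BOUNDARY_NAMES)
        if hi <= lo:
            raise ProfileError("boundary polylines do not overlap laterally")
        grid = np.linspace(lo, hi, max(int(round(hi - lo)), 2))
        depths = np.stack(
            [
                np.interp(grid, np.asarray(data[n]["x"], float),
                          np.asarray(data[n]["depth"], float))
                for n in BOUNDARY_NAMES
            ]
        )
        return cls(grid, depths, px_per_um=px_per_um)

    @classmethod
    def from_polyline_json(cls, path, px_per_um: float = 1.0) -> "LayerProfile":
        with open(path) as fh:
            return cls.from_polylines(json.load(fh), px_per_um=px_per_um)


@dataclass
class RegionMeasurement:
    """ORr measurement of one region window (default 250 um).

    ``sample_orr`` holds the per-interval ORr samples; ``mean_orr`` is their
    arithmetic mean.  ``measurable`` is False when any sample had zero total
    thickness (severe degeneration defeating layer delineation), in which
    case the summary values are NaN.
    """

    region_id: str
    x_start: float
    length: float = DEFAULT_REGION_LENGTH_UM
    sample_orr: tuple[float, ...] = field(default_factory=tuple)
    mean_orr: float = float("nan")
    sd_orr: float = float("nan")
    eye_id: str | None = None
    condition: str | None = None
    electrode_id: str | None = None
    in_pocket: bool = False
    measurable: bool = True


def layer_thicknesses(profile: LayerProfile, x: float) -> dict[str, float]:
    """Thickness of every layer band at lateral position ``x`` (microns).

    Returns the seven bands of :data:`LAYER_NAMES` plus the aggregate
    ``"OR"`` (OS + IS + ONL + OPL), ``"total"`` (ILM surface to OS outer
    edge) and ``"orr"`` (OR / total; NaN when total is zero).
    """
    d = profile.boundary_depths(float(x)).ravel()
    bands = np.diff(d)
    if np.any(bands < 0):  # defensive; construction already rejects crossing
        raise ProfileError(f"negative band thickness at x={x}")
    out = {name: float(t) for name, t in zip(LAYER_NAMES, bands)}
    out["OR"] = sum(out[n] for n in OUTER_LAYERS)
    out["total"] = float(d[-1] - d[0])
    out["orr"] = out["OR"] / out["total"] if out["total"] > 0 else float("nan")
    return out


def orr_at(profile: LayerProfile, x: float | np.ndarray) -> np.ndarray:
    """Vectorised ORr at lateral position(s) ``x``; NaN where total is 0."""
    d = profile.boundary_depths(np.atleast_1d(np.asarray(x, float)))
    total = d[-1] - d[0]
    outer = d[-1] - d[3]  # INL/OPL boundary to OS outer edge
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(total > 0, outer / total, np.nan)


def segment_regions(
    profile: LayerProfile,
    region_length: float = DEFAULT_REGION_LENGTH_UM,
) -> list[tuple[float, float]]:
    """Split the profile extent into adjacent ``region_length`` windows.

    Windows are half-open ``[x_start, x_start + region_length)``, left
    aligned to the profile's ``x_min``; a trailing remainder shorter than
    one region is discarded (and logged).
    """
    if region_length <= 0:
        raise ValueError("region_length must be positive")
    lo, hi = profile.extent
    extent = hi - lo
    n = int(np.floor(extent / region_length + 1e-9))
    if n < 1:
        raise ValueError(
            f"extent {extent:.1f} um shorter than one region ({region_length} um)"
        )
    windows = [(lo + i * region_length, lo + (i + 1) * region_length) for i in range(n)]
    remainder = extent - n * region_length
    if remainder > 1e-9:
        logger.info(
            "discarding trailing remainder of %.1f um (< one %g um region)",
            remainder, region_length,
        )
    return windows


def region_orr(
    profile: LayerProfile,
    window: tuple[float, float],
    interval: float = DEFAULT_SAMPLE_INTERVAL_UM,
    *,
    region_id: str | None = None,
    eye_id: str | None = None,
    condition: str | None = None,
    electrode_id: str | None = None,
    in_pocket: bool = False,
) -> RegionMeasurement:
    """Sample ORr across one region window and summarise it.

    ORr is sampled at the midpoints of consecutive ``interval``-wide bins
    (for a 250 um window at 50 um intervals: x_start + 25, 75, 125, 175,
    225), so adjacent regions never share a sample point.  The mean and SD
    of the samples are stored.  A region where any sample has zero total
    thickness is flagged unmeasurable.
    """
    x0, x1 = window
    lo, hi = profile.extent
    if x0 < lo - 1e-9 or x1 > hi + 1e-9:
        raise ValueError(f"window {window} outside profile extent [{lo}, {hi}]")
    if interval <= 0 or x1 - x0 < interval:
        raise ValueError("interval must be positive and fit inside the window")
    n = int(np.floor((x1 - x0) / interval + 1e-9))
    xs = x0 + interval * (np.arange(n) + 0.5)
    xs = np.clip(xs, lo, hi)
    samples = orr_at(profile, xs)
    rid = region_id if region_id is not None else f"r{x0:.0f}"
    measurable = bool(np.all(np.isfinite(samples)))
    return RegionMeasurement(
        region_id=rid,
        x_start=float(x0),
        length=float(x1 - x0),
        sample_orr=tuple(float(s) for s in samples),
        mean_orr=float(np.mean(samples)) if measurable else float("nan"),
        sd_orr=float(np.std(samples, ddof=1)) if measurable and n > 1 else float("nan"),
        eye_id=eye_id,
        condition=condition,
        electrode_id=electrode_id,
        in_pocket=in_pocket,
        measurable=measurable,
    )


def measure_section(
    profile: LayerProfile,
    *,
    region_length: float = DEFAULT_REGION_LENGTH_UM,
    interval: float = DEFAULT_SAMPLE_INTERVAL_UM,
    eye_id: str | None = None,
    condition: str | None = None,
    electrode_map: dict[int, str] | None = None,
    pocket_regions: Sequence[int] = (),
) -> list[RegionMeasurement]:
    """Segment a section and measure ORr for every region.

    ``electrode_map`` maps region index to a stimulating-electrode id (dye
    marking metadata); ``pocket_regions`` lists region indices overlying the
    suprachoroidal pocket.
    """
    electrode_map = electrode_map or {}
    pockets = set(pocket_regions)
    out = []
    for i, window in enumerate(segment_regions(profile, region_length)):
        out.append(
            region_orr(
                profile,
                window,
                interval,
                region_id=f"{eye_id or 'eye'}_{i:03d}",
                eye_id=eye_id,
                condition=condition,
                electrode_id=electrode_map.get(i),
                in_pocket=i in pockets or i in electrode_map,
            )
        )
    return out
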