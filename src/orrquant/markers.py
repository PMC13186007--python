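"""Marker quantification: fluorescence intensity, nuclei counts, DAB area.

Implements the per-region quantification rules used downstream of ORr
grading:

* fluorescence immunoreactivity as a background-subtracted layer-mask mean
  (the choroid supplies the background estimate), normalised per animal to
  that animal's control-eye mean;
* nuclei counting on the DAPI channel by automatic (Otsu) thresholding,
  distance-transform watershed splitting of touching nuclei, and an
  area/circularity particle filter, reported per mm of retina length;
* marker-positive nuclei by a pixelwise overlap rule (a nucleus is positive
  when at least a fraction of its pixels exceed an intensity threshold);
* DAB-positive area per retinal length from RGB images, classifying brown
  chromogen pixels by colour deconvolution with standard
  hematoxylin-DAB stain vectors and an optical-density threshold (a plain
  hue-window rule is available as an alternative);
* the RBPMS-positive to total GCL nuclei ratio.

Photoreceptor-marker quantification is refused for severely degenerated
(group 4) or indeterminate regions, where the outer retinal layers cannot
be reliably delineated.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from skimage.color import rgb2hed
from skimage.feature import peak_local_max
from skimage.filters import threshold_otsu
from skimage.measure import label as cc_label, regionprops
from skimage.segmentation import watershed

from .grouping import GroupLabel


class Group4ExclusionError(ValueError):
    """Photoreceptor markers are not quantified in group-4/indeterminate regions."""


@dataclass
class MarkerMeasurement:
    """One marker x layer x region quantification."""

    marker: str
    layer: str
    kind: str  # normalized_intensity | area_per_length | count | count_per_mm | ratio
    value: float
    region_id: str | None = None
    eye_id: str | None = None
    below_background: bool = False


@dataclass
class NucleusSet:
    """Watershed-split nuclei of one layer band.

    ``labels`` is the labelled mask (0 = background); ``props`` has one row
    per nucleus with columns (label, centroid_x_um, centroid_y_um,
    area_um2, circularity).
    """

    labels: np.ndarray
    props: pd.DataFrame

    def __len__(self) -> int:
        return len(self.props)


def assert_photoreceptor_analyzable(group: GroupLabel | int | None) -> None:
    """Reject group-4 and indeterminate regions for photoreceptor markers."""
    value = group.value if isinstance(group, GroupLabel) else group
    if value is None or value == 4:
        raise Group4ExclusionError(
            "photoreceptor markers are not analyzed in group-4 or "
            "indeterminate regions (outer layers cannot be delineated)"
        )


def fluorescence_intensity(
    channel: np.ndarray,
    target_mask: np.ndarray,
    choroid_mask: np.ndarray,
) -> float:
    """Background-subtracted mean intensity of a layer mask.

    Background is the mean intensity of the choroid mask; the result may be
    negative when the target falls below background (not clamped — the
    caller flags it).  Adding a constant offset to the whole image leaves
    the result unchanged.
    """
    channel = np.asarray(channel, dtype=float)
    target_mask = np.asarray(target_mask, dtype=bool)
    choroid_mask = np.asarray(choroid_mask, dtype=bool)
    if not target_mask.any() or not choroid_mask.any():
        raise ValueError("target and choroid masks must be non-empty")
    if (target_mask & choroid_mask).any():
        raise ValueError("target and choroid masks must be disjoint")
    return float(channel[target_mask].mean() - channel[choroid_mask].mean())


def normalize_to_control(value: float, control_values: Iterable[float]) -> float:
    """Normalise a background-subtracted intensity to the animal's control mean.

    ``control_values`` are background-subtracted intensities from all
    control-eye images of the same animal and marker.
    """
    ctrl = np.asarray(list(control_values), dtype=float)
    if ctrl.size == 0:
        raise ValueError("no control values")
    mean = float(ctrl.mean())
    if mean <= 0:
        raise ValueError(f"control mean must be positive, got {mean}")
    return float(value) / mean


def _mask_lateral_length_um(mask: np.ndarray, px_per_um: float) -> float:
    """Lateral extent of a mask in microns (columns containing mask pixels)."""
    cols = np.nonzero(mask.any(axis=0))[0]
    return cols.size / px_per_um if cols.size else 0.0


def count_nuclei(
    dapi: np.ndarray,
    layer_mask: np.ndarray,
    px_per_um: float = 1.0,
    *,
    min_area_um2: float = 0.0,
    circularity: tuple[float, float] = (0.0, 1.0),
    min_distance_um: float = 3.0,
    threshold: float | None = None,
) -> tuple[NucleusSet, float]:
    """Count DAPI nuclei in a layer band; returns (NucleusSet, count per mm).

    Foreground is selected by Otsu's threshold on the masked band (or an
    explicit ``threshold``); touching nuclei are split by a distance-
    transform watershed seeded at distance peaks at least
    ``min_distance_um`` apart; components are then filtered by area and
    circularity (``4*pi*area / perimeter**2``).  With ``min_area_um2=0``
    and circularity ``(0, 1)`` no shape filtering occurs and the count is
    the raw post-watershed component count.  The count is normalised by
    the lateral mask length in mm.
    """
    dapi = np.asarray(dapi, dtype=float)
    layer_mask = np.asarray(layer_mask, dtype=bool)
    if px_per_um <= 0:
        raise ValueError("px_per_um must be positive")
    if not layer_mask.any():
        raise ValueError("layer mask is empty")
    band = dapi[layer_mask]
    if threshold is None:
        if np.ptp(band) == 0:
            # flat band: everything fore- or background; flag via empty set
            threshold = np.inf if band.max() == 0 else band.max() - 1
        else:
            threshold = threshold_otsu(band)
    fg = (dapi > threshold) & layer_mask

    if not fg.any():
        empty = pd.DataFrame(
            columns=["label", "centroid_x_um", "centroid_y_um", "area_um2",
                     "circularity"]
        )
        return NucleusSet(np.zeros_like(dapi, dtype=int), empty), 0.0

    distance = ndi.distance_transform_edt(fg)
    min_dist_px = max(int(round(min_distance_um * px_per_um)), 1)
    peaks = peak_local_max(
        distance, min_distance=min_dist_px, labels=fg, exclude_border=False
    )
    seeds = np.zeros_like(distance, dtype=int)
    for i, (r, c) in enumerate(peaks, start=1):
        seeds[r, c] = i
    if seeds.max() == 0:
        labels = cc_label(fg)
    else:
        labels = watershed(-distance, seeds, mask=fg)

    um2_per_px = 1.0 / px_per_um**2
    rows = []
    lo_c, hi_c = circularity
    for p in regionprops(labels):
        area_um2 = p.area * um2_per_px
        perim = p.perimeter
        circ = 4.0 * np.pi * p.area / perim**2 if perim > 0 else 1.0
        circ = min(circ, 1.0)  # discretization can push slightly above 1
        if area_um2 < min_area_um2 or not (lo_c <= circ <= hi_c):
            labels[labels == p.label] = 0
            continue
        rows.append(
            {
                "label": p.label,
                "centroid_x_um": p.centroid[1] / px_per_um,
                "centroid_y_um": p.centroid[0] / px_per_um,
                "area_um2": area_um2,
                "circularity": circ,
            }
        )
    props = pd.DataFrame(
        rows, columns=["label", "centroid_x_um", "centroid_y_um", "area_um2",
                       "circularity"]
    )
    length_mm = _mask_lateral_length_um(layer_mask, px_per_um) / 1000.0
    count_per_mm = len(props) / length_mm if length_mm > 0 else float("nan")
    return NucleusSet(labels, props), count_per_mm


def positive_nuclei(
    nuclei: NucleusSet,
    channel: np.ndarray,
    intensity_threshold: float,
    overlap_fraction: float = 0.5,
) -> tuple[int, list[int]]:
    """Count nuclei positive for a co-registered marker channel.

    A nucleus is positive when at least ``overlap_fraction`` of its pixels
    exceed ``intensity_threshold``.  Returns (count, positive labels).
    """
    channel = np.asarray(channel, dtype=float)
    if channel.shape != nuclei.labels.shape:
        raise ValueError("marker channel and nuclei labels must be co-registered")
    if not 0 < overlap_fraction <= 1:
        raise ValueError("overlap_fraction must lie in (0, 1]")
    if channel.size and not (channel.min() <= intensity_threshold <= channel.max()):
        import warnings

        warnings.warn(
            "intensity threshold outside marker channel range", stacklevel=2
        )
    positive = []
    for lab in nuclei.props["label"].astype(int):
        px = channel[nuclei.labels == lab]
        if px.size and np.mean(px > intensity_threshold) >= overlap_fraction:
            positive.append(int(lab))
    return len(positive), positive


# Optical-density stain vectors (rows: hematoxylin, eosin, DAB) matching the
# standard H-DAB deconvolution basis used by rgb2hed.
DEFAULT_DAB_OD_THRESHOLD = 0.15


def dab_positive_area(
    rgb: np.ndarray,
    layer_mask: np.ndarray,
    px_per_um: float = 1.0,
    *,
    od_threshold: float = DEFAULT_DAB_OD_THRESHOLD,
    rule: str = "deconvolution",
    hue_window: tuple[float, float] = (0.02, 0.13),
    min_saturation: float = 0.25,
) -> float:
    """DAB-positive area per retinal length (um^2 per um) within a layer mask.

    ``rule="deconvolution"`` (default) separates the image into
    hematoxylin/eosin/DAB optical densities with the standard stain matrix
    and classifies pixels whose DAB density exceeds ``od_threshold``.
    ``rule="hue"`` instead classifies brown pixels by an HSV hue window
    with a minimum saturation; blue hematoxylin hues fall outside either
    rule.  The positive pixel area (um^2) is divided by the lateral mask
    length (um).
    """
    rgb = np.asarray(rgb)
    if rgb.ndim != 3 or rgb.shape[-1] != 3:
        raise ValueError("DAB quantification needs a 3-channel RGB image")
    layer_mask = np.asarray(layer_mask, dtype=bool)
    if not layer_mask.any():
        raise ValueError("layer mask is empty")
    if rgb.dtype != np.float64:
        rgb = rgb.astype(float) / np.iinfo(rgb.dtype).max if rgb.dtype.kind == "u" \
            else rgb.astype(float)

    if rule == "deconvolution":
        # rgb2hed scales stain OD by 1/-log10(1e-6); undo it so the
        # threshold is in true base-10 optical-density units
        dab_od = rgb2hed(rgb)[..., 2] * -np.log10(1e-6)
        positive = dab_od > od_threshold
    elif rule == "hue":
        from skimage.color import rgb2hsv

        hsv = rgb2hsv(rgb)
        lo, hi = hue_window
        positive = (
            (hsv[..., 0] >= lo) & (hsv[..., 0] <= hi)
            & (hsv[..., 1] >= min_saturation)
        )
    else:
        raise ValueError(f"unknown DAB rule {rule!r}")

    positive &= layer_mask
    area_um2 = positive.sum() / px_per_um**2
    length_um = _mask_lateral_length_um(layer_mask, px_per_um)
    return float(area_um2 / length_um)


def rbpms_ratio(rbpms_positive_count: float, gcl_nuclei_count: float) -> float:
    """RBPMS-positive nuclei as a fraction of total GCL nuclei."""
    if gcl_nuclei_count <= 0:
        raise ValueError("GCL nuclei count must be positive")
    ratio = float(rbpms_positive_count) / float(gcl_nuclei_count)
    if not 0 <= ratio <= 1:
        raise ValueError("positive count exceeds total GCL nuclei")
    return ratio
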