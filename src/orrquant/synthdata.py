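"""Synthetic retinal-section and cortical-response generator.

Generates layered cross-section image stacks (structure label mask, DAPI,
fluorescent marker, DAB RGB), exact ground-truth layer boundaries and
region tables, and per-electrode cortical spike-count tables with the
statistical structure the analysis pipeline assumes — so every downstream
stage can be exercised and validated without tissue.

The generator's statistical defaults encode the study conditions the
analysis targets:

* control regions draw mean ORr from Normal(0.55, 0.05) truncated to
  [0.39, 0.69];
* treated regions are assigned degeneration groups 1–4 from a target
  mixture, spatially arranged by a smoothed random field (Gaussian-filtered
  white noise, default correlation length 500 um) so severe and intact
  patches adjoin as in real heterogeneous degeneration;
* ONL nuclei per mm follow 10**((A + B*ORr + eps)/10) with A = 20.86 dB,
  B = 25.56 dB per ORr unit and Gaussian dB residuals (default SD 1.96);
* per-group marker effects (outer-segment opsin loss, ectopic opsin-positive
  ONL nuclei, inner-retinal DAB area, RBPMS/GCL ratio) follow the observed
  directionality of degeneration;
* per-group cortical thresholds rise with degeneration severity
  (82.43, 88.64, 98.25, 117.25, 124.26 uA for groups 0–4).

Image orientation: row 0 is the vitread (ILM) side; columns run along the
section.  All geometry is rendered so that per-column layer thicknesses
reproduce the target ORr field to within half a pixel.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from scipy import stats as sps
from scipy.optimize import brentq

from .geometry import (
    BOUNDARY_NAMES,
    LAYER_LABELS,
    LAYER_NAMES,
    LayerProfile,
    DEFAULT_REGION_LENGTH_UM,
    DEFAULT_SAMPLE_INTERVAL_UM,
)

# ---------------------------------------------------------------------------
# study-condition constants

CONTROL_ORR_MEAN = 0.55
CONTROL_ORR_SD = 0.05
CONTROL_ORR_RANGE = (0.39, 0.69)

DENSITY_A_DB = 20.86
DENSITY_B_DB = 25.56
DENSITY_RESID_SD_DB = 1.96

#: Target treated group mixture (groups 1-4), matching the observed
#: 272/220/263/79 split of treated regions.
DEFAULT_GROUP_MIXTURE = (272 / 834, 220 / 834, 263 / 834, 79 / 834)

#: ORr intervals from which treated group values are drawn.  A small margin
#: is kept clear of the group boundaries so that sub-pixel measurement
#: error cannot flip a region's ground-truth group.
GROUP_ORR_INTERVALS = {
    1: (0.455, 0.64),
    2: (0.355, 0.445),
    3: (0.205, 0.345),
    4: (0.02, 0.195),
}

#: Reference normative threshold implied by the control distribution
#: (mean - 2 SD); used to grade explicit user-supplied ORr fields.
REFERENCE_THRESHOLD = CONTROL_ORR_MEAN - 2 * CONTROL_ORR_SD

#: Per-group mean best cortical thresholds (uA).
GROUP_CORTICAL_THRESHOLD_UA = {0: 82.43, 1: 88.64, 2: 98.25, 3: 117.25, 4: 124.26}

#: Per-group d' selectivity targets (normalised firing reduction per mm).
GROUP_DPRIME = {0: 0.54, 1: 0.54, 2: 0.63, 3: 0.64, 4: 0.57}


@dataclass(frozen=True)
class MarkerEffects:
    """Per-group multiplicative marker effects and event rates."""

    os_intensity: float      # outer-segment opsin intensity, fold of control
    ectopic_rate: float      # fraction of ONL nuclei with ectopic opsin
    dab_area_per_um: float   # inner-retina DAB-positive area, um^2 per um
    rbpms_fraction: float    # RBPMS-positive fraction of GCL nuclei


#: Degeneration-severity directionality: opsin falls, ectopic nuclei and
#: inner-retinal DAB area rise, RBPMS/GCL ratio drops ~44% in treated eyes.
DEFAULT_MARKER_EFFECTS: dict[int, MarkerEffects] = {
    0: MarkerEffects(1.00, 0.01, 0.50, 0.60),
    1: MarkerEffects(0.85, 0.06, 0.60, 0.336),
    2: MarkerEffects(0.70, 0.12, 0.80, 0.336),
    3: MarkerEffects(0.55, 0.20, 1.20, 0.336),
    4: MarkerEffects(0.40, 0.30, 1.50, 0.336),
}


@dataclass(frozen=True)
class NucleiModel:
    """dB-space ONL density model parameters."""

    A_db: float = DENSITY_A_DB
    B_db: float = DENSITY_B_DB
    residual_sd_db: float = DENSITY_RESID_SD_DB


@dataclass
class SectionSpec:
    """Parameters of one synthetic retinal cross-section.

    ``orr_field`` may be None (condition-dependent sampling), a constant,
    a callable of lateral position (um), or an array sampled on the pixel
    grid; values must lie in [0, 1].  ``layer_fractions`` give relative
    band thicknesses within the outer (OS/IS/ONL/OPL) and inner
    (INL/IPL/GCL) compartments and must each sum to 1.
    """

    length_um: float = 2000.0
    px_per_um: float = 2.0
    condition: str = "treated"  # 'control' | 'treated'
    orr_field: float | Callable | np.ndarray | None = None
    outer_fractions: Mapping[str, float] = field(
        default_factory=lambda: {"OS": 0.2, "IS": 0.2, "ONL": 0.4, "OPL": 0.2}
    )
    inner_fractions: Mapping[str, float] = field(
        default_factory=lambda: {"INL": 0.3, "IPL": 0.5, "GCL": 0.2}
    )
    total_thickness_um: float = 200.0
    nuclei_model: NucleiModel = field(default_factory=NucleiModel)
    marker_effects: Mapping[int, MarkerEffects] = field(
        default_factory=lambda: dict(DEFAULT_MARKER_EFFECTS)
    )
    group_mixture: Sequence[float] = DEFAULT_GROUP_MIXTURE
    correlation_length_um: float = 500.0
    region_length_um: float = DEFAULT_REGION_LENGTH_UM
    nucleus_radius_um: float = 2.0
    max_nucleus_overlap: float = 0.6
    inl_nuclei_per_mm: float = 420.0
    gcl_nuclei_per_mm: float = 120.0
    marker_base_intensity: float = 150.0
    choroid_intensity: float = 20.0
    choroid_thickness_um: float = 30.0
    margin_um: float = 10.0
    seed: int = 0

    def validate(self) -> None:
        if self.length_um < self.region_length_um:
            raise ValueError("section shorter than one region")
        if self.px_per_um <= 0:
            raise ValueError("px_per_um must be positive")
        if self.condition not in ("control", "treated"):
            raise ValueError(f"unknown condition {self.condition!r}")
        for name, fr in (("outer", self.outer_fractions),
                         ("inner", self.inner_fractions)):
            if abs(sum(fr.values()) - 1.0) > 1e-9:
                raise ValueError(f"{name} layer fractions must sum to 1")
        if any(v < 0 for v in self.outer_fractions.values()):
            raise ValueError("layer fractions must be non-negative")
        if isinstance(self.orr_field, (int, float)):
            if not 0 <= self.orr_field <= 1:
                raise ValueError("orr_field values must lie in [0, 1]")
        mix = np.asarray(self.group_mixture, float)
        if mix.size != 4 or np.any(mix < 0) or abs(mix.sum() - 1) > 1e-9:
            raise ValueError("group_mixture must be 4 non-negative proportions summing to 1")


@dataclass
class SectionImages:
    """Rendered channels of one synthetic section.

    ``labels``: integer layer mask (values of geometry.LAYER_LABELS);
    ``dapi`` and ``marker``: float32 fluorescence channels; ``dab``: uint8
    RGB brightfield image; ``choroid_mask``: boolean mask of the rendered
    choroid band (background reference for intensity quantification).
    """

    labels: np.ndarray
    dapi: np.ndarray
    marker: np.ndarray
    dab: np.ndarray
    choroid_mask: np.ndarray
    px_per_um: float

    def save_tiff(self, path) -> None:
        """Write a multi-page TIFF: labels, DAPI, marker, DAB-RGB."""
        import tifffile

        with tifffile.TiffWriter(path) as tw:
            tw.write(self.labels.astype(np.uint8))
            tw.write(np.clip(self.dapi, 0, 255).astype(np.uint8))
            tw.write(np.clip(self.marker, 0, 255).astype(np.uint8))
            tw.write(self.dab)


@dataclass
class GroundTruth:
    """Exact scene truth for one synthetic section."""

    profile: LayerProfile
    regions: pd.DataFrame          # per-region truths (ORr, group, counts, ...)
    nuclei: pd.DataFrame           # per-nucleus (x_um, y_um, layer, region, positive)
    scene: dict                    # generator parameters for provenance


# ---------------------------------------------------------------------------
# helpers


def _overlap_fraction(u: float) -> float:
    """Pairwise disk-overlap fraction at centre distance 2*u*r."""
    return (2.0 / np.pi) * (np.arccos(u) - u * np.sqrt(1 - u * u))


def min_center_separation(radius: float, max_overlap: float) -> float:
    """Centre distance below which two equal disks overlap more than
    ``max_overlap`` of one disk's area."""
    if not 0 < max_overlap < 1:
        raise ValueError("max_overlap must lie in (0, 1)")
    u = brentq(lambda v: _overlap_fraction(v) - max_overlap, 1e-9, 1 - 1e-9)
    return 2.0 * radius * u


def _thin_points(xy: np.ndarray, min_sep: float) -> np.ndarray:
    """Greedy hard-core thinning (grid-accelerated): keep points >= min_sep apart."""
    if len(xy) == 0:
        return np.empty((0, 2))
    cell = min_sep
    grid: dict[tuple[int, int], list] = {}
    kept: list = []
    sep2 = min_sep * min_sep
    for p in xy:
        ci, cj = int(p[0] // cell), int(p[1] // cell)
        ok = True
        for di in (-1, 0, 1):
            if not ok:
                break
            for dj in (-1, 0, 1):
                for q in grid.get((ci + di, cj + dj), ()):
                    if (p[0] - q[0]) ** 2 + (p[1] - q[1]) ** 2 < sep2:
                        ok = False
                        break
                if not ok:
                    break
        if ok:
            kept.append(p)
            grid.setdefault((ci, cj), []).append(p)
    return np.asarray(kept) if kept else np.empty((0, 2))


def _render_disks(
    shape: tuple[int, int],
    centers_px: np.ndarray,
    radius_px: float,
    intensity: float | np.ndarray,
) -> np.ndarray:
    """Anti-aliased disks: per-pixel coverage ramps over one pixel at the rim."""
    img = np.zeros(shape, dtype=np.float32)
    if centers_px.size == 0:
        return img
    r_int = int(np.ceil(radius_px + 1))
    inten = np.broadcast_to(np.asarray(intensity, float), (len(centers_px),))
    for (cy, cx), amp in zip(centers_px, inten):
        y0, y1 = int(np.floor(cy)) - r_int, int(np.ceil(cy)) + r_int + 1
        x0, x1 = int(np.floor(cx)) - r_int, int(np.ceil(cx)) + r_int + 1
        y0c, x0c = max(y0, 0), max(x0, 0)
        y1c, x1c = min(y1, shape[0]), min(x1, shape[1])
        if y1c <= y0c or x1c <= x0c:
            continue
        yy, xx = np.mgrid[y0c:y1c, x0c:x1c]
        dist = np.hypot(yy + 0.5 - cy, xx + 0.5 - cx)
        cov = np.clip(radius_px + 0.5 - dist, 0.0, 1.0)
        patch = img[y0c:y1c, x0c:x1c]
        np.maximum(patch, (amp * cov).astype(np.float32), out=patch)
    return img


def _smoothed_noise(n: int, sigma_samples: float, rng: np.random.Generator) -> np.ndarray:
    z = rng.standard_normal(n)
    g = ndi.gaussian_filter1d(z, sigma=max(sigma_samples, 1e-6), mode="reflect")
    sd = g.std()
    return g / sd if sd > 0 else g


def _grade(orr: float) -> int:
    """Reference group for an explicit ORr value (treated condition)."""
    if orr >= REFERENCE_THRESHOLD:
        return 1
    if orr >= 0.35:
        return 2
    if orr >= 0.2:
        return 3
    return 4


# ---------------------------------------------------------------------------
# ORr field construction


def _sample_region_orr(
    spec: SectionSpec, n_regions: int, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Draw per-region target ORr and ground-truth group labels."""
    if spec.condition == "control":
        a = (CONTROL_ORR_RANGE[0] - CONTROL_ORR_MEAN) / CONTROL_ORR_SD
        b = (CONTROL_ORR_RANGE[1] - CONTROL_ORR_MEAN) / CONTROL_ORR_SD
        vals = sps.truncnorm.rvs(
            a, b, loc=CONTROL_ORR_MEAN, scale=CONTROL_ORR_SD,
            size=n_regions, random_state=rng,
        )
        return vals, np.zeros(n_regions, dtype=int)

    # treated: spatially correlated group assignment from the target mixture
    sigma_regions = spec.correlation_length_um / spec.region_length_um
    fieldvals = _smoothed_noise(n_regions, sigma_regions, rng)
    order = np.argsort(np.argsort(fieldvals))  # rank 0..n-1, high rank = high ORr
    # group counts from the mixture (largest-remainder rounding)
    mix = np.asarray(spec.group_mixture, float)
    raw = mix * n_regions
    counts = np.floor(raw).astype(int)
    for i in np.argsort(raw - counts)[::-1][: n_regions - counts.sum()]:
        counts[i] += 1
    # low ranks -> severe groups (group 4 first)
    group_by_rank = np.concatenate(
        [np.full(c, g) for g, c in zip((4, 3, 2, 1), counts[::-1])]
    )
    groups = group_by_rank[order]
    vals = np.empty(n_regions)
    for i, g in enumerate(groups):
        lo, hi = GROUP_ORR_INTERVALS[int(g)]
        vals[i] = rng.uniform(lo, hi)
    return vals, groups.astype(int)


def _resolve_orr_field(
    spec: SectionSpec, x_um: np.ndarray, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-pixel ORr field plus per-region (target orr, group) arrays."""
    n_regions = int(np.floor(spec.length_um / spec.region_length_um + 1e-9))
    region_idx = np.minimum(
        (x_um / spec.region_length_um).astype(int), n_regions - 1
    )
    if spec.orr_field is None:
        region_vals, groups = _sample_region_orr(spec, n_regions, rng)
        fld = region_vals[region_idx]
    else:
        if callable(spec.orr_field):
            fld = np.asarray([spec.orr_field(x) for x in x_um], dtype=float)
        elif np.ndim(spec.orr_field) == 0:
            fld = np.full_like(x_um, float(spec.orr_field))
        else:
            fld = np.asarray(spec.orr_field, dtype=float)
            if fld.shape != x_um.shape:
                raise ValueError("orr_field array must match the pixel grid")
        if np.any((fld < 0) | (fld > 1)):
            raise ValueError("orr_field values must lie in [0, 1]")
        region_vals = np.array(
            [fld[region_idx == i].mean() for i in range(n_regions)]
        )
        if spec.condition == "control":
            groups = np.zeros(n_regions, dtype=int)
        else:
            groups = np.array([_grade(v) for v in region_vals], dtype=int)
    return fld, region_vals, groups


# ---------------------------------------------------------------------------
# section generation


def generate_section(
    spec: SectionSpec, seed: int | None = None, *, render: bool = True
) -> tuple[SectionImages | None, GroundTruth]:
    """Render one synthetic section and its exact ground truth.

    The inner retina (INL+IPL+GCL) has fixed thickness
    ``total_thickness_um * (1 - 0.55)``; the outer compartment thickness is
    set per column so that the outer/total ratio equals the target ORr
    field, i.e. degeneration thins the outer retina and the total shrinks
    with it.  Rendering assigns each pixel to the band containing its
    centre, reproducing per-column thicknesses within half a pixel.

    With ``render=False`` the image channels are skipped (images is None)
    and only geometry and nuclei truth are produced; the DAB area truth,
    which is defined by the rendering, is then NaN.

    Returns ``(SectionImages, GroundTruth)``; two calls with the same spec
    and seed are bit-identical.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    ppu = spec.px_per_um
    width_px = int(round(spec.length_um * ppu))
    x_um = (np.arange(width_px) + 0.5) / ppu

    fld, region_orr_target, region_groups = _resolve_orr_field(spec, x_um, rng)

    inner_um = spec.total_thickness_um * (1.0 - CONTROL_ORR_MEAN)
    with np.errstate(divide="ignore"):
        outer_um = np.where(fld < 1.0, inner_um * fld / (1.0 - fld), np.inf)
    outer_um = np.minimum(outer_um, 5.0 * spec.total_thickness_um)

    # boundary depth curves, vitread to sclerad (um from image top)
    inner_cum = np.cumsum(
        [spec.inner_fractions[n] for n in ("GCL", "IPL", "INL")]
    )
    outer_cum = np.cumsum(
        [spec.outer_fractions[n] for n in ("OPL", "ONL", "IS", "OS")]
    )
    depths = np.empty((len(BOUNDARY_NAMES), width_px))
    depths[0] = spec.margin_um                               # ILM
    for k, f in enumerate(inner_cum):                         # GCL/IPL .. INL/OPL
        depths[1 + k] = spec.margin_um + f * inner_um
    base = spec.margin_um + inner_um
    for k, f in enumerate(outer_cum):                         # OPL/ONL .. OS/edge
        depths[4 + k] = base + f * outer_um

    # ground-truth profile spans the full [0, length] extent (edge-padded
    # beyond the outermost pixel centres) so region segmentation sees the
    # nominal section length
    x_prof = np.concatenate([[0.0], x_um, [spec.length_um]])
    depths_prof = np.concatenate(
        [depths[:, :1], depths, depths[:, -1:]], axis=1
    )
    profile = LayerProfile(x=x_prof, depths=depths_prof, px_per_um=ppu)

    max_depth = depths[-1].max()
    height_px = int(np.ceil((max_depth + spec.choroid_thickness_um
                             + spec.margin_um) * ppu))
    shape = (height_px, width_px)

    # label mask: assign each pixel centre to its band
    row_um = (np.arange(height_px) + 0.5)[:, None] / ppu       # (H, 1)
    labels = np.zeros(shape, dtype=np.uint8)
    for k, name in enumerate(LAYER_NAMES):
        inside = (row_um >= depths[k][None, :]) & (row_um < depths[k + 1][None, :])
        labels[inside] = LAYER_LABELS[name]
    choroid_mask = (row_um >= depths[-1][None, :]) & (
        row_um < depths[-1][None, :] + spec.choroid_thickness_um
    )

    n_regions = len(region_orr_target)
    region_idx_px = np.minimum(
        (x_um / spec.region_length_um).astype(int), n_regions - 1
    )

    # ---- nuclei -----------------------------------------------------------
    nm = spec.nuclei_model
    r_um = spec.nucleus_radius_um
    min_sep = min_center_separation(r_um, spec.max_nucleus_overlap)
    nuc_rows: list[dict] = []
    onl_counts = np.zeros(n_regions, dtype=int)
    eps_db = rng.normal(0.0, nm.residual_sd_db, size=n_regions)

    def place_in_band(n_target: int, x_lo: float, x_hi: float,
                      top: np.ndarray, bot: np.ndarray) -> np.ndarray:
        """Uniform placement in a band with hard-core thinning."""
        if n_target <= 0:
            return np.empty((0, 2))
        # oversample, thin, truncate to target
        n_try = int(np.ceil(n_target * 2.5)) + 8
        xs = rng.uniform(x_lo, x_hi, size=n_try)
        cols = np.clip((xs * ppu).astype(int), 0, width_px - 1)
        t, b = top[cols], bot[cols]
        usable = b - t > 2 * r_um
        frac = rng.uniform(size=n_try)
        ys = t + r_um + frac * np.maximum(b - t - 2 * r_um, 0.0)
        pts = np.column_stack([xs, ys])[usable]
        pts = _thin_points(pts, min_sep)
        return pts[:n_target]

    # ONL nuclei: density from the dB model per region
    onl_top = depths[BOUNDARY_NAMES.index("OPL/ONL")]
    onl_bot = depths[BOUNDARY_NAMES.index("ONL/IS")]
    for i in range(n_regions):
        orr_i = region_orr_target[i]
        dens = 10.0 ** ((nm.A_db + nm.B_db * orr_i + eps_db[i]) / 10.0)
        # count is deterministic given the dB residual, so the rendered
        # density is exactly the model's draw (no extra placement noise)
        n_target = int(round(dens * spec.region_length_um / 1000.0))
        x_lo = i * spec.region_length_um
        x_hi = min((i + 1) * spec.region_length_um, spec.length_um)
        pts = place_in_band(n_target, x_lo, x_hi, onl_top, onl_bot)
        onl_counts[i] = len(pts)
        eff = spec.marker_effects[int(region_groups[i])]
        pos = rng.uniform(size=len(pts)) < eff.ectopic_rate
        for (px_x, px_y), p in zip(pts, pos):
            nuc_rows.append({"x_um": px_x, "y_um": px_y, "layer": "ONL",
                             "region": i, "marker_positive": bool(p)})

    # INL and GCL nuclei at fixed per-mm densities; GCL nuclei carry the
    # RBPMS-positive flag at the group's target fraction
    for layer, top, bot, per_mm in (
        ("INL",
         depths[BOUNDARY_NAMES.index("IPL/INL")],
         depths[BOUNDARY_NAMES.index("INL/OPL")],
         spec.inl_nuclei_per_mm),
        ("GCL",
         depths[BOUNDARY_NAMES.index("ILM")],
         depths[BOUNDARY_NAMES.index("GCL/IPL")],
         spec.gcl_nuclei_per_mm),
    ):
        for i in range(n_regions):
            n_target = int(rng.poisson(per_mm * spec.region_length_um / 1000.0))
            x_lo = i * spec.region_length_um
            x_hi = min((i + 1) * spec.region_length_um, spec.length_um)
            pts = place_in_band(n_target, x_lo, x_hi, top, bot)
            eff = spec.marker_effects[int(region_groups[i])]
            if layer == "GCL":
                pos = rng.uniform(size=len(pts)) < eff.rbpms_fraction
            else:
                pos = np.zeros(len(pts), dtype=bool)
            for (px_x, px_y), p in zip(pts, pos):
                nuc_rows.append({"x_um": px_x, "y_um": px_y, "layer": layer,
                                 "region": i, "marker_positive": bool(p)})

    nuclei = pd.DataFrame(
        nuc_rows, columns=["x_um", "y_um", "layer", "region", "marker_positive"]
    )

    # ---- channels ---------------------------------------------------------
    images = None
    dab_area_true = np.full(n_regions, np.nan)
    if render:
        images, dab_area_true = _render_channels(
            spec, rng, shape, labels, choroid_mask, nuclei,
            region_groups, region_idx_px, n_regions,
        )

    # ---- region truth table ----------------------------------------------
    interval = DEFAULT_SAMPLE_INTERVAL_UM
    n_samp = int(spec.region_length_um // interval)
    region_rows = []
    gcl_counts = np.zeros(n_regions, dtype=int)
    rbpms_counts = np.zeros(n_regions, dtype=int)
    inl_counts = np.zeros(n_regions, dtype=int)
    if len(nuclei):
        for i in range(n_regions):
            sub = nuclei[nuclei["region"] == i]
            gcl = sub[sub["layer"] == "GCL"]
            gcl_counts[i] = len(gcl)
            rbpms_counts[i] = int(gcl["marker_positive"].sum())
            inl_counts[i] = len(sub[sub["layer"] == "INL"])
    for i in range(n_regions):
        x0 = i * spec.region_length_um
        xs = x0 + interval * (np.arange(n_samp) + 0.5)
        cols = np.clip((xs * ppu).astype(int), 0, width_px - 1)
        orr_true = float(np.mean(fld[cols]))
        g = int(region_groups[i])
        eff = spec.marker_effects[g]
        region_rows.append({
            "region": i,
            "x_start_um": x0,
            "orr_true": orr_true,
            "group_true": g,
            "onl_count": int(onl_counts[i]),
            "onl_per_mm": onl_counts[i] / (spec.region_length_um / 1000.0),
            "os_marker_intensity":
                spec.marker_base_intensity * eff.os_intensity,
            "os_effect": eff.os_intensity,
            "n_marker_positive_onl": int(
                nuclei[(nuclei["region"] == i) & (nuclei["layer"] == "ONL")
                       ]["marker_positive"].sum()
            ) if len(nuclei) else 0,
            "dab_area_per_um": dab_area_true[i] / spec.region_length_um,
            "inl_count": int(inl_counts[i]),
            "gcl_count": int(gcl_counts[i]),
            "rbpms_count": int(rbpms_counts[i]),
        })
    regions = pd.DataFrame(region_rows)

    scene = {
        "condition": spec.condition,
        "length_um": spec.length_um,
        "px_per_um": ppu,
        "total_thickness_um": spec.total_thickness_um,
        "nuclei_model": asdict(spec.nuclei_model),
        "seed": int(spec.seed if seed is None else seed),
        "orientation": "row 0 = vitread (ILM) side",
    }

    truth = GroundTruth(profile=profile, regions=regions, nuclei=nuclei,
                        scene=scene)
    return images, truth


def _render_channels(
    spec: SectionSpec,
    rng: np.random.Generator,
    shape: tuple[int, int],
    labels: np.ndarray,
    choroid_mask: np.ndarray,
    nuclei: pd.DataFrame,
    region_groups: np.ndarray,
    region_idx_px: np.ndarray,
    n_regions: int,
) -> tuple[SectionImages, np.ndarray]:
    """Render DAPI, fluorescent-marker and DAB channels for a section."""
    ppu = spec.px_per_um
    r_px = spec.nucleus_radius_um * ppu
    centers_px = np.column_stack(
        [nuclei["y_um"].to_numpy() * ppu, nuclei["x_um"].to_numpy() * ppu]
    ) if len(nuclei) else np.empty((0, 2))

    dapi = _render_disks(shape, centers_px, r_px, 200.0)
    dapi += 5.0  # tissue autofluorescence floor

    # fluorescent marker: OS band at group-scaled intensity above the choroid
    # background (so background subtraction recovers base * effect exactly),
    # plus ectopic marker-positive nuclei
    marker = np.full(shape, 5.0, dtype=np.float32)
    os_mask = labels == LAYER_LABELS["OS"]
    group_px = region_groups[region_idx_px]
    os_int_col = np.array(
        [spec.choroid_intensity
         + spec.marker_base_intensity * spec.marker_effects[int(g)].os_intensity
         for g in group_px]
    )
    marker_os = np.broadcast_to(os_int_col[None, :], shape)
    marker = np.where(os_mask, marker_os, marker).astype(np.float32)
    marker[choroid_mask] = spec.choroid_intensity
    if len(nuclei):
        posmask = nuclei["marker_positive"].to_numpy()
        ect = _render_disks(shape, centers_px[posmask], r_px,
                            spec.marker_base_intensity)
        marker = np.maximum(marker, ect)

    # DAB RGB: hematoxylin background + brown patches in the IPL, painted to
    # a per-group target area per retinal length
    from skimage.color import rgb_from_hed

    hed = np.zeros(shape + (3,), dtype=float)
    tissue = labels > 0
    hed[..., 0][tissue] = 0.35                     # hematoxylin concentration
    ipl_mask = labels == LAYER_LABELS["IPL"]
    dab_conc = np.zeros(shape, dtype=float)
    dab_area_true = np.zeros(n_regions)
    patch_r_px = max(int(round(2.0 * ppu)), 1)
    for i in range(n_regions):
        eff = spec.marker_effects[int(region_groups[i])]
        target_px = eff.dab_area_per_um * spec.region_length_um * ppu**2
        cols = np.nonzero(region_idx_px == i)[0]
        sub_ipl = np.zeros(shape, dtype=bool)
        sub_ipl[:, cols] = ipl_mask[:, cols]
        rows_av, cols_av = np.nonzero(sub_ipl)
        painted = 0
        attempts = 0
        while painted < target_px and rows_av.size and attempts < 500:
            attempts += 1
            j = rng.integers(rows_av.size)
            rr, cc = rows_av[j], cols_av[j]
            y0, y1 = max(rr - patch_r_px, 0), min(rr + patch_r_px + 1, shape[0])
            x0, x1 = max(cc - patch_r_px, 0), min(cc + patch_r_px + 1, shape[1])
            patch = sub_ipl[y0:y1, x0:x1] & (dab_conc[y0:y1, x0:x1] == 0)
            newly = int(patch.sum())
            if newly == 0:
                continue
            dab_conc[y0:y1, x0:x1][patch] = 0.6
            painted += newly
        dab_area_true[i] = painted / ppu**2
    hed[..., 2] = dab_conc
    od = hed @ rgb_from_hed  # stain concentrations -> RGB optical density
    rgb = np.power(10.0, -od)
    dab_img = np.clip(rgb * 255, 0, 255).astype(np.uint8)

    images = SectionImages(
        labels=labels,
        dapi=dapi.astype(np.float32),
        marker=marker.astype(np.float32),
        dab=dab_img,
        choroid_mask=choroid_mask,
        px_per_um=ppu,
    )
    return images, dab_area_true


# ---------------------------------------------------------------------------
# cortical generation


DEFAULT_CURRENTS_UA = tuple(np.arange(0.0, 751.0, 25.0))


def generate_cortical(
    group_mean_ua: float,
    group_label: int = 0,
    n_channels: int = 24,
    seed: int = 0,
    *,
    between_sd_ua: float = 20.0,
    falloff_per_mm: float = 0.5,
    channel_jitter_ua: float = 3.0,
    max_spikes: float = 40.0,
    slope_ua: float = 15.0,
    currents_ua: Sequence[float] = DEFAULT_CURRENTS_UA,
    grid_spacing_mm: float = 0.4,
    noise: str | None = "poisson",
    n_trials: int = 10,
    ipsi_offset_ua: float = 30.0,
    ipsi_gain: float = 0.6,
    threshold_distance_gain: float = 0.25,
    stim_electrode_id: str = "e0",
):
    """Simulate one stimulating electrode's cortical response battery.

    Channels form two rectangular grids (ipsi/contra hemisphere).  The best
    channel's true 50%-of-max current is drawn from
    Normal(``group_mean_ua``, ``between_sd_ua``); other channels respond at
    strictly higher currents.  Each channel's spike count follows a
    monotone logistic of current saturating at a channel-specific maximum
    that falls off linearly with distance from the best channel at
    ``falloff_per_mm`` (the ground-truth d').  ``falloff_per_mm = 0`` gives
    a spatially uniform map (true d' = 0).

    Returns ``(CorticalResponse, truth_dict)`` with
    ``truth_dict = {"threshold_ua", "d_prime", "best_channel", "group"}``.
    """
    from .cortical import CorticalResponse

    if group_mean_ua <= 0:
        raise ValueError("group mean threshold must be positive")
    if n_channels < 2:
        raise ValueError("need at least 2 channels")
    if falloff_per_mm < 0:
        raise ValueError("falloff must be non-negative (monotone sigmoid)")
    if slope_ua <= 0:
        raise ValueError("sigmoid slope must be positive (monotone sigmoid)")
    currents = np.asarray(currents_ua, dtype=float)
    if np.any(np.diff(currents) <= 0):
        raise ValueError("currents must be strictly increasing")

    rng = np.random.default_rng(seed)
    per_hemi = max(n_channels // 2, 1)
    ncols = int(np.ceil(np.sqrt(per_hemi)))

    def grid(n):
        pts = [((k % ncols) * grid_spacing_mm, (k // ncols) * grid_spacing_mm)
               for k in range(n)]
        return pts

    chans = []
    for hemi, n_h in (("contra", per_hemi), ("ipsi", n_channels - per_hemi)):
        for k, (gx, gy) in enumerate(grid(n_h)):
            chans.append({"channel": f"{hemi[:1]}{k}", "hemisphere": hemi,
                          "x_mm": gx, "y_mm": gy})

    t_best = float(max(rng.normal(group_mean_ua, between_sd_ua), 10.0))
    # best channel sits in the contra hemisphere near the grid centre
    contra = [c for c in chans if c["hemisphere"] == "contra"]
    best = contra[rng.integers(len(contra))]
    bx, by = best["x_mm"], best["y_mm"]

    rows = []
    for c in chans:
        ipsi = c["hemisphere"] != best["hemisphere"]
        d_t = np.hypot(c["x_mm"] - bx, c["y_mm"] - by)
        if c is best:
            t_c = t_best
        else:
            # channels away from the activation centre need more current:
            # threshold rises with distance, so the lowest-threshold channel
            # coincides with the strongest-responding one
            t_c = (t_best * (1.0 + threshold_distance_gain * d_t)
                   + abs(rng.normal(0.0, channel_jitter_ua)) + 0.5)
        if ipsi:
            # the ipsilateral representation is weaker and responds at
            # systematically higher currents (strong binocular asymmetry)
            t_c += ipsi_offset_ua
        d = np.hypot(c["x_mm"] - bx, c["y_mm"] - by)
        m_c = max_spikes * max(1.0 - falloff_per_mm * d, 0.0)
        if ipsi:
            m_c *= ipsi_gain
        mean_counts = m_c / (1.0 + np.exp(-(currents - t_c) / slope_ua))
        if noise == "poisson":
            # mean spike count over repeated 1 Hz stimulation trials
            counts = rng.poisson(mean_counts * n_trials) / float(n_trials)
        elif noise is None:
            counts = mean_counts
        else:
            raise ValueError(f"unknown noise model {noise!r}")
        for cur, cnt in zip(currents, counts):
            rows.append({**c, "current_uA": cur, "spikes": float(cnt)})

    table = pd.DataFrame(rows)
    resp = CorticalResponse(stim_electrode_id=stim_electrode_id, table=table)
    truth = {"threshold_ua": t_best, "d_prime": falloff_per_mm,
             "best_channel": best["channel"], "group": int(group_label)}
    return resp, truth


def generate_cortical_battery(
    group_means: Mapping[int, float] = GROUP_CORTICAL_THRESHOLD_UA,
    n_electrodes_per_group: int = 20,
    seed: int = 0,
    *,
    group_dprimes: Mapping[int, float] = GROUP_DPRIME,
    **kwargs,
) -> tuple[list, pd.DataFrame]:
    """Batteries of electrodes across degeneration groups.

    Returns ``(responses, truth_table)`` where ``truth_table`` has one row
    per electrode (electrode, group, threshold_ua, d_prime).
    """
    rng = np.random.default_rng(seed)
    responses, rows = [], []
    for g, mean in sorted(group_means.items()):
        for k in range(n_electrodes_per_group):
            eid = f"g{g}_e{k}"
            resp, truth = generate_cortical(
                mean, group_label=g, seed=int(rng.integers(2**31 - 1)),
                falloff_per_mm=group_dprimes.get(g, 0.5),
                stim_electrode_id=eid, **kwargs,
            )
            responses.append(resp)
            rows.append({"electrode": eid, "group": g,
                         "threshold_ua": truth["threshold_ua"],
                         "d_prime": truth["d_prime"]})
    return responses, pd.DataFrame(rows)
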