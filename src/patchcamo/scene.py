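"""Scene analysis: smoothing, microhabitat segmentation, patch statistics,
near-zone construction and target-background colour-contrast predictors.

The analysis chain for one photographed (or synthesised) scene is:

1. optionally smooth the Lab image with an edge-preserving ranked filter
   gated by receptor-noise-style discriminability thresholds,
2. classify every non-excluded pixel into a microhabitat with a
   diagonal-Gaussian naive Bayes classifier trained on the microhabitat
   colour groups,
3. run particle (connected-component) analysis on the label map to get
   the area of every patch,
4. build the "near zone" — a band one target-height wide around the
   target, separated from it by a thin exclusion ring — and
5. compute the two colour-contrast predictors fed to the survival
   models: CIEDE2000 between the target colour and the mean colour of
   the near zone, and between the target colour and the mean of the
   whole scene.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage import measure

from .color import delta_e_ciede2000
from .design import ColorGroup

__all__ = [
    "FilterParams",
    "HabitatClassifier",
    "ranked_smooth",
    "fit_classifier",
    "classify_pixels",
    "particle_analysis",
    "patch_summaries",
    "near_zone_mask",
    "contrast_predictors",
    "habitat_proportions",
    "NO_LABEL",
]

#: Label value for pixels outside the classification (target, exclusions).
NO_LABEL = -1


@dataclass(frozen=True)
class FilterParams:
    """Parameters of the ranked (edge-preserving) smoothing filter.

    weber_chrom / weber_lum are the chromatic and luminance Weber
    fractions gating which neighbours count as indistinguishable from the
    centre pixel; kernel_radius is the neighbourhood radius in px;
    falloff controls how fast the gate tightens with distance;
    iterations repeats the filter.  threshold_scale converts a Weber
    fraction into a Lab-unit gate: the luminance gate is
    ``weber_lum * 100 * threshold_scale`` at the centre (L spans 0-100)
    and the chromatic gate is ``weber_chrom * 100 * threshold_scale`` on
    Euclidean (a, b) distance, both multiplied by ``(1 - r/R)**falloff``.
    """

    weber_chrom: float = 0.05
    weber_lum: float = 0.1
    kernel_radius: int = 3
    falloff: float = 2.0
    iterations: int = 3
    threshold_scale: float = 2.0

    def __post_init__(self) -> None:
        if min(self.weber_chrom, self.weber_lum, self.kernel_radius, self.falloff) <= 0:
            raise ValueError("filter parameters must be positive")
        if self.iterations < 1:
            raise ValueError("iterations must be >= 1")


def ranked_smooth(lab_image, params: FilterParams = FilterParams()) -> np.ndarray:
    """Iterated edge-preserving ranked filter on a Lab image.

    For every pixel, neighbours within ``kernel_radius`` whose colour
    difference from the centre falls below the distance-weighted
    discriminability gate contribute to a channelwise median that
    replaces the centre.  The centre always contributes, so a uniform
    image is a fixed point and high-contrast boundaries are preserved.
    """
    img = np.asarray(lab_image, dtype=float)
    R = params.kernel_radius
    offsets, weights = [], []
    for dy in range(-R, R + 1):
        for dx in range(-R, R + 1):
            r = np.hypot(dy, dx)
            if r == 0 or r >= R:
                continue
            offsets.append((dy, dx))
            weights.append((1.0 - r / R) ** params.falloff)
    t_lum = params.weber_lum * 100.0 * params.threshold_scale
    t_chrom = params.weber_chrom * 100.0 * params.threshold_scale

    for _ in range(params.iterations):
        pad = np.pad(img, ((R, R), (R, R), (0, 0)), mode="edge")
        H, W = img.shape[:2]
        stack = np.empty((len(offsets) + 1, H, W, 3))
        stack[0] = img
        for k, ((dy, dx), w) in enumerate(zip(offsets, weights), start=1):
            nb = pad[R + dy : R + dy + H, R + dx : R + dx + W]
            ok = (np.abs(nb[..., 0] - img[..., 0]) < t_lum * w) & (
                np.hypot(nb[..., 1] - img[..., 1], nb[..., 2] - img[..., 2])
                < t_chrom * w
            )
            stack[k] = np.where(ok[..., None], nb, np.nan)
        img = np.nanmedian(stack, axis=0)
    return img


@dataclass
class HabitatClassifier:
    """Diagonal-covariance Gaussian class-conditional model per microhabitat."""

    names: list[str]
    means: np.ndarray  # (k, 3)
    sds: np.ndarray  # (k, 3), floored
    priors: np.ndarray  # (k,), sums to 1

    SD_FLOOR = 1e-6


def fit_classifier(groups: list[ColorGroup], priors=None) -> HabitatClassifier:
    """Fit the naive Bayes classifier from per-microhabitat colour groups."""
    if len(groups) < 2:
        raise ValueError("need at least two microhabitat groups")
    means = np.array([g.samples.mean(axis=0) for g in groups])
    sds = np.array([g.samples.std(axis=0, ddof=1) if len(g.samples) > 1 else np.zeros(3) for g in groups])
    sds = np.maximum(sds, HabitatClassifier.SD_FLOOR)
    if priors is None:
        priors = np.full(len(groups), 1.0 / len(groups))
    priors = np.asarray(priors, dtype=float)
    if priors.shape != (len(groups),) or abs(priors.sum() - 1.0) > 1e-9 or priors.min() < 0:
        raise ValueError("priors must be non-negative and sum to 1")
    return HabitatClassifier([g.name for g in groups], means, sds, priors)


def classify_pixels(clf: HabitatClassifier, lab_image, exclude_mask=None) -> np.ndarray:
    """Per-pixel argmax of log-prior + Gaussian log-likelihood.

    Excluded pixels get :data:`NO_LABEL`.  Exact posterior ties resolve to
    the lowest habitat index (argmax on first occurrence).
    """
    img = np.asarray(lab_image, dtype=float)
    flat = img.reshape(-1, 3)
    with np.errstate(divide="ignore"):
        logpri = np.log(clf.priors)
    # (npix, k): sum over channels of Gaussian log-densities
    z = (flat[:, None, :] - clf.means[None]) / clf.sds[None]
    ll = -0.5 * (z**2).sum(axis=2) - np.log(clf.sds).sum(axis=1)[None] + logpri[None]
    labels = ll.argmax(axis=1).reshape(img.shape[:2]).astype(np.int64)
    if exclude_mask is not None:
        m = np.asarray(exclude_mask, dtype=bool)
        if m.shape != labels.shape:
            raise ValueError("exclude_mask shape must match image")
        labels[m] = NO_LABEL
    return labels


def particle_analysis(label_map, connectivity: int = 8) -> pd.DataFrame:
    """Connected-component ("particle") analysis of a microhabitat label map.

    Returns one row per patch with columns ``habitat`` (label index),
    ``patch_id`` and ``area_px``.  Pixels labelled :data:`NO_LABEL` are
    outside every patch.
    """
    lm = np.asarray(label_map)
    if connectivity not in (4, 8):
        raise ValueError("connectivity must be 4 or 8")
    conn = 1 if connectivity == 4 else 2
    rows = []
    for lab in np.unique(lm):
        if lab == NO_LABEL:
            continue
        cc = measure.label(lm == lab, connectivity=conn)
        areas = np.bincount(cc.ravel())[1:]
        for pid, area in enumerate(areas, start=1):
            if area > 0:
                rows.append((int(lab), pid, int(area)))
    return pd.DataFrame(rows, columns=["habitat", "patch_id", "area_px"])


def patch_summaries(patch_table: pd.DataFrame) -> pd.DataFrame:
    """Per-habitat patch count, median area and areal proportion."""
    g = patch_table.groupby("habitat")["area_px"]
    out = pd.DataFrame(
        {"n_patches": g.size(), "median_area_px": g.median(), "total_area_px": g.sum()}
    )
    out["proportion"] = out["total_area_px"] / out["total_area_px"].sum()
    return out


def _dilate(mask: np.ndarray, px: int, element: str) -> np.ndarray:
    if px <= 0:
        return mask.copy()
    if element == "square":  # Chebyshev ball == separable maximum filter
        return ndimage.maximum_filter(mask.astype(np.uint8), size=2 * px + 1) > 0
    if element == "disc":  # Euclidean ball via distance transform
        return ndimage.distance_transform_edt(~mask) <= px
    raise ValueError("element must be 'square' or 'disc'")


def near_zone_mask(
    target_mask, band_width_px: int, exclusion_px: int = 0, element: str = "square"
) -> np.ndarray:
    """Band of ``band_width_px`` around the target, beyond an exclusion ring.

    The exclusion ring (``exclusion_px`` wide, hugging the target outline)
    keeps stray target pixels out of the background statistics.  The
    returned mask is disjoint from both the target and the ring, and is
    clipped at image borders.  ``band_width_px == 0`` yields an empty mask.
    """
    t = np.asarray(target_mask, dtype=bool)
    if band_width_px < 0 or exclusion_px < 0:
        raise ValueError("band and exclusion widths must be non-negative")
    if band_width_px == 0:
        return np.zeros_like(t)
    outer = _dilate(t, exclusion_px + band_width_px, element)
    inner = _dilate(t, exclusion_px, element)
    return outer & ~inner


def contrast_predictors(
    target_lab,
    lab_image,
    target_mask,
    band_width_px: int,
    exclusion_px: int = 0,
    exclusion_scene_mask=None,
    element: str = "square",
) -> tuple[float, float]:
    """(dE_near, dE_whole): target-background CIEDE2000 contrasts.

    dE_near compares the target colour with the mean Lab of the near
    zone; dE_whole with the mean of the whole scene minus the target,
    the exclusion ring and any scene-level exclusions (skyline etc.).
    """
    img = np.asarray(lab_image, dtype=float)
    t = np.asarray(target_mask, dtype=bool)
    near = near_zone_mask(t, band_width_px, exclusion_px, element)
    whole = ~_dilate(t, exclusion_px, element)
    if exclusion_scene_mask is not None:
        whole &= ~np.asarray(exclusion_scene_mask, dtype=bool)
        near &= ~np.asarray(exclusion_scene_mask, dtype=bool)
    if not near.any() or not whole.any():
        raise ValueError("empty background region")
    target_lab = np.asarray(target_lab, dtype=float)
    de_near = float(delta_e_ciede2000(target_lab, img[near].mean(axis=0)))
    de_whole = float(delta_e_ciede2000(target_lab, img[whole].mean(axis=0)))
    return de_near, de_whole


def habitat_proportions(label_map, region_mask=None, n_habitats: int | None = None) -> np.ndarray:
    """Proportion of labelled pixels per habitat within a region (sums to 1)."""
    lm = np.asarray(label_map)
    if region_mask is not None:
        lm = lm[np.asarray(region_mask, dtype=bool)]
    lm = lm[lm != NO_LABEL]
    if lm.size == 0:
        raise ValueError("no labelled pixels in region")
    k = n_habitats if n_habitats is not None else int(lm.max()) + 1
    counts = np.bincount(lm, minlength=k).astype(float)
    return counts / counts.sum()
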