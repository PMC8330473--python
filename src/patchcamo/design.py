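"""Target-colour design: specialist/generalist colour summaries and paint matching.

Specialist target colours summarise one microhabitat patch type (grass,
bracken, bramble, leaf litter); the generalist colour is the mean of the
whole visual scene, averaged across scenes.  Physical targets are painted,
so the final step maps each designed colour group onto the closest paints
from a commercial palette, under an exclusivity rule: a paint only
represents a group if its Lab coordinates fall inside that group's
per-channel range and no other group's, and it must not match another
group's median just as closely.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .color import delta_e_ciede2000

__all__ = [
    "ColorGroup",
    "PaintSwatch",
    "PaintSelection",
    "region_mean_lab",
    "generalist_color",
    "match_paints",
]


@dataclass
class ColorGroup:
    """A named set of Lab samples (one per selection/image) with box summaries."""

    name: str
    samples: np.ndarray  # (n, 3)

    def __post_init__(self) -> None:
        self.samples = np.atleast_2d(np.asarray(self.samples, dtype=float))
        if self.samples.ndim != 2 or self.samples.shape[1] != 3 or len(self.samples) == 0:
            raise ValueError("samples must be a non-empty (n, 3) array of Lab rows")

    @property
    def min(self) -> np.ndarray:
        return self.samples.min(axis=0)

    @property
    def max(self) -> np.ndarray:
        return self.samples.max(axis=0)

    @property
    def median(self) -> np.ndarray:
        """Channelwise median of the samples — the group's target colour."""
        return np.median(self.samples, axis=0)

    def contains(self, lab) -> bool:
        lab = np.asarray(lab, dtype=float)
        return bool(np.all(lab >= self.min) and np.all(lab <= self.max))


@dataclass(frozen=True)
class PaintSwatch:
    name: str
    lab: tuple[float, float, float]

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.lab)):
            raise ValueError(f"paint {self.name!r} has non-finite Lab")


@dataclass
class PaintSelection:
    """Selected paints for one group, with the shortfall (if any) reported."""

    group: str
    paints: list[tuple[str, float]] = field(default_factory=list)  # (name, dE to median)
    n_requested: int = 2
    n_eligible: int = 0

    @property
    def shortfall(self) -> int:
        return max(0, self.n_requested - len(self.paints))


def region_mean_lab(lab_image, mask) -> np.ndarray:
    """Arithmetic mean Lab over the masked pixels of an image."""
    img = np.asarray(lab_image, dtype=float)
    m = np.asarray(mask, dtype=bool)
    if m.shape != img.shape[:-1]:
        raise ValueError("mask shape must match image spatial shape")
    if not m.any():
        raise ValueError("mask selects no pixels")
    return img[m].mean(axis=0)


def generalist_color(scenes) -> np.ndarray:
    """Mean of per-scene whole-image mean colours, unweighted across scenes.

    ``scenes`` is a sequence of ``(lab_image, exclusion_mask)`` pairs; the
    exclusion mask (True = drop, e.g. sky, colour standards, man-made
    objects) may be None.
    """
    scenes = list(scenes)
    if not scenes:
        raise ValueError("need at least one scene")
    means = []
    for lab_image, excl in scenes:
        img = np.asarray(lab_image, dtype=float)
        keep = np.ones(img.shape[:-1], dtype=bool)
        if excl is not None:
            keep &= ~np.asarray(excl, dtype=bool)
        if not keep.any():
            raise ValueError("a scene is fully excluded")
        means.append(img[keep].mean(axis=0))
    return np.mean(means, axis=0)


def match_paints(
    palette: list[PaintSwatch],
    groups: list[ColorGroup],
    n_per_group: int = 2,
) -> dict[str, PaintSelection]:
    """Select the best-matching paints for each colour group.

    A paint is *eligible* for a group iff its Lab lies inside that group's
    per-channel [min, max] box and inside no other group's box.  Eligible
    paints are ranked by CIEDE2000 distance to the group's channelwise
    median, ascending (ties broken by paint name), and any paint whose
    distance to another group's median is less than or equal to its
    distance to this group's median is dropped (it matches the other group
    "just as closely").  The top ``n_per_group`` survivors are returned;
    a shortfall is reported on the selection, never silently padded.
    """
    if not palette:
        raise ValueError("palette is empty")
    medians = {g.name: g.median for g in groups}
    out: dict[str, PaintSelection] = {}
    for g in groups:
        eligible = []
        for paint in palette:
            inside = [h.name for h in groups if h.contains(paint.lab)]
            if inside != [g.name]:
                continue
            d_own = float(delta_e_ciede2000(paint.lab, medians[g.name]))
            d_other = min(
                (float(delta_e_ciede2000(paint.lab, m)) for n, m in medians.items() if n != g.name),
                default=np.inf,
            )
            if d_other <= d_own:  # ties broken toward exclusion
                continue
            eligible.append((d_own, paint.name))
        eligible.sort()
        sel = PaintSelection(
            group=g.name,
            paints=[(name, d) for d, name in eligible[:n_per_group]],
            n_requested=n_per_group,
            n_eligible=len(eligible),
        )
        out[g.name] = sel
    return out
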