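"""Online-experiment stimulus generation.

From each photographed location (left- and right-facing source images in
linear RGB), the experiment needs: a presentation-encoded 8-bit image,
three 1920x1080 "small" crops and three 3840x2160 "large" crops all
containing the target, the target recoloured to each of the five
treatment colours (four microhabitat specialists and the whole-image
generalist), and finally 20-slide sets balanced over habitat,
orientation, treatment and crop size.

Forty locations x 2 orientations x 6 crops x 5 treatments = 2400 images.
Because materialising that database is pixel-heavy, `build_database`
works on metadata by default (crop offsets, treatment, target box) and
pixels are rendered on demand.
"""

from __future__ import annotations

import warnings
import zlib
from dataclasses import dataclass, field, replace

import numpy as np

from .color import DEFAULT_POWER

__all__ = [
    "TreatmentColor",
    "TREATMENTS",
    "StimulusImage",
    "SlideSet",
    "LocationSource",
    "to_presentation_rgb",
    "make_crops",
    "recolor_target",
    "build_database",
    "sample_slide_set",
    "SlideSetError",
]

SMALL_CROP = (1080, 1920)  # rows, cols
LARGE_CROP = (2160, 3840)


@dataclass(frozen=True)
class TreatmentColor:
    name: str
    rgb: tuple[int, int, int]


#: The five treatment colours: per-area mean RGB of the presentation images.
TREATMENTS = (
    TreatmentColor("bracken", (143, 125, 92)),
    TreatmentColor("bramble", (112, 121, 85)),
    TreatmentColor("leaf_litter", (165, 139, 113)),
    TreatmentColor("grass", (132, 148, 78)),
    TreatmentColor("generalist", (123, 122, 81)),
)


@dataclass
class StimulusImage:
    """One stimulus: metadata always; pixels only when materialised."""

    image_id: str
    location: str
    habitat: str  # "wood" | "farm"
    orientation: str  # "left" | "right"
    crop_class: str  # "small" | "large"
    treatment: str
    target_box: tuple[int, int, int, int]  # r0, c0, r1, c1 within the crop
    frame_size: tuple[int, int]
    crop_offset: tuple[int, int] = (0, 0)  # top-left within the source image
    pixels: np.ndarray | None = None

    def __post_init__(self) -> None:
        r0, c0, r1, c1 = self.target_box
        h, w = self.frame_size
        if not (0 <= r0 < r1 <= h and 0 <= c0 < c1 <= w):
            raise ValueError(f"target box {self.target_box} not inside frame {self.frame_size}")

    @property
    def target_centre(self) -> tuple[float, float]:
        r0, c0, r1, c1 = self.target_box
        return ((r0 + r1) / 2.0, (c0 + c1) / 2.0)


@dataclass
class SlideSet:
    slides: list[StimulusImage]
    seed: int


class SlideSetError(ValueError):
    """A slide-set constraint cannot be met by the supplied database."""


def to_presentation_rgb(linear_image, max_brightness: float = 1.0, power: float = DEFAULT_POWER):
    """Encode a linear image for presentation: round(255 * (x/max)^power).

    Values above ``max_brightness`` are clipped with a warning.
    """
    arr = np.asarray(linear_image, dtype=float)
    if arr.min() < 0:
        raise ValueError("linear values must be non-negative")
    if arr.max() > max_brightness:
        warnings.warn("linear values above max_brightness clipped", stacklevel=2)
        arr = np.minimum(arr, max_brightness)
    return np.round(255.0 * (arr / max_brightness) ** power).astype(np.uint8)


def _feasible_offsets(src_shape, box, crop_shape):
    """Range of top-left offsets keeping the box inside the crop and the
    crop inside the source.  Returns (r_lo, r_hi, c_lo, c_hi) inclusive."""
    H, W = src_shape[:2]
    ch, cw = crop_shape
    r0, c0, r1, c1 = box
    r_lo, r_hi = max(0, r1 - ch), min(H - ch, r0)
    c_lo, c_hi = max(0, c1 - cw), min(W - cw, c0)
    if r_lo > r_hi or c_lo > c_hi:
        raise ValueError("target box cannot be contained in a crop of this size")
    return r_lo, r_hi, c_lo, c_hi


def _sample_offsets(rng, bounds, k):
    r_lo, r_hi, c_lo, c_hi = bounds
    n_feasible = (r_hi - r_lo + 1) * (c_hi - c_lo + 1)
    chosen: list[tuple[int, int]] = []
    for _ in range(200):
        cand = (int(rng.integers(r_lo, r_hi + 1)), int(rng.integers(c_lo, c_hi + 1)))
        if cand not in chosen:
            chosen.append(cand)
        if len(chosen) == k or len(chosen) == n_feasible:
            break
    while len(chosen) < k:  # degenerate feasible set: repeat
        chosen.append(chosen[len(chosen) % max(1, min(k, n_feasible))])
    return chosen[:k]


def make_crops(
    image: np.ndarray | None,
    target_box,
    seed: int,
    *,
    src_shape=None,
    meta: dict | None = None,
) -> list[StimulusImage]:
    """Cut three small and three large crops, each containing the target.

    Offsets are drawn reproducibly from the feasible offset set; the three
    crops per class are pairwise distinct whenever the feasible set allows.
    Pass ``image=None`` with ``src_shape`` for metadata-only crops.
    """
    if image is None:
        if src_shape is None:
            raise ValueError("need src_shape when image is None")
        shape = tuple(src_shape)
    else:
        image = np.asarray(image)
        shape = image.shape
    if shape[0] < LARGE_CROP[0] or shape[1] < LARGE_CROP[1]:
        raise ValueError(f"source {shape[:2]} smaller than the large crop {LARGE_CROP}")
    r0, c0, r1, c1 = target_box
    if r1 - r0 >= SMALL_CROP[0] or c1 - c0 >= SMALL_CROP[1]:
        raise ValueError("target box larger than the small crop frame")
    meta = meta or {}
    rng = np.random.default_rng(seed)
    out = []
    for crop_class, crop_shape in (("small", SMALL_CROP), ("large", LARGE_CROP)):
        bounds = _feasible_offsets(shape, target_box, crop_shape)
        for i, (orr, occ) in enumerate(_sample_offsets(rng, bounds, 3)):
            box_in_crop = (r0 - orr, c0 - occ, r1 - orr, c1 - occ)
            pix = None
            if image is not None:
                pix = image[orr : orr + crop_shape[0], occ : occ + crop_shape[1]].copy()
            out.append(
                StimulusImage(
                    image_id=f"{meta.get('location', 'loc')}_{meta.get('orientation', 'x')}_{crop_class}{i}",
                    location=meta.get("location", "loc"),
                    habitat=meta.get("habitat", "wood"),
                    orientation=meta.get("orientation", "left"),
                    crop_class=crop_class,
                    treatment=meta.get("treatment", "none"),
                    target_box=box_in_crop,
                    frame_size=crop_shape,
                    crop_offset=(orr, occ),
                    pixels=pix,
                )
            )
    return out


def recolor_target(image: np.ndarray, target_mask, treatment: TreatmentColor) -> np.ndarray:
    """Set the masked pixels (target plus its exclusion ring) to the
    treatment RGB exactly; every other pixel is untouched."""
    img = np.asarray(image)
    m = np.asarray(target_mask, dtype=bool)
    if m.shape != img.shape[:2]:
        raise ValueError("mask shape must match image")
    if not m.any():
        raise ValueError("empty target mask")
    out = img.copy()
    out[m] = np.asarray(treatment.rgb, dtype=img.dtype)
    return out


@dataclass
class LocationSource:
    """Source material for one field location: both orientations required."""

    location: str
    habitat: str
    target_boxes: dict[str, tuple[int, int, int, int]]  # orientation -> box
    images: dict[str, np.ndarray] = field(default_factory=dict)
    src_shape: tuple[int, int] = (2160, 3840)


def build_database(
    locations: list[LocationSource],
    treatments=TREATMENTS,
    seed: int = 0,
    permissive: bool = False,
) -> list[StimulusImage]:
    """Expand locations into the full stimulus database.

    Count = n_locations x 2 orientations x 6 crops x len(treatments);
    40 locations with the five standard treatments give 2400 images.
    A location missing an orientation raises (named) unless ``permissive``.
    """
    db: list[StimulusImage] = []
    for loc in locations:
        orientations = sorted(loc.target_boxes)
        if set(orientations) != {"left", "right"} and not permissive:
            raise ValueError(f"location {loc.location!r} is missing an orientation")
        for orientation in orientations:
            img = loc.images.get(orientation)
            crops = make_crops(
                img,
                loc.target_boxes[orientation],
                seed=zlib.crc32(f"{seed}|{loc.location}|{orientation}".encode()) % (2**31),
                src_shape=None if img is not None else loc.src_shape,
                meta={"location": loc.location, "habitat": loc.habitat, "orientation": orientation},
            )
            for crop in crops:
                for tr in treatments:
                    db.append(
                        replace(
                            crop,
                            image_id=f"{crop.image_id}_{tr.name}",
                            treatment=tr.name,
                            pixels=None if crop.pixels is None else crop.pixels,
                        )
                    )
    return db


def sample_slide_set(database: list[StimulusImage], seed: int, n_restarts: int = 500) -> SlideSet:
    """Draw a 20-slide set satisfying the joint design constraints.

    Constraints: 10 wood + 10 farm backgrounds with no repeated location,
    10 left- and 10 right-facing targets, exactly 4 slides of each of the
    5 treatments, exactly 8 small-crop slides, in seed-randomised order.
    Infeasibility raises :class:`SlideSetError` naming the unmet
    constraint.
    """
    treatments = sorted({s.treatment for s in database})
    required = sorted(t.name for t in TREATMENTS)
    missing = sorted(set(required) - set(treatments))
    if missing:
        raise SlideSetError(f"database has no images of treatment(s): {', '.join(missing)}")
    for hab in ("wood", "farm"):
        n_locs = len({s.location for s in database if s.habitat == hab})
        if n_locs < 10:
            raise SlideSetError(f"need >= 10 distinct {hab} locations, found {n_locs}")

    rng = np.random.default_rng(seed)
    by_key: dict[tuple, list[StimulusImage]] = {}
    for s in database:
        by_key.setdefault((s.habitat, s.location, s.orientation, s.crop_class, s.treatment), []).append(s)

    habitats = ["wood"] * 10 + ["farm"] * 10
    for _ in range(n_restarts):
        orientations = rng.permutation(["left"] * 10 + ["right"] * 10)
        treatments20 = rng.permutation([t.name for t in TREATMENTS] * 4)
        crops = rng.permutation(["small"] * 8 + ["large"] * 12)
        used_locations: set[str] = set()
        slides: list[StimulusImage] = []
        ok = True
        for hab, ori, tr, cc in zip(habitats, orientations, treatments20, crops):
            candidates = [
                key
                for key in by_key
                if key[0] == hab and key[1] not in used_locations
                and key[2] == ori and key[3] == cc and key[4] == tr
            ]
            if not candidates:
                ok = False
                break
            key = candidates[int(rng.integers(len(candidates)))]
            pool = by_key[key]
            slides.append(pool[int(rng.integers(len(pool)))])
            used_locations.add(key[1])
        if ok:
            idx = rng.permutation(len(slides))
            return SlideSet([slides[i] for i in idx], seed=seed)
    raise SlideSetError(
        "could not satisfy the joint habitat/orientation/treatment/crop constraints"
    )
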