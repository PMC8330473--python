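"""Synthetic data: patchy microhabitat scenes and simulated detection trials.

Field data for this kind of study are calibrated photographs of natural
scenes plus walk-up detection trials; neither is needed to exercise the
pipeline.  This module fabricates both with known ground truth:

* *Scenes* — a label map is built by smoothing one Gaussian noise field
  per microhabitat (smoothing length set by the requested patch scale),
  standardising each field, adding weight-derived offsets and taking the
  per-pixel argmax; the offsets are solved numerically so the expected
  areal fraction of each microhabitat matches its requested weight.
  Pixel colours are then drawn independently around each microhabitat's
  mean Lab with its per-channel SDs.  A target silhouette (by default a
  stylised hare, 40 cm tall by 26 cm wide at full scale) can be stamped
  into the scene.

* *Detection trials* — each presentation draws an event "time" on the
  transformed distance scale u = 1 - d/d_max from an exponential
  baseline scaled by exp(X beta + b_subject + b_position) with normal
  random effects; draws beyond the position's maximum u (how close the
  path ever gets) are censored, mirroring missed targets in the field.

Every stage draws from its own substream of a single seed, so adding a
stage never perturbs earlier streams.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage, optimize, stats
from skimage.transform import resize

__all__ = [
    "MicrohabitatSpec",
    "SceneSpec",
    "SyntheticScene",
    "TrialDesign",
    "generate_scene",
    "hare_silhouette",
    "place_target",
    "generate_detection_trials",
    "NO_LABEL",
]

NO_LABEL = -1  # target pixels carry no microhabitat label


@dataclass(frozen=True)
class MicrohabitatSpec:
    """One microhabitat: name, mean Lab colour, per-channel SDs, areal
    weight and characteristic patch diameter in pixels."""

    name: str
    mean_lab: tuple[float, float, float]
    sd_lab: tuple[float, float, float]
    weight: float
    patch_scale_px: float

    def __post_init__(self) -> None:
        if self.weight < 0:
            raise ValueError("weight must be >= 0")
        if min(self.sd_lab) < 0:
            raise ValueError("sd_lab components must be >= 0")
        if self.patch_scale_px <= 0:
            raise ValueError("patch_scale_px must be positive")


@dataclass(frozen=True)
class SceneSpec:
    """Scene dimensions, spatial scale, microhabitat mix and seed.

    ``local_bias`` optionally enriches one microhabitat around the scene
    centre — a Gaussian bump of the given strength (in field SD units)
    and radius added to that habitat's noise field.  It emulates a target
    site sitting in a locally distinctive patch of habitat, so that the
    immediate surrounds of a centred target differ from the scene-wide
    mix the way real target positions do.
    """

    width_px: int
    height_px: int
    px_per_mm: float
    microhabitats: tuple[MicrohabitatSpec, ...]
    seed: int = 0
    local_bias: tuple[int, float, float] | None = None  # (habitat, strength, radius_px)

    def __post_init__(self) -> None:
        if self.width_px <= 0 or self.height_px <= 0 or self.px_per_mm <= 0:
            raise ValueError("dimensions and scale must be positive")
        if len(self.microhabitats) < 1:
            raise ValueError("need at least one microhabitat")
        w = sum(m.weight for m in self.microhabitats)
        if abs(w - 1.0) > 1e-6:
            raise ValueError(f"microhabitat weights must sum to 1 (got {w})")
        if self.local_bias is not None and not (
            0 <= self.local_bias[0] < len(self.microhabitats) and self.local_bias[2] > 0
        ):
            raise ValueError("local_bias must name a valid habitat and positive radius")


@dataclass
class SyntheticScene:
    lab_image: np.ndarray  # (H, W, 3)
    label_map: np.ndarray  # (H, W) int, NO_LABEL under the target
    target_mask: np.ndarray  # (H, W) bool
    spec: SceneSpec

    @property
    def habitat_names(self) -> list[str]:
        return [m.name for m in self.spec.microhabitats]


def _weight_offsets(weights: np.ndarray) -> np.ndarray:
    """Offsets c such that P(argmax_i Z_i + c_i) matches the weights, for
    iid standard-normal fields.  Solved by quadrature + least squares."""
    k = len(weights)
    if k == 1 or np.allclose(weights, weights[0]):
        return np.zeros(k)
    nodes, wq = np.polynomial.hermite_e.hermegauss(61)
    phi_w = wq / math.sqrt(2 * math.pi) * np.exp(0)  # probabilists' weights

    def fractions(c):
        # P(i wins) = int phi(z) prod_{j != i} Phi(z + c_i - c_j) dz
        out = np.empty(k)
        for i in range(k):
            prod = np.ones_like(nodes)
            for j in range(k):
                if j != i:
                    prod *= stats.norm.cdf(nodes + c[i] - c[j])
            out[i] = np.sum(phi_w * prod)
        return out

    def resid(c_free):
        c = np.concatenate([[0.0], c_free])
        return fractions(c) - weights

    sol = optimize.least_squares(resid, np.zeros(k - 1), xtol=1e-10, ftol=1e-12)
    return np.concatenate([[0.0], sol.x])


def generate_scene(spec: SceneSpec) -> SyntheticScene:
    """Generate a patchy scene with ground-truth labels, reproducibly."""
    rng = np.random.default_rng(np.random.SeedSequence(spec.seed).spawn(2)[0])
    crng = np.random.default_rng(np.random.SeedSequence(spec.seed).spawn(2)[1])
    H, W = spec.height_px, spec.width_px
    k = len(spec.microhabitats)
    weights = np.array([m.weight for m in spec.microhabitats])
    offsets = _weight_offsets(weights)

    fields = np.empty((k, H, W))
    for i, m in enumerate(spec.microhabitats):
        f = ndimage.gaussian_filter(rng.standard_normal((H, W)), m.patch_scale_px / 2.0)
        sd = f.std()
        fields[i] = (f - f.mean()) / (sd if sd > 0 else 1.0) + offsets[i]
    if spec.local_bias is not None:
        hab, strength, radius = spec.local_bias
        yy, xx = np.mgrid[0:H, 0:W]
        r2 = (yy - (H - 1) / 2.0) ** 2 + (xx - (W - 1) / 2.0) ** 2
        fields[hab] += strength * np.exp(-r2 / (2.0 * radius**2))
    label_map = fields.argmax(axis=0).astype(np.int64)

    lab = np.empty((H, W, 3))
    for i, m in enumerate(spec.microhabitats):
        sel = label_map == i
        n = int(sel.sum())
        lab[sel] = np.asarray(m.mean_lab) + crng.standard_normal((n, 3)) * np.asarray(m.sd_lab)
    return SyntheticScene(lab, label_map, np.zeros((H, W), dtype=bool), spec)


def hare_silhouette(height_px: int) -> np.ndarray:
    """A stylised sitting-hare silhouette, ``height_px`` tall and about
    0.65x as wide (the 40 cm x 26 cm target aspect)."""
    if height_px < 4:
        raise ValueError("height_px must be at least 4")
    h = height_px
    w = max(3, round(0.65 * h))
    yy, xx = np.mgrid[0:h, 0:w]

    def ellipse(cy, cx, ry, rx):
        return ((yy - cy) / ry) ** 2 + ((xx - cx) / rx) ** 2 <= 1.0

    body = ellipse(0.68 * h, 0.5 * w, 0.31 * h, 0.48 * w)
    head = ellipse(0.33 * h, 0.68 * w, 0.14 * h, 0.22 * w)
    ear1 = ellipse(0.13 * h, 0.58 * w, 0.13 * h, 0.07 * w)
    ear2 = ellipse(0.13 * h, 0.76 * w, 0.13 * h, 0.07 * w)
    return body | head | ear1 | ear2


def place_target(
    scene: SyntheticScene,
    silhouette_mask=None,
    height_mm: float = 400.0,
    offset: tuple[int, int] | None = None,
) -> SyntheticScene:
    """Stamp a target silhouette into the scene (centred unless offset given).

    The silhouette is rescaled so its height is ``height_mm * px_per_mm``
    pixels (rounded).  Target pixels lose their microhabitat label.
    An empty silhouette leaves the scene unchanged.
    """
    H, W = scene.label_map.shape
    target_h = round(height_mm * scene.spec.px_per_mm)
    if silhouette_mask is None:
        silhouette_mask = hare_silhouette(target_h)
    sil = np.asarray(silhouette_mask, dtype=bool)
    if not sil.any():
        return SyntheticScene(
            scene.lab_image.copy(), scene.label_map.copy(),
            np.zeros((H, W), dtype=bool), scene.spec,
        )
    rows, cols = sil.any(axis=1), sil.any(axis=0)
    sil = sil[np.ix_(rows, cols)]  # bounding box, so the scaled height is exact
    sh, sw = sil.shape
    new_w = max(1, round(sw * target_h / sh))
    sil = resize(sil.astype(float), (target_h, new_w), order=0, anti_aliasing=False) > 0.5
    if target_h > H or sil.shape[1] > W:
        raise ValueError(
            f"scaled silhouette {sil.shape} does not fit scene {(H, W)}"
        )
    if offset is None:
        top, left = (H - target_h) // 2, (W - sil.shape[1]) // 2
    else:
        top, left = offset
    if top < 0 or left < 0 or top + target_h > H or left + sil.shape[1] > W:
        raise ValueError("silhouette placement falls outside the scene")
    mask = np.zeros((H, W), dtype=bool)
    mask[top : top + target_h, left : left + sil.shape[1]] = sil
    labels = scene.label_map.copy()
    labels[mask] = NO_LABEL
    return SyntheticScene(scene.lab_image.copy(), labels, mask, scene.spec)


@dataclass
class TrialDesign:
    """Design of a simulated detection experiment.

    Defaults mirror the field study's scale: 39 observer trials over 20
    transect positions (780 presentations), a generalist-vs-specialist
    log hazard ratio of log 0.5, random-effect SDs of 0.2 on the
    log-hazard scale, maximum viewing distances spread around ~60 m and
    a baseline hazard giving roughly one presentation in ten censored.
    """

    n_subjects: int = 39
    n_positions: int = 20
    strategy_log_hr: float = math.log(0.5)
    delta_e_log_hr: float = 0.0
    subject_sd: float = 0.2
    position_sd: float = 0.2
    d_max_range: tuple[float, float] = (30.0, 90.0)
    d_min_range: tuple[float, float] = (2.0, 10.0)
    baseline_hazard: float = 4.0
    timeout_s: float = 10.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 1 or self.n_positions < 1:
            raise ValueError("need at least one subject and one position")
        if min(self.subject_sd, self.position_sd) < 0:
            raise ValueError("random-effect SDs must be >= 0")
        if not (0 < self.d_min_range[1] < self.d_max_range[0]):
            raise ValueError("d_min range must sit strictly below d_max range")
        if self.baseline_hazard < 0:
            raise ValueError("baseline_hazard must be >= 0")


def generate_detection_trials(
    design: TrialDesign, covariates: pd.DataFrame | None = None
) -> pd.DataFrame:
    """Simulate one presentation per (subject, position) pair.

    If ``covariates`` is given it must have one row per presentation in
    (subject-major) order, with a ``log_hr`` attribute on the frame's
    ``attrs`` mapping column names to true slopes; otherwise a balanced
    binary ``strategy`` covariate (1 = generalist) with slope
    ``strategy_log_hr`` is generated per subject.

    Returns a tidy frame with one row per presentation: ids, covariates,
    distances, the transformed response u = 1 - d/d_max, and the event
    indicator (0 = missed; the response then records the closest
    approach 1 - d_min/d_max).
    """
    ss = np.random.SeedSequence(design.seed).spawn(4)
    rng_layout, rng_dist, rng_re, rng_event = (np.random.default_rng(s) for s in ss)
    ns, npos = design.n_subjects, design.n_positions
    n = ns * npos

    subject = np.repeat(np.arange(ns), npos)
    position = np.tile(np.arange(npos), ns)

    d_max = rng_dist.uniform(*design.d_max_range, size=npos)
    d_min = rng_dist.uniform(*design.d_min_range, size=npos)

    if covariates is None:
        half = npos // 2
        strat = np.zeros((ns, npos), dtype=int)
        base = np.r_[np.ones(half, dtype=int), np.zeros(npos - half, dtype=int)]
        for s in range(ns):
            strat[s] = rng_layout.permutation(base)
        covariates = pd.DataFrame({"strategy": strat.ravel()})
        covariates.attrs["log_hr"] = {"strategy": design.strategy_log_hr}
    else:
        if len(covariates) != n:
            raise ValueError(f"covariates must have {n} rows")
        covariates = covariates.reset_index(drop=True)
        if "log_hr" not in covariates.attrs:
            raise ValueError("covariates frame needs attrs['log_hr'] slope mapping")

    eta = np.zeros(n)
    for col, slope in covariates.attrs["log_hr"].items():
        eta += slope * covariates[col].to_numpy(dtype=float)
    b_subj = rng_re.standard_normal(ns) * design.subject_sd
    b_pos = rng_re.standard_normal(npos) * design.position_sd
    eta += b_subj[subject] + b_pos[position]

    u_max = 1.0 - d_min[position] / d_max[position]
    rate = design.baseline_hazard * np.exp(eta)
    draws = rng_event.exponential(1.0, size=n)
    u = np.where(rate > 0, draws / np.maximum(rate, 1e-300), np.inf)
    event = u <= u_max
    response = np.where(event, u, u_max)
    d_detect = np.where(event, d_max[position] * (1.0 - u), np.nan)

    out = pd.DataFrame(
        {
            "subject": subject,
            "position": position,
            "d_max": d_max[position],
            "d_min": d_min[position],
            "d_detect": d_detect,
            "response": response,
            "event": event.astype(int),
        }
    )
    for col in covariates.columns:
        out[col] = covariates[col].to_numpy()
    out.attrs["log_hr"] = dict(covariates.attrs["log_hr"])
    return out
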