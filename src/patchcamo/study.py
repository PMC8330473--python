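"""End-to-end synthetic study: scenes -> target colours -> contrast
predictors -> detection trials -> survival model ladder.

This is the glue that exercises the whole pipeline the way the field
study does, at a scale a laptop handles in seconds: a set of transect
positions, each a synthetic patchy scene with a hare-shaped target;
specialist target colours designed from the microhabitat colour groups
and a generalist colour from the whole-scene mean; per-position,
per-colour CIEDE2000 contrast predictors against the near zone and the
whole scene; and detection trials whose true hazard is driven by the
near-zone contrast — so the model ranking (near-zone contrast over
whole-scene contrast over the coarse specialist/generalist dichotomy)
is a property the fitted AIC ladder should recover.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import design, scene, synth
from .survival import CoxFrailtyModel, aic_ladder

__all__ = ["StudySpec", "SyntheticStudy", "simulate_study", "fit_ladder"]

#: Default microhabitat palette: temperate greens and browns (grass,
#: dried bracken, leaf litter, dark bramble), Gaussian in Lab.
DEFAULT_MICROHABITATS = (
    ("grass", (50.0, -18.0, 30.0), (4.0, 2.5, 3.0), 0.25),
    ("bracken", (48.0, 8.0, 25.0), (4.0, 2.5, 3.0), 0.25),
    ("leaf_litter", (42.0, 10.0, 20.0), (4.0, 2.5, 3.0), 0.25),
    ("bramble", (32.0, -12.0, 15.0), (4.0, 2.5, 3.0), 0.25),
)


@dataclass
class StudySpec:
    """Conditions of a synthetic detection study.

    The defaults shrink the photographic side so the target stands
    ~64 px tall in a 384x512 scene, and mirror the field design at its
    natural scale: 40 photographed target locations, 20 observers who
    each search every location (800 presentations), the per-unit
    contrast effect on the log-hazard scale, and censoring of roughly
    one presentation in ten.
    """

    n_positions: int = 40
    n_subjects: int = 20
    scene_px: tuple[int, int] = (384, 512)
    px_per_mm: float = 0.16
    patch_scale_px: float = 8.0
    microhabitats: tuple = DEFAULT_MICROHABITATS
    target_height_mm: float = 400.0
    exclusion_px: int = 2
    delta_e_log_hr: float = 0.06
    local_bias_strength: float = 2.0
    subject_sd: float = 0.2
    position_sd: float = 0.2
    baseline_hazard: float = 1.5
    seed: int = 0


@dataclass
class SyntheticStudy:
    spec: StudySpec
    predictors: pd.DataFrame  # one row per (position, colour)
    trials: pd.DataFrame  # one row per presentation
    scenes: list = field(default_factory=list)


def _scene_spec(spec: StudySpec, position: int) -> synth.SceneSpec:
    mhs = tuple(
        synth.MicrohabitatSpec(name, mean, sd, w, spec.patch_scale_px)
        for name, mean, sd, w in spec.microhabitats
    )
    # each target site sits in a locally enriched patch of one habitat,
    # rotating over positions, so near zones differ from the scene mix
    bias = (position % len(mhs), spec.local_bias_strength,
            1.5 * spec.target_height_mm * spec.px_per_mm)
    return synth.SceneSpec(
        width_px=spec.scene_px[1],
        height_px=spec.scene_px[0],
        px_per_mm=spec.px_per_mm,
        microhabitats=mhs,
        seed=int(np.random.SeedSequence((spec.seed, 101, position)).generate_state(1)[0] % (2**31)),
        local_bias=bias,
    )


def simulate_study(spec: StudySpec = StudySpec(), keep_scenes: bool = False) -> SyntheticStudy:
    """Build scenes, design colours, measure contrasts, simulate trials.

    Target colours per position set: four specialists (each microhabitat's
    designed colour from pooled scene selections) and one generalist (the
    cross-scene whole-image mean).  Each subject sees each position once,
    with colours rotated so every colour appears equally often per subject.
    The true log hazard of a presentation is
    ``delta_e_log_hr * dE_near + b_subject + b_position``.
    """
    # --- scenes with targets ---------------------------------------------
    scenes = []
    for pos in range(spec.n_positions):
        sc = synth.generate_scene(_scene_spec(spec, pos))
        scenes.append(synth.place_target(sc, height_mm=spec.target_height_mm))

    # --- colour design: pooled specialist groups + generalist -------------
    names = [m[0] for m in spec.microhabitats]
    groups = []
    for i, name in enumerate(names):
        samples = []
        for sc in scenes:
            sel = sc.label_map == i
            if sel.any():
                samples.append(sc.lab_image[sel].mean(axis=0))
        groups.append(design.ColorGroup(name, np.array(samples)))
    generalist = design.generalist_color((sc.lab_image, sc.target_mask) for sc in scenes)
    colours = {name: g.median for name, g in zip(names, groups)}
    colours["generalist"] = generalist

    # --- contrast predictors per (position, colour) -----------------------
    band = round(spec.target_height_mm * spec.px_per_mm)
    rows = []
    for pos, sc in enumerate(scenes):
        for cname, lab in colours.items():
            de_near, de_whole = scene.contrast_predictors(
                lab, sc.lab_image, sc.target_mask, band, spec.exclusion_px
            )
            rows.append((pos, cname, int(cname == "generalist"), de_near, de_whole))
    preds = pd.DataFrame(
        rows, columns=["position", "colour", "strategy_generalist", "de_near", "de_whole"]
    )

    # --- presentation covariates: rotate colours over positions -----------
    colour_names = list(colours)
    n_col = len(colour_names)
    cov_rows = []
    for s in range(spec.n_subjects):
        for pos in range(spec.n_positions):
            cname = colour_names[(pos + s) % n_col]
            cov_rows.append((pos, cname))
    cov = pd.DataFrame(cov_rows, columns=["position", "colour"]).merge(
        preds, on=["position", "colour"], how="left"
    )
    cov = cov[["strategy_generalist", "de_near", "de_whole"]].copy()
    cov.attrs["log_hr"] = {"de_near": spec.delta_e_log_hr}

    td = synth.TrialDesign(
        n_subjects=spec.n_subjects,
        n_positions=spec.n_positions,
        subject_sd=spec.subject_sd,
        position_sd=spec.position_sd,
        baseline_hazard=spec.baseline_hazard,
        seed=int(np.random.SeedSequence((spec.seed, 202)).generate_state(1)[0] % (2**31)),
    )
    trials = synth.generate_detection_trials(td, covariates=cov)
    return SyntheticStudy(spec, preds, trials, scenes if keep_scenes else [])


def fit_ladder(study: SyntheticStudy, frailty=("subject", "position")) -> pd.DataFrame:
    """Fit the contrast/strategy/null model ladder and rank by AIC.

    Mirrors the field analysis: one model per predictor of detection risk
    (near-zone contrast, whole-scene contrast, specialist/generalist
    strategy) plus a null model, all sharing the same random effects.
    """
    tr = study.trials
    fr = list(frailty)
    fits, labels = [], []
    for label, cols in (
        ("de_near", ["de_near"]),
        ("de_whole", ["de_whole"]),
        ("strategy", ["strategy_generalist"]),
        ("null", []),
    ):
        m = CoxFrailtyModel.from_dataframe(tr, cols, frailty=fr)
        fits.append(m.fit())
        labels.append(label)
    return aic_ladder(fits, labels)
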