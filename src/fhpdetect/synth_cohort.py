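"""Synthetic posture-cohort generator.

The study population this package targets (lateral photographs of
adolescents screened for forward head posture) is not publicly available,
so every pipeline stage is exercised against cohorts drawn from an
explicit generative model:

* a subject is FHP-positive with the study prevalence (1024/1651 by
  default) and receives demographics drawn from class-conditional
  truncated normals matching the published cohort table (age 12.1 ± 1.2 y
  clipped to [10, 15], height ≈ 160/158 cm, mass ≈ 55/54 kg, ~53% female);
* the head geometry is driven by three latent angles drawn from
  class-conditional truncated normals — the ear elevation EAH, the
  ear–nose separation ENA and a small eye–nose offset — with FHP subjects
  given systematically smaller means.  The nose and eye elevations follow
  as NAH = EAH + ENA and PAH = NAH + offset, which enforces the
  ear < nose < eye elevation ordering and makes the four angles mutually
  consistent by construction (in 2-D the angle between the ear and nose
  rays *is* the difference of their elevations);
* landmark coordinates are back-solved by placing the shoulder vertex at
  a canvas anchor and the ear/nose/eye on rays at the drawn elevations.
  The *vertical* heights of ear, nose and eye above the shoulder (which
  become d3, d1, d2) are drawn from class-independent distributions and
  each ray's radius is solved as height/sin(elevation): forward head
  posture displaces the head anteriorly at a similar vertical height, so
  smaller angles mean longer, flatter rays while the vertical distances
  carry no class signal.  The four angle features are therefore the only
  informative features in the 12-feature universe (the demographics are
  near-identical across classes, as in the published cohort table).
  Coordinates are then perturbed by isotropic Gaussian noise; detector
  confidences are Beta-distributed, and keypoints may drop out.  The
  remaining 14 keypoints are cosmetic template offsets so emitted files
  are format-complete.

The class-conditional angle means/SDs are illustrative defaults — the
real cohort's angle distributions are unpublished — chosen to give a
Bayes-optimal accuracy around 0.80, comfortably above the 62% majority
rate but far from separable.  Because the latents are Gaussians with
shared SDs, the generator's Bayes accuracy has a closed form
(:func:`bayes_accuracy`), giving trained classifiers an analytic ceiling.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Tuple

import numpy as np
import pandas as pd
from scipy.stats import norm, truncnorm

from .errors import FHPError
from .features import compute_features, feature_frame
from .landmark_io import (
    KEYPOINT_NAMES, N_KEYPOINTS, Keypoint, PoseRecord, SubjectMeta,
    write_openpose_json, extract_anatomical_points,
)

# truncation bounds for the latent draws (degrees / pixels)
EAH_BOUNDS = (20.0, 80.0)
ENA_BOUNDS = (2.0, 40.0)
OFFSET_BOUNDS = (0.5, 15.0)
PAH_MAX = 88.0
AGE_BOUNDS = (10.0, 15.0)
HEIGHT_BOUNDS = (130.0, 195.0)
MASS_BOUNDS = (15.0, 130.0)
HEAD_HEIGHT_BOUNDS = (100.0, 210.0)

_MAX_RESAMPLE = 200


@dataclass(frozen=True)
class ClassAngleParams:
    """Latent angle distribution for one class, degrees."""

    eah_mean: float
    eah_sd: float
    ena_mean: float
    ena_sd: float
    pupil_offset_mean: float
    pupil_offset_sd: float


@dataclass(frozen=True)
class ClassDemographics:
    age_mean: float
    age_sd: float
    height_mean: float
    height_sd: float
    mass_mean: float
    mass_sd: float
    female_fraction: float


@dataclass
class CohortParams:
    """Full generative configuration; ``seed`` is mandatory for every draw."""

    n_subjects: int = 1651
    prevalence: float = 1024 / 1651
    # illustrative (non-study) class-conditional angle defaults; FHP smaller
    fhp_angles: ClassAngleParams = field(default_factory=lambda: ClassAngleParams(
        eah_mean=47.0, eah_sd=6.0, ena_mean=11.0, ena_sd=4.0,
        pupil_offset_mean=4.0, pupil_offset_sd=2.0))
    normal_angles: ClassAngleParams = field(default_factory=lambda: ClassAngleParams(
        eah_mean=55.0, eah_sd=6.0, ena_mean=14.0, ena_sd=4.0,
        pupil_offset_mean=5.0, pupil_offset_sd=2.0))
    # demographics from the published cohort table
    fhp_demo: ClassDemographics = field(default_factory=lambda: ClassDemographics(
        age_mean=12.08, age_sd=1.15, height_mean=160.38, height_sd=9.22,
        mass_mean=55.48, mass_sd=16.16, female_fraction=542 / 1024))
    normal_demo: ClassDemographics = field(default_factory=lambda: ClassDemographics(
        age_mean=12.09, age_sd=1.17, height_mean=158.18, height_sd=11.09,
        mass_mean=54.18, mass_sd=15.43, female_fraction=331 / 627))
    # class-independent vertical heights above the shoulder, pixels
    neck_length_mean: float = 155.0   # vertical ear height; becomes d3 exactly
    neck_length_sd: float = 10.0
    nose_height_mean: float = 135.0   # becomes d1
    nose_height_sd: float = 10.0
    eye_height_mean: float = 150.0    # becomes d2
    eye_height_sd: float = 10.0
    landmark_noise_sd: float = 1.5    # pixels, isotropic
    confidence_alpha: float = 8.0     # Beta(alpha, beta) detector confidence
    confidence_beta: float = 2.0
    dropout_prob: float = 0.0         # per-keypoint missingness
    canvas_width: int = 640
    canvas_height: int = 960
    anchor: Tuple[float, float] = (280.0, 400.0)  # shoulder position
    seed: int = 0

    def __post_init__(self):
        if not 0.0 < self.prevalence < 1.0:
            raise ValueError("prevalence must lie in (0, 1)")
        if self.seed is None:
            raise ValueError("seed is mandatory")

    def angles(self, label: int) -> ClassAngleParams:
        return self.fhp_angles if label == 1 else self.normal_angles

    def demo(self, label: int) -> ClassDemographics:
        return self.fhp_demo if label == 1 else self.normal_demo


def _tnorm(rng, mean, sd, bounds) -> float:
    if sd == 0:
        return float(np.clip(mean, *bounds))
    a, b = (bounds[0] - mean) / sd, (bounds[1] - mean) / sd
    return float(truncnorm.rvs(a, b, loc=mean, scale=sd, random_state=rng))


def sample_demographics(params: CohortParams, class_label: int, rng) -> SubjectMeta:
    """Draw one subject's demographics for a class; BMI derived."""
    d = params.demo(class_label)
    age = _tnorm(rng, d.age_mean, d.age_sd, AGE_BOUNDS)
    height = _tnorm(rng, d.height_mean, d.height_sd, HEIGHT_BOUNDS)
    mass = _tnorm(rng, d.mass_mean, d.mass_sd, MASS_BOUNDS)
    gender = "female" if rng.random() < d.female_fraction else "male"
    return SubjectMeta(
        gender=gender, age=age, height=height, weight=mass,
        bmi=mass / (height / 100.0) ** 2,
        label="FHP" if class_label == 1 else "normal",
    )


# cosmetic skeleton template: keypoint index -> offset from the shoulder
# anchor (pixels, image coordinates).  Side view: left-side points nearly
# coincide with right-side ones.
_TEMPLATE_OFFSETS: Dict[int, Tuple[float, float]] = {
    1: (8.0, -20.0),     # neck
    3: (6.0, 95.0),      # right elbow
    4: (40.0, 150.0),    # right wrist (arms folded)
    5: (-6.0, 4.0),      # left shoulder (overlapping in side view)
    6: (0.0, 97.0),      # left elbow
    7: (36.0, 152.0),    # left wrist
    8: (4.0, 190.0),     # right hip
    9: (6.0, 330.0),     # right knee
    10: (8.0, 470.0),    # right ankle
    11: (-2.0, 191.0),   # left hip
    12: (0.0, 331.0),    # left knee
    13: (2.0, 471.0),    # left ankle
    15: (-4.0, 0.0),     # left eye placeholder, filled relative to right eye
    17: (-4.0, 0.0),     # left ear placeholder
}


def _draw_latents(params: CohortParams, class_label: int, rng):
    ang = params.angles(class_label)
    for _ in range(_MAX_RESAMPLE):
        eah = _tnorm(rng, ang.eah_mean, ang.eah_sd, EAH_BOUNDS)
        ena = _tnorm(rng, ang.ena_mean, ang.ena_sd, ENA_BOUNDS)
        off = _tnorm(rng, ang.pupil_offset_mean, ang.pupil_offset_sd, OFFSET_BOUNDS)
        if eah + ena + off < PAH_MAX:
            return eah, ena, off
    raise FHPError("could not draw a feasible angle combination; check CohortParams")


def sample_pose(
    params: CohortParams, class_label: int, rng, subject_id: str = "synthetic"
) -> Tuple[PoseRecord, Dict[str, float]]:
    """Back-solve one pose from drawn latent angles.

    Returns the record plus the ground-truth angles/distances it encodes
    (before noise), for forward–inverse round-trip tests.
    """
    eah, ena, off = _draw_latents(params, class_label, rng)
    nah, pah = eah + ena, eah + ena + off
    # vertical heights are class-independent; radii follow from the angles
    d3 = _tnorm(rng, params.neck_length_mean, params.neck_length_sd, HEAD_HEIGHT_BOUNDS)
    d1 = _tnorm(rng, params.nose_height_mean, params.nose_height_sd, HEAD_HEIGHT_BOUNDS)
    d2 = _tnorm(rng, params.eye_height_mean, params.eye_height_sd, HEAD_HEIGHT_BOUNDS)
    ax, ay = params.anchor

    def placed(angle_deg: float, height: float) -> Tuple[float, float]:
        th = math.radians(angle_deg)
        return (ax + height / math.tan(th), ay - height)

    pts = {
        2: (ax, ay),             # shoulder (RAP)
        16: placed(eah, d3),     # ear (REAMP)
        0: placed(nah, d1),      # nose (NP)
        14: placed(pah, d2),     # eye (RPCP)
    }
    truth = {
        "EAH": eah, "ENA": ena, "NAH": nah, "PAH": pah,
        "d1": d1, "d2": d2, "d3": d3,
    }
    for idx, offs in _TEMPLATE_OFFSETS.items():
        if idx == 15:
            base = pts[14]
        elif idx == 17:
            base = pts[16]
        else:
            base = (ax, ay)
        pts[idx] = (base[0] + offs[0], base[1] + offs[1])

    keypoints: Dict[int, Keypoint] = {}
    for idx in range(N_KEYPOINTS):
        if idx not in pts:
            continue
        if params.dropout_prob > 0 and rng.random() < params.dropout_prob:
            continue
        x, y = pts[idx]
        if params.landmark_noise_sd > 0:
            x += rng.normal(0.0, params.landmark_noise_sd)
            y += rng.normal(0.0, params.landmark_noise_sd)
        x = float(np.clip(x, 0.0, params.canvas_width))
        y = float(np.clip(y, 0.0, params.canvas_height))
        conf = float(np.clip(rng.beta(params.confidence_alpha, params.confidence_beta),
                             0.05, 1.0))
        keypoints[idx] = Keypoint(idx, KEYPOINT_NAMES[idx], x, y, conf)
    record = PoseRecord(
        subject_id=subject_id, keypoints=keypoints,
        image_width=params.canvas_width, image_height=params.canvas_height,
    )
    return record, truth


def sample_cohort(params: CohortParams):
    """Draw the full cohort in memory.

    Returns (records, metas, truths, labels) with class labels drawn
    Bernoulli(prevalence); reproducible per ``params.seed``.
    """
    rng = np.random.default_rng(params.seed)
    records, metas, truths, labels = [], [], [], []
    for i in range(params.n_subjects):
        label = int(rng.random() < params.prevalence)
        sid = f"S{i:05d}"
        meta = sample_demographics(params, label, rng)
        rec, truth = sample_pose(params, label, rng, subject_id=sid)
        records.append(rec)
        metas.append(meta)
        truths.append(truth)
        labels.append(label)
    return records, metas, truths, labels


def simulate_feature_table(params: CohortParams, conf_min: float = 0.0) -> pd.DataFrame:
    """Cohort → feature table through the real forward path (anatomical
    point extraction + angle computation).  Subjects whose feature points
    dropped out are omitted."""
    from .errors import IncompleteLandmarksError

    records, metas, _, _ = sample_cohort(params)
    vectors = []
    for rec, meta in zip(records, metas):
        try:
            pts = extract_anatomical_points(rec, conf_min)
        except IncompleteLandmarksError:
            continue
        vectors.append(compute_features(pts, meta, subject_id=rec.subject_id))
    return feature_frame(vectors)


def generate_cohort(params: CohortParams, out_dir) -> dict:
    """Materialise a cohort on disk: one pose JSON per subject plus a
    demographics/label CSV and a latent-truth CSV.  Byte-identical per seed."""
    out = Path(out_dir)
    (out / "poses").mkdir(parents=True, exist_ok=True)
    records, metas, truths, labels = sample_cohort(params)
    for rec in records:
        write_openpose_json([rec], out / "poses" / f"{rec.subject_id}.json")
    demo_rows, truth_rows = [], []
    for rec, meta, truth, label in zip(records, metas, truths, labels):
        demo_rows.append({
            "subject_id": rec.subject_id, "gender": meta.gender,
            "age": meta.age, "height": meta.height, "weight": meta.weight,
            "bmi": meta.bmi, "label": meta.label,
        })
        truth_rows.append({"subject_id": rec.subject_id, "label": label, **truth})
    demo_cols = ["subject_id", "gender", "age", "height", "weight", "bmi", "label"]
    truth_cols = ["subject_id", "label", "EAH", "ENA", "NAH", "PAH", "d1", "d2", "d3"]
    pd.DataFrame(demo_rows, columns=demo_cols).to_csv(
        out / "demographics.csv", index=False, float_format="%.10g")
    pd.DataFrame(truth_rows, columns=truth_cols).to_csv(
        out / "truth.csv", index=False, float_format="%.10g")
    return {
        "n_subjects": len(records),
        "n_positive": int(sum(labels)),
        "poses_dir": str(out / "poses"),
        "demographics_csv": str(out / "demographics.csv"),
        "truth_csv": str(out / "truth.csv"),
    }


def bayes_accuracy(params: CohortParams) -> float:
    """Closed-form Bayes-optimal accuracy of the generative model.

    The three latent angle draws are class-conditional Gaussians; with the
    default (shared-SD) configuration the log-likelihood ratio is linear
    and the optimal rule's accuracy depends only on the Mahalanobis
    distance d between class means and the prevalence pi:

        acc = pi * Phi(d/2 + t/d) + (1 - pi) * Phi(d/2 - t/d),  t = log(pi/(1-pi))

    Unequal per-class SDs are pooled (sqrt of the mean variance), making
    the value an approximation in that case; truncation of the latents is
    ignored (the default bounds clip well under 5% of the mass).
    Demographics are omitted: with near-identical class means they carry
    negligible signal.
    """
    f, g = params.fhp_angles, params.normal_angles
    d2 = 0.0
    for mf, sf, mg, sg in (
        (f.eah_mean, f.eah_sd, g.eah_mean, g.eah_sd),
        (f.ena_mean, f.ena_sd, g.ena_mean, g.ena_sd),
        (f.pupil_offset_mean, f.pupil_offset_sd, g.pupil_offset_mean, g.pupil_offset_sd),
    ):
        pooled_var = 0.5 * (sf * sf + sg * sg)
        if pooled_var > 0:
            d2 += (mf - mg) ** 2 / pooled_var
    d = math.sqrt(d2)
    pi = params.prevalence
    if d == 0:
        return max(pi, 1 - pi)
    t = math.log(pi / (1 - pi))
    return pi * norm.cdf(d / 2 + t / d) + (1 - pi) * norm.cdf(d / 2 - t / d)
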