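"""Synthetic DBS cohort generator.

Builds complete synthetic subjects — bilateral ellipsoidal nucleus atlas
with motor sub-regions, implanted electrodes with per-stratum displacement,
frontal air cavities, small rigid subcortical-refine (SCRF) transforms, and
pre/post clinical scores — with the statistical structure the downstream
analysis assumes, all under a single root seed.

The generator's role is parameter recovery: every injected truth
(displacement vector, cavity volume, SCRF parameters, outcome effect) is
recoverable by the corresponding downstream metric, so the whole pipeline
can be exercised end-to-end without patient imaging.

Conventions: world coordinates are RAS+ millimetres (X lateral, positive
towards the subject's right; Y anterior; Z superior).  The left hemisphere
is always implantation order 1 — the cohort this emulates was implanted left
side first in every case.  Default outcome effects are calibrated to the
reported cohort: percentage changes at 12 months with SDs taken as half the
published mean (+/- 2 SD) parentheticals.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .leads import ElectrodeModel, LeadSpec, load_lead_library
from .metrics import rigid_affine
from .volumes import LabelVolume, centered_affine, ellipsoid_mask

HEMISPHERES = ("left", "right")
NUCLEI = ("GPi", "STN")
SCORES = ("UPDRS3", "UPDRS4", "LEDD", "PDQ39", "weight")

# substream tags: subject k's draws never depend on n_subjects
_STREAM_TARGET = 0
_STREAM_DISPLACEMENT = 1
_STREAM_POSTOP = 2
_STREAM_OUTCOMES = 3
_STREAM_STIM = 4

#: Atlas label codes.  Motor voxels carry their own code; the "main" region
#: of a nucleus is the union of its main and motor labels, so every motor
#: voxel is by construction also a main-nucleus voxel.
ATLAS_LABELS = {
    "GPi_main_left": 1, "GPi_motor_left": 2,
    "GPi_main_right": 3, "GPi_motor_right": 4,
    "STN_main_left": 5, "STN_motor_left": 6,
    "STN_main_right": 7, "STN_motor_right": 8,
    "brain_other": 9,
}


class ConfigurationError(ValueError):
    """The cohort configuration is incomplete or inconsistent."""


class AtlasSizingError(ValueError):
    """The requested grid cannot contain the configured anatomy."""


def subject_rng(seed: int, subject_index: int, stream: int) -> np.random.Generator:
    """Independent substream for (subject, stream) under one root seed."""
    return np.random.default_rng(
        np.random.SeedSequence((int(seed), int(subject_index), int(stream)))
    )


# --------------------------------------------------------------------------
# configuration
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class Stratum:
    """Mean displacement vector and per-axis SDs (mm) for one stratum."""

    mean: tuple[float, float, float]
    sd: tuple[float, float, float]

    def __post_init__(self) -> None:
        if len(self.mean) != 3 or len(self.sd) != 3:
            raise ConfigurationError("mean and sd must be 3-vectors")
        if any(s < 0 for s in self.sd):
            raise ConfigurationError("standard deviations must be >= 0")


@dataclass(frozen=True)
class OutcomeEffect:
    """Mean percentage change post vs pre and its SD (percentage points)."""

    mean_pct: float
    sd_pct: float

    def __post_init__(self) -> None:
        if self.sd_pct < 0:
            raise ConfigurationError("outcome dispersion must be >= 0")


def default_displacement_model() -> dict:
    """Per-stratum displacement defaults: GPi noisier than STN, a small
    lateral bias on the second (right) side.  The right-hemisphere lateral
    SD is additionally inflated by ``right_x_variance_multiplier``."""
    return {
        ("left", "GPi"): Stratum((0.0, 0.0, 0.0), (1.0, 1.0, 1.0)),
        ("right", "GPi"): Stratum((0.5, 0.0, 0.0), (1.0, 1.0, 1.0)),
        ("left", "STN"): Stratum((0.0, 0.0, 0.0), (0.7, 0.7, 0.7)),
        ("right", "STN"): Stratum((0.3, 0.0, 0.0), (0.7, 0.7, 0.7)),
    }


def default_outcome_effects() -> dict:
    # cohort-calibrated percentage changes; SD = half the published 2-SD span
    return {
        "UPDRS3": OutcomeEffect(-45.9, 11.75),
        "UPDRS4": OutcomeEffect(-72.2, 11.75),
        "LEDD_GPi": OutcomeEffect(0.9, 12.55),
        "LEDD_STN": OutcomeEffect(-54.3, 12.45),
        "PDQ39": OutcomeEffect(-32.1, 17.3),
        "weight": OutcomeEffect(8.7, 2.7),
    }


def default_baseline_scores() -> dict:
    # pre-operative score distributions (mean, SD); SD = half the published
    # 2-SD parenthetical; body weight is not tabulated and uses a generic
    # adult distribution
    return {
        "UPDRS3": (48.1, 4.75),
        "UPDRS4": (8.6, 2.2),
        "LEDD": (1112.8, 287.65),
        "PDQ39": (76.5, 11.25),
        "weight": (78.0, 7.0),
    }


@dataclass(frozen=True)
class AtlasSpec:
    """Geometry of the synthetic bilateral atlas (all mm / mm^3)."""

    grid_shape: tuple[int, int, int] = (121, 145, 121)
    voxel_size: float = 1.0
    gpi_volume_mm3: float = 470.0      # per side
    stn_volume_mm3: float = 160.0      # per side
    gpi_center: tuple[float, float, float] = (20.0, -4.0, -2.0)   # right side
    stn_center: tuple[float, float, float] = (11.0, -13.0, -7.0)  # right side
    gpi_axis_ratio: tuple[float, float, float] = (1.4, 1.0, 0.62)
    stn_axis_ratio: tuple[float, float, float] = (1.45, 1.0, 0.73)
    brain_center: tuple[float, float, float] = (0.0, -5.0, 0.0)
    brain_semi_axes: tuple[float, float, float] = (50.0, 60.0, 45.0)

    def __post_init__(self) -> None:
        if self.voxel_size <= 0:
            raise ConfigurationError("voxel_size must be > 0")
        if any(s < 8 for s in self.grid_shape):
            raise AtlasSizingError("grid too small for a bilateral atlas")


@dataclass(frozen=True)
class CohortConfig:
    """Everything the generator needs, under one seed.

    ``gpi_fraction`` is the probability a subject is a GPi case (default
    15/38, the cohort's target mix).  ``right_x_variance_multiplier``
    inflates the right-hemisphere lateral displacement SD, emulating the
    X-dominant second-side variance.  Stimulation defaults are 60 us pulse
    width at 130 Hz.
    """

    n_subjects: int = 38
    gpi_fraction: float = 15.0 / 38.0
    displacement_model: dict = field(default_factory=default_displacement_model)
    right_x_variance_multiplier: float = 2.0
    pneumocephalus_volume_range_ml: tuple[float, float] = (0.0, 20.0)
    scrf_translation_scale_mm: float = 0.5
    scrf_rotation_scale_deg: float = 0.5
    outcome_effects: dict = field(default_factory=default_outcome_effects)
    baseline_scores: dict = field(default_factory=default_baseline_scores)
    atlas: AtlasSpec = field(default_factory=AtlasSpec)
    lead_mix: dict = field(default_factory=lambda: {
        "6170": 20 / 38, "6147": 8 / 38, "Cartesia": 7 / 38, "3389": 3 / 38,
    })
    amplitude_mean_v: float = 3.0
    amplitude_sd_v: float = 0.5
    pulse_width_us: float = 60.0
    frequency_hz: float = 130.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ConfigurationError("n_subjects must be >= 1")
        if not 0.0 <= self.gpi_fraction <= 1.0:
            raise ConfigurationError("gpi_fraction must be in [0, 1]")
        if self.right_x_variance_multiplier < 1.0:
            raise ConfigurationError("right_x_variance_multiplier must be >= 1")
        lo, hi = self.pneumocephalus_volume_range_ml
        if lo < 0 or hi < lo:
            raise ConfigurationError("invalid pneumocephalus volume range")
        if self.scrf_translation_scale_mm < 0 or self.scrf_rotation_scale_deg < 0:
            raise ConfigurationError("SCRF scales must be >= 0")
        for key, stratum in self.displacement_model.items():
            if not isinstance(stratum, Stratum):
                raise ConfigurationError(f"stratum {key} must be a Stratum")


# --------------------------------------------------------------------------
# atlas
# --------------------------------------------------------------------------

def _semi_axes(volume_mm3: float, ratio) -> np.ndarray:
    ratio = np.asarray(ratio, dtype=float)
    scale = (volume_mm3 * 3.0 / (4.0 * np.pi) / np.prod(ratio)) ** (1.0 / 3.0)
    return ratio * scale


def atlas_mask(atlas: LabelVolume, nucleus: str, hemisphere: str,
               reference: str = "main") -> np.ndarray:
    """Boolean mask for a nucleus region.

    ``reference='main'`` is the whole nucleus (main union motor voxels);
    ``'motor'`` is the motor sub-region alone.
    """
    if reference == "main":
        names = [f"{nucleus}_main_{hemisphere}", f"{nucleus}_motor_{hemisphere}"]
    elif reference == "motor":
        names = [f"{nucleus}_motor_{hemisphere}"]
    else:
        raise ValueError("reference must be 'main' or 'motor'")
    return atlas.mask(names)


def atlas_region_labels(nucleus: str, hemisphere: str, reference: str) -> list[str]:
    if reference == "main":
        return [f"{nucleus}_main_{hemisphere}", f"{nucleus}_motor_{hemisphere}"]
    return [f"{nucleus}_motor_{hemisphere}"]


def brain_mask_volume(atlas: LabelVolume) -> LabelVolume:
    """Binary brain mask (label 1) covering every labelled voxel."""
    return LabelVolume(
        (atlas.data > 0).astype(np.int16), atlas.affine.copy(), {"brain": 1}
    )


def generate_atlas(spec: AtlasSpec | None = None) -> LabelVolume:
    """Deterministic bilateral ellipsoidal atlas with motor sub-regions.

    GPi and STN are axis-aligned ellipsoids mirrored about the midline; the
    motor sub-region is the posterior half-ellipsoid for the STN and a
    posteroventral half-ellipsoid (an oblique cut) for the GPi.  A large
    ellipsoidal brain mask contains all nuclei.
    """
    spec = spec or AtlasSpec()
    shape = tuple(spec.grid_shape)
    affine = centered_affine(shape, spec.voxel_size)
    vol = LabelVolume(np.zeros(shape, dtype=np.int16), affine,
                      labels=dict(ATLAS_LABELS))

    half_extent = np.array(shape) * spec.voxel_size / 2.0
    for center, semi, what in (
        (spec.brain_center, spec.brain_semi_axes, "brain"),
        (spec.gpi_center, _semi_axes(spec.gpi_volume_mm3, spec.gpi_axis_ratio), "GPi"),
        (spec.stn_center, _semi_axes(spec.stn_volume_mm3, spec.stn_axis_ratio), "STN"),
    ):
        if np.any(np.abs(np.asarray(center)) + np.asarray(semi) > half_extent):
            raise AtlasSizingError(
                f"{what} ellipsoid does not fit the {shape} grid at "
                f"{spec.voxel_size} mm voxels"
            )

    brain = ellipsoid_mask(vol, spec.brain_center, spec.brain_semi_axes)
    vol.data[brain] = ATLAS_LABELS["brain_other"]

    ijk = np.indices(shape).reshape(3, -1).T
    xyz = vol.voxel_to_world(ijk).reshape(*shape, 3)

    for nucleus, center_r, volume, ratio in (
        ("GPi", spec.gpi_center, spec.gpi_volume_mm3, spec.gpi_axis_ratio),
        ("STN", spec.stn_center, spec.stn_volume_mm3, spec.stn_axis_ratio),
    ):
        semi = _semi_axes(volume, ratio)
        for hemisphere in HEMISPHERES:
            center = np.asarray(center_r, dtype=float).copy()
            if hemisphere == "left":
                center[0] = -center[0]
            inside = ellipsoid_mask(vol, center, semi)
            if not inside.any():
                raise AtlasSizingError(f"{nucleus} {hemisphere} has no voxels")
            if nucleus == "STN":
                motor_cut = xyz[..., 1] < center[1]          # posterior half
            else:
                motor_cut = (xyz[..., 1] - center[1]) + (xyz[..., 2] - center[2]) < 0.0
            vol.data[inside] = ATLAS_LABELS[f"{nucleus}_main_{hemisphere}"]
            vol.data[inside & motor_cut] = ATLAS_LABELS[f"{nucleus}_motor_{hemisphere}"]
    return vol


# --------------------------------------------------------------------------
# subjects
# --------------------------------------------------------------------------

@dataclass
class SubjectRecord:
    """One synthetic subject with all injected ground truth."""

    id: str
    target: str                                   # GPi or STN
    electrodes: dict[str, ElectrodeModel]
    scrf: dict[str, np.ndarray]                   # per-hemisphere 4x4 affine
    displacement_truth: dict[str, np.ndarray]     # injected tip displacement, mm
    scrf_truth: dict[str, dict]                   # translation/rotation params
    pneumocephalus_truth_ml: float
    scores_pre: dict[str, float]
    scores_post: dict[str, float]
    outcome_pct_truth: dict[str, float]
    stimulation: dict[str, float]
    lead_model: str


@dataclass
class Cohort:
    """Generated cohort: atlas, template brain mask, and all subjects."""

    config: CohortConfig
    atlas: LabelVolume
    template_brain: LabelVolume
    subjects: list[SubjectRecord]


def _draw_target(config: CohortConfig, subject_index: int) -> str:
    rng = subject_rng(config.seed, subject_index, _STREAM_TARGET)
    return "GPi" if rng.random() < config.gpi_fraction else "STN"


def _entry_direction(hemisphere: str) -> np.ndarray:
    # tip->entry: superior, slightly anterior and lateral (a typical frontal
    # burr-hole trajectory); lateral sign follows the hemisphere
    lateral = 0.15 if hemisphere == "right" else -0.15
    d = np.array([lateral, 0.30, 0.94])
    return d / np.linalg.norm(d)


def _stratum_displacement(
    config: CohortConfig, hemisphere: str, nucleus: str,
    rng: np.random.Generator,
) -> np.ndarray:
    key = (hemisphere, nucleus)
    if key not in config.displacement_model:
        raise ConfigurationError(f"displacement model lacks stratum {key}")
    stratum = config.displacement_model[key]
    sd = np.asarray(stratum.sd, dtype=float).copy()
    if hemisphere == "right":
        sd[0] *= config.right_x_variance_multiplier
    return np.asarray(stratum.mean, dtype=float) + rng.standard_normal(3) * sd


def generate_electrodes(
    atlas: LabelVolume,
    config: CohortConfig,
    subject_index: int,
    target: str,
    lead: LeadSpec,
) -> tuple[dict[str, ElectrodeModel], dict[str, np.ndarray]]:
    """Bilateral electrodes for one subject.

    The planned position puts a mid-array contact centre on the motor
    sub-nucleus centroid ("centre of the motor component of the nucleus"),
    as a surgeon plans the active contact to sit at target with spare
    contacts either side; the realised tip is the planned tip plus a
    displacement drawn from the (hemisphere, nucleus) stratum.  Returns the
    electrodes and the injected displacement truth per hemisphere.
    """
    rng = subject_rng(config.seed, subject_index, _STREAM_DISPLACEMENT)
    electrodes: dict[str, ElectrodeModel] = {}
    truth: dict[str, np.ndarray] = {}
    for hemisphere in HEMISPHERES:  # left first: implantation order 1 then 2
        motor = atlas_region_labels(target, hemisphere, "motor")
        planned_contact = atlas.centroid_world(motor)
        direction = _entry_direction(hemisphere)
        target_contact = (lead.n_contacts - 1) // 2
        planned_tip = planned_contact - direction * (
            lead.tip_to_first_contact_centre + target_contact * lead.contact_pitch
        )
        displacement = _stratum_displacement(config, hemisphere, target, rng)
        electrodes[hemisphere] = ElectrodeModel(
            tip=planned_tip + displacement,
            direction=direction,
            spec=lead,
            hemisphere=hemisphere,
        )
        truth[hemisphere] = displacement
    return electrodes, truth


def carve_air_cavity(
    brain: LabelVolume,
    volume_ml: float,
    rng: np.random.Generator,
) -> tuple[LabelVolume, float]:
    """Remove a frontal ellipsoidal air cavity of ~``volume_ml`` from a mask.

    The cavity is centred in the anterior (most +Y) third of the mask, where
    post-durotomy air collects in a supine patient.  The ellipsoid is scaled
    by bisection so the carved voxel count matches the request; the returned
    truth is the exactly carved volume in mL.
    """
    mask = brain.mask("brain") if "brain" in brain.labels else brain.data > 0
    n_brain = int(mask.sum())
    vv = brain.voxel_volume
    target_voxels = volume_ml * 1000.0 / vv
    if target_voxels > n_brain:
        raise ValueError(
            f"requested cavity ({volume_ml} mL) exceeds brain mask volume "
            f"({n_brain * vv / 1000.0:.1f} mL)"
        )
    out = brain.copy()
    if volume_ml <= 0:
        return out, 0.0

    ijk = np.argwhere(mask)
    xyz = brain.voxel_to_world(ijk)
    y_lo, y_hi = xyz[:, 1].min(), xyz[:, 1].max()
    anterior = xyz[:, 1] >= y_lo + 2.0 * (y_hi - y_lo) / 3.0
    center = xyz[anterior].mean(axis=0)
    center[0] += rng.normal(0.0, 3.0)   # small lateral jitter
    center[2] += rng.normal(0.0, 3.0)

    r0 = (3.0 * volume_ml * 1000.0 / (4.0 * np.pi)) ** (1.0 / 3.0)
    ratio = np.array([1.2, 0.8, 1.0])
    dist2 = lambda s: (((xyz - center) / (ratio * r0 * s)) ** 2).sum(axis=1)

    lo, hi = 0.0, 4.0
    while (dist2(hi) <= 1.0).sum() < target_voxels and hi < 64.0:
        hi *= 2.0
    for _ in range(50):
        mid = 0.5 * (lo + hi)
        if (dist2(mid) <= 1.0).sum() < target_voxels:
            lo = mid
        else:
            hi = mid
    carved = dist2(hi) <= 1.0
    out.data[tuple(ijk[carved].T)] = 0
    return out, float(carved.sum()) * vv / 1000.0


def generate_scrf(config: CohortConfig, rng: np.random.Generator) -> tuple[np.ndarray, dict]:
    """One small rigid SCRF affine plus its ground-truth parameters."""
    t = rng.standard_normal(3) * config.scrf_translation_scale_mm
    r = rng.standard_normal(3) * config.scrf_rotation_scale_deg
    if config.scrf_translation_scale_mm == 0:
        t = np.zeros(3)
    if config.scrf_rotation_scale_deg == 0:
        r = np.zeros(3)
    return rigid_affine(t, r), {"translation_mm": t.tolist(),
                                "rotation_deg": r.tolist()}


def generate_postop_state(
    subject_index: int,
    brain: LabelVolume,
    config: CohortConfig,
) -> tuple[LabelVolume, dict[str, np.ndarray], dict]:
    """Post-operative state for one subject.

    Carves the air cavity (volume drawn uniformly from the configured
    range), draws per-hemisphere SCRF affines, and returns
    ``(air-modified brain mask, scrf transforms, truth record)``.
    """
    rng = subject_rng(config.seed, subject_index, _STREAM_POSTOP)
    lo, hi = config.pneumocephalus_volume_range_ml
    requested = float(rng.uniform(lo, hi))
    carved_brain, true_ml = carve_air_cavity(brain, requested, rng)
    scrf, scrf_truth = {}, {}
    for hemisphere in HEMISPHERES:
        scrf[hemisphere], scrf_truth[hemisphere] = generate_scrf(config, rng)
    truth = {"pneumocephalus_ml": true_ml, "scrf": scrf_truth,
             "requested_ml": requested}
    return carved_brain, scrf, truth


def generate_outcomes(
    config: CohortConfig,
    subject_index: int,
    target: str,
) -> tuple[dict, dict, dict]:
    """Pre/post clinical scores for one subject.

    ``post = pre * (1 + pct/100)`` with pct drawn per score from the
    configured effect; LEDD uses the target-specific effect (GPi vs STN).
    Scores are floored at zero.  Returns (pre, post, pct truth).
    """
    for score in SCORES:
        key = f"LEDD_{target}" if score == "LEDD" else score
        if key not in config.outcome_effects:
            raise ConfigurationError(f"outcome effect missing for {key}")
    rng = subject_rng(config.seed, subject_index, _STREAM_OUTCOMES)
    pre, post, pct_truth = {}, {}, {}
    for score in SCORES:
        mu, sd = config.baseline_scores[score]
        value = max(0.0, float(rng.normal(mu, sd)))
        key = f"LEDD_{target}" if score == "LEDD" else score
        effect = config.outcome_effects[key]
        pct = float(rng.normal(effect.mean_pct, effect.sd_pct)) \
            if effect.sd_pct > 0 else effect.mean_pct
        pre[score] = value
        post[score] = max(0.0, value * (1.0 + pct / 100.0))
        pct_truth[score] = pct
    return pre, post, pct_truth


def generate_subject(
    config: CohortConfig,
    subject_index: int,
    atlas: LabelVolume,
    template_brain: LabelVolume,
    lead_library: dict[str, LeadSpec],
    keep_brain: bool = False,
):
    """Generate one complete subject (optionally returning its carved brain)."""
    target = _draw_target(config, subject_index)
    stim_rng = subject_rng(config.seed, subject_index, _STREAM_STIM)
    models = sorted(config.lead_mix)
    probs = np.array([config.lead_mix[m] for m in models], dtype=float)
    probs /= probs.sum()
    lead_model = models[int(stim_rng.choice(len(models), p=probs))]
    lead = lead_library[lead_model]

    electrodes, disp_truth = generate_electrodes(
        atlas, config, subject_index, target, lead
    )
    carved_brain, scrf, postop_truth = generate_postop_state(
        subject_index, template_brain, config
    )
    pre, post, pct_truth = generate_outcomes(config, subject_index, target)
    amplitude = float(np.clip(
        stim_rng.normal(config.amplitude_mean_v, config.amplitude_sd_v), 0.5, 6.0
    ))
    record = SubjectRecord(
        id=f"sub-{subject_index:03d}",
        target=target,
        electrodes=electrodes,
        scrf=scrf,
        displacement_truth=disp_truth,
        scrf_truth=postop_truth["scrf"],
        pneumocephalus_truth_ml=postop_truth["pneumocephalus_ml"],
        scores_pre=pre,
        scores_post=post,
        outcome_pct_truth=pct_truth,
        stimulation={
            "amplitude_v": amplitude,
            "pulse_width_us": config.pulse_width_us,
            "frequency_hz": config.frequency_hz,
        },
        lead_model=lead_model,
    )
    if keep_brain:
        return record, carved_brain
    return record


def generate_cohort(config: CohortConfig | None = None) -> Cohort:
    """Generate the full cohort under ``config.seed``.

    Identical configs (including seed) give bit-identical cohorts; subject k
    is invariant to ``n_subjects`` because every random draw lives in a
    per-subject substream.  Carved post-operative brain masks are not stored
    (they are large); regenerate them per subject with
    :func:`generate_postop_state` — it is deterministic.
    """
    config = config or CohortConfig()
    atlas = generate_atlas(config.atlas)
    template_brain = brain_mask_volume(atlas)
    lead_library = load_lead_library()
    missing = set(config.lead_mix) - set(lead_library)
    if missing:
        raise ConfigurationError(f"lead model(s) not in library: {sorted(missing)}")
    subjects = [
        generate_subject(config, k, atlas, template_brain, lead_library)
        for k in range(config.n_subjects)
    ]
    return Cohort(config=config, atlas=atlas,
                  template_brain=template_brain, subjects=subjects)
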