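"""End-to-end pipeline: simulate -> accuracy metrics -> volumetry -> VAT ->
statistics -> report.

Each stage is a plain function taking the in-memory cohort plus the run
configuration and writing tidy CSV/JSON artefacts into the output
directory.  Electrodes are generated in brain-shift-corrected (SCRF) space;
the uncorrected ("nSCRF") variant of every metric maps each electrode
through the inverse of its hemisphere's SCRF affine.  The left hemisphere is
implantation order 1 throughout (left side implanted first).
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as dio
from .leads import contact_centers
from .metrics import (
    AccuracyResult,
    DistanceField,
    apply_scrf,
    boundary_distance,
    centroid_offset,
    flag_outliers,
    results_to_frame,
    summarise_accuracy,
    target_plot_table,
)
from .stats import (
    StatResult,
    ZeroVarianceError,
    anova_oneway,
    glm_fit,
    paired_t,
    pearson,
    results_table,
    two_sample_t,
)
from .synthetic import (
    HEMISPHERES,
    SCORES,
    Cohort,
    CohortConfig,
    atlas_region_labels,
    generate_cohort,
    generate_postop_state,
    subject_rng,
)
from .vat import ConductivityModel, compute_vat
from .volumetry import ShiftRecord, pneumocephalus_volume, shift_accuracy_correlations, shift_magnitude

logger = logging.getLogger(__name__)

_STREAM_FAILURES = 90


class PipelineError(RuntimeError):
    """A pipeline stage failed; carries the stage and subject."""

    def __init__(self, stage: str, subject: str | None, cause: Exception):
        self.stage, self.subject = stage, subject
        who = f" (subject {subject})" if subject else ""
        super().__init__(f"stage {stage!r}{who} failed: {cause}")


@dataclass(frozen=True)
class VatSettings:
    grid_extent_mm: float = 40.0
    grid_spacing_mm: float = 0.5
    threshold_v_per_mm: float = 0.2
    conductivity: ConductivityModel = field(default_factory=ConductivityModel)


@dataclass(frozen=True)
class StatsSettings:
    alpha: float = 0.05
    within_threshold_mm: float = 2.0
    shift_family_m: int = 3


@dataclass(frozen=True)
class RunConfig:
    """Fully defaulted pipeline configuration; a copy is written to every
    output directory so the manifest alone reproduces the run."""

    cohort: CohortConfig = field(default_factory=CohortConfig)
    vat: VatSettings = field(default_factory=VatSettings)
    stats: StatsSettings = field(default_factory=StatsSettings)
    registration_failures: int = 6
    vat_failures: int = 2

    @property
    def seed(self) -> int:
        return self.cohort.seed

    def with_seed(self, seed: int) -> "RunConfig":
        return dataclasses.replace(
            self, cohort=dataclasses.replace(self.cohort, seed=seed)
        )

    def to_dict(self) -> dict:
        def unpack(obj):
            if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
                return {k: unpack(v) for k, v in dataclasses.asdict(obj).items()}
            if isinstance(obj, dict):
                # stratum keys are (hemisphere, nucleus) tuples
                return {
                    ":".join(k) if isinstance(k, tuple) else str(k): unpack(v)
                    for k, v in obj.items()
                }
            if isinstance(obj, (list, tuple)):
                return [unpack(v) for v in obj]
            if isinstance(obj, np.ndarray):
                return obj.tolist()
            return obj

        return unpack(self)


def load_run_config(path: str | Path | None = None, seed: int | None = None) -> RunConfig:
    """Load a RunConfig from YAML/JSON, applying defaults for absent keys."""
    from .synthetic import AtlasSpec, OutcomeEffect, Stratum

    cfg = RunConfig()
    if path is not None:
        raw = yaml.safe_load(Path(path).read_text()) or {}
        cohort_raw = raw.get("cohort", {})
        if "displacement_model" in cohort_raw:
            cohort_raw["displacement_model"] = {
                tuple(k.split(":")): Stratum(tuple(v["mean"]), tuple(v["sd"]))
                for k, v in cohort_raw["displacement_model"].items()
            }
        if "outcome_effects" in cohort_raw:
            cohort_raw["outcome_effects"] = {
                k: OutcomeEffect(**v) for k, v in cohort_raw["outcome_effects"].items()
            }
        if "atlas" in cohort_raw:
            atlas_raw = {
                k: tuple(v) if isinstance(v, list) else v
                for k, v in cohort_raw["atlas"].items()
            }
            cohort_raw["atlas"] = AtlasSpec(**atlas_raw)
        for key in ("pneumocephalus_volume_range_ml", "baseline_scores"):
            if key in cohort_raw and isinstance(cohort_raw[key], list):
                cohort_raw[key] = tuple(cohort_raw[key])
        cohort = dataclasses.replace(CohortConfig(), **cohort_raw)
        vat_raw = dict(raw.get("vat", {}))
        if "conductivity" in vat_raw:
            vat_raw["conductivity"] = ConductivityModel(**vat_raw["conductivity"])
        cfg = RunConfig(
            cohort=cohort,
            vat=dataclasses.replace(VatSettings(), **vat_raw),
            stats=dataclasses.replace(StatsSettings(), **raw.get("stats", {})),
            registration_failures=raw.get("registration_failures", 6),
            vat_failures=raw.get("vat_failures", 2),
        )
    if seed is not None:
        cfg = cfg.with_seed(seed)
    return cfg


# --------------------------------------------------------------------------
# failure simulation
# --------------------------------------------------------------------------

@dataclass
class FailureReport:
    excluded_registration: list[str]
    excluded_vat: list[str]
    completers: list[str]
    n_subjects: int
    completion_pct: int

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def simulate_failures(
    subject_ids,
    registration_failures: int,
    vat_failures: int,
    seed: int,
) -> FailureReport:
    """Randomly mark subjects excluded at the registration or VAT stage.

    Downstream analyses use only completers; the completion percentage is
    reported to the nearest integer.
    """
    ids = list(subject_ids)
    n = len(ids)
    if registration_failures + vat_failures > n:
        raise ValueError("failure counts exceed the cohort size")
    rng = subject_rng(seed, 0, _STREAM_FAILURES)
    order = rng.permutation(n)
    reg = sorted(ids[i] for i in order[:registration_failures])
    vat = sorted(ids[i] for i in order[registration_failures:
                                       registration_failures + vat_failures])
    completers = [i for i in ids if i not in set(reg) | set(vat)]
    pct = int(round(100.0 * len(completers) / n))
    return FailureReport(reg, vat, completers, n, pct)


# --------------------------------------------------------------------------
# stages
# --------------------------------------------------------------------------

def simulate_stage(config: RunConfig, outdir: Path) -> Cohort:
    cohort = generate_cohort(config.cohort)
    dio.write_nifti(cohort.atlas, outdir / "atlas.nii.gz")
    dio.write_nifti(cohort.template_brain, outdir / "template_brain.nii.gz")
    dio.save_subjects(cohort.subjects, outdir / "subjects.json")
    dio.scores_table(cohort.subjects).to_csv(outdir / "scores.csv", index=False)
    for s in cohort.subjects:
        for h in HEMISPHERES:
            dio.save_affine_txt(s.scrf[h], outdir / f"scrf_{s.id}_{h}.txt")
    return cohort


def accuracy_stage(cohort: Cohort, config: RunConfig, outdir: Path,
                   completers: list[str]) -> pd.DataFrame:
    """Boundary distance and centroid offset per electrode x reference x
    SCRF state, with Tukey outlier flags within each reference group."""
    atlas = cohort.atlas
    fields: dict = {}
    subjects = [s for s in cohort.subjects if s.id in set(completers)]
    rows: list[AccuracyResult] = []
    for s in subjects:
        for h in HEMISPHERES:
            corrected = s.electrodes[h]
            uncorrected = apply_scrf(corrected, np.linalg.inv(s.scrf[h]))
            for reference in ("main", "motor"):
                labels = tuple(atlas_region_labels(s.target, h, reference))
                if labels not in fields:
                    fields[labels] = DistanceField(atlas, list(labels))
                for scrf_applied, electrode in ((True, corrected),
                                                (False, uncorrected)):
                    bd = boundary_distance(electrode, atlas, list(labels),
                                           field=fields[labels])
                    off, norm = centroid_offset(electrode, atlas, list(labels))
                    rows.append(AccuracyResult(
                        subject=s.id, hemisphere=h, nucleus=s.target,
                        reference=reference, boundary_distance=bd,
                        dx=off[0], dy=off[1], dz=off[2], centroid_norm=norm,
                        scrf_applied=scrf_applied,
                    ))
    df = results_to_frame(rows)
    # outlier flags within each reference x SCRF-state family
    for (_, _), grp in df.groupby(["reference", "scrf_applied"]):
        if len(grp) >= 4:
            df.loc[grp.index, "outlier"] = flag_outliers(
                grp["boundary_distance"].to_numpy()
            )
    df["implantation_order"] = np.where(df["hemisphere"] == "left", 1, 2)
    df.to_csv(outdir / "accuracy.csv", index=False)

    scrf_df = df[df["scrf_applied"]]
    thr = config.stats.within_threshold_mm
    summarise_accuracy(scrf_df, ["reference"], threshold_mm=thr).to_csv(
        outdir / "summary_overall.csv", index=False)
    summarise_accuracy(scrf_df, ["nucleus", "reference"], threshold_mm=thr).to_csv(
        outdir / "summary_by_nucleus.csv", index=False)
    summarise_accuracy(
        scrf_df, ["hemisphere", "implantation_order", "reference"],
        threshold_mm=thr,
    ).to_csv(outdir / "summary_by_hemisphere.csv", index=False)
    target_plot_table(df).to_csv(outdir / "target_plots.csv", index=False)
    return df


def volumetry_stage(cohort: Cohort, config: RunConfig, outdir: Path,
                    completers: list[str], accuracy: pd.DataFrame) -> pd.DataFrame:
    """Pneumocephalus, SCRF magnitude and their correlations with accuracy."""
    acc = accuracy[(accuracy["scrf_applied"]) & (accuracy["reference"] == "main")]
    mean_bd = acc.groupby("subject")["boundary_distance"].mean()
    records = []
    for s in cohort.subjects:
        if s.id not in set(completers):
            continue
        carved, scrf, _ = generate_postop_state(
            int(s.id.split("-")[1]), cohort.template_brain, cohort.config
        )
        air_ml = pneumocephalus_volume(cohort.template_brain, carved, label=1)
        mag = float(np.mean([shift_magnitude(scrf[h]) for h in HEMISPHERES]))
        records.append(ShiftRecord(
            subject=s.id, scrf_magnitude=mag, pneumocephalus_ml=air_ml,
            mean_boundary_distance=float(mean_bd.loc[s.id]),
        ))
    rec_df = pd.DataFrame([vars(r) for r in records])
    rec_df.to_csv(outdir / "shift_records.csv", index=False)
    try:
        corr = shift_accuracy_correlations(
            rec_df, family_m=config.stats.shift_family_m)
    except (ZeroVarianceError, ValueError) as exc:
        # degenerate cohorts (e.g. every electrode on target) carry no
        # correlation information; emit an empty table rather than abort
        logger.warning("shift correlations unavailable: %s", exc)
        corr = pd.DataFrame(columns=["analysis", "r", "r2", "df", "p",
                                     "p_corrected", "n", "dropped"])
    corr.to_csv(outdir / "shift_correlations.csv", index=False)
    return rec_df


def vat_stage(cohort: Cohort, config: RunConfig, outdir: Path,
              vat_completers: list[str]) -> pd.DataFrame:
    """Simplified finite-difference VAT per electrode with nucleus overlap."""
    atlas = cohort.atlas
    nucleus_codes = [v for k, v in atlas.labels.items() if k != "brain_other"]

    def grey_fn(xyz):
        ijk = np.round(atlas.world_to_voxel(xyz)).astype(int)
        ok = np.all((ijk >= 0) & (ijk < atlas.data.shape), axis=1)
        lab = np.zeros(len(ijk), dtype=atlas.data.dtype)
        lab[ok] = atlas.data[tuple(ijk[ok].T)]
        return np.isin(lab, nucleus_codes)

    rows = []
    keep = set(vat_completers)
    for s in cohort.subjects:
        if s.id not in keep:
            continue
        for h in HEMISPHERES:
            electrode = s.electrodes[h]
            motor_labels = atlas_region_labels(s.target, h, "motor")
            main_labels = atlas_region_labels(s.target, h, "main")
            motor_centroid = atlas.centroid_world(motor_labels)
            centers = contact_centers(electrode)
            active = int(np.argmin(
                np.linalg.norm(centers - motor_centroid, axis=1)))
            main_codes = [atlas.labels[n] for n in main_labels]
            motor_codes = [atlas.labels[n] for n in motor_labels]

            def regions_fn(xyz):
                ijk = np.round(atlas.world_to_voxel(xyz)).astype(int)
                ok = np.all((ijk >= 0) & (ijk < atlas.data.shape), axis=1)
                lab = np.zeros(len(ijk), dtype=atlas.data.dtype)
                lab[ok] = atlas.data[tuple(ijk[ok].T)]
                return {"main": np.isin(lab, main_codes),
                        "motor": np.isin(lab, motor_codes)}

            try:
                res = compute_vat(
                    electrode, active, s.stimulation["amplitude_v"],
                    grey_mask_fn=grey_fn, region_masks_fn=regions_fn,
                    conductivity=config.vat.conductivity,
                    threshold=config.vat.threshold_v_per_mm,
                    grid_extent_mm=config.vat.grid_extent_mm,
                    grid_spacing_mm=config.vat.grid_spacing_mm,
                )
            except Exception as exc:  # noqa: BLE001 - stage failure contract
                raise PipelineError("vat", s.id, exc) from exc
            rows.append({
                "subject": s.id, "hemisphere": h, "nucleus": s.target,
                "active_contact": active,
                "amplitude_v": s.stimulation["amplitude_v"],
                "vat_volume_mm3": res.vat_volume_mm3,
                "overlap_main_mm3": res.overlaps["main"]["overlap_mm3"],
                "overlap_main_fraction": res.overlaps["main"]["fraction"],
                "overlap_motor_mm3": res.overlaps["motor"]["overlap_mm3"],
                "overlap_motor_fraction": res.overlaps["motor"]["fraction"],
            })
    df = pd.DataFrame(rows)
    df.to_csv(outdir / "vat_overlap.csv", index=False)
    return df


def _pct_change(subjects, score):
    out = {}
    for s in subjects:
        pre = s.scores_pre[score]
        if pre > 0:
            out[s.id] = 100.0 * (s.scores_post[score] - pre) / pre
    return out


def stats_stage(cohort: Cohort, config: RunConfig, outdir: Path,
                completers: list[str], accuracy: pd.DataFrame,
                vat_df: pd.DataFrame) -> pd.DataFrame:
    subjects = [s for s in cohort.subjects if s.id in set(completers)]
    results: list[StatResult] = []

    # outcome change table + paired pre/post tests per score
    outcome_rows = []
    for score in SCORES:
        pre = [s.scores_pre[score] for s in subjects]
        post = [s.scores_post[score] for s in subjects]
        res = paired_t(pre, post)
        res.test = f"paired_t[{score}]"
        results.append(res)
        pct = np.array(list(_pct_change(subjects, score).values()))
        outcome_rows.append({
            "score": score, "n": len(subjects),
            "mean_pct_change": pct.mean(), "sd_pct_change": pct.std(ddof=1),
            "t": res.statistic, "df": res.df, "p": res.p,
        })
    pd.DataFrame(outcome_rows).to_csv(outdir / "outcomes.csv", index=False)

    # target-specific LEDD contrast (GPi vs STN percentage change)
    ledd = _pct_change(subjects, "LEDD")
    gpi = [ledd[s.id] for s in subjects if s.target == "GPi" and s.id in ledd]
    stn = [ledd[s.id] for s in subjects if s.target == "STN" and s.id in ledd]
    if len(gpi) >= 2 and len(stn) >= 2:
        res = two_sample_t(gpi, stn)
        res.test = "two_sample_t[LEDD_pct_GPi_vs_STN]"
        results.append(res)

    # accuracy contrasts on the SCRF main-nucleus boundary distances
    acc = accuracy[(accuracy["scrf_applied"]) & (accuracy["reference"] == "main")]
    both = accuracy[accuracy["scrf_applied"]]

    def guarded(fn, name, *args):
        try:
            res = fn(*args)
        except (ZeroVarianceError, ValueError) as exc:
            logger.warning("contrast %s skipped: %s", name, exc)
            return
        res.test = name
        results.append(res)

    gpi_d = acc.loc[acc["nucleus"] == "GPi", "boundary_distance"]
    stn_d = acc.loc[acc["nucleus"] == "STN", "boundary_distance"]
    if len(gpi_d) >= 2 and len(stn_d) >= 2:
        guarded(two_sample_t, "two_sample_t[accuracy_GPi_vs_STN]", gpi_d, stn_d)
    left = acc.loc[acc["hemisphere"] == "left", "boundary_distance"]
    right = acc.loc[acc["hemisphere"] == "right", "boundary_distance"]
    guarded(two_sample_t, "two_sample_t[accuracy_side1_vs_side2]", left, right)
    guarded(
        two_sample_t, "two_sample_t[accuracy_main_vs_motor]",
        both.loc[both["reference"] == "main", "boundary_distance"],
        both.loc[both["reference"] == "motor", "boundary_distance"],
    )
    groups = [g["boundary_distance"].to_numpy()
              for _, g in both.groupby(["nucleus", "hemisphere", "reference"])
              if len(g) >= 2]
    if len(groups) >= 2:
        guarded(anova_oneway, "anova[nucleus_x_hemisphere_x_reference]", groups)
    wide = acc.pivot_table(index="subject", columns="hemisphere",
                           values="boundary_distance")
    if {"left", "right"} <= set(wide.columns) and len(wide.dropna()) >= 3:
        guarded(pearson, "pearson[accuracy_left_vs_right]",
                wide.dropna()["left"], wide.dropna()["right"])

    # GLM: motor outcome vs accuracy and motor-VAT coverage (STN cases, the
    # target with enough outcome data in the emulated cohort)
    if not vat_df.empty:
        stn_ids = [s.id for s in subjects if s.target == "STN"]
        upd = _pct_change(subjects, "UPDRS3")
        mean_bd = acc.groupby("subject")["boundary_distance"].mean()
        motor_cov = vat_df.groupby("subject")["overlap_motor_fraction"].mean()
        ids = [i for i in stn_ids
               if i in upd and i in mean_bd.index and i in motor_cov.index]
        if len(ids) >= 5:
            y = [upd[i] for i in ids]
            X = np.column_stack([mean_bd.loc[ids], motor_cov.loc[ids]])
            try:
                _, coef_results = glm_fit(y, X, names=["accuracy", "motor_vat"])
                results.extend(coef_results)
            except ValueError as exc:
                logger.warning("GLM skipped: %s", exc)

    table = results_table(results)
    table.to_csv(outdir / "stats.csv", index=False)
    return table


def report_stage(config: RunConfig, outdir: Path,
                 failures: FailureReport) -> dict:
    import nibabel
    import scipy

    from . import __version__

    manifest = {
        "seed": config.seed,
        "config": config.to_dict(),
        "completion": failures.to_dict(),
        "completion_pct": failures.completion_pct,
        "versions": {
            "dbsaudit": __version__,
            "numpy": np.__version__,
            "scipy": scipy.__version__,
            "pandas": pd.__version__,
            "nibabel": nibabel.__version__,
        },
        "outputs": sorted(p.name for p in outdir.iterdir()
                          if p.is_file() and p.name != "manifest.json"),
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1) + "\n")
    return manifest


def run_pipeline(config: RunConfig, outdir: str | Path) -> dict:
    """Run every stage and return the run manifest.

    Identical configurations (including the seed) produce byte-identical
    CSV outputs.  Any stage failure aborts with the stage name and subject.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    (outdir / "config.yaml").write_text(yaml.safe_dump(config.to_dict()))

    timings: dict[str, float] = {}

    def timed(stage, fn, *args):
        t0 = time.perf_counter()
        try:
            out = fn(*args)
        except PipelineError:
            raise
        except Exception as exc:  # noqa: BLE001 - stage failure contract
            (outdir / "INVALID").write_text(f"failed during stage {stage}\n")
            raise PipelineError(stage, None, exc) from exc
        timings[stage] = time.perf_counter() - t0
        logger.info("stage %s: %.1f s", stage, timings[stage])
        return out

    cohort = timed("simulate", simulate_stage, config, outdir)
    ids = [s.id for s in cohort.subjects]
    failures = simulate_failures(
        ids, config.registration_failures, config.vat_failures, config.seed
    )
    (outdir / "completion.json").write_text(
        json.dumps(failures.to_dict(), indent=1) + "\n"
    )
    accuracy = timed("metrics", accuracy_stage, cohort, config, outdir,
                     failures.completers)
    timed("volumetry", volumetry_stage, cohort, config, outdir,
          failures.completers, accuracy)
    vat_df = timed("vat", vat_stage, cohort, config, outdir, failures.completers)
    timed("stats", stats_stage, cohort, config, outdir, failures.completers,
          accuracy, vat_df)
    return report_stage(config, outdir, failures)
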