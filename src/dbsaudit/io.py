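"""Standard-format I/O: NIfTI-1 volumes, JSON records, text affines, CSV tables."""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .leads import ElectrodeModel, LeadSpec
from .metrics import validate_affine
from .synthetic import SubjectRecord
from .volumes import LabelVolume


def read_nifti(path: str | Path) -> LabelVolume:
    """Read a 3-D NIfTI-1 file (.nii or .nii.gz) into a :class:`LabelVolume`."""
    img = nib.load(str(path))
    if img.ndim != 3:
        raise ValueError(f"{path}: expected a 3-D volume, got {img.ndim}-D")
    if img.affine is None:
        raise ValueError(f"{path}: image carries no affine")
    data = np.asanyarray(img.dataobj)
    if np.issubdtype(data.dtype, np.floating):
        data = np.round(data).astype(np.int32)
    return LabelVolume(data, np.asarray(img.affine, dtype=float))


def write_nifti(volume: LabelVolume, path: str | Path) -> None:
    """Write a :class:`LabelVolume` as NIfTI-1; write/read round-trips."""
    img = nib.Nifti1Image(np.asarray(volume.data, dtype=np.int16), volume.affine)
    nib.save(img, str(path))


def save_affine_txt(matrix: np.ndarray, path: str | Path) -> None:
    """Write a 4x4 world-space affine as a whitespace text matrix."""
    np.savetxt(str(path), validate_affine(matrix), fmt="%.17g")


def load_affine_txt(path: str | Path) -> np.ndarray:
    return validate_affine(np.loadtxt(str(path)))


# --------------------------------------------------------------------------
# subject records
# --------------------------------------------------------------------------

def _electrode_to_dict(e: ElectrodeModel) -> dict:
    return {
        "tip": e.tip.tolist(),
        "direction": e.direction.tolist(),
        "hemisphere": e.hemisphere,
        "implantation_order": e.implantation_order,
        "spec": {
            "model_name": e.spec.model_name,
            "n_contacts": e.spec.n_contacts,
            "contact_length": e.spec.contact_length,
            "contact_pitch": e.spec.contact_pitch,
            "tip_to_first_contact_centre": e.spec.tip_to_first_contact_centre,
            "directional": e.spec.directional,
        },
    }


def _electrode_from_dict(d: dict) -> ElectrodeModel:
    return ElectrodeModel(
        tip=np.asarray(d["tip"]),
        direction=np.asarray(d["direction"]),
        spec=LeadSpec(**d["spec"]),
        hemisphere=d["hemisphere"],
        implantation_order=d["implantation_order"],
    )


def subject_to_dict(s: SubjectRecord) -> dict:
    return {
        "id": s.id,
        "target": s.target,
        "lead_model": s.lead_model,
        "electrodes": {h: _electrode_to_dict(e) for h, e in s.electrodes.items()},
        "scrf": {h: np.asarray(m).tolist() for h, m in s.scrf.items()},
        "displacement_truth": {h: np.asarray(v).tolist()
                               for h, v in s.displacement_truth.items()},
        "scrf_truth": s.scrf_truth,
        "pneumocephalus_truth_ml": s.pneumocephalus_truth_ml,
        "scores_pre": s.scores_pre,
        "scores_post": s.scores_post,
        "outcome_pct_truth": s.outcome_pct_truth,
        "stimulation": s.stimulation,
    }


def subject_from_dict(d: dict) -> SubjectRecord:
    return SubjectRecord(
        id=d["id"],
        target=d["target"],
        electrodes={h: _electrode_from_dict(e) for h, e in d["electrodes"].items()},
        scrf={h: validate_affine(np.asarray(m)) for h, m in d["scrf"].items()},
        displacement_truth={h: np.asarray(v)
                            for h, v in d["displacement_truth"].items()},
        scrf_truth=d["scrf_truth"],
        pneumocephalus_truth_ml=d["pneumocephalus_truth_ml"],
        scores_pre=d["scores_pre"],
        scores_post=d["scores_post"],
        outcome_pct_truth=d["outcome_pct_truth"],
        stimulation=d["stimulation"],
        lead_model=d["lead_model"],
    )


def save_subjects(subjects, path: str | Path) -> None:
    Path(path).write_text(
        json.dumps([subject_to_dict(s) for s in subjects], indent=1) + "\n"
    )


def load_subjects(path: str | Path) -> list[SubjectRecord]:
    return [subject_from_dict(d) for d in json.loads(Path(path).read_text())]


def scores_table(subjects) -> pd.DataFrame:
    """Tidy cohort score table: one row per subject x score (pre and post)."""
    rows = []
    for s in subjects:
        for score, pre in s.scores_pre.items():
            rows.append({
                "id": s.id, "target": s.target, "score": score,
                "pre": pre, "post": s.scores_post[score],
            })
    return pd.DataFrame(rows)
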