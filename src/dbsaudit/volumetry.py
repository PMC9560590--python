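"""Pneumocephalus volumetry and brain-shift magnitude.

Pneumocephalus (intracranial air after durotomy) is quantified as the
difference between the expected brain volume (a template mask) and the
actually extracted brain volume, in mL.  Brain shift is proxied by the
magnitude of the subcortical-refine (SCRF) affine: the summed elementwise
deviation of the transformation matrix from identity.  The SCRF magnitude is
dimensionally heterogeneous — it mixes unitless rotation/scale terms with
millimetre translations, exactly as a raw matrix sum would — and is used
only as a relative severity index.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .metrics import validate_affine
from .stats import StatResult, pearson
from .volumes import LabelVolume

logger = logging.getLogger(__name__)


@dataclass
class ShiftRecord:
    """Per-subject brain-shift summary used in the correlation analysis."""

    subject: str
    scrf_magnitude: float        # unitless sum, >= 0, 0 iff identity
    pneumocephalus_ml: float     # >= 0
    mean_boundary_distance: float  # mm, mean across hemispheres


def pneumocephalus_volume(
    template_brain: LabelVolume,
    actual_brain: LabelVolume,
    label=1,
) -> float:
    """Air volume in mL: (template voxels - actual voxels) x voxel volume.

    Negative differences (a segmentation larger than the template) clamp to
    zero with a warning; the definition only measures missing brain.
    """
    template_brain.require_same_grid(actual_brain)
    n_template = int(template_brain.mask(label).sum())
    n_actual = int(actual_brain.mask(label).sum())
    diff_mm3 = (n_template - n_actual) * template_brain.voxel_volume
    if diff_mm3 < 0:
        logger.warning(
            "actual brain mask exceeds template by %.1f mm^3; clamping to 0",
            -diff_mm3,
        )
        return 0.0
    return diff_mm3 / 1000.0


def shift_magnitude(scrf: np.ndarray) -> float:
    """SCRF magnitude: sum of |T - I| over the 12 active affine elements.

    The 3x3 linear block plus the translation column (mm); the constant
    homogeneous row is excluded.  Zero exactly at the identity.
    """
    m = validate_affine(scrf)
    dev = m - np.eye(4)
    return float(np.abs(dev[:3, :4]).sum())


def shift_accuracy_correlations(
    records,
    family_m: int = 3,
) -> pd.DataFrame:
    """The three pairwise Pearson correlations among accuracy, shift and air.

    Accuracy is each subject's mean boundary distance across hemispheres.
    Rows with missing values are dropped pairwise with a logged count.
    Bonferroni correction uses ``family_m`` (default 3, one per test).
    """
    if isinstance(records, pd.DataFrame):
        df = records
    else:
        df = pd.DataFrame([vars(r) for r in records])
    pairs = [
        ("accuracy_vs_shift", "mean_boundary_distance", "scrf_magnitude"),
        ("accuracy_vs_pneumocephalus", "mean_boundary_distance", "pneumocephalus_ml"),
        ("shift_vs_pneumocephalus", "scrf_magnitude", "pneumocephalus_ml"),
    ]
    rows = []
    for name, xcol, ycol in pairs:
        sub = df[[xcol, ycol]].dropna()
        dropped = len(df) - len(sub)
        if dropped:
            logger.info("%s: dropped %d incomplete record(s)", name, dropped)
        if len(sub) < 4:
            raise ValueError(f"{name}: need >= 4 complete records, have {len(sub)}")
        res = pearson(sub[xcol], sub[ycol]).corrected(family_m)
        rows.append({
            "analysis": name,
            "r": res.statistic,
            "r2": res.extra["r2"],
            "df": res.df,
            "p": res.p,
            "p_corrected": res.p_corrected,
            "n": res.n,
            "dropped": dropped,
        })
    return pd.DataFrame(rows)
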