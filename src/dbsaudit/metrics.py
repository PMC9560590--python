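"""Electrode accuracy metrics against nucleus targets.

Two complementary definitions are implemented:

* **boundary distance** — the shortest Euclidean distance from any electrode
  contact to the surface of the target region, zero when a contact lies
  inside it.  This is the headline accuracy measure.
* **centroid offset** — the displacement of the electrode from the target's
  centre of gravity, decomposed into lateral (X), anterior (Y) and vertical
  (Z) components; the basis of the target plots and of per-axis variance
  analysis.

Both are evaluated with and without the subcortical-refine (SCRF) affine so
the contribution of brain-shift compensation can be appraised.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
from scipy import ndimage

from .leads import ElectrodeModel, contact_centers
from .volumes import LabelVolume


# --------------------------------------------------------------------------
# affine transforms
# --------------------------------------------------------------------------

def validate_affine(matrix: np.ndarray) -> np.ndarray:
    """Validate a 4x4 homogeneous world-space affine and return it as float."""
    m = np.asarray(matrix, dtype=float)
    if m.shape != (4, 4):
        raise ValueError("affine must be 4x4")
    if not np.allclose(m[3], [0, 0, 0, 1]):
        raise ValueError("affine last row must be (0, 0, 0, 1)")
    if abs(np.linalg.det(m[:3, :3])) < 1e-12:
        raise ValueError("affine is singular")
    return m


def rigid_affine(translation=(0.0, 0.0, 0.0), rotation_deg=(0.0, 0.0, 0.0)) -> np.ndarray:
    """Build a rigid 4x4 affine from a translation (mm) and XYZ Euler angles (deg)."""
    from scipy.spatial.transform import Rotation

    m = np.eye(4)
    m[:3, :3] = Rotation.from_euler("xyz", rotation_deg, degrees=True).as_matrix()
    m[:3, 3] = translation
    return m


def apply_affine_points(matrix: np.ndarray, points: np.ndarray) -> np.ndarray:
    points = np.asarray(points, dtype=float)
    return points @ matrix[:3, :3].T + matrix[:3, 3]


def apply_scrf(electrode: ElectrodeModel, scrf: np.ndarray) -> ElectrodeModel:
    """Map an electrode through a world-space affine (e.g. the SCRF).

    The tip is mapped directly; the direction is re-derived from the mapped
    contact axis and renormalised, so shear or scale in the affine cannot
    leave a non-unit direction behind.
    """
    m = validate_affine(scrf)
    new_tip = apply_affine_points(m, electrode.tip)
    axis_point = apply_affine_points(m, electrode.tip + electrode.direction)
    new_dir = axis_point - new_tip
    new_dir /= np.linalg.norm(new_dir)
    return ElectrodeModel(
        tip=new_tip,
        direction=new_dir,
        spec=electrode.spec,
        hemisphere=electrode.hemisphere,
        implantation_order=electrode.implantation_order,
    )


# --------------------------------------------------------------------------
# distance field
# --------------------------------------------------------------------------

class DistanceField:
    """Euclidean distance-to-region field for one label of a volume.

    The field is the distance transform of the complement mask (distance from
    each outside voxel centre to the nearest labelled voxel centre, in mm),
    sampled with trilinear interpolation at query points.  Points inside the
    region evaluate to 0; with ``signed=True`` they return the negative
    depth to the region surface instead (an opt-in diagnostic).
    """

    def __init__(self, region: LabelVolume, label) -> None:
        mask = region.mask(label)
        if not mask.any():
            raise ValueError(f"region has no voxels with label {label!r}")
        lin = region.affine[:3, :3]
        if not np.allclose(lin.T @ lin, np.diag(region.voxel_sizes ** 2), atol=1e-9):
            raise ValueError("distance fields require an orthogonal affine")
        self.region = region
        self.mask = mask
        sampling = region.voxel_sizes
        self._outer = ndimage.distance_transform_edt(~mask, sampling=sampling)
        self._inner: np.ndarray | None = None
        self._sampling = sampling
        self._tree = None

    def _inner_field(self) -> np.ndarray:
        if self._inner is None:
            self._inner = ndimage.distance_transform_edt(
                self.mask, sampling=self._sampling
            )
        return self._inner

    def inside(self, points_mm: np.ndarray) -> np.ndarray:
        """Whether each world point falls in a labelled voxel (nearest lookup)."""
        ijk = np.round(self.region.world_to_voxel(np.atleast_2d(points_mm))).astype(int)
        ok = np.all((ijk >= 0) & (ijk < self.mask.shape), axis=1)
        res = np.zeros(len(ijk), dtype=bool)
        res[ok] = self.mask[tuple(ijk[ok].T)]
        return res

    def distance(self, points_mm: np.ndarray, signed: bool = False) -> np.ndarray:
        """Distance (mm) from each world point to the region surface.

        0 (or negative depth when ``signed``) for points inside the region.
        """
        pts = np.atleast_2d(np.asarray(points_mm, dtype=float))
        ijk = self.region.world_to_voxel(pts)
        d = ndimage.map_coordinates(self._outer, ijk.T, order=1, mode="nearest")
        # queries off the grid cannot be served by the sampled field; fall
        # back to the exact distance to the nearest surface voxel centre
        off_grid = np.any((ijk < 0) | (ijk > np.array(self.mask.shape) - 1),
                          axis=1)
        if off_grid.any():
            if self._tree is None:
                from scipy.spatial import cKDTree

                surf = self.mask & ~ndimage.binary_erosion(self.mask)
                self._tree = cKDTree(
                    self.region.voxel_to_world(np.argwhere(surf))
                )
            d[off_grid] = self._tree.query(pts[off_grid])[0]
        inside = self.inside(pts)
        if signed:
            depth = ndimage.map_coordinates(
                self._inner_field(), ijk.T, order=1, mode="nearest"
            )
            d = np.where(inside, -depth, d)
        else:
            d = np.where(inside, 0.0, d)
        return d


def boundary_distance(
    electrode: ElectrodeModel,
    region: LabelVolume,
    label,
    signed: bool = False,
    field: DistanceField | None = None,
) -> float:
    """Shortest distance from any electrode contact to the region surface (mm).

    Returns 0 when at least one contact centre lies inside the region; with
    ``signed=True`` an inside contact contributes its negative depth instead.
    A pre-built :class:`DistanceField` can be supplied to amortise the
    distance transform over many electrodes.
    """
    if field is None:
        field = DistanceField(region, label)
    centers = contact_centers(electrode)
    return float(field.distance(centers, signed=signed).min())


def centroid_offset(
    electrode: ElectrodeModel,
    region: LabelVolume,
    label,
) -> tuple[np.ndarray, float]:
    """Offset of the electrode from the region's centre of gravity.

    The reference contact is the contact nearest the centroid, paralleling
    the "any contact" convention of the boundary-distance definition.
    Returns ``(offset, norm)`` where ``offset = contact - centroid`` in world
    mm, decomposed along X (lateral), Y (anterior), Z (superior).
    """
    if not region.mask(label).any():
        raise ValueError(f"region has no voxels with label {label!r}")
    centroid = region.centroid_world(label)
    centers = contact_centers(electrode)
    dists = np.linalg.norm(centers - centroid, axis=1)
    ref = centers[int(np.argmin(dists))]
    offset = ref - centroid
    return offset, float(np.linalg.norm(offset))


# --------------------------------------------------------------------------
# outliers and summaries
# --------------------------------------------------------------------------

def flag_outliers(distances) -> np.ndarray:
    """One-sided Tukey rule: flag values above Q3 + 1.5 x IQR.

    Distances are bounded below by 0, so only the high side is screened.
    Requires at least 4 values for the quartiles to be meaningful.
    """
    x = np.asarray(distances, dtype=float)
    if x.ndim != 1 or x.size < 4:
        raise ValueError("outlier flagging needs at least 4 values")
    q1, q3 = np.percentile(x, [25, 75])
    return x > q3 + 1.5 * (q3 - q1)


@dataclass
class AccuracyResult:
    """Accuracy of one electrode against one reference region."""

    subject: str
    hemisphere: str
    nucleus: str                 # GPi or STN
    reference: str               # main or motor
    boundary_distance: float     # mm, >= 0
    dx: float                    # centroid offset components, mm
    dy: float
    dz: float
    centroid_norm: float
    scrf_applied: bool
    outlier: bool = False


def results_to_frame(results) -> pd.DataFrame:
    """Tidy DataFrame (one row per electrode x reference x SCRF state)."""
    if isinstance(results, pd.DataFrame):
        return results
    return pd.DataFrame([asdict(r) for r in results])


def summarise_accuracy(
    results,
    strata=("nucleus", "reference"),
    value: str = "boundary_distance",
    threshold_mm: float = 2.0,
) -> pd.DataFrame:
    """Stratified accuracy summary.

    One row per stratum with n, mean, SD, mean +/- 2 SD, Tukey outlier count
    and the count (and fraction) of electrodes within ``threshold_mm`` of the
    target.  The 2 mm default mirrors the clinical "within 2 mm of intended
    target" convention.
    """
    df = results_to_frame(results)
    if df.empty:
        raise ValueError("no accuracy results to summarise")
    strata = list(strata)
    unknown = [s for s in strata if s not in df.columns]
    if unknown:
        raise KeyError(f"unknown grouping key(s): {unknown}")

    rows = []
    for key, grp in df.groupby(strata, sort=True):
        vals = grp[value].to_numpy(dtype=float)
        mean = vals.mean()
        sd = vals.std(ddof=1) if len(vals) > 1 else 0.0
        n_out = int(flag_outliers(vals).sum()) if len(vals) >= 4 else 0
        row = dict(zip(strata, key if isinstance(key, tuple) else (key,)))
        row.update(
            n=len(vals),
            mean=mean,
            sd=sd,
            mean_minus_2sd=mean - 2 * sd,
            mean_plus_2sd=mean + 2 * sd,
            outliers=n_out,
            within_threshold=int((vals <= threshold_mm).sum()),
            frac_within_threshold=float((vals <= threshold_mm).mean()),
        )
        rows.append(row)
    return pd.DataFrame(rows)


def target_plot_table(
    results,
    reference: str | None = None,
    with_and_without_scrf: bool = True,
) -> pd.DataFrame:
    """Per-electrode centroid offsets for target plots.

    One row per electrode x reference x SCRF state, grouped by nucleus,
    hemisphere and reference.  The plots show X (lateral) against Y
    (anterior); Z is retained in the table for completeness.  The SCRF state
    column distinguishes brain-shift-corrected ("SCRF") from uncorrected
    ("nSCRF") coordinates.
    """
    df = results_to_frame(results).copy()
    if reference is not None:
        df = df[df["reference"] == reference]
    if not with_and_without_scrf:
        df = df[df["scrf_applied"]]
    df["scrf_state"] = np.where(df["scrf_applied"], "SCRF", "nSCRF")
    cols = ["subject", "nucleus", "hemisphere", "reference", "scrf_state",
            "dx", "dy", "dz", "centroid_norm"]
    return (
        df[cols]
        .sort_values(["nucleus", "hemisphere", "reference", "scrf_state", "subject"])
        .reset_index(drop=True)
    )
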