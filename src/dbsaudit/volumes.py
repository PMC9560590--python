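"""Labelled volumetric grids in world (RAS+, mm) coordinates.

A :class:`LabelVolume` couples a 3-D integer label array with a 4x4
voxel-to-world affine, the representation used throughout the package for
nucleus atlases, brain masks and air cavities.  World coordinates follow the
RAS+ convention: X increases to the subject's right (lateral), Y anterior,
Z superior, all in millimetres.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


class GridMismatchError(ValueError):
    """Two volumes that must share a grid (shape + affine) do not."""


@dataclass
class LabelVolume:
    """3-D integer label grid with a voxel-to-world affine.

    Parameters
    ----------
    data
        Integer label array, shape ``(i, j, k)``.
    affine
        4x4 homogeneous voxel-to-world matrix (mm).
    labels
        Optional mapping from human-readable label names to integer codes.
    """

    data: np.ndarray
    affine: np.ndarray
    labels: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"label grid must be 3-D, got {self.data.ndim}-D")
        self.affine = np.asarray(self.affine, dtype=float)
        if self.affine.shape != (4, 4):
            raise ValueError("affine must be 4x4")
        if not np.allclose(self.affine[3], [0, 0, 0, 1]):
            raise ValueError("affine last row must be (0, 0, 0, 1)")

    # -- geometry -----------------------------------------------------------

    @property
    def voxel_sizes(self) -> np.ndarray:
        """Voxel edge lengths in mm (norms of the affine columns)."""
        return np.linalg.norm(self.affine[:3, :3], axis=0)

    @property
    def voxel_volume(self) -> float:
        """Volume of one voxel in mm^3."""
        return float(abs(np.linalg.det(self.affine[:3, :3])))

    def voxel_to_world(self, ijk: np.ndarray) -> np.ndarray:
        """Map voxel indices (continuous allowed), shape (..., 3), to world mm."""
        ijk = np.asarray(ijk, dtype=float)
        return ijk @ self.affine[:3, :3].T + self.affine[:3, 3]

    def world_to_voxel(self, xyz: np.ndarray) -> np.ndarray:
        """Map world mm coordinates to continuous voxel indices."""
        xyz = np.asarray(xyz, dtype=float)
        inv = np.linalg.inv(self.affine)
        return xyz @ inv[:3, :3].T + inv[:3, 3]

    # -- label access -------------------------------------------------------

    def resolve_label(self, label: int | str) -> int:
        if isinstance(label, str):
            try:
                return self.labels[label]
            except KeyError:
                raise KeyError(
                    f"label {label!r} not defined; known: {sorted(self.labels)}"
                ) from None
        return int(label)

    def mask(self, label: int | str | list | tuple | set) -> np.ndarray:
        """Boolean mask of voxels carrying ``label`` (or any of several)."""
        if isinstance(label, (list, tuple, set, frozenset)):
            codes = [self.resolve_label(l) for l in label]
            return np.isin(self.data, codes)
        return self.data == self.resolve_label(label)

    def label_volume_mm3(self, label) -> float:
        return float(self.mask(label).sum()) * self.voxel_volume

    def centroid_world(self, label) -> np.ndarray:
        """Centre of gravity of the labelled voxels in world mm."""
        m = self.mask(label)
        if not m.any():
            raise ValueError(f"label {label!r} has no voxels")
        ijk = np.argwhere(m)
        return self.voxel_to_world(ijk).mean(axis=0)

    def same_grid(self, other: "LabelVolume", atol: float = 1e-6) -> bool:
        return self.data.shape == other.data.shape and np.allclose(
            self.affine, other.affine, atol=atol
        )

    def require_same_grid(self, other: "LabelVolume") -> None:
        if not self.same_grid(other):
            raise GridMismatchError(
                f"grids differ: shapes {self.data.shape} vs {other.data.shape}, "
                "or affines disagree"
            )

    def copy(self) -> "LabelVolume":
        return LabelVolume(self.data.copy(), self.affine.copy(), dict(self.labels))


def centered_affine(shape, voxel_size) -> np.ndarray:
    """Axis-aligned RAS affine placing the grid centre at world origin."""
    voxel_size = np.broadcast_to(np.asarray(voxel_size, dtype=float), (3,))
    aff = np.eye(4)
    aff[:3, :3] = np.diag(voxel_size)
    aff[:3, 3] = -voxel_size * (np.asarray(shape) - 1) / 2.0
    return aff


def ellipsoid_mask(volume: LabelVolume, center_mm, semi_axes_mm) -> np.ndarray:
    """Boolean mask of voxels whose centres lie in an axis-aligned ellipsoid."""
    center_mm = np.asarray(center_mm, dtype=float)
    semi = np.asarray(semi_axes_mm, dtype=float)
    if np.any(semi <= 0):
        raise ValueError("semi-axes must be positive")
    shape = volume.data.shape
    ii, jj, kk = np.meshgrid(
        np.arange(shape[0]), np.arange(shape[1]), np.arange(shape[2]),
        indexing="ij",
    )
    ijk = np.stack([ii, jj, kk], axis=-1).reshape(-1, 3)
    xyz = volume.voxel_to_world(ijk).reshape(*shape, 3)
    d = (xyz - center_mm) / semi
    return (d ** 2).sum(axis=-1) <= 1.0
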