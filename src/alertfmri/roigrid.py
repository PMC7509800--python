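"""Systematic cubic-grid ROI atlas.

The brain mask is partitioned by a fixed grid of 15-mm cubes (125 voxels of
3 mm per full cube); every in-mask voxel belongs to the cube containing its
center.  Selection of "hotspot" ROIs from a group map is automated by a
|T| threshold, augmented by the mirror rule (a selected lateralized ROI
pulls in its contralateral counterpart), and each selected ROI is allocated
to the task-positive network (CEN) or the deactivating network (DMN) by the
sign of its group-mean percent signal change.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from alertfmri.errors import ConfigurationError, GeometryError

__all__ = [
    "GridRoi",
    "RoiGrid",
    "NetworkSignal",
    "build_roi_grid",
    "roi_mean_psc",
    "select_rois",
    "apply_mirror_rule",
    "assign_networks",
    "network_mean",
    "tumor_overlap_per_roi",
    "tumor_overlap_per_subject",
]

DEFAULT_EDGE_MM = 15.0


@dataclass(frozen=True)
class GridRoi:
    roi_id: int
    corner_mm: tuple[float, float, float]  # minimum corner of the cube
    edge_mm: float
    voxel_indices: np.ndarray  # (n, 3) int voxel coordinates inside the mask
    center_mm: tuple[float, float, float]
    hemisphere: str  # "L" | "R" | "midline"

    @property
    def n_voxels(self) -> int:
        return int(self.voxel_indices.shape[0])


@dataclass
class RoiGrid:
    rois: list[GridRoi]
    origin_mm: tuple[float, float, float]
    edge_mm: float
    voxel_size_mm: float
    affine: np.ndarray
    shape: tuple[int, int, int]
    network_of: dict[int, str] = field(default_factory=dict)

    @property
    def n_rois(self) -> int:
        return len(self.rois)

    def roi(self, roi_id: int) -> GridRoi:
        return self._by_id[roi_id]

    @property
    def _by_id(self) -> dict[int, GridRoi]:
        return {r.roi_id: r for r in self.rois}

    def rois_in_network(self, network: str) -> list[int]:
        return [rid for rid, nw in sorted(self.network_of.items()) if nw == network]

    def label_volume(self) -> np.ndarray:
        """Voxelwise ROI labels (roi_id + 1; 0 = outside all ROIs)."""
        vol = np.zeros(self.shape, dtype=np.int32)
        for r in self.rois:
            ijk = r.voxel_indices
            vol[ijk[:, 0], ijk[:, 1], ijk[:, 2]] = r.roi_id + 1
        return vol

    def to_table(self) -> pd.DataFrame:
        rows = []
        for r in self.rois:
            rows.append(
                {
                    "roi_id": r.roi_id,
                    "center_x_mm": r.center_mm[0],
                    "center_y_mm": r.center_mm[1],
                    "center_z_mm": r.center_mm[2],
                    "hemisphere": r.hemisphere,
                    "n_voxels": r.n_voxels,
                    "network": self.network_of.get(r.roi_id, "none"),
                }
            )
        return pd.DataFrame(rows)


@dataclass(frozen=True)
class NetworkSignal:
    """Per-subject network-averaged percent signal change."""

    subject_id: str
    cen_psc: float
    dmn_psc: float
    per_roi_psc: dict[int, float]


def _check_affine(affine: np.ndarray) -> float:
    """Validate an axis-aligned affine; return the isotropic voxel size."""
    lin = np.asarray(affine, dtype=float)[:3, :3]
    off = lin - np.diag(np.diag(lin))
    if np.any(np.abs(off) > 1e-9):
        raise GeometryError("affine with shear/rotation is unsupported; use an axis-aligned grid")
    sizes = np.diag(lin)
    if np.any(sizes <= 0):
        raise GeometryError("affine must have positive diagonal (no axis flips)")
    if not np.allclose(sizes, sizes[0]):
        raise GeometryError(f"anisotropic voxels are unsupported: {sizes}")
    return float(sizes[0])


def voxel_centers_mm(shape: tuple[int, int, int], affine: np.ndarray) -> np.ndarray:
    """World coordinates of every voxel center, shaped (nx, ny, nz, 3)."""
    ii, jj, kk = np.meshgrid(
        np.arange(shape[0]), np.arange(shape[1]), np.arange(shape[2]), indexing="ij"
    )
    ijk1 = np.stack([ii, jj, kk, np.ones_like(ii)], axis=-1)
    return np.einsum("rc,...c->...r", np.asarray(affine, dtype=float), ijk1)[..., :3]


def build_roi_grid(
    brain_mask: np.ndarray,
    affine: np.ndarray,
    edge_mm: float = DEFAULT_EDGE_MM,
    origin_mm: tuple[float, float, float] = (0.0, 0.0, 0.0),
) -> RoiGrid:
    """Partition a brain mask into cubic grid ROIs.

    Grid planes sit at ``origin + k * edge`` on each world axis; a voxel is
    assigned to the half-open cube ``[corner, corner + edge)`` containing
    its center.  Empty cubes are discarded and ROIs are numbered by
    ascending (z, y, x) cube position.
    """
    mask = np.asarray(brain_mask, dtype=bool)
    if not mask.any():
        raise ConfigurationError("brain mask is empty")
    voxel_size = _check_affine(affine)
    if edge_mm <= 0 or abs(edge_mm / voxel_size - round(edge_mm / voxel_size)) > 1e-9:
        raise ConfigurationError(
            f"edge_mm={edge_mm} must be a positive multiple of voxel size {voxel_size}"
        )

    centers = voxel_centers_mm(mask.shape, affine)
    origin = np.asarray(origin_mm, dtype=float)
    cube_idx = np.floor((centers - origin) / edge_mm).astype(int)

    in_mask = np.argwhere(mask)
    cubes = cube_idx[mask]  # (n_in_mask, 3)
    # deterministic numbering: z, then y, then x ascending
    order_keys = [tuple(c[::-1]) for c in cubes]
    unique_cubes = sorted(set(order_keys))
    cube_rank = {c: i for i, c in enumerate(unique_cubes)}
    labels = np.array([cube_rank[k] for k in order_keys])

    rois: list[GridRoi] = []
    for rid, cube_zyx in enumerate(unique_cubes):
        cube = np.array(cube_zyx[::-1], dtype=float)
        corner = origin + cube * edge_mm
        center = corner + edge_mm / 2.0
        cx = center[0]
        hemisphere = "midline" if abs(cx) < 1e-9 else ("L" if cx < 0 else "R")
        rois.append(
            GridRoi(
                roi_id=rid,
                corner_mm=tuple(corner),
                edge_mm=edge_mm,
                voxel_indices=in_mask[labels == rid],
                center_mm=tuple(center),
                hemisphere=hemisphere,
            )
        )
    return RoiGrid(
        rois=rois,
        origin_mm=tuple(origin),
        edge_mm=edge_mm,
        voxel_size_mm=voxel_size,
        affine=np.asarray(affine, dtype=float),
        shape=mask.shape,
    )


def _roi_mean(volume: np.ndarray, roi: GridRoi) -> float:
    ijk = roi.voxel_indices
    return float(np.mean(volume[ijk[:, 0], ijk[:, 1], ijk[:, 2]]))


def roi_mean_psc(activation_map, grid: RoiGrid, regressor: str) -> dict[int, float]:
    """Unweighted mean PSC over each ROI's voxels, keyed by roi_id."""
    psc = activation_map.psc[regressor]
    if psc.shape != grid.shape:
        raise GeometryError(
            f"map shape {psc.shape} does not match grid shape {grid.shape}"
        )
    out: dict[int, float] = {}
    for roi in grid.rois:
        if roi.n_voxels == 0:
            warnings.warn(f"ROI {roi.roi_id} is empty; excluded from averaging")
            continue
        out[roi.roi_id] = _roi_mean(psc, roi)
    return out


def select_rois(
    group, grid: RoiGrid, t_threshold: float = 4.0, mirror: bool = True
) -> list[int]:
    """Select hotspot ROIs whose ROI-mean group |T| crosses the threshold.

    Automated stand-in for by-eye hotspot picking; with ``mirror`` the
    contralateral counterparts of selected lateralized ROIs are added.
    """
    if t_threshold <= 0:
        raise ConfigurationError(f"t_threshold must be > 0, got {t_threshold}")
    if group.t.shape != grid.shape:
        raise GeometryError("group map and grid shapes differ")
    selected = [
        roi.roi_id
        for roi in grid.rois
        if roi.n_voxels > 0 and abs(_roi_mean(group.t, roi)) >= t_threshold
    ]
    if mirror:
        selected = apply_mirror_rule(selected, grid)
    return selected


def _mirror_plane_check(grid: RoiGrid) -> None:
    # the set of x grid planes must be symmetric under x -> -x, which holds
    # iff the origin is congruent to 0 or edge/2 modulo the edge; the
    # half-offset case puts ROI centers on the midline (x = 0)
    r = grid.origin_mm[0] % grid.edge_mm
    half = grid.edge_mm / 2.0
    if min(abs(r), abs(r - grid.edge_mm), abs(r - half)) > 1e-9:
        raise GeometryError(
            "mirror rule requires an x-symmetric grid; anchor origin_mm[0] at "
            "an integer multiple of edge_mm (or edge_mm/2 for midline ROIs)"
        )


def apply_mirror_rule(selected: list[int], grid: RoiGrid) -> list[int]:
    """Add the contralateral mirror of each selected lateralized ROI.

    Reflection maps an ROI center (x, y, z) to (−x, y, z); the mirror is
    added only when an ROI exists there (the mask itself need not be
    symmetric).  Idempotent, and a no-op for midline ROIs.
    """
    _mirror_plane_check(grid)
    by_center = {
        (round(r.center_mm[0], 6), round(r.center_mm[1], 6), round(r.center_mm[2], 6)): r.roi_id
        for r in grid.rois
    }
    out = list(selected)
    chosen = set(selected)
    for rid in selected:
        roi = grid.roi(rid)
        cx, cy, cz = roi.center_mm
        if abs(cx) < 1e-9:
            continue
        mirror_id = by_center.get((round(-cx, 6), round(cy, 6), round(cz, 6)))
        if mirror_id is not None and mirror_id not in chosen:
            out.append(mirror_id)
            chosen.add(mirror_id)
    return sorted(out)


def assign_networks(selected: list[int], group, grid: RoiGrid) -> dict[int, str]:
    """Allocate selected ROIs to networks by group-mean PSC sign.

    Positive ROI-mean group PSC → CEN (task-positive); negative → DMN
    (deactivating); exactly zero → "none" (flagged with a warning).
    """
    if not selected:
        raise ConfigurationError("cannot assign networks to an empty selection")
    network_of: dict[int, str] = {}
    for rid in selected:
        mean_psc = _roi_mean(group.mean_psc, grid.roi(rid))
        if mean_psc > 0:
            network_of[rid] = "CEN"
        elif mean_psc < 0:
            network_of[rid] = "DMN"
        else:
            warnings.warn(f"ROI {rid} has exactly zero group-mean PSC; network 'none'")
            network_of[rid] = "none"
    return network_of


def network_mean(
    per_roi_psc: dict[int, float],
    network_of: dict[int, str],
    subject_id: str = "",
) -> NetworkSignal:
    """Unweighted mean PSC over the ROIs of each network."""
    values: dict[str, float] = {}
    for nw in ("CEN", "DMN"):
        members = [rid for rid, n in network_of.items() if n == nw]
        if not members:
            warnings.warn(f"network {nw} has no ROIs; mean undefined (NaN)")
            values[nw] = float("nan")
        else:
            values[nw] = float(np.mean([per_roi_psc[rid] for rid in members]))
    return NetworkSignal(
        subject_id=subject_id,
        cen_psc=values["CEN"],
        dmn_psc=values["DMN"],
        per_roi_psc={rid: per_roi_psc[rid] for rid in network_of},
    )


def _overlap_count(mask: np.ndarray, roi: GridRoi) -> int:
    ijk = roi.voxel_indices
    return int(np.count_nonzero(mask[ijk[:, 0], ijk[:, 1], ijk[:, 2]]))


def tumor_overlap_per_roi(masks: list, roi: GridRoi, grid_shape=None) -> float:
    """Cohort-level tumor load of one ROI, in percent.

    ``100 × Σ_subjects |roi ∩ tumor_s| / (n_voxels(roi) × n_subjects)``.
    """
    if not masks:
        raise ConfigurationError("need at least one tumor mask")
    total = 0
    for tm in masks:
        arr = tm.mask if hasattr(tm, "mask") else np.asarray(tm, dtype=bool)
        if grid_shape is not None and arr.shape != tuple(grid_shape):
            raise GeometryError("tumor mask shape does not match grid")
        total += _overlap_count(arr, roi)
    return 100.0 * total / (roi.n_voxels * len(masks))


def tumor_overlap_per_subject(mask, grid: RoiGrid, selected: list[int]) -> float:
    """One subject's tumor load over the selected ROIs, in percent.

    ``100 × Σ_selected |roi ∩ tumor| / Σ_selected n_voxels(roi)``.
    """
    if not selected:
        raise ConfigurationError("overlap undefined for an empty ROI selection")
    arr = mask.mask if hasattr(mask, "mask") else np.asarray(mask, dtype=bool)
    if arr.shape != grid.shape:
        raise GeometryError("tumor mask shape does not match grid")
    overlap = sum(_overlap_count(arr, grid.roi(rid)) for rid in selected)
    denom = sum(grid.roi(rid).n_voxels for rid in selected)
    return 100.0 * overlap / denom
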