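"""ROI lattice construction, hub bookkeeping, and the midsagittal flip.

Coordinate convention: template mm space with negative x in the left
hemisphere.  A voxel index ``(i, j, k)`` on a grid of shape ``dims`` with
isotropic/anisotropic voxel size ``voxel_mm`` maps to

    mm = (index - (dims - 1) / 2) * voxel_mm

so that for an even x-dimension the interhemispheric plane (x = 0 mm) lies
exactly between the two central voxel columns and the midsagittal flip
``i <-> X - 1 - i`` is an exact index reversal with no interpolation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

logger = logging.getLogger(__name__)

HUB_COLUMNS = ["name", "hemisphere", "x", "y", "z", "network", "is_language"]


# ---------------------------------------------------------------------------
# coordinate helpers
# ---------------------------------------------------------------------------

def voxel_to_mm(indices: np.ndarray, dims: Sequence[int], voxel_mm: Sequence[float]) -> np.ndarray:
    """Map voxel indices (N x 3) to template mm coordinates."""
    indices = np.asarray(indices, dtype=float)
    dims = np.asarray(dims, dtype=float)
    voxel_mm = np.asarray(voxel_mm, dtype=float)
    return (indices - (dims - 1) / 2.0) * voxel_mm


def mm_to_voxel(coords: np.ndarray, dims: Sequence[int], voxel_mm: Sequence[float]) -> np.ndarray:
    """Map mm coordinates to the nearest voxel index (N x 3, int)."""
    coords = np.asarray(coords, dtype=float)
    dims = np.asarray(dims, dtype=float)
    voxel_mm = np.asarray(voxel_mm, dtype=float)
    idx = np.rint(coords / voxel_mm + (dims - 1) / 2.0).astype(int)
    return idx


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class RoiAtlas:
    """Labelled ROI field on a template grid.

    ``labels`` holds integer ROI ids (0 = background, ids contiguous from 1).
    ``homologues`` maps ROI id -> id of the mirror-image ROI when the label
    field is exactly mirror symmetric (None otherwise).
    """

    labels: np.ndarray
    voxel_mm: tuple[float, float, float]
    spacing_mm: float | None = None
    z_range_mm: tuple[float, float] | None = None
    homologues: dict[int, int] | None = None

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3:
            raise ValueError("label field must be 3-D")
        vm = np.broadcast_to(np.asarray(self.voxel_mm, dtype=float), (3,))
        self.voxel_mm = tuple(float(v) for v in vm)
        ids = np.unique(self.labels)
        ids = ids[ids > 0]
        if len(ids) and not np.array_equal(ids, np.arange(1, len(ids) + 1)):
            raise ValueError("ROI ids must be contiguous from 1")
        self._n_rois = int(len(ids))

    @property
    def n_rois(self) -> int:
        return self._n_rois

    @property
    def dims(self) -> tuple[int, int, int]:
        return self.labels.shape  # type: ignore[return-value]

    def roi_voxels(self, roi_id: int) -> np.ndarray:
        """Voxel indices (N x 3) belonging to one ROI."""
        return np.argwhere(self.labels == roi_id)

    def centroids_mm(self) -> np.ndarray:
        """Per-ROI centroid in template mm coordinates (n_rois x 3)."""
        cents = np.empty((self.n_rois, 3))
        for r in range(1, self.n_rois + 1):
            vox = self.roi_voxels(r)
            if len(vox) == 0:
                raise ValueError(f"ROI {r} is empty")
            cents[r - 1] = voxel_to_mm(vox, self.dims, self.voxel_mm).mean(axis=0)
        return cents

    def is_symmetric(self) -> bool:
        return self.homologues is not None


@dataclass
class HubSet:
    """The lateralization hubs: named cortical regions with a hemisphere,
    a network assignment (left- or right-lateralized) and a language flag
    (true only for the two core language regions).

    ``roi_id`` is the atlas ROI housing the hub; ``left_roi_id`` is the
    left-hemisphere instance used when evaluating lateralization (the hub's
    own ROI for left hubs, its mirror homologue for right hubs).
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in HUB_COLUMNS if c not in self.table.columns]
        if missing:
            raise ValueError(f"hub table missing columns: {missing}")
        tab = self.table.reset_index(drop=True).copy()
        tab["is_language"] = tab["is_language"].astype(bool)
        bad_hemi = ~tab["hemisphere"].isin(["L", "R"])
        if bad_hemi.any():
            raise ValueError(f"invalid hemisphere for hubs: {list(tab.loc[bad_hemi, 'name'])}")
        # hemisphere must agree with the sign of the x coordinate
        sign_mismatch = ((tab["hemisphere"] == "L") & (tab["x"] > 0)) | (
            (tab["hemisphere"] == "R") & (tab["x"] < 0)
        )
        if sign_mismatch.any():
            raise ValueError(
                "hub hemisphere inconsistent with x sign: "
                f"{list(tab.loc[sign_mismatch, 'name'])}"
            )
        if (tab["is_language"] & (tab["network"] != "left-lateralized")).any():
            raise ValueError("language hubs must belong to the left-lateralized network")
        self.table = tab

    @classmethod
    def from_csv(cls, path) -> "HubSet":
        return cls(pd.read_csv(path))

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)

    @property
    def names(self) -> list[str]:
        return list(self.table["name"])

    def n_in_network(self, network: str) -> int:
        return int((self.table["network"] == network).sum())

    def is_full_config(self) -> bool:
        """True when the set matches the canonical 20-hub configuration:
        9 left-lateralized + 11 right-lateralized hubs, 2 language hubs."""
        return (
            self.n_in_network("left-lateralized") == 9
            and self.n_in_network("right-lateralized") == 11
            and int(self.table["is_language"].sum()) == 2
        )


@dataclass
class TimeCourseMatrix:
    """Per-ROI mean time courses: one row per atlas ROI."""

    values: np.ndarray  # R x T
    roi_ids: np.ndarray
    subject_id: str = ""
    flipped: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.roi_ids = np.asarray(self.roi_ids)
        if self.values.ndim != 2 or self.values.shape[0] != len(self.roi_ids):
            raise ValueError("values must be R x T with one row per ROI")
        if not np.isfinite(self.values).all():
            raise ValueError("time courses contain non-finite entries")


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def flip_midsagittal(obj, *, allow_odd: bool = False):
    """Mirror a volume, 4-D run, BoldRun, or RoiAtlas across the midsagittal
    plane (x axis reversal).

    Requires an even x-dimension (mirror plane exactly between the two
    central columns) unless ``allow_odd`` is set, in which case the central
    column maps onto itself.
    """
    from .preprocess import BoldRun  # local import to avoid a cycle

    if isinstance(obj, BoldRun):
        _check_even(obj.data.shape[0], allow_odd)
        return replace(obj, data=obj.data[::-1].copy(), flipped=not obj.flipped)
    if isinstance(obj, RoiAtlas):
        _check_even(obj.labels.shape[0], allow_odd)
        return RoiAtlas(
            labels=obj.labels[::-1].copy(),
            voxel_mm=obj.voxel_mm,
            spacing_mm=obj.spacing_mm,
            z_range_mm=obj.z_range_mm,
            homologues=obj.homologues,
        )
    arr = np.asarray(obj)
    if arr.ndim not in (3, 4):
        raise ValueError("expected a 3-D volume or 4-D run")
    _check_even(arr.shape[0], allow_odd)
    return arr[::-1].copy()


def _check_even(nx: int, allow_odd: bool) -> None:
    if nx % 2 != 0 and not allow_odd:
        raise ValueError(
            f"x-dimension {nx} is odd; the midsagittal flip is exact only for "
            "even grids (pass allow_odd=True to override)"
        )


def compute_homologues(labels: np.ndarray) -> dict[int, int]:
    """Map each ROI id to its mirror-image ROI id.

    Raises if the label field is not exactly mirror symmetric (some ROI's
    mirrored voxel set is not itself a single ROI).
    """
    labels = np.asarray(labels)
    flipped = labels[::-1]
    ids = np.unique(labels)
    ids = ids[ids > 0]
    mapping: dict[int, int] = {}
    for r in ids:
        partner = np.unique(flipped[labels == r])
        if len(partner) != 1 or partner[0] == 0:
            raise ValueError(f"label field not mirror symmetric at ROI {r}")
        mapping[int(r)] = int(partner[0])
    # involution check
    for a, b in mapping.items():
        if mapping.get(b) != a:
            raise ValueError(f"homologue map is not an involution at ROI {a}")
    return mapping


def build_lattice(
    grey_mask: np.ndarray,
    voxel_mm,
    spacing_mm: float = 5.0,
    z_range_mm: tuple[float, float] = (-35.0, 70.0),
) -> RoiAtlas:
    """Build a lattice ROI atlas covering a grey-matter mask.

    Seed points are placed on a regular grid at ``spacing_mm`` intervals
    (in template mm), kept only where they land on a mask voxel inside the
    closed z range; every in-mask, in-range voxel is then assigned to its
    nearest surviving seed.  Ties are broken by the lowest seed id after
    sorting seeds lexicographically by (x, y, z).  Empty seeds are dropped
    and ids renumbered contiguously.
    """
    grey_mask = np.asarray(grey_mask).astype(bool)
    if grey_mask.ndim != 3:
        raise ValueError("grey mask must be 3-D")
    dims = grey_mask.shape
    vm = np.broadcast_to(np.asarray(voxel_mm, dtype=float), (3,))

    vox = np.argwhere(grey_mask)
    if len(vox) == 0:
        raise ValueError("grey mask is empty")
    mm = voxel_to_mm(vox, dims, vm)
    in_z = (mm[:, 2] >= z_range_mm[0]) & (mm[:, 2] <= z_range_mm[1])
    vox, mm = vox[in_z], mm[in_z]
    if len(vox) == 0:
        raise ValueError("no mask voxels inside the z range")

    # candidate seed grid in mm, covering the mask's bounding box
    lo, hi = mm.min(axis=0), mm.max(axis=0)
    axes = [np.arange(np.floor(lo[d] / spacing_mm) * spacing_mm, hi[d] + spacing_mm / 2, spacing_mm) for d in range(3)]
    seeds_mm = np.array(np.meshgrid(*axes, indexing="ij")).reshape(3, -1).T
    # keep seeds whose nearest voxel is an in-mask, in-range voxel
    seed_idx = mm_to_voxel(seeds_mm, dims, vm)
    inside = np.all((seed_idx >= 0) & (seed_idx < np.array(dims)), axis=1)
    seeds_mm, seed_idx = seeds_mm[inside], seed_idx[inside]
    on_mask = grey_mask[seed_idx[:, 0], seed_idx[:, 1], seed_idx[:, 2]]
    seed_z = voxel_to_mm(seed_idx, dims, vm)[:, 2]
    keep = on_mask & (seed_z >= z_range_mm[0]) & (seed_z <= z_range_mm[1])
    seeds_mm = seeds_mm[keep]
    if len(seeds_mm) == 0:
        raise ValueError("no lattice seed survives the mask/z-range restriction")
    # deterministic ordering for tie-breaks
    order = np.lexsort((seeds_mm[:, 2], seeds_mm[:, 1], seeds_mm[:, 0]))
    seeds_mm = seeds_mm[order]

    tree = cKDTree(seeds_mm)
    _, assign = tree.query(mm, k=1)
    # cKDTree resolves exact ties by index order, which is our sorted order;
    # enforce it explicitly for voxels equidistant to several seeds.
    d_best = np.linalg.norm(mm - seeds_mm[assign], axis=1)
    cand = tree.query_ball_point(mm, d_best + 1e-9)
    assign = np.array([min(c) for c in cand])

    labels = np.zeros(dims, dtype=np.int32)
    used, renum = np.unique(assign, return_inverse=True)
    labels[vox[:, 0], vox[:, 1], vox[:, 2]] = renum + 1
    atlas = RoiAtlas(
        labels=labels,
        voxel_mm=tuple(vm),
        spacing_mm=float(spacing_mm),
        z_range_mm=tuple(z_range_mm),
    )
    try:
        atlas.homologues = compute_homologues(labels)
    except ValueError:
        atlas.homologues = None
    return atlas


def extract_timecourses(bold, atlas: RoiAtlas) -> TimeCourseMatrix:
    """Mean time course per ROI (row r = per-volume mean over ROI r's voxels)."""
    data = np.asarray(bold.data, dtype=float)
    if data.shape[:3] != atlas.labels.shape:
        raise ValueError(
            f"atlas grid {atlas.labels.shape} does not match run grid {data.shape[:3]}"
        )
    flat = data.reshape(-1, data.shape[3])
    lab = atlas.labels.reshape(-1)
    rows = np.empty((atlas.n_rois, data.shape[3]))
    for r in range(1, atlas.n_rois + 1):
        sel = lab == r
        if not sel.any():
            raise ValueError(f"ROI {r} has no voxels on this grid")
        rows[r - 1] = flat[sel].mean(axis=0)
    return TimeCourseMatrix(
        values=rows,
        roi_ids=np.arange(1, atlas.n_rois + 1),
        subject_id=getattr(bold, "subject_id", ""),
        flipped=getattr(bold, "flipped", False),
    )


def assign_hubs(hubs: HubSet, atlas: RoiAtlas) -> HubSet:
    """Attach atlas ROI ids to hubs.

    Each hub is mapped to the lattice ROI whose centroid is nearest
    (Euclidean, mm) to the configured hub coordinate; the distance is
    logged.  ``left_roi_id`` is the left-hemisphere instance of the hub:
    its own ROI for left hubs and the mirror homologue for right hubs
    (requires a symmetric atlas).
    """
    cents = atlas.centroids_mm()
    tab = hubs.table.copy()
    coords = tab[["x", "y", "z"]].to_numpy(dtype=float)
    d = np.linalg.norm(coords[:, None, :] - cents[None, :, :], axis=2)
    roi_ids = d.argmin(axis=1) + 1
    for name, rid, dist in zip(tab["name"], roi_ids, d.min(axis=1)):
        logger.info("hub %s -> ROI %d (%.2f mm)", name, rid, dist)
    tab["roi_id"] = roi_ids
    if atlas.homologues is None:
        raise ValueError("hub assignment requires a mirror-symmetric atlas")
    tab["left_roi_id"] = [
        rid if hemi == "L" else atlas.homologues[int(rid)]
        for rid, hemi in zip(tab["roi_id"], tab["hemisphere"])
    ]
    return HubSet(tab)
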