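"""Synthetic resting-state cohorts with known lateralization structure.

The generator emulates a two-group, multi-site resting-state study on a
small template grid: mirror-symmetric hub ROIs, latent Gaussian hub signals
with configurable Fisher-z couplings, voxel noise, spike-contaminated
realignment traces with group-specific spike rates, independent nuisance
time courses, and a phenotype table whose distributions follow the ranges
of a large public autism sample (two diagnostic groups, site structure,
verbal/performance IQ, quantitative and categorical handedness, ADOS social
and communication totals).

The central property is the *symmetric null*: with no injected effects the
label field and the coupling structure are exactly mirror symmetric, so the
flip-based lateralization index is symmetric about zero on every connection.
A left-lateralization effect is injected by raising the coupling of a named
left-hemisphere hub pair by dz (Fisher z) for one group while the mirrored
right-hemisphere pair keeps the baseline coupling.

Couplings are specified on the observed (ROI-mean) scale: the latent
correlation is inflated by the known voxel-noise attenuation factor so that
the expected ROI-mean coupling equals the requested value.  Requested
couplings implying a non-positive-definite latent covariance are rejected,
never silently repaired.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator

import numpy as np
import pandas as pd

from .atlas import HubSet, RoiAtlas, compute_homologues, mm_to_voxel, voxel_to_mm
from .preprocess import BoldRun, NuisanceSet

LEFT_HUB_NAMES = ["Br", "We", "PC", "MP", "TP", "MT", "LP", "lS", "SF"]
RIGHT_HUB_NAMES = ["AI", "Bh", "DL", "DP", "FE", "IP", "LIP", "MC", "MI", "PO", "rS"]
LANGUAGE_HUBS = ("Br", "We")  # Broca and Wernicke areas


# ---------------------------------------------------------------------------
# specs
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LateralizationEffect:
    """A planted lateralization deficit/excess on one hub-pair connection:
    the named pair's coupling becomes base_edge_z + dz for the group while
    the mirrored pair stays at base_edge_z."""

    hub_a: str
    hub_b: str
    dz_control: float = 0.0
    dz_autism: float = 0.0

    @property
    def label(self) -> str:
        return f"{self.hub_a}--{self.hub_b}"


@dataclass
class CohortSpec:
    """Conditions for one simulated cohort.

    Defaults emulate a short multi-site resting-state acquisition: TR 2 s,
    120 volumes, moderate hub coupling (z = 0.3), unit-variance hub signal
    with voxel noise sd 0.3 on a baseline intensity of 2000 (so spike-free
    DVARS sits far below the 0.2% scrub threshold), and a higher
    per-volume motion-spike probability in the autism group (0.05 vs 0.02),
    mirroring the group motion difference seen in real multi-site data.
    """

    n_control: int = 20
    n_autism: int = 20
    n_sites: int = 3
    grid_dims: tuple[int, int, int] = (24, 24, 16)
    voxel_mm: float = 3.0
    tr_seconds: float = 2.0
    n_volumes: int = 120
    base_edge_z: float = 0.3
    lateralization_effects: list[LateralizationEffect] = field(default_factory=list)
    motion_spike_rate: dict = field(default_factory=lambda: {"control": 0.02, "autism": 0.05})
    noise_sd: float = 0.3
    seed: int = 0
    # generator details
    baseline_intensity: float = 2000.0
    drift_sd_mm: float = 0.01
    drift_sd_rad: float = 2e-4
    spike_mm: tuple[float, float] = (0.4, 1.0)
    spacing_mm: float = 5.0
    hub_table: pd.DataFrame | None = None
    overlap_sites: tuple[str, ...] = ("SITE01",)
    compensate_attenuation: bool = True

    def __post_init__(self) -> None:
        if self.n_control < 0 or self.n_autism < 0:
            raise ValueError("group sizes must be non-negative")
        if self.grid_dims[0] % 2 != 0:
            raise ValueError("grid x-dimension must be even (mirror plane between voxels)")
        for eff in self.lateralization_effects:
            if not (np.isfinite(eff.dz_control) and np.isfinite(eff.dz_autism)):
                raise ValueError(f"non-finite dz on connection {eff.label}")
        for grp, rate in self.motion_spike_rate.items():
            if not 0.0 <= rate <= 1.0:
                raise ValueError(f"motion_spike_rate[{grp}] must be in [0, 1]")
        if self.n_volumes < 2:
            raise ValueError("need at least 2 volumes")

    def hubs_or_default(self) -> pd.DataFrame:
        if self.hub_table is not None:
            return self.hub_table
        return synthetic_hub_table(grid_dims=self.grid_dims, voxel_mm=self.voxel_mm)


@dataclass
class SubjectRecord:
    """One row of the phenotype table."""

    subject_id: str
    site_id: str
    diagnosis: str  # control | autism | asperger | pdd_nos
    age: float
    sex: str  # M | F
    handedness_cat: str | None
    handedness_quant: float | None
    verbal_iq: float | None
    performance_iq: float | None
    ados_social: float | None
    ados_communication: float | None

    def __post_init__(self) -> None:
        if self.diagnosis not in ("control", "autism", "asperger", "pdd_nos"):
            raise ValueError(f"unknown diagnosis '{self.diagnosis}'")
        if self.handedness_quant is not None and not np.isnan(self.handedness_quant):
            if not -100 <= self.handedness_quant <= 100:
                raise ValueError("quantitative handedness must lie in [-100, 100]")
        for name in ("verbal_iq", "performance_iq", "ados_social", "ados_communication"):
            v = getattr(self, name)
            if v is not None and not np.isnan(v) and v < 0:
                raise ValueError(f"{name} must be non-negative")

    @property
    def dx_group(self) -> str:
        """Diagnostic group: 'control' or 'autism' (spectrum)."""
        return "control" if self.diagnosis == "control" else "autism"

    @classmethod
    def from_row(cls, row) -> "SubjectRecord":
        return cls(**{k: row[k] for k in (
            "subject_id", "site_id", "diagnosis", "age", "sex", "handedness_cat",
            "handedness_quant", "verbal_iq", "performance_iq",
            "ados_social", "ados_communication")})


# ---------------------------------------------------------------------------
# hub fixtures and symmetric atlas
# ---------------------------------------------------------------------------

def synthetic_hub_table(
    n_left: int = 9,
    n_right: int = 11,
    grid_dims: tuple[int, int, int] = (24, 24, 16),
    voxel_mm: float = 3.0,
) -> pd.DataFrame:
    """A synthetic hub table on a small test grid.

    Hub coordinates are placed deterministically on the grid (left hubs on
    even y rows, right hubs on odd y rows, so no hub ever collides with the
    mirror image of another).  With the default 9 + 11 configuration the
    names follow the standard hub abbreviations, with Broca (Br) and
    Wernicke (We) flagged as the two language hubs.  These coordinates are
    synthetic test fixtures, not template-space hub locations.
    """
    X, Y, Z = grid_dims
    if X % 2 != 0:
        raise ValueError("grid x-dimension must be even")

    def slots(i_range, j_parity):
        out = []
        for k in range(1, Z - 1):
            for j in range(1, Y - 1):
                if j % 2 != j_parity:
                    continue
                for i in i_range:
                    out.append((i, j, k))
        return out

    left_slots = slots(range(1, X // 2), 0)
    right_slots = slots(range(X // 2 + 1, X - 1), 1)
    if n_left > len(left_slots) or n_right > len(right_slots):
        raise ValueError("grid too small for the requested hub count")

    def spread(cands, n):
        idx = np.unique(np.linspace(0, len(cands) - 1, n).round().astype(int))
        step = 0
        while len(idx) < n:  # pathological tiny grids
            step += 1
            idx = np.unique(np.concatenate([idx, [min(len(cands) - 1, idx[-1] + step)]]))
        return [cands[i] for i in idx[:n]]

    left = spread(left_slots, n_left)
    right = spread(right_slots, n_right)

    if n_left == 9 and n_right == 11:
        left_names, right_names = LEFT_HUB_NAMES, RIGHT_HUB_NAMES
    else:
        left_names = [f"L{i + 1}" for i in range(n_left)]
        right_names = [f"R{i + 1}" for i in range(n_right)]
    language = set(left_names[: min(2, n_left)]) if n_left != 9 else set(LANGUAGE_HUBS)

    rows = []
    vm = (voxel_mm,) * 3
    for names, vox_list, hemi, network in [
        (left_names, left, "L", "left-lateralized"),
        (right_names, right, "R", "right-lateralized"),
    ]:
        if not vox_list:
            continue
        mm = voxel_to_mm(np.array(vox_list), grid_dims, vm)
        for name, (x, y, z) in zip(names, mm):
            rows.append(dict(name=name, hemisphere=hemi, x=x, y=y, z=z,
                             network=network, is_language=name in language))
    return pd.DataFrame(rows)


def packaged_hub_fixture() -> pd.DataFrame:
    """The synthetic 20-hub fixture shipped with the package (coordinates on
    the default 24 x 24 x 16 test grid; not template-space locations).  An
    empty template documenting the expected columns ships alongside it as
    ``data/hub_template.csv``."""
    from importlib.resources import files

    with (files("hemiflip") / "data" / "synthetic_hubs_20.csv").open() as fh:
        return pd.read_csv(fh)


def make_symmetric_atlas(
    grid_dims: tuple[int, int, int],
    voxel_mm: float,
    spacing_mm: float,
    hub_spec: pd.DataFrame,
) -> tuple[RoiAtlas, HubSet]:
    """Build an exactly mirror-symmetric hub atlas: one ROI per hub (all
    voxels within spacing_mm/2 of the hub coordinate, Chebyshev in mm, at
    least the nearest voxel) plus the mirror-image ROI of every hub.

    Returns the atlas and the hub set with ROI ids attached.  Rejects hubs
    outside the grid (naming them) and overlapping ROIs.
    """
    X, Y, Z = grid_dims
    if X % 2 != 0:
        raise ValueError("grid x-dimension must be even (mirror plane between voxels)")
    vm = (float(voxel_mm),) * 3
    hubs = hub_spec.reset_index(drop=True)

    def roi_voxels(coord):
        rngs = []
        for d, (c, v, n) in enumerate(zip(coord, vm, grid_dims)):
            centers = (np.arange(n) - (n - 1) / 2.0) * v
            sel = np.flatnonzero(np.abs(centers - c) <= spacing_mm / 2.0 + 1e-9)
            if len(sel) == 0:
                sel = np.array([int(np.clip(np.argmin(np.abs(centers - c)), 0, n - 1))])
            rngs.append(sel)
        return np.array(np.meshgrid(*rngs, indexing="ij")).reshape(3, -1).T

    labels = np.zeros(grid_dims, dtype=np.int32)
    owner: dict[tuple, str] = {}
    hub_sets: list[frozenset] = []
    for _, row in hubs.iterrows():
        coord = np.array([row["x"], row["y"], row["z"]], dtype=float)
        nearest = mm_to_voxel(coord[None, :], grid_dims, vm)[0]
        if np.any(nearest < 0) or np.any(nearest >= np.array(grid_dims)):
            raise ValueError(f"hub '{row['name']}' at {tuple(coord)} lies outside the grid")
        vox = roi_voxels(coord)
        vset = frozenset(map(tuple, vox))
        for v in vset:
            if v in owner:
                raise ValueError(f"hub '{row['name']}' overlaps ROI of '{owner[v]}'")
            owner[v] = row["name"]
        hub_sets.append(vset)

    n_hubs = len(hubs)
    for rid, vset in enumerate(hub_sets, start=1):
        for i, j, k in vset:
            labels[i, j, k] = rid

    # mirror ROIs: the homologue of every hub ROI
    next_id = n_hubs + 1
    for rid, vset in enumerate(hub_sets, start=1):
        mirrored = frozenset((X - 1 - i, j, k) for i, j, k in vset)
        if mirrored in hub_sets:
            continue  # a hub placed exactly at another hub's mirror
        clash = [owner[v] for v in mirrored if v in owner]
        if clash:
            raise ValueError(
                f"mirror ROI of hub '{hubs.loc[rid - 1, 'name']}' overlaps {set(clash)}"
            )
        for i, j, k in mirrored:
            labels[i, j, k] = next_id
            owner[(i, j, k)] = f"~{hubs.loc[rid - 1, 'name']}"
        next_id += 1

    atlas = RoiAtlas(labels=labels, voxel_mm=vm, spacing_mm=float(spacing_mm),
                     homologues=None)
    atlas.homologues = compute_homologues(labels)

    tab = hubs.copy()
    tab["roi_id"] = np.arange(1, n_hubs + 1)
    tab["left_roi_id"] = [
        rid if hemi == "L" else atlas.homologues[rid]
        for rid, hemi in zip(tab["roi_id"], tab["hemisphere"])
    ]
    return atlas, HubSet(tab)


# ---------------------------------------------------------------------------
# latent coupling structure
# ---------------------------------------------------------------------------

def latent_correlation(
    spec: CohortSpec, atlas: RoiAtlas, hubs: HubSet, group: str
) -> np.ndarray:
    """Latent ROI-signal correlation matrix for one diagnostic group.

    Within-network hub pairs (and their mirror pairs) couple at
    tanh(base_edge_z); connections named in ``lateralization_effects`` get
    tanh(base_edge_z + dz) at the hubs' own-hemisphere pair while the
    mirrored pair keeps the baseline.  With attenuation compensation the
    latent correlations are inflated so the *observed* ROI-mean couplings
    land on the requested Fisher-z values.
    """
    k = atlas.n_rois
    if atlas.homologues is None:
        raise ValueError("latent model requires a mirror-symmetric atlas")
    tab = hubs.table
    roi_of = dict(zip(tab["name"], tab["roi_id"].astype(int)))
    hom = atlas.homologues

    r = np.eye(k)
    base = float(np.tanh(spec.base_edge_z))

    def set_pair(a: int, b: int, val: float) -> None:
        r[a - 1, b - 1] = r[b - 1, a - 1] = val

    for network in ("left-lateralized", "right-lateralized"):
        ids = [int(i) for i in tab.loc[tab["network"] == network, "roi_id"]]
        for i, a in enumerate(ids):
            for b in ids[i + 1:]:
                set_pair(a, b, base)
                set_pair(hom[a], hom[b], base)

    for eff in spec.lateralization_effects:
        for name in (eff.hub_a, eff.hub_b):
            if name not in roi_of:
                raise ValueError(f"effect names unknown hub '{name}'")
        dz = eff.dz_control if group == "control" else eff.dz_autism
        a, b = roi_of[eff.hub_a], roi_of[eff.hub_b]
        set_pair(a, b, float(np.tanh(spec.base_edge_z + dz)))
        set_pair(hom[a], hom[b], base)  # mirrored pair keeps the baseline

    if spec.compensate_attenuation and spec.noise_sd > 0:
        sizes = np.array([np.count_nonzero(atlas.labels == i) for i in range(1, k + 1)])
        f = np.sqrt(1.0 + spec.noise_sd**2 / sizes)
        off = ~np.eye(k, dtype=bool)
        r[off] = (r * np.outer(f, f))[off]

    too_big = np.abs(r[~np.eye(k, dtype=bool)]) >= 1.0
    if too_big.any():
        raise ValueError(
            "requested couplings leave no room for voxel noise (|latent r| >= 1); "
            f"offending effects: {[e.label for e in spec.lateralization_effects]}"
        )
    return r


def _cholesky_or_reject(r: np.ndarray, spec: CohortSpec) -> np.ndarray:
    try:
        return np.linalg.cholesky(r)
    except np.linalg.LinAlgError:
        raise ValueError(
            "requested couplings imply a non-positive-definite latent "
            "covariance; offending effect connections: "
            f"{[e.label for e in spec.lateralization_effects]}"
        ) from None


# ---------------------------------------------------------------------------
# per-subject simulation
# ---------------------------------------------------------------------------

def simulate_subject(
    spec: CohortSpec,
    subject: SubjectRecord,
    atlas: RoiAtlas,
    hubs: HubSet,
    rng: np.random.Generator | int,
) -> tuple[BoldRun, NuisanceSet]:
    """Simulate one subject's BOLD run and nuisance traces.

    ROI voxel series = latent ROI signal + independent Gaussian noise on a
    constant baseline; background voxels carry baseline + noise only.
    Realignment parameters are smooth random-walk drifts plus single-volume
    displacement spikes at the group's per-volume spike probability.
    Nuisance traces (CSF/WM/soft-tissue stand-ins) are AR(1) series drawn
    independently of the hub signals.
    """
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(int(rng))
    t = spec.n_volumes
    k = atlas.n_rois

    r = latent_correlation(spec, atlas, hubs, subject.dx_group)
    chol = _cholesky_or_reject(r, spec)
    latent = rng.standard_normal((t, k)) @ chol.T  # rows have covariance r

    data = rng.standard_normal(atlas.labels.shape + (t,), dtype=np.float32)
    if spec.noise_sd != 1.0:
        data *= np.float32(spec.noise_sd)
    data += np.float32(spec.baseline_intensity)
    flat = data.reshape(-1, t)
    lab = atlas.labels.reshape(-1)
    for roi in range(1, k + 1):
        flat[lab == roi] += latent[:, roi - 1].astype(np.float32)

    # realignment parameters: drift + spikes
    drift_sd = np.array([spec.drift_sd_mm] * 3 + [spec.drift_sd_rad] * 3)
    motion = np.cumsum(rng.normal(0.0, drift_sd, size=(t, 6)), axis=0)
    rate = spec.motion_spike_rate.get(subject.dx_group, 0.0)
    spikes = np.flatnonzero(rng.random(t - 1) < rate) + 1
    for s in spikes:
        axis = int(rng.integers(0, 3))
        mag = rng.uniform(*spec.spike_mm) * (1 if rng.random() < 0.5 else -1)
        motion[s, axis] += mag  # single-volume excursion

    def ar1(phi=0.9, sd=1.0):
        e = rng.normal(0.0, sd * np.sqrt(1 - phi**2), size=t)
        out = np.empty(t)
        out[0] = rng.normal(0.0, sd)
        for i in range(1, t):
            out[i] = phi * out[i - 1] + e[i]
        return out

    nuisance = NuisanceSet(csf=ar1(), wm=ar1(), soft_tissue=ar1(), motion=motion)
    bold = BoldRun(
        data=data, tr_seconds=spec.tr_seconds, voxel_mm=(spec.voxel_mm,) * 3,
        motion_params=motion, subject_id=subject.subject_id, site_id=subject.site_id,
    )
    return bold, nuisance


# ---------------------------------------------------------------------------
# phenotypes and cohorts
# ---------------------------------------------------------------------------

def simulate_phenotypes(spec: CohortSpec, rng: np.random.Generator) -> pd.DataFrame:
    """Phenotype table with one row per subject.

    Values are drawn uniformly within the printed ranges of the emulated
    sample: age 6.5-56 y (controls) / 7-64 y (autism group); verbal IQ
    67-147 / 50-149; performance IQ 67-155 / 59-157; ADOS social +
    communication totals 0-4 (controls, mostly missing) / 2-22; quantitative
    handedness on [-100, 100] with a right-handed majority; ~1.5% of
    subjects lack any handedness measure.  Sites are assigned uniformly.
    """
    rows = []
    n_total = spec.n_control + spec.n_autism
    width = max(3, len(str(n_total)))
    for i in range(n_total):
        is_control = i < spec.n_control
        grp = "control" if is_control else "autism"
        if is_control:
            diagnosis = "control"
        else:
            diagnosis = rng.choice(["autism", "asperger", "pdd_nos"], p=[0.62, 0.23, 0.15])
        age = rng.uniform(6.47, 56.2) if is_control else rng.uniform(7.0, 64.0)
        sex = "M" if rng.random() < (0.82 if is_control else 0.886) else "F"
        # handedness: right-handed majority, occasional zero, rare missing
        u = rng.random()
        if u < 0.015:
            hq = np.nan
        elif u < 0.03:
            hq = 0.0
        elif u < 0.12:
            hq = rng.uniform(-100.0, -5.0)
        else:
            hq = rng.uniform(5.0, 100.0)
        if np.isnan(hq):
            hc = None
        elif rng.random() < 0.5:
            hc = "R" if hq > 0 else ("L" if hq < 0 else "A")
        else:
            hc = None  # categorical missing: recoded from the quantitative value
        viq = rng.uniform(67, 147) if is_control else rng.uniform(50, 149)
        piq = rng.uniform(67, 155) if is_control else rng.uniform(59, 157)
        if is_control:
            has_ados = rng.random() < 0.07
            soc = float(rng.integers(0, 3)) if has_ados else np.nan
            com = float(rng.integers(0, 3)) if has_ados else np.nan
        else:
            soc = float(rng.integers(1, 15))
            com = float(rng.integers(1, 9))
        rows.append(dict(
            subject_id=f"sub{str(i + 1).zfill(width)}",
            site_id=f"SITE{rng.integers(1, spec.n_sites + 1):02d}",
            diagnosis=diagnosis, dx_group=grp, age=age, sex=sex,
            handedness_cat=hc, handedness_quant=hq,
            verbal_iq=viq, performance_iq=piq,
            ados_social=soc, ados_communication=com,
        ))
    return pd.DataFrame(rows)


@dataclass
class Cohort:
    """A fully materialized synthetic cohort."""

    spec: CohortSpec
    atlas: RoiAtlas
    hubs: HubSet
    phenotypes: pd.DataFrame
    runs: list  # list[(BoldRun, NuisanceSet)] aligned with phenotype rows


def cohort_stream(spec: CohortSpec):
    """Streaming cohort: returns (atlas, hubs, phenotypes, subject iterator).

    The iterator yields (SubjectRecord, BoldRun, NuisanceSet) one subject at
    a time so large cohorts never live in memory at once.  Deterministic:
    the same spec and seed reproduce the cohort bit for bit.
    """
    spec.__post_init__()  # re-validate (dataclass fields may have been mutated)
    atlas, hubs = make_symmetric_atlas(
        spec.grid_dims, spec.voxel_mm, spec.spacing_mm, spec.hubs_or_default()
    )
    seeds = np.random.SeedSequence(spec.seed).spawn(spec.n_control + spec.n_autism + 1)
    phenotypes = simulate_phenotypes(spec, np.random.default_rng(seeds[0]))

    def gen() -> Iterator[tuple[SubjectRecord, BoldRun, NuisanceSet]]:
        for i, (_, row) in enumerate(phenotypes.iterrows()):
            record = SubjectRecord.from_row(row)
            bold, nuis = simulate_subject(
                spec, record, atlas, hubs, np.random.default_rng(seeds[i + 1])
            )
            yield record, bold, nuis

    return atlas, hubs, phenotypes, gen()


def simulate_cohort(spec: CohortSpec) -> Cohort:
    """Materialize a full cohort (atlas, hubs, phenotypes, all runs)."""
    atlas, hubs, phenotypes, stream = cohort_stream(spec)
    runs = [(bold, nuis) for _, bold, nuis in stream]
    return Cohort(spec=spec, atlas=atlas, hubs=hubs, phenotypes=phenotypes, runs=runs)
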