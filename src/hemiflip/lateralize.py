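"""Flip-based functional lateralization.

Connectivity is the Fisher z-transformed Pearson correlation between ROI
mean time courses.  For each within-hemisphere hub pair ("connection") the
lateralization index (LI) is the difference

    li = z_unflipped - z_flipped

evaluated at the connection's *left-hemisphere* ROI instances (the hubs'
own ROIs for left-network connections, their mirror homologues for
right-network connections).  In this frame a positive li always means
"more left-lateralized": left-network connections are left-lateralized at
li > 0, and right-network connections are right-lateralized at li < 0, so
the degree of lateralization toward the right network's own hemisphere is
-li.  Mixed (left x right) pairs are evaluated in the same left-hemisphere
frame, i.e. with the right hub mapped to its mirrored coordinate; they are
produced for pattern maps only and excluded from group statistics.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd

from .atlas import HubSet, TimeCourseMatrix

R_CLIP = 1.0 - 1e-12  # correlations clipped away from +/-1 before atanh

LEFT_LANGUAGE = "left-language"
LEFT_NONLANGUAGE = "left-nonlanguage"
RIGHT = "right"
MIXED = "mixed"


@dataclass
class ConnectivityMatrix:
    """R x R symmetric matrix of Fisher-transformed Pearson correlations
    (diagonal undefined, stored as NaN)."""

    z: np.ndarray
    roi_ids: np.ndarray
    subject_id: str = ""
    flipped: bool = False

    def __post_init__(self) -> None:
        self.z = np.asarray(self.z, dtype=float)
        if self.z.ndim != 2 or self.z.shape[0] != self.z.shape[1]:
            raise ValueError("connectivity must be a square matrix")
        if not np.allclose(self.z, self.z.T, equal_nan=True):
            raise ValueError("connectivity matrix must be symmetric")

    def at(self, roi_a: int, roi_b: int) -> float:
        ia = int(np.flatnonzero(self.roi_ids == roi_a)[0])
        ib = int(np.flatnonzero(self.roi_ids == roi_b)[0])
        return float(self.z[ia, ib])


@dataclass(frozen=True)
class Connection:
    """An unordered hub pair with its laterality class and statistical group.

    ``left_roi_a``/``left_roi_b`` are the left-hemisphere ROI instances at
    which the LI is evaluated.
    """

    hub_a: str
    hub_b: str
    laterality_class: str  # left-lateralized | right-lateralized | mixed
    group: str  # left-language | left-nonlanguage | right | mixed
    left_roi_a: int
    left_roi_b: int

    def __post_init__(self) -> None:
        if self.hub_a == self.hub_b:
            raise ValueError("a connection needs two distinct hubs")

    @property
    def label(self) -> str:
        return f"{self.hub_a}--{self.hub_b}"


def fisher_connectivity(tc: TimeCourseMatrix) -> ConnectivityMatrix:
    """Fisher z connectivity: z[a, b] = atanh(r[a, b]) with r clipped to
    |r| <= 1 - 1e-12.

    ROIs with zero temporal variance get NaN rows/columns (their
    correlations are undefined) and are reported in a warning.
    """
    values = tc.values
    if values.shape[1] < 3:
        raise ValueError("need at least 3 time points for a correlation")
    sd = values.std(axis=1)
    degenerate = np.flatnonzero(sd == 0)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.corrcoef(values)
    if len(degenerate):
        warnings.warn(
            f"{len(degenerate)} ROI(s) with zero variance; their connectivity "
            f"is undefined: rois {list(tc.roi_ids[degenerate])}",
            RuntimeWarning,
            stacklevel=2,
        )
        r[degenerate, :] = np.nan
        r[:, degenerate] = np.nan
    z = np.arctanh(np.clip(r, -R_CLIP, R_CLIP))
    np.fill_diagonal(z, np.nan)
    return ConnectivityMatrix(z=z, roi_ids=np.asarray(tc.roi_ids),
                              subject_id=tc.subject_id, flipped=tc.flipped)


def enumerate_connections(hubs: HubSet, include_mixed: bool = False) -> list[Connection]:
    """All unordered within-network ipsilateral hub pairs.

    With the full 20-hub configuration this yields 36 left-lateralized
    connections (15 involving a language hub, 21 not) and 55
    right-lateralized connections.  With ``include_mixed``, all left x right
    pairs are added, evaluated after mapping the right hub to its mirrored
    left-hemisphere position (pattern maps only, never group testing).
    """
    tab = hubs.table
    if "left_roi_id" not in tab.columns:
        raise ValueError("hubs have no ROI assignment; run assign_hubs first")
    rows = {r["name"]: r for _, r in tab.iterrows()}
    conns: list[Connection] = []
    for network, cls in [("left-lateralized", "left-lateralized"),
                         ("right-lateralized", "right-lateralized")]:
        names = list(tab.loc[tab["network"] == network, "name"])
        for a, b in combinations(names, 2):
            if cls == "left-lateralized":
                group = LEFT_LANGUAGE if (rows[a]["is_language"] or rows[b]["is_language"]) else LEFT_NONLANGUAGE
            else:
                group = RIGHT
            conns.append(Connection(a, b, cls, group,
                                    int(rows[a]["left_roi_id"]), int(rows[b]["left_roi_id"])))
    if include_mixed:
        left = list(tab.loc[tab["network"] == "left-lateralized", "name"])
        right = list(tab.loc[tab["network"] == "right-lateralized", "name"])
        for a in left:
            for b in right:
                conns.append(Connection(a, b, MIXED, MIXED,
                                        int(rows[a]["left_roi_id"]), int(rows[b]["left_roi_id"])))
    return conns


def lateralization_index(
    z_unflipped: ConnectivityMatrix,
    z_flipped: ConnectivityMatrix,
    connections: list[Connection],
) -> pd.DataFrame:
    """Per-connection LI for one subject: z_unflipped - z_flipped at the
    connection's left-hemisphere ROI pair.

    Undefined entries (zero-variance ROIs) propagate as NaN and are counted
    by downstream QC.  Returns a tidy frame with one row per connection.
    """
    if z_unflipped.subject_id != z_flipped.subject_id:
        raise ValueError("unflipped and flipped matrices come from different subjects")
    if z_unflipped.flipped or not z_flipped.flipped:
        raise ValueError("pass (unflipped, flipped) matrices in that order")
    rows = []
    for c in connections:
        li = z_unflipped.at(c.left_roi_a, c.left_roi_b) - z_flipped.at(c.left_roi_a, c.left_roi_b)
        rows.append(
            dict(subject_id=z_unflipped.subject_id, hub_a=c.hub_a, hub_b=c.hub_b,
                 connection=c.label, laterality_class=c.laterality_class,
                 group=c.group, li=li)
        )
    return pd.DataFrame(rows)


def connection_group_means(table: pd.DataFrame) -> pd.DataFrame:
    """Per-subject mean LI over the three connection groups
    (left-language, left-nonlanguage, right).

    Missing li values are excluded from the means; the number of missing
    connections per subject is reported in ``n_missing``.  A group with no
    defined li for a subject yields NaN.  Mixed connections are ignored.
    """
    tab = table[table["group"].isin([LEFT_LANGUAGE, LEFT_NONLANGUAGE, RIGHT])]
    out = (
        tab.pivot_table(index="subject_id", columns="group", values="li",
                        aggfunc="mean", dropna=True)
        .reindex(columns=[LEFT_LANGUAGE, LEFT_NONLANGUAGE, RIGHT])
    )
    out.columns = ["left_language", "left_nonlanguage", "right"]
    n_missing = tab.assign(miss=tab["li"].isna()).groupby("subject_id")["miss"].sum()
    out["n_missing"] = n_missing.reindex(out.index).astype(int)
    return out.reset_index()
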