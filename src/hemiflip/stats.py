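"""Group statistics for the lateralization analysis.

Per-connection one-sample and two-sample t-tests with Benjamini-Hochberg
FDR control at q < 0.05 over the family of ipsilateral hub connections,
paired contrasts between the three connection groups (left-language,
left-nonlanguage, right), subject inclusion-criteria presets, and
brain-behaviour correlations (Pearson for symptom severity, Spearman for
age and quantitative handedness).

Severity is the sum of the ADOS social and communication domain totals.
The two-sample test defaults to the pooled-variance (Student) form with
df = n1 + n2 - 2 (minus per-connection missingness); Welch is available as
an option.  Reported P values are uncorrected two-sided; FDR significance
is a separate flag.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .lateralize import LEFT_LANGUAGE, LEFT_NONLANGUAGE, RIGHT


# ---------------------------------------------------------------------------
# inclusion criteria
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class InclusionCriteria:
    """A named set of subject-inclusion restrictions.

    The base restriction (all presets) keeps only subjects from sites where
    at least ``min_site_n`` subjects pass the upstream processing checks.
    The stricter toggles mirror the usual secondary-analysis criteria of
    multi-site resting-state studies: minimum post-scrub volume retention,
    exclusion of sites whose control subjects may overlap earlier public
    samples, right-handed-only, male-only, strict-autism-diagnosis-only,
    and group-specific verbal-IQ windows.
    """

    name: str = "A"
    min_retention: float | None = None  # e.g. 0.5 for >= 50% volumes kept
    exclude_sites: tuple[str, ...] = ()
    right_handed_only: bool = False
    male_only: bool = False
    autism_dx_only: bool = False
    verbal_iq_window: dict | None = None  # {"autism": (80, 130), "control": (70, 120)}
    min_site_n: int = 20


VERBAL_IQ_WINDOW = {"autism": (80.0, 130.0), "control": (70.0, 120.0)}


def criteria_preset(
    letter: str,
    overlap_sites: tuple[str, ...] = (),
    min_site_n: int = 20,
) -> InclusionCriteria:
    """Named presets A-H.

    A: base criteria only.  B: post-scrub retention >= 50%.  C: exclusion
    of possible-overlap sites (caller supplies the site list).  D: B and C
    together.  E: right-handed subjects only.  F: males only.  G: strict
    autism diagnosis only (Asperger and PDD-NOS excluded).  H: verbal IQ
    80-130 (autism) / 70-120 (controls).
    """
    letter = letter.upper()
    kw: dict = dict(name=letter, min_site_n=min_site_n)
    if letter == "A":
        pass
    elif letter == "B":
        kw["min_retention"] = 0.5
    elif letter == "C":
        kw["exclude_sites"] = tuple(overlap_sites)
    elif letter == "D":
        kw["min_retention"] = 0.5
        kw["exclude_sites"] = tuple(overlap_sites)
    elif letter == "E":
        kw["right_handed_only"] = True
    elif letter == "F":
        kw["male_only"] = True
    elif letter == "G":
        kw["autism_dx_only"] = True
    elif letter == "H":
        kw["verbal_iq_window"] = dict(VERBAL_IQ_WINDOW)
    else:
        raise ValueError(f"unknown criteria preset '{letter}' (expected A-H)")
    return InclusionCriteria(**kw)


def recode_handedness(phenotypes: pd.DataFrame) -> pd.Series:
    """Categorical handedness with the quantitative recoding applied first:
    when the categorical measure is missing, positive quantitative values
    become right-handed, negative left-handed, and zero ambidextrous.
    Subjects missing both stay missing."""
    cat = phenotypes["handedness_cat"].copy()
    quant = phenotypes["handedness_quant"]
    missing_cat = cat.isna()
    has_quant = quant.notna()
    fill = pd.Series(
        np.select([quant > 0, quant < 0, quant == 0], ["R", "L", "A"], default=None),
        index=phenotypes.index, dtype=object,
    )
    cat.loc[missing_cat & has_quant] = fill.loc[missing_cat & has_quant]
    return cat


def apply_inclusion(
    phenotypes: pd.DataFrame,
    qc: pd.DataFrame,
    criteria: InclusionCriteria,
) -> tuple[list[str], dict[str, int]]:
    """Deterministic subject subset under one criteria set.

    Returns the included subject ids and a per-criterion exclusion count.
    Raises if any single criterion empties the sample, naming it.
    """
    ph = phenotypes.copy()
    ph["dx_group"] = np.where(ph["diagnosis"] == "control", "control", "autism")
    ph["handedness"] = recode_handedness(ph)
    ph = ph.merge(qc[["subject_id", "retention_fraction"]], on="subject_id", how="left")

    keep = pd.Series(True, index=ph.index)
    log: dict[str, int] = {}

    def restrict(name: str, mask: pd.Series) -> None:
        nonlocal keep
        dropped = int((keep & ~mask).sum())
        log[name] = dropped
        keep = keep & mask
        if not keep.any():
            raise ValueError(f"criterion '{name}' excludes every subject")

    # base: minimum per-site sample size among processable subjects
    site_n = ph.groupby("site_id")["subject_id"].transform("count")
    restrict("min_site_n", site_n >= criteria.min_site_n)

    if criteria.min_retention is not None:
        restrict("retention",
                 ph["retention_fraction"].fillna(0.0) >= criteria.min_retention)
    if criteria.exclude_sites:
        restrict("overlap_sites", ~ph["site_id"].isin(criteria.exclude_sites))
    if criteria.right_handed_only:
        restrict("right_handed", ph["handedness"] == "R")
    if criteria.male_only:
        restrict("male", ph["sex"] == "M")
    if criteria.autism_dx_only:
        restrict("autism_dx",
                 (ph["dx_group"] == "control") | (ph["diagnosis"] == "autism"))
    if criteria.verbal_iq_window is not None:
        lo_hi = ph["dx_group"].map(criteria.verbal_iq_window)
        lo = lo_hi.map(lambda w: w[0])
        hi = lo_hi.map(lambda w: w[1])
        restrict("verbal_iq", ph["verbal_iq"].between(lo, hi))

    return list(ph.loc[keep, "subject_id"]), log


# ---------------------------------------------------------------------------
# multiple testing
# ---------------------------------------------------------------------------

def fdr_bh(pvalues, q: float = 0.05) -> np.ndarray:
    """Benjamini-Hochberg step-up rejection flags at level q.

    NaN p values are never rejected and do not count toward the family.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return np.zeros(0, dtype=bool)
    ok = ~np.isnan(p)
    if np.any((p[ok] < 0) | (p[ok] > 1)):
        raise ValueError("p values must lie in [0, 1]")
    flags = np.zeros(p.shape, dtype=bool)
    if ok.sum():
        rej, *_ = multipletests(p[ok], alpha=q, method="fdr_bh")
        flags[ok] = rej
    return flags


# ---------------------------------------------------------------------------
# per-connection tests
# ---------------------------------------------------------------------------

def _li_wide(table: pd.DataFrame) -> pd.DataFrame:
    """Subjects x connections matrix of LI, ipsilateral connections only."""
    tab = table[table["laterality_class"].isin(["left-lateralized", "right-lateralized"])]
    return tab.pivot_table(index="subject_id", columns="connection", values="li",
                           aggfunc="first", dropna=False)


def _conn_meta(table: pd.DataFrame) -> pd.DataFrame:
    cols = ["connection", "hub_a", "hub_b", "laterality_class", "group"]
    return table[cols].drop_duplicates("connection").set_index("connection")


def one_sample_lateralization(
    table: pd.DataFrame, q: float = 0.05, by_group: pd.Series | None = None
) -> pd.DataFrame:
    """Per-connection one-sample t-tests of LI against zero, BH-corrected
    within each diagnostic group's family of ipsilateral connections.

    ``by_group`` maps subject_id -> diagnostic group; when omitted all
    subjects form one family.  Connections with zero LI variance are
    reported as degenerate (NaN t and p, untested); all-missing connections
    are reported untested.
    """
    wide = _li_wide(table)
    meta = _conn_meta(table)
    if by_group is None:
        groups = pd.Series("all", index=wide.index)
    else:
        groups = by_group.reindex(wide.index)
    rows = []
    for grp in groups.dropna().unique():
        sub = wide.loc[groups == grp]
        for conn in wide.columns:
            x = sub[conn].dropna().to_numpy()
            n = len(x)
            if n < 3:
                t = p = df = np.nan
                status = "untested"
            elif np.std(x, ddof=1) == 0:
                t = p = np.nan
                df = n - 1
                status = "degenerate"
            else:
                res = sps.ttest_1samp(x, 0.0)
                t, p, df = float(res.statistic), float(res.pvalue), n - 1
                status = "tested"
            rows.append(dict(dx_group=grp, connection=conn, mean_li=float(np.mean(x)) if n else np.nan,
                             n=n, t=t, df=df, p=p, status=status, **meta.loc[conn].to_dict()))
    out = pd.DataFrame(rows)
    out["fdr_significant"] = False
    for grp in out["dx_group"].unique():
        sel = out["dx_group"] == grp
        out.loc[sel, "fdr_significant"] = fdr_bh(out.loc[sel, "p"].to_numpy(), q=q)
    return out


def two_sample_group_test(
    table: pd.DataFrame,
    groups: pd.Series,
    q: float = 0.05,
    equal_var: bool = True,
) -> pd.DataFrame:
    """Per-connection two-sample t-tests (control minus autism) on LI with
    BH-FDR jointly over the tested family of ipsilateral connections.

    ``groups`` maps subject_id -> 'control' | 'autism'.  Pooled-variance
    (Student) by default, df = n1 + n2 - 2 after per-connection missingness;
    ``equal_var=False`` switches to Welch.
    """
    wide = _li_wide(table)
    meta = _conn_meta(table)
    g = groups.reindex(wide.index)
    a = wide.loc[g == "control"]
    b = wide.loc[g == "autism"]
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both diagnostic groups need at least one subject")
    rows = []
    for conn in wide.columns:
        x = a[conn].dropna().to_numpy()
        y = b[conn].dropna().to_numpy()
        if len(x) < 2 or len(y) < 2:
            rows.append(dict(connection=conn, n_control=len(x), n_autism=len(y),
                             t=np.nan, df=np.nan, p=np.nan, status="untested",
                             mean_control=np.nan, mean_autism=np.nan,
                             direction="", **meta.loc[conn].to_dict()))
            continue
        mc, ma = float(np.mean(x)), float(np.mean(y))
        if np.std(x, ddof=1) == 0 and np.std(y, ddof=1) == 0 and mc == ma:
            # identical degenerate groups: no evidence of a difference
            rows.append(dict(connection=conn, n_control=len(x), n_autism=len(y),
                             t=0.0, df=len(x) + len(y) - 2, p=1.0, status="tested",
                             mean_control=mc, mean_autism=ma, direction="",
                             **meta.loc[conn].to_dict()))
            continue
        res = sps.ttest_ind(x, y, equal_var=equal_var)
        df = len(x) + len(y) - 2 if equal_var else float(res.df)
        direction = "control_more_left" if mc > ma else "autism_more_left"
        rows.append(dict(connection=conn, n_control=len(x), n_autism=len(y),
                         t=float(res.statistic), df=df, p=float(res.pvalue),
                         status="tested", mean_control=mc, mean_autism=ma,
                         direction=direction, **meta.loc[conn].to_dict()))
    out = pd.DataFrame(rows)
    out["fdr_significant"] = fdr_bh(out["p"].to_numpy(), q=q)
    return out


def paired_group_contrasts(triples: pd.DataFrame, groups: pd.Series) -> pd.DataFrame:
    """Paired t-tests between the three connection-group means, separately
    per diagnostic group.

    ``triples`` is the per-subject output of ``connection_group_means``.
    The right-network column enters as -li so all three columns share one
    magnitude scale (degree of lateralization toward the network's own
    hemisphere).  Contrasts: left-language vs left-nonlanguage,
    left-language vs right, left-nonlanguage vs right.  Groups with fewer
    than 3 complete subjects are reported untested.
    """
    tri = triples.set_index("subject_id")
    tri = tri.assign(right_degree=-tri["right"])
    g = groups.reindex(tri.index)
    contrasts = [
        ("left_language_vs_left_nonlanguage", "left_language", "left_nonlanguage"),
        ("left_language_vs_right", "left_language", "right_degree"),
        ("left_nonlanguage_vs_right", "left_nonlanguage", "right_degree"),
    ]
    rows = []
    for grp in g.dropna().unique():
        sub = tri.loc[g == grp]
        for name, c1, c2 in contrasts:
            pair = sub[[c1, c2]].dropna()
            if len(pair) < 3:
                rows.append(dict(dx_group=grp, contrast=name, n=len(pair),
                                 t=np.nan, df=np.nan, p=np.nan, status="untested",
                                 mean_diff=np.nan))
                continue
            diff = (pair[c1] - pair[c2]).to_numpy()
            if diff.std(ddof=1) == 0 and diff.mean() == 0:
                t, p = 0.0, 1.0  # identical columns: no paired difference
            else:
                res = sps.ttest_rel(pair[c1], pair[c2])
                t, p = float(res.statistic), float(res.pvalue)
            rows.append(dict(dx_group=grp, contrast=name, n=len(pair),
                             t=t, df=len(pair) - 1, p=p, status="tested",
                             mean_diff=float(diff.mean())))
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# brain-behaviour correlations
# ---------------------------------------------------------------------------

def severity(phenotypes: pd.DataFrame) -> pd.Series:
    """Symptom severity: ADOS social + communication domain totals."""
    return phenotypes.set_index("subject_id")[["ados_social", "ados_communication"]].sum(
        axis=1, min_count=2
    )


def phenotype_correlations(
    table: pd.DataFrame,
    phenotypes: pd.DataFrame,
    connections_of_interest: list[str],
    include_controls_with_ados: bool = True,
) -> pd.DataFrame:
    """Correlations between LI and phenotype for the flagged connections.

    Per connection: Pearson r of LI vs severity within the autism group
    (and optionally within autism + controls who have ADOS scores), and
    Spearman rho of LI vs age and vs quantitative handedness per diagnostic
    group.  Pairs are pairwise-complete; fewer than 3 pairs -> untested.
    """
    wide = _li_wide(table)
    ph = phenotypes.set_index("subject_id")
    dx = np.where(ph["diagnosis"] == "control", "control", "autism")
    ph = ph.assign(dx_group=dx, severity=severity(phenotypes))

    def corr(x: pd.Series, y: pd.Series, method: str):
        pair = pd.concat([x, y], axis=1, join="inner").dropna()
        if len(pair) < 3:
            return np.nan, np.nan, len(pair)
        if pair.iloc[:, 0].nunique() == 1 or pair.iloc[:, 1].nunique() == 1:
            return np.nan, np.nan, len(pair)  # constant input: undefined
        if method == "pearson":
            r, p = sps.pearsonr(pair.iloc[:, 0], pair.iloc[:, 1])
        else:
            r, p = sps.spearmanr(pair.iloc[:, 0], pair.iloc[:, 1])
        return float(r), float(p), len(pair)

    rows = []
    for conn in connections_of_interest:
        if conn not in wide.columns:
            raise ValueError(f"connection '{conn}' not present in the LI table")
        li = wide[conn]
        autism_ids = ph.index[ph["dx_group"] == "autism"]
        r, p, n = corr(li.reindex(autism_ids), ph.loc[autism_ids, "severity"], "pearson")
        rows.append(dict(connection=conn, variable="severity", dx_group="autism",
                         method="pearson", r=r, p=p, n=n))
        if include_controls_with_ados:
            r, p, n = corr(li, ph["severity"], "pearson")
            rows.append(dict(connection=conn, variable="severity", dx_group="all_with_ados",
                             method="pearson", r=r, p=p, n=n))
        for grp in ("control", "autism"):
            ids = ph.index[ph["dx_group"] == grp]
            for var in ("age", "handedness_quant"):
                r, p, n = corr(li.reindex(ids), ph.loc[ids, var], "spearman")
                rows.append(dict(connection=conn, variable=var, dx_group=grp,
                                 method="spearman", r=r, p=p, n=n))
    return pd.DataFrame(rows)
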