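"""End-to-end orchestration: simulate -> preprocess -> extract -> flip ->
lateralize -> test, from one config, with a reproducibility manifest.

The heavy lifting lives in the other modules; this one wires them together
per subject (streaming, so cohorts never sit in memory at once), assembles
the tidy LI table and QC table, and runs the group statistics under a named
inclusion-criteria preset.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .atlas import HubSet, RoiAtlas, extract_timecourses, flip_midsagittal
from .lateralize import (
    Connection,
    connection_group_means,
    enumerate_connections,
    fisher_connectivity,
)
from .preprocess import BoldRun, NuisanceSet, preprocess_run, roi_snr
from .stats import (
    InclusionCriteria,
    apply_inclusion,
    criteria_preset,
    one_sample_lateralization,
    paired_group_contrasts,
    phenotype_correlations,
    two_sample_group_test,
)
from .synthdata import CohortSpec, LateralizationEffect, cohort_stream

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """One pipeline run.  Every analysis parameter defaults to the standard
    value: band 0.001-0.1 Hz, scrub threshold 0.2, q = 0.05, 5-mm lattice
    spacing, z range [-35, 70] (the last two apply to real-mask lattices)."""

    cohort: CohortSpec = field(default_factory=CohortSpec)
    low_hz: float = 0.001
    high_hz: float = 0.1
    scrub_threshold: float = 0.2
    q: float = 0.05
    criteria: str = "A"
    min_site_n: int = 20
    equal_var: bool = True
    compute_snr: bool = True
    out_dir: str | None = None

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        cohort_raw = raw.pop("cohort", {})
        effects = [LateralizationEffect(**e) for e in cohort_raw.pop("lateralization_effects", [])]
        for key in ("grid_dims", "spike_mm", "overlap_sites"):
            if key in cohort_raw:
                cohort_raw[key] = tuple(cohort_raw[key])
        spec = CohortSpec(lateralization_effects=effects, **cohort_raw)
        return cls(cohort=spec, **raw)

    def to_dict(self) -> dict:
        d = asdict(self)
        if self.cohort.hub_table is not None:
            d["cohort"]["hub_table"] = self.cohort.hub_table.to_dict("records")
        return d


@dataclass
class StudyResult:
    """All statistics for one inclusion-criteria preset."""

    criteria: str
    n_control: int
    n_autism: int
    connection_tests: pd.DataFrame  # two-sample, per connection
    one_sample: pd.DataFrame  # per group pattern maps
    contrasts: pd.DataFrame  # paired connection-group contrasts
    correlations: pd.DataFrame  # phenotype correlations for flagged connections
    exclusion_log: dict[str, int] = field(default_factory=dict)

    def significant_connections(self) -> list[str]:
        ct = self.connection_tests
        if len(ct) == 0:
            return []
        return list(ct.loc[ct["fdr_significant"], "connection"])

    def summary(self) -> dict:
        return dict(
            criteria=self.criteria,
            n_control=self.n_control,
            n_autism=self.n_autism,
            n_connections_tested=int((self.connection_tests["status"] == "tested").sum())
            if len(self.connection_tests) else 0,
            fdr_significant=self.significant_connections(),
            exclusions=self.exclusion_log,
        )

    def save(self, out_dir) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.connection_tests.to_csv(out / "connection_tests.csv", index=False)
        self.one_sample.to_csv(out / "one_sample_patterns.csv", index=False)
        self.contrasts.to_csv(out / "group_contrasts.csv", index=False)
        self.correlations.to_csv(out / "phenotype_correlations.csv", index=False)
        with open(out / "summary.json", "w") as fh:
            json.dump(self.summary(), fh, indent=2)


# ---------------------------------------------------------------------------
# per-subject computation
# ---------------------------------------------------------------------------

def subject_lateralization(
    bold: BoldRun,
    nuisance: NuisanceSet,
    atlas: RoiAtlas,
    connections: list[Connection],
    low_hz: float = 0.001,
    high_hz: float = 0.1,
    scrub_threshold: float = 0.2,
) -> tuple[np.ndarray, dict]:
    """Preprocess one run and compute its LI on every connection.

    Returns (li vector aligned with ``connections``, QC row dict).
    """
    cleaned, scrubbed = preprocess_run(
        bold, nuisance=nuisance, low_hz=low_hz, high_hz=high_hz,
        scrub_threshold=scrub_threshold,
    )
    tc_u = extract_timecourses(cleaned, atlas)
    tc_f = extract_timecourses(flip_midsagittal(cleaned), atlas)
    z_u = fisher_connectivity(tc_u).z
    z_f = fisher_connectivity(tc_f).z
    ia = np.array([c.left_roi_a - 1 for c in connections])
    ib = np.array([c.left_roi_b - 1 for c in connections])
    li = z_u[ia, ib] - z_f[ia, ib]
    qc = dict(
        subject_id=bold.subject_id,
        site_id=bold.site_id,
        retention_fraction=scrubbed.retention_fraction,
        mean_fd_pre=scrubbed.mean_fd_pre,
        mean_fd_post=scrubbed.mean_fd_post,
        n_volumes_kept=int(scrubbed.kept_mask.sum()),
        n_missing_li=int(np.isnan(li).sum()),
    )
    return li, qc


def hub_snrs(bold: BoldRun, atlas: RoiAtlas, hubs: HubSet) -> dict[str, float]:
    """Per-hub SNR on the raw (pre-regression, pre-scrub) run."""
    out = {}
    for _, row in hubs.table.iterrows():
        mask = atlas.labels == int(row["roi_id"])
        out[f"snr_{row['name']}"] = roi_snr(bold, mask)
    return out


# ---------------------------------------------------------------------------
# cohort-level computation
# ---------------------------------------------------------------------------

def compute_cohort_lateralization(
    spec: CohortSpec,
    low_hz: float = 0.001,
    high_hz: float = 0.1,
    scrub_threshold: float = 0.2,
    compute_snr: bool = True,
    include_mixed: bool = False,
):
    """Simulate a cohort and compute the tidy LI table plus QC table.

    Returns (li_table, qc, phenotypes, hubs, connections).  Deterministic
    given the spec's seed.
    """
    atlas, hubs, phenotypes, stream = cohort_stream(spec)
    connections = enumerate_connections(hubs, include_mixed=include_mixed)
    li_rows, qc_rows, subject_ids = [], [], []
    for record, bold, nuis in stream:
        li, qc = subject_lateralization(
            bold, nuis, atlas, connections,
            low_hz=low_hz, high_hz=high_hz, scrub_threshold=scrub_threshold,
        )
        if compute_snr:
            qc.update(hub_snrs(bold, atlas, hubs))
        li_rows.append(li)
        qc_rows.append(qc)
        subject_ids.append(record.subject_id)
        logger.debug("subject %s done (retention %.2f)", record.subject_id,
                     qc["retention_fraction"])
    li_mat = np.array(li_rows)
    n_conn = len(connections)
    li_table = pd.DataFrame(
        dict(
            subject_id=np.repeat(subject_ids, n_conn),
            hub_a=np.tile([c.hub_a for c in connections], len(subject_ids)),
            hub_b=np.tile([c.hub_b for c in connections], len(subject_ids)),
            connection=np.tile([c.label for c in connections], len(subject_ids)),
            laterality_class=np.tile([c.laterality_class for c in connections],
                                     len(subject_ids)),
            group=np.tile([c.group for c in connections], len(subject_ids)),
            li=li_mat.reshape(-1),
        )
    )
    qc = pd.DataFrame(qc_rows)
    return li_table, qc, phenotypes, hubs, connections


def analyze_lateralization(
    li_table: pd.DataFrame,
    qc: pd.DataFrame,
    phenotypes: pd.DataFrame,
    criteria: InclusionCriteria,
    q: float = 0.05,
    equal_var: bool = True,
) -> StudyResult:
    """Group statistics under one inclusion-criteria preset."""
    included, log = apply_inclusion(phenotypes, qc, criteria)
    tab = li_table[li_table["subject_id"].isin(included)]
    ph = phenotypes[phenotypes["subject_id"].isin(included)]
    groups = pd.Series(
        np.where(ph["diagnosis"] == "control", "control", "autism"),
        index=ph["subject_id"],
    )
    n_control = int((groups == "control").sum())
    n_autism = int((groups == "autism").sum())

    two_sample = two_sample_group_test(tab, groups, q=q, equal_var=equal_var)
    one_sample = one_sample_lateralization(tab, q=q, by_group=groups)
    triples = connection_group_means(tab)
    contrasts = paired_group_contrasts(triples, groups)
    flagged = list(two_sample.loc[two_sample["fdr_significant"], "connection"])
    correlations = phenotype_correlations(tab, ph, flagged) if flagged else pd.DataFrame(
        columns=["connection", "variable", "dx_group", "method", "r", "p", "n"]
    )
    return StudyResult(
        criteria=criteria.name, n_control=n_control, n_autism=n_autism,
        connection_tests=two_sample, one_sample=one_sample,
        contrasts=contrasts, correlations=correlations, exclusion_log=log,
    )


def run_pipeline(config: RunConfig):
    """Run the full pipeline from one config.

    Returns (StudyResult, qc table, li_table, manifest dict); writes all
    artifacts plus the manifest under ``config.out_dir`` when set.
    Deterministic given the cohort seed.
    """
    li_table, qc, phenotypes, hubs, connections = compute_cohort_lateralization(
        config.cohort, low_hz=config.low_hz, high_hz=config.high_hz,
        scrub_threshold=config.scrub_threshold, compute_snr=config.compute_snr,
    )
    criteria = criteria_preset(
        config.criteria, overlap_sites=config.cohort.overlap_sites,
        min_site_n=config.min_site_n,
    )
    result = analyze_lateralization(
        li_table, qc, phenotypes, criteria, q=config.q, equal_var=config.equal_var
    )
    manifest = _manifest(config, result, qc)
    if config.out_dir is not None:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        li_table.to_csv(out / "li_table.csv", index=False)
        qc.to_csv(out / "qc.csv", index=False)
        phenotypes.to_csv(out / "phenotypes.csv", index=False)
        hubs.to_csv(out / "hubs.csv")
        result.save(out)
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2)
        with open(out / "report.txt", "w") as fh:
            fh.write(make_report(result))
    return result, qc, li_table, manifest


def _manifest(config: RunConfig, result: StudyResult, qc: pd.DataFrame) -> dict:
    import scipy
    import statsmodels

    cfg = config.to_dict()
    cfg_json = json.dumps(cfg, sort_keys=True, default=str)
    return dict(
        config=cfg,
        config_sha256=hashlib.sha256(cfg_json.encode()).hexdigest(),
        versions=dict(
            hemiflip=__version__, numpy=np.__version__, scipy=scipy.__version__,
            pandas=pd.__version__, statsmodels=statsmodels.__version__,
        ),
        counts=dict(
            n_subjects_simulated=int(len(qc)),
            n_included=result.n_control + result.n_autism,
            n_control=result.n_control,
            n_autism=result.n_autism,
            n_connections=int(result.connection_tests["connection"].nunique())
            if len(result.connection_tests) else 0,
            n_fdr_significant=len(result.significant_connections()),
        ),
        mean_retention=float(qc["retention_fraction"].mean()) if len(qc) else None,
    )


# ---------------------------------------------------------------------------
# reporting
# ---------------------------------------------------------------------------

def make_report(result: StudyResult) -> str:
    """Human-readable summary: per-connection group patterns and
    differences with significance markers, plus the contrast and
    correlation tables.  Significance markers (*) appear only on
    FDR-significant rows."""
    lines = [
        f"Lateralization analysis — inclusion criteria {result.criteria}",
        f"included subjects: {result.n_control} control / {result.n_autism} autism",
        "",
    ]
    ct = result.connection_tests
    lines.append(f"Group differences (two-sample t, FDR q flags) — {len(ct)} connections")
    if len(ct):
        for _, r in ct.iterrows():
            star = " *" if r["fdr_significant"] else ""
            t = f"{r['t']:7.3f}" if np.isfinite(r.get("t", np.nan)) else "    n/a"
            p = f"{r['p']:.2e}" if np.isfinite(r.get("p", np.nan)) else "n/a"
            lines.append(
                f"  {r['connection']:<12s} [{r['group']:<16s}] t={t} p={p}{star}"
            )
    lines.append("")
    os_ = result.one_sample
    lines.append("Within-group lateralization patterns (one-sample t vs 0)")
    if len(os_):
        for grp in os_["dx_group"].unique():
            sub = os_[os_["dx_group"] == grp]
            n_sig = int(sub["fdr_significant"].sum())
            lines.append(f"  group {grp}: {n_sig}/{len(sub)} connections FDR-significant")
            for _, r in sub.iterrows():
                star = " *" if r["fdr_significant"] else ""
                mean = f"{r['mean_li']:+.3f}" if np.isfinite(r.get("mean_li", np.nan)) else "  n/a"
                lines.append(f"    {r['connection']:<12s} mean li {mean}{star}")
    lines.append("")
    lines.append("Connection-group contrasts (paired t on common magnitude scale)")
    for _, r in result.contrasts.iterrows():
        t = f"{r['t']:.3f}" if np.isfinite(r.get("t", np.nan)) else "n/a"
        p = f"{r['p']:.4f}" if np.isfinite(r.get("p", np.nan)) else "n/a"
        lines.append(f"  {r['dx_group']:<8s} {r['contrast']:<36s} t={t} p={p}")
    lines.append("")
    lines.append("Phenotype correlations on flagged connections")
    if len(result.correlations) == 0:
        lines.append("  (no FDR-significant connections)")
    for _, r in result.correlations.iterrows():
        rv = f"{r['r']:+.3f}" if np.isfinite(r.get("r", np.nan)) else "n/a"
        pv = f"{r['p']:.4f}" if np.isfinite(r.get("p", np.nan)) else "n/a"
        lines.append(
            f"  {r['connection']:<12s} {r['variable']:<17s} [{r['dx_group']:<14s}]"
            f" {r['method']:<8s} r={rv} p={pv} n={r['n']}"
        )
    return "\n".join(lines) + "\n"


def criteria_table(results: list[StudyResult]) -> pd.DataFrame:
    """Criteria-comparison table across presets: per preset the included
    n's and the FDR-significant connections with their t and p."""
    rows = []
    for res in results:
        ct = res.connection_tests
        sig = ct[ct["fdr_significant"]] if len(ct) else ct
        if len(sig) == 0:
            rows.append(dict(criteria=res.criteria,
                             n_total=res.n_control + res.n_autism,
                             n_autism=res.n_autism, connection=None,
                             t=np.nan, p=np.nan))
        for _, r in sig.iterrows():
            rows.append(dict(criteria=res.criteria,
                             n_total=res.n_control + res.n_autism,
                             n_autism=res.n_autism, connection=r["connection"],
                             t=r["t"], p=r["p"]))
    return pd.DataFrame(rows)
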