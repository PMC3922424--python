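"""Tests for inclusion criteria, FDR, the per-connection tests, paired
contrasts, and phenotype correlations."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from hemiflip.stats import (
    apply_inclusion,
    criteria_preset,
    fdr_bh,
    one_sample_lateralization,
    paired_group_contrasts,
    phenotype_correlations,
    recode_handedness,
    severity,
    two_sample_group_test,
)


def phenotype_row(subject_id, diagnosis="control", site="SITE01", sex="M",
                  hc=None, hq=50.0, viq=100.0, age=20.0, soc=None, com=None):
    return dict(subject_id=subject_id, site_id=site, diagnosis=diagnosis,
                age=age, sex=sex, handedness_cat=hc, handedness_quant=hq,
                verbal_iq=viq, performance_iq=100.0,
                ados_social=soc, ados_communication=com)


def li_rows(subject_id, conns, values):
    return [dict(subject_id=subject_id, hub_a=c[0], hub_b=c[1],
                 connection=f"{c[0]}--{c[1]}", laterality_class=c[2],
                 group=c[3], li=v) for c, v in zip(conns, values)]


CONNS = [("A", "B", "left-lateralized", "left-language"),
         ("A", "C", "left-lateralized", "left-nonlanguage"),
         ("X", "Y", "right-lateralized", "right")]


def make_table(li_by_subject):
    rows = []
    for sid, vals in li_by_subject.items():
        rows += li_rows(sid, CONNS, vals)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# inclusion criteria
# ---------------------------------------------------------------------------

class TestApplyInclusion:
    def _qc(self, ids, retention=0.9):
        return pd.DataFrame(dict(subject_id=ids,
                                 retention_fraction=[retention] * len(ids)))

    def test_autism_verbal_iq_79_excluded_under_window(self):
        ph = pd.DataFrame([
            phenotype_row("a1", "autism", viq=79.0),
            phenotype_row("a2", "autism", viq=80.0),
            phenotype_row("c1", "control", viq=75.0),
        ])
        crit = criteria_preset("H", min_site_n=1)
        included, log = apply_inclusion(ph, self._qc(ph["subject_id"]), crit)
        assert "a1" not in included and "a2" in included and "c1" in included
        assert log["verbal_iq"] == 1

    def test_retention_below_half_excluded(self):
        ph = pd.DataFrame([phenotype_row("s1"), phenotype_row("s2")])
        qc = pd.DataFrame(dict(subject_id=["s1", "s2"],
                               retention_fraction=[0.49, 0.50]))
        crit = criteria_preset("B", min_site_n=1)
        included, _ = apply_inclusion(ph, qc, crit)
        assert included == ["s2"]

    def test_positive_quantitative_handedness_is_right(self):
        ph = pd.DataFrame([
            phenotype_row("s1", hc=None, hq=30.0),
            phenotype_row("s2", hc=None, hq=-30.0),
            phenotype_row("s3", hc=None, hq=0.0),
            phenotype_row("s4", hc="L", hq=90.0),  # categorical wins
        ])
        hand = recode_handedness(ph)
        assert list(hand) == ["R", "L", "A", "L"]
        crit = criteria_preset("E", min_site_n=1)
        included, _ = apply_inclusion(ph, self._qc(ph["subject_id"]), crit)
        assert included == ["s1"]

    def test_min_site_n_base_criterion(self):
        ph = pd.DataFrame(
            [phenotype_row(f"s{i}", site="BIG") for i in range(5)]
            + [phenotype_row("t1", site="TINY")])
        crit = criteria_preset("A", min_site_n=5)
        included, log = apply_inclusion(ph, self._qc(ph["subject_id"]), crit)
        assert "t1" not in included and len(included) == 5
        assert log["min_site_n"] == 1

    def test_overlap_site_exclusion(self):
        ph = pd.DataFrame([phenotype_row("s1", site="SITE01"),
                           phenotype_row("s2", site="SITE02")])
        crit = criteria_preset("C", overlap_sites=("SITE01",), min_site_n=1)
        included, _ = apply_inclusion(ph, self._qc(ph["subject_id"]), crit)
        assert included == ["s2"]

    def test_strict_autism_dx_only(self):
        ph = pd.DataFrame([phenotype_row("a1", "autism"),
                           phenotype_row("a2", "asperger"),
                           phenotype_row("a3", "pdd_nos"),
                           phenotype_row("c1", "control")])
        crit = criteria_preset("G", min_site_n=1)
        included, _ = apply_inclusion(ph, self._qc(ph["subject_id"]), crit)
        assert set(included) == {"a1", "c1"}

    def test_emptying_criterion_named(self):
        ph = pd.DataFrame([phenotype_row("s1", sex="F")])
        crit = criteria_preset("F", min_site_n=1)
        with pytest.raises(ValueError, match="male"):
            apply_inclusion(ph, self._qc(["s1"]), crit)

    def test_presets_monotone_under_added_restrictions(self):
        from hemiflip.synthdata import CohortSpec, simulate_phenotypes
        rng = np.random.default_rng(8)
        ph = simulate_phenotypes(CohortSpec(n_control=60, n_autism=60, n_sites=2), rng)
        qc = pd.DataFrame(dict(subject_id=ph["subject_id"],
                               retention_fraction=rng.uniform(0.3, 1.0, len(ph))))
        counts = {}
        for letter in "ABCDEFGH":
            crit = criteria_preset(letter, overlap_sites=("SITE01",), min_site_n=1)
            counts[letter] = len(apply_inclusion(ph, qc, crit)[0])
        assert all(counts[k] <= counts["A"] for k in "BCDEFGH")
        assert counts["D"] <= counts["B"] and counts["D"] <= counts["C"]


# ---------------------------------------------------------------------------
# FDR
# ---------------------------------------------------------------------------

def bh_stepup_reference(p, q):
    """Independent literal step-up: largest k with p_(k) <= k q / m."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p)
    k_max = 0
    for i, idx in enumerate(order, start=1):
        if p[idx] <= i * q / m:
            k_max = i
    flags = np.zeros(m, dtype=bool)
    flags[order[:k_max]] = True
    return flags


class TestFdrBH:
    def test_single_small_p_rejected(self):
        assert fdr_bh([0.001]).tolist() == [True]

    def test_three_borderline_all_rejected(self):
        # 0.04 <= (3/3) * 0.05 in the step-up
        assert fdr_bh([0.04, 0.04, 0.04]).tolist() == [True, True, True]

    def test_all_ones_none_rejected(self):
        assert not fdr_bh([1.0, 1.0, 1.0]).any()

    def test_empty_input(self):
        assert fdr_bh([]).size == 0

    def test_nan_never_rejected(self):
        flags = fdr_bh([0.001, np.nan])
        assert flags.tolist() == [True, False]

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(st.lists(st.integers(0, 100), min_size=1, max_size=6))
    def test_matches_exhaustive_stepup_on_grid(self, grid_idx):
        p = np.array(grid_idx) * 0.01
        np.testing.assert_array_equal(fdr_bh(p, q=0.05),
                                      bh_stepup_reference(p, 0.05))


# ---------------------------------------------------------------------------
# one-sample tests
# ---------------------------------------------------------------------------

class TestOneSample:
    def test_zero_variance_reported_degenerate(self):
        table = make_table({f"s{i}": [0.5, 0.1 * i, 0.2] for i in range(10)})
        res = one_sample_lateralization(table)
        row = res[res["connection"] == "A--B"].iloc[0]
        assert row["status"] == "degenerate" and np.isnan(row["t"])

    def test_strong_effect_detected(self, rng):
        vals = rng.normal(0.3, 0.1, size=50)
        table = make_table({f"s{i}": [vals[i], 0.0, 0.0] for i in range(50)})
        res = one_sample_lateralization(table)
        row = res[res["connection"] == "A--B"].iloc[0]
        assert row["p"] < 1e-6 and row["fdr_significant"]

    def test_too_few_subjects_untested(self):
        table = make_table({"s1": [0.1, 0.2, 0.3], "s2": [0.0, 0.1, 0.2]})
        res = one_sample_lateralization(table)
        assert (res["status"] == "untested").all()


# ---------------------------------------------------------------------------
# two-sample tests
# ---------------------------------------------------------------------------

def groups_series(ids_control, ids_autism):
    return pd.Series({**{s: "control" for s in ids_control},
                      **{s: "autism" for s in ids_autism}})


class TestTwoSample:
    def test_identical_groups_give_t_zero(self):
        vals = {f"c{i}": [0.1, 0.2, 0.3] for i in range(5)}
        vals.update({f"a{i}": [0.1, 0.2, 0.3] for i in range(5)})
        res = two_sample_group_test(make_table(vals),
                                    groups_series([f"c{i}" for i in range(5)],
                                                  [f"a{i}" for i in range(5)]))
        assert (res["t"] == 0).all() and (res["p"] == 1).all()

    def test_planted_difference_fdr_significant(self, rng):
        n = 100
        vals = {}
        for i in range(n):
            vals[f"c{i}"] = [rng.normal(0.3, 0.2), rng.normal(0, 0.2), rng.normal(0, 0.2)]
            vals[f"a{i}"] = [rng.normal(0.0, 0.2), rng.normal(0, 0.2), rng.normal(0, 0.2)]
        res = two_sample_group_test(make_table(vals),
                                    groups_series([f"c{i}" for i in range(n)],
                                                  [f"a{i}" for i in range(n)]))
        row = res[res["connection"] == "A--B"].iloc[0]
        assert row["fdr_significant"] and row["direction"] == "control_more_left"
        assert row["df"] == 2 * n - 2

    def test_welch_option(self, rng):
        vals = {f"c{i}": [rng.normal(0, 1), 0.1, 0.2] for i in range(20)}
        vals.update({f"a{i}": [rng.normal(0, 1), 0.1, 0.2] for i in range(20)})
        res = two_sample_group_test(make_table(vals),
                                    groups_series([f"c{i}" for i in range(20)],
                                                  [f"a{i}" for i in range(20)]),
                                    equal_var=False)
        assert np.isfinite(res.loc[res["connection"] == "A--B", "t"]).all()

    def test_empty_group_rejected(self):
        table = make_table({"c1": [0.1, 0.2, 0.3]})
        with pytest.raises(ValueError, match="group"):
            two_sample_group_test(table, groups_series(["c1"], []))


# ---------------------------------------------------------------------------
# paired contrasts
# ---------------------------------------------------------------------------

class TestPairedContrasts:
    def _triples(self, ll, ln, r, ids=None):
        ids = ids or [f"s{i}" for i in range(len(ll))]
        return pd.DataFrame(dict(subject_id=ids, left_language=ll,
                                 left_nonlanguage=ln, right=r,
                                 n_missing=0))

    def test_identical_columns_give_t_zero(self):
        x = np.linspace(0.1, 0.5, 10)
        tri = self._triples(x, x, -x)  # right enters as -li
        g = pd.Series("control", index=tri["subject_id"])
        res = paired_group_contrasts(tri, g)
        assert (res["t"] == 0).all() and (res["p"] == 1).all()

    def test_shifted_column_detected(self, rng):
        n = 400
        base = rng.normal(0.2, 0.2, n)
        tri = self._triples(base + 0.1, base, -base + rng.normal(0, 0.01, n))
        g = pd.Series("control", index=tri["subject_id"])
        res = paired_group_contrasts(tri, g).set_index("contrast")
        assert res.loc["left_language_vs_left_nonlanguage", "p"] < 1e-3

    def test_sign_flips_when_columns_swapped(self, rng):
        n = 30
        a, b = rng.normal(0.3, 0.1, n), rng.normal(0.1, 0.1, n)
        g = pd.Series("control", index=[f"s{i}" for i in range(n)])
        t1 = paired_group_contrasts(self._triples(a, b, -b), g).set_index("contrast")
        t2 = paired_group_contrasts(self._triples(b, a, -a), g).set_index("contrast")
        assert t1.loc["left_language_vs_left_nonlanguage", "t"] == pytest.approx(
            -t2.loc["left_language_vs_left_nonlanguage", "t"])

    def test_small_group_untested(self):
        tri = self._triples([0.1, 0.2], [0.0, 0.1], [-0.1, -0.2])
        g = pd.Series("autism", index=tri["subject_id"])
        res = paired_group_contrasts(tri, g)
        assert (res["status"] == "untested").all()


# ---------------------------------------------------------------------------
# phenotype correlations
# ---------------------------------------------------------------------------

class TestPhenotypeCorrelations:
    def _phenotypes(self, n, rng, severity_values=None):
        rows = []
        for i in range(n):
            soc = severity_values[i] - 5 if severity_values is not None else 7.0
            rows.append(phenotype_row(f"a{i}", "autism", hq=rng.uniform(-100, 100),
                                      age=rng.uniform(8, 40), soc=soc, com=5.0))
        return pd.DataFrame(rows)

    def test_severity_is_social_plus_communication(self):
        ph = pd.DataFrame([phenotype_row("a1", "autism", soc=7.0, com=5.0)])
        assert severity(ph).loc["a1"] == 12.0

    def test_planted_negative_relationship_recovered(self, rng):
        n = 80
        sev = rng.uniform(4, 20, n)
        ph = self._phenotypes(n, rng, severity_values=sev)
        li = -0.05 * sev + rng.normal(0, 0.1, n)
        table = make_table({f"a{i}": [li[i], 0.0, 0.0] for i in range(n)})
        res = phenotype_correlations(table, ph, ["A--B"])
        row = res[(res["variable"] == "severity") & (res["dx_group"] == "autism")].iloc[0]
        assert row["r"] < -0.5 and row["p"] < 1e-3 and row["method"] == "pearson"

    def test_null_relationship_small_r(self, rng):
        n = 200
        sev = rng.uniform(4, 20, n)
        ph = self._phenotypes(n, rng, severity_values=sev)
        li = rng.normal(0, 0.2, n)
        table = make_table({f"a{i}": [li[i], 0.0, 0.0] for i in range(n)})
        res = phenotype_correlations(table, ph, ["A--B"])
        row = res[(res["variable"] == "severity") & (res["dx_group"] == "autism")].iloc[0]
        assert abs(row["r"]) < 0.2

    def test_age_and_handedness_use_spearman(self, rng):
        ph = self._phenotypes(30, rng)
        table = make_table({f"a{i}": [rng.normal(), 0.0, 0.0] for i in range(30)})
        res = phenotype_correlations(table, ph, ["A--B"])
        sp = res[res["variable"].isin(["age", "handedness_quant"])]
        assert (sp["method"] == "spearman").all()

    def test_too_few_pairs_untested(self, rng):
        ph = self._phenotypes(2, rng)
        table = make_table({f"a{i}": [0.1, 0.0, 0.0] for i in range(2)})
        res = phenotype_correlations(table, ph, ["A--B"])
        row = res[(res["variable"] == "severity") & (res["dx_group"] == "autism")].iloc[0]
        assert np.isnan(row["r"]) and row["n"] == 2
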