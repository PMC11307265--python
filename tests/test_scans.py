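"""Association scans: groupings, event axes, strata, conservation laws."""
from __future__ import annotations

import math

import numpy as np
import pandas as pd
import pytest

from pvsignal import (
    ChemicalSubgroup,
    ContingencyTable,
    Dataset,
    Era,
    Outcome,
    ReactionRecord,
    Seriousness,
    Sex,
    chi_square,
    classify_drugs,
    compute,
    demographic_tests,
    outcome_scan,
    parse_strata,
    round_half_up,
    seriousness_scan,
    soc_scan,
    sudep_scan,
    top_pt_table,
    yearly_soc_series,
)
from pvsignal.scans import apply_strata, build_table
from pvsignal.simulate import MarginSpec, margin_replicator

from conftest import make_report

SUDEP_PT = "Sudden unexplained death in epilepsy"


@pytest.fixture(scope="module")
def scaled_replica():
    """Table-3-shaped margins scaled down 1:100 for fast scan tests."""
    spec = MarginSpec(
        totals={"old": 3727, "new": 6785},
        cells={
            "old": {"Blood and lymphatic system disorders": 87,
                    "Hepatobiliary disorders": 61,
                    "Investigations": 266},
            "new": {"Blood and lymphatic system disorders": 75,
                    "Hepatobiliary disorders": 55,
                    "Investigations": 342},
        },
    )
    return Dataset(margin_replicator(spec))


class TestSocScan:
    def test_era_scan_matches_direct_2x2(self, scaled_replica):
        table = soc_scan(scaled_replica, grouping="era")
        row = table.row("old", "Blood and lymphatic system disorders")
        expected = compute(ContingencyTable(87, 3727 - 87, 75, 6785 - 75))
        assert row["a"] == 87 and row["c"] == 75
        assert row["ror"] == pytest.approx(expected.ror)
        assert row["prr"] == pytest.approx(expected.prr)
        assert row["chi2"] == pytest.approx(expected.chi2)

    def test_new_rows_are_reciprocal(self, scaled_replica):
        table = soc_scan(scaled_replica, grouping="era")
        old = table.row("old", "Hepatobiliary disorders")
        new = table.row("new", "Hepatobiliary disorders")
        assert new["ror"] == pytest.approx(1.0 / old["ror"])

    def test_a_cells_partition_era_total(self, scaled_replica):
        table = soc_scan(scaled_replica, grouping="era")
        old_rows = table.frame[table.frame.exposure == "old"]
        assert old_rows["a"].sum() == 3727

    def test_single_soc_not_countable(self, catalogue):
        reports = [make_report(report_id=f"R{i}", drugs=("Phenobarbital",))
                   for i in range(3)]
        reports += [make_report(report_id=f"S{i}", drugs=("Levetiracetam",))
                    for i in range(3)]
        classify_drugs(reports, catalogue)
        ds = Dataset(reports)
        table = soc_scan(ds, grouping="era")
        assert not table.frame["countable"].any()

    def test_unclassified_era_excluded_from_both_arms(self, catalogue):
        reports = [make_report(report_id="A", drugs=("Phenobarbital",)),
                   make_report(report_id="B", drugs=("Levetiracetam",)),
                   make_report(report_id="C", drugs=("Cannabidiol",))]
        classify_drugs(reports, catalogue)
        table = soc_scan(Dataset(reports), grouping="era")
        assert (table.frame[["a", "b", "c", "d"]].sum(axis=1) == 2).all()

    def test_determinism_under_row_permutation(self, catalogue):
        reports = [make_report(report_id=f"R{i}",
                               drugs=("Phenobarbital" if i % 2 else "Pregabalin",),
                               reactions=[ReactionRecord(pt=f"PT{i % 5}")])
                   for i in range(40)]
        classify_drugs(reports, catalogue)
        a = soc_scan(Dataset(list(reports)), grouping="era").frame
        b = soc_scan(Dataset(list(reversed(reports))), grouping="era").frame
        pd.testing.assert_frame_equal(a, b)


class TestSeriousnessScan:
    def _reports(self, catalogue):
        reactions_old = [
            ReactionRecord(pt="Rash", seriousness=frozenset(
                {Seriousness.DEATH, Seriousness.LIFE_THREATENING})),
            ReactionRecord(pt="Seizure", seriousness=frozenset(
                {Seriousness.HOSPITALISATION})),
        ]
        reactions_new = [
            ReactionRecord(pt="Nausea"),  # unspecified seriousness
            ReactionRecord(pt="Rash", seriousness=frozenset(
                {Seriousness.HOSPITALISATION})),
        ]
        reports = [make_report(report_id="O1", drugs=("Phenobarbital",),
                               reactions=reactions_old),
                   make_report(report_id="N1", drugs=("Pregabalin",),
                               reactions=reactions_new)]
        classify_drugs(reports, catalogue)
        return reports

    def test_multilabel_counts_both_criteria(self, catalogue):
        table = seriousness_scan(Dataset(self._reports(catalogue)), grouping="era")
        death = table.row("old", Seriousness.DEATH.value)
        lt = table.row("old", Seriousness.LIFE_THREATENING.value)
        assert death["a"] == 1 and lt["a"] == 1  # one PT feeds both rows

    def test_unspecified_stays_in_denominator(self, catalogue):
        table = seriousness_scan(Dataset(self._reports(catalogue)), grouping="era")
        hosp = table.row("new", Seriousness.HOSPITALISATION.value)
        assert hosp["a"] == 1 and hosp["b"] == 1  # the unspecified PT sits in b

    def test_all_unspecified_not_countable(self, catalogue):
        reports = [make_report(report_id="A", drugs=("Phenobarbital",)),
                   make_report(report_id="B", drugs=("Pregabalin",))]
        classify_drugs(reports, catalogue)
        table = seriousness_scan(Dataset(reports), grouping="era")
        assert not table.frame["countable"].any()

    def test_subgroup_grouping_has_all_subgroups(self, catalogue):
        table = seriousness_scan(Dataset(self._reports(catalogue)),
                                 grouping="subgroup")
        assert set(table.frame["exposure"]) == {g.value for g in ChemicalSubgroup}


class TestOutcomeScan:
    def test_outcome_rows_partition_known_outcomes(self, catalogue):
        outcomes = [Outcome.FATAL, Outcome.RECOVERED, Outcome.RECOVERED,
                    Outcome.RECOVERING, Outcome.UNSPECIFIED]
        reports = [make_report(report_id=f"R{i}", drugs=("Phenobarbital",),
                               reactions=[ReactionRecord(pt="Seizure", outcome=o)])
                   for i, o in enumerate(outcomes)]
        reports.append(make_report(report_id="N", drugs=("Pregabalin",),
                                   reactions=[ReactionRecord(
                                       pt="Rash", outcome=Outcome.FATAL)]))
        classify_drugs(reports, catalogue)
        table = outcome_scan(Dataset(reports), grouping="era")
        old = table.frame[table.frame.exposure == "old"]
        assert old["a"].sum() == 4  # 5 old PTs, one unspecified

    def test_fatal_vs_rest_hand_checked(self, catalogue):
        # 4 PTs: old {fatal, recovered}; new {fatal, fatal}
        reports = [
            make_report(report_id="O", drugs=("Phenobarbital",), reactions=[
                ReactionRecord(pt="A", outcome=Outcome.FATAL),
                ReactionRecord(pt="B", outcome=Outcome.RECOVERED)]),
            make_report(report_id="N", drugs=("Pregabalin",), reactions=[
                ReactionRecord(pt="C", outcome=Outcome.FATAL),
                ReactionRecord(pt="D", outcome=Outcome.FATAL)]),
        ]
        classify_drugs(reports, catalogue)
        table = outcome_scan(Dataset(reports), grouping="era")
        fatal = table.row("old", Outcome.FATAL.value)
        # hand computation: a=1, b=1, c=2, d=0
        assert (fatal["a"], fatal["b"], fatal["c"], fatal["d"]) == (1, 1, 2, 0)
        assert not fatal["countable"]

    def test_empty_stratum_empty_but_no_error(self, catalogue):
        reports = [make_report(report_id="R", drugs=("Phenobarbital",))]
        classify_drugs(reports, catalogue)
        table = outcome_scan(Dataset(reports), grouping="era",
                             strata={"sex": "male"})
        assert (table.frame[["a", "b", "c", "d"]].to_numpy() == 0).all()


class TestSudepScan:
    def test_no_sudep_all_not_countable(self, catalogue):
        reports = [make_report(report_id="A", drugs=("Phenobarbital",)),
                   make_report(report_id="B", drugs=("Pregabalin",))]
        classify_drugs(reports, catalogue)
        table = sudep_scan(Dataset(reports), grouping="era")
        assert not table.frame["countable"].any()
        assert (table.frame["a"] == 0).all()

    def test_substance_a_cells_sum_to_sudep_total(self, catalogue):
        reports = [
            make_report(report_id="A", drugs=("Phenobarbital",),
                        reactions=[ReactionRecord(pt=SUDEP_PT)]),
            make_report(report_id="B", drugs=("Levetiracetam",),
                        reactions=[ReactionRecord(pt=SUDEP_PT),
                                   ReactionRecord(pt="Seizure")]),
            make_report(report_id="C", drugs=("Pregabalin",),
                        reactions=[ReactionRecord(pt="Rash")]),
        ]
        classify_drugs(reports, catalogue)
        table = sudep_scan(Dataset(reports), grouping="substance")
        assert table.frame["a"].sum() == 2

    def test_configurable_terms(self, catalogue):
        reports = [make_report(report_id="A", drugs=("Phenobarbital",),
                               reactions=[ReactionRecord(pt="Sudden death")]),
                   make_report(report_id="B", drugs=("Pregabalin",),
                               reactions=[ReactionRecord(pt="Seizure")])]
        classify_drugs(reports, catalogue)
        ds = Dataset(reports)
        default = sudep_scan(ds, grouping="era")
        custom = sudep_scan(ds, grouping="era", sudep_terms=["Sudden death"])
        assert default.frame["a"].sum() == 0
        assert custom.frame["a"].sum() == 1


class TestTopPt:
    def _dataset(self, catalogue, counts):
        reports = []
        i = 0
        for pt, n in counts.items():
            for _ in range(n):
                reports.append(make_report(
                    report_id=f"R{i}", drugs=("Phenobarbital",),
                    reactions=[ReactionRecord(pt=pt)]))
                i += 1
        classify_drugs(reports, catalogue)
        return Dataset(reports)

    def test_percent_two_decimals(self, catalogue):
        ds = self._dataset(catalogue, {"Seizure": 7, "Rash": 3})
        table = top_pt_table(ds, n=2)
        assert table.iloc[0]["pt"] == "Seizure"
        assert table.iloc[0]["percent"] == 70.0

    def test_ties_broken_alphabetically(self, catalogue):
        ds = self._dataset(catalogue, {"Zoster": 2, "Anaemia": 2, "Rash": 2})
        table = top_pt_table(ds, n=3)
        assert list(table["pt"]) == ["Anaemia", "Rash", "Zoster"]

    def test_n_zero_empty(self, catalogue):
        ds = self._dataset(catalogue, {"Seizure": 2})
        assert top_pt_table(ds, n=0).empty

    def test_n_larger_than_vocabulary(self, catalogue):
        ds = self._dataset(catalogue, {"Seizure": 2, "Rash": 1})
        assert len(top_pt_table(ds, n=50)) == 2


class TestYearlySeries:
    def _dataset(self, catalogue):
        reports = []
        for i, (year, pt) in enumerate([(2012, "Seizure"), (2012, "Rash"),
                                        (2014, "Seizure"), (2014, "Seizure")]):
            reports.append(make_report(report_id=f"R{i}", year=year,
                                       drugs=("Phenobarbital",),
                                       reactions=[ReactionRecord(pt=pt, soc="X")]))
        classify_drugs(reports, catalogue)
        return Dataset(reports)

    def test_zero_fill_complete_grid(self, catalogue):
        series = yearly_soc_series(self._dataset(catalogue))
        assert set(series["year"]) == {2012, 2013, 2014}
        assert series[series.year == 2013]["count"].sum() == 0

    def test_yearly_totals_conserved(self, catalogue):
        ds = self._dataset(catalogue)
        series = yearly_soc_series(ds)
        assert series["count"].sum() == len(ds.pt_frame)

    def test_column_sums_match_soc_scan_totals(self, scaled_replica):
        series = yearly_soc_series(scaled_replica)
        scan = soc_scan(scaled_replica, grouping="era")
        per_soc_scan = scan.frame[scan.frame.exposure == "old"].set_index("event")
        for soc, group in series.groupby("soc"):
            row = per_soc_scan.loc[soc]
            assert group["count"].sum() == row["a"] + row["c"]

    def test_empty_dataset(self, catalogue):
        assert yearly_soc_series(Dataset([])).empty


class TestStrata:
    def test_parse_mini_language(self):
        strata = parse_strata("sex=female,age=18-64,year=2012:2021")
        assert strata == {"sex": "female", "age": "18-64", "year": (2012, 2021)}

    def test_parse_single_year(self):
        assert parse_strata("year=2015") == {"year": (2015, 2015)}

    def test_parse_rejects_unknown_key(self):
        with pytest.raises(ValueError, match="unknown stratum"):
            parse_strata("planet=mars")

    def test_parse_rejects_bad_pair(self):
        with pytest.raises(ValueError, match="key=value"):
            parse_strata("justakey")

    def test_stratified_cells_sum_to_unstratified(self, catalogue):
        reports = []
        for i in range(30):
            sex = Sex.MALE if i % 3 == 0 else (Sex.FEMALE if i % 3 == 1
                                               else Sex.UNSPECIFIED)
            drug = "Phenobarbital" if i % 2 else "Pregabalin"
            reports.append(make_report(report_id=f"R{i}", sex=sex, drugs=(drug,),
                                       reactions=[ReactionRecord(pt=f"PT{i % 4}",
                                                                 soc="S")]))
        classify_drugs(reports, catalogue)
        ds = Dataset(reports)
        full = soc_scan(ds, grouping="era").frame.set_index(["exposure", "event"])
        parts = [soc_scan(ds, grouping="era", strata={"sex": s}).frame
                 .set_index(["exposure", "event"])
                 for s in ("male", "female", "unspecified")]
        summed = sum(p[["a", "b", "c", "d"]] for p in parts)
        pd.testing.assert_frame_equal(summed, full[["a", "b", "c", "d"]])


class TestBuildTable:
    def test_masks(self, catalogue):
        reports = [make_report(report_id="A", drugs=("Phenobarbital",),
                               reactions=[ReactionRecord(pt="Seizure", soc="N"),
                                          ReactionRecord(pt="Rash", soc="S")]),
                   make_report(report_id="B", drugs=("Pregabalin",),
                               reactions=[ReactionRecord(pt="Seizure", soc="N")])]
        classify_drugs(reports, catalogue)
        frame = Dataset(reports).pt_frame
        table = build_table(frame,
                            (frame["era"].astype(str) == "old").to_numpy(),
                            (frame["soc"].astype(str) == "N").to_numpy())
        assert (table.a, table.b, table.c, table.d) == (1, 1, 1, 0)
        assert table.n == len(frame)

    def test_always_false_exposure(self, catalogue):
        reports = [make_report(report_id="A", drugs=("Phenobarbital",))]
        classify_drugs(reports, catalogue)
        frame = Dataset(reports).pt_frame
        table = build_table(frame, np.zeros(len(frame), bool),
                            np.ones(len(frame), bool))
        assert table.a == 0 and table.b == 0

    def test_swap_symmetry(self, catalogue):
        reports = [make_report(report_id="A", drugs=("Phenobarbital",),
                               reactions=[ReactionRecord(pt="X", soc="N")]),
                   make_report(report_id="B", drugs=("Pregabalin",),
                               reactions=[ReactionRecord(pt="Y", soc="S")])]
        classify_drugs(reports, catalogue)
        frame = Dataset(reports).pt_frame
        exposed = (frame["era"].astype(str) == "old").to_numpy()
        event = (frame["soc"].astype(str) == "N").to_numpy()
        t = build_table(frame, exposed, event)
        s = build_table(frame, ~exposed, event)
        assert (s.a, s.b, s.c, s.d) == (t.c, t.d, t.a, t.b)


class TestDemographics:
    def test_matches_direct_chi_square(self, catalogue):
        reports = []
        for i in range(60):
            sex = [Sex.MALE, Sex.FEMALE, Sex.UNSPECIFIED][i % 3]
            drug = "Phenobarbital" if i % 2 else "Pregabalin"
            pt = SUDEP_PT if i % 10 == 0 else "Seizure"
            reports.append(make_report(report_id=f"R{i}", sex=sex, drugs=(drug,),
                                       reactions=[ReactionRecord(pt=pt)]))
        classify_drugs(reports, catalogue)
        ds = Dataset(reports)
        results = {r["test"]: r for r in demographic_tests(ds)}

        frame = ds.pt_frame
        cells = [[int(((frame.era.astype(str) == era)
                       & (frame.sex.astype(str) == sx)).sum())
                  for sx in ("male", "female", "unspecified")]
                 for era in ("old", "new")]
        from pvsignal import chi_square_rxc
        expected = chi_square_rxc(cells)
        assert results["era_by_sex_pt"]["chi2"] == pytest.approx(expected[0])
        assert results["era_by_sex_pt"]["dof"] == 2

        assert results["sudep_by_sex_report"]["dof"] == 1
        assert results["sudep_by_sex_report"]["n"] == 40  # unspecified excluded

    def test_zero_margin_skipped_with_reason(self, catalogue):
        reports = [make_report(report_id="A", sex=Sex.MALE, drugs=("Phenobarbital",))]
        classify_drugs(reports, catalogue)
        results = {r["test"]: r for r in demographic_tests(Dataset(reports))}
        assert results["era_by_sex_pt"]["skipped"]
        assert "reason" in results["era_by_sex_pt"]

    def test_null_permutation_p_uniform(self, catalogue):
        """Permuting sex labels under the null gives p-values consistent
        with uniformity (KS sanity at the 1% level)."""
        rng = np.random.default_rng(42)
        from scipy import stats as sps

        n = 400
        eras = np.array(["old", "new"])[rng.integers(0, 2, n)]
        sexes = np.array(["male", "female"])[rng.integers(0, 2, n)]
        pvals = []
        for _ in range(200):
            permuted = rng.permutation(sexes)
            cells = [[int(((eras == e) & (permuted == s)).sum())
                      for s in ("male", "female")] for e in ("old", "new")]
            from pvsignal import chi_square_rxc
            _, _, p = chi_square_rxc(cells)
            pvals.append(p)
        ks = sps.kstest(pvals, "uniform")
        assert ks.pvalue > 0.01


class TestAttribution:
    def test_all_suspected_vs_first_listed(self, catalogue):
        reports = [make_report(report_id="A",
                               drugs=("Phenobarbital", "Pregabalin"),
                               reactions=[ReactionRecord(pt="Seizure")])]
        classify_drugs(reports, catalogue)
        assert len(Dataset(reports, attribution="all_suspected").pt_frame) == 2
        assert len(Dataset(reports, attribution="first_listed").pt_frame) == 1

    def test_unknown_attribution_rejected(self):
        with pytest.raises(ValueError):
            Dataset([], attribution="whatever")


def test_scan_conservation(scaled_replica):
    """Exposure + comparator event counts equal the dataset total for
    each event level."""
    frame = scaled_replica.pt_frame
    scan = soc_scan(scaled_replica, grouping="era")
    totals = frame[frame.era.astype(str) != "unclassified"]["soc"].astype(
        str).value_counts()
    old = scan.frame[scan.frame.exposure == "old"].set_index("event")
    for soc, count in totals.items():
        assert old.loc[soc, "a"] + old.loc[soc, "c"] == count
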