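import io

import numpy as np
import pandas as pd
import pytest

from care_index.data_model import (
    BiomarkerSpec,
    CognitiveDomainMap,
    DegenerateReferenceError,
    SchemaError,
    ValidationError,
    canonical_panel,
    change_scores,
    composite_z,
    read_cohort,
    shared_panel,
    write_cohort,
)

from conftest import make_table


PANEL2 = [BiomarkerSpec("MMSE", "decrease"), BiomarkerSpec("AVLT", "decrease")]


def cohort_csv(rows, header="subject_id,group,cohort,MMSE,AVLT"):
    return io.StringIO("\n".join([header] + rows))


class TestReadCohort:
    def test_group_counts_and_missingness(self):
        rows = [f"A{i:03d},{'P-MCI' if i < 12 else 'N-MCI'},ADNI,27,{30 + i}" for i in range(46)]
        table = read_cohort(cohort_csv(rows), PANEL2)
        assert table.n_subjects == 46
        assert table.group_counts == {"N-MCI": 34, "P-MCI": 12}

    def test_header_only_file_gives_empty_cohort(self):
        table = read_cohort(cohort_csv([]), PANEL2)
        assert table.n_subjects == 0

    def test_all_na_column_preserved_as_missing(self):
        rows = [f"A{i},N-MCI,ADNI,28,NA" for i in range(5)]
        table = read_cohort(cohort_csv(rows), PANEL2)
        assert table.data["AVLT"].isna().all()
        assert not table.data["MMSE"].isna().any()

    def test_na_tokens_case_insensitive_and_empty(self):
        rows = ["A1,N-MCI,ADNI,na,", "A2,N-MCI,ADNI,Na,25"]
        table = read_cohort(cohort_csv(rows), PANEL2)
        assert table.data["MMSE"].isna().all()
        assert table.data["AVLT"].isna().tolist() == [True, False]

    def test_missing_required_column_names_it(self):
        with pytest.raises(SchemaError, match="group"):
            read_cohort(cohort_csv(["A1,ADNI,28,30"], header="subject_id,cohort,MMSE,AVLT"), PANEL2)

    def test_missing_biomarker_column_names_it(self):
        with pytest.raises(SchemaError, match="AVLT"):
            read_cohort(cohort_csv(["A1,N-MCI,ADNI,28"], header="subject_id,group,cohort,MMSE"), PANEL2)

    def test_duplicate_subject_id_rejected(self):
        rows = ["A1,N-MCI,ADNI,28,30", "A1,P-MCI,ADNI,25,20"]
        with pytest.raises(ValidationError, match="A1"):
            read_cohort(cohort_csv(rows), PANEL2)

    def test_unparseable_group_rows_dropped_and_counted(self):
        rows = ["A1,N-MCI,ADNI,28,30", "A2,???,ADNI,25,20", "A3,P-MCI,ADNI,24,18"]
        table = read_cohort(cohort_csv(rows), PANEL2)
        assert table.n_subjects == 2
        assert table.n_rejected_rows == 1

    def test_round_trip_preserves_values_and_missingness(self, tmp_path):
        rows = ["A1,N-MCI,ADNI,28.123456789,NA", "A2,P-MCI,ADNI,NA,19.5"]
        table = read_cohort(cohort_csv(rows), PANEL2)
        path = tmp_path / "cohort.csv"
        write_cohort(table, path)
        again = read_cohort(path, PANEL2)
        pd.testing.assert_frame_equal(table.data, again.data)


class TestPanel:
    def test_canonical_panel_has_ten_unique_directed_biomarkers(self):
        panel = canonical_panel()
        assert len(panel) == 10
        assert len({b.name for b in panel}) == 10
        assert {b.direction for b in panel} == {"increase", "decrease"}

    def test_invalid_direction_rejected(self):
        with pytest.raises(ValueError):
            BiomarkerSpec("x", "sideways")

    def test_shared_panel_preserves_first_cohort_order(self):
        full = canonical_panel()
        reduced = [b for b in full if b.name not in ("ABETA", "PTAU", "ADAS")]
        a = make_table(full, [[0.0] * 10])
        b = make_table(reduced, [[0.0] * 7])
        names = shared_panel(a, b)
        assert names == [x.name for x in full if x.name not in ("ABETA", "PTAU", "ADAS")]


class TestCompositeZ:
    domain_map = CognitiveDomainMap({"memory": ["t1", "t2"], "speed": ["t3"]})

    def build(self, rows):
        panel = []
        n = len(rows)
        data = pd.DataFrame(
            {
                "subject_id": [f"S{i}" for i in range(n)],
                "group": ["N-MCI"] * n,
                "cohort": "X",
            }
        )
        for j, t in enumerate(["t1", "t2", "t3"]):
            data[t] = [r[j] for r in rows]
        from care_index.data_model import CohortTable

        return CohortTable(cohort_id="X", data=data, panel=panel)

    def test_reference_mean_scores_zero(self):
        table = self.build([[10.0, 20.0, 30.0], [14.0, 24.0, 34.0]])
        ref = {"t1": (10.0, 2.0), "t2": (20.0, 4.0), "t3": (30.0, 1.0)}
        z = composite_z(table, self.domain_map, reference=ref)
        assert z.loc["S0"].tolist() == [0.0, 0.0]

    def test_opposite_z_scores_average_to_zero(self):
        table = self.build([[12.0, 16.0, 30.0]])
        ref = {"t1": (10.0, 2.0), "t2": (20.0, 4.0), "t3": (30.0, 1.0)}
        z = composite_z(table, self.domain_map, reference=ref)
        assert z.loc["S0", "memory"] == pytest.approx(0.0)

    def test_hand_computed_three_test_domain(self):
        dm = CognitiveDomainMap({"d": ["t1", "t2", "t3"]})
        table = self.build([[12.0, 18.0, 31.5]])
        ref = {"t1": (10.0, 2.0), "t2": (20.0, 4.0), "t3": (30.0, 1.0)}
        # z = (+1, -0.5, +1.5) -> mean 2/3
        z = composite_z(table, dm, reference=ref)
        assert z.loc["S0", "d"] == pytest.approx((1.0 - 0.5 + 1.5) / 3)

    def test_higher_worse_tests_are_sign_flipped(self):
        dm = CognitiveDomainMap({"d": ["t1"]})
        table = self.build([[12.0, 0.0, 0.0]])
        ref = {"t1": (10.0, 2.0), "t2": (1.0, 1.0), "t3": (1.0, 1.0)}
        z = composite_z(table, dm, reference=ref, higher_worse=["t1"])
        assert z.loc["S0", "d"] == pytest.approx(-1.0)

    def test_order_of_tests_within_domain_is_irrelevant(self):
        table = self.build([[12.0, 18.0, 30.0], [8.0, 22.0, 29.0]])
        ref = {"t1": (10.0, 2.0), "t2": (20.0, 4.0), "t3": (30.0, 1.0)}
        a = composite_z(table, CognitiveDomainMap({"d": ["t1", "t2"]}), reference=ref)
        b = composite_z(table, CognitiveDomainMap({"d": ["t2", "t1"]}), reference=ref)
        pd.testing.assert_frame_equal(a, b)

    def test_subject_with_no_available_test_is_missing(self):
        table = self.build([[np.nan, np.nan, 31.0]])
        ref = {"t1": (10.0, 2.0), "t2": (20.0, 4.0), "t3": (30.0, 1.0)}
        z = composite_z(table, self.domain_map, reference=ref)
        assert np.isnan(z.loc["S0", "memory"])
        assert z.loc["S0", "speed"] == pytest.approx(1.0)

    def test_degenerate_reference_sd_raises(self):
        table = self.build([[10.0, 20.0, 30.0]])
        ref = {"t1": (10.0, 0.0), "t2": (20.0, 4.0), "t3": (30.0, 1.0)}
        with pytest.raises(DegenerateReferenceError):
            composite_z(table, self.domain_map, reference=ref)

    def test_duplicate_test_across_domains_rejected(self):
        with pytest.raises(ValidationError):
            CognitiveDomainMap({"a": ["t1"], "b": ["t1"]})


class TestChangeScores:
    def test_identical_waves_give_zero_deltas(self):
        table = make_table(PANEL2, [[28.0, 40.0], [25.0, 33.0]])
        delta, dropped = change_scores(table, table, ["MMSE", "AVLT"])
        assert dropped == 0
        assert (delta == 0).all().all()

    def test_simple_arithmetic(self):
        base = make_table(PANEL2, [[28.0, 40.0]])
        fup = make_table(PANEL2, [[24.0, 35.0]])
        delta, _ = change_scores(base, fup, ["MMSE"])
        assert delta.loc["S000", "MMSE"] == -4.0

    def test_nonoverlapping_subjects_dropped_and_counted(self):
        base = make_table(PANEL2, [[28.0, 40.0]] * 56)
        fup_full = make_table(PANEL2, [[24.0, 35.0]] * 44)
        delta, dropped = change_scores(base, fup_full, ["MMSE"])
        assert len(delta) == 44
        assert dropped == 12

    def test_disjoint_waves_raise(self):
        base = make_table(PANEL2, [[28.0, 40.0]], cohort_id="A")
        fup = make_table(PANEL2, [[24.0, 35.0]], cohort_id="B")
        fup.data["subject_id"] = ["ZZZ"]
        with pytest.raises(ValidationError):
            change_scores(base, fup, ["MMSE"])
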