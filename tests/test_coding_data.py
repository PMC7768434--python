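"""Data model, CSV I/O and the packaged published-marginal fixture."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import qualnet as qn
from qualnet.errors import FormatError, ValidationError

from conftest import make_incidence

# hand-summed from the published per-code counts before implementation
TABLE1_TOTAL_LINKS = 220
TABLE1_PATIENT_TOTALS = {"1": 0, "2": 2, "3": 2, "4": 1, "5": 7, "6": 5, "7": 4}
TABLE1_EXPERT_TOTALS = {"1": 27, "2": 29, "3": 33, "4": 28, "5": 20, "6": 22, "7": 40}


class TestCodebook:
    def test_minimal_codebook(self, tmp_path):
        p = tmp_path / "cb.csv"
        p.write_text("theme_id,code_id,label\n1,1.1,only code\n")
        cb = qn.load_codebook(p)
        assert len(cb.themes) == 1 and len(cb.codes) == 1

    def test_prefix_rule_violation(self, tmp_path):
        p = tmp_path / "cb.csv"
        p.write_text("theme_id,code_id,label\n1,2.1,misfiled\n")
        with pytest.raises(ValidationError, match="2.1"):
            qn.load_codebook(p)

    def test_missing_column_is_format_error(self, tmp_path):
        p = tmp_path / "cb.csv"
        p.write_text("theme_id,label\n1,x\n")
        with pytest.raises(FormatError):
            qn.load_codebook(p)

    def test_duplicate_code_id_rejected(self):
        with pytest.raises(ValidationError):
            qn.Codebook(
                themes=(("1", "t"),),
                codes=(("1.1", "1", "a"), ("1.1", "1", "b")),
            )


class TestRoster:
    def test_patient_subgroup_must_be_none(self):
        with pytest.raises(ValidationError):
            qn.Interviewee("P_1", qn.Role.patient, qn.Subgroup.basic_scientist)
        with pytest.raises(ValidationError):
            qn.Interviewee("E_1", qn.Role.expert, qn.Subgroup.none)


class TestResponses:
    def test_duplicates_collapse_with_warning(self, tiny_codebook, tiny_roster,
                                              tmp_path, caplog):
        p = tmp_path / "r.csv"
        p.write_text(
            "interviewee_id,code_id,concern_label\n"
            "E_1,1.1,yes\nE_1,1.1,yes\nE_2,1.2,no\n"
        )
        with caplog.at_level("WARNING"):
            table = qn.load_responses(p, tiny_codebook, tiny_roster)
        assert len(table) == 2
        assert "duplicate" in caplog.text

    def test_conflicting_labels_rejected(self, tiny_codebook, tiny_roster, tmp_path):
        p = tmp_path / "r.csv"
        p.write_text(
            "interviewee_id,code_id,concern_label\nE_1,1.1,yes\nE_1,1.1,no\n"
        )
        with pytest.raises(ValidationError, match="conflicting"):
            qn.load_responses(p, tiny_codebook, tiny_roster)

    def test_empty_file_with_header(self, tiny_codebook, tiny_roster, tmp_path):
        p = tmp_path / "r.csv"
        p.write_text("interviewee_id,code_id,concern_label\n")
        assert len(qn.load_responses(p, tiny_codebook, tiny_roster)) == 0

    def test_unknown_ids_named_in_error(self, tiny_codebook, tiny_roster, tmp_path):
        p = tmp_path / "r.csv"
        p.write_text("interviewee_id,code_id\nE_9,1.1\n")
        with pytest.raises(ValidationError, match="E_9"):
            qn.load_responses(p, tiny_codebook, tiny_roster)


class TestIncidence:
    def test_sum_equals_record_count(self, tiny_codebook, tiny_roster):
        table = qn.ResponseTable(
            records=(
                qn.ResponseRecord("E_1", "1.1"),
                qn.ResponseRecord("E_2", "2.1"),
            )
        )
        inc = qn.build_incidence(table, tiny_codebook, tiny_roster)
        assert inc.B.sum() == len(table)
        assert inc.B.shape == (3, 3)

    def test_empty_and_saturated(self, tiny_codebook, tiny_roster):
        empty = qn.build_incidence(qn.ResponseTable(()), tiny_codebook, tiny_roster)
        assert empty.B.sum() == 0 and empty.B.shape == (3, 3)
        full = qn.ResponseTable(
            records=tuple(
                qn.ResponseRecord(iv.interviewee_id, cid)
                for cid in tiny_codebook.code_ids
                for iv in tiny_roster
            )
        )
        inc = qn.build_incidence(full, tiny_codebook, tiny_roster)
        assert inc.B.sum() == inc.M * inc.N

    def test_nonbinary_entries_rejected(self):
        with pytest.raises(ValidationError):
            make_incidence([[0, 2]])


class TestMarginalSummary:
    def test_counts_split_by_role(self, tiny_codebook, tiny_roster):
        inc = make_incidence(
            [[1, 1, 0], [0, 0, 1], [1, 0, 0]],
            codes=tiny_codebook.code_ids,
            ivs=[iv.interviewee_id for iv in tiny_roster],
        )
        ms = qn.marginal_summary(inc, tiny_roster, tiny_codebook)
        assert ms.per_code["1.1"] == (1, 1)
        assert ms.per_code["1.2"] == (0, 1)
        assert ms.per_theme["1"] == (1, 2)
        assert ms.total_links == 4

    def test_row_sum_identity(self, tiny_codebook, tiny_roster):
        rng = np.random.default_rng(5)
        inc = make_incidence(
            rng.integers(0, 2, (3, 3)),
            codes=tiny_codebook.code_ids,
            ivs=[iv.interviewee_id for iv in tiny_roster],
        )
        ms = qn.marginal_summary(inc, tiny_roster, tiny_codebook)
        for i, cid in enumerate(inc.code_index):
            assert sum(ms.per_code[cid]) == inc.B[i].sum()

    def test_all_zero(self, tiny_codebook, tiny_roster):
        inc = make_incidence(
            np.zeros((3, 3), dtype=int),
            codes=tiny_codebook.code_ids,
            ivs=[iv.interviewee_id for iv in tiny_roster],
        )
        ms = qn.marginal_summary(inc, tiny_roster, tiny_codebook)
        assert ms.total_links == 0
        assert all(v == (0, 0) for v in ms.per_code.values())


class TestTable1Fixture:
    def test_shape_and_named_entries(self, table1):
        cb, ms = table1
        assert len(cb.themes) == 7
        assert len(cb.codes) == 43
        assert ms.per_code["2.1"] == (0, 1)
        assert ms.per_code["7.8"] == (0, 11)
        assert ms.per_theme["7"] == (4, 40)

    def test_totals_recompute_from_per_code(self, table1):
        cb, ms = table1
        assert ms.total_links == TABLE1_TOTAL_LINKS
        for tid in cb.theme_ids:
            members = cb.codes_of_theme(tid)
            assert ms.per_theme[tid] == (
                sum(ms.per_code[c][0] for c in members),
                sum(ms.per_code[c][1] for c in members),
            )
            assert ms.per_theme[tid] == (
                TABLE1_PATIENT_TOTALS[tid],
                TABLE1_EXPERT_TOTALS[tid],
            )

    def test_roster_split(self, roster16):
        assert len(roster16) == 16
        assert sum(iv.role is qn.Role.patient for iv in roster16) == 2
        assert (
            sum(iv.subgroup is qn.Subgroup.clinician_health_system for iv in roster16)
            == 10
        )
        assert sum(iv.subgroup is qn.Subgroup.basic_scientist for iv in roster16) == 4


class TestIncidenceIO:
    def test_round_trip(self, tmp_path):
        rng = np.random.default_rng(11)
        inc = make_incidence(rng.integers(0, 2, (5, 4)))
        p = tmp_path / "B.csv"
        qn.write_incidence(inc, p)
        back = qn.read_incidence(p)
        assert np.array_equal(back.B, inc.B)
        assert back.code_index == inc.code_index
        assert back.interviewee_index == inc.interviewee_index

    def test_empty_matrix_rejected(self, tmp_path):
        p = tmp_path / "B.csv"
        p.write_text("code_id\n")
        with pytest.raises(FormatError):
            qn.read_incidence(p)

    def test_nonbinary_cell_rejected(self, tmp_path):
        p = tmp_path / "B.csv"
        p.write_text("code_id,v0,v1\nc0,0,2\n")
        with pytest.raises(FormatError):
            qn.read_incidence(p)


@settings(max_examples=25, deadline=None, derandomize=True)
@given(
    data=st.data(),
    M=st.integers(1, 6),
    N=st.integers(1, 6),
)
def test_io_round_trips_on_random_valid_inputs(tmp_path_factory, data, M, N):
    """Codebook, responses and incidence all survive write -> read bit-exactly."""
    tmp = tmp_path_factory.mktemp("io")
    codes = tuple((f"1.{i}", "1", f"code {i}") for i in range(1, M + 1))
    cb = qn.Codebook(themes=(("1", "t1"),), codes=codes)
    roster = [qn.Interviewee("P_1", qn.Role.patient)] + [
        qn.Interviewee(f"E_{j}", qn.Role.expert, qn.Subgroup.clinician_health_system)
        for j in range(1, N)
    ]
    records = []
    for cid, _, _ in codes:
        for iv in roster:
            if data.draw(st.booleans()):
                label = data.draw(st.sampled_from(list(qn.ConcernLabel)))
                records.append(qn.ResponseRecord(iv.interviewee_id, cid, label))
    table = qn.ResponseTable(records=tuple(records))

    cb_path = tmp / "cb.csv"
    qn.coding_data.write_codebook(cb, cb_path)
    assert qn.load_codebook(cb_path).codes == cb.codes

    ro_path = tmp / "roster.csv"
    qn.coding_data.write_roster(roster, ro_path)
    assert qn.coding_data.load_roster(ro_path) == roster

    re_path = tmp / "resp.csv"
    qn.coding_data.write_responses(table, re_path)
    assert qn.load_responses(re_path, cb, roster).records == table.records

    inc = qn.build_incidence(table, cb, roster)
    b_path = tmp / "B.csv"
    qn.write_incidence(inc, b_path)
    back = qn.read_incidence(b_path)
    assert np.array_equal(back.B, inc.B)


def test_round_half_away():
    assert qn.round_half_away(13.75) == 14
    assert qn.round_half_away(5.12) == 5
    assert qn.round_half_away(6.5) == 7
    assert qn.round_half_away(-1.5) == -2
    assert qn.round_half_away(0.0) == 0
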