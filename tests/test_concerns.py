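"""Dichotomization, the yes/no multigraph and the controversy partition."""

import numpy as np
import pytest

import qualnet as qn
from qualnet.concerns import NO_NODE, YES_NODE
from qualnet.errors import ValidationError


def _table(rows):
    return qn.ResponseTable(
        records=tuple(qn.ResponseRecord(i, c, qn.ConcernLabel(l)) for i, c, l in rows)
    )


class TestClassify:
    def test_keeps_yes_no_drops_rest(self):
        table = _table(
            [
                ("E_1", "1.1", "yes"),
                ("E_2", "1.1", "no"),
                ("E_3", "1.1", "unclassifiable"),
                ("E_1", "1.2", "absent"),
            ]
        )
        cls = qn.classify_responses(table)
        assert cls.labels == {
            ("1.1", "E_1"): qn.ConcernLabel.yes,
            ("1.1", "E_2"): qn.ConcernLabel.no,
        }
        assert cls.excluded_responses == 2
        assert cls.excluded_codes == {"1.2"}

    def test_all_unclassifiable(self):
        table = _table([("E_1", "1.1", "unclassifiable")])
        cls = qn.classify_responses(table)
        assert not cls.labels
        assert cls.excluded_codes == {"1.1"}

    def test_conservation(self):
        rng = np.random.default_rng(3)
        labels = rng.choice(["yes", "no", "unclassifiable", "absent"], 60)
        rows = [(f"E_{k}", f"1.{1 + k % 5}", l) for k, l in enumerate(labels)]
        table = _table(rows)
        cls = qn.classify_responses(table)
        assert len(cls.labels) + cls.excluded_responses == len(table)


class TestSyntheticCorpusClassification:
    """The packaged marginal-consistent corpus with synthetic concern splits."""

    def test_counts_match_reconstruction_targets(self):
        cb, _, responses = qn.table1_synthetic_responses(seed=5)
        cls = qn.classify_responses(responses)
        assert len(cls.excluded_codes) == 15  # 43 codes, 28 dichotomizable
        # 22 responses dropped within codes that kept at least one label
        kept = {c for c, _ in cls.labels}
        dropped_in_kept = sum(
            1
            for r in responses.records
            if r.code_id in kept
            and r.concern_label not in (qn.ConcernLabel.yes, qn.ConcernLabel.no)
        )
        assert dropped_in_kept == 22

    def test_incidence_rows_match_published_splits(self):
        cb, _, responses = qn.table1_synthetic_responses(seed=5)
        ci = qn.build_concern_incidence(qn.classify_responses(responses), cb)
        assert ci.M == 28
        row = dict(zip(ci.code_index, map(tuple, ci.Bp)))
        assert row["1.1"] == (4, 1)  # four of five voiced the concern
        assert row["6.4"] == (5, 4)  # five of nine worried, four did not
        assert ci.Bp.sum() == 137

    def test_partition_matches_published_counts(self):
        cb, _, responses = qn.table1_synthetic_responses(seed=5)
        ci = qn.build_concern_incidence(qn.classify_responses(responses), cb)
        rep = qn.controversy_report(ci)
        assert rep.no_concern == {"1.6", "2.2", "6.3", "6.5", "7.6"}
        assert len(rep.controversial) == 11
        assert len(rep.all_concern) == 12


class TestConcernIncidence:
    def test_simple_counting(self, tiny_codebook):
        table = _table(
            [("E_1", "1.1", "yes"), ("E_2", "1.1", "yes"), ("E_3", "1.1", "no")]
        )
        ci = qn.build_concern_incidence(qn.classify_responses(table), tiny_codebook)
        assert ci.code_index == ("1.1",)
        assert tuple(ci.Bp[0]) == (2, 1)

    def test_rows_follow_codebook_order(self, tiny_codebook):
        table = _table([("E_1", "2.1", "no"), ("E_1", "1.1", "yes")])
        ci = qn.build_concern_incidence(qn.classify_responses(table), tiny_codebook)
        assert ci.code_index == ("1.1", "2.1")

    def test_empty_classification_rejected(self, tiny_codebook):
        cls = qn.classify_responses(_table([("E_1", "1.1", "absent")]))
        with pytest.raises(ValidationError):
            qn.build_concern_incidence(cls, tiny_codebook)


class TestConcernNetwork:
    def test_single_code_block_structure(self):
        ci = qn.ConcernIncidence(Bp=np.array([[2, 1]]), code_index=("1.1",))
        mg = qn.build_concern_network(ci)
        expected = np.array([[0, 2, 1], [2, 0, 0], [1, 0, 0]])
        assert np.array_equal(mg.Ap, expected)
        assert mg.node_order == ("1.1", YES_NODE, NO_NODE)

    def test_shape_and_weight_conservation(self):
        rng = np.random.default_rng(7)
        Bp = rng.integers(0, 5, (28, 2))
        Bp[Bp.sum(axis=1) == 0, 0] = 1
        ci = qn.ConcernIncidence(
            Bp=Bp, code_index=tuple(f"1.{i}" for i in range(1, 29))
        )
        mg = qn.build_concern_network(ci)
        assert mg.Ap.shape == (30, 30)
        assert np.array_equal(mg.Ap, mg.Ap.T)
        assert not mg.Ap[:28, :28].any() and not mg.Ap[28:, 28:].any()
        assert mg.Ap.sum() // 2 == Bp.sum()

    def test_export_round_trip(self, tmp_path):
        import networkx as nx

        ci = qn.ConcernIncidence(
            Bp=np.array([[2, 1], [0, 3]]), code_index=("1.1", "1.2")
        )
        mg = qn.build_concern_network(ci)
        p = tmp_path / "c.gexf"
        qn.export_concern_graph(mg, "gexf", p)
        back = nx.read_gexf(p)
        assert back.nodes[YES_NODE]["answer"] == "yes"
        assert back["1.1"][YES_NODE]["weight"] == 2
        assert back["1.2"][NO_NODE]["weight"] == 3
        with pytest.raises(ValidationError):
            qn.export_concern_graph(mg, "pdf", tmp_path / "c.pdf")


class TestControversy:
    def test_sign_pattern_partition(self):
        ci = qn.ConcernIncidence(
            Bp=np.array([[0, 3], [2, 1], [4, 0]]),
            code_index=("1.1", "1.2", "1.3"),
        )
        rep = qn.controversy_report(ci)
        assert rep.no_concern == {"1.1"}
        assert rep.controversial == {"1.2"}
        assert rep.all_concern == {"1.3"}

    def test_all_rows_pure_yes(self):
        ci = qn.ConcernIncidence(
            Bp=np.array([[3, 0], [1, 0]]), code_index=("1.1", "1.2")
        )
        rep = qn.controversy_report(ci)
        assert not rep.no_concern and not rep.controversial
        assert rep.all_concern == {"1.1", "1.2"}

    def test_partition_is_exact_cover(self):
        rng = np.random.default_rng(19)
        Bp = rng.integers(0, 4, (20, 2))
        Bp[Bp.sum(axis=1) == 0, 1] = 2
        ci = qn.ConcernIncidence(
            Bp=Bp, code_index=tuple(f"1.{i}" for i in range(1, 21))
        )
        rep = qn.controversy_report(ci)
        sets = [rep.no_concern, rep.all_concern, rep.controversial]
        assert sum(len(s) for s in sets) == 20
        assert frozenset().union(*sets) == set(ci.code_index)

    def test_yes_no_relabeling_antisymmetry(self):
        """Swapping every yes and no swaps B' columns and the outer categories."""
        rng = np.random.default_rng(11)
        rows = [
            (f"E_{k}", f"1.{1 + k % 6}", rng.choice(["yes", "no", "unclassifiable"]))
            for k in range(40)
        ]
        cb = qn.Codebook(
            themes=(("1", "t"),),
            codes=tuple((f"1.{i}", "1", f"c{i}") for i in range(1, 7)),
        )
        swap = {"yes": "no", "no": "yes", "unclassifiable": "unclassifiable"}
        ci = qn.build_concern_incidence(qn.classify_responses(_table(rows)), cb)
        ci_sw = qn.build_concern_incidence(
            qn.classify_responses(_table([(i, c, swap[l]) for i, c, l in rows])), cb
        )
        assert ci.code_index == ci_sw.code_index
        assert np.array_equal(ci.Bp[:, ::-1], ci_sw.Bp)
        rep, rep_sw = qn.controversy_report(ci), qn.controversy_report(ci_sw)
        assert rep.no_concern == rep_sw.all_concern
        assert rep.all_concern == rep_sw.no_concern
        assert rep.controversial == rep_sw.controversial
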