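"""Consensus scoring, criteria, enrichment, and activity calls."""

import numpy as np
import pytest

from targetfish.consensus import (
    ConsensusError,
    assemble_predicted_space,
    build_selection_report,
    classify_assay_results,
    confirmed_target_count,
    criterion_consistency,
    criterion_panel_hits,
    criterion_ranking,
    enrichment,
    subtract_known,
)
from targetfish.datasets import dhc_panel_inhibition
from targetfish.external import PredictionMatrix
from targetfish.mining import InteractionRecord, KnownSpace


def _bool_matrix(name, pairs, anchor=False, scores=None):
    entries = {p: (scores[p] if scores else 1.0) for p in pairs}
    return PredictionMatrix(name, entries, "boolean", is_anchor=anchor, rank_semantics="higher_better")


class TestAssemble:
    def test_anchor_plus_two_servers_gives_cs_three(self):
        pair = ("cpd1", "PROT_A")
        mats = [
            _bool_matrix("ANCHOR", [pair], anchor=True),
            _bool_matrix("S1", [pair]),
            _bool_matrix("S2", [pair]),
            _bool_matrix("S3", []),
        ]
        (rec,) = assemble_predicted_space(mats)
        assert rec.cs == 3
        assert rec.anchor_hit
        assert rec.eligible

    def test_single_server_pair_not_eligible(self):
        mats = [
            _bool_matrix("ANCHOR", [], anchor=True),
            _bool_matrix("S1", [("c", "T")]),
        ]
        (rec,) = assemble_predicted_space(mats)
        assert rec.cs == 1
        assert not rec.anchor_hit
        assert not rec.eligible

    def test_cs_equals_brute_force_per_pair_method_count(self):
        rng = np.random.default_rng(0)
        pairs = [(f"c{i}", f"T{j}") for i in range(3) for j in range(2)]
        picks = {
            name: [p for p in pairs if rng.random() < 0.6]
            for name in ("ANCHOR", "M1", "M2", "M3")
        }
        mats = [_bool_matrix(n, ps, anchor=(n == "ANCHOR")) for n, ps in picks.items()]
        records = assemble_predicted_space(mats)
        for rec in records:
            expected = sum((rec.compound_id, rec.target_id) in ps for ps in picks.values())
            assert rec.cs == expected

    def test_cs_conservation(self):
        rng = np.random.default_rng(1)
        pairs = [(f"c{i}", f"T{j}") for i in range(4) for j in range(3)]
        mats = [
            _bool_matrix(n, [p for p in pairs if rng.random() < 0.5], anchor=(n == "A"))
            for n in ("A", "B", "C")
        ]
        records = assemble_predicted_space(mats)
        assert sum(r.cs for r in records) == sum(m.n_entries for m in mats)

    def test_zero_or_two_anchors_fatal(self):
        with pytest.raises(ConsensusError):
            assemble_predicted_space([_bool_matrix("M", [("c", "T")])])
        with pytest.raises(ConsensusError):
            assemble_predicted_space(
                [_bool_matrix("A", [], anchor=True), _bool_matrix("B", [], anchor=True)]
            )

    def test_unbinarized_matrix_fatal(self):
        m = PredictionMatrix("M", {("c", "T"): 0.5}, "higher_better", is_anchor=True)
        with pytest.raises(ConsensusError):
            assemble_predicted_space([m])


class TestSubtractKnown:
    def _records(self, pairs):
        mats = [_bool_matrix("A", pairs, anchor=True)]
        return assemble_predicted_space(mats)

    def test_known_pair_removed(self):
        records = self._records([("c1", "T1"), ("c1", "T2")])
        known = KnownSpace(records=[InteractionRecord("c1", "T1", 1)])
        out = subtract_known(records, known)
        assert {(r.compound_id, r.target_id) for r in out} == {("c1", "T2")}

    def test_empty_known_space_is_identity(self):
        records = self._records([("c1", "T1"), ("c2", "T2")])
        assert subtract_known(records, KnownSpace()) == records

    def test_exact_set_difference_and_idempotence(self):
        pairs = [(f"c{i}", "T") for i in range(10)]
        records = self._records(pairs)
        known = KnownSpace(records=[InteractionRecord(f"c{i}", "T", 1) for i in range(3)])
        once = subtract_known(records, known)
        assert len(once) == 7
        assert subtract_known(once, known) == once

    def test_parent_pair_removes_stereoisomer_prediction(self):
        records = self._records([("c1_s2", "T1")])
        known = KnownSpace(records=[InteractionRecord("c1", "T1", 1)])
        out = subtract_known(records, known, parent_of={"c1_s2": "c1"})
        assert out == []


class TestCriteria:
    def _space(self):
        # panel compound p1 hits T1 with anchor+2; p2 hits T1 anchor only;
        # off-panel o1 hits T2 with anchor+1
        mats = [
            _bool_matrix("A", [("p1", "T1"), ("p2", "T1"), ("o1", "T2")], anchor=True),
            _bool_matrix("M1", [("p1", "T1"), ("o1", "T2")]),
            _bool_matrix("M2", [("p1", "T1"), ("p2", "T3")]),
        ]
        return assemble_predicted_space(mats)

    def test_panel_hits_require_anchor_and_min_cs(self):
        hits = criterion_panel_hits(self._space(), panel=["p1", "p2"], min_cs=2)
        assert hits == {"T1": [("p1", 3)]}

    def test_empty_panel_fatal(self):
        with pytest.raises(ConsensusError):
            criterion_panel_hits(self._space(), panel=[])

    def test_ranking_competition_ties_and_lexicographic_order(self):
        mats = [
            _bool_matrix(
                "A",
                [("c1", "T1"), ("c2", "T1"), ("c1", "T2"), ("c2", "T2"), ("c1", "T3")],
                anchor=True,
            ),
            _bool_matrix(
                "M",
                [("c1", "T1"), ("c2", "T1"), ("c1", "T2"), ("c2", "T2"), ("c1", "T3")],
            ),
        ]
        rankings = criterion_ranking(assemble_predicted_space(mats), cs_levels=[2])
        assert [(t.rank, t.target_id, t.frequency) for t in rankings] == [
            (1, "T1", 2),
            (1, "T2", 2),
            (3, "T3", 1),
        ]

    def test_frequency_monotone_across_cs_levels(self):
        rng = np.random.default_rng(3)
        pairs = [(f"c{i}", f"T{j}") for i in range(6) for j in range(4)]
        mats = [
            _bool_matrix(n, [p for p in pairs if rng.random() < 0.6], anchor=(n == "A"))
            for n in ("A", "B", "C", "D")
        ]
        rankings = criterion_ranking(assemble_predicted_space(mats), cs_levels=[2, 3, 4])
        freq = {}
        for t in rankings:
            freq.setdefault(t.target_id, {})[t.cs_level] = t.frequency
        for levels in freq.values():
            values = [levels.get(k, 0) for k in (2, 3, 4)]
            assert values == sorted(values, reverse=True)

    def test_consistency_evidence_is_pairwise_pathway_intersection(self):
        records = self._space()
        known = KnownSpace(records=[InteractionRecord("p9", "T9", 1)])
        annotations = {
            "T1": ["arachidonic acid metabolism", "other"],
            "T2": ["steroid metabolism"],
            "T9": ["arachidonic acid metabolism"],
            "T3": [],
        }
        out = criterion_consistency(records, known, annotations)
        assert out["T1"]["related_targets"] == ["T9"]
        assert out["T2"]["related_targets"] == []
        assert out["T3"]["related_targets"] == []

    def test_novelty_false_when_panel_compound_has_known_interaction(self):
        records = self._space()
        known = KnownSpace(records=[InteractionRecord("p1", "T1", 2)])
        out = criterion_consistency(records, known, {}, panel=["p1", "p2"])
        assert out["T1"]["novelty"] is False
        assert out["T2"]["novelty"] is True

    def test_selection_requires_assay_and_novelty(self):
        records = self._space()
        known = KnownSpace(records=[InteractionRecord("p1", "T1", 2)])
        report = build_selection_report(
            records,
            known,
            {},
            assay_available={"T1": True, "T2": True, "T3": False},
            panel=["p1", "p2", "o1"],
        )
        assert report["T1"]["selected"] is False  # known, not novel
        assert report["T2"]["selected"] is True
        assert report["T3"]["selected"] is False  # no assay


class TestEnrichment:
    def test_perfect_ranking_reaches_maximal_factor(self):
        known_pairs = [(f"c{i}", "T") for i in range(5)]
        other = [(f"d{i}", "T") for i in range(45)]
        scores = {p: 1.0 - 0.001 * i for i, p in enumerate(known_pairs)}
        scores.update({p: 0.5 - 0.001 * i for i, p in enumerate(other)})
        m = PredictionMatrix("M", scores, "boolean", is_anchor=True, rank_semantics="higher_better")
        known = KnownSpace(records=[InteractionRecord(c, t, 1) for c, t in known_pairs])
        ef = enrichment([m], known, top_k=5)
        assert ef["M"] == pytest.approx(50 / 5)

    def test_random_scores_give_factor_near_one(self):
        rng = np.random.default_rng(8)
        pairs = [(f"c{i}", f"T{j}") for i in range(50) for j in range(20)]
        scores = {p: float(rng.random()) for p in pairs}
        m = PredictionMatrix("M", scores, "boolean", is_anchor=True, rank_semantics="higher_better")
        known_pairs = [pairs[i] for i in rng.choice(len(pairs), size=100, replace=False)]
        known = KnownSpace(records=[InteractionRecord(c, t, 1) for c, t in known_pairs])
        ef = enrichment([m], known, top_k=200)
        assert 0.5 < ef["M"] < 2.0

    def test_empty_known_space_fatal(self):
        m = _bool_matrix("M", [("c", "T")], anchor=True)
        with pytest.raises(ConsensusError):
            enrichment([m], KnownSpace(), top_k=1)


class TestActivityCalls:
    @pytest.mark.parametrize(
        "mean,sd,expected",
        [
            (99.2, 1.2, "active"),  # strong, tight replicates
            (85.4, 9.3, "active"),
            (-50.7, 22.7, "inactive"),  # negative mean is ambiguous
            (13.8, 2.0, "inactive"),  # below the 30% floor
            (48.1, 12.0, "inactive"),  # relative sd 24.9% > 20%
            (30.0, 6.0, "active"),  # boundary: exactly 30%, exactly 20% rel sd
            (29.99, 0.1, "inactive"),
            (52.7, 49.6, "inactive"),  # noisy replicates
        ],
    )
    def test_activity_rule(self, mean, sd, expected):
        (call,) = classify_assay_results([("c", "T", mean, sd)])
        assert call.call == expected

    def test_negative_sd_fatal(self):
        with pytest.raises(ConsensusError):
            classify_assay_results([("c", "T", 50.0, -1.0)])

    def test_confirmed_count_distinct_targets(self):
        calls = classify_assay_results(
            [("c1", "T1", 90, 1), ("c2", "T1", 80, 2), ("c3", "T2", 10, 1)]
        )
        assert confirmed_target_count(calls) == 1

    def test_all_inactive_gives_zero(self):
        calls = classify_assay_results([("c1", "T1", 5, 1), ("c2", "T2", -20, 3)])
        assert confirmed_target_count(calls) == 0

    def test_bundled_inhibition_panel_confirms_four_targets(self):
        calls = classify_assay_results(dhc_panel_inhibition())
        assert len(calls) == 60
        assert confirmed_target_count(calls) == 4
        confirmed = {c.target_id for c in calls if c.call == "active"}
        assert confirmed == {"ALOX5", "PTGS1", "HSD17B3", "AKR1C3"}
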