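import itertools
import math
from collections import Counter

import pytest
from hypothesis import given, settings, strategies as st

from invarel import patterns as pat
from invarel.candidates import CandidateInstance, Sentence
from invarel.patterns import (ENTITY1, ENTITY2, RELATION, AlignmentConfig,
                              ContextFrame, InstanceCluster, InvarianceConfig,
                              PolynomialRepr, align_pair,
                              best_instance_representation, build_frame_counts,
                              cluster_by_invariance, consolidate_coefficients,
                              consolidate_pattern, extract_context_frames,
                              invariant_score, learn_patterns, read_patterns,
                              score_frame, write_patterns)
from oracles import brute_force_alignment_score, rotated_conic_coefficients


def make_instance(pos, e1, e2, rel=None, instance_id="k1", label="CPR:3"):
    """Minimal candidate instance around a normalized PoS sequence."""
    tokens = [f"w{i}" for i in range(len(pos))]
    sentence = Sentence("D", 0, " ".join(tokens), (0, 0), tokens, list(pos),
                        tokens, [], {})
    return CandidateInstance(
        instance_id=instance_id, doc_id="D", sentence=sentence,
        relation_class=label,
        entity1=("T1", e1, pos[e1]), entity2=("T2", e2, pos[e2]),
        proximal_verb=(rel, "RELATION") if rel is not None else None,
        proximal_verb_lemma="induce" if rel is not None else None,
        norm_tokens=list(tokens), norm_pos=list(pos),
        orig_token_map=[(i, i) for i in range(len(pos))])


class TestFrameExtraction:
    def test_four_frames_per_role_mid_sentence(self):
        pos = ["DT", "NN", "JJ", "CHEMICAL", "NN", "RELATION", "DT",
               "GENEPRO", "NN", "NN", "NN"]
        inst = make_instance(pos, e1=3, e2=7, rel=5)
        frames = extract_context_frames(inst, n=3)
        by_role = Counter(f.rfg_role for f in frames)
        assert by_role == {ENTITY1: 4, RELATION: 4, ENTITY2: 4}

    def test_anchor_at_start_truncates_left(self):
        pos = ["CHEMICAL", "NN", "NN", "NN", "GENEPRO", "NN", "NN", "NN"]
        inst = make_instance(pos, e1=0, e2=4)
        e1_frames = [f for f in extract_context_frames(inst, 3)
                     if f.rfg_role == ENTITY1]
        for f in e1_frames:
            assert f.anchor_offset == 0  # cannot shift left of the boundary
            assert f.tags[0] == "CHEMICAL"

    def test_negative_instance_has_no_relation_frames(self):
        pos = ["NN", "NN", "NN", "CHEMICAL", "NN", "GENEPRO", "NN", "NN", "NN"]
        inst = make_instance(pos, e1=3, e2=5, rel=None, label="NEG")
        roles = {f.rfg_role for f in extract_context_frames(inst, 3)}
        assert roles == {ENTITY1, ENTITY2}

    def test_frame_width_bounded(self):
        pos = ["NN"] * 12
        pos[5] = "CHEMICAL"
        pos[8] = "GENEPRO"
        inst = make_instance(pos, e1=5, e2=8)
        for f in extract_context_frames(inst, 3):
            assert len(f.tags) <= 4


class TestScoreFrame:
    def test_documented_counting_example(self):
        counts = Counter({("DT",): 5, ("DT", "CHEMICAL"): 3,
                          ("DT", "CHEMICAL", "VBZ"): 2})
        frame = ContextFrame(ENTITY1, 1, 1, ("DT", "CHEMICAL", "VBZ"), "k1")
        assert score_frame(frame, counts).rho == pytest.approx((3 / 5) * (2 / 3))

    def test_self_conditioned_frame_scores_one_plus_fringe(self):
        counts = Counter({("CHEMICAL",): 4, ("CHEMICAL", "NN"): 1})
        frame = ContextFrame(ENTITY1, 0, 0, ("CHEMICAL", "NN"), "k1")
        assert score_frame(frame, counts, fringe=1e-8).rho == \
            pytest.approx(1.0 + 1e-8)

    def test_unique_frame_with_unique_prefixes(self):
        counts = Counter({("DT",): 1, ("DT", "CHEMICAL"): 1})
        frame = ContextFrame(ENTITY1, 1, 1, ("DT", "CHEMICAL"), "k1")
        assert score_frame(frame, counts).rho == pytest.approx(1.0)

    def test_missing_frame_rejected(self):
        frame = ContextFrame(ENTITY1, 1, 1, ("DT", "CHEMICAL"), "k1")
        with pytest.raises(ValueError, match="counts"):
            score_frame(frame, Counter())

    def test_scores_nonnegative_and_case1_bounded(self):
        pos = ["DT", "NN", "JJ", "CHEMICAL", "NN", "RELATION", "DT",
               "GENEPRO", "NN", "JJ", "NN"]
        instances = [make_instance(pos, 3, 7, 5, instance_id=f"k{i}")
                     for i in range(3)]
        counts = build_frame_counts(instances, 3)
        for inst in instances:
            for frame in extract_context_frames(inst, 3):
                rho = score_frame(frame, counts).rho
                assert rho >= 0
                if frame.anchor_offset > 0:
                    assert rho <= 1.0 + 1e-12


class TestCoefficients:
    def _scores(self, values):
        out = {}
        for role, rho in values.items():
            frame = ContextFrame(role, 0, 0, ("X",), "k1")
            out[role] = [pat.FrameScore(rho, frame)]
        return out

    def test_product_rule(self):
        poly = consolidate_coefficients(
            self._scores({ENTITY1: 2.0, RELATION: 3.0, ENTITY2: 1.0}), "k1")
        assert (poly.p20, poly.p11, poly.p02) == (6.0, 18.0, 3.0)

    def test_pass_through_without_relation(self):
        poly = consolidate_coefficients(
            self._scores({ENTITY1: 2.0, ENTITY2: 1.0}), "k1")
        assert (poly.p20, poly.p11, poly.p02) == (2.0, 2.0, 1.0)

    def test_all_unit_scores(self):
        poly = consolidate_coefficients(
            self._scores({ENTITY1: 1.0, RELATION: 1.0, ENTITY2: 1.0}), "k1")
        assert (poly.p20, poly.p11, poly.p02) == (1.0, 1.0, 1.0)

    def test_missing_entity_role_rejected(self):
        with pytest.raises(ValueError, match="ENTITY2"):
            consolidate_coefficients(self._scores({ENTITY1: 1.0}), "k1")


class TestInvariant:
    @pytest.mark.parametrize("coeffs,expected", [
        ((1.0, 0.0, 1.0), 2.0),
        ((0.0, 2.0, 0.0), 2.0),
        ((2.0, 0.0, 1.0), 5.0),
    ])
    def test_closed_form(self, coeffs, expected):
        poly = PolynomialRepr(*coeffs, instance_id="k")
        assert invariant_score(poly).value == pytest.approx(expected)

    def test_rotated_form_same_invariant(self):
        q20, q11, q02 = rotated_conic_coefficients(2.0, 0.0, 1.0, math.pi / 4)
        assert (q20, q02) == pytest.approx((1.5, 1.5))
        assert abs(q11) == pytest.approx(1.0)
        original = invariant_score(PolynomialRepr(2.0, 0.0, 1.0, "k")).value
        rotated = invariant_score(PolynomialRepr(q20, q11, q02, "k")).value
        assert original == pytest.approx(5.0)
        assert rotated == pytest.approx(original, abs=1e-9)

    @given(st.floats(-5, 5), st.floats(-5, 5), st.floats(-5, 5),
           st.floats(0, 2 * math.pi))
    @settings(max_examples=200, deadline=None)
    def test_rotation_invariance_property(self, p20, p11, p02, angle):
        q = rotated_conic_coefficients(p20, p11, p02, angle)
        original = invariant_score(PolynomialRepr(p20, p11, p02, "k")).value
        rotated = invariant_score(PolynomialRepr(*q, instance_id="k")).value
        assert rotated == pytest.approx(original, abs=1e-9)


class TestBestRepresentation:
    def _instances(self):
        pos = ["DT", "NN", "JJ", "CHEMICAL", "NN", "RELATION", "DT",
               "GENEPRO", "NN", "JJ", "NN"]
        return [make_instance(pos, 3, 7, 5, instance_id=f"k{i}")
                for i in range(2)]

    def test_identical_instances_identical_invariant(self):
        instances = self._instances()
        counts = build_frame_counts(instances, 3)
        config = InvarianceConfig(n=3)
        reps = [best_instance_representation(i, counts, config)
                for i in instances]
        assert reps[0].score.value == pytest.approx(reps[1].score.value)

    def test_evaluates_all_offsets_and_takes_argmax(self):
        instances = self._instances()
        counts = build_frame_counts(instances, 3)
        config = InvarianceConfig(n=3)
        inst = instances[0]
        values = {}
        frames = extract_context_frames(inst, 3)
        by_ec = {}
        for f in frames:
            by_ec.setdefault(f.e_c, {})[f.rfg_role] = f
        for e_c, role_frames in by_ec.items():
            scores = {r: [score_frame(f, counts, config.fringe)]
                      for r, f in role_frames.items()}
            poly = consolidate_coefficients(scores, inst.instance_id)
            values[e_c] = invariant_score(poly, e_c).value
        assert len(values) == 4
        best = best_instance_representation(inst, counts, config)
        assert best.score.value == pytest.approx(max(values.values()))
        expected_ec = min(e for e, v in values.items()
                          if v == max(values.values()))
        assert best.score.e_c == expected_ec


class TestClustering:
    def test_ratio_rule(self):
        clusters = cluster_by_invariance(
            [("a", 4.0), ("b", 4.0), ("c", 2.0)], InvarianceConfig())
        assert [sorted(c.members) for c in clusters] == [["a", "b"], ["c"]]

    def test_singleton(self):
        clusters = cluster_by_invariance([("a", 3.0)], InvarianceConfig())
        assert len(clusters) == 1 and clusters[0].members == ["a"]

    def test_planted_ratio_partition(self):
        config = InvarianceConfig(ratio_tolerance=0.01)
        clusters = cluster_by_invariance(
            [("a", 9.0), ("b", 3.0), ("c", 3.0), ("d", 1.0)], config)
        assert [sorted(c.members) for c in clusters] == [["a"], ["b", "c"], ["d"]]

    def test_non_positive_score_rejected(self):
        with pytest.raises(ValueError, match="non-positive"):
            cluster_by_invariance([("a", 0.0)], InvarianceConfig())

    @given(st.lists(st.floats(0.5, 50), min_size=1, max_size=12))
    @settings(max_examples=100, deadline=None)
    def test_permutation_invariance_and_idempotence(self, values):
        import random as _random
        scored = [(f"i{k}", v) for k, v in enumerate(values)]
        shuffled = list(scored)
        _random.Random(0).shuffle(shuffled)
        config = InvarianceConfig()
        a = [sorted(c.members) for c in cluster_by_invariance(scored, config)]
        b = [sorted(c.members) for c in cluster_by_invariance(shuffled, config)]
        assert a == b
        # idempotence: reclustering each cluster's members splits nothing
        for cluster in cluster_by_invariance(scored, config):
            sub = [(i, v) for i, v in scored if i in cluster.members]
            assert len(cluster_by_invariance(sub, config)) == 1


class TestAlignment:
    def test_all_match(self):
        score, _ = align_pair(["NN", "DT", "VB"], ["NN", "DT", "VB"])
        assert score == 6

    def test_single_mismatch_beats_gaps(self):
        score, (a, b) = align_pair(["NN"], ["DT"])
        assert score == -2
        assert a == ("NN",) and b == ("DT",)

    def test_one_gap(self):
        score, _ = align_pair(["NN", "DT"], ["NN"])
        assert score == 0

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            align_pair([], ["NN"])

    @given(st.lists(st.sampled_from("ABCD"), min_size=1, max_size=6),
           st.lists(st.sampled_from("ABCD"), min_size=1, max_size=6))
    @settings(max_examples=300, deadline=None)
    def test_matches_brute_force(self, a, b):
        score, (aligned_a, aligned_b) = align_pair(a, b)
        assert score == pytest.approx(brute_force_alignment_score(a, b))
        # the returned alignment realizes the returned score
        realized = 0.0
        for x, y in zip(aligned_a, aligned_b):
            if x == pat.GAP or y == pat.GAP:
                realized += -2
            else:
                realized += 2 if x == y else -2
        assert realized == pytest.approx(score)
        assert tuple(s for s in aligned_a if s != pat.GAP) == tuple(a)
        assert tuple(s for s in aligned_b if s != pat.GAP) == tuple(b)


class TestConsolidatePattern:
    def _rep(self, iid, frames):
        out = {}
        for role, tags in frames.items():
            out[role] = ContextFrame(role, 0, 0, tuple(tags), iid)
        poly = PolynomialRepr(1, 1, 1, iid)
        return pat.InstanceRepresentation(poly, invariant_score(poly), out)

    def test_singleton_pattern_verbatim(self):
        reps = {"a": self._rep("a", {ENTITY1: ("CHEMICAL", "DT"),
                                     RELATION: ("RELATION", "NN"),
                                     ENTITY2: ("GENEPRO", "JJ")})}
        cluster = InstanceCluster(["a"], 1.0, "CPR:3")
        pattern = consolidate_pattern(cluster, reps)
        assert pattern.entity1_context == ("CHEMICAL", "DT")
        assert pattern.relation_context == ("RELATION", "NN")
        assert pattern.entity2_context == ("GENEPRO", "JJ")
        assert pattern.support == 1

    def test_two_identical_members(self):
        frames = {ENTITY1: ("CHEMICAL", "DT"), RELATION: ("RELATION",),
                  ENTITY2: ("GENEPRO",)}
        reps = {"a": self._rep("a", frames), "b": self._rep("b", frames)}
        cluster = InstanceCluster(["a", "b"], 1.0, "CPR:3")
        pattern = consolidate_pattern(cluster, reps)
        assert pattern.entity1_context == ("CHEMICAL", "DT")
        assert pattern.support == 2

    def test_majority_tie_resolved_to_first_member(self):
        reps = {"a": self._rep("a", {ENTITY1: ("CHEMICAL", "DT", "JJ"),
                                     RELATION: ("RELATION",),
                                     ENTITY2: ("GENEPRO",)}),
                "b": self._rep("b", {ENTITY1: ("CHEMICAL", "DT", "NN"),
                                     RELATION: ("RELATION",),
                                     ENTITY2: ("GENEPRO",)})}
        cluster = InstanceCluster(["a", "b"], 1.0, "CPR:3")
        pattern = consolidate_pattern(cluster, reps)
        assert pattern.entity1_context[:2] == ("CHEMICAL", "DT")
        assert pattern.entity1_context[2] == "JJ"  # first-processed member wins

    def test_empty_cluster_rejected(self):
        with pytest.raises(ValueError):
            consolidate_pattern(InstanceCluster([], 1.0, "CPR:3"), {})


class TestLearnPatterns:
    def test_identical_corpus_single_pattern(self):
        pos = ["DT", "NN", "JJ", "CHEMICAL", "NN", "RELATION", "DT",
               "GENEPRO", "NN", "JJ", "NN"]
        instances = [make_instance(pos, 3, 7, 5, instance_id=f"k{i}")
                     for i in range(4)]
        learned = learn_patterns(instances, InvarianceConfig(n=3))
        assert list(learned) == ["CPR:3"]
        assert len(learned["CPR:3"]) == 1
        assert learned["CPR:3"][0].support == 4

    def test_empty_input(self):
        assert learn_patterns([], InvarianceConfig()) == {}

    def test_two_planted_templates_recovered(self):
        pos_a = ["DT", "NN", "JJ", "CHEMICAL", "RB", "RELATION", "DT",
                 "GENEPRO", "NN", "NN", "NN"]
        pos_b = ["IN", "NN", "NN", "CHEMICAL", "RELATION", "JJ", "GENEPRO",
                 "NN", "IN", "NN", "NN"]
        instances = (
            [make_instance(pos_a, 3, 7, 5, f"a{i}", "CPR:3") for i in range(4)]
            + [make_instance(pos_b, 3, 6, 4, f"b{i}", "CPR:4") for i in range(4)])
        learned = learn_patterns(instances, InvarianceConfig(n=3))
        assert set(learned) == {"CPR:3", "CPR:4"}
        assert sum(len(v) for v in learned.values()) >= 2
        # each class pattern anchors at its own planted context
        assert learned["CPR:3"][0].entity1_context[0] == "CHEMICAL"
        assert learned["CPR:4"][0].entity1_context[0] == "CHEMICAL"
        assert learned["CPR:3"][0] != learned["CPR:4"][0]

    def test_round_trip_serialization(self, tmp_path):
        pos = ["DT", "NN", "JJ", "CHEMICAL", "NN", "RELATION", "DT",
               "GENEPRO", "NN", "JJ", "NN"]
        instances = [make_instance(pos, 3, 7, 5, instance_id=f"k{i}")
                     for i in range(3)]
        learned = learn_patterns(instances, InvarianceConfig(n=3))
        path = tmp_path / "patterns.tsv"
        write_patterns(learned, path)
        assert read_patterns(path) == learned
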