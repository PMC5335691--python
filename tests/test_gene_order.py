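import numpy as np
import pytest

from mitokit import load_study_manifest, load_study_tree
from mitokit.gene_order import (
    GROUND_PATTERN,
    EventInferenceError,
    RearrangementEvent,
    SignedGeneOrder,
    apply_events,
    block_inversion,
    breakpoint_distance,
    canonicalize,
    duplication,
    extract_gene_order,
    ground_pattern,
    group_patterns,
    infer_events,
    parse_newick,
    pattern_tree_consistency,
    translocation,
)
from mitokit.synthetic_data import (
    apply_event_script,
    build_record,
    default_config,
    random_event_script,
)
from mitokit.vocab import GENE_TOKENS

from oracles import bfs_min_events, naive_breakpoints

GP = GROUND_PATTERN


def rotations(order):
    toks = order.tokens
    for i in range(len(toks)):
        yield SignedGeneOrder(tokens=toks[i:] + toks[:i],
                              include_cr=order.include_cr)


def mirror(order):
    return SignedGeneOrder(
        tokens=tuple((t, -s) for t, s in reversed(order.tokens)),
        include_cr=order.include_cr)


def random_toy_order(rng, n):
    return SignedGeneOrder(tokens=tuple(
        (f"g{i + 1}", 1 if rng.random() < 0.7 else -1) for i in range(n)))


class TestGroundPattern:
    def test_contents(self):
        names = GP.names()
        assert len(names) == 38
        assert set(names) == set(GENE_TOKENS) | {"CR"}

    def test_without_cr(self):
        assert len(ground_pattern(include_cr=False)) == 37


class TestExtract:
    def test_ground_record_matches_ground(self, ground_record):
        assert extract_gene_order(ground_record) == GP

    def test_exclude_cr(self, ground_record):
        order = extract_gene_order(ground_record, include_cr=False)
        assert len(order) == 37
        assert "CR" not in order.names()

    def test_extra_trnq_flanked_by_nad4l_and_trnt(self):
        cfg = default_config(seed=5)
        cfg.pattern_scripts["XQ"] = [duplication("trnQ.2", -1, "nad4l", "trnT")]
        cfg.taxon_patterns["dup_taxon"] = "XQ"
        rec = build_record(cfg, "dup_taxon", pattern="XQ",
                           rng=np.random.default_rng(5))
        order = extract_gene_order(rec)
        assert len(order) == 39
        names = list(order.names())
        i = names.index("nad4l")
        assert names[i + 1].startswith("trnQ")
        assert names[i + 2] == "trnT"
        # both copies present, disambiguated in genome order
        assert sum(1 for n in names if n.split(".")[0] == "trnQ") == 2

    def test_strand_mirror_symmetry(self, ground_record):
        # annotate the reverse-complemented molecule: coordinates reflected,
        # strands flipped, genome order reversed
        from dataclasses import replace
        L = ground_record.length
        mirrored = replace(ground_record)
        mirrored.features = [
            replace(f, start=L - f.end + 1, end=L - f.start + 1,
                    strand=-f.strand)
            for f in ground_record.features
        ]
        assert extract_gene_order(mirrored) == extract_gene_order(ground_record)

    def test_empty_features_error(self, ground_record):
        from dataclasses import replace
        rec = replace(ground_record)
        rec.features = []
        with pytest.raises(ValueError, match="no usable features"):
            extract_gene_order(rec)


class TestCanonicalize:
    def test_rotation_invariance(self):
        expected = canonicalize(GP)
        for rot in rotations(GP):
            assert canonicalize(rot).tokens == expected.tokens

    def test_mirror_invariance(self):
        assert canonicalize(mirror(GP)).tokens == canonicalize(GP).tokens

    def test_idempotence_on_random_orders(self):
        rng = np.random.default_rng(17)
        for _ in range(100):
            n = int(rng.integers(4, 12))
            order = random_toy_order(rng, n)
            shift = int(rng.integers(n))
            shuffled = SignedGeneOrder(
                tokens=order.tokens[shift:] + order.tokens[:shift])
            once = canonicalize(shuffled, anchor="g1")
            twice = canonicalize(once, anchor="g1")
            assert once.tokens == twice.tokens

    def test_missing_anchor_errors(self):
        order = SignedGeneOrder(tokens=(("trnA", 1), ("trnB", 1)))
        with pytest.raises(ValueError, match="anchor"):
            canonicalize(order)


class TestBreakpointDistance:
    def test_identity(self):
        assert breakpoint_distance(GP, GP) == 0
        for rot in rotations(GP):
            assert breakpoint_distance(GP, rot) == 0
        assert breakpoint_distance(GP, mirror(GP)) == 0

    def test_single_trna_move_is_three(self):
        derived = apply_event_script(GP, [translocation("trnG", 1, "trnA", "trnR")])
        assert breakpoint_distance(GP, derived) == 3
        assert breakpoint_distance(GP, derived) == naive_breakpoints(GP, derived)

    def test_internal_block_inversion_is_two(self):
        block = (("trnA", 1), ("trnR", 1), ("trnN", 1))
        derived = apply_event_script(GP, [block_inversion(block)])
        assert breakpoint_distance(GP, derived) == 2
        assert breakpoint_distance(GP, derived) == naive_breakpoints(GP, derived)

    def test_matches_naive_oracle_on_random_pairs(self):
        rng = np.random.default_rng(23)
        for _ in range(50):
            script = random_event_script(GP, int(rng.integers(1, 4)), rng)
            script = [e for e in script if e.kind not in ("duplication", "loss")]
            derived = apply_event_script(GP, script)
            assert breakpoint_distance(GP, derived) == naive_breakpoints(GP, derived)

    def test_metric_properties(self):
        rng = np.random.default_rng(31)
        for _ in range(30):
            orders = []
            for _k in range(3):
                script = random_event_script(GP, int(rng.integers(0, 4)), rng)
                script = [e for e in script if e.kind not in ("duplication", "loss")]
                orders.append(apply_event_script(GP, script))
            a, b, c = orders
            dab = breakpoint_distance(a, b)
            dba = breakpoint_distance(b, a)
            assert dab == dba
            assert (dab == 0) == (a == b)
            assert dab <= breakpoint_distance(a, c) + breakpoint_distance(c, b)

    def test_multiset_mismatch_errors(self):
        smaller = SignedGeneOrder(tokens=GP.tokens[:-1])
        with pytest.raises(ValueError, match="trnY"):
            breakpoint_distance(GP, smaller)


class TestInferEvents:
    def test_identical_orders(self):
        assert infer_events(GP, GP) == []

    def test_four_gene_block_inversion_recovered(self):
        block = (("trnA", 1), ("trnR", 1), ("trnN", 1), ("trnS1", 1))
        derived = apply_event_script(GP, [block_inversion(block)])
        events = infer_events(GP, derived)
        assert len(events) == 1
        ev = events[0]
        assert ev.kind == "block-inversion"
        assert [g for g, _ in ev.genes] == ["trnS1", "trnN", "trnR", "trnA"]
        assert all(s == -1 for _, s in ev.genes)
        assert apply_events(GP, events) == derived

    def test_translocation_with_inversion_and_contexts(self):
        derived = apply_event_script(
            GP, [translocation("trnD", -1, "trnS2", "nad1", invert=True)])
        events = infer_events(GP, derived)
        assert len(events) == 1
        ev = events[0]
        assert ev.kind == "translocation+inversion"
        assert ev.genes == (("trnD", -1),)
        assert ev.source_context == ("trnK", "atp8")
        assert ev.target_context == ("trnS2", "nad1")

    def test_duplication_and_loss_reported_first(self):
        derived = apply_event_script(
            GP, [duplication("trnQ.2", -1, "nad4l", "trnT"),
                 RearrangementEvent("loss", (("trnY", 0),))])
        events = infer_events(GP, derived)
        kinds = [e.kind for e in events]
        assert kinds[0] == "loss"
        assert kinds[1] == "duplication"
        assert apply_events(GP, events) == derived

    def test_replay_soundness_200_random_scripts(self):
        rng = np.random.default_rng(2024)
        for _ in range(200):
            script = random_event_script(GP, int(rng.integers(1, 5)), rng)
            derived = apply_event_script(GP, script)
            events = infer_events(GP, derived)
            assert apply_events(GP, events) == derived

    def test_within_two_of_bfs_minimum_on_toys(self):
        rng = np.random.default_rng(99)
        for _ in range(40):
            n = int(rng.integers(5, 10))
            ref = random_toy_order(rng, n)
            n_ev = int(rng.integers(1, 3)) if n >= 7 else int(rng.integers(1, 4))
            script = random_event_script(ref, n_ev, rng, anchor="g1")
            script = [e for e in script if e.kind not in ("duplication", "loss")]
            derived = apply_event_script(ref, script)
            heuristic = infer_events(ref, derived)
            minimum = bfs_min_events(ref, derived, max_depth=max(len(script), 1))
            if minimum is None:
                minimum = len(script)
            assert minimum <= len(heuristic) <= minimum + 2

    def test_nonconvergence_carries_partial_list(self):
        # mismatched multisets beyond dup/loss repair cannot occur via the
        # public API; exercise the error type through a crafted kind check
        with pytest.raises(ValueError):
            RearrangementEvent("warp", (("trnA", 1),))
        err = EventInferenceError("stuck", [])
        assert err.partial == []


class TestApplyEvents:
    def test_empty_script_is_identity(self):
        assert apply_event_script(GP, []) == GP

    def test_script_then_inverse_restores_ground(self):
        script = [translocation("trnG", 1, "trnA", "trnR")]
        inverse = [translocation("trnG", 1, "cox3", "nad3")]
        assert apply_event_script(apply_event_script(GP, script), inverse) == GP

    def test_double_block_inversion_restores_ground(self):
        block = (("trnA", 1), ("trnR", 1), ("trnN", 1))
        once = apply_event_script(GP, [block_inversion(block)])
        inverted_block = tuple((t, -s) for t, s in reversed(block))
        twice = apply_event_script(once, [block_inversion(inverted_block)])
        assert twice == GP
        assert once != GP

    def test_unresolvable_context_errors(self):
        with pytest.raises(ValueError, match="cannot apply"):
            apply_events(GP, [RearrangementEvent("loss", (("trnZ9", 0),))])

    def test_ax2_style_script(self):
        cfg = default_config(seed=1)
        derived = apply_event_script(GP, cfg.pattern_scripts["Ax2"])
        assert breakpoint_distance(GP, derived) > 0
        events = infer_events(GP, derived)
        assert apply_events(GP, events) == derived
        assert any(e.kind == "block-inversion" for e in events)


class TestGroupPatterns:
    def test_three_plus_two(self):
        pa = apply_event_script(GP, [translocation("trnG", 1, "trnA", "trnR")])
        ap = apply_event_script(GP, [translocation("trnE", -1, "trnT", "trnP",
                                                   invert=True)])
        orders = {f"pa{i}": pa for i in range(3)} | {f"ap{i}": ap for i in range(2)}
        patterns = group_patterns(orders)
        sizes = sorted(len(p.members) for p in patterns)
        assert sizes == [2, 3]
        assert all(p.label.startswith("P") for p in patterns)

    def test_all_ground_single_gr(self):
        patterns = group_patterns({f"r{i}": GP for i in range(4)})
        assert len(patterns) == 1
        assert patterns[0].label == "Gr"
        assert patterns[0].breakpoints_vs_ground == 0
        assert patterns[0].events_vs_ground == []

    def test_all_unique_singletons(self):
        rng = np.random.default_rng(4)
        orders = {}
        genes = ["trnG", "trnE", "trnD", "trnH"]
        for i, g in enumerate(genes):
            orders[f"u{i}"] = apply_event_script(
                GP, [translocation(g, 1, "cox1", "trnL2")])
        patterns = group_patterns(orders)
        assert len(patterns) == 4
        assert all(len(p.members) == 1 for p in patterns)

    def test_supplied_labels_used(self):
        pa = apply_event_script(GP, [translocation("trnG", 1, "trnA", "trnR")])
        orders = {"a": pa, "b": pa, "c": GP}
        labels = {"a": "Pa", "b": "Pa", "c": "Gr"}
        patterns = group_patterns(orders, labels=labels)
        assert {p.label for p in patterns} == {"Gr", "Pa"}

    def test_input_order_invariance(self):
        pa = apply_event_script(GP, [translocation("trnG", 1, "trnA", "trnR")])
        orders = {"b": pa, "a": GP, "c": pa}
        p1 = group_patterns(dict(sorted(orders.items())))
        p2 = group_patterns(dict(sorted(orders.items(), reverse=True)))
        as_sets = lambda ps: {(p.label, tuple(sorted(p.members))) for p in ps}
        assert as_sets(p1) == as_sets(p2)


class TestNewickAndFitch:
    def test_two_leaves(self):
        t = parse_newick("(A,B);")
        assert sorted(t.leaf_labels()) == ["A", "B"]

    def test_branch_lengths_parsed_and_ignored(self):
        t = parse_newick("((A:1,B:2):0.5,C:3);")
        assert sorted(t.leaf_labels()) == ["A", "B", "C"]

    def test_duplicate_labels_error(self):
        with pytest.raises(ValueError, match="duplicate"):
            parse_newick("((A,B),(A,C));")

    def test_malformed_error(self):
        with pytest.raises(ValueError):
            parse_newick("((A,B);")

    def test_hand_computed_fitch(self):
        t = parse_newick("((A,B),(C,D));")
        report = pattern_tree_consistency(
            t, {"A": "X", "B": "O", "C": "X", "D": "O"})
        assert report.steps == 2
        assert report.min_steps == 1
        assert not report.consistent
        assert report.monophyletic == {"O": False, "X": False}

    def test_uniform_labels_zero_steps(self):
        t = parse_newick("((A,B),(C,D));")
        report = pattern_tree_consistency(t, {l: "Z" for l in "ABCD"})
        assert report.steps == 0
        assert report.consistent

    def test_clade_confined_is_consistent(self):
        t = parse_newick("(((A,B),(C,D)),(E,F));")
        assignment = {"A": "Gr", "B": "Gr", "C": "X", "D": "X",
                      "E": "Y", "F": "Y"}
        report = pattern_tree_consistency(t, assignment)
        assert report.steps == report.min_steps == 2
        assert report.monophyletic["X"] and report.monophyletic["Y"]

    def test_unassigned_leaf_errors(self):
        t = parse_newick("(A,B);")
        with pytest.raises(ValueError, match="B"):
            pattern_tree_consistency(t, {"A": "X"})


class TestStudyFixtureConsistency:
    """The bundled manifest/tree transcribed from the study design."""

    def test_manifest_counts(self):
        m = load_study_manifest()
        assert len(m) == 45
        assert (m["role"] == "ingroup").sum() == 33
        assert (m["role"] == "outgroup").sum() == 12

    def test_pattern_monophyly(self):
        m = load_study_manifest()
        tree = parse_newick(load_study_tree())
        assignment = dict(zip(m["record_id"], m["pattern"]))
        report = pattern_tree_consistency(tree, assignment)
        for label in ("Pa", "Ap1", "Ap2", "Up", "Ax2"):
            assert report.monophyletic[label], label
        # Ax2 is nested inside the Ax1 background: their union forms a clade
        union = {rid: ("Ax" if lab in ("Ax1", "Ax2") else lab)
                 for rid, lab in assignment.items()}
        union_report = pattern_tree_consistency(tree, union)
        assert union_report.monophyletic["Ax"]

    def test_fitch_steps_minimal(self):
        m = load_study_manifest()
        tree = parse_newick(load_study_tree())
        assignment = dict(zip(m["record_id"], m["pattern"]))
        report = pattern_tree_consistency(tree, assignment)
        assert report.steps == report.min_steps == 6
        assert report.consistent
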