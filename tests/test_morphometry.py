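"""SWC parsing and morphometric index checks against hand-computed
values and structural invariants."""

import math

import numpy as np
import pytest

from bmsf.morphometry import (
    CORE_METRICS,
    SWCParseError,
    batch_extract,
    bifurcation_metrics,
    branch_metrics,
    compute_profile,
    distance_metrics,
    parse_swc,
    size_metrics,
    spatial_extents,
    terminal_metrics,
    topology_counts,
)
from bmsf.synthetic import TreeSpec, generate_toy_swc

from conftest import random_tree, swc_text


class TestParsing:
    def test_minimal_tree_has_one_root_and_two_compartments(self):
        rec = parse_swc(swc_text([
            (1, 1, 0, 0, 0, 5, -1),
            (2, 3, 10, 0, 0, 1, 1),
            (3, 3, 20, 0, 0, 1, 2),
        ]))
        assert rec.roots == [1]
        assert len(rec.nodes) == 3  # 2 non-root nodes = 2 compartments

    @pytest.mark.parametrize("rows, match", [
        ([(1, 1, 0, 0, 0, 5, -1), (2, 3, 1, 0, 0, 1, 99)], "parent"),
        ([(1, 1, 0, 0, 0, 5, -1), (2, 3, 1, 0, 0, -1, 1)], "radius"),
        ([(1, 1, 0, 0, 0, 5, -1), (1, 3, 1, 0, 0, 1, 1)], "duplicate"),
        ([(1, 1, 0, 0, 0, 5, 2), (2, 3, 1, 0, 0, 1, 1)], "cycle|root"),
    ])
    def test_invalid_input_raises(self, rows, match):
        with pytest.raises(SWCParseError, match=match):
            parse_swc(swc_text(rows))

    def test_comments_only_is_no_nodes_error(self):
        with pytest.raises(SWCParseError, match="no nodes"):
            parse_swc("# header only\n# more header\n")

    def test_malformed_line_error_names_line_number(self):
        with pytest.raises(SWCParseError, match=":2:"):
            parse_swc("1 1 0 0 0 5 -1\n2 3 bad 0 0 1 1\n")


class TestTopology:
    def test_two_stem_tree_counts_by_hand(self, two_stem_tree):
        c = topology_counts(two_stem_tree)
        assert c == {"N_s": 2, "N_bi": 1, "N_t": 3, "N_br": 4,
                     "Fr": 6, "BO": 1}

    def test_unbranched_neurite(self):
        rec = parse_swc(swc_text([
            (1, 1, 0, 0, 0, 5, -1),
            (2, 3, 10, 0, 0, 1, 1),
            (3, 3, 20, 0, 0, 1, 2),
        ]))
        c = topology_counts(rec)
        assert (c["N_s"], c["N_bi"], c["N_t"], c["N_br"], c["BO"]) \
            == (1, 0, 1, 1, 0)

    @pytest.mark.parametrize("depth", [1, 2, 4])
    def test_full_binary_tree_closed_forms(self, depth):
        rec = parse_swc(generate_toy_swc(TreeSpec(
            branch_prob=1.0, max_depth=depth, stem_count=1, seed=3)))
        c = topology_counts(rec)
        assert c["N_t"] == 2 ** depth
        assert c["N_bi"] == 2 ** depth - 1
        assert c["BO"] == depth

    def test_branch_count_identity_on_random_trees(self):
        for seed in range(100):
            c = topology_counts(random_tree(seed))
            assert c["N_br"] == c["N_bi"] + c["N_t"]


class TestExtents:
    def test_uniform_grid_on_line_gives_95_percent_extent(self):
        n = 21
        rows = [(1, 1, 0, 0, 0, 1, -1)]
        rows += [(i + 2, 3, (i + 1) * 5.0, 0, 0, 0.5, i + 1)
                 for i in range(n - 1)]
        ext = spatial_extents(parse_swc(swc_text(rows)))
        assert ext["NH"] == pytest.approx(0.95 * 100.0, abs=1e-9)
        assert ext["NW"] == pytest.approx(0.0, abs=1e-9)
        assert ext["ND"] == pytest.approx(0.0, abs=1e-9)

    def test_single_node_extents_zero(self):
        ext = spatial_extents(parse_swc("1 1 0 0 0 5 -1\n"))
        assert ext == {"NW": 0.0, "NH": 0.0, "ND": 0.0}

    def test_rigid_rotation_leaves_extents_unchanged(self):
        rec = random_tree(7)
        before = spatial_extents(rec)
        rng = np.random.default_rng(0)
        # random rotation via QR of a Gaussian matrix
        q, _ = np.linalg.qr(rng.standard_normal((3, 3)))
        rotated = parse_swc(swc_text([
            (n.id, n.type_code, *np.round(q @ n.position, 12),
             n.radius, n.parent_id)
            for n in rec.nodes
        ]))
        after = spatial_extents(rotated)
        for key in before:
            assert after[key] == pytest.approx(before[key], abs=1e-6)


class TestSizeAndDistance:
    def test_single_cylinder_arithmetic(self):
        rec = parse_swc(swc_text([
            (1, 1, 0, 0, 0, 5, -1),
            (2, 3, 10, 0, 0, 1, 1),
        ]))
        m = size_metrics(rec)
        assert m["Le"] == pytest.approx(10)
        assert m["Su"] == pytest.approx(2 * math.pi * 10)
        assert m["SA"] == m["Su"]
        assert m["Vo"] == pytest.approx(math.pi * 10)
        assert m["Di"] == pytest.approx(2)
        assert m["Dp"] == pytest.approx(2 ** 1.5)
        assert m["SS"] == pytest.approx(4 * math.pi * 25)  # sphere, r=5

    def test_length_matches_independent_traversal(self):
        rec = random_tree(11)
        soma = rec.soma_ids()
        expected = sum(
            float(np.linalg.norm(n.position - rec.index[n.parent_id].position))
            for n in rec.nodes if n.parent_id != -1 and n.id not in soma)
        assert size_metrics(rec)["Le"] == pytest.approx(expected, rel=1e-12)

    def test_straight_neurite_ed_equals_pd(self):
        rec = parse_swc(swc_text([
            (1, 1, 0, 0, 0, 1, -1),
            (2, 3, 15, 0, 0, 0.5, 1),
            (3, 3, 30, 0, 0, 0.5, 2),
        ]))
        d = distance_metrics(rec)
        assert d["ED"] == pytest.approx(30)
        assert d["PD"] == pytest.approx(30)

    def test_right_angle_elbow(self):
        rec = parse_swc(swc_text([
            (1, 1, 0, 0, 0, 1, -1),
            (2, 3, 10, 0, 0, 0.5, 1),
            (3, 3, 10, 10, 0, 0.5, 2),
        ]))
        d = distance_metrics(rec)
        assert d["PD"] == pytest.approx(20)
        assert d["ED"] == pytest.approx(10 * math.sqrt(2))

    def test_pd_dominates_ed_on_random_trees(self):
        for seed in range(100):
            d = distance_metrics(random_tree(seed))
            assert d["PD"] >= d["ED"] - 1e-9


class TestBranches:
    def test_straight_tapering_branch(self):
        # first neurite node diameter 2, final diameter 1, path 10
        rec = parse_swc(swc_text([
            (1, 1, 0, 0, 0, 5, -1),
            (2, 3, 5, 0, 0, 1, 1),
            (3, 3, 10, 0, 0, 0.5, 2),
        ]))
        m = branch_metrics(rec)
        assert m["Co"] == pytest.approx(1.0)
        assert m["Bpl"] == pytest.approx(10.0)
        assert m["Ta1"] == pytest.approx(0.1)
        assert m["Ta2"] == pytest.approx(0.5)

    def test_no_taper_gives_zero(self):
        rec = parse_swc(swc_text([
            (1, 1, 0, 0, 0, 5, -1),
            (2, 3, 5, 0, 0, 1, 1),
            (3, 3, 10, 0, 0, 1, 2),
        ]))
        m = branch_metrics(rec)
        assert m["Ta1"] == 0.0
        assert m["Ta2"] == 0.0

    def test_zigzag_contracts_below_one(self):
        rec = parse_swc(swc_text([
            (1, 1, 0, 0, 0, 1, -1),
            (2, 3, 10, 0, 0, 0.5, 1),
            (3, 3, 10, 10, 0, 0.5, 2),
            (4, 3, 20, 10, 0, 0.5, 3),
        ]))
        assert branch_metrics(rec)["Co"] < 1.0

    def test_contraction_in_unit_interval_on_random_trees(self):
        for seed in range(50):
            co = branch_metrics(random_tree(seed))["Co"]
            assert 0.0 < co <= 1.0 + 1e-12


class TestBifurcations:
    def test_symmetric_y_formula_arithmetic(self, symmetric_y):
        m = bifurcation_metrics(symmetric_y)
        assert m["DR"] == pytest.approx(1.0)
        assert m["PDR"] == pytest.approx(0.5)
        assert m["Pa"] == 0.0          # tips 1,1 -> defined as 0
        assert m["Bal"] == pytest.approx(120.0, abs=1e-6)
        assert m["Bar"] == pytest.approx(120.0, abs=1e-6)
        assert m["Btl"] == pytest.approx(60.0, abs=1e-6)
        assert m["Pc"] == pytest.approx(2 ** -0.5)
        assert m["Pk2"] == pytest.approx(0.5)
        # d1=d2=1, dp=2: |2 - 2^n| minimized at n=1
        assert m["Pk"] == pytest.approx(1.0, abs=0.01)

    def test_partition_asymmetry_two_vs_one_tips(self):
        rec = parse_swc(swc_text([
            (1, 1, 0, 0, 0, 2, -1),
            (2, 3, 10, 0, 0, 1, 1),       # bifurcation, subtrees 2 and 1
            (3, 3, 20, 5, 0, 0.8, 2),     # bifurcates again
            (4, 3, 30, 10, 0, 0.5, 3),
            (5, 3, 30, 0, 0, 0.5, 3),
            (6, 3, 20, -5, 0, 0.8, 2),    # tip
        ]))
        m = bifurcation_metrics(rec)
        # two bifurcations: Pa = |(2-1)/(2+1-2)| = 1 and Pa = 0 (1,1)
        assert m["Pa"] == pytest.approx((1.0 + 0.0) / 2)

    def test_rall_grid_recovers_constructed_exponent(self):
        # choose d1 = d2 = 2^(1/3) so d1^1.5 + d2^1.5 = 2^1.5 exactly
        r = 2 ** (1 / 3) / 2
        rec = parse_swc(swc_text([
            (1, 1, 0, 0, 0, 2, -1),
            (2, 3, 10, 0, 0, 1, 1),
            (3, 3, 15, 5, 0, round(r, 9), 2),
            (4, 3, 15, -5, 0, round(r, 9), 2),
        ]))
        m = bifurcation_metrics(rec)
        assert m["Pk"] == pytest.approx(1.5, abs=0.01)
        assert m["RP"] == m["Pk"]

    def test_unbranched_tree_flags_undefined(self):
        rec = parse_swc(swc_text([
            (1, 1, 0, 0, 0, 5, -1),
            (2, 3, 10, 0, 0, 1, 1),
        ]))
        m = bifurcation_metrics(rec)
        assert m["DR"] == 0.0
        assert "DR" in m["_undefined"]


class TestTerminal:
    def test_hillman_threshold_weighting(self, symmetric_y):
        t = terminal_metrics(symmetric_y)
        assert t["HT"] == pytest.approx(0.5 * 2 + 0.25 * 1 + 0.25 * 1)
        assert t["Lpd"] == pytest.approx(2.0)
        assert t["Dt"] == pytest.approx(1.0)

    def test_equal_diameter_degenerate_case(self):
        rec = parse_swc(swc_text([
            (1, 1, 0, 0, 0, 2, -1),
            (2, 3, 10, 0, 0, 0.5, 1),
            (3, 3, 15, 5, 0, 0.5, 2),
            (4, 3, 15, -5, 0, 0.5, 2),
        ]))
        assert terminal_metrics(rec)["HT"] == pytest.approx(1.0)

    def test_averages_over_terminal_bifurcations(self):
        # two terminal bifurcations with HT 1.5 and 1.0 -> mean 1.25
        rec = parse_swc(swc_text([
            (1, 1, 0, 0, 0, 2, -1),
            (2, 3, 10, 0, 0, 1, 1),
            (3, 3, 15, 5, 0, 0.5, 2),
            (4, 3, 15, -5, 0, 0.5, 2),
            (5, 3, 0, 10, 0, 0.5, 1),
            (6, 3, 5, 15, 0, 0.25, 5),
            (7, 3, -5, 15, 0, 0.25, 5),
        ]))
        # HT1 = 0.5*2 + 0.5*1 = 1.5; HT2 = 0.5*1 + 0.5*0.5 = 0.75
        assert terminal_metrics(rec)["HT"] == pytest.approx((1.5 + 0.75) / 2)


class TestProfile:
    def test_internal_consistency_and_determinism(self, two_stem_tree):
        p1 = compute_profile(two_stem_tree)
        p2 = compute_profile(two_stem_tree)
        assert p1.values == p2.values
        assert p1["N_br"] == p1["N_bi"] + p1["N_t"]
        assert set(p1.values) == set(CORE_METRICS)

    def test_empty_metric_set(self, two_stem_tree):
        assert compute_profile(two_stem_tree, []).values == {}

    def test_unknown_metric_lists_supported(self, two_stem_tree):
        with pytest.raises(ValueError, match="supported"):
            compute_profile(two_stem_tree, ["NOPE"])

    def test_additivity_of_summed_metrics(self):
        stem1 = [(2, 3, 10, 0, 0, 1, 1), (3, 3, 20, 0, 0, 1, 2)]
        stem2 = [(4, 3, 0, 10, 0, 0.5, 1), (5, 3, 0, 25, 0, 0.5, 4)]
        soma = [(1, 1, 0, 0, 0, 5, -1)]
        union = parse_swc(swc_text(soma + stem1 + stem2))
        only1 = parse_swc(swc_text(soma + stem1))
        only2 = parse_swc(swc_text(soma + stem2))
        for key in ("Le", "Su", "Vo"):
            assert size_metrics(union)[key] == pytest.approx(
                size_metrics(only1)[key] + size_metrics(only2)[key])

    def test_rotation_translation_invariance_of_profile(self):
        rec = random_tree(13)
        rng = np.random.default_rng(42)
        q, _ = np.linalg.qr(rng.standard_normal((3, 3)))
        shift = np.array([5.0, -3.0, 2.0])
        moved = parse_swc(swc_text([
            (n.id, n.type_code, *np.round(q @ n.position + shift, 12),
             n.radius, n.parent_id)
            for n in rec.nodes
        ]))
        p1, p2 = compute_profile(rec), compute_profile(moved)
        for key in CORE_METRICS:
            assert p2[key] == pytest.approx(p1[key], abs=1e-6), key


class TestBatchExtract:
    def test_six_files_two_classes(self, tmp_path):
        labels = {}
        for i in range(6):
            cls = "bushy" if i % 2 else "sparse"
            prob = 0.9 if i % 2 else 0.2
            text = generate_toy_swc(TreeSpec(branch_prob=prob, seed=i))
            (tmp_path / f"n{i}.swc").write_text(text)
            labels[f"n{i}"] = cls
        table = batch_extract(tmp_path, labels)
        assert table.shape == (6, len(CORE_METRICS) + 1)
        assert set(table["label"]) == {"bushy", "sparse"}

    def test_corrupt_file_skipped_with_warning(self, tmp_path):
        for i in range(5):
            (tmp_path / f"n{i}.swc").write_text(
                generate_toy_swc(TreeSpec(seed=i)))
        (tmp_path / "bad.swc").write_text("1 1 0 0 0 -5 -1\n")
        labels = {f"n{i}": "a" for i in range(5)}
        labels["bad"] = "a"
        with pytest.warns(UserWarning, match="bad.swc"):
            table = batch_extract(tmp_path, labels)
        assert len(table) == 5
        assert table.attrs["skipped"] == 1

    def test_rerun_is_identical(self, tmp_path):
        (tmp_path / "n0.swc").write_text(generate_toy_swc(TreeSpec(seed=5)))
        t1 = batch_extract(tmp_path, {"n0": "x"})
        t2 = batch_extract(tmp_path, {"n0": "x"})
        assert t1.equals(t2)

    def test_zero_parseable_files_is_error(self, tmp_path):
        (tmp_path / "bad.swc").write_text("not swc\n")
        with pytest.raises(ValueError), pytest.warns(UserWarning):
            batch_extract(tmp_path, {"bad": "a"})
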