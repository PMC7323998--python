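import numpy as np
import pytest

from crestrack import fate
from crestrack.geometry import Box, Sphere
from crestrack.lineage import LineageForest, Segment
from crestrack.simulate import build_embryo_model, simulate_populations
from tests.conftest import coarse_config


def toy_forest(labels_by_tree):
    """Build a forest of simple trees; each entry is a list of leaf labels.

    Each tree is a root dividing into len(labels) leaves via a binary comb.
    Returns (forest, labels dict keyed by leaf segment id).
    """
    segs, labels = [], {}
    sid = 0
    frame = 0
    for leaf_labels in labels_by_tree:
        if len(leaf_labels) == 1:
            segs.append(Segment(sid, None, 0, 10, np.zeros((11, 3))))
            labels[sid] = leaf_labels[0]
            sid += 1
            continue
        root = sid
        segs.append(Segment(root, None, 0, 4, np.zeros((5, 3))))
        sid += 1
        parent = root
        for k, lab in enumerate(leaf_labels):
            if k < len(leaf_labels) - 1 and k > 0:
                # internal continuation for comb shape
                pass
        # binary division: root -> two leaves (supports 2 labels)
        for lab in leaf_labels[:2]:
            segs.append(Segment(sid, root, 5, 10, np.zeros((6, 3))))
            labels[sid] = lab
            sid += 1
    forest = LineageForest(segs, dt_h=1.0, t_start_hpf=0.0)
    for s in forest.terminals():
        labels.setdefault(s.segment_id, "unlabelled")
    return forest, labels


class TestSelection:
    def test_whole_field_selects_all_alive(self, default_forest):
        model, truth, forest = default_forest
        region = Box((-1e6,) * 3, (1e6,) * 3)
        sel = fate.select_cells(forest, region, 20.0)
        frame = forest.frame_of_time(20.0)
        assert sel == {s.segment_id for s in forest.alive_at(frame)}

    def test_disjoint_region_is_empty(self, default_forest):
        _, _, forest = default_forest
        assert fate.select_cells(forest, Sphere((9e5, 0, 0), 1.0), 20.0) == set()

    def test_proximal_eye_selection_at_17_is_pure_early_wave(self, default_forest):
        model, truth, forest = default_forest
        region = model.eye_shell(6.0) & model.proximal_half()
        sel = fate.select_cells(forest, region, 17.0)
        assert sel
        assert all(forest.segments[s].population == "1NC" for s in sel)


class TestPropagation:
    def test_forward_from_roots_covers_everything(self, default_forest):
        _, truth, forest = default_forest
        roots = {r.segment_id for r in forest.roots()}
        prop = fate.propagate_selection(
            forest, roots, truth.config.t_start_hpf, truth.config.t_end_hpf, "forward"
        )
        assert prop.segment_ids == set(forest.segments)

    def test_backward_includes_parent_segment(self, default_forest):
        _, truth, forest = default_forest
        child = next(s for s in forest.terminals() if s.parent_id is not None)
        t_child = forest.time_of_frame(child.start_frame) + 0.2
        prop = fate.propagate_selection(
            forest, {child.segment_id}, t_child, truth.config.t_start_hpf, "backward"
        )
        assert child.parent_id in prop.segment_ids

    def test_backward_origin_of_late_wave_is_mediodorsal(self, default_forest):
        model, truth, forest = default_forest
        labels = fate.classify_destination(forest, model, 30.0)
        distal = {
            s.segment_id for s in forest.terminals()
            if labels[s.segment_id] == "distal" and s.population == "2NC"
        }
        prop = fate.propagate_selection(forest, distal, 24.0, 11.0, "backward")
        roots = {forest.root_of(s) for s in distal}
        origins = np.array(
            [forest.segments[r].positions[0] for r in roots]
        )
        inside = model.origin_zone_2nc(origins)
        assert inside.mean() >= 0.8

    def test_unknown_selection_ids_raise(self, default_forest):
        _, _, forest = default_forest
        with pytest.raises(ValueError, match="absent"):
            fate.propagate_selection(forest, {999999}, 17.0, 11.0, "backward")

    def test_forward_of_backward_contains_selection(self, default_forest):
        _, truth, forest = default_forest
        region_sel = {s.segment_id for s in forest.alive_at(forest.frame_of_time(24.0))}
        back = fate.propagate_selection(forest, region_sel, 24.0, 11.0, "backward")
        fwd = fate.propagate_selection(
            forest, back.segment_ids & {r.segment_id for r in forest.roots()},
            11.0, 31.0, "forward",
        )
        assert region_sel <= fwd.segment_ids


class TestClassification:
    def test_pole_labels(self, default_forest):
        model, truth, forest = default_forest
        # synthetic one-cell forests pinned at the poles
        n = truth.config.n_frames
        for point, expect in (
            (model.lens_center, "distal"),
            (model.eye_center - model.eye_radius * model.u, "proximal"),
        ):
            seg = Segment(0, None, 0, n - 1, np.tile(point, (n, 1)))
            f = LineageForest([seg], dt_h=truth.config.dt_h,
                              t_start_hpf=truth.config.t_start_hpf)
            labels = fate.classify_destination(f, model, 30.0)
            assert labels[0] == expect

    def test_equatorial_tie_breaks_proximal(self, default_forest):
        model, truth, _ = default_forest
        n = truth.config.n_frames
        p = model.eye_center + model.eye_radius * model.axis_dv  # on equator plane
        seg = Segment(0, None, 0, n - 1, np.tile(p, (n, 1)))
        f = LineageForest([seg], dt_h=truth.config.dt_h,
                          t_start_hpf=truth.config.t_start_hpf)
        assert fate.classify_destination(f, model, 30.0, margin_um=0.0)[0] == "proximal"

    def test_every_terminal_gets_exactly_one_label(self, default_forest):
        model, _, forest = default_forest
        labels = fate.classify_destination(forest, model, 30.0)
        terms = forest.terminals()
        assert set(labels) == {s.segment_id for s in terms}
        allowed = {"proximal", "distal", "periocular", "unlabelled"}
        assert all(v in allowed for v in labels.values())

    def test_population_versus_label_confusion_is_low(self):
        # averaged over embryos: off-diagonal (wrong-compartment) cells stay
        # within the stray-branch budget of the mixing program
        rates = []
        for seed in range(5):
            cfg = coarse_config(seed=seed)
            model = build_embryo_model(cfg)
            truth = simulate_populations(model, cfg)
            forest = LineageForest.from_truth(truth)
            labels = fate.classify_destination(forest, model, 30.0)
            pairs = [
                (s.population, labels[s.segment_id])
                for s in forest.terminals()
                if labels[s.segment_id] in ("proximal", "distal")
            ]
            off = sum(1 for p, l in pairs if (p == "1NC") != (l == "proximal"))
            rates.append(off / len(pairs))
        assert np.mean(rates) <= 0.05


class TestHomogeneity:
    def test_printed_totals_arithmetic(self):
        rep = fate.HomogeneityReport.from_counts(113, 10)
        assert rep.percent_homogeneous == 91
        assert rep.percent_mixed == 9
        assert np.isclose(rep.fraction_homogeneous, 103 / 113)

    def test_all_singletons_same_label(self):
        forest, labels = toy_forest([["proximal"], ["proximal"], ["proximal"]])
        rep = fate.lineage_homogeneity(forest, labels)
        assert rep.n_lineages == 3 and rep.percent_homogeneous == 100

    def test_one_mixed_of_three(self):
        forest, labels = toy_forest(
            [["proximal", "distal"], ["distal", "distal"], ["proximal"]]
        )
        rep = fate.lineage_homogeneity(forest, labels)
        assert rep.n_mixed == 1 and rep.n_lineages == 3
        assert np.isclose(rep.fraction_homogeneous, 2 / 3)

    def test_periocular_terminals_do_not_make_a_lineage_mixed(self):
        forest, labels = toy_forest([["distal", "periocular"], ["periocular"]])
        rep = fate.lineage_homogeneity(forest, labels)
        assert rep.n_lineages == 1 and rep.n_mixed == 0
        assert rep.n_excluded == 1

    def test_missing_labels_raise(self, default_forest):
        _, _, forest = default_forest
        with pytest.raises(ValueError, match="missing"):
            fate.lineage_homogeneity(forest, {})

    @pytest.mark.parametrize("f_mix", [0.0, 0.09, 0.5])
    def test_programmed_mixing_fraction_is_recovered(self, f_mix):
        n_mixed = n_lin = 0
        for seed in range(5):
            cfg = coarse_config(seed=seed, mixing_fraction=f_mix)
            model = build_embryo_model(cfg)
            truth = simulate_populations(model, cfg)
            forest = LineageForest.from_truth(truth)
            labels = fate.classify_destination(forest, model, 30.0)
            rep = fate.lineage_homogeneity(forest, labels)
            n_mixed += rep.n_mixed
            n_lin += rep.n_lineages
        assert n_lin >= 200
        ci = 1.96 * np.sqrt(f_mix * (1 - f_mix) / n_lin)
        assert f_mix - ci <= n_mixed / n_lin <= f_mix + ci


class TestPenetrance:
    @pytest.mark.parametrize(
        "a,n,expected",
        [(9, 23, "39% (9/23)"), (0, 9, "0% (0/9)"), (5, 5, "100% (5/5)"),
         (7, 8, "88% (7/8)"), (3, 12, "25% (3/12)")],
    )
    def test_formatting(self, a, n, expected):
        outcomes = [("g", True)] * a + [("g", False)] * (n - a)
        rep = fate.penetrance_table(outcomes)
        assert rep.formatted("g") == expected

    def test_grouping_by_genotype(self):
        rep = fate.penetrance_table(
            [("wt", False), ("wt", False), ("mut", True), ("mut", False)]
        )
        assert rep.rows["wt"].percent == 0
        assert rep.rows["mut"].formatted == "50% (1/2)"


class TestDefectCall:
    @pytest.mark.parametrize(
        "genotype,expected",
        [("wildtype", False), ("pax6b_null", True), ("pax6_double_null", True)],
    )
    def test_genotype_calls(self, genotype, expected):
        cfg = coarse_config(seed=0, genotype=genotype, mixing_fraction=0.0)
        model = build_embryo_model(cfg)
        truth = simulate_populations(model, cfg)
        forest = LineageForest.from_truth(truth)
        labels = fate.classify_destination(forest, model, 30.0)
        affected, _ = fate.defect_call(forest, labels)
        assert affected is expected

    def test_double_mutant_sends_early_wave_distal(self):
        cfg = coarse_config(seed=0, genotype="pax6_double_null", mixing_fraction=0.0)
        model = build_embryo_model(cfg)
        truth = simulate_populations(model, cfg)
        forest = LineageForest.from_truth(truth)
        labels = fate.classify_destination(forest, model, 30.0)
        _, counts = fate.defect_call(forest, labels)
        assert counts["n_2nc_distal"] == 0
        assert counts["n_1nc_distal"] > 0

    def test_empty_forest_is_affected_with_flag(self):
        forest = LineageForest([], dt_h=1.0, t_start_hpf=0.0)
        affected, info = fate.defect_call(forest, {})
        assert affected and "flag" in info
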