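"""Binarization, threshold grids, sweeps, count curves and persistence."""

import numpy as np
import pytest

from kfca.context import build_lattice
from kfca.expression import ExpressionMatrix
from kfca.simulate import generate_expression, generate_plan, score_recovery
from kfca.sweep import (
    KFCABiclusterer,
    bicluster_norm,
    binarize_over,
    binarize_under,
    concept_count_curve,
    persistence,
    persistence_report,
    sequence_from_json,
    sequence_to_json,
    slope_change_points,
    sweep,
    threshold_grid,
)

from conftest import random_context  # noqa: F401  (shared helpers live there)


def _random_matrix(seed, m, n, lo=-1.0, hi=1.0):
    rng = np.random.default_rng(seed)
    return ExpressionMatrix(
        rng.uniform(lo, hi, size=(m, n)),
        [f"g{i + 1}" for i in range(m)],
        [f"c{j + 1}" for j in range(n)],
    )


class TestBinarize:
    def test_under_threshold_below_min_is_empty(self, small_matrix):
        ctx = binarize_under(small_matrix, -5.0)
        assert not ctx.incidence.any()
        assert len(build_lattice(ctx)) == 2

    def test_under_threshold_at_max_is_full(self, small_matrix):
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            ctx = binarize_under(small_matrix, 2.0)
        assert ctx.incidence.all()
        assert len(build_lattice(ctx)) == 1

    def test_under_hand_checked_incidence(self, small_matrix):
        ctx = binarize_under(small_matrix, -1.0)
        expected = np.array(
            [[1, 0, 1], [0, 1, 0], [1, 1, 1]], dtype=bool
        )
        np.testing.assert_array_equal(ctx.incidence, expected)

    def test_over_hand_checked_incidence(self, small_matrix):
        ctx = binarize_over(small_matrix, 1.0)
        expected = np.array(
            [[0, 1, 0], [0, 0, 1], [0, 0, 0]], dtype=bool
        )
        np.testing.assert_array_equal(ctx.incidence, expected)

    def test_over_above_max_is_empty(self, small_matrix):
        assert not binarize_over(small_matrix, 3.0).incidence.any()

    def test_trichotomy_at_zero(self):
        em = _random_matrix(31, 12, 5)
        em.values[0, 0] = 0.0  # plant an exact zero
        under = binarize_under(em, 0.0).incidence
        over = binarize_over(em, 0.0).incidence
        assert (under | over).all()
        np.testing.assert_array_equal(under & over, em.values == 0.0)

    def test_wrong_sign_threshold_warns_but_runs(self, small_matrix):
        with pytest.warns(UserWarning, match="positive"):
            binarize_under(small_matrix, 0.5)
        with pytest.warns(UserWarning, match="negative"):
            binarize_over(small_matrix, -0.5)


class TestBiclusterNorm:
    def test_singleton_bicluster_is_the_cell_value(self, small_matrix):
        from kfca.context import Concept

        c = Concept(frozenset({"g2"}), frozenset({"c2"}))
        assert bicluster_norm(small_matrix, c, "under") == -3.0
        assert bicluster_norm(small_matrix, c, "over") == -3.0

    def test_empty_sides_are_errors(self, small_matrix):
        from kfca.context import Concept

        with pytest.raises(ValueError, match="undefined"):
            bicluster_norm(small_matrix, Concept(frozenset(), frozenset({"c1"})), "under")

    @pytest.mark.parametrize("direction", ["under", "over"])
    def test_norm_consistency_across_swept_lattices(self, direction):
        """Every non-degenerate concept of a thresholded lattice clears the
        threshold: max-norm <= phi for under, min-norm >= phi for over."""
        for seed in (41, 42):
            em = _random_matrix(seed, 12, 5)
            grid = threshold_grid(em, direction, max_points=6)
            seq = sweep(em, direction, grid)
            for t in seq.thresholds:
                for c in seq.lattices[t].concepts:
                    if not c.extent or not c.intent:
                        continue
                    norm = bicluster_norm(em, c, direction)
                    assert norm <= t if direction == "under" else norm >= t

    def test_maximality_of_concepts_small_exhaustive(self):
        """Adding any gene or condition to a swept concept breaks the bound."""
        em = _random_matrix(43, 6, 4)
        phi = float(np.median(em.values[em.values <= 0]))
        ctx = binarize_under(em, phi)
        for c in build_lattice(ctx).concepts:
            if not c.extent or not c.intent:
                continue
            for g in set(em.gene_ids) - c.extent:
                from kfca.context import Concept

                grown = Concept(c.extent | {g}, c.intent)
                assert bicluster_norm(em, grown, "under") > phi
            for cond in set(em.condition_ids) - c.intent:
                from kfca.context import Concept

                grown = Concept(c.extent, c.intent | {cond})
                assert bicluster_norm(em, grown, "under") > phi


class TestThresholdGrid:
    def test_observed_values_split_by_sign(self):
        em = ExpressionMatrix([[-0.3, -0.1, 0.2]], ["g1"], ["a", "b", "c"])
        assert threshold_grid(em, "under") == [-0.3, -0.1]
        assert threshold_grid(em, "over") == [0.2]

    def test_empty_side_warns_and_returns_empty(self):
        em = ExpressionMatrix([[0.5, 1.0]], ["g1"], ["a", "b"])
        with pytest.warns(UserWarning, match="empty grid"):
            assert threshold_grid(em, "under") == []

    def test_include_zero_appends_synthetic_origin(self):
        em = ExpressionMatrix([[-0.3, 0.2]], ["g1"], ["a", "b"])
        assert threshold_grid(em, "under", include_zero=True) == [-0.3, 0.0]

    def test_histogram_decimation_matches_oracle(self):
        em = _random_matrix(44, 50, 5)
        got = threshold_grid(em, "under", max_points=10)
        assert len(got) == 10
        # oracle: equal-width bins over in-range values, value nearest centre
        vals = np.unique(em.values)
        vals = vals[vals <= 0]
        edges = np.linspace(vals.min(), vals.max(), 11)
        expected = []
        for b in range(10):
            hi_ok = vals <= edges[b + 1] if b == 9 else vals < edges[b + 1]
            inbin = vals[(vals >= edges[b]) & hi_ok]
            if inbin.size:
                centre = (edges[b] + edges[b + 1]) / 2
                expected.append(float(inbin[np.argmin(np.abs(inbin - centre))]))
        assert got == sorted(expected)

    def test_grid_values_come_from_the_data(self):
        em = _random_matrix(45, 20, 4)
        observed = set(np.unique(em.values))
        for t in threshold_grid(em, "under", max_points=7):
            assert t in observed


class TestSweep:
    def test_single_threshold_equals_direct_construction(self):
        em = _random_matrix(46, 8, 4)
        seq = sweep(em, "under", [-0.2])
        direct = build_lattice(binarize_under(em, -0.2))
        assert seq.lattices[-0.2].concepts == direct.concepts

    def test_under_contexts_nest_with_threshold(self):
        em = _random_matrix(47, 12, 5)
        grid = threshold_grid(em, "under", max_points=8)
        incid = [binarize_under(em, t).incidence for t in grid]
        for a, b in zip(incid, incid[1:]):
            assert not (a & ~b).any()  # a subset of b

    def test_over_contexts_nest_the_other_way(self):
        em = _random_matrix(48, 12, 5)
        grid = threshold_grid(em, "over", max_points=8)
        incid = [binarize_over(em, t).incidence for t in grid]
        for a, b in zip(incid, incid[1:]):
            assert not (b & ~a).any()

    def test_unsorted_grid_rejected(self):
        em = _random_matrix(49, 4, 3)
        with pytest.raises(ValueError, match="increasing"):
            sweep(em, "under", [-0.1, -0.5])

    def test_planted_modules_appear_as_concepts_between_level_and_zero(self):
        plan = generate_plan(30, 8, 2, 0.15, (-1.0, -1.0), 0.0, seed=50, disjoint=True)
        em = generate_expression(plan)
        for phi in (-0.9, -0.5, -0.1):
            lat = build_lattice(binarize_under(em, phi))
            concepts = set(lat.concepts)
            for k in range(plan.p):
                from kfca.context import Concept

                assert Concept(plan.module_genes(k), plan.module_conditions(k)) in concepts

    def test_sequence_json_round_trip(self):
        em = _random_matrix(51, 8, 4)
        seq = sweep(em, "under", threshold_grid(em, "under", max_points=4))
        back = sequence_from_json(sequence_to_json(seq))
        assert back.direction == seq.direction
        assert back.thresholds == seq.thresholds
        for t in seq.thresholds:
            assert back.lattices[t].concepts == seq.lattices[t].concepts


class TestCountCurve:
    def test_degenerate_extremes(self, small_matrix):
        import warnings

        seq = sweep(small_matrix, "under", [-5.0])
        assert concept_count_curve(seq) == [(-5.0, 2)]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            seq = sweep(small_matrix, "under", [2.0])
        assert concept_count_curve(seq) == [(2.0, 1)]

    def test_counts_match_per_threshold_enumeration(self):
        from kfca.context import enumerate_concepts

        em = _random_matrix(52, 12, 5)
        grid = threshold_grid(em, "under", max_points=6)
        seq = sweep(em, "under", grid)
        curve = concept_count_curve(seq)
        for (t, count) in curve:
            assert count == len(enumerate_concepts(binarize_under(em, t)))

    def test_counts_are_monotone_along_an_under_sweep_of_nested_contexts(self):
        # not a theorem in general, but on a powerset-reaching fixture the
        # curve must end at the full-incidence count of 1
        em = ExpressionMatrix([[-1.0, -2.0]], ["g1"], ["a", "b"])
        seq = sweep(em, "under", [-2.0, -1.0])
        assert [c for _, c in concept_count_curve(seq)] == [2, 1]


class TestSlopeChange:
    def test_linear_curve_has_zero_second_difference(self):
        curve = [(-0.5, 10), (-0.4, 20), (-0.3, 30), (-0.2, 40)]
        pts = slope_change_points(curve, 2)
        assert len(pts) == 2  # all ties at zero magnitude, nearest 0 first
        assert pts == [-0.3, -0.4]

    def test_step_jump_ranks_first(self):
        curve = [(-0.5, 5), (-0.4, 5), (-0.3, 50), (-0.2, 50)]
        assert slope_change_points(curve, 1)[0] in (-0.4, -0.3)

    def test_matches_direct_second_difference(self):
        rng = np.random.default_rng(53)
        ts = np.sort(rng.uniform(-1, 0, size=12))
        counts = rng.integers(2, 200, size=12)
        curve = list(zip(ts.tolist(), counts.tolist()))
        got = slope_change_points(curve, 3)
        d2 = {ts[i]: abs(counts[i + 1] - 2 * counts[i] + counts[i - 1]) for i in range(1, 11)}
        expected = sorted(d2, key=lambda t: (-d2[t], abs(t)))[:3]
        assert got == expected

    def test_short_curve_rejected_and_k_clamped(self):
        with pytest.raises(ValueError):
            slope_change_points([(-0.1, 1), (0.0, 2)], 1)
        curve = [(-0.3, 1), (-0.2, 5), (-0.1, 2)]
        assert len(slope_change_points(curve, 10)) == 1


class TestPersistence:
    def test_ever_present_intent_spans_the_grid(self):
        plan = generate_plan(20, 6, 1, 0.2, (-1.0, -1.0), 0.0, seed=54)
        em = generate_expression(plan)
        grid = [-0.9, -0.5, -0.1]
        seq = sweep(em, "under", grid)
        rec = persistence(seq, plan.module_conditions(0))
        assert rec.present_at == (-0.9, -0.5, -0.1)
        assert rec.interval == (-0.9, -0.1)
        assert rec.span == pytest.approx(0.8)

    def test_absent_intent_yields_empty_record(self):
        em = _random_matrix(55, 6, 4)
        seq = sweep(em, "under", threshold_grid(em, "under", max_points=3))
        rec = persistence(seq, {"c1", "c4"} if True else set())
        if rec.present_at == ():
            assert rec.interval is None and rec.span is None

    def test_presence_matches_per_threshold_reenumeration(self):
        plan = generate_plan(25, 6, 2, 0.2, (-1.0, -0.6), 0.1, seed=56, disjoint=True)
        em = generate_expression(plan)
        grid = threshold_grid(em, "under", max_points=6)
        seq = sweep(em, "under", grid)
        intent = plan.module_conditions(0)
        rec = persistence(seq, intent)
        expected = []
        for t in grid:
            lat = build_lattice(binarize_under(em, t))
            if any(c.intent == intent and c.extent for c in lat.concepts):
                expected.append(t)
        assert list(rec.present_at) == expected

    def test_report_sorted_by_span(self):
        em = _random_matrix(57, 10, 4)
        seq = sweep(em, "under", threshold_grid(em, "under", max_points=5))
        report = persistence_report(seq)
        spans = [r.span or 0.0 for r in report]
        assert spans == sorted(spans, reverse=True)


class TestEstimator:
    def test_fit_exposes_sequence_and_biclusters(self):
        em = _random_matrix(58, 15, 5)
        model = KFCABiclusterer(direction="under", max_points=5).fit(em.to_frame())
        assert model.thresholds_ == model.sequence_.thresholds
        assert model.rows_.shape[1] == 15
        assert model.columns_.shape[1] == 5
        assert model.rows_.shape[0] == model.columns_.shape[0]
        # reference lattice is the threshold nearest zero
        assert model.reference_threshold_ == min(model.thresholds_, key=abs)

    def test_biclusters_are_all_ones_submatrices_of_the_incidence(self):
        em = _random_matrix(59, 12, 4)
        model = KFCABiclusterer(direction="under", max_points=4).fit(em.values)
        inc = em.values <= model.reference_threshold_
        for rows, cols in zip(model.rows_, model.columns_):
            assert inc[np.ix_(rows, cols)].all()

    def test_get_params_set_params_round_trip(self):
        model = KFCABiclusterer(direction="over", max_points=7, include_zero=False)
        params = model.get_params()
        clone = KFCABiclusterer().set_params(**params)
        assert clone.get_params() == params

    def test_explicit_grid_and_reference(self):
        em = _random_matrix(60, 8, 4)
        model = KFCABiclusterer(
            direction="under", grid=[-0.5, -0.1], reference_threshold=-0.5
        ).fit(em)
        assert model.reference_threshold_ == -0.5
        assert model.thresholds_ == (-0.5, -0.1)
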