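"""PCA axis inference, orthogonalization, orientation and projection."""

import numpy as np
import pandas as pd
import pytest

import resilax as rx
from resilax.axes import fit_principal_axes, orthogonalize, select_component

from conftest import make_axis, make_dataset


def standardized(ds):
    st = rx.fit_standardizer(ds)
    return rx.apply_standardizer(ds, st), st


class TestPrincipalAxes:
    def test_axes_are_orthonormal_with_ordered_variance(self):
        rng = np.random.default_rng(0)
        ds = make_dataset(rng.normal(5, 2, (30, 12)))
        std, _ = standardized(ds)
        comps = fit_principal_axes(std, 5)
        V = np.stack([v for v, _ in comps])
        np.testing.assert_allclose(V @ V.T, np.eye(5), atol=1e-9)
        fracs = [f for _, f in comps]
        assert all(a >= b for a, b in zip(fracs, fracs[1:]))
        assert sum(fracs) <= 1 + 1e-12

    def test_planted_rank_one_direction_is_recovered(self):
        rng = np.random.default_rng(1)
        direction = rng.normal(size=40)
        direction /= np.linalg.norm(direction)
        scores = rng.normal(size=15) * 5
        X = np.outer(direction, scores) + rng.normal(scale=0.01, size=(40, 15))
        ds = make_dataset(X + 6.0)
        std, _ = standardized(ds)
        (v, frac), *_ = fit_principal_axes(std, 2)
        # compare in the standardized space: rescale the planted direction
        st = rx.fit_standardizer(ds)
        planted = direction / st.sd
        planted /= np.linalg.norm(planted)
        assert abs(v @ planted) > 0.99

    def test_k_beyond_rank_is_rejected(self):
        rng = np.random.default_rng(2)
        ds = make_dataset(rng.normal(5, 2, (10, 4)))
        std, _ = standardized(ds)
        with pytest.raises(ValueError, match="rank"):
            fit_principal_axes(std, 4)


class TestSelectComponent:
    def _nuisance_plus_trend(self, trend_strength):
        rng = np.random.default_rng(3)
        n_genes, n = 60, 14
        nuisance = rng.normal(size=n_genes)
        trend_dir = rng.normal(size=n_genes)
        t = np.arange(n, dtype=float)
        X = (np.outer(nuisance, rng.normal(size=n) * 4)
             + np.outer(trend_dir, (t - t.mean()) / t.std() * trend_strength)
             + rng.normal(scale=0.1, size=(n_genes, n)))
        ds = make_dataset(X + 6.0, t_dev=44 + t)
        std, _ = standardized(ds)
        comps = fit_principal_axes(std, 5)
        scores = np.stack([std.values.to_numpy().T @ v for v, _ in comps])
        return comps, scores, ds.samples["t_dev"].to_numpy()

    def test_modes_agree_when_trend_is_second(self):
        comps, scores, t = self._nuisance_plus_trend(trend_strength=2.0)
        assert select_component(comps, t, scores, "fixed_second") == 2
        assert select_component(comps, t, scores, "max_association") == 2

    def test_dominant_trend_splits_the_modes(self, caplog):
        comps, scores, t = self._nuisance_plus_trend(trend_strength=30.0)
        assert select_component(comps, t, scores, "fixed_second") == 2
        with caplog.at_level("WARNING"):
            assert select_component(comps, t, scores, "max_association") == 1
        assert "not the usual component 2" in caplog.text

    def test_constant_covariate_rejected(self):
        comps, scores, t = self._nuisance_plus_trend(2.0)
        with pytest.raises(ValueError, match="constant"):
            select_component(comps, np.ones_like(t), scores, "max_association")

    def test_fewer_than_two_components_rejected(self):
        comps, scores, t = self._nuisance_plus_trend(2.0)
        with pytest.raises(ValueError, match="at least 2"):
            select_component(comps[:1], t, scores[:1], "fixed_second")


class TestOrthogonalize:
    def test_already_orthogonal_axes_unchanged(self):
        h = orthogonalize(make_axis([1, 0, 0]), make_axis([0, 1, 0]))
        np.testing.assert_allclose(h.loadings, [1, 0, 0], atol=1e-12)
        assert h.confound_overlap == pytest.approx(0.0, abs=1e-12)

    def test_diagonal_candidate_loses_confound_component(self):
        cand = make_axis(np.array([1, 1, 0]) / np.sqrt(2))
        conf = make_axis([1, 0, 0])
        h = orthogonalize(cand, conf)
        np.testing.assert_allclose(h.loadings, [0, 1, 0], atol=1e-12)
        assert h.confound_overlap == pytest.approx(1 / np.sqrt(2))

    def test_parallel_axes_are_degenerate(self):
        with pytest.raises(ValueError, match="degenerate"):
            orthogonalize(make_axis([1, 0, 0]), make_axis([1, 0, 0]))

    def test_result_orthogonal_to_confound_in_its_space(self):
        rng = np.random.default_rng(4)
        # different per-gene scales on the two axes: orthogonality holds in
        # the candidate's standardized coordinates
        cand = make_axis(rng.normal(size=30), sd=rng.uniform(0.5, 2.0, 30))
        conf = make_axis(rng.normal(size=30), sd=rng.uniform(0.5, 2.0, 30))
        h = orthogonalize(cand, conf)
        assert abs(h.dot(conf)) < 1e-9
        assert np.linalg.norm(h.loadings) == pytest.approx(1.0, abs=1e-9)


class TestOrientationAndProjection:
    def _axis_and_data(self):
        rng = np.random.default_rng(5)
        n_genes, n = 25, 10
        direction = rng.normal(size=n_genes)
        t = np.arange(n, dtype=float)
        X = np.outer(direction, t - t.mean()) + rng.normal(scale=0.05, size=(n_genes, n))
        ds = make_dataset(X + 5.0, t_dev=44 + t)
        st = rx.fit_standardizer(ds)
        std = rx.apply_standardizer(ds, st)
        (v, frac), *_ = fit_principal_axes(std, 2)
        axis = rx.Axis("D", v, std.gene_ids, st.subset(std.gene_ids),
                       component_index=1, variance_explained=frac)
        return axis, ds

    def test_orientation_makes_scores_increase_and_is_idempotent(self):
        axis, ds = self._axis_and_data()
        oriented = rx.orient_axis(axis, ds, "t_dev")
        proj = rx.project(ds, oriented)
        assert np.corrcoef(proj["score"], proj["t_dev"])[0, 1] > 0.99
        again = rx.orient_axis(oriented, ds, "t_dev")
        np.testing.assert_array_equal(again.loadings, oriented.loadings)
        flipped = rx.orient_axis(oriented.flipped(), ds, "t_dev")
        np.testing.assert_allclose(flipped.loadings, oriented.loadings)

    def test_training_mean_profile_projects_to_zero(self):
        axis, ds = self._axis_and_data()
        probe = make_dataset(axis.standardizer.mean[:, None])
        proj = rx.project(probe, axis)
        assert abs(proj["score"].iloc[0]) < 1e-9

    def test_projection_is_linear_in_standardized_space(self):
        axis, ds = self._axis_and_data()
        st = axis.standardizer
        rng = np.random.default_rng(6)
        za, zb = rng.normal(size=(2, len(st.gene_ids)))
        alpha, beta = 1.7, -0.4
        def score(z):
            probe = make_dataset((st.mean + st.sd * z)[:, None])
            return rx.project(probe, axis)["score"].iloc[0]
        lhs = score(alpha * za + beta * zb)
        assert lhs == pytest.approx(alpha * score(za) + beta * score(zb), rel=1e-9)

    def test_projection_invariant_to_gene_order(self):
        axis, ds = self._axis_and_data()
        shuffled = ds.subset_genes(list(ds.gene_ids[::-1]))
        a = rx.project(ds, axis)["score"]
        b = rx.project(shuffled, axis)["score"]
        np.testing.assert_allclose(a, b, atol=1e-12)


class TestDeriveAxisPair:
    def test_pipeline_is_deterministic_bit_for_bit(self, default_study):
        ds = rx.filter_low_expression(default_study.dataset, 4.5)
        from resilax.workflow import reference_axes
        d1, h1 = reference_axes(ds)
        d2, h2 = reference_axes(ds)
        np.testing.assert_array_equal(d1.loadings, d2.loadings)
        np.testing.assert_array_equal(h1.loadings, h2.loadings)

    def test_save_load_round_trip(self, default_results, tmp_path):
        axis = default_results.axis_h
        rx.save_axis(axis, tmp_path / "H")
        back = rx.load_axis(tmp_path / "H")
        np.testing.assert_allclose(back.loadings, axis.loadings, atol=1e-11)
        assert back.name == axis.name
        assert back.component_index == axis.component_index
        assert back.confound_overlap == pytest.approx(axis.confound_overlap)
        np.testing.assert_allclose(back.standardizer.sd, axis.standardizer.sd,
                                   rtol=1e-10)
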