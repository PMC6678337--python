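"""EM core: E-step/M-step correctness against enumeration oracles,
assignment rules, likelihood monotonicity and fit behaviour."""

import numpy as np
import pytest
from scipy.stats import norm

import scina
from scina import (
    ExpressionMatrix,
    FitOptions,
    ModelParams,
    SignatureSet,
    assign,
    e_step,
    fit,
    log_likelihood,
    m_step,
)
from scina.simulate import SimulationConfig, simulate_dataset

from oracles import posterior_oracle, weighted_moments_oracle


def _expr(values, gene_ids=None):
    values = np.atleast_2d(np.asarray(values, float))
    g, n = values.shape
    return ExpressionMatrix(
        gene_ids=np.asarray(gene_ids or [f"g{i}" for i in range(g)], dtype=object),
        cell_ids=np.asarray([f"c{i}" for i in range(n)], dtype=object),
        values=values,
    )


def _params(genes, class_names, mu_high, mu_low, sd_high, sd_low, tau):
    return ModelParams(
        genes=list(genes),
        class_names=list(class_names),
        mu_high=np.asarray(mu_high, float),
        mu_low=np.asarray(mu_low, float),
        sd_high=np.asarray(sd_high, float),
        sd_low=np.asarray(sd_low, float),
        tau=np.asarray(tau, float),
    )


class TestEStep:
    def test_degenerate_prior_forces_class(self):
        expr = _expr([[1.0, 2.0, 3.0]])
        sigs = SignatureSet({"A": ["g0"], "B": ["g0"]})
        params = _params(["g0"], ["A", "B", "unknown"], [4], [0], [1], [1], [1, 0, 0])
        post = e_step(params, expr, sigs)
        np.testing.assert_allclose(post, np.tile([1.0, 0.0, 0.0], (3, 1)))

    def test_symmetric_setup_gives_half_half(self):
        # two disjoint one-gene signatures, mirrored parameters, cell equidistant
        expr = _expr([[2.0], [2.0]])
        sigs = SignatureSet({"A": ["g0"], "B": ["g1"]})
        params = _params(
            ["g0", "g1"], ["A", "B"], [4, 4], [0, 0], [1, 1], [1, 1], [0.5, 0.5]
        )
        post = e_step(params, expr, sigs)
        np.testing.assert_allclose(post[0], [0.5, 0.5], atol=1e-12)

    def test_fixed_params_two_types_matches_enumeration(self):
        # no M-step involved: posterior for a cell at (4, 0) by direct enumeration
        expr = _expr([[4.0], [0.0]])
        sigs = SignatureSet({"A": ["g0"], "B": ["g1"]})
        params = _params(
            ["g0", "g1"],
            ["A", "B", "unknown"],
            [4, 4],
            [0, 0],
            [1, 1],
            [1, 1],
            [1 / 3, 1 / 3, 1 / 3],
        )
        post = e_step(params, expr, sigs)
        expected, _ = posterior_oracle(
            expr.values,
            ["g0", "g1"],
            [{"g0"}, {"g1"}, set()],
            np.array([4.0, 4.0]),
            np.array([0.0, 0.0]),
            np.array([1.0, 1.0]),
            np.array([1.0, 1.0]),
            np.array([1 / 3, 1 / 3, 1 / 3]),
        )
        np.testing.assert_allclose(post, expected, atol=1e-12)

    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
    def test_random_small_instance_matches_oracle(self, seed):
        rng = np.random.default_rng(seed)
        genes = ["g0", "g1", "g2"]
        class_genes = [{"g0", "g1"}, {"g2"}, set()]
        expr = _expr(rng.normal(2, 2, size=(3, 5)))
        tau = rng.dirichlet(np.ones(3))
        params = _params(
            genes,
            ["A", "B", "unknown"],
            rng.uniform(3, 5, 3),
            rng.uniform(-0.5, 0.5, 3),
            rng.uniform(0.5, 2, 3),
            rng.uniform(0.5, 2, 3),
            tau,
        )
        sigs = SignatureSet({"A": ["g0", "g1"], "B": ["g2"]})
        post = e_step(params, expr, sigs)
        expected, ll_expected = posterior_oracle(
            expr.values, genes, class_genes,
            params.mu_high, params.mu_low, params.sd_high, params.sd_low, tau,
        )
        np.testing.assert_allclose(post, expected, atol=1e-10)
        assert log_likelihood(params, expr, sigs) == pytest.approx(ll_expected, abs=1e-10)

    def test_rows_sum_to_one(self):
        rng = np.random.default_rng(11)
        expr = _expr(rng.normal(1, 3, size=(4, 50)))
        sigs = SignatureSet({"A": ["g0", "g1"], "B": ["g2", "g3"]})
        params = _params(
            ["g0", "g1", "g2", "g3"], ["A", "B", "unknown"],
            [4] * 4, [0] * 4, [1] * 4, [1] * 4, [1 / 3] * 3,
        )
        post = e_step(params, expr, sigs)
        np.testing.assert_allclose(post.sum(axis=1), 1.0, atol=1e-9)


class TestMStep:
    def _setup(self):
        rng = np.random.default_rng(5)
        expr = _expr(rng.normal(2, 2, size=(2, 4)))
        sigs = SignatureSet({"A": ["g0"], "B": ["g1"]})
        params = _params(
            ["g0", "g1"], ["A", "B", "unknown"], [4, 4], [0, 0], [1, 1], [1, 1], [1 / 3] * 3
        )
        return expr, sigs, params

    def test_hard_posterior_gives_group_moments(self):
        expr, sigs, params = self._setup()
        post = np.array([[1, 0, 0], [1, 0, 0], [0, 1, 0], [0, 0, 1]], float)
        new = m_step(post, expr, sigs, params)
        x0 = expr.gene_values("g0")
        hi = x0[:2]
        lo = x0[2:]
        assert new.mu_high[0] == pytest.approx(max(hi.mean(), lo.mean()))
        # g0 high mode comes from cells 0,1; low mode from cells 2,3 (up to ordering swap)
        means = sorted([new.mu_high[0], new.mu_low[0]])
        assert means == pytest.approx(sorted([hi.mean(), lo.mean()]))

    def test_uniform_posterior_estimates_global_mean(self):
        expr, sigs, params = self._setup()
        post = np.full((4, 3), 1 / 3)
        new = m_step(post, expr, sigs, params)
        for gi, g in enumerate(["g0", "g1"]):
            global_mean = expr.gene_values(g).mean()
            # both modes see constant weights -> both estimate the global mean
            assert new.mu_high[gi] == pytest.approx(global_mean)
            assert new.mu_low[gi] == pytest.approx(global_mean)

    def test_soft_posterior_matches_weighted_moment_oracle(self):
        expr, sigs, params = self._setup()
        rng = np.random.default_rng(9)
        post = rng.dirichlet(np.ones(3), size=4)
        new = m_step(post, expr, sigs, params)
        x0 = expr.gene_values("g0")
        mu, sd = weighted_moments_oracle(x0, post[:, 0])  # class A marks g0
        # the A-responsibility moments land in one of the two (possibly swapped) modes
        if np.isclose(new.mu_high[0], mu):
            assert new.sd_high[0] == pytest.approx(sd)
        else:
            assert new.mu_low[0] == pytest.approx(mu)
            assert new.sd_low[0] == pytest.approx(sd)
        np.testing.assert_allclose(new.tau, post.mean(axis=0))

    def test_mu_ordering_enforced(self):
        expr, sigs, params = self._setup()
        # posterior that puts the "high" responsibility on the low cells
        x0 = expr.gene_values("g0")
        low_cells = np.argsort(x0)[:2]
        post = np.zeros((4, 3))
        post[:, 2] = 1.0
        post[low_cells, :] = [1.0, 0.0, 0.0]
        new = m_step(post, expr, sigs, params)
        assert np.all(new.mu_high >= new.mu_low)


class TestAssign:
    def test_argmax(self):
        labels = assign(np.array([[0.1, 0.7, 0.2]]), ["A", "B", "unknown"])
        assert labels[0] == "B"

    def test_tie_prefers_known_class(self):
        labels = assign(np.array([[0.5, 0.5]]), ["A", "unknown"])
        assert labels[0] == "A"

    def test_exhaustive_argmax_on_fit(self):
        ds = simulate_dataset(SimulationConfig(r=4, n_cells=100, seed=3))
        res = fit(ds.expression, ds.signatures)
        expected = [res.class_names[int(np.argmax(row))] for row in res.posterior]
        assert list(res.labels) == expected

    def test_no_unknown_column_when_disallowed(self):
        with pytest.raises(ValueError):
            assign(np.array([[0.5, 0.5]]), ["A", "unknown"], allow_unknown=False)


class TestLogLikelihood:
    def test_closed_form_single_cell(self):
        expr = _expr([[4.0]])
        sigs = SignatureSet({"A": ["g0"]})
        params = _params(["g0"], ["A"], [4.0], [0.0], [1.3], [1.0], [1.0])
        expected = np.log(1.0) + norm.logpdf(4.0, 4.0, 1.3)
        assert log_likelihood(params, expr, sigs) == pytest.approx(expected, abs=1e-12)


class TestFit:
    def test_perfectly_separated_bimodal(self):
        values = [[5.0, 5.0, 5.0, 0.0, 0.0, 0.0]]
        expr = _expr(values)
        sigs = SignatureSet({"T": ["g0"]})
        res = fit(expr, sigs, FitOptions(sd_floor=1e-2))
        assert list(res.labels) == ["T"] * 3 + ["unknown"] * 3

    def test_allow_unknown_off_never_emits_unknown(self):
        ds = simulate_dataset(SimulationConfig(r=5, n_cells=400, seed=2))
        assert (ds.truth.true_labels == "unknown").any()
        res = fit(ds.expression, ds.signatures, FitOptions(allow_unknown=False))
        assert "unknown" not in set(res.labels)
        assert res.posterior.shape[1] == 5

    def test_zero_variance_gene_dropped_with_warning(self):
        rng = np.random.default_rng(0)
        values = np.vstack([rng.normal(2, 1, 20), np.full(20, 3.0)])
        expr = _expr(values)
        sigs = SignatureSet({"A": ["g0", "g1"]})
        res = fit(expr, sigs)
        assert res.params.genes == ["g0"]
        assert any("zero-variance" in w for w in res.validation.warnings)

    def test_all_genes_zero_variance_is_hard_error(self):
        expr = _expr(np.full((1, 10), 2.0))
        sigs = SignatureSet({"A": ["g0"]})
        with pytest.raises(ValueError):
            fit(expr, sigs)

    def test_loglik_trace_monotone_over_many_seeds(self):
        # EM ascent property across >=50 independently simulated fits
        bad = 0
        for seed in range(50):
            ds = simulate_dataset(SimulationConfig(r=5, n_cells=150, seed=seed))
            res = fit(ds.expression, ds.signatures, FitOptions(max_iter=40))
            diffs = np.diff(res.loglik_trace)
            if not np.all(diffs >= -1e-6):
                bad += 1
        assert bad == 0

    def test_posterior_rows_normalised(self):
        ds = simulate_dataset(SimulationConfig(r=4, n_cells=200, seed=8))
        res = fit(ds.expression, ds.signatures)
        np.testing.assert_allclose(res.posterior.sum(axis=1), 1.0, atol=1e-9)

    def test_signature_order_permutation_equivariance(self):
        ds = simulate_dataset(SimulationConfig(r=4, n_cells=300, seed=4))
        res_a = fit(ds.expression, ds.signatures)
        reordered = ds.signatures.subset_labels(list(reversed(ds.signatures.labels)))
        res_b = fit(ds.expression, reordered)
        assert list(res_a.labels) == list(res_b.labels)
        # posterior columns permute with class order
        for lab in res_a.class_names:
            ia = res_a.class_names.index(lab)
            ib = res_b.class_names.index(lab)
            np.testing.assert_allclose(
                res_a.posterior[:, ia], res_b.posterior[:, ib], atol=1e-8
            )

    def test_cell_order_permutation_equivariance(self):
        ds = simulate_dataset(SimulationConfig(r=3, n_cells=120, seed=6))
        res_a = fit(ds.expression, ds.signatures)
        rng = np.random.default_rng(0)
        perm = rng.permutation(ds.expression.n_cells)
        shuffled = ExpressionMatrix(
            gene_ids=ds.expression.gene_ids.copy(),
            cell_ids=ds.expression.cell_ids[perm],
            values=ds.expression.values[:, perm],
        )
        res_b = fit(shuffled, ds.signatures)
        assert list(res_b.labels) == list(res_a.labels[perm])

    def test_parameter_recovery_well_separated(self):
        # tight high modes: fitted mu_high within 3 standard errors of truth
        cfg = SimulationConfig(
            r=5, n_cells=2000, high_sd_range=(0.1, 0.5), low_sd_range=(0.1, 0.5), seed=13
        )
        ds = simulate_dataset(cfg)
        res = fit(ds.expression, ds.signatures)
        for gi, g in enumerate(res.params.genes):
            lab = ds.truth.gene_type[g]
            n_high = ds.truth.counts[lab]
            se = ds.truth.gene_sd_high[g] / np.sqrt(n_high)
            assert abs(res.params.mu_high[gi] - ds.truth.gene_mu_high[g]) < 3 * se + 1e-3

    def test_low_marker_pipeline_end_to_end(self):
        # type B is identified by LOW expression of gene X
        rng = np.random.default_rng(21)
        x_vals = np.concatenate([rng.normal(5, 0.3, 30), rng.normal(0, 0.3, 30)])
        y_vals = np.concatenate([rng.normal(0, 0.3, 30), rng.normal(4, 0.3, 30)])
        expr = _expr(np.vstack([x_vals, y_vals]), gene_ids=["X", "Y"])
        sigs = SignatureSet.from_raw_names({"A": ["X"], "B": ["low_X", "Y"]})
        res = fit(expr, sigs, FitOptions(allow_unknown=False))
        assert list(res.labels) == ["A"] * 30 + ["B"] * 30
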