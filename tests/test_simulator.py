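"""Synthetic study generator: LD structure, heritability scaling, determinism."""

import numpy as np
import pytest

from gsreg.datatypes import ExpressionDataset
from gsreg.errors import UsageError
from gsreg.scores import standardize_columns
from gsreg.simulate import (
    SimulationConfig,
    build_pathways,
    compute_sumstats,
    draw_true_weights,
    estimate_weights_lasso,
    make_founders,
    resample_genotypes,
    simulate_expression,
    simulate_phenotype,
    simulate_study,
)


@pytest.fixture(scope="module")
def small_panel():
    config = SimulationConfig(
        n_blocks=2, snps_per_block=50, n_genes=4, n_sets=3,
        set_size_range=(2, 3), min_set_size=2,
    )
    return config, make_founders(config, seed=1)


class TestFounders:
    def test_block_bounds(self, small_panel):
        _, panel = small_panel
        assert panel.block_bounds == [(0, 50), (50, 100)]
        assert np.all(np.diff(panel.snp_positions) > 0)

    def test_deterministic(self, small_panel):
        config, panel = small_panel
        again = make_founders(config, seed=1)
        np.testing.assert_array_equal(panel.haplotypes, again.haplotypes)

    def test_maf_floor(self, small_panel):
        config, panel = small_panel
        freq = panel.haplotypes.mean(axis=0)
        maf = np.minimum(freq, 1 - freq)
        assert maf.min() >= config.maf_floor - 1e-9

    def test_adjacent_ld_strong(self, small_panel):
        """The mosaic model induces substantial within-block LD."""
        _, panel = small_panel
        geno = resample_genotypes(panel, 2000, seed=2).astype(float)
        adj = []
        for lo, hi in panel.block_bounds:
            for s in range(lo, hi - 1):
                adj.append(abs(np.corrcoef(geno[:, s], geno[:, s + 1])[0, 1]))
        assert np.mean(adj) > 0.3

    def test_between_block_independence(self, small_panel):
        _, panel = small_panel
        geno = resample_genotypes(panel, 10_000, seed=3).astype(float)
        (l0, h0), (l1, h1) = panel.block_bounds
        r = np.corrcoef(geno.T)[l0:h0, l1:h1]
        assert np.abs(r).max() < 0.1

    def test_cis_window_too_small(self):
        with pytest.raises(UsageError, match="cis window"):
            make_founders(
                SimulationConfig(n_blocks=2, snps_per_block=12, n_genes=2,
                                 cis_window_bp=1, set_size_range=(1, 2)),
                seed=0,
            )


class TestResampling:
    def test_single_block_rows_are_founder_copies(self, small_panel):
        _, panel = small_panel
        geno = resample_genotypes(panel, 40, seed=4)
        founders = panel.genotypes
        lo, hi = panel.block_bounds[0]
        founder_rows = {tuple(row) for row in founders[:, lo:hi]}
        for row in geno[:, lo:hi]:
            assert tuple(row) in founder_rows

    def test_allele_frequency_conserved(self, small_panel):
        _, panel = small_panel
        geno = resample_genotypes(panel, 5000, seed=5)
        founder_freq = panel.genotypes.mean(axis=0) / 2
        sample_freq = geno.mean(axis=0) / 2
        se = np.sqrt(founder_freq * (1 - founder_freq) / 5000) + 1 / np.sqrt(5000)
        assert np.all(np.abs(sample_freq - founder_freq) < 5 * se)

    def test_deterministic(self, small_panel):
        _, panel = small_panel
        a = resample_genotypes(panel, 25, seed=6)
        b = resample_genotypes(panel, 25, seed=6)
        np.testing.assert_array_equal(a, b)


class TestExpression:
    def _geno(self, small_panel, n=400, seed=7):
        _, panel = small_panel
        return standardize_columns(resample_genotypes(panel, n, seed=seed))

    def test_h2_one_is_noise_free(self, small_panel):
        config, panel = small_panel
        x = self._geno(small_panel)
        w, _ = draw_true_weights(panel, config, seed=8)
        expr = simulate_expression(x, w, 1.0, seed=9, gene_ids=panel.gene_ids)
        np.testing.assert_allclose(expr.values.T, x @ w, atol=1e-12)

    def test_h2_half_noise_equals_signal_variance(self, small_panel):
        """At h2 = 0.5 the injected noise variance equals the per-sample
        genetic variance, per the matching formula."""
        config, panel = small_panel
        x = self._geno(small_panel)
        w, _ = draw_true_weights(panel, config, seed=10)
        g_val = x @ w
        reps = [
            simulate_expression(x, w, 0.5, seed=s, gene_ids=panel.gene_ids).values.T - g_val
            for s in range(20)
        ]
        noise_var = np.mean([r.var(axis=0) for r in reps], axis=0)
        np.testing.assert_allclose(noise_var, (g_val**2).mean(axis=0), rtol=0.15)

    def test_realized_heritability_concentrates(self):
        """Across many genes the genetic share of expression variance is h2."""
        config = SimulationConfig(
            n_blocks=10, snps_per_block=60, n_genes=200, n_ref=500,
            set_size_range=(5, 20),
        )
        panel = make_founders(config, seed=11)
        x = standardize_columns(resample_genotypes(panel, 500, seed=12))
        w, _ = draw_true_weights(panel, config, seed=13)
        expr = simulate_expression(x, w, config.h2_gene, seed=14, gene_ids=panel.gene_ids)
        g_val = x @ w
        h2 = g_val.var(axis=0) / expr.values.T.var(axis=0)
        assert abs(h2.mean() - config.h2_gene) < 0.02


class TestLasso:
    def test_high_signal_recovers_causal_snp(self):
        config = SimulationConfig(
            n_blocks=5, snps_per_block=60, n_genes=50, n_ref=500, h2_gene=0.9,
            set_size_range=(5, 20),
        )
        panel = make_founders(config, seed=15)
        x = standardize_columns(resample_genotypes(panel, config.n_ref, seed=16))
        w_true, causal = draw_true_weights(panel, config, seed=17)
        expr = simulate_expression(x, w_true, config.h2_gene, seed=18, gene_ids=panel.gene_ids)
        fitted = estimate_weights_lasso(expr, x, panel.cis_windows, panel.snp_ids, seed=19)
        hits = 0
        for g, gid in enumerate(fitted.gene_ids):
            top = panel.snp_ids[int(np.argmax(np.abs(fitted.weights[:, g])))]
            hits += top in causal[gid]
        assert len(fitted.gene_ids) >= 45
        assert hits / len(fitted.gene_ids) >= 0.9

    def test_empty_cis_window_drops_gene(self, small_panel, caplog):
        import logging

        config, panel = small_panel
        x = standardize_columns(resample_genotypes(panel, 200, seed=21))
        w, _ = draw_true_weights(panel, config, seed=20)
        expr = simulate_expression(x, w, 0.5, seed=22, gene_ids=panel.gene_ids)
        windows = {g: win for g, win in panel.cis_windows.items() if g != panel.gene_ids[0]}
        with caplog.at_level(logging.WARNING):
            fitted = estimate_weights_lasso(expr, x, windows, panel.snp_ids, seed=23)
        assert panel.gene_ids[0] not in fitted.gene_ids
        assert "empty cis window" in caplog.text

    def test_deterministic(self, small_panel):
        config, panel = small_panel
        x = standardize_columns(resample_genotypes(panel, 200, seed=23))
        w, _ = draw_true_weights(panel, config, seed=24)
        expr = simulate_expression(x, w, 0.5, seed=25, gene_ids=panel.gene_ids)
        a = estimate_weights_lasso(expr, x, panel.cis_windows, panel.snp_ids, seed=26)
        b = estimate_weights_lasso(expr, x, panel.cis_windows, panel.snp_ids, seed=26)
        np.testing.assert_array_equal(a.weights, b.weights)


class TestPathways:
    def test_overlap_removal_and_pruning(self):
        universe = [f"gene{i:04d}" for i in range(60)]
        sets, causal_id = build_pathways(
            universe, n_sets=30, set_size_range=(5, 12), causal_set_size=10,
            allow_overlap=False, min_set_size=5, seed=27,
        )
        causal = set(sets.members[causal_id])
        assert len(causal) == 10
        for sid in sets.set_ids:
            if sid == causal_id:
                continue
            assert not causal & set(sets.members[sid])
            assert len(sets.members[sid]) >= 5

    def test_overlap_allowed_keeps_causal_genes(self):
        universe = [f"gene{i:04d}" for i in range(40)]
        sets, causal_id = build_pathways(
            universe, n_sets=40, set_size_range=(5, 15), causal_set_size=12,
            allow_overlap=True, min_set_size=5, seed=28,
        )
        causal = set(sets.members[causal_id])
        shared = sum(
            bool(causal & set(sets.members[s])) for s in sets.set_ids if s != causal_id
        )
        assert shared > 0

    def test_deterministic(self):
        universe = [f"gene{i:04d}" for i in range(30)]
        args = dict(n_sets=10, set_size_range=(3, 6), causal_set_size=4,
                    allow_overlap=False, min_set_size=3)
        a = build_pathways(universe, seed=29, **args)
        b = build_pathways(universe, seed=29, **args)
        assert a[0].members == b[0].members and a[1] == b[1]

    def test_infeasible_sizes(self):
        with pytest.raises(UsageError):
            build_pathways(["g1", "g2"], n_sets=2, set_size_range=(3, 5),
                           causal_set_size=None, allow_overlap=False,
                           min_set_size=2, seed=0)


class TestPhenotype:
    def _expr(self, n=800, g=10, seed=30):
        rng = np.random.default_rng(seed)
        return ExpressionDataset(
            gene_ids=[f"gene{i}" for i in range(g)],
            sample_ids=[f"s{i}" for i in range(n)],
            values=rng.normal(size=(g, n)),
        )

    def test_variance_one_limit_is_noise_free(self):
        expr = self._expr()
        y, alpha = simulate_phenotype(expr, expr.gene_ids[:4], 1.0, seed=31)
        a_std = standardize_columns(expr.values[:4].T)
        np.testing.assert_allclose(y, a_std @ alpha, atol=1e-12)

    def test_null_trait(self):
        expr = self._expr()
        y, alpha = simulate_phenotype(expr, expr.gene_ids[:4], 0.0, seed=32)
        np.testing.assert_array_equal(alpha, 0.0)
        assert y.std() > 0

    def test_variance_fraction_concentrates(self):
        """Realized share of trait variance from causal expression ~ 0.1."""
        expr = self._expr(n=1000, g=12)
        fractions = []
        for seed in range(30):
            y, alpha = simulate_phenotype(expr, expr.gene_ids, 0.1, seed=seed)
            signal = standardize_columns(expr.values.T) @ alpha
            fractions.append(signal.var() / y.var())
        assert abs(np.mean(fractions) - 0.1) < 0.03


class TestSumstats:
    def test_perfect_snp(self, small_panel):
        _, panel = small_panel
        x = standardize_columns(resample_genotypes(panel, 200, seed=33))
        gwas = compute_sumstats(x, x[:, 0], panel.snp_ids)
        assert gwas.beta[0] == pytest.approx(1.0)

    def test_matches_dot_products(self):
        rng = np.random.default_rng(34)
        x = rng.normal(size=(50, 5))
        y = rng.normal(size=50)
        gwas = compute_sumstats(x, y, [f"rs{i}" for i in range(5)])
        xs, ys = standardize_columns(x), standardize_columns(y)
        np.testing.assert_allclose(gwas.beta, xs.T @ ys / 50, atol=1e-12)


class TestStudies:
    def test_replicates_bit_identical(self, mini_config):
        a = simulate_study(mini_config, seed=99, mode="both")
        b = simulate_study(mini_config, seed=99, mode="both")
        np.testing.assert_array_equal(a.gwas.beta, b.gwas.beta)
        np.testing.assert_array_equal(a.weights.weights, b.weights.weights)
        np.testing.assert_array_equal(a.expression.values, b.expression.values)
        assert a.sets.members == b.sets.members
        assert a.truth.causal_set_id == b.truth.causal_set_id

    def test_truth_invariants(self, mini_replicate, mini_config):
        truth = mini_replicate.truth
        k = int(mini_config.k_causal_snps)
        nz = (truth.true_weights != 0).sum(axis=0)
        assert np.all(nz == k)
        causal_genes = set(truth.sets.members[truth.causal_set_id])
        for gid, a in zip(truth.gene_ids, truth.alpha):
            if gid not in causal_genes:
                assert a == 0.0

    def test_outputs_are_consistent(self, mini_replicate):
        rep = mini_replicate
        assert rep.gwas.n_gwas == 300
        assert rep.ld.snp_ids == rep.weights.snp_ids
        assert rep.expression.phenotype is not None
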