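"""Instrument construction: harmonization, the valid-SNP selection rule,
greedy LD clumping, allelic scoring, and the threshold grid."""

import numpy as np
import pandas as pd
import pytest

import validmr as v
from validmr.exceptions import (
    DegenerateScoreError,
    EmptyIntersectionError,
    UnknownSNPError,
)
from validmr.instruments import DEFAULT_THRESHOLDS
from validmr.synth import GenotypePanel, GwasSummary


def make_gwas(ids, betas, ps, alleles=None, trait="t"):
    alleles = alleles if alleles is not None else ["A"] * len(ids)
    return GwasSummary(
        snp_id=np.asarray(ids), effect_allele=np.asarray(alleles),
        beta=np.asarray(betas, float), p=np.asarray(ps, float), trait=trait,
    )


def make_independent_panel(n, ids, seed=0):
    rng = np.random.default_rng(seed)
    m = len(ids)
    mafs = rng.uniform(0.2, 0.4, m)
    dosages = rng.binomial(2, mafs, size=(n, m)).astype(float)
    return GenotypePanel(
        dosages=dosages,
        snp_ids=np.asarray(ids),
        effect_alleles=np.array(["A"] * m),
        positions=(np.arange(m) + 1) * 10_000,
        ld_blocks=np.arange(m),
        mafs=mafs,
    )


class TestHarmonize:
    def test_identity_tables(self):
        ids = [f"rs{i}" for i in range(6)]
        panel = make_independent_panel(30, ids)
        g = make_gwas(ids, np.arange(6) * 0.1, np.linspace(0.01, 0.9, 6))
        joined = v.harmonize(g, g, panel)
        assert len(joined) == 6
        np.testing.assert_allclose(joined["beta_outcome"], joined["beta_exposure"])

    def test_allele_swap_flips_outcome_beta(self):
        ids = ["rs1", "rs2"]
        panel = make_independent_panel(30, ids)
        exp = make_gwas(ids, [0.2, 0.3], [0.5, 0.5], alleles=["A", "A"])
        out = make_gwas(ids, [0.1, -0.4], [0.5, 0.5], alleles=["A", "G"])
        joined = v.harmonize(exp, out, panel)
        np.testing.assert_allclose(joined["beta_outcome"], [0.1, 0.4])

    def test_intersection_matches_set_oracle(self):
        rng = np.random.default_rng(3)
        all_ids = [f"rs{i}" for i in range(300)]
        exp_ids = list(rng.choice(all_ids, 200, replace=False))
        out_ids = list(rng.choice(all_ids, 200, replace=False))
        panel = make_independent_panel(20, all_ids)
        exp = make_gwas(exp_ids, rng.normal(size=200), rng.uniform(0.01, 1, 200))
        out = make_gwas(out_ids, rng.normal(size=200), rng.uniform(0.01, 1, 200))
        joined = v.harmonize(exp, out, panel)
        assert set(joined["SNP"]) == set(exp_ids) & set(out_ids)

    def test_empty_intersection_raises(self):
        panel = make_independent_panel(20, ["rs1", "rs2"])
        a = make_gwas(["rs1"], [0.1], [0.5])
        b = make_gwas(["rs9"], [0.1], [0.5])
        with pytest.raises(EmptyIntersectionError):
            v.harmonize(a, b, panel)


class TestSelectValidSnps:
    def test_stated_rule(self):
        ids = ["keep", "pleio"]
        panel = make_independent_panel(20, ids)
        exp = make_gwas(ids, [0.2, 0.2], [0.01, 0.01])
        out = make_gwas(ids, [0.0, 0.0], [0.60, 0.30])
        joined = v.harmonize(exp, out, panel)
        assert v.select_valid_snps(joined, 0.50) == ["keep"]
        assert set(v.select_valid_snps(joined, 0.25)) == {"keep", "pleio"}

    def test_empty_table(self):
        joined = pd.DataFrame(
            columns=["SNP", "p_exposure", "p_outcome", "beta_exposure", "position"]
        )
        assert v.select_valid_snps(joined, 0.5) == []

    def test_matches_brute_force_across_grid(self):
        rng = np.random.default_rng(7)
        ids = [f"rs{i}" for i in range(1000)]
        panel = make_independent_panel(10, ids)
        exp = make_gwas(ids, rng.normal(size=1000), rng.uniform(1e-4, 1, 1000))
        out = make_gwas(ids, rng.normal(size=1000), rng.uniform(1e-4, 1, 1000))
        joined = v.harmonize(exp, out, panel)
        for c in DEFAULT_THRESHOLDS:
            oracle = [
                row.SNP
                for row in joined.itertuples()
                if row.p_exposure < 0.05 and row.p_outcome > c
            ]
            assert v.select_valid_snps(joined, c) == oracle

    def test_warns_outside_grid(self):
        ids = ["rs1"]
        panel = make_independent_panel(20, ids)
        joined = v.harmonize(make_gwas(ids, [0.1], [0.01]), make_gwas(ids, [0], [0.9]), panel)
        with pytest.warns(UserWarning):
            v.select_valid_snps(joined, 0.7)


def greedy_clump_oracle(joined, candidates, panel, r2_max, window):
    """Independent re-implementation: explicit loop over full correlation
    matrix, no shared code with the library routine."""
    sub = joined[joined["SNP"].isin(candidates)]
    rows = sorted(
        sub.itertuples(), key=lambda r: (r.p_exposure, r.position, r.SNP)
    )
    col = {s: i for i, s in enumerate(panel.snp_ids)}
    R2 = np.corrcoef(panel.dosages, rowvar=False) ** 2
    kept, removed = [], set()
    for r in rows:
        if r.SNP in removed:
            continue
        kept.append(r.SNP)
        for other in rows:
            if other.SNP == r.SNP or other.SNP in removed:
                continue
            if abs(other.position - r.position) <= window and R2[
                col[r.SNP], col[other.SNP]
            ] > r2_max:
                removed.add(other.SNP)
    return kept


class TestClump:
    def test_independent_snps_all_retained(self):
        ids = [f"rs{i}" for i in range(8)]
        panel = make_independent_panel(4000, ids, seed=1)
        exp = make_gwas(ids, np.ones(8), np.linspace(0.001, 0.04, 8))
        joined = v.harmonize(exp, make_gwas(ids, np.zeros(8), np.ones(8)), panel)
        kept = v.clump(joined, ids, panel, r2_max=0.1, window=10**9)
        assert set(kept) == set(ids)

    def test_perfectly_correlated_pair_keeps_smaller_p(self):
        rng = np.random.default_rng(2)
        d = rng.binomial(2, 0.3, size=(50, 1)).astype(float)
        panel = GenotypePanel(
            dosages=np.hstack([d, d]),
            snp_ids=np.array(["a", "b"]),
            effect_alleles=np.array(["A", "A"]),
            positions=np.array([100, 200]),
            ld_blocks=np.array([0, 0]),
            mafs=np.array([0.3, 0.3]),
        )
        exp = make_gwas(["a", "b"], [0.1, 0.1], [0.02, 0.001])
        joined = v.harmonize(exp, make_gwas(["a", "b"], [0, 0], [1, 1]), panel)
        assert v.clump(joined, ["a", "b"], panel, 0.1, 10**6) == ["b"]

    def test_matches_exhaustive_greedy_oracle(self, small_cfg):
        cfg = small_cfg.replace(n_snps=20, n_individuals=500, ld_block_size=10, seed=21)
        panel = v.simulate_genotypes(cfg)
        exp, out = v.simulate_gwas_pair(cfg, panel)
        joined = v.harmonize(exp, out, panel)
        candidates = list(panel.snp_ids)
        for r2_max, window in [(0.1, 250_000), (0.5, 50_000), (0.05, 10**9)]:
            got = v.clump(joined, candidates, panel, r2_max, window)
            want = greedy_clump_oracle(joined, candidates, panel, r2_max, window)
            assert got == want


class TestScorePrs:
    def test_single_snp_identity(self):
        panel = make_independent_panel(30, ["rs1"], seed=4)
        raw = v.score_prs(panel, ["rs1"], np.array([1.0]), standardize=False)
        np.testing.assert_allclose(raw, panel.dosages[:, 0])

    def test_empty_list(self):
        panel = make_independent_panel(10, ["rs1"])
        np.testing.assert_array_equal(
            v.score_prs(panel, [], np.array([]), standardize=False), np.zeros(10)
        )
        with pytest.raises(DegenerateScoreError):
            v.score_prs(panel, [], np.array([]))

    def test_matches_double_loop_oracle(self):
        rng = np.random.default_rng(5)
        ids = [f"rs{i}" for i in range(5)]
        panel = make_independent_panel(10, ids, seed=5)
        betas = rng.normal(size=5)
        raw = v.score_prs(panel, ids, betas, standardize=False)
        oracle = np.zeros(10)
        for i in range(10):
            for j in range(5):
                oracle[i] += betas[j] * panel.dosages[i, j]
        np.testing.assert_allclose(raw, oracle, rtol=0, atol=1e-12)

    def test_unknown_snp_raises(self):
        panel = make_independent_panel(10, ["rs1"])
        with pytest.raises(UnknownSNPError):
            v.score_prs(panel, ["nope"], np.array([1.0]))

    def test_missing_dosage_mean_imputed(self):
        panel = make_independent_panel(10, ["rs1", "rs2"], seed=6)
        panel.dosages[0, 0] = np.nan
        raw = v.score_prs(panel, ["rs1", "rs2"], np.array([1.0, 1.0]), standardize=False)
        expected0 = 2 * panel.mafs[0] + panel.dosages[0, 1]
        assert raw[0] == pytest.approx(expected0)

    def test_scoring_linearity_over_disjoint_sets(self, small_cohort):
        panel, exp, _, _ = small_cohort
        ids = list(panel.snp_ids[:20])
        betas = exp.beta[:20]
        full = v.score_prs(panel, ids, betas, standardize=False)
        part = v.score_prs(panel, ids[:7], betas[:7], standardize=False) + v.score_prs(
            panel, ids[7:], betas[7:], standardize=False
        )
        np.testing.assert_allclose(full, part, atol=1e-10)


class TestInstrumentGrid:
    def test_default_grid_has_ten_score_vectors(self, small_grid, small_cohort):
        panel = small_cohort[0]
        assert small_grid.scores.shape == (panel.n_individuals, 10)
        assert small_grid.thresholds == tuple(DEFAULT_THRESHOLDS)

    def test_inactive_outcome_filter_gives_identical_sets(self):
        rng = np.random.default_rng(8)
        ids = [f"rs{i}" for i in range(50)]
        panel = make_independent_panel(200, ids, seed=8)
        exp = make_gwas(ids, rng.normal(size=50), rng.uniform(1e-4, 0.2, 50))
        out = make_gwas(ids, np.zeros(50), np.ones(50))
        grid = v.build_instrument_grid(exp, out, panel)
        sets = [tuple(grid.retained_snps[c]) for c in grid.thresholds]
        assert len(set(sets)) == 1

    def test_retained_sets_monotone_in_c(self, small_grid):
        small_grid.assert_monotone()  # raises on violation
        ordered = sorted(small_grid.thresholds)
        assert all(
            set(small_grid.retained_snps[b]) <= set(small_grid.retained_snps[a])
            for a, b in zip(ordered, ordered[1:])
        )

    def test_every_retained_snp_satisfies_selection_rule(self, small_cohort):
        panel, exp, out, _ = small_cohort
        est = v.ValidPRSGrid().fit(exp, out, panel)
        joined = est.joined_.set_index("SNP")
        for c, snps in est.grid_.retained_snps.items():
            for s in snps:
                assert joined.loc[s, "p_exposure"] < 0.05
                assert joined.loc[s, "p_outcome"] > c

    def test_pleiotropic_contamination_decreases_with_c(self):
        """A discovery GWAS with moderate power leaves pleiotropic SNPs with
        outcome p-values spread over (0, 1); stricter purging (larger c) must
        then remove proportionally more of them. Pooled over replicates so the
        expectation, not one noisy realization, is tested."""
        pleio_kept = np.zeros(10)
        total_kept = np.zeros(10)
        for seed in range(5):
            cfg = v.TrueModelConfig(
                n_individuals=500, n_snps=1000, frac_pleiotropic=0.3,
                frac_exposure_only=0.2, frac_outcome_only=0.1,
                h2_exposure=0.5, h2_outcome=0.5, gwas_n=3000, seed=40 + seed,
            )
            panel = v.simulate_genotypes(cfg)
            exp, out = v.simulate_gwas_pair(cfg, panel)
            grid = v.build_instrument_grid(exp, out, panel)
            pleio = set(panel.snp_ids[exp.snp_class == "pleiotropic"])
            for j, c in enumerate(sorted(grid.thresholds)):
                snps = grid.retained_snps[c]
                total_kept[j] += len(snps)
                pleio_kept[j] += sum(s in pleio for s in snps)
        frac = pleio_kept / total_kept
        assert frac[-1] < frac[0]
        assert frac[5:].mean() < frac[:5].mean()

    def test_valid_prs_tracks_true_genetic_score_without_pleiotropy(self):
        # 1000 exposure-causal SNPs, no LD, no pleiotropy
        cfg = v.TrueModelConfig(
            n_individuals=5000, n_snps=2000, frac_exposure_only=0.5,
            frac_outcome_only=0.2, frac_pleiotropic=0.0,
            ld_block_size=1, ld_block_rho=0.0, seed=3,
        )
        panel = v.simulate_genotypes(cfg)
        exp, out = v.simulate_gwas_pair(cfg, panel)
        gd, _ = v.true_polygenic_scores(cfg, panel)
        grid = v.build_instrument_grid(exp, out, panel)
        for j in range(len(grid.thresholds)):
            assert np.corrcoef(grid.scores[:, j], gd)[0, 1] > 0.5

    def test_transform_scores_new_panel_with_fitted_weights(self, small_cohort):
        panel, exp, out, _ = small_cohort
        est = v.ValidPRSGrid().fit(exp, out, panel)
        again = est.transform(panel)
        np.testing.assert_allclose(again.scores, est.grid_.scores, atol=1e-12)

    def test_get_set_params_roundtrip(self):
        est = v.ValidPRSGrid(r2_max=0.2)
        est.set_params(**est.get_params())
        assert est.get_params()["r2_max"] == 0.2
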