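"""DEP calling, attribution, FGO-originated persistence, set enrichment."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import hypergeom

from oetomics import differential as diff
from oetomics import preprocess as pp
from oetomics.simulate import generate_chx_experiment


def reps(**rows):
    df = pd.DataFrame(rows).T
    df.index.name = "gene_id"
    df.columns = [f"rep{i+1}" for i in range(df.shape[1])]
    return df


class TestDepCall:
    def test_identical_groups_not_called(self):
        a = reps(g1=[10.0, 10.2])
        out = diff.dep_call(a, a.copy())
        assert out.loc["g1", "direction"] == "none"

    def test_t_statistic_matches_hand_formula(self):
        a = reps(g1=[10.0, 10.1])
        b = reps(g1=[13.0, 13.1])
        out = diff.dep_call(a, b)
        # pooled equal-variance t-test, df = 2
        xa, xb = np.array([10.0, 10.1]), np.array([13.0, 13.1])
        sp2 = (xa.var(ddof=1) + xb.var(ddof=1)) / 2
        t = (xb.mean() - xa.mean()) / np.sqrt(sp2 * (1 / 2 + 1 / 2))
        from scipy.stats import t as tdist

        p_oracle = 2 * tdist.sf(abs(t), df=2)
        assert out.loc["g1", "log2_fc"] == pytest.approx(3.0)
        assert out.loc["g1", "p_value"] == pytest.approx(p_oracle, rel=1e-12)
        assert out.loc["g1", "direction"] == "up"

    def test_zero_variance_equal_means_convention(self):
        a = reps(g1=[10.0, 10.0])
        out = diff.dep_call(a, a.copy())
        assert out.loc["g1", "p_value"] == 1.0

    def test_zero_variance_distinct_means_is_significant(self):
        out = diff.dep_call(reps(g1=[10.0, 10.0]), reps(g1=[13.0, 13.0]))
        assert out.loc["g1", "p_value"] == 0.0
        assert out.loc["g1", "direction"] == "up"

    def test_single_replicate_skipped(self):
        out = diff.dep_call(reps(g1=[10.0, np.nan]), reps(g1=[13.0, 13.1]))
        assert not out.loc["g1", "tested"]
        assert out.loc["g1", "direction"] == "none"

    def test_dep_count_monotone_in_thresholds(self, bundle_noisy):
        corrected = pp.apply_batch_correction(
            bundle_noisy.protein, pp.compute_batch_factors(bundle_noisy.protein)
        )
        replicate = pp.replicate_matrix_with_derived_fgo(corrected)
        loose = diff.deps_all_transitions(replicate, fc_threshold=0.5)
        strict = diff.deps_all_transitions(replicate, fc_threshold=2.0)
        n = lambda t: (t["direction"] != "none").sum()
        assert n(strict) <= n(loose)
        lo_p = diff.deps_all_transitions(replicate, p_threshold=0.01)
        hi_p = diff.deps_all_transitions(replicate, p_threshold=0.1)
        assert n(lo_p) <= n(hi_p)


class TestAttribution:
    @pytest.fixture()
    def transitions(self):
        return [f"t{i}" for i in range(6)]

    def changes(self, transitions, **rows):
        df = pd.DataFrame(rows, index=transitions).T
        df.index.name = "gene_id"
        return df

    def deps_one(self, transition):
        return pd.DataFrame(
            {
                "transition": [transition],
                "direction": ["up"],
                "log2_fc": [2.0],
                "p_value": [0.01],
            },
            index=pd.Index(["g1"], name="gene_id"),
        )

    def test_mrna_change_two_stages_earlier_attributed_to_mrna(self, transitions):
        # protein up at t4, mRNA up 2.5-fold at t2 (two transitions earlier)
        mrna = self.changes(transitions, g1=[0, 0, np.log2(2.5), 0, 0, 0])
        rpf = self.changes(transitions, g1=[0.0] * 6)
        table, _ = diff.attribute_changes(self.deps_one("t4"), rpf, mrna)
        assert table["category"].iloc[0] == "mrna_contributed"

    def test_rpf_only_when_mrna_flat(self, transitions):
        mrna = self.changes(transitions, g1=[0.0] * 6)
        rpf = self.changes(transitions, g1=[0, 0, 0, 0, np.log2(3), 0])
        table, _ = diff.attribute_changes(self.deps_one("t4"), rpf, mrna)
        assert table["category"].iloc[0] == "rpf_only"

    def test_unexplained_when_both_layers_flat(self, transitions):
        flat = self.changes(transitions, g1=[0.0] * 6)
        table, _ = diff.attribute_changes(self.deps_one("t4"), flat, flat.copy())
        assert table["category"].iloc[0] == "unexplained"

    def test_opposite_sign_change_does_not_count(self, transitions):
        mrna = self.changes(transitions, g1=[0, 0, 0, 0, -2.0, 0])
        rpf = self.changes(transitions, g1=[0.0] * 6)
        table, _ = diff.attribute_changes(self.deps_one("t4"), rpf, mrna)
        assert table["category"].iloc[0] == "unexplained"

    def test_window_does_not_reach_before_series_start(self, transitions):
        mrna = self.changes(transitions, g1=[np.log2(3), 0, 0, 0, 0, 0])
        rpf = self.changes(transitions, g1=[0.0] * 6)
        table, _ = diff.attribute_changes(self.deps_one("t4"), rpf, mrna)
        assert table["category"].iloc[0] == "unexplained"

    def test_fractions_sum_to_one_per_transition(self, bundle_noisy):
        from oetomics import concordance as conc

        corrected = pp.apply_batch_correction(
            bundle_noisy.protein, pp.compute_batch_factors(bundle_noisy.protein)
        )
        replicate = pp.replicate_matrix_with_derived_fgo(corrected)
        deps = diff.deps_all_transitions(replicate)
        rpf_changes = conc.change_matrix(pp.merge_replicates(bundle_noisy.rpf))
        mrna_changes = conc.change_matrix(pp.merge_replicates(bundle_noisy.mrna))
        _, fractions = diff.attribute_changes(deps, rpf_changes, mrna_changes)
        np.testing.assert_allclose(fractions.sum(axis=1), 1.0)


class TestFgoOriginated:
    def test_zero_noise_matches_planted_truth(self, averaged0, truth0):
        protein, rpf, _ = averaged0
        genes, persistence = diff.fgo_originated(protein, rpf)
        assert set(genes) == set(truth0.index[truth0["is_fgo_originated"]])
        assert 0.0 <= persistence <= 1.0

    def test_gene_with_rpf_above_threshold_excluded(self):
        from oetomics.matrix import stage_matrix
        from oetomics.stages import DEFAULT_STAGES

        stages = list(DEFAULT_STAGES)
        protein = stage_matrix(
            "protein_log2_ibaq",
            pd.DataFrame({"g1": [10.0] * 7, "g2": [10.0] * 7}, index=stages).T,
        )
        rpf = stage_matrix(
            "rpf_fpkm",
            pd.DataFrame(
                {"g1": [50, 50, 0, 0, 6, 0, 0], "g2": [50, 50, 0, 0, 0, 0, 0]},
                index=stages,
            ).T.astype(float),
        )
        genes, persistence = diff.fgo_originated(protein, rpf)
        assert list(genes) == ["g2"]
        assert persistence == 1.0


class TestChxResponse:
    def test_identical_conditions_give_no_repressed_genes(self):
        dmso = reps(g1=[10.0, 10.2], g2=[12.0, 12.1])
        repressed, unaffected = diff.chx_response(dmso, dmso.copy())
        assert repressed == set()
        assert unaffected == {"g1", "g2"}

    def test_planted_repressed_genes_recovered_exactly(self):
        dmso, chx, truth = generate_chx_experiment(
            n_genes=100, n_repressed=20, log2_fold=3.0, noise_sd=0.0, seed=4
        )
        repressed, _ = diff.chx_response(dmso, chx)
        assert repressed == truth

    def test_twofold_change_below_fourfold_rule_unaffected(self):
        dmso = reps(g1=[10.0, 10.05])
        chx = reps(g1=[9.0, 9.05])  # down 2-fold only
        repressed, unaffected = diff.chx_response(dmso, chx)
        assert repressed == set() and unaffected == {"g1"}


class TestOverlapEnrichment:
    def test_consistent_split_matches_hypergeometric_oracle(self):
        universe = {f"g{i}" for i in range(20)}
        half = {f"g{i}" for i in range(10)}
        res = diff.overlap_enrichment(half, half, universe)
        # two-sided Fisher p: sum of all tables with prob <= observed
        rv = hypergeom(20, 10, 10)
        p_obs = rv.pmf(10)
        oracle = sum(rv.pmf(k) for k in range(0, 11) if rv.pmf(k) <= p_obs + 1e-12)
        assert res.overlap == 10
        assert res.p_value == pytest.approx(oracle, rel=1e-9)

    def test_disjoint_cover_has_zero_overlap(self):
        universe = {f"g{i}" for i in range(10)}
        a = {f"g{i}" for i in range(5)}
        res = diff.overlap_enrichment(a, universe - a, universe)
        assert res.overlap == 0

    def test_independent_random_sets_have_odds_near_one(self, rng):
        universe = {f"g{i}" for i in range(2000)}
        ulist = sorted(universe)
        odds = []
        for _ in range(20):
            a = set(rng.choice(ulist, 600, replace=False))
            b = set(rng.choice(ulist, 600, replace=False))
            res = diff.overlap_enrichment(a, b, universe)
            if np.isfinite(res.odds_ratio):
                odds.append(res.odds_ratio)
        assert np.median(odds) == pytest.approx(1.0, abs=0.15)


class TestDormantMrna:
    def test_translation_gain_without_mrna_gain_is_dormant(self):
        from oetomics.matrix import stage_matrix
        from oetomics.stages import DEFAULT_STAGES

        stages = list(DEFAULT_STAGES)
        mk = lambda rows, layer: stage_matrix(
            layer, pd.DataFrame(rows, index=stages).T.astype(float)
        )
        rpf = mk({"g1": [10, 30, 1, 1, 1, 1, 1], "g2": [10, 30, 1, 1, 1, 1, 1]}, "rpf_fpkm")
        mrna = mk({"g1": [50, 50, 1, 1, 1, 1, 1], "g2": [20, 50, 1, 1, 1, 1, 1]}, "mrna_fpkm")
        out = diff.dormant_mrna_set(rpf, mrna)
        assert list(out) == ["g1"]  # g2 mRNA ratio 2.5 disqualifies

    def test_zero_noise_bundle_recovers_planted_dormant_set(self, averaged0, truth0):
        _, rpf, mrna = averaged0
        out = diff.dormant_mrna_set(rpf, mrna)
        assert set(out) == set(truth0.index[truth0["is_dormant"]])
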