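"""Gene-wise concordance, lagged change correlation, IDRs, associations."""

import numpy as np
import pandas as pd
import pytest

from oetomics import concordance as conc
from oetomics.errors import InputError
from oetomics.matrix import stage_matrix
from oetomics.stages import DEFAULT_STAGES


def layer(rows: dict, name="protein_log2_ibaq"):
    df = pd.DataFrame(rows, index=list(DEFAULT_STAGES)).T
    df.index.name = "gene_id"
    return stage_matrix(name, df)


class TestGenewiseCorrelation:
    def test_monotone_transform_gives_perfect_correlation(self):
        x = np.array([1, 3, 2, 5, 4, 7, 6], dtype=float)
        protein = layer({"g": 8 + 0.5 * x})
        rpf = layer({"g": 2.0**x}, "rpf_fpkm")
        table, _ = conc.genewise_correlation(protein, rpf)
        assert table.loc["g", "r"] == pytest.approx(1.0)
        assert table.loc["g", "bin"] == "high"

    def test_reversed_ranks_give_minus_one(self):
        x = np.arange(7.0)
        protein = layer({"g": 8 + x})
        rpf = layer({"g": 100 - 10 * x}, "rpf_fpkm")
        table, _ = conc.genewise_correlation(protein, rpf)
        assert table.loc["g", "r"] == pytest.approx(-1.0)

    def test_seven_point_pair_matches_rank_formula(self):
        x = np.array([10.0, 11.5, 11.0, 12.0, 11.2, 13.0, 12.5])
        y = np.array([3.0, 9.0, 4.0, 8.0, 7.0, 20.0, 12.0])
        table, _ = conc.genewise_correlation(layer({"g": x}), layer({"g": y}, "rpf_fpkm"))
        rx = x.argsort().argsort().astype(float)
        ry = y.argsort().argsort().astype(float)
        oracle = np.corrcoef(rx, ry)[0, 1]
        assert table.loc["g", "r"] == pytest.approx(oracle, rel=1e-12)

    def test_bin_boundaries_assigned_to_medium(self):
        assert conc._bin_correlation(0.2) == "medium"
        assert conc._bin_correlation(0.5) == "medium"
        assert conc._bin_correlation(0.51) == "high"
        assert conc._bin_correlation(0.19) == "low"

    def test_bin_fractions_sum_to_one(self, averaged0):
        protein, rpf, _ = averaged0
        table, _ = conc.genewise_correlation(protein, rpf)
        defined = table[table["bin"] != "undefined"]
        fracs = defined["bin"].value_counts(normalize=True)
        assert fracs.sum() == pytest.approx(1.0)


class TestChangeMatrix:
    def test_constant_gene_has_zero_changes(self):
        changes = conc.change_matrix(layer({"g": [9.0] * 7}))
        assert (changes.loc["g"] == 0).all()

    def test_changes_telescope_to_endpoint_difference(self, rng):
        vals = rng.uniform(6, 14, 7)
        changes = conc.change_matrix(layer({"g": vals}))
        assert changes.loc["g"].sum() == pytest.approx(vals[-1] - vals[0])

    def test_three_stage_hand_computed_differences(self):
        changes = conc.change_matrix(layer({"g": [8.0, 10.0, 9.0, 9, 9, 9, 9]}))
        assert changes.loc["g", "FGO->MII"] == 2.0
        assert changes.loc["g", "MII->1C"] == -1.0

    def test_fpkm_layer_uses_log2_pseudocount(self):
        changes = conc.change_matrix(layer({"g": [0.0, 3.0, 3, 3, 3, 3, 3]}, "rpf_fpkm"))
        assert changes.loc["g", "FGO->MII"] == pytest.approx(np.log2(4) - np.log2(1))


class TestLaggedChangeCorrelation:
    def test_identical_changes_give_unit_diagonal(self, rng):
        pc = pd.DataFrame(
            rng.normal(0, 1, (30, 6)),
            index=[f"g{i}" for i in range(30)],
            columns=[f"t{i}" for i in range(6)],
        )
        corr = conc.lagged_change_correlation(pc, pc)
        np.testing.assert_allclose(np.diag(corr.to_numpy(float)), 1.0)

    def test_planted_one_stage_lag_detected(self, rng):
        n = 200
        rpf_changes = pd.DataFrame(
            rng.normal(0, 1, (n, 6)),
            index=[f"g{i}" for i in range(n)],
            columns=[f"t{i}" for i in range(6)],
        )
        protein_changes = rpf_changes.shift(1, axis=1).fillna(0.0)
        corr = conc.lagged_change_correlation(protein_changes, rpf_changes)
        lag1 = conc.lag_diagonal(corr, lag=1).to_numpy(float)
        lag0 = conc.lag_diagonal(corr, lag=0).to_numpy(float)[1:]
        assert np.all(lag1 > 0.99)
        assert np.all(np.abs(lag0) < 0.2)

    def test_permuted_genes_destroy_correlation(self, rng):
        n = 300
        pc = pd.DataFrame(
            rng.normal(0, 1, (n, 6)),
            index=[f"g{i}" for i in range(n)],
            columns=[f"t{i}" for i in range(6)],
        )
        oc = pc.copy()
        oc.index = pc.index[rng.permutation(n)]
        corr = conc.lagged_change_correlation(pc, oc)
        assert np.abs(corr.to_numpy(float)).max() < 0.2


class TestIdrSegments:
    def test_all_low_scores_give_no_segments(self):
        segs, has = conc.idr_segments(np.zeros(100))
        assert segs == [] and not has

    def test_run_of_31_is_a_segment(self):
        scores = np.zeros(100)
        scores[9:40] = 0.9  # residues 10..40, 31 long
        segs, has = conc.idr_segments(scores)
        assert has and len(segs) == 1
        assert (segs[0].start, segs[0].end) == (10, 40)
        assert segs[0].length == 31

    def test_run_of_exactly_30_is_not_a_segment(self):
        scores = np.zeros(100)
        scores[10:40] = 0.9  # 30 residues: not strictly more than 30
        segs, has = conc.idr_segments(scores)
        assert segs == [] and not has

    def test_matches_brute_force_scan(self, rng):
        def brute(scores, cutoff=0.5, min_len=30):
            out = []
            n = len(scores)
            for i in range(n):
                for j in range(i, n):
                    if all(s > cutoff for s in scores[i : j + 1]):
                        if j - i + 1 > min_len:
                            left_ok = i == 0 or scores[i - 1] <= cutoff
                            right_ok = j == n - 1 or scores[j + 1] <= cutoff
                            if left_ok and right_ok:
                                out.append((i + 1, j + 1))
            return out

        for _ in range(10):
            scores = rng.uniform(0, 1, rng.integers(31, 200))
            segs, _ = conc.idr_segments(scores)
            assert [(s.start, s.end) for s in segs] == brute(list(scores))

    def test_empty_scores_rejected(self):
        with pytest.raises(InputError):
            conc.idr_segments(np.array([]))

    def test_planted_idr_segments_recovered(self, bundle0, truth0):
        for t in bundle0.truth[:40]:
            segs, has = conc.idr_segments(bundle0.disorder[t.gene_id])
            assert has == t.has_idr
            if t.has_idr:
                assert (segs[0].start, segs[0].end) == t.idr_segment


class TestFeatureAssociation:
    def test_identical_groups_not_significant(self):
        values = pd.Series(
            [1.0, 2, 3, 4, 1, 2, 3, 4], index=[f"g{i}" for i in range(8)]
        )
        groups = pd.Series(
            ["a"] * 4 + ["b"] * 4, index=values.index
        )
        out = conc.feature_association(values, groups)
        assert out["p_value"].iloc[0] > 0.5

    def test_separated_groups_match_enumeration_oracle(self):
        values = pd.Series(
            [1.0, 2, 3, 10, 11, 12], index=[f"g{i}" for i in range(6)]
        )
        groups = pd.Series(["a"] * 3 + ["b"] * 3, index=values.index)
        out = conc.feature_association(values, groups)
        # U statistic for complete separation is 0; exact two-sided p is
        # 2 * P(U <= 0) = 2 / C(6,3) = 0.1
        assert out["statistic"].iloc[0] == 0.0
        assert out["p_value"].iloc[0] == pytest.approx(0.1)

    def test_planted_half_life_effect_detected(self, rng):
        # low-concordance genes get 2x half-lives
        n = 60
        groups = pd.Series(
            ["low"] * n + ["high"] * n, index=[f"g{i}" for i in range(2 * n)]
        )
        half_life = pd.Series(
            np.concatenate(
                [rng.lognormal(np.log(20), 0.3, n), rng.lognormal(np.log(10), 0.3, n)]
            ),
            index=groups.index,
        )
        out = conc.feature_association(half_life, groups)
        assert out["p_value"].iloc[0] < 1e-6

    def test_binary_feature_uses_fisher(self):
        values = pd.Series(
            [1, 1, 1, 1, 0, 0, 0, 0, 1, 0], index=[f"g{i}" for i in range(10)], dtype=float
        )
        groups = pd.Series(["a"] * 5 + ["b"] * 5, index=values.index)
        out = conc.feature_association(values, groups, binary=True)
        from scipy.stats import fisher_exact

        oracle = fisher_exact([[4, 1], [1, 4]], "two-sided")[1]
        assert out["p_value"].iloc[0] == pytest.approx(oracle)
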