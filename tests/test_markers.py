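"""Differential tests, BH correction, and screening presets vs oracles."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as hst

from oracles import bh_oracle, welch_t_oracle
from spatomix.markers import (
    adjust_bh,
    differential_features,
    markers_per_group,
    screen_markers,
)


def frame_from_groups(a: np.ndarray, b: np.ndarray) -> tuple[pd.DataFrame, list, list]:
    values = np.vstack([a, b]).astype(float)
    idx = [f"a{i}" for i in range(len(a))] + [f"b{i}" for i in range(len(b))]
    frame = pd.DataFrame(values, index=idx, columns=[f"f{j}" for j in range(values.shape[1])])
    return frame, idx[: len(a)], idx[len(a):]


class TestDifferentialFeatures:
    def test_identical_constant_groups(self):
        frame, ga, gb = frame_from_groups(np.full((3, 1), 5.0), np.full((3, 1), 5.0))
        rec = differential_features(frame, ga, gb)
        assert rec["fold_change"].iloc[0] == 1.0
        assert rec["p_value"].iloc[0] == 1.0
        assert rec["t_statistic"].iloc[0] == 0.0

    def test_fold_change_is_ratio_of_means(self):
        frame, ga, gb = frame_from_groups(
            np.array([[9.0], [11.0], [10.0]]), np.array([[4.0], [6.0], [5.0]])
        )
        rec = differential_features(frame, ga, gb)
        assert rec["fold_change"].iloc[0] == pytest.approx(2.0)

    def test_welch_t_and_p_match_textbook_oracle(self):
        a = np.array([[1.0], [2.0], [3.0], [4.0]])
        b = np.array([[2.0], [3.0], [4.0], [5.0]])
        frame, ga, gb = frame_from_groups(a, b)
        rec = differential_features(frame, ga, gb)
        t_ref, p_ref = welch_t_oracle(a.ravel(), b.ravel())
        assert rec["t_statistic"].iloc[0] == pytest.approx(t_ref, abs=1e-10)
        assert rec["p_value"].iloc[0] == pytest.approx(p_ref, abs=1e-10)

    def test_oracle_agreement_on_random_data(self):
        rng = np.random.default_rng(0)
        a = rng.normal(5.0, 2.0, size=(9, 4))
        b = rng.normal(6.0, 1.0, size=(7, 4))
        frame, ga, gb = frame_from_groups(a, b)
        rec = differential_features(frame, ga, gb)
        for j in range(4):
            t_ref, p_ref = welch_t_oracle(a[:, j], b[:, j])
            assert rec["t_statistic"].iloc[j] == pytest.approx(t_ref, abs=1e-10)
            assert rec["p_value"].iloc[j] == pytest.approx(p_ref, abs=1e-10)

    def test_group_swap_inverts_fc_and_negates_t(self):
        rng = np.random.default_rng(1)
        a = rng.uniform(1, 10, size=(6, 3))
        b = rng.uniform(1, 10, size=(5, 3))
        frame, ga, gb = frame_from_groups(a, b)
        fwd = differential_features(frame, ga, gb)
        rev = differential_features(frame, gb, ga)
        assert np.allclose(rev["fold_change"], 1.0 / fwd["fold_change"])
        assert np.allclose(rev["t_statistic"], -fwd["t_statistic"])
        assert np.allclose(rev["p_value"], fwd["p_value"])

    def test_small_groups_rejected(self):
        frame, ga, gb = frame_from_groups(np.ones((1, 2)), np.ones((3, 2)))
        with pytest.raises(ValueError, match=">= 2"):
            differential_features(frame, ga, gb)

    def test_fold_values_decouple_scales(self):
        frame, ga, gb = frame_from_groups(
            np.array([[2.0], [2.0]]), np.array([[1.0], [1.0]])
        )
        raw = frame * 10.0
        rec = differential_features(frame, ga, gb, fold_values=raw)
        assert rec["mean_a"].iloc[0] == pytest.approx(20.0)
        assert rec["fold_change"].iloc[0] == pytest.approx(2.0)


class TestAdjustBh:
    def test_hand_computed_example(self):
        q = adjust_bh([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(q, [0.04, 0.04, 0.04, 0.04])

    def test_single_p_unchanged(self):
        assert adjust_bh([0.37])[0] == pytest.approx(0.37)

    def test_all_equal_collapse(self):
        assert np.allclose(adjust_bh([0.2, 0.2, 0.2]), 0.2)

    def test_exhaustive_subsets_match_bruteforce(self):
        # all non-empty subsets of a fixed p-grid up to length 12
        grid = [0.001, 0.008, 0.02, 0.04, 0.05, 0.11, 0.2, 0.33, 0.5, 0.7, 0.9, 1.0]
        for r in range(1, len(grid) + 1):
            for subset in itertools.combinations(grid, r):
                assert np.allclose(
                    adjust_bh(list(subset)), bh_oracle(list(subset)), atol=0
                ), subset

    def test_statsmodels_agreement(self):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(2)
        p = rng.uniform(0, 1, 200)
        _, q_ref, _, _ = multipletests(p, method="fdr_bh")
        assert np.allclose(adjust_bh(p), q_ref, atol=1e-14)

    @settings(deadline=None, derandomize=True)
    @given(hst.lists(hst.floats(min_value=0.0, max_value=1.0), min_size=1, max_size=40))
    def test_q_monotone_in_p_and_at_least_p(self, ps):
        p = np.asarray(ps)
        q = adjust_bh(p)
        assert np.all(q >= p - 1e-15)
        order = np.argsort(p, kind="stable")
        assert np.all(np.diff(q[order]) >= -1e-15)

    def test_out_of_range_p_raises(self):
        with pytest.raises(ValueError):
            adjust_bh([0.5, 1.2])


class TestScreenMarkers:
    def record(self, **kw):
        base = dict(
            feature_id="f", modality="gene", group="g", reference="r",
            mean_a=1.0, mean_b=1.0, fold_change=1.0, log2_fc=0.0,
            t_statistic=0.0, p_value=1.0, q_value=1.0, n_a=5, n_b=5,
        )
        base.update(kw)
        return pd.DataFrame([base])

    def test_fc_below_threshold_rejected(self):
        rec = self.record(fold_change=1.9, q_value=0.01)
        assert len(screen_markers(rec, "genes_enrichment")) == 0

    def test_fc_exactly_2_is_inclusive(self):
        rec = self.record(fold_change=2.0, q_value=0.049)
        assert len(screen_markers(rec, "genes_enrichment")) == 1

    def test_metabolite_preset_only_needs_fc(self):
        rec = self.record(fold_change=1.5, p_value=0.9, q_value=0.9)
        assert len(screen_markers(rec, "metabolites_network")) == 1

    def test_cluster_preset_needs_strict_log2fc(self):
        rec = self.record(log2_fc=1.0, p_value=0.001)
        assert len(screen_markers(rec, "cluster_markers")) == 0
        rec = self.record(log2_fc=1.01, p_value=0.001)
        assert len(screen_markers(rec, "cluster_markers")) == 1

    def test_unknown_preset_raises(self):
        with pytest.raises(ValueError, match="invalid-argument"):
            screen_markers(self.record(), "bogus")

    def test_operating_characteristics_on_planted_markers(self):
        # 2000 features, 200 planted at log2FC = 2, 50 samples per group
        rng = np.random.default_rng(20429)
        n, m, m_true = 50, 2000, 200
        base = rng.lognormal(0.0, 0.8, size=m)
        mu_a = np.tile(base, (n, 1))
        mu_b = mu_a.copy()
        mu_b[:, :m_true] *= 4.0
        disp = 2.0
        counts_a = rng.negative_binomial(disp, disp / (disp + mu_a))
        counts_b = rng.negative_binomial(disp, disp / (disp + mu_b))
        frame, ga, gb = frame_from_groups(counts_b, counts_a)
        rec = differential_features(frame, ga, gb)
        hits = set(screen_markers(rec, "genes_enrichment")["feature_id"])
        true_set = {f"f{j}" for j in range(m_true)}
        sens = len(hits & true_set) / m_true
        fdr = len(hits - true_set) / max(len(hits), 1)
        assert sens >= 0.9
        assert fdr <= 0.1


class TestMarkersPerGroup:
    def test_one_vs_rest_finds_planted_marker(self):
        rng = np.random.default_rng(5)
        counts = rng.poisson(5.0, size=(30, 10)).astype(float)
        counts[:10, 0] *= 10  # feature f0 marks group 'x'
        idx = [f"s{i}" for i in range(30)]
        frame = pd.DataFrame(counts, index=idx, columns=[f"f{j}" for j in range(10)])
        groups = pd.Series(["x"] * 10 + ["y"] * 10 + ["z"] * 10, index=idx)
        result = markers_per_group(frame, groups, "cluster_markers")
        assert "f0" in set(result["x"]["feature_id"])
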