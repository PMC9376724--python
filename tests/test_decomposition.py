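"""Per-gene MI, SRI bookkeeping, annotation summaries and the NRI/RE curve."""

import numpy as np
import pandas as pd
import pytest

from phenoinfo import (
    PairedDataset,
    annotation_sri_summary,
    pc_phenotype_mi,
    per_gene_mi,
    preprocess,
    redundancy_explained,
    sri_pair,
)
from phenoinfo.decomposition import SRIMatrix, gene_gene_mi, set_mi, sri_matrix
from oracles import exact_discrete_mi


def make_sri_matrix(values, genes):
    values = np.asarray(values, dtype=float)
    return SRIMatrix(
        values=pd.DataFrame(values, index=genes, columns=genes),
        per_pair_spread=pd.DataFrame(np.zeros_like(values), index=genes, columns=genes),
        gene_labels=list(genes),
    )


# ---------------------------------------------------------------------------
# arithmetic: NRI / redundancy explained
# ---------------------------------------------------------------------------


class TestRedundancyExplained:
    def test_toy_hand_evaluation(self):
        # n=4 genes, E[I] = {1: 0.5, 2: 0.8, 4: 1.0}: NRI(2) = 0.8*4/2 = 1.6,
        # RE(2) = 1 - (1.6 - 1.0)/(2.0 - 1.0) = 0.4
        curve = redundancy_explained({1: 0.5, 2: 0.8, 4: 1.0}, full_mi=1.0, n=4)
        row = curve.table.set_index("k")
        assert row.loc[2, "nri"] == pytest.approx(1.6)
        assert row.loc[2, "redundancy_explained"] == pytest.approx(0.4)

    def test_boundaries_exact(self):
        curve = redundancy_explained({1: 0.5, 3: 0.7, 5: 0.9}, n=5)
        row = curve.table.set_index("k")
        assert row.loc[1, "redundancy_explained"] == 0.0
        assert row.loc[5, "redundancy_explained"] == 1.0
        assert row.loc[1, "nri"] == pytest.approx(2.5)  # sum of single-gene MIs
        assert row.loc[5, "nri"] == pytest.approx(0.9)  # the full MI

    def test_no_redundancy_flagged(self):
        curve = redundancy_explained({1: 0.1, 4: 1.0}, full_mi=1.0, n=4)
        assert not curve.valid
        assert np.isnan(curve.table["redundancy_explained"]).all()

    def test_k1_required(self):
        with pytest.raises(ValueError, match="k=1"):
            redundancy_explained({2: 0.8, 4: 1.0}, n=4)


# ---------------------------------------------------------------------------
# annotation summary (pure aggregation over a constructed SRI matrix)
# ---------------------------------------------------------------------------


class TestAnnotationSummary:
    def test_single_label_equals_global_mean(self):
        genes = ["a", "b", "c"]
        vals = [[np.nan, -0.2, -0.4], [-0.2, np.nan, -0.6], [-0.4, -0.6, np.nan]]
        sri = make_sri_matrix(vals, genes)
        out = annotation_sri_summary(sri, {g: "all" for g in genes})
        assert out.loc["all", "all"] == pytest.approx(sri.mean_sri)

    def test_cross_label_synergy_exceeds_within(self):
        genes = ["a", "b", "c", "d"]
        vals = np.full((4, 4), -0.5)
        vals[0, 2] = vals[2, 0] = 0.8  # planted cross-label synergy
        vals[0, 3] = vals[3, 0] = 0.7
        vals[1, 2] = vals[2, 1] = 0.9
        vals[1, 3] = vals[3, 1] = 0.6
        np.fill_diagonal(vals, np.nan)
        sri = make_sri_matrix(vals, genes)
        out = annotation_sri_summary(sri, {"a": "L1", "b": "L1", "c": "L2", "d": "L2"})
        assert out.loc["L1", "L2"] > out.loc["L1", "L1"]
        assert out.loc["L1", "L2"] > out.loc["L2", "L2"]
        assert out.loc["L1", "L2"] == out.loc["L2", "L1"]

    def test_gene_order_invariance(self):
        rng = np.random.default_rng(0)
        genes = ["a", "b", "c", "d"]
        vals = rng.normal(size=(4, 4))
        vals = (vals + vals.T) / 2
        np.fill_diagonal(vals, np.nan)
        ann = {"a": "x", "b": "y", "c": "x", "d": "y"}
        out1 = annotation_sri_summary(make_sri_matrix(vals, genes), ann)
        perm = [2, 0, 3, 1]
        out2 = annotation_sri_summary(
            make_sri_matrix(vals[np.ix_(perm, perm)], [genes[i] for i in perm]), ann
        )
        pd.testing.assert_frame_equal(out1, out2)

    def test_singleton_label_within_cell_undefined(self):
        genes = ["a", "b", "c"]
        vals = np.full((3, 3), -0.3)
        np.fill_diagonal(vals, np.nan)
        out = annotation_sri_summary(
            make_sri_matrix(vals, genes), {"a": "solo", "b": "rest", "c": "rest"}
        )
        assert np.isnan(out.loc["solo", "solo"])
        assert np.isfinite(out.loc["solo", "rest"])

    def test_unlabeled_gene_rejected(self):
        sri = make_sri_matrix(np.zeros((2, 2)), ["a", "b"])
        with pytest.raises(ValueError, match="annotation"):
            annotation_sri_summary(sri, {"a": "x"})


# ---------------------------------------------------------------------------
# estimation-backed decomposition on planted fixtures
# ---------------------------------------------------------------------------


class TestSRIPair:
    def test_xor_pair_is_synergistic_one_bit(self, xor_pair):
        assert xor_pair.sri_bits is not None
        # exact decomposition: I(pair;xor)=1, I(single;xor)=0 => SRI=+1 bit
        assert xor_pair.sri_bits == pytest.approx(1.0, abs=0.2)
        assert xor_pair.mi_i.value == pytest.approx(0.0, abs=0.1)

    def test_matches_exhaustive_discrete_oracle(self, xor_dataset, xor_pair):
        bits = (xor_dataset.counts.to_numpy() > 0).astype(int)
        xor = np.logical_xor(bits[:, 0], bits[:, 1]).astype(int)
        oracle_sri = (
            exact_discrete_mi(bits[:, :2], xor)
            - exact_discrete_mi(bits[:, 0], xor)
            - exact_discrete_mi(bits[:, 1], xor)
        )
        assert xor_pair.sri_bits == pytest.approx(oracle_sri, abs=0.2)

    def test_independent_distractor_sri_near_zero(self, xor_dataset, xor_config, xor_cache):
        pair = sri_pair(xor_dataset, "x1", "z", xor_config, single_cache=xor_cache)
        assert pair.sri_bits == pytest.approx(0.0, abs=0.15)

    def test_exact_copy_fully_redundant(self, xor_config):
        rng = np.random.default_rng(7)
        n = 3000
        g = rng.integers(0, 2, size=n)
        traces = g[:, None] + 0.1 * rng.standard_normal((n, 2))
        ds = preprocess(
            PairedDataset.from_arrays(
                np.column_stack([g, g]).astype(int), traces, gene_labels=["g", "copy"]
            )
        )
        pair = sri_pair(ds, "g", "copy", xor_config)
        assert pair.sri_bits == pytest.approx(-pair.mi_i.value, abs=0.15)

    def test_bookkeeping_is_exact(self, xor_pair):
        pair = xor_pair
        assert pair.sri_bits == pytest.approx(
            pair.mi_pair.value - pair.mi_i.value - pair.mi_j.value, abs=1e-12
        )
        quad = np.sqrt(pair.mi_pair.spread**2 + pair.mi_i.spread**2 + pair.mi_j.spread**2)
        assert pair.spread_bits == pytest.approx(quad, abs=1e-12)

    def test_same_gene_rejected(self, xor_dataset, xor_config):
        with pytest.raises(ValueError, match="distinct"):
            sri_pair(xor_dataset, "x1", "x1", xor_config)


@pytest.fixture(scope="module")
def pc_curve(coupled_sim, deep_config):
    ds, _ = coupled_sim
    return pc_phenotype_mi(ds, deep_config, max_components=ds.n_genes)


class TestPerGeneMI(object):
    def test_ranking_matches_construction(self, pg_result):
        table = pg_result.table.set_index("gene")
        # genes 0,1 strongly coupled, 2 weak, 3-5 independent by construction
        strong = table.loc[["g000", "g001"], "mi_bits"]
        null = table.loc[["g003", "g004", "g005"], "mi_bits"]
        assert strong.min() > 0.25
        assert null.abs().max() < 0.1

    def test_cumulative_and_mean_summaries(self, pg_result):
        cum = pg_result.cumulative_descending()
        assert cum["cumulative_bits"].iloc[-1] == pytest.approx(
            pg_result.table["mi_bits"].sum(), abs=1e-9
        )
        assert np.all(np.diff(cum["mi_bits"]) <= 1e-12)
        assert pg_result.mean_mi == pytest.approx(pg_result.table["mi_bits"].mean())

    def test_requires_preprocessed(self, fast_config):
        raw = PairedDataset.from_arrays(
            np.random.default_rng(0).poisson(5, (50, 2)),
            np.random.default_rng(1).standard_normal((50, 4)),
        )
        with pytest.raises(ValueError, match="preprocess"):
            per_gene_mi(raw, fast_config)


@pytest.fixture(scope="module")
def gg_result(coupled_sim, deep_config, pg_result):
    ds, _ = coupled_sim
    return gene_gene_mi(ds, deep_config, per_gene=pg_result)


class TestGeneGeneMI:
    def test_shared_latent_genes_more_informative(self, gg_result):
        loaded = gg_result.mean_to_others[["g000", "g001"]].mean()
        unloaded = gg_result.mean_to_others[["g003", "g004", "g005"]].mean()
        assert loaded > unloaded
        assert gg_result.spearman_r > 0

    def test_matrix_symmetric_nan_diagonal(self, gg_result):
        m = gg_result.values.to_numpy()
        np.testing.assert_allclose(m, m.T, equal_nan=True)
        assert np.isnan(np.diag(m)).all()


class TestSRIMatrixOnFixture:
    def test_redundant_pair_most_negative(self, sri_result):
        # the two identically-loaded genes form the most redundant pair
        n = len(sri_result.gene_labels)
        off = sri_result.values.where(~np.eye(n, dtype=bool))
        min_pair = off.stack().idxmin()
        assert set(min_pair) == {"g000", "g001"}
        assert sri_result.values.loc["g000", "g001"] < -0.15
        assert sri_result.mean_sri < 0

    def test_diagonal_is_negative_self_mi(self, sri_result, pg_result):
        v = sri_result.values.loc["g000", "g000"]
        assert v == pytest.approx(-pg_result.estimates["g000"].value, abs=1e-9)

    def test_informative_genes_more_redundant(self, sri_result):
        # negative rank correlation: higher MI genes have lower (more
        # negative) mean SRI on this all-redundant fixture
        assert sri_result.spearman_r < 0


class TestPCPhenotypeMI:
    def test_single_latent_coupling_plateaus_after_first_pc(self, pc_curve):
        mi = pc_curve["mi_bits"].to_numpy()
        assert mi[0] > 0.25  # PC1 carries the coupled latent
        assert mi[2] - mi[0] < 0.15  # little additional information beyond PC1
        assert pc_curve["mi_norm"].max() == pytest.approx(1.0)

    def test_full_rank_matches_all_genes_within_spread(
        self, pc_curve, coupled_sim, deep_config
    ):
        ds, _ = coupled_sim
        all_genes = set_mi(ds, ds.gene_labels, deep_config)
        tol = 3 * max(all_genes.spread, 0.1)
        assert pc_curve["mi_bits"].iloc[-1] == pytest.approx(all_genes.value, abs=tol)
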