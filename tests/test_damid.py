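"""DamID statistics: filtering, PCA z-scores, overlaps, clustering,
and the gene-proximity Monte-Carlo test."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import kstest

from linc_chromatin.damid import (
    cluster_fold_changes,
    filter_genes,
    group_overlap,
    pca_regression_hits,
    proximity_mc_test,
    read_occupancy_table,
)
from linc_chromatin.synthetic import SynthDamidSpec, gen_damid_table


def _table(ctrl, mut, fdr=None, gatc=None):
    n = len(ctrl)
    df = pd.DataFrame(
        {
            "gene_id": [f"g{i}" for i in range(n)],
            "chrom": "chr2L",
            "start": np.arange(n) * 1000,
            "end": np.arange(n) * 1000 + 500,
            "fdr": 0.01 if fdr is None else fdr,
            "n_gatc": 5 if gatc is None else gatc,
        }
    )
    for r in (1, 2, 3):
        df[f"occ_ctrl_rep{r}"] = ctrl
        df[f"occ_mut_rep{r}"] = mut
    return df


class TestFiltering:
    def test_boundary_values_are_strict(self):
        tab = _table(
            np.zeros(3), np.zeros(3), fdr=[0.05, 0.049, 0.01], gatc=[5, 1, 2]
        )
        kept = filter_genes(tab)
        # fdr == 0.05 removed (strict <); n_gatc == 1 removed (strict >)
        assert list(kept["gene_id"]) == ["g2"]

    def test_empty_table_passes_through(self):
        tab = _table(np.zeros(0), np.zeros(0))
        assert len(filter_genes(tab)) == 0

    def test_empty_result_warns(self):
        tab = _table(np.zeros(2), np.zeros(2), fdr=0.5)
        with pytest.warns(UserWarning):
            filter_genes(tab)


def _oracle_z(ctrl, mut):
    """Closed-form total-least-squares orientation, independent of the
    eigendecomposition route used by the implementation."""
    x = ctrl - ctrl.mean()
    y = mut - mut.mean()
    sxx, syy, sxy = (x * x).sum(), (y * y).sum(), (x * y).sum()
    theta = 0.5 * np.arctan2(2 * sxy, sxx - syy)  # major-axis angle
    normal = np.array([-np.sin(theta), np.cos(theta)])  # perpendicular
    if normal @ np.array([-1.0, 1.0]) < 0:
        normal = -normal
    r = x * normal[0] + y * normal[1]
    return r / r.std(ddof=1)


class TestPcaRegression:
    def test_matches_closed_form_oracle(self, rng):
        ctrl = rng.normal(0, 1, 10)
        mut = 0.8 * ctrl + rng.normal(0, 0.3, 10)
        res = pca_regression_hits(_table(ctrl, mut))
        np.testing.assert_allclose(
            res["z_pca"].to_numpy(), _oracle_z(ctrl, mut), atol=1e-9
        )

    def test_displaced_point_is_the_only_hit(self):
        ctrl = np.linspace(-2, 2, 9)
        mut = ctrl.copy()
        mut[4] += 3.0  # one gene far off the identity line, mutant-enriched
        res = pca_regression_hits(_table(ctrl, mut))
        assert res["significant"].sum() == 1
        assert res.loc[4, "significant"]
        assert res.loc[4, "z_pca"] > 0
        assert res.loc[4, "direction"] == "increased"

    def test_zscores_negate_under_condition_swap(self, rng):
        ctrl = rng.normal(0, 1, 50)
        mut = ctrl + rng.normal(0, 0.2, 50)
        a = pca_regression_hits(_table(ctrl, mut))["z_pca"].to_numpy()
        b = pca_regression_hits(_table(mut, ctrl))["z_pca"].to_numpy()
        np.testing.assert_allclose(a, -b, atol=1e-9)

    def test_invariant_to_gene_order(self, rng):
        ctrl = rng.normal(0, 1, 40)
        mut = ctrl + rng.normal(0, 0.2, 40)
        tab = _table(ctrl, mut)
        shuffled = tab.sample(frac=1, random_state=0).reset_index(drop=True)
        a = pca_regression_hits(tab).set_index("gene_id")["z_pca"]
        b = pca_regression_hits(shuffled).set_index("gene_id")["z_pca"]
        np.testing.assert_allclose(a.sort_index(), b.sort_index(), atol=1e-12)

    def test_null_calibration_five_percent(self):
        tab, _ = gen_damid_table(SynthDamidSpec(n_genes=10_000, n_true_hits=0), seed=1)
        res = pca_regression_hits(filter_genes(tab))
        assert abs(res["significant"].mean() - 0.05) < 0.01

    def test_degenerate_cloud_raises(self):
        with pytest.raises(ValueError):
            pca_regression_hits(_table(np.ones(5), np.ones(5)))


class TestOperatingPoint:
    """Sensitivity/specificity of the caller on spiked tables, checked
    against a Gaussian-mixture oracle for the variance inflation that the
    spiked hits impose on the z normalization."""

    @staticmethod
    def _oracle(n, f, effect, rsd):
        from scipy.stats import norm

        s0 = rsd * np.sqrt(2.0 / 3.0) / np.sqrt(2.0)
        mu = effect / np.sqrt(2.0)
        stot = np.sqrt(s0**2 + f * mu**2 * (1 - f))
        thr = 1.96 * stot
        fp = (1 - f) * n * norm.sf(thr / s0)
        sens = norm.sf((thr - mu) / s0) + norm.cdf((-thr - mu) / s0)
        return sens, fp / (fp + f * n * sens)

    @pytest.mark.parametrize("rsd,max_fdr", [(0.2, None), (0.12, 0.1)])
    def test_sensitivity_and_fdr(self, rsd, max_fdr):
        spec = SynthDamidSpec(replicate_sd=rsd)
        sens_o, fdr_o = self._oracle(spec.n_genes, 0.01, spec.effect_size, rsd)
        sens, fdr = [], []
        for s in range(10):
            tab, truth = gen_damid_table(spec, seed=s)
            res = pca_regression_hits(filter_genes(tab)).merge(truth, on="gene_id")
            called = res[res.significant & (res.direction == "increased")]
            sens.append(res.loc[res.true_hit, "significant"].mean())
            fdr.append(1.0 - called["true_hit"].mean())
        assert np.mean(sens) >= 0.9
        assert np.mean(sens) >= sens_o - 0.05
        assert abs(np.mean(fdr) - fdr_o) < 0.12
        if max_fdr is not None:
            assert np.mean(fdr) <= max_fdr


class TestOverlap:
    @pytest.mark.parametrize(
        "a,b,expected",
        [
            ({"a"}, {"b"}, 0.0),
            ({"a", "b"}, {"a", "b"}, 100.0),
            ({"a", "b", "c"}, {"c", "d"}, 25.0),
            (set(), set(), 0.0),
        ],
    )
    def test_jaccard_percent(self, a, b, expected):
        assert group_overlap(a, b) == expected

    def test_min_denominator(self):
        assert group_overlap({"a", "b", "c"}, {"c", "d"}, denominator="min") == 50.0


class TestGapClustering:
    def test_three_blobs(self, rng):
        X = np.vstack(
            [
                rng.normal([0, 0, 0], 0.2, (60, 3)),
                rng.normal([5, 5, 0], 0.2, (60, 3)),
                rng.normal([0, 5, 5], 0.2, (60, 3)),
            ]
        )
        res = cluster_fold_changes(X, seed=0)
        assert res.k == 3
        truth = np.repeat([0, 1, 2], 60)
        from sklearn.metrics import adjusted_rand_score

        assert adjusted_rand_score(truth, res.labels) == 1.0
        # label structure is stable across seeds (up to permutation)
        res2 = cluster_fold_changes(X, seed=99)
        assert adjusted_rand_score(res.labels, res2.labels) == 1.0

    def test_single_blob(self, rng):
        res = cluster_fold_changes(rng.normal(0, 1, (80, 3)), seed=0)
        assert res.k == 1

    def test_missing_rows_dropped_and_imputed(self, rng):
        X = rng.normal(0, 1, (40, 3))
        X[0] = np.nan  # all-missing row: dropped
        X[1, 2] = np.nan  # partial: imputed as 0
        with pytest.warns(UserWarning):
            res = cluster_fold_changes(X, k_max=3, seed=0)
        assert len(res.labels) == 39
        assert res.kept_index[0] == 1


@pytest.fixture(scope="module")
def annotation():
    tab, _ = gen_damid_table(SynthDamidSpec(n_true_hits=0), seed=2)
    return tab.rename(columns={"gene_id": "name"})[
        ["chrom", "start", "end", "name"]
    ].assign(score=0, strand="+")


class TestProximity:
    def test_two_close_genes_counted(self):
        ann = pd.DataFrame(
            {
                "chrom": ["chr2L"] * 4,
                "start": [0, 10_000, 100_000, 400_000],
                "end": [1000, 11_000, 101_000, 401_000],
                "name": list("abcd"),
                "score": 0,
                "strand": "+",
            }
        )
        res = proximity_mc_test(["a", "b"], ann, nruns=50, seed=0)
        assert res.observed_count == 2  # gap 9000 < 10000

    def test_hits_on_distinct_chromosomes_score_zero(self):
        ann = pd.DataFrame(
            {
                "chrom": ["chr2L", "chr2R", "chr3L", "chr3R"],
                "start": [0, 0, 0, 0],
                "end": [1000] * 4,
                "name": list("abcd"),
                "score": 0,
                "strand": "+",
            }
        )
        res = proximity_mc_test(list("abcd"), ann, nruns=50, seed=0)
        assert res.observed_count == 0
        assert res.p_value == 1.0

    def test_p_value_formula_exact(self, annotation):
        hits = annotation["name"].iloc[:100]
        res = proximity_mc_test(hits, annotation, nruns=200, seed=3)
        nge = int((res.null_counts >= res.observed_count).sum())
        assert res.p_value == (nge + 1) / (200 + 1)
        assert 1 / 201 <= res.p_value <= 1.0

    def test_clustered_truth_is_significant(self):
        tab, truth = gen_damid_table(
            SynthDamidSpec(n_true_hits=40, clustering="clustered"), seed=3
        )
        ann = tab.rename(columns={"gene_id": "name"})[
            ["chrom", "start", "end", "name"]
        ].assign(score=0, strand="+")
        res = proximity_mc_test(
            truth.loc[truth.true_hit, "gene_id"], ann, nruns=1000, seed=5
        )
        assert res.p_value < 0.05
        assert res.observed_count > res.null_median

    def test_null_matches_bruteforce_oracle(self, annotation):
        """The null count must agree with an O(n^2) re-implementation on
        the same sampled gene sets."""
        rng = np.random.default_rng(9)
        for _ in range(5):
            pick = rng.choice(len(annotation), 60, replace=False)
            sub = annotation.iloc[pick]
            res = proximity_mc_test(sub["name"], annotation, nruns=1, seed=0)
            # brute force on the observed set
            cnt = 0
            rows = sub.to_dict("records")
            for i, gi in enumerate(rows):
                best = np.inf
                for j, gj in enumerate(rows):
                    if i == j or gi["chrom"] != gj["chrom"]:
                        continue
                    gap = max(
                        0,
                        max(
                            gi["start"] - gj["end"],
                            gj["start"] - gi["end"],
                        ),
                    )
                    best = min(best, gap)
                cnt += best < 10_000
            assert res.observed_count == cnt

    def test_null_p_uniform_and_valid(self, annotation):
        """With rich count support, null p-values are ~uniform; at any
        rate they must be valid (sub-uniform)."""
        rng = np.random.default_rng(1)
        ps = []
        for r in range(200):
            pick = rng.choice(len(annotation), 300, replace=False)
            ps.append(
                proximity_mc_test(
                    annotation["name"].iloc[pick], annotation, nruns=199,
                    seed=1000 + r,
                ).p_value
            )
        assert kstest(ps, "uniform").pvalue > 0.01
        for alpha in (0.05, 0.1, 0.25):
            assert np.mean(np.asarray(ps) <= alpha) <= alpha + 0.05

    def test_more_hits_than_genes_raises(self, annotation):
        with pytest.raises(ValueError):
            proximity_mc_test(
                list(annotation["name"]) + ["extra"], annotation, nruns=10, seed=0
            )


def test_occupancy_tsv_roundtrip(tmp_path):
    tab, _ = gen_damid_table(SynthDamidSpec(n_genes=50), seed=0)
    path = tmp_path / "occ.tsv"
    tab.to_csv(path, sep="\t", index=False)
    back = read_occupancy_table(path)
    pd.testing.assert_frame_equal(back, tab)
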