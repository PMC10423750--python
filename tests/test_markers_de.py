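"""Marker AUC statistics, pseudobulk construction and the DE engine."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import kstest

from cardiomap import markers_de as md


class TestAUC:
    def test_worked_example(self):
        expr = np.array([3, 5, 7, 1, 2, 6], dtype=float)
        mask = np.array([True, True, True, False, False, False])
        assert md.auc_one_vs_rest(expr, mask) == pytest.approx(7 / 9)

    def test_identical_distributions_give_half(self):
        expr = np.array([2.0, 2.0, 2.0, 2.0])
        mask = np.array([True, True, False, False])
        assert md.auc_one_vs_rest(expr, mask) == pytest.approx(0.5)

    def test_perfect_separation_gives_one(self):
        expr = np.array([5.0, 6.0, 1.0, 2.0])
        mask = np.array([True, True, False, False])
        assert md.auc_one_vs_rest(expr, mask) == pytest.approx(1.0)

    def test_against_pair_counting_oracle(self, rng):
        def brute(x, mask):
            inside, outside = x[mask], x[~mask]
            wins = sum((a > b) + 0.5 * (a == b) for a in inside for b in outside)
            return wins / (len(inside) * len(outside))

        for _ in range(500):
            n = rng.integers(4, 15)
            x = rng.integers(0, 4, size=n).astype(float)  # many ties
            mask = np.zeros(n, dtype=bool)
            mask[rng.choice(n, size=rng.integers(1, n), replace=False)] = True
            if mask.all() or not mask.any():
                continue
            assert md.auc_one_vs_rest(x, mask) == pytest.approx(brute(x, mask))

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            md.auc_one_vs_rest(np.ones(3), np.ones(3, dtype=bool))


class TestBH:
    def test_closed_form_step_up(self):
        p = np.array([0.001, 0.008, 0.039, 0.041, 0.042, 0.06, 0.074, 0.205, 0.212, 0.36])
        m = len(p)
        order = np.argsort(p)
        raw = p[order] * m / np.arange(1, m + 1)
        stepped = np.minimum.accumulate(raw[::-1])[::-1]
        expected = np.empty(m)
        expected[order] = np.minimum(stepped, 1.0)
        np.testing.assert_allclose(md.bh_adjust(p), expected)

    def test_adjusted_not_below_raw(self, rng):
        p = rng.uniform(size=50)
        assert (md.bh_adjust(p) >= p - 1e-12).all()


class TestPseudobulk:
    def test_column_below_min_nuclei_excluded(self):
        counts = np.ones((50, 4))
        ct = ["A"] * 24 + ["B"] * 26
        sm = ["s1"] * 50
        pb = md.pseudobulk(counts, ct, sm, min_nuclei=25)
        assert "A|s1" not in pb.col_meta.index
        assert "B|s1" in pb.col_meta.index
        with pytest.raises(ValueError):
            md.pseudobulk(counts, ct, sm, min_nuclei=200)

    def test_summation(self):
        counts = np.array([[1, 0], [2, 3]])
        pb = md.pseudobulk(counts, ["A", "A"], ["s1", "s1"], min_nuclei=1)
        np.testing.assert_array_equal(pb.counts.to_numpy().ravel(), [3, 3])

    def test_total_counts_conserved(self, rng):
        counts = rng.integers(0, 5, size=(50, 8))
        ct = rng.choice(["A", "B"], size=50)
        sm = rng.choice(["s1", "s2"], size=50)
        pb = md.pseudobulk(counts, ct, sm, min_nuclei=1)
        assert pb.counts.to_numpy().sum() == counts.sum()

    def test_misaligned_labels_rejected(self):
        with pytest.raises(ValueError):
            md.pseudobulk(np.ones((4, 2)), ["A"], ["s1"], min_nuclei=1)


class TestPrefilter:
    def _counts(self, pct_case, pct_ctrl, rng, n=400):
        X = np.zeros((2 * n, 3))
        X[:, 0] = 1  # anchor gene everywhere
        case = np.arange(n)
        ctrl = np.arange(n, 2 * n)
        X[case[: int(pct_case * n)], 1] = 1
        X[ctrl[: int(pct_ctrl * n)], 1] = 1
        X[:, 2] = 1
        masks = {"case": np.r_[np.ones(n, bool), np.zeros(n, bool)],
                 "ctrl": np.r_[np.zeros(n, bool), np.ones(n, bool)]}
        return X, masks

    def test_rare_in_both_groups_dropped(self, rng):
        X, masks = self._counts(0.005, 0.005, rng)
        kept = md.prefilter_genes(X, masks)
        assert "G00001" not in kept

    def test_rare_in_one_group_retained(self, rng):
        X, masks = self._counts(0.005, 0.05, rng)
        kept = md.prefilter_genes(X, masks)
        assert "G00001" in kept

    def test_mitochondrial_gene_always_dropped(self, rng):
        X, masks = self._counts(0.5, 0.5, rng)
        gmeta = pd.DataFrame(
            {"symbol": ["MT-X", "B", "RPS9"], "mitochondrial": [True, False, False],
             "ribosomal": [False, False, False]},
            index=["g0", "g1", "g2"],
        )
        kept = md.prefilter_genes(X, masks, gene_meta=gmeta)
        assert list(kept) == ["g1"]  # MT flag and ribosomal prefix both dropped

    def test_low_count_pseudobulk_rule(self, rng):
        X, masks = self._counts(0.5, 0.5, rng)
        pbc = pd.DataFrame(
            {"c1": [100, 2, 100], "c2": [100, 2, 100]},
            index=["G00000", "G00001", "G00002"],
        )
        kept = md.prefilter_genes(X, masks, pseudobulk_counts=pbc, min_samples=2)
        assert "G00001" not in kept


class TestSizeFactors:
    def test_identical_columns_unit_factors(self):
        counts = pd.DataFrame(np.tile([[10], [20], [30]], (1, 4)))
        np.testing.assert_allclose(md.size_factors(counts), 1.0)

    def test_doubled_column_factor_two(self):
        base = np.array([[10, 20], [20, 40], [30, 60]], dtype=float)
        sf = md.size_factors(pd.DataFrame(base))
        assert sf.iloc[1] / sf.iloc[0] == pytest.approx(2.0)

    def test_factors_positive(self, rng):
        counts = pd.DataFrame(rng.integers(1, 100, size=(50, 6)))
        assert (md.size_factors(counts) > 0).all()

    def test_no_common_positive_gene_rejected(self):
        counts = pd.DataFrame([[1, 0], [0, 1]])
        with pytest.raises(ValueError):
            md.size_factors(counts)


def _null_pseudobulk(rng, n_genes=2000, n_a=8, n_b=7, depth=40_000):
    counts = rng.poisson(
        rng.dirichlet(np.full(n_genes, 0.5)) * depth, size=(n_a + n_b, n_genes)
    ).T
    meta = pd.DataFrame(
        {
            "cell_type": "A",
            "sample": [f"s{i}" for i in range(n_a + n_b)],
            "n_nuclei": 100,
            "condition": ["case"] * n_a + ["ctrl"] * n_b,
            "age": rng.integers(40, 70, n_a + n_b),
            "sex": rng.choice(["M", "F"], n_a + n_b),
        },
        index=pd.Index([f"A|s{i}" for i in range(n_a + n_b)]),
    )
    return md.PseudobulkMatrix(pd.DataFrame(counts, columns=meta.index), meta)


class TestFitDE:
    def test_type_one_error_calibrated_under_null(self, rng):
        pb = _null_pseudobulk(rng)
        res = md.fit_de(pb, ("case", "ctrl"))
        assert len(res) >= 2000
        rate = (res["p"] < 0.05).mean()
        assert 0.03 <= rate <= 0.07

    def test_planted_fold_change_recovered(self, de_bundle):
        bundle, truth = de_bundle
        out = md.run_dual_de(
            bundle, truth.nucleus_celltype.to_numpy(),
            keep_mask=truth.clean_singlets().to_numpy(),
        )
        est = out["corrected"].set_index(["gene", "cell_type"])["logFC"]
        planted = truth.de_gene_table.set_index(["gene", "cell_type"])["log2fc"]
        common = est.index.intersection(planted.index)
        assert len(common) > 50
        err = (est.loc[common] - planted.loc[common]).abs()
        assert err.median() < 0.5

    def test_covariate_only_signal_leaves_condition_null(self, rng):
        pb = _null_pseudobulk(rng, n_genes=1000)
        # inject an age effect on every gene, no condition effect
        age = pb.col_meta["age"].to_numpy(float)
        bump = np.exp(0.02 * (age - age.mean()))
        counts = (pb.counts.to_numpy() * bump[None, :]).round().astype(int)
        pb2 = md.PseudobulkMatrix(
            pd.DataFrame(counts, index=pb.counts.index, columns=pb.counts.columns),
            pb.col_meta,
        )
        res = md.fit_de(pb2, ("case", "ctrl"))
        assert kstest(res["p"], "uniform").pvalue > 0.01

    def test_small_group_skipped(self, rng):
        pb = _null_pseudobulk(rng, n_genes=50, n_a=2, n_b=7)
        with pytest.raises(ValueError):
            md.fit_de(pb, ("case", "ctrl"))


class TestConcordance:
    def _frame(self, adj_p, logfc):
        return pd.DataFrame(
            {
                "gene": [f"g{i}" for i in range(len(adj_p))],
                "cell_type": "A",
                "contrast": "case_vs_ctrl",
                "logFC": logfc,
                "p": adj_p,
                "adj_p": adj_p,
            }
        )

    def test_significant_in_one_run_only_excluded(self):
        a = self._frame([0.01, 0.01], [1.0, 1.0])
        b = self._frame([0.01, 0.50], [1.0, 1.0])
        sig = md.concordance_filter(a, b)
        assert sig["gene"].tolist() == ["g0"]

    def test_sign_disagreement_excluded(self):
        a = self._frame([0.01], [1.0])
        b = self._frame([0.01], [-1.0])
        assert len(md.concordance_filter(a, b)) == 0

    def test_identical_inputs_return_significant_set(self):
        a = self._frame([0.01, 0.2, 0.03], [1, 1, -2])
        sig = md.concordance_filter(a, a.copy())
        assert set(sig["gene"]) == {"g0", "g2"}

    def test_mismatched_universe_rejected(self):
        a = self._frame([0.01], [1.0])
        b = self._frame([0.01, 0.2], [1.0, 1.0])
        with pytest.raises(ValueError):
            md.concordance_filter(a, b)


class TestFibrosis:
    def _pb(self, rng, slope=0.0, n=6, n_genes=300):
        fib = np.linspace(5, 60, n)
        base = rng.dirichlet(np.full(n_genes, 0.5)) * 30_000
        counts = rng.poisson(base, size=(n, n_genes)).astype(float)
        # noiseless monotone response: the n=6, p<0.005 design has little
        # power, so the planted example isolates the operation itself
        counts[:, 0] = np.round(50 * np.exp(slope * (fib - fib.mean()) / fib.std()))
        meta = pd.DataFrame(
            {
                "cell_type": "fibroblast",
                "sample": [f"s{i}" for i in range(n)],
                "n_nuclei": 100,
                "condition": "ICM",
                "age": rng.integers(45, 70, n),
                "sex": rng.choice(["M", "F"], n),
                "fibrosis_pct": fib,
            },
            index=pd.Index([f"f|s{i}" for i in range(n)]),
        )
        genes = pd.Index([f"G{i:05d}" for i in range(n_genes)])
        return md.PseudobulkMatrix(
            pd.DataFrame(counts.T, index=genes, columns=meta.index), meta
        )

    def test_planted_monotone_gene_recovered(self, rng):
        pb = self._pb(rng, slope=1.2)
        hits = md.fibrosis_association(pb, pb)
        assert "G00000" in set(hits["gene"])

    def test_permuted_covariate_yields_no_hits(self, rng):
        pb = self._pb(rng, slope=0.0)
        hits = md.fibrosis_association(pb, pb)
        assert len(hits) <= 3  # ~0.005 * 300 expected under the null

    def test_two_samples_rejected(self, rng):
        pb = self._pb(rng, n=2)
        with pytest.raises(ValueError):
            md.fibrosis_association(pb, pb)


class TestMarkers:
    def test_threshold_logic_and_tiered_presets(self):
        auc = pd.DataFrame({"c1": [0.7]}, index=["g1"])
        pct_hi = pd.DataFrame({"c1": [0.30]}, index=["g1"])
        pct_lo = pd.DataFrame({"c1": [0.20]}, index=["g1"])
        de = pd.DataFrame(
            {"gene": ["g1"], "cluster": ["c1"], "logFC": [2.5], "p": [0.001],
             "adj_p": [0.001]}
        )
        assert md.select_markers(auc, de, pct_hi, md.MarkerCriteria.global_preset()) == {
            "c1": ["g1"]
        }
        assert md.select_markers(auc, de, pct_lo, md.MarkerCriteria.global_preset()) == {
            "c1": []
        }
        assert md.select_markers(auc, de, pct_lo, md.MarkerCriteria.subcluster_preset()) == {
            "c1": ["g1"]
        }

    def test_planted_markers_selected_with_high_precision(self, de_bundle):
        bundle, truth = de_bundle
        clean = truth.clean_singlets().to_numpy()
        ct = truth.nucleus_celltype.to_numpy()[clean]
        from cardiomap import cluster as cl

        logX = cl.normalize_log(bundle.raw_counts[clean])
        X = bundle.raw_counts[clean]
        types = sorted(set(ct))
        auc = pd.DataFrame(
            {t: md.auc_one_vs_rest(logX, ct == t) for t in types},
            index=bundle.gene_ids,
        )
        pct = pd.DataFrame(
            {t: md.pct_expressed(X, ct == t) for t in types}, index=bundle.gene_ids
        )
        pb = md.pseudobulk(
            X, ct, bundle.nucleus_meta["sample"].to_numpy()[clean],
            min_nuclei=20, gene_ids=bundle.gene_ids,
        )
        de = md.ovr_marker_de(pb)
        markers = md.select_markers(auc, de, pct, md.MarkerCriteria.global_preset())
        # generative truth of "marker for type t": the planted exclusive
        # genes plus any gene whose program rate in t is >4x every other
        # type's (the fold-change the selection thresholds demand)
        # a gene is genuinely marker-like for t when its program rate
        # exceeds 4x the geometric mean of the other types' rates (the
        # log-scale one-vs-rest contrast the selection model estimates)
        progs = truth.programs + 1e-5  # pseudocount on the rate scale
        for t in types:
            sel = set(markers[t])
            assert sel, f"no markers selected for {t}"
            others = progs.drop(index=t)
            geo = np.exp(np.log(others).mean(axis=0))
            enriched = set(progs.columns[(progs.loc[t] > 4 * geo).to_numpy()])
            genuine = enriched | set(truth.marker_genes[t])
            precision = len(sel & genuine) / len(sel)
            assert precision >= 0.9
            recall = len(sel & set(truth.marker_genes[t])) / len(truth.marker_genes[t])
            assert recall >= 0.9
            # planted exclusive markers never selected for a foreign type
            for o in types:
                if o != t:
                    assert not set(truth.marker_genes[t]) & set(markers[o])

    def test_ovr_model_needs_two_clusters(self, rng):
        pb = _null_pseudobulk(rng, n_genes=20)
        with pytest.raises(ValueError):
            md.ovr_marker_de(pb)


class TestPatientPCA:
    def test_conditions_separate(self, de_bundle):
        from sklearn.metrics import silhouette_score

        bundle, truth = de_bundle
        clean = truth.clean_singlets().to_numpy()
        samples = bundle.nucleus_meta["sample"].to_numpy()[clean]
        pb = md.pseudobulk(
            bundle.corrected_counts[clean], ["all"] * clean.sum(), samples,
            min_nuclei=1, gene_ids=bundle.gene_ids,
        )
        counts = pb.counts.copy()
        counts.columns = pb.col_meta["sample"]
        coords = md.patient_pca(counts)
        cond = [s.split("_")[0] for s in coords.index]
        assert silhouette_score(coords.iloc[:, :1], cond) > 0.5

    def test_duplicated_sample_identical_coordinates(self, rng):
        counts = pd.DataFrame(rng.integers(10, 100, size=(200, 5)),
                              columns=list("abcde"))
        counts["e"] = counts["a"]
        coords = md.patient_pca(counts)
        np.testing.assert_allclose(coords.loc["a"], coords.loc["e"], atol=1e-9)

    def test_centered_and_min_samples(self, rng):
        counts = pd.DataFrame(rng.integers(10, 100, size=(100, 4)))
        coords = md.patient_pca(counts)
        np.testing.assert_allclose(coords.mean(axis=0), 0, atol=1e-8)
        with pytest.raises(ValueError):
            md.patient_pca(counts.iloc[:, :2])
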