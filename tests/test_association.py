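"""OLS and mixed-model association tests, cis and genome scans."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import dosaqtl as dq


class TestOls:
    def test_perfect_fit(self):
        rng = np.random.default_rng(0)
        g = rng.binomial(2, 0.3, 100).astype(float)
        res = dq.test_variant_ols(g, g.copy())
        assert res.beta == pytest.approx(1.0)
        assert res.p < 1e-100

    def test_constant_dosage_untestable(self):
        res = dq.test_variant_ols(np.full(50, 1.0), np.random.default_rng(0).normal(size=50))
        assert res.status == "untestable" and not res.testable

    def test_permutation_type_one_error(self):
        rng = np.random.default_rng(1)
        g = rng.binomial(2, 0.3, 450).astype(float)
        y = rng.standard_normal(450)
        reps = 2000
        # permute phenotype, re-test: rejection rate at 0.05 stays nominal
        pvals = [dq.test_variant_ols(g, rng.permutation(y)).p for _ in range(reps)]
        assert np.mean(np.asarray(pvals) < 0.05) == pytest.approx(0.05, abs=0.01)

    def test_bulk_matches_single(self):
        rng = np.random.default_rng(2)
        G = rng.binomial(2, 0.2, size=(20, 200)).astype(float)
        y = rng.standard_normal(200)
        frame = dq.bulk_ols(G, y)
        for i in range(20):
            res = dq.test_variant_ols(G[i], y)
            assert frame["beta"].iloc[i] == pytest.approx(res.beta, rel=1e-10)
            assert frame["p"].iloc[i] == pytest.approx(res.p, rel=1e-8)

    def test_null_pvalues_uniform(self):
        rng = np.random.default_rng(3)
        G = rng.binomial(2, 0.25, size=(10_000, 450)).astype(float)
        y = rng.standard_normal(450)
        ps = dq.bulk_ols(G, y)["p"].to_numpy()
        ks = stats.kstest(ps, "uniform").statistic
        assert ks < 0.02

    def test_effect_frequency_bookkeeping(self):
        # beta^2 * 2p(1-p) recovers V at large n
        rng = np.random.default_rng(4)
        n, maf, V = 20_000, 0.1, 0.05
        g = rng.binomial(2, maf, n).astype(float)
        beta = dq.effect_from_variance(V, maf)
        y = beta * (g - 2 * maf) + rng.normal(0, np.sqrt(1 - V), n)
        res = dq.test_variant_ols(g, y)
        p_hat = g.mean() / 2
        assert res.beta**2 * 2 * p_hat * (1 - p_hat) == pytest.approx(V, abs=0.02)


class TestMixedModel:
    def test_identity_kinship_reduces_to_ols(self):
        rng = np.random.default_rng(5)
        n = 120
        y = rng.standard_normal(n)
        null = dq.fit_null_mixed(y, np.eye(n))
        for _ in range(5):
            g = rng.binomial(2, 0.3, n).astype(float)
            pm = dq.test_variant_mixed(g, null).p
            po = dq.test_variant_ols(g, y).p
            assert pm == pytest.approx(po, rel=1e-6)

    def test_heritability_recovered_with_sibs(self):
        # single-cohort REML of h2 is noisy with 200 sib pairs, so average
        rng = np.random.default_rng(6)
        n = 400
        K = np.eye(n)
        for i in range(0, n, 2):
            K[i, i + 1] = K[i + 1, i] = 0.5
        L = np.linalg.cholesky(K)
        h2 = 0.4
        fits = []
        for _ in range(5):
            y = np.sqrt(h2) * (L @ rng.standard_normal(n)) + np.sqrt(
                1 - h2
            ) * rng.standard_normal(n)
            fits.append(dq.fit_null_mixed(y, K).h2)
        assert np.mean(fits) == pytest.approx(0.4, abs=0.1)

    def test_boundary_flagged_on_pure_noise(self):
        rng = np.random.default_rng(7)
        n = 200
        K = np.eye(n)
        for i in range(0, n, 2):
            K[i, i + 1] = K[i + 1, i] = 0.5
        fits = [
            dq.fit_null_mixed(rng.standard_normal(n), K).h2 for _ in range(10)
        ]
        assert np.median(fits) < 0.2  # no genetic signal to find

    def test_non_psd_kinship_rejected(self):
        K = np.eye(10)
        K[0, 1] = K[1, 0] = 2.0
        with pytest.raises(ValueError):
            dq.fit_null_mixed(np.random.default_rng(0).normal(size=10), K)

    def test_mixed_matches_ols_on_unrelated_cohort(self, pool, cohort, dosage_matrix):
        rng = np.random.default_rng(8)
        y = rng.standard_normal(cohort.n_individuals)
        null = dq.fit_null_mixed(y, cohort.kinship)  # identity for unrelateds
        rows = np.flatnonzero(dosage_matrix.variants["maf"].to_numpy() > 0.05)[:200]
        for i in rows[:50]:
            pm = dq.test_variant_mixed(dosage_matrix.dosages[i], null).p
            po = dq.test_variant_ols(dosage_matrix.dosages[i], y).p
            assert abs(np.log10(pm) - np.log10(po)) < 0.05


class TestScans:
    def _planted_trait(self, pool, cohort, V, seed):
        truth = dq.make_truth_table(
            cohort, pool, 1, variance_explained=V, causal_bin="common", seed=seed
        )
        pt = dq.simulate_traits(
            cohort, truth, dq.make_covariates(cohort.n_individuals, seed=seed), seed=seed
        )
        ann = dq.make_probe_annotation(truth, pool, seed=seed)
        return truth, pt, ann

    def test_index_recovers_planted_causal(self, pool, cohort, dosage_matrix):
        # causal mid-window at V=0.10: index = causal in nearly all noise draws
        rng = np.random.default_rng(9)
        kept, _ = dq.filter_variants(dosage_matrix)
        maf = kept.variants["maf"].to_numpy()
        # choose a causal with no near-perfect proxy so the index is unambiguous
        cand = np.flatnonzero(maf > 0.2)
        causal = None
        for c in cand:
            r2max = 0.0
            g = kept.dosages[c]
            for j in rng.choice(kept.n_variants, 200, replace=False):
                if j != c:
                    r2max = max(r2max, dq.pairwise_r2(g, kept.dosages[j]))
            if r2max < 0.8:
                causal = int(c)
                break
        assert causal is not None
        g = kept.dosages[causal]
        p_hat = g.mean() / 2
        beta = dq.effect_from_variance(0.10, min(p_hat, 1 - p_hat))
        pos = int(kept.variants["pos"].iloc[causal])
        ann = pd.DataFrame({"trait": ["T0"], "chrom": ["1"], "tss": [pos]})
        hits = 0
        reps = 200
        for r in range(reps):
            y = beta * (g - g.mean()) + rng.normal(0, np.sqrt(0.90), g.size)
            scan = dq.scan_cis("T0", y, ann, kept)
            if int(scan.index["pos"]) == pos:
                hits += 1
        assert hits / reps >= 0.95

    def test_empty_window_empty_result(self, dosage_matrix):
        ann = pd.DataFrame({"trait": ["T9"], "chrom": ["99"], "tss": [5_000_000]})
        scan = dq.scan_cis("T9", np.zeros(dosage_matrix.n_samples), ann, dosage_matrix)
        assert scan.results.empty and scan.index is None

    def test_traits_do_not_leak_state(self, pool, cohort, dosage_matrix):
        truth, pt, ann = self._planted_trait(pool, cohort, 0.10, seed=10)
        t = truth["trait"].iloc[0]
        y = pt.traits[t].to_numpy()
        s1 = dq.scan_cis(t, y, ann, dosage_matrix)
        dq.scan_cis(t, np.random.default_rng(1).normal(size=y.size), ann, dosage_matrix)
        s3 = dq.scan_cis(t, y, ann, dosage_matrix)
        pd.testing.assert_frame_equal(s1.results, s3.results)

    def test_scan_window_bounds(self, pool, cohort, dosage_matrix):
        truth, pt, ann = self._planted_trait(pool, cohort, 0.10, seed=11)
        t = truth["trait"].iloc[0]
        scan = dq.scan_cis(t, pt.traits[t].to_numpy(), ann, dosage_matrix)
        tss = int(ann["tss"].iloc[0])
        assert scan.results["pos"].between(tss - 1_000_000, tss + 1_000_000).all()

    def test_index_by_bin_partition(self, pool, cohort, dosage_matrix):
        truth, pt, ann = self._planted_trait(pool, cohort, 0.10, seed=12)
        t = truth["trait"].iloc[0]
        scan = dq.scan_cis(t, pt.traits[t].to_numpy(), ann, dosage_matrix)
        for label, row in scan.index_by_bin.items():
            if label == "common":
                assert row["maf"] >= 0.05
            else:
                assert row["maf"] < 0.05

    def test_genome_scan_mixed_model(self, pool):
        coh = dq.sample_cohort(pool, 120, relatedness=dq.SibshipSpec(30), seed=13)
        dm = dq.degrade_to_dosages(coh, pool, dq.QualitySpec(1.0), seed=14)
        sub = dm.take(np.arange(100))
        rng = np.random.default_rng(15)
        y = rng.standard_normal(120)
        scan = dq.scan_genome("B0", y, sub, model="mixed", kinship=coh.kinship)
        assert len(scan.results) == 100
        assert (scan.results["model"] == "mixed").all()
        with pytest.raises(ValueError):
            dq.scan_genome("B0", y, sub, model="mixed", kinship=None)
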