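"""Conditional analysis: opposing-bin conditioning, clumping, classification."""

import numpy as np
import pandas as pd
import pytest

import dosaqtl as dq
from dosaqtl.conditional import (
    ATTENUATED,
    COLLINEAR,
    FULLY_EXPLAINED,
    RETAINED,
    classify_scan,
)

from _oracles import brute_force_clump


class TestBestOpposingVariant:
    def _frame(self, mafs, ps):
        return pd.DataFrame({"maf": mafs, "p": ps, "pos": range(100, 100 + 100 * len(ps), 100)})

    def test_no_low_frequency_variants_none(self):
        res = self._frame([0.3, 0.2], [1e-8, 1e-3])
        assert dq.best_opposing_variant(res, "common") is None

    def test_argmin_selected(self):
        res = self._frame([0.3, 0.02, 0.03], [1e-8, 1e-3, 1e-8])
        best = dq.best_opposing_variant(res, "common")
        assert best["maf"] == 0.03  # smaller p among low-frequency rows

    def test_tie_breaks_to_lower_position(self):
        res = self._frame([0.02, 0.03], [1e-5, 1e-5])
        best = dq.best_opposing_variant(res, "common")
        assert best["pos"] == 100


class TestConditionalTest:
    def test_empty_set_equals_unconditional(self):
        rng = np.random.default_rng(0)
        g = rng.binomial(2, 0.3, 200).astype(float)
        y = 0.4 * g + rng.standard_normal(200)
        unc = dq.test_variant_ols(g, y)
        cond = dq.conditional_test(y, g, None)
        assert cond.beta == pytest.approx(unc.beta, rel=1e-12)
        assert cond.p == pytest.approx(unc.p, rel=1e-10)

    def test_orthogonal_conditioner_changes_little(self):
        rng = np.random.default_rng(1)
        g = rng.binomial(2, 0.3, 450).astype(float)
        other = rng.binomial(2, 0.3, 450).astype(float)
        y = 0.4 * g + rng.standard_normal(450)
        p0 = dq.test_variant_ols(g, y).p
        p1 = dq.conditional_test(y, g, other).p
        assert abs(np.log10(p1) - np.log10(p0)) < 0.2

    def test_conditioning_on_causal_kills_proxy(self):
        # proxy at r2 ~ 0.9 with the causal loses its signal once conditioned
        killed = 0
        reps = 60
        for r in range(reps):
            dm, y, info = dq.simulate_tagged_locus(
                450, maf_causal=0.184, maf_tag=0.2, variance_explained=0.10,
                n_background=0, seed=100 + r,
            )
            causal = dm.dosages[info["causal_row"]]
            proxy = dm.dosages[info["tag_row"]]
            if dq.pairwise_r2(causal, proxy) < 0.8:
                continue
            res = dq.conditional_test(y, proxy, causal)
            if res.status == "ok" and res.p > 0.05:
                killed += 1
        assert killed / reps >= 0.90

    def test_collinear_conditioner_flagged(self):
        rng = np.random.default_rng(2)
        g = rng.binomial(2, 0.3, 100).astype(float)
        y = rng.standard_normal(100)
        res = dq.conditional_test(y, g, g.copy())
        assert res.status == COLLINEAR
        assert np.isnan(res.p)

    def test_conditioning_on_self_forbidden(self):
        g = np.arange(20.0)
        with pytest.raises(ValueError):
            dq.conditional_test(np.arange(20.0), g, g)

    def test_redundant_conditioners_dropped(self):
        rng = np.random.default_rng(3)
        g = rng.binomial(2, 0.3, 100).astype(float)
        c = rng.binomial(2, 0.2, 100).astype(float)
        y = 0.5 * g + rng.standard_normal(100)
        res = dq.conditional_test(y, g, np.vstack([c, c * 1.0]))
        assert res.status == "ok"
        assert len(res.conditioning) == 1


class TestClump:
    def test_all_correlated_single_index(self):
        rng = np.random.default_rng(4)
        base = rng.binomial(2, 0.3, 100).astype(float)
        G = np.vstack([base, base, base]) + rng.normal(0, 0.01, (3, 100))
        res = pd.DataFrame({"p": [1e-6, 1e-5, 1e-7], "pos": [1, 2, 3], "maf": 0.3})
        cs = dq.clump(res, G, p_max=1e-4, r2_max=0.2)
        assert cs.indices == [2]  # smallest p wins, rest removed

    def test_independent_signals_both_kept(self):
        rng = np.random.default_rng(5)
        G = rng.binomial(2, 0.3, size=(2, 500)).astype(float)
        res = pd.DataFrame({"p": [1e-6, 1e-5], "pos": [1, 2], "maf": 0.3})
        cs = dq.clump(res, G, p_max=1e-4, r2_max=0.2)
        assert sorted(cs.indices) == [0, 1]

    def test_p_max_gate(self):
        rng = np.random.default_rng(6)
        G = rng.binomial(2, 0.3, size=(2, 100)).astype(float)
        res = pd.DataFrame({"p": [1e-6, 1e-3], "pos": [1, 2], "maf": 0.3})
        cs = dq.clump(res, G, p_max=1e-4, r2_max=0.2)
        assert cs.indices == [0]

    def test_matches_brute_force_on_random_instances(self):
        rng = np.random.default_rng(7)
        for trial in range(20):
            m = int(rng.integers(3, 16))
            G = rng.binomial(2, 0.3, size=(m, 80)).astype(float)
            G += rng.normal(0, 0.05, G.shape)
            pvals = 10.0 ** rng.uniform(-8, -2, m)
            pos = np.arange(m) * 10
            res = pd.DataFrame({"p": pvals, "pos": pos, "maf": 0.3})
            cs = dq.clump(res, G, p_max=1e-4, r2_max=0.3)
            R2 = np.zeros((m, m))
            for i in range(m):
                for j in range(m):
                    if i != j:
                        R2[i, j] = dq.pairwise_r2(G[i], G[j])
            ref = brute_force_clump(pvals, pos, R2, 1e-4, 0.3)
            assert cs.indices == ref

    def test_survivors_mutually_independent(self):
        rng = np.random.default_rng(8)
        m = 12
        G = rng.binomial(2, 0.3, size=(m, 200)).astype(float)
        res = pd.DataFrame(
            {"p": 10.0 ** rng.uniform(-9, -5, m), "pos": np.arange(m), "maf": 0.3}
        )
        cs = dq.clump(res, G, p_max=1e-4, r2_max=0.2)
        for a in cs.indices:
            for b in cs.indices:
                if a != b:
                    assert dq.pairwise_r2(G[a], G[b]) < 0.2


class TestClassification:
    @pytest.mark.parametrize(
        "p_unc,p_cond,label",
        [
            (1e-8, 0.3, FULLY_EXPLAINED),
            (1e-8, 1e-7, RETAINED),
            (1e-8, 1e-3, ATTENUATED),
        ],
    )
    def test_rule_application(self, p_unc, p_cond, label):
        assert dq.classify_signal(p_unc, p_cond, 1e-6) == label

    def test_collinear_excluded(self):
        assert dq.classify_signal(1e-8, None, 1e-6, status=COLLINEAR) == COLLINEAR

    def test_undefined_conditional_p_rejected(self):
        with pytest.raises(ValueError):
            dq.classify_signal(1e-8, np.nan, 1e-6)

    def test_classify_scan_partition(self):
        # every classified signal gets exactly one of the defined labels
        labels = set()
        for r in range(20):
            dm, y, info = dq.simulate_tagged_locus(450, seed=300 + r)
            scan = dq.bulk_ols(dm.dosages, y)
            res = pd.concat([dm.variants[["pos", "maf"]], scan], axis=1)
            rec = classify_scan(y, res, dm.dosages, discovery_threshold=1e-4)
            if rec is not None:
                labels.add(rec.classification)
        assert labels <= {FULLY_EXPLAINED, RETAINED, ATTENUATED, COLLINEAR}
        assert labels  # at least one signal classified


class TestCompareDetection:
    def _signals(self):
        return pd.DataFrame(
            {"trait": ["T0", "T1"], "chrom": ["1", "1"], "pos": [1000, 500_000],
             "p": [1e-9, 1e-8]}
        )

    def _results(self, ps, pos=None):
        return pd.DataFrame(
            {
                "trait": ["T0", "T1"],
                "chrom": ["1", "1"],
                "pos": pos or [1000, 500_000],
                "p": ps,
            }
        )

    def test_identity_fully_detected(self):
        sig = self._signals()
        rep = dq.compare_detection(sig, self._results([1e-9, 1e-8]), 1e-6)
        assert rep["detected_strict"].all() and rep["detected_loose"].all()

    def test_absent_regions_nothing_detected(self):
        sig = self._signals()
        far = self._results([1e-9, 1e-8], pos=[10_000_000, 20_000_000])
        rep = dq.compare_detection(sig, far, 1e-6)
        assert not rep["detected_strict"].any()
        assert rep["weaker_or_absent"].all()

    def test_degraded_set_detects_fewer(self):
        # dosage quality 0.5 at the causal attenuates the second set's signal
        rows_a, rows_b = [], []
        for r in range(25):
            dm, y, info = dq.simulate_tagged_locus(450, variance_explained=0.08,
                                                   seed=400 + r)
            causal = info["causal_row"]
            scan_a = dq.bulk_ols(dm.dosages, y)
            pos = dm.variants["pos"].to_numpy()
            rows_a.append({"trait": f"T{r}", "chrom": "1",
                           "pos": pos[causal], "p": scan_a["p"].iloc[causal]})
            rng = np.random.default_rng(500 + r)
            noisy = dm.dosages.copy()
            g = noisy[causal]
            p_hat = g.mean() / 2
            lam = 0.5
            noisy[causal] = np.clip(
                2 * p_hat + lam * (g - 2 * p_hat)
                + rng.normal(0, 0.3, g.size), 0, 2,
            )
            scan_b = dq.bulk_ols(noisy, y)
            for i in range(len(pos)):
                rows_b.append({"trait": f"T{r}", "chrom": "1", "pos": pos[i],
                               "p": scan_b["p"].iloc[i]})
        sig_a = pd.DataFrame(rows_a)
        res_b = pd.DataFrame(rows_b)
        rep = dq.compare_detection(sig_a, res_b, strict_threshold=1e-6)
        frac_a = np.mean(sig_a["p"] < 1e-6)
        frac_b = rep["detected_strict"].mean()
        assert frac_b < frac_a

    def test_missing_trait_counts_as_no_proxy(self):
        sig = self._signals()
        only_t0 = self._results([1e-9, 1e-8]).iloc[:1]
        rep = dq.compare_detection(sig, only_t0, 1e-6)
        assert not rep.loc[rep["trait"] == "T1", "has_proxy"].iloc[0]
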