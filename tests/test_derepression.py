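import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from cystkit.derepression import (
    bh_fdr,
    differential_expression,
    improvement_analysis,
    ks_derepression_test,
    seed_match_targets,
    seed_sites,
)
from cystkit.synthgen import (
    DiseaseDesign,
    gen_disease_treatment_counts,
    gen_utr_fasta,
)


def bh_brute_force(p):
    """Independent BH step-up: q_(i) = min_{j>=i} p_(j)·m/j, capped at 1."""
    p = np.asarray(p, float)
    m = p.size
    order = np.argsort(p, kind="mergesort")
    q_sorted = np.empty(m)
    running = 1.0
    for i in range(m - 1, -1, -1):
        running = min(running, p[order[i]] * m / (i + 1))
        q_sorted[i] = running
    q = np.empty(m)
    q[order] = q_sorted
    return q


def ks_d_brute_force(x, y):
    """Max absolute CDF gap over all pooled sample points."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    pts = np.concatenate([x, y])
    return max(abs((x <= t).mean() - (y <= t).mean()) for t in pts)


class TestSeedMatch:
    def test_planted_sites_classified_by_type(self, mir17):
        motifs = seed_sites(mir17)
        # prefix with T so the base before a planted 7mer-A1 site cannot
        # extend it into an 8mer (that would need the m8 complement)
        utrs = {
            "with8": "TTTT" + motifs["8mer"] + "CCCC",
            "with7m8": "TTTT" + motifs["7mer-m8"] + "CCCC",
            "with7a1": "TTTT" + motifs["7mer-A1"] + "CCCC",
            "none": "GGGGCCCCGGGGCCCC",
        }
        ann = seed_match_targets(utrs, mir17)
        assert ann.loc["with8", "site_types"] == "8mer"
        assert ann.loc["with7m8", "site_types"] == "7mer-m8"
        assert ann.loc["with7a1", "site_types"] == "7mer-A1"
        assert not ann.loc["none", "is_target"]
        assert (ann["is_target"] == (ann["n_sites"] >= 1)).all()

    def test_m8_context_distinguishes_8mer_from_7mers(self, mir17):
        # 7mer-m8 followed by A is an 8mer, not two sites
        motifs = seed_sites(mir17)
        ann = seed_match_targets({"u": "GG" + motifs["7mer-m8"] + "A" + "GG"}, mir17)
        assert ann.loc["u", "n_8mer"] == 1
        assert ann.loc["u", "n_7mer_m8"] == 0
        assert ann.loc["u", "n_7mer_a1"] == 0

    def test_rna_alphabet_accepted(self, mir17):
        motifs = seed_sites(mir17)
        rna = ("GG" + motifs["8mer"] + "GG").replace("T", "U")
        ann = seed_match_targets({"u": rna}, mir17)
        assert ann.loc["u", "n_8mer"] == 1

    def test_generator_truth_table_agrees_exactly(self, mir17):
        seqs, truth = gen_utr_fasta(
            100, {"8mer": 10, "7mer-m8": 10, "7mer-A1": 10}, mir17, seed=5)
        ann = seed_match_targets(seqs, mir17)
        assert (ann["is_target"] == truth["is_target"]).all()
        planted = truth.loc[truth["is_target"], "site_type"]
        assert (ann.loc[planted.index, "site_types"] == planted).all()

    def test_short_mirna_rejected(self):
        with pytest.raises(ValueError, match="8 nt"):
            seed_sites("ACGUACG")

    def test_invalid_alphabet_rejected(self, mir17):
        with pytest.raises(ValueError):
            seed_match_targets({"u": "ACGTNNN"}, mir17)


class TestDifferentialExpression:
    @staticmethod
    def null_counts(n_genes=200, n=4, seed=0):
        rng = np.random.default_rng(seed)
        mu = rng.lognormal(4, 1, n_genes)
        counts = pd.DataFrame(
            {f"s{i}": rng.poisson(mu) for i in range(2 * n)},
            index=[f"g{i}" for i in range(n_genes)])
        labels = pd.Series(["a"] * n + ["b"] * n, index=counts.columns)
        return counts, labels

    def test_identical_groups_have_zero_log2fc(self):
        counts, _ = self.null_counts()
        doubled = pd.concat([counts, counts.add_suffix("_copy")], axis=1)
        labels = pd.Series(["a"] * counts.shape[1] + ["b"] * counts.shape[1],
                           index=doubled.columns)
        de = differential_expression(doubled, labels, "a", "b")
        assert np.allclose(de["log2fc"], 0.0)

    def test_doubled_counts_give_log2fc_near_one(self):
        rng = np.random.default_rng(1)
        base = rng.poisson(500, size=(300, 4))
        counts = pd.DataFrame(
            np.hstack([base, 2 * base]),
            columns=[f"s{i}" for i in range(8)],
            index=[f"g{i}" for i in range(300)])
        # equalize library sizes so CPM sees the per-gene doubling
        gene = "g0"
        counts.loc["ballast"] = 0
        lib = counts.sum(axis=0)
        counts.loc["ballast"] = lib.max() - lib
        labels = pd.Series(["a"] * 4 + ["b"] * 4, index=counts.columns)
        de = differential_expression(counts, labels, "a", "b")
        assert de.loc[gene, "log2fc"] == pytest.approx(1.0, abs=0.02)

    def test_group_with_one_sample_rejected(self):
        counts, labels = self.null_counts(n=2)
        labels.iloc[0] = "c"
        with pytest.raises(ValueError, match="at least 2"):
            differential_expression(counts, labels, "a", "b")

    def test_null_type_one_error_near_nominal(self):
        design = DiseaseDesign(n_genes=5000, frac_dysregulated=0.0, seed=11)
        dc = gen_disease_treatment_counts(design)
        combined, labels = dc.combined()
        de = differential_expression(combined, labels, "control", "disease")
        frac = (de["p_value"] < 0.05).mean()
        # nominal 0.05 within MC error plus the Welch-on-log2CPM approximation
        assert frac == pytest.approx(0.05, abs=0.015)
        assert (de["fdr"] < 0.05).sum() <= 5  # BH keeps the null quiet


class TestBH:
    def test_single_p_unchanged(self):
        assert bh_fdr([0.03])[0] == pytest.approx(0.03)

    def test_hand_worked_step_up(self):
        assert np.allclose(bh_fdr([0.01, 0.02, 0.03, 0.04]), [0.04] * 4)

    def test_all_ones_stay_one(self):
        assert np.allclose(bh_fdr([1.0, 1.0, 1.0]), 1.0)

    def test_monotone_in_sorted_order(self):
        rng = np.random.default_rng(0)
        p = rng.uniform(size=40)
        q = bh_fdr(p)
        order = np.argsort(p)
        assert np.all(np.diff(q[order]) >= -1e-12)

    @given(st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1, max_size=8))
    def test_matches_brute_force_step_up(self, p):
        assert np.allclose(bh_fdr(p), bh_brute_force(p), atol=1e-12)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_fdr([0.5, 1.5])


def de_frame(log2fc, fdr=None, genes=None):
    log2fc = np.asarray(log2fc, float)
    genes = genes or [f"g{i}" for i in range(log2fc.size)]
    return pd.DataFrame(
        {"log2fc": log2fc,
         "p_value": fdr if fdr is not None else np.ones(log2fc.size),
         "fdr": fdr if fdr is not None else np.ones(log2fc.size)},
        index=pd.Index(genes, name="gene"))


class TestKS:
    def test_disjoint_supports_give_d_one(self):
        de = de_frame([2, 3] + [0, 1] * 10)
        targets = ["g0", "g1"] + [f"g{i}" for i in range(2, 10)]
        # pad target group to the minimum size with more high values
        de = de_frame([2, 3, 2.5, 2.2, 2.9, 2.1, 2.7, 2.4, 2.8, 2.6] + [0, 1] * 10)
        targets = [f"g{i}" for i in range(10)]
        res = ks_derepression_test(de, targets)
        assert res.d_statistic == 1.0
        assert res.median_shift > 0

    def test_identical_multisets_give_d_zero(self):
        vals = list(range(10))
        de = de_frame(vals + vals)
        res = ks_derepression_test(de, [f"g{i}" for i in range(10)])
        assert res.d_statistic == 0.0

    def test_equals_brute_force_on_small_vectors(self, rng):
        for _ in range(20):
            nx, ny = rng.integers(10, 16, 2)
            x = rng.normal(size=nx)
            y = rng.normal(0.5, 1.2, size=ny)
            de = de_frame(np.concatenate([x, y]))
            res = ks_derepression_test(de, [f"g{i}" for i in range(nx)])
            assert res.d_statistic == pytest.approx(ks_d_brute_force(x, y), abs=1e-12)

    def test_invariant_under_common_monotone_transform(self, rng):
        x = rng.normal(size=30)
        y = rng.normal(1.0, 2.0, size=40)
        de1 = de_frame(np.concatenate([x, y]))
        de2 = de_frame(np.concatenate([np.tanh(x), np.tanh(y)]))
        targets = [f"g{i}" for i in range(30)]
        assert ks_derepression_test(de1, targets).d_statistic == pytest.approx(
            ks_derepression_test(de2, targets).d_statistic)

    def test_small_group_rejected(self):
        de = de_frame(list(range(15)))
        with pytest.raises(ValueError, match=">= 10"):
            ks_derepression_test(de, ["g0", "g1"])

    def test_null_rejection_rate_near_alpha(self):
        rng = np.random.default_rng(13)
        rejections = 0
        n_rep = 1000
        for _ in range(n_rep):
            vals = rng.normal(size=400)
            de = de_frame(vals)
            res = ks_derepression_test(de, [f"g{i}" for i in range(200)],
                                       method="asymp")
            rejections += res.p_value < 0.05
        assert rejections / n_rep == pytest.approx(0.05, abs=0.02)


def naive_improved_set(dis, trt, fdr_cut=0.05, lfc_cut=0.5):
    """Independent three-condition filter over the shared universe."""
    out = []
    for g in dis.index.intersection(trt.index):
        if dis.loc[g, "fdr"] >= fdr_cut:
            continue
        if trt.loc[g, "fdr"] < fdr_cut and abs(trt.loc[g, "log2fc"]) > lfc_cut \
                and np.sign(trt.loc[g, "log2fc"]) == -np.sign(dis.loc[g, "log2fc"]):
            out.append(g)
    return set(out)


class TestImprovement:
    def test_exact_reversal_gives_rho_minus_one_and_full_set(self, rng):
        lfc = rng.normal(0, 2, 50)
        lfc[np.abs(lfc) < 0.6] += np.sign(lfc[np.abs(lfc) < 0.6]) * 0.7
        dis = de_frame(lfc, fdr=np.full(50, 0.001))
        trt = de_frame(-lfc, fdr=np.full(50, 0.001))
        res = improvement_analysis(dis, trt)
        assert res.rho == pytest.approx(-1.0)
        assert res.n_improved == res.n_dysregulated == 50

    def test_same_direction_gives_rho_plus_one_and_empty_set(self, rng):
        lfc = rng.normal(0, 2, 50) + 1.0
        dis = de_frame(lfc, fdr=np.full(50, 0.001))
        trt = de_frame(lfc, fdr=np.full(50, 0.001))
        res = improvement_analysis(dis, trt)
        assert res.rho == pytest.approx(1.0)
        assert res.n_improved == 0

    def test_empty_dysregulated_set_flagged(self):
        dis = de_frame([1.0, -1.0], fdr=np.array([0.9, 0.9]))
        trt = de_frame([1.0, -1.0], fdr=np.array([0.9, 0.9]))
        res = improvement_analysis(dis, trt)
        assert res.n_dysregulated == 0 and not res.rho_defined

    def test_matches_naive_filter(self, rng):
        n = 300
        dis = de_frame(rng.normal(0, 1.5, n), fdr=rng.uniform(0, 0.2, n))
        trt = de_frame(rng.normal(0, 1.5, n), fdr=rng.uniform(0, 0.2, n))
        res = improvement_analysis(dis, trt)
        assert set(res.improved_genes) == naive_improved_set(dis, trt)
        assert res.n_improved <= res.n_dysregulated

    def test_generator_rescue_fraction_recovered(self):
        design = DiseaseDesign(n_genes=3000, frac_dysregulated=0.1,
                               rescue_fraction=0.6, seed=3)
        dc = gen_disease_treatment_counts(design)
        combined, labels = dc.combined()
        de_dis = differential_expression(combined, labels, "control", "disease")
        de_trt = differential_expression(combined, labels, "disease", "treated")
        res = improvement_analysis(de_dis, de_trt)
        assert res.rho < -0.5
        detected_true = int((dc.truth["is_dysregulated"]
                             & (de_dis["fdr"] < 0.05)).sum())
        center = design.rescue_fraction * detected_true
        half_width = 1.96 * np.sqrt(detected_true * 0.6 * 0.4)
        assert abs(res.n_improved - center) <= half_width

    def test_rho_becomes_more_negative_with_stronger_rescue(self):
        rhos = []
        for strength in (0.2, 0.6, 1.0):
            rho_acc = []
            for seed in (1, 2, 3):
                dc = gen_disease_treatment_counts(DiseaseDesign(
                    n_genes=1000, rescue_strength=strength, seed=seed))
                combined, labels = dc.combined()
                de_dis = differential_expression(combined, labels, "control", "disease")
                de_trt = differential_expression(combined, labels, "disease", "treated")
                rho_acc.append(improvement_analysis(de_dis, de_trt).rho)
            rhos.append(np.mean(rho_acc))
        assert rhos[0] > rhos[1] > rhos[2]
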