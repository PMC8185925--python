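import itertools
import math

import numpy as np
import pandas as pd
import pytest

from rametab import (assign_activity_group, assign_crp_group,
                     differential_abundance_scan, hypergeometric_enrichment,
                     log2_fold_change)
from rametab.scans import confounder_screen


class TestActivityGroups:
    @pytest.mark.parametrize("score,expected", [
        (3.2, "lower"), (3.2000001, "higher"), (1.2, "lower"),
        (7.0, "higher"), (0.0, "lower")])
    def test_boundary_belongs_to_lower(self, score, expected):
        assert assign_activity_group(score) == expected

    def test_partition_covers_all_samples(self, discovery):
        _, meta, _, _ = discovery
        labels = assign_activity_group(meta["das28_crp"])
        counts = pd.Series(labels).value_counts()
        assert counts.sum() == len(meta)

    def test_missing_score_rejected(self):
        with pytest.raises(ValueError):
            assign_activity_group(float("nan"))

    @pytest.mark.parametrize("crp,expected", [(3.0, "low"), (3.01, "high")])
    def test_crp_boundary_belongs_to_low(self, crp, expected):
        assert assign_crp_group(crp) == expected


class TestFoldChange:
    def setup_method(self):
        self.labels = pd.Series(["higher"] * 3 + ["lower"] * 3)

    def _matrix(self, hi, lo):
        return pd.DataFrame({"m": list(hi) + list(lo)})

    def test_equal_means_give_zero(self):
        m = self._matrix([1, 2, 3], [3, 2, 1])
        assert log2_fold_change(m, self.labels, "m") == pytest.approx(0.0)

    def test_doubling_gives_one(self):
        m = self._matrix([2, 4, 6], [1, 2, 3])
        assert log2_fold_change(m, self.labels, "m") == pytest.approx(1.0)

    def test_subtle_band(self):
        m = self._matrix([1.2, 1.2, 1.2], [1.0, 1.0, 1.0])
        assert log2_fold_change(m, self.labels, "m") == pytest.approx(
            math.log2(1.2))

    def test_zero_denominator_rejected(self):
        m = self._matrix([1, 2, 3], [0, 0, 0])
        with pytest.raises(ValueError):
            log2_fold_change(m, self.labels, "m")


def brute_force_upper_tail(N, K, n, k):
    """P(X >= k) by exhaustive enumeration of all n-subsets."""
    universe = range(N)
    inside = set(range(K))
    total = hits = 0
    for draw in itertools.combinations(universe, n):
        total += 1
        hits += len(inside.intersection(draw)) >= k
    return hits / total


class TestEnrichment:
    def _annotation(self, N, K):
        return pd.DataFrame({
            "sub_pathway": ["target"] * K + ["other"] * (N - K),
            "super_pathway": "x", "hmdb_id": None,
        }, index=[f"m{i}" for i in range(N)])

    @pytest.mark.parametrize("N,K,n,k", [
        (10, 4, 3, 2), (12, 5, 4, 3), (9, 3, 5, 1), (8, 8, 3, 3)])
    def test_matches_exhaustive_enumeration(self, N, K, n, k):
        ann = self._annotation(N, K)
        hits = [f"m{i}" for i in range(k)] + \
            [f"m{K + i}" for i in range(n - k)]
        res = hypergeometric_enrichment(hits, "target", ann)
        assert res.p_value == pytest.approx(
            brute_force_upper_tail(N, K, n, k), abs=1e-12)
        assert res.fold_enrichment == pytest.approx((k / n) / (K / N))

    def test_whole_universe_pathway_is_null(self):
        ann = self._annotation(6, 6)
        res = hypergeometric_enrichment(["m0", "m1"], "target", ann)
        assert res.p_value == pytest.approx(1.0)
        assert res.fold_enrichment == pytest.approx(1.0)

    def test_example_from_enumeration(self):
        # N=10, K=4, n=3, k>=2 -> 40/120
        ann = self._annotation(10, 4)
        res = hypergeometric_enrichment(["m0", "m1", "m5"], "target", ann)
        assert res.p_value == pytest.approx(1 / 3, abs=1e-12)

    def test_empty_universe_rejected(self):
        ann = self._annotation(5, 2)
        with pytest.raises(ValueError):
            hypergeometric_enrichment([], "target", ann, universe=[])

    def test_unknown_pathway_rejected(self):
        ann = self._annotation(5, 2)
        with pytest.raises(ValueError):
            hypergeometric_enrichment([], "nope", ann)


def fisher_exact_enumeration(table):
    """Two-sided Fisher p by enumerating all tables with fixed margins."""
    a, b = table[0]
    c, d = table[1]
    r1, r2 = a + b, c + d
    c1 = a + c
    def prob(x):
        return (math.comb(r1, x) * math.comb(r2, c1 - x)
                / math.comb(r1 + r2, c1))
    p_obs = prob(a)
    lo = max(0, c1 - r2)
    hi = min(r1, c1)
    return sum(prob(x) for x in range(lo, hi + 1)
               if prob(x) <= p_obs * (1 + 1e-12))


class TestConfounderScreen:
    def _meta(self, seed=0, n_pat=30):
        rng = np.random.default_rng(seed)
        pat = np.repeat([f"P{i:02d}" for i in range(n_pat)], 2)
        visit = np.tile([1, 2], n_pat)
        das = rng.uniform(1.5, 6.5, 2 * n_pat)
        return pd.DataFrame({
            "patient_id": pat, "cohort": "discovery", "visit": visit,
            "das28_crp": das, "crp": rng.lognormal(1, 1, 2 * n_pat),
            "age": np.repeat(rng.normal(60, 12, n_pat), 2),
            "sex": np.repeat(rng.choice(["female", "male"], n_pat), 2),
            "bmi": np.repeat(rng.normal(30, 5, n_pat), 2),
            "smoking": np.repeat(rng.choice(["ever", "never"], n_pat), 2),
            "duration_years": np.repeat(rng.uniform(1, 20, n_pat), 2),
            "methotrexate": np.repeat(rng.integers(0, 2, n_pat), 2),
            "prednisone": np.repeat(rng.integers(0, 2, n_pat), 2),
            "csdmard": np.repeat(rng.integers(0, 2, n_pat), 2),
            "tnfi_bdmard": np.repeat(rng.integers(0, 2, n_pat), 2),
            "non_tnfi_bdmard": np.repeat(rng.integers(0, 2, n_pat), 2),
        }, index=[f"P{i:02d}_V{v}" for i, v in
                  zip(np.repeat(range(n_pat), 2), visit)])

    def test_fisher_p_matches_margin_enumeration(self):
        from scipy.stats import fisher_exact
        rng = np.random.default_rng(4)
        for _ in range(25):
            a, b, c, d = rng.integers(0, 11, 4)
            if (a + b) == 0 or (c + d) == 0 or (a + c) == 0 or (b + d) == 0:
                continue
            p_scipy = fisher_exact([[a, b], [c, d]])[1]
            p_enum = fisher_exact_enumeration([[a, b], [c, d]])
            assert p_scipy == pytest.approx(p_enum, abs=1e-9)

    def test_symmetric_table_is_null(self):
        from scipy.stats import fisher_exact
        or_, p = fisher_exact([[5, 5], [5, 5]])
        assert or_ == pytest.approx(1.0) and p == pytest.approx(1.0)

    def test_sample_odds_ratio_and_exact_p(self):
        from scipy.stats import fisher_exact
        table = [[10, 5], [5, 10]]
        assert (10 * 10) / (5 * 5) == pytest.approx(4.0)
        assert fisher_exact(table)[1] == pytest.approx(
            fisher_exact_enumeration(table), abs=1e-9)

    def test_mcnemar_five_discordant_pairs(self):
        from statsmodels.stats.contingency_tables import mcnemar
        res = mcnemar(np.array([[10, 5], [0, 10]]), exact=True)
        assert res.pvalue == pytest.approx(2 * 0.5 ** 5)

    def test_screen_report_structure(self):
        screen = confounder_screen(self._meta())
        assert set(screen.fisher["covariate"]) >= {
            "age_gt_60", "sex_male", "bmi_gt_30", "duration_gt_9y",
            "smoking_ever", "methotrexate"}
        assert screen.fisher["p_value"].dropna().between(0, 1).all()
        assert len(screen.mcnemar) == 5
        assert 0 <= screen.wilcoxon_das28_p <= 1
        sig = screen.fisher[screen.fisher["testable"]
                            & (screen.fisher["p_value"] < 0.05)]
        assert len(screen.adjustment_set) == len(sig)

    def test_one_level_covariate_reported_untestable(self):
        meta = self._meta()
        meta["sex"] = "female"
        screen = confounder_screen(meta)
        row = screen.fisher.set_index("covariate").loc["sex_male"]
        assert not row["testable"]
        assert "sex" not in screen.adjustment_set


class TestDifferentialAbundanceScan:
    def test_detects_strong_group_difference(self, discovery):
        abundance, meta, _, _ = discovery
        abundance = abundance.copy()
        labels = assign_activity_group(meta["das28_crp"])
        # inject a metabolite strongly separated between activity groups
        rng = np.random.default_rng(0)
        x = rng.normal(1.0, 0.4, len(meta))
        x[np.asarray(labels) == "higher"] += 0.8
        abundance["spiked"] = x
        res = differential_abundance_scan(abundance, meta)
        row = res.set_index("metabolite_id").loc["spiked"]
        assert row["significant"]
        assert row["coefficient"] > 0
        assert row["log2_fold_change"] > 0

    def test_constant_metabolite_excluded_not_crash(self, discovery):
        abundance, meta, _, _ = discovery
        abundance = abundance.copy()
        abundance["flat"] = 1.0
        res = differential_abundance_scan(abundance, meta)
        assert "flat" not in set(res["metabolite_id"])

    def test_single_group_rejected(self, discovery):
        abundance, meta, _, _ = discovery
        meta = meta.copy()
        meta["das28_crp"] = 2.0
        with pytest.raises(ValueError):
            differential_abundance_scan(abundance, meta)

    def test_fdr_column_on_request(self, discovery):
        abundance, meta, _, _ = discovery
        res = differential_abundance_scan(abundance.iloc[:, :8], meta,
                                          add_fdr=True)
        assert "fdr_bh" in res.columns
        assert (res["fdr_bh"] >= res["p_value"] - 1e-12).all()
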