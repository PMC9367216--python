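import itertools
import math

import numpy as np
import pytest
from scipy import stats as sps

from tcrshare.models import HLATable, SampleMeta
from tcrshare.stats import (
    diversity,
    fisher_exact_2x2,
    hla_enrichment,
    kruskal_wallis,
    t_two_sample,
    wilcoxon_rank_sum,
)
from conftest import make_repertoire


class TestDiversity:
    def test_uniform_repertoire_closed_form(self, uniform4):
        rep = diversity(uniform4)
        assert rep.shannon == pytest.approx(math.log(4))
        assert rep.simpson == pytest.approx(0.25)
        assert rep.clonality == pytest.approx(0.0, abs=1e-12)
        assert rep.d50 == 2

    def test_single_clonotype_degenerate(self):
        rep = diversity(make_repertoire("s", [10]))
        assert rep.shannon == 0.0
        assert rep.simpson == 1.0
        assert rep.clonality == 1.0
        assert rep.d50 == 1

    def test_hand_computed_half_quarter_quarter(self):
        rep = diversity(make_repertoire("s", [2, 1, 1]))
        assert rep.shannon == pytest.approx(1.5 * math.log(2))
        assert rep.d50 == 1

    def test_shannon_maximal_only_at_uniform(self):
        uni = diversity(make_repertoire("s", [10, 10, 10, 10]))
        for counts in ([11, 10, 10, 9], [20, 10, 5, 5], [37, 1, 1, 1]):
            perturbed = diversity(make_repertoire("s", counts))
            assert perturbed.shannon < uni.shannon
            assert perturbed.simpson > uni.simpson


class TestWilcoxon:
    def test_identical_multisets_p_one(self):
        res = wilcoxon_rank_sum([1, 2, 3], [1, 2, 3])
        assert res.p_value == pytest.approx(1.0)

    def test_exact_agrees_with_full_permutation_enumeration(self):
        rng = np.random.default_rng(0)
        for _ in range(25):
            nx, ny = int(rng.integers(2, 9)), int(rng.integers(2, 9))
            x = rng.integers(0, 6, size=nx).astype(float)  # ties on purpose
            y = rng.integers(0, 6, size=ny).astype(float)
            res = wilcoxon_rank_sum(x, y)
            # independent enumeration over index subsets
            pooled = np.concatenate([x, y])
            ranks = sps.rankdata(pooled)
            w_obs = ranks[:nx].sum()
            sums = [ranks[list(c)].sum()
                    for c in itertools.combinations(range(nx + ny), nx)]
            sums = np.array(sums)
            p = min(1.0, 2 * min((sums <= w_obs + 1e-9).mean(),
                                 (sums >= w_obs - 1e-9).mean()))
            assert res.p_value == pytest.approx(p)

    def test_large_sample_normal_approximation_reasonable(self):
        rng = np.random.default_rng(1)
        x = rng.normal(0, 1, 30)
        y = rng.normal(1, 1, 30)
        res = wilcoxon_rank_sum(x, y)
        ref = sps.mannwhitneyu(x, y, alternative="two-sided",
                               method="asymptotic", use_continuity=False)
        assert res.p_value == pytest.approx(ref.pvalue, rel=1e-6)

    def test_monotone_transform_invariance(self):
        x = [0.1, 0.5, 0.9, 1.4]
        y = [0.2, 0.3, 1.0, 2.0]
        a = wilcoxon_rank_sum(x, y)
        b = wilcoxon_rank_sum(np.exp(x), np.exp(y))
        assert a.p_value == pytest.approx(b.p_value)


class TestFisher:
    def test_diagonal_three_three(self):
        res = fisher_exact_2x2([[3, 0], [0, 3]])
        assert res.p_value == pytest.approx(0.1)

    def test_agrees_with_hypergeometric_enumeration_small_margins(self):
        rng = np.random.default_rng(2)
        for _ in range(40):
            a, b, c, d = (int(v) for v in rng.integers(0, 8, size=4))
            if (a + b) == 0 or (c + d) == 0 or (a + c) == 0 or (b + d) == 0:
                continue
            res = fisher_exact_2x2([[a, b], [c, d]])
            n = a + b + c + d
            row1, col1 = a + b, a + c
            support = range(max(0, row1 + col1 - n), min(row1, col1) + 1)
            probs = {k: sps.hypergeom.pmf(k, n, col1, row1) for k in support}
            p = sum(v for v in probs.values() if v <= probs[a] * (1 + 1e-9))
            assert res.p_value == pytest.approx(p, abs=1e-10)


class TestTTestAndKW:
    def test_zero_variance_na_flagged_not_raised(self):
        res = t_two_sample([1.0, 1.0, 1.0], [1.0, 1.0])
        assert res.is_na and "zero variance" in res.note

    def test_kw_identical_values_na(self):
        res = kruskal_wallis([[1, 1], [1, 1], [1, 1]])
        assert res.is_na

    def test_kw_type_one_error_calibrated(self):
        rng = np.random.default_rng(3)
        rejections = 0
        n_sim = 1000
        for _ in range(n_sim):
            groups = [rng.normal(size=10) for _ in range(3)]
            if kruskal_wallis(groups).p_value < 0.05:
                rejections += 1
        assert 0.03 <= rejections / n_sim <= 0.07

    def test_group_order_invariance(self):
        x = [3.0, 1.0, 2.0]
        y = [5.0, 4.0, 6.0]
        assert t_two_sample(x, y).p_value == pytest.approx(
            t_two_sample(sorted(x), sorted(y)).p_value
        )
        assert wilcoxon_rank_sum(x, y).p_value == pytest.approx(
            wilcoxon_rank_sum(sorted(x), sorted(y)).p_value
        )


class TestHLAEnrichment:
    def _meta(self, n=10):
        return (
            [SampleMeta(f"GC{i}", "tumor", "II", 60, "male") for i in range(n)]
            + [SampleMeta(f"HC{i}", "control", "NA", 60, "male") for i in range(n)]
        )

    def test_universal_allele_p_one(self):
        meta = self._meta(3)
        hla = [HLATable(m.sample_id, frozenset({"A*02:01"})) for m in meta]
        table = hla_enrichment(hla, meta)
        assert table.loc[table.allele == "A*02:01", "p"].iloc[0] == pytest.approx(1.0)

    def test_planted_enrichment_ranks_first(self):
        meta = self._meta(10)
        hla = []
        for i, m in enumerate(meta):
            alleles = {"B*07:02"} if i % 2 else {"B*07:02", "C*04:01"}
            if m.group == "tumor" and i < 8:
                alleles.add("A*02:01")
            if m.group == "control" and i == 10:
                alleles.add("A*02:01")
            hla.append(HLATable(m.sample_id, frozenset(alleles)))
        table = hla_enrichment(hla, meta)
        assert table.iloc[0]["allele"] == "A*02:01"
        # oracle: direct Fisher on the carrier table
        expected = sps.fisher_exact([[8, 2], [1, 9]]).pvalue
        assert table.iloc[0]["p"] == pytest.approx(expected)

    def test_one_row_per_observed_allele(self):
        meta = self._meta(3)
        hla = [HLATable(m.sample_id, frozenset({"A*01:01", "B*08:01"})) for m in meta]
        assert len(hla_enrichment(hla, meta)) == 2
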