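"""Repertoire diversity indices and the cohort statistical tests.

Diversity is summarised by the minimal standard set — Shannon entropy
(nats), Simpson index, clonality and D50.  Group tests are two-sided
throughout: Wilcoxon rank-sum (exact enumeration for small samples, else
a tie-corrected normal approximation), Kruskal–Wallis, Welch's t, and
Fisher's exact test for 2x2 carrier tables.
"""

from __future__ import annotations

import dataclasses
import itertools
import math

import numpy as np
import pandas as pd
from scipy import stats as sps

from .models import HLATable, Repertoire, SampleMeta

#: combined sample size at or below which the Wilcoxon null is enumerated
WILCOXON_EXACT_MAX_N = 20


@dataclasses.dataclass
class DiversityReport:
    sample_id: str
    n_unique: int
    shannon: float
    simpson: float
    clonality: float
    d50: int


def diversity(rep: Repertoire) -> DiversityReport:
    """Shannon (nats), Simpson, clonality and D50 for one repertoire.

    Clonality is ``1 - shannon / ln(n_unique)``; a single-clonotype
    repertoire is fully clonal by convention (clonality 1).  D50 is the
    smallest number of top clonotypes reaching half the repertoire, with
    fraction ties broken by cdr3_nt lexicographic order.
    """
    f = rep.df["fraction"].to_numpy()
    shannon = float(-(f * np.log(f)).sum())
    simpson = float((f**2).sum())
    n = len(f)
    clonality = 1.0 if n == 1 else float(1.0 - shannon / math.log(n))
    order = rep.df.sort_values(["fraction", "cdr3_nt"], ascending=[False, True])
    d50 = int(np.searchsorted(order["fraction"].cumsum().to_numpy(), 0.5) + 1)
    return DiversityReport(rep.sample_id, n, shannon, simpson, clonality, d50)


def diversity_table(reps: list[Repertoire]) -> pd.DataFrame:
    rows = [dataclasses.asdict(diversity(r)) for r in reps]
    return pd.DataFrame(rows)


@dataclasses.dataclass
class TestResult:
    test_name: str
    statistic: float
    p_value: float
    group_sizes: tuple[int, ...]
    note: str = ""

    @property
    def is_na(self) -> bool:
        return not np.isfinite(self.p_value)


def t_two_sample(x, y) -> TestResult:
    """Two-sided Welch two-sample t-test; zero-variance input is
    NA-flagged rather than raised."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("t-test needs >= 2 observations per group")
    if x.var(ddof=1) == 0 and y.var(ddof=1) == 0:
        return TestResult("t_two_sample", np.nan, np.nan, (len(x), len(y)),
                          note="zero variance in both groups")
    stat, p = sps.ttest_ind(x, y, equal_var=False)
    return TestResult("t_two_sample", float(stat), float(p), (len(x), len(y)))


def kruskal_wallis(groups: list) -> TestResult:
    """Two-sided Kruskal–Wallis H test across >= 2 groups."""
    arms = [np.asarray(g, dtype=float) for g in groups]
    if len(arms) < 2 or any(len(a) < 1 for a in arms):
        raise ValueError("kruskal-wallis needs >= 2 non-empty groups")
    sizes = tuple(len(a) for a in arms)
    pooled = np.concatenate(arms)
    if np.ptp(pooled) == 0:
        return TestResult("kruskal_wallis", np.nan, np.nan, sizes,
                          note="all values identical")
    stat, p = sps.kruskal(*arms)
    return TestResult("kruskal_wallis", float(stat), float(p), sizes)


def _wilcoxon_exact(ranks: np.ndarray, nx: int, w_obs: float) -> float:
    """Two-sided p by full enumeration of rank assignments (midranks kept,
    so the enumeration is the permutation null even under ties)."""
    n_le = 0
    n_ge = 0
    total = 0
    for comb in itertools.combinations(range(len(ranks)), nx):
        w = ranks[list(comb)].sum()
        total += 1
        if w <= w_obs + 1e-9:
            n_le += 1
        if w >= w_obs - 1e-9:
            n_ge += 1
    return min(1.0, 2.0 * min(n_le, n_ge) / total)


def wilcoxon_rank_sum(x, y) -> TestResult:
    """Two-sided Wilcoxon rank-sum (Mann–Whitney) test.

    For combined n <= 20 the permutation null is enumerated exactly;
    otherwise a tie-corrected normal approximation (no continuity
    correction) is used.  The statistic is the Mann–Whitney U of ``x``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    nx, ny = len(x), len(y)
    if nx < 1 or ny < 1:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([x, y])
    ranks = sps.rankdata(pooled)
    w = float(ranks[:nx].sum())
    u = w - nx * (nx + 1) / 2.0
    n = nx + ny
    if n <= WILCOXON_EXACT_MAX_N:
        p = _wilcoxon_exact(ranks, nx, w)
        return TestResult("wilcoxon", u, p, (nx, ny))
    mu = nx * ny / 2.0
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(((tie_counts**3 - tie_counts)).sum()) / (n * (n - 1))
    var = nx * ny / 12.0 * ((n + 1) - tie_term)
    if var == 0:
        return TestResult("wilcoxon", u, np.nan, (nx, ny), note="all values identical")
    z = (u - mu) / math.sqrt(var)
    p = float(2.0 * sps.norm.sf(abs(z)))
    return TestResult("wilcoxon", u, min(1.0, p), (nx, ny))


def fisher_exact_2x2(table) -> TestResult:
    """Two-sided Fisher exact test (summation of tables with probability
    at most the observed table's)."""
    t = np.asarray(table, dtype=np.int64)
    if t.shape != (2, 2) or (t < 0).any():
        raise ValueError("need a non-negative 2x2 table")
    stat, p = sps.fisher_exact(t, alternative="two-sided")
    return TestResult("fisher_exact", float(stat), float(p),
                      (int(t[0].sum()), int(t[1].sum())))


def hla_enrichment(hla: list[HLATable], meta: list[SampleMeta]) -> pd.DataFrame:
    """Per-allele carrier enrichment between tumor and control.

    For every observed allele: the 2x2 carrier table, two-sided Fisher p,
    and Benjamini–Hochberg q.  Alleles carried by nobody are skipped.
    """
    groups = {m.sample_id: m.group for m in meta}
    typed = [h for h in hla if h.sample_id in groups]
    n_tumor = sum(1 for h in typed if groups[h.sample_id] == "tumor")
    n_control = len(typed) - n_tumor
    if n_tumor < 2 or n_control < 2:
        raise ValueError("need >= 2 HLA-typed samples per group")
    alleles = sorted({a for h in typed for a in h.alleles})
    rows = []
    for allele in alleles:
        tc = sum(1 for h in typed if groups[h.sample_id] == "tumor" and allele in h.alleles)
        cc = sum(1 for h in typed if groups[h.sample_id] == "control" and allele in h.alleles)
        if tc + cc == 0:
            continue
        res = fisher_exact_2x2([[tc, n_tumor - tc], [cc, n_control - cc]])
        rows.append(
            {
                "allele": allele,
                "tumor_carriers": tc,
                "tumor_noncarriers": n_tumor - tc,
                "control_carriers": cc,
                "control_noncarriers": n_control - cc,
                "odds_ratio": res.statistic,
                "p": res.p_value,
            }
        )
    out = pd.DataFrame(rows)
    if not out.empty:
        out["q"] = sps.false_discovery_control(out["p"])
        out = out.sort_values("p").reset_index(drop=True)
    return out
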