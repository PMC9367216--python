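"""TRBV/TRBJ and V-J pair usage profiles and group comparisons.

Usage can be weighted by read fraction (``by_count``, the default — the
usual meaning of "usage frequency") or by unique clonotype
(``by_clonotype``).  Group comparisons use a two-sided Welch t-test for
two groups and Kruskal–Wallis for more; raw p-values and
Benjamini–Hochberg q-values are both reported.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats as sps

from .models import Repertoire, SampleMeta

logger = logging.getLogger(__name__)

AXES = ("V", "J", "VJ")
WEIGHTINGS = ("by_count", "by_clonotype")


def _gene_key(rep: Repertoire, axis: str) -> pd.Series:
    if axis == "V":
        return rep.df["v_gene"]
    if axis == "J":
        return rep.df["j_gene"]
    if axis == "VJ":
        return rep.df["v_gene"] + "|" + rep.df["j_gene"]
    raise ValueError(f"unknown axis {axis!r}; expected one of {AXES}")


def usage_profile(
    rep: Repertoire,
    axis: str = "V",
    weighting: str = "by_count",
    reference: list[str] | None = None,
) -> pd.Series:
    """Per-sample gene (or gene-pair) usage weights summing to 1.

    Genes from ``reference`` that are absent in the sample get weight 0.
    """
    if weighting not in WEIGHTINGS:
        raise ValueError(f"unknown weighting {weighting!r}")
    key = _gene_key(rep, axis)
    if weighting == "by_count":
        w = rep.df["fraction"].groupby(key.to_numpy()).sum()
    else:
        w = pd.Series(1.0, index=key).groupby(level=0).sum() / len(rep.df)
    w = w.sort_index()
    if reference is not None:
        w = w.reindex(sorted(set(reference) | set(w.index)), fill_value=0.0)
    w.name = rep.sample_id
    return w


def usage_matrix(
    reps: list[Repertoire],
    axis: str = "V",
    weighting: str = "by_count",
    reference: list[str] | None = None,
) -> pd.DataFrame:
    """Samples x genes usage matrix (absent genes filled with 0)."""
    profiles = [usage_profile(r, axis, weighting, reference) for r in reps]
    return pd.DataFrame(profiles).fillna(0.0).sort_index(axis=1)


def pooled_usage(
    reps: list[Repertoire], axis: str = "V", weighting: str = "by_count"
) -> pd.Series:
    """Cohort-pooled usage: samples contribute in proportion to their
    total read counts (for ``by_count``) or unique clonotype counts."""
    sizes = np.array(
        [r.total_count if weighting == "by_count" else r.n_unique for r in reps],
        dtype=float,
    )
    mat = usage_matrix(reps, axis, weighting)
    pooled = mat.mul(sizes / sizes.sum(), axis=0).sum(axis=0)
    return pooled / pooled.sum()


def compare_usage(
    mat: pd.DataFrame,
    meta: list[SampleMeta],
    design: str = "tumor_vs_control",
) -> pd.DataFrame:
    """Per-gene group comparison of usage weights.

    ``design='tumor_vs_control'`` runs a two-sided Welch t-test per gene;
    ``design='stage_groups'`` compares control + stages I–IV with
    Kruskal–Wallis.  Zero-variance (degenerate) genes are NA-flagged.
    Returns a table sorted by raw p with BH q-values.
    """
    groups = {m.sample_id: m.group for m in meta}
    stages = {m.sample_id: m.stage for m in meta}
    missing = [s for s in mat.index if s not in groups]
    if missing:
        raise ValueError(f"samples without metadata: {missing}")

    if design == "tumor_vs_control":
        labels = pd.Series([groups[s] for s in mat.index], index=mat.index)
        level_order = ["tumor", "control"]
    elif design == "stage_groups":
        labels = pd.Series(
            [stages[s] if groups[s] == "tumor" else "control" for s in mat.index],
            index=mat.index,
        )
        level_order = ["control", "I", "II", "III", "IV"]
    else:
        raise ValueError(f"unknown design {design!r}")
    levels = [g for g in level_order if (labels == g).sum() > 0]
    if len(levels) < 2 or min((labels == g).sum() for g in levels) < 2:
        raise ValueError("need >= 2 samples in >= 2 groups")

    rows = []
    for gene in mat.columns:
        vals = mat[gene]
        if (vals == 0).all():
            logger.info("gene %s absent in all samples; skipped", gene)
            continue
        arms = [vals[labels == g].to_numpy() for g in levels]
        means = {f"mean_{g}": float(a.mean()) for g, a in zip(levels, arms)}
        pooled = np.concatenate(arms)
        if np.ptp(pooled) == 0:
            stat, p = np.nan, np.nan
        elif len(levels) == 2:
            stat, p = sps.ttest_ind(arms[0], arms[1], equal_var=False)
        else:
            stat, p = sps.kruskal(*arms)
        rows.append({"gene": gene, **means, "stat": float(stat), "p": float(p)})
    table = pd.DataFrame(rows)
    if table.empty:
        return table
    table["q"] = np.nan
    ok = table["p"].notna()
    if ok.any():
        table.loc[ok, "q"] = sps.false_discovery_control(table.loc[ok, "p"])
    return table.sort_values("p", na_position="last").reset_index(drop=True)
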