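"""Clonal-expansion tiers.

Clonotypes are binned by their within-sample read fraction into four
tiers: hyper-expanded (> 1%), large (> 0.1%), medium (> 0.01%) and small
(<= 0.01%).  Upper tiers take the strict inequality, so a clone at exactly
1% is *large*, and exactly 0.01% is *small*.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from .models import Repertoire

TIERS = ("hyper", "large", "medium", "small")

#: strictly decreasing tier floors (exclusive): hyper > 0.01, large > 0.001,
#: medium > 0.0001, small otherwise
DEFAULT_THRESHOLDS = (0.01, 0.001, 0.0001)


def classify_tier(fraction: float, thresholds=DEFAULT_THRESHOLDS) -> str:
    """Tier label for one clonotype fraction."""
    if not 0.0 < fraction <= 1.0:
        raise ValueError(f"fraction {fraction} outside (0, 1]")
    hyper, large, medium = thresholds
    if fraction > hyper:
        return "hyper"
    if fraction > large:
        return "large"
    if fraction > medium:
        return "medium"
    return "small"


def classify_tier_array(fractions, thresholds=DEFAULT_THRESHOLDS) -> np.ndarray:
    """Vectorised tier labels for an array of fractions in (0, 1]."""
    f = np.asarray(fractions, dtype=float)
    if ((f <= 0) | (f > 1)).any():
        raise ValueError("fractions outside (0, 1]")
    hyper, large, medium = thresholds
    return np.select(
        [f > hyper, f > large, f > medium], ["hyper", "large", "medium"], "small"
    )


@dataclasses.dataclass
class TierAbundance:
    """Per-sample summed fraction and clonotype count in each tier."""

    sample_id: str
    fractions: dict[str, float]
    counts: dict[str, int]


def tier_abundance(rep: Repertoire, thresholds=DEFAULT_THRESHOLDS) -> TierAbundance:
    """Summed fraction and clonotype count per tier; tiers partition the
    repertoire, so fractions sum to 1 and counts to ``n_unique``."""
    labels = classify_tier_array(rep.df["fraction"].to_numpy(), thresholds)
    s = pd.Series(rep.df["fraction"].to_numpy()).groupby(labels).agg(["sum", "size"])
    fractions = {t: float(s["sum"].get(t, 0.0)) for t in TIERS}
    counts = {t: int(s["size"].get(t, 0)) for t in TIERS}
    return TierAbundance(rep.sample_id, fractions, counts)


def tier_abundance_table(reps: list[Repertoire], thresholds=DEFAULT_THRESHOLDS) -> pd.DataFrame:
    """Long-format cohort table: sample_id, tier, abundance, n_clonotypes."""
    rows = []
    for rep in reps:
        ta = tier_abundance(rep, thresholds)
        for t in TIERS:
            rows.append((rep.sample_id, t, ta.fractions[t], ta.counts[t]))
    return pd.DataFrame(rows, columns=["sample_id", "tier", "abundance", "n_clonotypes"])
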