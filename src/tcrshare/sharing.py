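"""Cohort-level CDR3 sharing taxonomy and tumor-specific clone discovery.

Sharing is computed on amino-acid CDR3 sequences alone: within each
sample, nucleotide variants encoding one CDR3 aa are pooled by summing
their fractions, and occupancy counts samples (presence/absence).  Every
cohort CDR3 falls into exactly one of four classes:

* ``T_and_C``       — present in >= 1 tumor and >= 1 control sample;
* ``T_or_C_tumor``  — present in >= 2 tumor samples and no control;
* ``T_or_C_control``— present in >= 2 control samples and no tumor;
* ``individual``    — present in exactly one sample.

Hyper-expanded tumor-specific CDR3s are the ``T_or_C_tumor`` records
whose within-sample pooled fraction exceeds 1% in at least one tumor
sample; an exclusion database (e.g. a SARS-CoV-2-associated CDR3
catalogue) is then subtracted from the candidates.
"""

from __future__ import annotations

import dataclasses
from typing import Iterable, NamedTuple

import numpy as np
import pandas as pd

from .expansion import DEFAULT_THRESHOLDS, TIERS, classify_tier_array
from .models import Repertoire, SampleMeta

SHARING_CLASSES = ("T_and_C", "T_or_C_tumor", "T_or_C_control", "individual")

OCCUPANCY_COLUMNS = [
    "n_tumor_samples",
    "n_control_samples",
    "sharing_class",
    "max_fraction_tumor",
    "max_fraction_control",
]


class SharingRecord(NamedTuple):
    cdr3_aa: str
    n_tumor_samples: int
    n_control_samples: int
    sharing_class: str
    max_fraction_tumor: float
    max_fraction_control: float


def classify_sharing(n_tumor: int, n_control: int) -> str:
    """Sharing class from group occupancy counts (total occupancy >= 1)."""
    if n_tumor + n_control < 1:
        raise ValueError("occupancy must be at least 1")
    if n_tumor >= 1 and n_control >= 1:
        return "T_and_C"
    if n_tumor >= 2:
        return "T_or_C_tumor"
    if n_control >= 2:
        return "T_or_C_control"
    return "individual"


def _aa_table(cohort: Iterable[Repertoire], meta: list[SampleMeta]) -> pd.DataFrame:
    groups = {m.sample_id: m.group for m in meta}
    if len(groups) != len(meta):
        raise ValueError("duplicate sample_id in metadata")
    parts = []
    for rep in cohort:
        if rep.sample_id not in groups:
            raise ValueError(f"repertoire {rep.sample_id!r} has no metadata")
        frac = rep.aa_fractions()
        parts.append(
            pd.DataFrame(
                {
                    "cdr3_aa": frac.index,
                    "fraction": frac.to_numpy(),
                    "sample_id": rep.sample_id,
                    "group": groups[rep.sample_id],
                }
            )
        )
    return pd.concat(parts, ignore_index=True)


def build_occupancy(cohort: list[Repertoire], meta: list[SampleMeta]) -> pd.DataFrame:
    """One row per distinct cohort CDR3 aa, indexed by sequence.

    Columns: group occupancy counts, sharing class, and the maximum
    within-sample pooled fraction over each group.
    """
    tab = _aa_table(cohort, meta)
    is_tumor = tab["group"].to_numpy() == "tumor"
    frac = tab["fraction"].to_numpy()
    agg = pd.DataFrame(
        {
            "cdr3_aa": tab["cdr3_aa"],
            "n_tumor_samples": is_tumor.astype(np.int64),
            "n_control_samples": (~is_tumor).astype(np.int64),
            "max_fraction_tumor": np.where(is_tumor, frac, 0.0),
            "max_fraction_control": np.where(is_tumor, 0.0, frac),
        }
    ).groupby("cdr3_aa").agg(
        n_tumor_samples=("n_tumor_samples", "sum"),
        n_control_samples=("n_control_samples", "sum"),
        max_fraction_tumor=("max_fraction_tumor", "max"),
        max_fraction_control=("max_fraction_control", "max"),
    )
    nt = agg["n_tumor_samples"].to_numpy()
    nc = agg["n_control_samples"].to_numpy()
    agg["sharing_class"] = np.select(
        [(nt >= 1) & (nc >= 1), nt >= 2, nc >= 2],
        ["T_and_C", "T_or_C_tumor", "T_or_C_control"],
        "individual",
    )
    return agg[OCCUPANCY_COLUMNS]


def occupancy_records(occupancy: pd.DataFrame) -> Iterable[SharingRecord]:
    for cdr3_aa, row in occupancy.iterrows():
        yield SharingRecord(
            cdr3_aa,
            int(row["n_tumor_samples"]),
            int(row["n_control_samples"]),
            str(row["sharing_class"]),
            float(row["max_fraction_tumor"]),
            float(row["max_fraction_control"]),
        )


def class_abundance(
    rep: Repertoire, occupancy: pd.DataFrame, thresholds=DEFAULT_THRESHOLDS
) -> pd.DataFrame:
    """Sharing-class x expansion-tier summed fractions for one sample.

    Tiers are evaluated on this sample's pooled aa-level fractions; the
    class x tier cells partition the sample's total mass.
    """
    frac = rep.aa_fractions()
    missing = frac.index.difference(occupancy.index)
    if len(missing):
        raise ValueError(
            f"{rep.sample_id}: {len(missing)} CDR3 missing from the occupancy index "
            "(build it from the same cohort)"
        )
    classes = occupancy.loc[frac.index, "sharing_class"].to_numpy()
    tiers = classify_tier_array(frac.to_numpy(), thresholds)
    table = (
        pd.DataFrame({"cls": classes, "tier": tiers, "fraction": frac.to_numpy()})
        .groupby(["cls", "tier"])["fraction"]
        .sum()
        .unstack(fill_value=0.0)
    )
    return table.reindex(index=SHARING_CLASSES, columns=TIERS, fill_value=0.0)


def class_share_of_unique(occupancy: pd.DataFrame) -> pd.Series:
    """Cohort-wide share of unique CDR3 aa in each sharing class."""
    return (
        occupancy["sharing_class"].value_counts(normalize=True)
        .reindex(SHARING_CLASSES, fill_value=0.0)
    )


@dataclasses.dataclass
class TumorSpecificSet:
    """Hyper-expanded tumor-specific CDR3s before and after exclusion."""

    candidates: frozenset[str]
    retained: frozenset[str]
    excluded: frozenset[str]


def find_tumor_specific_hyper(
    occupancy: pd.DataFrame,
    exclusion: set[str] | frozenset[str] = frozenset(),
    hyper_threshold: float = 0.01,
) -> TumorSpecificSet:
    """Tumor-group-restricted CDR3s that are hyper-expanded somewhere.

    Candidates are ``T_or_C_tumor`` records (>= 2 tumor samples, absent
    from controls) with pooled fraction > ``hyper_threshold`` in at least
    one tumor sample.  Exclusion matching is exact, case-insensitive.
    """
    mask = (occupancy["sharing_class"] == "T_or_C_tumor") & (
        occupancy["max_fraction_tumor"] > hyper_threshold
    )
    candidates = frozenset(occupancy.index[mask])
    exclusion_uc = {s.upper() for s in exclusion}
    excluded = frozenset(s for s in candidates if s.upper() in exclusion_uc)
    return TumorSpecificSet(candidates, candidates - excluded, excluded)


def set_abundance(rep: Repertoire, cdr3_set: Iterable[str]) -> float:
    """Summed pooled aa-level fraction of a CDR3 set within one sample."""
    target = set(cdr3_set)
    frac = rep.aa_fractions()
    return float(frac[frac.index.isin(target)].sum())


def track_clonotypes(
    cohort: list[Repertoire], cdr3_list: list[str], drop_empty: bool = False
) -> pd.DataFrame:
    """Per-sample pooled fraction matrix (samples x CDR3; 0 when absent).

    With ``drop_empty``, samples carrying none of the tracked CDR3s are
    removed from the matrix.
    """
    if not cdr3_list:
        raise ValueError("cdr3_list must be non-empty")
    rows = {}
    for rep in cohort:
        frac = rep.aa_fractions()
        rows[rep.sample_id] = [float(frac.get(c, 0.0)) for c in cdr3_list]
    mat = pd.DataFrame.from_dict(rows, orient="index", columns=list(cdr3_list))
    if drop_empty:
        mat = mat.loc[(mat > 0).any(axis=1)]
    return mat
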