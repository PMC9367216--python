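"""Antigen-specificity annotation and EBV-specific abundance.

CDR3s are matched against curated specificity databases by exact,
case-insensitive amino-acid identity.  A cluster is EBV-specific when it
contains at least one annotated EBV-specific member; the per-sample
EBV-specific abundance is the summed repertoire fraction of *all* CDR3s
belonging to EBV-specific clusters — including members the databases do
not list, since clustering is the workaround for database incompleteness.
"""

from __future__ import annotations

import dataclasses
from typing import Iterable, Mapping, NamedTuple

import numpy as np
import pandas as pd
from scipy import stats as sps

from .clustering import CDR3Cluster
from .models import AntigenRecord, Repertoire, SampleMeta
from .sharing import set_abundance
from .stats import t_two_sample, kruskal_wallis, TestResult

#: accepted species synonyms for Epstein–Barr virus (lower-cased)
EBV_SYNONYMS = frozenset(
    {"ebv", "epstein-barr virus", "epstein barr virus", "hhv-4", "hhv4",
     "human herpesvirus 4"}
)


class AnnotationResult(NamedTuple):
    cdr3_aa: str
    matched_records: tuple[AntigenRecord, ...]
    is_ebv: bool


def annotate(
    cdr3_set: Iterable[str],
    db: list[AntigenRecord],
    species_synonyms: frozenset[str] = EBV_SYNONYMS,
) -> dict[str, AnnotationResult]:
    """Exact case-insensitive lookup of each CDR3 in the database.

    Multiple hits (one CDR3 binding several epitopes) are all retained.
    """
    if not db:
        raise ValueError("empty antigen database")
    index: dict[str, list[AntigenRecord]] = {}
    for rec in db:
        index.setdefault(rec.cdr3_aa.upper(), []).append(rec)
    out = {}
    for cdr3 in cdr3_set:
        hits = tuple(index.get(cdr3.upper(), ()))
        is_ebv = any(h.antigen_species.lower() in species_synonyms for h in hits)
        out[cdr3] = AnnotationResult(cdr3, hits, is_ebv)
    return out


def label_ebv_clusters(
    clusters: list[CDR3Cluster],
    annotations: Mapping[str, AnnotationResult],
) -> list[CDR3Cluster]:
    """Attach antigen labels to clusters; every member must be annotated.

    A cluster is EBV-specific iff at least one member is EBV-annotated;
    its label set is the union of member species labels.
    """
    labeled = []
    for c in clusters:
        missing = [m for m in c.members if m not in annotations]
        if missing:
            raise ValueError(f"cluster {c.cluster_id}: unannotated members {missing[:3]}")
        labels = frozenset(
            rec.antigen_species
            for m in c.members
            for rec in annotations[m].matched_records
        )
        labeled.append(CDR3Cluster(c.cluster_id, c.members, labels))
    return labeled


def ebv_cluster_members(
    clusters: list[CDR3Cluster],
    annotations: Mapping[str, AnnotationResult],
) -> frozenset[str]:
    """Union of member CDR3s over all EBV-specific clusters."""
    members: set[str] = set()
    for c in clusters:
        if any(annotations[m].is_ebv for m in c.members if m in annotations):
            members.update(c.members)
    return frozenset(members)


@dataclasses.dataclass
class EBVAbundance:
    sample_id: str
    abundance: float
    n_ebv_cluster_cdr3_present: int


def ebv_abundance(rep: Repertoire, ebv_members: frozenset[str]) -> EBVAbundance:
    """Per-sample summed fraction over the EBV-specific cluster CDR3s."""
    frac = rep.aa_fractions()
    present = frac.index.isin(ebv_members)
    return EBVAbundance(
        sample_id=rep.sample_id,
        abundance=float(frac[present].sum()),
        n_ebv_cluster_cdr3_present=int(present.sum()),
    )


def abundance_series(reps: list[Repertoire], cdr3_set: Iterable[str]) -> pd.Series:
    """Per-sample abundance of an arbitrary CDR3 set (e.g. the retained
    tumor-specific set or the EBV cluster universe)."""
    target = frozenset(cdr3_set)
    return pd.Series(
        {rep.sample_id: set_abundance(rep, target) for rep in reps}, name="abundance"
    )


DESIGNS = ("stage_vs_control", "age_binary_60", "sex", "tumor_vs_control")


def compare_abundance(
    values: pd.Series,
    meta: list[SampleMeta],
    design: str,
    tumor_only: bool = False,
) -> pd.DataFrame:
    """Group comparison of a per-sample abundance.

    Designs: ``tumor_vs_control`` and ``sex`` (Welch t); ``age_binary_60``
    (age >= 60 vs younger, Welch t); ``stage_vs_control`` (Kruskal–Wallis
    over control + stages I–IV plus pairwise stage-vs-control t-tests).
    ``tumor_only`` restricts to tumor samples (e.g. tumor-specific
    abundance comparisons within the patient group).
    """
    info = {m.sample_id: m for m in meta}
    sids = [s for s in values.index if s in info]
    if len(sids) != len(values):
        raise ValueError("abundance values include samples without metadata")
    if tumor_only:
        sids = [s for s in sids if info[s].group == "tumor"]
    vals = values.loc[sids]

    def arm(label_fn, name):
        sel = vals[[label_fn(info[s]) for s in vals.index]]
        return name, sel.to_numpy()

    rows = []
    if design in ("sex", "age_binary_60", "tumor_vs_control"):
        if design == "sex":
            a = arm(lambda m: m.sex == "male", "male")
            b = arm(lambda m: m.sex == "female", "female")
        elif design == "age_binary_60":
            a = arm(lambda m: m.age >= 60, "age>=60")
            b = arm(lambda m: m.age < 60, "age<60")
        else:
            a = arm(lambda m: m.group == "tumor", "tumor")
            b = arm(lambda m: m.group == "control", "control")
        res = t_two_sample(a[1], b[1])
        rows.append(_row(design, f"{a[0]}_vs_{b[0]}", res, {a[0]: a[1], b[0]: b[1]}))
    elif design == "stage_vs_control":
        strata = {"control": vals[[info[s].group == "control" for s in vals.index]].to_numpy()}
        for st in ("I", "II", "III", "IV"):
            strata[st] = vals[[info[s].stage == st for s in vals.index]].to_numpy()
        present = {k: v for k, v in strata.items() if len(v) >= 2}
        skipped = set(strata) - set(present)
        if skipped:
            import logging

            logging.getLogger(__name__).info("strata skipped (n < 2): %s", sorted(skipped))
        if len(present) > 2:
            res = kruskal_wallis(list(present.values()))
            rows.append(_row(design, "omnibus", res, present))
        for st in ("I", "II", "III", "IV"):
            if st in present and "control" in present:
                res = t_two_sample(present[st], present["control"])
                rows.append(
                    _row(design, f"{st}_vs_control", res,
                         {st: present[st], "control": present["control"]})
                )
    else:
        raise ValueError(f"unknown design {design!r}; expected one of {DESIGNS}")
    return pd.DataFrame(rows)


def _row(design: str, comparison: str, res: TestResult, arms: dict) -> dict:
    out = {
        "design": design,
        "comparison": comparison,
        "test": res.test_name,
        "statistic": res.statistic,
        "p": res.p_value,
    }
    for name, arr in arms.items():
        arr = np.asarray(arr, dtype=float)
        out[f"n_{name}"] = len(arr)
        out[f"mean_{name}"] = float(arr.mean()) if len(arr) else np.nan
    return out
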