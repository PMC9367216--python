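import numpy as np
import pandas as pd
import pytest

from tcrshare.models import AntigenRecord, Repertoire, SampleMeta
from tcrshare.simulate import SimConfig, simulate_cohort


def make_repertoire(sample_id, counts, cdr3_aa=None, v=None, j=None):
    """Small hand-built repertoire; nt sequences are synthesized codon-wise."""
    from tcrshare.models import CODONS

    n = len(counts)
    if cdr3_aa is None:
        letters = "ACDEFGHIKLMNPQRSTVWY"
        cdr3_aa = [f"CASS{letters[i % 20]}{'G' * (i // 20)}QYF" for i in range(n)]
    nts = ["".join(CODONS[a][0] for a in aa) for aa in cdr3_aa]
    df = pd.DataFrame(
        {
            "cdr3_nt": nts,
            "cdr3_aa": cdr3_aa,
            "v_gene": v or ["TRBV20-1"] * n,
            "j_gene": j or ["TRBJ2-1"] * n,
            "count": counts,
        }
    )
    return Repertoire.from_counts(sample_id, df)


@pytest.fixture
def uniform4():
    return make_repertoire("uniform4", [25, 25, 25, 25])


@pytest.fixture(scope="session")
def small_cohort():
    """One clean 10+10 simulated cohort shared across read-only tests."""
    cfg = SimConfig(
        n_control=10, n_tumor=10, clones_per_sample=1000, public_pool_size=300,
        n_planted_tumor_specific=10, n_ebv_families=2, ebv_family_size=8, seed=11,
    )
    return simulate_cohort(cfg)


@pytest.fixture(scope="session")
def mini_antigen_db():
    """A 30-record miniature specificity database: a mix of EBV, CMV and
    influenza entries, with one CDR3 annotated against two species."""
    rng = np.random.default_rng(2024)
    from tcrshare.simulate import _batch_cdr3

    lengths = rng.integers(12, 17, size=28)
    aas, _ = _batch_cdr3(lengths, rng)
    species = ["EBV"] * 10 + ["CMV"] * 9 + ["InfluenzaA"] * 9
    records = [
        AntigenRecord(a, f"EPI{i:02d}", s, "fixture")
        for i, (a, s) in enumerate(zip(aas, species))
    ]
    # one CDR3 binding two species (multi-hit retention)
    records.append(AntigenRecord(aas[0], "EPI99", "CMV", "fixture"))
    records.append(AntigenRecord(aas[1], "EPI98", "EBV", "fixture"))
    return records


def cohort_meta(n_tumor=3, n_control=3, stages=None):
    meta = [SampleMeta(f"HC{i:03d}", "control", "NA", 50 + i, "female")
            for i in range(n_control)]
    stages = stages or ["II"] * n_tumor
    meta += [SampleMeta(f"GC{i:03d}", "tumor", stages[i], 55 + i, "male")
             for i in range(n_tumor)]
    return meta
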