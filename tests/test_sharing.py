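import numpy as np
import pandas as pd
import pytest

from tcrshare.models import SampleMeta
from tcrshare.sharing import (
    SHARING_CLASSES,
    build_occupancy,
    class_abundance,
    classify_sharing,
    find_tumor_specific_hyper,
    set_abundance,
    track_clonotypes,
)
from conftest import cohort_meta, make_repertoire


@pytest.mark.parametrize(
    "nt,nc,cls",
    [
        (1, 1, "T_and_C"),
        (5, 3, "T_and_C"),
        (2, 0, "T_or_C_tumor"),
        (0, 2, "T_or_C_control"),
        (1, 0, "individual"),
        (0, 1, "individual"),
    ],
)
def test_classify_sharing(nt, nc, cls):
    assert classify_sharing(nt, nc) == cls


def test_classify_sharing_requires_occupancy():
    with pytest.raises(ValueError):
        classify_sharing(0, 0)


class TestBuildOccupancy:
    def test_presence_counts_samples_not_reads(self):
        meta = cohort_meta(1, 1)
        r1 = make_repertoire("HC000", [99, 1], cdr3_aa=["CASSLF", "CAAAAF"])
        r2 = make_repertoire("GC000", [1, 1], cdr3_aa=["CASSLF", "CTTTTF"])
        occ = build_occupancy([r1, r2], meta)
        assert occ.loc["CASSLF", "n_tumor_samples"] == 1
        assert occ.loc["CASSLF", "n_control_samples"] == 1
        assert occ.loc["CASSLF", "sharing_class"] == "T_and_C"
        assert occ.loc["CAAAAF", "sharing_class"] == "individual"

    def test_nucleotide_variants_pooled_at_aa_level(self):
        # the same aa CDR3 from two nt variants contributes the summed fraction
        meta = cohort_meta(1, 0)
        df = pd.DataFrame(
            {
                "cdr3_nt": ["TGTGCTTTC", "TGCGCTTTC", "TGTGGGTTC"],
                "cdr3_aa": ["CAF", "CAF", "CGF"],
                "v_gene": ["TRBV2"] * 3,
                "j_gene": ["TRBJ1-1"] * 3,
                "count": [6, 5, 989],
            }
        )
        from tcrshare.models import Repertoire

        rep = Repertoire.from_counts("GC000", df)
        occ = build_occupancy([rep], meta)
        assert occ.loc["CAF", "max_fraction_tumor"] == pytest.approx(0.011)

    def test_disjoint_cohort_all_individual(self, small_cohort):
        reps, meta, _ = small_cohort
        occ = build_occupancy(reps, meta)
        assert set(occ["sharing_class"]).issubset(set(SHARING_CLASSES))
        # presence in exactly one sample <=> individual
        solo = occ[(occ.n_tumor_samples + occ.n_control_samples) == 1]
        assert (solo["sharing_class"] == "individual").all()

    def test_repertoire_without_metadata_rejected(self):
        rep = make_repertoire("mystery", [1])
        with pytest.raises(ValueError, match="metadata"):
            build_occupancy([rep], cohort_meta(1, 1))


class TestClassAbundance:
    def test_individual_only_sample(self):
        meta = cohort_meta(1, 1)
        r1 = make_repertoire("HC000", [3, 7], cdr3_aa=["CAAAAF", "CTTTTF"])
        r2 = make_repertoire("GC000", [5, 5], cdr3_aa=["CGGGGF", "CSSSSF"])
        occ = build_occupancy([r1, r2], meta)
        ca = class_abundance(r1, occ)
        assert ca.loc["individual"].sum() == pytest.approx(1.0)

    def test_partition_sums_to_one_for_cohort(self, small_cohort):
        reps, meta, _ = small_cohort
        occ = build_occupancy(reps, meta)
        for rep in reps:
            ca = class_abundance(rep, occ)
            assert ca.to_numpy().sum() == pytest.approx(1.0, abs=1e-9)
            assert (ca.to_numpy() >= 0).all()

    def test_public_clone_containment(self):
        meta = cohort_meta(1, 1)
        shared = "CASSPLGIF"
        r1 = make_repertoire("HC000", [30, 70], cdr3_aa=[shared, "CTTTTF"])
        r2 = make_repertoire("GC000", [40, 60], cdr3_aa=[shared, "CGGGGF"])
        occ = build_occupancy([r1, r2], meta)
        ca = class_abundance(r1, occ)
        assert ca.loc["T_and_C"].sum() >= 0.3

    def test_foreign_occupancy_index_rejected(self):
        meta = cohort_meta(1, 1)
        r1 = make_repertoire("HC000", [1], cdr3_aa=["CAAAAF"])
        r2 = make_repertoire("GC000", [1], cdr3_aa=["CTTTTF"])
        occ = build_occupancy([r1, r2], meta)
        other = make_repertoire("HC000", [1], cdr3_aa=["CWWWWF"])
        with pytest.raises(ValueError, match="occupancy"):
            class_abundance(other, occ)


class TestTumorSpecific:
    def test_clean_recovery_and_exclusion(self, small_cohort):
        reps, meta, gt = small_cohort
        occ = build_occupancy(reps, meta)
        planted = set(gt.planted_tumor_specific)
        excl = set(sorted(planted)[:3])
        ts = find_tumor_specific_hyper(occ, excl)
        assert set(ts.candidates) == planted
        assert set(ts.excluded) == excl
        assert set(ts.retained) == planted - excl
        assert ts.retained | ts.excluded == ts.candidates

    def test_single_carrier_not_a_candidate(self):
        meta = cohort_meta(2, 1)
        hot = "CASSHEATF"
        r1 = make_repertoire("GC000", [5, 95], cdr3_aa=[hot, "CAAAAF"])
        r2 = make_repertoire("GC001", [1], cdr3_aa=["CTTTTF"])
        rc = make_repertoire("HC000", [1], cdr3_aa=["CGGGGF"])
        occ = build_occupancy([r1, r2, rc], meta)
        assert hot not in find_tumor_specific_hyper(occ).candidates

    def test_exclusion_is_case_insensitive_and_monotone(self, small_cohort):
        reps, meta, gt = small_cohort
        occ = build_occupancy(reps, meta)
        planted = sorted(gt.planted_tumor_specific)
        small = find_tumor_specific_hyper(occ, {planted[0].lower()})
        big = find_tumor_specific_hyper(occ, set(planted[:5]))
        assert planted[0] in small.excluded
        assert big.retained <= small.retained


class TestTracking:
    def test_absent_cdr3_with_drop_empty(self, small_cohort):
        reps, _, _ = small_cohort
        mat = track_clonotypes(reps, ["CWWWWWWWWF"], drop_empty=True)
        assert mat.empty

    def test_planted_clone_tracks_its_carriers(self, small_cohort):
        reps, _, gt = small_cohort
        cdr3, carriers = sorted(gt.planted_tumor_specific.items())[0]
        mat = track_clonotypes(reps, [cdr3], drop_empty=True)
        assert sorted(mat.index) == sorted(carriers)
        assert (mat[cdr3] > 0).all()

    def test_matrix_fractions_match_occupancy_maxima(self, small_cohort):
        reps, meta, gt = small_cohort
        occ = build_occupancy(reps, meta)
        cdr3s = sorted(gt.planted_tumor_specific)[:5]
        mat = track_clonotypes(reps, cdr3s)
        groups = {m.sample_id: m.group for m in meta}
        tumor_rows = [s for s in mat.index if groups[s] == "tumor"]
        for c in cdr3s:
            assert mat.loc[tumor_rows, c].max() == pytest.approx(
                occ.loc[c, "max_fraction_tumor"]
            )

    def test_set_abundance_is_a_sum_of_fractions(self):
        rep = make_repertoire("s", [40, 60], cdr3_aa=["CAAAAF", "CTTTTF"])
        assert set_abundance(rep, {"CAAAAF"}) == pytest.approx(0.4)
        assert set_abundance(rep, {"CWWWWF"}) == 0.0
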