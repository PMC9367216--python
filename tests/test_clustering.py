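import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from tcrshare.clustering import (
    CDR3Cluster,
    ClusterParams,
    build_clusters,
    pair_score,
    position_profile,
)

AA = "ACDEFGHIKLMNPQRSTVWY"


def brute_force_clusters(seqs, params):
    """Independent oracle: all-pairs scoring + naive transitive closure."""
    seqs = sorted(set(seqs))
    adj = {s: set() for s in seqs}
    for a, b in itertools.combinations(seqs, 2):
        s = pair_score(a, b, params)
        if s is not None and s >= params.score_threshold - 1e-9:
            adj[a].add(b)
            adj[b].add(a)
    seen, comps = set(), []
    for s in seqs:
        if s in seen:
            continue
        stack, comp = [s], []
        while stack:
            x = stack.pop()
            if x in seen:
                continue
            seen.add(x)
            comp.append(x)
            stack.extend(adj[x] - seen)
        if len(comp) >= 2:
            comps.append(tuple(sorted(comp)))
    comps.sort(key=lambda c: (-len(c), c[0]))
    return comps


def random_cdr3s(rng, n, lengths=(10, 11, 12)):
    out = set()
    while len(out) < n:
        L = int(rng.choice(lengths))
        out.add("C" + "".join(rng.choice(list(AA), size=L - 2)) + "F")
    return sorted(out)


class TestPairScore:
    def test_identical_sequences_hit_diagonal_floor(self):
        rng = np.random.default_rng(0)
        for seq in random_cdr3s(rng, 20, lengths=(15,)):
            s = pair_score(seq, seq)
            assert s is not None and s >= 4.0  # minimum BLOSUM62 diagonal

    def test_length_mismatch_incomparable(self):
        assert pair_score("CASSLF", "CASSLGF") is None

    def test_hand_lookup_blosum62(self):
        # flanks 2/2 on length 6: mid positions 2,3 are (A,A),(A,A) -> 4.0
        assert pair_score("CAAAAF", "CAAATF") == pytest.approx(4.0)
        # (A,A)=4 and (A,T)=0 -> mean 2.0
        assert pair_score("CAAAAF", "CAATTF") == pytest.approx(2.0)

    def test_symmetry_and_self_maximality(self):
        rng = np.random.default_rng(1)
        seqs = random_cdr3s(rng, 15, lengths=(12,))
        for a, b in itertools.combinations(seqs, 2):
            assert pair_score(a, b) == pytest.approx(pair_score(b, a))
            assert pair_score(a, a) >= pair_score(a, b)

    def test_empty_mid_region_incomparable(self):
        params = ClusterParams(flank_left=3, flank_right=3)
        assert pair_score("CASSLF", "CASSLF", params) is None

    def test_require_same_v(self):
        params = ClusterParams(require_same_v=True)
        assert pair_score("CAAAAF", "CAAAAF", params, "TRBV2", "TRBV30") is None
        assert pair_score("CAAAAF", "CAAAAF", params, "TRBV2", "TRBV2") is not None


class TestBuildClusters:
    def test_mutually_incomparable_yields_nothing(self):
        seqs = ["CAAAAF", "CAAAAAF", "CAAAAAAF"]  # all different lengths
        assert build_clusters(seqs) == []

    def test_oracle_equivalence_random_instances(self):
        rng = np.random.default_rng(7)
        for _ in range(30):
            n = int(rng.integers(5, 80))
            seqs = random_cdr3s(rng, n)
            thr = float(rng.uniform(0.5, 4.5))
            params = ClusterParams(score_threshold=thr)
            got = [c.members for c in build_clusters(seqs, params)]
            assert got == brute_force_clusters(seqs, params)

    def test_threshold_refinement_monotone(self):
        rng = np.random.default_rng(8)
        seqs = random_cdr3s(rng, 60, lengths=(11,))
        low = build_clusters(seqs, ClusterParams(score_threshold=0.5))
        high = build_clusters(seqs, ClusterParams(score_threshold=2.5))
        coarse = {m: c.cluster_id for c in low for m in c.members}
        for c in high:
            parents = {coarse.get(m) for m in c.members}
            assert len(parents) == 1 and None not in parents

    def test_clusters_are_disjoint_and_within_input(self):
        rng = np.random.default_rng(9)
        seqs = random_cdr3s(rng, 100)
        clusters = build_clusters(seqs, ClusterParams(score_threshold=1.0))
        seen = set()
        for c in clusters:
            assert len(c.members) >= 2
            assert len({len(m) for m in c.members}) == 1
            assert not (set(c.members) & seen)
            seen.update(c.members)
        assert seen <= set(seqs)

    def test_planted_family_forms_one_cluster(self, small_cohort):
        _, _, gt = small_cohort
        fam = gt.ebv_families[0]
        # brute-force check that every member clears the threshold to the seed
        for m in fam["members"]:
            assert pair_score(fam["seed"], m) >= 2.5
        clusters = build_clusters(fam["members"])
        assert len(clusters) == 1
        assert set(clusters[0].members) == set(fam["members"])

    def test_deterministic_ordering(self):
        seqs = ["CAAAAF", "CAAATF", "CWWWWF", "CWWWIF", "CKKKKF", "CKKKRF"]
        c1 = build_clusters(seqs, ClusterParams(score_threshold=2.0))
        c2 = build_clusters(list(reversed(seqs)), ClusterParams(score_threshold=2.0))
        assert [c.members for c in c1] == [c.members for c in c2]


@settings(deadline=None, max_examples=40, derandomize=True)
@given(
    st.lists(
        st.text(alphabet=AA, min_size=8, max_size=12).map(lambda s: "C" + s + "F"),
        min_size=2, max_size=25, unique=True,
    ),
    st.floats(min_value=-1.0, max_value=5.0),
)
def test_property_oracle_equivalence(seqs, threshold):
    params = ClusterParams(score_threshold=threshold)
    got = [c.members for c in build_clusters(seqs, params)]
    assert got == brute_force_clusters(seqs, params)


class TestPositionProfile:
    def test_identical_members_zero_entropy(self):
        prof = position_profile(["CASSLF"] * 4)
        assert np.allclose(prof.entropy, 0.0)

    def test_even_split_gives_ln2(self):
        prof = position_profile(["CASSAF", "CASSGF"])
        assert prof.entropy[4] == pytest.approx(np.log(2))
        assert np.allclose(prof.entropy[[0, 1, 2, 3, 5]], 0.0)

    def test_frequencies_sum_to_one(self):
        prof = position_profile(["CASSLF", "CASSGF", "CATTLF"])
        assert np.allclose(prof.frequencies.sum(axis=1), 1.0)
        assert (prof.entropy <= np.log(20) + 1e-12).all()

    def test_planted_family_mid_region_diversity(self, small_cohort):
        _, _, gt = small_cohort
        fam = gt.ebv_families[0]
        prof = position_profile(fam["members"])
        L = prof.length
        flanks = list(range(4)) + list(range(L - 5, L))
        assert np.allclose(prof.entropy[flanks], 0.0)
        assert 4 <= int(np.argmax(prof.entropy)) < L - 5
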