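"""Synthetic two-group TCR-beta cohort generator.

Emulates the repertoire structure the downstream analysis assumes: a
tumor and a control arm, heavy-tailed clone sizes spanning the four
expansion tiers, near-normal CDR3 lengths, configurable TRBV/TRBJ usage
(defaulting to cohort-level frequencies led by TRBV20-1 at 9.24% and
TRBJ2-1 at 19.2%), a shared public-clone pool, planted tumor-specific
hyper-expanded clones, and planted EBV-motif sequence families whose
members differ from their seed at no more than two mid-region positions.

The generator returns the planted structure as a :class:`GroundTruth` so
every downstream stage can be tested for exact recovery.  All randomness
flows from one integer seed; each sample draws from its own deterministic
substream, so adding a sample never perturbs earlier ones.
"""

from __future__ import annotations

import dataclasses
import json
import math
from pathlib import Path

import numpy as np

from .models import AA_ALPHABET, CODONS, Repertoire, SampleMeta
from . import io as rio


def _fill_usage(pinned: dict[str, float], others: dict[str, float]) -> dict[str, float]:
    """Combine pinned gene frequencies with relative weights for the rest,
    renormalised so the whole map sums to 1."""
    rem = 1.0 - sum(pinned.values())
    tot = sum(others.values())
    usage = dict(pinned)
    usage.update({g: w * rem / tot for g, w in others.items()})
    return usage


# Cohort-level defaults: the two leading V and J genes are pinned to the
# printed cohort frequencies; the remaining functional genes get plausible
# relative weights for a human peripheral-blood TRB repertoire.
DEFAULT_V_USAGE = _fill_usage(
    {"TRBV20-1": 0.0924, "TRBV6-1": 0.0842},
    {
        "TRBV2": 1.2, "TRBV3-1": 0.7, "TRBV4-1": 1.0, "TRBV4-2": 0.6,
        "TRBV4-3": 0.5, "TRBV5-1": 2.5, "TRBV5-4": 0.8, "TRBV5-5": 0.6,
        "TRBV5-6": 0.7, "TRBV6-2": 0.8, "TRBV6-3": 0.6, "TRBV6-4": 0.5,
        "TRBV6-5": 1.6, "TRBV6-6": 0.7, "TRBV7-2": 1.5, "TRBV7-3": 0.8,
        "TRBV7-6": 0.7, "TRBV7-7": 0.5, "TRBV7-8": 0.8, "TRBV7-9": 1.8,
        "TRBV9": 1.5, "TRBV10-1": 0.4, "TRBV10-2": 0.6, "TRBV10-3": 0.8,
        "TRBV11-1": 0.5, "TRBV11-2": 1.0, "TRBV11-3": 0.6, "TRBV12-3": 1.2,
        "TRBV12-4": 0.8, "TRBV12-5": 0.6, "TRBV13": 0.5, "TRBV14": 0.7,
        "TRBV15": 0.6, "TRBV16": 0.3, "TRBV18": 0.7, "TRBV19": 1.8,
        "TRBV24-1": 0.6, "TRBV25-1": 0.7, "TRBV27": 1.6, "TRBV28": 1.7,
        "TRBV29-1": 1.4, "TRBV30": 0.8,
    },
)
DEFAULT_J_USAGE = _fill_usage(
    {"TRBJ2-1": 0.192, "TRBJ2-7": 0.139},
    {
        "TRBJ1-1": 1.5, "TRBJ1-2": 1.2, "TRBJ1-3": 0.4, "TRBJ1-4": 0.6,
        "TRBJ1-5": 1.1, "TRBJ1-6": 0.6, "TRBJ2-2": 1.0, "TRBJ2-3": 1.3,
        "TRBJ2-4": 0.35, "TRBJ2-5": 1.5, "TRBJ2-6": 0.35,
    },
)

# Interior amino-acid background, loosely tracking junction composition
# (serine/glycine rich); order follows AA_ALPHABET.
_AA_BG_RAW = {
    "A": 0.055, "C": 0.010, "D": 0.040, "E": 0.055, "F": 0.030,
    "G": 0.110, "H": 0.020, "I": 0.025, "K": 0.025, "L": 0.070,
    "M": 0.012, "N": 0.035, "P": 0.045, "Q": 0.055, "R": 0.065,
    "S": 0.130, "T": 0.065, "V": 0.045, "W": 0.008, "Y": 0.060,
}
AA_BACKGROUND = np.array([_AA_BG_RAW[a] for a in AA_ALPHABET])
AA_BACKGROUND = AA_BACKGROUND / AA_BACKGROUND.sum()

_AA_BYTES = np.frombuffer(AA_ALPHABET.encode(), dtype=np.uint8)
_C_IDX = AA_ALPHABET.index("C")
_F_IDX = AA_ALPHABET.index("F")
_N_CODONS = np.array([len(CODONS[a]) for a in AA_ALPHABET])
_MAX_CODONS = int(_N_CODONS.max())
_CODON_TABLE = np.zeros((len(AA_ALPHABET), _MAX_CODONS, 3), dtype=np.uint8)
for _i, _a in enumerate(AA_ALPHABET):
    for _j, _c in enumerate(CODONS[_a]):
        _CODON_TABLE[_i, _j] = np.frombuffer(_c.encode(), dtype=np.uint8)


def _batch_cdr3(lengths: np.ndarray, rng: np.random.Generator) -> tuple[list[str], list[str]]:
    """Vectorised draw of CDR3 (aa, nt) pairs: C ... F with interior
    residues from the background distribution and uniformly chosen codons."""
    lengths = np.asarray(lengths, dtype=np.int64)
    if len(lengths) == 0:
        return [], []
    if (lengths < 3).any():
        raise ValueError("CDR3 length must be >= 3")
    total = int(lengths.sum())
    ends = np.cumsum(lengths)
    starts = ends - lengths
    aa_idx = np.empty(total, dtype=np.int64)
    interior_mask = np.ones(total, dtype=bool)
    interior_mask[starts] = False
    interior_mask[ends - 1] = False
    aa_idx[starts] = _C_IDX
    aa_idx[ends - 1] = _F_IDX
    n_interior = int(interior_mask.sum())
    aa_idx[interior_mask] = rng.choice(len(AA_ALPHABET), size=n_interior, p=AA_BACKGROUND)
    codon_choice = np.floor(rng.random(total) * _N_CODONS[aa_idx]).astype(np.int64)
    aa_str = _AA_BYTES[aa_idx].tobytes().decode()
    nt_str = _CODON_TABLE[aa_idx, codon_choice].reshape(-1).tobytes().decode()
    aas = [aa_str[a:b] for a, b in zip(starts, ends)]
    nts = [nt_str[3 * a : 3 * b] for a, b in zip(starts, ends)]
    return aas, nts


def simulate_cdr3(
    v_gene: str, j_gene: str, length: int, rng: np.random.Generator
) -> tuple[str, str]:
    """Draw one CDR3 for a (V, J) context: returns ``(cdr3_nt, cdr3_aa)``.

    The amino-acid sequence starts with the conserved cysteine and ends
    with the conserved phenylalanine; the nucleotide sequence is an
    in-frame coding sequence of it.
    """
    if not 8 <= length <= 24:
        raise ValueError(f"CDR3 length {length} outside [8, 24]")
    aas, nts = _batch_cdr3(np.array([length]), rng)
    return nts[0], aas[0]


def length_pmf(mean: float, sd: float, lo: int = 8, hi: int = 24):
    """Discrete near-normal CDR3 length law on [lo, hi].

    The pmf is the normal density evaluated at integer lengths and
    renormalised, so the realised mean and sd match the configured values
    (rounding a continuous draw would inflate the variance).
    """
    lengths = np.arange(lo, hi + 1)
    p = np.exp(-0.5 * ((lengths - mean) / sd) ** 2)
    return lengths, p / p.sum()


@dataclasses.dataclass
class SimConfig:
    """Study-condition parameters for the synthetic cohort.

    Defaults mirror the profiled cohort: 68 tumor / 49 control samples,
    ~12,000 unique clonotypes per sample, zipf(1.5) clone sizes, CDR3
    lengths 14.5 +/- 1.5 aa on [8, 24], and the printed leading V/J gene
    frequencies.
    """

    n_control: int = 49
    n_tumor: int = 68
    clones_per_sample: int = 12000
    clones_dispersion: float = 0.05
    clone_size_law: str = "zipf"          # "zipf" or "lognormal"
    zipf_s: float = 1.5
    lognormal_mu: float = 0.0
    lognormal_sigma: float = 2.0
    reads_per_clone: float = 200.0
    cdr3_len_mean: float = 14.5
    cdr3_len_sd: float = 1.5
    cdr3_len_min: int = 8
    cdr3_len_max: int = 24
    v_usage: dict[str, float] = dataclasses.field(
        default_factory=lambda: dict(DEFAULT_V_USAGE)
    )
    j_usage: dict[str, float] = dataclasses.field(
        default_factory=lambda: dict(DEFAULT_J_USAGE)
    )
    public_pool_size: int = 2000
    public_rate: float = 0.1
    public_fraction_low: float = 2e-5
    public_fraction_high: float = 5e-4
    n_planted_tumor_specific: int = 20
    planted_min_fraction: float = 0.02
    planted_max_carriers: int = 5
    planted_low_fraction: float = 5e-4
    planted_high_fraction: float = 8e-3
    n_ebv_families: int = 3
    ebv_family_size: int = 15
    ebv_fraction_low: float = 5e-4
    ebv_fraction_high: float = 5e-3
    ebv_background_rate: float = 0.05
    ebv_stageiv_rate: float = 0.5
    stage_probs: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)
    seed: int = 0

    def validate(self) -> None:
        for name, usage in (("v_usage", self.v_usage), ("j_usage", self.j_usage)):
            if abs(sum(usage.values()) - 1.0) > 1e-9:
                raise ValueError(f"{name} must sum to 1")
            if any(p < 0 for p in usage.values()):
                raise ValueError(f"{name} has negative probabilities")
        if self.n_control < 0 or self.n_tumor < 0:
            raise ValueError("negative group size")
        if self.n_planted_tumor_specific > 0 and self.n_tumor < 2:
            raise ValueError("planting tumor-specific clones needs >= 2 tumor samples")
        if self.n_planted_tumor_specific > 0 and self.planted_min_fraction <= 0.01:
            raise ValueError(
                "planted_min_fraction must exceed the 1% hyper-expansion threshold"
            )
        if self.clone_size_law not in ("zipf", "lognormal"):
            raise ValueError(f"unknown clone_size_law {self.clone_size_law!r}")
        if abs(sum(self.stage_probs) - 1.0) > 1e-9:
            raise ValueError("stage_probs must sum to 1")
        n_special = self.n_planted_tumor_specific + self.n_ebv_families * self.ebv_family_size
        if n_special >= self.clones_per_sample:
            raise ValueError("planted clones exceed clones_per_sample: infeasible")
        if self.ebv_family_size > 0 and self.n_ebv_families > 0 and self.ebv_family_size < 2:
            raise ValueError("ebv_family_size must be >= 2")


@dataclasses.dataclass
class GroundTruth:
    """Planted structure of a simulated cohort (the test oracle)."""

    planted_tumor_specific: dict[str, list[str]]   # cdr3_aa -> tumor carriers
    ebv_families: list[dict]                        # {"seed": aa, "members": [aa...]}
    public_pool: list[str]

    def to_json(self, path: str | Path) -> None:
        payload = {
            "planted_tumor_specific": {
                k: sorted(v) for k, v in sorted(self.planted_tumor_specific.items())
            },
            "ebv_families": [
                {"seed": f["seed"], "members": sorted(f["members"])}
                for f in self.ebv_families
            ],
            "public_pool": sorted(self.public_pool),
        }
        Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruth":
        payload = json.loads(Path(path).read_text())
        return cls(
            planted_tumor_specific=payload["planted_tumor_specific"],
            ebv_families=payload["ebv_families"],
            public_pool=payload["public_pool"],
        )


def _allocate_stages(n_tumor: int, probs, rng: np.random.Generator) -> list[str]:
    """Largest-remainder allocation of tumor stages, then a random shuffle:
    the realised composition follows the configured distribution exactly up
    to rounding, so every stage with positive probability is represented
    once n_tumor is large enough."""
    stages = ["I", "II", "III", "IV"]
    probs = np.asarray(probs, dtype=float)
    exact = probs * n_tumor
    counts = np.floor(exact).astype(int)
    rem = n_tumor - counts.sum()
    order = np.argsort(-(exact - counts), kind="stable")
    for i in range(rem):
        counts[order[i]] += 1
    out = [s for s, c in zip(stages, counts) for _ in range(c)]
    rng.shuffle(out)
    return out


def _unique_cdr3(
    n: int,
    lengths_pool,
    pmf,
    rng: np.random.Generator,
    reserved: set[str],
) -> tuple[list[str], list[str]]:
    """Draw n CDR3s whose aa sequences are distinct and outside ``reserved``."""
    aas: list[str] = []
    nts: list[str] = []
    seen = set(reserved)
    while len(aas) < n:
        k = n - len(aas)
        ls = rng.choice(lengths_pool, size=k, p=pmf)
        cand_aa, cand_nt = _batch_cdr3(ls, rng)
        for a, t in zip(cand_aa, cand_nt):
            if a not in seen:
                seen.add(a)
                aas.append(a)
                nts.append(t)
    return aas, nts


#: intra-family pairwise mean score floor guaranteed by the family model:
#: <= 2 substitutions per member, each scoring >= +1 against the seed
#: residue, over a mid-region of >= 10 scored positions (length >= 14,
#: flanks 2/2) gives mean >= ((10 - 2) * 4 + 2) / 10.
EBV_FAMILY_SCORE_FLOOR = 3.4
EBV_FAMILY_MIN_LENGTH = 14


def _conservative_alternatives() -> dict[str, str]:
    """For each residue, the residues scoring >= +1 against it under
    BLOSUM62 (excluding itself).  Restricting family substitutions to
    these partners guarantees every member scores at least
    :data:`EBV_FAMILY_SCORE_FLOOR` against its seed, so planted families
    stay connected at any clustering stringency up to that floor."""
    from Bio.Align import substitution_matrices

    mat = substitution_matrices.load("BLOSUM62")
    out = {}
    for a in AA_ALPHABET:
        out[a] = "".join(b for b in AA_ALPHABET if b != a and mat[a, b] >= 1)
    return out


def _make_ebv_family(
    seed_aa: str,
    seed_nt: str,
    size: int,
    rng: np.random.Generator,
    alternatives: dict[str, str],
    reserved: set[str],
) -> tuple[list[str], list[str]]:
    """Build a same-length family around a seed by substituting 1-2
    positions inside the mutable window (positions 4 .. L-6, 0-based), with
    the first four and last five residues conserved."""
    length = len(seed_aa)
    window = [p for p in range(4, length - 5) if alternatives[seed_aa[p]]]
    if len(window) < 2:
        raise ValueError(f"seed {seed_aa!r} too short for family generation")
    # combinatorial capacity of <= 2 substitutions over the window
    per_pos = [len(alternatives[seed_aa[p]]) for p in window]
    capacity = sum(per_pos) + sum(
        per_pos[i] * per_pos[j]
        for i in range(len(per_pos)) for j in range(i + 1, len(per_pos))
    )
    if capacity < 2 * size:
        raise ValueError(f"seed {seed_aa!r} supports too few distinct members")
    members = [seed_aa]
    nts = [seed_nt]
    seen = set(reserved) | {seed_aa}
    attempts = 0
    while len(members) < size:
        attempts += 1
        if attempts > 10000:
            raise ValueError("could not generate enough distinct family members")
        n_sub = int(rng.integers(1, 3))
        pos = rng.choice(window, size=min(n_sub, len(window)), replace=False)
        chars = list(seed_aa)
        for p in pos:
            alts = alternatives[seed_aa[p]]
            chars[p] = alts[int(rng.integers(len(alts)))]
        cand = "".join(chars)
        if cand in seen:
            continue
        seen.add(cand)
        members.append(cand)
        # recode the substituted positions on top of the seed's nt sequence
        nt = list(seed_nt)
        for p in pos:
            codons = CODONS[cand[p]]
            nt[3 * p : 3 * p + 3] = codons[int(rng.integers(len(codons)))]
        nts.append("".join(nt))
    return members, nts


def _solve_target_counts(base_total: int, targets: np.ndarray) -> np.ndarray:
    """Smallest integer counts c_i with c_i / (base_total + sum c) >= f_i."""
    f = np.asarray(targets, dtype=float)
    if f.sum() >= 0.8:
        raise ValueError("planted fractions sum too close to 1: infeasible")
    counts = np.ceil(f * base_total / (1.0 - f.sum())).astype(np.int64)
    for _ in range(1000):
        total = base_total + counts.sum()
        need = np.ceil(f * (total - counts) / (1.0 - f)).astype(np.int64)
        if (counts >= need).all():
            return counts
        counts = np.maximum(counts, need)
    raise RuntimeError("target count solver did not converge")


def _clone_weights(n: int, config: SimConfig, rng: np.random.Generator) -> np.ndarray:
    if config.clone_size_law == "zipf":
        return np.arange(1, n + 1, dtype=float) ** (-config.zipf_s)
    return rng.lognormal(config.lognormal_mu, config.lognormal_sigma, size=n)


def simulate_cohort(
    config: SimConfig,
) -> tuple[list[Repertoire], list[SampleMeta], GroundTruth]:
    """Generate the synthetic cohort: repertoires, metadata, ground truth.

    Deterministic given ``config.seed``.  Planted tumor-specific clones
    appear in at least two tumor samples, exceed ``planted_min_fraction``
    in at least one of them, and never occur in a control sample.
    """
    config.validate()
    seed = int(config.seed)
    g_rng = np.random.default_rng([seed, 0])
    lengths_pool, pmf = length_pmf(
        config.cdr3_len_mean, config.cdr3_len_sd, config.cdr3_len_min, config.cdr3_len_max
    )

    # --- metadata -------------------------------------------------------
    control_ids = [f"HC{i + 1:03d}" for i in range(config.n_control)]
    tumor_ids = [f"GC{i + 1:03d}" for i in range(config.n_tumor)]
    stages = _allocate_stages(config.n_tumor, config.stage_probs, g_rng)
    meta: list[SampleMeta] = []
    for sid in control_ids:
        meta.append(
            SampleMeta(sid, "control", "NA", int(g_rng.integers(35, 80)),
                       str(g_rng.choice(["male", "female"])))
        )
    for sid, stage in zip(tumor_ids, stages):
        meta.append(
            SampleMeta(sid, "tumor", stage, int(g_rng.integers(35, 80)),
                       str(g_rng.choice(["male", "female"])))
        )

    # --- planted structure ---------------------------------------------
    reserved: set[str] = set()
    planted_aa, planted_nt = _unique_cdr3(
        config.n_planted_tumor_specific, lengths_pool, pmf, g_rng, reserved
    )
    reserved.update(planted_aa)

    alternatives = _conservative_alternatives() if config.n_ebv_families else {}
    fam_len_pool = lengths_pool[(lengths_pool >= EBV_FAMILY_MIN_LENGTH)]
    fam_pmf = pmf[(lengths_pool >= EBV_FAMILY_MIN_LENGTH)]
    fam_pmf = fam_pmf / fam_pmf.sum()
    ebv_families: list[dict] = []
    ebv_member_nt: dict[str, str] = {}
    for _ in range(config.n_ebv_families):
        for _attempt in range(100):
            (seed_aa,), (seed_nt,) = _unique_cdr3(1, fam_len_pool, fam_pmf, g_rng, reserved)
            try:
                members, nts = _make_ebv_family(
                    seed_aa, seed_nt, config.ebv_family_size, g_rng, alternatives, reserved
                )
                break
            except ValueError:
                continue  # seed had too few substitutable positions; redraw
        else:
            raise RuntimeError("could not find a usable EBV family seed")
        reserved.update(members)
        ebv_families.append({"seed": seed_aa, "members": members})
        ebv_member_nt.update(dict(zip(members, nts)))

    public_aa, public_nt = _unique_cdr3(
        config.public_pool_size, lengths_pool, pmf, g_rng, reserved
    )
    gene_v = sorted(config.v_usage)
    gene_j = sorted(config.j_usage)
    pv = np.array([config.v_usage[g] for g in gene_v])
    pj = np.array([config.j_usage[g] for g in gene_j])
    pv = pv / pv.sum()
    pj = pj / pj.sum()

    def _vj(n: int, rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
        return (
            np.array(gene_v)[rng.choice(len(gene_v), size=n, p=pv)],
            np.array(gene_j)[rng.choice(len(gene_j), size=n, p=pj)],
        )

    public_v, public_j = _vj(config.public_pool_size, g_rng)
    planted_v, planted_j = _vj(config.n_planted_tumor_specific, g_rng)
    n_ebv = len(ebv_member_nt)
    ebv_order = [m for fam in ebv_families for m in fam["members"]]
    ebv_v, ebv_j = _vj(n_ebv, g_rng)
    ebv_vj = {m: (v, j) for m, v, j in zip(ebv_order, ebv_v, ebv_j)}

    # carrier plans: seq -> {sample_id: target_fraction}
    special_plan: dict[str, dict[str, float]] = {sid: {} for sid in control_ids + tumor_ids}
    planted_carriers: dict[str, list[str]] = {}
    for aa in planted_aa:
        k = int(g_rng.integers(2, min(config.planted_max_carriers, config.n_tumor) + 1))
        carriers = list(g_rng.choice(tumor_ids, size=k, replace=False))
        planted_carriers[aa] = sorted(carriers)
        anchor = carriers[0]
        special_plan[anchor][aa] = float(
            g_rng.uniform(1.1 * config.planted_min_fraction, 2.0 * config.planted_min_fraction)
        )
        for sid in carriers[1:]:
            special_plan[sid][aa] = float(
                g_rng.uniform(config.planted_low_fraction, config.planted_high_fraction)
            )

    stage_by_id = {m.sample_id: m.stage for m in meta}
    all_ids = control_ids + tumor_ids
    for member in ebv_order:
        rates = np.array(
            [
                config.ebv_stageiv_rate if stage_by_id[sid] == "IV" else config.ebv_background_rate
                for sid in all_ids
            ]
        )
        # one guaranteed placement, weighted by the per-sample rates
        home = all_ids[int(g_rng.choice(len(all_ids), p=rates / rates.sum()))]
        carriers = {home}
        hits = g_rng.random(len(all_ids)) < rates
        carriers.update(sid for sid, h in zip(all_ids, hits) if h)
        for sid in sorted(carriers):
            special_plan[sid][member] = float(
                g_rng.uniform(config.ebv_fraction_low, config.ebv_fraction_high)
            )

    special_nt = dict(zip(planted_aa, planted_nt))
    special_nt.update(ebv_member_nt)
    special_vj = {aa: (v, j) for aa, v, j in zip(planted_aa, planted_v, planted_j)}
    special_vj.update(ebv_vj)
    special_set = set(special_nt)

    # --- per-sample assembly -------------------------------------------
    reps: list[Repertoire] = []
    import pandas as pd

    for idx, m in enumerate(meta):
        rng = np.random.default_rng([seed, 1, idx])
        n_clones = max(
            20,
            int(round(rng.normal(config.clones_per_sample,
                                 config.clones_per_sample * config.clones_dispersion))),
        )
        ls = rng.choice(lengths_pool, size=n_clones, p=pmf)
        bg_aa, bg_nt = _batch_cdr3(ls, rng)
        keep = [i for i, a in enumerate(bg_aa) if a not in special_set]
        bg_aa = [bg_aa[i] for i in keep]
        bg_nt = [bg_nt[i] for i in keep]
        n_bg = len(bg_aa)
        v, j = _vj(n_bg, rng)
        weights = _clone_weights(n_bg, config, rng)
        total_reads = max(n_bg, int(round(config.reads_per_clone * n_bg)))
        counts = np.maximum(1, np.rint(weights / weights.sum() * total_reads)).astype(np.int64)

        rows_nt = list(bg_nt)
        rows_aa = list(bg_aa)
        rows_v = list(v)
        rows_j = list(j)
        rows_count = list(counts)

        # public clones: small, sub-expansion fractions of the base mass
        base_total = int(counts.sum())
        pub_hits = np.nonzero(rng.random(config.public_pool_size) < config.public_rate)[0]
        for i in pub_hits:
            f = rng.uniform(config.public_fraction_low, config.public_fraction_high)
            rows_nt.append(public_nt[i])
            rows_aa.append(public_aa[i])
            rows_v.append(public_v[i])
            rows_j.append(public_j[i])
            rows_count.append(max(1, int(round(f * base_total))))

        plan = special_plan[m.sample_id]
        if plan:
            base_total = int(np.sum(rows_count))
            seqs = sorted(plan)
            targets = np.array([plan[s] for s in seqs])
            sp_counts = _solve_target_counts(base_total, targets)
            for aa, c in zip(seqs, sp_counts):
                sv, sj = special_vj[aa]
                rows_nt.append(special_nt[aa])
                rows_aa.append(aa)
                rows_v.append(sv)
                rows_j.append(sj)
                rows_count.append(int(c))

        df = pd.DataFrame(
            {
                "cdr3_nt": rows_nt,
                "cdr3_aa": rows_aa,
                "v_gene": rows_v,
                "j_gene": rows_j,
                "count": np.asarray(rows_count, dtype=np.int64),
            }
        )
        reps.append(Repertoire.from_counts(m.sample_id, df))

    gt = GroundTruth(
        planted_tumor_specific=planted_carriers,
        ebv_families=ebv_families,
        public_pool=sorted(public_aa),
    )

    # defensive: the planting contract must hold exactly
    control_set = set()
    for rep, m in zip(reps, meta):
        if m.group == "control":
            control_set.update(rep.df["cdr3_aa"])
    leaked = control_set & set(planted_carriers)
    if leaked:
        raise RuntimeError(f"planted tumor-specific CDR3 leaked into controls: {leaked}")
    return reps, meta, gt


def write_cohort(
    out_dir: str | Path,
    reps: list[Repertoire],
    meta: list[SampleMeta],
    ground_truth: GroundTruth | None = None,
) -> None:
    """Write the cohort as AIRR TSVs plus metadata and ground-truth JSON."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    for rep in reps:
        rio.write_clonotype_table(rep, out_dir / f"{rep.sample_id}.tsv")
    rio.write_metadata(meta, out_dir / "metadata.tsv")
    if ground_truth is not None:
        ground_truth.to_json(out_dir / "ground_truth.json")
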