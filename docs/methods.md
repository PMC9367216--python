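# Methods

## Scope and frequency conventions

The pipeline starts from per-sample clonotype tables; read QC, clonotype
assembly and error correction are upstream concerns.  A clonotype is
identified within a sample by (CDR3 nucleotide sequence, TRBV gene, TRBJ
gene); duplicate keys in an input are collapsed by summing counts.  All
frequencies are count shares: `fraction = count / total_count`, always
recomputed from counts so that tiers, sharing abundances, usage and
diversity share one denominator.  Cross-sample comparisons (sharing,
tracking, cluster membership, EBV abundance) operate on CDR3 amino-acid
sequences: nucleotide variants of one CDR3 aa within a sample are pooled
by summing their fractions.  Only productive CDR3s are analysed; records
with stop codons or non-standard residues are dropped and counted in the
log, never silently.

## Expansion tiers and sharing classes

Tier boundaries are strict on the upper side (hyper > 1% ≥ large
> 0.1% ≥ medium > 0.01% ≥ small), so a clone at exactly a boundary falls
into the lower tier; the three thresholds are configurable but must be
strictly decreasing.  Sharing classes are decided purely by group
occupancy (number of samples carrying the sequence, not read counts):
T&C when both groups carry it, T/C-tumor / T/C-control when exactly one
group carries it in ≥ 2 samples, individual when total occupancy is 1.
The four classes partition the cohort CDR3 universe by construction; the
class × tier table of a sample partitions its read mass.

"Hyper-expanded tumor-specific" means: class T/C-tumor **and** pooled
fraction > 1% in at least one tumor sample.  Requiring only one
hyper-expanded carrier is the weakest reading consistent with tracking
the same clone at sub-hyper levels in other carriers.  Exclusion-list
matching is exact amino-acid string equality, case-insensitive, and
enlarging the exclusion list can only shrink the retained set.

## Statistical tests

All tests are two-sided.  Two-group comparisons of derived per-sample
quantities use Welch's t (the common default of R's `t.test`, and the
data offer no reason to assume equal variances); more than two groups
use Kruskal–Wallis.  The Wilcoxon rank-sum test enumerates the
permutation null exactly (midranks retained, so ties are handled) when
the combined sample size is ≤ 20, and otherwise uses the tie-corrected
normal approximation without continuity correction; the two-sided p is
`min(1, 2·min(P(W ≤ w), P(W ≥ w)))`.  Fisher's exact test sums tables
with probability at most the observed one.  Zero-variance inputs yield
NA-flagged results rather than exceptions.  Gene-usage and HLA tables
report raw p (significance flags mirror raw p) alongside
Benjamini–Hochberg q.

Diversity indices: Shannon entropy in nats, Simpson index Σ f²,
clonality 1 − H/ln(richness) (defined as 1 for a single-clonotype
repertoire, the monoclonal limit), and D50 with fraction ties broken by
nucleotide-sequence lexicographic order.

## Specificity clustering

The clustering is a transparent, oracle-testable variant of
alignment-score specificity grouping: only equal-length CDR3s are
compared (optionally also requiring equal TRBV); the score is the *mean*
per-position substitution-matrix value over the mid-region, with
`flank_left = 2` and `flank_right = 2` residues excluded because the
`C(A)SS…` / `…F` boundaries are nearly invariant; pairs scoring at or
above the threshold are linked and clusters are the connected components
(singletons discarded).  Mean-per-position scoring makes one threshold
meaningful across lengths.  The shipped default is BLOSUM62 with
threshold 2.5 — the stringency of a mostly conserved mid-region with a
couple of tolerated substitutions.  Output ordering is fully
deterministic (clusters by size then smallest member; members sorted).
Gapped alignment and motif-enrichment methods are out of scope.

Connected components are single-linkage: at permissive thresholds,
chance similarities between unrelated sequences can chain clusters
together.  This matters for exact-recovery testing (below).

## EBV-specific abundance

CDR3s are annotated by exact case-insensitive lookup in specificity
databases; one CDR3 may match several epitopes and all hits are kept.
A configurable synonym list ("EBV", "Epstein-Barr virus", "HHV-4", …)
decides which species labels count as EBV.  A cluster is EBV-specific
iff it contains at least one annotated EBV-specific member; a sample's
EBV-specific abundance is the summed pooled fraction of **all** CDR3s in
EBV-specific clusters, annotated or not — clustering exists precisely to
extend incomplete databases.  The same machinery scores the retained
tumor-specific set by swapping the CDR3 universe.  Abundance is compared
across tumor stage (Kruskal–Wallis omnibus plus per-stage vs control
Welch t), age dichotomised at 60 years, and sex.

## Synthetic cohort model

The generator emulates the repertoire structure the analysis assumes,
with defaults set to the profiled study conditions:

| parameter | default | meaning |
| --- | --- | --- |
| `n_control`, `n_tumor` | 49, 68 | group sizes |
| `clones_per_sample` | 12,000 (±5% dispersion) | unique clonotypes per sample |
| `clone_size_law` | zipf, s = 1.5 | rank-frequency law of background clones |
| `reads_per_clone` | 200 | sets the count scale (total reads ≈ 200 × clones) |
| `cdr3_len_mean`, `cdr3_len_sd` | 14.5, 1.5 aa on [8, 24] | CDR3 length law |
| `v_usage`, `j_usage` | TRBV20-1 = 9.24%, TRBV6-1 = 8.42%, TRBJ2-1 = 19.2%, TRBJ2-7 = 13.9%, remainder plausible | gene-draw probabilities |
| `public_pool_size`, `public_rate` | 2,000, 0.1 | shared pool and per-sample inclusion probability |
| `n_planted_tumor_specific` | 20, anchor fraction ≥ 1.1 × 2% | tumor-only hyper-expanded clones |
| `n_ebv_families`, `ebv_family_size` | 3, 15 | same-specificity sequence families |
| `stage_probs` | uniform over I–IV | tumor stage composition |

Integer CDR3 lengths are drawn from the normal density evaluated at the
integers of [8, 24] and renormalised — not from rounding a continuous
draw, which would inflate the variance by 1/12 — so empirical length
moments match the configured values.  CDR3s start with the conserved
cysteine and end with the conserved phenylalanine; interior residues
follow a fixed Ser/Gly-rich background, and nucleotide sequences are
built codon-wise so translation always reproduces the amino-acid
sequence.  Stage labels follow the configured distribution by
largest-remainder allocation (then shuffling), so every stage with
positive probability is represented once the arm is large enough.

Background clone counts follow the configured rank-frequency law scaled
to the read depth (1-read floor).  Public clones are sampled per sample
from a finite pool at small sub-expansion fractions.  Planted
tumor-specific clones are placed in 2–5 tumor samples with an integer
count solver that guarantees the anchor carrier's pooled fraction meets
its target despite rounding; the generator verifies they never occur in
a control sample.  EBV families are built around a seed of length ≥ 14:
each member substitutes 1–2 positions inside the mutable window
(positions 5 … L−6, 1-based; the first four and last five residues are
conserved) with residues scoring ≥ +1 against the seed residue under
BLOSUM62.  That rule gives a provable seed–member mean-score floor of
`EBV_FAMILY_SCORE_FLOOR = 3.4` (≥ 8 of ≥ 10 scored positions on the
diagonal, worst diagonal 4, substitutions ≥ +1), so a planted family is
guaranteed connected at any clustering stringency up to 3.4.  Family
members are planted into at least one sample each, preferentially into
stage-IV patients (`ebv_stageiv_rate` vs `ebv_background_rate`), at
sub-hyper fractions — EBV-reactive clones exist in healthy repertoires
too, just at lower abundance.  All randomness flows from one integer
seed; each sample has its own deterministic substream, so adding a
sample never perturbs earlier ones.

What the generator does **not** model: mechanistic V(D)J recombination
(TdT insertions, chew-back), thymic selection, sequencing error,
V-gene/length covariation, or biological covariance between age, sex and
repertoire structure.  Passing recovery tests therefore demonstrates
correctness of the analysis logic under the stated generative
assumptions, not performance on real cohorts.

## Exact-recovery testing and problem sizes

Recovery tests assert *exact* equality with the planted ground truth.
For tumor-specific discovery this holds at the shipped defaults: planted
clones are the only tumor-restricted multi-carrier hyper-expanded
sequences because background hyper-expanded clones are private and
public/EBV clones stay sub-hyper by construction.  For EBV family
recovery, exactness additionally requires that no background sequence
links into a family cluster.  Under the Ser/Gly-rich background the
probability that two random same-length mid-regions reach mean score
2.5 is ~10⁻⁵–10⁻⁶ per pair — enough for single-linkage chaining at
cohort scale — so exact-recovery checks cluster at the family floor
stringency 3.4, where families are provably connected and the background
exceedance probability (< 4 × 10⁻⁷ per pair) makes chance links
improbable at the tested universe sizes.  The default threshold for
general analysis remains 2.5.

Tests and the acceptance script run on scaled-down cohorts chosen as the
smallest sizes at which each property is meaningfully exercised: 10–20
samples with 800–2,000 clonotypes for partition and recovery checks,
≤ 100 sequences per instance for brute-force clustering equivalence
(200 instances), 10⁶ sampled clonotypes for usage/length fidelity
(empirical V-usage within total variation 0.01 of the configured law),
and a 6-sample toy cohort for byte-identical pipeline determinism.

## Numerical conventions

Partition identities are asserted at 1e-9; fraction round-trips at 1e-9;
input fraction columns are cross-checked at 1e-6.  Score-threshold
comparisons use a 1e-9 slack so exact boundary scores count as linked.
Output TSVs are written with `%.10g` floats and manifests with sorted
keys, which is what makes reruns byte-identical.  The Wilcoxon
exact/asymptotic switch at combined n = 20 is a config constant.

## Known limitations

* Clustering is O(n²) within each length group; cohort-universe
  clustering beyond ~10⁵ sequences per length becomes expensive.
* Exact Wilcoxon enumeration is combinatorial; above combined n = 20 the
  normal approximation is used.
* The stage-IV EBV planting encodes the direction of the effect being
  tested; the recovery test demonstrates the estimator detects a planted
  signal, not that the signal exists in nature.
* HLA-conditioned analyses are limited to stratified reruns of the
  usage comparison and per-allele Fisher enrichment.
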