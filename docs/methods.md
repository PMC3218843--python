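# Methods

## Problem and model

Short-read SNP discovery fails in redundant genomic contexts (paralogous
genes, repeats, segmental duplications) because reads from those regions
align to several loci. Callers that keep only uniquely mapped reads leave
such regions uncovered; callers that keep a best-guess alignment
mis-assign reads and call SNPs at the wrong copy. `multisnp` genotypes
every covered locus from the *complete* read map, unique and multi-mapped
reads together, under a multi-locus Bayesian model.

### Per-read likelihood

A read r with d+1 candidate placements is equally likely to have been
templated by any of them. Given a diploid genotype xy at the focal locus
(reference elsewhere),

    P(r | G_xy) = 1/(d+1) · [ ½ P(r|s(x)) + ½ P(r|s(y)) + Σ_j P(r|s_j, ref) ]

where s(a) is the focal placement's template with allele a substituted at
the read offset over the locus, and the background terms are the read's
other placements with the reference base. Each template probability is a
mixture of a read-specific quality model and a global binomial error
model:

    P(r|s) = λ · Π_i [ (1−p_i) or p_i/3 ]  +  (1−λ) · C(n,k) e^k (1−e)^(n−k)

with p_i = 10^(−q_i/10) (capped at 0.75, the uninformative limit of a
Phred 0), matched/mismatched positions taken against the hypothesized
template, k the placement's mismatch count, n the read length. λ = 0.67
weights the read-specific term by default (a switch flips the
orientation), e = 0.0003 is the global per-base error rate.

### Configuration marginalization

Per-locus posteriors marginalize over a restricted multi-locus
configuration space. The restriction: among the loci linked to the focal
locus through its covering reads' other placements (the "homologous
offsets"), at most one locus deviates from the reference. Exact parallel
mutations in duplicated copies are population-genetically negligible, so
either the focal locus carries one of the ten diploid genotypes (all
linked loci reference), or the focal locus is homozygous-reference and
exactly one linked paralogous locus carries a variant. The posterior at
locus l over the ten unordered genotypes is

    P(xy | reads)  ∝ π(xy) · Π_i P(r_i | G_xy)                    xy ≠ ref/ref
    P(RR | reads)  ∝ π(RR) · Σ_c w_c Π_i P(r_i | G_c)             c over {all-ref} ∪ {(j, g)}

where the background-configuration weights w_c are the products of
per-locus priors over the linked set, normalized so that an uninformative
column returns exactly the per-locus prior (the restricted joint prior's
raw marginal would differ from the documented prior by O(ϑ²); normalizing
keeps "no data ⇒ prior" exact). This competition is what prevents a true
SNP in a duplicated region from being called twice: variant multireads
support "SNP here" and "SNP at the paralog" equally, so neither locus
reaches a confident call unless uniquely anchored reads break the tie.

Priors follow a heterozygosity parameter ϑ = 0.001: homozygous-reference
1−ϑ−ϑ²; the three single-alternative heterozygotes share ϑ/2; the three
homozygous alternatives share ϑ/2; the three double-alternative
heterozygotes share ϑ² (uniform split within each class).

Scope: a locus's posterior uses its covering reads only. Evidence at a
paralogous locus carried by reads that do not cover the focal locus is
seen by that locus's own column, not the focal one. Reads with more than
`max_linked_loci` placements (default 64) contribute only inert
background mass: a read spread over that many loci is essentially
uninformative about any one of them (its evidence scales as 1/d), and
enumerating its configurations would cost O(d) per covered locus. The
same rule is applied identically in the readable per-column
implementation and the vectorized engine, which are tested for exact
agreement.

### Calls and stringency

The MAP genotype is reported per locus with stringency
Q = −10·log10(1 − P_MAP), capped at 255 (ties resolve to
homozygous-reference, then lexicographically — never call a SNP on a
tie). A locus is a significant SNP when MAP ≠ hom-ref and Q ≥ Q_eff. With
degeneracy correction on, Q_eff = Q_min + 10·log10(m) where m − 1 is the
number of distinct loci linked to the locus through shared multi-mapped
reads — a Bonferroni-style correction on the phred scale (α/m ⇒
+10·log10 m) across the paralogous sites that share the evidence. Q ≥ 40
(posterior error < 10⁻⁴) is the default working threshold; Q ≥ 13
(P < 0.05) maximizes sensitivity and Q ≥ 90 specificity.

### Information diagnostic

Under a homogeneous-read simplification (n identical reads, each with d
other placements, common background term c) the log posterior odds
between genotypes is exactly n·log[(p_xy + dc)/(p_x'y' + dc)]: linear in
depth, washed out as d grows. `information_diagnostic` exposes this as a
per-locus confidence heuristic; it also motivates choosing the mismatch
bound k to maximize the ratio of mean read depth to mean alignments per
read (`select_k`), and the guidance k ≈ 1/|r| + e_max + π with k ≤ 0.03
per base (`recommend_k`).

## Aligner

A brute-force ungapped k-mismatch enumerator stands in for an external
aligner so the pipeline runs end-to-end at desk scale. It returns *every*
placement on either strand within Hamming distance k, using a pigeonhole
seed index (one exact segment among k+1 must match) with full vectorized
verification — exact, and cross-checked in tests against a naive
full-scan. 'N' counts as a mismatch on either side. Paired-end units are
formed first (opposite strands, outer span within 150–300 nt by default);
mates without a valid joint placement are rescued as single-end units.
SAM 1.x is written via pysam (MAPQ 255, NM/MD tags; placements beyond a
unit's first are flagged secondary), and any external SAM can be imported
— mismatches are recomputed against the reference on load.

## Mapping strategies

UNI keeps units with exactly one placement; BESTNO keeps the
minimum-mismatch placement only when unique; BEST picks one
minimum-mismatch placement, ties broken uniformly with a recorded seed;
ALL keeps all placements for units with at most d_cap (default 200)
placements and wholly discards units over the cap (max-d, not top-d —
truncating to the top d would bias the multiplicity denominator). BESTNO
is defined as the unique-minimum-mismatch stratum; the definition is
behavioral in origin and an external best-map can be imported instead via
SAM.

## Simulator

The generator reproduces the benchmarking conditions the model was
designed for:

- **Templates**: a random unit (GC fraction 0.40 by default) concatenated
  `copies` times; copies 2..c diverge by independent per-base substitution
  at 0/2/5/10%. The two-copy concatenation of a 94,678-nt unit totals
  189,356 loci.
- **Variants**: per-locus independent heterozygous (0.0005) and
  homozygous (0.0005) substitutions; alternative bases uniform over the
  three non-reference bases (no transition bias). The truth table records
  every event.
- **Reads**: pairs = floor(coverage·|G| / (2·read_len)) — floor, so the
  requested coverage is a lower bound. Insert ~ Normal(250, 30), redrawn
  (≤100 attempts) when shorter than the read or past the sequence end;
  start uniform; haplotype uniform; mate 2 reverse-complemented. Errors
  flip each base to a uniform different base at 0.001/base.
- **Qualities**: per-cycle Normal(mean_c, 10), rounded, clipped to
  [2, 40]; the 36 cycle means are an empirical Illumina-era profile
  (32.8 … 24.2), linearly interpolated over relative cycle position for
  other read lengths.
- **Seeding**: one global integer seed spawns named streams (template /
  variants / reads / qualities), so each component is independently
  reproducible.

What the simulator does *not* emulate: indels and structural variation,
GC/coverage bias from library preparation, platform-specific error
profiles (color-space, flowgrams), correlated errors, or base-quality
miscalibration. Passing tests therefore demonstrate correctness of the
model and pipeline under idealized substitution-only resequencing, not
robustness to real-library artifacts.

## Evaluation

Confusion categories: TP (significant call, exact diploid genotype), TPFG
(significant call at a truth locus, wrong genotype), FP, FN, TN over the
assayed loci (depth > 0). Two printed formula variants exist for
sensitivity and accuracy — one crediting TPFG as a detection, one not —
and both are implemented ("methods" vs "figure"); FDR =
(FP+TPFG)/(TP+FP+TPFG) and FPR = (FP+TPFG)/(FP+TPFG+TN) in both.
Accuracy is also reported phred-transformed, −10·log10(1−acc) (and a
coefficient-1 variant). Undefined 0/0 rates are NaN, never 0. The
closed-form read-loss expectation P[Binom(|r|, e) > k] quantifies reads
discarded by the mismatch bound from errors alone.

## Numerical choices

- Log-space accumulation with a 1e−300 likelihood floor; per-column
  renormalization; all-zero likelihood columns flagged no-call.
- Per-base error probabilities capped at 0.75 (Phred 0 ⇒ uniform over 4
  bases).
- Q caps at 255; beyond Q ≈ 100, 1 − P is below double precision and Q is
  reported at the cap region without further meaning.
- The vectorized engine aggregates entries by (locus, called base) with
  bincount segment sums; paralog-configuration deltas are incremental
  log-ratio updates per (entry, linked locus) group. It requires a
  uniform read length.

## Problem sizes used in the shipped tests

The strategy-comparison benchmark runs five replicates of a 10-kb unit
duplicated at 5% divergence, 50× 36-nt paired-end coverage, k = 2; the
negative control uses the same geometry at 0% divergence. These sizes
were chosen so the full suite runs in well under an hour on one CPU while
preserving the degeneracy regime of interest (two-fold paralogy, APR ≈ 2).

## Known limitations

- Substitutions only; columns near real indels would be genotyped as-is.
- The configuration space is per-column; long-range evidence linking
  paralog copies through reads not covering the focal locus is not
  pooled.
- The degeneracy-corrected threshold's exact historical form is not
  published; the +10·log10(m) phred-scale Bonferroni is this package's
  reconstruction.
- No base-quality recalibration, population imputation, or
  platform-specific error models.
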