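# multisnp

Multi-locus Bayesian SNP genotyping that uses **multiply mapped** short
reads instead of discarding them.

Eukaryotic genomes are full of near-identical sequence — paralogous
genes, repeats, segmental duplications — and short reads from those
regions align to several loci. Standard callers either keep only
uniquely mapped reads (leaving redundant regions uncovered and their
SNPs undiscovered) or keep a single best-guess alignment (mis-assigning
reads and calling SNPs at the wrong copy). `multisnp` genotypes every
covered locus from the complete read map with a Bayesian model that
marginalizes each read over its d+1 candidate placements and, per locus,
over the restricted multi-locus configurations in which at most one of
the read-linked paralogous loci deviates from the reference.

For a read r with placements s₁…s_{d+1} and diploid genotype xy at the
focal locus:

    P(r | G_xy) = 1/(d+1) · [ ½ P(r|s(x)) + ½ P(r|s(y)) + Σ_j P(r|s_j, ref) ]
    P(r | s)    = λ·P_read(q) + (1−λ)·P_bin(n, k, e)

with P_read the per-base quality-score likelihood (Π (1−p_i) over
matches, p_i/3 over mismatches), P_bin the binomial point mass at the
placement's mismatch count, λ = 0.67, e = 3×10⁻⁴. Posteriors over the
ten unordered diploid genotypes use a heterozygosity prior
(hom-ref 1−ϑ−ϑ², ϑ = 10⁻³) and are summarized by the MAP genotype and
its stringency Q = −10·log10(1 − P_MAP); a SNP is significant when
MAP ≠ hom-ref and Q clears a degeneracy-corrected threshold
Q_min + 10·log10(m) over the m loci sharing the evidence. The package
includes everything needed to validate the method end-to-end with no
external data: a paired-end read simulator with an empirical quality
profile, an exhaustive k-mismatch aligner with SAM I/O, the four
read-map strategies (UNI / BESTNO / BEST / ALL), and a truth-based
benchmarking module. See `docs/methods.md` for the full model.

## Worked example

Simulate a two-copy template (2 kb unit, 5% inter-copy divergence — a
hard, degenerate target), inject variants at 10⁻³/locus, sequence to
50×, and genotype from the total read map:

```python
from multisnp import *
from multisnp.model import MultiMapGenotyper

spec = TemplateSpec(unit_length=2000, copies=2, inter_copy_divergence=0.05, seed=7)
genome = build_template(spec)
sample = inject_variation(genome, 0.0005, 0.0005, seed=8)
print("truth:", [(t.pos, t.genotype, t.zygosity) for t in sample.truth])

reads = sample_pe_reads(sample, coverage=50, read_len=36, seed=9)
alns = align_reads(reads, genome, k=2)
res = MultiMapGenotyper.from_alignments(alns, genome, strategy="ALL").fit()
print(res.summary())
```

```
truth: [(108, 'CT', 'het'), (840, 'AC', 'het'), (2306, 'CC', 'hom'), (3656, 'GG', 'hom')]
Multi-locus Bayesian genotyping results
===============================================
Strategy: ALL      k = 2   d_cap = 200
Params:   e = 0.0003  lambda = 0.67  theta = 0.001
Reads retained:              5553
Alignments:                  8363   (APR = 1.51)
Loci assayed:                4000   (100.0% of genome)
Mean depth:                 75.27
Non-unique reads:           50.6%
Significant SNPs (Q >= 40, degeneracy-corrected): 4
-----------------------------------------------
seq              pos  ref   MAP        Q  depth
template         108    C    CT    129.3     34
template         840    A    AC    255.0     93
template        2306    T    CC    255.0     90
template        3656    A    GG    255.0    100
```

All four injected variants are recovered with the correct diploid
genotypes and no false positives, even though half the reads map to both
copies (APR 1.51, 50.6% non-unique). With `strategy="UNI"` the
duplicated interior is barely covered; with `strategy="BEST"`
mis-assigned variant reads produce false calls at the paralogous copy —
the orderings the benchmarking suite asserts. `res.posteriors` is a
DataFrame with the full ten-genotype posterior, depth, multiplicity and
degeneracy diagnostics per locus; `res.calls()`, `res.to_tsv()` and
`res.to_vcf()` extract and export significant SNPs.

The same pipeline is scriptable from the shell:

```sh
multisnp simulate --out sim --seed 7
multisnp align --ref sim/reference.fasta --fastq1 sim/reads_1.fastq \
               --fastq2 sim/reads_2.fastq -k 2 --out sim/aln.sam
multisnp genotype --sam sim/aln.sam --ref sim/reference.fasta \
                  --strategy all --max-d 200 -k 2 -Q 40 --out sim/geno
multisnp evaluate --calls sim/geno.calls.tsv --truth sim/truth.tsv
multisnp run --config config.yaml --out rundir   # end-to-end with manifest
```

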