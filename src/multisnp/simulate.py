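"""Synthetic templates, diploid sample genomes and error-prone paired-end reads.

The generator reproduces the study conditions used to benchmark the
genotyper: repetitive reference templates built by concatenating diverged
copies of a random unit, diploid sample genomes obtained by injecting
heterozygous and homozygous substitutions at known rates, and paired-end
reads with Gaussian insert sizes, uniform base-call errors and per-cycle
Phred qualities drawn around an empirical Illumina-style profile.

Coordinates are 0-based half-open throughout; truth tables are written
0-based and only converted to 1-based in VCF-like exports.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from . import _seq
from ._seq import decode, encode, stream

# Per-cycle mean Phred scores measured from 36-nt paired-end Illumina 1G
# yeast data; used as the default empirical quality profile.
DEFAULT_QUALITY_MEANS = np.array(
    [32.8, 32.6, 32.5, 32.5, 31.9, 31.8, 31.7, 31.8, 31.5, 31.3, 31.2, 31.0,
     30.5, 30.4, 29.9, 30.0, 29.3, 29.5, 29.3, 29.2, 29.1, 29.3, 29.4, 29.6,
     29.3, 29.3, 28.6, 28.4, 28.0, 27.7, 27.2, 26.3, 26.2, 26.0, 24.8, 24.2]
)


class ReferenceGenome:
    """Named nucleotide sequences serving as the known reference template.

    Parameters
    ----------
    sequences : dict of str -> str
        Mapping of sequence name to nucleotide string over {A,C,G,T,N}.
    """

    def __init__(self, sequences: dict[str, str]):
        if not sequences:
            raise ValueError("genome must contain at least one sequence")
        if any(len(s) == 0 for s in sequences.values()):
            raise ValueError("sequences must be non-empty")
        self.sequences = dict(sequences)
        self._encoded = {n: encode(s) for n, s in self.sequences.items()}
        self._caches: dict = {}  # seed indexes etc., owned by align module

    @property
    def names(self) -> list[str]:
        return list(self.sequences)

    @property
    def total_length(self) -> int:
        return sum(len(s) for s in self.sequences.values())

    def encoded(self, name: str) -> np.ndarray:
        return self._encoded[name]

    def __getitem__(self, name: str) -> str:
        return self.sequences[name]

    @classmethod
    def from_fasta(cls, path) -> "ReferenceGenome":
        records = {r.id: str(r.seq).upper() for r in SeqIO.parse(str(path), "fasta")}
        return cls(records)

    def to_fasta(self, path) -> None:
        records = [SeqRecord(Seq(s), id=n, description="") for n, s in self.sequences.items()]
        SeqIO.write(records, str(path), "fasta")


@dataclass
class TemplateSpec:
    """Recipe for a synthetic repetitive template.

    ``copies`` tandem copies of a random ``unit_length``-nt unit are
    concatenated; copies 2..c diverge from copy 1 by independent per-base
    substitution at ``inter_copy_divergence``.
    """

    unit_length: int
    copies: int = 1
    inter_copy_divergence: float = 0.0
    gc_fraction: float = 0.40
    seed: int = 0
    name: str = "template"

    def __post_init__(self):
        if self.unit_length < 1:
            raise ValueError("unit_length must be >= 1")
        if self.copies < 1:
            raise ValueError("copies must be >= 1")
        if not 0.0 <= self.inter_copy_divergence <= 1.0:
            raise ValueError("divergence must be in [0, 1]")
        if not 0.0 <= self.gc_fraction <= 1.0:
            raise ValueError("gc_fraction must be in [0, 1]")


@dataclass
class TruthEntry:
    """One injected variant: genotype is the unordered diploid pair, e.g. 'AT'."""

    seq_name: str
    pos: int  # 0-based
    ref: str
    genotype: str
    zygosity: str  # "het" | "hom"


@dataclass
class SampleGenome:
    """Diploid haplotype pair per reference sequence plus the variant truth table."""

    reference: ReferenceGenome
    haplotypes: dict[str, tuple[np.ndarray, np.ndarray]]
    truth: list[TruthEntry] = field(default_factory=list)

    def haplotype_str(self, name: str, hap: int) -> str:
        return decode(self.haplotypes[name][hap])

    def to_fasta(self, path) -> None:
        records = []
        for name, (h1, h2) in self.haplotypes.items():
            records.append(SeqRecord(Seq(decode(h1)), id=f"{name}_hap1", description=""))
            records.append(SeqRecord(Seq(decode(h2)), id=f"{name}_hap2", description=""))
        SeqIO.write(records, str(path), "fasta")

    def write_truth(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("seq\tpos0\tref\tgenotype\tzygosity\n")
            for t in self.truth:
                fh.write(f"{t.seq_name}\t{t.pos}\t{t.ref}\t{t.genotype}\t{t.zygosity}\n")


def read_truth(path) -> list[TruthEntry]:
    out = []
    with open(path) as fh:
        header = fh.readline()
        assert header.startswith("seq")
        for line in fh:
            seq, pos, ref, gt, zyg = line.rstrip("\n").split("\t")
            out.append(TruthEntry(seq, int(pos), ref, gt, zyg))
    return out


@dataclass
class QualityModel:
    """Per-cycle Gaussian Phred-score model.

    ``position_means`` holds the mean score per sequencing cycle; scores are
    drawn Normal(mean, sd), rounded, and clipped to [floor, ceiling]. For
    read lengths other than the profile length the means are linearly
    interpolated over relative cycle position.
    """

    position_means: np.ndarray = field(default_factory=lambda: DEFAULT_QUALITY_MEANS.copy())
    position_sd: float = 10.0
    floor: int = 2
    ceiling: int = 40

    def means_for_length(self, read_len: int) -> np.ndarray:
        m = np.asarray(self.position_means, dtype=float)
        if not np.all(np.isfinite(m)):
            raise ValueError("position means must be finite")
        if read_len == len(m):
            return m
        x = np.linspace(0.0, 1.0, read_len)
        xp = np.linspace(0.0, 1.0, len(m))
        return np.interp(x, xp, m)

    def sample(self, n_reads: int, read_len: int, rng: np.random.Generator,
               clip: bool = True) -> np.ndarray:
        means = self.means_for_length(read_len)
        q = rng.normal(means, self.position_sd, size=(n_reads, read_len))
        q = np.rint(q)
        if clip:
            q = np.clip(q, self.floor, self.ceiling)
        return q.astype(np.int16)


@dataclass
class ReadSet:
    """Simulated reads with truth origins (origins are for evaluation only).

    Sequences and qualities are stored as dense (n, read_len) arrays; use
    :meth:`records` for string-level access or :meth:`to_fastq` to export.
    """

    ids: list[str]
    mate: np.ndarray          # 1 or 2; 0 for single-end
    seqs: np.ndarray          # (n, L) uint8 encoded
    quals: np.ndarray         # (n, L) int16 Phred
    origin_seq: list[str]
    origin_start: np.ndarray  # 0-based
    origin_strand: np.ndarray  # "+" / "-"

    def __len__(self) -> int:
        return len(self.ids)

    @property
    def read_len(self) -> int:
        return self.seqs.shape[1]

    def records(self) -> Iterator[tuple[str, int, str, str]]:
        for i in range(len(self.ids)):
            yield (self.ids[i], int(self.mate[i]), decode(self.seqs[i]),
                   "".join(chr(q + 33) for q in self.quals[i]))

    def to_fastq(self, prefix) -> list[str]:
        """Write mates to ``<prefix>_1.fastq`` / ``<prefix>_2.fastq``.

        Single-end reads (mate 0) go to ``<prefix>.fastq``.
        """
        paths = []
        handles = {}
        try:
            for rid, mate, seq, qual in self.records():
                if mate not in handles:
                    suffix = f"_{mate}.fastq" if mate else ".fastq"
                    p = f"{prefix}{suffix}"
                    handles[mate] = open(p, "w")
                    paths.append(p)
                handles[mate].write(f"@{rid}/{mate}\n{seq}\n+\n{qual}\n" if mate
                                    else f"@{rid}\n{seq}\n+\n{qual}\n")
        finally:
            for fh in handles.values():
                fh.close()
        return paths


def build_template(spec: TemplateSpec) -> ReferenceGenome:
    """Build a repetitive reference from a :class:`TemplateSpec`.

    Copy 1 is random with the requested GC fraction; copies 2..c substitute
    each base independently (to a uniformly chosen different base) with
    probability ``inter_copy_divergence``.
    """
    rng = stream(spec.seed, "template")
    pa = (1.0 - spec.gc_fraction) / 2.0
    pg = spec.gc_fraction / 2.0
    unit = rng.choice(4, size=spec.unit_length, p=[pa, pg, pg, pa]).astype(np.uint8)
    parts = [unit]
    for _ in range(1, spec.copies):
        copy = unit.copy()
        mask = rng.random(spec.unit_length) < spec.inter_copy_divergence
        if mask.any():
            # uniformly one of the 3 non-reference bases
            shift = rng.integers(1, 4, size=int(mask.sum()))
            copy[mask] = (copy[mask] + shift) % 4
        parts.append(copy)
    seq = decode(np.concatenate(parts))
    return ReferenceGenome({spec.name: seq})


def inject_variation(ref: ReferenceGenome, het_rate: float, hom_rate: float,
                     seed: int = 0) -> SampleGenome:
    """Derive a diploid sample genome by injecting substitutions at known rates.

    Each locus independently becomes a heterozygous variant with probability
    ``het_rate`` (one haplotype substituted) or a homozygous variant with
    probability ``hom_rate`` (both haplotypes carry the same alternative).
    """
    if het_rate < 0 or hom_rate < 0:
        raise ValueError("rates must be non-negative")
    if het_rate + hom_rate > 1:
        raise ValueError("het_rate + hom_rate must not exceed 1")
    rng = stream(seed, "variants")
    haplotypes = {}
    truth: list[TruthEntry] = []
    for name in ref.names:
        base = ref.encoded(name)
        h1 = base.copy()
        h2 = base.copy()
        u = rng.random(len(base))
        het_loci = np.flatnonzero(u < het_rate)
        hom_loci = np.flatnonzero((u >= het_rate) & (u < het_rate + hom_rate))
        # alternative base: uniform over the 3 non-reference bases
        for loci, zyg in ((het_loci, "het"), (hom_loci, "hom")):
            if len(loci) == 0:
                continue
            alts = (base[loci] + rng.integers(1, 4, size=len(loci))) % 4
            if zyg == "het":
                which = rng.integers(0, 2, size=len(loci))  # which haplotype mutates
                h1[loci[which == 0]] = alts[which == 0]
                h2[loci[which == 1]] = alts[which == 1]
            else:
                h1[loci] = alts
                h2[loci] = alts
            for pos, alt in zip(loci.tolist(), alts.tolist()):
                rb = _seq.ALPHABET[base[pos]]
                ab = _seq.ALPHABET[alt]
                gt = "".join(sorted(rb + ab)) if zyg == "het" else ab + ab
                truth.append(TruthEntry(name, pos, rb, gt, zyg))
        haplotypes[name] = (h1, h2)
    truth.sort(key=lambda t: (t.seq_name, t.pos))
    return SampleGenome(ref, haplotypes, truth)


def pair_count(coverage: float, genome_length: int, read_len: int) -> int:
    """Number of read pairs simulated: floor(coverage * |G| / (2 * read_len)).

    Floor is used, so the requested coverage is a lower bound.
    """
    return int(coverage * genome_length // (2 * read_len))


def sample_pe_reads(sample: SampleGenome, coverage: float, read_len: int = 36,
                    insert_mean: float = 250.0, insert_sd: float = 30.0,
                    error_rate: float = 0.001,
                    qmodel: QualityModel | None = None, seed: int = 0,
                    clip_qualities: bool = True) -> ReadSet:
    """Sample error-prone paired-end reads from a diploid sample genome.

    Each pair is drawn from a uniformly chosen haplotype of a length-weighted
    sequence; the insert length is Gaussian(insert_mean, insert_sd), redrawn
    (up to 100 attempts) when shorter than the read or beyond the sequence
    end. Mate 1 reads the fragment 5'->3'; mate 2 is the reverse complement
    of the fragment's other end. Base-call errors flip each base to a
    uniformly chosen different base with probability ``error_rate``.
    """
    if coverage <= 0:
        raise ValueError("coverage must be positive")
    if qmodel is None:
        qmodel = QualityModel()
    ref = sample.reference
    n_pairs = pair_count(coverage, ref.total_length, read_len)
    rng = stream(seed, "reads")
    qrng = stream(seed, "qualities")

    names = ref.names
    lengths = np.array([len(ref[n]) for n in names], dtype=float)
    if np.all(lengths < read_len):
        raise ValueError("all sequences shorter than the read length")
    probs = lengths / lengths.sum()

    seq_choice = rng.choice(len(names), size=n_pairs, p=probs)
    hap_choice = rng.integers(0, 2, size=n_pairs)
    inserts = np.rint(rng.normal(insert_mean, insert_sd, size=n_pairs)).astype(int)
    seq_len = lengths[seq_choice].astype(int)
    bad = (inserts < read_len) | (inserts > seq_len)
    attempts = 0
    while bad.any():
        attempts += 1
        if attempts > 100:
            raise RuntimeError(
                "could not draw valid insert sizes; genome too short for the "
                "insert distribution")
        redraw = np.rint(rng.normal(insert_mean, insert_sd, size=int(bad.sum()))).astype(int)
        inserts[bad] = redraw
        bad = (inserts < read_len) | (inserts > seq_len)
    starts = (rng.random(n_pairs) * (seq_len - inserts + 1)).astype(int)

    n_reads = 2 * n_pairs
    seqs = np.empty((n_reads, read_len), dtype=np.uint8)
    origin_start = np.empty(n_reads, dtype=int)
    origin_strand = np.empty(n_reads, dtype="U1")
    origin_seq: list[str] = [""] * n_reads
    ids: list[str] = [""] * n_reads
    mate = np.empty(n_reads, dtype=np.int8)

    offsets = np.arange(read_len)
    for si, name in enumerate(names):
        sel = np.flatnonzero(seq_choice == si)
        if len(sel) == 0:
            continue
        haps = sample.haplotypes[name]
        for hap in (0, 1):
            idx = sel[hap_choice[sel] == hap]
            if len(idx) == 0:
                continue
            s = starts[idx]
            e = s + inserts[idx] - read_len  # mate-2 start (forward coords)
            seqs[2 * idx] = haps[hap][s[:, None] + offsets]
            seqs[2 * idx + 1] = _seq.complement(haps[hap][e[:, None] + offsets])[:, ::-1]
            origin_start[2 * idx] = s
            origin_start[2 * idx + 1] = e
        for i in sel:
            origin_seq[2 * i] = name
            origin_seq[2 * i + 1] = name
    origin_strand[0::2] = "+"
    origin_strand[1::2] = "-"
    mate[0::2] = 1
    mate[1::2] = 2
    for i in range(n_pairs):
        ids[2 * i] = f"r{i:07d}"
        ids[2 * i + 1] = f"r{i:07d}"

    if error_rate > 0:
        err = rng.random((n_reads, read_len)) < error_rate
        if err.any():
            shift = rng.integers(1, 4, size=int(err.sum())).astype(np.uint8)
            seqs[err] = (seqs[err] + shift) % 4

    quals = qmodel.sample(n_reads, read_len, qrng, clip=clip_qualities)
    return ReadSet(ids, mate, seqs, quals, origin_seq, origin_start, origin_strand)
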