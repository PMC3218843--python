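"""Read-map strategies, pileups and map statistics.

Four strategies decide which of a read unit's candidate placements are
retained:

UNI
    keep units with exactly one placement;
BESTNO
    keep the minimum-mismatch placement only when it is unique (ties drop
    the unit);
BEST
    keep one minimum-mismatch placement, breaking ties uniformly at random
    with a recorded seed;
ALL
    keep every placement for units with at most ``d_cap`` placements
    (max-d semantics: units over the cap are wholly discarded).

A retained mate's multiplicity d+1 is the number of unit placements it
participates in; it feeds the genotyper's marginalization over templates.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator

import numpy as np

from ._seq import ALPHABET, complement, encode, stream
from .align import Alignment, AlignmentSet, PairPlacement, ReadUnit, pair_alignments
from .simulate import ReadSet, ReferenceGenome

STRATEGIES = ("UNI", "BESTNO", "BEST", "ALL")


@dataclass
class MappingStrategy:
    kind: str = "ALL"
    d_cap: int = 200   # d+1 in the usual notation; ALL only
    seed: int = 0      # BEST tie-breaking

    def __post_init__(self):
        self.kind = self.kind.upper()
        if self.kind not in STRATEGIES:
            raise ValueError(f"unknown strategy {self.kind!r}")
        if self.kind == "ALL" and self.d_cap < 1:
            raise ValueError("d_cap must be >= 1 for ALL")


@dataclass
class ReadMap:
    """Retained read units after a strategy has been applied."""

    units: list[ReadUnit]
    strategy: MappingStrategy
    k: int
    reads: ReadSet | None = None

    def mate_alignments(self) -> Iterator[tuple[int, list[Alignment]]]:
        """Yield (read index, placements) per retained mate.

        The list length is the mate's multiplicity d+1.
        """
        for unit in self.units:
            for mate, ridx in unit.read_indices.items():
                alns = []
                for p in unit.placements:
                    a = p.a1 if mate == 1 else p.a2
                    if a is None and len(unit.read_indices) == 1:
                        a = p.a1 or p.a2
                    if a is not None:
                        alns.append(a)
                if alns:
                    yield ridx, alns


def apply_strategy(alns: AlignmentSet, strategy: MappingStrategy) -> ReadMap:
    """Filter an alignment set down to the placements a strategy retains.

    Deterministic given the strategy seed; idempotent and order-independent
    over read units.
    """
    rng = stream(strategy.seed, "best-ties")
    kept: list[ReadUnit] = []
    for unit in alns.units:
        n = len(unit.placements)
        if n == 0:
            continue
        kind = strategy.kind
        if kind == "UNI":
            if n == 1:
                kept.append(unit)
        elif kind in ("BESTNO", "BEST"):
            mm = [p.mismatches for p in unit.placements]
            best = min(mm)
            ties = [p for p, m in zip(unit.placements, mm) if m == best]
            if kind == "BESTNO":
                if len(ties) == 1:
                    kept.append(ReadUnit(unit.read_id, ties, unit.read_indices))
            else:
                choice = ties[0] if len(ties) == 1 else ties[int(rng.integers(len(ties)))]
                kept.append(ReadUnit(unit.read_id, [choice], unit.read_indices))
        elif kind == "ALL":
            if n <= strategy.d_cap:
                kept.append(unit)
    return ReadMap(kept, strategy, alns.k, reads=alns.reads)


# ---------------------------------------------------------------------------
# Pileups (reference, per-column representation)

@dataclass
class OtherContext:
    """One of a read's other placements, seen from a focal pileup entry.

    ``locus`` is the genome position homologous to the focal locus (where
    the same read base lands under this placement); ``offset`` is that
    base's read coordinate there (identical physical base).
    """

    seq_name: str
    locus: int
    ref_base: str
    mismatch_offsets: tuple[int, ...]
    offset: int


@dataclass
class PileupEntry:
    base: str                 # called base over the focal locus
    qual: int                 # its Phred score
    quals: np.ndarray         # full read quality vector (sequencing order)
    offset: int               # read coordinate covering the focal locus
    mismatch_offsets: tuple[int, ...]  # focal alignment vs reference
    multiplicity: int         # d+1 for this mate
    others: list[OtherContext] = field(default_factory=list)


@dataclass
class PileupColumn:
    seq_name: str
    locus: int
    ref_base: str
    entries: list[PileupEntry]

    @property
    def depth(self) -> int:
        return len(self.entries)


def _entry_for(aln: Alignment, reads: ReadSet, ridx: int, locus: int,
               alns: list[Alignment], genome: ReferenceGenome) -> PileupEntry:
    L = aln.read_len
    j = locus - aln.start
    o = j if aln.strand == "+" else L - 1 - j
    code = reads.seqs[ridx][o]
    base = ALPHABET[complement(np.array([code]))[0]] if aln.strand == "-" else ALPHABET[code]
    quals = reads.quals[ridx]
    others = []
    for other in alns:
        if other is aln:
            continue
        oo = o  # same physical base, same read coordinate
        jj = oo if other.strand == "+" else L - 1 - oo
        glocus = other.start + jj
        ref_b = genome[other.seq_name][glocus]
        others.append(OtherContext(other.seq_name, glocus, ref_b,
                                   other.mismatch_offsets, oo))
    return PileupEntry(base=base, qual=int(quals[o]), quals=quals, offset=o,
                       mismatch_offsets=aln.mismatch_offsets,
                       multiplicity=len(alns), others=others)


def build_pileups(read_map: ReadMap, genome: ReferenceGenome) -> Iterator[PileupColumn]:
    """Stream one column per covered locus, in (sequence, locus) order.

    Each entry records the read's other placements with the reference base
    at the homologous offset, which the genotyper's background terms and
    paralog configurations need. This is the plain per-column path; the
    model's fit() computes the same quantities vectorized.
    """
    reads = read_map.reads
    if reads is None:
        raise ValueError("read map lacks read sequences")
    cols: dict[tuple[str, int], list] = {}
    for ridx, alns in read_map.mate_alignments():
        for aln in alns:
            if aln.end > len(genome[aln.seq_name]):
                raise ValueError("alignment out of genome bounds")
            for locus in range(aln.start, aln.end):
                cols.setdefault((aln.seq_name, locus), []).append((aln, ridx, alns))
    for (name, locus) in sorted(cols):
        entries = [_entry_for(aln, reads, ridx, locus, alns, genome)
                   for aln, ridx, alns in cols[(name, locus)]]
        yield PileupColumn(name, locus, genome[name][locus], entries)


# ---------------------------------------------------------------------------
# Map statistics and k selection

@dataclass
class MapStats:
    mean_depth: float
    mean_alignments_per_read: float
    degeneracy_ratio: float
    fraction_covered: float
    fraction_nonunique: float
    n_reads: int
    n_alignments: int


def map_stats(read_map: ReadMap, genome: ReferenceGenome) -> MapStats:
    """Depth / alignments-per-read summary of a retained read map."""
    total = genome.total_length
    covered = np.zeros(total, dtype=bool)
    offsets = {}
    off = 0
    for n in genome.names:
        offsets[n] = off
        off += len(genome[n])
    n_reads = 0
    n_alns = 0
    n_nonuniq = 0
    aligned_bases = 0
    for _, alns in read_map.mate_alignments():
        n_reads += 1
        n_alns += len(alns)
        if len(alns) > 1:
            n_nonuniq += 1
        for a in alns:
            covered[offsets[a.seq_name] + a.start:offsets[a.seq_name] + a.end] = True
            aligned_bases += a.read_len
    n_cov = int(covered.sum())
    mean_depth = aligned_bases / n_cov if n_cov else 0.0
    apr = n_alns / n_reads if n_reads else 0.0
    ratio = mean_depth / apr if apr > 0 else float("nan")
    return MapStats(mean_depth, apr, ratio, n_cov / total,
                    n_nonuniq / n_reads if n_reads else 0.0, n_reads, n_alns)


def select_k(stats_by_k: dict[int, MapStats]) -> int:
    """Pick the k maximizing mean depth / mean alignments-per-read (ties: smallest k)."""
    if not stats_by_k:
        raise ValueError("no candidate k supplied")
    best_k = None
    best_ratio = -np.inf
    for k in sorted(stats_by_k):
        r = stats_by_k[k].degeneracy_ratio
        if np.isfinite(r) and r > best_ratio:
            best_ratio = r
            best_k = k
    if best_k is None:
        best_k = min(stats_by_k)
    return best_k


# ---------------------------------------------------------------------------
# SAM import (round trip of align.write_sam; also accepts external maps)

def alignment_set_from_sam(path, genome: ReferenceGenome,
                           k: int | None = None,
                           insert_range: tuple[int, int] = (150, 300)) -> AlignmentSet:
    """Rebuild an AlignmentSet (reads + unit placements) from a SAM file.

    Mismatch counts and offsets are recomputed against the reference, so the
    import is robust to maps produced by external aligners. Mates sharing a
    query name are re-paired with the supplied insert range; mates with no
    valid joint placement fall back to single-end units.
    """
    import pysam

    by_read: dict[tuple[str, int], dict] = {}
    order: list[tuple[str, int]] = []
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as sam:
        for rec in sam:
            if rec.is_unmapped:
                continue
            mate = 1 if rec.is_read1 else (2 if rec.is_read2 else 0)
            key = (rec.query_name, mate)
            rev = rec.is_reverse
            seq = rec.query_sequence
            qual = rec.query_qualities
            if seq is None:
                continue
            enc = encode(seq)
            q = np.asarray(qual, dtype=np.int16) if qual is not None else np.full(len(seq), 30, np.int16)
            if rev:
                from ._seq import revcomp
                enc = revcomp(enc)
                q = q[::-1]
            if key not in by_read:
                by_read[key] = {"seq": enc, "qual": q, "alns": []}
                order.append(key)
            name = rec.reference_name
            start = rec.reference_start
            L = rec.query_length
            ref = genome.encoded(name)[start:start + L]
            win_read = encode(seq)  # SAM stores the genome-forward orientation
            mm = (win_read != ref) | (win_read == 4) | (ref == 4)
            goffs = np.flatnonzero(mm)
            offs = tuple(int(o) for o in goffs) if not rev else tuple(
                int((L - 1) - o) for o in goffs[::-1])
            by_read[key]["alns"].append(Alignment(
                rec.query_name, mate, name, int(start), "-" if rev else "+",
                int(mm.sum()), offs, int(L)))

    # assemble a ReadSet-like container
    ids = []
    mates = []
    seqs = []
    quals = []
    for (rid, mate) in order:
        ids.append(rid)
        mates.append(mate)
        seqs.append(by_read[(rid, mate)]["seq"])
        quals.append(by_read[(rid, mate)]["qual"])
    L = len(seqs[0]) if seqs else 0
    if any(len(s) != L for s in seqs):
        raise ValueError("mixed read lengths are not supported")
    reads = ReadSet(ids, np.array(mates, dtype=np.int8),
                    np.vstack(seqs) if seqs else np.empty((0, 0), np.uint8),
                    np.vstack(quals) if quals else np.empty((0, 0), np.int16),
                    [""] * len(ids), np.zeros(len(ids), dtype=int),
                    np.array([""] * len(ids), dtype="U1"))
    index = {key: i for i, key in enumerate(order)}

    units: list[ReadUnit] = []
    seen_pairs = set()
    for (rid, mate) in order:
        if (rid, mate) in seen_pairs:
            continue
        if mate == 1 and (rid, 2) in by_read:
            # records may repeat an alignment across joint placements; dedupe
            a1 = sorted(dict.fromkeys(by_read[(rid, 1)]["alns"]),
                        key=lambda a: (a.seq_name, a.start, a.strand))
            a2 = sorted(dict.fromkeys(by_read[(rid, 2)]["alns"]),
                        key=lambda a: (a.seq_name, a.start, a.strand))
            pairs = pair_alignments(a1, a2, insert_range)
            seen_pairs.add((rid, 2))
            if pairs:
                units.append(ReadUnit(rid, pairs, {1: index[(rid, 1)], 2: index[(rid, 2)]}))
                continue
            units.append(ReadUnit(rid, [PairPlacement(a, None) for a in a1], {1: index[(rid, 1)]}))
            units.append(ReadUnit(rid, [PairPlacement(None, a) for a in a2], {2: index[(rid, 2)]}))
        else:
            alns = sorted(dict.fromkeys(by_read[(rid, mate)]["alns"]),
                          key=lambda a: (a.seq_name, a.start, a.strand))
            if mate == 2:
                units.append(ReadUnit(rid, [PairPlacement(None, a) for a in alns],
                                      {2: index[(rid, mate)]}))
            else:
                units.append(ReadUnit(rid, [PairPlacement(a, None) for a in alns],
                                      {mate or 1: index[(rid, mate)]}))
    return AlignmentSet(units, k if k is not None else 0, reads=reads)
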