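"""Exhaustive ungapped k-mismatch alignment and SAM export.

The enumerator returns *every* placement of a read on either strand whose
Hamming distance to the reference is at most k, in deterministic order
(sequence name, start, strand). Internally it uses a pigeonhole seed index
(any placement with <= k mismatches contains at least one exact segment
among k+1 read segments) with full vectorized verification, so the search
is exact; a naive full-scan path is kept for cross-checking.

'N' in either the genome or the read counts as a mismatch.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from ._seq import encode, revcomp
from .simulate import ReadSet, ReferenceGenome


@dataclass(frozen=True)
class Alignment:
    """One ungapped placement of a read (or mate) on the reference."""

    read_id: str
    mate: int                 # 1/2 for PE mates, 0 for SE
    seq_name: str
    start: int                # 0-based
    strand: str               # "+" | "-"
    mismatches: int
    mismatch_offsets: tuple[int, ...]  # read coordinates (sequencing order)
    read_len: int
    paired: bool = False
    mate_start: int | None = None

    @property
    def end(self) -> int:
        return self.start + self.read_len


@dataclass
class PairPlacement:
    """A joint placement of a read unit: both mates, or a single mate (SE)."""

    a1: Alignment | None
    a2: Alignment | None

    @property
    def mismatches(self) -> int:
        return sum(a.mismatches for a in (self.a1, self.a2) if a is not None)

    def alignments(self):
        return [a for a in (self.a1, self.a2) if a is not None]


@dataclass
class ReadUnit:
    """A read pair (or rescued singleton) with its candidate joint placements."""

    read_id: str
    placements: list[PairPlacement]
    # indices into the originating ReadSet for mate 1 / mate 2 (or the single read)
    read_indices: dict[int, int] = field(default_factory=dict)


@dataclass
class AlignmentSet:
    """All candidate placements per read unit, plus the parameters used."""

    units: list[ReadUnit]
    k: int
    reads: ReadSet | None = None
    d_cap: int | None = None


def _seed_index(genome: ReferenceGenome, name: str, seg: int):
    """Sorted rolling-hash index of all seg-mers of one sequence (cached)."""
    cache = genome._caches.setdefault("seed_index", {})
    key = (name, seg)
    if key in cache:
        return cache[key]
    g = genome.encoded(name).astype(np.int64)
    npos = len(g) - seg + 1
    if npos <= 0:
        cache[key] = None
        return None
    powers = 5 ** np.arange(seg - 1, -1, -1, dtype=np.int64)
    win = sliding_window_view(g, seg)
    hashes = win @ powers
    order = np.argsort(hashes, kind="stable").astype(np.int64)
    cache[key] = (hashes[order], order, powers)
    return cache[key]


def _windows(genome: ReferenceGenome, name: str, read_len: int):
    cache = genome._caches.setdefault("windows", {})
    key = (name, read_len)
    if key not in cache:
        cache[key] = sliding_window_view(genome.encoded(name), read_len)
    return cache[key]


def _candidate_starts(genome: ReferenceGenome, name: str, read: np.ndarray, k: int):
    """Pigeonhole candidate start positions for one oriented read."""
    L = len(read)
    seg = L // (k + 1)
    if seg < 4:  # short segments degenerate; fall back to scanning everything
        return np.arange(max(len(genome.encoded(name)) - L + 1, 0))
    idx = _seed_index(genome, name, seg)
    if idx is None:
        return np.empty(0, dtype=np.int64)
    sorted_hashes, order, powers = idx
    glen = len(genome.encoded(name))
    cands = []
    for i in range(k + 1):
        off = i * seg
        piece = read[off:off + seg].astype(np.int64)
        if (piece == 4).any():  # seeds containing N can never match exactly
            continue
        h = int(piece @ powers)
        lo = np.searchsorted(sorted_hashes, h, side="left")
        hi = np.searchsorted(sorted_hashes, h, side="right")
        if hi > lo:
            cands.append(order[lo:hi] - off)
    if not cands:
        return np.empty(0, dtype=np.int64)
    starts = np.unique(np.concatenate(cands))
    return starts[(starts >= 0) & (starts <= glen - L)]


def _verify(genome: ReferenceGenome, name: str, read: np.ndarray,
            starts: np.ndarray, k: int):
    """Keep candidate starts with Hamming distance <= k; return (starts, mm-matrix)."""
    if len(starts) == 0:
        return starts, None
    win = _windows(genome, name, len(read))[starts]
    mm = (win != read) | (win == 4) | (read == 4)
    nmm = mm.sum(axis=1)
    ok = nmm <= k
    return starts[ok], mm[ok]


def enumerate_alignments(read_seq, genome: ReferenceGenome, k: int,
                         read_id: str = "read", mate: int = 0,
                         exhaustive_scan: bool = False) -> list[Alignment]:
    """Enumerate every ungapped placement with Hamming distance <= k.

    ``read_seq`` may be a string or an encoded uint8 array. With
    ``exhaustive_scan`` the pigeonhole index is bypassed and every window is
    checked directly (slow; used for cross-validation).
    """
    if k < 0:
        raise ValueError("k must be non-negative")
    fwd = encode(read_seq) if isinstance(read_seq, str) else np.asarray(read_seq, dtype=np.uint8)
    if len(fwd) == 0:
        raise ValueError("empty read")
    rev = revcomp(fwd)
    out: list[Alignment] = []
    L = len(fwd)
    for name in genome.names:
        glen = len(genome.encoded(name))
        if L > glen:
            raise ValueError(f"read longer than sequence {name!r}")
        for strand, oriented in (("+", fwd), ("-", rev)):
            if exhaustive_scan:
                starts = np.arange(glen - L + 1)
            else:
                starts = _candidate_starts(genome, name, oriented, k)
            starts, mm = _verify(genome, name, oriented, starts, k)
            for row, s in enumerate(starts):
                offs = np.flatnonzero(mm[row])
                if strand == "-":  # convert genome offsets to read coordinates
                    offs = (L - 1) - offs[::-1]
                out.append(Alignment(read_id, mate, name, int(s), strand,
                                     len(offs), tuple(int(o) for o in offs), L))
    out.sort(key=lambda a: (a.seq_name, a.start, a.strand))
    return out


def pair_alignments(alns1: list[Alignment], alns2: list[Alignment],
                    insert_range: tuple[int, int]) -> list[PairPlacement]:
    """Combine mate placements into valid pairs.

    A pair is valid when the mates sit on the same sequence, on opposite
    strands in forward--reverse orientation, with an outer span inside
    ``insert_range``. Returns the list of valid joint placements (possibly
    empty; the caller falls back to single-end treatment).
    """
    lo, hi = insert_range
    if lo > hi:
        raise ValueError("insert_range min exceeds max")
    pairs: list[PairPlacement] = []
    for a1 in alns1:
        for a2 in alns2:
            if a1.seq_name != a2.seq_name or a1.strand == a2.strand:
                continue
            left, right = (a1, a2) if a1.strand == "+" else (a2, a1)
            if right.start < left.start:
                continue
            span = right.end - left.start
            if lo <= span <= hi:
                p1 = replace(a1, paired=True, mate_start=a2.start)
                p2 = replace(a2, paired=True, mate_start=a1.start)
                pairs.append(PairPlacement(p1, p2))
    pairs.sort(key=lambda p: (p.a1.seq_name, p.a1.start, p.a2.start))
    return pairs


def align_reads(reads: ReadSet, genome: ReferenceGenome, k: int,
                insert_range: tuple[int, int] = (150, 300)) -> AlignmentSet:
    """Align a simulated read set: pairs first, then singleton rescue.

    Mates are enumerated independently; mates forming at least one valid
    pair become a paired unit whose placements are the valid pairs. Mates of
    pairs with no valid joint placement are rescued as single-end units.
    """
    units: list[ReadUnit] = []
    n = len(reads)
    i = 0
    while i < n:
        rid = reads.ids[i]
        if i + 1 < n and reads.ids[i + 1] == rid and reads.mate[i] == 1 and reads.mate[i + 1] == 2:
            a1 = enumerate_alignments(reads.seqs[i], genome, k, rid, 1)
            a2 = enumerate_alignments(reads.seqs[i + 1], genome, k, rid, 2)
            pairs = pair_alignments(a1, a2, insert_range)
            if pairs:
                units.append(ReadUnit(rid, pairs, {1: i, 2: i + 1}))
            else:  # rescue each mate as SE
                if a1:
                    units.append(ReadUnit(rid, [PairPlacement(a, None) for a in a1], {1: i}))
                if a2:
                    units.append(ReadUnit(rid, [PairPlacement(None, a) for a in a2], {2: i + 1}))
            i += 2
        else:
            alns = enumerate_alignments(reads.seqs[i], genome, k, rid, int(reads.mate[i]))
            if alns:
                units.append(ReadUnit(rid, [PairPlacement(a, None) for a in alns],
                                      {int(reads.mate[i]) or 1: i}))
            i += 1
    return AlignmentSet(units, k, reads=reads)


# ---------------------------------------------------------------------------
# SAM export

def _md_tag(genome: ReferenceGenome, aln: Alignment) -> str:
    ref = genome.encoded(aln.seq_name)[aln.start:aln.end]
    # mismatch offsets are in read coordinates; convert to genome-forward offsets
    if aln.strand == "-":
        goffs = sorted((aln.read_len - 1) - o for o in aln.mismatch_offsets)
    else:
        goffs = sorted(aln.mismatch_offsets)
    md = []
    prev = 0
    from ._seq import ALPHABET
    for o in goffs:
        md.append(str(o - prev))
        md.append(ALPHABET[ref[o]])
        prev = o + 1
    md.append(str(aln.read_len - prev))
    return "".join(md)


def write_sam(alignment_sets: AlignmentSet, genome: ReferenceGenome, path) -> None:
    """Write all placements to a SAM file (FLAG/POS per the standard, NM/MD tags).

    Placements beyond the first of a unit are flagged secondary so standard
    tools treat the file sensibly; this module's reader accepts either.
    """
    import pysam

    header = {
        "HD": {"VN": "1.6", "SO": "unsorted"},
        "SQ": [{"SN": n, "LN": len(genome[n])} for n in genome.names],
    }
    reads = alignment_sets.reads
    tid = {n: i for i, n in enumerate(genome.names)}
    with pysam.AlignmentFile(str(path), "w", header=header) as out:
        for unit in alignment_sets.units:
            for pi, placement in enumerate(unit.placements):
                for aln in placement.alignments():
                    seg = pysam.AlignedSegment(out.header)
                    seg.query_name = unit.read_id
                    idx = unit.read_indices.get(aln.mate or 1)
                    if reads is not None and idx is not None:
                        seq = reads.seqs[idx]
                        qual = reads.quals[idx]
                    else:
                        raise ValueError("alignment set lacks read sequences")
                    if aln.strand == "-":
                        seq = revcomp(seq)
                        qual = qual[::-1]
                    from ._seq import decode
                    seg.query_sequence = decode(seq)
                    seg.query_qualities = pysam.qualitystring_to_array(
                        "".join(chr(int(q) + 33) for q in qual))
                    seg.reference_id = tid[aln.seq_name]
                    seg.reference_start = aln.start
                    seg.cigarstring = f"{aln.read_len}M"
                    seg.mapping_quality = 255
                    flag = 0
                    if aln.strand == "-":
                        flag |= 0x10
                    if aln.mate in (1, 2):
                        flag |= 0x1 | (0x40 if aln.mate == 1 else 0x80)
                    if aln.paired:
                        flag |= 0x2
                        other = placement.a2 if aln.mate == 1 else placement.a1
                        if other is not None:
                            seg.next_reference_id = tid[other.seq_name]
                            seg.next_reference_start = other.start
                            if other.strand == "-":
                                flag |= 0x20
                            left = min(aln.start, other.start)
                            right = max(aln.end, other.end)
                            tlen = right - left
                            seg.template_length = tlen if aln.start <= other.start else -tlen
                    elif aln.mate in (1, 2):
                        flag |= 0x8  # mate unmapped (singleton rescue)
                    if pi > 0:
                        flag |= 0x100
                    seg.flag = flag
                    seg.set_tag("NM", aln.mismatches)
                    seg.set_tag("MD", _md_tag(genome, aln))
                    out.write(seg)
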