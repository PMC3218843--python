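"""Truth-based benchmarking of SNP call sets.

Confusion classification uses five categories: TP (significant call at a
truth locus with the exact diploid genotype), TPFG ("true position, false
genotype": significant call at a truth locus with the wrong genotype), FP
(significant call elsewhere), FN (missed truth locus), TN (the remaining
assayed loci). Two printed variants of the sensitivity/accuracy formulas
are in circulation — one counting TPFG as partial credit, one not — so
both are provided behind a flag.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

from scipy.stats import binom


@dataclass
class ConfusionCounts:
    tp: int = 0
    tn: int = 0
    fp: int = 0
    fn: int = 0
    tpfg: int = 0

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn + self.tpfg


@dataclass
class MetricsReport:
    variant: str
    tpr: float
    fnr: float
    fpr: float
    fdr: float
    accuracy: float
    transformed_accuracy: float   # coefficient 10 (phred-like)
    transformed_accuracy_log: float  # coefficient 1


def _norm_gt(g: str) -> str:
    return "".join(sorted(g.upper()))


def classify_calls(calls, truth, assayed_loci) -> ConfusionCounts:
    """Tally the confusion categories for one call set.

    ``calls``: iterable of (seq, pos0, genotype) significant calls;
    ``truth``: iterable of TruthEntry or (seq, pos0, genotype) tuples;
    ``assayed_loci``: iterable of (seq, pos0) loci with read depth > 0
    (the universe over which TN/FN are counted).
    """
    truth_map = {}
    for t in truth:
        if hasattr(t, "seq_name"):
            truth_map[(t.seq_name, t.pos)] = _norm_gt(t.genotype)
        else:
            truth_map[(t[0], int(t[1]))] = _norm_gt(t[2])
    assayed = set(assayed_loci)
    counts = ConfusionCounts()
    called = set()
    for seq, pos, g in calls:
        key = (seq, int(pos))
        if key not in assayed:
            raise ValueError(f"call at unassayed locus {key}")
        called.add(key)
        if key in truth_map:
            if _norm_gt(g) == truth_map[key]:
                counts.tp += 1
            else:
                counts.tpfg += 1
        else:
            counts.fp += 1
    for key in truth_map:
        if key in assayed and key not in called:
            counts.fn += 1
    counts.tn = len(assayed) - counts.tp - counts.tpfg - counts.fp - counts.fn
    return counts


def _ratio(num: float, den: float) -> float:
    return num / den if den > 0 else float("nan")


def metrics(counts: ConfusionCounts, variant: str = "methods",
            max_transform: float = 255.0) -> MetricsReport:
    """All performance rates for one confusion tally.

    ``variant="methods"`` uses TPR = TP/(TP+FN) and
    accuracy = (TP+TN)/total; ``variant="figure"`` counts TPFG as a
    detection: TPR = (TP+TPFG)/(TP+TPFG+FN), accuracy = (TP+TPFG+TN)/total.
    FDR = (FP+TPFG)/(TP+FP+TPFG) and FPR = (FP+TPFG)/(FP+TPFG+TN) in both.
    Undefined (0/0) rates are reported as NaN.
    """
    if variant not in ("methods", "figure"):
        raise ValueError("variant must be 'methods' or 'figure'")
    c = counts
    if variant == "methods":
        tpr = _ratio(c.tp, c.tp + c.fn)
        acc = _ratio(c.tp + c.tn, c.total)
    else:
        tpr = _ratio(c.tp + c.tpfg, c.tp + c.tpfg + c.fn)
        acc = _ratio(c.tp + c.tpfg + c.tn, c.total)
    fnr = 1.0 - tpr if not math.isnan(tpr) else float("nan")
    fpr = _ratio(c.fp + c.tpfg, c.fp + c.tpfg + c.tn)
    fdr = _ratio(c.fp + c.tpfg, c.tp + c.fp + c.tpfg)
    t10 = transform_accuracy(acc, 10, max_transform) if not math.isnan(acc) else float("nan")
    t1 = transform_accuracy(acc, 1, max_transform) if not math.isnan(acc) else float("nan")
    return MetricsReport(variant, tpr, fnr, fpr, fdr, acc, t10, t1)


def transform_accuracy(acc: float, coefficient: float = 10,
                       max_value: float = 255.0) -> float:
    """Phred-like accuracy transform: -coefficient * log10(1 - acc)."""
    if not 0.0 <= acc <= 1.0:
        raise ValueError("accuracy outside [0, 1]")
    if acc >= 1.0:
        return max_value
    return min(max_value, -coefficient * math.log10(1.0 - acc))


def inverse_transform_accuracy(value: float, coefficient: float = 10) -> float:
    return 1.0 - 10.0 ** (-value / coefficient)


@dataclass
class Concordance:
    matching: int
    discordant: int
    a_specific: int
    b_specific: int

    @property
    def rate(self) -> float:
        den = self.matching + self.discordant
        return self.matching / den if den > 0 else float("nan")


def concordance(calls_a, calls_b) -> Concordance:
    """Agreement between two call sets over a shared coordinate space.

    Matching: same locus and genotype; discordant: same locus, different
    genotype; the rest are set-specific loci.
    """
    a = {(s, int(p)): _norm_gt(g) for s, p, g in calls_a}
    b = {(s, int(p)): _norm_gt(g) for s, p, g in calls_b}
    shared = a.keys() & b.keys()
    matching = sum(1 for k in shared if a[k] == b[k])
    return Concordance(matching, len(shared) - matching,
                       len(a.keys() - shared), len(b.keys() - shared))


def expected_discard_fraction(read_len: int, per_base_error: float, k: int) -> float:
    """Chance a read exceeds the mismatch bound from base-call errors alone.

    P[Binomial(read_len, per_base_error) > k] — the closed-form expectation
    for reads lost to the aligner's k-mismatch cutoff absent any true
    divergence.
    """
    if read_len < 0 or k < 0 or not 0.0 <= per_base_error <= 1.0:
        raise ValueError("invalid arguments")
    if per_base_error == 0.0:
        return 0.0
    return float(binom.sf(k, read_len, per_base_error))


def recommend_k(read_len: int, e_max: float, divergence: float) -> tuple[float, int]:
    """Mismatch budget k ~ 1/|r| + e_max + divergence, per base of read.

    Returns (per-base proportion, integer k = ceil(proportion * read_len));
    warns when the proportion exceeds the 0.03 mismatches-per-base rule of
    thumb, beyond which spurious alignments escalate.
    """
    if read_len <= 0:
        raise ValueError("read_len must be positive")
    if e_max < 0 or divergence < 0:
        raise ValueError("rates must be non-negative")
    proportion = 1.0 / read_len + e_max + divergence
    k = math.ceil(proportion * read_len)
    if proportion > 0.03:
        warnings.warn(
            f"recommended mismatch proportion {proportion:.4f} exceeds 0.03 "
            "per base; expect elevated spurious alignment", stacklevel=2)
    return proportion, k
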