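"""Bayesian diploid genotyping from pileups of multiply mapped reads.

Per-locus posteriors over the ten unordered diploid genotypes are computed
from per-read likelihoods that mix a global binomial error model with a
read-specific quality-score model, marginalizing each read over its d+1
candidate template placements. Loci linked through shared multi-mapped
reads compete for a variant signal: the posterior marginalizes over the
restricted multi-locus configuration space in which at most one of the
linked paralogous loci deviates from the reference (a variant read then
either supports a SNP at the focal locus or is explained by a SNP at one
of its paralogs). This is what keeps a true SNP in a duplicated region
from being called twice, once at each copy.

This module holds the readable per-column implementation and the scalar
operations; :mod:`multisnp._engine` computes identical quantities
vectorized for whole read maps.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .readmap import PileupColumn

GENOTYPES: tuple[str, ...] = (
    "AA", "AC", "AG", "AT", "CC", "CG", "CT", "GG", "GT", "TT")
_BASES = "ACGT"

LIKELIHOOD_FLOOR = 1e-300
# a Phred score of 0 claims no information; cap the error probability where
# all four bases become equally likely (1-p = p/3 = 1/4)
_P_ERR_MAX = 0.75


@dataclass
class ModelParams:
    """Tunable parameters of the genotyping model.

    e : global per-base sequencing error rate for the binomial component.
    lam : mixture weight, placed on the read-specific quality-score model by
        default; ``lambda_on_read=False`` moves it to the global binomial
        model instead.
    theta : population heterozygosity driving the genotype prior.
    q_threshold : minimum stringency Q for a significant SNP call.
    max_q : cap applied to Q (posterior mass can reach 1 numerically).
    degeneracy_correction : raise the effective threshold by 10*log10(m)
        at loci linked to m-1 other loci through shared multi-mapped reads.
    max_linked_loci : reads with more placements than this contribute only
        inert background mass, not paralog-configuration candidates. A read
        spread over that many loci is ~uninformative about any one of them
        (its per-locus evidence scales as 1/d), and enumerating its
        configurations would cost O(d) per covered locus.
    """

    e: float = 0.0003
    lam: float = 0.67
    theta: float = 0.001
    q_threshold: float = 40.0
    max_q: float = 255.0
    degeneracy_correction: bool = True
    lambda_on_read: bool = True
    max_linked_loci: int = 64

    def __post_init__(self):
        if not 0.0 < self.e < 1.0:
            raise ValueError("e must be in (0, 1)")
        if not 0.0 <= self.lam <= 1.0:
            raise ValueError("lambda must be in [0, 1]")
        if not 0.0 <= self.theta < 1.0:
            raise ValueError("theta must be in [0, 1)")
        if 1.0 - self.theta - self.theta ** 2 <= 0.0:
            raise ValueError("theta too large: hom-ref prior mass non-positive")

    @property
    def read_weight(self) -> float:
        return self.lam if self.lambda_on_read else 1.0 - self.lam


def p_bin(n: int, kobs: int, e: float) -> float:
    """Binomial point mass: probability of exactly ``kobs`` errors in ``n`` bases."""
    if not 0.0 < e < 1.0:
        raise ValueError("e must be in (0, 1)")
    if not 0 <= kobs <= n:
        raise ValueError("mismatch count outside [0, n]")
    return math.comb(n, kobs) * e ** kobs * (1.0 - e) ** (n - kobs)


def phred_to_prob(q) -> np.ndarray:
    """Per-base error probability from Phred, capped at the uninformative limit."""
    p = np.power(10.0, -np.asarray(q, dtype=float) / 10.0)
    return np.minimum(p, _P_ERR_MAX)


def p_read(qualities, mismatch_offsets) -> float:
    """Read-specific template probability from per-base qualities.

    Matching positions contribute (1 - p_i); mismatching positions p_i / 3
    (substitution errors spread uniformly over the three wrong bases).
    """
    q = np.asarray(qualities, dtype=float)
    if np.any(q < 0):
        raise ValueError("negative quality score")
    p = phred_to_prob(q)
    offs = np.asarray(list(mismatch_offsets), dtype=int)
    if len(offs) and (offs.min() < 0 or offs.max() >= len(q)):
        raise ValueError("mismatch offset outside the read")
    is_mm = np.zeros(len(q), dtype=bool)
    is_mm[offs] = True
    return float(np.prod(np.where(is_mm, p / 3.0, 1.0 - p)))


def read_template_prob(qualities, mismatch_offsets, params: ModelParams) -> float:
    """Mixture likelihood of a read given one hypothesized template.

    ``read_weight * P_read + (1 - read_weight) * P_bin`` with P_bin evaluated
    at the observed mismatch count.
    """
    n = len(qualities)
    w = params.read_weight
    return (w * p_read(qualities, mismatch_offsets)
            + (1.0 - w) * p_bin(n, len(tuple(mismatch_offsets)), params.e))


def genotype_prior(ref_base: str, theta: float) -> dict[str, float]:
    """Per-locus prior over the ten genotypes given the reference base.

    Class masses: hom-ref 1 - t - t^2; single-alternative heterozygotes t/2;
    homozygous alternatives t/2; double-alternative heterozygotes t^2
    (t = theta). Mass within a class is split uniformly over its three
    genotypes, so the distribution sums to 1 exactly.
    """
    hom_ref = 1.0 - theta - theta ** 2
    if hom_ref <= 0.0:
        raise ValueError("theta too large: hom-ref prior mass non-positive")
    if ref_base not in _BASES:
        raise ValueError(f"reference base {ref_base!r} not in ACGT")
    prior = {}
    for g in GENOTYPES:
        n_ref = (g[0] == ref_base) + (g[1] == ref_base)
        if n_ref == 2:
            prior[g] = hom_ref
        elif n_ref == 1:
            prior[g] = theta / 6.0
        elif g[0] == g[1]:
            prior[g] = theta / 6.0
        else:
            prior[g] = theta ** 2 / 3.0
    return prior


def q_score(p_map: float, max_q: float = 255.0) -> float:
    """Stringency Q = -10 log10(1 - P), capped at ``max_q``."""
    if not 0.0 <= p_map <= 1.0:
        raise ValueError("posterior probability outside [0, 1]")
    if p_map >= 1.0:
        return max_q
    return min(max_q, -10.0 * math.log10(1.0 - p_map))


@dataclass
class GenotypePosterior:
    """Posterior over the ten diploid genotypes at one locus."""

    seq_name: str
    locus: int
    ref_base: str
    posterior: dict[str, float]
    map_genotype: str
    q: float
    depth: int
    mean_multiplicity: float
    degeneracy: float          # sum of d_i over covering reads / depth
    n_linked: int              # distinct paralogous loci linked via shared reads
    vaf: float                 # non-reference fraction among covering bases
    no_call: bool = False


@dataclass
class VariantCall:
    posterior: GenotypePosterior
    significant: bool
    effective_threshold: float


def _map_genotype(log_post: dict[str, float], ref_base: str) -> str:
    """MAP genotype; exact ties resolve to hom-ref, then lexicographically."""
    best = max(log_post.values())
    hom_ref = ref_base * 2
    if hom_ref in log_post and log_post[hom_ref] == best:
        return hom_ref
    for g in GENOTYPES:  # lexicographic order
        if log_post[g] == best:
            return g
    raise AssertionError("unreachable")


def _entry_allele_probs(entry, params: ModelParams):
    """(L_match, L_mismatch) for substituting an allele at the entry's offset.

    L_match applies when the hypothesized allele equals the called base,
    L_mismatch otherwise; both exclude/include the focal position in the
    alignment's mismatch set accordingly.
    """
    offs_other = tuple(o for o in entry.mismatch_offsets if o != entry.offset)
    l_match = read_template_prob(entry.quals, offs_other, params)
    l_mis = read_template_prob(entry.quals, offs_other + (entry.offset,), params)
    return l_match, l_mis


def _context_terms(entry, params: ModelParams):
    """Background mass and per-linked-locus substitution terms for one entry.

    Returns ``(background_sum, groups)`` with
    ``groups = {(seq, locus): (ref_base, T_ref_sum, [(C_match, C_mis, count)])}``.
    Identical placements are aggregated (probabilities computed once per
    distinct context, weighted by multiplicity). Entries whose read exceeds
    ``max_linked_loci`` placements return empty groups: their placements add
    background mass only.
    """
    from collections import Counter

    if entry.multiplicity > params.max_linked_loci + 1:
        # locus identity is irrelevant for inert background; key by content
        counted = Counter((tuple(ctx.mismatch_offsets),) for ctx in entry.others)
        background = sum(count * read_template_prob(entry.quals, offs, params)
                         for (offs,), count in counted.items())
        return background, {}

    counted = Counter(
        (ctx.seq_name, ctx.locus, ctx.ref_base, tuple(ctx.mismatch_offsets), ctx.offset)
        for ctx in entry.others)
    out: dict[tuple[str, int], list] = {}
    background = 0.0
    for (seq, locus, rb, offs, off), count in counted.items():
        t_ref = count * read_template_prob(entry.quals, offs, params)
        background += t_ref
        offs_other = tuple(o for o in offs if o != off)
        c_match = read_template_prob(entry.quals, offs_other, params)
        c_mis = read_template_prob(entry.quals, offs_other + (off,), params)
        key = (seq, locus)
        if key in out:
            prev_rb, prev_t, prev_subs = out[key]
            out[key] = (prev_rb, prev_t + t_ref, prev_subs + [(c_match, c_mis, count)])
        else:
            out[key] = (rb, t_ref, [(c_match, c_mis, count)])
    return background, out


def read_likelihood(entry, genotype: str, params: ModelParams) -> float:
    """Likelihood of one pileup entry under a focal genotype.

    ``(1/(d+1)) * [ 1/2 P(r|s(x)) + 1/2 P(r|s(y)) + sum_j P(r|s_j, ref) ]``
    — the read is equally likely to have been templated by any of its d+1
    placements; the focal placement averages the two haplotype alleles and
    the other placements carry the reference base (the configuration with
    the variant, if any, at the focal locus).
    """
    if entry.multiplicity < 1:
        raise ValueError("multiplicity must be >= 1")
    l_match, l_mis = _entry_allele_probs(entry, params)
    x, y = genotype[0], genotype[1]
    lx = l_match if x == entry.base else l_mis
    ly = l_match if y == entry.base else l_mis
    background, _ = _context_terms(entry, params)
    return (0.5 * lx + 0.5 * ly + background) / entry.multiplicity


def locus_posterior(column: PileupColumn, params: ModelParams) -> GenotypePosterior:
    """Posterior over the ten genotypes at one pileup column.

    Marginalizes over the assumption-restricted configuration space: either
    every linked locus matches the reference (the focal locus carries any of
    the ten genotypes), or the focal locus is hom-ref and exactly one linked
    paralogous locus carries a variant. The background-configuration mixture
    is normalized so that an uninformative column returns the per-locus
    prior exactly. Zero depth returns the prior.
    """
    ref = column.ref_base
    if ref not in _BASES:
        # unmodelled reference base: uniform posterior, flagged no-call
        u = {g: 0.1 for g in GENOTYPES}
        return GenotypePosterior(column.seq_name, column.locus, ref, u,
                                 GENOTYPES[0], 0.0, column.depth, 0.0, 0.0, 1,
                                 0.0, no_call=True)
    prior = genotype_prior(ref, params.theta)
    if column.depth == 0:
        gp = dict(prior)
        return GenotypePosterior(column.seq_name, column.locus, ref, gp,
                                 ref * 2, q_score(gp[ref * 2], params.max_q),
                                 0, 0.0, 0.0, 1, 0.0)

    hom_ref = ref * 2
    floor = LIKELIHOOD_FLOOR
    # per-entry building blocks
    entry_data = []
    linked: dict[tuple[str, int], str] = {}
    for e in column.entries:
        l_match, l_mis = _entry_allele_probs(e, params)
        background, ctxs = _context_terms(e, params)
        entry_data.append((e, l_match, l_mis, background, ctxs))
        for key, (rb, _, _) in ctxs.items():
            linked.setdefault(key, rb)

    def loglik_focal(genotype: str) -> float:
        total = 0.0
        for e, l_match, l_mis, background, _ in entry_data:
            lx = l_match if genotype[0] == e.base else l_mis
            ly = l_match if genotype[1] == e.base else l_mis
            total += math.log(max((0.5 * lx + 0.5 * ly + background) / e.multiplicity,
                                  floor))
        return total

    ll = {g: loglik_focal(g) for g in GENOTYPES}

    # configurations with the variant at a linked paralogous locus
    t_mass = params.theta + params.theta ** 2  # prior mass off hom-ref per locus
    m = len(linked)
    adj = 0.0
    if m > 0 and t_mass > 0.0:
        terms = [math.log(1.0 - t_mass) * m]  # all-reference configuration
        base_w = math.log(1.0 - t_mass) * (m - 1)
        for key, rb in linked.items():
            if rb not in _BASES:
                continue
            pj = genotype_prior(rb, params.theta)
            for g in GENOTYPES:
                if g == rb * 2:
                    continue
                # delta log-likelihood of substituting genotype g at this locus
                dll = 0.0
                for e, l_match, l_mis, background, ctxs in entry_data:
                    if key not in ctxs:
                        continue
                    _, t_ref, subs = ctxs[key]
                    t_new = 0.0
                    for c_match, c_mis, count in subs:
                        cu = c_match if g[0] == e.base else c_mis
                        cv = c_match if g[1] == e.base else c_mis
                        t_new += count * (0.5 * cu + 0.5 * cv)
                    lx = l_match if e.base == ref else l_mis  # focal is hom-ref
                    t0 = lx + background
                    dll += (math.log(max(t0 - t_ref + t_new, floor))
                            - math.log(max(t0, floor)))
                terms.append(base_w + math.log(pj[g]) + dll)
        log_z = math.log((1.0 - t_mass) ** (m - 1)
                         * ((1.0 - t_mass) + m * t_mass))
        mx = max(terms)
        adj = mx + math.log(sum(math.exp(t - mx) for t in terms)) - log_z

    log_post = {}
    for g in GENOTYPES:
        lp = math.log(prior[g]) + ll[g]
        if g == hom_ref:
            lp += adj
        log_post[g] = lp
    mx = max(log_post.values())
    if not math.isfinite(mx):
        u = {g: 0.1 for g in GENOTYPES}
        return GenotypePosterior(column.seq_name, column.locus, ref, u, hom_ref,
                                 0.0, column.depth, 0.0, 0.0, m + 1, 0.0,
                                 no_call=True)
    weights = {g: math.exp(lp - mx) for g, lp in log_post.items()}
    z = sum(weights.values())
    post = {g: w / z for g, w in weights.items()}

    depth = column.depth
    mult = [e.multiplicity for e in column.entries]
    vaf = sum(1 for e in column.entries if e.base != ref) / depth
    map_g = _map_genotype(log_post, ref)
    return GenotypePosterior(
        column.seq_name, column.locus, ref, post, map_g,
        q_score(post[map_g], params.max_q), depth,
        float(np.mean(mult)), float(sum(d - 1 for d in mult)) / depth,
        m + 1, vaf)


def effective_threshold(q_threshold: float, n_linked: int,
                        degeneracy_correction: bool = True) -> float:
    """Bonferroni-style stringency on the phred scale: + 10 log10(m)."""
    if not degeneracy_correction or n_linked <= 1:
        return q_threshold
    return q_threshold + 10.0 * math.log10(n_linked)


def call_variants(posteriors, params: ModelParams) -> list[VariantCall]:
    """Flag significant SNPs: MAP differs from hom-ref and Q clears the
    (degeneracy-corrected) stringency threshold."""
    calls = []
    for gp in posteriors:
        q_eff = effective_threshold(params.q_threshold, gp.n_linked,
                                    params.degeneracy_correction)
        sig = (not gp.no_call
               and gp.map_genotype != gp.ref_base * 2
               and gp.q >= q_eff)
        calls.append(VariantCall(gp, sig, q_eff))
    return calls


def information_diagnostic(n: float, d: float, p_xy: float, p_alt: float,
                           c: float = 1.0) -> float:
    """Exact log posterior-odds under the homogeneous-read simplification.

    With n identically behaving reads, each aligning to d other loci with
    common background term c and genotype-dependent likelihoods p_xy vs
    p_alt (equal priors), the log-odds is ``n * log((p_xy + d c)/(p_alt + d c))``:
    linear in depth, washed out as d grows.
    """
    if not (0.0 < p_xy <= 1.0 and 0.0 < p_alt <= 1.0):
        raise ValueError("likelihood terms must be in (0, 1]")
    return n * math.log((p_xy + d * c) / (p_alt + d * c))
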