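"""Shared test utilities: an independent enumeration oracle and a
one-replicate benchmark runner.

The oracle computes per-locus genotype posteriors by explicit string-level
enumeration — brute-force placement scanning, haplotype construction per
multi-locus configuration, per-base template probabilities — sharing no
code with the package's likelihood/pileup machinery.
"""

from __future__ import annotations

import math

from multisnp.align import align_reads
from multisnp.evaluate import classify_calls, metrics
from multisnp.genotype import GENOTYPES, ModelParams
from multisnp.model import MultiMapGenotyper
from multisnp.readmap import MappingStrategy, apply_strategy
from multisnp.simulate import TemplateSpec, build_template, inject_variation, sample_pe_reads

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def _revcomp(s: str) -> str:
    return "".join(_COMP[c] for c in reversed(s))


def _placements(read: str, genome: str, k: int):
    """All (start, strand) with Hamming distance <= k, both strands."""
    out = []
    L = len(read)
    rc = _revcomp(read)
    for strand, r in (("+", read), ("-", rc)):
        for s in range(len(genome) - L + 1):
            window = genome[s:s + L]
            mm = sum(1 for a, b in zip(r, window) if a != b or a == "N" or b == "N")
            if mm <= k:
                out.append((s, strand))
    return out


def _template_prob(read: str, quals, template: str, params: ModelParams) -> float:
    """Mixture likelihood of a read given one concrete template string."""
    pr = 1.0
    mm = 0
    n = len(read)
    for i in range(n):
        p = min(10.0 ** (-quals[i] / 10.0), 0.75)
        if read[i] == template[i] and read[i] != "N" and template[i] != "N":
            pr *= 1.0 - p
        else:
            pr *= p / 3.0
            mm += 1
    w = params.read_weight
    p_bin = math.comb(n, mm) * params.e ** mm * (1.0 - params.e) ** (n - mm)
    return w * pr + (1.0 - w) * p_bin


def oracle_posterior(genome: str, reads, focal: int, paralog_loci, k: int,
                     params: ModelParams) -> dict[str, float]:
    """Posterior at ``focal`` by exhaustive configuration enumeration.

    ``reads``: list of (sequence, quality list). Configurations: every
    linked locus matches the reference, except at most one of
    {focal} + paralog_loci carries a non-reference diploid genotype. Each
    configuration's likelihood is the product over reads of the mean over
    placements and haplotypes of the string-level template probability.
    The background mixture inside the hom-ref branch is normalized so an
    uninformative instance returns the per-locus prior.
    """
    from multisnp.genotype import genotype_prior

    placements = [_placements(r, genome, k) for r, _ in reads]

    def config_loglik(subs: dict[int, tuple[str, str]]) -> float:
        haps = []
        for h in (0, 1):
            gl = list(genome)
            for j, pair in subs.items():
                gl[j] = pair[h]
            haps.append("".join(gl))
        ll = 0.0
        for (r, q), pls in zip(reads, placements):
            total = 0.0
            for s, strand in pls:
                for hap in haps:
                    template = hap[s:s + len(r)]
                    if strand == "-":
                        template = _revcomp(template)
                    total += 0.5 * _template_prob(r, q, template, params)
            ll += math.log(max(total / len(pls), 1e-300))
        return ll

    ref_f = genome[focal]
    prior_f = genotype_prior(ref_f, params.theta)
    others = [j for j in paralog_loci if j != focal]
    t_mass = params.theta + params.theta ** 2
    m = len(others)

    log_num = {}
    for g in GENOTYPES:
        if g != ref_f * 2:
            log_num[g] = math.log(prior_f[g]) + config_loglik({focal: (g[0], g[1])})
    # hom-ref branch: all-reference plus one-SNP-at-a-paralog configurations
    terms = [m * math.log(1.0 - t_mass) + config_loglik({})]
    for j in others:
        prior_j = genotype_prior(genome[j], params.theta)
        for g in GENOTYPES:
            if g == genome[j] * 2:
                continue
            terms.append((m - 1) * math.log(1.0 - t_mass) + math.log(prior_j[g])
                         + config_loglik({j: (g[0], g[1])}))
    log_z = (m - 1) * math.log(1.0 - t_mass) + math.log((1.0 - t_mass) + m * t_mass) \
        if m > 0 else 0.0
    mx = max(terms)
    log_num[ref_f * 2] = (math.log(prior_f[ref_f * 2]) + mx
                          + math.log(sum(math.exp(t - mx) for t in terms)) - log_z)

    mx = max(log_num.values())
    weights = {g: math.exp(v - mx) for g, v in log_num.items()}
    z = sum(weights.values())
    return {g: w / z for g, w in weights.items()}


def run_replicate(seed: int, unit_length: int = 10000, copies: int = 2,
                  divergence: float = 0.05, coverage: float = 50,
                  k: int = 2, q_threshold: float = 40.0,
                  strategies=("UNI", "BEST", "ALL")):
    """Simulate one sample genome, align, and score each mapping strategy.

    Returns (truth, {strategy: (counts, figure-variant MetricsReport)}).
    """
    spec = TemplateSpec(unit_length=unit_length, copies=copies,
                        inter_copy_divergence=divergence, seed=seed)
    genome = build_template(spec)
    sample = inject_variation(genome, 0.0005, 0.0005, seed=seed + 1000)
    reads = sample_pe_reads(sample, coverage=coverage, read_len=36, seed=seed + 2000)
    alns = align_reads(reads, genome, k)
    results = {}
    for strat in strategies:
        rm = apply_strategy(alns, MappingStrategy(strat, d_cap=200))
        res = MultiMapGenotyper(rm, genome, ModelParams(q_threshold=q_threshold)).fit()
        df = res.posteriors
        calls = res.calls(q_threshold)
        counts = classify_calls(
            list(zip(calls["seq"], calls["pos"], calls["map_genotype"])),
            sample.truth, list(zip(df["seq"], df["pos"])))
        results[strat] = (counts, metrics(counts, "figure"))
    return sample.truth, results
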