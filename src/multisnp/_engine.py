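"""Vectorized whole-genome computation of the per-locus genotype posteriors.

Implements exactly the model in :mod:`multisnp.genotype` (tests assert
agreement with the per-column reference to float precision) using flat
numpy arrays: one row per (alignment, offset) pileup entry, bincount
segment sums keyed by (locus, called base), and an incremental update for
the paralog-configuration terms. Requires a uniform read length.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import genotype as gt
from ._seq import complement
from .readmap import ReadMap
from .simulate import ReferenceGenome

_FLOOR = gt.LIKELIHOOD_FLOOR


@dataclass
class PosteriorTable:
    """Columnar result of the engine: one row per covered locus."""

    frame: pd.DataFrame          # seq, pos, ref, MAP, Q, depth, ...
    log_posterior: np.ndarray    # (n_loci, 10) log posteriors (normalized)


def _prior_matrix(theta: float) -> np.ndarray:
    """(4 ref bases, 10 genotypes) prior table."""
    out = np.empty((4, 10))
    for r, base in enumerate("ACGT"):
        pri = gt.genotype_prior(base, theta)
        out[r] = [pri[g] for g in gt.GENOTYPES]
    return out


def compute_posteriors(read_map: ReadMap, genome: ReferenceGenome,
                       params: gt.ModelParams) -> PosteriorTable:
    mates = list(read_map.mate_alignments())
    names = genome.names
    seq_offset = {}
    off = 0
    for n in names:
        seq_offset[n] = off
        off += len(genome[n])
    total_len = off
    gcat = np.concatenate([genome.encoded(n) for n in names])

    if not mates:
        frame = pd.DataFrame(columns=["seq", "pos", "ref", "map_genotype", "q",
                                      "depth", "mean_multiplicity", "degeneracy",
                                      "n_linked", "vaf", "no_call"])
        return PosteriorTable(frame, np.empty((0, 10)))

    reads = read_map.reads
    L = reads.read_len

    # ---- flat alignment arrays -------------------------------------------
    a_ridx, a_start, a_rev, a_mate_id = [], [], [], []
    pair_a, pair_b = [], []  # ordered alignment pairs within a mate
    for mid, (ridx, alns) in enumerate(mates):
        base_idx = len(a_ridx)
        for a in alns:
            a_ridx.append(ridx)
            a_start.append(seq_offset[a.seq_name] + a.start)
            a_rev.append(a.strand == "-")
            a_mate_id.append(mid)
        # reads over the linkage cap contribute background mass only
        c = len(alns)
        if 1 < c <= params.max_linked_loci + 1:
            for i in range(c):
                for j in range(c):
                    if i != j:
                        pair_a.append(base_idx + i)
                        pair_b.append(base_idx + j)
    a_ridx = np.asarray(a_ridx)
    a_start = np.asarray(a_start, dtype=np.int64)
    a_rev = np.asarray(a_rev)
    a_mate_id = np.asarray(a_mate_id)
    n_aln = len(a_ridx)
    n_mates = len(mates)

    # ---- per-entry arrays (alignment-major, genome offset j minor) -------
    j = np.tile(np.arange(L), n_aln)
    ent_aln = np.repeat(np.arange(n_aln), L)
    gpos = a_start[ent_aln] + j
    o = np.where(a_rev[ent_aln], L - 1 - j, j)           # read coordinate
    raw = reads.seqs[a_ridx[ent_aln], o]
    b = np.where(a_rev[ent_aln], complement(raw), raw)   # called base
    q = reads.quals[a_ridx[ent_aln], o]
    p = gt.phred_to_prob(q)
    ref = gcat[gpos]
    ismm = (b != ref) | (b == 4) | (ref == 4)

    log_match = np.log1p(-p)
    log_f = np.log(p / 3.0) - log_match                  # mismatch penalty factor

    seg = np.arange(0, n_aln * L, L)
    nmm = np.add.reduceat(ismm.astype(np.int64), seg)
    log_pread_ref = np.add.reduceat(log_match + ismm * log_f, seg)

    w = params.read_weight
    pbin = np.array([gt.p_bin(L, k, params.e) for k in range(L + 1)])
    a_ref_prob = w * np.exp(log_pread_ref) + (1.0 - w) * pbin[nmm]

    tot_a = np.zeros(n_mates)
    np.add.at(tot_a, a_mate_id, a_ref_prob)
    dp1 = np.bincount(a_mate_id, minlength=n_mates).astype(float)

    # ---- per-entry allele-substitution likelihoods -----------------------
    lp_match = log_pread_ref[ent_aln] - ismm * log_f
    m_match = nmm[ent_aln] - ismm
    l_m = w * np.exp(lp_match) + (1.0 - w) * pbin[m_match]
    l_x = w * np.exp(lp_match + log_f) + (1.0 - w) * pbin[m_match + 1]

    aref_e = a_ref_prob[ent_aln]
    mate_e = a_mate_id[ent_aln]
    bg = tot_a[mate_e] - aref_e                          # reference background
    dp1_e = dp1[mate_e]
    log_dp1 = np.log(dp1_e)

    lw0 = np.log(np.maximum(l_x + bg, _FLOOR)) - log_dp1          # allele misses
    lw1 = np.log(np.maximum(0.5 * (l_m + l_x) + bg, _FLOOR)) - log_dp1
    lw2 = np.log(np.maximum(l_m + bg, _FLOOR)) - log_dp1          # both match

    nbins = total_len * 5
    key = gpos * 5 + np.minimum(b, 4).astype(np.int64)
    b0 = np.bincount(key, weights=lw0, minlength=nbins).reshape(total_len, 5)
    b1 = np.bincount(key, weights=lw1, minlength=nbins).reshape(total_len, 5)
    b2 = np.bincount(key, weights=lw2, minlength=nbins).reshape(total_len, 5)
    tot0 = np.bincount(gpos, weights=lw0, minlength=total_len)
    depth = np.bincount(gpos, minlength=total_len)
    mult_sum = np.bincount(gpos, weights=dp1_e, minlength=total_len)
    nonref = np.bincount(gpos, weights=(b != ref).astype(float), minlength=total_len)

    covered = np.flatnonzero(depth > 0)
    nc = len(covered)

    gidx = [(("ACGT".index(g[0]), "ACGT".index(g[1]))) for g in gt.GENOTYPES]
    ll = np.empty((nc, 10))
    for gi, (x, y) in enumerate(gidx):
        if x == y:
            ll[:, gi] = tot0[covered] + b2[covered, x] - b0[covered, x]
        else:
            ll[:, gi] = (tot0[covered] + b1[covered, x] - b0[covered, x]
                         + b1[covered, y] - b0[covered, y])

    # ---- paralog-configuration terms for the hom-ref branch --------------
    t_mass = params.theta + params.theta ** 2
    hom_adj = np.zeros(total_len)
    n_linked = np.ones(total_len)
    if pair_a:
        pa = np.repeat(np.asarray(pair_a, dtype=np.int64), L)
        pb = np.repeat(np.asarray(pair_b, dtype=np.int64), L)
        oo = np.tile(np.arange(L, dtype=np.int64), len(pair_a))
        e_a = pa * L + np.where(a_rev[pa], L - 1 - oo, oo)
        e_b = pb * L + np.where(a_rev[pb], L - 1 - oo, oo)

        # aggregate per (focal entry, linked locus): substituting a genotype
        # at locus j swaps every placement of the read that covers j at once
        ekey = e_a * np.int64(total_len) + gpos[e_b]
        ukey, first, inv = np.unique(ekey, return_index=True, return_inverse=True)
        nd = len(ukey)
        d0 = np.bincount(inv, weights=l_x[e_b] - aref_e[e_b], minlength=nd)
        d1 = np.bincount(inv, weights=0.5 * (l_m[e_b] + l_x[e_b]) - aref_e[e_b],
                         minlength=nd)
        d2 = np.bincount(inv, weights=l_m[e_b] - aref_e[e_b], minlength=nd)
        rec_col = gpos[e_a][first]
        rec_j = (ukey % np.int64(total_len)).astype(np.int64)
        rec_b = b[e_a][first]
        t0 = tot_a[a_mate_id[pa]][first]  # hom-ref focal entry total (identity)
        lt0 = np.log(np.maximum(t0, _FLOOR))
        c0 = np.log(np.maximum(t0 + d0, _FLOOR)) - lt0
        c1 = np.log(np.maximum(t0 + d1, _FLOOR)) - lt0
        c2 = np.log(np.maximum(t0 + d2, _FLOOR)) - lt0

        gkey = rec_col * total_len + rec_j
        uniq, grp = np.unique(gkey, return_inverse=True)
        ng = len(uniq)
        grp_col = (uniq // total_len).astype(np.int64)
        grp_j = (uniq % total_len).astype(np.int64)
        gk = grp * 5 + np.minimum(rec_b, 4).astype(np.int64)
        g0 = np.bincount(gk, weights=c0, minlength=ng * 5).reshape(ng, 5)
        g1 = np.bincount(gk, weights=c1, minlength=ng * 5).reshape(ng, 5)
        g2 = np.bincount(gk, weights=c2, minlength=ng * 5).reshape(ng, 5)
        gtot0 = np.bincount(grp, weights=c0, minlength=ng)

        # per group: logsumexp over the 9 non-reference genotypes at locus j
        prior4 = _prior_matrix(params.theta)
        ref_j = gcat[grp_j]
        valid = ref_j < 4
        dll = np.empty((ng, 10))
        for gi, (x, y) in enumerate(gidx):
            if x == y:
                dll[:, gi] = gtot0 + g2[:, x] - g0[:, x]
            else:
                dll[:, gi] = gtot0 + g1[:, x] - g0[:, x] + g1[:, y] - g0[:, y]
        logw = np.full((ng, 10), -np.inf)
        logw[valid] = np.log(prior4[np.minimum(ref_j[valid], 3)])
        # exclude the hom-ref genotype of locus j (that is the all-ref config)
        homref_gi = np.array([gt.GENOTYPES.index("ACGT"[r] * 2) for r in range(4)])
        logw[valid, homref_gi[ref_j[valid]]] = -np.inf
        terms = logw + dll
        tmax = terms.max(axis=1)
        safe = np.isfinite(tmax)
        m_group = np.full(ng, -np.inf)
        m_group[safe] = tmax[safe] + np.log(
            np.exp(terms[safe] - tmax[safe][:, None]).sum(axis=1))

        # combine groups per column
        order = np.argsort(grp_col, kind="stable")
        gc_sorted = grp_col[order]
        mg_sorted = m_group[order]
        col_ids, first = np.unique(gc_sorted, return_index=True)
        bounds = np.append(first, ng)
        log1mt = math.log(1.0 - t_mass) if t_mass > 0 else 0.0
        for ci, col in enumerate(col_ids):
            ms = mg_sorted[bounds[ci]:bounds[ci + 1]]
            m = len(ms)
            n_linked[col] = 1 + m
            if t_mass <= 0.0:
                continue
            mx = max(ms.max(), m * log1mt)
            s = math.exp(m * log1mt - mx) + float(
                np.exp((m - 1) * log1mt + ms - mx).sum())
            log_z = (m - 1) * log1mt + math.log((1.0 - t_mass) + m * t_mass)
            hom_adj[col] = mx + math.log(s) - log_z

    # ---- priors, posterior, MAP ------------------------------------------
    prior4 = _prior_matrix(params.theta)
    ref_cov = gcat[covered]
    valid_ref = ref_cov < 4
    log_prior = np.full((nc, 10), -math.log(10.0))
    log_prior[valid_ref] = np.log(prior4[np.minimum(ref_cov[valid_ref], 3)])

    homref_gi = np.array([gt.GENOTYPES.index("ACGT"[r] * 2) for r in range(4)])
    lp = log_prior + ll
    rows = np.flatnonzero(valid_ref)
    lp[rows, homref_gi[ref_cov[rows]]] += hom_adj[covered[rows]]

    mx = lp.max(axis=1, keepdims=True)
    log_post = lp - mx - np.log(np.exp(lp - mx).sum(axis=1, keepdims=True))

    map_idx = lp.argmax(axis=1)
    best = lp[np.arange(nc), map_idx]
    # ties resolve toward hom-ref
    hr = np.full(nc, -1)
    hr[rows] = homref_gi[ref_cov[rows]]
    tie = (hr >= 0) & (lp[np.arange(nc), np.maximum(hr, 0)] == best)
    map_idx[tie] = hr[tie]
    p_map = np.exp(log_post[np.arange(nc), map_idx])
    with np.errstate(divide="ignore"):
        qv = np.where(p_map >= 1.0, params.max_q,
                      np.minimum(params.max_q,
                                 -10.0 * np.log10(np.maximum(1.0 - p_map, 0.0))))

    # map global positions back to (seq, pos)
    bounds = np.cumsum([len(genome[n]) for n in names])
    seq_idx = np.searchsorted(bounds, covered, side="right")
    starts = np.concatenate([[0], bounds[:-1]])
    pos = covered - starts[seq_idx]

    genos = np.array(gt.GENOTYPES)
    frame = pd.DataFrame({
        "seq": [names[i] for i in seq_idx],
        "pos": pos,
        "ref": ["ACGTN"[r] for r in ref_cov],
        "map_genotype": genos[map_idx],
        "q": qv,
        "depth": depth[covered],
        "mean_multiplicity": mult_sum[covered] / depth[covered],
        "degeneracy": (mult_sum[covered] - depth[covered]) / depth[covered],
        "n_linked": n_linked[covered].astype(int),
        "vaf": nonref[covered] / depth[covered],
        "no_call": ~valid_ref,
    })
    for gi, g in enumerate(gt.GENOTYPES):
        frame[f"p_{g}"] = np.exp(log_post[:, gi])
    return PosteriorTable(frame, log_post)
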