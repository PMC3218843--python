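"""Model / Results interface over the multi-locus genotyper.

``MultiMapGenotyper`` wraps a read map and a reference genome; ``fit()``
computes the per-locus genotype posteriors and returns a
``GenotypingResults`` carrying the estimates, stringencies, diagnostics,
significant-call extraction and exporters.

Example
-------
>>> model = MultiMapGenotyper.from_sam("reads.sam", "ref.fasta",
...                                    strategy="all", mismatches=2)
>>> res = model.fit()
>>> print(res.summary())
>>> calls = res.calls(q_threshold=40)
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import _engine
from .genotype import ModelParams, effective_threshold
from .readmap import MappingStrategy, ReadMap, alignment_set_from_sam, apply_strategy, map_stats
from .simulate import ReferenceGenome


class MultiMapGenotyper:
    """Bayesian diploid genotyping model over a retained read map.

    Parameters
    ----------
    read_map : ReadMap
        Alignments retained by a mapping strategy (UNI/BESTNO/BEST/ALL).
    genome : ReferenceGenome
        The known reference template.
    params : ModelParams, optional
        Error rate, mixture weight, heterozygosity prior, stringency.
    """

    def __init__(self, read_map: ReadMap, genome: ReferenceGenome,
                 params: ModelParams | None = None):
        self.read_map = read_map
        self.genome = genome
        self.params = params or ModelParams()

    @classmethod
    def from_sam(cls, sam_path, fasta_path, strategy: str = "all",
                 max_d: int = 200, mismatches: int = 2,
                 insert_range: tuple[int, int] = (150, 300),
                 params: ModelParams | None = None,
                 strategy_seed: int = 0) -> "MultiMapGenotyper":
        genome = (fasta_path if isinstance(fasta_path, ReferenceGenome)
                  else ReferenceGenome.from_fasta(fasta_path))
        alns = alignment_set_from_sam(sam_path, genome, k=mismatches,
                                      insert_range=insert_range)
        rm = apply_strategy(alns, MappingStrategy(strategy, d_cap=max_d,
                                                  seed=strategy_seed))
        return cls(rm, genome, params)

    @classmethod
    def from_alignments(cls, alignment_set, genome: ReferenceGenome,
                        strategy: str = "all", max_d: int = 200,
                        params: ModelParams | None = None,
                        strategy_seed: int = 0) -> "MultiMapGenotyper":
        rm = apply_strategy(alignment_set, MappingStrategy(strategy, d_cap=max_d,
                                                           seed=strategy_seed))
        return cls(rm, genome, params)

    def fit(self) -> "GenotypingResults":
        table = _engine.compute_posteriors(self.read_map, self.genome, self.params)
        return GenotypingResults(self, table)


class GenotypingResults:
    """Fitted per-locus genotype posteriors and derived SNP calls."""

    def __init__(self, model: MultiMapGenotyper, table: _engine.PosteriorTable):
        self.model = model
        self.params = model.params
        self._table = table

    @property
    def posteriors(self) -> pd.DataFrame:
        """One row per assayed locus (depth > 0) with the 10 posteriors,
        MAP genotype, stringency Q and degeneracy diagnostics."""
        return self._table.frame

    @property
    def log_posterior(self) -> np.ndarray:
        return self._table.log_posterior

    def calls(self, q_threshold: float | None = None,
              degeneracy_correction: bool | None = None) -> pd.DataFrame:
        """Loci with significant non-reference MAP genotypes.

        A locus is significant when its MAP genotype differs from
        homozygous-reference and Q clears the effective threshold
        ``q_threshold + 10 log10(m)`` (m = 1 + linked paralogous loci) when
        degeneracy correction is on.
        """
        qt = self.params.q_threshold if q_threshold is None else q_threshold
        corr = (self.params.degeneracy_correction if degeneracy_correction is None
                else degeneracy_correction)
        df = self.posteriors
        if df.empty:
            return df.assign(effective_threshold=[], significant=[])
        q_eff = np.array([effective_threshold(qt, int(m), corr)
                          for m in df["n_linked"]])
        hom_ref = df["ref"].str.repeat(2)
        sig = (~df["no_call"]) & (df["map_genotype"] != hom_ref) & (df["q"] >= q_eff)
        out = df.assign(effective_threshold=q_eff, significant=sig)
        return out[out["significant"]].reset_index(drop=True)

    def map_statistics(self):
        return map_stats(self.model.read_map, self.model.genome)

    def summary(self, q_threshold: float | None = None) -> str:
        """Plain-text overview in the spirit of a model-results summary."""
        df = self.posteriors
        stats = self.map_statistics()
        calls = self.calls(q_threshold)
        qt = self.params.q_threshold if q_threshold is None else q_threshold
        p = self.params
        lines = [
            "Multi-locus Bayesian genotyping results",
            "=" * 47,
            f"Strategy: {self.model.read_map.strategy.kind:<8} "
            f"k = {self.model.read_map.k}   d_cap = {self.model.read_map.strategy.d_cap}",
            f"Params:   e = {p.e}  lambda = {p.lam}  theta = {p.theta}",
            f"Reads retained:        {stats.n_reads:>10d}",
            f"Alignments:            {stats.n_alignments:>10d}"
            f"   (APR = {stats.mean_alignments_per_read:.2f})",
            f"Loci assayed:          {len(df):>10d}"
            f"   ({100 * stats.fraction_covered:.1f}% of genome)",
            f"Mean depth:            {stats.mean_depth:>10.2f}",
            f"Non-unique reads:      {100 * stats.fraction_nonunique:>9.1f}%",
            f"Significant SNPs (Q >= {qt:g}"
            + (", degeneracy-corrected" if p.degeneracy_correction else "")
            + f"): {len(calls)}",
        ]
        if len(calls):
            lines.append("-" * 47)
            lines.append(f"{'seq':<12}{'pos':>8} {'ref':>4} {'MAP':>5} {'Q':>8} {'depth':>6}")
            for _, row in calls.head(20).iterrows():
                lines.append(f"{row['seq']:<12}{row['pos']:>8d} {row['ref']:>4} "
                             f"{row['map_genotype']:>5} {row['q']:>8.1f} {row['depth']:>6d}")
            if len(calls) > 20:
                lines.append(f"... and {len(calls) - 20} more")
        return "\n".join(lines)

    # ---- exporters -------------------------------------------------------

    def to_tsv(self, path, q_threshold: float | None = None) -> None:
        """Per-locus VCF-like TSV (1-based positions)."""
        qt = self.params.q_threshold if q_threshold is None else q_threshold
        df = self.posteriors
        q_eff = np.array([effective_threshold(qt, int(m),
                                              self.params.degeneracy_correction)
                          for m in df["n_linked"]]) if len(df) else np.array([])
        hom_ref = df["ref"].str.repeat(2)
        sig = (~df["no_call"]) & (df["map_genotype"] != hom_ref) & (df["q"] >= q_eff)
        out = pd.DataFrame({
            "seq": df["seq"],
            "pos1": df["pos"] + 1,
            "ref": df["ref"],
            "MAP_genotype": df["map_genotype"],
            "Q": df["q"].round(4),
            "depth": df["depth"],
            "mean_multiplicity": df["mean_multiplicity"].round(4),
            "significant": np.where(sig, 1, 0),
        })
        out.to_csv(path, sep="\t", index=False)

    def to_vcf(self, path, q_threshold: float | None = None) -> None:
        """VCF 4.2 export of the significant SNPs (GT, GQ, DP)."""
        calls = self.calls(q_threshold)
        genome = self.model.genome
        with open(path, "w") as fh:
            fh.write("##fileformat=VCFv4.2\n")
            fh.write("##source=multisnp\n")
            for n in genome.names:
                fh.write(f"##contig=<ID={n},length={len(genome[n])}>\n")
            fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
            fh.write('##FORMAT=<ID=GQ,Number=1,Type=Integer,Description="Genotype quality">\n')
            fh.write('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">\n')
            fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tsample\n")
            for _, row in calls.iterrows():
                ref = row["ref"]
                alts = sorted({a for a in row["map_genotype"] if a != ref})
                alleles = [ref] + alts
                gt_idx = "/".join(str(alleles.index(a))
                                  for a in sorted(row["map_genotype"]))
                gq = int(min(row["q"], self.params.max_q))
                fh.write(f"{row['seq']}\t{int(row['pos']) + 1}\t.\t{ref}\t"
                         f"{','.join(alts)}\t{row['q']:.1f}\tPASS\t.\t"
                         f"GT:GQ:DP\t{gt_idx}:{gq}:{int(row['depth'])}\n")
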