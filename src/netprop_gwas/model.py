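"""Model/results interface over the propagation workflow.

:class:`NetworkGWAS` bundles the three data ingredients (gene seed
scores, the molecular network, optionally a gold-standard set) and
``fit()`` runs the restart walk, returning a
:class:`NetworkGWASResults` that carries the ranked gene list,
convergence diagnostics, evaluation metrics and export helpers.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from . import gwas_io, network_io, propagation, evaluation
from .evaluation import EvaluationReport, RankedGeneList
from .gwas_io import GeneAnnotation, GeneScoreVector, SnpRecord
from .network_io import PropagationNetwork
from .propagation import PropagationConfig, PropagationResult


class NetworkGWAS:
    """Network-assisted gene prioritization from GWAS summary statistics.

    Parameters
    ----------
    scores : GeneScoreVector
        Per-gene seed scores (-log10 best SNP p in window).
    network : PropagationNetwork
        The molecular network to propagate over.
    gold : set of str, optional
        Gold-standard gene symbols for evaluation.

    Examples
    --------
    >>> model = NetworkGWAS.from_data(snps, genes, network, gold=gold)
    >>> results = model.fit(alpha=0.5)
    >>> print(results.summary())
    """

    def __init__(
        self,
        scores: GeneScoreVector,
        network: PropagationNetwork,
        gold: set[str] | None = None,
    ) -> None:
        self.scores = scores
        self.network = network
        self.gold = set(gold) if gold is not None else None
        self.seeds, self.coverage = network_io.align_scores(network, scores)

    @classmethod
    def from_data(
        cls,
        snps: Sequence[SnpRecord],
        genes: Sequence[GeneAnnotation],
        network: PropagationNetwork,
        gold: Iterable[str] | None = None,
        window_bp: int = gwas_io.DEFAULT_WINDOW_BP,
        p_floor: float = gwas_io.DEFAULT_P_FLOOR,
    ) -> "NetworkGWAS":
        """Build the model from parsed SNPs and gene annotations."""
        scores = gwas_io.assign_gene_scores(snps, genes, window_bp=window_bp, p_floor=p_floor)
        return cls(scores, network, gold=set(gold) if gold is not None else None)

    @classmethod
    def from_files(
        cls,
        summary_stats: str | Path,
        annotations: str | Path,
        network: str | Path,
        gold: str | Path | None = None,
        window_bp: int = gwas_io.DEFAULT_WINDOW_BP,
        p_floor: float = gwas_io.DEFAULT_P_FLOOR,
        column_map: Mapping[str, str] | None = None,
        annotation_format: str = "auto",
        network_weighted: bool = False,
        edge_weight_attr: str | None = None,
    ) -> "NetworkGWAS":
        """Build the model straight from the four input files.

        The network format is chosen by extension: ``.cx``/``.json`` is
        CX, ``.sif`` is SIF, anything else a 2/3-column edge list.
        """
        snps, _ = gwas_io.read_summary_stats(summary_stats, column_map=column_map)
        genes = gwas_io.read_gene_annotations(annotations, format=annotation_format)
        net = load_network(network, weighted=network_weighted,
                           edge_weight_attr=edge_weight_attr)
        gold_set = evaluation.read_gene_set(gold) if gold is not None else None
        return cls.from_data(snps, genes, net, gold=gold_set,
                             window_bp=window_bp, p_floor=p_floor)

    def fit(
        self,
        alpha: float = 0.5,
        tol: float = 1e-6,
        max_iter: int = 1000,
        normalization: str = "column-stochastic",
        k: int = evaluation.DEFAULT_TOP_K,
    ) -> "NetworkGWASResults":
        """Run the restart walk and rank all network genes.

        Returns a results object; evaluation against the gold set is
        included when the model holds one and ``k`` fits the universe.
        """
        config = PropagationConfig(alpha=alpha, tol=tol, max_iter=max_iter,
                                   normalization=normalization)
        operator = propagation.normalize_adjacency(self.network, mode=normalization)
        prop = propagation.propagate(operator, self.seeds, config)
        ranked = evaluation.rank_genes(self.network.nodes, self.seeds, prop.final_scores)
        report = None
        if self.gold is not None:
            report = evaluation.evaluate(ranked, self.gold, k=min(k, len(ranked)))
        return NetworkGWASResults(
            model=self, config=config, propagation=prop, ranked=ranked, report=report
        )


def load_network(
    path: str | Path,
    weighted: bool = False,
    edge_weight_attr: str | None = None,
) -> PropagationNetwork:
    """Dispatch on file extension: CX JSON, SIF, or edge list."""
    suffix = Path(path).suffix.lower()
    if suffix in (".cx", ".json"):
        return network_io.read_cx(path, edge_weight_attr=edge_weight_attr)
    return network_io.read_edgelist(path, weighted=weighted)


@dataclass
class NetworkGWASResults:
    """Fitted prioritization: ranked genes, diagnostics, evaluation."""

    model: NetworkGWAS
    config: PropagationConfig
    propagation: PropagationResult
    ranked: RankedGeneList
    report: EvaluationReport | None = None

    @property
    def converged(self) -> bool:
        return self.propagation.converged

    def top(self, k: int = 100) -> list[str]:
        return self.ranked.top(k)

    def evaluate(self, gold: Iterable[str], k: int = evaluation.DEFAULT_TOP_K) -> EvaluationReport:
        """Score the ranking against an arbitrary gold set."""
        return evaluation.evaluate(self.ranked, gold, k=min(k, len(self.ranked)))

    def export_subnetwork(
        self,
        out_prefix: str | Path,
        top_n: int = 100,
        gold: Iterable[str] | None = None,
    ) -> tuple[Path, Path]:
        """Write the induced top-``top_n`` subnetwork as CX + SIF.

        Node attributes carried in the CX: ``seed_score``,
        ``propagated_score``, ``rank`` and, when a gold set is
        available, ``in_gold``.
        """
        from . import pipeline

        gold_set = set(gold) if gold is not None else self.model.gold
        return pipeline.export_subnetwork(
            self.model.network, self.ranked, out_prefix, top_n=top_n, gold=gold_set
        )

    def summary(self) -> str:
        """Human-readable run summary in the spirit of a fit report."""
        n = self.model.network
        lines = [
            "Network-assisted GWAS prioritization",
            "=" * 52,
            f"network nodes         {n.n_nodes}",
            f"network edges         {n.n_edges}",
            f"scored genes in net   {self.model.coverage.scored_in_network}",
            f"scored genes missing  {self.model.coverage.scored_not_in_network}",
            f"unscored net genes    {self.model.coverage.unscored_in_network}",
            "-" * 52,
            f"alpha                 {self.config.alpha}",
            f"normalization         {self.config.normalization}",
            f"iterations            {self.propagation.iterations}"
            f" (converged={self.propagation.converged})",
            f"final residual (L1)   {self.propagation.residual:.3g}",
            "-" * 52,
            "top 10 genes (rank, symbol, seed, propagated):",
        ]
        for row in self.ranked.table.head(10).itertuples(index=False):
            lines.append(
                f"  {row.rank:>4d}  {row.symbol:<12s} {row.seed_score:8.4f} "
                f"{row.propagated_score:10.6f}"
            )
        if self.report is not None:
            lines.append("-" * 52)
            lines.extend(str(self.report).splitlines())
        return "\n".join(lines)
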