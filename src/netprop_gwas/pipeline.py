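"""End-to-end orchestration: files in, ranked list + report + export out.

``run`` executes the four stages in order — gene scoring, network
loading and alignment, propagation, evaluation — and writes the ranked
TSV, a JSON report, the top-gene subnetwork (CX + SIF), and a run log.
Two runs with the same configuration and inputs produce byte-identical
primary outputs; any stage failure aborts with the stage name and
removes partial outputs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass
from pathlib import Path

from . import evaluation, gwas_io
from .errors import NetpropError
from .evaluation import RankedGeneList
from .model import NetworkGWAS, NetworkGWASResults, load_network

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Everything that determines one pipeline run."""

    summary_stats: str
    annotations: str
    network: str
    out_dir: str
    gold: str | None = None
    window_bp: int = gwas_io.DEFAULT_WINDOW_BP
    p_floor: float = gwas_io.DEFAULT_P_FLOOR
    alpha: float = 0.5
    tol: float = 1e-6
    max_iter: int = 1000
    normalization: str = "column-stochastic"
    k: int = 100
    top_n: int = 100
    annotation_format: str = "auto"
    network_weighted: bool = False
    edge_weight_attr: str | None = None
    column_map: dict[str, str] | None = None

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True)


@dataclass
class RunOutputs:
    """Paths written by one successful run."""

    ranked_tsv: Path
    report_json: Path | None
    subnetwork_cx: Path
    subnetwork_sif: Path
    log_file: Path
    config_json: Path


def run(config: RunConfig) -> tuple[NetworkGWASResults, RunOutputs]:
    """Execute the full pipeline described by ``config``.

    Returns the fitted results plus the paths written.  Raises
    :class:`~netprop_gwas.errors.NetpropError` subclasses tagged with
    the failing stage; partial outputs are removed on failure.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log_file = out / "run.log"
    handler = logging.FileHandler(log_file, mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    root = logging.getLogger("netprop_gwas")
    root.addHandler(handler)
    root.setLevel(logging.INFO)

    written: list[Path] = [log_file]
    stage = "configuration"
    try:
        config_json = out / "config.json"
        config_json.write_text(config.to_json() + "\n")
        written.append(config_json)
        logger.info("run config:\n%s", config.to_json())

        stage = "gene scoring"
        snps, n_skipped = gwas_io.read_summary_stats(
            config.summary_stats, column_map=config.column_map
        )
        genes = gwas_io.read_gene_annotations(
            config.annotations, format=config.annotation_format
        )
        scores = gwas_io.assign_gene_scores(
            snps, genes, window_bp=config.window_bp, p_floor=config.p_floor
        )
        logger.info(
            "scored %d genes from %d SNPs (%d rows skipped, %d SNPs unmapped, "
            "%d genes without SNPs)",
            len(scores), len(snps), n_skipped, scores.n_unmapped_snps,
            scores.n_scoreless_genes,
        )

        stage = "network loading"
        network = load_network(
            config.network,
            weighted=config.network_weighted,
            edge_weight_attr=config.edge_weight_attr,
        )
        gold = evaluation.read_gene_set(config.gold) if config.gold else None
        model = NetworkGWAS(scores, network, gold=gold)

        stage = "propagation"
        results = model.fit(
            alpha=config.alpha,
            tol=config.tol,
            max_iter=config.max_iter,
            normalization=config.normalization,
            k=config.k,
        )
        logger.info(
            "propagation: %d iterations, residual %.3g, converged=%s",
            results.propagation.iterations, results.propagation.residual,
            results.propagation.converged,
        )

        stage = "output"
        ranked_tsv = out / "ranked_genes.tsv"
        results.ranked.to_tsv(ranked_tsv)
        written.append(ranked_tsv)
        report_json = None
        if results.report is not None:
            report_json = out / "evaluation.json"
            results.report.to_json(report_json)
            written.append(report_json)
            logger.info("evaluation:\n%s", results.report)
        top_n = min(config.top_n, len(results.ranked))
        cx_path, sif_path = results.export_subnetwork(out / "subnetwork", top_n=top_n)
        written.extend([cx_path, sif_path])
        return results, RunOutputs(
            ranked_tsv=ranked_tsv,
            report_json=report_json,
            subnetwork_cx=cx_path,
            subnetwork_sif=sif_path,
            log_file=log_file,
            config_json=config_json,
        )
    except Exception as exc:
        for p in written:
            if p != log_file and p.exists():
                p.unlink()
        if isinstance(exc, NetpropError):
            raise type(exc)(f"[stage: {stage}] {exc}") from exc
        raise NetpropError(f"[stage: {stage}] {exc}") from exc
    finally:
        root.removeHandler(handler)
        handler.close()


def export_subnetwork(network, ranked: RankedGeneList, out_prefix: str | Path,
                      top_n: int = 100, gold=None):
    """Functional form of subnetwork export for stage-wise CLI use."""
    from .network_io import write_cx, write_sif
    from .errors import InputError

    if top_n > len(ranked):
        raise InputError(f"top_n={top_n} exceeds universe size {len(ranked)}")
    top_symbols = ranked.top(top_n)
    sub = network.subgraph(top_symbols)
    if sub.n_edges == 0:
        logger.warning("export_subnetwork: induced subgraph has no edges")
    gold_set = set(gold) if gold is not None else None
    attrs: dict[str, dict[str, object]] = {}
    for row in ranked.table.head(top_n).itertuples(index=False):
        a: dict[str, object] = {
            "seed_score": float(row.seed_score),
            "propagated_score": float(row.propagated_score),
            "rank": int(row.rank),
        }
        if gold_set is not None:
            a["in_gold"] = row.symbol in gold_set
        attrs[row.symbol] = a
    cx_path = Path(f"{out_prefix}.cx")
    sif_path = Path(f"{out_prefix}.sif")
    write_cx(sub, cx_path, node_attributes=attrs)
    write_sif(sub, sif_path)
    return cx_path, sif_path
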