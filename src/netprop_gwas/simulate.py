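"""Deterministic synthetic GWAS + network studies with a planted module.

The generator emulates the signal-aggregation mechanism that network
propagation exploits: a densely interconnected "disease module" of
genes in which only a fraction carry genome-wide-significant SNPs.
Propagation should recover the unseeded module members through their
seeded neighbors — the synthetic analogue of a gene reaching the top of
the ranking despite never attaining a significant association itself.

Layout: genes sit on synthetic chromosomes as fixed-length,
non-overlapping bodies separated by 10 kb, so each SNP placed inside a
gene body falls in exactly one gene's default +/-10 kb window.  Null
SNP p-values are uniform(0, 1), the null of a well-calibrated GWAS.
The network is a planted-partition graph: module gene pairs connect
with probability ``module_edge_p``, all other pairs with the lower
``background_edge_p``.  Every output is byte-reproducible from
``rng_seed``.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np

from .errors import ConfigurationError
from .gwas_io import GeneAnnotation, SnpRecord

GENE_LENGTH_BP = 10_000
GENE_GAP_BP = 10_000
GENES_PER_CHROM = 25


@dataclass(frozen=True)
class PlantedModuleSpec:
    """Parameters of one synthetic study.

    Defaults describe a modest desk-scale study: 300 genes, a 20-gene
    module of which half carry a significant SNP (p near 1e-6, nominal
    but clearly above the background), 5 SNPs per gene, and a
    planted-partition network whose module is ~12x denser than the
    background.
    """

    n_genes: int = 300
    n_snps_per_gene: int = 5
    module_size: int = 20
    seeded_fraction: float = 0.5
    signal_p: float = 1e-6
    background_edge_p: float = 0.02
    module_edge_p: float = 0.25
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.module_size > self.n_genes:
            raise ConfigurationError(
                f"module_size {self.module_size} exceeds n_genes {self.n_genes}"
            )
        if not (0.0 < self.seeded_fraction <= 1.0):
            raise ConfigurationError(
                f"seeded_fraction must lie in (0, 1], got {self.seeded_fraction}"
            )
        if not (0.0 < self.signal_p < 1.0):
            raise ConfigurationError(f"signal_p must lie in (0, 1), got {self.signal_p}")
        if not (0.0 <= self.background_edge_p < self.module_edge_p <= 1.0):
            raise ConfigurationError(
                "module edge probability must exceed background edge probability"
            )
        if self.n_genes < 2 or self.n_snps_per_gene < 1:
            raise ConfigurationError("need at least 2 genes and 1 SNP per gene")


@dataclass
class SyntheticStudy:
    """In-memory form of one generated study."""

    snps: list[SnpRecord]
    genes: list[GeneAnnotation]
    edges: list[tuple[str, str]]
    module_genes: list[str]
    seeded_genes: list[str]

    @property
    def unseeded_module_genes(self) -> list[str]:
        seeded = set(self.seeded_genes)
        return [g for g in self.module_genes if g not in seeded]


def _gene_layout(n_genes: int) -> list[GeneAnnotation]:
    """Place fixed-length gene bodies on synthetic chromosomes."""
    genes = []
    width = len(str(n_genes))
    for i in range(n_genes):
        chrom = str(i // GENES_PER_CHROM + 1)
        slot = i % GENES_PER_CHROM
        start = 1 + slot * (GENE_LENGTH_BP + GENE_GAP_BP)
        genes.append(
            GeneAnnotation(
                symbol=f"G{i:0{width}d}",
                chrom=chrom,
                start=start,
                end=start + GENE_LENGTH_BP - 1,
            )
        )
    return genes


def simulate_study(spec: PlantedModuleSpec) -> SyntheticStudy:
    """Generate one study in memory; fully determined by ``spec``."""
    rng = np.random.default_rng(spec.rng_seed)
    genes = _gene_layout(spec.n_genes)
    symbols = [g.symbol for g in genes]

    module_idx = np.sort(rng.choice(spec.n_genes, size=spec.module_size, replace=False))
    module = [symbols[i] for i in module_idx]
    n_seeded = max(1, int(round(spec.seeded_fraction * spec.module_size)))
    seeded_idx = np.sort(rng.choice(module_idx, size=n_seeded, replace=False))
    seeded = [symbols[i] for i in seeded_idx]
    seeded_set = set(seeded)

    snps: list[SnpRecord] = []
    snp_counter = 0
    for g in genes:
        offsets = rng.integers(0, GENE_LENGTH_BP, size=spec.n_snps_per_gene)
        pvals = rng.uniform(0.0, 1.0, size=spec.n_snps_per_gene)
        pvals = np.clip(pvals, 1e-12, 1.0)  # uniform null, bounded away from 0
        if g.symbol in seeded_set:
            # one significant SNP at the p-value scale of the planted signal
            pvals[0] = spec.signal_p * rng.uniform(0.1, 1.0)
        for off, p in zip(offsets, pvals):
            snps.append(
                SnpRecord(
                    snp_id=f"rs{snp_counter}",
                    chrom=g.chrom,
                    pos=g.start + int(off),
                    pvalue=float(p),
                )
            )
            snp_counter += 1

    in_module = np.zeros(spec.n_genes, dtype=bool)
    in_module[module_idx] = True
    edges: list[tuple[str, str]] = []
    for i in range(spec.n_genes):
        for j in range(i + 1, spec.n_genes):
            p_edge = (
                spec.module_edge_p
                if in_module[i] and in_module[j]
                else spec.background_edge_p
            )
            if rng.random() < p_edge:
                edges.append((symbols[i], symbols[j]))
    return SyntheticStudy(
        snps=snps, genes=genes, edges=edges, module_genes=module, seeded_genes=seeded
    )


@dataclass(frozen=True)
class FixtureFiles:
    """Paths to the four files one generated study writes."""

    summary_stats: Path
    annotations: Path
    network: Path
    gold: Path


def generate(spec: PlantedModuleSpec, out_dir: str | Path) -> FixtureFiles:
    """Write one synthetic study to disk in the formats the pipeline reads.

    Produces a PLINK ``.assoc``-style summary-statistics table, a
    4-column gene annotation table, a tab-separated edge list, and a
    newline-delimited gold set (the planted module).  Identical specs
    produce byte-identical files.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    study = simulate_study(spec)

    paths = FixtureFiles(
        summary_stats=out / "summary_stats.assoc",
        annotations=out / "genes.tsv",
        network=out / "network.txt",
        gold=out / "gold.txt",
    )
    with open(paths.summary_stats, "w") as fh:
        fh.write("CHR SNP BP P\n")
        for s in study.snps:
            fh.write(f"{s.chrom} {s.snp_id} {s.pos} {s.pvalue:.10g}\n")
    with open(paths.annotations, "w") as fh:
        fh.write("symbol\tchrom\tstart\tend\n")
        for g in study.genes:
            fh.write(f"{g.symbol}\t{g.chrom}\t{g.start}\t{g.end}\n")
    with open(paths.network, "w") as fh:
        fh.write("# planted-partition synthetic network\n")
        for u, v in study.edges:
            fh.write(f"{u}\t{v}\n")
    with open(paths.gold, "w") as fh:
        for sym in study.module_genes:
            fh.write(sym + "\n")
    return paths


def null_spec(spec: PlantedModuleSpec) -> PlantedModuleSpec:
    """The matched null study: same layout and network, no planted signal.

    Implemented by pushing the "significant" SNP p-values to the
    uniform scale, so seeded genes are indistinguishable from
    background.  Used for calibration checks.
    """
    return replace(spec, signal_p=0.999)
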