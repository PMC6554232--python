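"""Read GWAS summary statistics and gene annotations; score genes.

The gene score used throughout the package is the -log10 of the smallest
association p-value among SNPs falling within a symmetric genomic window
around the gene body.  The window is measured from the annotated gene
start/end (not the TSS) and is inclusive at exactly ``window_bp`` base
pairs on either side.  No linkage-disequilibrium correction is applied:
every SNP inside a gene's window is a candidate for that gene, and a SNP
inside two overlapping windows contributes to both genes.
"""

from __future__ import annotations

import io
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError, InputError

logger = logging.getLogger(__name__)

#: PLINK ``.assoc`` column names, the default dialect.
DEFAULT_COLUMNS = {"snp": "SNP", "chrom": "CHR", "pos": "BP", "p": "P"}

#: Default half-window around the gene body, in base pairs.
DEFAULT_WINDOW_BP = 10_000

#: Smallest p-value admitted before the -log10 transform; keeps scores
#: finite when a p-value is reported as 0 without perturbing rank order.
DEFAULT_P_FLOOR = 1e-300


def normalize_chrom(chrom: str) -> str:
    """Strip a leading ``chr`` prefix and uppercase X/Y/MT names."""
    c = str(chrom).strip()
    if c.lower().startswith("chr"):
        c = c[3:]
    if c.lower() in ("x", "y", "mt", "m"):
        c = "MT" if c.lower() in ("mt", "m") else c.upper()
    return c


@dataclass(frozen=True)
class SnpRecord:
    """A single SNP association result.

    Attributes
    ----------
    snp_id : str
        Variant identifier (e.g. an rsID).
    chrom : str
        Chromosome name, normalized (no ``chr`` prefix).
    pos : int
        1-based base-pair position.
    pvalue : float
        Association p-value in (0, 1].
    """

    snp_id: str
    chrom: str
    pos: int
    pvalue: float

    def __post_init__(self) -> None:
        if not (0.0 < self.pvalue <= 1.0):
            raise InputError(f"SNP {self.snp_id}: p-value {self.pvalue} outside (0, 1]")
        if self.pos < 1:
            raise InputError(f"SNP {self.snp_id}: position {self.pos} < 1")
        if not self.chrom:
            raise InputError(f"SNP {self.snp_id}: empty chromosome")


@dataclass(frozen=True)
class GeneAnnotation:
    """A gene body on 1-based inclusive coordinates."""

    symbol: str
    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise InputError(
                f"gene {self.symbol}: start {self.start} > end {self.end}"
            )


@dataclass
class GeneScoreVector:
    """Per-gene seed scores (-log10 of the best candidate p-value).

    ``entries`` maps gene symbol to a non-negative finite score.  Genes
    whose window contained no SNP score 0 and are tallied in
    ``n_scoreless_genes``; SNPs landing in no gene window are tallied in
    ``n_unmapped_snps``.
    """

    entries: dict[str, float] = field(default_factory=dict)
    n_unmapped_snps: int = 0
    n_scoreless_genes: int = 0

    def __getitem__(self, symbol: str) -> float:
        return self.entries[symbol]

    def __len__(self) -> int:
        return len(self.entries)

    def to_tsv(self, path: str | Path) -> None:
        """Write the scores as a 2-column TSV (symbol, score).

        Full float precision, so a write/read round-trip is exact and
        stage-wise runs match the end-to-end pipeline bit for bit.
        """
        with open(path, "w") as fh:
            fh.write("symbol\tscore\n")
            for sym in sorted(self.entries):
                fh.write(f"{sym}\t{self.entries[sym]:.17g}\n")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "GeneScoreVector":
        df = pd.read_csv(path, sep="\t")
        return cls(entries=dict(zip(df["symbol"].astype(str), df["score"].astype(float))))


def read_summary_stats(
    path: str | Path,
    column_map: Mapping[str, str] | None = None,
    delimiter: str | None = None,
) -> tuple[list[SnpRecord], int]:
    """Read a PLINK ``.assoc``-style summary-statistics table.

    Parameters
    ----------
    path : str or Path
        Whitespace- or ``delimiter``-separated table with a header row.
    column_map : mapping, optional
        Overrides for the logical column names ``snp``, ``chrom``,
        ``pos``, ``p`` (defaults: SNP, CHR, BP, P), which also lets
        SNPTEST-style files be read.
    delimiter : str, optional
        Explicit field separator; default is any whitespace.

    Returns
    -------
    (records, n_skipped)
        One :class:`SnpRecord` per valid row, in file order, and the
        number of rows skipped for missing/non-numeric/out-of-range
        values.
    """
    cols = dict(DEFAULT_COLUMNS)
    if column_map:
        cols.update(column_map)
    try:
        if delimiter is None:
            df = pd.read_csv(path, sep=r"\s+", dtype=str)
        else:
            df = pd.read_csv(path, sep=delimiter, dtype=str)
    except pd.errors.EmptyDataError as exc:
        raise InputError(f"{path}: empty summary-statistics file") from exc
    for logical, name in cols.items():
        if name not in df.columns:
            raise ConfigurationError(
                f"{path}: required column {name!r} (for {logical!r}) not found; "
                f"available columns: {list(df.columns)}"
            )
    if len(df) == 0:
        raise InputError(f"{path}: summary-statistics file has a header but no rows")

    records: list[SnpRecord] = []
    n_skipped = 0
    for row in df.itertuples(index=False):
        d = dict(zip(df.columns, row))
        try:
            p = float(d[cols["p"]])
            pos = int(float(d[cols["pos"]]))
            if not np.isfinite(p) or not (0.0 < p <= 1.0):
                raise ValueError
            records.append(
                SnpRecord(
                    snp_id=str(d[cols["snp"]]),
                    chrom=normalize_chrom(d[cols["chrom"]]),
                    pos=pos,
                    pvalue=p,
                )
            )
        except (ValueError, TypeError, InputError):
            n_skipped += 1
    if n_skipped:
        logger.info("read_summary_stats: skipped %d invalid rows", n_skipped)
    return records, n_skipped


def _merge_duplicates(annots: list[GeneAnnotation]) -> list[GeneAnnotation]:
    """Merge duplicate symbols to the union span (conservative)."""
    by_symbol: dict[str, GeneAnnotation] = {}
    for a in annots:
        prev = by_symbol.get(a.symbol)
        if prev is None:
            by_symbol[a.symbol] = a
        else:
            if prev.chrom != a.chrom:
                raise InputError(
                    f"gene {a.symbol}: duplicate rows on different chromosomes "
                    f"({prev.chrom} vs {a.chrom})"
                )
            by_symbol[a.symbol] = GeneAnnotation(
                symbol=a.symbol,
                chrom=a.chrom,
                start=min(prev.start, a.start),
                end=max(prev.end, a.end),
            )
    return list(by_symbol.values())


def read_gene_annotations(
    path: str | Path, format: str = "auto"
) -> list[GeneAnnotation]:
    """Read gene annotations from BED or a 4-column symbol table.

    BED rows (``chrom start end name``, 0-based half-open) are converted
    to 1-based inclusive coordinates.  Tabular rows are
    ``symbol chrom start end``, already 1-based inclusive; a header is
    permitted and detected.  Duplicate symbols merge to the union span.

    Parameters
    ----------
    format : {"auto", "bed", "table"}
    """
    if format not in ("auto", "bed", "table"):
        raise ConfigurationError(f"unknown annotation format {format!r}")
    lines: list[tuple[int, list[str]]] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) < 4:
                raise InputError(f"{path}:{lineno}: expected 4 columns, got {len(parts)}")
            lines.append((lineno, parts[:4]))
    if not lines:
        raise InputError(f"{path}: no annotation rows")

    def _is_int(s: str) -> bool:
        try:
            int(s)
            return True
        except ValueError:
            return False

    first = lines[0][1]
    if format == "auto":
        # BED is chrom/start/end/name; the 4-column table is
        # symbol/chrom/start/end, so an integer last column means table
        if _is_int(first[2]) and _is_int(first[3]):
            format = "table"
        elif _is_int(first[1]) and _is_int(first[2]):
            format = "bed"
        else:
            # header row on a tabular file
            format = "table"
            lines = lines[1:]
            if not lines:
                raise InputError(f"{path}: header only, no annotation rows")
    elif format == "table" and not (_is_int(first[2]) and _is_int(first[3])):
        lines = lines[1:]
        if not lines:
            raise InputError(f"{path}: header only, no annotation rows")

    annots: list[GeneAnnotation] = []
    for lineno, parts in lines:
        try:
            if format == "bed":
                chrom, start0, end0, symbol = parts
                start, end = int(start0) + 1, int(end0)
            else:
                symbol, chrom, s, e = parts
                start, end = int(s), int(e)
        except ValueError as exc:
            raise InputError(f"{path}:{lineno}: unparseable coordinates") from exc
        if start > end:
            raise InputError(f"{path}:{lineno}: start > end after conversion")
        annots.append(
            GeneAnnotation(symbol=symbol, chrom=normalize_chrom(chrom), start=start, end=end)
        )
    return _merge_duplicates(annots)


def assign_gene_scores(
    snps: Sequence[SnpRecord],
    genes: Sequence[GeneAnnotation],
    window_bp: int = DEFAULT_WINDOW_BP,
    p_floor: float = DEFAULT_P_FLOOR,
) -> GeneScoreVector:
    """Score each gene by the best SNP p-value within its window.

    A SNP is a candidate for a gene when it lies on the same chromosome
    with position in ``[start - window_bp, end + window_bp]`` (inclusive
    at both boundaries).  The gene score is
    ``-log10(max(p_floor, min candidate p))``; genes with no candidate
    SNP score 0.  SNPs inside several genes' windows contribute to each.

    Parameters
    ----------
    window_bp : int
        Non-negative half-window in base pairs (default 10 kb).
    p_floor : float
        Lower clamp on p-values in (0, 1), keeping scores finite.
    """
    if window_bp < 0:
        raise ConfigurationError(f"window_bp must be >= 0, got {window_bp}")
    if not (0.0 < p_floor < 1.0):
        raise ConfigurationError(f"p_floor must lie in (0, 1), got {p_floor}")
    if not genes:
        raise InputError("assign_gene_scores: empty gene list")
    if not snps:
        logger.warning("assign_gene_scores: no SNPs supplied; all gene scores are 0")
        return GeneScoreVector(
            entries={g.symbol: 0.0 for g in genes},
            n_unmapped_snps=0,
            n_scoreless_genes=len(genes),
        )

    # group SNPs per chromosome, sorted by position, for windowed range queries
    by_chrom: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
    order = np.arange(len(snps))
    chroms = np.array([s.chrom for s in snps])
    positions = np.array([s.pos for s in snps], dtype=np.int64)
    pvals = np.array([s.pvalue for s in snps], dtype=float)
    for c in np.unique(chroms):
        idx = order[chroms == c]
        srt = idx[np.argsort(positions[idx], kind="stable")]
        by_chrom[c] = (positions[srt], pvals[srt], srt)

    mapped = np.zeros(len(snps), dtype=bool)
    entries: dict[str, float] = {}
    n_scoreless = 0
    for g in genes:
        score = 0.0
        has_candidate = False
        hit = by_chrom.get(g.chrom)
        if hit is not None:
            pos_sorted, p_sorted, orig_idx = hit
            lo = np.searchsorted(pos_sorted, g.start - window_bp, side="left")
            hi = np.searchsorted(pos_sorted, g.end + window_bp, side="right")
            if hi > lo:
                has_candidate = True
                best = float(p_sorted[lo:hi].min())
                score = -np.log10(max(p_floor, best))
                mapped[orig_idx[lo:hi]] = True
        if not has_candidate:
            n_scoreless += 1
        entries[g.symbol] = score
    return GeneScoreVector(
        entries=entries,
        n_unmapped_snps=int((~mapped).sum()),
        n_scoreless_genes=n_scoreless,
    )
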