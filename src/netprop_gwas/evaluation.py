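"""Rank propagated genes and validate against a gold-standard set.

Two metrics: upper-tail hypergeometric enrichment of the top-k genes,
and AUROC via the Mann-Whitney rank-sum identity (ties get half
credit).  The universe for both is the set of genes in the ranked list,
i.e. the propagation network — only networked genes receive propagated
scores, so gold genes outside the network are dropped (and counted)
before testing.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import InputError

logger = logging.getLogger(__name__)

DEFAULT_TOP_K = 100


@dataclass
class RankedGeneList:
    """Genes ordered by propagated score, descending.

    Backed by a DataFrame with columns ``symbol``, ``seed_score``,
    ``propagated_score``, ``rank`` (1-based).  Ties in propagated score
    break by higher seed score, then lexicographic symbol, so the order
    is fully deterministic.
    """

    table: pd.DataFrame

    def __len__(self) -> int:
        return len(self.table)

    @property
    def symbols(self) -> list[str]:
        return self.table["symbol"].tolist()

    def top(self, k: int) -> list[str]:
        return self.table["symbol"].head(k).tolist()

    def to_tsv(self, path: str | Path) -> None:
        out = self.table.copy()
        out["seed_score"] = out["seed_score"].map(lambda x: f"{x:.10g}")
        out["propagated_score"] = out["propagated_score"].map(lambda x: f"{x:.10g}")
        out.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "RankedGeneList":
        df = pd.read_csv(path, sep="\t", dtype={"symbol": str})
        return cls(table=df)


def rank_genes(
    nodes: Sequence[str],
    seeds: np.ndarray,
    propagated: np.ndarray,
) -> RankedGeneList:
    """Sort genes by propagated score (desc); ties by seed score, then symbol."""
    seeds = np.asarray(seeds, dtype=float)
    propagated = np.asarray(propagated, dtype=float)
    if not (len(nodes) == len(seeds) == len(propagated)):
        raise InputError("rank_genes: nodes, seeds and propagated scores must align")
    df = pd.DataFrame(
        {"symbol": list(nodes), "seed_score": seeds, "propagated_score": propagated}
    )
    df = df.sort_values(
        by=["propagated_score", "seed_score", "symbol"],
        ascending=[False, False, True],
        kind="mergesort",
    ).reset_index(drop=True)
    df["rank"] = np.arange(1, len(df) + 1)
    return RankedGeneList(table=df)


def restrict_gold(ranked: RankedGeneList, gold: Iterable[str]) -> set[str]:
    """Intersect the gold set with the ranked universe, logging drops."""
    gold = set(gold)
    universe = set(ranked.symbols)
    kept = gold & universe
    dropped = len(gold) - len(kept)
    if dropped:
        logger.info("gold set: %d gene(s) absent from the network dropped", dropped)
    return kept


def hypergeometric_topk(
    ranked: RankedGeneList, gold: Iterable[str], k: int = DEFAULT_TOP_K
) -> tuple[int, float]:
    """Upper-tail hypergeometric test of the top-k genes.

    Returns ``(overlap, p)`` with ``p = P(X >= overlap)`` for X
    hypergeometric(universe, gold-in-universe, k) — the probability that
    a random size-k draw from the universe hits at least the observed
    number of gold genes.
    """
    universe = len(ranked)
    if k > universe:
        raise InputError(f"k={k} exceeds universe size {universe}")
    gold_in = restrict_gold(ranked, gold)
    if not gold_in:
        logger.warning("hypergeometric_topk: gold set disjoint from universe")
        return 0, 1.0
    overlap = len(set(ranked.top(k)) & gold_in)
    # P(X >= overlap) = sf(overlap - 1)
    p = float(stats.hypergeom.sf(overlap - 1, universe, len(gold_in), k))
    return overlap, min(p, 1.0)


def auroc(ranked: RankedGeneList, gold: Iterable[str]) -> float:
    """AUROC of the propagated scores against the gold labels.

    Computed by the Mann-Whitney identity on the raw propagated scores
    (not the tie-broken ranks): the probability that a uniformly random
    gold gene scores above a uniformly random non-gold gene, ties
    counting one half.
    """
    gold_in = restrict_gold(ranked, gold)
    scores = ranked.table["propagated_score"].to_numpy(dtype=float)
    labels = ranked.table["symbol"].isin(gold_in).to_numpy()
    n_pos = int(labels.sum())
    n_neg = len(labels) - n_pos
    if n_pos == 0 or n_neg == 0:
        raise InputError(
            "auroc: undefined — universe must contain both gold and non-gold genes"
        )
    # midranks give ties half credit
    r = stats.rankdata(scores, method="average")
    u = r[labels].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


@dataclass
class EvaluationReport:
    """Top-k enrichment and AUROC of a ranking against a gold set."""

    k: int
    overlap: int
    universe: int
    gold_in_universe: int
    hypergeom_p: float
    auroc: float

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(asdict(self), indent=2) + "\n"
        if path is not None:
            Path(path).write_text(text)
        return text

    def __str__(self) -> str:
        return (
            f"universe              {self.universe}\n"
            f"gold in universe      {self.gold_in_universe}\n"
            f"top-{self.k} overlap        {self.overlap}\n"
            f"hypergeometric p      {self.hypergeom_p:.3g}\n"
            f"AUROC                 {self.auroc:.4f}"
        )


def evaluate(
    ranked: RankedGeneList, gold: Iterable[str], k: int = DEFAULT_TOP_K
) -> EvaluationReport:
    """Run both metrics and bundle them into an :class:`EvaluationReport`."""
    gold = set(gold)
    gold_in = restrict_gold(ranked, gold)
    overlap, p = hypergeometric_topk(ranked, gold, k=k)
    return EvaluationReport(
        k=k,
        overlap=overlap,
        universe=len(ranked),
        gold_in_universe=len(gold_in),
        hypergeom_p=p,
        auroc=auroc(ranked, gold),
    )


def read_gene_set(path: str | Path) -> set[str]:
    """Read a newline-delimited gene-symbol list (``#`` comments allowed)."""
    symbols = set()
    with open(path) as fh:
        for line in fh:
            s = line.strip()
            if s and not s.startswith("#"):
                symbols.add(s)
    if not symbols:
        raise InputError(f"{path}: empty gene set")
    return symbols
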