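"""Load molecular networks (CX JSON, SIF, edge lists) for propagation.

All inputs normalize to the same contract: an undirected weighted graph
with unique gene-symbol nodes in lexicographic order, no self-loops,
parallel edges collapsed keeping the maximum weight, and isolated nodes
removed (a zero-degree node breaks degree normalization downstream).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import scipy.sparse as sp

from .errors import FormatError, InputError
from .gwas_io import GeneScoreVector

logger = logging.getLogger(__name__)


@dataclass
class PropagationNetwork:
    """Undirected weighted graph aligned with gene symbols.

    ``nodes`` is lexicographically sorted and defines the row/column
    order of the symmetric, zero-diagonal ``adjacency`` matrix.
    """

    nodes: list[str]
    adjacency: sp.csr_matrix
    n_self_loops_dropped: int = 0
    n_isolates_removed: int = 0
    _index: dict[str, int] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self._index = {sym: i for i, sym in enumerate(self.nodes)}

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_edges(self) -> int:
        return self.adjacency.nnz // 2

    @property
    def degree(self) -> np.ndarray:
        """Weighted degree per node, in node order."""
        return np.asarray(self.adjacency.sum(axis=1)).ravel()

    def index_of(self, symbol: str) -> int:
        return self._index[symbol]

    def edges(self) -> Iterable[tuple[str, str, float]]:
        """Yield each undirected edge once, as (u, v, weight) with u < v."""
        coo = sp.triu(self.adjacency, k=1).tocoo()
        for i, j, w in zip(coo.row, coo.col, coo.data):
            yield self.nodes[i], self.nodes[j], float(w)

    def subgraph(self, symbols: Iterable[str]) -> "PropagationNetwork":
        """Induced subgraph on ``symbols`` (missing symbols ignored)."""
        keep = sorted(s for s in symbols if s in self._index)
        idx = np.array([self._index[s] for s in keep], dtype=int)
        sub = self.adjacency[np.ix_(idx, idx)].tocsr() if len(idx) else sp.csr_matrix((0, 0))
        return PropagationNetwork(nodes=keep, adjacency=sub)


def _build_network(
    edge_weights: Mapping[tuple[str, str], float],
    declared_nodes: Iterable[str] | None = None,
) -> PropagationNetwork:
    """Normalize raw edges into a :class:`PropagationNetwork`.

    Collapses parallel/reversed edges keeping max weight, drops
    self-loops, removes isolates, sorts nodes lexicographically.
    """
    collapsed: dict[tuple[str, str], float] = {}
    n_loops = 0
    for (u, v), w in edge_weights.items():
        if u == v:
            n_loops += 1
            continue
        if w <= 0:
            raise InputError(f"edge {u}-{v}: non-positive weight {w}")
        key = (u, v) if u < v else (v, u)
        collapsed[key] = max(w, collapsed.get(key, 0.0))
    if n_loops:
        logger.info("dropped %d self-loop(s)", n_loops)

    connected = set()
    for u, v in collapsed:
        connected.add(u)
        connected.add(v)
    declared = set(declared_nodes) if declared_nodes is not None else set(connected)
    isolates = declared - connected
    if isolates:
        logger.info("removed %d isolated node(s): %s", len(isolates),
                    ", ".join(sorted(isolates)[:10]))
    nodes = sorted(connected)
    index = {s: i for i, s in enumerate(nodes)}
    n = len(nodes)
    rows, cols, data = [], [], []
    for (u, v), w in collapsed.items():
        i, j = index[u], index[v]
        rows += [i, j]
        cols += [j, i]
        data += [w, w]
    adj = sp.csr_matrix((data, (rows, cols)), shape=(n, n))
    return PropagationNetwork(
        nodes=nodes,
        adjacency=adj,
        n_self_loops_dropped=n_loops,
        n_isolates_removed=len(isolates),
    )


def _cx_aspects(raw: object, path: str | Path) -> dict[str, list]:
    """Collect CX aspects from either the list-of-fragments or dict form."""
    aspects: dict[str, list] = {}
    if isinstance(raw, dict):
        for k, v in raw.items():
            if isinstance(v, list):
                aspects.setdefault(k, []).extend(v)
    elif isinstance(raw, list):
        for fragment in raw:
            if not isinstance(fragment, dict):
                continue
            for k, v in fragment.items():
                if isinstance(v, list):
                    aspects.setdefault(k, []).extend(v)
    else:
        raise FormatError(f"{path}: CX document is neither a list nor an object")
    return aspects


def read_cx(
    path: str | Path, edge_weight_attr: str | None = None
) -> PropagationNetwork:
    """Read an NDEx CX JSON network.

    Node names come from the ``n`` attribute of the ``nodes`` aspect;
    edges from the ``edges`` aspect (``s``/``t`` node ids).  Edges are
    undirected, de-duplicated (max weight kept), self-loops dropped.

    Parameters
    ----------
    edge_weight_attr : str, optional
        Name of an ``edgeAttributes`` entry to use as edge weight;
        default treats the network as unweighted (all weights 1).
    """
    with open(path) as fh:
        try:
            raw = json.load(fh)
        except json.JSONDecodeError as exc:
            raise FormatError(f"{path}: invalid JSON: {exc}") from exc
    aspects = _cx_aspects(raw, path)
    if "nodes" not in aspects:
        raise FormatError(f"{path}: CX document lacks a 'nodes' aspect")
    if "edges" not in aspects:
        raise FormatError(f"{path}: CX document lacks an 'edges' aspect")

    id_to_name: dict[int, str] = {}
    for entry in aspects["nodes"]:
        nid = entry.get("@id")
        name = entry.get("n")
        if nid is None or name is None:
            raise FormatError(f"{path}: CX node entry missing '@id' or 'n': {entry}")
        id_to_name[int(nid)] = str(name)

    weights_by_edge_id: dict[int, float] = {}
    if edge_weight_attr is not None:
        for entry in aspects.get("edgeAttributes", []):
            if entry.get("n") == edge_weight_attr:
                try:
                    weights_by_edge_id[int(entry["po"])] = float(entry["v"])
                except (KeyError, TypeError, ValueError) as exc:
                    raise FormatError(
                        f"{path}: bad edgeAttributes entry for {edge_weight_attr!r}: {entry}"
                    ) from exc

    edge_weights: dict[tuple[str, str], float] = {}
    for entry in aspects["edges"]:
        try:
            s, t = int(entry["s"]), int(entry["t"])
        except (KeyError, TypeError, ValueError) as exc:
            raise FormatError(f"{path}: CX edge entry missing 's'/'t': {entry}") from exc
        if s not in id_to_name or t not in id_to_name:
            raise FormatError(
                f"{path}: edge references undeclared node id {s if s not in id_to_name else t}"
            )
        w = weights_by_edge_id.get(int(entry.get("@id", -1)), 1.0)
        u, v = id_to_name[s], id_to_name[t]
        key = (u, v) if u < v else (v, u)
        edge_weights[key] = max(w, edge_weights.get(key, 0.0))
    return _build_network(edge_weights, declared_nodes=id_to_name.values())


def read_edgelist(path: str | Path, weighted: bool = False) -> PropagationNetwork:
    """Read a 2/3-column edge list or SIF file.

    ``#`` comment lines are skipped.  Three-column lines are read as
    ``source weight?`` when ``weighted`` is set, otherwise as SIF
    ``source interaction target``.
    """
    edge_weights: dict[tuple[str, str], float] = {}
    n_rows = 0
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) == 2:
                u, v, w = parts[0], parts[1], 1.0
            elif len(parts) == 3:
                if weighted:
                    u, v = parts[0], parts[1]
                    try:
                        w = float(parts[2])
                    except ValueError as exc:
                        raise InputError(
                            f"{path}:{lineno}: non-numeric weight {parts[2]!r}"
                        ) from exc
                else:
                    u, _interaction, v = parts  # SIF dialect
                    w = 1.0
            else:
                raise FormatError(f"{path}:{lineno}: expected 2 or 3 columns, got {len(parts)}")
            n_rows += 1
            key = (u, v) if u <= v else (v, u)
            edge_weights[key] = max(w, edge_weights.get(key, 0.0))
    if n_rows == 0:
        raise InputError(f"{path}: no edges found")
    return _build_network(edge_weights)


@dataclass(frozen=True)
class CoverageReport:
    """Overlap between scored genes and network nodes."""

    scored_in_network: int
    scored_not_in_network: int
    unscored_in_network: int


def align_scores(
    network: PropagationNetwork, scores: GeneScoreVector
) -> tuple[np.ndarray, CoverageReport]:
    """Project gene scores onto the network's node order.

    Entry ``i`` of the returned seed vector is the score of node ``i``'s
    symbol, 0 when the symbol is unscored.  Symbols are matched exactly
    and case-sensitively; the coverage report surfaces namespace
    mismatches.
    """
    if network.n_nodes == 0:
        raise InputError("align_scores: empty network")
    seed = np.zeros(network.n_nodes)
    hit = 0
    for sym, val in scores.entries.items():
        i = network._index.get(sym)
        if i is not None:
            seed[i] = val
            hit += 1
    report = CoverageReport(
        scored_in_network=hit,
        scored_not_in_network=len(scores.entries) - hit,
        unscored_in_network=network.n_nodes - hit,
    )
    if hit == 0:
        raise InputError(
            "align_scores: no scored gene appears in the network — "
            "likely an identifier-namespace mismatch"
        )
    logger.info(
        "align_scores: %d scored genes in network, %d scored genes absent, "
        "%d network genes unscored",
        report.scored_in_network, report.scored_not_in_network,
        report.unscored_in_network,
    )
    return seed, report


def write_sif(network: PropagationNetwork, path: str | Path,
              interaction: str = "pp") -> None:
    """Write the network as SIF; isolated nodes cannot occur by contract."""
    with open(path, "w") as fh:
        for u, v, _w in network.edges():
            fh.write(f"{u}\t{interaction}\t{v}\n")


def write_cx(
    network: PropagationNetwork,
    path: str | Path,
    node_attributes: Mapping[str, Mapping[str, object]] | None = None,
) -> None:
    """Write the network as CX JSON with an optional nodeAttributes aspect.

    ``node_attributes`` maps symbol -> {attribute name -> value}.
    """
    node_ids = {sym: i for i, sym in enumerate(network.nodes)}
    nodes_aspect = [{"@id": node_ids[s], "n": s} for s in network.nodes]
    edges_aspect = []
    edge_attr_aspect = []
    for eid, (u, v, w) in enumerate(network.edges()):
        edges_aspect.append({"@id": eid, "s": node_ids[u], "t": node_ids[v], "i": "pp"})
        if w != 1.0:
            edge_attr_aspect.append({"po": eid, "n": "weight", "v": w, "d": "double"})
    document: list[dict] = [
        {"numberVerification": [{"longNumber": 2**48}]},
        {"metaData": [
            {"name": "nodes", "elementCount": len(nodes_aspect)},
            {"name": "edges", "elementCount": len(edges_aspect)},
        ]},
        {"nodes": nodes_aspect},
        {"edges": edges_aspect},
    ]
    if edge_attr_aspect:
        document.append({"edgeAttributes": edge_attr_aspect})
    if node_attributes:
        na = []
        for sym, attrs in node_attributes.items():
            if sym not in node_ids:
                continue
            for name, value in attrs.items():
                dtype = ("boolean" if isinstance(value, bool)
                         else "integer" if isinstance(value, (int, np.integer))
                         else "double" if isinstance(value, (float, np.floating))
                         else "string")
                if isinstance(value, (np.integer, np.floating)):
                    value = value.item()
                na.append({"po": node_ids[sym], "n": name, "v": value, "d": dtype})
        document.append({"nodeAttributes": na})
    document.append({"status": [{"error": "", "success": True}]})
    with open(path, "w") as fh:
        json.dump(document, fh, indent=1)
        fh.write("\n")
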