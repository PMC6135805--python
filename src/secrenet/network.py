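"""Protein–protein interaction network loading and first-neighbor expansion.

Seed proteins from the secretome funnel are expanded to their potential
interaction partners — the direct neighbors in a confidence-weighted PPI
network such as HIPPIE. Only first neighbors are used; no diffusion or
multi-hop propagation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import networkx as nx
import pandas as pd

from .proteomics import normalize_identifiers

logger = logging.getLogger(__name__)


class PPINetwork:
    """Undirected simple graph over gene symbols with per-edge confidence."""

    def __init__(self, graph: nx.Graph | None = None):
        self.graph = graph if graph is not None else nx.Graph()

    @property
    def nodes(self) -> set[str]:
        return set(self.graph.nodes)

    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def add_edge(self, a: str, b: str, confidence: float, evidence: str = "") -> bool:
        """Add an edge, dropping self-loops and keeping the max confidence of
        duplicates. Returns True if a new edge was created."""
        if a == b:
            return False
        if not (0.0 <= confidence <= 1.0):
            raise ValueError(f"confidence {confidence} outside [0, 1] for edge {a}-{b}")
        if self.graph.has_edge(a, b):
            if confidence > self.graph[a][b]["confidence"]:
                self.graph[a][b]["confidence"] = confidence
                if evidence:
                    self.graph[a][b]["evidence"] = evidence
            return False
        self.graph.add_edge(a, b, confidence=confidence, evidence=evidence)
        return True

    def neighbors(self, node: str) -> set[str]:
        return set(self.graph.neighbors(node))

    def degree(self, node: str) -> int:
        return self.graph.degree(node)

    def edge_table(self) -> pd.DataFrame:
        rows = [
            {"node_a": min(a, b), "node_b": max(a, b), "confidence": d["confidence"]}
            for a, b, d in self.graph.edges(data=True)
        ]
        return (
            pd.DataFrame(rows, columns=["node_a", "node_b", "confidence"])
            .sort_values(["node_a", "node_b"])
            .reset_index(drop=True)
        )


@dataclass
class ExpansionResult:
    """First-neighbor expansion of a seed protein set."""

    per_seed: dict[str, set[str]]
    union_partners: set[str] = field(default_factory=set)
    unmatched_seeds: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.union_partners = set().union(*self.per_seed.values()) if self.per_seed else set()

    def n_interactions(self) -> int:
        """Total number of seed–partner pairs (potential PPI)."""
        return sum(len(v) for v in self.per_seed.values())

    def to_dict(self) -> dict:
        return {
            "per_seed": {s: sorted(v) for s, v in sorted(self.per_seed.items())},
            "union_partners": sorted(self.union_partners),
            "unmatched_seeds": sorted(self.unmatched_seeds),
        }


def load_network(
    path: str | Path,
    dialect: str = "edgelist",
    min_confidence: float = 0.0,
    mapping: Mapping[str, str] | None = None,
) -> PPINetwork:
    """Read a PPI network from a HIPPIE-style TSV or a generic edge list.

    ``hippie`` rows are tab-separated (entry-name, entrez-id, entry-name,
    entrez-id, confidence, evidence) with no header; ``edgelist`` rows are
    (node_a, node_b, confidence) with an optional header line. Identifiers
    are normalized to gene symbols (HIPPIE entry-name suffixes like
    ``_HUMAN`` are stripped), edges below ``min_confidence`` and self-loops
    are dropped, and duplicate edges keep the maximum confidence.
    """
    if dialect not in {"hippie", "edgelist"}:
        raise ValueError(f"unknown dialect {dialect!r}")
    net = PPINetwork()
    n_below, n_self, n_dup = 0, 0, 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if dialect == "hippie":
                if len(parts) < 5:
                    raise ValueError(f"{path}: malformed HIPPIE row at line {lineno}")
                raw_a, raw_b, conf_s = parts[0], parts[2], parts[4]
                evidence = parts[5] if len(parts) > 5 else ""
                raw_a = raw_a.split("_")[0]
                raw_b = raw_b.split("_")[0]
            else:
                if len(parts) < 3:
                    raise ValueError(f"{path}: malformed edge-list row at line {lineno}")
                raw_a, raw_b, conf_s = parts[0], parts[1], parts[2]
                evidence = ""
            if lineno == 1 and dialect == "edgelist":
                try:
                    float(conf_s)
                except ValueError:
                    continue  # header line
            try:
                conf = float(conf_s)
            except ValueError as exc:
                raise ValueError(
                    f"{path}: non-numeric confidence {conf_s!r} at line {lineno}"
                ) from exc
            (a,) = normalize_identifiers([raw_a], mapping)
            (b,) = normalize_identifiers([raw_b], mapping)
            if a == b:
                n_self += 1
                continue
            if conf < min_confidence:
                n_below += 1
                continue
            if not net.add_edge(a, b, conf, evidence):
                n_dup += 1
    if n_self:
        logger.warning("dropped %d self-loop rows", n_self)
    logger.info(
        "loaded %d nodes / %d edges (%d below confidence %.2f, %d duplicates merged)",
        len(net.nodes), net.n_edges(), n_below, min_confidence, n_dup,
    )
    if net.n_edges() == 0 and n_self == 0:
        raise ValueError(f"{path}: empty network")
    return net


def filter_confidence(network: PPINetwork, min_confidence: float) -> PPINetwork:
    """Return a copy keeping only edges with confidence >= min_confidence."""
    out = PPINetwork()
    for a, b, d in network.graph.edges(data=True):
        if d["confidence"] >= min_confidence:
            out.add_edge(a, b, d["confidence"], d.get("evidence", ""))
    return out


def expand(
    network: PPINetwork,
    seeds: Iterable[str],
    include_seed_partners: bool = True,
) -> ExpansionResult:
    """First-neighbor expansion of seed proteins.

    Seeds absent from the network are listed in ``unmatched_seeds`` rather
    than silently dropped. With ``include_seed_partners=False``, other seed
    proteins are removed from each partner set.
    """
    seed_set = set(seeds)
    if not seed_set:
        raise ValueError("empty seed set")
    per_seed: dict[str, set[str]] = {}
    unmatched: list[str] = []
    for s in sorted(seed_set):
        if s not in network.nodes:
            unmatched.append(s)
            continue
        partners = network.neighbors(s)
        if not include_seed_partners:
            partners -= seed_set
        per_seed[s] = partners
    if unmatched:
        logger.warning("%d seeds not found in the network: %s",
                       len(unmatched), ", ".join(unmatched[:10]))
    return ExpansionResult(per_seed=per_seed, unmatched_seeds=unmatched)


def degree_summary(network: PPINetwork) -> pd.DataFrame:
    """Per-node degree table, ordered by (-degree, symbol)."""
    rows = [{"node": n, "degree": network.degree(n)} for n in network.nodes]
    df = pd.DataFrame(rows, columns=["node", "degree"])
    return (
        df.sort_values(["degree", "node"], ascending=[False, True])
        .reset_index(drop=True)
    )
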