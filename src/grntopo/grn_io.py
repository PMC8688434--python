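"""Parsing and assembly of regulator→target interaction lists into gene networks.

A gene regulatory network (GRN) arrives as a delimited text file with one
directed regulator→target interaction per row, optionally carrying a free-text
evidence label (e.g. ``confirmed``).  Interactions are filtered on that label,
deduplicated, and assembled into an *undirected* simple graph: directionality
is consumed only to assign each gene a role (``regulator``, ``target`` or
``both``) and is then discarded for all topology computations.  The directed
interaction list is kept on the network object for provenance.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx

logger = logging.getLogger(__name__)

ROLE_REGULATOR = "regulator"
ROLE_TARGET = "target"
ROLE_BOTH = "both"


class GrnIOError(Exception):
    """Base error for interaction parsing and network assembly."""


class ParseError(GrnIOError):
    """A row could not be parsed; message names the offending line."""


class EmptyNetworkError(GrnIOError):
    """No interactions survived parsing/filtering."""


@dataclass(frozen=True)
class RegulatoryInteraction:
    """One directed regulator→target record.

    Attributes
    ----------
    regulator : str
        Non-empty gene identifier of the regulating gene (e.g. a TF).
    target : str
        Non-empty gene identifier of the regulated gene.
    evidence : str or None
        Optional free-text evidence label from the source resource.
    """

    regulator: str
    target: str
    evidence: str | None = None

    def __post_init__(self) -> None:
        if not self.regulator or not self.target:
            raise ValueError("regulator and target identifiers must be non-empty")

    @property
    def is_self_loop(self) -> bool:
        return self.regulator == self.target


@dataclass
class GeneNetwork:
    """Undirected simple graph over genes, each gene carrying a role.

    A gene's role is ``both`` iff it appears at least once as regulator AND at
    least once as target in the source interactions; ``regulator`` iff it only
    regulates; ``target`` iff it is only regulated.  Self-loop interactions are
    recorded separately and excluded from the edge set (they would distort
    neighbor-degree statistics such as K_nn).
    """

    graph: nx.Graph
    roles: dict[str, str]
    name: str = "grn"
    interactions: list[RegulatoryInteraction] = field(default_factory=list)
    self_loops: list[str] = field(default_factory=list)

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def genes_with_role(self, role: str) -> list[str]:
        return sorted(g for g, r in self.roles.items() if r == role)

    def role_counts(self) -> dict[str, int]:
        counts = {ROLE_REGULATOR: 0, ROLE_TARGET: 0, ROLE_BOTH: 0}
        for r in self.roles.values():
            counts[r] += 1
        return counts

    def summary(self) -> dict[str, int]:
        c = self.role_counts()
        return {
            "nodes": self.n_nodes,
            "edges": self.n_edges,
            "regulators": c[ROLE_REGULATOR],
            "targets": c[ROLE_TARGET],
            "both": c[ROLE_BOTH],
        }


def _clean(token: str, casefold: bool) -> str:
    token = token.strip()
    return token.casefold() if casefold else token


def parse_interactions(
    path: str | Path,
    column_map: Mapping[str, int | str] | None = None,
    filter_spec: Iterable[str] | None = None,
    *,
    delimiter: str = "\t",
    header: bool = False,
    casefold: bool = True,
) -> list[RegulatoryInteraction]:
    """Read a delimited edge list into deduplicated interactions.

    Parameters
    ----------
    path
        Edge-list text file, one interaction per row.
    column_map
        Maps the keys ``"regulator"``, ``"target"`` and optionally
        ``"evidence"`` to column indices (or header names when ``header``).
        Defaults to columns 0/1 and, if present, 2.
    filter_spec
        Evidence keep-list; when given, only rows whose evidence is in it are
        retained.  A gene pair is kept if *any* of its rows passes the filter.
    delimiter, header, casefold
        Input dialect; ``casefold`` lower-cases and strips identifiers.

    Returns
    -------
    list of RegulatoryInteraction
        Duplicates collapsed to the first occurrence, row order preserved.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"interaction file not found: {path}")
    column_map = dict(column_map or {"regulator": 0, "target": 1})
    keep = {_clean(e, casefold) for e in filter_spec} if filter_spec is not None else None

    lines = path.read_text().splitlines()
    start = 0
    if header:
        if not lines:
            raise ParseError(f"{path}: empty file, expected a header row")
        head = [h.strip() for h in lines[0].split(delimiter)]
        resolved: dict[str, int] = {}
        for key, col in column_map.items():
            if isinstance(col, str):
                if col not in head:
                    raise ParseError(f"{path}: header column {col!r} not found")
                resolved[key] = head.index(col)
            else:
                resolved[key] = col
        column_map = resolved
        start = 1

    reg_col = int(column_map["regulator"])
    tar_col = int(column_map["target"])
    evi_col = column_map.get("evidence")

    seen: set[tuple[str, str]] = set()
    out: list[RegulatoryInteraction] = []
    for lineno, line in enumerate(lines[start:], start=start + 1):
        if not line.strip():
            continue
        fields = line.split(delimiter)
        try:
            regulator = _clean(fields[reg_col], casefold)
            targ = _clean(fields[tar_col], casefold)
        except IndexError:
            raise ParseError(
                f"{path}: line {lineno}: missing regulator or target field"
            ) from None
        if not regulator or not targ:
            raise ParseError(f"{path}: line {lineno}: empty regulator or target field")
        evidence = None
        if evi_col is not None and int(evi_col) < len(fields):
            evidence = _clean(fields[int(evi_col)], casefold)
        if keep is not None and (evidence is None or evidence not in keep):
            continue
        key = (regulator, targ)
        if key in seen:
            continue
        seen.add(key)
        out.append(RegulatoryInteraction(regulator, targ, evidence))

    if not out:
        raise EmptyNetworkError(
            f"{path}: no interactions left after parsing/filtering"
        )
    return out


def build_network(
    interactions: Sequence[RegulatoryInteraction], name: str = "grn"
) -> GeneNetwork:
    """Assemble interactions into an undirected, role-labeled :class:`GeneNetwork`.

    One node per distinct gene, one edge per distinct unordered pair;
    reciprocal pairs (A→B and B→A) collapse to a single edge and both genes
    become role ``both``.  Self-loops are flagged and excluded from the edge
    set; the lonely gene is still registered as a node.
    """
    if not interactions:
        raise EmptyNetworkError("cannot build a network from an empty interaction list")

    graph = nx.Graph()
    as_regulator: set[str] = set()
    as_target: set[str] = set()
    self_loops: list[str] = []
    for it in interactions:
        as_regulator.add(it.regulator)
        as_target.add(it.target)
        if it.is_self_loop:
            self_loops.append(it.regulator)
            graph.add_node(it.regulator)
            logger.warning("self-loop on gene %s excluded from the edge set", it.regulator)
            continue
        graph.add_edge(it.regulator, it.target)

    roles: dict[str, str] = {}
    for gene in graph.nodes:
        reg = gene in as_regulator
        tar = gene in as_target
        roles[gene] = ROLE_BOTH if (reg and tar) else (ROLE_REGULATOR if reg else ROLE_TARGET)

    net = GeneNetwork(
        graph=graph,
        roles=roles,
        name=name,
        interactions=list(interactions),
        self_loops=self_loops,
    )
    logger.info("built network %s: %s", name, net.summary())
    return net


def load_network(
    path: str | Path,
    name: str | None = None,
    **parse_kwargs,
) -> GeneNetwork:
    """Convenience wrapper: :func:`parse_interactions` then :func:`build_network`."""
    path = Path(path)
    interactions = parse_interactions(path, **parse_kwargs)
    return build_network(interactions, name=name or path.stem)


def write_edge_list(network: GeneNetwork, path: str | Path) -> None:
    """Write the directed interaction list as a TSV (regulator, target, evidence)."""
    with open(path, "w") as fh:
        for it in network.interactions:
            fh.write(f"{it.regulator}\t{it.target}\t{it.evidence or ''}\n")


def write_roles(network: GeneNetwork, path: str | Path) -> None:
    """Write a gene_id → role TSV."""
    with open(path, "w") as fh:
        fh.write("gene_id\trole\n")
        for gene in sorted(network.roles):
            fh.write(f"{gene}\t{network.roles[gene]}\n")


def write_graphml(network: GeneNetwork, path: str | Path) -> None:
    g = network.graph.copy()
    nx.set_node_attributes(g, network.roles, "role")
    nx.write_graphml(g, path)
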