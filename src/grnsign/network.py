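"""Signed, directed gene regulatory networks.

A regulatory network is a directed graph whose nodes are genes and whose
edges are transcription-factor → target interactions carrying a sign:
+1 for activation, -1 for repression.  This module holds the in-memory
representation, the edge-list readers/writers, and the small structural
queries the consistency analysis needs (degree profiles, single-regulator
targets, operon expansion).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, NamedTuple

ACTIVATION = 1
REPRESSION = -1

_ROLE_MAP = {
    "activation": ACTIVATION,
    "activator": ACTIVATION,
    "+": ACTIVATION,
    "+1": ACTIVATION,
    "1": ACTIVATION,
    "repression": REPRESSION,
    "repressor": REPRESSION,
    "-": REPRESSION,
    "−": REPRESSION,  # unicode minus
    "-1": REPRESSION,
}


class Edge(NamedTuple):
    regulator: str
    target: str
    sign: int


class NetworkParseError(ValueError):
    """A line of an edge-list file could not be interpreted."""


class NetworkValidationError(ValueError):
    """The edge set violates a structural invariant."""


@dataclass
class RegulatoryNetwork:
    """A validated signed directed regulatory network.

    ``edges`` holds at most one edge per (regulator, target) pair; every
    endpoint is listed in ``nodes``.  ``conflicting_pairs`` records
    (regulator, target) pairs that carried both signs in the input and were
    quarantined under permissive parsing.  ``operon_map`` maps a target gene
    to its operon id; see :meth:`expand_operons`.
    """

    nodes: set[str]
    edges: list[Edge]
    operon_map: dict[str, str] = field(default_factory=dict)
    conflicting_pairs: list[tuple[str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        seen: dict[tuple[str, str], int] = {}
        deduped: list[Edge] = []
        conflicts: list[tuple[str, str]] = []
        for e in self.edges:
            if e.sign not in (ACTIVATION, REPRESSION):
                raise NetworkValidationError(f"edge {e} has sign {e.sign!r}, expected +1 or -1")
            key = (e.regulator, e.target)
            if key in seen:
                if seen[key] != e.sign and key not in conflicts:
                    conflicts.append(key)
                continue
            seen[key] = e.sign
            deduped.append(e)
        if conflicts:
            raise NetworkValidationError(
                "conflicting signs for regulator-target pair(s): "
                + ", ".join(f"({r}, {t})" for r, t in conflicts)
            )
        self.edges = deduped
        self.nodes = set(self.nodes)
        for e in self.edges:
            self.nodes.add(e.regulator)
            self.nodes.add(e.target)

    # -- structural queries -------------------------------------------------

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def regulators(self) -> set[str]:
        """Genes with out-degree >= 1 (the TF set)."""
        return {e.regulator for e in self.edges}

    def targets(self) -> set[str]:
        return {e.target for e in self.edges}

    def self_loops(self) -> list[Edge]:
        return [e for e in self.edges if e.regulator == e.target]

    def expand_operons(self) -> "RegulatoryNetwork":
        """Propagate each operon's regulatory edges to all member genes.

        Every gene mapped to an operon inherits the edges whose target is any
        gene of that operon; assessment stays per-gene.  Without an operon map
        this is the identity.
        """
        if not self.operon_map:
            return self
        members: dict[str, set[str]] = {}
        for gene, operon in self.operon_map.items():
            members.setdefault(operon, set()).add(gene)
        new_edges: list[Edge] = []
        seen: set[tuple[str, str]] = set()
        for e in self.edges:
            genes = members.get(self.operon_map.get(e.target, ""), {e.target})
            for g in sorted(genes | {e.target}):
                key = (e.regulator, g)
                if key not in seen:
                    seen.add(key)
                    new_edges.append(Edge(e.regulator, g, e.sign))
        return RegulatoryNetwork(set(self.nodes), new_edges, dict(self.operon_map))


@dataclass(frozen=True)
class DegreeProfile:
    """Per-node out- and in-degree; the invariant a rewiring null preserves."""

    out_degree: Mapping[str, int]
    in_degree: Mapping[str, int]

    @property
    def n_edges(self) -> int:
        return sum(self.out_degree.values())


def degree_profile(net: RegulatoryNetwork) -> DegreeProfile:
    out_d = {n: 0 for n in net.nodes}
    in_d = {n: 0 for n in net.nodes}
    for e in net.edges:
        out_d[e.regulator] += 1
        in_d[e.target] += 1
    assert sum(out_d.values()) == sum(in_d.values()) == net.n_edges
    return DegreeProfile(out_d, in_d)


def single_regulator_targets(net: RegulatoryNetwork) -> set[str]:
    """Targets regulated by exactly one TF (unambiguous regulation)."""
    in_d = degree_profile(net).in_degree
    return {t for t in net.targets() if in_d[t] == 1}


# -- parsing ---------------------------------------------------------------


def parse_role(token: str) -> int:
    try:
        return _ROLE_MAP[token.strip().lower()]
    except KeyError:
        raise NetworkParseError(f"unknown interaction role {token!r}") from None


def read_edge_list(
    path: str | Path,
    dialect: str = "tsv",
    permissive: bool = False,
) -> RegulatoryNetwork:
    """Read a signed edge list.

    ``tsv`` dialect: header line, then ``regulator<TAB>target<TAB>role``
    with an optional 4th column ``operon`` (the target's operon id).
    ``sif`` dialect: no header, ``regulator<TAB>role<TAB>target``.
    Role strings are mapped case-insensitively; ``#`` lines are comments.
    Duplicate pairs with one sign are deduplicated; pairs carrying both signs
    abort, or are quarantined (and reported) when ``permissive`` is set.
    """
    if dialect not in ("tsv", "sif"):
        raise ValueError(f"unknown dialect {dialect!r}")
    path = Path(path)
    edges: list[Edge] = []
    operon_map: dict[str, str] = {}
    with path.open() as fh:
        lines = fh.readlines()
    for lineno, raw in enumerate(lines, start=1):
        if dialect == "tsv" and lineno == 1:
            continue
        line = raw.rstrip("\n")
        if not line.strip() or line.lstrip().startswith("#"):
            continue
        cols = line.split("\t")
        if len(cols) < 3:
            raise NetworkParseError(f"{path}:{lineno}: expected >=3 tab-separated columns")
        if dialect == "tsv":
            reg, tgt, role = cols[0], cols[1], cols[2]
            if len(cols) >= 4 and cols[3].strip():
                operon_map[tgt] = cols[3].strip()
        else:
            reg, role, tgt = cols[0], cols[1], cols[2]
        try:
            sign = parse_role(role)
        except NetworkParseError as err:
            raise NetworkParseError(f"{path}:{lineno}: {err}") from None
        edges.append(Edge(reg.strip(), tgt.strip(), sign))

    if not permissive:
        return RegulatoryNetwork(set(), edges, operon_map)

    # permissive: quarantine conflicting pairs instead of aborting
    signs_by_pair: dict[tuple[str, str], set[int]] = {}
    for e in edges:
        signs_by_pair.setdefault((e.regulator, e.target), set()).add(e.sign)
    conflicts = sorted(k for k, v in signs_by_pair.items() if len(v) > 1)
    kept = [e for e in edges if (e.regulator, e.target) not in set(conflicts)]
    nodes = {g for e in edges for g in (e.regulator, e.target)}
    net = RegulatoryNetwork(nodes, kept, operon_map)
    net.conflicting_pairs = list(conflicts)
    return net


def write_edge_list(net: RegulatoryNetwork, path: str | Path) -> None:
    """Write the tsv dialect (inverse of :func:`read_edge_list`)."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write("regulator\ttarget\trole\toperon\n")
        for e in sorted(net.edges):
            role = "activation" if e.sign == ACTIVATION else "repression"
            operon = net.operon_map.get(e.target, "")
            fh.write(f"{e.regulator}\t{e.target}\t{role}\t{operon}\n")


def topological_order(net: RegulatoryNetwork) -> list[str]:
    """Nodes ordered so every regulator precedes its targets.

    Raises ``ValueError`` on a cyclic network (self-loops included).
    """
    from graphlib import CycleError, TopologicalSorter

    # insert in sorted order so the returned order is stable across
    # processes (set iteration depends on the interpreter hash seed)
    ts: TopologicalSorter[str] = TopologicalSorter()
    for n in sorted(net.nodes):
        ts.add(n)
    for e in sorted(net.edges):
        ts.add(e.target, e.regulator)
    try:
        return list(ts.static_order())
    except CycleError as err:
        raise ValueError(f"network contains a cycle: {err.args[1]}") from None
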