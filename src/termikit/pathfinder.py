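"""Path finding in the protease web.

Proteases, their inhibitors and their substrates form a directed network —
the protease web — in which a protease acts on downstream substrates not
only directly but also by cleaving other proteases or by cleaving and so
inactivating protease inhibitors.  Given a candidate protease and a list
of observed substrates (with cleavage positions), this module builds the
web from knowledgebase cleavage and inhibition events, dynamically extends
it with hypothesized edges from the candidate to the listed proteins, and
enumerates every mechanistically meaningful path from the candidate to
each substrate.

Path grammar
------------
A path is a node-simple sequence of typed directed edges starting at the
query protease.  The first edge is a cleavage; a cleavage edge may be
followed by another cleavage (the cleaved protease acts) or by an
inhibition edge out of the cleaved protein (the cleaved inhibitor's
inhibition is the next link); an inhibition edge must be followed by a
cleavage by the inhibited protease; and the final edge is a cleavage into
the target whose position matches the observed terminus (P1 convention)
within the position window.  A path consisting solely of the single
hypothesized query→target edge is reported separately as
"hypothesized-direct" — an explanation must contain at least one
knowledgebase edge.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Optional, Sequence

import networkx as nx
import pandas as pd

from .kb import Knowledgebase
from .analysis import QueryPeptide, locate_terminus, classify_terminus

__all__ = [
    "CleaveEdge",
    "InhibitEdge",
    "ProteaseWeb",
    "PathQuery",
    "PathTarget",
    "ExplanationPath",
    "PathSearchResult",
    "PathfinderError",
    "build_web",
    "extend_with_query",
    "find_paths",
    "map_orthologs",
    "to_dot",
    "run_pathfinder",
    "MAX_PATHS_PER_TARGET",
]

MAX_PATHS_PER_TARGET = 10_000


class PathfinderError(Exception):
    pass


@dataclass(frozen=True, order=True)
class CleaveEdge:
    source: str
    target: str
    p1_position: int
    origin: str = "kb"  # kb | inferred

    kind = "cleave"


@dataclass(frozen=True, order=True)
class InhibitEdge:
    source: str
    target: str
    origin: str = "kb"

    kind = "inhibit"


@dataclass(frozen=True)
class ProteaseWeb:
    """Typed directed multigraph over protein accessions."""

    cleave_edges: frozenset[CleaveEdge]
    inhibit_edges: frozenset[InhibitEdge]

    @property
    def nodes(self) -> frozenset[str]:
        out = set()
        for e in self.cleave_edges:
            out.update((e.source, e.target))
        for e in self.inhibit_edges:
            out.update((e.source, e.target))
        return frozenset(out)

    def roles(self) -> dict[str, set[str]]:
        """protease: ≥1 outgoing KB cleavage; inhibitor: ≥1 outgoing KB
        inhibition; substrate_only otherwise."""
        roles: dict[str, set[str]] = {n: set() for n in self.nodes}
        for e in self.cleave_edges:
            if e.origin == "kb":
                roles[e.source].add("protease")
        for e in self.inhibit_edges:
            roles[e.source].add("inhibitor")
        for n, r in roles.items():
            if not r:
                r.add("substrate_only")
        return roles

    def out_edges(self, node: str) -> list:
        return sorted(
            [e for e in self.cleave_edges if e.source == node],
        ) + sorted(
            [e for e in self.inhibit_edges if e.source == node],
        )

    def to_networkx(self) -> nx.MultiDiGraph:
        g = nx.MultiDiGraph()
        for e in sorted(self.cleave_edges):
            g.add_edge(e.source, e.target, kind="cleave",
                       p1_position=e.p1_position, origin=e.origin)
        for e in sorted(self.inhibit_edges):
            g.add_edge(e.source, e.target, kind="inhibit", origin=e.origin)
        return g


@dataclass(frozen=True)
class PathTarget:
    accession: str
    position: Optional[int] = None  # observed terminal residue, 1-based
    terminus_type: str = "N"
    approximate_position: bool = False  # set when carried across species


@dataclass(frozen=True)
class PathQuery:
    protease_accession: str
    targets: tuple[PathTarget, ...]
    species: Optional[str] = None
    cross_species: bool = False
    max_length: int = 4
    position_window: int = 0
    any_position: bool = False


@dataclass(frozen=True)
class ExplanationPath:
    edges: tuple

    @property
    def length(self) -> int:
        return len(self.edges)

    @property
    def is_direct(self) -> bool:
        return self.length == 1

    @property
    def contains_inferred(self) -> bool:
        return any(e.origin == "inferred" for e in self.edges)

    @property
    def nodes(self) -> tuple[str, ...]:
        return (self.edges[0].source,) + tuple(e.target for e in self.edges)

    def sort_key(self):
        return (self.length, self.nodes,
                tuple(getattr(e, "p1_position", -1) for e in self.edges))


@dataclass
class PathSearchResult:
    explanations: dict[str, list[ExplanationPath]]
    hypothesized_direct: dict[str, list[ExplanationPath]]
    truncated: dict[str, bool] = field(default_factory=dict)

    def all_paths(self) -> list[ExplanationPath]:
        out = []
        for paths in self.explanations.values():
            out.extend(paths)
        for paths in self.hypothesized_direct.values():
            out.extend(paths)
        return out


# ---------------------------------------------------------------------------

def build_web(kb: Knowledgebase, species: Optional[str] = None) -> ProteaseWeb:
    """Construct the protease web from all cleavage and inhibition events.

    ``species`` restricts cleavages to events of that species and
    inhibitions to those whose inhibitor and protease proteins belong to
    it.  Duplicate edges collapse (frozenset semantics).
    """
    cleave = set()
    for c in kb.cleavages:
        if species is not None and c.species != species:
            continue
        cleave.add(CleaveEdge(c.protease_accession, c.substrate_accession,
                              c.p1_position, "kb"))
    inhibit = set()
    for i in kb.inhibitions:
        if species is not None:
            a = kb.protein(i.inhibitor_accession)
            b = kb.protein(i.protease_accession)
            if a is None or b is None or a.species != species or b.species != species:
                continue
        inhibit.add(InhibitEdge(i.inhibitor_accession, i.protease_accession, "kb"))
    return ProteaseWeb(frozenset(cleave), frozenset(inhibit))


def implied_p1(position: int, terminus_type: str) -> int:
    """P1 index of the cleavage that would create the observed terminus."""
    return position - 1 if terminus_type == "N" else position


def extend_with_query(web: ProteaseWeb, query: PathQuery) -> ProteaseWeb:
    """Add a hypothesized cleavage edge from the query protease to each
    target at its observed position; the input web is not modified.

    An identical knowledgebase edge takes precedence (stays origin ``kb``);
    self-edges (target == query protease) are never added.
    """
    existing = {(e.source, e.target, e.p1_position) for e in web.cleave_edges}
    new_edges = set(web.cleave_edges)
    for t in query.targets:
        if t.accession == query.protease_accession:
            continue
        p1 = implied_p1(t.position, t.terminus_type) if t.position is not None else 0
        if (query.protease_accession, t.accession, p1) in existing:
            continue
        new_edges.add(CleaveEdge(query.protease_accession, t.accession,
                                 p1, "inferred"))
    return ProteaseWeb(frozenset(new_edges), web.inhibit_edges)


def _final_edge_matches(edge: CleaveEdge, target: PathTarget,
                        query: PathQuery) -> bool:
    if edge.target != target.accession:
        return False
    if edge.origin == "inferred":
        return True  # placed at the observed position by construction
    if query.any_position or target.position is None:
        return True
    want = implied_p1(target.position, target.terminus_type)
    return abs(edge.p1_position - want) <= query.position_window


def find_paths(web: ProteaseWeb, query: PathQuery) -> PathSearchResult:
    """Enumerate every grammar-valid node-simple path of length ≤
    ``max_length`` from the query protease to each target.

    Exhaustive depth-first enumeration; beyond
    :data:`MAX_PATHS_PER_TARGET` paths a target's list is truncated and
    flagged.  Paths are returned in a deterministic order (length, then
    node sequence, then positions).
    """
    if query.max_length < 1:
        raise ValueError("max_length must be >= 1")
    if query.protease_accession not in web.nodes:
        raise PathfinderError(
            f"query protease {query.protease_accession!r} absent from the web")

    targets_by_acc: dict[str, list[PathTarget]] = {}
    for t in query.targets:
        targets_by_acc.setdefault(t.accession, []).append(t)

    explanations: dict[str, list[ExplanationPath]] = {t.accession: []
                                                      for t in query.targets}
    hypothesized: dict[str, list[ExplanationPath]] = {t.accession: []
                                                      for t in query.targets}
    truncated: dict[str, bool] = {t.accession: False for t in query.targets}

    def record(path: tuple, acc: str) -> None:
        p = ExplanationPath(path)
        bucket = (hypothesized if (p.length == 1 and
                                   path[0].origin == "inferred")
                  else explanations)
        if len(bucket[acc]) >= MAX_PATHS_PER_TARGET:
            truncated[acc] = True
            return
        bucket[acc].append(p)

    def dfs(node: str, visited: frozenset[str], path: tuple,
            last_kind: Optional[str]) -> None:
        if len(path) == query.max_length:
            return
        for edge in web.out_edges(node):
            if edge.target in visited:
                continue
            if last_kind is None and edge.kind != "cleave":
                continue  # a path opens with a cleavage by the query protease
            if last_kind == "inhibit" and edge.kind != "cleave":
                continue  # the inhibited protease must act next
            new_path = path + (edge,)
            if edge.kind == "cleave" and edge.target in targets_by_acc:
                for t in targets_by_acc[edge.target]:
                    if _final_edge_matches(edge, t, query):
                        record(new_path, edge.target)
                        break
            dfs(edge.target, visited | {edge.target}, new_path, edge.kind)

    dfs(query.protease_accession, frozenset({query.protease_accession}), (), None)
    for acc in explanations:
        explanations[acc].sort(key=ExplanationPath.sort_key)
        hypothesized[acc].sort(key=ExplanationPath.sort_key)
    return PathSearchResult(explanations, hypothesized, truncated)


# ---------------------------------------------------------------------------
# cross-species mapping

def _best_ortholog_map(kb: Knowledgebase) -> dict[str, str]:
    """accession → partner-species accession, reduced to the
    highest-score pair per accession (ties broken lexicographically)."""
    best: dict[str, tuple[float, str]] = {}
    for o in kb.orthologs:
        for a, b in ((o.accession_a, o.accession_b),
                     (o.accession_b, o.accession_a)):
            score = o.score if o.score is not None else 0.0
            cur = best.get(a)
            if cur is None or (score, _NegStr(b)) > (cur[0], _NegStr(cur[1])):
                best[a] = (score, b)
    return {a: b for a, (_, b) in best.items()}


class _NegStr(str):
    """Orders lexicographically *smaller* strings as larger, so that a
    max-comparison prefers the alphabetically first partner on score ties."""

    def __lt__(self, other):  # pragma: no cover - trivial
        return str.__gt__(self, other)

    def __gt__(self, other):
        return str.__lt__(self, other)


def map_orthologs(query: PathQuery, kb: Knowledgebase
                  ) -> tuple[PathQuery, list[str]]:
    """Replace the query protease and each target by its one-to-one
    ortholog in the partner species.

    Targets without an ortholog are dropped and reported; observed
    positions are carried over unchanged but flagged approximate, since
    residue numbering is species-specific.  A query protease without an
    ortholog is an error — there is nothing to search.
    """
    mapping = _best_ortholog_map(kb)
    mapped_protease = mapping.get(query.protease_accession)
    if mapped_protease is None:
        raise PathfinderError(
            f"no ortholog for query protease {query.protease_accession!r}")
    dropped: list[str] = []
    new_targets = []
    for t in query.targets:
        partner = mapping.get(t.accession)
        if partner is None:
            dropped.append(f"{t.accession}: no ortholog")
            continue
        new_targets.append(replace(
            t, accession=partner,
            approximate_position=t.position is not None))
    return (replace(query, protease_accession=mapped_protease,
                    targets=tuple(new_targets)),
            dropped)


# ---------------------------------------------------------------------------
# output

def to_dot(paths: Iterable[ExplanationPath], web: ProteaseWeb,
           query_protease: Optional[str] = None,
           list_proteins: Iterable[str] = ()) -> str:
    """Graphviz DOT digraph of exactly the nodes and edges on the given
    paths.

    Cleavage edges are solid arrows labeled with the P1 position (dotted
    when hypothesized from the list); inhibition edges carry tee arrowheads
    labeled ``inh``.  The query node is colored, list proteins gray.
    Emission order is sorted, so output is deterministic.
    """
    nodes: set[str] = set()
    edges: set = set()
    for p in paths:
        nodes.update(p.nodes)
        edges.update(p.edges)
    listed = set(list_proteins)
    lines = ["digraph protease_web {"]
    for node in sorted(nodes):
        attrs = []
        if node == query_protease:
            attrs.append('style=filled, fillcolor="tomato"')
        elif node in listed:
            attrs.append('style=filled, fillcolor="gray80"')
        lines.append(f'  "{node}"' + (f" [{', '.join(attrs)}]" if attrs else "") + ";")
    for edge in sorted(edges, key=lambda e: (e.source, e.target, e.kind,
                                             getattr(e, "p1_position", -1))):
        if edge.kind == "cleave":
            attrs = [f'label="{edge.p1_position}"']
            if edge.origin == "inferred":
                attrs.append("style=dotted")
        else:
            attrs = ['arrowhead=tee', 'label="inh"']
        lines.append(f'  "{edge.source}" -> "{edge.target}" [{", ".join(attrs)}];')
    lines.append("}")
    return "\n".join(lines) + "\n"


def paths_frame(result: PathSearchResult) -> pd.DataFrame:
    rows = []
    for acc in sorted(set(result.explanations) | set(result.hypothesized_direct)):
        ranked = result.explanations.get(acc, []) + \
            result.hypothesized_direct.get(acc, [])
        for rank, p in enumerate(ranked, start=1):
            hypo = p.length == 1 and p.edges[0].origin == "inferred"
            rows.append({
                "target": acc,
                "path_rank": rank,
                "length": p.length,
                "node_sequence": "->".join(p.nodes),
                "edge_types": ";".join(e.kind for e in p.edges),
                "positions": ";".join(
                    str(e.p1_position) if e.kind == "cleave" else "-"
                    for e in p.edges),
                "contains_inferred": p.contains_inferred,
                "hypothesized_direct": hypo,
                "truncated": result.truncated.get(acc, False),
            })
    return pd.DataFrame(rows, columns=["target", "path_rank", "length",
                                       "node_sequence", "edge_types",
                                       "positions", "contains_inferred",
                                       "hypothesized_direct", "truncated"])


@dataclass
class PathfinderRunResult:
    query: PathQuery
    web: ProteaseWeb
    result: PathSearchResult
    diagnostics: list[str] = field(default_factory=list)


def run_pathfinder(query_list: Sequence[QueryPeptide], protease: str,
                   kb: Knowledgebase, species: Optional[str] = None,
                   cross_species: bool = False, max_length: int = 4,
                   position_window: int = 0, any_position: bool = False,
                   cleaved_only: bool = False,
                   out_dir=None) -> PathfinderRunResult:
    """Derive targets from a terminal-peptide list and search the web.

    Targets are the located termini of the query list (with
    ``cleaved_only``, just those classified as cleavage-derived, the mode
    used downstream of a terminus analysis).  Per-target problems are
    reported as diagnostics and never abort the run.  With ``out_dir``
    set, writes ``paths.tsv`` and ``paths.dot``.
    """
    diagnostics: list[str] = []
    targets: list[PathTarget] = []
    seen: set[tuple[str, int, str]] = set()
    for q in query_list:
        ann = locate_terminus(q, kb.protein(q.protein_accession))
        if not ann.located:
            diagnostics.append(f"{q.protein_accession}:{q.peptide}: {ann.status}")
            continue
        if cleaved_only:
            ann = classify_terminus(ann, kb, window=position_window)
            if "cleaved" not in ann.categories:
                continue
        key = (q.protein_accession, ann.position, q.terminus_type)
        if key in seen:
            continue
        seen.add(key)
        targets.append(PathTarget(q.protein_accession, ann.position,
                                  q.terminus_type))

    query = PathQuery(protease_accession=protease, targets=tuple(targets),
                      species=species, cross_species=cross_species,
                      max_length=max_length, position_window=position_window,
                      any_position=any_position)
    if cross_species:
        query, dropped = map_orthologs(query, kb)
        diagnostics.extend(dropped)
        species = None  # the mapped accessions belong to the partner species

    web = build_web(kb, species=species)
    extended = extend_with_query(web, query)
    if query.protease_accession not in extended.nodes:
        diagnostics.append(
            f"query protease {query.protease_accession!r} has no edges; "
            "no paths to search")
        result = PathSearchResult({}, {}, {})
    else:
        result = find_paths(extended, query)

    run = PathfinderRunResult(query, extended, result, diagnostics)
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths_frame(result).to_csv(out / "paths.tsv", sep="\t", index=False)
        dot = to_dot(result.all_paths(), extended,
                     query_protease=query.protease_accession,
                     list_proteins=[t.accession for t in query.targets])
        (out / "paths.dot").write_text(dot)
    return run
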