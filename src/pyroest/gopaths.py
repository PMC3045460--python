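"""GO DAG loading, leaf-to-root path enumeration and node-usage counting.

Only ``is_a`` edges are traversed (standard practice for namespace-rooted
analyses; part_of and other relations are ignored).  Because a DAG has no
single leaf-to-root distance, the depth used for binned reports is the
*minimum* root-ward distance, while usage counting itself follows *all*
distinct paths: for every assignment and every path from its term to the
root, each node on that path (term and root inclusive) is incremented once
per path.
"""

from __future__ import annotations

import warnings
from collections import Counter, deque
from dataclasses import dataclass, field

import networkx as nx
import obonet
import pandas as pd


@dataclass
class GoDag:
    terms: dict[str, tuple[str, str]]            # id -> (name, namespace)
    parents: dict[str, frozenset[str]]           # is_a parents

    @property
    def roots(self) -> set[str]:
        return {t for t, p in self.parents.items() if not p}

    def children(self) -> dict[str, set[str]]:
        ch: dict[str, set[str]] = {t: set() for t in self.parents}
        for t, ps in self.parents.items():
            for p in ps:
                ch[p].add(t)
        return ch


@dataclass
class UsageCounter:
    counts: Counter = field(default_factory=Counter)
    total_paths: int = 0
    skipped: list[tuple[str, str]] = field(default_factory=list)


def _dag_from_graph(graph: nx.MultiDiGraph) -> GoDag:
    terms = {}
    parents: dict[str, frozenset] = {}
    for node, data in graph.nodes(data=True):
        terms[node] = (data.get("name", node), data.get("namespace", ""))
        ps = {v for _, v, key in graph.out_edges(node, keys=True)
              if key == "is_a"}
        parents[node] = frozenset(ps)
    is_a = nx.DiGraph((u, v) for u, v, key in graph.edges(keys=True)
                      if key == "is_a")
    is_a.add_nodes_from(terms)
    if not nx.is_directed_acyclic_graph(is_a):
        cycle = nx.find_cycle(is_a)
        raise ValueError(f"is_a cycle detected: {cycle}")
    return GoDag(terms=terms, parents=parents)


def load_obo(path) -> GoDag:
    """Load an OBO 1.2 file into a GoDag (obsolete terms are dropped)."""
    graph = obonet.read_obo(path)   # obonet already drops obsolete terms
    dag = _dag_from_graph(graph)
    if not dag.roots:
        warnings.warn("ontology has no root term")
    return dag


def load_obo_text(text: str) -> GoDag:
    import io
    return _dag_from_graph(obonet.read_obo(io.StringIO(text)))


def enumerate_paths(dag: GoDag, term: str, root: str) -> list[list[str]]:
    """All distinct root-ward is_a paths from term to root (ordered lists).

    A hit at the root itself yields one zero-length path; an unreachable root
    yields an empty list.
    """
    if term not in dag.parents or root not in dag.parents:
        raise KeyError("term and root must be in the DAG")
    memo: dict[str, list[list[str]]] = {root: [[root]]}

    def rec(t: str) -> list[list[str]]:
        if t in memo:
            return memo[t]
        paths = [[t] + p for parent in sorted(dag.parents[t])
                 for p in rec(parent)]
        memo[t] = paths
        return paths

    return rec(term)


def count_paths(dag: GoDag, term: str, root: str) -> int:
    """Number of distinct paths term -> root (memoized; no materialization)."""
    memo: dict[str, int] = {root: 1}

    def rec(t: str) -> int:
        if t not in memo:
            memo[t] = sum(rec(p) for p in dag.parents[t])
        return memo[t]

    return rec(term)


def count_usage(dag: GoDag, assignments, root: str) -> UsageCounter:
    """Increment every node on every term->root path, once per path per hit.

    ``assignments`` is an iterable of (query_id, term_id).  Terms missing
    from the DAG or not reaching the root are skipped and reported.
    """
    usage = UsageCounter()
    cache: dict[str, list[list[str]]] = {}
    for query, term in assignments:
        if term not in dag.parents:
            usage.skipped.append((query, term))
            continue
        if term not in cache:
            cache[term] = enumerate_paths(dag, term, root)
        paths = cache[term]
        if not paths:
            usage.skipped.append((query, term))
            continue
        for path in paths:
            for node in path:
                usage.counts[node] += 1
            usage.total_paths += 1
    return usage


def term_depths(dag: GoDag, root: str) -> dict[str, int]:
    """Minimum root-ward distance (in is_a edges) of every reachable term."""
    children = dag.children()
    depths = {root: 0}
    queue = deque([root])
    while queue:
        t = queue.popleft()
        for c in children.get(t, ()):
            if c not in depths:
                depths[c] = depths[t] + 1
                queue.append(c)
    return depths


def terms_at_depth(
    dag: GoDag, usage: UsageCounter, k: int, root: str
) -> pd.DataFrame:
    """Terms at minimum depth k with usage > 0, with usage proportions."""
    if k < 1:
        raise ValueError("k must be >= 1")
    depths = term_depths(dag, root)
    rows = [
        {"term": t, "name": dag.terms[t][0], "depth": k,
         "count": usage.counts[t]}
        for t, d in sorted(depths.items())
        if d == k and usage.counts.get(t, 0) > 0
    ]
    df = pd.DataFrame(rows, columns=["term", "name", "depth", "count"])
    total = df["count"].sum()
    df["proportion"] = df["count"] / total if total else 0.0
    return df


def compare_usage(
    dag: GoDag, usage_a: UsageCounter, usage_b: UsageCounter, k: int, root: str
) -> pd.DataFrame:
    """Side-by-side depth-k term proportions for two assignment sets."""
    a = terms_at_depth(dag, usage_a, k, root).set_index("term")
    b = terms_at_depth(dag, usage_b, k, root).set_index("term")
    terms = sorted(set(a.index) | set(b.index))
    rows = []
    for t in terms:
        pa = float(a["proportion"].get(t, 0.0))
        pb = float(b["proportion"].get(t, 0.0))
        rows.append({
            "term": t, "name": dag.terms[t][0],
            "proportion_a": pa, "proportion_b": pb, "difference": pa - pb,
        })
    return pd.DataFrame(rows, columns=["term", "name", "proportion_a",
                                       "proportion_b", "difference"])


def read_assignments(path) -> list[tuple[str, str]]:
    """Two-column TSV (query_id, term_id); blank lines and '#' comments skipped."""
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            query, term = line.split("\t")[:2]
            out.append((query, term))
    return out
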