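"""Multigraph network views with bipartite pseudonodes and the i.* vocabulary.

Protein nodes are keyed by full ROGID string; each n-ary record contributes
a hexagon-style pseudonode keyed by its RIGID, adjacent only to its member
proteins. Every evidence edge corresponds to one source record, so parallel
edges between the same two proteins represent overlapping evidence and all
carry the same RIGID. Node attributes track search provenance (``i.order``,
``i.query``), filter state (``i.alive``, ``i.alive_degree``) and store-wide
degree (``i.overall_degree``); edge attributes carry provenance and the
bibliometric scores.
"""

from __future__ import annotations

import logging
import random
from pathlib import Path
from typing import Callable, Iterable, Mapping

import networkx as nx

from irefkit.mitab_io import SourceRecord
from irefkit.store import ConsolidatedStore

logger = logging.getLogger(__name__)


class NetworkView:
    """A materialized search result: multigraph + attribute vocabulary."""

    def __init__(self) -> None:
        self.graph: nx.MultiGraph = nx.MultiGraph()
        self._toggled_pairs: set[frozenset[str]] = set()
        self.count_pseudonode_neighbours = True  # complex co-membership counts

    # -- node/edge views -------------------------------------------------

    @property
    def protein_nodes(self) -> list[str]:
        return [n for n, d in self.graph.nodes(data=True) if not d["i.pseudonode"]]

    @property
    def pseudonodes(self) -> list[str]:
        return [n for n, d in self.graph.nodes(data=True) if d["i.pseudonode"]]

    def visible_edges(self) -> list[tuple[str, str, object]]:
        return [
            (u, v, k)
            for u, v, k, d in self.graph.edges(keys=True, data=True)
            if d.get("visible", True)
        ]

    def hidden_edges(self) -> list[tuple[str, str, object]]:
        return [
            (u, v, k)
            for u, v, k, d in self.graph.edges(keys=True, data=True)
            if not d.get("visible", True)
        ]

    def parallel_edges(self, u: str, v: str) -> list[object]:
        if not self.graph.has_edge(u, v):
            return []
        return list(self.graph[u][v])

    def _ensure_protein_node(
        self,
        rogid: str,
        order: int,
        store: ConsolidatedStore | None,
    ) -> None:
        if rogid in self.graph:
            return  # merging build: prior attributes stay put
        attrs = {
            "i.order": order,
            "i.query": [],
            "i.alive": False,
            "i.alive_degree": 0,
            "i.overall_degree": 0,
            "i.pseudonode": False,
            "i.canonical_rogid": rogid,
        }
        if store is not None:
            attrs["i.overall_degree"] = store.overall_degree.get(rogid, 0)
            interactor = store.interactors.get(rogid)
            if interactor is not None:
                if interactor.canonical_rogid is not None:
                    attrs["i.canonical_rogid"] = interactor.canonical_rogid.full
                attrs["irogid"] = interactor.irogid
        self.graph.add_node(rogid, **attrs)


def _edge_attrs(record: SourceRecord, store: ConsolidatedStore | None) -> dict:
    rigid = record.rigid.value
    attrs = {
        "rigid": rigid,
        "record_id": record.record_id,
        "i.src_intxn_db": record.source_db,
        "i.method_name": record.method_name,
        "i.method_cv": record.method_cv,
        "i.PMID": list(record.pmids),
        "i.flag": False,
        "predicted": record.predicted,
        "i.score_np": None,
        "i.score_lpr": None,
        "visible": True,
    }
    if store is not None:
        group = store.rigid_groups.get(rigid)
        if group is not None:
            attrs["i.score_np"] = group.score_np
            attrs["i.score_lpr"] = group.score_lpr
    return attrs


def build_view(
    records: Iterable[SourceRecord],
    query_rogids: set[str],
    search_index: int = 0,
    store: ConsolidatedStore | None = None,
    view: NetworkView | None = None,
    query_terms: Mapping[str, list[str]] | None = None,
) -> NetworkView:
    """Materialize records into a view, merging into ``view`` if given.

    Query nodes get ``i.order = 2*search_index`` and their neighbours
    ``2*search_index + 1``; nodes already present keep their attributes.
    ``query_terms`` maps ROGID -> search terms that matched it; matched
    terms are appended to the node's ``i.query`` list.
    """
    if view is None:
        view = NetworkView()
    graph = view.graph
    for record in records:
        rigid = record.rigid.value
        member_rogids = [r.full for r in record.participant_rogids]
        for rogid in member_rogids:
            order = 2 * search_index if rogid in query_rogids else 2 * search_index + 1
            view._ensure_protein_node(rogid, order, store)
        if record.edgetype == "X":
            a, b = member_rogids
            graph.add_edge(a, b, key=record.record_id, **_edge_attrs(record, store))
        else:
            if rigid not in graph:
                graph.add_node(rigid, **{"i.pseudonode": True, "rigid": rigid})
            for idx, rogid in enumerate(member_rogids):
                graph.add_edge(
                    rigid, rogid, key=(record.record_id, idx),
                    **_edge_attrs(record, store),
                )
    if query_terms:
        for rogid, terms in query_terms.items():
            if rogid in graph:
                bucket = graph.nodes[rogid].setdefault("i.query", [])
                for term in terms:
                    if term not in bucket:
                        bucket.append(term)
    _check_parallel_rigids(view)
    return view


def _check_parallel_rigids(view: NetworkView) -> None:
    """All parallel edges between one protein pair must share one RIGID."""
    graph = view.graph
    seen: set[tuple[str, str]] = set()
    for u, v in graph.edges():
        pair = (u, v) if u <= v else (v, u)
        if pair in seen:
            continue
        seen.add(pair)
        if graph.nodes[u]["i.pseudonode"] or graph.nodes[v]["i.pseudonode"]:
            continue
        rigids = {d["rigid"] for d in graph[u][v].values()}
        if len(rigids) > 1:  # pragma: no cover - construction guarantees
            raise AssertionError(f"parallel edges between {u} and {v} carry {rigids}")


def toggle_multi_edges(
    view: NetworkView,
    pairs: Iterable[tuple[str, str]] | None = None,
    rng: random.Random | None = None,
) -> NetworkView:
    """Collapse or re-expand parallel edges for the selected node pairs.

    For an untoggled pair, exactly one edge stays visible: an edge whose
    ``i.flag`` the user set wins, otherwise the smallest record id (or a
    seeded random pick when ``rng`` is given). Toggling an already-toggled
    pair restores all of its edges.
    """
    graph = view.graph
    if pairs is None:
        pairs = {
            tuple(sorted((u, v)))
            for u, v in graph.edges()
            if graph.number_of_edges(u, v) > 1
        }
    for u, v in pairs:
        if not graph.has_edge(u, v):
            continue
        pair_key = frozenset((u, v)) if u != v else frozenset((u, f"self:{v}"))
        keys = list(graph[u][v])
        if pair_key in view._toggled_pairs:
            for k in keys:
                graph[u][v][k]["visible"] = True
            view._toggled_pairs.discard(pair_key)
            continue
        if len(keys) < 2:
            continue
        flagged = [k for k in keys if graph[u][v][k]["i.flag"]]
        if flagged:
            keep = flagged[0]
        elif rng is not None:
            keep = rng.choice(keys)
        else:
            keep = min(keys, key=lambda k: graph[u][v][k]["record_id"])
        for k in keys:
            graph[u][v][k]["visible"] = k == keep
        graph[u][v][keep]["i.flag"] = True
        view._toggled_pairs.add(pair_key)
    return view


def set_alive(view: NetworkView, predicate: Callable[[str, dict], bool]) -> NetworkView:
    """Set ``i.alive`` on every protein node from a (node, attrs) predicate."""
    for node, data in view.graph.nodes(data=True):
        if data["i.pseudonode"]:
            continue
        data["i.alive"] = bool(predicate(node, data))
    update_alive_degree(view)
    return view


def _alive_neighbours(view: NetworkView, node: str) -> set[str]:
    graph = view.graph
    result: set[str] = set()
    for neighbour in graph.neighbors(node):
        data = graph.nodes[neighbour]
        if data["i.pseudonode"]:
            if not view.count_pseudonode_neighbours:
                continue
            for co_member in graph.neighbors(neighbour):
                if co_member == node:
                    continue
                if not graph.nodes[co_member]["i.pseudonode"] and graph.nodes[co_member]["i.alive"]:
                    result.add(co_member)
        elif data["i.alive"]:
            result.add(neighbour)
    result.discard(node)
    return result


def update_alive_degree(view: NetworkView) -> NetworkView:
    """Recompute ``i.alive_degree`` = distinct alive protein neighbours.

    Parallel edges count once; pseudonode adjacency contributes the alive
    protein co-members of the n-ary record (switchable via
    ``view.count_pseudonode_neighbours``).
    """
    for node, data in view.graph.nodes(data=True):
        if data["i.pseudonode"]:
            continue
        data["i.alive_degree"] = len(_alive_neighbours(view, node))
    return view


def select_between(view: NetworkView, selected_nodes: set[str]) -> list[tuple[str, str, object]]:
    """Alive-mark a selection and return its induced evidence edges.

    Binary edges are induced when both endpoints are selected; a
    pseudonode's edges are induced only when every member of the n-ary
    record is selected, matching neighbourhood completion restricted to the
    selection.
    """
    if len(selected_nodes) < 2:
        logger.warning("select_between needs at least 2 nodes; no-op")
        return []
    set_alive(view, lambda node, _data: node in selected_nodes)
    graph = view.graph
    edges: list[tuple[str, str, object]] = []
    for pseudo in view.pseudonodes:
        members = set(graph.neighbors(pseudo))
        if members <= selected_nodes:
            edges.extend((pseudo, m, k) for m in graph[pseudo] for k in graph[pseudo][m])
    for u, v, k, d in graph.edges(keys=True, data=True):
        if graph.nodes[u]["i.pseudonode"] or graph.nodes[v]["i.pseudonode"]:
            continue
        if u in selected_nodes and v in selected_nodes:
            edges.append((u, v, k))
    return edges


_LIST_ATTRS = ("i.query", "i.PMID")


def export_view(
    view: NetworkView,
    target_id_type: str,
    store: ConsolidatedStore,
) -> nx.MultiGraph:
    """Collapse the view onto a target identifier type.

    Protein nodes without the target identifier are dropped along with
    their exclusive edges; nodes sharing a target value merge into one node
    with cumulative (concatenated) attributes. Pseudonodes survive if at
    least two of their members do. ``target_id_type`` ``rogid`` or
    ``canonical_rogid`` are supported alongside accession types.
    """
    def target_of(rogid: str) -> str | None:
        if target_id_type == "rogid":
            return rogid
        if target_id_type == "canonical_rogid":
            return view.graph.nodes[rogid].get("i.canonical_rogid", rogid)
        interactor = store.interactors.get(rogid)
        if interactor is None:
            return None
        values = interactor.accessions.get(target_id_type)
        return values[0] if values else None

    if target_id_type not in ("rogid", "canonical_rogid") and not any(
        t == target_id_type for t in ("uniprot", "refseq", "entrez_gene",
                                      "gene_symbol", "pdb", "xref", "original_reference")
    ):
        raise ValueError(f"unknown identifier type {target_id_type!r}")

    mapping: dict[str, str] = {}
    for node in view.protein_nodes:
        target = target_of(node)
        if target is None:
            logger.info("node %s lacks %s identifier; dropped from export", node, target_id_type)
            continue
        mapping[node] = f"{target_id_type}:{target}"

    out: nx.MultiGraph = nx.MultiGraph()
    for node, target in mapping.items():
        source_attrs = view.graph.nodes[node]
        if target not in out:
            attrs = dict(source_attrs)
            attrs["constituents"] = [node]
            attrs = {k: (list(v) if isinstance(v, list) else v) for k, v in attrs.items()}
            out.add_node(target, **attrs)
        else:
            merged = out.nodes[target]
            merged["constituents"].append(node)
            for key in _LIST_ATTRS:
                merged.setdefault(key, [])
                merged[key] = list(merged[key]) + list(source_attrs.get(key, []))
            merged["i.overall_degree"] = max(
                merged.get("i.overall_degree", 0), source_attrs.get("i.overall_degree", 0)
            )
    for pseudo in view.pseudonodes:
        surviving = [m for m in view.graph.neighbors(pseudo) if m in mapping]
        if len(surviving) >= 2:
            out.add_node(pseudo, **dict(view.graph.nodes[pseudo]))
    for u, v, k, d in view.graph.edges(keys=True, data=True):
        nu = mapping.get(u, u if u in out else None)
        nv = mapping.get(v, v if v in out else None)
        if nu is None or nv is None:
            continue
        out.add_edge(nu, nv, key=k, **dict(d))
    return out


def write_export(graph: nx.MultiGraph, prefix: str | Path) -> None:
    """Write an exported graph as edge list + node/edge attribute TSVs."""
    prefix = Path(prefix)
    node_attrs = sorted({k for _, d in graph.nodes(data=True) for k in d})
    with open(f"{prefix}.nodes.tsv", "w") as handle:
        handle.write("node\t" + "\t".join(node_attrs) + "\n")
        for node in sorted(graph.nodes):
            cells = [str(node)]
            for attr in node_attrs:
                value = graph.nodes[node].get(attr, "")
                cells.append("|".join(map(str, value)) if isinstance(value, list) else str(value))
            handle.write("\t".join(cells) + "\n")
    edge_attrs = sorted({k for *_, d in graph.edges(data=True) for k in d})
    with open(f"{prefix}.edges.tsv", "w") as handle:
        handle.write("source\ttarget\tkey\t" + "\t".join(edge_attrs) + "\n")
        for u, v, k, d in sorted(graph.edges(keys=True, data=True), key=lambda e: str(e[:3])):
            cells = [str(u), str(v), str(k)]
            for attr in edge_attrs:
                value = d.get(attr, "")
                cells.append("|".join(map(str, value)) if isinstance(value, list) else str(value))
            handle.write("\t".join(cells) + "\n")
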