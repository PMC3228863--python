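"""Mining operations: spoke-represented complexes, disease groups, adjacency matrices.

Spoke detection looks for sets of two or more binary records from one
source database that share a publication, an experimental method known to
produce n-ary data, and a common (hub) interactor — the signature of an
n-ary result that a database disassembled into hub-spoke binary edges.

The adjacency matrix classifies every (row, column) protein pair of two
user groups by their relationship in a view: direct evidence edge,
indirect via a length-2 protein path or shared n-ary membership, both, or
neither; identical row/column proteins form SELF cells listing direct
interactors.
"""

from __future__ import annotations

import logging
from collections import defaultdict
from dataclasses import dataclass, field
from pathlib import Path

from irefkit.mitab_io import SourceRecord
from irefkit.graph import NetworkView

logger = logging.getLogger(__name__)

#: Co-purification-style PSI-MI method terms treated as n-ary-producing by
#: default; configurable via a methods file (one MI id per line).
DEFAULT_NARY_METHODS = frozenset({
    "MI:0004",  # affinity chromatography technology
    "MI:0096",  # pull down
    "MI:0006",  # anti bait coimmunoprecipitation
    "MI:0007",  # anti tag coimmunoprecipitation
    "MI:0019",  # coimmunoprecipitation
    "MI:0676",  # tandem affinity purification
    "MI:0401",  # biochemical
})


@dataclass
class SpokeCandidate:
    """A possible spoke-represented complex reassembled from binary records."""

    hub_rogid: str
    member_rogids: set[str]
    source_db: str
    pmid: int
    method_cv: str
    record_ids: list[int]

    def __post_init__(self) -> None:
        if len(self.record_ids) < 2:
            raise ValueError("spoke candidate needs at least 2 supporting records")
        if self.hub_rogid not in self.member_rogids:
            raise ValueError("hub must be among members")


@dataclass
class DiseaseGroup:
    digid: int
    title: str
    omim_ids: set[int] = field(default_factory=set)
    gene_ids: set[int] = field(default_factory=set)


@dataclass
class AdjacencyCell:
    """One cell of the group-vs-group adjacency matrix."""

    row_rogid: str
    col_rogid: str
    cell_class: str  # DIRECT | INDIRECT | BOTH | NONE | SELF
    intermediates: list[str] = field(default_factory=list)

    _COLOURS = {
        "DIRECT": "red", "INDIRECT": "blue", "BOTH": "green",
        "NONE": "black", "SELF": "self",
    }

    @property
    def colour(self) -> str:
        return self._COLOURS[self.cell_class]

    @property
    def symbol(self) -> bool:
        """Whether the direct-interaction mark is shown in the cell."""
        return self.cell_class in ("DIRECT", "BOTH")


def load_nary_methods(path: str | Path) -> frozenset[str]:
    """Read a methods file: one PSI-MI accession per line, '#' comments."""
    methods = set()
    with open(path) as handle:
        for line in handle:
            line = line.strip()
            if line and not line.startswith("#"):
                methods.add(line.split()[0])
    return frozenset(methods)


def detect_spoke_complexes(
    records: list[SourceRecord],
    nary_methods: frozenset[str] | None = None,
) -> list[SpokeCandidate]:
    """Find candidate spoke-represented complexes among binary records.

    Binary records are partitioned by (source database, PMID, n-ary-capable
    method, shared interactor); each partition of two or more records
    yields one candidate whose members are the hub plus all partners. When
    a record carries a bait role, only the bait qualifies as that record's
    hub; records without bait annotation allow either participant.
    """
    if nary_methods is None:
        nary_methods = DEFAULT_NARY_METHODS
    buckets: dict[tuple[str, int, str, str], list[SourceRecord]] = defaultdict(list)
    for record in records:
        if record.edgetype != "X":
            continue
        if record.method_cv not in nary_methods:
            continue
        bait = record.bait
        hubs = [bait.full] if bait is not None else [r.full for r in record.participant_rogids]
        for pmid in record.pmids:
            for hub in set(hubs):
                buckets[(record.source_db, pmid, record.method_cv, hub)].append(record)

    candidates = []
    claimed: set[tuple[str, int, str, frozenset[int]]] = set()
    for (source_db, pmid, method_cv, hub), bucket in sorted(
        buckets.items(), key=lambda item: (-len(item[1]), item[0])
    ):
        if len(bucket) < 2:
            continue
        record_ids = sorted({r.record_id for r in bucket})
        if len(record_ids) < 2:
            continue
        signature = (source_db, pmid, method_cv, frozenset(record_ids))
        if signature in claimed:
            continue  # same record set already emitted under the other hub
        claimed.add(signature)
        members = {hub}
        for record in bucket:
            members.update(r.full for r in record.participant_rogids)
        candidates.append(SpokeCandidate(
            hub_rogid=hub,
            member_rogids=members,
            source_db=source_db,
            pmid=pmid,
            method_cv=method_cv,
            record_ids=record_ids,
        ))
    candidates.sort(key=lambda c: (c.source_db, c.pmid, c.method_cv, c.hub_rogid))
    return candidates


def read_disease_groups(path: str | Path) -> list[DiseaseGroup]:
    """Read a 4-column (digid, title, omim_id, gene_id) TSV into groups."""
    groups: dict[int, DiseaseGroup] = {}
    with open(path) as handle:
        for line in handle:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            digid, title, omim_id, gene_id = line.split("\t")
            group = groups.setdefault(int(digid), DiseaseGroup(digid=int(digid), title=title))
            if omim_id != "-":
                group.omim_ids.add(int(omim_id))
            if gene_id != "-":
                group.gene_ids.add(int(gene_id))
    return [groups[d] for d in sorted(groups)]


def disease_search(
    query: str | int,
    groups: list[DiseaseGroup],
    search_type: str = "digid",
) -> set[int]:
    """Resolve a disease query to a set of Entrez gene ids.

    ``digid`` matches one group by id; ``omim`` returns the genes of the
    group containing the OMIM id; ``omim_title`` unions the genes of every
    group whose title contains the fragment (case-insensitive).
    """
    if search_type == "digid":
        wanted = int(query)
        for group in groups:
            if group.digid == wanted:
                return set(group.gene_ids)
        return set()
    if search_type == "omim":
        wanted = int(query)
        genes: set[int] = set()
        for group in groups:
            if wanted in group.omim_ids:
                genes |= group.gene_ids
        return genes
    if search_type == "omim_title":
        fragment = str(query).lower()
        genes = set()
        for group in groups:
            if fragment in group.title.lower():
                genes |= group.gene_ids
        return genes
    raise ValueError(f"unknown disease search type {search_type!r}")


def _direct_neighbours(view: NetworkView, node: str) -> set[str]:
    graph = view.graph
    return {
        n for n in graph.neighbors(node)
        if not graph.nodes[n]["i.pseudonode"] and n != node
    }


def adjacency_matrix(
    view: NetworkView,
    group_a: set[str],
    group_b: set[str],
) -> dict[tuple[str, str], AdjacencyCell]:
    """Classify every (row in B, column in A) pair of protein nodes.

    Intermediates list both intermediate proteins (length-2 paths) and
    pseudonode RIGIDs (shared n-ary membership); intermediates may
    themselves belong to either group. Cells whose entire row or column is
    NONE are marked hidden via :func:`hidden_rows_cols`.
    """
    if not group_a or not group_b:
        raise ValueError("both groups must be non-empty")
    graph = view.graph
    unknown = (group_a | group_b) - set(graph.nodes)
    if unknown:
        raise ValueError(f"nodes not in view: {sorted(unknown)}")

    matrix: dict[tuple[str, str], AdjacencyCell] = {}
    for row in sorted(group_b):
        for col in sorted(group_a):
            if row == col:
                matrix[(row, col)] = AdjacencyCell(
                    row_rogid=row, col_rogid=col, cell_class="SELF",
                    intermediates=sorted(_direct_neighbours(view, row)),
                )
                continue
            direct = graph.has_edge(row, col)
            intermediates: list[str] = []
            row_nb = set(graph.neighbors(row))
            col_nb = set(graph.neighbors(col))
            for shared in sorted(row_nb & col_nb):
                if graph.nodes[shared]["i.pseudonode"]:
                    intermediates.append(shared)  # co-membership in n-ary record
                else:
                    intermediates.append(shared)
            if direct and intermediates:
                cell_class = "BOTH"
            elif direct:
                cell_class = "DIRECT"
            elif intermediates:
                cell_class = "INDIRECT"
            else:
                cell_class = "NONE"
            matrix[(row, col)] = AdjacencyCell(
                row_rogid=row, col_rogid=col,
                cell_class=cell_class, intermediates=intermediates,
            )
    return matrix


def hidden_rows_cols(
    matrix: dict[tuple[str, str], AdjacencyCell],
) -> tuple[set[str], set[str]]:
    """Rows and columns that contain only NONE cells (hidden by default)."""
    rows = {r for r, _ in matrix}
    cols = {c for _, c in matrix}
    hidden_rows = {
        r for r in rows
        if all(matrix[(r, c)].cell_class == "NONE" for c in cols if (r, c) in matrix)
    }
    hidden_cols = {
        c for c in cols
        if all(matrix[(r, c)].cell_class == "NONE" for r in rows if (r, c) in matrix)
    }
    return hidden_rows, hidden_cols


def matrix_select(
    matrix: dict[tuple[str, str], AdjacencyCell],
    view: NetworkView,
    row: str | None = None,
    col: str | None = None,
) -> tuple[set[str], list[tuple[str, str, object]]]:
    """Translate a heading or cell click into a node/edge selection.

    A heading (only ``row`` or only ``col``) selects that protein node. A
    cell selects row and column nodes, any intermediates, and the evidence
    edges realizing the relationship; NONE (hidden) cells select nothing.
    """
    graph = view.graph
    if row is not None and col is None:
        return ({row} if row in graph else set()), []
    if col is not None and row is None:
        return ({col} if col in graph else set()), []
    cell = matrix.get((row, col))
    if cell is None or cell.cell_class == "NONE":
        return set(), []
    nodes = {row, col}
    edges: list[tuple[str, str, object]] = []
    if cell.cell_class == "SELF":
        nodes |= set(cell.intermediates)
        for partner in cell.intermediates:
            edges.extend((row, partner, k) for k in view.parallel_edges(row, partner))
        return nodes, edges
    if cell.symbol:
        edges.extend((row, col, k) for k in view.parallel_edges(row, col))
    for mid in cell.intermediates:
        nodes.add(mid)
        edges.extend((row, mid, k) for k in view.parallel_edges(row, mid))
        edges.extend((mid, col, k) for k in view.parallel_edges(mid, col))
    return nodes, edges


def write_matrix_tsv(
    matrix: dict[tuple[str, str], AdjacencyCell],
    path: str | Path,
    include_hidden: bool = True,
) -> None:
    """Write the matrix as a long-form TSV (row, col, class, symbol, intermediates)."""
    hidden_rows, hidden_cols = hidden_rows_cols(matrix)
    with open(path, "w") as handle:
        handle.write("row\tcol\tclass\tcolour\tsymbol\tintermediates\thidden\n")
        for (row, col), cell in sorted(matrix.items()):
            hidden = row in hidden_rows or col in hidden_cols
            if hidden and not include_hidden:
                continue
            handle.write("\t".join([
                row, col, cell.cell_class, cell.colour,
                "¤" if cell.symbol else "-",
                "|".join(cell.intermediates) or "-",
                "1" if hidden else "0",
            ]) + "\n")


def write_matrix_html(
    matrix: dict[tuple[str, str], AdjacencyCell],
    path: str | Path,
) -> None:
    """Write an HTML table with the red/blue/green/black cell colouring."""
    colours = {"red": "#d9534f", "blue": "#337ab7", "green": "#5cb85c",
               "black": "#000000", "self": "#aaaaaa"}
    rows = sorted({r for r, _ in matrix})
    cols = sorted({c for _, c in matrix})
    hidden_rows, hidden_cols = hidden_rows_cols(matrix)
    lines = ["<table border='1' style='border-collapse:collapse'>",
             "<tr><th></th>" + "".join(f"<th>{c}</th>" for c in cols if c not in hidden_cols) + "</tr>"]
    for row in rows:
        if row in hidden_rows:
            continue
        cells = [f"<th>{row}</th>"]
        for col in cols:
            if col in hidden_cols:
                continue
            cell = matrix[(row, col)]
            text = ("¤ " if cell.symbol else "") + ", ".join(cell.intermediates)
            cells.append(
                f"<td style='background:{colours[cell.colour]};color:#fff'>{text}</td>"
            )
        lines.append("<tr>" + "".join(cells) + "</tr>")
    lines.append("</table>")
    Path(path).write_text("\n".join(lines) + "\n")
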