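"""Related gene groups (RGGs) and canonical ROGID assignment.

Genes are grouped into RGGs when they share at least one identical protein
product (connected components of the shared-product relation). Each RGG's
product list is expanded with isoform-linked proteins and gene
cross-referenced proteins, and one member is chosen as the canonical
representative: a UniProt-canonical member if there is exactly one, the
longest among several, else the longest member overall, with ties broken by
ASCII-smallest ROGID so the choice is implementation-independent.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx

from irefkit.identity import Rogid


@dataclass
class RelatedGeneGroup:
    rgg_id: int
    gene_ids: set[int]
    protein_rogids: set[str] = field(default_factory=set)
    canonical_rogid: str | None = None


def build_rggs(gene_to_proteins: dict[int, set[str]]) -> list[RelatedGeneGroup]:
    """Group genes into RGGs by connected components of product sharing.

    Genes with no products form singleton groups. Group ids are assigned in
    order of the smallest gene id in each group, so the output is
    deterministic for a given input map.
    """
    graph: nx.Graph = nx.Graph()
    graph.add_nodes_from(("g", gene) for gene in gene_to_proteins)
    for gene, proteins in gene_to_proteins.items():
        for protein in proteins:
            graph.add_edge(("g", gene), ("p", protein))
    groups = []
    components = []
    for component in nx.connected_components(graph):
        genes = {node[1] for node in component if node[0] == "g"}
        proteins = {node[1] for node in component if node[0] == "p"}
        components.append((min(genes), genes, proteins))
    for rgg_id, (_, genes, proteins) in enumerate(sorted(components)):
        groups.append(RelatedGeneGroup(rgg_id=rgg_id, gene_ids=genes, protein_rogids=proteins))
    return groups


def expand_rgg(
    group: RelatedGeneGroup,
    isoform_links: dict[str, set[str]] | None = None,
    xref_links: dict[int, set[str]] | None = None,
) -> RelatedGeneGroup:
    """Add isoform-linked and gene-cross-referenced proteins to a group.

    Single pass (isoforms of newly added isoforms are not chased) and
    monotone: proteins are only ever added. Returns the same group object.
    """
    added: set[str] = set()
    if isoform_links:
        for protein in group.protein_rogids:
            added.update(isoform_links.get(protein, ()))
    if xref_links:
        for gene in group.gene_ids:
            added.update(xref_links.get(gene, ()))
    group.protein_rogids |= added
    return group


def select_canonical(
    group: RelatedGeneGroup,
    uniprot_canonical_flags: dict[str, bool],
    lengths: dict[str, int],
) -> str:
    """Choose the canonical ROGID for an expanded group.

    Priority: sole UniProt-canonical member; longest among several
    UniProt-canonical members; otherwise longest member overall. Length ties
    break to the ASCII-smallest ROGID.
    """
    if not group.protein_rogids:
        raise ValueError(f"RGG {group.rgg_id} has no protein members")
    flagged = [r for r in group.protein_rogids if uniprot_canonical_flags.get(r, False)]
    pool = flagged if flagged else sorted(group.protein_rogids)
    chosen = min(pool, key=lambda r: (-lengths[r], r))
    group.canonical_rogid = chosen
    return chosen


def assign_canonicals(
    gene_to_proteins: dict[int, set[str]],
    isoform_links: dict[str, set[str]] | None = None,
    xref_links: dict[int, set[str]] | None = None,
    uniprot_canonical_flags: dict[str, bool] | None = None,
    lengths: dict[str, int] | None = None,
    all_rogids: set[str] | None = None,
) -> tuple[dict[str, str], list[RelatedGeneGroup]]:
    """Full canonicalization: RGG build, expansion, canonical choice.

    Returns (rogid -> canonical rogid, groups). Proteins in ``all_rogids``
    that end up in no gene group become their own canonical representative,
    so every interactor carries a canonical assignment.
    """
    uniprot_canonical_flags = uniprot_canonical_flags or {}
    lengths = dict(lengths or {})
    groups = build_rggs(gene_to_proteins)
    assignment: dict[str, str] = {}
    for group in groups:
        expand_rgg(group, isoform_links, xref_links)
        if not group.protein_rogids:
            continue
        for rogid in group.protein_rogids:
            lengths.setdefault(rogid, 0)
        canonical = select_canonical(group, uniprot_canonical_flags, lengths)
        for rogid in group.protein_rogids:
            assignment[rogid] = canonical
    if all_rogids:
        for rogid in all_rogids:
            assignment.setdefault(rogid, rogid)
    return assignment, groups


def read_two_column_links(path) -> dict[str, set[str]]:
    """Read a 2-column TSV into a symmetric key -> linked-set map."""
    links: dict[str, set[str]] = {}
    with open(path) as handle:
        for line in handle:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            a, b = line.split("\t")
            links.setdefault(a, set()).add(b)
    return links


def write_canonical_table(assignment: dict[str, str], groups: list[RelatedGeneGroup], path) -> None:
    """Write (rogid, canonical_rogid, rgg_id) TSV; rgg_id -1 for ungrouped."""
    rgg_of: dict[str, int] = {}
    for group in groups:
        for rogid in group.protein_rogids:
            rgg_of[rogid] = group.rgg_id
    with open(path, "w") as handle:
        for rogid in sorted(assignment):
            handle.write(f"{rogid}\t{assignment[rogid]}\t{rgg_of.get(rogid, -1)}\n")
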