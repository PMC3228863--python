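"""Consolidated interaction store: RIGID grouping, lookup tables, searches.

Consolidation groups source records that share a participant ROGID multiset
under one RIGID, which is what collapses the two-fold redundancy of
multi-database interaction data into distinct interactions. The store also
keeps the accession lookup tables that let a query in any supported
accession system resolve to ROGIDs, and answers neighbourhood queries.
"""

from __future__ import annotations

import logging
from collections import defaultdict
from dataclasses import dataclass, field

from irefkit.identity import Rogid
from irefkit.mitab_io import Interactor, SourceRecord

logger = logging.getLogger(__name__)

SEARCH_TYPES = (
    "uniprot", "refseq", "entrez_gene", "gene_symbol", "pdb", "xref",
    "original_reference", "rogid",
)

# Search types resolved through genes: the query names a gene, the result is
# the ROGIDs of all its protein products.
_GENE_TYPES = {"entrez_gene", "gene_symbol"}

# Symbols are conventionally case-folded; base64 ROGIDs are case-significant.
_CASE_INSENSITIVE = {"gene_symbol"}


@dataclass
class RigidGroup:
    """All source records sharing one RIGID, with bibliometric scores."""

    rigid: str
    record_ids: list[int] = field(default_factory=list)
    distinct_pmids: set[int] = field(default_factory=set)
    score_np: int | None = None
    score_lpr: int | None = None


class ConsolidatedStore:
    """Interactors, RIGID groups and lookup tables over one record corpus."""

    def __init__(self) -> None:
        self.interactors: dict[str, Interactor] = {}
        self.records: dict[int, SourceRecord] = {}
        self.rigid_groups: dict[str, RigidGroup] = {}
        self.record_rigid: dict[int, str] = {}
        self.lookup_table: dict[tuple[str, str], set[str]] = defaultdict(set)
        self.overall_degree: dict[str, int] = {}
        self._partners: dict[str, set[str]] = defaultdict(set)
        self._records_by_rogid: dict[str, set[int]] = defaultdict(set)
        self.n_input_records = 0
        self.n_excluded_records = 0

    # -- construction ---------------------------------------------------

    def add_interactor(self, interactor: Interactor) -> None:
        key = interactor.rogid.full
        existing = self.interactors.get(key)
        if existing is None:
            self.interactors[key] = interactor
        else:
            for acc_type, values in interactor.accessions.items():
                for value in values:
                    existing.add_accession(acc_type, value)
            if existing.sequence is None:
                existing.sequence = interactor.sequence
            if existing.canonical_rogid is None:
                existing.canonical_rogid = interactor.canonical_rogid
        self._index_accessions(self.interactors[key])

    def _index_accessions(self, interactor: Interactor) -> None:
        key = interactor.rogid.full
        self.lookup_table[("rogid", key)].add(key)
        for acc_type, values in interactor.accessions.items():
            for value in values:
                if acc_type in _CASE_INSENSITIVE:
                    value = value.lower()
                self.lookup_table[(acc_type, value)].add(key)

    def add_record(self, record: SourceRecord) -> None:
        self.n_input_records += 1
        unknown = [r.full for r in record.participant_rogids if r.full not in self.interactors]
        if unknown:
            self.n_excluded_records += 1
            logger.warning(
                "record %d references unknown interactors %s; excluded",
                record.record_id, unknown,
            )
            return
        rigid = record.rigid.value
        self.records[record.record_id] = record
        self.record_rigid[record.record_id] = rigid
        group = self.rigid_groups.setdefault(rigid, RigidGroup(rigid=rigid))
        group.record_ids.append(record.record_id)
        group.distinct_pmids.update(record.pmids)
        members = {r.full for r in record.participant_rogids}
        for member in members:
            self._records_by_rogid[member].add(record.record_id)
            self._partners[member].update(members - {member})

    def finalize(self) -> None:
        """Recompute degrees after all records are added."""
        self.overall_degree = {
            rogid: len(self._partners.get(rogid, ())) for rogid in self.interactors
        }

    # -- statistics ------------------------------------------------------

    @property
    def n_records(self) -> int:
        return len(self.records)

    @property
    def n_rigids(self) -> int:
        return len(self.rigid_groups)

    @property
    def n_rogids(self) -> int:
        return len(self.interactors)

    @property
    def n_participating_rogids(self) -> int:
        """Distinct interactors appearing in at least one kept record."""
        return len(self._records_by_rogid)

    def summary(self) -> dict[str, int]:
        return {
            "source_records": self.n_records,
            "distinct_rigids": self.n_rigids,
            "distinct_rogids": self.n_rogids,
            "excluded_records": self.n_excluded_records,
        }

    # -- scores ----------------------------------------------------------

    def compute_scores(self) -> None:
        """Attach np (publication count) and lpr scores to every RIGID group.

        ``score_np`` is the number of distinct supporting PMIDs. ``score_lpr``
        is the minimum, over those PMIDs, of the number of distinct RIGIDs
        each PMID supports anywhere in the corpus — a low value means at
        least one supporting publication was low-throughput.
        """
        rigids_per_pmid: dict[int, set[str]] = defaultdict(set)
        for record_id, record in self.records.items():
            rigid = self.record_rigid[record_id]
            for pmid in record.pmids:
                rigids_per_pmid[pmid].add(rigid)
        for group in self.rigid_groups.values():
            if not group.distinct_pmids:
                group.score_np = None
                group.score_lpr = None
                logger.warning("rigid %s has no supporting PMIDs; scores null", group.rigid)
                continue
            group.score_np = len(group.distinct_pmids)
            group.score_lpr = min(len(rigids_per_pmid[p]) for p in group.distinct_pmids)

    # -- search ----------------------------------------------------------

    def lookup(self, query: str, search_type: str) -> set[str]:
        """Resolve one identifier to the set of matching full ROGID strings.

        Gene-type queries (``entrez_gene``, ``gene_symbol``) return the
        ROGIDs of every protein product of the gene. Unknown identifiers
        return the empty set.
        """
        if search_type not in SEARCH_TYPES:
            raise ValueError(f"unsupported search type {search_type!r}")
        if search_type in _CASE_INSENSITIVE:
            query = query.lower()
        hits = self.lookup_table.get((search_type, query), set())
        if not hits:
            logger.info("no match for %s query %r", search_type, query)
        return set(hits)

    def canonical_expand(self, rogids: set[str]) -> set[str]:
        """Expand a ROGID set to all members of its canonical groups."""
        wanted_canonicals = set()
        for rogid in rogids:
            interactor = self.interactors.get(rogid)
            if interactor is not None and interactor.canonical_rogid is not None:
                wanted_canonicals.add(interactor.canonical_rogid.full)
        expanded = set(rogids)
        if wanted_canonicals:
            for key, interactor in self.interactors.items():
                if (
                    interactor.canonical_rogid is not None
                    and interactor.canonical_rogid.full in wanted_canonicals
                ):
                    expanded.add(key)
        return expanded

    def neighbourhood(self, rogids: set[str], iterations: int = 1) -> list[SourceRecord]:
        """Breadth-first record retrieval around a ROGID set.

        iterations=0 returns only records fully inside the query set (the
        induced record set); iterations=k first expands the node set k times
        through record co-membership, then returns every record touching it.
        """
        if iterations < 0:
            raise ValueError("iterations must be >= 0")
        if iterations == 0:
            return self.complete_neighbourhood(rogids)
        # k-step BFS over the record hypergraph: a record is retrieved when
        # it touches any node reachable within k-1 expansion steps.
        reached = self._nodes_within(rogids, iterations - 1)
        result_ids: set[int] = set()
        for rogid in reached:
            result_ids.update(self._records_by_rogid.get(rogid, ()))
        return [self.records[i] for i in sorted(result_ids)]

    def _nodes_within(self, rogids: set[str], steps: int) -> set[str]:
        nodes = set(rogids)
        frontier = set(rogids)
        for _ in range(steps):
            new_nodes: set[str] = set()
            for rogid in frontier:
                for record_id in self._records_by_rogid.get(rogid, ()):
                    for member in self.records[record_id].participant_rogids:
                        new_nodes.add(member.full)
            frontier = new_nodes - nodes
            nodes |= new_nodes
            if not frontier:
                break
        return nodes

    def complete_neighbourhood(self, current_rogids: set[str]) -> list[SourceRecord]:
        """All records whose participants all lie within ``current_rogids``.

        Idempotent: completing a completed view adds nothing, because the
        node set is unchanged.
        """
        candidate_ids: set[int] = set()
        for rogid in current_rogids:
            candidate_ids.update(self._records_by_rogid.get(rogid, ()))
        result = []
        for record_id in sorted(candidate_ids):
            record = self.records[record_id]
            if all(r.full in current_rogids for r in record.participant_rogids):
                result.append(record)
        return result

    # -- reachability bookkeeping ----------------------------------------

    def reachability(self, type_order: list[str] | None = None) -> dict[str, float]:
        """Fraction of ROGIDs first reachable per accession type.

        Types are tried in ``type_order``; each interactor is counted under
        the first type it carries, with a final catch-all class for
        interactors reachable only by ROGID. Fractions sum to 1.
        """
        if type_order is None:
            type_order = ["uniprot", "refseq", "pdb", "xref"]
        counts = {t: 0 for t in type_order}
        counts["rogid_only"] = 0
        for interactor in self.interactors.values():
            for acc_type in type_order:
                if interactor.accessions.get(acc_type):
                    counts[acc_type] += 1
                    break
            else:
                counts["rogid_only"] += 1
        total = max(len(self.interactors), 1)
        return {t: c / total for t, c in counts.items()}


def consolidate(
    records: list[SourceRecord],
    interactors: dict[str, Interactor],
) -> ConsolidatedStore:
    """Build a consolidated store from parsed records and interactors."""
    store = ConsolidatedStore()
    for interactor in interactors.values():
        store.add_interactor(interactor)
    for record in records:
        store.add_record(record)
    store.finalize()
    store.compute_scores()
    return store
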