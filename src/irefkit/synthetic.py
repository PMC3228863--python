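"""Seeded synthetic corpora exercising every structure the pipeline handles.

A generated corpus contains: redundant records re-curated across simulated
source databases (same participant multiset, permuted order, switched
accession systems), splice-isoform products of shared genes, n-ary records,
planted spoke patterns (hub + partners, one publication, one
co-purification method, one database) among decoys, high-throughput
publications of configurable yield (for lpr scoring), and predicted edges.
Ground-truth tables are produced by independent bookkeeping during
generation — participant multisets, union-find gene groups, planted spoke
membership and per-publication yields — never by running the pipeline
itself.
"""

from __future__ import annotations

import json
import random
import string
from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml

from irefkit.identity import Rogid, compute_rogid
from irefkit.mitab_io import (
    Interactor,
    SourceRecord,
    write_annotation_table,
    write_fasta,
    write_mitab,
)
from irefkit.mining import DEFAULT_NARY_METHODS, DiseaseGroup

RESIDUES = "ACDEFGHIKLMNPQRSTVWY"

# methods outside DEFAULT_NARY_METHODS, used for regular/HTP records
_BINARY_METHODS = [
    ("MI:0018", "two hybrid"),
    ("MI:0114", "x-ray crystallography"),
    ("MI:0077", "nuclear magnetic resonance"),
]
_NARY_METHOD_LIST = sorted(DEFAULT_NARY_METHODS)

_DISEASE_TITLES = [
    "Breast cancer", "Leukoencephalopathy", "Cardiomyopathy, dilated",
    "Obesity, severe", "Deafness, autosomal recessive", "Diabetes mellitus",
]


class SimConfigError(ValueError):
    """Raised for inconsistent simulation configurations."""


@dataclass
class SimConfig:
    n_proteins: int = 100
    n_genes: int = 60
    isoform_rate: float = 0.3
    n_records: int = 200
    n_source_dbs: int = 3
    duplication_rate: float = 0.3
    nary_fraction: float = 0.1
    nary_size_range: tuple[int, int] = (3, 6)
    spoke_pattern_count: int = 3
    spoke_size_range: tuple[int, int] = (3, 6)
    htp_paper_count: int = 1
    htp_yield: int = 20
    predicted_fraction: float = 0.05
    decoy_nary_method_fraction: float = 0.2
    taxids: tuple[int, ...] = (9606,)
    seed: int = 0

    def validate(self) -> None:
        for name in ("isoform_rate", "duplication_rate", "nary_fraction",
                     "predicted_fraction", "decoy_nary_method_fraction"):
            value = getattr(self, name)
            if not 0.0 <= value <= 1.0:
                raise SimConfigError(f"{name} must be in [0, 1], got {value}")
        for name in ("n_proteins", "n_genes", "n_records", "n_source_dbs"):
            if getattr(self, name) <= 0:
                raise SimConfigError(f"{name} must be positive")
        if self.nary_fraction > 0 and self.nary_size_range[1] < 3:
            raise SimConfigError("nary_fraction > 0 requires nary_size_range max >= 3")
        if self.nary_size_range[0] > self.nary_size_range[1]:
            raise SimConfigError("nary_size_range must be (low, high) with low <= high")
        if self.spoke_pattern_count and self.spoke_size_range[0] < 2:
            raise SimConfigError("spoke patterns need at least 2 partners")
        if self.n_proteins < self.nary_size_range[1] + 1:
            raise SimConfigError("n_proteins too small for requested n-ary sizes")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimConfig":
        with open(path) as handle:
            data = yaml.safe_load(handle) or {}
        for key in ("nary_size_range", "spoke_size_range", "taxids"):
            if key in data:
                data[key] = tuple(data[key])
        return cls(**data)


@dataclass
class Corpus:
    """In-memory generated corpus plus its ground truth."""

    config: SimConfig
    records: list[SourceRecord]
    interactors: dict[str, Interactor]
    sequences: dict[str, str]
    gene_to_proteins: dict[int, set[str]]
    isoform_links: dict[str, set[str]]
    xref_links: dict[int, set[str]]
    uniprot_canonical_flags: dict[str, bool]
    disease_groups: list[DiseaseGroup]
    ground_truth: dict = field(default_factory=dict)


class _UnionFind:
    def __init__(self) -> None:
        self.parent: dict[int, int] = {}

    def find(self, x: int) -> int:
        self.parent.setdefault(x, x)
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, a: int, b: int) -> None:
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[max(ra, rb)] = min(ra, rb)


def _multiset_key(rogids: list[str]) -> tuple[str, ...]:
    return tuple(sorted(rogids))


def generate_corpus(config: SimConfig, out_dir: str | Path | None = None) -> Corpus:
    """Generate a corpus (optionally writing its files) from a seeded config.

    The same seed yields a byte-identical corpus. Ground truth recorded:
    ``rigid_groups`` (participant-multiset key -> record ids),
    ``n_distinct_interactions``, ``n_distinct_interactors``,
    ``gene_groups`` (list of gene-id lists), ``canonical_of`` (rogid ->
    canonical rogid), ``spoke_candidates`` (planted hub/member/record sets)
    and ``publication_yields`` (pmid -> distinct interactions supported).
    """
    config.validate()
    rng = random.Random(config.seed)

    # --- proteins -------------------------------------------------------
    sequences: dict[str, str] = {}
    rogids: list[str] = []
    lengths: dict[str, int] = {}
    while len(rogids) < config.n_proteins:
        length = rng.randint(50, 500)
        seq = "".join(rng.choice(RESIDUES) for _ in range(length))
        taxid = rng.choice(config.taxids)
        rogid = compute_rogid(seq, taxid).full
        if rogid in sequences:
            continue
        sequences[rogid] = seq
        lengths[rogid] = length
        rogids.append(rogid)

    interactors: dict[str, Interactor] = {}
    for i, rogid in enumerate(rogids):
        entry = Interactor(
            rogid=Rogid.from_full(rogid),
            taxid=Rogid.from_full(rogid).taxid,
            sequence=sequences[rogid],
            irogid=i,
        )
        entry.add_accession("uniprot", f"P{10000 + i}")
        entry.add_accession("refseq", f"NP_{100000 + i}")
        if rng.random() < 0.3:
            entry.add_accession("pdb", f"{rng.randint(1, 9)}" + "".join(
                rng.choice(string.ascii_uppercase) for _ in range(3)))
        if rng.random() < 0.2:
            entry.add_accession("original_reference", f"OLD_{i}")
        if rng.random() < 0.2:
            entry.add_accession("xref", f"XR_{i}")
        interactors[rogid] = entry

    # --- genes, isoforms, canonical ground truth ------------------------
    gene_to_proteins: dict[int, set[str]] = {}
    uf = _UnionFind()
    gene_ids = [1000 + g for g in range(config.n_genes)]
    for gene in gene_ids:
        uf.find(gene)
        gene_to_proteins[gene] = set()
    unassigned = list(rogids)
    rng.shuffle(unassigned)
    # ~70% of proteins are gene products; the rest stay orphan so isoform
    # and xref expansion links have material to pull in
    n_assigned = max(1, int(round(0.7 * config.n_proteins)))
    for i, rogid in enumerate(unassigned[:n_assigned]):
        gene = gene_ids[i % config.n_genes]
        gene_to_proteins[gene].add(rogid)
    # plant shared products: some adjacent gene pairs share one product
    for i in range(1, config.n_genes):
        if rng.random() < config.isoform_rate / 2:
            donor, receiver = gene_ids[i - 1], gene_ids[i]
            if gene_to_proteins[donor]:
                shared = rng.choice(sorted(gene_to_proteins[donor]))
                gene_to_proteins[receiver].add(shared)
                uf.union(donor, receiver)
    for gene, proteins in gene_to_proteins.items():
        for rogid in proteins:
            interactors[rogid].add_accession("entrez_gene", str(gene))
            interactors[rogid].add_accession("gene_symbol", f"GENE{gene}")

    # isoform/xref expansion links stay inside the owning gene's group so
    # planted group membership is exact
    isoform_links: dict[str, set[str]] = {}
    xref_links: dict[int, set[str]] = {}
    grouped = {r for proteins in gene_to_proteins.values() for r in proteins}
    orphan_pool = [r for r in unassigned[n_assigned:] if r not in grouped]
    for gene in gene_ids:
        if orphan_pool and rng.random() < config.isoform_rate and gene_to_proteins[gene]:
            orphan = orphan_pool.pop()
            if rng.random() < 0.5:
                anchor = rng.choice(sorted(gene_to_proteins[gene]))
                isoform_links.setdefault(anchor, set()).add(orphan)
            else:
                xref_links.setdefault(gene, set()).add(orphan)
            grouped.add(orphan)
            interactors[orphan].add_accession("entrez_gene", str(gene))
            interactors[orphan].add_accession("gene_symbol", f"GENE{gene}")

    # expected expanded membership per gene-group component
    component_of: dict[int, int] = {g: uf.find(g) for g in gene_ids}
    expected_members: dict[int, set[str]] = {}
    for gene in gene_ids:
        root = component_of[gene]
        members = expected_members.setdefault(root, set())
        members |= gene_to_proteins[gene]
        members |= xref_links.get(gene, set())
    for anchor, extras in isoform_links.items():
        for gene in gene_ids:
            if anchor in gene_to_proteins[gene]:
                expected_members[component_of[gene]] |= extras

    uniprot_canonical_flags = {r: False for r in rogids}
    canonical_of: dict[str, str] = {}
    gene_groups: list[list[int]] = []
    for root in sorted(expected_members):
        members = expected_members[root]
        genes_in_group = sorted(g for g in gene_ids if component_of[g] == root)
        gene_groups.append(genes_in_group)
        if not members:
            continue
        ordered = sorted(members)
        n_flagged = rng.choice([0, 1, 1, 2])
        flagged = rng.sample(ordered, min(n_flagged, len(ordered)))
        for rogid in flagged:
            uniprot_canonical_flags[rogid] = True
        pool = flagged if flagged else ordered
        canonical = min(pool, key=lambda r: (-lengths[r], r))
        for rogid in members:
            canonical_of[rogid] = canonical
    for rogid in rogids:
        canonical_of.setdefault(rogid, rogid)
    for rogid, canonical in canonical_of.items():
        interactors[rogid].canonical_rogid = Rogid.from_full(canonical)

    # --- interaction records --------------------------------------------
    dbs = [f"simdb{d}" for d in range(config.n_source_dbs)] + ["ophid"]
    source_dbs = dbs[: config.n_source_dbs]
    records: list[SourceRecord] = []
    used_pairs: set[frozenset[str]] = set()
    used_nary: set[tuple[str, ...]] = set()
    rigid_groups: dict[tuple[str, ...], list[int]] = {}
    pmid_of_record: dict[int, list[int]] = {}
    next_pmid = [100000]
    next_acc = [1]

    def fresh_pmid() -> int:
        next_pmid[0] += 1
        return next_pmid[0]

    def add_record(record: SourceRecord) -> None:
        records.append(record)
        key = _multiset_key([r.full for r in record.participant_rogids])
        rigid_groups.setdefault(key, []).append(record.record_id)
        pmid_of_record[record.record_id] = list(record.pmids)

    def new_record_id() -> int:
        return len(records)

    # planted spoke patterns (excluded from duplication/prediction)
    spoke_truth = []
    spoke_db = source_dbs[0]
    for _ in range(config.spoke_pattern_count):
        n_partners = rng.randint(*config.spoke_size_range)
        members = rng.sample(rogids, n_partners + 1)
        hub, partners = members[0], members[1:]
        pmid = fresh_pmid()
        method = rng.choice(_NARY_METHOD_LIST)
        spoke_ids = []
        ok_partners = []
        for partner in partners:
            pair = frozenset((hub, partner))
            if pair in used_pairs:
                continue
            used_pairs.add(pair)
            record = SourceRecord(
                record_id=new_record_id(),
                source_db=spoke_db,
                source_acc=f"S{next_acc[0]}",
                participants=[(Rogid.from_full(hub), "bait"),
                              (Rogid.from_full(partner), "prey")],
                pmids=[pmid],
                method_cv=method,
                method_name="co-purification",
                interaction_type_cv="MI:0914",
                interaction_type_name="association",
                edgetype="X",
            )
            next_acc[0] += 1
            add_record(record)
            spoke_ids.append(record.record_id)
            ok_partners.append(partner)
        if len(spoke_ids) >= 2:
            spoke_truth.append({
                "hub": hub,
                "members": sorted([hub] + ok_partners),
                "source_db": spoke_db,
                "pmid": pmid,
                "method_cv": method,
                "record_ids": spoke_ids,
            })

    # regular records: binary (with decoy n-ary-method singletons) + n-ary
    n_regular = max(config.n_records - len(records), 0)
    htp_pmids = [fresh_pmid() for _ in range(config.htp_paper_count)]
    htp_quota = {p: config.htp_yield for p in htp_pmids}

    def assign_pmid(allow_htp: bool) -> int:
        if allow_htp:
            for pmid in htp_pmids:
                if htp_quota[pmid] > 0:
                    htp_quota[pmid] -= 1
                    return pmid
        return fresh_pmid()

    base_records: list[SourceRecord] = []
    for _ in range(n_regular):
        db = rng.choice(source_dbs)
        predicted = rng.random() < config.predicted_fraction
        if predicted:
            db = "ophid"
        if rng.random() < config.nary_fraction:
            size = rng.randint(max(config.nary_size_range[0], 3), config.nary_size_range[1])
            for _attempt in range(20):
                members = tuple(sorted(rng.sample(rogids, size)))
                if members not in used_nary:
                    break
            used_nary.add(members)
            record = SourceRecord(
                record_id=new_record_id(),
                source_db=db,
                source_acc=f"S{next_acc[0]}",
                participants=[(Rogid.from_full(m), "neutral") for m in members],
                pmids=[assign_pmid(allow_htp=False)],
                method_cv=rng.choice(_NARY_METHOD_LIST),
                method_name="co-purification",
                interaction_type_cv="MI:0914",
                interaction_type_name="association",
                edgetype="C",
                predicted=predicted,
            )
        else:
            for _attempt in range(50):
                a, b = rng.sample(rogids, 2)
                pair = frozenset((a, b))
                if pair not in used_pairs:
                    break
            else:
                continue
            used_pairs.add(pair)
            decoy_nary_method = rng.random() < config.decoy_nary_method_fraction
            if decoy_nary_method:
                method_cv = rng.choice(_NARY_METHOD_LIST)
                method_name = "co-purification"
                pmid = fresh_pmid()  # unique pmid: never forms a spoke bucket
            else:
                method_cv, method_name = rng.choice(_BINARY_METHODS)
                pmid = assign_pmid(allow_htp=True)
            record = SourceRecord(
                record_id=new_record_id(),
                source_db=db,
                source_acc=f"S{next_acc[0]}",
                participants=[(Rogid.from_full(a), "neutral"),
                              (Rogid.from_full(b), "neutral")],
                pmids=[pmid],
                method_cv=method_cv,
                method_name=method_name,
                interaction_type_cv="MI:0915",
                interaction_type_name="physical association",
                edgetype="X",
                predicted=predicted,
            )
        next_acc[0] += 1
        add_record(record)
        base_records.append(record)

    # cross-database re-curation: same participants (permuted), same pmids,
    # uid columns switched to a different accession system
    acc_cycle = ["refseq", "uniprot", "rogid"]
    for base in list(base_records):
        if base.predicted:
            continue  # predicted edges exist only in the prediction db
        if rng.random() >= config.duplication_rate:
            continue
        other_dbs = [d for d in source_dbs if d != base.source_db] or source_dbs
        participants = list(base.participants)
        rng.shuffle(participants)
        acc_type = rng.choice(acc_cycle)
        record = SourceRecord(
            record_id=new_record_id(),
            source_db=rng.choice(other_dbs),
            source_acc=f"S{next_acc[0]}",
            participants=participants,
            pmids=list(base.pmids),
            method_cv=base.method_cv,
            method_name=base.method_name,
            interaction_type_cv=base.interaction_type_cv,
            interaction_type_name=base.interaction_type_name,
            edgetype=base.edgetype,
            predicted=base.predicted,
            uid_types=tuple([acc_type] * len(participants)),
        )
        next_acc[0] += 1
        add_record(record)

    # --- publication yields (distinct interactions per pmid) ------------
    supported: dict[int, set[tuple[str, ...]]] = {}
    for key, record_ids in rigid_groups.items():
        for record_id in record_ids:
            for pmid in pmid_of_record[record_id]:
                supported.setdefault(pmid, set()).add(key)
    publication_yields = {pmid: len(keys) for pmid, keys in supported.items()}

    # --- disease groups --------------------------------------------------
    disease_groups = []
    for i, title in enumerate(_DISEASE_TITLES):
        digid = 100 + i
        genes = set(rng.sample(gene_ids, min(4, len(gene_ids))))
        omims = {600000 + 10 * i + j for j in range(2)}
        disease_groups.append(DiseaseGroup(
            digid=digid, title=title, omim_ids=omims, gene_ids=genes,
        ))

    touched = sorted({
        r.full for record in records for r in record.participant_rogids
    })
    ground_truth = {
        "rigid_groups": {"|".join(k): v for k, v in rigid_groups.items()},
        "n_source_records": len(records),
        "n_distinct_interactions": len(rigid_groups),
        "n_distinct_interactors": len(touched),
        "gene_groups": gene_groups,
        "expected_group_members": {
            str(root): sorted(members) for root, members in expected_members.items()
        },
        "canonical_of": canonical_of,
        "uniprot_canonical_flags": uniprot_canonical_flags,
        "spoke_candidates": spoke_truth,
        "publication_yields": publication_yields,
    }

    corpus = Corpus(
        config=config,
        records=records,
        interactors=interactors,
        sequences=sequences,
        gene_to_proteins=gene_to_proteins,
        isoform_links=isoform_links,
        xref_links=xref_links,
        uniprot_canonical_flags=uniprot_canonical_flags,
        disease_groups=disease_groups,
        ground_truth=ground_truth,
    )
    if out_dir is not None:
        write_corpus(corpus, out_dir)
    return corpus


def write_corpus(corpus: Corpus, out_dir: str | Path) -> None:
    """Write all corpus files and ground-truth tables to a directory."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_mitab(corpus.records, out / "corpus.mitab", corpus.interactors)
    write_fasta(corpus.sequences, out / "corpus.fasta")
    write_annotation_table(corpus.interactors.values(), out / "annotations.tsv")
    with open(out / "gene2product.tsv", "w") as handle:
        for gene in sorted(corpus.gene_to_proteins):
            for rogid in sorted(corpus.gene_to_proteins[gene]):
                handle.write(f"{gene}\t{rogid}\n")
    with open(out / "isoform_links.tsv", "w") as handle:
        for anchor in sorted(corpus.isoform_links):
            for other in sorted(corpus.isoform_links[anchor]):
                handle.write(f"{anchor}\t{other}\n")
    with open(out / "xref_links.tsv", "w") as handle:
        for gene in sorted(corpus.xref_links):
            for rogid in sorted(corpus.xref_links[gene]):
                handle.write(f"{gene}\t{rogid}\n")
    with open(out / "uniprot_canonical.tsv", "w") as handle:
        for rogid in sorted(corpus.uniprot_canonical_flags):
            flag = corpus.uniprot_canonical_flags[rogid]
            handle.write(f"{rogid}\t{int(flag)}\n")
    with open(out / "disease_groups.tsv", "w") as handle:
        for group in corpus.disease_groups:
            omims = sorted(group.omim_ids) or ["-"]
            genes = sorted(group.gene_ids) or ["-"]
            for omim in omims:
                handle.write(f"{group.digid}\t{group.title}\t{omim}\t-\n")
            for gene in genes:
                handle.write(f"{group.digid}\t{group.title}\t-\t{gene}\n")
    with open(out / "ground_truth.json", "w") as handle:
        json.dump(corpus.ground_truth, handle, indent=1, sort_keys=True)
    with open(out / "config.yaml", "w") as handle:
        yaml.safe_dump(asdict(corpus.config), handle, sort_keys=True)
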