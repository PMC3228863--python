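import random

import pytest

from irefkit.graph import build_view
from irefkit.mining import (
    DEFAULT_NARY_METHODS,
    AdjacencyCell,
    DiseaseGroup,
    SpokeCandidate,
    adjacency_matrix,
    detect_spoke_complexes,
    disease_search,
    hidden_rows_cols,
    load_nary_methods,
    matrix_select,
    read_disease_groups,
    write_matrix_html,
    write_matrix_tsv,
)
from irefkit.store import consolidate
from irefkit.synthetic import SimConfig, generate_corpus

from conftest import binary_record, make_protein, nary_record


def build(records, proteins):
    return consolidate(records, {p.rogid.full: p for p in proteins})


# ----------------------------------------------------------------- spokes

class TestSpokeDetection:
    def spoke_records(self, hub, partners, *, db="dbA", pmid=50, method="MI:0004"):
        return [
            binary_record(i, hub, partner, source_db=db, pmids=(pmid,),
                          method_cv=method, roles=("bait", "prey"))
            for i, partner in enumerate(partners)
        ]

    def test_five_records_one_hub_six_members(self, proteins):
        extras = [make_protein(f"MW{'A' * i}K") for i in range(5)]
        hub = proteins[0]
        records = self.spoke_records(hub, extras)
        candidates = detect_spoke_complexes(records)
        assert len(candidates) == 1
        (cand,) = candidates
        assert cand.hub_rogid == hub.rogid.full
        assert len(cand.member_rogids) == 6
        assert len(cand.record_ids) == 5

    def test_single_record_no_candidate(self, proteins):
        records = self.spoke_records(proteins[0], [proteins[1]])
        assert detect_spoke_complexes(records) == []

    def test_two_source_dbs_evaluated_separately(self, proteins):
        hub, p1, p2 = proteins[:3]
        records = (
            self.spoke_records(hub, [p1], db="dbA")
            + [binary_record(9, hub, p2, source_db="dbB", pmids=(50,),
                             method_cv="MI:0004", roles=("bait", "prey"))]
        )
        assert detect_spoke_complexes(records) == []

    def test_non_nary_method_never_contributes(self, proteins):
        hub = proteins[0]
        records = self.spoke_records(hub, proteins[1:4], method="MI:0018")
        assert detect_spoke_complexes(records) == []

    def test_mismatched_pmids_split_buckets(self, proteins):
        hub = proteins[0]
        records = [
            binary_record(i, hub, p, pmids=(100 + i,), method_cv="MI:0004",
                          roles=("bait", "prey"))
            for i, p in enumerate(proteins[1:4])
        ]
        assert detect_spoke_complexes(records) == []

    def test_bait_preferred_as_hub(self, proteins):
        hub = proteins[0]
        records = self.spoke_records(hub, proteins[1:3])
        (cand,) = detect_spoke_complexes(records)
        assert cand.hub_rogid == hub.rogid.full

    def test_nary_records_ignored(self, proteins):
        records = [
            nary_record(0, proteins[:3], pmids=(50,)),
            nary_record(1, proteins[:3], pmids=(50,), source_acc="other"),
        ]
        assert detect_spoke_complexes(records) == []

    def test_custom_methods_file(self, tmp_path, proteins):
        methods_file = tmp_path / "methods.txt"
        methods_file.write_text("# co-purification methods\nMI:0018\n")
        methods = load_nary_methods(methods_file)
        assert methods == frozenset({"MI:0018"})
        hub = proteins[0]
        records = self.spoke_records(hub, proteins[1:3], method="MI:0018")
        (cand,) = detect_spoke_complexes(records, methods)
        assert cand.method_cv == "MI:0018"

    def test_candidate_invariants_enforced(self, proteins):
        with pytest.raises(ValueError):
            SpokeCandidate("h", {"h", "x"}, "dbA", 1, "MI:0004", record_ids=[1])
        with pytest.raises(ValueError):
            SpokeCandidate("h", {"x", "y"}, "dbA", 1, "MI:0004", record_ids=[1, 2])

    @pytest.mark.parametrize("seed", range(25))
    def test_planted_patterns_precision_recall_one(self, seed):
        """Planted spokes among decoys recovered exactly (the 100-instance
        sweep lives in the acceptance suite)."""
        corpus = generate_corpus(SimConfig(
            spoke_pattern_count=4, decoy_nary_method_fraction=0.4, seed=seed,
        ))
        candidates = detect_spoke_complexes(corpus.records)
        got = {
            (c.hub_rogid, tuple(sorted(c.member_rogids)), c.source_db, c.pmid, c.method_cv)
            for c in candidates
        }
        planted = {
            (t["hub"], tuple(t["members"]), t["source_db"], t["pmid"], t["method_cv"])
            for t in corpus.ground_truth["spoke_candidates"]
        }
        assert got == planted

    def test_candidates_satisfy_invariants(self, corpus):
        for cand in detect_spoke_complexes(corpus.records):
            assert len(cand.record_ids) >= 2
            assert cand.hub_rogid in cand.member_rogids
            supporting = [r for r in corpus.records if r.record_id in cand.record_ids]
            assert all(r.edgetype == "X" for r in supporting)
            assert {r.source_db for r in supporting} == {cand.source_db}
            assert all(cand.pmid in r.pmids for r in supporting)
            assert {r.method_cv for r in supporting} == {cand.method_cv}
            assert all(
                cand.hub_rogid in {p.full for p in r.participant_rogids}
                for r in supporting
            )


# ---------------------------------------------------------------- disease

class TestDiseaseSearch:
    @pytest.fixture
    def groups(self):
        return [
            DiseaseGroup(197, "Breast cancer", {114480}, {672, 675}),
            DiseaseGroup(198, "Breast-ovarian cancer", {604370}, {675, 5888}),
            DiseaseGroup(300, "Deafness", {220290}, {2706}),
        ]

    def test_unknown_digid_empty(self, groups):
        assert disease_search(999, groups) == set()

    def test_digid_returns_genes(self, groups):
        assert disease_search("197", groups) == {672, 675}

    def test_omim_id_finds_containing_group(self, groups):
        assert disease_search(604370, groups, search_type="omim") == {675, 5888}

    def test_title_fragment_unions_groups(self, groups):
        assert disease_search("cancer", groups, search_type="omim_title") == {672, 675, 5888}

    def test_title_match_case_insensitive(self, groups):
        assert disease_search("BREAST", groups, search_type="omim_title") == {672, 675, 5888}

    def test_unknown_search_type(self, groups):
        with pytest.raises(ValueError):
            disease_search("x", groups, search_type="icd10")

    def test_table_round_trip(self, tmp_path, groups):
        path = tmp_path / "digid.tsv"
        lines = []
        for g in groups:
            for omim in sorted(g.omim_ids):
                lines.append(f"{g.digid}\t{g.title}\t{omim}\t-")
            for gene in sorted(g.gene_ids):
                lines.append(f"{g.digid}\t{g.title}\t-\t{gene}")
        path.write_text("\n".join(lines) + "\n")
        loaded = read_disease_groups(path)
        assert [(g.digid, g.title, g.omim_ids, g.gene_ids) for g in loaded] == [
            (g.digid, g.title, g.omim_ids, g.gene_ids) for g in groups
        ]


# ----------------------------------------------------------------- matrix

def matrix_oracle(view, group_a, group_b):
    """Brute-force classification by length-<=2 path / shared-pseudonode
    enumeration over the raw edge list."""
    graph = view.graph
    protein = lambda n: not graph.nodes[n]["i.pseudonode"]
    classes = {}
    for row in group_b:
        for col in group_a:
            if row == col:
                classes[(row, col)] = "SELF"
                continue
            direct = graph.number_of_edges(row, col) > 0
            inter = set()
            for x in graph.nodes:
                if x in (row, col):
                    continue
                if graph.number_of_edges(row, x) > 0 and graph.number_of_edges(x, col) > 0:
                    inter.add(x)
            if direct and inter:
                classes[(row, col)] = "BOTH"
            elif direct:
                classes[(row, col)] = "DIRECT"
            elif inter:
                classes[(row, col)] = "INDIRECT"
            else:
                classes[(row, col)] = "NONE"
    return classes


class TestAdjacencyMatrix:
    @pytest.fixture
    def abx_view(self, proteins):
        a, b, x, y = proteins[:4]
        records = [
            binary_record(0, a, b),       # direct a-b
            binary_record(1, a, x),       # path a-x
            binary_record(2, x, b),       # path x-b
            binary_record(3, y, y),       # unrelated self loop keeps y in view
        ]
        store = build(records, proteins[:4])
        view = build_view(records, set(), store=store)
        return view, a, b, x, y

    def test_direct_cell(self, proteins):
        a, b = proteins[:2]
        records = [binary_record(0, a, b)]
        view = build_view(records, set(), store=build(records, proteins[:2]))
        matrix = adjacency_matrix(view, {a.rogid.full}, {b.rogid.full})
        cell = matrix[(b.rogid.full, a.rogid.full)]
        assert cell.cell_class == "DIRECT"
        assert cell.colour == "red" and cell.symbol and cell.intermediates == []

    def test_indirect_cell(self, proteins):
        a, b, x = proteins[:3]
        records = [binary_record(0, a, x), binary_record(1, x, b)]
        view = build_view(records, set(), store=build(records, proteins[:3]))
        cell = adjacency_matrix(view, {a.rogid.full}, {b.rogid.full})[
            (b.rogid.full, a.rogid.full)]
        assert cell.cell_class == "INDIRECT"
        assert cell.colour == "blue" and not cell.symbol
        assert cell.intermediates == [x.rogid.full]

    def test_both_cell(self, abx_view):
        view, a, b, x, y = abx_view
        cell = adjacency_matrix(view, {a.rogid.full}, {b.rogid.full})[
            (b.rogid.full, a.rogid.full)]
        assert cell.cell_class == "BOTH"
        assert cell.colour == "green" and cell.symbol
        assert cell.intermediates == [x.rogid.full]

    def test_none_cell_and_hiding(self, abx_view):
        view, a, b, x, y = abx_view
        matrix = adjacency_matrix(view, {a.rogid.full, y.rogid.full}, {b.rogid.full})
        assert matrix[(b.rogid.full, y.rogid.full)].cell_class == "NONE"
        assert matrix[(b.rogid.full, y.rogid.full)].colour == "black"
        hidden_rows, hidden_cols = hidden_rows_cols(matrix)
        assert hidden_cols == {y.rogid.full}
        assert hidden_rows == set()

    def test_self_cell_lists_direct_interactors(self, abx_view):
        view, a, b, x, y = abx_view
        matrix = adjacency_matrix(view, {a.rogid.full}, {a.rogid.full, b.rogid.full})
        cell = matrix[(a.rogid.full, a.rogid.full)]
        assert cell.cell_class == "SELF"
        assert set(cell.intermediates) == {b.rogid.full, x.rogid.full}

    def test_shared_pseudonode_is_indirect(self, proteins):
        record = nary_record(0, proteins[:3])
        store = build([record], proteins)
        view = build_view([record], set(), store=store)
        a, b = proteins[0].rogid.full, proteins[1].rogid.full
        cell = adjacency_matrix(view, {a}, {b})[(b, a)]
        assert cell.cell_class == "INDIRECT"
        assert cell.intermediates == [record.rigid.value]

    def test_empty_group_errors(self, abx_view):
        view, a, *_ = abx_view
        with pytest.raises(ValueError):
            adjacency_matrix(view, set(), {a.rogid.full})

    def test_transpose_under_group_swap(self, corpus):
        store = consolidate(corpus.records, corpus.interactors)
        view = build_view(list(store.records.values()), set(), store=store)
        rng = random.Random(2)
        nodes = view.protein_nodes
        group_a = set(rng.sample(nodes, 8))
        group_b = set(rng.sample(nodes, 8))
        fwd = adjacency_matrix(view, group_a, group_b)
        rev = adjacency_matrix(view, group_b, group_a)
        for (row, col), cell in fwd.items():
            mirror = rev[(col, row)]
            assert mirror.cell_class == cell.cell_class
            assert sorted(mirror.intermediates) == sorted(cell.intermediates)

    @pytest.mark.parametrize("seed", range(5))
    def test_equals_brute_force_oracle_random_graphs(self, seed):
        corpus = generate_corpus(SimConfig(
            n_proteins=60, n_genes=30, n_records=150, nary_fraction=0.2, seed=seed,
        ))
        store = consolidate(corpus.records, corpus.interactors)
        view = build_view(list(store.records.values()), set(), store=store)
        rng = random.Random(seed)
        nodes = view.protein_nodes
        group_a = set(rng.sample(nodes, min(10, len(nodes))))
        group_b = set(rng.sample(nodes, min(10, len(nodes))))
        matrix = adjacency_matrix(view, group_a, group_b)
        expected = matrix_oracle(view, group_a, group_b)
        got = {pair: cell.cell_class for pair, cell in matrix.items()}
        assert got == expected


class TestMatrixSelect:
    @pytest.fixture
    def setup(self, proteins):
        a, b, x = proteins[:3]
        records = [
            binary_record(0, a, b),
            binary_record(1, a, b, source_db="dbB"),
            binary_record(2, a, x),
            binary_record(3, x, b),
        ]
        store = build(records, proteins[:3])
        view = build_view(records, set(), store=store)
        matrix = adjacency_matrix(view, {a.rogid.full}, {b.rogid.full})
        return view, matrix, a, b, x

    def test_heading_selects_node(self, setup):
        view, matrix, a, b, x = setup
        nodes, edges = matrix_select(matrix, view, row=b.rogid.full)
        assert nodes == {b.rogid.full} and edges == []

    def test_direct_cell_selects_parallel_edges(self, setup):
        view, matrix, a, b, x = setup
        nodes, edges = matrix_select(matrix, view, row=b.rogid.full, col=a.rogid.full)
        assert {a.rogid.full, b.rogid.full, x.rogid.full} == nodes
        direct = [e for e in edges if {e[0], e[1]} == {a.rogid.full, b.rogid.full}]
        assert len(direct) == 2  # both parallel direct edges

    def test_intermediate_edges_included(self, setup):
        view, matrix, a, b, x = setup
        _, edges = matrix_select(matrix, view, row=b.rogid.full, col=a.rogid.full)
        bundles = {frozenset((e[0], e[1])) for e in edges}
        assert frozenset((a.rogid.full, x.rogid.full)) in bundles
        assert frozenset((x.rogid.full, b.rogid.full)) in bundles

    def test_none_cell_empty(self, proteins):
        a, b, c, d = proteins[:4]
        records = [binary_record(0, a, b), binary_record(1, c, d)]
        store = build(records, proteins[:4])
        view = build_view(records, set(), store=store)
        matrix = adjacency_matrix(view, {a.rogid.full}, {c.rogid.full})
        nodes, edges = matrix_select(matrix, view, row=c.rogid.full, col=a.rogid.full)
        assert nodes == set() and edges == []


class TestMatrixOutputs:
    def test_tsv_and_html_written(self, tmp_path, proteins):
        a, b = proteins[:2]
        records = [binary_record(0, a, b)]
        view = build_view(records, set(), store=build(records, proteins[:2]))
        matrix = adjacency_matrix(view, {a.rogid.full}, {b.rogid.full})
        write_matrix_tsv(matrix, tmp_path / "m.tsv")
        write_matrix_html(matrix, tmp_path / "m.html")
        tsv = (tmp_path / "m.tsv").read_text()
        assert "DIRECT" in tsv and "¤" in tsv
        html = (tmp_path / "m.html").read_text()
        assert "<table" in html and "#d9534f" in html
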