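# irefkit

Headless library + CLI for working with consolidated protein–protein
interaction data under a sequence-hash identity scheme.

Every distinct protein (amino-acid sequence + NCBI taxon) gets a **ROGID**
(unpadded base64 SHA-1 of the uppercased sequence, with the taxid appended);
every interaction record gets a **RIGID** (unpadded base64 SHA-1 of its
ASCII-sorted participant ROGIDs). Because these keys are derivable by anyone
from the raw data, records curated independently by different source
databases collapse into the same interaction group, regardless of which
accession system each database used.

On top of that identity scheme the package provides:

- **PSI-MITAB 2.5 I/O** in a tab-delimited dialect with extension columns
  (`rogida`, `rogidb`, `rigid`, `crogida`, `crogidb`, `edgetype`,
  `numParticipants`, `roles`); n-ary records are serialized bipartite-style
  as one row per member sharing a `complex:<rigid>` key.
- A **consolidated store**: RIGID grouping, multi-accession lookup tables
  (UniProt, RefSeq, Entrez Gene, gene symbol, PDB, xref, retired
  accessions, raw ROGIDs), bibliometric scores per interaction group
  (`np` = distinct supporting publications, `lpr` = lowest
  interaction-yield among them), neighbourhood queries and neighbourhood
  completion.
- **Canonicalization**: related gene groups built from shared protein
  products, expanded via isoform/cross-reference links, with a canonical
  ROGID chosen per group (UniProt-canonical first, then longest, ties to
  ASCII-smallest) — used for canonical search expansion.
- A **network view**: multigraph of protein nodes with one evidence edge
  per source record, hexagon-style pseudonodes for n-ary records, the
  `i.*` node/edge attribute vocabulary (`i.order`, `i.query`, `i.alive`,
  `i.alive_degree`, `i.overall_degree`, `i.flag`, `i.score_np`,
  `i.score_lpr`, ...), multi-edge toggling, between-nodes selection, and
  identifier-collapsing export.
- **Mining**: spoke-represented-complex detection (binary records sharing
  database, publication, co-purification-style method and a hub),
  disease-group search (digid / OMIM id / title fragment), and a
  group-vs-group adjacency matrix classifying pairs as
  DIRECT/INDIRECT/BOTH/NONE/SELF with intermediates listed per cell.
- A **synthetic corpus generator** that plants all of the above structures
  with full ground-truth bookkeeping, used by the test and acceptance
  suites.

## CLI

```bash
# generate a seeded synthetic corpus with ground truth
irefkit simulate --seed 1 --out corpus/

# build a flat-file index from MITAB (+ FASTA + annotation table)
irefkit build-index --mitab corpus/corpus.mitab --fasta corpus/corpus.fasta \
    --annotations corpus/annotations.tsv --out index/

# search (any accession type), expand, complete the neighbourhood
irefkit search --index index/ --type uniprot --query P10001 \
    --iterations 1 --complete --canonical-expand --out hits

# two-group comparison, COMPARE{...|...} syntax or explicit groups
irefkit search --index index/ --query 'COMPARE{P10001,P10002|P10003}' --out cmp
irefkit matrix --index index/ --group-a P10001,P10002 --group-b P10003 --out cmp

# spoke-represented complex candidates over the whole index
irefkit spokes --index index/ --out spokes.tsv

# collapse the network onto another identifier type
irefkit export --index index/ --id-type entrez_gene --out exported

# ROGIDs for a FASTA file
irefkit rogid sequences.fasta --taxid 9606
```

Exit codes: 0 success, 1 validation error, 2 I/O error. Each command
prints a JSON run summary.

## Tests

```bash
python -m pytest -q tests/
```

The suite includes unit tests per module, hypothesis property tests
(hash determinism, RIGID permutation invariance, round-trips) and
`tests/test_acceptance.py`, which implements the acceptance criteria at
full stated scale (independent SHA-1/base64 oracle, 10,000-sequence
collision check, brute-force consolidation/score/matrix/BFS oracles,
100-instance planted-structure recovery sweeps).

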