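"""Reading and writing interaction records in a PSI-MITAB 2.5 dialect.

The dialect is the 15 standard MITAB 2.5 columns followed by eight
extension columns::

    uidA uidB altA altB aliasA aliasB method author pmids taxa taxb
    interactionType sourcedb interactionIdentifier confidence
    rogida rogidb rigid crogida crogidb edgetype numParticipants roles

Binary records occupy one row. An n-ary record with *k* members is
serialized as *k* rows sharing ``uidA = "complex:<rigid>"``, one row per
member, with the member in the B columns. Missing fields are ``-``.
Extension identifier columns are recomputable from sequences; on read they
are verified against recomputed values when sequences are available, and
the recomputed value wins on mismatch (with a warning).

The ``confidence`` column carries ``predicted:1`` for predicted
(OPHID-style) edges; all other records write ``-``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO

from irefkit.identity import Rigid, Rogid, compute_rigid, compute_rogid

logger = logging.getLogger(__name__)

COLUMNS = [
    "uidA", "uidB", "altA", "altB", "aliasA", "aliasB",
    "method", "author", "pmids", "taxa", "taxb",
    "interactionType", "sourcedb", "interactionIdentifier", "confidence",
    "rogida", "rogidb", "rigid", "crogida", "crogidb",
    "edgetype", "numParticipants", "roles",
]

MISSING = "-"

ROLES = ("bait", "prey", "neutral")

ACCESSION_TYPES = (
    "uniprot", "refseq", "entrez_gene", "gene_symbol", "pdb", "xref",
    "original_reference",
)

# uid column prefix <-> accession type
_UID_PREFIX = {
    "uniprot": "uniprotkb",
    "refseq": "refseq",
    "entrez_gene": "entrezgene",
    "gene_symbol": "genesymbol",
    "pdb": "pdb",
    "xref": "xref",
    "original_reference": "originalreference",
    "rogid": "rogid",
}
_PREFIX_UID = {v: k for k, v in _UID_PREFIX.items()}


class MitabParseError(ValueError):
    """Raised for malformed MITAB rows; carries the 1-based line number."""

    def __init__(self, message: str, line_number: int | None = None):
        self.line_number = line_number
        if line_number is not None:
            message = f"line {line_number}: {message}"
        super().__init__(message)


@dataclass
class Interactor:
    """One distinct (sequence, taxon) protein.

    ``accessions`` maps accession type to a list of values; the ``rogid``
    equals ``compute_rogid(sequence, taxid)`` whenever the sequence is
    known. ``irogid`` is an integer surrogate unique within one store.
    """

    rogid: Rogid
    taxid: int
    sequence: str | None = None
    irogid: int | None = None
    accessions: dict[str, list[str]] = field(default_factory=dict)
    canonical_rogid: Rogid | None = None

    def add_accession(self, acc_type: str, value: str) -> None:
        values = self.accessions.setdefault(acc_type, [])
        if value not in values:
            values.append(value)

    def preferred_uid(self) -> tuple[str, str]:
        """(accession type, value) used for uid columns, by fixed priority."""
        for acc_type in ("uniprot", "refseq", "entrez_gene", "pdb", "xref"):
            if self.accessions.get(acc_type):
                return acc_type, self.accessions[acc_type][0]
        return "rogid", self.rogid.full


@dataclass
class SourceRecord:
    """One interaction record from one source database (binary or n-ary)."""

    record_id: int
    source_db: str
    source_acc: str
    participants: list[tuple[Rogid, str]]  # (rogid, role)
    pmids: list[int] = field(default_factory=list)
    method_cv: str | None = None
    method_name: str | None = None
    interaction_type_cv: str | None = None
    interaction_type_name: str | None = None
    edgetype: str = "X"
    predicted: bool = False
    uid_types: tuple[str, ...] | None = None  # accession type used per uid column

    def __post_init__(self) -> None:
        if self.edgetype not in ("X", "C"):
            raise ValueError(f"edgetype must be 'X' or 'C', got {self.edgetype!r}")
        if self.edgetype == "X" and len(self.participants) != 2:
            raise ValueError("binary (X) records must have exactly 2 participants")
        if self.edgetype == "C" and len(self.participants) < 2:
            raise ValueError("n-ary (C) records must have at least 2 participants")
        baits = sum(1 for _, role in self.participants if role == "bait")
        if baits > 1:
            raise ValueError("at most one bait per record")
        for _, role in self.participants:
            if role not in ROLES:
                raise ValueError(f"unknown participant role {role!r}")

    @property
    def participant_rogids(self) -> list[Rogid]:
        return [rogid for rogid, _ in self.participants]

    @property
    def rigid(self) -> Rigid:
        return compute_rigid(self.participant_rogids)

    @property
    def bait(self) -> Rogid | None:
        for rogid, role in self.participants:
            if role == "bait":
                return rogid
        return None


def _fmt_cv(cv: str | None, name: str | None) -> str:
    if cv is None and name is None:
        return MISSING
    return f"{cv or 'MI:0000'}({name or '-'})"


def _parse_cv(text: str) -> tuple[str | None, str | None]:
    if text == MISSING or not text:
        return None, None
    if "(" in text and text.endswith(")"):
        cv, name = text.split("(", 1)
        name = name[:-1]
        return (cv or None), (None if name == MISSING else name)
    return text, None


def _fmt_uid(interactor: Interactor | None, rogid: Rogid, acc_type: str | None) -> tuple[str, str]:
    """Return (uid cell, accession type actually used)."""
    if interactor is not None and acc_type and interactor.accessions.get(acc_type):
        return f"{_UID_PREFIX[acc_type]}:{interactor.accessions[acc_type][0]}", acc_type
    if acc_type == "rogid" or interactor is None:
        return f"rogid:{rogid.full}", "rogid"
    used, value = interactor.preferred_uid()
    return f"{_UID_PREFIX[used]}:{value}", used


def _fmt_alt(interactor: Interactor | None) -> str:
    if interactor is None:
        return MISSING
    parts = []
    for acc_type in ("uniprot", "refseq", "entrez_gene", "pdb"):
        for value in interactor.accessions.get(acc_type, []):
            parts.append(f"{_UID_PREFIX[acc_type]}:{value}")
    return "|".join(parts) if parts else MISSING


def _fmt_alias(interactor: Interactor | None) -> str:
    if interactor is None:
        return MISSING
    parts = [f"genesymbol:{v}" for v in interactor.accessions.get("gene_symbol", [])]
    return "|".join(parts) if parts else MISSING


def _member_cells(
    rogid: Rogid,
    role: str,
    interactors: dict[str, Interactor] | None,
    acc_type: str | None,
) -> dict[str, str]:
    interactor = interactors.get(rogid.full) if interactors else None
    uid, used = _fmt_uid(interactor, rogid, acc_type)
    crogid = MISSING
    if interactor is not None and interactor.canonical_rogid is not None:
        crogid = interactor.canonical_rogid.full
    return {
        "uid": uid,
        "alt": _fmt_alt(interactor),
        "alias": _fmt_alias(interactor),
        "tax": f"taxid:{rogid.taxid}",
        "rogid": rogid.full,
        "crogid": crogid,
        "role": role,
        "used": used,
    }


def write_mitab(
    records: Iterable[SourceRecord],
    path: str | Path,
    interactors: dict[str, Interactor] | None = None,
) -> None:
    """Serialize records to a MITAB file (see module docstring for dialect).

    ``interactors`` (keyed by full ROGID string) supplies accessions for the
    uid/alt/alias columns and canonical ROGIDs; without it, uid columns fall
    back to ``rogid:`` form.
    """
    path = Path(path)
    lines = ["#" + "\t".join(COLUMNS)]
    for rec in records:
        rigid = rec.rigid.value
        shared = {
            "method": _fmt_cv(rec.method_cv, rec.method_name),
            "author": MISSING,
            "pmids": "|".join(f"pubmed:{p}" for p in rec.pmids) or MISSING,
            "interactionType": _fmt_cv(rec.interaction_type_cv, rec.interaction_type_name),
            "sourcedb": rec.source_db,
            "interactionIdentifier": f"{rec.source_db}:{rec.source_acc}",
            "confidence": "predicted:1" if rec.predicted else MISSING,
            "rigid": rigid,
            "edgetype": rec.edgetype,
            "numParticipants": str(len(rec.participants)),
        }
        uid_types = rec.uid_types or (None,) * len(rec.participants)
        if rec.edgetype == "X":
            a = _member_cells(*rec.participants[0], interactors, uid_types[0])
            b = _member_cells(*rec.participants[1], interactors, uid_types[1])
            lines.append("\t".join([
                a["uid"], b["uid"], a["alt"], b["alt"], a["alias"], b["alias"],
                shared["method"], shared["author"], shared["pmids"],
                a["tax"], b["tax"],
                shared["interactionType"], shared["sourcedb"],
                shared["interactionIdentifier"], shared["confidence"],
                a["rogid"], b["rogid"], shared["rigid"],
                a["crogid"], b["crogid"],
                shared["edgetype"], shared["numParticipants"],
                f"{a['role']}|{b['role']}",
            ]))
        else:
            complex_uid = f"complex:{rigid}"
            for (rogid, role), acc_type in zip(rec.participants, uid_types):
                b = _member_cells(rogid, role, interactors, acc_type)
                lines.append("\t".join([
                    complex_uid, b["uid"], MISSING, b["alt"], MISSING, b["alias"],
                    shared["method"], shared["author"], shared["pmids"],
                    MISSING, b["tax"],
                    shared["interactionType"], shared["sourcedb"],
                    shared["interactionIdentifier"], shared["confidence"],
                    rigid, b["rogid"], shared["rigid"],
                    MISSING, b["crogid"],
                    shared["edgetype"], shared["numParticipants"],
                    b["role"],
                ]))
    path.write_text("\n".join(lines) + "\n")


def _parse_member(cells: dict[str, str], suffix: str, line_no: int) -> tuple[Rogid, str, str | None]:
    """Extract (rogid, uid accession type) for member A or B of a row."""
    rogid_text = cells["rogid" + suffix.lower()]
    try:
        rogid = Rogid.from_full(rogid_text)
    except Exception as exc:
        raise MitabParseError(f"bad rogid{suffix} {rogid_text!r}: {exc}", line_no)
    uid = cells["uid" + suffix]
    uid_type = None
    if ":" in uid:
        prefix = uid.split(":", 1)[0]
        uid_type = _PREFIX_UID.get(prefix)
    return rogid, uid, uid_type


def _harvest_accessions(interactor: Interactor, alt: str, alias: str) -> None:
    for cell in (alt, alias):
        if cell == MISSING:
            continue
        for chunk in cell.split("|"):
            if ":" not in chunk:
                continue
            prefix, value = chunk.split(":", 1)
            acc_type = _PREFIX_UID.get(prefix)
            if acc_type:
                interactor.add_accession(acc_type, value)


def read_mitab(
    path: str | Path,
    sequences: dict[str, str] | None = None,
) -> tuple[list[SourceRecord], dict[str, Interactor]]:
    """Parse a MITAB file into records plus a deduplicated interactor table.

    Rows sharing one ``complex:<rigid>`` uidA are assembled into a single
    n-ary record regardless of row order. ``sequences`` (full ROGID string
    -> amino-acid sequence) enables verification of the identifier columns:
    a stored ROGID that disagrees with the recomputed one is replaced by the
    recomputed value with a warning.

    Returns
    -------
    (records, interactors)
        ``interactors`` is keyed by full ROGID string.
    """
    path = Path(path)
    interactors: dict[str, Interactor] = {}
    binary_rows: list[tuple[int, dict[str, str]]] = []
    complex_rows: dict[str, list[tuple[int, dict[str, str]]]] = {}

    with path.open() as handle:
        for line_no, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#") or line.startswith("uidA\t"):
                continue
            cells_list = line.split("\t")
            if len(cells_list) != len(COLUMNS):
                raise MitabParseError(
                    f"expected {len(COLUMNS)} columns, found {len(cells_list)}",
                    line_no,
                )
            cells = dict(zip(COLUMNS, cells_list))
            if cells["uidA"].startswith("complex:"):
                # two redundant n-ary records share a RIGID (hence uidA);
                # the source accession keeps their rows apart
                group_key = f"{cells['uidA']}\t{cells['interactionIdentifier']}"
                complex_rows.setdefault(group_key, []).append((line_no, cells))
            else:
                binary_rows.append((line_no, cells))

    records: list[SourceRecord] = []
    next_id = 0

    def _interactor_for(rogid: Rogid, cells: dict[str, str], suffix: str) -> Rogid:
        nonlocal_seq = sequences.get(rogid.full) if sequences else None
        if nonlocal_seq is not None:
            recomputed = compute_rogid(nonlocal_seq, rogid.taxid)
            if recomputed.full != rogid.full:
                logger.warning(
                    "stored rogid %s disagrees with recomputed %s; recomputed wins",
                    rogid.full, recomputed.full,
                )
                rogid = recomputed
        entry = interactors.get(rogid.full)
        if entry is None:
            entry = Interactor(rogid=rogid, taxid=rogid.taxid, sequence=nonlocal_seq)
            interactors[rogid.full] = entry
        _harvest_accessions(entry, cells["alt" + suffix], cells["alias" + suffix])
        crogid = cells["crogid" + suffix.lower()]
        if crogid != MISSING and entry.canonical_rogid is None:
            entry.canonical_rogid = Rogid.from_full(crogid)
        return rogid

    def _shared_fields(cells: dict[str, str]) -> dict:
        method_cv, method_name = _parse_cv(cells["method"])
        itype_cv, itype_name = _parse_cv(cells["interactionType"])
        pmids = []
        if cells["pmids"] != MISSING:
            for chunk in cells["pmids"].split("|"):
                value = chunk.split(":", 1)[-1]
                if value.isdigit():
                    pmids.append(int(value))
                else:
                    logger.warning("unparseable pmid field %r; kept null", chunk)
        source_acc = cells["interactionIdentifier"]
        if ":" in source_acc:
            source_acc = source_acc.split(":", 1)[1]
        return {
            "source_db": cells["sourcedb"],
            "source_acc": source_acc,
            "pmids": pmids,
            "method_cv": method_cv,
            "method_name": method_name,
            "interaction_type_cv": itype_cv,
            "interaction_type_name": itype_name,
            "predicted": cells["confidence"].startswith("predicted:"),
        }

    for line_no, cells in binary_rows:
        rogid_a, _, type_a = _parse_member(cells, "A", line_no)
        rogid_b, _, type_b = _parse_member(cells, "B", line_no)
        rogid_a = _interactor_for(rogid_a, cells, "A")
        rogid_b = _interactor_for(rogid_b, cells, "B")
        roles = cells["roles"].split("|") if cells["roles"] != MISSING else ["neutral", "neutral"]
        if len(roles) != 2:
            raise MitabParseError(f"binary row needs 2 roles, got {cells['roles']!r}", line_no)
        records.append(SourceRecord(
            record_id=next_id,
            participants=[(rogid_a, roles[0]), (rogid_b, roles[1])],
            edgetype="X",
            uid_types=(type_a, type_b) if (type_a or type_b) else None,
            **_shared_fields(cells),
        ))
        next_id += 1

    # Complex groups are assembled in deterministic (sorted-key) order so the
    # record list is independent of row order in the file.
    for complex_uid in sorted(complex_rows):
        rows = complex_rows[complex_uid]
        participants: list[tuple[Rogid, str]] = []
        uid_types: list[str | None] = []
        for line_no, cells in rows:
            rogid_b, _, type_b = _parse_member(cells, "B", line_no)
            rogid_b = _interactor_for(rogid_b, cells, "B")
            role = cells["roles"] if cells["roles"] != MISSING else "neutral"
            participants.append((rogid_b, role))
            uid_types.append(type_b)
        # member rows carry identical shared metadata; first row wins
        order = sorted(range(len(rows)), key=lambda i: rows[i][0])
        participants = [participants[i] for i in order]
        uid_types = [uid_types[i] for i in order]
        first_cells = rows[order[0]][1]
        if len(participants) == 2:
            logger.warning(
                "n-ary record %s lists only 2 members; kept with edgetype C",
                complex_uid,
            )
        records.append(SourceRecord(
            record_id=next_id,
            participants=participants,
            edgetype="C",
            uid_types=tuple(uid_types) if any(uid_types) else None,
            **_shared_fields(first_cells),
        ))
        next_id += 1

    for i, entry in enumerate(interactors.values()):
        entry.irogid = i

    return records, interactors


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read sequences keyed by full ROGID string from a FASTA file."""
    return {record.id: str(record.seq) for record in SeqIO.parse(str(path), "fasta")}


def write_fasta(sequences: dict[str, str], path: str | Path) -> None:
    """Write sequences keyed by full ROGID string to a FASTA file."""
    with Path(path).open("w") as handle:
        for name in sorted(sequences):
            handle.write(f">{name}\n{sequences[name]}\n")


def read_annotation_table(path: str | Path) -> list[tuple[str, int, str, str]]:
    """Read a 4-column (rogid, taxid, accession_type, accession_value) TSV."""
    rows = []
    with Path(path).open() as handle:
        for line_no, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 4:
                raise MitabParseError("annotation table needs 4 columns", line_no)
            rogid, taxid, acc_type, value = parts
            rows.append((rogid, int(taxid), acc_type, value))
    return rows


def write_annotation_table(
    interactors: Iterable[Interactor], path: str | Path
) -> None:
    lines = []
    for entry in interactors:
        for acc_type in sorted(entry.accessions):
            for value in entry.accessions[acc_type]:
                lines.append(f"{entry.rogid.full}\t{entry.taxid}\t{acc_type}\t{value}")
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))
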