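"""Sequence-hash identifiers for interactors (ROGID) and interactions (RIGID).

A ROGID is the base64-encoded SHA-1 digest of an uppercased, whitespace-free
amino-acid sequence with trailing ``=`` padding stripped, followed by the
decimal NCBI taxonomy identifier. A RIGID is the base64-encoded SHA-1 digest
of the concatenation of the participant ROGIDs sorted in ASCII byte order,
again with padding stripped. Both keys are global: anyone holding the
sequence and taxon (or the participant list) can regenerate them, which is
what makes cross-database record consolidation possible.
"""

from __future__ import annotations

import base64
import hashlib
import logging
import re
from dataclasses import dataclass
from typing import Iterable, Sequence

logger = logging.getLogger(__name__)

# 20 standard residues plus ambiguity/extension codes B, J, O, U, X, Z and *.
_IUPAC_EXTENDED = set("ACDEFGHIKLMNPQRSTVWYBJOUXZ*")

#: Number of base64 characters in an unpadded SHA-1 digest (20 bytes).
DIGEST_LEN = 27

_WHITESPACE_RE = re.compile(r"\s+")


class InvalidInputError(ValueError):
    """Raised when an identifier cannot be computed from the given input."""


@dataclass(frozen=True)
class Rogid:
    """Redundant object group identifier for one (sequence, taxon) protein."""

    digest_part: str
    taxid: int

    def __post_init__(self) -> None:
        if len(self.digest_part) != DIGEST_LEN:
            raise InvalidInputError(
                f"ROGID digest part must be {DIGEST_LEN} characters, "
                f"got {len(self.digest_part)!r}"
            )

    @property
    def full(self) -> str:
        return f"{self.digest_part}{self.taxid}"

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.full

    @classmethod
    def from_full(cls, full: str) -> "Rogid":
        """Split a full ROGID string back into digest part and taxid."""
        digest_part, tax = full[:DIGEST_LEN], full[DIGEST_LEN:]
        if not tax.isdigit():
            raise InvalidInputError(f"malformed ROGID string: {full!r}")
        return cls(digest_part=digest_part, taxid=int(tax))


@dataclass(frozen=True)
class Rigid:
    """Redundant interaction group identifier for one participant multiset."""

    value: str

    def __post_init__(self) -> None:
        if len(self.value) != DIGEST_LEN:
            raise InvalidInputError(
                f"RIGID must be {DIGEST_LEN} characters, got {self.value!r}"
            )

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.value


def _sha1_b64(data: bytes) -> str:
    """Unpadded base64 of the SHA-1 digest of ``data``."""
    return base64.b64encode(hashlib.sha1(data).digest()).decode("ascii").rstrip("=")


def compute_rogid(sequence: str, taxid: int) -> Rogid:
    """Compute the ROGID for an amino-acid sequence and NCBI taxon.

    The sequence is stripped of all whitespace and uppercased before
    hashing; the taxid is appended as decimal text after the digest (it is
    not part of the hashed bytes).

    Parameters
    ----------
    sequence:
        Amino-acid sequence; case and embedded whitespace are ignored.
    taxid:
        Positive NCBI taxonomy identifier.

    Raises
    ------
    InvalidInputError
        If the sequence is empty after whitespace stripping or the taxid is
        not a positive integer.
    """
    cleaned = _WHITESPACE_RE.sub("", sequence).upper()
    if not cleaned:
        raise InvalidInputError("empty sequence")
    if not isinstance(taxid, int) or isinstance(taxid, bool) or taxid <= 0:
        raise InvalidInputError(f"taxid must be a positive integer, got {taxid!r}")
    nonstandard = set(cleaned) - _IUPAC_EXTENDED
    if nonstandard:
        # Legacy records contain nonstandard residues; hash as-is, never drop.
        logger.warning(
            "sequence contains non-IUPAC residue characters %s; hashing as-is",
            "".join(sorted(nonstandard)),
        )
    return Rogid(digest_part=_sha1_b64(cleaned.encode("ascii")), taxid=taxid)


def _rigid_from_sorted_strings(rogid_strings: Sequence[str]) -> Rigid:
    """Hash an already-validated list of full ROGID strings.

    Isolated so the duplicate-participant policy (multiset preserved, i.e.
    a self-interaction listing a protein twice hashes it twice) can be
    changed in exactly one place.
    """
    joined = "".join(sorted(rogid_strings)).encode("ascii")
    return Rigid(value=_sha1_b64(joined))


def compute_rigid(participant_rogids: Iterable[Rogid | str]) -> Rigid:
    """Compute the RIGID for a multiset of participant ROGIDs.

    Participants are sorted by ASCII byte order of their full ROGID strings
    and concatenated without separator before digesting, so the result is
    invariant under permutation of the input list. Duplicate participants
    are preserved (hashed as many times as listed).

    Raises
    ------
    InvalidInputError
        If the participant list is empty.
    """
    strings = [r.full if isinstance(r, Rogid) else str(r) for r in participant_rogids]
    if not strings:
        raise InvalidInputError("participant list must be non-empty")
    return _rigid_from_sorted_strings(strings)


def filename_safe(key: Rogid | Rigid | str) -> str:
    """Return the filename-safe form of an identifier.

    Replaces ``/`` with ``_`` and ``+`` with ``-`` (the base64url
    convention); all other characters pass through unchanged. The mapping is
    injective on valid keys because ``_`` and ``-`` are not in the standard
    base64 alphabet.
    """
    text = key.full if isinstance(key, Rogid) else key.value if isinstance(key, Rigid) else key
    return text.replace("/", "_").replace("+", "-")


def filename_unsafe(safe: str) -> str:
    """Invert :func:`filename_safe`, restoring the base64 alphabet."""
    return safe.replace("_", "/").replace("-", "+")
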