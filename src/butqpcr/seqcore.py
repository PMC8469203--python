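"""IUPAC ambiguity-code algebra and degenerate-sequence operations.

A degenerate oligonucleotide is written over the 15-letter IUPAC nucleotide
alphabet, each letter denoting a nonempty subset of {A, C, G, T}.  The
*degeneracy* of such a sequence is the number of concrete (A/C/G/T-only)
variants it represents: the product of the per-position subset sizes.  These
primitives underpin primer design, in-silico PCR and the concentration rule
used for degenerate qPCR assays.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from itertools import product as _iterproduct
from typing import Iterable, Iterator

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "IUPAC_SETS",
    "SET_TO_SYMBOL",
    "DegenerateSeq",
    "SequenceRecord",
    "consensus_symbol",
    "degeneracy",
    "expand",
    "matches",
    "revcomp",
    "read_fasta",
    "write_fasta",
]

#: IUPAC nucleotide symbol -> set of concrete bases it denotes.
IUPAC_SETS: dict[str, frozenset[str]] = {
    "A": frozenset("A"),
    "C": frozenset("C"),
    "G": frozenset("G"),
    "T": frozenset("T"),
    "R": frozenset("AG"),
    "Y": frozenset("CT"),
    "S": frozenset("CG"),
    "W": frozenset("AT"),
    "K": frozenset("GT"),
    "M": frozenset("AC"),
    "B": frozenset("CGT"),
    "D": frozenset("AGT"),
    "H": frozenset("ACT"),
    "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
}

SET_TO_SYMBOL: dict[frozenset[str], str] = {s: c for c, s in IUPAC_SETS.items()}

_BASE_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

#: symbol -> symbol of the complemented base set (closed under complementation)
COMPLEMENT: dict[str, str] = {
    c: SET_TO_SYMBOL[frozenset(_BASE_COMPLEMENT[b] for b in s)]
    for c, s in IUPAC_SETS.items()
}

#: default cap on explicit expansion, guarding pathological patterns
DEFAULT_EXPANSION_CAP = 4096


class ExpansionCapExceeded(ValueError):
    """Raised when explicit expansion would produce more variants than allowed."""


def consensus_symbol(bases: Iterable[str]) -> str:
    """Return the minimal IUPAC symbol whose base set equals ``bases``.

    ``bases`` must be a nonempty collection of concrete bases (A/C/G/T).
    """
    s = frozenset(bases)
    if not s:
        raise ValueError("consensus of an empty base set is undefined")
    try:
        return SET_TO_SYMBOL[s]
    except KeyError:
        bad = sorted(s - frozenset("ACGT"))
        raise ValueError(f"not concrete bases: {bad}") from None


@dataclass(frozen=True)
class DegenerateSeq:
    """An IUPAC-coded oligonucleotide.

    Immutable; compares and hashes by its string form.  Invalid symbols are
    rejected at construction.
    """

    seq: str

    def __post_init__(self) -> None:
        if not self.seq:
            raise ValueError("empty degenerate sequence")
        s = self.seq.upper()
        bad = sorted(set(s) - set(IUPAC_SETS))
        if bad:
            raise ValueError(f"invalid IUPAC symbol(s): {bad}")
        object.__setattr__(self, "seq", s)

    def __len__(self) -> int:
        return len(self.seq)

    def __str__(self) -> str:
        return self.seq

    def __iter__(self) -> Iterator[str]:
        return iter(self.seq)

    def base_sets(self) -> list[frozenset[str]]:
        return [IUPAC_SETS[c] for c in self.seq]

    @property
    def degeneracy(self) -> int:
        return math.prod(len(IUPAC_SETS[c]) for c in self.seq)

    @property
    def is_concrete(self) -> bool:
        return self.degeneracy == 1

    def expand(self, cap: int = DEFAULT_EXPANSION_CAP) -> set[str]:
        d = self.degeneracy
        if d > cap:
            raise ExpansionCapExceeded(
                f"degeneracy {d} exceeds the expansion cap {cap}"
            )
        return {
            "".join(p) for p in _iterproduct(*(sorted(s) for s in self.base_sets()))
        }

    def revcomp(self) -> "DegenerateSeq":
        return DegenerateSeq("".join(COMPLEMENT[c] for c in reversed(self.seq)))


def _coerce(s: "DegenerateSeq | str") -> DegenerateSeq:
    return s if isinstance(s, DegenerateSeq) else DegenerateSeq(s)


def degeneracy(s: "DegenerateSeq | str") -> int:
    """Number of concrete variants the pattern represents."""
    return _coerce(s).degeneracy


def expand(s: "DegenerateSeq | str", cap: int = DEFAULT_EXPANSION_CAP) -> set[str]:
    """Explicit set of concrete variants; refuses when degeneracy exceeds ``cap``."""
    return _coerce(s).expand(cap)


def revcomp(s: "DegenerateSeq | str") -> DegenerateSeq:
    """Reverse complement on the ambiguity alphabet (an involution)."""
    return _coerce(s).revcomp()


def matches(
    pattern: "DegenerateSeq | str",
    window: str,
    max_mismatch: int = 0,
) -> tuple[bool, int]:
    """Match a degenerate pattern against a concrete window of equal length.

    A position matches iff the window base belongs to the pattern's base set
    there.  A template ``N`` (or any non-ACGT character, e.g. a gap) never
    matches: masked template regions must not produce phantom binding sites.

    Returns ``(ok, n_mismatches)`` where ``ok`` is ``n_mismatches <= max_mismatch``.
    """
    p = _coerce(pattern)
    if len(p) != len(window):
        raise ValueError(
            f"pattern length {len(p)} != window length {len(window)}"
        )
    mm = 0
    for c, w in zip(p.seq, window.upper()):
        if w not in IUPAC_SETS[c] or w not in "ACGT":
            mm += 1
    return mm <= max_mismatch, mm


@dataclass
class SequenceRecord:
    """A concrete nucleotide sequence with an identifier.

    Sequences are uppercased on ingestion; U is mapped to T with a warning;
    N is tolerated but flagged via :attr:`has_ambiguous`.  Gap characters
    (``-``) are only legal when the record is part of an alignment.
    """

    id: str
    seq: str
    description: str = ""
    has_ambiguous: bool = field(default=False, init=False)

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("sequence record id must be nonempty")
        s = self.seq.upper().replace(" ", "")
        if "U" in s:
            warnings.warn(f"{self.id}: RNA alphabet detected, mapping U->T")
            s = s.replace("U", "T")
        bad = set(s) - set("ACGTN-")
        if bad:
            raise ValueError(f"{self.id}: unexpected characters {sorted(bad)}")
        self.seq = s
        self.has_ambiguous = "N" in s

    def __len__(self) -> int:
        return len(self.seq)

    def ungapped(self) -> str:
        return self.seq.replace("-", "")


def read_fasta(path) -> list[SequenceRecord]:
    """Read a (possibly wrapped) multi-FASTA file into SequenceRecords."""
    out = []
    for rec in SeqIO.parse(str(path), "fasta"):
        out.append(SequenceRecord(id=rec.id, seq=str(rec.seq), description=rec.description))
    if not out:
        raise ValueError(f"no FASTA records found in {path}")
    return out


def write_fasta(records: Iterable[SequenceRecord], path) -> None:
    seqs = [
        SeqRecord(Seq(r.seq), id=r.id, description=r.description) for r in records
    ]
    SeqIO.write(seqs, str(path), "fasta")
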