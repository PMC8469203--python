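"""Packaged reference panel: curated *but*-gene target taxa and the
six-cluster degenerate primer panel, with TSV loaders and writers.

The *but* gene (butyryl-CoA:acetate CoA-transferase) is the dominant terminal
gene of colonic butyrate synthesis.  The packaged panel covers 36 curated
gut butyrate-producer genomes, grouped by phylogenetic proximity into six
clusters (A-F), each served by one degenerate primer pair.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Optional

from .quant import recommend_concentration
from .seqcore import DegenerateSeq

__all__ = [
    "TargetRecord",
    "PanelEntry",
    "load_reference_panel",
    "load_primer_panel",
    "write_primer_panel",
    "download_manifest",
    "CLUSTERS",
]

CLUSTERS = ("A", "B", "C", "D", "E", "F")


@dataclass(frozen=True)
class TargetRecord:
    """One curated *but*-gene-bearing taxon (strain-level)."""

    taxon: str
    nt_accession: str
    prot_accession: str
    cluster: Optional[str] = None
    seq: Optional[str] = None

    def __post_init__(self) -> None:
        if not self.taxon or not self.nt_accession or not self.prot_accession:
            raise ValueError("taxon and accessions must be nonempty")
        if self.cluster is not None and self.cluster not in CLUSTERS:
            raise ValueError(f"unknown cluster label {self.cluster!r}")


@dataclass(frozen=True)
class PanelEntry:
    """A degenerate primer pair serving one cluster of target taxa."""

    cluster: str
    fwd: DegenerateSeq
    rev: DegenerateSeq
    expected_len: int
    pair_degeneracy: int = field(init=False)
    recommended_conc: float = field(init=False)

    def __post_init__(self) -> None:
        if self.expected_len <= len(self.fwd) + len(self.rev):
            raise ValueError(
                f"cluster {self.cluster}: expected product length "
                f"{self.expected_len} not longer than the two primers"
            )
        object.__setattr__(
            self, "pair_degeneracy", self.fwd.degeneracy * self.rev.degeneracy
        )
        object.__setattr__(
            self, "recommended_conc", recommend_concentration(self.pair_degeneracy)
        )


def _parse_tsv(text: str, path: str, n_min: int, n_max: int) -> list[tuple[int, list[str]]]:
    rows = []
    for lineno, line in enumerate(text.splitlines(), start=1):
        if not line.strip() or line.lstrip().startswith("#"):
            continue
        fields = line.rstrip("\n").split("\t")
        if not (n_min <= len(fields) <= n_max):
            raise ValueError(
                f"{path}, line {lineno}: expected {n_min}..{n_max} "
                f"tab-separated fields, got {len(fields)}"
            )
        rows.append((lineno, fields))
    if not rows:
        raise ValueError(f"{path}: no data rows")
    return rows


def _packaged(name: str) -> str:
    return resources.files("butqpcr.data").joinpath(name).read_text()


def load_reference_panel(path: "str | Path | None" = None) -> list[TargetRecord]:
    """Load the curated target table (36 taxon/accession records).

    Reads the packaged fixture unless ``path`` points to a user TSV with the
    same schema (taxon, nt_accession, prot_accession, cluster).
    """
    src = str(path) if path else "targets.tsv"
    text = Path(path).read_text() if path else _packaged("targets.tsv")
    rows = _parse_tsv(text, src, 3, 4)
    header_line, header = rows[0]
    if header[:3] != ["taxon", "nt_accession", "prot_accession"]:
        raise ValueError(f"{src}, line {header_line}: unexpected header {header}")
    records = []
    seen = set()
    for lineno, f in rows[1:]:
        cluster = f[3] if len(f) > 3 and f[3] else None
        try:
            rec = TargetRecord(f[0], f[1], f[2], cluster)
        except ValueError as e:
            raise ValueError(f"{src}, line {lineno}: {e}") from None
        key = (rec.taxon, rec.nt_accession)
        if key in seen:
            raise ValueError(f"{src}, line {lineno}: duplicate record {key}")
        seen.add(key)
        records.append(rec)
    return records


def load_primer_panel(path: "str | Path | None" = None) -> list[PanelEntry]:
    """Load the degenerate primer panel (clusters A-F)."""
    src = str(path) if path else "primers.tsv"
    text = Path(path).read_text() if path else _packaged("primers.tsv")
    rows = _parse_tsv(text, src, 4, 4)
    header_line, header = rows[0]
    if header != ["cluster", "fwd", "rev", "expected_len"]:
        raise ValueError(f"{src}, line {header_line}: unexpected header {header}")
    entries = []
    for lineno, f in rows[1:]:
        try:
            entries.append(
                PanelEntry(f[0], DegenerateSeq(f[1]), DegenerateSeq(f[2]), int(f[3]))
            )
        except ValueError as e:
            raise ValueError(f"{src}, line {lineno}: {e}") from None
    return entries


def write_primer_panel(entries: Iterable[PanelEntry], path: "str | Path") -> None:
    """Serialize panel entries back to the primers.tsv schema."""
    lines = ["cluster\tfwd\trev\texpected_len"]
    for e in entries:
        lines.append(f"{e.cluster}\t{e.fwd}\t{e.rev}\t{e.expected_len}")
    Path(path).write_text("\n".join(lines) + "\n")


def download_manifest(records: Optional[Iterable[TargetRecord]] = None) -> str:
    """One nucleotide accession per line, for users who want to fetch the
    real template sequences (e.g. via NCBI efetch) for wet-panel validation.
    The library itself performs no network access.
    """
    if records is None:
        records = load_reference_panel()
    return "\n".join(r.nt_accession for r in records) + "\n"
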