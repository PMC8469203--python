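"""Degenerate primer-pair design on a clade, and the tree-descent driver.

The design problem: a functional gene (here *but*) is too variable across all
target taxa for any single primer pair, even a degenerate one.  The remedy is
phylogeny-guided: attempt one degenerate pair for the whole tree; where the
within-group variability defeats every candidate window, step down to the
child clades and try again, until every (designable) leaf is covered by some
cluster's pair.  Candidate primers are column-wise IUPAC consensi of
alignment windows, screened by degeneracy, Wallace-rule melting temperature,
GC content, 3'-clamp and member coverage.
"""

from __future__ import annotations

from bisect import bisect_left, bisect_right
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .panel import PanelEntry
from .seqcore import (
    IUPAC_SETS,
    SET_TO_SYMBOL,
    DegenerateSeq,
    SequenceRecord,
    matches,
)

__all__ = [
    "DesignConstraints",
    "DesignResult",
    "RecursiveDesignResult",
    "window_consensus",
    "primer_tm_range",
    "primer_gc_mean",
    "scan_candidates",
    "design_for_cluster",
    "recursive_design",
    "align_with_mafft",
]


@dataclass(frozen=True)
class DesignConstraints:
    """Screening thresholds for candidate primers and pairs.

    Defaults are calibrated so that every pair of the packaged six-cluster
    *but* panel passes the primer-level screen (lengths 18-23 nt, per-primer
    degeneracy up to 216, pair degeneracy up to 1728, Wallace Tm spanning
    50-68 °C, a concrete 3'-terminal base).
    """

    primer_len: tuple[int, int] = (18, 23)
    max_primer_degeneracy: int = 256
    max_pair_degeneracy: int = 2048
    product_len: tuple[int, int] = (400, 800)
    tm_range: tuple[float, float] = (48.0, 70.0)
    max_pair_delta_tm: float = 8.0
    gc_range: tuple[float, float] = (0.30, 0.70)
    three_prime_clamp: int = 1
    min_coverage: float = 1.0
    tm_target: float = 60.0

    def __post_init__(self) -> None:
        for lo, hi, what in (
            (*self.primer_len, "primer_len"),
            (*self.product_len, "product_len"),
            (*self.tm_range, "tm_range"),
            (*self.gc_range, "gc_range"),
        ):
            if lo > hi:
                raise ValueError(f"empty {what} range ({lo}, {hi})")
        if not (0 < self.min_coverage <= 1):
            raise ValueError("min_coverage must be in (0, 1]")


@dataclass(frozen=True)
class Candidate:
    """A screened primer candidate anchored to alignment columns.

    ``start``/``end`` are 0-based half-open alignment columns of the binding
    window on the plus strand; for reverse orientation the primer itself is
    the reverse complement of the window consensus.
    """

    primer: DegenerateSeq
    start: int
    end: int
    orientation: str  # "F" or "R"
    degeneracy: int
    tm_lo: float
    tm_hi: float
    gc: float

    @property
    def tm_mid(self) -> float:
        return 0.5 * (self.tm_lo + self.tm_hi)


@dataclass
class DesignResult:
    """Outcome of a design attempt on one clade."""

    members: frozenset[str]
    status: str  # "success" | "failure"
    pair: Optional[PanelEntry] = None
    diagnostics: dict = field(default_factory=dict)

    @property
    def success(self) -> bool:
        return self.status == "success"


@dataclass
class RecursiveDesignResult:
    """Covering panel produced by the root-down descent."""

    results: list[DesignResult]
    undesignable: list[str]
    attempts: int

    @property
    def clusters(self) -> list[frozenset[str]]:
        return [r.members for r in self.results]


def primer_tm_range(p: DegenerateSeq) -> tuple[float, float]:
    """Min/max Wallace-rule Tm (2(A+T) + 4(G+C)) over the primer's variants.

    Computed per position (min/max over each base set), avoiding expansion.
    """
    lo = hi = 0.0
    for s in p.base_sets():
        contrib = [2.0 if b in "AT" else 4.0 for b in s]
        lo += min(contrib)
        hi += max(contrib)
    return lo, hi


def primer_gc_mean(p: DegenerateSeq) -> float:
    """Mean GC fraction over the primer's variants (per-position average)."""
    return float(
        np.mean([sum(b in "GC" for b in s) / len(s) for s in p.base_sets()])
    )


def window_consensus(
    msa: Sequence[SequenceRecord], start: int, length: int
) -> Optional[DegenerateSeq]:
    """Column-wise IUPAC consensus of an alignment window.

    Returns ``None`` (design failure for this window) when any member carries
    a gap inside the window.  A member ``N`` makes the column ``N``.
    """
    if start < 0 or length < 1 or any(start + length > len(r.seq) for r in msa):
        raise ValueError("window out of alignment range")
    symbols = []
    for col in range(start, start + length):
        bases = {r.seq[col] for r in msa}
        if "-" in bases:
            return None
        if "N" in bases:
            symbols.append("N")
            continue
        symbols.append(SET_TO_SYMBOL[frozenset().union(*(IUPAC_SETS[b] for b in bases))])
    return DegenerateSeq("".join(symbols))


class _ColumnProfile:
    """Per-column consensus profile with prefix sums for O(1) window stats."""

    def __init__(self, msa: Sequence[SequenceRecord]) -> None:
        if not msa:
            raise ValueError("empty alignment")
        lens = {len(r.seq) for r in msa}
        if len(lens) > 1:
            raise ValueError("aligned sequences must have equal length")
        self.msa = msa
        L = lens.pop()
        self.length = L
        self.symbols = np.empty(L, dtype="<U1")
        gap = np.zeros(L, dtype=bool)
        log_deg = np.zeros(L)
        tm_lo = np.zeros(L)
        tm_hi = np.zeros(L)
        gc = np.zeros(L)
        concrete = np.zeros(L, dtype=bool)
        for col in range(L):
            bases = {r.seq[col] for r in msa}
            if "-" in bases:
                gap[col] = True
                self.symbols[col] = "-"
                continue
            if "N" in bases:
                s = frozenset("ACGT")
            else:
                s = frozenset().union(*(IUPAC_SETS[b] for b in bases))
            self.symbols[col] = SET_TO_SYMBOL[s]
            log_deg[col] = np.log2(len(s))
            contrib = [2.0 if b in "AT" else 4.0 for b in s]
            tm_lo[col] = min(contrib)
            tm_hi[col] = max(contrib)
            gc[col] = sum(b in "GC" for b in s) / len(s)
            concrete[col] = len(s) == 1
        z = np.zeros(1)
        self.cum_gap = np.concatenate([z, np.cumsum(gap)])
        self.cum_logdeg = np.concatenate([z, np.cumsum(log_deg)])
        self.cum_tmlo = np.concatenate([z, np.cumsum(tm_lo)])
        self.cum_tmhi = np.concatenate([z, np.cumsum(tm_hi)])
        self.cum_gc = np.concatenate([z, np.cumsum(gc)])
        self.concrete = concrete

    def window_ok(self, a: int, b: int) -> bool:
        return self.cum_gap[b] - self.cum_gap[a] == 0

    def window_logdeg(self, a: int, b: int) -> float:
        return float(self.cum_logdeg[b] - self.cum_logdeg[a])

    def window_tm(self, a: int, b: int) -> tuple[float, float]:
        return (
            float(self.cum_tmlo[b] - self.cum_tmlo[a]),
            float(self.cum_tmhi[b] - self.cum_tmhi[a]),
        )

    def window_gc(self, a: int, b: int) -> float:
        return float(self.cum_gc[b] - self.cum_gc[a]) / (b - a)

    def window_seq(self, a: int, b: int) -> DegenerateSeq:
        return DegenerateSeq("".join(self.symbols[a:b]))


def _coverage(primer: DegenerateSeq, msa, a: int, b: int, orientation: str) -> float:
    """Fraction of members the oriented primer matches with 0 mismatches."""
    site = primer if orientation == "F" else primer.revcomp()
    n_ok = sum(1 for r in msa if matches(site, r.seq[a:b], 0)[0])
    return n_ok / len(msa)


def scan_candidates(
    msa: Sequence[SequenceRecord],
    constraints: DesignConstraints = DesignConstraints(),
    orientation: str = "F",
    _profile: Optional[_ColumnProfile] = None,
    _diag: Optional[dict] = None,
) -> list[Candidate]:
    """All alignment windows passing the primer-level screen, ranked.

    Rank order: degeneracy ascending, then Wallace-Tm midpoint proximity to
    the Tm target (60 °C by default, matching a 60 °C annealing protocol),
    then leftmost window.  Reverse candidates are reverse-complemented window
    consensi with the 3' clamp applied at their own 3' end.
    """
    if orientation not in ("F", "R"):
        raise ValueError("orientation must be 'F' or 'R'")
    prof = _profile if _profile is not None else _ColumnProfile(msa)
    cns = constraints
    diag = _diag if _diag is not None else {}
    out: list[Candidate] = []
    max_logdeg = np.log2(cns.max_primer_degeneracy)
    for length in range(cns.primer_len[0], cns.primer_len[1] + 1):
        for a in range(0, prof.length - length + 1):
            b = a + length
            if not prof.window_ok(a, b):
                diag["gap"] = diag.get("gap", 0) + 1
                continue
            if prof.window_logdeg(a, b) > max_logdeg + 1e-9:
                diag["degeneracy"] = diag.get("degeneracy", 0) + 1
                continue
            # 3' clamp: terminal positions of the oriented primer concrete
            if cns.three_prime_clamp > 0:
                clamp_cols = (
                    prof.concrete[b - cns.three_prime_clamp : b]
                    if orientation == "F"
                    else prof.concrete[a : a + cns.three_prime_clamp]
                )
                if not clamp_cols.all():
                    diag["clamp"] = diag.get("clamp", 0) + 1
                    continue
            tm_lo, tm_hi = prof.window_tm(a, b)
            if tm_lo < cns.tm_range[0] or tm_hi > cns.tm_range[1]:
                diag["tm"] = diag.get("tm", 0) + 1
                continue
            gc = prof.window_gc(a, b)
            if not (cns.gc_range[0] <= gc <= cns.gc_range[1]):
                diag["gc"] = diag.get("gc", 0) + 1
                continue
            window = prof.window_seq(a, b)
            primer = window if orientation == "F" else window.revcomp()
            if _coverage(primer, prof.msa, a, b, orientation) < cns.min_coverage:
                diag["coverage"] = diag.get("coverage", 0) + 1
                continue
            out.append(
                Candidate(
                    primer=primer,
                    start=a,
                    end=b,
                    orientation=orientation,
                    degeneracy=primer.degeneracy,
                    tm_lo=tm_lo,
                    tm_hi=tm_hi,
                    gc=gc,
                )
            )
    out.sort(
        key=lambda c: (c.degeneracy, abs(c.tm_mid - cns.tm_target), c.start)
    )
    return out


def _ref_positions(ref: SequenceRecord) -> np.ndarray:
    """Map alignment column -> 0-based ungapped position on the reference.

    Gap columns inherit the position of the previous residue; only gap-free
    windows consult the map, so this is safe.
    """
    pos = np.zeros(len(ref.seq), dtype=int)
    p = -1
    for i, c in enumerate(ref.seq):
        if c != "-":
            p += 1
        pos[i] = p
    return pos


def design_for_cluster(
    msa: Sequence[SequenceRecord],
    constraints: DesignConstraints = DesignConstraints(),
    cluster_label: str = "X",
    reference_index: int = 0,
    _pair_budget: int = 250,
) -> DesignResult:
    """Best degenerate primer pair for one clade, or a diagnosed failure.

    The product length (5' end of the forward site to the 5' end of the
    reverse site on the opposite strand, inclusive) is measured on the
    ungapped reference member (the first member by default).  Pair selection
    minimizes pair degeneracy, then joint Tm proximity to the target, then
    position; ties break leftmost-forward, making output deterministic.

    ``_pair_budget`` bounds the number of top-ranked forward/reverse
    candidates examined exhaustively before falling back to a full scan.
    """
    members = frozenset(r.id for r in msa)
    prof = _ColumnProfile(msa)
    diag: dict = {}
    fwd = scan_candidates(msa, constraints, "F", _profile=prof, _diag=diag)
    rev = scan_candidates(msa, constraints, "R", _profile=prof, _diag=diag)
    diag["n_fwd_candidates"] = len(fwd)
    diag["n_rev_candidates"] = len(rev)
    if not fwd or not rev:
        return DesignResult(members, "failure", diagnostics=diag)

    refpos = _ref_positions(msa[reference_index])
    plo, phi = constraints.product_len

    def product_len(f: Candidate, r: Candidate) -> int:
        return int(refpos[r.end - 1] - refpos[f.start] + 1)

    def pair_key(f: Candidate, r: Candidate):
        return (
            f.degeneracy * r.degeneracy,
            abs(f.tm_mid - constraints.tm_target)
            + abs(r.tm_mid - constraints.tm_target),
            f.start,
            r.start,
        )

    def feasible(f: Candidate, r: Candidate) -> bool:
        if r.start < f.end:
            return False
        if f.degeneracy * r.degeneracy > constraints.max_pair_degeneracy:
            return False
        if abs(f.tm_mid - r.tm_mid) > constraints.max_pair_delta_tm:
            return False
        return plo <= product_len(f, r) <= phi

    def search(fs: list[Candidate], rs: list[Candidate]):
        # index reverse candidates by end column for product-range pruning
        rs_by_end = sorted(rs, key=lambda c: c.end)
        ends = [c.end for c in rs_by_end]
        best = None
        best_key = None
        n_prod_fail = 0
        for f in fs:
            ref_f = refpos[f.start]
            lo_i = bisect_left(ends, f.end)
            for i in range(lo_i, len(rs_by_end)):
                r = rs_by_end[i]
                pl = refpos[r.end - 1] - ref_f + 1
                if pl > phi:
                    break  # ends sorted; refpos monotone on gap-free cols
                if pl < plo:
                    n_prod_fail += 1
                    continue
                if not feasible(f, r):
                    continue
                k = pair_key(f, r)
                if best_key is None or k < best_key:
                    best, best_key = (f, r), k
        return best, n_prod_fail

    budget = _pair_budget
    best, n_prod_fail = search(fwd[:budget], rev[:budget])
    if best is None and (len(fwd) > budget or len(rev) > budget):
        best, n_prod_fail = search(fwd, rev)
    diag["product_len_fail"] = n_prod_fail
    if best is None:
        return DesignResult(members, "failure", diagnostics=diag)
    f, r = best
    entry = PanelEntry(
        cluster=cluster_label,
        fwd=f.primer,
        rev=r.primer,
        expected_len=product_len(f, r),
    )
    diag["fwd_start_col"] = f.start
    diag["rev_start_col"] = r.start
    return DesignResult(members, "success", pair=entry, diagnostics=diag)


def _slice_alignment(
    msa_by_id: dict[str, SequenceRecord], members: Sequence[str]
) -> list[SequenceRecord]:
    """Re-slice a global MSA to a clade: keep members, drop all-gap columns."""
    rows = [msa_by_id[m] for m in members]
    arr = np.array([list(r.seq) for r in rows])
    keep = ~(arr == "-").all(axis=0)
    return [
        SequenceRecord(r.id, "".join(arr[i, keep]), r.description)
        for i, r in enumerate(rows)
    ]


def recursive_design(
    tree,
    msa: Sequence[SequenceRecord],
    constraints: DesignConstraints = DesignConstraints(),
) -> RecursiveDesignResult:
    """Root-down descent: design on a clade, recurse into children on failure.

    Emitted clades are disjoint and, together with the undesignable leaves,
    partition the leaf set.  Cluster labels are assigned A, B, C, ... in
    emission (preorder) order.
    """
    by_id = {r.id: r for r in msa}
    leaf_set = tree.leaf_set()
    if leaf_set != set(by_id):
        raise ValueError(
            "tree leaves and alignment ids differ: "
            f"only-in-tree={sorted(leaf_set - set(by_id))}, "
            f"only-in-msa={sorted(set(by_id) - leaf_set)}"
        )
    labels = _label_stream()
    results: list[DesignResult] = []
    undesignable: list[str] = []
    attempts = 0

    def visit(node) -> None:
        nonlocal attempts
        members = sorted(t.name for t in node.get_terminals())
        sub = _slice_alignment(by_id, members)
        attempts += 1
        res = design_for_cluster(sub, constraints, cluster_label="?")
        if res.success:
            res.pair = PanelEntry(  # rebuilt: PanelEntry is frozen
                cluster=next(labels),
                fwd=res.pair.fwd,
                rev=res.pair.rev,
                expected_len=res.pair.expected_len,
            )
            results.append(res)
            return
        if not node.clades:  # leaf-level failure
            undesignable.extend(members)
            return
        for child in node.clades:
            visit(child)

    visit(tree.root)
    return RecursiveDesignResult(results, undesignable, attempts)


def _label_stream():
    i = 0
    while True:
        # A..Z then A1, B1, ...
        yield chr(ord("A") + i % 26) + ("" if i < 26 else str(i // 26))
        i += 1


def align_with_mafft(records: Sequence[SequenceRecord]) -> list[SequenceRecord]:
    """Align unaligned input with the mafft command-line tool.

    Convenience only — the design functions accept any pre-computed MSA.
    """
    import subprocess
    import tempfile
    from pathlib import Path

    from .seqcore import read_fasta, write_fasta

    with tempfile.TemporaryDirectory() as td:
        inp = Path(td) / "in.fasta"
        out = Path(td) / "out.fasta"
        write_fasta(records, inp)
        try:
            with open(out, "w") as fh:
                subprocess.run(
                    ["mafft", "--auto", "--quiet", str(inp)],
                    stdout=fh,
                    check=True,
                )
        except FileNotFoundError:
            raise RuntimeError("mafft not found on PATH") from None
        return read_fasta(out)
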