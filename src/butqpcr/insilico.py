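"""Degenerate in-silico PCR: binding-site search, amplicon prediction and a
local off-target screen for a primer panel.

A binding site is any template window that a (degenerate) primer matches
within the mismatch budget, with the 3'-terminal ``clamp_exact`` positions
matching exactly — mismatches at the extension end abolish qPCR
amplification, so they are never tolerated.  An amplicon pairs a forward
site with a downstream reverse-complement site of the reverse primer; the
product length runs from the 5' end of the forward site to the 5' end of the
reverse site on the opposite strand, inclusive (the convention under which
the packaged panel's expected lengths are stated).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

from .panel import PanelEntry
from .seqcore import IUPAC_SETS, DegenerateSeq, SequenceRecord

__all__ = [
    "BindingSite",
    "AmpliconHit",
    "find_binding_sites",
    "predict_amplicons",
    "offtarget_screen",
]


@dataclass(frozen=True)
class BindingSite:
    """A primer binding site; ``start`` is 0-based on the plus strand."""

    start: int
    strand: str  # "+": primer binds as given; "-": primer binds the minus strand
    mismatches: int


@dataclass(frozen=True)
class AmpliconHit:
    """A predicted PCR product.

    Coordinates are 1-based inclusive plus-strand positions of the two primer
    binding windows.  ``strand`` is "+" when the forward primer sits on the
    plus strand (product length = rev_end - fwd_start + 1) and "-" for the
    mirrored orientation (product length = fwd_end - rev_start + 1).
    """

    template_id: str
    strand: str
    fwd_start: int
    fwd_end: int
    rev_start: int
    rev_end: int
    product_len: int
    fwd_mismatches: int
    rev_mismatches: int


def _scan(pattern: DegenerateSeq, template: str, max_mismatch: int,
          clamp_positions: Sequence[int]) -> list[tuple[int, int]]:
    """All (start, mismatches) where pattern matches the plus-strand window.

    ``clamp_positions`` are pattern indices that must match exactly.
    """
    sets = pattern.base_sets()
    m = len(sets)
    hits = []
    for start in range(len(template) - m + 1):
        mm = 0
        ok = True
        for i in range(m):
            if template[start + i] not in sets[i]:
                if i in clamp_positions:
                    ok = False
                    break
                mm += 1
                if mm > max_mismatch:
                    ok = False
                    break
        if ok:
            hits.append((start, mm))
    return hits


def find_binding_sites(
    primer: DegenerateSeq,
    template: "SequenceRecord | str",
    max_mismatch: int = 0,
    clamp_exact: int = 2,
) -> list[BindingSite]:
    """Binding sites of a primer on both strands of a concrete template.

    A plus-strand site means the primer sequence itself matches the template
    window; a minus-strand site means the primer's reverse complement does
    (the primer would anneal to the minus strand, extending leftwards).
    Template ``N`` matches nothing.
    """
    seq = template.seq if isinstance(template, SequenceRecord) else template.upper()
    if len(primer) > len(seq):
        return []
    m = len(primer)
    clamp_plus = set(range(m - clamp_exact, m))  # 3' end of the given primer
    sites = [
        BindingSite(s, "+", mm) for s, mm in _scan(primer, seq, max_mismatch, clamp_plus)
    ]
    rc = primer.revcomp()
    clamp_minus = set(range(0, clamp_exact))  # primer 3' end maps to window start
    sites += [
        BindingSite(s, "-", mm) for s, mm in _scan(rc, seq, max_mismatch, clamp_minus)
    ]
    sites.sort(key=lambda b: (b.start, b.strand))
    return sites


def predict_amplicons(
    pair: PanelEntry,
    template: SequenceRecord,
    max_mismatch: int = 0,
    product_len: Optional[tuple[int, int]] = None,
    clamp_exact: int = 2,
) -> list[AmpliconHit]:
    """All predicted products of a primer pair on a template, both
    orientations, sorted by (forward-site start, product length).

    ``product_len`` restricts reported products to a length window; by
    default anything at least as long as the two primers combined is kept.
    """
    fwd_sites = find_binding_sites(pair.fwd, template, max_mismatch, clamp_exact)
    rev_sites = find_binding_sites(pair.rev, template, max_mismatch, clamp_exact)
    lf, lr = len(pair.fwd), len(pair.rev)
    lo = product_len[0] if product_len else lf + lr
    hi = product_len[1] if product_len else len(template.seq)
    hits = []
    # orientation "+": forward on plus strand, reverse primer on minus strand
    for f in (s for s in fwd_sites if s.strand == "+"):
        for r in (s for s in rev_sites if s.strand == "-"):
            if r.start < f.start + lf:
                continue
            plen = (r.start + lr) - f.start
            if lo <= plen <= hi:
                hits.append(
                    AmpliconHit(
                        template_id=template.id,
                        strand="+",
                        fwd_start=f.start + 1,
                        fwd_end=f.start + lf,
                        rev_start=r.start + 1,
                        rev_end=r.start + lr,
                        product_len=plen,
                        fwd_mismatches=f.mismatches,
                        rev_mismatches=r.mismatches,
                    )
                )
    # orientation "-": the amplicon reads off the minus strand
    for r in (s for s in rev_sites if s.strand == "+"):
        for f in (s for s in fwd_sites if s.strand == "-"):
            if f.start < r.start + lr:
                continue
            plen = (f.start + lf) - r.start
            if lo <= plen <= hi:
                hits.append(
                    AmpliconHit(
                        template_id=template.id,
                        strand="-",
                        fwd_start=f.start + 1,
                        fwd_end=f.start + lf,
                        rev_start=r.start + 1,
                        rev_end=r.start + lr,
                        product_len=plen,
                        fwd_mismatches=f.mismatches,
                        rev_mismatches=r.mismatches,
                    )
                )
    hits.sort(key=lambda h: (min(h.fwd_start, h.rev_start), h.product_len, h.strand))
    return hits


def offtarget_screen(
    panel: Iterable[PanelEntry],
    templates: Sequence[SequenceRecord],
    template_clusters: Optional[Mapping[str, str]] = None,
    max_mismatch: int = 2,
    clamp_exact: int = 2,
    product_len: Optional[tuple[int, int]] = None,
) -> pd.DataFrame:
    """Permissive cross-amplification screen of a panel against templates.

    ``template_clusters`` maps template ids to their true cluster label (if
    known).  A row is flagged when a pair amplifies a template assigned to a
    different cluster.  Returns one row per predicted amplicon with columns
    (cluster, template, template_cluster, product_len, fwd_mismatches,
    rev_mismatches, off_target); an empty frame if nothing amplifies.
    """
    template_clusters = template_clusters or {}
    rows = []
    for entry in panel:
        for t in templates:
            for hit in predict_amplicons(
                entry, t, max_mismatch=max_mismatch,
                product_len=product_len, clamp_exact=clamp_exact,
            ):
                tc = template_clusters.get(t.id)
                rows.append(
                    {
                        "cluster": entry.cluster,
                        "template": t.id,
                        "template_cluster": tc,
                        "strand": hit.strand,
                        "product_len": hit.product_len,
                        "fwd_mismatches": hit.fwd_mismatches,
                        "rev_mismatches": hit.rev_mismatches,
                        "off_target": tc is not None and tc != entry.cluster,
                    }
                )
    cols = [
        "cluster", "template", "template_cluster", "strand", "product_len",
        "fwd_mismatches", "rev_mismatches", "off_target",
    ]
    df = pd.DataFrame(rows, columns=cols)
    return df.sort_values(["cluster", "template", "product_len"]).reset_index(drop=True)
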