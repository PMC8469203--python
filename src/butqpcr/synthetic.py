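"""Synthetic data with known ground truth for every pipeline stage.

Three generators, all pure functions of (spec, seed):

* :func:`simulate_family` — a homologous gene family evolved down a given
  tree by i.i.d. substitutions, with clade-specific *conserved islands*
  (windows immune to substitution inside their clade but free to diverge
  outside it).  This emulates the design problem: a divergent functional
  gene whose clades each retain primer-able stretches.
* :func:`simulate_qpcr` — long-format Ct tables for a two-reference assay
  panel with known per-group true copy ratios, sample-level biological
  spread and replicate-level measurement noise.
* :func:`simulate_counts` — multinomial sequencing counts at fixed depth
  from true taxon proportions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .phylo import CladeTree, parse_newick
from .seqcore import SequenceRecord

__all__ = [
    "Island",
    "FamilySpec",
    "QpcrSimSpec",
    "simulate_family",
    "simulate_qpcr",
    "simulate_counts",
    "clade_family_spec",
    "study_qpcr_spec",
]

_BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class Island:
    """A window immune to substitution within one clade (a leaf-name set)."""

    clade: frozenset
    start: int
    length: int

    def __post_init__(self) -> None:
        if self.start < 0 or self.length < 1:
            raise ValueError("island window must be within the ancestor")


@dataclass(frozen=True)
class FamilySpec:
    """Parameters of a simulated gene family.

    ``subst_prob`` is the per-site substitution probability applied on every
    branch (branch lengths in the newick are ignored for mutation; the
    within/between split is carried by ``deep_subst_prob`` applied to
    branches whose child clade contains more than one island clade — see
    :func:`clade_family_spec` for the standard construction).
    """

    newick: str
    ancestor_len: int = 800
    subst_prob: float = 0.02
    deep_subst_prob: Optional[float] = None
    islands: tuple = ()
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.subst_prob < 1):
            raise ValueError("substitution probability must be in [0, 1)")
        if self.deep_subst_prob is not None and not (0 <= self.deep_subst_prob < 1):
            raise ValueError("substitution probability must be in [0, 1)")
        for isl in self.islands:
            if isl.start + isl.length > self.ancestor_len:
                raise ValueError("island window exceeds the ancestor length")


def simulate_family(
    spec: FamilySpec,
) -> tuple[list[SequenceRecord], CladeTree, list[Island]]:
    """Evolve an ancestor down the tree; returns (leaf records, tree, islands).

    Substitutions are i.i.d. per site, uniform over the three alternative
    bases (no indels).  A site inside an island does not mutate on branches
    lying entirely within the island's clade, so island content is identical
    across the clade's leaves but diverges freely between clades.
    Deterministic per (spec, seed).
    """
    tree = parse_newick(spec.newick)
    rng = np.random.default_rng(spec.seed)
    L = spec.ancestor_len
    ancestor = rng.integers(0, 4, size=L)
    islands = list(spec.islands)

# A branch is "inside" an island's clade when its child leaf set is a
    # *proper* subset of the clade; the stem edge entering the clade root is
    # deliberately outside, so island content mutated there is inherited by
    # the whole clade (conserved within, divergent between clades).
    def protected_mask(leafset: frozenset) -> np.ndarray:
        mask = np.zeros(L, dtype=bool)
        for isl in islands:
            if leafset < isl.clade:
                mask[isl.start : isl.start + isl.length] = True
        return mask

    def branch_prob(leafset: frozenset) -> float:
        if spec.deep_subst_prob is None:
            return spec.subst_prob
        inside = any(leafset < isl.clade for isl in islands)
        return spec.subst_prob if inside else spec.deep_subst_prob

    records: list[SequenceRecord] = []

    def descend(node, seq: np.ndarray) -> None:
        for child in node.clades:
            leafset = frozenset(t.name for t in child.get_terminals())
            p = branch_prob(leafset)
            child_seq = seq.copy()
            if p > 0:
                hit = rng.random(L) < p
                hit &= ~protected_mask(leafset)
                if hit.any():
                    shift = rng.integers(1, 4, size=int(hit.sum()))
                    child_seq[hit] = (child_seq[hit] + shift) % 4
            if child.is_terminal():
                records.append(
                    SequenceRecord(child.name, "".join(_BASES[child_seq]))
                )
            else:
                descend(child, child_seq)

    root = tree.root
    if root.is_terminal():  # single-leaf degenerate tree
        records.append(SequenceRecord(root.name, "".join(_BASES[ancestor])))
    else:
        descend(root, ancestor)
    # stable order: tree leaf order
    order = {name: i for i, name in enumerate(tree.leaf_names())}
    records.sort(key=lambda r: order[r.id])
    return records, tree, islands


def clade_family_spec(
    k: int,
    leaves_per_clade: int = 3,
    ancestor_len: int = 800,
    within_prob: float = 0.02,
    between_prob: float = 0.5,
    island_len: int = 30,
    island_starts: tuple[int, int] = (60, 620),
    seed: int = 0,
) -> FamilySpec:
    """Standard k-clade construction with two planted islands per clade.

    Each clade keeps a forward-island and a reverse-island window (shared
    coordinates, clade-specific content after divergence), spaced so a
    primer pair designed inside them yields a product in the default
    400-800 nt window.  Between-clade branches substitute at
    ``between_prob`` per site, destroying cross-clade conservation.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    names = [
        [f"c{ci}_l{li}" for li in range(leaves_per_clade)] for ci in range(k)
    ]

    def subtree(leaves: list[str]) -> str:
        if len(leaves) == 1:
            return leaves[0]
        return "(" + ",".join(leaves) + ")"

    clade_strs = [subtree(n) for n in names]
    # balanced nesting of clades so intermediate nodes exist for k > 2
    while len(clade_strs) > 1:
        clade_strs = [
            "(" + ",".join(clade_strs[i : i + 2]) + ")" if i + 1 < len(clade_strs)
            else clade_strs[i]
            for i in range(0, len(clade_strs), 2)
        ]
    newick = clade_strs[0] + ";" if k > 1 else "(" + ",".join(names[0]) + ");"
    islands = []
    for ci in range(k):
        clade = frozenset(names[ci])
        for start in island_starts:
            islands.append(Island(clade=clade, start=start, length=island_len))
    return FamilySpec(
        newick=newick,
        ancestor_len=ancestor_len,
        subst_prob=within_prob,
        deep_subst_prob=between_prob,
        islands=tuple(islands),
        seed=seed,
    )


@dataclass(frozen=True)
class QpcrSimSpec:
    """Ground truth for a simulated two-group qPCR study.

    ``ratios`` maps group -> {cluster -> true target/UNC6 copy ratio}.
    ``ratio_log2_sd`` is the per-sample biological spread of the true ratio
    on the log2 (Ct) scale; ``noise_sd`` is per-replicate measurement noise
    in cycles.  The 16S reference Ct sits ``s16_offset_mean`` cycles from
    the spike Ct with per-sample variation ``s16_offset_sd`` (bacterial-load
    differences), which makes the two normalizations agree only up to a
    sample-specific constant, as with real fecal DNA.
    """

    groups: Mapping[str, int]
    ratios: Mapping[str, Mapping[str, float]]
    ref_ct_mean: float = 22.0
    ref_ct_sd: float = 1.0
    s16_offset_mean: float = -8.0
    s16_offset_sd: float = 1.0
    ratio_log2_sd: float = 0.0
    noise_sd: float = 0.5
    replicates: int = 3
    efficiency: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if any(n < 1 for n in self.groups.values()):
            raise ValueError("group sizes must be >= 1")
        for g, per in self.ratios.items():
            if any(r <= 0 for r in per.values()):
                raise ValueError(f"group {g}: true ratios must be positive")
        if self.noise_sd < 0 or self.ref_ct_sd < 0 or self.ratio_log2_sd < 0:
            raise ValueError("standard deviations must be >= 0")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")


def simulate_qpcr(spec: QpcrSimSpec) -> pd.DataFrame:
    """Long-format Ct table (sample, group, assay, replicate, ct).

    Target Ct = spike Ct - log_E(true ratio) + noise; references UNC6 and
    S16 are included for every sample.  Deterministic per (spec, seed).
    """
    rng = np.random.default_rng(spec.seed)
    log_e = np.log2(spec.efficiency)
    rows = []
    for group, n in spec.groups.items():
        per_cluster = spec.ratios[group]
        for i in range(n):
            sample = f"{group}_{i:03d}"
            ct_unc6 = rng.normal(spec.ref_ct_mean, spec.ref_ct_sd)
            ct_s16 = ct_unc6 + rng.normal(spec.s16_offset_mean, spec.s16_offset_sd)
            true_ct = {"UNC6": ct_unc6, "S16": ct_s16}
            for cluster, ratio in per_cluster.items():
                sample_log2_ratio = np.log2(ratio)
                if spec.ratio_log2_sd > 0:
                    sample_log2_ratio += rng.normal(0.0, spec.ratio_log2_sd)
                true_ct[cluster] = ct_unc6 - sample_log2_ratio / log_e
            for assay, ct in true_ct.items():
                for rep in range(1, spec.replicates + 1):
                    noise = rng.normal(0.0, spec.noise_sd) if spec.noise_sd > 0 else 0.0
                    rows.append(
                        {
                            "sample": sample,
                            "group": group,
                            "assay": assay,
                            "replicate": rep,
                            "ct": ct + noise,
                        }
                    )
    return pd.DataFrame(rows, columns=["sample", "group", "assay", "replicate", "ct"])


def study_qpcr_spec(
    n_per_group: int = 60,
    seed: int = 0,
    ratio_log2_sd: float = 1.1,
    noise_sd: float = 0.5,
) -> QpcrSimSpec:
    """Two-group study emulating the published cohort structure.

    Per-cluster true median copy ratios follow the published summary table
    (spike normalization): the first group carries the higher cluster-C
    abundance (211 vs 86) and the remaining clusters sit at their reported
    medians.  The biological spread default (1.1 log2 cycles) is back-solved
    from the reported IQR/median ratios under a log-normal model.
    """
    vg = {"A": 3.5, "B": 0.45, "C": 211.0, "D": 63.0, "E": 0.28, "F": 12.5}
    ob = {"A": 4.8, "B": 0.28, "C": 86.0, "D": 34.0, "E": 0.32, "F": 17.6}
    return QpcrSimSpec(
        groups={"VG": n_per_group, "OB": n_per_group},
        ratios={"VG": vg, "OB": ob},
        ratio_log2_sd=ratio_log2_sd,
        noise_sd=noise_sd,
        seed=seed,
    )


def simulate_counts(
    proportions: pd.DataFrame, depth: int, seed: int = 0
) -> pd.DataFrame:
    """Multinomial count table at fixed depth from true taxon proportions.

    ``proportions`` is samples x taxa with rows summing to 1.
    """
    p = proportions.to_numpy(dtype=float)
    if (p < 0).any() or not np.allclose(p.sum(axis=1), 1.0, atol=1e-8):
        raise ValueError("proportions must be non-negative and sum to 1 per sample")
    if depth < 1:
        raise ValueError("depth must be >= 1")
    rng = np.random.default_rng(seed)
    counts = np.vstack([rng.multinomial(depth, row / row.sum()) for row in p])
    out = pd.DataFrame(counts, index=proportions.index, columns=proportions.columns)
    out.attrs["state"] = "raw"
    return out
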