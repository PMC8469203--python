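"""Relative quantification of target-gene abundance from qPCR Ct tables.

Quantification follows the comparative (ΔCt) method: with amplification
efficiency E (E = 2 means perfect doubling per cycle), the target-to-reference
copy ratio in a sample is E**(Ct_ref - Ct_target).  Two reference strategies
are supported, mirroring the two normalizations used for fecal DNA:

* ``UNC6`` — an external spike (a *C. elegans* netrin-gene fragment added in a
  fixed amount before DNA isolation); independent of community composition.
* ``S16`` — the bacterial 16S rRNA gene (total bacterial load); biased by the
  variable per-genome 16S copy number, optionally corrected by an average
  copies-per-genome factor (4.2 from in-silico genome surveys).

Ct tables are long-format with columns (sample, group, assay, replicate, ct);
assays are the cluster labels A-F plus the reference assays UNC6 and S16.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "REFERENCE_ASSAYS",
    "QPCR_COLUMNS",
    "copy_ratio",
    "recommend_concentration",
    "sixteenS_copy_correction",
    "aggregate_replicates",
    "normalize_table",
    "NormalizationResult",
    "read_ct_table",
    "write_ct_table",
]

REFERENCE_ASSAYS = ("UNC6", "S16")
QPCR_COLUMNS = ("sample", "group", "assay", "replicate", "ct")

#: average 16S rRNA gene copies per bacterial genome (in-silico survey value)
DEFAULT_16S_COPIES_PER_GENOME = 4.2


def copy_ratio(ct_target: float, ct_ref: float, efficiency: float = 2.0) -> float:
    """Target copies per reference copy: efficiency**(ct_ref - ct_target)."""
    if not (np.isfinite(ct_target) and np.isfinite(ct_ref)):
        raise ValueError("non-finite Ct; flag the well as missing instead")
    if efficiency <= 1.0:
        raise ValueError("amplification efficiency must exceed 1")
    return float(efficiency ** (ct_ref - ct_target))


def recommend_concentration(pair_degeneracy: int) -> float:
    """Recommended per-pair primer concentration in nM.

    Conventional (degeneracy 1) primers run at 200 nM; highly degenerate
    pairs need more because each concrete variant is correspondingly diluted.
    The rule interpolates log-linearly from 200 nM at degeneracy 1 to the
    1 uM ceiling at degeneracy >= 256, rounded to 10 nM.
    """
    if pair_degeneracy < 1:
        raise ValueError("degeneracy must be >= 1")
    frac = min(1.0, math.log2(pair_degeneracy) / 8.0)
    return round((200.0 + 800.0 * frac) / 10.0) * 10.0


def sixteenS_copy_correction(
    copy_ratio: float, copies_per_genome: float = DEFAULT_16S_COPIES_PER_GENOME
) -> float:
    """Convert a per-16S-copy ratio to per-genome-equivalent units."""
    if copies_per_genome <= 0:
        raise ValueError("copies_per_genome must be positive")
    return copy_ratio * copies_per_genome


def read_ct_table(path: "str | Path") -> pd.DataFrame:
    """Read a long-format Ct TSV (columns sample, group, assay, replicate, ct)."""
    df = pd.read_csv(path, sep="\t", comment="#")
    return validate_ct_table(df)


def write_ct_table(df: pd.DataFrame, path: "str | Path") -> None:
    df.to_csv(path, sep="\t", index=False)


def validate_ct_table(df: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in QPCR_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"Ct table missing column(s) {missing}")
    bad = df["ct"].notna() & (df["ct"] <= 0)
    if bad.any():
        raise ValueError(f"non-positive Ct values at rows {list(df.index[bad])}")
    return df


def aggregate_replicates(df: pd.DataFrame, outlier_cycles: float = 0.5) -> pd.DataFrame:
    """Average technical replicates per (sample, group, assay).

    A replicate is dropped when its Ct deviates from the replicate median by
    more than ``outlier_cycles`` cycles (set ``inf`` to disable); remaining
    Cts are arithmetically averaged, which is the geometric mean on the copy
    scale.  NaN Cts (failed wells) are ignored.
    """
    validate_ct_table(df)

    def _agg(s: pd.Series) -> float:
        s = s.dropna()
        if s.empty:
            return float("nan")
        keep = s[(s - s.median()).abs() <= outlier_cycles]
        # all-outlier degenerate case: fall back to the plain median
        return float(keep.mean()) if not keep.empty else float(s.median())

    out = (
        df.groupby(["sample", "group", "assay"], sort=False)["ct"]
        .apply(_agg)
        .reset_index()
    )
    return out


@dataclass
class NormalizationResult:
    """Normalized abundance table plus samples that lacked the reference."""

    table: pd.DataFrame
    reference: str
    missing_reference: list = field(default_factory=list)


def normalize_table(
    df: pd.DataFrame,
    reference: str = "UNC6",
    efficiency: float = 2.0,
    outlier_cycles: float = 0.5,
    copies_per_genome: "float | None" = None,
) -> NormalizationResult:
    """ΔCt-normalize a long-format Ct table against one reference assay.

    Returns one row per (sample, cluster) with the target/reference copy
    ratio; when ``reference='S16'`` and ``copies_per_genome`` is given, a
    ``genome_equivalents`` column is added.  Samples without the reference
    assay are listed in :attr:`NormalizationResult.missing_reference` rather
    than silently dropped.
    """
    if reference not in REFERENCE_ASSAYS:
        raise ValueError(f"reference must be one of {REFERENCE_ASSAYS}")
    agg = aggregate_replicates(df, outlier_cycles=outlier_cycles)
    targets = agg[~agg["assay"].isin(REFERENCE_ASSAYS)]
    if targets.empty:
        raise ValueError("Ct table contains no target assays")
    refs = (
        agg[agg["assay"] == reference]
        .set_index("sample")["ct"]
        .to_dict()
    )
    rows, missing = [], []
    for (sample, group), sub in targets.groupby(["sample", "group"], sort=False):
        ct_ref = refs.get(sample, float("nan"))
        if not np.isfinite(ct_ref):
            missing.append(sample)
            continue
        for _, r in sub.iterrows():
            if not np.isfinite(r["ct"]):
                continue
            rows.append(
                {
                    "sample": sample,
                    "group": group,
                    "cluster": r["assay"],
                    "reference": reference,
                    "copy_ratio": copy_ratio(r["ct"], ct_ref, efficiency),
                }
            )
    table = pd.DataFrame(rows, columns=["sample", "group", "cluster", "reference", "copy_ratio"])
    if reference == "S16" and copies_per_genome is not None:
        table["genome_equivalents"] = table["copy_ratio"].map(
            lambda x: sixteenS_copy_correction(x, copies_per_genome)
        )
    return NormalizationResult(table=table, reference=reference, missing_reference=missing)
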