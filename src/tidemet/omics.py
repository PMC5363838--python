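"""Read-count normalizations for metagenomes and metatranscriptomes.

Two normalizations are implemented:

* Per-ORF transcriptional activity within a genome bin:

      activity = (reads / length) / (bin reads / bin length)

  so an activity of 1.0 is the bin-average transcription per base pair;
  the ORF-length-weighted mean activity of a bin is exactly 1.

* Functional-gene abundance normalized to the conserved single-copy RNA
  polymerase gene rpoBC:

      value = reads(gene family) / reads(rpoBC)

Count tables are pandas DataFrames with columns orf_id, bin_id, length,
count (and optionally family).
"""

from __future__ import annotations

import warnings
from typing import Dict, Mapping, Optional

import pandas as pd

REQUIRED_COLUMNS = ("orf_id", "bin_id", "length", "count")

#: Gene families tracked in the environmental-survey comparison.
GENE_FAMILIES = ("pflAB", "bd-I", "bd-II", "heme-copper oxidase", "dsrAB", "nirS", "rpoBC")


class CountTableError(ValueError):
    pass


def validate_count_table(counts: pd.DataFrame) -> pd.DataFrame:
    """Check a count table: required columns, unique ORFs, positive
    lengths, non-negative counts."""
    missing = [c for c in REQUIRED_COLUMNS if c not in counts.columns]
    if missing:
        raise CountTableError(f"count table missing column(s): {missing}")
    if counts["orf_id"].duplicated().any():
        dupes = counts.loc[counts["orf_id"].duplicated(), "orf_id"].tolist()
        raise CountTableError(f"duplicate orf_id(s): {dupes[:5]}")
    if (counts["length"] <= 0).any():
        raise CountTableError("ORF lengths must be positive")
    if (counts["count"] < 0).any():
        raise CountTableError("read counts must be non-negative")
    return counts


def transcriptional_activity(counts: pd.DataFrame) -> pd.DataFrame:
    """Per-ORF transcriptional activity, bin-relative.

    Returns a DataFrame (orf_id, bin_id, length, count, activity).  Bins
    with zero total reads are skipped with a warning.  Within every
    retained bin the length-weighted mean activity is exactly 1.
    """
    counts = validate_count_table(counts)
    frames = []
    for bin_id, grp in counts.groupby("bin_id", sort=False):
        total_reads = grp["count"].sum()
        if total_reads == 0:
            warnings.warn(f"bin {bin_id!r} has zero reads; skipped")
            continue
        total_length = grp["length"].sum()
        density = grp["count"] / grp["length"]
        out = grp.copy()
        out["activity"] = density / (total_reads / total_length)
        frames.append(out)
    if not frames:
        raise CountTableError("no bin has any reads")
    return pd.concat(frames, ignore_index=True)


def normalize_to_rpobc(
    family_counts: Mapping[str, float],
    rpobc_count: Optional[float] = None,
    sum_bd: bool = False,
) -> Dict[str, float]:
    """Functional-gene read counts normalized to rpoBC.

    ``rpobc_count`` defaults to the "rpoBC" entry of ``family_counts``.
    With ``sum_bd=True`` an additional "bd (total)" entry holds the sum of
    the bd-I and bd-II oxidase families.
    """
    if rpobc_count is None:
        rpobc_count = family_counts.get("rpoBC", 0.0)
    if rpobc_count is None or rpobc_count <= 0:
        raise CountTableError("normalizer absent: rpoBC count must be positive")
    out = {
        fam: cnt / rpobc_count
        for fam, cnt in family_counts.items()
        if fam != "rpoBC"
    }
    if sum_bd:
        out["bd (total)"] = out.get("bd-I", 0.0) + out.get("bd-II", 0.0)
    return out


def family_counts_from_table(counts: pd.DataFrame) -> Dict[str, float]:
    """Aggregate a count table with a ``family`` column into per-family
    read totals."""
    if "family" not in counts.columns:
        raise CountTableError("count table has no 'family' column")
    tagged = counts.dropna(subset=["family"])
    return tagged.groupby("family")["count"].sum().to_dict()
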