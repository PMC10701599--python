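"""Reading aligned fragments and building filtered / downsampled / admixed sets.

Fragment sets are pandas DataFrames with one row per cfDNA fragment and the
columns in :data:`FRAGMENT_COLUMNS`. Single-end (long-read) data yield one
fragment per primary alignment with length equal to the aligned reference
span; paired-end data yield one fragment per properly oriented pair with
length equal to the absolute template length.

The post-alignment filter removes unmapped reads, secondary and supplementary
alignments, marked PCR duplicates, and alignments with mapping quality below
5. Duplicate marking is consumed as flags — it happens upstream.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import pysam

from ._util import as_rng

__all__ = [
    "FRAGMENT_COLUMNS",
    "FragmentRecord",
    "AdmixtureSpec",
    "SIZE_STRATA",
    "load_fragments",
    "filter_fragments",
    "downsample_fragments",
    "select_size_range",
    "build_admixture",
    "read_fragments_tsv",
    "write_fragments_tsv",
]

FRAGMENT_COLUMNS = ["name", "contig", "start", "end", "length", "mapq",
                    "strand", "unmapped", "secondary", "supplementary",
                    "duplicate", "label"]

#: The three size strata used throughout: ultra-short, mono-nucleosomal
#: (150-300 bp) and long (>300 bp) fragments. Bounds are lo-inclusive,
#: hi-exclusive.
SIZE_STRATA = {
    "lt150": (0, 150),
    "150to300": (150, 300),
    "gt300": (300, float("inf")),
}


@dataclass
class FragmentRecord:
    """One aligned cfDNA fragment (record-level view of a fragment table row)."""

    name: str
    contig: str
    start: int
    end: int
    length: int
    mapq: int
    strand: str
    unmapped: bool = False
    secondary: bool = False
    supplementary: bool = False
    duplicate: bool = False
    label: str | None = None


def _label_from_name(name: str) -> str | None:
    if "|" in name:
        return name.rsplit("|", 1)[1]
    return None


def load_fragments(path, layout: str = "single_end") -> pd.DataFrame:
    """Load a SAM/BAM file into a fragment table.

    ``single_end``: one fragment per alignment record, length = aligned
    reference span. ``paired_end``: one fragment per properly oriented pair
    (taken from the leftmost mate, template length > 0), length = |TLEN|.
    Truth labels are recovered from a ``name|label`` read-name convention
    when present.
    """
    if layout not in ("single_end", "paired_end"):
        raise ValueError(f"unknown layout {layout!r}")
    rows = []
    try:
        af = pysam.AlignmentFile(str(path), check_sq=False)
    except (OSError, ValueError) as exc:
        raise OSError(f"cannot read alignment file {path}: {exc}") from exc
    with af:
        for a in af:
            if layout == "paired_end":
                if (not a.is_paired or not a.is_proper_pair or a.is_unmapped
                        or a.is_secondary or a.is_supplementary):
                    continue
                if a.template_length <= 0:  # keep only the leftmost mate
                    continue
                start = a.reference_start
                end = start + a.template_length
                length = a.template_length
            else:
                if a.is_unmapped:
                    rows.append((a.query_name, "*", -1, -1, 0,
                                 a.mapping_quality, "+", True, a.is_secondary,
                                 a.is_supplementary, a.is_duplicate,
                                 _label_from_name(a.query_name or "")))
                    continue
                start = a.reference_start
                end = a.reference_end if a.reference_end is not None else start
                length = end - start
            rows.append((a.query_name, a.reference_name, start, end, length,
                         a.mapping_quality, "-" if a.is_reverse else "+",
                         False, a.is_secondary, a.is_supplementary,
                         a.is_duplicate, _label_from_name(a.query_name or "")))
    return pd.DataFrame(rows, columns=FRAGMENT_COLUMNS)


def filter_fragments(records: pd.DataFrame, min_mapq: int = 5) -> pd.DataFrame:
    """Apply the post-alignment filters; order is preserved and the operation
    is idempotent. Survivors are mapped, primary, non-supplementary,
    non-duplicate alignments with mapq >= ``min_mapq``."""
    if len(records) == 0:
        return records.copy()
    keep = (~records["unmapped"].astype(bool)
            & ~records["secondary"].astype(bool)
            & ~records["supplementary"].astype(bool)
            & ~records["duplicate"].astype(bool)
            & (records["mapq"] >= min_mapq))
    return records.loc[keep].reset_index(drop=True)


def downsample_fragments(records: pd.DataFrame, count: int | None = None,
                         fraction: float | None = None,
                         seed=0) -> pd.DataFrame:
    """Random downsampling without replacement, reproducible under seed.

    Exactly one of ``count`` / ``fraction`` must be given. Input order is
    preserved in the subset, so downsampling to the full size is the identity.
    """
    if (count is None) == (fraction is None):
        raise ValueError("give exactly one of count or fraction")
    n = len(records)
    rng = as_rng(seed)
    if count is not None:
        if count > n:
            raise ValueError(f"requested {count} fragments but only {n} available")
        k = int(count)
        idx = rng.choice(n, size=k, replace=False)
    else:
        if not (0.0 <= fraction <= 1.0):
            raise ValueError("fraction must be in [0, 1]")
        idx = np.flatnonzero(rng.random(n) < fraction)
    idx = np.sort(idx)
    return records.iloc[idx].reset_index(drop=True)


def select_size_range(records: pd.DataFrame, lo: float, hi: float) -> pd.DataFrame:
    """Keep fragments with lo <= length < hi (hi may be inf)."""
    if not lo < hi:
        raise ValueError("need lo < hi")
    keep = (records["length"] >= lo) & (records["length"] < hi)
    return records.loc[keep].reset_index(drop=True)


@dataclass
class AdmixtureSpec:
    """Recipe for one in-silico admixture.

    ``components`` is a list of (fragment table, amount) pairs, where amount
    is an exact count (int) or a sampling proportion (float). Proportions
    must sum to 1; counts must sum to ``target``.
    """

    components: list
    target: int
    seed: int = 0

    def __post_init__(self):
        if self.target <= 0:
            raise ValueError("target must be positive")
        amounts = [a for _, a in self.components]
        if all(isinstance(a, (int, np.integer)) for a in amounts):
            self.mode = "count"
            if sum(amounts) != self.target:
                raise ValueError("component counts must sum to target")
        else:
            self.mode = "proportion"
            if not np.isclose(sum(float(a) for a in amounts), 1.0):
                raise ValueError("component proportions must sum to 1")


def build_admixture(spec: AdmixtureSpec) -> pd.DataFrame:
    """Mix components into one fragment set of exactly ``spec.target`` rows.

    Count mode draws exact per-component counts; proportion mode draws
    multinomial counts. Sampling is without replacement per component and
    the concatenated result is shuffled, all reproducibly under the seed.
    """
    rng = as_rng(spec.seed)
    if spec.mode == "count":
        counts = [int(a) for _, a in spec.components]
    else:
        counts = rng.multinomial(spec.target,
                                 [float(a) for _, a in spec.components]).tolist()
    parts = []
    for i, ((frame, _), k) in enumerate(zip(spec.components, counts)):
        if k > len(frame):
            raise ValueError(
                f"component {i} has {len(frame)} fragments, cannot draw {k}")
        if k:
            parts.append(downsample_fragments(frame, count=k, seed=rng))
    out = pd.concat(parts, ignore_index=True) if parts else pd.DataFrame(
        columns=FRAGMENT_COLUMNS)
    perm = rng.permutation(len(out))
    return out.iloc[perm].reset_index(drop=True)


def write_fragments_tsv(records: pd.DataFrame, path) -> None:
    records.to_csv(path, sep="\t", index=False)


def read_fragments_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    for col, default in (("unmapped", False), ("secondary", False),
                         ("supplementary", False), ("duplicate", False),
                         ("label", None), ("name", None), ("mapq", 60),
                         ("strand", "+")):
        if col not in df.columns:
            df[col] = default
    if "length" not in df.columns:
        df["length"] = df["end"] - df["start"]
    return df[FRAGMENT_COLUMNS]
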