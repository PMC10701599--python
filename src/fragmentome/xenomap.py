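"""Graft/host read assignment for xenograft cfDNA aligned to two genomes.

Each read is aligned independently against the graft (human) and host
(mouse) genomes; its origin is called by comparing primary-alignment mapping
qualities: a read present in only one genome belongs to it, a read present
in both belongs to the genome with strictly greater mapq, and mapq ties are
called ambiguous and excluded from both (each molecule has one origin, so
keeping ties on both sides would double count). Assigned reads must reach
the minimum mapping quality (default 5) or they are left unassigned.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .fragmentomics import proportion_in_range, size_histogram
from .ingest import SIZE_STRATA

__all__ = ["AssignmentResult", "assign_by_best_genome", "origin_size_summary"]


@dataclass
class AssignmentResult:
    """Per-read origin calls. ``table`` columns: name, mapq_a, mapq_b, call;
    calls are the two genome labels plus 'ambiguous' and 'unassigned'."""

    table: pd.DataFrame
    labels: tuple = ("genomeA", "genomeB")
    min_mapq: int = 5

    @property
    def counts(self) -> dict:
        return self.table["call"].value_counts().to_dict()

    @property
    def n_ties(self) -> int:
        return int((self.table["call"] == "ambiguous").sum())

    def names_for(self, label: str) -> pd.Series:
        return self.table.loc[self.table["call"] == label, "name"]


def assign_by_best_genome(alignments_a: pd.DataFrame,
                          alignments_b: pd.DataFrame,
                          min_mapq: int = 5,
                          labels: tuple = ("genomeA", "genomeB")) -> AssignmentResult:
    """Assign reads to their genome of origin by primary-alignment mapq."""
    for side, df in (("A", alignments_a), ("B", alignments_b)):
        if df["name"].duplicated().any():
            dup = df.loc[df["name"].duplicated(), "name"].iloc[0]
            raise ValueError(
                f"duplicate primary alignment for read {dup!r} in genome {side}")
    a = alignments_a[["name", "mapq"]].rename(columns={"mapq": "mapq_a"})
    b = alignments_b[["name", "mapq"]].rename(columns={"mapq": "mapq_b"})
    merged = a.merge(b, on="name", how="outer")
    mapq_a = merged["mapq_a"].to_numpy(float)
    mapq_b = merged["mapq_b"].to_numpy(float)
    has_a = ~np.isnan(mapq_a)
    has_b = ~np.isnan(mapq_b)
    call = np.full(len(merged), "unassigned", dtype=object)
    only_a = has_a & ~has_b
    only_b = has_b & ~has_a
    call[only_a & (mapq_a >= min_mapq)] = labels[0]
    call[only_b & (mapq_b >= min_mapq)] = labels[1]
    both = has_a & has_b
    win_a = both & (mapq_a > mapq_b)
    win_b = both & (mapq_b > mapq_a)
    call[win_a & (mapq_a >= min_mapq)] = labels[0]
    call[win_b & (mapq_b >= min_mapq)] = labels[1]
    call[both & (mapq_a == mapq_b)] = "ambiguous"
    table = pd.DataFrame({"name": merged["name"], "mapq_a": mapq_a,
                          "mapq_b": mapq_b, "call": call})
    return AssignmentResult(table=table, labels=labels, min_mapq=min_mapq)


def origin_size_summary(result: AssignmentResult,
                        fragments_a: pd.DataFrame,
                        fragments_b: pd.DataFrame,
                        l_max: int = 5000) -> dict:
    """Per-origin size histograms and size-range proportions.

    Fragment lengths for each origin are taken from that genome's alignment
    set. Returns {origin label: {"histogram", "proportion_gt_300",
    "strata_proportions", "n"}}.
    """
    out = {}
    for label, frags in zip(result.labels, (fragments_a, fragments_b)):
        names = set(result.names_for(label))
        sub = frags.loc[frags["name"].isin(names)]
        hist = size_histogram(sub, l_max=l_max)
        strata = {k: (proportion_in_range(sub, lo, hi) if len(sub) else
                      float("nan"))
                  for k, (lo, hi) in SIZE_STRATA.items()}
        out[label] = {
            "histogram": hist,
            "proportion_gt_300": strata["gt300"],
            "strata_proportions": strata,
            "n": int(len(sub)),
        }
    return out
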