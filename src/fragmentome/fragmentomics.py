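"""Fragment-size distributions and 5' fragment-end trinucleotide analysis.

Size histograms run from 1 bp to a configurable maximum (default 5,000 bp;
longer fragments go to an overflow bucket excluded from the density). End
motifs are the three reference bases at each fragment's 5' terminus (reverse
complemented on the minus strand), read from the reference rather than the
read bases so the analysis is robust to long-read base errors. Motif
diversity is summarized with a Gini index over the 64 trinucleotide
proportions: 0 for uniform usage, (K-1)/K as mass concentrates on one motif.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._util import BASES, TRINUCLEOTIDES, motif_codes
from .ingest import SIZE_STRATA
from .simulate import ensure_reference

__all__ = [
    "SizeHistogram",
    "EndMotifProfile",
    "size_histogram",
    "proportion_in_range",
    "end_motif_profile",
    "gini_index",
]


@dataclass
class SizeHistogram:
    """Counts per integer fragment length 1..l_max plus an overflow bucket."""

    counts: np.ndarray  # index 0 unused; counts[l] = fragments of length l
    l_max: int
    overflow: int = 0

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    @property
    def density(self) -> np.ndarray:
        t = self.total
        return self.counts / t if t else self.counts.astype(float)

    @property
    def empty(self) -> bool:
        return self.total == 0

    @property
    def median(self) -> float | None:
        if self.empty:
            return None
        cum = np.cumsum(self.counts)
        t = self.total
        lo = int(np.searchsorted(cum, (t + 1) // 2))
        hi = int(np.searchsorted(cum, t // 2 + 1))
        return (lo + hi) / 2.0

    @property
    def mode(self) -> int | None:
        if self.empty:
            return None
        return int(self.counts.argmax())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"length": np.arange(1, self.l_max + 1),
                             "count": self.counts[1:],
                             "density": self.density[1:]})


def _lengths_of(records) -> np.ndarray:
    if isinstance(records, pd.DataFrame):
        return records["length"].to_numpy(np.int64)
    return np.asarray(records, dtype=np.int64)


def size_histogram(records, l_max: int = 5000) -> SizeHistogram:
    """Histogram of fragment lengths; lengths above l_max go to overflow."""
    lengths = _lengths_of(records)
    if len(lengths) and (lengths <= 0).any():
        raise ValueError("fragment lengths must be positive")
    over = int((lengths > l_max).sum())
    in_range = lengths[lengths <= l_max]
    counts = np.bincount(in_range, minlength=l_max + 1).astype(np.int64)
    return SizeHistogram(counts=counts, l_max=l_max, overflow=over)


def proportion_in_range(records, lo: float, hi: float = float("inf")) -> float:
    """Fraction of fragments with lo <= length < hi."""
    if not lo < hi:
        raise ValueError("need lo < hi")
    if isinstance(records, SizeHistogram):
        lengths = np.repeat(np.arange(len(records.counts)), records.counts)
    else:
        lengths = _lengths_of(records)
    if len(lengths) == 0:
        return float("nan")
    return float(((lengths >= lo) & (lengths < hi)).mean())


@dataclass
class EndMotifProfile:
    """5' trinucleotide composition of one fragment stratum."""

    counts: np.ndarray  # 64 trinucleotide counts
    n_skipped: int = 0  # termini within 3 bp of a contig edge
    n_with_n: int = 0  # motifs containing an N base
    stratum: str = "all"
    motifs: list = field(default_factory=lambda: list(TRINUCLEOTIDES))

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    @property
    def proportions(self) -> np.ndarray:
        t = self.total
        return self.counts / t if t else self.counts.astype(float)

    @property
    def gini(self) -> float:
        return gini_index(self.proportions) if self.total else float("nan")

    @property
    def base_proportions(self) -> dict:
        """Single-base 5' proportions (the 'fraction starting with T' view)."""
        p = self.proportions.reshape(4, 4, 4).sum(axis=(1, 2))
        return dict(zip(BASES, p.tolist()))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"motif": self.motifs, "count": self.counts,
                             "proportion": self.proportions,
                             "stratum": self.stratum})


def _motif_codes_for(records: pd.DataFrame, ref, minus: np.ndarray) -> np.ndarray:
    codes = np.full(len(records), -2, dtype=np.int64)  # -2 = off-edge skip
    starts = records["start"].to_numpy(np.int64)
    ends = records["end"].to_numpy(np.int64)
    contigs = records["contig"].to_numpy()
    for name in ref.names:
        m = contigs == name
        if not m.any():
            continue
        L = len(ref.seqs[name])
        edge_ok = np.where(minus[m], (ends[m] - 3 >= 0) & (ends[m] <= L),
                           (starts[m] >= 0) & (starts[m] + 3 <= L))
        vals = motif_codes(ref.seqs[name], starts[m], ends[m], minus[m])
        vals[~edge_ok] = -2  # distinguish edge skips from N motifs
        codes[m] = vals
    return codes


def end_motif_profile(records: pd.DataFrame, reference,
                      strata: dict | None = None,
                      both_ends: bool = False) -> dict:
    """Tally 5' end trinucleotides per size stratum.

    Returns {stratum name: EndMotifProfile}; pass ``strata=None`` for the
    three standard strata plus an "all" profile, or a custom {name: (lo, hi)}
    mapping. Conservation: motif counts + skipped + N-containing = input size
    within each stratum (doubled when ``both_ends`` adds each fragment's
    opposite-end motif as well).
    """
    ref = ensure_reference(reference)
    strata = dict(strata) if strata is not None else dict(SIZE_STRATA)
    strata.setdefault("all", (0, float("inf")))
    minus = records["strand"].to_numpy() == "-"
    codes = _motif_codes_for(records, ref, minus)
    lengths = records["length"].to_numpy(np.int64)
    if both_ends:
        codes = np.concatenate([codes, _motif_codes_for(records, ref, ~minus)])
        lengths = np.concatenate([lengths, lengths])
    out = {}
    for label, (lo, hi) in strata.items():
        sel = (lengths >= lo) & (lengths < hi)
        c = codes[sel]
        counts = np.bincount(c[c >= 0], minlength=64).astype(np.int64)
        out[label] = EndMotifProfile(
            counts=counts,
            n_skipped=int((c == -2).sum()),
            n_with_n=int((c == -1).sum()),
            stratum=label)
    return out


def gini_index(proportions) -> float:
    """Gini diversity index of a nonnegative vector over K categories.

    Mean-absolute-difference form: G = sum_ij |p_i - p_j| / (2 K sum(p)).
    Invariant to rescaling and to permutation of categories; 0 iff uniform;
    tends to (K-1)/K as mass concentrates on one category.
    """
    p = np.asarray(proportions, dtype=float)
    if p.ndim != 1 or len(p) == 0:
        raise ValueError("proportions must be a nonempty 1-d vector")
    if (p < 0).any():
        raise ValueError("proportions must be nonnegative")
    s = p.sum()
    if s <= 0:
        raise ValueError("proportions must not be all zero")
    x = np.sort(p)
    K = len(x)
    idx = np.arange(K)
    # sum_ij |x_i - x_j| = 2 * sum_k (2k - K + 1) x_(k) for sorted x
    mad_sum = 2.0 * np.sum((2 * idx - K + 1) * x)
    return float(mad_sum / (2.0 * K * s))
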