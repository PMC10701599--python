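"""Synthetic cfDNA data generation.

Produces toy reference genomes and labeled, aligned cfDNA fragment sets with
the statistical structure the downstream analyses assume:

* fragment sizes following the nucleosomal ladder of plasma cfDNA (modes near
  167 bp and multiples thereof) or the short non-nucleosomal profile of urine
  cfDNA (median near 82 bp);
* tumor-labeled fragments shifted toward shorter sizes, with the shift growing
  per nucleosome multiple (20 bp at mono-nucleosome scale, >100 bp beyond);
* segmental copy-number aberrations sampled at a configurable tumor fraction;
* optional 5' trinucleotide end-motif bias and coverage depletion around
  TSS-like sites;
* two-genome xenograft mixtures with configurable cross-mapping.

Everything is deterministic under a fixed seed, and writable as plain FASTA /
SAM / TSV so the rest of the package can be exercised with no external data.
"""
from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import pysam
from scipy import stats

from ._util import as_rng, decode_seq, encode_seq, gc_cumsum, motif_codes, spawn_seeds

__all__ = [
    "ToyReference",
    "SizeModel",
    "CNASegment",
    "CNAProfile",
    "SimulationConfig",
    "SimulatedSample",
    "XenograftMapqModel",
    "make_toy_reference",
    "sample_fragment_lengths",
    "simulate_sample",
    "simulate_xenograft_pair",
    "write_sample",
]


@dataclass
class ToyReference:
    """A small in-memory reference genome with a per-window GC track.

    Sequences are stored as uint8 codes (A=0, C=1, G=2, T=3, N=4). The GC
    track holds the realized GC fraction per non-overlapping window of
    ``gc_window`` bp (last window may be partial).
    """

    names: list[str]
    seqs: dict[str, np.ndarray]
    gc_window: int = 1000
    gc_track: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self):
        if len(set(self.names)) != len(self.names):
            raise ValueError("contig names must be unique")
        self._gc_cum: dict[str, np.ndarray] = {}
        if not self.gc_track:
            self.gc_track = {n: self._compute_gc_track(n) for n in self.names}

    def _compute_gc_track(self, name: str) -> np.ndarray:
        cum = self.gc_cum(name)
        L = len(self.seqs[name])
        edges = np.arange(0, L + self.gc_window, self.gc_window)
        edges[-1] = L
        widths = np.diff(edges)
        return (cum[edges[1:]] - cum[edges[:-1]]) / np.maximum(widths, 1)

    def gc_cum(self, name: str) -> np.ndarray:
        if name not in self._gc_cum:
            self._gc_cum[name] = gc_cumsum(self.seqs[name])
        return self._gc_cum[name]

    @property
    def contig_lengths(self) -> dict[str, int]:
        return {n: len(self.seqs[n]) for n in self.names}

    @property
    def total_length(self) -> int:
        return sum(len(s) for s in self.seqs.values())

    def fetch(self, name: str, start: int, end: int) -> str:
        return decode_seq(self.seqs[name][start:end])

    def gc_fraction(self, name: str, starts, ends) -> np.ndarray:
        """Vectorized GC fraction over [start, end) intervals."""
        cum = self.gc_cum(name)
        starts = np.asarray(starts, dtype=np.int64)
        ends = np.asarray(ends, dtype=np.int64)
        width = np.maximum(ends - starts, 1)
        return (cum[ends] - cum[starts]) / width

    def write_fasta(self, path, line_width: int = 70) -> None:
        with open(path, "w") as fh:
            for name in self.names:
                fh.write(f">{name}\n")
                seq = decode_seq(self.seqs[name])
                for i in range(0, len(seq), line_width):
                    fh.write(seq[i:i + line_width] + "\n")

    @classmethod
    def from_fasta(cls, path, gc_window: int = 1000) -> "ToyReference":
        import pyfaidx

        fa = pyfaidx.Fasta(str(path), as_raw=True, sequence_always_upper=True)
        names = list(fa.keys())
        seqs = {n: encode_seq(str(fa[n][:])) for n in names}
        return cls(names=names, seqs=seqs, gc_window=gc_window)


def ensure_reference(ref) -> ToyReference:
    """Accept a ToyReference or a FASTA path."""
    if isinstance(ref, ToyReference):
        return ref
    return ToyReference.from_fasta(ref)


def make_toy_reference(n_contigs: int, contig_length_bp: int, gc_low: float,
                       gc_high: float, seed: int, gc_window: int = 1000,
                       names=None) -> ToyReference:
    """Generate a random reference whose per-window GC varies smoothly
    between ``gc_low`` and ``gc_high``.

    The window-level GC targets are a smoothed, min-max rescaled noise
    sequence, so realized mean GC stays inside the requested bounds (up to
    binomial noise within windows; exact at degenerate bounds 0 and 1).
    """
    if n_contigs < 1:
        raise ValueError("n_contigs must be >= 1")
    if contig_length_bp <= 0:
        raise ValueError("contig_length_bp must be positive")
    if not (0.0 <= gc_low <= gc_high <= 1.0):
        raise ValueError("need 0 <= gc_low <= gc_high <= 1")
    rng = as_rng(seed)
    if names is None:
        names = [f"chr{i + 1}" for i in range(n_contigs)]
    seqs = {}
    for name in names:
        n_win = math.ceil(contig_length_bp / gc_window)
        raw = rng.random(n_win)
        if n_win >= 5:  # moving-average smoothing for spatial coherence
            kernel = np.ones(5) / 5.0
            raw = np.convolve(np.pad(raw, 2, mode="edge"), kernel, mode="valid")
        lo, hi = raw.min(), raw.max()
        if hi > lo:
            scaled = (raw - lo) / (hi - lo)
        else:
            scaled = np.full(n_win, 0.5)
        target = gc_low + (gc_high - gc_low) * scaled
        p_gc = np.repeat(target, gc_window)[:contig_length_bp]
        is_gc = rng.random(contig_length_bp) < p_gc
        pick = rng.random(contig_length_bp) < 0.5
        codes = np.where(is_gc, np.where(pick, 1, 2), np.where(pick, 0, 3))
        seqs[name] = codes.astype(np.uint8)
    return ToyReference(names=list(names), seqs=seqs, gc_window=gc_window)


@dataclass
class SizeModel:
    """Mixture-of-truncated-normal fragment size model.

    ``modes`` is a list of (mean bp, sd bp, weight). Tumor-labeled fragments
    subtract ``tumor_shift[i]`` from the mean of mode i, modelling the
    progressive shortening of tumor cfDNA per nucleosome multiple.
    """

    kind: str
    modes: tuple = ()
    tumor_shift: tuple = ()
    min_length: int = 20
    max_length: int = 5000

    PLASMA_MODES = ((167.0, 10.0, 0.46), (334.0, 20.0, 0.28),
                    (501.0, 30.0, 0.16), (668.0, 40.0, 0.10))
    PLASMA_SHIFT = (20.0, 60.0, 110.0, 130.0)
    URINE_MODES = ((82.0, 25.0, 1.0),)
    URINE_SHIFT = (10.0,)

    def __post_init__(self):
        if not self.modes:
            raise ValueError("size model needs at least one mode")
        w = np.array([m[2] for m in self.modes], dtype=float)
        if (w < 0).any() or w.sum() <= 0:
            raise ValueError("mode weights must be nonnegative with positive sum")
        if not np.isclose(w.sum(), 1.0):
            w = w / w.sum()
            self.modes = tuple((m, s, wi) for (m, s, _), wi in zip(self.modes, w))
        if len(self.tumor_shift) != len(self.modes):
            raise ValueError("tumor_shift must give one value per mode")
        for (mean, _, _), shift in zip(self.modes, self.tumor_shift):
            if mean - shift < self.min_length:
                raise ValueError("shifted mode mean falls below min_length")

    @classmethod
    def plasma(cls, modes=None, tumor_shift=None, **kw) -> "SizeModel":
        return cls(kind="plasma", modes=tuple(modes or cls.PLASMA_MODES),
                   tumor_shift=tuple(tumor_shift or cls.PLASMA_SHIFT), **kw)

    @classmethod
    def urine(cls, modes=None, tumor_shift=None, **kw) -> "SizeModel":
        return cls(kind="urine", modes=tuple(modes or cls.URINE_MODES),
                   tumor_shift=tuple(tumor_shift or cls.URINE_SHIFT), **kw)

    @property
    def weights(self) -> np.ndarray:
        return np.array([m[2] for m in self.modes], dtype=float)


def sample_fragment_lengths(model: SizeModel, label: str, n: int, seed) -> np.ndarray:
    """Draw n integer fragment lengths for a given truth label."""
    if n < 1:
        raise ValueError("n must be >= 1")
    if label not in ("tumor", "normal"):
        raise ValueError(f"unknown label {label!r}; expected 'tumor' or 'normal'")
    rng = as_rng(seed)
    comp = rng.choice(len(model.modes), size=n, p=model.weights)
    out = np.empty(n, dtype=np.int64)
    for i, (mean, sd, _) in enumerate(model.modes):
        m = comp == i
        k = int(m.sum())
        if k == 0:
            continue
        mu = mean - (model.tumor_shift[i] if label == "tumor" else 0.0)
        if sd <= 0:
            vals = np.full(k, mu)
        else:
            a = (model.min_length - mu) / sd
            b = (model.max_length - mu) / sd
            vals = stats.truncnorm.rvs(a, b, loc=mu, scale=sd, size=k,
                                       random_state=rng)
        out[m] = np.clip(np.rint(vals), model.min_length,
                         model.max_length).astype(np.int64)
    return out


@dataclass
class CNASegment:
    contig: str
    start: int
    end: int
    copy: int


@dataclass
class CNAProfile:
    """Segmental integer copy-number truth over a reference.

    Regions not covered by a segment sit at the background ploidy (default 2).
    """

    segments: list = field(default_factory=list)
    ploidy: float = 2.0
    max_copy: int = 3

    def __post_init__(self):
        by_contig: dict[str, list[CNASegment]] = {}
        for seg in self.segments:
            if seg.end <= seg.start:
                raise ValueError("segment end must exceed start")
            if not (0 <= seg.copy):
                raise ValueError("copy number must be nonnegative")
            by_contig.setdefault(seg.contig, []).append(seg)
        for segs in by_contig.values():
            segs.sort(key=lambda s: s.start)
            for a, b in zip(segs, segs[1:]):
                if b.start < a.end:
                    raise ValueError("CNA segments must not overlap")

    def intervals(self, ref: ToyReference) -> pd.DataFrame:
        """Tile each contig into (contig, start, end, copy) pieces."""
        rows = []
        by_contig: dict[str, list[CNASegment]] = {}
        for seg in self.segments:
            if seg.contig not in ref.seqs:
                raise ValueError(f"segment contig {seg.contig!r} not in reference")
            if seg.end > len(ref.seqs[seg.contig]):
                raise ValueError("CNA segment extends beyond contig end")
            by_contig.setdefault(seg.contig, []).append(seg)
        for name in ref.names:
            L = len(ref.seqs[name])
            pos = 0
            for seg in sorted(by_contig.get(name, []), key=lambda s: s.start):
                if seg.start > pos:
                    rows.append((name, pos, seg.start, self.ploidy))
                rows.append((name, seg.start, seg.end, float(seg.copy)))
                pos = seg.end
            if pos < L:
                rows.append((name, pos, L, self.ploidy))
        return pd.DataFrame(rows, columns=["contig", "start", "end", "copy"])


@dataclass
class SimulationConfig:
    """Full recipe for one synthetic cfDNA sample."""

    reference: ToyReference
    size_model: SizeModel
    n_fragments: int
    tumor_fraction: float = 0.0
    cna: CNAProfile | None = None
    end_motif_bias: np.ndarray | None = None  # 64 relative weights
    tss_sites: pd.DataFrame | None = None  # columns contig, pos
    tss_halfwidth: int = 100
    tss_keep_prob: float = 0.3
    mapq: int = 60
    seed: int = 0
    name_prefix: str = "frag"

    def __post_init__(self):
        if self.n_fragments < 0:
            raise ValueError("n_fragments must be nonnegative")
        if not (0.0 <= self.tumor_fraction <= 1.0):
            raise ValueError("tumor_fraction must be in [0, 1]")
        if self.end_motif_bias is not None:
            b = np.asarray(self.end_motif_bias, dtype=float)
            if b.shape != (64,) or (b < 0).any() or b.sum() <= 0:
                raise ValueError("end_motif_bias must be 64 nonnegative weights, not all zero")
            self.end_motif_bias = b
        if self.tss_sites is not None:
            lens = self.reference.contig_lengths
            for row in self.tss_sites.itertuples():
                if row.contig not in lens or not (0 <= row.pos < lens[row.contig]):
                    raise ValueError("TSS-like site off reference")

    def to_json(self) -> str:
        d = {
            "n_fragments": self.n_fragments,
            "tumor_fraction": self.tumor_fraction,
            "size_model": {"kind": self.size_model.kind,
                           "modes": [list(m) for m in self.size_model.modes],
                           "tumor_shift": list(self.size_model.tumor_shift)},
            "seed": self.seed,
            "mapq": self.mapq,
            "tss_halfwidth": self.tss_halfwidth,
            "tss_keep_prob": self.tss_keep_prob,
            "contigs": self.reference.contig_lengths,
            "cna": None if self.cna is None else [
                [s.contig, s.start, s.end, s.copy] for s in self.cna.segments],
        }
        return json.dumps(d, indent=2, sort_keys=True)


@dataclass
class SimulatedSample:
    fragments: pd.DataFrame
    truth: pd.DataFrame
    config: SimulationConfig


def _placement_tables(ref: ToyReference, cna: CNAProfile | None):
    """Per-label piecewise-uniform placement distributions.

    Normal fragments land uniformly; tumor fragments land with density
    proportional to local copy number over ploidy.
    """
    if cna is None:
        iv = pd.DataFrame(
            [(n, 0, len(ref.seqs[n]), 2.0) for n in ref.names],
            columns=["contig", "start", "end", "copy"])
        ploidy = 2.0
    else:
        iv = cna.intervals(ref)
        ploidy = cna.ploidy
    length = (iv["end"] - iv["start"]).to_numpy(dtype=float)
    tables = {}
    for label in ("normal", "tumor"):
        w = length if label == "normal" else length * iv["copy"].to_numpy() / ploidy
        cw = np.cumsum(w)
        tables[label] = (iv, cw)
    return tables


def _place(rng, tables, label, lengths, ref: ToyReference):
    iv, cw = tables[label]
    total = cw[-1]
    u = rng.random(len(lengths)) * total
    idx = np.searchsorted(cw, u, side="right")
    idx = np.minimum(idx, len(cw) - 1)
    seg_start = iv["start"].to_numpy()[idx]
    seg_end = iv["end"].to_numpy()[idx]
    contig_idx = iv["contig"].to_numpy()[idx]
    offs = rng.random(len(lengths)) * (seg_end - seg_start)
    start = (seg_start + offs).astype(np.int64)
    contig_len = np.array([len(ref.seqs[c]) for c in contig_idx])
    start = np.minimum(start, np.maximum(contig_len - lengths, 0))
    end = np.minimum(start + lengths, contig_len)
    return contig_idx, start, end


def simulate_sample(config: SimulationConfig) -> SimulatedSample:
    """Generate one labeled cfDNA fragment set.

    Tumor labels are Bernoulli(tumor fraction); tumor fragments are placed
    with probability proportional to local copy number; every fragment's 5'
    trinucleotide is consistent with the reference at its terminus; optional
    end-motif bias is applied by rejection sampling and TSS-like depletion by
    rejection thinning (fragments whose midpoint falls within the configured
    half-width of a site are kept with probability ``tss_keep_prob``).
    """
    ref = config.reference
    rng = as_rng(config.seed)
    n = config.n_fragments
    tables = _placement_tables(ref, config.cna)
    bias = None
    if config.end_motif_bias is not None:
        bias = config.end_motif_bias / config.end_motif_bias.max()
    site_pos = None
    if config.tss_sites is not None and len(config.tss_sites):
        site_pos = {c: np.sort(g["pos"].to_numpy())
                    for c, g in config.tss_sites.groupby("contig")}

    chunks = []
    remaining = n
    rounds = 0
    while remaining > 0:
        rounds += 1
        if rounds > 500:
            raise RuntimeError(
                "simulation rejection loop failed to converge; check that the "
                "end-motif bias is achievable on this reference")
        is_tumor = rng.random(remaining) < config.tumor_fraction
        lengths = np.empty(remaining, dtype=np.int64)
        n_t = int(is_tumor.sum())
        if n_t:
            lengths[is_tumor] = sample_fragment_lengths(
                config.size_model, "tumor", n_t, rng)
        if remaining - n_t:
            lengths[~is_tumor] = sample_fragment_lengths(
                config.size_model, "normal", remaining - n_t, rng)
        contig = np.empty(remaining, dtype=object)
        start = np.empty(remaining, dtype=np.int64)
        end = np.empty(remaining, dtype=np.int64)
        for label, mask in (("tumor", is_tumor), ("normal", ~is_tumor)):
            if mask.any():
                c, s, e = _place(rng, tables, label, lengths[mask], ref)
                contig[mask] = c
                start[mask] = s
                end[mask] = e
        minus = rng.random(remaining) < 0.5

        keep = np.ones(remaining, dtype=bool)
        # 5' end-motif bias via rejection
        motifs = np.full(remaining, -1, dtype=np.int64)
        for cname in ref.names:
            m = contig == cname
            if m.any():
                motifs[m] = motif_codes(ref.seqs[cname], start[m], end[m], minus[m])
        if bias is not None:
            ok = motifs >= 0
            acc = np.zeros(remaining, dtype=bool)
            acc[ok] = rng.random(int(ok.sum())) < bias[motifs[ok]]
            keep &= acc
        # TSS-like depletion via thinning on fragment midpoints
        if site_pos is not None:
            mid = (start + end) // 2
            near = np.zeros(remaining, dtype=bool)
            for cname, pos_arr in site_pos.items():
                m = contig == cname
                if not m.any():
                    continue
                j = np.searchsorted(pos_arr, mid[m])
                left = np.abs(mid[m] - pos_arr[np.maximum(j - 1, 0)])
                right = np.abs(pos_arr[np.minimum(j, len(pos_arr) - 1)] - mid[m])
                near[m] = np.minimum(left, right) <= config.tss_halfwidth
            thin = near & (rng.random(remaining) >= config.tss_keep_prob)
            keep &= ~thin

        if keep.any():
            chunks.append(pd.DataFrame({
                "contig": contig[keep],
                "start": start[keep],
                "end": end[keep],
                "length": (end - start)[keep],
                "strand": np.where(minus[keep], "-", "+"),
                "motif": motifs[keep],
                "label": np.where(is_tumor[keep], "tumor", "normal"),
            }))
        remaining -= int(keep.sum())

    if chunks:
        frags = pd.concat(chunks, ignore_index=True)
    else:
        frags = pd.DataFrame(columns=["contig", "start", "end", "length",
                                      "strand", "motif", "label"])
    frags["name"] = [f"{config.name_prefix}{i:08d}|{lab}"
                     for i, lab in enumerate(frags["label"])]
    frags["mapq"] = config.mapq
    for col in ("unmapped", "secondary", "supplementary", "duplicate"):
        frags[col] = False
    order = {n: i for i, n in enumerate(ref.names)}
    frags["_c"] = frags["contig"].map(order)
    frags = frags.sort_values(["_c", "start", "name"], kind="mergesort")
    frags = frags.drop(columns="_c").reset_index(drop=True)
    truth = frags[["name", "label", "contig", "start", "end", "length",
                   "strand"]].copy()
    return SimulatedSample(fragments=frags, truth=truth, config=config)


def write_sample(sample: SimulatedSample, outdir, basename: str = "sample",
                 write_fasta: bool = True) -> dict:
    """Write a simulated sample as SAM + truth TSV (+ reference FASTA + config).

    Output bytes are a pure function of the simulation config, so a fixed
    seed reproduces files exactly.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    ref = sample.config.reference
    paths = {}
    if write_fasta:
        fasta = outdir / f"{basename}.ref.fa"
        ref.write_fasta(fasta)
        paths["fasta"] = str(fasta)
    sam_path = outdir / f"{basename}.sam"
    header = {"HD": {"VN": "1.6", "SO": "coordinate"},
              "SQ": [{"SN": n, "LN": len(ref.seqs[n])} for n in ref.names]}
    with pysam.AlignmentFile(str(sam_path), "wh", header=header) as out:
        hdr = out.header
        for row in sample.fragments.itertuples():
            a = pysam.AlignedSegment(hdr)
            a.query_name = row.name
            a.flag = 16 if row.strand == "-" else 0
            a.reference_id = ref.names.index(row.contig)
            a.reference_start = int(row.start)
            a.mapping_quality = int(row.mapq)
            a.cigarstring = f"{int(row.length)}M"
            out.write(a)
    paths["sam"] = str(sam_path)
    truth_path = outdir / f"{basename}.truth.tsv"
    sample.truth.to_csv(truth_path, sep="\t", index=False)
    paths["truth"] = str(truth_path)
    cfg_path = outdir / f"{basename}.config.json"
    cfg_path.write_text(sample.config.to_json() + "\n")
    paths["config"] = str(cfg_path)
    return paths


@dataclass
class XenograftMapqModel:
    """How reads map to their own vs the other genome.

    Reads always align to their genome of origin at ``primary_mapq``. A
    ``cross_fraction`` of reads additionally aligns to the other genome with
    a mapq drawn uniformly from ``cross_mapq`` (inclusive bounds), kept below
    the primary mapq so origins stay separable.
    """

    primary_mapq: int = 60
    cross_mapq: tuple = (5, 30)
    cross_fraction: float = 0.1

    def __post_init__(self):
        if not (0.0 <= self.cross_fraction <= 1.0):
            raise ValueError("cross_fraction must be in [0, 1]")
        if self.cross_mapq[1] >= self.primary_mapq:
            raise ValueError("cross-mapping mapq must stay below primary mapq")


def _refs_identical(a: ToyReference, b: ToyReference) -> bool:
    if a.names != b.names:
        return False
    return all(np.array_equal(a.seqs[n], b.seqs[n]) for n in a.names)


def simulate_xenograft_pair(config_graft: SimulationConfig,
                            config_host: SimulationConfig,
                            mapq_model: XenograftMapqModel,
                            seed: int):
    """Simulate a xenograft plasma sample aligned against two genomes.

    Returns (alignments vs graft genome, alignments vs host genome, truth).
    Graft reads come from ``config_graft`` on its own reference, host reads
    from ``config_host``; a configurable fraction of each cross-maps to the
    other genome at lower mapq.
    """
    ref_g = config_graft.reference
    ref_h = config_host.reference
    if _refs_identical(ref_g, ref_h):
        raise ValueError("graft and host references are identical; origin undefined")
    seeds = spawn_seeds(seed, 4)
    parts = []
    for origin, cfg, own_ref, other_ref, s_sim, s_cross in (
            ("graft", config_graft, ref_g, ref_h, seeds[0], seeds[1]),
            ("host", config_host, ref_h, ref_g, seeds[2], seeds[3])):
        if cfg.n_fragments == 0:
            parts.append((origin, None, None))
            continue
        cfg2 = SimulationConfig(
            reference=own_ref, size_model=cfg.size_model,
            n_fragments=cfg.n_fragments, tumor_fraction=cfg.tumor_fraction,
            cna=cfg.cna, mapq=mapq_model.primary_mapq, seed=s_sim,
            name_prefix=origin)
        own = simulate_sample(cfg2).fragments.copy()
        own["name"] = [f"{origin}{i:07d}" for i in range(len(own))]
        rng = as_rng(s_cross)
        cross_mask = rng.random(len(own)) < mapq_model.cross_fraction
        cross = own.loc[cross_mask, ["name", "length"]].copy()
        if len(cross):
            other_names = other_ref.names
            lens = np.array([len(other_ref.seqs[c]) for c in other_names],
                            dtype=float)
            ci = rng.choice(len(other_names), size=len(cross), p=lens / lens.sum())
            contig = np.array(other_names, dtype=object)[ci]
            L = lens[ci].astype(np.int64)
            flen = np.minimum(cross["length"].to_numpy(), L)
            start = (rng.random(len(cross)) * np.maximum(L - flen, 1)).astype(np.int64)
            cross["contig"] = contig
            cross["start"] = start
            cross["end"] = start + flen
            cross["length"] = flen
            cross["strand"] = np.where(rng.random(len(cross)) < 0.5, "-", "+")
            cross["mapq"] = rng.integers(mapq_model.cross_mapq[0],
                                         mapq_model.cross_mapq[1] + 1,
                                         size=len(cross))
            for col in ("unmapped", "secondary", "supplementary", "duplicate"):
                cross[col] = False
            cross["label"] = origin
        parts.append((origin, own, cross))

    cols = ["name", "contig", "start", "end", "length", "mapq", "strand",
            "unmapped", "secondary", "supplementary", "duplicate", "label"]

    def _frame(items):
        items = [x[cols] for x in items if x is not None and len(x)]
        if not items:
            return pd.DataFrame(columns=cols)
        return pd.concat(items, ignore_index=True)

    graft_own, graft_cross = parts[0][1], parts[0][2]
    host_own, host_cross = parts[1][1], parts[1][2]
    if graft_own is not None:
        graft_own = graft_own.assign(label="graft")
    if host_own is not None:
        host_own = host_own.assign(label="host")
    aln_graft = _frame([graft_own, host_cross])
    aln_host = _frame([host_own, graft_cross])
    truth_rows = []
    for origin, own in (("graft", graft_own), ("host", host_own)):
        if own is not None:
            truth_rows.append(pd.DataFrame({"name": own["name"],
                                            "origin": origin}))
    truth = (pd.concat(truth_rows, ignore_index=True) if truth_rows
             else pd.DataFrame(columns=["name", "origin"]))
    return aln_graft, aln_host, truth
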