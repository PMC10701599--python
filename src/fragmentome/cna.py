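"""Copy-number and tumor-fraction estimation from binned fragment counts.

The estimator follows the standard low-coverage WGS mixture model for
circulating tumor DNA: with normal (non-tumor) fraction ``n``, background
ploidy ``phi`` and integer copy number ``c_k`` in state k, the expected bin
log2 ratio is

    m_k(n, phi) = log2( (n * 2 + (1 - n) * c_k) / (n * 2 + (1 - n) * phi) )

A hidden Markov model over copy-number states {0, 1, 2, 3} with sticky
transitions and Gaussian emissions centered at m_k is fit by coordinate
ascent of the profile likelihood (a bracket search over n alternated with a
1-d emission-sd update), run once per normal-fraction restart (0.95, 0.99,
0.995, 0.999 by default); the restart with the highest log-likelihood is
reported.
Tumor fraction is 1 - n, and a sample is called "detected" when the tumor
fraction exceeds 3%.

Bin counts are GC-corrected (local regression of count on GC, with a
GC-decile median fallback for small bin sets), optionally normalized to a
panel of normals, and expressed as log2 ratios to the sample median.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from numba import njit
from scipy.optimize import minimize_scalar

from .simulate import ensure_reference

__all__ = [
    "BinProfile",
    "PanelOfNormals",
    "HMMConfig",
    "TumorFractionEstimate",
    "CopyNumberSegment",
    "bin_fragments",
    "correct_and_normalize",
    "expected_log2_ratio",
    "hmm_loglik",
    "fit_tumor_fraction",
    "viterbi_segments",
]


@dataclass
class BinProfile:
    """Fixed-width genome bins with raw counts, GC, mappability and
    (after correction) log2 ratios. ``bins`` columns: contig, start, end,
    count, gc, mappability, log2, masked."""

    bins: pd.DataFrame
    bin_width: int
    n_off_reference: int = 0

    @property
    def unmasked(self) -> pd.DataFrame:
        return self.bins.loc[~self.bins["masked"]]

    def to_tsv(self, path) -> None:
        self.bins.to_csv(path, sep="\t", index=False)


def bin_fragments(records: pd.DataFrame, bin_width: int, reference,
                  mappability: pd.DataFrame | None = None) -> BinProfile:
    """Count fragments into fixed-width bins by fragment midpoint.

    GC is computed from the reference per bin; mappability defaults to 1
    everywhere (an optional table with columns contig, start, mappability can
    override it). Fragments falling off the reference are tallied to
    ``n_off_reference`` so the total is conserved.
    """
    ref = ensure_reference(reference)
    rows = []
    for name in ref.names:
        L = len(ref.seqs[name])
        starts = np.arange(0, L, bin_width, dtype=np.int64)
        ends = np.minimum(starts + bin_width, L)
        gc = ref.gc_fraction(name, starts, ends)
        for s, e, g in zip(starts, ends, gc):
            rows.append((name, int(s), int(e), 0, float(g), 1.0))
    bins = pd.DataFrame(rows, columns=["contig", "start", "end", "count",
                                       "gc", "mappability"])
    if mappability is not None:
        key = bins.merge(mappability, on=["contig", "start"], how="left",
                         suffixes=("", "_ovr"))
        bins["mappability"] = key["mappability_ovr"].fillna(1.0).to_numpy()

    off = 0
    offsets = {}
    pos = 0
    for name in ref.names:
        offsets[name] = pos
        pos += int(np.ceil(len(ref.seqs[name]) / bin_width))
    counts = np.zeros(len(bins), dtype=np.int64)
    mid = ((records["start"].to_numpy(np.int64)
            + records["end"].to_numpy(np.int64)) // 2)
    for name, grp_idx in records.groupby("contig").groups.items():
        if name not in offsets:
            off += len(grp_idx)
            continue
        L = len(ref.seqs[name])
        m = mid[records.index.get_indexer(grp_idx)]
        ok = (m >= 0) & (m < L)
        off += int((~ok).sum())
        b = offsets[name] + (m[ok] // bin_width)
        np.add.at(counts, b, 1)
    bins["count"] = counts
    bins["log2"] = np.nan
    bins["masked"] = False
    return BinProfile(bins=bins, bin_width=bin_width, n_off_reference=off)


@dataclass
class PanelOfNormals:
    """Per-bin median log2 (and dispersion) across control samples, plus a
    bin mask; must share binning with the target samples."""

    table: pd.DataFrame  # contig, start, end, median_log2, dispersion, masked
    bin_width: int

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path, bin_width: int | None = None) -> "PanelOfNormals":
        table = pd.read_csv(path, sep="\t")
        if bin_width is None:
            bin_width = int((table["end"] - table["start"]).mode().iloc[0])
        return cls(table=table, bin_width=bin_width)

    @classmethod
    def from_profiles(cls, profiles: list["BinProfile"]) -> "PanelOfNormals":
        if not profiles:
            raise ValueError("panel of normals needs at least one profile")
        width = profiles[0].bin_width
        base = profiles[0].bins[["contig", "start", "end"]].copy()
        logs = np.stack([p.bins["log2"].to_numpy(float) for p in profiles])
        masks = np.stack([p.bins["masked"].to_numpy(bool) for p in profiles])
        base["median_log2"] = np.nanmedian(np.where(masks, np.nan, logs), axis=0)
        with np.errstate(all="ignore"):
            base["dispersion"] = np.nanstd(np.where(masks, np.nan, logs), axis=0)
        base["masked"] = masks.all(axis=0) | ~np.isfinite(base["median_log2"])
        return cls(table=base, bin_width=width)


def _gc_correct(count: np.ndarray, gc: np.ndarray) -> np.ndarray:
    """Divide counts by a smooth GC-bias curve.

    Local (lowess) regression of count on GC when enough bins are available;
    GC-decile median scaling otherwise.
    """
    from statsmodels.nonparametric.smoothers_lowess import lowess

    if len(count) >= 200:
        fit = lowess(count, gc, frac=0.3, it=2, return_sorted=True)
        pred = np.interp(gc, fit[:, 0], fit[:, 1])
    else:
        deciles = np.quantile(gc, np.linspace(0, 1, 11))
        deciles[0] -= 1e-9
        which = np.clip(np.searchsorted(deciles, gc, side="right") - 1, 0, 9)
        pred = np.empty_like(count, dtype=float)
        for d in range(10):
            m = which == d
            if m.any():
                pred[m] = np.median(count[m])
    floor = 0.05 * max(np.median(count), 1.0)
    pred = np.maximum(pred, floor)
    return count / pred


def correct_and_normalize(profile: BinProfile,
                          pon: PanelOfNormals | None = None,
                          gc_bounds: tuple = (0.3, 0.6),
                          min_mappability: float = 0.9) -> BinProfile:
    """GC/mappability-correct bin counts and express them as log2 ratios.

    Bins with extreme GC, low mappability or zero count are masked. When a
    panel of normals is supplied, its per-bin median log2 is subtracted
    (so a sample normalized against itself is exactly zero).
    """
    bins = profile.bins.copy()
    if bins["count"].sum() == 0:
        raise ValueError("profile has zero total count")
    gc = bins["gc"].to_numpy(float)
    mask = ((bins["mappability"] < min_mappability)
            | (gc < gc_bounds[0]) | (gc > gc_bounds[1])
            | (bins["count"] <= 0))
    if pon is not None:
        if pon.bin_width != profile.bin_width or len(pon.table) != len(bins):
            raise ValueError("panel of normals binning does not match sample")
        mask |= pon.table["masked"].to_numpy(bool)
    mask = mask.to_numpy() if hasattr(mask, "to_numpy") else mask
    if mask.all():
        raise ValueError("all bins masked; cannot normalize")
    count = bins["count"].to_numpy(float)
    corrected = np.full(len(bins), np.nan)
    corr = _gc_correct(count[~mask], gc[~mask])
    corr = corr / bins["mappability"].to_numpy(float)[~mask]
    corrected[~mask] = corr
    med = np.median(corrected[~mask])
    log2 = np.full(len(bins), np.nan)
    log2[~mask] = np.log2(corrected[~mask] / med)
    if pon is not None:
        log2[~mask] = log2[~mask] - pon.table["median_log2"].to_numpy(float)[~mask]
    bins["log2"] = log2
    bins["masked"] = mask
    return BinProfile(bins=bins, bin_width=profile.bin_width,
                      n_off_reference=profile.n_off_reference)


def expected_log2_ratio(n, c_k, phi: float = 2.0, floor: float = -8.0):
    """Expected log2 ratio of a copy-``c_k`` state in a sample with normal
    fraction ``n`` and background ploidy ``phi``. Zero whenever c_k == phi;
    the -inf limit (c_k = 0, n = 0) is floored at ``floor``."""
    n = np.asarray(n, dtype=float)
    c = np.asarray(c_k, dtype=float)
    if np.any((n < 0) | (n > 1)):
        raise ValueError("n must be in [0, 1]")
    if np.any(c < 0) or phi <= 0:
        raise ValueError("need c_k >= 0 and phi > 0")
    num = n * 2.0 + (1.0 - n) * c
    den = n * 2.0 + (1.0 - n) * phi
    with np.errstate(divide="ignore"):
        out = np.log2(num / den)
    out = np.where(np.isfinite(out), out, floor)
    out = np.maximum(out, floor)
    if out.ndim == 0:
        return float(out)
    return out


@dataclass
class HMMConfig:
    """Settings for the copy-number HMM."""

    states: tuple = (0, 1, 2, 3)
    restarts: tuple = (0.95, 0.99, 0.995, 0.999)
    ploidy: float = 2.0
    self_transition: float = 0.99
    emission_sd: float | None = None  # None -> estimated from the data
    subclonal: bool = False  # no subclonal states
    max_iter: int = 30
    tol: float = 1e-6
    tf_threshold: float = 0.03
    n_bounds: tuple = (0.5, 0.99999)
    log2_floor: float = -8.0
    estimate_ploidy: bool = False  # initial ploidy 2, re-estimation off
    start_neutral_prob: float = 0.5  # start mass on the neutral (ploidy) state

    def __post_init__(self):
        if any(not (0.0 < r < 1.0) for r in self.restarts):
            raise ValueError("restarts must lie in (0, 1)")
        if list(self.states) != sorted(self.states):
            raise ValueError("states must be sorted ascending")
        if not (0.0 < self.self_transition < 1.0):
            raise ValueError("self_transition must lie in (0, 1)")
        if self.subclonal:
            raise ValueError("subclonal states are disabled")


@dataclass
class TumorFractionEstimate:
    normal_fraction: float
    tumor_fraction: float
    ploidy: float
    restart_table: pd.DataFrame  # restart_n0, n_hat, sd_hat, loglik, converged
    selected_restart: int
    state_path: np.ndarray  # copy-number state per unmasked bin
    emission_sd: float
    detected: bool

    def to_dict(self) -> dict:
        return {
            "normal_fraction": self.normal_fraction,
            "tumor_fraction": self.tumor_fraction,
            "ploidy": self.ploidy,
            "selected_restart": int(self.selected_restart),
            "emission_sd": self.emission_sd,
            "detected": bool(self.detected),
            "restarts": self.restart_table.to_dict(orient="records"),
        }


@dataclass
class CopyNumberSegment:
    contig: str
    start: int
    end: int
    copy: int
    mean_log2: float
    n_bins: int


def _log_transition(config: HMMConfig) -> np.ndarray:
    K = len(config.states)
    p = config.self_transition
    T = np.full((K, K), (1.0 - p) / (K - 1) if K > 1 else 1.0)
    np.fill_diagonal(T, p if K > 1 else 1.0)
    return np.log(T)


def start_probs(config: HMMConfig) -> np.ndarray:
    """Initial state distribution: extra mass on the neutral (ploidy) state
    so the degenerate TF -> 0 regime, where all state means coincide,
    resolves to the neutral path."""
    K = len(config.states)
    states = np.array(config.states, dtype=float)
    neutral = np.flatnonzero(states == config.ploidy)
    if K == 1 or len(neutral) == 0:
        return np.full(K, 1.0 / K)
    p = config.start_neutral_prob
    out = np.full(K, (1.0 - p) / (K - 1))
    out[neutral[0]] = p
    return out


def _log_emissions(x: np.ndarray, n: float, config: HMMConfig,
                   sd: float) -> np.ndarray:
    means = expected_log2_ratio(n, np.array(config.states, float),
                                config.ploidy, config.log2_floor)
    z = (x[:, None] - means[None, :]) / sd
    return -0.5 * z**2 - np.log(sd) - 0.5 * np.log(2.0 * np.pi)


def hmm_loglik(log2s, n: float, phi: float, config: HMMConfig,
               sd: float | None = None) -> float:
    """Forward-algorithm log-likelihood of a bin log2 series."""
    x = np.asarray(log2s, dtype=float)
    if x.size == 0:
        raise ValueError("empty log2 series")
    cfg = config if phi == config.ploidy else HMMConfig(
        states=config.states, restarts=config.restarts, ploidy=phi,
        self_transition=config.self_transition,
        emission_sd=config.emission_sd, max_iter=config.max_iter,
        tol=config.tol, tf_threshold=config.tf_threshold,
        n_bounds=config.n_bounds, log2_floor=config.log2_floor)
    if sd is None:
        sd = cfg.emission_sd if cfg.emission_sd is not None else _robust_sd(x)
    return _forward_ll(x, n, cfg, sd)


@njit(cache=False)
def _forward_ll_kernel(logE, logT, logS):  # pragma: no cover - via wrapper
    T, K = logE.shape
    alpha = np.empty(K)
    tmp = np.empty(K)
    for k in range(K):
        alpha[k] = logS[k] + logE[0, k]
    for t in range(1, T):
        for j in range(K):
            mx = -1e300
            for i in range(K):
                v = alpha[i] + logT[i, j]
                if v > mx:
                    mx = v
            s = 0.0
            for i in range(K):
                s += np.exp(alpha[i] + logT[i, j] - mx)
            tmp[j] = mx + np.log(s) + logE[t, j]
        for j in range(K):
            alpha[j] = tmp[j]
    mx = alpha[0]
    for k in range(1, K):
        if alpha[k] > mx:
            mx = alpha[k]
    s = 0.0
    for k in range(K):
        s += np.exp(alpha[k] - mx)
    return mx + np.log(s)


@njit(cache=False)
def _viterbi_kernel(logE, logT, logS):  # pragma: no cover - via wrapper
    T, K = logE.shape
    delta = np.empty(K)
    tmp = np.empty(K)
    back = np.zeros((T, K), dtype=np.int64)
    for k in range(K):
        delta[k] = logS[k] + logE[0, k]
    for t in range(1, T):
        for j in range(K):
            best = -1e300
            arg = 0
            for i in range(K):
                v = delta[i] + logT[i, j]
                if v > best:
                    best = v
                    arg = i
            tmp[j] = best + logE[t, j]
            back[t, j] = arg
        for j in range(K):
            delta[j] = tmp[j]
    path = np.empty(T, dtype=np.int64)
    best = -1e300
    arg = 0
    for k in range(K):
        if delta[k] > best:
            best = delta[k]
            arg = k
    path[T - 1] = arg
    for t in range(T - 2, -1, -1):
        path[t] = back[t + 1, path[t + 1]]
    return path


def _forward_ll(x, n, config, sd) -> float:
    return float(_forward_ll_kernel(_log_emissions(x, n, config, sd),
                                    _log_transition(config),
                                    np.log(start_probs(config))))


def _viterbi(x, n, config, sd) -> np.ndarray:
    path = _viterbi_kernel(_log_emissions(x, n, config, sd),
                           _log_transition(config),
                           np.log(start_probs(config)))
    return np.array(config.states)[path]


def _robust_sd(x: np.ndarray) -> float:
    mad = np.median(np.abs(x - np.median(x)))
    return max(1.4826 * mad, 0.01)


def _fit_restart(x: np.ndarray, n0: float, config: HMMConfig):
    """Profile-likelihood fit of the normal fraction from one restart.

    Coordinate ascent alternating a bracket search over n (coarse scan of
    the n bounds followed by bounded Brent refinement to 1e-4) with a 1-d
    emission-sd update. The bracket search makes the fit robust to the
    secondary local optima the copy-number likelihood develops near n = 1.
    Returns (n_hat, sd_hat, loglik, converged).
    """
    lo, hi = config.n_bounds
    n = float(np.clip(n0, lo, hi))
    sd = (config.emission_sd if config.emission_sd is not None
          else _robust_sd(x))
    fixed_sd = config.emission_sd is not None
    converged = False
    for _ in range(max(config.max_iter // 10, 2)):
        n_prev, sd_prev = n, sd
        grid = np.unique(np.concatenate([
            np.arange(lo, hi, 0.025), [n, float(np.clip(n0, lo, hi)), hi]]))
        lls = np.array([_forward_ll(x, g, config, sd) for g in grid])
        best = int(np.argmax(lls))
        b_lo = grid[max(best - 1, 0)]
        b_hi = grid[min(best + 1, len(grid) - 1)]
        res = minimize_scalar(lambda nn: -_forward_ll(x, nn, config, sd),
                              bounds=(b_lo, b_hi), method="bounded",
                              options={"xatol": 1e-4})
        n = float(res.x) if -res.fun >= lls[best] else float(grid[best])
        if not fixed_sd:
            res_sd = minimize_scalar(
                lambda s: -_forward_ll(x, n, config, max(s, 1e-3)),
                bounds=(5e-3, max(4.0 * sd, 0.1)), method="bounded",
                options={"xatol": 1e-4})
            sd = max(float(res_sd.x), 1e-3)
        if abs(n - n_prev) < 1e-4 and abs(sd - sd_prev) < 1e-4:
            converged = True
            break
    ll = _forward_ll(x, n, config, sd)
    return n, sd, float(ll), converged


def fit_tumor_fraction(profile: BinProfile,
                       config: HMMConfig | None = None) -> TumorFractionEstimate:
    """Estimate tumor fraction from a corrected bin profile.

    Runs the EM fit from each normal-fraction restart, reports the restart
    table, selects the maximum-likelihood restart and derives TF = 1 - n.
    """
    config = config or HMMConfig()
    un = profile.unmasked
    x = un["log2"].to_numpy(float)
    if x.size == 0:
        raise ValueError("no unmasked bins to fit")
    rows = []
    for n0 in config.restarts:
        n_hat, sd_hat, ll, conv = _fit_restart(x, n0, config)
        rows.append((n0, n_hat, sd_hat, ll, conv))
    table = pd.DataFrame(rows, columns=["restart_n0", "n_hat", "sd_hat",
                                        "loglik", "converged"])
    best = int(table["loglik"].idxmax())
    n_hat = float(table.loc[best, "n_hat"])
    sd_hat = float(table.loc[best, "sd_hat"])
    tf = 1.0 - n_hat
    path = _viterbi(x, n_hat, config, sd_hat)
    return TumorFractionEstimate(
        normal_fraction=n_hat, tumor_fraction=tf, ploidy=config.ploidy,
        restart_table=table, selected_restart=best, state_path=path,
        emission_sd=sd_hat, detected=tf > config.tf_threshold)


def viterbi_segments(profile: BinProfile,
                     estimate: TumorFractionEstimate) -> pd.DataFrame:
    """Merge the MAP state path into copy-number segments.

    Adjacent unmasked bins in the same state and contig are merged; segments
    partition the unmasked bins. Columns: contig, start, end, copy,
    mean_log2, n_bins.
    """
    un = profile.unmasked.reset_index(drop=True)
    path = estimate.state_path
    if len(path) != len(un):
        raise ValueError("state path does not match unmasked bins")
    segs = []
    cur = None
    for i, row in enumerate(un.itertuples()):
        state = int(path[i])
        if cur is not None and cur["contig"] == row.contig and cur["copy"] == state:
            cur["end"] = row.end
            cur["sum_log2"] += row.log2
            cur["n_bins"] += 1
        else:
            if cur is not None:
                segs.append(cur)
            cur = {"contig": row.contig, "start": row.start, "end": row.end,
                   "copy": state, "sum_log2": row.log2, "n_bins": 1}
    if cur is not None:
        segs.append(cur)
    out = pd.DataFrame(segs)
    out["mean_log2"] = out["sum_log2"] / out["n_bins"]
    return out[["contig", "start", "end", "copy", "mean_log2", "n_bins"]]
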