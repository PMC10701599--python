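# Methods

This note documents the models, defaults and numerical choices behind
`fragmentome`, and what the synthetic data generator does and does not
emulate.

## Copy-number and tumor-fraction model

Bin counts from shallow whole-genome cfDNA sequencing are modelled as a
two-component admixture: a fraction *n* of normal (diploid) cfDNA and
1 − *n* of tumor cfDNA whose genome carries segmental integer copy numbers
*c<sub>k</sub>*. With background ploidy φ (fixed at 2), the expected log2
depth ratio of a bin in state *k* is

    m_k(n, φ) = log2( (2n + (1 − n) c_k) / (2n + (1 − n) φ) )

so m = 0 whenever c = φ, a clonal 4-copy gain in a pure tumor is one
doubling, and all states collapse onto 0 as *n* → 1. The c = 0, n = 0
limit (−∞) is floored at −8.

**Preprocessing.** Fragments are counted into fixed-width bins by fragment
midpoint (unambiguous for long fragments straddling a boundary). Counts
are divided by a GC-bias curve obtained by lowess regression of count on
bin GC (frac = 0.3, 2 robustifying iterations); below 200 usable bins the
lowess is replaced by GC-decile median scaling, which is stabler on tiny
bin sets. Corrected counts are divided by bin mappability, log2-scaled
against their median, and, when a panel of normals is given, the per-bin
panel median log2 is subtracted (a sample normalized against itself is
exactly zero). Bins are masked when mappability < 0.9, GC is outside
[0.30, 0.60], or the count is zero; all three bounds are configurable.

**HMM.** Copy-number states {0, 1, 2, 3} (no subclonal states), sticky
transitions with self-transition probability 0.99, Gaussian emissions
N(m_k, σ²). The initial state distribution places probability 0.5 on the
neutral (c = φ) state and splits the rest uniformly: in the degenerate
TF → 0 regime every state mean coincides and the maximum a posteriori path
would otherwise be decided by noise; the neutral-favoring start resolves
that degeneracy toward the diploid labeling, as is conventional for
copy-number HMMs. Forward likelihood and Viterbi decoding run in log space
(numba-compiled kernels).

**Fitting.** The normal fraction is estimated by coordinate ascent of the
profile likelihood: a coarse scan of n over [0.5, 0.99999] (step 0.025)
followed by bounded Brent refinement of the best bracket to 1e-4,
alternated with a one-dimensional update of the emission sd (initialized
at 1.4826·MAD of the log2 series, floored at 0.01, or fixed if supplied),
iterated to joint convergence of 1e-4. This search is run once per
normal-fraction restart value (defaults 0.95, 0.99, 0.995, 0.999); each
restart's (n̂, σ̂, log-likelihood) row is reported and the
maximum-likelihood row is selected, TF = 1 − n̂. Because the scan brackets
the whole admissible range, the restart values do not steer the optimum —
they are retained for the reported restart table and as the entry points
of the search. A plain local ascent from the restart values was tried
first and rejected: the likelihood develops a secondary local optimum
just below n = 1, and restarts at 0.95–0.999 all fall into it,
systematically underestimating TF (0.12 at a simulated truth of 0.20,
with a log-likelihood 20 units below the true optimum). φ re-estimation is
off by default (initial and fixed value 2). A sample is called *detected*
when TF > 0.03; the n search bound of 0.5 caps reportable TF at 0.5.

## Synthetic cfDNA generator

The generator exists so that every analysis can be exercised, and its
estimators validated by parameter recovery, without controlled-access
patient data. It emulates, with defaults chosen once:

- **Fragment sizes.** Plasma: mixture of truncated normals at the
  nucleosomal ladder, modes (167, 334, 501, 668) bp, sds (10, 20, 30, 40)
  bp, weights (0.46, 0.28, 0.16, 0.10) — placing ~53% of fragments above
  300 bp, the scale long-read platforms report for plasma. Urine: a single
  short mode (82, 25) bp, no periodicity. Lengths are truncated to
  [20, 5000] bp. Tumor-labeled fragments subtract (20, 60, 110, 130) bp
  from the four plasma mode means — the mono-nucleosomal 20 bp shortening
  of tumor cfDNA, growing monotonically beyond 100 bp at multi-nucleosome
  scale; the exact multi-nucleosome values are free parameters here since
  only the mono-nucleosome shift and the monotone trend are established.
- **Placement.** Normal fragments land uniformly; tumor fragments land
  with density proportional to local copy number over ploidy, so a copy-c
  segment is oversampled by c/φ. Toy references are random sequences with
  per-window GC varying smoothly inside configurable bounds (defaults
  0.35–0.55, inside the analysis GC mask).
- **End motifs.** The 5′ trinucleotide of every fragment equals the
  reference at its 5′ terminus (reverse-complemented on the minus strand).
  An optional 64-weight bias table is imposed by rejection sampling.
- **TSS-like depletion.** Fragments whose midpoint falls within a
  half-width (default 100 bp) of a declared site are kept with a
  configurable probability (default 0.3) and otherwise re-drawn — a
  thinning mechanism that produces the coverage dip without asserting a
  generative model of nucleosome positioning.
- **Xenograft mixtures.** Graft and host samples are generated on two
  distinct toy references; every read aligns to its own genome at mapq 60
  and a configurable fraction (default 0.1) cross-maps to the other genome
  at a uniformly drawn lower mapq (5–30 by default), keeping origins
  separable by construction.

It does **not** emulate sequencing error or base qualities, adapter
content, duplicate structure, mappability variation (toy references are
uniformly mappable), centromeres or real chromatin. Passing recovery tests
therefore demonstrate correctness of the estimators under the stated
generative assumptions — not performance on real cfDNA, where alignment
artifacts, panel-of-normals quality and biological copy-number complexity
dominate.

## Fragmentomics

Size histograms run over integer lengths 1..5,000 bp; longer fragments go
to an overflow bucket excluded from the density, and median/mode are
computed on in-range lengths. The three size strata — <150 bp, 150–300 bp,
>300 bp (lo-inclusive, hi-exclusive) — partition any fragment set exactly.

End-motif diversity is the Gini index over the 64 trinucleotide
proportions, in mean-absolute-difference form

    G = Σ_i Σ_j |p_i − p_j| / (2 K Σ p),   K = 64,

computed via the sorted-vector identity and verified against the O(K²)
double sum. G = 0 for uniform usage and → 63/64 as mass concentrates on
one motif; it is invariant to count rescaling and category permutation.
Whether an upstream tool's diversity index uses counts, proportions or a
Lorenz-curve estimator is not fixed by this package's sources; the form
above satisfies every comparative use made of it (diversity across size
strata and platforms). Motifs are read from the reference, not the read
bases, so long-read base errors do not contaminate the profile; motifs
containing N and termini within 3 bp of a contig edge are tallied
separately so counts always reconcile.

## Nucleosome profiling

Coverage around each site of a set is accumulated over ±1,000 bp, each
fragment contributing its full aligned span (midpoint-only counting is
available) with weight 1/bias(GC). The fragment-GC bias curve is the
observed fragment-GC distribution divided by the distribution expected
from uniformly placed fragments of the same lengths on the same contigs
(deterministic internal placement), smoothed over 5 GC bins of width 0.02,
floored at 0.05 and normalized to weighted mean 1; with fewer than 1,000
fragments the curve falls back to flat and is flagged low-confidence.
Minus-strand sites are flipped so positive relative positions point
downstream. The aggregate profile is normalized by its own window mean
(mean 1 by construction). "Central coverage" is the mean over ±500 bp —
the window the analyses here summarize — with both the central and window
half-widths configurable. Cross-sample concordance is the Pearson
correlation of per-site central/window coverage ratios over matched site
sets. Site lists arrive as pre-filtered BED; mappability-based site
filtering is upstream of this package.

## Xenograft assignment

A read aligned to both genomes is assigned to the one with strictly
greater primary-alignment mapq; reads below mapq 5 in their winning genome
are unassigned. Equal mapq is called *ambiguous* and excluded from both
genomes — a deliberate choice: per-read origin is unique, and keeping ties
on both sides would double-count them. Tie counts are reported.

## Orchestration and determinism

The pipeline runs ingest → copy number → fragmentomics → nucleosome
profiling, records per-stage status and wall times (informational only,
never asserted), and emits one JSON report plus TSV artifacts. Every
stochastic step takes a seed; child seeds are spawned from a single root
seed via `numpy` SeedSequence, so a fixed configuration reproduces every
numeric output, and simulated FASTA/SAM/TSV files byte-identically. The
limit-of-detection ladder simulates each replicate once at the deepest
depth and downsamples without replacement to the lower depths, mirroring
an in-silico dilution series; at 15% tumor fraction over a 3,000-bin
genome the detection rate is non-increasing in depth reduction.

## Problem sizes used in validation

Recovery and concordance checks run at desk scale, chosen once: toy
genomes of 4–30 Mb with 10 kb bins standing in for a 3 Gb genome at 1 Mb
bins (same bin count, 3,000; similar per-bin counts at the simulated
depths), 800k fragments for tumor-fraction recovery at TF ∈
{0, 0.1, 0.2, 0.4} with a gain and a loss segment per contig, 1M-fragment
pairs at a high-burden truth (TF 0.5, 40% of the genome aberrant) for
bin-level log2 concordance — bin-level Poisson noise, not the estimator,
bounds that correlation, so a strongly aberrant truth is the informative
regime — and 10-replicate depth ladders at 1M/500k/100k/50k fragments.

## Known limitations

- The Gaussian emission model is a simplification of heavier-tailed
  alternatives; outlier bins (real-data artifacts) are handled only by
  masking, not by the emission distribution.
- Tumor fraction is estimated from copy-number displacement alone: a
  genome with no (or balanced, sub-resolution) aberrations yields TF ≈ 0
  regardless of true burden, and reportable TF is capped at 0.5.
- The panel of normals is a per-bin median/dispersion table; no
  centromere/blacklist annotation is built in (masks are configurable).
- Fragment placement, end motifs and depletion are independent in the
  generator; real cfDNA couples them (e.g. size-dependent end-motif
  usage).
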