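# Methods

This note documents the models, conventions and numerical choices behind
`songpath`, in the order data flows through the pipeline.

## Synthetic syllables

Real zebra finch syllables are short harmonic sounds with frequency
sweeps, varying noisiness and sometimes amplitude modulation. The
generator (`songpath.syllables`) emulates exactly these axes: a harmonic
stack whose fundamental sweeps linearly between two endpoints, a
per-harmonic amplitude rolloff, a broadband-noise mixing fraction (both
components normalized to unit RMS before mixing), optional sinusoidal AM
(fixed depth 0.9), 5 ms raised-cosine onset/offset ramps to avoid
clicks, and peak normalization to 0.9. Harmonics that would exceed
Nyquist are dropped rather than aliased. Synthesis is a pure function of
(spec, sample rate): the noise seed lives in the spec.

What the generator does **not** emulate: natural micro-jitter of
period, formant-like filtering, reverberation, recording noise, or the
within-type rendition variability of real birds beyond what the
parameter jitter in a stimulus script provides. Tests passing on these
stimuli therefore demonstrate the pipeline's correctness and internal
consistency, not segmentation or clustering performance on field
recordings.

Defaults: 44.1 kHz mono, 16-bit PCM on disk. Acoustic features use
512-sample Hann frames with 75 % overlap — a conventional bioacoustics
trade-off between time and frequency resolution, independent of the
imaging STFT below. Wiener entropy is the mean over frames of
ln(geometric mean / arithmetic mean) of the power spectrum (≤ 0, with 0
iff flat; an all-zero signal gets a −50 sentinel and a warning);
FM is the mean absolute frame-to-frame change of the spectral peak;
goodness of pitch is the peak real-cepstrum magnitude in the 400–1000 Hz
pitch band; AM is the mean absolute derivative of the analytic-signal
envelope. Stimulus-set matching uses standardized median differences
(median gap over IQR-based SD-equivalent, flag threshold 0.5 — a
convention; the threshold is exposed).

## Imaging featurization

Each syllable becomes a 2352-element vector through an image pipeline
chosen for repertoire-scale clustering rather than acoustic fidelity:

1. **STFT**: n_fft = 512, win_length = 256, hop_length = 8, Hann
   window, no center padding (frame count ⌊(N−256)/8⌋+1, 257 frequency
   bins), power in dB, clipped 80 dB below the per-image maximum.
   The clip gives silence a finite floor so the later min–max
   normalization is well defined.
2. **Colormap**: per-image min–max normalization (gain drops out), then
   a continuous piecewise-linear blue→white→red transfer
   (0 → (0,0,1), ½ → (1,1,1), 1 → (1,0,0)), evaluated analytically
   rather than through a quantized lookup table. A constant image maps
   to the midpoint with a warning.
3. **Square canvas**: the time axis is linearly resampled to the
   frequency-axis length, so every syllable occupies a square image
   regardless of duration; rows run high→low frequency as displayed.
4. **Resize + flatten**: bilinear resampling (centered pixel
   coordinates, no antialias filter — at exact 2× decimation this is
   the 2×2 block average) to 28×28 per channel, flattened row-major,
   channel-last. Output always lies in [0,1].

Consequences worth knowing: absolute path-length values depend on these
conventions (colormap interpolation, dB floor, resize kernel) and are
not numerically comparable across differently-conventioned pipelines;
relative comparisons within one pipeline are.

Z-scoring is per pixel column across syllables with the sample SD
(ddof = 1); zero-variance columns are set to 0 and flagged rather than
dropped, keeping the 2352-column contract.

## Embedding, clustering, centroids

The z-scored matrix is projected to 2-D with UMAP (default 15
neighbors, min distance 0.1, fixed seed 42 — all exposed; the neighbor
count shrinks with a warning on small inputs). A PCA fallback
(`method="pca"`) keeps every downstream stage testable and fast without
the manifold step. Clustering is k-means (fixed seed, n_init 10) or
HDBSCAN (`method="density"`, min cluster size 5, noise label −1).
Cluster ids are renumbered by descending size, ties by first occurrence,
so labels are reproducible and row-order invariant up to that
tie-break.

Centroids default to the arithmetic mean of a cluster's coordinates.
A geometric-mean aggregation is also provided because embedding
coordinates are signed where a geometric mean is undefined: coordinates
are shifted per axis so the global minimum sits at +1, the per-axis
geometric mean is taken, and the shift is subtracted back (axes already
positive are used as-is; `shift=False` rejects non-positive input
instead). The arithmetic mean is the default because the shifted
geometric mean depends on the arbitrary shift. Density-method noise
points join no centroid and therefore never enter the path length.

`stability_report` re-embeds the matrix under several seeds, recomputes
each bird's path length, and reports the seed-by-bird table plus
pairwise Spearman rank correlations — the operational check that the
complexity *ranking* of birds survives embedding stochasticity.

## Path length

The song score is the **minimum** total centroid-to-centroid distance
over orderings of all k clusters — the shortest *open* Hamiltonian path
(no return to start), with all per-order lengths available for k ≤ 8.
Two exact solvers: exhaustive enumeration over the k!/2
reversal-distinct orders for k ≤ 8, and a Held–Karp dynamic program
(states = subset × endpoint, O(2ᵏ k²)) for k ≤ 15; they are asserted
equal on the overlapping range against the brute-force oracle. Ties are
broken by the lexicographically smallest optimal order (both directions
compete), with a 10⁻⁹ relative tolerance for tie detection. k > 15 is
refused rather than approximated — exact computation is the point of
the metric, and 15 clusters already exceeds any observed repertoire
here. Metrics: Euclidean, cosine (1 − cosine similarity; zero vectors
rejected), Manhattan, Chebyshev.

## Choice experiment

The simulator mirrors the operant design: a 10-min silent baseline,
a 30-min playback phase (2 s perch dwell + ~1 s stimulus + 5 s
inter-trial interval, so ~120 trials fit with headroom), and a 10-min
silent post phase. Playback choices are Bernoulli in the long-path
perch with log-odds μ + b, b ~ Normal(0, σ_bird); silent-phase perch
landings follow a separate side-bias log-odds (default 0), so a phase
effect is simulated by offsetting the two. Side assignment and session
order are counterbalanced across birds. Interruptions are flagged with
configurable probability and **count as choices by default** — the
perch trigger is the choice; a flag excludes them. Logs round-trip
losslessly through a flat CSV.

The baseline screen is a three-stage state machine on (left, right)
trigger counts with threshold max-side ratio ≥ 0.80 (equality
triggers): biased first baseline → rerun; same-side bias again →
retest later; same-side bias on retest → exclude; any stage that breaks
the streak → pass. It is invariant to left/right relabeling.

### Hierarchical Bayesian logistic model

choice (1 = long-path side) ~ μ + Xβ + bird intercepts
[+ stimulus intercepts], binomial likelihood with logit link, fit on
playback-phase triggers by default; when phase enters as a fixed
effect, silent-phase triggers are coded against the session's long-path
side. Priors: Normal(0, 1.5) on μ and fixed effects (weakly
informative on the probability scale, and proper enough to handle
complete separation), half-Normal(1) on random-effect SDs, non-centered
bird/stimulus effects.

Sampling is affine-invariant ensemble MCMC (emcee) with
differential-evolution moves — the default stretch move mixes too
slowly in this ~25-dimensional posterior — 48 walkers, 20 000 steps
(5 000 burn-in, thinned by 5) by default, reaching split-R̂ < 1.01
(computed over walker chains via arviz) in ~15–20 s on one core; the
threshold is configurable and violations are *flagged*, never silently
discarded. The likelihood is evaluated on trials aggregated into
binomial cells per (bird × covariate pattern × stimulus), which is
exact and fast. For LOO, per-trial Bernoulli log-likelihoods are
computed on ~1 000 thinned draws and scored with Pareto-smoothed
importance sampling (arviz); `compare_models` fits all candidates on
identical rows (differing subsets are rejected) and flags models within
one SE of the best as indistinguishable.

## Design analysis

With true effect A = ln(pr/(1−pr)), standard error s, λ = A/s and z*
the two-sided critical value: power = Φ(λ−z*) + Φ(−λ−z*); Type S is
the wrong-sign share of that probability; Type M is
E[|λ+Z| · 1{|λ+Z|>z*}]/(power·λ), evaluated with truncated-normal
closed forms (quadrature under an optional t reference). A seeded
Monte-Carlo mode is the independent oracle. At A = 0, power = α,
Type S = ½ and Type M is reported as undefined. The default s = 0.22
is the pessimistic (maximum) simulated standard error for the 22-bird ×
~120-trial design; at that value pr = 0.60 gives power 0.454 and
Type M 1.47 — note 1.47, not 1.4: the closed form is reported at full
precision even where a looser rounding circulates.

`se_distribution` simulates the SE the design can expect: per scenario,
bird intercepts ~ Normal(0, σ_bird = 0.5) and per-session deviations
~ Normal(0, σ_slope = 0.25) (assumed values, exposed in the signature)
generate hierarchical binomial data, and the population-effect SE is
estimated by an intercept-only logistic MLE with a cluster-robust
(per-bird) sandwich variance — a fast, documented stand-in for
refitting the full hierarchical model 10⁴ times. With both variance
components zero it reproduces the pooled-binomial closed form
√(1/(N p(1−p))) within sampling error.

## Problem sizes used in the test suite

Tests run the pipeline at desk scale as a matter of design: 60-syllable
feature matrices for embedding/clustering, 25 random centroid sets per
metric for the solver cross-check, and 20 replicate 22 × 120 simulated
experiments with shortened chains (6 000 steps) for parameter recovery —
at that length the point estimates are stable while the strict R̂
threshold may still flag, which the recovery test tolerates knowingly.

## Known limitations

- Absolute path lengths are convention-dependent (see above); only
  within-pipeline comparisons are meaningful.
- UMAP determinism is per (seed, library version); stability across
  versions is what `stability_report` is for.
- The geometric-mean centroid depends on its shift convention; prefer
  the arithmetic default unless reproducing a geometric-mean analysis.
- The SE simulator's variance components are assumptions, not
  estimates; its min/mean/max summarize those assumptions only.
- Ensemble MCMC walker chains are interacting, so walker-wise split-R̂
  is a conservative but imperfect diagnostic; the configurable
  threshold and the reported value let callers decide.
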