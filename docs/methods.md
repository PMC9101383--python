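# Methods

This note documents the models, conventions and design choices behind
`soundscapemap`: what each stage computes, which knobs matter, what the
synthetic soundscape generator does and does not emulate, and where the
numerically delicate spots are.

## Spectrogram substrate

Every index is computed from one common substrate: a linear-magnitude
short-time Fourier transform with non-overlapping windows. With a
window of `N` samples at sampling rate `fs`, the frequency resolution is
`FR = fs / N` and the time resolution `TR = N / fs`, so `FR * TR = 1`
exactly. The defaults (`fs = 48 kHz`, `N = 1024`) give `FR = 46.875 Hz`
and `TR ≈ 21.3 ms`; a 1-second integration window then spans
`J = floor(1 / TR) = 46` frames. Zero overlap is forced by the
`TR = 1/FR` identity; the window function defaults to Hann, with a
rectangular option for closed-form tests (a bin-centred sinusoid under a
rectangular window is a single spectral line). Rows below 100 Hz and
above 24 kHz are masked out before any index is computed (configurable).

Trailing samples that do not fill a window, and trailing frames that do
not fill an integration block, are dropped and logged; frame counts are
conserved otherwise.

## Eco-acoustic indices

Seven per-second indices, each with its own transform on top of the
magnitude substrate:

* **ACI** `= Σ_f Σ_t |A[f,t+1] − A[f,t]| / Σ_t A[f,t]` — relative
  frame-to-frame variation per bin, summed over bins. The per-bin ratio
  is scale-free: per-bin gain changes cancel, steady tones drive the
  ratio toward 0, impulsive content inflates it. Bins with zero total
  amplitude contribute 0. Computed on the whole 1 s block (no
  sub-clumping — integration already happens at 1 s).
* **ADI / AEI** — Shannon entropy (nats) and Gini coefficient of the
  per-band occupancy vector: the fraction of cells per 1 kHz band (up
  to 24 kHz) whose level exceeds −50 dB relative to the block maximum.
  Band width, ceiling and threshold are configurable; note that the
  block-maximum reference makes occupancy — hence ADI/AEI — sensitive
  to whatever the loudest source in the window is.
* **H** — product of the normalized Shannon entropies of the per-frame
  RMS envelope (temporal) and the frame-averaged spectrum (spectral),
  in [0, 1]. Computed from the STFT envelope rather than a
  sample-level analytic envelope so that all indices share one
  substrate; this diverges slightly from implementations that use the
  Hilbert envelope.
* **BI** — cells are converted to dB re the block maximum, averaged
  over frames into a mean dB spectrum, restricted to the biophony band
  (default 1–8 kHz), min-referenced within the band and summed times
  the bin width in kHz.
* **NDSI** `= (B − A)/(B + A)` on summed squared magnitudes in a
  biophony band (default 1–8 kHz) and an anthrophony band (default
  0.1–1 kHz). The 1 kHz boundary (rather than the conventional 2 kHz)
  reflects environments where low-frequency traffic noise spills
  upward and where common birds (corvids, pigeons) call below 2 kHz.
  The anthrophony band's lower edge (100 Hz) is this package's choice.
* **DSC** — per-frame amplitude-weighted mean frequency, averaged over
  frames with nonzero energy, reported in kHz ("dynamic": the centroid
  is taken per frame, then averaged; the centroid-of-mean-spectrum
  variant is available).

All-silent windows yield flagged zeros rather than raising, so long
unattended recordings never abort; flags propagate into the tidy CSV.

When broadband technophony contaminates the biophony band, BI and NDSI
lose their meaning; the standard fallback is the five-index set
{ACI, ADI, AEI, H, DSC}.

Published ADI values from field studies often exceed the `ln(bands)`
ceiling implied by the standard 1 kHz-band formulation, because the band
structure and threshold conventions differ between toolchains. The band
layout here is explicit configuration; no attempt is made to reproduce
any particular published magnitude.

## Descriptors and the feature matrix

Each index series is summarized by mean, median, mode, sample (n−1)
standard deviation, interquartile range (linear-interpolation
quantiles), and the biased moment coefficients g1 (skewness) and g2
(excess kurtosis). The mode of a continuous series is the midpoint of
the fullest histogram bin, with the Freedman–Diaconis bin width; the FD
rule degenerates under heavy ties (IQR → 0 while the range stays wide),
in which case Sturges' rule is used, and the bin count is capped at
1000. Constant series return 0 for all spread/shape descriptors by
convention. Features are laid out index-major (`ACI_mean … DSC_kurtosis`):
16 sites × 7 indices × 7 descriptors = 16 × 49, or 16 × 35 for the
five-index set.

## PCA, retention and contributions

Features mix units (nats, kHz, Gini fractions), so PCA standardizes by
default, i.e. eigendecomposes the correlation matrix; eigenvalues then
sum to the number of features. Eigenvector signs are fixed by making
the largest-magnitude loading positive, which together with
lowest-index tie-breaking everywhere makes runs bit-reproducible.
Dimensions are retained by the smallest `d` whose cumulative explained
variance reaches a target (default 78%); a Kaiser eigenvalue-above-1
rule and the union of both are available. The default is 78% rather
than a round 80% so that a profile like 54.1 + 15.8 + 8.3 = 78.2%
retains three dimensions under its own rule. Per-feature contributions
to a dimension are squared loadings normalized to 100% per column;
index-level contributions sum the seven descriptors of each index.

## Clustering

Four algorithms under the Euclidean metric on the retained PCA scores:

* **k-means** — scikit-learn, k-means++ initialization, 25 restarts,
  fixed seed.
* **Ward** — scipy agglomerative linkage cut at k.
* **PAM** — deterministic BUILD seeding plus best-single-swap
  iterations to convergence (implemented here; no maintained PAM
  exists in the scientific Python stack).
* **DIANA** — divisive analysis: repeatedly split the cluster with the
  largest diameter by seeding a splinter with the observation of
  maximal average dissimilarity and migrating points while their mean
  distance to the splinter is smaller than to the remainder
  (implemented here; cross-checked against the R reference
  implementation on small instances).

Labels are 1..k in order of first occurrence. Internal validation
follows the clValid trio: mean silhouette, Dunn index (min inter-cluster
distance / max intra-cluster diameter), and connectivity (Σ over points
and neighbour ranks j = 1..L of 1/j for each j-th nearest neighbour
outside the point's cluster; lower is better). All-singleton solutions
have no defined silhouette and are reported as 0 with a flag.
Visualization uses classical (Torgerson) MDS: double-centre −D²/2,
eigendecompose, scale the top eigenvectors by √eigenvalue; negative
eigenvalues are clamped to zero.

## Between-cluster tests

Small per-cluster samples and non-normal descriptor distributions (the
Shapiro–Wilk gate is provided) call for rank tests: two-sided
Wilcoxon–Mann–Whitney for two clusters, Kruskal–Wallis (tie-corrected,
chi-square reference) for three or more. WMW uses the exact null
distribution when the pooled sample is ≤ 20 without ties — the regime
of a 16-site study split 7/8 — and otherwise the normal approximation
with tie and continuity corrections. p-values are reported raw per
index at α = 0.05; a Holm option exists but is off by default, matching
the reporting convention of the surveys this mirrors. An index whose
values are identical at every site is flagged and skipped (both rank
tests are degenerate under total ties); a singleton cluster alone does
not trigger the skip.

## Sensor QC

A fleet of low-cost recorders is screened by exposing each unit to the
same white noise and comparing the ACI of the recordings: units within
3% (relative) of the fleet centre are kept, in a single pass. Because
the per-bin ACI ratio is scale-free the screen is invariant to common
gain rescaling — and, by the same token, *blind to amplitude faults*:
mis-gain and even severe clipping shift the white-noise ACI by well
under 1%. What it does catch is temporal-structure faults: steady
tonal contamination (supply whine) depresses the ratio, impulsive
glitches inflate it. The centre statistic is selectable: the mean
matches the simplest convention, but a minority of faulty units with an
asymmetric fault mix can pull the mean's 3% band off the healthy
cluster entirely, so the median is recommended (and used in the
acceptance fixture). QC spectra use a 512-point transform, independent
of the 1024-point analysis setting.

## Synthetic soundscape generator

The generator renders seeded per-site scenes with the statistical
structure the analysis assumes — a park parcel bordered by a highway:

* **Traffic bed**: Gaussian noise through a 6th-order 400 Hz Butterworth
  low-pass (≥ 90% of power below 1 kHz), RMS-scaled to a dBFS level.
  At study level the highway is a **line source**, so received level
  decays cylindrically at 10 dB per decade of road distance from a
  −12 dBFS @ 10 m reference; `render_site`'s default for an isolated
  point source is the inverse-distance law (20 dB/decade, −6.02 dB per
  doubling).
* **Bird chirps**: a Poisson stream (events/minute) of 0.1–1.0 s linear
  FM tones inside 1.5–8 kHz with Hann envelopes and random amplitudes.
  The spatial pattern is a **road-effect zone**: songbird activity is
  depressed in the near strip (8 chirps/min up to the median road
  distance) and recovers in the interior (60 chirps/min beyond it) — a
  step, not a linear gradient, reflecting the threshold response of
  breeding-bird density to road proximity. This step is the planted
  two-group structure the clustering is asked to recover.
* **Construction beeps**: 0.3 s pulsed ~1 kHz alarm bursts with 2nd/3rd
  harmonics, heard at near-strip sites (30/min), received level
  decaying with road distance like the traffic.
* **Take-off transients**: noise with a −12 dB/octave tilt above 800 Hz
  under a rise–hold–decay envelope — loud, low-frequency-dominated
  events that depress band-occupancy diversity (ADI) and drag the
  spectral centroid (DSC) down while leaving ACI nearly unchanged.
* **Sensor self-noise**: every rendered site includes a −55 dBFS white
  noise floor. This matters: with digital silence in signal-free bins,
  ACI becomes sensitive to the signal-to-leakage ratio and tracks
  traffic level; with a realistic floor, signal-free bins behave
  identically across sites and ACI is stable, as observed in field
  data.
* **Ground truth**: the near/far median split of road distance
  (8 + 8 sites on a 4 × 4 grid spanning 40–130 m behind a road buffer
  strip), written with every component parameter to `truth.csv`.

Scenes default to 60 s per site — desk scale; field sessions of
several hours shrink descriptor sampling noise by √T but do not change
the planted geometry. A `traffic_gradient_only` switch plants the
traffic-level gradient alone (constant chirp rate, no beeps) to test
which indices respond to pure level differences: the evenness indices
(ADI, AEI, H) separate the resulting clusters, while ACI — blind to
stationary level — does not.

What the generator does **not** emulate: species-specific song
structure, propagation with diffraction and wind/temperature gradients,
geophony (available as an option but off by default), recorder
directivity, and diurnal nonstationarity. Passing tests therefore show
that the pipeline recovers planted level/occupancy/rate structure from
audio, not that any particular field study's numbers are reproducible.

## Numerical conventions

Zero denominators yield flagged zeros (NDSI, DSC, band occupancy) or
contribute nothing (ACI bins); dB conversions floor at −120 dB re block
max to avoid −inf; 0·ln 0 := 0 throughout; ties break toward the lowest
index (histogram mode bin, DIANA splinter seed, cluster relabeling);
k-means randomness is confined to its seeded initialization. The
acceptance script derives every seed from its `--seed` argument.

## Problem sizes in the shipped checks

The test-suite and acceptance-script simulations use 16 sites × 60 s,
20 study replicates for recovery rates, 10 for test-direction rates,
2000 replicates for type-I-error calibration, and a 46-unit fleet with
24 planted faults — sizes chosen so the full analysis remains a
minutes-scale desk computation while keeping Monte-Carlo standard
errors a few times smaller than the tolerances being checked.
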