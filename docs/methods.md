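# Methods

## The clock model

The engine integrates any model given declaratively as species, rate
constants, and one right-hand-side expression per species (JSON on disk,
parsed with sympy and compiled once).  Four species tags (`per2_mrna`,
`bmal1_mrna`, `bmal1_clock_unphospho`, `phospho_bmal1_clock_nuclear`) and
one rate tag (`k_phos`) connect an arbitrary model to the analyses.  A full
published parameterization of the detailed mammalian clock can be supplied
through this interface; the repository deliberately does not transcribe
one.

The bundled default is a 7-state reduced model with the interlocked
negative/positive feedback architecture of Becker-Weimann et al. (2004):
active (phosphorylated) nuclear BMAL1:CLOCK drives *Per2/Cry* transcription;
nuclear PER2/CRY both represses its own transcription and activates *Bmal1*,
giving the observed *Per2*/*Bmal1* antiphase; BMAL1 protein passes through
cytoplasmic, nuclear-unphosphorylated and nuclear-phosphorylated pools, the
last conversion governed by `k_phos`.  All parameters are the published
ones except `k_phos` (their k6a = 0.09/h), which is set to **0.3/h**.
Rationale: with the slower published value, the unphosphorylated nuclear
pool is large and drains slowly, so the maximal phospho-BMAL1:CLOCK
induction under a rate-increase protocol keeps growing with protocol
duration (44% spread across 0.2–8 h).  At 0.3/h the pool drains within
minutes of a strong stimulus and the induction maximum is nearly
duration-independent (≈3.5% spread across 0.2–8 h), the qualitative
behavior of the detailed model this pipeline targets, while the limit cycle
(period 23.50 h, well inside the circadian 22–26 h band) and all amplitudes
are essentially unchanged.  This constant was fixed from the
duration-insensitivity analysis alone, before any downstream result was
produced, and is not revisited.

A consequence worth stating plainly: in this reduced model the baseline
phosphorylation flux is already fast, so a 15-fold rate increase raises the
phospho maximum by only ~1–2% and shifts *Per2* by at most ~1.6 h. The
*structure* of the response — monotone in factor, flat in duration,
CT-dependent with delay and advance lobes, suppressed when the rate is
zeroed — is the object of study here; absolute induction amplitudes of the
detailed 181-variable model are not reproduced at this scale.

### Protocols, circadian time, phase shifts

* A protocol multiplies `k_phos` by `factor` on `[t_start, t_start+d)`;
  integration is split exactly at the window boundaries so the solver never
  steps across a discontinuity (LSODA, rtol 1e-8, atol 1e-10, output every
  0.05 h).  A smooth half-sine `pulse` shape is available; on the default
  model it behaves like the constant multiplier, which is the default.
* Circadian time 0 is the *Bmal1* mRNA peak on the converged limit cycle
  (found by peak-interval convergence after a 400-h transient, verified by
  one-period state recurrence).  Protocol onsets are therefore circadian
  times directly.
* Phase shift Δφ: *Per2* mRNA peak times (parabolically interpolated) of
  the perturbed run are compared with the unperturbed reference on the last
  three matched cycles, skipping two full cycles after protocol end;
  the mean circular difference is wrapped into (−τ/2, τ/2], **positive =
  advance**.  The cosinor fit offers an alternative phase estimate for
  external traces; peak comparison is used for model trajectories because
  it needs no waveform assumption.
* Fold change = max(perturbed)/max(unperturbed) of a species over the 24 h
  window from protocol onset — the ratio of maximum induction levels, which
  makes the no-op protocol give exactly 1.  Dividing instead by the
  unperturbed level at the onset instant is available
  (`baseline="onset"`) but conflates induction with the species' own cycle.

## Fixed-cell N/C quantification

Nuclei: Otsu threshold on a Gaussian-smoothed (σ = 1 px) nuclear-stain
channel, connected components, minimum area 50 px; fixed-threshold and
external-mask routes exist, and an optional distance-transform watershed
splits touching nuclei (off by default).  Cytoplasm: each nucleus dilated
outward by 3 px (`expand_labels`, which assigns contested pixels to the
nearest nucleus — deterministic), minus all nuclei.  Per cell and channel
the table reports mean nuclear intensity, mean ring intensity and their
ratio; cells whose ring is empty or clipped by the image border are flagged
(`no_cytoplasm`, `edge`) and retained in the table rather than dropped.
"Average" is the arithmetic mean and no background subtraction is applied;
both choices are stated rather than inherited from any instrument.

## Tracking and the positive-rate rule

Linking is greedy nearest-centroid with a hard displacement cap: matches
are taken in globally ascending distance order, anything beyond `max_disp`
starts a new track (identities are never swapped across a jump).  Relative
nuclear intensity is summed nuclear / summed whole-cell reporter intensity,
with zero-denominator frames marked missing.  The positive rate thresholds
each treated cell's maximum post-stimulus fold change (baseline = mean of
all pre-stimulus frames) at the linearly interpolated (type-7) 75th
percentile of the control distribution, counting strictly-above as
positive — so a tie-free control scored against itself yields exactly 25%.
Note the rule's arithmetic: with true responder fraction p and a strong
response, the expected measured rate is p + 0.25(1−p) (≈0.85 at p = 0.8),
since a quarter of non-responders land above the control quantile by
construction; measured rates on rendered datasets come out at 80–85%.

## Synchrony networks

The graphical lasso (scikit-learn's solver) is fit at the fixed penalty
ρ = 0.013 to the cells' series, **centered per cell but not variance
scaled**.  This departs from the more common z-scoring deliberately: on
standardized series with ~40 frames, sampling noise in correlations (~0.16)
dwarfs ρ and the fitted network is near-complete regardless of condition,
erasing the local/global contrast.  On the natural relative-nuclear-
intensity scale (per-cell variances ~1e-3 to 1e-2) the same ρ is genuinely
selective: pure-noise populations give empty networks, stimulated ones give
sparse structured networks.  `standardize=True` restores z-scoring when the
input is not on that scale.

Every fit is verified against the stationarity (KKT) conditions of the
off-diagonal-penalized objective, computed independently of the solver:
W − S must equal ρ·sign(Θ) on nonzero off-diagonals, stay within ρ on zero
ones, and match on the diagonal.  A near-singular covariance (perfectly
synchronous cells) is retried along a fixed diagonal-jitter ladder
(1e-6 … 5e-2) with a warning; failure of the whole ladder is an error, not
a silent result.  Edges are off-diagonal precision entries above 1e-8 in
magnitude.  Neighbors are Delaunay edges (Qhull) of per-track mean
positions; co-circular degeneracies resolve deterministically for identical
input.  The expanding-window time course recomputes the network on [0, t]
per evaluation time (minimum 3 frames; shorter windows are reported as
unavailable) against the fixed neighbor graph.

## Rhythm analysis

The 24-h moving average uses a trapezoidal kernel (half-weight endpoints)
spanning exactly one window: it annihilates a cosine at the window period
*and* any linear trend exactly, which a plain even-length boxcar does not
(half-sample phase offset).  Half-windows at the edges are dropped, never
padded.  The periodogram is the normalized least-squares (Lomb–Scargle)
power on a 512-point period grid over 18–30 h; the false-alarm probability
uses the Beta(1,(N−3)/2) null of the single-frequency power with a
Bonferroni-style correction over the grid — standard, slightly
conservative.  The cosinor is exact linear least squares on {1, cos, sin}
at fixed τ; when τ is free, the periodogram peak seeds a ±2-h grid at
0.01-h steps and the residual sum of squares picks the period.  Acrophase
is the time of the fitted maximum on the trace's own time axis mod τ, so
pre/post-event fits on one record are directly comparable; phase shifts
between fits are circular differences in (−τ/2, τ/2].  Damping is not
modeled (single-component, undamped cosinor); on damped traces the fitted
amplitude is an effective average over the record.

## Synthetic data: what it does and does not emulate

* **Fixed-cell images**: non-overlapping cells as concentric disks —
  cytoplasm at intensity c, nucleus at r·c with r the prescribed N/C ratio —
  plus additive Gaussian noise (a Poisson option is unnecessary for the
  recovery tests and omitted).  Rejection-sampled placement; impossible
  densities raise an error.  No point-spread function, shading, or
  out-of-focus light: recovery tests validate the measurement arithmetic
  and masks, not robustness to optics.
* **Time-lapse datasets**: 80 cells (within the 63–135 per-arm range of the
  motivating experiments), 41 frames at 3 min, stimulus at 30 min,
  responder fraction 0.8; responders rise sigmoidally from baseline
  U(0.35, 0.45) by amplitude U(0.25, 0.45) with latency mean 30 min, SD
  35 min and 5-min rise time; additive noise SD 0.04 on the ratio.  With
  spatial correlation on, latencies come from Gaussian-smoothed white noise
  (σ = 12 on a 64-grid over the 500-px field) so neighbors share response
  timing; off, latencies are i.i.d. with the same marginal spread.
  Rendered stacks place r·I_tot in the nucleus and the rest in the
  cytoplasmic annulus so perfect segmentation recovers r exactly.  No
  mitosis, cell death, or track fragmentation.
* **Traces**: mesor + linear trend + exponentially damped cosine
  (τ = 24.4 h, 10-min sampling) + Gaussian noise; a phase-shift event
  re-anchors the acrophase from the event time onward.

One seed fully determines each dataset (independent spawned sub-streams per
component), so generated fixtures are bit-reproducible.

Problem sizes throughout (200-cell tracking runs, 40 seed pairs for the
synchrony contrast, 10 datasets for rate recovery, 20 random instances for
the stationarity audit) were chosen to give stable statistics at desk
scale; they are package defaults, not measurement limits.

## Known limitations

* Reduced-model induction amplitudes are compressed (see above); only the
  response structure transfers to detailed parameterizations.
* The Dex-15h experimental condition is mapped to protocol onset CT 15
  (hours after the CT0 anchor); an explicit entrainment simulation of the
  pre-synchronizing stimulus is not performed.
* The tracker has no gap closing or lineage handling; it is a contract
  implementation for synthetic data and pre-tracked tables, not a
  replacement for dedicated segmentation/tracking tools, which plug in via
  the label-stack interface.
* ρ = 0.013 is adopted as given; no stability selection over the penalty is
  performed, and the local/global indices inherit its arbitrariness.
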