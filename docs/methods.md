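# Methods

## Model and analysis chain

A trial's activation matrix M (m muscles × t samples, non-negative) is
modelled as M = W C + E with non-negative factors: W (m × n) holds the
muscle synergies as unit-norm columns, C (n × t) the neural commands, and
n < m. The chain is: preprocess raw EMG → factorize each trial → align
synergy ordering across trials → compute the stability and size indices →
regress indices against balance scores or training sessions.

### Preprocessing

Raw EMG is full-wave rectified, low-pass filtered, normalized, and windowed.

- **Filter**: 4th-order Butterworth, 32 Hz cutoff, applied forward–backward
  (`scipy.signal.sosfiltfilt`). Zero-phase filtering is used so the envelope
  is not delayed: the analysis window is placed relative to the perturbation
  trigger and a causal filter's group delay would shift response content out
  of it. Order and cutoff are configurable. The filtered envelope is clipped
  at zero before normalization because zero-phase filtering of a rectified
  signal rings slightly negative.
- **Normalization**: each muscle is divided by its maximum processed
  amplitude over *all* trials of the experiment, so the per-muscle maximum
  over the set is 1 and amplitudes are comparable across muscles. An
  alternative reference — the mean across trials of per-trial maxima — is
  selectable (`mode="mean-of-maxima"`); with it, entries may exceed 1 on the
  strongest trial. A muscle that is identically zero in every trial raises
  an error rather than dividing by zero.
- **Window**: t = round(duration · rate / 1000) samples from the half-open
  interval starting `latency_ms` after the trigger. Defaults 40 ms latency
  and 160 ms duration capture the initial APR burst at 1 kHz (t = 160).
  A fixed latency is used rather than a per-trial onset detector; the
  latency is a config parameter.

### Factorization

- **Algorithm**: Lee–Seung multiplicative updates for the squared Frobenius
  objective. Update denominators are floored at 1e-12; with strictly
  positive uniform-(0,1] initialization the iterates stay positive and the
  residual is non-increasing.
- **Restarts**: NMF is non-convex, so the fit is restarted from
  `restarts` (default 20) independent random initializations and the
  restart with the highest similarity L is kept. Seeding uses
  `numpy.random.SeedSequence` spawning, so results are bit-reproducible.
- **Convergence**: stop when the relative residual decrease per iteration
  falls below 1e-6, or after 2000 iterations.
- **Normalization**: after fitting, each column of W is scaled to unit
  Euclidean norm and the matching row of C by the inverse factor, leaving
  W C unchanged.
- **Similarity L** = 100 · (1 − (1/m) Σᵢ mean_j E²ᵢⱼ / mean_j M′²ᵢⱼ) with
  M′ = W C: each muscle's residual power is weighed against that muscle's
  *reconstructed* power (the denominator is M′, not M), so one poorly
  reconstructed muscle lowers L regardless of its amplitude. L = 100 iff
  E = 0; a muscle row of M′ that is identically zero makes the ratio
  undefined and raises an error.
- **Dimension selection**: the smallest n in 1..m−1 whose best-of-restarts
  L exceeds the threshold (default 75). If none qualifies, n = m − 1 is
  reported with a flag. At the participant level the common dimension is
  the smallest n whose L exceeds the threshold in *every* analyzed trial —
  the strictest reading, guaranteeing each trial individually meets the fit
  criterion; a mean-L rule would admit trials below threshold. A fixed n
  can be supplied instead (`PipelineConfig(n=2)`).

### Indices

All correlations use the Pearson coefficient written with population
standard deviations (denominator m); this is algebraically identical to the
usual sample formula, and the implementation is cross-checked against
`scipy.stats.pearsonr` in the tests.

- **Matching**: NMF determines W only up to a column permutation, so before
  comparing trials each trial's synergies are re-sorted against the first
  trial (the reference) to the permutation maximizing the summed
  per-synergy correlation — equivalently, the permutation maximizing SSI.
  n is small (2–3), so exact search over all n! orderings is used; ties go
  to the lexicographically smallest permutation for determinism. One
  permutation per trial is applied jointly to W's columns and C's rows,
  keeping the synergy–command pairing coherent. Global joint matching over
  all trials was rejected: with a fixed reference the per-trial exact
  search is already optimal for the pairwise objective at these n, and the
  result does not depend on trial-visit order.
- **SSI** = meanᵢ [ 2/(p(p−1)) Σ_{l<q} r(W_l⁽ⁱ⁾, W_q⁽ⁱ⁾) ]. The pair sum is
  over *unordered* pairs, counted once: only then does an ensemble of
  identical synergy matrices give exactly 1.
- **SSI_c**: the same statistic over command rows C⁽ⁱ⁾.
- **SCI** = 2/(n(n−1)) Σ_{i<j} W⁽ⁱ⁾·W⁽ʲ⁾, requiring unit-norm non-negative
  columns and n ≥ 2; for an ensemble it is reported per trial with mean and
  SD, since each trial has its own W.
- Negative correlations are kept as-is, not clipped: the nominal [0, 1]
  range of SSI/SSI_c presumes matched non-negative synergy vectors, and on
  adversarial input the indices can go negative. A warning is emitted
  instead of clamping so the value still reflects the data.

### Trends

Index-vs-score and index-vs-session relations are summarized by ordinary
least squares (`scipy.stats.linregress`): slope, intercept and Pearson r.
No multiple-testing correction is applied — these are raw descriptive
regressions. Balance scores ({−2, −1, +1, +2}, observer-assigned) are
consumed as data; trials are filtered to one score level (+1 by default,
the hand-raised-but-balanced response) and truncated to the first five
qualifying trials so every participant contributes responses of the same
quality and count.

## Synthetic cohorts

The generator produces trials from the forward model itself:
M = clip₀(perturb(W*, σ_W) · perturb(C*, σ_C) + ε), ε ~ N(0, noise_sd²).

- **W\***: non-negative unit columns with *exactly* equal pairwise angles,
  built as w_i = a·s + b·e_i with a shared random direction s, disjoint
  private coordinates e_i, a = √cos θ and a² + b² = 1, so wᵢ·wⱼ = cos θ for
  every pair and SCI(W*) = cos θ for n = 2. Acute angles need m ≥ n + 1
  coordinates; θ = 90° needs m ≥ n.
- **C\***: one Gaussian burst per synergy with staggered centers (over the
  middle 60% of the window), random width (6–12% of t) and amplitude
  (0.6–1.0), mimicking the staggered agonist bursts of a posture response.
- **Perturbations**: additive truncated Gaussians; the perturbed W is
  re-normalized to unit columns, so σ_W moves synergy *directions* (what
  SSI measures), not amplitude. All randomness derives from
  (seed, trial_index), so cohorts regenerate bit-identically.
- **Profiles** (defaults; geometry m=6, n=2, t=160, p=5 trials, matching a
  six-muscle APR montage at 1 kHz):
  - skilled: σ_W = 0.05, σ_C = 0.30, θ = 40°, noise 0.02 — stable, small
    synergy space, variable commands.
  - unskilled: σ_W = 0.35, σ_C = 0.05, θ = 80°, noise 0.02 — wandering,
    large space, stereotyped commands.

  The σ values are set relative to the unit column norms and ~0.6–1.0
  command amplitudes: 0.05 is small against either scale, 0.30–0.35 is a
  large fraction of it; the angles put the two profiles' SCI near 0.77 and
  0.17, bracketing the mid-range default of 60° (SCI 0.5) used for
  profile-neutral fixtures.

### What the generator does and does not emulate

It reproduces the *structure* the indices are defined on — low-rank
non-negative trials with controlled cross-trial synergy drift, command
variability and inter-synergy angle. It does not emulate motor-unit action
potentials, electrode crosstalk, fatigue, trial-to-trial latency jitter, or
platform dynamics. Passing tests therefore demonstrate that the estimation
chain recovers planted structure and orders cohorts correctly under the
model's own assumptions, not that real EMG satisfies those assumptions.

## Numerical choices and degenerate inputs

- Epsilon floor 1e-12 in NMF update denominators; unit-norm checks at 1e-9
  (decompositions) and 1e-6 (SCI input).
- Constant vectors make Pearson r undefined and raise errors (zero
  variance), as do all-zero synergy columns, all-zero reconstruction rows,
  and muscles that are silent across an entire experiment.
- Half-open sample windows [start, start + t) avoid double-counting edge
  samples.
- SCI is undefined for n = 1; single-synergy participants report SSI/SSI_c
  only.

## Problem sizes

Stochastic checks use the default cohort geometry (6 × 160 trials, 5 per
participant) with 8–10 NMF restarts, 20 replicates for the sign tests on
the skilled/unskilled contrast and the 5-session training schedule, 20
replicates for dimension-selection recovery and 10 for parameter recovery.
These sizes give stable sign-test outcomes at conventional significance
while keeping a full run of the suite under a minute on one core.

## Known limitations

- The fixed-latency window assumes the response latency is constant across
  trials and participants; a per-trial onset detector is out of scope.
- Matching maximizes correlation with the first analyzed trial; if that
  trial's decomposition is an outlier, alignment quality degrades (the
  exhaustive per-trial search is still optimal for the chosen objective).
- Multiplicative-update NMF converges to local optima; restarts mitigate
  but do not eliminate this, and very correlated synergies (θ → 0) are
  intrinsically hard to separate regardless of algorithm.
- CSV with sidecar metadata is the only input format; vendor EMG formats
  and artifact rejection are out of scope.
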