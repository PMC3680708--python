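# Methods

## Event model and conventions

All analyses operate on *pulse-event tables*: tab-separated text with one
row per sonar pulse (`epoch_id`, `bat_id`, `onset_s`, `duration_ms`).
Time is epoch-relative, 0-based, half-open `[0, T)` with T = 10 s by
default. Onsets are seconds; durations and windows are milliseconds at
the I/O surface and converted to seconds internally. Within one emitter,
onsets must be strictly increasing (equal onsets are duplicate rows and
are rejected); simultaneous onsets *across* emitters are legal — they are
precisely the collisions the analysis is about. Files are validated on
read and never silently repaired. Pulse durations default to the 4–8 ms
range typical of free-tailed-bat pulses in a small chamber.

## Solitary emitters

A solitary bat is modelled as a renewal process with mean rate r₀.
Two inter-pulse-interval (IPI) laws are provided:

- `gamma` (default), shape k = 4, mean 1/r₀. Real calling is far more
  regular than Poisson; a gamma with moderate shape captures that
  regularity while staying parameterizable. No IPI distribution is
  identified by the source data, so k = 4 is a modelling choice, chosen
  once as a realistic middle ground between Poisson (k = 1) and clock-like
  (k → ∞) calling.
- `poisson` (exponential IPIs), used wherever closed forms are wanted:
  for independent Poisson trains the expected cross overlap rate is
  2·C(n,2)·r²·τ and the expected clear fraction is e^(−2(n−1)rτ).

Defaults for r₀: 5.0 Hz for naive bats, 1.8 Hz for chamber-habituated
bats. Both are configuration values, not hard-coded constants.

## Mutual suppression

Groups are simulated event-driven. Each bat keeps a next-scheduled
emission time drawn from its own renewal model; when any bat fires, every
other bat *hears* the pulse with probability `hearing_prob` (default 1)
and postpones its next emission. A bat never suppresses itself, and a
refractory floor `min_ipi_ms` (default 20 ms, well below any natural IPI
at ≤ 10 Hz) prevents pathological bursting.

Two postponement semantics are implemented because the behavioural data
constrain only the delay (~80 ms), not its composition rule:

- `restart` (default): a pulse heard at time t pushes the hearer's next
  emission to at least t + δ; a later pulse re-triggers the delay from its
  own time. This is a listen-before-send rule — the bat waits until the
  channel has been quiet for δ.
- `additive`: every heard pulse adds the full δ, so suppression
  accumulates linearly with acoustic density. Under this rule the
  self-consistent per-bat rate is r = 1/(1/r₀ + (n−1)δ), an exact inverse
  first-order curve in group size.

Both rules produce strictly decreasing per-bat rates with group size
(≈ 4.9, 4.5, 3.9, … 1.6 Hz for n = 1…8 at defaults under `restart`);
`additive` suppresses more strongly. The `restart` default follows the
listen-before-send interpretation of the behaviour.

## Noise stimuli and the duty-cycle response

Stimulus schedules are symbolic interval tilings (no waveform synthesis):
a noise burst of `burst_ms` alternating with `silent_ms` of silence,
duty cycle = burst/(burst+silent). The behavioural response switches at a
duty threshold (default 50 %):

- **Below threshold** each burst onset acts like a heard conspecific
  pulse and postpones the next emission by the suppression delay, pulling
  the realized rate below baseline.
- **At or above threshold** the bat treats the noise as continuous and
  its emission rate during noise intervals is multiplied by
  `noise_rate_multiplier` (default 2.3/1.8 ≈ 1.28, the observed
  noise/silence rate ratio in habituated solitary bats). Rate modulation
  is implemented by time-rescaling the renewal process through the
  piecewise-constant intensity, so interval rates are matched in
  expectation (exactly for Poisson IPIs).

Known limitation: with the pure `restart` rule, a below-threshold
stimulus whose period is shorter than the delay (e.g. 10 ms bursts with
40 ms silences, period 50 ms < 80 ms) silences the simulated bat
entirely, whereas real bats only reduce their rates. The simulator is
therefore realistic for low-duty stimuli with period > δ (such as the
10 % duty stimulus) and conservative elsewhere.

## Overlap detection and epoch statistics

An overlap (interference) is an unordered pair of pulses whose onset
difference lies in the half-open window [0, τ); a pair at exactly τ does
not count. τ defaults to 10 ms — the conservatively measured window — with
80 ms as the empirically determined effective alternative. Detection is a
linear sweep over the merged sorted onset sequence, verified in tests
against an O(P²) all-pairs oracle. Chains of ≥ 3 mutually close pulses
count as all constituent pairs; the *clear fraction* counts each pulse
once no matter how many events touch it. Same-emitter pairs are excluded
by default (`cross_only`), since interference is between bats; an
all-pairs mode exists because field recordings often cannot attribute
pulses to individuals. An optional duration-aware mode instead flags any
temporal intersection of [onset, onset+duration] intervals.

Per-epoch statistics report both the pooled rate (total pulses / T) and
the per-bat rate (pooled / n); pooled is the default in fits because pair
recordings typically cannot be attributed per bat. Pulse efficiency is
exposed in both of its conventional forms — the clear fraction
(proportion) and `efficient_rate` = pooled − overlap rate (difference);
the proportion is canonical.

## Cross-pairing null and comparison

The null for pair statistics superposes two solitary epochs — bats that
demonstrably cannot hear each other — preserving every onset exactly.
All C(N, 2) unordered pairings of the given source epochs are always
enumerated (100 sources → 4950 virtual pairs); any sampling of sources is
the caller's responsibility, keeping the construction deterministic.
Ensemble comparison uses two-sided Mann-Whitney U on pooled rate and on
overlap rate (exact enumeration for small tie-free samples, normal
approximation with tie correction otherwise), per-ensemble Pearson
correlation of overlap rate against pooled rate, and the zero-overlap
fractions. Because cross-pairings share source epochs, their statistics
are not mutually independent; the type-I-control test therefore builds
its ensembles from disjoint, freshly generated pairs.

## Channel model

With n emitters at per-bat rate r and window τ, traffic load is
λ = n·r·τ. An unslotted random-access channel gives the collision-free
probability p = e^(−2λ) (a pulse fails if any other onset lands within τ
on either side) and normalized throughput S = λ·e^(−2λ), maximal at
S = 1/(2e) ≈ 18.4 % of capacity when λ = ½. The optimal per-bat rate is
the closed form r\* = 1/(2nτ), cross-checked by golden-section numeric
maximization (tolerance 1e−9 on the bounded search; the two must agree to
1e−6 relative). τ presets: 0.010 s ("measured") and 0.080 s
("effective"). Note one source of quoted optima rounds from a plotted
grid (3.25 and 1.0 Hz for n = 2 and 10 at τ = 80 ms); this package
reports the closed form (3.125 and 0.625 Hz), which coincides with the
quoted values for n = 3 and n = 5 after rounding.

Model efficiency has two modes: the canonical `exponential` mode returns
p = e^(−2λ) (self-consistent, dimensionless, validated against simulated
clear fractions), while `paper_literal` returns 1 − r·τⁿ in the caller's
stated units — the historically printed form, which is not dimensionally
safe and is clamped to [0, 1] with a warning when it escapes that range.
The interference-rate regression is likewise implemented as a general
power law I = c·r^k (fit in log-log space) rather than the literal r·τⁿ,
because the literal form cannot place pairs and triads on one curve with
a fixed τ; the Poisson closed form 2·C(n,2)·r²·τ is provided as the
mechanistic reference, and the fitted c implies an effective window c/2
for pairs.

The inverse group-size regression y = a + b/x is fit by linear least
squares in 1/x; a is the large-group asymptotic rate (Hz), b the solitary
excess (Hz·bats). Noiseless inputs are recovered to machine precision.

## Problem sizes and numerical choices

Test ensembles are sized so that every stochastic assertion has a
comfortable margin at its stated tolerance: 200 simulated epochs per
group size for behavioural direction, 500–2000 epochs for closed-form and
ratio checks (3-standard-error bands), 400 replicates for the 5 %
type-I-control band, 500 replicates for noisy parameter recovery. Seeds
are fixed throughout; every generator is a pure function of its
arguments, and a saved run configuration reproduces event tables
byte-for-byte.

## What the synthetic data does and does not show

The generators emulate the statistical structure the analysis assumes —
renewal pulse timing, an 80 ms suppression delay, duty-cycle-dependent
noise response — not bat acoustics: no waveforms, no spectrograms, no
echoes, no frequency content, no movement. Passing tests demonstrate that
the pipeline's statistics and models behave correctly on data with that
structure; they do not validate the behavioural assumptions themselves,
and empirical quantities measured from real recordings (absolute group
rates, zero-overlap percentages, correlation strengths) are reproduced
here only in direction and order of magnitude, not in value.
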