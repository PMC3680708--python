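# sonarchannel

Tools for studying how group size and mutual acoustic suppression shape
sonar pulse-emission rates in echolocating bats — and why slowing down is
the optimal strategy when many bats share one acoustic channel.

Free-tailed bats postpone their next sonar pulse by roughly 80 ms whenever
they hear a neighbour's pulse. In groups this mutual suppression drives
per-bat emission rates down from ~5 Hz (solitary) toward a ~1 Hz asymptote
as group size grows. `sonarchannel` packages the full analysis chain for
this phenomenon:

- **Synthetic pulse trains** — renewal-process solitary emitters, an
  event-driven simulator of mutually suppressing groups, and periodic
  noise-burst stimuli with the observed behavioural response (brief bursts
  suppress, quasi-continuous noise at duty cycle ≥ 50 % facilitates).
- **Interference statistics** — overlap detection between pulse onsets
  within a window τ (10 ms measured, 80 ms effective), per-epoch rates,
  and pulse efficiency (the fraction of pulses free of overlaps).
- **Cross-pairing Monte Carlo null** — superpose all C(N, 2) unordered
  pairs of independently recorded solitary epochs (100 epochs → 4950
  virtual pairs) to get the chance-level overlap distribution, and compare
  a real or simulated ensemble against it with rank tests.
- **Shared-channel model** — pure-ALOHA mathematics for the acoustic
  channel. With n bats at rate r (Hz) and window τ (s), traffic load is
  λ = n·r·τ, the collision-free probability is p = e^(−2λ), and normalized
  throughput S = λ·e^(−2λ) peaks at 1/(2e) ≈ 18.4 % of capacity when
  λ = 1/2. The throughput-optimal per-bat rate is therefore
  r\* = 1/(2·n·τ) — 1.25 Hz/bat for five bats at τ = 80 ms, close to
  observed group rates. Regression helpers fit the inverse group-size
  curve y = a + b/x and the overlap-rate power law I = c·r^k.

## Worked example

`examples/` holds one short script per capability. Group suppression and
the channel optimum together tell the core story:

```sh
$ python examples/02_group_suppression.py
n=1: per-bat rate 4.94 Hz
n=2: per-bat rate 4.53 Hz
n=3: per-bat rate 3.87 Hz
n=4: per-bat rate 3.14 Hz
n=5: per-bat rate 2.53 Hz
n=6: per-bat rate 2.12 Hz
n=7: per-bat rate 1.81 Hz
n=8: per-bat rate 1.59 Hz
inverse fit: y = 1.79 + 3.74/x  (R^2 = 0.754)
```

Each line is the mean per-bat emission rate over 100 simulated 10-s
epochs: a solitary bat calls at its ~5 Hz baseline, and every added
neighbour suppresses it further. The fitted inverse curve summarizes the
decline (`a` = large-group asymptote, `b/x` = solitary excess).

```sh
$ python examples/05_channel_model.py
peak throughput S_max = 0.1839 (18.4 % of capacity) at load lambda = 0.500
n= 2: optimal rate 3.125 Hz/bat (efficiency at optimum 0.368)
n= 3: optimal rate 2.083 Hz/bat (efficiency at optimum 0.368)
n= 5: optimal rate 1.250 Hz/bat (efficiency at optimum 0.368)
n=10: optimal rate 0.625 Hz/bat (efficiency at optimum 0.368)
```

The channel peaks at the same 18.4 % of capacity for every group size, but
the per-bat rate that achieves it falls as 1/n: larger groups should call
more slowly, which is exactly what the suppression behaviour produces.

A `sonarchannel` command-line tool wraps the same functions
(`simulate`, `overlaps`, `null`, `compare`, `model`, `fit`, `demo`);
subcommands compose through TSV event tables and stats files. `demo` runs
the whole pipeline from one seed and writes a JSON summary.

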