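"""Cross-pairing Monte Carlo null vs. mutually suppressing pairs.

Superposing two independently simulated solitary epochs yields a virtual
pair that cannot hear each other — the chance-level baseline.  All C(40,2)
= 780 cross-pairings form the null ensemble; an ensemble of interacting
(suppressing) pairs is then compared against it with a two-sided
Mann-Whitney test on pooled emission rate.
"""

from sonarchannel import (
    EpochRecording, SuppressionParams, compare, epoch_stats,
    gen_group_suppression, gen_solitary, null_distribution,
)

sources = [
    EpochRecording(f"sol{s}", 10.0,
                   [gen_solitary(5.0, 10.0, "poisson", seed=s)])
    for s in range(40)
]
null = null_distribution(sources, tau_ms=10.0)
print(f"null: {null.summary['n_pairs']} virtual pairs, pooled rate "
      f"{null.summary['pooled_rate_mean']:.2f} +/- "
      f"{null.summary['pooled_rate_sd']:.2f} Hz, zero-overlap fraction "
      f"{null.zero_overlap_fraction:.2f}")

params = SuppressionParams(ipi_model="poisson")
real = [epoch_stats(gen_group_suppression(2, params, seed=s), tau_ms=10.0)
        for s in range(60)]
res = compare(real, null)
print(f"suppressed pairs: {res.real_mean_sd[0]:.2f} +/- "
      f"{res.real_mean_sd[1]:.2f} Hz; Mann-Whitney p = {res.rate_p:.2g}")
print("a small p with a lower suppressed mean says interacting pairs call "
      "slower than deaf-to-each-other pairs would by chance.")
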