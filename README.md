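# cpaudit

Conditional-power machinery for auditing randomised trials that stopped
early for futility.

When a trial's data safety and monitoring board looks at interim data, the
decision to stop for futility is usually framed in terms of **conditional
power (CP)**: the probability of a statistically significant result at the
planned completion, given the data so far and an assumption about future
data. Surveys of stopped trials need to recompute CP from whatever the
reports disclose — an effect estimate and SE, a Z statistic, sometimes
only a p-value — and must be honest about the many reports that disclose
too little. This package provides that machinery for methodologists and
trial statisticians: the closed-form CP calculation, converters from
reported summaries to the information scale, an audit pipeline over
per-trial registry tables, and a group-sequential simulator that both
cross-checks the closed form by brute force and demonstrates the
estimation biases a futility rule induces.

## The calculation

On information time `t_k = I_k / I_K` (with `I_k = SE(theta_hat_k)^-2`),
one-sided conditional power at look k under a hypothesised future effect
theta is

    CP_k(theta) = 1 - Phi( (c - Z_k sqrt(t_k) - theta sqrt(I_K)(1 - t_k))
                           / sqrt(1 - t_k) ),

and the two-sided version adds the symmetric term in -c, with
`c = Phi^-1(1 - alpha)` or `Phi^-1(1 - alpha/2)`. Supported future-data
hypotheses: the **current trend** continues, the **design** effect holds,
an optimistic **upper confidence limit**, or the **null**. CP below a
threshold (default 0.15) classifies the look as futile. See
`docs/methods.md` for conventions and derivations, and
`docs/registry_schema.md` for the audit table format.

## Worked example

A two-sided trial (alpha 0.05, 80% power at a design effect of 0.30) is
halfway through its information and sees an interim estimate of 0.08 with
SE 0.10 (Z = 0.8):

```
$ cpaudit compute-cp --z 0.8 --t 0.5 --alpha 0.05 --sidedness two \
    --design-effect 0.3 --power 0.8 --estimate 0.08 --se 0.1 \
    --hypothesis current_trend
{
  "cp": 0.07445546575997959,
  ...
  "futile": true,
  "threshold": 0.15,
  "hypothesis": "current_trend"
}
```

If the observed trend is what the future holds, the trial has a 7.4%
chance of ending significant — below the 15% threshold, so stopping for
futility is defensible. The same interim look under the design
hypothesis gives `"cp": 0.5036..., "futile": false`: if the protocol
effect is still believed, the trial retains a coin-flip chance and a case
for continuing. This hypothesis-dependence is exactly why audits compute
both.

The pipeline commands operate on whole registry tables:

```
$ cpaudit generate-registry --n 52 --seed 1 --out registry.csv
$ cpaudit audit registry.csv --out-audits audits.csv --out-summary summary.json
```

The audit prints status counts (computed / reported-only / insufficient),
CP distributions binned at <15%, 15–30%, 30–50% and >50% under both
hypotheses, and sponsor-stratified bins. `cpaudit simulate --config
sim.yaml --seed 2` runs the group-sequential simulator and prints the
stopped-stratum, completed-stratum and overall estimation biases.

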