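# motifnet

Spiking and mean-field network models in which short-term synaptic
dynamics (facilitation/depression) interact with triplet
spike-timing-dependent plasticity, together with the connectivity-motif
statistics of the structures that emerge.  Networks whose synapses are
short-term depressing grow predominantly unidirectional strong
connections, while facilitating networks grow reciprocal ones; the
package reproduces this effect in simulation and explains it with a
Wilson–Cowan-style rate description.

## What is in the box

| module                  | contents |
|-------------------------|----------|
| `motifnet.dynamics`     | adaptive exponential integrate-and-fire step, PSC kinetics, utilization/resource short-term dynamics and their stationary closure |
| `motifnet.plasticity`   | triplet STDP rule (four-detector, all-to-all), pair-based and anti controls, timing/frequency pairing protocols, LTD→LTP crossover bisection, rate-pair maps |
| `motifnet.netsim`       | wiring construction, traveling-wave and Ornstein–Uhlenbeck stimuli, the coupled (numba-accelerated) network simulator, rate summaries |
| `motifnet.motifs`       | strong/weak convention, symmetry index with Monte-Carlo significance, pairwise motif tallies against the Bernoulli-independence null |
| `motifnet.meanfield`    | threshold-linear rate model with short-term-dynamics efficacies, equilibria + stability, STDP drift, heterogeneous trajectories, mixed-p sweeps, depressing rate bound |
| `motifnet.experiments`  | per-figure experiment runner, YAML config validation, fixtures, delimited-text IO, run manifests |
| `motifnet.cli`          | `motifnet` command-line interface |

## CLI

```bash
motifnet simulate --composition facilitating --seed 1 --duration-ms 30000
motifnet protocol --kind crossover --delta-t-ms -10
motifnet protocol --kind frequency --variant pair --delta-t-ms -10
motifnet meanfield --mode equilibria --sd-kind depressing --h 2.0
motifnet motifs --weights runs/w_final.tsv --sd-kind runs/sd_kind.tsv
motifnet repro fig2_stats --seed 3 --outdir runs
motifnet fixtures --n 10 --seed 0 --outdir fixtures
```

`repro` accepts any of: `fig1_toy`, `fig2_stats`, `fig3_controls`,
`fig5_rules`, `fig6_large`, `fig7_meanfield_hetero`, `fig8_mixed_sweep`.
Each run writes delimited-text tables plus a `manifest.json` into its own
directory and is bit-reproducible given the seed.  Custom settings go in
a YAML config (`--config`), validated against the experiment's schema.

## Notes on scaling

Default experiment parameters are calibrated for desk-scale runs: toy
networks use 10 neurons and 30 s of simulated time with an increased
plasticity rate; the "large" network runs 100 neurons for 60 s.  Runs
executed with `--scale < 1` are flagged `scaled_down` in their manifest.
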