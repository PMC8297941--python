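# synflow

Synergistic information flow in spiking neural networks: transfer-entropy
effective connectivity, partial information decomposition (PID) of triads,
and motif-level statistics, with a synthetic spiking-network generator that
provides ground truth.

## The problem

When two neurons J and K both send information to a receiver I, part of
what I "computes" is visible only in their *joint* activity — the synergy.
A central question about cortical microcircuits is how that synergy depends
on the direction of the surrounding information flow: the feedforward edges
into the receiver, *recurrent* edges between the two senders, and
*feedback* edges from the receiver back to its senders. This package
implements the full analysis chain used to ask that question of
multielectrode spike recordings (e.g. from organotypic cortical cultures),
and — because such recordings are rarely shareable — a generative model of
comparable spiking data with planted connectivity, so every step can be
validated against known ground truth.

## The method

1. **Effective networks.** Spike trains are binarized at synaptic
   timescales (1, 1.6, 3.5 ms bins with matched delays) and every directed
   pair is scored with plug-in transfer entropy
   `TE(J→I) = I(I_t ; J_{t−d} | I_{t−d})`. Edges are kept when the observed
   TE beats interval-jitter surrogates (`p < α`, default α = 0.001 with
   5000 surrogates); weights are TE normalized by the receiver's entropy.
2. **Triads and motifs.** Every pair of senders with significant edges into
   a common receiver is a synergistic triad. Its 4 optional edges (2
   recurrent + 2 feedback) define a catalog of exactly 10 motif classes
   (9 recurrence × feedback categories; the two chiral variants of the
   1-recurrent/1-feedback motif are kept distinct).
3. **PID.** Each triad's multivariate TE is decomposed as
   `mvTE = redundancy + unique_J + unique_K + synergy`, with redundancy by
   Williams–Beer `I_min` (default) or by the BROJA convex program, both
   conditioned on the receiver's past. Interaction information
   (`synergy − redundancy`) is available as the non-PID contrast.
4. **Statistics.** Motif-level aggregation feeds paired signed-rank tests
   (recurrent vs feedback motifs, each vs the default-motif baseline),
   label-permutation nulls, a two-factor repeated-measures ANOVA over the
   recurrence × feedback grid, Spearman correlations, regress-out controls,
   per-network edge-weight regressions, bootstrap CIs, synergy-share
   accounting, and the significance-vs-weight decile trend.

See `docs/methods.md` for the models, estimator conventions, surrogate
design, and the validation studies.

## Worked example

Plant three triads — recurrent (2,0), feedback (0,1), and default (0,0) —
simulate ten minutes of spiking, rebuild the network from the spikes alone,
and decompose every recovered triad:

```python
import numpy as np
from synflow import (generate_ground_truth, SimConfig, simulate,
                     build_network, TS1, triad_pid_table)

graph = generate_ground_truth(
    n_neurons=9, background_density=0.0,
    planted=[(2, 0, None), (0, 1, None), (0, 0, None)],
    weight_range=(0.10, 0.15), seed=1,
)
trains = simulate(graph, SimConfig(duration_ms=600_000, coupling_delay_ms=1.0, seed=2))
print(f"simulated {len(trains)} neurons, "
      f"mean rate {np.mean([t.rate_hz for t in trains]):.2f} Hz")

net = build_network(trains, TS1, n_jitter=999, alpha=0.01, seed=3)
print(f"effective network density: {net.density:.3f}")

table = triad_pid_table(trains, net)
cols = ["sender_a", "sender_b", "receiver", "recurrent_count",
        "feedback_count", "synergy_norm", "redundancy_norm"]
print(table[cols].round(4).to_string(index=False))
```

Output:

```
simulated 9 neurons, mean rate 1.54 Hz
effective network density: 0.125
 sender_a  sender_b  receiver  recurrent_count  feedback_count  synergy_norm  redundancy_norm
        0         1         2                2               0        0.0313           0.0299
        3         4         5                0               1        0.0926           0.0597
        6         7         8                0               0        0.0107           0.0106
```

The jitter test recovered exactly the nine planted edges (density
9/72 = 0.125, no false positives), and classification reproduced each
planted motif class. `synergy_norm` is the synergy as a fraction of the
receiver's entropy — e.g. the joint state of senders 3 and 4 accounts for
about 9% of receiver 5's capacity beyond what each sender contributes
alone plus their overlap.

The same pipeline is scriptable from the shell:

```sh
synflow simulate --n-neurons 9 --plant 2,0 --plant 0,0 --duration 600 --out spikes.txt
synflow decompose spikes.txt --alpha 0.01 --n-jitter 999 --out triads.tsv
synflow run-all --out-dir run1 --seed 7      # full pipeline + manifest
```

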