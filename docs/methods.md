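# Methods

`synflow` quantifies how the directionality of fine-timescale information
flow in a spiking network relates to synergistic integration. This note
documents the models, the estimators, the surrogate and statistical
machinery, the synthetic-data generator, and the design decisions that were
genuinely open.

## Effective networks from transfer entropy

Spike trains are binarized into neuron × time-bin rasters at bin widths
matched to synaptic delays. Three canonical timescales are provided —
1 ms bins with a 1-bin delay, 1.6 ms with 2 bins, and 3.5 ms with 2 bins,
approximately covering 0.05–3 ms, 1.6–6.4 ms and 3.5–14 ms — but every
analysis accepts an arbitrary `TimescaleSpec`, because the mapping from
(bin width, delay) pairs to delay windows is a modelling choice, not a
derived fact. Bins are binary (a bin is 1 if it contains ≥ 1 spike): in the
sparse regime of cortical culture recordings the overwhelming majority of
bins are empty, and binary alphabets keep every joint distribution at 8–16
states where plug-in estimation is reliable.

Transfer entropy from J to I at delay d is the plug-in conditional mutual
information

    TE(J→I) = I(I_t ; J_{t−d} | I_{t−d}),

with order-1 target history. Multivariate TE conditions the receiver's
present on both senders' pasts jointly, conditional TE additionally
conditions on the third neuron's past, and all estimators reduce to sums
over the empirical joint table, so the chain rule
`mvTE = TE(J→I) + cTE(K→I|J)` holds to machine precision on the same data.
Plug-in estimators are positively biased at finite length (bias ∝ 1/N);
bias-corrected estimators are deliberately out of scope, because edge
*significance* is decided by surrogates, not by the raw TE value.

### Interval-jitter significance

An edge is significant when its TE exceeds the TE of jittered surrogates:
`p = (1 + #{null ≥ observed}) / (1 + n_jitter)`, significant iff `p < α`
(defaults α = 0.001 with 5000 surrogates; the reduced α = 0.05 / 999 and
α = 0.01 / 199 configurations are used in the calibration and recovery
studies for speed). Two properties of the surrogate family matter and both
were settled empirically during design:

* **Fixed windows, not spike-centered windows.** Surrogates redraw each
  source event uniformly within its fixed window of `2 × jitter_window_ms`
  (default 20 ms, i.e. displacements comparable to ±10 ms spike-centered
  jitter). Spike-centered windows make every surrogate's sampling region
  track the observed spike, which breaks exchangeability between the
  observed train and its surrogates; measured on independent trains that
  inflates the top-tail rejection rate to ≈ 0.08 at a nominal 0.049.
* **One event per bin.** Surrogates sample bins within each window without
  replacement. A binarized observed train can never occupy a bin twice,
  while continuous redraws occasionally collide and merge; that residual
  asymmetry alone was measurable. With both properties the null rejection
  rate is statistically indistinguishable from the attainable nominal level
  (0.042–0.05 at 49/1000 over 1000 replicates).

Jittering preserves slow structure (rates, population bursts) by
construction, so the null hypothesis being tested is "no source→target
structure at sub-window precision" — the correct null for synaptic-delay
effective connectivity in bursty recordings.

Normalized TE divides by the binned entropy of the receiving neuron,
expressing an edge weight as the proportion of the receiver's capacity the
sender accounts for. Zero-entropy receivers yield NaN normalized values
that are logged and excluded listwise downstream, never silently zeroed.

## Partial information decomposition

For each synergistic triad (two senders with significant edges into one
receiver), the multivariate TE is decomposed into redundancy, two unique
terms, and synergy. Both redundancy measures are computed per
receiver-past stratum and averaged with p(I_past) weights, so the
decomposition applies to exactly the past-conditioned quantity TE is built
from. Whether the BROJA variant should inherit the same stratified
conditioning is not determined by any external constraint; stratification
is this package's documented choice, and makes the two methods directly
comparable term by term.

* **I_min** (Williams–Beer): the expected minimum specific information
  either sender alone provides about each receiver state. All four terms
  are nonnegative; the identity `synergy = mvTE − TE_a − TE_b + redundancy`
  defines synergy.
* **I_broja**: synergy is the part of mvTE lost when minimizing over joint
  distributions that preserve both pairwise (receiver, sender) marginals
  within each stratum; redundancy is back-computed from the identity. For
  binary variables the feasible polytope has one free parameter per
  receiver state (Fréchet bounds of a 2×2 table), giving a 2-D smooth
  convex program per stratum. It is solved by L-BFGS-B with analytic
  gradients, polished by projected Newton steps (the Hessian is closed
  form), with Brent coordinate sweeps and a compass search as fallbacks.
  The subtlety is the boundary: where a cell probability vanishes the
  gradient diverges, and at degenerate corners two divergences cancel only
  along joint directions, so the gradient is discontinuous and a pure KKT
  residual is ill-posed. Convergence is therefore certified by the compass
  pass (including diagonal directions); a genuine failure raises with the
  residual reported. On the canonical gates (XOR, AND, UNQ, duplicated
  source) both methods agree with exhaustive/grid-search oracles to ≤ 1e−6.

Interaction information, `mvTE − TE_a − TE_b = synergy − redundancy`, is
provided as the non-PID contrast. Values within −1e−12 of zero are clamped
to zero and logged. Normalization modes: receiver entropy (default; terms
then lie in [0, 1]), mvTE, or a supplied feedforward weight.

## Motif catalog

A synergistic triad's four optional edges (two recurrent, between the
senders; two feedback, receiver back to a sender) give 16 configurations
that collapse to 10 classes under exchange of the senders, keyed by
`(recurrent_count, feedback_count, chirality)`. Chirality separates the two
(1,1) motifs — *parallel* when the feedback edge targets the emitter of the
recurrent edge — which are conformationally equivalent as unlabeled graphs
but distinct once node roles are fixed. Canonical ids 1–10 order classes by
extra edges, then recurrent count, then chirality; identity is carried by
the key, not the id, since any specific numbering of the two chiral motifs
is a display convention. Grouping chiralities gives the 9
recurrence × feedback categories used by the ANOVA grid.

Under an Erdős–Rényi null at edge density p, the expected frequency of a
motif given its feedforward pair is reported in the `p^k` convention
(k = optional edges present), with the exact conditional form
`multiplicity · p^e (1−p)^{4−e}` computed alongside; the exact form sums to
1 over the 9 categories and is what the calibration suite tests against.
The `p^k` reading of "number of edges" as *extra* edges is the only one
consistent with sparse networks: at ~1% density the two 3-edge motifs have
expected share ≈ 2p ≈ 2.3%, matching reported chance levels, whereas p³
would be three orders of magnitude smaller.

## Statistics

All motif-level statistics operate on tidy per-triad tables. Aggregation
is per (network, motif); "recurrent motifs" have more recurrent than
feedback edges and "feedback motifs" the converse. The battery: paired
Wilcoxon signed-rank comparisons across networks (recurrent vs feedback,
each group vs the default-motif baseline), a within-network label
permutation null, a two-factor repeated-measures ANOVA on the per-network
3×3 cell-mean grid (univariate, uncorrected for sphericity — the
error-term structure is otherwise unconstrained, and this is the choice
that reproduces the textbook df of (2, 2(n−1)) and (4, 4(n−1))), Spearman
correlations (exact permutation p for n ≤ 8, t-approximation beyond — full
enumeration at the often-suggested n = 12 would cost 4.8×10⁸ permutations
per call), OLS regress-out controls, per-network multiple regressions of
normalized synergy on feedforward/recurrent/feedback edge weights (absent
edges contribute weight 0; the mean over the 0–2 edges of a type is the
default predictor, switchable), percentile bootstrap CIs (10,000 draws by
default), synergy-share accounting with t-tests of share ratios against 1,
and the decile trend of significance probability vs TE weight. The ANOVA
is implemented as an explicit sums-of-squares decomposition so that
zero-variance responses give F = 0 rather than 0/0; statsmodels' AnovaRM
serves as the independent oracle in the test suite. Per-network ANOVA
inclusion requires ≥ 30 observations per factor level. No multiple-testing
correction is applied (α = 0.05 per test); undefined aggregates are NaN
and excluded listwise with logged counts.

Every significance machine is calibrated against a matched simulated null
in the acceptance suite: jitter test on independent trains, signed-rank and
RM-ANOVA on iid Gaussian aggregates, permutation on labels independent of
values — rejection rates must sit at the attainable nominal level within
binomial error at 1000 replicates.

## Synthetic spiking networks

No recordings ship with the package; the generator emulates the
statistical structure the analyses assume and provides ground truth.

**Dynamics.** Discrete-time conditionally-Bernoulli spiking at a 1 ms step:

    P(spike_i at t) = 1 − exp(−[ r_i g(t) Δ + Σ_j w_ji x_j(t − d_ji) + c·1{≥2 arrivals} ])

The exponential-hazard saturation means a step's spike is the OR of
independent events — one for the baseline, one per arriving presynaptic
spike — so the simulation runs as an exact event-driven cascade over the
sparse spikes (tens of thousands of events per simulated hour) instead of
a dense time loop. Spike times are placed uniformly within their step.
All couplings are excitatory, the regime in which binary TE has detection
power. All randomness descends from one integer seed through a
SeedSequence split (rates, bursts, baseline spikes, propagation,
within-step placement); identical seeds give identical trains.

**Rates.** Per-neuron rates are lognormal, default mean ≈ 2.1 Hz with ~80%
of neurons below 3 Hz (µ = 0.242, σ = 1 on log-rate). By default the drawn
rates are *targets*: each baseline hazard is reduced by the neuron's
expected synaptic drive (first order, including the aligned-chain
correction when the coincidence term is active), mimicking homeostatic
rate regulation in cultured networks and keeping the realized rate
distribution equal to the drawn one regardless of in-degree. Baselines are
floored at 5% of target (logged), so neurons whose drive exceeds their
target run above it.

**Bursts.** A shared multiplicative gain alternates between quiet
(exponential, mean 10 s) and burst (uniform 1–10 s) periods, with the
burst gain (default 2.5) and quiet gain balanced so the long-run mean gain
is 1. Transitions are smoothed over 100 ms: population bursts recruit over
tens of milliseconds, and instantaneous shared rate steps would put
genuine millisecond-synchronous structure into every neuron pair — which
the jitter test then correctly (and confusingly) reports as connectivity.

**Connectivity.** Directed graphs with independent background edges at a
configurable density (~1% is typical of the emulated recordings) and
planted triads of chosen motif class on disjoint node triples; background
edges never touch planted triples, so planted classes are exact ground
truth. Hazard gains are uniform on a configurable range; the coupling
strength distribution of real functional networks is only loosely
constrained (lognormal-ish), so the range is a config choice, not a claim.

**Coincidence detection.** The optional supralinear term `c` (extra hazard
when ≥ 2 presynaptic spikes arrive in one step) emulates the threshold
coincidence detection of real neurons. It matters for the directional
study below: a purely additive-OR receiver *wastes* coincident input
(saturation), so sender–sender coupling would reduce rather than increase
synergy — the additive model is qualitatively wrong for this question.

### What the recovery studies show

*Edge/motif recovery* plants one triad of each of seven classes on 21
neurons (30 simulated minutes, 1 ms delays analyzed at the 1 ms/1-bin
timescale, gains 0.10–0.15, α = 0.01 with 199 surrogates). These gains are
strong in the detection sense — a direct edge produces hundreds of
precisely lagged coincidences, z ≫ 10 above the surrogate threshold — yet
weak enough that multi-hop common-cause paths (coincidence rate ∝ p³ in
the transmission probability) stay below it. At transmission probabilities
around 0.4 the jitter test starts flagging those multi-hop flows: they are
*real* information flow, and exact motif recovery then degrades even while
the false-positive count against ground truth stays small. Measured:
sensitivity 1.0, false positives ≤ 2α, exact class recovery 1.0.

*Directional replication* simulates ensembles of 12-neuron networks, each
planting two (2,0) recurrent triads and two (0,0) default triads
(homogeneous 4 Hz targets; feedforward gains 0.10–0.15; recurrent gains
0.5–0.7; coincidence gain 2.5; feedforward delays 3 and 2 ms, recurrent
1 ms, so a sender_a spike relayed through sender_b reaches the receiver
together with its direct input; analysis at 2 ms bins, 1-bin delay).
Networks are rebuilt from spikes alone, triads re-enumerated, classified
and decomposed; per network the triad-mean normalized synergy of
recurrent-group motifs is compared with the default group by paired
signed-rank across ≥ 20 networks. Under these conditions recurrent-motif
synergy exceeds the default baseline at p ≈ 10⁻³–10⁻⁴. Homogeneous rate
targets are used because between-triad rate heterogeneity otherwise
dominates the paired contrast; the homeostatic compensation keeps receiver
entropy matched between groups, so the comparison is not a disguised
receiver-rate effect.

**What passing these studies does and does not show.** The generator
reproduces the features the analysis chain is sensitive to — sparse binary
rasters, lognormal rates, shared bursts, delayed excitatory coupling,
coincidence-sensitive integration — but not refractoriness, inhibition,
oscillatory fine structure, spatial embedding, or spike-sorting artifacts.
Green recovery and directional tests certify that the pipeline detects
planted structure and the planted synergy ordering under its own model;
they are not evidence about any particular biological dataset.

## Numerical conventions

Bins are half-open `[b·w, (b+1)·w)`; spikes at exactly the recording
duration are discarded, as is the trailing partial bin. The add-one
p-value convention keeps p > 0; ties count against significance. Surrogate
and permutation counts must satisfy `n ≥ 1/α − 1` or a config error is
raised before any computation. Probabilities within −1e−12 of zero are
clamped; empirical joints must sum to 1 within 1e−12. Simulation memory is
O(neurons × steps) booleans (≈ 36 MB for 20 neurons × 30 min at 1 ms).

## Study sizes

The shipped studies run on a single CPU in minutes: 1000-replicate null
calibrations on 600 s train pairs, one 21-neuron × 30 min recovery
network, 20-network directional ensembles at 600 s each, and 40–60
Erdős–Rényi graphs for the motif null. All sizes are arguments, so any
study can be scaled up unchanged.

## Known limitations

Plug-in TE is biased upward at finite length; only significance, not raw
magnitude, should be compared across very different lengths. Interval
jitter destroys within-window structure beyond independence (e.g.
refractoriness), making the test approximate for data with strong
inter-spike dependencies at the window scale. The BROJA optimizer is
specialized to binary alphabets. The RM-ANOVA assumes sphericity
uncorrected. Inhibitory coupling is out of scope throughout: the binary
sparse TE used here has little power against rate decreases, so the
generator plants none.
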