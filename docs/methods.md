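# Methods

This note records the modeling choices behind the package: what the
synthetic data emulates, how the graphs are built, how the networks are
trained, and where the design was genuinely open.

## Synthetic annotated ECG

The generator emits 10-second single-lead records with, per beat, a class
label in {N, S, V} and P/QRS/T segment boundaries as 0-based half-open
sample ranges. It reproduces the statistical contrasts a beat classifier
relies on, not the electrophysiology:

- **V** beats have a widened QRS (`v_qrs_widen`, default ×1.9 on a 100 ms
  normal QRS) and, by default, no P annotation (`p_noP = 1.0`) —
  configurable, which also exercises variable per-beat node counts.
- **S** beats are premature: the preceding RR interval is shortened by
  `s_prematurity` (default 35 %). Their waveform morphology is otherwise
  normal, so S detection must come from timing, which is the interesting
  regime for the relational (beat-graph) pathway.
- **N** beats follow the patient's resting rhythm with fractional RR
  jitter (`rr_jitter`, default 4 %).

Waveforms are sums of per-segment templates — Gaussian bumps for P and T,
a sharp biphasic difference-of-Gaussians for QRS — plus white noise
(`noise_sd`, default 0.03 against a unit QRS). The classifier consumes
annotations and waveform segments, never template identity. Sampling rate
defaults to 250 Hz and only affects rendering: every graph feature is
expressed in seconds.

Datasets draw each patient's resting RR uniformly from 0.65–1.05 s
(`patient_rr_range`), emulating inter-patient heart-rate variability.
This matters: with a single global rhythm, absolute interval features
alone identify premature beats and the relational pathway is redundant;
with per-patient rhythms, "premature" is relative to the owner's rate, as
in real data. Class mixtures are realized by per-record largest-remainder
quotas with randomized remainders, so realized proportions track the
target (default: the study mixture 75.0/15.2/10.4 %, normalized) to well
within a percentage point over a few hundred beats. One global seed
spawns per-patient child seeds; identical arguments give byte-identical
datasets.

Very premature beats get special casing during scheduling: a P wave that
would collide with the previous T is first shifted, then dropped (buried
P), and if the QRS itself still collides the previous T annotation is
trimmed — mimicking how such beats present in delineated recordings.
Records are truncated to complete beats inside 10 s; partial beats are
never annotated.

What passing tests on this generator do **not** show: robustness to
delineation errors, baseline wander, electrode artifacts, atrial
fibrillation and other rhythms outside {N, S, V}, or bundle-branch-block
morphology. Results on synthetic data are a functional verification of
the pipeline, not a clinical performance claim.

## Record format

One directory per record: `signal.csv` (`sample_index,value`) and
`annotation.json` (patient/record ids, sampling rate, per-beat class and
segment ranges). The annotation model is a pydantic schema; the exported
JSON Schema ships at `ecg_graphnet/schemas/annotation.schema.json`.
Validation enforces: every beat has a QRS; onset < offset within the
signal; segments sorted and non-overlapping. Longer recordings are split
into consecutive 10-second windows; a beat belongs to the window holding
its QRS onset (a convention — straddling beats are clamped at the edge),
and no beat is duplicated or dropped.

## Segment embeddings

Each segment type has its own fully connected autoencoder
(64 → 32 → 16 → 32 → 64). Segments are linearly resampled to 64 points
and min-max normalized to [0, 1] (constant segments map to all-0.5); the
encoder's output passes through a logistic squashing, so every latent
coordinate lies strictly in (0, 1). The latent size 16 makes the node
feature dimension 3 + 1 + 16 + 2 = 22. Training minimizes full-batch MSE
with Adam (120 epochs, lr 3·10⁻³) and is deterministic under a seed.
Autoencoders are refit on every training fold; validation and test
segments are embedded with frozen parameters.

## Graphs

Segment-graph edges: unit self-loops; chronologically adjacent pairs
weighted by the logistic w(Δt) = 1/(1+exp(α(Δt−δ₀))) of the
offset-to-next-onset gap (α = 10 /s, δ₀ = 0.3 s); QRS–QRS pairs within a
5-node window (±2 QRS positions), weighted on the onset-to-onset gap.
P-P and combined edge schemes are available behind `GraphConfig.edges`
for ablation; QRS-only is the default. If two rules produce the same
edge the larger weight wins. The logistic form and its parameters are
package choices; the contract enforced everywhere is monotone decrease
in the gap with weights in (0, 1).

Beat-graph (path) edges use the same logistic at the RR scale
(`rr_alpha = 6 /s`, `rr_delta0 = 0.7 s` ≈ typical resting RR). The
segment-scale parameters would map every physiological RR interval to a
weight near zero and erase the RR signal — the midpoint must sit inside
the feature's dynamic range. Raw-RR weights are available
(`raw_rr_weights`).

Pooling follows the stated sum exactly: limits −k..j include the
neighboring QRS nodes; weights (1 − c|i|) are floored at 0 while the
normalizer 1/(1+k+j) is kept as printed (no renormalization); boundary
beats truncate k or j to the available nodes. `inclusive=False` stops one
node short of the neighboring QRS on each side. k and j are
node-position offsets, which is what makes the index arithmetic in the
sum well defined.

## Minority-class augmentation

Training sets are rebalanced toward targets (default 40/30/30) by
extracting subgraphs of consecutive same-class ectopic beats (runs capped
at 8 beats), rebuilding their adjacency with the standard rules, and
jittering only the width and distance features (multiplicative Gaussian,
sd 5 %); one-hot and embedding coordinates are identity-bearing and left
untouched, and raw signal samples are never modified. Extracted
subgraphs keep the source record's boundary distance features: a
premature beat's short preceding gap is its label-relevant context and
would otherwise be lost with the removed neighbor. Because windows
contain no N beats, the N beat count is invariant under augmentation, and
originals are never mutated. A greedy loop adds one subgraph for the
most-deficient class until all proportions are within `tol` (2 pp) of
target or a growth cap is hit (then: warning plus achieved proportions).

Limitation, measured honestly: at very small scales (≈ 15 patients) this
scheme can *reduce* minority F1 — a single-beat S subgraph carries little
evidence for a class defined by its relation to neighboring beats — while
at the 40-patient benchmark scale its effect is neutral to mildly
positive. The distribution contract is guaranteed; a performance gain is
not, and is not asserted by the test suite.

## Networks and training

GC layer: Z = Â H W + b with Â = D^{−1/2} A D^{−1/2} over the weighted
adjacency including self-loops (degrees are therefore strictly positive);
each GC/FC block applies batch normalization then ReLU. Defaults: segment
blocks 22 → 32 → 32, one beat-graph block 32 → 32, prediction block
(64 with concat skip) → 16 → 3 → softmax. These sizes came from a
desk-scale grid exploration under the package's CPU-budget problem sizes;
all are configurable, and the additive-skip variant requires matching
channel widths. Parameter initialization draws per-block child seeds, so
architectures sharing a seed share the parameters of their common blocks.

Batches stack graphs block-diagonally (sparse Â, pooling operator, and
beat-graph Â), so training is full-batch over all training graphs.
Batch-norm running statistics use momentum 1.0 — i.e. the latest training
batch's moments. With full-batch training the batch is the training
distribution; exponential averaging (momentum ≪ 1) makes inference-mode
statistics lag the fast-moving weights, which silently corrupts the
validation loss that early stopping watches. For minibatch regimes the
momentum is configurable.

Optimization: per-beat cross-entropy, Adam (lr 5·10⁻³), at most 400
epochs, early stopping after 40 epochs without validation-loss
improvement (best parameters restored). With a plateau (e.g. lr = 0) the
loop runs exactly 1 + patience epochs. Argmax ties break toward the
fixed class order N < S < V. Everything is deterministic under the run
seed.

Per-class metrics for a class absent from the labels are undefined and
reported as NaN, excluded from the Macro F1 denominator (switchable to
zero-filling). Fold aggregation reports mean, error range (max − min)/2,
and standard deviation.

## Protocols and problem sizes

- **Benchmark cross-validation**: 40 synthetic patients × 6 records
  (≈ 2 800 beats), pronounced class contrasts
  (`strong_contrast_morphology`: V width ×2.2, S prematurity 45 %,
  rhythm jitter 3 %, noise 0.03), augmentation to 50/25/25 on training
  folds, 5-fold interpatient CV. These sizes keep a full architecture
  comparison within minutes on one CPU while leaving headroom below the
  performance ceiling so architecture differences remain visible.
- **Pattern/size generalization**: patients owning an 8-beat record with
  ≥ 1 N beat and a run of ≥ 4 consecutive same-class ectopic beats (the
  run rule; the reference patterns are single-class runs like NNNNSSSS)
  become test patients. Training uses only the remaining patients'
  8-beat records under 5-fold CV; the five models are combined by
  soft-voting (mean probabilities, argmax). Test sets: Pattern
  (qualifying records), Size (≥ 9-beat records), Control (other 8-beat
  records). Generator layout: 20 training-side and 8 test-side patients;
  size records realize each patient's own rhythm, so rhythm and graph
  size are not confounded.

## Known limitations

- The generator's morphology is schematic; embeddings learned on it will
  not transfer to real waveforms.
- Heavier rhythm classes (paced beats, fusion beats, bundle branch
  block) are out of scope, as is automatic P/QRS/T delineation — inputs
  must arrive annotated.
- Exact-match accuracy is sensitive to graph length and is reported per
  protocol set, not comparable across sets of different sizes.
- The NumPy training loop is full-batch; datasets far beyond ~10⁵ beats
  would need minibatching (and a batch-norm momentum < 1).
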