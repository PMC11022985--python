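# Methods

## Problem and model

`soluens` predicts aqueous solubility, log S = log10 of molar solubility, for
small organic molecules directly from their string representation, together
with a decomposition of predictive uncertainty. Each ensemble member m is a
recurrent network that maps a tokenized SELFIES string x to a Gaussian
predictive distribution N(mu_m(x), sigma_m^2(x)). The member architecture is

    token ids -> embedding (64)
              -> bidirectional RNN layer 1 (GRU or LSTM, 64 units/direction)
              -> bidirectional RNN layer 2 (64 units/direction, final states)
              -> layer normalization (learned gain/bias)
              -> dense 32 (ReLU) -> dense 16 (ReLU)
              -> { linear head -> mu,  softplus head -> sigma }

with dropout (rate 0.35) after the embedding and after each dense layer
during training. The sigma head's softplus output is floored at
`sigma_floor` (default 1e-3 log S) and interpreted as a standard deviation;
the member's aleatoric variance is its square. Padding (id 0) is masked in
the recurrent layers: state updates at pad positions are suppressed, so
trailing padding cannot change the output (this is tested by comparing padded
and unpadded forward passes). The bidirectional directions are merged by
concatenation; the two stacked layers read the layer-1 output sequence, and
the network head reads the concatenation of the two final states.

A deep ensemble of N independently initialized and trained members is
aggregated as the moments of the uniform Gaussian mixture:

    mu*         = (1/N) sum_m mu_m
    sigma_ale^2 = (1/N) sum_m sigma_m^2        (aleatoric uncertainty)
    sigma_epi^2 = (1/N) sum_m (mu_m - mu*)^2   (epistemic uncertainty)

so that sigma_ale^2 + sigma_epi^2 is exactly the mixture variance
E[X^2] - E[X]^2. With N = 1 the epistemic term is identically zero. Note that
sigma_epi^2 is the population (ddof = 0) variance of the member means: as an
estimator of the between-member variance its expectation scales like
(1 - 1/N) times the member-population variance, so its *mean* over a test set
tends to grow slightly with N even as its sampling tail shortens. Ensembling
narrows the tail of the uncertainty distributions rather than shifting their
center.

## Tokenization

SMILES inputs are converted to SELFIES with a self-contained codec
(`soluens.selfies_codec`) covering atoms B/C/N/O/F/P/S/Cl/Br/I with common
±1 charges, single/double/triple bonds, nested branches and rings.
Stereochemistry, isotopes, radicals, multi-fragment species and other
elements raise an encoding error; aromatic rings are kekulized. The codec
follows the published SELFIES grammar conventions (index alphabet, branch and
ring length encoding), and on the supported subset its output matches the
reference grammar token-for-token (e.g. acetic acid
`[C][C][=Branch1][C][=O][O]`, benzene
`[C][=C][C][=C][C][=C][Ring1][=Branch1]`). The decoder guarantees inversion
of encoder output; it is not a repair engine for arbitrary token strings and
raises on strings it cannot derive.

The vocabulary maps every distinct token of the training corpus to a
contiguous id: `<pad>` = 0, `<unk>` = 1, chemical tokens from 2 in
lexicographic order, making the build deterministic and order/duplicate
invariant. The count of "distinct tokens" is reported excluding the two
specials. Out-of-vocabulary tokens at prediction time map to `<unk>` with a
warning (strict mode raises instead); sequences longer than `max_len`
(default 128) are rejected during training preparation and truncated with a
warning at prediction.

## Data pipeline

Training data are (SMILES, log S) CSVs. Augmentation generates at most ten
new unique randomized SMILES per record by seeded random atom renumbering
(attempts capped at 10x the target so single-representation molecules
terminate), each new string inheriting the parent's label; duplicates are
removed globally at the exact-string level (a canonical-level mode is
available). The 80/20 shuffle-split is performed after augmentation, so
different representations of one molecule can land in both halves; every
split therefore emits a leakage report (parents present on both sides), and
a by-parent split mode avoids the leakage entirely. This ordering replicates
the upstream pipeline; the leakage materially flatters test metrics, which is
why the report is always produced.

## Training

Members are trained on the heteroscedastic Gaussian negative log-likelihood
(exact form, constant included)

    l = 1/2 log(2 pi sigma^2) + (y - mu)^2 / (2 sigma^2)

with Adam at a fixed learning rate (default 1e-4, beta1 0.9, beta2 0.999).
With adversarial training enabled (default), each iteration performs two
optimizer updates sharing one Adam state: one on the clean batch, then one on
the batch whose embedded representation is perturbed by the fast-gradient-sign
step x' = x + eps * sign(grad_x l). Because the raw inputs are discrete
tokens, the perturbation acts on the embedding output; the perturbed input is
a constant of the second update (the embedding matrix receives no gradient
there), the perturbation gradient comes from the clean pass (that iteration's
dropout mask), and the perturbed pass re-samples dropout. With eps = 0 the
procedure is bit-identical to performing the clean update twice, which is
tested. eps defaults to 0.01 in embedding units and is configurable; no value
is canonical. Defaults of 50 epochs and batch size 32 are configurable; no
early stopping or model selection is performed — final-epoch weights are
kept. Member diversity comes solely from per-member seeds (initialization,
shuffling, dropout); duplicate seeds trigger a warning.

All computation is float64 numpy via a small reverse-mode tape
(`soluens.autodiff`), gradient-checked against central finite differences;
training is exactly reproducible given the seeds.

## Synthetic corpus

The generator (`soluens.synthetic`) emits valid SMILES of linear
carbon/oxygen chains (5–14 heavy atoms, no adjacent oxygens, up to three
single-atom branches on interior carbons) with labels

    y = a*n_heavy + b*n_oxygen + Normal(0, c0 + c1 * oxygen_fraction),

defaults a = -0.3, b = 0.8, c0 = 0.1, c1 = 0.4, chosen so heavier molecules
are less soluble, oxygen-rich ones more soluble and noisier, spanning a few
log units like curated solubility data. Both the mean structure and the noise
law are recoverable by construction (ordinary least squares on the two counts
recovers a and b; the noise std is a function of the oxygen fraction, which
is readable from the token sequence). What the corpus does *not* emulate:
rings, aromaticity, heteroatoms beyond oxygen, charges, measurement-protocol
bias, and any nonlinear structure–property relationship — so passing the
scaled-down tests demonstrates that the machinery recovers a known
heteroscedastic signal, not that the model is accurate on real chemistry.

## Scaled-down experiments

The uncertainty experiments (`soluens.experiments`) train pools of tiny
members — embedding 16, one-direction width 16, GRU, dropout 0.0, no
adversarial updates, Adam lr 0.01, batch 64, 50 epochs — on the 80% split of
the 2000-molecule corpus and on its first 200 records. Sub-ensembles of size
N are the first N members of the pool, so all sizes share seeds. Problem
sizes were chosen so the whole study trains twenty members in minutes on one
CPU. Two deliberate deviations from the full-scale defaults, made once after
pilot convergence runs and then frozen: dropout is disabled (rate 0.35 is
sized for 64-unit members on ~10^5 augmented samples; on a 16-unit member it
leaves the mean badly underfit, and the sigma head then tracks model bias
instead of noise), and the learning rate is raised to 0.01 (1e-4 cannot
traverse the loss landscape in 50 epochs at this scale). GRU is used because
it is the cheaper gate and the gate choice is immaterial to what the study
measures. Under these conditions the aleatoric head's predicted sigma
correlates with the true noise std at r ≈ 0.95 on held-out molecules, and
mean epistemic variance drops by an order of magnitude when the training set
grows from 200 to 1600 records.

## Numerical choices and degenerate inputs

- sigma floor 1e-3 log S keeps the NLL bounded and the variance positive.
- Layer normalization uses eps = 1e-5 and learned gain/bias.
- Glorot-uniform initialization; LSTM forget-gate bias 1; embedding
  U(-0.05, 0.05).
- Inverted dropout (scaling at train time); inference is always
  deterministic.
- Empty batches, non-finite labels/losses, out-of-range token ids and
  vocabulary/model size mismatches raise immediately with diagnostics.
- Pearson r on a constant vector is reported as missing (NaN) with a
  warning, not as zero. The ±0.5 log% boundary is closed (|error| <= 0.5
  counts as correct).

## Known limitations

- The SELFIES codec covers the organic subset described above, not the full
  grammar; exotic species fail loudly at encoding.
- The model is not invariant to the input representation of a molecule; this
  is inherent to string-based encoders and is the reason randomized-SMILES
  augmentation exists. Canonicalize inputs for reproducible single-string
  predictions.
- Training is pure numpy on CPU: fine for the scaled-down studies and small
  corpora, hours for database-scale ensembles (`scripts/full_scale.py` is the
  opt-in entry point for that).
- Splitting after augmentation leaks parent molecules across the split by
  design (replicating the upstream pipeline); use `--by-parent` for honest
  generalization estimates.
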