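# Methods

## Problem setting

A polyprotic molecule has one micro-pKa per titratable site but only a
handful of measurable macro-pKa values. `micropka` treats the molecule as
a *bag* and its ionizable atoms as *instances*: the bag label (the
most-acidic or most-basic macro-pKa) is an exact function of the instance
values, so instance-level predictions can be learned from bag-level
supervision alone. The package restricts itself to the two extreme macro
values; intermediate (2nd, 3rd) dissociation constants, tautomer
averaging and C–H acidity are out of scope by design.

## Ionizable-site rules

* acidic site: any non-carbon heavy atom with ≥ 1 attached hydrogen
  (implicit + explicit);
* basic site: any nitrogen with formal charge ≤ 0.

The sets may overlap (a neutral N–H is both). Structures are standardized
before site perception: largest covalent fragment kept (salt stripping),
charges neutralized by proton addition/removal wherever valence allows
(RDKit `Uncharger`), canonical SMILES emitted. Non-neutralizable charges
(e.g. quaternary N) are kept and flagged rather than rejected; the basic
rule then excludes them naturally. Zwitterions are neutralized on both
ends when valence permits. Standardization is idempotent and
order-insensitive to salt fragment listing; all atom indices refer to the
canonical SMILES atom order.

## Graph featurization

Eight atom descriptors — element {C,N,O,S,F,Cl,Br,I,P,other}, degree 0–5,
formal charge {−1,0,+1,other}, hybridization {sp,sp²,sp³,other}, aromatic
flag, total H count 0–4, ring membership, chirality tag — and four bond
descriptors — bond type {single,double,triple,aromatic}, conjugation,
ring membership, stereo tag — all one-hot with an "other" bucket where
the list is open-ended (35 atom slots, 10 bond slots). The schema is a
frozen object serialized into every checkpoint; loading a checkpoint with
a different schema is an error, never a silent re-encode.

## Network

Input features are projected to a hidden state (default 200, leaky-ReLU).
Each of the 6 graph-attention layers computes, per directed edge *u→v*,
a leaky-ReLU attention logit from the two endpoint states, normalizes over
*v*'s in-neighborhood by softmax (weights are non-negative and sum to 1),
aggregates messages `W·h_u + W_b·e_uv` (bond features enter every layer),
applies an ELU, and updates `h_v` with a GRU cell. Dropout acts on node
states between layers and inside the head. There is deliberately **no
molecule-level readout**: the final atom states feed a small fully
connected head (default one hidden layer of 128) emitting one scalar per
atom. Separate models are trained for the acidic and the basic task.

The network, Adam, and MC-dropout run on a compact reverse-mode autodiff
engine over NumPy edge-list operations (gather / segment-sum / shifted
segment-softmax); float64 throughout. Deterministic mode (dropout off) is
bitwise reproducible, and initialization is fully determined by the model
seed (Glorot uniform). Gradient correctness is tested against central
finite differences.

## Pooling

Masking replaces non-site atoms by the absorbing element (+∞/−∞), which
is implemented as *exclusion from the sum* — mathematically identical
(10^(−∞) = 0) and free of NaN/overflow in gradients. Pooling uses a
max-shifted exponent scheme: with `m = min v`,
`pool_acidic(v) = m − log10 Σ 10^{−(v_i−m)}`; exponents are ≤ 0, so any
value range a model can emit (and the full −10.1…40 label range) pools
without overflow. Consequences used as test oracles: the macro value is
bounded by the extremal micro value with equality iff exactly one site;
appending a site strictly moves it; `pool(v+c) = pool(v)+c`; basic pooling
is the mirror image of acidic pooling under sign flip. The gradient of
the macro w.r.t. site *i* is the softmin/softmax weight
`10^{∓pKa_i}/Σ_j 10^{∓pKa_j}` — learning signal is routed to sites in
proportion to their dominance. Molecules with no site of the requested
mode are excluded from training batches and reported as unpredictable
(`no-site`) at inference; the pooled value is undefined on an empty bag.

## Training and evaluation

70:15:15 random split (largest-remainder rounding, leftover going to the
earlier subset on ties; deterministic per seed). Loss is MSE between
pooled macro predictions and labels; Adam (lr 3e-3, batch 128, gradient
clipped at norm 5), validation-MAE early stopping (patience 30, max 500
epochs) with lr halving after 10 stalled epochs; best-validation
parameters are returned. Multiple independent runs re-seed both the split
and the initialization, and are summarized as mean ± sample standard
deviation.

Metrics: MAE, RMSE, R² (flagged undefined for n < 2 or constant truths).
Applicability-domain analysis assigns each test molecule its maximum
Tanimoto similarity (1024-bit radius-2 Morgan fingerprints) over the
training set, binned into [0,0.3), [0.3,0.4), [0.4,0.5), [0.5,0.6),
[0.6,1.0] — 0.5 is the salient practical boundary; the exact outer edges
are configuration.

Dominant-site analysis: the predicted dominant set G collects every site
within ε of the extremal predicted micro value (default ε = 0.1 pKa
units — far below chemically meaningful differences, configurable).
Against an expert assignment h, the consistency indicator is `1{h ∈ G}`
and the consistency rate its mean; each disagreement is quantified by the
difference value |f(g) − f(h)|. When G has several elements the reported
difference is the worst case over g ∈ G (a deliberate choice; any single
element would also be defensible).

## Uncertainty and search

MC-dropout: n (default 100) stochastic forward passes with dropout left
active; the 95% interval is the empirical 2.5/97.5 percentile — a
percentile interval is robust to skew, at the price of collapsing for
n = 1. The interval is widened to include the sample mean in the rare
skewed-small-sample case, and is exactly degenerate when dropout is 0.

Similarity search stores, per reference molecule, the final-layer
embedding of its dominant ionizable atom (ties broken by lowest atom
index) plus its experimental pKa; queries return entries with Euclidean
distance < 0.05, nearest first, at most 4. The index carries a hash of
the model architecture + parameters, and querying with any other model is
a stale-index error. The PCA export takes the top-2 principal components
of mean-centered embeddings, with each component's sign fixed by making
its largest-magnitude loading positive.

## Synthetic data generator

Real micro-pKa ground truth is unavailable, so recovery is validated on
constructed molecules. Scaffolds are small frames (benzene, C3–C5
chains, cyclohexane; ≤ 20 heavy atoms, chosen to keep CPU training fast);
1–6 ionizable groups are attached (carboxyl 4.2, phenol 10.0, aliphatic
alcohol 15.0, sulfonamide N–H 10.1, thiol 9.0; amine 10.6, aniline 4.6,
pyridinic N 5.2 — plausible magnitudes and orderings, not literature
constants), plus 0–3 perturbing substituents (F, Cl, methyl, methoxy)
whose additive shifts (≤ ±1.5 units, decaying over graph distance 1–3)
create both well-separated and near-tied bags. True micro-pKa is a
deterministic function of the assembled graph; the macro label is the
*exact* pooled value plus Normal(0, σ) noise. Every generated molecule is
re-checked against the rule-based site enumerator and resampled if any
unintended site appears, so the truth map always covers exactly the sites
the model sees. Generation is bit-reproducible from (n, mode, σ, seed).

What the generator does *not* emulate: real chemical diversity (ring
assortments, charge-separated species, tautomerism), non-additive
electronic effects, measurement error structure, and any resemblance to
the value distribution of curated experimental sets. Passing the recovery
test therefore demonstrates that the *mechanism* — micro values learned
through bag-level supervision — works when the pooling model is correct;
it does not certify accuracy on real molecules.

## Problem sizes used in the shipped experiments

The recovery experiment trains 2,000 molecules (noise σ = 0.2, hidden
width 64, ~80 epochs to early stop, ≈ 6–7 minutes on one CPU) and
evaluates on the 300-molecule held-out split: held-out macro MAE ≈ 0.18,
Spearman(predicted, true micro) ≈ 0.9, dominant-site consistency ≈ 0.99
on the first recorded run — computed fresh by `scripts/acceptance.py` and
by the acceptance test, never hard-coded. The pooling oracle uses 10,000
random vectors; the search check a 1,000-entry index.

## Known limitations

* Site rules are syntactic: every N counts as basic (amides included) and
  every heteroatom-H as acidic; the model must learn that some sites are
  irrelevant, exactly as weak acidity suppresses them in the pooling sum.
* Weakly contributing sites (e.g. an alcohol next to a carboxyl) receive
  almost no gradient, so their micro values are poorly constrained — the
  recovery Spearman is dominated by sites that matter to some bag.
* Single attention head, fixed hidden sizes; hyperparameters are exposed
  in `ModelConfig` but no automated search ships with the package.
* Checkpoints and embedding indices are NumPy archives tied to the exact
  feature schema; there is no cross-version migration.
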