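# Methods

This note documents the model, the synthetic study conditions, the numerical
and design choices, and the limitations of what the tests demonstrate.

## Model and assumptions

The model predicts right-censored survival from four patient modalities:
clinical variables (four categoricals + age), mRNA expression, miRNA
expression and copy-number variation (CNV). Its structure is a bilayer
extractor: modality-specific encoders produce fixed-length representations
(`d`-vectors), and a multihead-attention layer pools the per-patient 4×`d`
modality-token matrix into a fused feature `Y` that feeds the survival head.
The working assumptions are (i) prognostic signal is carried by a minority of
features within each modality, (ii) an absent modality is informative only of
"not measured" (zero-vector imputation, no statistical imputation), and
(iii) risk ordering, not calibration, is the target (evaluation is by
concordance).

The attention is computed **per patient over the four modality tokens**: the
value of attention here is cross-modal weighting within a patient. A
batch-level reading (attention across patients) would break inference-time
batch independence and is not implemented. The final projection `w_last` is
applied elementwise, keeping `Y` a length-`d` feature vector so the survival
head and the auxiliary classifier have usable capacity; `w_last` is
initialised at ones (an identity gate), which keeps early gradients to the
encoders well scaled. The query is initialised uniform on
`(−1/√d, 1/√d)`; only the distribution family of the initialisers is
prescribed by the model family, the bounds are package choices.

### Survival heads

The head is configurable:

* `discrete_time` (default): per-bin conditional hazards via sigmoid over
  `time_bins = 20` equal-quantile bins of the training times; the loss is the
  exact censored likelihood (events contribute their bin's hazard and prior
  survival, censored records survival through their bin). Risk is
  `1 − mean survival over bins`, a strictly monotone summary fixed for
  determinism.
* `cox`: scalar log-risk with the negative Breslow partial likelihood.

The underlying likelihood of the model family is not fixed by its
description; the discrete-time head is the lineage convention and remains
the default. At the desk scale used here, the ranking-aligned Cox loss
converges to a markedly higher test concordance than the
calibration-oriented discrete likelihood (≈0.78–0.80 vs ≈0.70 on the study
cohort), so the canned study configuration selects the Cox head.

### Training

Adam (default) with learning rate 0.001, batch size 256, 100 epochs, weight
decay as explicit L2 on the gradients. When a validation set is provided,
the validation C-index is tracked per epoch and the best-epoch parameters
are restored at the end (standard model selection; the privacy accountant
covers released training gradients, not the selection step — the usual
convention for private training pipelines). Batch normalisation sits after
each affine and before the ReLU; during private steps the protected
encoders' batch-norm layers run on running statistics so per-sample
gradients stay separable (batch statistics would couple samples and
invalidate the sensitivity bound).

## Synthetic cohorts

`privsurv.synthetic` draws feature matrices i.i.d. standard normal, plants
`n_informative[m]` prognostic features per genomic modality plus one
continuous (standardised age) and one categorical-level clinical signal, and
generates survival times from an exponential proportional-hazards model with
log-hazard `effect_size ×` (sum of planted features). Censoring is
independent uniform on `(0, c_max)` with `c_max` solved by bisection from
the closed-form censoring probability, so the expected censored fraction
equals `censor_rate`. All randomness flows from one seeded generator;
cohorts are bitwise reproducible.

Generator defaults mirror a pan-cancer multi-omics cohort: 11,094 patients;
1579 mRNA / 743 miRNA / 2711 CNV features; missing-modality rates
3.1 / 9.7 / 8.3 %; four clinical categoricals plus age. The censoring rate
default is 0.3, a typical large-registry value. What the generator does
**not** emulate: gene–gene correlation structure, batch effects,
heavy-tailed expression distributions, informative censoring, or
nonlinearity of the true risk. Passing tests therefore demonstrate
mechanism correctness and signal recovery under a linear proportional-hazards
truth — not clinical performance.

### Desk-scale study conditions

Tests and the acceptance script run one fixed configuration
(`privsurv.experiments`): 2000 patients; 120/60/90 genomic features with
6/4/5 planted; effect 1.0; 30% censoring; 10% missing per genomic modality;
8 cancer types. Model: widths (64,32)/(48,24)/(64,32), `d = 32`, `H = 4`,
dropout 0.1, Cox head, Adam at 3e-3, weight decay 1e-3, batch 256, 150
epochs with validation-based selection. These sizes were chosen once as the
smallest conditions under which the generative risk scores ≈0.91 concordance
and a correctly implemented model recovers ≥0.75; larger learning rate and
weight decay than the full-scale defaults are the usual rescaling for a
small cohort.

## Preprocessing conventions

* Variance screening keeps features with population variance strictly above
  the threshold, computed over non-missing patients (defaults 7 for mRNA,
  0.2 for CNV — appropriate for expression-scale data; the synthetic study
  uses no screening since its features are unit-variance by construction).
  miRNA is never thresholded.
* Min-max normalisation maps to the closed interval [0, 1]; external values
  are clipped; constant columns map to 0 (not dropped) so shapes remain
  stable once statistics are frozen. Statistics always come from the
  reference (training) cohort.
* Clinical categoricals get a fitted vocabulary with a reserved unknown
  index reachable only at inference; records with missing clinical fields
  or follow-up are excluded upstream by the generator contract.
* External cohorts are aligned to the training feature list by reindexing
  with zero fill — the same convention as missing-modality imputation; an
  overlap below 50% warns but proceeds.

## Relevance propagation

The ε-rule stabiliser defaults to 1e-6, sign-matched to the denominator.
Biases are apportioned equally among the contributing inputs
(`u_q / fan_in` inside each message) rather than discarded; the zero-bias
analytic case then recovers exact proportional decomposition, and layer sums
are conserved up to the stabiliser. Output relevance is initialised at the
head's pre-activation outputs and summed across outputs during the backward
sweep. The attention layer is treated as the linear combination it is at
fixed weights: fused-coordinate relevance is split over tokens in proportion
to `a_t · V_t`; the key/query computation graph is not decomposed (the
allocator only needs encoder-input scores). Per-feature scores aggregate as
the mean absolute per-patient relevance over a fixed reference batch
(first 256 training rows), refreshed every `E = 5` epochs during private
training. Percentile summaries use the nearest-rank definition at the
25/50/75/100th percentiles of each layer's per-neuron score spectrum.

## Privacy mechanism and accounting

Per-sample gradients of each protected encoder are clipped to L1 norm
`C = 1` (per-sample norms and clipped averages are computed in closed form
from each affine layer's cached input/output-gradient pair — no per-sample
gradient tensors are materialised). Neighbouring datasets are batch
replace-one, giving L1 sensitivity `2C/|L|` for the averaged gradient; each
parameter group receives `Laplace(0, 2C/(|L| ε_g))` noise, an `ε_g`-DP
release by the standard Laplace-mechanism argument. Groups are: one group
per relevance interval (the first-layer weight rows of that interval's
features) plus one "deep" group (first-layer biases and all deeper
parameters, budgeted at the interval mean). The perturbation bound of the
budget map defaults to `Δ = 0.4 (ε_max − ε_min)/(n − 1)`, strictly below
the half-spacing that guarantees monotonicity; `δ_k` is drawn once per
training run.

Multi-step accounting is genuinely underdetermined for this mechanism
family, so the accountant reports two clearly separated figures:

* **per-period guarantee** — noise parameters are constant within a
  relevance-refresh period; composing the 3 modalities × (n + 1) groups once
  spends exactly the global ε = 0.8. This is the figure the allocation is
  normalised to.
* **naive across-training composition** — the basic-composition sum over
  every released step (e.g. 600 for 150 epochs at 8 steps/epoch/period
  sweep), reported so no reader mistakes the per-period figure for a
  whole-training bound.

A uniform mode (same global ε, all groups equal — no relevance guidance) is
included as the ablation comparator.

### Measured privacy–utility behaviour, and its limit

On the study cohort, non-private training reaches test C ≈ 0.75–0.80;
private training at ε = 0.8 reaches ≈ 0.57–0.60. The loss is structural,
not an implementation artifact: with L1 clipping at `C` spread over a
protected encoder's ~10⁴ parameters, the largest coordinate of the averaged
clipped gradient carries ~1e-4·C, while the per-step noise scale is
`2C/(|L| ε_g)` ≈ 0.09·C — a per-coordinate signal-to-noise ratio near 1e-3.
No choice of clip bound changes this ratio, and the architecture cannot fall
back on untrained encoders: a shared head cannot decode four mutually
unaligned random projections, so encoder learning is precisely what the
noise forecloses. Tighter mechanisms (Gaussian noise with subsampled
Rényi/moments accounting) would change the picture but are deliberately out
of scope for this mechanism family. Consequently utility is essentially flat
across finite ε under Adam (whose normalisation absorbs the noise scale),
the adaptive-vs-uniform comparison is a statistical tie at these budgets,
and the acceptance suite records the small-utility-loss expectation as a
failing test by design rather than weakening it.

## Evaluation machinery

* **C-index**: pairs are comparable iff the earlier observed time carries an
  event; tied event times are not comparable; tied risks count 0.5
  (Harrell's conventions; exact agreement with a brute-force enumeration
  oracle is asserted, and with lifelines on tie-free data).
* **Splits**: five seeded stratified 60/20/20 splits whose test sets are the
  disjoint parts of a stratified 5-fold partition; stratification is by the
  event indicator.
* **Bootstrap comparison**: models are rescored on 1000 resamples of the
  test set; each pair is tested with `t = mean(d*) / sd(d*)` on the paired
  bootstrap differences, referred to a t distribution with B − 1 degrees of
  freedom, Bonferroni-corrected over pairs; 95% CIs are bootstrap
  percentiles. The bootstrap spread estimates the sampling standard
  deviation of the observed difference itself — dividing by √B, as a literal
  paired t-test on replicates would, treats correlated resamples as
  independent evidence and rejects almost always for any two noisy models.
  The implemented form is calibrated (measured type-I rate 6% at nominal
  5% over 100 audits). Degenerate resamples without comparable pairs are
  redrawn and counted.

## Numerical choices and degenerate inputs

* Hazards are clamped to [1e-7, 1 − 1e-7] inside the discrete likelihood;
  the Cox loss max-shifts scores before exponentiation.
* Time-bin edges are deduplicated quantiles; `c_max` calibration brackets
  the closed-form censoring probability with `brentq`.
* `partition_intervals` collapses tied quantile cuts (warning) and never
  creates empty top intervals; all-equal scores yield one interval.
* Constant normalisation columns map to 0; empty variance-filter results
  warn and return 0-feature blocks; all-censored inputs to the C-index and
  single-class classifier labels raise.
* Checkpoints round-trip bitwise (parameters, batch-norm running statistics
  and bin edges in one `.npz`, configuration and vocabularies in JSON).

## Known limitations

* The NumPy training loop is single-threaded BLAS-bound; full-scale
  (11k × 2711) cohorts train, but slowly.
* LRP is implemented for the dense/batch-norm/ReLU encoder family only.
* The privacy analysis covers released encoder gradients; validation-based
  model selection and batch-norm running statistics are outside the formal
  guarantee, as is everything about the unprotected clinical branch by
  design.
* Discrete-time risks summarise to the same ordering as the hazards; with
  very few bins, within-bin orderings are unidentifiable by construction.
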