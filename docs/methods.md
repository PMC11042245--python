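# Methods

## Problem setting

Given a few hundred compounds with measured potency against one protein
target, build a regression model of activity from structure alone and use it
to rank untested libraries. The activity scale throughout is pChEMBL =
−log₁₀ of the effective molar concentration, so 100 nM ↔ 7.0 and each unit is
a ten-fold potency change. "Active" means pChEMBL ≥ 7, inclusive at the
boundary.

## Curation model

Raw assay tables carry one measurement per row: structure (SMILES), endpoint
type, relation qualifier, value, unit. The curation contract is:

- **Unit vocabulary.** nM, uM (with µ/μ aliases), mM, M, case-insensitive.
  Anything else (%, mg/mL, …) is rejected with reason "unknown unit"; the
  endpoint whitelist (IC50, EC50, AC50, Ki, Kd by default) rejects
  non-concentration endpoints such as Emax or fold-change, for which a log
  molar transform is undefined.
- **Qualifiers.** Only "=" records are kept by default. Censored values
  ("<", ">") would bias a regression label; the set is configurable for
  users who want to keep bounds as point estimates.
- **Aggregation.** Each admissible record is converted to pChEMBL *first*;
  a compound's label is the unweighted arithmetic mean over its records,
  regardless of endpoint type. Averaging on the log scale is the standard
  convention for mixed potency endpoints (geometric-mean of concentrations)
  and is the only order of operations that makes mixed-endpoint aggregation
  well defined. We do not average per endpoint type before combining; with
  typical replicate counts (1–3) a two-stage mean would only reweight noise.
- **Deduplication.** Identity is RDKit canonical SMILES. No salt stripping
  or tautomer normalisation is applied — identity is at the level of the
  encoded molecule. Canonical-SMILES generation is delegated to RDKit; the
  dialect is therefore pinned to the toolkit version.
- **Accounting.** Every input row lands either in a compound or in the
  rejects log with a reason; curation of curation output is a fixed point.

pChEMBL values are stored at full precision and reported at 2 decimals,
matching how such values are conventionally printed.

## Fingerprints

Descriptors are binary hashed circular (Morgan/ECFP) fingerprints, radius 3
(≈ ECFP6), folded to 512 bits — a deliberately compact representation
suitable for a few hundred training compounds. RDKit perceives and hashes
the atom environments; the fold onto n_bits is the modulus of the sparse
environment identifier, implemented natively, and reproduces RDKit's own
folded fingerprint exactly (tested bit-for-bit on a structurally varied
panel). Chirality flags are off, the toolkit default. n_bits must be a power
of two so folding behaves as truncation of the identifier's low bits.

Tanimoto similarity is |A∩B|/|A∪B| on the bit sets. The degenerate
all-zero/all-zero case (possible only for the empty molecule) is defined as
1.0 — two empty environment sets are identical — with a warning. Novelty of
a candidate is its maximum Tanimoto against the training matrix, computed
exhaustively (n ≤ a few hundred training compounds; no index needed), ties
broken to the first training row.

## Model benchmark

Ten scikit-learn regressors are compared under one fixed outer 5-fold
partition (seeded shuffle, fold sizes differing by ≤ 1). Hyperparameters
are chosen per outer fold by exhaustive grid search scored with 3-fold inner
CV mean test RMSE on the outer-training data only, so the held-out fold
never leaks into model selection; a no-leakage test corrupts held-out labels
and verifies the trained model is unchanged. Ties in the grid break to
declaration order; ties for champion break by lower mean test RMSE, then
name. "Train" metrics are the refit model's predictions on its own outer
training folds (not inner-CV aggregates) — the optimistic-looking train R²
this produces for flexible models is expected and documented.

Default grids are compact (tree counts {100, 300}, regularisation strengths
over a few decades, SVR C ∈ {1, 10}) and overridable via config: grid
contents are configuration, not science, and the defaults are sized for a
desk-scale study on one CPU. Lasso/elastic-net get max_iter = 20000 because
coordinate descent converges slowly on sparse 0/1 designs at weak
regularisation.

Randomness policy: one master seed; every fold assignment, grid-search inner
split and stochastic model fit derives its own seed as
`(master * 2654435761 + crc32(purpose)) mod 2³¹`. Two runs with the same
config are byte-identical.

The R²/RMSE implementation computes the defining sums directly; the test
suite checks it against an independent direct-summation oracle to 1e-10 and
uses scikit-learn's metrics only as a cross-check, never as the
implementation.

## Simulated-screening validation

`reshuffle_split` shuffles with a seed and takes `floor(0.9·n)` compounds
for training (375 → 337/38) — the floor rule, rather than `round`, keeps the
reserved set's size stable and reproduces the conventional 90/10 sizes at
odd n. The champion is rebuilt on the 90% and "screens" the reserved 10%:
every reserved compound is predicted, predicted hits are pChEMBL ≥ threshold
(inclusive), and the report counts recovered actives among true actives
(recall) *and* among predicted hits (precision) — both denominators are
printed rather than collapsed into one figure. Train/eval disjointness is
checked by structure key and overlap is a hard error. The evaluation-set
rows are processed in sorted-key order, so the report is invariant to input
order.

## Screening

Libraries (SMILES text or SDF V2000) are canonicalised, deduplicated and
scored; unparseable entries are logged, never fatal. Hit selection is either
threshold mode (all predicted ≥ 7, inclusive — consistent by construction
with the activity labelling rule) or top-K mode (K best regardless of
threshold, default 200, the conventional budget for sending compounds to a
confirmatory assay). Ranking is predicted value descending with ties broken
by ascending structure key, dense ranks 1..n; top-K output is a prefix of
the full ranking, so increasing K only appends. Each hit carries its
max-Tanimoto novelty and nearest training compound.

## Synthetic data generator

The generator emulates the statistical structure of a curated single-target
inhibitor set, not its chemistry:

- **Two scaffold families.** The "active" family is two closely related
  4-aminoquinazoline cores (a congeneric series sharing a core, as real
  inhibitor series do); the "inactive" family is two unrelated small aromatic
  cores (benzamide, benzenesulfonamide). Within-family Tanimoto similarity
  exceeds between-family similarity, giving the two-cluster chemical space
  the t-SNE stage is meant to reveal.
- **Additive SAR.** pChEMBL = base(scaffold) + effect(R1) + effect(R2) +
  N(0, noise_sd), clipped to [2.72, 9.00]. Substituents come from a
  15-fragment library (H, alkyls, halogens, OMe, NMe₂, phenyl, nitro, …)
  with effects spanning ±0.8 log-units — a realistic spread for analogue
  series. Bases are 7.6 (active family) and 5.0 (inactive). Defaults:
  n = 400, noise_sd = 0.4, active fraction target 0.57.
- **Active fraction.** The family allocation solves
  target = f·P(active | active family) + (1−f)·P(active | inactive family)
  exactly, with the clear-probabilities enumerated over substituent pairs and
  integrated over the noise; an unreachable target raises with a diagnosis.
  The realised fraction fluctuates around the target by sampling noise.
- **Assembly.** Substituents are spliced into `{R1}`/`{R2}` slots of the
  core SMILES (substituent rings use index 9 to avoid colliding with open
  core rings), then re-parsed and canonicalised; anything RDKit rejects is
  skipped and retried, so every emitted structure is valid by construction.
- **Raw records.** `generate_raw_records` inverts the curation transform:
  each compound emits 1 + Poisson(λ) measurements with value 10^(−pChEMBL)
  re-expressed in a random concentration unit, optional log-scale jitter and
  optional non-canonical SMILES re-encodings — exercising unit conversion,
  replicate averaging and deduplication end to end.

What the generator does **not** emulate: real pharmacophores, activity
cliffs, assay-to-assay systematic shifts, censored measurements, or any
particular target's chemotype landscape. Passing tests therefore demonstrate
the pipeline's correctness and its ability to recover a planted
structure–activity signal of realistic magnitude — not predictive
performance on any real target.

## Reference study conditions and what the tests check

The acceptance-level tests and `scripts/acceptance.py` run one synthetic
study at n = 400, noise sd 0.4, ~57% actives (raw records with λ = 0.5
replicates, log-jitter sd 0.05, alternate SMILES encodings), then:

- benchmark all ten models (5-fold outer, 3-fold inner CV) and require the
  champion's mean test R² ≥ 0.6 — the planted signal is recoverable;
- permute the labels and require the best test R² ≤ 0.15 — the pipeline
  finds nothing when there is nothing (this permutation null also serves as
  the negative control for the screening recall below);
- rebuild the champion on a 90% reshuffle and require ≥ 80% recall of true
  actives on the reserved 10% at threshold 7.

These sizes run in a few minutes on one CPU. The split-size check (337/38 at
n = 375) and the IC50→pChEMBL conversions of documented inhibitors (5 nM →
8.30, …, 9300 nM → 5.03) are exact.

## Numerical and degenerate-input choices

- R² is explicitly signalled as undefined (ConstantTargetError) when the
  actual values are constant, rather than returning −inf or NaN.
- `to_molar` rejects non-positive values before the log; pchembl of a
  non-positive molar value is an error, never NaN.
- t-SNE: perplexity 30, 1000 iterations, PCA init, seeded; effective
  perplexity is capped at (n−1)/3 for small inputs. Distances are Euclidean
  on the 0/1 matrix by default (equivalent to monotone in Hamming distance);
  a Jaccard mode is available.
- Empty prediction input returns an empty output; an empty training matrix,
  empty library, or empty evaluation set is an error.

## Known limitations

- A single descriptor type (512-bit ECFP6); no counted fingerprints,
  physicochemical descriptors or learned representations.
- No structure standardisation beyond canonicalisation — salts and tautomers
  are distinct compounds.
- Grid defaults are small; serious use should widen them via `model_grids`.
- The simulated screen's recall depends on the active-class margin around
  the threshold; datasets whose actives cluster just above threshold will
  show lower recall at equal model quality.
- t-SNE coordinates are for visual exploration only; no quantitative
  cluster statistics are derived from them.
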