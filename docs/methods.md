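# Methods

## The simulated screening experiment

`screenratio` models ligand-based virtual screening as a supervised binary
classification problem on binary molecular fingerprints. One experiment
fixes a pool of known actives and a large decoy pool, then:

1. **Positive split.** A fraction `train_fraction` (default 0.18) of the
   actives, rounded half-to-even, becomes the positive training set. This
   split is drawn once per experiment and never varies across grid cells;
   the remaining actives are the test positives in every screening
   library.
2. **Grid.** For each cell of the grid
   (ratio `r` × library size `L` × trial), `round(r · n_train_pos)`
   training negatives are sampled without replacement from the decoy pool,
   and the screening library is the test positives merged with
   `L − n_test_pos` decoys sampled from the *remaining* pool. Train and
   test sets are therefore disjoint by construction in every cell; decoy
   draws are fresh per trial while training positives stay fixed.
3. **Scoring.** Each classifier is trained per cell and produces hard
   labels for the whole library; recall, precision and MCC are computed
   per trial and averaged per cell (mean of per-trial metrics, not pooled
   confusion counts — the two differ, and a test constructs a case where
   they do).
4. **Recommendation.** Per (classifier, fingerprint, L), the
   cost-effectiveness curve Δ(r) = best_mcc − mean_mcc(r) is scanned for
   the smallest grid ratio with Δ(r) ≤ t (default t = 0.03). Ties for the
   best MCC resolve toward the smaller, cheaper ratio. Because the set of
   qualifying ratios grows with t, the recommended ratio is monotone
   non-increasing in t.

Default grid: 17 ratios {0.5, 1, 2, 4, 7, 10, 15, 20, 25, 30, 40, 50, 60,
70, 80, 90, 100}, eight library sizes {5k, 10k, 25k, 50k, 75k, 100k, 200k,
400k}, 10 trials — 1,360 cells per classifier and fingerprint.

### Determinism and seeding

Every run is reproducible from a single `base_seed`. Each grid cell derives
its own seed as `base_seed XOR crc32("ratio|size|trial") mod 2^31` — stable
across processes (Python's built-in `hash` is randomized per process) and
distinct across cells. The synthetic generator derives per-stream seeds as
`master_seed + fixed offset` (templates, actives, decoys), keeping the
streams independent but stable. Re-running the same config and seed
reproduces every output table byte-for-byte, serial or parallel
(parallelism is across grid cells only; cells are computed independently).

## Curation conventions

Potency is standardized to Ki in nM: Ki passes through, pKi (molar scale)
maps to `10^(9−pKi)` nM, IC50 is divided by 2 (the Kalliokoski
conversion). A compound is active iff Ki < 100 nM — strictly, so a
compound at exactly 100 nM (pKi 7) is inactive. The molecular-weight
window 200 Da < MW < 700 Da is likewise strict at both ends. When one
compound carries several measurements, the median of the standardized Ki
values is used: the median resists a single discordant assay, and no
widely agreed precedence exists among Ki/pKi/IC50 measurements of the same
compound. Duplicate structures are removed on the canonical structure
string (falling back to the compound id), first occurrence kept, so
curation is order-stable.

## Classifiers

Naive Bayes and 1-NN are implemented natively; they are simple enough to
verify by hand and serve as reference points for the harness.

* **Bernoulli naive Bayes.** Per-class per-bit rates with add-one
  (Laplace) smoothing, θ̂ = (count + 1)/(n_c + 2); class priors from
  training counts, so the prior log-odds of the active class fall
  monotonically as the training ratio grows. Prediction is the
  higher-posterior class, with a tie at exactly 0.5 going to the inactive
  class (the conservative call in a screening context).
* **1-nearest-neighbor.** Euclidean distance, which on binary vectors
  orders candidates identically to Hamming distance; distances are
  computed through the identity ‖x−t‖² = |x| + |t| − 2·x·t with a float32
  matrix product (all values are integers < 2²⁴, so float32 is exact) and
  ties go to the lowest training-row index.

The SVM, decision-tree and random-forest algorithms are scikit-learn
adapters configured to the conventional defaults used in screening
benchmarks: SVM with cost parameter 1 and a normalized polynomial kernel
K(x,y) = k(x,y)/√(k(x,x)·k(y,y)), k(x,y) = (x·y + 1)^degree, degree 2 by
default (the usual tool default for this kernel leaves the degree
unstated; it is a config key); explicit training-data normalization is a
no-op on 0/1 features. The tree uses entropy splits with cost-complexity
pruning as a C4.5-style learner — exact C4.5 error-based pruning is not
reproduced, and no claim here depends on tree internals. The random forest
uses 10 trees of unlimited depth with a fixed seed (default 1). Prediction
is hard-label throughout; the evaluation uses no ranking scores.

## The synthetic data generator

The generator emulates the statistical structure of a curated
actives-plus-catalogue-decoys dataset on a keyed 166-bit fingerprint:

* **Actives** belong to `k` chemotype clusters. Each chemotype is a
  template row drawn Bernoulli(`template_density`) per bit; an active is a
  uniformly chosen template with each bit flipped independently with
  probability `active_flip_prob`. The expected active–template Tanimoto
  has the first-order closed form m(1−p) / (m + (d−m)p) for a template
  with m set bits, which the tests compare against simulation.
* **Decoys** are background rows with per-bit Bernoulli rates
  (`decoy_bit_probs`, drawn once per model) except for a fraction
  `near_active_fraction` of **near-actives**: template-derived rows with
  a heavier flip probability `near_active_flip_prob`. Near-actives are
  the hard decoys — screening compounds highly similar to true ligands —
  and their density is what makes one target harder to screen than
  another. The `similarity_density(actives, screen, s)` statistic
  (fraction of screening compounds whose best Tanimoto to any active is
  ≥ s; cutoff parameter, default 0.7) quantifies this on any dataset.

Defaults (chosen once as a realistic mid-sized screening target, and used
by the tests and the acceptance script): k = 8 chemotypes, d = 166,
template_density = 0.3, active_flip_prob = 0.12, decoy per-bit rates
uniform on (0.05, 0.5), near_active_fraction = 0.01,
near_active_flip_prob = 0.30. Two considerations fix the near-active
settings. First, random catalogue compounds are overwhelmingly dissimilar
from a target's ligands, so hard decoys should be rare (1%). Second, in
this generative family a near-active flips more bits than an active by
construction, which makes it closer in expectation to the actives than to
other near-actives — a 1-NN classifier can therefore never fully reject
them no matter how many training negatives it sees, and they act as a
floor on the false-positive rate. Keeping that floor small keeps
best-ratio precision high, so the cost of an under-sized training set
grows in absolute MCC terms with library size — the regime in which the
question "what training ratio does this library size need?" has a
non-trivial answer. With abundant hard decoys the MCC scale itself
collapses as the library grows and every ratio looks alike.

What the generator does **not** emulate: real fingerprint bit
correlations (bits are independent given the chemotype), chemically valid
structures, assay noise in the labels, and chemotype imbalance (clusters
are uniform). Passing the qualitative tests therefore shows the harness
reproduces the class-imbalance/library-size phenomenology under a clean
cluster model, not that any particular real target would yield the same
recommended ratios.

## Measures and numerical conventions

Recall counts only the test positives, so for a fixed trained model and
fixed test positives it is *exactly* invariant to how many decoys are
screened — an exact identity, asserted as such in the tests, not a
statistical trend. Precision and MCC degrade with library size whenever
the decoy false-positive rate is nonzero. MCC's numerator and the product
under its root are evaluated in exact integer arithmetic before one
floating square root, so counts up to 10⁷ per cell lose no precision.
Degenerate denominators (no positive predictions; an empty class) return
0 — the no-skill value — with a degeneracy flag, keeping trial averages
defined; degenerate-cell counts are carried through the aggregated tables
and logged. Precision-recall trajectories are parametric in the training
ratio (not in a score threshold), ordered by increasing ratio, with
quadrant labels split at recall = precision = 0.5 and the boundary
belonging to quadrant I.

## Problem sizes used in tests and the acceptance script

The qualitative reproduction runs a scaled experiment: a 150-compound
active pool (27 training positives at the 18% split), a 25,000-compound
decoy pool, ratios {0.5, 2, 10, 40, 100}, library sizes {5k, 20k}, 5
trials, with naive Bayes and 1-NN. The replicate check (does the
recommended ratio grow with library size?) repeats that experiment over
10 seeds at 3 trials each and reports the majority fraction. These sizes
preserve the phenomena of interest — ratio-driven precision/recall
trade-off, library-size dilution of precision, NB's flat MCC profile —
at desk scale. Independent-draw decoy sampling per library size is the
default; nested decoy supersets across sizes are not implemented.

## Known limitations

* Recommendations are only as fine as the ratio grid; no interpolation
  between grid ratios is attempted.
* The SVM/tree/forest adapters match the conventional settings
  parameter-by-parameter but are not bit-reproductions of other toolkits'
  internals.
* Structure standardization (fragment removal, neutralization,
  tautomer/mesomer canonicalization) is out of scope; curation assumes
  the structure strings it receives are already canonical. Fingerprinting
  real structures requires a chemistry backend (RDKit when installed).
* `aggregate_trials` requires a complete grid (equal trial counts per
  cell) and refuses partial results rather than silently averaging them.
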