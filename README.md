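# screenratio

Training-set design for machine-learning-based virtual screening: how many
inactive training examples should you use, given the size of the library
you are about to screen?

## The problem

Ligand-based virtual screening trains a binary classifier on known actives
(confirmed binders of a protein target) and presumed inactives (decoys
drawn from a large compound catalogue), then screens a library of 10³–10⁶
compounds. Two design choices dominate the outcome:

* the **IN/A training ratio** *r* — the number of inactive training
  examples per active training example; and
* the **screening-library size** *L* — how many compounds are classified.

Raising *r* improves precision but costs recall and training time, and the
trade-off shifts with *L*: a false-positive rate that is tolerable at 5,000
compounds buries the hits at 400,000. `screenratio` simulates this
experiment end to end — curating activity records, assembling the
ratio × library-size grid, training classifiers, scoring them, and
recommending the smallest training ratio that is still cost-effective.

## Evaluation and the cost-effectiveness rule

Each grid cell (classifier, fingerprint, *r*, *L*, trial) is scored by

* recall R = TP / (TP + FN)
* precision P = TP / (TP + FP)
* MCC = (TP·TN − FP·FN) / √((TP+FP)(TP+FN)(TN+FP)(TN+FN))

averaged over trials. For one classifier, fingerprint and library size, let
`best_mcc = max_r MCC(r)` over the ratio grid and `Δ(r) = best_mcc − MCC(r)`.
Given a **cost-effectiveness threshold** *t* (default 0.03), the
recommended training ratio is the smallest grid ratio with `Δ(r) ≤ t` —
the cheapest training set whose performance is within *t* MCC of the best
achievable.

## What's in the box

* `curation` — standardize Ki/pKi/IC50 activity records to Ki (nM)
  (pKi → 10^(9−pKi) nM, IC50 → IC50/2), label actives at Ki < 100 nM
  (strict), filter 200 Da < MW < 700 Da, deduplicate by structure.
* `fingerprints` — binary fingerprint matrices (keyed 166-bit MACCS-like
  and hashed path-based kinds), plain-text table I/O, Tanimoto similarity,
  and a pluggable structure→fingerprint backend (RDKit used when present).
* `synthetic` — a chemotype-cluster generator for actives plus a decoy
  pool with a controllable fraction of near-active hard decoys, so the
  whole pipeline runs and is tested without any external database.
* `design` — the experiment grid (default 17 ratios 0.5–100, eight library
  sizes 5k–400k, 10 trials) with a fixed positive training split (18% of
  actives), fresh per-trial decoy draws and strict train/test disjointness.
* `classifiers` — native Bernoulli naive Bayes and 1-nearest-neighbor
  reference implementations, plus scikit-learn-backed SVM (normalized
  polynomial kernel), decision-tree and random-forest (10 trees) adapters.
* `metrics`, `optimizer` — the measures above, trial aggregation,
  precision-recall trajectories, and the cost-effectiveness recommender.
* a `screenratio` CLI with `curate`, `simulate`, `run`, `optimize` and
  `report` subcommands.

## Worked example

```python
from screenratio import RunConfig, run_experiment

config = RunConfig.from_dict({
    "data": {"n_actives": 150, "n_decoys": 25_000},
    "design": {
        "ratio_grid": [0.5, 2, 10, 40, 100],
        "library_sizes": [5_000, 20_000],
        "n_trials": 5,
        "train_fraction": 0.18,
    },
    "classifiers": [{"algorithm": "nb"}, {"algorithm": "knn1"}],
    "thresholds": [0.03],
    "base_seed": 1,
})
results, cell_means, recommendations = run_experiment(config)
print(recommendations.to_string(index=False))
```

prints

```
classifier fingerprint  library_size  threshold  optimal_ratio  best_mcc  mcc_at_optimal
      knn1   keyed-166          5000       0.03           40.0  0.801560        0.788625
      knn1   keyed-166         20000       0.03           40.0  0.596227        0.585497
        nb   keyed-166          5000       0.03            2.0  0.770200        0.770200
        nb   keyed-166         20000       0.03            2.0  0.541565        0.526347
```

Reading the table: for the 1-NN classifier, a 40:1 inactive:active training
set is the smallest one whose mean MCC is within 0.03 of the best ratio on
this grid, at both library sizes; its best MCC drops from 0.80 to 0.60 as
the screening library grows from 5k to 20k (precision dilutes with library
size while recall is unchanged). Naive Bayes is nearly insensitive to the
training ratio, so a 2:1 ratio already suffices — but its ceiling is lower.
`results` holds the per-trial confusion counts and measures; `cell_means`
the per-cell trial averages used above.

The same experiment from the shell:

```bash
screenratio run config.yaml --output-dir out/   # writes results.csv,
                                                # recommendations.csv, manifest.json
screenratio report out/                         # plots + summary.json
```

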