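"""Experiment grid: training/test assembly over ratios, sizes and trials.

A simulated screening experiment fixes a positive training set once (a
random ~18% of the known actives), then sweeps a grid of inactive:active
(IN/A) training ratios crossed with screening-library sizes. For each
grid cell and trial, training negatives are drawn fresh from the decoy
pool and the screening library is the remaining actives merged with
decoys sampled from the pool *excluding* the training negatives, so no
compound is ever both trained on and screened.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

DEFAULT_RATIO_GRID = (
    0.5, 1, 2, 4, 7, 10, 15, 20, 25, 30, 40, 50, 60, 70, 80, 90, 100,
)
DEFAULT_LIBRARY_SIZES = (
    5_000, 10_000, 25_000, 50_000, 75_000, 100_000, 200_000, 400_000,
)
DEFAULT_N_TRIALS = 10
DEFAULT_TRAIN_FRACTION = 0.18


class CapacityError(ValueError):
    """Decoy pool too small for the requested assembly."""


@dataclass(frozen=True)
class ExperimentDesign:
    """Grid definition: IN/A ratios x library sizes x trials.

    Defaults follow the standard benchmark design: 17 ratios from 0.5 to
    100, eight library sizes from 5k to 400k, ten trials per cell, and a
    fixed positive training set of 18% of the actives.
    """

    ratio_grid: tuple = DEFAULT_RATIO_GRID
    library_sizes: tuple = DEFAULT_LIBRARY_SIZES
    n_trials: int = DEFAULT_N_TRIALS
    train_fraction: float = DEFAULT_TRAIN_FRACTION
    base_seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "ratio_grid", tuple(self.ratio_grid))
        object.__setattr__(self, "library_sizes", tuple(self.library_sizes))
        if list(self.ratio_grid) != sorted(set(self.ratio_grid)):
            raise ValueError("ratio_grid must be strictly increasing")
        if any(r <= 0 for r in self.ratio_grid):
            raise ValueError("ratios must be positive")
        if list(self.library_sizes) != sorted(set(self.library_sizes)):
            raise ValueError("library_sizes must be strictly increasing")
        if any(int(s) != s or s <= 0 for s in self.library_sizes):
            raise ValueError("library sizes must be positive integers")
        if self.n_trials < 1:
            raise ValueError("n_trials must be >= 1")
        if not 0.0 < self.train_fraction < 1.0:
            raise ValueError("train_fraction must be in (0, 1)")


@dataclass(frozen=True)
class TrialAssembly:
    """One realized train/test split for a grid cell.

    ``test_labels[i]`` is 1 iff ``test_ids[i]`` is an active. Training and
    test id sets are disjoint by construction.
    """

    train_pos_ids: tuple
    train_neg_ids: tuple
    test_ids: tuple
    test_labels: np.ndarray
    cell: tuple  # (ratio, library_size, trial_index)


def round_half_even(x: float) -> int:
    """Banker's rounding to int (numpy convention), used for set sizes."""
    return int(np.rint(x))


def split_actives(
    active_ids: Sequence[str], train_fraction: float, seed: int
) -> tuple[list[str], list[str]]:
    """Fix the positive training set: a random ``train_fraction`` of actives.

    The split is made once per experiment; training positives never vary
    across grid cells. Returns (train_pos_ids, test_pos_ids).
    """
    n = len(active_ids)
    if n < 2:
        raise ValueError("need at least 2 actives to split")
    if not 0.0 < train_fraction < 1.0:
        raise ValueError("train_fraction must be in (0, 1)")
    n_train = round_half_even(train_fraction * n)
    if n_train == 0 or n_train == n:
        raise ValueError(
            f"train_fraction {train_fraction} leaves an empty train or test "
            f"positive set for n={n}"
        )
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    train_idx = np.sort(perm[:n_train])
    test_idx = np.sort(perm[n_train:])
    ids = np.asarray(active_ids, dtype=object)
    return list(ids[train_idx]), list(ids[test_idx])


def assemble_trial(
    train_pos_ids: Sequence[str],
    test_pos_ids: Sequence[str],
    decoy_pool_ids: Sequence[str],
    ratio: float,
    library_size: int,
    seed: int,
    trial: int | None = None,
) -> TrialAssembly:
    """Realize one grid cell: sample training negatives and test decoys.

    Training negatives: ``round(ratio * n_train_pos)`` decoys sampled
    without replacement. Test decoys: ``library_size - n_test_pos`` decoys
    sampled without replacement from the *remaining* pool. The test set is
    the shuffled merge of test positives and test decoys.
    """
    n_pos = len(train_pos_ids)
    n_test_pos = len(test_pos_ids)
    n_neg = round_half_even(ratio * n_pos)
    n_test_dec = library_size - n_test_pos
    if n_test_dec < 0:
        raise ValueError(
            f"library_size {library_size} smaller than the {n_test_pos} test positives"
        )
    required = n_neg + n_test_dec
    if required > len(decoy_pool_ids):
        raise CapacityError(
            f"decoy pool too small: need {required} "
            f"({n_neg} training negatives + {n_test_dec} test decoys), "
            f"have {len(decoy_pool_ids)}"
        )
    rng = np.random.default_rng(seed)
    pool = np.asarray(decoy_pool_ids, dtype=object)
    picked = rng.choice(len(pool), size=required, replace=False)
    train_neg = pool[picked[:n_neg]]
    test_dec = pool[picked[n_neg:]]

    test_ids = np.concatenate([np.asarray(test_pos_ids, dtype=object), test_dec])
    test_labels = np.zeros(len(test_ids), dtype=np.uint8)
    test_labels[: n_test_pos] = 1
    order = rng.permutation(len(test_ids))
    return TrialAssembly(
        train_pos_ids=tuple(train_pos_ids),
        train_neg_ids=tuple(train_neg),
        test_ids=tuple(test_ids[order]),
        test_labels=test_labels[order],
        cell=(float(ratio), int(library_size), trial),
    )


def cell_seed(base_seed: int, ratio: float, library_size: int, trial: int) -> int:
    """Deterministic per-cell seed: base_seed XOR a stable hash of the cell.

    Uses CRC32 of the cell triple's text form, so the seed is stable
    across runs and Python processes (unlike the built-in ``hash``).
    """
    key = f"{float(ratio)!r}|{int(library_size)}|{int(trial)}"
    return (int(base_seed) ^ zlib.crc32(key.encode())) % (2**31)


def enumerate_cells(design: ExperimentDesign) -> list[tuple[float, int, int]]:
    """All grid cells in deterministic size-major order.

    Order: library size, then ratio, then trial index.
    """
    return [
        (float(r), int(s), t)
        for s in design.library_sizes
        for r in design.ratio_grid
        for t in range(design.n_trials)
    ]
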