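"""Synthetic fingerprint populations with controllable chemotype structure.

Real virtual-screening benchmarks draw actives from a bioactivity
database and decoys from a large commercial catalogue. This module
emulates the *statistical* structure of such data without chemistry:

* Actives are organized in chemotype clusters. Each chemotype is a
  binary template; an active is its template with independent per-bit
  flip noise (``active_flip_prob``). Low flip probability gives tight,
  easily separable chemotype clusters; probabilities approaching 0.5
  dissolve the cluster structure.
* Decoys are mostly "background" vectors with independent per-bit
  Bernoulli rates (``decoy_bit_probs``), plus a controllable fraction of
  "near-actives" — hard decoys generated from the chemotype templates
  with a larger flip probability. The near-active fraction is the dial
  for the density of screening compounds highly similar to the actives,
  which drives target-to-target differences in screening difficulty.

All sampling is reproducible: the model carries a master seed, and each
sampling stream derives its own seed as ``master + fixed offset`` so the
streams are independent but stable.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .fingerprints import FingerprintMatrix, KIND_KEYED_166, KINDS, bulk_tanimoto

# fixed per-stream seed offsets (documented: templates / actives / decoys)
_STREAM_TEMPLATES = 0
_STREAM_ACTIVES = 1_000_003
_STREAM_DECOYS = 2_000_003

#: Default similarity cutoff for the similarity-density statistic.
DEFAULT_SIMILARITY_CUTOFF = 0.7


@dataclass
class ChemotypeModel:
    """Generative model for one target's actives and its decoy pool.

    Parameters
    ----------
    templates
        k x d binary matrix, one row per chemotype scaffold.
    active_flip_prob
        Per-bit flip probability for actives around their template,
        in [0, 0.5). Controls within-chemotype diversity.
    decoy_bit_probs
        Length-d per-bit Bernoulli rates for background decoys.
    near_active_fraction
        Fraction of decoys generated as hard near-actives, in [0, 1].
    near_active_flip_prob
        Flip probability for near-active decoys; must exceed
        ``active_flip_prob`` (they are more diffuse than true actives)
        and may not exceed 0.5.
    seed
        Master seed for all derived sampling streams.
    """

    templates: np.ndarray
    active_flip_prob: float
    decoy_bit_probs: np.ndarray
    near_active_fraction: float
    near_active_flip_prob: float
    seed: int

    def __post_init__(self) -> None:
        self.templates = np.ascontiguousarray(self.templates, dtype=np.uint8)
        self.decoy_bit_probs = np.asarray(self.decoy_bit_probs, dtype=np.float64)
        if self.templates.ndim != 2 or self.templates.shape[0] < 1:
            raise ValueError("templates must be a k x d matrix with k >= 1")
        if self.decoy_bit_probs.shape != (self.templates.shape[1],):
            raise ValueError("decoy_bit_probs length must equal the bit-width")
        if not 0.0 <= self.active_flip_prob < 0.5:
            raise ValueError("active_flip_prob must be in [0, 0.5)")
        if not 0.0 <= self.near_active_fraction <= 1.0:
            raise ValueError("near_active_fraction must be in [0, 1]")
        if not (
            self.active_flip_prob < self.near_active_flip_prob <= 0.5
        ):
            raise ValueError(
                "near_active_flip_prob must lie in (active_flip_prob, 0.5]"
            )
        if np.any(self.decoy_bit_probs < 0) or np.any(self.decoy_bit_probs > 1):
            raise ValueError("decoy_bit_probs must lie in [0, 1]")

    @property
    def k(self) -> int:
        return self.templates.shape[0]

    @property
    def d(self) -> int:
        return self.templates.shape[1]


def make_chemotypes(
    k: int,
    d: int,
    template_density: float,
    seed: int,
    allow_empty: bool = False,
) -> np.ndarray:
    """Sample k chemotype templates, i.i.d. Bernoulli(density) per bit.

    An all-zero template is normally a degenerate input (a scaffold with
    no substructure keys) and is rejected unless ``allow_empty``; offending
    templates are resampled deterministically.
    """
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    if not 0.0 < template_density < 1.0:
        if allow_empty and template_density == 0.0:
            return np.zeros((k, d), dtype=np.uint8)
        raise ValueError(f"template_density must be in (0, 1), got {template_density}")
    rng = np.random.default_rng(seed + _STREAM_TEMPLATES)
    templates = (rng.random((k, d)) < template_density).astype(np.uint8)
    if not allow_empty:
        for i in range(k):  # resample rare all-zero draws
            while templates[i].sum() == 0:
                templates[i] = (rng.random(d) < template_density).astype(np.uint8)
    return templates


def default_model(
    k: int = 8,
    d: int = 166,
    template_density: float = 0.3,
    active_flip_prob: float = 0.12,
    decoy_density_range: tuple[float, float] = (0.05, 0.5),
    near_active_fraction: float = 0.01,
    near_active_flip_prob: float = 0.30,
    seed: int = 0,
) -> ChemotypeModel:
    """Build a model with realistic defaults for a keyed 166-bit fingerprint.

    Defaults emulate a typical screening target: a handful of chemotype
    families (k=8) with moderate within-family variation, background
    decoys whose per-bit rates vary across bits (drawn once, uniformly
    over ``decoy_density_range``), and a rare fraction (1%) of hard
    near-active decoys. Background decoys are well separated from the
    chemotype clusters — as random catalogue compounds are from a
    target's ligands — so a classifier's background false-positive rate
    falls toward zero as training negatives accumulate, while the rare
    near-actives set a floor on precision that grows in absolute terms
    with library size.
    """
    templates = make_chemotypes(k, d, template_density, seed)
    rng = np.random.default_rng(seed + _STREAM_TEMPLATES + 1)
    lo, hi = decoy_density_range
    decoy_bit_probs = rng.uniform(lo, hi, size=d)
    return ChemotypeModel(
        templates=templates,
        active_flip_prob=active_flip_prob,
        decoy_bit_probs=decoy_bit_probs,
        near_active_fraction=near_active_fraction,
        near_active_flip_prob=near_active_flip_prob,
        seed=seed,
    )


def _kind_for_width(d: int) -> str:
    return KIND_KEYED_166 if d == 166 else "hashed-path"


def sample_actives(
    model: ChemotypeModel, n: int, seed: int | None = None
) -> FingerprintMatrix:
    """Draw n actives: a uniform chemotype template plus bit-flip noise.

    Row ids encode the chemotype index as ``ACT<row>_C<chemotype>`` so the
    ground-truth cluster assignment travels with the data.
    """
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    rng = np.random.default_rng(
        model.seed + _STREAM_ACTIVES if seed is None else seed
    )
    chemo = rng.integers(0, model.k, size=n)
    bits = model.templates[chemo].copy()
    flips = rng.random((n, model.d)) < model.active_flip_prob
    bits ^= flips.astype(np.uint8)
    ids = [f"ACT{i:06d}_C{c}" for i, c in enumerate(chemo)]
    return FingerprintMatrix(ids, bits, _kind_for_width(model.d))


def chemotype_of(ids: Sequence[str]) -> np.ndarray:
    """Recover the chemotype indices encoded in active row ids."""
    return np.array([int(cid.rsplit("_C", 1)[1]) for cid in ids])


def sample_decoys(
    model: ChemotypeModel, n: int, seed: int | None = None
) -> FingerprintMatrix:
    """Draw n decoys: background rows plus near-active hard decoys.

    Each row is independently a near-active with probability
    ``near_active_fraction`` (template + heavier flip noise) and a
    background Bernoulli row otherwise; rows are returned in a
    deterministically shuffled order under the stream seed.
    """
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    rng = np.random.default_rng(
        model.seed + _STREAM_DECOYS if seed is None else seed
    )
    near = rng.random(n) < model.near_active_fraction
    bits = (rng.random((n, model.d)) < model.decoy_bit_probs[None, :]).astype(np.uint8)
    n_near = int(near.sum())
    if n_near:
        chemo = rng.integers(0, model.k, size=n_near)
        hard = model.templates[chemo].copy()
        flips = rng.random((n_near, model.d)) < model.near_active_flip_prob
        hard ^= flips.astype(np.uint8)
        bits[near] = hard
    order = rng.permutation(n)
    bits = bits[order]
    near = near[order]
    ids = [
        f"DEC{i:07d}{'_H' if h else ''}" for i, h in enumerate(near)
    ]
    return FingerprintMatrix(ids, bits, _kind_for_width(model.d))


def similarity_density(
    actives: FingerprintMatrix,
    screen: FingerprintMatrix,
    s: float = DEFAULT_SIMILARITY_CUTOFF,
) -> float:
    """Fraction of screening compounds with max Tanimoto >= s to any active.

    This is the density of screening compounds highly similar to the
    actives — the statistic that explains why some targets are harder to
    screen than others.
    """
    if not 0.0 <= s <= 1.0:
        raise ValueError(f"similarity cutoff must be in [0, 1], got {s}")
    if actives.width != screen.width:
        raise ValueError(
            f"bit-width mismatch: actives {actives.width} vs screen {screen.width}"
        )
    if screen.n == 0:
        raise ValueError("screening set is empty")
    # chunk the screen side to bound memory on large libraries
    n_hit = 0
    chunk = max(1, 10_000_000 // max(actives.n, 1))
    for start in range(0, screen.n, chunk):
        sim = bulk_tanimoto(screen.bits[start : start + chunk], actives.bits)
        n_hit += int(np.sum(sim.max(axis=1) >= s))
    return n_hit / screen.n


def expected_template_tanimoto(n_template_bits: int, d: int, flip_prob: float) -> float:
    """First-order expected Tanimoto between an active and its template.

    For a template with m set bits, the intersection is Binomial(m, 1-p)
    and the union is m plus Binomial(d-m, p) newly flipped-on bits; the
    ratio-of-expectations approximation E[X]/E[Y] is accurate to O(1/m)
    for the fingerprint widths used here.
    """
    m, p = n_template_bits, flip_prob
    return m * (1.0 - p) / (m + (d - m) * p)
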