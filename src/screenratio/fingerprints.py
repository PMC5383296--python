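"""Binary molecular fingerprints: containers, I/O, Tanimoto similarity.

Two fingerprint kinds are supported:

* ``keyed-166`` — a 166-bit keyed substructure fingerprint (MACCS-like);
  the width is enforced.
* ``hashed-path`` — a hashed path-based fingerprint (CDK-style), default
  width 1024 bits with path length 6.

Fingerprints are stored as an n x d uint8 matrix with row identifiers.
Computing fingerprints from structures is delegated to a pluggable
chemistry backend (an RDKit backend is registered automatically when
RDKit is importable); the synthetic generator is the primary data source
for testing.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Sequence

import numpy as np

KIND_KEYED_166 = "keyed-166"
KIND_HASHED_PATH = "hashed-path"
KINDS = (KIND_KEYED_166, KIND_HASHED_PATH)

KEYED_WIDTH = 166
DEFAULT_HASHED_WIDTH = 1024
DEFAULT_PATH_LENGTH = 6


class FingerprintFormatError(ValueError):
    """Raised when a fingerprint table violates the format contract."""


@dataclass
class FingerprintMatrix:
    """Binary fingerprint matrix with row identifiers.

    ``bits`` is an n x d uint8 array with entries in {0, 1}; ``ids`` has
    one unique identifier per row; ``kind`` tags the fingerprint family.
    """

    ids: list[str]
    bits: np.ndarray
    kind: str = KIND_KEYED_166

    def __post_init__(self) -> None:
        self.bits = np.ascontiguousarray(self.bits, dtype=np.uint8)
        if self.bits.ndim != 2:
            raise ValueError(f"bits must be 2-D, got shape {self.bits.shape}")
        if len(self.ids) != self.bits.shape[0]:
            raise ValueError(
                f"{len(self.ids)} ids but {self.bits.shape[0]} fingerprint rows"
            )
        if self.bits.size and self.bits.max() > 1:
            raise ValueError("fingerprint entries must be 0 or 1")
        if len(set(self.ids)) != len(self.ids):
            raise ValueError("duplicate compound ids in fingerprint matrix")
        if self.kind not in KINDS:
            raise ValueError(f"unknown fingerprint kind {self.kind!r}")
        if self.kind == KIND_KEYED_166 and self.bits.shape[1] != KEYED_WIDTH:
            raise ValueError(
                f"kind {KIND_KEYED_166} requires width {KEYED_WIDTH}, "
                f"got {self.bits.shape[1]}"
            )

    @property
    def n(self) -> int:
        return self.bits.shape[0]

    @property
    def width(self) -> int:
        return self.bits.shape[1]

    def subset(self, ids: Sequence[str]) -> "FingerprintMatrix":
        """Rows for the given ids, in the given order."""
        index = {cid: i for i, cid in enumerate(self.ids)}
        rows = [index[cid] for cid in ids]
        return FingerprintMatrix(list(ids), self.bits[rows], self.kind)


def load_fingerprints(path, kind: str = KIND_KEYED_166) -> FingerprintMatrix:
    """Load a fingerprint table from delimited text.

    Two layouts are auto-detected: ``compound_id<sep>bitstring`` where the
    bitstring is contiguous 0/1 characters, or ``compound_id`` followed by
    d single-bit columns. Separator may be comma, tab or whitespace.
    Ragged rows, non-binary symbols and duplicate ids are format errors
    reported with the offending row.
    """
    path = Path(path)
    ids: list[str] = []
    rows: list[np.ndarray] = []
    width: int | None = None
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.replace(",", " ").replace("\t", " ").split()
            if lineno == 1 and fields[0].lower() in ("compound_id", "id"):
                continue  # header row
            cid = fields[0]
            if len(fields) == 2:
                bitchars = fields[1]
            else:
                bitchars = "".join(fields[1:])
            if not bitchars or any(c not in "01" for c in bitchars):
                raise FingerprintFormatError(
                    f"{path}:{lineno}: non-binary fingerprint symbols for id {cid!r}"
                )
            if width is None:
                width = len(bitchars)
            elif len(bitchars) != width:
                raise FingerprintFormatError(
                    f"{path}:{lineno}: row width {len(bitchars)} != {width} for id {cid!r}"
                )
            if cid in set(ids):
                raise FingerprintFormatError(
                    f"{path}:{lineno}: duplicate compound id {cid!r}"
                )
            ids.append(cid)
            rows.append(np.frombuffer(bitchars.encode(), dtype=np.uint8) - ord("0"))
    if not rows:
        raise FingerprintFormatError(f"{path}: no fingerprint rows found")
    return FingerprintMatrix(ids, np.vstack(rows), kind)


def save_fingerprints(fps: FingerprintMatrix, path) -> None:
    """Write a fingerprint table as ``compound_id<TAB>bitstring`` lines."""
    with open(path, "w") as fh:
        fh.write("compound_id\tbits\n")
        for cid, row in zip(fps.ids, fps.bits):
            fh.write(f"{cid}\t{''.join('1' if b else '0' for b in row)}\n")


# --- pluggable structure -> fingerprint backends -------------------------

_BACKENDS: dict[str, Callable] = {}


class BackendError(RuntimeError):
    """Raised when no chemistry backend can compute fingerprints."""


def register_backend(name: str, fn: Callable) -> None:
    """Register a fingerprinting backend.

    ``fn(structures, kind, width) -> (ids_kept_indices, bits)`` must return
    the indices of parseable structures and their fingerprint rows.
    """
    _BACKENDS[name] = fn


def _rdkit_backend(structures, kind, width):
    from rdkit import Chem, RDLogger
    from rdkit.Chem import MACCSkeys

    RDLogger.DisableLog("rdApp.*")
    kept, rows = [], []
    for i, smi in enumerate(structures):
        mol = Chem.MolFromSmiles(smi)
        if mol is None:
            continue
        if kind == KIND_KEYED_166:
            fp = MACCSkeys.GenMACCSKeys(mol)  # 167 bits, bit 0 unused
            arr = np.zeros(KEYED_WIDTH, dtype=np.uint8)
            for b in fp.GetOnBits():
                if b >= 1:
                    arr[b - 1] = 1
        else:
            fp = Chem.RDKFingerprint(mol, maxPath=DEFAULT_PATH_LENGTH, fpSize=width)
            arr = np.zeros(width, dtype=np.uint8)
            for b in fp.GetOnBits():
                arr[b] = 1
        kept.append(i)
        rows.append(arr)
    return kept, rows


try:  # RDKit is optional; the synthetic generator does not need it
    import rdkit  # noqa: F401

    register_backend("rdkit", _rdkit_backend)
except ImportError:  # pragma: no cover
    pass


def compute_fingerprints(
    structures: Sequence[str],
    kind: str = KIND_KEYED_166,
    width: int = DEFAULT_HASHED_WIDTH,
    backend: str | None = None,
    ids: Sequence[str] | None = None,
) -> FingerprintMatrix:
    """Compute fingerprints from line-notation structures via a backend.

    Unparseable structures are skipped (their ids are dropped). Raises
    :class:`BackendError` when no backend is registered.
    """
    if kind not in KINDS:
        raise ValueError(f"unknown fingerprint kind {kind!r}")
    if backend is None:
        if not _BACKENDS:
            raise BackendError(
                "no chemistry backend registered; install rdkit or call "
                "register_backend()"
            )
        backend = next(iter(_BACKENDS))
    if backend not in _BACKENDS:
        raise BackendError(f"backend {backend!r} not registered")
    d = KEYED_WIDTH if kind == KIND_KEYED_166 else width
    kept, rows = _BACKENDS[backend](structures, kind, d)
    if ids is None:
        ids = [f"S{i}" for i in range(len(structures))]
    out_ids = [str(ids[i]) for i in kept]
    bits = np.vstack(rows) if rows else np.zeros((0, d), dtype=np.uint8)
    return FingerprintMatrix(out_ids, bits, kind)


# --- similarity ----------------------------------------------------------


def tanimoto(a: np.ndarray, b: np.ndarray) -> float:
    """Tanimoto similarity |a AND b| / |a OR b| of two binary vectors.

    Two all-zero vectors are identical objects, so their similarity is
    defined as 1.
    """
    a = np.asarray(a)
    b = np.asarray(b)
    if a.shape != b.shape:
        raise ValueError(f"length mismatch: {a.shape} vs {b.shape}")
    inter = int(np.sum((a != 0) & (b != 0)))
    union = int(np.sum((a != 0) | (b != 0)))
    if union == 0:
        return 1.0
    return inter / union


def bulk_tanimoto(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    """Pairwise Tanimoto matrix between the rows of two binary matrices.

    Returns an |A| x |B| float array. Uses the popcount identity
    |a OR b| = |a| + |b| - |a AND b| with a single matrix product.
    """
    A = np.asarray(A, dtype=np.float32)
    B = np.asarray(B, dtype=np.float32)
    if A.shape[1] != B.shape[1]:
        raise ValueError(f"bit-width mismatch: {A.shape[1]} vs {B.shape[1]}")
    inter = A @ B.T
    ca = A.sum(axis=1)[:, None]
    cb = B.sum(axis=1)[None, :]
    union = ca + cb - inter
    with np.errstate(invalid="ignore", divide="ignore"):
        sim = inter / union
    sim[union == 0] = 1.0  # both rows all-zero
    return sim
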