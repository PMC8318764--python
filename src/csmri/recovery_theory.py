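"""Uniqueness theory for k-sparse recovery on small explicit matrices.

Implements the spark (smallest number of linearly dependent columns),
uniqueness certificates for k-sparse solutions (unique iff spark > 2k),
and an exhaustive L0 decoder.  All three enumerate column subsets and are
guarded to N <= 16 columns.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path

import numpy as np

#: Enumeration guard: subset searches are exponential in N.
MAX_THEORY_COLUMNS = 16

#: Sentinel returned when no linearly dependent column subset exists.
SPARK_FULL = "full"

#: Relative singular-value tolerance for rank decisions.
RANK_TOL = 1e-10

#: Magnitude below which an entry counts as zero when measuring sparsity.
ZERO_TOL = 1e-12


def sparsity(values: np.ndarray, zero_tol: float = ZERO_TOL) -> int:
    """Number of entries with magnitude above ``zero_tol``."""
    return int(np.count_nonzero(np.abs(np.asarray(values)) > zero_tol))


@dataclass(frozen=True)
class SparseSignal:
    """A vector together with its declared sparsity."""

    values: np.ndarray
    zero_tol: float = ZERO_TOL
    k: int = field(init=False)

    def __post_init__(self) -> None:
        object.__setattr__(self, "values", np.asarray(self.values))
        object.__setattr__(self, "k", sparsity(self.values, self.zero_tol))

    @property
    def support(self) -> tuple[int, ...]:
        return tuple(np.flatnonzero(np.abs(self.values) > self.zero_tol))


def _check_theory_matrix(theta: np.ndarray) -> np.ndarray:
    theta = np.atleast_2d(np.asarray(theta))
    if theta.shape[1] > MAX_THEORY_COLUMNS:
        raise ValueError(f"subset enumeration is limited to N <= {MAX_THEORY_COLUMNS} columns")
    if not np.all(np.isfinite(theta.real)) or not np.all(np.isfinite(theta.imag if np.iscomplexobj(theta) else theta.real)):
        raise ValueError("matrix entries must be finite")
    return theta


def _subset_dependent(theta: np.ndarray, subset: tuple[int, ...]) -> bool:
    """True when the chosen columns are linearly dependent at RANK_TOL."""
    sub = theta[:, subset]
    s = np.linalg.svd(sub, compute_uv=False)
    if s.size == 0 or s[0] <= 0:
        return True
    return bool(s[-1] < RANK_TOL * s[0]) or len(subset) > min(sub.shape)


def spark(theta: np.ndarray) -> int | str:
    """Smallest number of linearly dependent columns, or ``"full"``.

    For an M-by-N matrix with N > M the answer is at most M + 1; the
    sentinel ``"full"`` is returned only when every subset that exists
    (sizes up to min(M + 1, N)) is independent, i.e. a square-or-tall
    matrix of full column rank.
    """
    theta = _check_theory_matrix(theta)
    m, n = theta.shape
    for size in range(1, min(m + 1, n) + 1):
        for subset in combinations(range(n), size):
            if _subset_dependent(theta, subset):
                return size
    return SPARK_FULL


def _smallest_dependent_subset(theta: np.ndarray, max_size: int) -> tuple[int, ...] | None:
    m, n = theta.shape
    for size in range(1, min(max_size, min(m + 1, n)) + 1):
        for subset in combinations(range(n), size):
            if _subset_dependent(theta, subset):
                return subset
    return None


@dataclass(frozen=True)
class UniquenessCertificate:
    """Certificate that k-sparse solutions of ``Theta a = B`` are (non-)unique.

    ``unique`` is True exactly when ``spark(Theta) > 2k``.  When False and
    a dependent subset of size <= 2k exists, ``witness`` holds two distinct
    at-most-k-sparse vectors with equal measurements, verified to 1e-8.
    """

    spark_value: int | str
    k: int
    unique: bool
    witness: tuple[np.ndarray, np.ndarray] | None = None
    rank_tol: float = RANK_TOL
    zero_tol: float = ZERO_TOL

    def to_dict(self) -> dict:
        d = {
            "spark_value": self.spark_value,
            "k": self.k,
            "unique": self.unique,
            "rank_tol": self.rank_tol,
            "zero_tol": self.zero_tol,
            "witness": None,
        }
        if self.witness is not None:
            a1, a2 = self.witness
            d["witness"] = {
                "a1_real": a1.real.tolist(),
                "a1_imag": a1.imag.tolist() if np.iscomplexobj(a1) else [0.0] * a1.size,
                "a2_real": a2.real.tolist(),
                "a2_imag": a2.imag.tolist() if np.iscomplexobj(a2) else [0.0] * a2.size,
            }
        return d

    def save_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))


def certify_uniqueness(theta: np.ndarray, k: int) -> UniquenessCertificate:
    """Certify whether every k-sparse solution of ``Theta a = B`` is unique.

    Non-unique instances come with a witness pair built by splitting a
    null vector supported on the smallest dependent subset into two
    at-most-k-sparse halves: ``a1 - a2`` lies in the null space, so both
    halves measure identically.
    """
    if k < 0:
        raise ValueError("k must be >= 0")
    theta = _check_theory_matrix(theta)
    sp = spark(theta)
    unique = sp == SPARK_FULL or (isinstance(sp, int) and sp > 2 * k)
    witness = None
    if not unique:
        subset = _smallest_dependent_subset(theta, max_size=2 * k)
        if subset is not None:
            sub = theta[:, subset]
            _, _, vh = np.linalg.svd(sub)
            null_vec = vh[-1].conj()
            null_vec = null_vec / np.linalg.norm(null_vec)
            n = theta.shape[1]
            dtype = complex if np.iscomplexobj(theta) else float
            a1 = np.zeros(n, dtype=dtype)
            a2 = np.zeros(n, dtype=dtype)
            half = (len(subset) + 1) // 2
            for pos, col in enumerate(subset):
                if pos < half:
                    a1[col] = null_vec[pos]
                else:
                    a2[col] = -null_vec[pos]
            gap = np.linalg.norm(theta @ a1 - theta @ a2)
            if gap > 1e-8:
                raise RuntimeError(f"witness verification failed, measurement gap {gap:.3e}")
            if np.linalg.norm(a1 - a2) <= 1e-8:
                raise RuntimeError("degenerate witness: halves coincide")
            witness = (a1, a2)
    return UniquenessCertificate(spark_value=sp, k=k, unique=unique, witness=witness)


def l0_decode(b: np.ndarray, theta: np.ndarray, k_max: int) -> SparseSignal | None:
    """Sparsest solution of ``Theta a = B`` by exhaustive support search.

    Supports are visited in increasing size, lexicographically within a
    size; each is least-squares fitted and accepted when the residual is
    at most ``1e-8 * ||B||``.  Ties at the winning sparsity are broken by
    smaller residual, then by lexicographic support order.  Returns None
    when no support of size <= ``k_max`` reaches the residual bound.
    """
    theta = _check_theory_matrix(theta)
    b = np.asarray(b).ravel()
    m, n = theta.shape
    if b.size != m:
        raise ValueError(f"measurement length {b.size} does not match M={m}")
    if k_max < 0 or k_max > n:
        raise ValueError(f"k_max must be in [0, {n}]")
    bnorm = np.linalg.norm(b)
    bound = 1e-8 * bnorm
    dtype = complex if (np.iscomplexobj(theta) or np.iscomplexobj(b)) else float
    if bnorm <= ZERO_TOL:
        return SparseSignal(np.zeros(n, dtype=dtype))
    for size in range(0, k_max + 1):
        best: tuple[float, np.ndarray] | None = None
        for subset in combinations(range(n), size):
            if size == 0:
                residual = bnorm
                coeffs = np.zeros(0, dtype=dtype)
            else:
                sub = theta[:, subset]
                coeffs, _, _, _ = np.linalg.lstsq(sub, b, rcond=None)
                residual = float(np.linalg.norm(sub @ coeffs - b))
            if residual <= bound and (best is None or residual < best[0]):
                x = np.zeros(n, dtype=dtype)
                if size:
                    x[list(subset)] = coeffs
                best = (residual, x)
        if best is not None:
            return SparseSignal(best[1])
    return None
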