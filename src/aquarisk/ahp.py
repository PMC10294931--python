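"""Analytic-hierarchy-process weight derivation and consistency diagnostics.

Criterion weights come from pairwise comparison matrices: `a[i][j]` states how
much more important criterion *i* is than criterion *j* on the Saaty 1-9
scale, with `a[j][i] = 1/a[i][j]`.  The weight vector is the principal right
eigenvector of the matrix (Perron-Frobenius guarantees a unique positive one)
normalised to sum 1, and judgement coherence is diagnosed through

    CI = (lambda_max - n) / (n - 1),    CR = CI / RI(n),

where ``lambda_max`` is the dominant eigenvalue, which equals ``n`` exactly
for a perfectly consistent matrix, and RI(n) is the expected CI of random
reciprocal matrices of order n.  Judgements are conventionally accepted when
CR < 0.1.

Matrices here are tiny (n <= 9 in the default model), so the eigenvector is
computed by deterministic power iteration and cross-checked in the test suite
against a dense eigendecomposition.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .errors import ConvergenceError, MatrixError

#: Saaty's average random consistency index for matrix orders 1..9.  The
#: largest sibling group in the default model has nine criteria; larger
#: matrices require a user-supplied table.
DEFAULT_RI_TABLE: dict[int, float] = {
    1: 0.0, 2: 0.0, 3: 0.58, 4: 0.90, 5: 1.12,
    6: 1.24, 7: 1.32, 8: 1.41, 9: 1.45,
}

#: admissible entries of the 1-9 importance scale and their reciprocals
SAATY_SCALE = sorted({float(k) for k in range(1, 10)}
                     | {1.0 / k for k in range(1, 10)})

RECIPROCITY_TOL = 1e-9
CONSISTENCY_THRESHOLD = 0.1

_POWER_TOL = 1e-12
_POWER_MAXITER = 10_000


class PairwiseComparisonMatrix:
    """Positive reciprocal square matrix of importance ratios.

    Parameters
    ----------
    entries
        Square array-like of positive ratios with unit diagonal and
        ``a[j][i] = 1/a[i][j]`` (within ``1e-9``).
    ids
        Optional criterion identifiers, one per row.
    symmetrize
        Replace each pair by its geometric mean ratio
        ``a[i][j] <- sqrt(a[i][j]/a[j][i])`` before validating; off by
        default, intended for hand-entered matrices with rounding slack.
    """

    def __init__(self, entries, ids=None, *, symmetrize: bool = False):
        a = np.asarray(entries, dtype=float)
        if a.ndim != 2 or a.shape[0] != a.shape[1]:
            raise MatrixError(f"matrix must be square, got shape {a.shape}")
        if a.size == 0:
            raise MatrixError("matrix must have order >= 1")
        if not np.all(np.isfinite(a)) or np.any(a <= 0):
            raise MatrixError("all entries must be finite and > 0")
        if symmetrize:
            a = np.sqrt(a / a.T)
        if not np.allclose(np.diag(a), 1.0, rtol=0, atol=RECIPROCITY_TOL):
            raise MatrixError("diagonal entries must equal 1")
        if not np.allclose(a * a.T, 1.0, rtol=RECIPROCITY_TOL, atol=RECIPROCITY_TOL):
            raise MatrixError(
                "matrix is not reciprocal: a[j][i] must equal 1/a[i][j]"
            )
        self.values = a
        self.n = a.shape[0]
        self.ids = list(ids) if ids is not None else [f"c{i+1}" for i in range(self.n)]
        if len(self.ids) != self.n:
            raise MatrixError(f"{len(self.ids)} ids for order-{self.n} matrix")
        off_scale = [
            v for v in a.ravel()
            if min(abs(v - s) for s in SAATY_SCALE) > 1e-9
        ]
        if off_scale:
            warnings.warn(
                f"{len(off_scale)} entries fall outside the Saaty 1-9 scale "
                "and its reciprocals",
                stacklevel=2,
            )

    @classmethod
    def from_file(cls, path: str | Path, *, delimiter: str | None = None,
                  symmetrize: bool = False) -> "PairwiseComparisonMatrix":
        """Read a delimited square table; a non-numeric first row is a header
        of criterion ids, an optional first column repeating them is dropped."""
        import pandas as pd

        path = Path(path)
        if delimiter is None:
            delimiter = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
        try:
            frame = pd.read_csv(path, sep=delimiter, header=None, comment="#")
        except Exception as exc:
            raise MatrixError(f"cannot parse matrix file {path}: {exc}") from exc
        ids = None
        first = frame.iloc[0]
        if not np.all([_is_number(v) for v in first]):
            ids = [str(v) for v in first]
            frame = frame.iloc[1:]
        if frame.shape[1] == frame.shape[0] + 1 or (
            ids is not None and not np.all([_is_number(v) for v in frame.iloc[:, 0]])
        ):
            frame = frame.iloc[:, 1:]
            if ids is not None and len(ids) == frame.shape[1] + 1:
                ids = ids[1:]
        try:
            values = frame.astype(float).to_numpy()
        except ValueError as exc:
            raise MatrixError(f"non-numeric entries in {path}: {exc}") from exc
        return cls(values, ids=ids, symmetrize=symmetrize)


def _is_number(v) -> bool:
    try:
        float(v)
    except (TypeError, ValueError):
        return False
    return True


@dataclass(frozen=True)
class WeightVector:
    """Positive weights summing to one, aligned with the matrix criteria."""

    ids: tuple[str, ...]
    weights: tuple[float, ...]

    def as_array(self) -> np.ndarray:
        return np.asarray(self.weights)

    def as_dict(self) -> dict[str, float]:
        return dict(zip(self.ids, self.weights))


@dataclass(frozen=True)
class ConsistencyReport:
    """Diagnostics for one comparison matrix: lambda_max, CI, RI, CR, verdict."""

    n: int
    lambda_max: float
    ci: float
    ri: float
    cr: float
    consistent: bool

    def as_dict(self) -> dict:
        return {
            "n": self.n,
            "lambda_max": self.lambda_max,
            "CI": self.ci,
            "RI": self.ri,
            "CR": self.cr,
            "consistent": self.consistent,
        }


def _power_iteration(a: np.ndarray) -> tuple[float, np.ndarray]:
    n = a.shape[0]
    v = np.full(n, 1.0 / n)
    for _ in range(_POWER_MAXITER):
        av = a @ v
        nxt = av / av.sum()
        if np.max(np.abs(nxt - v)) < _POWER_TOL:
            v = nxt
            break
        v = nxt
    else:
        raise ConvergenceError(
            f"power iteration did not converge within {_POWER_MAXITER} "
            f"iterations for order-{n} matrix"
        )
    av = a @ v
    lam = float((v @ av) / (v @ v))
    return lam, v


def derive_weights(m: PairwiseComparisonMatrix) -> WeightVector:
    """Principal-eigenvector weights of a comparison matrix, normalised to 1."""
    _, v = _power_iteration(m.values)
    v = v / v.sum()
    return WeightVector(ids=tuple(m.ids), weights=tuple(float(x) for x in v))


def lambda_max(m: PairwiseComparisonMatrix) -> float:
    """Dominant eigenvalue; >= n, with equality iff the matrix is consistent."""
    lam, _ = _power_iteration(m.values)
    return lam


def consistency_index(lam: float, n: int) -> float:
    """CI = (lambda_max - n)/(n - 1); zero for a consistent matrix.

    A 1x1 matrix is trivially consistent, so its CI is defined as 0 even
    though the formula's denominator vanishes.
    """
    if n < 1:
        raise ValueError(f"matrix order must be >= 1, got {n}")
    if lam < n - 1e-9:
        raise ValueError(
            f"lambda_max ({lam}) below matrix order ({n}); not a valid "
            "dominant eigenvalue of a reciprocal matrix"
        )
    if n == 1:
        return 0.0
    return (lam - n) / (n - 1)


def consistency_ratio(ci: float, n: int,
                      ri_table: dict[int, float] | None = None
                      ) -> tuple[float, float, bool]:
    """Return ``(RI, CR, consistent)`` for a given CI and matrix order.

    For n <= 2 the random index is zero and a reciprocal matrix is always
    consistent, so CR is reported as 0 and the verdict requires CI ~ 0.
    """
    table = DEFAULT_RI_TABLE if ri_table is None else ri_table
    if n not in table:
        raise MatrixError(
            f"no random consistency index for matrix order {n}; supply an "
            "RI table covering this order"
        )
    ri = table[n]
    if ri > 0:
        cr = ci / ri
        return ri, cr, cr < CONSISTENCY_THRESHOLD
    return ri, 0.0, ci <= 1e-9


def consistency_report(m: PairwiseComparisonMatrix,
                       ri_table: dict[int, float] | None = None
                       ) -> ConsistencyReport:
    """Full diagnostics for one matrix."""
    lam = lambda_max(m)
    ci = consistency_index(lam, m.n)
    ri, cr, ok = consistency_ratio(ci, m.n, ri_table)
    return ConsistencyReport(n=m.n, lambda_max=lam, ci=ci, ri=ri, cr=cr,
                             consistent=ok)


def consistent_matrix(weights, ids=None) -> PairwiseComparisonMatrix:
    """Build the perfectly consistent matrix ``a[i][j] = w[i]/w[j]``.

    Useful for round-trip checks: ``derive_weights`` recovers ``weights``
    (up to normalisation) exactly, and ``lambda_max`` equals the order.
    """
    w = np.asarray(weights, dtype=float)
    if np.any(w <= 0):
        raise MatrixError("weights must be strictly positive")
    return PairwiseComparisonMatrix(np.outer(w, 1.0 / w), ids=ids)
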