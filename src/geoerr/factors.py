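"""Factor dimensions of assay error and their stability under simulation.

Extraction is principal-component style: the first k eigenvectors of the
correlation matrix scaled by the square roots of their eigenvalues, followed
by a Kaiser-normalized varimax rotation. Replicated solutions are matched to
a reference by Tucker congruence with optimal column assignment and sign
flips before loadings are averaged, mirroring how simulated factor tables
are summarized (mean loading r-bar, loading SD s_r, prominence flags).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment

__all__ = [
    "FactorSolution",
    "ReplicationSummary",
    "tract_average",
    "varimax",
    "factor_solution",
    "tucker_congruence",
    "align_factors",
    "replication_summary",
    "factor_scores",
]


def tract_average(
    samples,
    tess=None,
    transform_log: bool = False,
    delta: Sequence[float] | dict | None = None,
) -> pd.DataFrame:
    """Arithmetic mean of per-metal assay errors by tract.

    With ``transform_log`` the mean is taken of ln(error + delta_m); delta
    defaults to 0 per metal. Returns a (tract x metal) DataFrame sorted by
    tract id. If a tessellation is given, every tract must have samples.
    """
    metals = samples.metals
    err = samples.errors()
    if transform_log:
        if delta is None:
            d = np.zeros(len(metals))
        elif isinstance(delta, dict):
            d = np.array([delta[m] for m in metals], dtype=float)
        else:
            d = np.asarray(delta, dtype=float)
        if np.any(err + d <= 0):
            raise ValueError("error + delta must be positive for the log transform")
        err = np.log(err + d)
    df = pd.DataFrame(err, columns=metals)
    df["tract_id"] = samples.tract_ids
    out = df.groupby("tract_id").mean().sort_index()
    if tess is not None:
        missing = [t for t in tess.tract_ids if t not in out.index]
        if missing:
            raise ValueError(f"tracts without samples: {missing}")
        out = out.loc[sorted(tess.tract_ids)]
    return out


@dataclass
class FactorSolution:
    loadings: np.ndarray  # (p, k)
    pct_variance: np.ndarray  # (k,)
    communalities: np.ndarray  # (p,)
    metals: list[str] | None = None

    def __post_init__(self) -> None:
        self.loadings = np.asarray(self.loadings, dtype=float)
        self.pct_variance = np.asarray(self.pct_variance, dtype=float)
        self.communalities = np.asarray(self.communalities, dtype=float)
        if np.any(np.abs(self.loadings) > 1 + 1e-9):
            raise ValueError("|loading| > 1")

    @property
    def k(self) -> int:
        return self.loadings.shape[1]


def varimax(
    loadings: np.ndarray,
    kaiser_normalize: bool = True,
    tol: float = 1e-8,
    max_iter: int = 1000,
) -> np.ndarray:
    """Varimax rotation of a loading matrix.

    Maximizes the variance of squared loadings per factor over orthogonal
    rotations; rows are optionally Kaiser-normalized (divided by their
    communality root) during rotation. Uses the classical pairwise planar
    rotations with the exact optimal angle per factor pair (this escapes
    the saddle configurations where gradient-style updates stall);
    converges when no pairwise rotation angle exceeds ``tol``.
    """
    L = np.asarray(loadings, dtype=float).copy()
    p, k = L.shape
    if k < 2:
        return L
    h = np.ones(p)
    if kaiser_normalize:
        h = np.sqrt((L**2).sum(axis=1))
        h[h == 0] = 1.0
        L = L / h[:, None]
    for _ in range(max_iter):
        max_angle = 0.0
        for i in range(k - 1):
            for j in range(i + 1, k):
                a, b = L[:, i], L[:, j]
                u = a**2 - b**2
                v = 2.0 * a * b
                A, B = u.sum(), v.sum()
                C = (u**2 - v**2).sum()
                D = (2.0 * u * v).sum()
                num = D - 2.0 * A * B / p
                den = C - (A**2 - B**2) / p
                phi = 0.25 * np.arctan2(num, den)
                if abs(phi) > tol:
                    c, s = np.cos(phi), np.sin(phi)
                    L[:, i], L[:, j] = c * a + s * b, -s * a + c * b
                max_angle = max(max_angle, abs(phi))
        if max_angle <= tol:
            break
    return L * h[:, None]


def _order_and_sign(L: np.ndarray) -> np.ndarray:
    """Deterministic presentation: columns by explained variance descending,
    each column's dominant loading made positive."""
    var = (L**2).sum(axis=0)
    order = np.argsort(-var)
    L = L[:, order]
    for j in range(L.shape[1]):
        if L[np.argmax(np.abs(L[:, j])), j] < 0:
            L[:, j] = -L[:, j]
    return L


def factor_solution(matrix, k: int = 4) -> FactorSolution:
    """Varimax-rotated principal-component factor solution of a data matrix.

    ``matrix`` is observations x variables (e.g. tracts x metals); the
    correlation matrix is eigendecomposed, the first k components scaled by
    the square roots of their eigenvalues, and the result varimax-rotated.
    Percent variance is the column sum of squared rotated loadings over the
    number of variables.
    """
    if isinstance(matrix, pd.DataFrame):
        metals = list(matrix.columns)
        X = matrix.to_numpy(dtype=float)
    else:
        metals = None
        X = np.asarray(matrix, dtype=float)
    n, p = X.shape
    if n < k + 2:
        raise ValueError(f"need at least {k + 2} observations for k={k}")
    sd = X.std(axis=0, ddof=1)
    if np.any(sd == 0):
        raise ValueError("constant column in input matrix")
    R = np.corrcoef(X, rowvar=False)
    if not np.all(np.isfinite(R)):
        raise ValueError("singular correlation matrix")
    eigval, eigvec = np.linalg.eigh(R)
    idx = np.argsort(-eigval)[:k]
    lam = np.clip(eigval[idx], 0, None)
    L = eigvec[:, idx] * np.sqrt(lam)
    L = _order_and_sign(varimax(L))
    # Rounding can push a loading a hair past 1.
    L = np.clip(L, -1.0, 1.0)
    pct = (L**2).sum(axis=0) / p * 100.0
    return FactorSolution(
        loadings=L,
        pct_variance=pct,
        communalities=(L**2).sum(axis=1),
        metals=metals,
    )


def tucker_congruence(a: np.ndarray, b: np.ndarray) -> float:
    """Cosine similarity between two loading vectors."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        raise ValueError("zero loading vector")
    return float(a @ b / (na * nb))


def align_factors(
    reference: FactorSolution, candidate: FactorSolution
) -> FactorSolution:
    """Permute and sign-flip candidate columns to best match the reference.

    The permutation maximizes the total absolute Tucker congruence over the
    k x k congruence matrix (optimal assignment); columns whose matched
    congruence is negative are sign-flipped. Idempotent and deterministic.
    """
    if reference.loadings.shape != candidate.loadings.shape:
        raise ValueError("dimension mismatch between solutions")
    k = reference.k
    C = np.empty((k, k))
    for i in range(k):
        for j in range(k):
            C[i, j] = tucker_congruence(
                reference.loadings[:, i], candidate.loadings[:, j]
            )
    row, col = linear_sum_assignment(-np.abs(C))
    perm = np.empty(k, dtype=int)
    perm[row] = col
    signs = np.sign(C[row, col])
    signs[signs == 0] = 1.0
    order = np.argsort(row)  # rows are already 0..k-1 sorted, keep explicit
    L = candidate.loadings[:, perm] * signs[order][None, :]
    return FactorSolution(
        loadings=L,
        pct_variance=candidate.pct_variance[perm],
        communalities=candidate.communalities,
        metals=candidate.metals,
    )


@dataclass
class ReplicationSummary:
    mean_loadings: np.ndarray  # (p, k)
    sd_loadings: np.ndarray  # (p, k)
    prominent: np.ndarray  # (p, k) bool
    threshold: float
    mean_pct_variance: np.ndarray  # (k,)
    assignment: list[int | None]  # 1-based factor per metal, None if below
    metals: list[str] | None
    derived_threshold: float  # smallest prominent |mean loading|

    def to_frame(self) -> pd.DataFrame:
        p, k = self.mean_loadings.shape
        idx = self.metals if self.metals else list(range(p))
        cols = {}
        for j in range(k):
            cols[f"F{j + 1}_mean"] = self.mean_loadings[:, j]
            cols[f"F{j + 1}_sd"] = self.sd_loadings[:, j]
        df = pd.DataFrame(cols, index=idx)
        df["assigned"] = [a if a is not None else "—" for a in self.assignment]
        return df


def replication_summary(
    solutions: Sequence[FactorSolution],
    reference: FactorSolution,
    threshold: float = 0.49,
) -> ReplicationSummary:
    """Element-wise mean and SD of loadings over aligned replications.

    A metal's prominent factor is the column where |mean loading| is row
    maximal, provided it exceeds ``threshold``; metals with no loading above
    threshold stay unassigned. ``derived_threshold`` reports the smallest
    prominent |mean loading| actually observed.
    """
    if len(solutions) < 2:
        raise ValueError("need at least 2 replications")
    stack = np.stack([align_factors(reference, s).loadings for s in solutions])
    mean = stack.mean(axis=0)
    sd = stack.std(axis=0, ddof=1)
    pct = np.stack(
        [align_factors(reference, s).pct_variance for s in solutions]
    ).mean(axis=0)
    p, k = mean.shape
    prominent = np.zeros((p, k), dtype=bool)
    assignment: list[int | None] = []
    for i in range(p):
        j = int(np.argmax(np.abs(mean[i])))
        if np.abs(mean[i, j]) >= threshold:
            prominent[i, j] = True
            assignment.append(j + 1)
        else:
            assignment.append(None)
    flagged = np.abs(mean[prominent])
    derived = float(flagged.min()) if flagged.size else float("nan")
    return ReplicationSummary(
        mean_loadings=mean,
        sd_loadings=sd,
        prominent=prominent,
        threshold=threshold,
        mean_pct_variance=pct,
        assignment=assignment,
        metals=reference.metals,
        derived_threshold=derived,
    )


def factor_scores(solution: FactorSolution, matrix) -> np.ndarray:
    """Regression (Thomson) factor scores from a rotated solution.

    Scores = Z R^+ Lambda with Z the column-standardized data and R its
    correlation matrix (pseudo-inverted for numerical safety).
    """
    X = (
        matrix.to_numpy(dtype=float)
        if isinstance(matrix, pd.DataFrame)
        else np.asarray(matrix, dtype=float)
    )
    Z = (X - X.mean(axis=0)) / X.std(axis=0, ddof=1)
    R = np.corrcoef(X, rowvar=False)
    return Z @ np.linalg.pinv(R) @ solution.loadings
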