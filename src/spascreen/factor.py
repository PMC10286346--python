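"""Factorability diagnostics and principal-component item reduction.

The 20 binary items are correlated (phi, i.e. Pearson on 0/1 responses, as
in the classical SPSS workflow; tetrachoric available behind a flag),
screened with the Kaiser--Meyer--Olkin sampling-adequacy index and Bartlett's
test of sphericity, decomposed by PCA on the correlation matrix, rotated
with varimax, and each item assigned to the component where its absolute
rotated loading peaks (subject to a minimum-loading threshold).

Variance shares are expressed over the *retained* components only (the
"common variance" convention), so they sum to 1.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .cohort import CohortDataset

__all__ = [
    "CorrelationMatrix",
    "FactorabilityReport",
    "FactorSolution",
    "ComponentAssignment",
    "correlation_matrix",
    "tetrachoric_rho",
    "kmo_index",
    "bartlett_sphericity",
    "extract_components",
    "varimax_rotate",
    "varimax_criterion",
    "rotate_solution",
    "assign_items",
]


@dataclass(frozen=True)
class CorrelationMatrix:
    values: np.ndarray
    items: tuple[str, ...]
    degenerate: tuple[str, ...] = ()  # zero-variance items (zeroed off-diagonals)

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        p = len(self.items)
        if v.shape != (p, p):
            raise ValueError("matrix shape does not match item labels")
        if not np.allclose(v, v.T, atol=1e-12):
            raise ValueError("correlation matrix must be symmetric")
        if not np.allclose(np.diag(v), 1.0, atol=1e-12):
            raise ValueError("correlation matrix must have unit diagonal")
        if np.any(np.abs(v) > 1 + 1e-12):
            raise ValueError("correlations must lie in [-1, 1]")

    @property
    def p(self) -> int:
        return len(self.items)


@dataclass(frozen=True)
class FactorabilityReport:
    kmo: float
    bartlett_chi2: float
    bartlett_df: int
    bartlett_p: float


@dataclass(frozen=True)
class FactorSolution:
    """Eigen-structure of the item correlation matrix.

    ``eigenvalues`` holds the full descending spectrum; ``loadings`` is the
    p x k (possibly rotated) loading matrix for the retained components;
    ``variance_shares`` are per-component shares of the retained variance.
    """

    eigenvalues: np.ndarray
    loadings: np.ndarray
    communalities: np.ndarray
    variance_shares: np.ndarray
    items: tuple[str, ...]
    rotated: bool = False
    converged: bool = True

    @property
    def n_components(self) -> int:
        return self.loadings.shape[1]

    def to_json_dict(self) -> dict:
        return {
            "items": list(self.items),
            "eigenvalues": [float(e) for e in self.eigenvalues],
            "n_components": self.n_components,
            "loadings": [[float(v) for v in row] for row in self.loadings],
            "communalities": [float(c) for c in self.communalities],
            "variance_shares": [float(s) for s in self.variance_shares],
            "rotated": self.rotated,
            "converged": self.converged,
        }

    def write(self, json_path: str | Path, tsv_path: str | Path | None = None) -> None:
        Path(json_path).write_text(json.dumps(self.to_json_dict(), indent=2))
        if tsv_path is not None:
            cols = [f"C{j + 1}" for j in range(self.n_components)]
            df = pd.DataFrame(self.loadings, index=list(self.items), columns=cols)
            df["communality"] = self.communalities
            df.to_csv(tsv_path, sep="\t", index_label="item")


def correlation_matrix(
    dataset: CohortDataset,
    groups: Iterable[str] | None = None,
    method: str = "pearson_phi",
) -> CorrelationMatrix:
    """Pairwise item correlations over the selected subjects.

    Zero-variance items get zero off-diagonal entries and are reported in
    ``degenerate``; an all-constant dataset is rejected.
    """
    if method not in ("pearson_phi", "tetrachoric"):
        raise ValueError(f"unknown correlation method {method!r}")
    x = dataset.response_matrix(groups)
    if x.shape[0] < 2:
        raise ValueError("need at least 2 subjects to correlate")
    sd = x.std(axis=0)
    constant = sd == 0
    if constant.all():
        raise ValueError("all items are constant; nothing to correlate")

    p = x.shape[1]
    r = np.eye(p)
    live = np.where(~constant)[0]
    if method == "pearson_phi":
        sub = np.corrcoef(x[:, live], rowvar=False)
        sub = np.atleast_2d(sub)
        for ii, i in enumerate(live):
            for jj, j in enumerate(live):
                r[i, j] = sub[ii, jj]
    else:
        for ii, i in enumerate(live):
            for j in live[ii + 1:]:
                a = int(((x[:, i] == 1) & (x[:, j] == 1)).sum())
                b = int(((x[:, i] == 1) & (x[:, j] == 0)).sum())
                c = int(((x[:, i] == 0) & (x[:, j] == 1)).sum())
                d = int(((x[:, i] == 0) & (x[:, j] == 0)).sum())
                r[i, j] = r[j, i] = tetrachoric_rho(a, b, c, d)
    np.fill_diagonal(r, 1.0)
    r = (r + r.T) / 2.0
    degenerate = tuple(dataset.item_ids[i] for i in np.where(constant)[0])
    return CorrelationMatrix(values=r, items=dataset.item_ids, degenerate=degenerate)


def tetrachoric_rho(a: int, b: int, c: int, d: int) -> float:
    """Tetrachoric correlation of a 2x2 table by inverting the bivariate
    normal upper-quadrant probability (zero cells get a 0.5 continuity add)."""
    cells = np.array([a, b, c, d], dtype=float)
    if (cells == 0).any():
        cells = cells + 0.5
    a_, b_, c_, d_ = cells
    n = cells.sum()
    p1 = (a_ + b_) / n  # P(first item = 1)
    p2 = (a_ + c_) / n  # P(second item = 1)
    p11 = a_ / n
    h = stats.norm.ppf(1 - p1)
    k = stats.norm.ppf(1 - p2)

    def upper_quadrant(rho: float) -> float:
        mvn = stats.multivariate_normal(mean=[0, 0], cov=[[1, rho], [rho, 1]])
        # P(X > h, Y > k) = 1 - F(h, inf) - F(inf, k) + F(h, k)
        return 1 - stats.norm.cdf(h) - stats.norm.cdf(k) + mvn.cdf([h, k])

    f = lambda rho: upper_quadrant(rho) - p11
    lo, hi = -0.999, 0.999
    if f(lo) * f(hi) > 0:
        return 1.0 if f(hi) < 0 else -1.0
    return float(optimize.brentq(f, lo, hi, xtol=1e-8))


def kmo_index(R: CorrelationMatrix) -> float:
    """Kaiser--Meyer--Olkin sampling adequacy.

    KMO = sum of squared off-diagonal correlations divided by that sum plus
    the sum of squared anti-image partial correlations (from the inverse of
    the correlation matrix).
    """
    r = R.values
    cond = np.linalg.cond(r)
    if not np.isfinite(cond) or cond > 1e12:
        raise ValueError(
            f"correlation matrix is singular or near-singular (cond={cond:.3g})"
        )
    s = np.linalg.inv(r)
    dsq = np.sqrt(np.outer(np.diag(s), np.diag(s)))
    q = -s / dsq
    off = ~np.eye(R.p, dtype=bool)
    r2 = float((r[off] ** 2).sum())
    q2 = float((q[off] ** 2).sum())
    if r2 + q2 == 0:
        raise ValueError("KMO undefined: no off-diagonal correlation (identity matrix)")
    return r2 / (r2 + q2)


def bartlett_sphericity(R: CorrelationMatrix, n: int) -> tuple[float, int, float]:
    """Bartlett's test that the correlation matrix is the identity.

    chi2 = -(n - 1 - (2p + 5)/6) * ln det R, with p(p-1)/2 degrees of freedom.
    Returns (chi2, df, p).
    """
    p = R.p
    if n <= p:
        raise ValueError("Bartlett's test requires n > number of items")
    sign, logdet = np.linalg.slogdet(R.values)
    if sign <= 0:
        raise ValueError("correlation matrix must be positive-definite")
    chi2 = -(n - 1 - (2 * p + 5) / 6.0) * logdet
    df = p * (p - 1) // 2
    return float(chi2), int(df), float(stats.chi2.sf(chi2, df))


def factorability(R: CorrelationMatrix, n: int) -> FactorabilityReport:
    chi2, df, pval = bartlett_sphericity(R, n)
    return FactorabilityReport(
        kmo=kmo_index(R), bartlett_chi2=chi2, bartlett_df=df, bartlett_p=pval
    )


def extract_components(
    R: CorrelationMatrix,
    retention: str = "kaiser",
    k: int | None = None,
) -> FactorSolution:
    """PCA of the correlation matrix (unrotated).

    Retains components with eigenvalue > 1 under ``"kaiser"`` (the default)
    or exactly ``k`` under ``"fixed_k"``.  Loadings are eigenvector *
    sqrt(eigenvalue); communalities are row sums of squared retained
    loadings.
    """
    eigval, eigvec = np.linalg.eigh(R.values)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]

    if retention == "kaiser":
        n_keep = int((eigval > 1.0).sum())
        if n_keep == 0:
            n_keep = 1
    elif retention == "fixed_k":
        if k is None or not (1 <= k <= R.p):
            raise ValueError("fixed_k retention needs 1 <= k <= p")
        n_keep = k
    else:
        raise ValueError(f"unknown retention rule {retention!r}")

    lam = eigvec[:, :n_keep] * np.sqrt(np.clip(eigval[:n_keep], 0, None))
    # sign convention: largest-magnitude loading in each column positive
    for j in range(n_keep):
        col = lam[:, j]
        if col[np.argmax(np.abs(col))] < 0:
            lam[:, j] = -col
    communalities = (lam**2).sum(axis=1)
    shares = eigval[:n_keep] / eigval[:n_keep].sum()
    return FactorSolution(
        eigenvalues=eigval.copy(),
        loadings=lam,
        communalities=communalities,
        variance_shares=shares,
        items=R.items,
        rotated=False,
    )


def varimax_criterion(loadings: np.ndarray) -> float:
    """Raw varimax objective: sum over components of the variance of squared
    loadings."""
    sq = np.asarray(loadings, dtype=float) ** 2
    p = sq.shape[0]
    return float((sq**2).sum(axis=0).sum() / p - ((sq.sum(axis=0) / p) ** 2).sum())


def varimax_rotate(
    loadings: np.ndarray,
    kaiser_normalize: bool = True,
    tol: float = 1e-6,
    max_iter: int = 100,
) -> tuple[np.ndarray, bool]:
    """Orthogonal varimax rotation by iterative pairwise planar rotations.

    Sweeps all column pairs, each time applying the closed-form optimal
    angle, until the criterion gain of a full sweep drops below ``tol``.
    Returns (rotated loadings, converged flag); communalities are preserved
    and each column is sign-flipped so its largest-magnitude entry is
    positive.
    """
    lam = np.array(loadings, dtype=float, copy=True)
    p, k = lam.shape
    if k < 2:
        return lam, True

    h = np.sqrt((lam**2).sum(axis=1))
    if kaiser_normalize:
        scale = np.where(h > 1e-12, h, 1.0)
        lam = lam / scale[:, None]

    converged = False
    crit = varimax_criterion(lam)
    for _ in range(max_iter):
        for i in range(k - 1):
            for j in range(i + 1, k):
                x, y = lam[:, i], lam[:, j]
                u = x**2 - y**2
                v = 2.0 * x * y
                a_ = u.sum()
                b_ = v.sum()
                c_ = (u**2 - v**2).sum()
                d_ = 2.0 * (u * v).sum()
                num = d_ - 2.0 * a_ * b_ / p
                den = c_ - (a_**2 - b_**2) / p
                phi = 0.25 * math.atan2(num, den)
                if abs(phi) < 1e-14:
                    continue
                cs, sn = math.cos(phi), math.sin(phi)
                xi = cs * x + sn * y
                yj = -sn * x + cs * y
                lam[:, i], lam[:, j] = xi, yj
        new_crit = varimax_criterion(lam)
        if new_crit - crit < tol:
            converged = True
            crit = new_crit
            break
        crit = new_crit

    if kaiser_normalize:
        lam = lam * scale[:, None]
    for j in range(k):
        col = lam[:, j]
        if col[np.argmax(np.abs(col))] < 0:
            lam[:, j] = -col
    return lam, converged


def rotate_solution(
    sol: FactorSolution,
    kaiser_normalize: bool = True,
    tol: float = 1e-6,
    max_iter: int = 100,
) -> FactorSolution:
    """Varimax-rotate a solution; components reordered by descending rotated
    variance share (column sum of squares) and relabelled C1..Ck."""
    lam, converged = varimax_rotate(
        sol.loadings, kaiser_normalize=kaiser_normalize, tol=tol, max_iter=max_iter
    )
    col_ss = (lam**2).sum(axis=0)
    order = np.argsort(col_ss)[::-1]
    lam = lam[:, order]
    col_ss = col_ss[order]
    return FactorSolution(
        eigenvalues=sol.eigenvalues.copy(),
        loadings=lam,
        communalities=(lam**2).sum(axis=1),
        variance_shares=col_ss / col_ss.sum(),
        items=sol.items,
        rotated=True,
        converged=converged,
    )


@dataclass(frozen=True)
class ComponentAssignment:
    """Item-to-component map from a rotated solution.

    ``assignments`` maps item_id -> (1-based component index, loading).
    Components are numbered in the solution's (descending variance share)
    order.
    """

    assignments: dict
    unassigned: tuple[str, ...]
    loading_threshold: float
    n_components: int
    items: tuple[str, ...] = field(default=())

    def component_items(self, component: int) -> tuple[str, ...]:
        """Items of one component, in the solution's item order."""
        return tuple(
            it for it in self.items
            if it in self.assignments and self.assignments[it][0] == component
        )

    def components(self) -> tuple[int, ...]:
        return tuple(range(1, self.n_components + 1))

    def to_json_dict(self) -> dict:
        return {
            "loading_threshold": self.loading_threshold,
            "n_components": self.n_components,
            "assignments": {
                it: {"component": comp, "loading": float(lo)}
                for it, (comp, lo) in self.assignments.items()
            },
            "unassigned": list(self.unassigned),
        }


def assign_items(
    rotated: FactorSolution, loading_threshold: float = 0.36
) -> ComponentAssignment:
    """Assign each item to the component of its maximum absolute rotated
    loading, provided it reaches ``loading_threshold``; ties within 1e-9 go
    to the lower component index."""
    lam = rotated.loadings
    assignments: dict[str, tuple[int, float]] = {}
    unassigned: list[str] = []
    for i, item in enumerate(rotated.items):
        row = np.abs(lam[i])
        best = row.max()
        if best >= loading_threshold:
            j = int(np.nonzero(row >= best - 1e-9)[0][0])
            assignments[item] = (j + 1, float(lam[i, j]))
        else:
            unassigned.append(item)
    return ComponentAssignment(
        assignments=assignments,
        unassigned=tuple(unassigned),
        loading_threshold=loading_threshold,
        n_components=rotated.n_components,
        items=rotated.items,
    )
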