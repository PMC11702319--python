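"""Principal component model of the standardized geochemistry matrix.

The decomposition follows the psychometric convention under which the
standardized data matrix factorizes as Z = P B^T: loadings B (p x k) are
eigenvectors of the correlation matrix scaled by sqrt(eigenvalue), i.e.
variable-component correlations, and scores P (n x k) are the standardized
projections with unit sample variance per column.  Varimax rotation, the
broken-stick significance screen for loadings, and a discretization-based
independence check of the retained components live here as well.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.stats import chi2_contingency

__all__ = [
    "FactorModel",
    "LoadingSignificance",
    "fit_pca",
    "retain_components",
    "varimax",
    "varimax_rotate",
    "broken_stick_thresholds",
    "significant_loadings",
    "pc_independence_test",
]


@dataclass
class FactorModel:
    """Eigenvalues, loadings, scores and the score-coefficient matrix.

    ``score_coefficients`` W maps standardized data to scores (P = Z W); it
    is carried through rotation so that an arbitrary new standardized sample
    (for instance, the artificial zero-concentration sample of the APCS
    construction) can be projected into component space.
    """

    eigenvalues: np.ndarray            # all min(n-1, p) eigenvalues
    loadings: pd.DataFrame             # p x k
    scores: pd.DataFrame               # n x k
    score_coefficients: pd.DataFrame   # p x k
    variance_fraction: np.ndarray      # k values in [0, 1]
    rotated: bool = False
    rotation: np.ndarray | None = None  # k x k orthogonal matrix

    @property
    def k(self) -> int:
        return self.loadings.shape[1]

    @property
    def p(self) -> int:
        return self.loadings.shape[0]

    @property
    def n(self) -> int:
        return self.scores.shape[0]

    @property
    def parameters(self) -> list[str]:
        return list(self.loadings.index)

    def communalities(self) -> pd.Series:
        return (self.loadings ** 2).sum(axis=1)

    def reconstruct(self) -> pd.DataFrame:
        """Model-implied standardized data, P B^T."""
        return pd.DataFrame(
            self.scores.to_numpy() @ self.loadings.to_numpy().T,
            index=self.scores.index, columns=self.loadings.index,
        )


@dataclass
class LoadingSignificance:
    """Boolean p x k matrix from the broken-stick screen plus the thresholds."""

    significant: pd.DataFrame
    thresholds: np.ndarray
    method: str

    def parameters_on(self, component) -> list[str]:
        """Parameter names significant on the given component label/index."""
        col = self.significant[component] if component in self.significant.columns \
            else self.significant.iloc[:, component]
        return list(col.index[col])


def _fix_signs(loadings: np.ndarray, *companions: np.ndarray):
    """Make the largest-|loading| entry of each column positive.

    Component signs are arbitrary; this pins them deterministically.  Any
    companion matrices (scores, score coefficients, rotation) are flipped
    consistently.
    """
    flips = np.ones(loadings.shape[1])
    for c in range(loadings.shape[1]):
        j = np.argmax(np.abs(loadings[:, c]))
        if loadings[j, c] < 0:
            flips[c] = -1.0
    out = [loadings * flips]
    out.extend(m * flips for m in companions)
    return out if companions else out[0]


def fit_pca(z: pd.DataFrame) -> FactorModel:
    """Full-rank eigen-decomposition of the correlation matrix of Z.

    Z must already be standardized (mean 0, sample SD 1 per column).  With
    n - 1 < p the correlation matrix is rank deficient; only the leading
    min(n - 1, p) components are returned, with a warning.
    """
    if not isinstance(z, pd.DataFrame):
        z = pd.DataFrame(np.asarray(z, dtype=float))
    n, p = z.shape
    zv = z.to_numpy(dtype=float)
    col_mean = zv.mean(axis=0)
    col_sd = zv.std(axis=0, ddof=1)
    if np.any(np.abs(col_mean) > 1e-8) or np.any(np.abs(col_sd - 1) > 1e-8):
        raise ValueError("input is not standardized (columns must have "
                         "mean 0 and sample SD 1)")
    corr = zv.T @ zv / (n - 1)
    eigvals, eigvecs = np.linalg.eigh(corr)
    order = np.argsort(eigvals)[::-1]
    eigvals = np.clip(eigvals[order], 0.0, None)
    eigvecs = eigvecs[:, order]

    k = min(n - 1, p)
    if k < p:
        warnings.warn(
            f"rank-deficient input (n={n}, p={p}): keeping {k} components",
            stacklevel=2,
        )
    lam = eigvals[:k]
    positive = lam > max(lam[0], 1.0) * 1e-12
    k = int(positive.sum())
    lam = lam[:k]
    vecs = eigvecs[:, :k]

    loadings = vecs * np.sqrt(lam)
    score_coef = vecs / np.sqrt(lam)
    scores = zv @ score_coef
    loadings, scores, score_coef = _fix_signs(loadings, scores, score_coef)

    comp_names = [f"PC{i + 1}" for i in range(k)]
    return FactorModel(
        eigenvalues=eigvals,
        loadings=pd.DataFrame(loadings, index=z.columns, columns=comp_names),
        scores=pd.DataFrame(scores, index=z.index, columns=comp_names),
        score_coefficients=pd.DataFrame(score_coef, index=z.columns,
                                        columns=comp_names),
        variance_fraction=lam / p,
        rotated=False,
    )


def retain_components(model: FactorModel, rule: str = "guttman_kaiser",
                      k: int | None = None) -> int:
    """Number of components to keep.

    ``guttman_kaiser`` counts eigenvalues strictly greater than 1 (an
    eigenvalue of exactly 1 carries no more variance than a single original
    variable and is excluded).  ``fixed_k`` passes through a user-chosen k,
    the hook for scree-plot judgement, which is not automated.
    """
    if rule == "guttman_kaiser":
        return int(np.sum(model.eigenvalues > 1.0))
    if rule == "fixed_k":
        if k is None:
            raise ValueError("fixed_k retention requires k")
        if k > model.k:
            raise ValueError(f"k={k} exceeds available components ({model.k})")
        return int(k)
    raise ValueError(f"unknown retention rule {rule!r}")


# ---------------------------------------------------------------------------
# Varimax rotation
# ---------------------------------------------------------------------------

def varimax(a: np.ndarray, normalize: bool = True, tol: float = 1e-12,
            max_iter: int = 5000) -> tuple[np.ndarray, np.ndarray]:
    """Orthogonal varimax rotation of a loading matrix.

    Kaiser's criterion is maximized by the classic SVD update.  With
    ``normalize`` (Kaiser row normalization) each row is scaled to unit
    communality before rotation and rescaled afterwards, which keeps
    high-communality variables from dominating the criterion.  Iterations
    stop when the rotation matrix is stationary to ``tol``, which is chosen
    tight so that repeated runs and exact-recovery comparisons agree to
    numerical precision.

    Returns (rotated loadings, rotation matrix R) with ``rotated = a @ R``.
    """
    a = np.asarray(a, dtype=float)
    p, k = a.shape
    if k < 2:
        return a.copy(), np.eye(k)
    work = a
    if normalize:
        h = np.sqrt((a ** 2).sum(axis=1))
        h[h == 0] = 1.0
        work = a / h[:, None]
    rot = np.eye(k)
    for _ in range(max_iter):
        lam = work @ rot
        u, s, vt = np.linalg.svd(
            work.T @ (lam ** 3 - lam * (lam ** 2).mean(axis=0))
        )
        new_rot = u @ vt
        if np.max(np.abs(new_rot - rot)) < tol:
            rot = new_rot
            break
        rot = new_rot
    rotated = a @ rot
    return rotated, rot


def varimax_rotate(model: FactorModel, k: int) -> FactorModel:
    """Rotate the first k components of a fitted model.

    Scores and score coefficients are rotated by the same orthogonal matrix
    so Z = P B^T is preserved; per-variable communalities are invariant.
    Rotated components are re-ordered by explained variance (column sum of
    squared loadings) and sign-fixed, and the variance fractions are
    recomputed as column sums of B^2 / p.  Rotation of a single component is
    undefined; k < 2 returns the truncated model unchanged.
    """
    if k > model.k:
        raise ValueError(f"k={k} exceeds available components ({model.k})")
    b = model.loadings.to_numpy()[:, :k]
    scores = model.scores.to_numpy()[:, :k]
    coefs = model.score_coefficients.to_numpy()[:, :k]
    comp_names = [f"PC{i + 1}" for i in range(k)]
    if k < 2:
        return replace(
            model,
            loadings=model.loadings.iloc[:, :k],
            scores=model.scores.iloc[:, :k],
            score_coefficients=model.score_coefficients.iloc[:, :k],
            variance_fraction=model.variance_fraction[:k],
        )
    b_rot, rot = varimax(b)
    scores_rot = scores @ rot
    coefs_rot = coefs @ rot
    # order by explained variance, then pin signs
    explained = (b_rot ** 2).sum(axis=0)
    order = np.argsort(explained)[::-1]
    b_rot, scores_rot, coefs_rot = (b_rot[:, order], scores_rot[:, order],
                                    coefs_rot[:, order])
    rot = rot[:, order]
    b_rot, scores_rot, coefs_rot, rot = _fix_signs(
        b_rot, scores_rot, coefs_rot, rot
    )
    return FactorModel(
        eigenvalues=model.eigenvalues,
        loadings=pd.DataFrame(b_rot, index=model.loadings.index,
                              columns=comp_names),
        scores=pd.DataFrame(scores_rot, index=model.scores.index,
                            columns=comp_names),
        score_coefficients=pd.DataFrame(coefs_rot,
                                        index=model.loadings.index,
                                        columns=comp_names),
        variance_fraction=(b_rot ** 2).sum(axis=0) / model.p,
        rotated=True,
        rotation=rot,
    )


# ---------------------------------------------------------------------------
# Broken-stick loading significance
# ---------------------------------------------------------------------------

def broken_stick_thresholds(p: int) -> np.ndarray:
    """Expected ordered fractions when a unit stick breaks into p pieces.

    b_m = (1/p) * sum_{i=m}^{p} 1/i.  The values sum to one and decrease
    strictly; an observed variance share exceeding its rank's expectation is
    larger than random apportionment would produce.
    """
    if p < 1:
        raise ValueError("p must be >= 1")
    inv = 1.0 / np.arange(1, p + 1)
    return np.cumsum(inv[::-1])[::-1] / p


def significant_loadings(model: FactorModel, method: str = "per_variable"
                         ) -> LoadingSignificance:
    """Broken-stick screen for which loadings exceed random expectation.

    ``per_variable`` (default): for each variable, its squared loadings
    across the k retained components are ranked descending and compared
    sequentially to the broken-stick expectations for k pieces; components
    are flagged significant from the top rank down, stopping at the first
    rank whose squared loading falls below its expectation.  A variable with
    an evenly spread communality therefore flags nothing.

    ``per_component``: for each component, squared loadings across the p
    variables are normalized by their column sum and compared, again
    rank-wise and sequentially, to the broken-stick expectations for p
    pieces.  With a single retained component the per-variable construction
    is degenerate (its only threshold is 1), so this variant is used.
    """
    b = model.loadings.to_numpy()
    p, k = b.shape
    sig = np.zeros((p, k), dtype=bool)
    if method == "per_variable" and k == 1:
        method = "per_component"
    if method == "per_variable":
        thresholds = broken_stick_thresholds(k)
        sq = b ** 2
        for j in range(p):
            order = np.argsort(sq[j])[::-1]
            for rank, comp in enumerate(order):
                if sq[j, comp] > thresholds[rank]:
                    sig[j, comp] = True
                else:
                    break
    elif method == "per_component":
        thresholds = broken_stick_thresholds(p)
        for c in range(k):
            share = b[:, c] ** 2
            total = share.sum()
            if total <= 0:
                continue
            share = share / total
            order = np.argsort(share)[::-1]
            for rank, j in enumerate(order):
                if share[j] > thresholds[rank]:
                    sig[j, c] = True
                else:
                    break
    else:
        raise ValueError(f"unknown method {method!r}")
    return LoadingSignificance(
        significant=pd.DataFrame(sig, index=model.loadings.index,
                                 columns=model.loadings.columns),
        thresholds=thresholds,
        method=method,
    )


# ---------------------------------------------------------------------------
# Component independence check
# ---------------------------------------------------------------------------

def pc_independence_test(scores, n_bins: int = 4, alpha: float = 0.05,
                         construction: str = "pairwise") -> pd.DataFrame:
    """Chi-square independence check on discretized component scores.

    Each score column is cut into ``n_bins`` equal-width intervals spanning
    its observed range.  ``pairwise`` builds one contingency table per
    component pair; ``component_by_bin`` builds a single k x n_bins table of
    bin occupancies and tests homogeneity of the bin profiles across
    components.  Empty rows/columns are dropped before computing degrees of
    freedom.  Returns a frame with statistic, p-value and the decision at
    ``alpha`` ("reject" means dependence was detected).
    """
    scores = pd.DataFrame(scores)
    n, k = scores.shape
    if k < 2:
        raise ValueError("need at least two components")
    if n < 2 * n_bins:
        raise ValueError("too few observations for the requested binning")

    def discretize(col: np.ndarray) -> np.ndarray:
        lo, hi = col.min(), col.max()
        if hi <= lo:
            raise ValueError("constant score column (zero-width bins)")
        edges = np.linspace(lo, hi, n_bins + 1)
        idx = np.searchsorted(edges, col, side="right") - 1
        return np.clip(idx, 0, n_bins - 1)

    binned = np.column_stack([discretize(scores.iloc[:, j].to_numpy())
                              for j in range(k)])
    rows = []
    if construction == "pairwise":
        for a in range(k):
            for b in range(a + 1, k):
                table = np.zeros((n_bins, n_bins))
                np.add.at(table, (binned[:, a], binned[:, b]), 1)
                table = table[table.sum(axis=1) > 0][:, table.sum(axis=0) > 0]
                stat, pval, dof, _ = chi2_contingency(table, correction=False)
                rows.append({
                    "pair": f"{scores.columns[a]}-{scores.columns[b]}",
                    "statistic": stat, "p_value": pval, "dof": dof,
                    "decision": "reject" if pval < alpha else "independent",
                })
    elif construction == "component_by_bin":
        table = np.zeros((k, n_bins))
        for j in range(k):
            np.add.at(table[j], binned[:, j], 1)
        table = table[table.sum(axis=1) > 0][:, table.sum(axis=0) > 0]
        stat, pval, dof, _ = chi2_contingency(table, correction=False)
        rows.append({
            "pair": "all-components", "statistic": stat, "p_value": pval,
            "dof": dof,
            "decision": "reject" if pval < alpha else "independent",
        })
    else:
        raise ValueError(f"unknown construction {construction!r}")
    return pd.DataFrame(rows)
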