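"""Injury-space modelling: archetypal analysis and PCA co-embedding.

Archetypal analysis (AA) decomposes the n x p injury score matrix X as
X ~ A @ Z with Z = B @ X, where the rows of A (per-sample archetype
scores) and of B (archetype composition weights) are constrained to the
probability simplex.  The archetypes Z are therefore extreme but
data-supported phenotypes on the convex hull of the cohort, and every
biopsy is described as a convex mixture of them; its scores sum to 1
and the highest score defines its cluster.

The optimiser is classical alternating simplex-constrained least
squares: given Z, each row of A is the simplex-constrained projection
of the sample onto the archetypes; given A, the unconstrained optimal
archetypes are projected back onto the convex hull of the data via
simplex-constrained rows of B.  Initialisation is furthest-sum vertex
seeding, and the best of several random restarts (by residual sum of
squares, RSS) is returned.  A candidate B-update is accepted only if it
does not increase the RSS, which makes the RSS trajectory monotone.

The same standardized matrix feeds a PCA used purely for visualisation;
component signs are pinned by feature anchors so that PC1 grows with
injury, AKI sits at negative PC2, and inflamed injury at negative PC3.
"""

from __future__ import annotations

import dataclasses
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment, nnls
from scipy.stats import rankdata

__all__ = [
    "StandardizedMatrix",
    "ArchetypeModel",
    "PCAModel",
    "standardize",
    "simplex_lstsq",
    "fit_archetypes",
    "rss_scree",
    "archetype_scores",
    "assign_clusters",
    "label_archetypes",
    "fit_pca",
    "top_correlated_genes",
    "ARCHETYPE_LABELS",
]

#: Scenario labels in reference-profile order (see synthetic_cohort).
ARCHETYPE_LABELS = ["AKI1", "AKI2", "minor injury", "CKD/AKI", "CKD", "no injury"]


# ---------------------------------------------------------------------------
# Standardization
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class StandardizedMatrix:
    """Column-wise z-scored matrix with the means/SDs used to produce it."""

    values: np.ndarray
    feature_names: list[str]
    sample_ids: list[str]
    means: np.ndarray
    sds: np.ndarray

    @property
    def df(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.sample_ids, columns=self.feature_names)

    def transform(self, table: pd.DataFrame) -> np.ndarray:
        """Apply the stored standardization to new data with the same columns."""
        X = table[self.feature_names].to_numpy(dtype=float)
        return (X - self.means) / self.sds


def standardize(score_table: pd.DataFrame) -> StandardizedMatrix:
    """Columnwise z-scores (sample SD, ddof=1); constant columns become zeros."""
    if len(score_table) < 2:
        raise ValueError("standardize needs at least 2 samples per column")
    X = score_table.to_numpy(dtype=float)
    means = X.mean(axis=0)
    sds = X.std(axis=0, ddof=1)
    safe = sds.copy()
    constant = sds == 0
    if constant.any():
        import warnings

        warnings.warn(
            f"constant columns standardized to zeros: "
            f"{[c for c, f in zip(score_table.columns, constant) if f]}"
        )
        safe[constant] = 1.0
    Z = (X - means) / safe
    return StandardizedMatrix(
        Z, list(score_table.columns), list(map(str, score_table.index)), means, safe
    )


# ---------------------------------------------------------------------------
# Simplex-constrained least squares
# ---------------------------------------------------------------------------

def simplex_lstsq(basis: np.ndarray, target: np.ndarray, penalty: float | None = None) -> np.ndarray:
    """Solve ``min || w @ basis - target ||`` subject to w >= 0, sum(w) = 1.

    The sum-to-one constraint is imposed by augmenting the nonnegative
    least-squares system with a heavily weighted row of ones, then
    renormalising the active weights exactly.  ``basis`` is (m, p),
    ``target`` is (p,).
    """
    m = basis.shape[0]
    if penalty is None:
        scale = max(1.0, float(np.abs(basis).max()), float(np.abs(target).max()))
        penalty = 200.0 * scale
    design = np.vstack([basis.T, np.full((1, m), penalty)])
    rhs = np.concatenate([target, [penalty]])
    w, _ = nnls(design, rhs)
    total = w.sum()
    if total <= 0:  # degenerate; fall back to uniform weights
        return np.full(m, 1.0 / m)
    return w / total


def _project_rows(basis: np.ndarray, targets: np.ndarray) -> np.ndarray:
    """Simplex-constrained projection of each row of ``targets`` onto ``basis`` rows."""
    scale = max(1.0, float(np.abs(basis).max()), float(np.abs(targets).max()))
    penalty = 200.0 * scale
    m = basis.shape[0]
    design = np.vstack([basis.T, np.full((1, m), penalty)])
    out = np.empty((targets.shape[0], m))
    for i, t in enumerate(targets):
        rhs = np.concatenate([t, [penalty]])
        w, _ = nnls(design, rhs)
        s = w.sum()
        out[i] = w / s if s > 0 else np.full(m, 1.0 / m)
    return out


# ---------------------------------------------------------------------------
# Archetype model
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class ArchetypeModel:
    """Fitted archetypal-analysis model.

    ``Z`` (k x p) are archetype coordinates in the standardized feature
    space, ``A`` (n x k) per-sample convex weights, ``B`` (k x n)
    composition weights over the fitted data, so that ``Z = B @ X``.
    ``means``/``sds`` record the standardization applied to the raw
    score table before fitting.
    """

    k: int
    Z: np.ndarray
    A: np.ndarray
    B: np.ndarray
    rss: float
    n_iter: int
    converged: bool
    seed: int | None
    restarts: int
    feature_names: list[str]
    sample_ids: list[str]
    means: np.ndarray
    sds: np.ndarray

    def to_dict(self) -> dict:
        return {
            "k": self.k,
            "Z": self.Z.tolist(),
            "A": self.A.tolist(),
            "B": self.B.tolist(),
            "rss": self.rss,
            "n_iter": self.n_iter,
            "converged": self.converged,
            "seed": self.seed,
            "restarts": self.restarts,
            "feature_names": self.feature_names,
            "sample_ids": self.sample_ids,
            "means": self.means.tolist(),
            "sds": self.sds.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ArchetypeModel":
        return cls(
            k=int(d["k"]),
            Z=np.asarray(d["Z"], dtype=float),
            A=np.asarray(d["A"], dtype=float),
            B=np.asarray(d["B"], dtype=float),
            rss=float(d["rss"]),
            n_iter=int(d["n_iter"]),
            converged=bool(d["converged"]),
            seed=d.get("seed"),
            restarts=int(d.get("restarts", 1)),
            feature_names=list(d.get("feature_names", [])),
            sample_ids=list(d.get("sample_ids", [])),
            means=np.asarray(d.get("means", []), dtype=float),
            sds=np.asarray(d.get("sds", []), dtype=float),
        )

    @property
    def archetype_table(self) -> pd.DataFrame:
        """Archetypes mapped back to the natural (unstandardized) feature scale."""
        Z = self.Z
        if self.means.size:
            Z = Z * self.sds + self.means
        return pd.DataFrame(
            Z, columns=self.feature_names or None,
            index=[f"archetype_{i + 1}" for i in range(self.k)],
        )


def _furthest_sum_init(X: np.ndarray, k: int, rng: np.random.Generator) -> np.ndarray:
    """Furthest-sum vertex seeding: greedily pick mutually distant samples."""
    n = X.shape[0]
    first = int(rng.integers(n))
    chosen = [first]
    dist_sum = np.linalg.norm(X - X[first], axis=1)
    # discard the random starter after enough points, as in standard practice
    for _ in range(k - 1):
        dist_sum[chosen] = -np.inf
        nxt = int(np.argmax(dist_sum))
        chosen.append(nxt)
        d = np.linalg.norm(X - X[nxt], axis=1)
        dist_sum = np.where(np.isneginf(dist_sum), -np.inf, dist_sum + d)
    if k > 1:
        # replace the random seed point by the furthest from the rest
        rest = chosen[1:]
        dist_sum2 = np.zeros(n)
        for j in rest:
            dist_sum2 += np.linalg.norm(X - X[j], axis=1)
        dist_sum2[rest] = -np.inf
        chosen[0] = int(np.argmax(dist_sum2))
        if chosen[0] in rest:  # degenerate tiny-n case
            chosen[0] = first
    return np.array(sorted(set(chosen)) if len(set(chosen)) == k else chosen)


def _coerce_matrix(X) -> tuple[np.ndarray, list[str], list[str], np.ndarray, np.ndarray]:
    if isinstance(X, StandardizedMatrix):
        return X.values, X.feature_names, X.sample_ids, X.means, X.sds
    if isinstance(X, pd.DataFrame):
        arr = X.to_numpy(dtype=float)
        return arr, list(map(str, X.columns)), list(map(str, X.index)), np.array([]), np.array([])
    arr = np.asarray(X, dtype=float)
    return arr, [], [], np.array([]), np.array([])


def _single_fit(
    X: np.ndarray,
    k: int,
    max_iter: int,
    tol: float,
    rng: np.random.Generator,
    init: str = "furthest_sum",
) -> tuple[np.ndarray, np.ndarray, np.ndarray, float, int, bool]:
    n, p = X.shape
    if init == "furthest_sum":
        idx = _furthest_sum_init(X, k, rng)
    else:  # random vertex seeding keeps restarts diverse on tiny inputs
        idx = rng.choice(n, size=k, replace=False)
    B = np.zeros((k, n))
    B[np.arange(k), idx] = 1.0
    Z = B @ X
    A = _project_rows(Z, X)
    rss = float(((X - A @ Z) ** 2).sum())
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        # fast move: unconstrained optimal archetypes projected onto
        # conv(X); accepted only when it does not increase the RSS
        Zstar, *_ = np.linalg.lstsq(A, X, rcond=None)
        B_new = _project_rows(X, Zstar)
        Z_new = B_new @ X
        rss_new = float(((X - A @ Z_new) ** 2).sum())
        if rss_new <= rss * (1 + 1e-12) + 1e-15:
            B, Z = B_new, Z_new
        # exact block coordinate descent over B rows: for fixed A and the
        # other rows, the optimal row j is the simplex projection of
        # t_j = R_j' a_j / ||a_j||^2 onto conv(X); always non-increasing
        Y = B @ X
        for j in range(k):
            a = A[:, j]
            nrm = float(a @ a)
            if nrm < 1e-12:
                continue  # archetype currently unused; leave its composition
            R_j = X - A @ Y + np.outer(a, Y[j])
            t_j = (R_j.T @ a) / nrm
            B[j] = simplex_lstsq(X, t_j)
            Y[j] = B[j] @ X
        Z = Y
        # weight update is the exact per-sample simplex projection
        A = _project_rows(Z, X)
        rss_next = float(((X - A @ Z) ** 2).sum())
        if rss - rss_next <= tol * max(rss, 1e-12):
            rss = min(rss_next, rss)
            converged = True
            break
        rss = rss_next
    return A, B, Z, rss, it, converged


def fit_archetypes(
    X,
    k: int,
    *,
    max_iter: int = 500,
    tol: float = 1e-6,
    restarts: int = 10,
    seed: int | None = 0,
) -> ArchetypeModel:
    """Fit k archetypes by alternating simplex-constrained least squares.

    ``X`` may be a :class:`StandardizedMatrix`, a DataFrame, or a plain
    array (rows = samples).  The best of ``restarts`` random
    initialisations by RSS is returned.
    """
    arr, feat, samp, means, sds = _coerce_matrix(X)
    n, p = arr.shape
    if not np.isfinite(arr).all():
        raise ValueError("input matrix contains non-finite values")
    if k < 1 or k > n:
        raise ValueError(f"k={k} must satisfy 1 <= k <= n={n}")
    ss = np.random.SeedSequence(seed)
    best = None
    # first restart uses furthest-sum vertex seeding; the rest draw random
    # vertex sets so restarts stay diverse even when furthest-sum is
    # deterministic (small n)
    for i, child in enumerate(ss.spawn(max(1, restarts))):
        rng = np.random.default_rng(child)
        init = "furthest_sum" if i == 0 else "random"
        A, B, Z, rss, it, conv = _single_fit(arr, k, max_iter, tol, rng, init=init)
        if best is None or rss < best[3]:
            best = (A, B, Z, rss, it, conv)
    A, B, Z, rss, it, conv = best
    return ArchetypeModel(
        k=k, Z=Z, A=A, B=B, rss=rss, n_iter=it, converged=conv,
        seed=seed, restarts=restarts, feature_names=feat, sample_ids=samp,
        means=means, sds=sds,
    )


def rss_scree(
    X,
    k_range: Iterable[int] = range(2, 8),
    *,
    restarts: int = 10,
    seed: int | None = 0,
    max_iter: int = 500,
    tol: float = 1e-6,
) -> pd.Series:
    """Best-of-restarts RSS for each candidate number of archetypes."""
    ks = list(k_range)
    vals = [
        fit_archetypes(X, k, restarts=restarts, seed=seed, max_iter=max_iter, tol=tol).rss
        for k in ks
    ]
    return pd.Series(vals, index=pd.Index(ks, name="k"), name="rss")


def archetype_scores(model: ArchetypeModel, X_new) -> np.ndarray:
    """Simplex-constrained least-squares weights of new samples on fixed archetypes."""
    arr = X_new.values if isinstance(X_new, StandardizedMatrix) else np.asarray(
        X_new.to_numpy(dtype=float) if isinstance(X_new, pd.DataFrame) else X_new,
        dtype=float,
    )
    if arr.ndim == 1:
        arr = arr[None, :]
    if arr.shape[1] != model.Z.shape[1]:
        raise ValueError(
            f"feature dimension {arr.shape[1]} does not match model ({model.Z.shape[1]})"
        )
    return _project_rows(model.Z, arr)


def assign_clusters(A: np.ndarray, sample_ids: Sequence[str] | None = None) -> pd.DataFrame:
    """Argmax cluster per sample; ties break toward the lowest archetype index.

    Returns a DataFrame with 1-based ``archetype_index`` and the winning
    ``max_score``.
    """
    A = np.asarray(A, dtype=float)
    idx = A.argmax(axis=1)  # np.argmax returns the first (lowest) index on ties
    out = pd.DataFrame(
        {
            "archetype_index": idx + 1,
            "max_score": A[np.arange(len(A)), idx],
        }
    )
    if sample_ids is not None:
        out.insert(0, "sample_id", list(map(str, sample_ids)))
    return out


def label_archetypes(
    model: ArchetypeModel,
    score_table: pd.DataFrame | None = None,
    clinical: pd.DataFrame | None = None,
) -> tuple[dict[int, str], pd.DataFrame]:
    """Map archetype indices to scenario labels by profile matching.

    Each fitted archetype (on the natural feature scale) is matched
    one-to-one to the built-in reference scenario profiles by maximising
    total Pearson correlation (Hungarian assignment).  Returns the
    ``{1-based index: label}`` mapping and a per-archetype report of
    mean features over assigned samples (from ``score_table`` when
    given, else the archetype coordinates themselves).
    """
    from .synthetic_cohort import reference_profiles

    report_source = model.archetype_table
    if model.k != 6:
        labels = {i + 1: f"archetype_{i + 1}" for i in range(model.k)}
        return labels, report_source

    ref = reference_profiles()  # 6 x 12, rows in ARCHETYPE_LABELS order
    fitted = model.archetype_table
    common = [c for c in ref.columns if c in fitted.columns]
    if len(common) < 3:
        # unnamed features: fall back to positional columns
        common = list(range(min(ref.shape[1], fitted.shape[1])))
        F = fitted.to_numpy()[:, : len(common)]
        R = ref.to_numpy()[:, : len(common)]
    else:
        F = fitted[common].to_numpy()
        R = ref[common].to_numpy()
    corr = np.corrcoef(F, R)[: model.k, model.k:]
    row, col = linear_sum_assignment(-corr)
    labels = {int(r) + 1: ARCHETYPE_LABELS[int(c)] for r, c in zip(row, col)}

    if score_table is not None:
        assignment = assign_clusters(model.A)
        grouped = score_table.copy()
        grouped["archetype_index"] = assignment["archetype_index"].to_numpy()
        report = grouped.groupby("archetype_index").mean()
        report.index = [labels[i] for i in report.index]
    else:
        report = report_source.copy()
        report.index = [labels[i + 1] for i in range(model.k)]
    return labels, report


# ---------------------------------------------------------------------------
# PCA co-embedding
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class PCAModel:
    loadings: pd.DataFrame          # p x p, columns PC1..PCp, orthonormal
    scores: pd.DataFrame            # n x p
    explained_variance_ratio: np.ndarray
    anchors: dict[str, str]

    def to_dict(self) -> dict:
        return {
            "loadings": self.loadings.to_dict(),
            "explained_variance_ratio": self.explained_variance_ratio.tolist(),
            "anchors": self.anchors,
        }


#: sign anchors: component -> (feature, required sign of that loading)
_PC_ANCHORS: dict[str, tuple[str, int]] = {
    "PC1": ("IRRAT", +1),   # PC1 grows with injury
    "PC2": ("IRRAT", -1),   # AKI sits at negative PC2
    "PC3": ("IGT", -1),     # inflamed injury sits at negative PC3
}


def fit_pca(X: StandardizedMatrix | pd.DataFrame) -> PCAModel:
    """PCA of the standardized score matrix with deterministic sign anchors."""
    from sklearn.decomposition import PCA

    if isinstance(X, StandardizedMatrix):
        arr, feats, samples = X.values, X.feature_names, X.sample_ids
    else:
        arr = X.to_numpy(dtype=float)
        feats = list(map(str, X.columns))
        samples = list(map(str, X.index))
    n, p = arr.shape
    if n <= p:
        raise ValueError(f"PCA needs n > p (got n={n}, p={p})")
    pca = PCA(n_components=p, svd_solver="full")
    scores = pca.fit_transform(arr)
    load = pca.components_.T.copy()  # p x p, columns are components

    pc_names = [f"PC{i + 1}" for i in range(p)]
    anchors: dict[str, str] = {}
    for j, name in enumerate(pc_names):
        if name in _PC_ANCHORS and _PC_ANCHORS[name][0] in feats:
            feat, want = _PC_ANCHORS[name]
            i = feats.index(feat)
            if np.sign(load[i, j]) not in (0.0, want):
                load[:, j] *= -1
                scores[:, j] *= -1
            anchors[name] = f"{feat} loading {'positive' if want > 0 else 'negative'}"
        else:
            # deterministic fallback: largest-|loading| feature positive
            i = int(np.abs(load[:, j]).argmax())
            if load[i, j] < 0:
                load[:, j] *= -1
                scores[:, j] *= -1
            anchors[name] = f"largest-loading feature ({feats[i]}) positive"
    return PCAModel(
        loadings=pd.DataFrame(load, index=feats, columns=pc_names),
        scores=pd.DataFrame(scores, index=samples, columns=pc_names),
        explained_variance_ratio=pca.explained_variance_ratio_,
        anchors=anchors,
    )


def top_correlated_genes(
    expr,
    pc_scores: pd.Series,
    n_top: int = 10,
) -> pd.DataFrame:
    """Probes ranked by descending Spearman correlation with a PC score.

    ``expr`` is an ExpressionMatrix; ``pc_scores`` a Series indexed by
    sample id.  Ties in rho break alphabetically by probe id.
    """
    shared = [s for s in expr.values.columns if s in pc_scores.index]
    if len(shared) < 3:
        raise ValueError("need at least 3 shared samples for rank correlation")
    block = expr.values[shared].to_numpy(dtype=float)
    y = pc_scores.loc[shared].to_numpy(dtype=float)
    ry = rankdata(y)
    rx = np.apply_along_axis(rankdata, 1, block)
    rx_c = rx - rx.mean(axis=1, keepdims=True)
    ry_c = ry - ry.mean()
    denom = np.sqrt((rx_c ** 2).sum(axis=1) * (ry_c ** 2).sum())
    with np.errstate(invalid="ignore"):
        rho = np.where(denom > 0, (rx_c * ry_c).sum(axis=1) / denom, 0.0)
    out = pd.DataFrame({"probe_id": expr.values.index, "rho": rho})
    out = out.sort_values(["rho", "probe_id"], ascending=[False, True], kind="stable")
    return out.head(n_top).reset_index(drop=True)
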