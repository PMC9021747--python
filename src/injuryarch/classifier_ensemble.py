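"""Out-of-fold ensemble classifier probabilities.

Four clinical endpoints are predicted from molecular features: ci-lesion
score > 1, ct-lesion score > 1, eGFR <= 30, and proteinuria positivity.
Each endpoint is scored by an ensemble of probabilistic binary learners
trained in K-fold cross-validation; every sample's score comes only
from models fitted on the other folds (strictly out-of-fold), and the
final per-sample probability is the median across learners.

The learner roster is configurable; the default is three diverse
probabilistic learners.  The contract the downstream analysis depends
on is the out-of-fold median, not a particular roster.
"""

from __future__ import annotations

import logging
import warnings
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .formats import CANONICAL_FEATURES, PBT_FEATURES, validate_scores

__all__ = [
    "ENDPOINTS",
    "binary_targets",
    "make_folds",
    "default_methods",
    "oof_ensemble",
    "assemble_score_table",
]

log = logging.getLogger(__name__)

ENDPOINTS = ["ciProb", "ctProb", "lowGFRProb", "ProtProb"]


def binary_targets(clinical: pd.DataFrame) -> dict[str, pd.Series]:
    """Derive the four binary endpoint labels from the clinical table.

    ci>1 / ct>1 are positive for lesion scores 2-3; lowGFR is positive
    for eGFR <= 30 (boundary included); proteinuria follows its flag.
    Missing inputs yield missing labels, excluded from training.
    """
    idx = pd.Index(clinical["sample_id"].astype(str), name="sample_id")

    def over1(col: str) -> pd.Series:
        s = clinical[col]
        out = pd.array([pd.NA if pd.isna(v) else bool(v > 1) for v in s], dtype="boolean")
        return pd.Series(out, index=idx)

    egfr = clinical["egfr"]
    low = pd.Series(
        pd.array([pd.NA if pd.isna(v) else bool(v <= 30) for v in egfr], dtype="boolean"),
        index=idx,
    )
    prot = pd.Series(pd.array(clinical["proteinuria_positive"], dtype="boolean"), index=idx)
    return {
        "ciProb": over1("ci_score"),
        "ctProb": over1("ct_score"),
        "lowGFRProb": low,
        "ProtProb": prot,
    }


def make_folds(
    sample_ids: Sequence[str],
    labels: Sequence[bool],
    K: int = 10,
    seed: int = 0,
) -> pd.Series:
    """Deterministic fold assignment 1..K, stratified by label when possible.

    Stratification applies when both classes have at least K members;
    otherwise plain shuffled folds.  Fold sizes differ by at most one.
    """
    if K < 2:
        raise ValueError("K must be >= 2")
    ids = np.asarray(list(map(str, sample_ids)))
    y = np.asarray(labels, dtype=bool)
    if len(ids) < K:
        raise ValueError(f"need at least K={K} labeled samples, got {len(ids)}")
    rng = np.random.default_rng(seed)
    folds = np.empty(len(ids), dtype=int)
    stratify = y.sum() >= K and (~y).sum() >= K
    if stratify:
        start = 0
        for cls in (True, False):
            pos = np.flatnonzero(y == cls)
            rng.shuffle(pos)
            # continue the round-robin across strata to keep sizes within 1
            folds[pos] = (np.arange(len(pos)) + start) % K + 1
            start += len(pos)
    else:
        order = rng.permutation(len(ids))
        folds[order] = np.arange(len(ids)) % K + 1
    return pd.Series(folds, index=pd.Index(ids, name="sample_id"), name="fold")


def default_methods(seed: int = 0) -> list[tuple[str, Callable]]:
    """Default roster: three diverse probabilistic learners."""
    from sklearn.ensemble import HistGradientBoostingClassifier, RandomForestClassifier
    from sklearn.linear_model import LogisticRegression
    from sklearn.pipeline import make_pipeline
    from sklearn.preprocessing import StandardScaler

    return [
        (
            "logistic",
            lambda: make_pipeline(
                StandardScaler(), LogisticRegression(max_iter=2000, random_state=seed)
            ),
        ),
        (
            "random_forest",
            lambda: RandomForestClassifier(
                n_estimators=200, min_samples_leaf=2, random_state=seed, n_jobs=1
            ),
        ),
        (
            "grad_boost",
            lambda: HistGradientBoostingClassifier(random_state=seed),
        ),
    ]


def _proba1(model, X: np.ndarray) -> np.ndarray:
    proba = model.predict_proba(X)
    classes = list(model.classes_) if hasattr(model, "classes_") else None
    if classes is not None and True in classes:
        return proba[:, classes.index(True)]
    if classes is not None and 1 in classes:
        return proba[:, classes.index(1)]
    # trained on a single all-negative fold
    return np.zeros(X.shape[0])


def oof_ensemble(
    features: pd.DataFrame,
    endpoint: pd.Series,
    folds: pd.Series | None = None,
    methods: Sequence[tuple[str, Callable]] | None = None,
    seed: int = 0,
    K: int = 10,
) -> pd.DataFrame:
    """Strictly out-of-fold ensemble probabilities for one endpoint.

    For every fold, each method trains on the other K-1 folds only and
    predicts the held-out fold.  Returns a DataFrame over the labeled
    samples with one column per method plus ``final`` (the per-sample
    median across methods).  A method that fails on a fold is excluded
    from that fold's medians with a warning.
    """
    if methods is None:
        methods = default_methods(seed)
    if len(methods) < 1:
        raise ValueError("need at least one method")

    labeled = endpoint.dropna()
    common = features.index.intersection(labeled.index)
    y = labeled.loc[common].astype(bool).to_numpy()
    X = features.loc[common].to_numpy(dtype=float)
    if folds is None:
        folds = make_folds(common, y, K=K, seed=seed)
    f = folds.loc[common].to_numpy()

    out = pd.DataFrame(index=common, dtype=float)
    for name, _ in methods:
        out[name] = np.nan
    for fold_id in np.unique(f):
        train, test = f != fold_id, f == fold_id
        if y[train].all() or not y[train].any():
            log.warning("fold %s: single-class training set", fold_id)
        for name, factory in methods:
            try:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    model = factory()
                    model.fit(X[train], y[train])
                    out.loc[test, name] = _proba1(model, X[test])
            except Exception as exc:  # failed method excluded from this fold's median
                log.warning("method %s failed on fold %s: %s", name, fold_id, exc)
    out["final"] = out[[n for n, _ in methods]].median(axis=1, skipna=True)
    if out["final"].isna().any():
        raise RuntimeError("all methods failed on some fold; no score available")
    return out


def assemble_score_table(
    pbt_scores: pd.DataFrame,
    ensemble_scores: dict[str, pd.Series | pd.DataFrame],
) -> pd.DataFrame:
    """Join PBT scores and the four classifier probabilities into the
    canonical 12-column score table.

    Biopsies lacking any classifier score are dropped with a logged
    count; disjoint sample sets are an error.
    """
    table = pbt_scores[PBT_FEATURES].copy()
    for name in ENDPOINTS:
        s = ensemble_scores[name]
        if isinstance(s, pd.DataFrame):
            s = s["final"]
        table[name] = s.reindex(table.index)
    complete = table.dropna()
    if complete.empty:
        raise ValueError("no biopsy has a complete 12-feature score vector")
    dropped = len(table) - len(complete)
    if dropped:
        log.info("dropped %d biopsies lacking a classifier score", dropped)
    complete = complete[CANONICAL_FEATURES]
    return validate_scores(complete.astype(float))
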