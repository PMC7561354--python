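"""Per-larva behavior vectors, PCA embedding and efficiency prediction.

Each qualifying larva (at least five capture attempts) contributes a
six-dimensional behavior vector: capture efficiency e = Ns / h, number of
attempts n, mean capture speed, mean capture distance, mean turn-ratio and
mean time-to-prey.  Columns are standardized to (x - mu_x) / sigma_x with
one exception: the turn-ratio is centred at 1, the value of a perfectly
aimed first turn, so its sign encodes undershoot vs overshoot.

The embedding is the eigendecomposition of the covariance of the
standardized matrix.  Principal component regression (PCR) predicts
efficiency from the leading PC scores of the five predictor covariates
(efficiency itself is excluded from the predictor matrix by default, so
the prediction is leakage-free); prediction error is reported as a
cross-validated RMSEP and its coefficient of variation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
import numpy as np
import pandas as pd
from sklearn.linear_model import LinearRegression
from sklearn.model_selection import KFold

__all__ = [
    "BEHAVIOR_COLUMNS",
    "MIN_ATTEMPTS",
    "build_behavior_matrix",
    "pca_embed",
    "PCAResult",
    "pcr_efficiency",
    "PCRResult",
]

logger = logging.getLogger(__name__)

MIN_ATTEMPTS = 5
BEHAVIOR_COLUMNS = [
    "efficiency",
    "attempts",
    "capture_speed_mm_s",
    "capture_distance_mm",
    "turn_ratio",
    "t_prey_s",
]
TURN_RATIO_CENTRE = 1.0


def build_behavior_matrix(
    per_larva: pd.DataFrame,
    *,
    min_attempts: int = MIN_ATTEMPTS,
    six_dimensional: bool = True,
    standardize: bool = True,
) -> pd.DataFrame:
    """Assemble and standardize the per-larva behavior matrix.

    ``per_larva`` needs columns larva_id, attempts, successes,
    capture_speed_mm_s, capture_distance_mm, turn_ratio and (for the
    six-dimensional variant) t_prey_s — the three kinematic columns being
    either model-estimated per-larva means (from the group model) or
    empirical means.  Larvae with fewer than ``min_attempts`` capture
    attempts are excluded with a log entry.  Returns the standardized
    matrix indexed by larva_id (raw values in ``.attrs['raw']``).
    """
    df = per_larva.copy()
    low = df["attempts"] < min_attempts
    for lid in df.loc[low, "larva_id"]:
        logger.info("excluding larva %s: fewer than %d capture attempts", lid, min_attempts)
    df = df.loc[~low].reset_index(drop=True)
    df["efficiency"] = df["successes"] / df["attempts"]
    cols = BEHAVIOR_COLUMNS if six_dimensional else BEHAVIOR_COLUMNS[:-1]
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ValueError(f"missing behavior columns: {missing}")
    mat = df.set_index("larva_id")[cols].astype(float).dropna()
    raw = mat.copy()
    if standardize:
        centre = mat.mean()
        centre["turn_ratio"] = TURN_RATIO_CENTRE
        mat = (mat - centre) / raw.std(ddof=1)
    mat.attrs["raw"] = raw
    return mat


@dataclass
class PCAResult:
    loadings: pd.DataFrame  # columns PC1.., rows = behavior variables
    scores: pd.DataFrame  # rows = larvae
    explained_variance_ratio: np.ndarray


def pca_embed(matrix: pd.DataFrame) -> PCAResult:
    """Eigendecomposition of the covariance of the standardized matrix.

    Components are ordered by decreasing eigenvalue with a deterministic
    sign convention (the largest-magnitude loading of each component is
    positive).  Rank-deficient input yields fewer components, with notice.
    """
    X = matrix.to_numpy(dtype=float)
    if X.shape[0] < 3:
        raise ValueError("PCA needs at least 3 larvae")
    Xc = X - X.mean(axis=0)
    cov = np.cov(Xc, rowvar=False, ddof=1)
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    tol = max(X.shape) * np.finfo(float).eps * max(evals.max(), 0)
    rank = int(np.sum(evals > tol))
    if rank < len(evals):
        logger.info("rank-deficient matrix: keeping %d of %d components", rank, len(evals))
    evals, evecs = evals[:rank], evecs[:, :rank]
    # sign convention: largest-|loading| entry positive
    for j in range(rank):
        k = np.argmax(np.abs(evecs[:, j]))
        if evecs[k, j] < 0:
            evecs[:, j] = -evecs[:, j]
    names = [f"PC{j + 1}" for j in range(rank)]
    scores = Xc @ evecs
    return PCAResult(
        loadings=pd.DataFrame(evecs, index=matrix.columns, columns=names),
        scores=pd.DataFrame(scores, index=matrix.index, columns=names),
        explained_variance_ratio=evals / evals.sum(),
    )


@dataclass
class PCRResult:
    n_components: int
    coefficients: np.ndarray  # regression coefficients on PC scores
    intercept: float
    r2_insample: float  # fraction of response variance explained in-sample
    rmsep: float  # cross-validated root mean squared prediction error
    rmsep_cv: float  # RMSEP / mean response (coefficient of variation)
    cumulative_r2: np.ndarray  # in-sample R^2 for 1..n_components
    pca: PCAResult


def pcr_efficiency(
    matrix: pd.DataFrame,
    n_components: int = 2,
    *,
    response: str = "efficiency",
    exclude_response: bool = True,
    n_folds: int = 10,
    seed: int = 0,
    cv_denominator: str = "mean",
) -> PCRResult:
    """Principal component regression of capture efficiency.

    PCA runs on the predictor covariates (the response column is dropped
    first when ``exclude_response``, the default, so no leakage); the
    response is regressed on the leading ``n_components`` PC scores.
    RMSEP comes from seeded k-fold cross-validation; its coefficient of
    variation divides by the response mean (or sd, selectable).
    """
    # regress the response on its original scale (RMSEP and CV are then in
    # efficiency units); predictors stay standardized
    raw = matrix.attrs.get("raw")
    y = (raw if raw is not None else matrix)[response].to_numpy(dtype=float)
    pred = matrix.drop(columns=[response]) if exclude_response else matrix
    pca = pca_embed(pred)
    scores = pca.scores.to_numpy()
    if n_components > scores.shape[1]:
        raise ValueError(
            f"n_components={n_components} exceeds available rank {scores.shape[1]}"
        )

    cum_r2 = []
    for k in range(1, n_components + 1):
        model = LinearRegression().fit(scores[:, :k], y)
        cum_r2.append(model.score(scores[:, :k], y))
    model = LinearRegression().fit(scores[:, :n_components], y)

    n = len(y)
    folds = KFold(n_splits=min(n_folds, n), shuffle=True, random_state=seed)
    sq_err = np.empty(n)
    for train, test in folds.split(scores):
        m = LinearRegression().fit(scores[train, :n_components], y[train])
        sq_err[test] = (y[test] - m.predict(scores[test, :n_components])) ** 2
    rmsep = float(np.sqrt(sq_err.mean()))
    denom = float(np.mean(y)) if cv_denominator == "mean" else float(np.std(y, ddof=1))

    return PCRResult(
        n_components=n_components,
        coefficients=model.coef_.copy(),
        intercept=float(model.intercept_),
        r2_insample=float(cum_r2[-1]),
        rmsep=rmsep,
        rmsep_cv=rmsep / denom if denom else np.nan,
        cumulative_r2=np.asarray(cum_r2),
        pca=pca,
    )
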