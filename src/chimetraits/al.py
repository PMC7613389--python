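"""Active-learning LUT optimization (the HAL sample-selection loop).

Starting from a small randomly seeded training pool, candidates from the
LUT are ranked by one of five heuristics, proposed one at a time, and kept
only when the retrained model strictly improves the validation RMSE.  Every
LUT sample is considered exactly once; the result is a reduced LUT holding
only the spectra that increased model performance.

Heuristics
----------
Diversity-based: EBD (min Euclidean distance to the labeled pool), ABD
(min spectral angle to the labeled pool), CBD (k-means clusters least
represented in the labeled pool first).  Uncertainty-based: PAL (variance
across a bootstrap pool of regressors), RSAL (a residual-magnitude
regression predicts where the current model errs most).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

from . import gpr
from .metrics import compute_metrics

logger = logging.getLogger(__name__)

__all__ = [
    "ALState",
    "HEURISTICS",
    "rank_ebd",
    "rank_abd",
    "rank_cbd",
    "rank_pal",
    "rank_rsal",
    "al_run",
]


def rank_ebd(candidates: np.ndarray, labeled: np.ndarray) -> np.ndarray:
    """Euclidean distance-based diversity: most distant candidates first.

    score(c) = min over labeled ℓ of ||x_c − x_ℓ||₂, descending.
    Returns positions into ``candidates``.
    """
    cand = np.atleast_2d(np.asarray(candidates, dtype=float))
    lab = np.atleast_2d(np.asarray(labeled, dtype=float))
    if lab.shape[0] == 0:
        raise ValueError("EBD requires a non-empty labeled pool")
    d2 = (
        np.sum(cand**2, axis=1)[:, None]
        + np.sum(lab**2, axis=1)[None, :]
        - 2.0 * cand @ lab.T
    )
    scores = np.sqrt(np.maximum(d2.min(axis=1), 0.0))
    return _stable_descending(scores)


def rank_abd(candidates: np.ndarray, labeled: np.ndarray) -> np.ndarray:
    """Angle-based diversity: largest minimum spectral angle first.

    score(c) = min over labeled ℓ of arccos(⟨x_c, x_ℓ⟩ / (‖x_c‖‖x_ℓ‖)),
    descending.  Zero-norm candidates are excluded (ranked last) with a
    warning.
    """
    cand = np.atleast_2d(np.asarray(candidates, dtype=float))
    lab = np.atleast_2d(np.asarray(labeled, dtype=float))
    cand_norm = np.linalg.norm(cand, axis=1)
    lab_norm = np.linalg.norm(lab, axis=1)
    lab_ok = lab_norm > 0
    if not lab_ok.any():
        raise ValueError("ABD requires at least one non-zero labeled vector")
    zero_cand = cand_norm == 0
    if zero_cand.any():
        logger.warning("ABD: %d zero-norm candidate(s) ranked last", zero_cand.sum())
    cosines = (cand @ lab[lab_ok].T) / np.outer(
        np.where(cand_norm > 0, cand_norm, 1.0), lab_norm[lab_ok]
    )
    angles = np.arccos(np.clip(cosines, -1.0, 1.0))
    scores = angles.min(axis=1)
    scores[zero_cand] = -1.0
    return _stable_descending(scores)


def rank_cbd(
    candidates: np.ndarray, labeled: np.ndarray, seed: int = 0, n_clusters: int = 10
) -> np.ndarray:
    """Cluster-based diversity.

    k-means over the candidates (k = min(n_clusters, #candidates), seeded);
    clusters are visited in ascending order of how many labeled points they
    contain, and candidates within a cluster are ordered by proximity to the
    centroid.  Ties break by candidate position.
    """
    cand = np.atleast_2d(np.asarray(candidates, dtype=float))
    lab = np.atleast_2d(np.asarray(labeled, dtype=float))
    if cand.shape[0] < 2:
        return np.arange(cand.shape[0])
    k = min(n_clusters, cand.shape[0])
    km = KMeans(n_clusters=k, random_state=seed, n_init=4)
    assign = km.fit_predict(cand)
    centroids = km.cluster_centers_
    if lab.shape[0]:
        lab_assign = np.argmin(
            np.linalg.norm(lab[:, None, :] - centroids[None, :, :], axis=2), axis=1
        )
        lab_counts = np.bincount(lab_assign, minlength=k)
    else:
        lab_counts = np.zeros(k, dtype=int)
    order = []
    for cluster in sorted(range(k), key=lambda c: (lab_counts[c], c)):
        members = np.flatnonzero(assign == cluster)
        dists = np.linalg.norm(cand[members] - centroids[cluster], axis=1)
        order.extend(members[np.lexsort((members, dists))])
    return np.asarray(order, dtype=int)


def rank_pal(
    candidates: np.ndarray,
    labeled_X: np.ndarray,
    labeled_y: np.ndarray,
    n_regressors: int = 5,
    seed: int = 0,
    hp: gpr.GPRHyperparams | None = None,
) -> np.ndarray:
    """Variance-based pool of regressors.

    ``n_regressors`` GP models are trained on seeded bootstrap resamples of
    the labeled pool; candidates with the largest ensemble prediction
    variance rank first.  If hyperparameters are supplied the ensemble is
    solved at fixed θ (the AL loop passes the current model's θ).
    """
    cand = np.atleast_2d(np.asarray(candidates, dtype=float))
    X = np.atleast_2d(np.asarray(labeled_X, dtype=float))
    y = np.asarray(labeled_y, dtype=float)
    if len(y) < 4:
        raise ValueError("PAL requires at least 4 labeled samples")
    rng = np.random.default_rng(seed)
    preds = np.empty((n_regressors, cand.shape[0]))
    for m in range(n_regressors):
        for _ in range(50):
            idx = rng.integers(0, len(y), size=len(y))
            if np.unique(idx).size >= 2 and np.ptp(y[idx]) > 0:
                break
        model = (
            gpr.refit_solve(X[idx], y[idx], hp)
            if hp is not None
            else gpr.fit(X[idx], y[idx], restarts=1, seed=seed + m)
        )
        preds[m], _ = gpr.predict(model, cand)
    scores = preds.var(axis=0)
    return _stable_descending(scores)


def rank_rsal(
    candidates: np.ndarray,
    labeled_X: np.ndarray,
    labeled_y: np.ndarray,
    seed: int = 0,
    n_folds: int = 5,
    hp: gpr.GPRHyperparams | None = None,
) -> np.ndarray:
    """Residual regression AL.

    Out-of-fold absolute residuals of the main model are computed on a
    seeded k-fold split of the labeled pool; an auxiliary GP regresses
    |residual| on the inputs, and candidates where it predicts the largest
    residuals rank first.
    """
    from sklearn.model_selection import KFold

    cand = np.atleast_2d(np.asarray(candidates, dtype=float))
    X = np.atleast_2d(np.asarray(labeled_X, dtype=float))
    y = np.asarray(labeled_y, dtype=float)
    if len(y) < 4:
        raise ValueError("RSAL requires at least 4 labeled samples")
    folds = min(n_folds, len(y))
    if folds < n_folds:
        logger.warning("RSAL: reducing folds to %d for pool size %d", folds, len(y))
    residuals = np.empty_like(y)
    splitter = KFold(n_splits=folds, shuffle=True, random_state=seed)
    for tr, te in splitter.split(X):
        model = (
            gpr.refit_solve(X[tr], y[tr], hp)
            if hp is not None
            else gpr.fit(X[tr], y[tr], restarts=1, seed=seed)
        )
        mean, _ = gpr.predict(model, X[te])
        residuals[te] = np.abs(y[te] - mean)
    aux = gpr.fit(X, residuals, restarts=1, seed=seed)
    scores, _ = gpr.predict(aux, cand)
    return _stable_descending(np.asarray(scores))


def _stable_descending(scores: np.ndarray) -> np.ndarray:
    """Descending argsort with ties broken by position (total order, no NaN)."""
    scores = np.asarray(scores, dtype=float)
    if np.any(~np.isfinite(scores)):
        raise ValueError("heuristic produced non-finite scores")
    return np.lexsort((np.arange(scores.size), -scores))


HEURISTICS = ("EBD", "ABD", "CBD", "PAL", "RSAL")


@dataclass
class ALState:
    """Audit trail of one active-learning run."""

    heuristic: str
    labeled_idx: list[int]
    candidate_idx: list[int]
    history: list[dict] = field(default_factory=list)

    def history_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.history, columns=["iteration", "candidate_id", "accepted", "rmse"]
        )

    def to_csv(self, path) -> None:
        self.history_frame().to_csv(path, index=False)


def _rank(heuristic, cand_X, lab_X, lab_y, seed, hp):
    if heuristic == "EBD":
        return rank_ebd(cand_X, lab_X)
    if heuristic == "ABD":
        return rank_abd(cand_X, lab_X)
    if heuristic == "CBD":
        return rank_cbd(cand_X, lab_X, seed=seed)
    if heuristic == "PAL":
        return rank_pal(cand_X, lab_X, lab_y, seed=seed, hp=hp)
    if heuristic == "RSAL":
        return rank_rsal(cand_X, lab_X, lab_y, seed=seed, hp=hp)
    raise ValueError(f"unknown AL heuristic {heuristic!r}; choose from {HEURISTICS}")


def al_run(
    lut_X: np.ndarray,
    lut_y: np.ndarray,
    val_X: np.ndarray,
    val_y: np.ndarray,
    heuristic: str = "EBD",
    init_size: int = 20,
    seed: int = 0,
    restarts: int = 1,
    refit_every: int = 5,
) -> tuple[np.ndarray, gpr.GPRModel, ALState]:
    """Run the accept-if-better sample-selection loop.

    Parameters
    ----------
    lut_X, lut_y : candidate pool (LUT) inputs and targets.
    val_X, val_y : validation set guiding acceptance and reporting metrics.
    heuristic : one of EBD, ABD, CBD, PAL, RSAL.
    init_size : size of the random initial pool (default 20).
    refit_every : hyperparameters are re-optimized after this many accepted
        samples (default: every acceptance); trial candidates are always
        evaluated by re-solving at the current θ, so rejections stay cheap.
        A post-acceptance refit is adopted only if it does not worsen the
        validation RMSE, preserving strict monotonicity.

    Returns the reduced-pool indices (into the LUT), the best model and the
    ALState audit trail.  Accepted-step validation RMSE is strictly
    decreasing by construction; the final model is never worse than the
    initial one.
    """
    if heuristic not in HEURISTICS:
        raise ValueError(f"unknown AL heuristic {heuristic!r}; choose from {HEURISTICS}")
    lut_X = np.atleast_2d(np.asarray(lut_X, dtype=float))
    lut_y = np.asarray(lut_y, dtype=float)
    val_X = np.atleast_2d(np.asarray(val_X, dtype=float))
    val_y = np.asarray(val_y, dtype=float)
    if init_size < 2:
        raise ValueError("init_size must be >= 2")
    if len(val_y) == 0:
        raise ValueError("validation set must be non-empty")
    rng = np.random.default_rng(seed)
    all_idx = np.arange(len(lut_y))
    labeled = list(rng.choice(all_idx, size=min(init_size, len(all_idx)), replace=False))
    candidates = [i for i in all_idx if i not in set(labeled)]

    model = gpr.fit(lut_X[labeled], lut_y[labeled], restarts=max(restarts, 1), seed=seed)
    pred, _ = gpr.predict(model, val_X)
    best_rmse = compute_metrics(val_y, pred).rmse if len(val_y) >= 2 else float(
        np.sqrt(np.mean((val_y - pred) ** 2))
    )
    state = ALState(heuristic, labeled, list(candidates))
    state.history.append(
        {"iteration": 0, "candidate_id": -1, "accepted": True, "rmse": best_rmse}
    )

    iteration = 0
    accepted_since_refit = 0
    ranking: list[int] = []
    need_rank = True
    while candidates:
        iteration += 1
        if need_rank or not ranking:
            order = _rank(
                heuristic,
                lut_X[candidates],
                lut_X[labeled],
                lut_y[labeled],
                seed + iteration,
                model.hyperparams,
            )
            ranking = [candidates[i] for i in order]
            need_rank = False
        pick = ranking.pop(0)
        candidates.remove(pick)
        trial = labeled + [pick]
        trial_model = gpr.refit_solve(lut_X[trial], lut_y[trial], model.hyperparams)
        pred, _ = gpr.predict(trial_model, val_X)
        rmse = float(np.sqrt(np.mean((val_y - pred) ** 2)))
        accepted = rmse < best_rmse
        if accepted:
            labeled = trial
            model = trial_model
            best_rmse = rmse
            accepted_since_refit += 1
            if accepted_since_refit >= refit_every:
                refit = gpr.fit(
                    lut_X[labeled], lut_y[labeled], restarts=max(restarts, 1), seed=seed
                )
                pred, _ = gpr.predict(refit, val_X)
                refit_rmse = float(np.sqrt(np.mean((val_y - pred) ** 2)))
                if refit_rmse <= best_rmse:
                    model = refit
                    best_rmse = refit_rmse
                accepted_since_refit = 0
            need_rank = True  # pool changed: re-rank remaining candidates
        state.history.append(
            {
                "iteration": iteration,
                "candidate_id": int(pick),
                "accepted": accepted,
                "rmse": best_rmse if accepted else rmse,
            }
        )
    state.labeled_idx = list(labeled)
    state.candidate_idx = []
    return np.asarray(labeled), model, state
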