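"""Two-group PLS discriminant analysis with cross-validated diagnostics.

Components are extracted by NIPALS on column-autoscaled X against a
centered ±1 class vector (PLS1). R² is the cumulative fraction of
class-variable variance explained in-fit; Q² its cross-validated
counterpart, 1 − PRESS/SS over held-out class predictions; accuracy is the
fraction of held-out samples whose predicted class (sign of the predicted
response) is correct. Cross-validation is leave-one-out for small samples
(n < 20, the regime of 6–8 animals per group) and stratified 10-fold
otherwise. Scaling parameters are always re-estimated inside each training
fold, never from the full data.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold

__all__ = ["PlsdaModel", "fit_plsda", "plsda_predict", "plsda_q2",
           "plsda_accuracy", "plsda_scores_export"]

_EPS = 1e-12


def _encode(y) -> tuple[np.ndarray, list]:
    """±1 coding; the positive class is the first label encountered."""
    y = np.asarray(y)
    classes = list(pd.unique(y))
    if len(classes) != 2:
        raise ValueError(f"PLS-DA requires exactly two classes, got {classes}")
    return np.where(y == classes[0], 1.0, -1.0), classes


@dataclass
class PlsdaModel:
    """Fitted PLS1 discriminant model (all arrays are training-data shaped)."""

    weights: np.ndarray        # (d, A) X-weights, unit norm
    loadings: np.ndarray       # (d, A) X-loadings
    scores: np.ndarray         # (n, A) X-scores, mutually orthogonal
    y_loadings: np.ndarray     # (A,) regression of y on each score
    classes: list              # [positive, negative] original labels
    x_mean: np.ndarray
    x_sd: np.ndarray
    y_mean: float
    r2: np.ndarray             # cumulative R2 per component count (A,)

    @property
    def n_components(self) -> int:
        return self.weights.shape[1]

    def coefficients(self, k: int | None = None) -> np.ndarray:
        """Regression vector on the autoscaled X for the first k components."""
        k = self.n_components if k is None else k
        W, P, c = self.weights[:, :k], self.loadings[:, :k], self.y_loadings[:k]
        return W @ np.linalg.solve(P.T @ W, c)


def fit_plsda(X, y, n_components: int = 5, *, scale: bool = True) -> PlsdaModel:
    """NIPALS PLS-DA fit on autoscaled X against a centered ±1 class vector.

    Deterministic for fixed input. Deflation stops early (recording the
    actual component count) when the residual weight vector collapses.
    ``scale=False`` skips unit-variance scaling (columns are still
    centered), for callers that standardize externally.
    """
    X = np.asarray(X, dtype=float)
    y_num, classes = _encode(y)
    n, d = X.shape
    counts = [int((y_num == 1).sum()), int((y_num == -1).sum())]
    if min(counts) < 3:
        raise ValueError("each class needs >= 3 samples")
    if n_components > min(n - 1, d):
        raise ValueError(f"n_components={n_components} exceeds "
                         f"min(n_samples-1, n_features) = {min(n - 1, d)}")

    x_mean = X.mean(axis=0)
    if scale:
        x_sd = X.std(axis=0, ddof=1)
        x_sd = np.where(x_sd < _EPS, 1.0, x_sd)
    else:
        x_sd = np.ones(d)
    Xa = (X - x_mean) / x_sd
    y_mean = float(y_num.mean())
    ya = y_num - y_mean
    ss_y = float(ya @ ya)

    W, P, T, C, r2 = [], [], [], [], []
    for _ in range(n_components):
        w = Xa.T @ ya
        nw = np.linalg.norm(w)
        if nw < _EPS:
            break
        w = w / nw
        t = Xa @ w
        tt = float(t @ t)
        if tt < _EPS:
            break
        p = Xa.T @ t / tt
        c = float(ya @ t) / tt
        Xa = Xa - np.outer(t, p)
        ya = ya - c * t
        W.append(w); P.append(p); T.append(t); C.append(c)
        r2.append(1.0 - float(ya @ ya) / ss_y if ss_y > 0 else 1.0)
    if not W:
        raise ValueError("no extractable PLS component (X carries no "
                         "covariance with the class vector)")
    return PlsdaModel(np.column_stack(W), np.column_stack(P),
                      np.column_stack(T), np.array(C), classes,
                      x_mean, x_sd, y_mean, np.array(r2))


def plsda_predict(model: PlsdaModel, X, k: int | None = None) -> np.ndarray:
    """Continuous class prediction (around ±1) for new samples."""
    Xs = (np.asarray(X, dtype=float) - model.x_mean) / model.x_sd
    return model.y_mean + Xs @ model.coefficients(k)


def _folds(y_num: np.ndarray, seed: int = 0):
    """LOO below n=20, else stratified 10-fold; refold on a degenerate fold."""
    n = len(y_num)
    if n < 20:
        return [(np.delete(np.arange(n), i), np.array([i])) for i in range(n)]
    for attempt in range(10):
        cv = StratifiedKFold(n_splits=10, shuffle=True,
                             random_state=seed + attempt)
        folds = list(cv.split(np.zeros(n), y_num))
        if all(len(np.unique(y_num[tr])) == 2 for tr, _ in folds):
            return folds
    raise ValueError("could not build folds with both classes present")


def _cv_predictions(X, y, n_components: int, seed: int = 0):
    """Held-out continuous predictions per cumulative component count."""
    X = np.asarray(X, dtype=float)
    y_num, classes = _encode(y)
    n = len(y_num)
    preds = np.full((n, n_components), np.nan)
    ss = 0.0
    for tr, te in _folds(y_num, seed):
        model = fit_plsda(X[tr], np.asarray(y)[tr], n_components)
        for k in range(1, n_components + 1):
            kk = min(k, model.n_components)
            preds[te, k - 1] = plsda_predict(model, X[te], kk)
        ss += float(((y_num[te] - y_num[tr].mean()) ** 2).sum())
    return preds, y_num, classes, ss


def plsda_q2(X, y, n_components: int = 5, seed: int = 0) -> np.ndarray:
    """Cross-validated predictive fraction Q² per cumulative component count.

    Q²(k) = 1 − PRESS(k)/SS with PRESS summed over held-out predictions and
    SS the held-out squared deviation from the training-fold class mean.
    """
    preds, y_num, _, ss = _cv_predictions(X, y, n_components, seed)
    press = ((y_num[:, None] - preds) ** 2).sum(axis=0)
    return 1.0 - press / ss


def plsda_accuracy(X, y, n_components: int = 5, seed: int = 0,
                   *, resubstitution: bool = False) -> float:
    """Fraction of samples classified correctly by the sign of the predicted
    response — cross-validated by default, in-fit with ``resubstitution``."""
    if resubstitution:
        model = fit_plsda(X, y, n_components)
        pred = plsda_predict(model, X)
        y_num, _ = _encode(y)
        return float((np.sign(pred) == y_num).mean())
    preds, y_num, _, _ = _cv_predictions(X, y, n_components, seed)
    return float((np.sign(preds[:, -1]) == y_num).mean())


def plsda_scores_export(model: PlsdaModel, sample_ids=None) -> pd.DataFrame:
    """Per-sample coordinates on the first two components, for score plots."""
    k = min(2, model.n_components)
    out = pd.DataFrame(model.scores[:, :k],
                       columns=[f"component_{i + 1}" for i in range(k)])
    if sample_ids is not None:
        out.index = pd.Index(sample_ids, name="sample_id")
    return out
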