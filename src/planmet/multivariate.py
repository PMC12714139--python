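"""PCA and PLS-DA with SIMCA-style validation statistics.

PLS-DA is NIPALS PLS2 against a one-hot, column-centred class matrix, with
per-component deflation of X and Y.  Model quality is summarised the way
chemometrics software reports it:

* R2X(cum), R2Y(cum) — cumulative fractions of X / Y variance explained;
* Q2(cum) — cross-validated predictive ability from K-fold (default
  sevenfold) CV using the product rule
  ``Q2(cum) = 1 - prod_a PRESS_a / SS_{a-1}``, where ``PRESS_a`` is the
  out-of-fold prediction error of the a-component model and ``SS_{a-1}``
  the residual Y sum of squares after a-1 components fitted on the full
  data (the simpler global ``1 - PRESS_A/SS_0`` is available via
  ``q2_rule="global"``);
* CV-ANOVA — an F test of the cross-validated residuals against total Y
  variation: ``F = ((SSY - PRESS)/A) / (PRESS/(n - 1 - A))`` on
  (A, n - 1 - A) degrees of freedom.

Cross-validation folds are random, stratified by class and seed
controlled.  When the requested number of components is None, A is chosen
to maximise Q2(cum), capped at 5.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .io import ValidationError

__all__ = ["PLSModel", "pca", "plsda_fit", "q2_crossval", "cv_anova"]

MAX_AUTO_COMPONENTS = 5
NIPALS_TOL = 1e-12
NIPALS_MAX_ITER = 500


# ---------------------------------------------------------------------------
# PCA
# ---------------------------------------------------------------------------

def pca(matrix: np.ndarray, n_components: int,
        ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Principal components of a preprocessed samples x features matrix.

    Returns (scores, loadings, r2x per component); component k explains
    ``r2x[k]`` of the total (centred) variance.  Computed by SVD after
    centring.
    """
    x = np.asarray(matrix, dtype=float)
    n, m = x.shape
    if n_components > min(n - 1, m):
        raise ValidationError(
            f"n_components={n_components} exceeds min(n_samples-1, "
            f"n_features)={min(n - 1, m)}")
    xc = x - x.mean(axis=0)
    u, s, vt = np.linalg.svd(xc, full_matrices=False)
    total = float((s ** 2).sum())
    scores = u[:, :n_components] * s[:n_components]
    loadings = vt[:n_components].T
    r2x = (s[:n_components] ** 2) / total
    return scores, loadings, r2x


# ---------------------------------------------------------------------------
# PLS-DA
# ---------------------------------------------------------------------------

def _one_hot(classes) -> tuple[np.ndarray, list]:
    labels = sorted(set(classes))
    if len(labels) < 2:
        raise ValidationError("PLS-DA needs >= 2 classes")
    lookup = {c: i for i, c in enumerate(labels)}
    y = np.zeros((len(classes), len(labels)))
    for i, c in enumerate(classes):
        y[i, lookup[c]] = 1.0
    return y, labels


def _nipals(x: np.ndarray, y: np.ndarray, n_components: int,
            ) -> dict[str, np.ndarray]:
    """NIPALS PLS2 on centred X, Y; returns weights/scores/loadings and
    per-component explained sums of squares."""
    xr, yr = x.copy(), y.copy()
    n, m = x.shape
    ssx0 = float((x ** 2).sum())
    ssy0 = float((y ** 2).sum())
    W = np.zeros((m, n_components))
    P = np.zeros((m, n_components))
    C = np.zeros((y.shape[1], n_components))
    T = np.zeros((n, n_components))
    r2x = np.zeros(n_components)
    ssy_resid = np.zeros(n_components + 1)
    ssy_resid[0] = ssy0
    for a in range(n_components):
        u = yr[:, np.argmax((yr ** 2).sum(axis=0))].copy()
        t = np.zeros(n)
        for _ in range(NIPALS_MAX_ITER):
            w = xr.T @ u / (u @ u)
            nw = np.linalg.norm(w)
            if nw == 0:
                raise ValidationError(
                    f"NIPALS component {a + 1}: X residual exhausted")
            w /= nw
            t_new = xr @ w
            c = yr.T @ t_new / (t_new @ t_new)
            u = yr @ c / (c @ c)
            if np.linalg.norm(t_new - t) <= NIPALS_TOL * max(
                    np.linalg.norm(t_new), 1e-30):
                t = t_new
                break
            t = t_new
        else:
            raise ValidationError(
                f"NIPALS did not converge for component {a + 1} "
                f"after {NIPALS_MAX_ITER} iterations")
        p = xr.T @ t / (t @ t)
        xr = xr - np.outer(t, p)
        yr = yr - np.outer(t, c)
        W[:, a], P[:, a], C[:, a], T[:, a] = w, p, c, t
        r2x[a] = (t @ t) * (p @ p) / ssx0 if ssx0 > 0 else 0.0
        ssy_resid[a + 1] = float((yr ** 2).sum())
    return {"W": W, "P": P, "C": C, "T": T, "r2x": r2x,
            "ssx0": ssx0, "ssy0": ssy0, "ssy_resid": ssy_resid}


def _regression_coef(W: np.ndarray, P: np.ndarray, C: np.ndarray,
                     a: int) -> np.ndarray:
    """B such that Yhat = Xc @ B for the a-component model."""
    w, p, c = W[:, :a], P[:, :a], C[:, :a]
    return w @ np.linalg.solve(p.T @ w, c.T)


@dataclass
class PLSModel:
    """Fitted PLS-DA model with cross-validated quality statistics."""

    n_components: int
    scores: np.ndarray            # T (n x A)
    x_loadings: np.ndarray        # P (m x A)
    weights: np.ndarray           # W (m x A)
    y_loadings: np.ndarray        # C (g x A)
    x_mean: np.ndarray
    y_mean: np.ndarray
    class_labels: list
    r2x_cum: float
    r2y_cum: float
    r2x_per_component: np.ndarray
    q2_cum: float = np.nan
    press_per_component: np.ndarray = field(
        default_factory=lambda: np.array([]))
    cv_anova_F: float = np.nan
    cv_anova_p: float = np.nan

    def predict(self, x_new: np.ndarray) -> np.ndarray:
        b = _regression_coef(self.weights, self.x_loadings,
                             self.y_loadings, self.n_components)
        return (np.asarray(x_new) - self.x_mean) @ b + self.y_mean

    def summary(self) -> dict[str, float]:
        return {"n_components": self.n_components,
                "r2x_cum": self.r2x_cum, "r2y_cum": self.r2y_cum,
                "q2_cum": self.q2_cum, "cv_anova_F": self.cv_anova_F,
                "cv_anova_p": self.cv_anova_p}


def _stratified_folds(classes, folds: int, seed: int,
                      rng: np.random.Generator | None = None) -> np.ndarray:
    """Fold assignment per sample: random, stratified by class."""
    rng = rng or np.random.default_rng(seed)
    classes = np.asarray(classes)
    assign = np.empty(len(classes), dtype=int)
    offset = 0
    for label in sorted(set(classes.tolist())):
        idx = np.flatnonzero(classes == label)
        idx = rng.permutation(idx)
        # rotate starting fold between classes to even out fold sizes
        assign[idx] = (np.arange(len(idx)) + offset) % folds
        offset += len(idx)
    return assign


def q2_crossval(x: np.ndarray, classes, n_components: int, folds: int = 7,
                seed: int = 0) -> tuple[float, np.ndarray]:
    """K-fold cross-validated Q2(cum) and PRESS per component.

    PRESS_a sums squared out-of-fold Y errors of the a-component model
    (each fold's model is centred on its training data);
    Q2(cum) = 1 - prod_a PRESS_a / SS_{a-1} with SS from the full-data fit.
    """
    x = np.asarray(x, dtype=float)
    y, labels = _one_hot(classes)
    n = x.shape[0]
    if folds > n:
        raise ValidationError(f"folds={folds} exceeds n_samples={n}")
    counts = {c: list(classes).count(c) for c in labels}
    if folds > min(counts.values()):
        warnings.warn(
            f"folds={folds} exceeds the smallest class size "
            f"{min(counts.values())}; stratification relaxed")
    assign = _stratified_folds(classes, folds, seed)
    press = np.zeros(n_components)
    for f in range(folds):
        test = assign == f
        train = ~test
        if not test.any():
            continue
        if len(set(np.asarray(classes)[train].tolist())) < 2:
            raise ValidationError(
                f"fold {f} leaves a single class in training data")
        xm = x[train].mean(axis=0)
        ym = y[train].mean(axis=0)
        fit = _nipals(x[train] - xm, y[train] - ym, n_components)
        xt = x[test] - xm
        for a in range(1, n_components + 1):
            b = _regression_coef(fit["W"], fit["P"], fit["C"], a)
            err = y[test] - (xt @ b + ym)
            press[a - 1] += float((err ** 2).sum())
    full = _nipals(x - x.mean(axis=0), y - y.mean(axis=0), n_components)
    ss_prev = full["ssy_resid"][:n_components]   # SS_{a-1}
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(ss_prev > 0, press / ss_prev, np.inf)
    q2_cum = 1.0 - float(np.prod(ratio))
    return q2_cum, press


def cv_anova(n_components: int, press_total: float, ssy_total: float,
             n_samples: int) -> tuple[float, float]:
    """CV-ANOVA F and p for a cross-validated PLS model.

    F = ((SSY - PRESS)/A) / (PRESS/(n - 1 - A)) on (A, n - 1 - A) df;
    when PRESS >= SSY the model has no predictive ability and p = 1.
    """
    a = n_components
    df2 = n_samples - 1 - a
    if df2 <= 0:
        raise ValidationError(
            f"CV-ANOVA needs n - 1 - A > 0 (n={n_samples}, A={a})")
    if press_total >= ssy_total:
        return 0.0, 1.0
    f = ((ssy_total - press_total) / a) / (press_total / df2)
    return float(f), float(stats.f.sf(f, a, df2))


def plsda_fit(x: np.ndarray, classes, n_components: int | None = None,
              folds: int = 7, seed: int = 0, q2_rule: str = "product",
              cross_validate: bool = True) -> PLSModel:
    """Fit PLS-DA and attach cross-validated quality statistics.

    ``x`` is a preprocessed samples x features matrix; ``classes`` the
    per-sample labels.  With ``n_components=None`` the component count
    maximising Q2(cum) (capped at 5) is used.
    """
    x = np.asarray(x, dtype=float)
    y, labels = _one_hot(classes)
    counts = {c: list(classes).count(c) for c in labels}
    if min(counts.values()) < 2:
        raise ValidationError("every class needs >= 2 samples")
    n = x.shape[0]
    max_a = min(MAX_AUTO_COMPONENTS, n - 2, np.linalg.matrix_rank(x))

    if n_components is None:
        if not cross_validate:
            raise ValidationError(
                "automatic component selection requires cross-validation")
        best_a, best_q2 = 1, -np.inf
        for a in range(1, max_a + 1):
            q2, _ = q2_crossval(x, classes, a, folds=folds, seed=seed)
            if q2 > best_q2:
                best_a, best_q2 = a, q2
        n_components = best_a

    xm, ym = x.mean(axis=0), y.mean(axis=0)
    fit = _nipals(x - xm, y - ym, n_components)
    r2y_cum = 1.0 - fit["ssy_resid"][n_components] / fit["ssy0"] \
        if fit["ssy0"] > 0 else np.nan
    model = PLSModel(
        n_components=n_components, scores=fit["T"],
        x_loadings=fit["P"], weights=fit["W"], y_loadings=fit["C"],
        x_mean=xm, y_mean=ym, class_labels=labels,
        r2x_cum=float(fit["r2x"].sum()), r2y_cum=float(r2y_cum),
        r2x_per_component=fit["r2x"],
    )
    if cross_validate:
        q2, press = q2_crossval(x, classes, n_components, folds=folds,
                                seed=seed)
        if q2_rule == "global":
            model.q2_cum = 1.0 - press[-1] / fit["ssy0"]
        elif q2_rule == "product":
            model.q2_cum = q2
        else:
            raise ValidationError(f"unknown q2_rule {q2_rule!r}")
        model.press_per_component = press
        model.cv_anova_F, model.cv_anova_p = cv_anova(
            n_components, float(press[-1]), fit["ssy0"], n)
    return model
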