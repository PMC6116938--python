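"""Group-affinity and sex classification of craniometric tables.

Affinity: linear discriminant analysis (pooled within-class covariance) on
log-shape ratios, contrasting the target against recent population samples
and pre-/post-LGM Upper Palaeolithic groups, with leave-one-out
cross-validated confusion and per-target posterior probabilities.

Sex: raw measurements (size carries dimorphism signal), a random-forest
permutation-importance ranking of the variables on the known-sex reference
rows, forward selection of the subset with the best LOOCV accuracy, and an
LDA on that subset. Posteriors above 0.95 are flagged as a reliability band
in the report, not used as a decision rule.

Priors default to equal across classes: reference group sizes reflect
preservation and collection history, not prevalence.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.tree import DecisionTreeClassifier

from .measurements import measurement_columns


@dataclass
class LDAModel:
    estimator: LinearDiscriminantAnalysis
    classes: list[str]
    variables: list[str]
    loadings: pd.DataFrame  # variables x discriminant functions

    @property
    def n_functions(self) -> int:
        return self.loadings.shape[1]


@dataclass
class ClassificationReport:
    classes: list[str]
    loadings: pd.DataFrame
    cv_confusion: pd.DataFrame           # row-stochastic probabilities
    cv_counts: pd.DataFrame              # absolute numbers
    cv_accuracy: float
    target_posteriors: pd.DataFrame      # targets x classes
    selected_variables: list[str] = field(default_factory=list)
    threshold_bands: dict[float, pd.DataFrame] = field(default_factory=dict)
    pca_scores: pd.DataFrame | None = None
    pca_explained: np.ndarray | None = None
    seed: int | None = None


def _as_matrix(table: pd.DataFrame, variables: list[str] | None = None
               ) -> tuple[np.ndarray, list[str]]:
    cols = variables if variables is not None else measurement_columns(table)
    X = table[cols].to_numpy(dtype=float)
    if np.isnan(X).any():
        raise ValueError("table has missing cells; impute before classification")
    return X, cols


def lda_fit(table: pd.DataFrame, labels: pd.Series, *,
            priors: str = "equal",
            variables: list[str] | None = None) -> LDAModel:
    """Fit an LDA with ``min(classes - 1, variables)`` discriminant functions.

    ``priors`` is ``"equal"`` or ``"proportional"``. With fewer rows than
    variables + classes the pooled covariance is rank-deficient; a warning is
    issued and the SVD solver's pseudo-inverse behaviour acts as the ridge
    fallback.
    """
    X, cols = _as_matrix(table, variables)
    y = np.asarray(labels)
    classes = sorted(set(y.tolist()))
    if len(classes) < 2:
        raise ValueError("LDA needs at least 2 classes")
    for c in classes:
        if (y == c).sum() < 2:
            raise ValueError(f"class {c!r} has fewer than 2 rows")
    if len(X) < X.shape[1] + len(classes):
        warnings.warn("fewer rows than variables + classes; pooled covariance "
                      "is regularized", stacklevel=2)
    prior_vec = (np.full(len(classes), 1.0 / len(classes))
                 if priors == "equal" else None)
    est = LinearDiscriminantAnalysis(solver="svd", priors=prior_vec)
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", message="Variables are collinear")
        est.fit(X, y)
    n_fun = min(len(classes) - 1, X.shape[1])
    loadings = pd.DataFrame(
        est.scalings_[:, :n_fun], index=cols,
        columns=[f"LD{i + 1}" for i in range(n_fun)],
    )
    return LDAModel(estimator=est, classes=[str(c) for c in est.classes_],
                    variables=cols, loadings=loadings)


def lda_posterior(model: LDAModel, rows: pd.DataFrame | np.ndarray
                  ) -> pd.DataFrame:
    """Posterior class probabilities for complete rows; each row sums to 1."""
    if isinstance(rows, pd.DataFrame):
        X = rows[model.variables].to_numpy(dtype=float)
        index = rows.index
    else:
        X = np.atleast_2d(np.asarray(rows, dtype=float))
        index = pd.RangeIndex(len(X))
    if np.isnan(X).any():
        raise ValueError("missing cells in posterior query; impute upstream")
    post = model.estimator.predict_proba(X)
    return pd.DataFrame(post, index=index, columns=model.classes)


def loocv_confusion(table: pd.DataFrame, labels: pd.Series, *,
                    priors: str = "equal",
                    variables: list[str] | None = None,
                    thresholds: tuple[float, ...] = (0.5, 0.95),
                    ) -> tuple[pd.DataFrame, pd.DataFrame, float,
                               dict[float, pd.DataFrame]]:
    """Leave-one-out confusion for LDA.

    Returns (row-stochastic probability table, absolute-count table, overall
    accuracy, per-threshold banded tables). In a banded table a row is only
    assigned to a class when its posterior reaches the threshold; otherwise
    it counts as ``indeterminate``.
    """
    X, cols = _as_matrix(table, variables)
    y = np.asarray([str(v) for v in labels])
    classes = sorted(set(y.tolist()))
    n = len(X)
    post = np.zeros((n, len(classes)))
    sub = table.copy()
    for i in range(n):
        mask = np.ones(n, dtype=bool)
        mask[i] = False
        model_i = lda_fit(sub.iloc[mask], pd.Series(y[mask]),
                          priors=priors, variables=cols)
        p = lda_posterior(model_i, X[i][None, :]).iloc[0]
        post[i] = [p.get(c, 0.0) for c in classes]
    pred_idx = post.argmax(axis=1)
    counts = pd.DataFrame(0, index=classes, columns=classes, dtype=int)
    for yi, pi in zip(y, pred_idx):
        counts.loc[yi, classes[pi]] += 1
    row_sums = counts.sum(axis=1).replace(0, 1)
    probs = counts.div(row_sums, axis=0)
    accuracy = float((np.array(classes)[pred_idx] == y).mean())
    bands: dict[float, pd.DataFrame] = {}
    for thr in thresholds:
        banded = pd.DataFrame(0, index=classes,
                              columns=classes + ["indeterminate"], dtype=int)
        for i, yi in enumerate(y):
            if post[i, pred_idx[i]] >= thr:
                banded.loc[yi, classes[pred_idx[i]]] += 1
            else:
                banded.loc[yi, "indeterminate"] += 1
        bands[thr] = banded
    return probs, counts, accuracy, bands


def rf_rank_variables(table: pd.DataFrame, labels: pd.Series, *,
                      n_trees: int = 1000, seed: int = 0,
                      variables: list[str] | None = None,
                      ) -> list[tuple[str, float]]:
    """Rank variables by random-forest permutation importance.

    A bagged forest of decision trees (feature subsampling sqrt(p)) is grown
    on bootstrap samples; importance of a variable is the mean decrease in
    out-of-bag accuracy when that variable's values are permuted among the
    out-of-bag rows. Deterministic for a given seed; descending order, ties
    broken by column order.
    """
    if n_trees < 50:
        warnings.warn("fewer than 50 trees gives unstable importances",
                      stacklevel=2)
    X, cols = _as_matrix(table, variables)
    y = np.asarray([str(v) for v in labels])
    n, p = X.shape
    rng = np.random.default_rng(seed)
    drops = np.zeros(p)
    weights = np.zeros(p)
    for _ in range(n_trees):
        boot = rng.integers(0, n, size=n)
        oob = np.setdiff1d(np.arange(n), boot)
        if len(oob) == 0:
            continue
        tree = DecisionTreeClassifier(
            max_features="sqrt",
            random_state=int(rng.integers(0, 2 ** 31 - 1)),
        ).fit(X[boot], y[boot])
        base_acc = (tree.predict(X[oob]) == y[oob]).mean()
        for j in range(p):
            Xp = X[oob].copy()
            Xp[:, j] = rng.permutation(Xp[:, j])
            perm_acc = (tree.predict(Xp) == y[oob]).mean()
            drops[j] += base_acc - perm_acc
            weights[j] += 1
    importance = drops / np.maximum(weights, 1)
    order = sorted(range(p), key=lambda j: (-importance[j], j))
    return [(cols[j], float(importance[j])) for j in order]


def _fast_loocv_accuracy(X: np.ndarray, y: np.ndarray,
                         priors: str = "equal") -> float:
    """Plain-numpy leave-one-out LDA accuracy (pooled covariance, Gaussian
    discriminant). Matches the full LDA classifier's decisions; used inside
    selection loops where fitting a full estimator per fold is wasteful."""
    classes = sorted(set(y.tolist()))
    n = len(X)
    correct = 0
    for i in range(n):
        mask = np.ones(n, dtype=bool)
        mask[i] = False
        Xt, yt = X[mask], y[mask]
        means = {}
        pooled = np.zeros((X.shape[1], X.shape[1]))
        counts = {}
        for c in classes:
            Xc = Xt[yt == c]
            counts[c] = len(Xc)
            if len(Xc) < 2:
                return np.nan
            means[c] = Xc.mean(axis=0)
            pooled += (Xc - means[c]).T @ (Xc - means[c])
        pooled /= (len(Xt) - len(classes))
        prec = np.linalg.pinv(pooled)
        best_c, best_score = None, -np.inf
        total = sum(counts.values())
        for c in classes:
            d = X[i] - means[c]
            score = -0.5 * d @ prec @ d
            if priors == "proportional":
                score += np.log(counts[c] / total)
            if score > best_score:
                best_score, best_c = score, c
        correct += best_c == y[i]
    return correct / n


def select_variable_subset(table: pd.DataFrame, labels: pd.Series,
                           ranking: list[tuple[str, float]], *,
                           max_k: int | None = None,
                           priors: str = "equal") -> list[str]:
    """Forward-select the prefix of the ranking with the best LOOCV accuracy.

    Ties go to the smaller subset, guarding against overfitting the model
    with variables that add no cross-validated signal.
    """
    ranked = [code for code, _ in ranking]
    p = len(ranked)
    if max_k is None:
        max_k = p
    if max_k > p:
        warnings.warn(f"max_k={max_k} clipped to {p} variables", stacklevel=2)
        max_k = p
    X_all = table[ranked].to_numpy(dtype=float)
    col_pos = {c: j for j, c in enumerate(ranked)}
    y = np.asarray([str(v) for v in labels])
    best_acc, best_subset = -1.0, ranked[:1]
    for k in range(1, max_k + 1):
        subset = ranked[:k]
        acc = _fast_loocv_accuracy(
            X_all[:, [col_pos[c] for c in subset]], y, priors=priors)
        if np.isnan(acc):
            continue
        if acc > best_acc + 1e-12:
            best_acc, best_subset = acc, subset
    return best_subset


def affinity_analysis(table: pd.DataFrame, labels: pd.Series,
                      target_rows: pd.DataFrame, *,
                      priors: str = "equal") -> ClassificationReport:
    """Population-affinity LDA on a size-adjusted, completed table.

    Fits the discriminant on the labelled reference rows, reports loadings,
    LOOCV confusion (probabilities with absolute counts), and posterior
    probabilities for the target rows.
    """
    model = lda_fit(table, labels, priors=priors)
    probs, counts, acc, bands = loocv_confusion(table, labels, priors=priors)
    posts = lda_posterior(model, target_rows)
    return ClassificationReport(
        classes=model.classes, loadings=model.loadings,
        cv_confusion=probs, cv_counts=counts, cv_accuracy=acc,
        target_posteriors=posts, threshold_bands=bands,
    )


def nested_loocv_accuracy(table: pd.DataFrame, labels: pd.Series,
                          ranking: list[tuple[str, float]], *,
                          max_k: int | None = None,
                          priors: str = "equal") -> float:
    """Outer LOOCV accuracy with the subset size re-selected in every fold.

    The non-nested estimate (select the subset on all rows, then LOOCV the
    selected subset) is optimistic because it reports a maximum over subset
    sizes; re-running the forward selection inside each outer fold removes
    that bias, at the cost of an inner cross-validation per fold.
    """
    y = np.asarray([str(v) for v in labels])
    ranked = [code for code, _ in ranking]
    if max_k is None:
        max_k = len(ranked)
    max_k = min(max_k, len(ranked))
    X_all = table[ranked].to_numpy(dtype=float)
    n = len(table)
    classes = sorted(set(y.tolist()))
    correct = 0
    for i in range(n):
        mask = np.ones(n, dtype=bool)
        mask[i] = False
        # inner selection of the subset size on the training rows only
        best_acc, best_k = -1.0, 1
        for k in range(1, max_k + 1):
            acc = _fast_loocv_accuracy(X_all[mask][:, :k], y[mask],
                                       priors=priors)
            if not np.isnan(acc) and acc > best_acc + 1e-12:
                best_acc, best_k = acc, k
        Xt, yt = X_all[mask][:, :best_k], y[mask]
        pooled = np.zeros((best_k, best_k))
        means = {}
        counts = {}
        for c in classes:
            Xc = Xt[yt == c]
            means[c], counts[c] = Xc.mean(axis=0), len(Xc)
            pooled += (Xc - means[c]).T @ (Xc - means[c])
        pooled /= (len(Xt) - len(classes))
        prec = np.linalg.pinv(pooled)
        scores = {}
        for c in classes:
            d = X_all[i, :best_k] - means[c]
            scores[c] = -0.5 * d @ prec @ d
            if priors == "proportional":
                scores[c] += np.log(counts[c] / len(Xt))
        correct += max(scores, key=scores.get) == y[i]
    return correct / n


def sex_analysis(table: pd.DataFrame, labels: pd.Series,
                 target_rows: pd.DataFrame, *, seed: int = 0,
                 n_trees: int = 1000, max_k: int | None = None,
                 priors: str = "equal",
                 nested: bool = False) -> ClassificationReport:
    """Sex classification from raw measurements.

    Random-forest permutation importance ranks the variables on the known-sex
    rows; the ranking prefix with the best LOOCV LDA accuracy is selected;
    the final LDA reports loadings, banded LOOCV confusion (0.5 and 0.95
    posterior thresholds) and target posteriors. A PCA of the selected
    variables, with the targets projected, summarises the separation.

    With ``nested=True`` the reported accuracy re-selects the subset size
    inside each leave-one-out fold (unbiased, slower); the default reports
    the LOOCV accuracy of the selected subset, which is optimistic under
    weak signal because the subset was chosen to maximize it.
    """
    ranking = rf_rank_variables(table, labels, n_trees=n_trees, seed=seed)
    selected = select_variable_subset(table, labels, ranking,
                                      max_k=max_k, priors=priors)
    model = lda_fit(table, labels, priors=priors, variables=selected)
    probs, counts, acc, bands = loocv_confusion(table, labels, priors=priors,
                                                variables=selected)
    if nested:
        acc = nested_loocv_accuracy(table, labels, ranking, max_k=max_k,
                                    priors=priors)
    posts = lda_posterior(model, target_rows)

    X = table[selected].to_numpy(dtype=float)
    mu, sd = X.mean(axis=0), X.std(axis=0, ddof=0)
    sd[sd == 0] = 1.0
    Z = (X - mu) / sd
    U, s, Vt = np.linalg.svd(Z, full_matrices=False)
    explained = s ** 2 / (s ** 2).sum()
    scores = pd.DataFrame(Z @ Vt.T, index=table.index,
                          columns=[f"PC{i + 1}" for i in range(Vt.shape[0])])
    Zt = (target_rows[selected].to_numpy(dtype=float) - mu) / sd
    t_scores = pd.DataFrame(Zt @ Vt.T, index=target_rows.index,
                            columns=scores.columns)
    return ClassificationReport(
        classes=model.classes, loadings=model.loadings,
        cv_confusion=probs, cv_counts=counts, cv_accuracy=acc,
        target_posteriors=posts, selected_variables=selected,
        threshold_bands=bands,
        pca_scores=pd.concat([scores, t_scores]),
        pca_explained=explained, seed=seed,
    )
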