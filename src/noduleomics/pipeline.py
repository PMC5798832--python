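"""Signature building: quantile normalization, Wilcoxon screening,
sequential forward selection with SVM/LOOCV, evaluation and baselines.

The statistical back half mirrors a classical radiomics signature
study: feature vectors are quantile-normalized across cases (each
case's value distribution becomes identical, removing batch effects
while preserving within-case ranks), screened per feature with a
two-sided Wilcoxon rank-sum test at alpha = 0.05 without multiplicity
correction, and a k-feature signature is grown greedily: at each step
the candidate that maximizes leave-one-out cross-validated SVM
accuracy joins the signature. Two reference baselines put the
signature accuracy in context: LOOCV on *all* screened features, and
the mean LOOCV accuracy of random k-subsets of the screened set.

The SVM is a linear-kernel classifier with C = 1 and per-fold feature
standardization (fit on training cases only — the held-out case never
influences its own fold's parameters). Quantile normalization is
applied to the full table before screening and selection, which leaks
marginal distribution information across folds; a strict per-fold
variant is available via ``normalize_per_fold`` in
:func:`loocv_predictions` for sensitivity analyses.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.svm import SVC

from .volumes import ParameterError

POSITIVE_CLASS = "malignant"


@dataclass
class FeatureTable:
    """Cases x features matrix with class labels.

    ``X`` is a float DataFrame indexed by case_id; ``y`` maps case_id
    to ``benign``/``malignant``.
    """

    X: pd.DataFrame
    y: pd.Series

    def __post_init__(self):
        if self.X.isna().any().any():
            raise ParameterError("feature table contains missing values")
        if self.X.columns.duplicated().any():
            raise ParameterError("feature names must be unique")
        if not self.X.index.equals(self.y.index):
            self.y = self.y.loc[self.X.index]

    @property
    def n_cases(self) -> int:
        return len(self.X)

    @property
    def classes(self) -> list[str]:
        return sorted(self.y.unique())

    @classmethod
    def from_csv(cls, path) -> "FeatureTable":
        df = pd.read_csv(path).set_index("case_id")
        return cls(df.drop(columns=["label"]).astype(float), df["label"])

    def to_csv(self, path) -> None:
        out = self.X.copy()
        out.insert(0, "label", self.y)
        out.to_csv(path, index_label="case_id")


@dataclass(frozen=True)
class SvmConfig:
    kernel: str = "linear"
    C: float = 1.0

    def make(self) -> SVC:
        return SVC(kernel=self.kernel, C=self.C)


@dataclass(frozen=True)
class SignatureModel:
    """Ordered selected feature names + classifier configuration."""

    features: tuple[str, ...]
    svm: SvmConfig
    step_accuracies: tuple[float, ...] = ()


@dataclass(frozen=True)
class EvaluationReport:
    """LOOCV confusion counts and derived metrics (fractions in [0, 1])."""

    tp: int
    fn: int
    tn: int
    fp: int
    predictions: pd.Series | None = None

    @property
    def n_cases(self) -> int:
        return self.tp + self.fn + self.tn + self.fp

    @property
    def accuracy(self) -> float:
        return (self.tp + self.tn) / self.n_cases

    @property
    def sensitivity(self) -> float:
        return self.tp / (self.tp + self.fn)

    @property
    def specificity(self) -> float:
        return self.tn / (self.tn + self.fp)

    @classmethod
    def from_predictions(cls, y_true: pd.Series, y_pred: pd.Series,
                         positive: str = POSITIVE_CLASS) -> "EvaluationReport":
        pos = y_true == positive
        hit = y_true == y_pred
        return cls(
            tp=int((pos & hit).sum()), fn=int((pos & ~hit).sum()),
            tn=int((~pos & hit).sum()), fp=int((~pos & ~hit).sum()),
            predictions=y_pred,
        )


def quantile_normalize(t: FeatureTable) -> FeatureTable:
    """Make every case's feature-value distribution identical.

    The value at within-case rank r is replaced by the mean, across
    cases, of their rank-r values; ties receive the average of the
    tied ranks' reference values.
    """
    if t.n_cases < 2:
        raise ParameterError("quantile normalization needs >= 2 cases")
    V = t.X.to_numpy(dtype=np.float64)
    n_feat = V.shape[1]
    reference = np.sort(V, axis=1).mean(axis=0)
    out = np.empty_like(V)
    grid = np.arange(1, n_feat + 1, dtype=np.float64)
    for i in range(V.shape[0]):
        ranks = sps.rankdata(V[i], method="average")
        out[i] = np.interp(ranks, grid, reference)
    return FeatureTable(pd.DataFrame(out, index=t.X.index, columns=t.X.columns), t.y)


def _ranksum_p(a: np.ndarray, b: np.ndarray) -> float:
    """Two-sided rank-sum p: exact for small tie-free groups, else the
    tie-corrected normal approximation."""
    if np.all(a == a[0]) and np.all(b == a[0]):
        return 1.0
    pooled = np.concatenate([a, b])
    has_ties = np.unique(pooled).size < pooled.size
    method = "exact" if (len(a) <= 10 and len(b) <= 10 and not has_ties) else "asymptotic"
    return float(sps.mannwhitneyu(a, b, alternative="two-sided", method=method).pvalue)


def wilcoxon_screen(t: FeatureTable, alpha: float = 0.05) -> pd.Series:
    """Per-feature two-sided Wilcoxon rank-sum screen.

    Returns the p-values of the features with p < alpha, ordered by
    ascending p (ties keep table column order). The ordering matters
    downstream: SFS breaks accuracy ties by screen rank, so equal-CV
    candidates resolve toward the stronger marginal association. No
    multiple-testing correction is applied.
    """
    classes = t.classes
    if len(classes) != 2:
        raise ParameterError(f"screening needs exactly two classes, got {classes}")
    g0 = t.y == classes[0]
    if g0.sum() < 2 or (~g0).sum() < 2:
        raise ParameterError("each class needs >= 2 cases")
    A = t.X.loc[g0].to_numpy(dtype=np.float64)
    B = t.X.loc[~g0].to_numpy(dtype=np.float64)
    pvals = np.array([_ranksum_p(A[:, j], B[:, j]) for j in range(A.shape[1])])
    sel = pvals < alpha
    out = pd.Series(pvals[sel], index=t.X.columns[sel], name="p")
    return out.sort_values(kind="stable")


def _standardize(train: np.ndarray):
    mu = train.mean(axis=0)
    sd = train.std(axis=0)
    sd = np.where(sd == 0, 1.0, sd)
    return mu, sd


def loocv_predictions(
    t: FeatureTable,
    features,
    svm: SvmConfig = SvmConfig(),
    return_fold_params: bool = False,
    normalize_per_fold: bool = False,
):
    """Leave-one-out predictions; training folds never see the held-out case.

    With ``normalize_per_fold`` the quantile-normalization reference is
    re-fit per training fold and the held-out case mapped through it
    (the strict no-leakage variant).
    """
    features = list(features)
    if not features:
        raise ParameterError("need at least one feature")
    if len(set(t.y)) < 2:
        raise ParameterError("both classes must be present")
    Xall = t.X[features].to_numpy(dtype=np.float64)
    y = t.y.to_numpy()
    n = len(y)
    preds = []
    fold_params = []
    for i in range(n):
        idx = np.arange(n) != i
        Xtr, ytr = Xall[idx], y[idx]
        xte = Xall[~idx]
        if normalize_per_fold:
            full = t.X.to_numpy(dtype=np.float64)
            ref = np.sort(full[idx], axis=1).mean(axis=0)
            grid = np.arange(1, full.shape[1] + 1, dtype=np.float64)
            cols = [t.X.columns.get_loc(f) for f in features]
            qn = np.empty_like(full)
            for r in np.flatnonzero(idx):
                qn[r] = np.interp(sps.rankdata(full[r], method="average"), grid, ref)
            qn[i] = np.interp(sps.rankdata(full[i], method="average"), grid, ref)
            Xtr = qn[idx][:, cols]
            xte = qn[i:i + 1, cols]
        if len(np.unique(ytr)) < 2:
            raise ParameterError("degenerate training fold: a single class remains")
        mu, sd = _standardize(Xtr)
        clf = svm.make()
        clf.fit((Xtr - mu) / sd, ytr)
        preds.append(clf.predict((xte - mu) / sd)[0])
        if return_fold_params:
            fold_params.append((mu.copy(), sd.copy()))
    pred = pd.Series(preds, index=t.X.index, name="prediction")
    if return_fold_params:
        return pred, fold_params
    return pred


def loocv_evaluate(t: FeatureTable, features, svm: SvmConfig = SvmConfig(),
                   positive: str = POSITIVE_CLASS) -> EvaluationReport:
    """LOOCV confusion counts and accuracy/sensitivity/specificity."""
    pred = loocv_predictions(t, features, svm)
    return EvaluationReport.from_predictions(t.y, pred, positive)


def _loocv_accuracy(t: FeatureTable, features, svm: SvmConfig) -> float:
    pred = loocv_predictions(t, features, svm)
    return float((pred == t.y).mean())


def sfs_select(t: FeatureTable, candidates, k: int = 4,
               svm: SvmConfig = SvmConfig()) -> SignatureModel:
    """Greedy sequential forward selection of a k-feature signature.

    At each step the candidate maximizing the LOOCV accuracy of the
    SVM on (current set + candidate) is added. Accuracy ties are
    broken by the smaller index in the candidate ordering, which makes
    the procedure fully deterministic.
    """
    candidates = list(candidates)
    if not candidates:
        raise ParameterError("candidate set is empty")
    if k < 1:
        raise ParameterError("k must be >= 1")
    if k > len(candidates):
        raise ParameterError(f"k={k} exceeds {len(candidates)} candidates")
    selected: list[str] = []
    step_acc: list[float] = []
    remaining = list(candidates)
    for _ in range(k):
        best_feat = None
        best_acc = -1.0
        for f in remaining:  # ties resolved by candidate order
            acc = _loocv_accuracy(t, selected + [f], svm)
            if acc > best_acc:
                best_acc = acc
                best_feat = f
        selected.append(best_feat)
        step_acc.append(best_acc)
        remaining.remove(best_feat)
    return SignatureModel(tuple(selected), svm, tuple(step_acc))


@dataclass(frozen=True)
class RandomSignatureBaseline:
    mean_accuracy: float
    accuracies: np.ndarray
    size: int
    n_perm: int
    seed: int


def random_signature_baseline(t: FeatureTable, candidates, size: int = 4,
                              n_perm: int = 1000, seed: int = 0,
                              svm: SvmConfig = SvmConfig()) -> RandomSignatureBaseline:
    """LOOCV accuracy distribution of random ``size``-subsets of the
    screened candidates (permutation reference for the signature)."""
    candidates = list(candidates)
    if len(candidates) < size:
        raise ParameterError("fewer candidates than the requested subset size")
    rng = np.random.default_rng(seed)
    accs = np.empty(n_perm)
    for p in range(n_perm):
        subset = rng.choice(candidates, size=size, replace=False)
        accs[p] = _loocv_accuracy(t, list(subset), svm)
    return RandomSignatureBaseline(float(accs.mean()), accs, size, n_perm, seed)


def all_features_baseline(t: FeatureTable, candidates,
                          svm: SvmConfig = SvmConfig()) -> EvaluationReport:
    """LOOCV evaluation using every screened feature as the predictor."""
    return loocv_evaluate(t, list(candidates), svm)


def heatmap_export(t: FeatureTable, features, z_csv=None, order_file=None):
    """Per-feature z-scores plus a hierarchical-clustering case order.

    Returns ``(zmatrix, order)`` where ``zmatrix`` is features x cases
    and ``order`` the leaf order of average-linkage Euclidean
    clustering of the cases' z-scored signature vectors. Zero-variance
    features get z-score 0.
    """
    from scipy.cluster.hierarchy import leaves_list, linkage

    features = list(features)
    if not features:
        raise ParameterError("need at least one feature")
    sub = t.X[features]
    mu = sub.mean(axis=0)
    sd = sub.std(axis=0, ddof=0)
    z = (sub - mu).div(sd.where(sd > 0, 1.0), axis=1)
    z.loc[:, sd == 0] = 0.0
    if len(z) > 1:
        order = [t.X.index[i] for i in leaves_list(linkage(z.to_numpy(), method="average", metric="euclidean"))]
    else:
        order = list(t.X.index)
    zmat = z.T[order]
    if z_csv is not None:
        zmat.to_csv(z_csv, index_label="feature")
    if order_file is not None:
        pd.Series(order, name="case_id").to_csv(order_file, index=False)
    return zmat, order
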