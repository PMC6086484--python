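"""Cluster validation by supervised classification, and conversion-rate
statistics for the ex vivo / in vivo reprogramming experiments.

The classifier protocol checks that cell clusters are real, separable
transcriptional states: a stratified 80/20 split per cluster, min-max
scaling and a 30-component PCA (no whitening) fitted on the training
cells only, an RBF-kernel SVM tuned by 3-fold cross-validated grid
search, and held-out accuracy read off the confusion matrix.  Conversion
rates are the fraction of reporter-positive cells double-positive for a
hair-cell marker (dislodged endogenous cells excluded from numerator and
denominator) and are compared across conditions on per-sample
proportions with Student's t or a two-way ANOVA for factorial designs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.decomposition import PCA
from sklearn.metrics import confusion_matrix
from sklearn.model_selection import GridSearchCV, StratifiedShuffleSplit
from sklearn.preprocessing import MinMaxScaler
from sklearn.svm import SVC

__all__ = [
    "ClassifierConfig",
    "ClassifierReport",
    "train_validate_classifier",
    "conversion_rate",
    "compare_rates",
]


@dataclass(frozen=True)
class ClassifierConfig:
    """Protocol parameters of the cluster-validation classifier."""

    test_fraction: float = 0.2
    n_pcs: int = 30
    whiten: bool = False
    cv_folds: int = 3
    c_grid: tuple[float, ...] = (0.1, 1.0, 10.0, 100.0)
    gamma_grid: tuple[float, ...] = (1e-3, 1e-2, 1e-1, 1.0, 10.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.test_fraction < 1.0:
            raise ValueError("test_fraction must be in (0, 1)")
        if self.n_pcs < 1:
            raise ValueError("n_pcs must be >= 1")
        if not self.c_grid or not self.gamma_grid:
            raise ValueError("parameter grids must be non-empty")


@dataclass
class ClassifierReport:
    accuracy: float
    confusion: pd.DataFrame
    best_params: dict
    n_train: int
    n_test: int
    config: ClassifierConfig = field(repr=False, default=ClassifierConfig())
    # fitted transforms, exposed so leakage (test cells influencing the
    # fit) is checkable from the outside
    scaler: MinMaxScaler | None = field(repr=False, default=None)
    pca: PCA | None = field(repr=False, default=None)
    train_index: np.ndarray | None = field(repr=False, default=None)
    test_index: np.ndarray | None = field(repr=False, default=None)


def train_validate_classifier(matrix: np.ndarray,
                              labels: np.ndarray | pd.Series,
                              config: ClassifierConfig = ClassifierConfig()
                              ) -> ClassifierReport:
    """Run the stratified split / scale / PCA / grid-searched SVM protocol.

    ``matrix`` is cells x features (typically log2(expected count + 1)
    over selected genes).  All data-dependent transforms (min-max
    scaling, PCA) are fitted on the training split only, so held-out
    cells never leak into the fitted model.  With a single cluster the
    classifier is trivially perfect and accuracy 1.0 is returned.
    """
    X = np.asarray(matrix, dtype=float)
    y = np.asarray(labels)
    classes, counts = np.unique(y, return_counts=True)
    if counts.min() < 5:
        raise ValueError("every cluster needs >= 5 cells for a stratified "
                         "20% test split")

    if len(classes) == 1:
        conf = pd.DataFrame([[len(y)]], index=classes, columns=classes)
        return ClassifierReport(accuracy=1.0, confusion=conf, best_params={},
                                n_train=0, n_test=len(y), config=config)

    splitter = StratifiedShuffleSplit(n_splits=1,
                                      test_size=config.test_fraction,
                                      random_state=int(config.seed))
    (train_idx, test_idx), = splitter.split(X, y)
    train_counts = pd.Series(y[train_idx]).value_counts()
    if (train_counts < config.cv_folds).any():
        raise ValueError("a cluster has fewer training cells than CV folds")

    scaler = MinMaxScaler().fit(X[train_idx])
    Xtr = scaler.transform(X[train_idx])
    Xte = scaler.transform(X[test_idx])
    n_pcs = min(config.n_pcs, Xtr.shape[1], len(train_idx))
    pca = PCA(n_components=n_pcs, whiten=config.whiten,
              svd_solver="full", random_state=0).fit(Xtr)
    Ztr, Zte = pca.transform(Xtr), pca.transform(Xte)

    grid = GridSearchCV(
        SVC(kernel="rbf"),
        {"C": list(config.c_grid), "gamma": list(config.gamma_grid)},
        cv=config.cv_folds, n_jobs=1)
    grid.fit(Ztr, y[train_idx])
    pred = grid.predict(Zte)
    conf = confusion_matrix(y[test_idx], pred, labels=classes)
    conf = pd.DataFrame(conf, index=classes, columns=classes)
    acc = float(np.trace(conf.to_numpy()) / conf.to_numpy().sum())
    return ClassifierReport(accuracy=acc, confusion=conf,
                            best_params=dict(grid.best_params_),
                            n_train=len(train_idx), n_test=len(test_idx),
                            config=config, scaler=scaler, pca=pca,
                            train_index=train_idx, test_index=test_idx)


# ---------------------------------------------------------------------------
# Conversion rates
# ---------------------------------------------------------------------------

def conversion_rate(table: pd.DataFrame) -> pd.DataFrame:
    """Per-sample and pooled conversion rates from a count table.

    ``table`` needs columns sample, condition, reporter_pos, double_pos
    and optionally excluded (dislodged endogenous cells, removed from
    both numerator and denominator).  The rate is
    (double_pos - excluded) / (reporter_pos - excluded).
    """
    t = table.copy()
    if "excluded" not in t.columns:
        t["excluded"] = 0
    for col in ("reporter_pos", "double_pos", "excluded"):
        if (t[col] < 0).any():
            raise ValueError(f"negative counts in column {col!r}")
    if (t["double_pos"] > t["reporter_pos"]).any():
        raise ValueError("double_pos exceeds reporter_pos")
    denom = t["reporter_pos"] - t["excluded"]
    if (denom <= 0).any():
        bad = list(t.loc[denom <= 0, "sample"])
        raise ValueError(f"no countable reporter-positive cells in {bad}")
    t["rate"] = (t["double_pos"] - t["excluded"]) / denom
    return t[["sample", "condition", "rate", "reporter_pos", "double_pos",
              "excluded"]]


def compare_rates(table: pd.DataFrame, design: str = "t",
                  factors: tuple[str, str] | None = None) -> dict:
    """Compare per-sample conversion rates across conditions.

    ``design='t'`` runs two-sided Student's t tests for every condition
    pair.  ``design='anova2'`` expects conditions named like
    'A+B' / 'A' / 'B' / 'ctrl' for two factors (or explicit ``factors``
    column names already present in the table) and fits a two-way ANOVA
    with interaction on per-sample rates.  Returns a dict with the
    per-condition summary (mean, SEM, n) and the test table.
    """
    rates = conversion_rate(table) if "rate" not in table.columns else table
    summary = (rates.groupby("condition")["rate"]
               .agg(mean="mean", sem=lambda s: s.std(ddof=1) / np.sqrt(len(s)),
                    n="size"))
    out = {"summary": summary}

    if design == "t":
        rows = []
        conds = list(summary.index)
        for i in range(len(conds)):
            for j in range(i + 1, len(conds)):
                a = rates.loc[rates["condition"] == conds[i], "rate"]
                b = rates.loc[rates["condition"] == conds[j], "rate"]
                res = stats.ttest_ind(a, b)
                rows.append({"condition_a": conds[i], "condition_b": conds[j],
                             "t": float(res.statistic), "p": float(res.pvalue)})
        out["tests"] = pd.DataFrame(rows)
        return out

    if design == "anova2":
        df = rates.copy()
        if factors is not None:
            fa, fb = factors
        else:
            fa, fb = "factor_a", "factor_b"
            names = sorted({p for c in df["condition"].unique()
                            for p in c.split("+") if p.lower() != "ctrl"})
            if len(names) != 2:
                raise ValueError("cannot infer two factors from condition names")
            df[fa] = df["condition"].str.split("+").apply(lambda p: names[0] in p).astype(int)
            df[fb] = df["condition"].str.split("+").apply(lambda p: names[1] in p).astype(int)
        import statsmodels.formula.api as smf
        from statsmodels.stats.anova import anova_lm
        model = smf.ols(f"rate ~ C({fa}) * C({fb})", data=df).fit()
        out["tests"] = anova_lm(model, typ=2)
        return out

    raise ValueError("design must be 't' or 'anova2'")
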