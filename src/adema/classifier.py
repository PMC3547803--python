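"""Classification from class-specific bin-combination signatures.

:class:`ADEMAClassifier` is a scikit-learn style estimator. Fitting bins the
training cohort, builds metabolite subsets from a metabolic network (or takes
them precomputed), and derives per-subset combination statistics together
with the class-specific expected levels. A held-out sample is binned with the
training ranges (clamped) and scored per class by how much probability it
places on the combinations indicative of that class, weighted by marginal
information within each subset and by each subset's share of the total mutual
information across subsets:

    score_C(x) = sum_Sub w_Sub * sum_{o in O_C^Sub} u_o * p_x(o)

with ``w_Sub = I_Sub / sum I`` (uniform when all subsets are uninformative)
and ``u_o = mi_o / sum_{o' in O_C^Sub} mi_o'`` under the default
``score_weights="normalized"`` (``u_o = mi_o`` under ``"raw-mi"``). The
sample is predicted variable when its variable score strictly exceeds its
control score; ties go to control.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import fisher_exact
from sklearn.base import BaseEstimator, ClassifierMixin, clone
from sklearn.utils.validation import check_array, check_is_fitted, check_X_y

from .binning import bin_cohort
from .information import (
    CONTROL,
    VARIABLE,
    SubsetModel,
    _combination_probs,
    aggregate_expected_levels,
    enumerate_combinations,
    fit_subset_model,
)
from .subsets import MetaboliteSubset, build_subsets

__all__ = [
    "ADEMAClassifier",
    "EvalReport",
    "loocv",
    "compute_metrics",
    "save_model",
    "load_model",
]

logger = logging.getLogger("adema")


class ADEMAClassifier(ClassifierMixin, BaseEstimator):
    """Mutual-information substate classifier for two-class metabolite cohorts.

    Parameters
    ----------
    M : int, default 6
        Number of bins for soft discretization.
    k : int, default 3
        Spline order; the number of adjacent bins an observation can occupy.
    max_sub : int, default 8
        Maximum metabolites per subset; larger subsets are split. The
        combination space per subset is ``M ** subset_size``.
    strategy : {"efm", "neighborhood", "random", "file"}, default "efm"
        How subsets are chosen. "efm" and "neighborhood" need ``network``;
        "file"/precomputed subsets are passed via ``subsets``.
    network : MetabolicNetwork, optional
        Reaction network whose internal metabolites correspond (by name) to
        the feature columns.
    subsets : list of MetaboliteSubset or list of sequences of str, optional
        Precomputed subsets; overrides ``strategy``.
    metabolite_names : sequence of str, optional
        Feature names when ``X`` is a bare array (DataFrame columns are used
        automatically).
    n_random_subsets : int, optional
        Number of subsets for the random strategy.
    control_class : label, optional
        Which class label is the control group. Default: the smaller label
        (lexicographic for strings), logged.
    score_weights : {"normalized", "raw-mi"}, default "normalized"
    random_state : int, default 0
        Seed for the random subset strategy.

    Attributes
    ----------
    classes_ : ndarray of the two original labels, sorted
    control_class_, variable_class_ : the resolved original labels
    feature_names_ : list of metabolite names in column order
    ranges_ : (n_features, 2) training min/max per metabolite
    subsets_ : the metabolite subsets used (after splitting)
    subset_models_ : list of fitted SubsetModel
    expected_levels_ : ExpectedLevels (per-metabolite class bins and deltas)
    results_ : DataFrame view of expected_levels_
    """

    def __init__(
        self,
        M: int = 6,
        k: int = 3,
        max_sub: int = 8,
        strategy: str = "efm",
        network=None,
        subsets=None,
        metabolite_names=None,
        n_random_subsets: int | None = None,
        control_class=None,
        score_weights: str = "normalized",
        random_state: int = 0,
    ):
        self.M = M
        self.k = k
        self.max_sub = max_sub
        self.strategy = strategy
        self.network = network
        self.subsets = subsets
        self.metabolite_names = metabolite_names
        self.n_random_subsets = n_random_subsets
        self.control_class = control_class
        self.score_weights = score_weights
        self.random_state = random_state

    # ------------------------------------------------------------------ fit
    def fit(self, X, y):
        if not (self.M >= self.k >= 1):
            raise ValueError(f"require M >= k >= 1, got M={self.M}, k={self.k}")
        if self.score_weights not in ("normalized", "raw-mi"):
            raise ValueError(f"unknown score_weights {self.score_weights!r}")
        names = None
        if isinstance(X, pd.DataFrame):
            names = [str(c) for c in X.columns]
        X, y = check_X_y(X, y, dtype=float)
        self.classes_ = np.unique(y)
        if len(self.classes_) != 2:
            raise ValueError(
                f"exactly two classes required, got {list(self.classes_)}"
            )
        if self.control_class is None:
            self.control_class_ = self.classes_[0]
            logger.info("control class defaulted to %r", self.control_class_)
        else:
            if self.control_class not in self.classes_:
                raise ValueError(
                    f"control_class {self.control_class!r} not among {list(self.classes_)}"
                )
            self.control_class_ = self.control_class
        self.variable_class_ = (
            self.classes_[1] if self.control_class_ == self.classes_[0] else self.classes_[0]
        )
        labels = np.where(y == self.control_class_, CONTROL, VARIABLE)

        if names is None:
            if self.metabolite_names is not None:
                names = [str(n) for n in self.metabolite_names]
            else:
                names = [f"m{j + 1}" for j in range(X.shape[1])]
        if len(names) != X.shape[1]:
            raise ValueError("metabolite_names length does not match X")
        self.feature_names_ = names
        index = {m: j for j, m in enumerate(names)}

        self.subsets_ = self._resolve_subsets(names)
        missing = {m for s in self.subsets_ for m in s.members} - set(names)
        if missing:
            raise ValueError(f"subset metabolites not in cohort: {sorted(missing)}")
        if not self.subsets_:
            raise ValueError("no usable metabolite subsets")

        binned = bin_cohort(X, self.M, self.k)
        self.ranges_ = binned.ranges
        self.subset_models_ = [
            fit_subset_model(binned, labels, index, sub) for sub in self.subsets_
        ]
        self.expected_levels_ = aggregate_expected_levels(self.subset_models_, names)
        from .cohort import results_table  # local import to avoid cycle

        self.results_ = results_table(self.expected_levels_)
        return self

    def _resolve_subsets(self, names) -> list[MetaboliteSubset]:
        if self.subsets is not None:
            subs = [
                s if isinstance(s, MetaboliteSubset)
                else MetaboliteSubset(tuple(s), source=f"given:{i}")
                for i, s in enumerate(self.subsets)
            ]
            out = []
            from .subsets import split_subset

            for s in subs:
                out.extend(split_subset(s, self.max_sub))
            return out
        return build_subsets(
            self.strategy,
            measured=names,
            network=self.network,
            max_sub=self.max_sub,
            n_random_subsets=self.n_random_subsets,
            seed=self.random_state,
        )

    # -------------------------------------------------------------- predict
    def _class_scores(self, X) -> np.ndarray:
        """Columns: (control score, variable score) per sample."""
        check_is_fitted(self, "subset_models_")
        if isinstance(X, pd.DataFrame):
            missing = [m for m in self.feature_names_ if m not in X.columns]
            if missing:
                raise ValueError(f"sample is missing metabolite(s): {missing}")
            X = X[self.feature_names_]
        X = check_array(X, dtype=float)
        if X.shape[1] != len(self.feature_names_):
            raise ValueError(
                f"expected {len(self.feature_names_)} metabolites, got {X.shape[1]}"
            )
        binned = bin_cohort(X, self.M, self.k, ranges=self.ranges_)
        index = {m: j for j, m in enumerate(self.feature_names_)}
        total_I = sum(mod.I for mod in self.subset_models_)
        scores = np.zeros((X.shape[0], 2))
        for mod in self.subset_models_:
            w_sub = (
                mod.I / total_I if total_I > 0 else 1.0 / len(self.subset_models_)
            )
            idx = [index[m] for m in mod.subset.members]
            px = _combination_probs(binned.probs[:, idx, :])  # (n, M**d)
            for col, cls in enumerate((CONTROL, VARIABLE)):
                mask = mod.assigned == cls
                mi_c = mod.mi[mask]
                tot = mi_c.sum()
                if tot <= 0:
                    continue
                u = mi_c / tot if self.score_weights == "normalized" else mi_c
                scores[:, col] += w_sub * (px[:, mask] @ u)
        return scores

    def decision_function(self, X) -> np.ndarray:
        """Variable-class score minus control-class score per sample."""
        s = self._class_scores(X)
        return s[:, 1] - s[:, 0]

    def predict(self, X) -> np.ndarray:
        d = self.decision_function(X)
        n_tie = int((d == 0).sum())
        if n_tie:
            logger.info("%d tie(s) resolved to control", n_tie)
        return np.where(d > 0, self.variable_class_, self.control_class_)


# -------------------------------------------------------------- evaluation
@dataclass
class EvalReport:
    """LOOCV / confusion-table metrics with variable as the positive class."""

    tp: int
    fp: int
    fn: int
    tn: int
    accuracy: float
    precision: float
    recall: float
    f_measure: float
    fisher_p: float
    predictions: pd.DataFrame | None = None
    flagged_folds: list[int] = field(default_factory=list)

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


def compute_metrics(tp: int, fp: int, fn: int, tn: int) -> EvalReport:
    """Accuracy, precision, recall, F-measure (harmonic mean) and a two-tailed
    Fisher exact p-value, from confusion counts (variable = positive; 0/0
    rates are defined as 0)."""
    for c in (tp, fp, fn, tn):
        if c < 0:
            raise ValueError("confusion counts must be nonnegative")
    total = tp + fp + fn + tn
    if total == 0:
        raise ValueError("empty confusion table")
    accuracy = (tp + tn) / total
    precision = tp / (tp + fp) if tp + fp else 0.0
    recall = tp / (tp + fn) if tp + fn else 0.0
    f = (
        2 * precision * recall / (precision + recall)
        if precision + recall
        else 0.0
    )
    _, p = fisher_exact([[tp, fn], [fp, tn]], alternative="two-sided")
    return EvalReport(
        tp=tp, fp=fp, fn=fn, tn=tn,
        accuracy=accuracy, precision=precision, recall=recall,
        f_measure=f, fisher_p=float(p),
    )


def loocv(estimator: ADEMAClassifier, X, y) -> EvalReport:
    """Leave-one-out cross-validation.

    Each sample in turn is held out, the classifier is retrained on the rest
    (binning ranges recomputed from the remaining samples), and the held-out
    sample is classified with out-of-range values clamped. A fold whose
    training remainder loses one class entirely is flagged and excluded from
    the confusion counts.
    """
    if isinstance(X, pd.DataFrame):
        names = [str(c) for c in X.columns]
        X = X.to_numpy(dtype=float)
    else:
        names = None
        X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    n = X.shape[0]
    if n < 3:
        raise ValueError("LOOCV requires at least 3 samples")
    records = []
    flagged = []
    for i in range(n):
        rest = np.arange(n) != i
        if len(np.unique(y[rest])) < 2:
            flagged.append(i)
            logger.warning("fold %d excluded: training remainder is single-class", i)
            continue
        est = clone(estimator)
        if names is not None and est.metabolite_names is None:
            est.set_params(metabolite_names=names)
        est.fit(X[rest], y[rest])
        pred = est.predict(X[i : i + 1])[0]
        records.append({"fold": i, "true": y[i], "predicted": pred})
    if not records:
        raise ValueError("no usable LOOCV folds")
    preds = pd.DataFrame(records)
    # positive class = variable
    classes = np.unique(y)
    control = (
        estimator.control_class if estimator.control_class is not None else classes[0]
    )
    pos = classes[1] if control == classes[0] else classes[0]
    tp = int(((preds["true"] == pos) & (preds["predicted"] == pos)).sum())
    fn = int(((preds["true"] == pos) & (preds["predicted"] != pos)).sum())
    fp = int(((preds["true"] != pos) & (preds["predicted"] == pos)).sum())
    tn = int(((preds["true"] != pos) & (preds["predicted"] != pos)).sum())
    report = compute_metrics(tp, fp, fn, tn)
    report.predictions = preds
    report.flagged_folds = flagged
    return report


# ----------------------------------------------------------- serialization
def save_model(clf: ADEMAClassifier, directory: str | Path) -> None:
    """Persist a fitted classifier's prediction-relevant state as JSON.

    Only combinations with positive marginal information are stored (the
    others carry zero score weight), so the file stays small even for large
    combination spaces.
    """
    check_is_fitted(clf, "subset_models_")
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    payload = {
        "params": {
            "M": clf.M, "k": clf.k, "max_sub": clf.max_sub,
            "score_weights": clf.score_weights,
        },
        "control_class": _jsonable(clf.control_class_),
        "variable_class": _jsonable(clf.variable_class_),
        "feature_names": clf.feature_names_,
        "ranges": clf.ranges_.tolist(),
        "subsets": [
            {
                "members": list(mod.subset.members),
                "source": mod.subset.source,
                "I": mod.I,
                "expected_bins": {
                    c: mod.expected_bins[c].tolist() for c in mod.expected_bins
                },
                "degenerate": mod.degenerate,
                "entries": [
                    {
                        "index": int(i),
                        "mi": float(mod.mi[i]),
                        "term_control": float(mod.term_control[i]),
                        "term_variable": float(mod.term_variable[i]),
                        "assigned": str(mod.assigned[i]),
                    }
                    for i in np.flatnonzero(mod.mi > 0)
                ],
            }
            for mod in clf.subset_models_
        ],
    }
    (directory / "model.json").write_text(json.dumps(payload, indent=1))


def _jsonable(v):
    return v.item() if isinstance(v, np.generic) else v


def load_model(directory: str | Path) -> ADEMAClassifier:
    """Rebuild a fitted classifier saved by :func:`save_model`."""
    payload = json.loads((Path(directory) / "model.json").read_text())
    p = payload["params"]
    clf = ADEMAClassifier(
        M=p["M"], k=p["k"], max_sub=p["max_sub"], score_weights=p["score_weights"]
    )
    clf.control_class_ = payload["control_class"]
    clf.variable_class_ = payload["variable_class"]
    clf.classes_ = np.unique([clf.control_class_, clf.variable_class_])
    clf.feature_names_ = payload["feature_names"]
    clf.ranges_ = np.asarray(payload["ranges"], dtype=float)
    models = []
    for sub in payload["subsets"]:
        d = len(sub["members"])
        size = p["M"] ** d
        mi = np.zeros(size)
        term_c = np.zeros(size)
        term_v = np.zeros(size)
        assigned = np.full(size, CONTROL, dtype=object)
        for e in sub["entries"]:
            i = e["index"]
            mi[i] = e["mi"]
            term_c[i] = e["term_control"]
            term_v[i] = e["term_variable"]
            assigned[i] = e["assigned"]
        models.append(
            SubsetModel(
                subset=MetaboliteSubset(tuple(sub["members"]), source=sub["source"]),
                M=p["M"],
                combos=enumerate_combinations(p["M"], d),
                mi=mi, term_control=term_c, term_variable=term_v,
                p_o=np.zeros(size), p_o_control=np.zeros(size),
                p_o_variable=np.zeros(size),
                assigned=assigned, I=sub["I"],
                expected_bins={
                    c: np.asarray(v, dtype=int)
                    for c, v in sub["expected_bins"].items()
                },
                degenerate=sub["degenerate"],
            )
        )
    clf.subset_models_ = models
    clf.subsets_ = [m.subset for m in models]
    clf.expected_levels_ = aggregate_expected_levels(models, clf.feature_names_)
    from .cohort import results_table

    clf.results_ = results_table(clf.expected_levels_)
    return clf
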