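"""Feature normalization, F-score selection and RBF-SVM classification.

Subgraph feature vectors are min-max normalized to [0,1] with bounds learned
on the training set, ranked by the F-score — the ratio of between-class mean
separation to pooled within-class variance,

    F = [ (x+ - x)^2 + (x- - x)^2 ]
        / [ (1/(n+ - 1)) sum (x+_k - x+)^2  +  (1/(n- - 1)) sum (x-_k - x-)^2 ]

— and the top-k (default 15) features feed a soft-margin SVM with a radial
basis (Gaussian) kernel.  Labels are +1 for tumor and -1 for stroma.

The fitted model serializes to versioned JSON (support vectors, dual
coefficients, bias, kernel width, selected features, normalization bounds);
prediction is evaluated from those stored arrays, so a round-trip through
disk reproduces every decision value exactly.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import networkx as nx
import numpy as np
import pandas as pd
from sklearn.svm import SVC

from .features import FEATURE_CATEGORIES
from .synthetic import GroundTruth

__all__ = [
    "TUMOR_LABEL",
    "STROMA_LABEL",
    "NormalizationBounds",
    "f_score",
    "rank_and_select",
    "SvmModel",
    "train_svm",
    "train_classifier",
    "classify_subgraphs",
    "propagate_to_nuclei",
    "assign_truth_label",
    "ClassificationReport",
    "evaluate_classification",
]

TUMOR_LABEL = 1
STROMA_LABEL = -1


@dataclass
class NormalizationBounds:
    """Per-feature min/max learned on training data; transform clips to [0,1]."""

    names: List[str]
    mins: np.ndarray
    maxs: np.ndarray

    @classmethod
    def fit(cls, df: pd.DataFrame) -> "NormalizationBounds":
        mins = df.min(axis=0).to_numpy(dtype=float)
        maxs = df.max(axis=0).to_numpy(dtype=float)
        constant = np.isclose(mins, maxs)
        if constant.all():
            raise ValueError("all feature columns are constant; nothing to normalize")
        if constant.any():
            bad = [n for n, c in zip(df.columns, constant) if c]
            warnings.warn(f"constant feature columns mapped to 0: {bad}")
        return cls(list(df.columns), mins, maxs)

    def transform(self, df: pd.DataFrame) -> pd.DataFrame:
        x = df[self.names].to_numpy(dtype=float)
        span = self.maxs - self.mins
        with np.errstate(divide="ignore", invalid="ignore"):
            out = (x - self.mins) / span
        out[:, np.isclose(span, 0.0)] = 0.0
        return pd.DataFrame(np.clip(out, 0.0, 1.0), columns=self.names,
                            index=df.index)

    def inverse_transform(self, df: pd.DataFrame) -> pd.DataFrame:
        x = df[self.names].to_numpy(dtype=float)
        return pd.DataFrame(x * (self.maxs - self.mins) + self.mins,
                            columns=self.names, index=df.index)


def f_score(column: Sequence[float], labels: Sequence[int]) -> float:
    """Univariate F-score of one feature column against +-1 class labels.

    Zero-denominator cases (both classes constant) return +inf when the
    class means differ and 0 when they coincide.
    """
    x = np.asarray(column, dtype=float)
    y = np.asarray(labels)
    pos, neg = x[y == TUMOR_LABEL], x[y == STROMA_LABEL]
    if len(pos) < 2 or len(neg) < 2:
        raise ValueError("F-score needs >= 2 members per class")
    xbar, pbar, nbar = x.mean(), pos.mean(), neg.mean()
    num = (pbar - xbar) ** 2 + (nbar - xbar) ** 2
    den = (np.sum((pos - pbar) ** 2) / (len(pos) - 1)
           + np.sum((neg - nbar) ** 2) / (len(neg) - 1))
    if den == 0.0:
        return float("inf") if not np.isclose(pbar, nbar) else 0.0
    return float(num / den)


def rank_and_select(df: pd.DataFrame, labels: Sequence[int], k: int = 15
                    ) -> Tuple[pd.DataFrame, List[str]]:
    """Rank features by descending F-score and return the top ``k``.

    Ties are broken by the fixed column order of ``df``.  The ranking table
    has columns (feature, category, f_score).
    """
    if k <= 0:
        raise ValueError("k must be positive")
    if k > df.shape[1]:
        raise ValueError("k exceeds the number of features")
    scores = [f_score(df[c].to_numpy(), labels) for c in df.columns]
    order = sorted(range(len(scores)), key=lambda i: (-scores[i], i))
    ranking = pd.DataFrame({
        "feature": [df.columns[i] for i in order],
        "category": [FEATURE_CATEGORIES.get(df.columns[i], "?") for i in order],
        "f_score": [scores[i] for i in order],
    })
    selected = list(ranking["feature"].iloc[:k])
    return ranking, selected


@dataclass
class SvmModel:
    """A trained RBF-SVM over a selected, normalized feature subset.

    The decision function is sign( sum_i a_i K(sv_i, x) + b ) with
    K(u, v) = exp(-gamma ||u - v||^2); ``dual_coef`` holds a_i = alpha_i y_i.
    """

    selected: List[str]
    bounds: NormalizationBounds
    gamma: float
    C: float
    support_vectors: np.ndarray
    dual_coef: np.ndarray
    intercept: float
    version: int = 1

    def decision_function(self, features: pd.DataFrame) -> np.ndarray:
        x = self.bounds.transform(features)[self.selected].to_numpy(dtype=float)
        sv = self.support_vectors
        sq = (np.sum(x ** 2, axis=1)[:, None] + np.sum(sv ** 2, axis=1)[None, :]
              - 2.0 * x @ sv.T)
        kern = np.exp(-self.gamma * np.maximum(sq, 0.0))
        return kern @ self.dual_coef + self.intercept

    def predict(self, features: pd.DataFrame) -> np.ndarray:
        d = self.decision_function(features)
        return np.where(d >= 0, TUMOR_LABEL, STROMA_LABEL)

    # -- JSON round-trip ----------------------------------------------------
    def to_dict(self) -> Dict:
        return {
            "format": "tmagraph-svm",
            "version": self.version,
            "selected": self.selected,
            "bounds": {"names": self.bounds.names,
                       "mins": self.bounds.mins.tolist(),
                       "maxs": self.bounds.maxs.tolist()},
            "gamma": self.gamma,
            "C": self.C,
            "support_vectors": self.support_vectors.tolist(),
            "dual_coef": self.dual_coef.tolist(),
            "intercept": self.intercept,
        }

    @classmethod
    def from_dict(cls, d: Dict) -> "SvmModel":
        if d.get("format") != "tmagraph-svm":
            raise ValueError("not a tmagraph SVM model")
        return cls(
            selected=list(d["selected"]),
            bounds=NormalizationBounds(list(d["bounds"]["names"]),
                                       np.asarray(d["bounds"]["mins"], dtype=float),
                                       np.asarray(d["bounds"]["maxs"], dtype=float)),
            gamma=float(d["gamma"]),
            C=float(d["C"]),
            support_vectors=np.asarray(d["support_vectors"], dtype=float),
            dual_coef=np.asarray(d["dual_coef"], dtype=float),
            intercept=float(d["intercept"]),
            version=int(d.get("version", 1)),
        )

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh)

    @classmethod
    def load(cls, path) -> "SvmModel":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def train_svm(x_norm: np.ndarray, labels: np.ndarray, C: float = 1.0,
              gamma: float = 1.0) -> Tuple[np.ndarray, np.ndarray, float]:
    """Fit a soft-margin RBF-SVM; returns (support vectors, dual coefs, bias).

    Deterministic given the data and hyperparameters.  Raises on
    single-class input.
    """
    labels = np.asarray(labels)
    if np.unique(labels).size < 2:
        raise ValueError("training labels must cover both classes")
    svc = SVC(kernel="rbf", C=C, gamma=gamma)
    svc.fit(x_norm, labels)
    return svc.support_vectors_.copy(), svc.dual_coef_.ravel().copy(), float(svc.intercept_[0])


def train_classifier(features: pd.DataFrame, labels: Sequence[int],
                     k: int = 15, C: float = 1.0,
                     gamma: Optional[float] = None) -> SvmModel:
    """Normalize -> rank by F-score -> select top-k -> fit the RBF-SVM.

    ``gamma`` defaults to 1/k (one over the number of selected features).
    """
    labels = np.asarray(labels)
    bounds = NormalizationBounds.fit(features)
    normed = bounds.transform(features)
    _, selected = rank_and_select(normed, labels, k=k)
    if gamma is None:
        gamma = 1.0 / len(selected)
    sv, coef, b = train_svm(normed[selected].to_numpy(dtype=float), labels,
                            C=C, gamma=gamma)
    return SvmModel(selected=selected, bounds=bounds, gamma=float(gamma),
                    C=float(C), support_vectors=sv, dual_coef=coef, intercept=b)


def classify_subgraphs(model: SvmModel, features: pd.DataFrame) -> np.ndarray:
    """Predict +-1 per subgraph feature row."""
    if features.empty:
        return np.array([], dtype=int)
    return model.predict(features)


def propagate_to_nuclei(subgraphs: Sequence[nx.Graph],
                        predictions: Sequence[int]) -> Dict[int, int]:
    """Give every member nucleus its subgraph's predicted label."""
    out: Dict[int, int] = {}
    for g, p in zip(subgraphs, predictions):
        for node in g.nodes:
            out[int(node)] = int(p)
    return out


def assign_truth_label(subgraph: nx.Graph, truth: GroundTruth) -> int:
    """Ground-truth class of a subgraph: tumor iff a strict majority of
    member-nucleus centroids fall inside the tumor-region mask (ties are
    stroma, the conservative choice)."""
    mask = truth.tumor_region_mask
    h, w = mask.shape
    inside = 0
    nodes = list(subgraph.nodes)
    for node in nodes:
        r, c = subgraph.nodes[node]["record"].centroid
        ri, ci = int(round(r)), int(round(c))
        if 0 <= ri < h and 0 <= ci < w and mask[ri, ci]:
            inside += 1
    return TUMOR_LABEL if inside * 2 > len(nodes) else STROMA_LABEL


@dataclass
class ClassificationReport:
    """Per-core and aggregate overall / producer's accuracies (percent)."""

    per_core: pd.DataFrame            # columns: core_id, overall, tumor, stroma
    overall_mean: float = field(init=False)
    overall_sd: float = field(init=False)
    tumor_mean: float = field(init=False)
    tumor_sd: float = field(init=False)
    stroma_mean: float = field(init=False)
    stroma_sd: float = field(init=False)
    pooled_overall: float = 0.0

    def __post_init__(self):
        def agg(col):
            v = self.per_core[col].dropna()
            if v.empty:
                return float("nan"), float("nan")
            return float(v.mean()), float(v.std(ddof=1)) if len(v) > 1 else 0.0
        self.overall_mean, self.overall_sd = agg("overall")
        self.tumor_mean, self.tumor_sd = agg("tumor")
        self.stroma_mean, self.stroma_sd = agg("stroma")

    def as_dict(self) -> Dict:
        return {
            "overall": {"mean": self.overall_mean, "sd": self.overall_sd},
            "tumor": {"mean": self.tumor_mean, "sd": self.tumor_sd},
            "stroma": {"mean": self.stroma_mean, "sd": self.stroma_sd},
            "pooled_overall": self.pooled_overall,
            "per_core": self.per_core.to_dict(orient="records"),
        }


def evaluate_classification(table: pd.DataFrame) -> ClassificationReport:
    """Per-core overall and producer's accuracies from a prediction table.

    ``table`` needs columns ``core_id``, ``pred`` and ``truth`` (one row per
    nucleus, labels in {+1, -1}).  Producer's accuracy of a class is the
    fraction of that class's true nuclei labeled correctly; cores with no
    nuclei of a class are excluded from that class's aggregate.  Aggregates
    are mean +- sample standard deviation over cores; the pooled per-nucleus
    overall accuracy is reported alongside.
    """
    required = {"core_id", "pred", "truth"}
    if not required.issubset(table.columns):
        raise ValueError(f"prediction table needs columns {sorted(required)}")
    rows = []
    for core, grp in table.groupby("core_id", sort=True):
        correct = (grp["pred"] == grp["truth"])
        row = {"core_id": core, "overall": 100.0 * correct.mean()}
        for name, lab in (("tumor", TUMOR_LABEL), ("stroma", STROMA_LABEL)):
            cls = grp["truth"] == lab
            row[name] = 100.0 * correct[cls].mean() if cls.any() else np.nan
        rows.append(row)
    per_core = pd.DataFrame(rows, columns=["core_id", "overall", "tumor", "stroma"])
    report = ClassificationReport(per_core=per_core)
    report.pooled_overall = float(100.0 * (table["pred"] == table["truth"]).mean()) \
        if len(table) else float("nan")
    return report
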