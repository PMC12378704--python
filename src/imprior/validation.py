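"""Validation of candidates against control sequence sets.

Covers (i) similarity triage of candidates against positive (validated iM)
and negative (G4) controls with Levenshtein and k-mer Jaccard measures,
(ii) the rank-sum comparison of PSSM sliding scores between groups,
(iii) generation of CCC-free random negatives, and (iv) a random-forest
classifier on nucleotide composition + length features.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import edlib
import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import confusion_matrix, roc_auc_score, roc_curve
from sklearn.model_selection import GridSearchCV, StratifiedKFold, train_test_split

from .genome import VALID_ALPHABET

FEATURE_NAMES = ("freq_A", "freq_C", "freq_G", "freq_T", "length")


@dataclass
class ControlSets:
    """Positive (iM), negative (G4) and random CCC-free control sequences."""

    positives: list[str] = field(default_factory=list)
    negatives_g4: list[str] = field(default_factory=list)
    negatives_random: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        for s in self.negatives_random:
            if "CCC" in s:
                raise ValueError("random negatives must not contain 'CCC'")


def levenshtein(a: str, b: str) -> int:
    """Unit-cost edit distance (insertions, deletions, substitutions)."""
    if not a:
        return len(b)
    if not b:
        return len(a)
    return edlib.align(a, b, task="distance")["editDistance"]


def jaccard_kmer(a: str, b: str, k: int = 3) -> float:
    """Intersection-over-union of the distinct k-mer sets of two sequences."""
    if len(a) < k or len(b) < k:
        raise ValueError(f"both sequences must be at least {k} long")
    sa = {a[i : i + k] for i in range(len(a) - k + 1)}
    sb = {b[i : i + k] for i in range(len(b) - k + 1)}
    return len(sa & sb) / len(sa | sb)


def classify_by_similarity(
    candidates: list[str],
    controls: ControlSets,
    metric: str = "jaccard",
    k: int = 3,
    truth_labels: list[int] | None = None,
) -> pd.DataFrame:
    """Label each candidate by its best similarity to either control set.

    Each candidate is assigned the maximum similarity against the positive
    and against the negative (G4) controls; for Levenshtein the similarity
    is the negated distance (smaller distance = more similar). A candidate
    is labeled positive when strictly more similar to the positive set —
    an exact tie classifies as negative (conservative).

    When ``truth_labels`` (1 = genuine positive) are supplied with the
    Jaccard metric, a ROC over the max-positive similarity is computed and
    the result frame carries ``auc`` and the Youden-J ``cutoff`` as
    attributes ``df.attrs``.
    """
    if metric not in ("levenshtein", "jaccard"):
        raise ValueError("metric must be 'levenshtein' or 'jaccard'")
    if not controls.positives or not controls.negatives_g4:
        raise ValueError("control sets must be non-empty")
    if not candidates:
        return pd.DataFrame(columns=["seq", "sim_pos", "sim_neg", "label"])

    def best_sim(seq: str, pool: list[str]) -> float:
        if metric == "levenshtein":
            return max(-levenshtein(seq, c) for c in pool)
        return max(jaccard_kmer(seq, c, k) for c in pool)

    sim_pos = np.array([best_sim(s, controls.positives) for s in candidates])
    sim_neg = np.array([best_sim(s, controls.negatives_g4) for s in candidates])
    labels = np.where(sim_pos > sim_neg, "positive", "negative")
    df = pd.DataFrame(
        {"seq": candidates, "sim_pos": sim_pos, "sim_neg": sim_neg, "label": labels}
    )
    if truth_labels is not None:
        y = np.asarray(truth_labels)
        fpr, tpr, thresholds = roc_curve(y, sim_pos)
        youden = tpr - fpr
        df.attrs["auc"] = float(roc_auc_score(y, sim_pos))
        df.attrs["cutoff"] = float(thresholds[int(np.argmax(youden))])
    return df


def wilcoxon_rank_sum(
    x, y, continuity: bool = True
) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) test.

    Returns (W, p) with W the Mann-Whitney U statistic of the first
    sample. Exact enumeration is used for small samples (n + m <= 10,
    no ties); otherwise the normal approximation with tie correction and
    0.5 continuity correction. Identical samples give p = 1.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    if np.all(pooled == pooled[0]):
        return float(x.size * y.size / 2), 1.0
    has_ties = len(np.unique(pooled)) < pooled.size
    if x.size + y.size <= 10 and not has_ties:
        method = "exact"
    else:
        method = "asymptotic"
    res = stats.mannwhitneyu(
        x, y, alternative="two-sided", method=method,
        use_continuity=continuity,
    )
    return float(res.statistic), float(res.pvalue)


def generate_negative_sequences(
    n: int = 1000,
    len_range: tuple[int, int] = (15, 50),
    rng: np.random.Generator | int = 0,
) -> list[str]:
    """Random DNA sequences guaranteed to contain no 'CCC' substring.

    Lengths are uniform over ``len_range`` (inclusive). Bases are drawn
    uniformly with a per-position constraint: after two consecutive C's
    the next base is drawn from {A,G,T}.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(rng) if isinstance(rng, int) else rng
    lo, hi = len_range
    out = []
    bases = "ACGT"
    non_c = "AGT"
    for _ in range(n):
        L = int(rng.integers(lo, hi + 1))
        chars: list[str] = []
        for _ in range(L):
            if len(chars) >= 2 and chars[-1] == "C" and chars[-2] == "C":
                chars.append(non_c[rng.integers(3)])
            else:
                chars.append(bases[rng.integers(4)])
        out.append("".join(chars))
    return out


def extract_features(seq: str) -> pd.Series:
    """Nucleotide proportions plus length for one sequence."""
    if not seq:
        raise ValueError("empty sequence")
    bad = set(seq) - (VALID_ALPHABET - {"N"})
    if bad:
        raise ValueError(f"non-ACGT characters: {sorted(bad)}")
    L = len(seq)
    return pd.Series(
        {
            "freq_A": seq.count("A") / L,
            "freq_C": seq.count("C") / L,
            "freq_G": seq.count("G") / L,
            "freq_T": seq.count("T") / L,
            "length": L,
        }
    )


def feature_table(seqs: list[str]) -> pd.DataFrame:
    return pd.DataFrame([extract_features(s) for s in seqs])


@dataclass
class ClassifierReport:
    accuracy: float
    sensitivity: float
    specificity: float
    balanced_accuracy: float
    auc: float
    confusion: np.ndarray
    feature_importance: pd.Series
    chosen_mtry: int
    cv_results: pd.DataFrame


def train_and_evaluate_classifier(
    features: pd.DataFrame,
    labels,
    test_size: float = 0.3,
    folds: int = 10,
    mtry_grid: tuple[int, ...] = (1, 2, 3, 4, 5),
    n_trees: int = 500,
    rng_seed: int = 0,
) -> ClassifierReport:
    """Random forest on composition features with mtry tuned by CV.

    A stratified 70/30 split holds out the test set; the number of
    features considered per split (mtry) is chosen by ``folds``-fold
    cross-validated accuracy on the training portion, and all reported
    metrics come from the held-out 30%. Fully seeded, so results are
    reproducible bit-for-bit.
    """
    y = np.asarray(labels)
    if len(np.unique(y)) < 2:
        raise ValueError("need at least two classes")
    X = features[list(FEATURE_NAMES)].to_numpy()
    X_tr, X_te, y_tr, y_te = train_test_split(
        X, y, test_size=test_size, stratify=y, random_state=rng_seed
    )
    grid = GridSearchCV(
        RandomForestClassifier(n_estimators=n_trees, random_state=rng_seed),
        param_grid={"max_features": [m for m in mtry_grid if m <= X.shape[1]]},
        cv=StratifiedKFold(folds, shuffle=True, random_state=rng_seed),
        scoring="accuracy",
        n_jobs=1,
    )
    grid.fit(X_tr, y_tr)
    model = grid.best_estimator_
    y_hat = model.predict(X_te)
    proba = model.predict_proba(X_te)[:, list(model.classes_).index(1)]
    cm = confusion_matrix(y_te, y_hat, labels=[1, 0])
    tp, fn, fp, tn = cm[0, 0], cm[0, 1], cm[1, 0], cm[1, 1]
    sens = tp / (tp + fn) if tp + fn else float("nan")
    spec = tn / (tn + fp) if tn + fp else float("nan")
    return ClassifierReport(
        accuracy=float((tp + tn) / cm.sum()),
        sensitivity=float(sens),
        specificity=float(spec),
        balanced_accuracy=float((sens + spec) / 2),
        auc=float(roc_auc_score(y_te, proba)),
        confusion=cm,
        feature_importance=pd.Series(
            model.feature_importances_, index=list(FEATURE_NAMES)
        ).sort_values(ascending=False),
        chosen_mtry=int(grid.best_params_["max_features"]),
        cv_results=pd.DataFrame(grid.cv_results_),
    )
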