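"""The wrapper-selection fitness oracle.

A candidate solution is a binary mask over genes.  Its quality is measured
by a weighted-voting ensemble of four base classifiers (gradient-boosted
trees, RBF support-vector machine, random forest, decision tree):

1. the labeled samples are split 60/20/20 (train/validation/test),
   stratified by class;
2. the training partition is SMOTE-balanced (validation and test are left
   untouched);
3. the four learners are trained on the selected columns and evaluated on
   the validation partition; each receives a weight proportional to the
   product of its validation Accuracy, Precision, Recall, F1 and F2;
4. the ensemble predicts by weighted hard voting, and the mean of its five
   validation metrics (Avg) enters the fitness

       Fit(mask) = phi * (1 - Avg) + (1 - phi) * NF / AF        (minimized)

   with phi = 0.8, NF the selected count and AF the feature universe.  The
   ``literal`` form phi*Avg + (1-phi)*NF/AF (maximized) is also available.

The held-out test partition is never consulted during selection.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.ensemble import GradientBoostingClassifier, RandomForestClassifier
from sklearn.neighbors import NearestNeighbors
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from gwolfsel.io_prep import ExpressionDataError, ExpressionMatrix

# ---------------------------------------------------------------------------
# confusion counts and metrics
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


def confusion_from_labels(y_true: np.ndarray, y_pred: np.ndarray) -> ConfusionCounts:
    """Count the confusion table with cancer (1) as the positive class."""
    y_true = np.asarray(y_true).astype(int)
    y_pred = np.asarray(y_pred).astype(int)
    if y_true.shape != y_pred.shape:
        raise ValueError("label/prediction shape mismatch")
    return ConfusionCounts(
        tp=int(np.sum((y_true == 1) & (y_pred == 1))),
        tn=int(np.sum((y_true == 0) & (y_pred == 0))),
        fp=int(np.sum((y_true == 0) & (y_pred == 1))),
        fn=int(np.sum((y_true == 1) & (y_pred == 0))),
    )


@dataclass(frozen=True)
class MetricSet:
    """Ac, Pr, Re, F1, F2 plus MCC and balanced accuracy.

    A metric whose denominator vanishes is reported as 0 and listed in
    ``degenerate`` so zeros from undefined ratios are distinguishable from
    genuine zeros.
    """

    ac: float
    pr: float
    re: float
    f1: float
    f2: float
    mcc: float
    bac: float
    degenerate: tuple[str, ...] = ()

    def fitness_product(self) -> float:
        """Product of the five voting metrics (classifier-weight numerator)."""
        return self.ac * self.pr * self.re * self.f1 * self.f2

    def avg_five(self) -> float:
        return (self.ac + self.pr + self.re + self.f1 + self.f2) / 5.0


def _safe_div(num: float, den: float, name: str, degenerate: list[str]) -> float:
    if den == 0:
        degenerate.append(name)
        return 0.0
    return num / den


def compute_metrics(c: ConfusionCounts) -> MetricSet:
    """Exact confusion-table metrics (cancer = positive)."""
    if c.total == 0:
        raise ValueError("empty confusion table")
    degenerate: list[str] = []
    tp, tn, fp, fn = c.tp, c.tn, c.fp, c.fn
    ac = (tp + tn) / c.total
    pr = _safe_div(tp, tp + fp, "pr", degenerate)
    re = _safe_div(tp, tp + fn, "re", degenerate)
    f1 = _safe_div(2 * pr * re, pr + re, "f1", degenerate)
    f2 = _safe_div(5 * pr * re, 4 * pr + re, "f2", degenerate)
    mcc_den = np.sqrt(
        float(tp + fp) * float(tp + fn) * float(tn + fp) * float(tn + fn)
    )
    mcc = _safe_div(float(tp) * tn - float(fp) * fn, mcc_den, "mcc", degenerate)
    sens = _safe_div(tp, tp + fn, "bac", degenerate)
    spec = _safe_div(tn, tn + fp, "bac", degenerate)
    bac = 0.5 * (sens + spec)
    return MetricSet(ac, pr, re, f1, f2, mcc, bac, tuple(dict.fromkeys(degenerate)))


def metrics_from_labels(y_true: np.ndarray, y_pred: np.ndarray) -> MetricSet:
    return compute_metrics(confusion_from_labels(y_true, y_pred))


# ---------------------------------------------------------------------------
# stratified 60/20/20 split
# ---------------------------------------------------------------------------


@dataclass
class SplitSpec:
    fractions: tuple[float, float, float] = (0.6, 0.2, 0.2)
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.fractions) != 3 or any(f <= 0 for f in self.fractions):
            raise ValueError("three positive fractions required")
        if abs(sum(self.fractions) - 1.0) > 1e-9:
            raise ValueError("fractions must sum to 1")


@dataclass
class SplitResult:
    train: ExpressionMatrix
    validation: ExpressionMatrix
    test: ExpressionMatrix
    train_idx: np.ndarray
    validation_idx: np.ndarray
    test_idx: np.ndarray


def stratified_split(m: ExpressionMatrix, spec: SplitSpec) -> SplitResult:
    """Deterministic seeded 60/20/20 split, stratified by class.

    Within each class the counts are the floors of the fractions with the
    remainder handed out in train, validation, test order, so per-class
    proportions stay within one sample of the global fractions and every
    partition contains both classes.
    """
    y = m.require_labels()
    rng = np.random.default_rng(spec.seed)
    parts: list[list[int]] = [[], [], []]
    for cls in (1, 0):
        idx = np.flatnonzero(y == cls)
        if len(idx) < 3:
            raise ExpressionDataError(
                f"class {cls} has {len(idx)} samples; cannot stratify 3 ways"
            )
        idx = rng.permutation(idx)
        counts = [int(np.floor(f * len(idx))) for f in spec.fractions]
        leftover = len(idx) - sum(counts)
        for j in range(leftover):
            counts[j % 3] += 1
        if min(counts) == 0:  # every partition must see both classes
            counts = [max(1, c) for c in counts]
            while sum(counts) > len(idx):
                counts[int(np.argmax(counts))] -= 1
        start = 0
        for j, c in enumerate(counts):
            parts[j].extend(idx[start : start + c].tolist())
            start += c
    tr, va, te = (np.sort(np.asarray(p)) for p in parts)
    return SplitResult(
        train=m.select_samples(tr),
        validation=m.select_samples(va),
        test=m.select_samples(te),
        train_idx=tr,
        validation_idx=va,
        test_idx=te,
    )


# ---------------------------------------------------------------------------
# SMOTE
# ---------------------------------------------------------------------------


def smote_arrays(
    X: np.ndarray,
    y: np.ndarray,
    k: int = 5,
    rng: np.random.Generator | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Balance classes by synthesizing minority points on k-NN segments.

    Each synthetic sample is x + u * (x_nn - x) with u ~ U(0,1), where x is
    a random minority sample and x_nn one of its k minority nearest
    neighbors (k capped at minority size - 1).  Originals are kept unchanged
    and returned first.
    """
    rng = rng or np.random.default_rng()
    y = np.asarray(y).astype(int)
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) != 2:
        raise ValueError("SMOTE requires exactly two classes")
    minority = classes[np.argmin(counts)]
    n_min, n_maj = counts.min(), counts.max()
    if n_min == n_maj:
        return X.copy(), y.copy()
    if n_min < 2:
        raise ValueError("minority class must have >= 2 samples for SMOTE")
    Xm = X[y == minority]
    k_eff = min(k, n_min - 1)
    nn = NearestNeighbors(n_neighbors=k_eff + 1).fit(Xm)
    neighbors = nn.kneighbors(Xm, return_distance=False)[:, 1:]  # drop self
    n_new = int(n_maj - n_min)
    base = rng.integers(0, n_min, size=n_new)
    pick = rng.integers(0, k_eff, size=n_new)
    u = rng.random(n_new)
    x0 = Xm[base]
    x1 = Xm[neighbors[base, pick]]
    synth = x0 + u[:, None] * (x1 - x0)
    X_out = np.vstack([X, synth])
    y_out = np.concatenate([y, np.full(n_new, minority, dtype=y.dtype)])
    return X_out, y_out


def smote_balance(
    train: ExpressionMatrix, k: int = 5, rng: np.random.Generator | None = None
) -> ExpressionMatrix:
    """SMOTE on an ExpressionMatrix (samples are columns)."""
    y = train.require_labels()
    X_out, y_out = smote_arrays(train.values.T, y, k=k, rng=rng)
    n_new = X_out.shape[0] - train.n_samples
    sample_ids = list(train.sample_ids) + [f"synthetic_{i}" for i in range(n_new)]
    return ExpressionMatrix(
        values=X_out.T,
        gene_ids=list(train.gene_ids),
        sample_ids=sample_ids,
        labels=y_out.astype(np.int8),
    )


# ---------------------------------------------------------------------------
# weights, voting, fitness
# ---------------------------------------------------------------------------


def classifier_weights(val_metrics: list[MetricSet]) -> np.ndarray:
    """Normalized products of the five validation metrics, one per learner.

    If every product is zero (all learners degenerate on validation) the
    weights fall back to uniform.
    """
    products = np.array([ms.fitness_product() for ms in val_metrics], dtype=float)
    total = products.sum()
    if total <= 0:
        return np.full(len(val_metrics), 1.0 / len(val_metrics))
    return products / total


def ensemble_predict(
    per_clf_predictions: np.ndarray, weights: np.ndarray
) -> np.ndarray:
    """Weighted hard vote over binary predictions; ties go to cancer (1).

    ``per_clf_predictions`` is (n_classifiers, n_samples) over {0, 1}.
    """
    preds = np.asarray(per_clf_predictions)
    weights = np.asarray(weights, dtype=float)
    if preds.ndim != 2 or preds.shape[0] != weights.shape[0]:
        raise ValueError("weight/prediction arity mismatch")
    pos_score = weights @ (preds == 1)
    neg_score = weights @ (preds == 0)
    # tie (including float round-off) resolves toward the positive class
    return (pos_score >= neg_score - 1e-12).astype(np.int8)


@dataclass(frozen=True)
class FitnessValue:
    """Fitness of one mask, with its components (direction: minimize)."""

    fit: float
    avg_eclf: float
    nf: int
    af: int
    phi: float
    flags: tuple[str, ...] = ()


def fitness_from_components(
    avg_eclf: float, nf: int, af: int, phi: float = 0.8, literal: bool = False
) -> float:
    """Scalar fitness from ensemble average and feature fraction.

    Default is the minimized complement phi*(1-Avg) + (1-phi)*NF/AF; the
    literal (maximized) form phi*Avg + (1-phi)*NF/AF is kept for reference.
    """
    if not 0 < phi < 1:
        raise ValueError("phi must lie in (0,1)")
    if not 0 <= nf <= af:
        raise ValueError("NF must lie in [0, AF]")
    frac = nf / af
    if literal:
        return phi * avg_eclf + (1 - phi) * frac
    return phi * (1.0 - avg_eclf) + (1 - phi) * frac


def default_panel(seed: int = 0) -> list:
    """The four base learners clf_1..clf_4 with fixed small-sample settings.

    Hyperparameters are sized for ~10^2-sample training partitions (and for
    the ~10^4 fitness evaluations of a metaheuristic run): shallow boosted
    trees with sqrt feature subsampling, a compact random forest, an RBF
    SVM, and a depth-capped decision tree.
    """
    return [
        GradientBoostingClassifier(
            n_estimators=15, max_depth=2, max_features="sqrt", random_state=seed
        ),
        SVC(kernel="rbf", C=1.0, random_state=seed),
        RandomForestClassifier(n_estimators=12, max_depth=6, random_state=seed),
        DecisionTreeClassifier(max_depth=6, random_state=seed),
    ]


@dataclass
class FitnessEvaluator:
    """Caches and computes Fit(mask) for a fixed split.

    The training partition is SMOTE-balanced once at construction (seeded),
    so fitness is a pure function of the mask; results are cached by the
    mask's byte pattern.  The evaluator logs the sample ids it consults,
    which by construction never include the test partition.
    """

    split: SplitResult
    phi: float = 0.8
    smote_k: int = 5
    seed: int = 0
    literal: bool = False
    panel_factory: object = None

    def __post_init__(self) -> None:
        rng = np.random.default_rng(self.seed)
        bal = smote_balance(self.split.train, k=self.smote_k, rng=rng)
        self._X_train = bal.values.T            # samples x genes
        self._y_train = bal.require_labels()
        self._X_val = self.split.validation.values.T
        self._y_val = self.split.validation.require_labels()
        self._af = self.split.train.n_genes
        self._cache: dict[bytes, FitnessValue] = {}
        self.n_evaluations = 0
        self.consulted_sample_ids = set(self.split.train.sample_ids) | set(
            self.split.validation.sample_ids
        )
        if self.panel_factory is None:
            self.panel_factory = default_panel

    @property
    def af(self) -> int:
        return self._af

    def __call__(self, mask: np.ndarray) -> FitnessValue:
        return self.evaluate(mask)

    def evaluate(self, mask: np.ndarray) -> FitnessValue:
        mask = np.asarray(mask, dtype=np.int8)
        if mask.shape != (self._af,):
            raise ValueError(f"mask length {mask.shape} != AF {self._af}")
        key = mask.tobytes()
        hit = self._cache.get(key)
        if hit is not None:
            return hit
        value = self._evaluate_uncached(mask)
        self._cache[key] = value
        return value

    def _evaluate_uncached(self, mask: np.ndarray) -> FitnessValue:
        nf = int(mask.sum())
        if nf == 0:
            # worst possible fitness; nothing to train on
            fit = 0.0 if self.literal else 1.0
            return FitnessValue(fit, 0.0, 0, self._af, self.phi, ("empty_mask",))
        self.n_evaluations += 1
        cols = np.flatnonzero(mask)
        Xtr = self._X_train[:, cols]
        Xva = self._X_val[:, cols]
        val_preds = np.empty((4, len(self._y_val)), dtype=np.int8)
        val_metrics: list[MetricSet] = []
        for i, clf in enumerate(self.panel_factory(self.seed)):
            clf.fit(Xtr, self._y_train)
            pred = np.asarray(clf.predict(Xva), dtype=np.int8)
            val_preds[i] = pred
            val_metrics.append(metrics_from_labels(self._y_val, pred))
        weights = classifier_weights(val_metrics)
        ens_pred = ensemble_predict(val_preds, weights)
        ens_metrics = metrics_from_labels(self._y_val, ens_pred)
        avg = ens_metrics.avg_five()
        fit = fitness_from_components(avg, nf, self._af, self.phi, self.literal)
        flags = ()
        if all(ms.fitness_product() == 0 for ms in val_metrics):
            flags = ("uniform_weight_fallback",)
        return FitnessValue(fit, avg, nf, self._af, self.phi, flags)
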