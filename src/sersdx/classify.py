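"""Two-step RBF-SVM diagnosis with jackknife tuning and grouped cross-validation.

Step 1 discriminates normal controls from each tumor group; step 2
discriminates the tumor groups pairwise.  Hyperparameters (C, gamma) are
chosen by jackknife (leave-one-spectrum-out) accuracy over a power-of-two
grid.  Generalization is measured two ways: leave-one-spectrum-out (LOSO),
where single spectra are held out, and leave-one-patient-out (LOPO), where
all spectra of one patient are held out together so that patient identity
can never leak between train and test folds.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics.pairwise import rbf_kernel
from sklearn.svm import SVC

from .core import SpectraCohort
from .errors import ConfigError, DegenerateInputError, ValidationError

LOSO = "LOSO"
LOPO = "LOPO"

_STEP1_TASKS = (("Normal", "PA"), ("Normal", "WT"), ("Normal", "MEC"))
_STEP2_TASKS = (("PA", "WT"), ("PA", "MEC"), ("WT", "MEC"))


@dataclass
class ModelConfig:
    """RBF-SVM tuning configuration.

    ``gamma_mode='scale-relative'`` multiplies the gamma grid by the
    reference value 1 / (n_features * Var(X)) so that the same grid works
    across normalization conventions; ``'absolute'`` uses the grid as-is.
    ``reoptimize_per_fold`` enables nested tuning (jackknife re-run inside
    every outer CV fold); the default tunes once per task on the full task
    data, matching a train-then-test protocol.  ``class_weight='balanced'``
    (the default) counters the cohort's group-size imbalance.  The weights
    are computed ONCE from the whole task's class sizes and held fixed
    across CV folds: re-balancing inside each fold leaks the held-out
    label, because removing a spectrum (or patient) makes its own class
    the training minority, and the re-weighting then systematically favors
    exactly that class.  With equal class sizes this fold-wise artifact
    turns leave-one-out into an oracle that scores perfectly even on pure
    noise.
    """

    C_grid: tuple[float, ...] = tuple(2.0 ** np.arange(-5, 16, 2))
    gamma_grid: tuple[float, ...] = tuple(2.0 ** np.arange(-15, 4, 2))
    gamma_mode: str = "scale-relative"
    class_weight: str | None = "balanced"  # 'balanced' or None
    reoptimize_per_fold: bool = False

    def __post_init__(self) -> None:
        if not self.C_grid or not self.gamma_grid:
            raise ConfigError("hyperparameter grids must be non-empty")
        if any(c <= 0 for c in self.C_grid) or any(g <= 0 for g in self.gamma_grid):
            raise ConfigError("C and gamma values must be positive")
        if self.gamma_mode not in ("scale-relative", "absolute"):
            raise ConfigError(f"unknown gamma_mode {self.gamma_mode!r}")


@dataclass
class Dataset:
    """A binary task: spectra of two groups with patient identities."""

    X: np.ndarray  # (n_spectra, n_features)
    y: np.ndarray  # group labels, shape (n_spectra,)
    patients: np.ndarray  # patient ids, shape (n_spectra,)
    positive_label: str
    negative_label: str

    def __post_init__(self) -> None:
        if self.X.ndim != 2 or len(self.y) != len(self.X) or len(self.patients) != len(self.X):
            raise ValidationError("inconsistent dataset shapes")
        labels = set(np.unique(self.y))
        if not labels <= {self.positive_label, self.negative_label}:
            raise ValidationError(f"unexpected labels {labels}")

    @property
    def n(self) -> int:
        return len(self.X)

    def gamma_scale(self) -> float:
        var = float(self.X.var())
        if var == 0.0:
            return 1.0
        return 1.0 / (self.X.shape[1] * var)

    def resolved_gammas(self, config: ModelConfig) -> tuple[float, ...]:
        if config.gamma_mode == "absolute":
            return tuple(config.gamma_grid)
        scale = self.gamma_scale()
        return tuple(g * scale for g in config.gamma_grid)


@dataclass
class ConfusionCounts:
    tp: int
    fn: int
    tn: int
    fp: int
    positive_label: str = "positive"
    negative_label: str = "negative"

    def __post_init__(self) -> None:
        if min(self.tp, self.fn, self.tn, self.fp) < 0:
            raise ValidationError("confusion counts must be non-negative")

    @property
    def n_positive(self) -> int:
        return self.tp + self.fn

    @property
    def n_negative(self) -> int:
        return self.tn + self.fp


@dataclass
class MetricReport:
    sp: float
    se: float
    acc: float
    mcc: float
    task: tuple[str, str]  # (positive, negative)
    scheme: str
    counts: ConfusionCounts | None = None
    step: int | None = None


@dataclass
class EvaluationReport:
    reports: list[MetricReport] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)

    def get(self, positive: str, negative: str, scheme: str) -> MetricReport:
        for r in self.reports:
            if r.task == (positive, negative) and r.scheme == scheme:
                return r
        raise KeyError((positive, negative, scheme))


def build_task(cohort: SpectraCohort, positive: str, negative: str) -> Dataset:
    """Assemble the feature matrix for one binary task.

    Rows are the normalized intensity vectors of the two groups' spectra;
    patient ids are retained so LOPO folds can be formed.
    """
    if positive == negative:
        raise ConfigError("positive and negative labels must differ")
    spectra = [s for s in cohort.spectra if s.meta.group in (positive, negative)]
    groups_present = {s.meta.group for s in spectra}
    for g in (positive, negative):
        if g not in groups_present:
            raise ValidationError(f"group {g!r} has no spectra in the cohort")
    X = np.stack([s.intensity for s in spectra])
    y = np.array([s.meta.group for s in spectra])
    patients = np.array([s.meta.patient_id for s in spectra])
    return Dataset(X=X, y=y, patients=patients, positive_label=positive, negative_label=negative)


def _resolve_class_weight(config: ModelConfig, y: np.ndarray) -> dict | None:
    """Fixed prior-correction weights from the full task's class sizes.

    Returns None when ``config.class_weight`` is None; otherwise a dict
    equivalent to sklearn's 'balanced' heuristic evaluated on ``y`` once,
    so per-fold class removal cannot signal the held-out label.
    """
    if config.class_weight is None:
        return None
    classes, counts = np.unique(y, return_counts=True)
    n = len(y)
    return {c: n / (len(classes) * cnt) for c, cnt in zip(classes, counts)}


def _fit_predict(K_train: np.ndarray, y_train: np.ndarray, K_test_rows: np.ndarray,
                 C: float, class_weight) -> np.ndarray:
    svc = SVC(C=C, kernel="precomputed", class_weight=class_weight)
    svc.fit(K_train, y_train)
    return svc.predict(K_test_rows)


def _loo_predictions(K: np.ndarray, y: np.ndarray, C: float, class_weight) -> np.ndarray:
    """Exact leave-one-out predictions for a precomputed-kernel SVM.

    Removing a non-support vector leaves the SVM solution unchanged, so
    only support vectors need an actual refit; all other points take the
    full-model prediction.
    """
    n = len(y)
    svc = SVC(C=C, kernel="precomputed", class_weight=class_weight)
    svc.fit(K, y)
    preds = svc.predict(K)
    sv = set(svc.support_.tolist())
    idx = np.arange(n)
    for i in sv:
        tr = idx[idx != i]
        preds[i] = _fit_predict(K[np.ix_(tr, tr)], y[tr], K[np.ix_([i], tr)], C, class_weight)[0]
    return preds


def jackknife_optimize(dataset: Dataset, config: ModelConfig | None = None
                       ) -> tuple[float, float, float]:
    """Grid search (C, gamma) by leave-one-spectrum-out accuracy.

    Returns the winning (C, gamma, inner accuracy); ties broken toward the
    smallest C, then the smallest gamma.
    """
    config = config or ModelConfig()
    y = dataset.y
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2 or counts.min() < 2:
        raise DegenerateInputError("jackknife tuning needs >= 2 rows in each class")
    gammas = dataset.resolved_gammas(config)
    raw_gammas = tuple(config.gamma_grid)
    cw = _resolve_class_weight(config, y)
    results: dict[tuple[float, float], float] = {}
    for g_raw, g in zip(raw_gammas, gammas):
        K = rbf_kernel(dataset.X, gamma=g)
        for C in config.C_grid:
            preds = _loo_predictions(K, y, C, cw)
            results[(C, g_raw)] = float(np.mean(preds == y))
    best_acc = max(results.values())
    for C in sorted(config.C_grid):
        for g_raw in sorted(raw_gammas):
            if results[(C, g_raw)] == best_acc:
                g_eff = gammas[raw_gammas.index(g_raw)]
                return float(C), float(g_eff), best_acc
    raise RuntimeError("unreachable")


def _folds(dataset: Dataset, scheme: str):
    idx = np.arange(dataset.n)
    if scheme == LOSO:
        for i in idx:
            yield idx[idx != i], idx[i : i + 1]
    elif scheme == LOPO:
        for p in sorted(set(dataset.patients.tolist())):
            test = idx[dataset.patients == p]
            train = idx[dataset.patients != p]
            yield train, test
    else:
        raise ConfigError(f"unknown CV scheme {scheme!r}")


def cross_validate(
    dataset: Dataset,
    scheme: str,
    config: ModelConfig | None = None,
    return_details: bool = False,
    hyperparams: tuple[float, float] | None = None,
):
    """Pooled confusion counts for one task under one CV scheme.

    LOPO folds hold out every spectrum of one patient; a leakage guard
    asserts train and test patient sets never intersect.  A fold whose
    training portion lacks one class is skipped with a warning and
    reported in the details.  ``hyperparams`` supplies a pre-tuned
    (C, gamma) pair (gamma on the absolute scale) and skips the jackknife.
    """
    config = config or ModelConfig()
    cw = _resolve_class_weight(config, dataset.y)
    details: dict = {"scheme": scheme, "skipped_folds": [], "n_folds": 0}
    if hyperparams is not None:
        chosen = hyperparams
        details["C"], details["gamma"] = hyperparams
    elif config.reoptimize_per_fold:
        chosen = None
    else:
        C, gamma, inner_acc = jackknife_optimize(dataset, config)
        chosen = (C, gamma)
        details["C"], details["gamma"], details["inner_accuracy"] = C, gamma, inner_acc

    tp = fn = tn = fp = 0
    K_cache: dict[float, np.ndarray] = {}
    for train, test in _folds(dataset, scheme):
        details["n_folds"] += 1
        train_patients = set(dataset.patients[train].tolist())
        test_patients = set(dataset.patients[test].tolist())
        if scheme == LOPO and train_patients & test_patients:
            raise AssertionError("patient leakage between train and test folds")
        if len(set(dataset.y[train].tolist())) < 2:
            pid = dataset.patients[test][0]
            warnings.warn(f"LOPO fold for patient {pid!r} skipped: training fold lacks one class")
            details["skipped_folds"].append(str(pid))
            continue
        if chosen is None:
            sub = Dataset(
                X=dataset.X[train], y=dataset.y[train], patients=dataset.patients[train],
                positive_label=dataset.positive_label, negative_label=dataset.negative_label,
            )
            C, gamma, _ = jackknife_optimize(sub, config)
            K_tr = rbf_kernel(dataset.X[train], gamma=gamma)
            K_te = rbf_kernel(dataset.X[test], dataset.X[train], gamma=gamma)
        else:
            C, gamma = chosen
            if gamma not in K_cache:
                K_cache[gamma] = rbf_kernel(dataset.X, gamma=gamma)
            K = K_cache[gamma]
            K_tr = K[np.ix_(train, train)]
            K_te = K[np.ix_(test, train)]
        preds = _fit_predict(K_tr, dataset.y[train], K_te, C, cw)
        for truth, pred in zip(dataset.y[test], preds):
            if truth == dataset.positive_label:
                tp += int(pred == truth)
                fn += int(pred != truth)
            else:
                tn += int(pred == truth)
                fp += int(pred != truth)
    counts = ConfusionCounts(
        tp=tp, fn=fn, tn=tn, fp=fp,
        positive_label=dataset.positive_label, negative_label=dataset.negative_label,
    )
    if return_details:
        return counts, details
    return counts


def compute_metrics(
    counts: ConfusionCounts, scheme: str = "", step: int | None = None
) -> MetricReport:
    """Specificity, sensitivity, accuracy and Matthews correlation.

    MCC uses the standard four-count formula with the 0 convention when a
    marginal (hence the denominator) is zero.
    """
    tp, fn, tn, fp = counts.tp, counts.fn, counts.tn, counts.fp
    total = tp + fn + tn + fp
    if total == 0:
        raise DegenerateInputError("all confusion counts are zero")
    if counts.n_positive == 0 or counts.n_negative == 0:
        raise DegenerateInputError("both classes must be present")
    sp = tn / counts.n_negative
    se = tp / counts.n_positive
    acc = (tp + tn) / total
    den = math.sqrt(float(tp + fp) * (tp + fn) * (tn + fp) * (tn + fn))
    mcc = 0.0 if den == 0.0 else (tp * tn - fp * fn) / den
    return MetricReport(
        sp=sp, se=se, acc=acc, mcc=mcc,
        task=(counts.positive_label, counts.negative_label),
        scheme=scheme, counts=counts, step=step,
    )


def round_half_away(x: float) -> int:
    return int(math.floor(x + 0.5)) if x >= 0 else int(math.ceil(x - 0.5))


def counts_from_rates(
    se: float, sp: float, n_pos: int, n_neg: int,
    positive_label: str = "positive", negative_label: str = "negative",
) -> ConfusionCounts:
    """Reconstruct confusion counts from printed sensitivity/specificity.

    tp and tn are the rates times the class sizes rounded half away from
    zero; fn and fp are the complements.
    """
    if not (0.0 <= se <= 1.0 and 0.0 <= sp <= 1.0):
        raise ConfigError("rates must lie in [0, 1]")
    tp = round_half_away(se * n_pos)
    tn = round_half_away(sp * n_neg)
    return ConfusionCounts(
        tp=tp, fn=n_pos - tp, tn=tn, fp=n_neg - tn,
        positive_label=positive_label, negative_label=negative_label,
    )


def run_two_step(
    cohort: SpectraCohort,
    config: ModelConfig | None = None,
    schemes: tuple[str, ...] = (LOSO, LOPO),
) -> EvaluationReport:
    """Evaluate the full two-step diagnosis under each CV scheme.

    Step 1: Normal vs each tumor group; step 2: tumor groups pairwise.
    Positive-class conventions follow the reporting layout: Normal is the
    positive class in step-1 LOSO tables, the tumor is positive in step-1
    LOPO tables, and the first-listed tumor is positive in step 2.
    """
    config = config or ModelConfig()
    report = EvaluationReport()
    present = {g for g in cohort.groups if cohort.group_spectra(g)}
    for step, tasks in ((1, _STEP1_TASKS), (2, _STEP2_TASKS)):
        for a, b in tasks:
            if a not in present or b not in present:
                report.warnings.append(f"task {a} vs {b} skipped: group missing")
                continue
            # tune once per task; the data are identical under both schemes
            shared: tuple[float, float] | None = None
            if not config.reoptimize_per_fold:
                C, gamma, _ = jackknife_optimize(build_task(cohort, a, b), config)
                shared = (C, gamma)
            for scheme in schemes:
                if step == 1 and scheme == LOPO:
                    positive, negative = b, a  # tumor positive in LOPO step-1 tables
                else:
                    positive, negative = a, b
                ds = build_task(cohort, positive, negative)
                counts = cross_validate(ds, scheme, config, hyperparams=shared)
                report.reports.append(compute_metrics(counts, scheme=scheme, step=step))
    return report


__all__ = [
    "LOSO",
    "LOPO",
    "ModelConfig",
    "Dataset",
    "ConfusionCounts",
    "MetricReport",
    "EvaluationReport",
    "build_task",
    "jackknife_optimize",
    "cross_validate",
    "compute_metrics",
    "counts_from_rates",
    "round_half_away",
    "run_two_step",
]
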