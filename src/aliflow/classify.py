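"""Random-forest condition classification of LFP fragments.

Features are per-electrode power densities over 0.2-300 Hz, mean-pooled into
1-Hz bins for the 20 most active electrodes, one row per 10-s fragment. The
forest is trained on a stratified 70/30 fragment split and validated with
five-fold cross-validation on the training portion. Reporting follows the
study's framework: per-condition class repartition (fraction of fragments
assigned to each trained class), confidence upon prediction (CUP, the mean
predicted probability of the winning class), and a chi-square goodness-of-fit
test of the assignments against the random-assignment hypothesis (uniform
over the trained classes, 33.3% each for three).
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy import stats
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import StratifiedKFold, cross_val_score, train_test_split

from .ephys import PowerSpectrogram

__all__ = [
    "FeatureMatrix",
    "ClassificationReport",
    "ChiSquareResult",
    "build_features",
    "concat_features",
    "train_condition_classifier",
    "predict_repartition",
    "chi_square_vs_random",
]


@dataclass
class FeatureMatrix:
    """Fragment-level feature rows with labels and provenance.

    X : (fragments, electrodes * bins) float32, electrode-major column order
    y : condition label per fragment
    groups : source recording id per fragment
    electrode_ids : selected electrodes, in column-block order
    bin_hz : pooling width of the frequency bins
    """

    X: np.ndarray
    y: np.ndarray
    groups: np.ndarray
    electrode_ids: np.ndarray
    bin_hz: float

    def __post_init__(self) -> None:
        if np.isnan(self.X).any():
            raise ValueError("feature matrix contains missing values")
        if not (len(self.X) == len(self.y) == len(self.groups)):
            raise ValueError("X, y and groups must have one entry per fragment")

    def restrict_electrodes(self, electrode_ids: Sequence[int]) -> "FeatureMatrix":
        """Column subset for the given electrodes (order preserved as given)."""
        n_bins = self.X.shape[1] // len(self.electrode_ids)
        pos = {int(e): i for i, e in enumerate(self.electrode_ids)}
        cols = np.concatenate(
            [np.arange(pos[int(e)] * n_bins, (pos[int(e)] + 1) * n_bins) for e in electrode_ids]
        )
        return FeatureMatrix(
            X=self.X[:, cols],
            y=self.y,
            groups=self.groups,
            electrode_ids=np.asarray(list(electrode_ids)),
            bin_hz=self.bin_hz,
        )


@dataclass(frozen=True)
class ChiSquareResult:
    statistic: float
    dof: int
    pvalue: float
    expected_fraction: float  # uniform null: 1/k per class


@dataclass
class ClassificationReport:
    """Held-out performance, CV scores, repartition, CUP and chi-square."""

    accuracy: float
    cv_scores: List[float]
    classes: List[str]
    class_repartition: Dict[str, Dict[str, float]]
    cup: float
    cup_by_condition: Dict[str, float]
    chi2_by_condition: Dict[str, ChiSquareResult]
    n_train: int
    n_test: int
    seed: int
    hyperparameters: Dict[str, object]

    def to_dict(self) -> dict:
        d = asdict(self)
        return d

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), indent=2, **kwargs)


def _pool_bins(power: np.ndarray, freqs: np.ndarray, bin_hz: float) -> np.ndarray:
    """Mean-pool (fragments, raw bins) power into bin_hz-wide frequency bins."""
    df = freqs[1] - freqs[0]
    if np.isclose(bin_hz, df):
        return power
    # n_bins covers (0, freqs[-1]]; an exact top edge folds into the last bin
    n_bins = int(np.floor((freqs[-1] - 1e-9) / bin_hz)) + 1
    bin_id = np.floor(freqs / bin_hz + 1e-9).astype(int)
    bin_id = np.clip(bin_id, 0, n_bins - 1)
    counts = np.bincount(bin_id, minlength=n_bins).astype(float)
    onehot = np.zeros((len(freqs), n_bins))
    onehot[np.arange(len(freqs)), bin_id] = 1.0
    return (power @ onehot) / counts


def build_features(
    specs: Sequence[PowerSpectrogram],
    selected_electrodes: Sequence[int],
    bin_hz: float = 1.0,
    labels: Optional[Sequence[str]] = None,
) -> FeatureMatrix:
    """Assemble fragment-level features from per-recording spectrograms.

    Column order is deterministic: electrode-major in the order of
    ``selected_electrodes``, frequency-minor. Labels default to each
    spectrogram's per-fragment ground truth when present, else its condition.
    """
    if labels is not None and len(labels) != len(specs):
        raise ValueError("labels must have one entry per spectrogram")
    ref_freqs = specs[0].freqs
    rows, ys, groups = [], [], []
    for i, spec in enumerate(specs):
        if len(spec.freqs) != len(ref_freqs) or not np.allclose(spec.freqs, ref_freqs):
            raise ValueError("all spectrograms must share the same frequency grid")
        pos = {int(e): j for j, e in enumerate(spec.electrode_ids)}
        missing = [e for e in selected_electrodes if int(e) not in pos]
        if missing:
            raise ValueError(f"spectrogram {i} lacks electrodes {missing}")
        n_frag = spec.power.shape[1]
        pooled = [
            _pool_bins(spec.power[pos[int(e)]], spec.freqs, bin_hz) for e in selected_electrodes
        ]
        rows.append(np.concatenate(pooled, axis=1))
        if labels is not None:
            ys.extend([labels[i]] * n_frag)
        elif spec.fragment_labels is not None:
            ys.extend(spec.fragment_labels)
        else:
            ys.extend([spec.condition] * n_frag)
        groups.extend([i] * n_frag)
    X = np.concatenate(rows, axis=0).astype(np.float32)
    return FeatureMatrix(
        X=X,
        y=np.asarray(ys),
        groups=np.asarray(groups),
        electrode_ids=np.asarray(list(selected_electrodes)),
        bin_hz=bin_hz,
    )


def concat_features(parts: Sequence[FeatureMatrix]) -> FeatureMatrix:
    """Stack feature matrices built with the same electrodes and pooling."""
    first = parts[0]
    for p in parts[1:]:
        if p.X.shape[1] != first.X.shape[1] or not np.array_equal(p.electrode_ids, first.electrode_ids):
            raise ValueError("feature matrices are not column-compatible")
    offset = 0
    groups = []
    for p in parts:
        groups.append(p.groups + offset)
        offset += int(p.groups.max()) + 1 if len(p.groups) else 0
    return FeatureMatrix(
        X=np.concatenate([p.X for p in parts], axis=0),
        y=np.concatenate([p.y for p in parts]),
        groups=np.concatenate(groups),
        electrode_ids=first.electrode_ids,
        bin_hz=first.bin_hz,
    )


def chi_square_vs_random(repartition_counts: Sequence[int]) -> ChiSquareResult:
    """Chi-square goodness of fit of class-assignment counts against the
    random-assignment hypothesis (uniform: total/k expected per class;
    33.3% per class when three classes were trained)."""
    counts = np.asarray(repartition_counts, dtype=float)
    total = counts.sum()
    if total <= 0:
        raise ValueError("total assignment count must be > 0")
    k = len(counts)
    expected = total / k
    if expected < 1:
        import warnings

        warnings.warn(
            "expected count per class is below 1; the chi-square test is unreliable",
            RuntimeWarning,
            stacklevel=2,
        )
    stat, p = stats.chisquare(counts)
    return ChiSquareResult(statistic=float(stat), dof=k - 1, pvalue=float(p), expected_fraction=1.0 / k)


def predict_repartition(
    model: RandomForestClassifier,
    fm_test: FeatureMatrix,
    tested_condition: Optional[str] = None,
) -> Tuple[Dict[str, float], float]:
    """Class repartition and CUP of the model on test fragments.

    repartition[c] is the fraction of fragments assigned to trained class c;
    CUP is the mean predicted probability of the winning class.
    """
    if fm_test.X.shape[1] != model.n_features_in_:
        raise ValueError(
            f"feature columns ({fm_test.X.shape[1]}) do not match the trained "
            f"model ({model.n_features_in_})"
        )
    proba = model.predict_proba(fm_test.X)
    winners = np.argmax(proba, axis=1)
    cup = float(proba[np.arange(len(winners)), winners].mean())
    repartition = {
        str(c): float(np.mean(winners == i)) for i, c in enumerate(model.classes_)
    }
    return repartition, cup


def train_condition_classifier(
    fm: FeatureMatrix,
    train_frac: float = 0.7,
    n_folds: int = 5,
    seed: int = 0,
    n_estimators: int = 500,
    group_by_recording: bool = False,
) -> Tuple[RandomForestClassifier, ClassificationReport]:
    """Stratified 70/30 split, random-forest fit, CV, and full reporting.

    ``group_by_recording=True`` splits at the recording level instead
    (stricter: no fragments of one recording on both sides), at the cost of a
    split that is only approximately stratified.
    """
    classes, class_counts = np.unique(fm.y, return_counts=True)
    if len(classes) < 2:
        raise ValueError("need at least 2 classes to train")
    short = classes[class_counts < n_folds]
    if len(short):
        raise ValueError(f"classes {list(short)} have fewer than n_folds={n_folds} fragments")

    idx = np.arange(len(fm.y))
    if group_by_recording:
        from sklearn.model_selection import GroupShuffleSplit

        gss = GroupShuffleSplit(n_splits=1, train_size=train_frac, random_state=seed)
        tr, te = next(gss.split(idx, fm.y, groups=fm.groups))
    else:
        tr, te = train_test_split(
            idx, train_size=train_frac, stratify=fm.y, random_state=seed
        )
    X_tr, y_tr = fm.X[tr], fm.y[tr]
    X_te, y_te = fm.X[te], fm.y[te]

    model = RandomForestClassifier(
        n_estimators=n_estimators, max_features="sqrt", random_state=seed, n_jobs=1
    )
    cv = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    cv_scores = cross_val_score(model, X_tr, y_tr, cv=cv, n_jobs=1)
    model.fit(X_tr, y_tr)

    pred = model.predict(X_te)
    proba = model.predict_proba(X_te)
    winners = np.argmax(proba, axis=1)
    accuracy = float(np.mean(pred == y_te))

    repartition: Dict[str, Dict[str, float]] = {}
    cup_by_condition: Dict[str, float] = {}
    chi2_by_condition: Dict[str, ChiSquareResult] = {}
    for cond in np.unique(y_te):
        sel = y_te == cond
        counts = np.array([(pred[sel] == c).sum() for c in model.classes_])
        repartition[str(cond)] = {
            str(c): float(n) / counts.sum() for c, n in zip(model.classes_, counts)
        }
        cup_by_condition[str(cond)] = float(
            proba[sel, :][np.arange(sel.sum()), winners[sel]].mean()
        )
        chi2_by_condition[str(cond)] = chi_square_vs_random(counts)
    cup = float(proba[np.arange(len(winners)), winners].mean())

    report = ClassificationReport(
        accuracy=accuracy,
        cv_scores=[float(s) for s in cv_scores],
        classes=[str(c) for c in model.classes_],
        class_repartition=repartition,
        cup=cup,
        cup_by_condition=cup_by_condition,
        chi2_by_condition=chi2_by_condition,
        n_train=len(tr),
        n_test=len(te),
        seed=seed,
        hyperparameters={
            "n_estimators": n_estimators,
            "max_features": "sqrt",
            "train_frac": train_frac,
            "n_folds": n_folds,
            "group_by_recording": group_by_recording,
        },
    )
    return model, report
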