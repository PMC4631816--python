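"""Time-resolved 3-class decoding with a categorical vs. random-class null.

Sensor signals are averaged in 20-ms windows slid by 10 ms over −100…500
ms; each window's trials x channels matrix feeds a linear SVM (one
weight vector plus bias per class, prediction = argmax of the class
scores), evaluated by stratified 10-fold cross-validation. Under the
*categorical* scheme the three classes are the true body-part categories
(object trials are excluded); under the *random* scheme the 12 body
images are partitioned into three balanced classes that deliberately mix
categories, providing a null that preserves image identity but destroys
category structure.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import LinearSVC

from .simulate import BODY_CATEGORIES, EpochSet, StimulusSet

CHANCE = 1.0 / 3.0
FEATURE_RANGE = (-100.0, 500.0)  # ms
FEATURE_WIN = 20.0
FEATURE_STEP = 10.0


@dataclass(frozen=True)
class FeatureSet:
    """Per-window trials x channels matrices of 20-ms mean amplitudes."""

    features: np.ndarray  # (windows, trials, channels)
    window_starts: np.ndarray  # ms
    window_ms: float
    image_id: np.ndarray
    category: np.ndarray

    @property
    def n_windows(self) -> int:
        return self.features.shape[0]

    @property
    def window_centers(self) -> np.ndarray:
        return self.window_starts + self.window_ms / 2.0


@dataclass(frozen=True)
class LabelScheme:
    """Mapping image_id -> class in {0, 1, 2} for the 12 body images."""

    scheme: str  # "categorical" | "random"
    mapping: dict[int, int]
    class_names: tuple[str, ...]

    def labels_for(self, image_ids: np.ndarray) -> np.ndarray:
        return np.asarray([self.mapping.get(int(i), -1) for i in image_ids])


@dataclass(frozen=True)
class Classifier:
    """Per-class linear discriminants: score_k = w_k · x + b_k, predict argmax."""

    weights: np.ndarray  # (classes, features)
    biases: np.ndarray  # (classes,)
    classes: np.ndarray

    def scores(self, x: np.ndarray) -> np.ndarray:
        return x @ self.weights.T + self.biases

    def predict(self, x: np.ndarray) -> np.ndarray:
        return self.classes[np.argmax(self.scores(x), axis=1)]


@dataclass
class SchemeResult:
    """Cross-validated accuracy per window for one subject and scheme."""

    scheme: str
    accuracy: np.ndarray  # (windows,)
    n_correct: np.ndarray  # (windows,) summed over folds (and partitions)
    n_trials: int  # per partition
    window_centers: np.ndarray
    n_partitions: int = 1


@dataclass
class DecodingResult:
    """Cohort-level summary: accuracies, CIs, binomial and paired-t p-values."""

    window_centers: np.ndarray
    categorical_acc: np.ndarray  # (subjects, windows)
    random_acc: np.ndarray  # (subjects, windows)
    categorical_mean: np.ndarray = field(init=False)
    random_mean: np.ndarray = field(init=False)
    categorical_ci: np.ndarray | None = None  # (2, windows)
    random_ci: np.ndarray | None = None
    binom_p_categorical: np.ndarray | None = None
    binom_p_random: np.ndarray | None = None
    paired_p: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.categorical_mean = self.categorical_acc.mean(axis=0)
        self.random_mean = self.random_acc.mean(axis=0)


def extract_features(
    epochs: EpochSet,
    win_ms: float = FEATURE_WIN,
    step_ms: float = FEATURE_STEP,
    trange: tuple[float, float] = FEATURE_RANGE,
) -> FeatureSet:
    """Sliding-window mean amplitudes: windows [t, t+win) from trange[0] by step.

    Default 20-ms windows slid by 10 ms over −100…500 ms: 59 windows.
    """
    if win_ms <= 0 or step_ms <= 0:
        raise ValueError("window and step must be positive")
    t0, t1 = trange
    if t0 < epochs.times[0] or t1 > epochs.times[-1] + 1000.0 / epochs.sfreq:
        raise ValueError(f"feature range {trange} outside the epoch time axis")
    starts = np.arange(t0, t1 - win_ms + 0.5 * step_ms, step_ms)
    feats = np.empty((len(starts), epochs.n_trials, epochs.n_channels))
    for i, s in enumerate(starts):
        mask = epochs.time_mask(s, s + win_ms)
        feats[i] = epochs.data[:, :, mask].mean(axis=-1)
    return FeatureSet(
        features=feats,
        window_starts=starts,
        window_ms=win_ms,
        image_id=epochs.image_id.copy(),
        category=epochs.category.copy(),
    )


def make_labels(stimuli: StimulusSet, scheme: str = "categorical",
                seed: int = 0) -> LabelScheme:
    """Build the categorical or a seeded random class assignment.

    The random scheme draws balanced partitions (4 images per class) of
    the 12 body images, rejection-resampled until no class consists of
    images of a single category.
    """
    body = np.isin(stimuli.category, BODY_CATEGORIES)
    ids = stimuli.image_ids[body]
    cats = stimuli.category[body]
    if len(ids) != 12:
        raise ValueError(f"expected 12 body images, got {len(ids)}")
    if scheme == "categorical":
        mapping = {
            int(i): BODY_CATEGORIES.index(c) for i, c in zip(ids, cats)
        }
        return LabelScheme("categorical", mapping, BODY_CATEGORIES)
    if scheme != "random":
        raise ValueError(f"unknown scheme {scheme!r}")
    rng = np.random.default_rng(seed)
    cat_of = dict(zip(ids.tolist(), cats.tolist()))
    while True:
        perm = rng.permutation(ids)
        classes = [perm[0:4], perm[4:8], perm[8:12]]
        if all(len({cat_of[int(i)] for i in cl}) >= 2 for cl in classes):
            break
    mapping = {int(i): k for k, cl in enumerate(classes) for i in cl}
    return LabelScheme("random", mapping, ("r0", "r1", "r2"))


def train_classifier(x: np.ndarray, y: np.ndarray, c: float = 1.0) -> Classifier:
    """One-vs-rest linear max-margin classifier (hinge loss, penalty ``c``)."""
    classes = np.unique(y)
    if len(classes) < 2:
        raise ValueError("training data must contain at least two classes")
    svc = LinearSVC(C=c, loss="squared_hinge", dual=False, random_state=0,
                    max_iter=5000)
    svc.fit(x, y)
    if len(classes) == 2:
        w = np.vstack([-svc.coef_, svc.coef_])
        b = np.array([-svc.intercept_[0], svc.intercept_[0]])
    else:
        w = svc.coef_.copy()
        b = svc.intercept_.copy()
    return Classifier(weights=w, biases=b, classes=svc.classes_.copy())


def crossval_decode(
    featureset: FeatureSet,
    labelscheme: LabelScheme,
    k: int = 10,
    seed: int = 0,
    c: float = 1.0,
) -> SchemeResult:
    """Stratified k-fold decoding accuracy per sliding window.

    Features are z-scored per window using training-fold statistics only.
    Trials without a label under the scheme (object trials) are excluded.
    """
    y_all = labelscheme.labels_for(featureset.image_id)
    keep = y_all >= 0
    y = y_all[keep]
    if len(y) < k:
        raise ValueError(f"need at least k={k} labelled trials")
    feats = featureset.features[:, keep, :]
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    folds = list(skf.split(np.zeros(len(y)), y))
    n_win = featureset.n_windows
    n_correct = np.zeros(n_win, dtype=int)
    acc = np.zeros(n_win)
    for w in range(n_win):
        xw = feats[w]
        fold_acc = []
        for tr, te in folds:
            mu = xw[tr].mean(axis=0)
            sd = xw[tr].std(axis=0)
            sd[sd == 0] = 1.0
            clf = train_classifier((xw[tr] - mu) / sd, y[tr], c=c)
            pred = clf.predict((xw[te] - mu) / sd)
            n_ok = int((pred == y[te]).sum())
            n_correct[w] += n_ok
            fold_acc.append(n_ok / len(te))
        acc[w] = float(np.mean(fold_acc))
    return SchemeResult(
        scheme=labelscheme.scheme,
        accuracy=acc,
        n_correct=n_correct,
        n_trials=len(y),
        window_centers=featureset.window_centers.copy(),
    )


def decode_subject(
    epochs: EpochSet,
    scheme: str = "categorical",
    stimuli: StimulusSet | None = None,
    n_partitions: int = 20,
    k: int = 10,
    seed: int = 0,
    c: float = 1.0,
    featureset: FeatureSet | None = None,
) -> SchemeResult:
    """Decode one subject under one scheme.

    The random scheme is averaged over ``n_partitions`` independent seeded
    partitions of the images into classes.
    """
    if stimuli is None:
        stimuli = StimulusSet.default()
    if featureset is None:
        featureset = extract_features(epochs)
    if scheme == "categorical":
        labels = make_labels(stimuli, "categorical")
        return crossval_decode(featureset, labels, k=k, seed=seed, c=c)
    if scheme != "random":
        raise ValueError(f"unknown scheme {scheme!r}")
    part_seeds = np.random.SeedSequence(seed).generate_state(n_partitions) % (2**31)
    accs, ncs = [], []
    n_trials = 0
    for ps in part_seeds:
        labels = make_labels(stimuli, "random", seed=int(ps))
        res = crossval_decode(featureset, labels, k=k, seed=seed, c=c)
        accs.append(res.accuracy)
        ncs.append(res.n_correct)
        n_trials = res.n_trials
    return SchemeResult(
        scheme="random",
        accuracy=np.mean(accs, axis=0),
        n_correct=np.sum(ncs, axis=0),
        n_trials=n_trials,
        window_centers=featureset.window_centers.copy(),
        n_partitions=n_partitions,
    )


def _binom_p(n_correct: np.ndarray, n_total: int) -> np.ndarray:
    return np.array(
        [stats.binomtest(int(k), n_total, CHANCE).pvalue for k in n_correct]
    )


def _mean_ci(acc: np.ndarray, level: float = 0.95) -> np.ndarray:
    """t-based CI of the across-subject mean accuracy per window."""
    n = acc.shape[0]
    m = acc.mean(axis=0)
    if n < 2:
        return np.vstack([m, m])
    se = acc.std(axis=0, ddof=1) / np.sqrt(n)
    q = stats.t.ppf(0.5 + level / 2.0, n - 1)
    return np.vstack([m - q * se, m + q * se])


def test_significance(
    categorical: list[SchemeResult], random: list[SchemeResult]
) -> DecodingResult:
    """Cohort significance: pooled binomial tests vs chance and paired t-test.

    Per window, correct counts are pooled over subjects (and, for the
    random scheme, partitions) for a two-sided binomial test against 1/3;
    the categorical-vs-random comparison is a two-sided paired t-test of
    per-subject accuracies.
    """
    if len(categorical) < 2 or len(categorical) != len(random):
        raise ValueError("need matched results for at least two subjects")
    centers = categorical[0].window_centers
    cat_acc = np.vstack([r.accuracy for r in categorical])
    rnd_acc = np.vstack([r.accuracy for r in random])

    cat_counts = np.sum([r.n_correct for r in categorical], axis=0)
    cat_total = sum(r.n_trials for r in categorical)
    rnd_counts = np.sum([r.n_correct for r in random], axis=0)
    rnd_total = sum(r.n_trials * r.n_partitions for r in random)

    with np.errstate(invalid="ignore"):
        tt = stats.ttest_rel(cat_acc, rnd_acc, axis=0)
    paired_p = np.where(np.isnan(tt.pvalue), 1.0, tt.pvalue)

    return DecodingResult(
        window_centers=centers,
        categorical_acc=cat_acc,
        random_acc=rnd_acc,
        categorical_ci=_mean_ci(cat_acc),
        random_ci=_mean_ci(rnd_acc),
        binom_p_categorical=_binom_p(cat_counts, cat_total),
        binom_p_random=_binom_p(rnd_counts, rnd_total),
        paired_p=paired_p,
    )
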