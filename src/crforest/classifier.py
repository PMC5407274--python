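"""Repeat/random classification: first-order Markov negatives, random-forest
training, and evaluation.

The positive class is a set of known (or synthetic) CRISPR repeat
sequences; the negative class is sampled from a first-order Markov chain
fitted to the positives, so negatives share base and dinucleotide
composition but lose the palindromic stem signal.  A 500-tree random
forest with 5 features tried per split separates the two classes on the
32 triplet elements; a candidate is called "repeat" when at least half of
the trees vote for it.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import joblib
import numpy as np
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import roc_auc_score

from .repeat_scan import CandidateArray
from .structure_features import FEATURE_NAMES, N_FEATURES, featurize_batch

_NT = "ACGT"
_NT_INDEX = {c: i for i, c in enumerate(_NT)}

LABEL_REPEAT = "repeat"
LABEL_RANDOM = "random"

MODEL_FORMAT_VERSION = 1


@dataclass
class MarkovModel:
    """First-order nucleotide chain over A, C, G, T plus the empirical
    length pool of its training sequences."""

    initial: np.ndarray          # shape (4,)
    transition: np.ndarray       # shape (4, 4), row-stochastic
    length_pool: list[int]

    def __post_init__(self) -> None:
        self.initial = np.asarray(self.initial, dtype=float)
        self.transition = np.asarray(self.transition, dtype=float)
        if self.initial.shape != (4,) or self.transition.shape != (4, 4):
            raise ValueError("MarkovModel needs a 4-vector and a 4x4 matrix")
        if np.any(self.initial < 0) or np.any(self.transition < 0):
            raise ValueError("negative probabilities")
        if abs(self.initial.sum() - 1) > 1e-9 or \
                np.any(np.abs(self.transition.sum(axis=1) - 1) > 1e-9):
            raise ValueError("probabilities must sum to 1")


def fit_markov(positives: list[str]) -> MarkovModel:
    """Fit initial and transition frequencies from adjacent nucleotide
    pairs; positions involving N are skipped; an all-zero transition row
    receives add-one smoothing so sampling can never deadlock."""
    if not positives:
        raise ValueError("cannot fit a Markov model on an empty set")
    init = np.zeros(4)
    trans = np.zeros((4, 4))
    lengths = []
    for seq in positives:
        if len(seq) < 2:
            raise ValueError("training sequences must have length >= 2")
        lengths.append(len(seq))
        if seq[0] in _NT_INDEX:
            init[_NT_INDEX[seq[0]]] += 1
        for a, b in zip(seq, seq[1:]):
            if a in _NT_INDEX and b in _NT_INDEX:
                trans[_NT_INDEX[a], _NT_INDEX[b]] += 1
    if init.sum() == 0:
        init[:] = 1.0
    for r in range(4):
        if trans[r].sum() == 0:
            trans[r] = 1.0  # add-one smoothing on empty rows
    return MarkovModel(initial=init / init.sum(),
                       transition=trans / trans.sum(axis=1, keepdims=True),
                       length_pool=lengths)


def sample_negatives(model: MarkovModel, n: int, rng_seed: int) -> list[str]:
    """Draw *n* chain realizations; each length is sampled uniformly from
    the model's length pool. Reproducible under rng_seed."""
    if n < 0:
        raise ValueError("n must be >= 0")
    rng = np.random.default_rng(rng_seed)
    pool = np.asarray(model.length_pool)
    out = []
    for _ in range(n):
        length = int(pool[rng.integers(len(pool))])
        state = int(rng.choice(4, p=model.initial))
        chars = [_NT[state]]
        for _ in range(length - 1):
            state = int(rng.choice(4, p=model.transition[state]))
            chars.append(_NT[state])
        out.append("".join(chars))
    return out


@dataclass(frozen=True)
class TrainConfig:
    ntree: int = 500
    mtry: int = 5
    vote_threshold: float = 0.5
    train_fraction: float = 0.8
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.train_fraction < 1:
            raise ValueError("train_fraction must be in (0, 1)")
        if not 1 <= self.mtry <= N_FEATURES:
            raise ValueError(f"mtry must be in [1, {N_FEATURES}]")
        if self.ntree < 1:
            raise ValueError("ntree must be >= 1")


def split_dataset(pos: list, neg: list, config: TrainConfig = TrainConfig()
                  ) -> tuple[list[tuple[object, str]], list[tuple[object, str]]]:
    """Per-class shuffled 80/20 (by default) split.

    Each class is shuffled and split independently: the test partition
    takes floor((1 - train_fraction) * N) items, the training partition
    the remainder.  Returns (train, test) lists of (item, label) pairs.
    """
    rng = np.random.default_rng(config.rng_seed)
    train: list[tuple[object, str]] = []
    test: list[tuple[object, str]] = []
    for items, label in ((pos, LABEL_REPEAT), (neg, LABEL_RANDOM)):
        if len(items) < 2:
            raise ValueError(f"class {label!r} needs at least 2 examples")
        order = rng.permutation(len(items))
        # epsilon guards the floor against float artifacts (0.2*12000)
        n_test = int((1 - config.train_fraction) * len(items) + 1e-9)
        test_idx = set(order[:n_test].tolist())
        train.extend((items[i], label) for i in order[n_test:])
        test.extend((items[i], label) for i in order[:n_test])
    return train, test


@dataclass
class ClassifierModel:
    """A trained ensemble with its canonical feature order, training
    configuration and provenance (class sizes, folding engine)."""

    ensemble: RandomForestClassifier
    feature_order: tuple[str, ...]
    config: TrainConfig
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.feature_order) != N_FEATURES:
            raise ValueError("feature_order must name all 32 features")

    def _check_width(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != N_FEATURES:
            raise ValueError(
                f"expected {N_FEATURES} features, got {X.shape[1]}")
        return X

    def votes(self, X: np.ndarray) -> np.ndarray:
        """Fraction of trees voting 'repeat' for each row."""
        X = self._check_width(X)
        classes = self.ensemble.classes_
        tally = np.zeros(len(X))
        for tree in self.ensemble.estimators_:
            pred = classes[tree.predict(X).astype(int)]
            tally += pred == LABEL_REPEAT
        return tally / len(self.ensemble.estimators_)


def train_classifier(train: list[tuple[np.ndarray, str]],
                     config: TrainConfig = TrainConfig(),
                     provenance: dict | None = None) -> ClassifierModel:
    """Fit the seeded bootstrap ensemble on labeled 32-wide vectors."""
    X = np.vstack([np.asarray(v, dtype=float) for v, _ in train])
    y = np.array([label for _, label in train])
    if X.shape[1] != N_FEATURES:
        raise ValueError(f"expected {N_FEATURES} features, got {X.shape[1]}")
    if len(set(y)) < 2:
        raise ValueError("training set must contain both classes")
    forest = RandomForestClassifier(
        n_estimators=config.ntree,
        max_features=config.mtry,
        bootstrap=True,
        random_state=config.rng_seed % (2 ** 31),
    )
    forest.fit(X, y)
    prov = {"n_repeat": int((y == LABEL_REPEAT).sum()),
            "n_random": int((y == LABEL_RANDOM).sum())}
    prov.update(provenance or {})
    return ClassifierModel(ensemble=forest, feature_order=FEATURE_NAMES,
                           config=config, provenance=prov)


def classify_repeat(model: ClassifierModel,
                    features: np.ndarray) -> tuple[str, float]:
    """Label one feature vector; 'repeat' iff the tree-vote fraction
    reaches the vote threshold (ties go to 'repeat')."""
    vote = float(model.votes(features)[0])
    label = LABEL_REPEAT if vote >= model.config.vote_threshold \
        else LABEL_RANDOM
    return label, vote


@dataclass(frozen=True)
class EvalMetrics:
    accuracy: float
    sensitivity: float
    specificity: float
    precision: float
    auc: float

    def __post_init__(self) -> None:
        for name, v in dataclasses.asdict(self).items():
            if not 0 <= v <= 1:
                raise ValueError(f"{name} outside [0, 1]")


def evaluate(model: ClassifierModel,
             test: list[tuple[np.ndarray, str]]) -> EvalMetrics:
    """Confusion-matrix metrics at the vote threshold plus tie-corrected
    rank-statistic AUC over the vote scores."""
    y = np.array([label for _, label in test])
    if len(set(y)) < 2:
        raise ValueError("test set must contain both classes")
    X = np.vstack([np.asarray(v, dtype=float) for v, _ in test])
    votes = model.votes(X)
    pred = np.where(votes >= model.config.vote_threshold,
                    LABEL_REPEAT, LABEL_RANDOM)
    is_pos = y == LABEL_REPEAT
    tp = int(np.sum((pred == LABEL_REPEAT) & is_pos))
    tn = int(np.sum((pred == LABEL_RANDOM) & ~is_pos))
    fp = int(np.sum((pred == LABEL_REPEAT) & ~is_pos))
    fn = int(np.sum((pred == LABEL_RANDOM) & is_pos))
    return EvalMetrics(
        accuracy=(tp + tn) / len(y),
        sensitivity=tp / (tp + fn),
        specificity=tn / (tn + fp),
        precision=tp / (tp + fp) if tp + fp else 0.0,
        auc=float(roc_auc_score(is_pos, votes)),
    )


def classify_candidate(model: ClassifierModel, candidate: CandidateArray,
                       mode: str = "consensus") -> tuple[str, float]:
    """Label a candidate array by its repeat sequence.

    mode 'consensus' classifies the consensus repeat; 'majority'
    classifies every repeat instance and calls 'repeat' when more than
    half of the instances are labeled repeat (vote = mean tree vote).
    """
    if mode not in ("consensus", "majority"):
        raise ValueError(f"unknown classify mode {mode!r}")
    if len(candidate.consensus_repeat) < 3:
        raise ValueError("consensus repeat shorter than 3 nt; "
                         "array rejected (cannot featurize)")
    engine = model.provenance.get("folding_engine", "auto")
    if mode == "consensus":
        feats = featurize_batch([candidate.consensus_repeat], engine=engine)
        return classify_repeat(model, feats[0])
    feats = featurize_batch(candidate.repeat_seqs, engine=engine)
    votes = model.votes(feats)
    labels = votes >= model.config.vote_threshold
    label = LABEL_REPEAT if labels.mean() > 0.5 else LABEL_RANDOM
    return label, float(votes.mean())


# ---------------------------------------------------------------------------
# end-to-end training + persistence

def train_pipeline(positives: list[str], negatives: list[str] | None = None,
                   config: TrainConfig = TrainConfig(),
                   negative_ratio: float = 1.05,
                   engine: str = "auto",
                   ) -> tuple[ClassifierModel, EvalMetrics, dict]:
    """Deduplicate positives, build (or accept) negatives, featurize,
    split per class, train and evaluate.  Returns model, held-out metrics
    and a summary dict with the partition sizes."""
    pos = list(dict.fromkeys(positives))  # exact-string deduplication
    if negatives is None:
        markov = fit_markov(pos)
        negatives = sample_negatives(markov, round(negative_ratio * len(pos)),
                                     rng_seed=config.rng_seed + 1)
    train_seqs, test_seqs = split_dataset(pos, negatives, config)
    feats = {s: f for s, f in zip(
        [s for s, _ in train_seqs + test_seqs],
        featurize_batch([s for s, _ in train_seqs + test_seqs],
                        engine=engine))}
    train = [(feats[s], lab) for s, lab in train_seqs]
    test = [(feats[s], lab) for s, lab in test_seqs]
    from .structure_features import default_engine
    model = train_classifier(
        train, config,
        provenance={"folding_engine": engine if engine != "auto"
                    else default_engine(),
                    "n_positive_input": len(pos),
                    "n_negative_input": len(negatives)})
    metrics = evaluate(model, test)
    summary = {"n_train": len(train), "n_test": len(test),
               "n_train_repeat": sum(l == LABEL_REPEAT for _, l in train),
               "n_train_random": sum(l == LABEL_RANDOM for _, l in train),
               "n_test_repeat": sum(l == LABEL_REPEAT for _, l in test),
               "n_test_random": sum(l == LABEL_RANDOM for _, l in test)}
    return model, metrics, summary


def save_model(model: ClassifierModel, path: str) -> None:
    joblib.dump({"format_version": MODEL_FORMAT_VERSION,
                 "feature_order": list(model.feature_order),
                 "config": dataclasses.asdict(model.config),
                 "provenance": model.provenance,
                 "ensemble": model.ensemble}, path)


def load_model(path: str) -> ClassifierModel:
    blob = joblib.load(path)
    if blob.get("format_version") != MODEL_FORMAT_VERSION:
        raise ValueError("unsupported model format version")
    if tuple(blob["feature_order"]) != FEATURE_NAMES:
        raise ValueError("model feature order does not match this build; "
                         "refusing to classify")
    return ClassifierModel(ensemble=blob["ensemble"],
                           feature_order=tuple(blob["feature_order"]),
                           config=TrainConfig(**blob["config"]),
                           provenance=blob["provenance"])
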