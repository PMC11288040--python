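"""Hierarchical voting ensemble for ROSes classification.

Level 0 decides ROSes vs non-ROSes by *hard voting* over three component
models, each seeing its own view of the sequence:

* a gradient-boosted tree model (XGBoost) on 3-mer counts;
* a convolutional model — one convolution layer over the L x 20 one-hot
  encoding whose filters are one-hot patches sampled from the training
  sequences, global max/mean pooling, and a trained dense head;
* a feed-forward network (two hidden layers) on residue composition plus
  length.

A sequence is called ROSes when two or more component models vote positive
(probability >= 0.5); three positive votes give "high" confidence, exactly
two give "medium".  Level 1 assigns one of the 26 ROSes categories by
*soft voting*: the unweighted mean of the three models' class-probability
vectors, argmax with lexicographic tie-break on the category name.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from pathlib import Path
from typing import Sequence

import joblib
import numpy as np
import pandas as pd
from sklearn.neural_network import MLPClassifier
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from xgboost import XGBClassifier

from .config import (
    AA_INDEX,
    ALPHABET,
    DEFAULT_CATEGORIES,
    N_AA,
    encode_sequence,
    validate_sequence,
)

ROSES = "ROSes"
NON_ROSES = "non-ROSes"
VOTE_THRESHOLD = 0.5


# ---------------------------------------------------------------------------
# feature views
# ---------------------------------------------------------------------------


@dataclasses.dataclass
class FeatureViews:
    """The three per-sequence encodings consumed by the component models."""

    kmer_counts: np.ndarray  # (kmer_dim,)
    onehot_windows: np.ndarray  # (L, 20), rows one-hot
    composition: np.ndarray  # (20,), sums to 1
    length: int


def featurize(sequence: str, k: int = 3, kmer_dim: int = 8000) -> FeatureViews:
    """Deterministic feature views of one sequence.

    k-mer counts live in a fixed ``kmer_dim``-dimensional space (bucket =
    base-20 k-mer index mod kmer_dim; the default 8000 = 20**3 is the full
    3-mer space, so hashing only kicks in for smaller dims).
    """
    validate_sequence(sequence)
    if len(sequence) < k:
        raise ValueError(f"sequence length {len(sequence)} shorter than k={k}")
    idx = encode_sequence(sequence)
    L = len(idx)
    # hashed k-mer counts
    powers = N_AA ** np.arange(k)
    kmer_index = np.zeros(L - k + 1, dtype=np.int64)
    for j in range(k):
        kmer_index += idx[j:L - k + 1 + j] * powers[j]
    counts = np.bincount(kmer_index % kmer_dim, minlength=kmer_dim).astype(np.float64)
    # one-hot
    onehot = np.zeros((L, N_AA))
    onehot[np.arange(L), idx] = 1.0
    comp = np.bincount(idx, minlength=N_AA) / L
    return FeatureViews(counts, onehot, comp, L)


@dataclasses.dataclass
class EnsembleConfig:
    seed: int = 0
    k: int = 3
    kmer_dim: int = 8000  # 20**3: the full 3-mer space (hashing only if smaller)
    n_filters: int = 512
    filter_width: int = 8
    xgb_estimators: int = 150
    xgb_depth: int = 4
    mlp_hidden: tuple[int, int] = (64, 32)


# ---------------------------------------------------------------------------
# component models
# ---------------------------------------------------------------------------


class _SingleClassModel:
    """Degenerate fallback when training data contain a single class."""

    def __init__(self, cls: int, n_classes: int):
        self.cls = cls
        self.n_classes = n_classes

    def predict_proba(self, X):
        out = np.zeros((len(X), self.n_classes))
        out[:, self.cls] = 1.0
        return out


class _ComponentModel:
    """Shared fit/predict plumbing: featurize, train, emit class probabilities."""

    def __init__(self, config: EnsembleConfig):
        self.config = config
        self.model = None
        self.classes_: np.ndarray | None = None

    def _encode(self, sequences: Sequence[str]) -> np.ndarray:
        raise NotImplementedError

    def _make_estimator(self):
        raise NotImplementedError

    def fit(self, sequences: Sequence[str], y: np.ndarray) -> "_ComponentModel":
        X = self._encode(sequences)
        classes = np.unique(y)
        self.classes_ = classes
        if len(classes) == 1:
            self.model = _SingleClassModel(0, 1)
            return self
        self.model = self._make_estimator()
        self.model.fit(X, np.searchsorted(classes, y))
        return self

    def predict_proba(self, sequences: Sequence[str]) -> np.ndarray:
        """(n, n_present_classes) probabilities in self.classes_ order."""
        if self.model is None:
            raise RuntimeError("model is not fitted")
        X = self._encode(sequences)
        return self.model.predict_proba(X)


class KmerBoostModel(_ComponentModel):
    """Gradient-boosted trees on hashed k-mer counts."""

    name = "tree"

    def _encode(self, sequences):
        cfg = self.config
        return np.stack([
            featurize(s, cfg.k, cfg.kmer_dim).kmer_counts for s in sequences
        ])

    def _make_estimator(self):
        cfg = self.config
        return XGBClassifier(
            n_estimators=cfg.xgb_estimators,
            max_depth=cfg.xgb_depth,
            learning_rate=0.3,
            tree_method="hist",
            n_jobs=1,
            random_state=cfg.seed,
            verbosity=0,
        )


class ConvPoolModel(_ComponentModel):
    """One convolution layer + global max/mean pooling + dense head.

    The convolution filters are one-hot encodings of sequence windows
    sampled (seeded) from the training set — a patch-dictionary
    convolution, so each filter's max-pooled activation is the best local
    match of its source window anywhere in the input.  Only the dense head
    is trained by gradient descent.  Sequences shorter than the receptive
    field are right-padded with neutral zero rows.
    """

    name = "conv"

    def __init__(self, config: EnsembleConfig):
        super().__init__(config)
        self.filters: np.ndarray | None = None

    def _sample_filters(self, sequences: Sequence[str]) -> np.ndarray:
        cfg = self.config
        w = cfg.filter_width
        rng = np.random.default_rng(cfg.seed + 101)
        donors = [s for s in sequences if len(s) >= w] or list(sequences)
        filters = np.zeros((cfg.n_filters, w * N_AA))
        for f in range(cfg.n_filters):
            s = donors[int(rng.integers(0, len(donors)))]
            start = int(rng.integers(0, max(len(s) - w, 0) + 1))
            patch = s[start:start + w]
            for j, ch in enumerate(patch):
                filters[f, j * N_AA + AA_INDEX[ch]] = 1.0
        return filters

    def _pool(self, onehot: np.ndarray) -> np.ndarray:
        w = self.config.filter_width
        if onehot.shape[0] < w:
            pad = np.zeros((w - onehot.shape[0], N_AA))
            onehot = np.vstack([onehot, pad])
        windows = np.lib.stride_tricks.sliding_window_view(onehot, (w, N_AA))
        flat = windows.reshape(windows.shape[0], -1)
        act = flat @ self.filters.T
        return np.concatenate([act.max(axis=0), act.mean(axis=0)])

    def fit(self, sequences: Sequence[str], y: np.ndarray) -> "_ComponentModel":
        self.filters = self._sample_filters(sequences)
        return super().fit(sequences, y)

    def _encode(self, sequences):
        if self.filters is None:
            raise RuntimeError("conv filters not initialised; call fit first")
        cfg = self.config
        return np.stack([
            self._pool(featurize(s, cfg.k, cfg.kmer_dim).onehot_windows)
            for s in sequences
        ])

    def _make_estimator(self):
        cfg = self.config
        return MLPClassifier(hidden_layer_sizes=(64,), max_iter=800,
                             random_state=cfg.seed)


class CompositionDenseModel(_ComponentModel):
    """Two-hidden-layer feed-forward network on composition + length."""

    name = "dense"

    def _encode(self, sequences):
        cfg = self.config
        rows = []
        for s in sequences:
            fv = featurize(s, cfg.k, cfg.kmer_dim)
            rows.append(np.append(fv.composition, fv.length / 100.0))
        return np.stack(rows)

    def _make_estimator(self):
        cfg = self.config
        return make_pipeline(
            StandardScaler(),
            MLPClassifier(
                hidden_layer_sizes=cfg.mlp_hidden,
                max_iter=2000,
                random_state=cfg.seed,
            ),
        )


def _make_components(config: EnsembleConfig) -> list[_ComponentModel]:
    return [KmerBoostModel(config), ConvPoolModel(config), CompositionDenseModel(config)]


COMPONENT_NAMES = ("tree", "conv", "dense")


# ---------------------------------------------------------------------------
# voting
# ---------------------------------------------------------------------------


@dataclasses.dataclass
class VoteResult:
    """Level-0 hard-vote outcome."""

    component_votes: tuple[bool, bool, bool]
    label: str
    confidence: str  # high | medium | none


def hard_vote(component_votes: Sequence[bool]) -> VoteResult:
    """Majority rule: >= 2 positive votes -> ROSes; 3 -> high, 2 -> medium."""
    votes = tuple(bool(v) for v in component_votes)
    if len(votes) != 3:
        raise ValueError("hard_vote requires exactly three component votes")
    n = sum(votes)
    if n == 3:
        return VoteResult(votes, ROSES, "high")
    if n == 2:
        return VoteResult(votes, ROSES, "medium")
    return VoteResult(votes, NON_ROSES, "none")


@dataclasses.dataclass
class CategoryPrediction:
    """Level-1 soft-vote outcome over the 26-category label space."""

    per_model_probs: np.ndarray  # (3, n_categories)
    mean_probs: np.ndarray
    label: str


def soft_vote(per_model_probs: np.ndarray, categories: Sequence[str]) -> CategoryPrediction:
    """Unweighted mean of the three probability rows, argmax with
    lexicographic tie-break on the category name."""
    probs = np.asarray(per_model_probs, dtype=float)
    if probs.shape != (3, len(categories)):
        raise ValueError(f"expected a 3 x {len(categories)} matrix, got {probs.shape}")
    sums = probs.sum(axis=1)
    if np.any(np.abs(sums - 1.0) > 1e-6):
        bad = int(np.argmax(np.abs(sums - 1.0)))
        raise ValueError(f"probability row {bad} sums to {sums[bad]!r}, not 1")
    mean = probs.mean(axis=0)
    best = mean.max()
    tied = [categories[i] for i in np.flatnonzero(mean == best)]
    return CategoryPrediction(probs, mean, min(tied))


# ---------------------------------------------------------------------------
# level-0 / level-1 ensembles
# ---------------------------------------------------------------------------


class Level0Ensemble:
    """Three binary component models + hard voting."""

    def __init__(self, components: list[_ComponentModel], config: EnsembleConfig):
        self.components = components
        self.config = config

    def component_probas(self, sequences: Sequence[str]) -> np.ndarray:
        """(3, n) positive-class probabilities."""
        out = []
        for comp in self.components:
            probs = comp.predict_proba(sequences)
            if probs.shape[1] == 1:
                pos = np.full(len(sequences), float(comp.classes_[0] == 1))
            else:
                pos = probs[:, list(comp.classes_).index(1)]
            out.append(pos)
        return np.stack(out)

    def votes(self, sequences: Sequence[str]) -> np.ndarray:
        """(n, 3) boolean component votes at the 0.5 threshold."""
        return (self.component_probas(sequences) >= VOTE_THRESHOLD).T

    def positive_proba(self, sequences: Sequence[str]) -> np.ndarray:
        """Soft level-0 score: mean of the three positive probabilities."""
        return self.component_probas(sequences).mean(axis=0)

    def predict(self, sequences: Sequence[str]) -> list[VoteResult]:
        return [hard_vote(v) for v in self.votes(sequences)]


class Level1Ensemble:
    """Three multiclass component models + soft voting over 26 categories."""

    def __init__(self, components: list[_ComponentModel], config: EnsembleConfig,
                 categories: Sequence[str]):
        self.components = components
        self.config = config
        self.categories = list(categories)
        self.present: np.ndarray | None = None  # indices of trained categories

    def per_model_probs(self, sequences: Sequence[str]) -> np.ndarray:
        """(n, 3, n_categories); absent categories get zero columns."""
        n_cat = len(self.categories)
        out = np.zeros((len(sequences), 3, n_cat))
        for m, comp in enumerate(self.components):
            probs = comp.predict_proba(sequences)
            for j, cls in enumerate(comp.classes_):
                out[:, m, self.present[cls]] = probs[:, j]
        return out

    def predict(self, sequences: Sequence[str]) -> list[CategoryPrediction]:
        return [soft_vote(p, self.categories) for p in self.per_model_probs(sequences)]


def train_level0(
    pos_sequences: Sequence[str],
    neg_sequences: Sequence[str],
    config: EnsembleConfig | None = None,
) -> Level0Ensemble:
    """Fit the three level-0 component models on positives vs background."""
    config = config or EnsembleConfig()
    if not pos_sequences or not neg_sequences:
        raise ValueError("both the positive and negative class must be nonempty")
    sequences = list(pos_sequences) + list(neg_sequences)
    y = np.array([1] * len(pos_sequences) + [0] * len(neg_sequences))
    components = _make_components(config)
    for comp in components:
        comp.fit(sequences, y)
    return Level0Ensemble(components, config)


def train_level1(
    sequences: Sequence[str],
    labels: Sequence[str],
    config: EnsembleConfig | None = None,
    categories: Sequence[str] | None = None,
) -> Level1Ensemble:
    """Fit the three level-1 multiclass models over the 26-name label space."""
    config = config or EnsembleConfig()
    categories = list(categories) if categories is not None else list(DEFAULT_CATEGORIES)
    if len(sequences) != len(labels):
        raise ValueError("sequences and labels must have equal length")
    unknown = set(labels) - set(categories)
    if unknown:
        raise ValueError(f"labels outside the category space: {sorted(unknown)}")
    counts = pd.Series(list(labels)).value_counts()
    singletons = counts[counts < 2]
    if len(counts) > 1 and len(singletons):
        raise ValueError(
            "categories with a single member cannot be trained under "
            f"stratified splitting: {sorted(singletons.index)}"
        )
    cat_index = {c: i for i, c in enumerate(categories)}
    present = sorted({cat_index[l] for l in labels})
    y = np.array([present.index(cat_index[l]) for l in labels])
    components = _make_components(config)
    for comp in components:
        comp.fit(list(sequences), y)
    ens = Level1Ensemble(components, config, categories)
    ens.present = np.array(present)
    return ens


# ---------------------------------------------------------------------------
# end-to-end classification
# ---------------------------------------------------------------------------


def classify(
    records: Sequence[tuple[str, str]],
    level0: Level0Ensemble,
    level1: Level1Ensemble | None = None,
) -> pd.DataFrame:
    """Classify sequences: hard-vote label + confidence, soft-vote category.

    Non-ROSes rows get an empty category (the hierarchy contract).  Records
    with alphabet violations are reported with a warning and skipped (lenient
    mode); the run continues.
    """
    categories = level1.categories if level1 is not None else list(DEFAULT_CATEGORIES)
    prob_cols = [f"p_{i + 1}" for i in range(len(categories))]
    columns = ["id", "vote_tree", "vote_conv", "vote_dense", "label",
               "confidence", "category"] + prob_cols
    valid: list[tuple[str, str]] = []
    for rid, seq in records:
        try:
            validate_sequence(seq, context=f"record {rid!r}")
            if len(seq) < level0.config.k:
                raise ValueError(f"record {rid!r} shorter than k={level0.config.k}")
        except ValueError as exc:
            warnings.warn(str(exc))
            continue
        valid.append((rid, seq))
    if not valid:
        return pd.DataFrame(columns=columns)
    ids = [r for r, _ in valid]
    seqs = [s for _, s in valid]
    votes = level0.votes(seqs)
    vote_results = [hard_vote(v) for v in votes]
    pos_idx = [i for i, vr in enumerate(vote_results) if vr.label == ROSES]
    cat_preds: dict[int, CategoryPrediction] = {}
    if pos_idx and level1 is not None:
        preds = level1.predict([seqs[i] for i in pos_idx])
        cat_preds = dict(zip(pos_idx, preds))
    rows = []
    for i, (rid, vr) in enumerate(zip(ids, vote_results)):
        row = {
            "id": rid,
            "vote_tree": bool(vr.component_votes[0]),
            "vote_conv": bool(vr.component_votes[1]),
            "vote_dense": bool(vr.component_votes[2]),
            "label": vr.label,
            "confidence": vr.confidence,
            "category": "",
        }
        probs = np.zeros(len(categories))
        if i in cat_preds:
            row["category"] = cat_preds[i].label
            probs = cat_preds[i].mean_probs
        row.update({c: p for c, p in zip(prob_cols, probs)})
        rows.append(row)
    return pd.DataFrame(rows, columns=columns)


# ---------------------------------------------------------------------------
# model bundle persistence
# ---------------------------------------------------------------------------


def save_bundle(path: str | Path, level0: Level0Ensemble,
                level1: Level1Ensemble | None = None) -> None:
    """Save a model bundle: JSON manifest + per-model joblib blobs."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    manifest = {
        "format_version": 1,
        "seed": level0.config.seed,
        "config": dataclasses.asdict(level0.config),
        "categories": level1.categories if level1 is not None else None,
        "components": list(COMPONENT_NAMES),
    }
    (path / "manifest.json").write_text(json.dumps(manifest, indent=2))
    joblib.dump(level0, path / "level0.joblib")
    if level1 is not None:
        joblib.dump(level1, path / "level1.joblib")


def load_bundle(path: str | Path) -> tuple[Level0Ensemble, "Level1Ensemble | None"]:
    path = Path(path)
    level0 = joblib.load(path / "level0.joblib")
    level1_path = path / "level1.joblib"
    level1 = joblib.load(level1_path) if level1_path.exists() else None
    return level0, level1
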