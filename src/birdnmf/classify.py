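"""SVM species classification and the cross-validated evaluation harness.

Syllable-level segmental features feed a one-vs-one RBF-kernel SVM trained on
z-score-normalized features, with the kernel hyperparameters (C, gamma)
chosen by an inner 5-fold cross-validated grid search. A recording is labeled
by majority vote over its syllables. Evaluation uses a stratified outer
K-fold (default 6) over recordings in which every learned object — NMF
filter bank, per-class spectral bases, feature normalizer, hyperparameters —
is fitted on the training folds only.
"""

from __future__ import annotations

import hashlib
import json
from collections import Counter
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

from . import features as ft
from . import nmf_core, preprocess, temporal
from .preprocess import AudioSignal, Spectrogram, SyllableSegment
from .synth import SyntheticDataset

DEFAULT_OUTER_FOLDS = 6
DEFAULT_INNER_FOLDS = 5
# LIBSVM-style grid: log2 C in -3..7, log2 gamma in -7..3, steps of 2
DEFAULT_GRID = tuple(
    (2.0**c, 2.0**g) for c in range(-3, 8, 2) for g in range(-7, 4, 2)
)

FRONTEND_NAMES = ("mfcc", "nmf_cc", "h_cc", "mfcc+h_cc", "nmf_cc+h_cc")


@dataclass(frozen=True)
class FrontendConfig:
    """Which short-time front-end to run and with what parameters."""

    name: str = "mfcc"
    deltas: bool = False
    with_gnmf: bool = True
    K_filterbank: int = ft.DEFAULT_N_FILTERS
    K_per_class: int = ft.DEFAULT_K_PER_CLASS
    n_ceps: int = ft.DEFAULT_N_CEPS
    n_ceps_hcc: int = ft.DEFAULT_N_CEPS_HCC
    n_restarts: int = nmf_core.DEFAULT_N_RESTARTS
    max_iter: int = nmf_core.DEFAULT_MAX_ITER
    tol: float = nmf_core.DEFAULT_TOL

    def __post_init__(self) -> None:
        if self.name not in FRONTEND_NAMES:
            raise ValueError(f"unknown front-end {self.name!r}")

    @property
    def uses_nmf_bank(self) -> bool:
        return "nmf_cc" in self.name

    @property
    def uses_mel_bank(self) -> bool:
        return "mfcc" in self.name

    @property
    def uses_hcc(self) -> bool:
        return "h_cc" in self.name


@dataclass
class PreparedRecording:
    """A recording after band-pass, STFT and syllable segmentation."""

    recording_id: str
    spec: Spectrogram
    segments: list[SyllableSegment]
    label: str | None = None


@dataclass
class FrontendArtifacts:
    """Objects learned from training data that the front-end needs."""

    mel_bank: ft.FilterBank | None = None
    nmf_bank: ft.FilterBank | None = None
    sbv_model: ft.SbvModel | None = None

    def checksums(self) -> dict[str, str]:
        out = {}
        if self.nmf_bank is not None:
            out["nmf_bank"] = _array_checksum(self.nmf_bank.filters)
        if self.sbv_model is not None:
            out["sbv_model"] = _array_checksum(self.sbv_model.W_bs)
        return out


@dataclass
class ClassifierModel:
    """z-score normalizer + one-vs-one RBF SVM + class bookkeeping."""

    mean: np.ndarray
    scale: np.ndarray
    svm: SVC
    classes: list[str]
    hyperparams: tuple[float, float]  # (C, gamma)

    def normalize(self, X: np.ndarray) -> np.ndarray:
        return (X - self.mean) / self.scale

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.svm.predict(self.normalize(X))


@dataclass
class EvaluationReport:
    """Cross-validated accuracies and an averaged confusion matrix."""

    classes: list[str]
    per_fold_accuracy: list[float]  # %
    per_species_accuracy: dict[str, float]  # %
    confusion: np.ndarray  # (C, C), column-normalized %, fold-averaged
    overall_accuracy: float  # %
    fold_details: list[dict] = field(default_factory=list)
    config: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "classes": self.classes,
            "per_fold_accuracy": self.per_fold_accuracy,
            "per_species_accuracy": self.per_species_accuracy,
            "confusion": self.confusion.tolist(),
            "overall_accuracy": self.overall_accuracy,
            "fold_details": self.fold_details,
            "config": self.config,
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))

    def confusion_frame(self) -> pd.DataFrame:
        # columns: correct class; rows: hypothesized class
        return pd.DataFrame(self.confusion, index=self.classes, columns=self.classes)


def _array_checksum(arr: np.ndarray) -> str:
    return hashlib.sha256(np.ascontiguousarray(arr).tobytes()).hexdigest()[:16]


def prepare_recording(
    signal: AudioSignal,
    recording_id: str,
    label: str | None = None,
    band: tuple[float, float] = (preprocess.DEFAULT_BAND_LOW_HZ,
                                 preprocess.DEFAULT_BAND_HIGH_HZ),
    window: float = preprocess.DEFAULT_WINDOW_S,
    shift: float = preprocess.DEFAULT_SHIFT_S,
    n_fft: int = preprocess.DEFAULT_N_FFT,
    threshold_db: float = preprocess.DEFAULT_THRESHOLD_DB,
    min_frames: int = preprocess.DEFAULT_MIN_FRAMES,
) -> PreparedRecording:
    """Band-pass, compute the magnitude spectrogram and segment syllables."""
    filtered = preprocess.bandpass(signal, band[0], band[1])
    spec = preprocess.magnitude_spectrogram(filtered, window=window,
                                            shift=shift, n_fft=n_fft)
    segments = preprocess.segment_syllables(spec, threshold_db=threshold_db,
                                            min_frames=min_frames)
    return PreparedRecording(recording_id, spec, segments, label)


def prepare_dataset(dataset: SyntheticDataset, **kwargs) -> list[PreparedRecording]:
    """Prepare every recording of a synthetic dataset."""
    return [
        prepare_recording(sig, f"rec_{i:04d}", label=label, **kwargs)
        for i, (sig, label, _) in enumerate(dataset.recordings)
    ]


def learn_frontend_artifacts(
    train_recs: Sequence[PreparedRecording],
    config: FrontendConfig,
    seed: int | None = None,
) -> FrontendArtifacts:
    """Fit the front-end's learned objects on training recordings only."""
    arts = FrontendArtifacts()
    sample_rate = train_recs[0].spec.sample_rate
    n_fft = 2 * (train_recs[0].spec.n_bins - 1)
    if config.uses_mel_bank:
        arts.mel_bank = ft.mel_filterbank(config.K_filterbank, n_fft, sample_rate)
    if config.uses_nmf_bank:
        arts.nmf_bank = ft.learn_nmf_filterbank(
            [r.spec for r in train_recs],
            K=config.K_filterbank,
            n_restarts=config.n_restarts,
            max_iter=config.max_iter,
            tol=config.tol,
            seed=seed,
        )
    if config.uses_hcc:
        grouped: dict[str, list[Spectrogram]] = {}
        for r in sorted(train_recs, key=lambda r: r.recording_id):
            grouped.setdefault(r.label, []).append(r.spec)
        arts.sbv_model = ft.learn_class_sbvs(
            {k: grouped[k] for k in sorted(grouped)},
            K=config.K_per_class,
            n_restarts=config.n_restarts,
            max_iter=config.max_iter,
            tol=config.tol,
            seed=seed,
        )
    return arts


def extract_short_time(
    recs: Sequence[PreparedRecording],
    artifacts: FrontendArtifacts,
    config: FrontendConfig,
    seed: int | None = None,
) -> list[ft.ShortTimeFeatures]:
    """Per-frame features for a batch of recordings under one front-end.

    Activation inference for the H_CC path decouples across spectrogram
    columns, so it runs once on the concatenated spectrograms and the frames
    are split back per recording; deltas are then applied per recording so
    they never straddle recording boundaries.
    """
    parts: list[list[ft.ShortTimeFeatures]] = []
    if config.uses_mel_bank or config.uses_nmf_bank:
        bank = artifacts.nmf_bank if config.uses_nmf_bank else artifacts.mel_bank
        parts.append(
            [ft.cepstral_features(r.spec, bank, n_ceps=config.n_ceps) for r in recs]
        )
    if config.uses_hcc:
        V = np.concatenate([r.spec.V for r in recs], axis=1)
        H = nmf_core.infer_activations(
            V, artifacts.sbv_model.W_bs,
            max_iter=config.max_iter, tol=config.tol, seed=seed,
            dtype=artifacts.sbv_model.W_bs.dtype,
        )
        all_hcc = ft.hcc_from_activations(
            H, n_ceps=config.n_ceps_hcc, with_gnmf=config.with_gnmf
        )
        offsets = np.cumsum([0] + [r.spec.n_frames for r in recs])
        parts.append(
            [
                ft.ShortTimeFeatures(all_hcc.X[offsets[i]:offsets[i + 1]],
                                     all_hcc.layout)
                for i in range(len(recs))
            ]
        )
    combined = parts[0]
    for extra in parts[1:]:
        combined = [ft.concat_features(a, b) for a, b in zip(combined, extra)]
    if config.deltas:
        combined = [ft.append_deltas(f) for f in combined]
    return combined


def extract_segmental(
    recs: Sequence[PreparedRecording],
    artifacts: FrontendArtifacts,
    config: FrontendConfig,
    seed: int | None = None,
) -> list[list[temporal.SegmentalFeature]]:
    """Segmental (per-syllable) features, grouped by recording."""
    short_time = extract_short_time(recs, artifacts, config, seed=seed)
    out = []
    for rec, stf in zip(recs, short_time):
        out.append(
            [
                temporal.integrate_segment(stf, seg, label=rec.label)
                for seg in rec.segments
            ]
        )
    return out


def train_classifier(
    feats: Sequence[temporal.SegmentalFeature],
    grid: Sequence[tuple[float, float]] = DEFAULT_GRID,
    inner_folds: int = DEFAULT_INNER_FOLDS,
    seed: int | None = None,
) -> ClassifierModel:
    """Fit the normalizer + one-vs-one RBF SVM with inner-CV grid search.

    The z-score normalizer and the (C, gamma) selection both use the training
    data only; ties in inner-CV accuracy go to the smaller C, then the
    smaller gamma; the winning setting is refit on all training data.
    """
    if not feats:
        raise ValueError("no training features")
    X = np.vstack([f.vector for f in feats])
    y = np.asarray([f.label for f in feats])
    classes = sorted(set(y))
    if len(classes) < 2:
        raise ValueError("need at least 2 classes")
    counts = Counter(y)
    small = [c for c in classes if counts[c] < inner_folds]
    if small:
        raise ValueError(
            f"classes {small} have fewer samples than inner_folds={inner_folds}"
        )
    mean = X.mean(axis=0)
    scale = np.maximum(X.std(axis=0), 1e-8)
    Xn = (X - mean) / scale
    skf = StratifiedKFold(n_splits=inner_folds, shuffle=True, random_state=_to_rs(seed))
    splits = list(skf.split(Xn, y))
    best_acc, best_params = -1.0, None
    for C, gamma in sorted(grid):
        correct = 0
        for tr, te in splits:
            svm = SVC(C=C, gamma=gamma, kernel="rbf")
            svm.fit(Xn[tr], y[tr])
            correct += int((svm.predict(Xn[te]) == y[te]).sum())
        acc = correct / len(y)
        if acc > best_acc:
            best_acc, best_params = acc, (C, gamma)
    C, gamma = best_params
    svm = SVC(C=C, gamma=gamma, kernel="rbf", decision_function_shape="ovo")
    svm.fit(Xn, y)
    return ClassifierModel(mean, scale, svm, classes, (C, gamma))


def _to_rs(seed: int | None) -> int | None:
    return None if seed is None else int(seed) % (2**31)


def classify_recording(
    model: ClassifierModel,
    syllable_features: Sequence[temporal.SegmentalFeature],
) -> str:
    """Majority vote over per-syllable SVM decisions.

    Ties go to whichever tied label comes first in the model's class order.
    """
    if not syllable_features:
        raise ValueError("recording has no syllables to classify")
    X = np.vstack([f.vector for f in syllable_features])
    votes = Counter(model.predict(X))
    top = max(votes.values())
    for cls in model.classes:
        if votes.get(cls, 0) == top:
            return cls
    raise AssertionError("unreachable: votes must come from model classes")


class _FoldStats:
    """Accumulates per-fold outcomes for one front-end."""

    def __init__(self, classes: list[str]) -> None:
        self.classes = classes
        self.per_fold_acc: list[float] = []
        self.fold_confusions: list[np.ndarray] = []
        self.species_correct: Counter = Counter()
        self.species_total: Counter = Counter()
        self.fold_details: list[dict] = []
        self.total_correct = 0
        self.total = 0


def _union_needs(fronts: Sequence[FrontendConfig]) -> tuple[bool, bool, bool]:
    return (
        any(f.uses_mel_bank for f in fronts),
        any(f.uses_nmf_bank for f in fronts),
        any(f.uses_hcc for f in fronts),
    )


def _assemble_frontend(
    config: FrontendConfig,
    base: dict[str, list[ft.ShortTimeFeatures]],
) -> list[ft.ShortTimeFeatures]:
    """Combine precomputed per-family features into one front-end's layout."""
    keys = []
    if config.uses_mel_bank:
        keys.append("mel")
    if config.uses_nmf_bank:
        keys.append("nmf")
    if config.uses_hcc:
        keys.append("hcc")
    combined = base[keys[0]]
    for key in keys[1:]:
        combined = [ft.concat_features(a, b) for a, b in zip(combined, base[key])]
    if config.deltas:
        combined = [ft.append_deltas(f) for f in combined]
    return combined


def kfold_evaluate(
    recordings: Sequence[PreparedRecording],
    frontend: FrontendConfig | Sequence[FrontendConfig],
    n_folds: int = DEFAULT_OUTER_FOLDS,
    inner_folds: int = DEFAULT_INNER_FOLDS,
    grid: Sequence[tuple[float, float]] = DEFAULT_GRID,
    seed: int | None = None,
) -> EvaluationReport | list[EvaluationReport]:
    """Stratified K-fold evaluation at the recording level.

    Per fold, everything learnable (NMF filter bank, class bases, feature
    normalizer, SVM hyperparameters) is fit on the training recordings only;
    test recordings are labeled by majority voting over their syllables. A
    test recording in which segmentation found no syllable counts as an
    error. The confusion matrix is column-normalized per fold (columns =
    correct class, in %) and averaged over folds.

    ``frontend`` may be a sequence of configurations, in which case all
    front-ends are evaluated on identical folds, sharing the learned filter
    bank, class bases and inferred activations — the natural setup for
    comparing front-ends — and a report is returned per configuration. The
    per-front-end results are identical to evaluating each alone with the
    same seed.
    """
    single = isinstance(frontend, FrontendConfig)
    fronts: list[FrontendConfig] = [frontend] if single else list(frontend)
    if not fronts:
        raise ValueError("need at least one front-end configuration")
    shared = lambda f: (f.K_filterbank, f.K_per_class, f.n_restarts, f.max_iter,
                        f.tol, f.n_ceps, f.n_ceps_hcc, f.with_gnmf)
    if any(shared(f) != shared(fronts[0]) for f in fronts[1:]):
        raise ValueError("batched front-ends must share NMF and cepstral parameters")
    labels = np.asarray([r.label for r in recordings])
    classes = sorted(set(labels))
    counts = Counter(labels)
    small = [c for c in classes if counts[c] < n_folds]
    if small:
        raise ValueError(f"classes {small} have fewer recordings than {n_folds} folds")
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=_to_rs(seed))
    cls_index = {c: i for i, c in enumerate(classes)}
    root = np.random.SeedSequence(seed)
    fold_seeds = [int(s.generate_state(1)[0] % (2**31)) for s in root.spawn(n_folds)]
    stats = [_FoldStats(classes) for _ in fronts]
    need_mel, need_nmf, need_hcc = _union_needs(fronts)
    union = FrontendConfig(
        name="mfcc+h_cc" if need_hcc else "mfcc",
        K_filterbank=fronts[0].K_filterbank,
        K_per_class=fronts[0].K_per_class,
        n_restarts=fronts[0].n_restarts,
        max_iter=fronts[0].max_iter,
        tol=fronts[0].tol,
    )
    for fold, (tr_idx, te_idx) in enumerate(skf.split(np.zeros(len(labels)), labels)):
        fseed = fold_seeds[fold]
        train = [recordings[i] for i in tr_idx]
        test = [recordings[i] for i in te_idx]
        arts = FrontendArtifacts()
        sample_rate = train[0].spec.sample_rate
        n_fft = 2 * (train[0].spec.n_bins - 1)
        if need_mel:
            arts.mel_bank = ft.mel_filterbank(union.K_filterbank, n_fft, sample_rate)
        if need_nmf:
            arts.nmf_bank = learn_frontend_artifacts(
                train, FrontendConfig("nmf_cc", K_filterbank=union.K_filterbank,
                                      n_restarts=union.n_restarts,
                                      max_iter=union.max_iter, tol=union.tol),
                seed=fseed,
            ).nmf_bank
        if need_hcc:
            arts.sbv_model = learn_frontend_artifacts(
                train, FrontendConfig("h_cc", K_per_class=union.K_per_class,
                                      n_restarts=union.n_restarts,
                                      max_iter=union.max_iter, tol=union.tol),
                seed=fseed,
            ).sbv_model
        base_train = _base_features(train, arts, fronts, fseed)
        base_test = _base_features(test, arts, fronts, fseed + 1)
        for fi, front in enumerate(fronts):
            st = stats[fi]
            train_stf = _assemble_frontend(front, base_train)
            test_stf = _assemble_frontend(front, base_test)
            flat_train = [
                temporal.integrate_segment(stf, seg, label=rec.label)
                for rec, stf in zip(train, train_stf)
                for seg in rec.segments
            ]
            model = train_classifier(flat_train, grid=grid,
                                     inner_folds=inner_folds, seed=fseed)
            conf = np.zeros((len(classes), len(classes)))
            n_correct = 0
            for rec, stf in zip(test, test_stf):
                feats = [
                    temporal.integrate_segment(stf, seg, label=rec.label)
                    for seg in rec.segments
                ]
                st.species_total[rec.label] += 1
                if not feats:
                    continue  # unclassifiable: counted as an error, off-matrix
                pred = classify_recording(model, feats)
                conf[cls_index[pred], cls_index[rec.label]] += 1
                if pred == rec.label:
                    n_correct += 1
                    st.species_correct[rec.label] += 1
            st.per_fold_acc.append(100.0 * n_correct / len(test))
            st.total_correct += n_correct
            st.total += len(test)
            col_sums = np.maximum(conf.sum(axis=0, keepdims=True), 1e-12)
            st.fold_confusions.append(100.0 * conf / col_sums)
            st.fold_details.append(
                {
                    "fold": fold,
                    "seed": fseed,
                    "train_ids": [r.recording_id for r in train],
                    "test_ids": [r.recording_id for r in test],
                    "hyperparams": {"C": model.hyperparams[0],
                                    "gamma": model.hyperparams[1]},
                    "artifact_checksums": arts.checksums(),
                }
            )
    reports = [
        EvaluationReport(
            classes=classes,
            per_fold_accuracy=st.per_fold_acc,
            per_species_accuracy={
                c: 100.0 * st.species_correct[c] / st.species_total[c]
                for c in classes
            },
            confusion=np.mean(st.fold_confusions, axis=0),
            overall_accuracy=100.0 * st.total_correct / st.total,
            fold_details=st.fold_details,
            config={
                "frontend": front.name,
                "deltas": front.deltas,
                "with_gnmf": front.with_gnmf,
                "n_folds": n_folds,
                "inner_folds": inner_folds,
                "seed": seed,
            },
        )
        for st, front in zip(stats, fronts)
    ]
    return reports[0] if single else reports


def _base_features(
    recs: Sequence[PreparedRecording],
    arts: FrontendArtifacts,
    fronts: Sequence[FrontendConfig],
    seed: int,
) -> dict[str, list[ft.ShortTimeFeatures]]:
    """Per-family short-time features shared across front-ends."""
    base: dict[str, list[ft.ShortTimeFeatures]] = {}
    n_ceps = fronts[0].n_ceps
    if arts.mel_bank is not None:
        base["mel"] = [
            ft.cepstral_features(r.spec, arts.mel_bank, n_ceps=n_ceps) for r in recs
        ]
    if arts.nmf_bank is not None:
        base["nmf"] = [
            ft.cepstral_features(r.spec, arts.nmf_bank, n_ceps=n_ceps) for r in recs
        ]
    if arts.sbv_model is not None:
        hcc_front = next(f for f in fronts if f.uses_hcc)
        V = np.concatenate([r.spec.V for r in recs], axis=1)
        H = nmf_core.infer_activations(
            V, arts.sbv_model.W_bs,
            max_iter=hcc_front.max_iter, tol=hcc_front.tol, seed=seed,
            dtype=arts.sbv_model.W_bs.dtype,
        )
        all_hcc = ft.hcc_from_activations(
            H, n_ceps=hcc_front.n_ceps_hcc, with_gnmf=hcc_front.with_gnmf
        )
        offsets = np.cumsum([0] + [r.spec.n_frames for r in recs])
        base["hcc"] = [
            ft.ShortTimeFeatures(all_hcc.X[offsets[i]:offsets[i + 1]], all_hcc.layout)
            for i in range(len(recs))
        ]
    return base
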