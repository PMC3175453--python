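"""End-to-end orchestration.

Ties the stages together: decompose a recording, featurize its components,
score them with a trained classifier, and either reconstruct the EEG without
the artifactual components or — for motor-imagery BCI, where the spatial
covariance must keep full rank — retain the most neural source components
and run common spatial patterns (CSP) + LDA on them.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import linalg, signal
from sklearn.metrics import roc_auc_score

from . import bss, features as feat
from .core_io import Decomposition, EEGRecording, Montage, TrainedModel
from .learn import LabeledFeatureSet, predict, train_rlda
from .synthetic import ComponentCorpus

DEFAULT_CSP_BAND = (8.0, 30.0)
DEFAULT_CSP_PAIRS = 3


# ---------------------------------------------------------------------------
# Component classification
# ---------------------------------------------------------------------------

@dataclass
class ClassifiedComponents:
    """Per-component artifact scores for one decomposition."""

    decomposition: Decomposition
    features: pd.DataFrame
    scores: np.ndarray             # higher = more artifactual
    labels: np.ndarray             # +1 artifact, -1 neural


def classify_components(rec: EEGRecording, montage: Montage,
                        model: TrainedModel, k: int = bss.DEFAULT_N_COMPONENTS
                        ) -> ClassifiedComponents:
    """Decompose, featurize and score every component of a recording."""
    decomp = bss.tdsep(rec, k=k)
    table = feat.assemble_features(decomp, montage)
    scores, labels = predict(model, table)
    return ClassifiedComponents(decomposition=decomp, features=table,
                                scores=scores, labels=labels)


def featurize_corpus(corpus: ComponentCorpus, montage: Montage
                     ) -> LabeledFeatureSet:
    """Feature matrix + labels for a synthetic component corpus."""
    lf = feat.build_leadfield(montage)
    rows = [
        feat.compute_component_features(corpus.sources[i],
                                        corpus.patterns[:, i],
                                        corpus.fs, montage, lf)
        for i in range(len(corpus.kinds))
    ]
    frame = pd.DataFrame(rows, columns=feat.FEATURE_NAMES)
    return LabeledFeatureSet.from_frame(frame, corpus.labels)


# ---------------------------------------------------------------------------
# Artifact removal
# ---------------------------------------------------------------------------

@dataclass
class CleaningResult:
    retained: np.ndarray
    removed: np.ndarray
    scores: np.ndarray
    cleaned: np.ndarray            # channels x samples
    policy: str


def remove_and_reconstruct(decomp: Decomposition, scores: np.ndarray,
                           retain: int | None = None,
                           threshold: float | None = None,
                           restore_mean: bool = True) -> CleaningResult:
    """Back-project the retained components to sensor space.

    Policies: ``retain`` keeps the n components with the lowest artifact
    scores; ``threshold`` removes components scoring above it.  Removing no
    component reproduces the rank-k PCA approximation of the recording.
    """
    scores = np.asarray(scores, dtype=float)
    k = decomp.n_components
    if (retain is None) == (threshold is None):
        raise ValueError("specify exactly one of retain= or threshold=")
    if retain is not None:
        if not 0 <= retain <= k:
            raise ValueError(f"retain={retain} outside [0, {k}]")
        order = np.argsort(scores, kind="stable")
        retained = np.sort(order[:retain])
        policy = f"retain-{retain}"
    else:
        retained = np.where(scores <= threshold)[0]
        policy = f"threshold-{threshold:g}"
    removed = np.setdiff1d(np.arange(k), retained)
    cleaned = decomp.patterns[:, retained] @ decomp.sources[retained]
    if restore_mean:
        cleaned = cleaned + decomp.mean[:, None]
    return CleaningResult(retained=retained, removed=removed, scores=scores,
                          cleaned=cleaned, policy=policy)


# ---------------------------------------------------------------------------
# Common spatial patterns
# ---------------------------------------------------------------------------

@dataclass
class CSPModel:
    """CSP filters + log-variance LDA for two-class trials."""

    cov_pos: np.ndarray
    cov_neg: np.ndarray
    filters: np.ndarray            # n_selected x n_signals
    eigenvalues: np.ndarray        # variance fraction of class +1, selected
    selected: np.ndarray
    band: tuple[float, float]
    fs: float
    lda_w: np.ndarray
    lda_b: float


def _bandpass_trials(trials: np.ndarray, band: tuple[float, float],
                     fs: float) -> np.ndarray:
    sos = signal.butter(4, band, btype="bandpass", fs=fs, output="sos")
    return signal.sosfiltfilt(sos, trials, axis=-1)


def _log_variance(filtered: np.ndarray) -> np.ndarray:
    return np.log(np.maximum(filtered.var(axis=-1), 1e-300))


def csp_train(trials: np.ndarray, labels: np.ndarray,
              n_filters_per_class: int = DEFAULT_CSP_PAIRS,
              band: tuple[float, float] = DEFAULT_CSP_BAND,
              fs: float = 100.0) -> CSPModel:
    """Fit CSP filters and the log-variance LDA on source-space trials.

    Trial covariances are trace-normalized and averaged per class; the
    generalized eigenproblem of the class covariances yields filters sorted
    by the variance fraction of class +1, from which the extreme
    ``n_filters_per_class`` pairs are kept.  Requires full-rank covariances.
    """
    trials = np.asarray(trials, dtype=float)
    labels = np.asarray(labels, dtype=float)
    if trials.ndim != 3:
        raise ValueError("trials must be n_trials x n_signals x n_samples")
    for cls in (1.0, -1.0):
        if np.sum(labels == cls) < 2:
            raise ValueError("need at least 2 trials per class")
    filtered = _bandpass_trials(trials, band, fs)
    covs = np.einsum("tcn,tdn->tcd", filtered, filtered)
    traces = np.trace(covs, axis1=1, axis2=2)
    covs = covs / traces[:, None, None]
    cov_pos = covs[labels > 0].mean(axis=0)
    cov_neg = covs[labels < 0].mean(axis=0)
    total = cov_pos + cov_neg
    k = total.shape[0]
    eigvals_total = np.linalg.eigvalsh(total)
    if eigvals_total.min() < eigvals_total.max() * 1e-10:
        raise ValueError(
            "rank-deficient trial covariance: CSP solves an eigenvalue "
            "problem and requires the data covariance to have full rank"
        )
    evals, evecs = linalg.eigh(cov_pos, total)
    order = np.argsort(evals)[::-1]           # descending class-+1 fraction
    evals, evecs = evals[order], evecs[:, order]
    npairs = max(1, min(n_filters_per_class, k // 2))
    selected = np.unique(np.r_[np.arange(npairs), np.arange(k - npairs, k)])
    filters = evecs[:, selected].T
    x = _log_variance(np.einsum("fc,tcn->tfn", filters, filtered))
    w, b, _ = train_rlda(x, labels)
    return CSPModel(cov_pos=cov_pos, cov_neg=cov_neg, filters=filters,
                    eigenvalues=evals[selected], selected=selected,
                    band=band, fs=fs, lda_w=w, lda_b=b)


def csp_scores(model: CSPModel, trials: np.ndarray) -> np.ndarray:
    """LDA decision scores of trials under fixed, previously fitted filters."""
    filtered = _bandpass_trials(np.asarray(trials, dtype=float),
                                model.band, model.fs)
    x = _log_variance(np.einsum("fc,tcn->tfn", model.filters, filtered))
    return x @ model.lda_w + model.lda_b


def auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """Area under the ROC curve of scores against +-1 labels."""
    return float(roc_auc_score(np.asarray(labels) > 0, scores))


# ---------------------------------------------------------------------------
# BCI evaluation
# ---------------------------------------------------------------------------

@dataclass
class BCIResult:
    retain_grid: np.ndarray
    errors: np.ndarray             # 1 - AUC per retained count
    baseline_error: float          # no artifact reduction (all k sources)
    component_scores: np.ndarray
    n_components: int


def bci_evaluate(trials_train: np.ndarray, labels_train: np.ndarray,
                 trials_test: np.ndarray, labels_test: np.ndarray,
                 montage: Montage, model: TrainedModel,
                 k: int = bss.DEFAULT_N_COMPONENTS,
                 retain_grid: np.ndarray | None = None,
                 n_filters_per_class: int = DEFAULT_CSP_PAIRS,
                 band: tuple[float, float] = DEFAULT_CSP_BAND,
                 fs: float = 100.0) -> BCIResult:
    """1 - AUC of CSP+LDA against the number of retained source components.

    The decomposition, component scores, CSP filters and LDA are fitted on
    the training trials only; the fixed transforms are applied to the test
    trials.  The baseline uses all k source components (no artifact
    reduction).
    """
    trials_train = np.asarray(trials_train, dtype=float)
    trials_test = np.asarray(trials_test, dtype=float)
    n_tr, n_ch, n_samp = trials_train.shape
    cont = trials_train.transpose(1, 0, 2).reshape(n_ch, n_tr * n_samp)
    rec = EEGRecording(data=cont, fs=fs, channel_names=list(montage.names))
    k = min(k, n_ch)
    decomp = bss.tdsep(rec, k=k)
    table = feat.assemble_features(decomp, montage)
    comp_scores, _ = predict(model, table)

    src_train = np.einsum("fc,tcn->tfn", decomp.filters,
                          trials_train - decomp.mean[None, :, None])
    src_test = np.einsum("fc,tcn->tfn", decomp.filters,
                         trials_test - decomp.mean[None, :, None])

    def error_for(rows: np.ndarray) -> float:
        csp = csp_train(src_train[:, rows, :], labels_train,
                        n_filters_per_class, band, fs)
        return 1.0 - auc(csp_scores(csp, src_test[:, rows, :]), labels_test)

    baseline = error_for(np.arange(k))
    if retain_grid is None:
        retain_grid = np.arange(k, max(1, k // 5) - 1, -1)
    retain_grid = np.asarray(retain_grid, dtype=int)
    neural_order = np.argsort(comp_scores, kind="stable")
    errors = np.array([error_for(np.sort(neural_order[:n]))
                       for n in retain_grid])
    return BCIResult(retain_grid=retain_grid, errors=errors,
                     baseline_error=baseline, component_scores=comp_scores,
                     n_components=k)
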