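"""Synthetic ERP data at two levels of realism.

1. Continuous pseudo-EEG: stimulus-locked ERP templates (a strong early
   occipital negativity around 150 ms, a weaker late central positivity
   around 400 ms for targets; no evoked response for non-targets) added to
   AR(1) background noise, exercised through the full preprocessing and
   feature pipeline.
2. Direct feature-space sampling: class-conditional Gaussian feature
   vectors with a known mixing matrix, for the statistical theory
   (convergence rates, noise-amplification calibration, learning curves).

SNR conventions (the ratio is not standardized in the ERP literature, so
it is pinned down here): for continuous synthesis, ``snr`` is the peak
target-template amplitude divided by the noise standard deviation at the
working rate; for feature-space sampling via
:func:`feature_space_model`, ``snr`` is the Mahalanobis separation
``‖Σ^{-1/2}(μ+ − μ−)‖`` so the Bayes-optimal AUC is Φ(snr/2).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import scipy.signal
from scipy.stats import norm

from ._utils import as_rng
from .epochs import NONTARGET, TARGET, EpochSet
from .features import ContinuousRecording, FeatureConfig, extract_epochs, interval_means, preprocess
from .meanmap import ClassMeans, MixingMatrix
from .paradigm import SpellerGrid, StimulusSchedule, label_events

__all__ = [
    "CHANNELS_31",
    "OCCIPITAL_WEIGHTS",
    "CENTRAL_WEIGHTS",
    "ErpTemplates",
    "SimulationParams",
    "default_templates",
    "simulate_recording",
    "epochs_from_recording",
    "sample_feature_epochs",
    "sample_trial_epochs",
    "feature_space_model",
    "bayes_auc",
    "STUDY_FEATURE_SEPARATION",
    "template_feature_means",
    "homogeneity_violation",
]

# 31-channel extended 10-20 montage; dropping Fp1/Fp2 leaves the 29
# channels the feature pipeline retains by default.
CHANNELS_31 = (
    "Fp1", "Fp2", "F7", "F3", "Fz", "F4", "F8",
    "FC5", "FC1", "FC2", "FC6", "T7", "C3", "Cz", "C4", "T8",
    "CP5", "CP1", "CP2", "CP6", "P7", "P3", "Pz", "P4", "P8",
    "PO7", "PO3", "PO4", "PO8", "O1", "O2",
)

# topography weights of the two target components
OCCIPITAL_WEIGHTS = {"O1": 1.0, "O2": 1.0, "PO7": 0.6, "PO3": 0.6, "PO4": 0.6, "PO8": 0.6}
CENTRAL_WEIGHTS = {"Cz": 1.0, "C3": 0.7, "C4": 0.7, "CP1": 0.7, "CP2": 0.7, "FC1": 0.5, "FC2": 0.5, "Pz": 0.5}

# default component parameters: trough depth/latency/width of the early
# negativity and peak of the late positivity (Gaussian bumps)
N150_AMP_UV = -8.0
N150_LATENCY_MS = 150.0
N150_SIGMA_MS = 25.0
P300_AMP_UV = 2.0
P300_LATENCY_MS = 400.0
P300_SIGMA_MS = 60.0


# Feature-space class separation calibrated so that the Bayes-optimal
# binary AUC, Φ(snr/2), equals the supervised decoding ceiling observed on
# the visual speller data the generator emulates (97.5%).
STUDY_FEATURE_SEPARATION = float(2.0 * norm.ppf(0.975))


@dataclass(frozen=True)
class ErpTemplates:
    """Per-channel target and non-target evoked waveforms on [0, 700] ms."""

    target_waveform: np.ndarray  # (C, S), microvolts
    nontarget_waveform: np.ndarray
    template_rate: float
    channel_names: tuple[str, ...]
    occipital_channels: tuple[str, ...]
    central_channels: tuple[str, ...]

    @property
    def times_ms(self) -> np.ndarray:
        return np.arange(self.target_waveform.shape[1]) * 1000.0 / self.template_rate


def default_templates(
    sampling_rate: float = 1000.0, channel_names: Sequence[str] = CHANNELS_31
) -> ErpTemplates:
    """Two-component target template; zero non-target response."""
    times = np.arange(int(round(0.7 * sampling_rate))) * 1000.0 / sampling_rate
    n150 = N150_AMP_UV * np.exp(-0.5 * ((times - N150_LATENCY_MS) / N150_SIGMA_MS) ** 2)
    p300 = P300_AMP_UV * np.exp(-0.5 * ((times - P300_LATENCY_MS) / P300_SIGMA_MS) ** 2)
    target = np.zeros((len(channel_names), len(times)))
    for i, ch in enumerate(channel_names):
        target[i] = OCCIPITAL_WEIGHTS.get(ch, 0.0) * n150 + CENTRAL_WEIGHTS.get(ch, 0.0) * p300
    return ErpTemplates(
        target_waveform=target,
        nontarget_waveform=np.zeros_like(target),
        template_rate=sampling_rate,
        channel_names=tuple(channel_names),
        occipital_channels=tuple(c for c in channel_names if c in OCCIPITAL_WEIGHTS),
        central_channels=tuple(c for c in channel_names if c in CENTRAL_WEIGHTS),
    )


@dataclass(frozen=True)
class SimulationParams:
    """Knobs of the continuous pseudo-EEG synthesizer (study defaults)."""

    sampling_rate: float = 1000.0
    soa_ms: float = 250.0
    snr: float = 5.0  # template peak amplitude / noise SD at the working rate
    noise_model: str = "ar1"  # 'ar1' or 'white'
    ar_coeff: float = 0.95
    trial_gap_s: float = 8.0  # 4 s cue + 4 s feedback between characters
    pre_s: float = 0.5  # lead-in before the first onset
    post_s: float = 1.0  # tail after the last onset

    def __post_init__(self) -> None:
        if self.snr < 0:
            raise ValueError("snr must be non-negative")
        if not (0 <= self.ar_coeff < 1):
            raise ValueError("AR(1) coefficient must lie in [0, 1)")
        if self.noise_model not in ("ar1", "white"):
            raise ValueError("noise_model must be 'ar1' or 'white'")


def _ar1_noise(shape: tuple[int, int], rho: float, rng: np.random.Generator) -> np.ndarray:
    """Stationary unit-variance AR(1) rows (burn-in discarded)."""
    burn = 200
    white = rng.standard_normal((shape[0], shape[1] + burn))
    driven = np.sqrt(1.0 - rho**2) * white
    out = scipy.signal.lfilter([1.0], [1.0, -rho], driven, axis=1)
    return out[:, burn:]


def simulate_recording(
    params: SimulationParams,
    schedules: Sequence[StimulusSchedule],
    attended_symbols: Sequence[int],
    grid: SpellerGrid,
    templates: ErpTemplates | None = None,
    rng: np.random.Generator | int | None = None,
) -> tuple[ContinuousRecording, np.ndarray]:
    """Continuous pseudo-EEG for a list of trials; returns ground truth.

    The signal is the sum, over stimulus events, of the target or
    non-target template (according to whether the event highlights the
    trial's attended symbol) placed at the event onset, scaled so the
    target-template peak equals ``snr`` noise standard deviations, plus
    unit-variance noise. Labels are returned separately and never enter
    the recording container.
    """
    rng = as_rng(rng)
    if len(schedules) != len(attended_symbols):
        raise ValueError("need one attended symbol per trial schedule")
    templates = templates or default_templates(params.sampling_rate)
    if abs(templates.template_rate - params.sampling_rate) > 1e-9:
        raise ValueError("template rate must match the sampling rate")

    fs = params.sampling_rate
    soa = int(round(params.soa_ms / 1000.0 * fs))
    gap = int(round(params.trial_gap_s * fs))
    pre = int(round(params.pre_s * fs))
    onsets, labels = [], []
    cursor = pre
    for schedule, attended in zip(schedules, attended_symbols):
        trial_labels = label_events(schedule, attended, grid)
        for k in range(len(schedule)):
            onsets.append(cursor + k * soa)
        labels.append(trial_labels)
        cursor += len(schedule) * soa + gap
    onsets = np.asarray(onsets, dtype=int)
    if np.any(np.diff(onsets) <= 0):
        raise ValueError("event onsets are not strictly increasing")
    labels = np.concatenate(labels)

    n_channels = len(templates.channel_names)
    n_time = onsets[-1] + templates.target_waveform.shape[1] + int(round(params.post_s * fs))
    if params.noise_model == "white":
        signal = rng.standard_normal((n_channels, n_time))
    else:
        signal = _ar1_noise((n_channels, n_time), params.ar_coeff, rng)

    peak = np.max(np.abs(templates.target_waveform))
    scale = params.snr / peak if peak > 0 else 0.0
    span = templates.target_waveform.shape[1]
    for onset, label in zip(onsets, labels):
        wave = templates.target_waveform if label == TARGET else templates.nontarget_waveform
        signal[:, onset : onset + span] += scale * wave

    recording = ContinuousRecording(
        samples=signal,
        sampling_rate=fs,
        event_onsets=onsets,
        channel_names=templates.channel_names,
    )
    return recording, labels


def epochs_from_recording(
    recording: ContinuousRecording,
    config: FeatureConfig,
    schedules: Sequence[StimulusSchedule],
    labels: np.ndarray | None = None,
) -> EpochSet:
    """Run the feature pipeline and attach schedule metadata per epoch."""
    processed = preprocess(recording, config)
    windows = extract_epochs(processed, config)
    feats = interval_means(windows, config, processed.channel_names)
    group = np.concatenate([s.groups() for s in schedules])
    trial = np.concatenate(
        [np.full(len(s), s.trial_id, dtype=int) for s in schedules]
    )
    highlighted = [h for s in schedules for h in s.highlighted()]
    if feats.shape[0] != len(group):
        raise ValueError("recording events and schedule events disagree")
    return EpochSet(
        features=feats, group=group, trial=trial, highlighted=highlighted, label=labels
    )


# -- direct feature-space sampling -----------------------------------------


def sample_feature_epochs(
    mixing: MixingMatrix,
    n_per_group: Sequence[int],
    class_means: ClassMeans,
    covariance: np.ndarray,
    rng: np.random.Generator | int | None = None,
    exact_counts: bool = True,
) -> EpochSet:
    """Gaussian feature epochs honouring the mixing matrix's proportions.

    With ``exact_counts`` (the paradigm's regime) group g contains exactly
    round(π+g · n_g) targets; with ``exact_counts=False`` each epoch is a
    Bernoulli(π+g) draw (the IID regime of the convergence theory). True
    labels are stored for evaluation only.
    """
    rng = as_rng(rng)
    covariance = np.asarray(covariance, dtype=float)
    d = class_means.target_mean.shape[0]
    if covariance.shape != (d, d):
        raise ValueError("covariance must be D x D for D-dimensional class means")
    try:
        chol = np.linalg.cholesky(covariance)
    except np.linalg.LinAlgError as err:
        raise ValueError("covariance must be positive definite") from err

    parts = []
    for g, n_g in enumerate(n_per_group):
        pi_target = mixing.proportions[g, 0]
        if exact_counts:
            n_pos = int(round(pi_target * n_g))
            labels = np.full(n_g, NONTARGET)
            labels[rng.choice(n_g, size=n_pos, replace=False)] = TARGET
        else:
            labels = np.where(rng.random(n_g) < pi_target, TARGET, NONTARGET)
        noise = rng.standard_normal((n_g, d)) @ chol.T
        means = np.where(
            (labels == TARGET)[:, None], class_means.target_mean, class_means.nontarget_mean
        )
        parts.append(
            EpochSet(
                features=means + noise,
                group=np.full(n_g, mixing.group_names[g]),
                label=labels,
            )
        )
    return EpochSet.concat(parts)


def sample_trial_epochs(
    schedules: Sequence[StimulusSchedule],
    attended_symbols: Sequence[int],
    grid: SpellerGrid,
    class_means: ClassMeans,
    covariance: np.ndarray,
    rng: np.random.Generator | int | None = None,
) -> EpochSet:
    """Feature-space epochs for whole trials, keeping schedule metadata.

    Labels follow the schedules and attended symbols exactly (16 targets
    per study trial by construction), so the per-group proportions match
    the paradigm's mixing matrix rather than Bernoulli draws.
    """
    rng = as_rng(rng)
    covariance = np.asarray(covariance, dtype=float)
    chol = np.linalg.cholesky(covariance)
    d = class_means.target_mean.shape[0]
    parts = []
    for schedule, attended in zip(schedules, attended_symbols):
        labels = label_events(schedule, attended, grid)
        n = len(schedule)
        means = np.where(
            (labels == TARGET)[:, None], class_means.target_mean, class_means.nontarget_mean
        )
        parts.append(
            EpochSet(
                features=means + rng.standard_normal((n, d)) @ chol.T,
                group=schedule.groups(),
                trial=np.full(n, schedule.trial_id, dtype=int),
                highlighted=schedule.highlighted(),
                label=labels,
            )
        )
    return EpochSet.concat(parts)


def template_feature_means(
    templates: ErpTemplates | None = None, config: FeatureConfig | None = None
) -> ClassMeans:
    """Noise-free interval-mean features of the two templates.

    The templates are placed in a silent recording and run through the
    standard pipeline, giving the deterministic feature-space image of the
    target and non-target responses (D = 174 with the default montage).
    """
    templates = templates or default_templates()
    config = config or FeatureConfig()
    fs = templates.template_rate
    span = templates.target_waveform.shape[1]
    pre = int(round(0.5 * fs))
    means = []
    for wave in (templates.target_waveform, templates.nontarget_waveform):
        samples = np.zeros((len(templates.channel_names), pre + span + int(round(0.5 * fs))))
        samples[:, pre : pre + span] = wave
        rec = ContinuousRecording(
            samples=samples,
            sampling_rate=fs,
            event_onsets=np.asarray([pre]),
            channel_names=templates.channel_names,
        )
        processed = preprocess(rec, config)
        windows = extract_epochs(processed, config)
        means.append(interval_means(windows, config, processed.channel_names)[0])
    return ClassMeans(target_mean=means[0], nontarget_mean=means[1])


def feature_space_model(
    snr: float = STUDY_FEATURE_SEPARATION,
    templates: ErpTemplates | None = None,
    config: FeatureConfig | None = None,
) -> tuple[ClassMeans, np.ndarray]:
    """(class means, identity covariance) with Mahalanobis separation ``snr``.

    The class-mean difference keeps the template-derived feature topography
    but is rescaled to norm ``snr`` against unit-variance isotropic noise,
    so the Bayes-optimal binary AUC equals Φ(snr/2).
    """
    base = template_feature_means(templates, config)
    diff = base.difference
    norm_ = np.linalg.norm(diff)
    if norm_ == 0:
        raise ValueError("templates produce no class-mean difference")
    mu_target = snr * diff / norm_
    d = diff.shape[0]
    return (
        ClassMeans(target_mean=mu_target, nontarget_mean=np.zeros(d)),
        np.eye(d),
    )


def bayes_auc(snr: float) -> float:
    """Optimal AUC of the feature-space model at a given separation."""
    return float(norm.cdf(snr / 2.0))


def homogeneity_violation(
    epochs: EpochSet, group, shift: np.ndarray
) -> EpochSet:
    """Shift the target-class epochs of one group (violates homogeneity).

    Test fixture for the homogeneity bootstrap: adds ``shift`` to the
    feature vectors of the chosen group's target epochs so that the
    class-conditional distributions are no longer group-independent.
    """
    if epochs.label is None:
        raise ValueError("homogeneity_violation needs labelled epochs")
    if group not in set(epochs.group.tolist()):
        raise ValueError(f"group {group!r} not present")
    shift = np.asarray(shift, dtype=float)
    features = epochs.features.copy()
    mask = (epochs.group == group) & (epochs.label == TARGET)
    features[mask] += shift
    return EpochSet(
        features=features,
        group=epochs.group.copy(),
        trial=None if epochs.trial is None else epochs.trial.copy(),
        highlighted=None if epochs.highlighted is None else list(epochs.highlighted),
        label=epochs.label.copy(),
    )
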