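"""Raw trial signals -> analysis-ready windowed KAM waveform and discrete features.

Processing steps: zero-phase (forward-backward) Butterworth low-pass filtering
at 6 Hz of the moment and kinematic channels, force-threshold event detection
on the unfiltered vertical ground reaction force (initial contact = first
frame strictly above 10 N, end of stance = first later frame strictly below
10 N), extraction of the first-100 ms window of the filtered mass-normalised
knee abduction moment, and the discrete at-contact / within-window features
used by the risk models.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal as sps

from kamrisk.config import ProcessingConfig


class NoContactError(ValueError):
    """The force series never exceeds the contact threshold."""


class TruncatedStanceError(ValueError):
    """The force series never drops below the threshold after contact."""


class InvalidTrialError(ValueError):
    """The series is too short to contain the analysis window."""


@dataclass
class TrialRecording:
    """Raw multichannel time series for one cutting-manoeuvre trial."""

    trial_id: str
    athlete_id: str
    leg: str
    condition: str
    sampling_rate: float
    mass_kg: float
    channels: dict[str, np.ndarray]
    kam_normalized: bool = False

    def __post_init__(self) -> None:
        lengths = {len(v) for v in self.channels.values()}
        if len(lengths) > 1:
            raise ValueError("all channels must have equal length")
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        if self.mass_kg <= 0:
            raise ValueError("mass_kg must be positive")


@dataclass
class DiscreteFeatures:
    early_kam_max: float
    highest_kam_stance: float
    knee_abd_angle_ic: float
    knee_flex_angle_ic: float
    vgrf_max_100ms: float
    trunk_foot_ml_ic: float
    trunk_foot_ap_ic: float
    window_exceeds_stance: bool = False


@dataclass
class ProcessedTrial:
    trial_id: str
    athlete_id: str
    ic_frame: int
    eos_frame: int
    window: np.ndarray
    features: DiscreteFeatures


@dataclass
class ProcessedCohort:
    """Vectorised processing result: aligned window matrix + feature table."""

    windows: np.ndarray  # (n_trials, window_len) filtered KAM, N.m/kg
    features: pd.DataFrame  # one row per trial incl. ic/eos frames
    sampling_rate: float
    config: ProcessingConfig = field(default_factory=ProcessingConfig)


def lowpass_filter(
    series: np.ndarray, sampling_rate: float, cutoff: float = 6.0, order: int = 2
) -> np.ndarray:
    """Zero-phase low-pass Butterworth filter (applied forward and backward).

    The forward-backward application squares the magnitude response, so the
    amplitude gain at the cutoff frequency is 0.5 and the phase shift is zero.
    Works on a 1-D series or on an (n_trials, n_frames) matrix (last axis).
    """
    series = np.asarray(series, dtype=float)
    nyquist = sampling_rate / 2.0
    if not (0.0 < cutoff < nyquist):
        raise ValueError(f"cutoff must lie in (0, {nyquist}) Hz")
    b, a = sps.butter(order, cutoff / nyquist, btype="low")
    padlen = 3 * max(len(a), len(b))
    if series.shape[-1] <= padlen:
        raise ValueError(f"series too short to filter (need > {padlen} samples)")
    return sps.filtfilt(b, a, series, axis=-1)


def detect_initial_contact(vgrf: np.ndarray, threshold: float = 10.0) -> int:
    """First frame where the unfiltered vGRF strictly exceeds the threshold (N)."""
    vgrf = np.asarray(vgrf)
    if vgrf.size == 0:
        raise NoContactError("empty force series")
    above = vgrf > threshold
    if not above.any():
        raise NoContactError(f"force never exceeds {threshold} N")
    return int(np.argmax(above))


def detect_end_of_stance(vgrf: np.ndarray, ic_frame: int, threshold: float = 10.0) -> int:
    """First frame after ``ic_frame`` where the vGRF falls strictly below the threshold."""
    vgrf = np.asarray(vgrf)
    if not (0 <= ic_frame < len(vgrf)):
        raise ValueError("ic_frame outside series")
    below = vgrf[ic_frame + 1 :] < threshold
    if not below.any():
        raise TruncatedStanceError(f"force never drops below {threshold} N after contact")
    return int(ic_frame + 1 + np.argmax(below))


def window_length(sampling_rate: float, duration: float = 0.100) -> int:
    """Number of samples in the analysis window: floor(duration * rate)."""
    return int(np.floor(duration * sampling_rate))


def extract_window(
    kam_filtered: np.ndarray, ic_frame: int, sampling_rate: float, duration: float = 0.100
) -> np.ndarray:
    """The first ``duration`` seconds of the filtered KAM, starting at contact.

    At 400 Hz this is 40 samples (t = 0 ... 97.5 ms); the sign-of-derivative
    feature vector computed downstream then has 39 elements.
    """
    n = window_length(sampling_rate, duration)
    kam_filtered = np.asarray(kam_filtered)
    if ic_frame + n > len(kam_filtered):
        raise InvalidTrialError(
            f"need {n} samples after contact frame {ic_frame}, have {len(kam_filtered) - ic_frame}"
        )
    return kam_filtered[ic_frame : ic_frame + n]


def normalize_moment(
    kam: np.ndarray, mass_kg: float, already_normalized: bool = False
) -> np.ndarray:
    """Divide a moment series (N.m) by body mass -> N.m/kg; idempotent via flag."""
    if mass_kg <= 0:
        raise ValueError("mass_kg must be positive")
    kam = np.asarray(kam, dtype=float)
    return kam if already_normalized else kam / mass_kg


def extract_discrete_features(
    trial: TrialRecording,
    ic_frame: int,
    eos_frame: int,
    window: np.ndarray,
    *,
    filtered: dict[str, np.ndarray] | None = None,
) -> DiscreteFeatures:
    """Discrete per-trial features from events, the window and filtered channels.

    Maxima over [ic, ic + window) for the early KAM and the mass-normalised
    vGRF; maximum over [ic, eos) of the filtered KAM for the stance-phase
    peak; angle and trunk-foot channels sampled at initial contact.
    """
    if filtered is None:
        filtered = {
            ch: lowpass_filter(trial.channels[ch], trial.sampling_rate)
            for ch in ("kam_nm_kg", "knee_flex_deg", "knee_abd_deg",
                       "trunk_foot_ml_pct", "trunk_foot_ap_pct")
        }
    kam_f = normalize_moment(filtered["kam_nm_kg"], trial.mass_kg, trial.kam_normalized)
    n_win = len(window)
    exceeds = ic_frame + n_win > eos_frame
    vgrf_win = trial.channels["vgrf_n"][ic_frame : ic_frame + n_win]
    return DiscreteFeatures(
        early_kam_max=float(np.max(window)),
        highest_kam_stance=float(np.max(kam_f[ic_frame:eos_frame])),
        knee_abd_angle_ic=float(filtered["knee_abd_deg"][ic_frame]),
        knee_flex_angle_ic=float(filtered["knee_flex_deg"][ic_frame]),
        vgrf_max_100ms=float(np.max(vgrf_win) / trial.mass_kg),
        trunk_foot_ml_ic=float(filtered["trunk_foot_ml_pct"][ic_frame]),
        trunk_foot_ap_ic=float(filtered["trunk_foot_ap_pct"][ic_frame]),
        window_exceeds_stance=bool(exceeds),
    )


def process_trial(trial: TrialRecording, config: ProcessingConfig | None = None) -> ProcessedTrial:
    """Process a single trial: filter, detect events, window, extract features."""
    cfg = config or ProcessingConfig()
    ic = detect_initial_contact(trial.channels["vgrf_n"], cfg.threshold_n)
    eos = detect_end_of_stance(trial.channels["vgrf_n"], ic, cfg.threshold_n)
    filtered = {
        ch: lowpass_filter(trial.channels[ch], trial.sampling_rate, cfg.cutoff_hz, cfg.filter_order)
        for ch in ("kam_nm_kg", "knee_flex_deg", "knee_abd_deg",
                   "trunk_foot_ml_pct", "trunk_foot_ap_pct")
    }
    kam_f = normalize_moment(filtered["kam_nm_kg"], trial.mass_kg, trial.kam_normalized)
    window = extract_window(kam_f, ic, trial.sampling_rate, cfg.window_s)
    feats = extract_discrete_features(trial, ic, eos, window, filtered=filtered)
    return ProcessedTrial(
        trial_id=trial.trial_id,
        athlete_id=trial.athlete_id,
        ic_frame=ic,
        eos_frame=eos,
        window=window,
        features=feats,
    )


FEATURE_COLUMNS = [
    "early_kam_max",
    "highest_kam_stance",
    "knee_abd_angle_ic",
    "knee_flex_angle_ic",
    "vgrf_max_100ms",
    "trunk_foot_ml_ic",
    "trunk_foot_ap_ic",
]


def process_cohort(cohort, config: ProcessingConfig | None = None) -> ProcessedCohort:
    """Vectorised equivalent of :func:`process_trial` over a whole cohort.

    Filtering is applied to the full-length series before any windowing, in a
    single pass per channel; event detection uses only the raw force channel.
    """
    cfg = config or ProcessingConfig()
    fs = cohort.sampling_rate
    vgrf = cohort.signals["vgrf_n"]
    n_trials, n_frames = vgrf.shape

    above = vgrf > cfg.threshold_n
    if not above.any(axis=1).all():
        raise NoContactError("at least one trial never exceeds the contact threshold")
    ic = np.argmax(above, axis=1)

    frames = np.arange(n_frames)[None, :]
    below_after = (vgrf < cfg.threshold_n) & (frames > ic[:, None])
    if not below_after.any(axis=1).all():
        raise TruncatedStanceError("at least one trial never ends its stance phase")
    eos = np.argmax(below_after, axis=1)

    filt = {
        ch: lowpass_filter(cohort.signals[ch], fs, cfg.cutoff_hz, cfg.filter_order)
        for ch in ("kam_nm_kg", "knee_flex_deg", "knee_abd_deg",
                   "trunk_foot_ml_pct", "trunk_foot_ap_pct")
    }
    mass = (
        cohort.athletes.set_index("athlete_id")["mass_kg"]
        .loc[cohort.trials["athlete_id"]]
        .to_numpy()
    )
    kam_f = filt["kam_nm_kg"]
    if not cohort.kam_normalized:
        kam_f = kam_f / mass[:, None]

    n_win = window_length(fs, cfg.window_s)
    if (ic + n_win > n_frames).any():
        raise InvalidTrialError("analysis window extends past the end of a recording")
    windows = kam_f[np.arange(n_trials)[:, None], ic[:, None] + np.arange(n_win)[None, :]]

    in_stance = (frames >= ic[:, None]) & (frames < eos[:, None])
    highest = np.max(np.where(in_stance, kam_f, -np.inf), axis=1)
    in_win = (frames >= ic[:, None]) & (frames < (ic + n_win)[:, None])
    vgrf_max = np.max(np.where(in_win, vgrf, -np.inf), axis=1) / mass

    rows = np.arange(n_trials)
    features = pd.DataFrame(
        {
            "trial_id": cohort.trials["trial_id"].to_numpy(),
            "athlete_id": cohort.trials["athlete_id"].to_numpy(),
            "ic_frame": ic,
            "eos_frame": eos,
            "early_kam_max": windows.max(axis=1),
            "highest_kam_stance": highest,
            "knee_abd_angle_ic": filt["knee_abd_deg"][rows, ic],
            "knee_flex_angle_ic": filt["knee_flex_deg"][rows, ic],
            "vgrf_max_100ms": vgrf_max,
            "trunk_foot_ml_ic": filt["trunk_foot_ml_pct"][rows, ic],
            "trunk_foot_ap_ic": filt["trunk_foot_ap_pct"][rows, ic],
            "window_exceeds_stance": ic + n_win > eos,
        }
    )
    return ProcessedCohort(windows=windows, features=features, sampling_rate=fs, config=cfg)
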