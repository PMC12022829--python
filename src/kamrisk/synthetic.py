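"""Seeded synthetic cutting-manoeuvre cohort generator.

Emulates a gait-lab data set of adolescent athletes performing a cutting
manoeuvre: per-trial multichannel time series (knee abduction moment, vertical
ground reaction force, knee angles, trunk-foot centre-of-mass offsets) plus an
athlete table with a later-ACL-injury outcome.  The generated statistical
structure is what the downstream analysis assumes:

* six smooth waveform-shape archetypes, two of which contain an early peak
  (a positive interior maximum of the knee abduction moment within the first
  100 ms after initial contact);
* injury is recorded per leg (injured athletes have one or both legs flagged);
  legs that are later injured produce early-peak trials at a higher rate
  (trial-level odds ratio configurable, default 7.2), with logit-scale
  per-athlete heterogeneity;
* the knee abduction angle at initial contact is shifted on later-injured legs
  so that a logistic regression recovers a configurable per-degree odds ratio
  (default 1.4); all other covariates carry no effect.

Waveform shapes are parametric stand-ins (sums of raised-cosine segments plus
band-limited noise); no marker-level kinematics or inverse dynamics are
modelled.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal as sps
from scipy.optimize import brentq
from scipy.special import expit, logit

from kamrisk.config import CovariateParams, GeneratorConfig

EARLY_PEAK_ARCHETYPES = (2, 4)

#: archetype shape constants (seconds): raised-cosine rise/fall spans
_RISE_A1 = 0.18
_RISE_A2, _FALL_A2 = 0.020, 0.15
_RISE_A4, _FALL_A4 = 0.048, 0.13
_DIP_A3, _RECOVER_A3 = 0.048, 0.16
_DIP_A5, _RECOVER_A5 = 0.020, 0.15
_FALL_A6 = 0.16
_LATE_WIDTH = 0.17
_STANCE_TAPER = 0.06


class InfeasibleConfigError(ValueError):
    """Raised when no early-peak rate pair can satisfy the requested marginals."""


# ---------------------------------------------------------------------------
# rate calibration
# ---------------------------------------------------------------------------

def ep_rates_from_or(
    target_or: float, overall_rate: float, injured_trial_fraction: float
) -> tuple[float, float]:
    """Solve for per-status early-peak trial rates (p0 uninjured, p1 injured).

    The pair satisfies the two marginal constraints

        f * p1 + (1 - f) * p0 = overall_rate
        [p1 / (1 - p1)] / [p0 / (1 - p0)] = target_or

    where ``f`` is the fraction of trials contributed by injured athletes.
    The left-hand side of the first equation is strictly increasing in p0
    (p1 is an increasing function of p0 at fixed odds ratio), so the root is
    unique and found by bracketing.
    """
    if target_or < 1.0:
        raise ValueError("target_or must be >= 1")
    if not (0.0 < overall_rate < 1.0):
        raise ValueError("overall_rate must lie in (0, 1)")
    if not (0.0 < injured_trial_fraction < 1.0):
        raise ValueError("injured_trial_fraction must lie in (0, 1)")
    if target_or == 1.0:
        return overall_rate, overall_rate

    f = injured_trial_fraction

    def p1_of(p0: float) -> float:
        odds1 = target_or * p0 / (1.0 - p0)
        return odds1 / (1.0 + odds1)

    def g(p0: float) -> float:
        return f * p1_of(p0) + (1.0 - f) * p0 - overall_rate

    lo, hi = 1e-12, overall_rate
    if g(lo) > 0 or g(hi) < 0:
        raise InfeasibleConfigError(
            f"no early-peak rate pair matches OR={target_or}, "
            f"overall rate={overall_rate}, injured fraction={f}"
        )
    p0 = brentq(g, lo, hi, xtol=1e-14)
    return float(p0), float(p1_of(p0))


def _centered_logit(p: float, sd: float, n_quad: int = 41) -> float:
    """Logit location l such that E_z[expit(l + sd*z)] = p for z ~ N(0,1)."""
    p = float(np.clip(p, 1e-12, 1 - 1e-12))
    if sd <= 0.0:
        return float(logit(p))
    from numpy.polynomial.hermite import hermgauss

    nodes, weights = hermgauss(n_quad)
    w = weights / np.sqrt(np.pi)
    zs = np.sqrt(2.0) * nodes

    def mean_rate(l: float) -> float:
        return float(np.sum(w * expit(l + sd * zs)))

    lo, hi = logit(p) - 6.0 * sd, logit(p) + 6.0 * sd
    return float(brentq(lambda l: mean_rate(l) - p, lo, hi, xtol=1e-12))


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

TRUTH_TRIAL_COLUMNS = [
    "trial_id",
    "athlete_id",
    "leg",
    "condition",
    "true_archetype",
    "true_early_peak",
    "true_ic_frame",
    "true_eos_frame",
]


@dataclass
class TruthTable:
    """Ground-truth labels for a generated cohort (per-trial and per-athlete)."""

    trials: pd.DataFrame
    athletes: pd.DataFrame

    def validate(self) -> None:
        ep = self.trials["true_archetype"].isin(EARLY_PEAK_ARCHETYPES)
        if not (ep == self.trials["true_early_peak"]).all():
            raise AssertionError("early-peak flag inconsistent with archetype")


@dataclass
class Cohort:
    """A generated cohort: metadata tables plus per-channel signal matrices.

    ``signals`` maps channel name to an (n_trials, n_frames) array; rows align
    with ``trials``.  The knee abduction moment channel is emitted already
    mass-normalised (N.m/kg).
    """

    sampling_rate: float
    trials: pd.DataFrame
    athletes: pd.DataFrame
    signals: dict[str, np.ndarray] = field(default_factory=dict)
    kam_normalized: bool = True

    SIGNAL_CHANNELS = (
        "kam_nm_kg",
        "vgrf_n",
        "knee_flex_deg",
        "knee_abd_deg",
        "trunk_foot_ml_pct",
        "trunk_foot_ap_pct",
    )

    @property
    def n_trials(self) -> int:
        return len(self.trials)

    @property
    def truth(self) -> TruthTable:
        return TruthTable(
            trials=self.trials[TRUTH_TRIAL_COLUMNS].copy(),
            athletes=self.athletes[["athlete_id", "injured"]].copy(),
        )

    def iter_trials(self):
        """Yield single-trial recordings (see signal_processing.TrialRecording)."""
        from kamrisk.signal_processing import TrialRecording

        mass = self.athletes.set_index("athlete_id")["mass_kg"]
        for i, row in enumerate(self.trials.itertuples(index=False)):
            yield TrialRecording(
                trial_id=row.trial_id,
                athlete_id=row.athlete_id,
                leg=row.leg,
                condition=row.condition,
                sampling_rate=self.sampling_rate,
                mass_kg=float(mass[row.athlete_id]),
                channels={ch: self.signals[ch][i] for ch in self.SIGNAL_CHANNELS},
                kam_normalized=self.kam_normalized,
            )

    def to_dir(self, out_dir) -> None:
        from pathlib import Path

        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.athletes.to_csv(out / "athletes.csv", index=False)
        self.trials.to_csv(out / "trials.csv", index=False)
        n_frames = self.signals["kam_nm_kg"].shape[1]
        frame = np.tile(np.arange(n_frames), self.n_trials)
        long = pd.DataFrame(
            {
                "trial_id": np.repeat(self.trials["trial_id"].to_numpy(), n_frames),
                "frame": frame,
                "time_s": frame / self.sampling_rate,
            }
        )
        for ch in self.SIGNAL_CHANNELS:
            long[ch] = self.signals[ch].ravel()
        long.to_csv(out / "timeseries_long.csv", index=False, float_format="%.5g")

    @classmethod
    def from_dir(cls, in_dir, sampling_rate: float | None = None) -> "Cohort":
        from pathlib import Path

        src = Path(in_dir)
        athletes = pd.read_csv(src / "athletes.csv")
        trials = pd.read_csv(src / "trials.csv")
        long = pd.read_csv(src / "timeseries_long.csv")
        n_trials = len(trials)
        n_frames = len(long) // n_trials
        if sampling_rate is None:
            t = long["time_s"].to_numpy()[:n_frames]
            sampling_rate = float(round(1.0 / (t[1] - t[0])))
        order = {tid: i for i, tid in enumerate(trials["trial_id"])}
        idx = long["trial_id"].map(order).to_numpy()[::n_frames]
        signals = {}
        for ch in cls.SIGNAL_CHANNELS:
            mat = long[ch].to_numpy().reshape(-1, n_frames)
            out = np.empty_like(mat)
            out[idx] = mat
            signals[ch] = out
        return cls(
            sampling_rate=sampling_rate, trials=trials, athletes=athletes, signals=signals
        )


# ---------------------------------------------------------------------------
# feature-level sampling (no time series) — also the fast path for power runs
# ---------------------------------------------------------------------------

def sample_cohort_features(
    config: GeneratorConfig, rng: np.random.Generator | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Draw athletes, injury status, archetypes and trial covariates.

    Returns ``(trials, athletes)`` data frames carrying ground truth and the
    at-contact covariate values, without synthesising any waveform.  Used by
    :func:`make_cohort` (which adds the signals) and directly by power/type-I
    simulation harnesses where only the regression design is needed.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    cov = config.covariates
    n_a, n_t = config.n_athletes, config.trials_per_athlete

    athlete_id = np.array([f"A{i:03d}" for i in range(n_a)])
    sex = np.where(rng.random(n_a) < config.female_fraction, "F", "M")
    mass = np.clip(rng.normal(62.0, 10.0, n_a), 40.0, 95.0)

    injured = np.zeros(n_a, dtype=bool)
    if config.n_injured > 0 and n_a > 0:
        female_idx = np.flatnonzero(sex == "F")
        pool = female_idx if len(female_idx) >= config.n_injured else np.arange(n_a)
        injured[rng.choice(pool, size=config.n_injured, replace=False)] = True

    # injury is recorded per leg: a configurable fraction of injured athletes
    # have both legs injured, the rest one leg (side drawn at random)
    inj_r = np.zeros(n_a, dtype=bool)
    inj_l = np.zeros(n_a, dtype=bool)
    inj_idx = np.flatnonzero(injured)
    n_both = int(round(config.bilateral_fraction * len(inj_idx)))
    for rank, a in enumerate(inj_idx):
        if rank < n_both:
            inj_r[a] = inj_l[a] = True
        elif rng.random() < 0.5:
            inj_r[a] = True
        else:
            inj_l[a] = True

    z = rng.standard_normal(n_a)

    athletes = pd.DataFrame(
        {
            "athlete_id": athlete_id,
            "sex": sex,
            "mass_kg": mass,
            "injured": injured,
            "injured_leg_r": inj_r,
            "injured_leg_l": inj_l,
        }
    )

    n_trials = n_a * n_t
    if n_trials == 0:
        trials = pd.DataFrame(
            columns=TRUTH_TRIAL_COLUMNS
            + [
                "leg_injured",
                "knee_abd_angle_ic",
                "knee_flex_angle_ic",
                "trunk_foot_ml_ic",
                "trunk_foot_ap_ic",
                "impact_grf_n_kg",
                "early_kam_amp",
                "late_kam_amp",
            ]
        )
        return trials, athletes

    a_idx = np.repeat(np.arange(n_a), n_t)
    trial_no = np.tile(np.arange(n_t), n_a)
    leg_is_r = trial_no % 2 == 0
    leg_injured = np.where(leg_is_r, inj_r[a_idx], inj_l[a_idx])

    if config.ep_rate_uninjured is not None and config.ep_rate_injured is not None:
        p0, p1 = config.ep_rate_uninjured, config.ep_rate_injured
    else:
        f_inj = float(leg_injured.mean())
        if config.generating_or == 1.0 or f_inj == 0.0:
            p0 = p1 = config.overall_ep_rate
        else:
            p0, p1 = ep_rates_from_or(config.generating_or, config.overall_ep_rate, f_inj)

    # centre the per-status logits so the heterogeneity-mixed marginal rate
    # still equals p0 / p1 (E_z[expit(l + sd*z)] = p), keeping the overall
    # early-peak trial fraction on target
    l0 = _centered_logit(p0, config.athlete_heterogeneity_sd)
    l1 = _centered_logit(p1, config.athlete_heterogeneity_sd)
    base_logit = np.where(leg_injured, l1, l0)
    propensity = expit(base_logit + config.athlete_heterogeneity_sd * z[a_idx])
    is_ep = rng.random(n_trials) < propensity

    # archetype draw: early-peak trials split between the two early-peak
    # archetypes, other trials among the rest, per the renormalised mixture
    w = np.asarray(config.archetype_mixture, dtype=float)
    arch_ids = np.arange(1, 7)
    ep_mask_arch = np.isin(arch_ids, EARLY_PEAK_ARCHETYPES)
    w_ep = np.where(ep_mask_arch, w, 0.0)
    w_non = np.where(~ep_mask_arch, w, 0.0)
    if w_ep.sum() <= 0 or w_non.sum() <= 0:
        raise InfeasibleConfigError("archetype mixture must weight both early-peak and other shapes")
    w_ep, w_non = w_ep / w_ep.sum(), w_non / w_non.sum()
    u = rng.random(n_trials)
    arch = np.where(
        is_ep,
        arch_ids[np.searchsorted(np.cumsum(w_ep), u, side="right").clip(max=5)],
        arch_ids[np.searchsorted(np.cumsum(w_non), u, side="right").clip(max=5)],
    )

    # covariates: only the knee abduction angle carries an injury effect.
    # For x | injured-leg ~ N(mu0 + delta, sd^2) vs N(mu0, sd^2) otherwise,
    # Bayes' rule gives a logistic model in x with slope delta / sd^2, so
    # delta = log-OR-per-degree * sd^2 targets the configured per-degree OR.
    delta = config.abd_angle_logor_per_deg * cov.knee_abd_sd**2
    abd = rng.normal(cov.knee_abd_mean, cov.knee_abd_sd, n_trials) + delta * leg_injured
    flex = rng.normal(cov.knee_flex_mean, cov.knee_flex_sd, n_trials)
    trunk_ml = rng.normal(cov.trunk_ml_mean, cov.trunk_ml_sd, n_trials)
    trunk_ap = rng.normal(cov.trunk_ap_mean, cov.trunk_ap_sd, n_trials)
    impact = np.clip(
        rng.normal(cov.impact_grf_mean_n_kg, cov.impact_grf_sd_n_kg, n_trials), 8.0, None
    )
    early_amp = np.clip(rng.normal(cov.early_kam_mean, cov.early_kam_sd, n_trials), 0.1, None)
    late_amp = np.clip(rng.normal(cov.late_kam_mean, cov.late_kam_sd, n_trials), 0.2, None)
    # adduction-dominant trials still develop a positive mid-stance abduction
    # bump, only smaller; it must clear the negative early plateau so the
    # stance-phase maximum remains a (positive) late event
    late_amp = np.where(arch == 6, np.clip(rng.normal(0.55, 0.10, n_trials), 0.40, None), late_amp)

    fs = config.sampling_rate
    ic = rng.integers(int(round(0.075 * fs)), int(round(0.125 * fs)) + 1, n_trials)
    stance = rng.uniform(0.55, 0.68, n_trials)
    eos = ic + np.round(stance * fs).astype(int)
    if eos.max() >= config.n_frames:
        raise InfeasibleConfigError("trial_duration too short to contain stance")

    trials = pd.DataFrame(
        {
            "trial_id": [f"A{i // n_t:03d}_t{i % n_t:02d}" for i in range(n_trials)],
            "athlete_id": athlete_id[a_idx],
            "leg": np.where(leg_is_r, "R", "L"),
            "leg_injured": leg_injured,
            "condition": np.where(trial_no < (n_t + 1) // 2, "pre", "post"),
            "true_archetype": arch,
            "true_early_peak": is_ep,
            "true_ic_frame": ic,
            "true_eos_frame": eos,
            "knee_abd_angle_ic": abd,
            "knee_flex_angle_ic": flex,
            "trunk_foot_ml_ic": trunk_ml,
            "trunk_foot_ap_ic": trunk_ap,
            "impact_grf_n_kg": impact,
            "early_kam_amp": early_amp,
            "late_kam_amp": late_amp,
        }
    )
    # consistency: the archetype draw, not the Bernoulli, is authoritative
    trials["true_early_peak"] = trials["true_archetype"].isin(EARLY_PEAK_ARCHETYPES)
    return trials, athletes


# ---------------------------------------------------------------------------
# waveform synthesis
# ---------------------------------------------------------------------------

def _halfcos_rise(t: np.ndarray, span) -> np.ndarray:
    """Smooth 0 -> 1 rise over [0, span], clamped outside; zero for t < 0."""
    x = np.clip(t / span, 0.0, 1.0)
    return np.where(t >= 0.0, 0.5 * (1.0 - np.cos(np.pi * x)), 0.0)


def _rise_fall(t: np.ndarray, rise, fall, amp) -> np.ndarray:
    """Asymmetric raised-cosine bump: 0 -> amp over ``rise``, back to 0 over ``fall``."""
    up = amp * _halfcos_rise(t, rise)
    down = amp * 0.5 * (1.0 + np.cos(np.pi * np.clip((t - rise) / fall, 0.0, 1.0)))
    return np.where(t < rise, up, np.where(t < rise + fall, down, 0.0))


def _kam_clean(
    t_post: np.ndarray,
    arch: np.ndarray,
    early_amp: np.ndarray,
    late_amp: np.ndarray,
    late_center: np.ndarray,
    rise_jitter: np.ndarray,
    stance_s: np.ndarray,
) -> np.ndarray:
    """Noise-free mass-normalised KAM (N.m/kg); rows are trials.

    ``t_post`` is time since initial contact (negative before contact).  Two
    archetypes (2 and 4) contain an early peak: a positive interior maximum
    15-50 ms after contact followed by a decline.  The remaining shapes are a
    monotone rise (1), adduction valleys mirroring the early-peak pair (3
    late, 5 early), and an adduction-dominant monotone decline (6).  All
    shapes add a late-stance abduction bump peaking around 310 ms, so the
    stance-phase maximum usually occurs well after the 100 ms analysis window.
    """
    A = early_amp[:, None]
    L = late_amp[:, None]
    j = rise_jitter[:, None]

    comp = np.zeros_like(t_post)
    m = arch == 1
    if m.any():
        comp[m] = (A[m] * 0.8) * _halfcos_rise(t_post[m], _RISE_A1)
    m = arch == 2
    if m.any():
        comp[m] = _rise_fall(t_post[m], _RISE_A2 + j[m], _FALL_A2, A[m])
    m = arch == 4
    if m.any():
        comp[m] = _rise_fall(t_post[m], _RISE_A4 + j[m], _FALL_A4, 0.9 * A[m])
    m = arch == 3
    if m.any():
        comp[m] = -_rise_fall(t_post[m], _DIP_A3 + j[m], _RECOVER_A3, 0.45 * A[m])
    m = arch == 5
    if m.any():
        comp[m] = -_rise_fall(t_post[m], _DIP_A5 + j[m], _RECOVER_A5, 0.5 * A[m])
    m = arch == 6
    if m.any():
        comp[m] = -(A[m] * 0.8) * _halfcos_rise(t_post[m], _FALL_A6)

    x = np.clip((t_post - late_center[:, None]) / _LATE_WIDTH, -1.0, 1.0)
    late = L * 0.5 * (1.0 + np.cos(np.pi * x))
    late[np.abs(t_post - late_center[:, None]) >= _LATE_WIDTH] = 0.0

    T = stance_s[:, None]
    env = _halfcos_rise(T - t_post, _STANCE_TAPER)  # 1 in stance, tapers to 0 at T
    env[t_post < 0.0] = 0.0
    return env * (comp + late)


def _band_limited_noise(
    rng: np.random.Generator, shape: tuple[int, int], sd: float, fs: float, cutoff: float = 15.0
) -> np.ndarray:
    if sd <= 0.0:
        return np.zeros(shape)
    white = rng.standard_normal(shape)
    b, a = sps.butter(2, cutoff / (fs / 2.0), btype="low")
    filtered = sps.filtfilt(b, a, white, axis=-1)
    scale = filtered.std()
    return filtered * (sd / scale) if scale > 0 else filtered


def synth_waveform(
    archetype: int,
    params: dict | None = None,
    noise_sd: float = 0.0,
    rng: np.random.Generator | None = None,
    *,
    sampling_rate: float = 400.0,
    n_frames: int = 400,
    ic_frame: int = 40,
    eos_frame: int | None = None,
) -> np.ndarray:
    """Synthesise one mass-normalised KAM series for a single trial.

    ``params`` may override ``early_amp``, ``late_amp``, ``late_center``,
    ``rise_jitter`` and ``stance_s``.  Additive band-limited noise with
    standard deviation ``noise_sd`` (N.m/kg) is drawn from ``rng``.
    """
    if archetype not in range(1, 7):
        raise ValueError(f"unknown archetype {archetype!r}; expected 1..6")
    p = {
        "early_amp": 0.45,
        "late_amp": 0.85,
        "late_center": 0.31,
        "rise_jitter": 0.0,
        "stance_s": 0.60 if eos_frame is None else (eos_frame - ic_frame) / sampling_rate,
    }
    if params:
        p.update(params)
    t_post = (np.arange(n_frames)[None, :] - ic_frame) / sampling_rate
    series = _kam_clean(
        t_post,
        np.array([archetype]),
        np.array([p["early_amp"]]),
        np.array([p["late_amp"]]),
        np.array([p["late_center"]]),
        np.array([p["rise_jitter"]]),
        np.array([p["stance_s"]]),
    )[0]
    if noise_sd > 0.0:
        if rng is None:
            rng = np.random.default_rng()
        series = series + _band_limited_noise(rng, (1, n_frames), noise_sd, sampling_rate)[0]
    return series


def synth_vgrf(
    true_ic_frame: int,
    rng: np.random.Generator | None = None,
    *,
    sampling_rate: float = 400.0,
    n_frames: int = 400,
    stance_s: float = 0.5,
    mass_kg: float = 62.0,
    impact_n_kg: float = 18.0,
    pre_noise_amp: float = 2.5,
) -> tuple[np.ndarray, int]:
    """Synthesise one vertical ground reaction force series (N).

    The series is strictly below 10 N before ``true_ic_frame``, exceeds 10 N
    at ``true_ic_frame``, stays at or above 10 N through stance, and drops
    below 10 N at the returned end-of-stance index.
    """
    if rng is None:
        rng = np.random.default_rng()
    eos = true_ic_frame + int(round(stance_s * sampling_rate))
    if not (0 <= true_ic_frame < eos < n_frames):
        raise ValueError("initial contact / stance do not fit in the series")
    series = _vgrf_batch(
        rng,
        np.array([true_ic_frame]),
        np.array([eos]),
        np.array([mass_kg]),
        np.array([impact_n_kg]),
        n_frames,
        sampling_rate,
        pre_noise_amp=pre_noise_amp,
    )[0]
    return series, eos


def _vgrf_batch(
    rng: np.random.Generator,
    ic: np.ndarray,
    eos: np.ndarray,
    mass: np.ndarray,
    impact_n_kg: np.ndarray,
    n_frames: int,
    fs: float,
    pre_noise_amp: float = 2.5,
) -> np.ndarray:
    """Vectorised vGRF synthesis honouring the 10 N threshold contract."""
    n = len(ic)
    frames = np.arange(n_frames)[None, :]
    t_post = (frames - ic[:, None]) / fs
    T = (eos - ic)[:, None] / fs
    tau = np.clip(t_post / T, 0.0, 1.0)

    body = 1.05 * 9.81 * mass[:, None] * np.sin(np.pi * tau) ** 0.8
    imp_c, imp_w = 0.040, 0.035
    x = np.clip((t_post - imp_c) / imp_w, -1.0, 1.0)
    impact = (impact_n_kg * mass)[:, None] * 0.5 * (1.0 + np.cos(np.pi * x))
    impact[np.abs(t_post - imp_c) >= imp_w] = 0.0

    wobble = _band_limited_noise(rng, (n, n_frames), 5.0, fs, cutoff=10.0)
    stance_mask = (frames >= ic[:, None]) & (frames < eos[:, None])
    series = np.where(stance_mask, np.maximum(12.0 + body + impact + wobble, 10.5), 0.0)

    out_noise = np.abs(rng.normal(0.0, pre_noise_amp, (n, n_frames)))
    out_noise = np.clip(out_noise, 0.0, min(9.0, 3.5 * pre_noise_amp))
    series = np.where(stance_mask, series, out_noise)
    return series


def _angle_batch(
    value_ic: np.ndarray, t_post: np.ndarray, swing_amp: float, swing_hz: float
) -> np.ndarray:
    """Channel = at-contact value + a slow sine that vanishes at contact."""
    return value_ic[:, None] + swing_amp * np.sin(2.0 * np.pi * swing_hz * t_post)


def make_cohort(config: GeneratorConfig) -> tuple[Cohort, TruthTable]:
    """Generate a full synthetic cohort: metadata, truth table and signals.

    A single seeded RNG stream drives the whole cohort, with separate draws in
    a fixed order, so identical configs give bit-identical cohorts.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    trials, athletes = sample_cohort_features(config, rng)
    n = len(trials)
    n_frames = config.n_frames
    fs = config.sampling_rate

    if n == 0:
        cohort = Cohort(
            sampling_rate=fs,
            trials=trials,
            athletes=athletes,
            signals={ch: np.zeros((0, n_frames)) for ch in Cohort.SIGNAL_CHANNELS},
        )
        return cohort, cohort.truth

    ic = trials["true_ic_frame"].to_numpy()
    eos = trials["true_eos_frame"].to_numpy()
    arch = trials["true_archetype"].to_numpy()
    mass = athletes.set_index("athlete_id")["mass_kg"].loc[trials["athlete_id"]].to_numpy()

    t_post = (np.arange(n_frames)[None, :] - ic[:, None]) / fs
    stance_s = (eos - ic) / fs

    late_center = np.clip(rng.normal(0.31, 0.02, n), 0.28, 0.36)
    jit = config.rise_jitter_s
    rise_jitter = rng.uniform(-jit, jit, n)
    kam = _kam_clean(
        t_post,
        arch,
        trials["early_kam_amp"].to_numpy(),
        trials["late_kam_amp"].to_numpy(),
        late_center,
        rise_jitter,
        stance_s,
    )
    kam = kam + _band_limited_noise(rng, (n, n_frames), config.noise_sd, fs)

    vgrf = _vgrf_batch(
        rng, ic, eos, mass, trials["impact_grf_n_kg"].to_numpy(), n_frames, fs
    )

    signals = {
        "kam_nm_kg": kam,
        "vgrf_n": vgrf,
        "knee_flex_deg": trials["knee_flex_angle_ic"].to_numpy()[:, None]
        + 25.0 * _halfcos_rise(t_post, 0.30),
        "knee_abd_deg": _angle_batch(trials["knee_abd_angle_ic"].to_numpy(), t_post, 1.5, 1.0),
        "trunk_foot_ml_pct": _angle_batch(trials["trunk_foot_ml_ic"].to_numpy(), t_post, 2.0, 0.8),
        "trunk_foot_ap_pct": _angle_batch(trials["trunk_foot_ap_ic"].to_numpy(), t_post, 3.0, 0.6),
    }

    cohort = Cohort(
        sampling_rate=fs,
        trials=trials,
        athletes=athletes,
        signals=signals,
        kam_normalized=True,
    )
    return cohort, cohort.truth
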