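"""Synthetic call records, respiration traces and tonal audio.

These generators emulate the statistical structure of infant marmoset
recording studies so the full analysis pipeline is testable without any
recordings:

* a developmental dataset (13 subjects, ~244 sessions over postnatal days
  1-60) in which contact-call proportion rises with age while trill and
  twitter proportions fall, and contact syllables lengthen with age;
* a heliox experiment (3 subjects with 19, 19 and 27 sessions, air and
  heliox in counterbalanced order every session) in which heliox boosts
  trill/twitter log-odds and multiplicatively shortens contact syllables;
* tonal waveforms (harmonic stacks in the marmoset F0 band) for the
  spectral operations;
* noisy sinusoid-like respiration traces sampled at 100 Hz.

Every generator is deterministic per seed and emits tables that the
statistics module ingests unchanged.  Durations are log-normal per call
type with medians ordered contact > trill-syllable > twitter-syllable;
per-session call counts are negative binomial (overdispersed); both are
stated generator conventions, not measured quantities.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "DevGenConfig",
    "HelioxGenConfig",
    "RespTrace",
    "gen_development_calls",
    "gen_heliox_sessions",
    "gen_tonal_waveform",
    "gen_respiration",
    "logodds_for_relative_increase",
]

CALL_TYPES = ("contact", "trill", "twitter")


@dataclass(frozen=True)
class DevGenConfig:
    """Developmental-dataset generator settings.

    The call-type mixture is a day-dependent multinomial logit with
    contact as the reference class.  Defaults put the day-1 mixture near
    (contact 0.5, trill 0.2, twitter 0.3) and drive trill/twitter to a
    few percent by day 60, the published developmental trajectory shape.
    Contact syllable duration is log-normal with a median growing
    linearly in age.
    """

    n_subjects: int = 13
    day_min: int = 1
    day_max: int = 60
    total_sessions: int = 244
    calls_per_session_mean: float = 25.0
    calls_per_session_shape: float = 5.0
    trill_logit0: float = -0.874
    trill_logit_slope: float = -0.0463
    twitter_logit0: float = -0.448
    twitter_logit_slope: float = -0.0619
    subject_logit_sd: float = 0.3
    contact_median0_s: float = 0.5
    contact_median_slope_s: float = 1.0 / 60.0
    contact_sigma: float = 0.25
    trill_median_s: float = 0.12
    trill_sigma: float = 0.3
    twitter_median_s: float = 0.05
    twitter_sigma: float = 0.3
    seed: int = 0


@dataclass(frozen=True)
class HelioxGenConfig:
    """Heliox-experiment generator settings.

    Condition effects are the study conditions the analysis must recover:
    heliox adds ``trill_logodds`` / ``twitter_logodds`` to the respective
    mixture logits and multiplies contact syllable durations by
    ``duration_factor``.  The default log-odds boosts are solved (see
    :func:`logodds_for_relative_increase`) so that, under the default
    session design (air mixtures over each subject's session days and
    subject-offset distribution), the expected relative proportion
    increases are 36.5% (trill) and 41.8% (twitter); the
    default duration factor 0.89 encodes the 11% contact shortening.
    Session order alternates air-first/heliox-first (counterbalanced).
    """

    sessions_per_subject: tuple = (19, 19, 27)
    session_day_step: int = 2
    day_min: int = 1
    calls_per_condition_mean: float = 22.0
    calls_per_condition_shape: float = 5.0
    trill_logodds: float = 0.515
    twitter_logodds: float = 0.569
    duration_factor: float = 0.89
    dev: DevGenConfig = field(default_factory=DevGenConfig)
    seed: int = 0


@dataclass
class RespTrace:
    """Uniformly sampled respiration signal."""

    t: np.ndarray
    values: np.ndarray
    sample_rate: float


def _mixture(day, cfg: DevGenConfig, subj_off=(0.0, 0.0), boosts=(0.0, 0.0)):
    """Day-dependent (contact, trill, twitter) probabilities."""
    lr = cfg.trill_logit0 + cfg.trill_logit_slope * day + subj_off[0] + boosts[0]
    lw = cfg.twitter_logit0 + cfg.twitter_logit_slope * day + subj_off[1] + boosts[1]
    w = np.array([1.0, np.exp(lr), np.exp(lw)])
    return w / w.sum()


def logodds_for_relative_increase(
    base_mixtures: np.ndarray, trill_increase: float, twitter_increase: float
) -> tuple:
    """Solve for (trill, twitter) log-odds boosts producing target mean
    relative proportion increases over a set of air mixtures.

    ``base_mixtures`` has one (contact, trill, twitter) row per day/cell.
    Solved by fixed-point iteration on the renormalised softmax; converges
    in a handful of steps for effects of this size.
    """
    base = np.asarray(base_mixtures, float)
    dr = np.log1p(trill_increase)
    dw = np.log1p(twitter_increase)
    for _ in range(200):
        w = base * np.exp([0.0, dr, dw])
        mix = w / w.sum(axis=1, keepdims=True)
        rr = mix[:, 1].mean() / base[:, 1].mean()
        rw = mix[:, 2].mean() / base[:, 2].mean()
        step_r = np.log((1 + trill_increase) / rr)
        step_w = np.log((1 + twitter_increase) / rw)
        dr += step_r
        dw += step_w
        if abs(step_r) < 1e-12 and abs(step_w) < 1e-12:
            break
    return float(dr), float(dw)


def _session_days(cfg: DevGenConfig, rng):
    """Allocate total_sessions across subjects on an even day schedule."""
    base = cfg.total_sessions // cfg.n_subjects
    extra = cfg.total_sessions % cfg.n_subjects
    out = []
    for s in range(cfg.n_subjects):
        n = base + (1 if s < extra else 0)
        days = np.unique(
            np.round(np.linspace(cfg.day_min, cfg.day_max, n)).astype(int)
        )
        out.append(days)
    return out


def _syllable_plan(call_type: str, rng):
    """(n_syllables, gap range) per call: twitters are multi-syllable
    bursts, trills a few syllables, contacts one or two phrases."""
    if call_type == "twitter":
        return int(rng.integers(4, 9)), (0.03, 0.12)
    if call_type == "trill":
        return int(rng.integers(1, 4)), (0.05, 0.2)
    return int(rng.integers(1, 3)), (0.1, 0.35)


def _draw_duration(call_type: str, day: int, cfg: DevGenConfig, rng, factor: float = 1.0):
    if call_type == "contact":
        med = (cfg.contact_median0_s + cfg.contact_median_slope_s * day) * factor
        sigma = cfg.contact_sigma
    elif call_type == "trill":
        med, sigma = cfg.trill_median_s, cfg.trill_sigma
    else:
        med, sigma = cfg.twitter_median_s, cfg.twitter_sigma
    return float(rng.lognormal(np.log(med), sigma))


def _emit_calls(
    rows: list,
    subject: str,
    day: int,
    session: str,
    order: int,
    condition: str,
    n_calls: int,
    cfg: DevGenConfig,
    subj_off,
    boosts,
    duration_factor: float,
    rng,
):
    t = float(rng.uniform(0.0, 2.0))
    probs = _mixture(day, cfg, subj_off, boosts)
    for _ in range(n_calls):
        ct = CALL_TYPES[rng.choice(3, p=probs)]
        n_syl, gap_rng = _syllable_plan(ct, rng)
        dur_factor = duration_factor if ct == "contact" else 1.0
        for _k in range(n_syl):
            dur = _draw_duration(ct, day, cfg, rng, dur_factor)
            rows.append(
                {
                    "subject": subject,
                    "day": int(day),
                    "session": session,
                    "order": order,
                    "condition": condition,
                    "call_type": ct,
                    "onset_s": round(t, 6),
                    "offset_s": round(t + dur, 6),
                }
            )
            t += dur + float(rng.uniform(*gap_rng))
        t += float(rng.uniform(2.0, 8.0))  # inter-call silence (> grouping gap)


def _ncounts(mean, shape, rng, size=None):
    p = shape / (shape + mean)
    draw = rng.negative_binomial(shape, p, size=size)
    return np.maximum(draw, 1)


def gen_development_calls(config: DevGenConfig | None = None) -> pd.DataFrame:
    """Synthetic developmental dataset: one row per syllable.

    Columns: subject, day, session, order, condition (all ``air``),
    call_type, onset_s, offset_s.  Deterministic per config seed.
    """
    cfg = config or DevGenConfig()
    rng = np.random.default_rng(cfg.seed)
    rows: list = []
    for s, days in enumerate(_session_days(cfg, rng)):
        subject = f"dev{s + 1:02d}"
        off = rng.normal(0.0, cfg.subject_logit_sd, size=2)
        for j, day in enumerate(days):
            n_calls = int(_ncounts(cfg.calls_per_session_mean, cfg.calls_per_session_shape, rng))
            _emit_calls(
                rows, subject, day, f"{subject}_s{j + 1:02d}", 1, "air",
                n_calls, cfg, off, (0.0, 0.0), 1.0, rng,
            )
    return pd.DataFrame(rows)


def gen_heliox_sessions(config: HelioxGenConfig | None = None) -> pd.DataFrame:
    """Synthetic heliox experiment: one row per syllable.

    Each session contains both conditions; ``order`` records which came
    first (1 or 2) with the leading condition alternating by session.
    Heliox boosts the trill/twitter logits and shortens contact syllables
    by ``duration_factor``.  Deterministic per config seed.
    """
    cfg = config or HelioxGenConfig()
    dev = cfg.dev
    rng = np.random.default_rng(cfg.seed)
    rows: list = []
    for s, n_sessions in enumerate(cfg.sessions_per_subject):
        subject = f"hx{s + 1}"
        off = rng.normal(0.0, dev.subject_logit_sd, size=2)
        for j in range(n_sessions):
            day = cfg.day_min + cfg.session_day_step * j
            session = f"{subject}_s{j + 1:02d}"
            heliox_first = (j + s) % 2 == 0
            conds = ("heliox", "air") if heliox_first else ("air", "heliox")
            for order, cond in enumerate(conds, start=1):
                n_calls = int(
                    _ncounts(cfg.calls_per_condition_mean, cfg.calls_per_condition_shape, rng)
                )
                boosts = (
                    (cfg.trill_logodds, cfg.twitter_logodds)
                    if cond == "heliox"
                    else (0.0, 0.0)
                )
                d_factor = cfg.duration_factor if cond == "heliox" else 1.0
                _emit_calls(
                    rows, subject, day, session, order, cond,
                    n_calls, dev, off, boosts, d_factor, rng,
                )
    return pd.DataFrame(rows)


def gen_tonal_waveform(
    f0_hz: float,
    harmonic_amplitudes,
    duration_s: float,
    sample_rate: float = 44100.0,
    noise_sd: float = 0.0,
    seed: int | None = None,
) -> np.ndarray:
    """Harmonic stack: sum_k a_k sin(2 pi k f0 t), optional noise floor.

    Raises ValueError when any harmonic reaches the Nyquist frequency.
    """
    amps = np.asarray(harmonic_amplitudes, float)
    if amps.size == 0:
        raise ValueError("need at least one harmonic amplitude")
    top = f0_hz * amps.size
    if top >= sample_rate / 2:
        raise ValueError(
            f"harmonic {amps.size} at {top:.0f} Hz reaches Nyquist ({sample_rate / 2:.0f} Hz)"
        )
    t = np.arange(int(round(duration_s * sample_rate))) / sample_rate
    x = np.zeros_like(t)
    for k, a in enumerate(amps, start=1):
        x += a * np.sin(2 * np.pi * k * f0_hz * t)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        x = x + rng.normal(0.0, noise_sd, size=t.size)
    return x


def gen_respiration(
    cycle_rate_hz: float,
    duration_s: float,
    noise_sd: float = 0.1,
    seed: int | None = None,
    sample_rate: float = 100.0,
) -> RespTrace:
    """Noisy sinusoid-like respiration trace (100 Hz sampling).

    The rate statistic recovers ``cycle_rate_hz`` within ~5% for
    noise_sd <= 0.2.
    """
    if cycle_rate_hz <= 0:
        raise ValueError("cycle_rate_hz must be positive")
    rng = np.random.default_rng(seed)
    t = np.arange(int(round(duration_s * sample_rate))) / sample_rate
    phase = rng.uniform(0, 2 * np.pi)
    x = np.sin(2 * np.pi * cycle_rate_hz * t + phase)
    if noise_sd > 0:
        x = x + rng.normal(0.0, noise_sd, size=t.size)
    return RespTrace(t=t, values=x, sample_rate=sample_rate)
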