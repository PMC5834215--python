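"""Statistical pipeline for the heliox experiment.

Call records (one row per syllable: subject, postnatal day, session,
condition air/heliox, call type, onset/offset) are grouped into calls,
summarised as per-condition call-type proportions, and tested with the
study's models:

* occurrence of a target call type: binomial GLM with logit link,
  ``logit(P(type)) = alpha + beta1*S2 + beta2*S3 + beta3*I_heliox``,
  with subject dummies S2/S3 and the condition indicator; the effect size
  of the condition term is the AUC ratio
  ``r = (AUC_c - AUC_0) / (AUC_0 - 0.5)`` comparing ROC areas of the model
  with and without the condition variable;
* contact-syllable duration: each syllable's duration is expressed as a
  fraction of the same subject's same-day mean duration in air, and an
  identity-link linear model with the same design estimates the
  fractional change under heliox; effect size is Cohen's f^2;
* call rate: Wilcoxon signed-rank test on paired per-session air/heliox
  rates (an arousal control — heliox should not change how much the
  animal calls);
* spectrum: Welch PSD per syllable, F0 = first spectral peak,
  F1 = second peak, and the F1/F0 amplitude ratio in dB (heliox boosts
  the second harmonic via the vocal-tract resonance shift);
* respiration: cycles per second of an extracted respiratory trace over
  the union of call windows.

No multiple-testing correction is applied anywhere: the pipeline reports
raw per-model p-values, mirroring how the individual tests are used.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import signal
from scipy.stats import wilcoxon
from sklearn.metrics import roc_auc_score

__all__ = [
    "REQUIRED_COLUMNS",
    "OccurrenceGLM",
    "DurationGLM",
    "PSDResult",
    "group_syllables",
    "condition_proportions",
    "fit_occurrence_glm",
    "auc_effect_ratio",
    "fit_duration_model",
    "cohens_f2",
    "call_rate_test",
    "welch_spectrum",
    "harmonic_metrics",
    "respiration_rate",
]

REQUIRED_COLUMNS = ("subject", "day", "session", "condition", "call_type", "onset_s", "offset_s")


def group_syllables(records: pd.DataFrame, max_gap_s: float = 0.5) -> pd.DataFrame:
    """Merge consecutive same-type syllables into calls.

    Within each (subject, session, condition), syllables of the same call
    type separated by gaps of at most ``max_gap_s`` (0.5 s) belong to one
    call.  A different call type always starts a new call, whatever the
    gap.  Returns one row per call with the call span (onset of first to
    offset of last syllable), the number of syllables, and
    ``syllable_total_s`` (summed syllable durations, i.e. phonation time).

    Raises ValueError on overlapping syllables within a group.
    """
    req = [c for c in REQUIRED_COLUMNS if c not in records.columns]
    if req:
        raise ValueError(f"missing columns: {req}")
    out = []
    group_cols = ["subject", "session", "condition"]
    carry = [c for c in ("day", "order") if c in records.columns]
    for keys, grp in records.groupby(group_cols, sort=False):
        grp = grp.sort_values("onset_s")
        onsets = grp["onset_s"].to_numpy(float)
        offsets = grp["offset_s"].to_numpy(float)
        if np.any(offsets[:-1] > onsets[1:] + 1e-12):
            idx = int(np.argmax(offsets[:-1] > onsets[1:] + 1e-12))
            raise ValueError(
                f"overlapping syllables in {dict(zip(group_cols, keys))} near onset {onsets[idx + 1]}"
            )
        types = grp["call_type"].to_numpy()
        new_call = np.ones(len(grp), dtype=bool)
        if len(grp) > 1:
            gaps = onsets[1:] - offsets[:-1]
            same = types[1:] == types[:-1]
            new_call[1:] = ~(same & (gaps <= max_gap_s))
        call_id = np.cumsum(new_call) - 1
        for cid in np.unique(call_id):
            m = call_id == cid
            rec = {
                "subject": keys[0],
                "session": keys[1],
                "condition": keys[2],
                "call_type": types[m][0],
                "onset_s": float(onsets[m][0]),
                "offset_s": float(offsets[m][-1]),
                "n_syllables": int(m.sum()),
                "syllable_total_s": float(np.sum(offsets[m] - onsets[m])),
            }
            for c in carry:
                rec[c] = grp[c].iloc[int(np.argmax(m))]
            out.append(rec)
    calls = pd.DataFrame(out)
    return calls.sort_values(["subject", "session", "onset_s"]).reset_index(drop=True)


def condition_proportions(calls: pd.DataFrame, pair_window: int = 2) -> pd.DataFrame:
    """Call-type proportions per (subject, session-pair, condition).

    Sessions are paired in chronological blocks of ``pair_window``
    consecutive sessions (the counterbalanced design alternates which
    condition comes first), and within each block the proportion of each
    call type is the number of calls of that type divided by the total
    calls in that condition.  The abscissa ``day`` is the mean of the
    paired sessions' postnatal days.  Empty condition cells are omitted.
    """
    rows = []
    for subj, grp in calls.groupby("subject", sort=False):
        sessions = np.sort(grp["session"].unique())
        for b0 in range(0, len(sessions), pair_window):
            block = sessions[b0:b0 + pair_window]
            sub = grp[grp["session"].isin(block)]
            day = float(sub["day"].mean()) if "day" in sub.columns else np.nan
            for cond, cell in sub.groupby("condition", sort=False):
                total = len(cell)
                if total == 0:
                    continue
                counts = cell["call_type"].value_counts()
                for ct in ("contact", "trill", "twitter"):
                    rows.append(
                        {
                            "subject": subj,
                            "pair": b0 // pair_window,
                            "day": day,
                            "condition": cond,
                            "call_type": ct,
                            "proportion": float(counts.get(ct, 0)) / total,
                            "n_calls": total,
                        }
                    )
    return pd.DataFrame(rows)


def _design_matrix(df: pd.DataFrame) -> pd.DataFrame:
    """Intercept + subject dummies (first subject is reference) + condition."""
    subjects = np.sort(df["subject"].unique())
    X = pd.DataFrame(index=df.index)
    X["const"] = 1.0
    for i, s in enumerate(subjects[1:], start=2):
        X[f"S{i}"] = (df["subject"] == s).astype(float)
    X["heliox"] = (df["condition"] == "heliox").astype(float)
    return X


@dataclass
class OccurrenceGLM:
    """Logistic occurrence model for one call type.

    ``params``/``bse``/``pvalues`` are indexed by term name; the condition
    term is ``heliox`` (its coefficient is the log-odds change under
    heliox).  ``effect_size_r`` is the AUC ratio of the condition term.
    ``separation`` flags (quasi-)perfect separation.
    """

    target: str
    params: pd.Series
    bse: pd.Series
    pvalues: pd.Series
    effect_size_r: float | None = None
    separation: bool = False
    model_result: object = field(default=None, repr=False)
    reduced_result: object = field(default=None, repr=False)

    @property
    def beta3(self) -> float:
        return float(self.params["heliox"])

    @property
    def beta3_se(self) -> float:
        return float(self.bse["heliox"])


def fit_occurrence_glm(calls: pd.DataFrame, target_type: str) -> OccurrenceGLM:
    """Binomial GLM for the occurrence of ``target_type`` among calls.

    One row per call (post-grouping); the response is the indicator that
    the call is of the target type.  Predictors: intercept, subject
    dummies, heliox indicator.  The AUC-ratio effect size compares the
    full model with the one lacking the condition term.
    """
    if calls["subject"].nunique() < 2:
        raise ValueError("need >= 2 subjects to fit subject dummies")
    if set(calls["condition"].unique()) != {"air", "heliox"}:
        raise ValueError("both conditions must be present")
    y = (calls["call_type"] == target_type).astype(float)
    X = _design_matrix(calls)

    import warnings
    from statsmodels.tools.sm_exceptions import PerfectSeparationWarning

    separation = False
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        full = sm.GLM(y, X, family=sm.families.Binomial()).fit()
        reduced = sm.GLM(y, X.drop(columns="heliox"), family=sm.families.Binomial()).fit()
        separation = any(issubclass(w.category, PerfectSeparationWarning) for w in caught)
    if np.any(np.abs(full.params) > 15):  # runaway logit coefficients
        separation = True

    r = None
    try:
        r = auc_effect_ratio(
            full.fittedvalues.to_numpy(), reduced.fittedvalues.to_numpy(), y.to_numpy()
        )
    except ValueError:
        pass
    return OccurrenceGLM(
        target=target_type,
        params=full.params,
        bse=full.bse,
        pvalues=full.pvalues,
        effect_size_r=r,
        separation=separation,
        model_result=full,
        reduced_result=reduced,
    )


def auc_effect_ratio(p_full, p_reduced, outcomes) -> float:
    """AUC-ratio effect size r = (AUC_c - AUC_0) / (AUC_0 - 0.5).

    ``p_full``/``p_reduced`` are fitted probabilities of the models with
    and without the condition term on identical rows; AUCs are in-sample
    ROC areas against the observed indicator.  The 0.5 in the denominator
    discounts chance-level discrimination.  Undefined (ValueError) when
    the reduced model does not beat chance.
    """
    outcomes = np.asarray(outcomes, float)
    auc_c = roc_auc_score(outcomes, np.asarray(p_full, float))
    auc_0 = roc_auc_score(outcomes, np.asarray(p_reduced, float))
    if auc_0 <= 0.5:
        raise ValueError(f"reduced-model AUC {auc_0:.3f} <= 0.5; ratio undefined")
    return float((auc_c - auc_0) / (auc_0 - 0.5))


@dataclass
class DurationGLM:
    """Linear model for fractional contact-syllable duration.

    ``beta3`` is the mean fractional-duration change under heliox
    (e.g. -0.11 for an 11% shortening).  ``dropped_days`` lists
    (subject, day) cells excluded because no air calls anchored the
    daily normalisation.
    """

    params: pd.Series
    bse: pd.Series
    pvalues: pd.Series
    cohens_f2: float
    power: float | None = None
    dropped_days: list = field(default_factory=list)
    model_result: object = field(default=None, repr=False)

    @property
    def beta3(self) -> float:
        return float(self.params["heliox"])

    @property
    def beta3_se(self) -> float:
        return float(self.bse["heliox"])


def fit_duration_model(contact_syllables: pd.DataFrame, alpha: float = 0.05) -> DurationGLM:
    """Identity-link linear model for fractional contact-syllable duration.

    Each syllable's duration is divided by the mean duration of the same
    subject's air-condition syllables on the same day; days without air
    calls for a subject are dropped (and reported).  Fits
    ``d = alpha + beta1*S2 + beta2*S3 + beta3*I_heliox + eps`` by OLS.
    Cohen's f^2 for the condition term compares R^2 of the full and
    condition-free models; power is the analytic power of the partial
    F-test at level ``alpha``.
    """
    df = contact_syllables.copy()
    df["duration_s"] = df["offset_s"] - df["onset_s"]
    air_mean = (
        df[df["condition"] == "air"]
        .groupby(["subject", "day"])["duration_s"]
        .mean()
        .rename("air_mean_s")
    )
    df = df.join(air_mean, on=["subject", "day"])
    dropped = (
        df.loc[df["air_mean_s"].isna(), ["subject", "day"]]
        .drop_duplicates()
        .itertuples(index=False, name=None)
    )
    dropped = sorted(dropped)
    df = df.dropna(subset=["air_mean_s"])
    if df.empty:
        raise ValueError("no (subject, day) cell has air-condition contact calls")
    d = df["duration_s"] / df["air_mean_s"]
    X = _design_matrix(df)
    full = sm.OLS(d.to_numpy(), X).fit()
    reduced = sm.OLS(d.to_numpy(), X.drop(columns="heliox")).fit()
    if float(np.var(d)) < 1e-20:
        f2 = 0.0  # constant response: nothing to explain
    elif 1.0 - full.rsquared < 1e-12:
        # noiseless construction: the design explains everything
        f2 = 0.0 if full.rsquared - reduced.rsquared < 1e-12 else float("inf")
    else:
        f2 = cohens_f2(full.rsquared, max(reduced.rsquared, 0.0))

    # analytic power of the partial F-test for the condition term
    from scipy.stats import ncf, f as f_dist

    n, k = X.shape
    if not np.isfinite(f2):
        power = 1.0
    else:
        ncp = f2 * n
        crit = f_dist.ppf(1 - alpha, 1, n - k)
        power = float(1.0 - ncf.cdf(crit, 1, n - k, ncp))
    return DurationGLM(
        params=full.params,
        bse=full.bse,
        pvalues=full.pvalues,
        cohens_f2=f2,
        power=power,
        dropped_days=list(dropped),
        model_result=full,
    )


def cohens_f2(r2_full: float, r2_reduced: float) -> float:
    """Cohen's f^2 = (R2_full - R2_reduced) / (1 - R2_full)."""
    if not 0 <= r2_reduced <= r2_full:
        raise ValueError("need 0 <= r2_reduced <= r2_full")
    if r2_full >= 1:
        raise ValueError("f^2 undefined at R2_full = 1")
    return (r2_full - r2_reduced) / (1.0 - r2_full)


def call_rate_test(air_rates, heliox_rates):
    """Wilcoxon signed-rank test on paired per-session call rates.

    Returns (statistic, p).  All-zero differences (identical rates) give
    p = 1.0 by convention: no evidence of a shift.  Fewer than 5 pairs
    emit a UserWarning (the test has essentially no power there).
    """
    import warnings

    air = np.asarray(air_rates, float)
    hel = np.asarray(heliox_rates, float)
    if air.shape != hel.shape:
        raise ValueError("paired rates must have equal length")
    if air.size < 5:
        warnings.warn(f"only {air.size} pairs: signed-rank test is near-powerless")
    diffs = hel - air
    if np.allclose(diffs, 0):
        return 0.0, 1.0
    stat, p = wilcoxon(hel, air)
    return float(stat), float(p)


@dataclass
class PSDResult:
    """Welch spectrum with harmonic landmarks (filled by harmonic_metrics)."""

    freqs: np.ndarray
    psd: np.ndarray
    f0: float | None = None
    f1: float | None = None
    f1_f0_ratio_db: float | None = None


def welch_spectrum(
    waveform: np.ndarray,
    sample_rate: float,
    nperseg: int = 1024,
    overlap: float = 0.5,
    window: str = "hann",
) -> PSDResult:
    """Welch power spectral density of one syllable's waveform.

    Mean-removed, Hann-tapered 1024-sample segments with 50% overlap by
    default.  The syllable must span at least two segments.  NaN or
    infinite samples are rejected.
    """
    x = np.asarray(waveform, float)
    if not np.all(np.isfinite(x)):
        raise ValueError("waveform contains NaN or infinite samples")
    noverlap = int(round(nperseg * overlap))
    if x.size < nperseg + (nperseg - noverlap):
        raise ValueError(
            f"syllable too short: {x.size} samples < 2 Welch windows "
            f"({nperseg} with {noverlap} overlap)"
        )
    freqs, psd = signal.welch(
        x, fs=sample_rate, window=window, nperseg=nperseg, noverlap=noverlap,
        detrend="constant",
    )
    return PSDResult(freqs=freqs, psd=psd)


def harmonic_metrics(
    psd: PSDResult,
    min_prominence_frac: float = 1e-3,
    convention: str = "amplitude",
) -> PSDResult:
    """Locate F0 (first spectral peak) and F1 (second peak) and their ratio.

    The ratio is reported in dB.  Under the default ``amplitude``
    convention it is 20*log10 of the amplitude ratio, computed as
    10*log10 of the PSD (power) ratio — on a power spectrum the two
    conventions coincide numerically; ``power`` is accepted as an alias
    and gives the same value.  A single-peak spectrum leaves ``f1`` and
    the ratio as None.
    """
    if convention not in ("amplitude", "power"):
        raise ValueError("convention must be 'amplitude' or 'power'")
    peaks, _ = signal.find_peaks(psd.psd, prominence=min_prominence_frac * psd.psd.max())
    if peaks.size == 0:
        raise ValueError("no spectral peaks found")

    def band_power(i):
        # +-1 bin around the peak: spectral leakage splits an off-bin tone
        # across neighbours, so a single-bin read underestimates it
        lo, hi = max(i - 1, 0), min(i + 2, psd.psd.size)
        return float(np.sum(psd.psd[lo:hi]))

    f0 = float(psd.freqs[peaks[0]])
    out = PSDResult(freqs=psd.freqs, psd=psd.psd, f0=f0)
    if peaks.size >= 2:
        out.f1 = float(psd.freqs[peaks[1]])
        out.f1_f0_ratio_db = float(
            10.0 * np.log10(band_power(peaks[1]) / band_power(peaks[0]))
        )
    return out


def respiration_rate(
    trace: np.ndarray,
    call_windows,
    sample_rate: float = 100.0,
    min_prominence_frac: float = 0.2,
):
    """Respiratory cycles per second over the union of call windows.

    ``trace`` is a uniformly sampled respiration signal (100 Hz in the
    study's video extraction); ``call_windows`` is an iterable of
    (onset_s, offset_s).  Cycles are counted by peak detection restricted
    to samples inside the (merged, overlap-safe) windows and divided by
    the total call duration.  Returns (rate_hz, n_cycles); a trace with
    no detectable peaks returns rate 0.0 with n_cycles 0.
    """
    x = np.asarray(trace, float)
    windows = sorted((float(a), float(b)) for a, b in call_windows)
    if not windows or any(b <= a for a, b in windows):
        raise ValueError("call windows must be non-empty with offset > onset")
    merged = [list(windows[0])]
    for a, b in windows[1:]:
        if a <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], b)
        else:
            merged.append([a, b])
    total = sum(b - a for a, b in merged)
    # count peaks segment by segment so window edges never create peaks
    n_cycles = 0
    for a, b in merged:
        i0, i1 = int(a * sample_rate), min(int(b * sample_rate) + 1, x.size)
        chunk = x[i0:i1]
        if chunk.size < 3:
            continue
        pk, _ = signal.find_peaks(chunk, prominence=min_prominence_frac * max(np.ptp(chunk), 1e-12))
        n_cycles += pk.size
    return (n_cycles / total if total > 0 else 0.0), int(n_cycles)
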