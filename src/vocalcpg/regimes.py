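"""Call-type regime classification and the (I, gamma1) regime diagram.

A simulated trace is assigned one of the marmoset call types from the
oscillatory structure of its two CPGs:

* laryngeal CPG at a fixed point (x2 essentially flat) -> **contact** call
  (immature at low drive, mature at high drive);
* laryngeal CPG on a limit cycle with the respiratory trace only weakly
  modulated at laryngeal rates -> **trill**;
* laryngeal limit cycle that breaks respiration into fast "minibreaths"
  (strong high-frequency power in x1) -> **twitter**.

Sweeping the relative drive I over [0, 1] at each respiratory time constant
gamma1 produces the regime diagram; the fraction of the I interval occupied
by each call type is that type's simulated proportion.  Because gamma1
stands in for (inverse) lung size, the proportion-versus-gamma1 curves are
the model's developmental trajectories.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cpg import CPGParams, SimTrace, rk4_batch

__all__ = [
    "CALL_TYPES",
    "COLLAPSED_TYPES",
    "RegimeThresholds",
    "RegimeDiagram",
    "ProportionCurve",
    "collapse_call_type",
    "dominant_frequency",
    "classify_regime",
    "sweep_regime_diagram",
    "proportions_from_diagram",
]

CALL_TYPES = ("contact_immature", "contact_mature", "trill", "twitter")
COLLAPSED_TYPES = ("contact", "trill", "twitter")

#: label used for grid cells whose integration blew up
ERROR_LABEL = "error"


def collapse_call_type(label: str) -> str:
    """Map the four-way labels onto {contact, trill, twitter}."""
    if label.startswith("contact"):
        return "contact"
    return label


@dataclass(frozen=True)
class RegimeThresholds:
    """Classification cutoffs (the published regions give no numeric values;
    these defaults reproduce the qualitative diagram layout and are exposed
    in config).

    The call-type label is read off the respiratory trace x1, whose rhythm
    sets call duration: twitter when the minibreath-scale rhythm dominates
    x1, trill when the breathing rhythm is shortened relative to the intact
    gamma1-implied rate while the laryngeal CPG oscillates, contact when
    breathing stays slow and intact.

    fast_band_hz : x1 spectral components at or above this frequency count
        as minibreath-scale.  A fixed 1.5 Hz sits between the fastest
        intact breathing fundamental (~gamma1 / 6.66 ~ 0.5 Hz) and the
        slowest laryngeal modulation (~2 Hz); it is deliberately not tied
        to gamma1, because harmonics of the relaxation-shaped slow breath
        leak well above any multiple of the fundamental.
    lar_osc_min : minimum fast-band (high-passed) x2 peak-to-peak amplitude
        to call the laryngeal CPG oscillating.
    resp_mod_min : minimum relative fast-band power in x1 for the
        minibreath rhythm to count as dominating (twitter).
    trill_factor : breathing counts as shortened (trill) when the measured
        mean breath period falls below 1/trill_factor of the intact
        gamma1-implied period.
    resp_period_scale : the uncoupled oscillator's relaxation period is
        ``resp_period_scale / gamma`` seconds (~6.66/gamma, the classic
        van der Pol unit-mu period); sets the gamma1-implied intact rate.
    breath_prominence : minimum peak prominence for a local x1 maximum to
        count as a breath (full breaths swing ~4 peak-to-peak).
    min_breath_s : minimum spacing between counted breaths.
    """

    fast_band_hz: float = 1.5
    lar_osc_min: float = 0.5
    resp_mod_min: float = 0.5
    trill_factor: float = 1.35
    resp_period_scale: float = 6.66
    breath_prominence: float = 1.5
    min_breath_s: float = 0.3

    def __post_init__(self):
        if min(self.fast_band_hz, self.lar_osc_min, self.resp_mod_min,
               self.trill_factor, self.resp_period_scale,
               self.breath_prominence, self.min_breath_s) <= 0:
            raise ValueError("all thresholds must be strictly positive")

    def intact_breathing_hz(self, gamma1: float) -> float:
        return gamma1 / self.resp_period_scale


def dominant_frequency(series: np.ndarray, dt: float, power_floor: float = 1e-10) -> float:
    """Frequency (Hz) of the largest non-DC spectral peak of the series.

    The series is mean-detrended before the FFT.  Returns 0.0 when the
    non-DC power never rises above ``power_floor`` times the squared data
    scale — the fixed-point case.
    """
    x = np.asarray(series, dtype=float)
    if x.size < 64:
        raise ValueError(f"need at least 64 samples, got {x.size}")
    x = x - x.mean()
    spec = np.abs(np.fft.rfft(x)) ** 2
    freqs = np.fft.rfftfreq(x.size, d=dt)
    spec[0] = 0.0
    scale = max(np.max(np.abs(x)) ** 2, 1.0)
    if spec.max() < power_floor * scale * x.size:
        return 0.0
    return float(freqs[np.argmax(spec)])


def _fast_band_fraction(x: np.ndarray, dt: float, fast_band_hz: float) -> float:
    """Fraction of non-DC spectral power of ``x`` above ``fast_band_hz``."""
    x = np.asarray(x, dtype=float) - np.mean(x)
    spec = np.abs(np.fft.rfft(x)) ** 2
    freqs = np.fft.rfftfreq(x.size, d=dt)
    spec[0] = 0.0
    total = spec.sum()
    if total <= 0:
        return 0.0
    return float(spec[freqs >= fast_band_hz].sum() / total)


def _highpass_ptp(x: np.ndarray, dt: float, cutoff_hz: float) -> float:
    """Peak-to-peak of the components of ``x`` at or above ``cutoff_hz``."""
    x = np.asarray(x, dtype=float)
    X = np.fft.rfft(x - x.mean())
    freqs = np.fft.rfftfreq(x.size, d=dt)
    X[freqs < cutoff_hz] = 0.0
    return float(np.ptp(np.fft.irfft(X, x.size)))


def _mean_breath_period(x1: np.ndarray, dt: float, thresholds: RegimeThresholds) -> float:
    """Mean interval between prominent x1 maxima (s); NaN when < 3 breaths."""
    from scipy.signal import find_peaks

    peaks, _ = find_peaks(
        np.asarray(x1, float),
        prominence=thresholds.breath_prominence,
        distance=max(1, int(round(thresholds.min_breath_s / dt))),
    )
    if peaks.size < 3:
        return float("nan")
    return float(np.mean(np.diff(peaks)) * dt)


def _classify_arrays(
    x1: np.ndarray,
    x2: np.ndarray,
    mean_I: float,
    dt: float,
    gamma1: float,
    thresholds: RegimeThresholds,
) -> str:
    frac = _fast_band_fraction(x1, dt, thresholds.fast_band_hz)
    if frac >= thresholds.resp_mod_min:
        return "twitter"
    period = _mean_breath_period(x1, dt, thresholds)
    intact_period = 1.0 / thresholds.intact_breathing_hz(gamma1)
    shortened = np.isfinite(period) and period <= intact_period / thresholds.trill_factor
    if shortened and _highpass_ptp(x2, dt, thresholds.fast_band_hz) >= thresholds.lar_osc_min:
        return "trill"
    return "contact_immature" if mean_I < 0.5 else "contact_mature"


def classify_regime(
    trace: SimTrace, thresholds: RegimeThresholds, gamma1: float
) -> str:
    """Classify a post-burn-in trace into a call-type regime.

    The label is read off the respiratory rhythm, which sets call duration:

    * the minibreath-scale rhythm dominates x1 (relative fast-band power
      >= ``resp_mod_min``) -> **twitter**: respiration broken into
      minibreaths;
    * the mean breath period is shortened below 1/``trill_factor`` of the
      intact gamma1-implied period while the laryngeal CPG oscillates ->
      **trill**;
    * otherwise breathing is slow and intact -> **contact**, immature when
      the mean drive lies below 0.5 and mature above.

    ``gamma1`` is the respiratory time constant used to produce the trace;
    it sets the intact breathing period the trill rule compares against.
    """
    return _classify_arrays(
        trace.x1, trace.x2, float(np.mean(trace.I)), trace.dt, gamma1, thresholds
    )


@dataclass
class RegimeDiagram:
    """Call-type label per (gamma1, I) grid cell."""

    gamma1_grid: np.ndarray
    I_grid: np.ndarray
    labels: np.ndarray  # shape (len(gamma1_grid), len(I_grid)), dtype object/str

    def __post_init__(self):
        if self.labels.shape != (len(self.gamma1_grid), len(self.I_grid)):
            raise ValueError("labels shape must be (n_gamma1, n_I)")

    def to_dataframe(self) -> pd.DataFrame:
        g, i = np.meshgrid(self.gamma1_grid, self.I_grid, indexing="ij")
        return pd.DataFrame(
            {"gamma1": g.ravel(), "I": i.ravel(), "label": self.labels.ravel()}
        )

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)


@dataclass
class ProportionCurve:
    """Call-type proportions against an abscissa (gamma1 or postnatal day).

    ``df`` has the abscissa as its first column and one column per
    collapsed call type (plus the contact sub-variants when available);
    every proportion lies in [0, 1] and the collapsed types sum to <= 1
    per row (cells that failed to integrate count toward no type).
    """

    abscissa: str
    df: pd.DataFrame

    def proportions(self, call_type: str) -> np.ndarray:
        return self.df[call_type].to_numpy()

    def to_csv(self, path) -> None:
        self.df.to_csv(path, index=False)


def sweep_regime_diagram(
    gamma1_grid,
    I_grid,
    params: CPGParams | None = None,
    thresholds: RegimeThresholds | None = None,
    dt: float = 0.01,
    n_burn: int = 500,
    n_keep: int = 2000,
) -> RegimeDiagram:
    """Classify every (gamma1, I) grid cell under constant drive.

    Each cell is integrated with the fixed-step RK4 protocol (500 burn-in +
    2000 kept steps at dt = 0.01 by default) at constant relative drive and
    classified by :func:`classify_regime`.  Cells are integrated in one
    vectorised batch per gamma1 row.  Deterministic.  Blow-ups are recorded
    as ``"error"`` labels rather than aborting the sweep.
    """
    params = params or CPGParams()
    gamma1_grid = np.asarray(gamma1_grid, dtype=float)
    I_grid = np.asarray(I_grid, dtype=float)
    if gamma1_grid.size == 0 or I_grid.size == 0:
        raise ValueError("grids must be non-empty")

    a1 = params.resp.a_min + I_grid * (params.resp.a_max - params.resp.a_min)
    a2 = params.lar.a_min + I_grid * (params.lar.a_max - params.lar.a_min)

    th = thresholds or RegimeThresholds()
    labels = np.empty((gamma1_grid.size, I_grid.size), dtype=object)
    for gi, g1 in enumerate(gamma1_grid):
        x1, x2, bad = rk4_batch(
            a1,
            a2,
            np.full_like(a1, g1),
            params.lar.gamma,
            params.resp.coupling_in,
            params.lar.coupling_in,
            dt=dt,
            n_burn=n_burn,
            n_keep=n_keep,
        )
        for ii in range(I_grid.size):
            if bad[ii]:
                labels[gi, ii] = ERROR_LABEL
            else:
                labels[gi, ii] = _classify_arrays(x1[ii], x2[ii], I_grid[ii], dt, g1, th)
    return RegimeDiagram(gamma1_grid=gamma1_grid, I_grid=I_grid, labels=labels)


#: default sweep grids: the constant-drive diagram's dynamic range.  Under
#: sustained drive the transition from intact slow breathing to
#: laryngeal-entrained fast breathing crosses gamma1 ~ 1.6-2.2, so the
#: developmental sweep covers [1.2, 2.4]; I covers its full [0, 1] span.
DEFAULT_GAMMA1_GRID = np.round(np.arange(1.2, 2.4001, 0.025), 6)
DEFAULT_I_GRID = np.round(np.arange(0.0, 1.0001, 0.01), 6)


def proportions_from_diagram(diagram: RegimeDiagram) -> ProportionCurve:
    """Per-gamma1 call proportions: the fraction of the I in [0, 1] range
    occupied by each call type's regime."""
    rows = []
    n_I = diagram.I_grid.size
    for gi, g1 in enumerate(diagram.gamma1_grid):
        row_labels = diagram.labels[gi]
        rec = {"gamma1": g1}
        for ct in CALL_TYPES:
            rec[ct] = float(np.sum(row_labels == ct)) / n_I
        rec["contact"] = rec["contact_immature"] + rec["contact_mature"]
        rows.append(rec)
    df = pd.DataFrame(rows)[
        ["gamma1", "contact", "trill", "twitter", "contact_immature", "contact_mature"]
    ]
    return ProportionCurve(abscissa="gamma1", df=df)
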