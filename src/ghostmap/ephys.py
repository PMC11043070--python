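"""Intrinsic-feature extraction and hormone-response classification.

Whole-cell current-clamp recordings are reduced to resting membrane
potential (RMP, mV), input resistance (Ri, MOhm, from hyperpolarizing
current steps or -5 pA monitor pulses) and action-potential shape features
at rheobase.  A cell's response to a bath-applied hormone is summarised by
the pre/post change in RMP and Ri and classified as activated (dRMP >= +2 mV
and |dRi| >= 10 %), inhibited (dRMP <= -2 mV and |dRi| >= 10 %) or
non-responsive.  The "10 % change" criterion is read as a magnitude; both
criteria must hold jointly by default (an ``or`` combination is available
for sensitivity analysis).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats

from .core import (
    EphysRecording, InsufficientDataError, ResponseCall, StepSweep,
    ValidationError,
)

#: dV/dt crossing (mV/ms) marking action-potential threshold / spike onset
AP_DVDT_THRESHOLD = 20.0
#: half-window (ms) masked around each spike when averaging voltage
SPIKE_MASK_HALF_MS = 5.0
#: post-peak search windows (ms) for fast / medium afterhyperpolarization
FAHP_WINDOW_MS = 5.0
MAHP_WINDOW_MS = (50.0, 200.0)


@dataclass
class ResponseRuleParams:
    """Thresholds and timing windows of the response-classification rule."""
    delta_rmp_threshold: float = 2.0       # mV
    delta_ri_threshold_pct: float = 10.0   # %
    pre_window: float = 30.0               # s, ends at application onset
    post_offset: float = 300.0             # s after onset
    post_window: float = 30.0              # s
    combine: str = "and"                   # and | or

    def __post_init__(self) -> None:
        if self.delta_rmp_threshold <= 0 or self.delta_ri_threshold_pct <= 0:
            raise ValidationError("response thresholds must be > 0")
        if min(self.pre_window, self.post_window) <= 0 or self.post_offset < 0:
            raise ValidationError("windows must be > 0")
        if self.combine not in ("and", "or"):
            raise ValidationError("combine must be 'and' or 'or'")


@dataclass
class ApFeatures:
    threshold: float     # mV
    amplitude: float     # mV, peak - threshold
    halfwidth: float     # ms at half amplitude
    fAHP: float          # mV below threshold
    mAHP: float | None   # mV below threshold; None if trace too short
    measured_at: float   # pA (rheobase)


def round_half_up(x: float) -> int:
    """Round halves away from zero upward (33.5 -> 34), as in report tables."""
    return int(np.floor(x + 0.5))


# ---------------------------------------------------------------------------
# Input resistance
# ---------------------------------------------------------------------------

def input_resistance(steps) -> float:
    """Ri (MOhm) from steady-state deflections to hyperpolarizing steps.

    ``steps`` is a sequence of ``(injected current pA, steady-state dV mV)``
    pairs with currents <= 0 (at least two distinct levels).  Ri is the
    least-squares slope of dV against I; mV/pA = GOhm, hence the x1000.
    """
    arr = np.asarray(steps, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise ValidationError("steps must be (current, deltaV) pairs")
    i, dv = arr[:, 0], arr[:, 1]
    if (i > 0).any():
        raise ValidationError("input-resistance steps must be hyperpolarizing (<= 0 pA)")
    if len(np.unique(i)) < 2:
        raise InsufficientDataError("need >= 2 distinct current levels")
    slope = np.polyfit(i, dv, 1)[0]
    return float(slope * 1000.0)


# ---------------------------------------------------------------------------
# Spike detection and voltage averaging
# ---------------------------------------------------------------------------

def _spike_onsets(time: np.ndarray, voltage: np.ndarray) -> np.ndarray:
    """Indices where dV/dt first exceeds the AP threshold (upward crossings)."""
    if len(time) < 2:
        return np.array([], dtype=int)
    dvdt = np.gradient(voltage, time * 1000.0)   # mV/ms
    above = dvdt > AP_DVDT_THRESHOLD
    onsets = np.flatnonzero(above & ~np.roll(above, 1))
    if above[0]:
        onsets = np.unique(np.concatenate([[0], onsets]))
    return onsets


def spike_mask(time: np.ndarray, voltage: np.ndarray) -> np.ndarray:
    """Boolean mask of samples NOT within +-5 ms of a spike onset."""
    keep = np.ones(len(time), dtype=bool)
    half = SPIKE_MASK_HALF_MS / 1000.0
    for idx in _spike_onsets(time, voltage):
        keep &= np.abs(time - time[idx]) > half
    return keep


def resting_potential(recording: EphysRecording,
                      window: tuple[float, float] | None = None) -> float:
    """Spike-masked mean membrane potential over a time window (mV).

    Samples during monitor-pulse current injection (current != 0, plus a
    50 ms settle margin) are excluded when a current trace is present.
    """
    t, v = recording.time, recording.voltage
    if window is None:
        window = (t[0], t[-1])
    t0, t1 = window
    if t0 < t[0] - 1e-9 or t1 > t[-1] + 1e-9:
        raise ValidationError(
            f"window [{t0}, {t1}] s outside recording span [{t[0]}, {t[-1]}] s")
    sel = (t >= t0) & (t <= t1)
    keep = sel & spike_mask(t, v)
    if recording.current is not None:
        keep &= ~_near_pulse(t, recording.current, margin=0.05)
    if not keep.any():
        raise InsufficientDataError("no usable samples in window after masking")
    return float(v[keep].mean())


def _near_pulse(t: np.ndarray, current: np.ndarray, margin: float) -> np.ndarray:
    """Samples during nonzero current or within `margin` s after it."""
    active = current != 0
    out = active.copy()
    if margin > 0 and active.any():
        # dilate forward in time by `margin`
        dt = np.median(np.diff(t)) if len(t) > 1 else margin
        k = max(1, int(round(margin / dt)))
        for shift in range(1, k + 1):
            out[shift:] |= active[:-shift]
    return out


# ---------------------------------------------------------------------------
# Rheobase and AP shape
# ---------------------------------------------------------------------------

def rheobase_and_ap(sweeps: list[StepSweep]
                    ) -> tuple[float | None, ApFeatures | None]:
    """Lowest step current eliciting a spike, and AP features at that sweep.

    Returns ``(None, None)`` when no sweep spikes (flagged no-rheobase).
    Threshold is the voltage at the first dV/dt > 20 mV/ms crossing;
    amplitude is peak minus threshold; halfwidth is measured at half
    amplitude by linear interpolation; fAHP (mAHP) is threshold minus the
    voltage minimum within 5 ms (50-200 ms) after the peak.
    """
    spiking = [(s.current_pA, s) for s in sweeps
               if len(_spike_onsets(s.time, s.voltage))]
    if not spiking:
        return None, None
    rheobase, sweep = min(spiking, key=lambda cs: cs[0])
    t, v = sweep.time, sweep.voltage
    onset = _spike_onsets(t, v)[0]
    threshold = float(v[onset])
    # peak within 10 ms of onset
    stop = np.searchsorted(t, t[onset] + 0.010)
    peak_idx = onset + int(np.argmax(v[onset:stop]))
    peak = float(v[peak_idx])
    amplitude = peak - threshold
    if amplitude <= 0:
        raise ValidationError("non-positive AP amplitude; check threshold criterion")
    half_level = threshold + amplitude / 2.0

    def _cross(i0: int, i1: int, step: int) -> float:
        # linear interpolation of the half-level crossing time, scanning from i0
        prev = i0
        for j in range(i0 + step, i1, step):
            if (v[j] - half_level) * (v[prev] - half_level) <= 0 and v[j] != v[prev]:
                frac = (half_level - v[prev]) / (v[j] - v[prev])
                return float(t[prev] + frac * (t[j] - t[prev]))
            prev = j
        return float(t[i1 - (1 if step > 0 else -1)])

    t_up = _cross(onset, peak_idx + 1, 1)
    t_down = _cross(peak_idx, len(v), 1)
    halfwidth = (t_down - t_up) * 1000.0

    f_stop = np.searchsorted(t, t[peak_idx] + FAHP_WINDOW_MS / 1000.0)
    fahp = threshold - float(v[peak_idx:max(f_stop, peak_idx + 1)].min())
    m_lo = np.searchsorted(t, t[peak_idx] + MAHP_WINDOW_MS[0] / 1000.0)
    m_hi = np.searchsorted(t, t[peak_idx] + MAHP_WINDOW_MS[1] / 1000.0)
    mahp = threshold - float(v[m_lo:m_hi].min()) if m_hi > m_lo else None
    return float(rheobase), ApFeatures(threshold, amplitude, halfwidth,
                                       fahp, mahp, float(rheobase))


# ---------------------------------------------------------------------------
# Pre/post hormone deltas
# ---------------------------------------------------------------------------

def _pulse_intervals(t: np.ndarray, current: np.ndarray) -> list[tuple[int, int]]:
    """Contiguous [start, stop) index runs where current is nonzero."""
    active = current != 0
    runs = []
    i = 0
    n = len(active)
    while i < n:
        if active[i]:
            j = i
            while j < n and active[j]:
                j += 1
            runs.append((i, j))    # [i, j)
            i = j
        else:
            i += 1
    return runs


def _ri_from_pulses(recording: EphysRecording, t0: float, t1: float) -> float:
    """Mean Ri (MOhm) over monitor pulses fully inside [t0, t1]."""
    t, v, cur = recording.time, recording.voltage, recording.current
    if cur is None:
        raise ValidationError("recording has no current trace for Ri monitoring")
    ris = []
    for i, j in _pulse_intervals(t, cur):
        width = t[j - 1] - t[i]
        base_t0 = t[i] - max(0.3 * width, 0.05)
        if t[i] < t0 or t[j - 1] > t1 or base_t0 < t[0]:
            continue
        base_sel = (t >= base_t0) & (t < t[i]) & (cur == 0)
        steady = slice(i + (j - i) // 2, j)        # last half of the pulse
        if not base_sel.any():
            continue
        deflection = v[steady].mean() - v[base_sel].mean()   # mV
        amp = cur[steady].mean()                              # pA
        ris.append(deflection / amp * 1000.0)
    if not ris:
        raise InsufficientDataError(f"no complete monitor pulses in [{t0}, {t1}] s")
    return float(np.mean(ris))


def response_deltas(recording: EphysRecording,
                    params: ResponseRuleParams | None = None
                    ) -> tuple[float, float]:
    """(delta RMP mV, delta Ri %) between the pre and post hormone windows."""
    params = params or ResponseRuleParams()
    onset = recording.application_onset
    pre = (onset - params.pre_window, onset)
    post = (onset + params.post_offset,
            onset + params.post_offset + params.post_window)
    for name, (a, b) in (("pre", pre), ("post", post)):
        if a < recording.time[0] - 1e-9 or b > recording.time[-1] + 1e-9:
            raise ValidationError(f"{name} window [{a}, {b}] s outside recording")
    delta_rmp = (resting_potential(recording, post)
                 - resting_potential(recording, pre))
    ri_pre = _ri_from_pulses(recording, *pre)
    ri_post = _ri_from_pulses(recording, *post)
    if ri_pre == 0:
        raise ValidationError("Ri_pre is zero; percentage change undefined")
    delta_ri_pct = 100.0 * (ri_post - ri_pre) / ri_pre
    return float(delta_rmp), float(delta_ri_pct)


# ---------------------------------------------------------------------------
# Classification rule and contingency testing
# ---------------------------------------------------------------------------

def classify_response(delta_rmp: float, delta_ri_pct: float,
                      params: ResponseRuleParams | None = None) -> ResponseCall:
    """Apply the activated / inhibited / non-responsive rule (boundaries inclusive)."""
    params = params or ResponseRuleParams()
    if not (np.isfinite(delta_rmp) and np.isfinite(delta_ri_pct)):
        raise ValidationError("deltas must be finite")
    ri_ok = abs(delta_ri_pct) >= params.delta_ri_threshold_pct
    up = delta_rmp >= params.delta_rmp_threshold
    down = delta_rmp <= -params.delta_rmp_threshold
    if params.combine == "and":
        category = "activated" if (up and ri_ok) else (
            "inhibited" if (down and ri_ok) else "nonresponsive")
    else:
        category = "activated" if (up or (ri_ok and delta_rmp > 0)) else (
            "inhibited" if (down or (ri_ok and delta_rmp < 0)) else "nonresponsive")
    return ResponseCall(float(delta_rmp), float(delta_ri_pct), category)


def response_contingency_test(table) -> dict:
    """Pearson chi-squared (no continuity correction) on a population x
    category count table, plus integer-rounded per-population percentages.

    ``table`` is a DataFrame (rows = populations, columns = categories) or a
    2D array of non-negative integers with positive column totals.
    """
    if isinstance(table, pd.DataFrame):
        counts = table.to_numpy()
        rows, cols = list(table.index), list(table.columns)
    else:
        counts = np.asarray(table)
        rows = [f"pop{i}" for i in range(counts.shape[0])]
        cols = [f"cat{j}" for j in range(counts.shape[1])]
    if (counts < 0).any() or not np.issubdtype(counts.dtype, np.integer):
        raise ValidationError("contingency table must hold non-negative integers")
    if (counts.sum(axis=0) == 0).any() or (counts.sum(axis=1) == 0).any():
        raise ValidationError("degenerate margin: a row or column total is zero")
    chi2, p, df, _ = scipy.stats.chi2_contingency(counts, correction=False)
    pct = pd.DataFrame(
        [[round_half_up(100.0 * c / rt) for c in row]
         for row, rt in zip(counts, counts.sum(axis=1))],
        index=rows, columns=cols)
    return {"chi2": float(chi2), "df": int(df), "p": float(p), "percentages": pct}


def permutation_chi2_pvalue(table, n_draws: int = 100_000, seed: int = 0) -> float:
    """Permutation-null p-value for the Pearson chi-squared statistic.

    Draws tables with both margins fixed (multivariate hypergeometric rows)
    and returns the fraction with chi-squared >= the observed value.
    """
    counts = np.asarray(table, dtype=np.int64)
    if counts.shape[0] != 2:
        raise ValidationError("permutation null implemented for 2-row tables")
    col_tot = counts.sum(axis=0)
    row0 = int(counts.sum(axis=1)[0])
    total = int(counts.sum())
    exp = np.outer(counts.sum(axis=1), col_tot) / total
    chi2_obs = ((counts - exp) ** 2 / exp).sum()
    rng = np.random.default_rng(seed)
    draws0 = rng.multivariate_hypergeometric(col_tot, row0, size=n_draws)
    draws1 = col_tot[None, :] - draws0
    chi2 = (((draws0 - exp[0]) ** 2 / exp[0]).sum(axis=1)
            + ((draws1 - exp[1]) ** 2 / exp[1]).sum(axis=1))
    return float((chi2 >= chi2_obs - 1e-12).mean())


def summarize_calls(calls: list[ResponseCall]) -> pd.Series:
    """Count calls per category (activated / inhibited / nonresponsive)."""
    counts = pd.Series(0, index=["activated", "inhibited", "nonresponsive"])
    for c in calls:
        counts[c.category] += 1
    return counts
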