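"""Delayed-fluorescence (DF) induction features and decay fitting.

DF is emitted in dark intervals by charge recombination in PSII. Its
induction curve shows two maxima (I_1 near 7 ms, I_2 near 50-100 ms) with a
minimum D_2 between them; the decay at I_1 is summarized by one or two
exponential components.

The module accepts already-constructed induction/decay curves; it does not
reconstruct them from raw light/dark interval records.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit
from scipy.signal import find_peaks, savgol_filter

from .errors import CoverageError, FitError, OjipError, ValidationError
from .io_formats import Channel, KineticTrace

__all__ = ["DfWindows", "DfFeatures", "df_induction_features", "fit_df_decay", "df_table"]


@dataclass(frozen=True)
class DfWindows:
    """Search windows for the induction maxima, in ms.

    The I_2 window starts at 20 ms so that a second maximum anywhere from
    tens of ms up to the end of the record is found.
    """

    i1_lo_ms: float = 2.0
    i1_hi_ms: float = 20.0
    i2_lo_ms: float = 20.0
    i2_hi_ms: float = 300.0
    prominence_frac: float = 0.01  # floor as a fraction of the curve range
    smooth_window: int = 5


@dataclass(frozen=True)
class DfFeatures:
    """Characteristic points of a DF induction curve and decay fit.

    Absent features (e.g. no second maximum) are NaN with the corresponding
    ``has_*`` flag False. Decay fields are NaN unless filled by
    :func:`fit_df_decay`.
    """

    I1_time_us: float = math.nan
    I1_value: float = math.nan
    I2_time_us: float = math.nan
    I2_value: float = math.nan
    D2_time_us: float = math.nan
    D2_value: float = math.nan
    has_I1: bool = False
    has_I2: bool = False
    decay_amps: tuple = ()
    decay_taus_ms: tuple = ()
    decay_residual_norm: float = math.nan
    group_label: str = ""
    replicate_id: str = ""


def _require_df(trace: KineticTrace) -> None:
    if trace.channel is not Channel.DF:
        raise ValidationError(f"expected a DF trace, got {trace.channel.value}")


def df_induction_features(trace: KineticTrace, search_cfg: DfWindows | None = None
                          ) -> DfFeatures:
    """Locate I_1, I_2 and D_2 on a DF induction curve.

    I_1 (I_2) is the highest local maximum of the lightly smoothed curve in
    its window; D_2 the global minimum between them when both exist, else the
    global minimum. A missing maximum is flagged, never raised.
    """
    _require_df(trace)
    cfg = search_cfg or DfWindows()
    t_ms = trace.times / 1000.0
    if t_ms[0] > cfg.i1_lo_ms or t_ms[-1] < cfg.i2_lo_ms:
        raise CoverageError(
            f"trace [{t_ms[0]:g}, {t_ms[-1]:g}] ms does not cover the search windows"
        )
    wl = min(cfg.smooth_window, len(trace) if len(trace) % 2 else len(trace) - 1)
    smooth = savgol_filter(trace.values, wl, 2) if wl >= 3 else trace.values
    prominence = cfg.prominence_frac * float(np.ptp(smooth))
    peaks, _ = find_peaks(smooth, prominence=max(prominence, 0.0) or None)

    def best_peak(lo: float, hi: float) -> int | None:
        cand = [p for p in peaks if lo <= t_ms[p] <= hi]
        if not cand:
            return None
        return max(cand, key=lambda p: smooth[p])

    i1 = best_peak(cfg.i1_lo_ms, cfg.i1_hi_ms)
    i2 = best_peak(cfg.i2_lo_ms, cfg.i2_hi_ms)
    if i1 is not None and i2 is not None and i2 == i1:
        i2 = None

    feat = {"group_label": trace.group_label, "replicate_id": trace.replicate_id}
    if i1 is not None:
        feat.update(has_I1=True, I1_time_us=float(trace.times[i1]),
                    I1_value=float(trace.values[i1]))
    if i2 is not None:
        feat.update(has_I2=True, I2_time_us=float(trace.times[i2]),
                    I2_value=float(trace.values[i2]))
    if i1 is not None and i2 is not None:
        seg = slice(i1, i2 + 1)
        d2 = i1 + int(np.argmin(smooth[seg]))
    else:
        d2 = int(np.argmin(smooth))
    feat.update(D2_time_us=float(trace.times[d2]), D2_value=float(trace.values[d2]))
    return DfFeatures(**feat)


def _multi_exp(t_ms: np.ndarray, *params: float) -> np.ndarray:
    half = len(params) // 2
    amps, taus = params[:half], params[half:]
    out = np.zeros_like(t_ms, dtype=float)
    for a, tau in zip(amps, taus):
        out += a * np.exp(-t_ms / tau)
    return out


def _decay_init(t_ms: np.ndarray, v: np.ndarray, n_components: int) -> list[float]:
    """Deterministic initialization: log-linear tail fit for the slow
    component, then peeling for the fast one. No random restarts."""
    pos = v > 0
    if pos.sum() < 4:
        raise FitError("too few positive samples to initialize a decay fit")
    tail = pos & (t_ms >= np.quantile(t_ms[pos], 2 / 3))
    if tail.sum() < 3:
        tail = pos
    slope, intercept = np.polyfit(t_ms[tail], np.log(v[tail]), 1)
    tau_slow = -1.0 / slope if slope < 0 else float(t_ms[-1])
    a_slow = float(np.exp(intercept))
    if n_components == 1:
        return [a_slow, tau_slow]
    resid = v - a_slow * np.exp(-t_ms / tau_slow)
    head = (resid > 0) & (t_ms <= np.quantile(t_ms, 1 / 3))
    if head.sum() >= 3:
        s2, i2 = np.polyfit(t_ms[head], np.log(resid[head]), 1)
        tau_fast = -1.0 / s2 if s2 < 0 else tau_slow / 10.0
        a_fast = float(np.exp(i2))
    else:
        tau_fast, a_fast = tau_slow / 10.0, max(float(v[0]) - a_slow, 1e-6)
    return [a_fast, a_slow, max(tau_fast, 1e-6), tau_slow]


def fit_df_decay(decay: KineticTrace, n_components: int = 2,
                 features: DfFeatures | None = None) -> DfFeatures:
    """Least-squares multi-exponential fit of a DF decay curve.

    Components are returned ordered by tau ascending. Raises
    :class:`FitError` with diagnostics on non-convergence or degenerate
    input (e.g. an all-zero trace).
    """
    _require_df(decay)
    if n_components not in (1, 2):
        raise ValidationError("n_components must be 1 or 2")
    if len(decay) < 10:
        raise ValidationError("need >= 10 decay samples")
    t_ms = decay.times / 1000.0
    v = decay.values
    if np.all(v <= 0):
        raise FitError("decay trace has no positive signal")
    p0 = _decay_init(t_ms, v, n_components)
    n = n_components
    try:
        popt, _ = curve_fit(
            _multi_exp, t_ms, v, p0=p0,
            bounds=([0.0] * n + [1e-9] * n, [np.inf] * 2 * n),
            maxfev=20000,
        )
    except (RuntimeError, ValueError) as exc:
        raise FitError(f"decay fit did not converge (init {p0}): {exc}") from exc
    amps, taus = popt[:n], popt[n:]
    order = np.argsort(taus)
    amps, taus = amps[order], taus[order]
    resid = float(np.linalg.norm(v - _multi_exp(t_ms, *popt)))
    base = features or DfFeatures(group_label=decay.group_label,
                                  replicate_id=decay.replicate_id)
    return DfFeatures(
        **{**base.__dict__,
           "decay_amps": tuple(float(a) for a in amps),
           "decay_taus_ms": tuple(float(x) for x in taus),
           "decay_residual_norm": resid}
    )


def df_table(induction_traces: list[KineticTrace],
             decay_traces: list[KineticTrace] | None = None,
             search_cfg: DfWindows | None = None,
             n_components: int = 2) -> tuple[pd.DataFrame, list[dict]]:
    """Per-replicate DF feature table; decay traces are matched to induction
    traces by (group, replicate)."""
    if not induction_traces:
        raise ValidationError("need at least one DF induction trace")
    decay_by_key = {
        (t.group_label, t.replicate_id): t for t in (decay_traces or [])
    }
    rows, failures = [], []
    for trace in induction_traces:
        try:
            feat = df_induction_features(trace, search_cfg)
            dec = decay_by_key.get((trace.group_label, trace.replicate_id))
            if dec is not None:
                feat = fit_df_decay(dec, n_components, features=feat)
            row = {"group": feat.group_label, "replicate": feat.replicate_id}
            for name in ("I1_time_us", "I1_value", "I2_time_us", "I2_value",
                         "D2_time_us", "D2_value", "has_I1", "has_I2",
                         "decay_residual_norm"):
                row[name] = getattr(feat, name)
            for k, (a, tau) in enumerate(zip(feat.decay_amps, feat.decay_taus_ms), 1):
                row[f"decay_amp{k}"] = a
                row[f"decay_tau{k}_ms"] = tau
            rows.append(row)
        except OjipError as exc:
            failures.append(
                {"group": trace.group_label, "replicate": trace.replicate_id,
                 "error": f"{type(exc).__name__}: {exc}"}
            )
    return pd.DataFrame(rows), failures
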