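"""Modulated 820 nm reflection (MR/MR_o) kinetics.

The 820 nm reflection reports the redox state of P700 and plastocyanin: after
the onset of actinic light MR/MR_o first falls (net oxidation driven by PSI
turnover) and then rises again (re-reduction by electrons arriving from
PSII). The analysis normalizes the raw signal to its first reliable sample
(0.7 ms), then estimates

* ``V_PSI``        — maximum rate of decrease on the oxidation window
  (default 0.7-20 ms),
* ``V_PSII_PSI``   — maximum rate of increase on the re-reduction window
  (default 20-300 ms),
* ``V_PSII``       — their sum (by definition),
* ``t_min``        — the time of the MR/MR_o minimum.

Derivatives are taken on a uniform linear-ms resampling of each window with a
Savitzky-Golay local-polynomial filter (window length and order
configurable); slopes are reported per ms by default (``per_s`` available).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.signal import savgol_filter

from .errors import CoverageError, InvalidSignalError, OjipError, ValidationError
from .io_formats import Channel, KineticTrace

__all__ = ["MrWindows", "SlopeConfig", "MrParameters", "normalize_mr", "mr_slopes", "mr_table"]


@dataclass(frozen=True)
class MrWindows:
    """Oxidation / re-reduction analysis windows, in ms."""

    t0_ms: float = 0.7
    split_ms: float = 20.0
    t_end_ms: float = 300.0


@dataclass(frozen=True)
class SlopeConfig:
    """Derivative-estimation settings."""

    n_resample: int = 1000  # uniform points per window
    window_length: int = 7  # Savitzky-Golay window (odd)
    polyorder: int = 2
    time_base: str = "per_ms"  # or "per_s"

    def __post_init__(self) -> None:
        if self.window_length % 2 == 0 or self.window_length <= self.polyorder:
            raise ValidationError("window_length must be odd and exceed polyorder")
        if self.time_base not in ("per_ms", "per_s"):
            raise ValidationError("time_base must be 'per_ms' or 'per_s'")


@dataclass(frozen=True)
class MrParameters:
    """Slope parameters of one normalized MR/MR_o curve."""

    MR_o: float  # raw signal at 0.7 ms (pre-normalization reference)
    t_min_ms: float
    V_PSI: float
    V_PSII_PSI: float
    V_PSII: float
    group_label: str = ""
    replicate_id: str = ""


def normalize_mr(trace: KineticTrace, t0_ms: float = 0.7) -> tuple[KineticTrace, float]:
    """Divide an MR trace by its value at the first reliable time.

    Returns ``(normalized trace, MR_o)``. The reference value is linearly
    interpolated at ``t0_ms``; it is exact when 0.7 ms is a sample time.
    """
    if trace.channel is not Channel.MR:
        raise ValidationError(f"expected an MR trace, got {trace.channel.value}")
    t0_us = t0_ms * 1000.0
    if trace.times[0] > t0_us + 1e-9:
        raise CoverageError(f"trace starts at {trace.times[0] / 1000:g} ms, after t0 = {t0_ms} ms")
    mr_o = float(np.interp(t0_us, trace.times, trace.values))
    if mr_o <= 0:
        raise InvalidSignalError(f"MR_o = {mr_o:g} <= 0: cannot normalize")
    return trace.with_values(trace.values / mr_o), mr_o


def _window_slope(t_ms: np.ndarray, v: np.ndarray, lo: float, hi: float,
                  cfg: SlopeConfig, sign: float) -> float:
    """Max of sign * dv/dt (per ms) on [lo, hi], clamped at 0."""
    grid = np.linspace(lo, hi, cfg.n_resample)
    vg = np.interp(grid, t_ms, v)
    dt = grid[1] - grid[0]
    wl = min(cfg.window_length, cfg.n_resample if cfg.n_resample % 2 else cfg.n_resample - 1)
    deriv = savgol_filter(vg, wl, cfg.polyorder, deriv=1, delta=dt, mode="interp")
    slope = max(float(np.max(sign * deriv)), 0.0)
    # float dust from the filter on a flat curve is not a slope
    eps = 1e-12 * max(1.0, float(np.max(np.abs(vg)))) / dt
    return slope if slope > eps else 0.0


def mr_slopes(trace: KineticTrace, windows: MrWindows | None = None,
              slope_cfg: SlopeConfig | None = None) -> MrParameters:
    """Normalize an MR trace and extract slope parameters and ``t_min``.

    ``V_PSII = V_PSI + V_PSII_PSI`` holds exactly by construction.
    """
    windows = windows or MrWindows()
    cfg = slope_cfg or SlopeConfig()
    norm, mr_o = normalize_mr(trace, windows.t0_ms)
    t_ms = norm.times / 1000.0
    if t_ms[-1] < windows.t_end_ms - 1e-9:
        raise CoverageError(
            f"trace ends at {t_ms[-1]:g} ms, before the analysis window end "
            f"{windows.t_end_ms:g} ms"
        )
    v_psi = _window_slope(t_ms, norm.values, windows.t0_ms, windows.split_ms, cfg, -1.0)
    v_psii_psi = _window_slope(t_ms, norm.values, windows.split_ms, windows.t_end_ms, cfg, +1.0)
    if cfg.time_base == "per_s":
        v_psi *= 1000.0
        v_psii_psi *= 1000.0

    # t_min: argmin of the lightly smoothed curve on a dense uniform grid
    grid = np.linspace(windows.t0_ms, windows.t_end_ms, 3 * cfg.n_resample)
    vg = np.interp(grid, t_ms, norm.values)
    smooth = savgol_filter(vg, cfg.window_length, cfg.polyorder, mode="interp")
    t_min = float(grid[int(np.argmin(smooth))])

    return MrParameters(
        MR_o=mr_o, t_min_ms=t_min, V_PSI=v_psi, V_PSII_PSI=v_psii_psi,
        V_PSII=v_psi + v_psii_psi,
        group_label=trace.group_label, replicate_id=trace.replicate_id,
    )


def mr_table(traces: list[KineticTrace], windows: MrWindows | None = None,
             slope_cfg: SlopeConfig | None = None) -> tuple[pd.DataFrame, list[dict]]:
    """Per-replicate MR parameter table; failures reported, not dropped."""
    if not traces:
        raise ValidationError("need at least one MR trace")
    rows, failures = [], []
    for trace in traces:
        try:
            p = mr_slopes(trace, windows, slope_cfg)
            rows.append(
                {"group": p.group_label, "replicate": p.replicate_id, "MR_o": p.MR_o,
                 "t_min_ms": p.t_min_ms, "V_PSI": p.V_PSI,
                 "V_PSII_PSI": p.V_PSII_PSI, "V_PSII": p.V_PSII}
            )
        except OjipError as exc:
            failures.append(
                {"group": trace.group_label, "replicate": trace.replicate_id,
                 "error": f"{type(exc).__name__}: {exc}"}
            )
    return pd.DataFrame(rows), failures
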