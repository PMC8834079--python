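"""JIP-test parameterization of OJIP prompt-fluorescence transients.

The polyphasic fluorescence rise of a dark-adapted leaf is reduced to
fiducial markers — F_o (20 us), F_K (300 us), F_J (2 ms), F_I (30 ms) and the
maximum F_m = F_P — and from them the standard energy-flux quantities:

quantum yields / efficiencies
    phi_Po   = 1 - F_o/F_m            (= F_v/F_m, max PSII photochemistry)
    psi_o    = 1 - V_J                (electron moved beyond Q_A-)
    phi_Eo   = phi_Po * psi_o         (electron transport yield)
    delta_Ro = (1 - V_I) / (1 - V_J)  (inter-photosystem transfer efficiency)
    phi_Ro   = phi_Po * (1 - V_I)     (PSI end-acceptor reduction yield)
    phi_Do   = 1 - phi_Po             (dissipation yield)
    gamma_RC = 1 / (1 + ABS/RC)       (RC chlorophyll fraction)

specific (per reaction center) fluxes, per ms
    TR0/RC = M_o / V_J ;  ABS/RC = TR0/RC / phi_Po ;  ET0/RC = TR0/RC * psi_o
    RE0/RC = TR0/RC * psi_o * delta_Ro ;  DI0/RC = ABS/RC - TR0/RC

phenomenological (per cross section at t = F_m) fluxes, in trace units
    ABS/CS_M ~ F_m ;  TR0/CS_M = phi_Po F_m ;  ET0/CS_M = phi_Eo F_m
    RE0/CS_M = phi_Ro F_m ;  DI0/CS_M = ABS/CS_M - TR0/CS_M
    RC/CS_o = phi_Po (V_J/M_o) F_o ;  RC/CS_M = phi_Po (V_J/M_o) F_m

with V_t = (F_t - F_o)/(F_m - F_o) and the initial-slope approximation
M_o = 4 (F_K - F_o)/(F_m - F_o) per ms. Marker values are read off the trace
by piecewise-linear interpolation against log10(time); F_m is the trace
maximum (earliest time on ties), optionally after a 5-point median smooth.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass

import numpy as np
import pandas as pd

from .errors import CoverageError, DegenerateTransientError, OjipError, ValidationError
from .io_formats import Channel, KineticTrace

__all__ = [
    "MarkerTimes",
    "OjipMarkers",
    "QuantumYields",
    "SpecificFluxes",
    "PhenomenologicalFluxes",
    "extract_markers",
    "quantum_yields",
    "specific_fluxes",
    "phenomenological_fluxes",
    "analyze_transient",
    "jip_table",
]


@dataclass(frozen=True)
class MarkerTimes:
    """Fiducial marker times in microseconds (O, K, J, I steps)."""

    t_O: float = 20.0
    t_K: float = 300.0
    t_J: float = 2_000.0
    t_I: float = 30_000.0


@dataclass(frozen=True)
class OjipMarkers:
    """Fiducial fluorescence values and derived normalizations."""

    F_o: float
    F_K: float
    F_J: float
    F_I: float
    F_m: float
    t_Fm_us: float
    F_v: float
    V_J: float
    V_I: float
    M_o: float  # per ms


@dataclass(frozen=True)
class QuantumYields:
    phi_Po: float
    psi_o: float
    phi_Eo: float
    phi_Ro: float
    delta_Ro: float
    phi_Do: float
    gamma_RC: float


@dataclass(frozen=True)
class SpecificFluxes:
    """Per-reaction-center energy fluxes (per-ms relative units)."""

    ABS_RC: float
    TR0_RC: float
    ET0_RC: float
    RE0_RC: float
    DI0_RC: float


@dataclass(frozen=True)
class PhenomenologicalFluxes:
    """Per-cross-section fluxes and RC densities (input-trace units)."""

    ABS_CSM: float
    TR0_CSM: float
    ET0_CSM: float
    RE0_CSM: float
    DI0_CSM: float
    RC_CSo: float
    RC_CSM: float


def _interp_log_time(trace: KineticTrace, t_us: float) -> float:
    return float(np.interp(np.log10(t_us), np.log10(trace.times), trace.values))


def extract_markers(trace: KineticTrace, marker_times: MarkerTimes | None = None,
                    smooth: bool = False) -> OjipMarkers:
    """Read the OJIP fiducial markers off a PF trace.

    Raises :class:`CoverageError` if the trace does not span the marker
    times, and :class:`DegenerateTransientError` if F_v <= 0 (no variable
    fluorescence — e.g. a constant trace).
    """
    if trace.channel is not Channel.PF:
        raise ValidationError(f"expected a PF trace, got {trace.channel.value}")
    mt = marker_times or MarkerTimes()
    if trace.times[0] > mt.t_O or trace.times[-1] < mt.t_I:
        raise CoverageError(
            f"trace [{trace.times[0]:g}, {trace.times[-1]:g}] us does not cover "
            f"markers [{mt.t_O:g}, {mt.t_I:g}] us"
        )
    values = trace.values
    if smooth:
        from scipy.ndimage import median_filter

        values = median_filter(trace.values, size=5, mode="nearest")
    i_max = int(np.argmax(values))  # argmax takes the earliest tie
    f_m = float(values[i_max])
    t_fm = float(trace.times[i_max])
    f_o = _interp_log_time(trace, mt.t_O)
    f_k = _interp_log_time(trace, mt.t_K)
    f_j = _interp_log_time(trace, mt.t_J)
    f_i = _interp_log_time(trace, mt.t_I)
    f_v = f_m - f_o
    if f_v <= 0:
        raise DegenerateTransientError(f"F_v = {f_v:g} <= 0: no variable fluorescence")
    v_j = (f_j - f_o) / f_v
    v_i = (f_i - f_o) / f_v
    m_o = 4.0 * (f_k - f_o) / f_v
    return OjipMarkers(f_o, f_k, f_j, f_i, f_m, t_fm, f_v, v_j, v_i, m_o)


def specific_fluxes(markers: OjipMarkers) -> SpecificFluxes:
    """Per-RC energy fluxes from the markers (TR0/RC = M_o / V_J etc.)."""
    if markers.V_J == 0:
        raise DegenerateTransientError("V_J = 0: per-RC fluxes undefined")
    phi_po = 1.0 - markers.F_o / markers.F_m
    tr0 = markers.M_o / markers.V_J
    abs_rc = tr0 / phi_po
    psi_o = 1.0 - markers.V_J
    if markers.V_J == 1.0:
        raise DegenerateTransientError("V_J = 1: delta_Ro undefined")
    delta_ro = (1.0 - markers.V_I) / (1.0 - markers.V_J)
    et0 = tr0 * psi_o
    re0 = tr0 * psi_o * delta_ro
    return SpecificFluxes(abs_rc, tr0, et0, re0, abs_rc - tr0)


def quantum_yields(markers: OjipMarkers) -> QuantumYields:
    """Quantum yields and efficiencies from the markers."""
    phi_po = 1.0 - markers.F_o / markers.F_m
    psi_o = 1.0 - markers.V_J
    if markers.V_J == 1.0:
        raise DegenerateTransientError("V_J = 1: delta_Ro undefined")
    delta_ro = (1.0 - markers.V_I) / (1.0 - markers.V_J)
    phi_eo = phi_po * psi_o
    phi_ro = phi_po * (1.0 - markers.V_I)
    # gamma_RC needs ABS/RC, which is undefined in the V_J -> 0 limit where
    # the other yields still are; report NaN there instead of failing.
    if markers.V_J == 0:
        gamma_rc = float("nan")
    else:
        gamma_rc = 1.0 / (1.0 + specific_fluxes(markers).ABS_RC)
    return QuantumYields(phi_po, psi_o, phi_eo, phi_ro, delta_ro, 1.0 - phi_po, gamma_rc)


def phenomenological_fluxes(markers: OjipMarkers,
                            yields: QuantumYields | None = None) -> PhenomenologicalFluxes:
    """Per-cross-section fluxes, using ABS/CS_M ~ F_m and ABS/CS_o ~ F_o.

    Outputs carry the same (instrument-count) units as the input trace.
    """
    y = yields or quantum_yields(markers)
    abs_csm = markers.F_m
    tr0 = y.phi_Po * abs_csm
    rc_scale = y.phi_Po * (markers.V_J / markers.M_o)
    return PhenomenologicalFluxes(
        ABS_CSM=abs_csm,
        TR0_CSM=tr0,
        ET0_CSM=y.phi_Eo * abs_csm,
        RE0_CSM=y.phi_Ro * abs_csm,
        DI0_CSM=abs_csm - tr0,
        RC_CSo=rc_scale * markers.F_o,
        RC_CSM=rc_scale * markers.F_m,
    )


@dataclass(frozen=True)
class TransientAnalysis:
    """Full JIP parameter set for one transient."""

    markers: OjipMarkers
    yields: QuantumYields
    specific: SpecificFluxes
    phenomenological: PhenomenologicalFluxes
    group_label: str = ""
    replicate_id: str = ""

    def to_row(self) -> dict:
        row = {"group": self.group_label, "replicate": self.replicate_id}
        for part in (self.markers, self.yields, self.specific, self.phenomenological):
            row.update(asdict(part))
        return row


def analyze_transient(trace: KineticTrace, marker_times: MarkerTimes | None = None,
                      smooth: bool = False) -> TransientAnalysis:
    markers = extract_markers(trace, marker_times, smooth)
    yields = quantum_yields(markers)
    return TransientAnalysis(
        markers=markers,
        yields=yields,
        specific=specific_fluxes(markers),
        phenomenological=phenomenological_fluxes(markers, yields),
        group_label=trace.group_label,
        replicate_id=trace.replicate_id,
    )


def jip_table(traces: list[KineticTrace], marker_times: MarkerTimes | None = None,
              smooth: bool = False) -> tuple[pd.DataFrame, list[dict]]:
    """Per-replicate JIP parameter table.

    Returns ``(table, failures)``; replicates whose analysis raises are
    reported in ``failures`` (group, replicate, error), never silently
    dropped.
    """
    if not traces:
        raise ValidationError("need at least one PF trace")
    rows, failures = [], []
    for trace in traces:
        try:
            rows.append(analyze_transient(trace, marker_times, smooth).to_row())
        except OjipError as exc:
            failures.append(
                {"group": trace.group_label, "replicate": trace.replicate_id,
                 "error": f"{type(exc).__name__}: {exc}"}
            )
    return pd.DataFrame(rows), failures
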