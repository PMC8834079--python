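"""Synthetic PF / DF / MR kinetics and absorbance records with known truth.

The generators are *descriptive*, not mechanistic: each channel is modelled by
the simplest smooth curve family that reproduces the fiducial features the
analyses extract (OJIP anchor values, an MR/MR_o valley with a closed-form
minimum, two DF induction maxima, bi-exponential DF decay), so every analyzer
can be tested for exact parameter recovery without instrument data.

The prompt-fluorescence model is a monotone shape-preserving (PCHIP)
interpolant of relative variable fluorescence V(t) through the O/K/J/I/P
anchors on a log10-time axis, rescaled to ``F(t) = F_o + V(t) * (F_m - F_o)``.
The anchor times are inserted into the sampling grid so a noise-free trace
reproduces the anchor values exactly.

The MR/MR_o model is the valley curve

    MR/MR_o(t) = 1 - A * (1 - exp(-t/a)) * exp(-t/b),   t in ms,

whose minimum sits at ``t_min = a * ln((a + b) / a)`` — a closed form used as
an oracle for the slope analyzer.
"""

from __future__ import annotations

import warnings
import zlib
from dataclasses import dataclass, field, replace

import numpy as np

from .errors import ConfigurationError
from .io_formats import AbsorbanceRecord, Channel, KineticTrace
from . import pigments as _pigments

__all__ = [
    "LogGrid",
    "LinearGrid",
    "PfSpec",
    "MrSpec",
    "DfSpec",
    "PigmentTruth",
    "GroupSpec",
    "make_pf_trace",
    "make_mr_trace",
    "make_df_traces",
    "make_absorbance_record",
    "make_dataset",
    "mr_model",
    "mr_model_tmin",
    "default_group_specs",
]


@dataclass(frozen=True)
class LogGrid:
    """Log10-spaced sampling grid, microseconds."""

    t_min_us: float = 20.0
    t_max_us: float = 300_000.0
    n: int = 600

    def times(self) -> np.ndarray:
        if self.n < 60:
            raise ConfigurationError(f"log grid needs >= 60 points, got {self.n}")
        if not 0 < self.t_min_us < self.t_max_us:
            raise ConfigurationError("grid bounds must satisfy 0 < t_min < t_max")
        return np.geomspace(self.t_min_us, self.t_max_us, self.n)


@dataclass(frozen=True)
class LinearGrid:
    """Uniform sampling grid, microseconds."""

    t_min_us: float = 0.0
    t_max_us: float = 100_000.0
    n: int = 200

    def times(self) -> np.ndarray:
        if self.n < 10:
            raise ConfigurationError(f"linear grid needs >= 10 points, got {self.n}")
        return np.linspace(self.t_min_us, self.t_max_us, self.n)


@dataclass(frozen=True)
class PfSpec:
    """Ground truth for one OJIP prompt-fluorescence transient.

    ``v_K``, ``v_J``, ``v_I`` are relative variable fluorescence at the K, J
    and I steps; anchor times default to O=20 us, K=300 us, J=2 ms, I=30 ms,
    P=300 ms. ``noise_sd`` is i.i.d. Gaussian noise in instrument counts.
    """

    f_o: float = 500.0
    f_m: float = 2500.0
    v_K: float | None = None  # default 0.25 * v_J, keeps M_o positive
    v_J: float = 0.5
    v_I: float = 0.8
    t_anchors_us: tuple = (20.0, 300.0, 2000.0, 30_000.0, 300_000.0)
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (self.f_m > self.f_o > 0):
            raise ConfigurationError(f"need f_m > f_o > 0, got f_o={self.f_o}, f_m={self.f_m}")
        vk = self.v_K if self.v_K is not None else 0.25 * self.v_J
        object.__setattr__(self, "v_K", float(vk))
        if not (0 < self.v_K < self.v_J < self.v_I < 1):
            raise ConfigurationError(
                f"need 0 < v_K < v_J < v_I < 1, got ({self.v_K}, {self.v_J}, {self.v_I})"
            )
        if self.noise_sd < 0:
            raise ConfigurationError("noise_sd must be >= 0")
        if len(self.t_anchors_us) != 5 or np.any(np.diff(self.t_anchors_us) <= 0):
            raise ConfigurationError("t_anchors_us must be 5 increasing times")


@dataclass(frozen=True)
class MrSpec:
    """Ground truth for one modulated 820 nm reflection valley curve.

    ``amplitude`` is the fractional valley depth A; ``tau_ox_ms`` (a) and
    ``tau_red_ms`` (b) the oxidation and re-reduction time constants; ``gain``
    an arbitrary instrument scale so normalization is exercised downstream.
    """

    amplitude: float = 0.05
    tau_ox_ms: float = 8.0
    tau_red_ms: float = 70.0
    t0_ms: float = 0.7  # first reliable sample
    gain: float = 1000.0
    noise_sd: float = 0.0  # on the normalized curve, before gain
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.amplitude < 1):
            raise ConfigurationError("amplitude must be in [0, 1): the signal would cross zero")
        if self.tau_ox_ms <= 0 or self.tau_red_ms <= 0:
            raise ConfigurationError("time constants must be positive")
        if self.gain <= 0:
            raise ConfigurationError("gain must be positive")


@dataclass(frozen=True)
class DfSpec:
    """Ground truth for delayed-fluorescence induction and decay curves.

    Induction is a sum of two log-normal bumps (widths in log10-time units)
    over a fast-decaying baseline; decay at the first maximum I_1 is a sum of
    two exponentials.
    """

    peak1_time_us: float = 7_000.0
    peak2_time_us: float = 60_000.0
    peak1_amp: float = 1000.0
    peak2_amp: float = 600.0
    bump_width: float = 0.25  # log10-time units
    baseline_amp: float = 50.0
    baseline_tau_us: float = 500.0
    decay_amps: tuple = (60.0, 40.0)
    decay_taus_ms: tuple = (2.0, 20.0)
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.peak1_time_us < self.peak2_time_us:
            raise ConfigurationError("peak1_time must precede peak2_time")
        if self.peak1_amp <= 0 or self.peak2_amp < 0 or self.bump_width <= 0:
            raise ConfigurationError("bump amplitudes and width must be positive")
        if min(self.decay_taus_ms) <= 0:
            raise ConfigurationError("decay time constants must be positive")


@dataclass(frozen=True)
class PigmentTruth:
    """Ground-truth pigment contents in mg per g fresh weight."""

    chl_a: float = 0.38
    chl_b: float = 0.09
    carotenoids: float = 0.14
    extract_volume_ml: float = 10.0
    fresh_mass_g: float = 0.1
    noise_cv: float = 0.0  # replicate-level coefficient of variation


@dataclass(frozen=True)
class GroupSpec:
    """All per-group ground truth for a simulated experiment."""

    pf: PfSpec = field(default_factory=PfSpec)
    mr: MrSpec = field(default_factory=MrSpec)
    df: DfSpec = field(default_factory=DfSpec)
    pigments: PigmentTruth = field(default_factory=PigmentTruth)


def _pf_noise_free(spec: PfSpec, times_us: np.ndarray) -> np.ndarray:
    from scipy.interpolate import PchipInterpolator

    log_anchors = np.log10(np.asarray(spec.t_anchors_us, dtype=float))
    v_anchors = np.array([0.0, spec.v_K, spec.v_J, spec.v_I, 1.0])
    interp = PchipInterpolator(log_anchors, v_anchors, extrapolate=True)
    v = np.clip(interp(np.log10(times_us)), 0.0, 1.0)
    return spec.f_o + v * (spec.f_m - spec.f_o)


def make_pf_trace(spec: PfSpec, sampling: LogGrid | None = None,
                  group_label: str = "", replicate_id: str = "") -> KineticTrace:
    """Generate one OJIP transient on a log grid (anchors inserted exactly)."""
    sampling = sampling or LogGrid()
    t = sampling.times()
    anchors = np.asarray(spec.t_anchors_us, dtype=float)
    if anchors[0] < t[0] - 1e-9 or anchors[-1] > t[-1] + 1e-9:
        raise ConfigurationError(
            f"sampling grid [{t[0]}, {t[-1]}] us does not cover anchors "
            f"[{anchors[0]}, {anchors[-1]}] us"
        )
    t = np.unique(np.concatenate([t, anchors]))
    values = _pf_noise_free(spec, t)
    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        values = np.maximum(values + rng.normal(0.0, spec.noise_sd, t.size), 0.0)
    return KineticTrace(Channel.PF, t, values, group_label, replicate_id)


def mr_model(t_ms: np.ndarray, amplitude: float, tau_ox_ms: float, tau_red_ms: float) -> np.ndarray:
    """Noise-free normalized MR/MR_o valley model (t in ms)."""
    t_ms = np.asarray(t_ms, dtype=float)
    return 1.0 - amplitude * (1.0 - np.exp(-t_ms / tau_ox_ms)) * np.exp(-t_ms / tau_red_ms)


def mr_model_tmin(tau_ox_ms: float, tau_red_ms: float) -> float:
    """Closed-form time of the valley minimum, ``a * ln((a + b) / a)`` (ms)."""
    return tau_ox_ms * np.log((tau_ox_ms + tau_red_ms) / tau_ox_ms)


def make_mr_trace(spec: MrSpec, sampling: LogGrid | None = None,
                  group_label: str = "", replicate_id: str = "") -> KineticTrace:
    """Generate an un-normalized MR trace (model x gain) on a log grid."""
    sampling = sampling or LogGrid(t_min_us=spec.t0_ms * 1000.0, t_max_us=300_000.0, n=600)
    t = sampling.times()
    if t[0] > spec.t0_ms * 1000.0 + 1e-9:
        raise ConfigurationError(f"grid must start at or before t0 = {spec.t0_ms} ms")
    values = mr_model(t / 1000.0, spec.amplitude, spec.tau_ox_ms, spec.tau_red_ms)
    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        values = values + rng.normal(0.0, spec.noise_sd, t.size)
    return KineticTrace(Channel.MR, t, values * spec.gain, group_label, replicate_id)


def _df_bump_centers(spec: DfSpec) -> tuple[float, float]:
    """Bump centers (log10 us) adjusted so the *composite* curve has its
    local maxima exactly at the nominal peak times.

    Each bump's tail tilts the other bump's maximum; a few fixed-point
    iterations cancel that tilt (and the baseline's) at the nominal times.
    """
    w2 = spec.bump_width**2
    x1, x2 = np.log10(spec.peak1_time_us), np.log10(spec.peak2_time_us)
    amps = (spec.peak1_amp, spec.peak2_amp)

    def d_bump(x: float, c: float, amp: float) -> float:
        return -amp * (x - c) / w2 * np.exp(-((x - c) ** 2) / (2 * w2))

    def d_base(x: float) -> float:
        t = 10.0**x
        return -spec.baseline_amp * (t / spec.baseline_tau_us) * np.log(10) * np.exp(
            -t / spec.baseline_tau_us)

    c1, c2 = x1, x2
    for _ in range(6):
        other1 = d_bump(x1, c2, amps[1]) + d_base(x1)
        other2 = d_bump(x2, c1, amps[0]) + d_base(x2)
        c1 = x1 - w2 * other1 / amps[0] if amps[0] > 0 else x1
        c2 = x2 - w2 * other2 / amps[1] if amps[1] > 0 else x2
    return c1, c2


def _df_induction_noise_free(spec: DfSpec, t_us: np.ndarray) -> np.ndarray:
    x = np.log10(t_us)
    c1, c2 = _df_bump_centers(spec)
    bump1 = spec.peak1_amp * np.exp(-((x - c1) ** 2) / (2 * spec.bump_width**2))
    bump2 = spec.peak2_amp * np.exp(-((x - c2) ** 2) / (2 * spec.bump_width**2))
    baseline = spec.baseline_amp * np.exp(-t_us / spec.baseline_tau_us)
    return bump1 + bump2 + baseline


def make_df_traces(spec: DfSpec, induction_sampling: LogGrid | None = None,
                   decay_sampling: LinearGrid | None = None,
                   group_label: str = "", replicate_id: str = "") -> tuple[KineticTrace, KineticTrace]:
    """Generate (induction, decay-at-I1) DF traces.

    Warns (never errors) if the two induction bumps merge into a single mode.
    """
    induction_sampling = induction_sampling or LogGrid(t_min_us=100.0, t_max_us=300_000.0, n=600)
    decay_sampling = decay_sampling or LinearGrid(t_min_us=0.0, t_max_us=100_000.0, n=200)

    t_ind = induction_sampling.times()
    v_ind = _df_induction_noise_free(spec, t_ind)
    interior = (v_ind[1:-1] > v_ind[:-2]) & (v_ind[1:-1] > v_ind[2:])
    if int(interior.sum()) < 2 and spec.peak2_amp > 0:
        warnings.warn("DF induction bumps overlap into a single mode", stacklevel=2)

    t_dec = decay_sampling.times()
    amps = np.asarray(spec.decay_amps, dtype=float)
    taus = np.asarray(spec.decay_taus_ms, dtype=float) * 1000.0
    v_dec = np.sum(amps[:, None] * np.exp(-t_dec[None, :] / taus[:, None]), axis=0)

    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        v_ind = np.maximum(v_ind + rng.normal(0.0, spec.noise_sd, t_ind.size), 0.0)
        v_dec = np.maximum(v_dec + rng.normal(0.0, spec.noise_sd, t_dec.size), 0.0)

    return (
        KineticTrace(Channel.DF, t_ind, v_ind, group_label, replicate_id),
        KineticTrace(Channel.DF, t_dec, v_dec, group_label, replicate_id),
    )


def make_absorbance_record(truth: PigmentTruth, seed: int = 0,
                           group_label: str = "", replicate_id: str = "",
                           dialect: str = "acetone80") -> AbsorbanceRecord:
    """Absorbances obtained by inverting the pigment equations from truth.

    Replicate variation is applied on the concentration scale (multiplicative
    Gaussian with ``noise_cv``) before inversion, mimicking biological spread.
    """
    rng = np.random.default_rng(seed)
    conc = np.array([truth.chl_a, truth.chl_b, truth.carotenoids])
    if truth.noise_cv > 0:
        conc = np.maximum(conc * (1.0 + rng.normal(0.0, truth.noise_cv, 3)), 0.0)
    # mg/g FW -> ug/mL in the extract
    ug_ml = conc * 1000.0 * truth.fresh_mass_g / truth.extract_volume_ml
    a_a, a_b, a_470 = _pigments.invert_concentrations(*ug_ml, dialect=dialect)
    return AbsorbanceRecord(
        a_red_chl_a=a_a, a_red_chl_b=a_b, a_470=a_470,
        extract_volume=truth.extract_volume_ml, fresh_mass=truth.fresh_mass_g,
        group_label=group_label, replicate_id=replicate_id,
    )


def derive_seed(master_seed: int, *parts: str) -> int:
    """Deterministic per-stream seed from the master seed and string tags."""
    tag = "/".join(parts).encode()
    return (int(master_seed) * 1_000_003 + zlib.crc32(tag)) % (2**31)


def make_dataset(group_specs: dict[str, GroupSpec], n_replicates: int = 3,
                 seed: int = 0, pf_sampling: LogGrid | None = None,
                 mr_sampling: LogGrid | None = None,
                 ) -> tuple[list[KineticTrace], list[AbsorbanceRecord]]:
    """Full simulated experiment: per group x replicate, one PF + one MR +
    two DF traces and one absorbance record, all reproducibly seeded."""
    if n_replicates < 2:
        raise ConfigurationError("need n_replicates >= 2")
    if len(set(group_specs)) != len(group_specs):
        raise ConfigurationError("duplicate group labels")
    traces: list[KineticTrace] = []
    records: list[AbsorbanceRecord] = []
    for label, gs in group_specs.items():
        for rep in range(1, n_replicates + 1):
            rid = str(rep)
            pf = replace(gs.pf, seed=derive_seed(seed, label, rid, "PF"))
            mr = replace(gs.mr, seed=derive_seed(seed, label, rid, "MR"))
            df = replace(gs.df, seed=derive_seed(seed, label, rid, "DF"))
            traces.append(make_pf_trace(pf, pf_sampling, label, rid))
            traces.append(make_mr_trace(mr, mr_sampling, label, rid))
            traces.extend(make_df_traces(df, group_label=label, replicate_id=rid))
            records.append(
                make_absorbance_record(gs.pigments, derive_seed(seed, label, rid, "ABS"),
                                       label, rid)
            )
    return traces, records


def default_group_specs() -> dict[str, GroupSpec]:
    """Wild-type vs yellow-leaf-mutant study conditions.

    PF anchors are chosen so the analyzer recovers the reported group-level
    photochemistry: WT F_v/F_m = 0.82, psi_o = 0.70, phi_Ro = 0.20, with
    F_m = 2.6e4 counts giving RC/CS_M ~ 2.1e4; MT F_v/F_m = 0.73,
    psi_o = 0.43, phi_Ro = 0.12, with F_m = 2.4e4 and a larger K-step
    fraction so RC/CS_M ~ 1.2e4 while the dissipation flux per cross section
    (DI0/CS_M = phi_Do * F_m) comes out *higher* than WT, as observed for
    the mutant. Noise is 1% of F_m.

    The MT MR valley is deeper and faster (stronger PSI oxidation and
    re-reduction), with both minima inside the observed 15-20 ms window and
    the MT minimum earlier; MR noise reflects the heavy modulation averaging
    of the 820 nm channel. MT DF peaks are lower than WT. Pigment truths are
    the group means of the pigment assay (mg/g FW) with 5% replicate CV.
    """
    wt = GroupSpec(
        pf=PfSpec(f_o=0.18 * 26000, f_m=26000, v_J=0.30, v_I=1 - 0.20 / 0.82,
                  noise_sd=260.0),
        mr=MrSpec(amplitude=0.05, tau_ox_ms=8.0, tau_red_ms=70.0, noise_sd=1e-4),
        df=DfSpec(peak1_amp=1000.0, peak2_amp=600.0, decay_amps=(60.0, 40.0),
                  noise_sd=10.0),
        pigments=PigmentTruth(chl_a=0.38, chl_b=0.09, carotenoids=0.14, noise_cv=0.05),
    )
    mt = GroupSpec(
        pf=PfSpec(f_o=0.27 * 24000, f_m=24000, v_K=0.2056, v_J=0.57,
                  v_I=1 - 0.12 / 0.73, noise_sd=240.0),
        mr=MrSpec(amplitude=0.07, tau_ox_ms=6.5, tau_red_ms=70.0, noise_sd=1e-4),
        df=DfSpec(peak1_amp=600.0, peak2_amp=350.0, decay_amps=(36.0, 24.0),
                  noise_sd=10.0),
        pigments=PigmentTruth(chl_a=0.07, chl_b=0.03, carotenoids=0.15, noise_cv=0.05),
    )
    return {"WT": wt, "MT": mt}
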