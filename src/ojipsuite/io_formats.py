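"""Reading and writing kinetic traces and absorbance tables.

All time axes are stored internally in microseconds; file dialects declare
their own unit. Only delimited text (CSV/TSV, autodetected by extension) is
supported — no binary instrument export format is parsed.

Trace file dialect (default): header ``time_us,value[,channel,group,replicate]``,
UTF-8, ``.`` decimal separator. Absorbance file: header
``a_chl_a,a_chl_b,a_470,volume_ml,mass_g,group,replicate``.
"""

from __future__ import annotations

import enum
import logging
import os
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import FormatError, SchemaError, ValidationError

__all__ = [
    "Channel",
    "KineticTrace",
    "AbsorbanceRecord",
    "TraceDialect",
    "read_traces",
    "write_traces",
    "read_absorbances",
    "write_absorbances",
]

logger = logging.getLogger(__name__)

_US_PER_UNIT = {"us": 1.0, "ms": 1000.0, "s": 1e6}


class Channel(str, enum.Enum):
    """Measurement channel of a kinetic trace."""

    PF = "PF"  # prompt chlorophyll a fluorescence
    DF = "DF"  # delayed chlorophyll a fluorescence
    MR = "MR"  # modulated 820 nm reflection


@dataclass(frozen=True)
class KineticTrace:
    """One time-resolved signal for one replicate.

    Parameters
    ----------
    channel : Channel
        PF, DF or MR.
    times : ndarray
        Strictly increasing sample times in microseconds.
    values : ndarray
        Signal values; instrument counts for PF/DF (must be >= 0),
        arbitrary reflection units for MR.
    group_label, replicate_id : str
        Experimental-design metadata carried through every analysis table.
    """

    channel: Channel
    times: np.ndarray
    values: np.ndarray
    group_label: str = ""
    replicate_id: str = ""

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype=float)
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "channel", Channel(self.channel))
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "values", values)
        if times.ndim != 1 or values.ndim != 1:
            raise ValidationError("times and values must be one-dimensional")
        if len(times) != len(values):
            raise ValidationError(
                f"times ({len(times)}) and values ({len(values)}) differ in length"
            )
        if len(times) < 2:
            raise ValidationError(f"a trace needs >= 2 samples, got {len(times)}")
        if not (np.all(np.isfinite(times)) and np.all(np.isfinite(values))):
            raise ValidationError("times and values must be finite")
        if np.any(np.diff(times) <= 0):
            row = int(np.argmax(np.diff(times) <= 0)) + 1
            raise ValidationError(f"times not strictly increasing at sample {row}")
        if self.channel in (Channel.PF, Channel.DF) and np.any(values < 0):
            raise ValidationError(f"{self.channel.value} values must be >= 0")

    def __len__(self) -> int:
        return len(self.times)

    def with_values(self, values: np.ndarray) -> "KineticTrace":
        """Copy of this trace with new values on the same time axis."""
        return replace(self, values=np.asarray(values, dtype=float))


@dataclass(frozen=True)
class AbsorbanceRecord:
    """Spectrophotometric readings for one pigment extract.

    The two chlorophyll absorbances are read at the solvent dialect's red
    peaks (663.2/646.8 nm in 80% acetone, 664.2/648.6 nm in 95% ethanol);
    carotenoids at 470 nm.
    """

    a_red_chl_a: float
    a_red_chl_b: float
    a_470: float
    extract_volume: float  # mL
    fresh_mass: float  # g
    group_label: str = ""
    replicate_id: str = ""

    def __post_init__(self) -> None:
        for name in ("a_red_chl_a", "a_red_chl_b", "a_470"):
            v = float(getattr(self, name))
            object.__setattr__(self, name, v)
            if not np.isfinite(v) or v < 0:
                raise ValidationError(f"absorbance {name} must be finite and >= 0, got {v}")
        for name in ("extract_volume", "fresh_mass"):
            v = float(getattr(self, name))
            object.__setattr__(self, name, v)
            if not np.isfinite(v) or v <= 0:
                raise ValidationError(f"{name} must be positive, got {v}")


@dataclass(frozen=True)
class TraceDialect:
    """Column mapping and time unit of a trace file."""

    time_unit: str = "us"  # one of us | ms | s
    time_col: str = "time_us"
    value_col: str = "value"
    channel_col: str = "channel"
    group_col: str = "group"
    replicate_col: str = "replicate"
    default_channel: Channel = Channel.PF
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.time_unit not in _US_PER_UNIT:
            raise SchemaError(f"unknown time unit {self.time_unit!r} (use us/ms/s)")


def _read_table(path: str | os.PathLike) -> pd.DataFrame:
    sep = "\t" if str(path).endswith((".tsv", ".tab")) else ","
    try:
        return pd.read_csv(path, sep=sep, comment="#", float_precision="round_trip")
    except (pd.errors.ParserError, UnicodeDecodeError) as exc:
        raise FormatError(f"{path}: cannot parse as delimited text: {exc}") from exc


def read_traces(path: str | os.PathLike, dialect: TraceDialect | None = None) -> list[KineticTrace]:
    """Read kinetic traces from a delimited-text file.

    Rows are grouped into one trace per unique (channel, group, replicate)
    combination, preserving file order. Times are converted to microseconds.
    """
    dialect = dialect or TraceDialect()
    df = _read_table(path)
    for col in (dialect.time_col, dialect.value_col):
        if col not in df.columns:
            raise SchemaError(f"{path}: missing required column {col!r}")
    if dialect.channel_col not in df.columns:
        logger.warning("%s: no %r column; defaulting channel to %s",
                       path, dialect.channel_col, dialect.default_channel.value)
        df = df.assign(**{dialect.channel_col: dialect.default_channel.value})
    for col, default in ((dialect.group_col, ""), (dialect.replicate_col, "")):
        if col not in df.columns:
            df = df.assign(**{col: default})

    scale = _US_PER_UNIT[dialect.time_unit]
    traces: list[KineticTrace] = []
    keys = df[[dialect.channel_col, dialect.group_col, dialect.replicate_col]].astype(str)
    for (chan, group, rep), sub in df.groupby(
        [keys[dialect.channel_col], keys[dialect.group_col], keys[dialect.replicate_col]],
        sort=False,
    ):
        times = sub[dialect.time_col].to_numpy(dtype=float) * scale
        # one label set may hold several sweeps (e.g. DF induction then DF
        # decay): a drop in time starts a new trace; an exact repeat is an
        # error in the file.
        dup = np.nonzero(np.diff(times) == 0)[0]
        if dup.size:
            row = int(sub.index[dup[0] + 1]) + 2  # +2: header + 1-based
            raise FormatError(f"{path}: time column not strictly increasing at row {row}")
        starts = np.concatenate([[0], np.nonzero(np.diff(times) < 0)[0] + 1, [times.size]])
        values = sub[dialect.value_col].to_numpy(dtype=float)
        for lo, hi in zip(starts[:-1], starts[1:]):
            try:
                traces.append(
                    KineticTrace(
                        channel=Channel(chan),
                        times=times[lo:hi],
                        values=values[lo:hi],
                        group_label=group,
                        replicate_id=rep,
                    )
                )
            except ValueError as exc:
                raise FormatError(f"{path}: unknown channel {chan!r}") from exc
    return traces


def write_traces(traces: list[KineticTrace], path: str | os.PathLike,
                 header_comment: str | None = None) -> str:
    """Write traces in the canonical dialect; re-readable by :func:`read_traces`.

    Column order is fixed (``time_us,value,channel,group,replicate``) and
    floats are written with ``repr`` round-trip precision.
    """
    if not traces:
        raise ValidationError("cannot write an empty trace list")
    frames = [
        pd.DataFrame(
            {
                "time_us": t.times,
                "value": t.values,
                "channel": t.channel.value,
                "group": t.group_label,
                "replicate": t.replicate_id,
            }
        )
        for t in traces
    ]
    out = pd.concat(frames, ignore_index=True)
    with open(path, "w", encoding="utf-8", newline="") as fh:
        if header_comment:
            for line in header_comment.splitlines():
                fh.write(f"# {line}\n")
        out.to_csv(fh, index=False)
    return str(path)


_ABS_COLUMNS = ["a_chl_a", "a_chl_b", "a_470", "volume_ml", "mass_g", "group", "replicate"]


def read_absorbances(path: str | os.PathLike) -> list[AbsorbanceRecord]:
    """Read absorbance records; each row is validated against the domain invariants."""
    df = _read_table(path)
    missing = [c for c in _ABS_COLUMNS[:5] if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s) {missing}")
    records = []
    for i, row in df.iterrows():
        try:
            records.append(
                AbsorbanceRecord(
                    a_red_chl_a=row["a_chl_a"],
                    a_red_chl_b=row["a_chl_b"],
                    a_470=row["a_470"],
                    extract_volume=row["volume_ml"],
                    fresh_mass=row["mass_g"],
                    group_label=str(row.get("group", "")),
                    replicate_id=str(row.get("replicate", "")),
                )
            )
        except ValidationError as exc:
            raise ValidationError(f"{path}: row {i + 2}: {exc}") from exc
    return records


def write_absorbances(records: list[AbsorbanceRecord], path: str | os.PathLike) -> str:
    if not records:
        raise ValidationError("cannot write an empty absorbance list")
    df = pd.DataFrame(
        {
            "a_chl_a": [r.a_red_chl_a for r in records],
            "a_chl_b": [r.a_red_chl_b for r in records],
            "a_470": [r.a_470 for r in records],
            "volume_ml": [r.extract_volume for r in records],
            "mass_g": [r.fresh_mass for r in records],
            "group": [r.group_label for r in records],
            "replicate": [r.replicate_id for r in records],
        }
    )
    df.to_csv(path, index=False)
    return str(path)
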