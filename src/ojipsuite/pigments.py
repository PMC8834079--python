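"""Lichtenthaler spectrophotometric pigment quantification.

Concentrations in the extract (ug/mL) are linear combinations of three
absorbances; two published solvent dialects are supported:

acetone80 (80% acetone, red peaks 663.2 / 646.8 nm)::

    c_a  = 12.25 A663.2 - 2.79 A646.8
    c_b  = 21.50 A646.8 - 5.10 A663.2
    c_x  = (1000 A470 - 1.82 c_a - 85.02 c_b) / 198

ethanol95 (95% ethanol, red peaks 664.2 / 648.6 nm)::

    c_a  = 13.36 A664.2 - 5.19 A648.6
    c_b  = 27.43 A648.6 - 8.12 A664.2
    c_x  = (1000 A470 - 2.13 c_a - 97.64 c_b) / 209

Contents per fresh mass follow as ``mg/g = c * V_mL / (1000 * m_g)``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ConfigurationError, ValidationError
from .io_formats import AbsorbanceRecord

__all__ = [
    "PigmentResult",
    "pigment_concentrations",
    "pigment_table",
    "invert_concentrations",
    "DIALECTS",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class _Dialect:
    # c_a = ca_a * A_a + ca_b * A_b ; c_b = cb_a * A_a + cb_b * A_b
    ca_a: float
    ca_b: float
    cb_a: float
    cb_b: float
    # c_x = (1000 A470 - x_a c_a - x_b c_b) / x_den
    x_a: float
    x_b: float
    x_den: float


DIALECTS = {
    "acetone80": _Dialect(12.25, -2.79, -5.10, 21.50, 1.82, 85.02, 198.0),
    "ethanol95": _Dialect(13.36, -5.19, -8.12, 27.43, 2.13, 97.64, 209.0),
}


@dataclass(frozen=True)
class PigmentResult:
    """Pigment contents per fresh mass (Lichtenthaler method).

    ``chl_ab_ratio`` is NaN when chl b is zero (flagged undefined).
    """

    chl_a: float  # mg/g FW
    chl_b: float
    chl_total: float
    chl_ab_ratio: float
    carotenoids: float
    solvent_dialect: str
    group_label: str = ""
    replicate_id: str = ""


def _get_dialect(dialect: str) -> _Dialect:
    try:
        return DIALECTS[dialect]
    except KeyError:
        raise ConfigurationError(
            f"unknown solvent dialect {dialect!r}; choose from {sorted(DIALECTS)}"
        ) from None


def pigment_concentrations(rec: AbsorbanceRecord, dialect: str = "acetone80") -> PigmentResult:
    """Convert one absorbance record to pigment contents (mg/g fresh weight).

    Negative solved concentrations (possible for noisy near-zero extracts)
    clamp to 0 with a logged warning.
    """
    d = _get_dialect(dialect)
    c_a = d.ca_a * rec.a_red_chl_a + d.ca_b * rec.a_red_chl_b
    c_b = d.cb_a * rec.a_red_chl_a + d.cb_b * rec.a_red_chl_b
    c_x = (1000.0 * rec.a_470 - d.x_a * c_a - d.x_b * c_b) / d.x_den
    clamped = [n for n, c in (("chl_a", c_a), ("chl_b", c_b), ("carotenoids", c_x)) if c < 0]
    if clamped:
        logger.warning("negative concentration(s) %s clamped to 0 (%s/%s)",
                       clamped, rec.group_label, rec.replicate_id)
    c_a, c_b, c_x = (max(c, 0.0) for c in (c_a, c_b, c_x))
    scale = rec.extract_volume / (1000.0 * rec.fresh_mass)  # ug/mL -> mg/g FW
    chl_a, chl_b, car = c_a * scale, c_b * scale, c_x * scale
    ratio = chl_a / chl_b if chl_b > 0 else float("nan")
    return PigmentResult(chl_a, chl_b, chl_a + chl_b, ratio, car, dialect,
                         rec.group_label, rec.replicate_id)


def invert_concentrations(chl_a_ug_ml: float, chl_b_ug_ml: float, car_ug_ml: float,
                          dialect: str = "acetone80") -> tuple[float, float, float]:
    """Absorbances that solve the dialect's equations for the given ug/mL
    concentrations — the forward model of the synthetic generator."""
    d = _get_dialect(dialect)
    m = np.array([[d.ca_a, d.ca_b], [d.cb_a, d.cb_b]])
    a_a, a_b = np.linalg.solve(m, [chl_a_ug_ml, chl_b_ug_ml])
    if a_a < 0 or a_b < 0:
        raise ValidationError("concentrations invert to negative absorbances")
    a_470 = (d.x_den * car_ug_ml + d.x_a * chl_a_ug_ml + d.x_b * chl_b_ug_ml) / 1000.0
    return float(a_a), float(a_b), float(a_470)


def pigment_table(recs: list[AbsorbanceRecord], dialect="acetone80") -> pd.DataFrame:
    """Per-replicate pigment table (columns mirror the standard pigment assay
    report: chl a, chl b, total, a/b ratio, carotenoids).

    ``dialect`` may be one name or a per-record sequence; mixing dialects in
    one table is a configuration error (coefficients would not be comparable).
    """
    if not recs:
        raise ValidationError("need at least one absorbance record")
    if not isinstance(dialect, str):
        unique = set(dialect)
        if len(unique) != 1:
            raise ConfigurationError(f"mixed solvent dialects in one table: {sorted(unique)}")
        dialect = unique.pop()
    rows = []
    for rec in recs:
        res = pigment_concentrations(rec, dialect)
        rows.append(
            {
                "group": res.group_label,
                "replicate": res.replicate_id,
                "chl_a": res.chl_a,
                "chl_b": res.chl_b,
                "chl_total": res.chl_total,
                "chl_ab_ratio": res.chl_ab_ratio,
                "carotenoids": res.carotenoids,
            }
        )
    return pd.DataFrame(rows)
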