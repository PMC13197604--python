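"""Quantum yields of photosystem II from PAM chlorophyll fluorescence.

Three standard parameters are derived per measurement:

- ``F_v/F_m = (F_m - F_o)/F_m`` — maximum quantum yield of open PSII centres
  in dark-adapted tissue;
- ``Phi_PSII = 1 - F_s/F'_m`` — effective quantum yield of a light-adapted
  sample;
- ``Phi_NPQ = F_s/F'_m - F_s/F_m`` — fraction of absorbed light thermally
  dissipated via qE-type, xanthophyll-regulated non-photochemical quenching.

Raw F values are taken as the instrument reports them (relative units); no
calibration is re-applied.  Physiologically anomalous records (F_o > F_m,
F_s > F'_m, non-positive maxima) are retained but flagged invalid so that
downstream statistics can exclude them without losing the audit trail.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Optional

import numpy as np
import pandas as pd

__all__ = [
    "STAGES",
    "FluorescenceRecord",
    "fv_fm",
    "phi_psii",
    "phi_npq",
    "derive_all",
    "derive_table",
    "read_fluorescence_csv",
    "write_yields_csv",
]

#: Tissue-stage codes: seedling, young stem, old stem, haustorium, flower,
#: seed, plus the outgroup-only leaf stage.
STAGES = ("sdlg", "y", "o", "h", "f", "sd", "leaf")


class InvalidMeasurementError(ValueError):
    """A fluorescence value violates a hard precondition (e.g. F_m <= 0)."""


@dataclass(frozen=True)
class FluorescenceRecord:
    species: str
    individual: str
    stage: str
    F_o: float
    F_m: float
    F_s: float
    F_m_prime: float
    fv_fm: Optional[float] = None
    phi_psii: Optional[float] = None
    phi_npq: Optional[float] = None
    valid: bool = True


def fv_fm(F_o: float, F_m: float) -> float:
    """Maximum quantum yield of open PSII centres, (F_m - F_o)/F_m."""
    if F_m <= 0:
        raise InvalidMeasurementError(f"F_m must be positive, got {F_m}")
    if F_o < 0:
        raise InvalidMeasurementError(f"F_o must be non-negative, got {F_o}")
    return (F_m - F_o) / F_m


def phi_psii(F_s: float, F_m_prime: float) -> float:
    """Effective quantum yield of PSII in the light, 1 - F_s/F'_m."""
    if F_m_prime <= 0:
        raise InvalidMeasurementError(f"F'_m must be positive, got {F_m_prime}")
    return 1.0 - F_s / F_m_prime


def phi_npq(F_s: float, F_m_prime: float, F_m: float) -> float:
    """Quantum yield of regulated non-photochemical quenching.

    ``F_s/F'_m - F_s/F_m``; non-negative whenever F_m >= F'_m, which holds
    for a physiologically sensible measurement (quenching can only lower the
    light-adapted maximum).
    """
    if F_m_prime <= 0 or F_m <= 0:
        raise InvalidMeasurementError("F'_m and F_m must be positive")
    return F_s / F_m_prime - F_s / F_m


def _record_valid(r: FluorescenceRecord) -> bool:
    return (
        r.F_m > 0
        and r.F_m_prime > 0
        and 0 <= r.F_o <= r.F_m
        and 0 <= r.F_s <= r.F_m_prime
    )


def derive_all(records: Iterable[FluorescenceRecord]) -> list[FluorescenceRecord]:
    """Fill the three derived yields on every record.

    Records violating preconditions are returned with ``valid=False`` and
    yields left unset rather than dropped: the outlier screen downstream
    decides what to exclude.  Raw F fields are never mutated.
    """
    out = []
    for rec in records:
        if _record_valid(rec):
            out.append(
                replace(
                    rec,
                    fv_fm=fv_fm(rec.F_o, rec.F_m),
                    phi_psii=phi_psii(rec.F_s, rec.F_m_prime),
                    phi_npq=phi_npq(rec.F_s, rec.F_m_prime, rec.F_m),
                    valid=True,
                )
            )
        else:
            out.append(replace(rec, valid=False))
    return out


def derive_table(df: pd.DataFrame) -> pd.DataFrame:
    """Vectorized :func:`derive_all` on a raw fluorescence table.

    Expects columns species, individual, stage, F_o, F_m, F_s, F_m_prime;
    returns a copy with fv_fm, phi_psii, phi_npq and a boolean ``valid``
    column appended (yields are NaN on invalid rows).
    """
    out = df.copy()
    F_o = out["F_o"].to_numpy(float)
    F_m = out["F_m"].to_numpy(float)
    F_s = out["F_s"].to_numpy(float)
    F_mp = out["F_m_prime"].to_numpy(float)
    valid = (F_m > 0) & (F_mp > 0) & (F_o >= 0) & (F_o <= F_m) & (F_s >= 0) & (F_s <= F_mp)
    with np.errstate(divide="ignore", invalid="ignore"):
        out["fv_fm"] = np.where(valid, (F_m - F_o) / np.where(F_m != 0, F_m, np.nan), np.nan)
        out["phi_psii"] = np.where(valid, 1.0 - F_s / np.where(F_mp != 0, F_mp, np.nan), np.nan)
        out["phi_npq"] = np.where(
            valid,
            F_s / np.where(F_mp != 0, F_mp, np.nan) - F_s / np.where(F_m != 0, F_m, np.nan),
            np.nan,
        )
    out["valid"] = valid
    return out


def read_fluorescence_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    required = {"species", "individual", "stage", "F_o", "F_m", "F_s", "F_m_prime"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"fluorescence table missing columns: {sorted(missing)}")
    return df


def write_yields_csv(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False)
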