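"""Dose quantities derived from scan settings.

Implements the standard chain of CT dose estimates:

    mAs  = tube current x exposure time
    DLP  = CTDIvol x scan length [cm]
    effective diameter = sqrt(AP x ML) rounded half-up to whole cm
    SSDE = CTDIvol x size-dependent factor(effective diameter)
    ED   = DLP x diameter-specific conversion factor

Conversion factors are data, not code: they ship as an editable CSV
(``ctqa/data/conversion_factors.csv``) keyed by effective diameter in cm,
with linear interpolation between entries and strict refusal to
extrapolate outside the tabulated range.
"""

from __future__ import annotations

import math
import os
from dataclasses import dataclass, field
from importlib import resources
from typing import Optional

import numpy as np
import pandas as pd

__all__ = [
    "ScanRecord",
    "ConversionTable",
    "DoseEstimates",
    "compute_mas",
    "compute_dlp",
    "effective_diameter",
    "compute_ssde",
    "compute_effective_dose",
    "estimate_doses",
    "default_conversion_table",
    "load_scan_records",
]


@dataclass
class ScanRecord:
    """Acquisition settings for one scan, plus optional patient diameters."""

    kvp: float  # kV
    ma: float  # mA
    rotation_time: float  # s (doubles as exposure time in axial mode)
    ctdi_vol: float | None = None  # mGy, 32 cm reference phantom
    scan_length: float | None = None  # cm
    ap_diameter: float | None = None  # cm
    ml_diameter: float | None = None  # cm
    scan_id: str = ""
    phantom: str = ""
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name in ("kvp", "ma", "rotation_time", "ctdi_vol", "scan_length",
                     "ap_diameter", "ml_diameter"):
            value = getattr(self, name)
            if value is not None and (not math.isfinite(value) or value <= 0):
                raise ValueError(f"{name} must be strictly positive, got {value}")

    @property
    def mas(self) -> float:
        return compute_mas(self.ma, self.rotation_time)


def compute_mas(ma: float, exposure_time: float) -> float:
    """Tube current-time product in mAs."""
    if ma <= 0 or exposure_time <= 0:
        raise ValueError("mA and exposure time must be positive")
    return ma * exposure_time


def compute_dlp(ctdi_vol: float, scan_length: float) -> float:
    """Dose-length product: CTDIvol [mGy] x scan length [cm]."""
    if ctdi_vol <= 0 or scan_length <= 0:
        raise ValueError("CTDIvol and scan length must be positive")
    return ctdi_vol * scan_length


def effective_diameter(ap: float, ml: float) -> int:
    """Effective diameter sqrt(AP x ML), rounded half-up to whole centimetres."""
    if ap <= 0 or ml <= 0:
        raise ValueError("AP and ML diameters must be positive")
    return int(math.floor(math.sqrt(ap * ml) + 0.5))


class ConversionTable:
    """Size-dependent SSDE and effective-dose conversion factors.

    Rows map an integer effective diameter (cm) to an SSDE factor
    (dimensionless) and an ED factor (mSv per mGy*cm).  Lookups at
    non-tabulated diameters inside the table range interpolate linearly;
    lookups outside the range raise.
    """

    def __init__(self, diameters, ssde_factors, ed_factors):
        d = np.asarray(diameters, dtype=float)
        s = np.asarray(ssde_factors, dtype=float)
        e = np.asarray(ed_factors, dtype=float)
        if d.size == 0 or d.size != s.size or d.size != e.size:
            raise ValueError("table columns must be non-empty and equal length")
        if len(np.unique(d)) != d.size:
            raise ValueError("duplicate effective diameters in conversion table")
        if np.any(s <= 0) or np.any(e <= 0):
            raise ValueError("conversion factors must be strictly positive")
        order = np.argsort(d)
        self.diameters = d[order]
        self.ssde_factors = s[order]
        self.ed_factors = e[order]

    @classmethod
    def from_csv(cls, path: str | os.PathLike) -> "ConversionTable":
        df = pd.read_csv(os.fspath(path), comment="#")
        return cls(
            df["effective_diameter_cm"].to_numpy(),
            df["ssde_factor"].to_numpy(),
            df["ed_factor"].to_numpy(),
        )

    def _interp(self, diameter: float, values: np.ndarray) -> float:
        if diameter < self.diameters[0] or diameter > self.diameters[-1]:
            raise ValueError(
                f"effective diameter {diameter} cm outside the tabulated range "
                f"[{self.diameters[0]:g}, {self.diameters[-1]:g}] cm; refusing to extrapolate"
            )
        return float(np.interp(diameter, self.diameters, values))

    def ssde_factor(self, diameter: float) -> float:
        return self._interp(diameter, self.ssde_factors)

    def ed_factor(self, diameter: float) -> float:
        return self._interp(diameter, self.ed_factors)


def default_conversion_table() -> ConversionTable:
    """The packaged conversion-factor table."""
    with resources.as_file(
        resources.files("ctqa.data").joinpath("conversion_factors.csv")
    ) as path:
        return ConversionTable.from_csv(path)


def compute_ssde(ctdi_vol: float, diameter: float, table: ConversionTable) -> float:
    """Size-specific dose estimate [mGy]."""
    if ctdi_vol <= 0:
        raise ValueError("CTDIvol must be positive")
    return ctdi_vol * table.ssde_factor(diameter)


def compute_effective_dose(dlp: float, diameter: float, table: ConversionTable) -> float:
    """Effective dose [mSv] = DLP x diameter-specific conversion factor."""
    if dlp <= 0:
        raise ValueError("DLP must be positive")
    return dlp * table.ed_factor(diameter)


@dataclass
class DoseEstimates:
    mas: float
    dlp: float | None = None
    effective_diameter: int | None = None
    ssde: float | None = None
    effective_dose: float | None = None


def estimate_doses(
    record: ScanRecord, table: Optional[ConversionTable] = None
) -> DoseEstimates:
    """Derive all available dose quantities for one scan record.

    SSDE and effective dose are filled in only when the record carries both
    chest diameters and a conversion table is supplied.
    """
    est = DoseEstimates(mas=record.mas)
    if record.ctdi_vol is not None and record.scan_length is not None:
        est.dlp = compute_dlp(record.ctdi_vol, record.scan_length)
    if record.ap_diameter is not None and record.ml_diameter is not None:
        est.effective_diameter = effective_diameter(record.ap_diameter, record.ml_diameter)
        if table is not None:
            if record.ctdi_vol is not None:
                est.ssde = compute_ssde(record.ctdi_vol, est.effective_diameter, table)
            if est.dlp is not None:
                est.effective_dose = compute_effective_dose(
                    est.dlp, est.effective_diameter, table
                )
    return est


def load_scan_records(path: str | os.PathLike) -> list[ScanRecord]:
    """Read scan settings from a CSV with per-scan rows.

    Recognized columns: scan_id, phantom, kvp, ma, rotation_time, ctdi_vol,
    scan_length, ap_diameter, ml_diameter.  Missing optional columns yield
    ``None`` fields.
    """
    df = pd.read_csv(os.fspath(path), comment="#")

    def opt(row, col):
        if col in row and pd.notna(row[col]):
            return float(row[col])
        return None

    records = []
    for _, row in df.iterrows():
        records.append(
            ScanRecord(
                kvp=float(row["kvp"]),
                ma=float(row["ma"]),
                rotation_time=float(row.get("rotation_time", 0.28)),
                ctdi_vol=opt(row, "ctdi_vol"),
                scan_length=opt(row, "scan_length"),
                ap_diameter=opt(row, "ap_diameter"),
                ml_diameter=opt(row, "ml_diameter"),
                scan_id=str(row.get("scan_id", "")),
                phantom=str(row.get("phantom", "")),
            )
        )
    return records
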