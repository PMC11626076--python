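"""Reader ratings, diagnostic-quality decisions, ICC(3,k) and dose response.

A scan counts as diagnostic when the across-reader mean of the five-item
Likert sum exceeds 14 AND every reader rates overall quality at least 3.
Inter-reader reliability uses the two-way mixed, consistency, average-
measures intraclass correlation ICC(3,k) = (MSR - MSE) / MSR.
"""

from __future__ import annotations

import math
import os
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .dosimetry import ConversionTable, ScanRecord, estimate_doses
from .sharpness import ScanSharpness

__all__ = [
    "RATING_ITEMS",
    "QUALITY_ITEMS",
    "RatingTable",
    "DiagnosticDecision",
    "DoseResponseFit",
    "ICCResult",
    "diagnostic_decision",
    "icc_3k",
    "icc_interpretation",
    "fit_dose_response",
    "threshold_analysis",
    "ThresholdResult",
]

QUALITY_ITEMS = (
    "streak_artefacts",
    "noise",
    "pleura_sharpness",
    "structure_sharpness",
    "small_structure_visibility",
)
RATING_ITEMS = ("overall",) + QUALITY_ITEMS

DEFAULT_SUM_THRESHOLD = 14.0  # strict: mean five-item sum must exceed this
DEFAULT_OVERALL_MIN = 3  # every reader's overall score must reach this


class RatingTable:
    """Likert scores (1-4) indexed by scan, reader and item.

    Construct from a long-format DataFrame/CSV with columns
    ``scan_id, reader_id, item, score``.  Items are ``overall`` plus the
    five quality items; ``overall`` never enters the five-item sum.
    """

    def __init__(self, frame: pd.DataFrame):
        required = {"scan_id", "reader_id", "item", "score"}
        missing = required - set(frame.columns)
        if missing:
            raise ValueError(f"ratings table missing columns: {sorted(missing)}")
        frame = frame.copy()
        bad_items = set(frame["item"]) - set(RATING_ITEMS)
        if bad_items:
            raise ValueError(f"unknown rating items: {sorted(bad_items)}")
        scores = frame["score"].to_numpy()
        if not np.isin(scores, [1, 2, 3, 4]).all():
            raise ValueError("all Likert scores must be integers in 1..4")
        dupes = frame.duplicated(["scan_id", "reader_id", "item"])
        if dupes.any():
            raise ValueError("duplicate (scan, reader, item) ratings")
        self.frame = frame
        self.scans = list(pd.unique(frame["scan_id"]))
        self.readers = list(pd.unique(frame["reader_id"]))

    @classmethod
    def from_csv(cls, path: str | os.PathLike) -> "RatingTable":
        return cls(pd.read_csv(os.fspath(path), comment="#"))

    def _pivot(self) -> pd.DataFrame:
        return self.frame.pivot_table(
            index=["scan_id", "reader_id"], columns="item", values="score", aggfunc="first"
        )

    def scores_for(self, scan_id) -> pd.DataFrame:
        """Readers x items score matrix for one scan; errors on missing cells."""
        sub = self._pivot().loc[scan_id] if scan_id in set(self.frame["scan_id"]) else None
        if sub is None:
            raise KeyError(f"scan {scan_id!r} not present in ratings")
        sub = sub.reindex(index=self.readers, columns=list(RATING_ITEMS))
        if sub.isna().any().any():
            missing = [
                (r, c) for r in sub.index for c in sub.columns if pd.isna(sub.loc[r, c])
            ]
            raise ValueError(f"missing ratings for scan {scan_id!r}: {missing}")
        return sub

    def item_matrix(self, item: str) -> np.ndarray:
        """scans x readers matrix of one item's scores (for ICC)."""
        if item not in RATING_ITEMS:
            raise ValueError(f"unknown item {item!r}")
        wide = self.frame[self.frame["item"] == item].pivot(
            index="scan_id", columns="reader_id", values="score"
        )
        wide = wide.reindex(index=self.scans, columns=self.readers)
        if wide.isna().any().any():
            raise ValueError(f"missing {item!r} ratings; ICC requires complete data")
        return wide.to_numpy(dtype=float)

    def composite_sum_matrix(self) -> np.ndarray:
        """scans x readers matrix of the five-item sums."""
        return sum(self.item_matrix(item) for item in QUALITY_ITEMS)


@dataclass
class DiagnosticDecision:
    scan_id: object
    mean_item_sum: float  # across-reader mean of the five-item sum, in [5, 20]
    all_readers_overall_ok: bool
    diagnostic: bool


def diagnostic_decision(
    ratings: RatingTable,
    scan_id,
    sum_threshold: float = DEFAULT_SUM_THRESHOLD,
    overall_min: int = DEFAULT_OVERALL_MIN,
) -> DiagnosticDecision:
    """Apply the diagnostic-quality rule to one scan.

    Diagnostic iff the across-reader mean five-item sum strictly exceeds
    ``sum_threshold`` and every reader's overall score is >= ``overall_min``.
    """
    scores = ratings.scores_for(scan_id)
    item_sums = scores[list(QUALITY_ITEMS)].sum(axis=1)
    mean_sum = float(item_sums.mean())
    overall_ok = bool((scores["overall"] >= overall_min).all())
    return DiagnosticDecision(
        scan_id=scan_id,
        mean_item_sum=mean_sum,
        all_readers_overall_ok=overall_ok,
        diagnostic=(mean_sum > sum_threshold) and overall_ok,
    )


@dataclass
class ICCResult:
    value: float
    msr: float
    mse: float
    df1: int
    df2: int
    ci_low: float = math.nan
    ci_high: float = math.nan
    interpretation: str = ""


def icc_interpretation(value: float) -> str:
    """Reliability band label for an ICC value."""
    if value < 0.5:
        return "poor"
    if value < 0.75:
        return "moderate"
    if value <= 0.9:
        return "good"
    return "excellent"


def icc_3k(scores: np.ndarray, confidence: float | None = 0.95) -> ICCResult:
    """ICC(3,k): two-way mixed, consistency, average of k raters.

    ``scores`` is an n_subjects x k_raters matrix with no missing cells.
    Returns (MSR - MSE) / MSR from the two-way ANOVA mean squares, with an
    optional F-based confidence interval.
    """
    scores = np.asarray(scores, dtype=float)
    if scores.ndim != 2:
        raise ValueError("scores must be a 2D subjects x raters matrix")
    n, k = scores.shape
    if n < 2 or k < 2:
        raise ValueError(f"need at least 2 subjects and 2 raters, got {n}x{k}")
    if not np.isfinite(scores).all():
        raise ValueError("scores contain missing or non-finite cells")

    grand = scores.mean()
    row_means = scores.mean(axis=1)
    col_means = scores.mean(axis=0)
    ssr = k * np.sum((row_means - grand) ** 2)
    ssc = n * np.sum((col_means - grand) ** 2)
    sst = np.sum((scores - grand) ** 2)
    sse = sst - ssr - ssc
    df1 = n - 1
    df2 = (n - 1) * (k - 1)
    msr = ssr / df1
    mse = sse / df2
    if msr <= 0:
        raise ValueError("between-subject mean square is zero; ICC undefined")
    value = (msr - mse) / msr

    result = ICCResult(
        value=float(value), msr=float(msr), mse=float(mse), df1=df1, df2=df2,
        interpretation=icc_interpretation(float(value)),
    )
    if confidence is not None and mse > 0:
        alpha = 1.0 - confidence
        f_obs = msr / mse
        fl = f_obs / stats.f.ppf(1 - alpha / 2, df1, df2)
        fu = f_obs * stats.f.ppf(1 - alpha / 2, df2, df1)
        result.ci_low = float(1 - 1 / fl)
        result.ci_high = float(1 - 1 / fu)
    return result


@dataclass
class DoseResponseFit:
    predictor: str
    response: str
    degree: int
    coefficients: np.ndarray  # ascending powers
    r_squared: float
    residual_ss: float
    _x: np.ndarray = field(default_factory=lambda: np.empty(0), repr=False)
    _y: np.ndarray = field(default_factory=lambda: np.empty(0), repr=False)

    def predict(self, x) -> np.ndarray:
        return np.polynomial.polynomial.polyval(np.asarray(x, dtype=float), self.coefficients)

    def ci_band(self, x, confidence: float = 0.95) -> tuple[np.ndarray, np.ndarray]:
        """Pointwise CI for the fitted mean curve (reporting/plotting only)."""
        x = np.asarray(x, dtype=float)
        design = np.vander(self._x, self.degree + 1, increasing=True)
        n, p = design.shape
        dof = n - p
        if dof <= 0:
            raise ValueError("not enough points for a confidence band")
        sigma2 = self.residual_ss / dof
        cov = sigma2 * np.linalg.inv(design.T @ design)
        x0 = np.vander(x, self.degree + 1, increasing=True)
        se = np.sqrt(np.einsum("ij,jk,ik->i", x0, cov, x0))
        t = stats.t.ppf(0.5 + confidence / 2, dof)
        center = self.predict(x)
        return center - t * se, center + t * se


def fit_dose_response(
    doses: Sequence[float],
    responses: Sequence[float],
    degree: int = 3,
    predictor: str = "dose",
    response: str = "response",
) -> DoseResponseFit:
    """Ordinary least-squares polynomial fit of an image-quality metric to dose."""
    if degree not in (1, 2, 3):
        raise ValueError(f"degree must be 1, 2 or 3, got {degree}")
    x = np.asarray(doses, dtype=float)
    y = np.asarray(responses, dtype=float)
    if x.size != y.size:
        raise ValueError("doses and responses must have equal length")
    if x.size < degree + 2:
        raise ValueError(f"need at least {degree + 2} points for a degree-{degree} fit")
    if len(np.unique(x)) <= degree:
        raise ValueError("design is rank deficient: too few distinct dose values")
    design = np.vander(x, degree + 1, increasing=True)
    coef, _, rank, _ = np.linalg.lstsq(design, y, rcond=None)
    if rank < degree + 1:
        raise ValueError("design is rank deficient")
    fitted = design @ coef
    rss = float(np.sum((y - fitted) ** 2))
    tss = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 if tss == 0 else 1.0 - rss / tss
    return DoseResponseFit(
        predictor=predictor,
        response=response,
        degree=degree,
        coefficients=coef,
        r_squared=r2,
        residual_ss=rss,
        _x=x,
        _y=y,
    )


@dataclass
class ThresholdResult:
    found: bool
    record: Optional[ScanRecord] = None
    sharpness_cutoff: float = math.nan  # HU/mm, median steepness of the chosen scan
    decision: Optional[DiagnosticDecision] = None


def threshold_analysis(
    scans: Sequence[tuple[ScanRecord, ScanSharpness, DiagnosticDecision]],
    table: Optional[ConversionTable] = None,
) -> ThresholdResult:
    """Lowest-dose diagnostic scan and its median steepness as sharpness cut-off.

    Among scans whose decision is diagnostic, selects the one with minimal
    effective dose (falling back to CTDIvol when effective dose is not
    computable, then mAs as final tie-break).  Returns an empty result when
    no scan is diagnostic.
    """
    candidates = []
    for record, sharp, decision in scans:
        if not decision.diagnostic:
            continue
        doses = estimate_doses(record, table)
        ed = doses.effective_dose if doses.effective_dose is not None else math.inf
        ctdi = record.ctdi_vol if record.ctdi_vol is not None else math.inf
        candidates.append(((ed, ctdi, doses.mas), record, sharp, decision))
    if not candidates:
        return ThresholdResult(found=False)
    key, record, sharp, decision = min(candidates, key=lambda c: c[0])
    return ThresholdResult(
        found=True,
        record=record,
        sharpness_cutoff=float(sharp.median_steepness),
        decision=decision,
    )
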