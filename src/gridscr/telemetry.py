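"""Acoustic-telemetry activity spaces (bivariate normal KUDs).

Passive acoustic monitoring gives, per tagged individual, a series of
detections at fixed receivers.  Fitting a bivariate normal to the detection
positions yields a parametric kernel utilization distribution whose
q-quantile area ``-2 pi ln(1-q) sqrt(det(Sigma))`` is directly comparable to
the SCR model's activity-space estimate: for an isotropic covariance
``sigma^2 I`` it equals the closed-form circular area.  This is the
independent check of the SCR stationarity/activity-space assumptions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "DetectionSeries",
    "KUDResult",
    "filter_series",
    "fit_bvn_kud",
    "kud_population_summary",
]

DAYS_PER_MONTH = 30.44


@dataclass
class DetectionSeries:
    """Detections of one acoustic tag.

    ``times`` are days (float) since an arbitrary epoch, non-decreasing;
    ``receiver_ids`` aligns with times; ``receiver_positions`` maps receiver
    id -> (x, y) km.
    """

    tag_id: str
    times: np.ndarray
    receiver_ids: np.ndarray
    receiver_positions: dict

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.receiver_ids = np.asarray(self.receiver_ids)
        if self.times.shape != self.receiver_ids.shape:
            raise ValueError("times and receiver_ids must align")
        if np.any(np.diff(self.times) < 0):
            raise ValueError("timestamps must be non-decreasing")
        missing = set(np.unique(self.receiver_ids)) - set(self.receiver_positions)
        if missing:
            raise ValueError(f"receivers without positions: {sorted(missing)}")

    @property
    def n_detections(self) -> int:
        return self.times.size

    @property
    def span_months(self) -> float:
        if self.times.size == 0:
            return 0.0
        return float(self.times[-1] - self.times[0]) / DAYS_PER_MONTH

    def positions(self) -> np.ndarray:
        """(n, 2) detection positions = receiver coordinates per detection."""
        return np.array([self.receiver_positions[r] for r in self.receiver_ids], dtype=float)


@dataclass
class KUDResult:
    """Bivariate normal KUD fit for one tag."""

    tag_id: str
    n_detections: int
    span_months: float
    cov: np.ndarray = field(repr=False)
    area: float
    quantile: float


def filter_series(
    series: list, min_detections: int = 100, min_months: float = 10.0
) -> list:
    """Keep tags with strictly more than ``min_detections`` detections and a
    first-to-last span of at least ``min_months`` (30.44-day months)."""
    return [
        s
        for s in series
        if s.n_detections > min_detections and s.span_months >= min_months
    ]


def fit_bvn_kud(series: DetectionSeries, q: float = 0.99) -> KUDResult:
    """Fit a bivariate normal KUD and its q-quantile area.

    The position sample is the receiver position of every detection; the
    covariance is the sample covariance and the area generalizes the circular
    formula to ellipses: ``-2 pi ln(1-q) sqrt(det(Sigma))``.
    """
    if not (0.0 < q < 1.0):
        raise ValueError("quantile must lie in (0, 1)")
    pos = series.positions()
    if np.unique(pos, axis=0).shape[0] < 3:
        raise ValueError(
            f"tag {series.tag_id}: need detections on >= 3 distinct receivers"
        )
    cov = np.cov(pos.T, ddof=1)
    det = float(np.linalg.det(cov))
    if det <= 0 or not np.isfinite(det):
        raise ValueError(
            f"tag {series.tag_id}: degenerate detection geometry (collinear receivers)"
        )
    area = -2.0 * np.pi * np.log1p(-q) * np.sqrt(det)
    return KUDResult(series.tag_id, series.n_detections, series.span_months, cov, float(area), q)


def kud_population_summary(results: list) -> dict:
    """Mean KUD area with normal-approximation 95% CI, plus min and max."""
    if len(results) < 2:
        raise ValueError("population summary needs at least 2 individuals")
    areas = np.array([r.area for r in results], dtype=float)
    se = areas.std(ddof=1) / np.sqrt(areas.size)
    mean = float(areas.mean())
    return {
        "n": int(areas.size),
        "mean": mean,
        "ci": (mean - 1.96 * se, mean + 1.96 * se),
        "min": float(areas.min()),
        "max": float(areas.max()),
    }
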