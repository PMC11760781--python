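"""Statistical model of Q-score versus reported resolution.

Across the EMDB archive, model-average Q-scores track the reported map
resolution d closely.  A cubic polynomial fitted to ~10k archived map/model
pairs gives the expected value

    Q_mean(d) = -0.0016 d³ + 0.0434 d² - 0.3956 d + 1.3366

and three vertical offsets of that curve summarise the empirical residual
distribution:

    Q_peak     = Q_mean + 0.024    (mode of the residuals)
    Q_low_95%  = Q_mean - 0.126    (2.5th residual percentile)
    Q_high_95% = Q_mean + 0.109    (97.5th residual percentile)

so 95% of archive entries fall between the low and high curves.  The
residual distribution is skewed toward low Q (poorly fitted models), which
is why |offset_low| > offset_high and the mode sits above the mean.  These
published constants ship as :data:`PUBLISHED_MODEL`; the same pipeline
(cubic least squares + offset calibration) can be re-run on any
user-supplied (resolution, Q) table.  A regression-free rolling-window
variant provides the same three curves directly from windowed data.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import ComputationError, ExtrapolationWarning, InputError

__all__ = [
    "ResolutionStatModel",
    "CalibrationDataset",
    "PUBLISHED_MODEL",
    "q_mean",
    "q_bounds",
    "fit_regression",
    "calibrate_offsets",
    "rolling_window_bounds",
    "classify_entry",
    "Classification",
]


@dataclass(frozen=True)
class ResolutionStatModel:
    """Cubic trend plus offsets defining the Q-vs-resolution curves.

    ``coefficients`` are (c3, c2, c1, c0) of Q_mean(d); the three offsets
    place the peak (mode) curve and the 95% coverage band.  ``r_squared``
    is populated when the model came from a fit.
    """

    coefficients: tuple
    offset_peak: float = 0.0
    offset_low: float = 0.0
    offset_high: float = 0.0
    resolution_domain: tuple = (1.0, 10.0)
    r_squared: float | None = None

    def __post_init__(self) -> None:
        if len(self.coefficients) < 1:
            raise InputError("need at least one polynomial coefficient")
        if not (self.offset_low <= self.offset_high):
            raise InputError("offset_low must not exceed offset_high")

    def to_json(self, path=None) -> str:
        payload = {
            "coefficients": list(self.coefficients),
            "offset_peak": self.offset_peak,
            "offset_low": self.offset_low,
            "offset_high": self.offset_high,
            "resolution_domain": list(self.resolution_domain),
            "r_squared": self.r_squared,
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text + "\n")
        return text

    @classmethod
    def from_json(cls, source) -> "ResolutionStatModel":
        if isinstance(source, (str, bytes)) and str(source).lstrip().startswith("{"):
            payload = json.loads(source)
        else:
            with open(source) as fh:
                payload = json.load(fh)
        return cls(
            coefficients=tuple(payload["coefficients"]),
            offset_peak=payload["offset_peak"],
            offset_low=payload["offset_low"],
            offset_high=payload["offset_high"],
            resolution_domain=tuple(payload["resolution_domain"]),
            r_squared=payload.get("r_squared"),
        )


#: constants of the published archive-wide calibration
PUBLISHED_MODEL = ResolutionStatModel(
    coefficients=(-0.0016, 0.0434, -0.3956, 1.3366),
    offset_peak=0.024,
    offset_low=-0.126,
    offset_high=0.109,
    resolution_domain=(1.0, 10.0),
)


@dataclass
class CalibrationDataset:
    """Rows of (reported resolution d [Å], model-average Q)."""

    d: np.ndarray
    q: np.ndarray
    entry_ids: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=np.float64).ravel()
        self.q = np.asarray(self.q, dtype=np.float64).ravel()
        if self.d.shape != self.q.shape:
            raise InputError("resolution and Q arrays must have the same length")
        if np.any((self.d <= 0) | (self.d > 10)):
            raise InputError("resolutions must lie in (0, 10] Å")
        if np.any(np.abs(self.q) > 1):
            raise InputError("Q values must lie in [-1, 1]")

    def __len__(self) -> int:
        return len(self.d)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "CalibrationDataset":
        cols = {c.lower(): c for c in frame.columns}
        d_col = cols.get("resolution") or cols.get("d")
        q_col = cols.get("q") or cols.get("qscore") or cols.get("q_score")
        if d_col is None or q_col is None:
            raise InputError(
                "calibration table needs 'resolution' and 'q' columns, "
                f"got {list(frame.columns)}"
            )
        ids = None
        id_col = cols.get("entry_id") or cols.get("id")
        if id_col is not None:
            ids = frame[id_col].to_numpy()
        return cls(frame[d_col].to_numpy(), frame[q_col].to_numpy(), ids)

    @classmethod
    def read_csv(cls, path, sep=None) -> "CalibrationDataset":
        frame = pd.read_csv(path, sep=sep, engine="python")
        return cls.from_frame(frame)


def _polyval(coefficients, d):
    return np.polyval(np.asarray(coefficients, dtype=np.float64), d)


def q_mean(d, model: ResolutionStatModel = PUBLISHED_MODEL):
    """Expected model-average Q at reported resolution d (Å).

    Evaluating outside the model's calibrated resolution domain emits an
    :class:`ExtrapolationWarning` but still returns the polynomial value.
    """
    d_arr = np.asarray(d, dtype=np.float64)
    lo, hi = model.resolution_domain
    if np.any((d_arr < lo) | (d_arr > hi)):
        warnings.warn(
            f"resolution outside calibrated domain [{lo}, {hi}] Å; extrapolating",
            ExtrapolationWarning,
            stacklevel=2,
        )
    out = _polyval(model.coefficients, d_arr)
    return float(out) if np.isscalar(d) or d_arr.ndim == 0 else out


def q_bounds(d, model: ResolutionStatModel = PUBLISHED_MODEL):
    """(Q_peak, Q_low_95%, Q_high_95%) at resolution d."""
    mean = q_mean(d, model)
    return (
        mean + model.offset_peak,
        mean + model.offset_low,
        mean + model.offset_high,
    )


def fit_regression(data: CalibrationDataset, degree: int = 3) -> ResolutionStatModel:
    """Ordinary least-squares polynomial fit of Q on d.

    Returns a model with coefficients and R² populated and offsets zero;
    follow with :func:`calibrate_offsets` for the peak/95% curves.
    """
    if degree < 0:
        raise InputError("degree must be non-negative")
    if len(np.unique(data.d)) < degree + 1:
        raise ComputationError(
            f"need at least {degree + 1} distinct resolutions for degree {degree}"
        )
    with warnings.catch_warnings():
        warnings.simplefilter("error", np.exceptions.RankWarning)
        try:
            coeffs = np.polyfit(data.d, data.q, degree)
        except np.exceptions.RankWarning as exc:
            raise ComputationError(f"rank-deficient polynomial design: {exc}") from exc
    fitted = _polyval(coeffs, data.d)
    ss_res = float(np.sum((data.q - fitted) ** 2))
    ss_tot = float(np.sum((data.q - data.q.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    return ResolutionStatModel(
        coefficients=tuple(coeffs),
        resolution_domain=(float(data.d.min()), float(data.d.max())),
        r_squared=r2,
    )


def _mode_offset(residuals: np.ndarray, window: float, step: float = 0.001) -> float:
    """Offset maximizing the residual count within ±window/2, grid-searched
    at ``step`` over the residual range; ties break to the smallest |offset|."""
    r = np.sort(residuals)
    lo = np.floor(r[0] / step) * step
    hi = np.ceil(r[-1] / step) * step
    grid = np.arange(lo, hi + step / 2, step)
    counts = np.searchsorted(r, grid + window / 2, side="right") - np.searchsorted(
        r, grid - window / 2, side="left"
    )
    best = counts == counts.max()
    candidates = grid[best]
    return float(candidates[np.argmin(np.abs(candidates))])


def calibrate_offsets(
    data: CalibrationDataset,
    model: ResolutionStatModel,
    peak_window: float = 0.01,
    coverage: float = 0.95,
) -> ResolutionStatModel:
    """Calibrate the peak and 95%-coverage offsets from fit residuals.

    ``offset_peak`` is the vertical shift of the trend curve that captures
    the most residuals inside a window of width ``peak_window`` (the mode of
    the residual distribution); the low/high offsets are the equal-tail
    residual quantiles enclosing ``coverage`` of the data.
    """
    if len(data) < 40:
        raise ComputationError(
            f"offset calibration needs >= 40 points, got {len(data)}"
        )
    if not (0 < coverage < 1):
        raise InputError("coverage must be in (0, 1)")
    residuals = data.q - _polyval(model.coefficients, data.d)
    tail = (1.0 - coverage) / 2.0
    low, high = np.quantile(residuals, [tail, 1.0 - tail])
    peak = _mode_offset(residuals, peak_window)
    return replace(
        model,
        offset_peak=peak,
        offset_low=float(low),
        offset_high=float(high),
    )


def rolling_window_bounds(
    data: CalibrationDataset,
    window_width: float = 0.5,
    coverage: float = 0.95,
    peak_window: float = 0.01,
    query_d: np.ndarray | None = None,
    min_points: int = 20,
) -> pd.DataFrame:
    """Regression-free peak/95% curves from a rolling resolution window.

    At each query resolution the mode and equal-tail quantiles of the Q
    values within ±window_width/2 are tabulated.  Windows with fewer than
    ``min_points`` entries yield NaN rows (a flagged gap in the curve).
    """
    if len(data) < 40:
        raise ComputationError("rolling bounds need >= 40 points")
    if query_d is None:
        query_d = np.arange(data.d.min(), data.d.max() + 1e-9, 0.1)
    order = np.argsort(data.d)
    d_sorted = data.d[order]
    q_sorted = data.q[order]
    tail = (1.0 - coverage) / 2.0
    rows = []
    for d0 in np.asarray(query_d, dtype=np.float64):
        i = np.searchsorted(d_sorted, d0 - window_width / 2, side="left")
        j = np.searchsorted(d_sorted, d0 + window_width / 2, side="right")
        qs = q_sorted[i:j]
        if len(qs) < min_points:
            rows.append((d0, np.nan, np.nan, np.nan, len(qs)))
            continue
        low, high = np.quantile(qs, [tail, 1.0 - tail])
        peak = _mode_offset(qs, peak_window)
        rows.append((d0, peak, low, high, len(qs)))
    return pd.DataFrame(rows, columns=["d", "q_peak", "q_low", "q_high", "n"])


@dataclass(frozen=True)
class Classification:
    """Outcome of comparing an entry's Q to the archive curves at its d."""

    label: str  # typical | outlier_low | outlier_high
    q: float
    d: float
    q_mean: float
    q_peak: float
    q_low: float
    q_high: float


def classify_entry(
    d: float, q: float, model: ResolutionStatModel = PUBLISHED_MODEL
) -> Classification:
    """Classify (resolution, Q) against the 95% band; the band is closed, so
    a Q exactly on a bound is 'typical'."""
    mean = q_mean(d, model)
    peak, low, high = mean + model.offset_peak, mean + model.offset_low, mean + model.offset_high
    if q < low:
        label = "outlier_low"
    elif q > high:
        label = "outlier_high"
    else:
        label = "typical"
    return Classification(label, float(q), float(d), mean, peak, low, high)
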