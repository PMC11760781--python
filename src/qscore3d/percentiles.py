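"""Percentile ranks of a Q-score against an archive reference table.

Two complementary metrics rank a map/model pair against archived entries:

* **Q-relative-all** — the percentage of all reference entries whose
  model-average Q is strictly lower.  High values mean high overall map and
  model quality.
* **Q-relative-resolution** — the same strict-less-than percentage computed
  only over entries whose reported resolution lies within a window w of the
  query's resolution (membership |d_ref - d| <= w/2, w being the total
  window width).  Values near 50% mean "as commonly observed at this
  resolution"; below ~5% suggests a misfitted model or an optimistic map,
  above ~95% over-sharpening or an underestimated reported resolution.

The default window width of 0.5 Å keeps the rank nearly uncorrelated with
resolution inside the window while retaining enough entries for a stable
percentile; :func:`window_size_diagnostics` reproduces that trade-off on any
reference table.  When the scored entry itself appears in the reference
table (matched by id) it is excluded from both numerator and denominator so
an entry never ranks against itself.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ComputationError, InputError

__all__ = [
    "ReferenceTable",
    "RelativeScores",
    "q_relative_all",
    "q_relative_resolution",
    "window_size_diagnostics",
    "interpret_relative",
]


@dataclass
class ReferenceTable:
    """Archive reference rows (entry id, reported resolution Å, model Q)."""

    entry_ids: np.ndarray
    d: np.ndarray
    q: np.ndarray

    def __post_init__(self) -> None:
        self.entry_ids = np.asarray(self.entry_ids, dtype=object).ravel()
        self.d = np.asarray(self.d, dtype=np.float64).ravel()
        self.q = np.asarray(self.q, dtype=np.float64).ravel()
        if not (len(self.entry_ids) == len(self.d) == len(self.q)):
            raise InputError("reference table columns must have equal length")
        if len(self.entry_ids) == 0:
            raise InputError("reference table is empty")
        if len(set(self.entry_ids)) != len(self.entry_ids):
            raise InputError("reference table entry ids must be unique")
        if np.any(self.d <= 0):
            raise InputError("reference resolutions must be positive")

    def __len__(self) -> int:
        return len(self.d)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "ReferenceTable":
        cols = {c.lower(): c for c in frame.columns}
        try:
            id_col = cols.get("entry_id") or cols["id"]
            d_col = cols.get("resolution") or cols["d"]
            q_col = cols["q"]
        except KeyError as exc:
            raise InputError(
                f"reference table needs entry_id/resolution/q columns, got {list(frame.columns)}"
            ) from exc
        return cls(frame[id_col].to_numpy(), frame[d_col].to_numpy(), frame[q_col].to_numpy())

    @classmethod
    def read_csv(cls, path, sep=None) -> "ReferenceTable":
        return cls.from_frame(pd.read_csv(path, sep=sep, engine="python"))

    def _mask_excluding(self, exclude_id) -> np.ndarray:
        if exclude_id is None:
            return np.ones(len(self), dtype=bool)
        return self.entry_ids != exclude_id


@dataclass(frozen=True)
class RelativeScores:
    """Both percentile ranks plus the window occupancy used."""

    q_relative_all: float
    q_relative_resolution: float
    window_width: float
    n_window: int
    n_total: int


def q_relative_all(q: float, ref: ReferenceTable, exclude_id=None) -> float:
    """Percentile rank against the whole reference table (strict less-than)."""
    mask = ref._mask_excluding(exclude_id)
    n = int(mask.sum())
    if n == 0:
        raise ComputationError("reference table empty after self-exclusion")
    return 100.0 * float(np.count_nonzero(ref.q[mask] < q)) / n


def q_relative_resolution(
    q: float,
    d: float,
    ref: ReferenceTable,
    window_width: float = 0.5,
    exclude_id=None,
    half_width_mode: bool = False,
) -> RelativeScores:
    """Percentile rank against reference entries of similar resolution.

    Window membership is |d_ref - d| <= window_width/2 (total-width
    convention); ``half_width_mode`` treats ``window_width`` as the
    half-width instead.
    """
    if window_width <= 0:
        raise InputError("window_width must be positive")
    mask = ref._mask_excluding(exclude_id)
    half = window_width if half_width_mode else window_width / 2.0
    in_window = mask & (np.abs(ref.d - d) <= half)
    n_window = int(in_window.sum())
    if n_window == 0:
        raise ComputationError(
            f"no reference entries within ±{half:g} Å of {d:g} Å; "
            "try a larger window width"
        )
    rel_res = 100.0 * float(np.count_nonzero(ref.q[in_window] < q)) / n_window
    return RelativeScores(
        q_relative_all=q_relative_all(q, ref, exclude_id),
        q_relative_resolution=rel_res,
        window_width=window_width,
        n_window=n_window,
        n_total=int(mask.sum()),
    )


def window_size_diagnostics(
    ref: ReferenceTable,
    widths,
    split: float = 5.0,
    half_width_mode: bool = False,
) -> pd.DataFrame:
    """Window-occupancy and resolution-bias diagnostics per window width.

    For each width: min/mean/max number of reference entries per window,
    and the Pearson correlation between each entry's own
    Q-relative-resolution (self-excluded) and its resolution, computed
    separately for entries below and at/above the ``split`` resolution.
    A correlation near zero means the rank is unbiased by resolution
    within the window.
    """
    order = np.argsort(ref.d)
    d_sorted = ref.d[order]
    q_sorted = ref.q[order]
    n = len(ref)
    rows = []
    for w in widths:
        half = w if half_width_mode else w / 2.0
        i = np.searchsorted(d_sorted, d_sorted - half, side="left")
        j = np.searchsorted(d_sorted, d_sorted + half, side="right")
        counts = j - i
        rel = np.empty(n)
        for k in range(n):
            qs = q_sorted[i[k] : j[k]]
            denom = counts[k] - 1  # exclude the entry itself
            if denom <= 0:
                rel[k] = np.nan
                continue
            num = int(np.count_nonzero(qs < q_sorted[k]))
            rel[k] = 100.0 * num / denom
        corr = {}
        for name, sel in (
            ("corr_below_split", d_sorted < split),
            ("corr_at_or_above_split", d_sorted >= split),
        ):
            sel = sel & np.isfinite(rel)
            if sel.sum() >= 3 and np.std(rel[sel]) > 0 and np.std(d_sorted[sel]) > 0:
                corr[name] = float(np.corrcoef(d_sorted[sel], rel[sel])[0, 1])
            else:
                corr[name] = np.nan
        rows.append(
            {
                "width": float(w),
                "n_min": int(counts.min()),
                "n_mean": float(counts.mean()),
                "n_max": int(counts.max()),
                **corr,
            }
        )
    return pd.DataFrame(rows)


def interpret_relative(scores: RelativeScores) -> str:
    """Advisory code from Q-relative-resolution.

    Below 5% suggests a misfitted model or a lower-resolution map than
    reported ('suspect_low'); 95% or above suggests over-sharpening or an
    underestimated reported resolution ('suspect_high'); anything between is
    'as_expected'.
    """
    r = scores.q_relative_resolution
    if r < 5.0:
        return "suspect_low"
    if r >= 95.0:
        return "suspect_high"
    return "as_expected"
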