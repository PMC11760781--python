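"""Atomic B-factors from Q-scores.

A poorly resolved atom (low Q) corresponds to density that is spread out, the
same effect an atomic displacement parameter (B-factor) has in a calculated
map.  The conversion is linear in the Q deficit,

    B = (1 - Q_atom) · f        [Å²]

with a single scaling factor f shared by all atoms.  f is chosen by a scan:
for each candidate f a model-map is rendered from the coordinates with the
implied B-factors — each heavy atom contributing an isotropic Gaussian of
variance σ₀² + B/(8π²) and integral proportional to its electron count — and
compared to the experimental map by Pearson correlation about the mean
(CC-mean) over voxels near the model.  The f with the highest CC-mean wins
(ties to the smallest f).  The scan covers f = 0…300 in steps of 10 by
default, matching the range over which archived maps at ~1–4 Å resolution
are well described.
"""

from __future__ import annotations

from dataclasses import dataclass
import warnings

import gemmi
import numpy as np
import pandas as pd

from .errors import ComputationError, InputError
from .maps import DensityGrid
from .models import AtomicModel
from .qscore import QScoreTable

__all__ = [
    "BFactorScan",
    "q_to_bfactor",
    "render_model_map",
    "cc_mean",
    "model_mask",
    "scan_scaling",
]

_EIGHT_PI_SQ = 8.0 * np.pi**2


def q_to_bfactor(q, f: float):
    """B = (1 - q) · f.  Accepts scalars or arrays; f must be non-negative."""
    if f < 0:
        raise InputError("scaling factor f must be non-negative")
    q_arr = np.asarray(q, dtype=np.float64)
    out = (1.0 - q_arr) * f
    return float(out) if np.isscalar(q) or q_arr.ndim == 0 else out


def _electron_counts(atoms) -> np.ndarray:
    return np.array([gemmi.Element(a.element).atomic_number for a in atoms], dtype=np.float64)


def _atom_boxes(grid: DensityGrid, centers, radii):
    """Yield (voxel index slices, squared distances) for spheres around atoms."""
    shape = np.array(grid.shape)
    for center, radius in zip(centers, radii):
        idx = (center - grid.origin) / grid.voxel_size
        lo = np.maximum(np.ceil(idx - radius / grid.voxel_size).astype(int), 0)
        hi = np.minimum(np.floor(idx + radius / grid.voxel_size).astype(int), shape - 1)
        if np.any(lo > hi):
            continue
        axes = [
            grid.origin[k] + grid.voxel_size[k] * np.arange(lo[k], hi[k] + 1)
            for k in range(3)
        ]
        dx = axes[0] - center[0]
        dy = axes[1] - center[1]
        dz = axes[2] - center[2]
        d2 = (
            dx[:, None, None] ** 2
            + dy[None, :, None] ** 2
            + dz[None, None, :] ** 2
        )
        sl = tuple(slice(lo[k], hi[k] + 1) for k in range(3))
        yield sl, d2


def render_model_map(
    model: AtomicModel,
    template: DensityGrid,
    b_factors=None,
    sigma0: float = 0.6,
    cutoff_sigmas: float = 4.0,
) -> DensityGrid:
    """Render a model-map on the template's grid.

    Each heavy atom contributes a normalised isotropic Gaussian with variance
    σ₀² + B/(8π²) and integral equal to its electron count, so raising an
    atom's B spreads its density without changing its total mass.  σ₀ is the
    width of a zero-B atom and defaults to the Q-score reference width.
    ``b_factors`` aligns with ``model.scoreable_atoms()`` (or the per-atom
    ``b_factor`` slots when omitted).
    """
    atoms = model.scoreable_atoms()
    if not atoms:
        raise ComputationError("model has no heavy atoms to render")
    if b_factors is None:
        b = np.array([a.b_factor for a in atoms], dtype=np.float64)
    else:
        b = np.asarray(b_factors, dtype=np.float64).ravel()
        if b.shape != (len(atoms),):
            raise InputError(f"need {len(atoms)} B-factors, got shape {b.shape}")
    if np.any(~np.isfinite(b)) or np.any(b < 0):
        raise InputError("B-factors must be finite and non-negative")

    var = sigma0**2 + b / _EIGHT_PI_SQ
    sigma = np.sqrt(var)
    amp = _electron_counts(atoms) / (2.0 * np.pi * var) ** 1.5
    centers = np.array([a.xyz for a in atoms])
    values = np.zeros(template.shape)
    radii = cutoff_sigmas * sigma
    for (sl, d2), a, v in zip(_atom_boxes(template, centers, radii), amp, var):
        values[sl] += a * np.exp(-d2 / (2.0 * v))
    return DensityGrid(values, template.voxel_size.copy(), template.origin.copy())


def model_mask(template: DensityGrid, model: AtomicModel, radius: float = 3.0) -> np.ndarray:
    """Boolean grid of voxels within ``radius`` Å of any heavy atom."""
    atoms = model.scoreable_atoms()
    centers = np.array([a.xyz for a in atoms])
    mask = np.zeros(template.shape, dtype=bool)
    for sl, d2 in _atom_boxes(template, centers, np.full(len(atoms), radius)):
        mask[sl] |= d2 <= radius**2
    return mask


def cc_mean(map_a: DensityGrid, map_b: DensityGrid, mask: np.ndarray | None = None) -> float:
    """Pearson correlation about the mean between two maps on the same grid,
    optionally restricted to a boolean mask (e.g. near-model voxels)."""
    if map_a.shape != map_b.shape:
        raise InputError(f"grid shapes differ: {map_a.shape} vs {map_b.shape}")
    if not np.allclose(map_a.voxel_size, map_b.voxel_size) or not np.allclose(
        map_a.origin, map_b.origin
    ):
        raise InputError("maps must share voxel size and origin")
    a = map_a.values
    b = map_b.values
    if mask is not None:
        a = a[mask]
        b = b[mask]
    else:
        a = a.ravel()
        b = b.ravel()
    a = a - a.mean()
    b = b - b.mean()
    denom = np.sqrt((a**2).sum() * (b**2).sum())
    if denom == 0:
        raise ComputationError("zero variance in a map over the comparison region")
    return float(np.clip((a * b).sum() / denom, -1.0, 1.0))


@dataclass
class BFactorScan:
    """Result of the scaling-factor scan."""

    f_grid: np.ndarray
    cc_values: np.ndarray
    f_opt: float
    b_factors: np.ndarray  # aligned with model.scoreable_atoms()
    q_used: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"f": self.f_grid, "cc_mean": self.cc_values})


def scan_scaling(
    model: AtomicModel,
    table: QScoreTable,
    density: DensityGrid,
    f_range: tuple = (0.0, 300.0),
    f_step: float = 10.0,
    sigma0: float = 0.6,
    mask_radius: float = 3.0,
) -> BFactorScan:
    """Find the Q→B scaling factor maximizing map/model-map CC-mean.

    Atoms with undefined Q are filled with the median defined Q (so they get
    the median B); Q above 1 is clamped to 1 with a warning.  The returned
    B-factors come from the argmax f (ties resolved toward the smallest f,
    so a sharp map yields f_opt = 0, i.e. all-zero B).
    """
    atoms = model.scoreable_atoms()
    lut = table.lookup()
    q = np.array(
        [
            lut[(a.residue_key, a.atom_name, a.altloc)].q
            if (a.residue_key, a.atom_name, a.altloc) in lut
            else np.nan
            for a in atoms
        ]
    )
    defined = np.isfinite(q)
    if not defined.any():
        raise ComputationError("no defined Q-scores available for the scan")
    if np.any(q[defined] > 1.0):
        warnings.warn("Q-scores above 1 clamped to 1 for B-factor conversion", stacklevel=2)
        q = np.minimum(q, 1.0)
    q = np.where(defined, q, np.median(q[defined]))

    fs = np.arange(f_range[0], f_range[1] + f_step / 2, f_step)
    mask = model_mask(density, model, mask_radius)
    ccs = np.empty(len(fs))
    for i, f in enumerate(fs):
        rendered = render_model_map(model, density, q_to_bfactor(q, float(f)), sigma0=sigma0)
        ccs[i] = cc_mean(density, rendered, mask)
    best = int(np.argmax(ccs))  # first maximum -> smallest f on ties
    f_opt = float(fs[best])
    return BFactorScan(fs, ccs, f_opt, q_to_bfactor(q, f_opt), q)
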