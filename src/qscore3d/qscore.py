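"""Per-atom Q-scores.

The Q-score of an atom measures how well the density around it resembles the
density of a fully resolved atom.  Map values are sampled on concentric
spherical shells centred on the atom (keeping only sample points that are
closer to this atom than to any other heavy atom, so neighbouring density is
never attributed to the wrong atom) and correlated, about the mean, with a
reference Gaussian profile

    g(r) = exp(-r^2 / (2 sigma_ref^2)),   sigma_ref = 0.6 Å by default.

A Pearson correlation of 1 means the local density falls off exactly like the
reference peak (fully resolved atom); values near 0 mean no correspondence;
negative values indicate density that increases away from the atom.  Because
Pearson correlation is invariant to affine maps of either series, neither the
map's absolute scale nor the reference amplitude/offset matters.

Point placement on each shell uses seeded rejection sampling, so results are
deterministic for a given ``rng_seed`` and independent of scoring order.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from zlib import crc32

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .errors import ComputationError
from .models import Atom, AtomicModel

__all__ = [
    "QScoreParams",
    "AtomQ",
    "QScoreTable",
    "sample_shell_points",
    "reference_gaussian",
    "atom_q",
    "model_q",
]


@dataclass(frozen=True)
class QScoreParams:
    """Sampling parameters for the Q-score.

    Defaults reproduce the published method: reference width 0.6 Å, shells
    every 0.1 Å out to 2.0 Å, up to 8 points per shell.  ``min_points`` is
    the smallest sample count for which a correlation is considered defined;
    below it the atom is flagged rather than given a misleading number.
    """

    sigma_ref: float = 0.6
    max_radius: float = 2.0
    radial_step: float = 0.1
    points_per_shell: int = 8
    rng_seed: int = 0
    min_points: int = 10
    max_attempts: int = 96

    def __post_init__(self) -> None:
        if self.sigma_ref <= 0:
            raise ValueError("sigma_ref must be positive")
        if not (0 < self.radial_step <= self.max_radius):
            raise ValueError("need 0 < radial_step <= max_radius")
        if self.points_per_shell < 1:
            raise ValueError("points_per_shell must be >= 1")

    @property
    def radii(self) -> np.ndarray:
        """Shell radii 0, step, 2·step, …, max_radius."""
        n = int(round(self.max_radius / self.radial_step))
        return np.linspace(0.0, n * self.radial_step, n + 1)


@dataclass
class AtomQ:
    """Q-score of one atom; ``q`` is NaN when undefined (too few samples or
    zero map variance over the samples)."""

    atom: Atom
    q: float
    n_points: int

    @property
    def defined(self) -> bool:
        return bool(np.isfinite(self.q))


@dataclass
class QScoreTable:
    """Per-atom Q values for a model plus the model-level average."""

    entries: list
    params: QScoreParams

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self):
        return iter(self.entries)

    @property
    def q_values(self) -> np.ndarray:
        return np.array([e.q for e in self.entries])

    @property
    def model_average(self) -> float:
        """Unweighted mean Q over all atoms with a defined score."""
        q = self.q_values
        defined = np.isfinite(q)
        if not defined.any():
            raise ComputationError("no atom has a defined Q-score")
        return float(q[defined].mean())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "chain": [e.atom.chain for e in self.entries],
                "resnum": [e.atom.res_seq for e in self.entries],
                "resname": [e.atom.res_name for e in self.entries],
                "atom": [e.atom.atom_name for e in self.entries],
                "element": [e.atom.element for e in self.entries],
                "q": [e.q for e in self.entries],
                "n_points": [e.n_points for e in self.entries],
            }
        )

    def lookup(self) -> dict:
        """(residue_key, atom_name, altloc) -> AtomQ for aggregation."""
        return {
            (e.atom.residue_key, e.atom.atom_name, e.atom.altloc): e
            for e in self.entries
        }


def reference_gaussian(radii, sigma_ref: float) -> np.ndarray:
    """Reference profile g(r) = exp(-r² / (2 σ_ref²)).

    Amplitude and offset are irrelevant downstream: the Q correlation is
    invariant to affine transforms of either series.
    """
    r = np.asarray(radii, dtype=np.float64)
    return np.exp(-(r**2) / (2.0 * sigma_ref**2))


def _shell_rng(params: QScoreParams, atom: Atom, radius: float) -> np.random.Generator:
    # stable per-(seed, atom, shell) stream: scoring order never matters
    key = f"{atom.chain}|{atom.res_seq}|{atom.icode}|{atom.res_name}|{atom.atom_name}|{atom.altloc}"
    return np.random.default_rng(
        [params.rng_seed & 0x7FFFFFFF, crc32(key.encode()), int(round(radius * 1000))]
    )


def _heavy_atom_tree(model: AtomicModel):
    heavy = [a for a in model.atoms if not a.is_hydrogen]
    coords = np.array([a.xyz for a in heavy]) if heavy else np.zeros((0, 3))
    return heavy, cKDTree(coords) if len(heavy) else None


def sample_shell_points(
    atom: Atom,
    radius: float,
    model: AtomicModel,
    params: QScoreParams,
    _tree=None,
    _atom_index=None,
) -> np.ndarray:
    """Sample up to ``points_per_shell`` points on the sphere of ``radius``
    around ``atom``, each strictly closer to this atom than to any other
    heavy atom.  Radius 0 returns the atom position itself.  May return
    fewer points (or none) in crowded regions.
    """
    if radius < 0:
        raise ValueError("radius must be >= 0")
    if radius == 0:
        return atom.xyz[np.newaxis, :].copy()

    if _tree is None:
        heavy, tree = _heavy_atom_tree(model)
        atom_index = next(
            (i for i, a in enumerate(heavy) if a is atom), None
        )
        if atom_index is None:
            # atom not in the model list (e.g. standalone use): match by position
            d, atom_index = tree.query(atom.xyz)
            if d > 1e-9:
                raise ValueError("atom is not a heavy atom of the model")
    else:
        tree, atom_index = _tree, _atom_index

    rng = _shell_rng(params, atom, radius)
    accepted = []
    n_drawn = 0
    while n_drawn < params.max_attempts and len(accepted) < params.points_per_shell:
        batch = min(params.max_attempts - n_drawn, 32)
        n_drawn += batch
        vec = rng.normal(size=(batch, 3))
        norms = np.linalg.norm(vec, axis=1)
        ok = norms > 1e-12
        vec = vec[ok] / norms[ok, np.newaxis]
        pts = atom.xyz + radius * vec
        _, nearest = tree.query(pts)
        for p, idx in zip(pts, nearest):
            if idx == atom_index:
                accepted.append(p)
                if len(accepted) == params.points_per_shell:
                    break
    if not accepted:
        return np.zeros((0, 3))
    return np.array(accepted)


def _atom_samples(atom, grid, params, tree, atom_index):
    """(radii, map values) for all accepted in-grid samples of one atom."""
    rad_list = []
    pt_list = []
    for r in params.radii:
        pts = sample_shell_points(atom, float(r), None, params, _tree=tree, _atom_index=atom_index)
        if len(pts):
            pt_list.append(pts)
            rad_list.append(np.full(len(pts), r))
    if not pt_list:
        return np.zeros(0), np.zeros(0)
    pts = np.vstack(pt_list)
    radii = np.concatenate(rad_list)
    vals = np.asarray(grid.interpolate(pts), dtype=np.float64)
    in_grid = np.isfinite(vals)
    return radii[in_grid], vals[in_grid]


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    xc = x - x.mean()
    yc = y - y.mean()
    # a series that is constant up to floating-point jitter carries no
    # signal: require spread above 1e-10 relative to the series' scale
    if np.ptp(x) <= 1e-10 * max(1.0, float(np.abs(x).max())):
        return np.nan
    denom = np.sqrt((xc**2).sum() * (yc**2).sum())
    if denom == 0:
        return np.nan
    return float(np.clip((xc * yc).sum() / denom, -1.0, 1.0))


def atom_q(
    atom: Atom,
    grid,
    model: AtomicModel,
    params: QScoreParams | None = None,
    _tree=None,
    _atom_index=None,
) -> AtomQ:
    """Q-score of one heavy atom against a density grid (or any object with
    a ``DensityGrid``-style ``interpolate`` method)."""
    params = params or QScoreParams()
    if _tree is None:
        heavy, tree = _heavy_atom_tree(model)
        try:
            atom_index = next(i for i, a in enumerate(heavy) if a is atom)
        except StopIteration:
            d, atom_index = tree.query(atom.xyz)
            if d > 1e-9:
                raise ValueError("atom is not a heavy atom of the model") from None
    else:
        tree, atom_index = _tree, _atom_index
    radii, vals = _atom_samples(atom, grid, params, tree, atom_index)
    n = len(vals)
    if n < params.min_points:
        return AtomQ(atom, np.nan, n)
    ref = reference_gaussian(radii, params.sigma_ref)
    return AtomQ(atom, _pearson(vals, ref), n)


def model_q(model: AtomicModel, grid, params: QScoreParams | None = None) -> QScoreTable:
    """Q-scores for every scoreable atom of a model.

    Scoreable atoms are non-hydrogen, occupancy > 0 and primary-altloc; the
    table's ``model_average`` is the unweighted mean over defined scores.
    """
    params = params or QScoreParams()
    atoms = model.scoreable_atoms()
    if not atoms:
        raise ComputationError("model has no scoreable (heavy, occupied) atoms")
    heavy, tree = _heavy_atom_tree(model)
    index_of = {id(a): i for i, a in enumerate(heavy)}
    entries = [
        atom_q(a, grid, model, params, _tree=tree, _atom_index=index_of[id(a)])
        for a in atoms
    ]
    table = QScoreTable(entries, params)
    table.model_average  # raises if not a single atom is scoreable
    return table
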