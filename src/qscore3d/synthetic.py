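"""Synthetic fixtures: toy models, rendered maps, calibration tables.

Everything the pipeline consumes can be generated here deterministically,
so the full stack is exercisable without downloading archive entries.  Toy
models carry correct residue/atom naming for every molecule class (a short
peptide including glycine, a purine/pyrimidine dinucleotide, a small ligand
and a water) but deliberately simplified geometry: rings are regular
polygons and moieties are spaced to avoid clashes.  That is sufficient for
everything the scoring pipeline looks at — atom names, elements, classes
and non-overlapping positions — while keeping coordinates hard-coded
constants rather than downloads.

Calibration tables emulate the statistical structure of the archive survey:
Q follows a cubic trend in resolution plus skew-normal residuals (skewed
toward low Q, as poorly fitted models produce a heavy low tail).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from scipy.spatial.distance import cdist

from .bfactors import render_model_map
from .maps import DensityGrid, write_map
from .models import Atom, AtomicModel
from .resstats import CalibrationDataset, PUBLISHED_MODEL

__all__ = [
    "FixtureSpec",
    "GaussianField",
    "make_toy_model",
    "make_isolated_model",
    "make_map",
    "make_calibration_table",
]


@dataclass(frozen=True)
class FixtureSpec:
    """Knobs for fixture generation; defaults give clean, noise-free inputs.

    Map rendering: ``b_factor`` (Å², scalar applied to all atoms unless a
    per-atom array is passed to :func:`make_map`), additive Gaussian voxel
    noise of sd ``noise_sd`` (map units), ``voxel_size`` in Å and ``pad`` Å
    of margin around the model.  Calibration tables: ``n_rows`` entries with
    resolutions uniform over ``resolution_range``, Q = cubic(``coefficients``)
    + skew-normal residual (shape ``skew_a`` < 0 skews toward low Q,
    ``skew_scale`` sets the spread; the residual is centred to mean zero).
    """

    spacing: float = 8.0
    voxel_size: float = 0.5
    pad: float = 4.0
    b_factor: float = 0.0
    noise_sd: float = 0.0
    rng_seed: int = 0
    n_rows: int = 10_000
    resolution_range: tuple = (1.0, 10.0)
    coefficients: tuple = PUBLISHED_MODEL.coefficients
    skew_a: float = -4.0
    skew_scale: float = 0.065


def _ring(center, radius, n, start_angle=0.0):
    """n points on a circle in the xy-plane (z constant)."""
    ang = start_angle + 2 * np.pi * np.arange(n) / n
    return np.stack(
        [center[0] + radius * np.sin(ang), center[1] + radius * np.cos(ang),
         np.full(n, center[2])],
        axis=1,
    )


def _peptide_atoms(origin) -> list:
    """ALA-GLY-SER tripeptide along +x with idealised bond lengths."""
    backbone = {
        "N": (-1.2, 0.6, 0.0),
        "CA": (0.0, 0.0, 0.0),
        "C": (1.3, 0.6, 0.4),
        "O": (1.4, 1.8, 0.5),
    }
    sidechains = {
        "ALA": {"CB": (0.0, -0.8, 1.2)},
        "GLY": {},
        "SER": {"CB": (0.0, -0.8, 1.2), "OG": (0.0, -1.5, 2.4)},
    }
    atoms = []
    for i, res in enumerate(("ALA", "GLY", "SER")):
        shift = np.asarray(origin) + np.array([3.8 * i, 0.0, 0.0])
        for name, xyz in {**backbone, **sidechains[res]}.items():
            atoms.append(
                Atom("A", res, i + 1, name, name[0], np.asarray(xyz) + shift,
                     mol_class="protein")
            )
    return atoms


_SUGAR_R = 1.18          # pentagon radius giving ~1.39 Å ring bonds
_BASE_BOND = 1.40


def _nucleotide_atoms(chain, res_name, res_seq, base_names, origin, with_phosphate=True):
    """One nucleotide: phosphate cluster (-x), sugar pentagon, base ring (+y)."""
    origin = np.asarray(origin, dtype=float)
    atoms = []
    sugar_names = ["C1'", "C2'", "C3'", "C4'", "O4'"]
    # C1' is the vertex facing the base (+y)
    sugar = _ring(origin, _SUGAR_R, 5, start_angle=0.0)
    for name, xyz in zip(sugar_names, sugar):
        atoms.append(Atom(chain, res_name, res_seq, name, name[0], xyz,
                          mol_class="nucleotide"))
    outward = {n: (xyz - origin) / np.linalg.norm(xyz - origin)
               for n, xyz in zip(sugar_names, sugar)}
    extras = {"C5'": ("C4'", 1.5), "O3'": ("C3'", 1.4), "O2'": ("C2'", 1.4)}
    for name, (anchor, bond) in extras.items():
        base_xyz = sugar[sugar_names.index(anchor)]
        atoms.append(Atom(chain, res_name, res_seq, name, name[0],
                          base_xyz + outward[anchor] * bond, mol_class="nucleotide"))
    if with_phosphate:
        p0 = origin + np.array([-4.3, 0.0, 0.0])
        for name, off in (
            ("P", (0.0, 0.0, 0.0)),
            ("OP1", (0.0, 1.5, 0.0)),
            ("OP2", (0.0, -1.06, 1.06)),
            ("O5'", (1.6, 0.0, 0.0)),
        ):
            atoms.append(Atom(chain, res_name, res_seq, name, name[0],
                              p0 + np.asarray(off), mol_class="nucleotide"))
    n_base = len(base_names)
    base_r = _BASE_BOND / (2.0 * np.sin(np.pi / n_base))
    base_center = origin + np.array([0.0, 1.45 + _SUGAR_R + base_r, 0.0])
    # first base atom (the glycosidic nitrogen) faces the sugar
    base = _ring(base_center, base_r, n_base, start_angle=np.pi)
    for name, xyz in zip(base_names, base):
        atoms.append(Atom(chain, res_name, res_seq, name, name[0], xyz,
                          mol_class="nucleotide"))
    return atoms


_GUANINE = ["N9", "C8", "N7", "C5", "C6", "O6", "N1", "C2", "N2", "N3", "C4"]
_CYTOSINE = ["N1", "C2", "O2", "N3", "C4", "N4", "C5", "C6"]


def _ligand_atoms(chain, origin) -> list:
    """8-atom pyranose-like ligand 'LIG' (untabulated name => ligand class)."""
    origin = np.asarray(origin, dtype=float)
    names = ["C1", "C2", "C3", "O5", "C4", "C5"]
    ring = _ring(origin, _BASE_BOND / (2.0 * np.sin(np.pi / 6)), 6)
    atoms = [
        Atom(chain, "LIG", 1, n, n[0], xyz, mol_class="ligand")
        for n, xyz in zip(names, ring)
    ]
    for name, anchor in (("O2", 1), ("O3", 2)):
        direction = (ring[anchor] - origin) / np.linalg.norm(ring[anchor] - origin)
        atoms.append(Atom(chain, "LIG", 1, name, "O", ring[anchor] + 1.4 * direction,
                          mol_class="ligand"))
    return atoms


def make_toy_model(spec: FixtureSpec | None = None) -> AtomicModel:
    """Deterministic toy model with all molecule classes.

    Chain A: ALA-GLY-SER peptide; chain B: G+C RNA dinucleotide (the 5'
    nucleotide carries the phosphate, the second does not, exercising the
    terminal-nucleotide path); chain C: small ligand; chain W: one water.
    Molecules are stacked ``spec.spacing`` Å apart along z.
    """
    spec = spec or FixtureSpec()
    s = spec.spacing
    atoms = list(_peptide_atoms((0.0, 0.0, 0.0)))
    atoms += _nucleotide_atoms("B", "G", 1, _GUANINE, (1.0, -1.0, s),
                               with_phosphate=True)
    atoms += _nucleotide_atoms("B", "C", 2, _CYTOSINE, (10.0, -1.0, s),
                               with_phosphate=False)
    atoms += _ligand_atoms("C", (2.0, 1.0, 2 * s))
    atoms.append(Atom("W", "HOH", 1, "O", "O", (10.5, 1.0, 2 * s),
                      mol_class="water", hetero=True))
    return AtomicModel(atoms)


def make_isolated_model(n_atoms: int = 5, spacing: float = 12.0,
                        element: str = "C") -> AtomicModel:
    """Widely separated single atoms: each is its own 'ligand' residue.

    With spacing well above twice the sampling radius, every shell point is
    attributed to its own atom and the local density of each atom is an
    undisturbed single peak.
    """
    atoms = [
        Atom("X", "LIG", i + 1, element, element,
             np.array([spacing * i, 0.0, 0.0]), mol_class="ligand", hetero=True)
        for i in range(n_atoms)
    ]
    return AtomicModel(atoms)


class GaussianField:
    """Analytic sum-of-Gaussians density with the DensityGrid sampling
    interface.

    Evaluates the exact field at arbitrary points, with no voxelization or
    interpolation error — the right object for identities that hold for the
    correlation kernel itself (e.g. Q = 1 on a map that *is* the reference
    Gaussian around each atom).
    """

    def __init__(self, model: AtomicModel, sigma: float = 0.6,
                 amplitudes=None, offset: float = 0.0, scale: float = 1.0):
        self.centers = np.array([a.xyz for a in model.scoreable_atoms()])
        self.sigma = float(sigma)
        n = len(self.centers)
        self.amplitudes = (
            np.ones(n) if amplitudes is None else np.asarray(amplitudes, float)
        )
        self.offset = float(offset)
        self.scale = float(scale)

    def interpolate(self, points) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(points, dtype=np.float64))
        d2 = cdist(pts, self.centers, "sqeuclidean")
        vals = (np.exp(-d2 / (2.0 * self.sigma**2)) * self.amplitudes).sum(axis=1)
        return self.scale * vals + self.offset


def make_map(
    model: AtomicModel,
    spec: FixtureSpec | None = None,
    b_factors=None,
    path=None,
) -> DensityGrid:
    """Render a density map for a model with controlled blur and noise.

    The grid covers the model's bounding box plus ``spec.pad`` Å; per-atom
    B-factors default to ``spec.b_factor`` everywhere; Gaussian voxel noise
    of sd ``spec.noise_sd`` is added with the spec's seed.  Optionally
    written to ``path`` as MRC.
    """
    spec = spec or FixtureSpec()
    atoms = model.scoreable_atoms()
    coords = np.array([a.xyz for a in atoms])
    lo = coords.min(axis=0) - spec.pad
    hi = coords.max(axis=0) + spec.pad
    shape = np.ceil((hi - lo) / spec.voxel_size).astype(int) + 1
    template = DensityGrid(np.zeros(shape), np.full(3, spec.voxel_size), lo)
    if b_factors is None:
        b_factors = np.full(len(atoms), float(spec.b_factor))
    grid = render_model_map(model, template, b_factors)
    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.rng_seed)
        grid.values = grid.values + rng.normal(0.0, spec.noise_sd, size=grid.shape)
    if path is not None:
        write_map(grid, path)
    return grid


def make_calibration_table(
    spec: FixtureSpec | None = None, seed: int | None = None
) -> CalibrationDataset:
    """Synthetic (resolution, Q) archive table.

    Resolutions are uniform over the spec's range; Q is the cubic trend plus
    a mean-centred skew-normal residual, clamped to [-1, 1].  Negative
    ``skew_a`` reproduces the archive's heavy low-Q tail, which is what makes
    the calibrated |offset_low| exceed offset_high.
    """
    spec = spec or FixtureSpec()
    if spec.n_rows < 100:
        raise ValueError("calibration tables need at least 100 rows")
    rng = np.random.default_rng(spec.rng_seed if seed is None else seed)
    lo, hi = spec.resolution_range
    d = rng.uniform(lo, hi, size=spec.n_rows)
    resid = stats.skewnorm.rvs(spec.skew_a, loc=0.0, scale=spec.skew_scale,
                               size=spec.n_rows, random_state=rng)
    resid -= stats.skewnorm.mean(spec.skew_a, loc=0.0, scale=spec.skew_scale)
    q = np.clip(np.polyval(spec.coefficients, d) + resid, -1.0, 1.0)
    ids = np.array([f"SYN-{i:06d}" for i in range(spec.n_rows)], dtype=object)
    return CalibrationDataset(d, q, ids)
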