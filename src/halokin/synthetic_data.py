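"""Seeded generators for every input the analysis modules consume.

The wet-lab and simulation inputs of a halophilic-enzyme characterization
(saturation curves, structures, MD trajectories, coupled-assay traces) are
emulated here with explicit seeds, so the whole pipeline runs without any
external file:

* Michaelis-Menten saturation data with multiplicative Gaussian noise
  (CV-style assay error);
* toy atom clusters with known burial (isolated atom, pair, icosahedrally
  caged atom, random cluster);
* trajectories with per-atom isotropic Gaussian fluctuation, optionally
  wrapped in per-frame rigid-body motion;
* coupled-assay progress curves with additive Gaussian noise on v2.

All generators are pure functions of (parameters, seed): one 64-bit seed
per call, no hidden global state, identical output on rerun.
"""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np
from scipy.spatial.transform import Rotation

from .assay_design import AssaySpec, ProgressCurve, simulate_coupled_assay
from .errors import InvalidParameterError
from .kinetics import KineticDataset, michaelis_menten
from .structure_metrics import (
    ATOMIC_MASSES,
    DEFAULT_ATOMIC_MASS,
    DEFAULT_VDW_RADIUS,
    VDW_RADII,
    Structure,
)
from .traj_analysis import Trajectory

__all__ = [
    "gen_mm_dataset",
    "gen_toy_structure",
    "gen_random_cluster",
    "gen_trajectory",
    "gen_progress_curve",
]


def _structure_from_coords(coords: np.ndarray, element: str = "C") -> Structure:
    n = coords.shape[0]
    r = VDW_RADII.get(element, DEFAULT_VDW_RADIUS)
    m = ATOMIC_MASSES.get(element, DEFAULT_ATOMIC_MASS)
    return Structure(
        serial=np.arange(1, n + 1),
        atom_name=np.array([element] * n, dtype=object),
        element=np.array([element] * n, dtype=object),
        res_name=np.array(["UNK"] * n, dtype=object),
        chain_id=np.array(["A"] * n, dtype=object),
        res_seq=np.arange(1, n + 1),
        coords=np.asarray(coords, dtype=float),
        vdw_radius=np.full(n, r),
        mass=np.full(n, m),
    )


def gen_mm_dataset(
    Vmax: float,
    KM: float,
    s_values: Sequence[float],
    cv: float = 0.0,
    replicates: int = 1,
    seed: int = 0,
    condition_label: str = "synthetic",
    substrate_name: str = "S",
) -> KineticDataset:
    """Saturation data v = Vmax*s/(KM+s) * (1 + eps), eps ~ N(0, cv).

    Multiplicative noise mimics constant-CV assay error; cv = 0 returns the
    exact model values.
    """
    if Vmax <= 0 or KM <= 0:
        raise InvalidParameterError("Vmax and KM must be > 0")
    if cv < 0:
        raise InvalidParameterError("cv must be >= 0")
    if replicates < 1 or len(s_values) == 0:
        raise InvalidParameterError("need >= 1 replicate and non-empty s_values")
    rng = np.random.default_rng(seed)
    pts = []
    for rep in range(replicates):
        for s in s_values:
            v = float(michaelis_menten(s, Vmax, KM))
            if cv > 0:
                v *= 1.0 + rng.normal(0.0, cv)
            pts.append((float(s), v, rep))
    return KineticDataset(condition_label, substrate_name, pts)


def gen_toy_structure(kind: str, d: float = 3.0, element: str = "C") -> Structure:
    """Toy clusters with analytically known burial.

    ``"isolated"``: one atom at the origin.  ``"pair"``: two atoms ``d``
    apart on x.  ``"caged"``: a central atom surrounded by the 12 vertices
    of an icosahedron at radius ``d``; at small ``d`` the centre is fully
    buried.
    """
    phi = (1.0 + np.sqrt(5.0)) / 2.0
    if kind == "isolated":
        coords = np.zeros((1, 3))
    elif kind == "pair":
        coords = np.array([[0.0, 0.0, 0.0], [d, 0.0, 0.0]])
    elif kind == "caged":
        base = np.array(
            [
                [0, 1, phi], [0, -1, phi], [0, 1, -phi], [0, -1, -phi],
                [1, phi, 0], [-1, phi, 0], [1, -phi, 0], [-1, -phi, 0],
                [phi, 0, 1], [-phi, 0, 1], [phi, 0, -1], [-phi, 0, -1],
            ],
            dtype=float,
        )
        base /= np.linalg.norm(base[0])
        coords = np.vstack([[0.0, 0.0, 0.0], d * base])
    else:
        raise InvalidParameterError(
            f"unknown toy kind {kind!r}; use isolated|pair|caged"
        )
    return _structure_from_coords(coords, element)


def gen_random_cluster(
    n_atoms: int, extent: float = 15.0, seed: int = 0, element: str = "C"
) -> Structure:
    """Uniform random atom cloud in a cube of side ``extent`` (generic,
    rank-3 geometry; convenient for invariance and convergence fixtures)."""
    if n_atoms < 1:
        raise InvalidParameterError("n_atoms must be >= 1")
    rng = np.random.default_rng(seed)
    coords = rng.uniform(-extent / 2.0, extent / 2.0, size=(n_atoms, 3))
    return _structure_from_coords(coords, element)


def gen_trajectory(
    reference: Structure,
    sigma_per_atom: Sequence[float] | float,
    n_frames: int,
    rigid_motion: bool = False,
    seed: int = 0,
    translation_scale: float = 3.0,
) -> Trajectory:
    """Frames = reference + per-coordinate N(0, sigma_i) noise.

    With ``rigid_motion`` every frame is additionally rotated by a uniform
    random rotation and translated by N(0, translation_scale) per axis
    (applied after the noise), emulating unremoved global tumbling.
    """
    if n_frames < 2:
        raise InvalidParameterError("n_frames must be >= 2")
    n = reference.n_atoms
    sig = np.broadcast_to(np.asarray(sigma_per_atom, dtype=float), (n,)).copy()
    if np.any(sig < 0):
        raise InvalidParameterError("sigma values must be >= 0")
    rng = np.random.default_rng(seed)
    frames = reference.coords[None, :, :] + rng.normal(
        0.0, 1.0, size=(n_frames, n, 3)
    ) * sig[None, :, None]
    if rigid_motion:
        quats = rng.normal(size=(n_frames, 4))
        quats /= np.linalg.norm(quats, axis=1, keepdims=True)
        trans = rng.normal(0.0, translation_scale, size=(n_frames, 3))
        for i in range(n_frames):
            R = Rotation.from_quat(quats[i]).as_matrix()
            frames[i] = frames[i] @ R.T + trans[i]
    return Trajectory(topology=reference, frames=frames)


def gen_progress_curve(
    spec: AssaySpec,
    noise_sd: float,
    seed: int = 0,
    t_end: float = 20.0,
    dt: Optional[float] = None,
) -> ProgressCurve:
    """Coupled-assay curve with additive Gaussian noise on v2 (seeded);
    noise_sd = 0 reproduces :func:`simulate_coupled_assay` exactly."""
    if noise_sd < 0:
        raise InvalidParameterError("noise_sd must be >= 0")
    curve = simulate_coupled_assay(spec, t_end, dt=dt)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        curve.v2 = curve.v2 + rng.normal(0.0, noise_sd, size=curve.v2.shape)
    return curve
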