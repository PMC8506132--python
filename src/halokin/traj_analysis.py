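"""Trajectory observables: superposition, RMSD, RMSF, Rg, nonbonded energies.

Implements the standard molecular-dynamics analysis toolbox used to compare
protein dynamics at low and high salt: optimal rigid-body superposition
(Kabsch), per-frame RMSD against a reference, per-residue RMSF about the
mean structure, mass-weighted radius of gyration per selection, and direct
pairwise Coulomb + Lennard-Jones interaction energies between two atom
selections (e.g. a substrate and a binding loop), plus replicate averaging
with windowed statistics.

Input trajectories are multi-model PDB or per-frame XYZ tables and are
assumed to be already imaged (no periodic-boundary treatment is applied).
Energies are direct sums in kcal/mol with Lorentz-Berthelot combination;
there is no cutoff by default and no Ewald/PME — this is selection-pair
analysis, not a total-system energy.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .errors import (
    ClashError,
    DegenerateGeometryError,
    InvalidParameterError,
    MissingParameterError,
    PDBFormatError,
    SelectionError,
)
from .structure_metrics import Structure, parse_pdb

__all__ = [
    "COULOMB_CONSTANT",
    "Trajectory",
    "Selection",
    "NonbondedParams",
    "SeriesStats",
    "SuperposeResult",
    "read_trajectory_pdb",
    "read_trajectory_xyz",
    "write_trajectory_pdb",
    "kabsch_superpose",
    "rmsd_series",
    "rmsf",
    "radius_of_gyration",
    "rg_series",
    "lj_from_ab",
    "read_nonbonded_tsv",
    "interaction_energy",
    "energy_series",
    "replicate_stats",
]

#: Coulomb constant in kcal A mol^-1 e^-2.
COULOMB_CONSTANT = 332.0636

#: Minimum pair distance (A) below which an energy evaluation is a clash.
CLASH_DISTANCE_A = 0.1


@dataclass
class Trajectory:
    """A topology plus an ordered stack of coordinate frames (Angstrom)."""

    topology: Structure
    frames: np.ndarray
    frame_times_ns: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 3 or self.frames.shape[2] != 3:
            raise InvalidParameterError("frames must be (n_frames, n_atoms, 3)")
        if self.frames.shape[1] != self.topology.n_atoms:
            raise InvalidParameterError(
                f"frames carry {self.frames.shape[1]} atoms but topology has "
                f"{self.topology.n_atoms}"
            )
        if not np.all(np.isfinite(self.frames)):
            raise InvalidParameterError("frame coordinates must be finite")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.frames.shape[1]


@dataclass(frozen=True)
class Selection:
    """Atom predicate: chain ids, inclusive 1-based residue ranges,
    atom-name set and/or residue-name set; all given criteria must hold."""

    chains: Optional[frozenset] = None
    residue_ranges: Optional[tuple[tuple[int, int], ...]] = None
    atom_names: Optional[frozenset] = None
    res_names: Optional[frozenset] = None

    def resolve(self, structure: Structure) -> np.ndarray:
        """Indices of matching atoms; raises SelectionError when empty."""
        mask = np.ones(structure.n_atoms, dtype=bool)
        if self.chains is not None:
            mask &= np.isin(structure.chain_id.astype(str), list(self.chains))
        if self.residue_ranges is not None:
            rmask = np.zeros(structure.n_atoms, dtype=bool)
            for lo, hi in self.residue_ranges:
                rmask |= (structure.res_seq >= lo) & (structure.res_seq <= hi)
            mask &= rmask
        if self.atom_names is not None:
            mask &= np.isin(structure.atom_name.astype(str), list(self.atom_names))
        if self.res_names is not None:
            mask &= np.isin(structure.res_name.astype(str), list(self.res_names))
        idx = np.nonzero(mask)[0]
        if idx.size == 0:
            raise SelectionError(f"selection {self} matches no atoms")
        return idx

    @classmethod
    def parse(cls, expr: str) -> "Selection":
        """Parse e.g. ``"chain A and resid 178-190 and name CA"``.

        Clauses joined by 'and': chain <ids>, resid <n|n-m>[,...],
        name <names>, resname <names>.  ``"all"`` selects everything.
        """
        expr = expr.strip()
        if expr.lower() in ("", "all"):
            return cls()
        chains = atom_names = res_names = None
        ranges = None
        for clause in expr.split(" and "):
            parts = clause.split()
            if len(parts) < 2:
                raise SelectionError(f"cannot parse selection clause {clause!r}")
            kw, args = parts[0].lower(), " ".join(parts[1:]).replace(",", " ").split()
            if kw == "chain":
                chains = frozenset(args)
            elif kw == "resid":
                rr = []
                for a in args:
                    if "-" in a:
                        lo, hi = a.split("-", 1)
                        rr.append((int(lo), int(hi)))
                    else:
                        rr.append((int(a), int(a)))
                ranges = tuple(rr)
            elif kw == "name":
                atom_names = frozenset(args)
            elif kw == "resname":
                res_names = frozenset(args)
            else:
                raise SelectionError(f"unknown selection keyword {kw!r}")
        return cls(
            chains=chains, residue_ranges=ranges,
            atom_names=atom_names, res_names=res_names,
        )


# -- trajectory readers -----------------------------------------------------

def read_trajectory_pdb(text: str) -> Trajectory:
    """Read a multi-model PDB (MODEL/ENDMDL blocks) as a trajectory.

    The topology comes from the first model; every model must carry the
    same number of atoms.  A file without MODEL records is a one-frame
    trajectory.
    """
    blocks: list[str] = []
    current: list[str] = []
    in_model = False
    for line in text.splitlines():
        if line.startswith("MODEL"):
            in_model = True
            current = []
        elif line.startswith("ENDMDL"):
            blocks.append("\n".join(current))
            in_model = False
        elif in_model:
            current.append(line)
    if not blocks:
        blocks = [text]
    structures = [parse_pdb(b) for b in blocks]
    n0 = structures[0].n_atoms
    for i, s in enumerate(structures[1:], start=2):
        if s.n_atoms != n0:
            raise PDBFormatError(
                f"model {i} has {s.n_atoms} atoms, expected {n0}"
            )
    frames = np.stack([s.coords for s in structures])
    return Trajectory(topology=structures[0], frames=frames)


def read_trajectory_xyz(text: str) -> Trajectory:
    """Read concatenated XYZ frames (``n\\ncomment\\nelement x y z``...).

    A minimal carbon-like topology is synthesized from the element symbols
    (sequential residue numbers, chain 'A').
    """
    from .structure_metrics import (
        ATOMIC_MASSES, DEFAULT_ATOMIC_MASS, DEFAULT_VDW_RADIUS, VDW_RADII,
    )

    lines = text.splitlines()
    pos = 0
    frames = []
    elements: list[str] = []
    while pos < len(lines):
        if not lines[pos].strip():
            pos += 1
            continue
        try:
            n = int(lines[pos].strip())
        except ValueError:
            raise PDBFormatError(f"line {pos + 1}: expected an atom count")
        body = lines[pos + 2 : pos + 2 + n]
        if len(body) < n:
            raise PDBFormatError(f"truncated XYZ frame starting at line {pos + 1}")
        coords = np.empty((n, 3))
        frame_elems = []
        for j, ln in enumerate(body):
            parts = ln.split()
            if len(parts) < 4:
                raise PDBFormatError(f"line {pos + 3 + j}: malformed XYZ atom line")
            frame_elems.append(parts[0].upper())
            try:
                coords[j] = [float(parts[1]), float(parts[2]), float(parts[3])]
            except ValueError:
                raise PDBFormatError(f"line {pos + 3 + j}: unparseable coordinates")
        if not elements:
            elements = frame_elems
        frames.append(coords)
        pos += 2 + n
    if not frames:
        raise PDBFormatError("no XYZ frames found")
    n = len(elements)
    topo = Structure(
        serial=np.arange(1, n + 1),
        atom_name=np.array(elements, dtype=object),
        element=np.array(elements, dtype=object),
        res_name=np.array(["UNK"] * n, dtype=object),
        chain_id=np.array(["A"] * n, dtype=object),
        res_seq=np.arange(1, n + 1),
        coords=frames[0],
        vdw_radius=np.array(
            [VDW_RADII.get(e, DEFAULT_VDW_RADIUS) for e in elements]
        ),
        mass=np.array([ATOMIC_MASSES.get(e, DEFAULT_ATOMIC_MASS) for e in elements]),
    )
    return Trajectory(topology=topo, frames=np.stack(frames))


def write_trajectory_pdb(traj: Trajectory) -> str:
    """Serialize a trajectory as MODEL/ENDMDL blocks."""
    from .structure_metrics import write_pdb
    from dataclasses import replace

    parts = []
    for i in range(traj.n_frames):
        body = write_pdb(replace(traj.topology, coords=traj.frames[i]))
        body = body.rsplit("END", 1)[0].rstrip("\n")
        parts.append(f"MODEL     {i + 1:>4d}\n{body}\nENDMDL")
    return "\n".join(parts) + "\nEND\n"


# -- superposition and fluctuation observables ------------------------------

@dataclass(frozen=True)
class SuperposeResult:
    """Proper rotation R (det=+1), translation t, and the minimized RMSD;
    the mobile set maps onto the reference via x -> x R^T + t."""

    rotation: np.ndarray
    translation: np.ndarray
    rmsd: float


def kabsch_superpose(
    mobile: np.ndarray,
    reference: np.ndarray,
    weights: Optional[np.ndarray] = None,
) -> SuperposeResult:
    """Optimal weighted rigid-body superposition (Kabsch, via SVD).

    Reflections are corrected through the sign of the smallest singular
    value, so the returned rotation is always proper.  Degenerate point
    sets (all collinear or coincident) raise
    :class:`DegenerateGeometryError` naming the rank.
    """
    P = np.asarray(mobile, dtype=float)
    Q = np.asarray(reference, dtype=float)
    if P.shape != Q.shape:
        raise InvalidParameterError(
            f"atom counts differ: {P.shape} vs {Q.shape}"
        )
    if P.ndim != 2 or P.shape[1] != 3 or P.shape[0] < 3:
        raise InvalidParameterError("need >= 3 points of dimension 3")
    if weights is None:
        w = np.ones(P.shape[0])
    else:
        w = np.asarray(weights, dtype=float)
        if w.shape != (P.shape[0],) or np.any(w < 0) or w.sum() == 0:
            raise InvalidParameterError("weights must be non-negative, not all zero")
    wn = w / w.sum()
    cp = wn @ P
    cq = wn @ Q
    Pc = P - cp
    Qc = Q - cq
    H = (Pc * wn[:, None]).T @ Qc
    U, S, Vt = np.linalg.svd(H)
    rank = int(np.sum(S > S[0] * 1e-10)) if S[0] > 0 else 0
    if rank < 2:
        raise DegenerateGeometryError(
            f"covariance rank {rank}: point set is collinear or coincident; "
            "the optimal rotation is not unique"
        )
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = cq - R @ cp
    diff = Pc @ R.T - Qc
    rmsd = float(np.sqrt(np.sum(wn * np.einsum("ij,ij->i", diff, diff))))
    return SuperposeResult(rotation=R, translation=t, rmsd=rmsd)


def _resolve(traj: Trajectory, selection: Optional[Selection]) -> np.ndarray:
    if selection is None:
        return np.arange(traj.n_atoms)
    return selection.resolve(traj.topology)


def rmsd_series(
    traj: Trajectory,
    reference_frame: int = 0,
    selection: Optional[Selection] = None,
    weights: Optional[np.ndarray] = None,
) -> np.ndarray:
    """Per-frame RMSD (A) after superposing each frame onto the reference."""
    idx = _resolve(traj, selection)
    ref = traj.frames[reference_frame][idx]
    out = np.empty(traj.n_frames)
    for i in range(traj.n_frames):
        out[i] = kabsch_superpose(traj.frames[i][idx], ref, weights).rmsd
    return out


def rmsf(
    traj: Trajectory,
    selection: Optional[Selection] = None,
    align: bool = True,
) -> pd.DataFrame:
    """Per-residue RMSF (A) about the mean structure.

    With ``align=True`` the frames are superposed twice (onto the first
    frame, then onto the resulting mean) before computing per-atom
    RMSF_i = sqrt(<|r_i - <r_i>|^2>); atom values are averaged per residue.
    """
    if traj.n_frames < 2:
        raise InvalidParameterError("RMSF needs >= 2 frames")
    idx = _resolve(traj, selection)
    X = traj.frames[:, idx, :].copy()
    if align:
        ref = X[0]
        for _pass in range(2):
            for i in range(X.shape[0]):
                res = kabsch_superpose(X[i], ref)
                X[i] = X[i] @ res.rotation.T + res.translation
            ref = X.mean(axis=0)
    mean = X.mean(axis=0)
    atom_rmsf = np.sqrt(np.mean(np.sum((X - mean) ** 2, axis=2), axis=0))
    topo = traj.topology
    df = pd.DataFrame(
        {
            "chain": topo.chain_id[idx],
            "resseq": topo.res_seq[idx],
            "resname": topo.res_name[idx],
            "rmsf": atom_rmsf,
        }
    )
    return (
        df.groupby(["chain", "resseq"], sort=False)
        .agg(resname=("resname", "first"), rmsf=("rmsf", "mean"))
        .reset_index()
    )


def radius_of_gyration(
    coords: np.ndarray, masses: Optional[np.ndarray] = None
) -> float:
    """Rg = sqrt(sum m_i |r_i - r_com|^2 / sum m_i); unit masses when omitted."""
    coords = np.asarray(coords, dtype=float)
    if coords.ndim != 2 or coords.shape[1] != 3 or coords.shape[0] == 0:
        raise InvalidParameterError("coords must be a non-empty (n, 3) array")
    if masses is None:
        m = np.ones(coords.shape[0])
    else:
        m = np.asarray(masses, dtype=float)
        if m.shape != (coords.shape[0],):
            raise InvalidParameterError("masses must match the atom count")
    if not (m.sum() > 0):
        raise InvalidParameterError("total mass must be > 0")
    com = m @ coords / m.sum()
    return float(np.sqrt(m @ np.sum((coords - com) ** 2, axis=1) / m.sum()))


def rg_series(
    traj: Trajectory,
    selection: Optional[Selection] = None,
    mass_weighted: bool = True,
) -> np.ndarray:
    """Per-frame radius of gyration over a selection."""
    idx = _resolve(traj, selection)
    masses = traj.topology.mass[idx] if mass_weighted else None
    return np.array(
        [radius_of_gyration(traj.frames[i][idx], masses) for i in range(traj.n_frames)]
    )


# -- nonbonded energies -----------------------------------------------------

def lj_from_ab(A: float, B: float) -> tuple[float, float]:
    """Convert (A, B) Lennard-Jones coefficients to (epsilon, sigma).

    U = A/r^12 - B/r^6 = 4 eps [(sigma/r)^12 - (sigma/r)^6], so
    sigma = (A/B)^(1/6) and eps = B^2/(4A).
    """
    if not (A > 0 and B > 0):
        raise InvalidParameterError("A and B must be > 0")
    return B * B / (4.0 * A), (A / B) ** (1.0 / 6.0)


@dataclass
class NonbondedParams:
    """Per-atom charge (e), LJ epsilon (kcal/mol) and sigma (A), aligned to
    a topology; NaN marks atoms without parameters (error only when used)."""

    charge: np.ndarray
    epsilon: np.ndarray
    sigma: np.ndarray
    coulomb_constant: float = COULOMB_CONSTANT

    def __post_init__(self) -> None:
        for name in ("charge", "epsilon", "sigma"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        if not (self.charge.shape == self.epsilon.shape == self.sigma.shape):
            raise InvalidParameterError("parameter arrays must share one shape")
        defined = ~np.isnan(self.epsilon)
        if np.any(self.epsilon[defined] < 0):
            raise InvalidParameterError("epsilon must be >= 0")
        defined_s = ~np.isnan(self.sigma)
        if np.any(self.sigma[defined_s] <= 0):
            raise InvalidParameterError("sigma must be > 0")

    def check_coverage(self, topology: Structure, idx: np.ndarray) -> None:
        bad = idx[
            np.isnan(self.charge[idx])
            | np.isnan(self.epsilon[idx])
            | np.isnan(self.sigma[idx])
        ]
        if bad.size:
            names = [
                f"{topology.chain_id[i]}/{topology.res_seq[i]}/{topology.atom_name[i]}"
                for i in bad[:20]
            ]
            raise MissingParameterError(
                f"missing nonbonded parameters for atoms: {', '.join(names)}"
                + (" ..." if bad.size > 20 else "")
            )


def read_nonbonded_tsv(path_or_buffer, topology: Structure) -> NonbondedParams:
    """Read ``chain,resseq,atom_name,charge_e,eps_kcal,sigma_A`` (TSV) and
    align the rows to the topology's atoms; unmatched atoms stay NaN."""
    df = pd.read_csv(path_or_buffer, sep="\t", comment="#")
    required = ["chain", "resseq", "atom_name", "charge_e", "eps_kcal", "sigma_A"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise InvalidParameterError(f"parameter TSV missing columns: {missing}")
    table = {
        (str(r.chain), int(r.resseq), str(r.atom_name)): (
            float(r.charge_e), float(r.eps_kcal), float(r.sigma_A)
        )
        for r in df.itertuples()
    }
    n = topology.n_atoms
    charge = np.full(n, np.nan)
    eps = np.full(n, np.nan)
    sigma = np.full(n, np.nan)
    for i in range(n):
        key = (
            str(topology.chain_id[i]),
            int(topology.res_seq[i]),
            str(topology.atom_name[i]),
        )
        if key in table:
            charge[i], eps[i], sigma[i] = table[key]
    return NonbondedParams(charge=charge, epsilon=eps, sigma=sigma)


def interaction_energy(
    coords: np.ndarray,
    sel_a: np.ndarray,
    sel_b: np.ndarray,
    params: NonbondedParams,
    cutoff: Optional[float] = None,
    topology: Optional[Structure] = None,
) -> tuple[float, float]:
    """Selection-pair electrostatic and van der Waals energies (kcal/mol).

    electrostatic = sum k q_i q_j / r_ij over i in A, j in B;
    vdw = sum 4 eps_ij [(sigma_ij/r_ij)^12 - (sigma_ij/r_ij)^6] with
    Lorentz-Berthelot combination (sigma arithmetic, epsilon geometric).
    Direct sums with no cutoff unless one is given.
    """
    sel_a = np.asarray(sel_a, dtype=int)
    sel_b = np.asarray(sel_b, dtype=int)
    if np.intersect1d(sel_a, sel_b).size:
        raise InvalidParameterError("selections A and B must be disjoint")
    if topology is not None:
        params.check_coverage(topology, np.concatenate([sel_a, sel_b]))
    else:
        both = np.concatenate([sel_a, sel_b])
        if np.any(
            np.isnan(params.charge[both])
            | np.isnan(params.epsilon[both])
            | np.isnan(params.sigma[both])
        ):
            raise MissingParameterError(
                "missing nonbonded parameters for selected atoms"
            )
    coords = np.asarray(coords, dtype=float)
    ra = coords[sel_a]
    rb = coords[sel_b]
    diff = ra[:, None, :] - rb[None, :, :]
    r = np.sqrt(np.einsum("ijk,ijk->ij", diff, diff))
    if np.any(r < CLASH_DISTANCE_A):
        i, j = np.unravel_index(int(np.argmin(r)), r.shape)
        raise ClashError(
            f"atoms {int(sel_a[i])} and {int(sel_b[j])} are {r[i, j]:.4f} A apart "
            f"(< {CLASH_DISTANCE_A} A)"
        )
    mask = np.ones_like(r, dtype=bool) if cutoff is None else r <= cutoff
    qq = params.charge[sel_a][:, None] * params.charge[sel_b][None, :]
    elec = params.coulomb_constant * np.sum((qq / r)[mask])
    sig = 0.5 * (params.sigma[sel_a][:, None] + params.sigma[sel_b][None, :])
    eps = np.sqrt(params.epsilon[sel_a][:, None] * params.epsilon[sel_b][None, :])
    sr6 = (sig / r) ** 6
    vdw = np.sum((4.0 * eps * (sr6**2 - sr6))[mask])
    return float(elec), float(vdw)


def energy_series(
    traj: Trajectory,
    selection_a: Selection,
    selection_b: Selection,
    params: NonbondedParams,
    cutoff: Optional[float] = None,
) -> pd.DataFrame:
    """Per-frame electrostatic and vdW energies between two selections."""
    ia = selection_a.resolve(traj.topology)
    ib = selection_b.resolve(traj.topology)
    rows = [
        interaction_energy(
            traj.frames[i], ia, ib, params, cutoff=cutoff, topology=traj.topology
        )
        for i in range(traj.n_frames)
    ]
    return pd.DataFrame(rows, columns=["electrostatic_kcal", "vdw_kcal"])


# -- replicate statistics ---------------------------------------------------

@dataclass
class SeriesStats:
    """Pointwise mean/SD across replicates plus a windowed summary.

    ``window`` is a half-open frame slice (start, stop); the window mean and
    SD are computed from each replicate's window mean (the between-replicate
    convention used when reporting e.g. "last 10 ns" values).
    """

    mean: np.ndarray
    sd: np.ndarray
    window: Optional[tuple[int, int]] = None
    window_mean: Optional[float] = None
    window_sd: Optional[float] = None
    n_replicates: int = 1


def fraction_window(n: int, start_frac: float, stop_frac: float) -> tuple[int, int]:
    """Frame window from fractions of the series length, e.g. (0.9, 1.0)
    for the last 10% ("last 10 ns" of a 100 ns run)."""
    if not (0 <= start_frac < stop_frac <= 1):
        raise InvalidParameterError("need 0 <= start < stop <= 1")
    return int(round(start_frac * n)), int(round(stop_frac * n))


def replicate_stats(
    series_list: Sequence[np.ndarray],
    window: Optional[tuple[int, int]] = None,
) -> SeriesStats:
    """Mean and sample SD across replicate series of equal length."""
    if len(series_list) == 0:
        raise InvalidParameterError("need at least one series")
    arrs = [np.asarray(s, dtype=float) for s in series_list]
    n = arrs[0].shape[0]
    for a in arrs[1:]:
        if a.shape[0] != n:
            raise InvalidParameterError("replicate series have unequal lengths")
    stack = np.stack(arrs)
    mean = stack.mean(axis=0)
    sd = stack.std(axis=0, ddof=1) if len(arrs) > 1 else np.zeros(n)
    wmean = wsd = None
    if window is not None:
        lo, hi = window
        if not (0 <= lo < hi <= n):
            raise InvalidParameterError(f"window {window} outside series of length {n}")
        per_rep = stack[:, lo:hi].mean(axis=1)
        wmean = float(per_rep.mean())
        wsd = float(per_rep.std(ddof=1)) if len(arrs) > 1 else 0.0
    return SeriesStats(
        mean=mean, sd=sd, window=window, window_mean=wmean, window_sd=wsd,
        n_replicates=len(arrs),
    )
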