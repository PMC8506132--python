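"""Structure parsing, Shrake-Rupley SASA and haloadaptation shell statistics.

Halophilic proteins adapt to molar salt with an acidified, hydrated surface
and a shrunken hydrophobic core.  To quantify this, every residue is
classified by its solvent-accessible surface area (SASA, 1.4 A water
probe): residues with SASA >= 20 A^2 belong to the exposed (external)
shell, the rest to the core (internal shell).  Composition statistics per
shell (residue-type percentages, acidic D+E fraction, tryptophan exposure
counts, core fraction by count and by standard residue volume) are then
compared between a halophilic protein and a non-halophilic reference.

SASA is computed with the Shrake-Rupley test-point method on a
deterministic golden-spiral point set; by default the point sphere is
oriented in a frame derived from the structure's principal axes, which
makes the computed areas exactly invariant under global rotation and
translation of the coordinates.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .errors import (
    EmptyStructureError,
    InvalidParameterError,
    PDBFormatError,
)

__all__ = [
    "Structure",
    "SasaResult",
    "CompositionReport",
    "VDW_RADII",
    "ATOMIC_MASSES",
    "RESIDUE_VOLUMES_A3",
    "HYDROPHOBIC_RESIDUES",
    "parse_pdb",
    "write_pdb",
    "sphere_points",
    "shrake_rupley_sasa",
    "classify_shells",
    "shell_composition",
    "compare_compositions",
    "write_shell_table",
]

#: Van der Waals radii in Angstrom (Bondi-style set); unknown elements
#: default to carbon.
VDW_RADII: dict[str, float] = {
    "C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80, "P": 1.80, "H": 1.20,
}
DEFAULT_VDW_RADIUS = 1.70

ATOMIC_MASSES: dict[str, float] = {
    "H": 1.008, "C": 12.011, "N": 14.007, "O": 15.999, "S": 32.06,
    "P": 30.974, "SE": 78.971, "FE": 55.845, "ZN": 65.38, "MG": 24.305,
    "K": 39.098, "NA": 22.990, "CL": 35.45,
}
DEFAULT_ATOMIC_MASS = 12.011

#: Standard amino-acid volumes (A^3), Zamyatnin-style partial volumes.
RESIDUE_VOLUMES_A3: dict[str, float] = {
    "ALA": 88.6, "ARG": 173.4, "ASN": 114.1, "ASP": 111.1, "CYS": 108.5,
    "GLN": 143.8, "GLU": 138.4, "GLY": 60.1, "HIS": 153.2, "ILE": 166.7,
    "LEU": 166.7, "LYS": 168.6, "MET": 162.9, "PHE": 189.9, "PRO": 112.7,
    "SER": 89.0, "THR": 116.1, "TRP": 227.8, "TYR": 193.6, "VAL": 140.0,
}
DEFAULT_RESIDUE_VOLUME = 140.0

#: Residue types counted as hydrophobic for the "hydrophobic core" wording.
HYDROPHOBIC_RESIDUES = frozenset(
    {"ALA", "VAL", "LEU", "ILE", "MET", "PHE", "TRP", "CYS", "GLY"}
)

#: Protein backbone atom names, excluded in side-chain-only SASA mode.
BACKBONE_ATOMS = frozenset({"N", "CA", "C", "O", "OXT"})

ACIDIC_RESIDUES = frozenset({"ASP", "GLU"})


@dataclass
class Structure:
    """Atoms as parallel arrays (coordinates in Angstrom)."""

    serial: np.ndarray
    atom_name: np.ndarray
    element: np.ndarray
    res_name: np.ndarray
    chain_id: np.ndarray
    res_seq: np.ndarray
    coords: np.ndarray
    vdw_radius: np.ndarray
    mass: np.ndarray
    charge: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 2 or self.coords.shape[1] != 3:
            raise InvalidParameterError("coords must be (n_atoms, 3)")
        if not np.all(np.isfinite(self.coords)):
            raise InvalidParameterError("coordinates must be finite")
        if not np.all(np.asarray(self.vdw_radius) > 0):
            raise InvalidParameterError("vdw radii must be > 0")

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[0]

    def subset(self, mask_or_idx) -> "Structure":
        """New Structure restricted to the given boolean mask or indices."""
        m = np.asarray(mask_or_idx)
        return Structure(
            serial=self.serial[m],
            atom_name=self.atom_name[m],
            element=self.element[m],
            res_name=self.res_name[m],
            chain_id=self.chain_id[m],
            res_seq=self.res_seq[m],
            coords=self.coords[m],
            vdw_radius=self.vdw_radius[m],
            mass=self.mass[m],
            charge=None if self.charge is None else self.charge[m],
        )

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "Structure":
        """Copy with coords mapped through x -> x R^T + t."""
        return replace(
            self, coords=self.coords @ np.asarray(rotation).T + np.asarray(translation)
        )


def _element_from_name(name: str) -> str:
    """Infer the element from a PDB atom name (fallback when cols 77-78 blank)."""
    stripped = "".join(ch for ch in name if ch.isalpha())
    if not stripped:
        return ""
    # names like 1HB / HG21 are hydrogens
    if name.strip()[0].isdigit() or stripped[0] == "H":
        return "H"
    return stripped[0].upper()


def parse_pdb(
    text: str,
    *,
    include_hetatm: bool = True,
    vdw_radii: Optional[dict[str, float]] = None,
) -> Structure:
    """Parse fixed-column PDB ATOM/HETATM records into a :class:`Structure`.

    Only the first MODEL of a multi-model file is read (trajectories go
    through :func:`halokin.traj_analysis.read_trajectory_pdb`).  Coordinates
    come from columns 31-38/39-46/47-54; the element from columns 77-78 with
    an atom-name fallback.  Van der Waals radii are assigned per element.
    Malformed numeric fields raise :class:`PDBFormatError` naming the line.
    """
    radii_table = VDW_RADII if vdw_radii is None else vdw_radii
    records = ("ATOM  ", "HETATM") if include_hetatm else ("ATOM  ",)
    serial, names, elements, resnames, chains, resseqs, xyz = (
        [], [], [], [], [], [], []
    )
    in_model = 0
    seen_keys: set[tuple[str, int, str]] = set()
    for lineno, line in enumerate(text.splitlines(), start=1):
        rec = line[:6]
        if rec.startswith("MODEL"):
            in_model += 1
            if in_model > 1:
                break
            continue
        if rec.startswith("ENDMDL"):
            break
        if rec not in records:
            continue
        altloc = line[16:17]
        if altloc not in (" ", "", "A"):
            continue
        try:
            x = float(line[30:38])
            y = float(line[38:46])
            z = float(line[46:54])
            rs = int(line[22:26])
            try:
                sn = int(line[6:11])
            except ValueError:
                sn = len(serial) + 1
        except ValueError:
            raise PDBFormatError(
                f"line {lineno}: unparseable coordinate or residue field: {line!r}"
            )
        name = line[12:16].strip()
        elem = line[76:78].strip().upper() if len(line) >= 77 else ""
        if not elem:
            elem = _element_from_name(line[12:16])
        chain = line[21:22]
        key = (chain, rs, name)
        if key in seen_keys:
            raise PDBFormatError(
                f"line {lineno}: duplicate atom (chain {chain!r}, residue {rs}, "
                f"name {name!r})"
            )
        seen_keys.add(key)
        serial.append(sn)
        names.append(name)
        elements.append(elem)
        resnames.append(line[17:20].strip())
        chains.append(chain)
        resseqs.append(rs)
        xyz.append((x, y, z))
    if not serial:
        raise EmptyStructureError("no ATOM/HETATM records found")
    elements_arr = np.array(elements, dtype=object)
    radii = np.array(
        [radii_table.get(e, DEFAULT_VDW_RADIUS) for e in elements], dtype=float
    )
    masses = np.array(
        [ATOMIC_MASSES.get(e, DEFAULT_ATOMIC_MASS) for e in elements], dtype=float
    )
    return Structure(
        serial=np.array(serial, dtype=int),
        atom_name=np.array(names, dtype=object),
        element=elements_arr,
        res_name=np.array(resnames, dtype=object),
        chain_id=np.array(chains, dtype=object),
        res_seq=np.array(resseqs, dtype=int),
        coords=np.array(xyz, dtype=float),
        vdw_radius=radii,
        mass=masses,
    )


def write_pdb(structure: Structure) -> str:
    """Serialize a Structure as minimal fixed-column ATOM records."""
    lines = []
    for i in range(structure.n_atoms):
        name = str(structure.atom_name[i])
        # standard PDB alignment: 1-letter elements start in column 14
        name_field = f" {name:<3s}" if len(name) < 4 else name[:4]
        lines.append(
            "ATOM  {serial:>5d} {name}{alt}{res:<3s} {chain}{resseq:>4d}    "
            "{x:8.3f}{y:8.3f}{z:8.3f}{occ:6.2f}{b:6.2f}          {elem:>2s}".format(
                serial=int(structure.serial[i]),
                name=name_field,
                alt=" ",
                res=str(structure.res_name[i])[:3],
                chain=str(structure.chain_id[i])[:1] or "A",
                resseq=int(structure.res_seq[i]),
                x=structure.coords[i, 0],
                y=structure.coords[i, 1],
                z=structure.coords[i, 2],
                occ=1.0,
                b=0.0,
                elem=str(structure.element[i])[:2],
            )
        )
    lines.append("END")
    return "\n".join(lines) + "\n"


def sphere_points(n: int) -> np.ndarray:
    """Deterministic golden-spiral distribution of ``n`` unit vectors."""
    i = np.arange(n, dtype=float) + 0.5
    phi = np.arccos(1.0 - 2.0 * i / n)
    theta = np.pi * (1.0 + np.sqrt(5.0)) * i
    return np.column_stack(
        [np.sin(phi) * np.cos(theta), np.sin(phi) * np.sin(theta), np.cos(phi)]
    )


def _principal_frame(coords: np.ndarray) -> np.ndarray:
    """Right-handed orthonormal frame from the principal axes of ``coords``.

    Rotating the structure rotates this frame identically (axis signs are
    fixed by order-weighted projections, which are rotation-invariant), so a
    point sphere oriented in this frame co-rotates with the structure and
    SASA becomes exactly rotation-invariant.  Falls back to the identity for
    < 3 atoms or (near-)degenerate principal moments.
    """
    n = coords.shape[0]
    if n < 3:
        return np.eye(3)
    centered = coords - coords.mean(axis=0)
    cov = centered.T @ centered / n
    evals, evecs = np.linalg.eigh(cov)
    scale = max(evals[-1], 1e-30)
    gaps = np.diff(evals) / scale
    if np.any(gaps < 1e-8):  # symmetric/degenerate cloud: no unique frame
        return np.eye(3)
    order_w = np.arange(1, n + 1, dtype=float)
    axes = []
    for k in (2, 1):  # two largest principal axes
        v = evecs[:, k]
        d = float(order_w @ (centered @ v))
        if abs(d) < 1e-12 * scale:
            d = float(order_w**2 @ (centered @ v))
        if d < 0:
            v = -v
        axes.append(v)
    axes.append(np.cross(axes[0], axes[1]))
    return np.column_stack(axes)


@dataclass
class SasaResult:
    """Per-atom SASA (A^2, aligned to the input structure; excluded atoms 0)
    and a per-residue table (chain, resseq, resname, sasa)."""

    atom_sasa: np.ndarray
    residues: pd.DataFrame
    probe: float
    n_points: int


def shrake_rupley_sasa(
    structure: Structure,
    probe: float = 1.4,
    n_points: int = 960,
    include_hydrogens: bool = False,
    sidechain_only: bool = False,
    orient: str = "principal",
) -> SasaResult:
    """Shrake-Rupley solvent-accessible surface area.

    For each atom, ``n_points`` test points are placed on a sphere of radius
    r_vdw + probe; the accessible area is (exposed points / n_points) x
    4 pi (r+probe)^2.  A point is buried when it falls strictly inside a
    neighbour's expanded sphere.  Hydrogens are excluded by default (typical
    for heavy-atom homology models).  ``sidechain_only`` restricts the
    per-residue sums to non-backbone atoms; per-atom areas are unaffected.

    ``orient="principal"`` (default) aligns the test-point sphere with the
    structure's principal axes, making areas exactly invariant under global
    rigid motion; ``orient="fixed"`` keeps the laboratory frame.
    """
    if structure.n_atoms == 0:
        raise EmptyStructureError("empty structure")
    if n_points < 16:
        raise InvalidParameterError("n_points must be >= 16")
    if not (probe >= 0):
        raise InvalidParameterError("probe radius must be >= 0")
    if orient not in ("principal", "fixed"):
        raise InvalidParameterError("orient must be 'principal' or 'fixed'")

    included = np.ones(structure.n_atoms, dtype=bool)
    if not include_hydrogens:
        included &= structure.element != "H"
    idx = np.nonzero(included)[0]
    if idx.size == 0:
        raise EmptyStructureError("no atoms left after hydrogen exclusion")

    coords = structure.coords[idx]
    radii = structure.vdw_radius[idx] + probe

    pts = sphere_points(n_points)
    if orient == "principal":
        pts = pts @ _principal_frame(coords).T

    tree = cKDTree(coords)
    max_r = radii.max()
    atom_sasa = np.zeros(structure.n_atoms)
    for k in range(idx.size):
        ri = radii[k]
        neighbours = tree.query_ball_point(coords[k], ri + max_r)
        neighbours = [j for j in neighbours if j != k]
        test = coords[k] + ri * pts
        if neighbours:
            nb = np.array(neighbours, dtype=int)
            d = np.linalg.norm(coords[nb] - coords[k], axis=1)
            nb = nb[d < ri + radii[nb]]
            exposed = np.ones(n_points, dtype=bool)
            for j in nb:
                dj = np.linalg.norm(test - coords[j], axis=1)
                exposed &= dj >= radii[j]
                if not exposed.any():
                    break
            n_exposed = int(exposed.sum())
        else:
            n_exposed = n_points
        atom_sasa[idx[k]] = n_exposed / n_points * 4.0 * np.pi * ri**2

    in_sum = included.copy()
    if sidechain_only:
        is_backbone = np.isin(structure.atom_name.astype(str), list(BACKBONE_ATOMS))
        in_sum &= ~is_backbone
    df = pd.DataFrame(
        {
            "chain": structure.chain_id,
            "resseq": structure.res_seq,
            "resname": structure.res_name,
            "sasa": np.where(in_sum, atom_sasa, 0.0),
        }
    )
    residues = (
        df.groupby(["chain", "resseq"], sort=False)
        .agg(resname=("resname", "first"), sasa=("sasa", "sum"))
        .reset_index()
    )
    return SasaResult(
        atom_sasa=atom_sasa, residues=residues, probe=probe, n_points=n_points
    )


#: SASA threshold (A^2) separating exposed (external) from core (internal).
EXPOSURE_THRESHOLD_A2 = 20.0


def classify_shells(
    per_residue: pd.DataFrame | SasaResult, threshold: float = EXPOSURE_THRESHOLD_A2
) -> pd.DataFrame:
    """Label residues exposed (sasa >= threshold, boundary inclusive) or core."""
    if isinstance(per_residue, SasaResult):
        per_residue = per_residue.residues
    df = per_residue.copy()
    if "sasa" not in df.columns:
        raise InvalidParameterError("per-residue table needs a 'sasa' column")
    if len(df) and np.any(df["sasa"].to_numpy() < 0):
        raise InvalidParameterError("SASA values must be >= 0")
    df["shell"] = np.where(df["sasa"] >= threshold, "exposed", "core")
    return df


@dataclass
class CompositionReport:
    """Shell-composition statistics of one structure.

    per_shell_percent: % of each residue type within each shell;
    core_fraction_count / core_fraction_volume: core share of all residues
    by count and by standard residue volume; hydrophobic_core_fraction_volume:
    volume share of core residues belonging to the hydrophobic set;
    acidic_percent: % of D+E per shell; exposure_counts: per-type
    "exposed/total" counts.
    """

    per_shell_percent: pd.DataFrame
    core_fraction_count: float
    core_fraction_volume: float
    hydrophobic_core_fraction_volume: float
    acidic_percent: dict[str, float]
    exposure_counts: pd.DataFrame
    shell_labels: tuple[str, ...] = ("core", "exposed")
    hydrophobic_set: frozenset = HYDROPHOBIC_RESIDUES


def shell_composition(
    shells: pd.DataFrame,
    hydrophobic_set: frozenset = HYDROPHOBIC_RESIDUES,
    volumes: Optional[dict[str, float]] = None,
) -> CompositionReport:
    """Composition statistics from a labelled shell table.

    Percentages are per shell: count of a residue type divided by the shell
    size.  The core fraction is reported both by residue count and by summed
    standard residue volume (the "total volume" reading of the
    hydrophobic-core share); the hydrophobic-core volume fraction restricts
    the numerator to hydrophobic residue types.
    """
    if len(shells) == 0:
        raise InvalidParameterError("shell table is empty")
    if "shell" not in shells.columns:
        raise InvalidParameterError("table must carry a 'shell' column")
    vols = RESIDUE_VOLUMES_A3 if volumes is None else volumes

    counts = shells.groupby(["shell", "resname"]).size().rename("count")
    shell_sizes = shells.groupby("shell").size()
    pct = (100.0 * counts / shell_sizes.reindex(
        counts.index.get_level_values("shell")).to_numpy()).rename("percent")
    per_shell = pd.concat([counts, pct], axis=1)

    n_total = len(shells)
    core_mask = shells["shell"] == "core"
    core_fraction_count = 100.0 * core_mask.sum() / n_total

    res_vol = shells["resname"].map(lambda r: vols.get(r, DEFAULT_RESIDUE_VOLUME))
    total_vol = float(res_vol.sum())
    core_fraction_volume = 100.0 * float(res_vol[core_mask].sum()) / total_vol
    hydro_core = core_mask & shells["resname"].isin(hydrophobic_set)
    hydrophobic_core_fraction_volume = (
        100.0 * float(res_vol[hydro_core].sum()) / total_vol
    )

    acidic = {}
    for sh, grp in shells.groupby("shell"):
        acidic[sh] = 100.0 * grp["resname"].isin(ACIDIC_RESIDUES).sum() / len(grp)

    expo = (
        shells.assign(exposed=shells["shell"] == "exposed")
        .groupby("resname")
        .agg(exposed=("exposed", "sum"), total=("exposed", "size"))
        .reset_index()
    )
    expo["report"] = expo["exposed"].astype(int).astype(str) + "/" + expo[
        "total"
    ].astype(str)

    return CompositionReport(
        per_shell_percent=per_shell,
        core_fraction_count=float(core_fraction_count),
        core_fraction_volume=float(core_fraction_volume),
        hydrophobic_core_fraction_volume=float(hydrophobic_core_fraction_volume),
        acidic_percent=acidic,
        exposure_counts=expo,
        shell_labels=tuple(sorted(shells["shell"].unique())),
        hydrophobic_set=hydrophobic_set,
    )


def compare_compositions(
    report_a: CompositionReport, report_b: CompositionReport
) -> pd.DataFrame:
    """Per-(shell, residue-type) percentage differences, sorted by |diff|.

    Types absent from one report count as 0%.  Raises when the two reports
    use different shell schemes.
    """
    if set(report_a.shell_labels) != set(report_b.shell_labels):
        raise InvalidParameterError(
            f"shell schemes differ: {report_a.shell_labels} vs "
            f"{report_b.shell_labels}"
        )
    a = report_a.per_shell_percent["percent"]
    b = report_b.per_shell_percent["percent"]
    idx = a.index.union(b.index)
    a = a.reindex(idx, fill_value=0.0)
    b = b.reindex(idx, fill_value=0.0)
    out = pd.DataFrame(
        {
            "shell": idx.get_level_values(0),
            "resname": idx.get_level_values(1),
            "pct_a": a.to_numpy(),
            "pct_b": b.to_numpy(),
            "difference": (a - b).to_numpy(),
        }
    )
    return out.reindex(
        out["difference"].abs().sort_values(ascending=False, kind="stable").index
    ).reset_index(drop=True)


def write_shell_table(shells: pd.DataFrame, path) -> None:
    """TSV columns: chain,resseq,resname,sasa_A2,shell."""
    shells.rename(columns={"sasa": "sasa_A2"}).to_csv(path, sep="\t", index=False)


def write_composition_json(report: CompositionReport, path) -> None:
    payload = {
        "per_shell_percent": [
            {"shell": sh, "resname": rn, "percent": float(p)}
            for (sh, rn), p in report.per_shell_percent["percent"].items()
        ],
        "core_fraction_count": report.core_fraction_count,
        "core_fraction_volume": report.core_fraction_volume,
        "hydrophobic_core_fraction_volume": report.hydrophobic_core_fraction_volume,
        "acidic_percent": report.acidic_percent,
        "exposure_counts": report.exposure_counts.to_dict("records"),
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1)
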