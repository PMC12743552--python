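"""Protein structures, multi-model trajectories and core geometry.

This module provides the structural substrate for interface analysis of the
von Willebrand factor A1/A2 domain pair (and any comparable two-partner
complex): PDB ingestion with author residue numbering kept verbatim,
multi-model files as trajectories, Kabsch superposition, per-frame
Cα-RMSD, Shrake–Rupley solvent-accessible surface area (SASA) and the
buried SASA of a two-partner complex.

Units are Å throughout; times are nanoseconds.
"""

from __future__ import annotations

import io
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.spatial import cKDTree
from scipy.spatial.transform import Rotation

__all__ = [
    "VDW_RADII",
    "Atom",
    "Structure",
    "Trajectory",
    "SuperposeResult",
    "PDBParseError",
    "read_structure",
    "read_trajectory",
    "write_structure",
    "write_trajectory",
    "superpose",
    "rmsd_ca",
    "sasa",
    "buried_sasa",
    "sphere_points",
]

#: Bondi-style van der Waals radii (Å), element-keyed.  Configurable per call;
#: these defaults cover everything occurring in protein heavy/H atoms here.
VDW_RADII: Mapping[str, float] = {
    "C": 1.70,
    "N": 1.55,
    "O": 1.52,
    "S": 1.80,
    "H": 1.20,
    "P": 1.80,
}


class PDBParseError(ValueError):
    """Raised when a PDB file cannot be ingested."""


@dataclass
class Atom:
    """A single atom with author numbering and a vdW radius.

    ``res_seq`` is the author residue number exactly as printed in the PDB
    (e.g. 1323 for D1323 of VWF-A1); no renumbering is ever applied.
    """

    serial: int
    name: str
    element: str
    res_name: str
    res_seq: int
    chain_id: str
    coords: np.ndarray
    vdw_radius: float

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float).reshape(3)
        if not np.all(np.isfinite(self.coords)):
            raise ValueError(f"non-finite coordinates for atom {self.name}")
        if self.vdw_radius <= 0:
            raise ValueError(f"vdw_radius must be > 0 (atom {self.name})")


@dataclass
class Structure:
    """An ordered collection of atoms partitioned into chains."""

    atoms: list[Atom]

    def __post_init__(self) -> None:
        if not self.atoms:
            raise ValueError("a Structure must contain at least one atom")
        seen: set[tuple[str, int, str]] = set()
        for a in self.atoms:
            key = (a.chain_id, a.res_seq, a.name)
            if key in seen:
                raise ValueError(f"duplicate atom identity {key}")
            seen.add(key)

    def __len__(self) -> int:
        return len(self.atoms)

    @property
    def coords(self) -> np.ndarray:
        """(n_atoms, 3) coordinate array, Å."""
        return np.array([a.coords for a in self.atoms], dtype=float)

    @property
    def chain_ids(self) -> list[str]:
        """Chain identifiers in order of first appearance."""
        out: list[str] = []
        for a in self.atoms:
            if a.chain_id not in out:
                out.append(a.chain_id)
        return out

    @property
    def chains(self) -> dict[str, list[int]]:
        """Atom indices per chain id."""
        out: dict[str, list[int]] = {}
        for i, a in enumerate(self.atoms):
            out.setdefault(a.chain_id, []).append(i)
        return out

    def select(
        self,
        chains: Iterable[str] | None = None,
        names: Iterable[str] | None = None,
        elements: Iterable[str] | None = None,
        res_seq: Iterable[int] | None = None,
    ) -> np.ndarray:
        """Return indices of atoms matching every given filter."""
        chains = set(chains) if chains is not None else None
        names = set(names) if names is not None else None
        elements = set(elements) if elements is not None else None
        res_seq = set(res_seq) if res_seq is not None else None
        idx = [
            i
            for i, a in enumerate(self.atoms)
            if (chains is None or a.chain_id in chains)
            and (names is None or a.name in names)
            and (elements is None or a.element in elements)
            and (res_seq is None or a.res_seq in res_seq)
        ]
        return np.array(idx, dtype=int)

    def subset(self, indices: Iterable[int]) -> "Structure":
        return Structure([self.atoms[i] for i in indices])

    def ca_indices(self, chains: Iterable[str] | None = None) -> np.ndarray:
        return self.select(chains=chains, names=["CA"])


@dataclass
class Trajectory:
    """A topology plus per-frame coordinates congruent with it."""

    topology: Structure
    frames: list[np.ndarray]
    frame_interval_ns: float = 1.0

    def __post_init__(self) -> None:
        if not self.frames:
            raise ValueError("a Trajectory needs at least one frame")
        if self.frame_interval_ns <= 0:
            raise ValueError("frame_interval_ns must be > 0")
        n = len(self.topology)
        self.frames = [np.asarray(f, dtype=float) for f in self.frames]
        for k, f in enumerate(self.frames):
            if f.shape != (n, 3):
                raise ValueError(
                    f"frame {k} has shape {f.shape}, expected ({n}, 3)"
                )

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    @property
    def times_ns(self) -> np.ndarray:
        return np.arange(self.n_frames) * self.frame_interval_ns


# ---------------------------------------------------------------------------
# PDB input/output
# ---------------------------------------------------------------------------

def _element_of(bio_atom) -> str:
    el = (bio_atom.element or "").strip().upper()
    if not el:
        # fall back to the first alphabetic character of the atom name
        for ch in bio_atom.get_name():
            if ch.isalpha():
                el = ch.upper()
                break
    return el


def _convert_model(model, radii: Mapping[str, float]) -> Structure:
    atoms: list[Atom] = []
    for chain in model:
        for residue in chain:
            het, seq, icode = residue.id
            if icode.strip():
                raise PDBParseError(
                    f"insertion code {icode!r} at residue {seq} is not "
                    "supported; renumber the structure first"
                )
            for bio_atom in residue:
                # Disordered atoms: Biopython has already selected the
                # highest-occupancy altloc (ties keep the first).
                el = _element_of(bio_atom)
                if el not in radii:
                    raise PDBParseError(
                        f"no vdW radius for element {el!r} "
                        f"(atom {bio_atom.get_name()}, residue {seq}); "
                        "pass a radii table covering it"
                    )
                atoms.append(
                    Atom(
                        serial=bio_atom.serial_number,
                        name=bio_atom.get_name(),
                        element=el,
                        res_name=residue.get_resname(),
                        res_seq=seq,
                        chain_id=chain.id,
                        coords=np.array(bio_atom.get_coord(), dtype=float),
                        vdw_radius=radii[el],
                    )
                )
    if not atoms:
        raise PDBParseError("no ATOM/HETATM records found (empty structure)")
    return Structure(atoms)


def read_structure(
    path: str | Path,
    model_policy: str = "first",
    radii: Mapping[str, float] = VDW_RADII,
):
    """Read a PDB file (v3.3 fixed columns) into Structure objects.

    Parameters
    ----------
    model_policy : {"first", "all"}
        ``"first"`` returns a single :class:`Structure`; ``"all"`` returns a
        list with one Structure per MODEL record.
    radii : mapping
        Element-keyed vdW radii (Å) assigned to every atom.

    Raises
    ------
    PDBParseError
        On malformed coordinate fields (the message names the line), files
        with zero atom records, or insertion codes.
    """
    from Bio.PDB import PDBParser
    from Bio.PDB.PDBExceptions import PDBConstructionException

    if model_policy not in ("first", "all"):
        raise ValueError("model_policy must be 'first' or 'all'")
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    parser = PDBParser(PERMISSIVE=False, QUIET=True)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            bio_structure = parser.get_structure(path.stem, str(path))
    except PDBConstructionException as exc:
        raise PDBParseError(f"malformed PDB record in {path.name}: {exc}") from exc
    models = list(bio_structure)
    if not models:
        raise PDBParseError(f"{path.name}: no models found (empty structure)")
    if model_policy == "first":
        return _convert_model(models[0], radii)
    return [_convert_model(m, radii) for m in models]


def read_trajectory(
    path: str | Path,
    frame_interval_ns: float = 1.0,
    radii: Mapping[str, float] = VDW_RADII,
) -> Trajectory:
    """Assemble a Trajectory from a multi-MODEL PDB of congruent models."""
    models = read_structure(path, model_policy="all", radii=radii)
    top = models[0]
    ident = [(a.chain_id, a.res_seq, a.name) for a in top.atoms]
    for k, m in enumerate(models[1:], start=2):
        if [(a.chain_id, a.res_seq, a.name) for a in m.atoms] != ident:
            raise PDBParseError(
                f"model {k} is not congruent with model 1 (atom tables differ)"
            )
    return Trajectory(top, [m.coords for m in models], frame_interval_ns)


def _format_atom_name(name: str, element: str) -> str:
    # PDB v3.3: single-letter elements start in column 14 unless the name
    # itself is 4 characters long.
    if len(name) >= 4:
        return name[:4]
    if len(element) == 1:
        return f" {name:<3s}"
    return f"{name:<4s}"


def _atom_record(a: Atom, serial: int, coords: np.ndarray) -> str:
    return (
        f"ATOM  {serial:5d} {_format_atom_name(a.name, a.element)} "
        f"{a.res_name:>3s} {a.chain_id:1s}{a.res_seq:4d}    "
        f"{coords[0]:8.3f}{coords[1]:8.3f}{coords[2]:8.3f}"
        f"{1.00:6.2f}{0.00:6.2f}          {a.element:>2s}"
    )


def write_structure(structure: Structure, path: str | Path) -> None:
    """Write a single-model PDB (fixed-width v3.3 ATOM records)."""
    buf = io.StringIO()
    for i, a in enumerate(structure.atoms, start=1):
        buf.write(_atom_record(a, i, a.coords) + "\n")
    buf.write("END\n")
    Path(path).write_text(buf.getvalue())


def write_trajectory(traj: Trajectory, path: str | Path) -> None:
    """Write a multi-MODEL PDB, one MODEL per frame."""
    buf = io.StringIO()
    for k, frame in enumerate(traj.frames, start=1):
        buf.write(f"MODEL     {k:4d}\n")
        for i, a in enumerate(traj.topology.atoms, start=1):
            buf.write(_atom_record(a, i, frame[i - 1]) + "\n")
        buf.write("ENDMDL\n")
    buf.write("END\n")
    Path(path).write_text(buf.getvalue())


# ---------------------------------------------------------------------------
# Superposition and RMSD
# ---------------------------------------------------------------------------

@dataclass
class SuperposeResult:
    """Optimal rigid transform mapping mobile onto reference."""

    rotation: np.ndarray
    translation: np.ndarray
    rmsd: float

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return np.asarray(coords, float) @ self.rotation.T + self.translation


def superpose(mobile: np.ndarray, reference: np.ndarray) -> SuperposeResult:
    """Least-squares rigid superposition (Kabsch, proper rotation only).

    Returns the rotation/translation minimizing the RMSD between the moved
    mobile set and the reference, with det(rotation) = +1 guaranteed (no
    reflections), and the minimized RMSD in Å.
    """
    P = np.asarray(mobile, dtype=float)
    Q = np.asarray(reference, dtype=float)
    if P.shape != Q.shape:
        raise ValueError(f"point-count mismatch: {P.shape} vs {Q.shape}")
    if P.ndim != 2 or P.shape[1] != 3 or P.shape[0] < 3:
        raise ValueError("superposition needs >= 3 points of dimension 3")
    pc, qc = P.mean(axis=0), Q.mean(axis=0)
    P0, Q0 = P - pc, Q - qc
    # degenerate (collinear) sets leave the rotation underdetermined
    if np.linalg.matrix_rank(P0, tol=1e-8) < 2 or np.linalg.matrix_rank(Q0, tol=1e-8) < 2:
        raise ValueError("degenerate (collinear) point set; superposition undefined")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        rot, rssd = Rotation.align_vectors(Q0, P0)
    R = rot.as_matrix()
    t = qc - R @ pc
    rmsd = float(rssd) / math.sqrt(P.shape[0])
    return SuperposeResult(rotation=R, translation=t, rmsd=rmsd)


def rmsd_ca(
    traj: Trajectory,
    reference_frame: int = 0,
    chains: Iterable[str] | None = None,
    res_seq: Iterable[int] | None = None,
) -> np.ndarray:
    """Per-frame Cα-RMSD (Å) to a reference frame after optimal superposition.

    The value at ``reference_frame`` is exactly 0 by construction.
    """
    sel = traj.topology.select(chains=chains, names=["CA"], res_seq=res_seq)
    if sel.size < 3:
        raise ValueError(
            f"selection resolves to {sel.size} CA atoms; need at least 3"
        )
    if not 0 <= reference_frame < traj.n_frames:
        raise IndexError("reference_frame out of range")
    ref = traj.frames[reference_frame][sel]
    out = np.empty(traj.n_frames)
    for i, frame in enumerate(traj.frames):
        if i == reference_frame:
            out[i] = 0.0
        else:
            out[i] = superpose(frame[sel], ref).rmsd
    return out


# ---------------------------------------------------------------------------
# Solvent-accessible surface area (Shrake–Rupley)
# ---------------------------------------------------------------------------

def sphere_points(n: int) -> np.ndarray:
    """Deterministic golden-section spiral of n unit vectors."""
    k = np.arange(n)
    z = 1.0 - (2.0 * k + 1.0) / n
    phi = k * math.pi * (3.0 - math.sqrt(5.0))
    r = np.sqrt(np.clip(1.0 - z * z, 0.0, None))
    return np.column_stack([r * np.cos(phi), r * np.sin(phi), z])


def sasa(
    structure: Structure,
    probe_radius: float = 1.4,
    n_points: int = 960,
) -> tuple[float, np.ndarray]:
    """Shrake–Rupley SASA: total and per-atom areas in Å².

    Test points are a fixed golden-spiral set, so results are deterministic
    for a given ``n_points``.  A point is accessible when it lies outside
    every other atom's probe-expanded sphere.
    """
    if probe_radius < 0:
        raise ValueError("probe_radius must be >= 0")
    if n_points < 32:
        raise ValueError("n_points must be >= 32")
    centers = structure.coords
    n = len(structure)
    expanded = np.array([a.vdw_radius for a in structure.atoms]) + probe_radius
    unit = sphere_points(n_points)
    tree = cKDTree(centers)
    rmax = expanded.max()
    per_atom = np.empty(n)
    for i in range(n):
        cand = tree.query_ball_point(centers[i], expanded[i] + rmax)
        test = centers[i] + expanded[i] * unit
        accessible = np.ones(n_points, dtype=bool)
        for j in cand:
            if j == i:
                continue
            d = np.linalg.norm(centers[j] - centers[i])
            if d >= expanded[i] + expanded[j]:
                continue
            d2 = np.einsum("ij,ij->i", test - centers[j], test - centers[j])
            accessible &= d2 > expanded[j] ** 2
        per_atom[i] = accessible.mean() * 4.0 * math.pi * expanded[i] ** 2
    return float(per_atom.sum()), per_atom


def buried_sasa(
    complex_structure: Structure,
    part_a: Iterable[str],
    part_b: Iterable[str],
    probe_radius: float = 1.4,
    n_points: int = 960,
) -> float:
    """Interface area buried on complexation: SASA(A) + SASA(B) − SASA(AB), Å².

    ``part_a`` and ``part_b`` are disjoint chain-id sets that together cover
    the complex.  Exactly symmetric under exchange of the two partners.
    """
    part_a, part_b = set(part_a), set(part_b)
    if part_a & part_b:
        raise ValueError(f"overlapping chain sets: {sorted(part_a & part_b)}")
    present = set(complex_structure.chain_ids)
    leftover = present - (part_a | part_b)
    if leftover:
        raise ValueError(
            f"chains {sorted(leftover)} belong to neither partner"
        )
    sub_a = complex_structure.subset(complex_structure.select(chains=part_a))
    sub_b = complex_structure.subset(complex_structure.select(chains=part_b))
    total_ab, _ = sasa(complex_structure, probe_radius, n_points)
    total_a, _ = sasa(sub_a, probe_radius, n_points)
    total_b, _ = sasa(sub_b, probe_radius, n_points)
    return total_a + total_b - total_ab
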