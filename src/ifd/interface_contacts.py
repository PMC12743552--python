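"""Per-frame detection of interdomain hydrogen bonds and salt bridges.

Geometric criteria follow the standard trajectory-analysis definitions used
for the VWF A1/A2 interface: a hydrogen bond requires donor–acceptor
distance < 3.5 Å and an angle < 30°; a salt bridge requires an acidic-
residue oxygen within 4 Å of a basic-residue nitrogen.

Angle convention (important): by default the angle is donor-centered — the
angle between the D→H bond vector and the D→A vector, 0° meaning perfect
alignment.  Set ``HBondCriteria.angle_convention = "h_centered"`` to use the
deviation from linearity at the hydrogen instead (180° − ∠D–H–A).  Both are
common in trajectory tooling; results differ only marginally for near-linear
bonds.

Detections are aggregated at the residue-pair level: any qualifying
atom-level contact marks the residue pair present in that frame.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, NamedTuple

import numpy as np

from .core_structures import Structure

__all__ = [
    "HBondCriteria",
    "SaltBridgeCriteria",
    "InteractionKey",
    "ContactDetail",
    "detect_hbonds",
    "detect_salt_bridges",
    "SIDECHAIN_DONORS",
    "SIDECHAIN_ACCEPTORS",
    "ACIDIC_ATOMS",
    "BASIC_ATOMS",
    "HIS_BASIC_ATOMS",
]

# N/O-based donor/acceptor chemistry.  Backbone N donates (except proline),
# backbone O (and OXT) accepts; sulfur is excluded throughout.
SIDECHAIN_DONORS: frozenset[tuple[str, str]] = frozenset(
    {
        ("SER", "OG"), ("THR", "OG1"), ("TYR", "OH"),
        ("ASN", "ND2"), ("GLN", "NE2"),
        ("LYS", "NZ"),
        ("ARG", "NE"), ("ARG", "NH1"), ("ARG", "NH2"),
        ("HIS", "ND1"), ("HIS", "NE2"),
        ("TRP", "NE1"),
    }
)
SIDECHAIN_ACCEPTORS: frozenset[tuple[str, str]] = frozenset(
    {
        ("ASP", "OD1"), ("ASP", "OD2"),
        ("GLU", "OE1"), ("GLU", "OE2"),
        ("ASN", "OD1"), ("GLN", "OE1"),
        ("SER", "OG"), ("THR", "OG1"), ("TYR", "OH"),
        ("HIS", "ND1"), ("HIS", "NE2"),
    }
)

ACIDIC_ATOMS: dict[str, tuple[str, ...]] = {
    "ASP": ("OD1", "OD2"),
    "GLU": ("OE1", "OE2"),
}
BASIC_ATOMS: dict[str, tuple[str, ...]] = {
    "ARG": ("NE", "NH1", "NH2"),
    "LYS": ("NZ",),
}
HIS_BASIC_ATOMS: tuple[str, ...] = ("ND1", "NE2")

#: Maximum covalent H–donor distance (Å) used to attach hydrogens.
H_ATTACH_CUTOFF = 1.2


@dataclass
class HBondCriteria:
    d_max: float = 3.5
    angle_max: float = 30.0
    require_hydrogen: bool = True
    angle_convention: str = "donor_centered"  # or "h_centered"

    def __post_init__(self) -> None:
        if self.d_max <= 0:
            raise ValueError("d_max must be > 0")
        if not 0 < self.angle_max < 90:
            raise ValueError("angle_max must lie in (0, 90) degrees")
        if self.angle_convention not in ("donor_centered", "h_centered"):
            raise ValueError("unknown angle convention")


@dataclass
class SaltBridgeCriteria:
    d_max: float = 4.0
    include_his: bool = False

    def __post_init__(self) -> None:
        if self.d_max <= 0:
            raise ValueError("d_max must be > 0")

    def basic_atoms(self) -> dict[str, tuple[str, ...]]:
        table = dict(BASIC_ATOMS)
        if self.include_his:
            table["HIS"] = HIS_BASIC_ATOMS
        return table


class InteractionKey(NamedTuple):
    """A residue-pair interaction identity (atom-agnostic).

    ``side_a`` always lies in partner A's chain set, ``side_b`` in partner
    B's; the label follows the field convention, e.g. ``R1334-E1598``.
    """

    kind: str  # "hbond" | "saltbridge"
    chain_a: str
    res_a: int
    resname_a: str
    chain_b: str
    res_b: int
    resname_b: str

    @property
    def label(self) -> str:
        return (
            f"{_ONE_LETTER.get(self.resname_a, 'X')}{self.res_a}-"
            f"{_ONE_LETTER.get(self.resname_b, 'X')}{self.res_b}"
        )

    def swapped(self) -> "InteractionKey":
        return InteractionKey(
            self.kind,
            self.chain_b, self.res_b, self.resname_b,
            self.chain_a, self.res_a, self.resname_a,
        )


_ONE_LETTER = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}


@dataclass
class ContactDetail:
    """Atom-level record behind one detection."""

    key: InteractionKey
    atom_a: str
    atom_b: str
    distance: float
    angle: float | None = None


def _is_donor(res_name: str, atom_name: str) -> bool:
    if atom_name == "N" and res_name != "PRO":
        return True
    return (res_name, atom_name) in SIDECHAIN_DONORS


def _is_acceptor(res_name: str, atom_name: str) -> bool:
    if atom_name in ("O", "OXT"):
        return True
    return (res_name, atom_name) in SIDECHAIN_ACCEPTORS


def attach_hydrogens(topology: Structure) -> dict[int, list[int]]:
    """Map heavy-atom index -> bonded hydrogen indices (same residue,
    within ``H_ATTACH_CUTOFF`` Å in the topology coordinates)."""
    coords = topology.coords
    heavy_by_res: dict[tuple[str, int], list[int]] = {}
    hyd_by_res: dict[tuple[str, int], list[int]] = {}
    for i, a in enumerate(topology.atoms):
        key = (a.chain_id, a.res_seq)
        if a.element == "H":
            hyd_by_res.setdefault(key, []).append(i)
        else:
            heavy_by_res.setdefault(key, []).append(i)
    attached: dict[int, list[int]] = {}
    for res, hyds in hyd_by_res.items():
        heavies = heavy_by_res.get(res, [])
        for h in hyds:
            best, best_d = None, H_ATTACH_CUTOFF
            for j in heavies:
                d = float(np.linalg.norm(coords[h] - coords[j]))
                if d <= best_d:
                    best, best_d = j, d
            if best is not None:
                attached.setdefault(best, []).append(h)
    return attached


def _angle_deg(v1: np.ndarray, v2: np.ndarray) -> float:
    c = float(np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2)))
    return math.degrees(math.acos(max(-1.0, min(1.0, c))))


def _partner_indices(
    topology: Structure, partner_a: Iterable[str], partner_b: Iterable[str]
) -> tuple[set[str], set[str]]:
    a, b = set(partner_a), set(partner_b)
    if a & b:
        raise ValueError(f"partners share chains: {sorted(a & b)}")
    return a, b


def _residue_of(atom) -> tuple[str, int, str]:
    return (atom.chain_id, atom.res_seq, atom.res_name)


def detect_hbonds(
    frame: np.ndarray,
    topology: Structure,
    partner_a: Iterable[str],
    partner_b: Iterable[str],
    criteria: HBondCriteria | None = None,
    return_details: bool = False,
):
    """Cross-partner hydrogen bonds in one frame.

    A bond is reported when the donor–acceptor distance is < ``d_max`` and,
    for some hydrogen covalently attached to the donor, the angle (under the
    configured convention) is < ``angle_max``.  With
    ``require_hydrogen=False`` the angle test is skipped (distance-only
    mode, for hydrogen-free structures).

    Returns a set of residue-pair :class:`InteractionKey` (side_a in partner
    A); with ``return_details=True`` also the atom-level records.
    """
    criteria = criteria or HBondCriteria()
    chains_a, chains_b = _partner_indices(topology, partner_a, partner_b)
    frame = np.asarray(frame, dtype=float)
    atoms = topology.atoms

    attached = attach_hydrogens(topology) if criteria.require_hydrogen else {}
    if criteria.require_hydrogen and not any(
        a.element == "H" for a in atoms
    ):
        raise ValueError(
            "require_hydrogen=True but the topology contains no hydrogens; "
            "use HBondCriteria(require_hydrogen=False) for distance-only "
            "detection on hydrogen-free structures"
        )

    donors = [
        i for i, a in enumerate(atoms)
        if a.element != "H" and _is_donor(a.res_name, a.name)
    ]
    acceptors = [
        i for i, a in enumerate(atoms)
        if a.element != "H" and _is_acceptor(a.res_name, a.name)
    ]

    keys: set[InteractionKey] = set()
    details: list[ContactDetail] = []

    def side_of(chain: str) -> str:
        return "a" if chain in chains_a else ("b" if chain in chains_b else "")

    for d in donors:
        da = atoms[d]
        sd = side_of(da.chain_id)
        if not sd:
            continue
        hyds = attached.get(d, [])
        if criteria.require_hydrogen and not hyds:
            continue
        for acc in acceptors:
            aa = atoms[acc]
            sa = side_of(aa.chain_id)
            if not sa or sa == sd:
                continue
            dist = float(np.linalg.norm(frame[acc] - frame[d]))
            if not dist < criteria.d_max:
                continue
            angle_ok, best_angle = (not criteria.require_hydrogen), None
            for h in hyds:
                if criteria.angle_convention == "donor_centered":
                    ang = _angle_deg(frame[h] - frame[d], frame[acc] - frame[d])
                else:
                    ang = 180.0 - _angle_deg(frame[d] - frame[h], frame[acc] - frame[h])
                if best_angle is None or ang < best_angle:
                    best_angle = ang
                if ang < criteria.angle_max:
                    angle_ok = True
            if not angle_ok:
                continue
            if sd == "a":
                key = InteractionKey("hbond", *_residue_of(da), *_residue_of(aa))
                det = ContactDetail(key, da.name, aa.name, dist, best_angle)
            else:
                key = InteractionKey("hbond", *_residue_of(aa), *_residue_of(da))
                det = ContactDetail(key, aa.name, da.name, dist, best_angle)
            keys.add(key)
            details.append(det)

    if return_details:
        return keys, details
    return keys


def detect_salt_bridges(
    frame: np.ndarray,
    topology: Structure,
    partner_a: Iterable[str],
    partner_b: Iterable[str],
    criteria: SaltBridgeCriteria | None = None,
    return_details: bool = False,
):
    """Cross-partner salt bridges in one frame.

    A bridge is reported per residue pair when the minimum distance over the
    acidic-oxygen × basic-nitrogen atom pairs is < ``d_max``.
    """
    criteria = criteria or SaltBridgeCriteria()
    chains_a, chains_b = _partner_indices(topology, partner_a, partner_b)
    frame = np.asarray(frame, dtype=float)
    atoms = topology.atoms
    basic_table = criteria.basic_atoms()

    acidic = [
        i for i, a in enumerate(atoms)
        if a.name in ACIDIC_ATOMS.get(a.res_name, ())
    ]
    basic = [
        i for i, a in enumerate(atoms)
        if a.name in basic_table.get(a.res_name, ())
    ]

    best: dict[InteractionKey, ContactDetail] = {}
    for i in acidic:
        ai = atoms[i]
        for j in basic:
            aj = atoms[j]
            if ai.chain_id in chains_a and aj.chain_id in chains_b:
                key = InteractionKey("saltbridge", *_residue_of(ai), *_residue_of(aj))
                name_a, name_b = ai.name, aj.name
            elif ai.chain_id in chains_b and aj.chain_id in chains_a:
                key = InteractionKey("saltbridge", *_residue_of(aj), *_residue_of(ai))
                name_a, name_b = aj.name, ai.name
            else:
                continue
            dist = float(np.linalg.norm(frame[j] - frame[i]))
            if not dist < criteria.d_max:
                continue
            if key not in best or dist < best[key].distance:
                best[key] = ContactDetail(key, name_a, name_b, dist)

    if return_details:
        return set(best), list(best.values())
    return set(best)
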