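"""Occlusion-based screening of docked A1/A2 poses.

The biological screen: in the autoinhibited conformation of von Willebrand
factor, the A2 domain must shield the GPIbα-binding site on A1.  Candidate
docked A1/A2 poses are therefore judged by how completely the A2 "blocker"
covers the footprint that GPIbα leaves on A1 in a reference A1/GPIbα
complex.  The qualitative visual screen is operationalized here as a
covered-fraction statistic: superpose the pose's receptor onto the
reference receptor, transform the blocker, and count the fraction of
footprint residues with a heavy atom within the contact cutoff of the
blocker.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .core_structures import Structure, read_structure, superpose

__all__ = [
    "ReferenceComplex",
    "CandidatePose",
    "OcclusionReport",
    "binding_footprint",
    "occlusion_score",
    "rank_poses",
    "load_poses",
]


@dataclass
class ReferenceComplex:
    """A receptor/ligand complex defining the footprint to occlude."""

    structure: Structure
    receptor_chains: set[str]
    ligand_chains: set[str]

    def __post_init__(self) -> None:
        self.receptor_chains = set(self.receptor_chains)
        self.ligand_chains = set(self.ligand_chains)
        if not self.receptor_chains or not self.ligand_chains:
            raise ValueError("receptor and ligand chain sets must be non-empty")
        if self.receptor_chains & self.ligand_chains:
            raise ValueError("receptor and ligand chains overlap")


@dataclass
class CandidatePose:
    """A docked receptor/blocker pose, optionally with an external docking
    score (lower is more favorable)."""

    structure: Structure
    receptor_chains: set[str]
    blocker_chains: set[str]
    external_score: float | None = None
    name: str = ""

    def __post_init__(self) -> None:
        self.receptor_chains = set(self.receptor_chains)
        self.blocker_chains = set(self.blocker_chains)
        if self.receptor_chains & self.blocker_chains:
            raise ValueError("receptor and blocker chains overlap")


@dataclass
class OcclusionReport:
    footprint_residues: set[tuple[str, int]]
    covered_residues: set[tuple[str, int]]
    covered_fraction: float
    min_blocker_distance: float


def _heavy_indices(structure: Structure, chains: Iterable[str]) -> np.ndarray:
    idx = structure.select(chains=chains)
    return np.array([i for i in idx if structure.atoms[i].element != "H"], dtype=int)


def binding_footprint(
    ref: ReferenceComplex, contact_cutoff: float = 4.5
) -> set[tuple[str, int]]:
    """Receptor residues with any heavy atom within ``contact_cutoff`` Å of
    any ligand heavy atom: the ligand's binding footprint."""
    rec = _heavy_indices(ref.structure, ref.receptor_chains)
    lig = _heavy_indices(ref.structure, ref.ligand_chains)
    coords = ref.structure.coords
    tree = cKDTree(coords[lig])
    dists, _ = tree.query(coords[rec], k=1)
    footprint = {
        (ref.structure.atoms[i].chain_id, ref.structure.atoms[i].res_seq)
        for i, d in zip(rec, dists)
        if d < contact_cutoff
    }
    if not footprint:
        warnings.warn(
            f"empty binding footprint at cutoff {contact_cutoff} Å; "
            "the ligand may be too far from the receptor",
            stacklevel=2,
        )
    return footprint


def occlusion_score(
    pose: CandidatePose,
    ref: ReferenceComplex,
    contact_cutoff: float = 4.5,
) -> OcclusionReport:
    """Fraction of the reference footprint covered by the pose's blocker.

    The pose receptor is superposed onto the reference receptor over CA
    atoms shared by author residue number, the transform is applied to the
    blocker, and a footprint residue counts as covered when any of its
    heavy atoms lies within ``contact_cutoff`` Å of a transformed blocker
    heavy atom.
    """
    ref_ca = {
        ref.structure.atoms[i].res_seq: i
        for i in ref.structure.ca_indices(chains=ref.receptor_chains)
    }
    pose_ca = {
        pose.structure.atoms[i].res_seq: i
        for i in pose.structure.ca_indices(chains=pose.receptor_chains)
    }
    shared = sorted(set(ref_ca) & set(pose_ca))
    if len(shared) < 3:
        raise ValueError(
            f"only {len(shared)} shared receptor CA atoms; need >= 3"
        )
    ref_coords = ref.structure.coords
    pose_coords = pose.structure.coords
    fit = superpose(
        pose_coords[[pose_ca[r] for r in shared]],
        ref_coords[[ref_ca[r] for r in shared]],
    )
    blocker = fit.apply(pose_coords[_heavy_indices(pose.structure, pose.blocker_chains)])

    footprint = binding_footprint(ref, contact_cutoff)
    if not footprint:
        return OcclusionReport(set(), set(), 0.0, float("inf"))
    tree = cKDTree(blocker)
    covered: set[tuple[str, int]] = set()
    min_d = float("inf")
    rec_heavy = _heavy_indices(ref.structure, ref.receptor_chains)
    for i in rec_heavy:
        a = ref.structure.atoms[i]
        key = (a.chain_id, a.res_seq)
        if key not in footprint:
            continue
        d, _ = tree.query(ref_coords[i], k=1)
        min_d = min(min_d, float(d))
        if d < contact_cutoff:
            covered.add(key)
    return OcclusionReport(
        footprint_residues=footprint,
        covered_residues=covered,
        covered_fraction=len(covered) / len(footprint),
        min_blocker_distance=min_d,
    )


def rank_poses(
    poses: Sequence[CandidatePose],
    ref: ReferenceComplex,
    contact_cutoff: float = 4.5,
    min_covered: float = 0.5,
) -> pd.DataFrame:
    """Score and rank candidate poses by the occlusion criterion.

    Poses with covered fraction below ``min_covered`` are excluded.
    Survivors are sorted by external docking score ascending when present,
    otherwise by covered fraction descending; ties resolve by pose name.
    Returns a DataFrame (pose, covered_fraction, min_blocker_distance_A,
    external_score, rank).
    """
    if not poses:
        raise ValueError("at least one pose required")
    records = []
    for k, pose in enumerate(poses):
        rep = occlusion_score(pose, ref, contact_cutoff)
        records.append(
            {
                "pose": pose.name or f"pose_{k}",
                "covered_fraction": rep.covered_fraction,
                "min_blocker_distance_A": rep.min_blocker_distance,
                "external_score": pose.external_score,
            }
        )
    df = pd.DataFrame.from_records(records)
    df = df[df["covered_fraction"] >= min_covered].copy()
    if df.empty:
        warnings.warn("all poses fail the occlusion criterion", stacklevel=2)
        df["rank"] = pd.Series(dtype=int)
        return df
    has_score = df["external_score"].notna()
    scores = pd.to_numeric(df["external_score"], errors="coerce").fillna(0.0)
    df["_primary"] = np.where(has_score, 0, 1)
    df["_secondary"] = np.where(has_score, scores, -df["covered_fraction"])
    df = df.sort_values(["_primary", "_secondary", "pose"], kind="stable")
    df = df.drop(columns=["_primary", "_secondary"]).reset_index(drop=True)
    df["rank"] = np.arange(1, len(df) + 1)
    return df


def load_poses(
    pose_dir: str | Path,
    receptor_chains: Iterable[str],
    blocker_chains: Iterable[str],
    scores_csv: str | Path | None = None,
) -> list[CandidatePose]:
    """Load a directory of pose PDBs plus an optional docking-score table
    (CSV with columns pose_id, score; pose_id matches the file stem)."""
    pose_dir = Path(pose_dir)
    scores: dict[str, float] = {}
    if scores_csv is not None:
        df = pd.read_csv(scores_csv)
        scores = dict(zip(df["pose_id"].astype(str), df["score"].astype(float)))
    poses = []
    for path in sorted(pose_dir.glob("*.pdb")):
        poses.append(
            CandidatePose(
                structure=read_structure(path),
                receptor_chains=set(receptor_chains),
                blocker_chains=set(blocker_chains),
                external_score=scores.get(path.stem),
                name=path.stem,
            )
        )
    if not poses:
        raise FileNotFoundError(f"no .pdb files in {pose_dir}")
    return poses
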