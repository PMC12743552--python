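"""Seed-deterministic generators for every input class of the pipeline.

Real inputs to this kind of interface study — equilibrium/steered MD
trajectories, BLI sensorgrams, AFM contact cycles — are large or
instrument-bound.  These generators produce small stand-ins with *known
ground truth*: toy two-chain complexes with planted hydrogen bonds and
salt bridges at requested geometries, multi-frame trajectories whose
interface contacts follow planted per-frame occupancy laws (Bernoulli or
two-state Markov), spring-model pulling curves with a planted rupture and
dissociation, 1:1 Langmuir sensorgram sets, and Bernoulli-adhesion AFM
cycle sets.

Every generator returns a machine-readable truth manifest alongside the
data, and identical seeds give bit-identical output.  The occupancy
patterns are statistical stand-ins — no physical dynamics is integrated —
so downstream recovery tests demonstrate estimator correctness, not force-
field realism.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from . import presets
from .binding_kinetics import Sensorgram, simulate_sensorgram
from .core_structures import VDW_RADII, Atom, Structure, Trajectory
from .force_spectroscopy import AfmCycleSet, ForceCurve
from .interface_contacts import InteractionKey

import pandas as pd

__all__ = [
    "make_toy_complex",
    "make_random_toy_complex",
    "manifest_keys",
    "make_trajectory",
    "make_smd_curve",
    "make_sensorgram_set",
    "make_afm_cycles",
]

#: Displacement (Å) of a contact's acceptor-side group in the broken state;
#: safely beyond every default cutoff.
OFF_DISPLACEMENT_A = 6.0
_MIN_SEPARATION_A = 0.8


def _rotation_about_z(angle_deg: float) -> np.ndarray:
    a = math.radians(angle_deg)
    return np.array(
        [[math.cos(a), -math.sin(a), 0.0], [math.sin(a), math.cos(a), 0.0], [0.0, 0.0, 1.0]]
    )


def _atom(serial, name, element, res_name, res_seq, chain, xyz) -> Atom:
    return Atom(
        serial=serial,
        name=name,
        element=element,
        res_name=res_name,
        res_seq=res_seq,
        chain_id=chain,
        coords=np.asarray(xyz, dtype=float),
        vdw_radius=VDW_RADII[element],
    )


def make_toy_complex(
    hbond_geometries: Sequence[tuple[float, float]] = ((2.9, 10.0),),
    salt_bridge_distances: Sequence[float] = (3.5,),
    spacing: float = 20.0,
    orientations_deg: Sequence[float] | None = None,
) -> tuple[Structure, list[dict]]:
    """Build a two-chain complex with planted cross-chain interactions.

    Each hydrogen-bond site is a serine hydroxyl donor (chain A: OG with
    its HG hydrogen) facing a glutamine side-chain oxygen acceptor (chain
    B: OE1) placed at the requested donor–acceptor ``(distance, angle)``;
    the angle is donor-centered relative to the O–H bond.  Each salt-bridge
    site is an aspartate OD1 (chain A) facing an arginine NH1 (chain B) at
    the requested distance.  Sites are spaced ``spacing`` Å apart along x
    so they cannot cross-talk at the default cutoffs.

    Returns the structure and a manifest: one record per planted site with
    its geometry and whether it satisfies the default criteria.
    """
    atoms_a: list[Atom] = []
    atoms_b: list[Atom] = []
    manifest: list[dict] = []
    serial = 1
    site = 0
    n_sites = len(hbond_geometries) + len(salt_bridge_distances)
    if orientations_deg is None:
        orientations_deg = [0.0] * n_sites

    for i, (dist, angle) in enumerate(hbond_geometries):
        origin = np.array([site * spacing, 0.0, 0.0])
        rot = _rotation_about_z(orientations_deg[site])
        donor = origin
        hydrogen = origin + rot @ np.array([1.0, 0.0, 0.0])
        acc_dir = _rotation_about_z(angle) @ np.array([1.0, 0.0, 0.0])
        acceptor = origin + rot @ (dist * acc_dir)
        res_a, res_b = 100 + i, 300 + i
        atoms_a += [
            _atom(serial, "CA", "C", "SER", res_a, "A", donor + rot @ [-1.5, -1.5, 0.0]),
            _atom(serial + 1, "OG", "O", "SER", res_a, "A", donor),
            _atom(serial + 2, "HG", "H", "SER", res_a, "A", hydrogen),
        ]
        atoms_b += [
            _atom(serial + 3, "CA", "C", "GLN", res_b, "B", acceptor + rot @ [1.5, 1.5, 0.0]),
            _atom(serial + 4, "OE1", "O", "GLN", res_b, "B", acceptor),
        ]
        serial += 5
        manifest.append(
            {
                "site": site,
                "kind": "hbond",
                "chain_a": "A", "res_a": res_a, "resname_a": "SER",
                "chain_b": "B", "res_b": res_b, "resname_b": "GLN",
                "distance_A": float(dist),
                "angle_deg": float(angle),
                "qualifies": bool(dist < 3.5 and angle < 30.0),
                "moving_atoms": ["OE1"],
            }
        )
        site += 1

    for j, dist in enumerate(salt_bridge_distances):
        origin = np.array([site * spacing, 0.0, 0.0])
        rot = _rotation_about_z(orientations_deg[site])
        acid = origin
        base = origin + rot @ np.array([dist, 0.0, 0.0])
        res_a, res_b = 200 + j, 400 + j
        atoms_a += [
            _atom(serial, "CA", "C", "ASP", res_a, "A", acid + rot @ [-1.5, 1.5, 0.0]),
            _atom(serial + 1, "OD1", "O", "ASP", res_a, "A", acid),
        ]
        atoms_b += [
            _atom(serial + 2, "CA", "C", "ARG", res_b, "B", base + rot @ [1.5, -1.5, 0.0]),
            _atom(serial + 3, "NH1", "N", "ARG", res_b, "B", base),
        ]
        serial += 4
        manifest.append(
            {
                "site": site,
                "kind": "saltbridge",
                "chain_a": "A", "res_a": res_a, "resname_a": "ASP",
                "chain_b": "B", "res_b": res_b, "resname_b": "ARG",
                "distance_A": float(dist),
                "angle_deg": None,
                "qualifies": bool(dist < 4.0),
                "moving_atoms": ["NH1"],
            }
        )
        site += 1

    atoms = atoms_a + atoms_b  # chain-grouped, matching PDB reader ordering
    if not atoms:
        # two inert chains so that "zero planted pairs" is still a complex
        atoms = [
            _atom(1, "CA", "C", "GLY", 1, "A", [0.0, 0.0, 0.0]),
            _atom(2, "CA", "C", "GLY", 2, "B", [50.0, 0.0, 0.0]),
        ]
    structure = Structure(atoms)
    coords = structure.coords
    from scipy.spatial.distance import pdist

    if len(atoms) > 1 and pdist(coords).min() < _MIN_SEPARATION_A:
        raise ValueError(
            f"infeasible geometry: atoms closer than {_MIN_SEPARATION_A} Å"
        )
    return structure, manifest


def make_random_toy_complex(
    seed: int,
    max_hbond_sites: int = 3,
    max_salt_bridge_sites: int = 2,
) -> tuple[Structure, list[dict]]:
    """A randomized toy complex for oracle testing: random site counts,
    donor–acceptor distances spanning both sides of the cutoffs, angles in
    [0°, 60°], and random in-plane orientations."""
    rng = np.random.default_rng(seed)
    n_hb = int(rng.integers(1, max_hbond_sites + 1))
    n_sb = int(rng.integers(0, max_salt_bridge_sites + 1))
    hb = [
        (float(rng.uniform(2.5, 4.5)), float(rng.uniform(0.0, 60.0)))
        for _ in range(n_hb)
    ]
    sb = [float(rng.uniform(2.8, 5.2)) for _ in range(n_sb)]
    orient = [float(rng.uniform(0.0, 360.0)) for _ in range(n_hb + n_sb)]
    return make_toy_complex(hb, sb, orientations_deg=orient)


def manifest_keys(manifest: Sequence[dict], qualifying_only: bool = True) -> list[InteractionKey]:
    """InteractionKeys expected from a toy-complex manifest."""
    keys = []
    for rec in manifest:
        if qualifying_only and not rec["qualifies"]:
            continue
        keys.append(
            InteractionKey(
                rec["kind"],
                rec["chain_a"], rec["res_a"], rec["resname_a"],
                rec["chain_b"], rec["res_b"], rec["resname_b"],
            )
        )
    return keys


def _site_states(
    spec, n_frames: int, rng: np.random.Generator
) -> np.ndarray:
    """Per-frame on/off states: Bernoulli(p) for a float spec, stationary
    two-state Markov for a (p_on, p_off) pair."""
    if isinstance(spec, (tuple, list)):
        p_on, p_off = float(spec[0]), float(spec[1])
        if not (0 <= p_on <= 1 and 0 <= p_off <= 1):
            raise ValueError("Markov rates must lie in [0, 1]")
        states = np.empty(n_frames, dtype=bool)
        stationary = p_on / (p_on + p_off) if (p_on + p_off) > 0 else 0.0
        states[0] = rng.random() < stationary
        for f in range(1, n_frames):
            if states[f - 1]:
                states[f] = rng.random() >= p_off
            else:
                states[f] = rng.random() < p_on
        return states
    p = float(spec)
    if not 0 <= p <= 1:
        raise ValueError("Bernoulli p must lie in [0, 1]")
    return rng.random(n_frames) < p


def make_trajectory(
    topology: Structure,
    manifest: Sequence[dict],
    occupancy: Mapping[int, object],
    n_frames: int,
    seed: int,
    frame_interval_ns: float = 0.1,
) -> tuple[Trajectory, np.ndarray, list[InteractionKey]]:
    """Animate a toy complex so each planted site follows a planted
    occupancy law.

    ``occupancy`` maps manifest site indices to either a Bernoulli
    probability (float) or a two-state Markov ``(p_on, p_off)`` pair.  In
    "off" frames the site's chain-B group is displaced 6 Å along the pair
    axis, beyond every default cutoff; sites not listed stay in their base
    geometry.  Returns the trajectory, the truth presence matrix
    (sites × frames, ordered like ``sorted(occupancy)``), and the matching
    interaction keys.
    """
    if n_frames < 1:
        raise ValueError("n_frames must be >= 1")
    rng = np.random.default_rng(seed)
    base = topology.coords
    site_ids = sorted(occupancy)
    by_site = {rec["site"]: rec for rec in manifest}
    moves = []
    for s in site_ids:
        rec = by_site[s]
        group = topology.select(
            chains=[rec["chain_b"]], res_seq=[rec["res_b"]]
        )
        # displace the whole chain-B side group (tip atoms + CA follow)
        donor_like = topology.select(chains=[rec["chain_a"]], res_seq=[rec["res_a"]])
        axis = base[group].mean(axis=0) - base[donor_like].mean(axis=0)
        axis = axis / np.linalg.norm(axis)
        moves.append((group, OFF_DISPLACEMENT_A * axis))

    truth = np.empty((len(site_ids), n_frames), dtype=bool)
    for row, s in enumerate(site_ids):
        truth[row] = _site_states(occupancy[s], n_frames, rng)

    frames = []
    for f in range(n_frames):
        coords = base.copy()
        for row, (group, shift) in enumerate(moves):
            if not truth[row, f]:
                coords[group] += shift
        frames.append(coords)
    keys = manifest_keys([by_site[s] for s in site_ids], qualifying_only=False)
    return Trajectory(topology, frames, frame_interval_ns), truth, keys


def make_smd_curve(
    rupture_force_pN: float = presets.SMD_RUPTURE_FORCE_PN["wt"][0],
    rupture_time_ns: float = 20.0,
    dissociation_time_ns: float = presets.SMD_DISSOCIATION_TIME_NS["wt"][0],
    spring_k_pN_per_A: float = presets.SMD_SPRING_K_PN_PER_A,
    pull_velocity_A_per_ns: float = presets.SMD_PULL_VELOCITY_A_PER_NS,
    duration_ns: float = presets.SMD_DURATION_NS,
    dt_ns: float = 0.01,
    noise_sd_pN: float = 0.0,
    n_hbonds_initial: int = 7,
    buried_sasa_initial_A2: float = 900.0,
    collapse_tau_ns: float = 0.25,
    seed: int = 0,
) -> tuple[ForceCurve, dict]:
    """A pulling force curve with a planted rupture peak and dissociation.

    The force ramps linearly to the planted peak (the spring extension
    resists the cantilever motion), then collapses exponentially after
    rupture; hydrogen-bond count and buried SASA decay to exactly zero at
    the planted dissociation time and stay there.  Planted times are
    snapped to the time grid and the snapped values are reported as truth.
    """
    if noise_sd_pN < 0:
        raise ValueError("noise_sd_pN must be >= 0")
    if not 0 < rupture_time_ns <= dissociation_time_ns <= duration_ns:
        raise ValueError("need 0 < rupture <= dissociation <= duration")
    t = np.arange(0.0, duration_ns + dt_ns / 2, dt_ns)
    i_rup = int(round(rupture_time_ns / dt_ns))
    i_diss = int(round(dissociation_time_ns / dt_ns))
    t_rup, t_diss = t[i_rup], t[i_diss]

    force = np.where(
        t <= t_rup,
        rupture_force_pN * t / t_rup,
        rupture_force_pN * np.exp(-(t - t_rup) / collapse_tau_ns),
    )
    rng = np.random.default_rng(seed)
    if noise_sd_pN > 0:
        force = force + rng.normal(0.0, noise_sd_pN, size=t.shape)

    frac_left = np.clip(1.0 - t / t_diss, 0.0, None)
    hbonds = np.ceil(n_hbonds_initial * frac_left).astype(int)
    sasa = buried_sasa_initial_A2 * frac_left

    curve = ForceCurve(
        time_ns=t,
        force_pN=force,
        hbond_count=hbonds,
        buried_sasa_A2=sasa,
        pull_velocity_A_per_ns=pull_velocity_A_per_ns,
        spring_k_pN_per_A=spring_k_pN_per_A,
    )
    truth = {
        "rupture_force_pN": float(rupture_force_pN),
        "rupture_time_ns": float(t_rup),
        "dissociation_time_ns": float(t_diss),
        "noise_sd_pN": float(noise_sd_pN),
        "seed": int(seed),
    }
    return curve, truth


def make_sensorgram_set(
    kon: float = presets.KINETIC_TRIPLES["wt"]["kon"],
    koff: float = presets.KINETIC_TRIPLES["wt"]["koff"],
    rmax_nm: float = 1.0,
    concentrations_M: Sequence[float] = presets.BLI_CONCENTRATIONS_M,
    t_assoc_s: float = presets.BLI_T_ASSOC_S,
    t_dissoc_s: float = presets.BLI_T_DISSOC_S,
    dt_s: float = 0.2,
    noise_sd_nm: float = 0.0,
    seed: int = 0,
) -> tuple[list[Sensorgram], dict]:
    """Sensorgrams at serial analyte dilutions following 1:1 Langmuir
    kinetics, with a manifest of the generating parameters."""
    if len(set(concentrations_M)) != len(concentrations_M):
        raise ValueError("duplicate concentrations")
    rng = np.random.default_rng(seed)
    curves = [
        simulate_sensorgram(
            kon, koff, rmax_nm, c, t_assoc_s, t_dissoc_s, dt_s, noise_sd_nm, rng
        )
        for c in concentrations_M
    ]
    truth = {
        "kon_per_M_per_s": float(kon),
        "koff_per_s": float(koff),
        "KD_M": float(koff / kon),
        "Rmax_nm": float(rmax_nm),
        "concentrations_M": [float(c) for c in concentrations_M],
        "t_assoc_s": float(t_assoc_s),
        "t_dissoc_s": float(t_dissoc_s),
        "noise_sd_nm": float(noise_sd_nm),
        "seed": int(seed),
    }
    return curves, truth


def make_afm_cycles(
    p_adhesion: float | Sequence[float] = presets.AFM_ADHESION_FREQUENCY_PCT["wt"] / 100.0,
    force_mu_pN: float = presets.AFM_MEAN_RUPTURE_FORCE_PN["wt"],
    force_sd_pN: float = presets.AFM_FORCE_SD_PN,
    n_substrates: int = presets.AFM_N_SUBSTRATES,
    points_per_substrate: int = presets.AFM_POINTS_PER_SUBSTRATE,
    cycles_per_point: int = presets.AFM_CYCLES_PER_POINT,
    seed: int = 0,
) -> tuple[AfmCycleSet, dict]:
    """AFM contact cycles with Bernoulli adhesion and Gaussian rupture
    forces (drawn only for adhered cycles).

    ``p_adhesion`` may be a scalar or one probability per substrate.
    """
    if np.isscalar(p_adhesion):
        p_by_sub = [float(p_adhesion)] * n_substrates
    else:
        p_by_sub = [float(p) for p in p_adhesion]
        if len(p_by_sub) != n_substrates:
            raise ValueError("one adhesion probability per substrate required")
    for p in p_by_sub:
        if not 0.0 <= p <= 1.0:
            raise ValueError("adhesion probability must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    rows = []
    for s in range(n_substrates):
        for pt in range(points_per_substrate):
            adhered = rng.random(cycles_per_point) < p_by_sub[s]
            forces = np.where(
                adhered, rng.normal(force_mu_pN, force_sd_pN, cycles_per_point), np.nan
            )
            for c in range(cycles_per_point):
                rows.append(
                    {
                        "substrate_id": s + 1,
                        "point_id": pt + 1,
                        "cycle_id": c + 1,
                        "adhered": bool(adhered[c]),
                        "rupture_force_pN": float(forces[c]) if adhered[c] else np.nan,
                    }
                )
    cycles = AfmCycleSet(pd.DataFrame(rows))
    truth = {
        "p_adhesion_by_substrate": p_by_sub,
        "force_mu_pN": float(force_mu_pN),
        "force_sd_pN": float(force_sd_pN),
        "n_substrates": int(n_substrates),
        "points_per_substrate": int(points_per_substrate),
        "cycles_per_point": int(cycles_per_point),
        "seed": int(seed),
    }
    return cycles, truth
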