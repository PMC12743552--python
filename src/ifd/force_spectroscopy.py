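"""Pulling-curve and AFM adhesion analysis.

Two experiment classes share this module:

* Constant-velocity steered pulling (force-ramp): a virtual spring of
  stiffness ``k`` (pN/Å) moves at velocity ``v`` (Å/ns); the instantaneous
  force is ``F = k (v t − x)`` with ``x`` the pulled atom's displacement
  along the pulling axis.  From a force–time trace annotated with interface
  hydrogen-bond counts and buried SASA, the dissociation time is the first
  instant from which both stay at zero, and the rupture force is the force
  peak before it.

* AFM contact-cycle force spectroscopy: repeated approach–retract cycles
  with Bernoulli adhesion; adhesion frequency is the fraction of cycles
  showing a specific unbinding event, aggregated per substrate (mean ± SEM
  across substrates), and rupture forces are pooled and Gaussian-fitted to
  report the most probable rupture force Xc.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .occupancy_stats import GaussianFit, fit_gaussian

__all__ = [
    "ForceCurve",
    "PullingResult",
    "AfmCycleSet",
    "AdhesionSummary",
    "RuptureDistribution",
    "spring_force",
    "dissociation_time",
    "rupture_force",
    "adhesion_frequency",
    "rupture_distribution",
]


@dataclass
class ForceCurve:
    """A force–time trace, optionally annotated with interface contacts."""

    time_ns: np.ndarray
    force_pN: np.ndarray
    hbond_count: np.ndarray | None = None
    buried_sasa_A2: np.ndarray | None = None
    pull_velocity_A_per_ns: float | None = None
    spring_k_pN_per_A: float | None = None

    def __post_init__(self) -> None:
        self.time_ns = np.asarray(self.time_ns, dtype=float)
        self.force_pN = np.asarray(self.force_pN, dtype=float)
        if self.time_ns.shape != self.force_pN.shape:
            raise ValueError("time and force series must have equal length")
        if self.time_ns.size < 1:
            raise ValueError("empty force curve")
        if np.any(np.diff(self.time_ns) <= 0):
            raise ValueError("time must be strictly increasing")
        for attr in ("hbond_count", "buried_sasa_A2"):
            v = getattr(self, attr)
            if v is not None:
                v = np.asarray(v, dtype=float)
                if v.shape != self.time_ns.shape:
                    raise ValueError(f"{attr} length mismatch")
                setattr(self, attr, v)

    def to_csv(self, path: str | Path) -> None:
        cols = {"time_ns": self.time_ns, "force_pN": self.force_pN}
        if self.hbond_count is not None:
            cols["hbond_count"] = self.hbond_count.astype(int)
        if self.buried_sasa_A2 is not None:
            cols["buried_sasa_A2"] = self.buried_sasa_A2
        pd.DataFrame(cols).to_csv(path, index=False)

    @classmethod
    def from_csv(
        cls,
        path: str | Path,
        pull_velocity_A_per_ns: float | None = None,
        spring_k_pN_per_A: float | None = None,
    ) -> "ForceCurve":
        df = pd.read_csv(path)
        return cls(
            time_ns=df["time_ns"].to_numpy(),
            force_pN=df["force_pN"].to_numpy(),
            hbond_count=df["hbond_count"].to_numpy() if "hbond_count" in df else None,
            buried_sasa_A2=df["buried_sasa_A2"].to_numpy() if "buried_sasa_A2" in df else None,
            pull_velocity_A_per_ns=pull_velocity_A_per_ns,
            spring_k_pN_per_A=spring_k_pN_per_A,
        )


@dataclass
class PullingResult:
    rupture_force_pN: float
    rupture_time_ns: float
    dissociation_time_ns: float | None

    def __post_init__(self) -> None:
        if (
            self.dissociation_time_ns is not None
            and self.rupture_time_ns > self.dissociation_time_ns
        ):
            raise ValueError("rupture cannot follow dissociation")


def spring_force(t_ns: float, x_steered_A: float, v_A_per_ns: float, k_pN_per_A: float) -> float:
    """Virtual-spring force F = k (v t − x), pN.

    ``x_steered_A`` is the pulled atom's displacement projected on the
    pulling axis.  With the reference setup k = 69.48 pN/Å and v = 5 Å/ns.
    """
    if k_pN_per_A <= 0 or v_A_per_ns <= 0:
        raise ValueError("spring constant and velocity must be positive")
    return k_pN_per_A * (v_A_per_ns * t_ns - x_steered_A)


def dissociation_time(curve: ForceCurve, sasa_eps: float = 1.0) -> float | None:
    """Earliest time from which hbond_count == 0 and buried SASA < eps hold
    through the end of the trace (sustained-zero rule).

    Returns None when the contacts never vanish for good.
    """
    if curve.hbond_count is None or curve.buried_sasa_A2 is None:
        raise ValueError("curve lacks hbond_count/buried_sasa annotations")
    gone = (curve.hbond_count == 0) & (curve.buried_sasa_A2 < sasa_eps)
    if not gone[-1]:
        return None
    # last index where contact still present, +1 = first sustained-zero index
    alive = np.nonzero(~gone)[0]
    first = alive[-1] + 1 if alive.size else 0
    return float(curve.time_ns[first])


def rupture_force(curve: ForceCurve, smooth_window: int = 1) -> PullingResult:
    """Peak force before dissociation.

    The force may be smoothed with a centered moving average of
    ``smooth_window`` samples (default 1 = raw trace).  When the curve
    carries contact annotations the peak search is restricted to times up
    to the dissociation time; ties take the earliest sample.
    """
    if curve.time_ns.size < 2:
        raise ValueError("need at least 2 samples")
    if smooth_window < 1:
        raise ValueError("smooth_window must be >= 1")
    force = curve.force_pN
    if smooth_window > 1:
        kernel = np.ones(smooth_window) / smooth_window
        force = np.convolve(force, kernel, mode="same")
    t_diss = None
    if curve.hbond_count is not None and curve.buried_sasa_A2 is not None:
        t_diss = dissociation_time(curve)
    if t_diss is not None:
        mask = curve.time_ns <= t_diss
        if not mask.any():
            raise ValueError("empty search window before dissociation")
    else:
        mask = np.ones_like(curve.time_ns, dtype=bool)
    idx = np.nonzero(mask)[0]
    peak = idx[np.argmax(force[idx])]  # argmax returns the first maximum
    return PullingResult(
        rupture_force_pN=float(force[peak]),
        rupture_time_ns=float(curve.time_ns[peak]),
        dissociation_time_ns=t_diss,
    )


@dataclass
class AfmCycleSet:
    """AFM contact cycles: substrate_id, point_id, cycle_id, adhered,
    rupture_force_pN (present iff adhered)."""

    cycles: pd.DataFrame

    REQUIRED = ("substrate_id", "point_id", "cycle_id", "adhered")

    def __post_init__(self) -> None:
        for col in self.REQUIRED:
            if col not in self.cycles.columns:
                raise ValueError(f"missing column {col!r}")
        if "rupture_force_pN" not in self.cycles.columns:
            self.cycles = self.cycles.assign(rupture_force_pN=np.nan)
        adhered = self.cycles["adhered"].astype(bool)
        has_force = self.cycles["rupture_force_pN"].notna()
        if not (adhered == has_force).all():
            raise ValueError("rupture_force_pN must be present iff adhered")

    def __len__(self) -> int:
        return len(self.cycles)

    def to_csv(self, path: str | Path) -> None:
        out = self.cycles.copy()
        out["adhered"] = out["adhered"].astype(int)
        out.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "AfmCycleSet":
        df = pd.read_csv(path)
        df["adhered"] = df["adhered"].astype(bool)
        return cls(df)


@dataclass
class AdhesionSummary:
    per_substrate_pct: pd.Series
    mean_pct: float
    sem_pct: float
    rupture_forces_pN: np.ndarray
    mean_rupture_force_pN: float
    n_cycles: int


def adhesion_frequency(cycles: AfmCycleSet) -> AdhesionSummary:
    """Adhesion frequency per substrate (events/cycles pooled over its
    points, %) with mean ± SEM across substrates (n−1 rule)."""
    df = cycles.cycles
    if len(df) == 0:
        raise ValueError("no cycles")
    grouped = df.groupby("substrate_id")["adhered"]
    per_sub = 100.0 * grouped.mean()
    n_sub = len(per_sub)
    sem = float(per_sub.std(ddof=1) / np.sqrt(n_sub)) if n_sub > 1 else float("nan")
    forces = df.loc[df["adhered"].astype(bool), "rupture_force_pN"].to_numpy(float)
    return AdhesionSummary(
        per_substrate_pct=per_sub,
        mean_pct=float(per_sub.mean()),
        sem_pct=sem,
        rupture_forces_pN=forces,
        mean_rupture_force_pN=float(forces.mean()) if forces.size else float("nan"),
        n_cycles=len(df),
    )


@dataclass
class RuptureDistribution:
    bin_centers_pN: np.ndarray
    frequencies: np.ndarray
    fit: GaussianFit | None
    mean_force_pN: float
    degenerate: bool = False

    @property
    def xc_pN(self) -> float:
        """Most probable rupture force (Gaussian center)."""
        if self.fit is None:
            return self.mean_force_pN
        return self.fit.mu


def rupture_distribution(cycles: AfmCycleSet, bin_width_pN: float = 5.0) -> RuptureDistribution:
    """Pooled rupture-force histogram with a Gaussian fit (Xc = fitted μ).

    Requires at least 20 adhered cycles.  A single-valued force set is
    flagged degenerate (no fit; Xc falls back to the mean).
    """
    forces = cycles.cycles.loc[
        cycles.cycles["adhered"].astype(bool), "rupture_force_pN"
    ].to_numpy(float)
    if forces.size < 20:
        raise ValueError(f"only {forces.size} adhesion events; need >= 20 to fit")
    mean_force = float(forces.mean())
    if np.unique(forces).size == 1:
        centers = np.array([mean_force])
        return RuptureDistribution(centers, np.array([float(forces.size)]), None, mean_force, degenerate=True)
    lo = np.floor(forces.min() / bin_width_pN) * bin_width_pN
    hi = np.ceil(forces.max() / bin_width_pN) * bin_width_pN
    edges = np.arange(lo, hi + bin_width_pN / 2, bin_width_pN)
    freqs, _ = np.histogram(forces, bins=edges)
    centers = (edges[:-1] + edges[1:]) / 2
    fit = fit_gaussian(centers, freqs.astype(float))
    return RuptureDistribution(centers, freqs.astype(float), fit, mean_force)
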