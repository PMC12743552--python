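"""Biolayer-interferometry sensorgrams and global 1:1 Langmuir fitting.

The 1:1 Langmuir model for an analyte at molar concentration C binding an
immobilized partner:

* association (0 ≤ t ≤ t_assoc):  R(t) = Req (1 − e^{−kobs t}) with
  kobs = kon C + koff and Req = Rmax C / (C + KD), KD = koff/kon;
* dissociation (t > t_assoc):     R(t) = R(t_assoc) e^{−koff (t − t_assoc)}.

``fit_langmuir_global`` shares kon, koff and Rmax across all concentration
curves (single binding site, uniform sensor loading) and minimizes the
joint residual over both phases.  Langmuir fits are initialization
sensitive, so a small multi-start grid over (kon, koff) decades is run and
the lowest-RSS solution kept.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import lmfit
import numpy as np
import pandas as pd

__all__ = [
    "Sensorgram",
    "KineticFit",
    "langmuir_response",
    "simulate_sensorgram",
    "fit_langmuir_global",
    "kd_from_rates",
]


@dataclass
class Sensorgram:
    """A single-concentration response trace with phase boundaries.

    Time in seconds, response in nm, concentration in molar.  The baseline
    is assumed pre-subtracted (response 0 at association start).
    """

    concentration_M: float
    time_s: np.ndarray
    response_nm: np.ndarray
    t_assoc_start: float = 0.0
    t_assoc_end: float = 60.0
    t_dissoc_end: float = 180.0

    def __post_init__(self) -> None:
        self.time_s = np.asarray(self.time_s, dtype=float)
        self.response_nm = np.asarray(self.response_nm, dtype=float)
        if self.time_s.shape != self.response_nm.shape:
            raise ValueError("time and response must have equal length")
        if np.any(np.diff(self.time_s) <= 0):
            raise ValueError("time must be strictly increasing")
        if not self.t_assoc_start < self.t_assoc_end < self.t_dissoc_end:
            raise ValueError("phase boundaries must be ordered")
        if self.concentration_M <= 0:
            raise ValueError("concentration must be positive")

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame(
            {"time_s": self.time_s, "response_nm": self.response_nm}
        ).to_csv(path, index=False)


def langmuir_response(
    t_s: np.ndarray,
    kon: float,
    koff: float,
    rmax: float,
    concentration_M: float,
    t_assoc_start: float = 0.0,
    t_assoc_end: float = 60.0,
) -> np.ndarray:
    """Closed-form 1:1 Langmuir response over association + dissociation."""
    t = np.asarray(t_s, dtype=float)
    c = concentration_M
    kobs = kon * c + koff
    req = rmax * c / (c + koff / kon)
    ta = np.clip(t - t_assoc_start, 0.0, t_assoc_end - t_assoc_start)
    assoc = req * (1.0 - np.exp(-kobs * ta))
    r_end = req * (1.0 - np.exp(-kobs * (t_assoc_end - t_assoc_start)))
    td = np.clip(t - t_assoc_end, 0.0, None)
    out = np.where(t <= t_assoc_end, assoc, r_end * np.exp(-koff * td))
    return out


def simulate_sensorgram(
    kon: float,
    koff: float,
    rmax: float,
    concentration_M: float,
    t_assoc_s: float = 60.0,
    t_dissoc_s: float = 120.0,
    dt_s: float = 0.2,
    noise_sd_nm: float = 0.0,
    rng: np.random.Generator | int | None = None,
) -> Sensorgram:
    """Simulate one sensorgram with optional additive Gaussian noise.

    Deterministic for a fixed seed/generator state.
    """
    for name, v in (("kon", kon), ("koff", koff), ("rmax", rmax)):
        if v <= 0:
            raise ValueError(f"{name} must be positive")
    if noise_sd_nm < 0:
        raise ValueError("noise_sd_nm must be >= 0")
    t = np.arange(0.0, t_assoc_s + t_dissoc_s + dt_s / 2, dt_s)
    r = langmuir_response(t, kon, koff, rmax, concentration_M, 0.0, t_assoc_s)
    if noise_sd_nm > 0:
        gen = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
        r = r + gen.normal(0.0, noise_sd_nm, size=t.shape)
    return Sensorgram(
        concentration_M=concentration_M,
        time_s=t,
        response_nm=r,
        t_assoc_start=0.0,
        t_assoc_end=t_assoc_s,
        t_dissoc_end=t_assoc_s + t_dissoc_s,
    )


@dataclass
class KineticFit:
    """Result of a global 1:1 Langmuir fit."""

    kon: float
    koff: float
    rmax: float
    kd: float
    rss: float
    rmse: float
    residuals: list[np.ndarray]
    n_starts: int

    def report(self) -> dict[str, float]:
        return {
            "kon_per_M_per_s": self.kon,
            "koff_per_s": self.koff,
            "Rmax_nm": self.rmax,
            "KD_M": self.kd,
            "rss": self.rss,
            "rmse_nm": self.rmse,
        }


class FitConvergenceError(RuntimeError):
    """Raised when no multi-start attempt converges; carries the grid and
    the best residual sum reached."""

    def __init__(self, message: str, best_rss: float, grid: list[tuple[float, float]]):
        super().__init__(message)
        self.best_rss = best_rss
        self.grid = grid


def _global_residual(params: lmfit.Parameters, curves: Sequence[Sensorgram], per_curve_rmax: bool) -> np.ndarray:
    kon = params["kon"].value
    koff = params["koff"].value
    chunks = []
    for i, c in enumerate(curves):
        rmax = params[f"rmax_{i}"].value if per_curve_rmax else params["rmax"].value
        model = langmuir_response(
            c.time_s, kon, koff, rmax, c.concentration_M, c.t_assoc_start, c.t_assoc_end
        )
        chunks.append(c.response_nm - model)
    return np.concatenate(chunks)


def fit_langmuir_global(
    curves: Sequence[Sensorgram],
    per_curve_rmax: bool = False,
    kon_starts: Sequence[float] = (1e3, 1e4, 1e5),
    koff_starts: Sequence[float] = (1e-3, 1e-2, 1e-1),
) -> KineticFit:
    """Globally fit shared (kon, koff, Rmax) to sensorgrams at several
    analyte concentrations.

    Nonlinear least squares over both phases of every curve jointly.  Each
    (kon, koff) start on the grid is tried with Rmax initialized from the
    maximum observed response; the lowest-RSS converged solution wins.
    Fewer than 3 concentrations triggers a warning but the fit proceeds.
    """
    if not curves:
        raise ValueError("no sensorgrams given")
    concs = [c.concentration_M for c in curves]
    if len(set(concs)) != len(concs):
        raise ValueError("duplicate analyte concentrations")
    if len(curves) < 3:
        warnings.warn(
            "fewer than 3 concentrations: the global fit is weakly "
            "constrained", stacklevel=2,
        )
    rmax0 = max(float(c.response_nm.max()) for c in curves)
    rmax0 = max(rmax0, 1e-6)

    best = None
    best_rss = np.inf
    grid = [(k1, k2) for k1 in kon_starts for k2 in koff_starts]
    for kon0, koff0 in grid:
        params = lmfit.Parameters()
        params.add("kon", value=kon0, min=1e-6)
        params.add("koff", value=koff0, min=1e-12)
        if per_curve_rmax:
            for i in range(len(curves)):
                params.add(f"rmax_{i}", value=rmax0, min=1e-9)
        else:
            params.add("rmax", value=rmax0, min=1e-9)
        try:
            res = lmfit.minimize(
                _global_residual, params, args=(curves, per_curve_rmax),
                method="leastsq", nan_policy="raise",
            )
        except Exception:
            continue
        rss = float(np.sum(res.residual**2))
        if res.success and rss < best_rss:
            best, best_rss = res, rss
    if best is None:
        raise FitConvergenceError(
            "no multi-start attempt converged", best_rss, grid
        )
    kon = float(best.params["kon"].value)
    koff = float(best.params["koff"].value)
    if per_curve_rmax:
        rmax = float(np.mean([best.params[f"rmax_{i}"].value for i in range(len(curves))]))
    else:
        rmax = float(best.params["rmax"].value)
    residuals = []
    offset = 0
    for c in curves:
        n = c.time_s.size
        residuals.append(best.residual[offset : offset + n].copy())
        offset += n
    n_total = sum(c.time_s.size for c in curves)
    return KineticFit(
        kon=kon,
        koff=koff,
        rmax=rmax,
        kd=koff / kon,
        rss=best_rss,
        rmse=float(np.sqrt(best_rss / n_total)),
        residuals=residuals,
        n_starts=len(grid),
    )


def kd_from_rates(kon: float, koff: float) -> float:
    """Equilibrium dissociation constant KD = koff / kon (molar)."""
    if kon <= 0:
        raise ValueError("kon must be positive")
    if koff < 0:
        raise ValueError("koff must be >= 0")
    return koff / kon
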