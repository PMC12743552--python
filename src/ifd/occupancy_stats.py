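"""Survival-rate statistics for interfacial contacts.

Turns per-frame hydrogen-bond / salt-bridge detections into occupancy
matrices, per-run survival percentages, multi-run mean ± SEM tables (the
shape used to report equilibrium runs of the VWF A1/A2 complex), filtered
and ranked tables, residue-pair heat-map matrices, and Gaussian fits of the
per-frame hydrogen-bond count distribution.

The survival rate of a contact is the percentage of trajectory frames in
which its geometric criteria hold.  Across runs the SEM uses the sample
(n−1) standard deviation divided by √n_runs; a contact absent from a run
contributes an explicit 0.0% to the aggregate.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path
from typing import Hashable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .core_structures import Trajectory
from .interface_contacts import (
    HBondCriteria,
    InteractionKey,
    SaltBridgeCriteria,
    detect_hbonds,
    detect_salt_bridges,
)

__all__ = [
    "OccupancyMatrix",
    "SurvivalTable",
    "GaussianFit",
    "occupancy_from_trajectory",
    "survival_rates",
    "aggregate_runs",
    "filter_table",
    "heatmap_matrix",
    "heatmap_png",
    "hbond_count_series",
    "fit_gaussian",
    "fit_count_histogram",
]


@dataclass
class OccupancyMatrix:
    """Presence of each interaction key across the frames of one run."""

    keys: list
    presence: np.ndarray  # (n_keys, n_frames) boolean
    frame_interval_ns: float = 1.0

    def __post_init__(self) -> None:
        self.presence = np.asarray(self.presence, dtype=bool)
        if self.presence.ndim != 2 or self.presence.shape[0] != len(self.keys):
            raise ValueError("presence must be (n_keys, n_frames)")
        if len(set(self.keys)) != len(self.keys):
            raise ValueError("duplicate interaction keys")

    @property
    def n_frames(self) -> int:
        return self.presence.shape[1]


def _sort_key(key) -> tuple:
    if isinstance(key, InteractionKey):
        return (key.kind, key.res_a, key.res_b, key.chain_a, key.chain_b)
    return (str(key),)


def occupancy_from_trajectory(
    traj: Trajectory,
    partner_a: Iterable[str],
    partner_b: Iterable[str],
    hb_criteria: HBondCriteria | None = None,
    sb_criteria: SaltBridgeCriteria | None = None,
    kinds: Sequence[str] = ("hbond", "saltbridge"),
) -> OccupancyMatrix:
    """Scan every frame with the contact detectors and build the occupancy
    matrix over the union of keys seen in any frame (deterministic order)."""
    partner_a, partner_b = list(partner_a), list(partner_b)
    per_frame: list[set] = []
    for frame in traj.frames:
        found: set = set()
        if "hbond" in kinds:
            found |= detect_hbonds(frame, traj.topology, partner_a, partner_b, hb_criteria)
        if "saltbridge" in kinds:
            found |= detect_salt_bridges(frame, traj.topology, partner_a, partner_b, sb_criteria)
        per_frame.append(found)
    keys = sorted(set().union(*per_frame) if per_frame else set(), key=_sort_key)
    presence = np.zeros((len(keys), len(per_frame)), dtype=bool)
    index = {k: i for i, k in enumerate(keys)}
    for f, found in enumerate(per_frame):
        for k in found:
            presence[index[k], f] = True
    return OccupancyMatrix(keys, presence, traj.frame_interval_ns)


def survival_rates(occ: OccupancyMatrix) -> dict:
    """Percentage of frames in which each key is present."""
    if occ.n_frames < 1:
        raise ValueError("at least one frame required")
    pct = 100.0 * occ.presence.mean(axis=1)
    return {k: float(p) for k, p in zip(occ.keys, pct)}


@dataclass
class SurvivalTable:
    """Per-key survival percentages across runs with mean ± SEM.

    ``data`` is indexed by the interaction keys with columns
    ``run_1 .. run_n, mean, sem`` (all percentages).
    """

    data: pd.DataFrame

    @property
    def keys(self) -> list:
        return list(self.data.index)

    @property
    def run_columns(self) -> list[str]:
        return [c for c in self.data.columns if c.startswith("run_")]

    def __len__(self) -> int:
        return len(self.data)

    def to_csv(self, path: str | Path) -> None:
        out = self.data.copy()
        labels = [_key_labels(k) for k in out.index]
        out.insert(0, "kind", [l[0] for l in labels])
        out.insert(1, "res_a", [l[1] for l in labels])
        out.insert(2, "res_b", [l[2] for l in labels])
        out.to_csv(path, index=False)


def _key_labels(key) -> tuple[str, str, str]:
    """(kind, res_a label, res_b label) for CSV export and heat maps.

    String keys of the form ``"R1334-E1598"`` are split on the dash; a
    ``#n`` suffix (used to keep distinct atom-level contacts of the same
    residue pair apart) is stripped from the labels.
    """
    if isinstance(key, InteractionKey):
        a, b = key.label.split("-")
        return key.kind, a, b
    strip = lambda s: str(s).split("#")[0]
    if isinstance(key, tuple) and len(key) >= 2:
        return ("", strip(key[-2]), strip(key[-1]))
    parts = str(key).split("-")
    if len(parts) == 2:
        return ("", strip(parts[0]), strip(parts[1]))
    return ("", strip(key), "")


def _residue_numbers(key) -> tuple[int, int]:
    if isinstance(key, InteractionKey):
        return key.res_a, key.res_b
    _, la, lb = _key_labels(key)
    num = lambda s: int(m.group()) if (m := re.search(r"\d+", s)) else 0
    return num(la), num(lb)


def aggregate_runs(run_maps: Sequence[Mapping[Hashable, float]]) -> SurvivalTable:
    """Combine per-run survival maps into a mean ± SEM table.

    Keys are unioned across runs; a key missing from a run contributes an
    explicit 0.0%.  SEM = sample standard deviation (n−1) / √n_runs, which
    requires at least two runs.
    """
    n_runs = len(run_maps)
    if n_runs < 2:
        raise ValueError("SEM undefined for fewer than 2 runs")
    keys: list = []
    for m in run_maps:
        for k in m:
            if k not in keys:
                keys.append(k)
    keys.sort(key=_sort_key)
    rows = {}
    for k in keys:
        vals = np.array([float(m.get(k, 0.0)) for m in run_maps])
        if np.any((vals < 0) | (vals > 100)):
            raise ValueError(f"survival out of [0, 100] for key {k}")
        rows[k] = list(vals) + [vals.mean(), vals.std(ddof=1) / np.sqrt(n_runs)]
    cols = [f"run_{i + 1}" for i in range(n_runs)] + ["mean", "sem"]
    df = pd.DataFrame.from_dict(rows, orient="index", columns=cols)
    return SurvivalTable(df)


def filter_table(table: SurvivalTable, threshold: float = 10.0) -> SurvivalTable:
    """Rows with mean survival strictly above ``threshold`` %, sorted by
    mean descending; ties broken by first-run survival (descending), then
    residue number (ascending)."""
    df = table.data[table.data["mean"] > threshold].copy()
    res_nums = [_residue_numbers(k) for k in df.index]
    df["_ra"] = [r[0] for r in res_nums]
    df["_rb"] = [r[1] for r in res_nums]
    run1 = df["run_1"] if "run_1" in df.columns else df["mean"]
    df = (
        df.assign(_mean_neg=-df["mean"], _run1_neg=-run1)
        .sort_values(["_mean_neg", "_run1_neg", "_ra", "_rb"], kind="stable")
        .drop(columns=["_mean_neg", "_run1_neg", "_ra", "_rb"])
    )
    return SurvivalTable(df)


def heatmap_matrix(table: SurvivalTable) -> pd.DataFrame:
    """Residue-A × residue-B matrix of mean survival percentages.

    Rows/columns are ordered by ascending residue number; cells without a
    table row are 0.  Rows sharing the same residue-pair labels (distinct
    atom-level contacts reported separately) are summed.
    """
    if len(table) == 0:
        return pd.DataFrame(dtype=float)
    labels = [_key_labels(k)[1:] for k in table.keys]
    nums = [_residue_numbers(k) for k in table.keys]
    rows = sorted(set(zip((l[0] for l in labels), (n[0] for n in nums))), key=lambda t: t[1])
    cols = sorted(set(zip((l[1] for l in labels), (n[1] for n in nums))), key=lambda t: t[1])
    mat = pd.DataFrame(
        0.0, index=[r[0] for r in rows], columns=[c[0] for c in cols]
    )
    for (la, lb), mean in zip(labels, table.data["mean"]):
        mat.loc[la, lb] += mean
    return mat


def heatmap_png(matrix: pd.DataFrame, path: str | Path, cmap: str = "viridis") -> None:
    """Render a survival heat-map matrix to PNG (partner-A residues on the
    y axis, partner-B on the x axis, cell color = mean survival %)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(1.0 + 0.5 * matrix.shape[1], 1.0 + 0.5 * matrix.shape[0]))
    im = ax.imshow(matrix.to_numpy(), cmap=cmap, vmin=0.0, aspect="auto")
    ax.set_xticks(range(matrix.shape[1]), labels=list(matrix.columns), rotation=90)
    ax.set_yticks(range(matrix.shape[0]), labels=list(matrix.index))
    fig.colorbar(im, ax=ax, label="mean survival (%)")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def hbond_count_series(occ: OccupancyMatrix) -> np.ndarray:
    """Per-frame count of present hydrogen bonds (all keys if the matrix
    carries no kind information)."""
    mask = np.array(
        [
            k.kind == "hbond" if isinstance(k, InteractionKey) else True
            for k in occ.keys
        ]
    )
    if len(occ.keys) == 0:
        return np.zeros(occ.presence.shape[1], dtype=int)
    return occ.presence[mask].sum(axis=0).astype(int)


@dataclass
class GaussianFit:
    """A Gaussian ``A·exp(−(x−μ)²/2σ²)`` fitted to binned frequencies."""

    mu: float
    sigma: float
    amplitude: float
    rss: float


def _gauss(x, amplitude, mu, sigma):
    return amplitude * np.exp(-((x - mu) ** 2) / (2.0 * sigma**2))


def fit_gaussian(centers: np.ndarray, frequencies: np.ndarray) -> GaussianFit:
    """Nonlinear least-squares Gaussian fit to a histogram."""
    x = np.asarray(centers, dtype=float)
    y = np.asarray(frequencies, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need >= 3 matched bins")
    w = np.clip(y, 0, None)
    if w.sum() <= 0:
        raise ValueError("all frequencies are zero")
    mu0 = float(np.average(x, weights=w))
    sigma0 = float(np.sqrt(np.average((x - mu0) ** 2, weights=w)))
    if sigma0 < 1e-12:
        raise ValueError(
            "degenerate histogram (zero spread): a Gaussian sigma cannot be "
            "resolved below the bin width; provide data with spread"
        )
    sigma0 = max(sigma0, 1e-3)
    p0 = (float(y.max()), mu0, sigma0)
    popt, _ = curve_fit(
        _gauss, x, y, p0=p0,
        bounds=([0.0, -np.inf, 1e-9], [np.inf, np.inf, np.inf]),
        maxfev=20000,
    )
    rss = float(np.sum((y - _gauss(x, *popt)) ** 2))
    return GaussianFit(mu=float(popt[1]), sigma=float(popt[2]), amplitude=float(popt[0]), rss=rss)


def fit_count_histogram(counts: np.ndarray) -> tuple[np.ndarray, np.ndarray, GaussianFit]:
    """Unit-width integer binning of a count series plus its Gaussian fit.

    Returns (bin centers, frequencies, fit).  Requires at least 10 samples;
    an all-equal series raises (sigma floor).
    """
    counts = np.asarray(counts)
    if counts.size < 10:
        raise ValueError("need >= 10 frames for a Gaussian fit")
    if np.unique(counts).size == 1:
        raise ValueError(
            "degenerate count series (all values equal): sigma would fall "
            "below the unit bin width; Gaussian fit not meaningful"
        )
    lo, hi = int(counts.min()), int(counts.max())
    centers = np.arange(lo, hi + 1)
    freqs = np.array([(counts == c).sum() for c in centers], dtype=float)
    return centers, freqs, fit_gaussian(centers, freqs)
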