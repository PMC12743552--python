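"""Reference values for the VWF A1/A2 interdomain interface.

These constants parameterize the synthetic generators and worked examples:
per-run survival percentages of the interfacial hydrogen bonds and salt
bridges from three independent 50-ns equilibrium runs of the wild-type
A1/A2 complex, the BLI kinetic triples for wild-type and triple-alanine
mutants, the steered-pulling setup constants, and the AFM sampling design.

They are inputs to the package (study conditions), not outputs of it; all
derived statistics elsewhere are recomputed from these raw values.
"""

from __future__ import annotations

# ---------------------------------------------------------------------------
# Interfacial hydrogen bonds: per-run survival %, three 50-ns runs, wild type.
# Key strings are residue-pair labels (A1 side first); "#2" marks a second,
# distinct contact reported for a residue pair that already has a row.
# printed mean/sem columns are the published 1-d.p. aggregates kept for
# cross-checking the aggregation code.
# ---------------------------------------------------------------------------
HBOND_SURVIVAL_RUNS: dict[str, tuple[float, float, float]] = {
    "R1334-E1598": (79.3, 59.1, 51.1),
    "Q1367-V1546": (78.1, 74.8, 27.9),
    "D1323-R1575": (67.7, 5.7, 88.7),
    "E1359-Y1544": (39.8, 42.4, 37.3),
    "K1371-E1554": (29.8, 38.2, 30.2),
    "F1366-V1548": (22.6, 59.5, 14.2),
    "S1325-Y1544": (19.0, 28.5, 29.2),
    "D1333-R1583": (0.0, 71.2, 0.0),
    "K1335-D1587": (16.0, 13.6, 38.6),
    "K1332-H1588": (17.9, 30.4, 8.9),
    "Q1367-V1546#2": (0.0, 0.0, 41.7),
    "A1327-R1583": (0.0, 17.0, 22.4),
    "R1334-D1596": (0.0, 0.0, 33.6),
}

HBOND_PRINTED_MEAN_SEM: dict[str, tuple[float, float]] = {
    "R1334-E1598": (63.2, 8.4),
    "Q1367-V1546": (60.3, 16.2),
    "D1323-R1575": (54.0, 24.9),
    "E1359-Y1544": (39.8, 1.5),
    "K1371-E1554": (32.7, 2.7),
    "F1366-V1548": (32.1, 13.9),
    "S1325-Y1544": (25.6, 3.3),
    "D1333-R1583": (23.7, 23.7),
    "K1335-D1587": (22.7, 8.0),
    "K1332-H1588": (19.1, 6.2),
    "Q1367-V1546#2": (13.9, 13.9),
    "A1327-R1583": (13.1, 6.7),
    "R1334-D1596": (11.2, 11.2),
}

# Salt bridges, same runs.
SALTBRIDGE_SURVIVAL_RUNS: dict[str, tuple[float, float, float]] = {
    "D1323-R1575": (69.9, 2.6, 87.9),
    "R1334-E1598": (64.8, 41.6, 30.4),
    "K1371-E1554": (39.9, 49.8, 39.4),
    "K1335-D1587": (28.7, 25.5, 62.1),
    "D1333-R1583": (0.0, 55.0, 0.0),
}

SALTBRIDGE_PRINTED_MEAN_SEM: dict[str, tuple[float, float]] = {
    "D1323-R1575": (53.4, 26.0),
    "R1334-E1598": (45.6, 10.2),
    "K1371-E1554": (43.1, 3.4),
    "K1335-D1587": (38.8, 11.7),
    "D1333-R1583": (18.3, 18.3),
}

#: The three strongest hydrogen-bond pairs (mean survival > 50%), in order.
TOP_HBOND_PAIRS: tuple[str, ...] = ("R1334-E1598", "Q1367-V1546", "D1323-R1575")

# ---------------------------------------------------------------------------
# BLI 1:1 Langmuir kinetics (global fits): kon [1/(M s)], koff [1/s], and the
# affinity KD as printed.  kd_printed is kept separately because it reflects
# display rounding: koff/kon gives 2.176 uM (WT) and 6.23 uM (A1_mut).
# ---------------------------------------------------------------------------
KINETIC_TRIPLES: dict[str, dict[str, float]] = {
    "wt": {"kon": 1.7e4, "koff": 3.7e-2, "kd_printed": 2.16e-6},
    "a1_mut": {"kon": 1.3e4, "koff": 8.1e-2, "kd_printed": 6.1e-6},
    "a2_mut": {"kon": 1.1e4, "koff": 4.6e-2, "kd_printed": 4.2e-6},
}

#: BLI schedule: serial A1 dilutions, 60 s association / 120 s dissociation.
BLI_CONCENTRATIONS_M: tuple[float, ...] = (125e-9, 250e-9, 500e-9, 1000e-9, 2000e-9, 4000e-9)
BLI_T_ASSOC_S: float = 60.0
BLI_T_DISSOC_S: float = 120.0

# ---------------------------------------------------------------------------
# Steered pulling (force-ramp) setup and outcomes.
# ---------------------------------------------------------------------------
SMD_SPRING_K_PN_PER_A: float = 69.48
SMD_PULL_VELOCITY_A_PER_NS: float = 5.0
SMD_DURATION_NS: float = 25.0

#: Mean rupture force (pN) and dissociation time (ns) per system, mean ± SEM
#: over three pulls.  (The dissociation times were printed with a seconds
#: unit label; on a 25-ns pull they are nanoseconds.)
SMD_RUPTURE_FORCE_PN: dict[str, tuple[float, float]] = {
    "wt": (358.7, 30.8),
    "a1_mut": (184.4, 23.2),
    "a2_mut": (213.2, 7.4),
}
SMD_DISSOCIATION_TIME_NS: dict[str, tuple[float, float]] = {
    "wt": (21.6, 0.9),
    "a1_mut": (11.6, 1.5),
    "a2_mut": (16.7, 0.8),
}

# ---------------------------------------------------------------------------
# AFM force spectroscopy: sampling design and outcomes.
# ---------------------------------------------------------------------------
AFM_CYCLES_PER_POINT: int = 100
AFM_POINTS_PER_SUBSTRATE: int = 5
AFM_N_SUBSTRATES: int = 3

#: Adhesion frequency (%), mean rupture force (pN), and Gaussian peak
#: center Xc (pN) per system.
AFM_ADHESION_FREQUENCY_PCT: dict[str, float] = {"wt": 19.1, "a1_mut": 14.5, "a2_mut": 6.4}
AFM_MEAN_RUPTURE_FORCE_PN: dict[str, float] = {"wt": 42.2, "a1_mut": 41.5, "a2_mut": 33.0}
AFM_GAUSSIAN_XC_PN: dict[str, float] = {"wt": 34.4, "a1_mut": 35.0, "a2_mut": 24.5}
#: Spread used by the synthetic rupture-force law (pN); a typical
#: single-bond AFM distribution width at this force scale.
AFM_FORCE_SD_PN: float = 8.0
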