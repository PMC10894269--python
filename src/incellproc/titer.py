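"""Endpoint-dilution titration (TCID50) and MOI-based virus dosing.

A baculovirus stock is titrated by serial 1:10 dilution across the rows of a
96-well plate seeded with insect cells; after incubation, a well is scored
positive when at least two fluorescent (infected) cells are seen. The 50%
endpoint — the dilution at which half the wells would be positive — gives
the titer in TCID50 per mL. Converting TCID50 to infectious units uses the
Poisson factor ln 2 ~= 0.69: at the 50% endpoint the mean number of
infectious units per well is -ln(0.5).

The dosing formula for an infection at a chosen multiplicity of infection:

    virus stock [mL] = (MOI x cell number) / (0.69 x TCID50/mL)
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "TiterPlate",
    "TiterResult",
    "TCID50_TO_IU",
    "score_wells",
    "tcid50",
    "volume_for_moi",
    "amplification_factor",
]

TCID50_TO_IU = 0.69  # infectious units per TCID50 (ln 2, Poisson 50% endpoint)
DEFAULT_POSITIVITY_THRESHOLD = 2  # fluorescent cells making a well positive
DEFAULT_INOCULUM_ML = 0.02  # 20 uL of diluted stock per well
DEFAULT_WELLS_PER_DILUTION = 6


@dataclass
class TiterPlate:
    """Outcome of one endpoint-dilution assay.

    ``dilution_log10`` lists the log10 of the *total* dilution per row
    (negative, strictly decreasing, constant step; typically -2 ... -9 for a
    1:10 pre-dilution followed by seven serial 1:10 transfers).
    """

    dilution_log10: list[float]
    positive_wells: list[int]
    wells_per_dilution: int = DEFAULT_WELLS_PER_DILUTION
    inoculum_volume_ml: float = DEFAULT_INOCULUM_ML
    positivity_threshold_cells: int = DEFAULT_POSITIVITY_THRESHOLD

    def __post_init__(self):
        if len(self.dilution_log10) != len(self.positive_wells):
            raise ValueError("one positive-well count per dilution required")
        diffs = np.diff(self.dilution_log10)
        if len(diffs) and ((diffs >= 0).any() or not np.allclose(diffs, diffs[0])):
            raise ValueError("dilutions must be strictly decreasing with a constant step")
        if any(not 0 <= p <= self.wells_per_dilution for p in self.positive_wells):
            raise ValueError("positive wells must be between 0 and wells_per_dilution")
        if self.inoculum_volume_ml <= 0:
            raise ValueError("inoculum volume must be > 0")

    @property
    def step(self) -> float:
        return abs(self.dilution_log10[1] - self.dilution_log10[0]) if len(self.dilution_log10) > 1 else 1.0

    @property
    def proportions(self) -> np.ndarray:
        return np.array(self.positive_wells, dtype=float) / self.wells_per_dilution


@dataclass
class TiterResult:
    tcid50_per_ml: float
    log10_endpoint_dilution: float
    method: str

    def __post_init__(self):
        if self.tcid50_per_ml <= 0:
            raise ValueError("titer must be > 0")


def score_wells(
    fluorescent_cell_counts: Sequence[Sequence[int]],
    threshold: int = DEFAULT_POSITIVITY_THRESHOLD,
) -> list[int]:
    """Positives per dilution row: a well counts as positive when it shows at
    least ``threshold`` fluorescent cells (default 2, so a lone
    autofluorescent cell does not score)."""
    out = []
    for row in fluorescent_cell_counts:
        for c in row:
            if c < 0:
                raise ValueError("cell counts must be >= 0")
        out.append(sum(1 for c in row if c >= threshold))
    return out


def tcid50(plate: TiterPlate, method: str = "spearman-karber") -> TiterResult:
    """Endpoint titer from well proportions.

    Spearman-Karber (default): with x100 the log10 dilution of the last fully
    positive row, d the dilution step and S the sum of positive proportions
    from that row onward, the 50% endpoint is m = x100 - d (S - 0.5) and the
    titer is 10^(-m) / inoculum volume. Requires the endpoint to be bracketed
    by a fully positive and a fully negative row. Reed-Muench is available
    behind ``method="reed-muench"``.
    """
    p = plate.proportions
    if not (p == 1.0).any():
        raise ValueError("endpoint not bracketed: no fully positive dilution")
    if not (p == 0.0).any():
        raise ValueError("endpoint not bracketed: no fully negative dilution")
    if method == "spearman-karber":
        # last row of the initial fully-positive run
        i100 = 0
        while i100 + 1 < len(p) and p[i100 + 1] == 1.0:
            i100 += 1
        x100 = plate.dilution_log10[i100]
        s = float(p[i100:].sum())
        m = x100 - plate.step * (s - 0.5)
    elif method == "reed-muench":
        m = _reed_muench_endpoint(plate)
    else:
        raise ValueError(f"unknown method {method!r}")
    return TiterResult(
        tcid50_per_ml=10.0 ** (-m) / plate.inoculum_volume_ml,
        log10_endpoint_dilution=m,
        method=method,
    )


def _reed_muench_endpoint(plate: TiterPlate) -> float:
    pos = np.array(plate.positive_wells, dtype=float)
    neg = plate.wells_per_dilution - pos
    # cumulative positives from the most dilute row upward, negatives downward
    cum_pos = pos[::-1].cumsum()[::-1]
    cum_neg = neg.cumsum()
    pct = 100.0 * cum_pos / (cum_pos + cum_neg)
    above = np.where(pct >= 50.0)[0]
    below = np.where(pct < 50.0)[0]
    i = above[-1]
    j = below[0]
    if pct[i] == pct[j]:
        frac = 0.0
    else:
        frac = (pct[i] - 50.0) / (pct[i] - pct[j])
    return plate.dilution_log10[i] - frac * plate.step


def volume_for_moi(moi: float, cell_number: float, tcid50_per_ml: float) -> float:
    """Milliliters of stock for a target MOI:
    volume = MOI x cells / (0.69 x TCID50/mL)."""
    if moi < 0 or cell_number <= 0:
        raise ValueError("moi must be >= 0 and cell_number > 0")
    if tcid50_per_ml <= 0:
        raise ValueError("TCID50/mL must be > 0")
    return moi * cell_number / (TCID50_TO_IU * tcid50_per_ml)


def amplification_factor(harvest_titer: float, infection_titer: float) -> float:
    """Fold increase of titer over one amplification passage."""
    if harvest_titer <= 0 or infection_titer <= 0:
        raise ValueError("titers must be > 0")
    return harvest_titer / infection_titer
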