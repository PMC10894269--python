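"""Per-reflection resolution, peakograms and salt powder-ring removal.

Precipitated salt in cellular samples produces powder rings whose spots get
indexed and integrated as if they were Bragg reflections of the protein
crystal. Because salt rings are far more intense than protein reflections at
the same resolution, they stand out in a *peakogram* — a 2D histogram of
reflection resolution against log10 peak intensity — and can be removed by
resolution-dependent intensity ceilings chosen off that plot.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .stream_io import (
    Chunk,
    CrystalRecord,
    StreamDataset,
    UnitCell,
    iter_crystals,
)

__all__ = [
    "ResolutionBand",
    "Peakogram",
    "SaltRemovalReport",
    "d_spacing",
    "peakogram",
    "filter_salt",
    "suggest_thresholds",
    "estimate_resolution_limit",
]


def d_spacing(h: int, k: int, l: int, cell: UnitCell) -> float:
    """Interplanar spacing d (Angstrom): d = 1 / |h a* + k b* + l c*|."""
    if h == 0 and k == 0 and l == 0:
        raise ValueError("d-spacing undefined for (0,0,0)")
    svec = np.array([h, k, l], dtype=float) @ cell.reciprocal_basis()
    return float(1.0 / np.linalg.norm(svec))


@dataclass(frozen=True)
class ResolutionBand:
    """Half-open resolution interval [d_min, d_max) in Angstrom with an
    intensity ceiling; reflections above the ceiling inside the band are
    treated as salt-ring contamination."""

    d_min: float
    d_max: float
    max_intensity: float

    def __post_init__(self):
        if not 0 < self.d_min < self.d_max:
            raise ValueError("require 0 < d_min < d_max")

    def contains(self, d: float) -> bool:
        return self.d_min <= d < self.d_max


def _check_bands(bands: Sequence[ResolutionBand]) -> None:
    ordered = sorted(bands, key=lambda b: b.d_min)
    for lo, hi in zip(ordered, ordered[1:]):
        if hi.d_min < lo.d_max:
            raise ValueError(f"overlapping resolution bands: {lo} and {hi}")


@dataclass
class Peakogram:
    """2D histogram over (1/d in 1/Angstrom, log10 peak intensity)."""

    res_edges: np.ndarray
    log_intensity_edges: np.ndarray
    counts: np.ndarray
    n_excluded_nonpositive: int = 0

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def to_tsv(self) -> str:
        lines = ["inv_d_lo\tinv_d_hi\tlog10I_lo\tlog10I_hi\tcount"]
        for i in range(self.counts.shape[0]):
            for j in range(self.counts.shape[1]):
                lines.append(
                    f"{self.res_edges[i]:.6g}\t{self.res_edges[i+1]:.6g}\t"
                    f"{self.log_intensity_edges[j]:.6g}\t{self.log_intensity_edges[j+1]:.6g}\t"
                    f"{int(self.counts[i, j])}"
                )
        return "\n".join(lines) + "\n"


def _reflection_quantity(r, quantity: str) -> float:
    if quantity == "peak":
        return r.peak_value
    if quantity == "intensity":
        return r.intensity
    raise ValueError(f"unknown quantity {quantity!r}; use 'peak' or 'intensity'")


def peakogram(
    dataset: StreamDataset,
    n_res_bins: int = 50,
    n_intensity_bins: int = 50,
    quantity: str = "peak",
) -> Peakogram:
    """Histogram every indexed reflection at (1/d, log10 of its peak value).

    Reflections with non-positive peak values cannot be placed on the log
    scale; they are excluded and counted separately.
    """
    inv_d = []
    logi = []
    excluded = 0
    for _, _, xtal in iter_crystals(dataset):
        for r in xtal.reflections:
            v = _reflection_quantity(r, quantity)
            if v <= 0:
                excluded += 1
                continue
            inv_d.append(1.0 / d_spacing(r.h, r.k, r.l, xtal.cell))
            logi.append(math.log10(v))
    if not inv_d:
        res_edges = np.linspace(0.0, 1.0, n_res_bins + 1)
        li_edges = np.linspace(0.0, 1.0, n_intensity_bins + 1)
        return Peakogram(res_edges, li_edges, np.zeros((n_res_bins, n_intensity_bins)), excluded)
    counts, res_edges, li_edges = np.histogram2d(
        inv_d, logi, bins=[n_res_bins, n_intensity_bins]
    )
    return Peakogram(res_edges, li_edges, counts, excluded)


@dataclass
class SaltRemovalReport:
    """What :func:`filter_salt` removed: counts per band and the exact
    identity of every removed reflection."""

    counts_per_band: dict[int, int] = field(default_factory=dict)
    removed: list[tuple[int, int, tuple[int, int, int], float]] = field(default_factory=list)
    # entries: (chunk frame_index, crystal index, (h,k,l), filtered value)

    @property
    def n_removed(self) -> int:
        return len(self.removed)


def filter_salt(
    dataset: StreamDataset,
    bands: Sequence[ResolutionBand],
    quantity: str = "peak",
) -> tuple[StreamDataset, SaltRemovalReport]:
    """Remove reflections whose d falls in a band and whose peak value (by
    default; integrated intensity optionally) exceeds the band's ceiling.

    Crystals and chunks are retained even if emptied, so chunk bookkeeping
    (frame order, hit counts) survives filtering. Retained reflections are
    passed through unaltered.
    """
    _check_bands(bands)
    report = SaltRemovalReport(counts_per_band={i: 0 for i in range(len(bands))})
    new_chunks = []
    for chunk in dataset.chunks:
        new_crystals = []
        for j, xtal in enumerate(chunk.crystals):
            kept = []
            for r in xtal.reflections:
                d = d_spacing(r.h, r.k, r.l, xtal.cell)
                v = _reflection_quantity(r, quantity)
                hit = next(
                    (i for i, b in enumerate(bands) if b.contains(d) and v > b.max_intensity),
                    None,
                )
                if hit is None:
                    kept.append(r)
                else:
                    report.counts_per_band[hit] += 1
                    report.removed.append((chunk.frame_index, j, (r.h, r.k, r.l), v))
            new_crystals.append(replace(xtal, reflections=kept))
        new_chunks.append(replace(chunk, crystals=new_crystals))
    return StreamDataset(chunks=new_chunks, header=dataset.header), report


def suggest_thresholds(
    dataset: StreamDataset,
    bands_d: Sequence[tuple[float, float]],
    q: float = 0.999,
    quantity: str = "peak",
) -> list[ResolutionBand]:
    """Suggest a ceiling per resolution interval as the q-th intensity
    quantile of the reflections inside it — a starting point for the manual
    choice normally made off the peakogram."""
    out = []
    for d_min, d_max in bands_d:
        vals = []
        for _, _, xtal in iter_crystals(dataset):
            for r in xtal.reflections:
                d = d_spacing(r.h, r.k, r.l, xtal.cell)
                if d_min <= d < d_max:
                    vals.append(_reflection_quantity(r, quantity))
        if not vals:
            warnings.warn(f"no reflections in band [{d_min}, {d_max})", stacklevel=2)
            ceiling = math.inf
        else:
            ceiling = float(np.quantile(vals, q))
        out.append(ResolutionBand(d_min=d_min, d_max=d_max, max_intensity=ceiling))
    return out


def estimate_resolution_limit(
    crystal: CrystalRecord,
    snr_cutoff: float = 1.0,
    shell_width: float = 0.02,
) -> float | None:
    """Per-crystal diffraction limit from the signal-to-noise falloff.

    Reflections are binned into shells of width ``shell_width`` in 1/d
    (1/Angstrom) starting at the lowest resolution; walking toward higher
    resolution, the limit is the d at the center of the last contiguous shell
    whose mean I/sigma stays at or above ``snr_cutoff``. Returns None when no
    shell qualifies or no reflection has sigma > 0.
    """
    pairs = [
        (1.0 / d_spacing(r.h, r.k, r.l, crystal.cell), r.intensity / r.sigma)
        for r in crystal.reflections
        if r.sigma > 0
    ]
    if not pairs:
        return None
    inv_d = np.array([p[0] for p in pairs])
    snr = np.array([p[1] for p in pairs])
    lo = inv_d.min()
    n_shells = int(np.ceil((inv_d.max() - lo) / shell_width)) or 1
    which = np.minimum(((inv_d - lo) / shell_width).astype(int), n_shells - 1)
    best = None
    for s in range(n_shells):
        sel = which == s
        if not sel.any():
            continue  # empty shells do not break contiguity
        if snr[sel].mean() < snr_cutoff:
            break
        center = lo + (s + 0.5) * shell_width
        best = 1.0 / center
    return best
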