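"""Symmetry reduction, scaling and Monte-Carlo merging of serial data.

Serial datasets consist of many partial observations of each reflection,
one small wedge or still per crystal. Merging averages the observations per
symmetry-unique reflection under a "unity" partiality model (every
observation weighted as if fully recorded), after per-crystal linear scales
have been estimated by alternating least squares against the running merge.
Quality is judged by half-dataset figures of merit: Rsplit and the
half-set Pearson correlation CC1/2, plus completeness, redundancy and
mean I/sigma, overall and in equal-volume resolution shells.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import gemmi
import numpy as np
import pandas as pd

from .reflection_filter import d_spacing
from .stream_io import Chunk, StreamDataset, UnitCell, iter_crystals, split_into_parts

__all__ = [
    "PointGroup",
    "get_point_group",
    "point_group_from_operators",
    "MergedReflection",
    "map_to_asu",
    "centering_allowed",
    "scale_crystals",
    "ScalingResult",
    "merge",
    "split_half_datasets",
    "rsplit",
    "cc_half",
    "completeness",
    "enumerate_unique_hkl",
    "shell_stats",
    "diffraction_power_slices",
    "merged_to_text",
]

# Representative symmorphic primitive space group for each supported point group.
_PG_SPACEGROUP = {
    "1": "P 1",
    "-1": "P -1",
    "2/m": "P 1 2/m 1",
    "mmm": "P m m m",
    "4/m": "P 4/m",
    "4/mmm": "P 4/m m m",
    "-3": "P -3",
    "6/m": "P 6/m",
    "6/mmm": "P 6/m m m",
    "m-3": "P m -3",
}


@dataclass(frozen=True)
class PointGroup:
    """A point group as integer rotation operators acting on (h, k, l).

    ``friedel`` additionally merges Friedel mates (h,k,l)/(-h,-k,-l) even if
    the operator set does not contain the inversion.
    """

    name: str
    operators: tuple[tuple[tuple[int, ...], ...], ...]
    friedel: bool = False

    def __post_init__(self):
        ops = {self._key(op) for op in self.matrices}
        ident = self._key(np.eye(3, dtype=int))
        if ident not in ops:
            raise ValueError("operator set must contain the identity")
        for a in self.matrices:
            for b in self.matrices:
                if self._key(a @ b) not in ops:
                    raise ValueError("operator set is not closed under composition")

    @staticmethod
    def _key(m: np.ndarray) -> tuple:
        return tuple(int(x) for x in np.asarray(m).ravel())

    @property
    def matrices(self) -> list[np.ndarray]:
        return [np.array(op, dtype=int) for op in self.operators]

    @property
    def order(self) -> int:
        return len(self.operators) * (2 if self.friedel and not self.has_inversion else 1)

    @property
    def has_inversion(self) -> bool:
        return any(np.array_equal(m, -np.eye(3, dtype=int)) for m in self.matrices)


def point_group_from_operators(name: str, matrices: Iterable, friedel: bool = False) -> PointGroup:
    ops = tuple(tuple(tuple(int(x) for x in row) for row in np.asarray(m)) for m in matrices)
    return PointGroup(name=name, operators=ops, friedel=friedel)


def get_point_group(name: str, friedel: bool = False) -> PointGroup:
    """Look up a supported point group (1, -1, 2/m, mmm, 4/m, 4/mmm, -3, 6/m,
    6/mmm, m-3) as a closed table of integer hkl rotation operators."""
    try:
        sg_name = _PG_SPACEGROUP[name]
    except KeyError:
        raise ValueError(
            f"unsupported point group {name!r}; choose from {sorted(_PG_SPACEGROUP)}"
        ) from None
    sg = gemmi.find_spacegroup_by_name(sg_name)
    seen = set()
    mats = []
    for op in sg.operations():
        m = np.array(op.rot, dtype=int) // gemmi.Op.DEN
        key = PointGroup._key(m)
        if key not in seen:
            seen.add(key)
            mats.append(m)
    return point_group_from_operators(name, mats, friedel=friedel)


def map_to_asu(h: int, k: int, l: int, pg: PointGroup) -> tuple[int, int, int]:
    """Deterministic orbit representative: the lexicographically greatest
    triple over all operator images (and Friedel mates when flagged)."""
    hkl = np.array([h, k, l], dtype=int)
    best = None
    for m in pg.matrices:
        img = hkl @ m
        cands = [img, -img] if pg.friedel else [img]
        for c in cands:
            t = (int(c[0]), int(c[1]), int(c[2]))
            if best is None or t > best:
                best = t
    return best


def map_to_asu_array(hkl: np.ndarray, pg: PointGroup) -> np.ndarray:
    """Vectorized :func:`map_to_asu` for an (n, 3) integer index array."""
    hkl = np.asarray(hkl, dtype=np.int64)
    images = [hkl @ m for m in pg.matrices]
    if pg.friedel:
        images += [-img for img in images]
    stack = np.stack(images)  # (n_images, n, 3)
    big = np.int64(1) << 21
    keys = ((stack[:, :, 0] + big) * (2 * big) + (stack[:, :, 1] + big)) * (2 * big) + (
        stack[:, :, 2] + big
    )
    best = keys.argmax(axis=0)
    return stack[best, np.arange(hkl.shape[0]), :]


def centering_allowed(h: int, k: int, l: int, centering: str) -> bool:
    """Lattice-centering reflection condition (systematic absences)."""
    if centering == "P":
        return True
    if centering == "I":
        return (h + k + l) % 2 == 0
    if centering == "F":
        return h % 2 == k % 2 == l % 2
    if centering == "A":
        return (k + l) % 2 == 0
    if centering == "B":
        return (h + l) % 2 == 0
    if centering == "C":
        return (h + k) % 2 == 0
    if centering == "H":
        return (-h + k + l) % 3 == 0
    raise ValueError(f"unknown centering {centering!r}")


# ---------------------------------------------------------------------------
# Scaling and merging

CrystalKey = tuple[int, int]  # (chunk frame_index, crystal index within chunk)


@dataclass
class ScalingResult:
    scales: dict[CrystalKey, float]
    flagged: list[CrystalKey] = field(default_factory=list)
    n_iterations: int = 0


def _observations(dataset: StreamDataset, pg: PointGroup):
    """Per crystal: asu hkl array and intensity array."""
    out: dict[CrystalKey, tuple[list[tuple[int, int, int]], np.ndarray]] = {}
    for chunk, j, xtal in iter_crystals(dataset):
        if xtal.reflections:
            raw = np.array([(r.h, r.k, r.l) for r in xtal.reflections])
            hkls = [tuple(map(int, row)) for row in map_to_asu_array(raw, pg)]
        else:
            hkls = []
        ints = np.array([r.intensity for r in xtal.reflections], dtype=float)
        out[(chunk.frame_index, j)] = (hkls, ints)
    return out


def scale_crystals(
    dataset: StreamDataset,
    pg: PointGroup,
    n_rounds: int = 3,
    tol: float = 1e-6,
) -> ScalingResult:
    """Per-crystal linear scales by alternating least squares.

    Each round merges with the current scales, then updates every crystal's
    scale as s_j = sum(I_obs * Imerged) / sum(Imerged^2) over its reflections,
    and renormalizes so the mean scale is one. Iteration stops after
    ``n_rounds`` rounds or when the largest relative scale change drops below
    ``tol``. Partiality is fixed at unity. A crystal sharing no reflection
    with the rest of the dataset keeps scale one and is flagged.
    """
    obs = _observations(dataset, pg)
    keys = list(obs)
    if not keys:
        return ScalingResult(scales={}, flagged=[], n_iterations=0)
    scales = {key: 1.0 for key in keys}

    counts: dict[tuple[int, int, int], int] = {}
    for hkls, _ in obs.values():
        for hkl in set(hkls):
            counts[hkl] = counts.get(hkl, 0) + 1
    flagged = [
        key
        for key in keys
        if not any(counts[hkl] > 1 for hkl in obs[key][0]) and len(keys) > 1
    ]
    flagged_set = set(flagged)

    it = 0
    for it in range(1, n_rounds + 1):
        sums: dict[tuple[int, int, int], list[float]] = {}
        for key in keys:
            hkls, ints = obs[key]
            s = scales[key]
            for hkl, intensity in zip(hkls, ints):
                acc = sums.setdefault(hkl, [0.0, 0])
                acc[0] += intensity / s
                acc[1] += 1
        merged = {hkl: total / n for hkl, (total, n) in sums.items()}

        new_scales = {}
        for key in keys:
            if key in flagged_set:
                new_scales[key] = 1.0
                continue
            hkls, ints = obs[key]
            ref = np.array([merged[hkl] for hkl in hkls])
            denom = float(ref @ ref)
            new_scales[key] = float(ints @ ref) / denom if denom > 0 else 1.0
        active = [k for k in keys if k not in flagged_set]
        mean = np.mean([new_scales[k] for k in active]) if active else 1.0
        for key in active:
            new_scales[key] /= mean
        change = max(
            abs(new_scales[k] - scales[k]) / max(abs(scales[k]), 1e-300) for k in keys
        )
        scales = new_scales
        if change < tol:
            break
    return ScalingResult(scales=scales, flagged=flagged, n_iterations=it)


@dataclass(frozen=True)
class MergedReflection:
    hkl_asu: tuple[int, int, int]
    intensity_merged: float
    sigma_merged: float
    n_obs: int

    def __post_init__(self):
        if self.n_obs < 1:
            raise ValueError("n_obs must be >= 1")
        if self.sigma_merged < 0:
            raise ValueError("sigma_merged must be >= 0")


def merge(
    dataset: StreamDataset,
    pg: PointGroup,
    scales: dict[CrystalKey, float] | None = None,
) -> list[MergedReflection]:
    """Monte-Carlo merge: per asu reflection, the mean of scaled observations.

    The merged sigma is the sample standard deviation over observations
    divided by sqrt(n) when n >= 2; a singly-observed reflection falls back
    to its own per-observation sigma (scaled), so n=1 reflections common in
    serial data are not discarded.
    """
    groups: dict[tuple[int, int, int], list[tuple[float, float]]] = {}
    for chunk, j, xtal in iter_crystals(dataset):
        if not xtal.reflections:
            continue
        s = 1.0 if scales is None else scales.get((chunk.frame_index, j), 1.0)
        raw = np.array([(r.h, r.k, r.l) for r in xtal.reflections])
        for r, asu_row in zip(xtal.reflections, map_to_asu_array(raw, pg)):
            asu = tuple(map(int, asu_row))
            groups.setdefault(asu, []).append((r.intensity / s, r.sigma / s))
    out = []
    for hkl in sorted(groups):
        vals = np.array([v for v, _ in groups[hkl]])
        n = len(vals)
        mean = float(vals.mean())
        if n >= 2:
            sig = float(vals.std(ddof=1) / math.sqrt(n))
        else:
            sig = groups[hkl][0][1]
        out.append(MergedReflection(hkl_asu=hkl, intensity_merged=mean, sigma_merged=sig, n_obs=n))
    return out


def split_half_datasets(dataset: StreamDataset) -> tuple[StreamDataset, StreamDataset]:
    """Deterministic half-dataset split by parity of chunk frame_index."""
    even = [c for c in dataset.chunks if c.frame_index % 2 == 0]
    odd = [c for c in dataset.chunks if c.frame_index % 2 == 1]
    return (
        StreamDataset(chunks=even, header=dataset.header),
        StreamDataset(chunks=odd, header=dataset.header),
    )


def _common(half1: Sequence[MergedReflection], half2: Sequence[MergedReflection]):
    d2 = {m.hkl_asu: m.intensity_merged for m in half2}
    pairs = [(m.intensity_merged, d2[m.hkl_asu]) for m in half1 if m.hkl_asu in d2]
    if not pairs:
        raise ValueError("no common reflections between the half-datasets")
    arr = np.array(pairs)
    return arr[:, 0], arr[:, 1]


def rsplit(half1: Sequence[MergedReflection], half2: Sequence[MergedReflection]) -> float:
    """Rsplit = 2^(-1/2) * sum|I1 - I2| / (0.5 * sum(I1 + I2)) over common hkl.

    Returns NaN when the denominator vanishes.
    """
    i1, i2 = _common(half1, half2)
    denom = 0.5 * float((i1 + i2).sum())
    if denom == 0:
        return float("nan")
    return float(2 ** (-0.5) * np.abs(i1 - i2).sum() / denom)


def cc_half(half1: Sequence[MergedReflection], half2: Sequence[MergedReflection]) -> float:
    """Half-set Pearson correlation CC1/2 over common hkl; NaN when fewer than
    three common reflections or either half has zero variance."""
    i1, i2 = _common(half1, half2)
    if len(i1) < 3 or i1.std() == 0 or i2.std() == 0:
        return float("nan")
    return float(np.corrcoef(i1, i2)[0, 1])


# ---------------------------------------------------------------------------
# Completeness and shells


def enumerate_unique_hkl(
    pg: PointGroup,
    cell: UnitCell,
    d_min: float,
    d_max: float = math.inf,
    apply_centering: bool = True,
) -> set[tuple[int, int, int]]:
    """All symmetry-unique reflections with d_min <= d (< d_max), by brute
    force over the index box |h| <= a/d_min etc. (exact because h = s.a)."""
    if d_min <= 0:
        raise ValueError("d_min must be > 0")
    hmax = int(cell.a / d_min) + 1
    kmax = int(cell.b / d_min) + 1
    lmax = int(cell.c / d_min) + 1
    rec = cell.reciprocal_basis()
    uniq: set[tuple[int, int, int]] = set()
    hh, kk, ll = np.meshgrid(
        np.arange(-hmax, hmax + 1), np.arange(-kmax, kmax + 1), np.arange(-lmax, lmax + 1),
        indexing="ij",
    )
    idx = np.stack([hh.ravel(), kk.ravel(), ll.ravel()], axis=1)
    idx = idx[(idx != 0).any(axis=1)]
    svec = idx @ rec
    d = 1.0 / np.linalg.norm(svec, axis=1)
    sel = (d >= d_min) & (d < d_max)
    kept = idx[sel]
    if apply_centering:
        ok = np.array(
            [centering_allowed(int(h), int(k), int(l), cell.centering) for h, k, l in kept]
        )
        kept = kept[ok] if len(kept) else kept
    if len(kept):
        for row in map_to_asu_array(kept, pg):
            uniq.add(tuple(map(int, row)))
    return uniq


def completeness(
    merged: Sequence[MergedReflection],
    pg: PointGroup,
    cell: UnitCell,
    d_min: float,
    d_max: float = math.inf,
) -> tuple[float, float]:
    """(completeness %, redundancy) of a merged list against all possible
    unique reflections in the resolution range."""
    possible = enumerate_unique_hkl(pg, cell, d_min, d_max)
    in_range = [
        m
        for m in merged
        if d_min <= d_spacing(*m.hkl_asu, cell) and d_spacing(*m.hkl_asu, cell) < d_max
    ]
    observed = {m.hkl_asu for m in in_range}
    pct = 100.0 * len(observed & possible) / len(possible) if possible else 0.0
    redundancy = (sum(m.n_obs for m in in_range) / len(observed)) if observed else 0.0
    return pct, redundancy


def _shell_edges(n_shells: int, d_min: float) -> list[tuple[float, float]]:
    """Equal-volume shells in 1/d^3 from infinity down to d_min: list of
    (d_max, d_min) per shell, low resolution first."""
    edges_s3 = np.linspace(0.0, 1.0 / d_min**3, n_shells + 1)
    bounds = [math.inf] + [float((1.0 / s3) ** (1 / 3)) for s3 in edges_s3[1:]]
    return [(bounds[i], bounds[i + 1]) for i in range(n_shells)]


def shell_stats(
    dataset: StreamDataset,
    pg: PointGroup,
    cell: UnitCell,
    n_shells: int,
    d_min: float,
    scales: dict[CrystalKey, float] | None = None,
) -> pd.DataFrame:
    """Per-shell serial figures of merit plus an overall row.

    Shells are contiguous and equal-volume in 1/d^3. Columns: d_max, d_min,
    n_unique, completeness, redundancy, mean_i_over_sigma, rsplit, cc_half.
    A shell with no possible reflection is flagged empty (NaN statistics).
    """
    if n_shells < 1:
        raise ValueError("n_shells must be >= 1")
    merged = merge(dataset, pg, scales)
    h1, h2 = split_half_datasets(dataset)
    m1 = merge(h1, pg, scales)
    m2 = merge(h2, pg, scales)

    rows = []
    shells = _shell_edges(n_shells, d_min) + [(math.inf, d_min)]
    labels = [str(i + 1) for i in range(n_shells)] + ["overall"]
    for (dmax, dmin), label in zip(shells, labels):
        def in_shell(ms):
            return [m for m in ms if dmin <= d_spacing(*m.hkl_asu, cell) and (dmax == math.inf or d_spacing(*m.hkl_asu, cell) < dmax)]

        sm = in_shell(merged)
        s1, s2 = in_shell(m1), in_shell(m2)
        pct, red = completeness(sm, pg, cell, dmin, dmax)
        possible = enumerate_unique_hkl(pg, cell, dmin, dmax)
        snr = (
            float(np.mean([m.intensity_merged / m.sigma_merged for m in sm if m.sigma_merged > 0]))
            if any(m.sigma_merged > 0 for m in sm)
            else float("nan")
        )
        try:
            rs = rsplit(s1, s2)
        except ValueError:
            rs = float("nan")
        try:
            cc = cc_half(s1, s2)
        except ValueError:
            cc = float("nan")
        rows.append(
            {
                "shell": label,
                "d_max": dmax,
                "d_min": dmin,
                "n_unique": len(sm),
                "completeness": pct,
                "redundancy": red,
                "mean_i_over_sigma": snr,
                "rsplit": rs,
                "cc_half": cc,
                "empty": len(possible) == 0,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Diffraction power over time


def diffraction_power_slices(dataset: StreamDataset, n_parts: int) -> pd.DataFrame:
    """Split the stream into equal-chunk contiguous parts (acquisition order
    tracks wall-clock time) and report the mean and best (smallest d)
    per-crystal resolution limit in each part, to reveal dose-dependent decay
    of diffraction power."""
    parts = split_into_parts(dataset, n_parts)
    rows = []
    for j, part in enumerate(parts):
        limits = [x.resolution_limit for _, _, x in iter_crystals(part)]
        if limits:
            rows.append(
                {
                    "part": j + 1,
                    "n_chunks": len(part),
                    "n_crystals": len(limits),
                    "mean_resolution": float(np.mean(limits)),
                    "best_resolution": float(np.min(limits)),
                }
            )
        else:
            warnings.warn(f"part {j + 1} contains no crystals", stacklevel=2)
            rows.append(
                {
                    "part": j + 1,
                    "n_chunks": len(part),
                    "n_crystals": 0,
                    "mean_resolution": float("nan"),
                    "best_resolution": float("nan"),
                }
            )
    return pd.DataFrame(rows)


def merged_to_text(merged: Sequence[MergedReflection]) -> str:
    """Merged intensities as a plain hkl table: h k l I sigma n."""
    lines = ["   h    k    l              I          sigma     n"]
    for m in merged:
        h, k, l = m.hkl_asu
        lines.append(
            f"{h:4d} {k:4d} {l:4d} {m.intensity_merged:14.4f} {m.sigma_merged:14.4f} {m.n_obs:5d}"
        )
    return "\n".join(lines) + "\n"
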