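"""Identification of rotational "wedges" in helical line-scan serial data.

During a serpentine (helical) grid scan the sample translates along lines
while the goniometer rotates continuously, inverting both directions at each
line end. A crystal sitting in the beam for several consecutive frames
therefore yields a short rotation series — a *wedge* — usable as a small
single-crystal dataset. Wedges are found from per-frame spot counts: the
frame with the maximum count marks the crystal center, and adjacent frames
are added while they hold at least a minimum number of spots. Crystals hit
more than once are deduplicated by comparing the unique-axis direction of
overlapping wedges: deviations above 6 degrees mark distinct crystals.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .stream_io import Orientation, StreamDataset

__all__ = [
    "ScanGeometry",
    "FrameSeries",
    "Wedge",
    "CrystalIdentity",
    "FramePosition",
    "frame_to_position",
    "find_centers",
    "grow_wedge",
    "find_wedges",
    "unique_axis_angle",
    "default_unique_axis",
    "wedges_overlap",
    "deduplicate_crystals",
    "export_wedges",
    "manifest_to_tsv",
    "manifest_to_json",
]

DEFAULT_ANGLE_THRESHOLD = 6.0  # degrees between unique axes marking distinct crystals
DEFAULT_MIN_CENTER_COUNT = 20
DEFAULT_MIN_SPOTS = 10


@dataclass(frozen=True)
class ScanGeometry:
    """Layout of a serpentine line scan.

    ``rot_per_frame`` is the magnitude of goniometer rotation per frame in
    degrees; ``h_step`` is the translation between adjacent frames within a
    line and ``v_step`` the spacing between lines, both in micrometers.
    """

    frames_per_line: int
    n_lines: int
    rot_per_frame: float
    serpentine: bool = True
    h_step: float = 1.0
    v_step: float = 1.0

    def __post_init__(self):
        if self.frames_per_line < 1 or self.n_lines < 1:
            raise ValueError("frames_per_line and n_lines must be >= 1")
        if self.rot_per_frame <= 0:
            raise ValueError("rot_per_frame must be > 0")

    @property
    def n_frames(self) -> int:
        return self.frames_per_line * self.n_lines


@dataclass
class FrameSeries:
    """Per-frame spot counts over a scan."""

    spot_counts: np.ndarray
    geometry: ScanGeometry

    def __post_init__(self):
        counts = np.asarray(self.spot_counts, dtype=int)
        if counts.ndim != 1:
            raise ValueError("spot_counts must be one-dimensional")
        if (counts < 0).any():
            raise ValueError("spot counts must be >= 0")
        if len(counts) > self.geometry.n_frames:
            raise ValueError("more frames than the scan geometry covers")
        self.spot_counts = counts

    def __len__(self) -> int:
        return len(self.spot_counts)

    @classmethod
    def from_dataset(cls, dataset: StreamDataset, geometry: ScanGeometry) -> "FrameSeries":
        counts = np.array([c.n_peaks for c in dataset.chunks], dtype=int)
        return cls(spot_counts=counts, geometry=geometry)


@dataclass(frozen=True)
class Wedge:
    """Contiguous frame window on one scan line, centered on the spot-count peak."""

    line_index: int
    start_frame: int
    center_frame: int
    end_frame: int
    rot_per_frame: float

    def __post_init__(self):
        if not self.start_frame <= self.center_frame <= self.end_frame:
            raise ValueError("wedge frames must satisfy start <= center <= end")

    @property
    def n_frames(self) -> int:
        return self.end_frame - self.start_frame + 1

    @property
    def rotation_range(self) -> float:
        return self.n_frames * self.rot_per_frame

    @property
    def frames(self) -> range:
        return range(self.start_frame, self.end_frame + 1)


@dataclass
class CrystalIdentity:
    """A set of wedges attributed to one physical crystal."""

    member_wedges: tuple[int, ...]
    representative_orientation: Orientation


@dataclass(frozen=True)
class FramePosition:
    line_index: int
    index_within_line: int
    rotation_angle: float
    x_um: float
    y_um: float


def frame_to_position(frame_index: int, geometry: ScanGeometry) -> FramePosition:
    """Map an acquisition-order frame index onto the serpentine scan path.

    On even lines the in-line index runs forward and the rotation accumulates
    +rot_per_frame per frame; on odd lines both invert. The rotation angle
    resets to zero at each line start.
    """
    if not 0 <= frame_index < geometry.n_frames:
        raise ValueError(f"frame {frame_index} outside the scan")
    line, raw = divmod(frame_index, geometry.frames_per_line)
    backwards = geometry.serpentine and line % 2 == 1
    idx = geometry.frames_per_line - 1 - raw if backwards else raw
    angle = -raw * geometry.rot_per_frame if backwards else raw * geometry.rot_per_frame
    return FramePosition(
        line_index=line,
        index_within_line=idx,
        rotation_angle=angle,
        x_um=idx * geometry.h_step,
        y_um=line * geometry.v_step,
    )


def find_centers(series: FrameSeries, min_center_count: int = DEFAULT_MIN_CENTER_COUNT) -> list[int]:
    """Local spot-count maxima (candidate crystal centers) within each line.

    A plateau of equal counts yields its earliest frame; maxima are never
    compared across line boundaries. Only frames with at least
    ``min_center_count`` spots qualify.
    """
    if min_center_count < 1:
        raise ValueError("min_center_count must be >= 1")
    counts = series.spot_counts
    fpl = series.geometry.frames_per_line
    centers: list[int] = []
    for line_start in range(0, len(counts), fpl):
        line = counts[line_start : line_start + fpl]
        i = 0
        while i < len(line):
            j = i
            while j + 1 < len(line) and line[j + 1] == line[i]:
                j += 1
            left_ok = i == 0 or line[i - 1] < line[i]
            right_ok = j == len(line) - 1 or line[j + 1] < line[i]
            if left_ok and right_ok and line[i] >= min_center_count:
                centers.append(line_start + i)
            i = j + 1
    return centers


def grow_wedge(
    center: int,
    series: FrameSeries,
    min_spots: int = DEFAULT_MIN_SPOTS,
    claimed: set[int] | None = None,
) -> Wedge:
    """Extend a wedge left and right from its center while frames keep at
    least ``min_spots`` spots, stopping at line boundaries and at frames
    already claimed by a previously grown (stronger) wedge."""
    counts = series.spot_counts
    if counts[center] < min_spots:
        raise ValueError(f"center frame {center} has fewer than {min_spots} spots")
    claimed = claimed if claimed is not None else set()
    fpl = series.geometry.frames_per_line
    line = center // fpl
    line_start = line * fpl
    line_end = min(line_start + fpl, len(counts)) - 1
    start = center
    while start - 1 >= line_start and counts[start - 1] >= min_spots and start - 1 not in claimed:
        start -= 1
    end = center
    while end + 1 <= line_end and counts[end + 1] >= min_spots and end + 1 not in claimed:
        end += 1
    return Wedge(
        line_index=line,
        start_frame=start,
        center_frame=center,
        end_frame=end,
        rot_per_frame=series.geometry.rot_per_frame,
    )


def find_wedges(
    series: FrameSeries,
    min_center_count: int = DEFAULT_MIN_CENTER_COUNT,
    min_spots: int = DEFAULT_MIN_SPOTS,
) -> list[Wedge]:
    """Find centers and grow all wedges, strongest center first.

    Growing in descending order of center spot count (ties: lower frame index
    first) makes frame claiming deterministic when two bumps abut. The
    returned list is sorted by start frame.
    """
    centers = find_centers(series, min_center_count)
    order = sorted(centers, key=lambda f: (-series.spot_counts[f], f))
    claimed: set[int] = set()
    wedges = []
    for center in order:
        if center in claimed:
            continue
        w = grow_wedge(center, series, min_spots, claimed)
        claimed.update(w.frames)
        wedges.append(w)
    return sorted(wedges, key=lambda w: w.start_frame)


def unique_axis_angle(o1: Orientation, o2: Orientation, axis_label: str = "c") -> float:
    """Angle in degrees between one reciprocal axis of two orientations,
    folded as an axis (theta -> min(theta, 180 - theta)), so in [0, 90]."""
    v1 = o1.axis(axis_label)
    v2 = o2.axis(axis_label)
    n1, n2 = np.linalg.norm(v1), np.linalg.norm(v2)
    if n1 < 1e-12 or n2 < 1e-12:
        raise ValueError("zero-length reciprocal axis")
    cosang = abs(float(np.dot(v1, v2)) / (n1 * n2))
    return float(np.degrees(np.arccos(min(cosang, 1.0))))


def default_unique_axis(lattice_type: str) -> str:
    """Conventional unique axis per lattice: c* for hexagonal, trigonal and
    tetragonal lattices, b* for monoclinic. Other lattices have no
    crystallographic unique axis; c* is used with a warning."""
    if lattice_type in {"hexagonal", "trigonal", "tetragonal"}:
        return "c"
    if lattice_type == "monoclinic":
        return "b"
    warnings.warn(
        f"lattice type {lattice_type!r} has no crystallographic unique axis; using c*",
        stacklevel=2,
    )
    return "c"


def wedges_overlap(w1: Wedge, w2: Wedge, geometry: ScanGeometry, mode: str = "frames") -> bool:
    """Do two wedges cover the same crystal position?

    ``frames`` mode tests frame-interval intersection; ``spatial`` mode tests
    whether any two member frames lie within max(h_step, v_step) micrometers
    of each other, which also captures a crystal spanning adjacent lines.
    """
    if mode == "frames":
        return w1.start_frame <= w2.end_frame and w2.start_frame <= w1.end_frame
    if mode == "spatial":
        cutoff = max(geometry.h_step, geometry.v_step)
        p1 = np.array([(p.x_um, p.y_um) for p in (frame_to_position(f, geometry) for f in w1.frames)])
        p2 = np.array([(p.x_um, p.y_um) for p in (frame_to_position(f, geometry) for f in w2.frames)])
        d2 = ((p1[:, None, :] - p2[None, :, :]) ** 2).sum(axis=2)
        return bool((d2 <= cutoff**2 + 1e-9).any())
    raise ValueError(f"unknown overlap mode {mode!r}")


def deduplicate_crystals(
    wedges: Sequence[Wedge],
    orientations: Sequence[Orientation | None],
    geometry: ScanGeometry,
    series: FrameSeries | None = None,
    angle_threshold: float = DEFAULT_ANGLE_THRESHOLD,
    mode: str = "frames",
    axis_label: str = "c",
) -> tuple[list[CrystalIdentity], list[int]]:
    """Group wedges into crystal identities.

    Two wedges are the same crystal when they overlap AND their unique-axis
    directions deviate by at most ``angle_threshold`` degrees; identities are
    the connected components of that relation. Non-overlapping wedges are
    never merged regardless of orientation. Wedges without an orientation are
    excluded with a warning and reported in the second return value.

    The representative orientation of an identity is that of the member wedge
    with the highest center spot count (first member if no series is given).
    """
    if len(wedges) != len(orientations):
        raise ValueError("wedges and orientations must have the same length")
    excluded = [i for i, o in enumerate(orientations) if o is None]
    if excluded:
        warnings.warn(f"{len(excluded)} wedge(s) without orientation excluded", stacklevel=2)
    active = [i for i in range(len(wedges)) if orientations[i] is not None]

    parent = {i: i for i in active}

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for ai in range(len(active)):
        for bi in range(ai + 1, len(active)):
            i, j = active[ai], active[bi]
            if not wedges_overlap(wedges[i], wedges[j], geometry, mode):
                continue
            ang = unique_axis_angle(orientations[i], orientations[j], axis_label)
            if ang <= angle_threshold:
                parent[find(i)] = find(j)

    groups: dict[int, list[int]] = {}
    for i in active:
        groups.setdefault(find(i), []).append(i)

    identities = []
    for members in groups.values():
        members = sorted(members)
        if series is not None:
            rep = max(members, key=lambda i: (series.spot_counts[wedges[i].center_frame], -i))
        else:
            rep = members[0]
        identities.append(
            CrystalIdentity(
                member_wedges=tuple(members),
                representative_orientation=orientations[rep],
            )
        )
    identities.sort(key=lambda ident: ident.member_wedges[0])
    return identities, excluded


# ---------------------------------------------------------------------------
# Manifest export


def export_wedges(
    identities: Iterable[CrystalIdentity],
    wedges: Sequence[Wedge],
    dataset: StreamDataset,
    geometry: ScanGeometry,
) -> list[dict]:
    """Flatten identities into manifest rows suitable for handing the wedges
    to rotation-series processing (one row per member wedge)."""
    by_frame = {c.frame_index: c for c in dataset.chunks}
    rows = []
    for ident_id, ident in enumerate(identities):
        for wedge_id in ident.member_wedges:
            w = wedges[wedge_id]
            missing = [f for f in w.frames if f not in by_frame]
            if missing:
                raise ValueError(f"frame {missing[0]} of wedge {wedge_id} not in dataset")
            rows.append(
                {
                    "identity_id": ident_id,
                    "wedge_id": wedge_id,
                    "line": w.line_index,
                    "start_frame": w.start_frame,
                    "end_frame": w.end_frame,
                    "center_frame": w.center_frame,
                    "start_angle_deg": frame_to_position(w.start_frame, geometry).rotation_angle,
                    "rotation_range_deg": w.rotation_range,
                    "image_ids": [by_frame[f].image_id for f in w.frames],
                }
            )
    return rows


MANIFEST_COLUMNS = [
    "identity_id",
    "wedge_id",
    "line",
    "start_frame",
    "end_frame",
    "center_frame",
    "start_angle_deg",
    "rotation_range_deg",
    "image_ids",
]


def manifest_to_tsv(rows: list[dict]) -> str:
    lines = ["\t".join(MANIFEST_COLUMNS)]
    for row in rows:
        vals = [row[c] for c in MANIFEST_COLUMNS]
        vals[-1] = ",".join(vals[-1])
        lines.append("\t".join(str(v) for v in vals))
    return "\n".join(lines) + "\n"


def manifest_to_json(rows: list[dict]) -> str:
    return json.dumps(rows, indent=2)
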