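"""Reading, writing and slicing of serial-crystallography stream files.

A *stream* is the text product of serial indexing: one *chunk* per detector
frame, each carrying a spot count and zero or more indexed crystals with a
unit cell, a reciprocal-space orientation matrix and a reflection table.
The dialect handled here follows the CrystFEL conventions (cells in nm on
disk, reciprocal vectors in nm^-1); in memory, cell lengths and d-spacings
are kept in Angstrom as is usual in crystallography.
"""

from __future__ import annotations

import io
import math
import warnings
from dataclasses import dataclass, field
from typing import Callable, Iterable, Iterator, TextIO

import numpy as np

__all__ = [
    "UnitCell",
    "Orientation",
    "ReflectionRecord",
    "CrystalRecord",
    "Chunk",
    "StreamDataset",
    "StreamParseError",
    "CellPartition",
    "read_stream",
    "write_stream",
    "select_chunks",
    "split_by_cell",
    "split_into_parts",
    "cells_match",
    "orientation_consistent",
    "iter_crystals",
]

CHUNK_BEGIN = "----- Begin chunk -----"
CHUNK_END = "----- End chunk -----"
CRYSTAL_BEGIN = "--- Begin crystal"
CRYSTAL_END = "--- End crystal"
REFL_HEADER = "h    k    l          I   sigma(I)       peak background  fs/px  ss/px panel"
REFL_START = "Reflections measured after indexing"
REFL_END = "End of reflections"

LATTICE_TYPES = {
    "triclinic",
    "monoclinic",
    "orthorhombic",
    "tetragonal",
    "trigonal",
    "hexagonal",
    "cubic",
}
CENTERINGS = {"P", "A", "B", "C", "I", "F", "H"}


class StreamParseError(ValueError):
    """Raised when a stream file violates the dialect; carries the line number."""

    def __init__(self, message: str, line_number: int | None = None):
        self.line_number = line_number
        if line_number is not None:
            message = f"line {line_number}: {message}"
        super().__init__(message)


@dataclass(frozen=True)
class UnitCell:
    """Crystallographic unit cell; lengths in Angstrom, angles in degrees."""

    a: float
    b: float
    c: float
    alpha: float
    beta: float
    gamma: float
    lattice_type: str = "triclinic"
    centering: str = "P"
    unique_axis_label: str = "none"

    def __post_init__(self):
        for name in ("a", "b", "c"):
            if getattr(self, name) <= 0:
                raise ValueError(f"cell length {name} must be > 0")
        for name in ("alpha", "beta", "gamma"):
            v = getattr(self, name)
            if not 0 < v < 180:
                raise ValueError(f"cell angle {name} must be in (0, 180)")
        if self.lattice_type not in LATTICE_TYPES:
            raise ValueError(f"unknown lattice type {self.lattice_type!r}")
        if self.centering not in CENTERINGS:
            raise ValueError(f"unknown centering {self.centering!r}")
        if self.unique_axis_label not in {"a", "b", "c", "none"}:
            raise ValueError(f"unknown unique axis {self.unique_axis_label!r}")
        try:
            np.linalg.cholesky(self.metric_tensor())
        except np.linalg.LinAlgError as exc:
            raise ValueError("cell parameters give a non-positive-definite metric") from exc

    def metric_tensor(self) -> np.ndarray:
        """Real-space metric tensor G (Angstrom^2)."""
        a, b, c = self.a, self.b, self.c
        ca, cb, cg = (math.cos(math.radians(x)) for x in (self.alpha, self.beta, self.gamma))
        return np.array(
            [
                [a * a, a * b * cg, a * c * cb],
                [a * b * cg, b * b, b * c * ca],
                [a * c * cb, b * c * ca, c * c],
            ]
        )

    def real_basis(self) -> np.ndarray:
        """Rows a, b, c as Cartesian vectors (Angstrom), a along x, b in xy."""
        a, b, c = self.a, self.b, self.c
        al, be, ga = (math.radians(x) for x in (self.alpha, self.beta, self.gamma))
        ca, cb, cg, sg = math.cos(al), math.cos(be), math.cos(ga), math.sin(ga)
        cy = (ca - cb * cg) / sg
        cz = math.sqrt(max(1.0 - cb * cb - cy * cy, 0.0))
        return np.array(
            [
                [a, 0.0, 0.0],
                [b * cg, b * sg, 0.0],
                [c * cb, c * cy, c * cz],
            ]
        )

    def reciprocal_basis(self) -> np.ndarray:
        """Rows a*, b*, c* in Angstrom^-1 (crystallographic convention, a*.a = 1)."""
        return np.linalg.inv(self.real_basis()).T

    def volume(self) -> float:
        return float(np.linalg.det(self.real_basis()))


@dataclass(eq=False)
class Orientation:
    """Reciprocal basis of an indexed crystal: rows a*, b*, c* in nm^-1."""

    reciprocal_basis: np.ndarray

    def __post_init__(self):
        m = np.asarray(self.reciprocal_basis, dtype=float)
        if m.shape != (3, 3):
            raise ValueError("reciprocal basis must be 3x3")
        if abs(np.linalg.det(m)) < 1e-12:
            raise ValueError("reciprocal basis is singular")
        self.reciprocal_basis = m

    def axis(self, label: str) -> np.ndarray:
        """One reciprocal axis vector by label 'a', 'b' or 'c' (trailing * allowed)."""
        idx = {"a": 0, "b": 1, "c": 2}[label.rstrip("*")]
        return self.reciprocal_basis[idx]

    def derived_cell_lengths_angstrom(self) -> tuple[float, float, float]:
        """Real-space axis lengths implied by the matrix, in Angstrom."""
        real_nm = np.linalg.inv(self.reciprocal_basis).T
        lengths = np.linalg.norm(real_nm, axis=1) * 10.0
        return tuple(float(x) for x in lengths)

    def __eq__(self, other) -> bool:
        return isinstance(other, Orientation) and np.array_equal(
            self.reciprocal_basis, other.reciprocal_basis
        )


@dataclass
class ReflectionRecord:
    h: int
    k: int
    l: int
    intensity: float
    sigma: float
    peak_value: float
    background: float
    fs: float
    ss: float
    panel_id: str = "p0"

    def __post_init__(self):
        if self.sigma < 0:
            raise ValueError("sigma must be >= 0")
        if self.fs < 0 or self.ss < 0:
            raise ValueError("detector coordinates must be >= 0")


@dataclass
class CrystalRecord:
    cell: UnitCell
    orientation: Orientation
    resolution_limit: float  # smallest d (Angstrom) to which the crystal diffracts
    reflections: list[ReflectionRecord] = field(default_factory=list)
    extra_lines: list[str] = field(default_factory=list)

    def __post_init__(self):
        if self.resolution_limit <= 0:
            raise ValueError("resolution_limit must be > 0")


@dataclass
class Chunk:
    frame_index: int
    image_id: str
    event_id: str
    n_peaks: int
    crystals: list[CrystalRecord] = field(default_factory=list)
    extra_lines: list[str] = field(default_factory=list)

    def __post_init__(self):
        if self.n_peaks < 0:
            raise ValueError("n_peaks must be >= 0")


@dataclass
class StreamDataset:
    chunks: list[Chunk] = field(default_factory=list)
    header: str = ""

    def __post_init__(self):
        indices = [c.frame_index for c in self.chunks]
        if any(b <= a for a, b in zip(indices, indices[1:])):
            raise ValueError("chunk frame_index must be strictly increasing")

    def __len__(self) -> int:
        return len(self.chunks)

    @property
    def n_crystals(self) -> int:
        return sum(len(c.crystals) for c in self.chunks)


def iter_crystals(dataset: StreamDataset) -> Iterator[tuple[Chunk, int, CrystalRecord]]:
    """Yield (chunk, crystal_index_within_chunk, crystal) over the dataset."""
    for chunk in dataset.chunks:
        for j, xtal in enumerate(chunk.crystals):
            yield chunk, j, xtal


def orientation_consistent(cell: UnitCell, orientation: Orientation, rel_tol: float = 0.02) -> bool:
    """Do the axis lengths implied by the orientation matrix agree with the cell?"""
    derived = orientation.derived_cell_lengths_angstrom()
    stated = (cell.a, cell.b, cell.c)
    return all(abs(d - s) <= rel_tol * s for d, s in zip(derived, stated))


# ---------------------------------------------------------------------------
# Parsing


def _open_source(source) -> TextIO:
    if hasattr(source, "read"):
        return source
    return open(source, "r", encoding="utf-8")


def read_stream(source) -> StreamDataset:
    """Parse a stream file (path or text handle) into a :class:`StreamDataset`.

    Cell lengths are converted from nm (file) to Angstrom (memory); the
    reciprocal orientation vectors stay in nm^-1. Frame indices are assigned
    0-based in file order. Malformed chunk or crystal blocks raise
    :class:`StreamParseError` naming the offending line.
    """
    handle = _open_source(source)
    close = not hasattr(source, "read")
    try:
        lines = handle.read().splitlines()
    finally:
        if close:
            handle.close()

    header_lines: list[str] = []
    chunks: list[Chunk] = []
    i = 0
    n = len(lines)
    while i < n and lines[i].strip() != CHUNK_BEGIN:
        header_lines.append(lines[i])
        i += 1
    header = "\n".join(header_lines)
    if header_lines and header:
        header += "\n"

    while i < n:
        if lines[i].strip() != CHUNK_BEGIN:
            raise StreamParseError(f"expected {CHUNK_BEGIN!r}", i + 1)
        i += 1
        chunk, i = _parse_chunk(lines, i, frame_index=len(chunks))
        chunks.append(chunk)
    return StreamDataset(chunks=chunks, header=header)


def _parse_chunk(lines: list[str], i: int, frame_index: int) -> tuple[Chunk, int]:
    image_id = ""
    event_id = ""
    n_peaks = 0
    crystals: list[CrystalRecord] = []
    extra: list[str] = []
    n = len(lines)
    while i < n:
        raw = lines[i]
        line = raw.strip()
        if line == CHUNK_END:
            return (
                Chunk(
                    frame_index=frame_index,
                    image_id=image_id,
                    event_id=event_id,
                    n_peaks=n_peaks,
                    crystals=crystals,
                    extra_lines=extra,
                ),
                i + 1,
            )
        if line == CHUNK_BEGIN:
            raise StreamParseError("chunk opened before previous one was closed", i + 1)
        if line.startswith("Image filename:"):
            image_id = line.split(":", 1)[1].strip()
        elif line.startswith("Event:"):
            event_id = line.split(":", 1)[1].strip()
        elif line.startswith("num_peaks"):
            n_peaks = int(line.split("=", 1)[1])
        elif line.startswith(CRYSTAL_BEGIN):
            xtal, i = _parse_crystal(lines, i + 1)
            crystals.append(xtal)
            continue
        elif line:
            extra.append(raw)
        i += 1
    raise StreamParseError(f"unterminated chunk (missing {CHUNK_END!r})", n)


def _parse_crystal(lines: list[str], i: int) -> tuple[CrystalRecord, int]:
    cell_nm = None
    lattice_type = "triclinic"
    centering = "P"
    unique_axis = "none"
    stars: dict[str, np.ndarray] = {}
    resolution_limit = None
    reflections: list[ReflectionRecord] = []
    extra: list[str] = []
    n = len(lines)
    while i < n:
        raw = lines[i]
        line = raw.strip()
        if line.startswith(CRYSTAL_END):
            if cell_nm is None:
                raise StreamParseError("crystal block without cell parameters", i + 1)
            for name in ("astar", "bstar", "cstar"):
                if name not in stars:
                    raise StreamParseError(f"crystal block missing {name}", i + 1)
            a, b, c, al, be, ga = cell_nm
            cell = UnitCell(
                a * 10.0,
                b * 10.0,
                c * 10.0,
                al,
                be,
                ga,
                lattice_type=lattice_type,
                centering=centering,
                unique_axis_label=unique_axis,
            )
            xtal = CrystalRecord(
                cell=cell,
                orientation=Orientation(np.array([stars["astar"], stars["bstar"], stars["cstar"]])),
                resolution_limit=resolution_limit if resolution_limit is not None else 1e6,
                reflections=reflections,
                extra_lines=extra,
            )
            return xtal, i + 1
        if line.startswith("Cell parameters"):
            fields = line.replace(",", " ").split()
            try:
                cell_nm = tuple(float(fields[j]) for j in (2, 3, 4, 6, 7, 8))
            except (IndexError, ValueError) as exc:
                raise StreamParseError(f"bad cell parameters line: {line!r}", i + 1) from exc
        elif line.startswith(("astar", "bstar", "cstar")):
            name = line.split("=")[0].strip()
            vals = line.split("=", 1)[1].split()
            stars[name] = np.array([float(v) for v in vals[:3]])
        elif line.startswith("lattice_type"):
            lattice_type = line.split("=", 1)[1].strip()
        elif line.startswith("centering"):
            centering = line.split("=", 1)[1].strip()
        elif line.startswith("unique_axis"):
            unique_axis = line.split("=", 1)[1].strip()
        elif line.startswith("diffraction_resolution_limit"):
            # "... = <v> nm^-1 or <d> A": the Angstrom figure is authoritative
            fields = line.split()
            resolution_limit = float(fields[-2])
        elif line.startswith(REFL_START):
            reflections, i = _parse_reflections(lines, i + 1)
            continue
        elif line:
            extra.append(raw)
        i += 1
    raise StreamParseError(f"unterminated crystal block (missing {CRYSTAL_END!r})", n)


def _parse_reflections(lines: list[str], i: int) -> tuple[list[ReflectionRecord], int]:
    n = len(lines)
    out: list[ReflectionRecord] = []
    if i < n and lines[i].strip().startswith("h "):
        i += 1  # column header
    while i < n:
        line = lines[i].strip()
        if line == REFL_END:
            return out, i + 1
        fields = line.split()
        if len(fields) < 10:
            raise StreamParseError(f"reflection row with {len(fields)} fields", i + 1)
        try:
            h, k, l = (int(fields[j]) for j in range(3))
        except ValueError as exc:
            raise StreamParseError(f"non-integer Miller index in {line!r}", i + 1) from exc
        out.append(
            ReflectionRecord(
                h=h,
                k=k,
                l=l,
                intensity=float(fields[3]),
                sigma=float(fields[4]),
                peak_value=float(fields[5]),
                background=float(fields[6]),
                fs=float(fields[7]),
                ss=float(fields[8]),
                panel_id=fields[9],
            )
        )
        i += 1
    raise StreamParseError(f"unterminated reflection table (missing {REFL_END!r})", n)


# ---------------------------------------------------------------------------
# Writing


def write_stream(dataset: StreamDataset, sink) -> None:
    """Emit the stream dialect; exact inverse of :func:`read_stream` at the
    printed precision (cells back to nm, 7 decimals; intensities %.7e)."""
    handle = sink if hasattr(sink, "write") else open(sink, "w", encoding="utf-8")
    close = not hasattr(sink, "write")
    try:
        handle.write(dataset.header)
        for chunk in dataset.chunks:
            _write_chunk(chunk, handle)
    finally:
        if close:
            handle.close()


def _write_chunk(chunk: Chunk, out: TextIO) -> None:
    out.write(f"{CHUNK_BEGIN}\n")
    out.write(f"Image filename: {chunk.image_id}\n")
    out.write(f"Event: {chunk.event_id}\n")
    out.write(f"num_peaks = {chunk.n_peaks}\n")
    for line in chunk.extra_lines:
        out.write(line + "\n")
    for xtal in chunk.crystals:
        _write_crystal(xtal, out)
    out.write(f"{CHUNK_END}\n")


def _write_crystal(xtal: CrystalRecord, out: TextIO) -> None:
    out.write(f"{CRYSTAL_BEGIN}\n")
    c = xtal.cell
    out.write(
        "Cell parameters %.7f %.7f %.7f nm, %.7f %.7f %.7f deg\n"
        % (c.a / 10.0, c.b / 10.0, c.c / 10.0, c.alpha, c.beta, c.gamma)
    )
    for name, row in zip(("astar", "bstar", "cstar"), xtal.orientation.reciprocal_basis):
        out.write("%s = %+.7f %+.7f %+.7f nm^-1\n" % (name, row[0], row[1], row[2]))
    out.write(f"lattice_type = {c.lattice_type}\n")
    out.write(f"centering = {c.centering}\n")
    out.write(f"unique_axis = {c.unique_axis_label}\n")
    out.write(
        "diffraction_resolution_limit = %.7f nm^-1 or %.7f A\n"
        % (10.0 / xtal.resolution_limit, xtal.resolution_limit)
    )
    for line in xtal.extra_lines:
        out.write(line + "\n")
    out.write(f"{REFL_START}\n")
    out.write(f"   {REFL_HEADER}\n")
    for r in xtal.reflections:
        out.write(
            " %4d %4d %4d %15.7e %15.7e %12.2f %12.2f %8.2f %8.2f %s\n"
            % (r.h, r.k, r.l, r.intensity, r.sigma, r.peak_value, r.background, r.fs, r.ss, r.panel_id)
        )
    out.write(f"{REFL_END}\n")
    out.write(f"{CRYSTAL_END}\n")


def stream_to_text(dataset: StreamDataset) -> str:
    buf = io.StringIO()
    write_stream(dataset, buf)
    return buf.getvalue()


def stream_from_text(text: str) -> StreamDataset:
    return read_stream(io.StringIO(text))


# ---------------------------------------------------------------------------
# Selection and splitting


def select_chunks(dataset: StreamDataset, predicate: Callable[[Chunk], bool]) -> StreamDataset:
    """New dataset holding the chunks for which ``predicate`` is true, in order."""
    return StreamDataset(
        chunks=[c for c in dataset.chunks if predicate(c)], header=dataset.header
    )


def cells_match(
    cell: UnitCell,
    reference: UnitCell,
    axis_rel_tol: float = 0.05,
    angle_abs_tol: float = 1.5,
) -> bool:
    """Axis lengths within a relative tolerance and angles within an absolute one."""
    axes_ok = all(
        abs(getattr(cell, n) - getattr(reference, n)) <= axis_rel_tol * getattr(reference, n)
        for n in ("a", "b", "c")
    )
    angles_ok = all(
        abs(getattr(cell, n) - getattr(reference, n)) <= angle_abs_tol
        for n in ("alpha", "beta", "gamma")
    )
    return axes_ok and angles_ok


@dataclass
class CellPartition:
    """Result of :func:`split_by_cell`: one dataset per reference plus leftovers."""

    matched: list[StreamDataset]
    unassigned: StreamDataset


def split_by_cell(
    dataset: StreamDataset,
    reference_cells: Iterable[UnitCell],
    axis_rel_tol: float = 0.05,
    angle_abs_tol: float = 1.5,
) -> CellPartition:
    """Partition chunks by matching each chunk's first crystal cell against an
    ordered reference list (first match wins). Chunks without crystals, or whose
    first crystal matches no reference, land in ``unassigned``.

    Separating apparent unit-cell populations this way mirrors grep-style
    stream cleaning used to split e.g. two c-axis polymorph populations.
    """
    refs = list(reference_cells)
    if not refs:
        raise ValueError("at least one reference cell is required")
    if axis_rel_tol <= 0 or angle_abs_tol <= 0:
        raise ValueError("tolerances must be > 0")
    bins: list[list[Chunk]] = [[] for _ in refs]
    leftover: list[Chunk] = []
    warned = False
    for chunk in dataset.chunks:
        if not chunk.crystals:
            leftover.append(chunk)
            continue
        cell = chunk.crystals[0].cell
        hits = [
            j for j, ref in enumerate(refs) if cells_match(cell, ref, axis_rel_tol, angle_abs_tol)
        ]
        if len(hits) > 1 and not warned:
            warnings.warn(
                "a cell matches more than one reference; first match wins", stacklevel=2
            )
            warned = True
        if hits:
            bins[hits[0]].append(chunk)
        else:
            leftover.append(chunk)
    return CellPartition(
        matched=[StreamDataset(chunks=b, header=dataset.header) for b in bins],
        unassigned=StreamDataset(chunks=leftover, header=dataset.header),
    )


def split_into_parts(dataset: StreamDataset, n_parts: int) -> list[StreamDataset]:
    """Contiguous parts in original order; sizes differ by at most one, with
    earlier parts taking the remainder (10 chunks in 4 parts -> 3,3,2,2)."""
    n = len(dataset.chunks)
    if not 1 <= n_parts <= n:
        raise ValueError(f"cannot split {n} chunks into {n_parts} parts")
    base, rem = divmod(n, n_parts)
    parts = []
    start = 0
    for j in range(n_parts):
        size = base + (1 if j < rem else 0)
        parts.append(StreamDataset(chunks=dataset.chunks[start : start + size], header=dataset.header))
        start += size
    return parts
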