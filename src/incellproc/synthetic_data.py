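"""Ground-truthed simulators for every processing stage.

The generators emulate the data shapes of an in cellulo serial helical
line-scan experiment — a stream of chunks with spot counts, indexed crystals
and reflection lists; salt-ring outliers; powder detector images; endpoint-
dilution plates — together with an exact truth record, so that every
algorithm in the package can be exercised against known ground truth. They
are pure functions of (parameters, seed). They make no attempt at physical
diffraction realism (no partiality, mosaicity or detector point spread);
their job is to realize the statistical models the algorithms assume.

Default conditions mirror a typical helical-scan acquisition: crystal
footprints of 3-15 frames within one line, spot-count bumps peaking between
30 and 200 over a Poisson background of mean 2, log-normal true intensities
(sigma of log I = 1), per-crystal scales log-uniform in [0.5, 2].
"""

from __future__ import annotations

import copy
import json
import math
import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
from scipy.spatial.transform import Rotation

from .merger import enumerate_unique_hkl, get_point_group
from .powder_fingerprint import DetectorImage, PowderFingerprint
from .reflection_filter import ResolutionBand, d_spacing
from .stream_io import (
    Chunk,
    CrystalRecord,
    Orientation,
    ReflectionRecord,
    StreamDataset,
    UnitCell,
)
from .titer import (
    DEFAULT_INOCULUM_ML,
    DEFAULT_POSITIVITY_THRESHOLD,
    DEFAULT_WELLS_PER_DILUTION,
    TCID50_TO_IU,
    TiterPlate,
    score_wells,
)
from .wedge_finder import ScanGeometry

__all__ = [
    "SimulatedCrystal",
    "SimulationTruth",
    "simulate_scan",
    "inject_salt_rings",
    "simulate_powder_image",
    "simulate_plate",
    "DEFAULT_CELL",
]

# Hexagonal cell of the kind the in-cell crystal systems form (a = b ~ 79,
# c ~ 170 Angstrom); any valid cell may be passed instead.
DEFAULT_CELL = UnitCell(
    79.0, 79.0, 170.0, 90.0, 90.0, 120.0,
    lattice_type="hexagonal", centering="P", unique_axis_label="c",
)


@dataclass
class SimulatedCrystal:
    line: int
    start_frame: int
    end_frame: int
    center_frame: int
    peak_count: int
    scale: float
    orientation: list[list[float]]  # reciprocal basis rows, nm^-1

    @property
    def n_frames(self) -> int:
        return self.end_frame - self.start_frame + 1


@dataclass
class SimulationTruth:
    """Exact record of what a simulation put into a dataset."""

    seed: int
    crystals: list[SimulatedCrystal] = field(default_factory=list)
    intensities: dict[tuple[int, int, int], float] = field(default_factory=dict)
    salt_outliers: list[tuple[int, int, tuple[int, int, int], float]] = field(default_factory=list)
    true_titer_per_ml: float | None = None

    def to_json(self) -> str:
        payload = asdict(self)
        payload["intensities"] = {",".join(map(str, k)): v for k, v in self.intensities.items()}
        payload["salt_outliers"] = [
            [frame, xtal, list(hkl), value] for frame, xtal, hkl, value in self.salt_outliers
        ]
        return json.dumps(payload, indent=2)


def _round_printed(x: float, fmt: str) -> float:
    """Snap a value to the precision the stream writer prints, so that a
    write -> read round trip is bit-exact."""
    return float(format(x, fmt))


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    quat = rng.normal(size=4)
    quat /= np.linalg.norm(quat)
    return Rotation.from_quat(quat).as_matrix()


def simulate_scan(
    geometry: ScanGeometry,
    n_crystals: int = 20,
    cell: UnitCell = DEFAULT_CELL,
    pointgroup: str = "1",
    noise_fraction: float = 0.05,
    seed: int = 0,
    d_min: float = 3.0,
    reflections_per_frame: int = 60,
    scale_range: tuple[float, float] = (0.5, 2.0),
    footprint_frames: tuple[int, int] = (3, 15),
    peak_count_range: tuple[int, int] = (30, 200),
    background_mean: float = 2.0,
    min_spots_in_footprint: int = 10,
    perturb_orientation: bool = False,
    intensity_scale: float = 100.0,
) -> tuple[StreamDataset, SimulationTruth]:
    """Simulate a serpentine helical-scan stream with known crystals.

    Crystals are dropped uniformly at random, one footprint of 3-15 frames
    per crystal within a single line, footprints pairwise disjoint (resampled
    on collision, error after 1000 attempts). Per-frame spot counts are a
    Gaussian bump peaking at the footprint center (peak drawn from
    ``peak_count_range``) on a Poisson background. Frames under a footprint
    carry an indexed crystal: a random orientation applied to the cell's
    reciprocal basis (constant within the footprint unless
    ``perturb_orientation`` adds sub-degree frame-to-frame jitter), and a
    random sample of reflections from a log-normal true intensity table with
    multiplicative Gaussian noise of ``noise_fraction`` and a per-crystal
    scale drawn log-uniformly from ``scale_range``.
    """
    rng = np.random.default_rng(seed)
    pg = get_point_group(pointgroup)
    hkls = sorted(enumerate_unique_hkl(pg, cell, d_min))
    truth_i = {
        hkl: _round_printed(intensity_scale * float(np.exp(rng.normal(0.0, 1.0))), ".7e")
        for hkl in hkls
    }

    n_frames = geometry.n_frames
    occupied: set[int] = set()
    crystals: list[SimulatedCrystal] = []
    rec_nm = cell.reciprocal_basis() * 10.0  # 1/Angstrom -> 1/nm
    for _ in range(n_crystals):
        for attempt in range(1000):
            length = int(rng.integers(footprint_frames[0], footprint_frames[1] + 1))
            if length > geometry.frames_per_line:
                continue
            line = int(rng.integers(0, geometry.n_lines))
            offset = int(rng.integers(0, geometry.frames_per_line - length + 1))
            start = line * geometry.frames_per_line + offset
            end = start + length - 1
            if end >= n_frames:
                continue
            # keep a 2-frame clearance between footprints so neighbouring
            # bumps cannot chain into one apparent wedge
            padded = set(range(start - 2, end + 3))
            if padded & occupied:
                continue
            occupied |= padded
            rot = _random_rotation(rng)
            crystals.append(
                SimulatedCrystal(
                    line=line,
                    start_frame=start,
                    end_frame=end,
                    center_frame=start + (length - 1) // 2,
                    peak_count=int(rng.integers(peak_count_range[0], peak_count_range[1] + 1)),
                    scale=float(np.exp(rng.uniform(np.log(scale_range[0]), np.log(scale_range[1])))),
                    orientation=(rec_nm @ rot.T).tolist(),
                )
            )
            break
        else:
            raise RuntimeError("could not place crystal footprint after 1000 attempts")

    counts = rng.poisson(background_mean, size=n_frames)
    for xtal in crystals:
        width = max(xtal.n_frames / 4.0, 0.8)
        for f in range(xtal.start_frame, xtal.end_frame + 1):
            bump = xtal.peak_count * math.exp(-0.5 * ((f - xtal.center_frame) / width) ** 2)
            counts[f] += max(int(round(bump)), min_spots_in_footprint)

    by_frame: dict[int, SimulatedCrystal] = {}
    for xtal in crystals:
        for f in range(xtal.start_frame, xtal.end_frame + 1):
            by_frame[f] = xtal

    chunks = []
    for f in range(n_frames):
        xtal = by_frame.get(f)
        records = []
        if xtal is not None:
            basis = np.array(xtal.orientation)
            if perturb_orientation:
                jitter = Rotation.from_rotvec(
                    rng.normal(0.0, math.radians(0.3), size=3)
                ).as_matrix()
                basis = basis @ jitter.T
            n_refl = min(reflections_per_frame, len(hkls))
            chosen = rng.choice(len(hkls), size=n_refl, replace=False)
            refls = []
            for ci in sorted(chosen):
                hkl = hkls[ci]
                true_val = truth_i[hkl]
                noisy = true_val * (1.0 + noise_fraction * rng.normal())
                intensity = _round_printed(xtal.scale * noisy, ".7e")
                sigma = _round_printed(xtal.scale * true_val * max(noise_fraction, 0.01), ".7e")
                refls.append(
                    ReflectionRecord(
                        h=hkl[0],
                        k=hkl[1],
                        l=hkl[2],
                        intensity=intensity,
                        sigma=sigma,
                        peak_value=_round_printed(abs(intensity) / 4.0, ".2f"),
                        background=_round_printed(float(rng.uniform(1.0, 5.0)), ".2f"),
                        fs=_round_printed(float(rng.uniform(0.0, 4000.0)), ".2f"),
                        ss=_round_printed(float(rng.uniform(0.0, 4000.0)), ".2f"),
                    )
                )
            records.append(
                CrystalRecord(
                    cell=cell,
                    orientation=Orientation(
                        np.array([[_round_printed(v, ".7f") for v in row] for row in basis])
                    ),
                    resolution_limit=_round_printed(float(rng.uniform(d_min, d_min + 1.5)), ".7f"),
                    reflections=refls,
                )
            )
        chunks.append(
            Chunk(
                frame_index=f,
                image_id=f"scan_{f:05d}.h5",
                event_id=f"//{f}",
                n_peaks=int(counts[f]),
                crystals=records,
            )
        )
    dataset = StreamDataset(chunks=chunks, header="Simulated helical-scan stream\n")
    truth = SimulationTruth(seed=seed, crystals=crystals, intensities=truth_i)
    return dataset, truth


def inject_salt_rings(
    dataset: StreamDataset,
    bands: list[ResolutionBand],
    intensity_multiplier: float = 10.0,
    n_per_band: int = 5,
    seed: int = 0,
) -> tuple[StreamDataset, list[tuple[int, int, tuple[int, int, int], float]]]:
    """Add salt-ring-like outlier reflections to random crystals.

    Each injected reflection sits at a d inside its band and carries a peak
    value of ``intensity_multiplier`` times the dataset's 99th peak-value
    percentile, so it exceeds any threshold chosen between the protein signal
    and the multiplier. Returns a new dataset plus the exact outlier list
    (frame_index, crystal index, hkl, peak value).
    """
    rng = np.random.default_rng(seed)
    peaks = [
        r.peak_value
        for c in dataset.chunks
        for x in c.crystals
        for r in x.reflections
    ]
    if not peaks:
        raise ValueError("dataset has no reflections to calibrate against")
    p99 = float(np.percentile(peaks, 99))
    value = _round_printed(intensity_multiplier * p99, ".2f")

    sites = [
        (ci, xi)
        for ci, chunk in enumerate(dataset.chunks)
        for xi in range(len(chunk.crystals))
    ]
    if not sites:
        raise ValueError("dataset has no crystals")

    new = copy.deepcopy(dataset)
    outliers = []
    for bi, band in enumerate(bands):
        for _ in range(n_per_band):
            ci, xi = sites[int(rng.integers(0, len(sites)))]
            xtal = new.chunks[ci].crystals[xi]
            hkl = _hkl_in_band(xtal.cell, band, rng)
            refl = ReflectionRecord(
                h=hkl[0],
                k=hkl[1],
                l=hkl[2],
                intensity=value,
                sigma=_round_printed(value * 0.01, ".7e"),
                peak_value=value,
                background=2.0,
                fs=_round_printed(float(rng.uniform(0, 4000)), ".2f"),
                ss=_round_printed(float(rng.uniform(0, 4000)), ".2f"),
            )
            xtal.reflections.append(refl)
            outliers.append((new.chunks[ci].frame_index, xi, hkl, value))
    return new, outliers


def _hkl_in_band(cell: UnitCell, band: ResolutionBand, rng: np.random.Generator) -> tuple[int, int, int]:
    hmax = int(cell.a / band.d_min) + 1
    kmax = int(cell.b / band.d_min) + 1
    lmax = int(cell.c / band.d_min) + 1
    candidates = []
    for h in range(-hmax, hmax + 1):
        for k in range(-kmax, kmax + 1):
            for l in range(-lmax, lmax + 1):
                if (h, k, l) == (0, 0, 0):
                    continue
                if band.contains(d_spacing(h, k, l, cell)):
                    candidates.append((h, k, l))
    if not candidates:
        raise ValueError(f"no reflection of this cell falls in band {band}")
    return candidates[int(rng.integers(0, len(candidates)))]


def simulate_powder_image(
    fingerprint: PowderFingerprint,
    shape: tuple[int, int] = (512, 512),
    pixel_size_mm: float = 0.2,
    distance_mm: float = 300.0,
    wavelength_angstrom: float = 1.0,
    beam_center_px: tuple[float, float] | None = None,
    ring_width_px: float = 2.0,
    background_level: float = 10.0,
    ring_amplitude: float = 50.0,
    seed: int = 0,
) -> DetectorImage:
    """Render a fingerprint as radially symmetric Gaussian annuli on a flat
    background with Poisson noise. Rings falling outside the detector are
    skipped with a warning."""
    rng = np.random.default_rng(seed)
    if beam_center_px is None:
        beam_center_px = ((shape[0] - 1) / 2.0, (shape[1] - 1) / 2.0)
    image = DetectorImage(
        data=np.zeros(shape),
        pixel_size_mm=pixel_size_mm,
        beam_center_px=beam_center_px,
        distance_mm=distance_mm,
        wavelength_angstrom=wavelength_angstrom,
    )
    rows, cols = np.indices(shape)
    r_px = np.hypot(rows - beam_center_px[0], cols - beam_center_px[1])
    expected = np.full(shape, float(background_level))
    r_max = r_px.max()
    for peak in fingerprint.peaks:
        try:
            radius = image.radius_px_for_s(peak.s_nm_inv)
        except ValueError:
            radius = math.inf
        if radius > r_max:
            warnings.warn(f"ring at s = {peak.s_nm_inv:.3f} nm^-1 outside detector; skipped")
            continue
        expected += (
            ring_amplitude
            * peak.multiplicity
            * np.exp(-0.5 * ((r_px - radius) / ring_width_px) ** 2)
        )
    image.data = rng.poisson(expected).astype(float)
    return image


def simulate_plate(
    true_titer_per_ml: float,
    dilution_log10: list[float] | None = None,
    wells_per_dilution: int = DEFAULT_WELLS_PER_DILUTION,
    inoculum_volume_ml: float = DEFAULT_INOCULUM_ML,
    positivity_threshold_cells: int = DEFAULT_POSITIVITY_THRESHOLD,
    spread_mean: float = 10.0,
    seed: int = 0,
) -> TiterPlate:
    """Simulate an endpoint-dilution plate from a known titer.

    Initial infections per well are Poisson with mean
    0.69 x titer x inoculum x 10^dilution (TCID50 converted to infectious
    units). By scoring time the infection has spread, so each initial
    infection shows as 1 + Poisson(``spread_mean``) fluorescent cells —
    which is why the two-fluorescent-cell positivity rule effectively scores
    "any infection" while rejecting single-cell artifacts.
    """
    if true_titer_per_ml <= 0:
        raise ValueError("titer must be > 0")
    if dilution_log10 is None:
        dilution_log10 = [-2.0 - i for i in range(8)]
    rng = np.random.default_rng(seed)
    counts_rows = []
    for x in dilution_log10:
        lam = TCID50_TO_IU * true_titer_per_ml * inoculum_volume_ml * 10.0**x
        row = []
        for _ in range(wells_per_dilution):
            initial = rng.poisson(lam)
            fluorescent = int(initial + rng.poisson(spread_mean * initial)) if initial else 0
            row.append(fluorescent)
        counts_rows.append(row)
    positives = score_wells(counts_rows, threshold=positivity_threshold_cells)
    return TiterPlate(
        dilution_log10=list(dilution_log10),
        positive_wells=positives,
        wells_per_dilution=wells_per_dilution,
        inoculum_volume_ml=inoculum_volume_ml,
        positivity_threshold_cells=positivity_threshold_cells,
    )
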