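# Methods

This note documents the models and procedures implemented by `incellproc`,
the choices made where the design was genuinely open, and what the
synthetic-data generators do and do not emulate.

## Stream model and units

A serial dataset is a list of chunks, one per detector frame in acquisition
order, each holding a spot count and zero or more indexed crystals (unit
cell, reciprocal orientation matrix, reflection table). Following the
CrystFEL convention, cell lengths are stored in nm in the file and converted
to Å in memory; reciprocal vectors stay in nm⁻¹. Frame indices are assigned
0-based in file order when no explicit serial number exists, because the
wedge finder needs a dense acquisition order. Unknown lines inside chunk and
crystal blocks are preserved verbatim and re-emitted, since real streams
carry per-facility extras.

The writer uses fixed printed precisions (cells %.7f nm, orientation
components %.7f nm⁻¹, intensities and sigmas %.7e, pixel coordinates %.2f).
A write→read cycle is bit-identical for any dataset whose values are exact
at those precisions; the generators snap their outputs accordingly, so the
round-trip invariant is checked with exact equality rather than tolerances.

Unit-cell population splitting (`split_by_cell`) matches each chunk's first
crystal against an ordered reference list, first match wins, with defaults
of 5 % relative on axis lengths and 1.5° absolute on angles. First-match
semantics are deterministic and mirror grep-style stream cleaning; a cell
matching two references triggers a warning.

## Wedge identification

Within each scan line, candidate crystal centers are strict-then-plateau
local maxima of the spot count (a plateau yields its earliest frame; maxima
are never compared across line boundaries) with at least `min_center_count`
spots. Wedges grow outward from each center while frames hold at least
`min_spots` spots, stopping at line boundaries and at frames already claimed
by a previously grown wedge. Growth order is descending center spot count
(ties: lower frame index), which makes claiming deterministic. A direct
consequence of this rule set is that one contiguous supra-threshold run
yields exactly one wedge: a weaker local maximum inside the run is absorbed
by the stronger wedge before its own turn. The thresholds default to 20
(center) and 10 (member frames); both are free parameters of the experiment
— spot-count scales depend on the upstream spot finder — and are therefore
explicit arguments everywhere.

Deduplication builds a graph over wedges with an edge where two wedges
overlap *and* their unique reciprocal axes deviate by at most 6° (folded to
[0°, 90°] since reciprocal axes are directionless); connected components are
crystal identities. Non-overlapping wedges never merge regardless of
orientation. Two overlap notions are provided: frame-interval intersection
(default, the conservative literal reading) and spatial proximity of member
frames within one scan step, which also catches a crystal spanning adjacent
lines — the serpentine path maps frame order to positions, inverting
direction and rotation sign on odd lines. The unique axis defaults to c\*
for hexagonal/trigonal/tetragonal lattices and b\* for monoclinic; other
lattices have no crystallographic unique axis, so the choice is configurable
and warned about.

## Salt-ring filtering

Salt precipitates in and around cells add powder rings whose spots are
indexed and integrated as if they were protein reflections. Because they are
far more intense at a given resolution, they are visible in the peakogram
(2-D histogram of 1/d against log₁₀ peak intensity, non-positive peaks
excluded and counted separately). Filtering removes a reflection when its d
falls in a user-chosen band [d_min, d_max) and its *peak* value (the
literal "maximum reflection intensity"; integrated intensity optionally)
exceeds the band's ceiling. Bands are half-open so adjacent bands partition
cleanly. Ceilings are chosen by the user off the peakogram, as in practice;
a helper proposes the q-th intensity quantile per band (default 0.999) as a
starting point. Crystals and chunks survive even if emptied, preserving
chunk bookkeeping.

Per-crystal resolution limits are estimated from the I/σ falloff in 0.02 Å⁻¹
shells walked from low resolution; the limit is the center d of the last
contiguous shell with mean I/σ at or above the cutoff (default 1.0), and the
result is undefined (None) when no shell qualifies.

## Scaling, merging and figures of merit

Symmetry reduction maps each (h, k, l) to the lexicographically greatest
triple over its point-group orbit (plus Friedel mates when enabled) — an
arbitrary but deterministic asymmetric-unit convention. Operator tables for
1, -1, 2/m, mmm, 4/m, 4/mmm, -3, 6/m, 6/mmm and m-3 are derived from the
corresponding symmorphic primitive space groups and validated for closure;
arbitrary groups can be supplied as matrices.

Per-crystal scales come from alternating least squares under a *unity*
partiality model: merge with current scales, then set each crystal's scale
to s_j = Σ(I_obs·Ī)/Σ(Ī²) over its reflections, renormalize to mean 1, and
iterate (default 3 rounds, stopping when the largest relative change falls
below 1e-6; more rounds and tighter tolerances are available and used where
near-exact convergence is wanted). A crystal sharing no reflection with the
rest keeps scale 1 and is flagged. Merging averages scaled observations per
unique reflection; the merged sigma is the sample standard deviation over
√n for n ≥ 2, falling back to the observation's own sigma for n = 1 so that
singly-observed reflections, common in serial data, are kept.

Half-datasets for Rsplit and CC½ are formed by parity of the chunk frame
index — deterministic and close to common practice. Shell tables use
equal-volume shells in 1/d³; completeness counts observed unique reflections
against a brute-force enumeration over the index box |h| ≤ a/d_min (exact,
since h = **s**·**a**), applying lattice-centering absences. Per-crystal
resolution cutoffs are honored as-is; "push-res"-style extensions are out of
scope. Diffraction power over time splits the stream into contiguous
equal-chunk parts (earlier parts take the remainder) and reports the mean
and best per-crystal resolution limit per part.

## Powder fingerprints

Ring positions are reported as s = 4π sin θ/λ = 2π/d, in nm⁻¹ (s = 20π/d
with d in Å) to match synchrotron SAXS axes. Enumeration is brute force over
the exact index box, keeps indices passing the lattice-centering reflection
condition (P/A/B/C/I/F/H), and groups indices of equal d within 1e-6
relative into one ring whose multiplicity is the group size. Only centering
absences are modeled and intensities default to multiplicity × 1: ring
*positions* are the fingerprint signal; structure factors and
Lorentz-polarization would only modulate heights. Fingerprint comparison —
greedy globally-nearest matching within an s tolerance, scored as
matched/max(n₁, n₂) — is this package's operationalization of
"similar/diverse fingerprints"; no quantitative score is inherited from
elsewhere.

Radial averaging computes per-pixel s from the flat-detector geometry
(θ = ½·atan(r/D)) and averages unmasked pixels per s bin. Background
subtraction replaces each pixel by max(0, p − f·⟨p⟩_window) with a square
moving-average window and f defaulting to 0.90, which flattens diffuse
cellular scatter while keeping faint rings.

## Titer and dosing

A well is positive with ≥ 2 fluorescent cells (one cell could be an
artifact). Spearman–Kärber is the default endpoint estimator: with x₁₀₀ the
log₁₀ dilution of the last row of the initial fully-positive run, d the
dilution step and S the sum of positive proportions from that row on,
m = x₁₀₀ − d(S − 0.5) and TCID₅₀/mL = 10^(−m)/V_inoc. The endpoint must be
bracketed by a fully positive and a fully negative row. Reed–Muench is
available behind a method flag and the method used is recorded in the
result. Dosing uses V = MOI·cells/(0.69·TCID₅₀ mL⁻¹); 0.69 ≈ ln 2 converts
TCID₅₀ to infectious units via the Poisson 50 % endpoint. Callers supply
final per-well log₁₀ dilutions (including any pre-dilution and plating
step) to avoid hidden conventions.

## Structure comparison

Cα sets are read from PDB/mmCIF (atom name CA; altloc resolved to highest
occupancy, ties to 'A') and paired on (chain, residue number) with an
optional numbering offset. Superposition is a proper-rotation Kabsch fit
over all common Cα; per-residue deviations and windowed maxima (e.g. a loop)
are computed *after* the global fit, not from a local fit, so that reported
loop deviations measure genuine conformational difference against the
globally aligned frame. A "mean RMSD" across several structures is the
arithmetic mean of their global Cα RMSDs versus the common reference.

## Synthetic data: what it emulates, and what it does not

`simulate_scan` emulates the shape of helical-scan serial data: crystals
dropped uniformly at random, one footprint of 3–15 frames within a single
line (footprints kept ≥ 2 frames apart so neighbouring bumps cannot chain
into one apparent wedge), Gaussian spot-count bumps peaking at 30–200 over a
Poisson background of mean 2, log-normal true intensities (σ_log I = 1,
median 100), per-crystal scales log-uniform in [0.5, 2], multiplicative
Gaussian intensity noise, and a constant random orientation per footprint
(optional sub-degree frame-to-frame jitter). It does **not** model
diffraction physics — no partiality, mosaicity, spot shape, detector point
spread or absorption — so passing tests demonstrate the correctness of the
algorithms under their stated statistical assumptions, not performance on
real detector data. `inject_salt_rings` adds outlier reflections at 10× the
dataset's 99th peak percentile inside chosen bands and records them exactly.
`simulate_powder_image` renders Gaussian annuli plus flat background and
Poisson noise. `simulate_plate` draws initial infections per well as
Poisson(0.69·titer·V·10^x) and lets each spread to 1 + Poisson(10)
fluorescent cells by scoring time; modelling the spread matters, because
scoring the *initial* count against the ≥ 2-cell rule would bias the
recovered titer by +log₁₀(1.678/0.69) ≈ +0.39, whereas with spread the rule
effectively scores "any infection" and the measured bias is ≈ +0.08 log₁₀.
All generators are pure functions of (parameters, seed).

## Problem sizes and numerical choices

The test suite and the acceptance script use 2000-frame scans with 20
crystals (10 seeds) for wedge recovery, 200 random instances of ≤ 50 wedges
for the dedup oracle, ~400-frame scans with 6–10 crystals for merging
statistics, 100 random triclinic cells for ring enumeration, 1000 simulated
plates for titer recovery, and 1000 small random datasets for the stream
round trip — sizes chosen to give stable statistics in seconds on one CPU.
Degenerate inputs follow explicit conventions: (0,0,0) has no d-spacing;
Rsplit/CC½ return NaN on vanishing denominators or variance; resolution
limits are None when no shell passes; an unbracketed titration plate is an
error naming the missing side; superposition requires ≥ 3 non-collinear
pairs.

## Known limitations

No geometry refinement, indexing, partiality modelling, MTZ export or
anomalous statistics; stream support targets the documented dialect, not
every CrystFEL version; powder intensities are multiplicity-weighted only;
screw-axis/glide absences require a user-supplied operator set; the dedup
overlap modes bracket, but do not assert, how "overlapping" was defined in
any particular upstream script.
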