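# incellproc

Processing toolkit for **in cellulo serial crystallography**: diffraction
data collected by scanning X-rays across living cells that have grown
protein micro-crystals inside them (for example baculovirus-infected insect
cells producing HEX-1 or IMPDH crystals).

During a *serial helical line scan* the sample translates along lines while
the goniometer rotates continuously, inverting both directions at each line
end. Each detector frame becomes one *chunk* of a CrystFEL-style text
stream; a crystal that stays in the beam for a few consecutive frames yields
a short rotation series — a *wedge*. This package covers the computational
stages between that stream and a merged reflection list, plus the assay
arithmetic around the experiment:

- **stream_io** — read/write/select/split stream files (chunks, indexed
  crystals, reflection tables; cells in nm on disk, Å in memory).
- **wedge_finder** — find wedges from per-frame spot counts (the maximum
  marks the crystal center; adjacent frames join while they hold a minimum
  spot count) and deduplicate crystals hit more than once: overlapping
  wedges whose unique reciprocal axes deviate by more than 6° are distinct
  crystals.
- **reflection_filter** — per-reflection resolution d = 1/|h**a**\* +
  k**b**\* + l**c**\*|, peakogram (resolution vs. log₁₀ peak intensity), and
  removal of salt powder-ring reflections by resolution-dependent intensity
  ceilings.
- **merger** — point-group reduction to the asymmetric unit, per-crystal
  scaling by alternating least squares (partiality fixed at unity),
  Monte-Carlo merging, and serial figures of merit
  Rsplit = 2^(−1/2)·Σ|I₁−I₂| / (½Σ(I₁+I₂)) and CC½ (half-set Pearson),
  with completeness/redundancy/⟨I/σ⟩ per equal-volume resolution shell, and
  diffraction-power-over-time slicing.
- **powder_fingerprint** — Debye-Scherrer ring prediction at
  s = 4π sin θ/λ = 2π/d (reported in nm⁻¹), azimuthal averaging of detector
  images, 90 %-moving-average background subtraction, and fingerprint
  comparison for polymorph discrimination.
- **titer** — endpoint-dilution TCID₅₀ (Spearman–Kärber, Reed–Muench
  optional), the dosing rule *V*[mL] = MOI·cells / (0.69·TCID₅₀ mL⁻¹), and
  amplification factors.
- **struct_compare** — Cα Kabsch superposition, global RMSD and per-residue
  deviations (e.g. loop maxima) between PDB/mmCIF structures.
- **synthetic_data** — ground-truthed simulators for every stage (scans,
  salt rings, powder images, titration plates), used throughout the tests.

## Worked example

Simulate a 2000-frame serpentine scan with 20 hidden crystals, find and
deduplicate the wedges, and merge:

```sh
incellproc simulate scan --frames-per-line 100 --n-lines 20 \
    --rot-per-frame 0.1 --n-crystals 20 --dmin 6.0 --seed 1 \
    --out scan.stream --truth-out truth.json
incellproc wedges scan.stream --frames-per-line 100 --n-lines 20 \
    --rot-per-frame 0.1 --out manifest.tsv
incellproc merge scan.stream --out merged.hkl
```

which prints

```
scan.stream: 2000 chunks, 222 crystal records
20 wedges -> 20 unique crystals
9349 unique reflections from 222 crystals
```

— 222 frames carry an indexed crystal, they group into 20 wedges, each a
distinct crystal identity (none overlap, so none merge), and merging the
scaled observations yields 9349 symmetry-unique intensities. The manifest
lists, per identity and wedge, the frame range, starting angle and rotation
range ready for rotation-series processing.

The same arithmetic from Python:

```python
from incellproc import TiterPlate, tcid50, volume_for_moi

plate = TiterPlate(dilution_log10=[-2, -3, -4, -5, -6, -7, -8, -9],
                   positive_wells=[6, 6, 6, 6, 3, 0, 0, 0])
result = tcid50(plate)           # 5.0e7 TCID50/mL
volume_for_moi(1.0, 1e6, result.tcid50_per_ml)   # 0.029 mL of stock
```

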