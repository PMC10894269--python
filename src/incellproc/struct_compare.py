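"""C-alpha superposition and RMSD between crystal structures.

Used to ask how a structure solved from crystals grown inside living cells
compares to a conventionally determined reference: a global least-squares
rigid-body superposition over the shared C-alpha atoms gives the overall
RMSD, and per-residue deviations after that global fit localize genuine
conformational differences (e.g. a flexible loop) rather than fitting them
away with a local alignment.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import gemmi
import numpy as np

__all__ = [
    "CalphaSet",
    "PairingResult",
    "read_calpha",
    "pair_by_residue",
    "superpose",
    "SuperpositionResult",
    "per_residue_deviation",
    "window_max_deviation",
]


@dataclass
class CalphaSet:
    """Ordered C-alpha records: (chain id, residue number, residue name, xyz)."""

    chain_ids: list[str]
    residue_numbers: list[int]
    residue_names: list[str]
    coords: np.ndarray  # (n, 3) Angstrom

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float)
        n = len(self.chain_ids)
        if not (len(self.residue_numbers) == len(self.residue_names) == n == len(self.coords)):
            raise ValueError("all record fields must have equal length")
        if not np.isfinite(self.coords).all():
            raise ValueError("coordinates must be finite")
        keys = list(zip(self.chain_ids, self.residue_numbers))
        if len(set(keys)) != len(keys):
            raise ValueError("(chain, residue number) pairs must be unique")

    def __len__(self) -> int:
        return len(self.chain_ids)

    def keys(self) -> list[tuple[str, int]]:
        return list(zip(self.chain_ids, self.residue_numbers))


def read_calpha(path: str, chains: list[str] | None = None) -> CalphaSet:
    """Extract C-alpha atoms from a PDB or mmCIF file (first model).

    Alternate locations resolve to the highest occupancy, ties to altloc 'A'.
    """
    structure = gemmi.read_structure(str(path))
    structure.setup_entities()
    model = structure[0]
    chain_ids, resnums, resnames, xyz = [], [], [], []
    for chain in model:
        if chains is not None and chain.name not in chains:
            continue
        for residue in chain:
            best = None
            for atom in residue:
                if atom.name != "CA":
                    continue
                altloc = atom.altloc if atom.altloc not in ("", "\x00") else "A"
                rank = (atom.occ, -ord(altloc))
                if best is None or rank > best[0]:
                    best = (rank, atom)
            if best is not None:
                atom = best[1]
                chain_ids.append(chain.name)
                resnums.append(residue.seqid.num)
                resnames.append(residue.name)
                xyz.append([atom.pos.x, atom.pos.y, atom.pos.z])
    return CalphaSet(chain_ids, resnums, resnames, np.array(xyz).reshape(-1, 3))


@dataclass
class PairingResult:
    pairs: list[tuple[int, int]]
    n_unmatched_a: int
    n_unmatched_b: int


def pair_by_residue(a: CalphaSet, b: CalphaSet, offset: int = 0) -> PairingResult:
    """Match records on (chain, residue number); ``offset`` is added to B's
    residue numbers first, recovering pairs across shifted numbering."""
    index_b = {(c, r + offset): i for i, (c, r) in enumerate(b.keys())}
    pairs = [(i, index_b[key]) for i, key in enumerate(a.keys()) if key in index_b]
    if not pairs:
        raise ValueError("no common (chain, residue) keys between the structures")
    return PairingResult(
        pairs=pairs,
        n_unmatched_a=len(a) - len(pairs),
        n_unmatched_b=len(b) - len(pairs),
    )


@dataclass
class SuperpositionResult:
    rotation: np.ndarray  # (3,3), proper (det = +1)
    translation: np.ndarray  # (3,)
    rmsd: float

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return coords @ self.rotation.T + self.translation


def superpose(a: CalphaSet, b: CalphaSet, pairs: list[tuple[int, int]]) -> SuperpositionResult:
    """Least-squares rigid-body superposition of B onto A over the pairs
    (Kabsch algorithm); the returned rotation is always proper."""
    if len(pairs) < 3:
        raise ValueError("at least 3 pairs required")
    pa = a.coords[[i for i, _ in pairs]]
    pb = b.coords[[j for _, j in pairs]]
    ca, cb = pa.mean(axis=0), pb.mean(axis=0)
    xa, xb = pa - ca, pb - cb
    if np.linalg.matrix_rank(xa, tol=1e-8) < 2 or np.linalg.matrix_rank(xb, tol=1e-8) < 2:
        raise ValueError("paired atoms are collinear; superposition is degenerate")
    h = xb.T @ xa
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    rotation = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    translation = ca - rotation @ cb
    moved = pb @ rotation.T + translation
    rmsd = float(np.sqrt(((moved - pa) ** 2).sum(axis=1).mean()))
    return SuperpositionResult(rotation=rotation, translation=translation, rmsd=rmsd)


def per_residue_deviation(
    a: CalphaSet,
    b: CalphaSet,
    pairs: list[tuple[int, int]],
    superposition: SuperpositionResult,
) -> list[tuple[tuple[str, int], float]]:
    """Per-pair C-alpha distance after applying the (global) superposition to
    B; keyed by A's (chain, residue number)."""
    moved = superposition.apply(b.coords)
    out = []
    for i, j in pairs:
        dist = float(np.linalg.norm(a.coords[i] - moved[j]))
        out.append(((a.chain_ids[i], a.residue_numbers[i]), dist))
    return out


def window_max_deviation(
    deviations: list[tuple[tuple[str, int], float]],
    start_residue: int,
    end_residue: int,
    chain: str | None = None,
) -> float:
    """Largest deviation over residues in [start, end] inclusive, optionally
    restricted to one chain; errors if the window covers no paired residue."""
    vals = [
        d
        for (c, r), d in deviations
        if start_residue <= r <= end_residue and (chain is None or c == chain)
    ]
    if not vals:
        raise ValueError(f"no paired residues in window [{start_residue}, {end_residue}]")
    return max(vals)
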