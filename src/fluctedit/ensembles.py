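"""Distance-distribution analysis of structural snapshot ensembles.

Post-processing of simulation snapshots stored as multi-model PDB files: per
frame Cα–Cα distances between two residues, and a nonparametric comparison of
two such distance series (median shift plus a two-sided Mann–Whitney U test).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .models import InvalidInputError


class MissingAtomError(KeyError):
    """A requested atom is absent from one or more frames."""


@dataclass
class SnapshotEnsemble:
    """Coordinate frames sharing one atom roster.

    ``atom_index`` maps (chain, residue_number, atom_name) -> column in
    ``coordinates`` (shape: frames x atoms x 3, Å).
    """

    atom_index: dict
    coordinates: np.ndarray

    def __post_init__(self) -> None:
        self.coordinates = np.asarray(self.coordinates, dtype=float)
        if self.coordinates.ndim != 3 or self.coordinates.shape[2] != 3:
            raise InvalidInputError("coordinates must have shape (frames, atoms, 3)")
        if self.n_frames < 2:
            raise InvalidInputError("ensemble needs >= 2 frames")
        if self.coordinates.shape[1] != len(self.atom_index):
            raise InvalidInputError("atom_index/coordinate column mismatch")

    @property
    def n_frames(self) -> int:
        return self.coordinates.shape[0]

    @classmethod
    def from_pdb(cls, path) -> "SnapshotEnsemble":
        """Read a multi-model PDB (one frame per MODEL); altloc '' or 'A' only."""
        from Bio.PDB import PDBParser

        structure = PDBParser(QUIET=True).get_structure("ens", path)
        frames = []
        roster = None
        for model in structure:
            atoms = {}
            for chain in model:
                for residue in chain:
                    het, resnum, _ = residue.get_id()
                    if het.strip():
                        continue
                    for atom in residue:
                        if atom.get_altloc() not in (" ", "", "A"):
                            continue
                        atoms[(chain.id, resnum, atom.get_name())] = atom.get_coord()
            keys = frozenset(atoms)
            if roster is None:
                roster = keys
            elif keys != roster:
                raise InvalidInputError("frames do not share one atom roster")
            frames.append(atoms)
        if roster is None or len(frames) < 2:
            raise InvalidInputError(f"{path}: need >= 2 MODEL frames")
        index = {key: i for i, key in enumerate(sorted(roster))}
        coords = np.empty((len(frames), len(index), 3))
        for fi, atoms in enumerate(frames):
            for key, i in index.items():
                coords[fi, i] = atoms[key]
        return cls(atom_index=index, coordinates=coords)

    def to_pdb(self, path) -> None:
        """Write frames as MODEL/ENDMDL records (CA-style minimal PDB text)."""
        lines = []
        keys = sorted(self.atom_index, key=self.atom_index.get)
        for fi in range(self.n_frames):
            lines.append(f"MODEL     {fi + 1:4d}")
            serial = 1
            for chain, resnum, name in keys:
                x, y, z = self.coordinates[fi, self.atom_index[(chain, resnum, name)]]
                element = name[0]
                lines.append(
                    f"ATOM  {serial:5d} {name:^4s} ALA {chain}{resnum:4d}    "
                    f"{x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00          {element:>2s}")
                serial += 1
            lines.append("ENDMDL")
        lines.append("END")
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("\n".join(lines) + "\n")


def _parse_res(res) -> tuple:
    """Accept 'H:29' / ('H', 29) residue references."""
    if isinstance(res, str):
        chain, num = res.split(":")
        # tolerate an amino-acid letter as in 'H:I29'
        num = num if num.isdigit() else num[1:]
        return chain, int(num)
    chain, num = res
    return chain, int(num)


def ca_distance_series(ensemble: SnapshotEnsemble, res_a, res_b) -> np.ndarray:
    """Cα–Cα distance (Å) between two residues, one value per frame."""
    keys = [(*_parse_res(r), "CA") for r in (res_a, res_b)]
    for key in keys:
        if key not in ensemble.atom_index:
            raise MissingAtomError(f"no CA atom for {key[0]}:{key[1]} in any frame")
    a = ensemble.coordinates[:, ensemble.atom_index[keys[0]]]
    b = ensemble.coordinates[:, ensemble.atom_index[keys[1]]]
    return np.linalg.norm(a - b, axis=1)


@dataclass(frozen=True)
class DistanceComparison:
    series_a: np.ndarray
    series_b: np.ndarray
    median_shift: float      # median(a) - median(b), Å
    u_statistic: float
    p_value: float

    def __post_init__(self) -> None:
        if not (0 <= self.p_value <= 1) or not np.isfinite(self.median_shift):
            raise InvalidInputError("invalid comparison result")


def compare_distance_distributions(series_a, series_b) -> DistanceComparison:
    """Median shift and two-sided Mann–Whitney U test between two series.

    Exact enumeration when both sides have <= 8 tie-free values; otherwise the
    tie-corrected normal approximation.  Degenerate all-tied input returns
    p = 1.
    """
    a = np.asarray(series_a, dtype=float)
    b = np.asarray(series_b, dtype=float)
    if a.size < 5 or b.size < 5:
        raise InvalidInputError("both series need >= 5 values")
    shift = float(np.median(a) - np.median(b))
    pooled = np.concatenate([a, b])
    if np.all(pooled == pooled[0]):
        return DistanceComparison(a, b, shift, a.size * b.size / 2.0, 1.0)
    has_ties = np.unique(pooled).size < pooled.size
    method = "exact" if (a.size <= 8 and b.size <= 8 and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return DistanceComparison(a, b, shift, float(res.statistic),
                              float(min(res.pvalue, 1.0)))
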