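"""Mutation-candidate selection for fluctuation editing.

A residue is a candidate for alanine mutation when it (1) displays relaxation
dispersion, (2) lies outside the CDR loops, (3) has a large side chain (not
Ala/Gly/Ser/Thr/Val) and (4) exposes more than 20% of its theoretical maximum
solvent-accessible surface area.  The module also provides the composite
1H/15N chemical-shift-perturbation metric and its mean / mean-plus-SD flags.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np

from .models import InvalidInputError

#: residues counted as small (excluded from mutation)
SMALL_RESIDUES = frozenset("AGSTV")

_ONE_LETTER = frozenset("ACDEFGHIKLMNPQRSTVWY")

#: theoretical maximum ASA per residue (A^2), Tien et al. 2013 values,
#: used to normalise absolute ASA to percent exposure
MAX_ASA = {
    "A": 129.0, "R": 274.0, "N": 195.0, "D": 193.0, "C": 167.0,
    "E": 223.0, "Q": 225.0, "G": 104.0, "H": 224.0, "I": 197.0,
    "L": 201.0, "K": 236.0, "M": 224.0, "F": 240.0, "P": 159.0,
    "S": 155.0, "T": 172.0, "W": 285.0, "Y": 263.0, "V": 174.0,
}

THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLU": "E", "GLN": "Q", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}


@dataclass
class ResidueAnnotation:
    """Per-residue record feeding the four-criterion selection filter."""

    residue_id: str             # e.g. 'H:R71'
    has_dispersion: bool
    rex: float = 0.0
    in_cdr: bool = False
    relative_asa: float = 0.0   # percent
    csp: float | None = None
    asa_warning: bool = False   # set when atoms were missing in the structure

    def __post_init__(self) -> None:
        if self.rex < 0:
            raise InvalidInputError(f"{self.residue_id}: rex must be >= 0")
        if not (0 <= self.relative_asa <= 150):
            raise InvalidInputError(
                f"{self.residue_id}: relative_asa {self.relative_asa} outside [0, 150]%")

    @property
    def amino_acid(self) -> str:
        return self.residue_id.split(":", 1)[1][0]

    @property
    def chain(self) -> str:
        return self.residue_id.split(":", 1)[0]

    @property
    def number(self) -> int:
        return int(self.residue_id.split(":", 1)[1][1:])


@dataclass(frozen=True)
class CdrDefinition:
    """CDR loop boundaries per chain (inclusive residue-number ranges)."""

    scheme_name: str
    ranges: dict   # chain -> tuple of (start, end)

    def __post_init__(self) -> None:
        for chain, spans in self.ranges.items():
            spans = sorted(spans)
            for start, end in spans:
                if start > end:
                    raise InvalidInputError(f"{chain}: range {start}-{end} inverted")
            for (s1, e1), (s2, e2) in zip(spans, spans[1:]):
                if s2 <= e1:
                    raise InvalidInputError(f"{chain}: overlapping CDR ranges")

    def contains(self, chain: str, number: int) -> bool:
        return any(s <= number <= e for s, e in self.ranges.get(chain, ()))


#: Kabat CDR boundaries for antibody variable domains (default scheme)
KABAT_CDR = CdrDefinition(
    scheme_name="kabat",
    ranges={"H": ((31, 35), (50, 65), (95, 102)),
            "L": ((24, 34), (50, 56), (89, 97))},
)


def composite_csp(delta_h: float, delta_n: float, alpha: float = 0.14) -> float:
    """Composite amide chemical-shift perturbation in ppm.

    sqrt(ddH^2 + (alpha * ddN)^2) with the conventional 15N weight
    alpha = 0.14.
    """
    return math.hypot(delta_h, alpha * delta_n)


def csp_flags(csp_values):
    """Flag residues whose CSP exceeds the mean or mean + 1 SD.

    Thresholds are computed over all residues with data (population SD);
    comparisons are strict, so an all-identical set yields no flags.  Returns
    a list of 'none' | 'above_mean' | 'above_mean_plus_sd'.
    """
    values = np.asarray(list(csp_values), dtype=float)
    if values.size < 2:
        raise InvalidInputError("csp_flags needs >= 2 residues")
    mean = float(values.mean())
    sd = float(values.std())  # population SD
    flags = []
    for v in values:
        if v > mean + sd:
            flags.append("above_mean_plus_sd")
        elif v > mean:
            flags.append("above_mean")
        else:
            flags.append("none")
    return flags


def is_large_residue(amino_acid: str) -> bool:
    """False iff the one-letter code is Ala, Gly, Ser, Thr or Val."""
    aa = amino_acid.upper()
    if aa not in _ONE_LETTER:
        raise InvalidInputError(f"unknown amino-acid code {amino_acid!r}")
    return aa not in SMALL_RESIDUES


def relative_asa(structure, chain: str, number: int, probe_radius: float = 1.4,
                 n_points: int = 960):
    """Relative solvent-accessible surface area of one residue, in percent.

    Shrake–Rupley ASA (probe 1.4 A, >= 960 sphere points per atom) of the
    whole residue, normalised by the residue's theoretical maximum.  Accepts
    a Bio.PDB entity (structure/model) or a path to a PDB file.  Returns
    (percent, warning_flag); the flag is set when the residue is missing
    side-chain atoms, in which case the area of the present atoms is used.
    """
    from Bio.PDB import PDBParser
    from Bio.PDB.SASA import ShrakeRupley

    if isinstance(structure, (str, bytes)) or hasattr(structure, "__fspath__"):
        structure = PDBParser(QUIET=True).get_structure("s", structure)
    model = next(structure.get_models()) if structure.level == "S" else structure

    ShrakeRupley(probe_radius=probe_radius, n_points=n_points).compute(model, level="A")
    try:
        residue = model[chain][(" ", number, " ")]
    except KeyError:
        raise InvalidInputError(f"residue {chain}:{number} not found in structure")
    aa3 = residue.get_resname().upper()
    if aa3 not in THREE_TO_ONE:
        raise InvalidInputError(f"non-standard residue {aa3} at {chain}:{number}")
    aa = THREE_TO_ONE[aa3]
    area = sum(atom.sasa for atom in residue if atom.element != "H")

    heavy = {a.get_name() for a in residue if a.element != "H"}
    expected_min = {"N", "CA", "C", "O"} | ({"CB"} if aa != "G" else set())
    warn = not expected_min <= heavy
    if warn:
        warnings.warn(f"{chain}:{number} missing backbone/CB atoms; "
                      "ASA computed on present atoms")
    return 100.0 * area / MAX_ASA[aa], warn


@dataclass(frozen=True)
class SelectionDecision:
    residue_id: str
    selected: bool
    reason: str    # 'selected' or the first failed criterion


@dataclass(frozen=True)
class SelectionResult:
    selected: tuple        # residue ids, input order
    decisions: tuple       # SelectionDecision per input residue


def select_candidates(annotations, cdr: CdrDefinition | None = None,
                      asa_threshold: float = 20.0) -> SelectionResult:
    """Apply the four-criterion fluctuation-editing filter.

    A residue is selected iff it has dispersion, is not in a CDR, has a large
    side chain and exposes strictly more than ``asa_threshold`` percent of its
    maximum ASA.  When a CdrDefinition is given it overrides the annotations'
    ``in_cdr`` flags.  Each rejection records the first failed criterion in
    the order: dispersion, CDR, size, ASA.
    """
    selected, decisions = [], []
    for a in annotations:
        in_cdr = cdr.contains(a.chain, a.number) if cdr is not None else a.in_cdr
        if not a.has_dispersion:
            reason = "no_dispersion"
        elif in_cdr:
            reason = "in_cdr"
        elif not is_large_residue(a.amino_acid):
            reason = "small_residue"
        elif not a.relative_asa > asa_threshold:
            reason = "low_asa"
        else:
            reason = "selected"
            selected.append(a.residue_id)
        decisions.append(SelectionDecision(a.residue_id, reason == "selected", reason))
    return SelectionResult(selected=tuple(selected), decisions=tuple(decisions))
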