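"""Seeded synthetic-data generators with machine-readable ground truth.

Every pipeline input can be generated here: two-field dispersion datasets
from clustered two-state exchange, one-site ITC isotherms, residue-annotation
fixtures with known filter outcomes, DSC traces, and Gaussian-perturbed
coordinate ensembles.  All generators take a single integer seed; per-kind
substreams are derived deterministically, so the same seed reproduces the
same data bit for bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np

from .models import (CpmgGrid, DEFAULT_GRID, ExchangeParams, FieldContext,
                     InvalidInputError, carver_richards_r2eff, luz_meiboom_r2eff,
                     rex_amplitude)
from .fitting import DispersionCurve
from .selection import (CdrDefinition, KABAT_CDR, ResidueAnnotation,
                        SMALL_RESIDUES, is_large_residue)
from .thermo import DscTrace, ItcExperiment, R_GAS, one_site_itc_heats
from .ensembles import SnapshotEnsemble

# substream tags so different data kinds never share a random stream
_STREAM = {"dispersion": 1, "itc": 2, "annotation": 3, "ensemble": 4, "dsc": 5}


def _rng(seed: int, kind: str) -> np.random.Generator:
    return np.random.default_rng([int(seed), _STREAM[kind]])


#: default dispersion noise, s^-1; makes recovered k_ex standard errors
#: comparable to the +-15-50 s^-1 scale typical of two-field 15N data
DISPERSION_SIGMA = 0.3

_LARGE_AA = "RKQEFWYLIMNDH"


@dataclass(frozen=True)
class ClusterScenario:
    """Ground-truth definition of one residue cluster.

    ``model`` picks the generating closed form; Carver–Richards clusters give
    each residue a shift difference drawn from ``dw_range`` (ppm) at the
    shared minor population, fast-exchange clusters draw Phi from
    ``phi_range`` (ppm^2).
    """

    name: str
    k_ex: float
    model: str                      # 'carver_richards' | 'luz_meiboom'
    n_residues: int
    chain: str = "H"
    first_residue: int = 1
    p_minor: float = 0.03
    dw_range: tuple = (0.5, 2.0)
    phi_range: tuple = (0.01, 0.1)
    r2_0_range: tuple = (10.0, 18.0)


#: default two-cluster free-antibody scenario: one cluster in slow-to-
#: intermediate exchange at 840 s^-1, one fast cluster at 2033 s^-1
DEFAULT_CLUSTERS = (
    ClusterScenario(name="cluster1", k_ex=840.0, model="carver_richards",
                    n_residues=10, chain="H", first_residue=1),
    ClusterScenario(name="cluster2", k_ex=2033.0, model="luz_meiboom",
                    n_residues=10, chain="L", first_residue=1),
)


def gen_dispersion_dataset(seed: int, clusters=DEFAULT_CLUSTERS,
                           field_mhz=(600.0, 750.0), grid: CpmgGrid = DEFAULT_GRID,
                           noise_sigma: float = DISPERSION_SIGMA, n_decoys: int = 3):
    """Generate clustered two-field dispersion curves plus ground truth.

    Decoy residues are flat (R_ex < 0.5 s^-1), so the exclusion filter must
    remove them.  Returns (curves, truth) where truth records every
    generating parameter.
    """
    rng = _rng(seed, "dispersion")
    fields = [FieldContext(m) for m in field_mhz]
    nu = np.asarray(grid.nu_cpmg)
    curves = []
    truth = {"seed": int(seed), "noise_sigma": noise_sigma, "clusters": [], "decoys": []}

    used_chains = set()
    for cl in clusters:
        used_chains.add(cl.chain)
        rec = {"name": cl.name, "k_ex": cl.k_ex, "model": cl.model,
               "p_minor": cl.p_minor if cl.model == "carver_richards" else None,
               "residues": {}}
        for i in range(cl.n_residues):
            aa = _LARGE_AA[i % len(_LARGE_AA)]
            rid = f"{cl.chain}:{aa}{cl.first_residue + i}"
            r2_0 = {f"{f.spectrometer_frequency:g}": float(rng.uniform(*cl.r2_0_range))
                    for f in fields}
            if cl.model == "carver_richards":
                dw = float(rng.uniform(*cl.dw_range))
                res_rec = {"delta_omega_ppm": dw, "r2_0": r2_0}
            else:
                phi = float(rng.uniform(*cl.phi_range))
                res_rec = {"phi_ppm2": phi, "r2_0": r2_0}
            rec["residues"][rid] = res_rec
            for f in fields:
                if cl.model == "carver_richards":
                    params = ExchangeParams(r2_0=r2_0[f"{f.spectrometer_frequency:g}"],
                                            k_ex=cl.k_ex, p_minor=cl.p_minor,
                                            delta_omega_ppm=res_rec["delta_omega_ppm"])
                    clean = carver_richards_r2eff(nu, params, f)
                else:
                    params = ExchangeParams(r2_0=r2_0[f"{f.spectrometer_frequency:g}"],
                                            k_ex=cl.k_ex, phi_ppm2=res_rec["phi_ppm2"])
                    clean = luz_meiboom_r2eff(nu, params, f)
                noisy = clean + rng.normal(0.0, noise_sigma, nu.size) if noise_sigma > 0 else clean
                curves.append(DispersionCurve(rid, f, nu.copy(), noisy,
                                              np.full(nu.size, max(noise_sigma, 1e-6))))
        truth["clusters"].append(rec)

    chain = sorted(used_chains)[0] if used_chains else "H"
    start = 1000  # numbers far from any scenario residue
    for d in range(n_decoys):
        rid = f"{chain}:{_LARGE_AA[d % len(_LARGE_AA)]}{start + d}"
        kex = 1000.0
        rex = float(rng.uniform(0.05, 0.3))
        truth["decoys"].append(rid)
        for f in fields:
            phi_ppm2 = rex * kex / f.ppm_to_rad**2
            params = ExchangeParams(r2_0=float(rng.uniform(10, 18)), k_ex=kex,
                                    phi_ppm2=phi_ppm2)
            clean = luz_meiboom_r2eff(nu, params, f)
            noisy = clean + rng.normal(0.0, noise_sigma, nu.size) if noise_sigma > 0 else clean
            curves.append(DispersionCurve(rid, f, nu.copy(), noisy,
                                          np.full(nu.size, max(noise_sigma, 1e-6))))
    return curves, truth


#: default titration geometry: 2 uM macromolecule in a 1.4 ml cell,
#: 25 x 10 ul injections of 30 uM titrant at 293.15 K
DEFAULT_ITC_GEOMETRY = dict(
    cell_concentration=2e-6,
    syringe_concentration=30e-6,
    cell_volume=1.4e-3,
    injection_volumes=tuple([10e-6] * 25),
    temperature=293.15,
)


def gen_itc_experiment(seed: int, ka: float = 2.0e9, delta_h: float = -99.50,
                       n: float = 1.0, noise_sigma_j: float = 0.0,
                       geometry: dict | None = None):
    """One-site ITC isotherm (heats in J) plus ground truth."""
    rng = _rng(seed, "itc")
    geo = dict(DEFAULT_ITC_GEOMETRY)
    if geometry:
        geo.update(geometry)
    blank = ItcExperiment(heats=None, **geo)
    heats = one_site_itc_heats(ka, delta_h, n, blank)
    if noise_sigma_j > 0:
        heats = heats + rng.normal(0.0, noise_sigma_j, heats.size)
    experiment = ItcExperiment(heats=tuple(float(q) for q in heats), **geo)
    truth = {"seed": int(seed), "ka": ka, "delta_h": delta_h, "n": n,
             "noise_sigma_j": noise_sigma_j}
    return experiment, truth


def gen_annotation_fixture(seed: int, n_dispersive: int = 32, n_candidates: int = 8,
                           cdr: CdrDefinition = KABAT_CDR, n_silent: int = 5):
    """Residue-annotation fixture with an exactly known selection outcome.

    ``n_dispersive`` fluctuating residues are generated of which exactly
    ``n_candidates`` satisfy all four criteria; the remainder each fail one
    (CDR location, small side chain, or low ASA, in rotation).  ``n_silent``
    extra residues carry no dispersion.  The expected candidate set is
    enumerated directly from the predicates and returned with the fixture.
    """
    if n_candidates > n_dispersive:
        raise InvalidInputError("cannot have more candidates than dispersive residues")
    rng = _rng(seed, "annotation")
    cdr_positions = {ch: [s for s, e in spans] for ch, spans in cdr.ranges.items()}

    annotations = []
    # non-CDR heavy-chain numbers, walked in order and skipping CDR spans
    free_numbers = [n for n in range(1, 400) if not cdr.contains("H", n)]
    cursor = 0

    def next_free() -> int:
        nonlocal cursor
        n = free_numbers[cursor]
        cursor += 1
        return n

    for i in range(n_candidates):
        aa = _LARGE_AA[i % len(_LARGE_AA)]
        annotations.append(ResidueAnnotation(
            residue_id=f"H:{aa}{next_free()}", has_dispersion=True,
            rex=float(rng.uniform(1.5, 6.0)), in_cdr=False,
            relative_asa=float(rng.uniform(25.0, 60.0))))
    fail_modes = ["in_cdr", "small_residue", "low_asa"]
    for i in range(n_dispersive - n_candidates):
        mode = fail_modes[i % 3]
        rex = float(rng.uniform(1.5, 6.0))
        if mode == "in_cdr":
            chain = "H" if i % 2 == 0 else "L"
            num = int(rng.choice(cdr_positions[chain]))
            annotations.append(ResidueAnnotation(
                residue_id=f"{chain}:{_LARGE_AA[i % len(_LARGE_AA)]}{num}",
                has_dispersion=True, rex=rex, in_cdr=True,
                relative_asa=float(rng.uniform(25.0, 60.0))))
        elif mode == "small_residue":
            aa = sorted(SMALL_RESIDUES)[i % len(SMALL_RESIDUES)]
            annotations.append(ResidueAnnotation(
                residue_id=f"H:{aa}{next_free()}", has_dispersion=True,
                rex=rex, in_cdr=False, relative_asa=float(rng.uniform(25.0, 60.0))))
        else:
            annotations.append(ResidueAnnotation(
                residue_id=f"H:{_LARGE_AA[i % len(_LARGE_AA)]}{next_free()}",
                has_dispersion=True, rex=rex, in_cdr=False,
                relative_asa=float(rng.uniform(2.0, 19.0))))
    for i in range(n_silent):
        annotations.append(ResidueAnnotation(
            residue_id=f"H:{_LARGE_AA[i % len(_LARGE_AA)]}{next_free()}",
            has_dispersion=False, rex=0.0, in_cdr=False,
            relative_asa=float(rng.uniform(10.0, 60.0))))

    # independent brute-force enumeration of the expected candidate set
    expected = tuple(
        a.residue_id for a in annotations
        if a.has_dispersion and not a.in_cdr and is_large_residue(a.amino_acid)
        and a.relative_asa > 20.0)
    if len(expected) != n_candidates:
        raise InvalidInputError("fixture construction failed to hit the candidate count")
    return annotations, expected


def gen_dsc_trace(seed: int, delta_h: float = 300.0 * 4.184, t_mid: float = 348.0,
                  delta_h_vanthoff: float | None = None,
                  t_range: tuple = (310.0, 380.0), n_points: int = 701,
                  baseline_slope: float = 0.02, baseline_offset: float = 5.0,
                  noise_sigma: float = 0.0):
    """Two-state thermal-unfolding Cp trace whose excess area is ``delta_h``.

    The excess heat capacity follows the van't Hoff two-state form
    Cp_ex = dH_cal * dtheta/dT with theta the unfolded fraction; the linear
    instrumental baseline is returned alongside.  Units kJ/mol.
    """
    rng = _rng(seed, "dsc")
    dh_vh = delta_h_vanthoff if delta_h_vanthoff is not None else delta_h
    t = np.linspace(*t_range, n_points)
    k = np.exp(-dh_vh * 1000.0 / R_GAS * (1.0 / t - 1.0 / t_mid))
    theta = k / (1.0 + k)
    dtheta_dt = dh_vh * 1000.0 / (R_GAS * t**2) * theta * (1.0 - theta)
    baseline = baseline_offset + baseline_slope * (t - t[0])
    cp = baseline + delta_h * dtheta_dt
    if noise_sigma > 0:
        cp = cp + rng.normal(0.0, noise_sigma, t.size)
    truth = {"seed": int(seed), "delta_h": delta_h, "t_mid": t_mid}
    return DscTrace(temperatures=t, cp=cp, baseline=baseline), truth


def synthetic_ca_fold(n_per_chain: int = 20, chains=("H", "L"), spacing: float = 3.8,
                      chain_offset: float = 12.0):
    """Deterministic CA-only base coordinates for two chains (dict key -> xyz).

    Each chain is a gentle helix-like curve; chains run parallel at a fixed
    offset.  Purely synthetic stand-in geometry for ensemble tests.
    """
    base = {}
    for ci, chain in enumerate(chains):
        for i in range(n_per_chain):
            t = i * spacing
            base[(chain, i + 1, "CA")] = np.array([
                t * 0.9,
                5.0 * np.sin(t / 10.0) + ci * chain_offset,
                5.0 * np.cos(t / 10.0) + ci * 3.0,
            ])
    return base


def gen_snapshot_ensemble(seed: int, base_coordinates: dict | None = None,
                          amplitude: float = 0.5, n_frames: int = 130,
                          translate: dict | None = None):
    """Isotropically Gaussian-perturbed frames around base coordinates.

    ``translate`` optionally shifts named atoms' mean positions (key ->
    3-vector), e.g. to emulate a mutant ensemble whose loops sit closer.
    Returns (SnapshotEnsemble, truth) with ground-truth mean positions.
    """
    rng = _rng(seed, "ensemble")
    base = base_coordinates if base_coordinates is not None else synthetic_ca_fold()
    keys = sorted(base)
    mean = np.array([np.asarray(base[k], dtype=float) for k in keys])
    if translate:
        for key, vec in translate.items():
            mean[keys.index(key)] = mean[keys.index(key)] + np.asarray(vec, dtype=float)
    if n_frames < 2:
        raise InvalidInputError("need >= 2 frames")
    noise = (rng.normal(0.0, amplitude, (n_frames, len(keys), 3))
             if amplitude > 0 else np.zeros((n_frames, len(keys), 3)))
    coords = mean[None, :, :] + noise
    ensemble = SnapshotEnsemble(atom_index={k: i for i, k in enumerate(keys)},
                                coordinates=np.asarray(coords, dtype=float))
    truth = {"seed": int(seed), "amplitude": amplitude, "n_frames": n_frames,
             "mean_positions": {f"{c}:{r}:{a}": mean[i].tolist()
                                for i, (c, r, a) in enumerate(keys)}}
    return ensemble, truth


def build_structure(residue_specs):
    """Assemble a Bio.PDB Structure from explicit atom coordinates.

    ``residue_specs``: iterable of (chain_id, resnum, resname3,
    [(atom_name, element, (x, y, z)), ...]).  Used to construct synthetic
    test structures (extended peptides, packed clusters) without shipping
    coordinate files.
    """
    import numpy as np
    from Bio.PDB.StructureBuilder import StructureBuilder

    sb = StructureBuilder()
    sb.init_structure("synthetic")
    sb.init_model(0)
    seen_chains = set()
    serial = 1
    for chain_id, resnum, resname, atoms in residue_specs:
        if chain_id not in seen_chains:
            sb.init_chain(chain_id)
            sb.init_seg("    ")
            seen_chains.add(chain_id)
        sb.init_residue(resname, " ", resnum, " ")
        for name, element, xyz in atoms:
            sb.init_atom(name, np.asarray(xyz, dtype=float), 0.0, 1.0, " ",
                         name, serial, element=element)
            serial += 1
    return sb.get_structure()


#: crude extended side-chain templates (offsets from CA), full heavy-atom sets
_SIDECHAINS = {
    "GLY": [],
    "ALA": [("CB", "C", (0.0, 0.9, 1.25))],
    "LEU": [("CB", "C", (0.0, 1.0, 1.2)), ("CG", "C", (0.0, 2.1, 2.2)),
            ("CD1", "C", (-1.2, 3.0, 2.2)), ("CD2", "C", (1.2, 3.0, 2.3))],
    "ARG": [("CB", "C", (0.0, 1.0, 1.2)), ("CG", "C", (0.0, 2.1, 2.2)),
            ("CD", "C", (0.0, 3.3, 1.4)), ("NE", "N", (0.0, 4.5, 2.2)),
            ("CZ", "C", (0.0, 5.7, 1.6)), ("NH1", "N", (0.0, 5.9, 0.3)),
            ("NH2", "N", (0.0, 6.7, 2.4))],
}


def extended_tripeptide(center_aa3: str = "LEU"):
    """Synthetic fully extended Gly-X-Gly tripeptide (crude ideal geometry).

    The central residue carries its full heavy-atom side chain so the
    relative-ASA normalisation is meaningful; supported centers: GLY, ALA,
    LEU, ARG.
    """
    if center_aa3 not in _SIDECHAINS:
        raise InvalidInputError(f"no side-chain template for {center_aa3}")

    def backbone(x0, resname, resnum):
        ca = (x0 + 1.46, 0.9, 0.0)
        atoms = [("N", "N", (x0, 0.0, 0.0)),
                 ("CA", "C", ca),
                 ("C", "C", (x0 + 2.6, -0.1, 0.0)),
                 ("O", "O", (x0 + 2.6, -1.33, 0.0))]
        for name, element, off in _SIDECHAINS[resname]:
            atoms.append((name, element,
                          (ca[0] + off[0], ca[1] + off[1], ca[2] + off[2])))
        return ("A", resnum, resname, atoms)

    specs = [backbone(0.0, "GLY", 1),
             backbone(3.8, center_aa3, 2),
             backbone(7.6, "GLY", 3)]
    return build_structure(specs)


def buried_residue_cluster(center_aa3: str = "LEU", shell_radius: float = 4.6,
                           n_shell: int = 60):
    """Central residue enclosed by a packed shell of dummy alanine residues.

    The shell guarantees burial: every solvent probe position around the
    central residue is occluded.
    """
    center = [("A", 1, center_aa3, [("N", "N", (-1.2, 0.0, 0.0)),
                                    ("CA", "C", (0.0, 0.0, 0.0)),
                                    ("C", "C", (1.3, 0.6, 0.0)),
                                    ("O", "O", (1.4, 1.8, 0.0)),
                                    ("CB", "C", (0.0, -1.0, 1.1))])]
    # Fibonacci sphere of blocking CA atoms in a second chain
    golden = (1 + 5**0.5) / 2
    shell = []
    for i in range(n_shell):
        theta = 2 * np.pi * i / golden
        z = 1 - (2 * i + 1) / n_shell
        r = (1 - z * z) ** 0.5
        xyz = (shell_radius * r * np.cos(theta),
               shell_radius * r * np.sin(theta),
               shell_radius * z)
        shell.append(("B", i + 1, "ALA", [("CA", "C", xyz)]))
    return build_structure(center + shell)
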