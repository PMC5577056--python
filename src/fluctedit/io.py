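"""Delimited-text readers and writers for the pipeline's table dialects.

All tables are UTF-8, header required, '#' starts a comment line.  Columns
are whitespace- or comma-delimited (pandas sniffing).
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

from .models import FieldContext

#: dispersion table columns: one row per measurement
DISPERSION_COLUMNS = ["chain", "residue", "aa", "field_mhz", "nu_cpmg_hz", "r2eff", "sigma"]


def _read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#", sep=None, engine="python")


def residue_id(chain: str, aa: str, number: int) -> str:
    """Canonical residue identifier, e.g. 'H:R71'."""
    return f"{chain}:{aa}{int(number)}"


def parse_residue_id(rid: str):
    """Split 'H:R71' into (chain, aa, number)."""
    chain, rest = rid.split(":", 1)
    return chain, rest[0], int(rest[1:])


def read_dispersion_table(path):
    """Read a dispersion table into a list of DispersionCurve.

    Expected columns: chain, residue, aa, field_mhz, nu_cpmg_hz, r2eff, sigma.
    One curve is assembled per (residue, field) pair; rows may appear in any
    order, points are sorted by nu_cpmg.
    """
    from .fitting import DispersionCurve

    df = _read_table(path)
    missing = [c for c in DISPERSION_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing dispersion columns {missing}")
    curves = []
    for (chain, resnum, aa, mhz), grp in df.groupby(
            ["chain", "residue", "aa", "field_mhz"], sort=True):
        grp = grp.sort_values("nu_cpmg_hz")
        curves.append(DispersionCurve(
            residue_id=residue_id(chain, aa, resnum),
            field=FieldContext(float(mhz)),
            nu_cpmg=grp["nu_cpmg_hz"].to_numpy(float),
            r2eff=grp["r2eff"].to_numpy(float),
            sigma=grp["sigma"].to_numpy(float),
        ))
    return curves


def write_dispersion_table(curves, path) -> None:
    rows = []
    for c in curves:
        chain, aa, num = parse_residue_id(c.residue_id)
        for nu, r2, sg in zip(c.nu_cpmg, c.r2eff, c.sigma):
            rows.append((chain, num, aa, c.field.spectrometer_frequency, nu, r2, sg))
    df = pd.DataFrame(rows, columns=DISPERSION_COLUMNS)
    df.to_csv(path, index=False, float_format="%.6f")


ANNOTATION_COLUMNS = ["chain", "residue", "aa", "has_dispersion", "rex",
                      "in_cdr", "relative_asa"]


def read_annotation_table(path):
    """Read per-residue annotations (selection-filter inputs)."""
    from .selection import ResidueAnnotation

    df = _read_table(path)
    missing = [c for c in ANNOTATION_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing annotation columns {missing}")
    out = []
    for _, row in df.iterrows():
        out.append(ResidueAnnotation(
            residue_id=residue_id(row["chain"], row["aa"], row["residue"]),
            has_dispersion=bool(row["has_dispersion"]),
            rex=float(row["rex"]),
            in_cdr=bool(row["in_cdr"]),
            relative_asa=float(row["relative_asa"]),
            csp=float(row["csp"]) if "csp" in df.columns and pd.notna(row.get("csp")) else None,
        ))
    return out


def write_annotation_table(annotations, path) -> None:
    rows = []
    for a in annotations:
        chain, aa, num = parse_residue_id(a.residue_id)
        rows.append((chain, num, aa, int(a.has_dispersion), a.rex,
                     int(a.in_cdr), a.relative_asa, "" if a.csp is None else a.csp))
    df = pd.DataFrame(rows, columns=ANNOTATION_COLUMNS + ["csp"])
    df.to_csv(path, index=False)


def read_itc_table(path):
    """Read an ITC experiment: key/value header comments + injection rows.

    Columns: injection_ul, heat (J).  Metadata lines look like
    '# cell_concentration_m = 2e-6'.
    """
    from .thermo import ItcExperiment

    meta = {}
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            if line.startswith("#") and "=" in line:
                key, val = line[1:].split("=", 1)
                meta[key.strip()] = float(val)
    df = _read_table(path)
    return ItcExperiment(
        cell_concentration=meta["cell_concentration_m"],
        syringe_concentration=meta["syringe_concentration_m"],
        cell_volume=meta["cell_volume_l"],
        injection_volumes=tuple(v * 1e-6 for v in df["injection_ul"]),
        temperature=meta["temperature_k"],
        heats=tuple(df["heat_j"]),
    )


def write_itc_table(experiment, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"# cell_concentration_m = {experiment.cell_concentration!r}\n")
        fh.write(f"# syringe_concentration_m = {experiment.syringe_concentration!r}\n")
        fh.write(f"# cell_volume_l = {experiment.cell_volume!r}\n")
        fh.write(f"# temperature_k = {experiment.temperature!r}\n")
        fh.write("injection_ul,heat_j\n")
        heats = experiment.heats or [float("nan")] * len(experiment.injection_volumes)
        for dv, q in zip(experiment.injection_volumes, heats):
            fh.write(f"{dv * 1e6:.6f},{q!r}\n")


def read_dsc_table(path):
    """Read a DSC trace: columns temperature_k, cp_kj_mol_k [, baseline_kj_mol_k]."""
    from .thermo import DscTrace

    df = _read_table(path)
    baseline = df["baseline_kj_mol_k"].to_numpy(float) if "baseline_kj_mol_k" in df.columns else None
    return DscTrace(
        temperatures=df["temperature_k"].to_numpy(float),
        cp=df["cp_kj_mol_k"].to_numpy(float),
        baseline=baseline,
    )


def write_dsc_table(trace, path) -> None:
    import numpy as np

    data = {"temperature_k": trace.temperatures, "cp_kj_mol_k": trace.cp}
    if trace.baseline is not None:
        data["baseline_kj_mol_k"] = np.asarray(trace.baseline)
    pd.DataFrame(data).to_csv(path, index=False)


def write_json(obj, path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n", encoding="utf-8")


def read_json(path):
    return json.loads(Path(path).read_text(encoding="utf-8"))
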