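"""Readers and writers for the plain-text formats the pipeline consumes.

All machine-readable files are comma- or tab-delimited UTF-8 text with a
mandatory header row, "." decimal, and concentrations in molar (headers say
so); uncertainty always gets its own column, never a "+/-" glyph.  Readers
return the package's in-memory types; every reader/writer pair round-trips.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from .anisotropy import AnisotropyRead, TitrationSeries
from .cd import CDSpectrum
from .nmr import ShiftAssignment
from .peptides import (
    ConstraintSpec,
    PeptideSpec,
    count_backbone_amides,
    molar_extinction,
    parse_peptide,
)

__all__ = [
    "sha256_of",
    "read_plate_csv",
    "write_plate_csv",
    "read_cd_spectrum",
    "write_cd_spectrum",
    "read_shift_table",
    "write_shift_table",
    "read_peptide_config",
    "write_peptide_config",
    "write_variant_table",
]

PathLike = Union[str, Path]


def sha256_of(path: PathLike) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


# -- plate files ----------------------------------------------------------

PLATE_COLUMNS = ["well", "series_id", "x_conc_M", "P", "S", "G", "replicate"]


def read_plate_csv(
    path: PathLike,
    series_id: str,
    mode: str,
    tracer_conc: float = 50e-9,
    protein_conc: Optional[float] = None,
    subtract_control: bool = True,
) -> TitrationSeries:
    """One titration series from a plate CSV.

    Wells with ``series_id == "control"`` are blank wells; their mean P and S
    are subtracted from every sample read before anisotropy is computed
    (clipped at zero — a control cannot exceed a genuine signal).
    """
    df = pd.read_csv(path)
    missing = set(PLATE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"plate file {path} missing columns: {sorted(missing)}")
    ctrl_P = ctrl_S = 0.0
    if subtract_control:
        ctrl = df[df["series_id"] == "control"]
        if len(ctrl):
            ctrl_P, ctrl_S = float(ctrl["P"].mean()), float(ctrl["S"].mean())
    sel = df[df["series_id"] == series_id].copy()
    if sel.empty:
        raise ValueError(f"series {series_id!r} not found in {path}")
    xs = np.sort(sel["x_conc_M"].unique())
    reads: list[list[AnisotropyRead]] = []
    for x in xs:
        rows = sel[sel["x_conc_M"] == x].sort_values("replicate")
        reads.append([
            AnisotropyRead(P=max(r.P - ctrl_P, 0.0), S=max(r.S - ctrl_S, 0.0), G=r.G)
            for r in rows.itertuples()
        ])
    return TitrationSeries(mode=mode, x=xs, reads=reads,
                           tracer_conc=tracer_conc, protein_conc=protein_conc)


def write_plate_csv(path: PathLike, series: TitrationSeries, series_id: str) -> None:
    """Write a series as plate rows; synthesises P/S for value-only reads.

    A precomputed anisotropy r is emitted as the unique (P, S) pair with
    G = 1 and total intensity 300: S = 100*(1+2r), P = 100*(1-r).
    """
    rows = []
    for i, (x, reps) in enumerate(zip(series.x, series.reads)):
        for k, rep in enumerate(reps):
            if isinstance(rep, AnisotropyRead):
                P, S, G = rep.P, rep.S, rep.G
            else:
                r = float(rep)
                P, S, G = 100.0 * (1.0 - r), 100.0 * (1.0 + 2.0 * r), 1.0
            rows.append({"well": f"{series_id}_{i}_{k}", "series_id": series_id,
                         "x_conc_M": x, "P": P, "S": S, "G": G, "replicate": k})
    pd.DataFrame(rows, columns=PLATE_COLUMNS).to_csv(path, index=False)


# -- CD spectra -----------------------------------------------------------


def write_cd_spectrum(path: PathLike, spectrum: CDSpectrum,
                      meta_path: Optional[PathLike] = None) -> None:
    """Two-column text (wavelength_nm, ellipticity_mdeg) + JSON metadata sidecar."""
    pd.DataFrame({
        "wavelength_nm": spectrum.wavelengths,
        "ellipticity_mdeg": spectrum.ellipticity_mdeg,
    }).to_csv(path, index=False)
    meta_path = Path(meta_path) if meta_path else Path(path).with_suffix(".meta.json")
    meta = {
        "mw": spectrum.mw, "conc_mg_ml": spectrum.conc_mg_ml,
        "pathlength_mm": spectrum.pathlength_mm, "n_residues": spectrum.n_residues,
        "n_amide": spectrum.n_amide, "temperature_c": spectrum.temperature_c,
        "is_blank": spectrum.is_blank, "name": spectrum.name,
    }
    meta_path.write_text(json.dumps(meta, indent=1))


def read_cd_spectrum(path: PathLike, meta_path: Optional[PathLike] = None) -> CDSpectrum:
    df = pd.read_csv(path)
    for col in ("wavelength_nm", "ellipticity_mdeg"):
        if col not in df.columns:
            raise ValueError(f"CD file {path} missing column {col!r}")
    meta_path = Path(meta_path) if meta_path else Path(path).with_suffix(".meta.json")
    meta = json.loads(meta_path.read_text()) if meta_path.exists() else {}
    return CDSpectrum(
        wavelengths=df["wavelength_nm"].to_numpy(),
        ellipticity_mdeg=df["ellipticity_mdeg"].to_numpy(),
        **{k: meta[k] for k in ("mw", "conc_mg_ml", "pathlength_mm", "n_residues",
                                "n_amide", "temperature_c", "is_blank", "name")
           if k in meta},
    )


# -- shift tables ---------------------------------------------------------

SHIFT_COLUMNS = ["residue_index", "residue_type", "delta_ca_ppm", "delta_ha_ppm",
                 "peak_width_ppm"]


def write_shift_table(path: PathLike, assignments: Sequence[ShiftAssignment]) -> None:
    rows = [{
        "residue_index": a.residue_index, "residue_type": a.residue_type,
        "delta_ca_ppm": a.delta_ca, "delta_ha_ppm": a.delta_ha,
        "peak_width_ppm": a.peak_width,
    } for a in assignments]
    pd.DataFrame(rows, columns=SHIFT_COLUMNS).to_csv(path, sep="\t", index=False)


def read_shift_table(path: PathLike) -> list[ShiftAssignment]:
    df = pd.read_csv(path, sep="\t")
    missing = set(SHIFT_COLUMNS[:4]) - set(df.columns)
    if missing:
        raise ValueError(f"shift table {path} missing columns: {sorted(missing)}")

    def opt(v):
        return None if pd.isna(v) else float(v)

    return [
        ShiftAssignment(
            residue_index=int(r.residue_index),
            residue_type=str(r.residue_type),
            delta_ca=opt(r.delta_ca_ppm),
            delta_ha=opt(r.delta_ha_ppm),
            peak_width=opt(getattr(r, "peak_width_ppm", float("nan"))),
        )
        for r in df.itertuples()
    ]


# -- peptide configs and variant tables -----------------------------------


def _peptide_to_dict(p: PeptideSpec) -> dict:
    d = {"name": p.name, "sequence": p.sequence, "offset": p.numbering_offset,
         "n_term": p.n_term, "c_term": p.c_term}
    if p.constraint is not None:
        d["constraint"] = {"i": p.constraint.position_i, "j": p.constraint.position_j,
                           "spacing": p.constraint.spacing, "state": p.constraint.state}
    return d


def _peptide_from_dict(d: dict) -> PeptideSpec:
    constraint = None
    if d.get("constraint"):
        c = d["constraint"]
        constraint = ConstraintSpec(position_i=c["i"], position_j=c["j"],
                                    spacing=c.get("spacing", c["j"] - c["i"]),
                                    state=c.get("state", "red"))
    p = parse_peptide(d["sequence"], d["offset"], name=d.get("name", ""),
                      constraint=constraint)
    # explicit termini override anything inferred from the sequence string
    kwargs = {}
    if "n_term" in d:
        kwargs["n_term"] = d["n_term"]
    if "c_term" in d:
        kwargs["c_term"] = d["c_term"]
    if kwargs:
        from dataclasses import replace
        p = replace(p, **kwargs)
    return p


def write_peptide_config(path: PathLike, peptides: Sequence[PeptideSpec]) -> None:
    Path(path).write_text(json.dumps([_peptide_to_dict(p) for p in peptides], indent=1))


def read_peptide_config(path: PathLike) -> list[PeptideSpec]:
    data = json.loads(Path(path).read_text())
    if isinstance(data, dict):
        data = [data]
    return [_peptide_from_dict(d) for d in data]


def write_variant_table(path: PathLike, variants: Sequence[PeptideSpec]) -> None:
    """Delimited export of a designed variant list with chemistry bookkeeping."""
    rows = []
    for v in variants:
        c = v.constraint
        rows.append({
            "name": v.name, "sequence": v.sequence, "offset": v.numbering_offset,
            "constraint_i": c.position_i if c else None,
            "constraint_j": c.position_j if c else None,
            "state": c.state if c else None,
            "n_amide": count_backbone_amides(v),
            "epsilon": molar_extinction(v),
        })
    pd.DataFrame(rows).to_csv(path, index=False)
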