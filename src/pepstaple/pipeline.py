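"""End-to-end orchestration: design -> measure -> fit -> report.

A run configuration lists peptides and the data files measured for each
(competition plate series, CD spectrum, NMR shift table — all optional).
The pipeline fits whatever is present and assembles a per-peptide report
mirroring the screen's summary-table structure: IC50 with SD, MRE at
222 nm, % helicity (unrounded and rounded), and the free-energy difference
against a named reference peptide.  Failures are recorded per peptide and
never abort the run.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

import pandas as pd

from . import io as pio
from .anisotropy import delta_delta_g, fit_competition
from .cd import helicity_from_spectrum, mre_at, mre_spectrum, zero_blank
from .nmr import call_helical_segments, load_packaged_coil_table, secondary_shifts
from .peptides import PeptideSpec, count_backbone_amides, molar_extinction

logger = logging.getLogger("pepstaple")

__all__ = ["PeptideEntry", "RunConfig", "PeptideRecord", "StudyReport",
           "run_pipeline", "write_report", "read_run_config"]

PathLike = Union[str, Path]

REPORT_COLUMNS = [
    "name", "sequence", "offset", "constraint_state", "n_amide", "epsilon",
    "IC50_M", "IC50_sd_M", "MRE222", "percent_helicity", "rounded_helicity",
    "ddG_kJ_mol", "segments", "flags",
]


@dataclass
class PeptideEntry:
    """One peptide plus the measurement files associated with it."""

    peptide: PeptideSpec
    competition_plate: Optional[PathLike] = None
    plate_series_id: Optional[str] = None
    cd_spectrum: Optional[PathLike] = None
    cd_blank: Optional[PathLike] = None
    shift_table: Optional[PathLike] = None
    restrain_rmin: bool = False


@dataclass
class RunConfig:
    """Everything a pipeline run needs; paths are resolved at construction."""

    entries: list[PeptideEntry]
    reference: Optional[str] = None  # peptide name for the ddG column
    tracer_conc: float = 50e-9
    protein_conc: float = 15e-6
    temperature_K: float = 298.15
    rmin_value: float = -0.03
    output_dir: Optional[PathLike] = None

    def __post_init__(self) -> None:
        for e in self.entries:
            for attr in ("competition_plate", "cd_spectrum", "cd_blank", "shift_table"):
                p = getattr(e, attr)
                if p is not None:
                    setattr(e, attr, Path(p).resolve())


@dataclass
class PeptideRecord:
    name: str
    sequence: str
    offset: int
    constraint_state: Optional[str]
    n_amide: int
    epsilon: float
    IC50_M: Optional[float] = None
    IC50_sd_M: Optional[float] = None
    MRE222: Optional[float] = None
    percent_helicity: Optional[float] = None
    rounded_helicity: Optional[int] = None
    ddG_kJ_mol: Optional[float] = None
    segments: list[tuple[int, int]] = field(default_factory=list)
    flags: list[str] = field(default_factory=list)


@dataclass
class StudyReport:
    records: list[PeptideRecord]
    input_checksums: dict[str, str] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for r in self.records:
            rows.append({
                **{k: getattr(r, k) for k in REPORT_COLUMNS[:-2]},
                "segments": ";".join(f"{a}-{b}" for a, b in r.segments),
                "flags": ";".join(r.flags),
            })
        return pd.DataFrame(rows, columns=REPORT_COLUMNS)


def run_pipeline(config: RunConfig) -> StudyReport:
    """Fit every stage present for every peptide; never abort on one failure."""
    records: list[PeptideRecord] = []
    checksums: dict[str, str] = {}

    for entry in config.entries:
        p = entry.peptide
        rec = PeptideRecord(
            name=p.name, sequence=p.sequence, offset=p.numbering_offset,
            constraint_state=p.constraint.state if p.constraint else None,
            n_amide=count_backbone_amides(p), epsilon=molar_extinction(p),
        )
        for path in (entry.competition_plate, entry.cd_spectrum, entry.cd_blank,
                     entry.shift_table):
            if path is not None and Path(path).exists():
                checksums[str(path)] = pio.sha256_of(path)

        if entry.competition_plate is not None:
            try:
                series = pio.read_plate_csv(
                    entry.competition_plate,
                    series_id=entry.plate_series_id or p.name,
                    mode="competition",
                    tracer_conc=config.tracer_conc,
                    protein_conc=config.protein_conc,
                )
                fit = fit_competition(series, restrain_rmin=entry.restrain_rmin,
                                      rmin_value=config.rmin_value)
                rec.IC50_M = fit.IC50
                rec.IC50_sd_M = fit.IC50_sd
                if fit.monotonicity_warning:
                    rec.flags.append("competition-monotonicity")
            except Exception as exc:  # recorded, not fatal
                logger.warning("competition fit failed for %s: %s", p.name, exc)
                rec.flags.append(f"competition-error:{exc}")

        if entry.cd_spectrum is not None:
            try:
                sample = pio.read_cd_spectrum(entry.cd_spectrum)
                blank = (pio.read_cd_spectrum(entry.cd_blank)
                         if entry.cd_blank is not None else zero_blank(sample.wavelengths))
                if sample.n_amide is None:
                    sample.n_amide = rec.n_amide
                rec.MRE222 = mre_at(mre_spectrum(sample, blank))
                est = helicity_from_spectrum(sample, blank)
                rec.percent_helicity = est.percent_helicity
                rec.rounded_helicity = est.rounded_percent
            except Exception as exc:
                logger.warning("CD analysis failed for %s: %s", p.name, exc)
                rec.flags.append(f"cd-error:{exc}")

        if entry.shift_table is not None:
            try:
                assignments = pio.read_shift_table(entry.shift_table)
                profile = secondary_shifts(assignments, load_packaged_coil_table())
                rec.segments = [(s.start, s.end)
                                for s in call_helical_segments(profile)]
            except Exception as exc:
                logger.warning("NMR analysis failed for %s: %s", p.name, exc)
                rec.flags.append(f"nmr-error:{exc}")

        records.append(rec)

    if config.reference is not None:
        ref = next((r for r in records if r.name == config.reference), None)
        if ref is None or ref.IC50_M is None:
            for r in records:
                r.flags.append("ddG-skipped:no-reference-IC50")
        else:
            for r in records:
                if r.IC50_M is not None:
                    r.ddG_kJ_mol = delta_delta_g(ref.IC50_M, r.IC50_M,
                                                 config.temperature_K)

    return StudyReport(records=records, input_checksums=checksums)


def write_report(report: StudyReport, out_dir: PathLike,
                 basename: str = "study_report") -> dict[str, Path]:
    """Emit the report as CSV (fixed column order) and JSON; returns the paths."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    csv_path = out / f"{basename}.csv"
    json_path = out / f"{basename}.json"
    report.to_frame().to_csv(csv_path, index=False)
    payload = {
        "records": json.loads(report.to_frame().to_json(orient="records")),
        "input_checksums": report.input_checksums,
    }
    json_path.write_text(json.dumps(payload, indent=1))
    return {"csv": csv_path, "json": json_path}


def read_run_config(path: PathLike) -> RunConfig:
    """Load a JSON run configuration; file paths are relative to the config."""
    path = Path(path)
    data = json.loads(path.read_text())
    base = path.parent
    entries = []
    for d in data.get("peptides", []):
        peptide = pio._peptide_from_dict(d)
        entries.append(PeptideEntry(
            peptide=peptide,
            competition_plate=base / d["competition_plate"] if d.get("competition_plate") else None,
            plate_series_id=d.get("plate_series_id"),
            cd_spectrum=base / d["cd_spectrum"] if d.get("cd_spectrum") else None,
            cd_blank=base / d["cd_blank"] if d.get("cd_blank") else None,
            shift_table=base / d["shift_table"] if d.get("shift_table") else None,
            restrain_rmin=bool(d.get("restrain_rmin", False)),
        ))
    return RunConfig(
        entries=entries,
        reference=data.get("reference"),
        tracer_conc=float(data.get("tracer_conc", 50e-9)),
        protein_conc=float(data.get("protein_conc", 15e-6)),
        temperature_K=float(data.get("temperature_K", 298.15)),
        rmin_value=float(data.get("rmin_value", -0.03)),
    )
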