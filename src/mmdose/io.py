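"""File formats: patient "past" files, "future" files and configuration.

Both patient files are UTF-8 CSV with a record-type column, preceded by a
``#``-prefixed key/value header block.

past file::

    # mmdose past v1
    # patient_id: pt01
    # crcl_ml_min: 81.0
    # weight_kg: 69.0
    record,time_h,duration_h,amount_mg,conc_mg_L
    DOSE,0.0,0.5,4000,
    OBS,6.0,,,35.2

future file::

    # mmdose future v1
    # dose_min_mg: 100
    # dose_max_mg: 20000
    # dose_step_mg: 10
    record,time_h,duration_h,conc_mg_L,weight
    TEMPLATE,24.0,0.5,,
    TARGET,32.0,,13.6,

Times are decimal hours from the first dose; concentrations mg/L; dose
amounts mg (a ``g``/``mg`` suffix is accepted and converted on read).  A
blank TARGET weight defers to the assay-information default.
"""

from __future__ import annotations

import csv
from pathlib import Path

from .optimize import FutureTemplate, TargetSpec
from .pk import DoseEvent, PatientCovariates, Regimen
from .posterior import PatientPast


class FileFormatError(ValueError):
    """A past/future file is malformed; the message names the location."""


def _parse_header(lines: list[str], path, magic: str) -> dict[str, str]:
    if not lines or not lines[0].strip().startswith(magic):
        raise FileFormatError(f"{path}: expected header line '{magic}'")
    meta = {}
    for line in lines[1:]:
        if not line.startswith("#"):
            break
        if ":" in line:
            key, _, val = line.lstrip("#").partition(":")
            meta[key.strip()] = val.strip()
    return meta


def _parse_amount(text: str, path, row: int) -> float:
    s = text.strip().lower()
    try:
        if s.endswith("mg"):
            return float(s[:-2])
        if s.endswith("g"):
            return float(s[:-1]) * 1000.0
        return float(s)
    except ValueError:
        raise FileFormatError(f"{path} row {row}: bad dose amount {text!r}") from None


def _float(text: str, path, row: int, col: str) -> float:
    try:
        return float(text)
    except (TypeError, ValueError):
        raise FileFormatError(f"{path} row {row}: bad value {text!r} in column {col}") from None


def read_past(path) -> PatientPast:
    path = Path(path)
    lines = path.read_text(encoding="utf-8").splitlines()
    meta = _parse_header(lines, path, "# mmdose past")
    for key in ("patient_id", "crcl_ml_min", "weight_kg"):
        if key not in meta:
            raise FileFormatError(f"{path}: missing covariate header '{key}'")
    cov = PatientCovariates(meta["patient_id"],
                            _float(meta["crcl_ml_min"], path, 0, "crcl_ml_min"),
                            _float(meta["weight_kg"], path, 0, "weight_kg"))
    body = [ln for ln in lines if not ln.startswith("#") and ln.strip()]
    reader = csv.DictReader(body)
    doses, obs = [], []
    for rownum, rec in enumerate(reader, start=2):
        kind = (rec.get("record") or "").strip().upper()
        if kind == "DOSE":
            amount = _parse_amount(rec.get("amount_mg") or "", path, rownum)
            if amount < 0:
                raise FileFormatError(f"{path} row {rownum}: negative dose amount")
            duration = _float(rec.get("duration_h"), path, rownum, "duration_h")
            if duration <= 0:
                raise FileFormatError(f"{path} row {rownum}: duration must be > 0")
            doses.append(DoseEvent(_float(rec.get("time_h"), path, rownum, "time_h"),
                                   duration, amount))
        elif kind == "OBS":
            obs.append((_float(rec.get("time_h"), path, rownum, "time_h"),
                        _float(rec.get("conc_mg_L"), path, rownum, "conc_mg_L")))
        else:
            raise FileFormatError(f"{path} row {rownum}: unknown record type {kind!r}")
    obs.sort()
    try:
        return PatientPast(cov, Regimen(doses), tuple(obs))
    except ValueError as exc:
        raise FileFormatError(f"{path}: {exc}") from exc


def write_past(past: PatientPast, path) -> None:
    path = Path(path)
    with path.open("w", encoding="utf-8", newline="") as fh:
        fh.write("# mmdose past v1\n")
        fh.write(f"# patient_id: {past.covariates.patient_id}\n")
        fh.write(f"# crcl_ml_min: {past.covariates.crcl!r}\n")
        fh.write(f"# weight_kg: {past.covariates.weight!r}\n")
        writer = csv.writer(fh)
        writer.writerow(["record", "time_h", "duration_h", "amount_mg", "conc_mg_L"])
        for d in past.regimen.doses:
            writer.writerow(["DOSE", repr(d.start), repr(d.duration), repr(d.amount), ""])
        for t, c in past.observations:
            writer.writerow(["OBS", repr(t), "", "", repr(c)])


def read_future(path) -> tuple[FutureTemplate, TargetSpec]:
    path = Path(path)
    lines = path.read_text(encoding="utf-8").splitlines()
    meta = _parse_header(lines, path, "# mmdose future")
    lo = _float(meta.get("dose_min_mg", "100"), path, 0, "dose_min_mg")
    hi = _float(meta.get("dose_max_mg", "20000"), path, 0, "dose_max_mg")
    step = _float(meta.get("dose_step_mg", "10"), path, 0, "dose_step_mg")
    body = [ln for ln in lines if not ln.startswith("#") and ln.strip()]
    reader = csv.DictReader(body)
    dose_times, durations, targets = [], [], []
    for rownum, rec in enumerate(reader, start=2):
        kind = (rec.get("record") or "").strip().upper()
        if kind == "TEMPLATE":
            duration = _float(rec.get("duration_h"), path, rownum, "duration_h")
            if duration <= 0:
                raise FileFormatError(f"{path} row {rownum}: duration must be > 0")
            dose_times.append(_float(rec.get("time_h"), path, rownum, "time_h"))
            durations.append(duration)
        elif kind == "TARGET":
            lam_text = (rec.get("weight") or "").strip()
            lam = None if not lam_text else _float(lam_text, path, rownum, "weight")
            targets.append((_float(rec.get("time_h"), path, rownum, "time_h"),
                            _float(rec.get("conc_mg_L"), path, rownum, "conc_mg_L"),
                            lam))
        else:
            raise FileFormatError(f"{path} row {rownum}: unknown record type {kind!r}")
    if not targets:
        raise FileFormatError(f"{path}: future file contains no TARGET rows")
    if not dose_times:
        raise FileFormatError(f"{path}: future file contains no TEMPLATE rows")
    try:
        template = FutureTemplate(tuple(dose_times), tuple(durations), (lo, hi), step)
        return template, TargetSpec(tuple(targets))
    except ValueError as exc:
        raise FileFormatError(f"{path}: {exc}") from exc


def write_future(template: FutureTemplate, targets: TargetSpec, path) -> None:
    path = Path(path)
    with path.open("w", encoding="utf-8", newline="") as fh:
        fh.write("# mmdose future v1\n")
        fh.write(f"# dose_min_mg: {template.dose_bounds[0]!r}\n")
        fh.write(f"# dose_max_mg: {template.dose_bounds[1]!r}\n")
        fh.write(f"# dose_step_mg: {template.dose_grid_step!r}\n")
        writer = csv.writer(fh)
        writer.writerow(["record", "time_h", "duration_h", "conc_mg_L", "weight"])
        for t, dur in zip(template.dose_times, template.durations):
            writer.writerow(["TEMPLATE", repr(t), repr(dur), "", ""])
        for t, c, lam in targets.targets:
            writer.writerow(["TARGET", repr(t), "", repr(c),
                             "" if lam is None else repr(lam)])
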