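"""Readers and writers for the package's TSV dialects.

Peak map TSV: columns ``mz  rt  intensity  [im]  [faims_cv]``, tab-separated,
'.' decimal.  PSM TSV: columns ``run  sequence  modifications  charge
calibrated_mz  rt  [im]  [faims_cv]  proteins  probability`` with proteins
';'-separated.  Quantification reports: ``ions.tsv`` (long format),
``peptides.tsv`` and ``proteins.tsv`` (one intensity column per run).
"""
from __future__ import annotations

import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .model import (
    IonKey,
    PsmRecord,
    QuantRow,
    RunPeakMap,
    ValidationError,
    canonical_modifications,
    theoretical_mz,
)

PEAK_COLUMNS = ("mz", "rt", "intensity", "im", "faims_cv")
PSM_COLUMNS = (
    "run",
    "sequence",
    "modifications",
    "charge",
    "calibrated_mz",
    "rt",
    "im",
    "faims_cv",
    "proteins",
    "probability",
)


class ParseError(ValueError):
    """A TSV file did not match the documented dialect."""


def _read_tsv(path: str | Path, required: tuple[str, ...]) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        df = pd.read_csv(path, sep="\t", header=0, float_precision="round_trip")
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise ParseError(f"{path}: {exc}") from exc
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing required columns {missing}")
    return df


def read_peak_map(path: str | Path, run_id: str | None = None) -> RunPeakMap:
    """Read one run's peak map TSV into a sorted :class:`RunPeakMap`.

    The run id defaults to the file stem.  Malformed rows raise
    :class:`ParseError` with the 1-based file line; invariant violations
    (e.g. negative intensity) raise :class:`ValidationError` naming the row.
    """
    path = Path(path)
    df = _read_tsv(path, ("mz", "rt", "intensity"))
    run_id = run_id if run_id is not None else path.stem
    cols = {}
    for name in ("mz", "rt", "intensity"):
        try:
            col = pd.to_numeric(df[name], errors="raise").to_numpy(dtype=np.float64)
        except (ValueError, TypeError) as exc:
            bad = pd.to_numeric(df[name], errors="coerce")
            row = int(np.flatnonzero(bad.isna().to_numpy() & df[name].notna().to_numpy()
                                     | df[name].isna().to_numpy())[0])
            raise ParseError(
                f"{path}: malformed value in column {name!r} at line {row + 2}"
            ) from exc
        nan = np.flatnonzero(np.isnan(col))
        if nan.size:
            raise ParseError(
                f"{path}: missing value in column {name!r} at line {nan[0] + 2}"
            )
        cols[name] = col
    im = None
    if "im" in df.columns and df["im"].notna().any():
        im = pd.to_numeric(df["im"], errors="coerce").to_numpy(dtype=np.float64)
        if np.isnan(im).any():
            row = int(np.flatnonzero(np.isnan(im))[0])
            raise ValidationError(
                f"{path}: mixed ion-mobility presence (missing at line {row + 2})"
            )
    cv = None
    if "faims_cv" in df.columns and df["faims_cv"].notna().any():
        cv = pd.to_numeric(df["faims_cv"], errors="coerce").to_numpy(dtype=np.float64)
        if np.isnan(cv).any():
            row = int(np.flatnonzero(np.isnan(cv))[0])
            raise ValidationError(
                f"{path}: mixed FAIMS CV presence (missing at line {row + 2})"
            )
    try:
        return RunPeakMap(run_id=run_id, mz=cols["mz"], rt=cols["rt"],
                          intensity=cols["intensity"], im=im, faims_cv=cv)
    except ValidationError as exc:
        raise ValidationError(f"{path}: {exc}") from exc


def write_peak_map(pmap: RunPeakMap, path: str | Path) -> None:
    """Write a peak map back to the TSV dialect (lossless round-trip)."""
    data = {"mz": pmap.mz, "rt": pmap.rt, "intensity": pmap.intensity}
    if pmap.im is not None:
        data["im"] = pmap.im
    if pmap.faims_cv is not None:
        data["faims_cv"] = pmap.faims_cv
    # %.17g is round-trip exact for IEEE doubles
    pd.DataFrame(data).to_csv(path, sep="\t", index=False, float_format="%.17g")


def read_psm_table(path: str | Path, sanity_ppm: float = 50.0) -> list[PsmRecord]:
    """Read a PSM table; returns records sorted by (run, ion).

    Calibrated m/z values further than ``sanity_ppm`` from the sequence-derived
    theoretical m/z trigger a warning (never an error): calibration is an
    upstream responsibility and this check only catches gross column mix-ups.
    """
    path = Path(path)
    df = _read_tsv(path, ("run", "sequence", "charge", "calibrated_mz", "rt",
                          "proteins", "probability"))
    records: list[PsmRecord] = []
    n_warn = 0
    for idx, row in enumerate(df.itertuples(index=False)):
        try:
            ion = IonKey(
                sequence=str(row.sequence),
                modifications=canonical_modifications(getattr(row, "modifications", "")),
                charge=int(row.charge),
            )
            im = getattr(row, "im", None)
            im = None if im is None or pd.isna(im) else float(im)
            cv = getattr(row, "faims_cv", None)
            cv = None if cv is None or pd.isna(cv) else float(cv)
            proteins = () if pd.isna(row.proteins) else tuple(
                p for p in str(row.proteins).split(";") if p
            )
            rec = PsmRecord(
                ion=ion,
                run_id=str(row.run),
                calibrated_mz=float(row.calibrated_mz),
                rt=float(row.rt),
                im=im,
                faims_cv=cv,
                protein_ids=proteins,
                probability=float(row.probability),
            )
        except (ValueError, TypeError, ValidationError) as exc:
            raise ParseError(f"{path}: malformed PSM at line {idx + 2}: {exc}") from exc
        try:
            theo = theoretical_mz(ion)
            if abs(rec.calibrated_mz - theo) / theo * 1e6 > sanity_ppm:
                n_warn += 1
        except Exception:
            pass  # non-standard residues: sanity check not applicable
        records.append(rec)
    if n_warn:
        warnings.warn(
            f"{path}: {n_warn} PSM(s) with calibrated m/z > {sanity_ppm} ppm from "
            "the sequence-derived value", stacklevel=2,
        )
    records.sort(key=lambda r: (r.run_id, r.ion))
    return records


def write_psm_table(records: list[PsmRecord], path: str | Path) -> None:
    rows = []
    for r in records:
        rows.append({
            "run": r.run_id,
            "sequence": r.ion.sequence,
            "modifications": r.ion.modifications,
            "charge": r.ion.charge,
            "calibrated_mz": r.calibrated_mz,
            "rt": r.rt,
            "im": "" if r.im is None else r.im,
            "faims_cv": "" if r.faims_cv is None else r.faims_cv,
            "proteins": ";".join(r.protein_ids),
            "probability": r.probability,
        })
    pd.DataFrame(rows, columns=list(PSM_COLUMNS)).to_csv(path, sep="\t", index=False)


ION_REPORT_COLUMNS = (
    "run", "sequence", "modifications", "charge", "mz", "rt_apex", "rt_start",
    "rt_end", "im", "intensity", "source", "transfer_probability", "proteins",
)


def _fmt(x) -> str:
    if x is None:
        return ""
    if isinstance(x, float):
        return f"{x:.8g}"
    return str(x)


def build_peptide_table(rows: list[QuantRow], run_ids: list[str]) -> pd.DataFrame:
    """Peptide-level intensities: sum of ion intensities per sequence per run."""
    acc: dict[str, dict[str, float]] = {}
    n_ions: dict[str, set] = {}
    for r in rows:
        acc.setdefault(r.ion.sequence, {})
        acc[r.ion.sequence][r.run_id] = acc[r.ion.sequence].get(r.run_id, 0.0) + r.intensity
        n_ions.setdefault(r.ion.sequence, set()).add(r.ion)
    out = []
    for seq in sorted(acc):
        rec = {"sequence": seq, "n_ions": len(n_ions[seq])}
        for run in run_ids:
            rec[f"intensity_{run}"] = acc[seq].get(run, np.nan)
        out.append(rec)
    cols = ["sequence", "n_ions"] + [f"intensity_{run}" for run in run_ids]
    return pd.DataFrame(out, columns=cols)


def write_quant_reports(
    rows: list[QuantRow],
    protein_table: pd.DataFrame,
    out_dir: str | Path,
    run_ids: list[str] | None = None,
) -> dict[str, Path]:
    """Write ion-, peptide- and protein-level TSV reports.

    Returns the written paths.  Row order is deterministic; MBR rows carry a
    non-empty transfer probability.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    if run_ids is None:
        run_ids = sorted({r.run_id for r in rows})

    rows = sorted(rows, key=lambda r: (r.ion.sequence, r.ion.modifications,
                                       r.ion.charge, r.run_id, r.source))
    ion_path = out_dir / "ions.tsv"
    with ion_path.open("w") as fh:
        fh.write("\t".join(ION_REPORT_COLUMNS) + "\n")
        for r in rows:
            f = r.feature
            fh.write("\t".join([
                r.run_id, r.ion.sequence, r.ion.modifications, str(r.ion.charge),
                _fmt(None if f is None else f.mono_mz),
                _fmt(None if f is None else f.rt_apex),
                _fmt(None if f is None else f.rt_start),
                _fmt(None if f is None else f.rt_end),
                _fmt(None if f is None else f.im_center),
                _fmt(r.intensity), r.source,
                _fmt(r.transfer_probability),
                ";".join(r.protein_ids),
            ]) + "\n")

    pep_path = out_dir / "peptides.tsv"
    build_peptide_table(rows, run_ids).to_csv(
        pep_path, sep="\t", index=False, float_format="%.8g")

    prot_path = out_dir / "proteins.tsv"
    protein_table.to_csv(prot_path, sep="\t", index=False, float_format="%.8g")
    return {"ions": ion_path, "peptides": pep_path, "proteins": prot_path}
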