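"""Strict readers and writers for the package's plain-text data formats.

Schemas (all CSV, UTF-8, "." decimal separator, header required):

* tracks:    ``track_id,time_s,length_um,condition``
* turbidity: ``time_s,a350,condition``
* ITC:       ``injection_index,volume_uL,heat``  (heat in µJ)
* peaks:     ``mz,intensity``
* FASTA for peptide sequences, wrapped at 60 columns; the description
  line may carry a ``n_disulfides=<int>`` key.

Readers validate headers and numeric content and report offending
columns/lines; write-then-read is an identity on the numeric data.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .dynamics import Track, tracks_from_frame
from .itc import ITCSchedule, Titration
from .peptides import Peptide
from .polymerization import TurbidityCurve

__all__ = [
    "SchemaError",
    "read_tracks", "write_tracks",
    "read_turbidity", "write_turbidity",
    "read_itc", "write_itc",
    "read_peaks", "write_peaks",
    "read_fasta", "write_fasta",
]

_SCHEMAS = {
    "tracks": (["track_id", "time_s", "length_um", "condition"],
               {"time_s": float, "length_um": float}),
    "turbidity": (["time_s", "a350", "condition"],
                  {"time_s": float, "a350": float}),
    "itc": (["injection_index", "volume_uL", "heat"],
            {"injection_index": int, "volume_uL": float, "heat": float}),
    "peaks": (["mz", "intensity"], {"mz": float, "intensity": float}),
}

_FLOAT_FMT = "%.10g"


class SchemaError(ValueError):
    """A file does not conform to its declared schema."""


def _read_csv(path: str | Path, schema: str) -> pd.DataFrame:
    columns, dtypes = _SCHEMAS[schema]
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing column(s) {missing} "
                          f"for schema '{schema}' (found {list(df.columns)})")
    extra = [c for c in df.columns if c not in columns]
    if extra:
        raise SchemaError(f"{path}: unexpected column(s) {extra} "
                          f"for schema '{schema}'")
    for col, typ in dtypes.items():
        try:
            df[col] = df[col].astype(typ)
        except ValueError:
            bad = df.index[pd.to_numeric(df[col], errors="coerce").isna()]
            line = int(bad[0]) + 2 if len(bad) else "?"  # +2: header + 1-based
            raise SchemaError(f"{path}: non-numeric value in column "
                              f"'{col}' at line {line}") from None
    return df[columns]


def read_tracks(path: str | Path, as_tracks: bool = False
                ) -> pd.DataFrame | list[Track]:
    """Read a tracks CSV; optionally return built Track objects."""
    df = _read_csv(path, "tracks")
    return tracks_from_frame(df) if as_tracks else df


def write_tracks(data: pd.DataFrame | Iterable[Track], path: str | Path) -> None:
    if not isinstance(data, pd.DataFrame):
        frames = [pd.DataFrame({"track_id": tr.track_id, "time_s": tr.time,
                                "length_um": tr.length, "condition": tr.condition})
                  for tr in data]
        data = pd.concat(frames, ignore_index=True)
    cols = _SCHEMAS["tracks"][0]
    data[cols].to_csv(path, index=False, float_format=_FLOAT_FMT)


def read_turbidity(path: str | Path) -> dict[str, TurbidityCurve]:
    """Read a turbidity CSV into one curve per condition label."""
    df = _read_csv(path, "turbidity")
    out = {}
    for cond, grp in df.groupby("condition", sort=True):
        grp = grp.sort_values("time_s")
        out[str(cond)] = TurbidityCurve(time=grp["time_s"].to_numpy(),
                                        a350=grp["a350"].to_numpy(),
                                        condition=str(cond))
    return out


def write_turbidity(curves: Iterable[TurbidityCurve], path: str | Path) -> None:
    frames = [pd.DataFrame({"time_s": c.time, "a350": c.a350,
                            "condition": c.condition}) for c in curves]
    pd.concat(frames, ignore_index=True).to_csv(path, index=False,
                                                float_format=_FLOAT_FMT)


def read_itc(path: str | Path, schedule: ITCSchedule | None = None,
             blank_path: str | Path | None = None,
             **schedule_overrides) -> Titration:
    """Read an ITC CSV into a Titration.

    The CSV carries only per-injection volumes and heats; cell/syringe
    concentrations, cell volume and temperature come from ``schedule`` or
    keyword overrides of the default schedule. Injection volumes in the
    file replace the schedule's. A blank titration file may be attached.
    """
    df = _read_csv(path, "itc")
    df = df.sort_values("injection_index")
    expected = np.arange(1, len(df) + 1)
    if not np.array_equal(df["injection_index"].to_numpy(), expected):
        raise SchemaError(f"{path}: injection_index must run 1..n without gaps")
    if schedule is not None and schedule_overrides:
        raise ValueError("pass either schedule or overrides, not both")
    base = schedule if schedule is not None else ITCSchedule(**schedule_overrides)
    sched = ITCSchedule(cell_conc=base.cell_conc, syringe_conc=base.syringe_conc,
                        inj_volumes=tuple(df["volume_uL"]),
                        cell_volume=base.cell_volume, temperature=base.temperature)
    blank = None
    if blank_path is not None:
        bdf = _read_csv(blank_path, "itc").sort_values("injection_index")
        if len(bdf) != len(df):
            raise SchemaError(f"{blank_path}: blank has {len(bdf)} injections, "
                              f"experiment has {len(df)}")
        blank = bdf["heat"].to_numpy()
    return Titration(schedule=sched, heats=df["heat"].to_numpy(),
                     blank_heats=blank)


def write_itc(titration: Titration, path: str | Path) -> None:
    n = titration.schedule.n_injections
    pd.DataFrame({
        "injection_index": np.arange(1, n + 1),
        "volume_uL": titration.schedule.inj_volumes,
        "heat": titration.heats,
    }).to_csv(path, index=False, float_format=_FLOAT_FMT)


def read_peaks(path: str | Path) -> pd.DataFrame:
    return _read_csv(path, "peaks")


def write_peaks(peaks: pd.DataFrame, path: str | Path) -> None:
    peaks[_SCHEMAS["peaks"][0]].to_csv(path, index=False, float_format=_FLOAT_FMT)


def read_fasta(path: str | Path) -> list[Peptide]:
    """Read peptides from FASTA; ``n_disulfides=<k>`` in the description is honored."""
    peptides = []
    for rec in SeqIO.parse(str(path), "fasta"):
        n_ss = 0
        for token in rec.description.split():
            if token.startswith("n_disulfides="):
                n_ss = int(token.split("=", 1)[1])
        peptides.append(Peptide(sequence=str(rec.seq), n_disulfides=n_ss,
                                name=rec.id))
    if not peptides:
        raise SchemaError(f"{path}: no FASTA records found")
    return peptides


def write_fasta(peptides: Sequence[Peptide], path: str | Path) -> None:
    records = [SeqRecord(Seq(p.sequence), id=p.name or f"peptide_{i}",
                         description=f"n_disulfides={p.n_disulfides}")
               for i, p in enumerate(peptides)]
    with open(path, "w") as fh:
        SeqIO.write(records, fh, "fasta")
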