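"""File formats: long-format plate CSV, segment FASTA, tidy TSV tables.

The plate CSV is long/tidy — one row per well and timepoint — with a small
``# key=value`` header block holding plate-level metadata (the stimulation
time).  Segment FASTA headers follow ``receptorID|segment|group|class``.
"""
from __future__ import annotations

import warnings
from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .types import DataError, SegmentRecord, WellMeta, WellTrace

__all__ = [
    "PLATE_COLUMNS",
    "write_plate_csv",
    "read_plate_csv",
    "plate_to_welltraces",
    "read_segments_fasta",
    "write_segments_fasta",
]

PLATE_COLUMNS = [
    "well_id",
    "condition",
    "receptor",
    "arrestin",
    "grk_label",
    "role",
    "concentration_M",
    "replicate",
    "time_s",
    "donor",
    "acceptor",
]

_VALID_GROUPS = {"GRK2/3", "GRK2/3/5/6", "unclassified", "pre-coupling"}


def write_plate_csv(table: pd.DataFrame, path, stimulation_time_s: float) -> None:
    """Write a long-format plate table with its metadata header block."""
    path = Path(path)
    missing = [c for c in PLATE_COLUMNS if c not in table.columns]
    if missing:
        raise DataError(f"plate table missing column(s) {missing}")
    with open(path, "w", newline="") as fh:
        fh.write(f"# stimulation_time_s={stimulation_time_s:g}\n")
        table[PLATE_COLUMNS].to_csv(fh, index=False, float_format="%.10g")


def read_plate_csv(path):
    """Read and validate a plate CSV; returns (table, metadata dict).

    Malformed rows, missing columns, non-numeric channel values and duplicate
    (well, time) pairs are rejected with identifying detail.
    """
    path = Path(path)
    meta = {}
    header_lines = 0
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            header_lines += 1
            body = line[1:].strip()
            if "=" in body:
                key, _, value = body.partition("=")
                meta[key.strip()] = value.strip()
        else:
            raise DataError(f"{path}: empty file")
    try:
        table = pd.read_csv(path, skiprows=header_lines)
    except pd.errors.EmptyDataError:
        raise DataError(f"{path}: no data rows") from None
    if table.empty:
        raise DataError(f"{path}: no data rows")
    missing = [c for c in PLATE_COLUMNS if c not in table.columns]
    if missing:
        raise DataError(f"{path}: missing column(s) {missing}")
    for col in ("concentration_M", "time_s", "donor", "acceptor"):
        coerced = pd.to_numeric(table[col], errors="coerce")
        bad = coerced.isna() & table[col].notna()
        if bad.any():
            line_no = int(bad.idxmax()) + header_lines + 2  # header + 1-based
            raise DataError(f"{path}: non-numeric {col!r} value at line {line_no}")
        table[col] = coerced
    dup = table.duplicated(subset=["well_id", "time_s"])
    if dup.any():
        line_no = int(dup.idxmax()) + header_lines + 2
        raise DataError(f"{path}: duplicate (well_id, time_s) at line {line_no}")
    if "stimulation_time_s" in meta:
        meta["stimulation_time_s"] = float(meta["stimulation_time_s"])
    return table, meta


def plate_to_welltraces(table: pd.DataFrame, stimulation_time_s: float):
    """Materialise WellTrace objects from a validated long-format table."""
    wells = []
    for well_id, grp in table.groupby("well_id", sort=True):
        grp = grp.sort_values("time_s")
        roles = grp["role"].unique()
        if len(roles) != 1:
            raise DataError(f"well {well_id}: inconsistent roles {list(roles)}")
        first = grp.iloc[0]
        meta = WellMeta(
            well_id=str(well_id),
            condition=str(first["condition"]),
            role=str(first["role"]),
            concentration_M=float(first["concentration_M"]),
            replicate=int(first["replicate"]),
            stimulation_time_s=float(stimulation_time_s),
            receptor=str(first.get("receptor", "") or ""),
            arrestin=str(first.get("arrestin", "") or ""),
            grk_label=str(first.get("grk_label", "") or ""),
        )
        wells.append(
            WellTrace(
                time=grp["time_s"].to_numpy(dtype=float),
                donor=grp["donor"].to_numpy(dtype=float),
                acceptor=grp["acceptor"].to_numpy(dtype=float),
                meta=meta,
            )
        )
    return wells


def read_segments_fasta(path) -> list:
    """Read receptor segments from FASTA with receptorID|segment|group|class headers.

    Lower-case sequences are upper-cased with a warning; unknown group labels
    map to "unclassified" with a warning.
    """
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        fields = rec.description.split("|")
        if len(fields) != 4:
            raise DataError(
                f"{path}: header {rec.description!r} does not follow "
                "receptorID|segment|group|class"
            )
        receptor_id, segment_kind, group, cls = (f.strip() for f in fields)
        seq = str(rec.seq)
        if seq != seq.upper():
            warnings.warn(f"{receptor_id}: lower-case sequence upper-cased")
            seq = seq.upper()
        if group not in _VALID_GROUPS:
            warnings.warn(f"{receptor_id}: unknown group {group!r} mapped to 'unclassified'")
            group = "unclassified"
        records.append(
            SegmentRecord(
                receptor_id=receptor_id,
                segment_kind=segment_kind,
                sequence=seq,
                group_label=group,
                receptor_class=cls,
            )
        )
    if not records:
        raise DataError(f"{path}: no FASTA records")
    return records


def write_segments_fasta(records, path) -> None:
    seqs = [
        SeqRecord(
            Seq(r.sequence),
            id=f"{r.receptor_id}|{r.segment_kind}|{r.group_label}|{r.receptor_class}",
            description="",
        )
        for r in records
    ]
    SeqIO.write(seqs, str(path), "fasta")
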