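"""Readers and writers: multi-page TIFF stacks, CSV tables, FASTA pairs, JSON.

Stacks are 16-bit unsigned multi-page TIFFs with a JSON sidecar carrying
the frame interval, position id and any ground truth.  Tables are plain
CSV with a header row and '.' decimal points; unknown columns survive a
round-trip.  Ig sequence pairs are FASTA records whose ids share a prefix
and end in ``_germline`` / ``_mature``.
"""

from __future__ import annotations

import json
import math
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import tifffile
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .binding import DilutionSeries
from .errors import FormatError
from .imaging import FrameStack
from .shm import IgAlignedPair
from .synthetic import RawCompetitionTable, TitrationCurve

__all__ = [
    "read_stack",
    "write_stack",
    "read_titration",
    "write_titration",
    "read_dilution_series",
    "write_dilution_series",
    "read_competition_table",
    "write_competition_table",
    "read_ig_pairs",
    "write_ig_pairs",
    "write_json",
]


# --------------------------------------------------------------------------
# Stacks


def write_stack(path, stack: FrameStack, truth: Optional[dict] = None) -> None:
    """Write a stack as uint16 multi-page TIFF plus a JSON sidecar."""
    path = Path(path)
    frames = np.asarray(stack.frames)
    if frames.min() < 0 or frames.max() > np.iinfo(np.uint16).max:
        raise FormatError("intensities outside the uint16 range; rescale before writing")
    tifffile.imwrite(path, np.round(frames).astype(np.uint16))
    sidecar = {
        "frame_interval": stack.frame_interval,
        "position_id": stack.position_id,
    }
    if truth is not None:
        sidecar["truth"] = truth
    path.with_suffix(path.suffix + ".json").write_text(
        json.dumps(sidecar, sort_keys=True, indent=2)
    )


def read_stack(path, frame_interval: Optional[float] = None, position_id: Optional[str] = None) -> FrameStack:
    """Read a multi-page TIFF stack; metadata comes from the sidecar or arguments."""
    path = Path(path)
    try:
        with tifffile.TiffFile(path) as tif:
            shapes = {page.shape for page in tif.pages}
            if len(shapes) != 1:
                raise FormatError(f"{path}: pages have ragged dimensions {sorted(shapes)}")
            frames = tif.asarray()
    except FormatError:
        raise
    except Exception as exc:
        raise FormatError(f"{path}: unreadable TIFF ({exc})") from exc
    if frames.ndim == 2:
        frames = frames[np.newaxis]

    sidecar_path = path.with_suffix(path.suffix + ".json")
    if sidecar_path.exists():
        sidecar = json.loads(sidecar_path.read_text())
        frame_interval = frame_interval or sidecar.get("frame_interval")
        position_id = position_id or sidecar.get("position_id")
    return FrameStack(
        frames=frames.astype(float),
        frame_interval=frame_interval or 15.0,
        position_id=position_id or Path(path).stem,
    )


# --------------------------------------------------------------------------
# CSV tables


def _read_csv(path, required: Sequence[str]) -> pd.DataFrame:
    df = pd.read_csv(path)
    for col in required:
        if col not in df.columns:
            raise FormatError(f"{path}: missing required column {col!r}")
        if df[col].dtype == object and df[col].str.contains(",", na=False).any():
            raise FormatError(
                f"{path}: column {col!r} contains ',' — locale decimal commas are not "
                "supported; use '.' as the decimal separator"
            )
    return df


def write_titration(path, curve: TitrationCurve) -> None:
    pd.DataFrame({"concentration_ug_ml": curve.x, "signal": curve.y}).to_csv(path, index=False)


def read_titration(path) -> TitrationCurve:
    df = _read_csv(path, ["concentration_ug_ml", "signal"])
    return TitrationCurve(
        x=df["concentration_ug_ml"].to_numpy(float), y=df["signal"].to_numpy(float)
    )


def write_dilution_series(path, series: DilutionSeries) -> None:
    rows = [
        {"kind": "sample", "dilution": d, "signal": s}
        for d, s in zip(series.dilutions, series.signals)
    ] + [
        {"kind": "control", "dilution": math.nan, "signal": s}
        for s in series.control_signals
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def read_dilution_series(path) -> DilutionSeries:
    df = _read_csv(path, ["kind", "signal"])
    samples = df[df["kind"] == "sample"]
    if len(samples) and "dilution" not in df.columns:
        raise FormatError(f"{path}: missing required column 'dilution'")
    controls = df[df["kind"] == "control"]
    return DilutionSeries(
        dilutions=[int(d) for d in samples["dilution"]],
        signals=samples["signal"].astype(float).tolist(),
        control_signals=controls["signal"].astype(float).tolist(),
    )


def write_competition_table(path, table: RawCompetitionTable) -> None:
    rows = []
    for (first, second), raw in sorted(table.entries.items()):
        rows.append({"kind": "pair", "first_mab": first, "second_mab": second, "raw": raw})
    for second, raw in sorted(table.control_entries.items()):
        rows.append(
            {"kind": "control", "first_mab": table.control_id, "second_mab": second, "raw": raw}
        )
    for second, raw in sorted(table.self_entries.items()):
        rows.append({"kind": "self", "first_mab": second, "second_mab": second, "raw": raw})
    pd.DataFrame(rows).to_csv(path, index=False)


def read_competition_table(path) -> RawCompetitionTable:
    df = _read_csv(path, ["kind", "first_mab", "second_mab", "raw"])
    entries: dict[tuple[str, str], float] = {}
    control_entries: dict[str, float] = {}
    self_entries: dict[str, float] = {}
    control_id = "ctrl"
    mab_ids: list[str] = []
    for _, row in df.iterrows():
        second = str(row["second_mab"])
        raw = float(row["raw"])
        if second not in mab_ids:
            mab_ids.append(second)
        if row["kind"] == "pair":
            entries[(str(row["first_mab"]), second)] = raw
        elif row["kind"] == "control":
            control_entries[second] = raw
            control_id = str(row["first_mab"])
        elif row["kind"] == "self":
            self_entries[second] = raw
        else:
            raise FormatError(f"{path}: unknown row kind {row['kind']!r}")
    table = RawCompetitionTable(
        mab_ids=mab_ids,
        entries=entries,
        control_entries=control_entries,
        self_entries=self_entries,
        control_id=control_id,
    )
    table.validate()
    return table


# --------------------------------------------------------------------------
# FASTA


def write_ig_pairs(path, pairs: dict[str, tuple[str, str]]) -> None:
    """Write ``{prefix: (germline, mature)}`` as paired FASTA records."""
    records = []
    for prefix, (germline, mature) in pairs.items():
        records.append(SeqRecord(Seq(germline), id=f"{prefix}_germline", description=""))
        records.append(SeqRecord(Seq(mature), id=f"{prefix}_mature", description=""))
    SeqIO.write(records, str(path), "fasta")


def read_ig_pairs(path) -> dict[str, IgAlignedPair]:
    """Read paired ``*_germline`` / ``*_mature`` FASTA records."""
    germlines: dict[str, str] = {}
    matures: dict[str, str] = {}
    for record in SeqIO.parse(str(path), "fasta"):
        if record.id.endswith("_germline"):
            germlines[record.id[: -len("_germline")]] = str(record.seq)
        elif record.id.endswith("_mature"):
            matures[record.id[: -len("_mature")]] = str(record.seq)
        else:
            raise FormatError(
                f"{path}: record {record.id!r} has neither _germline nor _mature suffix"
            )
    missing = set(germlines) ^ set(matures)
    if missing:
        raise FormatError(f"{path}: unpaired sequence prefixes {sorted(missing)}")
    return {
        prefix: IgAlignedPair(germline=germlines[prefix], mature=matures[prefix])
        for prefix in sorted(germlines)
    }


def write_json(path, payload: dict) -> None:
    """Deterministic JSON output (sorted keys, stable float formatting)."""
    Path(path).write_text(json.dumps(payload, sort_keys=True, indent=2) + "\n")
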