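"""Peak tables and their TSV serialization.

One table holds the summed-spectrum peak heights of a single sample: one
amide record per modeled residue plus the methyl internal-standard records.
The on-disk dialect is a UTF-8 TSV with ``#`` comment lines (two of which
carry the experiment design and the noise rms as JSON metadata), a mandatory
header ``signal_id  kind  intensity  snr  overlap  condition  timepoint_min``
and one row per record.  The round trip is lossless.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

__all__ = ["PeakRecord", "PeakTable", "PeakTableParseError", "write_peak_table", "read_peak_table"]

COLUMNS = ("signal_id", "kind", "intensity", "snr", "overlap", "condition", "timepoint_min")


class PeakTableParseError(ValueError):
    """Raised on a malformed peak-table file; message names the line."""


@dataclass(frozen=True)
class PeakRecord:
    """One resonance: an amide (signal_id = residue number) or a methyl."""

    signal_id: int
    kind: str
    intensity: float
    snr: float
    overlap: bool = False

    def __post_init__(self) -> None:
        if self.kind not in ("amide", "methyl"):
            raise ValueError(f"kind must be 'amide' or 'methyl', got {self.kind!r}")
        if self.intensity < 0:
            raise ValueError(f"intensity must be >= 0, got {self.intensity!r}")


@dataclass(frozen=True)
class PeakTable:
    design: "ExperimentDesign"  # noqa: F821 - defined in thzhdx.experiment
    records: tuple[PeakRecord, ...]
    noise_rms: float

    def __init__(self, design, records: Iterable[PeakRecord], noise_rms: float) -> None:
        object.__setattr__(self, "design", design)
        object.__setattr__(self, "records", tuple(records))
        object.__setattr__(self, "noise_rms", noise_rms)

    def amides(self) -> list[PeakRecord]:
        return [r for r in self.records if r.kind == "amide"]

    def methyls(self) -> list[PeakRecord]:
        return [r for r in self.records if r.kind == "methyl"]

    def amide(self, residue_number: int) -> PeakRecord:
        for r in self.records:
            if r.kind == "amide" and r.signal_id == residue_number:
                return r
        raise KeyError(f"no amide record for residue {residue_number}")


def _fmt(value: float) -> str:
    if math.isinf(value):
        return "inf"
    return repr(float(value))


def write_peak_table(table: PeakTable, path: str | Path) -> None:
    """Write ``table`` as TSV (see module docstring for the dialect)."""
    design_dict = dataclasses.asdict(table.design)
    design_dict["storage_hours_range"] = list(design_dict["storage_hours_range"])
    lines = [
        "# thzhdx peak table",
        f"# design: {json.dumps(design_dict, sort_keys=True)}",
        f"# noise_rms: {_fmt(table.noise_rms)}",
        "\t".join(COLUMNS),
    ]
    for rec in table.records:
        lines.append(
            "\t".join(
                (
                    str(rec.signal_id),
                    rec.kind,
                    _fmt(rec.intensity),
                    _fmt(rec.snr),
                    "1" if rec.overlap else "0",
                    table.design.condition,
                    str(table.design.perturbation_minutes),
                )
            )
        )
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def _parse_float(text: str, column: str, lineno: int) -> float:
    try:
        return float(text)
    except ValueError:
        raise PeakTableParseError(f"line {lineno}: column {column!r} is not a number: {text!r}") from None


def read_peak_table(path: str | Path) -> PeakTable:
    """Read a peak-table TSV written by :func:`write_peak_table`.

    ``#`` comment lines are ignored except for the ``design``/``noise_rms``
    metadata lines; a missing required column or malformed row raises
    :class:`PeakTableParseError` naming the offending line.
    """
    from .experiment import ExperimentDesign  # deferred: avoids an import cycle

    design_dict: dict | None = None
    noise_rms: float | None = None
    header: list[str] | None = None
    records: list[PeakRecord] = []
    for lineno, raw in enumerate(Path(path).read_text(encoding="utf-8").splitlines(), start=1):
        line = raw.rstrip("\n")
        if not line.strip():
            continue
        if line.startswith("#"):
            body = line[1:].strip()
            if body.startswith("design:"):
                design_dict = json.loads(body[len("design:"):].strip())
            elif body.startswith("noise_rms:"):
                noise_rms = _parse_float(body[len("noise_rms:"):].strip(), "noise_rms", lineno)
            continue
        fields = line.split("\t")
        if header is None:
            header = fields
            missing = [c for c in COLUMNS if c not in header]
            if missing:
                raise PeakTableParseError(f"line {lineno}: missing column(s) {missing}")
            continue
        if len(fields) != len(header):
            raise PeakTableParseError(
                f"line {lineno}: expected {len(header)} fields, got {len(fields)}"
            )
        row = dict(zip(header, fields))
        records.append(
            PeakRecord(
                signal_id=int(row["signal_id"]),
                kind=row["kind"],
                intensity=_parse_float(row["intensity"], "intensity", lineno),
                snr=_parse_float(row["snr"], "snr", lineno),
                overlap=row["overlap"] not in ("0", "false", "False"),
            )
        )
    if header is None:
        raise PeakTableParseError("no header line found")
    if design_dict is None or noise_rms is None:
        raise PeakTableParseError("missing '# design:' or '# noise_rms:' metadata line")
    design_dict["storage_hours_range"] = tuple(design_dict["storage_hours_range"])
    design = ExperimentDesign(**design_dict)
    return PeakTable(design=design, records=records, noise_rms=noise_rms)
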