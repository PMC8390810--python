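"""Mapping classification results onto the protein structure.

Writes a copy of a PDB coordinate file with a per-residue numeric score in
the temperature-factor column (renderable by any standard structure viewer)
plus a plain-text attribute file, and tabulates label/onset counts.

Score convention: accelerated -> -1, decelerated -> +1, unchanged -> 0;
calls detected at both 6 and 12 min carry full weight, calls detected only
at 12 min half weight (+-0.5).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
from Bio.PDB import PDBIO, PDBParser

from .statistics import ClassificationResult

__all__ = ["ResidueAnnotation", "numeric_score", "annotate_structure", "summary_table"]


@dataclass(frozen=True)
class ResidueAnnotation:
    residue_number: int
    chain_id: str
    label: str
    onset: str
    numeric_score: float


def numeric_score(label: str, onset: str) -> float:
    """Signed, onset-shaded score for one residue."""
    sign = {"accelerated": -1.0, "decelerated": 1.0, "unchanged": 0.0}[label]
    weight = {"at_6_and_12": 1.0, "only_12": 0.5, "none": 0.0}[onset]
    if label == "unchanged":
        return 0.0
    return sign * (weight if weight > 0 else 1.0)


def annotate_structure(
    classifications: Iterable[ClassificationResult],
    pdb_path: str | Path,
    chain_id: str,
    out_pdb: str | Path,
    out_attributes: str | Path,
) -> list[ResidueAnnotation]:
    """Write the annotated coordinate file and the attribute table.

    All temperature factors are first zeroed; atoms of classified residues
    then receive the residue's numeric score.  Classified residues absent
    from the chain are skipped with a warning.  The attribute file holds
    ``chain  resnum  label  score`` rows sorted by residue number, so
    re-running on the same input is byte-identical.
    """
    classifications = list(classifications)
    if not classifications:
        raise ValueError("no classification results to annotate")
    parser = PDBParser(QUIET=True)
    structure = parser.get_structure("model", str(pdb_path))
    model = next(structure.get_models())  # single/first model only
    if chain_id not in [c.id for c in model]:
        raise ValueError(f"chain {chain_id!r} not found in {pdb_path}")
    chain = model[chain_id]
    for atom in model.get_atoms():
        atom.set_bfactor(0.0)

    present = {res.id[1] for res in chain if res.id[0] == " "}
    annotations: list[ResidueAnnotation] = []
    for result in sorted(classifications, key=lambda c: c.residue_number):
        score = numeric_score(result.label, result.onset)
        if result.residue_number not in present:
            warnings.warn(
                f"residue {result.residue_number} not in chain {chain_id}; skipped",
                stacklevel=2,
            )
            continue
        for atom in chain[(" ", result.residue_number, " ")]:
            atom.set_bfactor(score)
        annotations.append(
            ResidueAnnotation(result.residue_number, chain_id, result.label, result.onset, score)
        )

    io = PDBIO()
    io.set_structure(model)
    io.save(str(out_pdb))
    lines = ["chain\tresnum\tlabel\tscore"]
    lines += [
        f"{a.chain_id}\t{a.residue_number}\t{a.label}\t{a.numeric_score:g}" for a in annotations
    ]
    Path(out_attributes).write_text("\n".join(lines) + "\n", encoding="utf-8")
    return annotations


def summary_table(
    classifications: Iterable[ClassificationResult],
    class_by_residue: Mapping[int, str] | None = None,
) -> pd.DataFrame:
    """Counts per (label, onset) and, if a class map is given, per class."""
    rows = [
        {
            "label": c.label,
            "onset": c.onset,
            "hydropathy_class": (class_by_residue or {}).get(c.residue_number, ""),
        }
        for c in classifications
    ]
    frame = pd.DataFrame(rows, columns=["label", "onset", "hydropathy_class"])
    grouped = (
        frame.groupby(["label", "onset", "hydropathy_class"], sort=True)
        .size()
        .reset_index(name="count")
    )
    return grouped
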