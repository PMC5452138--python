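"""Per-sequence structural statistics extracted from folding output.

The reported quantities mirror the classic spacer-structure descriptors:
lowest energy state (LES, the MFE), total number of suboptimal structures,
number of hairpin (terminal) loops, and the count / percentage of paired
nucleotides.  All features are computed on the single lowest-energy
structure; the suboptimal set contributes only its cardinality.
"""
from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

from .fold import FoldResult, SecondaryStructure, StructureError, dotbracket_to_pairs
from .records import SequenceRecord


@dataclass
class StructureFeatures:
    id: str
    species: str
    group: str
    region: str
    length: int
    les: float
    n_structures: int
    n_hairpins: int
    n_paired: int
    pct_paired: float


def count_hairpins(structure: SecondaryStructure | str) -> int:
    """Number of hairpin loops: pairs (i, j) with no paired base inside.

    Accepts a structure object or a bare dot-bracket string.  A multibranch
    loop contributes no hairpin of its own; only terminal loops count.
    """
    if isinstance(structure, str):
        pairs = dotbracket_to_pairs(structure)  # raises on unbalanced input
    else:
        pairs = structure.pairs
    paired = set()
    for i, j in pairs:
        paired.add(i)
        paired.add(j)
    count = 0
    for i, j in pairs:
        if not any(k in paired for k in range(i + 1, j)):
            count += 1
    return count


def paired_stats(structure: SecondaryStructure) -> tuple[int, float]:
    """Count and percentage of nucleotides engaged in base pairs."""
    n_paired = 2 * len(structure.pairs)
    return n_paired, 100.0 * n_paired / structure.length


def featurize(fold: FoldResult, record: SequenceRecord) -> StructureFeatures:
    """Assemble the per-sequence feature row from a fold of ``record``."""
    optimal = fold.optimal()
    seq = record.ungapped()
    if optimal.length != len(seq):
        raise StructureError(
            f"fold length {optimal.length} does not match record {record.id!r} "
            f"length {len(seq)}"
        )
    n_paired, pct = paired_stats(optimal)
    return StructureFeatures(
        id=record.id,
        species=record.species,
        group=record.group,
        region=record.region,
        length=len(seq),
        les=fold.les,
        n_structures=fold.n_structures,
        n_hairpins=count_hairpins(optimal),
        n_paired=n_paired,
        pct_paired=pct,
    )


FEATURE_COLUMNS = [
    "id", "species", "group", "region", "length", "les",
    "n_structures", "n_hairpins", "n_paired", "pct_paired",
]


def write_features(rows: Sequence[StructureFeatures], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(FEATURE_COLUMNS)
        for r in rows:
            w.writerow([
                r.id, r.species, r.group, r.region, r.length,
                f"{r.les:.2f}", r.n_structures, r.n_hairpins, r.n_paired,
                f"{r.pct_paired:.4f}",
            ])
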