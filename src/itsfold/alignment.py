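"""Alignment descriptive statistics, ambiguous-column removal, gap coding.

Works on pre-aligned FASTA (alignment construction is upstream of this
package).  Column coordinates in every public interface and report are
1-based, closed intervals.
"""
from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

from .records import IUPAC_CHARS, SequenceRecord

#: Characters that count as unambiguous base states in variability scans.
_STATE_CHARS = set("ACGTU")
#: Characters that are neither states nor gaps -> "ambiguous" columns.
_AMBIGUITY = IUPAC_CHARS - _STATE_CHARS - {"-"}


@dataclass
class Alignment:
    labels: list[str]
    rows: list[str]
    region: str = "ITS1"
    group: str = ""

    def __post_init__(self) -> None:
        if len(self.rows) < 2:
            raise ValueError("alignment needs at least 2 rows")
        lengths = {len(r) for r in self.rows}
        if len(lengths) != 1:
            raise ValueError(f"rows have unequal lengths: {sorted(lengths)}")
        self.rows = [r.upper() for r in self.rows]
        for label, row in zip(self.labels, self.rows):
            bad = set(row) - IUPAC_CHARS
            if bad:
                raise ValueError(f"row {label!r}: illegal characters {sorted(bad)}")

    @property
    def length(self) -> int:
        return len(self.rows[0])

    @property
    def n_rows(self) -> int:
        return len(self.rows)

    def column(self, j: int) -> str:
        """Column j (0-based internally)."""
        return "".join(row[j] for row in self.rows)

    @classmethod
    def from_records(cls, records: Sequence[SequenceRecord], group: str = "") -> "Alignment":
        regions = {r.region for r in records}
        if len(regions) != 1:
            raise ValueError("aligned records must share one region")
        return cls(
            labels=[r.id for r in records],
            rows=[r.residues for r in records],
            region=records[0].region,
            group=group or records[0].group,
        )


@dataclass
class AlignmentStats:
    n_individuals: int
    n_species: int
    alignment_length: int
    n_variable: int
    pct_variable: float
    n_pi: int
    pct_pi: float


@dataclass
class IndelCharacterMatrix:
    """Simple indel coding: one binary character per distinct gap span."""

    characters: list[tuple[int, int]]  # 1-based closed [start, end] columns
    states: list[list[Optional[int]]]  # rows x characters; None = missing
    labels: list[str]


def variable_and_pi_sites(alignment: Alignment, n_species: int | None = None) -> AlignmentStats:
    """Count variable and parsimony-informative columns.

    A column is variable when >= 2 distinct unambiguous base states occur;
    it is parsimony-informative when >= 2 states each occur in >= 2 rows.
    Gaps and ambiguity codes are ignored as states (standard parsimony
    counting convention).
    """
    n_var = n_pi = 0
    for j in range(alignment.length):
        col = alignment.column(j)
        counts: dict[str, int] = {}
        for ch in col:
            if ch in _STATE_CHARS:
                counts[ch] = counts.get(ch, 0) + 1
        if len(counts) >= 2:
            n_var += 1
            if sum(1 for c in counts.values() if c >= 2) >= 2:
                n_pi += 1
    length = alignment.length
    return AlignmentStats(
        n_individuals=alignment.n_rows,
        n_species=n_species if n_species is not None else alignment.n_rows,
        alignment_length=length,
        n_variable=n_var,
        pct_variable=100.0 * n_var / length,
        n_pi=n_pi,
        pct_pi=100.0 * n_pi / length,
    )


def remove_ambiguous_columns(
    alignment: Alignment, mask: Sequence[tuple[int, int]] | None = None
) -> tuple[Alignment, dict[int, int]]:
    """Delete columns containing IUPAC ambiguity codes plus user-masked ranges.

    ``mask`` ranges are 1-based closed intervals (the hook through which
    manually judged alignment-uncertain regions enter).  Returns the reduced
    alignment and a 1-based old->new column index map for the surviving
    columns.
    """
    masked = set()
    if mask:
        for start, end in mask:
            if start < 1 or end > alignment.length or start > end:
                raise ValueError(
                    f"mask range ({start}, {end}) out of bounds for length {alignment.length}"
                )
            masked.update(range(start - 1, end))
    keep = []
    for j in range(alignment.length):
        if j in masked:
            continue
        if any(ch in _AMBIGUITY for ch in alignment.column(j)):
            continue
        keep.append(j)
    col_map = {j + 1: new + 1 for new, j in enumerate(keep)}
    new_rows = ["".join(row[j] for j in keep) for row in alignment.rows]
    reduced = Alignment(
        labels=list(alignment.labels), rows=new_rows,
        region=alignment.region, group=alignment.group,
    )
    return reduced, col_map


def _gap_runs(row: str) -> list[tuple[int, int]]:
    """0-based closed gap runs in one row."""
    runs = []
    start = None
    for j, ch in enumerate(row + "X"):  # sentinel flushes trailing run
        if ch == "-":
            if start is None:
                start = j
        elif start is not None:
            runs.append((start, j - 1))
            start = None
    return runs


def code_gaps_binary(alignment: Alignment) -> IndelCharacterMatrix:
    """Simple indel coding of gap spans.

    Each distinct internal gap span (identical start and end across rows)
    becomes one binary character: 1 for rows showing exactly that span, 0
    for rows with no gap overlapping it, missing (None) for rows whose own
    gap overlaps the span without matching it exactly (including strict
    containment in a longer gap).  Terminal gap runs are treated as missing
    data, not indels, and are never coded.
    """
    L = alignment.length
    per_row_runs = []
    spans: list[tuple[int, int]] = []
    for row in alignment.rows:
        runs = _gap_runs(row)
        internal = [(s, e) for s, e in runs if s > 0 and e < L - 1]
        terminal = [(s, e) for s, e in runs if s == 0 or e == L - 1]
        per_row_runs.append((internal, terminal))
        for span in internal:
            if span not in spans:
                spans.append(span)
    spans.sort()

    states: list[list[Optional[int]]] = []
    for internal, terminal in per_row_runs:
        row_states: list[Optional[int]] = []
        for s, e in spans:
            if (s, e) in internal:
                row_states.append(1)
            elif any(rs <= e and re >= s for rs, re in internal + terminal):
                row_states.append(None)  # overlapping but different span
            else:
                row_states.append(0)
        states.append(row_states)
    return IndelCharacterMatrix(
        characters=[(s + 1, e + 1) for s, e in spans],
        states=states,
        labels=list(alignment.labels),
    )


def gc_content(records: Sequence[SequenceRecord]) -> tuple[list[float], float]:
    """Per-record GC fraction and its mean.

    GC = (G + C + S) / (bases with determinate GC contribution), where the
    denominator counts A, C, G, T, U plus the two-state codes S (G/C) and
    W (A/T).  N, other ambiguity codes and gaps are ignored.
    """
    if not records:
        raise ValueError("gc_content needs at least one record")
    values = []
    for rec in records:
        seq = rec.residues
        num = sum(seq.count(ch) for ch in "GCS")
        den = sum(seq.count(ch) for ch in "ACGTUSW")
        if den == 0:
            raise ValueError(f"record {rec.id!r}: no countable bases")
        values.append(num / den)
    return values, sum(values) / len(values)


def write_alignment_stats(rows: Sequence[tuple[str, str, AlignmentStats]], path: str | Path) -> None:
    """Write Table-1-style per (group, region) alignment statistics."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow([
            "group", "region", "n_individuals", "n_species", "alignment_length",
            "n_variable", "pct_variable", "n_pi", "pct_pi",
        ])
        for group, region, st in rows:
            w.writerow([
                group, region, st.n_individuals, st.n_species, st.alignment_length,
                st.n_variable, f"{st.pct_variable:.2f}", st.n_pi, f"{st.pct_pi:.2f}",
            ])


def write_indel_matrix(matrix: IndelCharacterMatrix, path: str | Path) -> None:
    """TSV with 0/1/? coding, one row per sequence."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["id"] + [f"indel_{s}_{e}" for s, e in matrix.characters])
        for label, row in zip(matrix.labels, matrix.states):
            w.writerow([label] + ["?" if v is None else str(v) for v in row])


def indel_matrix_as_nexus_block(matrix: IndelCharacterMatrix) -> str:
    """Render the indel characters as a NEXUS-style standard-data block."""
    n, k = len(matrix.labels), len(matrix.characters)
    lines = [
        "BEGIN CHARACTERS; [simple indel coding]",
        f"  DIMENSIONS NCHAR={k};",
        '  FORMAT DATATYPE=STANDARD SYMBOLS="01" MISSING=?;',
        "  MATRIX",
    ]
    for label, row in zip(matrix.labels, matrix.states):
        coded = "".join("?" if v is None else str(v) for v in row)
        lines.append(f"    {label} {coded}")
    lines += ["  ;", "END;"]
    return "\n".join(lines) + "\n"
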