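"""Reading, writing, labelling and filtering of ITS sequence sets.

FASTA headers follow the convention ``id|species|group|region``; any field
missing from the header can be supplied through a tab-separated metadata
sidecar (columns: id, species, group, region).  Inputs are expected to be
pre-delimited ITS1 / ITS2 spacers (5.8S already removed upstream).
"""
from __future__ import annotations

import csv
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from Bio import SeqIO

from .records import REGIONS, SequenceRecord, SequenceValidationError


class FastaParseError(ValueError):
    pass


def _check_fasta_shape(path: Path) -> None:
    """Cheap structural validation so errors name the offending line."""
    with open(path) as fh:
        saw_header = False
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            if line.startswith(">"):
                saw_header = True
                if len(line) == 1:
                    raise FastaParseError(f"{path}:{lineno}: empty FASTA header")
            elif not saw_header:
                raise FastaParseError(
                    f"{path}:{lineno}: sequence data before first '>' header"
                )
        if not saw_header:
            raise FastaParseError(f"{path}: no FASTA records found")


def read_metadata(path: str | Path) -> dict[str, dict[str, str]]:
    """Read a TSV sidecar (id, species, group, region) into a mapping."""
    out: dict[str, dict[str, str]] = {}
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        for row in reader:
            rid = row["id"].strip()
            out[rid] = {
                k: (row.get(k) or "").strip() for k in ("species", "group", "region")
            }
    return out


def read_fasta(
    path: str | Path,
    region: str | None = None,
    group_map: Mapping[str, tuple[str, str]] | Mapping[str, dict] | None = None,
) -> list[SequenceRecord]:
    """Read a FASTA file into validated :class:`SequenceRecord` objects.

    Parameters
    ----------
    path:
        FASTA file, wrapped or unwrapped.
    region:
        Default region for records whose header/sidecar carries none.
    group_map:
        Optional ``id -> (species, group)`` pairs or ``id -> {species, group,
        region}`` dicts (as returned by :func:`read_metadata`); overrides
        header tokens.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    _check_fasta_shape(path)

    records: list[SequenceRecord] = []
    for entry in SeqIO.parse(str(path), "fasta"):
        tokens = entry.description.split("|")
        rid = tokens[0].split()[0].strip()
        species = tokens[1].strip() if len(tokens) > 1 else ""
        group = tokens[2].strip() if len(tokens) > 2 else ""
        reg = tokens[3].strip() if len(tokens) > 3 else ""
        if group_map and rid in group_map:
            meta = group_map[rid]
            if isinstance(meta, dict):
                species = meta.get("species") or species
                group = meta.get("group") or group
                reg = meta.get("region") or reg
            else:
                species, group = meta
        reg = reg or (region or "")
        if reg not in REGIONS:
            raise SequenceValidationError(
                f"record {rid!r}: no region given (header, sidecar or argument)"
            )
        seq = str(entry.seq)
        if not seq:
            raise SequenceValidationError(f"record {rid!r}: empty sequence")
        records.append(
            SequenceRecord(id=rid, residues=seq, species=species, group=group, region=reg)
        )
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for rec in records:
            header = f"{rec.id}|{rec.species}|{rec.group}|{rec.region}"
            fh.write(f">{header}\n")
            for i in range(0, len(rec.residues), width):
                fh.write(rec.residues[i : i + width] + "\n")


def dedupe_identical(
    records: Sequence[SequenceRecord], collapse_tu: bool = False
) -> list[SequenceRecord]:
    """Keep one record per (species, exact ungapped sequence) pair.

    Identical sequences from *different* species are all kept: the unit of
    deduplication is the within-species haplotype.  First occurrence wins;
    input order is preserved.
    """
    regions = {r.region for r in records}
    if len(regions) > 1:
        raise ValueError(f"records span multiple regions: {sorted(regions)}")
    seen: set[tuple[str, str]] = set()
    kept = []
    for rec in records:
        seq = rec.ungapped()
        if collapse_tu:
            seq = seq.replace("U", "T")
        key = (rec.species, seq)
        if key in seen:
            continue
        seen.add(key)
        kept.append(rec)
    return kept


def filter_terminal_missing(
    records: Sequence[SequenceRecord], max_terminal: int = 10
) -> tuple[list[SequenceRecord], list[tuple[str, str]]]:
    """Drop records with long runs of missing data (N or '-') at either end.

    Returns ``(kept, removed)`` where ``removed`` holds ``(id, reason)``
    rows for the removal report.
    """
    if max_terminal < 0:
        raise ValueError("max_terminal must be >= 0")
    missing = {"N", "-"}
    kept, removed = [], []
    for rec in records:
        seq = rec.residues
        lead = len(seq) - len(seq.lstrip("".join(missing)))
        trail = len(seq) - len(seq.rstrip("".join(missing)))
        if lead > max_terminal or trail > max_terminal:
            removed.append(
                (rec.id, f"terminal missing run {max(lead, trail)} > {max_terminal}")
            )
        else:
            kept.append(rec)
    return kept, removed


def write_removal_report(removed: Sequence[tuple[str, str]], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["id", "reason"])
        writer.writerows(removed)
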