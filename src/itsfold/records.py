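"""Core sequence record type shared across the pipeline.

An ITS data set is a flat list of :class:`SequenceRecord` objects, each
carrying the spacer region it came from (ITS1 or ITS2) and free-text
species / taxonomic-group labels (subgenus, section, ... the pipeline does
not care which rank).
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace

#: IUPAC nucleotide one-letter codes, including ambiguity codes, plus the
#: alignment gap character.  U is accepted alongside T so both DNA-templated
#: and transcribed spacer sequences can be handled as read.
IUPAC_CHARS = set("ACGTU") | set("RYSWKMBDHVN") | {"-"}

UNAMBIGUOUS = set("ACGTU")

REGIONS = ("ITS1", "ITS2")


class SequenceValidationError(ValueError):
    """A record violates the sequence alphabet or metadata contract."""


@dataclass
class SequenceRecord:
    """One ITS1 or ITS2 sequence with its labels.

    ``residues`` are stored uppercase; gaps ('-') are legal only when the
    record lives in an aligned context.  ``ungapped()`` gives the raw
    sequence used for folding, deduplication and null matching.
    """

    id: str
    residues: str
    species: str = ""
    group: str = ""
    region: str = "ITS1"

    def __post_init__(self) -> None:
        self.residues = self.residues.upper()
        if not self.residues:
            raise SequenceValidationError(f"record {self.id!r}: empty sequence")
        bad = set(self.residues) - IUPAC_CHARS
        if bad:
            raise SequenceValidationError(
                f"record {self.id!r}: illegal characters {sorted(bad)}"
            )
        if self.region not in REGIONS:
            raise SequenceValidationError(
                f"record {self.id!r}: region must be one of {REGIONS}, got {self.region!r}"
            )
        if not self.ungapped():
            raise SequenceValidationError(f"record {self.id!r}: gap-only sequence")

    def ungapped(self) -> str:
        return self.residues.replace("-", "")

    def with_residues(self, residues: str) -> "SequenceRecord":
        return replace(self, residues=residues)

    def __len__(self) -> int:
        return len(self.residues)
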