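"""Length- and GC-matched random sequences: the no-selection null.

For every real spacer sequence one random partner is generated with exactly
the same (ungapped) length and a G+C count fixed to ``round(gc * length)``
— an exact-count composition rather than i.i.d. draws, so the "similar GC"
matching carries no uncontrolled tolerance.  Within the GC budget the G/C
(and A/T) split is as even as possible, any odd remainder assigned by the
seeded generator, and positions are a uniform random permutation.

A dinucleotide-preserving shuffle of the source (Altschul-Erikson style) is
available as a stricter alternative null, off by default.
"""
from __future__ import annotations

import csv
from dataclasses import replace
from pathlib import Path
from typing import Literal, Sequence

import numpy as np

from .alignment import gc_content
from .records import SequenceRecord

NullMode = Literal["composition", "iid", "dinucleotide"]


def derive_seed(master_seed: int, index: int) -> int:
    """Stable per-record seed (< 2**31) from the master seed and position."""
    ss = np.random.SeedSequence(entropy=[int(master_seed), int(index)])
    return int(ss.generate_state(1)[0] % (2**31))


def _composition_null(seq: str, rng: np.random.Generator) -> str:
    L = len(seq)
    gc, _ = gc_content([SequenceRecord(id="_", residues=seq)])
    n_gc = int(round(gc[0] * L))
    n_at = L - n_gc
    n_g = n_gc // 2 + (int(rng.integers(0, 2)) if n_gc % 2 else 0)
    n_a = n_at // 2 + (int(rng.integers(0, 2)) if n_at % 2 else 0)
    letters = ["G"] * n_g + ["C"] * (n_gc - n_g) + ["A"] * n_a + ["T"] * (n_at - n_a)
    arr = np.array(letters)
    rng.shuffle(arr)
    return "".join(arr)


def _iid_null(seq: str, rng: np.random.Generator) -> str:
    L = len(seq)
    gc, _ = gc_content([SequenceRecord(id="_", residues=seq)])
    p_gc = gc[0]
    probs = [(1 - p_gc) / 2, p_gc / 2, p_gc / 2, (1 - p_gc) / 2]
    return "".join(rng.choice(list("ACGT"), size=L, p=probs))


def dinucleotide_shuffle(seq: str, rng: np.random.Generator) -> str:
    """Shuffle preserving exact dinucleotide counts (random Eulerian walk)."""
    if len(seq) < 3:
        return seq
    edges: dict[str, list[str]] = {}
    for a, b in zip(seq, seq[1:]):
        edges.setdefault(a, []).append(b)
    last = seq[-1]
    # pick a random last edge into `last` from each vertex to keep the walk
    # completable (Altschul-Erikson: build a spanning tree toward the end
    # vertex, shuffle the remaining edges)
    for _ in range(100):  # retry loop: rejection-sample valid walks
        trial = {a: list(bs) for a, bs in edges.items()}
        for a in trial:
            rng.shuffle(trial[a])
        out = [seq[0]]
        node = seq[0]
        ok = True
        for _step in range(len(seq) - 1):
            if not trial.get(node):
                ok = False
                break
            node = trial[node].pop()
            out.append(node)
        if ok and node == last:
            return "".join(out)
    return seq  # degenerate composition; fall back to the source


def matched_random_sequence(
    record: SequenceRecord, seed: int, mode: NullMode = "composition"
) -> SequenceRecord:
    """One random sequence matched in length (exactly) and GC to ``record``."""
    rng = np.random.default_rng(seed)
    source = record.ungapped()
    if mode == "composition":
        seq = _composition_null(source, rng)
    elif mode == "iid":
        seq = _iid_null(source, rng)
    elif mode == "dinucleotide":
        seq = dinucleotide_shuffle(source, rng)
    else:
        raise ValueError(f"unknown null mode {mode!r}")
    return replace(record, id=record.id + ".null", residues=seq)


def generate_null_cohort(
    records: Sequence[SequenceRecord],
    master_seed: int,
    mode: NullMode = "composition",
) -> list[SequenceRecord]:
    """One matched random sequence per input record, reproducibly seeded."""
    return [
        matched_random_sequence(rec, derive_seed(master_seed, idx), mode=mode)
        for idx, rec in enumerate(records)
    ]


def write_provenance(
    records: Sequence[SequenceRecord],
    nulls: Sequence[SequenceRecord],
    master_seed: int,
    path: str | Path,
) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["source_id", "null_id", "length", "gc_source", "gc_null", "seed"])
        for idx, (rec, nul) in enumerate(zip(records, nulls)):
            (gs,), _ = gc_content([rec])
            (gn,), _ = gc_content([nul])
            w.writerow([
                rec.id, nul.id, len(nul.ungapped()),
                f"{gs:.4f}", f"{gn:.4f}", derive_seed(master_seed, idx),
            ])
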