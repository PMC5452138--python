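"""Single-sequence secondary-structure prediction.

Two predictors are exposed:

* :func:`nussinov_maxpairs` — base-pair maximisation (the classic Nussinov
  recursion).  Deliberately simple; it doubles as a small-instance oracle
  for the energy-based folder in the test suite.
* :func:`fold_mfe` / :func:`fold_suboptimal` — Zuker-style minimum free
  energy folding under the nearest-neighbor model in :mod:`itsfold.energy`,
  with enumeration of distinct suboptimal structures inside an energy
  window (mfold-style: candidate pairs are ranked by the exact energy of
  the best structure in which they appear as an exterior-loop branch).

:func:`evaluate_energy` re-derives the energy of any structure by loop
decomposition, independently of the dynamic programming, and is the
internal consistency oracle.

T is transcribed to U before folding: spacers act at the rRNA-precursor
(RNA) level even though the inputs are DNA-templated sequences.
"""
from __future__ import annotations

import math
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from . import _dp
from .energy import (
    BASES,
    INF,
    PAIR_INDEX,
    PAIRS,
    SCALE,
    EnergyModel,
    default_model,
    encode_sequence,
)


class StructureError(ValueError):
    """A structure is inconsistent with its sequence or with itself."""


# ---------------------------------------------------------------------------
# structure containers


def pairs_to_dotbracket(length: int, pairs: Sequence[tuple[int, int]]) -> str:
    chars = ["."] * length
    for i, j in pairs:
        if not (1 <= i < j <= length):
            raise StructureError(f"pair ({i}, {j}) out of range for length {length}")
        if chars[i - 1] != "." or chars[j - 1] != ".":
            raise StructureError(f"position reused by pair ({i}, {j})")
        chars[i - 1] = "("
        chars[j - 1] = ")"
    db = "".join(chars)
    # crossing check via stack balance
    stack = []
    partner = {i: j for i, j in pairs}
    opens = {i for i, _ in pairs}
    closes = {j: i for i, j in pairs}
    for pos in range(1, length + 1):
        if pos in opens:
            stack.append(pos)
        elif pos in closes:
            if not stack or stack[-1] != closes[pos]:
                raise StructureError("pairs are crossing (pseudoknot)")
            stack.pop()
    return db


def dotbracket_to_pairs(dotbracket: str) -> list[tuple[int, int]]:
    stack = []
    pairs = []
    for pos, ch in enumerate(dotbracket, start=1):
        if ch == "(":
            stack.append(pos)
        elif ch == ")":
            if not stack:
                raise StructureError(f"unbalanced ')' at position {pos}")
            pairs.append((stack.pop(), pos))
        elif ch != ".":
            raise StructureError(f"illegal character {ch!r} in dot-bracket")
    if stack:
        raise StructureError(f"unbalanced '(' at position {stack[-1]}")
    return sorted(pairs)


@dataclass
class SecondaryStructure:
    """One folding of one sequence: dot-bracket, pair list (1-based), energy."""

    dotbracket: str
    pairs: list[tuple[int, int]]
    energy: Optional[float] = None

    def __post_init__(self) -> None:
        self.pairs = sorted(tuple(p) for p in self.pairs)
        if pairs_to_dotbracket(len(self.dotbracket), self.pairs) != self.dotbracket:
            raise StructureError("dot-bracket and pair list disagree")

    @classmethod
    def from_pairs(
        cls, length: int, pairs: Sequence[tuple[int, int]], energy: Optional[float] = None
    ) -> "SecondaryStructure":
        pairs = sorted(tuple(p) for p in pairs)
        return cls(pairs_to_dotbracket(length, pairs), pairs, energy)

    @classmethod
    def from_dotbracket(cls, dotbracket: str, energy: Optional[float] = None) -> "SecondaryStructure":
        return cls(dotbracket, dotbracket_to_pairs(dotbracket), energy)

    @property
    def length(self) -> int:
        return len(self.dotbracket)

    @property
    def n_pairs(self) -> int:
        return len(self.pairs)

    def pair_set(self) -> frozenset:
        return frozenset(self.pairs)


@dataclass
class FoldResult:
    """Ordered suboptimal-structure set for one sequence."""

    structures: list[SecondaryStructure]
    les: float
    n_structures: int

    def optimal(self) -> SecondaryStructure:
        return self.structures[0]


# ---------------------------------------------------------------------------
# Nussinov base-pair maximisation


def nussinov_maxpairs(sequence: str, min_loop: int = 3) -> tuple[int, SecondaryStructure]:
    """Maximum number of non-crossing allowed pairs with a loop constraint.

    Tie-break among co-optimal tracebacks: pair the outermost candidate
    (smallest i, then largest j).
    """
    codes = encode_sequence(sequence)
    n = len(codes)
    N = [[0] * n for _ in range(n)]
    for span in range(min_loop + 1, n):
        for i in range(n - span):
            j = i + span
            best = N[i + 1][j]
            for k in range(i + min_loop + 1, j + 1):
                if PAIR_INDEX[codes[i], codes[k]] >= 0:
                    inner = N[i + 1][k - 1] if k - i > 1 else 0
                    outer = N[k + 1][j] if k < j else 0
                    cand = 1 + inner + outer
                    if cand > best:
                        best = cand
            N[i][j] = best

    pairs: list[tuple[int, int]] = []
    stack = [(0, n - 1)]
    while stack:
        i, j = stack.pop()
        if j - i <= min_loop:
            continue
        target = N[i][j]
        if target == 0:
            continue
        hit = -1
        for k in range(j, i + min_loop, -1):  # largest j first
            if PAIR_INDEX[codes[i], codes[k]] >= 0:
                inner = N[i + 1][k - 1] if k - i > 1 else 0
                outer = N[k + 1][j] if k < j else 0
                if 1 + inner + outer == target:
                    hit = k
                    break
        if hit >= 0:
            pairs.append((i + 1, hit + 1))
            if hit - i > 1:
                stack.append((i + 1, hit - 1))
            if hit < j:
                stack.append((hit + 1, j))
        else:
            stack.append((i + 1, j))
    structure = SecondaryStructure.from_pairs(n, pairs)
    return len(pairs), structure


# ---------------------------------------------------------------------------
# energy evaluation by loop decomposition (independent of the DP)


def evaluate_energy(
    sequence: str, structure: SecondaryStructure, model: EnergyModel | None = None
) -> float:
    """Free energy of ``structure`` on ``sequence`` by loop decomposition.

    Decomposes into hairpin, stacked-pair, bulge/internal, multibranch and
    exterior loops and sums the model terms.  Shares only the parameter
    tables with the folding recursions, never the code path.
    """
    model = model or default_model()
    codes = encode_sequence(sequence)
    n = len(codes)
    if structure.length != n:
        raise StructureError(
            f"structure length {structure.length} != sequence length {n}"
        )
    partner = [-1] * n
    for i, j in structure.pairs:
        i0, j0 = i - 1, j - 1
        if partner[i0] != -1 or partner[j0] != -1:
            raise StructureError("a position participates in two pairs")
        p = PAIR_INDEX[codes[i0], codes[j0]]
        if p < 0:
            raise StructureError(
                f"pair ({i}, {j}) = {sequence[i0]}{sequence[j0]} is not allowed"
            )
        if j0 - i0 - 1 < model.min_hairpin_loop:
            raise StructureError(f"pair ({i}, {j}) closes a loop below the minimum size")
        partner[i0] = j0
        partner[j0] = i0

    def children_of(lo: int, hi: int) -> tuple[list[tuple[int, int]], int]:
        kids, unpaired, k = [], 0, lo
        while k <= hi:
            if partner[k] > k:
                kids.append((k, partner[k]))
                k = partner[k] + 1
            elif partner[k] == -1:
                unpaired += 1
                k += 1
            else:
                raise StructureError("pairs are crossing (pseudoknot)")
            # partner[k] < k inside this window means crossing
        return kids, unpaired

    total = 0  # centi-kcal/mol
    work, _ = children_of(0, n - 1)  # exterior loop: no penalty terms
    stack = list(work)
    while stack:
        i, j = stack.pop()
        kids, unpaired = children_of(i + 1, j - 1)
        p = PAIR_INDEX[codes[i], codes[j]]
        if not kids:
            total += int(model.hairpin[j - i - 1])
        elif len(kids) == 1:
            k, l = kids[0]
            n1, n2 = k - i - 1, j - l - 1
            if n1 == 0 and n2 == 0:
                total += int(model.stack[p, PAIR_INDEX[codes[k], codes[l]]])
            elif n1 == 0 or n2 == 0:
                total += int(model.bulge[n1 + n2])
            else:
                total += int(model.internal[n1 + n2])
        else:
            total += model.ml_a + model.ml_b * len(kids) + model.ml_c * unpaired
        stack.extend(kids)
    return total / SCALE


# ---------------------------------------------------------------------------
# MFE folding and suboptimal enumeration


def _run_fill(codes: np.ndarray, model: EnergyModel):
    return _dp.fill_matrices(
        codes, PAIR_INDEX, model.stack, model.hairpin, model.bulge, model.internal,
        model.ml_a, model.ml_b, model.ml_c, model.min_hairpin_loop,
        model.max_internal_loop,
    )


def _kernel_args(codes: np.ndarray, model: EnergyModel):
    return (
        codes, PAIR_INDEX, model.stack, model.hairpin, model.bulge, model.internal,
        model.ml_a, model.ml_b, model.ml_c, model.min_hairpin_loop,
        model.max_internal_loop,
    )


def fold_mfe(sequence: str, model: EnergyModel | None = None) -> SecondaryStructure:
    """Minimum-free-energy structure; an open chain has energy 0.0."""
    model = model or default_model()
    codes = encode_sequence(sequence)
    n = len(codes)
    if n > model.max_loop_size:
        raise ValueError(f"sequence longer than model.max_loop_size={model.max_loop_size}")
    V, WM, E, F = _run_fill(codes, model)
    out_i = np.empty(n // 2 + 1, dtype=np.int64)
    out_j = np.empty(n // 2 + 1, dtype=np.int64)
    cnt = _dp.trace_suffix(0, *_kernel_args(codes, model), V, WM, F, out_i, out_j, 0)
    pairs = [(int(out_i[k]) + 1, int(out_j[k]) + 1) for k in range(cnt)]
    return SecondaryStructure.from_pairs(n, pairs, energy=int(F[0]) / SCALE)


def fold_suboptimal(
    sequence: str,
    model: EnergyModel | None = None,
    percent_window: float = 10.0,
    max_structures: int = 20,
    min_pair_distance_between_structures: int = 3,
    max_candidates: int = 1000,
) -> FoldResult:
    """Distinct low-energy structures within a window of the MFE.

    Candidate base pairs (i, j) are ranked by ``E[<i] + V(i,j) + F[>j]`` —
    the exact energy of the best structure in which (i, j) is a branch of
    the exterior loop — and traced back in that order.  A candidate
    structure is kept when its energy lies within ``percent_window`` % of
    the lowest energy state and it differs from every kept structure by at
    least ``min_pair_distance_between_structures`` base pairs (symmetric
    difference of pair sets).  Enumeration stops at ``max_structures`` or
    after ``max_candidates`` candidates.
    """
    if percent_window <= 0:
        raise ValueError("percent_window must be > 0")
    if max_structures < 1:
        raise ValueError("max_structures must be >= 1")
    model = model or default_model()
    codes = encode_sequence(sequence)
    n = len(codes)
    V, WM, E, F = _run_fill(codes, model)
    mfe_int = int(F[0])

    out_i = np.empty(n // 2 + 1, dtype=np.int64)
    out_j = np.empty(n // 2 + 1, dtype=np.int64)
    args = _kernel_args(codes, model)
    cnt = _dp.trace_suffix(0, *args, V, WM, F, out_i, out_j, 0)
    mfe_pairs = [(int(out_i[k]) + 1, int(out_j[k]) + 1) for k in range(cnt)]
    mfe = SecondaryStructure.from_pairs(n, mfe_pairs, energy=mfe_int / SCALE)

    structures = [mfe]
    kept_sets = [mfe.pair_set()]
    seen = {mfe.pair_set()}
    thr = mfe_int * (100.0 - percent_window) / 100.0 + 1e-9

    if n >= 2 and len(structures) < max_structures:
        bound = E[:n].reshape(-1, 1) + V + F[1 : n + 1].reshape(1, -1)
        ii, jj = np.nonzero((V < INF) & (bound <= thr))
        if ii.size:
            b = bound[ii, jj]
            order = np.lexsort((-jj, ii, b))[:max_candidates]
            for idx in order:
                i, j = int(ii[idx]), int(jj[idx])
                nout = _dp.trace_prefix(i, *args, V, WM, E, out_i, out_j, 0)
                nout = _dp.trace_v(i, j, *args, V, WM, out_i, out_j, nout)
                nout = _dp.trace_suffix(j + 1, *args, V, WM, F, out_i, out_j, nout)
                pset = frozenset(
                    (int(out_i[k]) + 1, int(out_j[k]) + 1) for k in range(nout)
                )
                if pset in seen:
                    continue
                seen.add(pset)
                d = min_pair_distance_between_structures
                if any(len(pset ^ ks) < d for ks in kept_sets):
                    continue
                structures.append(
                    SecondaryStructure.from_pairs(
                        n, sorted(pset), energy=int(b[idx]) / SCALE
                    )
                )
                kept_sets.append(pset)
                if len(structures) >= max_structures:
                    break
    return FoldResult(structures=structures, les=mfe.energy, n_structures=len(structures))


# ---------------------------------------------------------------------------
# CT / dot-bracket file round-trips


def write_ct(sequence: str, structure: SecondaryStructure, path: str | Path, title: str = "") -> None:
    """Write a 6-column connect (CT) file, 1-based."""
    n = len(sequence)
    partner = [0] * (n + 1)
    for i, j in structure.pairs:
        partner[i], partner[j] = j, i
    header = f"{n}"
    if structure.energy is not None:
        header += f"  ENERGY = {structure.energy:.2f}"
    if title:
        header += f"  {title}"
    with open(path, "w") as fh:
        fh.write(header + "\n")
        for i in range(1, n + 1):
            fh.write(
                f"{i}\t{sequence[i - 1]}\t{i - 1}\t{(i + 1) % (n + 1)}\t{partner[i]}\t{i}\n"
            )


def read_ct(path: str | Path) -> tuple[str, SecondaryStructure]:
    lines = Path(path).read_text().splitlines()
    header = lines[0]
    m = re.search(r"ENERGY\s*=\s*(-?\d+(?:\.\d+)?)", header)
    energy = float(m.group(1)) if m else None
    n = int(header.split()[0])
    seq_chars, pairs = [], []
    for line in lines[1 : n + 1]:
        parts = line.split()
        i, base, partner = int(parts[0]), parts[1], int(parts[4])
        seq_chars.append(base)
        if partner > i:
            pairs.append((i, partner))
    sequence = "".join(seq_chars)
    return sequence, SecondaryStructure.from_pairs(n, pairs, energy=energy)


def write_dotbracket(
    sequence: str, structure: SecondaryStructure, path: str | Path, name: str = "structure"
) -> None:
    with open(path, "w") as fh:
        fh.write(f">{name}\n{sequence}\n{structure.dotbracket}")
        if structure.energy is not None:
            fh.write(f" ({structure.energy:.2f})")
        fh.write("\n")
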