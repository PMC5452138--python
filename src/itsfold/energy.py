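"""Nearest-neighbor free-energy model for single-sequence RNA folding.

The model is deliberately simple: Turner-style stacking free energies for
the six canonical pairs (Watson-Crick plus GU wobble), tabulated hairpin /
bulge / internal loop initiation penalties with logarithmic extrapolation
past the tabulated sizes, and an affine multibranch-loop term.  Dangling
ends, terminal mismatches and special small-loop tables are intentionally
omitted; the package's claims are about internal consistency and rank-level
comparisons, never about reproducing any particular program's energies.

All energies are kcal/mol at 37 C.  Internally they are carried as integer
centi-kcal/mol so dynamic-programming ties and cross-checks are exact.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np

#: canonical pair order used by all tables
PAIRS = ("AU", "CG", "GC", "GU", "UA", "UG")
BASES = "ACGU"
BASE_INDEX = {b: i for i, b in enumerate(BASES)}
BASE_INDEX["T"] = BASE_INDEX["U"]

#: scale factor from kcal/mol to the integer unit used in the DP
SCALE = 100

INF = np.int64(2**40)


def _pair_index_table() -> np.ndarray:
    tab = -np.ones((4, 4), dtype=np.int8)
    for k, pair in enumerate(PAIRS):
        i, j = BASE_INDEX[pair[0]], BASE_INDEX[pair[1]]
        tab[i, j] = k
    return tab

PAIR_INDEX = _pair_index_table()


@dataclass
class EnergyModel:
    """Parameter tables ready for the folding engine.

    Loop arrays are indexed by loop size (number of unpaired bases) and are
    pre-extended to ``max_loop_size`` using the logarithmic rule
    ``E(n) = E(n_ref) + coef * ln(n / n_ref)``.
    """

    stack: np.ndarray            # (6, 6) int64 centi-kcal
    hairpin: np.ndarray          # (max_loop_size+1,) int64; INF below min size
    bulge: np.ndarray
    internal: np.ndarray
    ml_a: int                    # multiloop closing penalty (centi-kcal)
    ml_b: int                    # per-branch
    ml_c: int                    # per-unpaired base
    min_hairpin_loop: int = 3
    max_internal_loop: int = 30
    coef: float = 1.079
    max_loop_size: int = 1024
    source: str = ""

    def loop_arrays(self):
        return self.hairpin, self.bulge, self.internal


def _extend(table: dict[int, float], max_size: int, coef: float) -> np.ndarray:
    arr = np.full(max_size + 1, INF, dtype=np.int64)
    ref = max(table)
    for n in range(min(table), max_size + 1):
        if n in table:
            val = table[n]
        else:
            val = table[ref] + coef * math.log(n / ref)
        arr[n] = round(val * SCALE)
    return arr


def _parse_sections(text: str) -> dict[str, list[str]]:
    sections: dict[str, list[str]] = {}
    current = None
    for raw in text.splitlines():
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if line.startswith("[") and line.endswith("]"):
            current = line[1:-1]
            sections[current] = []
        elif current is not None:
            sections[current].append(line)
    return sections


def load_energy_model(path: str | Path | None = None, max_loop_size: int = 1024) -> EnergyModel:
    """Load a parameter file; ``None`` loads the packaged default set."""
    if path is None:
        text = resources.files("itsfold.data").joinpath("nn_params.txt").read_text()
        source = "itsfold.data/nn_params.txt"
    else:
        text = Path(path).read_text()
        source = str(path)
    sec = _parse_sections(text)

    order = tuple(sec["pairs"][0].split())
    if order != PAIRS:
        raise ValueError(f"parameter file pair order must be {PAIRS}, got {order}")

    stack = np.full((6, 6), INF, dtype=np.int64)
    n_rows = 0
    for ln in sec["stack"]:
        parts = ln.split()
        if parts[0] not in PAIRS or len(parts) != 7:
            continue  # column-header line
        try:
            vals = [float(v) for v in parts[1:]]
        except ValueError:
            continue
        stack[PAIRS.index(parts[0])] = np.round(np.array(vals) * SCALE).astype(np.int64)
        n_rows += 1
    if n_rows != 6:
        raise ValueError("stack table must have 6 numeric rows")

    extra = dict(ln.split() for ln in sec.get("extrapolation", []))
    coef = float(extra.get("coef", 1.079))

    def table(name):
        return {int(p[0]): float(p[1]) for p in (ln.split() for ln in sec[name])}

    ml = dict(ln.split() for ln in sec["multiloop"])
    rules = dict(ln.split() for ln in sec.get("rules", []))

    return EnergyModel(
        stack=stack,
        hairpin=_extend(table("hairpin"), max_loop_size, coef),
        bulge=_extend(table("bulge"), max_loop_size, coef),
        internal=_extend(table("internal"), max_loop_size, coef),
        ml_a=round(float(ml["a"]) * SCALE),
        ml_b=round(float(ml["b"]) * SCALE),
        ml_c=round(float(ml["c"]) * SCALE),
        min_hairpin_loop=int(rules.get("min_hairpin_loop", 3)),
        max_internal_loop=int(rules.get("max_internal_loop", 30)),
        coef=coef,
        max_loop_size=max_loop_size,
        source=source,
    )


_DEFAULT_MODEL: EnergyModel | None = None


def default_model() -> EnergyModel:
    global _DEFAULT_MODEL
    if _DEFAULT_MODEL is None:
        _DEFAULT_MODEL = load_energy_model(None)
    return _DEFAULT_MODEL


def encode_sequence(sequence: str) -> np.ndarray:
    """Map a DNA/RNA string to integer codes (T is transcribed to U)."""
    codes = np.empty(len(sequence), dtype=np.int8)
    for i, ch in enumerate(sequence.upper()):
        idx = BASE_INDEX.get(ch)
        if idx is None:
            raise ValueError(
                f"position {i + 1}: {ch!r} is not one of A/C/G/T/U "
                "(resolve ambiguity codes before folding)"
            )
        codes[i] = idx
    return codes
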