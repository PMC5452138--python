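"""Synthetic ITS-like sequence families with controllable structural constraint.

The generator plants the features that make real ITS1/ITS2 spacers fold the
way they do: a fixed number of GC-rich reverse-complementary stem blocks
(each folding into one hairpin), the conserved central ``AAGGAA`` motif and
the complementary ``TCGAA``/``TTCGA`` terminal stem for ITS1-like families,
and AT-biased filler elsewhere so the designed stems dominate the energy
landscape (guanine is kept out of filler: without G the filler can only
form weak A:U pairs, mirroring how real spacer loops are less structured
than the conserved helices).

Evolution is a star phylogeny: every tip draws Poisson(divergence x length)
substitutions from the ancestor.  A substitution landing in a planted stem
co-mutates the partner base to restore an allowed pair (GU wobble included)
with probability ``compensatory_fraction`` — the compensatory-substitution
mechanism by which secondary structure is conserved under sequence
divergence.  Setting that fraction to 0 removes the constraint entirely;
the family then drifts toward unstructured sequence.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .fold import SecondaryStructure, evaluate_energy
from .records import SequenceRecord

#: pairing partners that restore an allowed pair (DNA letters, RNA rules
#: after T -> U: A:T/U, G:C, G:T/U wobble, ...)
_RESTORING = {"A": "T", "C": "G", "G": "CT", "T": "AG"}
_COMPLEMENT = {"A": "T", "T": "A", "G": "C", "C": "G"}

#: default geometry per region, chosen to match typical spacer families:
#: ITS1-like ~263 bp folding into 7 hairpins, ITS2-like ~206 bp into 3.
_REGION_DEFAULTS = {
    "ITS1": dict(length=263, n_stems=7),
    "ITS2": dict(length=206, n_stems=3),
}

CENTRAL_MOTIF = "AAGGAA"
TERMINAL_5 = "TCGAA"
TERMINAL_3 = "TTCGA"


@dataclass
class SynthConfig:
    region: str = "ITS1"
    n_groups: int = 4
    n_species_per_group: int | Sequence[int] = 3
    length: Optional[int] = None
    gc_target: float = 0.55
    n_stems: Optional[int] = None
    stem_length: int = 6
    #: helix pairs added around each conserved stem core, taken from the
    #: filler budget: real spacer helices extend well beyond their conserved
    #: 5-6 bp cores, and the planted fold must dominate typical background
    #: pairing for the family to model a structurally constrained spacer
    stem_flank: int = 3
    loop_length: int = 4
    divergence: float = 0.15
    compensatory_fraction: float = 0.9
    group_divergence: float = 0.0  # extra star level between groups (0 = flat)
    mutable_motifs: bool = False
    use_motifs: Optional[bool] = None  # default: True for ITS1-like only
    seed: int = 0

    def resolved(self) -> "SynthConfig":
        d = _REGION_DEFAULTS[self.region]
        cfg = SynthConfig(**{**self.__dict__})
        if cfg.length is None:
            cfg.length = d["length"]
        if cfg.n_stems is None:
            cfg.n_stems = d["n_stems"]
        if cfg.use_motifs is None:
            cfg.use_motifs = self.region == "ITS1"
        if not 0 <= cfg.compensatory_fraction <= 1:
            raise ValueError("compensatory_fraction must be in [0, 1]")
        if cfg.divergence < 0:
            raise ValueError("divergence must be >= 0")
        return cfg

    def species_counts(self) -> list[int]:
        if isinstance(self.n_species_per_group, int):
            return [self.n_species_per_group] * self.n_groups
        counts = list(self.n_species_per_group)
        if len(counts) != self.n_groups:
            raise ValueError("n_species_per_group list must have n_groups entries")
        return counts


def _stem_pair_types(rng: np.random.Generator, length: int) -> list[tuple[str, str]]:
    """GC-rich stem pairs: real spacer helices are strongly GC-biased."""
    choices = [("G", "C"), ("C", "G"), ("A", "T"), ("T", "A")]
    probs = [0.45, 0.45, 0.05, 0.05]
    idx = rng.choice(len(choices), size=length, p=probs)
    return [choices[k] for k in idx]


def build_ancestor(config: SynthConfig) -> tuple[SequenceRecord, SecondaryStructure]:
    """Construct the family ancestor and its planted structure.

    The ancestor folds (by design) into ``n_stems`` hairpins; for
    ITS1-like families the whole molecule is additionally closed by the
    5-bp terminal motif stem, and ``AAGGAA`` sits in the central spacer.
    """
    cfg = config.resolved()
    rng = np.random.default_rng(cfg.seed)
    L, S, loop = cfg.length, cfg.n_stems, cfg.loop_length
    K = cfg.stem_length + cfg.stem_flank  # full helix = conserved core + flanks

    term5 = TERMINAL_5 if cfg.use_motifs else ""
    term3 = TERMINAL_3 if cfg.use_motifs else ""
    central = CENTRAL_MOTIF if cfg.use_motifs else ""
    budget = S * (2 * K + loop) + len(term5) + len(term3) + len(central)
    n_spacers = S + 1
    filler_total = L - budget
    if filler_total < n_spacers:  # at least 1 nt between stems
        raise ValueError(
            f"length budget infeasible: {budget} structural nt + {n_spacers} "
            f"spacers > length {L}"
        )

    base_len, rem = divmod(filler_total, n_spacers)
    spacer_lens = [base_len + (1 if k < rem else 0) for k in range(n_spacers)]

    # --- assemble segments, tracking planted pairs and mutability ---------
    seq: list[str] = []
    planted: list[tuple[int, int]] = []
    motif_pos: set[int] = set()       # 0-based immutable positions
    stem_partner: dict[int, int] = {}  # 0-based position -> partner

    def append(text: str, immutable: bool = False) -> int:
        start = len(seq)
        seq.extend(text)
        if immutable:
            motif_pos.update(range(start, start + len(text)))
        return start

    append(term5, immutable=True)
    spacer_segments: list[tuple[int, int]] = []  # (start, length) for filler fill-in
    central_spacer = min(n_spacers // 2, S - 1)
    for s in range(S):
        start = len(seq)
        spacer_segments.append((start, spacer_lens[s]))
        seq.extend("?" * spacer_lens[s])
        if s == central_spacer and central:
            append(central, immutable=True)
        pair_types = _stem_pair_types(rng, K)
        loop_start = append("".join(p[0] for p in pair_types))
        # loops avoid T: a loop U would offer G:U wobble fuel to rearranged folds
        append("".join(rng.choice(list("AC"), size=loop)))
        append("".join(p[1] for p in reversed(pair_types)))
        for k in range(K):
            i = loop_start + k
            j = loop_start + 2 * K + loop - 1 - k
            planted.append((i + 1, j + 1))
            stem_partner[i] = j
            stem_partner[j] = i
    start = len(seq)
    spacer_segments.append((start, spacer_lens[S]))
    seq.extend("?" * spacer_lens[S])
    append(term3, immutable=True)
    assert len(seq) == L

    if cfg.use_motifs:
        for k in range(len(term5)):
            i, j = k, L - 1 - k
            planted.append((i + 1, j + 1))
            stem_partner[i] = j
            stem_partner[j] = i

    # --- fill spacers to hit the GC target (C only: no G in filler) -------
    gc_so_far = sum(1 for ch in seq if ch in "GC")
    gc_needed = int(round(cfg.gc_target * L)) - gc_so_far
    filler_positions = [
        p for start, ln in spacer_segments for p in range(start, start + ln)
    ]
    gc_needed = max(0, min(gc_needed, len(filler_positions)))
    c_positions = set(
        rng.choice(filler_positions, size=gc_needed, replace=False).tolist()
    ) if gc_needed else set()
    # Filler composition is balanced (G/C and A/T split evenly), matching
    # the statistics of the composition-matched null generator, so that a
    # family whose structure has fully drifted is indistinguishable from
    # its null cohort.
    gc_list = list(c_positions)
    rng.shuffle(gc_list)
    g_positions = set(gc_list[: len(gc_list) // 2])
    at_positions = [p for p in filler_positions if p not in c_positions]
    rng.shuffle(at_positions)
    a_positions = set(at_positions[: len(at_positions) // 2])
    for p in filler_positions:
        if p in c_positions:
            seq[p] = "G" if p in g_positions else "C"
        else:
            seq[p] = "A" if p in a_positions else "T"

    residues = "".join(seq)
    record = SequenceRecord(
        id=f"{cfg.region}_anc", residues=residues, species="ancestor",
        group="ancestor", region=cfg.region,
    )
    structure = SecondaryStructure.from_pairs(L, sorted(planted))
    structure.energy = evaluate_energy(residues, structure)
    record.__dict__["_planted_partner"] = stem_partner  # used by evolve_family
    record.__dict__["_motif_positions"] = motif_pos
    return record, structure


def _mutate(
    residues: list[str],
    rng: np.random.Generator,
    n_sub: int,
    mutable: np.ndarray,
    stem_partner: dict[int, int],
    c_fraction: float,
) -> None:
    swap = {"G": "C", "C": "G", "A": "T", "T": "A"}
    sites = rng.choice(mutable, size=n_sub, replace=True) if n_sub else []
    for site in sites:
        site = int(site)
        old = residues[site]
        if site in stem_partner and rng.random() < c_fraction:
            # Structure-preserving substitution: class-conserving swap
            # (G<->C, A<->T) with the partner co-substituted to its
            # Watson-Crick complement.  Keeps conserved helices at full
            # thermodynamic strength, as observed in real rRNA stems;
            # class-changing stem mutations fall in the free fraction.
            new = swap[old]
            residues[site] = new
            residues[stem_partner[site]] = _COMPLEMENT[new]
        else:
            residues[site] = rng.choice([b for b in "ACGT" if b != old])


def evolve_family(
    ancestor: SequenceRecord,
    planted: SecondaryStructure,
    config: SynthConfig,
) -> list[SequenceRecord]:
    """Star-phylogeny descendants of ``ancestor`` across the configured groups."""
    cfg = config.resolved()
    rng = np.random.default_rng(cfg.seed + 1)
    L = len(ancestor.residues)
    stem_partner = ancestor.__dict__.get("_planted_partner")
    if stem_partner is None:
        stem_partner = {}
        for i, j in planted.pairs:
            stem_partner[i - 1] = j - 1
            stem_partner[j - 1] = i - 1
    motif_pos = ancestor.__dict__.get("_motif_positions", set())
    if cfg.mutable_motifs:
        motif_pos = set()
    mutable = np.array([p for p in range(L) if p not in motif_pos], dtype=np.int64)

    tips = []
    for g, n_sp in enumerate(cfg.species_counts()):
        group = f"group{g + 1}"
        group_res = list(ancestor.residues)
        if cfg.group_divergence > 0:
            _mutate(group_res, rng, int(rng.poisson(cfg.group_divergence * L)),
                    mutable, stem_partner, cfg.compensatory_fraction)
        for s in range(n_sp):
            res = list(group_res)
            _mutate(res, rng, int(rng.poisson(cfg.divergence * L)),
                    mutable, stem_partner, cfg.compensatory_fraction)
            tips.append(SequenceRecord(
                id=f"{cfg.region}_g{g + 1}s{s + 1}",
                residues="".join(res),
                species=f"species_g{g + 1}s{s + 1}",
                group=group,
                region=cfg.region,
            ))
    return tips


def make_family(config: SynthConfig) -> tuple[list[SequenceRecord], SecondaryStructure]:
    """Convenience: ancestor + tips in one call (tips only are returned)."""
    ancestor, planted = build_ancestor(config)
    return evolve_family(ancestor, planted, config), planted
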