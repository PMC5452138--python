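# Methods

## Folding model

Single sequences are folded as RNA (T is transcribed to U on input; the
spacers act at the rRNA-precursor level even though the deposited
sequences are DNA-templated). The free-energy model is a deliberately
simplified nearest-neighbor set, shipped as a plain-text parameter file
(`itsfold/data/nn_params.txt`, sections `[stack]`, `[hairpin]`,
`[bulge]`, `[internal]`, `[multiloop]`):

* **Stacking**: Turner-style 37 °C free energies for all ordered pairs of
  the six canonical pairs (Watson–Crick plus G:U wobble), satisfying the
  nearest-neighbor symmetry ΔG(5'WX/ZY) = ΔG(5'YZ/XW).
* **Loops**: hairpin, bulge and internal-loop initiation penalties
  tabulated for sizes up to 30 nt and extrapolated beyond with
  E(n) = E(30) + 1.079·ln(n/30) kcal/mol (1.75·R·T at 310.15 K).
  The minimum hairpin loop is 3 nt; internal/bulge loops are capped at 30
  unpaired nucleotides inside the dynamic program.
* **Multibranch loops**: affine, a + b·(branches) + c·(unpaired) with
  a = 3.4, b = 0.4, c = 0.0 kcal/mol. c = 0 follows the newer Turner
  convention and keeps long unpaired stretches inside a closing stem from
  being absurdly penalised.
* **Omitted on purpose**: dangling ends, terminal mismatches, terminal-AU
  penalties, special small-loop tables, loop-asymmetry terms, coaxial
  stacking, pseudoknots. Numeric agreement with any particular folding
  program is a non-goal; the package's claims rest on internal
  consistency (see below) and on rank-level comparisons, which are robust
  to the exact parameter values (Spearman ρ ≈ 0.9 against RNAfold on
  random sequences, cross-checked in the test suite).

Energies are carried internally as integer centi-kcal/mol. That makes
co-optimality ties, traceback decisions, and the consistency contract
*exact* rather than float-tolerant.

The recursions are the standard Zuker scheme — V(i,j) for pair-closed
segments with hairpin / stack / bulge-internal / multibranch cases, a WM
array for multiloop segments (the two-WM split enforces ≥ 2 branches),
and exterior prefix/suffix arrays. An open chain has energy 0.0, so the
reported LES is never positive. Kernels are numba-compiled; a 280-nt
sequence folds in ~50 ms.

**Tie-breaking** among co-optimal structures is deterministic: at the
exterior level the outermost pairing wins (smallest i, then largest j);
inside V the cases are tried in a fixed order (hairpin, then
stack/internal in scan order, then multibranch split). Byte-identical
reruns are guaranteed; no claim is made that the chosen co-optimal
structure is canonical in any other sense.

**Internal consistency oracle.** `evaluate_energy` re-derives the energy
of any structure by loop decomposition — an independent code path that
shares only the parameter tables with the dynamic program. Every reported
energy (optimal and suboptimal) equals its loop-decomposition value
exactly, and on all sequences short enough to enumerate exhaustively
(≤ 14 nt) the DP minimum equals the enumeration minimum.

## Suboptimal structures

`fold_suboptimal` follows the mfold/RNAstructure recipe: every allowed
pair (i, j) is scored with E[prefix < i] + V(i, j) + F[suffix > j] — the
exact energy of the best structure in which (i, j) is an exterior-loop
branch — and candidates are traced back in ascending order of that
score. A candidate is kept if its energy lies within `percent_window`
(default 10%) of the LES and it differs from every kept structure by at
least `min_pair_distance` (default 3) base pairs (symmetric difference),
up to `max_structures` (default 20). The window/count/distance defaults
mirror the classic folding-program defaults.

Known simplification: alternatives that exist only strictly inside a
multibranch loop are not proposed as candidates (that would need the
O(n⁴) outside recursion). The structure *count* is therefore a lower
bound on the thermodynamic ensemble's diversity; since the count is used
comparatively (real vs. random under one procedure), this does not bias
the comparisons. A candidate-scan cap (default 1000) bounds work on
very shallow energy landscapes.

## Null model

For each real sequence the null partner has exactly the same ungapped
length and a G+C count of round(gc·L); within those budgets G/C and A/T
are split as evenly as possible (odd remainders assigned by the seeded
generator) and positions are a uniform random permutation. Exact-count
matching removes the uncontrolled tolerance that "similar GC content"
would otherwise carry; an i.i.d. mode and a dinucleotide-preserving
shuffle (random Eulerian walk with rejection, falling back to the source
on degenerate composition) are provided as alternatives. Per-record
seeds derive from (master seed, record index) via `SeedSequence`, are
recorded in the provenance table, and stay below 2³¹.

## Statistics

Mann–Whitney U is computed from joint midranks. The p-value policy:
exact enumeration when n+m ≤ 25 and the pooled data are tie-free;
seeded Monte-Carlo permutation (10⁵ draws) when n+m ≤ 25 with ties;
otherwise the normal approximation with tie and continuity corrections.
Kruskal–Wallis uses the tie-corrected H with a χ²(k−1) reference. A
constant pooled sample yields p = 1 with a warning rather than an error.
Raw p-values are reported (no multiple-testing correction), with a Holm
helper available. Rank-biserial correlation accompanies each U as an
effect size. Modes are reported with ties broken toward the smallest
value. scipy provides the exact/asymptotic machinery; the permutation
branch and all policies are this package's, and the test suite checks
the exact path against full enumeration over labelings.

## Alignment descriptive statistics

A column is *variable* if ≥ 2 distinct unambiguous base states occur
(gaps and IUPAC ambiguity codes are not states), and *parsimony-
informative* if ≥ 2 states each occur in ≥ 2 rows. "Ambiguous sites" are
removed as (i) any column containing an ambiguity code plus (ii) user-
masked column ranges — the manual judgement of alignment-uncertain
regions cannot be automated and enters through the mask. Gap spans are
coded as binary characters by simple indel coding: identical span → 1,
no overlapping gap → 0, any overlapping but non-identical gap
(including strict containment) → missing; terminal gap runs are treated
as missing data and never coded. GC content counts G+C+S over bases with
a determinate GC contribution (A, C, G, T, U, S, W). All coordinates in
reports are 1-based closed intervals.

## Synthetic families

The generator builds an ancestor that folds, by construction, into a
known number of hairpins, then evolves a star phylogeny from it.

* **Geometry** (defaults): ITS1-like 263 nt with 7 stems, ITS2-like
  206 nt with 3 stems; overall GC 0.55. ITS1-like ancestors carry the
  conserved central `AAGGAA` motif and the complementary `TCGAA`/`TTCGA`
  terminal stem that closes the molecule; motif positions are immutable
  under evolution by default.
* **Stems**: each planted helix is a conserved 6-bp core plus 3 flanking
  pairs (`stem_flank`), drawn GC-rich (pair classes GC/CG/AT/TA at
  0.45/0.45/0.05/0.05). Both choices are load-bearing: a lone 6-bp helix
  of average composition is not thermodynamically dominant over chance
  background pairing at GC 0.55, and the planted fold would not be the
  MFE. Real spacer helices are likewise longer than their conserved
  cores and strongly GC-biased. Hairpin loops avoid U so they do not
  offer G:U wobble partners to rearranged folds.
* **Filler** between stems is i.i.d. with G/C and A/T each split evenly —
  the same composition statistics the null generator produces — so that
  a family whose structure has fully drifted becomes statistically
  indistinguishable from its null cohort. (An earlier inert-filler
  design made *every* family distinguishable from its null on
  composition alone, which defeats the purpose of the negative control.)
* **Evolution**: each tip receives Poisson(divergence · L) substitutions
  at uniformly chosen non-motif sites. A substitution landing in a
  planted stem is *compensated* with probability c
  (`compensatory_fraction`): the site undergoes a class-conserving swap
  (G↔C, A↔T) and the partner is co-substituted to the Watson–Crick
  complement, so conserved helices keep full thermodynamic strength —
  mirroring the observation that compensated rRNA stems stay GC-rich.
  Uncompensated stem hits and all filler hits are free substitutions
  (uniform over the other three bases), so G:U pairs and broken pairs
  still accumulate in stems at rate (1−c). With c = 1 every planted pair
  stays pairable in every tip; with c = 0 structure decays freely.
* **Operating points**: the constrained condition is c = 0.9,
  divergence = 0.15 substitutions/site (4 groups × 3 species per
  region); the drifted condition is c = 0, divergence = 0.5. These were
  calibrated once against the folding pipeline and then frozen together
  with the test seeds.

**What the synthetic data do and do not show.** Families emulate the
size, GC content, motif content, hairpin counts and structural
conservation of real spacer families, and the >50% pairing and
ITS1-vs-ITS2 contrasts come out as in real data. They do not emulate
indel evolution, concerted evolution, tree-shaped (non-star) divergence,
or local GC heterogeneity; passing the parameter-recovery tests shows
the pipeline detects structural constraint of the planted kind, not that
it would have the same power on any real genus.

## Problem sizes

The test suite folds ~1,000 exhaustively checkable short sequences plus
40 synthetic study replicates (each 24 real + 24 null spacer-length
sequences); the acceptance script folds one 120 + 120 study. These sizes
keep a full run in minutes on one core while leaving every statistical
check adequately powered.

## Known limitations

* LES values are model-specific; only ranks and contrasts are
  comparable across folding engines. (Literature values for the same
  statistic, sometimes printed in "degrees", are read as kcal/mol.)
* The suboptimal count saturates at `max_structures` for sequences with
  deep, wide energy windows (10% of a large |LES| admits many folds), so
  contrasts in `n_structures` are weaker than contrasts in LES on the
  synthetic families.
* The 5.8S boundary is not detected; inputs must be pre-delimited
  ITS1/ITS2 (a coordinate sidecar can slice full amplicons upstream).
* The dinucleotide-shuffle null can fall back to the source sequence for
  degenerate compositions (documented, deterministic given the seed).
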