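# itsfold

Secondary-structure constraint analysis for nuclear ribosomal DNA internal
transcribed spacers (ITS1 and ITS2).

## The problem

ITS1 and ITS2 are excised from the rRNA precursor during ribosome
maturation, and correct processing depends on how they fold. If a spacer's
secondary structure matters to the organism, the sequence should look
*unusually foldable*: its minimum-free-energy structure should be more
stable, and its fold more constrained, than that of a random sequence with
the same length and GC content. That is a testable signature of selective
constraint — and it matters practically, because taxonomically complex
plant genera show ITS divergence so high that alignments break down, and
conserved secondary structure is one of the few anchors left for
homology.

`itsfold` implements that test as a reproducible pipeline:

1. **Fold** each spacer with a Zuker-style minimum-free-energy dynamic
   program under a simplified nearest-neighbor model (Turner-style
   stacking terms for the six canonical pairs including G:U, tabulated
   hairpin/bulge/internal-loop penalties, affine multibranch loops), plus
   a Nussinov base-pair-maximisation folder used as a small-instance
   oracle. Suboptimal structures within an energy window are enumerated
   mfold-style.
2. **Extract** the per-sequence statistics: lowest energy state
   LES = ΔG(MFE) in kcal/mol, total number of suboptimal structures,
   number of hairpin (terminal) loops, and the count and percentage of
   paired nucleotides.
3. **Generate the null**: for every real sequence, one random sequence
   with exactly the same length and GC count (exact-count composition,
   uniformly shuffled; a dinucleotide-preserving shuffle is available).
4. **Compare** with rank tests: Wilcoxon–Mann–Whitney (exact,
   permutation, or tie-corrected normal p depending on sample size and
   ties) between regions and against the null cohort; Kruskal–Wallis
   across taxonomic groups.
5. **Describe alignments**: variable and parsimony-informative site
   percentages, ambiguous-column removal, and simple indel coding of gap
   spans as binary characters.

A synthetic-data module generates ITS-like families (conserved motifs,
GC-rich stems that fold into a controlled number of hairpins, star-
phylogeny divergence with a tunable compensatory-substitution fraction)
so the whole pipeline is testable without downloading anything, and so
constraint detection can be validated by parameter recovery.

## Worked example

```python
from itsfold import fold_suboptimal, featurize, SequenceRecord
from itsfold.nulls import matched_random_sequence
from itsfold.stats import mann_whitney_u
from itsfold.synth import SynthConfig, make_family

# a synthetic ITS1-like family: 4 groups x 3 species, 7 planted stems,
# divergence 0.15 subs/site, 90% of stem hits compensated
family, planted = make_family(SynthConfig(region="ITS1", seed=5))

rec = family[0]
features = featurize(fold_suboptimal(rec.ungapped()), rec)
print(features.les, features.n_hairpins, features.pct_paired)
# -150.7 7 73.00380228136882

les_real = [featurize(fold_suboptimal(r.ungapped()), r).les for r in family]
les_null = [fold_suboptimal(matched_random_sequence(r, s).ungapped()).les
            for s, r in enumerate(family)]
print(mann_whitney_u(les_real, les_null).p_value)
# 7.39602301050679e-07
```

The family member folds into 7 hairpins at −150.7 kcal/mol with 73.0% of
bases paired; across the family, LES is far below that of the matched
random cohort (exact two-sided p ≈ 7.4e−07) — the family is flagged as
structurally constrained.

The same analysis from the shell:

```bash
itsfold synth --region ITS1 --seed 5 --out demo/
itsfold run --config config.yaml --seed 5 --out results/
```

`run` writes: per-sequence `features.tsv` (real + null), group summary
`summary.tsv` (mean (SD) per group, Table-style), `tests.tsv` (all rank
tests), `scatter.tsv` (LES vs number of structures per class),
`hairpin_freq.tsv`, the null cohort FASTA with a provenance table, and a
run log. Reruns with the same config and seed are byte-identical.

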