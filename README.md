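# abmotif

Cross-species discovery of **phenotype-related functional modules** from
protein functional-association networks.

Given a cohort of organisms split into phenotype-expressing (*positive*) and
non-expressing (*negative*) types — hydrogen producers vs. non-producers,
motile vs. non-motile, and so on — `abmotif` finds the groups of orthologous
gene clusters (COGs) whose mutual functional associations are conserved in
many positive organisms but few negative ones. Such conserved modules are
strong candidates for the cellular subsystems that realise the phenotype:
metabolic enzymes, but also their regulators, transporters and
uncharacterised partners.

## Method

1. **Two-typed, divided network.** Each organism's STRING-style weighted
   COG–COG association network (edges kept above a combined-score threshold)
   becomes one *division* of a single graph whose vertices are
   (organism, COG) pairs. Across divisions, *orthology* edges join equal
   COGs, and *conserved-association* edges join (A, c1)–(B, c2) exactly when
   the association c1–c2 exists in both A and B. A module conserved across
   organisms then appears as one **maximal clique** of this single graph —
   no multi-way clique comparison across networks is needed.

2. **(α, β)-criterion.** With the type-count c(S, t) = number of organisms
   of type t touching vertex set S, an *(α, β)-clique* is a maximal clique S
   with c(S, positive) ≥ α and c(S, negative) ≤ β. Enumeration is a
   pivotless Bron–Kerbosch recursion with two pruning bounds (cut a branch
   as soon as the negative count exceeds β; cut when the positives reachable
   from clique ∪ candidates fall below α). The bounds only prune: the output
   is identical in all three bound modes, and at (α = 0, β = #negatives) it
   is the full maximal-clique set.

3. **Parameter selection.** Candidate (α, β) pairs are screened with the
   one-sided hypergeometric test: drawing α + β organisms from the cohort,
   P(X ≥ α) with the positives as successes. Pairs with α ≥ β and p ≤ 0.005
   are kept, and for each β only the smallest qualifying α (*non-redundant*
   pairs). For the classic 9-positive / 8-negative hydrogen-production
   layout this selects exactly (7, 0), (8, 1), (9, 2).

4. **Scoring.** Each module gets the same hypergeometric tail as its
   phenotype-bias p-value, plus a phylogenetic diversity score
   S_p = (PP − PN − NN)/(PP + PN + NN) over pairwise organism distances
   (ordered-pair sums; +1 for modules carried only by phylogenetically
   spread positives, −1 for negatives only), which flags modules that are
   shared merely through common ancestry.

See `docs/methods.md` for assumptions, parameter defaults and numerical
details.

## Worked example

Simulate a 5-positive / 3-negative cohort with a 3-COG module planted in
four positive organisms, then run the finder at (α, β) = (4, 0):

```sh
abmotif simulate --n-pos 5 --n-neg 3 --universe-size 10 --seed 11 \
    --planted '[{"cog_ids": ["COG0001","COG0002","COG0003"],
                 "positive_carriers": ["pos01","pos02","pos03","pos04"]}]' \
    --out cohort/
abmotif enumerate $(for f in cohort/*.links.tsv; do echo --links $f; done) \
    --phenotypes cohort/phenotypes.tsv --distances cohort/distances.tsv \
    --alpha 4 --beta 0 --out out/
```

The run prints `1 modules -> out/modules.tsv`, and the table contains
exactly the planted module:

```text
cog_set                      positive_orgs            negative_orgs  alpha_count  beta_count  p_value               phylo_score
COG0001;COG0002;COG0003      pos01;pos02;pos03;pos04                 4            0           0.07142857142857142   1.0
```

Reading: the three COGs form a fully associated clique in exactly the four
planted carrier organisms and no negative one (α-count 4, β-count 0). The
p-value 0.071 is the chance that a module present in 4 of these 8 organisms
hits 4 positives by luck — unimpressive here only because the cohort is
tiny. The phylogenetic score 1.0 says every carrier is positive, the
strongest diversity signal the score can give. The same run prints a
`manifest.json` recording the config, seed and network summary, and the
library API (`abmotif.run_on_cohort`, `enumerate_ab_cliques`, ...) exposes
every step programmatically.

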