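# Methods

## Composition vectors

Each species is represented by the frequencies of length-K peptides counted
with a sliding window (step 1) inside every protein independently; windows
never span two proteins, and each order's frequencies are normalized by that
order's own total window count. From the (K−1)- and (K−2)-string
frequencies an order-(K−2) Markov model predicts
`p0(a1…aK) = p(prefix)·p(suffix)/p(core)`, and the composition-vector entry
is `(p − p0)/p0`. The support of the vector is exactly the set of "joins"
of two observed (K−1)-mers overlapping in K−2 positions: every observed
K-mer is such a join, and joins unseen as K-mers get score −1
(`p = 0, p0 > 0`). Entries with p0 = 0 are defined as 0 and, like exact
zeros, not stored (sparse absent-means-zero contract throughout).

Numerical notes: no finite-size correction factor is applied to the
frequency ratios — the correction is O(1/L), identical across species of
similar proteome size, and irrelevant to variance *ranking*, which is all
the selection uses. Scores are exact rational arithmetic in floating point;
the test suite checks them against dense brute-force oracles at 1e−12.

Sanitation: sequences are upper-cased; the ambiguity codes B, Z, J, X and
the stop marker `*` are removed before counting (they can never match a
K-string over the 20-letter alphabet); anything else non-canonical (U, O,
digits…) is a hard error. K defaults to 5 and is configurable 3–7; below 3
the background model is undefined.

## Key K-string selection

Across N species the population variance (divide by N) of each K-string's
scores is computed, with absent entries contributing 0. Selection depends
only on variance *ratios* — threshold = `(1 − r)·v_max` with reduction
r = 0.90 — so the population-vs-sample convention is immaterial (asserted
by a property test). The inequality at the threshold is strict; with
`v_max = 0` the selection is empty. Strings absent from every species have
variance 0 and can never be selected.

Extraction protocols (all seeded, all recorded in each key set's
provenance):

* **group keys** — shuffle species, deal them round-robin into `n_subgroups`
  near-equal subgroups (remainders to the earliest subgroups), select keys
  per subgroup, intersect;
* **broad/core keys** — repeat the group procedure on random samples of
  `group_size` species (without replacement within a repetition,
  independent across repetitions) until a new repetition's keys are ≥ 95%
  contained in the running union ("almost totally represented",
  quantified), or 10 repetitions; broad = union, core = intersection;
* **taxon-specific keys** — the group procedure inside each subtaxon,
  unioned with the supplied broad set;
* **global keys** — the union of all taxon-specific sets and the broad set.

Desk-scale adaptation: the subgroup intersection retains a clade-diagnostic
string only when *every* subgroup contains both carriers and non-carriers.
With a pool of 20 species and 5 subgroups of 4, a string carried by 5
species survives only when its carriers spread over all 5 subgroups
(probability 4^5/C(20,5) ≈ 6.6%) — the full-scale defaults are degenerate
on small pools. `effective_subgroups` therefore shrinks the subgroup count
so each subgroup holds at least ~2 species per clade (5 subgroups for
hundreds of species, 2 for a 20-species/4-clade pool), and subtaxa with
fewer than 4 species fall back to a plain whole-subtaxon selection. The
full-scale defaults (group_size 20, 5 subgroups, 10 repetitions, r = 0.90)
remain the library defaults.

### Sharing and bias

For key sets A (row) and B (column), bias = `100·(1 − |A∩B|/|B|)`, i.e. the
percentage of the *column* set absent from the row set, rounded to one
decimal; undefined (reported missing) when B is empty. The bundled
11-phylum reference table (`keystrings.reference`) stores published set
sizes and pairwise shared counts for metazoan mitochondrial phyla; the
bias cells and min/max/mean summaries are recomputed from those counts at
run time. Four printed cells of the original table disagree with the
formula (two by one rounding ulp, two outright); the computed values are
reported, not the printed ones.

## Trees

Cosine distance `D = (1 − C)/2 ∈ [0, 1]` over the union of supports, with
`C := 0` (D = 0.5) when a projected vector is all-zero — possible after
key-set projection of a distant species, and logged. Neighbor joining and
Newick I/O are delegated to scikit-bio; negative branch lengths are clamped
to zero (library convention). Topology comparison uses non-trivial leaf
bipartitions normalized as unordered side pairs, reporting both the shared
fraction `100·|B1∩B2|/max(|B1|,|B2|)` and the raw Robinson–Foulds count;
two identical-leaf star trees compare at 100.

Bootstrap: gene families are drawn with replacement (G draws from the
G-family universe) and the *same* draw applies to all species — a locus
bootstrap. Resampling independently per species would make the CVs
incomparable across species, so the per-species reading of the procedure
is deliberately not implemented. A replicate draw keeps
`1 − (1 − 1/G)^G` of the families in expectation (64.7% for G = 13); the
often-quoted "about 80% kept" is not reachable by any
draw-with-replacement scheme at G = 13 and is not targeted. Supports are
attached to the full-data tree as the percentage of replicates containing
each bipartition; a majority-rule consensus tree is also available.

## Chi-square test

Pearson `X² = Σ (O − E)²/E` over the k tested K-strings with
`E = total_windows · p0`, dof = k − 1, upper-tail p-value, 5% level.
Strings with E = 0 are dropped (with a warning); fewer than 2 testable
strings is an error.

Size check (the calibration the test suite runs): K = 3 over the full
20-letter alphabet, 500 sequences of length 60,000 from stationary
first-order Markov chains (one Dirichlet(10)-row transition matrix per
sequence), k = 10 tested strings per sequence sampled among cells with
E ≥ 5 (the textbook validity rule) under distinct middle letters (distinct
Markov cores, so cells are nearly independent). Because the expectations
are fitted from the same data, each Pearson cell has null mean ≈
`(1 − 1/20)² ≈ 0.90` rather than 1, so the k−1 dof convention is mildly
conservative; the observed rejection rate (~0.04) sits inside the
documented [0.02, 0.08] band. K = 5 would need multi-megabase chains to
reach E ≥ 5 and is not used for calibration.

## Conservativity and localization

For each alignment window (width 5, step 1), m = multiplicity of the most
frequent row segment (gaps are ordinary symbols);
`score = round(scale·(m−1)/(n−1))` with scale 15 and half-up rounding,
reproducing the endpoints (15 = all rows identical, 0 = all distinct) that
define the scale. Key occurrences are mapped per row with overlaps counted,
gapped rows matched on their ungapped residues and reported in alignment
columns; accumulation regions are maximal column runs with summed coverage
≥ min_total (default 1) over ≥ min_len (default 5) columns. The overlap
summary compares the fraction of region vs non-region columns whose best
covering window exceeds a conservativity cutoff (default 8).

## Synthetic data generator

The generator emulates the structure the method feeds on, with ground truth:

* a random root proteome over 13 mitochondrial-realistic gene lengths
  (atp8 ≈ 55 aa … nad5 ≈ 603 aa, ~3,800 aa total);
* evolution down a known tree (balanced over phyla, caterpillar within,
  unit branches) by per-site substitution with uniform replacement over the
  other 19 residues — no empirical rate matrix, no indels, no
  among-site rate variation beyond the block structure below;
* conserved blocks: gene intervals at `rate × multiplier` (default 0.1),
  emulating slow protein cores;
* clade-diagnostic motifs: 5-strings overwritten at a chosen clade's
  ancestor. Motifs must sit fully inside a conserved block — the
  biological picture is diagnostic variants embedded in conserved cores —
  and their sites are held invariant below the root/ancestor so presence
  and absence are exact, seed-independent ground truth;
* context strings: per motif, copies of its interior 3-mer core with
  neutral flanks planted in all species (inside blocks, invariant). These
  are what make a motif visible to the CV transform: a string whose
  prefix/suffix/core counts all equal its own count has p = p0 and scores
  exactly 0, while a common core with clade-unique flanks scores ≈ the
  number of context copies in carriers and is absent elsewhere;
* a reserved-pattern scrub: chance occurrences of any motif's 4-mer prefix
  or suffix (or the motif itself) outside engineered sites would distort
  the controlled counts, so the generator rewrites one free position of
  any such occurrence, at the root and after every branch.

The default substitution rate is 0.05 per site per branch unit, giving
~25–30% cross-phylum divergence — realistic for mitochondrial proteins —
and a clear contrast between blocks and background in the conservativity
profile. Because replacement is uniform and there are no indels, simulated
alignments are exact positional correspondences (`concatenated_alignment`),
and passing tests say nothing about alignment quality, empirical
substitution processes, compositional biases, or rate heterogeneity in real
data; they certify the counting, selection, tree and localization
machinery given data whose signal is known.

Named fixtures pin seeds as part of their identity: `twoclade-minimal`
(2 × 4 species, 3 genes), `small4x5` (4 × 5 species, 13 genes, 4 phylum
motifs + 2 deeper-clade motifs), `vertebrate-like10x2` (5 clades × 2).
The deeper-clade motifs give sister phyla shared keys, so the
key-projected tree recovers the phylum backbone, not just monophyly.

## Pipeline

`run_pipeline` reads a flat `key = value` config, runs
simulate/load → CVs → broad/specific/global keys → distances (full and
key-projected) → NJ + bootstrap supports → sharing table → composition
profiles → conservativity/localization, and writes everything plus a JSON
manifest (parameters, seeds, SHA-256 of every artifact) into a temporary
directory promoted atomically. Identical configs produce bit-identical
artifacts. Key-projected and full trees are compared both at the species
level and at the phylum level (monophyly + induced phylum topology); at
desk scale the two trees agree at the phylum level while the species-level
similarity is lower, since the projection deliberately discards most
within-phylum backbone signal.

## Known limitations

* The variance threshold is a heuristic corner estimate; no uncertainty is
  attached to the selected set.
* The sharing/bias reference covers 11 phyla of one published snapshot;
  the synthetic fixtures cannot (and do not try to) reproduce
  dataset-specific key counts.
* The chi-square test inherits the conservativeness discussed above;
  p-values near the 5% boundary should be read accordingly.
* The conservativity score is a segment-multiplicity statistic, not an
  evolutionary rate estimate; it saturates for n ≫ scale.
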