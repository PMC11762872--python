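# Methods

This note records the models, conventions and numerical choices behind
`ssphylo`, and what the synthetic-data experiments do and do not show.

## Coordinates, records, formats

All coordinates are 0-based, half-open `[start, end)`. Sequences are RNA
over `{A,C,G,U,N}`; `T` is normalized to `U` on input. Secondary structures
are dot-bracket strings with nested pairs only (no pseudoknots); validation
is stack-based and reports the first offending position. The xfasta dialect
is: one `>` header per entry, a sequence block, then a structure block of
equal total length; lines consisting only of `( ) .` are structure lines.
This dialect is our own definition — no claim of byte-compatibility with
other tools' xfasta files is made. Newick support values are stored as
integer internal-node labels, the dominant convention; the writer formats
branch lengths with six decimals so identical runs produce byte-identical
files.

## ITS2 annotation

The 5.8S end and 28S start are modeled as small plan-7-style profile HMMs:
per-column match emissions over `{A,C,G,U}` (maximum-likelihood column
frequencies with pseudocount 1), shared transition parameters
(match→insert = match→delete = δ = 0.02; insert→insert = delete→delete =
ε = 0.1). Scoring is Viterbi in log-odds space against a uniform
background. The scan is local in the sequence (flanking residues free) and
local in the model: a path may enter at any match column and leave at any
later column, paying a uniform −log L penalty at each end (L = number of
match columns). Model-local matching is what lets a flank truncated
mid-motif still be recognized from its surviving columns — with a strictly
model-global path space, the forced deletions outscore any partial match
and a spurious interior hit wins instead — while the entry+exit penalty of
−2·log 25 ≈ −6.4 nats keeps short lucky matches in random sequence below
the default log-odds floor of 0.

The ITS2 is the region strictly between the two hits. The proximal
interval extends it by up to L = 25 nt into each flanking gene (the
5.8S/28S interaction that closes the spacer); `full_proximal_stem` is true
only when neither extension is truncated by a sequence boundary, and only
such records pass the annotation filter. The 25-nt convention is the
operational definition used throughout; the alternative reading (only the
base-paired positions of the stem) is not implemented.

On noiseless planted motifs boundary recovery is exact; under ≤ 5 %
per-base substitution noise the median boundary error stays ≤ 2 nt (both
property-tested).

## Structure prediction

**Homology modeling.** The target is globally aligned to a template
sequence (match +2, mismatch −1, gap open −5, gap extend −2; a gap of
length k costs open + k·extend). A template pair (p, q) transfers to
target positions (i, j) iff both p and q align to non-gap target columns
and target[i], target[j] form a canonical or GU wobble pair. The
*structure transfer percentage* divides transferred pairs by the template's
pair count; the alternative denominator (fraction of target positions
receiving structure) is available via `denominator="target"`. The ≥ 50 %
homology filter is inclusive ("at least 50 %"). Template selection takes
the maximal percentage, ties keeping the earlier template in the list.

**Constrained folding.** The fold maximizes a weighted base-pair count
(GC = 3, AU = 2, GU = 1, stacking-free) over nested structures with a
minimum hairpin loop of 3 and N never pairing — a Nussinov-style
objective, deliberately simpler than a full thermodynamic model: it is
exactly checkable against exhaustive structure enumeration and sufficient
for homologous-helix recovery under ring constraints. Two constraint
classes exist: `forbidden` positions may not pair (the literal
lowercase-constraint semantics of constraint-folding programs), and
`exterior` positions may neither pair nor be enclosed by a pair. The
central ring of the ITS2 is passed as `exterior`: under pure base-pair
maximization a single long-range pair could otherwise enclose the whole
ring and collapse the four-helix architecture into one helix, which is
precisely what ring constraints are meant to prevent. Traceback is
deterministic: leave i unpaired at ties, then the smallest partner j, then
the leftmost split.

**Helix-core report.** A helix is rooted at each pair enclosed by no other
pair (emanating from the exterior/central loop); every pair nested inside
it — including sub-helices past multibranch points — counts toward its
length. Helices are reported 5′→3′; ties for the longest go to the
smallest index. The canonical eukaryote ITS2 core is four helices with the
third the longest.

## 12-letter encoding

Each position maps to (nucleotide) × (unpaired `.` | paired-left `(` |
paired-right `)`), a 12-letter alphabet. The concrete letters — unpaired
→ `A C G U`, paired-left → `B D H V`, paired-right → `E F I W` — are
arbitrary but fixed and versioned (`ssphylo-1`); every downstream score,
distance and likelihood is invariant under relabeling (property-tested).
`N` is legal only unpaired and becomes a 13th wildcard symbol excluded
from distances and likelihoods. Decoding validates that the implied
brackets balance, so decode∘encode is the identity on valid pairs.

## Alignment

The default 12×12 matrix separates the two fused channels:
score = (+2 same nucleotide / −1 different) + (+2 same pairing state / −2
different), i.e. +4 for identity down to −3 for a double mismatch; gap
open −8, gap extend −2, terminal gaps penalized like internal ones. Any
symmetric matrix can be loaded from TSV. Pairwise alignment is three-state
Gotoh with deterministic traceback (diagonal > gap-in-second > gap-in-first);
the fill is vectorized row-wise, the horizontal gap state via a
prefix-maximum recurrence. Multiple alignment is progressive: an NJ guide
tree on 1 − fractional-identity distances from all pairwise alignments
(exact at desk scale; no k-mer approximation), profiles merged in
postorder with profile–profile scores equal to the mean pairwise matrix
score over non-gap symbols, and "once a gap, always a gap". The degap
invariant (every output row reproduces its input) is asserted after every
merge.

## Trees

*Distances.* p-distance over columns comparable in both rows (gap or
wildcard in either row excludes the column from numerator and
denominator), corrected by the 12-state equal-rates closed form
d = −(11/12)·ln(1 − (12/11)·p), defined for p < 11/12; saturation raises
an error rather than clamping.

*Neighbor joining.* Saitou–Nei with the Studier–Keppler criterion;
negative branch-length estimates are clamped to zero with the deficit
moved to the sister edge; Q-ties resolve to the lexicographically smallest
label pair, making the tree deterministic. NJ is exact (topology and
branch lengths) on additive matrices, which the tests exploit as an
oracle.

*Parsimony.* Fitch set-intersection counts over the 12-state alphabet,
gaps as missing data (full state set); polytomies fold children pairwise,
which on the trifurcating root of an unrooted binary tree equals any
binary rooting. Site patterns are compressed and state sets held as
bitmasks. `mp_search` enumerates all unrooted topologies up to 8 taxa
(10 395 at n = 8), otherwise NNI hill-climbing with deterministic
first-improvement order from the NJ tree.

*Likelihood.* Felsenstein pruning with per-pattern rescaling. JC12 uses
the closed form P_same(t) = 1/12 + (11/12)·e^{−(12/11)t}; GTR12 builds
Q_ij = s_ij·π_j normalized to one expected substitution per site and
exponentiates with `scipy.linalg.expm`. Branch lengths are optimized
coordinate-wise by bounded Brent (tolerance 1e−6, bounds [1e−8, 10]);
topology search is NNI from the NJ start. GTR12 estimation fixes π at the
empirical symbol frequencies (pseudocount 1) and maximizes the likelihood
over log-exchangeabilities with L-BFGS-B. Zero-length branches (duplicate
sequences) are legal; the likelihood stays finite.

*Bootstrap and support.* Columns of the encoded alignment are resampled
with replacement (sequence and structure jointly — the encoding fuses
them), B = 100 by default, seeded. Support of an internal edge is the
percentage of replicate trees containing the same bipartition
(rooting-invariant canonical leaf-set encoding). All values are stored
exactly; hiding values ≤ 50 is purely a display rule of the Newick
writer. Outgroup rooting requires the outgroup to induce a single edge and
places the root at that edge's midpoint.

## Synthetic data

The generator emulates the study conditions the pipeline expects. The root
pair has four helices (default `[6, 8, 14, 5]` base pairs — third longest,
the eukaryote core) of 4-nt loops, separated by 5-nt central-ring spacers;
`site_count` pads the molecule with unpaired tail positions. Evolution
along the tree is event-based: substitution events arrive per site as
Poisson(branch length), each replacing the nucleotide uniformly by one of
the other three; if a paired position's new state breaks the pair, the
partner is redrawn from the allowed partners — the compensatory
co-substitution that conserves structure while sequence diverges. Trees
are Yule (birth–death with death rate 0) with leaves `t1..tn`, or
user-supplied. Indels are deletions only, confined to unpaired positions
(per-site deletion probability 1 − e^{−rate·t}), so true structures remain
well-defined and the true alignment stays in root coordinates. Cistrons
concatenate `[random 5.8S tail][25-nt 5.8S motif][ITS2][25-nt 28S
motif][random 28S head]` with the truth interval recorded; the two motifs
are fixed package constants so annotation models and data agree by
construction. Template sets mutate a source pair position-wise at chosen
divergence levels (compensatory at paired positions) while keeping its
structure, producing transfer percentages that straddle the 50 % filter.

What this does **not** emulate: insertions, rate heterogeneity across
sites, base-composition bias, structure rearrangement (helix gain/loss),
or realistic taxon sampling. Passing tests therefore demonstrate
correctness of the algorithms and the end-to-end plumbing under the
model's own assumptions, not performance on real chytrid data.

## Pipeline

Stages run in the order annotate → species filter → annotation filter →
structure prediction → homology filter → encode → align → trees →
bootstrap → root → report. Discard reasons form a closed vocabulary
(`not_binomial`, `annotation_failed`, `truncated_proximal_stem`,
`low_structural_homology`, `user_excluded`), and kept + discarded equals
the input count at every stage. The species filter accepts exactly
binomial names (two words, capitalized genus, lowercase epithet, epithet
not in {sp, sp., cf., aff., uncultured, environmental}). The region passed
to structure prediction is the proximal interval (ITS2 + 25-nt flanks),
matching the practice of modeling structures that include the proximal
stem. `homology_then_fold` re-folds each homology-modeled structure with
its central ring as an exterior constraint; the single-phase modes are
also exposed, and an overview preset (NJ only, no bootstrap) covers
large-scale scans. Fewer than four surviving records abort the run after
writing the manifest. With a fixed config and seed, manifests, alignments
and Newick files are byte-identical across runs.

## Problem sizes in tests and the acceptance script

The test suite and `scripts/acceptance.py` use desk-scale sizes chosen to
make every oracle exhaustive and every stochastic check well-resolved:
alignment oracles at lengths ≤ 6, fold enumeration at lengths ≤ 12, Fitch
brute force at ≤ 6 taxa, direct likelihood summation at ≤ 5 taxa, NJ
additivity at ≤ 10 taxa, topology recovery on a fixed 8-taxon tree
(branch lengths 0.05–0.3) with 2000 sites × 100 replicates, support
monotonicity at 500 vs 4000 sites, and full pipeline runs on 8 synthetic
cistrons of ~600-site spacers.

## Known limitations

- The folding objective is base-pair maximization, not a free-energy
  model; predicted helices are reliable only relative to that objective.
- The profile HMMs are trained from user-supplied (or generated) motif
  alignments; no curated rRNA models ship with the package.
- GTR12 estimation is a direct optimization on a fixed tree and is not
  iterated with topology search.
- No rate heterogeneity (Γ), no Bayesian inference, no pseudoknots.
- 4SALE/ProfDistS letter assignments and matrices are unpublished;
  equivalence with those tools holds at most up to relabeling and is not
  claimed.
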