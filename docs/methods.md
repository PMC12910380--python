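# Methods

## The model

`teao` profiles each column of a protein multiple sequence alignment (MSA)
with two Shannon entropies. The **global entropy** of column *c* is

    H_global[c] = - sum_a p_a log2 p_a ,

where *p_a* is the frequency of residue *a* among the standard residues
observed in the column (gaps and ambiguity codes excluded; see below). The
**subgroup-averaged entropy** removes the user's choice of protein
subfamilies by averaging over every partition cut from a UPGMA tree of the
sequences: for the level-*k* partition into subgroups *g* of sizes *n_g*,

    H_level[k][c] = sum_g (n_g / N) * H(column c restricted to g) ,
    H_avg[c]      = mean over k = 1..N of H_level[k][c] .

Within-level averaging is **size-weighted**, which makes the gap
`H_global - H_avg` exactly the average mutual information between a
column's residue and the subgroup label — by Jensen's inequality it is
never negative, the invariant the test suite checks. Across-level
averaging is unweighted; the alternative level set k = 2..N-1 (dropping
the trivial one-group and all-singleton partitions) is available via
`levels="inner"`.

Two per-column scores in [0, 1] summarise the two entropies:

    conservation = 1 - H_global / log2(20)
    specificity  = (H_global - H_avg) / (H_global + h0),   h0 = 0.5 bits

Conservation is 1 exactly when one residue is universal. Specificity is
the **fraction of the column's entropy explained by the subgrouping**,
which is the quantity that actually separates subfamily-specific columns
(entropy capped at log2 of the subfamily count but almost fully explained)
from merely variable columns (large entropy, mostly unexplained). A raw
normalised difference `(H_global - H_avg)/log2(20)` does not have this
property: a uniformly random column over 20 residues carries ~3.9 bits of
which ~2.6 remain after averaging, beating any 4-subfamily-specific column
(at most 2 bits total). The unsmoothed fraction fails in the opposite
direction — near-conserved columns with one or two noise substitutions
have tiny entropy that is trivially "explained" and rank spuriously high.
The pseudo-entropy h0 in the denominator damps them; 0.5 bits means
"columns carrying less variation than a single 50/50 substitution cannot
score highly". h0 is exposed as `specificity_smoothing` (must be > 0).

## Tree construction

Pairwise distances are p-distances over pairwise-complete columns: the
mismatch fraction among columns where both sequences carry a standard
residue. Pairs with no comparable column get distance 1.0 and a logged
warning rather than an error, so sparse alignments degrade gracefully.

UPGMA is implemented locally and deterministically rather than delegated
to a clustering library, because the subgroup partitions — and therefore
H_avg — must be bit-reproducible across environments. Merge height is half
the between-cluster average distance (classic ultrametric convention;
branch lengths in Newick output are height differences). Two numerical
choices matter:

- the between-cluster average is always computed as
  `(sum of leaf-pair distances) / (n_a * n_b)` with sums merged by exact
  addition, never as an incrementally rounded running average — so tie
  detection cannot drift through accumulated rounding;
- exact ties are broken by the lexicographically smallest pair of cluster
  *founding labels* (the smallest leaf label each cluster contains). Label
  — not index — tie-breaking makes the tree invariant to the input order
  of the sequences, which the test suite verifies by permutation.

Level *k* of the partition chain undoes the last *k-1* merges; level 1 is
one group, level N the singletons, and each level refines the previous
one. The selection loop is quadratic per merge (cubic overall), which is
deliberate: exactness and auditability are worth more here than the
fastest possible linkage, and alignments of a few thousand sequences
remain practical.

## Physicochemical variability

Entropy treats residues as interchangeable symbols. The z-scale profile
restores chemistry: the packaged table carries the first three principal
components of a large experimental amino-acid property panel (z1
lipophilicity, z2 steric bulk/polarizability, z3 polarity/charge); the
low-variance fourth and fifth components are not shipped. For every column
the population standard deviation (ddof = 0 — the column is the entire
population of interest) of each descriptor is taken over residue
*occurrences*: each sequence contributes one observation, so a column of
19 leucines and one aspartate scores differently from a 50/50 mix.
`weighted=False` switches to one observation per distinct residue, and
`ddof=1` to the sample SD, for sensitivity analysis. Gaps and ambiguity
codes contribute nothing; columns with fewer than two scored observations
are flagged `low_support` and report SD 0. Custom descriptor tables (any
number of numeric columns over exactly the 20 standard residues) plug into
the same machinery.

## Gaps, ambiguity codes, and degenerate columns

Gaps are excluded from entropy distributions by default: counting them as
a 21st symbol inflates entropy at ragged alignment edges. The switch
`gap_as_symbol=True` restores that behaviour for comparison. The per-column
gap fraction is always reported separately. Ambiguity codes (X, B, Z, J,
U, O) are accepted on input but excluded from residue counts, distances,
entropies and property scores — they have no single identity and no
z-scale values. Columns where at most one residue remains after exclusions
get entropy 0 with a `low_support` flag carried into all outputs, avoiding
NaN propagation while staying auditable.

## Taxonomic filtering

Lineages come from local NCBI-style dump files (tab-separated
accession-to-taxid table; `"\t|\t"`-delimited nodes/names tables, names
filtered to the scientific-name class), parsed entirely offline with a
cycle guard on parent walks and a malformed-line threshold (default 10%)
below which bad lines are logged, not fatal. Accessions are extracted from
FASTA identifiers by a configurable extractor whose default understands
UniProt-style `db|ACC|name` headers and bare accessions with version
suffixes. Filtering keeps sequences whose lineage passes through an
include taxon (and not an exclude taxon), preserves order, never drops
unmapped sequences silently, and refuses to produce an alignment of fewer
than two sequences. Rebalancing over-represented taxa is explicitly out of
scope; only filtering is provided.

## Screening

Candidate specificity/rheostat positions are reference-mapped columns that
pass four criteria: at least `min_distinct_residues` distinct standard
residues (default 10), entropy above a threshold (default: the top
quartile of H_global over reference-mapped columns — a scale-free default;
an absolute threshold in bits and the specificity metric are selectable),
distance from the termini (default 10 reference residues on each end), and
absence from a user-supplied exclusion list of known catalytic or binding
residues. Failing rows are retained with their failure reasons, so the
passing set can be reconstructed from the audit columns; tightening any
single criterion can only shrink it (tested).

## Synthetic data generator

The generator emulates exactly the structure subfamily analysis must
recover, not real evolution: planted subfamilies with per-column classes
`conserved` (one residue everywhere), `subfamily_specific` (one residue
per subfamily, drawn without replacement so subfamilies are maximally
discriminative), `random` (i.i.d. uniform over 20 residues) and `gappy`
(random plus i.i.d. gaps). Independent per-cell substitution noise is
applied on top. All draws come from one `numpy` generator seeded from the
spec — no global random state — so the same spec yields byte-identical
FASTA. The standard validation design used throughout the tests is 4
subfamilies x 8 sequences and 100 columns (10 conserved, 10 specific, 80
random), at substitution noise 0 and 0.05.

What passing these tests does **not** show: the generator has no
phylogenetic substitution process (no rate matrices, no indel evolution,
no branch-length structure within subfamilies), no alignment error, and no
taxonomic sampling bias. Results on real alignments therefore inherit the
quality of the MSA and the representativeness of the sequence sample in
ways the synthetic recovery tests cannot probe.

## Determinism

No pipeline stage consumes randomness except the fixture generator.
Identical inputs and configuration produce byte-identical TSV, Newick and
sidecar outputs across reruns (tested), and every figure is accompanied by
a machine-readable table of exactly the plotted values — tests assert on
those tables, never on pixels.

## Problem sizes in the validation suite

The test suite and `scripts/acceptance.py` run on the scales the method is
meant to certify rather than stress: 100 random distance matrices of up to
8 taxa against a brute-force UPGMA oracle, 50 random MSAs (4-10 sequences,
8-20 columns) for the concavity bound, and 100 replicates of the 32 x 100
synthetic design for noisy recovery. The full acceptance script completes
in seconds on one CPU.

## Known limitations

- The cubic UPGMA is not suitable for alignments of tens of thousands of
  sequences.
- p-distance ignores substitution multiplicity; no model-corrected
  distances are offered.
- Entropy is unweighted by sequence redundancy; heavily over-represented
  clades bias both entropies (use taxonomic filtering to mitigate).
- The specificity score depends on the tree being at least roughly right;
  with very few sequences per subfamily the partitions — and hence
  H_avg — are unstable.
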