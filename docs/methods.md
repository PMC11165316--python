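# Methods

## Rationale and model

Orthologous proteins that diverged within the last one or two hundred
million years accumulate many substitutions but very few long
insertions or deletions; proteomes without alternative splicing
(bacteria, and very nearly yeast) show almost no gaps ≥5 residues in
>90%-identical alignments. Long gaps between highly identical
orthologs are therefore treated as evidence of inconsistent canonical
isoform choice rather than of evolution. The method searches, within
each orthogroup, for a set of sequences — at most one per proteome —
that align essentially without gaps, and prefers that set as the
canonical representatives.

### Gap-only distance

For two rows of a multiple sequence alignment, let *B* be the columns
gapped in both rows, *G* the columns gapped in exactly one, and *L*
the total number of columns. The distance is

    d = |G| / (L − |B|)

Columns in *B* are excluded from numerator and denominator: they are
insertions belonging to third sequences, and counting them would
create phantom distance between two rows with identical gap
structure. The denominator is the *pairwise* effective length, not
the full MSA width; for a two-sequence alignment the two coincide
(a 5-residue gap in an otherwise full-length alignment of length 100
gives d = 0.05), and the pairwise form is robust to unrelated rows'
insertions. Terminal gaps count exactly like internal gaps, which is
what forces members of low-cost clades to have near-identical
lengths. Substitutions contribute nothing, by construction; the test
suite asserts exact invariance of the matrix under random residue
mutation.

Degenerate pairs (no column with a residue in either row) are an
error; they cannot occur in validated alignments, which forbid
all-gap columns.

### Tree construction

Trees are standard Saitou–Nei neighbor joining on the gap-distance
matrix: repeatedly join the pair minimizing
Q(i,j) = (n−2)·d(i,j) − Σ_k d(i,k) − Σ_k d(j,k), with the usual limb
length formulas, ending in a trifurcating root at the last join (the
tree is conceptually unrooted; the root only anchors traversal).
Numerical choices:

* **Ties.** Gap matrices are full of exact zeros, so Q ties are
  common. They are broken by the lexicographically smallest cluster
  pair, where a cluster is labelled by its smallest member accession.
  This makes trees bit-reproducible; clade-level results should not
  (and in the planted-truth tests do not) depend on tie order.
* **Negative limbs** (possible in NJ) are clamped to 0 after
  estimation and recorded on the tree; downstream costs must be
  non-negative.
* On additive matrices the construction is exact: leaf-to-leaf path
  sums reproduce the input within 1e-9 (measured ~1e-15).

### Low-cost clade search

Every internal node of the rooted tree is examined (exhaustive scan —
cheap at orthogroup scale). When a node's leaves contain several
sequences from one proteome (isoforms of a gene co-cluster), the
member minimizing the summed gap distance to the other proteomes'
leaves is kept; ties prefer canonical, then reviewed, then the
smallest accession. A resolved set becomes a candidate if it spans at
least `min_proteomes` (default 3, the same floor applied to whole
orthogroups) distinct proteomes and its **cost** — defined as the
*maximum* pairwise gap distance within the set — is at most
`cost_threshold` (default 0.02, inclusive). The maximum, rather than
a mean or a branch-length sum, is chosen so that cost 0 is literally
equivalent to "every pair aligns without gaps", and so the threshold
certifies every pair, not an average. Nested candidates are
deduplicated keeping the largest proteome coverage, then the lowest
cost.

With dedup by coverage, raising the cost threshold can
replace a candidate by a strictly larger one at an ancestral node; the
monotonicity guarantee is therefore stated (and tested) as coverage
monotonicity, while lowering `min_proteomes` grows the candidate set
exactly.

### Ranking, selection, policy

Candidates in an orthogroup are ordered lexicographically by
(i) cost ascending, (ii) proteome count descending, (iii) number of
current-canonical members descending, (iv) number of reviewed
human/mouse members descending, (v) length penalty ascending, with the
smallest member accession as a final deterministic tie-break. The
length penalty is |median(member lengths) − median(canonical lengths)|
/ median(canonical lengths), computed over the orthogroup's current
canonicals; the strict lexicographic order is a parameter-free
reading of "ranked by (i)…(v)" — a weighted score could be slotted in
later, and the planted-truth tests are designed so winners dominate on
criterion (i) and are insensitive to this choice.

Selection is greedy: best candidate first, then any further candidate
whose Gene-Centric gene groups are disjoint from everything selected,
so one orthogroup can yield several clades covering different gene
sets. Each member of a selected clade yields one suggestion:
`confirm` when the member is its gene group's current canonical,
otherwise `propose_change` naming the member's base accession — unless
the current canonical is reviewed (Swiss-Prot), in which case the row
is `flag_reviewed`: reviewed canonicals are never changed
automatically, only queued for curators.

Run accounting classifies each orthogroup as skipped (<3 proteomes),
no-low-cost, confirmed (all selected clades contain only current
canonicals), proposed (all selected clades propose ≥1 change), or
both (a mix across clades); the categories partition the input, which
is asserted on every run. In the summary counts, canonical members of
*proposing* clades are not counted as confirmed canonicals — only
members of all-confirm clades are.

### Gap statistics and BTOP

Pairwise search results arrive as 12-column m8 tables plus a BTOP
column (a 15-column dialect with query/subject lengths is also read;
without it query lengths are unknown and such hits cannot pass the
best-hit filter). BTOP decoding yields identity runs, mismatches and
side-attributed gap events (adjacent same-side gap columns merge);
re-encoding is exact for canonical strings. The best-hit filter keeps,
per query, the lowest-E hit (ties: bit score, then subject accession)
with query length strictly >100 and E strictly <1e-6. Distributions
are reported per half-open identity bin [lo, hi), default width 1
over [0, 101) so 100% identity is kept, and the ">90% identical"
subset is strict.

### Orthogroup extension

A target-proteome sequence inherits the orthogroup of its best
qualifying human hit: identity ≥50% (inclusive) and coverage of the
human sequence >75% (exclusive); both boundaries are configurable.
Coverage is alignment length minus gap columns on the human side of
the alignment, divided by the human sequence length — dashes in the
human row consume no human residues, whichever of query/subject the
human sequence is (the caller declares the orientation). Best =
highest identity, ties by coverage then human accession, making the
result independent of hit order.

## Synthetic data: what it emulates, what it does not

The generator builds orthogroups from exon blocks: a core of 4–11
shared blocks of 15–60 aa defines the biologically consistent (truth)
isoform, which evolves across proteomes by substitutions only (default
rate 0.05 per residue per proteome), so the truth clade has gap cost
exactly 0 by construction. In a configurable fraction of proteomes
(default 0.3, applied as an exact count) the database canonical is
instead a decoy with a proteome-specific N-terminal extension of
30–80 aa — the longest-isoform artifact — while the truth isoform
remains in the gene group under its own accession. Extensions differ
between proteomes in residues and length, so decoys never form a
low-cost clade with each other; block sizes guarantee every one-sided
block gap exceeds the 0.02 threshold at the sequence lengths
generated. Non-decoy proteomes optionally carry an exon-skip isoform
as a distractor; skip choices are proteome-indexed so no three
proteomes share one. Human and mouse truth canonicals are marked
reviewed for realism (and to exercise ranking criterion (iv));
decoy canonicals are unreviewed unless the `reviewed_decoys` switch is
used to exercise the flag-reviewed policy. Because blocks define
alignment columns directly, the generator emits the true MSA itself;
desk-scale runs and tests never invoke an external aligner (the
aligner interface is pluggable and validated against a deterministic
stub).

Pair-search simulation plants exact fractions: of `n_alignments`
(default 500), `round(n · frac_gt90)` are strictly >90% identical,
and of those `round(· frac_gap_ge5)` carry one gap of 5–30 residues;
other alignments may carry sub-threshold 1–4 aa gaps. Every query is
unique and strongly significant, so the best-hit filter keeps all of
them and the planted fractions are recovered exactly.

What passing these tests shows: the arithmetic, the tree construction,
the clade search, the ranking policy and the bookkeeping are correct,
and the method recovers planted isoform-selection artifacts perfectly
when the modelled structure (gap-free truth clades, large decoy gaps)
holds. What it does not show: behaviour on real alignments, where
aligner errors, genuine lineage-specific indels near the 0.02
threshold, fragmented gene models and wrong orthology assignments
blur the planted dichotomy; real-data yields will always include
no-low-cost and borderline families that the generator does not
emulate.

## Parameters

| parameter | default | meaning |
|---|---|---|
| `cost_threshold` | 0.02 | max pairwise gap distance accepted in a clade (inclusive); ~1 gapped residue per 50 aligned |
| `min_proteomes` | 3 | floor on distinct proteomes, for orthogroups and clades alike |
| `min_identity` | 0.50 | orthogroup-inheritance identity floor (inclusive) |
| `min_coverage` | 0.75 | orthogroup-inheritance human-coverage floor (exclusive) |
| `min_query_len` | 100 | best-hit filter keeps queries strictly longer than this |
| `max_evalue` | 1e-6 | best-hit filter significance bound (strict) |
| `substitution_rate` | 0.05 | generator: per-residue substitution probability per proteome |
| `decoy_fraction` | 0.3 | generator: fraction of proteomes with a decoy canonical (exact count) |

Problem sizes used by the test suite and the acceptance script — 1000
random MSAs for the distance oracle, 200 matrices per NJ check, 200
small orthogroups for brute-force clade equivalence, 500 six-proteome
orthogroups for planted-truth recovery, 500 planted pair alignments —
keep every check exhaustive at small scale while the whole suite runs
in seconds on one core.

## Known limitations

* The cost of a clade is its worst pair; a single borderline member
  vetoes an otherwise perfect clade. This is deliberate
  (conservative) but means large clades are harder to accept.
* Ranking is strict lexicographic; no trade-off between, say, one
  extra proteome and a slightly higher cost is possible.
* Duplicate-proteome resolution keeps exactly one member per proteome
  per tree node; co-orthologs (genuine within-proteome duplications)
  are not modelled separately from isoforms.
* The external-aligner path shells out to a user-supplied command and
  is validated structurally, not scientifically; alignment quality is
  inherited from the aligner.
* Orthogroup inheritance uses best-qualifying-hit only; no
  reciprocal-best or synteny evidence.
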