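# orthocanon

Canonical-isoform selection for reference proteomes via gap-distance
trees of orthologous sequences.

## The problem

Reference proteomes for organisms with alternative splicing distribute
one *canonical* protein per gene. For unreviewed (TrEMBL) entries the
canonical has historically been the longest isoform in the gene's
Gene-Centric group — a rule that picks inconsistently across species
and produces >90%-identical ortholog alignments with gaps hundreds of
residues long, which is biologically implausible: in bacteria and
yeast, which essentially lack isoforms, such alignments almost never
contain gaps ≥5 residues. Those artifactual gaps degrade similarity
searching, domain annotation, and everything built on canonical sets.

`orthocanon` addresses this with a tree-based strategy over
orthogroups. For every orthogroup (a Panther-style family of
orthologous genes across proteomes) it:

1. gathers all canonical **and** isoform sequences through the
   Gene-Centric mapping,
2. builds (or loads) a multiple sequence alignment,
3. computes a **gap-only distance** for every pair of rows: the number
   of alignment columns gapped in exactly one of the two sequences,
   divided by the number of columns with a residue in at least one —
   substitutions cost nothing, and terminal gaps count like internal
   ones, so d(i,j) = 0 ⇔ the pair aligns end-to-end without gaps,
4. builds a neighbor-joining tree from that matrix (Saitou–Nei Q
   criterion, deterministic tie-breaks),
5. scans the tree for **low-cost clades**: ≤1 sequence per proteome,
   spanning ≥3 proteomes, with cost = max pairwise gap distance
   ≤ 0.02,
6. ranks candidates by (cost, proteome coverage, canonical members,
   reviewed human/mouse members, length consistency), greedily selects
   candidates over disjoint Gene-Centric gene sets, and emits one
   suggestion per clade member: `confirm` if the member is already
   canonical, `propose_change` otherwise — unless the current
   canonical is reviewed (Swiss-Prot), which is never changed
   automatically, only flagged (`flag_reviewed`).

Two companion modules cover the surrounding analyses: `gapstats`
decodes BTOP alignment encodings from m8-style tabular searches and
summarizes identity/gap-length distributions per proteome pair, and
`orthomap` extends human-anchored orthogroup assignments to further
proteomes (≥50% identity, aligned over >75% of the human length).
A first-class synthetic-data generator (`simulate`) builds
exon-block orthogroups with planted decoy canonicals and pair-search
files with planted gap fractions, so the whole method is testable
without any downloads.

## Worked example

Simulate 8 orthogroups across 6 mammalian proteomes, a quarter of them
carrying decoy canonicals with N-terminal extensions, then run the
pipeline on the generated files:

```sh
orthocanon simulate --seed 3 --out demo --n-orthogroups 8 --decoy-group-fraction 0.25
orthocanon run \
    --fasta demo/fasta/HUMAN.fasta --fasta demo/fasta/MOUSE.fasta \
    --fasta demo/fasta/RAT.fasta   --fasta demo/fasta/BOVIN.fasta \
    --fasta demo/fasta/GORGO.fasta --fasta demo/fasta/MONDO.fasta \
    --gene-centric demo/gene_centric.tsv --orthogroups demo/orthogroups.tsv \
    --prealigned demo/prealigned --out demo_out
```

which prints

```
groups=8 skipped=0 no_low_cost=0 confirmed=6 proposed=2 both=0 proposed_changes=4
```

— 8 orthogroups analyzed, 6 whose best clade contains only current
canonicals (confirmed), 2 where a cheaper isoform clade exists
(proposed), and 4 individual canonical replacements. The per-member
rows land in `demo_out/suggestions.csv`:

```
orthogroup_id,proteome_id,gene_group_id,old_canonical,new_canonical,action,clade_cost,clade_size,rank
OG0000:SF1,BOVIN,GC0000_BOVIN,Q000003,X000003,propose_change,0,6,1
OG0000:SF1,GORGO,GC0000_GORGO,Q000004,Q000004,confirm,0,6,1
...
```

The first row proposes replacing the cow canonical `Q000003` (a decoy
with a planted N-terminal extension) by isoform accession `X000003`,
whose sequence sits in the zero-cost 6-proteome clade; the second
confirms the gorilla canonical, already in that clade. The pair-level
diagnostics run the same way:

```sh
orthocanon simulate --seed 3 --out demo --n-orthogroups 8 --pair-hits
orthocanon gapstats demo/pair_hits.m8btop --out demo_out/gapstats.csv
# alignments=500 gt90=250 frac_gt90=0.5000 gap_ge5_in_gt90=0.2000
```

recovering exactly the planted 50% of >90%-identical alignments and
the planted 20% of those with a gap ≥5 residues.

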