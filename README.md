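# phagealign

Partial-order multiple whole-genome alignment of functionally collinear
bacteriophage genomes.

## The problem

Tailed-phage genomes are mosaics.  Related strains keep their biological
functions in (nearly) the same genomic order — lysogeny, DNA assembly,
head, tail, lysis — but a given function may be carried by *variants*
with no detectable sequence similarity at all.  Score-based whole-genome
aligners read that lack of similarity as rearrangement or loss and
produce misleading alignments; dot plots and clustering stay
qualitative.  `phagealign` instead aligns sets of 2–~30 phage genomes
(typically 30–60 kb) using nothing but the equality relation, and keeps
the result as a partial order rather than forcing a linear layout.

## The model

Let 𝒢 = {G₁, …, Gₙ} be the genomes and ℳ a set of maximal exact
matches (MEMs) of length ≥ *m* between genome pairs.  A match
M = {G[s..t], H[u..v]} asserts the equalities G[s]=H[u], …, G[t]=H[v].

- **Columns.**  Positions p<sub>ij</sub> are *equivalent* when linked by
  a chain of match assertions; each equivalence class ⟦p<sub>ij</sub>⟧
  is a column of the multiple alignment, built with Union-Find.  A
  column is *valid* if it holds at most one position per genome;
  invalid columns (duplications, tandem repeats) are split into
  singletons.
- **Column graph.**  Columns are connected by per-genome successor
  edges.  𝒢 is *functionally collinear* w.r.t. ℳ exactly when this
  graph is acyclic; cycles are reported as strongly connected
  components with the genomic intervals involved (rearrangement
  evidence).  *m* is the method's only substantive parameter: it is
  raised, starting from 15, to the smallest value making the graph
  acyclic.
- **Alignment graph.**  Runs of consecutive columns with identical
  support merge into *exact* alignment vertices.  A vertex pair (U, V)
  with equal support whose in-between vertices all have support ⊆ sp(V)
  and whose spanning segments have equal length *contracts* into a
  gapless alignment vertex annotated with its percent identity (the
  fraction of columns where every supported genome agrees; displayed
  truncated, so 167/169 shows as 98 %).
- **Anchors.**  Vertices supported by all n genomes form the ordered
  *backbone*; the region between two anchors can be re-aligned on its
  own, usually at a much smaller *m*.  Genomes deposited with arbitrary
  circular start points are *normalized* first: every genome is rotated
  so the longest sequence shared by the whole set starts at position 1.

## Worked example

Simulate a 4-genome mosaic set (5 modules, 2 planted 250 bp universal
blocks), then align it:

```text
$ phagealign simulate --seed 11 --genomes 4 --modules 5 --universal 250,250 --out demo
INFO simulated 4 genomes, N_l=13035 bp; wrote demo.fasta and demo.truth.tsv

$ phagealign align demo.fasta --auto-m --out demo_aln
INFO auto-normalization applied; offsets: {'g0': 2088, 'g1': 1512, 'g2': 2278, 'g3': 1737}
INFO n=4 genomes, N_l=13035 bp
INFO m=15, matches=90, M_l=7395 bp
INFO vertices: 216 before contraction, 66 after, 24 aligning >=2 sequences, 15 contracted
INFO wrote demo_aln.json and demo_aln.dot
```

Reading the log: the four simulated genomes were deposited with
different start points, so they were rotated (`offsets`) to begin at
their longest shared sequence; 90 pairwise exact matches of ≥ 15 bp
(7 395 bp total) produced an acyclic column graph at the default
m = 15; its 216 exact vertices condensed to 66, of which 24 align two
or more genomes and 15 are contracted gapless alignments.  The DOT
output labels each vertex with per-genome coordinates, length and
truncated identity:

```text
v0 [label="g0:1-251\ng1:1-251\ng2:1-251\ng3:1-251\nlen=251 id=100%"];
v6 [label="g0:452-809\ng2:454-811\nlen=358 id=98%"];
```

`v0` is the planted universal block (an anchor: all four genomes),
sitting at position 1 in every genome after normalization; `v6` is a
contracted gapless alignment of two genomes, 358 bp at 98 % identity.
Render with `dot -Tsvg demo_aln.dot > demo_aln.svg`, list the backbone
with `phagealign anchors`, and re-align between two anchors with
`phagealign zoom --from 0 --to 1`.  Non-collinear input exits with
code 3 and prints the offending strongly connected components.

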