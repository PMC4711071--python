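# Methods

## Model and procedure

The aligner treats a multiple alignment as a set-theoretic object
derived solely from exact matches.  Given genomes 𝒢 = {G₁,…,Gₙ} and the
set ℳ of maximal exact matches (MEMs) of length ≥ m between all genome
pairs (forward strand, inter-genome only), the pipeline is:

1. **Columns.**  Each match asserts per-base equalities; the columns
   are the equivalence classes of genome positions under the transitive
   closure of those assertions (Union-Find with union-by-size and path
   halving).  Unmatched positions are singleton columns.
2. **Validity splitting.**  A column with two or more positions in one
   genome — the footprint of duplications or overlapping tandem-repeat
   matches — cannot take part in a collinear alignment.  The entire
   offending column is split into singletons.  This is deliberately
   conservative: it discards otherwise-consistent pairings carried by
   the same column, but it never invents homology and it makes the
   splitting rule order-independent and idempotent.
3. **Collinearity.**  The column graph links columns by per-genome
   positional adjacency.  The genome set is functionally collinear iff
   this graph is acyclic; otherwise every nontrivial strongly connected
   component is reported with the per-genome min/max positions of its
   columns as rearrangement evidence, and no alignment is produced.
   Aligning through rearrangements is out of scope by design.
4. **Merging.**  Maximal runs of consecutive columns with identical
   support become *exact* vertices (all rows identical).  A run merges
   exactly when every position of a column steps into the same
   successor column and the two columns have equal size; this is
   order-independent.
5. **Contraction.**  A pair (U, V) of vertices is contractible when U
   precedes V, sp(U) = sp(V), every vertex between them has support
   included in sp(V), and the per-genome segments spanning U..V all
   have the same length.  Maximal chains closed under contractible
   pairs merge into *contracted* vertices: gapless alignments whose
   identity is the exact fraction of columns in which all supported
   genomes carry the same base.
6. **Anchors and zooming.**  Vertices supported by every genome are
   anchors; ordered by the partial order they form the backbone.
   Consecutive anchors with equal spanning length in every genome bound
   a gapless region (boxed in the anchor view).  The region strictly
   between two anchors can be extracted and re-aligned independently,
   by default at the smallest acyclic m starting from 15.

"Between U and V" is read as "on any directed path from U to V".
Because every vertex on such a path is pinned to the per-genome
intervals it occupies (anything else would close a cycle), the check
reduces to walking each supported genome's path from U to V, which is
what the implementation does; the test oracle instead computes the
between-set literally from DFS reachability, and the two agree on every
tested instance.

## Parameters

- **m (minimum match length), default 15.**  The only substantive
  parameter.  Small m creates spurious columns and, through random
  repeats, cycles; the standard protocol raises m one unit at a time
  (ceiling 500) until the column graph is acyclic, and this minimal
  acyclic m is what `--auto-m` computes.  On a planted transposed block
  of length k this search returns exactly k+1.  Large fixed m (e.g.
  175) is useful for compact anchor views of many genomes.
- **Mask threshold, default 20 bp.**  Display-only: vertices shorter
  than this are hidden in DOT output, and any edge hiding ≥ 1 bp
  (masked vertices or skipped bases) is dotted and labeled with the
  hidden count, so base-pair accounting survives masking.
- **Contraction cap, default off.**  Without an upper bound a contracted
  vertex can in principle join same-length but unrelated sequences; a
  cap is exposed (`contract(..., max_length=...)`) but disabled by
  default, as phage data behave well in this regard.
- **Normalization, default auto.**  Phage genomes are circular in part
  of their life cycle; database records start at arbitrary points.
  Normalization finds the longest substring common to all genomes
  (each treated as circular, search capped at the shortest genome
  length) and rotates every genome so it starts there; ties are broken
  by the smallest start in the first genome, which makes the procedure
  deterministic and idempotent.  In `auto` mode rotation is applied
  when that substring does not start within 1 kb of position 1 in every
  genome, or retried after the column graph turns out cyclic; the exact
  trigger used by interactive tools is undocumented, so this heuristic
  is a documented stand-in.  Reverse-complement re-orientation is not
  performed: input genomes must be on the same strand.

Coordinates are 1-based inclusive everywhere user-facing; internal
indexing is 0-based half-open.  `N` is accepted on input but never
matches anything (including another `N`), so masked regions produce no
columns and count against identity.

## Identity display

Identity percentages are floored, not rounded: a 169-column contracted
vertex containing two single-nucleotide differences has identity
167/169 = 98.8 % and displays as 98 %.  The exact rational is kept on
the vertex and in the JSON output.

## MEM enumeration

MEMs are found by exact seed-and-extend: every MEM of length ≥ m
contains a k-mer seed (k = min(m, 21)); seeds are indexed by hashing,
extended maximally in both directions, and de-duplicated per diagonal
(two seeds inside one MEM extend to the same MEM, and no seed can cross
the mismatch that ends one).  This enumerates exactly the set of
maximal exact matches — verified against a quadratic dynamic-programming
finder on every tested instance.  Matches can also be imported/exported
as TSV so an external MEM finder can be substituted.  Note that MEM
maximality does not depend on m, so the minimal-m search filters one
match set instead of recomputing it.

## Synthetic mosaic generator

The generator emulates the modular structure of tailed-phage genomes:
`n_modules` functional modules in fixed order, each with a pool of
`variants_per_module` variant sequences drawn independently and
uniformly over {A,C,G,T} (variants of a module share no ancestry, so
cross-variant sequence similarity is only what chance provides); each
genome picks one variant per module independently, emulating horizontal
exchange, so variant groupings can switch from module to module.
Universal blocks planted identically in all genomes provide ground-truth
anchors.  Per-genome substitutions and short (1–5 bp) indels are
applied to modules and linkers.  Defaults — 6 genomes, 8 modules, 2
variants, 300–800 bp modules, 20–100 bp per-genome random linkers, 1 %
substitutions, 0.1 % indels, three 300 bp universal blocks — give
genomes of roughly 5–6 kb, a deliberately scaled-down mosaic with the
same structure as a full phage genome.

Deliberate simplifications, which bound what passing tests show about
real data:

- Planted universal/transposed/duplicated blocks are never mutated, so
  ground-truth intervals stay exact; real anchors are degraded by
  mutation and can fragment.
- Linkers are independent random sequences per genome (unalignable
  spacers); real intergenic regions are homologous and partially
  alignable.
- The bases flanking planted transposition and duplication blocks are
  forced to differ between the rearranged genome and the others, so a
  planted block of length k yields matches of exactly k; without this
  guard, chance 1-bp extensions would make the minimal acyclic m
  k+2 on a fraction of seeds.
- No phylogeny, no GC bias, no gene gain/loss; capsid size constraints
  appear only as bounded total length.

Chance k-mer sharing is real, however: at these genome sizes random
15-mers occasionally recur across genomes, which is precisely why the
minimal-acyclic-m protocol exists and is what the recovery tests run.

## Numerical and determinism notes

- All randomness flows from explicit integer seeds
  (`numpy.random.default_rng`); identical spec+seed yields identical
  FASTA bytes.
- Vertex order, topological tie-breaks (smallest first-genome
  coordinate), column numbering, DOT and JSON output are all
  deterministic; DOT output is byte-identical across runs.
- Identities are exact `fractions.Fraction` values; nothing in the
  pipeline uses floating point except reporting.
- Conservation — per genome, vertex lengths plus skipped bp equal the
  genome (or zoomed span) length — is asserted on every graph build.

## Known limitations

- Rearranged genome sets are detected and reported, not aligned.
- Same-strand input only; no reverse-complement matches or
  re-orientation.
- The quadratic reference implementation and the oracle-equivalence
  tests run on scaled-down instances (2–4 genomes, ≤ 2 kb); the
  production path has no such limit but its complexity is dominated by
  the per-base Union-Find pass, which is pure Python and so comfortable
  for tens-of-kb phage genomes rather than megabase chromosomes.
- Published-dataset statistics can only be verified after the user
  downloads the GenBank records (see `data/README.md`); one printed
  total for the trimmed Myco6 set is ambiguous by a few bp in the
  source, and the corresponding check tolerates that.
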