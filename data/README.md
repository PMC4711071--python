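# Published phage datasets (user-supplied)

The test `tests/test_acceptance.py::test_published_dataset_statistics`
and its companion reproduce published alignment statistics on three
sets of *Staphylococcus aureus* and *Mycobacterium* phage genomes.
The sequences are not redistributed here; download them from GenBank
and place the multi-FASTA files in this directory as `staph6.fasta`,
`myco6.fasta` and `myco29.fasta`.  Record ids must match the first
column of the corresponding `*.regions.tsv` file (rename the FASTA
headers from accession to phage name, or edit the TSVs).

Accessions:

| dataset | records (name = accession) |
|---|---|
| staph6 | 85=AY954953, 88=AY954966, 92=AY954967, 29=AY954964, 187=AY954950, 53=AY954952 |
| staph4 | phiETA3=NC_008799, phiNM1=NC_008583, phiNM2=DQ530360, B236=KP893290 |
| myco6 | U2=AY500152, Alvin=KP027205, DD5=EU744252, BillKnuckles=JN699000, Perseus=JN572689, Dreamboat=JN660814 |
| myco29 | U2=AY500152, Doom=JN153085, Alvin=KP027205, BXB1=AF271693, Solon=EU826470, Bethlehem=AY500153, DD5=EU744252, Pinto=KJ690250, BillKnuckles=JN699000, KBG=EU744248, Lesedi=JF937100, Museum=JF937103, Violet=JN687951, Kugel=JN699016, MrGordo=JN020140, KSSJEB=JF937110, Switzer=JF937108, Perseus=JN572689, Dreamboat=JN660814, Seabiscuit=KJ194585, Trouble=KF024724, BPBiebs31=JF957057, Wheeler=KF416340, Graduation=KF560331, JC27=JF937099, Thor=KP027204, Aeneas=JQ809703, SarFire=KF024726, SkiPole=GU247132 |

One way to fetch a dataset (untested plumbing, needs network):

```sh
for acc in AY954953 AY954966 AY954967 AY954964 AY954950 AY954952; do
  curl -s "https://eutils.ncbi.nlm.nih.gov/entrez/eutils/efetch.fcgi?db=nuccore&id=${acc}&rettype=fasta&retmode=text"
done > staph6.fasta
```

Notes:

- The `*.regions.tsv` files carry the published trimming coordinates
  (`id<TAB>start<TAB>end`, 1-based inclusive).  The myco29 genomes are
  all trimmed to [1, 33000]; the myco6 genomes to [75, end].
- The published total length for myco6 (274 292 bp) differs by 1 bp
  from the inclusive reading of its printed coordinates (274 293 bp);
  the source's end-point convention for that dataset cannot be pinned
  down, so the test tolerates a few bp there.
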