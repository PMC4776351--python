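# wgpscaf

Map-guided evaluation and scaffolding of draft genome assemblies using a
Whole Genome Profiling (WGP™) tag map and mate-pair sequencing data.

## The problem

Scaffolders driven only by paired reads lose consistency in repetitive or
low-coverage regions: they need several read pairs to trust a junction, so
poorly covered contigs stay unjoined, and repeats create ambiguous links. A
sequence-based physical map is an independent source of ordering
information. WGP maps order short sequence tags (~50 bp, flanking
restriction sites of a BAC library digest) within *BAC contigs*; each tag
`t(c, r)` carries its BAC contig `c` and a rank `r` — the mean rank of the
fingerprint-ordered BACs it occurs in, so ranks may be fractional and tied.

`wgpscaf` anchors a draft assembly on such a map and uses it two ways:

**Quality evaluation.** A scaffold `s((t1,p1),…,(tn,pn))` is described by
its uniquely aligned tags at positions `p1 ≤ … ≤ pn`. *Collinear segments*
are maximal runs of anchors whose ranks follow the map order (in either
direction; ties never break a run). Their lengths feed N50-style,
reference-free metrics: **An50** (50 % of the anchored assembly lies in
collinear segments ≥ An50 bp), **AnA50** (denominator: total assembly
size) and **AnG50** (denominator: estimated genome size), plus full
Anx/AnAx/AnGx curves for x = 1..100.

**Map-guided scaffolding.** Two anchored scaffolds form a *map-link* when
the BAC contig of the first one's last anchor equals that of the second
one's first anchor and the ranks satisfy `r(last_i) ≤ r(first_j)`.
Map-links are validated with mate pairs whose mates map to different
scaffolds; the gap is estimated naïvely from the library mean fragment
size μ and read length R:

    gap(+,+) = μ − pos1 − pos2 − 2R
    gap(+,−) = μ − (pos1 + R) − (len2 − pos2)
    gap(−,−) = μ − (len1 − pos1) − (len2 − pos2)
    gap(−,+) = μ − (len1 − pos1) − (pos2 + R)

The orientation class supported by the most pairs wins, and a link is kept
when the mean gap is at least `minGap` (−200 bp by default). One
supporting pair suffices — the point of map guidance is exactly that the
read-pair cutoff can be lowered without losing accuracy. Validated links
are written as a DistanceEst-style `.de` file and also merged internally
into super-scaffolds (FASTA + AGP v2.1).

A simulation module generates seeded synthetic genomes, WGP maps with
gamma-distributed rank occupancy (shape 1.07, scale 0.16), controlled map
errors (tags misplaced within their BAC contig, or moved to another
contig) and mate-pair fixtures, so the whole pipeline and its
error-robustness behaviour can be studied with no external data.

## Worked example

Simulate a small dataset and run the five stages end to end:

```sh
wgpscaf simulate --n-bac-contigs 1 --n-tags 400 --n-scaffolds 40 \
    --sigma 0 --seed 11 --out-dir demo
wgpscaf all --wgp-map demo/map.tsv --tag-bam demo/tags.sam \
    --mp-bam demo/pairs.sam --assembly demo/assembly.fasta \
    --mu 3000 --sigma 0 --read-length 100 --genome-size 200000 \
    --out-dir demo/out
```

The `map2qc` stage prints:

```
An50=4550	AnA50=4550	AnG50=4550
```

i.e. half of the anchored assembly sits in collinear segments of at least
4 550 bp (each 5 000 bp scaffold carries one segment spanning its ten tag
loci). The run log reports 39 map-links between the 40 scaffolds, all 39
validated by mate pairs, and `demo/out/scaffolds.fasta` contains one
super-scaffold of ~200 kb: N50 rises from 5 000 bp to 200 780 bp with zero
incorrect joins (`demo/out/scaffolds.agp` lists the joins and their
evidence).

Stages can equally be run one at a time (`wgp2map`, `map2qc`, `map2link`,
`pairs2links`, `links2scaf`) on the plain-text intermediates, and the `.de`
file can be fed to the SGA scaffolder instead of the built-in merger.

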