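# multiguide

Design CRISPR–Cas9 guide RNAs with an **exactly controlled number of
genomic target sites**, confined to noncoding regions (introns and
transposable elements), and validate that target multiplicity across a
panel of genome assemblies.

Most guide-design tools minimize off-targets. This package does the
opposite, deliberately: it searches a genome for 20-nt protospacers that
occur at a chosen copy number (2, 4, 8, … up to dozens of sites), so
that a single guide can deliver a titrated dose of double-strand breaks
— for example, to probe how many concurrent DSBs a germ cell tolerates.
It is aimed at *Drosophila* (and other small-genome) genome engineers,
but nothing in it is organism-specific.

## The model

A candidate guide is a 20-nt sequence drawn from a random position inside
an intron or annotated transposon, starting with a 5′ G and followed by
an NGG PAM. A genomic site counts as a **hit** of a guide when

* the 12 bases adjacent to the PAM (the *seed*, or proximal block) match
  perfectly,
* the 8 bases furthest from the PAM (the *distal* block) carry at most
  2 mismatches, and
* an NGG PAM flanks the site 3′ of the protospacer.

A guide's **multiplicity** is its number of perfect (0-mismatch) hits.
A guide is *selected* only if every one of its hits is perfect, lies
fully inside the allowed intron/TE regions, sits on a configured
chromosome, and is at least 10 kb (configurable) from every other hit on
the same chromosome — mismatched, off-region, off-chromosome or
clustered hits reject the guide outright. Candidates containing simple
repeats (≥ 4 tandem copies of a 1–2 nt unit, e.g. AAAA or ACACACAC) are
excluded at the sampling stage, and per-chromosome draw counts are
multinomial with probabilities proportional to chromosome length.

Companion procedures implement the quantitation used to validate edited
genomes: diploid target counts across an assembly panel (twice the mean
haploid perfect-hit count), amplicon edited/unedited classification
around the cut site via end-gap-free alignment, read-depth coverage
(reads × 300 bp / span), TE-family copy number
(reads × 300 / (consensus length × coverage)), qPCR copy number
2^(reference CT − target CT), insertion-call support filtering with
coverage-frequency zygosity labels, and signed insertion-to-TSS
distances.

## Worked example

Generate a synthetic two-chromosome genome with gene models and TE
annotation, then run the full search:

```sh
multiguide simulate genome --length chr2:80000 --length chr3:40000 \
    --seed 7 --out-dir fixture

cat > run.ini <<EOF
[genome]
fasta = fixture/genome.fa
chromosomes = chr2,chr3

[regions]
gtf = fixture/genes.gtf
repeats = fixture/repeats.out

[selection]
n_candidates = 500
multiplicities = 1,2
out_prefix = results
EOF

multiguide scan --config run.ini --seed 11
```

prints

```
multiplicity 1: 202 selected guide(s)
multiplicity 2: 0 selected guide(s)
202 selected / 202 candidates; tables written to results.*
```

On a 120-kb random genome every accepted candidate is unique, so all
guides have multiplicity 1 and none reaches 2 — controlled higher
multiplicities require genuinely repeated sequence, which is exactly
what the planting simulator provides:

```sh
multiguide simulate plant --genome fixture/genome.fa \
    --repeats fixture/repeats.out --k 4 --spacing 2000 --decoy 0:2 \
    --seed 3 --out-dir planted
multiguide count --genome planted/planted.fa --guides planted/guide.fa
```

```
     guide_id             sequence  total_hits  multiplicity  near_miss_hits                                                 hit_coordinates
planted_guide GACCTGCCGGAGTTTCCGGG           5             4               1 chr2:57248:+;chr2:60436:-;chr2:69949:+;chr2:72014:-;chr3:8389:+
```

The guide planted at 4 perfect sites is recovered with multiplicity 4;
the planted 2-mismatch decoy appears as the one near-miss hit (counted,
but disqualifying for selection). `multiguide validate` re-counts guides
across assembly FASTAs and reports haploid counts, the diploid number
(2 × mean) and a concordance flag; `multiguide quant` exposes the
coverage, copy-number, insertion-filter and TSS tools. To check designed
guides against a real reference (e.g. dm6 plus its GTF/RepeatMasker
annotation), point `multiguide count`/`scan` at the downloaded files.

The `results.tsv` columns are guide id, sequence, selection status,
rejection reasons, total hits, per-chromosome hit counts and
`chrom:start:strand` hit coordinates; hits are also written as BED6 and
selected guides as FASTA.

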