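# strngs

Anchor-based short-tandem-repeat (STR) profiling from amplicon
next-generation-sequencing reads, for cell line authentication and
culture cross-contamination screening.

STR profiling identifies a cell line by the number of times a 2–6 bp
motif is repeated at a panel of polymorphic loci (the CODIS-derived
human set, or the mouse authentication set). `strngs` calls these repeat
numbers directly from amplicon deep-sequencing reads, replacing
fragment-length capillary electrophoresis: reads are counted per repeat
length, so the output is quantitative — stutter artifacts, microvariant
alleles (e.g. 13.2), per-allele copy number and minor contaminating
lines down to ~1:200 all become visible.

## The calling model

For each locus a nine-column definition supplies two flanking *anchor*
sequences, the repeat unit size `k`, a base-pair correction, and an
optional SNP rule. For a read `r` containing both anchors exactly once,
in order, the repeat number is

```
n = (d(r) − bp_modifier) / k
```

where `d(r)` is the distance in bp between the end of the start anchor
and the start of the end anchor, and `bp_modifier` removes fixed
non-repeat bases inside that span (anchors placed a few bases away from
the tract to dodge known SNPs, or fixed interruptions inside the tract,
as at D21S11). A non-zero remainder is reported as a partial repeat:
`n = 11` whole units plus 2 bp prints as `11.2`. When a locus's SNP rule
trigger (e.g. `TATCAATCATC` at D13S317, created by an A>T variant) is
found in the read, the configured increment (+1 repeat) is added — the
variant creates an extra repeat unit without changing the measured
distance. Both orientations of every read are scanned.

Per-locus read spectra are then classified: lengths at ≥10% of locus
reads are **alleles** (including partial-repeat microvariants), whole-
repeat lengths below 10% are **stutter** (PCR slippage, predominantly
one repeat shorter), and partial-repeat lengths below 10% are **noise**.
Allele read-count ratios are snapped to small-integer copy states
(1:1, 3:2, 2:1, 3:1) — a ~2:1 ratio between two alleles indicates three
copies of the locus. Minor-contributor detection uses *informative
alleles*: repeat lengths unique to the minor line's reference profile,
ideally one to two repeats **longer** than the major's so they cannot be
confused with the major's −1-repeat stutter.

A fully seeded read simulator (stutter, partial-repeat noise,
substitution errors, mixtures, truth tables) generates all test data;
bundled panels carry the published locus names and motifs with synthetic
placeholder flanks/anchors, and users supply their own nine-column table
for real amplicons.

## Worked example

Simulate a diploid sample, profile it, and compare it with itself:

```
$ cat simspec.json
{"panel": "builtin:human",
 "components": [{"name": "s", "weight": 1.0,
   "genotype": {"D8S1179": [["13", 1], ["14", 1]], "TH01": [["7", 2]]}}],
 "reads_per_locus": 2000,
 "stutter": {"stutter_prob": 0.03, "minus_one_weight": 0.9},
 "seed": 5}

$ strngs simulate --spec simspec.json --out sim/
# simulated 4000 reads (seed=5) to sim
$ strngs profile --in sim/reads.fastq --out prof/ --sample-name demo
# reads: total=4000 assigned=4000 unassigned=0 ambiguous=0 malformed=0
$ grep -E "^(locus|D8S1179|TH01)" prof/demo.profile.csv | cut -c1-60
locus,repeat_length,reads,percent,class,top_sequence
D8S1179,12,29,1.43,stutter,TCTATCTATCTATCTATCTATCTATCTATCTA
D8S1179,13,1000,49.46,allele,TCTATCTATCTATCTATCTATCTATCTATC
D8S1179,14,992,49.06,allele,TCTATCTATCTATCTATCTATCTATCTATCT
D8S1179,15,1,0.05,stutter,TCTATCTATCTATCTATCTATCTATCTATCTAT
TH01,6,54,2.73,stutter,AATGAATGAATGAATGAATGAATG
TH01,7,1920,97.07,allele,AATGAATGAATGAATGAATGAATGAATG
TH01,8,4,0.20,stutter,AATGAATGAATGAATGAATGAATGAATGAATG
```

The sample is heterozygous 13/14 at D8S1179 (two allele classes near
50% each, flanked by low-frequency −1/+1 stutter) and homozygous 7 at
TH01, with ~97% of reads on the parent allele. `strngs compare --a prof/demo.profile.json --b prof/demo.profile.json
--out conc.json` reports `matched at 18 of 18 loci`; `strngs mixture`
takes a mixed-sample FASTQ plus two reference profiles and reports
informative-allele fractions, a pooled minor-fraction estimate with a
binomial confidence interval, and a detected / not-detected decision.

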