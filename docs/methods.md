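# Methods

## Repeat-length calling

A locus is defined by two anchor sequences flanking the repeat tract, a
repeat unit size `k` (2–6 bp), a base-pair correction `bp_modifier ≥ 0`,
and an optional SNP rule. Calling a read:

1. Search the read for both anchors; if neither orientation yields both,
   try the reverse complement. Matching is exact (`str.find`); an anchor
   occurring more than once in the searched orientation discards the
   read as *ambiguous*, which is tallied separately from a plain
   no-call. `N` bases never match.
2. The span is **exclusive**: the bases strictly between the last base
   of the start anchor and the first base of the end anchor. This
   convention is used consistently by the caller, the locus validator
   and the simulator; `bp_modifier` counts the fixed non-repeat bases
   inside that span (bases between an offset anchor and the tract, plus
   any fixed interruption or termination sequence).
3. `corrected = span − bp_modifier`. A negative value discards the read
   as *malformed*. Otherwise `divmod(corrected, k)` gives whole repeats
   plus a remainder in `[0, k)`, reported as `n` or `n.r` (`11.2` = 11
   units + 2 bp).
4. If the locus has a SNP rule and its trigger occurs anywhere in the
   oriented read, the rule's increment is added to the whole-repeat
   count. This models variants (D13S317 A>T) that create an extra
   repeat unit at the tract boundary without changing the inter-anchor
   distance; the trigger sequence itself spans the variant base, so
   only variant reads carry it.

Base qualities are never used in calling; an optional mean-quality read
filter and an optional ≤1-mismatch anchor mode exist but are off by
default, because tolerant matching changes stutter/noise statistics.
Mates of a pair are scanned independently; a locus covered by both mates
is counted twice, which leaves all percentage-based quantities unbiased
when coverage is uniform.

In multiplexed pools each read is scanned against every panel locus:
exactly one calling locus → assigned; none → unassigned; several →
ambiguous. Assigned + unassigned + ambiguous + malformed = total, always.

## Classification and genotypes

Per locus, read counts over repeat lengths form the spectrum. With the
allele threshold `allele_min_frac` (default 0.10, from the observation
that stutter stays below ~10% of locus reads under optimized PCR):

* frequency ≥ threshold → **allele** — including partial-repeat
  lengths, since genuine microvariant alleles (13.2) exist;
* whole-repeat length below threshold → **stutter**;
* partial-repeat length below threshold → **noise**.

A profile where nothing reaches the threshold is flagged `no allele`;
fewer than `min_reads` (default 100) locus reads flags `low-coverage`;
an empty locus yields a dropout-suspect genotype. Where the threshold
rule is genuinely underdetermined (a partial length between ~5% and
10%), this package always applies the 10% cut — one consistent reading,
stated here as the package's rule.

Allele fractions are renormalized over allele reads, sorted by count
(ties by ascending length, for determinism), and capped at four alleles.
With ≥2 alleles the top-two read-count ratio is compared against the
candidate copy states {1:1, 3:2, 2:1, 3:1}; the nearest candidate is
reported when its ratio is within ±0.2 of the observed ratio, otherwise
the copy state is undetermined and the genotype flagged `imbalance`.
The candidate set is deliberately small: read depth supports resolving
only low-integer copy configurations (e.g. ~2:1 ⇒ three copies).

Amelogenin has no repeat motif; it is folded into the same engine by
treating the 6-bp X/Y amplicon-length difference as the "repeat size":
the X form spans 0 extra bases (call 0 → category X), the Y form 6
(call 1 → Y). The category map lives in the notes column
(`categories=0:X,1:Y`) so the nine-column table round-trips bit-exactly.

Profile concordance counts a locus as matched iff the two allele
repeat-length sets are equal; it is symmetric and reflexively perfect.

## Mixture detection

Given reference profiles of a major and a minor line, the *informative
alleles* are minor alleles absent from the major's allele set at the
same locus, annotated with the signed bp offset to the nearest major
allele. An informative allele at exactly −1 repeat of a major allele is
flagged stutter-colliding and excluded from estimation and detection by
default, because the major's −1 stutter occupies the same length class.
Offsets of +1/+2 repeats are the preferred markers.

In the mixed sample the **unclassified** spectra are used (sub-threshold
lengths must stay visible). The pooled informative read fraction is
divided by the read-weighted mean allele *dose* — a heterozygous minor
carries each informative allele on one of two chromosomes, dose 0.5 —
to give the minor genome-fraction estimate; the 95% interval is exact
binomial (Clopper–Pearson) on the pooled count, scaled the same way.

Detection: the minor is called *detected* iff at least one
non-colliding informative allele has read fraction ≥ `min_frac`
(default 0.002) and read count ≥ `min_reads` (default 10). These
thresholds were chosen once so that, under the declared simulator noise
model at 100,000 reads per locus, the detection boundary falls between
1:200 (expected informative-allele fraction ≈ 0.5/201 ≈ 0.0025) and
1:1000 (≈ 0.0005) — the sensitivity boundary the method is designed to
achieve; they are not re-derived from data at run time.

## The simulator

`simulate` emulates amplicon deep sequencing: each read draws a
contributing genome by mixing weight, a locus uniformly, and an allele
by copy-number fraction, then rebuilds the amplicon from the locus
reference (flanks, anchor-to-tract prefix, repeat tract, termination
suffix). Error processes, applied in order:

* **stutter** (`stutter_prob`, default scenario values 0.03–0.05): the
  whole-repeat count shifts by −1 with `minus_one_weight` (default 0.8;
  stutter is predominantly one repeat shorter), remainder split evenly
  over +1 and −2. The shift distribution is a modeling choice — real
  data constrain only the predominance of −1 — and is fully
  parameterizable; mixture-sensitivity scenarios use weight 1.0 (all
  stutter at −1).
* **partial-repeat noise** (`partial_noise_prob`): a uniform 1..k−1 bp
  deletion in the tract, producing the `n.r` noise class.
* **substitutions** (`substitution_rate`): per-base errors anywhere in
  the read; they never change tract length but can destroy an anchor
  and make the read uncallable — as in real data, where such reads
  simply drop out of the locus tally.

Boundary clamping (a shift or deletion that would go below zero leaves
the read unchanged) is mirrored exactly by the analytic
`expected_spectrum`, so empirical call spectra converge to it (total
variation < 0.01 at 100,000 reads). Emitted FASTQ uses uniform Q40
symbols ('I') since calling ignores quality; reads are full amplicons
(~180 bp for the bundled loci) unless a read length truncates them.
Everything is reproducible byte-for-byte from the `SimSpec` seed, and a
truth table (read id, component, locus, true and emitted length, event)
reconciles with the FASTQ record-for-record.

What the simulator does **not** model: position-dependent Illumina
error profiles and quality scores, indels outside the tract, PCR
chimeras, locus-to-locus amplification bias, and stutter rates that
grow with repeat number. Passing tests therefore demonstrate the
correctness of the calling/classification/detection logic under the
declared generative model, not performance on any particular chemistry.

## Bundled panels

The human (18 loci) and mouse (15 loci) panels carry the published
locus names and plausible repeat motifs, but their reference sequences,
flanks and anchors are deterministic synthetic placeholders (fixed
seeds, motif-free flanks, 20-bp anchors) — sufficient for simulation,
testing and as a format example. Real genotyping requires a user table
with primer-derived anchors. D13S317 ships with the
`TATCAATCATC:+1` SNP rule and an 11-bp termination sequence inside its
span (`bp_modifier` 11); D21S11 models its 13 fixed interrupting bases
(`bp_modifier` 13); Amelogenin is the category locus described above.

## Problem sizes used in the bundled studies

* Mixture sensitivity: dilution series 1:1, 1:5, 1:10, 1:20, 1:100,
  1:200, 1:1000; one tetranucleotide locus; major 13/14, minor 15/16
  (informative offsets +1 and +2 repeats); 100,000 reads per locus;
  stutter 0.04 all at −1, substitutions 0.003, partial noise 0.0005;
  10 seeds per ratio; reference profiles from 20,000-read pure runs.
* Copy-ratio recovery: alleles 17 and 18 at 2:1 copies, 10,000
  error-free reads, 100 seeds; mean predominant:secondary read-count
  ratio reported with the 2:1 call rate.
* Spectrum convergence: 100,000 reads × 5 seeds; genotype recovery:
  four-locus diploid heterozygote, 1,000 reads per locus × 20 seeds.

## Known limitations

* Exact anchor matching makes calls sensitive to primer-proximal
  sequencing errors; such reads drop out rather than miscall.
* The copy-ratio candidate set cannot express states beyond 3:1.
* Mixture deconvolution of three or more contributors, likelihood-ratio
  interpretation, and population match statistics are out of scope.
* One SNP rule per locus; multiple boundary variants at one locus would
  need rule composition.
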