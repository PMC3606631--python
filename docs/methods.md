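# Methods

## The problem

The human KIR locus (chromosome 19q13.4) is a tandem array of highly
homologous natural-killer-cell receptor genes whose *gene content* varies
between chromosomes: whole genes are present or absent, duplicated, or fused
into hybrids. A chromosome's gene-content haplotype is well described as a
combination of one centromeric motif (cA01, cB01, cB02, or the rare cB03)
and one telomeric motif (tA01, tB01), separated by the 3DP1–2DL4 intergenic
recombination hotspot, plus recurrent *submotifs*: block deletions
(del3–del10), block insertions/duplications (ins3–ins5) and gene
hybridizations (hybd1). kirhap implements a complete in-silico version of a
sequence-based genotyping strategy for this system: multi-locus amplicon
assays read SNP peak heights, integer copy numbers are inferred from peak
ratios, diplotypes are resolved against a 37-haplotype catalog, population
haplotype and motif frequencies are estimated by maximum likelihood,
inter-gene linkage disequilibrium is mapped, and recombination breakpoints
are localized in aligned sequence triplets.

## Reference model

Sixteen canonical loci are ordered invariantly along the chromosome
(3DL3 first, 3DL2 last); 2DS3 and 2DS5 occupy one structural slot (the
"2DS35" block adjacent to 2DL5) and are collapsed to a merged 2DS35 count
at the catalog level, since they behave as allele sets of one locus for
haplotype structure. Hybrid pseudo-loci (2DL1/S1, 2DP1/L1, 3DL1/L2,
2DS2/S3) carry a 5' segment from one parent gene and a 3' segment from
another, with the crossover boundary at intron 3, intron 3, intron 5/exon 6
and intron 6 respectively; the boundary decides which parent's diagnostic
bases the hybrid presents to an assay amplifying a given exon.

The submotif grammar is implemented as ordered-list surgery on the motif
gene lists: each rule deletes or inserts a contiguous gene block or
replaces genes with a hybrid, and carries an applicability pattern (the
motif combinations it is observed on). Validation enforces contiguity,
per-haplotype copy bounds (no locus above two copies), and framework
conservation: 3DL3 is present on every haplotype, and every haplotype ends
in a 3DL2-derived segment — the full gene, the 3DL1/L2 fusion tail (the
fusion consumes the haplotype's own 3DL2), or the exons-1–3 remnant left
by the ~15 kb partial 3DL2 deletion carried by most del7 chromosomes
(modelled as the pseudo-locus `3DL2p`, invisible to every exon-4 assay).

### The packaged 37-haplotype catalog

The catalog is packaged fixture data (`data/haplotype_catalog.tsv`)
validated against the grammar at load time: every record's content vector
is recomputed from its `cen|tel[-submotif…]` name and must equal the
stored counts. The published motif-frequency table underdetermines the
exact membership of the 37 (its "associated region" column admits more
combinations than were observed), so membership is a transcription
decision of this package: six unaltered majors
({cA01,cB01,cB02} × {tA01,tB01}), cB03|tA01, the centromeric deletions
del3 (on cB01 and cB02), del4, del9, del10 (on cB01), hybd1 on all three
major centromeres with tA01, del5 (cA01/cB01 | tA01), del6
(cA01/cB02 | tB01), the del7/del8 family (cA01|tB01-del7 with and without
the partial 3DL2 deletion, cA01|tB01-del8, cB01|tB01-del7), ins3 and ins4
on four frames each, ins5 on four tA01 frames (cA01/cB01/cB02/cB03), and
two combined-alteration records (cB01|tA01-del3-hybd1,
cB02|tB01-del3-del6). A cB01|tB01-ins5 record is structurally excluded:
it would stack three 2DL5-2DS35 blocks on one chromosome, breaking the
two-copy haploid bound.

Frequencies: each submotif row's published percentage is divided among its
records (equally, except the del7/del8 family which uses the published
38/4/2 chromosome counts, with the remaining 11 of 55 on cB01|tB01-del7);
the remaining 93.40% major mass is spread over the six majors as the
product of centromeric and telomeric marginal weights (66.93 : 11.55 :
14.86 and 74.61 : 19.63, renormalized). The published major-motif rows
cannot be matched exactly on both sides simultaneously (their implied
denominators differ by a few chromosomes); a construction-time check
asserts the centromeric pure-major shares within 0.1 percentage points and
the intact-telomere shares within 0.25.

## Assay model

`data/assays.yaml` transcribes the 14 amplicon assays: amplified genes
(parenthesized genes amplify but carry no scored base), amplicon-local SNP
positions with the base each gene carries, primary/secondary diagnostic
targets, and peak-ratio copy-number rules. Bases not fixed by the source
table (the "other" allele at a diagnostic SNP) are reference-allele
assignments shared by the remaining genes. The two `3DL1-3DS1` assays'
"multiple SNPs" are modelled as one aggregate scored position each. The
2DS1:2DL1:2DS4 rule is three-way; the 2DL5:(2DL4+3DP1) rule is open-ended
("1 or multiple copies") and accepts any reduced small-integer ratio
verbatim.

Forward model: the height of base *b* at position *p* equals a per-assay
gain times the summed copy number of amplified loci carrying (*p*, *b*),
with hybrids folded into the parent whose segment spans the assay's exon.
Classification: a base is *present* at ≥5% of the position's tallest peak
(the detection floor; the source describes no threshold, and multiplicative
noise cannot cross this margin); among allowed classes matching the
presence pattern, the class minimizing the largest pairwise log-ratio
discrepancy wins, and the observation is *unclassifiable* if that minimum
exceeds 0.2 in natural log — half the gap between ln(3/2) and ln(1), the
tightest adjacent pair of published classes.

### Copy-number integration

Every assay observable — presence patterns and peak ratios — is invariant
to a global scaling of the copy vector, so absolute copy numbers are not
identifiable from the assays alone (a single haplotype and its homozygous
diplotype produce identical signatures). What pins the scale is the
haplotype structure rule set: a diploid vector must decompose into two
grammar-valid haplotypes. The solver therefore precomputes the assay
signature of every unordered pair drawn from the grammar universe (all 99
structurally valid haplotypes with up to two submotifs, not just the 37
observed ones, with every 2DS3/2DS5 realization of 2DS35 blocks) and
inverts observed signatures by table lookup. Noiseless observations hit an
exact entry; noisy observations are matched within their presence-pattern
bucket by minimizing the summed squared log discrepancy between observed
and expected peak ratios over all rules, with discretely violated rules
reported as discordances rather than silently absorbed. Presence calling
requires two independent diagnostic targets; a singly-confirmed locus is
flagged *provisional* only when the joint constraint system cannot explain
the signal (a fully concordant solution legitimately explains, e.g., the
single 2DS35-side target of a 2DS2/S3 hybrid). 3DL3 carries no assay
target at all and 2DL4/3DP1 are scored only jointly; these three loci are
documented exemptions of the coverage check, their counts being fixed by
the framework assumption and the block structure.

Some diplotypes are genuinely observationally ambiguous: gene content
cannot phase the centromeric against the telomeric half in double
heterozygotes (cA01|tA01 + cB01|tB01 versus cA01|tB01 + cB01|tA01 have
identical content), del7 and del8 share one content vector, and a few rare
copy-scale ties exist (e.g. {cA01|tA01, cB01|tA01-del9} versus
{cA01|tA01-del5, cB02|tA01-hybd1}). All observationally tied copy vectors
are reported (`GenotypeCall.alternatives`); 303 of the 703 catalog
diplotypes admit more than one consistent catalog pair. Ambiguity is
reported, never broken by a tie-rule — fabricating phase would bias every
downstream estimate — and the EM estimator is the principled consumer of
it.

## Diplotype resolution

`enumerate_pairs` matches a genotype against all unordered catalog pairs
in assay-observable coordinates (2DS35 collapsed; hybrids merged into the
parent they mimic at the scored exons; presence-only channels boolean),
deterministically ordered. `phase_with_rules` audits the surviving pairs
with the assignment rules — segregation of mutually exclusive genes
(2DL3 vs 2DS2-2DL2, 2DS1 vs 3DL1-2DS4), placement of the mobile
2DL5-2DS35 block from its flanking 2DP1-2DL1 / 3DS1-2DS1 copies, and the
strong-LD block audit — recording every applied rule in the resolution
trace; a pair failing a hard rule is removed with a trace entry.
Genotypes with provisional presence are excluded with an explicit status
rather than fuzzily matched.

For genotypes no catalog pair explains, `infer_novel` subtracts each
catalog haplotype that fits under the genotype and matches the residual
against the grammar universe (framework conservation, the
no-2DS2-2DL2-to-2DP1 rule, and block contiguity are enforced by the
grammar itself), ranking candidates by submotif edit distance to the
nearest catalog haplotype (default cap: 2 edits; beyond that the search
space grows combinatorially and the biological prior for multi-event
novelties is weak). Removing any single-submotif catalog record and
presenting a genotype that needs it reconstructs that record as the top
candidate at one edit.

## Population genetics

`em_frequencies` is the standard EM algorithm for multilocus haplotype
frequencies under Hardy-Weinberg: a genotype's likelihood is
Σ f(h1)f(h2)·(2 − δ_{h1h2}) over its consistent pairs; the E-step splits
each genotype across pairs in proportion to current frequencies.
Initialization is uniform over the catalog; iteration stops when the
log-likelihood improves by < 1e-8 (default cap 1000 iterations; the
log-likelihood is non-decreasing by construction and asserted in tests).
Phase ambiguity is resolved statistically; the only true confounding is
del7 versus del8 (identical gene content — also unseparated in the
original survey), whose class sum remains identifiable. Chromosome counts
use twice the number of resolved individuals; excluded samples are
reported separately.

`motif_summary` aggregates frequencies into the published table layout:
major rows count unaltered centromeric/telomeric motifs; single-alteration
haplotypes fall in their submotif row (cB03 with a further submotif files
under that submotif, matching the table's parent lists); two or more
alterations fall in *combined*. The submotif rows of the packaged table
sum to 6.60%, rounding to the published "about 7%".

`ld_pairwise` computes D' and r² between presence/absence indicators
(count ≥ 1; copy number deliberately unused) across haplotypes weighted by
frequency (or unweighted, treating the catalog as a sequence panel — both
readings of the original LD map are supported). D = p11 − pA·pB,
D' = D/Dmax with the usual bound, r² = D²/(pA qA pB qB); genes monomorphic
under the weighting (within 1e-12) are masked undefined. No
multiple-testing correction is applied (raw maps; recorded in the output
metadata).

## Breakpoint scanning

An aligned triplet (query + two candidate parents) yields informative
sites: columns where the parents differ and the query matches exactly one
(gap/N columns and three-way mismatches are excluded and counted). Each
boundary between consecutive informative sites is tested with a chi-square
on the 2×2 table of flank × supported parent, Bonferroni-corrected over
the number of boundaries, at α = 0.001, with continuity correction when
any cell is below 5. The flank *window of 20* counts informative sites per
side by default: at the package's reference conditions (5% parent
divergence) a 20-alignment-column flank holds roughly one informative
site, which can never reach the threshold (a 2×2 table with two entries
has a minimum attainable p ≈ 0.16), so the literal column reading has no
power by construction; it remains available as `window_unit="columns"`.
Calls are maximal, non-overlapping (strongest chi-square wins its
neighbourhood) and sorted; the reported interval is the half-open column
range between the flanking informative sites, which is the finest
localization the data permit. `identity_profile` produces the
complementary sliding-window percent-identity view (gap-excluded,
half-open 0-based windows).

This is a single transparent chi-square scan consistent with the stated
scan parameters, not a portfolio of recombination-detection methods; it is
meant to be auditable and sufficient for breakpoint localization on
aligned triplets.

## Synthetic data

The simulator is first-class, tested code and defines the conditions all
stochastic claims are made under:

* **Cohorts** — haplotypes drawn i.i.d. from the packaged frequencies
  (Hardy-Weinberg pairing); each 2DS35 block realized as 2DS3 or 2DS5 with
  probability 0.5 (the assays distinguish them; the catalog does not).
* **Peaks** — forward-model heights × per-assay gain uniform in [0.5, 2]
  (exercising gain invariance of within-assay ratios) × per-peak
  multiplicative lognormal noise, σ = 0.1 by default (dye-terminator peak
  variability is scale-proportional). At σ = 0.1 the raw ratio
  classifications are ~88% accurate (adjacent classes 1:1 and 3:2 are only
  0.405 apart in log space against a log-ratio sd of ~0.14 — no classifier
  could do much better), while the integrated per-locus genotype accuracy
  measured over a 400-sample cohort exceeds 99%: the redundancy across
  assays, consumed through continuous log-ratio scoring, is what the
  two-confirmation design buys.
* **Triplets** — parent A i.i.d. uniform, parent B at 5% i.i.d.
  divergence, query copying A then switching parent at each planted
  breakpoint; optional private query mutations for null triplets.
  Homology-tract realism (repeat-element flanks) is not modelled.

What the simulator does *not* emulate: allele-level sequence variation
within genes, PCR failure and primer-site polymorphism, correlated
(per-trace) noise, population structure and deviations from
Hardy-Weinberg, and genotyping-error modes other than peak-height noise.
Passing recovery tests therefore demonstrate the internal consistency and
statistical correctness of the method under its own generative
assumptions, not robustness to every laboratory failure mode.

## Problem sizes and numerical choices

Parameter-recovery runs use 10,000 individuals (the frequency-recovery
check) and 200–2,000 individuals for property tests; breakpoint power and
false-positive rates use 200 planted and 500 null triplets of 5,000
columns. The signature table over the grammar universe (≈8,500 candidate
diplotype realizations) is built once per process in a few seconds and
cached. All randomness flows from explicit integer seeds through
`numpy.random.default_rng`; outputs are bit-reproducible given (config,
seed). Ties in nearest-class ratio classification cannot occur for exact
integer inputs (classes are distinct points); ties among noisy solver
candidates are kept as alternatives rather than broken.

## Known limitations

* The catalog membership and per-haplotype frequency split are a
  transcription/reconstruction of a published figure and table, not of raw
  data; cohort-specific counts from the original survey are out of reach.
* Allele-level typing (e.g. 2DS4L/S groups, 3DL1 allele lineages) is below
  the model's resolution, which is exactly why del7/del8 and cen/tel phase
  in double heterozygotes remain ambiguous here while richer assays could
  separate them.
* The breakpoint scanner assumes a correctly aligned triplet and two
  plausible parents; alignment construction and parent search are out of
  scope.
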