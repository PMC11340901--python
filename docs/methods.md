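# Methods

`myzopop` implements the population-genomic toolkit for studying recent
secondary contact between two *Myzomela* honeyeater species that carry
neo-sex chromosomes: the invading *M. cardinalis* ("card") and the resident
*M. tristrami* ("tris"), with *M. pulchella* ("pulc") as outgroup.  The
genome is partitioned into inheritance compartments — autosomes, a new
pseudo-autosomal region (neo-PAR), ancestral and neo Z, ancestral and neo W,
and mtDNA — and every statistic is computed per compartment, because ploidy,
effective size, and transmission differ among them:

| compartment | inheritance  | copies (M / F) | Ne scaling |
|-------------|--------------|----------------|-----------|
| autosome    | biparental   | 2 / 2          | 1.00      |
| neo-PAR     | biparental   | 2 / 2          | 1.00      |
| Z, neo-Z    | Z-like       | 2 / 1          | 0.75      |
| W, neo-W    | maternal     | 0 / 1          | 0.25      |
| mtDNA       | maternal     | 1 / 1          | 0.25      |

The Ne scalings are the neutral-theory expectations under equal sex ratios,
random mating, and equal mutation rates in the sexes.

## Synthetic-data generator

The generator (`myzopop.simulate`) is first-class, tested code.  It emulates
the contact-zone study design rather than any released dataset.

**Demography.**  Five demes — outgroup, and an allopatric/sympatric deme per
species — under a coalescent model (msprime).  Backwards in time: the
sympatric demes merge into their allopatric source at the contact time,
the two species merge at the divergence time, and the outgroup joins at a
deeper split.  Defaults, with the reasoning:

* mutation rate `mu = 4.6e-9` per site per generation; generation lengths
  2.25 y (card), 2.51 y (tris), 2.37 y (pulc).
* divergence `T_div` = 1.1 My ≈ 462,000 generations; contact
  `T_contact` = 100 y ≈ 42 generations; outgroup split 2.5 My (the outgroup
  shared an ancestor with the pair < 3 Mya; the exact value only needs to be
  comfortably pre-divergence).
* effective sizes `Ne_card = 125,000`, `Ne_tris = 150,000`: calibrated from
  the species' observed autosomal diversities via `pi = 4*Ne*mu`
  (0.0023 and 0.0028); no direct Ne estimate is printed anywhere, so this
  back-calculation is the package's own choice.  `Ne_pulc = Ne_tris`.
* post-contact migration is continuous and direction-specific
  (`m_c2t`, `m_t2c`, per lineage per generation); contact-zone census sizes
  are unknown, so these are free parameters with defaults (0.004, 0.002)
  chosen to give total admixture fractions of order 10%, the magnitude of
  the autosomal admixture proportions the analyses are designed to resolve.
  An optional one-pulse admixture event (`pulse_c2t`, `pulse_t2c`) halfway
  through the contact period supports parameter-recovery experiments with a
  known admixture fraction α.
* `maternal_bias` (default 0.9) is the fraction of effective migrants that
  are female; it multiplies the migration and pulse rates for the
  maternally transmitted compartments.  Setting `maternal_bias = 1` with
  `m_t2c = 0` reproduces the fully asymmetric card→tris scenario for W and
  mtDNA.

**Maternal co-transmission.**  W, neo-W, and mtDNA are simulated on a single
non-recombining genealogy (one maternal lineage per sample, W-like sites
masked in males), because the three are co-inherited in a ZW system.  This
is what makes W and mitochondrial haplotype origins agree within an
individual, as the asymmetric-introgression analyses assume.  Setting
`link_maternal = False` reverts to independent per-compartment genealogies.

**Sample design.**  Defaults keep the study's sampling: 40 allopatric + 40
sympatric card, 20 + 30 tris, 12 hybrids, 1 outgroup female, split evenly
by sex.  Sequence lengths default to desk scale (≈1 Mb genome total across
compartments); they are the intended scaling knob, sample counts are not.

**Hybrids.**  F1s take one gamete from each species (card mother by
default, configurable); first-generation backcrosses cross an internally
synthesised F1 female with a recurrent-parent male.  Gametes recombine
freely between variant sites on biparental compartments, with a configurable
small number of crossovers on the Z (default 1), and not at all on W/mt.
Sex-specific recombination (Z recombining only in males) is not modelled —
a documented simplification.  Realised per-site ancestry of every gamete is
tracked, so the truth record carries each hybrid's actual card fraction
(F1 exactly 0.5; BC1 0.75/0.25 in expectation) and maternal origin.

**Sequencing emulation.**  Depth is Poisson around `depth_mean` (default
16.95x for two copies) scaled by copy number, with mtDNA elevated by a
configurable factor (default 10).  Site annotations (QD, SOR, FS, MQ,
rank sums) are drawn from mid-range "passing" distributions; an injectable
fraction of sites is pushed past exactly one hard-filter threshold so
filter behaviour is testable by construction.  Heteroplasmy is emulated as
an elevated minor-read fraction at a configurable fraction of mt sites.
The emitted all-sites VCF (v4.2, GT:DP, plus AD on mt records) round-trips
bit-identically through the reader.

**Engines.**  msprime is the default for every compartment.  A
discrete-generation backward Wright–Fisher sampler (`engine="wf"`) exists
for the small non-recombining maternal compartments; it tracks lineages
generation-by-generation through the migration epoch and jumps between
coalescences afterwards, then drops infinite-sites mutations on the
genealogy.  Both engines satisfy the same structural tests.

What the generator does *not* emulate: reference bias and mapping error,
base-calling error, indels and structural variation, selection and
linked selection, GC-biased gene conversion, and sex-specific recombination.
Passing tests therefore validate the estimators and the pipeline logic
under the stated neutral demography, not robustness to those artefacts.

## Filtering

The cascade mirrors a GATK-style workflow and is applied in a fixed order
asserted by the pipeline: (1) hard site filters — QD < 2, SOR > 3, FS > 60,
MQ < 40, rank-sum thresholds — plus an optional repeat mask, recoding
failing sites as missing; (2) depth bands on the per-site mean across
carrying samples — [10, 34]x for autosome/neo-PAR, [6, 24]x for sex-linked
sequence, ≥ 10x for mtDNA, plus heteroplasmy masking (minor-read fraction
> 0.2 in any sample; no published threshold exists, 0.2 is this package's
default) — and (3) masking of heterozygous female calls on Z/neo-Z/W/neo-W
(not the neo-PAR), which are artefactual on hemizygous sequence.  For
individual-level analyses a fourth step drops invariant sites, applies a
minor-allele-frequency floor of 0.05, and LD-prunes in 50-SNP windows
advanced by 5 SNPs, removing the later SNP of any pair with r² > 0.5
(r² = squared Pearson correlation of allele-count genotypes; "later" is the
deterministic tie-break).

The conventional rank-sum thresholds are −12.5 (MQRankSum) and −8.0
(ReadPosRankSum); a variant with +12.5/−80.0 is provided as
`HardFilterThresholds.as_printed()` for comparison with pipelines that used
those values.  All filters are idempotent and logged (stage, sites in/out).

## Estimators

**pi / dxy.**  Missing-data-aware ratio-of-counts: per site, differences
and comparisons among genotyped alleles (within one population:
`n_ref*n_alt` over `C(n,2)`; between: cross products); a window's value is
the summed ratio.  Invariant sites contribute comparisons only.  Tables can
be "variant-only with implicit invariants" for large clean simulations; the
window accounting then credits every unlisted position as fully genotyped
and invariant.  Windows are 50 kb tiles (last partial tile retained); a
window needs 10,000 genotyped sites to enter a compartment average, except
mtDNA, which is a single full-length window whose SE is reported as NA.

**FST.**  Weir–Cockerham (1984) two-population variance components a, b, c
per site, windowed as Σa / Σ(a+b+c) (ratio of sums, never a mean of
per-site ratios); negative values are retained in averages.  Sample sizes
are in individuals; hemizygous calls contribute half an individual and
cannot be heterozygous, which reduces to the standard estimator on fully
diploid data and gives per-site FST exactly 1 at a fixed difference.  A
Hudson estimator is available behind `estimator="hudson"` for sensitivity.

**Tajima's D.**  The 1989 constants at the full chromosome count of the
population; sites with any missing call in the population are excluded from
both the segregating-site count and the pairwise-difference sum
(complete-case per window, constants not recomputed per site — a stated
convention, logged so users can compare others).  Windows whose population
carries fewer than 4 chromosomes are reported as undefined.

**ABBA-BABA.**  Frequency-based (population samples, not single genomes).
Derived alleles are polarised as the P4-minor allele; P4-polymorphic sites
are retained with frequency weighting.  D = Σ(ABBA−BABA)/Σ(ABBA+BABA) with
a leave-one-block-out jackknife over contiguous equal-SNP blocks (default
20) giving SE, Z, and a two-sided normal p.  The f4 admixture ratio splits
P3 deterministically into even/odd-index halves and estimates the admixture
proportion under unidirectional P3→P2 flow; a non-positive denominator is
reported as undefined with an alternative-topology note.  fdM uses the
dynamic-donor denominator (pD = max(p2, p3) when p2 ≥ p1, mirrored and
negated otherwise), computed in 100-SNP windows (50 for W/neo-W, where SNP
density is low); panel summaries average windows with fdM ≥ 0, and the
unfiltered mean is reported alongside.  Per-region runs restrict sites by
compartment; polarisation is per-site against P4, so it is identical in
regional and genome-wide runs.

**Hybrid classification.**  Diagnostic panels are biallelic SNPs fixed for
alternate alleles between the allopatric reference samples with ≥ 5
genotyped individuals per side (the same "≥ 5" convention as the
private/fixed-allele scripts; no published value exists for the panel
itself).  The hybrid index h is the fraction of tris-diagnostic alleles by
direct counting — identical to the likelihood estimator at fixed-difference
loci — and interspecific heterozygosity H_int is the fraction of panel loci
heterozygous card/tris.  Triangle classes use configurable boxes (F1:
H_int ≥ 0.85 and h ∈ [0.4, 0.6]; parental: both ≤ 0.05 of a corner;
backcrosses between).  Panel-based ancestry (1 − h per compartment)
replaces a likelihood-based ancestry model by design; haploid compartments
(female Z, W, mt) are assigned card/tris by ≥ 90% diagnostic-allele
agreement, otherwise flagged recombinant.  PCA operates on mean-imputed
allele dosages scaled by sqrt(p(1−p)); the sign convention orients each
component so the allopatric card centroid is negative.

**Allele classes and the asymmetry test.**  A private allele is carried by
≥ 5 focal individuals (carriers, not allele copies) and absent from every
genotyped non-focal sample; fixed differences and shared polymorphisms
require ≥ 5 genotyped individuals per group.  The maternal-marker asymmetry
test crosses phenotypic species with the species of the maternally
inherited markers (W/neo-W for females, mtDNA for everyone; sympatric
individuals only) in a 2×2 table tested with a two-sided Fisher's exact
test (scipy's hypergeometric implementation; the test suite checks it
against a full enumeration oracle).

**Haplotype network.**  Identical haploid sequences collapse into nodes
(samples missing > 5% of variant sites are excluded; remaining missing
sites are ignored pairwise with the distance rescaled and rounded).  Edges
form a minimum-spanning network — all edges joining distinct components of
the strictly-shorter-edge graph, i.e. the union of every minimum spanning
tree — with Hamming-distance weights.  This replaces a
statistical-parsimony (TCS) network: the connection-probability calculation
is peripheral to the haplotype-sharing pattern the network is read for, and
an optional maximum-distance cutoff approximates its component splitting.

## Pipeline

`run_full_analysis` chains simulate (or VCF ingest) → filter → sex-linkage
classification → diversity → introgression → hybrids → alleles → network,
writing TSV artifacts shaped like the study's tables plus a provenance log.
Every artifact carries a hash of the full scenario configuration in a
header comment.  Both input modes (simulate / user VCF + sample sheet +
BED) share the downstream code path.  Sex-linkage calls use normalised
coverage boxes (autosomal: both sexes in [0.8, 1.2]; Z-linked: male
autosomal, female in [0.35, 0.65]; W-linked: male < 0.1); contig-level
calls never emit neo-PAR, which is only detectable with interval-level
input.

## Problem sizes

Simulations in the test-suite and the acceptance script are run at reduced
sequence lengths chosen for precision per compute: 10 Mb per compartment
for the neutral Z/A diversity ratio (400 windows), twenty 100-kb autosomes
for quartet statistics (~60–70k usable SNPs; many small chromosomes give the
block jackknife genuinely independent blocks, which matters because
post-contact admixture ancestry barely recombines in ~40 generations and is
therefore chromosome-scale), 400 kb of W for the maternal-asymmetry
scenario, and 1 Mb contigs for coverage.  Sample sizes follow the study
design or the stated construction throughout.

## Known limitations

* The W-like WC FST convention (hemizygotes as half-individuals) is one of
  several reasonable choices; comparisons of maternal compartments across
  tools should use the same convention on both sides.
* The jackknife assumes many approximately exchangeable blocks; on a single
  non-recombining W "locus" the SE understates ancestry sampling noise, so
  W-compartment f4 values are read qualitatively (direction), as in the
  analyses they reproduce.
* The f4 ratio assumes unidirectional P3→P2 flow; under extreme
  introgression the reverse-topology denominator can turn non-positive and
  is reported as undefined rather than extrapolated.
* Simulated annotations exist only to exercise thresholds; they carry no
  information about real base-calling artefacts.
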