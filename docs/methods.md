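# Methods

## Data model

Genotypes are held as a dense samples × markers `int8` matrix with codes
`hom_a` (0), `het` (1), `hom_b` (2), `missing` (−1).  Codes are relative
to a per-marker allele pair assigned by first observation order in the
source file, because PLINK text PED/MAP carries no REF/ALT metadata;
no downstream operation assumes `allele_a` is minor or reference.  A
consequence worth stating explicitly: PED round-trips are the identity
on genotype *configurations* but only gauge-fixed datasets (those whose
`allele_a` is the first allele a reader would observe) round-trip with
identical codes.  The simulator emits that gauge.  All coordinates are
1-based inclusive; interval sizes are reported in Mb rounded half-up to
two decimals (a block spanning 46,893,645–48,980,899 bp prints as
2.09 Mb).  Chromosome names are opaque strings; `"25"` and `"chr25"`
are distinct unless normalization is requested, to avoid silent
cross-assembly merges.

## Allelic association

The scan is the basic allelic test: for each marker the 2×2 table of
allele counts (cases/controls × allele A/B; a heterozygote contributes
one count to each column, missing genotypes are dropped) is tested with

  χ² = N(ad − bc)² / ((a+b)(c+d)(a+c)(b+d)),  df = 1,

with no continuity correction and no exact-test fallback, matching
PLINK 1.07 `--assoc`.  This choice is load-bearing: on the complete
separation table (12,0 / 0,6) the uncorrected statistic is exactly 18
(−log₁₀ P = 4.6558), while Yates gives 3.69 and Fisher 4.27; the tests
document the alternatives as non-matching.  Monomorphic markers are
reported with p = 1 rather than dropped so output rows equal marker
count; a zero group margin flags the marker untestable (p undefined).
−log₁₀(P) is computed via the chi-square log-survival function and kept
at full double precision; any 2-decimal display is formatting only.

## Runs of homozygosity

ROH calling follows the sliding-window method: every window of
`window_snp` consecutive SNPs is classified homozygous if it has at
most `window_max_het` heterozygous and `window_max_missing` missing
calls; each SNP is scored by the fraction of windows containing it that
are homozygous (near chromosome ends the denominator is the reduced
number of existing windows; a chromosome shorter than the window is a
single window).  SNPs at or above `snp_hit_threshold` form candidate
runs, split where adjacent SNPs are more than `seg_max_gap_kb` apart,
trimmed so both terminal SNPs are non-missing homozygous calls, and
kept when length ≥ `seg_min_kb`, SNP count ≥ `seg_min_snp`, and mean
density (segment kb / SNP) ≤ `seg_max_density_kb_per_snp`.

Defaults: window 150 SNPs / 1 het / 5 missing, threshold 0.05; segments
≥ 1,000 kb, ≥ 150 SNPs, ≤ 50 kb/SNP; gap split 1,000 kb.  Two
documented interpretation choices: windows are defined by SNP count
only (the 1,000-kb window figure is carried in `RohParams` for the
record but not enforced, matching PLINK 1.07's effective behavior with
these flags), and missing calls inside a run are retained — they are
not evidence of homozygosity but do not interrupt autozygosity.
Density is a segment-mean check, not a local sliding one.  A
brute-force implementation that materializes every window serves as the
test oracle on all instances up to 300 SNPs.

## Shared-locus mapping and control exclusion

Chromosomes where any case lacks a ROH segment are dropped; on the
rest, shared loci are the maximal intervals covered by at least one
segment of every case (interval intersection of per-case segment
unions).  Each locus is then refined by exact haplotype identity:
a marker is compatible when no case is heterozygous and all non-missing
case genotypes are the same homozygote (missing is compatible — a
no-call is not evidence against identity, a convention motivated by
array SNPs that fail in all samples).  If compatibility fails at more
than half the core markers the locus is discarded; otherwise the core
is trimmed to its largest violation-free run and extended outward
marker by marker while compatibility holds.  Terminal markers must be
fully observed homozygous in every case, so no interval starts or ends
on a het or missing call.  The refined interval can be smaller or
larger than the ROH consensus; the exact trimming/extension rule used
in the original analyses of this kind is never fully specified, and
this reconstruction is documented as such.

A control *carries* a refined locus when it is homozygous for the
shared allele at every informative marker (missing compatible).  Under
the recessive, fully penetrant model the exclusion is absolute: one
carrier control kills the locus.  `max_carrier_controls` can relax this
for incomplete-penetrance exploration but defaults to 0.  Retained loci
are ranked by the number of genome-wide peak-association markers they
contain, then by refined size.  Single-SNP association signals without
surrounding case homozygosity are excluded naturally because shared
loci require a ROH in every case.

## Stop-loss annotation

Transcripts are modeled as mRNA plus 1-based CDS coordinates; the CDS
must start ATG, end in a stop, and be length-divisible by 3; IUPAC
ambiguity codes are tolerated only outside the CDS.  For a c.
substitution the CDS is translated with the standard genetic code; a
substitution in the stop codon that yields a sense codon is a
stop-loss, and translation continues codon-by-codon into the 3′UTR
until the first in-frame stop.  The extension length counts the recoded
stop residue, so `next_stop_offset_nt = 3 × (extension_len − 1)`: a
stop 72 nt downstream gives a 25-residue extension.  Notation is
emitted in two dialects — the compact `p.*405Rext*25` (star = wild-type
stop, 405 = coded residues before it) and standard HGVS
`p.Ter406ArgextTer26` — because both residue-numbering conventions
occur in practice.  If a 3′UTR ambiguity code changes the reading
(residue content or stop placement), every distinct resolution is
reported; if no in-frame stop exists before the transcript end the
extension is open-ended and flagged.  Selenocysteine recoding is not
modeled.

## Protein statistics

`protein_stats` reports length, Arg+Lys and Asp+Glu counts (histidine
excluded from the "positive" count, the ProtParam convention), and the
isoelectric point: bisection on the Henderson–Hasselbalch net charge

  q(pH) = Σ_pos n_i /(1+10^(pH−pKa_i)) − Σ_neg n_j /(1+10^(pKa_j−pH))

with the Bjellqvist pKa set (side chains D 4.05, E 4.45, C 9.0, Y 10.0,
H 5.98, K 10.0, R 12.0; C-terminus 3.55; N-terminus residue-dependent:
A 7.59, M 7.0, S 6.93, P 8.36, T 6.82, V 7.44, E 7.7, default 7.5).
Charge is strictly decreasing in pH, so bisection on [0, 14] converges
to the unique zero; iteration runs to a pH step below 1e-4 rather than
stopping at a small-charge threshold, which keeps the answer within
1e-3 pH of a fine-grid search even for peptides with few ionizable
groups (near-flat charge curves).  pI is displayed at two decimals,
stored at full precision.

## Survey segregation

Records carry a phenotype (normal / affected / suspicious / unknown), a
genotype (hom_ref / het / hom_alt / missing) and optional boolean trait
tags.  Inference collapses to the 2×2 affected-vs-normal ×
risk-genotype-vs-other table; suspicious (tentative diagnosis) and
unknown rows are shown descriptively but never tested.  The two-sided
Fisher p sums hypergeometric probabilities ≤ the observed table's
probability (1e-7 relative slack for floating-point ties), the
convention of mainstream statistical libraries; an exact rational
enumeration oracle checks it in the tests, with scipy's
`fisher_exact` as a second, independent cross-check.  Odds ratios use
Haldane–Anscombe +0.5 when a zero cell exists.  Trait association
(e.g. fundus bronzing vs genotype) reuses the same machinery with the
trait as the "affected" label.  Note that an exact conditional test on
discrete data is conservative under the null: its p-values are
stochastically larger than uniform, which is what the null-calibration
test asserts (P(p ≤ α) ≤ α), not exact uniformity.

## Synthetic cohorts

The generator emulates a breed-isolate mapping cohort:

- **Founders.** `n_founder_haplotypes` (default 8) haplotypes per
  chromosome with per-marker allele frequencies ~ Uniform(0.1, 0.9);
  sample gametes are founder mosaics with crossovers from a Haldane
  (no-interference) map at `recomb_rate` cM/Mb (default 1, the ~1 cM/Mb
  genome average).  Marker positions are uniformly spaced with jitter.
- **Disease locus.** All cases receive two copies of a designated
  founder haplotype over the planted interval; controls keep whatever
  they drew but accidental homozygosity for that haplotype is broken
  (at most one copy), matching the recessive model in which aged
  unaffected controls cannot be autozygous for the causal haplotype.
- **Decoy loci.** Intervals painted homozygous into all cases *and*
  listed controls, reproducing breed-wide autozygosity blocks that
  shared-ROH analysis must reject via the control filter.  Carrier
  controls are painted with a 500-kb margin around the core — a real
  carrier's autozygous segment does not end exactly at the cross-case
  intersection boundary.
- **Boundaries.** The marker immediately flanking each planted interval
  carries a discordant haplotype in one case (a single heterozygote),
  the footprint a recombination breakpoint leaves; this makes the
  planted boundary well defined at marker resolution.
- **Noise.** Genotyping error (hom↔het flips, symmetric) and uniform
  missingness are injected last; phenotypes honor `penetrance` and
  `phenocopy_rate` (defaults 1 and 0, under which the affected set
  equals the two-copy carrier set exactly).

Painting is post hoc rather than produced by explicit pedigree
coalescence: it trades realism for exact control of the planted truth,
which `SimTruth` records for parameter-recovery tests.  What the
generator does **not** emulate: realistic recombination maps and
hotspots, array ascertainment bias in marker spacing and allele
frequency, genotype-calling artifacts correlated across samples
(e.g. a SNP failing in every animal), mutation, and pedigree
relatedness beyond the founder-pool abstraction.  Passing tests
therefore demonstrate correctness of the algorithms under the stated
population model, not calibration on real array data.

Study-scale defaults (`study_config`): five 25-Mb chromosomes at 2,000
SNPs each — 10k markers at 80 SNPs/Mb, the density of a ~170k-SNP array
on a ~2.4-Gb genome — 6 cases / 3 controls, one 2.09-Mb disease locus
and four control-carried decoys of 2.5–3 Mb.  The null scenario uses 24
founder haplotypes (outbred) and no planted intervals.  The transcript
generator builds a CDS of `n_codons` sense codons ending in TGA and a
3′UTR with no in-frame stop before the requested offset, an in-frame
TAG exactly there, and (when the UTR is long enough) an AATAAA
polyadenylation signal 37 bp downstream of that alternative stop.

## Numerical and interface choices

- Chi-square p-values via `scipy.stats.chi2.sf` / `logsf`; the tests
  check them against the closed form erfc(√(x/2)) for 1 df.
- Fisher via `scipy.stats.hypergeom` pmf summation, snapped to 1.0
  within 1e-9 to absorb float accumulation.
- ROH window sums via cumulative sums (O(m) per sample-chromosome).
- Everything is deterministic given explicit seeds
  (`numpy.random.default_rng`); pipeline output is invariant to sample
  ordering.
- File formats: PLINK text PED/MAP (hand-rolled reader/writer — no
  maintained Python reader for the text dialect exists in the stack),
  VCF via cyvcf2, FASTA via Biopython, tables via pandas TSV.

## Known limitations

- The haplotype-refinement rule is a reconstruction (see above); other
  reasonable rules move refined bounds by a few markers.
- Recessive exclusion assumes full penetrance in aged controls; the
  `max_carrier_controls` override is exploratory, not calibrated.
- The allelic test's asymptotic p is anti-conservative at these sample
  sizes; it is used as a ranking statistic, exactly as in the original
  small-cohort design, not as a calibrated genome-wide error rate.
- Sex chromosomes receive no special ploidy handling and binary
  PLINK/BGEN formats are out of scope.
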