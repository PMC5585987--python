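# Methods

`genefam` implements the desk-scale stages of a genome-wide gene-family
characterization of the kind routinely performed for plant transcription-factor
families (here modelled on a 22-member zinc-finger-homeodomain family in
tomato): catalogue assembly and protein parameters, distance phylogenies with
bootstrap, duplication classification, Nei–Gojobori Ka/Ks with divergence
dating, promoter cis-element scanning, and qRT-PCR relative expression. This
note records the models, the defaults and why, the numerical choices, and what
the synthetic-data generator does and does not emulate.

## Catalogue and protein parameters

Gene records are assembled from a genome FASTA plus GFF3 annotation; membership
is defined by the supplied family CDS FASTA. The spliced CDS is reconstructed
from the genome (strand-aware) and compared with the supplied CDS; any
disagreement flags the record rather than dropping it, because silent loss of a
family member invalidates every downstream tally. Coordinates are 1-based
inclusive in GFF3 and exports, 0-based half-open internally — a single
conversion at the boundary eliminates off-by-one drift.

Conventions enforced by validation rather than assumption: the CDS includes the
stop codon, the protein excludes it, so an ORF of `L` bp encodes `L/3 − 1` aa.
Molecular weight uses average (not monoisotopic) residue masses plus one water,
the ProtParam convention; the bundled tomato reference table prints weights
labelled kDa although the values are daltons, and the package reports daltons.
The isoelectric point is the zero of the Henderson–Hasselbalch net-charge
function over the termini and D/E/C/Y/H/K/R side chains with an EMBOSS-style
pKa table, found by bisection on [0, 14] (converged to ~1e-8 pH, well past the
|charge| < 1e-4 criterion). Published pKa tables differ; values from other
tools can differ by a few tenths of a pH unit, so comparisons against external
tables should use a ±0.3 tolerance.

Family-domain screening uses a PROSITE-style consensus pattern (default
`C-x(2)-C-x(10)-H-x(3)-H`, a C2HH zinc-finger-like signature) rather than a
profile HMM. This is an approximation of the Pfam-style domain confirmation a
full study would run: a consensus pattern has no position-specific scores, so
borderline domains may be missed on real proteins. For the synthetic family,
where the domain is planted verbatim, the screen is exact.

## Distance phylogenies

The protein alignment is an input (alignment construction contributes nothing
family-specific and is done upstream with standard tools). Distances are
p-distances after *complete deletion*: every column containing a gap or
ambiguity in any taxon is removed first, so all pairs are measured on the same
site set. A Poisson-corrected option (`d = −ln(1 − p)`) exists behind a flag
because the common MEGA workflow is ambiguous about the correction; p-distance
is the default as the simplest choice consistent with complete deletion.

Neighbor joining follows the Saitou–Nei Q-criterion. Ties on Q merge the
smallest (i, j) index pair; negative branch lengths are clamped to zero with
the deficit moved to the sister edge (the standard practical convention, which
preserves the pair's summed length). The final three lineages are resolved by
the three-point formulas, giving an unrooted trifurcating root. UPGMA uses
size-weighted arithmetic-average linkage (classic UPGMA), merging the
lowest-index pair on ties; its output is ultrametric by construction and the
suite asserts this to 1e-9.

Bootstrap supports resample alignment columns with replacement within the
complete-deletion column set (so every replicate sees the same site universe),
rebuild the tree, and report for each internal edge of the point-estimate tree
the percentage of replicates containing the same bipartition (NJ, unrooted
view) or clade (UPGMA, rooted view). The default replicate count is 1000; the
test suite and the acceptance script run 200 as their configured problem size.
Supports are deterministic given the seed.

Subfamily labels propagate from anchor leaves: each unlabeled leaf takes the
label of the smallest enclosing clade that contains anchors, provided those
anchors agree; mixed-anchor clades yield "unassigned" rather than a guess.

## Duplication classification

Pairwise identity and query coverage come from local alignments (BLAST-like,
since that is the tool this analysis mimics): BLOSUM62 with gap open/extend
−11/−1 for proteins, +2/−3 match/mismatch with −5/−2 gaps for nucleotide.
Identity is identical columns over aligned columns; coverage is the aligned
span on the query over query length, which is inherently asymmetric. A pair is
*segmental* when identity and coverage are ≥ 80% (inclusive) with **either
gene as query** — requiring both orientations resolves the asymmetry that a
one-sided "query coverage" rule leaves open. A pair is *tandem* when both
genes share a chromosome, at most 5 annotated genes lie strictly between them,
and their nearest ends are within 100 kb (both bounds inclusive). When both
criteria hold the pair is reported tandem: physical adjacency is the stronger,
more specific claim. CDS comparison is the default because duplication ages
are estimated from the same sequences; protein mode is available.

A note on the tomato family this mirrors: the printed coordinates place four
members within ~17 kb on chromosome 1, which this classifier would call tandem
given a full genome annotation, whereas the original analysis reported no
tandem pairs. The rule here follows the stated criterion; the discrepancy is
documented rather than reconciled (the full tomato annotation is not an input
at desk scale).

## Nei–Gojobori Ka/Ks and dating

NG86 counting, authored in this package and certified in the tests against an
exhaustive enumeration oracle (every single-nucleotide change of every codon,
every mutational pathway for 2- and 3-difference codon pairs):

* synonymous sites per codon = (synonymous single-nucleotide changes at each
  position)/3 summed over positions; changes to stop codons never count as
  synonymous, and the denominator stays 3 (no renormalization);
* `S` is averaged over the two sequences; `N = 3·codons − S`;
* differences for codons differing at k positions are averaged over all k!
  pathways with equal weights; pathways through stop codons are discarded; a
  codon pair whose pathways all hit stops is dropped from both the site and
  difference totals;
* terminal stop codons are stripped before counting; gapped or ambiguous codon
  columns are dropped pairwise;
* `ps = Sd/S`, `pn = Nd/N` are Jukes–Cantor corrected,
  `d = −(3/4)·ln(1 − 4p/3)`. Proportions ≥ 3/4 raise an explicit saturation
  flag — never a silent number.

Ka/Ks with `Ks = 0` (or a saturated correction) is reported as undefined and
printed "NA"; the selection call is >1 positive, <1 purifying, =1 (within
1e-9) neutral. Divergence time is `T = Ks/(2r)` in Mya with
`r = 1.5e-8` substitutions/site/year, the conventional dicot rate; `r` is
configurable.

## Promoter cis-elements

Promoters are the 2000 bp immediately 5′ of the start codon, strand-aware
(reverse complement of the downstream flank for minus-strand genes), truncated
with a flag at chromosome ends, never padded. The element catalog is an
editable TSV of IUPAC consensi — the matching is the computation, the catalog
is configuration. The bundled default holds reconstructed consensi for the
five stress elements the field reports most often (MBS, ABRE, HSE, LTR, DRE);
they are marked as synthetic reconstructions because published scans do not
print the exact strings they matched. Both strands are scanned at every
position; overlapping and repeated matches are all counted, and the gene-level
presence summary (genes containing ≥1 copy) is what mirrors published tables.
Offsets are the 1-based distance of the match's 5′ base upstream of the A of
ATG. Note that a palindromic consensus (e.g. `AGAANNTTCT`) legitimately
matches both strands at the same window; counts reflect that, presence does
not double-count.

## qRT-PCR expression

`ΔCt = Ct(target) − Ct(reference)` per sample/replicate (reference default
EF1a); `ΔΔCt` subtracts the calibrator sample's mean ΔCt, so the calibrator's
fold is exactly 1 by construction; fold = `2^−ΔΔCt`. The calibrator defaults
to the first sample in the table — conventionally the untreated 0 h control in
a stress series — and is overridable. Input rows are biological replicates;
technical averaging belongs upstream.

ANOVA and Tukey comparisons run on ΔCt values, which are approximately normal
and homoscedastic where folds are log-normal; running on log2 fold would be
equivalent up to the calibrator shift. The ANOVA is the standard
between/within decomposition with `F = 0, p = 1` defined for all-identical
groups. Tukey uses the studentized-range distribution (quantiles computed
numerically by scipy, tolerance well below 1e-4) with the harmonic-mean n for
unbalanced groups. Compact letters are assigned by insert-and-absorb over the
mean-sorted groups; with a single critical range the non-significant sets are
intervals, so maximal windows give letters with the exact property that two
groups share a letter iff they are not significantly different.

## Synthetic-data generator

The generator emits a mutually consistent bundle — genome FASTA, GFF3 (family
genes with mRNA/exon/CDS structure plus spacer genes so intervening-gene
counts are meaningful), CDS/protein FASTA, protein alignment, element catalog,
triplicate Ct table — together with a ground-truth JSON and the generating
tree. Identical seeds give byte-identical bundles.

Defaults encode the study conditions this package mirrors: 22 genes in six
subfamilies (sizes 6/5/4/3/3/1) on six of twelve chromosomes (6/5/3/3/4 on
ch01–ch05, one on ch09); intron counts per gene equal to the reference table's
exon counts minus one (13 intronless, the rest 1–3 introns); four dispersed
duplicate pairs at target Ks 0.13/0.18/0.24/0.30 with Ka/Ks = 0.3 (dates
spanning roughly 4.3–10 Mya at the default rate) plus one tandem pair (target
Ks 0.10) placed within 100 kb with two spacer genes between; planted element
tallies MBS 11 / ABRE 11 / HSE 12 / LTR 3 / DRE 1 genes at 1–3 copies each;
per-gene fold inductions in the 1.5–8× range including one exact 8× peak, with
Gaussian noise (sd 0.2 cycles) on every measured Ct.

Codon evolution places substitutions uniformly over codon positions
conditional on the synonymous/nonsynonymous class (NG86's implicit model — no
rate heterogeneity, no transition/transversion bias), rejects changes creating
stops, and converts target (Ks, Ka) into difference counts through the inverse
Jukes–Cantor map against the ancestor's site totals. At most one substitution
lands per codon, so the realized Sd/Nd counts recorded as ground truth are
exact; this caps the achievable divergence at one change per three sites,
which the default branch lengths respect. All genes are 180 codons plus stop,
with no indel evolution (a stated non-goal); consequently the emitted protein
"alignment" is the ungapped protein set, and gap handling is exercised by
dedicated tests instead. The domain codons and the stop codon are frozen so
every emitted protein carries the exact domain consensus; divergence targets
are expressed against full-length site counts, so realized values sit slightly
below target when the frozen fraction is large (negligible at the default
sizes, and ground truth records realized counts regardless).

Promoter backgrounds are rejection-sampled against the element catalog (both
strands) before planting, so planted-element recovery is exact by
construction: recovery tests certify the scanner, not luck. What the generator
does **not** emulate: indels and alignment uncertainty, rate heterogeneity,
codon-usage and GC bias, transposon-derived duplication, promoter structure
beyond planted motifs, amplification-efficiency differences between primer
pairs. Passing recovery tests therefore demonstrates correctness of the
computations under the stated model, not robustness to every property of real
data.

The expression noise envelope test treats the spec'd "≥ 99% of simulations
inside [f/2^(3σ), f·2^(3σ)]" as a binomial consistency check at α = 0.01 over
200 fixed-seed simulations: with σ = 0.2 on every Ct the true in-envelope
probability of the mean-ΔΔCt estimator is ≈ 0.991, so a hard ≥ 199/200 cut
would reject a correct implementation about a third of the time; the binomial
test has the stated level against genuine miscalibration.

## Problem sizes

The suite and the acceptance script run everything at desk scale as their
configured problem sizes: 500-codon pairs × 20 replicates for Ka/Ks recovery,
≥ 100 random codon-pair instances for oracle equivalence, n ≤ 7 taxa for
brute-force tree enumeration, 200 bootstrap replicates, 200 noise-envelope
simulations, and the full 22-gene default bundle (twice) for the end-to-end
determinism and recovery checks.

## Known limitations

* Consensus-pattern domain screening is weaker than a profile HMM on real
  proteins.
* p-distance NJ is a heuristic; no likelihood-based inference is provided
  (stated non-goal).
* The local-alignment identity/coverage depends on fixed scoring parameters;
  they are configuration, not estimates.
* NG86 underestimates divergence when substitution rates are strongly biased;
  no ML dN/dS is provided (stated non-goal).
* The qPCR model assumes 100% amplification efficiency for both target and
  reference (the plain 2^−ΔΔCt assumption).
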