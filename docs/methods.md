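# Methods

## Problem setting

A patient with multiple meningiomas carries two or more spatially separated
tumours. Each resected lesion yields a somatic SNV/INDEL call set (with
variant allele frequencies, VAF) and an allele-fraction-aware copy-number
segmentation (log2 copy ratio and minor-allele fraction, MAF, per segment),
called against the patient's matched blood. `mmclone` consumes these call
sets; it does not realign reads or re-call variants.

Two generative hypotheses are distinguished per patient. Under *monoclonal
origin*, all lesions descend from one founding clone, so the founder's
somatic alterations are truncal — present in every lesion — and later
private alterations produce branched evolution. Under *independent origin*,
lesions arise separately and share no somatic alterations (two tumours
acquiring the same somatic point mutation or the same arm-level breakpoint
pattern independently is vanishingly unlikely). The classifier therefore
reduces to a carefully defined notion of "shared".

## Filter chain

Variants pass three filters, in any order (they commute and are idempotent;
this is property-tested):

| filter | rule | boundary |
|---|---|---|
| population AF | drop if gnomAD AF > 0.01 | exactly 0.01 kept; missing kept |
| functional impact | keep consequence ∈ impact set | unknown terms logged + dropped |
| contamination | drop if VAF < contamination rate | VAF = rate kept |

The functional-impact set is not fully standardised across annotators; the
default is {missense, nonsense, frameshift, in-frame indel, splice-site,
start-lost, stop-lost}, excluding synonymous/intronic/UTR, and is
configurable. Missing population frequencies are kept distinct from 0.0:
absence from gnomAD is evidence of novelty, not commonness. The default
contamination rate is 0 (the rate is a property of each sequencing run and
must be supplied by the caller).

## Arm-level event calling

Segments use 0-based half-open coordinates internally; the SEG dialect on
disk is 1-based inclusive and converted at the boundary, which confines
off-by-one risk to the reader/writer pair. Per-lesion segments must
partition each chromosome (overlap is a validation error).

An arm carries an event when the merged length of qualifying segments covers
at least `min_arm_fraction` (default 0.5) of the arm:

* deletion: log2 copy ratio ≤ −0.3;
* amplification: log2 ≥ +0.3;
* LOH: MAF ≤ 0.40, irrespective of copy ratio (so both physical deletions
  and copy-neutral LOH qualify — a deleted segment with informative MAF
  yields *both* a deletion and an LOH event, which is intentional: the two
  signals are distinct lines of evidence).

These cutoffs are field-standard conventions for ~tumour-purity-diluted
arm-level calls, not measured constants, and are all configurable. Arm
boundaries are the GRCh37 centromere gaps; the heterochromatic p arms of the
acrocentric chromosomes (13, 14, 15, 21, 22) are excluded since exome
capture cannot observe them, so a q-arm-wide event on chromosome 22 is
reported as the chromosome-level event `chr22:deletion`. When every arm of a
metacentric chromosome shows the same event kind the arms likewise coalesce
to a `chrN` label.

## Shared features and the clonality rule

SNV features are identified across lesions by (chrom, pos, ref, alt); gene
and annotation differences do not split identity. CNV features are events of
the same (label, kind) whose footprints overlap reciprocally by ≥ 0.5 of each
footprint, clustered by single linkage; distinct same-arm events remain
distinct features. Multi-lesion shared segments can also be computed
directly as interval intersections of per-lesion state intervals
(commutative and associative; verified against a per-base oracle).

Every feature of a patient is then truncal (in all lesions), partially
shared, or private. The patient is called **monoclonal** when at least
`min_shared_drivers` (default 1) *driver* features are truncal, where driver
means a driver-panel SNV/INDEL (NF2, TRAF7, AKT1, KLF4, PIK3CA, PIK3R1,
SMO, SUFU, POLR2A, SMARCB1, PRKAR1A) or any CNV/LOH event; otherwise
**independent**. One shared driver is the minimal rule that separates the
two hypotheses given the near-zero probability of identical convergent
somatic events; requiring more shared features is a configuration away.

Subtype is per tumour: **NF2-loss** iff the filtered profile carries an NF2
SNV/INDEL or a chromosome 22 deletion event; otherwise **non-NF2**.

## Clonal-fraction estimators

Let c be the fraction of tumour cells carrying an event.

From a point mutation's VAF v: heterozygous diploid locus c = 2v;
copy-neutral LOH with the mutation on the duplicated allele c = v;
hemizygous locus (carriers retain one mutant copy, non-carriers two)
c = 2v/(1+v). These invert the forward model
E[VAF] = c/2, c, c/(2−c) respectively.

From an LOH segment's MAF m: the default is the copy-neutral
allelic-imbalance model c = 1 − 2m (m = 0.5 balanced → c = 0; m = 0 →
c = 1). A hemizygous-deletion model c = (1 − 2m)/(1 − m) is available via
`maf_model="deletion"`. The allelic-imbalance form is the default because it
is the relation that the paired MAF/VAF observations of the bundled cohort
satisfy (MAF 0.30 ↔ VAF 0.22, MAF 0.11 ↔ VAF 0.40); chrX events in this
mostly female cohort are treated as diploid loci.

Estimates are clipped to [0, 1]; raw values outside the range are flagged
`clipped` in the comparison table. MAF- and VAF-based estimates for the same
lesion are flagged concordant when they differ by ≤ 0.10 absolute — the
scale of the rounding in how such pairs are conventionally reported (0.44
and 0.78 read as "40 %" and "80 %").

## Phylogeny

Per patient, a binary matrix over driver-panel SNVs and CNV events (one row
per lesion, optional all-zero `germline` outgroup row) feeds a Manhattan
distance matrix — on binary data the Hamming count of differing features,
with SNV and CNV features weighted equally. Trees come from classical
Saitou–Nei neighbor joining: repeatedly join the pair minimising
Q(i,j) = (n−2)d(i,j) − Σₖd(i,k) − Σₖd(j,k), with the standard closed-form
branch lengths. NJ is exact on additive metrics, which the tests exploit:
path lengths on the output tree must reproduce any random tree metric to
1e-9.

Determinism choices (reference NJ implementations vary here): labels are
processed in sorted order and Q-ties are broken by the lowest (row, column)
index pair; negative branch lengths are clamped to zero with the deficit
moved to the sister branch so pair distances are preserved. Columns shared
by every lesion are retained — together with the germline row they form the
trunk. The Newick writer orders children by the smallest leaf label in each
subtree, so output is byte-stable; when the outgroup row is present the tree
is rooted at the germline leaf's attachment node.

## Synthetic data

The simulator emulates the study design — several lesions per patient, a
truncal driver burden, private alterations per lesion — under both
scenarios. Defaults: 2 lesions/patient, 5 truncal + 3 private SNVs, one
truncal chr22 deletion, one private CNV (deletion or LOH) per lesion,
true clonal fractions uniform on [0.6, 1.0], sequencing depth 500 (typical
high-coverage exome), one driver-panel SNV guaranteed per clone, and two
"artifact" calls per lesion (one gnomAD-common, one synonymous) that the
filter chain must remove. Under the independent scenario each lesion
receives its own founder alterations of the same total burden and nothing
is shared.

Observed VAFs are binomial(depth, expected VAF)/depth; a beta-binomial
overdispersion flag exists but is off by default since no segment-level
noise model is established for these call sets. Segment log2/MAF values are
emitted at their expectations — after averaging over the thousands of
markers in an arm-scale segment the residual noise is negligible relative
to read-level VAF noise, which is the quantity the estimators consume.
Private CNV arms are drawn without replacement across the whole patient and
never collide with truncal arms; SNV positions are resampled on collision
(bounded retries, then an error).

What the simulation does *not* emulate: subclonal structure beyond one
clonal fraction per event (no multi-cluster CCF deconvolution), mutational
signatures, read-level artefacts, tumour-in-normal contamination, and
segmentation breakpoint noise. Passing tests therefore demonstrate the
correctness of the feature logic, classifiers, estimators and tree
inference under a faithful but idealised observation model — not robustness
to segmentation error in real call sets.

## Bundled cohort fixture

`build_inpaper_fixture()` encodes, per lesion, the somatic alterations of a
published six-patient, fifteen-tumour multiple-meningioma cohort (plus one
uninvolved dura sample used as the outgroup sanity check). SNV coordinates
are representative positions within the GRCh37 loci of the named genes;
where an alteration's class is not specified (the chr8/15/18 "CNV events"),
deletions are encoded — subtype and clonality verdicts are insensitive to
that choice. The chrX LOH segments are encoded with log2 −0.2 so they are
called as LOH (their MAFs, 0.30 and 0.11, carry the clonality signal).

## Numerical and degenerate-input choices

* Filters and estimators validate domains strictly ([0,1] for fractions,
  [0,0.5] for MAF) and raise on violations rather than clamping inputs.
* A single-lesion patient yields a degenerate shared/private partition
  (flagged with a warning) and no clonality verdict or tree.
* A patient with no features at all is a hard error from the matrix builder
  (advice to review thresholds) which the pipeline records as a note.
* The pipeline collects per-patient failures instead of aborting the
  cohort; re-running with identical inputs and configuration produces a
  byte-identical report.

## Problem sizes used in the checks

The bundled-cohort computations are exact and instantaneous. Stochastic
checks use 100 simulated patients (50 per scenario) at depth 10⁴ for
scenario recovery, 500 event-level simulations at depth 10⁴ for estimator
recovery (3 delta-method standard errors, ≥ 99 % coverage), and 200 random
additive metrics on 4–8 leaves for NJ exactness.
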