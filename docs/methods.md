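# Methods

This note documents the models, conventions and numerical choices behind
cas9kit, and what the synthetic-data generators do and do not emulate.

## Target-site model and coordinates

An S. pyogenes Cas9 target is a 20-nt protospacer immediately 5′ of an NGG
PAM. Internally all coordinates are 0-based half-open on the forward strand;
`pam_start` is the first base of the NGG triplet for both strands (for a
reverse-strand site the PAM appears as CCN on the forward strand and
`pam_start` is the first C). The ±30-nt context window is anchored on the
first PAM base and spans `[pam_start − 30, pam_start + 3 + 30)`, clipped at
contig ends; which PAM base anchors the window is a convention, and this one
keeps the whole triplet inside every unclipped window. The scanner defaults
to both strands (Cas9 cuts either orientation); a forward-only mode exists
for strand-resolved analyses. Protospacers containing N are reported but
flagged, and excluded from background sampling because the substitution
matrix does not define scores against N.

## Donor design

The barcoded knockout donor follows the layout
`left arm (50) · TAA · fwd primer · barcode (20) · rev primer · right arm (50)`.
The deleted 20-nt window is centred on the blunt Cas9 cleavage point 3 bp 5′
of the PAM (between protospacer positions 17|18), i.e. 10 nt on each side of
the cut; the cut offset is configurable because the printed donor anatomy
fixes only the 20-nt total, not the frame. For reverse-strand sites the
insert is reverse-complemented into forward coordinates so the stop codon is
5′ on the protospacer strand. Arms are checked against the reference on
every design and on every `apply_template` call. Default common primers are
the standard yeast barcode-flanking U1/D1 sequences; both are parameters.
Batch barcode generation enforces distinctness with a pairwise Hamming floor
(default 5) by rejection sampling.

Point-mutation oligos default to a 59-nt core with the edit centred
(`core_flank=29`); an asymmetric `(left, right)` flank pair supports layouts
where the edit sits off-centre, as in the published cdt-1 repair oligos, and
`extension` adds up to 50 bp of homology per side (clipped at locus ends).
`protospacer_disrupted` reports whether a registered guide that matched the
wild-type locus end-to-end (either strand) no longer matches the edited
locus.

## Alignment and off-target adjudication

Guides are compared to candidate protospacers by Needleman–Wunsch global
alignment with match +2, mismatch −1 and affine gaps, implemented as a
three-state Gotoh DP with full traceback. Gap costs use the convention that
a length-L gap costs `gap_open + (L−1)·gap_extend`; the defaults (14, 4)
reproduce the R Biostrings `pairwiseAlignment` defaults (opening 10 plus
extension 4 per gapped column). This choice matters: with much cheaper gaps
(e.g. 5/2) the optimal alignment of two *unrelated* 20-mers often contains
gaps and its per-column match count can exceed 12, so the plausibility rule
below would fire on noise. Under the default scheme the optimal 20-vs-20
alignment is gapless except when a shifted register is strongly favoured,
and the match count of a substitution-only decoy equals its constructed
identity in >99.8% of cases (deviations occur only at near-zero identity and
stay far below the threshold).

Matches are counted on aligned columns of the optimal alignment (gap columns
are neither match nor mismatch). Ties among co-optimal alignments are broken
by a fixed state preference — substitution column, then gap in the target,
then gap in the guide — which is deterministic and avoids gaps whenever an
equally scoring substitution path exists; it is not a guaranteed global
minimum-gap selection among all co-optimal alignments, but the score and the
plausibility decision are tie-independent for gapless optima.

A candidate is a *plausible* off-target when the global alignment has at
least 12 perfect matches, the established minimum base-pairing for Cas9
cleavage. Separately, `p_better` ranks the candidate's Smith–Waterman local
score against local scores of the same guide versus a without-replacement
sample of genomic protospacers (default 10,000; the whole pool is used with
a shortfall flag when the genome yields fewer). "Better" means strictly
greater score, so ties do not count against the candidate. Local scoring of
the background batch is a numpy-vectorised Gotoh recursion across targets;
it is cross-checked against Biopython's `PairwiseAligner` in the tests, and
the global aligner additionally against a top-down recursive oracle and a
brute-force alignment enumerator at short lengths.

Candidate collection requires the PAM trinucleotide (not the whole
protospacer) to lie inside the variant's ±30-nt window, the window being
anchored on the variant's reference allele span. Variants with no adjacent
PAM are reported explicitly rather than dropped.

## Phenotype statistics

Targeting efficiency is a binomial proportion (positives / selection-plate
colonies). The default interval is Wilson score — well-behaved at the 0% and
100% efficiencies that single-locus screens produce — with Clopper–Pearson
("exact") and normal approximations available.

ΔΔCT uses per-condition means of replicate CTs by default (ΔCT = mean
target − mean control; ΔΔCT = ΔCT_test − ΔCT_ref; fold = 2^(−ΔΔCT)), with a
paired mode that differences replicate-matched CTs first. Dispersion is the
standard error of ΔΔCT from replicate variances, reported as a ±1 SE
multiplicative band on the fold. No amplification-efficiency correction is
applied (a 2-fold-per-cycle assumption, as in the comparative-CT method).

Growth fitness: AUC is the trapezoidal integral of OD600 over the observed
span (raw, not baseline-subtracted; the ABC subtraction of the
transporter-negative reference removes shared background growth). Curves on
different grids are linearly interpolated onto the union grid restricted to
the overlapping span; extrapolation is refused. Per-strain ABC uses each
replicate's AUC minus the mean reference-negative AUC; the fold is the ratio
of replicate-mean ABCs, with a delta-method standard error when replicate
sets are supplied. Consumption rates are negated least-squares slopes over
an explicit time window (the window is a required CLI argument because
published rates depend on the chosen linear phase).

## Synthetic data: what it emulates and what it does not

Generators are pure functions of (parameters, seed) and return ground-truth
ledgers. Defaults encode the study conditions the statistics are meant for:
biological triplicate, 72-hr plate-reader curves sampled every 15 min, ~1%
multiplicative (log-normal, unit-mean) OD noise, 0.1-cycle Gaussian CT
noise, true fitness folds {1.7, 2.6, 3.9}, sixfold sgRNA abundance, and
duplex/triplex targeting efficiencies 43%/19%.

The genome generator draws i.i.d. bases at a target GC (default 0.38,
yeast-like) and plants protospacer+PAM cassettes at stated positions. Decoy
protospacers are built by substituting 20−k guide positions, so the planted
gapless identity is exact; variants (SNP/MNP/1-nt INDEL) are placed at known
offsets from planted PAMs. The wild-type growth curve is logistic (K = 0.35
OD, r = 0.15 hr⁻¹, midpoint 30 hr); the transporter-negative reference is a
logistic at 15% of K; a fold-f strain's noiseless curve is
`minus + f·(wt − minus)`, which makes its true ABC ratio exactly f.

Not emulated: read-level sequencing (the pipeline consumes VCFs, not
FASTQs), sequencing error and variant-calling artefacts, position-dependent
Cas9 mismatch tolerance (all mismatches weigh equally, as in the match-count
rule), chromatin context, non-i.i.d. genome composition (repeats, GC
heterogeneity), lag/diauxic structure in growth curves, and qPCR efficiency
drift. Passing tests therefore validate the *computational* procedures and
their planted-truth recovery, not wet-lab effect sizes: the 43%/19%,
sixfold, fold-utilization and consumption-rate figures are experimental
outcomes that the simulations use as generator truth.

One caveat on planted-truth exactness: a background NGG site inside a
variant window can by chance resemble a guide. Planted-truth tests use fixed
seeds (deterministic datasets), and the acceptance script scores recovery
against planted sites only, so this residual randomness cannot flip reported
quantities.

## Problem sizes and reported quantities

The test suite and `scripts/acceptance.py` run on desk-scale inputs chosen
to make sampling error small relative to the quantities reported: 10–20-kb
genomes (PAM scans are oracle-checked at this size and scale linearly),
10,000-site background nulls, 200-seed fitness-recovery sweeps, 1,000-run
ΔΔCT calibration, pooled colony screens of 10 × 300 colonies, 25 simulated
qPCR experiments, and 10 simulated plate-reader runs. The acceptance script
derives every sub-seed from `--seed`, recomputes each quantity by running
the full corresponding pipeline stage, and reports values on the scales the
field uses (percentages, folds, g L⁻¹ hr⁻¹).
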