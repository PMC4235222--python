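# Methods

`exoncgh` models the complete analytic path of a gene-targeted array-CGH
diagnostic workflow for intragenic deletions: array design, probe-level
signal formation, segmentation, quality control and calling, manual-review
escalation, and in-silico breakpoint confirmation. This note documents the
models, the parameters that matter, and the design choices made where the
workflow left them open.

## The copy-number signal model

A two-color CGH probe reports `log2(test signal / reference signal)`. With
integer copy numbers the theoretical values are `log2(1/2) = -1` for a
heterozygous deletion, `log2(2/2) = 0` for copy-neutral, and
`log2(3/2) = 0.585` (conventionally printed 0.59) for a heterozygous
duplication (`expected_log2`). A zero-copy (hemizygous-deletion) state is
floored at a background-hybridization level of `eps = 0.1` copies, so the
reported ratio is about -3.3 rather than negative infinity — deep enough to
be unambiguous, finite enough to be numerically harmless.

## Hybridization attenuation

Real 60-mer probes do not report copy number directly; they report duplex
stability. Small lesions under a probe depress its signal without removing
the target copy. `probe_efficiency` captures this with a single disrupted
fraction `f` of the probe footprint:

* **Deletions** remove bases; the flanks remain one hybridizing stretch
  (the probe loops out the missing bases), so `f = deleted bases / 60`.
* **Insertions** sever the footprint's homology; the probe retains only the
  longest contiguous matching block, `f = 1 - longest_block / 60`.
* **Single-nucleotide changes** destabilize a fixed window of `w_snv = 15`
  bases centered on the variant.

Efficiency is `(1 - f) ** alpha` with destabilization exponent `alpha = 2`:
duplex yield falls faster than linearly in the mismatched fraction, which
is what makes a 12-bp lesion under a 60-mer visible at all (efficiency
`(48/60)^2 = 0.64`, pair value `log2(1.64/2) ~= -0.29`). Both `alpha` and
`w_snv` are calibration knobs, not measured constants; they are exposed as
arguments everywhere they enter.

Per-probe signal is the sum of allele efficiencies (one allele per copy; X
loci contribute a single allele in XY samples against a same-sex reference
pool), floored at `eps`, plus i.i.d. Gaussian noise with `probe_sd = 0.12`
— the middle of the accepted derivative-log-ratio QC band. Spike-in control
probes sit at 0. Dye bias, GC waves, spatial artifacts and probe-specific
affinity differences are deliberately not modelled; passing tests therefore
demonstrate the behavior of the analysis pipeline under calibrated white
noise, not its robustness to structured artifacts of real scanners.

## Array design

`build_manifest` tiles every exon plus `exon_flank_bp` of intronic flank
with 60-mers at `target_spacing_bp`, deterministically and left-anchored,
right-aligning a final probe so windows are covered end to end; an exon
window shorter than one probe receives a single probe centered on it. With
`antisense_duplication` every target footprint is emitted on both strands —
the redundancy that makes a single-footprint lesion reviewable. Backbone
probes tile the surrounding region every `backbone_spacing_bp` outside
target windows, and a handful of control probes are parked away from the
targets. Probe length is fixed at exactly 60.

The synthetic suite gives every gene a generous backbone (1-kb spacing,
50-80 kb margins). This stands in for the real arrays' thousands of
genome-wide backbone probes: the per-chromosome median baseline must remain
copy-neutral even when a large deletion removes most of a gene's target
probes (the multi-exon case deletes 8 of 10 exons).

## Segmentation

`cbs_segment` is a from-scratch circular binary segmentation: recursively,
the arc `(i, j]` of the probe-ordered values maximizing the two-sample
statistic `|T| = |mean_in - mean_out| / (s * sqrt(1/n_in + 1/n_out))` (with
pooled within-group sd `s`) is found by exhaustive vectorized search, and
the split is accepted when a within-segment permutation test of max `|T|`
(seeded, `n_permutations = 1000`, early-stopped) gives `p < alpha = 0.01`.
Adjacent segments closer than `prune_sd = 1.5` residual standard deviations
are merged back. Ties in the arc search break to the lexicographically
smallest `(i, j)`; a constant segment is never split. Segments smaller than
the four-probe calling minimum are produced and retained on purpose: the
minimum-probe rule belongs to calling, so two-probe events stay visible to
review.

## QC, calling and review

**DLR.** Array quality is the derivative log ratio spread. The default
estimator is robust: `1.4826 * MAD(first differences) / sqrt(2)`, which
estimates the per-probe noise sd while ignoring copy-number plateaus and
the few large derivative jumps at true CNV boundaries. On a small per-gene
array a plain sd-of-differences estimator is visibly inflated by a single
deep hemizygous deletion (two +-3.3 jumps among a few hundred differences
push an honest 0.12-noise array to 0.22), so the robust form is the
default; `sd_diff` and `plain_sd` remain selectable. Bands: below 0.20
accepted, 0.20-0.29 borderline, at or above 0.30 rejected (and the
pipeline aborts).

**Calling.** Automatic deletion calls need a segment mean at or below -0.6
over at least four probes; duplications +0.4. An X-chromosome deletion call
in an XY sample whose mean is shallower than the hemizygous depth band
(-2.5 under the simulator's `eps`) is flagged `hemizygous_underdepth` — the
signature of a sequence variant under the probes rather than a true
single-copy loss.

**Review.** Probes sharing an identical footprint (sense/antisense pairs)
are collapsed into evidence units; every maximal run of consecutive
footprints whose mean sits below `review_log2_threshold` becomes a review
candidate if at least one criterion holds: (a) two entirely non-overlapping
probes, or one footprint carried by both strands; (b) overlap with a
sequencing-primer interval (possible allelic dropout); (c) recessive gene
with one mutation already identified; (d) dominant gene with strong
clinical suspicion.

The review threshold defaults to **-0.10**, i.e. just below the noise
floor of an accepted-quality array, and deliberately not a significance
threshold. The rationale is sensitivity budgeting: the smallest reviewable
signal in the suite is a single sense/antisense pair at a model value of
-0.29 with a pair-mean standard error of 0.12/sqrt(2) ~= 0.085. A screen at
-0.25 would miss that event in roughly a third of arrays; at -0.10 its
sensitivity is about 99%, while a copy-neutral footprint pair false-alarms
about 12% of the time. That trade is intentional and mirrors how such
workflows operate in practice: review candidates are cheap to raise and
every one is sent to breakpoint-PCR/sequence follow-up, which is where
specificity lives — an unconfirmable candidate resolves to `unresolved` and
asserts nothing. The threshold is a surrogate for human manual review and
is exposed in `ReviewContext`.

## Breakpoint bounding and follow-up

For each call, the **inner** interval (union of deviant probe footprints)
is minimally deleted and the **outer** interval (between the nearest
flanking *normal* probes, skipping probes that are themselves below the
review threshold) is maximally deleted. Walking primer pairs are planned at
increasing offsets outside the inner interval (18-30-mers, Wallace-rule
melting estimate, admissibility band 52-62; windows without an admissible
primer are skipped with a warning), and each pair predicts the
deleted-allele amplicon as `product - deletion + insert`.

The simulated follow-up (`emit_local_sequence`) returns per-allele
sequences over a region with the allele's events applied. Only events fully
contained in the region are applied: an amplicon whose far primer sat
inside a deletion drops out in reality rather than reporting a truncated
junction, and modelling it otherwise produced phantom partial deletions.

## Junction analysis

`analyze_junction` decomposes a ref/alt pair by maximal common prefix and
suffix (trimmed to never overlap): deletion length, inserted bases, and the
placement ambiguity — the breakpoint microhomology, computed as
`max(0, maxPrefix + maxSuffix - min(len(ref), len(alt)))` for pure
deletions and pure insertions. Breakpoints are reported left-aligned with
the microhomology length separate (HGVS-like convention). Insert origin is
tested in order: reverse-complement match within `W = 500` bp of either
breakpoint (`inverted_local`); exact match in the supplied sequence set
(`distal_templated`); a flanking target-site duplication of at least
`t_min = 6` bases (`mobile_element_with_TSD`, with the TSD length
reported); otherwise `unknown`. Exact string matching only — alignment
heuristics are out of scope, matching the uniquely-mapping inserts the
workflow is built for. Equal-length middles classify as
`substitution_only`, which is what distinguishes SNV-driven false positives
from real losses.

`resolve_candidate` then classifies each candidate: `confirmed_deletion`
(any allele deletes at least one base), `insertion_fp`,
`sequence_variant_fp`, or `unresolved`.

## The synthetic case suite

`build_case_suite` constructs twelve cases on invented but size-realistic
gene geometries (synthetic coordinates; no genome build): deletions of
~58 kb, ~19 kb, ~3.7 kb, 2,319 bp (with a 69-bp insert templated from a
donor fragment on another chromosome — the donor interval's printed
1-based coordinates span exactly 69 bases), 1,325 bp (4-base
microhomology), 971 bp (3-base), 801 bp (11-bp inverted-local insert, with
a MIRb SINE 32 bp inside the deletion), 267 bp (2-base microhomology,
hemizygous), a compound heterozygote pairing a 3.6-kb deletion with a 12-bp
intronic deletion sitting 3 bp from a splice acceptor under a single
sense/antisense footprint, and three false positives: a 349-base
mobile-element insertion with a 16-base target-site duplication, a
hemizygous SNV under the probes, and compound-heterozygous SNVs in trans.
Reference sequences are random DNA with microhomologies and insert
junctions planted exactly (boundary mismatches installed so junctions
cannot slide further than constructed).

Per-gene design parameters differ deliberately — probe spacing 10-30 bp,
flanks 15-150 bp, strand duplication on two genes — reproducing the fact
that per-gene probe density, not deletion size alone, decides whether an
event crosses the calling threshold or must be rescued by review. One
documented size discrepancy is carried in the case-4 truth record: the
lesion is printed once as 2,318 bp and elsewhere as 2,319 bp; the suite
uses 2,319 and records the alternative.

Suite runs are deterministic in a single integer seed (per-case child
seeds derived via `numpy.random.SeedSequence`).

## Problem sizes and runtime

Per-gene manifests run 240-520 probes (targets plus backbone), sizes at
which exhaustive arc search inside CBS is exact and the full twelve-case
suite evaluates end to end in well under a minute per seed on one core.
The power analysis defaults to 200 permutations per split and toy
manifests of about 120 probes for the same reason. These sizes are the
package's chosen study conditions; nothing in the method depends on them.

## Known limitations

* Noise is i.i.d. Gaussian; no structured artifacts, so QC rejection is
  exercised only by synthetic high-noise profiles.
* The attenuation exponent and SNV window are plausible calibrations, not
  fitted to hybridization data; absolute sub-threshold signal values (for
  example the -0.29 of the two-probe case) inherit that uncertainty.
* Probe-specific behavior (the occasional normally-hybridizing probe inside
  a real deletion) is not modelled; the review machinery would tolerate it
  but the simulator never produces it.
* Junction origin assignment uses exact string matching; diverged or
  repetitive templates would resolve as `unknown`.
* The detection-limit result is conditional on the suite's probe layouts:
  a 12-bp lesion is only reviewable where a footprint covers it, which is
  exactly the probe-coverage point the workflow makes.
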