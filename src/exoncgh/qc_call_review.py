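"""Array QC (derivative log ratio), threshold calling, and manual review.

Calling follows the routine diagnostic rules: an automatic deletion call
needs a segment mean at or below -0.6 over at least four probes, a
duplication +0.4 over at least four probes.  Deletions this misses are the
point of the manual-review stage: any run of probe footprints whose mean
sits below a liberal review threshold is escalated to a candidate when at
least one of four clinical-context criteria holds:

a) the evidence comprises two entirely non-overlapping probes, or a
   sense/antisense pair over the same footprint;
b) the region overlaps a sequencing primer (possible allelic dropout);
c) the gene is recessive with one mutation already identified;
d) the gene is dominant with strong clinical suspicion.

Candidates are meant to be cheap to raise and expensive to confirm: the
screening threshold is deliberately permissive (just below the noise floor
of an accepted-quality array) because specificity comes from the downstream
breakpoint-PCR / junction-sequencing follow-up, not from the screen.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .design import GeneModel
from .segmentation import Segment
from .synthetic_data import ArrayProfile

SQRT2 = math.sqrt(2.0)

DELETION_LOG2_THRESHOLD = -0.6
DUPLICATION_LOG2_THRESHOLD = 0.4
MIN_PROBES_AUTO_CALL = 4
REVIEW_LOG2_THRESHOLD_DEFAULT = -0.10
HEMIZYGOUS_DEPTH_BAND = -2.5

DLR_ACCEPTED_MAX = 0.20   # < 0.20 accepted (0.08-0.19 band; cleaner arrays too)
DLR_BORDERLINE_MAX = 0.30  # 0.20-0.29 borderline; >= 0.30 rejected


@dataclass(frozen=True)
class DlrReport:
    dlr_value: float
    status: str  # accepted | borderline | rejected

    def __post_init__(self) -> None:
        if self.dlr_value < 0:
            raise ValueError("DLR is non-negative")


@dataclass(frozen=True)
class CallThresholds:
    deletion_log2: float = DELETION_LOG2_THRESHOLD
    duplication_log2: float = DUPLICATION_LOG2_THRESHOLD
    min_probes: int = MIN_PROBES_AUTO_CALL
    hemizygous_depth_log2: float = HEMIZYGOUS_DEPTH_BAND


@dataclass
class Call:
    segment: Segment
    call_class: str  # deletion | duplication | none
    auto: bool
    review_flags: set = field(default_factory=set)
    gene_symbol: str = ""

    def __post_init__(self) -> None:
        if self.call_class not in ("deletion", "duplication", "none"):
            raise ValueError(f"bad call class {self.call_class!r}")
        if self.auto and (self.segment.n_probes < MIN_PROBES_AUTO_CALL and self.call_class != "none"):
            # the auto flag is only legal on segments satisfying the rule
            raise ValueError("auto call on a segment below the probe minimum")


@dataclass
class ReviewContext:
    """Clinical and assay context consulted by the review criteria."""

    genes: dict[str, GeneModel] = field(default_factory=dict)
    sequencing_primer_intervals: list[tuple[str, int, int]] = field(default_factory=list)
    review_log2_threshold: float = REVIEW_LOG2_THRESHOLD_DEFAULT


_MAD_TO_SD = 1.4826022185056018  # consistency constant for Gaussian noise


def compute_dlr(profile: ArrayProfile, method: str = "robust_diff") -> DlrReport:
    """Derivative log ratio spread of a profile.

    ``robust_diff`` (default): scaled median absolute deviation of the
    consecutive-probe differences divided by sqrt(2) — estimates the
    per-probe noise sd while ignoring both true copy-number plateaus and
    the few large derivative jumps at real CNV boundaries (which would
    otherwise dominate a small gene-targeted array).  ``sd_diff`` uses the
    plain sd of the differences; ``plain_sd`` the sd of the values
    themselves (which conflates CNV signal with noise).
    """
    if len(profile) < 2:
        raise ValueError("DLR needs at least 2 probes")
    if method == "robust_diff":
        d = np.diff(profile.values)
        dlr = float(_MAD_TO_SD * np.median(np.abs(d - np.median(d))) / SQRT2)
    elif method == "sd_diff":
        dlr = float(np.std(np.diff(profile.values)) / SQRT2)
    elif method == "plain_sd":
        dlr = float(np.std(profile.values))
    else:
        raise ValueError(f"unknown DLR method {method!r}")
    return DlrReport(dlr, dlr_status(dlr))


def dlr_status(dlr: float) -> str:
    if dlr >= DLR_BORDERLINE_MAX:
        return "rejected"
    if dlr >= DLR_ACCEPTED_MAX:
        return "borderline"
    return "accepted"


def _segment_gene(segment: Segment, profile: ArrayProfile) -> str:
    genes = profile.manifest.df["gene"].to_numpy()[list(segment.probe_range)]
    named = [g for g in genes if g]
    if not named:
        return ""
    vals, counts = np.unique(named, return_counts=True)
    return str(vals[np.argmax(counts)])


def call_segments(
    segments: list[Segment],
    sample_sex: str,
    thresholds: CallThresholds | None = None,
    profile: ArrayProfile | None = None,
) -> list[Call]:
    """Threshold calling over segments.  X-linked deletion calls in an XY
    sample that are not as deep as a true hemizygous loss would be are
    flagged ``hemizygous_underdepth`` (SNV-under-probe suspects)."""
    if thresholds is None:
        thresholds = CallThresholds()
    calls: list[Call] = []
    for seg in segments:
        call_class = "none"
        auto = False
        flags: set[str] = set()
        if seg.mean_log2 <= thresholds.deletion_log2:
            call_class = "deletion"
            auto = seg.n_probes >= thresholds.min_probes
        elif seg.mean_log2 >= thresholds.duplication_log2:
            call_class = "duplication"
            auto = seg.n_probes >= thresholds.min_probes
        if (
            call_class == "deletion"
            and sample_sex == "XY"
            and seg.chrom in ("chrX", "X")
            and seg.mean_log2 > thresholds.hemizygous_depth_log2
        ):
            flags.add("hemizygous_underdepth")
        gene = _segment_gene(seg, profile) if profile is not None else ""
        calls.append(Call(segment=seg, call_class=call_class, auto=auto, review_flags=flags, gene_symbol=gene))
    return calls


def _collapse_footprints(profile: ArrayProfile) -> list[dict]:
    """Group probes sharing an identical footprint (sense/antisense pairs)
    into single evidence units, preserving manifest order."""
    df = profile.manifest.df
    footprints: list[dict] = []
    for i in range(len(df)):
        chrom, start, end = df.at[i, "chrom"], int(df.at[i, "start"]), int(df.at[i, "end"])
        if footprints and footprints[-1]["key"] == (chrom, start, end):
            footprints[-1]["indices"].append(i)
        else:
            footprints.append(
                {
                    "key": (chrom, start, end),
                    "chrom": chrom,
                    "start": start,
                    "end": end,
                    "indices": [i],
                    "gene": df.at[i, "gene"],
                    "category": df.at[i, "category"],
                }
            )
    for fp in footprints:
        fp["mean"] = float(profile.values[fp["indices"]].mean())
        fp["strands"] = set(df["strand"].to_numpy()[fp["indices"]])
    return footprints


def _criterion_a(run: list[dict], profile: ArrayProfile) -> bool:
    """Two entirely non-overlapping probes, or a same-footprint +/- pair."""
    for fp in run:
        if {"+", "-"} <= fp["strands"]:
            return True
    for i, a in enumerate(run):
        for b in run[i + 1:]:
            if a["end"] <= b["start"] or b["end"] <= a["start"]:
                return True
    return False


def review_candidates(
    profile: ArrayProfile,
    segments: list[Segment],
    calls: list[Call],
    context: ReviewContext,
) -> list[Call]:
    """Augment ``calls`` with manual-review candidates.

    Candidate = maximal run of consecutive footprints whose mean log2 sits
    below the review threshold, on one chromosome, provided at least one of
    criteria a-d holds.  Auto calls are passed through unchanged, and runs
    already inside an auto-called segment are not duplicated.
    """
    augmented = list(calls)
    auto_ranges = [
        (c.segment.chrom, c.segment.first_index, c.segment.first_index + c.segment.n_probes)
        for c in calls
        if c.auto
    ]

    footprints = _collapse_footprints(profile)
    runs: list[list[dict]] = []
    current: list[dict] = []
    for fp in footprints:
        below = fp["mean"] < context.review_log2_threshold and fp["category"] != "control"
        if below and (not current or current[-1]["chrom"] == fp["chrom"]):
            current.append(fp)
        else:
            if current:
                runs.append(current)
            current = [fp] if below else []
    if current:
        runs.append(current)

    df = profile.manifest.df
    for run in runs:
        indices = [i for fp in run for i in fp["indices"]]
        lo, hi = min(indices), max(indices) + 1
        chrom = run[0]["chrom"]
        inside_auto = any(c == chrom and lo >= a and hi <= b for c, a, b in auto_ranges)
        if inside_auto:
            continue

        gene_names = [fp["gene"] for fp in run if fp["gene"]]
        gene_symbol = gene_names[0] if gene_names else ""
        gene = context.genes.get(gene_symbol)

        flags: set[str] = set()
        if _criterion_a(run, profile):
            flags.add("two_probe_evidence")
        r_start, r_end = run[0]["start"], max(fp["end"] for fp in run)
        for p_chrom, p_start, p_end in context.sequencing_primer_intervals:
            if p_chrom == chrom and p_start < r_end and r_start < p_end:
                flags.add("primer_dropout")
                break
        if gene is not None and gene.inheritance in ("AR", "XL") and gene.known_mutation_count >= 1:
            flags.add("recessive_one_mutation")
        if gene is not None and gene.inheritance == "AD" and gene.clinical_suspicion:
            flags.add("dominant_suspicion")

        if not flags:
            continue

        mean = float(profile.values[indices].mean())
        seg = Segment(
            chrom=chrom,
            start=r_start,
            end=r_end,
            first_index=lo,
            n_probes=hi - lo,
            mean_log2=mean,
        )
        augmented.append(
            Call(segment=seg, call_class="deletion", auto=False, review_flags=flags, gene_symbol=gene_symbol)
        )
    return augmented
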