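"""Breakpoint bounding, in-silico walking primers and junction analysis.

From a deletion call, the probe layout bounds the lesion twice over: the
*inner* interval (union of the deviant probe footprints) must be at least
partially deleted, while the *outer* interval (between the nearest flanking
normal probes) caps how far the breakpoints can reach.  Walking-PCR primer
pairs are planned at increasing offsets outside the inner interval, and the
ref/alt sequence pair returned by follow-up is decomposed at the junction:
deleted length, inserted bases, breakpoint microhomology (reported with the
junction left-aligned, HGVS style), the likely origin of any insert
(inverted local sequence, distal template, mobile element with target-site
duplication), and nearby annotated repeats.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

from .design import ProbeManifest
from .qc_call_review import Call
from .synthetic_data import revcomp

INSERT_SEARCH_WINDOW_DEFAULT = 500  # bp around each breakpoint for inverted-local test
TSD_MIN_DEFAULT = 6                 # shortest accepted target-site duplication


@dataclass(frozen=True)
class BreakpointBounds:
    chrom: str
    inner: tuple[int, int]  # minimally deleted interval (span of deviant probes)
    outer: tuple[int, int]  # maximally deleted interval (between flanking normals)

    def __post_init__(self) -> None:
        if not (self.outer[0] <= self.inner[0] and self.inner[1] <= self.outer[1]):
            raise ValueError("outer interval must contain inner interval")


@dataclass(frozen=True)
class PrimerPair:
    step: int
    forward_start: int
    forward_seq: str
    forward_tm: float
    reverse_start: int
    reverse_seq: str
    reverse_tm: float
    product_bp: int  # normal-allele amplicon size


@dataclass
class PrimerPlan:
    pairs: list[PrimerPair] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)


@dataclass(frozen=True)
class PrimerParams:
    primer_length: int = 20
    tm_min: float = 52.0
    tm_max: float = 62.0
    step_bp: int = 250
    max_steps: int = 4


@dataclass
class JunctionReport:
    event_class: str  # deletion | insertion | deletion_with_insert | substitution_only | none
    deletion_length: int = 0
    microhomology_length: int = 0
    inserted_seq: str = ""
    insert_origin: str = "none"
    tsd_length: int = 0
    breakpoint_start: int = 0  # left-aligned, relative to the analyzed ref sequence
    breakpoint_end: int = 0
    nearby_repeats: list[tuple[str, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.microhomology_length < 0:
            raise ValueError("microhomology_length must be >= 0")
        if self.tsd_length > 0 and self.insert_origin != "mobile_element_with_TSD":
            raise ValueError("tsd_length only meaningful for mobile_element_with_TSD")


def bound_breakpoints(
    call: Call,
    manifest: ProbeManifest,
    profile=None,
    review_threshold: float | None = None,
) -> BreakpointBounds:
    """Min/max genomic coordinates of the aberration behind ``call``.

    inner = union span of the call's (deviant) probes; outer runs from the
    end of the nearest proximal *normal* probe to the start of the nearest
    distal normal probe, falling back to the chromosome start / the last
    probe's end when there is no flanking probe.  When ``profile`` (and a
    review threshold) is given, flanking probes that are themselves deviant
    — they may belong to the same lesion — are skipped rather than treated
    as normal anchors.
    """
    seg = call.segment
    if seg.n_probes < 1:
        raise ValueError("call references no deviant probes")
    df = manifest.df
    chrom_mask = df["chrom"] == seg.chrom
    chrom_idx = list(df.index[chrom_mask])
    lo, hi = seg.first_index, seg.first_index + seg.n_probes - 1
    inner = (int(df.at[lo, "start"]), int(df.at[hi, "end"]))

    if profile is not None and review_threshold is not None:
        deviant = profile.values < review_threshold
    else:
        deviant = None

    def is_normal(i: int) -> bool:
        return deviant is None or not deviant[i]

    before = [i for i in chrom_idx if i < lo and is_normal(i)]
    after = [i for i in chrom_idx if i > hi and is_normal(i)]
    outer_start = int(df.at[max(before), "end"]) if before else 0
    outer_end = int(df.at[min(after), "start"]) if after else int(df.loc[chrom_idx, "end"].max())
    outer_start = min(outer_start, inner[0])
    outer_end = max(outer_end, inner[1])
    return BreakpointBounds(chrom=seg.chrom, inner=inner, outer=(outer_start, outer_end))


def wallace_tm(seq: str) -> float:
    """Wallace rule melting estimate: 2(A+T) + 4(G+C).  Crude by design —
    wet-lab fidelity is out of scope, monotone length/GC behavior is not."""
    seq = seq.upper()
    return 2.0 * (seq.count("A") + seq.count("T")) + 4.0 * (seq.count("G") + seq.count("C"))


def _pick_primer(ref: str, window: tuple[int, int], params: PrimerParams, reverse: bool) -> tuple[int, str, float] | None:
    """First admissible primer (ACGT-only, Tm in band) in the window."""
    w_start = max(0, window[0])
    w_end = min(len(ref), window[1])
    for pos in range(w_start, w_end - params.primer_length + 1):
        seq = ref[pos: pos + params.primer_length]
        if any(b not in "ACGT" for b in seq.upper()):
            continue
        oriented = revcomp(seq) if reverse else seq
        tm = wallace_tm(oriented)
        if params.tm_min <= tm <= params.tm_max:
            return pos, oriented, tm
    return None


def design_walking_primers(
    bounds: BreakpointBounds,
    ref_seq: str,
    params: PrimerParams | None = None,
    ref_offset: int = 0,
) -> PrimerPlan:
    """Plan primer pairs walking outward from the inner interval.

    ``ref_seq`` covers the outer interval (genomic offset ``ref_offset``).
    Step k places the forward primer in the k-th window proximal to
    inner.start and the reverse primer in the k-th window distal to
    inner.end; windows without an admissible primer are skipped with a
    warning.  Steps widen monotonically.
    """
    if params is None:
        params = PrimerParams()
    plan = PrimerPlan()
    inner_lo = bounds.inner[0] - ref_offset
    inner_hi = bounds.inner[1] - ref_offset
    n_steps = 1 if bounds.inner == bounds.outer else params.max_steps
    for k in range(n_steps):
        f_window = (inner_lo - (k + 1) * params.step_bp, inner_lo - k * params.step_bp)
        r_window = (inner_hi + k * params.step_bp, inner_hi + (k + 1) * params.step_bp)
        fwd = _pick_primer(ref_seq, f_window, params, reverse=False)
        rev = _pick_primer(ref_seq, r_window, params, reverse=True)
        if fwd is None or rev is None:
            plan.warnings.append(f"step {k}: no admissible primer in window")
            continue
        product = (rev[0] + params.primer_length) - fwd[0]
        plan.pairs.append(
            PrimerPair(
                step=k,
                forward_start=fwd[0] + ref_offset,
                forward_seq=fwd[1],
                forward_tm=fwd[2],
                reverse_start=rev[0] + ref_offset,
                reverse_seq=rev[1],
                reverse_tm=rev[2],
                product_bp=product,
            )
        )
    return plan


def predicted_junction_amplicon(pair: PrimerPair, deletion_bp: int, insert_bp: int = 0) -> int:
    """Expected deleted-allele amplicon size for a candidate deletion."""
    return pair.product_bp - deletion_bp + insert_bp


def _common_prefix_len(a: str, b: str) -> int:
    n = min(len(a), len(b))
    for i in range(n):
        if a[i] != b[i]:
            return i
    return n


def _common_suffix_len(a: str, b: str) -> int:
    n = min(len(a), len(b))
    for i in range(1, n + 1):
        if a[-i] != b[-i]:
            return i - 1
    return n


def analyze_junction(
    ref_seq: str,
    alt_seq: str,
    search_fixture: Mapping[str, str] | None = None,
    insert_search_window: int = INSERT_SEARCH_WINDOW_DEFAULT,
    tsd_min: int = TSD_MIN_DEFAULT,
) -> JunctionReport:
    """Decompose a ref/alt sequence pair sharing flanking context.

    The junction is located from the longest common prefix/suffix (trimmed
    so they never overlap); breakpoints are reported left-aligned and the
    ambiguity of the placement — the breakpoint microhomology — separately.
    The origin of inserted bases is tested in order: reverse-complement
    match near either breakpoint (inverted_local), exact match in the
    supplied sequence set (distal_templated), then a flanking target-site
    duplication of at least ``tsd_min`` bases (mobile_element_with_TSD).
    """
    if ref_seq == alt_seq:
        return JunctionReport(event_class="none")

    max_p = _common_prefix_len(ref_seq, alt_seq)
    max_s = _common_suffix_len(ref_seq, alt_seq)
    if max_p == 0 and max_s == 0:
        warnings.warn("ref and alt share no flanking context")
        return JunctionReport(event_class="none")

    min_len = min(len(ref_seq), len(alt_seq))
    p = min(max_p, min_len)
    s = min(max_s, min_len - p)
    del_len = len(ref_seq) - p - s
    inserted = alt_seq[p: len(alt_seq) - s]

    # placement ambiguity: how far the junction can slide while producing
    # the same alt sequence
    mh = max(0, max_p + max_s - min_len) if (del_len == 0 or not inserted) else 0

    bp_start = max_p - mh  # left-aligned
    bp_end = bp_start + del_len

    if del_len > 0 and not inserted:
        event_class = "deletion"
    elif del_len == 0 and inserted:
        event_class = "insertion"
    elif del_len > 0 and inserted:
        event_class = "substitution_only" if len(ref_seq) == len(alt_seq) and del_len == len(inserted) else "deletion_with_insert"
    else:  # pragma: no cover - ref == alt handled above
        event_class = "none"

    origin = "none"
    tsd_len = 0
    if inserted and event_class != "substitution_only":
        origin = "unknown"
        w = insert_search_window
        near = (
            ref_seq[max(0, bp_start - w): bp_start + w]
            + " "
            + ref_seq[max(0, bp_end - w): bp_end + w]
        )
        if revcomp(inserted) in near:
            origin = "inverted_local"
        elif search_fixture and any(inserted in seq for seq in search_fixture.values()):
            origin = "distal_templated"
        else:
            prefix = alt_seq[:p]
            t = 0
            limit = min(len(inserted), len(prefix))
            for k in range(limit, tsd_min - 1, -1):
                if inserted[-k:] == prefix[-k:]:
                    t = k
                    break
            if t >= tsd_min:
                origin = "mobile_element_with_TSD"
                tsd_len = t

    if event_class == "substitution_only":
        return JunctionReport(
            event_class=event_class,
            deletion_length=0,
            microhomology_length=0,
            inserted_seq=inserted,
            insert_origin="none",
            breakpoint_start=bp_start,
            breakpoint_end=bp_end,
        )
    return JunctionReport(
        event_class=event_class,
        deletion_length=del_len,
        microhomology_length=mh,
        inserted_seq=inserted,
        insert_origin=origin if inserted else "none",
        tsd_length=tsd_len,
        breakpoint_start=bp_start,
        breakpoint_end=bp_end,
    )


def annotate_repeats(
    interval: tuple[str, int, int],
    repeat_track: Sequence[tuple[str, int, int, str]],
    window: int = 1000,
) -> list[tuple[str, int]]:
    """Repeats overlapping or within ``window`` bp (closed) of the interval.

    Distance is to the nearest breakpoint (interval endpoint): positive when
    the repeat lies inside the interval, negative outside, zero when it
    straddles a breakpoint.
    """
    chrom, start, end = interval
    out: list[tuple[str, int]] = []
    for r_chrom, r_start, r_end, name in repeat_track:
        if r_chrom != chrom:
            continue
        if r_end < start - window or r_start > end + window:
            continue
        straddles = (r_start < start < r_end) or (r_start < end < r_end)
        if straddles:
            dist = 0
        elif r_start >= start and r_end <= end:  # inside
            dist = min(r_start - start, end - r_end)
        else:  # outside
            gap = min(abs(start - r_end), abs(r_start - end))
            if gap > window:
                continue
            dist = -gap
        out.append((name, dist))
    return out


def resolve_candidate(
    call: Call,
    ref_seq: str,
    allele_seqs: Mapping[str, str],
    search_fixture: Mapping[str, str] | None = None,
    **junction_kwargs,
) -> tuple[str, JunctionReport | None]:
    """Classify a candidate from its follow-up sequences.

    confirmed_deletion — an allele shows a junction deleting >= 1 base;
    insertion_fp — pure insertion under the probes;
    sequence_variant_fp — alleles differ from reference only by
    substitutions; unresolved — no allele shows any event.
    """
    reports = [analyze_junction(ref_seq, alt, search_fixture, **junction_kwargs) for alt in allele_seqs.values()]
    deletions = [r for r in reports if r.event_class in ("deletion", "deletion_with_insert") and r.deletion_length >= 1]
    if deletions:
        best = min(deletions, key=lambda r: r.deletion_length)
        return "confirmed_deletion", best
    insertions = [r for r in reports if r.event_class == "insertion"]
    if insertions:
        return "insertion_fp", insertions[0]
    substitutions = [r for r in reports if r.event_class == "substitution_only"]
    if substitutions:
        return "sequence_variant_fp", substitutions[0]
    return "unresolved", None
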