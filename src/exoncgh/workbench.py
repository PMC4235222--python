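"""End-to-end pipeline driver, case-suite evaluation and power analysis.

``run_pipeline`` chains QC -> median centering -> segmentation -> threshold
calling -> manual-review escalation -> breakpoint bounding, mirroring the
routine diagnostic workflow (an array failing DLR QC is rejected outright;
data can be masked to the single gene ordered for testing).

``evaluate_suite`` pushes every synthetic case through the pipeline plus the
simulated sequence follow-up, resolving each candidate to a confirmed
deletion or a false-positive mechanism, and summarizes the detection limit
(the smallest confirmed deletion).

``power_analysis`` maps the detection fraction over a grid of deletion
sizes, probe densities and noise levels.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field, replace

import numpy as np

from .breakpoints import BreakpointBounds, JunctionReport, bound_breakpoints, resolve_candidate
from .cases import Case, build_case_suite
from .design import DesignParams, GeneModel, ProbeManifest, build_manifest
from .qc_call_review import (
    Call,
    CallThresholds,
    DlrReport,
    ReviewContext,
    call_segments,
    compute_dlr,
    review_candidates,
)
from .segmentation import CbsParams, Segment, cbs_segment, median_center
from .synthetic_data import ArrayProfile, Event, GenotypeSpec, NoiseModel, simulate_profile

logger = logging.getLogger("exoncgh")


@dataclass
class PipelineConfig:
    cbs: CbsParams = field(default_factory=CbsParams)
    thresholds: CallThresholds = field(default_factory=CallThresholds)
    gene_mask: str | None = None

    def resolved(self) -> dict:
        return {"cbs": asdict(self.cbs), "thresholds": asdict(self.thresholds), "gene_mask": self.gene_mask}


@dataclass
class PipelineReport:
    status: str  # ok | rejected
    dlr: DlrReport
    segments: list[Segment] = field(default_factory=list)
    calls: list[Call] = field(default_factory=list)
    candidates: list[Call] = field(default_factory=list)
    bounds: list[BreakpointBounds] = field(default_factory=list)
    config: dict = field(default_factory=dict)


@dataclass
class CaseOutcome:
    case_id: int
    gene: str
    truth: dict
    detected: str  # auto_call | review_candidate | missed
    resolutions: list[tuple[str, JunctionReport | None]] = field(default_factory=list)
    confirmed_deletions: list[int] = field(default_factory=list)
    detected_size: int | None = None
    review_flags: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.detected_size is not None and not self.confirmed_deletions:
            raise ValueError("detected_size requires a confirmed deletion")


@dataclass
class PowerCurve:
    deletion_sizes: list[int]
    probe_counts: list[int]
    noise_sds: list[float]
    n_reps: int
    auto_fraction: np.ndarray       # [size, probes, noise]
    candidate_fraction: np.ndarray  # auto or review candidate


def run_pipeline(
    manifest: ProbeManifest,
    profile: ArrayProfile,
    context: ReviewContext | None = None,
    config: PipelineConfig | None = None,
) -> PipelineReport:
    """QC-gated segmentation, calling and review for one hybridization."""
    if config is None:
        config = PipelineConfig()
    if context is None:
        context = ReviewContext()
    resolved = config.resolved()
    logger.info("pipeline config: %s", json.dumps(resolved, default=str))

    dlr = compute_dlr(profile)
    logger.info("DLR %.4f -> %s", dlr.dlr_value, dlr.status)
    if dlr.status == "rejected":
        return PipelineReport(status="rejected", dlr=dlr, config=resolved)

    centered = median_center(profile)
    segments = cbs_segment(centered, config.cbs)
    calls = call_segments(segments, profile.sample_sex, config.thresholds, profile=centered)
    reported = review_candidates(centered, segments, calls, context)

    if config.gene_mask is not None:
        reported = [c for c in reported if c.gene_symbol == config.gene_mask]

    interesting = [c for c in reported if c.auto or (not c.auto and c.review_flags)]
    deviant = [c for c in interesting if c.call_class in ("deletion", "duplication")]
    bounds = [
        bound_breakpoints(c, manifest, profile=centered, review_threshold=context.review_log2_threshold)
        for c in deviant
    ]

    logger.info(
        "segments=%d auto_calls=%d candidates=%d",
        len(segments), sum(c.auto for c in reported), len(deviant),
    )
    return PipelineReport(
        status="ok", dlr=dlr, segments=segments, calls=calls,
        candidates=deviant, bounds=bounds, config=resolved,
    )


def _followup_region(b: BreakpointBounds, fixture_len: int, margin: int = 150) -> tuple[int, int]:
    lo = max(0, b.outer[0] - margin)
    hi = min(fixture_len, b.outer[1] + margin)
    return lo, hi


def evaluate_case(case: Case, config: PipelineConfig | None = None) -> CaseOutcome:
    """Run one suite case end-to-end including simulated sequence follow-up."""
    from .synthetic_data import emit_local_sequence

    if config is None:
        config = PipelineConfig(gene_mask=case.gene)
    report = run_pipeline(case.manifest, case.profile, case.context, config)

    resolutions: list[tuple[str, JunctionReport | None]] = []
    confirmed: list[int] = []
    flags: set[str] = set()
    truth_hit_auto = False
    truth_hit_review = False
    truth_events = case.genotype.all_events()

    for call, bounds in zip(report.candidates, report.bounds):
        flags.update(call.review_flags)
        chrom = bounds.chrom
        fixture = case.ref_fixture[chrom]
        lo, hi = _followup_region(bounds, len(fixture))
        ref_seq = fixture[lo:hi]
        alleles = emit_local_sequence(case.genotype, case.ref_fixture, (chrom, lo, hi))
        resolution, junction = resolve_candidate(call, ref_seq, alleles, case.search_fixture)
        resolutions.append((resolution, junction))
        if resolution == "confirmed_deletion" and junction is not None:
            confirmed.append(junction.deletion_length)
        overlaps_truth = any(
            ev.chrom == chrom and max(ev.start, bounds.outer[0]) <= min(ev.end, bounds.outer[1])
            for ev in truth_events
        )
        if overlaps_truth:
            if call.auto:
                truth_hit_auto = True
            else:
                truth_hit_review = True

    if truth_hit_auto:
        detected = "auto_call"
    elif truth_hit_review:
        detected = "review_candidate"
    else:
        detected = "missed" if case.truth["expected_class"] == "deletion" else "no_call"

    confirmed = sorted(set(confirmed))
    return CaseOutcome(
        case_id=case.case_id,
        gene=case.gene,
        truth=case.truth,
        detected=detected,
        resolutions=resolutions,
        confirmed_deletions=confirmed,
        detected_size=min(confirmed) if confirmed else None,
        review_flags=sorted(flags),
    )


def evaluate_suite(
    seed: int = 0,
    probe_sd: float = 0.12,
    config: PipelineConfig | None = None,
    cases: list[Case] | None = None,
) -> tuple[list[CaseOutcome], dict]:
    """Run the twelve-case suite; returns per-case outcomes and a summary
    with the detection limit (smallest confirmed deletion, bp)."""
    if cases is None:
        cases = build_case_suite(seed=seed, probe_sd=probe_sd)
    outcomes = []
    for case in cases:
        case_config = config if config is not None else PipelineConfig(gene_mask=case.gene)
        if config is not None and config.gene_mask is None:
            case_config = replace(config, gene_mask=case.gene)
        outcomes.append(evaluate_case(case, case_config))

    all_confirmed = sorted(size for o in outcomes for size in o.confirmed_deletions)
    fp_resolutions = {
        o.case_id: sorted({r for r, _ in o.resolutions if r != "unresolved"})
        for o in outcomes
        if o.truth["expected_class"] == "no_deletion"
    }
    summary = {
        "n_cases": len(outcomes),
        "smallest_confirmed_deletion_bp": min(all_confirmed) if all_confirmed else None,
        "confirmed_deletions_bp": all_confirmed,
        "n_detected": sum(o.detected in ("auto_call", "review_candidate") for o in outcomes),
        "false_positive_resolutions": fp_resolutions,
    }
    return outcomes, summary


def power_analysis(
    deletion_sizes: list[int],
    probe_counts: list[int],
    noise_sds: list[float],
    n_reps: int = 50,
    seed: int = 0,
    cbs: CbsParams | None = None,
    review_threshold: float | None = None,
) -> PowerCurve:
    """Detection fraction (auto call / any candidate) over a simulation grid.

    Each cell simulates a heterozygous deletion spanning ``probe_count``
    consecutive probes of a single-exon toy gene and asks whether the
    pipeline auto-calls it or at least escalates it to review.
    """
    if not deletion_sizes or not probe_counts or not noise_sds:
        raise ValueError("grids must be non-empty")
    if cbs is None:
        cbs = CbsParams(n_permutations=200)
    auto = np.zeros((len(deletion_sizes), len(probe_counts), len(noise_sds)))
    cand = np.zeros_like(auto)
    ss = np.random.SeedSequence(seed)

    for a, size in enumerate(deletion_sizes):
        for b, n_probes in enumerate(probe_counts):
            manifest, del_start, del_end = _power_manifest(size, n_probes)
            if size > 0:
                events = (Event("deletion", "chr1", del_start, del_end),)
            else:
                events = ()
            genotype = GenotypeSpec("XX", allele1=events)
            gene = GeneModel("TOY", "chr1", "+", ((del_start - 1, del_end + 1),), "AR", 1, False)
            context = ReviewContext(genes={"TOY": gene})
            if review_threshold is not None:
                context.review_log2_threshold = review_threshold
            for c, sd in enumerate(noise_sds):
                hits_auto = 0
                hits_cand = 0
                for child in ss.spawn(n_reps):
                    noise_seed = int(child.generate_state(1)[0] % (2**31))
                    profile = simulate_profile(manifest, genotype, NoiseModel(sd, noise_seed))
                    rep = run_pipeline(manifest, profile, context,
                                       PipelineConfig(cbs=replace(cbs, seed=noise_seed)))
                    dels = [cc for cc in rep.candidates if cc.call_class == "deletion"]
                    if size > 0:
                        dels = [
                            cc for cc in dels
                            if cc.segment.chrom == "chr1"
                            and cc.segment.start < del_end and del_start < cc.segment.end
                        ]
                    if any(cc.auto for cc in dels):
                        hits_auto += 1
                    if dels:
                        hits_cand += 1
                auto[a, b, c] = hits_auto / n_reps
                cand[a, b, c] = hits_cand / n_reps
    return PowerCurve(deletion_sizes, probe_counts, noise_sds, n_reps, auto, cand)


def _power_manifest(size: int, n_probes: int, probe_length: int = 60,
                    n_flank: int = 30) -> tuple[ProbeManifest, int, int]:
    """Toy single-locus array: ``n_probes`` target probes over a ``size``-bp
    lesion (fully covered probes when the lesion is probe-sized or larger;
    otherwise probes each containing the small lesion), flanked by normal
    probes on both sides."""
    import pandas as pd

    del_start = 100_000
    del_end = del_start + max(size, 1)
    records = []
    if size >= probe_length:
        span = size - probe_length
        step = span // max(n_probes - 1, 1)
        positions = [del_start + min(i * step, span) for i in range(n_probes)]
    else:
        # small lesion: stagger probes so each footprint contains it
        positions = [max(0, del_start + size - probe_length + 5 * i) for i in range(n_probes)]
        positions = [min(p, del_start) for p in positions]
    for i, p in enumerate(sorted(set(positions))):
        records.append(("chr1", p, p + probe_length, f"TOY_t{i:04d}", "target", "+", "TOY"))
    left = del_start - 500
    right = del_end + 500
    for i in range(n_flank):
        s = left - i * 100
        records.append(("chr1", s - probe_length, s, f"fl_l{i:04d}", "target", "+", "TOY"))
        s = right + i * 100
        records.append(("chr1", s, s + probe_length, f"fl_r{i:04d}", "target", "+", "TOY"))
    df = pd.DataFrame(records, columns=["chrom", "start", "end", "probe_id", "category", "strand", "gene"])
    return ProbeManifest(df), del_start, del_end
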