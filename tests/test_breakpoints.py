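"""Breakpoint bounding, primer walking and junction characterization."""

import numpy as np
import pytest

from conftest import make_manifest, make_profile
from exoncgh.breakpoints import (
    PrimerParams,
    analyze_junction,
    annotate_repeats,
    bound_breakpoints,
    design_walking_primers,
    predicted_junction_amplicon,
    resolve_candidate,
)
from exoncgh.qc_call_review import Call
from exoncgh.segmentation import Segment
from exoncgh.synthetic_data import plant_microhomology, random_dna, revcomp


def call_over(first, n, manifest, mean=-1.0):
    df = manifest.df
    seg = Segment(
        chrom=df.at[first, "chrom"],
        start=int(df.at[first, "start"]),
        end=int(df.at[first + n - 1, "end"]),
        first_index=first,
        n_probes=n,
        mean_log2=mean,
    )
    return Call(segment=seg, call_class="deletion", auto=n >= 4)


class TestBounds:
    def test_inner_outer_by_construction(self):
        m = make_manifest(n_probes=20, spacing=100)  # probes at 100000+100i
        c = call_over(5, 3, m)
        b = bound_breakpoints(c, m)
        assert b.inner == (100_500, 100_760)
        assert b.outer == (100_460, 100_800)
        assert b.outer[0] <= b.inner[0] and b.inner[1] <= b.outer[1]

    def test_first_probe_on_chromosome_extends_to_start(self):
        m = make_manifest(n_probes=10)
        b = bound_breakpoints(call_over(0, 2, m), m)
        assert b.outer[0] == 0

    def test_deviant_flanks_skipped_when_profile_given(self):
        m = make_manifest(n_probes=20, spacing=100)
        x = np.zeros(20)
        x[5:12] = -1.0  # true lesion
        prof = make_profile(x, manifest=m)
        # a call covering only part of the lesion must not anchor its outer
        # bound on a still-deviant probe
        b = bound_breakpoints(call_over(5, 3, m), m, profile=prof, review_threshold=-0.1)
        assert b.outer[1] == int(m.df.at[12, "start"])

    def test_simulated_truth_inside_outer_outside_inner(self):
        from exoncgh.synthetic_data import Event, GenotypeSpec, NoiseModel, simulate_profile

        m = make_manifest(n_probes=40, spacing=100)
        start, end = 100_970, 101_970  # breakpoints between probe footprints
        g = GenotypeSpec("XX", allele1=(Event("deletion", "chr1", start, end),))
        prof = simulate_profile(m, g, NoiseModel(0.0, 0))
        deviant = np.flatnonzero(prof.values < -0.1)
        c = call_over(int(deviant[0]), len(deviant), m)
        b = bound_breakpoints(c, m, profile=prof, review_threshold=-0.1)
        assert b.outer[0] <= start and end <= b.outer[1]
        assert b.inner[0] >= start and end >= b.inner[1]


class TestPrimers:
    def setup_method(self):
        rng = np.random.default_rng(31)
        self.ref = random_dna(6_000, rng)

    def test_walking_steps_widen_monotonically(self):
        from exoncgh.breakpoints import BreakpointBounds

        b = BreakpointBounds("chr1", (2_500, 3_000), (2_000, 3_500))
        plan = design_walking_primers(b, self.ref, PrimerParams(step_bp=200, max_steps=3))
        assert plan.pairs, plan.warnings
        fwd = [p.forward_start for p in plan.pairs]
        rev = [p.reverse_start for p in plan.pairs]
        assert fwd == sorted(fwd, reverse=True)
        assert rev == sorted(rev)
        for p in plan.pairs:
            assert p.forward_start + len(p.forward_seq) <= 2_500
            assert p.reverse_start >= 3_000
            assert 18 <= len(p.forward_seq) <= 30

    def test_degenerate_bounds_single_pair(self):
        from exoncgh.breakpoints import BreakpointBounds

        b = BreakpointBounds("chr1", (2_500, 3_000), (2_500, 3_000))
        plan = design_walking_primers(b, self.ref, PrimerParams(step_bp=200))
        assert len(plan.pairs) <= 1

    def test_all_n_reference_empty_plan_with_warnings(self):
        from exoncgh.breakpoints import BreakpointBounds

        b = BreakpointBounds("chr1", (2_500, 3_000), (2_000, 3_500))
        plan = design_walking_primers(b, "N" * 6_000, PrimerParams(step_bp=200, max_steps=2))
        assert plan.pairs == []
        assert len(plan.warnings) == 2

    def test_predicted_deleted_allele_amplicon(self):
        from exoncgh.breakpoints import BreakpointBounds

        b = BreakpointBounds("chr1", (2_500, 3_000), (2_200, 3_300))
        plan = design_walking_primers(b, self.ref, PrimerParams(step_bp=200, max_steps=1))
        pair = plan.pairs[0]
        # 2,319-bp deletion with a 69-bp insert between the breakpoints
        assert predicted_junction_amplicon(pair, 2_319, 69) == pair.product_bp - 2_319 + 69


def build_deletion_alt(ref, start, end, ins=""):
    return ref[:start] + ins + ref[end:]


class TestJunction:
    def test_identity_is_no_event(self):
        rng = np.random.default_rng(41)
        ref = random_dna(300, rng)
        rep = analyze_junction(ref, ref)
        assert rep.event_class == "none"
        assert rep.deletion_length == 0
        assert rep.inserted_seq == ""

    @pytest.mark.parametrize("del_len,mh", [(1, 0), (12, 0), (12, 4), (100, 7), (971, 3), (1_325, 4)])
    def test_deletion_round_trip(self, del_len, mh):
        rng = np.random.default_rng(del_len + mh)
        ref = random_dna(del_len + 500, rng)
        start = 200
        ref = plant_microhomology(ref, start, start + del_len, mh)
        alt = build_deletion_alt(ref, start, start + del_len)
        rep = analyze_junction(ref, alt)
        assert rep.event_class == "deletion"
        assert rep.deletion_length == del_len
        assert rep.microhomology_length == mh
        assert rep.breakpoint_start == start
        assert rep.breakpoint_end == start + del_len

    def test_microhomology_symmetric_under_revcomp(self):
        rng = np.random.default_rng(43)
        ref = random_dna(800, rng)
        ref = plant_microhomology(ref, 300, 500, 5)
        alt = build_deletion_alt(ref, 300, 500)
        fwd = analyze_junction(ref, alt)
        rev = analyze_junction(revcomp(ref), revcomp(alt))
        assert rev.microhomology_length == fwd.microhomology_length == 5
        assert rev.deletion_length == fwd.deletion_length

    def test_substitution_only(self):
        rng = np.random.default_rng(44)
        ref = random_dna(200, rng)
        alt = ref[:100] + ("A" if ref[100] != "A" else "C") + ref[101:]
        rep = analyze_junction(ref, alt)
        assert rep.event_class == "substitution_only"
        assert rep.deletion_length == 0

    def test_inverted_local_insert_origin(self):
        rng = np.random.default_rng(45)
        ref = random_dna(2_000, rng)
        start, end = 500, 1_301  # 801-bp deletion
        ins = revcomp(ref[end:end + 11])
        if ref[start] == ins[0]:
            ref = ref[:start] + ("A" if ins[0] != "A" else "C") + ref[start + 1:]
        if ref[end - 1] == ins[-1]:
            ref = ref[:end - 1] + ("A" if ins[-1] != "A" else "C") + ref[end:]
        alt = build_deletion_alt(ref, start, end, ins)
        rep = analyze_junction(ref, alt)
        assert rep.event_class == "deletion_with_insert"
        assert rep.deletion_length == 801
        assert rep.inserted_seq == ins
        assert rep.insert_origin == "inverted_local"

    def test_distal_templated_insert_origin(self):
        rng = np.random.default_rng(46)
        ref = random_dna(3_000, rng)
        donor = random_dna(69, rng)
        start, end = 400, 2_719  # 2,319-bp deletion
        if ref[start] == donor[0]:
            ref = ref[:start] + ("A" if donor[0] != "A" else "C") + ref[start + 1:]
        if ref[end - 1] == donor[-1]:
            ref = ref[:end - 1] + ("A" if donor[-1] != "A" else "C") + ref[end:]
        alt = build_deletion_alt(ref, start, end, donor)
        rep = analyze_junction(ref, alt, search_fixture={"chr5": "TTTT" + donor + "GGGG"})
        assert rep.deletion_length == 2_319
        assert rep.insert_origin == "distal_templated"

    def test_target_site_duplication_detected(self):
        rng = np.random.default_rng(47)
        ref = random_dna(1_000, rng)
        q = 400
        element = random_dna(333, rng)
        if element[0] == ref[q]:
            element = ("A" if ref[q] != "A" else "C") + element[1:]
        if element[-1] == ref[q - 17]:
            element = element[:-1] + ("A" if ref[q - 17] != "A" else "C")
        ins = element + ref[q - 16:q]
        alt = ref[:q] + ins + ref[q:]
        rep = analyze_junction(ref, alt)
        assert rep.event_class == "insertion"
        assert rep.deletion_length == 0
        assert len(rep.inserted_seq) == 349
        assert rep.insert_origin == "mobile_element_with_TSD"
        assert rep.tsd_length == 16

    def test_disjoint_sequences_warn(self):
        with pytest.warns(UserWarning):
            rep = analyze_junction("AAAAAA", "CCCCCC")
        assert rep.event_class == "none"


class TestAnnotateRepeats:
    track = [
        ("chr12", 30_669, 30_849, "MIRb"),
        ("chr12", 50_000, 50_300, "AluY"),
        ("chr1", 100, 200, "L1"),
    ]

    def test_repeat_inside_deletion_distance_to_breakpoint(self):
        hits = annotate_repeats(("chr12", 30_080, 30_881), self.track)
        assert ("MIRb", 32) in hits

    def test_empty_track(self):
        assert annotate_repeats(("chr12", 0, 1_000), []) == []

    def test_window_edge_inclusive(self):
        hits = annotate_repeats(("chr12", 49_000, 49_500), self.track, window=500)
        assert ("AluY", -500) in hits
        assert annotate_repeats(("chr12", 48_000, 48_500), self.track, window=500) == []

    def test_other_chromosome_ignored(self):
        assert annotate_repeats(("chr2", 0, 10**6), self.track) == []


class TestResolveCandidate:
    def _call(self):
        m = make_manifest(n_probes=4)
        return call_over(1, 2, m)

    def test_confirmed_deletion(self):
        rng = np.random.default_rng(51)
        ref = random_dna(500, rng)
        ref = plant_microhomology(ref, 200, 212, 0)
        alt = build_deletion_alt(ref, 200, 212)
        res, rep = resolve_candidate(self._call(), ref, {"allele1": alt, "allele2": ref})
        assert res == "confirmed_deletion"
        assert rep.deletion_length == 12

    def test_substitutions_resolve_as_sequence_variant(self):
        rng = np.random.default_rng(52)
        ref = random_dna(400, rng)
        alt = ref[:150] + ("G" if ref[150] != "G" else "T") + ref[151:]
        res, _ = resolve_candidate(self._call(), ref, {"allele1": alt})
        assert res == "sequence_variant_fp"

    def test_pure_insertion_resolves_as_insertion_fp(self):
        rng = np.random.default_rng(53)
        ref = random_dna(400, rng)
        alt = ref[:200] + random_dna(349, rng) + ref[200:]
        res, rep = resolve_candidate(self._call(), ref, {"allele1": alt, "allele2": ref})
        assert res == "insertion_fp"
        assert len(rep.inserted_seq) == 349

    def test_no_event_unresolved(self):
        rng = np.random.default_rng(54)
        ref = random_dna(400, rng)
        res, rep = resolve_candidate(self._call(), ref, {"allele1": ref, "allele2": ref})
        assert res == "unresolved"
        assert rep is None
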