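"""Hybridization model: copy ratios, probe attenuation, simulation, sequences."""

import math

import numpy as np
import pytest

from conftest import make_manifest
from exoncgh.design import Probe
from exoncgh.synthetic_data import (
    Event,
    GenotypeSpec,
    NoiseModel,
    emit_local_sequence,
    expected_log2,
    plant_microhomology,
    probe_efficiency,
    random_dna,
    revcomp,
    simulate_profile,
)


class TestExpectedLog2:
    @pytest.mark.parametrize(
        "test,ref,value",
        [(1, 2, -1.0), (2, 2, 0.0), (3, 2, math.log2(1.5)), (4, 2, 1.0), (1, 1, 0.0)],
    )
    def test_copy_states(self, test, ref, value):
        assert expected_log2(test, ref) == pytest.approx(value)

    def test_duplication_prints_as_059(self):
        assert round(expected_log2(3, 2), 2) in (0.58, 0.59)

    def test_zero_copies_floored_at_background(self):
        assert expected_log2(0, 1, eps=0.1) == pytest.approx(math.log2(0.1))

    def test_negative_copies_rejected(self):
        with pytest.raises(ValueError):
            expected_log2(-1, 2)
        with pytest.raises(ValueError):
            expected_log2(1, 0)


class TestProbeEfficiency:
    probe = Probe("p", "chr1", 100, 160)

    def test_full_deletion_kills_signal(self):
        assert probe_efficiency(self.probe, [Event("deletion", "chr1", 50, 200)]) == 0.0

    def test_no_overlap_full_signal(self):
        assert probe_efficiency(self.probe, [Event("deletion", "chr1", 300, 400)]) == 1.0
        assert probe_efficiency(self.probe, []) == 1.0

    def test_partial_deletion_squared_attenuation(self):
        # 12 of 60 bases deleted, alpha=2 -> (48/60)^2
        eff = probe_efficiency(self.probe, [Event("deletion", "chr1", 110, 122)], alpha=2)
        assert eff == pytest.approx((48 / 60) ** 2)

    def test_insertion_keeps_longest_block(self):
        # insert at 140 splits the footprint 40 | 20
        eff = probe_efficiency(self.probe, [Event("insertion", "chr1", 140, 140, inserted_seq="A" * 100)])
        assert eff == pytest.approx((40 / 60) ** 2)

    def test_snv_disrupts_fixed_window(self):
        eff = probe_efficiency(self.probe, [Event("snv", "chr1", 130, 131, alt="A")], w_snv=15)
        assert eff == pytest.approx((45 / 60) ** 2)

    def test_snv_window_clipped_at_probe_edge(self):
        eff = probe_efficiency(self.probe, [Event("snv", "chr1", 100, 101, alt="A")], w_snv=15)
        # window [93, 108) clipped to [100, 108): 8 disrupted bases
        assert eff == pytest.approx((52 / 60) ** 2)

    def test_monotone_in_deleted_fraction(self):
        effs = [
            probe_efficiency(self.probe, [Event("deletion", "chr1", 100, 100 + k)])
            for k in range(1, 61)
        ]
        assert all(a >= b for a, b in zip(effs, effs[1:]))


class TestSimulateProfile:
    def test_noise_free_het_deletion_exact_ratios(self):
        m = make_manifest(n_probes=30, spacing=100)
        # deletion covering probes 10..19 completely
        start = 100_000 + 10 * 100
        end = 100_000 + 19 * 100 + 60
        g = GenotypeSpec("XX", allele1=(Event("deletion", "chr1", start, end),))
        prof = simulate_profile(m, g, NoiseModel(0.0, 0))
        assert np.allclose(prof.values[10:20], -1.0)
        assert np.allclose(np.delete(prof.values, range(10, 20)), 0.0)

    def test_hemizygous_deletion_drops_below_minus_three(self):
        m = make_manifest(n_probes=5, spacing=100, chrom="chrX")
        ev = Event("deletion", "chrX", 100_000, 100_260)
        g = GenotypeSpec("XY", allele1=(ev,))
        prof = simulate_profile(m, g, NoiseModel(0.0, 0))
        assert (prof.values[:2] <= -3).all()

    def test_sense_antisense_pair_small_deletion_value(self):
        # a 12-bp deletion under a duplicated-strand footprint: both probes
        # read log2((1 + 0.64)/2) ~= -0.286
        import pandas as pd

        from exoncgh.design import ProbeManifest

        rows = [
            ("chr1", 100_000, 100_060, "a+", "target", "+", "G"),
            ("chr1", 100_000, 100_060, "a-", "target", "-", "G"),
            ("chr1", 100_200, 100_260, "b+", "target", "+", "G"),
        ]
        m = ProbeManifest(pd.DataFrame(rows, columns=["chrom", "start", "end", "probe_id", "category", "strand", "gene"]))
        g = GenotypeSpec("XX", allele1=(Event("deletion", "chr1", 100_010, 100_022),))
        prof = simulate_profile(m, g, NoiseModel(0.0, 0))
        expected = math.log2((1 + 0.64) / 2)
        assert prof.values[0] == pytest.approx(expected)
        assert prof.values[1] == pytest.approx(expected)
        assert prof.values[2] == 0.0

    def test_no_events_all_zero(self):
        m = make_manifest(n_probes=20)
        prof = simulate_profile(m, GenotypeSpec("XX"), NoiseModel(0.0, 0))
        assert np.all(prof.values == 0.0)

    def test_seed_reproducibility(self):
        m = make_manifest(n_probes=50)
        g = GenotypeSpec("XX", allele1=(Event("deletion", "chr1", 100_500, 101_000),))
        a = simulate_profile(m, g, NoiseModel(0.12, 99))
        b = simulate_profile(m, g, NoiseModel(0.12, 99))
        assert np.array_equal(a.values, b.values)

    def test_autosomal_results_sex_independent(self):
        m = make_manifest(n_probes=20)
        ev = Event("deletion", "chr1", 100_300, 100_700)
        xx = simulate_profile(m, GenotypeSpec("XX", allele1=(ev,)), NoiseModel(0.12, 5))
        xy = simulate_profile(m, GenotypeSpec("XY", allele1=(ev,)), NoiseModel(0.12, 5))
        assert np.array_equal(xx.values, xy.values)

    def test_mismatched_chromosome_rejected(self):
        m = make_manifest(n_probes=5)
        g = GenotypeSpec("XX", allele1=(Event("deletion", "chr9", 1_000, 2_000),))
        with pytest.raises(ValueError):
            simulate_profile(m, g)

    def test_duplication_raises_ratio(self):
        m = make_manifest(n_probes=10)
        ev = Event("duplication", "chr1", 100_000, 100_460)
        prof = simulate_profile(m, GenotypeSpec("XX", allele1=(ev,)), NoiseModel(0.0, 0))
        assert np.allclose(prof.values[:4], math.log2(3 / 2))


class TestEmitLocalSequence:
    def setup_method(self):
        rng = np.random.default_rng(3)
        self.ref = {"chr1": random_dna(8_000, rng)}

    def test_identity_without_events(self):
        g = GenotypeSpec("XX")
        seqs = emit_local_sequence(g, self.ref, ("chr1", 1_000, 2_000))
        assert seqs["allele1"] == seqs["allele2"] == self.ref["chr1"][1_000:2_000]

    def test_deletion_shortens_by_exact_length(self):
        g = GenotypeSpec("XX", allele1=(Event("deletion", "chr1", 2_000, 2_971),))
        seqs = emit_local_sequence(g, self.ref, ("chr1", 1_000, 4_000))
        assert len(seqs["allele1"]) == 3_000 - 971
        assert len(seqs["allele2"]) == 3_000

    def test_deletion_with_insert_net_length_change(self):
        ins = "ACGTACGTACG"  # 11 bp
        g = GenotypeSpec("XX", allele1=(Event("deletion", "chr1", 2_000, 2_801, inserted_seq=ins),))
        seqs = emit_local_sequence(g, self.ref, ("chr1", 1_000, 4_000))
        assert len(seqs["allele1"]) - 3_000 == -801 + 11

    def test_snv_substitutes_single_base(self):
        g = GenotypeSpec("XX", allele1=(Event("snv", "chr1", 1_500, 1_501, alt="N"),))
        seqs = emit_local_sequence(g, self.ref, ("chr1", 1_000, 2_000))
        assert seqs["allele1"][500] == "N"
        assert seqs["allele1"][:500] == self.ref["chr1"][1_000:1_500]

    def test_partial_overlap_not_emitted(self):
        g = GenotypeSpec("XX", allele1=(Event("deletion", "chr1", 500, 1_500),))
        seqs = emit_local_sequence(g, self.ref, ("chr1", 1_000, 2_000))
        assert seqs["allele1"] == self.ref["chr1"][1_000:2_000]

    def test_unknown_region_rejected(self):
        with pytest.raises(ValueError):
            emit_local_sequence(GenotypeSpec("XX"), self.ref, ("chr9", 0, 100))
        with pytest.raises(ValueError):
            emit_local_sequence(GenotypeSpec("XX"), self.ref, ("chr1", 0, 10**9))


def test_plant_microhomology_creates_exact_repeat():
    rng = np.random.default_rng(0)
    seq = random_dna(500, rng)
    out = plant_microhomology(seq, 100, 200, 5)
    assert out[100:105] == out[200:205]
    assert out[105] != out[205]
    assert out[99] != out[199]


def test_revcomp():
    assert revcomp("ACGT") == "ACGT"
    assert revcomp("AACG") == "CGTT"
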