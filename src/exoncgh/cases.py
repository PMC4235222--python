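"""Synthetic replication suite: twelve intragenic-deletion cases.

Each case packages a per-gene probe manifest, a ground-truth genotype, a
simulated hybridization profile, reference-sequence fixtures for the
in-silico follow-up, and the clinical context the manual-review criteria
consult.  The gene geometries are invented but size-realistic stand-ins for
the real loci (synthetic coordinates; no genome build is used).

The case roster:

 1  BCKDHB  ~58 kb deletion of exon 9 (AR, one known point mutation)
 2  FH      ~19 kb deletion of exons 2-9 (AD, strong clinical suspicion)
 3  DBT     ~3.7 kb deletion of exon 5 (AR, one known point mutation)
 4  HPRT1   2,319-bp hemizygous deletion of exon 5 with a 69-bp insert
            templated from another chromosome (XL male)
 5  STK11   1,325-bp deletion of exon 8, 4-base breakpoint microhomology
 6  STK11   971-bp deletion of exon 3, 3-base microhomology
 7  PAH     801-bp partial exon 6 deletion with an 11-bp insert that is the
            reverse complement of the intronic breakpoint flank; a MIRb
            SINE sits 32 bp inside the deletion
 8  EMD     267-bp hemizygous deletion of exon 2, 2-base microhomology
 9  DBT     compound het: >3.5-kb (3,600-bp) partial exon 11 deletion and a
            12-bp intronic deletion 3 bp from the exon 5 splice acceptor,
            covered by a single sense/antisense probe pair
10  POMT1   false positive: 349-base mobile-element insertion with a
            16-base target-site duplication
11  SLC9A6  false positive: hemizygous SNV under the probes (XL male)
12  GALT    false positive: compound heterozygous missense SNVs in trans
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .design import DesignParams, GeneModel, ProbeManifest, build_manifest, span_inclusive
from .qc_call_review import ReviewContext
from .synthetic_data import (
    ArrayProfile,
    Event,
    GenotypeSpec,
    NoiseModel,
    plant_microhomology,
    random_dna,
    revcomp,
    simulate_profile,
)

GENE_BASE = 60_000  # genomic offset of every synthetic gene
PROBE_SD_SUITE = 0.12

# 1-based inclusive coordinates of the donor fragment whose copy appears
# between the HPRT1 breakpoints (annotated against the donor chromosome)
HPRT1_INSERT_DONOR_COORDS = (40_844_202, 40_844_270)
HPRT1_INSERT_LENGTH = span_inclusive(*HPRT1_INSERT_DONOR_COORDS)  # 69


def _exons(base: int, spacing: int, length: int, count: int) -> tuple[tuple[int, int], ...]:
    return tuple((base + spacing * i, base + spacing * i + length) for i in range(count))


_B = GENE_BASE

GENE_GEOMETRIES: dict[str, GeneModel] = {
    "BCKDHB": GeneModel("BCKDHB", "chr6", "+", _exons(_B, 30_000, 150, 10), "AR"),
    "FH": GeneModel("FH", "chr1", "+", _exons(_B, 2_400, 180, 10), "AD"),
    "DBT": GeneModel("DBT", "chr1", "+", _exons(_B, 5_500, 200, 11), "AR"),
    "HPRT1": GeneModel("HPRT1", "chrX", "+", _exons(_B, 4_500, 180, 9), "XL"),
    "STK11": GeneModel("STK11", "chr19", "+", _exons(_B, 2_300, 180, 10), "AD"),
    "PAH": GeneModel("PAH", "chr12", "+", _exons(_B, 6_000, 170, 13), "AR"),
    "EMD": GeneModel("EMD", "chrX", "+", _exons(_B, 450, 120, 6), "XL"),
    "POMT1": GeneModel("POMT1", "chr9", "+", _exons(_B, 900, 120, 10), "AR"),
    "SLC9A6": GeneModel("SLC9A6", "chrX", "+", _exons(_B, 3_000, 150, 10), "XL"),
    "GALT": GeneModel("GALT", "chr9", "+", _exons(_B, 350, 150, 11), "AR"),
}

_BASE_DESIGN = dict(
    probe_length=60,
    exon_flank_bp=150,
    target_spacing_bp=30,
    antisense_duplication=False,
    backbone_spacing_bp=1_000,
    backbone_margin_bp=50_000,
)

GENE_DESIGN_PARAMS: dict[str, DesignParams] = {
    "BCKDHB": DesignParams(**_BASE_DESIGN),
    "FH": DesignParams(**{**_BASE_DESIGN, "backbone_margin_bp": 80_000}),
    # short intronic flank + sense/antisense redundancy: leaves the region
    # 3 bp upstream of the exon 5 acceptor covered by a single probe pair
    "DBT": DesignParams(**{**_BASE_DESIGN, "exon_flank_bp": 15, "antisense_duplication": True}),
    "HPRT1": DesignParams(**_BASE_DESIGN),
    "STK11": DesignParams(**_BASE_DESIGN),
    "PAH": DesignParams(**{**_BASE_DESIGN, "target_spacing_bp": 20}),  # densest gene
    "EMD": DesignParams(**{**_BASE_DESIGN, "antisense_duplication": True}),
    "POMT1": DesignParams(**{**_BASE_DESIGN, "exon_flank_bp": 80, "target_spacing_bp": 10}),
    "SLC9A6": DesignParams(**{**_BASE_DESIGN, "target_spacing_bp": 15}),
    "GALT": DesignParams(**_BASE_DESIGN),
}


@dataclass
class Case:
    case_id: int
    gene: str
    description: str
    manifest: ProbeManifest
    genotype: GenotypeSpec
    profile: ArrayProfile
    truth: dict
    ref_fixture: dict[str, str]
    search_fixture: dict[str, str]
    context: ReviewContext
    repeat_track: list[tuple[str, int, int, str]] = field(default_factory=list)


def _other(base: str) -> str:
    return {"A": "C", "C": "A", "G": "T", "T": "G"}[base]


def _plant_insert_junction(seq: str, start: int, end: int, ins: str) -> tuple[str, str]:
    """Edit ``seq`` so the deletion-with-insert junction at [start, end) has
    unambiguous breakpoints: the insert's ends must not extend the flank
    matches.  Only deleted bases are edited, so the insert (possibly derived
    from ``seq``) is returned unchanged."""
    s = list(seq)
    if s[start] == ins[0]:
        s[start] = _other(ins[0])
    if s[end - 1] == ins[-1]:
        s[end - 1] = _other(ins[-1])
    return "".join(s), ins


def _make_context(gene: GeneModel, known_mutations: int, suspicion: bool,
                  primers: list[tuple[str, int, int]] | None = None) -> ReviewContext:
    model = GeneModel(
        gene.gene_symbol, gene.chrom, gene.strand, gene.exons,
        gene.inheritance, known_mutations, suspicion,
    )
    return ReviewContext(genes={gene.gene_symbol: model},
                         sequencing_primer_intervals=primers or [])


def _simulate(gene_symbol: str, genotype: GenotypeSpec, noise_seed: int,
              probe_sd: float) -> tuple[ProbeManifest, ArrayProfile]:
    manifest = build_manifest([GENE_GEOMETRIES[gene_symbol]], GENE_DESIGN_PARAMS[gene_symbol])
    profile = simulate_profile(manifest, genotype, NoiseModel(probe_sd, noise_seed))
    return manifest, profile


def _chrom_sequence(manifest: ProbeManifest, rng: np.random.Generator) -> str:
    length = int(manifest.df["end"].max()) + 200
    return random_dna(length, rng)


def build_case_suite(seed: int = 0, probe_sd: float = PROBE_SD_SUITE) -> list[Case]:
    """Build all twelve cases; fully deterministic in ``seed``."""
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(12)
    cases: list[Case] = []
    for i, builder in enumerate(_CASE_BUILDERS):
        child = children[i]
        rng = np.random.default_rng(child)
        noise_seed = int(child.generate_state(2)[1] % (2**31))
        cases.append(builder(rng, noise_seed, probe_sd))
    return cases


# -- individual case builders ---------------------------------------------------


def _simple_deletion_case(
    case_id: int,
    gene: str,
    description: str,
    del_start: int,
    del_end: int,
    mh: int,
    sex: str,
    known_mutations: int,
    suspicion: bool,
    rng: np.random.Generator,
    noise_seed: int,
    probe_sd: float,
    size_label: str,
) -> Case:
    model = GENE_GEOMETRIES[gene]
    deletion = Event("deletion", model.chrom, del_start, del_end)
    genotype = GenotypeSpec(sex, allele1=(deletion,))
    manifest, profile = _simulate(gene, genotype, noise_seed, probe_sd)
    ref = _chrom_sequence(manifest, rng)
    ref = plant_microhomology(ref, del_start, del_end, mh)
    truth = {
        "case": case_id,
        "gene": gene,
        "expected_class": "deletion",
        "expected_deletions": [del_end - del_start],
        "microhomology": mh,
        "size_label": size_label,
    }
    return Case(
        case_id, gene, description, manifest, genotype, profile, truth,
        {model.chrom: ref}, {}, _make_context(model, known_mutations, suspicion),
    )


def _case_1(rng, noise_seed, probe_sd):
    s, e = _B + 211_100, _B + 269_100  # ~58 kb over exon 9
    return _simple_deletion_case(1, "BCKDHB", "~58-kb deletion of exon 9",
                                 s, e, 0, "XX", 1, False, rng, noise_seed, probe_sd, "~58 kb")


def _case_2(rng, noise_seed, probe_sd):
    s, e = _B + 1_200, _B + 20_200  # ~19 kb over exons 2-9
    return _simple_deletion_case(2, "FH", "~19-kb deletion of exons 2-9",
                                 s, e, 0, "XY", 0, True, rng, noise_seed, probe_sd, "~19 kb")


def _case_3(rng, noise_seed, probe_sd):
    s, e = _B + 20_500, _B + 24_200  # ~3.7 kb over exon 5
    return _simple_deletion_case(3, "DBT", "~3.7-kb deletion of exon 5",
                                 s, e, 0, "XX", 1, False, rng, noise_seed, probe_sd, "~3.7 kb")


def _case_4(rng, noise_seed, probe_sd):
    gene = GENE_GEOMETRIES["HPRT1"]
    s, e = _B + 17_000, _B + 19_319  # 2,319 bp over exon 5
    donor_chrom = random_dna(400, rng)
    donor = donor_chrom[150:150 + HPRT1_INSERT_LENGTH]
    deletion = Event("deletion", "chrX", s, e, inserted_seq=donor)
    genotype = GenotypeSpec("XY", allele1=(deletion,))
    manifest, profile = _simulate("HPRT1", genotype, noise_seed, probe_sd)
    ref = _chrom_sequence(manifest, rng)
    ref, donor = _plant_insert_junction(ref, s, e, donor)
    truth = {
        "case": 4, "gene": "HPRT1", "expected_class": "deletion",
        "expected_deletions": [2319], "insert_length": HPRT1_INSERT_LENGTH,
        "insert_origin": "distal_templated",
        "insert_donor_coords_1based": HPRT1_INSERT_DONOR_COORDS,
        # a figure caption elsewhere prints 2,318 bp for this lesion; the
        # tabulated/primary value 2,319 is used here
        "alternative_size_print": 2318,
        "size_label": "2,319 bp",
    }
    return Case(4, "HPRT1", "2,319-bp hemizygous deletion of exon 5 with 69-bp templated insert",
                manifest, genotype, profile, truth,
                {"chrX": ref}, {"donor_chr5_fragment": donor_chrom},
                _make_context(gene, 0, False))


def _case_5(rng, noise_seed, probe_sd):
    s, e = _B + 15_500, _B + 16_825  # 1,325 bp over exon 8
    return _simple_deletion_case(5, "STK11", "1,325-bp deletion of exon 8 (mh 4)",
                                 s, e, 4, "XX", 0, True, rng, noise_seed, probe_sd, "1,325 bp")


def _case_6(rng, noise_seed, probe_sd):
    s, e = _B + 4_300, _B + 5_271  # 971 bp over exon 3
    return _simple_deletion_case(6, "STK11", "971-bp deletion of exon 3 (mh 3)",
                                 s, e, 3, "XX", 0, True, rng, noise_seed, probe_sd, "971 bp")


def _case_7(rng, noise_seed, probe_sd):
    gene = GENE_GEOMETRIES["PAH"]
    s, e = _B + 30_080, _B + 30_881  # 801 bp: 3' part of exon 6 + intron 6
    manifest = build_manifest([gene], GENE_DESIGN_PARAMS["PAH"])
    ref = _chrom_sequence(manifest, rng)
    ins = revcomp(ref[e:e + 11])  # inverted copy of the intron-6 breakpoint flank
    ref, ins = _plant_insert_junction(ref, s, e, ins)
    deletion = Event("deletion", "chr12", s, e, inserted_seq=ins)
    genotype = GenotypeSpec("XX", allele1=(deletion,))
    profile = simulate_profile(manifest, genotype, NoiseModel(probe_sd, noise_seed))
    # a MIRb SINE inside the deleted sequence, 32 bases from the intron-6
    # breakpoint
    repeat_track = [("chr12", e - 32 - 180, e - 32, "MIRb")]
    truth = {
        "case": 7, "gene": "PAH", "expected_class": "deletion",
        "expected_deletions": [801], "insert_length": 11,
        "insert_origin": "inverted_local", "size_label": "801 bp",
    }
    return Case(7, "PAH", "801-bp partial exon 6 deletion with 11-bp inverted insert",
                manifest, genotype, profile, truth, {"chr12": ref}, {},
                _make_context(gene, 1, False), repeat_track)


def _case_8(rng, noise_seed, probe_sd):
    s, e = _B + 400, _B + 667  # 267 bp over exon 2
    return _simple_deletion_case(8, "EMD", "267-bp hemizygous deletion of exon 2 (mh 2)",
                                 s, e, 2, "XY", 0, False, rng, noise_seed, probe_sd, "267 bp")


def _case_9(rng, noise_seed, probe_sd):
    gene = GENE_GEOMETRIES["DBT"]
    exon5_start = gene.exons[4][0]          # _B + 22_000
    small_e = exon5_start - 3               # 3 bp from the splice acceptor
    small_s = small_e - 12
    big_s, big_e = _B + 51_550, _B + 55_150  # 3,600 bp over the 5' end of exon 11
    small = Event("deletion", "chr1", small_s, small_e)
    big = Event("deletion", "chr1", big_s, big_e)
    genotype = GenotypeSpec("XX", allele1=(small,), allele2=(big,))
    manifest, profile = _simulate("DBT", genotype, noise_seed, probe_sd)
    ref = _chrom_sequence(manifest, rng)
    ref = plant_microhomology(ref, small_s, small_e, 0)
    ref = plant_microhomology(ref, big_s, big_e, 0)
    # the original sequencing amplification primer sat on the deleted bases
    primers = [("chr1", small_s - 5, small_e + 8)]
    truth = {
        "case": 9, "gene": "DBT", "expected_class": "deletion",
        "expected_deletions": [12, 3600], "smallest": 12,
        "size_label": "> 3.5 kb + 12 bp",
    }
    # the large CBS-callable deletion counts as "one mutation identified"
    return Case(9, "DBT", "compound het: 3.6-kb partial exon 11 deletion + 12-bp intronic deletion",
                manifest, genotype, profile, truth, {"chr1": ref}, {},
                _make_context(gene, 1, False, primers))


def _case_10(rng, noise_seed, probe_sd):
    gene = GENE_GEOMETRIES["POMT1"]
    q = _B + 1_860  # insertion point inside exon 3
    manifest = build_manifest([gene], GENE_DESIGN_PARAMS["POMT1"])
    ref = _chrom_sequence(manifest, rng)
    element = random_dna(349 - 16, rng)
    if element[0] == ref[q]:
        element = _other(element[0]) + element[1:]
    if element[-1] == ref[q - 17]:
        element = element[:-1] + _other(element[-1])
    tsd = ref[q - 16:q]  # target site duplicated at integration
    ins = element + tsd
    insertion = Event("insertion", "chr9", q, q, inserted_seq=ins)
    genotype = GenotypeSpec("XX", allele1=(insertion,))
    profile = simulate_profile(manifest, genotype, NoiseModel(probe_sd, noise_seed))
    truth = {
        "case": 10, "gene": "POMT1", "expected_class": "no_deletion",
        "expected_deletions": [], "fp_mechanism": "mobile_element_insertion",
        "insert_length": 349, "tsd_length": 16,
        "expected_resolution": "insertion_fp",
    }
    return Case(10, "POMT1", "false positive: 349-base mobile-element insertion with 16-base TSD",
                manifest, genotype, profile, truth, {"chr9": ref}, {},
                _make_context(gene, 1, False))


def _case_11(rng, noise_seed, probe_sd):
    gene = GENE_GEOMETRIES["SLC9A6"]
    pos = _B + 23_960  # intronic SNV just 5' of exon 9, under the probes
    manifest = build_manifest([gene], GENE_DESIGN_PARAMS["SLC9A6"])
    ref = _chrom_sequence(manifest, rng)
    snv = Event("snv", "chrX", pos, pos + 1, alt=_other(ref[pos]))
    genotype = GenotypeSpec("XY", allele1=(snv,))
    profile = simulate_profile(manifest, genotype, NoiseModel(probe_sd, noise_seed))
    truth = {
        "case": 11, "gene": "SLC9A6", "expected_class": "no_deletion",
        "expected_deletions": [], "fp_mechanism": "hemizygous_snv",
        "expected_resolution": "sequence_variant_fp",
    }
    return Case(11, "SLC9A6", "false positive: hemizygous SNV under the probes",
                manifest, genotype, profile, truth, {"chrX": ref}, {},
                _make_context(gene, 0, False))


def _case_12(rng, noise_seed, probe_sd):
    gene = GENE_GEOMETRIES["GALT"]
    pos1, pos2 = _B + 2_870, _B + 2_881  # 11 bp apart, in trans, exon 9
    manifest = build_manifest([gene], GENE_DESIGN_PARAMS["GALT"])
    ref = _chrom_sequence(manifest, rng)
    snv1 = Event("snv", "chr9", pos1, pos1 + 1, alt=_other(ref[pos1]))
    snv2 = Event("snv", "chr9", pos2, pos2 + 1, alt=_other(ref[pos2]))
    genotype = GenotypeSpec("XX", allele1=(snv1,), allele2=(snv2,))
    profile = simulate_profile(manifest, genotype, NoiseModel(probe_sd, noise_seed))
    truth = {
        "case": 12, "gene": "GALT", "expected_class": "no_deletion",
        "expected_deletions": [], "fp_mechanism": "compound_het_snvs",
        "expected_resolution": "sequence_variant_fp",
    }
    return Case(12, "GALT", "false positive: compound heterozygous missense SNVs",
                manifest, genotype, profile, truth, {"chr9": ref}, {},
                _make_context(gene, 1, False))


_CASE_BUILDERS = [
    _case_1, _case_2, _case_3, _case_4, _case_5, _case_6,
    _case_7, _case_8, _case_9, _case_10, _case_11, _case_12,
]
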