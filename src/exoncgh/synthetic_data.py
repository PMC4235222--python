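"""Probe-level log2-ratio simulation under a hybridization-attenuation model.

The simulator emulates a patient-vs-reference two-color hybridization on a
targeted 60-mer array.  Each allele contributes hybridization signal to a
probe according to how much of the probe's footprint survives intact on that
allele:

* a deletion removes bases from the footprint; the two flanks remain a
  single hybridizing stretch (the probe can loop out the missing bases), so
  the disrupted fraction f is simply the deleted fraction of the footprint;
* an insertion splits the footprint's homology in two; the probe retains at
  most the longest contiguous matching block, so f = 1 - longest/len;
* a single-nucleotide change destabilizes a fixed window ``w_snv`` of the
  duplex around the variant.

Efficiency is (1 - f) ** alpha with a destabilization exponent alpha
(default 2): 60-mer duplex stability falls off faster than linearly in the
mismatched fraction.  The per-probe ratio is

    log2( max(sum of allele efficiencies, eps) / reference ploidy ) + noise

with a background-hybridization floor eps (default 0.1 copies) so that
hemizygous deletions land near -3.3 rather than minus infinity, and i.i.d.
Gaussian probe noise whose default sd (0.12) sits mid-way through the
accepted derivative-log-ratio QC band.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .design import Probe, ProbeManifest

EPS_COPIES_DEFAULT = 0.1
ALPHA_DEFAULT = 2.0
W_SNV_DEFAULT = 15
PROBE_SD_DEFAULT = 0.12

_SEX_CHROMS = {"chrX", "X"}


@dataclass(frozen=True)
class Event:
    """A ground-truth lesion on one allele.

    ``deletion``/``duplication`` occupy [start, end); ``insertion`` has
    end == start and carries ``inserted_seq``; a deletion may also carry an
    ``inserted_seq`` placed between its breakpoints; ``snv`` uses
    start == position with ``alt`` the substituted base.
    """

    kind: str
    chrom: str
    start: int
    end: int
    inserted_seq: str = ""
    alt: str = ""

    def __post_init__(self) -> None:
        if self.kind not in ("deletion", "duplication", "insertion", "snv"):
            raise ValueError(f"unknown event kind {self.kind!r}")
        if self.kind in ("deletion", "duplication") and self.end - self.start < 1:
            raise ValueError(f"{self.kind} needs end - start >= 1")
        if self.kind == "insertion":
            if self.end != self.start:
                raise ValueError("insertion must have end == start")
            if not self.inserted_seq:
                raise ValueError("insertion needs inserted_seq")
        if self.kind == "snv" and not self.alt:
            raise ValueError("snv needs alt base")


@dataclass
class GenotypeSpec:
    """Per-allele ground truth for one sample.

    Autosomal loci have two alleles; X-linked loci in an XY sample live on
    allele 1 only (allele 2 carries no X events).
    """

    sample_sex: str
    allele1: tuple[Event, ...] = ()
    allele2: tuple[Event, ...] = ()

    def __post_init__(self) -> None:
        if self.sample_sex not in ("XX", "XY"):
            raise ValueError("sample_sex must be XX or XY")
        self.allele1 = tuple(self.allele1)
        self.allele2 = tuple(self.allele2)
        if self.sample_sex == "XY":
            for ev in self.allele2:
                if ev.chrom in _SEX_CHROMS:
                    raise ValueError("XY sample carries X events on allele 1 only")

    def alleles_for(self, chrom: str) -> list[tuple[Event, ...]]:
        if chrom in _SEX_CHROMS and self.sample_sex == "XY":
            return [tuple(e for e in self.allele1 if e.chrom == chrom)]
        return [
            tuple(e for e in self.allele1 if e.chrom == chrom),
            tuple(e for e in self.allele2 if e.chrom == chrom),
        ]

    def ploidy(self, chrom: str) -> int:
        return len(self.alleles_for(chrom))

    def all_events(self) -> list[Event]:
        return list(self.allele1) + list(self.allele2)


@dataclass(frozen=True)
class NoiseModel:
    probe_sd: float = PROBE_SD_DEFAULT
    seed: int = 0

    def __post_init__(self) -> None:
        if self.probe_sd < 0:
            raise ValueError("probe_sd must be >= 0")


@dataclass
class ArrayProfile:
    """Per-probe log2(test/reference) values aligned to a manifest."""

    manifest: ProbeManifest
    values: np.ndarray
    sample_sex: str = "XX"
    reference_sex: str = "XX"
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if len(self.values) != len(self.manifest):
            raise ValueError("one value per manifest probe required")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("profile values must be finite")

    def __len__(self) -> int:
        return len(self.values)

    def to_frame(self) -> pd.DataFrame:
        df = self.manifest.df.copy()
        df["log2_ratio"] = self.values
        return df

    def with_values(self, values: np.ndarray) -> "ArrayProfile":
        return ArrayProfile(self.manifest, values, self.sample_sex, self.reference_sex, dict(self.metadata))


def expected_log2(copies_test: float, copies_ref: int, eps: float = EPS_COPIES_DEFAULT) -> float:
    """Theoretical log2 ratio for a copy-number state.

    expected_log2(1, 2) = -1 (het deletion), (2, 2) = 0, (3, 2) = 0.585
    (printed as 0.59).  A zero-copy test state is floored at ``eps``
    background copies.
    """
    if copies_test < 0:
        raise ValueError("copies_test must be >= 0")
    if copies_ref < 1:
        raise ValueError("copies_ref must be >= 1")
    return math.log2(max(copies_test, eps) / copies_ref)


def _disruption(probe: Probe, events: Sequence[Event], w_snv: int) -> tuple[list[tuple[int, int]], list[int]]:
    """Disrupted sub-intervals of the probe footprint and junction split
    points (positions where an inserted sequence severs homology)."""
    disrupted: list[tuple[int, int]] = []
    splits: list[int] = []
    for ev in events:
        if ev.chrom != probe.chrom:
            continue
        if ev.kind == "deletion":
            s, e = max(ev.start, probe.start), min(ev.end, probe.end)
            if s < e:
                disrupted.append((s, e))
                if ev.inserted_seq:
                    splits.append(s)
        elif ev.kind == "insertion":
            if probe.start < ev.start < probe.end:
                splits.append(ev.start)
        elif ev.kind == "snv":
            w0 = ev.start - w_snv // 2
            s, e = max(w0, probe.start), min(w0 + w_snv, probe.end)
            if s < e:
                disrupted.append((s, e))
        # duplications do not disrupt the probe's own footprint

    return disrupted, splits


def probe_efficiency(
    probe: Probe,
    allele_events: Sequence[Event],
    alpha: float = ALPHA_DEFAULT,
    w_snv: int = W_SNV_DEFAULT,
) -> float:
    """Hybridization efficiency in [0, 1] of one probe against one allele.

    f is the fraction of the footprint that no longer participates in the
    best contiguous duplex; efficiency = (1 - f) ** alpha.
    """
    disrupted, splits = _disruption(probe, allele_events, w_snv)
    length = probe.end - probe.start
    if not disrupted and not splits:
        return 1.0

    # surviving pieces = footprint minus disrupted intervals
    pieces: list[tuple[int, int]] = []
    cursor = probe.start
    for s, e in sorted(disrupted):
        s = max(s, cursor)
        if s > cursor:
            pieces.append((cursor, s))
        cursor = max(cursor, e)
    if cursor < probe.end:
        pieces.append((cursor, probe.end))

    if not pieces:
        return 0.0

    # cut surviving pieces at insert junctions, then group into blocks: the
    # probe retains the heaviest contiguous block only
    split_points = sorted(set(splits))
    cut: list[tuple[int, int]] = []
    for s, e in pieces:
        for p in split_points:
            if s < p < e:
                cut.append((s, p))
                s = p
        cut.append((s, e))
    blocks: dict[int, int] = {}
    for s, e in cut:
        key = sum(1 for p in split_points if p <= s)
        blocks[key] = blocks.get(key, 0) + (e - s)
    matched = max(blocks.values())
    f = 1.0 - matched / length
    return (1.0 - f) ** alpha


def simulate_profile(
    manifest: ProbeManifest,
    genotype: GenotypeSpec,
    noise: NoiseModel | None = None,
    reference_sex: str | None = None,
    eps: float = EPS_COPIES_DEFAULT,
    alpha: float = ALPHA_DEFAULT,
    w_snv: int = W_SNV_DEFAULT,
) -> ArrayProfile:
    """Simulate one hybridization of ``genotype`` against a same-sex
    reference pool.  Deterministic for a fixed ``noise.seed``."""
    if noise is None:
        noise = NoiseModel()
    if reference_sex is None:
        reference_sex = genotype.sample_sex
    if reference_sex != genotype.sample_sex:
        raise ValueError("reference pool must be same-sex as the sample")

    event_chroms = {e.chrom for e in genotype.all_events()}
    manifest_chroms = set(manifest.df["chrom"].unique())
    unknown = event_chroms - manifest_chroms
    if unknown:
        raise ValueError(f"genotype events on chromosomes absent from manifest: {sorted(unknown)}")

    values = np.empty(len(manifest), dtype=float)
    for i, probe in enumerate(manifest.probes()):
        if probe.category == "control":
            values[i] = 0.0  # spike-in behaves copy-neutral
            continue
        alleles = genotype.alleles_for(probe.chrom)
        signal = sum(probe_efficiency(probe, ev, alpha=alpha, w_snv=w_snv) for ev in alleles)
        # duplications add whole extra copies of the footprint they span
        for ev_list in alleles:
            for ev in ev_list:
                if ev.kind == "duplication" and ev.chrom == probe.chrom and ev.start < probe.end and probe.start < ev.end:
                    overlap = min(ev.end, probe.end) - max(ev.start, probe.start)
                    signal += overlap / (probe.end - probe.start)
        ref = genotype.ploidy(probe.chrom)
        values[i] = math.log2(max(signal, eps) / ref)

    rng = np.random.default_rng(noise.seed)
    if noise.probe_sd > 0:
        values = values + rng.normal(0.0, noise.probe_sd, size=len(values))
    return ArrayProfile(
        manifest,
        values,
        sample_sex=genotype.sample_sex,
        reference_sex=reference_sex,
        metadata={"probe_sd": noise.probe_sd, "seed": noise.seed, "eps": eps, "alpha": alpha, "w_snv": w_snv},
    )


def emit_local_sequence(
    genotype: GenotypeSpec,
    ref_fixture: Mapping[str, str],
    region: tuple[str, int, int],
) -> dict[str, str]:
    """Per-allele sequences over ``region`` with the allele's events applied.

    Stands in for PCR/Sanger follow-up: a deletion removes bases (inserting
    any junction insert), an insertion adds bases, an SNV substitutes one.
    Only events fully contained in the region are applied — an amplicon
    whose far primer sat inside a deletion would drop out rather than
    report a truncated junction.
    """
    chrom, start, end = region
    if chrom not in ref_fixture:
        raise ValueError(f"region chromosome {chrom!r} not in reference fixture")
    ref = ref_fixture[chrom]
    if not (0 <= start < end <= len(ref)):
        raise ValueError("region outside reference fixture bounds")
    ref_seq = ref[start:end]

    out: dict[str, str] = {}
    for idx, events in enumerate(genotype.alleles_for(chrom), start=1):
        local = [
            e
            for e in events
            if (e.kind in ("insertion", "snv") and start <= e.start < end)
            or (e.kind in ("deletion", "duplication") and start <= e.start and e.end <= end)
        ]
        seq = ref_seq
        # apply right-to-left so earlier coordinates stay valid
        for ev in sorted(local, key=lambda e: e.start, reverse=True):
            s = max(ev.start, start) - start
            e = min(ev.end, end) - start
            if ev.kind == "deletion":
                seq = seq[:s] + ev.inserted_seq + seq[e:]
            elif ev.kind == "insertion":
                seq = seq[:s] + ev.inserted_seq + seq[s:]
            elif ev.kind == "snv":
                seq = seq[:s] + ev.alt + seq[s + 1:]
            elif ev.kind == "duplication":
                seq = seq[:e] + seq[s:e] + seq[e:]
        out[f"allele{idx}"] = seq
    return out


# -- sequence fixtures ----------------------------------------------------------

_BASES = np.array(list("ACGT"))


def random_dna(length: int, rng: np.random.Generator) -> str:
    return "".join(_BASES[rng.integers(0, 4, size=length)])


def _other_base(base: str) -> str:
    return {"A": "C", "C": "A", "G": "T", "T": "G"}[base]


def plant_microhomology(seq: str, start: int, end: int, mh: int) -> str:
    """Edit ``seq`` so the deletion [start, end) has exactly ``mh`` bases of
    breakpoint microhomology: seq[start:start+mh] == seq[end:end+mh], with
    mismatches installed at both ambiguity boundaries so the junction cannot
    slide further."""
    s = list(seq)
    for i in range(mh):  # elementwise so overlapping source/dest propagate
        s[end + i] = s[start + i]
    s[end + mh] = _other_base(s[start + mh])
    if start > 0:
        s[start - 1] = _other_base(s[end - 1])
    return "".join(s)


def revcomp(seq: str) -> str:
    return seq.translate(str.maketrans("ACGTacgt", "TGCAtgca"))[::-1]


def write_fasta(seqs: Mapping[str, str], path: str | Path) -> None:
    from Bio import SeqIO
    from Bio.Seq import Seq
    from Bio.SeqRecord import SeqRecord

    records = [SeqRecord(Seq(s), id=name, description="") for name, s in seqs.items()]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path: str | Path) -> dict[str, str]:
    from Bio import SeqIO

    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


# -- profile IO -----------------------------------------------------------------

def write_profile(profile: ArrayProfile, path: str | Path) -> None:
    import json

    df = pd.DataFrame({"probe_id": profile.manifest.df["probe_id"], "log2_ratio": profile.values})
    df.to_csv(path, sep="\t", index=False)
    sidecar = Path(str(path) + ".json")
    sidecar.write_text(
        json.dumps(
            {"sample_sex": profile.sample_sex, "reference_sex": profile.reference_sex, **profile.metadata},
            indent=1,
        )
    )


def read_profile(path: str | Path, manifest: ProbeManifest) -> ArrayProfile:
    import json

    df = pd.read_csv(path, sep="\t")
    order = df.set_index("probe_id")["log2_ratio"]
    values = order.reindex(manifest.df["probe_id"]).to_numpy()
    sidecar = Path(str(path) + ".json")
    meta = json.loads(sidecar.read_text()) if sidecar.exists() else {}
    return ArrayProfile(
        manifest,
        values,
        sample_sex=meta.get("sample_sex", "XX"),
        reference_sex=meta.get("reference_sex", meta.get("sample_sex", "XX")),
        metadata=meta,
    )
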