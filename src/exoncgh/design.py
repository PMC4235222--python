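"""Gene models and exon-centric probe manifests.

A targeted CGH array concentrates ~60-mer oligo probes on the exons (plus a
short intronic flank) of a panel of disease genes, with sparse genome
"backbone" probes in between for normalization context and a handful of
spike-in control probes.  This module builds such a manifest
deterministically from gene models.

Coordinates are 0-based half-open (BED convention) everywhere in memory and
on disk; 1-based inclusive coordinates appear only in human-readable report
strings.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

PROBE_LENGTH_DEFAULT = 60

MANIFEST_COLUMNS = ["chrom", "start", "end", "probe_id", "category", "strand", "gene"]


def span_inclusive(start_1based: int, end_1based: int) -> int:
    """Length of a 1-based inclusive genomic interval as printed in reports.

    E.g. an insert annotated chr5:40,844,202-40,844,270 spans 69 bases.
    """
    if end_1based < start_1based:
        raise ValueError("inclusive interval end precedes start")
    return end_1based - start_1based + 1


@dataclass(frozen=True)
class GeneModel:
    """One gene of the targeted panel.

    ``inheritance`` is AD / AR / XL and, together with
    ``known_mutation_count`` and ``clinical_suspicion``, provides the
    clinical context consumed by the manual-review criteria.
    """

    gene_symbol: str
    chrom: str
    strand: str
    exons: tuple[tuple[int, int], ...]
    inheritance: str = "AR"
    known_mutation_count: int = 0
    clinical_suspicion: bool = False

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be + or -, got {self.strand!r}")
        if self.inheritance not in ("AD", "AR", "XL"):
            raise ValueError(f"inheritance must be AD/AR/XL, got {self.inheritance!r}")
        if len(self.exons) < 1:
            raise ValueError("gene model needs at least one exon")
        if self.known_mutation_count < 0:
            raise ValueError("known_mutation_count must be >= 0")
        prev_end = None
        for s, e in self.exons:
            if e <= s:
                raise ValueError(f"empty/inverted exon ({s}, {e})")
            if prev_end is not None and s < prev_end:
                raise ValueError("exons must be sorted and non-overlapping")
            prev_end = e

    @property
    def span(self) -> tuple[int, int]:
        return self.exons[0][0], self.exons[-1][1]


@dataclass(frozen=True)
class Probe:
    probe_id: str
    chrom: str
    start: int
    end: int
    strand: str = "+"
    category: str = "target"
    gene_symbol: str = ""

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError("probe start must precede end")
        if self.category not in ("target", "backbone", "control"):
            raise ValueError(f"bad probe category {self.category!r}")


@dataclass(frozen=True)
class DesignParams:
    probe_length: int = PROBE_LENGTH_DEFAULT
    exon_flank_bp: int = 150
    target_spacing_bp: int = 30
    antisense_duplication: bool = False
    backbone_spacing_bp: int = 10_000
    backbone_margin_bp: int = 50_000
    n_control_probes: int = 10

    def __post_init__(self) -> None:
        if self.probe_length <= 0 or self.target_spacing_bp <= 0:
            raise ValueError("probe_length and target_spacing_bp must be positive")
        if self.exon_flank_bp < 0:
            raise ValueError("exon_flank_bp must be >= 0")
        if self.backbone_spacing_bp <= 0:
            raise ValueError("backbone_spacing_bp must be positive")


@dataclass
class ProbeManifest:
    """Probes sorted by (chrom, start, strand); ids unique."""

    df: pd.DataFrame
    design_params: DesignParams = field(default_factory=DesignParams)

    def __post_init__(self) -> None:
        df = self.df.reset_index(drop=True)
        if list(df.columns) != MANIFEST_COLUMNS:
            df = df[MANIFEST_COLUMNS]
        if df["probe_id"].duplicated().any():
            raise ValueError("duplicate probe ids in manifest")
        sort_cols = ["chrom", "start", "end", "strand"]
        if not df[sort_cols].equals(df.sort_values(sort_cols, kind="stable")[sort_cols].reset_index(drop=True)):
            df = df.sort_values(sort_cols, kind="stable").reset_index(drop=True)
        self.df = df

    def __len__(self) -> int:
        return len(self.df)

    def probes(self) -> list[Probe]:
        return [
            Probe(r.probe_id, r.chrom, int(r.start), int(r.end), r.strand, r.category, r.gene)
            for r in self.df.itertuples()
        ]

    def subset(self, category: str | None = None, gene: str | None = None) -> pd.DataFrame:
        df = self.df
        if category is not None:
            df = df[df["category"] == category]
        if gene is not None:
            df = df[df["gene"] == gene]
        return df


def _tile_window(start: int, end: int, probe_length: int, spacing: int) -> list[int]:
    """Deterministic left-anchored tiling of [start, end); guarantees the
    final base is covered by right-aligning a last probe when needed."""
    if end - start < probe_length:
        return [start]  # caller centers short windows
    positions = list(range(start, end - probe_length + 1, spacing))
    if positions[-1] + probe_length < end:
        positions.append(end - probe_length)
    return positions


def _merge_intervals(intervals: Iterable[tuple[int, int]]) -> list[tuple[int, int]]:
    merged: list[tuple[int, int]] = []
    for s, e in sorted(intervals):
        if merged and s <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], e))
        else:
            merged.append((s, e))
    return merged


def build_manifest(genes: Sequence[GeneModel], params: DesignParams | None = None) -> ProbeManifest:
    """Tile every exon +/- ``exon_flank_bp`` at ``target_spacing_bp`` with
    ``probe_length``-mers; optionally emit each target footprint on both
    strands; drop backbone probes every ``backbone_spacing_bp`` outside the
    targeted windows.

    An exon window shorter than one probe yields a single probe centered on
    the exon.  The construction is fully deterministic.
    """
    if params is None:
        params = DesignParams()
    if not genes:
        raise ValueError("empty gene list")

    L = params.probe_length
    records: list[tuple] = []
    target_windows_by_chrom: dict[str, list[tuple[int, int]]] = {}

    for gene in genes:
        windows = _merge_intervals(
            (max(0, s - params.exon_flank_bp), e + params.exon_flank_bp) for s, e in gene.exons
        )
        target_windows_by_chrom.setdefault(gene.chrom, []).extend(windows)
        footprints: list[tuple[int, int]] = []
        for w_start, w_end in windows:
            if w_end - w_start < L:
                # center the single probe on the window midpoint
                mid = (w_start + w_end) // 2
                s = max(0, mid - L // 2)
                footprints.append((s, s + L))
            else:
                footprints.extend((p, p + L) for p in _tile_window(w_start, w_end, L, params.target_spacing_bp))
        footprints = sorted(set(footprints))
        for i, (s, e) in enumerate(footprints):
            strands = ("+", "-") if params.antisense_duplication else ("+",)
            for strand in strands:
                suffix = "" if strand == "+" else "as"
                records.append(
                    (gene.chrom, s, e, f"{gene.gene_symbol}_t{i:05d}{suffix}", "target", strand, gene.gene_symbol)
                )

    # backbone probes: tile the margin around each chromosome's targeted span,
    # skipping positions whose footprint intersects a target window
    for chrom, windows in sorted(target_windows_by_chrom.items()):
        merged = _merge_intervals(windows)
        lo = max(0, merged[0][0] - params.backbone_margin_bp)
        hi = merged[-1][1] + params.backbone_margin_bp
        k = 0
        for pos in range(lo, hi, params.backbone_spacing_bp):
            s, e = pos, pos + L
            if any(s < we and ws < e for ws, we in merged):
                continue
            records.append((chrom, s, e, f"bb_{chrom}_{k:05d}", "backbone", "+", ""))
            k += 1

    # spike-in controls parked upstream of the first targeted chromosome
    first_chrom = sorted(target_windows_by_chrom)[0]
    ctrl_base = max(0, min(s for s, _ in target_windows_by_chrom[first_chrom]) - 2 * params.backbone_margin_bp)
    for j in range(params.n_control_probes):
        s = ctrl_base + j * 2 * L
        records.append((first_chrom, s, s + L, f"ctrl_{j:03d}", "control", "+", ""))

    df = pd.DataFrame(records, columns=MANIFEST_COLUMNS)
    return ProbeManifest(df, params)


# -- IO: 6/7-column BED-like TSV ------------------------------------------------

def write_manifest(manifest: ProbeManifest, path: str | Path) -> None:
    manifest.df.to_csv(path, sep="\t", header=False, index=False)


def read_manifest(path: str | Path, params: DesignParams | None = None) -> ProbeManifest:
    df = pd.read_csv(path, sep="\t", header=None, names=MANIFEST_COLUMNS, keep_default_na=False)
    df["gene"] = df["gene"].astype(str)
    return ProbeManifest(df, params or DesignParams())


def write_gene_models(genes: Sequence[GeneModel], path: str | Path) -> None:
    rows = []
    for g in genes:
        rows.append(
            {
                "gene": g.gene_symbol,
                "chrom": g.chrom,
                "strand": g.strand,
                "exon_starts": ",".join(str(s) for s, _ in g.exons),
                "exon_ends": ",".join(str(e) for _, e in g.exons),
                "inheritance": g.inheritance,
                "known_mutation_count": g.known_mutation_count,
                "clinical_suspicion": int(g.clinical_suspicion),
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_gene_models(path: str | Path) -> list[GeneModel]:
    df = pd.read_csv(path, sep="\t")
    genes = []
    for r in df.itertuples():
        starts = [int(x) for x in str(r.exon_starts).split(",")]
        ends = [int(x) for x in str(r.exon_ends).split(",")]
        genes.append(
            GeneModel(
                gene_symbol=r.gene,
                chrom=r.chrom,
                strand=r.strand,
                exons=tuple(zip(starts, ends)),
                inheritance=r.inheritance,
                known_mutation_count=int(r.known_mutation_count),
                clinical_suspicion=bool(r.clinical_suspicion),
            )
        )
    return genes
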