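import numpy as np
import pandas as pd
import pytest

from exoncgh.design import ProbeManifest
from exoncgh.synthetic_data import ArrayProfile


@pytest.fixture(scope="session")
def suite():
    from exoncgh.cases import build_case_suite

    return build_case_suite(seed=1)


@pytest.fixture(scope="session")
def suite_results(suite):
    """Full end-to-end evaluation of the twelve-case suite (shared across
    tests because segmentation dominates the cost)."""
    from exoncgh.workbench import evaluate_suite

    outcomes, summary = evaluate_suite(seed=1, cases=suite)
    return outcomes, summary


def make_manifest(n_probes=100, spacing=100, probe_length=60, chrom="chr1",
                  start=100_000, gene="TOY", strand="+") -> ProbeManifest:
    """Toy manifest: evenly spaced non-overlapping probes on one chromosome."""
    records = []
    for i in range(n_probes):
        s = start + i * spacing
        records.append((chrom, s, s + probe_length, f"{gene}_{i:04d}", "target", strand, gene))
    df = pd.DataFrame(records, columns=["chrom", "start", "end", "probe_id", "category", "strand", "gene"])
    return ProbeManifest(df)


def make_profile(values, manifest=None, sample_sex="XX", **kwargs) -> ArrayProfile:
    values = np.asarray(values, dtype=float)
    if manifest is None:
        manifest = make_manifest(n_probes=len(values))
    return ArrayProfile(manifest, values, sample_sex=sample_sex, reference_sex=sample_sex, **kwargs)
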