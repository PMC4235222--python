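"""Circular binary segmentation of probe-ordered log2 ratios.

The segmenter recursively looks for the arc of the (circularized) probe
sequence whose mean differs most from the rest, scored with the two-sample
t-like statistic

    T = (mean_in - mean_out) / (s * sqrt(1/n_in + 1/n_out))

with s the pooled within-group standard deviation.  Significance of the best
arc is assessed by permutation (within-chromosome shuffles, seeded); a split
is accepted when the permutation p-value of max |T| falls below ``alpha``.
After recursion, adjacent segments whose means differ by less than
``prune_sd`` residual standard deviations are merged back.

Segments smaller than the four-probe calling minimum are deliberately
produced and retained: the minimum-probe rule belongs to calling, so that
two-probe events stay visible to manual review.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .synthetic_data import ArrayProfile

_S_FLOOR = 1e-12


@dataclass(frozen=True)
class Segment:
    chrom: str
    start: int          # genomic start of first probe footprint
    end: int            # genomic end of last probe footprint
    first_index: int    # index of first probe in the profile (manifest order)
    n_probes: int
    mean_log2: float

    @property
    def probe_range(self) -> range:
        return range(self.first_index, self.first_index + self.n_probes)


@dataclass(frozen=True)
class CbsParams:
    alpha: float = 0.01
    n_permutations: int = 1000
    min_split_width: int = 2
    prune_sd: float = 1.5
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if self.n_permutations < 100:
            raise ValueError("n_permutations must be >= 100")
        if self.min_split_width < 1:
            raise ValueError("min_split_width must be >= 1")


def median_center(profile: ArrayProfile) -> ArrayProfile:
    """Subtract the per-chromosome median so each chromosome's baseline
    (the bulk copy-neutral state) sits at zero."""
    chroms = profile.manifest.df["chrom"].to_numpy()
    values = profile.values.copy()
    for chrom in np.unique(chroms):
        mask = chroms == chrom
        values[mask] -= np.median(values[mask])
    return profile.with_values(values)


def _t_matrix(x: np.ndarray, w: int) -> np.ndarray:
    """|T| for every admissible arc [i, j); inadmissible entries are NaN.

    Returned matrix has shape (n+1, n+1); entry [i, j] scores the arc of
    length j - i against its complement.
    """
    n = len(x)
    S = np.concatenate(([0.0], np.cumsum(x)))
    Q = float(np.sum(x * x))
    total = S[-1]

    i_idx = np.arange(n + 1)[:, None]
    j_idx = np.arange(n + 1)[None, :]
    n_in = (j_idx - i_idx).astype(float)
    valid = (n_in >= w) & (n - n_in >= w)

    with np.errstate(invalid="ignore", divide="ignore"):
        sum_in = S[j_idx] - S[i_idx]
        n_out = n - n_in
        mean_in = sum_in / n_in
        mean_out = (total - sum_in) / n_out
        ss_pool = Q - sum_in**2 / n_in - (total - sum_in) ** 2 / n_out
        ss_pool = np.maximum(ss_pool, 0.0)
        s = np.sqrt(ss_pool / max(n - 2, 1))
        s = np.maximum(s, _S_FLOOR)
        T = np.abs(mean_in - mean_out) / (s * np.sqrt(1.0 / n_in + 1.0 / n_out))
    T[~valid] = np.nan
    return T


def best_split(values: np.ndarray, min_split_width: int = 2) -> tuple[int, int, float]:
    """Best arc (i, j) — probe indices [i, j) — maximizing |T|, with ties
    broken by the lexicographically smallest (i, j).  Constant input returns
    T = 0 on the first admissible arc."""
    x = np.asarray(values, dtype=float)
    n = len(x)
    if n < 2 * min_split_width:
        raise ValueError("need at least 2 * min_split_width probes")
    T = _t_matrix(x, min_split_width)
    finite = np.nan_to_num(T, nan=-1.0)
    best = finite.max()
    cand = np.argwhere(np.isclose(finite, best, rtol=0.0, atol=1e-9) & (finite >= 0))
    # argwhere is row-major sorted, so the first candidate is the smallest (i, j)
    i, j = map(int, cand[0])
    return i, j, float(T[i, j])


def _perm_max_t(
    x: np.ndarray, w: int, n_perm: int, rng: np.random.Generator, obs: float, alpha: float
) -> float:
    """Permutation p-value of the observed max |T| with early stopping."""
    n = len(x)
    hits = 0
    done = 0
    chunk = 100
    thresh = obs - 1e-9
    while done < n_perm:
        m = min(chunk, n_perm - done)
        X = np.tile(x, (m, 1))
        X = rng.permuted(X, axis=1)
        S = np.concatenate((np.zeros((m, 1)), np.cumsum(X, axis=1)), axis=1)
        Q = np.sum(X * X, axis=1)
        total = S[:, -1]
        row_max = np.zeros(m)
        for L in range(w, n - w + 1):
            sum_in = S[:, L:] - S[:, : n - L + 1]
            n_in = float(L)
            n_out = float(n - L)
            mean_in = sum_in / n_in
            mean_out = (total[:, None] - sum_in) / n_out
            ss = Q[:, None] - sum_in**2 / n_in - (total[:, None] - sum_in) ** 2 / n_out
            s = np.sqrt(np.maximum(ss, 0.0) / max(n - 2, 1))
            s = np.maximum(s, _S_FLOOR)
            T = np.abs(mean_in - mean_out) / (s * np.sqrt(1.0 / n_in + 1.0 / n_out))
            row_max = np.maximum(row_max, T.max(axis=1))
        hits += int(np.sum(row_max >= thresh))
        done += m
        # cannot become significant anymore
        if (1 + hits) / (1 + n_perm) >= alpha:
            return (1 + hits) / (1 + n_perm)
        # cannot lose significance anymore
        if (1 + hits + (n_perm - done)) / (1 + n_perm) < alpha:
            break
    return (1 + hits) / (1 + n_perm)


def _segment_chrom(x: np.ndarray, params: CbsParams, rng: np.random.Generator) -> list[tuple[int, int]]:
    """Recursive CBS on one chromosome; returns probe-index boundaries."""
    out: list[tuple[int, int]] = []

    def recurse(lo: int, hi: int) -> None:
        n = hi - lo
        if n < 2 * params.min_split_width:
            out.append((lo, hi))
            return
        seg = x[lo:hi]
        if np.allclose(seg, seg[0]):
            out.append((lo, hi))
            return
        i, j, t = best_split(seg, params.min_split_width)
        if t <= 0:
            out.append((lo, hi))
            return
        p = _perm_max_t(seg, params.min_split_width, params.n_permutations, rng, t, params.alpha)
        if p >= params.alpha:
            out.append((lo, hi))
            return
        cuts = [c for c in (i, j) if 0 < c < n]
        if not cuts:
            out.append((lo, hi))
            return
        prev = 0
        for c in cuts + [n]:
            if c > prev:
                recurse(lo + prev, lo + c)
            prev = c

    recurse(0, len(x))
    return sorted(out)


def _merge_close(
    bounds: list[tuple[int, int]], x: np.ndarray, prune_sd: float
) -> list[tuple[int, int]]:
    """Merge adjacent segments whose means differ by < prune_sd * residual sd."""
    bounds = list(bounds)
    while len(bounds) > 1:
        means = np.array([x[a:b].mean() for a, b in bounds])
        resid = np.concatenate([x[a:b] - m for (a, b), m in zip(bounds, means)])
        s = float(np.std(resid))
        if s <= _S_FLOOR:
            s = _S_FLOOR
        diffs = np.abs(np.diff(means))
        k = int(np.argmin(diffs))
        if diffs[k] < prune_sd * s:
            bounds[k] = (bounds[k][0], bounds[k + 1][1])
            del bounds[k + 1]
        else:
            break
    return bounds


def cbs_segment(profile: ArrayProfile, params: CbsParams | None = None) -> list[Segment]:
    """Segment a (median-centered) profile per chromosome.

    Returns segments that partition the probe order of every chromosome,
    each with its probe count and mean log2 ratio.
    """
    if params is None:
        params = CbsParams()
    rng = np.random.default_rng(params.seed)
    df = profile.manifest.df
    chroms = df["chrom"].to_numpy()
    starts = df["start"].to_numpy()
    ends = df["end"].to_numpy()

    segments: list[Segment] = []
    # preserve manifest order: iterate chromosomes by first occurrence
    seen: list[str] = []
    for c in chroms:
        if c not in seen:
            seen.append(c)
    for chrom in seen:
        idx = np.flatnonzero(chroms == chrom)
        x = profile.values[idx]
        if len(x) == 1:
            bounds = [(0, 1)]
        else:
            bounds = _segment_chrom(x, params, rng)
            bounds = _merge_close(bounds, x, params.prune_sd)
        for a, b in bounds:
            gidx = idx[a:b]
            segments.append(
                Segment(
                    chrom=chrom,
                    start=int(starts[gidx].min()),
                    end=int(ends[gidx].max()),
                    first_index=int(gidx[0]),
                    n_probes=int(b - a),
                    mean_log2=float(x[a:b].mean()),
                )
            )
    return segments


def segments_to_frame(segments: list[Segment]):
    import pandas as pd

    return pd.DataFrame(
        [
            {
                "chrom": s.chrom,
                "start": s.start,
                "end": s.end,
                "first_index": s.first_index,
                "n_probes": s.n_probes,
                "mean_log2": s.mean_log2,
            }
            for s in segments
        ]
    )
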