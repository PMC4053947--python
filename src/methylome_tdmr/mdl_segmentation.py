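"""Minimum-description-length segmentation of probe runs.

Probes are first grouped into *runs*: maximal stretches of
position-sorted probes whose consecutive gaps are all < 3 kb. Each run
is then partitioned into segments of at most 50 probes so that the
total two-part description length — Gaussian data cost at the MLE of a
one-mean-per-tissue-group model plus a BIC-style parameter cost — is
minimal. The optimum is found exactly by dynamic programming;
``exhaustive_segment`` re-derives it by full enumeration and serves as
an independent oracle for short runs.
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations
from typing import Mapping, Optional, Sequence

import numpy as np

from .core_io import (
    BetaMatrix,
    ProbeAnnotation,
    SampleDesign,
    ValidationError,
    chromosome_sort_key,
)

MAX_GAP_BP = 3000
MAX_WINDOW = 50
VARIANCE_FLOOR = 1e-6
_TIE_TOL = 1e-9
_LOG2E = 1.0 / math.log(2.0)


@dataclass(frozen=True)
class Run:
    """Maximal stretch of probes with all consecutive gaps < max_gap."""

    run_id: int
    chromosome: str
    start: int  # global probe index, inclusive
    end: int  # global probe index, inclusive

    @property
    def n_probes(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class Segment:
    """Contiguous block of probes within a run, with its description length."""

    run_id: int
    chromosome: str
    start_idx: int  # global probe index, inclusive
    end_idx: int  # global probe index, inclusive
    dl_bits: float
    probe_ids: tuple[str, ...] = ()
    start_pos: int = 0  # 1-based bp of first probe
    end_pos: int = 0  # 1-based bp of last probe

    @property
    def n_probes(self) -> int:
        return self.end_idx - self.start_idx + 1


def build_runs(
    ann: Sequence[ProbeAnnotation], max_gap: int = MAX_GAP_BP
) -> list[Run]:
    """Partition position-sorted probes into maximal < max_gap runs.

    A gap exactly equal to ``max_gap`` breaks the run (strict "<").
    """
    runs: list[Run] = []
    if not ann:
        return runs
    start = 0
    for i in range(1, len(ann) + 1):
        if i == len(ann):
            new_run = True
        else:
            prev, cur = ann[i - 1], ann[i]
            if cur.chromosome == prev.chromosome:
                if cur.position <= prev.position:
                    raise ValidationError(
                        f"annotation not position-sorted at probe "
                        f"{cur.probe_id} ({cur.chromosome}:{cur.position})"
                    )
                new_run = cur.position - prev.position >= max_gap
            else:
                if chromosome_sort_key(cur.chromosome) < chromosome_sort_key(
                    prev.chromosome
                ):
                    raise ValidationError(
                        f"annotation not chromosome-sorted at probe "
                        f"{cur.probe_id}"
                    )
                new_run = True
        if new_run:
            runs.append(Run(len(runs), ann[start].chromosome, start, i - 1))
            start = i
    return runs


def _group_codes(
    bm: BetaMatrix, design: SampleDesign
) -> tuple[np.ndarray, list[str]]:
    """Integer tissue-group code per sample column, plus group names."""
    by_id = design.by_id()
    missing = [s for s in bm.sample_ids if s not in by_id]
    if missing:
        raise ValidationError(f"sample {missing[0]} not in design")
    groups = sorted({by_id[s].tissue_group for s in bm.sample_ids})
    code = {g: i for i, g in enumerate(groups)}
    return (
        np.array([code[by_id[s].tissue_group] for s in bm.sample_ids]),
        groups,
    )


def segment_dl(
    values: np.ndarray,
    group_codes: np.ndarray,
    variance_floor: float = VARIANCE_FLOOR,
) -> float:
    """Two-part description length of one segment, in bits.

    values: (p probes x s samples), no missing entries. Every value is
    an observation of its sample's tissue-group mean (one shared mean
    per group across the segment's probes) with pooled Gaussian noise.
    DL = -log2 likelihood at the MLE + ((G+1)/2) * log2(p*s).
    """
    values = np.asarray(values, dtype=float)
    if values.ndim == 1:
        values = values[None, :]
    if np.isnan(values).any():
        raise ValidationError("segment_dl requires complete values")
    group_codes = np.asarray(group_codes)
    uniq = np.unique(group_codes)
    if uniq.size < 2:
        raise ValidationError("segment_dl requires >= 2 tissue groups")
    p, s = values.shape
    n = p * s
    ss_resid = 0.0
    for g in uniq:
        sub = values[:, group_codes == g]
        ss_resid += float(((sub - sub.mean()) ** 2).sum())
    sigma2 = max(ss_resid / n, variance_floor)
    data_cost = 0.5 * n * math.log2(2.0 * math.pi * sigma2) + 0.5 * n * _LOG2E
    model_cost = 0.5 * (uniq.size + 1) * math.log2(n)
    return data_cost + model_cost


class _RunCosts:
    """Vectorised DL lookup for all sub-segments of one run."""

    def __init__(
        self,
        values: np.ndarray,
        group_codes: np.ndarray,
        variance_floor: float = VARIANCE_FLOOR,
    ):
        if np.isnan(values).any():
            raise ValidationError("segmentation requires complete probe rows")
        uniq, codes = np.unique(group_codes, return_inverse=True)
        self.n_groups = int(uniq.size)
        if self.n_groups < 2:
            raise ValidationError("segmentation requires >= 2 tissue groups")
        n_probes, n_samples = values.shape
        self.n_probes = n_probes
        self.n_samples = n_samples
        self.floor = variance_floor
        # per-probe per-group sums and sums of squares, cumulative over probes
        gsum = np.zeros((n_probes, self.n_groups))
        gsq = np.zeros((n_probes, self.n_groups))
        np.add.at(gsum.T, codes, values.T)
        np.add.at(gsq.T, codes, (values ** 2).T)
        self._csum = np.vstack([np.zeros(self.n_groups), np.cumsum(gsum, 0)])
        self._csq = np.vstack([np.zeros(self.n_groups), np.cumsum(gsq, 0)])
        self._gcount = np.bincount(codes, minlength=self.n_groups).astype(float)
        self._model_const = 0.5 * (self.n_groups + 1)

    def dl(self, i: int, j: int) -> float:
        """DL in bits of the segment spanning probes i..j inclusive."""
        p = j - i + 1
        sums = self._csum[j + 1] - self._csum[i]
        sqs = self._csq[j + 1] - self._csq[i]
        counts = p * self._gcount
        ss_resid = float((sqs - sums ** 2 / counts).sum())
        n = p * self.n_samples
        sigma2 = max(ss_resid / n, self.floor)
        return (
            0.5 * n * math.log2(2.0 * math.pi * sigma2)
            + 0.5 * n * _LOG2E
            + self._model_const * math.log2(n)
        )


def _run_values(bm: BetaMatrix, run: Run) -> np.ndarray:
    return bm.values[run.start : run.end + 1, :]


def _make_segments(
    bm: BetaMatrix,
    ann_by_id: Optional[Mapping[str, ProbeAnnotation]],
    run: Run,
    cuts: Sequence[int],
    costs: _RunCosts,
) -> list[Segment]:
    """Materialise segments from local cut positions within the run."""
    bounds = [0, *cuts, run.n_probes]
    segments = []
    for a, b in zip(bounds[:-1], bounds[1:]):
        start_idx = run.start + a
        end_idx = run.start + b - 1
        pids = tuple(bm.probe_ids[start_idx : end_idx + 1])
        if ann_by_id is not None:
            start_pos = ann_by_id[pids[0]].position
            end_pos = ann_by_id[pids[-1]].position
        else:
            start_pos = end_pos = 0
        segments.append(
            Segment(
                run_id=run.run_id,
                chromosome=run.chromosome,
                start_idx=start_idx,
                end_idx=end_idx,
                dl_bits=costs.dl(a, b - 1),
                probe_ids=pids,
                start_pos=start_pos,
                end_pos=end_pos,
            )
        )
    return segments


def segment_run(
    bm: BetaMatrix,
    design: SampleDesign,
    run: Run,
    max_window: int = MAX_WINDOW,
    annotation: Optional[Mapping[str, ProbeAnnotation]] = None,
) -> list[Segment]:
    """Optimal partition of a run into segments of <= max_window probes.

    Dynamic programming over cut points minimises the summed segment
    DLs; ties break toward fewer segments, then earlier boundaries.
    """
    codes, _ = _group_codes(bm, design)
    costs = _RunCosts(_run_values(bm, run), codes)
    n = run.n_probes
    # suffix DP: best[i] = (total DL, n segments, first-segment length)
    best_cost = np.empty(n + 1)
    best_nseg = np.empty(n + 1, dtype=int)
    best_len = np.zeros(n + 1, dtype=int)
    best_cost[n] = 0.0
    best_nseg[n] = 0
    for i in range(n - 1, -1, -1):
        c_best = math.inf
        s_best = 0
        l_best = 0
        for L in range(1, min(max_window, n - i) + 1):
            cand = costs.dl(i, i + L - 1) + best_cost[i + L]
            nseg = best_nseg[i + L] + 1
            if cand < c_best - _TIE_TOL or (
                cand <= c_best + _TIE_TOL and nseg < s_best
            ):
                c_best, s_best, l_best = cand, nseg, L
        best_cost[i] = c_best
        best_nseg[i] = s_best
        best_len[i] = l_best
    cuts = []
    i = best_len[0]
    while i < n:
        cuts.append(int(i))
        i += best_len[i]
    return _make_segments(bm, annotation, run, cuts, costs)


def exhaustive_segment(
    bm: BetaMatrix,
    design: SampleDesign,
    run: Run,
    max_window: int = MAX_WINDOW,
    annotation: Optional[Mapping[str, ProbeAnnotation]] = None,
    max_len: int = 16,
) -> list[Segment]:
    """Globally optimal partition by enumerating all 2^(n-1) cut sets.

    Test oracle for :func:`segment_run`; refuses runs longer than
    ``max_len``. Tie-breaking matches the DP: fewer segments, then
    lexicographically earliest cut positions.
    """
    n = run.n_probes
    if n > max_len:
        raise ValidationError(
            f"exhaustive_segment limited to runs of <= {max_len} probes "
            f"(got {n})"
        )
    codes, _ = _group_codes(bm, design)
    costs = _RunCosts(_run_values(bm, run), codes)
    best: Optional[tuple[float, int, tuple[int, ...]]] = None
    for k in range(n):
        for cuts in combinations(range(1, n), k):
            bounds = [0, *cuts, n]
            if any(b - a > max_window for a, b in zip(bounds[:-1], bounds[1:])):
                continue
            total = sum(
                costs.dl(a, b - 1)
                for a, b in zip(bounds[:-1], bounds[1:])
            )
            key = (total, k + 1, cuts)
            if best is None:
                best = key
            elif total < best[0] - _TIE_TOL:
                best = key
            elif total <= best[0] + _TIE_TOL and (k + 1, cuts) < best[1:]:
                best = key
    assert best is not None
    return _make_segments(bm, annotation, run, list(best[2]), costs)


def segment_all(
    bm: BetaMatrix,
    design: SampleDesign,
    ann: Sequence[ProbeAnnotation],
    max_gap: int = MAX_GAP_BP,
    max_window: int = MAX_WINDOW,
) -> list[Segment]:
    """Build runs from the annotation and segment each one."""
    ann_by_id = {a.probe_id: a for a in ann}
    ordered = [ann_by_id[p] for p in bm.probe_ids]
    runs = build_runs(ordered, max_gap=max_gap)
    segments: list[Segment] = []
    for run in runs:
        segments.extend(
            segment_run(bm, design, run, max_window=max_window,
                        annotation=ann_by_id)
        )
    return segments
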