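"""One-vs-rest ANOVA calling of tissue-specific DMRs on MDL segments.

Each segment with >= 3 probes is tested for every tissue group against
all remaining samples; per-sample segment means are the ANOVA
observations (technical replicates are collapsed to their mean first so
they do not inflate group n). Raw p-values are Bonferroni-adjusted over
the segments tested per target group and calls are retained at
adjusted p < 0.05.
"""
from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, replace
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .core_io import (
    BedRegion,
    BetaMatrix,
    ProbeAnnotation,
    SampleDesign,
    ValidationError,
    bed_score_from_p,
)
from .mdl_segmentation import Segment

CGI_TIE_ORDER = ("Island", "Shore", "Shelf", "OpenSea")


@dataclass(frozen=True)
class TDMRCall:
    segment: Segment
    target_group: str
    p_raw: float
    p_bonf: float
    delta_beta: float  # target mean - rest mean
    direction: str  # "hyper" | "hypo"
    n_probes: int
    genes: tuple[str, ...] = ()
    location_class: Optional[str] = None  # Promoter | Body | Intergenic
    cgi_class: Optional[str] = None


@dataclass
class TDMRSummary:
    per_group: pd.DataFrame  # hyper, hyper_annotated, hypo, hypo_annotated
    location_by_cgi: pd.DataFrame  # counts, location x CGI
    location_by_cgi_percent: pd.DataFrame
    total_calls: int


def collapse_replicates(
    bm: BetaMatrix, design: SampleDesign
) -> tuple[np.ndarray, list[str]]:
    """Average each sample with its technical replicates.

    Returns (probes x effective-samples values, effective sample ids);
    an effective sample is a design record with replicate_of unset.
    """
    sidx = bm.sample_index()
    members: dict[str, list[int]] = defaultdict(list)
    order: list[str] = []
    for s in design.samples:
        key = s.replicate_of if s.replicate_of is not None else s.sample_id
        if s.sample_id in sidx:
            if key not in members:
                order.append(key)
            members[key].append(sidx[s.sample_id])
    values = np.column_stack(
        [np.nanmean(bm.values[:, members[k]], axis=1) for k in order]
    )
    return values, order


def _two_group_f(target: np.ndarray, rest: np.ndarray) -> float:
    """One-way ANOVA p for two groups; zero between-group variance -> 1."""
    n1, n2 = target.size, rest.size
    grand = (target.sum() + rest.sum()) / (n1 + n2)
    ssb = n1 * (target.mean() - grand) ** 2 + n2 * (rest.mean() - grand) ** 2
    ssw = ((target - target.mean()) ** 2).sum() + ((rest - rest.mean()) ** 2).sum()
    if ssb <= 0:
        return 1.0
    if ssw <= 0:
        return 0.0
    f = ssb / (ssw / (n1 + n2 - 2))
    return float(stats.f.sf(f, 1, n1 + n2 - 2))


def test_segment(
    bm: BetaMatrix,
    design: SampleDesign,
    segment: Segment,
    target_group: str,
) -> tuple[float, float]:
    """One-vs-rest ANOVA on the segment's per-sample mean betas.

    Returns (p_raw, delta_beta) with delta = target mean - rest mean.
    """
    values, effective = collapse_replicates(bm, design)
    by_id = design.by_id()
    seg_means = np.nanmean(
        values[segment.start_idx : segment.end_idx + 1, :], axis=0
    )
    is_target = np.array(
        [by_id[s].tissue_group == target_group for s in effective]
    )
    target = seg_means[is_target]
    rest = seg_means[~is_target]
    if target.size < 2 or rest.size < 2:
        raise ValidationError(
            f"group {target_group!r}: need >= 2 samples on each side "
            f"(got {target.size} vs {rest.size})"
        )
    return _two_group_f(target, rest), float(target.mean() - rest.mean())


def call_tdmrs(
    bm: BetaMatrix,
    design: SampleDesign,
    segments: Sequence[Segment],
    alpha: float = 0.05,
    min_probes: int = 3,
    bonferroni: str = "per-group",
) -> list[TDMRCall]:
    """Test every eligible segment against every tissue group.

    ``bonferroni`` selects the correction universe: "per-group"
    multiplies by the number of segments tested for that group,
    "global" by segments x groups.
    """
    if bonferroni not in {"per-group", "global"}:
        raise ValidationError(f"unknown bonferroni mode {bonferroni!r}")
    values, effective = collapse_replicates(bm, design)
    by_id = design.by_id()
    groups = sorted({by_id[s].tissue_group for s in effective})
    group_masks = {
        g: np.array([by_id[s].tissue_group == g for s in effective])
        for g in groups
    }
    for g, mask in group_masks.items():
        if mask.sum() < 2 or (~mask).sum() < 2:
            raise ValidationError(
                f"group {g!r}: need >= 2 effective samples on each side"
            )
    eligible = [s for s in segments if s.n_probes >= min_probes]
    m = len(eligible)
    if bonferroni == "global":
        m *= len(groups)
    calls: list[TDMRCall] = []
    for seg in eligible:
        seg_means = np.nanmean(
            values[seg.start_idx : seg.end_idx + 1, :], axis=0
        )
        for g in groups:
            mask = group_masks[g]
            p_raw = _two_group_f(seg_means[mask], seg_means[~mask])
            p_bonf = min(1.0, p_raw * m)
            if p_bonf >= alpha:
                continue
            delta = float(seg_means[mask].mean() - seg_means[~mask].mean())
            calls.append(
                TDMRCall(
                    segment=seg,
                    target_group=g,
                    p_raw=p_raw,
                    p_bonf=p_bonf,
                    delta_beta=delta,
                    direction="hyper" if delta > 0 else "hypo",
                    n_probes=seg.n_probes,
                )
            )
    return calls


def annotate_calls(
    calls: Iterable[TDMRCall],
    annotation: Mapping[str, ProbeAnnotation],
) -> list[TDMRCall]:
    """Attach genes, location class and majority CGI class to calls.

    Location is promoter-dominant: any promoter-region probe makes the
    call Promoter; otherwise any gene entry makes it Body; else
    Intergenic. CGI ties resolve Island > Shore > Shelf > OpenSea.
    """
    out = []
    for call in calls:
        genes: dict[str, None] = {}
        has_promoter = False
        has_gene = False
        cgi_votes: dict[str, int] = defaultdict(int)
        for pid in call.segment.probe_ids:
            try:
                a = annotation[pid]
            except KeyError:
                raise ValidationError(f"probe {pid} has no annotation entry")
            for sym in a.gene_symbols:
                genes.setdefault(sym)
            if a.is_promoter:
                has_promoter = True
            if a.gene_entries:
                has_gene = True
            cgi_votes[a.cgi_relation] += 1
        location = (
            "Promoter" if has_promoter else "Body" if has_gene else "Intergenic"
        )
        top = max(cgi_votes.values())
        cgi = next(c for c in CGI_TIE_ORDER if cgi_votes.get(c, 0) == top)
        out.append(
            replace(call, genes=tuple(genes), location_class=location,
                    cgi_class=cgi)
        )
    return out


def summarize_calls(calls: Sequence[TDMRCall]) -> TDMRSummary:
    """Per-group hyper/hypo counts and the location x CGI cross-tab."""
    from .global_patterns import round_half_up

    groups = sorted({c.target_group for c in calls})
    rows = []
    for g in groups:
        gcalls = [c for c in calls if c.target_group == g]
        hyper = [c for c in gcalls if c.direction == "hyper"]
        hypo = [c for c in gcalls if c.direction == "hypo"]
        rows.append(
            {
                "tissue_group": g,
                "hyper": len(hyper),
                "hyper_annotated": sum(1 for c in hyper if c.genes),
                "hypo": len(hypo),
                "hypo_annotated": sum(1 for c in hypo if c.genes),
            }
        )
    per_group = pd.DataFrame(
        rows,
        columns=["tissue_group", "hyper", "hyper_annotated", "hypo",
                 "hypo_annotated"],
    ).set_index("tissue_group")
    locations = ("Promoter", "Body", "Intergenic")
    cross = pd.DataFrame(
        0, index=list(locations), columns=list(CGI_TIE_ORDER), dtype=int
    )
    for c in calls:
        cross.loc[c.location_class, c.cgi_class] += 1
    total = len(calls)
    percent = cross.map(
        lambda n: round_half_up(100.0 * n / total, 1) if total else 0.0
    )
    return TDMRSummary(per_group, cross, percent, total)


def fisher_2x2(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher exact p for the table [[a, b], [c, d]].

    Sums hypergeometric probabilities of all tables (at fixed margins)
    no more probable than the observed one. All-zero table -> 1.
    """
    for x in (a, b, c, d):
        if x < 0 or x != int(x):
            raise ValidationError("fisher_2x2 requires non-negative integers")
    total = a + b + c + d
    if total == 0:
        return 1.0
    row1 = a + b
    col1 = a + c
    rv = stats.hypergeom(total, col1, row1)
    k_min = max(0, row1 + col1 - total)
    k_max = min(row1, col1)
    support = np.arange(k_min, k_max + 1)
    pmf = rv.pmf(support)
    p_obs = rv.pmf(a)
    return float(min(1.0, pmf[pmf <= p_obs * (1 + 1e-7)].sum()))


def calls_to_frame(calls: Sequence[TDMRCall]) -> pd.DataFrame:
    """Flat table of calls for TSV export."""
    return pd.DataFrame(
        [
            {
                "chromosome": c.segment.chromosome,
                "start": c.segment.start_pos,
                "end": c.segment.end_pos,
                "target_group": c.target_group,
                "direction": c.direction,
                "n_probes": c.n_probes,
                "delta_beta": c.delta_beta,
                "p_raw": c.p_raw,
                "p_bonf": c.p_bonf,
                "genes": ";".join(c.genes),
                "location_class": c.location_class or "",
                "cgi_class": c.cgi_class or "",
                "probe_ids": ";".join(c.segment.probe_ids),
            }
            for c in calls
        ],
        columns=["chromosome", "start", "end", "target_group", "direction",
                 "n_probes", "delta_beta", "p_raw", "p_bonf", "genes",
                 "location_class", "cgi_class", "probe_ids"],
    )


def calls_to_bed(calls: Sequence[TDMRCall]) -> list[BedRegion]:
    return [
        BedRegion(
            chromosome=c.segment.chromosome,
            start=c.segment.start_pos,
            end=c.segment.end_pos,
            name=f"tDMR_{i}_{c.target_group}_{c.direction}",
            score=bed_score_from_p(c.p_bonf),
        )
        for i, c in enumerate(calls)
    ]
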