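"""Genome-wide methylation summaries.

Invariant classification, region/CGI distributions with 0.1-wide beta
histograms, tissue mean profiles with correlation and complete-linkage
clustering, one-way variance decomposition (tissue vs individual), and
gap-stratified consecutive-probe correlation diagnostics.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .core_io import (
    BetaMatrix,
    CGI_RELATIONS,
    GENE_REGIONS,
    ProbeAnnotation,
    SampleDesign,
    ValidationError,
)

HISTOGRAM_EDGES = np.linspace(0.0, 1.0, 11)


def round_half_up(x: float, ndigits: int = 1) -> float:
    """Decimal half-up rounding (0.05 -> 0.1 at one digit)."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def percent(count: float, total: float, ndigits: int = 1) -> float:
    """count/total as a percentage, half-up rounded."""
    if total == 0:
        return 0.0
    return round_half_up(100.0 * count / total, ndigits)


# ---------------------------------------------------------------------------
# invariant classification
# ---------------------------------------------------------------------------

def classify_invariant(
    bm: BetaMatrix, hi: float = 0.9, lo: float = 0.1
) -> pd.Series:
    """Label each probe InvariantHyper / InvariantHypo / Variable.

    InvariantHyper requires every non-missing beta strictly > hi;
    InvariantHypo strictly < lo. Probes with no observed values are
    Variable (a warning reports the count).
    """
    vals = bm.values
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN rows
        any_obs = ~np.isnan(vals).all(axis=1)
        all_hi = np.nanmin(vals, axis=1, initial=np.inf) > hi
        all_lo = np.nanmax(vals, axis=1, initial=-np.inf) < lo
    labels = np.where(
        any_obs & all_hi,
        "InvariantHyper",
        np.where(any_obs & all_lo, "InvariantHypo", "Variable"),
    )
    n_blank = int((~any_obs).sum())
    if n_blank:
        warnings.warn(f"{n_blank} probes with no observed values -> Variable")
    return pd.Series(labels, index=bm.probe_ids, name="invariant_label")


# ---------------------------------------------------------------------------
# region / CGI distributions
# ---------------------------------------------------------------------------

@dataclass
class RegionDistribution:
    grouping: str
    counts: pd.Series  # per class
    percentages: pd.Series  # per class, one decimal, half-up
    histograms: pd.DataFrame  # class x 10 beta bins (of all values)
    total: int


def _class_memberships(
    ann: Sequence[ProbeAnnotation], grouping: str
) -> list[tuple[str, list[str]]]:
    """(probe_id, classes) pairs; multi-region probes count in each class."""
    out = []
    for a in ann:
        if grouping == "gene_region":
            classes = sorted({r for _, r in a.gene_entries}) or ["Intergenic"]
        elif grouping == "cgi_relation":
            classes = [a.cgi_relation]
        elif grouping == "cgi_x_genic":
            genic = "intergenic" if a.is_intergenic else "intragenic"
            classes = [f"{a.cgi_relation}|{genic}"]
        else:
            raise ValidationError(f"unknown grouping {grouping!r}")
        out.append((a.probe_id, classes))
    return out


def distribution_by_region(
    bm: BetaMatrix,
    ann: Sequence[ProbeAnnotation],
    grouping: str = "gene_region",
    probe_subset: Optional[Iterable[str]] = None,
) -> RegionDistribution:
    """Counts, percentages and 0.1-bin beta histograms per class.

    ``probe_subset`` restricts the summary (e.g. to invariant probes);
    percentages are relative to the summed class counts, so a probe in
    two gene regions contributes to both.
    """
    if grouping == "gene_region":
        order = list(GENE_REGIONS) + ["Intergenic"]
    elif grouping == "cgi_relation":
        order = list(CGI_RELATIONS)
    else:
        order = None
    subset = set(probe_subset) if probe_subset is not None else None
    pidx = bm.probe_index()
    counts: dict[str, int] = {}
    hists: dict[str, np.ndarray] = {}
    for pid, classes in _class_memberships(ann, grouping):
        if pid not in pidx or (subset is not None and pid not in subset):
            continue
        row = bm.values[pidx[pid], :]
        row = row[~np.isnan(row)]
        h, _ = np.histogram(row, bins=HISTOGRAM_EDGES)
        for cls in classes:
            counts[cls] = counts.get(cls, 0) + 1
            hists[cls] = hists.get(cls, np.zeros(10, dtype=int)) + h
    if order is None:
        order = sorted(counts)
    order = [c for c in order if c in counts]
    count_s = pd.Series({c: counts[c] for c in order}, dtype=int)
    total = int(count_s.sum())
    pct = count_s.map(lambda n: percent(n, total))
    hist_df = pd.DataFrame(
        {c: hists[c] for c in order},
        index=[f"[{e:.1f},{e2:.1f})" for e, e2 in
               zip(HISTOGRAM_EDGES[:-1], HISTOGRAM_EDGES[1:])],
    ).T
    return RegionDistribution(grouping, count_s, pct, hist_df, total)


# ---------------------------------------------------------------------------
# tissue profiles, correlation, clustering
# ---------------------------------------------------------------------------

def tissue_mean_profiles(
    bm: BetaMatrix, design: SampleDesign, by: str = "tissue"
) -> pd.DataFrame:
    """Tissues x probes matrix of per-probe mean beta over samples."""
    if by not in {"tissue", "tissue_group"}:
        raise ValidationError(f"unknown profile key {by!r}")
    by_id = design.by_id()
    labels = [getattr(by_id[s], by) for s in bm.sample_ids]
    rows = {}
    for t in sorted(set(labels)):
        cols = [j for j, lab in enumerate(labels) if lab == t]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            rows[t] = np.nanmean(bm.values[:, cols], axis=1)
    return pd.DataFrame(rows, index=bm.probe_ids).T


def tissue_correlation_matrix(profiles: pd.DataFrame) -> pd.DataFrame:
    """Pairwise Pearson correlation of tissue profiles over probes."""
    if profiles.shape[1] < 2:
        raise ValidationError("need >= 2 probes to correlate profiles")
    sd = profiles.std(axis=1, ddof=0)
    flat = sd[sd == 0].index.tolist()
    if flat:
        raise ValidationError(
            f"zero-variance profile for tissue {flat[0]!r}: "
            "correlation undefined"
        )
    corr = np.corrcoef(profiles.values)
    np.fill_diagonal(corr, 1.0)
    return pd.DataFrame(corr, index=profiles.index, columns=profiles.index)


def cluster_tissues(
    profiles: pd.DataFrame,
    linkage: str = "complete",
    distance: str = "correlation",
) -> tuple[str, pd.DataFrame]:
    """Agglomerative clustering of tissue profiles.

    distance "correlation" uses 1 - Pearson r; "euclidean" is the
    alternative. Tissues are sorted lexicographically first so the
    result is independent of input row order. Returns (newick string,
    merge table).
    """
    profiles = profiles.sort_index()
    names = list(profiles.index)
    if len(names) < 2:
        raise ValidationError("need >= 2 tissues to cluster")
    if distance == "correlation":
        dmat = 1.0 - tissue_correlation_matrix(profiles).values
        np.fill_diagonal(dmat, 0.0)
        dmat = np.clip((dmat + dmat.T) / 2.0, 0.0, None)
        condensed = squareform(dmat, checks=False)
    elif distance == "euclidean":
        from scipy.spatial.distance import pdist

        condensed = pdist(profiles.values)
    else:
        raise ValidationError(f"unknown distance {distance!r}")
    Z = hierarchy.linkage(condensed, method=linkage)
    merge = pd.DataFrame(
        Z, columns=["left", "right", "height", "n_leaves"]
    )
    tree = hierarchy.to_tree(Z)
    newick = _to_newick(tree, names) + ";"
    return newick, merge


def _to_newick(node, names: list[str]) -> str:
    if node.is_leaf():
        return names[node.id]
    left = _to_newick(node.left, names)
    right = _to_newick(node.right, names)
    dl = max(node.dist - node.left.dist, 0.0)
    dr = max(node.dist - node.right.dist, 0.0)
    return f"({left}:{dl:.6g},{right}:{dr:.6g})"


# ---------------------------------------------------------------------------
# variance decomposition
# ---------------------------------------------------------------------------

@dataclass
class VarianceReport:
    r2_tissue: pd.Series
    r2_individual: pd.Series
    mean_r2_tissue: float
    mean_r2_individual: float


def variance_explained(
    bm: BetaMatrix, design: SampleDesign, factor: str
) -> pd.Series:
    """Per-probe one-way R^2 = SS_between / SS_total for one factor.

    factor is "tissue" or "individual"; probes with zero total sum of
    squares get R^2 = 0.
    """
    attr = {"tissue": "tissue", "individual": "individual_id"}.get(factor)
    if attr is None:
        raise ValidationError(f"unknown factor {factor!r}")
    by_id = design.by_id()
    labels = np.array([getattr(by_id[s], attr) for s in bm.sample_ids])
    levels = np.unique(labels)
    if levels.size < 2:
        raise ValidationError(f"factor {factor!r} needs >= 2 levels")
    vals = bm.values
    obs = ~np.isnan(vals)
    filled = np.where(obs, vals, 0.0)
    n_obs = obs.sum(axis=1)
    grand = filled.sum(axis=1) / np.maximum(n_obs, 1)
    ss_total = (np.where(obs, vals - grand[:, None], 0.0) ** 2).sum(axis=1)
    ss_between = np.zeros(bm.n_probes)
    for lev in levels:
        cols = labels == lev
        n_l = obs[:, cols].sum(axis=1)
        s_l = filled[:, cols].sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            mean_l = s_l / n_l
        contrib = n_l * (mean_l - grand) ** 2
        ss_between += np.where(n_l > 0, contrib, 0.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        r2 = np.where(ss_total > 0, ss_between / ss_total, 0.0)
    return pd.Series(np.clip(r2, 0.0, 1.0), index=bm.probe_ids,
                     name=f"r2_{factor}")


def variance_report(bm: BetaMatrix, design: SampleDesign) -> VarianceReport:
    r2_t = variance_explained(bm, design, "tissue")
    r2_i = variance_explained(bm, design, "individual")
    return VarianceReport(r2_t, r2_i, float(r2_t.mean()), float(r2_i.mean()))


def variance_by_annotation(
    bm: BetaMatrix,
    design: SampleDesign,
    ann: Sequence[ProbeAnnotation],
    grouping: str = "gene_region",
    factor: str = "tissue",
) -> dict[str, pd.Series]:
    """R^2 distributions stratified by annotation class."""
    r2 = variance_explained(bm, design, factor)
    present = set(bm.probe_ids)
    members: dict[str, list[str]] = {}
    for pid, classes in _class_memberships(ann, grouping):
        if pid not in present:
            continue
        for cls in classes:
            members.setdefault(cls, []).append(pid)
    out = {}
    for cls, pids in members.items():
        if not pids:
            warnings.warn(f"annotation class {cls!r} is empty; omitted")
            continue
        out[cls] = r2.loc[pids]
    return out


# ---------------------------------------------------------------------------
# distance and replicate diagnostics
# ---------------------------------------------------------------------------

def consecutive_probe_correlation(
    bm: BetaMatrix,
    ann: Sequence[ProbeAnnotation],
    threshold: int = 3000,
) -> tuple[float, float, pd.DataFrame]:
    """Correlation of adjacent probes, stratified by gap size.

    For every adjacent same-chromosome probe pair, the Pearson
    correlation of their beta vectors across samples. Returns (mean PCC
    for gaps < threshold, mean PCC for gaps >= threshold, full table);
    zero-variance pairs are skipped and counted in the table attrs.
    """
    ann_by_id = {a.probe_id: a for a in ann}
    rows = []
    skipped = 0
    for i in range(bm.n_probes - 1):
        a = ann_by_id[bm.probe_ids[i]]
        b = ann_by_id[bm.probe_ids[i + 1]]
        if a.chromosome != b.chromosome:
            continue
        x, y = bm.values[i, :], bm.values[i + 1, :]
        ok = ~np.isnan(x) & ~np.isnan(y)
        if ok.sum() < 3 or x[ok].std() == 0 or y[ok].std() == 0:
            skipped += 1
            continue
        pcc = float(np.corrcoef(x[ok], y[ok])[0, 1])
        rows.append(
            {"chromosome": a.chromosome, "gap": b.position - a.position,
             "pcc": pcc}
        )
    table = pd.DataFrame(rows, columns=["chromosome", "gap", "pcc"])
    table.attrs["skipped_pairs"] = skipped
    short = table.loc[table["gap"] < threshold, "pcc"]
    long_ = table.loc[table["gap"] >= threshold, "pcc"]
    return (
        float(short.mean()) if len(short) else float("nan"),
        float(long_.mean()) if len(long_) else float("nan"),
        table,
    )


def replicate_concordance(
    bm: BetaMatrix, design: SampleDesign
) -> pd.DataFrame:
    """Pearson correlation across probes for each declared replicate pair."""
    sidx = bm.sample_index()
    rows = []
    for rep, original in design.replicate_pairs():
        if rep not in sidx or original not in sidx:
            continue
        x = bm.values[:, sidx[rep]]
        y = bm.values[:, sidx[original]]
        ok = ~np.isnan(x) & ~np.isnan(y)
        pcc = float(np.corrcoef(x[ok], y[ok])[0, 1])
        rows.append({"sample": rep, "replicate_of": original, "pcc": pcc})
    return pd.DataFrame(rows, columns=["sample", "replicate_of", "pcc"])
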