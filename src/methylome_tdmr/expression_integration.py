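"""Methylation--expression correlation and its classification tables.

Gene-level (or tDMR-level) mean betas per tissue group are correlated
against a gene x tissue expression matrix; the resulting Pearson
coefficients are classified by sign and by the |r| > 0.5 strong
thresholds into Table-style rows.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .core_io import (
    BetaMatrix,
    PROMOTER_REGIONS,
    ProbeAnnotation,
    SampleDesign,
    ValidationError,
)
from .global_patterns import percent, tissue_mean_profiles
from .tdmr_caller import TDMRCall

#: region filters accepted by :func:`average_beta_by_gene`
REGION_FILTERS = (
    "Promoter+CGI", "TSS1500", "TSS200", "UTR5", "FirstExon", "Body",
    "UTR3", "Shore", "Shelf",
)


def _probe_qualifies(
    a: ProbeAnnotation, gene_region: str, region_filter: Optional[str]
) -> bool:
    if region_filter is None:
        return True
    if region_filter == "Promoter+CGI":
        return gene_region in PROMOTER_REGIONS and a.cgi_relation == "Island"
    if region_filter in {"Shore", "Shelf"}:
        return a.cgi_relation == region_filter
    return gene_region == region_filter


def average_beta_by_gene(
    bm: BetaMatrix,
    ann: Sequence[ProbeAnnotation],
    design: SampleDesign,
    region_filter: Optional[str] = None,
) -> pd.DataFrame:
    """Gene x tissue-group table of mean beta over qualifying probes.

    A gene qualifies with >= 1 probe passing the filter; genes with
    none are omitted. Filters: None (all probes), "Promoter+CGI"
    (promoter region and Island), a gene-region name, or
    "Shore"/"Shelf" (CGI relation, any region).
    """
    if region_filter is not None and region_filter not in REGION_FILTERS:
        raise ValidationError(f"unknown region filter {region_filter!r}")
    profiles = tissue_mean_profiles(bm, design, by="tissue_group")
    pidx = bm.probe_index()
    gene_probes: dict[str, list[int]] = {}
    for a in ann:
        if a.probe_id not in pidx:
            continue
        for sym, region in a.gene_entries:
            if _probe_qualifies(a, region, region_filter):
                gene_probes.setdefault(sym, []).append(pidx[a.probe_id])
    rows = {}
    for gene in sorted(gene_probes):
        cols = sorted(set(gene_probes[gene]))
        rows[gene] = np.nanmean(profiles.values[:, cols], axis=1)
    return pd.DataFrame(rows, index=profiles.index).T


def average_beta_by_tdmr(
    calls: Sequence[TDMRCall],
    bm: BetaMatrix,
    design: SampleDesign,
) -> pd.DataFrame:
    """tDMR x tissue-group table of mean beta over each call's probes."""
    profiles = tissue_mean_profiles(bm, design, by="tissue_group")
    pidx = bm.probe_index()
    rows = {}
    for i, call in enumerate(calls):
        cols = [pidx[p] for p in call.segment.probe_ids]
        rows[f"tdmr{i:05d}"] = np.nanmean(profiles.values[:, cols], axis=1)
    return pd.DataFrame(rows, index=profiles.index).T


def correlate_methylation_expression(
    meth: pd.DataFrame,
    expr: pd.DataFrame,
    min_shared: int = 3,
    gene_of: Optional[Mapping[str, str]] = None,
) -> tuple[pd.Series, dict[str, int]]:
    """Per-row Pearson correlation between methylation and expression.

    ``meth`` rows are genes (or tDMRs, with ``gene_of`` mapping row ids
    to gene symbols); columns are tissues, intersected with ``expr``
    columns. Duplicate expression rows per gene are collapsed by
    median. Rows with < min_shared shared tissues or zero variance on
    either side are skipped and counted.
    """
    shared = [t for t in meth.columns if t in expr.columns]
    if not shared:
        raise ValidationError("no shared tissues between methylation and "
                              "expression tables")
    expr = expr.groupby(level=0).median()
    pccs = {}
    skipped = {"no_expression": 0, "too_few_tissues": 0, "zero_variance": 0}
    for row_id, mrow in meth.iterrows():
        gene = gene_of.get(row_id, row_id) if gene_of is not None else row_id
        if gene not in expr.index:
            skipped["no_expression"] += 1
            continue
        x = mrow[shared].to_numpy(dtype=float)
        y = expr.loc[gene, shared].to_numpy(dtype=float)
        ok = ~np.isnan(x) & ~np.isnan(y)
        if ok.sum() < min_shared:
            skipped["too_few_tissues"] += 1
            continue
        if x[ok].std() == 0 or y[ok].std() == 0:
            skipped["zero_variance"] += 1
            continue
        pccs[row_id] = float(np.corrcoef(x[ok], y[ok])[0, 1])
    return pd.Series(pccs, dtype=float, name="pcc"), skipped


@dataclass
class CorrelationRow:
    label: str
    n_neg: int
    n_pos: int
    n_strong_neg: int
    n_strong_pos: int
    total: int
    pct_neg: float
    pct_pos: float
    pct_strong_neg: float
    pct_strong_pos: float


def classify_correlations(
    pccs: Sequence[float] | pd.Series,
    strong: float = 0.5,
    label: str = "Global",
    ndigits: int = 1,
) -> CorrelationRow:
    """Count correlations by sign and strong thresholds.

    PCC < 0 is negative, >= 0 positive (zero counts as positive so the
    two signs sum to the total); strong means strictly < -strong or
    > +strong.
    """
    arr = np.asarray(pd.Series(pccs).dropna(), dtype=float)
    n_neg = int((arr < 0).sum())
    n_pos = int((arr >= 0).sum())
    total = arr.size
    n_sneg = int((arr < -strong).sum())
    n_spos = int((arr > strong).sum())
    return CorrelationRow(
        label=label,
        n_neg=n_neg,
        n_pos=n_pos,
        n_strong_neg=n_sneg,
        n_strong_pos=n_spos,
        total=total,
        pct_neg=percent(n_neg, total, ndigits),
        pct_pos=percent(n_pos, total, ndigits),
        pct_strong_neg=percent(n_sneg, total, ndigits),
        pct_strong_pos=percent(n_spos, total, ndigits),
    )


def correlation_table(
    bm: BetaMatrix,
    ann: Sequence[ProbeAnnotation],
    design: SampleDesign,
    expr: pd.DataFrame,
    filters: Sequence[Optional[str]] = (None, "Promoter+CGI", "TSS1500",
                                        "TSS200", "UTR5", "FirstExon",
                                        "Body", "UTR3", "Shore", "Shelf"),
    strong: float = 0.5,
    min_shared: int = 3,
) -> pd.DataFrame:
    """Per-region-class correlation classification (Table-3 shape)."""
    rows = []
    for f in filters:
        meth = average_beta_by_gene(bm, ann, design, region_filter=f)
        if meth.empty:
            continue
        pccs, _ = correlate_methylation_expression(
            meth, expr, min_shared=min_shared
        )
        row = classify_correlations(
            pccs, strong=strong, label=f or "Global"
        )
        rows.append(vars(row))
    return pd.DataFrame(rows).set_index("label")
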