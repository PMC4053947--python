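"""Seeded generator of 450K-like datasets with planted ground truth.

Probe positions follow a cluster/gap mixture so that <3 kb runs exist;
beta values are drawn from Beta(mu*kappa, (1-mu)*kappa) around a
logit-shifted mean combining a (gene-region x CGI-class) baseline,
per-(probe, tissue-group) and per-(probe, individual) random effects,
and planted contiguous tDMR shifts recorded in a truth table.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import mdl_segmentation
from .core_io import (
    BetaMatrix,
    ProbeAnnotation,
    SampleDesign,
    SampleRecord,
    ValidationError,
)

_EPS = 1e-4

#: baseline mean beta keyed by (promoter-ness, CGI class); "body" covers
#: gene-body, 3'UTR and intergenic probes. Island/shore promoters are
#: nearly unmethylated, open-sea body probes nearly fully methylated,
#: intermediate combinations interpolate between the two modes.
DEFAULT_BASELINE_MEANS: dict[tuple[str, str], float] = {
    ("promoter", "Island"): 0.03,
    ("promoter", "Shore"): 0.06,
    ("promoter", "Shelf"): 0.60,
    ("promoter", "OpenSea"): 0.65,
    ("body", "Island"): 0.08,
    ("body", "Shore"): 0.50,
    ("body", "Shelf"): 0.92,
    ("body", "OpenSea"): 0.95,
}

DEFAULT_REGION_FRACTIONS: dict[str, float] = {
    "TSS1500": 0.13,
    "TSS200": 0.12,
    "UTR5": 0.08,
    "FirstExon": 0.07,
    "Body": 0.30,
    "UTR3": 0.08,
    "Intergenic": 0.22,
}

DEFAULT_CGI_FRACTIONS: dict[str, float] = {
    "Island": 0.35,
    "Shore": 0.25,
    "Shelf": 0.10,
    "OpenSea": 0.30,
}


@dataclass
class SimulationConfig:
    n_probes: int = 2000
    n_chromosomes: int = 4
    cluster_gap_mean: float = 150.0  # bp, geometric within clusters
    long_gap_offset: int = 3000  # bp, minimum between-cluster gap
    long_gap_mean: float = 2000.0  # bp beyond the offset
    w_cluster: float = 0.9  # probability the next gap stays in-cluster
    region_fractions: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_REGION_FRACTIONS)
    )
    cgi_fractions: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_CGI_FRACTIONS)
    )
    snp_fraction: float = 0.01
    label_switch_prob: float = 0.1  # chance a probe redraws region/CGI
    #   within its cluster; labels always redraw on cluster change
    n_tissue_groups: int = 12
    n_individuals: int = 4
    replicate_pairs: int = 2
    baseline_means: dict[tuple[str, str], float] = field(
        default_factory=lambda: dict(DEFAULT_BASELINE_MEANS)
    )
    noise_concentration: float = 100.0  # beta-distribution kappa
    tissue_sd: float = 0.0  # logit-scale per-(probe, group) effect
    individual_sd: float = 0.15  # logit-scale per-(probe, individual)
    n_dmrs: int = 30
    dmr_length_probes: tuple[int, int] = (3, 20)
    dmr_delta: tuple[float, float] = (0.3, 0.5)
    dmr_direction_prob: float = 0.5  # probability a DMR is hypo
    seed: int = 0

    def __post_init__(self) -> None:
        for name, frac in (
            ("region_fractions", self.region_fractions),
            ("cgi_fractions", self.cgi_fractions),
        ):
            if abs(sum(frac.values()) - 1.0) > 1e-9:
                raise ValidationError(f"{name} must sum to 1")
        if self.noise_concentration <= 2:
            raise ValidationError("noise_concentration must be > 2")
        lo, hi = self.dmr_delta
        if not (0 < lo <= hi < 1):
            raise ValidationError("dmr_delta must satisfy 0 < lo <= hi < 1")
        if not 0 <= self.w_cluster <= 1:
            raise ValidationError("w_cluster must be in [0, 1]")


@dataclass(frozen=True)
class DMRRecord:
    dmr_id: str
    chromosome: str
    probe_ids: tuple[str, ...]
    target_group: str
    direction: str  # "hyper" | "hypo"
    delta: float


@dataclass
class TruthTable:
    dmrs: list[DMRRecord] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "dmr_id": d.dmr_id,
                    "chromosome": d.chromosome,
                    "probe_ids": ";".join(d.probe_ids),
                    "target_group": d.target_group,
                    "direction": d.direction,
                    "delta": d.delta,
                }
                for d in self.dmrs
            ],
            columns=["dmr_id", "chromosome", "probe_ids", "target_group",
                     "direction", "delta"],
        )

    def write(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def read(cls, path: str | Path) -> "TruthTable":
        df = pd.read_csv(path, sep="\t", dtype=str)
        return cls(
            [
                DMRRecord(
                    r.dmr_id, r.chromosome, tuple(r.probe_ids.split(";")),
                    r.target_group, r.direction, float(r.delta)
                )
                for r in df.itertuples(index=False)
            ]
        )


def _logit(x: np.ndarray) -> np.ndarray:
    return np.log(x / (1.0 - x))


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


def generate_annotation(cfg: SimulationConfig) -> list[ProbeAnnotation]:
    """Probe annotations with clustered positions and class labels.

    Region and CGI classes are spatially coherent: they redraw on every
    cluster change and otherwise only with ``label_switch_prob``, so
    islands and gene blocks form contiguous stretches as on the real
    array. Non-intergenic probes of a cluster share a gene symbol.
    """
    rng = np.random.default_rng(cfg.seed)
    ann: list[ProbeAnnotation] = []
    if cfg.n_probes == 0:
        return ann
    regions = list(cfg.region_fractions)
    region_p = np.array([cfg.region_fractions[r] for r in regions])
    cgis = list(cfg.cgi_fractions)
    cgi_p = np.array([cfg.cgi_fractions[c] for c in cgis])
    per_chrom = np.full(cfg.n_chromosomes, cfg.n_probes // cfg.n_chromosomes)
    per_chrom[: cfg.n_probes % cfg.n_chromosomes] += 1
    probe_no = 0
    for ci in range(cfg.n_chromosomes):
        chrom = f"chr{ci + 1}"
        pos = int(rng.integers(10_000, 50_000))
        cluster_id = 0
        region = cgi = None
        for k in range(int(per_chrom[ci])):
            redraw = region is None
            if k > 0:
                if rng.random() < cfg.w_cluster:
                    gap = int(rng.geometric(1.0 / cfg.cluster_gap_mean))
                    redraw = redraw or rng.random() < cfg.label_switch_prob
                else:
                    gap = cfg.long_gap_offset + int(
                        rng.geometric(1.0 / cfg.long_gap_mean)
                    )
                    cluster_id += 1
                    redraw = True
                pos += gap
            if redraw:
                region = regions[int(rng.choice(len(regions), p=region_p))]
                cgi = cgis[int(rng.choice(len(cgis), p=cgi_p))]
            if region == "Intergenic":
                gene_entries: tuple[tuple[str, str], ...] = ()
            else:
                gene_entries = ((f"G{ci + 1}_{cluster_id}", region),)
            ann.append(
                ProbeAnnotation(
                    probe_id=f"cg{probe_no:07d}",
                    chromosome=chrom,
                    position=pos,
                    gene_entries=gene_entries,
                    cgi_relation=cgi,
                    snp_flag=bool(rng.random() < cfg.snp_fraction),
                )
            )
            probe_no += 1
    return ann


def generate_design(cfg: SimulationConfig) -> SampleDesign:
    """Balanced design: every group x individual, plus replicate twins."""
    samples = []
    for gi in range(cfg.n_tissue_groups):
        group = f"tissue{gi + 1:02d}"
        for ii in range(cfg.n_individuals):
            samples.append(
                SampleRecord(
                    sample_id=f"{group}_ind{ii + 1}",
                    tissue=group,
                    tissue_group=group,
                    individual_id=f"ind{ii + 1}",
                )
            )
    for r in range(min(cfg.replicate_pairs, len(samples))):
        src = samples[r]
        samples.append(
            SampleRecord(
                sample_id=f"{src.sample_id}_rep",
                tissue=src.tissue,
                tissue_group=src.tissue_group,
                individual_id=src.individual_id,
                replicate_of=src.sample_id,
            )
        )
    return SampleDesign(samples)


def _baseline_mu(
    ann: Sequence[ProbeAnnotation],
    baseline_means: dict[tuple[str, str], float],
) -> np.ndarray:
    mu = np.empty(len(ann))
    for i, a in enumerate(ann):
        key = "promoter" if a.is_promoter else "body"
        mu[i] = baseline_means[(key, a.cgi_relation)]
    return mu


def _plant_dmrs(
    cfg: SimulationConfig,
    ann: Sequence[ProbeAnnotation],
    groups: Sequence[str],
    rng: np.random.Generator,
) -> TruthTable:
    """Pick non-overlapping contiguous probe windows inside <3 kb runs."""
    runs = mdl_segmentation.build_runs(list(ann))
    min_len, max_len = cfg.dmr_length_probes
    taken = np.zeros(len(ann), dtype=bool)
    candidates = [r for r in runs if r.n_probes >= min_len]
    truth = TruthTable()
    attempts = 0
    while len(truth.dmrs) < cfg.n_dmrs and attempts < cfg.n_dmrs * 50:
        attempts += 1
        if not candidates:
            break
        run = candidates[int(rng.integers(len(candidates)))]
        length = int(
            rng.integers(min_len, min(max_len, run.n_probes) + 1)
        )
        start = run.start + int(rng.integers(run.n_probes - length + 1))
        if taken[start : start + length].any():
            continue
        taken[start : start + length] = True
        direction = "hypo" if rng.random() < cfg.dmr_direction_prob else "hyper"
        delta = float(rng.uniform(*cfg.dmr_delta))
        truth.dmrs.append(
            DMRRecord(
                dmr_id=f"dmr{len(truth.dmrs):04d}",
                chromosome=run.chromosome,
                probe_ids=tuple(
                    ann[i].probe_id for i in range(start, start + length)
                ),
                target_group=groups[int(rng.integers(len(groups)))],
                direction=direction,
                delta=delta,
            )
        )
    return truth


def generate_betas(
    cfg: SimulationConfig,
    ann: Sequence[ProbeAnnotation],
    design: SampleDesign,
) -> tuple[BetaMatrix, TruthTable]:
    """Draw the beta matrix and the planted-DMR truth table.

    Replicate pairs share the per-sample mean mu and differ only by
    Beta-distribution measurement noise.
    """
    rng = np.random.default_rng(cfg.seed + 1)
    n_probes = len(ann)
    groups = sorted({s.tissue_group for s in design.samples})
    individuals = sorted({s.individual_id for s in design.samples})
    g_index = {g: i for i, g in enumerate(groups)}
    i_index = {ind: i for i, ind in enumerate(individuals)}
    base_mu = _baseline_mu(ann, cfg.baseline_means)
    base_logit = _logit(np.clip(base_mu, _EPS, 1 - _EPS))
    tissue_eff = (
        rng.normal(0.0, cfg.tissue_sd, size=(n_probes, len(groups)))
        if cfg.tissue_sd > 0
        else np.zeros((n_probes, len(groups)))
    )
    indiv_eff = (
        rng.normal(0.0, cfg.individual_sd, size=(n_probes, len(individuals)))
        if cfg.individual_sd > 0
        else np.zeros((n_probes, len(individuals)))
    )
    truth = _plant_dmrs(cfg, ann, groups, rng)
    # per-(probe, group) logit override where a DMR is planted
    probe_idx = {a.probe_id: i for i, a in enumerate(ann)}
    dmr_logit = np.full((n_probes, len(groups)), np.nan)
    for d in truth.dmrs:
        sign = 1.0 if d.direction == "hyper" else -1.0
        for pid in d.probe_ids:
            i = probe_idx[pid]
            shifted = np.clip(base_mu[i] + sign * d.delta, _EPS, 1 - _EPS)
            dmr_logit[i, g_index[d.target_group]] = math.log(
                shifted / (1.0 - shifted)
            )
    # mu per (probe, effective sample); replicates reuse their source's mu
    mu_cache: dict[str, np.ndarray] = {}
    columns = []
    kappa = cfg.noise_concentration
    for s in design.samples:
        if s.replicate_of is not None and s.replicate_of in mu_cache:
            mu = mu_cache[s.replicate_of]
        else:
            gi = g_index[s.tissue_group]
            lo = np.where(
                np.isnan(dmr_logit[:, gi]), base_logit, dmr_logit[:, gi]
            )
            lo = lo + tissue_eff[:, gi] + indiv_eff[:, i_index[s.individual_id]]
            mu = np.clip(_sigmoid(lo), _EPS, 1 - _EPS)
            mu_cache[s.sample_id] = mu
        columns.append(rng.beta(mu * kappa, (1.0 - mu) * kappa))
    values = np.column_stack(columns) if columns else np.empty((n_probes, 0))
    bm = BetaMatrix(
        [a.probe_id for a in ann],
        [s.sample_id for s in design.samples],
        values,
    )
    return bm, truth


def generate_expression(
    gene_beta: pd.DataFrame,
    rho: float,
    seed: int,
    scale: float = 2.0,
    center: float = 8.0,
) -> pd.DataFrame:
    """Gene x tissue expression with target methylation correlation.

    Per gene, expression = rho * standardized(beta) + sqrt(1 - rho^2) *
    noise, then affinely rescaled; the expected Pearson correlation with
    the gene's beta profile is rho. Constant-beta genes get pure noise.
    """
    if not -1.0 <= rho <= 1.0:
        raise ValidationError(f"rho {rho} outside [-1, 1]")
    rng = np.random.default_rng(seed)
    x = gene_beta.values.astype(float)
    sd = x.std(axis=1, ddof=0, keepdims=True)
    mean = x.mean(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        z = np.where(sd > 0, (x - mean) / sd, 0.0)
    noise_w = math.sqrt(max(0.0, 1.0 - rho * rho))
    noise = rng.standard_normal(x.shape) if noise_w > 0 else np.zeros_like(x)
    expr = rho * z + noise_w * noise
    return pd.DataFrame(
        expr * scale + center, index=gene_beta.index,
        columns=gene_beta.columns,
    )


def generate_dataset(
    cfg: SimulationConfig,
) -> tuple[list[ProbeAnnotation], SampleDesign, BetaMatrix, TruthTable]:
    """Annotation, design and betas in one call (shared config seed)."""
    ann = generate_annotation(cfg)
    design = generate_design(cfg)
    bm, truth = generate_betas(cfg, ann, design)
    return ann, design, bm, truth
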