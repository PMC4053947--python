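"""Data model, readers/writers, and pre-analysis probe filters.

Coordinate conventions: annotation positions are 1-based; all exported
BED is 0-based half-open. Probe order is always (chromosome, position).
"""
from __future__ import annotations

import math
import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

GENE_REGIONS = ("TSS1500", "TSS200", "UTR5", "FirstExon", "Body", "UTR3")
PROMOTER_REGIONS = frozenset({"TSS1500", "TSS200", "UTR5", "FirstExon"})
CGI_RELATIONS = ("Island", "Shore", "Shelf", "OpenSea")

# sided manifest spellings collapse onto the unsided classes
_CGI_ALIASES = {
    "N_Shore": "Shore",
    "S_Shore": "Shore",
    "N_Shelf": "Shelf",
    "S_Shelf": "Shelf",
}

# The 17-tissue panel collapsed to the 12 functional groups used for
# one-vs-rest calling (paired vessels, marrow, adipose and skeletal
# tissues are processed together).
TISSUE_GROUP_17_TO_12: dict[str, str] = {
    "adipose_subcutaneous": "adipose",
    "adipose_abdominal": "adipose",
    "artery_coronary": "artery",
    "artery_splenic": "artery",
    "bone": "bone_cartilage",
    "joint_cartilage": "bone_cartilage",
    "bone_marrow_red": "bone_marrow",
    "bone_marrow_yellow": "bone_marrow",
    "gastric_mucosa": "gastric_mucosa",
    "lymph_node": "lymph_node",
    "tonsils": "tonsils",
    "bladder": "bladder",
    "gall_bladder": "gall_bladder",
    "aorta_thoracic": "aorta",
    "aorta_abdominal": "aorta",
    "medulla_oblongata": "medulla_oblongata",
    "ischiatic_nerve": "ischiatic_nerve",
}


class ValidationError(ValueError):
    """Input violates a documented contract (exit code 1 in the CLI)."""


class ParseError(ValueError):
    """Input file is syntactically malformed (exit code 1 in the CLI)."""


def chromosome_sort_key(chromosome: str) -> tuple[int, int, str]:
    """Natural ordering: chr1 < chr2 < ... < chr10 < chrX-style names."""
    m = re.fullmatch(r"(?:chr)?(\d+)", chromosome)
    if m:
        return (0, int(m.group(1)), "")
    return (1, 0, chromosome)


@dataclass(frozen=True)
class ProbeAnnotation:
    """Genomic location and functional classes of one array probe."""

    probe_id: str
    chromosome: str
    position: int  # 1-based bp
    gene_entries: tuple[tuple[str, str], ...] = ()  # (symbol, region)
    cgi_relation: str = "OpenSea"
    snp_flag: bool = False

    def __post_init__(self) -> None:
        if self.position < 1:
            raise ValidationError(
                f"probe {self.probe_id}: position {self.position} < 1"
            )
        if self.cgi_relation not in CGI_RELATIONS:
            raise ValidationError(
                f"probe {self.probe_id}: unknown CGI relation "
                f"{self.cgi_relation!r}"
            )
        for _, region in self.gene_entries:
            if region not in GENE_REGIONS:
                raise ValidationError(
                    f"probe {self.probe_id}: unknown gene region {region!r}"
                )

    @property
    def is_intergenic(self) -> bool:
        return not self.gene_entries

    @property
    def is_promoter(self) -> bool:
        return any(r in PROMOTER_REGIONS for _, r in self.gene_entries)

    @property
    def gene_symbols(self) -> tuple[str, ...]:
        seen: dict[str, None] = {}
        for sym, _ in self.gene_entries:
            seen.setdefault(sym)
        return tuple(seen)


@dataclass
class BetaMatrix:
    """Probes x samples methylation fractions in [0, 1]; NaN = missing."""

    probe_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray  # shape (n_probes, n_samples), float

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.probe_ids), len(self.sample_ids)):
            raise ValidationError(
                f"beta matrix shape {self.values.shape} does not match "
                f"{len(self.probe_ids)} probes x {len(self.sample_ids)} samples"
            )
        bad = np.where(
            ~np.isnan(self.values) & ((self.values < 0) | (self.values > 1))
        )
        if bad[0].size:
            i, j = bad[0][0], bad[1][0]
            raise ValidationError(
                f"beta value {self.values[i, j]!r} out of [0, 1] at probe "
                f"{self.probe_ids[i]}, sample {self.sample_ids[j]}"
            )

    @property
    def n_probes(self) -> int:
        return len(self.probe_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def probe_index(self) -> dict[str, int]:
        return {p: i for i, p in enumerate(self.probe_ids)}

    def sample_index(self) -> dict[str, int]:
        return {s: j for j, s in enumerate(self.sample_ids)}

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=self.probe_ids, columns=self.sample_ids
        )

    def subset_probes(self, keep: Sequence[int]) -> "BetaMatrix":
        keep = list(keep)
        return BetaMatrix(
            [self.probe_ids[i] for i in keep],
            list(self.sample_ids),
            self.values[keep, :],
        )

    def sort_by_position(
        self, annotation: Mapping[str, ProbeAnnotation]
    ) -> "BetaMatrix":
        """Reorder probes by (chromosome, position) using the annotation."""
        missing = [p for p in self.probe_ids if p not in annotation]
        if missing:
            raise ValidationError(
                f"probe {missing[0]} has no annotation entry"
            )
        order = sorted(
            range(self.n_probes),
            key=lambda i: (
                chromosome_sort_key(annotation[self.probe_ids[i]].chromosome),
                annotation[self.probe_ids[i]].position,
            ),
        )
        return self.subset_probes(order)


@dataclass(frozen=True)
class SampleRecord:
    sample_id: str
    tissue: str
    tissue_group: str
    individual_id: str
    replicate_of: Optional[str] = None


@dataclass
class SampleDesign:
    """Sample sheet: tissue, tissue group, individual and replicate links."""

    samples: list[SampleRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [s.sample_id for s in self.samples]
        if len(set(ids)) != len(ids):
            raise ValidationError("duplicate sample_id in design")
        known = set(ids)
        for s in self.samples:
            if s.replicate_of is not None and s.replicate_of not in known:
                raise ValidationError(
                    f"sample {s.sample_id}: replicate_of {s.replicate_of!r} "
                    "is not a declared sample"
                )

    @property
    def sample_ids(self) -> list[str]:
        return [s.sample_id for s in self.samples]

    def by_id(self) -> dict[str, SampleRecord]:
        return {s.sample_id: s for s in self.samples}

    def tissues(self) -> list[str]:
        return sorted({s.tissue for s in self.samples})

    def tissue_groups(self) -> list[str]:
        return sorted({s.tissue_group for s in self.samples})

    def group_of(self, sample_id: str) -> str:
        return self.by_id()[sample_id].tissue_group

    def replicate_pairs(self) -> list[tuple[str, str]]:
        return [
            (s.sample_id, s.replicate_of)
            for s in self.samples
            if s.replicate_of is not None
        ]


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def read_beta_matrix(
    path: str | Path,
    annotation: Optional[Mapping[str, ProbeAnnotation]] = None,
) -> BetaMatrix:
    """Read a probes x samples TSV (first column probe_id).

    When an annotation mapping is supplied, probes are re-sorted by
    (chromosome, position) and every probe must be annotated.
    """
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    if df.index.has_duplicates:
        dup = df.index[df.index.duplicated()][0]
        raise ValidationError(f"duplicate probe_id {dup!r} in {path}")
    values = np.empty(df.shape, dtype=float)
    for j, col in enumerate(df.columns):
        try:
            values[:, j] = pd.to_numeric(df[col], errors="raise")
        except (ValueError, TypeError) as exc:
            bad_row = next(
                (idx for idx, v in df[col].items()
                 if v is not None and not _is_floatable(v)),
                "?",
            )
            raise ParseError(
                f"{path}: malformed numeric in column {col!r}, row "
                f"{bad_row!r}: {exc}"
            ) from exc
    bm = BetaMatrix(list(df.index), list(df.columns), values)
    if annotation is not None:
        bm = bm.sort_by_position(annotation)
    return bm


def _is_floatable(token: str) -> bool:
    if token == "" or token != token:  # empty or NaN
        return True
    try:
        float(token)
        return True
    except ValueError:
        return False


def write_beta_matrix(bm: BetaMatrix, path: str | Path) -> None:
    bm.to_frame().to_csv(path, sep="\t", index_label="probe_id")


def read_annotation(path: str | Path) -> list[ProbeAnnotation]:
    """Read a manifest-style CSV into probe annotations.

    Multi-gene probes carry semicolon-joined parallel lists in the
    ``gene`` and ``gene_region`` columns.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    required = {"probe_id", "chromosome", "position", "gene",
                "gene_region", "cgi_relation", "snp_flag"}
    missing_cols = required - set(df.columns)
    if missing_cols:
        raise ParseError(
            f"{path}: missing annotation columns {sorted(missing_cols)}"
        )
    out: list[ProbeAnnotation] = []
    for row in df.itertuples(index=False):
        genes = [g for g in str(row.gene).split(";") if g]
        regions = [r for r in str(row.gene_region).split(";") if r]
        if genes and len(genes) != len(regions):
            raise ValidationError(
                f"probe {row.probe_id}: gene list {genes} and region list "
                f"{regions} differ in length"
            )
        cgi = _CGI_ALIASES.get(row.cgi_relation, row.cgi_relation)
        try:
            position = int(row.position)
        except ValueError as exc:
            raise ParseError(
                f"probe {row.probe_id}: malformed position "
                f"{row.position!r}"
            ) from exc
        out.append(
            ProbeAnnotation(
                probe_id=row.probe_id,
                chromosome=row.chromosome,
                position=position,
                gene_entries=tuple(zip(genes, regions)),
                cgi_relation=cgi,
                snp_flag=_parse_bool(row.snp_flag, row.probe_id),
            )
        )
    seen: dict[tuple[str, int], str] = {}
    for a in out:
        key = (a.chromosome, a.position)
        if key in seen and seen[key] != a.probe_id:
            raise ValidationError(
                f"probes {seen[key]} and {a.probe_id} share position "
                f"{a.chromosome}:{a.position}"
            )
        seen[key] = a.probe_id
    return out


def _parse_bool(token: str, probe_id: str) -> bool:
    t = str(token).strip().lower()
    if t in {"true", "1", "yes"}:
        return True
    if t in {"false", "0", "no", ""}:
        return False
    raise ValidationError(f"probe {probe_id}: unknown snp_flag {token!r}")


def write_annotation(ann: Iterable[ProbeAnnotation], path: str | Path) -> None:
    rows = []
    for a in ann:
        rows.append(
            {
                "probe_id": a.probe_id,
                "chromosome": a.chromosome,
                "position": a.position,
                "gene": ";".join(g for g, _ in a.gene_entries),
                "gene_region": ";".join(r for _, r in a.gene_entries),
                "cgi_relation": a.cgi_relation,
                "snp_flag": a.snp_flag,
            }
        )
    pd.DataFrame(
        rows,
        columns=["probe_id", "chromosome", "position", "gene",
                 "gene_region", "cgi_relation", "snp_flag"],
    ).to_csv(path, index=False)


def read_design(path: str | Path) -> SampleDesign:
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    required = {"sample_id", "tissue", "tissue_group", "individual_id"}
    if required - set(df.columns):
        raise ParseError(
            f"{path}: missing design columns "
            f"{sorted(required - set(df.columns))}"
        )
    samples = []
    for row in df.itertuples(index=False):
        rep = getattr(row, "replicate_of", "") or None
        samples.append(
            SampleRecord(row.sample_id, row.tissue, row.tissue_group,
                         row.individual_id, rep)
        )
    return SampleDesign(samples)


def write_design(design: SampleDesign, path: str | Path) -> None:
    pd.DataFrame(
        [
            {
                "sample_id": s.sample_id,
                "tissue": s.tissue,
                "tissue_group": s.tissue_group,
                "individual_id": s.individual_id,
                "replicate_of": s.replicate_of or "",
            }
            for s in design.samples
        ]
    ).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# filters and design transforms
# ---------------------------------------------------------------------------

def filter_probes(
    bm: BetaMatrix,
    annotation: Mapping[str, ProbeAnnotation],
    drop_snp: bool = True,
    drop_chromosomes: Iterable[str] = (),
) -> tuple[BetaMatrix, dict[str, int]]:
    """Remove SNP-flagged probes and probes on listed chromosomes.

    Returns the filtered matrix (order preserved) and a removal report
    keyed ``snp`` then per chromosome. A probe matching several criteria
    is attributed to the first one (snp before chromosome), so the
    counts sum to probes removed.
    """
    drop_chrom = set(drop_chromosomes)
    report: dict[str, int] = {}
    if drop_snp:
        report["snp"] = 0
    for c in sorted(drop_chrom, key=chromosome_sort_key):
        report[c] = 0
    keep: list[int] = []
    for i, pid in enumerate(bm.probe_ids):
        try:
            a = annotation[pid]
        except KeyError:
            raise ValidationError(f"probe {pid} has no annotation entry")
        if drop_snp and a.snp_flag:
            report["snp"] += 1
        elif a.chromosome in drop_chrom:
            report[a.chromosome] += 1
        else:
            keep.append(i)
    return bm.subset_probes(keep), report


def drop_incomplete_probes(bm: BetaMatrix) -> tuple[BetaMatrix, int]:
    """Drop probes with any missing value (needed before segmentation)."""
    complete = ~np.isnan(bm.values).any(axis=1)
    return bm.subset_probes(np.flatnonzero(complete)), int((~complete).sum())


def merge_tissue_groups(
    design: SampleDesign, mapping: Mapping[str, str]
) -> SampleDesign:
    """Re-assign tissue_group per a total tissue -> group mapping."""
    unmapped = {s.tissue for s in design.samples} - set(mapping)
    if unmapped:
        raise ValidationError(
            f"tissues without a group mapping: {sorted(unmapped)}"
        )
    return SampleDesign(
        [replace(s, tissue_group=mapping[s.tissue]) for s in design.samples]
    )


# ---------------------------------------------------------------------------
# BED export
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BedRegion:
    """Genomic interval carried in 1-based inclusive probe coordinates."""

    chromosome: str
    start: int  # 1-based, first probe position
    end: int  # 1-based, last probe position (inclusive)
    name: str
    score: float = 0.0
    strand: str = "."


def bed_score_from_p(p_adjusted: float, cap: float = 1000.0) -> float:
    """-log10 of an adjusted p-value, capped (0 maps to the cap)."""
    if p_adjusted <= 0:
        return cap
    return min(cap, -math.log10(p_adjusted))


def write_regions_bed(regions: Sequence[BedRegion], path: str | Path) -> None:
    """Write BED6; converts 1-based inclusive to 0-based half-open."""
    with open(path, "w") as fh:
        for r in regions:
            fh.write(
                f"{r.chromosome}\t{r.start - 1}\t{r.end}\t{r.name}\t"
                f"{r.score:g}\t{r.strand}\n"
            )


def read_regions_bed(path: str | Path) -> list[BedRegion]:
    regions = []
    with open(path) as fh:
        for line in fh:
            if not line.strip():
                continue
            chrom, start, end, name, score, strand = line.rstrip("\n").split("\t")
            regions.append(
                BedRegion(chrom, int(start) + 1, int(end), name,
                          float(score), strand)
            )
    return regions
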