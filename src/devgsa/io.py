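"""Readers, writers and filtering rules for the pipeline's external formats.

Formats handled here: delimited GWAS summary statistics with a configurable
column map, 5-column gene locus tables, GMT gene-set files, expression
matrices (genes x samples, TSV) with a sample-metadata table, and YAML run
manifests.  Filtering rules applied to loaded objects (minimum set size,
universe intersection) live here too, next to the parsers.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger(__name__)

#: The 13 developmental stages, ordered from conception onward.  Prenatal
#: bounds are postconceptual weeks (pcw), postnatal bounds are months or years.
STAGE_LABELS = (
    "early_fetal",
    "early_midfetal",
    "midfetal",
    "late_midfetal",
    "late_fetal",
    "early_infancy",
    "late_infancy",
    "early_childhood",
    "late_childhood",
    "adolescence",
    "early_adulthood",
    "mid_adulthood",
    "late_adulthood",
)


class DevgsaError(Exception):
    """Fatal input or contract violation."""


@dataclass(frozen=True)
class SnpRecord:
    """One row of GWAS summary statistics.

    ``pos`` is 1-based.  ``maf`` is the minor allele frequency, in [0, 0.5].
    """

    snp_id: str
    chrom: str
    pos: int
    allele1: str
    allele2: str
    pvalue: float
    n: int
    maf: float

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise DevgsaError(f"SNP {self.snp_id}: position must be >= 1")
        if not (0.0 < self.pvalue <= 1.0):
            raise DevgsaError(f"SNP {self.snp_id}: p-value {self.pvalue} outside (0, 1]")
        if not (0.0 <= self.maf <= 0.5):
            raise DevgsaError(f"SNP {self.snp_id}: MAF {self.maf} outside [0, 0.5]")


@dataclass(frozen=True)
class GeneLocus:
    """A gene's genomic interval, 1-based inclusive on both ends."""

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise DevgsaError(f"gene {self.gene_id}: start > end")
        if self.strand not in {"+", "-"}:
            raise DevgsaError(f"gene {self.gene_id}: unknown strand {self.strand!r}")


@dataclass
class GeneSetCollection:
    """Named gene sets plus the universe of genes known to the analysis.

    ``sets`` maps set name to an ordered, duplicate-free list of gene ids.
    """

    sets: dict[str, list[str]] = field(default_factory=dict)
    universe: list[str] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.sets)

    def __contains__(self, name: str) -> bool:
        return name in self.sets

    def __getitem__(self, name: str) -> list[str]:
        return self.sets[name]


@dataclass
class SampleMeta:
    """Per-sample metadata: a tagged age, sex, and 5 genotype PCs.

    ``age`` is a signed number in years: postnatal samples carry age in
    years; prenatal samples are encoded as (pcw - 40) / 52, i.e. negative
    values counting back from term.  ``age_unit`` tags the unit the age was
    originally expressed in ({"pcw", "years"}), so that stage assignment can
    operate on exact stage-table boundaries.  ``stage`` is assigned by
    :func:`devgsa.devexpr.assign_stage`, not read from disk.
    """

    sample_id: str
    age: float
    age_unit: str
    sex: str
    snp_pc: tuple[float, ...]
    stage: str | None = None

    def __post_init__(self) -> None:
        if len(self.snp_pc) != 5:
            raise DevgsaError(f"sample {self.sample_id}: expected 5 snpPCs, got {len(self.snp_pc)}")
        if self.age_unit not in {"pcw", "years"}:
            raise DevgsaError(f"sample {self.sample_id}: unknown age unit {self.age_unit!r}")
        if self.sex not in {"male", "female"}:
            raise DevgsaError(f"sample {self.sample_id}: unknown sex {self.sex!r}")

    @property
    def age_years(self) -> float:
        """Signed age in years ((pcw - 40)/52 when prenatal)."""
        if self.age_unit == "pcw":
            return (self.age - 40.0) / 52.0
        return self.age


@dataclass
class ExpressionMatrix:
    """Gene x sample expression values, in counts or RPKM."""

    genes: list[str]
    samples: list[SampleMeta]
    values: np.ndarray
    unit: str  # {"counts", "rpkm"}

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.genes), len(self.samples)):
            raise DevgsaError(
                f"expression matrix shape {self.values.shape} inconsistent with "
                f"{len(self.genes)} genes x {len(self.samples)} samples"
            )
        if self.unit not in {"counts", "rpkm"}:
            raise DevgsaError(f"unknown expression unit {self.unit!r}")
        if np.any(self.values < 0):
            raise DevgsaError("expression values must be non-negative")

    @property
    def sample_ids(self) -> list[str]:
        return [s.sample_id for s in self.samples]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.genes, columns=self.sample_ids)


# ---------------------------------------------------------------------------
# GWAS summary statistics
# ---------------------------------------------------------------------------

REQUIRED_GWAS_FIELDS = ("snp_id", "chrom", "pos", "pvalue")
OPTIONAL_GWAS_FIELDS = ("allele1", "allele2", "n", "maf")


def read_gwas_summary(path: str | Path, column_map: Mapping[str, str]) -> list[SnpRecord]:
    """Read delimited GWAS summary statistics into :class:`SnpRecord` rows.

    ``column_map`` maps field names (snp_id, chrom, pos, allele1, allele2,
    pvalue, n, maf) to the header names in the file.  Rows whose p-value or
    position fail to parse are dropped and counted in the log.
    """
    path = Path(path)
    for fieldname in REQUIRED_GWAS_FIELDS:
        if fieldname not in column_map:
            raise DevgsaError(f"column_map missing required field {fieldname!r}")
    df = pd.read_csv(path, sep=None, engine="python")
    for fieldname, col in column_map.items():
        if col not in df.columns:
            raise DevgsaError(f"column {col!r} (mapped to {fieldname!r}) absent from {path}")

    records: list[SnpRecord] = []
    n_dropped = 0
    for _, row in df.iterrows():
        pval = pd.to_numeric(row[column_map["pvalue"]], errors="coerce")
        pos = pd.to_numeric(row[column_map["pos"]], errors="coerce")
        if pd.isna(pval) or pd.isna(pos) or not (0.0 < pval <= 1.0):
            n_dropped += 1
            continue
        records.append(
            SnpRecord(
                snp_id=str(row[column_map["snp_id"]]),
                chrom=str(row[column_map["chrom"]]),
                pos=int(pos),
                allele1=str(row[column_map["allele1"]]) if "allele1" in column_map else "N",
                allele2=str(row[column_map["allele2"]]) if "allele2" in column_map else "N",
                pvalue=float(pval),
                n=int(row[column_map["n"]]) if "n" in column_map else 0,
                maf=float(row[column_map["maf"]]) if "maf" in column_map else 0.5,
            )
        )
    logger.info("read %d SNPs from %s (%d rows dropped)", len(records), path, n_dropped)
    if not records:
        raise DevgsaError(f"no valid SNP rows in {path}")
    return records


def snps_to_frame(snps: Sequence[SnpRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "snp_id": [s.snp_id for s in snps],
            "chrom": [s.chrom for s in snps],
            "pos": [s.pos for s in snps],
            "allele1": [s.allele1 for s in snps],
            "allele2": [s.allele2 for s in snps],
            "pvalue": [s.pvalue for s in snps],
            "n": [s.n for s in snps],
            "maf": [s.maf for s in snps],
        }
    )


def write_gwas_summary(snps: Sequence[SnpRecord], path: str | Path) -> None:
    snps_to_frame(snps).rename(
        columns={
            "snp_id": "SNP", "chrom": "CHR", "pos": "BP", "allele1": "A1",
            "allele2": "A2", "pvalue": "P", "n": "N", "maf": "MAF",
        }
    ).to_csv(path, sep="\t", index=False)


#: Column map matching files written by :func:`write_gwas_summary`.
DEFAULT_GWAS_COLUMNS = {
    "snp_id": "SNP", "chrom": "CHR", "pos": "BP", "allele1": "A1",
    "allele2": "A2", "pvalue": "P", "n": "N", "maf": "MAF",
}


# ---------------------------------------------------------------------------
# Gene loci
# ---------------------------------------------------------------------------

def read_gene_loci(path: str | Path) -> list[GeneLocus]:
    """Read a 5-column (gene_id, chrom, start, end, strand) locus table."""
    df = pd.read_csv(path, sep="\t")
    needed = {"gene_id", "chrom", "start", "end", "strand"}
    if not needed.issubset(df.columns):
        raise DevgsaError(f"locus table {path} missing columns {needed - set(df.columns)}")
    return [
        GeneLocus(str(r.gene_id), str(r.chrom), int(r.start), int(r.end), str(r.strand))
        for r in df.itertuples()
    ]


def write_gene_loci(loci: Sequence[GeneLocus], path: str | Path) -> None:
    pd.DataFrame(
        {
            "gene_id": [g.gene_id for g in loci],
            "chrom": [g.chrom for g in loci],
            "start": [g.start for g in loci],
            "end": [g.end for g in loci],
            "strand": [g.strand for g in loci],
        }
    ).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Gene sets (GMT)
# ---------------------------------------------------------------------------

def read_gmt(path: str | Path) -> GeneSetCollection:
    """Parse a GMT file: one set per line, ``name TAB description TAB genes...``.

    Duplicate genes within a line are de-duplicated preserving first
    occurrence; the description column is discarded.  Duplicate set names are
    fatal.
    """
    coll = GeneSetCollection()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise DevgsaError(f"{path}:{lineno}: GMT line needs name, description, genes")
            name = parts[0]
            if name in coll.sets:
                raise DevgsaError(f"{path}:{lineno}: duplicate set name {name!r}")
            seen: dict[str, None] = {}
            for g in parts[2:]:
                if g and g not in seen:
                    seen[g] = None
            coll.sets[name] = list(seen)
    logger.info("read %d gene sets from %s", len(coll), path)
    return coll


def write_gmt(coll: GeneSetCollection, path: str | Path, descriptions: Mapping[str, str] | None = None) -> None:
    with open(path, "w") as fh:
        for name, genes in coll.sets.items():
            desc = (descriptions or {}).get(name, "na")
            fh.write("\t".join([name, desc, *genes]) + "\n")


def filter_sets(
    coll: GeneSetCollection,
    universe: Iterable[str],
    min_size: int = 100,
) -> GeneSetCollection:
    """Intersect each set with ``universe``, then drop sets smaller than ``min_size``.

    The 100-gene default reflects the convention of excluding small pathway
    annotations, whose enrichment estimates are dominated by outlier genes.
    Gene order within sets is preserved.  Idempotent.
    """
    universe_list = list(dict.fromkeys(universe))
    if not universe_list:
        raise DevgsaError("filter_sets: universe is empty")
    uset = set(universe_list)
    out = GeneSetCollection(universe=universe_list)
    n_dropped = 0
    for name, genes in coll.sets.items():
        kept = [g for g in genes if g in uset]
        if len(kept) >= min_size:
            out.sets[name] = kept
        else:
            n_dropped += 1
    logger.info(
        "filter_sets: kept %d of %d sets (min_size=%d, universe=%d)",
        len(out), len(coll), min_size, len(uset),
    )
    return out


# ---------------------------------------------------------------------------
# Expression matrix + sample metadata
# ---------------------------------------------------------------------------

def read_sample_meta(path: str | Path) -> list[SampleMeta]:
    """Read a sample metadata TSV: sample_id, age, age_unit, sex, snp_pc1..5."""
    df = pd.read_csv(path, sep="\t")
    pc_cols = [f"snp_pc{i}" for i in range(1, 6)]
    needed = {"sample_id", "age", "age_unit", "sex", *pc_cols}
    if not needed.issubset(df.columns):
        raise DevgsaError(f"metadata {path} missing columns {needed - set(df.columns)}")
    return [
        SampleMeta(
            sample_id=str(r["sample_id"]),
            age=float(r["age"]),
            age_unit=str(r["age_unit"]),
            sex=str(r["sex"]),
            snp_pc=tuple(float(r[c]) for c in pc_cols),
        )
        for _, r in df.iterrows()
    ]


def write_sample_meta(samples: Sequence[SampleMeta], path: str | Path) -> None:
    rows = []
    for s in samples:
        row = {"sample_id": s.sample_id, "age": s.age, "age_unit": s.age_unit, "sex": s.sex}
        for i, v in enumerate(s.snp_pc, start=1):
            row[f"snp_pc{i}"] = v
        if s.stage is not None:
            row["stage"] = s.stage
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_expression(path: str | Path, samples: Sequence[SampleMeta], unit: str) -> ExpressionMatrix:
    """Read a genes-x-samples TSV (first column = gene id) against known samples."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    by_id = {s.sample_id: s for s in samples}
    missing = [c for c in df.columns if c not in by_id]
    if missing:
        raise DevgsaError(f"expression columns without metadata: {missing[:5]}")
    ordered = [by_id[c] for c in df.columns]
    return ExpressionMatrix(list(df.index), ordered, df.to_numpy(dtype=float), unit)


def write_expression(expr: ExpressionMatrix, path: str | Path) -> None:
    expr.to_frame().rename_axis("gene_id").to_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# Run manifest
# ---------------------------------------------------------------------------

def write_manifest(path: str | Path, manifest: Mapping) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(dict(manifest), fh, sort_keys=False)


def read_manifest(path: str | Path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)
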