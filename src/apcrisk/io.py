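"""Readers, writers, cohort filtering and run configuration.

File dialects: FASTA for the CDS (single record), tab-separated tables with a
header row for signatures, exposures, cohorts and genotypes, JSON for
reports, YAML for run configuration.  Mutation positions are CDS-relative
codons; the cohort table is MAF-like with one row per mutation and
sample-level copy-number/metadata columns repeated on each row.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Mapping, Optional

import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .cds import DEFAULT_REGIONS, CdsContext
from .genotypes import (
    TruncatingMutation,
    TumorClassification,
    TumorRecord,
    classify_tumor,
)


class DataValidationError(ValueError):
    """Input data failed validation (CLI exit code 3)."""


REQUIRED_COHORT_COLUMNS = [
    "sample",
    "codon",
    "mutation_class",
    "clonal",
    "cn_a",
    "cn_b",
    "wgd",
    "site",
    "msi",
    "pole",
    "is_primary",
    "prior_radiotherapy",
    "germline_apc",
    "lynch_syndrome",
]


def read_cds_fasta(
    path, regions: Optional[Mapping[str, tuple[int, int]]] = None
) -> CdsContext:
    """Read a single-record FASTA into a CDS context."""
    records = list(SeqIO.parse(str(path), "fasta"))
    if len(records) != 1:
        raise DataValidationError(
            f"{path}: expected exactly one FASTA record, found {len(records)}"
        )
    return CdsContext(str(records[0].seq), regions=dict(regions or DEFAULT_REGIONS))


def write_cds_fasta(ctx: CdsContext, path, name: str = "synthetic_cds") -> None:
    SeqIO.write([SeqRecord(Seq(ctx.sequence), id=name, description="")], str(path), "fasta")


def read_signature_matrix(path) -> pd.DataFrame:
    """COSMIC-format signature TSV: first column mutation type, rest signatures."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.empty:
        raise DataValidationError(f"{path}: empty signature matrix")
    return df


def read_exposures(path) -> pd.DataFrame:
    """Exposure TSV: first column sample id, one column per signature."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.empty:
        raise DataValidationError(f"{path}: empty exposure table")
    return df


def read_cohort_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in REQUIRED_COHORT_COLUMNS if c not in df.columns]
    if missing:
        raise DataValidationError(f"{path}: missing required columns: {missing}")
    return df


def write_tsv(df: pd.DataFrame, path, index: bool = False) -> None:
    df.to_csv(path, sep="\t", index=index)


def cohort_to_records(cohort: pd.DataFrame) -> list[TumorRecord]:
    """Group a tidy mutation table into per-tumour records."""
    records = []
    for sid, grp in cohort.groupby("sample", sort=True):
        first = grp.iloc[0]
        muts = [
            TruncatingMutation(
                codon=int(r.codon),
                mutation_class=str(r.mutation_class),
                clonal=bool(r.clonal),
            )
            for r in grp.itertuples()
        ]
        records.append(
            TumorRecord(
                sample=str(sid),
                mutations=muts,
                cn=(int(first.cn_a), int(first.cn_b)),
                wgd=bool(first.wgd),
                meta={
                    k: first[k]
                    for k in grp.columns
                    if k not in ("sample", "codon", "mutation_class", "clonal")
                },
            )
        )
    return records


def classifications_to_dataframe(results: list[TumorClassification]) -> pd.DataFrame:
    rows = []
    for r in results:
        rows.append(
            {
                "sample": r.sample,
                "M": None if r.excluded else r.genotype.M,
                "N": None if r.excluded else str(r.genotype.N),
                "X": None if r.excluded else r.genotype.X,
                "excluded_reason": r.exclusion_reason or "",
                "third_hits": r.third_hits,
            }
        )
    return pd.DataFrame(rows)


def read_genotypes_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"N": "string"})
    for col in ("sample", "M", "N"):
        if col not in df.columns:
            raise DataValidationError(f"{path}: missing genotype column {col!r}")
    mask = df["excluded_reason"].fillna("") == "" if "excluded_reason" in df else None
    if mask is not None:
        df = df[mask]
    return df.dropna(subset=["M", "N"])


def filter_cohort(
    cohort: pd.DataFrame, context: str = "MSS", cutoff_codon: int = 1569
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Apply the cohort inclusion rules and log one reason per exclusion.

    Keeps primary tumours with at least one clonal truncating mutation
    upstream of the SAMP cutoff, no radiotherapy before surgery, no germline
    APC/Lynch-syndrome predisposition, and the hypermutator status matching
    the requested context (``MSS`` excludes MSI and POLE tumours; ``MSI`` and
    ``POLE`` keep only the corresponding hypermutant tumours).
    """
    missing = [c for c in REQUIRED_COHORT_COLUMNS if c not in cohort.columns]
    if missing:
        raise DataValidationError(f"cohort is missing required columns: {missing}")
    if context not in ("MSS", "MSI", "POLE"):
        raise DataValidationError(f"unknown analysis context {context!r}")

    reasons: dict[str, str] = {}
    for sid, grp in cohort.groupby("sample"):
        first = grp.iloc[0]
        in_window = (
            grp["clonal"].astype(bool) & (grp["codon"].astype(int) <= cutoff_codon)
        ).any()
        if not bool(first.is_primary):
            reasons[sid] = "not a primary tumour"
        elif bool(first.prior_radiotherapy):
            reasons[sid] = "radiotherapy prior to surgery"
        elif bool(first.germline_apc):
            reasons[sid] = "germline APC mutation"
        elif bool(first.lynch_syndrome):
            reasons[sid] = "Lynch syndrome"
        elif not in_window:
            reasons[sid] = "no in-window truncating hit"
        elif context == "MSS" and bool(first.msi):
            reasons[sid] = "MSI tumour under MSS context"
        elif context == "MSS" and bool(first.pole):
            reasons[sid] = "POLE-mutant tumour under MSS context"
        elif context == "MSI" and not bool(first.msi):
            reasons[sid] = "not MSI under MSI context"
        elif context == "POLE" and not bool(first.pole):
            reasons[sid] = "not POLE-mutant under POLE context"
    kept = cohort[~cohort["sample"].isin(reasons)]
    log = pd.DataFrame(
        sorted(reasons.items()), columns=["sample", "exclusion_reason"]
    )
    return kept.reset_index(drop=True), log


def classify_cohort(
    cohort: pd.DataFrame, ctx: CdsContext
) -> list[TumorClassification]:
    """Genotype every tumour in a filtered cohort table."""
    return [classify_tumor(rec, ctx) for rec in cohort_to_records(cohort)]


@dataclasses.dataclass
class RunConfig:
    """Paths, constants and statistical settings for a pipeline run."""

    cds_fasta: Optional[str] = None
    sbs_signatures: Optional[str] = None
    indel_signatures: Optional[str] = None
    sbs_exposures: Optional[str] = None
    indel_exposures: Optional[str] = None
    cohort: Optional[str] = None
    context: str = "MSS"
    regions: Mapping[str, tuple[int, int]] = dataclasses.field(
        default_factory=lambda: dict(DEFAULT_REGIONS)
    )
    sbs_rate_per_bp_year: float = 1.45e-8
    window_bp: int = 4717
    stop_fraction: float = 0.052
    sbs_to_indel_ratio: float = 24.0
    frameshift_fraction: float = 0.88
    inclusion_threshold: float = 0.85
    bootstrap_B: int = 10_000
    uniform_risk_K: int = 10_000
    n_perm: int = 999
    alpha: float = 0.05
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise DataValidationError(f"{path}: unknown config keys: {sorted(unknown)}")
        cfg = cls(**raw)
        if "regions" in raw:
            cfg.regions = {k: tuple(v) for k, v in raw["regions"].items()}
        for name in (
            "cds_fasta",
            "sbs_signatures",
            "indel_signatures",
            "sbs_exposures",
            "indel_exposures",
            "cohort",
        ):
            p = getattr(cfg, name)
            if p is not None and not Path(p).exists():
                raise DataValidationError(f"{path}: {name} file not found: {p}")
        for name in (
            "sbs_rate_per_bp_year",
            "window_bp",
            "stop_fraction",
            "sbs_to_indel_ratio",
            "frameshift_fraction",
        ):
            if getattr(cfg, name) <= 0:
                raise DataValidationError(f"{path}: {name} must be positive")
        return cfg

    def settings_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["regions"] = {k: list(v) for k, v in self.regions.items()}
        return d


def write_json_report(payload: dict, path, settings: Optional[dict] = None) -> None:
    out = dict(payload)
    if settings is not None:
        out["settings"] = settings
    with open(path, "w") as fh:
        json.dump(out, fh, indent=2, default=str)
        fh.write("\n")
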