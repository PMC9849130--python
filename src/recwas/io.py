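"""Shared data model and readers/writers for the standard formats.

Coordinates are 1-based as in VCF; genomic intervals are half-open
``[start, end)`` internally.  The recessive coding used throughout the
package is defined on the ALTERNATE allele, not the minor allele: for a
common variant whose alternate allele is the major allele, "homozygous"
means homozygous-alternate.  Missing genotypes are dropped per variant
(complete-case), never imputed.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

CONSEQUENCES = ("pLoF", "missense", "other-coding", "intergenic", "intronic")
CLINICAL_CATEGORIES = ("likely_pathogenic", "likely_benign", "conflicting", "VUS", "none")

MISSING = -1  # sentinel for a missing haplotype allele / dosage


class VcfParseError(ValueError):
    """Raised when a VCF record cannot be interpreted."""


class ConfigError(ValueError):
    """Raised for unknown or malformed configuration keys."""


@dataclass
class VariantRecord:
    """One bi-allelic variant plus its annotation.

    ``af_alt`` is the alternate-allele frequency observed in the cohort;
    ``af_ref_pop`` the frequency in an external reference population
    (``None`` if unavailable).
    """

    chrom: str
    pos: int
    ref: str
    alt: str
    gene: str = ""
    consequence: str = "other-coding"
    clinical_category: str = "none"
    af_alt: float = float("nan")
    af_ref_pop: float | None = None

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")
        if self.consequence not in CONSEQUENCES:
            raise ValueError(f"unknown consequence {self.consequence!r}")
        if self.clinical_category not in CLINICAL_CATEGORIES:
            raise ValueError(f"unknown clinical_category {self.clinical_category!r}")
        for name in ("af_alt",):
            v = getattr(self, name)
            if not math.isnan(v) and not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} outside [0,1]: {v}")
        if self.af_ref_pop is not None and not 0.0 <= self.af_ref_pop <= 1.0:
            raise ValueError(f"af_ref_pop outside [0,1]: {self.af_ref_pop}")

    @property
    def key(self) -> str:
        """Canonical ``chrom:pos:ref:alt`` identifier."""
        return f"{self.chrom}:{self.pos}:{self.ref}:{self.alt}"


@dataclass
class GenotypeMatrix:
    """Phased per-haplotype alleles for N individuals x V variants.

    ``haplotypes`` is an ``(N, V, 2)`` int8 array of allele indicators
    (0 = reference, 1 = alternate, -1 = missing).  ``phased`` is a
    per-individual flag; haplotype order is meaningless for unphased
    individuals.
    """

    variants: list[VariantRecord]
    haplotypes: np.ndarray
    phased: np.ndarray
    sample_ids: list[str]

    def __post_init__(self) -> None:
        self.haplotypes = np.asarray(self.haplotypes, dtype=np.int8)
        self.phased = np.asarray(self.phased, dtype=bool)
        n, v, two = self.haplotypes.shape
        if two != 2:
            raise ValueError("haplotypes must have shape (N, V, 2)")
        if v != len(self.variants):
            raise ValueError("variant list does not match haplotype tensor")
        if n != len(self.sample_ids) or n != len(self.phased):
            raise ValueError("sample_ids/phased do not match haplotype tensor")
        keys = [rec.key for rec in self.variants]
        if len(set(keys)) != len(keys):
            raise ValueError("duplicate (chrom,pos,ref,alt) in variant list")

    @property
    def n_individuals(self) -> int:
        return self.haplotypes.shape[0]

    @property
    def n_variants(self) -> int:
        return self.haplotypes.shape[1]

    def dosage(self, j: int) -> np.ndarray:
        """Genotype dosage {0,1,2} for variant ``j``; MISSING where any allele is missing."""
        h = self.haplotypes[:, j, :]
        d = h.sum(axis=1).astype(np.int16)
        d[(h < 0).any(axis=1)] = MISSING
        return d

    def dosage_matrix(self) -> np.ndarray:
        """(N, V) float dosage matrix with NaN for missing genotypes."""
        d = self.haplotypes.sum(axis=2).astype(float)
        d[(self.haplotypes < 0).any(axis=2)] = np.nan
        return d

    def allele_frequencies(self) -> np.ndarray:
        """Alternate-allele frequency per variant from non-missing haplotypes."""
        h = self.haplotypes.astype(float)
        h[h < 0] = np.nan
        with np.errstate(invalid="ignore"):
            return np.nanmean(h, axis=(0, 2))

    def variant_index(self) -> dict[str, int]:
        return {rec.key: j for j, rec in enumerate(self.variants)}


@dataclass
class PhenotypeTable:
    """Binary endpoints, onset ages and covariates, aligned on individual id.

    ``endpoints`` is an N x K 0/1 frame; ``onset_age`` shares its shape and
    is NaN wherever the endpoint is 0.  ``covariates`` must be complete
    (no missing values) for individuals entering any test.
    """

    endpoints: pd.DataFrame
    covariates: pd.DataFrame
    onset_age: pd.DataFrame | None = None
    children_count: pd.Series | None = None

    def __post_init__(self) -> None:
        if not self.endpoints.index.equals(self.covariates.index):
            raise ValueError("endpoints and covariates must share an index")
        if self.onset_age is not None:
            if not self.onset_age.index.equals(self.endpoints.index):
                raise ValueError("onset_age index mismatch")
            for col in self.onset_age.columns:
                if col not in self.endpoints.columns:
                    continue
                affected = self.endpoints[col].to_numpy() == 1
                has_onset = self.onset_age[col].notna().to_numpy()
                if (has_onset & ~affected).any():
                    raise ValueError(f"onset_age present for unaffected individuals in {col!r}")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.endpoints.index)

    def endpoint(self, name: str) -> np.ndarray:
        return self.endpoints[name].to_numpy(dtype=float)

    def covariate_matrix(self, add_intercept: bool = True) -> np.ndarray:
        c = self.covariates.to_numpy(dtype=float)
        if add_intercept:
            c = np.column_stack([np.ones(len(c)), c])
        return c


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

def read_genotypes(path: str | Path) -> GenotypeMatrix:
    """Read a VCF with a GT field into a :class:`GenotypeMatrix`.

    Multi-allelic records are rejected (split them first).  Unphased
    genotypes are accepted but the individual is flagged ``phased=False``.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    sample_ids = list(vcf.samples)
    n = len(sample_ids)
    variants: list[VariantRecord] = []
    haps: list[np.ndarray] = []
    phased_all = np.ones(n, dtype=bool)
    for line_no, v in enumerate(vcf, start=1):
        if len(v.ALT) != 1:
            raise VcfParseError(
                f"multi-allelic record at {v.CHROM}:{v.POS} (record {line_no}); "
                "split multi-allelic sites (e.g. `bcftools norm -m-`) before loading"
            )
        g = np.asarray(v.genotypes, dtype=np.int64)  # (N, 3): a1, a2, phased
        if g.shape != (n, 3):
            raise VcfParseError(f"malformed GT at {v.CHROM}:{v.POS} (record {line_no})")
        h = g[:, :2].astype(np.int8)
        h[h > 1] = MISSING  # paranoid: only 0/1 alleles are valid post-split
        phased_all &= (g[:, 2] == 1) | (h < 0).any(axis=1)
        haps.append(h)
        variants.append(VariantRecord(chrom=str(v.CHROM), pos=int(v.POS), ref=v.REF, alt=v.ALT[0]))
    vcf.close()
    if not variants:
        tensor = np.zeros((n, 0, 2), dtype=np.int8)
    else:
        tensor = np.stack(haps, axis=1)
    gm = GenotypeMatrix(variants=variants, haplotypes=tensor, phased=phased_all,
                        sample_ids=sample_ids)
    af = gm.allele_frequencies()
    for j, rec in enumerate(gm.variants):
        rec.af_alt = float(af[j]) if np.isfinite(af[j]) else float("nan")
    return gm


def write_genotypes(geno: GenotypeMatrix, path: str | Path) -> None:
    """Write a minimal VCFv4.2 with GT-only FORMAT."""
    lines = ["##fileformat=VCFv4.2", '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">']
    for chrom in dict.fromkeys(rec.chrom for rec in geno.variants):
        lines.append(f"##contig=<ID={chrom}>")
    lines.append("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(geno.sample_ids))
    sep = np.where(geno.phased, "|", "/")
    for j, rec in enumerate(geno.variants):
        h = geno.haplotypes[:, j, :]
        gts = []
        for i in range(geno.n_individuals):
            a1, a2 = h[i]
            a1s = "." if a1 < 0 else str(int(a1))
            a2s = "." if a2 < 0 else str(int(a2))
            gts.append(f"{a1s}{sep[i]}{a2s}")
        lines.append(f"{rec.chrom}\t{rec.pos}\t.\t{rec.ref}\t{rec.alt}\t.\tPASS\t.\tGT\t"
                     + "\t".join(gts))
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Annotation / phenotype / covariate tables (TSV)
# ---------------------------------------------------------------------------

_ANNOTATION_COLS = ["chrom", "pos", "ref", "alt", "gene", "consequence",
                    "clinical_category", "af_ref_pop"]


def read_annotations(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    missing = set(_ANNOTATION_COLS) - set(df.columns)
    if missing:
        raise ValueError(f"annotation table missing columns: {sorted(missing)}")
    return df


def attach_annotations(geno: GenotypeMatrix, annotations: pd.DataFrame) -> None:
    """Merge an annotation table into the in-memory variant records (in place)."""
    ann = annotations.set_index(
        annotations.apply(lambda r: f"{r.chrom}:{r.pos}:{r.ref}:{r.alt}", axis=1))
    for rec in geno.variants:
        if rec.key not in ann.index:
            continue
        row = ann.loc[rec.key]
        rec.gene = "" if pd.isna(row.gene) else str(row.gene)
        rec.consequence = str(row.consequence)
        rec.clinical_category = str(row.clinical_category)
        rec.af_ref_pop = None if pd.isna(row.af_ref_pop) else float(row.af_ref_pop)


def write_annotations(variants: Sequence[VariantRecord], path: str | Path) -> None:
    rows = [{"chrom": r.chrom, "pos": r.pos, "ref": r.ref, "alt": r.alt, "gene": r.gene,
             "consequence": r.consequence, "clinical_category": r.clinical_category,
             "af_ref_pop": r.af_ref_pop} for r in variants]
    pd.DataFrame(rows, columns=_ANNOTATION_COLS).to_csv(path, sep="\t", index=False)


def read_phenotypes(endpoint_path: str | Path, covariate_path: str | Path) -> PhenotypeTable:
    ep = pd.read_csv(endpoint_path, sep="\t", index_col="individual_id")
    cov = pd.read_csv(covariate_path, sep="\t", index_col="individual_id")
    ep.index = ep.index.astype(str)
    cov.index = cov.index.astype(str)
    ep.index.name = cov.index.name = None
    onset_cols = [c for c in ep.columns if c.startswith("onset_")]
    children = None
    if "children_count" in ep.columns:
        children = ep.pop("children_count")
    onset = None
    if onset_cols:
        onset = ep[onset_cols].rename(columns=lambda c: c[len("onset_"):])
        ep = ep.drop(columns=onset_cols)
    return PhenotypeTable(endpoints=ep.astype(int), covariates=cov, onset_age=onset,
                          children_count=children)


def write_phenotypes(pheno: PhenotypeTable, endpoint_path: str | Path,
                     covariate_path: str | Path) -> None:
    ep = pheno.endpoints.copy()
    if pheno.onset_age is not None:
        for col in pheno.onset_age.columns:
            ep[f"onset_{col}"] = pheno.onset_age[col]
    if pheno.children_count is not None:
        ep["children_count"] = pheno.children_count
    ep.to_csv(endpoint_path, sep="\t", index_label="individual_id")
    pheno.covariates.to_csv(covariate_path, sep="\t", index_label="individual_id")


# ---------------------------------------------------------------------------
# Summary statistics
# ---------------------------------------------------------------------------

SUMMARY_COLUMNS = ["chrom", "pos", "ref", "alt", "phenotype", "model", "beta", "se", "p",
                   "n_hom", "n_het", "n_cases", "n_controls", "method",
                   "or_estimate", "or_ci_low", "or_ci_high"]


def write_summary_stats(results: Sequence, path: str | Path) -> None:
    """Write association results as a TSV, one row per variant x phenotype x model."""
    if not results:
        raise ValueError("results list is empty")
    rows = []
    for r in results:
        chrom, pos, ref, alt = r.variant_key.split(":")
        or_est, or_lo, or_hi = (r.or_ci if r.or_ci is not None else (np.nan, np.nan, np.nan))
        rows.append({"chrom": chrom, "pos": int(pos), "ref": ref, "alt": alt,
                     "phenotype": r.phenotype, "model": r.model, "beta": r.beta, "se": r.se,
                     "p": r.p, "n_hom": r.n_hom, "n_het": r.n_het, "n_cases": r.n_cases,
                     "n_controls": r.n_controls, "method": r.method,
                     "or_estimate": or_est, "or_ci_low": or_lo, "or_ci_high": or_hi})
    pd.DataFrame(rows, columns=SUMMARY_COLUMNS).to_csv(path, sep="\t", index=False,
                                                       float_format="%.17g")


def read_summary_stats(path: str | Path) -> list:
    from .association import AssociationResult

    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    out = []
    for row in df.itertuples(index=False):
        or_ci = None
        if not (pd.isna(row.or_estimate) and pd.isna(row.or_ci_low) and pd.isna(row.or_ci_high)):
            or_ci = (float(row.or_estimate), float(row.or_ci_low), float(row.or_ci_high))
        out.append(AssociationResult(
            variant_key=f"{row.chrom}:{row.pos}:{row.ref}:{row.alt}",
            phenotype=str(row.phenotype), model=str(row.model),
            beta=float(row.beta) if not pd.isna(row.beta) else float("nan"),
            se=float(row.se) if not pd.isna(row.se) else float("nan"),
            p=float(row.p), n_cases=int(row.n_cases), n_controls=int(row.n_controls),
            n_hom=int(row.n_hom), n_het=int(row.n_het), method=str(row.method), or_ci=or_ci))
    return out


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

@dataclass
class PipelineConfig:
    """Pipeline-wide thresholds; defaults mirror the analysis constants."""

    genome_wide_p: float = 5e-8
    min_hom: int = 5
    rec_margin: float = 1e-2
    r2_locus: float = 0.25
    n_null_samples: int = 1000
    n_af_bins: int = 15
    window_bp: int = 3_000_000
    fin_enrich_ratio: float = 2.0


def load_config(path: str | Path | None = None) -> PipelineConfig:
    """Load ``key=value`` configuration; absent keys keep their defaults."""
    cfg = PipelineConfig()
    if path is None:
        return cfg
    valid = {f.name: f.type for f in dataclasses.fields(PipelineConfig)}
    for raw in Path(path).read_text().splitlines():
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ConfigError(f"malformed config line {raw!r}; expected key=value")
        key, value = (s.strip() for s in line.split("=", 1))
        if key not in valid:
            raise ConfigError(f"unknown config key {key!r}; valid keys: {sorted(valid)}")
        current = getattr(cfg, key)
        caster = int if isinstance(current, int) else float
        try:
            setattr(cfg, key, caster(value))
        except ValueError as exc:
            raise ConfigError(f"cannot parse value for {key!r}: {value!r}") from exc
    return cfg
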