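"""Compound-heterozygote detection from phased genotypes.

A compound heterozygote carries alternate alleles of two different
qualifying variants of the same gene on opposite haplotypes (in trans).
Homozygosity for any single qualifying variant dominates the call.
Unphased individuals carrying two or more qualifying heterozygous variants
cannot be resolved and are labelled ``ambiguous``; downstream analyses
treat them conservatively (excluded alongside hom/comphet carriers).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Mapping

import numpy as np

from .io import GenotypeMatrix, VariantRecord

STATUSES = ("wildtype", "het_single", "comphet", "hom", "ambiguous")

#: default qualifying filter: likely-pathogenic annotation at a cohort
#: frequency at or above the 0.2% detectability floor
DEFAULT_AF_FLOOR = 0.002


def default_qualifying(rec: VariantRecord, af_floor: float = DEFAULT_AF_FLOOR) -> bool:
    return rec.clinical_category == "likely_pathogenic" and rec.af_alt >= af_floor


@dataclass
class BiallelicCallSet:
    """Per-individual biallelic status for one gene's qualifying variants."""

    gene: str
    qualifying_variants: list[str]         # variant keys
    status: np.ndarray                     # dtype=object, values in STATUSES
    sample_ids: list[str]

    def individuals_with(self, *statuses: str) -> set[str]:
        wanted = set(statuses)
        return {sid for sid, st in zip(self.sample_ids, self.status) if st in wanted}


def find_compound_heterozygotes(geno: GenotypeMatrix,
                                gene_map: Mapping[str, str] | None = None,
                                qualifying: Callable[[VariantRecord], bool] = default_qualifying,
                                ) -> dict[str, BiallelicCallSet]:
    """Assign {wildtype, het_single, comphet, hom, ambiguous} per gene.

    ``gene_map`` maps variant key -> gene; defaults to the ``gene`` field
    of the variant records.  Missing genotype calls are treated as
    reference for status purposes.
    """
    if gene_map is None:
        gene_map = {rec.key: rec.gene for rec in geno.variants if rec.gene}

    by_gene: dict[str, list[int]] = {}
    for j, rec in enumerate(geno.variants):
        gene = gene_map.get(rec.key, "")
        if gene and qualifying(rec):
            by_gene.setdefault(gene, []).append(j)

    if not by_gene:
        warnings.warn("no qualifying variants; empty compound-het call set", stacklevel=2)
        return {}

    n = geno.n_individuals
    out: dict[str, BiallelicCallSet] = {}
    for gene in sorted(by_gene):
        cols = by_gene[gene]
        h = np.clip(geno.haplotypes[:, cols, :], 0, 1)  # missing (-1) treated as ref
        dos = h.sum(axis=2)                             # (N, n_vars) in {0,1,2}
        status = np.full(n, "wildtype", dtype=object)
        n_het = (dos == 1).sum(axis=1)
        any_hom = (dos == 2).any(axis=1)
        hap_has_alt = h.max(axis=1)                     # (N, 2): any alt per haplotype
        trans = (hap_has_alt[:, 0] == 1) & (hap_has_alt[:, 1] == 1)

        status[n_het == 1] = "het_single"
        multi = n_het >= 2
        status[multi & geno.phased & trans] = "comphet"
        status[multi & geno.phased & ~trans] = "het_single"  # all alts in cis
        status[multi & ~geno.phased] = "ambiguous"
        status[any_hom] = "hom"
        out[gene] = BiallelicCallSet(gene=gene,
                                     qualifying_variants=[geno.variants[j].key for j in cols],
                                     status=status, sample_ids=list(geno.sample_ids))
    return out


def exclusion_set(callset: BiallelicCallSet, variant_key: str,
                  geno: GenotypeMatrix) -> set[str]:
    """Individuals to drop before testing a variant's heterozygous effect.

    Union of: individuals homozygous for ``variant_key``, compound
    heterozygotes in the gene, and ambiguous (unphased multi-het) carriers.
    """
    if variant_key not in callset.qualifying_variants:
        raise ValueError(f"{variant_key} is not a qualifying variant of gene {callset.gene}")
    j = geno.variant_index()[variant_key]
    dos = geno.dosage(j)
    hom_ids = {sid for sid, d in zip(geno.sample_ids, dos) if d == 2}
    return hom_ids | callset.individuals_with("comphet", "ambiguous")
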