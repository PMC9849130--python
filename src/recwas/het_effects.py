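"""Heterozygous-effect testing for recessive-acting variants.

After removing homozygous, compound-heterozygous and phase-ambiguous
carriers, the additive-coded test on the remaining individuals contrasts
heterozygotes against wild type, isolating any residual monoallelic
effect.  Nominal (p < 0.05) findings are reported as such without
multiplicity correction; every tested pair is returned so users can
correct downstream.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .association import AssociationResult, DegenerateInput, code_genotype, fit_association
from .comphet import BiallelicCallSet, exclusion_set
from .io import MISSING, GenotypeMatrix, PhenotypeTable, PipelineConfig


@dataclass
class HetEffectResult:
    result: AssociationResult
    n_excluded: int
    tier: str  # genome_wide | nominal | none


def test_heterozygous_effect(variant_key: str, geno: GenotypeMatrix, pheno: PhenotypeTable,
                             callset: BiallelicCallSet, endpoint: str,
                             config: PipelineConfig | None = None,
                             use_covariates: bool = True) -> HetEffectResult:
    """Additive-coded test of ``variant_key`` after excluding biallelic carriers.

    Raises :class:`DegenerateInput` when the genotype is constant after
    exclusion.  The fitted design is guaranteed to contain no dosage-2
    individuals for the tested variant.
    """
    config = config or PipelineConfig()
    excluded = exclusion_set(callset, variant_key, geno)
    keep = np.array([sid not in excluded for sid in geno.sample_ids])

    j = geno.variant_index()[variant_key]
    g = geno.dosage(j).astype(float)
    g[g == MISSING] = np.nan
    g = g[keep]
    assert not np.any(g == 2), "exclusion must remove every homozygous individual"

    order = {sid: i for i, sid in enumerate(pheno.sample_ids)}
    idx = [order[sid] for sid, k in zip(geno.sample_ids, keep) if k]
    y = pheno.endpoint(endpoint)[idx]
    C = pheno.covariates.to_numpy(dtype=float)[idx] if use_covariates else None

    x = code_genotype(g, "additive")
    res = fit_association(y, x, C=C, dosage=g, variant_key=variant_key,
                          phenotype=endpoint, model="additive")
    if res.p < config.genome_wide_p:
        tier = "genome_wide"
    elif res.p < 0.05:
        tier = "nominal"
    else:
        tier = "none"
    return HetEffectResult(result=res, n_excluded=int((~keep).sum()), tier=tier)
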