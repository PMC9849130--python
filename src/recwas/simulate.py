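"""Synthetic founder-population cohorts with known inheritance architecture.

Genotypes are generated under Hardy-Weinberg with an optional single
inbreeding coefficient ``F`` that inflates homozygosity the way a
bottlenecked population does: the homozygous-alternate fraction is
``q**2 + F*q*(1-q)``.  Disease liability acts on the log-odds scale via
per-genotype effects, so that every downstream association test has an
analytically known truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

from .io import GenotypeMatrix, PhenotypeTable, VariantRecord

#: human-readable labels for the five inheritance scenarios
SCENARIO_LABELS = {
    1: "dominant",
    2: "intermediate (het effect above additive midpoint)",
    3: "additive",
    4: "recessive with rare expressing heterozygotes",
    5: "recessive",
}


@dataclass(frozen=True)
class InheritanceScenario:
    """Generative spec for one of the five inheritance scenarios.

    The scenarios partition the plane of (heterozygous, homozygous)
    log-odds effects with ``b_hom > 0``:

    1. dominant: ``b_het == b_hom``
    2. ``b_hom/2 < b_het < b_hom``
    3. additive: ``b_het == b_hom/2`` exactly
    4. recessive with rare expressing heterozygotes: ``0 < b_het < b_hom/2``
    5. recessive: ``b_het == 0``
    """

    scenario_id: int
    b_het: float
    b_hom: float
    baseline_logit: float = -3.0

    def __post_init__(self) -> None:
        sid, bh, bhom = self.scenario_id, self.b_het, self.b_hom
        if sid not in SCENARIO_LABELS:
            raise ValueError(f"scenario_id must be in 1..5, got {sid}")
        if bhom != 0.0:  # b_hom == 0 permitted only as an explicit null
            checks = {
                1: bh == bhom,
                2: bhom / 2 < bh < bhom,
                3: bh == bhom / 2,
                4: 0 < bh < bhom / 2,
                5: bh == 0.0,
            }
            if not checks[sid]:
                raise ValueError(
                    f"effects (b_het={bh}, b_hom={bhom}) violate scenario {sid} "
                    f"({SCENARIO_LABELS[sid]})")

    @classmethod
    def from_homozygous_effect(cls, scenario_id: int, b_hom: float,
                               baseline_logit: float = -3.0,
                               het_fraction: float | None = None) -> "InheritanceScenario":
        """Build a scenario from its homozygous effect alone.

        ``het_fraction`` expresses ``b_het`` as a fraction of ``b_hom`` and
        is only consulted for scenarios 2 (default 0.75) and 4 (default 0.25);
        scenarios 1/3/5 are fully determined.
        """
        defaults = {1: 1.0, 2: 0.75, 3: 0.5, 4: 0.25, 5: 0.0}
        if scenario_id not in defaults:
            raise ValueError(f"scenario_id must be in 1..5, got {scenario_id}")
        frac = defaults[scenario_id]
        if het_fraction is not None:
            if scenario_id not in (2, 4):
                raise ValueError("het_fraction only applies to scenarios 2 and 4")
            frac = het_fraction
        return cls(scenario_id=scenario_id, b_het=frac * b_hom, b_hom=b_hom,
                   baseline_logit=baseline_logit)

    def genotype_effects(self) -> np.ndarray:
        return np.array([0.0, self.b_het, self.b_hom])


@dataclass
class VariantSpec:
    """Target frequency, location and annotation for one simulated variant."""

    maf: float
    chrom: str = "1"
    pos: int = 0
    gene: str = ""
    consequence: str = "missense"
    clinical_category: str = "none"
    af_ref_pop: float | None = None

    def __post_init__(self) -> None:
        if not 0.0 < self.maf < 0.5:
            raise ValueError(f"variant frequency must be in (0, 0.5), got {self.maf}")


@dataclass
class CohortSpec:
    """Cohort-level generative parameters.

    ``ld_pairs`` optionally lists ``(i, j, rho)`` triples: variant ``j``'s
    haplotypes copy variant ``i``'s with probability ``rho`` (else drawn
    fresh), giving haplotype correlation ~``rho`` for locus-collapse tests.
    ``cis_fraction`` applies to consecutive same-gene variant pairs and is
    the probability that a double-het carries both alternates in cis; the
    default 0 (independent phase) leaves the two variants in linkage
    equilibrium.
    """

    n_individuals: int
    variants: list[VariantSpec]
    inbreeding: float = 0.0
    seed: int = 0
    ld_pairs: list[tuple[int, int, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not 0.0 <= self.inbreeding < 1.0:
            raise ValueError(f"inbreeding coefficient must be in [0, 1), got {self.inbreeding}")
        if self.n_individuals < 1:
            raise ValueError("n_individuals must be positive")


def simulate_genotypes(spec: CohortSpec, rng: np.random.Generator | None = None) -> GenotypeMatrix:
    """Draw phased haplotypes for every variant in ``spec``.

    With inbreeding coefficient ``F`` an individual's two haplotypes are
    identical-by-descent (a single allele copied to both) with probability
    ``F`` and independent Bernoulli(q) draws otherwise, which yields the
    homozygote-excess moment ``q**2 + F*q*(1-q)`` exactly.
    """
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    n, v = spec.n_individuals, len(spec.variants)
    f = spec.inbreeding
    haps = np.zeros((n, v, 2), dtype=np.int8)
    ld_targets = {j: (i, rho) for i, j, rho in spec.ld_pairs}
    for j, vs in enumerate(spec.variants):
        if j in ld_targets:
            src, rho = ld_targets[j]
            fresh = rng.random((n, 2)) < vs.maf
            copy = rng.random((n, 2)) < rho
            haps[:, j, :] = np.where(copy, haps[:, src, :], fresh)
            continue
        a = rng.random((n, 2)) < vs.maf
        if f > 0:
            ibd = rng.random(n) < f
            a[ibd, 1] = a[ibd, 0]
        haps[:, j, :] = a
    variants = []
    for j, vs in enumerate(spec.variants):
        pos = vs.pos if vs.pos else (j + 1) * 100_000
        variants.append(VariantRecord(
            chrom=vs.chrom, pos=pos, ref="A", alt="C", gene=vs.gene,
            consequence=vs.consequence, clinical_category=vs.clinical_category,
            af_ref_pop=vs.af_ref_pop))
    gm = GenotypeMatrix(variants=variants, haplotypes=haps,
                        phased=np.ones(n, dtype=bool),
                        sample_ids=[f"S{i:06d}" for i in range(n)])
    af = gm.allele_frequencies()
    for j, rec in enumerate(gm.variants):
        rec.af_alt = float(af[j])
    return gm


def default_covariates(n: int, rng: np.random.Generator, n_pcs: int = 10,
                       n_batches: int = 4) -> pd.DataFrame:
    """Age ~ U(30, 80); sex ~ Bernoulli(0.55 female); PCs ~ N(0,1); batch categorical."""
    cov = {
        "age": rng.uniform(30.0, 80.0, n),
        "sex": (rng.random(n) < 0.55).astype(int),
    }
    batch = rng.integers(0, n_batches, n)
    for b in range(1, n_batches):
        cov[f"batch_{b}"] = (batch == b).astype(int)
    for k in range(1, n_pcs + 1):
        cov[f"PC{k}"] = rng.standard_normal(n)
    return pd.DataFrame(cov, index=[f"S{i:06d}" for i in range(n)])


def simulate_phenotype(geno: GenotypeMatrix, scenario: InheritanceScenario,
                       variant_index: int = 0, endpoint: str = "D1",
                       covariate_effects: Mapping[str, float] | None = None,
                       covariates: pd.DataFrame | None = None,
                       rng: np.random.Generator | None = None,
                       seed: int = 0) -> PhenotypeTable:
    """Draw a binary endpoint from the logistic liability model.

    ``logit(p_i) = baseline + b_het*[g_i==1] + b_hom*[g_i==2] + sum_c beta_c x_ic``.
    Individuals with a missing genotype get a liability from the baseline
    term only.  Returns a :class:`PhenotypeTable` whose generation log (the
    ``attrs`` of the endpoint frame) records the true parameters.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    n = geno.n_individuals
    if covariates is None:
        covariates = default_covariates(n, rng)
        covariates.index = geno.sample_ids
    g = geno.dosage(variant_index)
    eta = np.full(n, scenario.baseline_logit, dtype=float)
    eta[g == 1] += scenario.b_het
    eta[g == 2] += scenario.b_hom
    if covariate_effects:
        for name, beta in covariate_effects.items():
            eta += beta * covariates[name].to_numpy(dtype=float)
    p = 1.0 / (1.0 + np.exp(-eta))
    y = (rng.random(n) < p).astype(int)
    endpoints = pd.DataFrame({endpoint: y}, index=covariates.index)
    endpoints.attrs["truth"] = {
        "scenario_id": scenario.scenario_id, "b_het": scenario.b_het,
        "b_hom": scenario.b_hom, "baseline_logit": scenario.baseline_logit,
        "variant": geno.variants[variant_index].key, "endpoint": endpoint,
        "covariate_effects": dict(covariate_effects or {}),
    }
    return PhenotypeTable(endpoints=endpoints, covariates=covariates)


def simulate_onset(pheno: PhenotypeTable, geno: GenotypeMatrix, variant_index: int,
                   hazard_ratio_hom: float, hazard_ratio_het: float = 1.0,
                   endpoint: str = "D1", baseline_hazard: float = 0.02,
                   censor_age: float = 80.0, model: str = "exponential",
                   weibull_shape: float = 1.5,
                   rng: np.random.Generator | None = None, seed: int = 0) -> PhenotypeTable:
    """Draw genotype-specific onset ages with administrative censoring.

    Event times come from an exponential (default) or Weibull proportional
    hazard ``baseline_hazard * HR_g``; individuals whose time exceeds
    ``censor_age`` are censored and the endpoint indicator is reset to 0,
    so that onset_age is present exactly for cases.  Returns a new
    :class:`PhenotypeTable` (input not mutated).
    """
    if hazard_ratio_hom <= 0 or hazard_ratio_het <= 0:
        raise ValueError("hazard ratios must be > 0")
    if model not in ("exponential", "weibull"):
        raise ValueError(f"unknown onset model {model!r}")
    if rng is None:
        rng = np.random.default_rng(seed)
    n = len(pheno.sample_ids)
    g = geno.dosage(variant_index)
    hr = np.ones(n)
    hr[g == 1] = hazard_ratio_het
    hr[g == 2] = hazard_ratio_hom
    u = rng.random(n)
    if model == "exponential":
        t = -np.log(u) / (baseline_hazard * hr)
    else:
        t = (-np.log(u) / (baseline_hazard * hr)) ** (1.0 / weibull_shape)
    event = t < censor_age
    onset = np.where(event, t, np.nan)
    endpoints = pheno.endpoints.copy()
    endpoints[endpoint] = event.astype(int)
    endpoints.attrs = dict(pheno.endpoints.attrs)
    onset_df = pheno.onset_age.copy() if pheno.onset_age is not None \
        else pd.DataFrame(index=endpoints.index)
    onset_df[endpoint] = onset
    return PhenotypeTable(endpoints=endpoints, covariates=pheno.covariates,
                          onset_age=onset_df, children_count=pheno.children_count)


def simulate_matching_pool(n_intergenic: int,
                           af_sampler: Callable[[np.random.Generator, int], np.ndarray] | None = None,
                           genome_layout: Mapping[str, int] | None = None,
                           seed: int = 0,
                           anchor_variants: Sequence[VariantRecord] | None = None,
                           window_bp: int = 3_000_000) -> list[VariantRecord]:
    """Sample intergenic variants usable as a matched-resampling pool.

    Positions are drawn uniformly per chromosome from ``genome_layout``
    (chrom -> length in bp); if ``anchor_variants`` is given, a share of the
    pool is placed inside the same ``window_bp`` tiles as the anchors so
    that position-matched sampling is feasible.  Allele frequencies come
    from ``af_sampler`` (default: log-uniform on [1e-4, 0.5]).
    """
    rng = np.random.default_rng(seed)
    if n_intergenic == 0:
        return []
    if genome_layout is None:
        genome_layout = {"1": 240_000_000, "2": 240_000_000}
    if af_sampler is None:
        def af_sampler(r: np.random.Generator, k: int) -> np.ndarray:
            return np.exp(r.uniform(np.log(1e-4), np.log(0.5), k))
    afs = np.asarray(af_sampler(rng, n_intergenic), dtype=float)
    chroms = list(genome_layout)
    out: list[VariantRecord] = []
    anchors = list(anchor_variants or [])
    for i in range(n_intergenic):
        if anchors and i % 2 == 0:  # half the pool co-locates with anchors
            a = anchors[(i // 2) % len(anchors)]
            w0 = ((a.pos - 1) // window_bp) * window_bp  # tile anchored like enrichment windows
            chrom = a.chrom
            pos = int(rng.integers(w0 + 1, w0 + window_bp + 1))
        else:
            chrom = chroms[int(rng.integers(len(chroms)))]
            pos = int(rng.integers(1, genome_layout[chrom] + 1))
        out.append(VariantRecord(chrom=chrom, pos=pos, ref="A", alt="G",
                                 consequence="intergenic", af_alt=float(np.clip(afs[i], 0.0, 1.0))))
    return out
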