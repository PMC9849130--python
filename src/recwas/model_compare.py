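"""Additive-vs-recessive model comparison and locus collapsing.

A variant-phenotype association is called "recessive" when the recessive
P value is at least two orders of magnitude smaller than the additive P
value (``p_rec <= p_add * rec_margin`` with ``rec_margin = 1e-2``);
associations where the recessive P is merely smaller form a secondary
"non_additive_candidate" tier.  Correlated nearby variants associated with
the same parent trait are collapsed into loci via single-linkage
clustering on the r^2 > 0.25 graph.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .io import GenotypeMatrix

CATEGORIES = ("recessive", "non_additive_candidate", "additive_better_or_equal")


@dataclass
class ClassifiedAssociation:
    variant_key: str
    phenotype: str
    p_add: float
    p_rec: float
    category: str
    genome_wide_significant: bool


@dataclass
class Locus:
    members: list[str]            # variant keys, genomic order
    lead: str                     # member with the smallest min(p_add, p_rec)
    parent_trait: str


def classify_association(p_add: float, p_rec: float, genome_wide_p: float = 5e-8,
                         rec_margin: float = 1e-2) -> tuple[str, bool]:
    """Two-tier classification of one association; returns (category, significant)."""
    for name, p in (("p_add", p_add), ("p_rec", p_rec)):
        if not 0.0 < p <= 1.0:
            raise ValueError(f"{name} must be in (0,1], got {p}")
    if p_rec <= p_add * rec_margin:
        category = "recessive"
    elif p_rec < p_add:
        category = "non_additive_candidate"
    else:
        category = "additive_better_or_equal"
    return category, bool(min(p_add, p_rec) < genome_wide_p)


def classify_results(additive: Sequence, recessive: Sequence, genome_wide_p: float = 5e-8,
                     rec_margin: float = 1e-2) -> list[ClassifiedAssociation]:
    """Pair additive/recessive results by (variant, phenotype) and classify each pair."""
    rec_by_key = {(r.variant_key, r.phenotype): r for r in recessive}
    out = []
    for a in additive:
        r = rec_by_key.get((a.variant_key, a.phenotype))
        if r is None:
            continue
        category, sig = classify_association(a.p, r.p, genome_wide_p, rec_margin)
        out.append(ClassifiedAssociation(a.variant_key, a.phenotype, a.p, r.p, category, sig))
    return out


def ld_r2(g1: np.ndarray, g2: np.ndarray) -> float:
    """Squared Pearson correlation between two dosage vectors (complete cases)."""
    g1 = np.asarray(g1, dtype=float)
    g2 = np.asarray(g2, dtype=float)
    if g1.shape != g2.shape:
        raise ValueError("dosage vectors must have the same length")
    keep = np.isfinite(g1) & np.isfinite(g2) & (g1 >= 0) & (g2 >= 0)
    a, b = g1[keep], g2[keep]
    if len(a) < 2:
        raise ValueError("fewer than 2 complete cases")
    if np.all(a == a[0]) or np.all(b == b[0]):
        raise ValueError("constant dosage vector")
    r = np.corrcoef(a, b)[0, 1]
    return float(r * r)


class _UnionFind:
    def __init__(self, n: int) -> None:
        self.parent = list(range(n))

    def find(self, i: int) -> int:
        while self.parent[i] != i:
            self.parent[i] = self.parent[self.parent[i]]
            i = self.parent[i]
        return i

    def union(self, i: int, j: int) -> None:
        self.parent[self.find(i)] = self.find(j)


def collapse_loci(classified: Sequence[ClassifiedAssociation], geno: GenotypeMatrix,
                  r2_locus: float = 0.25, window_bp: int = 3_000_000,
                  parent_map: Mapping[str, str] | None = None) -> list[Locus]:
    """Collapse correlated variants into loci, per parent trait.

    Variants enter the same locus when they share a parent trait and are
    connected (transitively) through pairs on the same chromosome within
    ``window_bp`` of each other with dosage r^2 > ``r2_locus``.  The locus
    lead is the member with the smallest min(p_add, p_rec); ties break by
    genomic order.
    """
    parent_map = parent_map or {}
    index = geno.variant_index()
    missing = [c.variant_key for c in classified if c.variant_key not in index]
    if missing:
        raise ValueError(f"variants absent from genotype matrix: {missing[:5]}")

    by_trait: dict[str, list[ClassifiedAssociation]] = {}
    for c in classified:
        trait = parent_map.get(c.phenotype, c.phenotype)
        by_trait.setdefault(trait, []).append(c)

    dosages = geno.dosage_matrix()
    loci: list[Locus] = []
    for trait in sorted(by_trait):
        items = by_trait[trait]
        # one node per unique variant; best p across that trait's endpoints
        keys = sorted({c.variant_key for c in items},
                      key=lambda k: (geno.variants[index[k]].chrom, geno.variants[index[k]].pos))
        best_p = {k: min(min(c.p_add, c.p_rec) for c in items if c.variant_key == k)
                  for k in keys}
        uf = _UnionFind(len(keys))
        for i in range(len(keys)):
            vi = geno.variants[index[keys[i]]]
            for j in range(i + 1, len(keys)):
                vj = geno.variants[index[keys[j]]]
                if vi.chrom != vj.chrom or abs(vi.pos - vj.pos) > window_bp:
                    continue
                try:
                    r2 = ld_r2(dosages[:, index[keys[i]]], dosages[:, index[keys[j]]])
                except ValueError:
                    continue
                if r2 > r2_locus:
                    uf.union(i, j)
        groups: dict[int, list[str]] = {}
        for i, k in enumerate(keys):
            groups.setdefault(uf.find(i), []).append(k)
        for members in groups.values():
            lead = min(members, key=lambda k: (best_p[k], members.index(k)))
            loci.append(Locus(members=members, lead=lead, parent_trait=trait))
    return loci
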