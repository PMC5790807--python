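"""Shared-risk-SNP analysis across disease categories.

Starting from a GWAS-catalog-like table of risk SNPs, trait strings are
partitioned into disease categories by keyword matching.  Risk SNPs
shared between two categories are either identical variants or pairs of
variants co-inherited through strong linkage disequilibrium (r² above a
threshold with a known allele phase).  A shared SNP is *synergistic*
when the same allele predisposes to both categories and *antagonistic*
when one allele predisposes to one category and the alternative allele
to the other.  Shared SNPs are grouped into independent genomic loci,
and the excess of antagonistic sharing is quantified by an exact
binomial test against the sharing observed with non-ageing traits plus
a resampling null that redraws category-sized SNP sets from that pool.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .io_formats import LdTable, SnpCatalog, SnpRecord

logger = logging.getLogger("agealign")

#: Trait keywords for the four ageing-disease categories (case-insensitive
#: substring matching).  Traits matching nothing join the non-ageing pool.
DEFAULT_KEYWORDS: dict[str, tuple[str, ...]] = {
    "cancer": ("cancer", "carcinoma", "melanoma", "leukemia", "lymphoma", "glioma"),
    "CVD": ("coronary", "cardiovascular", "myocardial", "stroke", "hypertension",
            "atherosclerosis", "heart"),
    "NDD": ("alzheimer", "parkinson", "dementia", "cognitive decline",
            "amyotrophic", "neurodegener"),
    "T2D": ("type 2 diabetes", "type II diabetes", "insulin resistance"),
}

NON_AGEING_POOL = "non_ageing"

LABELS = ("synergistic", "antagonistic", "unclassified")


def build_trait_snp_sets(
    catalog: SnpCatalog,
    keyword_map: Mapping[str, Sequence[str]] | None = None,
) -> dict[str, list[SnpRecord]]:
    """Partition catalog records into disease categories by trait keywords.

    A record whose trait matches keywords of several categories is
    assigned to all of them; a record matching none joins the non-ageing
    pool under the key ``"non_ageing"``.
    """
    keyword_map = dict(keyword_map or DEFAULT_KEYWORDS)
    out: dict[str, list[SnpRecord]] = {cat: [] for cat in keyword_map}
    out[NON_AGEING_POOL] = []
    for rec in catalog.records:
        trait = rec.trait.lower()
        hits = [
            cat
            for cat, words in keyword_map.items()
            if any(w.lower() in trait for w in words)
        ]
        if hits:
            for cat in hits:
                out[cat].append(rec)
        else:
            out[NON_AGEING_POOL].append(rec)
    for cat, records in out.items():
        if not records:
            logger.warning("trait category %r matched no SNP record", cat)
    return out


# ---------------------------------------------------------------------------
# Sharing and classification
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SharedSnp:
    """One shared risk SNP: a record pair with its sharing mode."""

    rec1: SnpRecord
    rec2: SnpRecord
    mode: str  # "identical" | "LD"
    r2: float
    label: str = "unclassified"
    reason: str = ""


@dataclass
class SharedSnpSet:
    pairs: list[SharedSnp]
    loci: dict[str, int] | None = None  # rsID → locus id

    def __len__(self) -> int:
        return len(self.pairs)

    def counts(self) -> dict[str, int]:
        out = {label: 0 for label in LABELS}
        for p in self.pairs:
            out[p.label] += 1
        return out


def find_shared_risk_snps(
    set1: Sequence[SnpRecord],
    set2: Sequence[SnpRecord],
    ld: LdTable | None = None,
    r2_min: float = 0.8,
) -> SharedSnpSet:
    """Identical rsIDs plus cross-set pairs in strong LD (r² >= r2_min).

    Pairs of the same record appearing in both sets count once in
    identical mode; LD pairs require the pair to be present in the LD
    table (absent pairs are treated as unlinked).
    """
    ld = ld or LdTable()
    pairs: list[SharedSnp] = []
    seen: set[tuple[str, str]] = set()
    by_rsid2: dict[str, list[SnpRecord]] = {}
    for rec in set2:
        by_rsid2.setdefault(rec.rsid, []).append(rec)
    for rec1 in set1:
        for rec2 in by_rsid2.get(rec1.rsid, []):
            key = (rec1.rsid, rec2.rsid)
            if key not in seen:
                seen.add(key)
                pairs.append(SharedSnp(rec1=rec1, rec2=rec2, mode="identical", r2=1.0))
    for rec1 in set1:
        for rec2 in set2:
            if rec1.rsid == rec2.rsid:
                continue
            key = (rec1.rsid, rec2.rsid)
            if key in seen:
                continue
            r2 = ld.r2(rec1.rsid, rec2.rsid)
            if r2 >= r2_min:
                seen.add(key)
                pairs.append(SharedSnp(rec1=rec1, rec2=rec2, mode="LD", r2=r2))
    return SharedSnpSet(pairs=pairs)


def classify_shared_snp(pair: SharedSnp, ld: LdTable | None = None) -> SharedSnp:
    """Label a shared SNP as synergistic, antagonistic or unclassified.

    Identical mode: same risk allele in both sets ⇒ synergistic; one
    set's risk allele equal to the other's alternative allele ⇒
    antagonistic.  LD mode: the second SNP's risk allele is mapped
    through the haplotype phase onto the first SNP's alleles before the
    same rule applies.  Alleles that cannot be reconciled leave the pair
    unclassified with a reason.
    """
    rec1, rec2 = pair.rec1, pair.rec2
    if pair.mode == "identical":
        risk2, alt2 = rec2.risk_allele, rec2.alt_allele
    else:
        ld = ld or LdTable()
        link = ld.get(rec2.rsid, rec1.rsid)
        if link is None:
            return SharedSnp(
                **{**pair.__dict__, "label": "unclassified",
                   "reason": "phase map missing for LD pair"}
            )
        phase = link.phase_dict()  # rec2 allele → rec1 allele
        risk2 = phase.get(rec2.risk_allele)
        alt2 = phase.get(rec2.alt_allele)
        if risk2 is None or alt2 is None:
            return SharedSnp(
                **{**pair.__dict__, "label": "unclassified",
                   "reason": "risk alleles absent from phase map"}
            )
    alleles1 = {rec1.risk_allele, rec1.alt_allele}
    if {risk2, alt2} != alleles1:
        return SharedSnp(
            **{**pair.__dict__, "label": "unclassified",
               "reason": "allele sets do not correspond"}
        )
    label = "synergistic" if risk2 == rec1.risk_allele else "antagonistic"
    return SharedSnp(**{**pair.__dict__, "label": label})


def classify_shared_set(shared: SharedSnpSet, ld: LdTable | None = None) -> SharedSnpSet:
    return SharedSnpSet(
        pairs=[classify_shared_snp(p, ld) for p in shared.pairs], loci=shared.loci
    )


# ---------------------------------------------------------------------------
# Independent loci
# ---------------------------------------------------------------------------

def count_independent_loci(
    shared: SharedSnpSet,
    ld: LdTable | None = None,
    r2_cluster: float = 0.5,
    window_bp: int = 1_000_000,
) -> tuple[dict[str, int], int]:
    """Group shared SNPs into independent genomic loci.

    Loci are connected components of the graph joining shared SNPs with
    r² >= ``r2_cluster`` or same-chromosome distance <= ``window_bp``.
    Returns the rsID → locus-id assignment and the locus count.
    """
    ld = ld or LdTable()
    records: dict[str, SnpRecord] = {}
    for pair in shared.pairs:
        records.setdefault(pair.rec1.rsid, pair.rec1)
        records.setdefault(pair.rec2.rsid, pair.rec2)
    graph = nx.Graph()
    graph.add_nodes_from(records)
    rsids = list(records)
    for i, a in enumerate(rsids):
        for b in rsids[i + 1:]:
            ra, rb = records[a], records[b]
            close = (
                ra.chromosome == rb.chromosome
                and abs(ra.position - rb.position) <= window_bp
            )
            if close or ld.r2(a, b) >= r2_cluster:
                graph.add_edge(a, b)
    assignment: dict[str, int] = {}
    for locus_id, component in enumerate(
        sorted(nx.connected_components(graph), key=lambda c: min(c))
    ):
        for rsid in component:
            assignment[rsid] = locus_id
    shared.loci = assignment
    return assignment, len(set(assignment.values())) if assignment else 0


# ---------------------------------------------------------------------------
# Bias tests
# ---------------------------------------------------------------------------

def antagonism_bias_binomial(
    k_antagonistic: int,
    n_shared: int,
    background: SharedSnpSet,
) -> float:
    """One-sided exact binomial p for an excess of antagonistic sharing.

    The null antagonistic rate p0 is the antagonistic fraction among the
    classified shared SNPs of the background (non-ageing-trait) set;
    returns P(X >= k | n, p0).
    """
    if k_antagonistic > n_shared:
        raise ValueError("k cannot exceed n")
    counts = background.counts()
    n_bg = counts["synergistic"] + counts["antagonistic"]
    if n_bg == 0:
        raise ValueError("background set has no classified shared SNPs")
    p0 = counts["antagonistic"] / n_bg
    return float(stats.binom.sf(k_antagonistic - 1, n_shared, p0))


@dataclass
class RandomizationResult:
    synergistic: np.ndarray
    antagonistic: np.ndarray
    total_shared: np.ndarray
    p_synergistic: float
    p_antagonistic: float
    p_total: float


def randomization_null_snps(
    focal: Sequence[SnpRecord],
    replaced: Sequence[SnpRecord],
    pool: Sequence[SnpRecord],
    ld: LdTable | None = None,
    r2_min: float = 0.8,
    n_reps: int = 10_000,
    seed: int | None = None,
) -> RandomizationResult:
    """Resampling null for sharing between a focal category and another.

    Each replicate draws, without replacement, a pool subset the size of
    the ``replaced`` category and recomputes sharing and classification
    against the focal set.  Empirical p-values use the add-one
    correction (1 + #{null >= observed}) / (n_reps + 1).
    """
    if len(pool) < len(replaced):
        raise ValueError("pool smaller than the replaced SNP set")
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    rng = np.random.default_rng(seed)
    observed = classify_shared_set(
        find_shared_risk_snps(focal, replaced, ld, r2_min), ld
    ).counts()
    obs_total = sum(observed[label] for label in LABELS)
    pool = list(pool)
    syn = np.empty(n_reps, dtype=int)
    ant = np.empty(n_reps, dtype=int)
    tot = np.empty(n_reps, dtype=int)
    for i in range(n_reps):
        draw_idx = rng.choice(len(pool), size=len(replaced), replace=False)
        draw = [pool[j] for j in draw_idx]
        counts = classify_shared_set(
            find_shared_risk_snps(focal, draw, ld, r2_min), ld
        ).counts()
        syn[i] = counts["synergistic"]
        ant[i] = counts["antagonistic"]
        tot[i] = sum(counts[label] for label in LABELS)
    def emp(null: np.ndarray, obs: int) -> float:
        return (1 + int((null >= obs).sum())) / (n_reps + 1)
    return RandomizationResult(
        synergistic=syn,
        antagonistic=ant,
        total_shared=tot,
        p_synergistic=emp(syn, observed["synergistic"]),
        p_antagonistic=emp(ant, observed["antagonistic"]),
        p_total=emp(tot, obs_total),
    )


def shared_snp_table(shared: SharedSnpSet) -> pd.DataFrame:
    """Flat table of shared SNPs for reporting/writing."""
    rows = []
    for p in shared.pairs:
        rows.append(
            {
                "rsid_1": p.rec1.rsid,
                "trait_1": p.rec1.trait,
                "rsid_2": p.rec2.rsid,
                "trait_2": p.rec2.trait,
                "mode": p.mode,
                "r2": p.r2,
                "label": p.label,
                "reason": p.reason,
                "locus": (shared.loci or {}).get(p.rec1.rsid, -1),
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "rsid_1", "trait_1", "rsid_2", "trait_2",
            "mode", "r2", "label", "reason", "locus",
        ],
    )
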