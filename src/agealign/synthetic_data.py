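"""Synthetic data with the statistical structure the pipeline assumes.

Three generators stand in for the study's measured inputs:

* a cross-species expression study — negative-binomial RNA-seq counts
  over pseudo-species of two clades (fish and mammals), several tissues
  and ordered age groups, with monotone multiplicative ageing trends
  planted on the genes of selected processes;
* disease signatures whose gene foldchanges follow (or oppose) the
  planted ageing direction with Gaussian noise;
* risk-SNP catalogs with LD blocks, valid phase maps, a planted
  antagonistic fraction among cancer/degenerative shared SNPs, and a
  non-ageing trait pool with background sharing.

Every generator is a pure function of its parameters and seed, and each
returns a :class:`SimulationTruth` from which every expected downstream
outcome can be computed without re-reading the generated data.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .io_formats import (
    AGE_ORDER,
    DiseaseSignature,
    ExpressionStudy,
    GeneSetCollection,
    LdPair,
    LdTable,
    SnpCatalog,
    SnpRecord,
    rpkm_from_counts,
)

#: Pseudo-species in clade-interleaved order so any prefix of length >= 2
#: contains at least one fish and one mammal.
SPECIES_POOL = ("zebrafish", "mouse", "killifish", "human")
TISSUE_POOL = ("blood", "brain", "liver", "skin")

CANCER_TRAITS = ("Breast cancer", "Prostate cancer", "Lung carcinoma")
DEGENERATIVE_TRAITS = {
    "CVD": ("Coronary artery disease", "Hypertension"),
    "NDD": ("Alzheimer's disease", "Parkinson's disease"),
    "T2D": ("Type 2 diabetes",),
}
POOL_TRAITS = ("Height", "Hair color", "Eye color", "Bone mineral density",
               "Educational attainment")

_ALLELES = np.array(list("ACGT"))


@dataclass
class SimulationTruth:
    """Planted ground truth, serialisable alongside generated data."""

    seed: int | None = None
    # expression part
    genes: list[str] = field(default_factory=list)
    regulated_processes: dict[str, int] = field(default_factory=dict)  # pid → ±1
    gene_directions: dict[str, int] = field(default_factory=dict)  # gene → ±1
    effect: float = 0.0
    # disease part
    disease_coefficients: dict[str, dict] = field(default_factory=dict)
    # SNP part
    snp_pair_labels: list[list[str]] = field(default_factory=list)  # [rs1, rs2, label]
    n_shared_loci: int = 0
    antagonistic_fraction: float = 0.0

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=1, sort_keys=True))

    @classmethod
    def from_json(cls, path: str | Path) -> "SimulationTruth":
        return cls(**json.loads(Path(path).read_text()))


# ---------------------------------------------------------------------------
# Expression
# ---------------------------------------------------------------------------

def _age_groups(k: int) -> tuple[str, ...]:
    if k == 3:
        return ("young", "old_1", "old_2")
    if k == 4:
        return ("young", "mature_1", "old_1", "old_2")
    if k == 5:
        return AGE_ORDER
    raise ValueError("age_groups must be 3, 4 or 5")


def generate_expression_study(
    n_species: int = 4,
    n_tissues: int = 4,
    age_groups: int = 3,
    n_per_cell: int = 6,
    n_genes: int = 2000,
    n_processes: int = 200,
    n_regulated: int = 20,
    effect: float = 0.3,
    dispersion: float = 0.1,
    longitudinal: bool = False,
    seed: int | None = None,
) -> tuple[ExpressionStudy, GeneSetCollection, SimulationTruth]:
    """Cross-species study with planted ageing-regulated processes.

    Counts follow a negative-binomial law with gene-specific lognormal
    base means and common dispersion; genes of the ``n_regulated``
    planted processes carry a monotone multiplicative trend over the age
    groups, with ``effect`` the natural-log fold over the full age range
    (calibrated to move rank-scaled activities by roughly that amount).
    The trend has the same planted sign in every pseudo-species, so the
    fish/mammal consistency rule is satisfiable.  With
    ``longitudinal=True`` each pseudo-individual is sampled at the first
    and last age group with an individual-specific trend slope, and
    lifespans anti-correlated with that slope are written to the
    metadata.  Values are RPKM (computed from the simulated counts).
    """
    if n_regulated > n_processes:
        raise ValueError("n_regulated cannot exceed n_processes")
    if n_genes < 5 * n_processes:
        raise ValueError("need at least 5 genes per process")
    if not 2 <= n_species <= len(SPECIES_POOL):
        raise ValueError(f"n_species must be in [2, {len(SPECIES_POOL)}]")
    if not 1 <= n_tissues <= len(TISSUE_POOL):
        raise ValueError(f"n_tissues must be in [1, {len(TISSUE_POOL)}]")
    rng = np.random.default_rng(seed)
    species = SPECIES_POOL[:n_species]
    tissues = TISSUE_POOL[:n_tissues]
    ages = _age_groups(age_groups)

    genes = [f"g{i:05d}" for i in range(n_genes)]
    per_process = n_genes // n_processes
    sets = {
        f"P{j:04d}": frozenset(genes[j * per_process:(j + 1) * per_process])
        for j in range(n_processes)
    }
    collection = GeneSetCollection(name="synthetic_ontology", sets=sets)

    reg_idx = rng.choice(n_processes, size=n_regulated, replace=False)
    regulated = {
        f"P{j:04d}": (1 if k < (n_regulated + 1) // 2 else -1)
        for k, j in enumerate(sorted(reg_idx))
    }
    gene_dir = np.zeros(n_genes, dtype=int)
    for pid, direction in regulated.items():
        for g in sets[pid]:
            gene_dir[int(g[1:])] = direction

    base_mean = np.exp(rng.normal(np.log(200.0), 0.5, size=n_genes))
    gene_lengths = pd.Series(
        np.exp(rng.normal(np.log(2000.0), 0.3, size=n_genes)).round().astype(int),
        index=genes,
    )

    sample_ids: list[str] = []
    meta_rows: list[dict] = []
    mu_cols: list[np.ndarray] = []
    stage_of = {a: (i / (len(ages) - 1)) for i, a in enumerate(ages)}
    if longitudinal:
        sampled_ages = (ages[0], ages[-1])
        for sp in species:
            for ti in tissues:
                for ind in range(n_per_cell):
                    ind_id = f"{sp}_{ti}_i{ind}"
                    slope = rng.normal(1.0, 0.3)
                    lifespan = float(
                        1000.0 * np.exp(-0.5 * (slope - 1.0) + rng.normal(0, 0.1))
                    )
                    for tp, age in enumerate(sampled_ages):
                        sid = f"{ind_id}_t{tp}"
                        sample_ids.append(sid)
                        meta_rows.append(
                            {
                                "sample": sid, "species": sp, "tissue": ti,
                                "age_group": age, "individual_id": ind_id,
                                "lifespan": lifespan, "time_point": tp,
                            }
                        )
                        trend = np.exp(
                            effect * slope * stage_of[age] * gene_dir
                        )
                        lib = np.exp(rng.normal(0.0, 0.15))
                        mu_cols.append(base_mean * trend * lib)
    else:
        for sp in species:
            for ti in tissues:
                for age in ages:
                    for rep in range(n_per_cell):
                        sid = f"{sp}_{ti}_{age}_r{rep}"
                        sample_ids.append(sid)
                        meta_rows.append(
                            {
                                "sample": sid, "species": sp, "tissue": ti,
                                "age_group": age,
                                "individual_id": sid, "lifespan": np.nan,
                            }
                        )
                        trend = np.exp(effect * stage_of[age] * gene_dir)
                        lib = np.exp(rng.normal(0.0, 0.15))
                        mu_cols.append(base_mean * trend * lib)

    mu = np.column_stack(mu_cols)
    n_nb = 1.0 / dispersion
    counts = rng.negative_binomial(n_nb, n_nb / (n_nb + mu))
    counts_df = pd.DataFrame(counts, index=genes, columns=sample_ids)
    library_sizes = counts_df.sum(axis=0).astype(float)
    values = rpkm_from_counts(counts_df, gene_lengths, library_sizes)
    meta = pd.DataFrame(meta_rows).set_index("sample")
    study = ExpressionStudy(values=values, meta=meta, gene_lengths=gene_lengths)

    truth = SimulationTruth(
        seed=seed,
        genes=genes,
        regulated_processes=regulated,
        gene_directions={
            genes[i]: int(d) for i, d in enumerate(gene_dir) if d != 0
        },
        effect=effect,
    )
    return study, collection, truth


# ---------------------------------------------------------------------------
# Disease signatures
# ---------------------------------------------------------------------------

def generate_disease_signature(
    truth: SimulationTruth,
    category: str,
    c: int = 1,
    noise_sd: float = 0.3,
    disease_id: str | None = None,
    seed: int | None = None,
) -> DiseaseSignature:
    """Disease foldchanges aligned (c=+1) or anti-aligned (c=-1) with the
    planted ageing directions; genes outside regulated processes are
    pure noise."""
    if c not in (1, -1):
        raise ValueError("alignment coefficient c must be +1 or -1")
    if not truth.genes:
        raise ValueError("truth carries no expression part; generate a study first")
    rng = np.random.default_rng(seed)
    direction = np.array([truth.gene_directions.get(g, 0) for g in truth.genes])
    fc = c * direction.astype(float) + rng.normal(0.0, noise_sd, size=len(truth.genes))
    disease_id = disease_id or f"synthetic_{category}_c{c:+d}"
    truth.disease_coefficients[disease_id] = {
        "category": category, "c": int(c), "noise_sd": float(noise_sd),
    }
    return DiseaseSignature(
        disease_id=disease_id,
        category=category,
        foldchanges=pd.Series(fc, index=truth.genes),
    )


# ---------------------------------------------------------------------------
# SNP catalogs
# ---------------------------------------------------------------------------

def _pick_alleles(rng: np.random.Generator) -> tuple[str, str]:
    a, b = rng.choice(4, size=2, replace=False)
    return str(_ALLELES[a]), str(_ALLELES[b])


def generate_snp_catalog(
    n_loci: int = 30,
    max_snps_per_locus: int = 5,
    n_shared_loci: int = 12,
    antagonistic_fraction: float = 0.9,
    pool_size: int = 500,
    n_background_shared: int = 20,
    background_antagonistic_fraction: float = 0.2,
    seed: int | None = None,
) -> tuple[SnpCatalog, LdTable, SimulationTruth]:
    """Risk-SNP catalog with planted cancer/degenerative sharing.

    The first ``n_shared_loci`` loci each carry exactly one shared risk
    SNP between a cancer trait and a degenerative-disease trait, either
    as an identical rsID or as an LD pair (r² >= 0.9 with a valid phase
    map); ``round(antagonistic_fraction * n_shared_loci)`` of them are
    made antagonistic (deterministic count, so the planted fraction is
    recovered exactly).  Remaining loci hold unshared category SNPs in
    LD blocks.  A non-ageing pool of ``pool_size`` SNPs includes
    ``n_background_shared`` SNPs shared with the disease categories at a
    background antagonistic fraction, providing the null rate for the
    binomial bias test and material for the resampling null.
    Loci are separated by more than 5 Mb, so they stay independent under
    the default locus-clustering parameters.
    """
    if not 0.0 <= antagonistic_fraction <= 1.0:
        raise ValueError("antagonistic_fraction must lie in [0, 1]")
    if n_shared_loci > n_loci:
        raise ValueError("n_shared_loci cannot exceed n_loci")
    rng = np.random.default_rng(seed)
    records: list[SnpRecord] = []
    ld = LdTable()
    truth = SimulationTruth(
        seed=seed,
        n_shared_loci=n_shared_loci,
        antagonistic_fraction=antagonistic_fraction,
    )
    degen_cats = list(DEGENERATIVE_TRAITS)
    next_rs = iter(range(100_000, 10_000_000))

    def locus_position(i: int) -> tuple[str, int]:
        chrom = str(i % 22 + 1)
        pos = 10_000_000 + (i // 22) * 20_000_000 + int(rng.integers(0, 100_000))
        return chrom, pos

    n_ant = round(antagonistic_fraction * n_shared_loci)
    shared_labels = ["antagonistic"] * n_ant + ["synergistic"] * (n_shared_loci - n_ant)
    rng.shuffle(shared_labels)

    for i in range(n_shared_loci):
        chrom, pos = locus_position(i)
        label = shared_labels[i]
        cancer_trait = CANCER_TRAITS[i % len(CANCER_TRAITS)]
        cat = degen_cats[i % len(degen_cats)]
        degen_trait = DEGENERATIVE_TRAITS[cat][i % len(DEGENERATIVE_TRAITS[cat])]
        risk1, alt1 = _pick_alleles(rng)
        rs1 = f"rs{next(next_rs)}"
        records.append(SnpRecord(rs1, chrom, pos, cancer_trait, risk1, alt1))
        identical_mode = bool(rng.integers(0, 2))
        if identical_mode:
            rs2 = rs1
            if label == "synergistic":
                risk2, alt2 = risk1, alt1
            else:
                risk2, alt2 = alt1, risk1
            records.append(SnpRecord(rs2, chrom, pos, degen_trait, risk2, alt2))
        else:
            rs2 = f"rs{next(next_rs)}"
            a2, b2 = _pick_alleles(rng)  # phase: risk1→a2, alt1→b2
            if label == "synergistic":
                risk2, alt2 = a2, b2
            else:
                risk2, alt2 = b2, a2
            records.append(
                SnpRecord(rs2, chrom, pos + 5_000, degen_trait, risk2, alt2)
            )
            ld.add(
                LdPair(
                    rsid_a=rs1, rsid_b=rs2,
                    r2=float(rng.uniform(0.9, 1.0)),
                    phase=((risk1, a2), (alt1, b2)),
                )
            )
        truth.snp_pair_labels.append([rs1, rs2, label])

    all_cats = ["cancer"] + degen_cats
    for i in range(n_shared_loci, n_loci):
        chrom, pos = locus_position(i)
        cat = all_cats[int(rng.integers(0, len(all_cats)))]
        traits = (
            CANCER_TRAITS if cat == "cancer" else DEGENERATIVE_TRAITS[cat]
        )
        k = int(rng.integers(1, max_snps_per_locus + 1))
        block: list[tuple[str, str, str]] = []  # (rsid, risk, alt)
        for j in range(k):
            risk, alt = _pick_alleles(rng)
            rs = f"rs{next(next_rs)}"
            records.append(
                SnpRecord(
                    rs, chrom, pos + 5_000 * j,
                    traits[int(rng.integers(0, len(traits)))], risk, alt,
                )
            )
            for prev_rs, prev_risk, prev_alt in block:
                ld.add(
                    LdPair(
                        rsid_a=prev_rs, rsid_b=rs,
                        r2=float(rng.uniform(0.9, 1.0)),
                        phase=((prev_risk, risk), (prev_alt, alt)),
                    )
                )
            block.append((rs, risk, alt))

    # background sharing between disease categories and the pool
    n_bg_ant = round(background_antagonistic_fraction * n_background_shared)
    bg_labels = ["antagonistic"] * n_bg_ant + ["synergistic"] * (
        n_background_shared - n_bg_ant
    )
    rng.shuffle(bg_labels)
    pool_count = 0
    for i, label in enumerate(bg_labels):
        chrom, pos = locus_position(n_loci + i)
        cat = all_cats[i % len(all_cats)]
        traits = CANCER_TRAITS if cat == "cancer" else DEGENERATIVE_TRAITS[cat]
        risk, alt = _pick_alleles(rng)
        rs = f"rs{next(next_rs)}"
        records.append(
            SnpRecord(rs, chrom, pos, traits[i % len(traits)], risk, alt)
        )
        pool_trait = POOL_TRAITS[i % len(POOL_TRAITS)]
        if label == "synergistic":
            records.append(SnpRecord(rs, chrom, pos, pool_trait, risk, alt))
        else:
            records.append(SnpRecord(rs, chrom, pos, pool_trait, alt, risk))
        pool_count += 1

    i = 0
    while pool_count < pool_size:
        chrom, pos = locus_position(n_loci + n_background_shared + i)
        risk, alt = _pick_alleles(rng)
        rs = f"rs{next(next_rs)}"
        records.append(
            SnpRecord(
                rs, chrom, pos, POOL_TRAITS[int(rng.integers(0, len(POOL_TRAITS)))],
                risk, alt,
            )
        )
        pool_count += 1
        i += 1

    return SnpCatalog(records=records), ld, truth
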