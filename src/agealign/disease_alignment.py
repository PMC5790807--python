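"""Ageing-mediated disease alignment (AMDA), contribution scores (DAC)
and the classical MDS embedding of condition foldchange vectors.

The AMDA score compares a disease's normalized case-vs-control
foldchanges between ageing-induced (U) and ageing-repressed (R) genes:

    AMDA = mean{ f~_g : g in U } - mean{ f~_g : g in R },

where f~ are the disease foldchanges rank-normalized to [-1, +1].  A
positive score means ageing shifts the transcriptome toward the disease
signature (disease alignment), a negative one away from it (reversion).
By construction the score is bounded by [-2, +2].

The DAC score of a process measures how much its genes contribute to
that alignment: the shift in AMDA when the process's genes are removed,
summed over all (ageing, disease) comparisons of a disease category,
divided by the number of comparisons and scaled to an absolute maximum
of 1 within the category.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.stats import rankdata

from .ageing_signature import bh_adjust
from .io_formats import DiseaseSignature, GeneSetCollection

logger = logging.getLogger("agealign")


@dataclass(frozen=True)
class GeneLevelSignature:
    """Induced/repressed gene sets of one ageing data set."""

    dataset_id: str
    induced: frozenset[str]
    repressed: frozenset[str]

    def __post_init__(self) -> None:
        overlap = self.induced & self.repressed
        if overlap:
            # genes claimed by both directions carry no usable sign
            logger.info(
                "%s: dropping %d genes present in both induced and repressed sets",
                self.dataset_id,
                len(overlap),
            )
            object.__setattr__(self, "induced", self.induced - overlap)
            object.__setattr__(self, "repressed", self.repressed - overlap)


# ---------------------------------------------------------------------------
# Disease foldchange normalization
# ---------------------------------------------------------------------------

def normalize_disease_foldchanges(sig: DiseaseSignature) -> DiseaseSignature:
    """Rank-normalize raw foldchanges onto [-1, +1].

    norm_g = 2 * (rank_g - 1) / (N - 1) - 1, with average ranks for
    ties; a signature whose foldchanges are all identical normalizes to
    all zeros with a warning.
    """
    fc = sig.foldchanges.to_numpy(dtype=float)
    n = len(fc)
    if n < 2:
        raise ValueError("normalization needs at least 2 genes")
    if np.all(fc == fc[0]):
        logger.warning(
            "%s: all foldchanges identical; normalized signature is all zeros",
            sig.disease_id,
        )
        norm = np.zeros(n)
    else:
        ranks = rankdata(fc)
        norm = 2.0 * (ranks - 1.0) / (n - 1.0) - 1.0
    return replace(sig, normalized=pd.Series(norm, index=sig.foldchanges.index))


def _side_values(
    genes: frozenset[str],
    disease: DiseaseSignature,
    exclude: frozenset[str],
) -> np.ndarray:
    if disease.normalized is None:
        raise ValueError(
            f"{disease.disease_id}: normalize_disease_foldchanges must run first"
        )
    idx = disease.normalized.index.intersection(genes - exclude)
    return disease.normalized[idx].to_numpy(dtype=float)


def _exclusion_set(exclude: Iterable | None) -> frozenset[str]:
    """Flatten an optional list of gene sets / gene iterables."""
    if exclude is None:
        return frozenset()
    out: set[str] = set()
    for item in exclude if not isinstance(exclude, (str, GeneSetCollection)) else [exclude]:
        if isinstance(item, GeneSetCollection):
            for genes in item.sets.values():
                out |= genes
        elif isinstance(item, str):
            out.add(item)
        else:
            out |= set(item)
    return frozenset(out)


# ---------------------------------------------------------------------------
# AMDA
# ---------------------------------------------------------------------------

def amda_score(
    ageing: GeneLevelSignature,
    disease: DiseaseSignature,
    exclude: Iterable | None = None,
) -> float:
    """Difference of mean normalized disease foldchanges, U minus R.

    Restricted to genes measured in the disease set and not excluded;
    returns NaN (flagged in the log) when either side has no genes
    left.  The optional exclusion list supports sensitivity analyses
    that drop e.g. senescence or proliferation gene sets.
    """
    excl = _exclusion_set(exclude)
    u_vals = _side_values(ageing.induced, disease, excl)
    r_vals = _side_values(ageing.repressed, disease, excl)
    if len(u_vals) == 0 or len(r_vals) == 0:
        logger.warning(
            "AMDA undefined for (%s, %s): empty induced or repressed intersection",
            ageing.dataset_id,
            disease.disease_id,
        )
        return float("nan")
    return float(u_vals.mean() - r_vals.mean())


def _ranksum_p(u_vals: np.ndarray, r_vals: np.ndarray) -> float:
    """Two-sided rank-sum p; exact for small tie-free sides, else asymptotic."""
    small = max(len(u_vals), len(r_vals)) <= 25
    no_ties = len(np.unique(np.concatenate([u_vals, r_vals]))) == len(u_vals) + len(
        r_vals
    )
    method = "exact" if (small and no_ties) else "asymptotic"
    return float(
        stats.mannwhitneyu(
            u_vals, r_vals, alternative="two-sided", method=method
        ).pvalue
    )


@dataclass
class AmdaResult:
    ageing_id: str
    disease_id: str
    score: float
    p: float
    fdr: float = np.nan
    significant: bool = False

    def __post_init__(self) -> None:
        if np.isfinite(self.score) and abs(self.score) > 2 + 1e-12:
            raise ValueError("AMDA scores lie in [-2, +2] by construction")


def amda_significance(
    ageing_sets: Sequence[GeneLevelSignature],
    diseases: Sequence[DiseaseSignature],
    exclude: Iterable | None = None,
    fdr_alpha: float = 0.05,
) -> pd.DataFrame:
    """AMDA scores and Wilcoxon rank-sum significance for all pairs.

    Two-sided rank-sum test of the U-gene vs R-gene normalized
    foldchanges; BH-FDR across every (ageing, disease) pair tested
    together.  Pairs with fewer than two genes on either side get an
    undefined (NaN) p and never count as significant.
    """
    excl = _exclusion_set(exclude)
    rows = []
    for ageing in ageing_sets:
        for disease in diseases:
            u_vals = _side_values(ageing.induced, disease, excl)
            r_vals = _side_values(ageing.repressed, disease, excl)
            if len(u_vals) == 0 or len(r_vals) == 0:
                score, p = np.nan, np.nan
            else:
                score = float(u_vals.mean() - r_vals.mean())
                if len(u_vals) < 2 or len(r_vals) < 2:
                    logger.warning(
                        "AMDA p undefined for (%s, %s): side smaller than 2",
                        ageing.dataset_id,
                        disease.disease_id,
                    )
                    p = np.nan
                else:
                    p = _ranksum_p(u_vals, r_vals)
            rows.append(
                {
                    "ageing_id": ageing.dataset_id,
                    "disease_id": disease.disease_id,
                    "category": disease.category,
                    "score": score,
                    "p": p,
                }
            )
    table = pd.DataFrame(rows)
    table["fdr"] = bh_adjust(table["p"].to_numpy())
    table["significant"] = table["fdr"] < fdr_alpha
    table.loc[table["fdr"].isna(), "significant"] = False
    return table


def amda_randomization(
    ageing_sets: Sequence[GeneLevelSignature],
    diseases: Sequence[DiseaseSignature],
    n_reps: int = 100,
    seed: int | None = None,
    fdr_alpha: float = 0.05,
    exclude: Iterable | None = None,
) -> np.ndarray:
    """Null distribution of significant-alignment counts.

    Each replicate randomly reassigns the induced/repressed labels over
    U ∪ R (preserving set sizes) in every ageing set, then recomputes
    all AMDA tests; returns the per-replicate count of significant
    alignments.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    rng = np.random.default_rng(seed)
    counts = np.empty(n_reps, dtype=int)
    for i in range(n_reps):
        swapped = []
        for ageing in ageing_sets:
            pool = np.array(sorted(ageing.induced | ageing.repressed))
            rng.shuffle(pool)
            k = len(ageing.induced)
            swapped.append(
                GeneLevelSignature(
                    dataset_id=ageing.dataset_id,
                    induced=frozenset(pool[:k]),
                    repressed=frozenset(pool[k:]),
                )
            )
        table = amda_significance(
            swapped, diseases, exclude=exclude, fdr_alpha=fdr_alpha
        )
        counts[i] = int(table["significant"].sum())
    return counts


# ---------------------------------------------------------------------------
# DAC
# ---------------------------------------------------------------------------

@dataclass
class DacTable:
    """Process × disease-category DAC scores, crude and normalized."""

    crude: pd.DataFrame
    normalized: pd.DataFrame

    def __post_init__(self) -> None:
        with np.errstate(invalid="ignore"):
            if np.nanmax(np.abs(self.normalized.to_numpy()), initial=0.0) > 1 + 1e-12:
                raise ValueError("normalized DAC scores lie in [-1, +1]")


def dac_scores(
    processes: GeneSetCollection,
    ageing_sets: Sequence[GeneLevelSignature],
    diseases: Sequence[DiseaseSignature],
    scale: str = "category",
) -> DacTable:
    """Disease alignment contribution of each process, per category.

    crude(p, C) = sum over comparisons (a, d), d in C, of
    AMDA(a, d) - AMDA(a, d | genes of p removed); normalization divides
    by the number of comparisons and scales to an absolute maximum of 1
    (within each category by default, globally with ``scale='global'``).
    A comparison whose U or R side empties after removal is skipped for
    that process (logged).
    """
    if scale not in ("category", "global"):
        raise ValueError("scale must be 'category' or 'global'")
    categories = sorted({d.category for d in diseases})
    crude = pd.DataFrame(0.0, index=list(processes.sets), columns=categories)
    n_pairs = pd.DataFrame(0, index=list(processes.sets), columns=categories)
    base: dict[tuple[str, str], float] = {}
    for ageing in ageing_sets:
        for disease in diseases:
            base[(ageing.dataset_id, disease.disease_id)] = amda_score(ageing, disease)
    for pid, genes in processes.sets.items():
        for ageing in ageing_sets:
            for disease in diseases:
                full = base[(ageing.dataset_id, disease.disease_id)]
                if np.isnan(full):
                    continue
                if not (genes & (ageing.induced | ageing.repressed)):
                    reduced = full  # removal is a no-op
                else:
                    reduced = amda_score(ageing, disease, exclude=genes)
                if np.isnan(reduced):
                    logger.info(
                        "DAC: removing %s empties a side for (%s, %s); pair skipped",
                        pid,
                        ageing.dataset_id,
                        disease.disease_id,
                    )
                    continue
                crude.loc[pid, disease.category] += full - reduced
                n_pairs.loc[pid, disease.category] += 1
    with np.errstate(divide="ignore", invalid="ignore"):
        normalized = crude / n_pairs.replace(0, np.nan)
    normalized = normalized.fillna(0.0)
    if scale == "category":
        for cat in categories:
            peak = normalized[cat].abs().max()
            if peak > 0:
                normalized[cat] = normalized[cat] / peak
    else:
        peak = normalized.abs().to_numpy().max()
        if peak > 0:
            normalized = normalized / peak
    return DacTable(crude=crude, normalized=normalized)


# ---------------------------------------------------------------------------
# Classical MDS
# ---------------------------------------------------------------------------

def mds_embedding(
    conditions: pd.DataFrame, k: int = 2
) -> tuple[pd.DataFrame, np.ndarray]:
    """Classical (Torgerson) MDS of condition foldchange vectors.

    ``conditions`` holds one column per condition (disease or ageing
    data set) over a shared feature space; distances are Euclidean over
    pairwise-complete features, rescaled to the full feature count.
    Returns coordinates (conditions × axes) and the variance explained
    per axis (eigenvalue over the sum of positive eigenvalues).
    """
    if conditions.shape[1] < 3:
        raise ValueError("MDS needs at least 3 conditions")
    X = conditions.to_numpy(dtype=float).T  # conditions × features
    n, f = X.shape
    valid = ~np.isnan(X)
    d2 = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            both = valid[i] & valid[j]
            if not both.any():
                raise ValueError(
                    f"conditions {conditions.columns[i]!r} and "
                    f"{conditions.columns[j]!r} share no complete features"
                )
            diff = X[i, both] - X[j, both]
            d2[i, j] = d2[j, i] = (diff @ diff) * (f / both.sum())
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ d2 @ J
    eigvals, eigvecs = np.linalg.eigh((B + B.T) / 2)
    order = np.argsort(eigvals)[::-1]
    eigvals, eigvecs = eigvals[order], eigvecs[:, order]
    positive = eigvals > max(eigvals.max(), 0) * 1e-12
    n_pos = int(positive.sum())
    if n_pos < k:
        logger.warning(
            "MDS: only %d positive eigenvalues available (requested %d axes)",
            n_pos,
            k,
        )
        k = max(n_pos, 0)
    coords = eigvecs[:, :k] * np.sqrt(eigvals[:k])
    var_explained = (
        eigvals[:k] / eigvals[positive].sum() if n_pos else np.zeros(0)
    )
    out = pd.DataFrame(
        coords,
        index=conditions.columns,
        columns=[f"axis_{i + 1}" for i in range(k)],
    )
    return out, np.asarray(var_explained)
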