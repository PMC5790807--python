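"""Map gene expression onto process-activity matrices.

The activity of a process in a sample is the sum of the expression
values of its member genes (equivalent to the mean after the
normalisation cascade below).  Activities are made comparable across
samples by (1) quantile normalisation over all samples jointly and
(2) rank normalisation within each species × tissue stratum, with ranks
scaled to [0, 1].
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .io_formats import ExpressionStudy, GeneSetCollection

logger = logging.getLogger("agealign")

NORMALIZATION_STATES = ("raw", "quantile", "rank_scaled")


@dataclass
class ProcessActivityMatrix:
    """Process × sample activities with an explicit normalisation state.

    State transitions only raw → quantile → rank_scaled.
    """

    values: pd.DataFrame  # processes × samples
    ontology: str
    state: str
    strata: pd.Series  # sample → species/tissue stratum key

    def __post_init__(self) -> None:
        if self.state not in NORMALIZATION_STATES:
            raise ValueError(f"unknown normalisation state {self.state!r}")
        if set(self.values.columns) != set(self.strata.index):
            raise ValueError("stratum keys must cover exactly the sample set")
        self.strata = self.strata.loc[self.values.columns]


def filter_gene_sets_min_genes(
    sets: GeneSetCollection,
    studies: ExpressionStudy | Mapping[str, ExpressionStudy],
    min_genes: int = 5,
) -> GeneSetCollection:
    """Keep processes with >= ``min_genes`` measured genes in every
    species × tissue stratum.

    ``studies`` may be a single (possibly multi-species) study or a
    mapping species → study; studies must already be gene-filtered so
    that "measured" equals row membership.
    """
    if isinstance(studies, ExpressionStudy):
        studies = {"__all__": studies}
    # within one study the measured genes are identical for every species x
    # tissue stratum (one shared row space), so one set per study suffices
    # for the per-stratum requirement
    measured = [frozenset(study.values.index) for study in studies.values()]
    keep = [
        pid
        for pid, genes in sets.sets.items()
        if all(len(genes & m) >= min_genes for m in measured)
    ]
    if not keep:
        raise ValueError(
            f"no process retains {min_genes} measured genes in every stratum"
        )
    dropped = len(sets) - len(keep)
    if dropped:
        logger.info("filter_gene_sets_min_genes: removed %d processes", dropped)
    return sets.subset(keep)


def compute_process_activity(
    study: ExpressionStudy, sets: GeneSetCollection
) -> ProcessActivityMatrix:
    """Sum expression of each process's measured genes, per sample."""
    gene_index = study.values.index
    rows = {}
    for pid, genes in sets.sets.items():
        members = gene_index.intersection(genes)
        if len(members) == 0:
            raise ValueError(
                f"process {pid!r} has no measured genes; filter gene sets first"
            )
        rows[pid] = study.values.loc[members].sum(axis=0)
    values = pd.DataFrame(rows).T
    values.index.name = "process"
    return ProcessActivityMatrix(
        values=values, ontology=sets.name, state="raw", strata=study.strata()
    )


def quantile_normalize(values: pd.DataFrame) -> pd.DataFrame:
    """Quantile normalisation over all samples jointly.

    Each sample's sorted values are replaced by the across-sample mean of
    sorted values; ties within a sample are broken by input order
    (stable sort), which makes the result deterministic.
    """
    arr = values.to_numpy(dtype=float)
    order = np.argsort(arr, axis=0, kind="stable")
    sorted_vals = np.take_along_axis(arr, order, axis=0)
    mean_quantiles = sorted_vals.mean(axis=1)
    out = np.empty_like(arr)
    np.put_along_axis(out, order, mean_quantiles[:, None], axis=0)
    return pd.DataFrame(out, index=values.index, columns=values.columns)


def rank_scale_strata(values: pd.DataFrame, strata: pd.Series) -> pd.DataFrame:
    """Within each stratum, replace each process's values by
    (rank − 1)/(n − 1) with average ranks for ties."""
    out = np.empty(values.shape)
    cols = values.columns
    for stratum in strata.unique():
        mask = (strata.loc[cols] == stratum).to_numpy()
        n = int(mask.sum())
        if n < 2:
            raise ValueError(
                f"stratum {stratum!r} has a single sample; rank scaling undefined"
            )
        block = values.loc[:, mask].to_numpy(dtype=float)
        ranks = rankdata(block, axis=1)  # average ranks for ties
        out[:, mask] = (ranks - 1.0) / (n - 1.0)
    return pd.DataFrame(out, index=values.index, columns=cols)


def normalize_activities(m: ProcessActivityMatrix) -> ProcessActivityMatrix:
    """Run the full cascade raw → quantile → rank_scaled."""
    if m.state != "raw":
        raise ValueError(f"normalisation expects state 'raw', got {m.state!r}")
    quantiled = quantile_normalize(m.values)
    scaled = rank_scale_strata(quantiled, m.strata)
    return replace(m, values=scaled, state="rank_scaled")
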