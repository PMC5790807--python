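"""Detection of significantly ageing-regulated processes and genes.

The core procedure, per process:

1. assumption filter — Shapiro–Wilk normality of the full-model
   residuals and Levene homogeneity over design cells, both at
   p <= 0.005; failing processes are not considered further;
2. unbalanced type-II ANOVA on rank-scaled activity with categorical
   factors age group, species and tissue, all interactions up to
   three-way, followed by marginality-respecting backward selection at
   p > 0.05 (highest-order terms first, never removing a term contained
   in a retained higher-order term, stopping if the age-group main
   effect would be removed);
3. Benjamini–Hochberg FDR across processes; a process enters the ageing
   signature if its adjusted age p-value passes and its direction of
   regulation is consistent in at least one fish and one mammal species.

The type-II machinery is implemented directly on orthonormal column
bases of the candidate model matrices so that hundreds of processes and
permutation replicates can share the cached design decompositions; it is
cross-checked against ``statsmodels`` in the test suite.

Gene-level contrasts (ageing-induced and -repressed gene sets), the
age-label permutation null and per-individual lifespan correlations live
here as well.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.linalg import orth
from statsmodels.stats.multitest import multipletests

from .io_formats import AGE_ORDER, OLD_GROUPS, ExpressionStudy
from .process_activity import ProcessActivityMatrix

logger = logging.getLogger("agealign")

Term = tuple[str, ...]

#: Default split of the study species into fish and mammals, used by the
#: cross-clade conservation rule.
DEFAULT_SPECIES_CLASS = {
    "zebrafish": "fish",
    "killifish": "fish",
    "mouse": "mammal",
    "human": "mammal",
}

DEFAULT_AGE_GROUPS = ("young", "old_1", "old_2")


def bh_adjust(pvals: np.ndarray | Sequence[float]) -> np.ndarray:
    """Benjamini–Hochberg adjusted p-values (NaN entries stay NaN)."""
    p = np.asarray(pvals, dtype=float)
    out = np.full_like(p, np.nan)
    ok = ~np.isnan(p)
    if ok.any():
        out[ok] = multipletests(p[ok], method="fdr_bh")[1]
    return out


# ---------------------------------------------------------------------------
# Factorial design with type-II sums of squares
# ---------------------------------------------------------------------------

def model_terms(factors: Sequence[str], max_order: int = 3) -> list[Term]:
    """All main effects and interactions up to ``max_order``."""
    terms: list[Term] = []
    for order in range(1, min(len(factors), max_order) + 1):
        terms.extend(tuple(c) for c in combinations(factors, order))
    return terms


def term_name(term: Term) -> str:
    return ":".join(term)


class AnovaDesign:
    """A fixed-factor factorial design shared by many response vectors.

    Column bases for every candidate model are orthonormalised once and
    cached, so residual sums of squares for any response reduce to one
    matrix product.  Factors with a single observed level are dropped
    (they carry no information); interactions that add no estimable
    degrees of freedom (empty cells) are pruned with a logged note.
    """

    def __init__(
        self,
        meta: pd.DataFrame,
        factors: Sequence[str] = ("age_group", "species", "tissue"),
        max_order: int = 3,
    ):
        present = []
        for f in factors:
            if f not in meta.columns:
                raise ValueError(f"metadata lacks factor column {f!r}")
            if meta[f].nunique() > 1:
                present.append(f)
            else:
                logger.info("AnovaDesign: dropping single-level factor %r", f)
        if not present:
            raise ValueError("no factor with at least two levels")
        self.meta = meta
        self.factors = tuple(present)
        self.n = len(meta)
        self._labels = {f: meta[f].astype(str).to_numpy() for f in self.factors}
        self._blocks: dict[Term, np.ndarray] = {}
        self._bases: dict[frozenset[Term], np.ndarray] = {}
        self.terms = self._prune_inestimable(model_terms(self.factors, max_order))
        cell = meta[list(self.factors)].astype(str).agg("\x1f".join, axis=1)
        self.cells = cell.to_numpy()

    # -- design matrices ----------------------------------------------------

    def _block(self, term: Term) -> np.ndarray:
        if term not in self._blocks:
            combined = self._labels[term[0]]
            for f in term[1:]:
                combined = np.char.add(np.char.add(combined, "\x1f"), self._labels[f])
            codes, uniques = pd.factorize(combined)
            block = np.zeros((self.n, len(uniques)))
            block[np.arange(self.n), codes] = 1.0
            self._blocks[term] = block
        return self._blocks[term]

    def basis(self, terms: frozenset[Term]) -> np.ndarray:
        """Orthonormal basis of the model column space (with intercept)."""
        if terms not in self._bases:
            cols = [np.ones((self.n, 1))]
            cols.extend(self._block(t) for t in sorted(terms))
            self._bases[terms] = orth(np.hstack(cols))
        return self._bases[terms]

    def rank(self, terms: frozenset[Term]) -> int:
        return self.basis(terms).shape[1]

    def rss(self, y: np.ndarray, terms: frozenset[Term]) -> np.ndarray:
        """Residual sum of squares; ``y`` may be (n,) or (n, m)."""
        q = self.basis(terms)
        total = np.sum(np.square(y), axis=0)
        fitted = np.sum(np.square(q.T @ y), axis=0)
        return np.maximum(total - fitted, 0.0)

    def _prune_inestimable(self, terms: list[Term]) -> list[Term]:
        # a term is inestimable when it adds no degrees of freedom in the
        # type-II comparison (against all terms not containing it)
        kept = list(terms)
        for term in sorted(terms, key=len, reverse=True):
            base = frozenset(t for t in kept if not set(term) <= set(t))
            if self.rank(base | {term}) == self.rank(base):
                kept.remove(term)
                logger.info(
                    "AnovaDesign: dropping inestimable term %s (empty cells)",
                    term_name(term),
                )
        return kept

    # -- type-II ANOVA ------------------------------------------------------

    def type2_table(
        self, Y: np.ndarray, model: frozenset[Term]
    ) -> tuple[pd.DataFrame, np.ndarray, int]:
        """Type-II F tests for every term of ``model``.

        For term T the comparison is between the model of all terms not
        containing T, with and without T; the error term is the full
        ``model``'s residual mean square.  ``Y`` may be (n,) or (n, m);
        returns a long-format table plus the model RSS and residual df.
        """
        Y = np.asarray(Y, dtype=float)
        Y2 = Y if Y.ndim == 2 else Y[:, None]
        rss_full = self.rss(Y2, model)
        df_resid = self.n - self.rank(model)
        rows = []
        for term in sorted(model):
            base = frozenset(t for t in model if not set(term) <= set(t))
            with_t = base | {term}
            df_t = self.rank(with_t) - self.rank(base)
            ss = self.rss(Y2, base) - self.rss(Y2, with_t)
            if df_t == 0 or df_resid <= 0:
                fstat = np.full(Y2.shape[1], np.nan)
                pval = np.full(Y2.shape[1], np.nan)
            else:
                with np.errstate(divide="ignore", invalid="ignore"):
                    fstat = (ss / df_t) / (rss_full / df_resid)
                pval = stats.f.sf(fstat, df_t, df_resid)
            for j in range(Y2.shape[1]):
                rows.append(
                    {
                        "term": term_name(term),
                        "response": j,
                        "df": df_t,
                        "ss": ss[j],
                        "F": fstat[j],
                        "p": pval[j],
                    }
                )
        table = pd.DataFrame(rows)
        return table, rss_full, df_resid


# ---------------------------------------------------------------------------
# Assumption checks
# ---------------------------------------------------------------------------

@dataclass
class AssumptionCheck:
    passed: bool
    shapiro_p: float
    levene_p: float
    reason: str = ""


def check_model_assumptions(
    activity: np.ndarray | pd.Series, design: AnovaDesign, alpha: float = 0.005
) -> AssumptionCheck:
    """Shapiro–Wilk on full-model residuals and Levene over design cells.

    A process fails if either test yields p <= ``alpha``; degenerate
    responses (zero residual variance) fail with reason "degenerate".
    """
    y = np.asarray(activity, dtype=float)
    full = frozenset(design.terms)
    q = design.basis(full)
    resid = y - q @ (q.T @ y)
    if float(np.var(resid)) < 1e-24:
        return AssumptionCheck(False, np.nan, np.nan, reason="degenerate")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        sw_p = float(stats.shapiro(resid).pvalue)
    groups = [y[design.cells == c] for c in pd.unique(design.cells)]
    groups = [g for g in groups if len(g) >= 2]
    if len(groups) < 2:
        return AssumptionCheck(False, sw_p, np.nan, reason="too few cells")
    lev_p = float(stats.levene(*groups, center="median").pvalue)
    if sw_p <= alpha or lev_p <= alpha:
        return AssumptionCheck(False, sw_p, lev_p, reason="assumption violated")
    return AssumptionCheck(True, sw_p, lev_p)


# ---------------------------------------------------------------------------
# Backward selection
# ---------------------------------------------------------------------------

AGE_REMOVED = "age removed"


@dataclass
class AnovaFit:
    """Final state of one backward-selected model."""

    age_p: float | None  # None when the age main effect was removed
    model: frozenset[Term]
    age_removed: bool


def _removable(model: frozenset[Term]) -> list[Term]:
    """Terms not contained in any retained higher-order term."""
    return [t for t in model if not any(set(t) < set(s) for s in model)]


def backward_select_batch(
    Y: np.ndarray,
    design: AnovaDesign,
    reduce_alpha: float = 0.05,
    focus: str = "age_group",
) -> list[AnovaFit]:
    """Backward selection for many responses sharing one design.

    Each iteration removes, per response, the least significant
    removable term (largest p > ``reduce_alpha``; ties broken by higher
    order first, then lexicographic name).  Selection stops when nothing
    is removable or when the ``focus`` main effect itself would be
    removed (which yields the ``age removed`` sentinel).  Responses are
    grouped by their current model so the design decompositions and
    F tables are shared.
    """
    focus_term: Term = (focus,)
    if focus not in design.factors:
        raise ValueError(f"focus factor {focus!r} absent from the design")
    Y2 = Y if Y.ndim == 2 else Y[:, None]
    m = Y2.shape[1]
    results: list[AnovaFit | None] = [None] * m
    groups: dict[frozenset[Term], list[int]] = {frozenset(design.terms): list(range(m))}
    while groups:
        next_groups: dict[frozenset[Term], list[int]] = {}
        for model, idx in groups.items():
            table, _, _ = design.type2_table(Y2[:, idx], model)
            removable = _removable(model)
            # ordering key: larger p first, then higher order, then name
            pmat = {
                term_name(t): table[table["term"] == term_name(t)]
                .set_index("response")["p"]
                .to_numpy()
                for t in model
            }
            for local_j, j in enumerate(idx):
                best: tuple[float, int, str] | None = None
                best_term: Term | None = None
                for t in removable:
                    p = pmat[term_name(t)][local_j]
                    p = 1.0 if np.isnan(p) else float(p)
                    if p <= reduce_alpha:
                        continue
                    key = (p, len(t), _neg_name(t))
                    if best is None or key > best:
                        best, best_term = key, t
                if best_term is None:
                    p_age = pmat[term_name(focus_term)][local_j]
                    results[j] = AnovaFit(
                        age_p=float(p_age), model=model, age_removed=False
                    )
                elif best_term == focus_term:
                    results[j] = AnovaFit(age_p=None, model=model, age_removed=True)
                else:
                    new_model = frozenset(model - {best_term})
                    next_groups.setdefault(new_model, []).append(j)
        groups = {
            model: idx for model, idx in next_groups.items() if idx
        }
    return results  # type: ignore[return-value]


class _neg_name(str):
    """Reverse lexicographic comparison helper for tie-breaking."""

    def __new__(cls, term: Term):
        return super().__new__(cls, term_name(term))

    def __lt__(self, other):  # larger key wins, so invert
        return str(self) > str(other)

    def __gt__(self, other):
        return str(self) < str(other)


def fit_age_anova(
    activity: np.ndarray | pd.Series,
    design: AnovaDesign,
    reduce_alpha: float = 0.05,
) -> AnovaFit:
    """Backward-selected type-II ANOVA for a single response."""
    y = np.asarray(activity, dtype=float)
    return backward_select_batch(y[:, None], design, reduce_alpha=reduce_alpha)[0]


# ---------------------------------------------------------------------------
# Signature derivation
# ---------------------------------------------------------------------------

@dataclass
class AgeingSignature:
    """Process-level ageing signature plus optional gene-level sets."""

    table: pd.DataFrame  # per process: p, fdr, foldchange, direction, flags
    species_direction: pd.DataFrame  # process × species direction signs
    ontology: str = ""
    induced: frozenset[str] = field(default_factory=frozenset)
    repressed: frozenset[str] = field(default_factory=frozenset)

    @property
    def selected(self) -> list[str]:
        return list(self.table.index[self.table["selected"]])

    def __post_init__(self) -> None:
        if self.induced & self.repressed:
            raise ValueError("induced and repressed gene sets must be disjoint")


def derive_signature(
    pvals: pd.Series,
    foldchanges: pd.Series,
    species_direction: pd.DataFrame,
    species_class: Mapping[str, str] | None = None,
    fdr_alpha: float = 0.05,
    ontology: str = "",
) -> AgeingSignature:
    """Combine pooled p-values, foldchanges and per-species directions.

    A process is selected if its BH-adjusted pooled age p-value is
    <= ``fdr_alpha`` and its direction of regulation agrees with the
    pooled direction in at least one fish and at least one mammal
    species.  ``pvals`` may contain NaN for processes excluded upstream
    (assumption failures); those never enter the FDR family.
    """
    species_class = dict(species_class or DEFAULT_SPECIES_CLASS)
    missing = [s for s in species_direction.columns if s not in species_class]
    if missing:
        raise ValueError(f"species without fish/mammal class: {missing}")
    clades = set(species_class[s] for s in species_direction.columns)
    if clades != {"fish", "mammal"}:
        raise ValueError(
            "conservation rule needs at least one fish and one mammal species"
        )
    processes = pvals.index
    fdr = pd.Series(bh_adjust(pvals.to_numpy()), index=processes)
    direction = np.sign(foldchanges).astype(int)
    conserved = pd.Series(False, index=processes)
    for p in processes:
        d = direction[p]
        if d == 0:
            continue
        agree = species_direction.loc[p] == d
        fish_ok = any(
            agree[s] for s in species_direction.columns if species_class[s] == "fish"
        )
        mammal_ok = any(
            agree[s] for s in species_direction.columns if species_class[s] == "mammal"
        )
        conserved[p] = fish_ok and mammal_ok
    significant = fdr.le(fdr_alpha).fillna(False)
    table = pd.DataFrame(
        {
            "p": pvals,
            "fdr": fdr,
            "foldchange": foldchanges,
            "direction": np.where(direction > 0, "up", np.where(direction < 0, "down", "flat")),
            "significant": significant,
            "conserved": conserved,
            "selected": significant & conserved,
        }
    )
    table.index.name = "process"
    return AgeingSignature(
        table=table, species_direction=species_direction, ontology=ontology
    )


def activity_foldchange(
    activity: pd.DataFrame,
    meta: pd.DataFrame,
    young: str = "young",
    old: Sequence[str] = OLD_GROUPS,
) -> pd.Series:
    """Mean rank-scaled activity of old samples (both old groups pooled)
    minus mean of young samples, per process."""
    age = meta.loc[activity.columns, "age_group"]
    young_cols = activity.columns[age == young]
    old_cols = activity.columns[age.isin(old)]
    if len(young_cols) == 0 or len(old_cols) == 0:
        raise ValueError("foldchange needs both young and old samples")
    return activity[old_cols].mean(axis=1) - activity[young_cols].mean(axis=1)


def run_signature_analysis(
    activity: ProcessActivityMatrix,
    meta: pd.DataFrame,
    fdr_alpha: float = 0.05,
    assumption_alpha: float = 0.005,
    reduce_alpha: float = 0.05,
    age_groups: Sequence[str] = DEFAULT_AGE_GROUPS,
    species_class: Mapping[str, str] | None = None,
) -> AgeingSignature:
    """The full process-level pipeline on a rank-scaled activity matrix.

    Runs the assumption filter and the pooled three-factor analysis, the
    per-species stratified analyses (factors age group and tissue) for
    the direction consistency rule, BH-FDR, and the fish/mammal
    conservation rule.
    """
    if activity.state != "rank_scaled":
        raise ValueError("signature analysis expects a rank-scaled activity matrix")
    meta = meta.loc[activity.values.columns]
    keep = meta["age_group"].isin(age_groups)
    values = activity.values.loc[:, keep.to_numpy()]
    meta = meta.loc[keep]
    if meta["species"].nunique() < 2:
        raise ValueError("pooled analysis needs several species; "
                         "missing species stratification")
    processes = values.index
    Y = values.to_numpy(dtype=float).T  # samples × processes

    design = AnovaDesign(meta, factors=("age_group", "species", "tissue"))
    checks = [
        check_model_assumptions(Y[:, j], design, alpha=assumption_alpha)
        for j in range(Y.shape[1])
    ]
    passed = np.array([c.passed for c in checks])
    n_failed = int((~passed).sum())
    if n_failed:
        logger.info("assumption filter removed %d processes", n_failed)

    pvals = pd.Series(np.nan, index=processes)
    if passed.any():
        fits = backward_select_batch(
            Y[:, passed], design, reduce_alpha=reduce_alpha
        )
        sub = processes[passed]
        for pid, fit in zip(sub, fits):
            # the sentinel "age removed" means no age effect in the final
            # model; such processes stay in the FDR family with p = 1
            pvals[pid] = 1.0 if fit.age_removed else fit.age_p

    foldchanges = activity_foldchange(values, meta)

    species_dir = {}
    for sp, sp_meta in meta.groupby("species", observed=True):
        sp_values = values.loc[:, sp_meta.index]
        species_dir[sp] = np.sign(activity_foldchange(sp_values, sp_meta)).astype(int)
    species_direction = pd.DataFrame(species_dir)

    return derive_signature(
        pvals,
        foldchanges,
        species_direction,
        species_class=species_class,
        fdr_alpha=fdr_alpha,
        ontology=activity.ontology,
    )


# ---------------------------------------------------------------------------
# Age-label permutation null
# ---------------------------------------------------------------------------

def permute_age_labels(
    meta: pd.DataFrame, rng: np.random.Generator
) -> pd.DataFrame:
    """Permute age-group labels within each species × tissue stratum."""
    permuted = meta.copy()
    strata = meta["species"].astype(str) + "/" + meta["tissue"].astype(str)
    ages = permuted["age_group"].to_numpy().copy()
    for s in strata.unique():
        mask = (strata == s).to_numpy()
        ages[mask] = rng.permutation(ages[mask])
    permuted["age_group"] = ages
    return permuted


def age_label_permutation_null(
    activity: ProcessActivityMatrix,
    meta: pd.DataFrame,
    n_reps: int = 100,
    seed: int | None = None,
    **kwargs,
) -> np.ndarray:
    """Signature sizes under random within-stratum age-label reassignment.

    The activity normalisation does not depend on age labels, so each
    replicate reruns the signature analysis on permuted metadata only.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    rng = np.random.default_rng(seed)
    meta = meta.loc[activity.values.columns]
    sizes = np.empty(n_reps, dtype=int)
    for i in range(n_reps):
        permuted = permute_age_labels(meta, rng)
        sig = run_signature_analysis(activity, permuted, **kwargs)
        sizes[i] = len(sig.selected)
    return sizes


# ---------------------------------------------------------------------------
# Gene-level contrast
# ---------------------------------------------------------------------------

def differential_genes(
    study: ExpressionStudy,
    fdr_alpha: float = 0.05,
    young: str = "young",
    old: Sequence[str] = OLD_GROUPS,
) -> tuple[frozenset[str], frozenset[str], pd.DataFrame]:
    """Ageing-induced (U) and -repressed (R) genes: young vs pooled old.

    Two-sided rank-sum (Mann–Whitney) test per gene with BH-FDR;
    membership requires a non-zero median log-foldchange.  Genes with a
    constant value across all samples get p = 1 by convention.
    """
    age = study.meta["age_group"]
    young_cols = study.values.columns[age == young]
    old_cols = study.values.columns[age.isin(old)]
    if len(young_cols) < 3 or len(old_cols) < 3:
        raise ValueError("need at least 3 samples on each side of the contrast")
    a = study.values[old_cols].to_numpy(dtype=float)
    b = study.values[young_cols].to_numpy(dtype=float)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = stats.mannwhitneyu(a, b, axis=1, alternative="two-sided", method="auto")
    pvals = np.asarray(res.pvalue, dtype=float)
    constant = np.all(study.values.to_numpy() == study.values.to_numpy()[:, :1], axis=1)
    pvals[constant] = 1.0
    med_old = np.median(a, axis=1)
    med_young = np.median(b, axis=1)
    eps = 1e-12
    lfc = np.log2((med_old + eps) / (med_young + eps))
    fdr = bh_adjust(pvals)
    table = pd.DataFrame(
        {"p": pvals, "fdr": fdr, "median_log2_fc": lfc}, index=study.values.index
    )
    sig = table["fdr"] <= fdr_alpha
    induced = frozenset(table.index[sig & (table["median_log2_fc"] > 0)])
    repressed = frozenset(table.index[sig & (table["median_log2_fc"] < 0)])
    return induced, repressed, table


# ---------------------------------------------------------------------------
# Lifespan correlations
# ---------------------------------------------------------------------------

def individual_activity_change(
    activity: pd.DataFrame, meta: pd.DataFrame
) -> pd.DataFrame:
    """Later-minus-earlier activity per individual (two time points).

    Individuals are identified by ``individual_id``; sample order within
    an individual follows the age-group ordering (or a numeric
    ``time_point`` column when present).
    """
    if "individual_id" not in meta.columns:
        raise ValueError("longitudinal analysis requires individual_id metadata")
    order_key = (
        meta["time_point"]
        if "time_point" in meta.columns
        else meta["age_group"].map({g: i for i, g in enumerate(AGE_ORDER)})
    )
    changes = {}
    for ind, group in meta.groupby("individual_id"):
        if len(group) != 2:
            continue
        early, late = group.index[np.argsort(order_key.loc[group.index].to_numpy())]
        changes[ind] = activity[late] - activity[early]
    if not changes:
        raise ValueError("no individual with exactly two time points")
    out = pd.DataFrame(changes)
    out.index.name = "process"
    return out


def lifespan_correlation(
    activity_changes: pd.DataFrame, lifespans: pd.Series
) -> pd.DataFrame:
    """Pearson correlation of per-individual activity change vs lifespan.

    Returns one row per process with ``r`` and ``p``; processes (or
    cohorts) with zero variance are flagged with NaN.
    """
    common = activity_changes.columns.intersection(lifespans.index)
    if len(common) < 3:
        raise ValueError("need at least 3 individuals with both measurements")
    x = lifespans[common].to_numpy(dtype=float)
    rows = []
    degenerate_x = np.std(x) == 0
    for pid, row in activity_changes[common].iterrows():
        y = row.to_numpy(dtype=float)
        if degenerate_x or np.std(y) == 0:
            rows.append({"r": np.nan, "p": np.nan})
            continue
        r, p = stats.pearsonr(y, x)
        rows.append({"r": float(r), "p": float(p)})
    out = pd.DataFrame(rows, index=activity_changes.index)
    out.index.name = "process"
    return out
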