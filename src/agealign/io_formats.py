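"""Readers, writers and elementary preprocessing for the pipeline's inputs.

Four table families are handled here:

* gene × sample expression matrices (TSV) plus per-sample metadata
  (species, tissue, age group, individual, optional lifespan),
* gene-set ontologies in the GMT dialect,
* disease case-vs-control foldchange tables,
* GWAS-catalog-like risk-SNP tables and LD (linkage disequilibrium)
  tables carrying an explicit allele phase map.

All tabular I/O goes through :mod:`pandas`; the module adds the domain
containers and the validation the downstream statistics rely on.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

logger = logging.getLogger("agealign")

#: Recognised age-group labels, youngest to oldest.
AGE_ORDER = ("young", "mature_1", "mature_2", "old_1", "old_2")
#: Age groups pooled as "old" in foldchanges and gene-level contrasts.
OLD_GROUPS = ("old_1", "old_2")

VALID_ALLELES = frozenset("ACGT")

REQUIRED_META = ("species", "tissue", "age_group")


class FormatError(ValueError):
    """Raised when an input file violates its documented format."""


# ---------------------------------------------------------------------------
# Expression studies
# ---------------------------------------------------------------------------

@dataclass
class ExpressionStudy:
    """A gene × sample expression matrix with per-sample metadata.

    Parameters
    ----------
    values
        Non-negative expression values (raw counts or RPKM), genes as the
        row index, sample ids as columns.
    meta
        Per-sample metadata indexed by sample id.  Required columns:
        ``species``, ``tissue``, ``age_group``; optional: ``individual_id``,
        ``lifespan`` (days) and ``time_point`` for longitudinal designs.
    gene_lengths
        Optional per-gene transcript length in base pairs (needed to
        compute RPKM from counts).
    """

    values: pd.DataFrame
    meta: pd.DataFrame
    gene_lengths: pd.Series | None = None

    def __post_init__(self) -> None:
        if not self.values.index.is_unique:
            raise ValueError("gene ids must be unique")
        if not self.values.columns.equals(self.meta.index):
            # allow same set, different order
            if set(self.values.columns) != set(self.meta.index):
                raise ValueError("metadata does not cover the sample set")
            self.meta = self.meta.loc[self.values.columns]
        for col in REQUIRED_META:
            if col not in self.meta.columns:
                raise ValueError(f"metadata lacks required column {col!r}")
            if self.meta[col].isna().any():
                raise ValueError(f"metadata column {col!r} has missing entries")
        bad_age = set(self.meta["age_group"]) - set(AGE_ORDER)
        if bad_age:
            raise ValueError(f"unknown age groups: {sorted(bad_age)}")
        if (self.values.to_numpy() < 0).any():
            raise ValueError("expression values must be non-negative")

    @property
    def genes(self) -> list[str]:
        return list(self.values.index)

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)

    def strata(self) -> pd.Series:
        """Species × tissue stratum key per sample."""
        return self.meta["species"].astype(str) + "/" + self.meta["tissue"].astype(str)

    def lifespans(self) -> pd.Series:
        if "lifespan" not in self.meta.columns or self.meta["lifespan"].isna().all():
            raise ValueError(
                "this operation requires per-sample lifespan metadata, which is absent"
            )
        return self.meta["lifespan"]


def rpkm_from_counts(
    counts: pd.DataFrame,
    gene_lengths: pd.Series | Mapping[str, float],
    library_sizes: pd.Series | Mapping[str, float],
) -> pd.DataFrame:
    """Reads per kilobase of transcript per million mapped reads.

    ``rpkm[g, s] = counts[g, s] / ((length_g / 1e3) * (libsize_s / 1e6))``
    """
    lengths = pd.Series(gene_lengths).reindex(counts.index)
    libs = pd.Series(library_sizes).reindex(counts.columns)
    if lengths.isna().any():
        missing = list(counts.index[lengths.isna()])[:5]
        raise ValueError(f"missing gene lengths, e.g. {missing}")
    if libs.isna().any():
        raise ValueError("missing library sizes for some samples")
    if (lengths <= 0).any():
        raise ValueError("gene lengths must be positive")
    if (libs <= 0).any():
        raise ValueError("library sizes must be positive")
    denom = np.outer(lengths.to_numpy() / 1e3, libs.to_numpy() / 1e6)
    return pd.DataFrame(
        counts.to_numpy() / denom, index=counts.index, columns=counts.columns
    )


def filter_unexpressed_genes(study: ExpressionStudy) -> ExpressionStudy:
    """Drop genes with no detectable expression (value 0) in any sample.

    Applied per organism: a gene is retained only if it is positive in
    every sample of every species present in the study, so the surviving
    matrix is valid for each organism separately.  Gene order is preserved.
    """
    keep = (study.values > 0).all(axis=1)
    if not keep.any():
        logger.warning("filter_unexpressed_genes removed every gene")
    dropped = int((~keep).sum())
    if dropped:
        logger.info("filter_unexpressed_genes: removed %d genes", dropped)
    lengths = None
    if study.gene_lengths is not None:
        lengths = study.gene_lengths[study.values.index[keep]]
    return replace(study, values=study.values.loc[keep], gene_lengths=lengths)


def read_expression_study(
    expr_path: str | Path, meta_path: str | Path, lengths_path: str | Path | None = None
) -> ExpressionStudy:
    """Read an expression TSV (genes × samples) plus a metadata TSV."""
    values = pd.read_csv(expr_path, sep="\t", index_col=0)
    meta = pd.read_csv(meta_path, sep="\t", index_col=0)
    lengths = None
    if lengths_path is not None:
        lengths = pd.read_csv(lengths_path, sep="\t", index_col=0).iloc[:, 0]
    return ExpressionStudy(values=values, meta=meta, gene_lengths=lengths)


def write_expression_study(
    study: ExpressionStudy, expr_path: str | Path, meta_path: str | Path
) -> None:
    study.values.to_csv(expr_path, sep="\t")
    study.meta.to_csv(meta_path, sep="\t")


def parse_homolog_map(path: str | Path) -> dict[str, str]:
    """Read a two-column TSV of one-to-one homolog pairs (gene_a, gene_b).

    Ambiguous (many-to-many) mappings are dropped with a logged count.
    """
    table = pd.read_csv(path, sep="\t", header=0)
    if table.shape[1] < 2:
        raise FormatError("homolog map needs two columns")
    a, b = table.columns[:2]
    dup = table[a].duplicated(keep=False) | table[b].duplicated(keep=False)
    if dup.any():
        logger.info("parse_homolog_map: dropped %d ambiguous mappings", int(dup.sum()))
    table = table[~dup]
    return dict(zip(table[a], table[b]))


# ---------------------------------------------------------------------------
# Gene sets (GMT)
# ---------------------------------------------------------------------------

@dataclass
class GeneSetCollection:
    """A named ontology: process id → (label, gene ids)."""

    name: str
    sets: dict[str, frozenset[str]]
    labels: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for pid, genes in self.sets.items():
            if not genes:
                raise ValueError(f"gene set {pid!r} is empty")

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets)

    def subset(self, ids: Iterable[str]) -> "GeneSetCollection":
        ids = list(ids)
        return GeneSetCollection(
            name=self.name,
            sets={p: self.sets[p] for p in ids},
            labels={p: self.labels.get(p, p) for p in ids},
        )


def parse_gene_sets(path: str | Path, name: str | None = None) -> GeneSetCollection:
    """Parse a GMT file: tab-separated ``name<TAB>description<TAB>genes...``."""
    sets: dict[str, frozenset[str]] = {}
    labels: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(
                    f"{path}: line {lineno}: GMT lines need >= 3 tab-separated fields"
                )
            pid, desc, *genes = fields
            genes = [g for g in genes if g]
            sets[pid] = frozenset(genes)
            labels[pid] = desc
    return GeneSetCollection(name=name or Path(path).stem, sets=sets, labels=labels)


def write_gene_sets(collection: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w") as fh:
        for pid, genes in collection.sets.items():
            desc = collection.labels.get(pid, pid)
            fh.write("\t".join([pid, desc, *sorted(genes)]) + "\n")


# ---------------------------------------------------------------------------
# Disease signatures
# ---------------------------------------------------------------------------

DISEASE_CATEGORIES = ("cancer", "CVD", "NDD", "T2D", "other")


@dataclass
class DiseaseSignature:
    """Per-gene case-vs-control foldchanges for one disease data set.

    ``normalized`` is populated by
    :func:`agealign.disease_alignment.normalize_disease_foldchanges`
    and lies in [-1, +1].
    """

    disease_id: str
    category: str
    foldchanges: pd.Series
    normalized: pd.Series | None = None

    def __post_init__(self) -> None:
        if self.category not in DISEASE_CATEGORIES:
            raise ValueError(
                f"unknown disease category {self.category!r}; "
                f"expected one of {DISEASE_CATEGORIES}"
            )
        if not self.foldchanges.index.is_unique:
            raise ValueError("disease signature genes must be unique")
        if self.normalized is not None:
            vals = self.normalized.to_numpy(dtype=float)
            if np.nanmax(np.abs(vals)) > 1 + 1e-12:
                raise ValueError("normalized foldchanges must lie in [-1, +1]")


def read_disease_signature(
    path: str | Path, disease_id: str | None = None, category: str = "other"
) -> DiseaseSignature:
    """Read a two-column TSV ``gene<TAB>foldchange`` (header required)."""
    table = pd.read_csv(path, sep="\t", header=0)
    if table.shape[1] < 2:
        raise FormatError(f"{path}: disease signature needs gene and foldchange columns")
    fc = pd.Series(table.iloc[:, 1].to_numpy(dtype=float), index=table.iloc[:, 0])
    return DiseaseSignature(
        disease_id=disease_id or Path(path).stem, category=category, foldchanges=fc
    )


def write_disease_signature(sig: DiseaseSignature, path: str | Path) -> None:
    out = pd.DataFrame({"gene": sig.foldchanges.index, "foldchange": sig.foldchanges.to_numpy()})
    out.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# SNP catalogs and LD tables
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SnpRecord:
    rsid: str
    chromosome: str
    position: int  # 1-based
    trait: str
    risk_allele: str
    alt_allele: str

    def __post_init__(self) -> None:
        if self.risk_allele not in VALID_ALLELES or self.alt_allele not in VALID_ALLELES:
            raise ValueError(
                f"{self.rsid}: alleles must be one of A/C/G/T, "
                f"got {self.risk_allele}/{self.alt_allele}"
            )
        if self.risk_allele == self.alt_allele:
            raise ValueError(f"{self.rsid}: risk allele equals alternative allele")
        if self.position < 1:
            raise ValueError(f"{self.rsid}: positions are 1-based, got {self.position}")


@dataclass
class SnpCatalog:
    """Risk-SNP records; (rsID, trait) pairs are unique."""

    records: list[SnpRecord]

    def __post_init__(self) -> None:
        seen = set()
        for rec in self.records:
            key = (rec.rsid, rec.trait)
            if key in seen:
                raise ValueError(f"duplicate (rsID, trait) pair {key}")
            seen.add(key)

    def __len__(self) -> int:
        return len(self.records)

    def traits(self) -> set[str]:
        return {r.trait for r in self.records}


SNP_COLUMNS = ("rsid", "chromosome", "position", "trait", "risk_allele", "alt_allele")


def parse_snp_catalog(path: str | Path) -> SnpCatalog:
    table = pd.read_csv(path, sep="\t", header=0, dtype=str)
    missing = set(SNP_COLUMNS) - set(table.columns)
    if missing:
        raise FormatError(f"{path}: SNP catalog lacks columns {sorted(missing)}")
    records = [
        SnpRecord(
            rsid=row.rsid,
            chromosome=str(row.chromosome),
            position=int(row.position),
            trait=row.trait,
            risk_allele=row.risk_allele,
            alt_allele=row.alt_allele,
        )
        for row in table.itertuples(index=False)
    ]
    return SnpCatalog(records=records)


def write_snp_catalog(catalog: SnpCatalog, path: str | Path) -> None:
    rows = [
        (r.rsid, r.chromosome, r.position, r.trait, r.risk_allele, r.alt_allele)
        for r in catalog.records
    ]
    pd.DataFrame(rows, columns=list(SNP_COLUMNS)).to_csv(path, sep="\t", index=False)


@dataclass(frozen=True)
class LdPair:
    """One LD link with its haplotype phase.

    ``phase`` maps each allele of ``rsid_a`` to the allele of ``rsid_b``
    found on the same haplotype; it must be a bijection over the two
    alleles of each SNP.
    """

    rsid_a: str
    rsid_b: str
    r2: float
    phase: tuple[tuple[str, str], ...]  # ((a_allele, b_allele), ...)

    def __post_init__(self) -> None:
        if not 0.0 <= self.r2 <= 1.0:
            raise ValueError(f"r² must lie in [0, 1], got {self.r2}")
        a_side = [a for a, _ in self.phase]
        b_side = [b for _, b in self.phase]
        if len(self.phase) != 2 or len(set(a_side)) != 2 or len(set(b_side)) != 2:
            raise ValueError("phase map must be a bijection over two alleles per SNP")

    def phase_dict(self) -> dict[str, str]:
        return dict(self.phase)

    def inverse_phase_dict(self) -> dict[str, str]:
        return {b: a for a, b in self.phase}


class LdTable:
    """Symmetric lookup of LD pairs keyed by rsID pair."""

    def __init__(self, pairs: Iterable[LdPair] = ()):
        self._pairs: dict[frozenset[str], LdPair] = {}
        for p in pairs:
            self.add(p)

    def add(self, pair: LdPair) -> None:
        self._pairs[frozenset((pair.rsid_a, pair.rsid_b))] = pair

    def __len__(self) -> int:
        return len(self._pairs)

    def __iter__(self):
        return iter(self._pairs.values())

    def get(self, rs1: str, rs2: str) -> LdPair | None:
        """Return the pair oriented so that ``rsid_a == rs1`` (or None)."""
        pair = self._pairs.get(frozenset((rs1, rs2)))
        if pair is None:
            return None
        if pair.rsid_a == rs1:
            return pair
        return LdPair(
            rsid_a=rs1,
            rsid_b=pair.rsid_a,
            r2=pair.r2,
            phase=tuple(sorted((b, a) for a, b in pair.phase)),
        )

    def r2(self, rs1: str, rs2: str) -> float:
        """r² for a pair; absent pairs are treated as unlinked (0)."""
        pair = self._pairs.get(frozenset((rs1, rs2)))
        return 0.0 if pair is None else pair.r2

    def neighbours(self, rsid: str, r2_min: float = 0.0) -> list[LdPair]:
        out = []
        for key, pair in self._pairs.items():
            if rsid in key and pair.r2 >= r2_min:
                out.append(self.get(rsid, next(iter(key - {rsid}), rsid)))
        return out


LD_COLUMNS = ("rsid_a", "rsid_b", "r2", "phase")


def _format_phase(phase: tuple[tuple[str, str], ...]) -> str:
    return ",".join(f"{a}>{b}" for a, b in sorted(phase))


def _parse_phase(text: str) -> tuple[tuple[str, str], ...]:
    pairs = []
    for chunk in text.split(","):
        a, sep, b = chunk.partition(">")
        if not sep:
            raise FormatError(f"malformed phase entry {chunk!r}")
        pairs.append((a.strip(), b.strip()))
    return tuple(sorted(pairs))


def parse_ld_table(path: str | Path) -> LdTable:
    table = pd.read_csv(path, sep="\t", header=0, dtype=str)
    missing = set(LD_COLUMNS) - set(table.columns)
    if missing:
        raise FormatError(f"{path}: LD table lacks columns {sorted(missing)}")
    out = LdTable()
    for row in table.itertuples(index=False):
        out.add(
            LdPair(
                rsid_a=row.rsid_a,
                rsid_b=row.rsid_b,
                r2=float(row.r2),
                phase=_parse_phase(row.phase),
            )
        )
    return out


def write_ld_table(table: LdTable, path: str | Path) -> None:
    rows = [(p.rsid_a, p.rsid_b, p.r2, _format_phase(p.phase)) for p in table]
    pd.DataFrame(rows, columns=list(LD_COLUMNS)).to_csv(path, sep="\t", index=False)
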