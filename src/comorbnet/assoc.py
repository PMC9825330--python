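"""Parsing and filtering of PheWAS summary statistics into a disease x SNP z-score matrix.

A PheWAS (phenome-wide association study) tests each SNP against many phenotypes
and reports, per (phenotype, SNP) pair, an effect size (beta), its standard error
and an association P-value.  The per-pair z-score ``r = beta / se`` carries both
the strength and the *direction* of the genetic effect; the sparse matrix ``R``
of z-scores over significant associations is the raw material for the signed
disease-disease network.
"""

from __future__ import annotations

import logging
from collections import Counter
from collections.abc import Callable, Iterable, Mapping
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import sparse

logger = logging.getLogger(__name__)

#: default column names for tab-delimited summary-statistics files
DEFAULT_SCHEMA: dict[str, str] = {
    "phenotype_id": "phecode",
    "snp_id": "snp",
    "chrom": "chrom",
    "pos": "pos",
    "beta": "beta",
    "se": "se",
    "pval": "pval",
}

#: phenotype categories excluded from network construction by default
DEFAULT_EXCLUDED_CATEGORIES: frozenset[str] = frozenset(
    {"injuries & poisonings", "symptoms"}
)


@dataclass(frozen=True)
class AssociationRecord:
    """One (phenotype, SNP) summary-statistic row."""

    phenotype_id: str
    snp_id: str
    chrom: str
    pos: int
    beta: float
    se: float
    pval: float

    @property
    def z(self) -> float:
        """z-score r = beta / se; its sign is the direction of effect."""
        return self.beta / self.se


@dataclass(frozen=True)
class PhenotypeMeta:
    phenotype_id: str
    name: str
    category: str
    n_cases: int


@dataclass
class ReadReport:
    """Bookkeeping for a summary-statistics parse."""

    n_rows: int = 0
    n_kept: int = 0
    n_skipped: int = 0
    skip_reasons: Counter = field(default_factory=Counter)


@dataclass
class AssociationMatrix:
    """Sparse m x K matrix of z-scores over significant (phenotype, SNP) pairs.

    ``values[i, k]`` is zero (not stored) when phenotype i has no surviving
    association with SNP k; every stored value is finite and nonzero.
    """

    phenotypes: list[str]
    snps: list[str]
    values: sparse.csr_matrix

    def __post_init__(self) -> None:
        self.values = sparse.csr_matrix(self.values)
        m, k = self.values.shape
        if m != len(self.phenotypes) or k != len(self.snps):
            raise ValueError(
                f"matrix shape {self.values.shape} does not match id lists "
                f"({len(self.phenotypes)} phenotypes, {len(self.snps)} SNPs)"
            )
        self.values.eliminate_zeros()
        if self.values.nnz and not np.all(np.isfinite(self.values.data)):
            raise ValueError("association matrix contains non-finite z-scores")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def row_index(self, phenotype_id: str) -> int:
        return self.phenotypes.index(phenotype_id)

    # -- triplet serialization -------------------------------------------------

    def write(self, prefix: str | Path) -> None:
        """Write as a sparse triplet TSV plus phenotype/SNP id sidecars."""
        prefix = Path(prefix)
        coo = self.values.tocoo()
        with open(f"{prefix}.triplets.tsv", "w") as fh:
            fh.write("phenotype_id\tsnp_id\tz\n")
            for i, k, z in zip(coo.row, coo.col, coo.data):
                fh.write(f"{self.phenotypes[i]}\t{self.snps[k]}\t{float(z)!r}\n")
        Path(f"{prefix}.phenotypes.txt").write_text(
            "".join(f"{p}\n" for p in self.phenotypes)
        )
        Path(f"{prefix}.snps.txt").write_text("".join(f"{s}\n" for s in self.snps))

    @classmethod
    def read(cls, prefix: str | Path) -> "AssociationMatrix":
        prefix = Path(prefix)
        phenotypes = Path(f"{prefix}.phenotypes.txt").read_text().split()
        snps = Path(f"{prefix}.snps.txt").read_text().split()
        pidx = {p: i for i, p in enumerate(phenotypes)}
        sidx = {s: k for k, s in enumerate(snps)}
        rows, cols, data = [], [], []
        df = pd.read_csv(f"{prefix}.triplets.tsv", sep="\t",
                         dtype={"phenotype_id": str, "snp_id": str},
                         float_precision="round_trip")
        for p, s, z in df.itertuples(index=False):
            rows.append(pidx[p])
            cols.append(sidx[s])
            data.append(float(z))
        values = sparse.csr_matrix(
            (data, (rows, cols)), shape=(len(phenotypes), len(snps))
        )
        return cls(phenotypes, snps, values)


def read_summary_stats(
    path: str | Path,
    schema: Mapping[str, str] | None = None,
) -> tuple[list[AssociationRecord], ReadReport]:
    """Parse a tab-delimited summary-statistics file into association records.

    Rows with missing or unparseable beta, se or pval — or values violating the
    record invariants (se > 0, pval in (0, 1]) — are skipped and counted in the
    returned :class:`ReadReport`.

    Raises
    ------
    FileNotFoundError
        If the file cannot be read.
    ValueError
        If a schema column is absent from the file header.
    """
    schema = {**DEFAULT_SCHEMA, **(schema or {})}
    df = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    missing = [c for c in schema.values() if c not in df.columns]
    if missing:
        raise ValueError(f"columns {missing} not found in {path} (header: {list(df.columns)})")

    report = ReadReport(n_rows=len(df))
    records: list[AssociationRecord] = []
    for row in df.itertuples(index=False):
        raw = {field: getattr(row, schema[field]) for field in schema}
        try:
            beta = float(raw["beta"])
            se = float(raw["se"])
            pval = float(raw["pval"])
            pos = int(float(raw["pos"]))
        except (TypeError, ValueError):
            report.n_skipped += 1
            report.skip_reasons["unparseable"] += 1
            continue
        if not (np.isfinite(beta) and np.isfinite(se) and np.isfinite(pval)):
            report.n_skipped += 1
            report.skip_reasons["non-finite"] += 1
            continue
        if se <= 0:
            report.n_skipped += 1
            report.skip_reasons["se<=0"] += 1
            continue
        if not (0 < pval <= 1):
            report.n_skipped += 1
            report.skip_reasons["pval outside (0,1]"] += 1
            continue
        records.append(
            AssociationRecord(
                phenotype_id=str(raw["phenotype_id"]),
                snp_id=str(raw["snp_id"]),
                chrom=str(raw["chrom"]),
                pos=pos,
                beta=beta,
                se=se,
                pval=pval,
            )
        )
    report.n_kept = len(records)
    if report.n_skipped:
        logger.warning(
            "read_summary_stats: skipped %d/%d rows (%s)",
            report.n_skipped,
            report.n_rows,
            dict(report.skip_reasons),
        )
    return records, report


def read_phenotype_meta(path: str | Path) -> dict[str, PhenotypeMeta]:
    """Read tab-delimited phenotype metadata (phecode, name, category, n_cases)."""
    df = pd.read_csv(path, sep="\t", dtype={"phecode": str}, comment="#")
    return {
        str(r.phecode): PhenotypeMeta(str(r.phecode), str(r.name), str(r.category), int(r.n_cases))
        for r in df.itertuples(index=False)
    }


def apply_phenotype_filters(
    records: Iterable[AssociationRecord],
    meta: Mapping[str, PhenotypeMeta],
    min_cases: int = 1000,
    excluded_categories: frozenset[str] = DEFAULT_EXCLUDED_CATEGORIES,
) -> list[AssociationRecord]:
    """Drop records of phenotypes with < min_cases cases or an excluded category.

    Every record's phenotype must be present in ``meta``; an unknown phenotype
    id is a fatal error (it signals mismatched inputs, not missing data).
    """
    kept = []
    for rec in records:
        if rec.phenotype_id not in meta:
            raise ValueError(f"phenotype {rec.phenotype_id!r} missing from metadata table")
        m = meta[rec.phenotype_id]
        if m.n_cases >= min_cases and m.category not in excluded_categories:
            kept.append(rec)
    return kept


def apply_significance_filter(
    records: Iterable[AssociationRecord], alpha: float = 1e-4
) -> list[AssociationRecord]:
    """Keep records with association P-value strictly below ``alpha``."""
    if not (0 < alpha <= 1):
        raise ValueError(f"alpha must be in (0, 1], got {alpha}")
    return [rec for rec in records if rec.pval < alpha]


def _r2_lookup(
    r2_source: Callable[[str, str], float | None] | Mapping,
) -> Callable[[str, str], float | None]:
    if callable(r2_source):
        return r2_source

    def lookup(a: str, b: str) -> float | None:
        for key in ((a, b), (b, a), frozenset((a, b))):
            if key in r2_source:
                return r2_source[key]
        return None

    return lookup


def greedy_ld_prune(
    variants: Iterable[tuple[str, str, int, float]],
    r2_source: Callable[[str, str], float | None] | Mapping,
    window_kb: float = 50,
    step_kb: float = 5,
    r2_max: float = 0.5,
) -> set[str]:
    """Greedy linkage-disequilibrium pruning with a sliding genomic window.

    Variants are ``(snp_id, chrom, pos, min_pval)`` tuples, where ``min_pval``
    is the variant's best association P-value across phenotypes.  A window of
    ``window_kb`` slides along each chromosome in steps of ``step_kb``; within
    a window, for every pair with r² > ``r2_max`` the variant with the larger
    ``min_pval`` (less informative) is removed, ties broken by removing the one
    at the larger position.  Pairs whose r² is unknown (lookup returns None) are
    treated as independent.  The result is deterministic regardless of input
    order: variants are sorted by (chrom, pos, snp_id) internally.
    """
    if window_kb <= 0 or step_kb <= 0:
        raise ValueError("window_kb and step_kb must be positive")
    lookup = _r2_lookup(r2_source)
    window_bp = int(window_kb * 1000)
    step_bp = int(step_kb * 1000)

    by_chrom: dict[str, list[tuple[int, str, float]]] = {}
    for snp_id, chrom, pos, min_pval in variants:
        if pos < 0:
            raise ValueError(f"negative position for {snp_id}: {pos}")
        by_chrom.setdefault(str(chrom), []).append((int(pos), str(snp_id), float(min_pval)))

    retained: set[str] = set()
    for chrom in sorted(by_chrom):
        vs = sorted(by_chrom[chrom])
        removed: set[str] = set()
        start = vs[0][0]
        last = vs[-1][0]
        while start <= last:
            window = [v for v in vs if start <= v[0] < start + window_bp and v[1] not in removed]
            for a in range(len(window)):
                pos_a, id_a, p_a = window[a]
                if id_a in removed:
                    continue
                for b in range(a + 1, len(window)):
                    pos_b, id_b, p_b = window[b]
                    if id_a in removed:
                        break
                    if id_b in removed:
                        continue
                    r2 = lookup(id_a, id_b)
                    if r2 is None or r2 <= r2_max:
                        continue
                    # victim: larger min P-value; tie -> larger position
                    if (p_a, pos_a) > (p_b, pos_b):
                        removed.add(id_a)
                    else:
                        removed.add(id_b)
            start += step_bp
        retained.update(v[1] for v in vs if v[1] not in removed)
    return retained


def assemble_matrix(
    records: Iterable[AssociationRecord],
    retained_snps: set[str] | None = None,
) -> AssociationMatrix:
    """Assemble filtered records into the sparse disease x SNP z-score matrix R.

    Cell (i, k) holds r_ik = beta_ik / se_ik where a record survives filtering,
    and is absent otherwise.  Phenotype and SNP orders are sorted, so the matrix
    is invariant to input record order.  Duplicate (phenotype, SNP) keys are
    fatal.
    """
    recs = list(records)
    if retained_snps is not None:
        recs = [r for r in recs if r.snp_id in retained_snps]
    seen: set[tuple[str, str]] = set()
    for r in recs:
        key = (r.phenotype_id, r.snp_id)
        if key in seen:
            raise ValueError(f"duplicate (phenotype, SNP) record: {key}")
        seen.add(key)
    phenotypes = sorted({r.phenotype_id for r in recs})
    snps = sorted({r.snp_id for r in recs})
    pidx = {p: i for i, p in enumerate(phenotypes)}
    sidx = {s: k for k, s in enumerate(snps)}
    rows = [pidx[r.phenotype_id] for r in recs]
    cols = [sidx[r.snp_id] for r in recs]
    data = [r.z for r in recs]
    values = sparse.csr_matrix((data, (rows, cols)), shape=(len(phenotypes), len(snps)))
    return AssociationMatrix(phenotypes, snps, values)
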