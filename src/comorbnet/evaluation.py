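"""EHR-driven comorbidity measures and evaluation of propagated scores.

Ground truth for "these two diseases co-occur" comes from a patient x phenotype
binary diagnosis matrix.  For each disease pair the 2x2 contingency of
prevalences yields the phi-correlation

    phi_ij = (C_ij N - P_i P_j) / sqrt(P_i P_j (N - P_i)(N - P_j))

and the relative risk RR_ij = C_ij N / (P_i P_j).  A pair has EHR-driven
comorbidity when phi > 0 and RR > 1 (the two conditions are algebraically
equivalent for valid counts; both are computed and checked).  Propagated
scores are evaluated per index disease by ROC AUC and Spearman rank
correlation against RR, thresholded at Youden's J into direct (f >= J) and
inverse (f < J) comorbidity, and stratified into score deciles (tiers).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import sparse, stats
from sklearn.metrics import roc_auc_score

Z_95 = 1.959963984540054  # two-sided 95% normal quantile


@dataclass(frozen=True)
class PairCounts:
    """2x2 contingency summary for one disease pair in a cohort of n patients."""

    c_ij: int
    p_i: int
    p_j: int
    n: int

    def __post_init__(self) -> None:
        if self.n <= 0:
            raise ValueError("n must be positive")
        if not (0 <= self.c_ij <= min(self.p_i, self.p_j) <= self.n):
            raise ValueError(
                f"invalid pair counts: c={self.c_ij}, p_i={self.p_i}, "
                f"p_j={self.p_j}, n={self.n}"
            )


@dataclass(frozen=True)
class RelativeRisk:
    rr: float
    ci_low: float
    ci_high: float


@dataclass
class CohortTable:
    """Patient x phenotype binary diagnosis matrix."""

    phenotypes: list[str]
    matrix: np.ndarray  # (n_patients, m), values 0/1

    def __post_init__(self) -> None:
        X = np.asarray(self.matrix)
        if sparse.issparse(self.matrix):
            X = np.asarray(self.matrix.todense())
        if X.ndim != 2 or X.shape[1] != len(self.phenotypes):
            raise ValueError("cohort matrix shape does not match phenotype list")
        if not np.isin(X, (0, 1)).all():
            raise ValueError("cohort matrix must be binary (0/1)")
        self.matrix = X.astype(np.int8)

    @property
    def n_patients(self) -> int:
        return self.matrix.shape[0]

    def column(self, phenotype_id: str) -> np.ndarray:
        try:
            return self.matrix[:, self.phenotypes.index(phenotype_id)]
        except ValueError:
            raise KeyError(f"phenotype {phenotype_id!r} not in cohort") from None

    def pair_counts(self, pheno_i: str, pheno_j: str) -> PairCounts:
        a, b = self.column(pheno_i), self.column(pheno_j)
        return PairCounts(
            c_ij=int((a & b).sum()), p_i=int(a.sum()), p_j=int(b.sum()),
            n=self.n_patients,
        )

    # -- triplet serialization -------------------------------------------------

    def write(self, path: str | Path) -> None:
        """Sparse triplet export: one (patient, phenotype) diagnosis per line."""
        with open(path, "w") as fh:
            fh.write(f"# n_patients={self.n_patients}\n")
            fh.write(f"# phenotypes={','.join(self.phenotypes)}\n")
            fh.write("patient\tphenotype\n")
            rows, cols = np.nonzero(self.matrix)
            for r, c in zip(rows, cols):
                fh.write(f"{r}\t{self.phenotypes[c]}\n")

    @classmethod
    def read(cls, path: str | Path) -> "CohortTable":
        n_patients = None
        phenotypes: list[str] | None = None
        with open(path) as fh:
            for line in fh:
                if line.startswith("# n_patients="):
                    n_patients = int(line.split("=", 1)[1])
                elif line.startswith("# phenotypes="):
                    phenotypes = line.split("=", 1)[1].strip().split(",")
                elif not line.startswith("#"):
                    break
        df = pd.read_csv(path, sep="\t", comment="#", dtype={"phenotype": str})
        if phenotypes is None:
            phenotypes = sorted(df["phenotype"].unique())
        if n_patients is None:
            n_patients = int(df["patient"].max()) + 1
        X = np.zeros((n_patients, len(phenotypes)), dtype=np.int8)
        pidx = {p: k for k, p in enumerate(phenotypes)}
        X[df["patient"].to_numpy(), [pidx[p] for p in df["phenotype"]]] = 1
        return cls(phenotypes, X)


def phi_correlation(pc: PairCounts) -> float:
    """Pearson correlation of the two binary diagnosis indicators.

    Undefined (NaN) when either disease has zero or full prevalence.
    """
    if pc.p_i in (0, pc.n) or pc.p_j in (0, pc.n):
        return float("nan")
    num = pc.c_ij * pc.n - pc.p_i * pc.p_j
    den = math.sqrt(pc.p_i * pc.p_j * (pc.n - pc.p_i) * (pc.n - pc.p_j))
    return num / den


def relative_risk(pc: PairCounts) -> RelativeRisk:
    """Relative risk of co-occurrence, RR = C n / (P_i P_j), with a Katz-style
    95% CI exp(ln RR +/- 1.96 SE), SE^2 = 1/C - n/(P_i P_j) clamped at 0.

    RR > 1: the pair co-occurs more often than expected under independence.
    C = 0 gives RR = 0 with an undefined CI; zero prevalence gives NaN.
    """
    if pc.p_i == 0 or pc.p_j == 0:
        return RelativeRisk(float("nan"), float("nan"), float("nan"))
    if pc.c_ij == 0:
        return RelativeRisk(0.0, float("nan"), float("nan"))
    rr = pc.c_ij * pc.n / (pc.p_i * pc.p_j)
    se2 = max(1.0 / pc.c_ij - pc.n / (pc.p_i * pc.p_j), 0.0)
    se = math.sqrt(se2)
    return RelativeRisk(rr, rr * math.exp(-Z_95 * se), rr * math.exp(Z_95 * se))


def ehr_labels(cohort: CohortTable, index_disease: str) -> pd.DataFrame:
    """Per-disease EHR-driven comorbidity labels against one index disease.

    Returns a frame indexed by phenotype with columns phi, rr, rr_low, rr_high,
    label (+1 when phi > 0 and RR > 1, else -1) and evaluable (False when phi
    or RR is undefined — zero/full prevalence — in which case the disease is
    excluded from evaluation).
    """
    rows = []
    for pheno in cohort.phenotypes:
        if pheno == index_disease:
            continue
        pc = cohort.pair_counts(pheno, index_disease)
        phi = phi_correlation(pc)
        rr = relative_risk(pc)
        evaluable = not (math.isnan(phi) or math.isnan(rr.rr))
        label = 1 if (evaluable and phi > 0 and rr.rr > 1) else -1
        rows.append((pheno, phi, rr.rr, rr.ci_low, rr.ci_high, label, evaluable))
    return pd.DataFrame(
        rows,
        columns=["phenotype", "phi", "rr", "rr_low", "rr_high", "label", "evaluable"],
    ).set_index("phenotype")


def roc_auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """Rank-based AUC: probability a random +1 outscores a random -1 (ties 1/2).

    NaN when only one class is present.
    """
    labels = np.asarray(labels)
    if len(set(labels.tolist())) < 2:
        return float("nan")
    return float(roc_auc_score(labels, np.asarray(scores, dtype=float)))


def youden_threshold(scores: np.ndarray, labels: np.ndarray) -> float:
    """Score cutoff maximizing Youden's J = sensitivity + specificity - 1.

    Prediction rule: score >= threshold -> direct comorbidity.  Candidate
    thresholds are the observed scores; ties in J are broken toward the
    smallest threshold (the most inclusive direct set).  NaN when only one
    class is present.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    pos = labels == 1
    neg = labels == -1
    if not pos.any() or not neg.any():
        return float("nan")
    best_j, best_t = -np.inf, float("nan")
    for t in np.sort(np.unique(scores)):  # ascending -> '>=' keeps smallest tie
        pred = scores >= t
        sens = np.sum(pred & pos) / pos.sum()
        spec = np.sum(~pred & neg) / neg.sum()
        j = sens + spec - 1
        if j > best_j:
            best_j, best_t = j, float(t)
    return best_t


def categorize_comorbidity(
    scores: dict[str, float] | pd.Series, threshold: float
) -> tuple[set[str], set[str]]:
    """Partition diseases into the direct set (f >= J) and inverse set (f < J)."""
    s = pd.Series(scores)
    direct = set(s.index[s >= threshold])
    inverse = set(s.index[s < threshold])
    return direct, inverse


def assign_tiers(scores: dict[str, float] | pd.Series, n_tiers: int = 10) -> dict[str, int]:
    """Stratify scores into tiers (deciles by default) by descending rank.

    Tier 1 holds the highest scores (direct comorbidity group), tier
    ``n_tiers`` the lowest (inverse group).  When the count is not divisible,
    the remainder goes to the top tiers.  Score ties keep a stable order by
    phenotype id.
    """
    s = pd.Series(scores)
    if len(s) < n_tiers:
        raise ValueError(
            f"{len(s)} diseases cannot fill {n_tiers} tiers; "
            "pass a smaller n_tiers"
        )
    order = sorted(s.index, key=lambda p: (-s[p], p))
    base, rem = divmod(len(order), n_tiers)
    tiers: dict[str, int] = {}
    start = 0
    for t in range(1, n_tiers + 1):
        size = base + (1 if t <= rem else 0)
        for pheno in order[start:start + size]:
            tiers[pheno] = t
        start += size
    return tiers


def _exact_spearman_pvalue(x: np.ndarray, y: np.ndarray, rho: float) -> float:
    """Two-sided exact permutation P for Spearman rho (small n only)."""
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    count = 0
    total = 0
    for perm in itertools.permutations(range(len(ry))):
        r = np.corrcoef(rx, ry[list(perm)])[0, 1]
        if abs(r) >= abs(rho) - 1e-12:
            count += 1
        total += 1
    return count / total


def spearman_rank(
    f: np.ndarray, rr_values: np.ndarray, p_method: str = "t"
) -> tuple[float, float]:
    """Spearman rank correlation between scores and relative risks.

    Average ranks on ties; P-value from the large-sample t approximation, or
    an exact permutation test (``p_method="permutation"``, n <= 8).  Returns
    (NaN, NaN) for constant input.
    """
    f = np.asarray(f, dtype=float)
    rr_values = np.asarray(rr_values, dtype=float)
    if len(f) < 3:
        raise ValueError("need at least 3 paired observations")
    if np.all(f == f[0]) or np.all(rr_values == rr_values[0]):
        return float("nan"), float("nan")
    rho, pval = stats.spearmanr(f, rr_values)
    if p_method == "permutation":
        if len(f) > 8:
            raise ValueError("exact permutation P only available for n <= 8")
        pval = _exact_spearman_pvalue(f, rr_values, rho)
    elif p_method != "t":
        raise ValueError(f"unknown p_method {p_method!r}")
    return float(rho), float(pval)


@dataclass
class EvalResult:
    """Per-index-disease evaluation of propagated scores against the cohort."""

    index_disease: str
    auc: float
    youden_threshold: float
    spearman_rho: float
    spearman_p: float
    tiers: dict[str, int]
    direct_set: set[str]
    inverse_set: set[str]
    n_excluded: int
    table: pd.DataFrame = field(repr=False)


def evaluate_index_disease(
    scores: dict[str, float] | pd.Series,
    cohort: CohortTable,
    index_disease: str,
    n_tiers: int = 10,
) -> EvalResult:
    """Full transductive evaluation of comorbidity scores for one index disease.

    ``scores`` maps unlabeled phenotype -> propagated score.  Diseases with
    undefined phi/RR are excluded from AUC/J/rho (counted in ``n_excluded``)
    but still tiered and categorized.
    """
    s = pd.Series(scores, dtype=float)
    labels = ehr_labels(cohort, index_disease)
    common = [p for p in s.index if p in labels.index]
    labels = labels.loc[common]
    s = s.loc[common]
    ok = labels["evaluable"].to_numpy()
    auc = roc_auc(s.to_numpy()[ok], labels["label"].to_numpy()[ok])
    j = youden_threshold(s.to_numpy()[ok], labels["label"].to_numpy()[ok])
    rho, pval = (float("nan"), float("nan"))
    if ok.sum() >= 3:
        rho, pval = spearman_rank(s.to_numpy()[ok], labels["rr"].to_numpy()[ok])
    tiers = assign_tiers(s, n_tiers=n_tiers) if len(s) >= n_tiers else {}
    direct, inverse = categorize_comorbidity(s, j) if not math.isnan(j) else (set(), set())
    table = labels.copy()
    table.insert(0, "score", s)
    table["tier"] = pd.Series(tiers)
    table["category"] = np.where(table.index.isin(direct), "direct",
                                 np.where(table.index.isin(inverse), "inverse", ""))
    return EvalResult(
        index_disease=index_disease,
        auc=auc,
        youden_threshold=j,
        spearman_rho=rho,
        spearman_p=pval,
        tiers=tiers,
        direct_set=direct,
        inverse_set=inverse,
        n_excluded=int((~ok).sum()),
        table=table.sort_values("score", ascending=False),
    )
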