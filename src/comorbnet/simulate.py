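"""Synthetic PheWAS summary statistics and a matched patient cohort.

The generator plants the structure the signed-network method is built to
detect: diseases fall into clusters, within-cluster pairs share SNPs whose
effect signs mostly *agree* (synergistic), between-cluster pairs share SNPs
whose signs mostly *disagree* (antagonistic).  A matched cohort is then drawn
so that synergistic pairs co-occur more often than chance (RR > 1) and
antagonistic pairs less often (RR < 1), realizing at generation time the
relationship the method is supposed to recover.

The cohort model is a cheap sequential-conditional sampler, not a calibrated
epidemiological model; see docs/methods.md for what it does and does not
emulate.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import expit, logit

from .assoc import AssociationMatrix, AssociationRecord, assemble_matrix
from .evaluation import CohortTable

#: standard-error draw range for emitted summary statistics (log-uniform)
SE_RANGE = (0.01, 0.2)


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic PheWAS + cohort.

    Defaults give 30 diseases in 3 clusters with strong planted signal
    (|z| ~ folded N(5, 1), 90% sign concordance within clusters, 10% between)
    and a 20 000-patient cohort whose co-occurrence odds are boosted 3x for
    synergistic pairs and damped 3x for antagonistic ones.
    """

    m_diseases: int = 30
    n_clusters: int = 3
    snps_per_disease: int = 20
    shared_snps_within_cluster: int = 8
    shared_snps_between_clusters: int = 5
    concordance_within: float = 0.9
    concordance_between: float = 0.1
    effect_size_mean: float = 5.0
    n_patients: int = 20_000
    base_prevalence: float = 0.05
    comorbidity_boost: float = 3.0
    comorbidity_damp: float = 1.0 / 3.0
    seed: int = 0

    def validate(self) -> None:
        for name in ("concordance_within", "concordance_between", "base_prevalence"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if not self.comorbidity_boost > 1 > self.comorbidity_damp > 0:
            raise ValueError("require boost > 1 > damp > 0")
        for name in ("m_diseases", "n_clusters", "snps_per_disease", "n_patients"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.shared_snps_within_cluster < 0 or self.shared_snps_between_clusters < 0:
            raise ValueError("shared SNP counts must be non-negative")
        if self.n_clusters > self.m_diseases:
            raise ValueError("more clusters than diseases is infeasible")

    def clusters(self) -> np.ndarray:
        """Cluster assignment per disease (contiguous blocks)."""
        return np.arange(self.m_diseases) * self.n_clusters // self.m_diseases


@dataclass
class PlantedTruth:
    """Intended pair structure underlying a simulated dataset.

    ``pair_sign[(i, j)]`` (i < j, phenotype ids) is +1 for planted synergistic
    pairs, -1 for antagonistic; absent pairs are unrelated.  ``shared`` lists,
    per pair, the shared SNP ids with their realized sign concordance.
    """

    phenotypes: list[str]
    pair_sign: dict[tuple[str, str], int]
    shared: dict[tuple[str, str], list[tuple[str, bool]]] = field(repr=False)

    def sign(self, a: str, b: str) -> int:
        return self.pair_sign.get((min(a, b), max(a, b)), 0)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "phenotypes": self.phenotypes,
            "pairs": [
                {
                    "a": a,
                    "b": b,
                    "sign": s,
                    "shared": [
                        {"snp": snp, "concordant": conc}
                        for snp, conc in self.shared[(a, b)]
                    ],
                }
                for (a, b), s in sorted(self.pair_sign.items())
            ],
        }
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "PlantedTruth":
        payload = json.loads(Path(path).read_text())
        pair_sign = {}
        shared = {}
        for p in payload["pairs"]:
            key = (p["a"], p["b"])
            pair_sign[key] = int(p["sign"])
            shared[key] = [(d["snp"], bool(d["concordant"])) for d in p["shared"]]
        return cls(payload["phenotypes"], pair_sign, shared)


def _rng(config: SimulationConfig, stream: int) -> np.random.Generator:
    # one global seed, independent derived streams per stage
    return np.random.default_rng(np.random.SeedSequence(entropy=config.seed, spawn_key=(stream,)))


def _disease_ids(config: SimulationConfig) -> list[str]:
    width = len(str(config.m_diseases))
    return [f"D{i + 1:0{width}d}" for i in range(config.m_diseases)]


def simulate_summary_stats(
    config: SimulationConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, PlantedTruth]:
    """Emit PheWAS-style summary statistics with planted pair structure.

    Returns (records, metadata, truth).  ``records`` has one row per
    (phenotype, SNP) association with columns phecode, snp, chrom, pos, beta,
    se, pval; z-score magnitudes are folded-normal around
    ``effect_size_mean`` so planted associations are almost surely significant
    at P < 1e-4, beta = z * se with se log-uniform in [0.01, 0.2], and P the
    two-sided normal tail of z.  Deterministic under ``config.seed``.
    """
    config.validate()
    rng = _rng(config, 0)
    diseases = _disease_ids(config)
    clusters = config.clusters()

    # z[disease][snp] = planted z-score
    z: dict[str, dict[str, float]] = {d: {} for d in diseases}
    snp_counter = itertools.count(1)

    def draw_z(sign: int) -> float:
        return sign * abs(rng.normal(config.effect_size_mean, 1.0))

    # private SNPs
    for d in diseases:
        for _ in range(config.snps_per_disease):
            snp = f"rs{next(snp_counter)}"
            z[d][snp] = draw_z(1 if rng.random() < 0.5 else -1)

    # shared SNPs per pair, with sign concordance by cluster relation
    pair_sign: dict[tuple[str, str], int] = {}
    shared: dict[tuple[str, str], list[tuple[str, bool]]] = {}
    for a_idx, b_idx in itertools.combinations(range(config.m_diseases), 2):
        within = clusters[a_idx] == clusters[b_idx]
        n_shared = (config.shared_snps_within_cluster if within
                    else config.shared_snps_between_clusters)
        if n_shared == 0:
            continue
        a, b = diseases[a_idx], diseases[b_idx]
        concordance = (config.concordance_within if within
                       else config.concordance_between)
        pair_sign[(a, b)] = 1 if within else -1
        shared[(a, b)] = []
        for _ in range(n_shared):
            snp = f"rs{next(snp_counter)}"
            sign_a = 1 if rng.random() < 0.5 else -1
            concordant = bool(rng.random() < concordance)
            sign_b = sign_a if concordant else -sign_a
            z[a][snp] = draw_z(sign_a)
            z[b][snp] = draw_z(sign_b)
            shared[(a, b)].append((snp, concordant))

    # flatten to summary-statistic rows; SNP positions 100 kb apart on chr1
    n_snps = next(snp_counter) - 1
    pos_of = {f"rs{k}": 100_000 * k for k in range(1, n_snps + 1)}
    rows = []
    for d in diseases:
        for snp, zval in sorted(z[d].items(), key=lambda kv: pos_of[kv[0]]):
            se = float(np.exp(rng.uniform(np.log(SE_RANGE[0]), np.log(SE_RANGE[1]))))
            pval = float(max(2.0 * stats.norm.sf(abs(zval)), 5e-324))
            rows.append((d, snp, "1", pos_of[snp], zval * se, se, pval))
    records = pd.DataFrame(
        rows, columns=["phecode", "snp", "chrom", "pos", "beta", "se", "pval"]
    )
    meta = pd.DataFrame(
        {
            "phecode": diseases,
            "name": [f"synthetic disease {d}" for d in diseases],
            "category": [f"cluster_{c}" for c in clusters],
            # case counts of the (much larger) discovery PheWAS cohort, not of
            # the validation cohort drawn by simulate_cohort
            "n_cases": int(round(config.base_prevalence * 400_000)),
        }
    )
    truth = PlantedTruth(diseases, pair_sign, shared)
    return records, meta, truth


def records_from_frame(records: pd.DataFrame) -> list[AssociationRecord]:
    """Convert a simulated summary-stats frame into association records."""
    return [
        AssociationRecord(str(r.phecode), str(r.snp), str(r.chrom), int(r.pos),
                          float(r.beta), float(r.se), float(r.pval))
        for r in records.itertuples(index=False)
    ]


def simulate_phewas(config: SimulationConfig) -> tuple[AssociationMatrix, PlantedTruth]:
    """Simulated disease x SNP z-score matrix plus its planted truth."""
    records, _, truth = simulate_summary_stats(config)
    return assemble_matrix(records_from_frame(records)), truth


def simulate_cohort(truth: PlantedTruth, config: SimulationConfig) -> CohortTable:
    """Draw a binary patient x phenotype cohort matching the planted structure.

    Sequential-conditional model: per patient, diseases are visited in a
    random order; disease i occurs with

        logit P(i) = logit(base_prevalence)
                     + sum_{j present so far} log(boost or damp)

    with boost for planted synergistic (i, j) pairs and damp for antagonistic
    ones.  Deterministic under ``config.seed``.
    """
    config.validate()
    rng = _rng(config, 1)
    diseases = truth.phenotypes
    m = len(diseases)
    idx = {d: i for i, d in enumerate(diseases)}
    E = np.zeros((m, m))
    for (a, b), s in truth.pair_sign.items():
        eff = np.log(config.comorbidity_boost if s > 0 else config.comorbidity_damp)
        E[idx[a], idx[b]] = E[idx[b], idx[a]] = eff

    n = config.n_patients
    base_logit = logit(config.base_prevalence)
    orders = np.argsort(rng.random((n, m)), axis=1)  # independent shuffle per patient
    S = np.zeros((n, m), dtype=np.int8)
    rows = np.arange(n)
    for t in range(m):
        d = orders[:, t]
        logits = base_logit + np.einsum("ij,ij->i", S, E[d, :])
        S[rows, d] = (rng.random(n) < expit(logits)).astype(np.int8)
    return CohortTable(list(diseases), S)


def end_to_end_benchmark(
    config: SimulationConfig,
    mu: float = 1.0,
    alpha: float = 1e-4,
    unsigned_mode: str = "abs_cosine",
    index_diseases: list[str] | None = None,
) -> pd.DataFrame:
    """Signed-versus-unsigned comparison on one simulated dataset.

    Runs simulate -> significance filter -> assemble -> both networks ->
    propagate per index disease -> evaluate against the matched cohort.
    Returns one row per index disease with AUC and Spearman rho for each
    network; mean metrics are in ``DataFrame.attrs["means"]``.
    """
    from .assoc import apply_significance_filter
    from .network import build_signed_network, build_unsigned_network
    from .propagation import propagate_scores

    records, _, truth = simulate_summary_stats(config)
    recs = apply_significance_filter(records_from_frame(records), alpha=alpha)
    R = assemble_matrix(recs)
    signed = build_signed_network(R)
    unsigned = build_unsigned_network(R, mode=unsigned_mode)
    cohort = simulate_cohort(truth, config)

    from .evaluation import ehr_labels, roc_auc, spearman_rank

    rows = []
    for index in index_diseases or signed.nodes:
        labels = ehr_labels(cohort, index)
        labels = labels[labels["evaluable"]]
        present = [p for p in labels.index if p in signed.nodes]
        labels = labels.loc[present]
        if len(set(labels["label"])) < 2:
            continue
        f_signed = propagate_scores(signed, index, mu=mu)
        f_unsigned = propagate_scores(unsigned, index, mu=mu)
        fs = np.array([f_signed[p] for p in present])
        fu = np.array([f_unsigned[p] for p in present])
        y = labels["label"].to_numpy()
        rr = labels["rr"].to_numpy()
        rho_s, _ = spearman_rank(fs, rr)
        rho_u, _ = spearman_rank(fu, rr)
        rows.append((index, roc_auc(fs, y), roc_auc(fu, y), rho_s, rho_u))
    df = pd.DataFrame(
        rows,
        columns=["index_disease", "auc_signed", "auc_unsigned", "rho_signed", "rho_unsigned"],
    )
    df.attrs["means"] = df[["auc_signed", "auc_unsigned", "rho_signed", "rho_unsigned"]].mean().to_dict()
    return df
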