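"""Pipeline orchestration: simulate / build network / score / evaluate.

Every artifact written here carries a commented provenance header (config
hash, seed, package version) so a rerun with an identical configuration
reproduces byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from . import __version__
from .assoc import (
    AssociationMatrix,
    apply_phenotype_filters,
    apply_significance_filter,
    assemble_matrix,
    greedy_ld_prune,
    read_phenotype_meta,
    read_summary_stats,
)
from .evaluation import CohortTable, evaluate_index_disease
from .network import SignedGraph, build_signed_network, build_unsigned_network
from .propagation import propagate_scores, rescale_scores
from .simulate import SimulationConfig, simulate_cohort, simulate_summary_stats

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Thresholds and knobs for a full run; validated before any stage runs."""

    alpha: float = 1e-4
    min_cases: int = 1000
    window_kb: float = 50.0
    step_kb: float = 5.0
    r2_max: float = 0.5
    mu: float = 1.0
    solver: str = "auto"
    unsigned_mode: str = "abs_cosine"
    n_tiers: int = 10
    seed: int = 0

    def validate(self) -> None:
        if not (0 < self.alpha <= 1):
            raise ValueError(f"alpha must be in (0, 1], got {self.alpha}")
        if self.min_cases < 0:
            raise ValueError("min_cases must be non-negative")
        if self.window_kb <= 0 or self.step_kb <= 0:
            raise ValueError("window_kb and step_kb must be positive")
        if not (0 <= self.r2_max <= 1):
            raise ValueError("r2_max must be in [0, 1]")
        if self.mu < 0:
            raise ValueError("mu must be >= 0")
        if self.solver not in ("auto", "direct", "iterative"):
            raise ValueError(f"unknown solver {self.solver!r}")
        if self.unsigned_mode not in ("abs_cosine", "shared_count"):
            raise ValueError(f"unknown unsigned mode {self.unsigned_mode!r}")
        if self.n_tiers < 2:
            raise ValueError("n_tiers must be >= 2")

    def hash(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]

    def header_lines(self) -> list[str]:
        return [
            f"comorbnet v{__version__}",
            f"config_hash={self.hash()}",
            f"seed={self.seed}",
        ]


def _write_tsv(df: pd.DataFrame, path: Path, config: PipelineConfig, index: bool = False) -> None:
    with open(path, "w") as fh:
        for line in config.header_lines():
            fh.write(f"# {line}\n")
        df.to_csv(fh, sep="\t", index=index, float_format="%.10g")


def build_network_stage(
    summary_path: str | Path,
    meta_path: str | Path,
    config: PipelineConfig,
    r2_table: dict | None = None,
) -> tuple[SignedGraph, SignedGraph, AssociationMatrix]:
    """Parse, filter, prune and assemble, then build signed + unsigned networks."""
    config.validate()
    records, report = read_summary_stats(summary_path)
    meta = read_phenotype_meta(meta_path)
    records = apply_phenotype_filters(records, meta, min_cases=config.min_cases)
    records = apply_significance_filter(records, alpha=config.alpha)
    min_pval: dict[str, tuple[str, int, float]] = {}
    for r in records:
        prev = min_pval.get(r.snp_id)
        if prev is None or r.pval < prev[2]:
            min_pval[r.snp_id] = (r.chrom, r.pos, r.pval)
    variants = [(snp, c, p, mp) for snp, (c, p, mp) in min_pval.items()]
    retained = greedy_ld_prune(
        variants, r2_table or {}, window_kb=config.window_kb,
        step_kb=config.step_kb, r2_max=config.r2_max,
    )
    R = assemble_matrix(records, retained)
    logger.info(
        "pipeline: %d rows read, %d skipped, %d after filters, %d SNPs pruned",
        report.n_rows, report.n_skipped, len(records), len(min_pval) - len(retained),
    )
    return build_signed_network(R), build_unsigned_network(R, config.unsigned_mode), R


def score_stage(
    graph: SignedGraph, index_disease: str, config: PipelineConfig
) -> pd.DataFrame:
    """Propagate and rank scores for one index disease; TSV-ready frame."""
    raw = propagate_scores(graph, index_disease, mu=config.mu, solver=config.solver)
    scaled = rescale_scores(raw)
    rows = [
        (p, raw[p], scaled[p])
        for p in graph.nodes
        if p != index_disease
    ]
    df = pd.DataFrame(rows, columns=["phenotype_id", "raw_score", "rescaled_score"])
    df = df.sort_values(["raw_score", "phenotype_id"], ascending=[False, True], ignore_index=True)
    df["rank"] = range(1, len(df) + 1)
    return df


def run_pipeline(
    out_dir: str | Path,
    config: PipelineConfig,
    sim_config: SimulationConfig | None = None,
    summary_path: str | Path | None = None,
    meta_path: str | Path | None = None,
    cohort_path: str | Path | None = None,
    index_diseases: list[str] | None = None,
) -> dict[str, Path]:
    """Run simulate -> build-net -> score -> evaluate, writing all artifacts.

    Either a :class:`SimulationConfig` (synthetic run) or paths to summary
    statistics + metadata (+ optional cohort for evaluation) must be given.
    Returns a name -> path map of the artifacts written.
    """
    config.validate()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    artifacts: dict[str, Path] = {}

    cohort: CohortTable | None = None
    if sim_config is not None:
        sim_config.seed = config.seed
        records, meta, truth = simulate_summary_stats(sim_config)
        summary_path = out / "summary_stats.tsv"
        meta_path = out / "phenotype_meta.tsv"
        _write_tsv(records, summary_path, config)
        _write_tsv(meta, meta_path, config)
        truth.to_json(out / "planted_truth.json")
        cohort = simulate_cohort(truth, sim_config)
        cohort.write(out / "cohort.tsv")
        artifacts.update(
            summary_stats=summary_path, phenotype_meta=meta_path,
            planted_truth=out / "planted_truth.json", cohort=out / "cohort.tsv",
        )
    elif summary_path is None or meta_path is None:
        raise ValueError("need either sim_config or summary_path + meta_path")
    if cohort is None and cohort_path is not None:
        cohort = CohortTable.read(cohort_path)

    try:
        signed, unsigned, R = build_network_stage(summary_path, meta_path, config)
    except Exception as exc:  # noqa: BLE001 - name the failing stage
        raise RuntimeError(f"pipeline stage 'build-net' failed: {exc}") from exc
    signed.to_edge_list(out / "network_signed.tsv", header_lines=config.header_lines())
    unsigned.to_edge_list(out / "network_unsigned.tsv", header_lines=config.header_lines())
    signed.to_graphml(out / "network_signed.graphml")
    census = signed.census()
    artifacts["network_signed"] = out / "network_signed.tsv"
    artifacts["network_unsigned"] = out / "network_unsigned.tsv"

    indices = index_diseases or list(signed.nodes)
    score_frames = []
    eval_rows = []
    for index in indices:
        try:
            df = score_stage(signed, index, config)
        except Exception as exc:  # noqa: BLE001
            raise RuntimeError(f"pipeline stage 'score' failed for {index}: {exc}") from exc
        df.insert(0, "index_disease", index)
        score_frames.append(df)
        if cohort is not None and index in cohort.phenotypes:
            scores = dict(zip(df["phenotype_id"], df["raw_score"]))
            scores = {p: v for p, v in scores.items() if p in cohort.phenotypes}
            res = evaluate_index_disease(scores, cohort, index, n_tiers=config.n_tiers)
            eval_rows.append(
                (index, res.auc, res.youden_threshold, res.spearman_rho,
                 res.spearman_p, res.n_excluded)
            )
    scores_path = out / "scores.tsv"
    _write_tsv(pd.concat(score_frames, ignore_index=True), scores_path, config)
    artifacts["scores"] = scores_path

    if eval_rows:
        eval_df = pd.DataFrame(
            eval_rows,
            columns=["index_disease", "auc", "youden_threshold",
                     "spearman_rho", "spearman_p", "n_excluded"],
        )
        eval_path = out / "evaluation.tsv"
        _write_tsv(eval_df, eval_path, config)
        artifacts["evaluation"] = eval_path

    report = {
        "version": __version__,
        "config_hash": config.hash(),
        "seed": config.seed,
        "n_nodes": census.n_nodes,
        "n_edges": census.n_edges,
        "n_synergistic": census.n_synergistic,
        "n_antagonistic": census.n_antagonistic,
        "density_pct": census.density,
        "matrix_shape": list(R.shape),
    }
    report_path = out / "report.json"
    report_path.write_text(json.dumps(report, indent=1, sort_keys=True))
    artifacts["report"] = report_path
    return artifacts
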