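"""Signed disease-disease network construction.

Two diseases are linked when they share at least one significant SNP.  The edge
weight is the cosine similarity of their z-score vectors,

    w_ij = sum_{k in S} r_ik r_jk / (||r_i|| ||r_j||),

where S is the set of SNPs significant for *both* diseases and the norms run
over each disease's own stored z-scores.  Because z-scores are signed, w_ij
lies in [-1, 1]: a positive weight (synergistic association) means the shared
SNPs push both diseases in the same direction, a negative weight (antagonistic)
means they push in opposite directions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
from scipy import sparse
from sklearn.base import BaseEstimator, TransformerMixin

from .assoc import AssociationMatrix

logger = logging.getLogger(__name__)

UNSIGNED_MODES = ("abs_cosine", "shared_count")


@dataclass
class EdgeCensus:
    """Edge counts of a signed graph, with the derived density/sign fractions."""

    n_nodes: int
    n_edges: int
    n_synergistic: int
    n_antagonistic: int

    @property
    def density(self) -> float:
        """Percent of possible undirected pairs carrying an edge, 2 decimals."""
        possible = self.n_nodes * (self.n_nodes - 1) / 2
        return round(100.0 * self.n_edges / possible, 2)

    @property
    def pct_synergistic(self) -> int:
        return round(100.0 * self.n_synergistic / self.n_edges) if self.n_edges else 0

    @property
    def pct_antagonistic(self) -> int:
        return round(100.0 * self.n_antagonistic / self.n_edges) if self.n_edges else 0


@dataclass
class SignedGraph:
    """Undirected weighted graph over phenotypes; weights in [-1, 1], zero diagonal.

    An edge is present iff its weight is nonzero; sign encodes synergistic (+)
    versus antagonistic (-) association.
    """

    nodes: list[str]
    weights: np.ndarray

    def __post_init__(self) -> None:
        W = np.asarray(self.weights, dtype=float)
        if W.shape != (len(self.nodes), len(self.nodes)):
            raise ValueError("weight matrix shape does not match node list")
        if not np.allclose(W, W.T, atol=1e-12):
            raise ValueError("weight matrix must be symmetric")
        np.fill_diagonal(W, 0.0)
        self.weights = W

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    def node_index(self, phenotype_id: str) -> int:
        try:
            return self.nodes.index(phenotype_id)
        except ValueError:
            raise KeyError(f"phenotype {phenotype_id!r} not in graph") from None

    def census(self) -> EdgeCensus:
        return edge_census(self)

    # -- exports ---------------------------------------------------------------

    def to_edge_list(self, path: str | Path, header_lines: list[str] | None = None) -> None:
        """Write a weighted edge list (source, target, weight, sign); re-importable bit-exactly."""
        iu = np.triu_indices(self.n_nodes, k=1)
        with open(path, "w") as fh:
            for line in header_lines or []:
                fh.write(f"# {line}\n")
            fh.write("source\ttarget\tweight\tsign\n")
            for i, j in zip(*iu):
                w = self.weights[i, j]
                if w != 0.0:
                    sign = "+" if w > 0 else "-"
                    fh.write(f"{self.nodes[i]}\t{self.nodes[j]}\t{float(w)!r}\t{sign}\n")

    @classmethod
    def from_edge_list(cls, path: str | Path, nodes: list[str] | None = None) -> "SignedGraph":
        df = pd.read_csv(path, sep="\t", comment="#",
                         dtype={"source": str, "target": str},
                         float_precision="round_trip")
        if nodes is None:
            nodes = sorted(set(df["source"]).union(df["target"]))
        idx = {n: i for i, n in enumerate(nodes)}
        W = np.zeros((len(nodes), len(nodes)))
        for row in df.itertuples(index=False):
            i, j = idx[row.source], idx[row.target]
            W[i, j] = W[j, i] = float(row.weight)
        return cls(list(nodes), W)

    def to_graphml(self, path: str | Path) -> None:
        g = nx.Graph()
        g.add_nodes_from(self.nodes)
        iu = np.triu_indices(self.n_nodes, k=1)
        for i, j in zip(*iu):
            w = self.weights[i, j]
            if w != 0.0:
                g.add_edge(self.nodes[i], self.nodes[j], weight=float(w),
                           sign="+" if w > 0 else "-")
        nx.write_graphml(g, path)

    def to_frame(self) -> pd.DataFrame:
        """Heatmap-ready dense weight matrix, phenotype order preserved."""
        return pd.DataFrame(self.weights, index=self.nodes, columns=self.nodes)

    def category_crosstab(self, categories: dict[str, str]) -> pd.DataFrame:
        """Count edges between phenotype categories, split by sign.

        Returns a long-format table (category_a, category_b, n_synergistic,
        n_antagonistic) over unordered category pairs.
        """
        iu = np.triu_indices(self.n_nodes, k=1)
        rows: dict[tuple[str, str], list[int]] = {}
        for i, j in zip(*iu):
            w = self.weights[i, j]
            if w == 0.0:
                continue
            key = tuple(sorted((categories[self.nodes[i]], categories[self.nodes[j]])))
            counts = rows.setdefault(key, [0, 0])
            counts[0 if w > 0 else 1] += 1
        return pd.DataFrame(
            [(a, b, s, n) for (a, b), (s, n) in sorted(rows.items())],
            columns=["category_a", "category_b", "n_synergistic", "n_antagonistic"],
        )


class SignedNetworkBuilder(TransformerMixin, BaseEstimator):
    """Transform a disease x SNP z-score matrix into a disease-disease weight matrix.

    Parameters
    ----------
    mode : {"signed", "abs_cosine", "shared_count"}
        "signed" is the signed cosine similarity of z-score vectors.
        "abs_cosine" is the unsigned baseline: the same similarity computed on
        |z| values (all weights >= 0).  "shared_count" is the literature
        baseline: number of shared SNPs, normalized by the maximum over pairs.

    Attributes
    ----------
    n_cancelled_ : int
        Pairs sharing >= 1 SNP whose mixed-sign products cancelled to weight
        exactly 0 (dropped as edges); only meaningful for mode="signed".
    n_isolated_ : int
        Diseases with no stored SNPs (zero norm); their similarities are 0.
    """

    def __init__(self, mode: str = "signed"):
        self.mode = mode

    def fit(self, X: AssociationMatrix | sparse.spmatrix, y=None):
        if self.mode not in ("signed",) + UNSIGNED_MODES:
            raise ValueError(f"unknown mode {self.mode!r}")
        self.n_features_in_ = (X.shape if hasattr(X, "shape") else np.shape(X))[1]
        return self

    def transform(self, X: AssociationMatrix | sparse.spmatrix) -> np.ndarray:
        self.fit(X)
        Z = X.values if isinstance(X, AssociationMatrix) else sparse.csr_matrix(X)
        Z = sparse.csr_matrix(Z, dtype=float)
        m = Z.shape[0]
        if m == 0:
            raise ValueError("empty association matrix")
        support = (Z != 0).astype(np.int64)
        shared = np.asarray((support @ support.T).todense())

        if self.mode == "shared_count":
            W = shared.astype(float)
            np.fill_diagonal(W, 0.0)
            mx = W.max()
            if mx > 0:
                W /= mx
            self.n_cancelled_ = 0
            self.n_isolated_ = int((support.sum(axis=1) == 0).sum())
            return W

        if self.mode == "abs_cosine":
            Z = abs(Z)
        norms = np.sqrt(np.asarray(Z.multiply(Z).sum(axis=1)).ravel())
        self.n_isolated_ = int((norms == 0).sum())
        if self.n_isolated_:
            logger.info("%d disease(s) with no stored SNPs; similarities set to 0",
                        self.n_isolated_)
        safe = np.where(norms > 0, norms, 1.0)
        W = np.asarray((Z @ Z.T).todense()) / np.outer(safe, safe)
        W[norms == 0, :] = 0.0
        W[:, norms == 0] = 0.0
        np.fill_diagonal(W, 0.0)
        # numerical guard: |w| <= 1 exactly (Cauchy-Schwarz can overshoot in fp)
        np.clip(W, -1.0, 1.0, out=W)
        iu = np.triu_indices(m, k=1)
        self.n_cancelled_ = int(np.sum((shared[iu] > 0) & (W[iu] == 0.0)))
        if self.n_cancelled_:
            logger.info("%d pair(s) with shared SNPs cancelled to weight 0", self.n_cancelled_)
        return W


def pair_similarity(R: AssociationMatrix, i: int, j: int) -> float:
    """Signed similarity between diseases i and j of the association matrix.

    Returns 0 when the diseases share no SNPs or either has none stored.  The
    diagnostic self-similarity pair_similarity(R, i, i) is 1 for any disease
    with stored SNPs (cosine of a vector with itself).
    """
    ri = np.asarray(R.values.getrow(i).todense()).ravel()
    rj = np.asarray(R.values.getrow(j).todense()).ravel()
    ni, nj = np.linalg.norm(ri), np.linalg.norm(rj)
    if ni == 0 or nj == 0:
        logger.info("disease %s has no stored SNPs; similarity defined as 0",
                    R.phenotypes[i] if ni == 0 else R.phenotypes[j])
        return 0.0
    return float(np.dot(ri, rj) / (ni * nj))


def build_signed_network(R: AssociationMatrix) -> SignedGraph:
    """Construct the signed disease-disease network from the z-score matrix."""
    W = SignedNetworkBuilder(mode="signed").transform(R)
    return SignedGraph(list(R.phenotypes), W)


def build_unsigned_network(R: AssociationMatrix, mode: str = "abs_cosine") -> SignedGraph:
    """Construct the unsigned baseline network (all weights >= 0)."""
    if mode not in UNSIGNED_MODES:
        raise ValueError(f"unknown unsigned mode {mode!r}; choose from {UNSIGNED_MODES}")
    W = SignedNetworkBuilder(mode=mode).transform(R)
    return SignedGraph(list(R.phenotypes), W)


def edge_census(G: SignedGraph) -> EdgeCensus:
    """Count nodes, edges and sign composition of a signed graph."""
    if G.n_nodes < 2:
        raise ValueError("edge census requires at least 2 nodes")
    iu = np.triu_indices(G.n_nodes, k=1)
    w = G.weights[iu]
    return EdgeCensus(
        n_nodes=G.n_nodes,
        n_edges=int(np.sum(w != 0)),
        n_synergistic=int(np.sum(w > 0)),
        n_antagonistic=int(np.sum(w < 0)),
    )
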