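"""Candidate-gene expression and network statistics.

Builds a functional network of candidate genes from two evidence layers —
brain coexpression (Pearson |R| above a threshold, default 0.8) and
protein-protein interaction edges above a combined-score cutoff (default
400, strict) — and computes the statistics asked of such a network:
typed degrees, the correlation between a gene's connectivity and the number
of disorders it carries putative-functional DNMs in ("pleiotropy"),
module-membership Fisher enrichment of per-disorder gene sets, and a
logistic trend test of module membership on the number of shared disorders.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .burden import bh_adjust, odds_ratio_ci

logger = logging.getLogger(__name__)

DEFAULT_R_THRESHOLD = 0.8
DEFAULT_PPI_MIN_SCORE = 400.0


def coexpression_edges(
    expr: pd.DataFrame, threshold: float = DEFAULT_R_THRESHOLD
) -> pd.DataFrame:
    """Coexpression edges: unordered gene pairs with Pearson |R| > threshold.

    ``expr`` is genes x samples.  Genes with constant expression have no
    defined correlation and are excluded with a warning.  The threshold is
    strict.  Returns columns gene_a, gene_b, r, weight (=|r|).
    """
    if expr.shape[1] < 3:
        raise ValueError("need at least 3 samples to correlate")
    values = expr.to_numpy(dtype=float)
    sd = values.std(axis=1)
    keep = sd > 0
    if not keep.all():
        logger.warning("%d constant-expression gene(s) excluded", int((~keep).sum()))
    genes = expr.index[keep].to_numpy()
    values = values[keep]
    if len(genes) < 2:
        return pd.DataFrame(columns=["gene_a", "gene_b", "r", "weight"])
    r = np.corrcoef(values)
    iu = np.triu_indices(len(genes), k=1)
    mask = np.abs(r[iu]) > threshold
    return pd.DataFrame(
        {
            "gene_a": genes[iu[0][mask]],
            "gene_b": genes[iu[1][mask]],
            "r": r[iu][mask],
            "weight": np.abs(r[iu][mask]),
        }
    )


def filter_ppi(
    ppi: pd.DataFrame,
    min_score: float = DEFAULT_PPI_MIN_SCORE,
    strict: bool = True,
) -> pd.DataFrame:
    """Filter a PPI edge table on combined score.

    Self-edges are dropped with a warning; symmetric duplicates collapse to
    one undirected edge keeping the maximum score.  ``strict`` keeps only
    scores > min_score (set False for >=).
    """
    df = ppi.rename(columns=str.lower).copy()
    for col in ("gene_a", "gene_b", "combined_score"):
        if col not in df.columns:
            raise ValueError(f"PPI table missing column {col!r}")
    df["combined_score"] = pd.to_numeric(df["combined_score"])
    self_edges = df["gene_a"] == df["gene_b"]
    if self_edges.any():
        logger.warning("%d self-edge(s) dropped from PPI table", int(self_edges.sum()))
        df = df[~self_edges]
    lo = df[["gene_a", "gene_b"]].min(axis=1)
    hi = df[["gene_a", "gene_b"]].max(axis=1)
    df = df.assign(gene_a=lo, gene_b=hi)
    df = (
        df.groupby(["gene_a", "gene_b"], as_index=False)["combined_score"].max()
    )
    kept = df["combined_score"] > min_score if strict else df["combined_score"] >= min_score
    out = df[kept].reset_index(drop=True)
    out["weight"] = out["combined_score"]
    return out


@dataclass
class NetworkGraph:
    """Undirected multigraph of candidate genes with typed edges.

    Edge keys are the evidence type ("coexpression" or "ppi"); nodes carry
    the annotation columns supplied at merge time (n_disorders, tier, ...).
    """

    graph: nx.MultiGraph

    @property
    def nodes(self) -> list[str]:
        return list(self.graph.nodes)

    def typed_degree(self, edge_type: str) -> pd.Series:
        deg = {n: 0 for n in self.graph.nodes}
        for u, v, k in self.graph.edges(keys=True):
            if k == edge_type:
                deg[u] += 1
                deg[v] += 1
        return pd.Series(deg, name=f"degree_{edge_type}")

    def node_table(self) -> pd.DataFrame:
        rows = {n: dict(self.graph.nodes[n]) for n in self.graph.nodes}
        out = pd.DataFrame.from_dict(rows, orient="index")
        out["degree_coexpression"] = self.typed_degree("coexpression")
        out["degree_ppi"] = self.typed_degree("ppi")
        out["degree_total"] = out["degree_coexpression"] + out["degree_ppi"]
        out.index.name = "gene"
        return out

    def connected_fraction(self) -> float:
        """Fraction of annotated genes with at least one edge of either type."""
        degrees = dict(self.graph.degree())
        return float(np.mean([degrees[n] > 0 for n in self.graph.nodes]))


def merge_network(
    coexpr_edges: pd.DataFrame,
    ppi_edges: pd.DataFrame,
    annotations: pd.DataFrame,
) -> NetworkGraph:
    """Union of the coexpression and PPI layers over annotated genes.

    ``annotations`` (indexed by gene) must cover every gene on an edge;
    annotated genes without edges remain as degree-0 nodes.  No self-loops
    or duplicate (pair, type) edges survive the merge.
    """
    g = nx.MultiGraph()
    for gene, row in annotations.iterrows():
        g.add_node(gene, **row.to_dict())
    known = set(annotations.index)
    for edge_type, table in (("coexpression", coexpr_edges), ("ppi", ppi_edges)):
        if table is None or len(table) == 0:
            continue
        for _, row in table.iterrows():
            u, v = row["gene_a"], row["gene_b"]
            if u == v:
                continue
            for node in (u, v):
                if node not in known:
                    raise KeyError(f"edge gene {node!r} has no annotation")
            if not g.has_edge(u, v, key=edge_type):
                g.add_edge(u, v, key=edge_type, weight=float(row.get("weight", 1.0)))
    return NetworkGraph(graph=g)


@dataclass(frozen=True)
class CorrelationResult:
    rho: float
    p: float
    n: int
    degenerate: bool = False


def degree_vs_shared(
    net: NetworkGraph, annotation: str = "n_disorders"
) -> dict[str, CorrelationResult]:
    """Spearman correlation of typed degree with the pleiotropy annotation.

    Returns one result per edge type ("coexpression", "ppi").  Mid-ranks
    handle ties; p is the large-sample approximation.  All-tied inputs are
    degenerate and flagged (rho NaN).
    """
    ann = pd.Series(
        {n: net.graph.nodes[n].get(annotation) for n in net.graph.nodes}, dtype=float
    )
    if ann.isna().any():
        raise ValueError(f"every node needs a {annotation!r} annotation")
    if len(ann) < 3:
        raise ValueError("need at least 3 annotated nodes")
    out = {}
    for edge_type in ("coexpression", "ppi"):
        deg = net.typed_degree(edge_type).reindex(ann.index)
        if deg.nunique() <= 1 or ann.nunique() <= 1:
            out[edge_type] = CorrelationResult(np.nan, np.nan, len(ann), degenerate=True)
            continue
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            rho, p = stats.spearmanr(deg.to_numpy(), ann.to_numpy())
        out[edge_type] = CorrelationResult(float(rho), float(p), len(ann))
    return out


def module_enrichment(
    gene_set: Sequence[str],
    modules: Mapping[str, str] | pd.Series,
    background: Sequence[str],
) -> pd.DataFrame:
    """Fisher enrichment of a gene set in each coexpression module.

    Contingency per module, within the stated background: genes in-set and
    in-module (k), in-set out-of-module, out-of-set in-module, neither.
    ORs use the Haldane correction on zero cells; BH across modules.
    """
    background = set(background)
    if not background:
        raise ValueError("background is empty")
    gene_set = set(gene_set)
    if not gene_set <= background:
        raise ValueError("gene_set must be a subset of the background")
    modules = pd.Series(modules)
    modules = modules[modules.index.isin(background)]
    rows = []
    for module in sorted(modules.unique()):
        members = set(modules.index[modules == module])
        k = len(gene_set & members)
        a, b = k, len(gene_set) - k
        c = len(members) - k
        d = len(background) - len(gene_set) - c
        p = float(stats.fisher_exact([[a, b], [c, d]])[1])
        orci = odds_ratio_ci(a, b, c, d)
        rows.append(
            {
                "module": module, "k": k,
                "set_size": len(gene_set), "module_size": len(members),
                "background_size": len(background),
                "odds_ratio": orci.odds_ratio, "p": p,
            }
        )
    out = pd.DataFrame(rows)
    if len(out):
        out["p_adj"] = bh_adjust(out["p"].to_numpy())
    return out


@dataclass(frozen=True)
class TrendResult:
    """Logistic trend of a binary gene property on the shared-disorder count."""

    slope: float
    p: float
    separation: bool
    method: str  # "lr" (likelihood ratio) or "score" (separation fallback)


def shared_trend_test(indicator: Sequence, n_disorders: Sequence) -> TrendResult:
    """Logistic trend test of a binary indicator on an ordinal predictor.

    Fits logit P(y=1) = a + b*score by maximum likelihood and reports the
    likelihood-ratio p for b.  Under perfect separation the MLE diverges;
    the slope sign is kept, the result is flagged, and the p-value falls
    back to the (always defined) Cochran-Armitage-style score test.
    """
    import statsmodels.api as sm

    y = np.asarray(indicator, dtype=float)
    x = np.asarray(n_disorders, dtype=float)
    if set(np.unique(y)) - {0.0, 1.0}:
        raise ValueError("indicator must be binary")
    if len(np.unique(y)) < 2:
        raise ValueError("indicator has a single level; no trend to test")
    X = sm.add_constant(x)
    separation = False
    slope = np.nan
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = sm.Logit(y, X).fit(disp=False, maxiter=200)
        slope = float(fit.params[1])
        converged = bool(fit.mle_retvals.get("converged", True))
        if not converged or abs(slope) > 25:
            separation = True
    except Exception:  # pragma: no cover - statsmodels raises on hard separation
        separation = True
    if not separation:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            null = sm.Logit(y, np.ones((len(y), 1))).fit(disp=False)
        lr = 2.0 * (fit.llf - null.llf)
        p = float(stats.chi2.sf(max(lr, 0.0), df=1))
        return TrendResult(slope=slope, p=p, separation=False, method="lr")
    # score (Cochran-Armitage) test: defined regardless of separation
    p_bar = y.mean()
    u = np.sum((y - p_bar) * (x - x.mean()))
    var = p_bar * (1 - p_bar) * np.sum((x - x.mean()) ** 2)
    z = u / np.sqrt(var)
    p = float(stats.chi2.sf(z**2, df=1))
    if np.isnan(slope):
        slope = np.inf if z > 0 else -np.inf
    return TrendResult(slope=slope, p=p, separation=True, method="score")
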