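"""TADA-Denovo: Bayesian gene prioritisation from de novo mutation counts.

Model
-----
For a gene with per-class mutation rate mu and N sequenced trios, the DNM
count of a class is Poisson(2*N*mu) under the null.  In a risk gene the
rate is multiplied by a relative risk gamma drawn from a
Gamma(shape=gamma_bar*beta, rate=beta) prior, so the marginal under the
alternative is a gamma-Poisson (negative binomial) and the Bayes factor has
the closed form

    log BF = lgamma(x + gb) - lgamma(gb) + gb*log(beta/(beta+lam0))
             - x*log(beta+lam0) + lam0,        gb = gamma_bar*beta,
             lam0 = 2*N*mu.

Evidence over classes multiplies (log BFs add).  Genes are ranked by total
BF and the Bayesian FDR q-value of a gene is the running mean of the
posterior null probabilities P0 = (1-pi)/((1-pi) + pi*BF) down the ranking.

Two strategies are run: per-disorder, and combined (counts and trios pooled
over all case cohorts); a gene is a candidate when q < 0.05 in either, and
candidates tier by their best q.  Candidate genes with putative-functional
(Pfun) DNMs in >= 2 disorders are "shared", in exactly one "unique"; an
exact conditional Poisson test flags shared genes whose DNM rate is biased
toward one disorder.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import gammaln

from .burden import bh_adjust

logger = logging.getLogger(__name__)

Q_CANDIDATE = 0.05

#: Tier boundaries on q: tier 1 q <= 1e-4, tier 2 (1e-4, 1e-3], tier 3
#: (1e-3, 1e-2], tier 4 (1e-2, 0.05); "none" at q >= 0.05.
TIER_EDGES = (1e-4, 1e-3, 1e-2, Q_CANDIDATE)


@dataclass(frozen=True)
class TadaHyperparams:
    """Prior hyperparameters of the gamma-Poisson model.

    ``pi`` is the prior fraction of risk genes; ``gamma_bar[c]`` the prior
    mean relative risk of class ``c`` and ``beta[c]`` the gamma-prior rate.
    ``classes`` selects the evidence classes: the two-class TADA convention
    ("LoF", "Dmis") or the single aggregate ("Pfun",) — the default here.
    The Pfun prior mean (10.6) is the mutation-count-weighted mean of the
    LoF (20) and Dmis (4.7) literature defaults.
    """

    pi: float = 0.05
    gamma_bar: Mapping[str, float] = field(
        default_factory=lambda: {"LoF": 20.0, "Dmis": 4.7, "Pfun": 10.6}
    )
    beta: Mapping[str, float] = field(
        default_factory=lambda: {"LoF": 1.0, "Dmis": 1.0, "Pfun": 1.0}
    )
    classes: tuple[str, ...] = ("Pfun",)

    def __post_init__(self) -> None:
        if not 0.0 < self.pi < 1.0:
            raise ValueError(f"pi must be in (0, 1), got {self.pi}")
        if not self.classes:
            raise ValueError("classes must be non-empty")
        for c in self.classes:
            if self.gamma_bar.get(c, 0.0) < 1.0:
                raise ValueError(f"gamma_bar[{c}] must be >= 1")
            if self.beta.get(c, 0.0) <= 0.0:
                raise ValueError(f"beta[{c}] must be > 0")


def log_bf_class(x, mu, n_trios, gamma_bar: float, beta: float):
    """Closed-form log Bayes factor for one variant class (vectorised in x, mu).

    ``x`` is the observed DNM count, ``mu`` the per-chromosome per-generation
    mutation rate, ``n_trios`` the number of trios (lambda0 = 2*N*mu).
    """
    x = np.asarray(x)
    if np.any(x < 0) or not np.issubdtype(np.asarray(x).dtype, np.integer) and np.any(x != np.floor(x)):
        raise ValueError("counts must be non-negative integers")
    x = x.astype(float)
    mu = np.asarray(mu, dtype=float)
    if np.any(mu <= 0) or n_trios <= 0 or gamma_bar <= 0 or beta <= 0:
        raise ValueError("mu, n_trios, gamma_bar, beta must all be positive")
    lam0 = 2.0 * n_trios * mu
    gb = gamma_bar * beta
    out = (
        gammaln(x + gb)
        - gammaln(gb)
        + gb * np.log(beta / (beta + lam0))
        - x * np.log(beta + lam0)
        + lam0
    )
    return out if out.ndim else float(out)


def gene_bf(
    counts: Mapping[str, int],
    rates: Mapping[str, float],
    n_trios: int,
    params: TadaHyperparams,
) -> float:
    """Total log Bayes factor of one gene: sum of per-class log BFs.

    Classes with zero mutation rate are excluded with a warning (their
    Bayes factor is undefined); a class missing from ``rates`` is an error.
    """
    total = 0.0
    for c in params.classes:
        if c not in rates:
            raise KeyError(f"no mutation rate for class {c!r}")
        if rates[c] <= 0:
            logger.warning("class %s has zero rate; excluded from Bayes factor", c)
            continue
        total += float(
            log_bf_class(counts.get(c, 0), rates[c], n_trios,
                         params.gamma_bar[c], params.beta[c])
        )
    return total


def bayesian_fdr(log_bfs: Sequence[float], pi: float) -> np.ndarray:
    """Bayesian FDR q-values from log Bayes factors, in input order.

    P0_i = (1-pi)/((1-pi) + pi*BF_i); genes are sorted by decreasing BF and
    q_i is the mean P0 over the top-i genes.  Tied BFs share the q of the
    last (most conservative) tied position.
    """
    if not 0.0 < pi < 1.0:
        raise ValueError("pi must be in (0, 1)")
    lb = np.asarray(log_bfs, dtype=float)
    if lb.size == 0:
        return lb
    # log P0 = log(1-pi) - logaddexp(log(1-pi), log(pi) + logBF), stable for huge BF
    log_null = math.log1p(-pi)
    p0 = np.exp(log_null - np.logaddexp(log_null, math.log(pi) + lb))
    order = np.argsort(-lb, kind="stable")
    q_sorted = np.cumsum(p0[order]) / np.arange(1, lb.size + 1)
    # ties: propagate the q of the last member of each equal-BF block backwards
    lb_sorted = lb[order]
    for i in range(lb.size - 2, -1, -1):
        if lb_sorted[i] == lb_sorted[i + 1]:
            q_sorted[i] = q_sorted[i + 1]
    q = np.empty_like(q_sorted)
    q[order] = q_sorted
    return q


def assign_tiers(q) -> np.ndarray:
    """Candidate tier (1-4) from q; 0 encodes "none" (q >= 0.05)."""
    q = np.asarray(q, dtype=float)
    if np.any((q < 0) | (q > 1)):
        raise ValueError("q must lie in [0, 1]")
    tier = np.zeros(q.shape, dtype=int)
    tier[q < TIER_EDGES[3]] = 4
    tier[q <= TIER_EDGES[2]] = 3
    tier[q <= TIER_EDGES[1]] = 2
    tier[q <= TIER_EDGES[0]] = 1
    return tier


def classify_shared_unique(pfun_counts: Sequence[int]) -> tuple[int, str]:
    """Number of disorders with >= 1 Pfun DNM, and shared/unique status.

    "shared" means Pfun DNMs observed in at least two disorders; "unique"
    exactly one; "none" zero (inconsistent for a candidate gene — flagged
    by callers).
    """
    counts = np.asarray(pfun_counts)
    if np.any(counts < 0):
        raise ValueError("counts must be non-negative")
    n = int((counts > 0).sum())
    if n == 0:
        return 0, "none"
    return n, ("unique" if n == 1 else "shared")


def poisson_bias_test(x_d: int, n_d: int, x_rest: int, n_rest: int) -> float:
    """Exact conditional test for excess per-trio DNM rate in one disorder.

    Conditional on the total count, x_d ~ Binomial(x_d + x_rest,
    N_d/(N_d + N_rest)) under equal rates; returns the one-sided
    P(X >= x_d).
    """
    if n_d <= 0 or n_rest <= 0:
        raise ValueError("trio counts must be positive")
    if x_d < 0 or x_rest < 0 or x_d + x_rest < 1:
        raise ValueError("need at least one DNM in total")
    total = x_d + x_rest
    frac = n_d / (n_d + n_rest)
    return float(stats.binom.sf(x_d - 1, total, frac))


def _class_counts(df: pd.DataFrame, cls: str) -> pd.Series:
    if cls == "Pfun":
        return df.get("LoF", 0) + df.get("Dmis", 0)
    if cls not in df.columns:
        return pd.Series(0, index=df.index)
    return df[cls]


def _class_rates(rates: pd.DataFrame, cls: str) -> pd.Series:
    if cls == "Pfun":
        return rates["LoF"] + rates["Dmis"]
    if cls not in rates.columns:
        raise KeyError(f"no mutation rate column for class {cls!r}")
    return rates[cls]


def run_tada(
    counts: Mapping[str, pd.DataFrame],
    trios: Mapping[str, int],
    rates: pd.DataFrame,
    params: TadaHyperparams | None = None,
    mode: str = "both",
    q_threshold: float = Q_CANDIDATE,
) -> pd.DataFrame:
    """Run TADA-Denovo over case cohorts and prioritise candidate genes.

    Parameters
    ----------
    counts
        Mapping cohort label -> per-gene class-count DataFrame (as from
        :func:`dnmcross.classify.gene_class_counts`); case cohorts only.
    trios
        Trio totals per cohort.
    rates
        Per-gene mutation rates, indexed by gene, columns per class
        (LoF, Dmis, ...); defines the gene universe.
    mode
        "per_disorder", "combined" or "both".  Combined pools counts and
        trios over all case cohorts.  Candidates are the union of q <
        ``q_threshold`` calls across the strategies run.

    Returns a per-gene DataFrame with per-cohort Pfun counts, log BFs and
    q-values per strategy, the best q, candidacy, tier, the number of
    disorders with Pfun DNMs and shared/unique status.
    """
    if params is None:
        params = TadaHyperparams()
    if mode not in {"per_disorder", "combined", "both"}:
        raise ValueError(f"unknown mode {mode!r}")
    genes = rates.index
    cohorts = list(counts)
    aligned = {
        lab: df.reindex(genes, fill_value=0) for lab, df in counts.items()
    }
    out = pd.DataFrame(index=genes)
    out.index.name = "gene"
    pfun_by_cohort = pd.DataFrame(
        {lab: _class_counts(df, "Pfun") for lab, df in aligned.items()}
    )
    for lab in cohorts:
        out[f"pfun_{lab}"] = pfun_by_cohort[lab]

    q_cols = []
    if mode in {"per_disorder", "both"}:
        for lab in cohorts:
            lbf = np.zeros(len(genes))
            for c in params.classes:
                lbf += log_bf_class(
                    _class_counts(aligned[lab], c).to_numpy(),
                    _class_rates(rates, c).to_numpy(),
                    trios[lab], params.gamma_bar[c], params.beta[c],
                )
            out[f"log_bf_{lab}"] = lbf
            out[f"q_{lab}"] = bayesian_fdr(lbf, params.pi)
            q_cols.append(f"q_{lab}")
    if mode in {"combined", "both"}:
        n_total = sum(trios[lab] for lab in cohorts)
        lbf = np.zeros(len(genes))
        for c in params.classes:
            x = sum(_class_counts(aligned[lab], c).to_numpy() for lab in cohorts)
            lbf += log_bf_class(
                x, _class_rates(rates, c).to_numpy(), n_total,
                params.gamma_bar[c], params.beta[c],
            )
        out["log_bf_combined"] = lbf
        out["q_combined"] = bayesian_fdr(lbf, params.pi)
        q_cols.append("q_combined")

    out["q_best"] = out[q_cols].min(axis=1)
    out["candidate"] = out["q_best"] < q_threshold
    out["tier"] = assign_tiers(out["q_best"].to_numpy())
    shared = [classify_shared_unique(row) for row in pfun_by_cohort.to_numpy()]
    out["n_disorders"] = [s[0] for s in shared]
    out["status"] = [s[1] for s in shared]
    inconsistent = out["candidate"] & (out["n_disorders"] == 0)
    if inconsistent.any():
        logger.warning(
            "%d candidate gene(s) without any Pfun DNM (flagged 'none')",
            int(inconsistent.sum()),
        )
    return out


def bias_table(
    results: pd.DataFrame,
    counts: Mapping[str, pd.DataFrame],
    trios: Mapping[str, int],
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Disorder-bias tests for shared candidate genes.

    For every candidate gene with Pfun DNMs in >= 2 disorders, each disorder
    is tested against the pooled others with the exact conditional Poisson
    test; p-values are BH-adjusted across all tests in the table.
    """
    cohorts = list(counts)
    genes = results.index[results["candidate"] & (results["status"] == "shared")]
    rows = []
    for g in genes:
        x = {lab: int(results.loc[g, f"pfun_{lab}"]) for lab in cohorts}
        total = sum(x.values())
        for lab in cohorts:
            n_d = trios[lab]
            n_rest = sum(trios[o] for o in cohorts if o != lab)
            rows.append(
                {
                    "gene": g,
                    "disorder": lab,
                    "x_disorder": x[lab],
                    "x_rest": total - x[lab],
                    "p": poisson_bias_test(x[lab], n_d, total - x[lab], n_rest),
                }
            )
    out = pd.DataFrame(rows, columns=["gene", "disorder", "x_disorder", "x_rest", "p"])
    if len(out):
        out["p_adj"] = bh_adjust(out["p"].to_numpy())
        out["biased"] = out["p_adj"] < alpha
    else:
        out["p_adj"] = []
        out["biased"] = []
    return out
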