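"""Independent reference implementations used only to check the package.

Every function here recomputes a quantity by brute force — exhaustive
enumeration, direct definitions, or adaptive numerical integration — and is
deliberately kept independent of the code paths it validates.
"""

import itertools

import numpy as np
from scipy import integrate, stats


def fisher_enum(a: int, b: int, c: int, d: int) -> float:
    """Two-tailed Fisher p by exhaustive enumeration over fixed margins.

    Sums hypergeometric probabilities of every table with the observed
    margins whose probability does not exceed the observed one (with the
    customary 1+1e-7 tie tolerance of exact-test implementations).
    """
    row1, col1, n = a + b, a + c, a + b + c + d
    k_min = max(0, row1 + col1 - n)
    k_max = min(row1, col1)
    ks = np.arange(k_min, k_max + 1)
    pmf = stats.hypergeom.pmf(ks, n, col1, row1)
    p_obs = stats.hypergeom.pmf(a, n, col1, row1)
    return float(pmf[pmf <= p_obs * (1 + 1e-7)].sum())


def bh_naive(p_values) -> np.ndarray:
    """Benjamini-Hochberg adjusted p straight from the step-up definition.

    q_(i) = min_{j >= i} m * p_(j) / j over the sorted p-values, capped at 1.
    O(m^2), independent of any library implementation.
    """
    p = np.asarray(p_values, dtype=float)
    m = p.size
    order = np.argsort(p, kind="stable")
    q = np.empty(m)
    for rank_i, idx in enumerate(order, start=1):
        candidates = [
            m * p[order[j - 1]] / j for j in range(rank_i, m + 1)
        ]
        q[idx] = min(1.0, min(candidates))
    return q


def log_bf_quadrature(x: int, lam0: float, gamma_bar: float, beta: float) -> float:
    """Gamma-Poisson log Bayes factor by adaptive quadrature over gamma.

    Integrates Poisson(x; lam0*g)/Poisson(x; lam0) against the
    Gamma(gamma_bar*beta, rate=beta) prior density, with breakpoints at the
    prior mean and the integrand mode so narrow peaks are not missed.
    """
    shape = gamma_bar * beta
    mean = gamma_bar
    sd = np.sqrt(shape) / beta

    def integrand(g):
        if g <= 0:
            return 0.0
        return np.exp(
            x * np.log(g) - lam0 * (g - 1.0)
            + stats.gamma.logpdf(g, a=shape, scale=1.0 / beta)
        )

    hi = mean + 50 * sd + 20 * max(x, 1) / max(lam0 + beta, 1e-12) + 50
    pts = [max(mean - 5 * sd, 0.0), mean, mean + 5 * sd]
    if x + shape > 1:
        pts.append((x + shape - 1) / (lam0 + beta))
    pts = sorted({p for p in pts if 0 < p < hi})
    val, _ = integrate.quad(
        integrand, 0, hi, limit=800, epsabs=0, epsrel=1e-11, points=pts
    )
    return float(np.log(val))


def overlap_expectation_enum(n1: int, n2: int, weights) -> float:
    """Exact expected distinct-gene overlap by enumerating all assignments.

    Every ordered assignment of n1 hits and n2 hits to the weighted universe
    is enumerated with its probability; feasible only for tiny universes.
    """
    w = np.asarray(weights, dtype=float)
    p = w / w.sum()
    genes = range(len(w))
    total = 0.0
    for assign1 in itertools.product(genes, repeat=n1):
        p1 = np.prod([p[g] for g in assign1])
        s1 = set(assign1)
        for assign2 in itertools.product(genes, repeat=n2):
            p2 = np.prod([p[g] for g in assign2])
            total += p1 * p2 * len(s1 & set(assign2))
    return total


def pearson_edges_bruteforce(expr, threshold: float) -> set:
    """Pairwise-by-pair recomputation of the |R|-thresholded edge set."""
    edges = set()
    for ga, gb in itertools.combinations(expr.index, 2):
        xa = expr.loc[ga].to_numpy(float)
        xb = expr.loc[gb].to_numpy(float)
        if xa.std() == 0 or xb.std() == 0:
            continue
        r = np.corrcoef(xa, xb)[0, 1]
        if abs(r) > threshold:
            edges.add((min(ga, gb), max(ga, gb)))
    return edges


def hypergeom_or_p(k: int, set_size: int, module_size: int, background: int):
    """Two-sided enrichment p and OR from the hypergeometric law directly."""
    a, b = k, set_size - k
    c, d = module_size - k, background - set_size - module_size + k
    p = fisher_enum(a, b, c, d)
    or_ = (a * d) / (b * c) if b and c else np.inf
    return or_, p
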