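"""Synthetic trio-cohort generator under the gamma-Poisson risk-gene model.

The generator emulates the data a cross-disorder DNM meta-analysis
consumes: per-gene per-class mutation rates with log-normal heterogeneity
across genes (a coarse stand-in for gene length and trinucleotide context),
risk genes per disorder drawn partly from a common cross-disorder pool, and
per-gene DNM counts x ~ Poisson(2 * N * mu * gamma) with gamma drawn from
the same Gamma(gamma_bar*beta, beta) prior that the TADA Bayes factor
integrates.  Toy expression matrices, module labels and PPI tables make the
downstream network statistics testable without any external download.

Default marginal per-trio class rates reproduce a published control cohort
of 3391 trios with 411 LoF, 2257 missense and 932 synonymous DNMs; default
case cohorts mirror the five disorders of that compilation (ASD, UDD, EE,
ID, SCZ) at their published trio counts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterator, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .classify import DNMRecord, DEFAULT_DMIS_THRESHOLD

logger = logging.getLogger(__name__)

#: Published control-cohort marginals: 411 LoF, 662+1595 missense and 932
#: synonymous DNMs over 3391 trios.
CONTROL_TRIOS = 3391
DEFAULT_PER_TRIO_RATE = {
    "LoF": 411 / CONTROL_TRIOS,
    "mis": (662 + 1595) / CONTROL_TRIOS,
    "synonymous": 932 / CONTROL_TRIOS,
}
#: Fraction of control missense DNMs predicted deleterious (662 of 2257).
DEFAULT_DMIS_FRACTION = 662 / (662 + 1595)

DEFAULT_COHORTS = (
    ("ASD", 6511),
    ("UDD", 4293),
    ("EE", 933),
    ("ID", 1022),
    ("SCZ", 1094),
)

SIM_CLASSES = ("LoF", "Dmis", "Tmis", "synonymous")
RISK_CLASSES = ("LoF", "Dmis")

_LOF_CONSEQUENCE_CHOICES = ("frameshift", "stopgain", "splicing", "stoploss")
_LOF_CONSEQUENCE_PROBS = (0.40, 0.35, 0.20, 0.05)


class ConfigurationError(ValueError):
    """A simulation configuration violates its invariants."""


@dataclass
class SimulationConfig:
    """Full specification of one synthetic study.

    Serialising to YAML and reloading reproduces identical simulations
    under the same seed.
    """

    n_genes: int = 2000
    cohorts: list[tuple[str, int]] = field(
        default_factory=lambda: [list(c) for c in DEFAULT_COHORTS]
    )
    control_trios: int = CONTROL_TRIOS
    per_trio_rate: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_PER_TRIO_RATE)
    )
    dmis_fraction: float = DEFAULT_DMIS_FRACTION
    pi: dict[str, float] = field(
        default_factory=lambda: {name: 0.05 for name, _ in DEFAULT_COHORTS}
    )
    shared_pool_fraction: float = 0.5
    gamma_bar: dict[str, float] = field(
        default_factory=lambda: {"LoF": 20.0, "Dmis": 4.7}
    )
    beta: float = 1.0
    mu_sigma: float = 1.0  # log-normal sigma of per-gene mutability
    dmis_threshold: float = DEFAULT_DMIS_THRESHOLD
    seed: int = 0

    def __post_init__(self) -> None:
        self.cohorts = [(str(n), int(t)) for n, t in self.cohorts]
        if self.n_genes < 1:
            raise ConfigurationError("n_genes must be >= 1")
        if self.control_trios < 1 or any(t < 1 for _, t in self.cohorts):
            raise ConfigurationError("all trio counts must be positive")
        for cls in ("LoF", "mis", "synonymous"):
            if self.per_trio_rate.get(cls, 0.0) <= 0:
                raise ConfigurationError(f"per_trio_rate[{cls}] must be > 0")
        for name, value in (
            ("dmis_fraction", self.dmis_fraction),
            ("shared_pool_fraction", self.shared_pool_fraction),
            *((f"pi[{k}]", v) for k, v in self.pi.items()),
        ):
            if not 0.0 <= value <= 1.0:
                raise ConfigurationError(f"{name} must lie in [0, 1]")
        if any(g < 1.0 for g in self.gamma_bar.values()):
            raise ConfigurationError("gamma_bar values must be >= 1")
        if self.beta <= 0:
            raise ConfigurationError("beta must be > 0")
        missing = [n for n, _ in self.cohorts if n not in self.pi]
        if missing:
            raise ConfigurationError(f"pi missing for cohort(s): {missing}")

    # -- serialisation ------------------------------------------------------
    def to_yaml(self, path: str | Path) -> None:
        data = asdict(self)
        data["cohorts"] = [list(c) for c in self.cohorts]
        Path(path).write_text(yaml.safe_dump(data, sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimulationConfig":
        data = yaml.safe_load(Path(path).read_text())
        return cls(**data)


@dataclass(frozen=True)
class GeneModel:
    """Per-gene mutation rates, risk flags and relative risks."""

    gene_id: str
    mu: Mapping[str, float]  # class -> per-chromosome per-generation rate
    risk_status: Mapping[str, bool]
    rel_risk: Mapping[tuple[str, str], float]  # (disorder, class) -> gamma


class GeneUniverse:
    """Vectorised container for all gene models of one simulation.

    ``mu`` is genes x class (LoF, Dmis, Tmis, synonymous); ``risk_status``
    genes x disorder booleans; ``rel_risk[cls]`` genes x disorder gammas
    (1.0 everywhere risk_status is False, and always for Tmis/synonymous).
    """

    def __init__(self, mu: pd.DataFrame, disorders: Sequence[str]):
        self.mu = mu
        self.genes = list(mu.index)
        self.disorders = list(disorders)
        self.risk_status = pd.DataFrame(
            False, index=mu.index, columns=self.disorders
        )
        self.rel_risk = {
            cls: pd.DataFrame(1.0, index=mu.index, columns=self.disorders)
            for cls in RISK_CLASSES
        }

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    def gamma(self, disorder: str, cls: str) -> np.ndarray:
        """Relative-risk vector for a (disorder, class); 1.0 for non-risk classes."""
        if disorder == "control" or cls not in RISK_CLASSES:
            return np.ones(self.n_genes)
        if disorder not in self.disorders:
            raise KeyError(f"unknown disorder {disorder!r}")
        return self.rel_risk[cls][disorder].to_numpy()

    def rates_table(self) -> pd.DataFrame:
        out = self.mu.rename(
            columns={"LoF": "mu_lof", "Dmis": "mu_dmis",
                     "Tmis": "mu_tmis", "synonymous": "mu_syn"}
        )
        out.index.name = "gene"
        return out

    def truth_table(self) -> pd.DataFrame:
        rows = []
        for disorder in self.disorders:
            for cls in RISK_CLASSES:
                gam = self.rel_risk[cls][disorder]
                for gene in self.genes:
                    if self.risk_status.loc[gene, disorder]:
                        rows.append(
                            {"gene": gene, "disorder": disorder, "variant_class": cls,
                             "risk": True, "rel_risk": float(gam.loc[gene])}
                        )
        return pd.DataFrame(rows, columns=["gene", "disorder", "variant_class", "risk", "rel_risk"])

    def gene_models(self) -> Iterator[GeneModel]:
        """Yield per-gene GeneModel views (convenience; the frames are primary)."""
        for gene in self.genes:
            yield GeneModel(
                gene_id=gene,
                mu=self.mu.loc[gene].to_dict(),
                risk_status=self.risk_status.loc[gene].to_dict(),
                rel_risk={
                    (d, c): float(self.rel_risk[c][d].loc[gene])
                    for d in self.disorders
                    for c in RISK_CLASSES
                },
            )


def build_gene_universe(config: SimulationConfig) -> GeneUniverse:
    """Draw the per-gene mutation-rate table.

    One log-normal mutability multiplier per gene (sigma =
    ``config.mu_sigma``) scales all classes — genes that are long or
    mutable are so for every class — then each class column is rescaled so
    that the genome-wide per-trio rate sum(2*mu) matches
    ``config.per_trio_rate`` exactly.  Missense splits into Dmis/Tmis by
    ``config.dmis_fraction``.  Deterministic under ``config.seed``.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    n = config.n_genes
    mult = rng.lognormal(mean=0.0, sigma=config.mu_sigma, size=n)
    share = mult / mult.sum()
    genes = [f"G{i:05d}" for i in range(n)]
    mis = share * config.per_trio_rate["mis"] / 2.0
    mu = pd.DataFrame(
        {
            "LoF": share * config.per_trio_rate["LoF"] / 2.0,
            "Dmis": mis * config.dmis_fraction,
            "Tmis": mis * (1.0 - config.dmis_fraction),
            "synonymous": share * config.per_trio_rate["synonymous"] / 2.0,
        },
        index=pd.Index(genes, name="gene"),
    )
    return GeneUniverse(mu=mu, disorders=[name for name, _ in config.cohorts])


def assign_risk_genes(
    universe: GeneUniverse, config: SimulationConfig, rng: np.random.Generator
) -> GeneUniverse:
    """Flag risk genes per disorder and draw their relative risks.

    Each disorder gets floor(pi * n_genes) risk genes.  A fraction
    ``shared_pool_fraction`` of them is drawn from a common pool of size
    max_d floor(pi_d * n_genes) (inducing cross-disorder overlap); the
    remainder is drawn disjointly across disorders from genes outside the
    pool.  Risk genes receive gamma ~ Gamma(gamma_bar*beta, rate=beta) for
    LoF and Dmis independently; everything else keeps gamma = 1.
    """
    n = universe.n_genes
    k = {d: int(np.floor(config.pi[d] * n)) for d in universe.disorders}
    for d, kd in k.items():
        if config.pi[d] > 0 and kd < 1:
            logger.warning("pi*n_genes < 1 for %s: zero risk genes assigned", d)
    pool_size = max(k.values(), default=0)
    gene_idx = np.arange(n)
    pool = rng.choice(gene_idx, size=pool_size, replace=False) if pool_size else np.array([], dtype=int)
    outside = np.setdiff1d(gene_idx, pool)
    rng.shuffle(outside)
    cursor = 0
    for d in universe.disorders:
        kd = k[d]
        if kd == 0:
            continue
        n_shared = int(round(config.shared_pool_fraction * kd))
        n_shared = min(n_shared, pool_size)
        n_own = kd - n_shared
        if cursor + n_own > len(outside):
            raise ConfigurationError(
                "not enough genes outside the shared pool for disjoint risk sets; "
                "lower pi or raise n_genes"
            )
        chosen_shared = rng.choice(pool, size=n_shared, replace=False) if n_shared else np.array([], dtype=int)
        chosen_own = outside[cursor : cursor + n_own]
        cursor += n_own
        chosen = np.concatenate([chosen_shared, chosen_own]).astype(int)
        col = universe.risk_status.columns.get_loc(d)
        universe.risk_status.iloc[chosen, col] = True
        for cls in RISK_CLASSES:
            shape = config.gamma_bar[cls] * config.beta
            gammas = rng.gamma(shape=shape, scale=1.0 / config.beta, size=len(chosen))
            universe.rel_risk[cls].iloc[chosen, col] = gammas
    return universe


def build_universe(config: SimulationConfig) -> GeneUniverse:
    """Convenience: gene rates plus risk assignment, all from config.seed."""
    universe = build_gene_universe(config)
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 2]))
    return assign_risk_genes(universe, config, rng)


@dataclass
class SimulatedCohort:
    """One simulated trio cohort with its risk-gene truth."""

    disorder: str
    n_trios: int
    records: list[DNMRecord]
    truth: pd.DataFrame

    def counts(self) -> pd.DataFrame:
        from .classify import gene_class_counts

        tables = gene_class_counts(self.records)
        if self.disorder not in tables:
            return pd.DataFrame(columns=list(SIM_CLASSES))
        return tables[self.disorder]


def simulate_counts(
    universe: GeneUniverse,
    disorder: str,
    n_trios: int,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Per-gene per-class DNM counts: x ~ Poisson(2 * N * mu * gamma)."""
    if n_trios < 0:
        raise ValueError("n_trios must be >= 0")
    lam = np.empty((universe.n_genes, len(SIM_CLASSES)))
    for j, cls in enumerate(SIM_CLASSES):
        lam[:, j] = (
            2.0 * n_trios * universe.mu[cls].to_numpy() * universe.gamma(disorder, cls)
        )
    counts = rng.poisson(lam) if n_trios > 0 else np.zeros_like(lam, dtype=int)
    return pd.DataFrame(counts, index=universe.mu.index, columns=list(SIM_CLASSES))


def simulate_cohort(
    universe: GeneUniverse,
    disorder: str,
    n_trios: int,
    rng: np.random.Generator,
    dmis_threshold: float = DEFAULT_DMIS_THRESHOLD,
    study_id: str = "sim",
) -> SimulatedCohort:
    """Simulate one cohort and expand counts into DNM records.

    ``disorder`` must be "control" (gamma = 1 everywhere) or one of the
    configured disorders.  Missense records carry a score on the matching
    side of the Dmis threshold, so classification round-trips exactly; LoF
    counts expand into a realistic mix of LoF consequence terms.
    """
    if disorder != "control" and disorder not in universe.disorders:
        raise KeyError(f"unknown disorder {disorder!r}")
    counts = simulate_counts(universe, disorder, n_trios, rng)
    records: list[DNMRecord] = []
    for cls in SIM_CLASSES:
        col = counts[cls]
        hit_genes = np.repeat(col.index.to_numpy(), col.to_numpy())
        m = len(hit_genes)
        if m == 0:
            continue
        sample_ids = rng.integers(0, max(n_trios, 1), size=m)
        if cls == "LoF":
            consequences = rng.choice(_LOF_CONSEQUENCE_CHOICES, size=m, p=_LOF_CONSEQUENCE_PROBS)
            scores = np.full(m, np.nan)
        elif cls in ("Dmis", "Tmis"):
            consequences = np.full(m, "missense")
            u = rng.random(m)
            if cls == "Dmis":
                scores = dmis_threshold + u * (1.0 - dmis_threshold)
            else:
                scores = u * dmis_threshold * (1 - 1e-9)  # strictly below threshold
        else:
            consequences = np.full(m, "synonymous")
            scores = np.full(m, np.nan)
        for gene, sid, cons, score in zip(hit_genes, sample_ids, consequences, scores):
            records.append(
                DNMRecord(
                    study_id=study_id,
                    disorder=disorder,
                    sample_id=f"{disorder}_{int(sid):06d}",
                    gene=str(gene),
                    consequence=str(cons),
                    score=None if np.isnan(score) else float(np.round(score, 6)),
                )
            )
    truth = universe.truth_table()
    if disorder != "control":
        truth = truth[truth["disorder"] == disorder].reset_index(drop=True)
    else:
        truth = truth.iloc[0:0]
    return SimulatedCohort(disorder=disorder, n_trios=n_trios, records=records, truth=truth)


def simulate_study(config: SimulationConfig) -> tuple[GeneUniverse, list[SimulatedCohort]]:
    """Simulate every configured case cohort plus the control cohort."""
    universe = build_universe(config)
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 3]))
    cohorts = [
        simulate_cohort(universe, name, trios, rng, config.dmis_threshold)
        for name, trios in config.cohorts
    ]
    cohorts.append(
        simulate_cohort(universe, "control", config.control_trios, rng, config.dmis_threshold)
    )
    return universe, cohorts


def simulate_expression(
    n_genes: int,
    n_samples: int,
    module_sizes: Sequence[int],
    rng: np.random.Generator,
    noise_sd: float = 0.2,
    profiles: np.ndarray | None = None,
) -> tuple[pd.DataFrame, pd.Series]:
    """Toy genes x samples expression matrix with planted coexpression modules.

    Module k's genes share a smooth stage-dependent mean profile across
    samples (default: alternating rising/falling trends, emulating
    prenatal-high vs postnatal-high patterns) plus i.i.d. Gaussian noise.
    Genes beyond sum(module_sizes) are unassigned background noise ("M0").
    Returns (matrix, module labels).
    """
    k = len(module_sizes)
    if k > n_genes:
        raise ValueError("more modules than genes")
    if sum(module_sizes) > n_genes:
        raise ValueError("module sizes exceed n_genes")
    t = np.linspace(-1.0, 1.0, n_samples)
    if profiles is None:
        # Cosine harmonics: module 1 falls monotonically across stages
        # (prenatal-high), module 2 is U-shaped, etc.  Near-orthogonal by
        # construction, so an absolute-correlation threshold separates the
        # modules; exactly mirrored profiles could not be separated that way.
        profiles = np.array(
            [np.cos(np.pi * (m + 1) * (t + 1.0) / 2.0) for m in range(k)]
        )
    profiles = np.asarray(profiles, dtype=float)
    if profiles.shape != (k, n_samples):
        raise ValueError("profiles must be K x n_samples")
    genes = [f"G{i:05d}" for i in range(n_genes)]
    labels = pd.Series("M0", index=pd.Index(genes, name="gene"), name="module")
    values = rng.normal(0.0, max(noise_sd, 0.0), size=(n_genes, n_samples))
    row = 0
    for m, size in enumerate(module_sizes):
        values[row : row + size] += profiles[m]
        labels.iloc[row : row + size] = f"M{m + 1}"
        row += size
    expr = pd.DataFrame(values, index=labels.index, columns=[f"S{j:04d}" for j in range(n_samples)])
    return expr, labels


def simulate_ppi(
    genes: Sequence[str],
    modules: Mapping[str, str] | pd.Series,
    p_within: float,
    p_between: float,
    rng: np.random.Generator,
    score_range: tuple[float, float] = (401.0, 999.0),
) -> pd.DataFrame:
    """Random PPI edge table with module structure.

    Gene pairs in the same module connect with probability ``p_within``,
    others with ``p_between`` (p_between <= p_within required); edge scores
    are uniform on ``score_range``.  Undirected, no self-edges, no
    duplicate pairs.
    """
    if not 0.0 <= p_between <= p_within <= 1.0:
        raise ValueError("need 0 <= p_between <= p_within <= 1")
    modules = pd.Series(modules)
    genes = list(genes)
    n = len(genes)
    lab = modules.reindex(genes).to_numpy()
    iu = np.triu_indices(n, k=1)
    same = (lab[iu[0]] == lab[iu[1]]) & (lab[iu[0]] != "M0")
    prob = np.where(same, p_within, p_between)
    keep = rng.random(len(prob)) < prob
    lo, hi = score_range
    scores = rng.uniform(lo, hi, size=int(keep.sum()))
    garr = np.asarray(genes)
    return pd.DataFrame(
        {
            "gene_a": garr[iu[0][keep]],
            "gene_b": garr[iu[1][keep]],
            "combined_score": np.round(scores, 1),
        }
    )


def write_study(
    config: SimulationConfig, outdir: str | Path
) -> dict[str, Path]:
    """Simulate a study and write its tables under ``outdir``.

    Emits the DNM table (all cohorts pooled), the gene-rate table, the
    risk-gene truth table, a trio-count table and the config itself.
    """
    from .classify import write_dnm_table

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    universe, cohorts = simulate_study(config)
    paths = {
        "dnms": outdir / "dnms.tsv",
        "rates": outdir / "gene_rates.tsv",
        "truth": outdir / "truth.tsv",
        "trios": outdir / "trios.tsv",
        "config": outdir / "config.yaml",
    }
    records = [rec for cohort in cohorts for rec in cohort.records]
    write_dnm_table(records, paths["dnms"])
    universe.rates_table().to_csv(paths["rates"], sep="\t")
    universe.truth_table().to_csv(paths["truth"], sep="\t", index=False)
    trios = pd.DataFrame(
        [(c.disorder, c.n_trios) for c in cohorts], columns=["disorder", "n_trios"]
    )
    trios.to_csv(paths["trios"], sep="\t", index=False)
    config.to_yaml(paths["config"])
    return paths
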