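"""Synthetic risk-SNP catalogs with a known cross-population structure.

The generator emulates the data model of a curated GWAS-derived catalog:
each SNP has a latent risk-allele frequency in a reference population B
(European-like), a shifted frequency in population A (African-like),

    p_A = clip(p_B + delta + eta),   eta ~ Normal(0, unit_noise_sd),

and per-database frequency observations drawn Binomial(2 n_d, p_pop)/(2 n_d)
with database-specific sample sizes mirroring the very different scales of
the public sources (1000 Genomes << gnomAD < ALFA).  Odds ratios are
lognormal, floored at 1 so the catalog arrives already harmonized.  Optional
LD groups assign identical latent frequencies to blocks of SNPs and emit
pairwise r² values above the linkage threshold; r² is declared, not derived
from genotypes.

The unit-level noise eta represents locus-to-locus heterogeneity of the
between-population difference; without it a constant shift would make the
paired t-test degenerate.  All randomness flows from a root seed through a
documented counter scheme (``numpy.random.SeedSequence(seed,
spawn_key=(replicate,))``) so every replicate is independently reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from statsmodels.stats.proportion import proportion_confint

from .aggregate import aggregate_catalog
from .catalog import FrequencyObservation, LdPair, SnpCatalog, SnpRecord
from .stats import compare_populations

FREQ_CLIP = (0.01, 0.99)

#: Database sample sizes (individuals) reflecting the sources' scale ordering.
DEFAULT_DB_SIZES = {"1kg": 661, "alfa": 50_000, "gnomad": 8_000}


class ConfigError(ValueError):
    pass


@dataclass(frozen=True)
class SyntheticConfig:
    """Generative parameters for a synthetic two-population catalog.

    ``delta`` is the mean shift of population A's true risk-allele frequency
    relative to population B (positive: A carries more risk alleles).
    ``base_distribution`` draws population-B frequencies: ``("uniform", lo,
    hi)`` or ``("beta", a, b)``; draws are clipped to [0.01, 0.99] before
    binomial sampling.  Odds ratios are lognormal(or_log_mean, or_log_sd)
    floored at 1.
    """

    n_snps: int = 226
    delta: float = 0.0
    unit_noise_sd: float = 0.02
    base_distribution: tuple = ("uniform", 0.05, 0.95)
    or_log_mean: float = float(np.log(1.15))
    or_log_sd: float = 0.15
    db_sample_sizes: dict[str, int] = field(default_factory=lambda: dict(DEFAULT_DB_SIZES))
    n_ld_groups: int = 0
    ld_group_size: int = 3
    pop_a: str = "afr"
    pop_b: str = "eur"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_snps <= 0:
            raise ConfigError("n_snps must be positive")
        if abs(self.delta) >= FREQ_CLIP[1] - FREQ_CLIP[0]:
            raise ConfigError(f"delta {self.delta} pushes all frequencies to the clip bounds")
        if any(n <= 0 for n in self.db_sample_sizes.values()):
            raise ConfigError("database sample sizes must be positive")
        if self.n_ld_groups < 0 or self.ld_group_size < 2:
            raise ConfigError("need n_ld_groups >= 0 and ld_group_size >= 2")
        if self.n_ld_groups * self.ld_group_size > self.n_snps:
            raise ConfigError("LD groups cannot cover more SNPs than n_snps")


def replicate_rng(seed: int, replicate: int = 0) -> np.random.Generator:
    """Generator for one replicate: SeedSequence(seed, spawn_key=(replicate,))."""
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(replicate,)))


def _draw_base(rng: np.random.Generator, config: SyntheticConfig) -> np.ndarray:
    kind, *params = config.base_distribution
    if kind == "uniform":
        lo, hi = params
        draws = rng.uniform(lo, hi, size=config.n_snps)
    elif kind == "beta":
        a, b = params
        draws = rng.beta(a, b, size=config.n_snps)
    else:
        raise ConfigError(f"unknown base distribution {kind!r}")
    return np.clip(draws, *FREQ_CLIP)


def simulate_catalog(
    config: SyntheticConfig, replicate: int = 0
) -> tuple[SnpCatalog, list[LdPair], dict]:
    """Draw one synthetic catalog, its LD pairs, and the latent truth.

    The truth record carries the latent frequencies (``p_a``, ``p_b``), the
    odds ratios, the configured shift, and the LD group memberships.  The
    same ``(config.seed, replicate)`` always yields bit-identical output.
    """
    rng = replicate_rng(config.seed, replicate)
    n = config.n_snps

    p_b = _draw_base(rng, config)
    eta = rng.normal(0.0, config.unit_noise_sd, size=n)
    p_a = np.clip(p_b + config.delta + eta, *FREQ_CLIP)

    # LD blocks occupy the leading SNPs and share latent frequencies.
    group_of = np.full(n, -1)
    for g in range(config.n_ld_groups):
        idx = slice(g * config.ld_group_size, (g + 1) * config.ld_group_size)
        group_of[idx] = g
        members = range(g * config.ld_group_size, (g + 1) * config.ld_group_size)
        anchor = g * config.ld_group_size
        p_b[list(members)] = p_b[anchor]
        p_a[list(members)] = p_a[anchor]

    ors = np.maximum(rng.lognormal(config.or_log_mean, config.or_log_sd, size=n), 1.0)

    if np.all((p_a <= FREQ_CLIP[0]) | (p_a >= FREQ_CLIP[1])):
        raise ConfigError("configured shift pushed every frequency to a clip bound")

    records = []
    for i in range(n):
        if group_of[i] >= 0:
            chrom = str(group_of[i] + 1)
        else:
            chrom = str(i % 22 + 1)
        obs = {}
        for pop, p in ((config.pop_a, p_a[i]), (config.pop_b, p_b[i])):
            pop_obs = []
            for db, n_ind in sorted(config.db_sample_sizes.items()):
                ac = 2 * n_ind
                f = rng.binomial(ac, p) / ac
                pop_obs.append(FrequencyObservation(db, f, n_ind))
            obs[pop] = tuple(pop_obs)
        records.append(
            SnpRecord(
                rsid=f"rs{1000000 + i}",
                chromosome=chrom,
                position=(i + 1) * 10_000,
                risk_allele="A",
                ref_allele="G",
                odds_ratio=float(ors[i]),
                observations=obs,
            )
        )

    pairs: list[LdPair] = []
    for g in range(config.n_ld_groups):
        members = [f"rs{1000000 + i}" for i in range(g * config.ld_group_size, (g + 1) * config.ld_group_size)]
        for i in range(len(members)):
            for j in range(i + 1, len(members)):
                pairs.append(LdPair(members[i], members[j], float(rng.uniform(0.85, 0.99))))

    catalog = SnpCatalog(
        cancer_label="synthetic",
        records=tuple(records),
        populations=(config.pop_a, config.pop_b),
    )
    truth = {
        "p_a": p_a.copy(),
        "p_b": p_b.copy(),
        "odds_ratios": ors.copy(),
        "delta": config.delta,
        "ld_group_of": group_of.copy(),
        "seed": config.seed,
        "replicate": replicate,
    }
    return catalog, pairs, truth


@dataclass(frozen=True)
class RejectionRate:
    """Empirical rejection fraction with a 95% binomial (Wilson) interval."""

    rate: float
    n_reps: int
    alpha: float
    ci_low: float
    ci_high: float


def _rejection_rate(
    config: SyntheticConfig,
    alpha: float,
    n_reps: int,
    variant: str,
    direction: str,
    use_weighted: bool,
) -> RejectionRate:
    hits = 0
    for rep in range(n_reps):
        catalog, _, _ = simulate_catalog(config, replicate=rep)
        _, units = aggregate_catalog(catalog)
        comp = compare_populations(
            units,
            config.pop_a,
            config.pop_b,
            use_weighted=use_weighted,
            direction=direction,
            variant=variant,
        )
        if comp.ttest.p_one_tailed < alpha:
            hits += 1
    lo, hi = proportion_confint(hits, n_reps, alpha=0.05, method="wilson")
    return RejectionRate(hits / n_reps, n_reps, alpha, float(lo), float(hi))


def calibrate_type_i_error(
    config: SyntheticConfig,
    alpha: float = 0.05,
    n_reps: int = 1000,
    variant: str = "paired",
    direction: str = "greater",
    use_weighted: bool = True,
) -> RejectionRate:
    """Empirical type-I error of the full pipeline under delta = 0.

    Each replicate runs simulate -> aggregate -> compare and counts
    one-tailed p < alpha.
    """
    if config.delta != 0.0:
        raise ConfigError("type-I calibration requires delta = 0")
    if n_reps < 200 and alpha not in (0.0, 1.0):
        raise ConfigError("need at least 200 replicates for a meaningful rate")
    return _rejection_rate(config, alpha, n_reps, variant, direction, use_weighted)


def estimate_power(
    config: SyntheticConfig,
    alpha: float = 0.05,
    n_reps: int = 500,
    variant: str = "paired",
    direction: str = "greater",
    use_weighted: bool = True,
) -> RejectionRate:
    """Empirical power under the configured frequency shift."""
    if n_reps < 200 and alpha not in (0.0, 1.0):
        raise ConfigError("need at least 200 replicates for a meaningful rate")
    return _rejection_rate(config, alpha, n_reps, variant, direction, use_weighted)


def estimated_shift(config: SyntheticConfig, replicate: int = 0) -> float:
    """Point estimate of the frequency shift from one simulated catalog.

    mean pooled F(pop A) - mean pooled F(pop B), the quantity whose
    expectation is the generative delta.
    """
    catalog, _, _ = simulate_catalog(config, replicate=replicate)
    _, units = aggregate_catalog(catalog)
    fa = np.mean([u.pooled[config.pop_a] for u in units])
    fb = np.mean([u.pooled[config.pop_b] for u in units])
    return float(fa - fb)
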