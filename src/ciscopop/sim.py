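"""EASYPOP-style forward-time Wright-Fisher simulator and fixture generators.

The engine has two phases, matching how the simulated scenarios are built:

1. A **frequency-phase burn-in**: because all simulated loci recombine freely
   and mating is random, 1,000 generations of low migration can be run as a
   per-locus allele-frequency recursion (deterministic migration mixing,
   K-allele mutation, binomial resampling of 2N gene copies per deme). This
   makes the 8,000-locus, 1,000-generation scenarios desk-scale without
   changing the expected differentiation dynamics.
2. An **individual-based hybridization phase**: individuals are instantiated
   from the burn-in frequencies (Binomial(2, p) per locus, linkage
   equilibrium) and then migrate, mate and mutate explicitly, with pedigree
   ancestry vectors tracked so every sampled individual carries its true
   deme-of-origin fractions.

Migration semantics: ``m`` is the per-individual, per-generation emigration
probability. Island migrants pick a uniform other deme. In the linear (non-
circular) 1-D stepping-stone, every individual attempts to move left or right
with probability m/2 each; at the terminal demes the outward attempt is
dropped (the individual stays), so edge demes emigrate at rate m/2. Deme
sizes and the 50/50 sex ratio are restored each generation at reproduction:
each deme's adults (post-migration) produce exactly N offspring by drawing a
mother and a father uniformly with replacement.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .genotypes import DepthMatrix, GenotypeMatrix, LocusTable

__all__ = [
    "SimConfig", "SimResult", "Population",
    "burnin_allele_frequencies", "instantiate_individuals",
    "hybridization_phase", "run_erosion_experiment",
    "make_planted_island_genome", "make_paralog_depths",
    "make_known_ne_population",
]

# burn-in migration rates that produce the three preliminary differentiation
# levels (FST ~0.05 / ~0.10 / ~0.20 over 1,000 generations, N = 2,000)
EROSION_BURNIN_M = {"a": 0.001, "b": 0.0005, "c": 0.0001}


@dataclass
class SimConfig:
    """Demography, migration and mutation parameters of one scenario."""

    n_demes: int = 3
    deme_size: int = 2000          # diploids per deme (half female, half male)
    migration_model: str = "island"  # or "stepping_stone_1d"
    m: float = 0.001               # per-individual emigration probability
    mu: float = 1.0e-8             # per-locus per-generation mutation rate
    n_allelic_states: int = 2      # KAM states
    n_loci: int = 8000
    burnin_generations: int = 1000
    hybridization_generations: int = 5
    hybridization_m: float = 0.05
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "SimConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)

    def __post_init__(self):
        if not 0.0 <= self.m <= 1.0 or not 0.0 <= self.hybridization_m <= 1.0:
            raise ValueError("migration probabilities must lie in [0, 1]")
        if self.deme_size < 1 or self.n_demes < 1:
            raise ValueError("need at least one deme of at least one diploid")
        if self.n_allelic_states < 2:
            raise ValueError("KAM needs >= 2 allelic states")
        if self.migration_model not in ("island", "stepping_stone_1d"):
            raise ValueError(f"unknown migration model {self.migration_model!r}")


@dataclass
class SimResult:
    """Sampled genotypes with pedigree-true ancestry and an FST trajectory."""

    genotypes: GenotypeMatrix
    ancestry: np.ndarray                 # (n_sampled, n_demes), rows sum to 1
    fst_trajectory: np.ndarray           # one value per simulated generation
    config: SimConfig
    samples: dict = field(default_factory=dict)  # generation -> GenotypeMatrix


@dataclass
class Population:
    """Individual-based state: allele pairs, deme, sex and ancestry per adult."""

    calls: np.ndarray      # (n_ind, n_loci, 2) int8 allele indices
    deme: np.ndarray       # (n_ind,) int
    sex: np.ndarray        # (n_ind,) int, 0 = female, 1 = male
    ancestry: np.ndarray   # (n_ind, n_demes) float
    n_states: int = 2

    @property
    def n_demes(self) -> int:
        return self.ancestry.shape[1]

    def deme_sizes(self) -> np.ndarray:
        return np.bincount(self.deme, minlength=self.n_demes)

    def allele_frequencies(self) -> np.ndarray:
        """Per-deme frequency of allele 1 (biallelic), shape (n_demes, n_loci)."""
        d = self.calls.sum(axis=2, dtype=np.int32)
        out = np.empty((self.n_demes, self.calls.shape[1]))
        for k in range(self.n_demes):
            out[k] = d[self.deme == k].mean(axis=0) / 2.0
        return out

    def to_genotype_matrix(self, prefix: str = "sim") -> GenotypeMatrix:
        labels = [f"P{k + 1}" for k in self.deme]
        ids = [f"{prefix}_{i:05d}" for i in range(len(self.deme))]
        loci = LocusTable.simple([f"loc{j:06d}" for j in range(self.calls.shape[1])])
        return GenotypeMatrix(
            ids, labels, loci, self.calls.astype(np.int16),
            ancestry=self.ancestry.copy(),
            ancestry_pops=[f"P{k + 1}" for k in range(self.n_demes)],
        )


# ---------------------------------------------------------------------------
# migration kernels
# ---------------------------------------------------------------------------

def _backward_matrix(n_demes: int, m: float, model: str) -> np.ndarray:
    """B[k, j] = probability a post-migration gene copy in deme k came from j."""
    F = _forward_matrix(n_demes, m, model)      # F[j, k]: fraction of j moving to k
    col = F.sum(axis=0)
    return (F / col).T


def _forward_matrix(n_demes: int, m: float, model: str) -> np.ndarray:
    F = np.zeros((n_demes, n_demes))
    if n_demes == 1:
        return np.ones((1, 1))
    if model == "island":
        F[:] = m / (n_demes - 1)
        np.fill_diagonal(F, 1.0 - m)
    else:  # linear stepping stone; outward attempts at the edges are dropped
        for j in range(n_demes):
            left, right = j - 1, j + 1
            stay = 1.0 - m
            if left >= 0:
                F[j, left] = m / 2.0
            else:
                stay += m / 2.0
            if right < n_demes:
                F[j, right] = m / 2.0
            else:
                stay += m / 2.0
            F[j, j] = stay
    return F


def _nei_fst(freqs: np.ndarray) -> float:
    """Descriptive multilocus differentiation from per-deme frequencies.

    Ratio-of-sums (H_T - H_S)/H_T over loci, with the among-deme variance
    scaled by d/(d-1) so the value is comparable to a Weir-Cockerham theta
    on large samples.
    """
    d = freqs.shape[0]
    pbar = freqs.mean(axis=0)
    s2 = freqs.var(axis=0, ddof=1) if d > 1 else np.zeros_like(pbar)
    num = s2
    den = pbar * (1.0 - pbar) + s2 / d
    keep = den > 0
    if not keep.any():
        return 0.0
    return float(num[keep].sum() / den[keep].sum())


# ---------------------------------------------------------------------------
# phase 1: frequency-level burn-in
# ---------------------------------------------------------------------------

def burnin_allele_frequencies(config: SimConfig, rng: np.random.Generator | None = None):
    """Run the burn-in as a Wright-Fisher allele-frequency recursion.

    Every locus starts at p = 0.5 in every deme (maximal-diversity start for
    undifferentiated populations). Each generation applies deterministic
    migration mixing, symmetric 2-state KAM mutation, then binomial
    resampling of 2N gene copies per deme. Returns ``(freqs, trajectory)``
    with ``freqs`` of shape (n_demes, n_loci).
    """
    if config.n_allelic_states != 2:
        raise NotImplementedError(
            "the frequency-phase engine tracks biallelic loci only"
        )
    rng = np.random.default_rng(config.seed) if rng is None else rng
    d, L, N = config.n_demes, config.n_loci, config.deme_size
    B = _backward_matrix(d, config.m, config.migration_model)
    p = np.full((d, L), 0.5)
    traj = np.empty(config.burnin_generations)
    for g in range(config.burnin_generations):
        p = B @ p
        p = p * (1.0 - config.mu) + (1.0 - p) * config.mu
        p = rng.binomial(2 * N, p) / (2.0 * N)
        traj[g] = _nei_fst(p)
    return p, traj


def instantiate_individuals(
    freqs: np.ndarray, n_per_deme: int, seed=None, n_states: int = 2
) -> Population:
    """Draw deme-pure diploids from per-deme allele frequencies (HWE, LE).

    Each individual receives a one-hot ancestry vector for its deme and a
    sex; every deme gets exactly ``n_per_deme // 2`` females.
    """
    rng = np.random.default_rng(seed)
    freqs = np.asarray(freqs, dtype=float)
    if freqs.min() < 0 or freqs.max() > 1:
        raise ValueError("allele frequencies must lie in [0, 1]")
    d, L = freqs.shape
    n_tot = d * n_per_deme
    deme = np.repeat(np.arange(d), n_per_deme)
    calls = (rng.random((n_tot, L, 2)) < freqs[deme][:, :, None]).astype(np.int8)
    sex = np.empty(n_tot, dtype=np.int8)
    half = n_per_deme // 2
    for k in range(d):
        s = np.r_[np.zeros(half, dtype=np.int8),
                  np.ones(n_per_deme - half, dtype=np.int8)]
        sex[k * n_per_deme:(k + 1) * n_per_deme] = rng.permutation(s)
    ancestry = np.eye(d)[deme]
    return Population(calls, deme.astype(np.int64), sex, ancestry, n_states=n_states)


# ---------------------------------------------------------------------------
# phase 2: individual-based hybridization
# ---------------------------------------------------------------------------

def _migrate(pop: Population, m: float, model: str, rng: np.random.Generator) -> None:
    n = len(pop.deme)
    if m <= 0 or pop.n_demes == 1:
        return
    d = pop.n_demes
    if model == "island":
        movers = np.flatnonzero(rng.random(n) < m)
        shift = rng.integers(1, d, size=len(movers))
        pop.deme[movers] = (pop.deme[movers] + shift) % d
    else:
        # attempt left/right with m/2 each; outward attempts at edges dropped
        u = rng.random(n)
        left = u < m / 2.0
        right = (u >= m / 2.0) & (u < m)
        dest = pop.deme + right.astype(np.int64) - left.astype(np.int64)
        ok = (dest >= 0) & (dest < d)
        pop.deme[ok] = dest[ok]
    if (np.bincount(pop.deme, minlength=d) == 0).any():
        raise RuntimeError("migration emptied a deme")


def _reproduce(
    pop: Population, deme_size: int, mu: float, rng: np.random.Generator
) -> Population:
    d, L = pop.n_demes, pop.calls.shape[1]
    n_new = d * deme_size
    calls = np.empty((n_new, L, 2), dtype=np.int8)
    ancestry = np.empty((n_new, d))
    deme = np.repeat(np.arange(d), deme_size)
    sex = np.empty(n_new, dtype=np.int8)
    half = deme_size // 2
    cols = np.arange(L)[None, :]
    for k in range(d):
        here = pop.deme == k
        females = np.flatnonzero(here & (pop.sex == 0))
        males = np.flatnonzero(here & (pop.sex == 1))
        if len(females) == 0 or len(males) == 0:
            raise RuntimeError(f"deme {k} lacks one sex after migration")
        mothers = rng.choice(females, size=deme_size, replace=True)
        fathers = rng.choice(males, size=deme_size, replace=True)
        # free recombination: each locus transmits one uniformly chosen allele
        for parents, slot in ((mothers, 0), (fathers, 1)):
            bits = rng.integers(0, 2, size=(deme_size, L), dtype=np.int8)
            sub = pop.calls[parents]
            calls[k * deme_size:(k + 1) * deme_size, :, slot] = (
                np.take_along_axis(sub, bits[:, :, None].astype(np.intp), axis=2)[:, :, 0]
            )
        ancestry[k * deme_size:(k + 1) * deme_size] = (
            pop.ancestry[mothers] + pop.ancestry[fathers]
        ) / 2.0
        s = np.r_[np.zeros(half, dtype=np.int8),
                  np.ones(deme_size - half, dtype=np.int8)]
        sex[k * deme_size:(k + 1) * deme_size] = rng.permutation(s)
    if mu > 0:
        n_copies = calls.size
        n_mut = rng.poisson(mu * n_copies)
        if n_mut:
            flat = rng.integers(0, n_copies, size=n_mut)
            old = calls.reshape(-1)[flat]
            step = rng.integers(1, pop.n_states, size=n_mut).astype(np.int8)
            calls.reshape(-1)[flat] = (old + step) % pop.n_states
    return Population(calls, deme, sex, ancestry, n_states=pop.n_states)


def _sample_population(pop: Population, per_deme: int, rng, prefix="sim") -> Population:
    idx = []
    for k in range(pop.n_demes):
        here = np.flatnonzero(pop.deme == k)
        take = min(per_deme, len(here))
        idx.append(rng.choice(here, size=take, replace=False))
    idx = np.concatenate(idx)
    return Population(
        pop.calls[idx].copy(), pop.deme[idx].copy(), pop.sex[idx].copy(),
        pop.ancestry[idx].copy(), n_states=pop.n_states,
    )


def hybridization_phase(
    pop: Population,
    model: str,
    m: float,
    generations: int,
    seed=None,
    sample_per_deme: int | None = None,
    sample_at: Sequence[int] | None = None,
    mu: float = 0.0,
    deme_size: int | None = None,
    config: SimConfig | None = None,
    life_cycle: str = "mate_migrate",
) -> SimResult:
    """Run explicit migration + random mating for ``generations`` generations.

    ``life_cycle`` fixes the within-generation event order:
    ``"mate_migrate"`` (default) has each deme's adults reproduce first and
    the newborn cohort then disperse, so a sample taken after generation G
    reflects G-1 rounds of gene-flow mixing (natal dispersal); with
    ``"migrate_mate"`` adults disperse before breeding and the sample
    reflects G rounds.

    ``sample_at`` lists generation numbers (1-based) at which a sample of
    ``sample_per_deme`` individuals per deme is drawn (without replacement)
    and stored in ``SimResult.samples``; the final-generation sample is also
    returned as ``SimResult.genotypes``. With ``sample_per_deme=None`` whole
    demes are returned.
    """
    if life_cycle not in ("mate_migrate", "migrate_mate"):
        raise ValueError(f"unknown life cycle {life_cycle!r}")
    rng = np.random.default_rng(seed)
    if deme_size is None:
        deme_size = int(round(len(pop.deme) / pop.n_demes))
    sample_at = sorted(set(sample_at or [generations]))
    traj = np.empty(generations)
    samples: dict[int, GenotypeMatrix] = {}
    for g in range(1, generations + 1):
        if life_cycle == "migrate_mate":
            _migrate(pop, m, model, rng)
            pop = _reproduce(pop, deme_size, mu, rng)
        else:
            pop = _reproduce(pop, deme_size, mu, rng)
            _migrate(pop, m, model, rng)
        traj[g - 1] = _nei_fst(pop.allele_frequencies())
        if g in sample_at:
            sub = pop if sample_per_deme is None else _sample_population(
                pop, sample_per_deme, rng
            )
            samples[g] = sub.to_genotype_matrix(prefix=f"g{g}")
    last = samples[max(samples)] if samples else pop.to_genotype_matrix()
    return SimResult(
        genotypes=last,
        ancestry=last.ancestry,
        fst_trajectory=traj,
        config=config or SimConfig(
            n_demes=pop.n_demes, deme_size=deme_size, migration_model=model,
            m=m, hybridization_generations=generations,
        ),
        samples=samples,
    )


# ---------------------------------------------------------------------------
# the two simulation designs
# ---------------------------------------------------------------------------

def run_erosion_experiment(
    initial_fst_level: str,
    m: float,
    generations: int = 15,
    n_replicates: int = 50,
    seed=None,
    n_loci: int = 1000,
    n_demes: int = 2,
    deme_size: int = 2000,
    sample_per_deme: int = 100,
    burnin_generations: int = 1000,
) -> pd.DataFrame:
    """Hybridization eroding differentiation: replicate FST trajectories.

    ``initial_fst_level`` in {'a', 'b', 'c'} selects the burn-in migration
    rate (0.001 / 0.0005 / 0.0001) that sets the preliminary differentiation.
    Each replicate burns in at the frequency level, instantiates full demes,
    then applies ``generations`` generations of island hybridization at
    migration rate ``m``. FST (Weir-Cockerham theta) is measured on a fresh
    sample of ``sample_per_deme`` individuals per deme at generation 0 and
    after every hybridization generation. Returns a tidy table with columns
    replicate, generation, fst.
    """
    from .stats import wc_fst

    if initial_fst_level not in EROSION_BURNIN_M:
        raise ValueError(f"unknown initial level {initial_fst_level!r}")
    burn_m = EROSION_BURNIN_M[initial_fst_level]
    rng = np.random.default_rng(seed)

    # batch the frequency-phase burn-in across replicates (extra loci axis)
    cfg = SimConfig(
        n_demes=n_demes, deme_size=deme_size, m=burn_m,
        n_loci=n_loci * n_replicates, burnin_generations=burnin_generations,
    )
    freqs, _ = burnin_allele_frequencies(cfg, rng=rng)

    rows = []
    for r in range(n_replicates):
        f = freqs[:, r * n_loci:(r + 1) * n_loci]
        pop = instantiate_individuals(f, deme_size, seed=rng)
        # generation-0 sample drawn directly from the instantiated demes
        gm0 = _sample_population(pop, sample_per_deme, rng).to_genotype_matrix()
        res = hybridization_phase(
            pop, "island", m, generations, seed=rng,
            sample_per_deme=sample_per_deme, sample_at=range(1, generations + 1),
        )
        rows.append((r, 0, wc_fst(gm0).theta))
        for g, gm in sorted(res.samples.items()):
            rows.append((r, g, wc_fst(gm).theta))
    return pd.DataFrame(rows, columns=["replicate", "generation", "fst"])


# ---------------------------------------------------------------------------
# fixture generators with known truth
# ---------------------------------------------------------------------------

def _balding_nichols(pbar, fst, size, rng):
    """Per-deme frequencies around pbar with target differentiation fst."""
    if fst <= 0:
        return np.broadcast_to(pbar, size).copy()
    a = pbar * (1.0 - fst) / fst
    b = (1.0 - pbar) * (1.0 - fst) / fst
    return rng.beta(a, b, size=size)


def make_planted_island_genome(
    n_loci: int = 1000,
    n_lg: int = 5,
    island_lg: int = 0,
    island_span_cm: float = 10.0,
    island_fst: float = 0.4,
    background_fst: float = 0.05,
    seed=None,
    n_per_pop: int = 50,
    lg_length_cm: float = 100.0,
):
    """Two-population genome with a contiguous planted divergence island.

    Loci are spread uniformly over ``n_lg`` linkage groups of
    ``lg_length_cm``. Loci on ``island_lg`` whose position falls inside a
    central span of ``island_span_cm`` draw their two-population frequencies
    at ``island_fst``; all others at ``background_fst``. Returns
    ``(GenotypeMatrix, island_locus_indices)``.
    """
    rng = np.random.default_rng(seed)
    lg = rng.integers(0, n_lg, size=n_loci)
    cm = rng.uniform(0, lg_length_cm, size=n_loci)
    start = (lg_length_cm - island_span_cm) / 2.0
    in_island = (lg == island_lg) & (cm >= start) & (cm <= start + island_span_cm)
    pbar = rng.uniform(0.2, 0.8, size=n_loci)
    freqs = np.empty((2, n_loci))
    for pop_i in range(2):
        freqs[pop_i] = np.where(
            in_island,
            _balding_nichols(pbar, island_fst, n_loci, rng),
            _balding_nichols(pbar, background_fst, n_loci, rng),
        )
    pop = instantiate_individuals(freqs, n_per_pop, seed=rng)
    gm = pop.to_genotype_matrix(prefix="isl")
    df = gm.loci.df
    df["linkage_group"] = [f"LG{int(g) + 1}" for g in lg]
    df["cM"] = cm
    gm = GenotypeMatrix(
        gm.individual_ids, gm.pop_labels, LocusTable(df), gm.calls,
        ancestry=gm.ancestry, ancestry_pops=gm.ancestry_pops,
    )
    return gm, np.flatnonzero(in_island)


def make_paralog_depths(
    n_ind: int = 100,
    n_loci: int = 500,
    paralog_fraction: float = 0.1,
    mean_depth: float = 30.0,
    seed=None,
):
    """Read-depth fixture with planted paralogs (merged duplicate loci).

    Singleton loci draw HWE genotypes and symmetric heterozygote read
    ratios. A planted paralog merges two duplicated copies: the apparent
    genotype is heterozygous whenever the four gene copies disagree (excess
    heterozygosity) and reads are drawn from all four copies (read-ratio
    skew), at double depth. Returns ``(gm, depths, is_paralog)``.
    """
    rng = np.random.default_rng(seed)
    n_par = int(round(paralog_fraction * n_loci))
    is_par = np.zeros(n_loci, dtype=bool)
    if n_par:
        is_par[rng.choice(n_loci, size=n_par, replace=False)] = True
    p = np.where(is_par, rng.uniform(0.3, 0.7, n_loci), rng.uniform(0.1, 0.9, n_loci))

    # gene copies: 2 for singletons, 4 (two merged duplicates) for paralogs
    copies = rng.random((n_ind, n_loci, 4)) < p[None, :, None]
    copies[:, ~is_par, 2:] = copies[:, ~is_par, :2]  # singleton: duplicate pair
    n_copies = np.where(is_par, 4, 2)
    alt_copies = np.where(
        is_par[None, :], copies.sum(axis=2), copies[:, :, :2].sum(axis=2)
    )
    dosage = np.where(
        alt_copies == 0, 0, np.where(alt_copies == n_copies[None, :], 2, 1)
    ).astype(float)

    depth_mean = np.where(is_par, 2.0 * mean_depth, mean_depth)
    total = rng.poisson(depth_mean[None, :], size=(n_ind, n_loci))
    alt_p = alt_copies / n_copies[None, :]
    alt_reads = rng.binomial(total, alt_p)
    ref_reads = total - alt_reads

    gm = GenotypeMatrix.from_dosage(dosage, pop_labels=["pop1"] * n_ind)
    return gm, DepthMatrix(ref_reads, alt_reads), is_par


def make_known_ne_population(
    Ne: int = 200,
    sample_n: int = 50,
    n_loci: int = 2000,
    n_lg: int = 20,
    seed=None,
    generations: int = 50,
):
    """Isolated Wright-Fisher deme of known size for Ne parameter recovery.

    Loci start at uniformly drawn frequencies (0.1-0.9), the deme drifts for
    ``generations`` generations (enough for the inter-locus linkage
    disequilibrium of unlinked loci to reach its drift-recombination
    quasi-equilibrium), then ``sample_n`` individuals are sampled. Loci are
    assigned round-robin to ``n_lg`` linkage groups; monomorphic loci are
    dropped. Returns a GenotypeMatrix.
    """
    rng = np.random.default_rng(seed)
    freqs = rng.uniform(0.1, 0.9, size=(1, n_loci))
    pop = instantiate_individuals(freqs, Ne, seed=rng)
    res = hybridization_phase(
        pop, "island", 0.0, generations, seed=rng, sample_per_deme=sample_n,
        deme_size=Ne,
    )
    gm = res.genotypes
    dos = gm.dosage()
    maf = np.nanmean(dos, axis=0) / 2.0
    keep = np.flatnonzero((maf > 0) & (maf < 1))
    gm = gm.subset(locus_idx=keep)
    df = gm.loci.df
    df["linkage_group"] = [f"LG{(j % n_lg) + 1}" for j in range(len(df))]
    df["cM"] = [float(j // n_lg) for j in range(len(df))]
    return GenotypeMatrix(
        gm.individual_ids, gm.pop_labels, LocusTable(df), gm.calls,
        ancestry=gm.ancestry, ancestry_pops=gm.ancestry_pops,
    )
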