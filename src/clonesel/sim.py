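"""Forward-time simulation of a clonal hematopoietic stem-cell population.

The population is a fixed-size pool of N haploid cells evolving by
discrete Wright-Fisher generations: offspring are drawn multinomially
with clone weights proportional to count x fitness, fitness is
multiplicative over a clone's mutations, prod(1 + s_i), floored at 0,
and every offspring cell acquires a Poisson(mu.L) number of new
mutations under the infinite-sites assumption.  There is no
recombination, so a clone is fully described by its mutation set.

Two implementations are provided: a readable reference over
:class:`CloneTable` (:func:`step_generation`), and a numba kernel used
by :func:`run_simulation` for production-scale runs.  Both draw from the
same model; tests cross-check their output distributions.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import _engine
from .params import EvolutionParams, SimConfig
from .variants import empty_variant_table, make_variant_table

FITNESS_CLASSES = ("neutral", "beneficial", "deleterious")


class DegeneratePopulationError(RuntimeError):
    """Raised when every clone in the population has zero fitness."""


@dataclass(frozen=True)
class MutationRecord:
    """One mutation under the infinite-sites model."""

    id: int
    site_class: str          # "synonymous" | "nonsynonymous"
    fitness_class: str       # "neutral" | "beneficial" | "deleterious"
    s: float                 # signed selection coefficient
    in_driver_territory: bool
    origin_gen: int = 0

    def __post_init__(self) -> None:
        if self.site_class == "synonymous" and (
            self.s != 0.0 or self.fitness_class != "neutral"
        ):
            raise ValueError("synonymous mutations must be neutral with s = 0")
        if self.fitness_class == "beneficial" and not self.s > 0:
            raise ValueError("beneficial mutations must have s > 0")
        if self.fitness_class == "deleterious" and not self.s < 0:
            raise ValueError("deleterious mutations must have s < 0")


@dataclass
class CloneTable:
    """Clone-compressed population state: genotype (mutation-id set) -> count."""

    N: int
    clones: list[tuple[frozenset[int], int]] = field(default_factory=list)
    registry: dict[int, MutationRecord] = field(default_factory=dict)
    generation: int = 0
    fixed: frozenset[int] = frozenset()
    _id_counter: itertools.count = field(default_factory=itertools.count, repr=False)

    @classmethod
    def monomorphic(cls, N: int) -> "CloneTable":
        pop = cls(N=N)
        pop.clones = [(frozenset(), N)]
        return pop

    def validate(self) -> None:
        total = sum(c for _, c in self.clones)
        if total != self.N:
            raise ValueError(f"clone counts sum to {total}, expected N={self.N}")
        genotypes = [g for g, _ in self.clones]
        if len(set(genotypes)) != len(genotypes):
            raise ValueError("duplicate genotypes in clone table")
        for g in genotypes:
            for mid in g:
                if mid not in self.registry:
                    raise ValueError(f"mutation id {mid} missing from registry")

    def next_id(self) -> int:
        return next(self._id_counter)

    def clone_fitness(self, genotype: frozenset[int]) -> float:
        f = 1.0
        for mid in genotype:
            f *= 1.0 + self.registry[mid].s
        return max(f, 0.0)

    def variant_frequencies(self) -> dict[int, float]:
        """Cell fraction of every segregating (non-fixed) mutation."""
        counts: dict[int, int] = {}
        for genotype, c in self.clones:
            for mid in genotype:
                counts[mid] = counts.get(mid, 0) + c
        return {
            mid: c / self.N for mid, c in counts.items() if 0 < c < self.N
        }


def sample_mutation(
    params: EvolutionParams,
    config: SimConfig,
    rng: np.random.Generator,
    mid: int = 0,
    generation: int = 0,
) -> MutationRecord:
    """Draw one new mutation under the configured model.

    Site class is synonymous with probability 1 - frac_nonsyn (then
    neutral); otherwise the mutation is beneficial with probability
    ``p_beneficial`` (s ~ +Gamma) and deleterious otherwise
    (s ~ -Gamma).  Degenerate gammas (mean 0) yield s = 0.  Beneficial
    mutations always land in driver territory; all others do so with
    probability ``driver_frac``.

    ``params`` are used at the scale they are given; :func:`run_simulation`
    rescales before drawing.
    """
    if rng.random() >= config.frac_nonsyn:
        return MutationRecord(
            id=mid, site_class="synonymous", fitness_class="neutral", s=0.0,
            in_driver_territory=bool(rng.random() < config.driver_frac),
            origin_gen=generation,
        )
    if params.p_beneficial > 0 and rng.random() < params.p_beneficial:
        shape, rate = params.gamma_pos
        s = float(rng.gamma(shape, 1.0 / rate)) if rate > 0 else 0.0
        return MutationRecord(
            id=mid, site_class="nonsynonymous",
            fitness_class="beneficial" if s > 0 else "neutral", s=s,
            in_driver_territory=True, origin_gen=generation,
        )
    shape, rate = params.gamma_neg
    s = -float(rng.gamma(shape, 1.0 / rate)) if rate > 0 else 0.0
    return MutationRecord(
        id=mid, site_class="nonsynonymous",
        fitness_class="deleterious" if s < 0 else "neutral", s=s,
        in_driver_territory=bool(rng.random() < config.driver_frac),
        origin_gen=generation,
    )


def step_generation(
    pop: CloneTable,
    params: EvolutionParams,
    config: SimConfig,
    rng: np.random.Generator,
) -> CloneTable:
    """One Wright-Fisher generation (reference implementation).

    Offspring counts are multinomial with weights count x fitness; each
    offspring then mutates with probability 1 - exp(-mu.L), receiving a
    zero-truncated Poisson(mu.L) number of new mutations.  ``params``
    are taken at simulation scale (no rescaling here).
    """
    weights = np.array(
        [c * pop.clone_fitness(g) for g, c in pop.clones], dtype=float
    )
    wtot = weights.sum()
    if wtot <= 0:
        raise DegeneratePopulationError(
            "all clones have zero fitness; population cannot reproduce"
        )
    offspring = rng.multinomial(pop.N, weights / wtot)

    mu_genome = params.mu * config.L
    p_mut = 1.0 - np.exp(-mu_genome)
    gen = pop.generation + 1

    new = CloneTable(N=pop.N, registry=pop.registry, generation=gen,
                     fixed=pop.fixed, _id_counter=pop._id_counter)
    counts: dict[frozenset[int], int] = {}
    for (genotype, _), c in zip(pop.clones, offspring):
        if c == 0:
            continue
        m = rng.binomial(c, p_mut) if p_mut > 0 else 0
        if c - m > 0:
            counts[genotype] = counts.get(genotype, 0) + int(c - m)
        for _ in range(int(m)):
            k = _zt_poisson_py(mu_genome, rng)
            muts = set()
            for _ in range(k):
                mid = new.next_id()
                rec = sample_mutation(params, config, rng, mid=mid,
                                      generation=gen)
                new.registry[mid] = rec
                muts.add(mid)
            g2 = genotype | frozenset(muts)
            counts[g2] = counts.get(g2, 0) + 1
    new.clones = sorted(counts.items(), key=lambda kv: sorted(kv[0]))
    new.validate()
    return new


def _zt_poisson_py(lam: float, rng: np.random.Generator) -> int:
    if lam <= 0:
        return 1
    while True:
        k = rng.poisson(lam)
        if k >= 1:
            return int(k)
        # rejection is slow for tiny lam; invert the conditional instead
        if lam < 0.1:
            u = rng.random()
            p0 = np.exp(-lam)
            pk = lam * p0 / (1.0 - p0)
            c, k = pk, 1
            while u > c and k < 500:
                k += 1
                pk *= lam / k
                c += pk
            return k


def run_simulation(
    params: EvolutionParams,
    config: SimConfig | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Evolve a monomorphic population and return its variant table.

    Parameters are rescaled to the configured population size (holding
    N·mu and N·s at reference values), the population is evolved for
    ``config.n_generations`` Wright-Fisher generations via the numba
    kernel, and the segregating (non-fixed) mutations with cell fraction
    >= ``vaf_min`` are returned as a simulated variant table.
    Bit-reproducible for fixed (params, config, seed).
    """
    config = config or SimConfig.desk_scale()
    sim_params = config.rescaled(params)
    try:
        out = _run_engine_checked(sim_params, config, seed)
    except RuntimeError as err:
        raise DegeneratePopulationError(str(err)) from None
    n = len(out["vaf"])
    if n == 0:
        return empty_variant_table("simulated")
    consequence = np.where(out["synonymous"], "silent", "missense")
    gene = np.where(out["driver"], "driver_territory", "passenger_territory")
    vt = make_variant_table(
        {
            "variant_id": np.arange(n, dtype=np.int64),
            "vaf": out["vaf"],
            "consequence": consequence,
            "gene": gene,
            "driver": out["driver"],
            "s": out["s"],
            "origin_gen": out["origin_gen"],
        },
        provenance="simulated",
    )
    return vt


def _run_engine_checked(sim_params: EvolutionParams, config: SimConfig, seed: int):
    return _engine.run_engine(
        N=config.N,
        generations=config.n_generations,
        mu_genome=sim_params.mu * config.L,
        frac_nonsyn=config.frac_nonsyn,
        p_ben=sim_params.p_beneficial,
        gamma_pos=sim_params.gamma_pos,
        gamma_neg=sim_params.gamma_neg,
        driver_frac=config.driver_frac,
        vaf_min=config.vaf_min,
        seed=int(seed) % (2**31 - 1),
    )


def apply_sequencing_model(
    vt: pd.DataFrame,
    depth: int = 5000,
    min_reads: int = 5,
    min_per_strand: int = 2,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Emulate deep targeted sequencing of a variant table with true VAFs.

    Per variant, total supporting reads ~ Binomial(depth, vaf), split
    Binomial(total, 1/2) between strands.  A variant is retained only if
    it is supported by at least ``min_reads`` reads with at least
    ``min_per_strand`` on each strand (the duplex-panel retention rule);
    the observed VAF is total/depth.
    """
    if depth < min_reads:
        raise ValueError(f"depth {depth} below min_reads {min_reads}")
    rng = rng or np.random.default_rng()
    if len(vt) == 0:
        out = vt.copy()
        out.attrs["provenance"] = "observed"
        return out
    total = rng.binomial(depth, vt["vaf"].to_numpy(float))
    fwd = rng.binomial(total, 0.5)
    rev = total - fwd
    keep = (total >= min_reads) & (fwd >= min_per_strand) & (rev >= min_per_strand)
    out = vt.loc[keep].copy()
    out["reads_fwd"] = fwd[keep]
    out["reads_rev"] = rev[keep]
    out["depth"] = depth
    out["vaf"] = total[keep] / depth
    out.attrs["provenance"] = "observed"
    out.reset_index(drop=True, inplace=True)
    return out
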