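"""Evolutionary parameter grids and class labels.

Each simulated hematopoietic population is governed by four parameters:
the per-site per-generation mutation rate ``mu``, the probability ``p``
that a new nonsynonymous mutation is beneficial, and the means of the
gamma distributions from which beneficial (``s_p``) and deleterious
(``s_n``) selection coefficients are drawn.  Every parameter combination
collapses deterministically into one of four evolutionary classes:
neutral, positive, negative, or combination.

Parameters are expressed at a *reference scale* (haploid population of
``N_REF`` = 10,000 cells over an ``L_REF`` = 1 Mb region); the simulator
rescales them to the configured population size so that N·mu and N·s are
invariant (see :class:`SimConfig`).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

#: Canonical class order; also the tie-break order for argmax predictions.
CLASS_LABELS = ("neutral", "negative", "positive", "combination")

#: Reference (full) scale the parameter grids are quoted at.
N_REF = 10_000
L_REF = 1_000_000

#: Mutation-rate grid bounds (per site per generation, reference scale).
MU_RANGE = (1e-7, 1e-5)
#: Beneficial (driver) selection-coefficient means: strong enough to sweep
#: (N.s >= 50 at reference scale), as expected for ARCH driver mutations.
S_POS_MEAN_RANGE = (0.005, 0.05)
#: Deleterious (passenger) means for the negative-only grid sit at the
#: nearly-neutral boundary (N.s ~ 0.3-7 at reference scale): somatic
#: passenger DFEs are dominated by weak effects around the drift barrier,
#: which is also what makes purifying selection hard to tell from drift.
S_NEG_MEAN_RANGE = (3e-5, 7e-4)
#: In combination models the purifying component uses the strong core of
#: the deleterious range: passengers hitchhiking with driver clones are
#: only dynamically relevant when their cost is non-negligible.
S_NEG_MEAN_RANGE_COMBINATION = (0.02, 0.05)


@dataclass(frozen=True)
class EvolutionParams:
    """One point of the evolutionary parameter grid.

    Attributes
    ----------
    mu:
        Per-site per-generation mutation rate, reference scale.
    p_beneficial:
        Probability a new nonsynonymous mutation is beneficial.
        Training grids restrict it to [0, 0.5] plus the pure-positive
        case p = 1.
    gamma_pos, gamma_neg:
        (shape, rate) of the gamma distributions of beneficial and
        deleterious selection coefficients.  A (0, 0) pair encodes a
        degenerate distribution with mean 0 (no selection of that sign).
    """

    mu: float
    p_beneficial: float
    gamma_pos: tuple[float, float] = (0.0, 0.0)
    gamma_neg: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        if self.mu < 0:
            raise ValueError(f"mu must be non-negative, got {self.mu}")
        if not 0.0 <= self.p_beneficial <= 1.0:
            raise ValueError(f"p_beneficial outside [0, 1]: {self.p_beneficial}")
        for name in ("gamma_pos", "gamma_neg"):
            shape, rate = getattr(self, name)
            if shape < 0 or rate < 0 or (shape > 0) != (rate > 0):
                raise ValueError(f"ill-formed {name}=({shape}, {rate})")
        classify_model(self)  # rejects inconsistent tuples

    @property
    def s_pos_mean(self) -> float:
        """Mean beneficial selection coefficient (alpha/beta; 0 if degenerate)."""
        shape, rate = self.gamma_pos
        return shape / rate if rate > 0 else 0.0

    @property
    def s_neg_mean(self) -> float:
        """Mean deleterious selection coefficient (alpha/beta; 0 if degenerate)."""
        shape, rate = self.gamma_neg
        return shape / rate if rate > 0 else 0.0

    @property
    def class_label(self) -> str:
        return classify_model(self)

    def regression_targets(self) -> np.ndarray:
        """Targets for the regression heads: (log10 mu, p, s_p mean, s_n mean)."""
        return np.array(
            [np.log10(self.mu), self.p_beneficial, self.s_pos_mean, self.s_neg_mean]
        )


def classify_model(params: EvolutionParams) -> str:
    """Collapse a parameter tuple into its evolutionary class.

    neutral      : p = 0 and both gamma means are 0
    positive     : p > 0, beneficial mean > 0, deleterious mean = 0
    negative     : p = 0, beneficial mean = 0, deleterious mean > 0
    combination  : p > 0 and both means > 0

    Raises
    ------
    ValueError
        For inconsistent tuples (e.g. p > 0 with a zero beneficial mean),
        which are rejected as ill-formed grid points.
    """
    p = params.p_beneficial
    sp = params.gamma_pos[0] / params.gamma_pos[1] if params.gamma_pos[1] > 0 else 0.0
    sn = params.gamma_neg[0] / params.gamma_neg[1] if params.gamma_neg[1] > 0 else 0.0
    if p == 0 and sp == 0 and sn == 0:
        return "neutral"
    if p > 0 and sp > 0 and sn == 0:
        return "positive"
    if p == 0 and sp == 0 and sn > 0:
        return "negative"
    if p > 0 and sp > 0 and sn > 0:
        return "combination"
    raise ValueError(
        f"ill-formed grid point: p={p}, s_pos_mean={sp}, s_neg_mean={sn}"
    )


@dataclass(frozen=True)
class SimConfig:
    """Configuration of the forward clonal simulation.

    The defaults are the desk-scale study conditions used throughout the
    test-bench: N = 1,000 cells over a 20 kb region.  Relative to the
    reference scale (N_REF = 10,000, L_REF = 1 Mb), per-site mutation
    rates and selection coefficients are multiplied by ``N_ref / N`` so
    that the population-scaled quantities N·mu and N·s are held at their
    reference values; genome length is reduced independently, scaling
    overall diversity (theta) down by ``L / L_ref``.

    ``generations = None`` means 10·N (long-run default); the desk-scale
    constructor uses a fixed shorter run (see :meth:`desk_scale`).
    """

    N: int = 1_000
    L: int = 20_000
    frac_nonsyn: float = 2.0 / 3.0
    driver_frac: float = 0.1
    generations: int | None = None
    sample_n: int = 100
    vaf_min: float = 0.001
    N_ref: int = N_REF
    L_ref: int = L_REF

    def __post_init__(self) -> None:
        if self.N < 2:
            raise ValueError("N must be at least 2")
        if not 0 < self.frac_nonsyn < 1:
            raise ValueError("frac_nonsyn must be in (0, 1)")
        if not 0 < self.vaf_min < 1:
            raise ValueError("vaf_min must be in (0, 1)")
        if self.sample_n < 2:
            raise ValueError("sample_n must be at least 2")
        if self.generations is not None and self.generations < 1:
            raise ValueError("generations must be >= 1")

    @property
    def n_generations(self) -> int:
        return 10 * self.N if self.generations is None else self.generations

    @property
    def scale_factor(self) -> float:
        """Multiplier applied to mu and s to hold N·mu and N·s invariant."""
        return self.N_ref / self.N

    @property
    def L_syn(self) -> float:
        return self.L * (1.0 - self.frac_nonsyn)

    @property
    def L_nonsyn(self) -> float:
        return self.L * self.frac_nonsyn

    def rescaled(self, params: EvolutionParams) -> EvolutionParams:
        """Return simulation-scale parameters for reference-scale ``params``.

        Gamma shapes are preserved; rates are divided by the scale factor
        so that each sampled coefficient is multiplied by N_ref/N.
        """
        f = self.scale_factor
        def scale_gamma(g: tuple[float, float]) -> tuple[float, float]:
            shape, rate = g
            return (shape, rate / f) if rate > 0 else (0.0, 0.0)

        return replace(
            params,
            mu=params.mu * f,
            gamma_pos=scale_gamma(params.gamma_pos),
            gamma_neg=scale_gamma(params.gamma_neg),
        )

    @classmethod
    def desk_scale(cls, **overrides) -> "SimConfig":
        """Desk-scale conditions: N=1,000, L=20 kb, 500 generations."""
        defaults = dict(N=1_000, L=20_000, generations=500)
        defaults.update(overrides)
        return cls(**defaults)

    @classmethod
    def full_scale(cls, **overrides) -> "SimConfig":
        """Reference-scale conditions (N=10,000, 1 Mb); computationally heavy."""
        defaults = dict(N=N_REF, L=L_REF, generations=None)
        defaults.update(overrides)
        return cls(**defaults)


def _log_uniform(rng: np.random.Generator, lo: float, hi: float) -> float:
    return float(np.exp(rng.uniform(np.log(lo), np.log(hi))))


def sample_class_params(
    class_label: str,
    rng: np.random.Generator,
    *,
    mu_range: tuple[float, float] = MU_RANGE,
    s_pos_mean_range: tuple[float, float] = S_POS_MEAN_RANGE,
    s_neg_mean_range: tuple[float, float] = S_NEG_MEAN_RANGE,
    s_neg_mean_range_combination: tuple[float, float] = S_NEG_MEAN_RANGE_COMBINATION,
    shape_pos_range: tuple[float, float] = (0.5, 2.0),
    shape_neg_range: tuple[float, float] = (0.3, 2.0),
    shape_neg_range_combination: tuple[float, float] = (1.0, 3.0),
    p_range: tuple[float, float] = (0.05, 0.5),
    p_pure_positive: float = 0.15,
) -> EvolutionParams:
    """Draw one grid point from the stated parameter ranges of a class.

    mu is log-uniform over ``mu_range``.  Gamma means are log-uniform:
    beneficial coefficients over ``s_pos_mean_range`` (sweep-capable
    driver effects), deleterious over ``s_neg_mean_range`` for the
    negative-only class (the nearly-neutral regime) and over
    ``s_neg_mean_range_combination`` for combination models.  Deleterious
    shapes are log-uniform for the negative-only grid (zero-skewed
    fitness-effect distributions typical of passenger DFEs) and uniform
    for combination models.  For the positive class, p = 1 (pure
    positive selection) is included with probability ``p_pure_positive``;
    otherwise p ~ U over ``p_range``.
    """
    if class_label not in CLASS_LABELS:
        raise ValueError(f"unknown class {class_label!r}")
    mu = _log_uniform(rng, *mu_range)

    def gpos():
        mean = _log_uniform(rng, *s_pos_mean_range)
        shape = float(rng.uniform(*shape_pos_range))
        return (shape, shape / mean)

    if class_label == "neutral":
        return EvolutionParams(mu=mu, p_beneficial=0.0)
    if class_label == "positive":
        p = 1.0 if rng.random() < p_pure_positive else float(rng.uniform(*p_range))
        return EvolutionParams(mu=mu, p_beneficial=p, gamma_pos=gpos())
    if class_label == "negative":
        mean = _log_uniform(rng, *s_neg_mean_range)
        shape = _log_uniform(rng, *shape_neg_range)
        return EvolutionParams(
            mu=mu, p_beneficial=0.0, gamma_neg=(shape, shape / mean)
        )
    # combination
    p = float(rng.uniform(*p_range))
    mean = _log_uniform(rng, *s_neg_mean_range_combination)
    shape = float(rng.uniform(*shape_neg_range_combination))
    return EvolutionParams(
        mu=mu, p_beneficial=p, gamma_pos=gpos(),
        gamma_neg=(shape, shape / mean),
    )


def sample_novel_params(class_label: str, rng: np.random.Generator) -> EvolutionParams:
    """Grid points from parameter families absent from the training grid.

    Used to probe generalization: gamma shapes, selection-mean ranges,
    and the beneficial-probability law are all shifted relative to
    :func:`sample_class_params`.
    """
    return sample_class_params(
        class_label,
        rng,
        s_pos_mean_range=(0.008, 0.04),
        s_neg_mean_range=(5e-5, 5e-4),
        s_neg_mean_range_combination=(0.025, 0.045),
        shape_pos_range=(2.5, 5.0),
        shape_neg_range=(0.5, 2.5),
        shape_neg_range_combination=(1.5, 3.5),
        p_range=(0.1, 0.45),
        p_pure_positive=0.1,
    )
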