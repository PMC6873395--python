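"""Two-stage generative model for sparse sequencing count tables.

Stage one draws per-replicate feature abundances from a gamma law with mean
``mu`` and variance ``phi * mu**2``, so ``phi`` acts as a squared coefficient
of variation describing biological variability. Stage two models sequencing
as drawing a fixed number of reads *without replacement* from the finite pool
of fragments of each replicate, i.e. an exact multivariate hypergeometric
(MHG) draw. Zeros arise naturally: rare features are simply the ones most
likely never to be picked up at a finite depth.

The module is pure in-memory computation; file I/O lives in :mod:`otusim.io`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.special import gammaln

from .errors import (
    DegenerateSampleError,
    InsufficientPopulationError,
    InvalidParameterError,
)

__all__ = [
    "GroupParams",
    "SimulationParams",
    "Population",
    "SimulationResult",
    "sample_gamma_abundances",
    "build_population",
    "sample_mhg",
    "zero_probability",
    "simulate",
]


def _as_readonly(a: np.ndarray) -> np.ndarray:
    a = np.ascontiguousarray(a)
    a.setflags(write=False)
    return a


@dataclass(frozen=True)
class GroupParams:
    """Simulation parameters for one experimental group.

    Parameters
    ----------
    name:
        Group label, used for sample naming and metadata.
    mu:
        Mean abundance level per feature (length ``C``), non-negative.
    phi:
        Biological variability per feature (length ``C``), non-negative.
        ``phi == 0`` means the abundance is deterministic at ``mu``.
    lib_sizes:
        Requested library size (sequencing depth) of each replicate.
    """

    name: str
    mu: np.ndarray
    phi: np.ndarray
    lib_sizes: np.ndarray

    def __post_init__(self) -> None:
        mu = np.asarray(self.mu, dtype=float)
        phi = np.asarray(self.phi, dtype=float)
        lib = np.asarray(self.lib_sizes, dtype=np.int64)
        if mu.ndim != 1 or phi.ndim != 1 or lib.ndim != 1:
            raise InvalidParameterError(
                f"group {self.name!r}: mu, phi and lib_sizes must be 1-D vectors"
            )
        if mu.shape != phi.shape:
            raise InvalidParameterError(
                f"group {self.name!r}: mu has length {mu.size} but phi has length {phi.size}"
            )
        if mu.size == 0:
            raise InvalidParameterError(f"group {self.name!r}: empty parameter vectors")
        if lib.size == 0:
            raise InvalidParameterError(f"group {self.name!r}: needs at least one sample")
        if np.any(mu < 0) or not np.all(np.isfinite(mu)):
            raise InvalidParameterError(f"group {self.name!r}: mu must be finite and >= 0")
        if np.any(phi < 0) or not np.all(np.isfinite(phi)):
            raise InvalidParameterError(f"group {self.name!r}: phi must be finite and >= 0")
        if np.any(lib < 1):
            raise InvalidParameterError(f"group {self.name!r}: lib_sizes must be >= 1")
        object.__setattr__(self, "mu", _as_readonly(mu))
        object.__setattr__(self, "phi", _as_readonly(phi))
        object.__setattr__(self, "lib_sizes", _as_readonly(lib))

    @property
    def n_samples(self) -> int:
        return int(self.lib_sizes.size)

    @property
    def n_features(self) -> int:
        return int(self.mu.size)


@dataclass(frozen=True)
class SimulationParams:
    """Full parameter set: a shared feature axis plus per-group parameters.

    All groups must agree on the number and ordering of features.
    """

    feature_ids: tuple[str, ...]
    groups: tuple[GroupParams, ...]

    def __post_init__(self) -> None:
        feature_ids = tuple(str(f) for f in self.feature_ids)
        groups = tuple(self.groups)
        if not groups:
            raise InvalidParameterError("at least one group is required")
        C = len(feature_ids)
        if C == 0:
            raise InvalidParameterError("feature_ids must be non-empty")
        if len(set(feature_ids)) != C:
            raise InvalidParameterError("feature_ids must be unique")
        names = [g.name for g in groups]
        if len(set(names)) != len(names):
            raise InvalidParameterError(f"duplicate group names: {names}")
        for g in groups:
            if g.n_features != C:
                raise InvalidParameterError(
                    f"group {g.name!r} has {g.n_features} features, expected {C}"
                )
        object.__setattr__(self, "feature_ids", feature_ids)
        object.__setattr__(self, "groups", groups)

    @property
    def n_features(self) -> int:
        return len(self.feature_ids)

    @property
    def n_samples(self) -> int:
        return sum(g.n_samples for g in self.groups)

    @property
    def group_names(self) -> tuple[str, ...]:
        return tuple(g.name for g in self.groups)

    def sample_ids(self) -> tuple[str, ...]:
        """Canonical per-sample identifiers, ``<group>_r<replicate>``."""
        out: list[str] = []
        for g in self.groups:
            out.extend(f"{g.name}_r{j + 1}" for j in range(g.n_samples))
        return tuple(out)

    def sample_groups(self) -> tuple[str, ...]:
        """Group label of each sample, aligned with :meth:`sample_ids`."""
        out: list[str] = []
        for g in self.groups:
            out.extend([g.name] * g.n_samples)
        return tuple(out)


@dataclass(frozen=True)
class Population:
    """Integer urn of fragments available to the sequencer for one sample."""

    m: np.ndarray

    def __post_init__(self) -> None:
        m = np.asarray(self.m, dtype=np.int64)
        if m.ndim != 1 or m.size == 0:
            raise InvalidParameterError("population must be a non-empty 1-D integer vector")
        if np.any(m < 0):
            raise InvalidParameterError("population counts must be >= 0")
        object.__setattr__(self, "m", _as_readonly(m))

    @property
    def total(self) -> int:
        return int(self.m.sum())

    @property
    def n_features(self) -> int:
        return int(self.m.size)


@dataclass(frozen=True)
class SimulationResult:
    """Output of :func:`simulate`.

    ``counts`` is the synthetic OTU table (features x samples, integers).
    ``rel_abundance`` holds the per-sample fragment proportions recorded
    *before* the sequencing draw; its columns sum to one and constitute the
    ground truth composition for benchmarking downstream methods.
    """

    counts: np.ndarray
    rel_abundance: np.ndarray
    params_used: SimulationParams
    seed: int
    population_scale: float = 1.0
    sample_ids: tuple[str, ...] = field(default=())
    sample_groups: tuple[str, ...] = field(default=())

    def __post_init__(self) -> None:
        if not self.sample_ids:
            object.__setattr__(self, "sample_ids", self.params_used.sample_ids())
        if not self.sample_groups:
            object.__setattr__(self, "sample_groups", self.params_used.sample_groups())

    @property
    def feature_ids(self) -> tuple[str, ...]:
        return self.params_used.feature_ids

    def to_table(self):
        """View the simulated counts as a :class:`~otusim.estimation.GroupedCountTable`."""
        from .estimation import GroupedCountTable  # deferred: avoids import cycle

        return GroupedCountTable(
            counts=self.counts.copy(),
            feature_ids=self.feature_ids,
            sample_ids=self.sample_ids,
            group_of=dict(zip(self.sample_ids, self.sample_groups)),
        )


def sample_gamma_abundances(
    mu: Sequence[float],
    phi: Sequence[float],
    n_replicates: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Draw biological-replicate abundances from the gamma stage.

    Entry ``(i, r)`` follows a gamma law with shape ``1/phi[i]`` and scale
    ``phi[i] * mu[i]``, hence mean ``mu[i]`` and variance ``phi[i]*mu[i]**2``.
    ``phi[i] == 0`` degenerates to the constant ``mu[i]``; ``mu[i] == 0``
    yields exact zeros regardless of ``phi``.

    Returns a ``(C, n_replicates)`` float array.
    """
    mu = np.asarray(mu, dtype=float)
    phi = np.asarray(phi, dtype=float)
    if mu.shape != phi.shape or mu.ndim != 1:
        raise InvalidParameterError("mu and phi must be 1-D vectors of equal length")
    if np.any(mu < 0) or np.any(phi < 0):
        raise InvalidParameterError("mu and phi must be elementwise >= 0")
    if n_replicates < 1:
        raise InvalidParameterError("n_replicates must be >= 1")

    out = np.tile(mu[:, None], (1, n_replicates)).astype(float)
    stochastic = (phi > 0) & (mu > 0)
    if np.any(stochastic):
        shape = 1.0 / phi[stochastic]
        scale = phi[stochastic] * mu[stochastic]
        out[stochastic, :] = rng.gamma(
            shape[:, None], scale[:, None], size=(int(stochastic.sum()), n_replicates)
        )
    return out


def build_population(
    raw: Sequence[float], lib_size: int, population_scale: float = 1.0
) -> Population:
    """Convert continuous abundances into an integer fragment urn.

    The target total is ``max(round(sum(raw)), round(lib_size * population_scale))``
    so the urn is always large enough for the requested draw. Integerisation
    uses largest-remainder apportionment, which hits the target total exactly
    and keeps the urn proportions as close as possible to ``raw``.
    """
    raw = np.asarray(raw, dtype=float)
    if raw.ndim != 1 or raw.size == 0:
        raise InvalidParameterError("raw abundances must be a non-empty 1-D vector")
    if np.any(raw < 0) or not np.all(np.isfinite(raw)):
        raise InvalidParameterError("raw abundances must be finite and >= 0")
    if lib_size < 1:
        raise InvalidParameterError("lib_size must be >= 1")
    if population_scale < 1.0:
        raise InvalidParameterError("population_scale must be >= 1")
    total_raw = float(raw.sum())
    if total_raw <= 0.0:
        raise DegenerateSampleError("all abundances are zero; cannot build a population")

    target = max(int(round(total_raw)), int(round(lib_size * population_scale)))
    quotas = raw * (target / total_raw)
    base = np.floor(quotas).astype(np.int64)
    short = target - int(base.sum())
    if short > 0:
        # hand the leftover units to the largest fractional remainders;
        # stable sort makes ties deterministic (lower index wins)
        remainders = quotas - base
        order = np.argsort(-remainders, kind="stable")
        base[order[:short]] += 1
    return Population(m=base)


def sample_mhg(
    pop: Population,
    n_draws: int,
    rng: np.random.Generator,
    size: int | None = None,
) -> np.ndarray:
    """Exact multivariate hypergeometric draw from ``pop``.

    Uses the sequential conditional decomposition: feature ``i`` is drawn from
    a univariate hypergeometric over the items not yet allocated, and the last
    feature receives the remainder. This is exact and O(C) per replicate.

    With ``size=None`` a single draw is returned as a length-``C`` vector;
    otherwise a ``(C, size)`` matrix of independent draws.
    """
    n_draws = int(n_draws)
    if n_draws < 0:
        raise InvalidParameterError("n_draws must be >= 0")
    total = pop.total
    if n_draws > total:
        raise InsufficientPopulationError(
            f"requested {n_draws} draws from a population of {total} fragments"
        )
    single = size is None
    n_rep = 1 if single else int(size)
    if n_rep < 1:
        raise InvalidParameterError("size must be >= 1")

    m = pop.m
    C = m.size
    out = np.zeros((C, n_rep), dtype=np.int64)
    remaining_total = total
    remaining_draws = np.full(n_rep, n_draws, dtype=np.int64)
    for i in range(C - 1):
        ngood = int(m[i])
        nbad = remaining_total - ngood
        if ngood > 0:
            if nbad == 0:
                # only feature i (and later all-zero features) remain
                out[i] = remaining_draws
            else:
                active = remaining_draws > 0
                if np.any(active):
                    out[i, active] = rng.hypergeometric(
                        ngood, nbad, remaining_draws[active]
                    )
        remaining_total = nbad
        remaining_draws = remaining_draws - out[i]
    out[C - 1] = remaining_draws
    return out[:, 0] if single else out


def zero_probability(pop: Population, n_draws: int, feature: int) -> float:
    """Closed-form probability that ``feature`` receives zero reads.

    ``P(Y_i = 0) = C(total - m_i, n) / C(total, n)``, evaluated in log space
    so large urns do not overflow.
    """
    n_draws = int(n_draws)
    total = pop.total
    if n_draws < 0 or n_draws > total:
        raise InvalidParameterError("n_draws must lie in [0, population total]")
    m_i = int(pop.m[feature])
    if m_i == 0:
        return 1.0
    if n_draws > total - m_i:
        return 0.0

    def log_comb(n: int, k: int) -> float:
        return float(gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1))

    return float(np.exp(log_comb(total - m_i, n_draws) - log_comb(total, n_draws)))


def _sample_rng(seed: int, group_index: int, sample_index: int) -> np.random.Generator:
    # substream keyed by (group, sample): reproducible regardless of loop order
    ss = np.random.SeedSequence(entropy=int(seed), spawn_key=(group_index, sample_index))
    return np.random.default_rng(ss)


def simulate(
    params: SimulationParams, seed: int, population_scale: float = 1.0
) -> SimulationResult:
    """Run the full gamma + MHG generative chain for every sample.

    For each sample: draw replicate abundances from the gamma stage, build the
    integer fragment urn, record its proportions as the ground-truth relative
    abundances, then sample the requested library size without replacement.
    The same ``(params, seed, population_scale)`` triple always produces
    bit-identical output.
    """
    C = params.n_features
    N = params.n_samples
    counts = np.zeros((C, N), dtype=np.int64)
    rel = np.zeros((C, N), dtype=float)
    col = 0
    for g_idx, group in enumerate(params.groups):
        for s_idx in range(group.n_samples):
            n_j = int(group.lib_sizes[s_idx])
            rng = _sample_rng(seed, g_idx, s_idx)
            try:
                raw = sample_gamma_abundances(group.mu, group.phi, 1, rng)[:, 0]
                pop = build_population(raw, n_j, population_scale)
                rel[:, col] = pop.m / pop.total
                counts[:, col] = sample_mhg(pop, n_j, rng)
            except (InvalidParameterError, DegenerateSampleError,
                    InsufficientPopulationError) as err:
                raise type(err)(
                    f"group {group.name!r}, sample {s_idx + 1}: {err}"
                ) from err
            col += 1
    return SimulationResult(
        counts=counts,
        rel_abundance=rel,
        params_used=params,
        seed=int(seed),
        population_scale=float(population_scale),
    )
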