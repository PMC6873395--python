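"""Named, parameterized scenario families and the test-fixture generator.

A :class:`PresetScenario` is a compact recipe that expands deterministically
into a full :class:`~otusim.model.SimulationParams`: an abundance profile
(uniform, geometric or lognormal), a variability level, per-group library
sizes, and optional injected differential abundance between groups. The
built-in catalogue spans the regimes seen in real 16S studies: sparsity
roughly 70-97%, depths from a few thousand to several hundred thousand
reads, 2-40 groups and 2-5 replicates per group.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict
from typing import Sequence

import numpy as np

from .errors import InvalidParameterError
from .model import GroupParams, SimulationParams, SimulationResult, simulate

__all__ = [
    "PresetScenario",
    "expand_preset",
    "generate_fixture",
    "list_presets",
    "get_preset",
    "describe_preset",
    "ABUNDANCE_SHAPES",
]

ABUNDANCE_SHAPES = ("uniform", "geometric_skew", "lognormal_skew")


@dataclass(frozen=True)
class PresetScenario:
    """Recipe that expands into a full simulation parameter set.

    ``total_intensity`` fixes the sum of the group-1 ``mu`` vector; when left
    ``None`` it defaults to the midpoint of ``depth_range`` so that abundances
    live on the count scale of the simulated depths. ``phi_level`` is either a
    scalar applied to every feature or an explicit per-feature vector.
    """

    name: str
    n_features: int
    n_groups: int
    replicates_per_group: int
    abundance_shape: str = "geometric_skew"
    skew_parameter: float = 0.99
    phi_level: float | Sequence[float] = 0.5
    depth_range: tuple[int, int] = (10_000, 50_000)
    fraction_da_features: float = 0.0
    da_fold_change: float = 2.0
    seed: int = 0
    total_intensity: float | None = None

    def __post_init__(self) -> None:
        if self.n_features < 2:
            raise InvalidParameterError("n_features must be >= 2")
        if self.n_groups < 1:
            raise InvalidParameterError("n_groups must be >= 1")
        if self.replicates_per_group < 1:
            raise InvalidParameterError("replicates_per_group must be >= 1")
        if self.abundance_shape not in ABUNDANCE_SHAPES:
            raise InvalidParameterError(
                f"unknown abundance_shape {self.abundance_shape!r}; "
                f"choose from {ABUNDANCE_SHAPES}"
            )
        lo, hi = self.depth_range
        if lo < 1 or lo > hi:
            raise InvalidParameterError("depth_range must satisfy 1 <= min <= max")
        if not 0.0 <= self.fraction_da_features <= 1.0:
            raise InvalidParameterError("fraction_da_features must be in [0, 1]")
        if self.fraction_da_features > 0 and self.da_fold_change <= 1.0:
            raise InvalidParameterError("da_fold_change must be > 1")
        object.__setattr__(self, "depth_range", (int(lo), int(hi)))

    def to_dict(self) -> dict:
        d = asdict(self)
        d["depth_range"] = list(self.depth_range)
        if not np.isscalar(d["phi_level"]):
            d["phi_level"] = [float(x) for x in np.asarray(self.phi_level).ravel()]
        return d


def _base_mu(scenario: PresetScenario, rng: np.random.Generator) -> np.ndarray:
    C = scenario.n_features
    total = scenario.total_intensity
    if total is None:
        lo, hi = scenario.depth_range
        total = (lo + hi) / 2.0
    if total <= 0:
        raise InvalidParameterError("total_intensity must be > 0")
    if scenario.abundance_shape == "uniform":
        weights = np.ones(C)
    elif scenario.abundance_shape == "geometric_skew":
        r = scenario.skew_parameter
        if not 0.0 < r < 1.0:
            raise InvalidParameterError(
                "geometric_skew needs skew_parameter (common ratio) in (0, 1)"
            )
        weights = r ** np.arange(C)
    else:  # lognormal_skew
        sigma = scenario.skew_parameter
        if sigma <= 0:
            raise InvalidParameterError(
                "lognormal_skew needs skew_parameter (log-sd) > 0"
            )
        weights = rng.lognormal(mean=0.0, sigma=sigma, size=C)
    return total * weights / weights.sum()


def _phi_vector(scenario: PresetScenario) -> np.ndarray:
    phi = scenario.phi_level
    if np.isscalar(phi):
        if phi < 0:
            raise InvalidParameterError("phi_level must be >= 0")
        return np.full(scenario.n_features, float(phi))
    phi = np.asarray(phi, dtype=float)
    if phi.shape != (scenario.n_features,):
        raise InvalidParameterError(
            f"per-feature phi_level must have length {scenario.n_features}"
        )
    return phi


def expand_preset(scenario: PresetScenario) -> SimulationParams:
    """Deterministically expand a scenario into simulation parameters.

    Group 1 carries the base abundance profile. Each further group perturbs a
    random subset of ``fraction_da_features`` features by ``da_fold_change``
    — half up, half down (the odd one goes up) — giving known differential
    abundance for benchmarking. Library sizes are uniform integers over
    ``depth_range``. Expansion is pure: the same scenario always yields the
    same parameters.
    """
    rng = np.random.default_rng(
        np.random.SeedSequence(entropy=int(scenario.seed), spawn_key=(0xA11CE,))
    )
    C = scenario.n_features
    base = _base_mu(scenario, rng)
    phi = _phi_vector(scenario)
    lo, hi = scenario.depth_range

    groups: list[GroupParams] = []
    for k in range(scenario.n_groups):
        mu = base.copy()
        if k > 0 and scenario.fraction_da_features > 0:
            n_da = int(round(scenario.fraction_da_features * C))
            if n_da > 0:
                chosen = rng.choice(C, size=n_da, replace=False)
                n_up = math.ceil(n_da / 2)
                mu[chosen[:n_up]] *= scenario.da_fold_change
                mu[chosen[n_up:]] /= scenario.da_fold_change
        lib = rng.integers(lo, hi + 1, size=scenario.replicates_per_group)
        groups.append(
            GroupParams(name=f"group_{k + 1}", mu=mu, phi=phi, lib_sizes=lib)
        )
    feature_ids = tuple(f"OTU_{i + 1}" for i in range(C))
    return SimulationParams(feature_ids=feature_ids, groups=tuple(groups))


def generate_fixture(
    scenario: PresetScenario, population_scale: float = 1.0
) -> tuple[SimulationParams, SimulationResult]:
    """Expand a scenario and simulate it, returning ground truth and data."""
    params = expand_preset(scenario)
    result = simulate(params, seed=scenario.seed, population_scale=population_scale)
    return params, result


# Catalogue of replacement scenario families. Ranges are modelled on published
# real-data regimes (depths ~3e3-8e5, 2-40 groups, 2-5 replicates, sparsity up
# to ~97%); the numeric content is ours, not a reproduction of any original
# pre-coded parameter set.
_CATALOGUE: dict[str, dict] = {
    "tiny_uniform": dict(
        n_features=50,
        n_groups=2,
        replicates_per_group=3,
        abundance_shape="uniform",
        skew_parameter=0.0,
        phi_level=0.3,
        depth_range=(3_000, 5_000),
    ),
    "gut_like": dict(
        n_features=3541,
        n_groups=2,
        replicates_per_group=5,
        abundance_shape="geometric_skew",
        skew_parameter=0.9975,
        phi_level=0.6,
        depth_range=(88_692, 832_309),
    ),
    "cheese_like": dict(
        n_features=310,
        n_groups=40,
        replicates_per_group=3,
        abundance_shape="lognormal_skew",
        skew_parameter=2.5,
        phi_level=1.0,
        depth_range=(28_536, 349_754),
    ),
    "hmp_like": dict(
        n_features=9758,
        n_groups=8,
        replicates_per_group=5,
        abundance_shape="lognormal_skew",
        skew_parameter=3.0,
        phi_level=1.5,
        depth_range=(2_798, 24_095),
    ),
    "da_benchmark": dict(
        n_features=1000,
        n_groups=2,
        replicates_per_group=5,
        abundance_shape="geometric_skew",
        skew_parameter=0.995,
        phi_level=0.4,
        depth_range=(20_000, 40_000),
        fraction_da_features=0.1,
        da_fold_change=3.0,
    ),
}


def list_presets() -> tuple[str, ...]:
    return tuple(sorted(_CATALOGUE))


def get_preset(name: str, seed: int = 0, **overrides) -> PresetScenario:
    """Instantiate a catalogue scenario, optionally overriding any field."""
    try:
        spec = dict(_CATALOGUE[name])
    except KeyError:
        raise InvalidParameterError(
            f"unknown preset {name!r}; available: {', '.join(list_presets())}"
        ) from None
    spec.update(overrides)
    spec.setdefault("seed", seed)
    if "seed" in overrides:
        spec["seed"] = overrides["seed"]
    else:
        spec["seed"] = seed
    return PresetScenario(name=name, **spec)


def describe_preset(name: str) -> dict:
    return get_preset(name).to_dict()
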