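"""Estimate simulation parameters from a real grouped count table.

Workflow: normalise samples to a common scale, then take per-group moments.
The mean of normalised counts gives ``mu``; the variance, after subtracting
the Poisson-like component contributed by sequencing, gives the biological
variability ``phi`` (variance = mu * (1 + mu * phi), so
``phi = (s^2 - mu) / mu^2``). A plain CV^2 estimator is available as an
alternative for data where the technical component is negligible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Mapping, Sequence

import numpy as np

from .errors import (
    DegenerateSampleError,
    EstimationError,
    InvalidParameterError,
    TableFormatError,
)
from .model import GroupParams, SimulationParams

__all__ = [
    "GroupedCountTable",
    "Normalization",
    "PhiEstimator",
    "EstimatorConfig",
    "normalize_counts",
    "estimate_parameters",
    "assemble_params",
]


@dataclass
class GroupedCountTable:
    """Features x samples matrix of non-negative integer counts with group labels."""

    counts: np.ndarray
    feature_ids: tuple[str, ...]
    sample_ids: tuple[str, ...]
    group_of: dict[str, str]

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts)
        if counts.ndim != 2 or counts.size == 0:
            raise TableFormatError("count matrix must be 2-D and non-empty")
        if not np.issubdtype(counts.dtype, np.integer):
            as_int = np.asarray(counts, dtype=np.int64)
            if not np.array_equal(as_int, counts):
                raise TableFormatError("count matrix contains non-integer entries")
            counts = as_int
        if np.any(counts < 0):
            raise TableFormatError("count matrix contains negative entries")
        self.counts = counts.astype(np.int64)
        self.feature_ids = tuple(str(f) for f in self.feature_ids)
        self.sample_ids = tuple(str(s) for s in self.sample_ids)
        C, N = self.counts.shape
        if len(self.feature_ids) != C:
            raise TableFormatError(
                f"{len(self.feature_ids)} feature ids for {C} matrix rows"
            )
        if len(self.sample_ids) != N:
            raise TableFormatError(
                f"{len(self.sample_ids)} sample ids for {N} matrix columns"
            )
        if len(set(self.feature_ids)) != C:
            raise TableFormatError("duplicate feature ids")
        if len(set(self.sample_ids)) != N:
            raise TableFormatError("duplicate sample ids")
        missing = [s for s in self.sample_ids if s not in self.group_of]
        if missing:
            raise TableFormatError(f"samples without a group label: {missing}")
        self.group_of = {s: str(self.group_of[s]) for s in self.sample_ids}

    @property
    def n_features(self) -> int:
        return self.counts.shape[0]

    @property
    def n_samples(self) -> int:
        return self.counts.shape[1]

    @property
    def group_labels(self) -> tuple[str, ...]:
        """Group labels in first-appearance order over the sample axis."""
        seen: dict[str, None] = {}
        for s in self.sample_ids:
            seen.setdefault(self.group_of[s], None)
        return tuple(seen)

    @property
    def lib_sizes(self) -> np.ndarray:
        return self.counts.sum(axis=0)

    def columns_of(self, group: str) -> np.ndarray:
        idx = [j for j, s in enumerate(self.sample_ids) if self.group_of[s] == group]
        if not idx:
            raise TableFormatError(f"unknown group label {group!r}")
        return np.asarray(idx, dtype=int)


class Normalization(str, Enum):
    TOTAL_SUM = "total-sum-to-mean-depth"
    MEDIAN_OF_RATIOS = "median-of-ratios"


class PhiEstimator(str, Enum):
    POISSON_CORRECTED = "poisson_corrected"
    CV2 = "cv2"


@dataclass(frozen=True)
class EstimatorConfig:
    normalization: Normalization = Normalization.TOTAL_SUM
    phi_estimator: PhiEstimator = PhiEstimator.POISSON_CORRECTED
    phi_floor: float = 1e-8
    min_replicates_for_phi: int = 2

    def __post_init__(self) -> None:
        object.__setattr__(self, "normalization", Normalization(self.normalization))
        object.__setattr__(self, "phi_estimator", PhiEstimator(self.phi_estimator))
        if self.phi_floor <= 0:
            raise InvalidParameterError("phi_floor must be > 0")
        if self.min_replicates_for_phi < 2:
            raise InvalidParameterError("min_replicates_for_phi must be >= 2")


def scaling_factors(table: GroupedCountTable, config: EstimatorConfig) -> np.ndarray:
    """Per-sample multiplicative factors used by :func:`normalize_counts`."""
    lib = table.lib_sizes.astype(float)
    zero_cols = np.flatnonzero(lib == 0)
    if zero_cols.size:
        names = [table.sample_ids[j] for j in zero_cols]
        raise DegenerateSampleError(f"all-zero sample column(s): {names}")
    if config.normalization is Normalization.TOTAL_SUM:
        return lib.mean() / lib
    # median-of-ratios: reference is the geometric mean profile over features
    # observed in every sample; factors rescaled to mean 1 to stay count-scale
    counts = table.counts.astype(float)
    everywhere = np.all(counts > 0, axis=1)
    if not np.any(everywhere):
        raise EstimationError(
            "median-of-ratios needs at least one feature observed in every sample; "
            "use total-sum normalization for very sparse tables"
        )
    ref = np.exp(np.mean(np.log(counts[everywhere]), axis=1))
    size_factors = np.median(counts[everywhere] / ref[:, None], axis=0)
    size_factors /= size_factors.mean()
    return 1.0 / size_factors


def normalize_counts(table: GroupedCountTable, config: EstimatorConfig) -> np.ndarray:
    """Rescale each sample column to a common depth; values stay count-scale."""
    return table.counts.astype(float) * scaling_factors(table, config)[None, :]


def _phi_from_moments(
    mu: np.ndarray, s2: np.ndarray, config: EstimatorConfig
) -> np.ndarray:
    phi = np.zeros_like(mu)
    pos = mu > 0
    if config.phi_estimator is PhiEstimator.POISSON_CORRECTED:
        phi[pos] = (s2[pos] - mu[pos]) / mu[pos] ** 2
    else:
        phi[pos] = s2[pos] / mu[pos] ** 2
    phi[pos] = np.maximum(phi[pos], config.phi_floor)
    return phi


def estimate_parameters(
    table: GroupedCountTable,
    config: EstimatorConfig | None = None,
    user_phi: Mapping[str, Sequence[float]] | None = None,
) -> SimulationParams:
    """Estimate per-group ``mu``, ``phi`` and library sizes from a real table.

    Groups with fewer than ``min_replicates_for_phi`` samples cannot support a
    variance estimate; they are an error unless ``user_phi`` supplies a vector
    for them (hybrid mode).
    """
    config = config or EstimatorConfig()
    user_phi = dict(user_phi or {})
    normalized = normalize_counts(table, config)
    groups: list[GroupParams] = []
    for label in table.group_labels:
        cols = table.columns_of(label)
        sub = normalized[:, cols]
        mu = sub.mean(axis=1)
        if label in user_phi:
            phi = np.asarray(user_phi[label], dtype=float)
            if phi.shape != (table.n_features,):
                raise EstimationError(
                    f"user phi for group {label!r} has length {phi.size}, "
                    f"expected {table.n_features}"
                )
        elif cols.size < config.min_replicates_for_phi:
            raise EstimationError(
                f"group {label!r} has {cols.size} replicate(s); at least "
                f"{config.min_replicates_for_phi} are needed to estimate phi. "
                "Supply phi for this group explicitly (hybrid mode)."
            )
        else:
            s2 = sub.var(axis=1, ddof=1)
            phi = _phi_from_moments(mu, s2, config)
        groups.append(
            GroupParams(
                name=label,
                mu=mu,
                phi=phi,
                lib_sizes=table.counts[:, cols].sum(axis=0),
            )
        )
    return SimulationParams(feature_ids=table.feature_ids, groups=tuple(groups))


def assemble_params(
    estimated: SimulationParams | None = None,
    *,
    feature_ids: Sequence[str] | None = None,
    group_names: Sequence[str] | None = None,
    user_mu: Mapping[str, Sequence[float]] | None = None,
    user_phi: Mapping[str, Sequence[float]] | None = None,
    user_lib_sizes: Mapping[str, Sequence[int]] | None = None,
) -> SimulationParams:
    """Merge estimated and user-supplied parameters (hybrid mode).

    User vectors, keyed by group name, override the estimated ones per
    component. Without an estimate, ``feature_ids``, ``group_names`` and all
    three user mappings must fully specify the parameter set.
    """
    user_mu = dict(user_mu or {})
    user_phi = dict(user_phi or {})
    user_lib_sizes = dict(user_lib_sizes or {})

    if estimated is not None:
        feature_ids = estimated.feature_ids
        group_names = estimated.group_names
        base = {g.name: g for g in estimated.groups}
    else:
        if feature_ids is None or group_names is None:
            raise InvalidParameterError(
                "without an estimate, feature_ids and group_names are required"
            )
        base = {}

    groups: list[GroupParams] = []
    for name in group_names:
        est = base.get(name)
        mu = user_mu.get(name, est.mu if est is not None else None)
        phi = user_phi.get(name, est.phi if est is not None else None)
        lib = user_lib_sizes.get(name, est.lib_sizes if est is not None else None)
        for component, value in (("mu", mu), ("phi", phi), ("lib_sizes", lib)):
            if value is None:
                raise InvalidParameterError(
                    f"group {name!r}: no source provides {component}"
                )
        mu = np.asarray(mu, dtype=float)
        phi = np.asarray(phi, dtype=float)
        if mu.size != len(feature_ids) or phi.size != len(feature_ids):
            raise InvalidParameterError(
                f"group {name!r}: mu/phi length must equal the "
                f"{len(feature_ids)} features"
            )
        groups.append(GroupParams(name=name, mu=mu, phi=phi, lib_sizes=np.asarray(lib)))
    return SimulationParams(feature_ids=tuple(feature_ids), groups=tuple(groups))
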