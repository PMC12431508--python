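"""Latin-hypercube perturbation and synthetic-population generation.

Grows a cohort of synthetic users from a handful of real ones: each
realization adds a fresh stratified-normal perturbation to the real
rows, trains the WGAN on the perturbed data, and harvests every
converged snapshot at least 1000 epochs apart.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import norm

from .errors import ConfigurationError, DegenerateFeatureError
from .moments import DataMatrix
from .wgan import TrainConfig, train_with_harvest

__all__ = [
    "PerturbationConfig",
    "LHSample",
    "PerturbedDataset",
    "CohortMember",
    "PopulationCohort",
    "lhs_normal_samples",
    "perturb_dataset",
    "generate_population",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PerturbationConfig:
    """Controls the LHS perturbation / realization loop."""

    epsilon: float = 0.03
    seed: int = 0
    realizations: int = 5
    epoch_separation: int = 1000
    max_epochs: int = 50_000

    def __post_init__(self):
        if self.epsilon < 0:
            raise ConfigurationError("epsilon must be >= 0")
        if self.epoch_separation < 1:
            raise ConfigurationError("epoch_separation must be >= 1")


@dataclass
class LHSample:
    """n x m stratified standard-normal draws (one per stratum per column)."""

    values: np.ndarray


@dataclass
class PerturbedDataset:
    """Perturbed data in [0, 1] units plus the scaling metadata needed to
    recover raw units (per-feature min/max of the perturbed raw data) and
    the real data's original ranges used for back-scaling."""

    normalized: np.ndarray
    mins: np.ndarray
    maxs: np.ndarray
    real_mins: np.ndarray
    real_maxs: np.ndarray
    feature_names: list[str]

    def raw(self) -> np.ndarray:
        return self.normalized * (self.maxs - self.mins) + self.mins

    def as_data_matrix(self) -> DataMatrix:
        return DataMatrix(values=self.raw(), feature_names=self.feature_names)


@dataclass
class CohortMember:
    """One harvested synthetic user with full provenance."""

    user: str
    epsilon: float
    realization: int
    epoch: int
    data: np.ndarray


@dataclass
class PopulationCohort:
    """All harvested members plus per-realization accounting."""

    members: list[CohortMember] = field(default_factory=list)
    counts: dict[tuple[str, float, int], int] = field(default_factory=dict)
    failed_realizations: int = 0

    def __len__(self) -> int:
        return len(self.members)


def lhs_normal_samples(n: int, m: int, seed: int | np.random.Generator = 0) -> LHSample:
    """Latin-hypercube standard-normal sample, n rows x m columns.

    Per column: split [0, 1] into n equal strata, draw one uniform in
    each, shuffle the strata, and map through the normal quantile
    function — exactly one draw per stratum by construction.
    """
    if n < 1:
        raise ConfigurationError("n must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    u = (np.arange(n)[:, None] + rng.uniform(size=(n, m))) / n
    for j in range(m):
        u[:, j] = u[rng.permutation(n), j]
    return LHSample(values=norm.ppf(u))


def perturb_dataset(
    R: DataMatrix | np.ndarray, epsilon: float, seed: int | np.random.Generator = 0
) -> PerturbedDataset:
    """Seven-step LHS perturbation of a real dataset.

    (i) normalize each real feature to [0, 1]; (ii) draw one LHS
    standard-normal sample per feature, matching the row count;
    (iii) form P = R + epsilon * L in normalized units; (iv) scale P
    back to each feature's original data range; (v) clamp the step
    column at >= 0 (exact zeros are physiological and preserved);
    (vi) re-normalize each perturbed feature to [0, 1]; (vii) the
    result is ready to feed the WGAN, with scaling metadata attached.
    """
    if epsilon < 0:
        raise ConfigurationError("epsilon must be >= 0")
    if isinstance(R, DataMatrix):
        values, names = R.values, R.feature_names
    else:
        values = np.asarray(R, dtype=float)
        names = [f"f{i}" for i in range(values.shape[1])]
    n, m = values.shape
    real_mins = values.min(axis=0)
    real_maxs = values.max(axis=0)
    span = real_maxs - real_mins
    if np.any(span <= 0):
        raise DegenerateFeatureError("constant feature cannot be perturbed")
    normalized_real = (values - real_mins) / span
    L = lhs_normal_samples(n, m, seed).values
    P = normalized_real + epsilon * L
    raw = P * span + real_mins
    step_cols = [j for j, name in enumerate(names) if "step" in name.lower()]
    for j in step_cols:
        raw[:, j] = np.maximum(raw[:, j], 0.0)
    mins = raw.min(axis=0)
    maxs = raw.max(axis=0)
    out_span = np.where(maxs > mins, maxs - mins, 1.0)
    return PerturbedDataset(
        normalized=(raw - mins) / out_span,
        mins=mins,
        maxs=maxs,
        real_mins=real_mins,
        real_maxs=real_maxs,
        feature_names=list(names),
    )


def generate_population(
    users: list[DataMatrix],
    epsilon_grid: list[float],
    config: PerturbationConfig,
    train_config: TrainConfig | None = None,
    user_ids: list[str] | None = None,
) -> PopulationCohort:
    """Grow a synthetic cohort from real users via perturb-then-train.

    For every (user, epsilon, realization) triple: recompute a fresh LHS
    perturbation, train the WGAN to ``max_epochs`` gating on all three
    channel tolerances, and harvest converged snapshots separated by at
    least ``epoch_separation`` epochs.  Realizations that never harvest
    are counted, logged, and do not abort the run.
    """
    if not users:
        raise ConfigurationError("need at least one user")
    train_config = train_config or TrainConfig()
    user_ids = user_ids or [f"user{i}" for i in range(len(users))]
    cohort = PopulationCohort()
    seed_stream = np.random.default_rng(config.seed)
    for uid, user in zip(user_ids, users):
        for eps in epsilon_grid:
            for r in range(config.realizations):
                pert_seed = int(seed_stream.integers(0, 2**31 - 1))
                train_seed = int(seed_stream.integers(0, 2**31 - 1))
                perturbed = perturb_dataset(user, eps, seed=pert_seed)
                cfg = TrainConfig(
                    max_epochs=config.max_epochs,
                    rhr_tol=train_config.rhr_tol,
                    ahr_tol=train_config.ahr_tol,
                    ohr_tol=train_config.ohr_tol,
                    critic_steps_per_gen_step=train_config.critic_steps_per_gen_step,
                    learning_rate=train_config.learning_rate,
                    batch_size=train_config.batch_size,
                    check_every=train_config.check_every,
                    gate_channels=("rhr", "ahr", "ohr"),
                    seed=train_seed,
                )
                _, harvests = train_with_harvest(
                    perturbed.as_data_matrix(), cfg,
                    separation=config.epoch_separation,
                )
                key = (uid, eps, r)
                cohort.counts[key] = len(harvests)
                if not harvests:
                    cohort.failed_realizations += 1
                    logger.warning(
                        "realization produced no harvest: user=%s eps=%g r=%d",
                        uid, eps, r,
                    )
                for epoch, synth in harvests:
                    cohort.members.append(
                        CohortMember(user=uid, epsilon=eps, realization=r,
                                     epoch=epoch, data=synth)
                    )
    return cohort
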