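"""Weight-clipped Wasserstein GAN for tabular (heart rate, steps) twins.

Both networks are single-hidden-layer perceptrons (256 LeakyReLU units,
slope 0.2): the generator maps 100-dimensional standard-normal noise
through a tanh output to 2 features scaled to (-1, 1); the critic maps
2 features to one unbounded score, with all weights clipped to
[-0.01, 0.01] after every update to approximate the 1-Lipschitz
constraint.  Training minimizes the critic/generator min-max objective
with RMSProp, the classic companion optimizer to weight clipping.

Implemented directly on numpy (explicit backprop) so the package has no
deep-learning framework dependency; at two features and 256 hidden
units this is faster than framework overhead would allow anyway.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.stats import wasserstein_distance

from .errors import ConfigurationError, DegenerateFeatureError, TrainingDivergedError
from .moments import DataMatrix

__all__ = [
    "GeneratorSpec",
    "CriticSpec",
    "TrainConfig",
    "TwinResult",
    "WGANNetworks",
    "init_networks",
    "wgan_train_step",
    "critic_step",
    "generator_step",
    "pdf_delta",
    "train_twin",
    "train_with_harvest",
    "MinMaxScaler",
]

logger = logging.getLogger(__name__)

CHANNELS = ("rhr", "ahr", "ohr")


@dataclass(frozen=True)
class GeneratorSpec:
    noise_dim: int = 100
    hidden_units: int = 256
    leaky_slope: float = 0.2
    output_dim: int = 2


@dataclass(frozen=True)
class CriticSpec:
    input_dim: int = 2
    hidden_units: int = 256
    leaky_slope: float = 0.2
    clip_bound: float = 0.01


@dataclass(frozen=True)
class TrainConfig:
    """Training schedule and convergence tolerances.

    ``gate_channels`` lists which per-channel PDF distances must fall
    below tolerance for convergence: a lone digital twin gates on RHR
    only; population generation gates on all three channels.
    """

    max_epochs: int = 50_000
    rhr_tol: float = 7e-3
    ahr_tol: float = 1e-1
    ohr_tol: float = 1.5e-2
    critic_steps_per_gen_step: int = 5
    learning_rate: float = 5e-5
    batch_size: int = 64
    check_every: int = 100
    gate_channels: tuple[str, ...] = ("rhr",)
    seed: int = 0

    def __post_init__(self):
        if self.max_epochs < 1:
            raise ConfigurationError("max_epochs must be >= 1")
        for name in ("rhr_tol", "ahr_tol", "ohr_tol"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be positive")
        unknown = set(self.gate_channels) - set(CHANNELS)
        if unknown:
            raise ConfigurationError(f"unknown gate channels: {sorted(unknown)}")

    def tol(self, channel: str) -> float:
        return {"rhr": self.rhr_tol, "ahr": self.ahr_tol, "ohr": self.ohr_tol}[channel]


@dataclass
class TwinResult:
    """Output of a twin-training run."""

    synthetic: DataMatrix
    epochs_run: int
    converged: bool
    pdf_deltas: list[tuple[int, dict[str, float | None]]]
    seed: int


class MinMaxScaler:
    """Per-feature min-max map to (-1, 1), invertible back to raw units."""

    def __init__(self, data: np.ndarray):
        data = np.asarray(data, dtype=float)
        self.mins = data.min(axis=0)
        self.maxs = data.max(axis=0)
        span = self.maxs - self.mins
        if np.any(span <= 0):
            raise DegenerateFeatureError("constant feature cannot be min-max scaled")
        self.span = span

    def transform(self, x: np.ndarray) -> np.ndarray:
        return 2.0 * (x - self.mins) / self.span - 1.0

    def inverse(self, x: np.ndarray) -> np.ndarray:
        return (x + 1.0) / 2.0 * self.span + self.mins


class _MLP:
    """One-hidden-layer perceptron with explicit backprop and RMSProp."""

    def __init__(self, d_in: int, d_hidden: int, d_out: int, slope: float,
                 out_tanh: bool, rng: np.random.Generator):
        self.slope = slope
        self.out_tanh = out_tanh
        self.params = {
            "W1": rng.normal(0.0, 0.02, size=(d_in, d_hidden)),
            "b1": np.zeros(d_hidden),
            "W2": rng.normal(0.0, 0.02, size=(d_hidden, d_out)),
            "b2": np.zeros(d_out),
        }
        self._cache: dict[str, np.ndarray] = {}
        self._rms = {k: np.zeros_like(v) for k, v in self.params.items()}

    def forward(self, x: np.ndarray) -> np.ndarray:
        h = x @ self.params["W1"] + self.params["b1"]
        a = np.where(h > 0, h, self.slope * h)
        y = a @ self.params["W2"] + self.params["b2"]
        if self.out_tanh:
            y = np.tanh(y)
        self._cache = {"x": x, "h": h, "a": a, "y": y}
        return y

    def backward(self, dy: np.ndarray) -> tuple[dict[str, np.ndarray], np.ndarray]:
        """Gradients of the cached forward pass; returns (grads, dL/dx)."""
        c = self._cache
        if self.out_tanh:
            dy = dy * (1.0 - c["y"] ** 2)
        grads = {
            "W2": c["a"].T @ dy,
            "b2": dy.sum(axis=0),
        }
        da = dy @ self.params["W2"].T
        dh = da * np.where(c["h"] > 0, 1.0, self.slope)
        grads["W1"] = c["x"].T @ dh
        grads["b1"] = dh.sum(axis=0)
        dx = dh @ self.params["W1"].T
        return grads, dx

    def rmsprop_update(self, grads: dict[str, np.ndarray], lr: float,
                       rho: float = 0.9, eps: float = 1e-8) -> None:
        for k, g in grads.items():
            self._rms[k] = rho * self._rms[k] + (1.0 - rho) * g * g
            self.params[k] -= lr * g / (np.sqrt(self._rms[k]) + eps)

    def clip_weights(self, bound: float) -> None:
        for k in self.params:
            np.clip(self.params[k], -bound, bound, out=self.params[k])

    def max_abs_weight(self) -> float:
        return max(float(np.abs(v).max()) for v in self.params.values())


@dataclass
class WGANNetworks:
    generator: _MLP
    critic: _MLP
    gspec: GeneratorSpec
    cspec: CriticSpec
    rng: np.random.Generator = field(repr=False, default=None)


def init_networks(
    gspec: GeneratorSpec = GeneratorSpec(),
    cspec: CriticSpec = CriticSpec(),
    seed: int = 0,
) -> WGANNetworks:
    """Seeded generator/critic pair; identical seeds give identical weights."""
    rng = np.random.default_rng(seed)
    gen = _MLP(gspec.noise_dim, gspec.hidden_units, gspec.output_dim,
               gspec.leaky_slope, out_tanh=True, rng=rng)
    critic = _MLP(cspec.input_dim, cspec.hidden_units, 1,
                  cspec.leaky_slope, out_tanh=False, rng=rng)
    critic.clip_weights(cspec.clip_bound)
    return WGANNetworks(generator=gen, critic=critic, gspec=gspec, cspec=cspec, rng=rng)


def _sample_noise(nets: WGANNetworks, n: int, rng: np.random.Generator) -> np.ndarray:
    return rng.standard_normal((n, nets.gspec.noise_dim))


def critic_step(
    nets: WGANNetworks, real_batch: np.ndarray, lr: float,
    rng: np.random.Generator, fake_batch: np.ndarray | None = None,
) -> float:
    """One critic update maximizing E[D(real)] - E[D(fake)]; clips after.

    Returns the critic objective E[D(real)] - E[D(fake)] before the update.
    """
    n = real_batch.shape[0]
    if fake_batch is None:
        fake_batch = nets.generator.forward(_sample_noise(nets, n, rng))
    d_real = nets.critic.forward(real_batch)
    # loss_c = mean(D(fake)) - mean(D(real)); descend on it
    g_real, _ = nets.critic.backward(-np.ones_like(d_real) / n)
    d_fake = nets.critic.forward(fake_batch)
    g_fake, _ = nets.critic.backward(np.ones_like(d_fake) / fake_batch.shape[0])
    grads = {k: g_real[k] + g_fake[k] for k in g_real}
    objective = float(d_real.mean() - d_fake.mean())
    if not np.isfinite(objective):
        raise TrainingDivergedError("non-finite critic objective")
    nets.critic.rmsprop_update(grads, lr)
    nets.critic.clip_weights(nets.cspec.clip_bound)
    return objective


def generator_step(
    nets: WGANNetworks, batch_size: int, lr: float, rng: np.random.Generator
) -> float:
    """One generator update minimizing -E[D(G(z))]; returns that loss."""
    z = _sample_noise(nets, batch_size, rng)
    fake = nets.generator.forward(z)
    d_fake = nets.critic.forward(fake)
    loss = float(-d_fake.mean())
    if not np.isfinite(loss):
        raise TrainingDivergedError("non-finite generator loss")
    _, d_input = nets.critic.backward(-np.ones_like(d_fake) / batch_size)
    g_gen, _ = nets.generator.backward(d_input)
    nets.generator.rmsprop_update(g_gen, lr)
    return loss


def wgan_train_step(
    nets: WGANNetworks, real_batch: np.ndarray, config: TrainConfig,
    rng: np.random.Generator | None = None,
) -> dict[str, float]:
    """n_critic critic updates (fresh noise each) then one generator update.

    ``real_batch`` must already be scaled to (-1, 1) per feature.
    Returns the last critic objective and the generator loss.
    """
    rng = rng if rng is not None else nets.rng
    c_obj = 0.0
    for _ in range(config.critic_steps_per_gen_step):
        c_obj = critic_step(nets, real_batch, config.learning_rate, rng)
    g_loss = generator_step(nets, real_batch.shape[0], config.learning_rate, rng)
    return {"critic_objective": c_obj, "generator_loss": g_loss}


def _channel_values(samples: np.ndarray, channel: str) -> np.ndarray:
    """Heart-rate values of one channel; membership by the step column."""
    hr, steps = samples[:, 0], samples[:, 1]
    if channel == "rhr":
        return hr[steps <= 0.5]
    if channel == "ahr":
        return hr[steps > 0.5]
    if channel == "ohr":
        return hr
    raise ConfigurationError(f"unknown channel {channel!r}")


def pdf_delta(real: np.ndarray, synth: np.ndarray, channel: str) -> float | None:
    """Wasserstein-1 distance between a channel's real and synthetic PDFs.

    Values are min-max normalized over the pooled sample so tolerances
    are scale-free.  Returns None (with a warning) when either side has
    no observations in the channel.
    """
    rv = _channel_values(np.asarray(real, float), channel)
    sv = _channel_values(np.asarray(synth, float), channel)
    if rv.size == 0 or sv.size == 0:
        warnings.warn(f"channel {channel!r} empty on one side; PDF delta undefined",
                      stacklevel=2)
        return None
    lo = min(rv.min(), sv.min())
    hi = max(rv.max(), sv.max())
    if hi == lo:
        return 0.0
    return float(wasserstein_distance((rv - lo) / (hi - lo), (sv - lo) / (hi - lo)))


def _synthesize(nets: WGANNetworks, n: int, scaler: MinMaxScaler,
                rng: np.random.Generator) -> np.ndarray:
    """n synthetic rows in original units: inverse-scaled, steps clamped
    to >= 0 and rounded to integer counts, heart rate clipped to the
    physiological range."""
    out = np.empty((n, 2))
    for i in range(0, n, 4096):
        z = _sample_noise(nets, min(4096, n - i), rng)
        out[i : i + z.shape[0]] = nets.generator.forward(z)
    raw = scaler.inverse(out)
    raw[:, 0] = np.clip(raw[:, 0], 20.5, 249.5)
    raw[:, 1] = np.round(np.maximum(raw[:, 1], 0.0))
    return raw


def _gates_met(deltas: dict[str, float | None], config: TrainConfig,
               skip: set[str]) -> bool:
    evaluated = [ch for ch in config.gate_channels if ch not in skip]
    if not evaluated:
        return False
    for ch in evaluated:
        d = deltas.get(ch)
        # an empty synthetic channel is maximal disagreement, not a skip
        if d is None:
            d = 1.0
        if d >= config.tol(ch):
            return False
    return True


def _run_training(
    real: DataMatrix | np.ndarray,
    config: TrainConfig,
    harvest_separation: int | None,
    min_rows: int,
):
    values = real.values if isinstance(real, DataMatrix) else np.asarray(real, float)
    if values.shape[0] < min_rows:
        raise ConfigurationError(
            f"need >= {min_rows} rows to train a twin, got {values.shape[0]}"
        )
    if values.shape[1] != 2:
        raise ConfigurationError("twin training expects exactly 2 features (hr, steps)")
    n = values.shape[0]
    scaler = MinMaxScaler(values)
    scaled = scaler.transform(values)
    nets = init_networks(
        GeneratorSpec(), CriticSpec(), seed=config.seed
    )
    rng = np.random.default_rng(config.seed + 1)

    # channels absent in the real data are excluded from gating
    skip = {ch for ch in CHANNELS if _channel_values(values, ch).size == 0}
    for ch in skip & set(config.gate_channels):
        warnings.warn(f"real data has no {ch!r} observations; channel skipped",
                      stacklevel=3)

    trace: list[tuple[int, dict[str, float | None]]] = []
    harvests: list[tuple[int, np.ndarray]] = []
    last_harvest: int | None = None
    converged = False
    epochs_run = 0
    batch = config.batch_size
    since_gen = 0
    for epoch in range(1, config.max_epochs + 1):
        order = rng.permutation(n)
        for i in range(0, n, batch):
            rb = scaled[order[i : i + batch]]
            try:
                critic_step(nets, rb, config.learning_rate, rng)
            except TrainingDivergedError as exc:
                raise TrainingDivergedError(
                    f"critic diverged at epoch {epoch}", epoch=epoch
                ) from exc
            since_gen += 1
            if since_gen >= config.critic_steps_per_gen_step:
                generator_step(nets, rb.shape[0], config.learning_rate, rng)
                since_gen = 0
        epochs_run = epoch
        if epoch % config.check_every == 0 or epoch == config.max_epochs:
            synth = _synthesize(nets, n, scaler, rng)
            deltas = {ch: pdf_delta(values, synth, ch) for ch in CHANNELS if ch not in skip}
            trace.append((epoch, deltas))
            met = _gates_met(deltas, config, skip)
            if harvest_separation is None:
                if met:
                    converged = True
                    break
            else:
                if met and (last_harvest is None or epoch - last_harvest >= harvest_separation):
                    harvests.append((epoch, synth))
                    last_harvest = epoch
    final_rng = np.random.default_rng(config.seed + 2)
    synthetic = _synthesize(nets, n, scaler, final_rng)
    result = TwinResult(
        synthetic=DataMatrix(values=synthetic, feature_names=["heart_rate", "steps"]),
        epochs_run=epochs_run,
        converged=converged,
        pdf_deltas=trace,
        seed=config.seed,
    )
    return result, harvests


def train_twin(
    real: DataMatrix | np.ndarray, config: TrainConfig, min_rows: int = 500
) -> TwinResult:
    """Train a digital twin of one user's (heart rate, steps) rows.

    Training stops at the first convergence check where every gated
    channel's PDF distance is below tolerance, else at ``max_epochs``.
    The synthetic output has the same shape as the input, in original
    units.  Fully deterministic given (config, input).
    """
    result, _ = _run_training(real, config, harvest_separation=None, min_rows=min_rows)
    return result


def train_with_harvest(
    real: DataMatrix | np.ndarray,
    config: TrainConfig,
    separation: int = 1000,
    min_rows: int = 50,
) -> tuple[TwinResult, list[tuple[int, np.ndarray]]]:
    """Run to ``max_epochs`` harvesting a synthetic snapshot at every
    convergence check where all gates pass and at least ``separation``
    epochs have elapsed since the previous harvest."""
    if separation < 1:
        raise ConfigurationError("separation must be >= 1")
    cfg = config if config.gate_channels == CHANNELS else replace(
        config, gate_channels=CHANNELS
    )
    return _run_training(real, cfg, harvest_separation=separation, min_rows=min_rows)
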