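"""Particle swarm optimization of the CA detector parameters.

The search space is the unit cube: the detector triplet (delta, tau, rule)
is normalized to (delta' = delta/255, tau, rule' = rule/511) so the swarm
moves through [0, 1]^3.  Fitness is the Dice similarity coefficient of the
detected edge map against ground truth, averaged over the images of the
current training unit (a single image or a batch).

Two optimization protocols are supported by :func:`optimize_dataset`:

* sequential (batch_size = 1): one image at a time, the global best reset
  between images so the swarm does not get stuck in the previous image's
  optimum;
* batched (batch_size > 1): fitness is the mean DSC over the batch, with
  the same global-best reset between consecutive batches.

Particle positions and velocities carry over across units; personal bests
are reset to the current positions and re-evaluated on the new unit, since
fitness values measured on different training units are not comparable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from caedge.ca_core import DetectorParams, MOORE_OFFSETS, N_RULES, _phi_stack
from caedge.image_synthesis import LabeledSample
from caedge.metrics import dsc
from caedge.processing import ScenarioConfig, gaussian_prefilter, run_scenario


def _clip01(x: float) -> float:
    return min(max(float(x), 0.0), 1.0)


@dataclass(frozen=True)
class NormalizedParams:
    """Continuous unit-cube form of the detector triplet.

    delta_n = delta / 255, rule_n = rule / 511, tau unchanged.  Components
    are clamped into range on construction.
    """

    delta_n: float
    tau: float
    rule_n: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "delta_n", _clip01(self.delta_n))
        object.__setattr__(self, "tau", min(max(float(self.tau), 0.0), 1.0 - 1e-9))
        object.__setattr__(self, "rule_n", _clip01(self.rule_n))

    def as_vector(self) -> np.ndarray:
        return np.array([self.delta_n, self.tau, self.rule_n])

    @classmethod
    def from_vector(cls, v: Sequence[float]) -> "NormalizedParams":
        return cls(delta_n=float(v[0]), tau=float(v[1]), rule_n=float(v[2]))


def normalize_params(params: DetectorParams) -> NormalizedParams:
    """Map the integer triplet onto the unit cube."""
    return NormalizedParams(
        delta_n=params.delta / 255.0, tau=params.tau, rule_n=params.rule / float(N_RULES - 1)
    )


def denormalize_params(np_params: NormalizedParams) -> DetectorParams:
    """Back to the integer triplet; delta and rule round half up."""
    delta = int(np.floor(np_params.delta_n * 255.0 + 0.5))
    rule = int(np.floor(np_params.rule_n * (N_RULES - 1) + 0.5))
    return DetectorParams(delta=delta, tau=np_params.tau, rule=rule)


@dataclass
class SwarmConfig:
    """PSO hyperparameters.

    Defaults follow the standard setup for this detector: 100 particles,
    25 epochs per training unit, inertia omega = 0.05, cognitive factor
    c1 = 2.1, social factor c2 = 1.2, velocity clamp v_max = 1.0.
    """

    n_particles: int = 100
    epochs_per_unit: int = 25
    omega: float = 0.05
    c1: float = 2.1
    c2: float = 1.2
    v_max: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_particles < 1 or self.epochs_per_unit < 1:
            raise ValueError("n_particles and epochs_per_unit must be positive")
        if min(self.omega, self.c1, self.c2) < 0 or self.v_max <= 0:
            raise ValueError("omega, c1, c2 must be non-negative and v_max positive")


@dataclass
class SwarmState:
    """Positions, velocities, and best-so-far memory of the swarm."""

    positions: np.ndarray  # (n, 3) in [0, 1]
    velocities: np.ndarray  # (n, 3)
    pbest_positions: np.ndarray  # (n, 3)
    pbest_fitness: np.ndarray  # (n,)
    gbest_position: np.ndarray = field(default_factory=lambda: np.zeros(3))
    gbest_fitness: float = -np.inf


def update_velocity(
    velocity: np.ndarray,
    position: np.ndarray,
    pbest: np.ndarray,
    gbest: np.ndarray,
    config: SwarmConfig,
    rng: np.random.Generator,
) -> np.ndarray:
    """One velocity step: inertia + cognitive pull + social pull.

    v(t+1) = omega*v + r1*c1*(pbest - x) + r2*c2*(gbest - x), with r1, r2
    uniform in (0, 1) drawn independently per dimension, then clamped to
    [-v_max, v_max] componentwise.  Works on a single particle (shape (3,))
    or on the whole swarm (shape (n, 3)).
    """
    r1 = rng.random(np.shape(velocity))
    r2 = rng.random(np.shape(velocity))
    v_new = (
        config.omega * np.asarray(velocity)
        + r1 * config.c1 * (np.asarray(pbest) - np.asarray(position))
        + r2 * config.c2 * (np.asarray(gbest) - np.asarray(position))
    )
    return np.clip(v_new, -config.v_max, config.v_max)


def update_position(position: np.ndarray, velocity: np.ndarray) -> np.ndarray:
    """x(t+1) = x(t) + v(t+1), clamped into the unit cube."""
    return np.clip(np.asarray(position) + np.asarray(velocity), 0.0, 1.0)


class _FitnessEvaluator:
    """Mean-DSC fitness over a fixed batch, with per-image caching.

    The fitness image is the scenario's pre-filtered input (Gaussian
    smoothing for pre_post, the raw image otherwise) and by default the
    plain CA edge map on it is scored — the rule is what is optimized;
    post-processing belongs to test time.  Set ``include_post`` to score
    the thinned/cleaned map instead.

    On the default path the per-offset difference planes of each fitness
    image are precomputed once, so a particle evaluation reduces to a
    plane sum, a ratio, and a threshold.
    """

    def __init__(
        self,
        batch: Sequence[LabeledSample],
        scenario: ScenarioConfig,
        include_post: bool = False,
    ):
        if len(batch) == 0:
            raise ValueError("fitness batch must be non-empty")
        for sample in batch:
            if sample.image.shape != sample.truth.shape:
                raise ValueError(
                    f"image/truth shape mismatch: {sample.image.shape} vs {sample.truth.shape}"
                )
        self.scenario = scenario
        self._include_post = include_post
        sigma = scenario.sigma_smooth if scenario.scenario == "pre_post" else 0.0
        self.batch = [
            LabeledSample(gaussian_prefilter(s.image, sigma), np.asarray(s.truth))
            for s in batch
        ]
        self._fast = not include_post
        if self._fast:
            self._planes = [_phi_stack(np.asarray(s.image, dtype=float)) for s in self.batch]
            self._truths = [np.asarray(s.truth, dtype=bool) for s in self.batch]
            self._truth_sums = [int(t.sum()) for t in self._truths]

    def __call__(self, position: np.ndarray) -> float:
        params = denormalize_params(NormalizedParams.from_vector(position))
        if not self._fast:
            # Fitness images are already pre-filtered; run the post path only.
            post_cfg = ScenarioConfig(
                "post", 0.0, self.scenario.min_component_size
            ) if self.scenario.scenario != "plain" else ScenarioConfig("plain")
            return float(
                np.mean([dsc(run_scenario(s.image, params, post_cfg), s.truth)
                         for s in self.batch])
            )
        bits = [b for b in range(len(MOORE_OFFSETS)) if params.rule >> b & 1]
        scores = []
        for planes, truth, t_sum in zip(self._planes, self._truths, self._truth_sums):
            if bits:
                phi = planes[bits].sum(axis=0)
            else:
                phi = np.zeros(planes.shape[1:])
            denom = params.delta + phi
            mu = np.divide(phi, denom, out=np.zeros_like(phi), where=denom > 0)
            pred = mu > params.tau
            tp = int(np.sum(pred & truth))
            denom_dsc = int(pred.sum()) + t_sum  # = 2*TP + FP + FN
            scores.append(1.0 if denom_dsc == 0 else 2 * tp / denom_dsc)
        return float(np.mean(scores))


def evaluate_fitness(
    np_params: NormalizedParams,
    batch: Sequence[LabeledSample],
    scenario: Optional[ScenarioConfig] = None,
    include_post: bool = False,
) -> float:
    """Mean DSC of the detector's edge maps against truth over the batch.

    The detector runs on the scenario's pre-filtered image; set
    ``include_post`` to score the post-processed map instead of the plain
    CA output.
    """
    scenario = scenario or ScenarioConfig("plain")
    return _FitnessEvaluator(batch, scenario, include_post)(np_params.as_vector())


def _init_state(config: SwarmConfig, rng: np.random.Generator) -> SwarmState:
    n = config.n_particles
    return SwarmState(
        positions=rng.uniform(0.0, 1.0, size=(n, 3)),
        velocities=rng.uniform(-0.1, 0.1, size=(n, 3)),
        pbest_positions=np.zeros((n, 3)),
        pbest_fitness=np.full(n, -np.inf),
    )


def _reset_bests(state: SwarmState, evaluator: _FitnessEvaluator) -> None:
    """Re-anchor personal/global bests on a new training unit."""
    fits = np.array([evaluator(x) for x in state.positions])
    state.pbest_positions = state.positions.copy()
    state.pbest_fitness = fits
    best = int(np.argmax(fits))
    state.gbest_position = state.positions[best].copy()
    state.gbest_fitness = float(fits[best])


def optimize_unit(
    batch: Sequence[LabeledSample],
    config: SwarmConfig,
    *,
    state: Optional[SwarmState] = None,
    rng: Optional[np.random.Generator] = None,
    scenario: Optional[ScenarioConfig] = None,
    unit_index: int = 0,
    history: Optional[List[dict]] = None,
) -> Tuple[NormalizedParams, float, SwarmState]:
    """Optimize the detector on one training unit (a batch of images).

    Runs ``config.epochs_per_unit`` epochs of synchronous velocity and
    position updates over the whole swarm.  Personal bests update only on
    strict fitness improvement, and the global best is the best personal
    best.  If ``state`` is given, positions and velocities carry over but
    personal and global bests are reset and re-evaluated on this unit.
    Deterministic for a fixed ``rng``/seed.
    """
    scenario = scenario or ScenarioConfig("plain")
    if rng is None:
        rng = np.random.default_rng(config.seed)
    evaluator = _FitnessEvaluator(batch, scenario)
    if state is None:
        state = _init_state(config, rng)
    _reset_bests(state, evaluator)
    if history is not None:
        _log(history, unit_index, -1, state)
    for epoch in range(config.epochs_per_unit):
        state.velocities = update_velocity(
            state.velocities, state.positions, state.pbest_positions,
            state.gbest_position, config, rng,
        )
        state.positions = update_position(state.positions, state.velocities)
        fits = np.array([evaluator(x) for x in state.positions])
        improved = fits > state.pbest_fitness
        state.pbest_positions[improved] = state.positions[improved]
        state.pbest_fitness[improved] = fits[improved]
        best = int(np.argmax(state.pbest_fitness))
        if state.pbest_fitness[best] > state.gbest_fitness:
            state.gbest_fitness = float(state.pbest_fitness[best])
            state.gbest_position = state.pbest_positions[best].copy()
        if history is not None:
            _log(history, unit_index, epoch, state)
    return (
        NormalizedParams.from_vector(state.gbest_position),
        float(state.gbest_fitness),
        state,
    )


def _log(history: List[dict], unit: int, epoch: int, state: SwarmState) -> None:
    params = denormalize_params(NormalizedParams.from_vector(state.gbest_position))
    history.append(
        {
            "unit": unit,
            "epoch": epoch,
            "gbest_fitness": float(state.gbest_fitness),
            "delta": params.delta,
            "tau": params.tau,
            "rule": params.rule,
        }
    )


def optimize_dataset(
    samples: Sequence[LabeledSample],
    batch_size: int,
    config: SwarmConfig,
    scenario: Optional[ScenarioConfig] = None,
) -> Tuple[NormalizedParams, pd.DataFrame]:
    """Optimize over a dataset split into consecutive batches.

    The samples are partitioned into consecutive units of ``batch_size``
    images (the last unit may be short).  Between units the global best is
    reset — so the swarm is not anchored to the previous unit's optimum —
    and personal bests are re-evaluated on the new unit; positions and
    velocities carry over.  Returns the best parameters found on the final
    unit together with the full optimization history (one row per epoch:
    unit, epoch, gbest fitness, delta, tau, rule).
    """
    if len(samples) == 0:
        raise ValueError("samples must be non-empty")
    if batch_size < 1:
        raise ValueError(f"batch_size must be >= 1, got {batch_size}")
    rng = np.random.default_rng(config.seed)
    history: List[dict] = []
    state: Optional[SwarmState] = None
    best: Optional[NormalizedParams] = None
    for unit_index, start in enumerate(range(0, len(samples), batch_size)):
        batch = samples[start:start + batch_size]
        best, _, state = optimize_unit(
            batch, config, state=state, rng=rng, scenario=scenario,
            unit_index=unit_index, history=history,
        )
    return best, pd.DataFrame(history)


def exhaustive_search(
    batch: Sequence[LabeledSample],
    deltas: Sequence[int],
    taus: Sequence[float],
    rules: Optional[Sequence[int]] = None,
    scenario: Optional[ScenarioConfig] = None,
) -> Tuple[DetectorParams, float]:
    """Brute-force grid search over the (delta, tau, rule) grid.

    Evaluates the mean-DSC fitness at every grid point and returns the best
    triplet; an independent (if slow) alternative to the swarm for small
    images.
    """
    rules = range(N_RULES) if rules is None else rules
    scenario = scenario or ScenarioConfig("plain")
    evaluator = _FitnessEvaluator(batch, scenario)
    taus = np.asarray(taus, dtype=float)
    best_fit = -np.inf
    best_params = None
    if not evaluator._fast:
        for rule in rules:
            for delta in deltas:
                for tau in taus:
                    p = DetectorParams(delta=int(delta), tau=float(tau), rule=int(rule))
                    fit = evaluator(normalize_params(p).as_vector())
                    if fit > best_fit:
                        best_fit = fit
                        best_params = p
        return best_params, float(best_fit)
    # Plain scenario: hoist phi per rule and mu per delta out of the tau loop.
    for rule in rules:
        bits = [b for b in range(len(MOORE_OFFSETS)) if rule >> b & 1]
        phis = [
            planes[bits].sum(axis=0) if bits else np.zeros(planes.shape[1:])
            for planes in evaluator._planes
        ]
        for delta in deltas:
            mus = []
            for phi in phis:
                denom = delta + phi
                mus.append(np.divide(phi, denom, out=np.zeros_like(phi), where=denom > 0))
            for tau in taus:
                scores = []
                for mu, truth, t_sum in zip(mus, evaluator._truths, evaluator._truth_sums):
                    pred = mu > tau
                    tp = int(np.sum(pred & truth))
                    denom_dsc = int(pred.sum()) + t_sum
                    scores.append(1.0 if denom_dsc == 0 else 2 * tp / denom_dsc)
                fit = float(np.mean(scores))
                if fit > best_fit:
                    best_fit = fit
                    best_params = DetectorParams(delta=int(delta), tau=float(tau), rule=int(rule))
    return best_params, float(best_fit)
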