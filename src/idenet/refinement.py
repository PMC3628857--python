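"""Iterative spring-constant refinement (fluctuation matching).

Starting from an initial heterogeneous network, every spring constant is
adjusted until the model's per-bond distance variances reproduce target
variances measured from a reference ensemble (typically atomistic MD).  This
cannot be solved in closed form once anything anharmonic (a CG force field,
walls, excluded volume) contributes to the fluctuations, hence the iteration
against a pluggable fluctuation evaluator.

Two update rules are available:

* ``lyman``:  K' = K + alpha * kB T * (1/var_target - 1/var_current).
  The correction has the right dimensions (spring constant ~ thermal energy /
  variance) and the right sign: a too-floppy bond (var_current > var_target)
  is stiffened.  Step size alpha defaults to 0.05.
* ``direct``: K' = K * (var_current / var_target)^gamma.  Multiplicative
  rescaling; for an isolated harmonic bond (var = kB T / K) gamma = 1 lands
  on the fixed point in a single step, and in practice this rule converges
  faster than the additive one.

Both rules share the fixed point var_current == var_target, and both clamp
K to [K_min, K_max] to keep noisy (stochastic-evaluator) updates from driving
constants negative or unbounded.  Bond topology is immutable here: selection
precedes iteration, refinement only rescales strengths.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .engine import KB, AnalyticEvaluator
from .networks import ElasticNetwork


class RefinementError(RuntimeError):
    pass


@dataclass
class RefinementConfig:
    """Knobs of the refinement loop.

    ``evaluator`` maps an ElasticNetwork to per-bond distance variances
    (nm^2); see the engine module for the analytic / Langevin / external
    implementations.  ``K_max`` defaults to twice the largest initial
    constant when left as None.
    """

    rule: str = "direct"  # or "lyman"
    alpha: float = 0.05  # additive-rule step, dimensionless
    gamma: float = 1.0  # direct-rule exponent
    temperature: float = 300.0  # K, sets kBT of the additive rule
    K_min: float = 1.0  # kJ mol^-1 nm^-2
    K_max: float | None = None
    max_iter: int = 50
    rel_tol: float = 1e-2  # relative metric change declaring convergence
    evaluator: Callable[[ElasticNetwork], np.ndarray] = field(
        default_factory=AnalyticEvaluator
    )

    def __post_init__(self) -> None:
        if self.rule not in ("lyman", "direct"):
            raise RefinementError(f"unknown update rule {self.rule!r}")
        if not (0 < self.alpha <= 1):
            raise RefinementError("alpha must lie in (0, 1]")
        if self.gamma <= 0:
            raise RefinementError("gamma must be positive")
        if self.max_iter < 1:
            raise RefinementError("max_iter must be >= 1")
        if self.K_max is not None and self.K_min >= self.K_max:
            raise RefinementError("K_min must be below K_max")


@dataclass
class RefinementState:
    """Outcome of a refinement run, with the full metric history."""

    iteration: int
    network: ElasticNetwork
    per_bond_var_current: np.ndarray
    metric_history: list[float]
    converged: bool


def _check_variances(*arrays: np.ndarray) -> None:
    for a in arrays:
        if np.any(~np.isfinite(a)) or np.any(a <= 0):
            raise RefinementError("variances must be positive and finite")


def lyman_update(
    K: np.ndarray,
    var_target: np.ndarray,
    var_current: np.ndarray,
    alpha: float = 0.05,
    kBT: float = KB * 300.0,
    K_min: float = 1.0,
    K_max: float = np.inf,
) -> np.ndarray:
    """Additive fluctuation-matching update, clamped to [K_min, K_max]."""
    K, var_target, var_current = map(np.asarray, (K, var_target, var_current))
    _check_variances(var_target, var_current)
    return np.clip(K + alpha * kBT * (1.0 / var_target - 1.0 / var_current), K_min, K_max)


def direct_update(
    K: np.ndarray,
    var_target: np.ndarray,
    var_current: np.ndarray,
    gamma: float = 1.0,
    K_min: float = 1.0,
    K_max: float = np.inf,
) -> np.ndarray:
    """Multiplicative (direct-scaling) update, clamped to [K_min, K_max]."""
    K, var_target, var_current = map(np.asarray, (K, var_target, var_current))
    _check_variances(var_target, var_current)
    return np.clip(K * (var_current / var_target) ** gamma, K_min, K_max)


def convergence_metric(var_current: np.ndarray, var_target: np.ndarray) -> float:
    """Mean absolute variance mismatch over all bonds, nm^2."""
    var_current = np.asarray(var_current, float)
    var_target = np.asarray(var_target, float)
    if var_current.size == 0 or var_current.shape != var_target.shape:
        raise RefinementError("variance vectors empty or misaligned")
    return float(np.mean(np.abs(var_current - var_target)))


def refine(
    initial: ElasticNetwork,
    var_target: np.ndarray | Sequence[float],
    cfg: RefinementConfig,
    snapshot_callback: Callable[[int, ElasticNetwork, float], None] | None = None,
) -> RefinementState:
    """Iterate spring constants until bond variances match the targets.

    Each pass evaluates the current network's per-bond variances, records the
    mean absolute mismatch, and stops when that metric's relative change over
    an iteration falls below ``cfg.rel_tol`` (or is already numerically
    zero), else applies the update rule to every bond.  The bond set never
    changes.  Deterministic whenever the evaluator is.
    """
    var_target = np.asarray(var_target, dtype=float)
    if var_target.shape != (initial.n_bonds,):
        raise RefinementError(
            f"{initial.n_bonds} bonds but {var_target.shape} target variances"
        )
    _check_variances(var_target)
    K_max = cfg.K_max if cfg.K_max is not None else 2.0 * float(initial.K.max())
    kBT = KB * cfg.temperature
    net = initial.with_constants(initial.K, provenance="iden-refined")
    history: list[float] = []
    clamp_streak = 0
    converged = False
    var_current = None
    for it in range(cfg.max_iter + 1):
        try:
            var_current = np.asarray(cfg.evaluator(net), dtype=float)
        except Exception as exc:
            raise RefinementError(f"evaluator failed at iteration {it}: {exc}") from exc
        metric = convergence_metric(var_current, var_target)
        history.append(metric)
        if snapshot_callback is not None:
            snapshot_callback(it, net, metric)
        if metric <= 1e-12 * float(np.mean(var_target)):
            converged = True
            break
        if len(history) >= 2:
            prev = history[-2]
            if prev > 0 and abs(metric - prev) / prev < cfg.rel_tol:
                converged = True
                break
        if it == cfg.max_iter:
            break
        if cfg.rule == "lyman":
            K_new = lyman_update(
                net.K, var_target, var_current, cfg.alpha, kBT, cfg.K_min, K_max
            )
        else:
            K_new = direct_update(
                net.K, var_target, var_current, cfg.gamma, cfg.K_min, K_max
            )
        clamped = np.all((K_new <= cfg.K_min) | (K_new >= K_max))
        clamp_streak = clamp_streak + 1 if clamped else 0
        if clamp_streak >= 2:
            warnings.warn(
                "refinement stalled: every bond clamped for two consecutive "
                "iterations", RuntimeWarning, stacklevel=2,
            )
        net = net.with_constants(K_new)
    return RefinementState(
        iteration=len(history) - 1,
        network=net,
        per_bond_var_current=var_current,
        metric_history=history,
        converged=converged,
    )
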