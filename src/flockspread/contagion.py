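"""Order-of-acquisition diffusion under four social learning rules.

A novel behaviour is seeded in one individual (the demonstrator) and spreads
until everyone in the network is informed; exactly one naive individual
adopts per timestep and informed individuals never revert.  The rate at
which naive individual i acquires the behaviour is

    lambda_i(t) = lambda_0(t) * (T_i(t) + 1) * (1 - z_i(t)),

where z_i is the informed status (1/0), lambda_0 the baseline (asocial)
rate, and T_i a rule-specific transmission function of the individual's
weighted connections to informed others, x_i = sum_j a_ij z_j, and its total
strength, sum_j a_ij:

* ``simple``      T = s * x                     (classic network-based
  diffusion: rate proportional to connections to informed others)
* ``threshold``   T = c / (1 - sigma(-a b)) * (sigma(b (x - a)) - sigma(-a b))
  with sigma the logistic function: a sharp sigmoidal threshold at x = a,
  sharpness b, maximum c; exactly 0 at x = 0.
* ``proportion``  T = s * x / sum_j a_ij        (ratio of informed to all
  connections)
* ``conformity``  T = s * x^f / (x^f + (sum_j a_ij - x)^f), f >= 1:
  disproportionate copying of the majority; reduces to ``proportion`` at
  f = 1.

Because only the order of acquisition is simulated (OADA logic), the
baseline rate cancels: the next adopter is drawn among naive individuals
with probability proportional to T_i + 1.  The probability that a recorded
adoption event arose socially rather than asocially is the social share of
the total rate, p_social = T / (T + 1), which is 0 exactly when T = 0 and
approaches (never attains) 1 as T grows.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit

from .exceptions import InputError, StateError
from .network_builder import SocialNetwork

__all__ = [
    "RULES",
    "RuleSpec",
    "DiffusionState",
    "DiffusionRun",
    "transmission_value",
    "social_learning_probability",
    "next_adopter",
    "run_diffusion",
    "replicate_diffusions",
    "runs_to_frame",
    "default_rule_grid",
]

RULES = ("simple", "threshold", "proportion", "conformity")

#: headline parameter setting: s = a = f = 5, b = 3
DEFAULT_S = 5.0
DEFAULT_A = 5.0
DEFAULT_B = 3.0
DEFAULT_F = 5.0


@dataclass(frozen=True)
class RuleSpec:
    """A social learning rule plus its parameters.

    ``s`` is the social transmission strength (rate per unit connection
    relative to the asocial baseline), ``a`` the threshold location, ``b``
    the threshold sharpness, ``c`` the threshold maximum (defaults to ``s``),
    and ``f`` the conformity (frequency-dependence) exponent.
    """

    rule: str
    s: float = DEFAULT_S
    a: float = DEFAULT_A
    b: float = DEFAULT_B
    c: float | None = None
    f: float = DEFAULT_F

    def __post_init__(self):
        if self.rule not in RULES:
            raise InputError(f"unknown rule {self.rule!r}; expected one of {RULES}")
        if self.s <= 0:
            raise InputError("RuleSpec.s must be > 0")
        if self.b <= 0:
            raise InputError("RuleSpec.b must be > 0")
        if self.a <= 0:
            raise InputError("RuleSpec.a must be > 0")
        if self.f < 1:
            raise InputError("RuleSpec.f must be >= 1")
        if self.c is not None and self.c <= 0:
            raise InputError("RuleSpec.c must be > 0")

    @property
    def threshold_max(self) -> float:
        """Maximum of the threshold transmission function (c, default s)."""
        return self.s if self.c is None else self.c

    def label(self) -> str:
        return self.rule


def transmission_value(spec: RuleSpec, x, total):
    """Transmission function T for connections-to-informed ``x``.

    ``x`` and ``total`` may be scalars or arrays; ``total`` is the
    individual's summed edge weight (strength).  Ratio-based rules return 0
    for isolated individuals (total = 0).
    """
    x = np.asarray(x, dtype=float)
    total = np.asarray(total, dtype=float)
    if np.any(x < 0) or np.any(total < 0):
        raise InputError("transmission_value: x and total must be nonnegative")
    if np.any(x > total * (1 + 1e-9) + 1e-12):
        raise InputError("transmission_value: x exceeds total connections")

    if spec.rule == "simple":
        out = spec.s * x
    elif spec.rule == "threshold":
        sigma0 = expit(-spec.a * spec.b)
        scale = spec.threshold_max / (1.0 - sigma0)
        out = scale * (expit(spec.b * (x - spec.a)) - sigma0)
    elif spec.rule == "proportion":
        with np.errstate(invalid="ignore", divide="ignore"):
            out = np.where(total > 0, spec.s * x / np.where(total > 0, total, 1.0), 0.0)
    elif spec.rule == "conformity":
        xf = x**spec.f
        yf = np.maximum(total - x, 0.0) ** spec.f
        denom = xf + yf
        with np.errstate(invalid="ignore", divide="ignore"):
            out = np.where(denom > 0, spec.s * xf / np.where(denom > 0, denom, 1.0), 0.0)
    else:  # pragma: no cover - guarded by RuleSpec
        raise InputError(f"unknown rule {spec.rule!r}")
    return out if out.ndim else float(out)


def social_learning_probability(T, t_max: float | None = None):
    """p_social = T / (T + 1): the social share of the acquisition rate.

    Under lambda_i = lambda_0 (T + 1) the probability that an adoption was
    social rather than asocial is T/(T+1); it is 0 exactly when T = 0 and
    approaches 1 for strong transmission without attaining it.  Passing
    ``t_max`` switches to the alternative normalisation T / t_max (fraction
    of the rule's maximum transmission), which does reach 1.
    """
    T = np.asarray(T, dtype=float)
    if np.any(T < 0):
        raise InputError("social_learning_probability: T must be nonnegative")
    if t_max is not None:
        if t_max <= 0:
            raise InputError("social_learning_probability: t_max must be > 0")
        out = T / t_max
    else:
        out = T / (T + 1.0)
    return out if out.ndim else float(out)


@dataclass
class DiffusionState:
    """Informed-status vector z (True = informed) and timestep counter."""

    informed: np.ndarray
    t: int = 0

    @classmethod
    def seeded(cls, n: int, demonstrator_index: int) -> "DiffusionState":
        informed = np.zeros(n, dtype=bool)
        informed[demonstrator_index] = True
        return cls(informed=informed, t=0)


@dataclass
class DiffusionRun:
    """One complete diffusion on one network under one rule.

    Arrays are aligned with ``acquisition_order`` (the demonstrator is entry
    0 and carries x = T = p_social = 0: it is seeded, not an adoption event).
    """

    network_id: str
    rule: RuleSpec
    demonstrator: object
    acquisition_order: list
    x: np.ndarray
    total_connections: np.ndarray
    T: np.ndarray
    p_social: np.ndarray
    replicate: int = 0
    seed: object = None

    def __post_init__(self):
        if len(set(self.acquisition_order)) != len(self.acquisition_order):
            raise StateError("acquisition_order must be a permutation")


def _adoption_weights(net: SocialNetwork, state: DiffusionState, spec: RuleSpec):
    naive = np.flatnonzero(~state.informed)
    if naive.size == 0:
        raise StateError("next_adopter: no naive individuals left")
    totals = net.strength()
    x = net.weights[:, state.informed].sum(axis=1)
    T = np.asarray(transmission_value(spec, x[naive], totals[naive]))
    return naive, x, totals, T


def next_adopter(net: SocialNetwork, state: DiffusionState, spec: RuleSpec,
                 rng: np.random.Generator):
    """Sample the next adopter: naive individual i with probability
    proportional to T_i + 1 (relative acquisition rate; the asocial baseline
    cancels under order-of-acquisition logic)."""
    naive, _, _, T = _adoption_weights(net, state, spec)
    w = T + 1.0
    return net.nodes[rng.choice(naive, p=w / w.sum())]


def run_diffusion(net: SocialNetwork, spec: RuleSpec, demonstrator,
                  rng: np.random.Generator, replicate: int = 0,
                  seed=None) -> DiffusionRun:
    """Seed ``demonstrator`` and iterate until the whole network is informed.

    Records, for each adoption at the moment it happens, the adopter's
    weighted connections to informed others x, its strength, the
    transmission value T and p_social = T/(T+1).
    """
    if demonstrator not in net.nodes:
        raise InputError(f"demonstrator {demonstrator!r} not in network")
    n = net.size
    index = {node: k for k, node in enumerate(net.nodes)}
    d = index[demonstrator]

    weights = net.weights
    totals = weights.sum(axis=1)
    informed = np.zeros(n, dtype=bool)
    informed[d] = True
    x = weights[:, d].copy()

    order = [d]
    x_rec = np.zeros(n)
    T_rec = np.zeros(n)
    p_rec = np.zeros(n)

    for step in range(1, n):
        naive = np.flatnonzero(~informed)
        T = np.asarray(transmission_value(spec, x[naive], totals[naive]), dtype=float)
        w = T + 1.0
        pick_pos = rng.choice(naive.size, p=w / w.sum())
        pick = naive[pick_pos]
        order.append(pick)
        x_rec[step] = x[pick]
        T_rec[step] = T[pick_pos]
        p_rec[step] = T[pick_pos] / (T[pick_pos] + 1.0)
        informed[pick] = True
        x += weights[:, pick]

    return DiffusionRun(
        network_id=net.network_id,
        rule=spec,
        demonstrator=demonstrator,
        acquisition_order=[net.nodes[i] for i in order],
        x=x_rec,
        total_connections=totals[np.asarray(order)],
        T=T_rec,
        p_social=p_rec,
        replicate=replicate,
        seed=seed,
    )


def _network_stream(master_seed: int, network_id: str, replicate: int,
                    salt: int = 0) -> np.random.Generator:
    nid_hash = zlib.crc32(str(network_id).encode())
    return np.random.default_rng(
        np.random.SeedSequence([int(master_seed), nid_hash, replicate, salt])
    )


def replicate_diffusions(net: SocialNetwork, rules: Sequence, n_reps: int = 100,
                         master_seed: int = 0) -> list:
    """Replicate diffusions: per replicate one uniformly random demonstrator,
    shared across all rules so rule comparisons are paired.

    Seeds are derived deterministically from (master_seed, network_id,
    replicate, rule), so any run is reproducible in isolation.
    """
    if n_reps < 1:
        raise InputError("replicate_diffusions: n_reps must be >= 1")
    runs = []
    for rep in range(n_reps):
        demo_rng = _network_stream(master_seed, net.network_id, rep, salt=0)
        demonstrator = net.nodes[demo_rng.integers(net.size)]
        for rule_index, spec in enumerate(rules):
            rng = _network_stream(master_seed, net.network_id, rep, salt=rule_index + 1)
            runs.append(
                run_diffusion(
                    net, spec, demonstrator, rng, replicate=rep,
                    seed=(master_seed, net.network_id, rep, spec.rule),
                )
            )
    return runs


def default_rule_grid(s: float = DEFAULT_S, a: float = DEFAULT_A,
                      b: float = DEFAULT_B, f: float = DEFAULT_F) -> list:
    """The four rules at one parameter setting (headline: s = a = f = 5, b = 3)."""
    return [
        RuleSpec("simple", s=s),
        RuleSpec("threshold", s=s, a=a, b=b),
        RuleSpec("proportion", s=s),
        RuleSpec("conformity", s=s, f=f),
    ]


def runs_to_frame(runs: Iterable) -> pd.DataFrame:
    """Long-format adoption-event table (one row per individual per run)."""
    rows = []
    for run in runs:
        n = len(run.acquisition_order)
        for step in range(n):
            rows.append(
                (
                    run.network_id,
                    run.rule.rule,
                    run.replicate,
                    step + 1,
                    run.acquisition_order[step],
                    run.x[step],
                    run.total_connections[step],
                    run.T[step],
                    run.p_social[step],
                    step == 0,
                )
            )
    return pd.DataFrame(
        rows,
        columns=[
            "network_id", "rule", "replicate", "step", "individual_id",
            "x", "total_connections", "T", "p_social", "is_demonstrator",
        ],
    )
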