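"""Multievent capture-recapture model for survival with telemetry loss.

Tagged birds are checked once per year.  What the field team records (the
*event*) is not the bird's biological state: a silent tag can mean a dead
bird or a failed tag on a live bird.  The multievent framework is a hidden
Markov model that separates the two layers.

States (hidden):

* ``Aa`` — alive, GPS tag active
* ``Ai`` — alive, GPS tag inactive (failed or lost)
* ``Ra`` — recently dead with an active tag (recoverable this occasion)
* ``LD`` — long dead (absorbing)

Events (observed codes): ``0`` not observed, ``1`` detected via active
GPS, ``2`` resighted alive without GPS signal (ring read), ``3``
recovered dead.

Parameters: annual survival ``phi`` (optionally per strategy group), the
per-occasion probability ``lam`` of losing the GPS signal, and the
resighting probability ``p_Ai`` of a live bird whose tag is silent
(per group; residents are much easier to resight than migrants).  Three
constants are fixed by the study design and never estimated: every bird
is released alive with an active tag (``tau_Aa = 1``), an active tag makes
detection certain (``p_Aa = 1``), and every death with an active tag is
recovered (``r = 1``).

Transitions compose survival first, then tag fate, so ``Ra`` is reached
exactly when death occurs while the tag is still active; death takes
precedence when both would happen in the same interval.  ``Ra`` persists
one occasion and then collapses to ``LD``.

Likelihoods are computed with the forward algorithm, maximized on the
logit scale with multi-start quasi-Newton optimization, and models are
compared with QAICc using an externally supplied overdispersion
coefficient (c-hat / VIF).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import expit, logit

from .accel import InputError
from .trajectory import MIGRANT_STRATEGIES, RESIDENT_STRATEGIES, STRATEGIES

__all__ = [
    "STATES",
    "EVENTS",
    "EncounterHistory",
    "MultieventParams",
    "ModelSpec",
    "FitResult",
    "transition_matrix",
    "event_matrix",
    "history_loglik",
    "fit",
    "qaicc",
    "compare",
]

STATES: tuple[str, ...] = ("Aa", "Ai", "Ra", "LD")
EVENTS: tuple[int, ...] = (0, 1, 2, 3)

GroupValue = Union[float, Mapping[str, float]]


@dataclass
class EncounterHistory:
    """Event codes over annual occasions for one individual."""

    individual: str
    events: np.ndarray  # int codes in {0,1,2,3}
    group: str  # "resident"/"migrant" or a 4-level strategy
    first_occasion: int = 0

    def __post_init__(self) -> None:
        self.events = np.asarray(self.events, dtype=int)
        if self.events.ndim != 1 or len(self.events) < 2:
            raise InputError("encounter history needs >= 2 occasions")
        if not np.isin(self.events, EVENTS).all():
            raise InputError(f"event codes outside {EVENTS}")
        if not 0 <= self.first_occasion < len(self.events) - 1:
            raise InputError("first occasion out of range")
        if self.events[self.first_occasion] != 1:
            raise InputError("release occasion must carry event 1 (active tag)")


def _to_group2(group: str) -> str:
    if group in ("resident", "migrant"):
        return group
    if group in RESIDENT_STRATEGIES:
        return "resident"
    if group in MIGRANT_STRATEGIES:
        return "migrant"
    raise InputError(f"unknown strategy group {group!r}")


def _resolve(value: GroupValue, group: Optional[str]) -> float:
    if isinstance(value, Mapping):
        if group is None:
            raise InputError("group required for group-structured parameter")
        if group in value:
            return float(value[group])
        return float(value[_to_group2(group)])
    return float(value)


@dataclass
class MultieventParams:
    """Model parameters; scalars apply to every group.

    ``phi`` and ``p_ai`` may be dicts keyed by group.  The design
    constants tau_Aa, p_Aa and r are fixed at 1 and not fields.
    """

    phi: GroupValue
    lam: float
    p_ai: GroupValue

    TAU_AA: float = field(default=1.0, init=False, repr=False)
    P_AA: float = field(default=1.0, init=False, repr=False)
    R: float = field(default=1.0, init=False, repr=False)

    def validate(self) -> None:
        for name, value in (("phi", self.phi), ("lam", self.lam), ("p_ai", self.p_ai)):
            vals = value.values() if isinstance(value, Mapping) else [value]
            for v in vals:
                if not 0.0 <= float(v) <= 1.0:
                    raise InputError(f"{name}={v} outside [0, 1]")


def transition_matrix(params: MultieventParams, group: Optional[str] = None) -> np.ndarray:
    """4x4 row-stochastic state transition matrix over (Aa, Ai, Ra, LD).

    Survival acts first, then tag fate: an Aa bird survives and keeps the
    signal with probability phi*(1-lam), survives but loses it with
    phi*lam, and dies (while the tag was active, hence recoverable) with
    1-phi.  Recently dead becomes long dead after one occasion.
    """
    params.validate()
    phi = _resolve(params.phi, group)
    lam = float(params.lam)
    return np.array(
        [
            [phi * (1 - lam), phi * lam, 1 - phi, 0.0],
            [0.0, phi, 0.0, 1 - phi],
            [0.0, 0.0, 0.0, 1.0],
            [0.0, 0.0, 0.0, 1.0],
        ]
    )


def event_matrix(params: MultieventParams, group: Optional[str] = None) -> np.ndarray:
    """4x4 row-stochastic matrix of event probabilities (rows = states).

    Active tags are always detected (event 1); silent live birds are
    resighted (event 2) with probability p_Ai for their group; recent
    deaths with active tags are always recovered (event 3); long-dead
    birds are never observed.
    """
    params.validate()
    p = _resolve(params.p_ai, group)
    return np.array(
        [
            [0.0, 1.0, 0.0, 0.0],
            [1.0 - p, 0.0, p, 0.0],
            [0.0, 0.0, 0.0, 1.0],
            [1.0, 0.0, 0.0, 0.0],
        ]
    )


def history_loglik(history: EncounterHistory, params: MultieventParams) -> float:
    """Forward-algorithm log-likelihood of one encounter history.

    Conditioned on release in state Aa with a certain event 1 at the first
    occasion.  Returns ``-inf`` for histories with zero probability (e.g.
    a live detection after a dead recovery) rather than raising.
    """
    T = transition_matrix(params, history.group)
    B = event_matrix(params, history.group)
    alpha = np.array([1.0, 0.0, 0.0, 0.0])  # released as Aa; P(event 1 | Aa) = 1
    for t in range(history.first_occasion + 1, len(history.events)):
        alpha = (alpha @ T) * B[:, history.events[t]]
    total = alpha.sum()
    return float(np.log(total)) if total > 0 else -math.inf


@dataclass
class ModelSpec:
    """Which parameters vary by strategy group, plus QAICc inputs.

    ``phi_by`` / ``p_by``: "constant", "resident_migrant" or "strategy"
    (4-level).  ``c_hat`` is the externally estimated overdispersion
    coefficient; goodness-of-fit testing that produces it is out of scope
    here.  ``n_eff`` defaults to the number of individuals.
    """

    name: str = "model"
    phi_by: str = "constant"
    p_by: str = "resident_migrant"
    c_hat: float = 1.0
    n_eff: Optional[int] = None
    n_starts: int = 10
    seed: int = 0

    _LEVELS = {"constant", "resident_migrant", "strategy"}

    def __post_init__(self) -> None:
        if self.phi_by not in self._LEVELS or self.p_by not in self._LEVELS:
            raise InputError(f"structure must be one of {sorted(self._LEVELS)}")
        if self.c_hat < 1.0:
            raise InputError("c_hat must be >= 1")

    def groups_for(self, structure: str, histories: Sequence[EncounterHistory]) -> list[str]:
        if structure == "constant":
            return ["all"]
        if structure == "resident_migrant":
            present = sorted({_to_group2(h.group) for h in histories})
        else:
            present = sorted({h.group for h in histories})
            if not set(present) <= set(STRATEGIES):
                raise InputError(
                    "4-level structure requires 4-level strategy groups on histories"
                )
        return present

    def k(self, histories: Sequence[EncounterHistory]) -> int:
        return (
            len(self.groups_for(self.phi_by, histories))
            + 1  # lam
            + len(self.groups_for(self.p_by, histories))
        )


@dataclass
class FitResult:
    """Maximum-likelihood fit of one model specification."""

    spec: ModelSpec
    params: MultieventParams
    loglik: float
    k: int
    qaicc: float
    n_histories: int
    converged: bool
    estimates: pd.DataFrame  # name, estimate, se, ci_low, ci_high
    start_logliks: tuple[float, ...] = ()

    @property
    def deviance(self) -> float:
        return -2.0 * self.loglik


def _history_group_key(history: EncounterHistory, structure: str) -> str:
    if structure == "constant":
        return "all"
    if structure == "resident_migrant":
        return _to_group2(history.group)
    return history.group


class _Likelihood:
    """Vectorized forward likelihood over a set of encounter histories."""

    def __init__(self, histories: Sequence[EncounterHistory], spec: ModelSpec):
        self.spec = spec
        self.phi_groups = spec.groups_for(spec.phi_by, histories)
        self.p_groups = spec.groups_for(spec.p_by, histories)
        n_occ = len(histories[0].events)
        if any(len(h.events) != n_occ for h in histories):
            raise InputError("all histories must span the same occasions")
        self.n_occ = n_occ
        self.events = np.array([h.events for h in histories])
        self.first = np.array([h.first_occasion for h in histories])
        self.phi_idx = np.array(
            [self.phi_groups.index(_history_group_key(h, spec.phi_by)) for h in histories]
        )
        self.p_idx = np.array(
            [self.p_groups.index(_history_group_key(h, spec.p_by)) for h in histories]
        )
        self.n = len(histories)

    @property
    def n_params(self) -> int:
        return len(self.phi_groups) + 1 + len(self.p_groups)

    def unpack(self, theta: np.ndarray) -> tuple[np.ndarray, float, np.ndarray]:
        probs = expit(theta)
        n_phi = len(self.phi_groups)
        return probs[:n_phi], float(probs[n_phi]), probs[n_phi + 1:]

    def params_from(self, theta: np.ndarray) -> MultieventParams:
        phis, lam, ps = self.unpack(theta)
        phi = dict(zip(self.phi_groups, phis)) if len(phis) > 1 else float(phis[0])
        p = dict(zip(self.p_groups, ps)) if len(ps) > 1 else float(ps[0])
        return MultieventParams(phi=phi, lam=lam, p_ai=p)

    def loglik(self, theta: np.ndarray) -> float:
        phis, lam, ps = self.unpack(theta)
        # per-history transition/event matrices via group indexing
        T = np.zeros((len(phis), 4, 4))
        for g, phi in enumerate(phis):
            T[g] = [
                [phi * (1 - lam), phi * lam, 1 - phi, 0.0],
                [0.0, phi, 0.0, 1 - phi],
                [0.0, 0.0, 0.0, 1.0],
                [0.0, 0.0, 0.0, 1.0],
            ]
        B = np.zeros((len(ps), 4, 4))
        for g, p in enumerate(ps):
            B[g] = [
                [0.0, 1.0, 0.0, 0.0],
                [1.0 - p, 0.0, p, 0.0],
                [0.0, 0.0, 0.0, 1.0],
                [1.0, 0.0, 0.0, 0.0],
            ]
        alpha = np.zeros((self.n, 4))
        total = 0.0
        entered = self.first == 0
        alpha[entered, 0] = 1.0
        for t in range(1, self.n_occ):
            Tn = T[self.phi_idx]  # (n, 4, 4)
            propagated = np.einsum("ni,nij->nj", alpha, Tn)
            emit = B[self.p_idx, :, self.events[:, t]]  # (n, 4)
            new_alpha = propagated * emit
            new_alpha[~entered] = 0.0
            entering = self.first == t
            new_alpha[entering] = 0.0
            new_alpha[entering, 0] = 1.0
            entered = entered | entering
            scale = new_alpha.sum(axis=1)
            dead_end = entered & (scale <= 0.0)
            if dead_end.any():
                return -math.inf
            live = scale > 0
            total += float(np.log(scale[live]).sum())
            new_alpha[live] /= scale[live, None]
            alpha = new_alpha
        return total


def _numeric_hessian(f, x: np.ndarray, h: float = 1e-4) -> np.ndarray:
    n = len(x)
    H = np.zeros((n, n))
    for i in range(n):
        for j in range(i, n):
            ei = np.zeros(n); ei[i] = h
            ej = np.zeros(n); ej[j] = h
            H[i, j] = H[j, i] = (
                f(x + ei + ej) - f(x + ei - ej) - f(x - ei + ej) + f(x - ei - ej)
            ) / (4 * h * h)
    return H


def fit(histories: Sequence[EncounterHistory], spec: ModelSpec) -> FitResult:
    """Maximum-likelihood fit on the logit scale with seeded multi-start.

    The design constants (tau_Aa, p_Aa, r) stay fixed at 1.  Ties between
    starts are broken by lowest deviance, then lowest start index.  Wald
    confidence intervals are computed on the logit scale from a numerical
    Hessian and back-transformed.
    """
    if not histories:
        raise InputError("no encounter histories supplied")
    lik = _Likelihood(histories, spec)
    rng = np.random.default_rng(spec.seed)
    neg = lambda th: -lik.loglik(th)

    best = None
    start_logliks = []
    for start in range(spec.n_starts):
        theta0 = rng.uniform(-2.0, 2.0, size=lik.n_params)
        res = minimize(neg, theta0, method="L-BFGS-B")
        start_logliks.append(-res.fun)
        if best is None or res.fun < best.fun - 1e-9:
            best = res
    assert best is not None

    theta = best.x
    H = _numeric_hessian(neg, theta)
    try:
        cov = np.linalg.inv(H)
        se_logit = np.sqrt(np.clip(np.diag(cov), 0.0, np.inf))
    except np.linalg.LinAlgError:
        se_logit = np.full(len(theta), np.nan)

    names = (
        [f"phi[{g}]" for g in lik.phi_groups]
        + ["lambda"]
        + [f"p_Ai[{g}]" for g in lik.p_groups]
    )
    z = 1.959963984540054
    estimates = pd.DataFrame(
        {
            "parameter": names,
            "estimate": expit(theta),
            "se_logit": se_logit,
            "ci_low": expit(theta - z * se_logit),
            "ci_high": expit(theta + z * se_logit),
        }
    )
    k = lik.n_params
    n_eff = spec.n_eff if spec.n_eff is not None else len(histories)
    loglik_val = -float(best.fun)
    return FitResult(
        spec=spec,
        params=lik.params_from(theta),
        loglik=loglik_val,
        k=k,
        qaicc=qaicc(loglik_val, k, spec.c_hat, n_eff),
        n_histories=len(histories),
        converged=bool(best.success),
        estimates=estimates,
        start_logliks=tuple(start_logliks),
    )


def qaicc(loglik: float, k: int, c_hat: float, n_eff: int) -> float:
    """Small-sample quasi-AIC: -2*loglik/c_hat + 2k + 2k(k+1)/(n_eff-k-1)."""
    if c_hat < 1.0:
        raise InputError("c_hat must be >= 1")
    if n_eff <= k + 1:
        raise InputError(f"n_eff={n_eff} must exceed k+1={k + 1}")
    qaic = -2.0 * loglik / c_hat + 2.0 * k
    return qaic + 2.0 * k * (k + 1) / (n_eff - k - 1)


def compare(fits: Sequence[FitResult]) -> pd.DataFrame:
    """Model comparison table sorted by QAICc ascending, with deltas."""
    if not fits:
        raise InputError("no fits to compare")
    df = pd.DataFrame(
        {
            "model": [f.spec.name for f in fits],
            "k": [f.k for f in fits],
            "loglik": [f.loglik for f in fits],
            "deviance": [f.deviance for f in fits],
            "c_hat": [f.spec.c_hat for f in fits],
            "qaicc": [f.qaicc for f in fits],
        }
    ).sort_values("qaicc", kind="stable").reset_index(drop=True)
    df["delta_qaicc"] = df["qaicc"] - df["qaicc"].iloc[0]
    return df
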