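"""Five-compartment breast-cancer dynamics with a Caputo fractional order.

The state tracks cancer stem cells ``C``, tumor cells ``T``, healthy cells
``H``, immune cells ``I`` and excess estrogen ``E``.  Cancer stem cells grow
logistically, feed the tumor compartment, and both are promoted by estrogen
through Michaelis-Menten (half-saturation) terms and suppressed by the immune
response.  Healthy cells grow logistically and are lost to tumor crowding and
estrogen-induced DNA damage.  Immune cells have a constant source, are
recruited by the tumor, and are exhausted by tumor load and estrogen.  Excess
estrogen is infused at a constant rate and removed by washout plus absorption
into the three cell compartments.

The time derivative on the left-hand side is a Caputo derivative of order
``alpha`` in (0, 1]; ``alpha = 1`` recovers the classical first-order system.
The right-hand side itself is identical for every order.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, fields
from typing import Mapping, NamedTuple

import numpy as np

__all__ = [
    "ModelParameters",
    "FractionalOrder",
    "StateVector",
    "STATE_NAMES",
    "rhs",
    "case_parameters",
    "CASE_IDS",
]

STATE_NAMES = ("C", "T", "H", "I", "E")

#: Fields that sit in a denominator somewhere and must be strictly positive.
_STRICTLY_POSITIVE = frozenset({"M1", "M2", "M3", "a1", "a2", "a3", "w", "v"})


class StateVector(NamedTuple):
    """One point of the five-dimensional state space."""

    C: float
    T: float
    H: float
    I: float
    E: float


@dataclass(frozen=True)
class ModelParameters:
    """The 28 rate, capacity and threshold constants of the model.

    Units: rates are per unit time, capacities and half-saturation constants
    in the model's cell/concentration units; all values are nonnegative.
    """

    k1: float  # cancer stem cell division rate
    k2: float  # tumor cell production rate (from stem cells)
    q: float  # healthy cell division rate
    M1: float  # stem-cell carrying capacity
    M2: float  # tumor carrying capacity
    M3: float  # healthy-cell carrying capacity
    p1: float  # estrogen promotion of stem cells
    p2: float  # estrogen promotion of tumor cells
    p3: float  # estrogen-induced healthy-cell loss
    a1: float  # stem-cell half-saturation constant
    a2: float  # tumor half-saturation constant
    a3: float  # healthy-cell half-saturation constant
    gamma1: float  # immune kill rate of stem cells
    gamma2: float  # immune kill rate of tumor cells
    gamma3: float  # immune exhaustion by tumor cells
    n1: float  # tumor natural death rate
    n2: float  # immune natural death rate
    delta: float  # tumor-induced healthy-cell death rate
    s: float  # baseline immune source rate
    rho: float  # tumor-driven immune recruitment rate
    w: float  # tumor level at half-maximal immune recruitment
    u: float  # estrogen-induced immune suppression rate
    v: float  # estrogen level at half-maximal immune suppression
    tau: float  # constant estrogen infusion rate
    mu: float  # estrogen washout rate
    d1: float  # estrogen absorption by stem cells
    d2: float  # estrogen absorption by tumor cells
    d3: float  # estrogen absorption by healthy cells

    def __post_init__(self) -> None:
        for f in fields(self):
            value = getattr(self, f.name)
            if not math.isfinite(value):
                raise ValueError(f"parameter {f.name} must be finite, got {value!r}")
            if value < 0:
                raise ValueError(f"parameter {f.name} must be >= 0, got {value!r}")
            if f.name in _STRICTLY_POSITIVE and value == 0:
                raise ValueError(
                    f"parameter {f.name} appears in a denominator and must be > 0"
                )

    def to_dict(self) -> dict[str, float]:
        """Flat key-value form, suitable for YAML/JSON round trips."""
        return {f.name: float(getattr(self, f.name)) for f in fields(self)}

    @classmethod
    def from_dict(cls, mapping: Mapping[str, float]) -> "ModelParameters":
        names = {f.name for f in fields(cls)}
        unknown = set(mapping) - names
        if unknown:
            raise ValueError(f"unknown parameter keys: {sorted(unknown)}")
        missing = names - set(mapping)
        if missing:
            raise ValueError(f"missing parameter keys: {sorted(missing)}")
        return cls(**{k: float(v) for k, v in mapping.items()})


@dataclass(frozen=True)
class FractionalOrder:
    """Order of the Caputo derivative, in (0, 1]."""

    alpha: float

    def __post_init__(self) -> None:
        if not (0.0 < self.alpha <= 1.0) or not math.isfinite(self.alpha):
            raise ValueError(f"fractional order must lie in (0, 1], got {self.alpha!r}")


def rhs(
    state,
    params: ModelParameters,
    *,
    estrogen_bracket_times_E: bool = False,
) -> np.ndarray:
    """Evaluate the right-hand side of the five-compartment system.

    Parameters
    ----------
    state
        Length-5 array-like ``(C, T, H, I, E)``.
    params
        Validated model constants.
    estrogen_bracket_times_E
        The default estrogen balance is ``dE = tau - (mu + absorption terms)``,
        with a clearance bracket that is *not* proportional to ``E``.  Setting
        this flag multiplies the bracket by ``E``, giving the mass-action
        variant in which washout and absorption scale with the estrogen level.

    Returns
    -------
    numpy.ndarray
        The five compartment rates, in state order.

    Notes
    -----
    The system is autonomous: time enters only through the state.  Negative
    state values are accepted (an explicit solver may transiently overshoot);
    only non-finite states and vanishing denominators are rejected.
    """
    y = np.asarray(state, dtype=float)
    if y.shape != (5,):
        raise ValueError(f"state must have shape (5,), got {y.shape}")
    if not np.all(np.isfinite(y)):
        raise ValueError(f"non-finite state: {y!r}")
    C, T, H, I, E = y
    p = params

    for name, denom in (
        ("a1 + C", p.a1 + C),
        ("a2 + T", p.a2 + T),
        ("a3 + H", p.a3 + H),
        ("w + T", p.w + T),
        ("v + E", p.v + E),
    ):
        if denom == 0.0:
            raise ZeroDivisionError(f"vanishing denominator {name} in model right-hand side")

    dC = p.k1 * C * (1.0 - C / p.M1) - p.gamma1 * C * I + p.p1 * E * C / (p.a1 + C)
    dT = (
        p.k2 * C * (C / p.M1) * (1.0 - T / p.M2)
        - p.n1 * T
        - p.gamma2 * T * I
        + p.p2 * E * T / (p.a2 + T)
    )
    dH = p.q * H * (1.0 - H / p.M3) - p.delta * T * H - p.p3 * E * H / (p.a3 + H)
    dI = (
        p.s
        + p.rho * I * T / (p.w + T)
        - p.gamma3 * T * I
        - p.n2 * I
        - p.u * E * I / (p.v + E)
    )
    clearance = (
        p.mu
        + p.d1 * C / (p.a1 + C)
        + p.d2 * T / (p.a2 + T)
        + p.d3 * H / (p.a3 + H)
    )
    dE = p.tau - clearance * E if estrogen_bracket_times_E else p.tau - clearance
    return np.array([dC, dT, dH, dI, dE])


# Constants shared by all three study cases; only the fractional order varies.
_BASE_PARAMETERS = ModelParameters(
    k1=0.05,
    M1=0.02,
    p1=0.005,
    a1=0.6,
    gamma1=0.01,
    p2=0.01,
    a2=0.07,
    k2=0.02,
    M2=0.5,
    gamma2=0.1,
    n1=0.3,
    q=0.3,
    M3=0.4,
    p3=0.5,
    a3=0.5,
    delta=0.05,
    s=0.02,
    n2=0.005,
    gamma3=0.6,
    u=0.01,
    v=0.01,
    rho=0.07,
    w=0.02,
    tau=0.5,
    mu=0.1,
    d1=0.3,
    d2=0.3,
    d3=0.5,
)

_CASE_ALPHAS = {1: 0.5, 2: 0.7, 3: 0.9}

CASE_IDS = tuple(sorted(_CASE_ALPHAS))

#: Every compartment starts at 1.2 in all three cases.
_INITIAL_STATE = StateVector(1.2, 1.2, 1.2, 1.2, 1.2)


def case_parameters(
    case_id: int,
) -> tuple[ModelParameters, FractionalOrder, StateVector]:
    """Return the registered parameter set for one of the three study cases.

    The cases share every rate constant and the initial state (1.2 in each
    compartment) and differ only in the Caputo order: 0.5, 0.7 and 0.9 for
    cases 1, 2 and 3.
    """
    try:
        alpha = _CASE_ALPHAS[case_id]
    except (KeyError, TypeError):
        raise ValueError(
            f"unknown case {case_id!r}; valid cases are {list(CASE_IDS)}"
        ) from None
    return _BASE_PARAMETERS, FractionalOrder(alpha), _INITIAL_STATE
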