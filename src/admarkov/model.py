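"""Core nine-variable Alzheimer's disease progression model.

The model tracks nine concentrations (all in g/ml): neurons (N), amyloid beta
inside and outside neurons (A_beta_i, A_beta_o), tau protein (tau),
neurofibrillary tangles inside and outside neurons (F_i, F_o), astroglia (A),
and pro-/anti-inflammatory microglia (M1, M2).  Reactive-oxygen-species
inflammation is held at the constant level ``R0`` (no equation updates it in
the reduced model).

This module houses the state and parameter containers, the nine rate
equations, their decomposition into per-variable birth/death channels
(the state-dependent stoichiometry used by the stochastic engine), the
interaction graph of the equations, and closed-form fixed points used as
analytic oracles.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Dict, Mapping, Tuple

import numpy as np

__all__ = [
    "VARIABLES",
    "StateVector",
    "ParameterSet",
    "ModelOptions",
    "ChannelRates",
    "PROCESS_TAGS",
    "rhs",
    "channel_rates",
    "interaction_counts",
    "analytic_fixed_points",
]

#: Canonical variable order used everywhere (arrays, CSV columns, tie-breaks).
VARIABLES: Tuple[str, ...] = (
    "N",
    "A_beta_i",
    "A_beta_o",
    "tau",
    "F_i",
    "F_o",
    "A",
    "M1",
    "M2",
)

#: Markov process tags per variable.  Emigration rows describe quanta that
#: leave one compartment and arrive in another (A_beta_i -> A_beta_o via
#: neuron death, F_i -> F_o); the emigration flux is carried by the
#: destination's birth channel so that birth - death reassembles the rate
#: equations exactly.
PROCESS_TAGS: Mapping[str, Tuple[str, ...]] = {
    "N": ("Pure Death",),
    "A_beta_i": ("Birth", "Emigration"),
    "A_beta_o": ("Birth", "Death"),
    "tau": ("Birth", "Death"),
    "F_i": ("Birth", "Death", "Emigration"),
    "F_o": ("Birth", "Death"),
    "A": ("Birth", "Death"),
    "M1": ("Birth", "Death"),
    "M2": ("Birth", "Death"),
}


@dataclass(frozen=True)
class StateVector:
    """Concentrations of the nine species at one instant (g/ml).

    Default construction gives the disease-onset initial condition.
    """

    N: float = 0.14
    A_beta_i: float = 1e-6
    A_beta_o: float = 1e-8
    tau: float = 1.37e-10
    F_i: float = 3.36e-10
    F_o: float = 3.36e-11
    A: float = 0.14
    M1: float = 0.02
    M2: float = 0.02

    def __post_init__(self) -> None:
        for name in VARIABLES:
            value = getattr(self, name)
            if not np.isfinite(value):
                raise ValueError(f"state component {name!r} is not finite: {value}")
            if value < 0:
                raise ValueError(f"state component {name!r} is negative: {value}")

    def as_array(self) -> np.ndarray:
        """Return the state as a length-9 float array in canonical order."""
        return np.array([getattr(self, name) for name in VARIABLES], dtype=float)

    @classmethod
    def from_array(cls, values: np.ndarray) -> "StateVector":
        values = np.asarray(values, dtype=float)
        if values.shape != (9,):
            raise ValueError(f"expected 9 components, got shape {values.shape}")
        return cls(**dict(zip(VARIABLES, values.tolist())))

    def replace(self, **kwargs: float) -> "StateVector":
        return dataclasses.replace(self, **kwargs)


@dataclass(frozen=True)
class ParameterSet:
    """The 29 rate and saturation constants of the reduced model.

    Units are per day for first-order rates, g/ml/day for zeroth-order
    production terms, and g/ml (= g/cm^3) for half-saturation constants and
    reference densities.  ``R0`` is the constant inflammation level by
    reactive oxygen species; ``lambda_tau`` and ``lambda_tau0`` are treated
    as g/ml/day so the tau equation is dimensionally consistent.
    """

    lambda_Nd: float = 0.05 / 365.0       # neuron death rate with age, /day
    lambda_beta_i: float = 9.51e-6        # A_beta_i production, g/ml/day
    lambda_N: float = 8e-9                # A_beta_o production by neurons, g/ml/day
    lambda_MA: float = 0.045              # astrocyte production by M1, g/ml/day
    lambda_A: float = 8e-10               # A_beta_o production by astroglia, g/ml/day
    lambda_tau: float = 1.35e-11          # tau production by ROS, g/ml/day
    lambda_F: float = 1.662e-3            # NFT production by tau, /day
    lambda_AAbeta_o: float = 1.793        # astrocyte activation by A_beta_o, /day
    lambda_tau0: float = 8.1e-11          # healthy tau production, g/ml/day
    lambda_MF: float = 2e-2               # microglia activation by NFTs, /day
    d_Fi: float = 2.77e-3                 # F_i degradation, /day
    d_Fo: float = 2.77e-4                 # F_o degradation, /day
    d_M1: float = 0.015                   # M1 degradation, /day
    d_M2: float = 0.015                   # M2 degradation, /day
    d_AbetaoM: float = 2e-3               # A_beta_o clearance by microglia, /day
    d_Abetai: float = 9.51                # A_beta_i clearance, /day
    d_A: float = 1.2e-3                   # astrocyte death, /day
    d_NF: float = 3.4e-4                  # neuron death by NFTs, /day
    d_tau: float = 0.277                  # tau degradation, /day
    K_Fi: float = 3.36e-10                # half-saturation of intracellular NFTs, g/ml
    K_Fo: float = 2.58e-11                # average extracellular NFTs, g/ml
    K_Abetao: float = 7e-3                # Michaelis constant for A_beta_o clearance, g/ml
    M0_G: float = 0.047                   # microglia source density, g/ml
    beta_M1: float = 0.9                  # inflammation effect on M1
    beta_M2: float = 0.09                 # inflammation effect on M2
    theta: float = 0.9                    # M2 relative effectivity in clearance
    R0: float = 6.0                       # constant inflammation by ROS
    N0: float = 0.14                      # reference neuron density, g/ml
    A0: float = 0.14                      # reference astrocyte density, g/ml

    def __post_init__(self) -> None:
        for f in dataclasses.fields(self):
            value = getattr(self, f.name)
            if not np.isfinite(value) or value <= 0:
                raise ValueError(
                    f"parameter {f.name!r} must be strictly positive and finite, "
                    f"got {value}"
                )

    def replace(self, **kwargs: float) -> "ParameterSet":
        return dataclasses.replace(self, **kwargs)

    @classmethod
    def names(cls) -> Tuple[str, ...]:
        return tuple(f.name for f in dataclasses.fields(cls))


@dataclass(frozen=True)
class ModelOptions:
    """Structural switches of the model.

    ``abeta_o_clearance`` toggles the reconstructed Michaelis–Menten
    microglial clearance of extraneuronal amyloid beta,
    ``d_AbetaoM * (M1 + theta*M2) * A_beta_o / (A_beta_o + K_Abetao)``.
    The parameter table defines this clearance machinery even though the
    printed amyloid-beta-outside equation omits the term, and the
    amyloid-beta-outside row of the transition table lists a Death process;
    the flag defaults ON and exists so the literal printed equation is also
    available.  The neuron equation is always applied as a loss (pure death).
    """

    abeta_o_clearance: bool = True


@dataclass(frozen=True)
class ChannelRates:
    """Non-negative birth/death rate magnitudes per variable (g/ml/day).

    ``birth - death`` reassembles the deterministic rate equations exactly;
    emigration fluxes (A_beta_i -> A_beta_o, F_i -> F_o) are carried on the
    destination's birth channel, mirroring the printed equations in which the
    source equation has no corresponding loss term.
    """

    birth: np.ndarray
    death: np.ndarray
    processes: Mapping[str, Tuple[str, ...]] = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.processes is None:
            object.__setattr__(self, "processes", PROCESS_TAGS)

    def total(self) -> np.ndarray:
        """Per-variable total event rate (birth + death)."""
        return self.birth + self.death

    def net(self) -> np.ndarray:
        """Per-variable net rate; identical to the model's derivatives."""
        return self.birth - self.death


def _params_tuple(params: ParameterSet) -> Tuple[float, ...]:
    return tuple(getattr(params, f.name) for f in dataclasses.fields(params))


def _birth_death_arrays(
    x: np.ndarray, pt: Tuple[float, ...], clearance: bool,
    birth: np.ndarray, death: np.ndarray,
) -> None:
    """Fill ``birth``/``death`` (length 9) in place.  Hot path: scalar math."""
    (lam_Nd, lam_bi, lam_N, lam_MA, lam_A, lam_tau, lam_F, lam_AAbo, lam_tau0,
     lam_MF, d_Fi, d_Fo, d_M1, d_M2, d_AboM, d_Abi, d_A, d_NF, d_tau,
     K_Fi, K_Fo, K_Abo, M0G, b_M1, b_M2, theta, R0, N0, A0) = pt
    N, Abi, Abo, tau, Fi, Fo, A, M1, M2 = x
    nn = N / N0

    birth[0] = 0.0
    death[0] = d_NF * (Fi / (Fi + K_Fi)) * N if (Fi + K_Fi) > 0 else 0.0

    birth[1] = lam_bi * (1.0 + R0) * nn
    death[1] = d_Abi * Abi * nn

    birth[2] = lam_Nd * Abi + lam_N * nn + lam_A * (A / A0)
    death[2] = (
        d_AboM * (M1 + theta * M2) * (Abo / (Abo + K_Abo))
        if clearance and (Abo + K_Abo) > 0
        else 0.0
    )

    birth[3] = (lam_tau0 + lam_tau * R0) * nn
    death[3] = d_tau * tau * nn

    birth[4] = lam_F * tau * nn
    death[4] = d_Fi * Fi * nn

    birth[5] = lam_Nd * Fi
    death[5] = d_Fo * Fo

    birth[6] = lam_AAbo * Abo + lam_MA * M1
    death[6] = d_A * A

    sat = M0G * lam_MF * (Fo / (Fo + K_Fo)) if (Fo + K_Fo) > 0 else 0.0
    birth[7] = sat * b_M1
    death[7] = d_M1 * M1
    birth[8] = sat * b_M2
    death[8] = d_M2 * M2


def _validate_state_array(x: np.ndarray) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    if x.shape != (9,):
        raise ValueError(f"expected a length-9 state, got shape {x.shape}")
    if not np.all(np.isfinite(x)):
        raise ValueError("state contains non-finite components")
    if np.any(x < 0):
        bad = VARIABLES[int(np.argmax(x < 0))]
        raise ValueError(f"state component {bad!r} is negative")
    return x


def channel_rates(
    state: StateVector | np.ndarray,
    params: ParameterSet,
    opts: ModelOptions = ModelOptions(),
) -> ChannelRates:
    """Decompose the rate equations into birth/death magnitudes at ``state``.

    Neurons are pure death (zero birth).  The A_beta_i -> A_beta_o and
    F_i -> F_o emigration fluxes (``lambda_Nd`` times the source
    concentration) appear as part of the destination's birth.
    """
    x = state.as_array() if isinstance(state, StateVector) else _validate_state_array(state)
    if isinstance(state, StateVector):
        x = _validate_state_array(x)
    birth = np.empty(9)
    death = np.empty(9)
    _birth_death_arrays(x, _params_tuple(params), opts.abeta_o_clearance, birth, death)
    return ChannelRates(birth=birth, death=death)


def rhs(
    state: StateVector | np.ndarray,
    params: ParameterSet,
    opts: ModelOptions = ModelOptions(),
) -> np.ndarray:
    """Time derivatives of the nine concentrations (g/ml/day).

    The neuron equation is a saturating loss driven by intracellular tangles;
    amyloid beta and tau production/clearance scale with the surviving neuron
    fraction N/N0; microglia are sourced from a pool saturating in
    extracellular tangles.
    """
    ch = channel_rates(state, params, opts)
    return ch.net()


#: Structural dependency sets: which OTHER variables appear in each equation.
_DEPENDENCIES_BASE: Mapping[str, frozenset] = {
    "N": frozenset({"F_i"}),
    "A_beta_i": frozenset({"N"}),
    "A_beta_o": frozenset({"A_beta_i", "N", "A"}),
    "tau": frozenset({"N"}),
    "F_i": frozenset({"tau", "N"}),
    "F_o": frozenset({"F_i"}),
    "A": frozenset({"A_beta_o", "M1"}),
    "M1": frozenset({"F_o"}),
    "M2": frozenset({"F_o"}),
}


def interaction_dependencies(opts: ModelOptions = ModelOptions()) -> Dict[str, frozenset]:
    """Per-variable set of distinct other state variables in its equation."""
    deps = dict(_DEPENDENCIES_BASE)
    if opts.abeta_o_clearance:
        deps["A_beta_o"] = deps["A_beta_o"] | {"M1", "M2"}
    return deps


def interaction_counts(opts: ModelOptions = ModelOptions()) -> Dict[str, int]:
    """Number of distinct other state variables in each rate equation.

    Self-couplings and parameters are excluded; the count is purely
    structural and independent of parameter values.  With the clearance term
    on, the extraneuronal amyloid equation touches five other variables
    (A_beta_i, N, A, M1, M2) while tau touches only neurons.
    """
    return {name: len(deps) for name, deps in interaction_dependencies(opts).items()}


def analytic_fixed_points(params: ParameterSet) -> Dict[str, float]:
    """Closed-form equilibrium/asymptote values used as analytic oracles.

    ``A_beta_i`` and ``tau`` equilibrate where production balances clearance;
    both values are independent of N as long as any neurons survive.  The
    microglia entries are the saturated-tangle asymptotes (extracellular
    tangles far above their half-saturation), which the trajectories approach
    but need not attain within a finite horizon.
    """
    for name in ("d_Abetai", "d_tau", "d_M1", "d_M2"):
        if getattr(params, name) == 0:
            raise ZeroDivisionError(f"degradation rate {name!r} is zero")
    return {
        "A_beta_i": params.lambda_beta_i * (1.0 + params.R0) / params.d_Abetai,
        "tau": (params.lambda_tau0 + params.lambda_tau * params.R0) / params.d_tau,
        "M1": params.M0_G * params.lambda_MF * params.beta_M1 / params.d_M1,
        "M2": params.M0_G * params.lambda_MF * params.beta_M2 / params.d_M2,
    }
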