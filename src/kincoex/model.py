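"""Community model: modified Lotka-Volterra competition with pulsed antibiotic mortality.

The model describes a well-mixed batch culture of two or three bacterial
strains.  Each member grows logistically toward a shared carrying capacity,
is inhibited (or helped) by the other members through pairwise interaction
coefficients, may experience an Allee effect at low density, and suffers an
additional antibiotic-induced death rate that is switched on only during a
perturbation window.  For a member ``X`` with maximum per-capita growth rate
``r``, Allee constant ``a``, interaction coefficients ``alpha_Xj`` and death
rate ``mu_X`` the dynamics are

    dX/dt = r * X * [ X/(a + X) * (1 - X) - sum_j alpha_Xj * X_j ] - mu_X * X

Abundances are dimensionless fractions of the carrying capacity
``K = 1e9 CFU/ml`` (the saturation density of the experimental cultures), so
the experimentally relevant inoculum range 1e5-1e9 CFU/ml maps to normalized
total densities ``D`` in ``[1e-4, 1]``.

Positive interaction coefficients are inhibitory (competition) because they
enter the bracket with a minus sign; negative coefficients are facilitative.
A negative death rate is a hormetic growth boost (the detoxifying cooperator
grows *better* in sub-inhibitory antibiotic).  The cheater's death rate is a
decreasing linear function of the run's initial total density ``D``: the more
detoxifying biomass is inoculated, the faster the antibiotic drops below the
cheater's inhibitory concentration, so the smaller its realized kill rate.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence, Tuple

import numpy as np

__all__ = [
    "CARRYING_CAPACITY_CFU_PER_ML",
    "ROLES",
    "PHENOTYPE_DEATH_RATES",
    "StrainParams",
    "DeathModel",
    "InteractionMatrix",
    "CommunityModel",
    "evaluate_rhs",
    "effective_death_rate",
    "interior_fixed_point_two_member",
    "default_two_member",
    "default_three_member",
]

#: Normalization scale: abundance 1.0 corresponds to this density.
CARRYING_CAPACITY_CFU_PER_ML = 1e9

ROLES = ("cooperator", "cheater", "regulator")

#: Antibiotic response phenotypes of the regulator and their in-window death
#: rates (per hour): a sensitive strain is killed, a detoxifying strain gets a
#: hormetic boost, an intrinsically resistant strain is unaffected.
PHENOTYPE_DEATH_RATES = {"sensitive": 0.8, "detoxifying": -0.3, "intrinsic": 0.0}

# Shipped default parameters of the two-member cooperator/cheater system.
DEFAULT_COOPERATOR_RATE = 0.5  # h^-1, slow detoxifying strain
DEFAULT_CHEATER_RATE = 0.75  # h^-1, fast sensitive strain
DEFAULT_ALPHA_AB = 1.9  # inhibition of cooperator A by cheater B
DEFAULT_ALPHA_BA = 1.75  # inhibition of cheater B by cooperator A
DEFAULT_MU_A = -0.6  # h^-1, hormetic boost of the cooperator in antibiotic
DEFAULT_MU_B_MAX = 1.0  # h^-1, cheater kill rate with no protection
#: Normalized initial density at which cooperator-mediated protection of the
#: cheater becomes complete (2e8 CFU/ml); partial protection across the
#: experimental inoculum range places the dominance switch near 1e7 CFU/ml.
DEFAULT_D_PROTECT = 0.2
DEFAULT_WINDOW = (72.0, 96.0)  # absolute hours of the antibiotic pulse


def _check_finite_nonneg(value: float, name: str) -> None:
    if not np.isfinite(value) or value < 0:
        raise ValueError(f"{name} must be finite and >= 0, got {value!r}")


@dataclass(frozen=True)
class StrainParams:
    """Intrinsic parameters of one community member.

    Parameters
    ----------
    name
        Human-readable strain label (e.g. ``"KF-1"``).
    role
        One of ``"cooperator"``, ``"cheater"``, ``"regulator"``.
    max_growth_rate
        Maximum per-capita growth rate in 1/h; must be finite and >= 0.
    allee_constant
        Dimensionless Allee constant ``a`` in the factor ``X/(a+X)``.
        Zero disables the Allee effect (the factor is 1 for any X > 0).
    """

    name: str
    role: str
    max_growth_rate: float
    allee_constant: float = 0.0

    def __post_init__(self) -> None:
        if self.role not in ROLES:
            raise ValueError(f"role must be one of {ROLES}, got {self.role!r}")
        _check_finite_nonneg(self.max_growth_rate, "max_growth_rate")
        _check_finite_nonneg(self.allee_constant, "allee_constant")


@dataclass(frozen=True)
class DeathModel:
    """Antibiotic-induced death rate of one member, active only in a time window.

    Two kinds are supported:

    ``constant``
        The in-window rate is ``constant_rate`` (1/h).  Negative values are
        allowed and model hormesis (a growth boost).
    ``linear_in_density``
        The in-window rate is ``max(0, slope * D + intercept)`` where ``D`` is
        the run's *initial* normalized total density.  The clamp at zero means
        density-dependent protection can at best neutralize the kill rate,
        never turn it into growth.

    Outside ``[window_start, window_end)`` the effective rate is exactly 0.
    """

    kind: str = "constant"
    constant_rate: float = 0.0
    slope: float = 0.0
    intercept: float = 0.0
    window_start: float = DEFAULT_WINDOW[0]
    window_end: float = DEFAULT_WINDOW[1]

    def __post_init__(self) -> None:
        if self.kind not in ("constant", "linear_in_density"):
            raise ValueError(f"unknown death model kind {self.kind!r}")
        if not self.window_start < self.window_end:
            raise ValueError("window_start must be < window_end")

    def with_window(self, window: Optional[Tuple[float, float]]) -> "DeathModel":
        """Return a copy whose window matches ``window``; disable if ``None``."""
        if window is None:
            return replace(self, kind="constant", constant_rate=0.0,
                           slope=0.0, intercept=0.0)
        return replace(self, window_start=window[0], window_end=window[1])


NO_DEATH = DeathModel()


def effective_death_rate(death: DeathModel, t: float, initial_density: float) -> float:
    """Death rate of one member at absolute time ``t`` (hours).

    Returns 0 outside the antibiotic window.  Inside, a ``constant`` model
    returns its rate as-is (negative rates pass through — hormesis), while a
    ``linear_in_density`` model evaluates ``slope * D + intercept`` on the
    run's initial total density ``D`` and clamps the result below at zero.
    """
    if not (death.window_start <= t < death.window_end):
        return 0.0
    if death.kind == "constant":
        return death.constant_rate
    return max(0.0, death.slope * initial_density + death.intercept)


@dataclass(frozen=True, eq=False)
class InteractionMatrix:
    """Pairwise interaction coefficients ``alpha_ij`` (effect of member j on i).

    The diagonal is unused and must be zero — self-limitation is carried by
    the logistic ``(1 - X)`` term.  When ``symmetric_regulator`` is set and
    the community has a regulator (by convention the last member), its row
    and column must be mirror-equal (``alpha_iC == alpha_Ci``), encoding a
    perfect correlation between reciprocal interaction strengths.
    """

    coefficients: np.ndarray
    symmetric_regulator: bool = False

    def __post_init__(self) -> None:
        coeff = np.array(self.coefficients, dtype=float)
        if coeff.ndim != 2 or coeff.shape[0] != coeff.shape[1]:
            raise ValueError("coefficients must be a square matrix")
        if np.any(np.diag(coeff) != 0.0):
            raise ValueError("diagonal interaction entries must be zero")
        coeff.setflags(write=False)
        object.__setattr__(self, "coefficients", coeff)
        if self.symmetric_regulator and coeff.shape[0] >= 3:
            last = coeff.shape[0] - 1
            if not np.allclose(coeff[last, :], coeff[:, last], atol=1e-12):
                raise ValueError(
                    "symmetric_regulator requires mirror-equal regulator row/column"
                )

    @property
    def n(self) -> int:
        return self.coefficients.shape[0]


@dataclass(frozen=True, eq=False)
class CommunityModel:
    """A 2- or 3-member community: strains, interactions and death models."""

    members: Tuple[StrainParams, ...]
    interactions: InteractionMatrix
    deaths: Tuple[DeathModel, ...]

    def __post_init__(self) -> None:
        members = tuple(self.members)
        deaths = tuple(self.deaths)
        object.__setattr__(self, "members", members)
        object.__setattr__(self, "deaths", deaths)
        n = len(members)
        if n not in (2, 3):
            raise ValueError("community must have 2 or 3 members")
        if self.interactions.n != n:
            raise ValueError("interaction matrix dimension != member count")
        if len(deaths) != n:
            raise ValueError("need exactly one death model per member")
        object.__setattr__(
            self, "_rates", np.array([m.max_growth_rate for m in members])
        )
        object.__setattr__(
            self, "_allee", np.array([m.allee_constant for m in members])
        )

    @property
    def n_members(self) -> int:
        return len(self.members)

    @property
    def member_names(self) -> Tuple[str, ...]:
        return tuple(m.name for m in self.members)

    def index_of_role(self, role: str) -> int:
        """Index of the first member with the given role."""
        for i, m in enumerate(self.members):
            if m.role == role:
                return i
        raise KeyError(f"no member with role {role!r}")

    def with_member_rate(self, index: int, rate: float) -> "CommunityModel":
        members = list(self.members)
        members[index] = replace(members[index], max_growth_rate=rate)
        return replace(self, members=tuple(members))

    def with_death(self, index: int, death: DeathModel) -> "CommunityModel":
        deaths = list(self.deaths)
        deaths[index] = death
        return replace(self, deaths=tuple(deaths))

    def with_window(self, window: Optional[Tuple[float, float]]) -> "CommunityModel":
        """Align every member's antibiotic window with ``window`` (None = no drug)."""
        return replace(
            self, deaths=tuple(d.with_window(window) for d in self.deaths)
        )

    def with_interaction(self, i: int, j: int, value: float,
                         symmetric: bool = False) -> "CommunityModel":
        coeff = np.array(self.interactions.coefficients, dtype=float)
        coeff[i, j] = value
        if symmetric:
            coeff[j, i] = value
        return replace(
            self,
            interactions=InteractionMatrix(
                coeff, symmetric_regulator=self.interactions.symmetric_regulator
            ),
        )


def evaluate_rhs(
    model: CommunityModel,
    state: Sequence[float],
    t: float,
    initial_density: float,
) -> np.ndarray:
    """Right-hand side of the community ODEs at time ``t`` (1/h per member).

    ``initial_density`` is the run's normalized initial total density ``D``,
    which parameterizes density-dependent death models.  For an extinct
    member (abundance 0) the derivative is exactly 0; with a zero Allee
    constant the factor ``X/(a+X)`` is 1 for X > 0 and 0 at X = 0 (limit
    convention, so extinction is absorbing).
    """
    x = np.asarray(state, dtype=float)
    if x.shape != (model.n_members,):
        raise ValueError(
            f"state has shape {x.shape}, expected ({model.n_members},)"
        )
    if np.any(x < 0):
        raise ValueError("abundances must be non-negative")
    allee = model._allee
    denom = allee + x
    fac = np.divide(x, denom, out=np.zeros_like(x), where=denom > 0)
    deff = np.array(
        [effective_death_rate(d, t, initial_density) for d in model.deaths]
    )
    competition = model.interactions.coefficients @ x
    return model._rates * x * (fac * (1.0 - x) - competition) - deff * x


def interior_fixed_point_two_member(
    model: CommunityModel,
) -> Optional[Tuple[float, float]]:
    """Interior coexistence equilibrium of the drug-free two-member system.

    With zero Allee constants and zero death rates the equilibrium conditions
    reduce to ``1 - A = alpha_AB * B`` and ``1 - B = alpha_BA * A``, giving

        A* = (1 - alpha_AB) / (1 - alpha_AB * alpha_BA)
        B* = (1 - alpha_BA) / (1 - alpha_AB * alpha_BA)

    Returns ``None`` when the denominator vanishes or either component is not
    strictly positive (the equilibrium is then on or outside the boundary).
    Intended as an analytic oracle; requires a model satisfying the
    assumptions (raises ``ValueError`` otherwise).
    """
    if model.n_members != 2:
        raise ValueError("interior fixed point is defined for two members")
    if np.any(model._allee != 0):
        raise ValueError("requires zero Allee constants")
    for d in model.deaths:
        if not (d.kind == "constant" and d.constant_rate == 0.0):
            raise ValueError("requires zero death rates")
    a_ab = model.interactions.coefficients[0, 1]
    a_ba = model.interactions.coefficients[1, 0]
    denom = 1.0 - a_ab * a_ba
    if denom == 0.0:
        return None
    a_star = (1.0 - a_ab) / denom
    b_star = (1.0 - a_ba) / denom
    if a_star <= 0.0 or b_star <= 0.0:
        return None
    return (a_star, b_star)


def default_two_member(
    cooperator_rate: float = DEFAULT_COOPERATOR_RATE,
    cheater_rate: float = DEFAULT_CHEATER_RATE,
    alpha_ab: float = DEFAULT_ALPHA_AB,
    alpha_ba: float = DEFAULT_ALPHA_BA,
    mu_a: float = DEFAULT_MU_A,
    mu_b_max: float = DEFAULT_MU_B_MAX,
    d_protect: float = DEFAULT_D_PROTECT,
    window: Tuple[float, float] = DEFAULT_WINDOW,
    allee_a: float = 0.0,
    allee_b: float = 0.0,
) -> CommunityModel:
    """Shipped cooperator/cheater model of the experimental kin pair.

    The slow cooperator (KF-1-like, 0.5/h) detoxifies the antibiotic and is
    hormetically boosted during the pulse (``mu_a = -0.6``); the fast cheater
    (0.75/h) is killed at ``mu_b_max`` when unprotected, with protection
    increasing linearly in the initial total density up to full protection at
    ``d_protect``: ``mu_B(D) = mu_b_max * max(0, 1 - D/d_protect)``.
    """
    members = (
        StrainParams("cooperator_A", "cooperator", cooperator_rate, allee_a),
        StrainParams("cheater_B", "cheater", cheater_rate, allee_b),
    )
    interactions = InteractionMatrix(
        np.array([[0.0, alpha_ab], [alpha_ba, 0.0]])
    )
    deaths = (
        DeathModel("constant", constant_rate=mu_a,
                   window_start=window[0], window_end=window[1]),
        DeathModel("linear_in_density",
                   slope=-mu_b_max / d_protect, intercept=mu_b_max,
                   window_start=window[0], window_end=window[1]),
    )
    return CommunityModel(members, interactions, deaths)


def default_three_member(
    alpha_ac: float = 1.0,
    alpha_bc: float = 1.5,
    regulator_rate: float = DEFAULT_CHEATER_RATE,
    phenotype: str = "intrinsic",
    allee_c: float = 0.0,
    **two_member_kwargs,
) -> CommunityModel:
    """Two-member default plus a regulator C with symmetric interactions.

    ``alpha_ac`` and ``alpha_bc`` are the regulator's reciprocal interaction
    coefficients with the cooperator and the cheater (``alpha_ij = alpha_ji``
    for pairs involving C).  ``phenotype`` selects the regulator's in-window
    death rate from :data:`PHENOTYPE_DEATH_RATES`.
    """
    if phenotype not in PHENOTYPE_DEATH_RATES:
        raise ValueError(
            f"phenotype must be one of {sorted(PHENOTYPE_DEATH_RATES)}"
        )
    base = default_two_member(**two_member_kwargs)
    window = (base.deaths[0].window_start, base.deaths[0].window_end)
    members = base.members + (
        StrainParams("regulator_C", "regulator", regulator_rate, allee_c),
    )
    c = base.interactions.coefficients
    coeff = np.array(
        [
            [0.0, c[0, 1], alpha_ac],
            [c[1, 0], 0.0, alpha_bc],
            [alpha_ac, alpha_bc, 0.0],
        ]
    )
    interactions = InteractionMatrix(coeff, symmetric_regulator=True)
    deaths = base.deaths + (
        DeathModel("constant", constant_rate=PHENOTYPE_DEATH_RATES[phenotype],
                   window_start=window[0], window_end=window[1]),
    )
    return CommunityModel(members, interactions, deaths)
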