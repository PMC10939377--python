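"""Outcome classification and phase-diagram sweeps.

A community run is labelled operationally: *coexistence* means every member
survived the final growth cycle without its population shrinking by more
than a threshold fraction (default 20%) between the post-dilution start and
the pre-dilution end of that cycle; a shrinking or extinct member indicates
a pathway toward extinction and the run is labelled *exclusion*; a run in
which every member dies is a *collapse*.

Two sweep drivers reproduce the study's phase diagrams: a two-member sweep
over (cheater growth rate, initial total density) labelled by the dominant
member after the 7-day pulsed protocol, and a three-member sweep over the
regulator's symmetric interaction coefficients labelled by the coexistence
rule after the 5-day protocol, for each antibiotic-response phenotype of the
regulator.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from typing import Dict, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .model import (
    CommunityModel,
    DeathModel,
    PHENOTYPE_DEATH_RATES,
)
from .protocol import ProtocolSpec, SolverOptions, Trajectory, run_protocol

__all__ = [
    "OutcomeLabel",
    "Axis",
    "PhaseDiagram",
    "classify_coexistence",
    "classify_from_snapshots",
    "dominant_member",
    "interaction_regime",
    "sweep_two_member",
    "sweep_three_member",
]

logger = logging.getLogger(__name__)

CATEGORIES = ("coexistence", "exclusion", "collapse", "error")


@dataclass(frozen=True)
class OutcomeLabel:
    """Categorical outcome of one community run.

    ``per_member_decline`` holds each member's fractional change over the
    final cycle (negative = decline); ``dominant`` names the winner for
    exclusion outcomes and is ``None`` for coexistence and collapse.
    """

    category: str
    dominant: Optional[str]
    per_member_decline: Tuple[float, ...]

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise ValueError(f"unknown category {self.category!r}")
        if self.category == "exclusion" and self.dominant is None:
            raise ValueError("exclusion outcomes must carry a dominant label")


def dominant_member(state: Sequence[float],
                    names: Optional[Sequence[str]] = None) -> str:
    """Label (or index as string) of the most abundant member.

    Ties are broken toward the lowest member index, with a log note.
    Raises ``ValueError`` on an all-zero state (collapse has no dominant).
    """
    x = np.asarray(state, dtype=float)
    if not np.any(x > 0):
        raise ValueError("all members extinct: no dominant member")
    idx = int(np.argmax(x))
    if np.sum(x == x[idx]) > 1:
        logger.info("dominance tie at abundance %g; keeping lowest index", x[idx])
    return names[idx] if names is not None else str(idx)


def classify_from_snapshots(
    start: Sequence[float],
    end: Sequence[float],
    names: Sequence[str],
    decline_threshold: float = 0.20,
    floor: float = 0.0,
) -> OutcomeLabel:
    """Apply the coexistence rule to one cycle's start/end abundances.

    A member "declines" when ``(end - start)/start < -decline_threshold``
    (strict, so a decline of exactly the threshold still coexists); a member
    at or below ``floor`` at cycle end is extinct.
    """
    start = np.asarray(start, dtype=float)
    end = np.asarray(end, dtype=float)
    extinct = end <= floor
    decline = np.zeros(len(start))
    for i in range(len(start)):
        if start[i] > 0:
            decline[i] = (end[i] - start[i]) / start[i]
        else:
            decline[i] = 0.0 if extinct[i] else np.inf
    if np.all(extinct):
        return OutcomeLabel("collapse", None, tuple(decline))
    # strict inequality: a decline of exactly the threshold still coexists
    # (1e-12 slack absorbs round-off at the boundary)
    if np.any(extinct) or np.any(decline < -decline_threshold - 1e-12):
        return OutcomeLabel(
            "exclusion", dominant_member(end, list(names)), tuple(decline)
        )
    return OutcomeLabel("coexistence", None, tuple(decline))


def classify_coexistence(
    traj: Trajectory,
    decline_threshold: float = 0.20,
    baseline: str = "cycle_start",
) -> OutcomeLabel:
    """Coexistence label of a protocol run from its final-cycle snapshots.

    ``baseline`` selects the reference population for the decline rule:
    ``"cycle_start"`` (default) compares the final cycle's pre-dilution end
    against that same cycle's post-dilution start, so the rule measures net
    per-cycle decline; ``"global_initial"`` compares against the member's
    share of the run's initial inoculum instead.
    """
    if traj.n_cycles < 1:
        raise ValueError("trajectory has no complete cycle")
    if baseline == "cycle_start":
        start = traj.cycle_starts[-1]
    elif baseline == "global_initial":
        start = traj.cycle_starts[0]
    else:
        raise ValueError(f"unknown baseline {baseline!r}")
    floor = traj.metadata.get("solver", {}).get("extinction_floor", 0.0)
    return classify_from_snapshots(
        start, traj.cycle_ends[-1], traj.member_names,
        decline_threshold=decline_threshold, floor=floor,
    )


def interaction_regime(alpha_ac: float, alpha_bc: float) -> str:
    """Sign-pattern regime of the regulator's two interaction coefficients.

    Coefficients enter the growth bracket with a minus sign, so positive
    values are inhibitory: ``competition`` when both are positive,
    ``mutualism`` when both are negative, ``exploitation`` for mixed signs,
    and ``neutral_boundary`` when either coefficient is exactly zero.
    """
    if alpha_ac == 0.0 or alpha_bc == 0.0:
        return "neutral_boundary"
    if alpha_ac > 0 and alpha_bc > 0:
        return "competition"
    if alpha_ac < 0 and alpha_bc < 0:
        return "mutualism"
    return "exploitation"


@dataclass(frozen=True)
class Axis:
    name: str
    scale: str  # "linear" | "log"
    values: Tuple[float, ...]

    def __post_init__(self) -> None:
        if self.scale not in ("linear", "log"):
            raise ValueError("scale must be 'linear' or 'log'")

    @property
    def n(self) -> int:
        return len(self.values)


@dataclass
class PhaseDiagram:
    """Categorical outcome grid over two swept control parameters.

    ``category[i, j]`` corresponds to ``axes[0].values[i]`` and
    ``axes[1].values[j]``; ``dominant`` and ``regime`` are aligned grids
    (empty string where not applicable).
    """

    axes: Tuple[Axis, Axis]
    category: np.ndarray
    dominant: np.ndarray
    regime: np.ndarray
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        shape = (self.axes[0].n, self.axes[1].n)
        for grid in (self.category, self.dominant, self.regime):
            if grid.shape != shape:
                raise ValueError("grid shape does not match axis resolutions")

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for i, a in enumerate(self.axes[0].values):
            for j, b in enumerate(self.axes[1].values):
                rows.append(
                    {
                        f"{self.axes[0].name}": a,
                        f"{self.axes[1].name}": b,
                        "category": self.category[i, j],
                        "dominant": self.dominant[i, j],
                        "regime": self.regime[i, j],
                    }
                )
        return pd.DataFrame(rows)


def _sweep_solver(solver: Optional[SolverOptions]) -> SolverOptions:
    # Sweeps classify the continuum flow: no dense output (only cycle
    # boundaries are needed) and no extinction cutoff, so low-density
    # rebound through the antibiotic window is resolved exactly.
    if solver is not None:
        return solver
    return SolverOptions(output_resolution=None, extinction_floor=0.0)


def sweep_two_member(
    template: CommunityModel,
    spec: ProtocolSpec,
    cheater_rates: Sequence[float],
    densities: Sequence[float],
    decline_threshold: float = 0.20,
    solver: Optional[SolverOptions] = None,
) -> PhaseDiagram:
    """Phase diagram over (cheater growth rate, initial total density).

    Each grid cell runs the full pulsed protocol from an equal-proportion
    inoculum at total density ``D`` and is labelled by the dominant member of
    the final pre-dilution state; the coexistence rule's category is recorded
    alongside.  A failed run is recorded as the ``"error"`` category rather
    than aborting the sweep.
    """
    solver = _sweep_solver(solver)
    cheater_idx = template.index_of_role("cheater")
    rates = tuple(float(r) for r in cheater_rates)
    dens = tuple(float(d) for d in densities)
    shape = (len(rates), len(dens))
    category = np.empty(shape, dtype=object)
    dominant = np.empty(shape, dtype=object)
    regime = np.full(shape, "", dtype=object)
    from dataclasses import replace as _replace

    for (i, rate), (j, D) in itertools.product(
        enumerate(rates), enumerate(dens)
    ):
        model = template.with_member_rate(cheater_idx, rate)
        cell_spec = _replace(spec, initial_total_density=D)
        try:
            traj = run_protocol(model, cell_spec, solver=solver)
        except Exception as err:  # recorded, not raised
            logger.warning("sweep cell (%g, %g) failed: %s", rate, D, err)
            category[i, j] = "error"
            dominant[i, j] = ""
            continue
        label = classify_coexistence(traj, decline_threshold=decline_threshold)
        category[i, j] = label.category
        try:
            dominant[i, j] = dominant_member(traj.final_state,
                                             traj.member_names)
        except ValueError:
            dominant[i, j] = ""
    axes = (
        Axis("cheater_rate", "linear", rates),
        Axis("initial_density", "log", dens),
    )
    return PhaseDiagram(
        axes, category, dominant, regime,
        provenance={
            "sweep": "two_member",
            "protocol": spec.__dict__ | {"initial_total_density": "swept"},
            "decline_threshold": decline_threshold,
        },
    )


def sweep_three_member(
    template: CommunityModel,
    spec: ProtocolSpec,
    alpha_ac_values: Sequence[float],
    alpha_bc_values: Sequence[float],
    phenotypes: Sequence[str] = ("sensitive", "detoxifying", "intrinsic"),
    regulator_rate: Optional[float] = None,
    decline_threshold: float = 0.20,
    solver: Optional[SolverOptions] = None,
) -> Dict[str, PhaseDiagram]:
    """Phase diagrams over the regulator's symmetric interaction coefficients.

    For each phenotype (regulator death rate during the pulse) and each grid
    cell ``(alpha_AC, alpha_BC)``, sets the reciprocal coefficients
    symmetrically (``alpha_CA = alpha_AC``, ``alpha_CB = alpha_BC``), runs
    the protocol and labels the cell with the coexistence rule plus the
    sign-pattern interaction regime.  Returns one diagram per phenotype.
    """
    solver = _sweep_solver(solver)
    if template.n_members != 3:
        raise ValueError("three-member sweep needs a three-member template")
    reg_idx = template.index_of_role("regulator")
    coop_idx = template.index_of_role("cooperator")
    cheat_idx = template.index_of_role("cheater")
    if regulator_rate is not None:
        template = template.with_member_rate(reg_idx, regulator_rate)
    a_vals = tuple(float(a) for a in alpha_ac_values)
    b_vals = tuple(float(b) for b in alpha_bc_values)
    window = spec.antibiotic_window
    diagrams: Dict[str, PhaseDiagram] = {}
    for phenotype in phenotypes:
        mu_c = PHENOTYPE_DEATH_RATES[phenotype]
        death_c = DeathModel(
            "constant", constant_rate=mu_c,
            window_start=window[0] if window else 0.0,
            window_end=window[1] if window else 1.0,
        )
        base = template.with_death(reg_idx, death_c)
        shape = (len(a_vals), len(b_vals))
        category = np.empty(shape, dtype=object)
        dominant = np.empty(shape, dtype=object)
        regime = np.empty(shape, dtype=object)
        for (i, a_ac), (j, a_bc) in itertools.product(
            enumerate(a_vals), enumerate(b_vals)
        ):
            model = (
                base.with_interaction(coop_idx, reg_idx, a_ac, symmetric=True)
                .with_interaction(cheat_idx, reg_idx, a_bc, symmetric=True)
            )
            regime[i, j] = interaction_regime(a_ac, a_bc)
            try:
                traj = run_protocol(model, spec, solver=solver)
            except Exception as err:
                logger.warning(
                    "sweep cell (%g, %g, %s) failed: %s", a_ac, a_bc,
                    phenotype, err,
                )
                category[i, j] = "error"
                dominant[i, j] = ""
                continue
            label = classify_coexistence(
                traj, decline_threshold=decline_threshold
            )
            category[i, j] = label.category
            dominant[i, j] = label.dominant or ""
        axes = (
            Axis("alpha_AC", "linear", a_vals),
            Axis("alpha_BC", "linear", b_vals),
        )
        diagrams[phenotype] = PhaseDiagram(
            axes, category, dominant, regime,
            provenance={
                "sweep": "three_member",
                "phenotype": phenotype,
                "regulator_death_rate": mu_c,
                "regulator_rate": template.members[reg_idx].max_growth_rate,
                "protocol": spec.__dict__.copy(),
                "decline_threshold": decline_threshold,
            },
        )
    return diagrams
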