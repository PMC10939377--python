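"""Synthetic datasets with the statistical structure of the wet-lab assays.

Three generators mirror the study's experimental designs so the estimators
can be exercised end-to-end without any real data:

* monoculture OD600 growth curves across inoculum densities, with and
  without antibiotic, from logistic dynamics plus a constant antibiotic
  death/boost term and multiplicative lognormal measurement noise;
* co-culture colony-count trajectories sampled from a serial-dilution
  protocol run, with Poisson plating noise at an automatically chosen
  decadal dilution;
* antibiotic concentration series declining linearly in time at a rate
  proportional to the detoxifying strain's cell density.

Every generator is a pure function of its configuration and an integer
seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .empirical import effective_growth_rate, ODRecord
from .model import CARRYING_CAPACITY_CFU_PER_ML, CommunityModel
from .protocol import ProtocolSpec, SolverOptions, run_protocol

__all__ = [
    "SynthStrain",
    "SynthConfig",
    "logistic_with_death",
    "generate_od_curves",
    "generate_cocult_counts",
    "generate_smx_decay",
]

#: Conversion between optical density and viable density: OD 1.0/cm
#: corresponds to carrying capacity (1e9 CFU/ml).
DEFAULT_OD_PER_CELL = 1.0 / CARRYING_CAPACITY_CFU_PER_ML

#: Target per-plate colony window for the automatic dilution choice.
TARGET_COLONIES = (30, 300)


@dataclass(frozen=True)
class SynthStrain:
    """Ground-truth parameters of one simulated strain.

    ``smx_death_rate`` is the additional per-hour death rate in antibiotic-
    supplemented wells (negative = hormetic growth boost); it is constant
    over the assay because a monoculture of a non-detoxifying strain never
    clears the drug below its inhibitory concentration.
    """

    name: str
    growth_rate: float  # h^-1
    smx_death_rate: float = 0.0  # h^-1 while drug present


@dataclass(frozen=True)
class SynthConfig:
    """Settings shared by the synthetic-assay generators."""

    strains: Tuple[SynthStrain, ...] = (
        SynthStrain("cooperator_A", 0.5, smx_death_rate=-0.6),
        SynthStrain("cheater_B", 0.75, smx_death_rate=0.8),
    )
    carrying_capacity: float = CARRYING_CAPACITY_CFU_PER_ML
    od_per_cell: float = DEFAULT_OD_PER_CELL
    inoculum_densities: Tuple[float, ...] = tuple(np.logspace(5, 9, 5))
    smx_concentration: float = 200.0  # ug/l
    replicates: int = 6
    od_noise_sigma: float = 0.02  # lognormal sigma on OD
    sampling_interval: float = 0.5  # h
    horizon: float = 72.0  # h
    plated_volume: float = 0.01  # ml
    seed: int = 0

    def __post_init__(self) -> None:
        if self.od_noise_sigma < 0:
            raise ValueError("od_noise_sigma must be >= 0")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")


def logistic_with_death(
    x0: float, r: float, delta: float, capacity: float, t: np.ndarray
) -> np.ndarray:
    """Closed-form solution of dX/dt = r X (1 - X/K) - delta X.

    The net dynamics are logistic with rate ``rho = r - delta`` and an
    effective capacity ``K * rho / r`` (negative rho gives decay to zero).
    """
    t = np.asarray(t, dtype=float)
    if x0 == 0:
        return np.zeros_like(t)
    if r == 0.0:
        return x0 * np.exp(-delta * t)
    rho = r - delta
    if rho == 0.0:
        return x0 / (1.0 + (r / capacity) * x0 * t)
    k_eff = capacity * rho / r
    e = np.exp(rho * t)
    return k_eff * x0 * e / (k_eff + x0 * (e - 1.0))


def generate_od_curves(
    cfg: SynthConfig,
    conditions: Sequence[bool] = (False, True),
    seed: Optional[int] = None,
) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Monoculture OD600 curves plus their ground truth.

    Returns ``(od_table, truth_table)``.  The OD table is long-format with
    columns ``well, strain, initial_density, smx, time_h, od600``.  The
    truth table has one row per well with the intrinsic rate, the net rate
    in that condition, and the noiseless-limit effective growth rate (the
    threshold-crossing estimate computed on the noiseless sampled curve;
    NaN when the well starts at/above threshold or never crosses it).
    """
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    times = np.arange(0.0, cfg.horizon + cfg.sampling_interval / 2,
                      cfg.sampling_interval)
    od_rows = []
    truth_rows = []
    for strain in cfg.strains:
        for d_idx, density in enumerate(cfg.inoculum_densities):
            for smx in conditions:
                delta = strain.smx_death_rate if smx else 0.0
                x = logistic_with_death(
                    density, strain.growth_rate, delta,
                    cfg.carrying_capacity, times,
                )
                od_clean = x * cfg.od_per_cell
                eff_rate, t_thr, censored = _noiseless_effective_rate(
                    times, od_clean
                )
                for rep in range(cfg.replicates):
                    well = f"{strain.name}.d{d_idx}.{'smx' if smx else 'ctrl'}.r{rep}"
                    if cfg.od_noise_sigma > 0:
                        noise = np.exp(
                            cfg.od_noise_sigma * rng.standard_normal(len(times))
                        )
                    else:
                        noise = 1.0
                    od_obs = od_clean * noise
                    od_rows.append(
                        pd.DataFrame(
                            {
                                "well": well,
                                "strain": strain.name,
                                "initial_density": density,
                                "smx": smx,
                                "time_h": times,
                                "od600": od_obs,
                            }
                        )
                    )
                    truth_rows.append(
                        {
                            "well": well,
                            "strain": strain.name,
                            "initial_density": density,
                            "smx": smx,
                            "true_rate": strain.growth_rate,
                            "net_rate": strain.growth_rate - delta,
                            "true_effective_rate": eff_rate,
                            "true_t_threshold": t_thr,
                            "censored": censored,
                            "seed": cfg.seed if seed is None else seed,
                        }
                    )
    return pd.concat(od_rows, ignore_index=True), pd.DataFrame(truth_rows)


def _noiseless_effective_rate(times, od_clean, od_threshold: float = 0.5):
    if od_clean[0] >= od_threshold:
        return np.nan, np.nan, False
    rec = ODRecord("truth", "truth", 0.0, False, times, od_clean)
    est = effective_growth_rate(rec, od_threshold=od_threshold)
    if est.censored:
        return np.nan, np.nan, True
    return est.rate, est.t_threshold, False


def choose_dilution_factor(expected_cells_plated: float) -> float:
    """Smallest decadal dilution keeping the expected count at or below 300."""
    if expected_cells_plated <= TARGET_COLONIES[1]:
        return 1.0
    k = int(np.ceil(np.log10(expected_cells_plated / TARGET_COLONIES[1])))
    return float(10**k)


def generate_cocult_counts(
    model: CommunityModel,
    spec: ProtocolSpec,
    cfg: SynthConfig,
    seed: Optional[int] = None,
    solver: Optional[SolverOptions] = None,
) -> pd.DataFrame:
    """Selective-plating colony counts along a serial-dilution protocol run.

    Runs the protocol, converts each cycle-boundary abundance to an expected
    plated-cell count at an automatically chosen decadal dilution (targeting
    30-300 colonies), and draws the observed count from a Poisson with that
    expectation.  Columns: ``cycle, timepoint, strain, colonies,
    dilution_factor, plated_volume, true_cfu_per_ml, below_detection``.
    """
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    if solver is None:
        solver = SolverOptions(output_resolution=None)
    traj = run_protocol(model, spec, solver=solver)
    rows = []
    for k in range(traj.n_cycles):
        for timepoint, snapshot in (
            ("cycle_start", traj.cycle_starts[k]),
            ("cycle_end", traj.cycle_ends[k]),
        ):
            for j, name in enumerate(traj.member_names):
                density = snapshot[j] * cfg.carrying_capacity
                plated = density * cfg.plated_volume
                dilution = choose_dilution_factor(plated)
                expected = plated / dilution
                colonies = int(rng.poisson(expected)) if expected > 0 else 0
                rows.append(
                    {
                        "cycle": k,
                        "timepoint": timepoint,
                        "strain": name,
                        "colonies": colonies,
                        "dilution_factor": dilution,
                        "plated_volume": cfg.plated_volume,
                        "true_cfu_per_ml": density,
                        "below_detection": colonies == 0,
                    }
                )
    return pd.DataFrame(rows)


def generate_smx_decay(
    cooperator_density: float,
    initial_concentration: float = 200.0,
    clearance_coefficient: float = 1e-6,
    noise_sigma: float = 0.0,
    times: Optional[Sequence[float]] = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Antibiotic concentration series under detoxifier-mediated clearance.

    The concentration declines linearly at ``clearance_coefficient *
    cooperator_density`` (ug/l per hour), floored at zero, with additive
    Gaussian measurement noise.  ``clearance_coefficient`` is in ug/l per
    hour per CFU/ml.  Default sampling: 13 points over 24 h.
    """
    if initial_concentration < 0:
        raise ValueError("initial_concentration must be >= 0")
    rng = np.random.default_rng(seed)
    if times is None:
        times = np.linspace(0.0, 24.0, 13)
    times = np.asarray(times, dtype=float)
    slope = clearance_coefficient * cooperator_density
    clean = np.maximum(0.0, initial_concentration - slope * times)
    noise = noise_sigma * rng.standard_normal(len(times)) if noise_sigma > 0 else 0.0
    return pd.DataFrame(
        {
            "time_h": times,
            "smx_ug_per_l": clean + noise,
            "true_concentration": clean,
            "cooperator_density": cooperator_density,
            "true_slope": -slope,
            "seed": seed,
        }
    )
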