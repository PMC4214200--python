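"""Synthetic tri-culture batch time courses with known ground truth.

No raw metabolite tables are published for the consortium experiments,
so the pipeline is exercised on simulated batches that emulate the
observed behaviour: logistic acetate depletion of a 40 mM batch within
~10-11 days, mol-for-mol CH4 accumulation in the headspace, inorganic
carbon evolving by closed-vial speciation of the initial pool plus
biogenic CO2, and a trace-level H2 partial pressure that rises to a
quasi-steady plateau of tens of Pa during log phase and collapses when
the substrate runs out.  The plateau decreases with the medium's initial
inorganic carbon, as observed.  Each replicate adds multiplicative
lognormal measurement noise; the noise-free twin is retained so tests
can assert exact mass balance.

The generative model is phenomenological (shape-level), not a kinetic
(Monod/ODE) growth model: its purpose is to provide trajectories with
exactly known ground truth, not to predict real cultures.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .carbonate import MediumSpec, VialSpec, speciate_closed_vial
from .thermo import CultureState
from .units import ATM_PA, R_L_ATM

__all__ = [
    "ConditionSpec",
    "STUDY_CONDITIONS",
    "GeneratorConfig",
    "TimeCourse",
    "ORGANISMS",
    "generate_timecourse",
    "generate_study",
    "generate_abundances",
]

#: The three consortium members; the first is the aceticlastic methanogen,
#: the other two are the syntrophic pair (SAOB + hydrogenotroph).
ORGANISMS = (
    "Methanosaeta_thermophila",
    "Thermacetogenium_phaeum",
    "Methanothermobacter_thermautotrophicus",
)


@dataclass(frozen=True)
class ConditionSpec:
    """One initial-inorganic-carbon condition of the study design.

    ``label`` is the nominal initial [sigma-CO2] in mmol per liter of
    medium; ``bicarbonate_added`` (mol/L) and ``co2_headspace_fraction``
    are the medium recipe.  ``h2_plateau_pa`` and ``t_mid_days`` are
    generator calibration per condition (see docs/methods.md).
    """

    label: str
    bicarbonate_added: float
    co2_headspace_fraction: float
    h2_plateau_pa: float
    t_mid_days: float


#: The three media (5 mM NaHCO3 / 0% CO2; 35 mM / 20%; 35 mM / 100%),
#: keyed by their nominal initial [sigma-CO2] labels.
STUDY_CONDITIONS: dict[str, ConditionSpec] = {
    "5.0": ConditionSpec("5.0", 0.005, 0.0, 30.0, 3.2),
    "50.7": ConditionSpec("50.7", 0.035, 0.2, 24.0, 3.6),
    "113.4": ConditionSpec("113.4", 0.035, 1.0, 21.0, 4.0),
}


@dataclass(frozen=True)
class GeneratorConfig:
    """Configuration of one simulated condition.

    The defaults are the study conditions: 40 mM sodium acetate in a
    68/20 ml vial at 55 degC and pH 7.0, sampled daily for 15 days in
    triplicate with 5% relative measurement noise.
    """

    condition: str = "5.0"
    initial_acetate: float = 0.040  # mol/L
    duration_days: float = 15.0
    sampling_interval_days: float = 1.0
    n_replicates: int = 3
    consumption_rate: float = 0.7  # logistic steepness, 1/day
    t_mid_days: float | None = None  # None -> condition default
    h2_plateau_pa: float | None = None  # None -> condition default
    h2_rise_tau_days: float = 0.5
    h2_fall_offset_days: float = 4.5  # days after t_mid
    h2_fall_rate: float = 1.2  # 1/day
    ch4_per_acetate: float = 1.0  # molar CH4 yield
    noise_rel_sd: float = 0.05
    seed: int = 0
    pH: float = 7.0
    vial: VialSpec = field(default_factory=VialSpec)

    def __post_init__(self) -> None:
        if self.condition not in STUDY_CONDITIONS:
            raise ValueError(
                f"unknown condition {self.condition!r}; expected one of "
                f"{sorted(STUDY_CONDITIONS)}"
            )
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        if self.noise_rel_sd < 0.0:
            raise ValueError("noise_rel_sd must be >= 0")
        if not 0.0 < self.ch4_per_acetate <= 1.0:
            raise ValueError(
                "ch4_per_acetate must be in (0, 1]: more than one CH4 per "
                "acetate would be super-stoichiometric"
            )
        if self.initial_acetate <= 0.0:
            raise ValueError("initial_acetate must be > 0")
        if self.duration_days <= 0.0 or self.sampling_interval_days <= 0.0:
            raise ValueError("duration and sampling interval must be > 0")

    @property
    def condition_spec(self) -> ConditionSpec:
        return STUDY_CONDITIONS[self.condition]

    @property
    def resolved_t_mid(self) -> float:
        return (
            self.t_mid_days
            if self.t_mid_days is not None
            else self.condition_spec.t_mid_days
        )

    @property
    def resolved_h2_plateau(self) -> float:
        return (
            self.h2_plateau_pa
            if self.h2_plateau_pa is not None
            else self.condition_spec.h2_plateau_pa
        )

    @property
    def medium(self) -> MediumSpec:
        spec = self.condition_spec
        return MediumSpec(
            bicarbonate_added=spec.bicarbonate_added,
            co2_headspace_fraction=spec.co2_headspace_fraction,
            pH=self.pH,
        )


@dataclass(frozen=True)
class TimeCourse:
    """Replicate-structured series of culture states for one condition."""

    condition: str
    replicate: int
    states: tuple[CultureState, ...]
    truth: "TimeCourse | None" = None  # noise-free twin (replicate -1)

    def __post_init__(self) -> None:
        days = [s.day for s in self.states]
        if any(d is None for d in days) or any(
            b <= a for a, b in zip(days, days[1:])
        ):
            raise ValueError("states must carry strictly increasing days")

    @property
    def days(self) -> tuple[float, ...]:
        return tuple(s.day for s in self.states)

    def to_frame(self) -> pd.DataFrame:
        """Tidy frame in interchange units (mM, atm, Pa)."""
        return pd.DataFrame(
            {
                "condition": self.condition,
                "replicate": self.replicate,
                "day": [s.day for s in self.states],
                "acetate_mM": [s.acetate * 1e3 for s in self.states],
                "pCH4_atm": [s.p_ch4 for s in self.states],
                "pH2_Pa": [s.p_h2 * ATM_PA for s in self.states],
                "HCO3_mM": [s.bicarbonate * 1e3 for s in self.states],
                "pH": [s.pH for s in self.states],
            }
        )


def _consumed_fraction(t: np.ndarray, t_mid: float, rate: float) -> np.ndarray:
    """Clamped logistic consumption fraction: 0 at t=0, -> 1 late."""
    raw = 1.0 / (1.0 + np.exp(-rate * (t - t_mid)))
    raw0 = 1.0 / (1.0 + math.exp(rate * t_mid))
    return (raw - raw0) / (1.0 - raw0)


def _h2_profile(t: np.ndarray, config: GeneratorConfig) -> np.ndarray:
    """Rise to the plateau, quasi-steady through log phase, then decay."""
    plateau = config.resolved_h2_plateau
    rise = 1.0 - np.exp(-t / config.h2_rise_tau_days)
    t_fall = config.resolved_t_mid + config.h2_fall_offset_days
    fall = 1.0 / (1.0 + np.exp(config.h2_fall_rate * (t - t_fall)))
    return plateau * rise * fall


def _truth_states(config: GeneratorConfig) -> tuple[CultureState, ...]:
    vial = config.vial
    medium = config.medium
    n_steps = int(round(config.duration_days / config.sampling_interval_days))
    t = np.arange(n_steps + 1) * config.sampling_interval_days
    f = _consumed_fraction(t, config.resolved_t_mid, config.consumption_rate)

    consumed = config.initial_acetate * f  # mol/L of medium
    acetate = config.initial_acetate - consumed
    ch4_mol = consumed * config.ch4_per_acetate * vial.liquid_volume
    p_ch4 = ch4_mol * R_L_ATM * vial.temperature / vial.headspace_volume
    # Acetate carries 2 C; whatever does not leave as CH4 joins the
    # inorganic pool (1 C per acetate at the default 1:1 CH4 yield).
    inorganic_c = (2.0 - config.ch4_per_acetate) * consumed * vial.liquid_volume
    hco3 = np.empty_like(t, dtype=float)
    for i, extra in enumerate(inorganic_c):
        hco3[i] = speciate_closed_vial(vial, medium, extra).bicarbonate
    p_h2_pa = _h2_profile(t, config)

    return tuple(
        CultureState(
            temperature=vial.temperature,
            pH=config.pH,
            acetate=float(acetate[i]),
            bicarbonate=float(hco3[i]),
            p_ch4=float(p_ch4[i]),
            p_h2=float(p_h2_pa[i]) / ATM_PA,
            day=float(t[i]),
        )
        for i in range(len(t))
    )


def generate_timecourse(config: GeneratorConfig) -> list[TimeCourse]:
    """Simulate one condition: n_replicates noisy series plus their twin.

    Noise is independent multiplicative lognormal (sigma =
    ``noise_rel_sd`` on the log scale) on acetate, CH4, H2 and
    bicarbonate; pH is carried through unperturbed.  The same seed gives
    bit-identical output.
    """
    truth_states = _truth_states(config)
    truth = TimeCourse(config.condition, -1, truth_states)
    rng = np.random.default_rng(config.seed)
    out: list[TimeCourse] = []
    for rep in range(1, config.n_replicates + 1):
        noisy = []
        for s in truth_states:
            factors = rng.lognormal(0.0, config.noise_rel_sd, size=4)
            if config.noise_rel_sd == 0.0:
                factors = np.ones(4)
            noisy.append(
                replace(
                    s,
                    acetate=s.acetate * factors[0],
                    p_ch4=s.p_ch4 * factors[1],
                    p_h2=s.p_h2 * factors[2],
                    bicarbonate=s.bicarbonate * factors[3],
                )
            )
        out.append(TimeCourse(config.condition, rep, tuple(noisy), truth=truth))
    return out


def generate_study(
    seed: int = 0, **overrides
) -> dict[str, list[TimeCourse]]:
    """Simulate all three conditions with per-condition seeds.

    ``overrides`` are applied to every condition's
    :class:`GeneratorConfig`.  Condition seeds are derived from ``seed``
    deterministically.
    """
    study: dict[str, list[TimeCourse]] = {}
    for i, label in enumerate(STUDY_CONDITIONS):
        config = GeneratorConfig(
            condition=label, seed=seed * 8 + i + 1, **overrides
        )
        study[label] = generate_timecourse(config)
    return study


def generate_abundances(
    config: GeneratorConfig | None = None,
    suppression: Mapping[str, Mapping[str, float]] | None = None,
    *,
    base_copies: Mapping[str, float] | None = None,
    noise_sigma: float = 0.15,
    seed: int | None = None,
    conditions: Sequence[str] = tuple(STUDY_CONDITIONS),
    n_replicates: int | None = None,
) -> pd.DataFrame:
    """Simulate mid-exponential 16S rRNA copy-number tables.

    ``suppression`` maps organism -> condition -> multiplicative factor
    on the expected copy number relative to the first (reference)
    condition; omitted entries default to 1.  Replicates draw lognormal
    noise (sigma on the log scale, default 0.15 -- typical qRT-PCR
    replicate scatter).  Returns a tidy frame with columns organism,
    condition, replicate, copies.
    """
    config = config or GeneratorConfig()
    if suppression is not None:
        for organism, factors in suppression.items():
            for cond, f in factors.items():
                if f <= 0.0:
                    raise ValueError(
                        f"suppression factor for {organism}/{cond} must be > 0"
                    )
    suppression = suppression or {}
    base = dict(base_copies or {o: 1e8 for o in ORGANISMS})
    n_rep = n_replicates if n_replicates is not None else config.n_replicates
    rng = np.random.default_rng(seed if seed is not None else config.seed)
    rows = []
    for organism, base_n in base.items():
        factors = suppression.get(organism, {})
        for cond in conditions:
            expected = base_n * factors.get(cond, 1.0)
            for rep in range(1, n_rep + 1):
                copies = expected * rng.lognormal(0.0, noise_sigma)
                rows.append(
                    {
                        "organism": organism,
                        "condition": cond,
                        "replicate": rep,
                        "copies": copies,
                    }
                )
    return pd.DataFrame(rows)
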