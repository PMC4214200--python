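"""Pipeline stages turning time-course tables into the result surface.

Given replicate-structured metabolite time courses, these functions
produce per-day, per-reaction free-energy series with replicate
mean/SD and feasibility flags, log-phase (day 2-5) summaries, H2
counterfactuals, windowed methanogenic rates, normalized rates, and
normalized 16S abundances.  Replicate scatter uses the sample SD (n-1);
a replicate-day lacking a required analyte (e.g. H2 below detection at
day 0) is dropped from that day's statistics and logged, never imputed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .carbonate import VialSpec
from .synthetic import TimeCourse
from .thermo import (
    FEASIBILITY_THRESHOLD,
    REACTIONS,
    ActivityError,
    Reaction,
    ReactionMisuseError,
    delta_g,
    shift_h2,
)
from .units import ATM_PA, R_L_ATM

__all__ = [
    "DeltaGSeries",
    "LogPhaseSummary",
    "CounterfactualReport",
    "compute_dg_series",
    "logphase_summary",
    "counterfactual_report",
    "methanogenic_rate",
    "relative_rate",
    "normalize_abundance",
    "stoichiometry_check",
]

LOG_PHASE_WINDOW = (2.0, 5.0)


def _sample_sd(values) -> float:
    """Sample SD (ddof=1); exactly 0 for identical values or n < 2."""
    arr = np.asarray(values, dtype=float)
    if len(arr) < 2 or arr.max() == arr.min():
        return 0.0
    return float(arr.std(ddof=1))


@dataclass
class DeltaGSeries:
    """Per-day, per-replicate dG values for one condition and reaction.

    ``values`` is tidy (day, replicate, delta_g, feasible);
    ``errors`` records (replicate, day, message) for dropped records.
    """

    condition: str
    reaction: str
    values: pd.DataFrame
    threshold: float = FEASIBILITY_THRESHOLD
    errors: list[tuple[int, float, str]] = field(default_factory=list)

    def per_day(self) -> pd.DataFrame:
        """Replicate mean, sample SD (ddof=1), n and feasibility per day."""
        g = self.values.groupby("day")["delta_g"]
        out = g.agg(mean="mean", sd=_sample_sd, n="count")
        out["feasible"] = out["mean"] <= self.threshold
        return out.reset_index()


@dataclass(frozen=True)
class LogPhaseSummary:
    """Pooled mean/SD of a dG series over the log-phase window."""

    condition: str
    reaction: str
    window: tuple[float, float]
    mean: float
    sd: float
    n: int
    exceeds_threshold: bool
    threshold: float = FEASIBILITY_THRESHOLD


@dataclass(frozen=True)
class CounterfactualReport:
    """Replicate dG before/after imposing a counterfactual H2 pressure."""

    condition: str
    reaction: str
    day: float
    p_h2_to: float  # Pa
    before: pd.DataFrame  # replicate, p_h2_pa, delta_g
    before_mean: float
    before_sd: float
    after_mean: float
    after_sd: float


def compute_dg_series(
    timecourses: Iterable[TimeCourse],
    reactions: Sequence[Reaction] | None = None,
    threshold: float = FEASIBILITY_THRESHOLD,
    temperature_correction: bool = False,
) -> list[DeltaGSeries]:
    """Evaluate dG per replicate per day for each condition and reaction.

    Records whose activities make ln Q undefined (zero acetate, CH4 or
    H2 -- typically the day-0 sample) are collected into the series'
    error log and excluded from that day's statistics.
    """
    reactions = list(reactions) if reactions is not None else list(REACTIONS.values())
    rows: dict[tuple[str, str], list[dict]] = {}
    errors: dict[tuple[str, str], list[tuple[int, float, str]]] = {}
    for tc in timecourses:
        for rxn in reactions:
            key = (tc.condition, rxn.name)
            rows.setdefault(key, [])
            errors.setdefault(key, [])
            for state in tc.states:
                try:
                    dg = delta_g(
                        rxn,
                        state,
                        threshold=threshold,
                        temperature_correction=temperature_correction,
                    )
                except ActivityError as exc:
                    errors[key].append((tc.replicate, state.day, str(exc)))
                    continue
                rows[key].append(
                    {
                        "day": state.day,
                        "replicate": tc.replicate,
                        "delta_g": dg.value,
                        "feasible": dg.feasible,
                    }
                )
    out = []
    for (condition, rxn_name), recs in rows.items():
        frame = (
            pd.DataFrame(recs)
            .sort_values(["day", "replicate"])
            .reset_index(drop=True)
            if recs
            else pd.DataFrame(columns=["day", "replicate", "delta_g", "feasible"])
        )
        out.append(
            DeltaGSeries(
                condition=condition,
                reaction=rxn_name,
                values=frame,
                threshold=threshold,
                errors=errors[(condition, rxn_name)],
            )
        )
    return out


def logphase_summary(
    series: DeltaGSeries,
    window: tuple[float, float] = LOG_PHASE_WINDOW,
) -> LogPhaseSummary:
    """Pool all replicate-day values with day in the closed window."""
    lo, hi = window
    if lo > hi:
        raise ValueError(f"window start {lo} exceeds end {hi}")
    sel = series.values[(series.values["day"] >= lo) & (series.values["day"] <= hi)]
    if sel.empty:
        raise ValueError(
            f"window [{lo}, {hi}] contains no sampled days for "
            f"{series.condition}/{series.reaction}"
        )
    vals = sel["delta_g"].to_numpy(dtype=float)
    mean = float(np.mean(vals))
    sd = _sample_sd(vals)
    return LogPhaseSummary(
        condition=series.condition,
        reaction=series.reaction,
        window=(lo, hi),
        mean=mean,
        sd=sd,
        n=len(vals),
        exceeds_threshold=mean > series.threshold,
        threshold=series.threshold,
    )


def counterfactual_report(
    timecourses: Iterable[TimeCourse],
    reaction: Reaction,
    day: float,
    p_h2_to: float,
    threshold: float = FEASIBILITY_THRESHOLD,
) -> CounterfactualReport:
    """Shift each replicate's dG at ``day`` to a counterfactual H2 (Pa).

    Uses each replicate's own measured H2 as the starting pressure, the
    additive nu_H2*R*T*ln(p'/p) adjustment of :func:`syntherm.thermo.shift_h2`.
    """
    if reaction.h2_coefficient() == 0:
        raise ReactionMisuseError(
            f"reaction {reaction.name!r} has no H2 term; no counterfactual"
        )
    tcs = list(timecourses)
    if not tcs:
        raise ValueError("no timecourses supplied")
    condition = tcs[0].condition
    rows = []
    for tc in tcs:
        state = next((s for s in tc.states if s.day == day), None)
        if state is None:
            raise ValueError(f"day {day} not sampled in replicate {tc.replicate}")
        dg = delta_g(reaction, state, threshold=threshold)
        p_from_pa = state.p_h2 * ATM_PA
        shifted = shift_h2(
            dg.value, reaction, p_from_pa, p_h2_to, state.temperature
        )
        rows.append(
            {
                "replicate": tc.replicate,
                "p_h2_pa": p_from_pa,
                "delta_g": dg.value,
                "delta_g_shifted": shifted,
            }
        )
    before = pd.DataFrame(rows)

    def _sd(col: str) -> float:
        return _sample_sd(before[col])

    return CounterfactualReport(
        condition=condition,
        reaction=reaction.name,
        day=day,
        p_h2_to=p_h2_to,
        before=before,
        before_mean=float(before["delta_g"].mean()),
        before_sd=_sd("delta_g"),
        after_mean=float(before["delta_g_shifted"].mean()),
        after_sd=_sd("delta_g_shifted"),
    )


def _cumulative_ch4_per_liter(tc: TimeCourse, vial: VialSpec) -> np.ndarray:
    """Headspace CH4 converted to mol per liter of medium."""
    p = np.array([s.p_ch4 for s in tc.states])
    mol = p * vial.headspace_volume / (R_L_ATM * vial.temperature)
    return mol / vial.liquid_volume


def methanogenic_rate(tc: TimeCourse, vial: VialSpec | None = None) -> float:
    """Peak methanogenic rate, mol CH4 per liter of medium per day.

    Least-squares slope over the steepest contiguous 3-point window of
    cumulative CH4 -- a windowed estimate robust at the few time points
    of a batch experiment.
    """
    vial = vial or VialSpec()
    if len(tc.states) < 3:
        raise ValueError("methanogenic_rate needs at least 3 time points")
    days = np.array(tc.days)
    ch4 = _cumulative_ch4_per_liter(tc, vial)
    best = -np.inf
    for i in range(len(days) - 2):
        slope = np.polyfit(days[i : i + 3], ch4[i : i + 3], 1)[0]
        best = max(best, float(slope))
    return best


def relative_rate(
    rates: Mapping[str, Sequence[float]], reference: str
) -> dict[str, float]:
    """Mean rate per condition normalized to the reference condition."""
    if reference not in rates:
        raise ValueError(f"reference condition {reference!r} absent from rates")
    ref_mean = float(np.mean(rates[reference]))
    if ref_mean == 0.0:
        raise ZeroDivisionError("reference condition has zero mean rate")
    return {cond: float(np.mean(r)) / ref_mean for cond, r in rates.items()}


def normalize_abundance(
    copy_numbers: pd.DataFrame, reference: str
) -> pd.DataFrame:
    """Normalize 16S copy numbers per organism to a reference condition.

    Expects a tidy frame (organism, condition, replicate, copies).
    Returns per organism x condition the ratio of replicate means to the
    reference-condition mean, with the SD propagated by the first-order
    (ratio-of-means) delta method:
    SD(x/y) ~ (mx/my) * sqrt(SEM_x^2/mx^2 + SEM_y^2/my^2).
    """
    required = {"organism", "condition", "replicate", "copies"}
    missing = required - set(copy_numbers.columns)
    if missing:
        raise ValueError(f"copy-number table lacks columns: {sorted(missing)}")
    stats = (
        copy_numbers.groupby(["organism", "condition"])["copies"]
        .agg(mean="mean", sd=_sample_sd, n="count")
        .reset_index()
    )
    rows = []
    for organism, sub in stats.groupby("organism"):
        ref = sub[sub["condition"] == reference]
        if ref.empty:
            raise ValueError(
                f"reference condition {reference!r} absent for {organism!r}"
            )
        m_ref = float(ref["mean"].iloc[0])
        if m_ref == 0.0:
            raise ZeroDivisionError(
                f"reference mean copy number is zero for {organism!r}"
            )
        sem_ref2 = (float(ref["sd"].iloc[0]) ** 2) / float(ref["n"].iloc[0])
        for _, row in sub.iterrows():
            m = float(row["mean"])
            sem2 = (float(row["sd"]) ** 2) / float(row["n"])
            ratio = m / m_ref
            if row["condition"] == reference:
                sd = 0.0
            else:
                sd = abs(ratio) * np.sqrt(
                    sem2 / m**2 + sem_ref2 / m_ref**2
                ) if m != 0.0 else np.sqrt(sem2) / m_ref
            rows.append(
                {
                    "organism": organism,
                    "condition": row["condition"],
                    "relative_abundance": ratio,
                    "sd": float(sd),
                }
            )
    return pd.DataFrame(rows)


def stoichiometry_check(tc: TimeCourse, vial: VialSpec | None = None) -> float:
    """Mol CH4 produced per mol acetate consumed over the whole run."""
    vial = vial or VialSpec()
    if len(tc.states) < 2:
        raise ValueError("need initial and final samples")
    first, last = tc.states[0], tc.states[-1]
    consumed_mol = (first.acetate - last.acetate) * vial.liquid_volume
    if consumed_mol <= 0.0:
        raise ValueError("no acetate was consumed; ratio undefined")
    rt = R_L_ATM * vial.temperature
    ch4_mol = (last.p_ch4 - first.p_ch4) * vial.headspace_volume / rt
    return ch4_mol / consumed_mol
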