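"""Table I/O, run configuration and the end-to-end pipeline.

The single interchange format is tidy long CSV: one row per
condition x replicate x day with columns condition, replicate, day,
acetate_mM, pCH4_atm (or pCH4_Pa), pH2_Pa, HCO3_mM, pH.  Gas quantities
are stored in the units instruments report (CH4 in atm or Pa, trace H2
in Pa) and converted to atm internally.  Output files carry ``#`` header
comments naming units and the hash of the resolved configuration, so a
result file is always traceable to the exact parameters that made it.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path
from typing import Iterable

import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict, Field

from .analysis import (
    compute_dg_series,
    counterfactual_report,
    logphase_summary,
    methanogenic_rate,
    normalize_abundance,
    relative_rate,
    stoichiometry_check,
)
from .carbonate import MediumSpec, VialSpec, speciate_closed_vial
from .synthetic import (
    STUDY_CONDITIONS,
    GeneratorConfig,
    TimeCourse,
    generate_abundances,
    generate_study,
)
from .thermo import ACETATE_OXIDATION, FEASIBILITY_THRESHOLD, CultureState
from .units import ATM_PA

__all__ = [
    "SchemaError",
    "RunConfig",
    "read_timecourse_csv",
    "write_timecourse_csv",
    "run_pipeline",
]

logger = logging.getLogger("syntherm")

REQUIRED_COLUMNS = (
    "condition",
    "replicate",
    "day",
    "acetate_mM",
    "pH2_Pa",
    "HCO3_mM",
    "pH",
)
CH4_COLUMNS = ("pCH4_atm", "pCH4_Pa")


class SchemaError(ValueError):
    """A table does not match the tidy time-course schema."""


class AnalysisOptions(BaseModel):
    model_config = ConfigDict(extra="forbid")
    window: tuple[float, float] = (2.0, 5.0)
    threshold: float = FEASIBILITY_THRESHOLD
    reference_condition: str = "5.0"
    counterfactual_day: float = 5.0
    counterfactual_h2_pa: float = 10.0


class GeneratorOptions(BaseModel):
    model_config = ConfigDict(extra="forbid")
    initial_acetate: float = 0.040
    duration_days: float = 15.0
    sampling_interval_days: float = 1.0
    n_replicates: int = 3
    noise_rel_sd: float = 0.05


class VialOptions(BaseModel):
    model_config = ConfigDict(extra="forbid")
    total_volume: float = 0.068
    liquid_volume: float = 0.020
    temperature: float = 328.15

    def to_spec(self) -> VialSpec:
        return VialSpec(self.total_volume, self.liquid_volume, self.temperature)


class RunConfig(BaseModel):
    """Validated configuration of a full pipeline run.

    Unknown keys are rejected; the resolved config is echoed to the
    output directory as YAML alongside its hash.
    """

    model_config = ConfigDict(extra="forbid")
    seed: int = 0
    out_dir: Path = Path("syntherm_out")
    vial: VialOptions = Field(default_factory=VialOptions)
    generator: GeneratorOptions = Field(default_factory=GeneratorOptions)
    analysis: AnalysisOptions = Field(default_factory=AnalysisOptions)
    skip_simulate: bool = False
    quiet: bool = False

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.model_validate(raw)

    def resolved(self) -> dict:
        return json.loads(self.model_dump_json())

    def config_hash(self) -> str:
        """Hash of the scientific parameters (runtime plumbing excluded)."""
        resolved = self.resolved()
        for key in ("out_dir", "quiet", "skip_simulate"):
            resolved.pop(key, None)
        blob = json.dumps(resolved, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


def _header_comment(units: dict[str, str], config_hash: str | None) -> str:
    lines = [f"# units: {json.dumps(units)}"]
    if config_hash:
        lines.append(f"# config_hash: {config_hash}")
    return "\n".join(lines) + "\n"


def _write_csv(
    df: pd.DataFrame,
    path: Path,
    units: dict[str, str],
    config_hash: str | None = None,
) -> None:
    with open(path, "w") as fh:
        fh.write(_header_comment(units, config_hash))
        df.to_csv(fh, index=False)


def write_timecourse_csv(
    timecourses: Iterable[TimeCourse],
    path: str | Path,
    config_hash: str | None = None,
) -> None:
    """Write time courses as tidy CSV with a unit-naming header comment."""
    df = pd.concat([tc.to_frame() for tc in timecourses], ignore_index=True)
    units = {
        "day": "days",
        "acetate_mM": "mmol/L",
        "pCH4_atm": "atm",
        "pH2_Pa": "Pa",
        "HCO3_mM": "mmol/L",
        "pH": "-",
    }
    _write_csv(df, Path(path), units, config_hash)


def _detect_delimiter(path: Path) -> str:
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            return "\t" if "\t" in line else ","
    raise SchemaError(f"{path}: no data rows found")


def read_timecourse_csv(path: str | Path) -> list[TimeCourse]:
    """Read a tidy time-course CSV/TSV into typed records.

    Delimiter is autodetected; ``#`` lines are comments.  CH4 may be
    given as ``pCH4_atm`` or ``pCH4_Pa``; H2 is expected in Pa.  A
    missing column raises :class:`SchemaError` naming it; an
    unparseable cell raises with its line number.
    """
    path = Path(path)
    sep = _detect_delimiter(path)
    df = pd.read_csv(path, sep=sep, comment="#", skip_blank_lines=True)
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if not any(c in df.columns for c in CH4_COLUMNS):
        missing.append("pCH4_atm|pCH4_Pa")
    if missing:
        raise SchemaError(
            f"{path}: missing required column(s) {missing}; expected header "
            f"{list(REQUIRED_COLUMNS) + ['pCH4_atm or pCH4_Pa']}"
        )

    numeric = ["replicate", "day", "acetate_mM", "pH2_Pa", "HCO3_mM", "pH"] + [
        c for c in CH4_COLUMNS if c in df.columns
    ]
    problems = []
    for col in numeric:
        coerced = pd.to_numeric(df[col], errors="coerce")
        for idx in df.index[coerced.isna() & df[col].notna()]:
            # +2: header line and 1-based numbering (comments shift this
            # for files with leading comment lines).
            problems.append(f"line {idx + 2}: cell {col}={df.at[idx, col]!r}")
        df[col] = coerced
    if problems:
        raise SchemaError(f"{path}: unparseable cells: {'; '.join(problems)}")

    out: list[TimeCourse] = []
    for (cond, rep), sub in df.groupby(["condition", "replicate"], sort=True):
        sub = sub.sort_values("day")
        states = []
        for _, row in sub.iterrows():
            p_ch4 = (
                float(row["pCH4_atm"])
                if "pCH4_atm" in sub.columns
                else float(row["pCH4_Pa"]) / ATM_PA
            )
            states.append(
                CultureState(
                    temperature=328.15,
                    pH=float(row["pH"]),
                    acetate=float(row["acetate_mM"]) / 1e3,
                    bicarbonate=float(row["HCO3_mM"]) / 1e3,
                    p_ch4=p_ch4,
                    p_h2=float(row["pH2_Pa"]) / ATM_PA,
                    day=float(row["day"]),
                )
            )
        out.append(TimeCourse(str(cond), int(rep), tuple(states)))
    return out


def speciation_table(vial: VialSpec, pH: float = 7.0) -> pd.DataFrame:
    """Initial-medium speciation of the three study conditions."""
    rows = []
    for label, spec in STUDY_CONDITIONS.items():
        medium = MediumSpec(
            bicarbonate_added=spec.bicarbonate_added,
            co2_headspace_fraction=spec.co2_headspace_fraction,
            pH=pH,
        )
        res = speciate_closed_vial(vial, medium)
        rows.append(
            {
                "condition": label,
                "co2_aq_mM": res.co2_aq * 1e3,
                "HCO3_mM": res.bicarbonate * 1e3,
                "co2_gas_mmol": res.co2_gas_amount * 1e3,
                "p_co2_atm": res.p_co2,
                "total_inorganic_carbon_mM": res.total_inorganic_carbon,
            }
        )
    return pd.DataFrame(rows)


def run_pipeline(config: RunConfig) -> dict[str, Path]:
    """Simulate (optionally) -> speciate -> analyze; write all artifacts.

    Returns a manifest mapping artifact names to paths; the same config
    and seed give byte-identical numeric outputs.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    chash = config.config_hash()
    vial = config.vial.to_spec()
    manifest: dict[str, Path] = {}

    level = logging.WARNING if config.quiet else logging.INFO
    logging.basicConfig(level=level)

    tc_path = out / "timecourses.csv"
    if config.skip_simulate:
        if not tc_path.exists():
            raise FileNotFoundError(
                f"--skip-simulate requires an existing {tc_path}"
            )
        logger.info("simulate: skipped, reading %s", tc_path)
        study_flat = read_timecourse_csv(tc_path)
        truth_flat: list[TimeCourse] = []
    else:
        logger.info("simulate: three conditions, seed=%d", config.seed)
        study = generate_study(
            seed=config.seed,
            vial=vial,
            **config.generator.model_dump(),
        )
        study_flat = [tc for tcs in study.values() for tc in tcs]
        truth_flat = [tcs[0].truth for tcs in study.values()]
        write_timecourse_csv(study_flat, tc_path, chash)
        write_timecourse_csv(truth_flat, out / "timecourses_truth.csv", chash)
        manifest["timecourses_truth"] = out / "timecourses_truth.csv"
        # analyze what was written: the CSV is the single interchange
        # format, so fresh and --skip-simulate runs see identical data
        study_flat = read_timecourse_csv(tc_path)
    manifest["timecourses"] = tc_path

    logger.info("speciate: initial media")
    _write_csv(
        speciation_table(vial),
        out / "speciation.csv",
        {"co2_aq_mM": "mmol/L", "HCO3_mM": "mmol/L", "co2_gas_mmol": "mmol",
         "p_co2_atm": "atm", "total_inorganic_carbon_mM": "mmol/L medium"},
        chash,
    )
    manifest["speciation"] = out / "speciation.csv"

    logger.info("analyze: delta-G series and summaries")
    opts = config.analysis
    series = compute_dg_series(study_flat, threshold=opts.threshold)
    per_day = []
    summaries = []
    for s in series:
        day_stats = s.per_day()
        day_stats.insert(0, "reaction", s.reaction)
        day_stats.insert(0, "condition", s.condition)
        per_day.append(day_stats)
        summaries.append(logphase_summary(s, window=opts.window))
    _write_csv(
        pd.concat(per_day, ignore_index=True),
        out / "deltag_series.csv",
        {"mean": "kJ/mol", "sd": "kJ/mol", "day": "days"},
        chash,
    )
    manifest["deltag_series"] = out / "deltag_series.csv"

    _write_csv(
        pd.DataFrame(
            [
                {
                    "condition": s.condition,
                    "reaction": s.reaction,
                    "day_start": s.window[0],
                    "day_end": s.window[1],
                    "mean": s.mean,
                    "sd": s.sd,
                    "n": s.n,
                    "exceeds_threshold": s.exceeds_threshold,
                }
                for s in summaries
            ]
        ),
        out / "logphase_summary.csv",
        {"mean": "kJ/mol", "sd": "kJ/mol", "day_start": "days"},
        chash,
    )
    manifest["logphase_summary"] = out / "logphase_summary.csv"

    cf_rows = []
    by_condition: dict[str, list[TimeCourse]] = {}
    for tc in study_flat:
        by_condition.setdefault(tc.condition, []).append(tc)
    for cond, tcs in by_condition.items():
        rep = counterfactual_report(
            tcs,
            ACETATE_OXIDATION,
            day=opts.counterfactual_day,
            p_h2_to=opts.counterfactual_h2_pa,
            threshold=opts.threshold,
        )
        cf_rows.append(
            {
                "condition": cond,
                "reaction": rep.reaction,
                "day": rep.day,
                "p_h2_to_Pa": rep.p_h2_to,
                "before_mean": rep.before_mean,
                "before_sd": rep.before_sd,
                "after_mean": rep.after_mean,
                "after_sd": rep.after_sd,
            }
        )
    _write_csv(
        pd.DataFrame(cf_rows),
        out / "counterfactual.csv",
        {"before_mean": "kJ/mol", "after_mean": "kJ/mol", "p_h2_to_Pa": "Pa"},
        chash,
    )
    manifest["counterfactual"] = out / "counterfactual.csv"

    rates = {
        cond: [methanogenic_rate(tc, vial) for tc in tcs]
        for cond, tcs in by_condition.items()
    }
    rel = relative_rate(rates, opts.reference_condition)
    _write_csv(
        pd.DataFrame(
            [
                {
                    "condition": cond,
                    "mean_rate_mol_per_L_day": float(pd.Series(r).mean()),
                    "relative_rate": rel[cond],
                }
                for cond, r in rates.items()
            ]
        ),
        out / "rates.csv",
        {"mean_rate_mol_per_L_day": "mol CH4 / L medium / day"},
        chash,
    )
    manifest["rates"] = out / "rates.csv"

    # Abundance table: syntrophs suppressed at elevated CO2, the
    # aceticlastic methanogen unaffected (demo ground truth).
    suppression = {
        "Thermacetogenium_phaeum": {"50.7": 0.6, "113.4": 0.4},
        "Methanothermobacter_thermautotrophicus": {"50.7": 0.6, "113.4": 0.4},
    }
    abund = generate_abundances(
        GeneratorConfig(seed=config.seed + 1), suppression
    )
    rel_abund = normalize_abundance(abund, opts.reference_condition)
    _write_csv(
        rel_abund,
        out / "abundance_relative.csv",
        {"relative_abundance": "fold vs reference", "sd": "fold"},
        chash,
    )
    manifest["abundance_relative"] = out / "abundance_relative.csv"

    if not config.skip_simulate:
        truth_by_cond = {tc.condition: tc for tc in truth_flat}
        stoich = {
            cond: stoichiometry_check(tc, vial)
            for cond, tc in truth_by_cond.items()
        }
        _write_csv(
            pd.DataFrame(
                [{"condition": c, "ch4_per_acetate": v} for c, v in stoich.items()]
            ),
            out / "stoichiometry.csv",
            {"ch4_per_acetate": "mol/mol"},
            chash,
        )
        manifest["stoichiometry"] = out / "stoichiometry.csv"

    with open(out / "config_resolved.yaml", "w") as fh:
        yaml.safe_dump({"config_hash": chash, **config.resolved()}, fh)
    manifest["config"] = out / "config_resolved.yaml"

    with open(out / "manifest.json", "w") as fh:
        json.dump({k: str(v) for k, v in manifest.items()}, fh, indent=2)
    manifest["manifest"] = out / "manifest.json"
    logger.info("pipeline complete: %d artifacts in %s", len(manifest), out)
    return manifest
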