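"""Orchestration: simulate/load -> fit -> invert -> Arrhenius -> table.

`run_pipeline` drives the full analysis for one or more emulsion
conditions.  Per temperature it extracts two-component T1 and T2 fits
(or takes pre-fitted components from a table), assigns the short
components to the oil phase and the long ones to the water phase,
converts each phase's T1/T2 pair to a rotational correlation time —
by default through the K-free R2/R1 ratio — and finally regresses
ln tau_c on 1/T per phase to obtain activation energies, reported in a
long-format table with "value +/- SE" rendering.

Diagnostics record clamped ratios, non-convergent fits and regression
R^2 per condition so noisy runs remain inspectable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .arrhenius import ArrheniusModel, ArrheniusResults, activation_energy_table
from .bpp import BPPContext, CorrelationTime, clamp_ratio, tau_c_from_ratio, tau_c_from_r1
from .constants import celsius_to_kelvin
from .relaxation import (
    RelaxationComponent,
    assign_phases,
    fit_cpmg,
    fit_inversion_recovery,
)
from .simulate import EmulsionDataset, generate_dataset, load_dataset, paper_like_spec

__all__ = [
    "TemperatureSeriesRecord",
    "PipelineConfig",
    "PipelineResult",
    "PipelineError",
    "ConfigError",
    "run_pipeline",
    "analyze_dataset",
    "fit_dataset_components",
    "records_to_frame",
    "read_component_table",
    "write_component_table",
    "read_activation_table",
    "write_activation_table",
    "load_reference_activation_table",
]


class PipelineError(RuntimeError):
    """A stage failure, annotated with condition/temperature context."""


class ConfigError(ValueError):
    """An invalid pipeline configuration."""


@dataclass(frozen=True)
class TemperatureSeriesRecord:
    """Fitted components for one condition at one temperature.

    Holds exactly four components: oil and water T1 (T11, T12) and oil
    and water T2 (T21, T22), with oil shorter than water for both.
    """

    starch: str
    concentration_g_per_g: float
    fat: str
    temperature_c: float
    components: tuple[RelaxationComponent, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "components", tuple(self.components))
        t1 = [c for c in self.components if c.which == "T1"]
        t2 = [c for c in self.components if c.which == "T2"]
        if len(t1) != 2 or len(t2) != 2:
            raise ValueError(
                f"need exactly two T1 and two T2 components, got {len(t1)} and {len(t2)}"
            )
        for pair in (t1, t2):
            oil = [c for c in pair if c.phase == "oil"]
            water = [c for c in pair if c.phase == "water"]
            if len(oil) != 1 or len(water) != 1:
                raise ValueError("each of T1/T2 needs one oil and one water component")
            if not oil[0].time_constant < water[0].time_constant:
                raise ValueError(
                    "oil component must be shorter than the water component "
                    f"({pair[0].which}: oil {oil[0].time_constant}, water {water[0].time_constant})"
                )

    def component(self, which: str, phase: str) -> RelaxationComponent:
        for c in self.components:
            if c.which == which and c.phase == phase:
                return c
        raise KeyError((which, phase))

    @property
    def condition(self) -> tuple:
        return (self.starch, self.concentration_g_per_g, self.fat)


# ---------------------------------------------------------------------------
# tabular I/O

_COMPONENT_COLUMNS = [
    "starch", "concentration_g_per_g", "fat", "temperature_c",
    "which", "phase", "time_constant_s", "fraction",
]


def records_to_frame(records: list[TemperatureSeriesRecord]) -> pd.DataFrame:
    rows = []
    for rec in records:
        for c in rec.components:
            rows.append(
                {
                    "starch": rec.starch,
                    "concentration_g_per_g": rec.concentration_g_per_g,
                    "fat": rec.fat,
                    "temperature_c": rec.temperature_c,
                    "which": c.which,
                    "phase": c.phase,
                    "time_constant_s": c.time_constant,
                    "fraction": c.fraction,
                }
            )
    return pd.DataFrame(rows, columns=_COMPONENT_COLUMNS)


def write_component_table(records: list[TemperatureSeriesRecord], path) -> None:
    records_to_frame(records).to_csv(path, index=False)


def _check_columns(df: pd.DataFrame, required: list[str], what: str) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{what} is missing column(s): {missing}")


def read_component_table(path) -> list[TemperatureSeriesRecord]:
    """Read a long-format component table CSV into records.

    Schema: starch, concentration_g_per_g, fat, temperature_c, which
    (T1|T2), phase (oil|water), time_constant_s, fraction — four rows
    per (condition, temperature).  Validation raises naming the
    offending column or key.
    """
    df = pd.read_csv(path)
    _check_columns(df, _COMPONENT_COLUMNS, f"component table {path}")
    for col in ("concentration_g_per_g", "temperature_c", "time_constant_s", "fraction"):
        coerced = pd.to_numeric(df[col], errors="coerce")
        if coerced.isna().any() and not df[col].isna().any():
            bad = df.loc[coerced.isna(), col].iloc[0]
            raise ValueError(f"non-numeric value {bad!r} in column {col!r}")
        df[col] = coerced
    keys = ["starch", "concentration_g_per_g", "fat", "temperature_c", "which", "phase"]
    if df.duplicated(subset=keys).any():
        dupes = df[df.duplicated(subset=keys, keep=False)][keys].to_dict("records")
        raise ValueError(f"duplicate component keys: {dupes[:4]}")
    records = []
    group_keys = ["starch", "concentration_g_per_g", "fat", "temperature_c"]
    for (starch, conc, fat, temp), grp in df.groupby(group_keys, sort=False):
        comps = [
            RelaxationComponent(
                time_constant=row.time_constant_s,
                fraction=row.fraction,
                which=row.which,
                phase=row.phase,
            )
            for row in grp.itertuples()
        ]
        records.append(
            TemperatureSeriesRecord(
                starch=starch, concentration_g_per_g=conc, fat=fat,
                temperature_c=temp, components=comps,
            )
        )
    return records


_ACTIVATION_COLUMNS = [
    "starch", "concentration_g_per_g", "fat", "phase", "delta_ea_kj_mol", "se_kj_mol",
]


def write_activation_table(table: pd.DataFrame, path) -> None:
    """Write an activation-energy table CSV (full precision, no display column)."""
    _check_columns(table, _ACTIVATION_COLUMNS, "activation table")
    table[_ACTIVATION_COLUMNS].to_csv(path, index=False)


def read_activation_table(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _check_columns(df, _ACTIVATION_COLUMNS, f"activation table {path}")
    for col in ("delta_ea_kj_mol", "se_kj_mol"):
        if not pd.api.types.is_numeric_dtype(df[col]):
            raise ValueError(f"non-numeric values in column {col!r}")
    return df


def load_reference_activation_table() -> pd.DataFrame:
    """Published per-phase activation energies for starch-stabilised emulsions.

    Reference values shipped for schema and regression tests only —
    they derive from undeposited spectrometer data and are NOT
    recomputable by this package.
    """
    with resources.files("emulrelax.data").joinpath(
        "activation_energy_reference.csv"
    ).open() as fh:
        return pd.read_csv(fh)


# ---------------------------------------------------------------------------
# the pipeline


@dataclass
class PipelineConfig:
    """Configuration for `run_pipeline`.

    Exactly one input source: ``simulate`` (kwargs for
    `paper_like_spec`), ``dataset`` (a directory written by
    `EmulsionDataset.to_dir`) or ``components`` (a component-table CSV).
    ``mode`` selects the correlation-time route: ``"ratio"`` (default,
    K-free R2/R1) or ``"r1"`` (requires a dipolar prefactor via ``r0``
    and an explicit ``branch``).
    """

    mode: str = "ratio"
    branch: str | None = None
    r0: float | None = None
    simulate: dict | None = None
    dataset: str | None = None
    components: str | None = None
    n_components: int = 2
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.mode not in ("ratio", "r1"):
            raise ConfigError(
                f"unknown correlation-time mode {self.mode!r}; expected 'ratio' or 'r1'"
            )
        sources = [s for s in (self.simulate, self.dataset, self.components) if s is not None]
        if len(sources) != 1:
            raise ConfigError(
                "exactly one of 'simulate', 'dataset' or 'components' must be set"
            )
        if self.mode == "r1" and self.branch not in ("fast", "slow"):
            raise ConfigError("mode 'r1' requires branch 'fast' or 'slow'")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text())
        if not isinstance(raw, dict):
            raise ConfigError(f"config {path} is not a mapping")
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**raw)


@dataclass
class PipelineResult:
    """Output of one pipeline run."""

    table: pd.DataFrame  # long-format activation energies with display column
    fits: dict  # (condition, phase) -> ArrheniusResults
    diagnostics: pd.DataFrame  # per (condition, temperature, phase) tau_c extraction log
    records: list[TemperatureSeriesRecord]

    def summary(self) -> str:
        lines = ["Activation energies of rotational motion (kJ/mol):"]
        for _, row in self.table.iterrows():
            lines.append(
                f"  {row.starch} {row.concentration_g_per_g} {row.fat} "
                f"{row.phase:>5}: {row.formatted}"
            )
        n_clamped = int(self.diagnostics["ratio_clamped"].sum())
        if n_clamped:
            lines.append(f"  [{n_clamped} ratio(s) clamped at the physical floor]")
        return "\n".join(lines)


def fit_dataset_components(
    dataset: EmulsionDataset, metadata: dict | None = None
) -> tuple[list[TemperatureSeriesRecord], pd.DataFrame]:
    """Two-component T1 and T2 fits per temperature, phase-assigned.

    Returns the records and a per-temperature fit-diagnostics frame.
    """
    meta = dict(dataset.spec.metadata or {})
    if metadata:
        meta.update(metadata)
    starch = meta.get("starch", "unknown")
    conc = meta.get("concentration_g_per_g", float("nan"))
    fat = meta.get("fat", "unknown")
    records, diag_rows = [], []
    for temp, pair in dataset.traces.items():
        ctx_msg = f"condition ({starch}, {conc}, {fat}) at {temp:.1f} degC"
        try:
            fit_t1 = fit_inversion_recovery(pair["ir"], n_components=2)
            fit_t2 = fit_cpmg(pair["cpmg"], n_components=2)
            oil, water = assign_phases(fit_t1, fit_t2)
        except Exception as exc:  # noqa: BLE001 - context attached and re-raised
            raise PipelineError(f"fitting failed for {ctx_msg}: {exc}") from exc
        records.append(
            TemperatureSeriesRecord(
                starch=starch, concentration_g_per_g=conc, fat=fat,
                temperature_c=temp, components=tuple(oil + water),
            )
        )
        diag_rows.append(
            {
                "temperature_c": temp,
                "t1_converged": fit_t1.converged,
                "t2_converged": fit_t2.converged,
                "t1_residual_rms": fit_t1.residual_rms,
                "t2_residual_rms": fit_t2.residual_rms,
            }
        )
    return records, pd.DataFrame(diag_rows)


def _tau_for_phase(
    record: TemperatureSeriesRecord,
    phase: str,
    mode: str,
    ctx: BPPContext,
    branch: str | None,
) -> tuple[CorrelationTime, bool, float]:
    t1 = record.component("T1", phase).time_constant
    t2 = record.component("T2", phase).time_constant
    ratio = t1 / t2  # R2/R1 = T1/T2
    if mode == "ratio":
        _, clamped = clamp_ratio(ratio)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            tau = tau_c_from_ratio(ratio, ctx)
        return tau, clamped, ratio
    tau = tau_c_from_r1(1.0 / t1, ctx, branch=branch)
    return tau, False, ratio


def analyze_dataset(
    records: list[TemperatureSeriesRecord],
    mode: str = "ratio",
    branch: str | None = None,
    ctx: BPPContext | None = None,
) -> PipelineResult:
    """Correlation times and Arrhenius fits from fitted component records."""
    if ctx is None:
        ctx = BPPContext()
    if not records:
        raise PipelineError("no temperature records to analyze")
    by_condition: dict[tuple, list[TemperatureSeriesRecord]] = {}
    for rec in records:
        by_condition.setdefault(rec.condition, []).append(rec)

    fits: dict = {}
    fit_list: list[ArrheniusResults] = []
    meta_list: list[dict] = []
    diag_rows = []
    for condition, recs in by_condition.items():
        starch, conc, fat = condition
        if not recs:
            raise PipelineError(f"empty temperature series for condition {condition}")
        for phase in ("oil", "water"):
            points = []
            for rec in recs:
                try:
                    tau, clamped, ratio = _tau_for_phase(rec, phase, mode, ctx, branch)
                except Exception as exc:  # noqa: BLE001
                    raise PipelineError(
                        f"correlation-time extraction failed for condition "
                        f"{condition}, phase {phase}, T = {rec.temperature_c:.1f} degC: {exc}"
                    ) from exc
                t_k = celsius_to_kelvin(rec.temperature_c)
                points.append(CorrelationTime(tau.tau_c, temperature_k=t_k))
                diag_rows.append(
                    {
                        "starch": starch, "concentration_g_per_g": conc, "fat": fat,
                        "phase": phase, "temperature_c": rec.temperature_c,
                        "ratio_t1_over_t2": ratio, "ratio_clamped": clamped,
                        "tau_c_s": tau.tau_c,
                    }
                )
            try:
                fit = ArrheniusModel.from_points(points, phase=phase).fit()
            except Exception as exc:  # noqa: BLE001
                raise PipelineError(
                    f"Arrhenius fit failed for condition {condition}, phase {phase}: {exc}"
                ) from exc
            fits[(condition, phase)] = fit
            fit_list.append(fit)
            meta_list.append(
                {"starch": starch, "concentration_g_per_g": conc, "fat": fat}
            )
    table = activation_energy_table(fit_list, meta_list)
    return PipelineResult(
        table=table,
        fits=fits,
        diagnostics=pd.DataFrame(diag_rows),
        records=records,
    )


def run_pipeline(config: PipelineConfig | dict | str | Path) -> PipelineResult:
    """Run the full analysis described by ``config``.

    See `PipelineConfig` for the accepted keys; a dict or a YAML path is
    converted first.  Returns a `PipelineResult` whose ``table`` is the
    long-format activation-energy table (one row per condition and
    phase) regardless of input mode.
    """
    if isinstance(config, (str, Path)):
        config = PipelineConfig.from_yaml(config)
    elif isinstance(config, dict):
        config = PipelineConfig(**config)

    ctx_kwargs = {}
    if config.r0 is not None:
        ctx_kwargs["r0"] = config.r0
    elif config.mode == "r1":
        raise ConfigError("mode 'r1' requires 'r0' to fix the dipolar prefactor")
    ctx = BPPContext(**ctx_kwargs)

    if config.components is not None:
        records = read_component_table(config.components)
    else:
        if config.simulate is not None:
            dataset = generate_dataset(paper_like_spec(**config.simulate))
        else:
            dataset = load_dataset(config.dataset)
        records, _ = fit_dataset_components(dataset, metadata=config.metadata)
    return analyze_dataset(records, mode=config.mode, branch=config.branch, ctx=ctx)
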