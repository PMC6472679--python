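"""Exceedance statistics against rearing limits and framework orchestration.

The rearing evaluation compares predicted internal velocity profiles
against three flow-speed limits:

* the DO velocity limit ``u_DO`` (flow too slow to flush oxygen — the
  condition of interest is speed *below* the limit);
* the foraging limit 0.1 m/s (foraging improves below it, so time spent
  *above* it is adverse);
* the mobility limit 0.27 m/s (mobility is impaired above it).

Two depth-resolved statistics quantify each condition per height bin:
the percentage of valid samples meeting it and the longest continuous
duration meeting it.  The DO and foraging conditions use the mean-current
internal profile only; the mobility condition is evaluated both with and
without the turbulent-fluctuation term, since turbulence roughly triples
the peak internal velocity.

``run_framework`` wires the full pipeline: load or generate external
conditions, derive ``u_DO`` from the DO budget, apply the container
transfer over a scenario grid of biofouling coverages, and tabulate the
exceedance report.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass
from pathlib import Path
from typing import TYPE_CHECKING, Sequence

import numpy as np
import pandas as pd

from . import do_budget as do_budget_mod
from .evp_data import EXTERNAL, VelocityField, read_velocity_field
from .transfer import DEFAULT_COEFFICIENTS, TransferCoefficients, apply_to_field

if TYPE_CHECKING:  # pragma: no cover
    from .config import RunConfig

ABOVE = "above"
BELOW = "below"

LIMIT_DO = "do_velocity"
LIMIT_FORAGE = "foraging"
LIMIT_MOBILITY = "mobility"


class FrameworkError(RuntimeError):
    """Pipeline failure tagged with the stage that raised it."""


@dataclass(frozen=True)
class RearingLimits:
    """Behavioural and oxygen-supply velocity limits plus DO concentration limits."""

    u_forage: float = 0.1  # m/s
    u_mobility: float = 0.27  # m/s
    u_do: float = do_budget_mod.FALMOUTH_BUDGET.velocity_limit  # m/s
    do_survival: float = 4.5  # mg/L
    do_optimal: float = 6.4  # mg/L

    def __post_init__(self) -> None:
        for name in ("u_forage", "u_mobility", "u_do", "do_survival", "do_optimal"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be positive")
        if not self.u_forage < self.u_mobility:
            raise ValueError("foraging limit must lie below the mobility limit")


@dataclass(frozen=True)
class Scenario:
    """One evaluation scenario: biofouling coverage fraction and turbulence flag."""

    coverage: float = 0.0
    turbulence: bool = False


def _meets(series: np.ndarray, limit: float, condition: str) -> np.ndarray:
    s = np.asarray(series, dtype=float)
    if condition == BELOW:
        return (s < limit) & ~np.isnan(s)
    if condition == ABOVE:
        return (s > limit) & ~np.isnan(s)
    raise ValueError(f"condition must be {ABOVE!r} or {BELOW!r}, got {condition!r}")


def percent_time(series: np.ndarray, limit: float, condition: str) -> float:
    """Percentage of valid (non-missing) samples strictly meeting the condition."""
    s = np.asarray(series, dtype=float)
    valid = ~np.isnan(s)
    n_valid = int(valid.sum())
    if n_valid == 0:
        raise ValueError("percent_time undefined on an all-missing series")
    return 100.0 * _meets(s, limit, condition).sum() / n_valid


def longest_run(
    series: np.ndarray,
    limit: float,
    condition: str,
    cadence: float,
    times: pd.DatetimeIndex | None = None,
    gap_factor: float = 1.5,
) -> float:
    """Longest continuous duration (hours) over which the condition holds.

    Duration is the run length in samples times the nominal cadence.
    A missing sample terminates a run; so does a time gap larger than
    ``gap_factor * cadence`` when timestamps are supplied.
    """
    if cadence is None or not cadence > 0:
        raise ValueError("a positive nominal cadence is required")
    meets = _meets(series, limit, condition)
    if times is not None and len(times) != meets.size:
        raise ValueError("times length does not match series")
    gap_break = np.zeros(meets.size, dtype=bool)
    if times is not None and meets.size > 1:
        dt = np.diff(pd.DatetimeIndex(times).asi8) / 1e9
        gap_break[1:] = dt > gap_factor * cadence
    best = run = 0
    for i, ok in enumerate(meets):
        if not ok:
            run = 0
            continue
        run = 1 if (run == 0 or gap_break[i]) else run + 1
        best = max(best, run)
    return best * cadence / 3600.0


@dataclass
class ExceedanceReport:
    """Tidy per-height, per-scenario, per-limit exceedance statistics.

    ``table`` columns: height, coverage, turbulence, limit, condition,
    limit_value, percent_time, longest_run_hours, n_valid, n_missing.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        t = self.table
        finite = t["percent_time"].dropna()
        if ((finite < 0) | (finite > 100)).any():
            raise ValueError("percent_time outside [0, 100]")
        runs = t["longest_run_hours"].dropna()
        if (runs < 0).any():
            raise ValueError("negative longest run")

    def to_csv(self, path: str | Path) -> None:
        self.table.to_csv(path, index=False, float_format="%.6f")

    def subset(self, **match) -> pd.DataFrame:
        out = self.table
        for key, val in match.items():
            out = out[out[key] == val]
        return out


def evaluate_field(
    field: VelocityField,
    limits: RearingLimits,
    scenarios: Sequence[Scenario],
    coeffs: TransferCoefficients = DEFAULT_COEFFICIENTS,
    gap_factor: float = 1.5,
) -> ExceedanceReport:
    """Evaluate an external field against the rearing limits over a scenario grid.

    For each scenario the external field is transferred to an internal
    one; the DO and foraging conditions always use the mean-current
    internal profile, while the mobility condition uses the
    current+turbulence profile when the scenario's turbulence flag is set.
    """
    if len(scenarios) == 0:
        raise ValueError("at least one scenario is required")
    if field.provenance != EXTERNAL:
        raise ValueError(
            "evaluate_field expects an external field; it applies the transfer itself"
        )
    rows = []
    for sc in scenarios:
        internal_cur = apply_to_field(field, coeffs, sc.coverage, include_turbulence=False)
        mobility_field = (
            apply_to_field(field, coeffs, sc.coverage, include_turbulence=True)
            if sc.turbulence
            else internal_cur
        )
        checks = [
            (LIMIT_DO, BELOW, limits.u_do, internal_cur),
            (LIMIT_FORAGE, ABOVE, limits.u_forage, internal_cur),
            (LIMIT_MOBILITY, ABOVE, limits.u_mobility, mobility_field),
        ]
        for name, condition, limit, fld in checks:
            for j, h in enumerate(fld.heights):
                col = fld.speed[:, j]
                n_valid = int((~np.isnan(col)).sum())
                n_missing = col.size - n_valid
                if n_valid == 0:
                    pct, run = np.nan, np.nan
                else:
                    pct = percent_time(col, limit, condition)
                    run = longest_run(
                        col, limit, condition, fld.cadence, times=fld.times,
                        gap_factor=gap_factor,
                    )
                rows.append(
                    {
                        "height": h,
                        "coverage": sc.coverage,
                        "turbulence": sc.turbulence,
                        "limit": name,
                        "condition": condition,
                        "limit_value": limit,
                        "percent_time": pct,
                        "longest_run_hours": run,
                        "n_valid": n_valid,
                        "n_missing": n_missing,
                    }
                )
    return ExceedanceReport(pd.DataFrame(rows))


# ----------------------------------------------------------------------
# Orchestration


@dataclass
class FrameworkResult:
    report: ExceedanceReport
    limits: RearingLimits
    budget: do_budget_mod.DOBudget
    field: VelocityField
    outdir: Path | None = None


def _stage(name: str):
    class _Ctx:
        def __enter__(self):
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None and not isinstance(exc, FrameworkError):
                raise FrameworkError(f"[{name}] {exc}") from exc
            return False

    return _Ctx()


def run_framework(config: "RunConfig", outdir: str | Path | None = None) -> FrameworkResult:
    """Run the full pipeline from a validated configuration.

    Stages: DO budget -> limits -> external conditions (file or synthetic)
    -> optional storm-wave orbital envelope -> transfer + exceedance
    evaluation -> report files (CSV table, manifest, optional plots).
    Deterministic for a fixed seed.
    """
    from .synthetic import gen_current_field
    from .wave_kinematics import WaveState, orbital_amplitude_profile

    with _stage("do-budget"):
        budget = config.do_budget
        u_do = budget.velocity_limit

    with _stage("limits"):
        limits = RearingLimits(
            u_forage=config.limits.forage,
            u_mobility=config.limits.mobility,
            u_do=u_do,
            do_survival=config.limits.do_survival,
            do_optimal=config.limits.do_optimal,
        )

    with _stage("evp"):
        if config.evp.source == "synthetic":
            spec = config.evp.synthetic
            field = gen_current_field(spec)
        elif config.evp.source == "file":
            if not config.evp.path:
                raise ValueError("evp.source is 'file' but no path given")
            field = read_velocity_field(config.evp.path)
        else:
            raise ValueError(f"unknown evp source {config.evp.source!r}")
        if field.provenance != EXTERNAL:
            raise ValueError("the evaluation pipeline starts from an external field")

    if config.wave.enabled:
        with _stage("wave-kinematics"):
            if field.water_depth_ref is None:
                raise ValueError("wave envelope needs a reference water depth")
            state = WaveState(
                H=config.wave.H, T=config.wave.T, d=field.water_depth_ref,
                formula=config.wave.formula,
            )
            amp = orbital_amplitude_profile(state, field.heights)
            field = VelocityField(
                times=field.times,
                heights=field.heights,
                speed=field.speed + amp[None, :],
                cadence=field.cadence,
                provenance=EXTERNAL,
                water_depth_ref=field.water_depth_ref,
            )

    with _stage("evaluate"):
        report = evaluate_field(
            field, limits, config.scenarios.to_scenarios(), coeffs=config.coefficients
        )

    out: Path | None = None
    if outdir is not None or config.output.directory:
        with _stage("report"):
            out = Path(outdir) if outdir is not None else Path(config.output.directory)
            out.mkdir(parents=True, exist_ok=True)
            report.to_csv(out / "report.csv")
            _write_manifest(config, out / "manifest.txt")
            if config.output.plots:
                _write_plots(report, out)

    return FrameworkResult(report=report, limits=limits, budget=budget, field=field, outdir=out)


def _write_manifest(config: "RunConfig", path: Path) -> None:
    import numpy
    import pandas

    from . import __version__
    from .config import dump_config_yaml

    text = dump_config_yaml(config)
    digest = hashlib.sha256(text.encode()).hexdigest()
    with open(path, "w") as fh:
        fh.write(f"config_sha256: {digest}\n")
        fh.write(f"seed: {config.seed}\n")
        fh.write(f"sbcc_eval: {__version__}\n")
        fh.write(f"numpy: {numpy.__version__}\n")
        fh.write(f"pandas: {pandas.__version__}\n")


def _write_plots(report: ExceedanceReport, outdir: Path) -> None:
    """Depth-profile PNGs: one figure per limit, per statistic."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    for limit_name, grp in report.table.groupby("limit"):
        for stat, fname in (
            ("percent_time", f"{limit_name}_percent_time.png"),
            ("longest_run_hours", f"{limit_name}_longest_run.png"),
        ):
            fig, ax = plt.subplots(figsize=(5, 5))
            for (cov, turb), sub in grp.groupby(["coverage", "turbulence"]):
                label = f"{cov:.0%} fouling" + (", turb" if turb else "")
                ax.plot(sub[stat], sub["height"], marker="o", label=label)
            ax.set_xlabel("% of time" if stat == "percent_time" else "longest run (h)")
            ax.set_ylabel("height above seabed (m)")
            cond = grp["condition"].iloc[0]
            lim = grp["limit_value"].iloc[0]
            ax.set_title(f"{limit_name}: {cond} {lim:.4g} m/s")
            ax.legend(fontsize=8)
            fig.tight_layout()
            fig.savefig(outdir / fname, dpi=120)
            plt.close(fig)
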