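"""Run configuration: YAML round-trip and validation diagnostics.

A run is fully reproducible from its :class:`RunConfig` alone.  The
config holds plain scalars (not the validating parameter objects) so
that :func:`validate_config` can report every problem as a diagnostic
string instead of stopping at the first exception.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Any

import yaml

from .cohort import BandedCohort, CohortError
from .params import EventProbs, UnitCosts, SWEEPABLE_PARAMS

__all__ = ["RunConfig", "validate_config", "default_config"]


@dataclass
class RunConfig:
    """Everything a report run needs, serialisable to/from YAML."""

    # cohort: either a CSV path or inline band rows (lower, upper, n, n_any, n_high)
    cohort_csv: str | None = None
    bands: tuple[tuple[float, float, int, int, int], ...] | None = None
    # unit costs
    test_cost: float = 3000.0
    biopsy_cost: float = 10900.0
    ae_attendance_cost: float = 1300.0
    hosp_daily_cost: float = 4950.0
    mean_los: float = 4.67
    # event probabilities
    p_ae_given_biopsy: float = 39 / 569
    p_hosp_given_ae: float = 15 / 39
    # analysis plan
    base_cutoff: float = 35.0
    cutoffs: tuple[float, ...] = (25.0, 35.0, 55.0)
    # sweep rows as (param_name, low_or_None, high_or_None)
    sweeps: tuple[tuple[str, float | None, float | None], ...] = ()
    thresholds: tuple[str, ...] = ("specificity", "test_cost", "biopsy_cost")
    refusal_rate: float = 0.0
    # run plumbing
    output_dir: str = "ruleout_report"
    seed: int = 0
    verbosity: str = "info"
    currency: str = "HK$"

    # -- parameter-object accessors (raise on invalid values) --------

    def costs(self) -> UnitCosts:
        return UnitCosts(
            test_cost=self.test_cost,
            biopsy_cost=self.biopsy_cost,
            ae_attendance_cost=self.ae_attendance_cost,
            hosp_daily_cost=self.hosp_daily_cost,
            mean_los=self.mean_los,
        )

    def probs(self) -> EventProbs:
        return EventProbs(
            p_ae_given_biopsy=self.p_ae_given_biopsy,
            p_hosp_given_ae=self.p_hosp_given_ae,
        )

    def cohort(self) -> BandedCohort:
        if self.cohort_csv is not None:
            return BandedCohort.from_csv(self.cohort_csv)
        if self.bands is not None:
            return BandedCohort.from_records(self.bands)
        raise CohortError("config must provide either cohort_csv or inline bands")

    def sweep_specs(self):
        from .sweep import SweepSpec

        return [SweepSpec(name, low, high) for name, low, high in self.sweeps]

    # -- YAML round-trip ---------------------------------------------

    def to_dict(self) -> dict[str, Any]:
        bands = None
        if self.bands is not None:
            bands = [list(row) for row in self.bands]
        return {
            "cohort": {"csv": self.cohort_csv, "bands": bands},
            "costs": {
                "test": self.test_cost,
                "biopsy": self.biopsy_cost,
                "ae_attendance": self.ae_attendance_cost,
                "hosp_daily": self.hosp_daily_cost,
                "mean_los": self.mean_los,
            },
            "probabilities": {
                "ae_given_biopsy": self.p_ae_given_biopsy,
                "hosp_given_ae": self.p_hosp_given_ae,
            },
            "analysis": {
                "base_cutoff": self.base_cutoff,
                "cutoffs": list(self.cutoffs),
                "sweeps": [
                    {"param": name, "low": low, "high": high}
                    for name, low, high in self.sweeps
                ],
                "thresholds": list(self.thresholds),
                "refusal_rate": self.refusal_rate,
            },
            "run": {
                "output_dir": self.output_dir,
                "seed": self.seed,
                "verbosity": self.verbosity,
                "currency": self.currency,
            },
        }

    @classmethod
    def from_dict(cls, data: dict[str, Any]) -> "RunConfig":
        cohort = data.get("cohort", {}) or {}
        costs = data.get("costs", {}) or {}
        probs = data.get("probabilities", {}) or {}
        analysis = data.get("analysis", {}) or {}
        run = data.get("run", {}) or {}
        bands = cohort.get("bands")
        if bands is not None:
            bands = tuple(
                (float(r[0]), float(r[1]), int(r[2]), int(r[3]), int(r[4]))
                for r in bands
            )
        defaults = cls()
        sweeps = tuple(
            (s["param"], s.get("low"), s.get("high"))
            for s in analysis.get("sweeps", [])
        )
        return cls(
            cohort_csv=cohort.get("csv"),
            bands=bands,
            test_cost=float(costs.get("test", defaults.test_cost)),
            biopsy_cost=float(costs.get("biopsy", defaults.biopsy_cost)),
            ae_attendance_cost=float(costs.get("ae_attendance", defaults.ae_attendance_cost)),
            hosp_daily_cost=float(costs.get("hosp_daily", defaults.hosp_daily_cost)),
            mean_los=float(costs.get("mean_los", defaults.mean_los)),
            p_ae_given_biopsy=float(probs.get("ae_given_biopsy", defaults.p_ae_given_biopsy)),
            p_hosp_given_ae=float(probs.get("hosp_given_ae", defaults.p_hosp_given_ae)),
            base_cutoff=float(analysis.get("base_cutoff", defaults.base_cutoff)),
            cutoffs=tuple(float(c) for c in analysis.get("cutoffs", defaults.cutoffs)),
            sweeps=sweeps,
            thresholds=tuple(analysis.get("thresholds", defaults.thresholds)),
            refusal_rate=float(analysis.get("refusal_rate", 0.0)),
            output_dir=str(run.get("output_dir", defaults.output_dir)),
            seed=int(run.get("seed", defaults.seed)),
            verbosity=str(run.get("verbosity", defaults.verbosity)),
            currency=str(run.get("currency", defaults.currency)),
        )

    def to_yaml(self, path: str | Path | None = None) -> str:
        text = yaml.safe_dump(self.to_dict(), sort_keys=True, default_flow_style=None)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_yaml(cls, source: str | Path) -> "RunConfig":
        p = Path(source)
        text = p.read_text() if p.exists() else str(source)
        data = yaml.safe_load(text)
        if not isinstance(data, dict):
            raise CohortError("config file does not contain a mapping")
        return cls.from_dict(data)


def validate_config(config: RunConfig) -> list[str]:
    """All violations found in a config; the empty list means valid.

    Checks: non-negative costs, probabilities in [0, 1], a resolvable
    cohort with contiguous bands and consistent counts, and cut-offs
    sitting on band boundaries.
    """
    diags: list[str] = []
    for name in ("test_cost", "biopsy_cost", "ae_attendance_cost", "hosp_daily_cost", "mean_los"):
        if getattr(config, name) < 0:
            diags.append(f"{name} must be non-negative, got {getattr(config, name)}")
    for name in ("p_ae_given_biopsy", "p_hosp_given_ae", "refusal_rate"):
        v = getattr(config, name)
        if not 0.0 <= v <= 1.0:
            diags.append(f"{name} must lie in [0, 1], got {v}")
    for name, low, high in config.sweeps:
        if name not in SWEEPABLE_PARAMS:
            diags.append(f"sweep parameter {name!r} is not a model scalar")
        if low is not None and high is not None and low > high:
            diags.append(f"sweep bounds for {name!r} must satisfy low <= high")
    for name in config.thresholds:
        if name not in SWEEPABLE_PARAMS:
            diags.append(f"threshold parameter {name!r} is not a model scalar")
    if config.cohort_csv is None and config.bands is None:
        diags.append("config must provide either cohort_csv or inline bands")
        return diags
    try:
        cohort = config.cohort()
    except (CohortError, OSError, ValueError) as exc:
        diags.append(f"cohort: {exc}")
        return diags
    admissible = set(b.lower for b in cohort.bands)
    for cutoff in set(config.cutoffs) | {config.base_cutoff}:
        if cutoff not in admissible and cutoff > cohort.bands[0].lower:
            diags.append(f"cutoff not on band boundary: {cutoff:g} (boundaries {sorted(admissible)})")
    return diags


def default_config() -> RunConfig:
    """The built-in Hong Kong PHI analysis as a RunConfig."""
    from .datasets import (
        hong_kong_costs,
        hong_kong_cutoffs,
        hong_kong_event_probs,
        hong_kong_phi_cohort,
        hong_kong_sweep_specs,
    )

    cohort = hong_kong_phi_cohort()
    costs = hong_kong_costs()
    probs = hong_kong_event_probs()
    return RunConfig(
        bands=tuple(
            (b.lower, b.upper, b.n, b.n_any, b.n_high) for b in cohort.bands
        ),
        test_cost=costs.test_cost,
        biopsy_cost=costs.biopsy_cost,
        ae_attendance_cost=costs.ae_attendance_cost,
        hosp_daily_cost=costs.hosp_daily_cost,
        mean_los=costs.mean_los,
        p_ae_given_biopsy=probs.p_ae_given_biopsy,
        p_hosp_given_ae=probs.p_hosp_given_ae,
        base_cutoff=35.0,
        cutoffs=hong_kong_cutoffs(),
        sweeps=tuple(
            (s.param_name, s.low, s.high) for s in hong_kong_sweep_specs()
        ),
        thresholds=("specificity", "test_cost", "biopsy_cost"),
    )
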