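"""Bit-stable tabular report generation.

``run_report`` turns one :class:`~ruleout.config.RunConfig` into a
bundle of CSV tables (test performance, cost-consequence comparison,
base-case saving decomposition, one-way sensitivity analysis,
threshold analysis, tornado plot data) plus a JSON manifest echoing
the config.  Everything is deterministic: re-running the same config
produces byte-identical files.

Display tables round money half-up to whole currency units with
thousands separators and print rates to two decimal places; the
tornado CSV keeps full-precision floats for plotting layers.
"""

from __future__ import annotations

import csv
import json
import logging
from decimal import Decimal, ROUND_HALF_UP
from pathlib import Path

from . import __version__
from .cohort import performance_at_cutoff, biopsy_rate, missed_fraction
from .config import RunConfig, validate_config
from .model import cost_consequence_table, decompose_saving
from .params import EconParams
from .sweep import NoThresholdError, one_way_sweep, threshold_solve, tornado

__all__ = ["run_report", "ReportError", "fmt_money", "fmt_pct", "REPORT_FILES"]

logger = logging.getLogger("ruleout")

REPORT_FILES = (
    "performance.csv",
    "cost_consequence.csv",
    "base_case.csv",
    "sensitivity.csv",
    "threshold.csv",
    "tornado.csv",
    "manifest.json",
)


class ReportError(RuntimeError):
    """Report generation failed; partial outputs have been removed."""


def fmt_money(x: float) -> str:
    """Round half-up to whole currency units, with thousands separators."""
    q = Decimal(repr(x)).quantize(Decimal("1"), rounding=ROUND_HALF_UP)
    return f"{q:,}"


def fmt_pct(x: float, digits: int = 2) -> str:
    """A fraction as a percentage string with fixed decimals (no % sign)."""
    return f"{x * 100:.{digits}f}"


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, float) and obj == float("inf"):
        return "inf"
    return obj


def _write_csv(path: Path, header: list[str], rows: list[list]) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, lineterminator="\n")
        writer.writerow(header)
        writer.writerows(rows)


def run_report(config: RunConfig, output_dir: str | Path | None = None) -> dict[str, Path]:
    """Run every analysis in the config and write the report bundle.

    Returns a mapping of logical table name to written file path.
    Raises :class:`ReportError` on a malformed config; any files
    already written for this run are removed first.
    """
    diags = validate_config(config)
    if diags:
        raise ReportError("; ".join(diags))
    outdir = Path(output_dir if output_dir is not None else config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    try:
        cohort = config.cohort()
        costs = config.costs()
        probs = config.probs()
        base_params = EconParams.from_cohort(
            cohort, config.base_cutoff, probs, costs, refusal_rate=config.refusal_rate
        )

        # test performance per cut-off and grade
        perf_rows = []
        for cutoff in config.cutoffs:
            for grade in ("any", "high"):
                perf = performance_at_cutoff(cohort, cutoff, grade)
                perf_rows.append(
                    [
                        f"{cutoff:g}",
                        grade,
                        fmt_pct(float(perf.prevalence)),
                        fmt_pct(float(perf.sensitivity)),
                        fmt_pct(float(perf.specificity)),
                        fmt_pct(float(biopsy_rate(perf))),
                        fmt_pct(float(missed_fraction(perf))),
                    ]
                )
        path = outdir / "performance.csv"
        _write_csv(
            path,
            ["cutoff", "grade", "prevalence_pct", "sensitivity_pct",
             "specificity_pct", "biopsy_rate_pct", "missed_fraction_pct"],
            perf_rows,
        )
        written.append(path)
        logger.info("wrote %s", path)

        # cost-consequence comparison
        cc = cost_consequence_table(
            cohort, probs, costs, config.cutoffs, refusal_rate=config.refusal_rate
        )
        cc_rows = []
        for rec in cc.itertuples(index=False):
            cc_rows.append(
                [
                    rec.strategy,
                    fmt_pct(rec.biopsy_rate),
                    fmt_money(rec.cost_biopsies),
                    fmt_money(rec.cost_test),
                    fmt_money(rec.cost_ae),
                    fmt_money(rec.total_cost),
                    "" if rec.saving_vs_biopsy_all != rec.saving_vs_biopsy_all
                    else fmt_money(rec.saving_vs_biopsy_all),
                    "" if rec.missed_any != rec.missed_any else fmt_pct(rec.missed_any),
                    "" if rec.missed_high != rec.missed_high else fmt_pct(rec.missed_high),
                ]
            )
        path = outdir / "cost_consequence.csv"
        _write_csv(
            path,
            ["strategy", "biopsy_rate_pct", "cost_biopsies", "cost_test",
             "cost_ae", "total_cost", "saving_vs_biopsy_all",
             "missed_any_pct", "missed_high_pct"],
            cc_rows,
        )
        written.append(path)
        logger.info("wrote %s", path)

        # base-case saving decomposition
        d = decompose_saving(base_params)
        path = outdir / "base_case.csv"
        _write_csv(
            path,
            ["item", "value"],
            [
                ["cutoff", f"{config.base_cutoff:g}"],
                ["saving_from_avoided_biopsies", fmt_money(d.biopsy_saving)],
                ["saving_from_avoided_adverse_events", fmt_money(d.ae_saving)],
                ["cost_of_testing", fmt_money(d.test_cost)],
                ["net_saving_per_patient", fmt_money(d.net_saving)],
            ],
        )
        written.append(path)
        logger.info("wrote %s", path)

        # one-way sensitivity analysis
        specs = config.sweep_specs()
        sweep_entries = [one_way_sweep(base_params, s) for s in specs]
        path = outdir / "sensitivity.csv"
        _write_csv(
            path,
            ["param", "base_value", "low", "high", "saving_at_low", "saving_at_high"],
            [
                [e.param_name, repr(e.base_value), repr(e.low), repr(e.high),
                 fmt_money(e.saving_at_low), fmt_money(e.saving_at_high)]
                for e in sweep_entries
            ],
        )
        written.append(path)
        logger.info("wrote %s", path)

        # threshold (cost-neutrality) analysis
        thr_rows = []
        for name in config.thresholds:
            try:
                t = threshold_solve(base_params, name)
                thr_rows.append([t.param_name, repr(t.base_value), repr(t.neutral_value)])
            except NoThresholdError:
                thr_rows.append([name, repr(base_params.get(name)), "no threshold in range"])
        path = outdir / "threshold.csv"
        _write_csv(path, ["param", "base_value", "neutral_value"], thr_rows)
        written.append(path)
        logger.info("wrote %s", path)

        # tornado plot data (full precision, widest bar first)
        entries = tornado(base_params, specs) if specs else []
        path = outdir / "tornado.csv"
        _write_csv(
            path,
            ["param", "low", "high", "saving_low", "saving_high", "base_saving"],
            [
                [e.param_name, repr(e.low), repr(e.high),
                 repr(e.saving_at_low), repr(e.saving_at_high), repr(e.base_saving)]
                for e in entries
            ],
        )
        written.append(path)
        logger.info("wrote %s", path)

        # machine-readable manifest (infinite band bounds serialised as "inf")
        path = outdir / "manifest.json"
        manifest = {"package": "ruleout", "version": __version__, "config": config.to_dict()}
        path.write_text(json.dumps(_jsonable(manifest), indent=2, sort_keys=True, allow_nan=False) + "\n")
        written.append(path)
        logger.info("wrote %s", path)
    except Exception as exc:
        for p in written:
            p.unlink(missing_ok=True)
        if isinstance(exc, ReportError):
            raise
        raise ReportError(str(exc)) from exc
    return {p.name: p for p in written}
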