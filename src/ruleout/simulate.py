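"""Patient-level synthetic cohorts with the model's generative structure.

The closed-form decision model works on expectations.  This module
simulates the individual patients those expectations average over:
each man gets a score band (categorical on the band weights), a score
uniform within the band, a cancer status drawn from his band's
grade mix, and -- if the strategy sends him to biopsy -- a Bernoulli
adverse-event cascade (A&E attendance, then hospitalisation with a
1 + Poisson length of stay) with costs accrued per event.  Summaries
of a simulated cohort close the loop: banding the patients back up
must recover the configured operating characteristics, and mean
accrued cost must converge to the closed-form expected cost.

Patient-level output is a pandas DataFrame, one row per patient.
Randomness comes from one seed; each patient draws from a sub-stream
keyed by (seed, patient index), so cohort content does not depend on
iteration order and is byte-identical across runs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .cohort import Band, BandedCohort
from .params import EventProbs, ParamsError, UnitCosts

__all__ = ["SimConfig", "simulate_cohort", "summarize_to_bands", "PATIENT_COLUMNS"]

PATIENT_COLUMNS = (
    "phi_score",
    "band_index",
    "cancer",
    "biopsied",
    "ae_attended",
    "hospitalised",
    "los",
    "accrued_cost",
)

#: Finite sampling cap for an unbounded top score band.
DEFAULT_TOP_CAP = 100.0


@dataclass(frozen=True)
class SimConfig:
    """Generative parameters for a synthetic cohort.

    band_edges has one more entry than band_weights; the last edge may
    be infinite, in which case scores in the top band are sampled up
    to ``top_cap`` (band membership, not the score value, is all that
    feeds the model).  ``p_any``/``p_high`` are per-band cancer
    probabilities with ``p_high <= p_any``.  ``seed`` is mandatory:
    a cohort is reproducible from its config alone.
    """

    n_patients: int
    band_edges: tuple[float, ...]
    band_weights: tuple[float, ...]
    p_any: tuple[float, ...]
    p_high: tuple[float, ...]
    probs: EventProbs
    costs: UnitCosts
    seed: int
    top_cap: float = DEFAULT_TOP_CAP

    def __post_init__(self) -> None:
        k = len(self.band_weights)
        if len(self.band_edges) != k + 1 or k == 0:
            raise ParamsError("band_edges must have exactly one more entry than band_weights")
        if self.n_patients < 0:
            raise ParamsError("n_patients must be non-negative")
        if any(b <= a for a, b in zip(self.band_edges, self.band_edges[1:])):
            raise ParamsError("band_edges must be strictly increasing")
        if not math.isclose(sum(self.band_weights), 1.0, abs_tol=1e-9):
            raise ParamsError(f"band_weights must sum to 1, got {sum(self.band_weights)}")
        for name in ("band_weights", "p_any", "p_high"):
            vals = getattr(self, name)
            if len(vals) != k:
                raise ParamsError(f"{name} must have one entry per band")
            if any(not 0.0 <= v <= 1.0 for v in vals):
                raise ParamsError(f"{name} entries must lie in [0, 1]")
        if any(h > a for h, a in zip(self.p_high, self.p_any)):
            raise ParamsError("p_high must not exceed p_any in any band")

    @classmethod
    def from_cohort(
        cls,
        cohort: BandedCohort,
        probs: EventProbs,
        costs: UnitCosts,
        *,
        n_patients: int,
        seed: int,
        top_cap: float = DEFAULT_TOP_CAP,
    ) -> "SimConfig":
        """Generative parameters matching an observed banded cohort's proportions."""
        total = cohort.n_total
        if total == 0:
            raise ParamsError("cannot derive generative weights from an empty cohort")
        return cls(
            n_patients=n_patients,
            band_edges=tuple(b.lower for b in cohort.bands) + (cohort.bands[-1].upper,),
            band_weights=tuple(b.n / total for b in cohort.bands),
            p_any=tuple(b.n_any / b.n if b.n else 0.0 for b in cohort.bands),
            p_high=tuple(b.n_high / b.n if b.n else 0.0 for b in cohort.bands),
            probs=probs,
            costs=costs,
            seed=seed,
            top_cap=top_cap,
        )


def _simulate_patient(
    config: SimConfig,
    index: int,
    cum_weights: np.ndarray,
    use_test: bool,
    cutoff: float,
) -> tuple:
    rng = np.random.default_rng((config.seed, index))
    band = int(np.searchsorted(cum_weights, rng.random(), side="right"))
    lo = config.band_edges[band]
    hi = config.band_edges[band + 1]
    if math.isinf(hi):
        hi = max(config.top_cap, lo + 1.0)
    phi = lo + (hi - lo) * rng.random()

    u = rng.random()
    if u < config.p_high[band]:
        cancer = "high_grade"
    elif u < config.p_any[band]:
        cancer = "low_grade"
    else:
        cancer = "none"

    biopsied = (phi >= cutoff) if use_test else True
    cost = config.costs.test_cost if use_test else 0.0
    ae = hosp = False
    los = 0
    if biopsied:
        cost += config.costs.biopsy_cost
        ae = rng.random() < config.probs.p_ae_given_biopsy
        if ae:
            cost += config.costs.ae_attendance_cost
            hosp = rng.random() < config.probs.p_hosp_given_ae
            if hosp:
                los = 1 + int(rng.poisson(max(config.costs.mean_los - 1.0, 0.0)))
                cost += los * config.costs.hosp_daily_cost
    return phi, band, cancer, biopsied, ae, hosp, los, cost


def simulate_cohort(config: SimConfig, *, strategy: str | float = "biopsy_all") -> pd.DataFrame:
    """Simulate one patient-level cohort under a diagnostic strategy.

    ``strategy`` is either the string ``"biopsy_all"`` (everyone is
    biopsied, no test administered) or a numeric rule-out cut-off
    (everyone is tested; scores at or above the cut-off go to biopsy).

    Returns a DataFrame with one row per patient and columns
    ``phi_score, band_index, cancer, biopsied, ae_attended,
    hospitalised, los, accrued_cost``.
    """
    if isinstance(strategy, str):
        if strategy != "biopsy_all":
            raise ParamsError(f"unknown strategy {strategy!r}; use 'biopsy_all' or a numeric cut-off")
        use_test, cutoff = False, -math.inf
    else:
        use_test, cutoff = True, float(strategy)
    cum_weights = np.cumsum(config.band_weights)
    cum_weights[-1] = 1.0  # guard against float round-off at the top
    rows = [
        _simulate_patient(config, i, cum_weights, use_test, cutoff)
        for i in range(config.n_patients)
    ]
    df = pd.DataFrame(rows, columns=list(PATIENT_COLUMNS))
    if df.empty:
        df = pd.DataFrame({c: pd.Series(dtype=t) for c, t in zip(
            PATIENT_COLUMNS,
            [float, int, object, bool, bool, bool, int, float],
        )})
    return df


def summarize_to_bands(patients: pd.DataFrame, boundaries: Sequence[float]) -> BandedCohort:
    """Aggregate a patient-level cohort back into banded counts.

    ``boundaries`` are the band edges (sorted, length >= 2; the last
    may be infinite), typically ``SimConfig.band_edges``.
    """
    edges = [float(b) for b in boundaries]
    if len(edges) < 2 or any(b <= a for a, b in zip(edges, edges[1:])):
        raise ParamsError("boundaries must be a sorted sequence of at least two edges")
    scores = patients["phi_score"].to_numpy() if len(patients) else np.empty(0)
    idx = np.searchsorted(edges, scores, side="right") - 1
    if len(scores) and (idx.min() < 0 or idx.max() >= len(edges) - 1):
        raise ParamsError("some patient scores fall outside the given boundaries")
    cancer = patients["cancer"].to_numpy() if len(patients) else np.empty(0, dtype=object)
    bands = []
    for b in range(len(edges) - 1):
        in_band = idx == b
        n = int(in_band.sum())
        n_any = int(np.sum(in_band & (cancer != "none")))
        n_high = int(np.sum(in_band & (cancer == "high_grade")))
        bands.append(Band(edges[b], edges[b + 1], n, n_any, n_high))
    return BandedCohort(tuple(bands))
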