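"""Test operating characteristics from banded cohort counts.

A diagnostic score (here the Prostate Health Index, but any ordinal
rule-out score works) is often published not patient-by-patient but as
counts per score band: how many men fell in each band and how many of
them had cancer of each grade.  Because a rule-out cut-off placed on a
band boundary splits the cohort cleanly into test-negative (below) and
test-positive (at or above) arms, every confusion-matrix quantity --
prevalence, sensitivity, specificity, biopsy rate, missed-case fraction
-- is an exact ratio of integer counts.  This module keeps that
arithmetic exact with :class:`fractions.Fraction` and only converts to
float at the reporting layer.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass
from fractions import Fraction
from pathlib import Path
from typing import Iterable, Literal, Sequence

__all__ = [
    "Band",
    "BandedCohort",
    "TestPerformance",
    "CohortError",
    "UnresolvableCutError",
    "prevalence",
    "performance_at_cutoff",
    "biopsy_rate",
    "missed_fraction",
]

Grade = Literal["any", "high"]
_GRADES = ("any", "high")


class CohortError(ValueError):
    """Invalid banded-cohort input."""


class UnresolvableCutError(CohortError):
    """Cut-off falls inside a band, so counts cannot be split."""


@dataclass(frozen=True)
class Band:
    """One score band [lower, upper) with its cancer counts.

    Parameters
    ----------
    lower, upper
        Score bounds; the band is half-open, ``lower <= score < upper``.
        ``upper`` may be ``math.inf`` for an open top band.
    n
        Men in the band.
    n_any
        Of those, men with any-grade cancer (includes high grade).
    n_high
        Of those, men with high-grade (Gleason >= 7) cancer.
    """

    lower: float
    upper: float
    n: int
    n_any: int
    n_high: int

    def __post_init__(self) -> None:
        if not self.lower < self.upper:
            raise CohortError(f"band bounds must satisfy lower < upper, got [{self.lower}, {self.upper})")
        if not 0 <= self.n_high <= self.n_any <= self.n:
            raise CohortError(
                f"band counts must satisfy 0 <= n_high <= n_any <= n, got n={self.n}, n_any={self.n_any}, n_high={self.n_high}"
            )

    def n_grade(self, grade: Grade) -> int:
        if grade not in _GRADES:
            raise CohortError(f"unknown grade {grade!r}; expected one of {_GRADES}")
        return self.n_any if grade == "any" else self.n_high


@dataclass(frozen=True)
class BandedCohort:
    """An ordered, contiguous sequence of score bands covering the score range."""

    bands: tuple[Band, ...]

    def __post_init__(self) -> None:
        if not self.bands:
            raise CohortError("cohort must contain at least one band")
        object.__setattr__(self, "bands", tuple(self.bands))
        for a, b in zip(self.bands, self.bands[1:]):
            if a.upper != b.lower:
                raise CohortError(
                    f"bands must be contiguous and non-overlapping: [{a.lower}, {a.upper}) then [{b.lower}, {b.upper})"
                )

    # -- construction ------------------------------------------------

    @classmethod
    def from_records(cls, records: Iterable[Sequence]) -> "BandedCohort":
        """Build from (lower, upper, n, n_any, n_high) rows; upper may be 'inf'."""
        bands = []
        for lower, upper, n, n_any, n_high in records:
            bands.append(
                Band(float(lower), float(upper), int(n), int(n_any), int(n_high))
            )
        return cls(tuple(bands))

    @classmethod
    def from_csv(cls, path: str | Path) -> "BandedCohort":
        """Read a cohort CSV with columns lower,upper,n,n_any,n_high."""
        with open(path, newline="") as fh:
            reader = csv.DictReader(fh)
            required = {"lower", "upper", "n", "n_any", "n_high"}
            if reader.fieldnames is None or not required.issubset(reader.fieldnames):
                raise CohortError(f"cohort CSV must have columns {sorted(required)}")
            rows = [
                (r["lower"], r["upper"], r["n"], r["n_any"], r["n_high"])
                for r in reader
            ]
        if not rows:
            raise CohortError("cohort CSV contains no bands")
        return cls.from_records(rows)

    def to_csv(self, path: str | Path) -> None:
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["lower", "upper", "n", "n_any", "n_high"])
            for b in self.bands:
                upper = "inf" if math.isinf(b.upper) else b.upper
                writer.writerow([b.lower, upper, b.n, b.n_any, b.n_high])

    # -- totals ------------------------------------------------------

    @property
    def n_total(self) -> int:
        return sum(b.n for b in self.bands)

    def n_cancer(self, grade: Grade = "any") -> int:
        return sum(b.n_grade(grade) for b in self.bands)

    @property
    def boundaries(self) -> tuple[float, ...]:
        """Interior band boundaries -- the admissible cut-offs."""
        return tuple(b.lower for b in self.bands[1:])


@dataclass(frozen=True)
class TestPerformance:
    """Operating characteristics of the rule-out test at one cut-off.

    All three fractions are exact rationals of the cohort counts.
    """

    prevalence: Fraction
    sensitivity: Fraction
    specificity: Fraction
    grade: Grade
    cutoff: float

    def __post_init__(self) -> None:
        for name in ("prevalence", "sensitivity", "specificity"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise CohortError(f"{name} must lie in [0, 1], got {v}")


def prevalence(cohort: BandedCohort, grade: Grade = "any") -> Fraction:
    """Fraction of the cohort with cancer of the given grade."""
    total = cohort.n_total
    if total == 0:
        raise CohortError("cohort has no patients")
    return Fraction(cohort.n_cancer(grade), total)


def performance_at_cutoff(
    cohort: BandedCohort, cutoff: float, grade: Grade = "any"
) -> TestPerformance:
    """Sensitivity/specificity of ruling out below ``cutoff``.

    Bands with ``lower >= cutoff`` form the test-positive arm (sent to
    biopsy); bands below are test-negative.  The cut-off must coincide
    with a band boundary (or lie at/below the bottom of the score
    range, in which case everyone is test-positive): a cut inside a
    band cannot be resolved from banded counts.
    """
    lowers = {b.lower for b in cohort.bands}
    if cutoff not in lowers and cutoff > cohort.bands[0].lower:
        raise UnresolvableCutError(
            f"cut-off {cutoff} is not a band boundary of {sorted(lowers)}; counts cannot be split within a band"
        )
    positive = [b for b in cohort.bands if b.lower >= cutoff]
    tp = sum(b.n_grade(grade) for b in positive)
    pos_n = sum(b.n for b in positive)
    fp = pos_n - tp
    cancers = cohort.n_cancer(grade)
    non_cancers = cohort.n_total - cancers
    # Vacuous arms: with no cancers there is nothing to miss (Se = 1);
    # with no non-cancers there is no one to spare (Sp = 1).
    se = Fraction(tp, cancers) if cancers else Fraction(1)
    sp = Fraction(non_cancers - fp, non_cancers) if non_cancers else Fraction(1)
    return TestPerformance(
        prevalence=prevalence(cohort, grade),
        sensitivity=se,
        specificity=sp,
        grade=grade,
        cutoff=cutoff,
    )


def biopsy_rate(perf: TestPerformance) -> Fraction:
    """Expected fraction biopsied under the test-first strategy: pi*Se + (1-pi)*(1-Sp)."""
    pi = perf.prevalence
    return pi * perf.sensitivity + (1 - pi) * (1 - perf.specificity)


def missed_fraction(perf: TestPerformance) -> Fraction:
    """Fraction of the whole population whose cancer is wrongly ruled out: pi*(1-Se)."""
    return perf.prevalence * (1 - perf.sensitivity)
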