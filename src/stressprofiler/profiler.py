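"""Cutoff-based extreme-behavior phenotyping.

Animals run a five-test behavioral battery after trauma exposure; for each
test the most extreme 20% of the cohort (lowest or highest tail, depending
on what "worse" means for that test) are flagged, and an animal flagged in
at least three of the five tests is labeled "PTSD-like", otherwise
"resilient".  Cutoffs use the nearest-rank empirical quantile so that the
"lowest 20%" is a well-defined set of animals, and ties at the cutoff are
flagged (the boundary is inclusive).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "TestSpec",
    "BatteryConfig",
    "CutoffSet",
    "ClassificationResult",
    "ContingencyTable2x2",
    "DEFAULT_BATTERY",
    "compute_cutoffs",
    "flag_extremes",
    "classify",
    "prevalence_table",
]


@dataclass(frozen=True)
class TestSpec:
    """One battery test: the column holding its metric and which tail is extreme."""

    name: str
    column: str
    direction: str  # "low" or "high"

    def __post_init__(self) -> None:
        if self.direction not in ("low", "high"):
            raise ValueError(
                f"direction for test {self.name!r} must be 'low' or 'high', "
                f"got {self.direction!r}"
            )


@dataclass(frozen=True)
class BatteryConfig:
    """Declarative definition of the behavioral battery.

    Parameters
    ----------
    tests
        Ordered battery tests.
    min_extreme_tests
        An animal is PTSD-like when flagged extreme in at least this many
        tests (default 3 of 5).
    percentile
        Tail fraction defining "extreme" per test (default 0.20).
    require_complete
        Exclude animals missing any test from classification (default).
        When False, an animal is labeled from the tests it did complete
        using the proportional rule score/n_observed >= min/n_tests.
    min_score_filter
        Optional stricter inclusion threshold on the extremity score
        (e.g. for tissue-sampling inclusion); ``None`` disables it.
    """

    tests: tuple[TestSpec, ...]
    min_extreme_tests: int = 3
    percentile: float = 0.20
    require_complete: bool = True
    min_score_filter: int | None = None

    def __post_init__(self) -> None:
        if not self.tests:
            raise ValueError("battery needs at least one test")
        if not 0 < self.percentile < 0.5:
            raise ValueError("percentile must lie in (0, 0.5)")
        if not 1 <= self.min_extreme_tests <= len(self.tests):
            raise ValueError(
                "min_extreme_tests must lie in [1, number of tests]"
            )

    @property
    def columns(self) -> list[str]:
        return [t.column for t in self.tests]


#: The five-test battery used for PTSD-like subcategorization: risk-assessment
#: time, latency to peak startle amplitude and percent pre-pulse inhibition
#: are extreme when LOW; dark-phase home-cage activity and percent of marbles
#: buried are extreme when HIGH.
DEFAULT_BATTERY = BatteryConfig(
    tests=(
        TestSpec("risk_assessment", "risk_assessment_time", "low"),
        TestSpec("startle_latency", "startle_peak_latency", "low"),
        TestSpec("prepulse_inhibition", "ppi_percent", "low"),
        TestSpec("homecage_activity", "dark_phase_activity", "high"),
        TestSpec("marble_burying", "marbles_buried_percent", "high"),
    )
)


@dataclass(frozen=True)
class CutoffSet:
    """Per-test empirical cutoffs plus the reference-population sizes used."""

    cutoffs: dict[str, float]  # test name -> cutoff value
    directions: dict[str, str]  # test name -> "low"/"high"
    columns: dict[str, str]  # test name -> table column
    reference_sizes: dict[str, int]
    percentile: float


@dataclass
class ClassificationResult:
    """Per-animal extreme flags, extremity score and PTSD-like label."""

    flags: pd.DataFrame  # boolean (nullable) per animal x test
    score: pd.Series  # count of extreme tests
    n_tests_observed: pd.Series
    label: pd.Series  # "PTSD-like" / "resilient" (NA if excluded)
    table: pd.DataFrame  # the input table, aligned on index

    @property
    def included(self) -> pd.Series:
        return self.label.notna()


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Group x label counts (rows = groups, cols = [PTSD-like, resilient])."""

    a: int
    b: int
    c: int
    d: int
    row_names: tuple[str, str] = ("group1", "group2")
    col_names: tuple[str, str] = ("PTSD-like", "resilient")

    def __post_init__(self) -> None:
        counts = (self.a, self.b, self.c, self.d)
        if any(int(x) != x or x < 0 for x in counts):
            raise ValueError("counts must be non-negative integers")
        if sum(counts) < 1:
            raise ValueError("table must contain at least one observation")

    def to_array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]], dtype=float)

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d


def nearest_rank_cutoff(values: np.ndarray, percentile: float, direction: str) -> float:
    """Nearest-rank quantile with an inclusive boundary.

    For the low tail the cutoff is the ceil(q*n)-th smallest value, so the
    flagged set ``value <= cutoff`` is exactly the lowest ceil(q*n) animals
    (plus any ties at the boundary).  The high tail is symmetric.
    """
    v = np.sort(np.asarray(values, dtype=float))
    n = v.size
    if n < 2:
        raise ValueError("reference population needs at least 2 values")
    k = math.ceil(percentile * n)
    k = max(k, 1)
    if direction == "low":
        return float(v[k - 1])
    return float(v[n - k])


def compute_cutoffs(
    table: pd.DataFrame,
    config: BatteryConfig,
    reference: pd.DataFrame | None = None,
) -> CutoffSet:
    """Empirical per-test cutoffs over the reference population.

    The reference defaults to the full input table (cutoffs are computed on
    the pooled trauma-exposed cohort, across prenatal groups); pass
    ``reference`` to use an external cohort instead.
    """
    ref = table if reference is None else reference
    cutoffs: dict[str, float] = {}
    directions: dict[str, str] = {}
    columns: dict[str, str] = {}
    sizes: dict[str, int] = {}
    for t in config.tests:
        if t.column not in ref.columns:
            raise KeyError(f"battery column {t.column!r} missing from table")
        vals = pd.to_numeric(ref[t.column], errors="coerce").dropna().to_numpy()
        if vals.size < 2:
            raise ValueError(
                f"test {t.name!r}: fewer than 2 non-missing reference values"
            )
        cutoffs[t.name] = nearest_rank_cutoff(vals, config.percentile, t.direction)
        directions[t.name] = t.direction
        columns[t.name] = t.column
        sizes[t.name] = int(vals.size)
    return CutoffSet(cutoffs, directions, columns, sizes, config.percentile)


def flag_extremes(table: pd.DataFrame, cutoffs: CutoffSet) -> pd.DataFrame:
    """Boundary-inclusive extreme flags per animal x test.

    Low-direction tests flag ``value <= cutoff``; high-direction tests flag
    ``value >= cutoff``.  Missing measurements give a missing (pd.NA) flag.
    """
    out = {}
    for name, cut in cutoffs.cutoffs.items():
        col = cutoffs.columns[name]
        if col not in table.columns:
            raise KeyError(f"battery column {col!r} missing from table")
        vals = pd.to_numeric(table[col], errors="coerce")
        if cutoffs.directions[name] == "low":
            flag = vals <= cut
        else:
            flag = vals >= cut
        flag = flag.astype("boolean")
        flag[vals.isna()] = pd.NA
        out[name] = flag
    return pd.DataFrame(out, index=table.index)


def classify(
    flags: pd.DataFrame,
    config: BatteryConfig,
    table: pd.DataFrame | None = None,
) -> ClassificationResult:
    """k-of-n PTSD-like labeling from the flag matrix.

    Score = number of tests flagged extreme; label is "PTSD-like" iff
    score >= min_extreme_tests.  Animals with incomplete batteries are
    excluded by default (label = NA); with ``require_complete=False`` the
    proportional rule score/n_observed >= min/n_tests is applied instead.
    """
    if flags.empty:
        raise ValueError("empty flag matrix: nothing to classify")
    n_tests = len(config.tests)
    observed = flags.notna().sum(axis=1)
    score = (flags.fillna(False).astype(bool)).sum(axis=1)

    label = pd.Series(pd.NA, index=flags.index, dtype="object")
    if config.require_complete:
        complete = observed == n_tests
        ptsd = complete & (score >= config.min_extreme_tests)
        label[complete] = "resilient"
        label[ptsd] = "PTSD-like"
    else:
        has_any = observed > 0
        frac_needed = config.min_extreme_tests / n_tests
        ptsd = has_any & (score / observed.where(observed > 0) >= frac_needed)
        label[has_any] = "resilient"
        label[ptsd] = "PTSD-like"

    if config.min_score_filter is not None:
        label[score < config.min_score_filter] = pd.NA

    return ClassificationResult(
        flags=flags,
        score=score.rename("score"),
        n_tests_observed=observed.rename("n_tests_observed"),
        label=label.rename("label"),
        table=table if table is not None else pd.DataFrame(index=flags.index),
    )


def prevalence_table(
    result: ClassificationResult, grouping: pd.Series
) -> ContingencyTable2x2:
    """Counts of PTSD-like / resilient per group (2 groups exactly).

    Rows are the two group levels in sorted order; columns are
    [PTSD-like, resilient].  Excluded animals (label NA) are dropped.
    """
    grouping = grouping.reindex(result.label.index)
    mask = result.label.notna() & grouping.notna()
    lab = result.label[mask]
    grp = grouping[mask].astype(str)
    levels = sorted(grp.unique())
    if len(levels) != 2:
        raise ValueError(
            f"grouping has {len(levels)} levels; prevalence_table needs exactly 2 "
            "(stratify first for finer designs)"
        )
    counts = []
    for lv in levels:
        sub = lab[grp == lv]
        counts.append((int((sub == "PTSD-like").sum()), int((sub == "resilient").sum())))
    (a, b), (c, d) = counts
    return ContingencyTable2x2(a, b, c, d, row_names=(levels[0], levels[1]))
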