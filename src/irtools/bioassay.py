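"""WHO tube-bioassay analysis and enzyme-activity comparison.

Adult females are exposed to a diagnostic insecticide dose in tubes of
20-25 and mortality is scored at 24 h.  Under WHO criteria a population is
resistant when pooled mortality is below 90% (with at least 100 specimens
tested); 98% or more indicates susceptibility and the band between is
"suspected" resistance.  Synergist pre-exposure (PBO or DEM) that
significantly restores mortality implicates metabolic detoxification;
the with/without comparison is a Fisher exact test on pooled dead/alive
counts.  Biochemical enzyme activities (esterases, GST, MFO) are compared
between field and reference mosquitoes with the Mann-Whitney rank test.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import stats
from .stats import TestResult

__all__ = [
    "BioassaySummary",
    "pooled_mortality",
    "abbott_correct",
    "classify_susceptibility",
    "synergist_effect",
    "compare_enzyme_activity",
    "summarize_bioassay",
]

BIOASSAY_COLUMNS = ["population", "insecticide", "synergist", "tube_id",
                    "n_exposed", "n_dead_24h"]
ENZYME_COLUMNS = ["population", "enzyme_family", "individual_id", "activity"]

RESISTANT = "resistant"
SUSPECTED = "suspected"
SUSCEPTIBLE = "susceptible"
NOT_RESISTANT = "not_resistant"  # paper-mode collapse of the two upper classes

# plausible per-tube group size; outside this we warn but proceed
TUBE_SIZE_RANGE = (15, 30)
MIN_SPECIMENS = 100


@dataclass(frozen=True)
class BioassaySummary:
    """Pooled mortality of one population x insecticide x synergist condition."""

    population: str
    insecticide: str
    synergist: str
    mortality: float            # pooled, percent
    tube_sd: float              # SD of per-tube mortalities, percentage points
    n_total: int
    n_tubes: int
    corrected_mortality: float  # Abbott-corrected (equals mortality if no control)
    classification: str
    low_n: bool                 # fewer than 100 specimens tested

    def __post_init__(self) -> None:
        if not 0.0 <= self.mortality <= 100.0:
            raise ValueError("mortality must be within [0, 100]")


def _condition_rows(table: pd.DataFrame, population: str, insecticide: str,
                    synergist: str) -> pd.DataFrame:
    mask = (
        (table["population"] == population)
        & (table["insecticide"] == insecticide)
        & (table["synergist"] == synergist)
    )
    rows = table[mask]
    if rows.empty:
        raise ValueError(
            f"no bioassay rows for ({population}, {insecticide}, {synergist})"
        )
    return rows


def _validate_counts(rows: pd.DataFrame) -> None:
    if (rows["n_dead_24h"] > rows["n_exposed"]).any():
        raise ValueError("n_dead_24h exceeds n_exposed in a tube")
    if (rows["n_exposed"] < 1).any():
        raise ValueError("empty tube (n_exposed < 1)")
    out = rows[(rows["n_exposed"] < TUBE_SIZE_RANGE[0])
               | (rows["n_exposed"] > TUBE_SIZE_RANGE[1])]
    if not out.empty:
        warnings.warn(
            f"{len(out)} tube(s) outside the plausible group size "
            f"{TUBE_SIZE_RANGE[0]}-{TUBE_SIZE_RANGE[1]}", stacklevel=3)


def pooled_mortality(
    table: pd.DataFrame,
    population: str,
    insecticide: str,
    synergist: str = "none",
    thresholds: tuple = (90.0, 98.0),
    control_mortality: float | None = None,
    paper_mode: bool = False,
) -> BioassaySummary:
    """Pooled 24 h mortality of a condition, with WHO classification.

    Pooled mortality is 100 * total dead / total exposed; the per-tube SD
    (reported as error bars in assay figures) is the SD across tube-level
    mortalities.  If ``control_mortality`` is given, Abbott's correction is
    applied before classification (only in its 5-20% validity band).
    """
    rows = _condition_rows(table, population, insecticide, synergist)
    _validate_counts(rows)
    n_total = int(rows["n_exposed"].sum())
    mortality = 100.0 * float(rows["n_dead_24h"].sum()) / n_total
    per_tube = 100.0 * rows["n_dead_24h"].to_numpy() / rows["n_exposed"].to_numpy()
    tube_sd = float(per_tube.std(ddof=1)) if len(per_tube) > 1 else 0.0

    corrected = mortality
    if control_mortality is not None:
        corrected = abbott_correct(mortality, control_mortality)
    classification = classify_susceptibility(
        corrected, thresholds=thresholds, paper_mode=paper_mode)
    return BioassaySummary(
        population=population,
        insecticide=insecticide,
        synergist=synergist,
        mortality=mortality,
        tube_sd=tube_sd,
        n_total=n_total,
        n_tubes=int(len(rows)),
        corrected_mortality=corrected,
        classification=classification,
        low_n=n_total < MIN_SPECIMENS,
    )


def abbott_correct(observed: float, control: float) -> float:
    """Abbott's correction of observed mortality for control mortality.

    WHO practice: below 5% control mortality no correction is applied;
    between 5 and 20% the correction
    100 * (observed - control) / (100 - control) is used; above 20% the
    run is invalid.
    Both arguments and the result are percentages.
    """
    if not 0.0 <= control < 100.0:
        raise ValueError(f"control mortality must be in [0, 100), got {control}")
    if not 0.0 <= observed <= 100.0:
        raise ValueError(f"observed mortality must be in [0, 100], got {observed}")
    if control > 20.0:
        raise ValueError(
            f"invalid run: control mortality {control:.1f}% exceeds 20%")
    if control < 5.0:
        return float(observed)
    return float(100.0 * (observed - control) / (100.0 - control))


def classify_susceptibility(mortality: float, thresholds: tuple = (90.0, 98.0),
                            paper_mode: bool = False) -> str:
    """WHO resistance classification from (corrected) percent mortality.

    Strictly below the first threshold (90%) is resistant; at or above the
    second (98%) is susceptible; between is "suspected" resistance.  With
    ``paper_mode=True`` the call collapses to resistant / not-resistant at
    the 90% rule only.
    """
    lo, hi = thresholds
    if not 0 < lo <= hi <= 100:
        raise ValueError(f"bad thresholds {thresholds}")
    if mortality < lo:
        return RESISTANT
    if paper_mode:
        return NOT_RESISTANT
    return SUSPECTED if mortality < hi else SUSCEPTIBLE


def synergist_effect(
    table: pd.DataFrame,
    population: str,
    insecticide: str,
    synergist: str,
) -> tuple[TestResult, str]:
    """Fisher exact test of mortality with vs without synergist pre-exposure.

    Tube counts are pooled into a single 2x2 dead/alive table per arm.
    Returns the test result and the direction of the mortality change
    ("increased", "decreased" or "unchanged" with the synergist).
    """
    without = _condition_rows(table, population, insecticide, "none")
    with_syn = _condition_rows(table, population, insecticide, synergist)
    _validate_counts(without)
    _validate_counts(with_syn)

    def pool(rows):
        dead = int(rows["n_dead_24h"].sum())
        alive = int(rows["n_exposed"].sum()) - dead
        return dead, alive

    d0, a0 = pool(without)
    d1, a1 = pool(with_syn)
    result = stats.fisher_exact([[d0, a0], [d1, a1]])
    m0 = d0 / (d0 + a0)
    m1 = d1 / (d1 + a1)
    direction = "increased" if m1 > m0 else ("decreased" if m1 < m0 else "unchanged")
    return result, direction


def compare_enzyme_activity(
    activities: pd.DataFrame,
    field_population: str,
    reference_population: str,
    enzyme_family: str,
) -> tuple[TestResult, str]:
    """Mann-Whitney comparison of enzyme activity, field vs reference strain.

    Returns the test result and the direction of the field median relative
    to the reference ("elevated", "reduced" or "equal").
    """
    fam = activities[activities["enzyme_family"] == enzyme_family]
    field = fam.loc[fam["population"] == field_population, "activity"].to_numpy()
    ref = fam.loc[fam["population"] == reference_population, "activity"].to_numpy()
    if field.size < 2 or ref.size < 2:
        raise ValueError(
            f"need >= 2 individuals per group for {enzyme_family!r} "
            f"({field_population}: {field.size}, {reference_population}: {ref.size})"
        )
    if (field < 0).any() or (ref < 0).any():
        raise ValueError("enzyme activities must be non-negative")
    result = stats.mann_whitney(field, ref)
    diff = float(np.median(field) - np.median(ref))
    direction = "elevated" if diff > 0 else ("reduced" if diff < 0 else "equal")
    return result, direction


def summarize_bioassay(table: pd.DataFrame, paper_mode: bool = False,
                       alpha: float = 0.05) -> pd.DataFrame:
    """Per-condition summary of a full bioassay table.

    One row per population x insecticide x synergist (controls excluded),
    with pooled mortality, SD, classification, and — for synergist arms —
    the Fisher exact P of the with/without comparison.
    """
    conditions = (
        table.loc[table["insecticide"] != "control",
                  ["population", "insecticide", "synergist"]]
        .drop_duplicates()
        .itertuples(index=False)
    )
    out = []
    for pop, ins, syn in conditions:
        summ = pooled_mortality(table, pop, ins, syn, paper_mode=paper_mode)
        row = {
            "population": pop, "insecticide": ins, "synergist": syn,
            "mortality_pct": summ.mortality, "tube_sd_pct": summ.tube_sd,
            "n_total": summ.n_total, "classification": summ.classification,
            "low_n": summ.low_n, "synergist_p": np.nan,
            "synergist_significant": pd.NA, "synergist_direction": pd.NA,
        }
        if syn != "none":
            try:
                res, direction = synergist_effect(table, pop, ins, syn)
                row["synergist_p"] = res.p_value
                row["synergist_significant"] = bool(res.p_value < alpha)
                row["synergist_direction"] = direction
            except ValueError:
                pass  # no matching no-synergist arm
        out.append(row)
    return pd.DataFrame(out)
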