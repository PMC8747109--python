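"""Per-observation colonization indices, aggregation, and frequency classes.

From one 10x10 coded grid, seven indices summarize the colonization of the
corresponding root fragment:

- frequency F (%): share of grid columns (positions along the root axis)
  containing at least one fungal structure — the root's primary
  permissiveness toward the symbiont;
- intensity I (%): share of the 100 cells occupied by any structure —
  secondary permissiveness;
- arbuscule abundance Arb (%) and vesicle abundance Ves (%): share of cells
  holding the respective structure (as % of all cells, not of colonized
  cells);
- colonization degree Cdeg = F*I/100 (%): volumetric synthesis of extension
  along and within the root;
- non-mycorrhizal area nonM = 100 - I (%);
- mycorrhizal/non-mycorrhizal ratio M/nonM = I/(100 - I).

Because a column has 10 cells, I <= F always (pigeonhole), and
nonM + I = 100 holds exactly by construction.

Frequency classes M1..M5 partition [0, 100] into five 20-point bins and act
as the coding variable of the downstream statistics.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd

from .grid_model import GRID_SIZE, N_CELLS, ColonizationGrid, ObservationID, StructureCode

logger = logging.getLogger(__name__)

#: ratio reported for a fully colonized observation (I = 100): the ratio
#: I/(100-I) diverges, and 99.0 is used as the documented saturation value.
RATIO_CAP = 99.0

#: canonical order of the seven indices in tables and reports
INDEX_COLUMNS = [
    "frequency",
    "intensity",
    "arbuscules",
    "vesicles",
    "colonization_degree",
    "non_mycorrhizal",
    "m_nonm_ratio",
]

INDEX_TABLE_COLUMNS = ["replication", "segment", "field"] + INDEX_COLUMNS + ["freq_class"]


@dataclass(frozen=True)
class ColonizationRecord:
    """The seven colonization indices of one observation."""

    id: ObservationID
    frequency_pct: float
    intensity_pct: float
    arbuscules_pct: float
    vesicles_pct: float
    colonization_degree_pct: float
    non_mycorrhizal_pct: float
    m_nonm_ratio: float


@dataclass(frozen=True)
class FrequencyClass:
    """One of the five 20%-wide colonization-frequency classes M1..M5."""

    label: str
    lower_pct: float
    upper_pct: float


#: M1 = [0, 20], M2 = (20, 40], ..., M5 = (80, 100] — half-open on the left
#: except M1, so the five classes partition [0, 100] exactly.
FREQUENCY_CLASSES = [
    FrequencyClass("M1", 0.0, 20.0),
    FrequencyClass("M2", 20.0, 40.0),
    FrequencyClass("M3", 40.0, 60.0),
    FrequencyClass("M4", 60.0, 80.0),
    FrequencyClass("M5", 80.0, 100.0),
]

CLASS_LABELS = [fc.label for fc in FREQUENCY_CLASSES]


def complement_non_mycorrhizal(intensity_pct: float) -> float:
    """Non-mycorrhizal area from intensity: nonM = 100 - I, exactly."""
    return 100.0 - intensity_pct


def ratio_from_intensity(intensity_pct: float) -> float:
    """M/nonM ratio from intensity: I/(100 - I), capped at RATIO_CAP when
    the observation is fully colonized."""
    if intensity_pct >= 100.0:
        return RATIO_CAP
    return intensity_pct / (100.0 - intensity_pct)


def compute_indices(grid: ColonizationGrid) -> ColonizationRecord:
    """Compute the seven colonization indices of one grid.

    With 100 cells, raw counts are already percentages: I is the number of
    non-empty cells, F is 10x the number of columns containing any
    structure, Arb/Ves are the arbuscule/vesicle cell counts.
    """
    occupied = grid.cells != StructureCode.EMPTY
    intensity = float(occupied.sum())
    frequency = 10.0 * float(occupied.any(axis=0).sum())
    arb = float((grid.cells == StructureCode.ARBUSCULE).sum())
    ves = float((grid.cells == StructureCode.VESICLE).sum())
    if intensity >= N_CELLS:
        logger.warning("grid %s fully colonized; M/nonM ratio capped at %s",
                       grid.id, RATIO_CAP)
    return ColonizationRecord(
        id=grid.id,
        frequency_pct=frequency,
        intensity_pct=intensity,
        arbuscules_pct=arb,
        vesicles_pct=ves,
        colonization_degree_pct=frequency * intensity / 100.0,
        non_mycorrhizal_pct=complement_non_mycorrhizal(intensity),
        m_nonm_ratio=ratio_from_intensity(intensity),
    )


def assign_class(frequency_pct: float) -> FrequencyClass:
    """Map a colonization frequency to its class M1..M5.

    Boundaries belong to the lower class: 20.0 -> M1, 20.5 -> M2, 100 -> M5.
    """
    if not 0.0 <= frequency_pct <= 100.0:
        raise ValueError(f"frequency {frequency_pct} outside [0, 100]")
    idx = max(1, math.ceil(frequency_pct / 20.0)) - 1
    return FREQUENCY_CLASSES[idx]


def records_to_frame(records: Iterable[ColonizationRecord]) -> pd.DataFrame:
    """Tabulate records as the standard index table (one row per observation)."""
    rows = []
    for rec in records:
        rows.append(
            (
                *rec.id,
                rec.frequency_pct,
                rec.intensity_pct,
                rec.arbuscules_pct,
                rec.vesicles_pct,
                rec.colonization_degree_pct,
                rec.non_mycorrhizal_pct,
                rec.m_nonm_ratio,
                assign_class(rec.frequency_pct).label,
            )
        )
    if not rows:
        raise ValueError("no records")
    return pd.DataFrame(rows, columns=INDEX_TABLE_COLUMNS)


@dataclass(frozen=True)
class AggregateRecord:
    """Group mean and standard error for every index, plus group size."""

    key: object
    n: int
    means: dict[str, float]
    ses: dict[str, float]


def aggregate(
    records: Sequence[ColonizationRecord] | pd.DataFrame,
    by: str | Callable[[pd.Series], object] = "freq_class",
) -> list[AggregateRecord]:
    """Group records and compute mean and standard error of each index.

    ``by`` is a column of the index table (``freq_class``, ``segment``,
    ``replication``) or a callable applied row-wise to derive the key.
    The standard error is s/sqrt(n) with the sample (n-1) standard
    deviation; a singleton group reports se = 0.
    """
    df = records if isinstance(records, pd.DataFrame) else records_to_frame(records)
    if df.empty:
        raise ValueError("no records to aggregate")
    keys = df.apply(by, axis=1) if callable(by) else df[by]
    out = []
    for key, sub in df.groupby(keys, sort=True):
        n = len(sub)
        means = {c: float(sub[c].mean()) for c in INDEX_COLUMNS}
        if n > 1:
            ses = {c: float(sub[c].std(ddof=1) / math.sqrt(n)) for c in INDEX_COLUMNS}
        else:
            ses = {c: 0.0 for c in INDEX_COLUMNS}
        out.append(AggregateRecord(key=key, n=n, means=means, ses=ses))
    return out


def summarize_by_class(
    records: Sequence[ColonizationRecord] | pd.DataFrame,
) -> pd.DataFrame:
    """Class-level summary table: mean, se and n of each index per M1..M5 row.

    Classes with no members are omitted (with a logged warning). Columns are
    a (index, statistic) MultiIndex plus a trailing ``n`` level.
    """
    df = records if isinstance(records, pd.DataFrame) else records_to_frame(records)
    aggs = aggregate(df, by="freq_class")
    present = [a.key for a in aggs]
    for label in CLASS_LABELS:
        if label not in present:
            logger.warning("frequency class %s has no observations; omitted", label)
    rows = {}
    for a in aggs:
        row = {}
        for c in INDEX_COLUMNS:
            row[(c, "mean")] = a.means[c]
            row[(c, "se")] = a.ses[c]
        row[("n", "")] = a.n
        rows[a.key] = row
    out = pd.DataFrame.from_dict(rows, orient="index")
    out.index.name = "freq_class"
    return out.loc[[c for c in CLASS_LABELS if c in out.index]]
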