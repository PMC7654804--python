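"""Electrolyte-leakage phenotyping for heat-tolerance screens.

Membrane damage after heat stress is scored by relative electrical
conductivity (REC): the conductivity of a leaf-disc soak (``S1``) as a
percentage of the conductivity after boiling the same tissue (``S2``),
which releases all electrolytes.  Leaf relative injury (LRI) rescales the
heat-induced REC increase by the remaining headroom,

    LRI = (Lt - Lck) / (100 - Lck) * 100,

with ``Lck`` the pre-heat REC and ``Lt`` the post-heat REC, so a larger
LRI means more membrane damage, i.e. less heat tolerance.  Plants are
classified tolerant/sensitive against an LRI threshold (default 10%),
and the phenotypic extremes of a segregating population are pooled into
the tolerant/sensitive bulks that feed the QTL-seq scan.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

TOLERANT = "tolerant"
SENSITIVE = "sensitive"

#: Default LRI classification threshold, percent.
LRI_THRESHOLD = 10.0


class InvalidReadingError(ValueError):
    """A conductivity reading violates its physical constraints."""


class BulkConstructionError(ValueError):
    """Extreme bulks cannot be formed as requested."""


@dataclass(frozen=True)
class EcReading:
    """One plant's conductivity readings, pre- and post-heat.

    ``s1_*`` is the fresh-tissue conductivity, ``s2_*`` the conductivity
    after boiling; the boiled sample always leaks at least as much.
    """

    plant_id: str
    s1_before: float
    s2_before: float
    s1_after: float
    s2_after: float

    def __post_init__(self) -> None:
        for s1, s2 in ((self.s1_before, self.s2_before), (self.s1_after, self.s2_after)):
            if s2 <= 0 or s1 < 0 or s1 > s2:
                raise InvalidReadingError(
                    f"{self.plant_id}: conductances must satisfy 0 <= s1 <= s2, s2 > 0 "
                    f"(got s1={s1}, s2={s2})"
                )


@dataclass(frozen=True)
class PlantPhenotype:
    """Derived per-plant phenotype: REC before/after heat, LRI and class."""

    plant_id: str
    rec_ck: float  # pre-heat REC, percent (Lck)
    rec_t: float   # post-heat REC, percent (Lt)
    lri: float     # percent; may be negative for transgressive low segregants
    reaction: str  # TOLERANT or SENSITIVE


@dataclass(frozen=True)
class GroupSummary:
    """LRI summary for a labelled group of plants (mean ± s.e., range)."""

    label: str
    n: int
    mean: float
    se: float
    min: float
    max: float


def compute_rec(s1: float, s2: float) -> float:
    """Relative electrical conductivity, percent: ``S1 / S2 * 100``."""
    if s2 <= 0:
        raise InvalidReadingError(f"boiled-sample conductance must be positive (got {s2})")
    if s1 < 0 or s1 > s2:
        raise InvalidReadingError(f"fresh-sample conductance must lie in [0, s2] (got {s1})")
    return s1 / s2 * 100.0


def compute_lri(lt: float, lck: float) -> float:
    """Leaf relative injury, percent: ``(Lt - Lck) / (100 - Lck) * 100``.

    ``lck`` is the pre-heat (control) REC, ``lt`` the post-heat REC.
    The value may be negative when a plant leaks less after heat than
    before; such transgressive values are reported as computed, not
    clipped.
    """
    if lck >= 100.0:
        raise InvalidReadingError(f"control REC of {lck}% leaves no headroom for injury")
    return (lt - lck) / (100.0 - lck) * 100.0


def classify_reaction(lri: float, threshold: float = LRI_THRESHOLD) -> str:
    """Classify a plant tolerant (``lri < threshold``) or sensitive.

    The boundary value is assigned sensitive: tolerance is defined by a
    strict ``LRI < threshold`` and sensitivity by ``LRI >= threshold``.
    """
    if not math.isfinite(lri):
        raise InvalidReadingError(f"LRI must be finite (got {lri})")
    return TOLERANT if lri < threshold else SENSITIVE


def phenotype_from_reading(
    reading: EcReading, threshold: float = LRI_THRESHOLD
) -> PlantPhenotype:
    """Derive REC, LRI and reaction class from raw conductivities."""
    rec_ck = compute_rec(reading.s1_before, reading.s2_before)
    rec_t = compute_rec(reading.s1_after, reading.s2_after)
    lri = compute_lri(rec_t, rec_ck)
    return PlantPhenotype(reading.plant_id, rec_ck, rec_t, lri, classify_reaction(lri, threshold))


def _lri_values(group: Iterable) -> np.ndarray:
    vals = [p.lri if isinstance(p, PlantPhenotype) else float(p) for p in group]
    return np.asarray(vals, dtype=float)


def summarize_group(phenotypes: Sequence, label: str = "") -> GroupSummary:
    """Mean, standard error (sd/sqrt(n)), min and max of a group's LRI."""
    lri = _lri_values(phenotypes)
    if lri.size == 0:
        raise ValueError("cannot summarize an empty group")
    se = float(lri.std(ddof=1) / math.sqrt(lri.size)) if lri.size > 1 else 0.0
    return GroupSummary(label, int(lri.size), float(lri.mean()), se,
                        float(lri.min()), float(lri.max()))


def welch_t(group_a: Sequence, group_b: Sequence) -> Tuple[float, float]:
    """Two-sided Welch t-test on LRI values; returns ``(statistic, p)``."""
    a, b = _lri_values(group_a), _lri_values(group_b)
    if a.size < 2 or b.size < 2:
        raise ValueError("Welch t-test needs at least two observations per group")
    res = stats.ttest_ind(a, b, equal_var=False)
    return float(res.statistic), float(res.pvalue)


@dataclass(frozen=True)
class BulkSelection:
    """Plant ids in the tolerant (low-LRI) and sensitive (high-LRI) bulks."""

    tolerant_ids: Tuple[str, ...]
    sensitive_ids: Tuple[str, ...]


def select_bulks(
    phenotypes: Sequence[PlantPhenotype],
    n_per_bulk: int = 9,
    low_range: Optional[Tuple[float, float]] = None,
    high_range: Optional[Tuple[float, float]] = None,
) -> BulkSelection:
    """Select the two extreme bulks from a segregating population.

    The ``n_per_bulk`` lowest-LRI plants form the tolerant bulk and the
    ``n_per_bulk`` highest-LRI plants the sensitive bulk.  Ties at a
    cutoff are broken by plant id for determinism.  If LRI ranges are
    supplied (e.g. ``(1, 5)`` and ``(55, 77)``), every selected member
    must fall inside the respective range.
    """
    if n_per_bulk < 1:
        raise BulkConstructionError("n_per_bulk must be >= 1")
    if len(phenotypes) < 2 * n_per_bulk:
        raise BulkConstructionError(
            f"population of {len(phenotypes)} cannot supply two disjoint bulks of {n_per_bulk}"
        )
    ranked = sorted(phenotypes, key=lambda p: (p.lri, p.plant_id))
    low = ranked[:n_per_bulk]
    high = ranked[-n_per_bulk:]
    low_ids = {p.plant_id for p in low}
    if any(p.plant_id in low_ids for p in high):
        raise BulkConstructionError("bulks overlap; population too small or duplicated ids")
    for members, rng, name in ((low, low_range, "tolerant"), (high, high_range, "sensitive")):
        if rng is not None:
            lo, hi = rng
            bad = [p.plant_id for p in members if not (lo <= p.lri <= hi)]
            if bad:
                raise BulkConstructionError(
                    f"{name}-bulk members outside LRI range {rng}: {bad}"
                )
    return BulkSelection(tuple(p.plant_id for p in low), tuple(p.plant_id for p in high))


# ---------------------------------------------------------------------------
# Tabular I/O

def phenotype_table(
    readings: pd.DataFrame, threshold: float = LRI_THRESHOLD
) -> pd.DataFrame:
    """Compute REC/LRI/reaction columns from a readings table.

    Accepts either raw conductivities (columns ``plant_id, s1_before,
    s2_before, s1_after, s2_after``) or precomputed ``rec_ck, rec_t``.
    """
    df = readings.copy()
    if {"s1_before", "s2_before", "s1_after", "s2_after"}.issubset(df.columns):
        df["rec_ck"] = [compute_rec(a, b) for a, b in zip(df.s1_before, df.s2_before)]
        df["rec_t"] = [compute_rec(a, b) for a, b in zip(df.s1_after, df.s2_after)]
    elif not {"rec_ck", "rec_t"}.issubset(df.columns):
        raise ValueError("need s1/s2 conductance columns or precomputed rec_ck/rec_t")
    df["lri"] = [compute_lri(t, ck) for t, ck in zip(df.rec_t, df.rec_ck)]
    df["reaction"] = [classify_reaction(x, threshold) for x in df.lri]
    return df


def read_phenotypes(path, threshold: float = LRI_THRESHOLD) -> pd.DataFrame:
    """Read a phenotype TSV and derive REC/LRI/reaction columns."""
    return phenotype_table(pd.read_csv(path, sep="\t"), threshold)


def phenotypes_from_table(df: pd.DataFrame) -> list[PlantPhenotype]:
    """Convert a derived phenotype table into ``PlantPhenotype`` records."""
    return [
        PlantPhenotype(str(r.plant_id), float(r.rec_ck), float(r.rec_t),
                       float(r.lri), str(r.reaction))
        for r in df.itertuples()
    ]


def write_bulks(selection: BulkSelection, path) -> None:
    """Write bulk membership as a two-column TSV (plant_id, bulk T/S)."""
    rows = [(pid, "T") for pid in selection.tolerant_ids] + [
        (pid, "S") for pid in selection.sensitive_ids
    ]
    pd.DataFrame(rows, columns=["plant_id", "bulk"]).to_csv(path, sep="\t", index=False)
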