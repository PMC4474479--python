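"""Hit calling: fold-change cutoffs, toxicity exclusion, review flags.

Toxicity is evaluated first (a dying well says nothing about foci);
surviving wells are then classified by fold change with *inclusive* cutoffs
(fold <= 0.5 suppressor, fold >= 1.5 persistence).  A high per-nucleus
sub-threshold granule tally raises a non-blocking review flag, automating
the visual secondary screen that catches the "many tiny foci" artifact.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import pandas as pd

from .params import HitCriteria
from .quantify import NormalizedScore, WellQuant

CALL_TOXIC = "toxic"
CALL_SUPPRESSOR = "suppressor_hit"
CALL_PERSISTENCE = "persistence_hit"
CALL_NONE = "none"
CALLS = (CALL_PERSISTENCE, CALL_SUPPRESSOR, CALL_TOXIC, CALL_NONE)

FLAG_SUB_THRESHOLD = "sub_threshold_review"
FLAG_LOW_NUCLEI = "low_nuclei_count"


@dataclass(frozen=True)
class ScreenScore:
    """Final per-well classification with its supporting numbers."""

    well_id: str
    plate_id: str
    compound_id: str
    concentration_um: float
    timepoint_h: float
    fold_foci: float
    fold_nuclei: float
    call: str
    flags: frozenset = field(default_factory=frozenset)


def call_hit(
    score: NormalizedScore | None,
    quant: WellQuant,
    criteria: HitCriteria | None = None,
    compound_id: str = "",
    concentration_um: float = float("nan"),
    timepoint_h: float = float("nan"),
) -> ScreenScore:
    """Classify one well.

    A degenerate (zero-nucleus) well has no normalized score and is called
    toxic with the ``low_nuclei_count`` flag; otherwise toxicity precedes the
    fold-change classification, and the two fold cutoffs are inclusive.
    """
    if criteria is None:
        criteria = HitCriteria()
    flags = set()
    if not math.isnan(quant.mean_sub_threshold) and (
        quant.mean_sub_threshold >= criteria.sub_threshold_flag_level
    ):
        flags.add(FLAG_SUB_THRESHOLD)

    if quant.degenerate or score is None:
        flags.add(FLAG_LOW_NUCLEI)
        call, fold_foci, fold_nuclei = CALL_TOXIC, float("nan"), 0.0
    else:
        fold_foci, fold_nuclei = score.fold_foci, score.fold_nuclei
        if fold_nuclei < criteria.toxicity_cutoff:
            call = CALL_TOXIC
        elif fold_foci <= criteria.suppression_cutoff:
            call = CALL_SUPPRESSOR
        elif fold_foci >= criteria.persistence_cutoff:
            call = CALL_PERSISTENCE
        else:
            call = CALL_NONE

    return ScreenScore(
        well_id=quant.well_id,
        plate_id=quant.plate_id,
        compound_id=compound_id,
        concentration_um=concentration_um,
        timepoint_h=timepoint_h,
        fold_foci=fold_foci,
        fold_nuclei=fold_nuclei,
        call=call,
        flags=frozenset(flags),
    )


@dataclass(frozen=True)
class ScreenSummary:
    """Per-class counts and the hit rate over all scored wells."""

    n_scored: int
    n_persistence: int
    n_suppressor: int
    n_toxic: int
    n_none: int
    hit_rate_pct: float  # hits / scored wells, toxic wells in the denominator
    by_concentration: pd.DataFrame


def summarize_screen(scores: list[ScreenScore]) -> ScreenSummary:
    """Summarize calls; the hit rate counts both hit classes over all wells."""
    if not scores:
        raise ValueError("summarize_screen needs at least one score")
    df = scores_to_frame(scores)
    counts = df["call"].value_counts()
    n = len(df)
    hits = int(counts.get(CALL_PERSISTENCE, 0) + counts.get(CALL_SUPPRESSOR, 0))
    by_conc = (
        df.groupby("concentration_um", dropna=False)["call"]
        .value_counts()
        .unstack(fill_value=0)
        .reindex(columns=list(CALLS), fill_value=0)
        .reset_index()
    )
    return ScreenSummary(
        n_scored=n,
        n_persistence=int(counts.get(CALL_PERSISTENCE, 0)),
        n_suppressor=int(counts.get(CALL_SUPPRESSOR, 0)),
        n_toxic=int(counts.get(CALL_TOXIC, 0)),
        n_none=int(counts.get(CALL_NONE, 0)),
        hit_rate_pct=100.0 * hits / n,
        by_concentration=by_conc,
    )


def scores_to_frame(scores: list[ScreenScore]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "plate_id": s.plate_id,
                "well_id": s.well_id,
                "compound_id": s.compound_id,
                "concentration_um": s.concentration_um,
                "timepoint_h": s.timepoint_h,
                "fold_foci": s.fold_foci,
                "fold_nuclei": s.fold_nuclei,
                "call": s.call,
                "flags": ";".join(sorted(s.flags)),
            }
            for s in scores
        ]
    )
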