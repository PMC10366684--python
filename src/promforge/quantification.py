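"""Gate large-particle flow-cytometry events and summarize reporter expression.

Events carry, per animal: time of flight (TOF, a size proxy), peak-height
extinction (optical density proxy), and peak-height green fluorescence.
Adults are selected with an inclusive TOF window and a strict extinction
ceiling; per-strain green means are reported raw, baseline-subtracted
against a non-transgenic control, and/or as a ratio to that control. The
two normalizations are never mixed silently: the mode travels with the
output.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

EVENT_COLUMNS = ("strain", "tof", "extinction", "green")

PATTERNS = ("somatic_and_germline", "none", "germline_specific")


class MissingStrainError(KeyError):
    pass


@dataclass(frozen=True)
class GatingConfig:
    """Adult gate: ``tof_min <= tof <= tof_max`` and ``extinction < extinction_max``.

    TOF bounds are inclusive and the extinction bound strict ("below");
    both conventions are configurable and recorded in output metadata.
    """

    tof_min: float = 1500.0
    tof_max: float = 1800.0
    extinction_max: float = 35000.0

    def __post_init__(self) -> None:
        if not self.tof_min < self.tof_max:
            raise ValueError("tof_min must be < tof_max")
        if not self.extinction_max > 0:
            raise ValueError("extinction_max must be positive")

    def describe(self) -> str:
        return (
            f"tof in [{self.tof_min}, {self.tof_max}] (inclusive), "
            f"extinction < {self.extinction_max} (strict)"
        )


def validate_events(events: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in EVENT_COLUMNS if c not in events.columns]
    if missing:
        raise ValueError(f"event table missing columns: {missing}")
    if (events["tof"] < 0).any() or (events["extinction"] < 0).any():
        raise ValueError("tof and extinction must be non-negative")
    return events


def gate_adults(
    events: pd.DataFrame, config: GatingConfig = GatingConfig()
) -> pd.DataFrame:
    """Subset of events passing the adult gate, original order preserved."""
    validate_events(events)
    keep = (
        (events["tof"] >= config.tof_min)
        & (events["tof"] <= config.tof_max)
        & (events["extinction"] < config.extinction_max)
    )
    return events.loc[keep]


@dataclass(frozen=True)
class StrainSummary:
    strain: str
    n_gated: int
    mean_green: float
    sem_green: float | None  # undefined for n < 2
    baseline_subtracted_mean: float | None = None
    relative_to_control: float | None = None
    relative_mode: str | None = None


def summarize_strain(gated: pd.DataFrame, strain: str) -> StrainSummary:
    """Mean and SEM (n-1 sample SD / sqrt(n)) of green for one strain."""
    sub = gated.loc[gated["strain"] == strain, "green"]
    n = len(sub)
    if n == 0:
        raise MissingStrainError(f"no gated events for strain {strain!r}")
    mean = float(sub.mean())
    sem = float(sub.std(ddof=1) / math.sqrt(n)) if n >= 2 else None
    return StrainSummary(strain=strain, n_gated=n, mean_green=mean, sem_green=sem)


def summarize_strains(gated: pd.DataFrame) -> list[StrainSummary]:
    return [
        summarize_strain(gated, s) for s in sorted(gated["strain"].unique())
    ]


def baseline_subtract(
    summaries: list[StrainSummary], control_strain: str
) -> list[StrainSummary]:
    """Subtract the control's mean green from every strain's mean.

    The control itself maps to exactly 0; between-strain differences are
    preserved exactly.
    """
    control = _find(summaries, control_strain)
    return [
        replace(s, baseline_subtracted_mean=s.mean_green - control.mean_green)
        for s in summaries
    ]


def relative_to_control(
    summaries: list[StrainSummary],
    control_strain: str,
    mode: str = "difference",
) -> list[StrainSummary]:
    """Normalize strain means to the control, by difference or by ratio."""
    if mode not in ("difference", "ratio"):
        raise ValueError(f"mode must be 'difference' or 'ratio', got {mode!r}")
    control = _find(summaries, control_strain)
    if mode == "ratio" and control.mean_green == 0:
        raise ZeroDivisionError(
            f"control strain {control_strain!r} has zero mean green; "
            "ratio normalization undefined"
        )
    out = []
    for s in summaries:
        if mode == "difference":
            value = s.mean_green - control.mean_green
        else:
            value = s.mean_green / control.mean_green
        out.append(replace(s, relative_to_control=value, relative_mode=mode))
    return out


def _find(summaries: list[StrainSummary], strain: str) -> StrainSummary:
    for s in summaries:
        if s.strain == strain:
            return s
    raise MissingStrainError(f"control strain {strain!r} not in summaries")


@dataclass(frozen=True)
class VisualScore:
    """Blinded per-plate visual score on the 0-4 scale (0 = no expression at
    high magnification, 4 = visible at lowest magnification without zoom)."""

    strain: str  # possibly a blind code
    plate: int
    score: int

    def __post_init__(self) -> None:
        if self.score not in (0, 1, 2, 3, 4):
            raise ValueError(f"score must be an integer 0-4, got {self.score}")


def score_summary(
    scores: list[VisualScore],
    blinding: dict[str, str] | None = None,
) -> pd.DataFrame:
    """Per-strain mean and SEM of plate-replicate scores.

    *blinding* maps blind codes to true strain names and is applied before
    aggregation; an unknown code raises. Returns a frame indexed by strain
    with columns ``n_plates, mean_score, sem_score``.
    """
    rows = []
    for s in scores:
        if blinding is not None:
            if s.strain not in blinding:
                raise KeyError(f"unknown blind code {s.strain!r}")
            name = blinding[s.strain]
        else:
            name = s.strain
        rows.append({"strain": name, "score": s.score})
    df = pd.DataFrame(rows)
    grouped = df.groupby("strain")["score"]
    out = pd.DataFrame(
        {
            "n_plates": grouped.size(),
            "mean_score": grouped.mean(),
            "sem_score": grouped.apply(
                lambda g: g.std(ddof=1) / math.sqrt(len(g)) if len(g) >= 2 else np.nan
            ),
        }
    )
    return out.sort_index()


@dataclass(frozen=True)
class ExpressionPatternRecord:
    promoter: str
    pattern: str

    def __post_init__(self) -> None:
        if self.pattern not in PATTERNS:
            raise ValueError(
                f"pattern must be one of {PATTERNS}, got {self.pattern!r}"
            )


def classify_and_count(
    records: list[ExpressionPatternRecord],
) -> dict[str, int]:
    """Counts over the closed pattern set; every promoter appears once."""
    seen = Counter(r.promoter for r in records)
    dups = [p for p, n in seen.items() if n > 1]
    if dups:
        raise ValueError(f"duplicate promoters in pattern records: {dups}")
    counts = {p: 0 for p in PATTERNS}
    for r in records:
        counts[r.pattern] += 1
    return counts


def summaries_frame(summaries: list[StrainSummary]) -> pd.DataFrame:
    """Tabular view for TSV export."""
    return pd.DataFrame(
        [
            {
                "strain": s.strain,
                "n": s.n_gated,
                "mean": s.mean_green,
                "sem": s.sem_green,
                "baseline_subtracted": s.baseline_subtracted_mean,
                "relative_mode": s.relative_mode,
                "relative_value": s.relative_to_control,
            }
            for s in summaries
        ]
    )
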