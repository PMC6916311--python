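"""Processing of elicited opinions on trial bias into normal distributions.

An assessor states an interquartile range (IQR) for the ratio of odds ratios
expected in a trial, either on a plain scale (strategy a), on a scale overlaid
on the data-based bias distribution (strategy b), or by selecting quartile
areas of that distribution (strategy c).  Numeric IQRs are rounded to a 0.02
grid on the log-ROR scale and mapped to a normal via IQR = mean +/- 0.67 sd;
area selections are first converted to the quartiles of the corresponding
truncated normal.  Per-trial distributions are pooled across assessors by
taking medians of means and medians of standard deviations, so the pooled
distribution represents a typical assessor and is robust to extreme opinions.
"""

from __future__ import annotations

import math
import statistics
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from scipy.stats import norm

from .data_model import (
    AREAS,
    BiasDistribution,
    ElicitationRecord,
    FormatError,
    ValidationError,
)

__all__ = [
    "GRID",
    "IQR_Z",
    "AssessorNormal",
    "area_to_iqr",
    "area_opinion_to_normal",
    "iqr_to_normal",
    "pool_assessors",
    "pooled_bias_distributions",
    "process_elicitations",
    "read_assessor_normals",
    "round_log_ror",
    "write_assessor_normals",
]

#: rounding grid on the log-ROR scale
GRID = 0.02

#: the 75th standard-normal percentile rounded to 2 dp; stored once and never
#: recomputed as Phi^-1(0.75) ~= 0.6745 because the elicitation arithmetic
#: uses 0.67 exactly
IQR_Z = 0.67


@dataclass(frozen=True)
class AssessorNormal:
    """One assessor's processed opinion: a normal on the log-ROR scale."""

    assessor_id: str
    trial_id: str
    mean: float
    sd: float
    strategy: str = ""

    def __post_init__(self) -> None:
        if not (self.sd > 0 and math.isfinite(self.sd)):
            raise ValidationError(
                f"assessor normal sd must be > 0 (assessor {self.assessor_id}, "
                f"trial {self.trial_id})"
            )


def _grid_index(x: float) -> int:
    """Index of the nearest 0.02 grid point; exact midpoints round half away
    from zero (a 1e-9 guard absorbs binary representation error)."""
    y = x / GRID
    return int(math.copysign(math.floor(abs(y) + 0.5 + 1e-9), y))


def round_log_ror(x: float) -> float:
    """Round a log-ROR to the nearest multiple of 0.02 (ties away from zero)."""
    if not math.isfinite(x):
        raise ValidationError(f"log-ROR must be finite, got {x}")
    return _grid_index(x) * GRID


def iqr_to_normal(
    lower_ror: float,
    upper_ror: float,
    assessor_id: str = "",
    trial_id: str = "",
    strategy: str = "",
) -> AssessorNormal:
    """Map an elicited IQR on the ROR scale to a normal on the log-ROR scale.

    Both endpoints are rounded to the 0.02 log grid; the IQR is then read as
    mean +/- 0.67 sd under normality.
    """
    if not (0 < lower_ror < upper_ror) or not (
        math.isfinite(lower_ror) and math.isfinite(upper_ror)
    ):
        raise ValidationError(
            f"require 0 < lower < upper on the ROR scale, got ({lower_ror}, {upper_ror})"
        )
    k_lo = _grid_index(math.log(lower_ror))
    k_hi = _grid_index(math.log(upper_ror))
    if k_lo == k_hi:
        raise ValidationError(
            f"elicited IQR ({lower_ror}, {upper_ror}) collapses to a single grid "
            f"point after 0.02 rounding (zero-width opinion)"
        )
    lo, hi = k_lo * GRID, k_hi * GRID
    return AssessorNormal(
        assessor_id=assessor_id,
        trial_id=trial_id,
        mean=(lo + hi) / 2.0,
        sd=(hi - lo) / (2.0 * IQR_Z),
        strategy=strategy,
    )


def _area_bounds(areas: Sequence[str]) -> tuple[float, float]:
    labels = tuple(areas)
    if not labels:
        raise ValidationError("area selection must be non-empty")
    idx = sorted(AREAS.index(a) for a in labels)
    if len(set(idx)) != len(idx) or idx[-1] - idx[0] + 1 != len(idx):
        raise ValidationError(f"areas must be a contiguous selection, got {labels}")
    return 0.25 * idx[0], 0.25 * (idx[-1] + 1)


def area_to_iqr(
    reference: BiasDistribution, areas: Sequence[str]
) -> tuple[float, float]:
    """Quartiles (25%, 75%) of the reference normal truncated to the selected
    quartile areas, on the log-ROR scale.

    A, B, C, D are the four quartile regions of the reference distribution
    (A below its 25th percentile, D above its 75th); the outer areas extend to
    +/- infinity in probability terms. For a contiguous union with cumulative
    bounds (p_lo, p_hi) the truncated quartiles are the reference quantiles at
    p_lo + 0.25 (p_hi - p_lo) and p_lo + 0.75 (p_hi - p_lo).
    """
    p_lo, p_hi = _area_bounds(areas)
    q25 = p_lo + 0.25 * (p_hi - p_lo)
    q75 = p_lo + 0.75 * (p_hi - p_lo)
    lower = reference.mean + reference.sd * norm.ppf(q25)
    upper = reference.mean + reference.sd * norm.ppf(q75)
    return float(lower), float(upper)


def area_opinion_to_normal(
    reference: BiasDistribution,
    areas: Sequence[str],
    assessor_id: str = "",
    trial_id: str = "",
) -> AssessorNormal:
    """Convert an area selection into an assessor normal.

    The truncated-normal quartiles pass through the same 0.02 log-grid
    rounding as numerically elicited IQRs, for uniform processing.
    """
    lower, upper = area_to_iqr(reference, areas)
    return iqr_to_normal(
        math.exp(lower), math.exp(upper), assessor_id, trial_id, strategy="c"
    )


def pool_assessors(
    opinions: Sequence[AssessorNormal], source: str = "opinion"
) -> BiasDistribution:
    """Pool per-assessor normals for one trial: median of means, median of
    standard deviations (midpoint-of-central-pair for even counts)."""
    if not opinions:
        raise ValidationError("cannot pool an empty list of assessor opinions")
    trial_ids = {o.trial_id for o in opinions}
    if len(trial_ids) != 1:
        raise ValidationError(f"mixed trial_ids in pooling: {sorted(trial_ids)}")
    return BiasDistribution(
        mean=float(statistics.median(o.mean for o in opinions)),
        sd=float(statistics.median(o.sd for o in opinions)),
        source=source,
    )


def process_elicitations(
    records: Iterable[ElicitationRecord],
    references: Mapping[str, BiasDistribution] | None = None,
) -> list[AssessorNormal]:
    """Convert raw elicitation records to assessor normals.

    Strategies a and b follow the identical numeric-IQR path (the strategy
    label is kept only for grouping); strategy c requires the trial's
    data-based reference distribution in ``references``.
    """
    out: list[AssessorNormal] = []
    for rec in records:
        if rec.strategy in ("a", "b"):
            out.append(
                iqr_to_normal(
                    rec.lower_ror,
                    rec.upper_ror,
                    rec.assessor_id,
                    rec.trial_id,
                    strategy=rec.strategy,
                )
            )
        else:
            if references is None or rec.trial_id not in references:
                raise ValidationError(
                    f"strategy c requires a data-based reference distribution for "
                    f"trial {rec.trial_id!r}"
                )
            out.append(
                area_opinion_to_normal(
                    references[rec.trial_id], rec.areas, rec.assessor_id, rec.trial_id
                )
            )
    return out


def pooled_bias_distributions(
    records: Iterable[ElicitationRecord],
    references: Mapping[str, BiasDistribution] | None = None,
    strategy: str | None = None,
) -> dict[str, BiasDistribution]:
    """Pool elicitations per trial into bias distributions.

    ``strategy`` filters records first; if omitted, all records for a trial
    must share one strategy (methods are defined per strategy).
    """
    records = list(records)
    if strategy is not None:
        records = [r for r in records if r.strategy == strategy]
        if not records:
            raise ValidationError(f"no elicitation records with strategy {strategy!r}")
    normals = process_elicitations(records, references)
    by_trial: dict[str, list[AssessorNormal]] = {}
    for n in normals:
        by_trial.setdefault(n.trial_id, []).append(n)
    out: dict[str, BiasDistribution] = {}
    for trial_id, group in by_trial.items():
        strategies = {g.strategy for g in group}
        if len(strategies) != 1:
            raise ValidationError(
                f"trial {trial_id!r} mixes strategies {sorted(strategies)}; "
                f"pass an explicit strategy filter"
            )
        source = "area" if strategies == {"c"} else "opinion"
        out[trial_id] = pool_assessors(group, source=source)
    return out


_ASSESSOR_COLUMNS = ("assessor_id", "trial_id", "strategy", "mean", "sd")


def write_assessor_normals(
    normals: Iterable[AssessorNormal], path: str | Path
) -> None:
    rows = [
        {
            "assessor_id": n.assessor_id,
            "trial_id": n.trial_id,
            "strategy": n.strategy,
            "mean": repr(n.mean),
            "sd": repr(n.sd),
        }
        for n in normals
    ]
    pd.DataFrame(rows, columns=list(_ASSESSOR_COLUMNS)).to_csv(path, index=False)


def read_assessor_normals(path: str | Path) -> list[AssessorNormal]:
    df = pd.read_csv(path, float_precision="round_trip")
    for col in _ASSESSOR_COLUMNS:
        if col not in df.columns:
            raise FormatError(f"assessor table {path} is missing column {col!r}")
    return [
        AssessorNormal(
            assessor_id=str(r.assessor_id),
            trial_id=str(r.trial_id),
            strategy="" if pd.isna(r.strategy) else str(r.strategy),
            mean=float(r.mean),
            sd=float(r.sd),
        )
        for r in df.itertuples(index=False)
    ]
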