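"""Domain types and tabular I/O for bias-adjusted meta-analysis.

The package works with binary-outcome randomized trials carrying Cochrane-style
risk-of-bias judgements for three domains (sequence generation, allocation
concealment, blinding).  Trials judged *high* or *unclear* in a domain are
grouped into a single "flagged" category; the combination of flags across the
three domains is the trial's *bias profile*.  The universal currency between
modules is a normal distribution for bias on the log ratio-of-odds-ratios
(log-ROR) scale, where negative values mean exaggeration of benefit.
"""

from __future__ import annotations

import itertools
import json
import math
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

__all__ = [
    "AREAS",
    "ALL_PROFILE_KEYS",
    "FLAGGED_PROFILE_KEYS",
    "BiasDistribution",
    "BiasProfile",
    "DOMAINS",
    "ElicitationRecord",
    "FormatError",
    "JUDGEMENTS",
    "MCMCConfig",
    "PosteriorSummary",
    "TrialRecord",
    "ValidationError",
    "parse_judgement",
    "profile_key",
    "read_bias_priors",
    "read_elicitations",
    "read_summary",
    "read_trials",
    "write_bias_priors",
    "write_elicitations",
    "write_summary",
    "write_trials",
]

JUDGEMENTS = ("low", "high", "unclear")
DOMAINS = ("seq_gen", "alloc_conc", "blinding")
AREAS = ("A", "B", "C", "D")


class FormatError(ValueError):
    """A tabular input does not have the expected shape (columns, keys)."""


class ValidationError(ValueError):
    """A value violates a domain invariant."""


_JUDGEMENT_ALIASES = {
    "low": "low",
    "l": "low",
    "high": "high",
    "h": "high",
    "unclear": "unclear",
    "u": "unclear",
}


def parse_judgement(text: str) -> str:
    """Map a judgement string (case-insensitive, single letters allowed) to
    one of ``low``/``high``/``unclear``."""
    key = str(text).strip().lower()
    try:
        return _JUDGEMENT_ALIASES[key]
    except KeyError:
        raise ValidationError(f"unknown risk-of-bias judgement: {text!r}") from None


@dataclass(frozen=True)
class BiasProfile:
    """Risk-of-bias judgements for the three assessed domains.

    High and unclear judgements are merged into a single flag per domain
    (flag = 1); the original judgement string is retained for display.
    """

    seq_gen: str
    alloc_conc: str
    blinding: str

    def __post_init__(self) -> None:
        for domain in DOMAINS:
            value = getattr(self, domain)
            if value not in JUDGEMENTS:
                raise ValidationError(
                    f"judgement for {domain} must be one of {JUDGEMENTS}, got {value!r}"
                )

    @property
    def flags(self) -> tuple[int, int, int]:
        """Binary high-or-unclear flags in domain order (seq, conc, blind)."""
        return tuple(
            0 if getattr(self, d) == "low" else 1 for d in DOMAINS
        )  # type: ignore[return-value]

    @property
    def is_all_low(self) -> bool:
        return not any(self.flags)

    @property
    def key(self) -> str:
        return profile_key(self)

    @classmethod
    def from_key(cls, key: str) -> "BiasProfile":
        """Build a profile from a 3-character L/X key.

        The X flag collapses high and unclear; reconstructed profiles use
        ``unclear`` (the more common judgement) for flagged domains.
        """
        if len(key) != 3 or any(c not in "LX" for c in key):
            raise ValidationError(f"profile key must be 3 characters over L/X, got {key!r}")
        return cls(*("low" if c == "L" else "unclear" for c in key))


def profile_key(profile: BiasProfile) -> str:
    """Canonical 3-character key over {L, X} in domain order, X meaning
    high-or-unclear. Injective over the 8 flag combinations."""
    return "".join("X" if f else "L" for f in profile.flags)


ALL_PROFILE_KEYS = tuple(
    "".join(c) for c in itertools.product("LX", repeat=3)
)
FLAGGED_PROFILE_KEYS = tuple(k for k in ALL_PROFILE_KEYS if k != "LLL")


@dataclass(frozen=True)
class TrialRecord:
    """One randomized trial's 2x2 counts plus its bias profile."""

    trial_id: str
    meta_id: str
    events_ctrl: int
    n_ctrl: int
    events_trt: int
    n_trt: int
    profile: BiasProfile

    def __post_init__(self) -> None:
        for arm in ("ctrl", "trt"):
            events = getattr(self, f"events_{arm}")
            n = getattr(self, f"n_{arm}")
            if n < 1:
                raise ValidationError(f"trial {self.trial_id}: n_{arm} must be >= 1")
            if not 0 <= events <= n:
                raise ValidationError(
                    f"trial {self.trial_id}: events_{arm}={events} outside [0, {n}]"
                )


@dataclass(frozen=True)
class BiasDistribution:
    """Normal distribution for bias on the log-ROR scale.

    ``source`` records provenance: ``data`` (meta-epidemiological predictive),
    ``opinion`` (pooled elicited), ``fused`` (statistical combination) or
    ``area`` (area-selection elicitation).
    """

    mean: float
    sd: float
    source: str = "data"
    profile_key: str = "n/a"

    def __post_init__(self) -> None:
        if not math.isfinite(self.mean):
            raise ValidationError("bias distribution mean must be finite")
        if not (self.sd > 0 and math.isfinite(self.sd)):
            raise ValidationError(f"bias distribution sd must be > 0, got {self.sd}")
        if self.source not in ("data", "opinion", "fused", "area"):
            raise ValidationError(f"unknown bias source tag: {self.source!r}")


_STRATEGIES = ("a", "b", "c")


def _parse_areas(text: str) -> tuple[str, ...]:
    parts = tuple(p.strip().upper() for p in str(text).split("+") if p.strip())
    if not parts:
        return ()
    for p in parts:
        if p not in AREAS:
            raise ValidationError(f"unknown area label {p!r} (expected A-D)")
    idx = sorted(AREAS.index(p) for p in parts)
    if len(set(idx)) != len(idx):
        raise ValidationError(f"duplicate area labels in {text!r}")
    if idx[-1] - idx[0] + 1 != len(idx):
        raise ValidationError(f"areas must be contiguous, got {text!r}")
    return tuple(AREAS[i] for i in idx)


@dataclass(frozen=True)
class ElicitationRecord:
    """One assessor's opinion on one trial.

    Strategies ``a`` (plain scale) and ``b`` (scale overlaid on the data-based
    distribution) carry a numeric interquartile range on the ROR scale;
    strategy ``c`` carries a contiguous selection of quartile areas of the
    data-based distribution.
    """

    assessor_id: str
    trial_id: str
    strategy: str
    lower_ror: float | None = None
    upper_ror: float | None = None
    areas: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.strategy not in _STRATEGIES:
            raise ValidationError(f"strategy must be one of {_STRATEGIES}, got {self.strategy!r}")
        if self.strategy in ("a", "b"):
            lo, hi = self.lower_ror, self.upper_ror
            if lo is None or hi is None:
                raise ValidationError(
                    f"strategy {self.strategy!r} requires a numeric IQR "
                    f"(assessor {self.assessor_id}, trial {self.trial_id})"
                )
            if not (0 < lo < hi) or not (math.isfinite(lo) and math.isfinite(hi)):
                raise ValidationError(
                    f"IQR must satisfy 0 < lower < upper, got ({lo}, {hi}) "
                    f"(assessor {self.assessor_id}, trial {self.trial_id})"
                )
            if self.areas:
                raise ValidationError("areas are only valid for strategy c")
        else:
            if not self.areas:
                raise ValidationError(
                    f"strategy c requires a non-empty area selection "
                    f"(assessor {self.assessor_id}, trial {self.trial_id})"
                )
            object.__setattr__(self, "areas", _parse_areas("+".join(self.areas)))
            if self.lower_ror is not None or self.upper_ror is not None:
                raise ValidationError("numeric IQR is not valid for strategy c")


@dataclass
class PosteriorSummary:
    """Posterior medians and central 95% intervals for the intervention odds
    ratio and the heterogeneity variance tau^2, plus the maximum split-chain
    potential scale reduction factor."""

    or_median: float
    or_lo: float
    or_hi: float
    tau2_median: float
    tau2_lo: float
    tau2_hi: float
    rhat_max: float

    def validate(self) -> None:
        if not (self.or_lo <= self.or_median <= self.or_hi):
            raise ValidationError(
                "odds-ratio quantiles must be ordered lo <= median <= hi"
            )
        for name in ("tau2_median", "tau2_lo", "tau2_hi"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be >= 0")
        if not (self.tau2_lo <= self.tau2_median <= self.tau2_hi):
            raise ValidationError("tau^2 quantiles must be ordered lo <= median <= hi")

    def __post_init__(self) -> None:
        self.validate()

    @property
    def converged(self) -> bool:
        return self.rhat_max <= 1.05


@dataclass(frozen=True)
class MCMCConfig:
    """Sampler configuration.

    Defaults mirror the analysis conventions for this model family: 3 chains
    of 500,000 iterations after a 25,000-iteration burn-in. ``benefit_direction``
    states whether benefit corresponds to OR < 1 or OR > 1; bias priors are
    always expressed on the "negative log-ROR = exaggeration of benefit"
    orientation, and the sign handling is internal.
    """

    n_chains: int = 3
    n_iter: int = 500_000
    n_burnin: int = 25_000
    seed: int = 0
    benefit_direction: str = "or_lt_1"

    def __post_init__(self) -> None:
        if self.n_chains < 2:
            raise ValidationError("n_chains must be >= 2 (convergence diagnostic needs multiple chains)")
        if not (self.n_iter > self.n_burnin >= 0):
            raise ValidationError("require n_iter > n_burnin >= 0")
        if self.benefit_direction not in ("or_lt_1", "or_gt_1"):
            raise ValidationError("benefit_direction must be 'or_lt_1' or 'or_gt_1'")


# ---------------------------------------------------------------------------
# tabular readers / writers
# ---------------------------------------------------------------------------

_TRIAL_COLUMNS = (
    "trial_id",
    "meta_id",
    "events_ctrl",
    "n_ctrl",
    "events_trt",
    "n_trt",
    "rob_seq",
    "rob_conc",
    "rob_blind",
)


def _require_columns(df: pd.DataFrame, required: Sequence[str], what: str) -> None:
    for col in required:
        if col not in df.columns:
            raise FormatError(f"{what} is missing required column {col!r}")


def read_trials(path: str | Path) -> list[TrialRecord]:
    """Read a trials CSV (one row per trial; judgement strings are
    case-insensitive, single letters H/U/L accepted)."""
    df = pd.read_csv(path, float_precision="round_trip")
    _require_columns(df, _TRIAL_COLUMNS, f"trials file {path}")
    records = []
    for row in df.itertuples(index=False):
        profile = BiasProfile(
            parse_judgement(row.rob_seq),
            parse_judgement(row.rob_conc),
            parse_judgement(row.rob_blind),
        )
        records.append(
            TrialRecord(
                trial_id=str(row.trial_id),
                meta_id=str(row.meta_id),
                events_ctrl=int(row.events_ctrl),
                n_ctrl=int(row.n_ctrl),
                events_trt=int(row.events_trt),
                n_trt=int(row.n_trt),
                profile=profile,
            )
        )
    return records


def write_trials(records: Iterable[TrialRecord], path: str | Path) -> None:
    rows = [
        {
            "trial_id": r.trial_id,
            "meta_id": r.meta_id,
            "events_ctrl": r.events_ctrl,
            "n_ctrl": r.n_ctrl,
            "events_trt": r.events_trt,
            "n_trt": r.n_trt,
            "rob_seq": r.profile.seq_gen,
            "rob_conc": r.profile.alloc_conc,
            "rob_blind": r.profile.blinding,
        }
        for r in records
    ]
    pd.DataFrame(rows, columns=list(_TRIAL_COLUMNS)).to_csv(path, index=False)


_ELICITATION_COLUMNS = ("assessor_id", "trial_id", "strategy", "lower_ror", "upper_ror", "areas")


def read_elicitations(path: str | Path) -> list[ElicitationRecord]:
    """Read an elicitations CSV (``areas`` empty unless strategy is c)."""
    df = pd.read_csv(path, dtype={"areas": str}, keep_default_na=True, float_precision="round_trip")
    _require_columns(df, _ELICITATION_COLUMNS, f"elicitations file {path}")
    records = []
    for row in df.itertuples(index=False):
        strategy = str(row.strategy).strip().lower()
        areas_text = "" if pd.isna(row.areas) else str(row.areas)
        records.append(
            ElicitationRecord(
                assessor_id=str(row.assessor_id),
                trial_id=str(row.trial_id),
                strategy=strategy,
                lower_ror=None if pd.isna(row.lower_ror) else float(row.lower_ror),
                upper_ror=None if pd.isna(row.upper_ror) else float(row.upper_ror),
                areas=_parse_areas(areas_text) if areas_text else (),
            )
        )
    return records


def write_elicitations(records: Iterable[ElicitationRecord], path: str | Path) -> None:
    rows = [
        {
            "assessor_id": r.assessor_id,
            "trial_id": r.trial_id,
            "strategy": r.strategy,
            "lower_ror": "" if r.lower_ror is None else repr(r.lower_ror),
            "upper_ror": "" if r.upper_ror is None else repr(r.upper_ror),
            "areas": "+".join(r.areas),
        }
        for r in records
    ]
    pd.DataFrame(rows, columns=list(_ELICITATION_COLUMNS)).to_csv(path, index=False)


def write_bias_priors(priors: Mapping[str, BiasDistribution], path: str | Path) -> None:
    """Write a trial-keyed bias-prior table (log-ROR mean/sd per trial)."""
    rows = [
        {
            "trial_id": trial_id,
            "mean_logror": repr(dist.mean),
            "sd_logror": repr(dist.sd),
            "source": dist.source,
        }
        for trial_id, dist in priors.items()
    ]
    pd.DataFrame(rows, columns=["trial_id", "mean_logror", "sd_logror", "source"]).to_csv(
        path, index=False
    )


def read_bias_priors(path: str | Path) -> dict[str, BiasDistribution]:
    df = pd.read_csv(path, float_precision="round_trip")
    _require_columns(df, ("trial_id", "mean_logror", "sd_logror"), f"bias-prior table {path}")
    out: dict[str, BiasDistribution] = {}
    for row in df.itertuples(index=False):
        trial_id = str(row.trial_id)
        if trial_id in out:
            raise FormatError(f"duplicate trial_id {trial_id!r} in bias-prior table")
        source = getattr(row, "source", "data")
        out[trial_id] = BiasDistribution(
            mean=float(row.mean_logror),
            sd=float(row.sd_logror),
            source=str(source) if isinstance(source, str) else "data",
        )
    return out


def write_summary(
    summary: PosteriorSummary,
    path: str | Path,
    *,
    config: MCMCConfig | None = None,
    extra: Mapping[str, object] | None = None,
) -> None:
    """Write a results JSON with all summary fields plus run metadata."""
    summary.validate()
    doc: dict[str, object] = dict(asdict(summary))
    if config is not None:
        doc["config"] = asdict(config)
        doc["seed"] = config.seed
    if extra:
        doc.update(extra)
    Path(path).write_text(json.dumps(doc, indent=2) + "\n")


def read_summary(path: str | Path) -> PosteriorSummary:
    doc = json.loads(Path(path).read_text())
    fields = (
        "or_median",
        "or_lo",
        "or_hi",
        "tau2_median",
        "tau2_lo",
        "tau2_hi",
        "rhat_max",
    )
    return PosteriorSummary(**{k: float(doc[k]) for k in fields})
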