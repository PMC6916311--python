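"""Statistical combination of opinion-based and data-based bias distributions.

The pooled opinion N(mu_o, sigma_o^2) is treated as a single observation of
the bias with known variance, and the data-based distribution N(mu_d,
sigma_d^2) as its prior.  The posterior is the conjugate normal-normal
update, which is symmetric in the two inputs, so the roles could equally be
swapped.  Both sources receive equal weight; ``opinion_power`` is reserved
for down/up-weighting the opinion precision and defaults to 1.
"""

from __future__ import annotations

from typing import Mapping

from .data_model import BiasDistribution, ValidationError

__all__ = ["combine_normals", "combine_tables"]


def combine_normals(
    opinion: BiasDistribution,
    data: BiasDistribution,
    opinion_power: float = 1.0,
) -> BiasDistribution:
    """Precision-weighted combination of two normal bias distributions.

    mean = (w_d mu_d + w_o mu_o) / (w_d + w_o), sd = (w_d + w_o)^-1/2 with
    w = sd^-2.  The output is strictly more precise than either input.
    """
    if not (opinion.sd > 0 and data.sd > 0):
        raise ValidationError("both bias distributions must have sd > 0")
    if opinion_power <= 0:
        raise ValidationError("opinion_power must be > 0")
    w_o = opinion_power / opinion.sd**2
    w_d = 1.0 / data.sd**2
    total = w_d + w_o
    return BiasDistribution(
        mean=(w_d * data.mean + w_o * opinion.mean) / total,
        sd=total**-0.5,
        source="fused",
        profile_key=data.profile_key,
    )


def combine_tables(
    opinion: Mapping[str, BiasDistribution],
    data: Mapping[str, BiasDistribution],
) -> dict[str, BiasDistribution]:
    """Fuse trial-keyed opinion and data tables; every opinion trial must
    have a data counterpart."""
    missing = sorted(set(opinion) - set(data))
    if missing:
        raise ValidationError(f"no data-based distribution for trials: {missing}")
    return {tid: combine_normals(opinion[tid], data[tid]) for tid in opinion}
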