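"""Sex-difference statistics on adult life expectancy (ALE).

The central quantity is

    delta_e = (e_f - e_m) / max(e_f, e_m)

the proportional difference in ALE relative to the longer-lived sex:
delta_e in [-1, 1], positive values a female advantage, negative a male
advantage, directly expressible as a percent advantage P = 100*|delta_e|.
Applied draw-wise to paired posterior ALE samples it yields a posterior
for delta_e per species; the "zero overlap" statistic summarises how much
posterior mass sits on both sides of zero, and inverse-SD-weighted means
aggregate species into class or order summaries.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "ALEDifference",
    "GroupSummary",
    "ale_difference",
    "percent_advantage",
    "zero_overlap",
    "evidence_label",
    "summarize_delta",
    "weighted_group_mean",
]


@dataclass
class ALEDifference:
    """Posterior summary of delta_e for one species."""

    species: str
    delta_draws: np.ndarray
    mean: float
    sd: float
    ci_low: float
    ci_high: float
    zero_overlap: float

    def as_row(self) -> dict:
        return {
            "species": self.species,
            "mean": self.mean,
            "sd": self.sd,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "zero_overlap": self.zero_overlap,
            "evidence": evidence_label(self.zero_overlap),
        }


@dataclass
class GroupSummary:
    """Inverse-SD-weighted summary of delta_e over a species group."""

    group: str
    mean: float
    se: float
    ci_low: float
    ci_high: float
    n_species: int


def ale_difference(e_f, e_m):
    """delta_e = (e_f - e_m) / max(e_f, e_m); antisymmetric in the sexes.

    Accepts scalars or paired arrays (applied element-wise, e.g. draw-wise
    over paired posterior ALE samples).
    """
    ef = np.asarray(e_f, dtype=float)
    em = np.asarray(e_m, dtype=float)
    if np.any(ef <= 0) or np.any(em <= 0):
        raise ValueError("life expectancies must be strictly positive")
    out = (ef - em) / np.maximum(ef, em)
    return float(out) if out.ndim == 0 else out


def percent_advantage(delta: float) -> tuple:
    """Map delta_e to (percent advantage, favored sex).

    P = 100*|delta_e|; delta_e > 0 favours females, < 0 males, 0 neither.
    """
    if not -1.0 <= delta <= 1.0:
        raise ValueError("delta_e must lie in [-1, 1]")
    favored = "female" if delta > 0 else ("male" if delta < 0 else "none")
    return 100.0 * abs(delta), favored


def zero_overlap(samples, *, two_sided: bool = True, min_draws: int = 100) -> float:
    """Posterior-tail evidence that a quantity differs from zero.

    Doubles the smaller of the posterior masses below/above zero (a
    two-sided posterior tail probability), clipped to [0, 1].  Values
    <= 0.05 are conventionally read as strong evidence and values in
    (0.05, 0.125] as moderate evidence.  ``two_sided=False`` returns the
    undoubled smaller tail for sensitivity analysis.
    """
    x = np.asarray(samples, dtype=float)
    if x.size < min_draws:
        raise ValueError(f"need at least {min_draws} draws, got {x.size}")
    below = np.mean(x < 0)
    above = np.mean(x > 0)
    tail = min(below, above)
    return float(np.clip(2.0 * tail if two_sided else tail, 0.0, 1.0))


def evidence_label(overlap: float) -> str:
    if overlap <= 0.05:
        return "strong"
    if overlap <= 0.125:
        return "moderate"
    return "none"


def summarize_delta(species: str, ale_f_draws, ale_m_draws, level: float = 0.95) -> ALEDifference:
    """Draw-wise delta_e posterior summary from paired ALE samples."""
    delta = ale_difference(ale_f_draws, ale_m_draws)
    lo = (1.0 - level) / 2.0
    ci = np.quantile(delta, [lo, 1.0 - lo])
    return ALEDifference(
        species=species,
        delta_draws=delta,
        mean=float(delta.mean()),
        sd=float(delta.std(ddof=1)),
        ci_low=float(ci[0]),
        ci_high=float(ci[1]),
        zero_overlap=zero_overlap(delta),
    )


def weighted_group_mean(values, sds, group: str = "") -> GroupSummary:
    """Inverse-SD-weighted group mean with a weighted SE and normal CI.

    Weights w_i = 1/sd_i.  The weighted SE uses the weighted variance of
    the values divided by the effective sample size
    n_eff = (sum w)^2 / sum w^2, and the 95% CI is mean +/- 1.96*SE.
    A single species returns its own value with SE 0.
    """
    v = np.asarray(values, dtype=float)
    s = np.asarray(sds, dtype=float)
    if v.shape != s.shape:
        raise ValueError("values and sds must have equal length")
    if np.any(s <= 0):
        raise ValueError("posterior SDs must be strictly positive")
    w = 1.0 / s
    mean = float(np.sum(w * v) / np.sum(w))
    if v.size == 1:
        se = 0.0
    else:
        n_eff = np.sum(w) ** 2 / np.sum(w**2)
        wvar = np.sum(w * (v - mean) ** 2) / np.sum(w)
        se = float(np.sqrt(wvar / n_eff))
    return GroupSummary(
        group=group,
        mean=mean,
        se=se,
        ci_low=mean - 1.96 * se,
        ci_high=mean + 1.96 * se,
        n_species=int(v.size),
    )
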