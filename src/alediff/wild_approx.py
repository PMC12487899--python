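"""Life-expectancy approximations from published survival data.

Wild-population demographic data rarely come as individual records.  Two
published forms are handled here:

* a single annual adult mortality probability ``qa`` (or its complement,
  annual survival ``pa = 1 - qa``), from which life-table survivorship is
  approximated as lx = (1 - qa)^x — a constant-hazard assumption with
  hazard b = -log(1 - qa);
* a full life table (ages, lx), from which a pseudo-cohort of ages at
  death is reconstructed via Nx = floor(N * lx).

Adult life expectancy is then the sum of the lx series, and its sampling
variance follows Chiang's life-table approximation.  Age 0 of these
tables is the age at first reproduction of the source population.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .siler import SilerParams, sample_ages_at_death

__all__ = [
    "LifeTable",
    "survival_from_annual",
    "ale_from_lx",
    "ale_variance",
    "reconstruct_cohort",
    "simulate_from_reported",
    "read_life_table",
]


@dataclass
class LifeTable:
    """Survivorship table with integer ages from 0 (= age at first
    reproduction in the source) up to the maximum age omega."""

    ages: np.ndarray
    lx: np.ndarray

    def __post_init__(self) -> None:
        self.ages = np.asarray(self.ages, dtype=int)
        self.lx = np.asarray(self.lx, dtype=float)
        if self.lx[0] != 1.0:
            raise ValueError("lx must start at 1")
        if np.any(np.diff(self.lx) > 0):
            raise ValueError("lx must be non-increasing")

    @property
    def omega(self) -> int:
        return int(self.ages[-1])


def survival_from_annual(qa: float, omega: int) -> np.ndarray:
    """Survivorship under a constant annual mortality probability.

    lx = (1 - qa)^x for x = 0..omega, equivalent to exp(-b*x) with
    b = -log(1 - qa).
    """
    if not 0.0 <= qa <= 1.0:
        raise ValueError("qa must be a probability in [0, 1]")
    x = np.arange(omega + 1)
    return (1.0 - qa) ** x


def ale_from_lx(lx) -> float:
    """Adult life expectancy as the sum of the survivorship series."""
    return float(np.sum(np.asarray(lx, dtype=float)))


def _remaining_expectancy(lx: np.ndarray) -> np.ndarray:
    """e_x = sum_{t>=x} l_t / l_x for each age, 0 where l_x = 0."""
    lx = np.asarray(lx, dtype=float)
    tails = np.cumsum(lx[::-1])[::-1]
    with np.errstate(divide="ignore", invalid="ignore"):
        e = np.where(lx > 0, tails / np.where(lx > 0, lx, 1.0), 0.0)
    return e


def ale_variance(lx, qa, Dx, ax: float = 0.5) -> float:
    """Chiang-style sampling variance of the life expectancy at age 0.

    var(e0) ~= sum_x lx^2 [(1 - ax) + e_{x+1}]^2 [qx^2 (1 - qx) / Dx]

    over ages 0..omega-1, where e_{x+1} is the Chiang remaining
    expectancy at the next age (half-interval adjusted, so
    (1 - ax) + e_{x+1} equals the plain tail sum of the lx series over
    l_{x+1}) and Dx the number of deaths in the interval.  This is the
    delta-method variance of ``ale_from_lx`` under independent binomial
    death counts.  ``qa`` may be a scalar (age-constant, matching the
    constant-hazard approximation) or a per-age vector.
    """
    lx = np.asarray(lx, dtype=float)
    Dx = np.asarray(Dx, dtype=float)
    n = lx.size - 1
    if Dx.size != n:
        raise ValueError(f"need {n} death counts for {lx.size} survivorship values")
    if np.any(Dx <= 0):
        raise ValueError("every included age interval needs Dx > 0")
    q = np.broadcast_to(np.asarray(qa, dtype=float), (n,))
    # Chiang e_{x+1} = tail-series expectancy - (1 - ax); the bracket
    # below therefore reduces to the plain series expectancy at x+1
    e_next_chiang = _remaining_expectancy(lx)[1:] - (1.0 - ax)
    terms = lx[:n] ** 2 * ((1.0 - ax) + e_next_chiang) ** 2 * (
        q**2 * (1.0 - q) / Dx
    )
    return float(terms.sum())


def reconstruct_cohort(lx, N: int, *, ax: float = 0.0) -> tuple:
    """Pseudo-cohort ages at death from a survivorship series.

    Individuals alive at the start of age interval x are Nx = floor(N*lx)
    (nearest lower integer); deaths in the interval are
    Dx = Nx - N_{x+1} and are assigned age x + ax (interval start by
    default).  Survivors past the final age are emitted as censored at
    omega.  Returns ``(death_ages, n_censored)``.
    """
    lx = np.asarray(lx, dtype=float)
    if N < 1:
        raise ValueError("N must be >= 1")
    if np.any(np.diff(lx) > 0):
        raise ValueError("lx must be non-increasing")
    Nx = np.floor(N * lx).astype(int)
    Dx = Nx[:-1] - Nx[1:]
    ages = np.repeat(np.arange(lx.size - 1) + ax, Dx).astype(float)
    return ages, int(Nx[-1])


def simulate_from_reported(
    params: SilerParams, n: int, alpha: float, seed=None
) -> np.ndarray:
    """Ages at death sampled from reported Siler mortality parameters.

    The wild-mammal pathway: published Siler parameters and sample sizes
    define the death-age distribution, a cohort is simulated from it and
    can then be refitted like any individual-record dataset.
    """
    return sample_ages_at_death(params, alpha, n, seed)


def read_life_table(path_or_buf) -> LifeTable:
    """Read a CSV life table with ``age`` plus either ``lx`` or ``qx``.

    HMD-style column names (``Age``, ``lx`` per 100,000, ``qx``) are
    accepted; lx is renormalised so l0 = 1.
    """
    df = pd.read_csv(path_or_buf)
    df.columns = [c.strip().lower() for c in df.columns]
    if "age" not in df.columns:
        raise ValueError("life table needs an 'age' column")
    ages = (
        df["age"].astype(str).str.replace("+", "", regex=False).astype(float).astype(int)
    )
    if "lx" in df.columns:
        lx = df["lx"].astype(float).to_numpy()
        lx = lx / lx[0]
    elif "qx" in df.columns:
        qx = df["qx"].astype(float).to_numpy()
        lx = np.concatenate([[1.0], np.cumprod(1.0 - qx[:-1])])
    else:
        raise ValueError("life table needs an 'lx' or 'qx' column")
    return LifeTable(ages=ages.to_numpy(), lx=lx)
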