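"""Life-history covariate coding and hypothesis design matrices.

Three evolutionary hypotheses about sex differences in adult life
expectancy are tested with dedicated predictor sets:

* precopulatory sexual selection — sexual size dimorphism entered as
  additive log male and log female body mass, social monogamy, and (in
  birds-only runs) plumage dichromatism;
* postcopulatory sexual selection — relative testis mass entered as
  additive log testis mass and log male body mass, plus monogamy;
* cost of reproduction — log female mass, log female age at first birth,
  log annual productivity and a female-parental-care indicator.

Coding rules: a species is monogamous when both sexes exceed the
monogamy threshold (default 80% of individuals socially monogamous);
bird care scores on [-2, 2] map to female-only care when > 0; annual
productivity is neonate/egg mass x litter/clutch size x litters/clutches
per year.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd

__all__ = [
    "code_mating_system",
    "code_parental_care",
    "annual_productivity",
    "bird_monogamy_fraction",
    "build_design",
    "HYPOTHESES",
]

# predictor columns per hypothesis (log-transformed where log_ prefixed)
HYPOTHESES = {
    "precopulatory": ["log_male_mass", "log_female_mass", "monogamy"],
    "postcopulatory": ["log_male_mass", "log_testis_mass", "monogamy"],
    "cost": [
        "log_female_mass",
        "log_age_first_birth",
        "log_productivity",
        "female_care",
    ],
}

_LOG_SOURCES = {
    "log_male_mass": "male_mass",
    "log_female_mass": "female_mass",
    "log_testis_mass": "testis_mass",
    "log_age_first_birth": "age_first_birth",
    "log_productivity": "productivity",
}


def code_mating_system(female_monog, male_monog, threshold: float = 0.80):
    """Monogamy indicator: 1 iff BOTH sexes exceed the threshold fraction
    of socially monogamous individuals.  Returns NaN if either sex's score
    is missing.  Alternative thresholds (0.95, 0.99) support sensitivity
    analysis."""
    if female_monog is None or male_monog is None:
        return math.nan
    f, m = float(female_monog), float(male_monog)
    if math.isnan(f) or math.isnan(m):
        return math.nan
    if not (0.0 <= f <= 1.0 and 0.0 <= m <= 1.0):
        raise ValueError("monogamy fractions must lie in [0, 1]")
    return int(f > threshold and m > threshold)


def code_parental_care(score: float, cutoff: float = 0.0) -> int:
    """Female-care indicator from a continuous care score on [-2, 2].

    Scores <= cutoff (default 0) mean biparental or male care (0); scores
    above mean female care (1).  Alternative cutoffs (+-0.5, +-1) support
    the sensitivity analysis."""
    if not -2.0 <= score <= 2.0:
        raise ValueError("care score must lie in [-2, 2]")
    return int(score > cutoff)


def bird_monogamy_fraction(score: float) -> float:
    """Map a 0-4 ordinal monogamy score to a fraction in [0, 1] (score/4)."""
    if not 0.0 <= score <= 4.0:
        raise ValueError("bird monogamy scores lie on the 0-4 scale")
    return score / 4.0


def annual_productivity(
    offspring_mass: float, litter_size: float, litters_per_year: float
) -> float:
    """Annual female productivity (g/year): offspring mass x litter/clutch
    size x litters/clutches per year.  Zero values are legal here but are
    excluded (with a report entry) from log-scale designs downstream."""
    if min(offspring_mass, litter_size, litters_per_year) < 0:
        raise ValueError("productivity inputs must be nonnegative")
    return offspring_mass * litter_size * litters_per_year


def build_design(
    covariates: pd.DataFrame,
    hypothesis: str,
    interactions: str = "class-intercept",
    *,
    include_dichromatism: bool = False,
    include_hunted: bool = False,
) -> tuple:
    """Assemble the design matrix for one hypothesis.

    Parameters
    ----------
    covariates : DataFrame
        Species rows with a ``species`` column, a ``class`` column
        ('Mammalia'/'Aves') and the raw trait columns the hypothesis
        needs (male_mass, female_mass, testis_mass, monogamy,
        age_first_birth, productivity, female_care, dichromatism,
        hunted).
    hypothesis : {'precopulatory', 'postcopulatory', 'cost'}
    interactions : {'none', 'class-intercept', 'full'}
        'class-intercept' adds an Aves indicator column; 'full' also
        interacts every predictor with class.
    include_dichromatism : bool
        Add plumage dichromatism (meaningful for birds-only runs).
    include_hunted : bool
        Add the hunted flag and a hunted x monogamy interaction (wild
        sensitivity model); requires a monogamy column in the design.

    Returns
    -------
    (design, mask, report) : (DataFrame, boolean Series, dict)
        ``design`` has an intercept column first and is indexed by
        species; ``mask`` marks which input rows were kept; ``report``
        counts rows dropped for missing or non-positive log-scale values.
    """
    if hypothesis not in HYPOTHESES:
        raise KeyError(f"unknown hypothesis {hypothesis!r}")
    if interactions not in ("none", "class-intercept", "full"):
        raise ValueError(f"unknown interaction level {interactions!r}")
    df = covariates.copy()
    cols = list(HYPOTHESES[hypothesis])
    if include_dichromatism:
        cols.append("dichromatism")

    data = {}
    dropped_nonpositive = 0
    for col in cols:
        if col in _LOG_SOURCES:
            src = _LOG_SOURCES[col]
            if src not in df:
                raise KeyError(f"hypothesis {hypothesis!r} needs column {src!r}")
            raw = pd.to_numeric(df[src], errors="coerce")
            ok = raw > 0
            dropped_nonpositive += int((raw.notna() & ~ok).sum())
            data[col] = np.log(raw.where(ok))
        else:
            if col not in df:
                raise KeyError(f"hypothesis {hypothesis!r} needs column {col!r}")
            data[col] = pd.to_numeric(df[col], errors="coerce")
    design = pd.DataFrame(data, index=df.index)

    if interactions != "none":
        if "class" not in df:
            raise KeyError("class interactions need a 'class' column")
        design.insert(0, "class_aves", (df["class"] == "Aves").astype(float))
    if interactions == "full":
        for col in cols:
            design[f"class_aves:{col}"] = design["class_aves"] * design[col]
    if include_hunted:
        design["hunted"] = pd.to_numeric(df["hunted"], errors="coerce")
        if "monogamy" in design:
            design["hunted:monogamy"] = design["hunted"] * design["monogamy"]

    mask = design.notna().all(axis=1)
    report = {
        "n_input": int(len(df)),
        "n_kept": int(mask.sum()),
        "n_dropped_missing": int((~mask).sum()) - dropped_nonpositive,
        "n_dropped_nonpositive_log": dropped_nonpositive,
    }
    design = design[mask]
    design.insert(0, "intercept", 1.0)
    if "species" in df:
        design.index = df.loc[mask, "species"]
    if design.empty:
        raise ValueError("no species left after applying the row mask")
    return design, mask, report
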