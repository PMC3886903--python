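"""Selection-coefficient estimation from pairwise competition assays.

An evolved clone is mixed with a fluorescently labelled reference strain
(typically at 1:5) and the abundance ratio is followed for ~20
generations.  Under constant selection the log ratio drifts linearly, so
the selection coefficient s is the slope of an ordinary least squares fit
of ln(evolved/reference) against time in generations; relative fitness is
1 + s.  Batch and chemostat competitions use the same estimator.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

__all__ = [
    "CompetitionSeries",
    "FitnessEstimate",
    "estimate_selection_coefficient",
    "compare_fitness",
    "doubling_time",
    "selection_duration",
]

#: Counts of the rarer strain below this flag a time point as unreliable.
MIN_RELIABLE_COUNT = 100


@dataclass
class CompetitionSeries:
    """Time course of one competition assay.

    Either provide ``ratio`` directly or per-strain ``count_evolved`` /
    ``count_reference`` (the ratio is then derived).  Time is measured in
    generations and must be strictly increasing.
    """

    generations: np.ndarray
    ratio: np.ndarray | None = None
    count_evolved: np.ndarray | None = None
    count_reference: np.ndarray | None = None
    label: str = ""
    reference_genotype: str = "ancestor"
    unreliable_points: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.generations = np.asarray(self.generations, dtype=float)
        if self.ratio is None:
            if self.count_evolved is None or self.count_reference is None:
                raise ValueError("need either ratio or both count columns")
            ce = np.asarray(self.count_evolved, dtype=float)
            cr = np.asarray(self.count_reference, dtype=float)
            if np.any(ce <= 0) or np.any(cr <= 0):
                raise ValueError("strain counts must be positive")
            self.ratio = ce / cr
            rarer = np.minimum(ce, cr)
            self.unreliable_points = [
                int(i) for i in np.nonzero(rarer < MIN_RELIABLE_COUNT)[0]
            ]
        self.ratio = np.asarray(self.ratio, dtype=float)
        if len(self.generations) != len(self.ratio):
            raise ValueError("generations and ratio lengths differ")
        if len(self.generations) < 3:
            raise ValueError("competition series needs at least 3 points")
        if np.any(self.ratio <= 0):
            raise ValueError("ratios must be positive")
        if np.any(np.diff(self.generations) <= 0):
            raise ValueError("generations must be strictly increasing")


@dataclass
class FitnessEstimate:
    """Selection coefficient with regression uncertainty.

    ``ci95`` is the Student-t 95% confidence interval of the slope
    (df = n - 2); ``relative_fitness`` is 1 + s by definition.
    """

    s: float
    se: float
    ci95: tuple[float, float]
    n_points: int
    label: str = ""
    reference_genotype: str = "ancestor"

    @property
    def relative_fitness(self) -> float:
        return 1.0 + self.s


def estimate_selection_coefficient(series: CompetitionSeries) -> FitnessEstimate:
    """OLS slope of ln(ratio) on generations, with se and t-based 95% CI."""
    t = series.generations
    y = np.log(series.ratio)
    if np.ptp(t) == 0:
        raise ValueError("zero variance in time points")
    n = len(t)
    res = stats.linregress(t, y)
    slope, se = float(res.slope), float(res.stderr)
    if not math.isfinite(se):
        se = 0.0  # perfect fit: residual variance is exactly zero
    if n > 2 and se > 0:
        half = stats.t.ppf(0.975, n - 2) * se
    else:
        half = 0.0
    return FitnessEstimate(
        s=slope,
        se=se,
        ci95=(slope - half, slope + half),
        n_points=n,
        label=series.label,
        reference_genotype=series.reference_genotype,
    )


def compare_fitness(a: FitnessEstimate, b: FitnessEstimate) -> dict:
    """Two-sample z comparison of two selection coefficients.

    z = (s_a - s_b) / sqrt(se_a^2 + se_b^2), two-sided normal p.  If both
    standard errors are zero the comparison degenerates: identical point
    estimates give z = 0, p = 1; different ones are flagged with infinite
    z and p = 0.
    """
    delta = a.s - b.s
    pooled = math.hypot(a.se, b.se)
    if pooled == 0:
        if delta == 0:
            return {"delta_s": 0.0, "z": 0.0, "p": 1.0, "degenerate": False}
        return {
            "delta_s": delta,
            "z": math.copysign(math.inf, delta),
            "p": 0.0,
            "degenerate": True,
        }
    z = delta / pooled
    p = 2.0 * stats.norm.sf(abs(z))
    return {"delta_s": delta, "z": float(z), "p": float(p), "degenerate": False}


def doubling_time(dilution_rate: float) -> float:
    """Population doubling time (hours) in a chemostat diluted at D per hour.

    At steady state the growth rate equals the dilution rate, so
    t_double = ln(2) / D; D = 0.12/hr gives the familiar 5.8 hr.
    """
    if dilution_rate <= 0:
        raise ValueError("dilution_rate must be > 0")
    return math.log(2) / dilution_rate


def selection_duration(
    n_generations: int = 250, dilution_rate: float = 0.12
) -> dict:
    """Wall-clock duration of a selection of ``n_generations`` doublings."""
    hours = n_generations * doubling_time(dilution_rate)
    days = hours / 24.0
    return {"hours": hours, "days": days, "months": days / 30.44}
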