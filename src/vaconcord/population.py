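"""Population-level agreement: CSMF vectors, CSMF accuracy, its
chance-corrected transform, Spearman rank correlation of cause rankings,
and the redistribution of reference-undetermined deaths.

Cause-specific mortality fractions (CSMFs) summarise a coder's output at
population scale: the fraction of deaths it attributes to each cause. Two
coders can disagree on nearly every individual death yet produce almost
identical CSMFs, which is why population-level metrics are reported
alongside the individual-level battery.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm, rankdata

from .causes import CauseList
from .cohort import Cohort
from .individual import MetricResult

__all__ = [
    "CSMFVector",
    "PopulationComparison",
    "CHANCE_CSMF_ACCURACY",
    "csmf",
    "csmf_accuracy",
    "chance_corrected_csmf_accuracy",
    "spearman_rank_correlation",
    "redistribution_matrix",
]

#: CSMF accuracy expected from uninformed (random-allocation) coding; the
#: zero point of the chance-corrected transform
CHANCE_CSMF_ACCURACY = 0.632


@dataclass(frozen=True)
class CSMFVector:
    """Cause → fraction map over an analysis list; fractions sum to 1.

    ``includes_undetermined`` records whether the undetermined category is a
    component of the vector (descriptive mode) or was dropped and the
    substantive fractions renormalised (agreement mode without a coder-side
    undetermined column).
    """

    cause_list: CauseList
    fractions: pd.Series
    n: int
    includes_undetermined: bool = True

    def __post_init__(self) -> None:
        if (self.fractions < -1e-12).any():
            raise ValueError("CSMF fractions must be non-negative")
        total = float(self.fractions.sum())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"CSMF fractions must sum to 1, got {total}")

    def __getitem__(self, code: str) -> float:
        return float(self.fractions[code])

    @property
    def substantive(self) -> pd.Series:
        codes = list(self.cause_list.substantive_codes)
        return self.fractions.reindex(codes).dropna()

    def to_frame(self) -> pd.DataFrame:
        return self.fractions.rename("csmf").rename_axis("cause").reset_index()


def csmf(
    cohort: Cohort, coder: str = "reference", include_undetermined: bool = True
) -> CSMFVector:
    """Empirical CSMF of a coder (or ``"reference"``) over the cohort.

    With ``include_undetermined=False`` the universe shrinks to deaths with a
    substantive assignment and the fractions are renormalised over it.
    """
    if coder == "reference":
        col = "ref_cause"
    elif coder in cohort.coders:
        col = f"{coder}_cause"
    else:
        raise KeyError(f"unknown coder {coder!r}")
    cl = cohort.cause_list
    codes = list(cl.codes) if include_undetermined else list(cl.substantive_codes)
    assigned = cohort.frame[col]
    if not include_undetermined and cl.undetermined_code is not None:
        assigned = assigned[assigned != cl.undetermined_code]
    n = len(assigned)
    if n == 0:
        raise ValueError("CSMF undefined on an empty universe")
    counts = assigned.value_counts().reindex(codes, fill_value=0)
    return CSMFVector(cl, counts / n, n, include_undetermined)


def _check_comparable(reference: CSMFVector, predicted: CSMFVector) -> None:
    if list(reference.fractions.index) != list(predicted.fractions.index):
        raise ValueError("CSMF vectors are over different cause sets")
    if reference.includes_undetermined != predicted.includes_undetermined:
        raise ValueError("CSMF vectors use different undetermined conventions")


def csmf_accuracy(reference: CSMFVector, predicted: CSMFVector) -> float:
    """CSMF accuracy: 1 minus total absolute CSMF error scaled by its
    maximum attainable value given the reference distribution.

    .. math:: 1 - \\frac{\\sum_j |CSMF_j^{true} - CSMF_j^{pred}|}
                      {2\\,(1 - \\min_j CSMF_j^{true})}

    Equals 1 iff the vectors coincide and 0 when the predicted distribution
    puts all mass on the reference's smallest cause (the worst case).
    """
    _check_comparable(reference, predicted)
    t = reference.fractions.to_numpy(dtype=float)
    p = predicted.fractions.to_numpy(dtype=float)
    denom = 2.0 * (1.0 - float(t.min()))
    if denom == 0.0:
        raise ValueError("reference CSMF is degenerate (single cause)")
    acc = 1.0 - float(np.abs(t - p).sum()) / denom
    # clip only floating-point excursions, never genuine values
    return min(1.0, max(0.0, acc)) if -1e-12 < acc < 1 + 1e-12 else acc


def chance_corrected_csmf_accuracy(acc: float) -> float:
    """Affine rescaling of CSMF accuracy so random allocation scores 0:
    ``(acc - 0.632) / (1 - 0.632)``. May be negative."""
    return (acc - CHANCE_CSMF_ACCURACY) / (1.0 - CHANCE_CSMF_ACCURACY)


def spearman_rank_correlation(
    reference: CSMFVector, predicted: CSMFVector, level: float = 0.95
) -> MetricResult:
    """Spearman correlation between the two cause rankings.

    Causes are ranked by CSMF with rank 1 for the largest fraction and rank
    C for the smallest; ties receive averaged ranks; rho is the Pearson
    correlation of the two rank vectors. Ranking runs over substantive
    causes only. The CI uses the Fisher z transform with rank-correlation
    variance ``1.06/(C-3)``.
    """
    _check_comparable(reference, predicted)
    t = reference.substantive.to_numpy(dtype=float)
    p = predicted.substantive.to_numpy(dtype=float)
    C = len(t)
    if C < 3:
        raise ValueError("rank correlation needs at least 3 causes")
    if np.ptp(t) == 0 or np.ptp(p) == 0:
        return MetricResult(
            "spearman_rho", None, n=C, reason="constant rank vector (all CSMFs equal)"
        )
    # rank 1 = largest CSMF, ties averaged
    rt = rankdata(-t, method="average")
    rp = rankdata(-p, method="average")
    rho = float(np.corrcoef(rt, rp)[0, 1])
    if C > 3 and abs(rho) < 1.0:
        z = math.atanh(rho)
        se = math.sqrt(1.06 / (C - 3))
        q = norm.ppf(0.5 + level / 2)
        low, high = math.tanh(z - q * se), math.tanh(z + q * se)
    else:
        low = high = None
    return MetricResult("spearman_rho", rho, low, high, C)


def redistribution_matrix(undetermined_subset: Cohort, coder: str) -> CSMFVector:
    """Where a coder sends the deaths the reference called undetermined.

    Input must be exactly the reference-undetermined subset (see
    :meth:`Cohort.reference_undetermined_subset`); the result is the coder's
    cause distribution over those deaths, undetermined included.
    """
    undet = undetermined_subset.cause_list.undetermined_code
    if undet is not None and (undetermined_subset.frame["ref_cause"] != undet).any():
        raise ValueError("input must contain only reference-undetermined deaths")
    if len(undetermined_subset) == 0:
        raise ValueError("redistribution undefined on an empty subset")
    return csmf(undetermined_subset, coder, include_undetermined=True)


@dataclass(frozen=True)
class PopulationComparison:
    """Bundle of every population-level comparison between one reference
    CSMF vector and one coder's CSMF vector."""

    reference: CSMFVector
    predicted: CSMFVector
    csmf_accuracy: float = field(init=False)
    chance_corrected: float = field(init=False)
    rho: MetricResult = field(init=False)

    def __post_init__(self) -> None:
        acc = csmf_accuracy(self.reference, self.predicted)
        object.__setattr__(self, "csmf_accuracy", acc)
        object.__setattr__(self, "chance_corrected", chance_corrected_csmf_accuracy(acc))
        object.__setattr__(
            self, "rho", spearman_rank_correlation(self.reference, self.predicted)
        )

    @property
    def ranks_reference(self) -> pd.Series:
        s = self.reference.substantive
        return pd.Series(rankdata(-s.to_numpy(), method="average"), index=s.index)

    @property
    def ranks_predicted(self) -> pd.Series:
        s = self.predicted.substantive
        return pd.Series(rankdata(-s.to_numpy(), method="average"), index=s.index)
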