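"""Individual-level agreement: confusion tables, PPV, sensitivity,
chance-corrected concordance, overall agreement, Cohen's kappa.

All metrics compare a coder's single most-likely (thresholded) cause against
the reference cause, death by death. The reference side is assumed to have
had its undetermined causes excluded already; the coder side keeps an
undetermined column, which counts as disagreement with every substantive
reference cause and contributes to the kappa marginals, but has no
PPV/sensitivity/CCC of its own.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from statsmodels.stats.proportion import proportion_confint

from .causes import CauseList
from .cohort import Cohort

__all__ = [
    "MetricResult",
    "KappaBreakdown",
    "ConfusionTable",
    "UnsupportedCoderError",
    "build_confusion",
    "proportion_ci",
    "ppv",
    "sensitivity",
    "ccc",
    "mean_ccc",
    "overall_agreement",
    "cohens_kappa",
    "interpret_kappa",
    "KAPPA_BANDS",
]


class UnsupportedCoderError(ValueError):
    """The coder's output does not support the requested analysis
    (e.g. top-3 agreement for a single-cause coder)."""


@dataclass(frozen=True)
class MetricResult:
    """One metric value with optional CI and supporting count.

    An undefined metric (empty denominator, structurally impossible cause)
    carries ``value=None`` and a ``reason`` — it is never silently 0.
    """

    name: str
    value: float | None
    ci_low: float | None = None
    ci_high: float | None = None
    n: int = 0
    reason: str | None = None

    @property
    def is_defined(self) -> bool:
        return self.value is not None

    def __post_init__(self) -> None:
        if self.value is not None and self.ci_low is not None:
            if not (self.ci_low - 1e-12 <= self.value <= self.ci_high + 1e-12):
                raise ValueError(f"{self.name}: CI does not bracket value")


@dataclass(frozen=True)
class KappaBreakdown:
    """Observed agreement p_o, chance agreement p_e, and the resulting kappa."""

    p_o: float
    p_e: float
    kappa: float


class ConfusionTable:
    """Reference-by-coder cross-tabulation on the analysis cause list.

    Rows are substantive reference causes (the reference-undetermined deaths
    were excluded upstream); columns are substantive causes plus the coder's
    undetermined category. ``TP_j`` is the diagonal cell for cause *j*;
    ``FP_j`` and ``FN_j`` are the off-diagonal column and row remainders.
    """

    def __init__(self, counts: pd.DataFrame, cause_list: CauseList):
        if (counts.to_numpy() < 0).any():
            raise ValueError("confusion counts must be non-negative")
        self.counts = counts
        self.cause_list = cause_list

    @classmethod
    def from_cohort(cls, cohort: Cohort, coder: str) -> "ConfusionTable":
        return build_confusion(cohort, coder)

    @property
    def n(self) -> int:
        return int(self.counts.to_numpy().sum())

    def tp(self, cause: str) -> int:
        return int(self.counts.at[cause, cause])

    def fp(self, cause: str) -> int:
        return int(self.counts[cause].sum()) - self.tp(cause)

    def fn(self, cause: str) -> int:
        return int(self.counts.loc[cause].sum()) - self.tp(cause)

    def row_total(self, cause: str) -> int:
        return int(self.counts.loc[cause].sum())

    def col_total(self, cause: str) -> int:
        return int(self.counts[cause].sum())

    def to_frame(self) -> pd.DataFrame:
        return self.counts.copy()

    def write(self, path: str | Path) -> None:
        self.counts.to_csv(path, index_label="ref_cause")


def build_confusion(cohort: Cohort, coder: str) -> ConfusionTable:
    """Cross-tabulate reference vs coder thresholded causes.

    Requires the reference-undetermined exclusion to have run: a reference
    row of undetermined deaths would distort every row-based metric.
    """
    if coder not in cohort.coders:
        raise KeyError(f"unknown coder {coder!r}; cohort has {cohort.coders}")
    cl = cohort.cause_list
    undet = cl.undetermined_code
    rows = list(cl.substantive_codes)
    cols = list(cl.substantive_codes) + ([undet] if undet else [])
    if undet is not None and (cohort.frame["ref_cause"] == undet).any():
        raise ValueError(
            "cohort still contains reference-undetermined deaths; "
            "run exclude_reference_undetermined() first"
        )
    tab = pd.crosstab(cohort.frame["ref_cause"], cohort.frame[f"{coder}_cause"])
    counts = tab.reindex(index=rows, columns=cols, fill_value=0).astype(int)
    return ConfusionTable(counts, cl)


def proportion_ci(
    successes: int, n: int, level: float = 0.95, method: str = "wald"
) -> tuple[float, float]:
    """Binomial CI for a simple proportion.

    Default is the Wald interval ``p ± z·sqrt(p(1-p)/n)`` truncated to
    [0, 1]; ``method="wilson"`` gives the Wilson score interval.
    """
    if n <= 0:
        raise ValueError("n must be positive")
    sm_method = {"wald": "normal", "wilson": "wilson"}[method]
    low, high = proportion_confint(successes, n, alpha=1 - level, method=sm_method)
    return (max(0.0, float(low)), min(1.0, float(high)))


def _proportion_metric(
    name: str, successes: int, n: int, level: float, undefined_reason: str
) -> MetricResult:
    if n == 0:
        return MetricResult(name, None, n=0, reason=undefined_reason)
    low, high = proportion_ci(successes, n, level)
    return MetricResult(name, successes / n, low, high, n)


def ppv(table: ConfusionTable, cause: str, level: float = 0.95) -> MetricResult:
    """Positive predictive value for one cause: of the deaths the coder
    assigned to *j*, the fraction the reference also assigned to *j*."""
    tp, fp = table.tp(cause), table.fp(cause)
    return _proportion_metric(
        f"ppv[{cause}]", tp, tp + fp, level, "coder never predicts this cause"
    )


def sensitivity(table: ConfusionTable, cause: str, level: float = 0.95) -> MetricResult:
    """Sensitivity for one cause: of the reference deaths from *j*, the
    fraction the coder also assigned to *j*."""
    tp, fn = table.tp(cause), table.fn(cause)
    return _proportion_metric(
        f"sensitivity[{cause}]", tp, tp + fn, level, "no reference deaths of this cause"
    )


def ccc(table: ConfusionTable, cause: str, C: int | None = None) -> MetricResult:
    """Chance-corrected concordance for one cause.

    Rescales sensitivity so that random assignment among the C substantive
    causes scores 0: ``(sens_j - 1/C) / (1 - 1/C)``. Ranges from
    ``-1/(C-1)`` (sensitivity 0) to 1.
    """
    C = table.cause_list.C if C is None else C
    if C < 2:
        raise ValueError("chance correction needs at least 2 causes")
    sens = sensitivity(table, cause)
    if not sens.is_defined:
        return MetricResult(f"ccc[{cause}]", None, n=0, reason=sens.reason)
    value = (sens.value - 1 / C) / (1 - 1 / C)
    return MetricResult(f"ccc[{cause}]", value, n=sens.n)


def mean_ccc(table: ConfusionTable, C: int | None = None) -> MetricResult:
    """Unweighted mean CCC over causes with at least one reference death.

    Causes never assigned by the reference carry no concordance information
    and are left out of the mean; the per-cause vector remains available via
    :func:`ccc`.
    """
    C = table.cause_list.C if C is None else C
    values, n_total = [], 0
    for cause in table.cause_list.substantive_codes:
        r = ccc(table, cause, C)
        if r.is_defined:
            values.append(r.value)
            n_total += r.n
    if not values:
        return MetricResult("mean_ccc", None, n=0, reason="no cause has reference deaths")
    return MetricResult("mean_ccc", float(np.mean(values)), n=n_total)


def overall_agreement(
    cohort: Cohort, coder: str, top_k: int = 1, level: float = 0.95
) -> MetricResult:
    """Proportion of deaths whose reference cause is the coder's top cause
    (``top_k=1``) or among its three highest-ranked causes (``top_k=3``).

    Top-3 uses the ranked causes *ignoring* the coder's indeterminate
    cutoff, so a death thresholded to undetermined can still agree at k=3.
    Coders that emit a single cause per death (Tariff-style) cannot be
    scored at k=3 and raise :class:`UnsupportedCoderError`.
    """
    if coder not in cohort.coders:
        raise KeyError(f"unknown coder {coder!r}")
    if top_k not in (1, 3):
        raise ValueError("top_k must be 1 or 3")
    frame = cohort.frame
    n = len(frame)
    if n == 0:
        return MetricResult(f"overall_agreement_top{top_k}", None, n=0, reason="empty cohort")
    if top_k == 1:
        hits = int((frame["ref_cause"] == frame[f"{coder}_cause"]).sum())
    else:
        rank_cols = [f"{coder}_rank{r}" for r in (1, 2, 3)]
        missing_cols = [c for c in rank_cols if c not in frame.columns]
        if missing_cols:
            raise UnsupportedCoderError(
                f"coder {coder!r} does not expose 3 ranked causes ({missing_cols} absent); "
                "top-3 agreement is undefined for single-cause coders"
            )
        incomplete = frame["id"][(frame[rank_cols] == "").any(axis=1)]
        if not incomplete.empty:
            raise UnsupportedCoderError(
                f"coder {coder!r}: {len(incomplete)} records carry fewer than 3 "
                f"ranked causes (e.g. ids {incomplete.tolist()[:5]})"
            )
        hits = int(
            (frame[rank_cols].eq(frame["ref_cause"], axis=0)).any(axis=1).sum()
        )
    return _proportion_metric(f"overall_agreement_top{top_k}", hits, n, level, "empty")


def cohens_kappa(
    table: ConfusionTable, level: float = 0.95
) -> tuple[MetricResult, KappaBreakdown]:
    """Cohen's kappa over the union of reference and coder categories.

    ``p_o`` is the observed agreement proportion (diagonal mass) and ``p_e``
    the agreement expected from the marginals alone; kappa is
    ``(p_o - p_e) / (1 - p_e)``. The CI uses the large-sample
    (Fleiss-Cohen-Everitt) delta-method standard error. The coder-side
    undetermined column enters the marginals with a zero reference row.
    """
    n = table.n
    if n == 0:
        return (
            MetricResult("kappa", None, n=0, reason="empty table"),
            KappaBreakdown(float("nan"), float("nan"), float("nan")),
        )
    cats = list(table.counts.columns)  # union: substantive + coder undetermined
    square = table.counts.reindex(index=cats, columns=cats, fill_value=0)
    p = square.to_numpy(dtype=float) / n
    row = p.sum(axis=1)
    col = p.sum(axis=0)
    p_o = float(np.trace(p))
    p_e = float(row @ col)
    if p_e >= 1.0 - 1e-15:
        return (
            MetricResult("kappa", None, n=n, reason="degenerate marginals (p_e = 1)"),
            KappaBreakdown(p_o, p_e, float("nan")),
        )
    kappa = (p_o - p_e) / (1 - p_e)
    # Fleiss, Cohen & Everitt large-sample variance of kappa-hat
    diag = np.diag(p)
    a = float(np.sum(diag * ((1 - p_e) - (row + col) * (1 - p_o)) ** 2))
    off = p.copy()
    np.fill_diagonal(off, 0.0)
    # cell (i, j), i != j: weight is (column marginal of i + row marginal of j)^2
    b = float((1 - p_o) ** 2 * np.sum(off * (col[:, None] + row[None, :]) ** 2))
    c = (p_o * p_e - 2 * p_e + p_o) ** 2
    var = (a + b - c) / (n * (1 - p_e) ** 4)
    se = float(np.sqrt(max(var, 0.0)))
    from scipy.stats import norm

    z = norm.ppf(0.5 + level / 2)
    result = MetricResult(
        "kappa",
        kappa,
        max(-1.0, kappa - z * se),
        min(1.0, kappa + z * se),
        n,
    )
    return result, KappaBreakdown(p_o, p_e, kappa)


#: agreement bands for kappa (McHugh-style), with the printed gaps between
#: bands resolved as contiguous half-open intervals at the gap midpoints
KAPPA_BANDS: tuple[tuple[float, str], ...] = (
    (0.205, "None"),
    (0.395, "Minimal"),
    (0.595, "Weak"),
    (0.795, "Moderate"),
    (0.905, "Strong"),
    (np.inf, "Almost Perfect"),
)


def interpret_kappa(kappa: float) -> str:
    """Map a kappa value to its agreement band label.

    The published band edges (.21-.39, .40-.59, ...) leave gaps at the
    second decimal; the implementation uses the gap midpoints so every value
    in [-1, 1] receives exactly one label.
    """
    if not -1.0 <= kappa <= 1.0:
        raise ValueError(f"kappa must lie in [-1, 1], got {kappa}")
    for upper, label in KAPPA_BANDS:
        if kappa <= upper:
            return label
    raise AssertionError("unreachable")
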