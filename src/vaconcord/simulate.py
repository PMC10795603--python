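"""Synthetic VA cohorts with the statistical structure the evaluation assumes.

The real validation cohort is not publicly deposited, so this module
generates stand-in cohorts that reproduce its *shape*: a stratified
population (age group x sex x place of death), stratum-specific true
cause-of-death distributions over a 25-cause analysis list, a reference
coder that is correct except for an undetermined fraction, and automated
coders whose errors follow row-stochastic confusion matrices with an
undetermined column. Every generated quantity has a closed-form expectation
(:func:`expected_metrics`), which is what makes the full metric battery
testable without the study's data.

Generation model, per death:

1. draw a stratum from ``stratum_weights``;
2. draw the true cause from that stratum's CSMF;
3. the reference assignment is the true cause, replaced by undetermined
   with probability ``reference_undetermined_prob`` (reference error is
   modelled only through this mechanism — the reference is the standard);
4. for each coder, draw the assigned cause from row ``M[true]`` of its
   confusion matrix; the ranked list is a without-replacement ordering of
   the substantive part of that row (Gumbel top-k), so its first element is
   the assigned cause; synthetic propensity scores decrease down the list.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .causes import Cause, CauseList
from .cohort import AGE_GROUPS, Cohort

__all__ = [
    "ConfusionModel",
    "SimulationSpec",
    "generate",
    "expected_metrics",
    "default_cause_list",
    "default_spec",
]

StratumKey = tuple[str, str, str]  # (age_group, sex, place)


# ---------------------------------------------------------------------------
# Default study-shaped conditions
# ---------------------------------------------------------------------------

_DEFAULT_CAUSES: tuple[tuple[str, str], ...] = (
    ("hiv_aids", "HIV/AIDS"),
    ("pulmonary_tb", "Pulmonary tuberculosis"),
    ("pneumonia", "Acute respiratory infection incl. pneumonia"),
    ("diarrhoeal", "Diarrhoeal diseases"),
    ("other_infectious", "Other and unspecified infectious diseases"),
    ("maternal", "Maternal causes"),
    ("perinatal", "Perinatal conditions"),
    ("stillbirth", "Stillbirth"),
    ("malnutrition", "Malnutrition"),
    ("diabetes", "Diabetes mellitus"),
    ("acute_cardiac", "Acute cardiac disease"),
    ("other_cardiac", "Other cardiac disease"),
    ("stroke", "Stroke"),
    ("copd", "Chronic obstructive pulmonary disease"),
    ("other_respiratory", "Other respiratory disease"),
    ("digestive_cancer", "Digestive cancer"),
    ("lung_cancer", "Respiratory cancer"),
    ("other_cancers", "Other and unspecified cancers"),
    ("renal_failure", "Renal failure"),
    ("liver_disease", "Liver disease"),
    ("other_ncd", "Other and unspecified non-communicable diseases"),
    ("transport", "Transport-related injury"),
    ("homicide", "Assault/homicide"),
    ("suicide", "Intentional self-harm"),
    ("other_injuries", "Other and unspecified injuries"),
)

#: default all-ages CSMF over the substantive causes, anchored where the
#: study prints fractions (HIV/AIDS 0.22 of all deaths incl. undetermined,
#: broad groups HIV/TB 28.1%, other infectious/maternal/perinatal/
#: nutritional 8.8%, NCD 34.6%, injuries 12.6%) and renormalised to the
#: substantive universe
_BASE_CSMF_WITH_UNDET: dict[str, float] = {
    "hiv_aids": 0.220,
    "pulmonary_tb": 0.061,
    "pneumonia": 0.033,
    "diarrhoeal": 0.015,
    "other_infectious": 0.020,
    "maternal": 0.005,
    "perinatal": 0.014,
    "stillbirth": 0.0,
    "malnutrition": 0.001,
    "diabetes": 0.040,
    "acute_cardiac": 0.020,
    "other_cardiac": 0.030,
    "stroke": 0.060,
    "copd": 0.010,
    "other_respiratory": 0.012,
    "digestive_cancer": 0.010,
    "lung_cancer": 0.060,
    "other_cancers": 0.045,
    "renal_failure": 0.020,
    "liver_disease": 0.013,
    "other_ncd": 0.026,
    "transport": 0.050,
    "homicide": 0.042,
    "suicide": 0.016,
    "other_injuries": 0.018,
}

#: printed sample margins: 102/204/2018/3062 by age, 2579 F / 2807 M,
#: 2926 in facility / 2460 out, of 5386 deaths
_AGE_MARGIN = {"neonate": 102, "child": 204, "adult": 2018, "elder": 3062}
_SEX_MARGIN = {"female": 2579, "male": 2807}
_PLACE_MARGIN = {"in_facility": 2926, "out_of_facility": 2460}
_DEFAULT_N = 5386
_DEFAULT_UNDETERMINED = 0.158

_AGE_TILT: dict[str, dict[str, float]] = {
    "neonate": {},  # handled specially: all perinatal
    "child": {
        "diarrhoeal": 8, "pneumonia": 3, "other_infectious": 3, "malnutrition": 25,
        "perinatal": 4, "hiv_aids": 0.8, "diabetes": 0.1, "acute_cardiac": 0.1,
        "other_cardiac": 0.2, "stroke": 0.05, "copd": 0.05, "digestive_cancer": 0.1,
        "lung_cancer": 0.02, "other_cancers": 0.4, "renal_failure": 0.3,
        "liver_disease": 0.2, "maternal": 0.0, "transport": 1.2, "homicide": 0.4,
        "suicide": 0.05, "other_injuries": 1.5,
    },
    "adult": {
        "hiv_aids": 1.6, "pulmonary_tb": 1.3, "maternal": 3.0, "perinatal": 0.0,
        "malnutrition": 0.5, "transport": 1.5, "homicide": 1.8, "suicide": 1.5,
        "diabetes": 0.5, "acute_cardiac": 0.5, "stroke": 0.4, "copd": 0.3,
        "digestive_cancer": 0.6, "lung_cancer": 0.5, "other_cancers": 0.7,
    },
    "elder": {
        "hiv_aids": 0.5, "pulmonary_tb": 0.8, "maternal": 0.0, "perinatal": 0.0,
        "malnutrition": 0.3, "diarrhoeal": 0.5, "transport": 0.5, "homicide": 0.3,
        "suicide": 0.4, "other_injuries": 0.6, "diabetes": 1.5, "acute_cardiac": 1.5,
        "other_cardiac": 1.5, "stroke": 1.8, "copd": 1.5, "digestive_cancer": 1.3,
        "lung_cancer": 1.4, "other_cancers": 1.3,
    },
}

_SEX_TILT: dict[str, dict[str, float]] = {
    "male": {"maternal": 0.0, "pulmonary_tb": 1.4, "homicide": 1.5, "transport": 1.3,
             "suicide": 1.3, "lung_cancer": 1.2},
    "female": {"maternal": 2.0, "pulmonary_tb": 0.7},
}

#: per-cause diagonal of the default coder confusion matrices (probability a
#: coder recovers the true cause), loosely shaped like the observed pattern:
#: injuries and HIV recovered well, pneumonia / other infectious / renal
#: failure poorly
_DEFAULT_DIAGONAL: dict[str, float] = {
    "hiv_aids": 0.72, "pulmonary_tb": 0.52, "pneumonia": 0.18, "diarrhoeal": 0.35,
    "other_infectious": 0.15, "maternal": 0.50, "perinatal": 0.82, "stillbirth": 0.0,
    "malnutrition": 0.30, "diabetes": 0.45, "acute_cardiac": 0.30,
    "other_cardiac": 0.30, "stroke": 0.50, "copd": 0.45, "other_respiratory": 0.22,
    "digestive_cancer": 0.35, "lung_cancer": 0.50, "other_cancers": 0.42,
    "renal_failure": 0.15, "liver_disease": 0.30, "other_ncd": 0.22,
    "transport": 0.95, "homicide": 0.80, "suicide": 0.70, "other_injuries": 0.40,
}


def default_cause_list() -> CauseList:
    """The default 25-cause analysis list plus an undetermined category."""
    causes = tuple(Cause(code, label) for code, label in _DEFAULT_CAUSES)
    return CauseList("analysis25", causes + (Cause("undetermined", "Undetermined", True),))


def _tilted_csmf(cause_list: CauseList, age_group: str, sex: str) -> pd.Series:
    codes = list(cause_list.substantive_codes)
    if age_group == "neonate":
        # reference coding concentrates neonatal deaths heavily on perinatal
        # causes (never stillbirth), with a thin scatter of infections
        s = pd.Series(0.0, index=codes)
        s["perinatal"] = 0.92
        s["pneumonia"] = 0.02
        s["other_infectious"] = 0.02
        s["diarrhoeal"] = 0.01
        s["malnutrition"] = 0.01
        s["other_injuries"] = 0.02
        return s
    base = pd.Series({c: _BASE_CSMF_WITH_UNDET.get(c, 0.0) for c in codes})
    for cause, f in _AGE_TILT.get(age_group, {}).items():
        if cause in base.index:
            base[cause] *= f
    for cause, f in _SEX_TILT.get(sex, {}).items():
        if cause in base.index:
            base[cause] *= f
    return base / base.sum()


# ---------------------------------------------------------------------------
# Confusion model
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ConfusionModel:
    """Row-stochastic misclassification model for one coder.

    ``M`` has one row per substantive true cause and one column per
    substantive cause plus (when the cause list declares one) an
    undetermined column: ``M[i, j]`` is the probability the coder assigns
    cause *j* to a death whose true cause is *i*. Indeterminate assignment
    defaults into the undetermined column (``indeterminate_threshold = 0``);
    a positive threshold instead re-labels low-score top causes as
    undetermined, emulating an InterVA-style likelihood cutoff, at the cost
    of the closed-form expectations becoming approximate.
    """

    M: pd.DataFrame
    rank_depth: int = 3
    score_noise: float = 0.08
    indeterminate_threshold: float = 0.0

    def __post_init__(self) -> None:
        arr = self.M.to_numpy(dtype=float)
        if (arr < -1e-12).any():
            raise ValueError("confusion probabilities must be non-negative")
        if not np.allclose(arr.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("every confusion-matrix row must sum to 1")
        if self.rank_depth < 1:
            raise ValueError("rank_depth must be >= 1")
        if not 0.0 <= self.indeterminate_threshold <= 1.0:
            raise ValueError("indeterminate_threshold must lie in [0, 1]")

    @classmethod
    def identity(cls, cause_list: CauseList, rank_depth: int = 3) -> "ConfusionModel":
        rows = list(cause_list.substantive_codes)
        cols = rows + ([cause_list.undetermined_code] if cause_list.undetermined_code else [])
        M = pd.DataFrame(0.0, index=rows, columns=cols)
        for c in rows:
            M.at[c, c] = 1.0
        return cls(M, rank_depth=rank_depth)

    @classmethod
    def from_diagonal(
        cls,
        cause_list: CauseList,
        diagonal: Mapping[str, float],
        undetermined_prob: float = 0.0,
        spread_weights: Mapping[str, float] | None = None,
        rank_depth: int = 3,
        **kwargs,
    ) -> "ConfusionModel":
        """Build ``M`` from a per-cause recovery probability.

        Row *i* places ``diagonal[i]`` on the true cause,
        ``undetermined_prob`` on undetermined, and spreads the remainder
        over the other substantive causes proportionally to
        ``spread_weights`` (default: uniform). A floor in the default
        weights lets coders emit causes with zero true mass, e.g.
        stillbirths in a sample that contains none.
        """
        rows = list(cause_list.substantive_codes)
        undet = cause_list.undetermined_code
        cols = rows + ([undet] if undet else [])
        if spread_weights is None:
            spread_weights = {c: 1.0 for c in rows}
        M = pd.DataFrame(0.0, index=rows, columns=cols)
        for c in rows:
            d = float(diagonal.get(c, 0.5))
            rest = 1.0 - d - undetermined_prob
            if rest < -1e-12:
                raise ValueError(f"diagonal + undetermined exceed 1 for cause {c!r}")
            w = pd.Series({k: float(spread_weights.get(k, 0.0)) for k in rows if k != c})
            if w.sum() <= 0 and rest > 0:
                raise ValueError("spread weights are all zero")
            M.loc[c, w.index] = rest * (w / w.sum()).to_numpy()
            M.at[c, c] = d
            if undet:
                M.at[c, undet] = undetermined_prob
        return cls(M, rank_depth=rank_depth, **kwargs)


def _default_coders(cause_list: CauseList) -> dict[str, ConfusionModel]:
    # spread confusion toward common causes; small floor keeps rare columns
    # (incl. stillbirth) reachable by every coder
    spread = {
        c: _BASE_CSMF_WITH_UNDET.get(c, 0.0) + 0.01
        for c in cause_list.substantive_codes
    }
    base = _DEFAULT_DIAGONAL
    probabilistic = {c: min(0.92, v * 1.08) for c, v in base.items()}
    tariff = dict(base)
    # structural gaps: this coder never emits these causes
    tariff_spread = dict(spread)
    for gap in ("malnutrition", "other_cardiac"):
        tariff[gap] = 0.0
        tariff_spread[gap] = 0.0
    tariff["hiv_aids"] = 0.80
    tariff["diabetes"] = 0.55
    tariff["copd"] = 0.56
    tariff["homicide"] = 0.45
    def capped(diag: dict[str, float], undet: float) -> dict[str, float]:
        # leave a little off-diagonal mass so every coder can rank >=3 causes
        return {c: min(v, 0.98 - undet) for c, v in diag.items()}

    return {
        "interva5": ConfusionModel.from_diagonal(
            cause_list, capped(base, 0.10), undetermined_prob=0.10,
            spread_weights=spread,
        ),
        "insilicova": ConfusionModel.from_diagonal(
            cause_list, probabilistic, undetermined_prob=0.0, spread_weights=spread
        ),
        "tariff2": ConfusionModel.from_diagonal(
            cause_list, capped(tariff, 0.18), undetermined_prob=0.18,
            spread_weights=tariff_spread, rank_depth=1,
        ),
    }


# ---------------------------------------------------------------------------
# Simulation spec
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SimulationSpec:
    """Complete description of one synthetic cohort.

    ``stratum_weights`` is a Series over (age_group, sex, place) keys,
    ``csmf`` maps each stratum key to its true CSMF over the substantive
    causes, and ``reference_undetermined_prob`` is a scalar or per-stratum
    map. A seed is mandatory: cohorts are reproducible by construction.
    """

    cause_list: CauseList
    n: int
    stratum_weights: pd.Series
    csmf: Mapping[StratumKey, pd.Series]
    reference_undetermined_prob: float | Mapping[StratumKey, float]
    coders: Mapping[str, ConfusionModel]
    seed: int

    def __post_init__(self) -> None:
        if self.n <= 0:
            raise ValueError("n must be positive")
        if abs(float(self.stratum_weights.sum()) - 1.0) > 1e-9:
            raise ValueError("stratum weights must sum to 1")
        for key, p in self.csmf.items():
            if abs(float(p.sum()) - 1.0) > 1e-9:
                raise ValueError(f"CSMF for stratum {key} must sum to 1")
            if (p < -1e-12).any():
                raise ValueError(f"CSMF for stratum {key} has negative mass")
        for key in self.stratum_weights.index:
            if tuple(key) not in self.csmf:
                raise ValueError(f"no CSMF for stratum {tuple(key)}")

    def undetermined_prob(self, key: StratumKey) -> float:
        if isinstance(self.reference_undetermined_prob, Mapping):
            return float(self.reference_undetermined_prob[key])
        return float(self.reference_undetermined_prob)


def default_spec(
    n: int = _DEFAULT_N,
    seed: int = 0,
    reference_undetermined_prob: float = _DEFAULT_UNDETERMINED,
    coders: Mapping[str, ConfusionModel] | None = None,
    cause_list: CauseList | None = None,
) -> SimulationSpec:
    """The default study-shaped conditions: printed sample margins
    (age 102/204/2018/3062, sex 2579/2807, place 2926/2460 of 5386),
    undetermined fraction 0.158, and three coders emulating a deterministic
    propensity coder, a probabilistic coder, and a single-cause score coder."""
    cl = cause_list or default_cause_list()
    age_p = pd.Series(_AGE_MARGIN, dtype=float) / _DEFAULT_N
    sex_p = pd.Series(_SEX_MARGIN, dtype=float) / _DEFAULT_N
    place_p = pd.Series(_PLACE_MARGIN, dtype=float) / _DEFAULT_N
    keys = list(itertools.product(age_p.index, sex_p.index, place_p.index))
    weights = pd.Series(
        [age_p[a] * sex_p[s] * place_p[pl] for a, s, pl in keys],
        index=pd.MultiIndex.from_tuples(keys, names=["age_group", "sex", "place"]),
    )
    weights = weights / weights.sum()
    csmf = {
        (a, s, pl): _tilted_csmf(cl, a, s)
        for a, s, pl in keys
    }
    return SimulationSpec(
        cause_list=cl,
        n=n,
        stratum_weights=weights,
        csmf=csmf,
        reference_undetermined_prob=reference_undetermined_prob,
        coders=dict(coders) if coders is not None else _default_coders(cl),
        seed=seed,
    )


# ---------------------------------------------------------------------------
# Generation
# ---------------------------------------------------------------------------

_AGE_RANGES_YEARS = {
    "neonate": (0.0, 27 / 365.25),
    "child": (28 / 365.25, 11.9),
    "adult": (12.0, 49.9),
    "elder": (50.0, 95.0),
}


def generate(spec: SimulationSpec) -> Cohort:
    """Draw one cohort from the spec; identical spec + seed gives an
    identical cohort."""
    rng = np.random.default_rng(spec.seed)
    cl = spec.cause_list
    sub = list(cl.substantive_codes)
    undet = cl.undetermined_code
    n = spec.n

    keys = [tuple(k) for k in spec.stratum_weights.index]
    stratum_idx = rng.choice(len(keys), size=n, p=spec.stratum_weights.to_numpy())

    true_cause = np.empty(n, dtype=object)
    ref_cause = np.empty(n, dtype=object)
    age_years = np.empty(n, dtype=float)
    for si, key in enumerate(keys):
        mask = stratum_idx == si
        m = int(mask.sum())
        if m == 0:
            continue
        p = spec.csmf[key].reindex(sub, fill_value=0.0).to_numpy()
        true_cause[mask] = rng.choice(sub, size=m, p=p)
        lo, hi = _AGE_RANGES_YEARS[key[0]]
        age_years[mask] = rng.uniform(lo, hi, size=m)
        u = spec.undetermined_prob(key)
        repl = rng.random(m) < u
        refs = true_cause[mask].copy()
        if undet is not None:
            refs[repl] = undet
        ref_cause[mask] = refs

    data: dict[str, object] = {
        "id": [f"d{i:06d}" for i in range(n)],
        "age_value": np.round(age_years, 3),
        "age_unit": ["years"] * n,
        "sex": [keys[si][1] for si in stratum_idx],
        "place": [keys[si][2] for si in stratum_idx],
        "ref_cause": ref_cause,
    }

    true_idx = np.array([sub.index(c) for c in true_cause])
    for name, model in spec.coders.items():
        Msub = model.M.reindex(index=sub, columns=sub, fill_value=0.0).to_numpy()
        u_col = (
            model.M[undet].reindex(sub, fill_value=0.0).to_numpy()
            if undet is not None and undet in model.M.columns
            else np.zeros(len(sub))
        )
        rows = Msub[true_idx]  # (n, C) substantive probabilities per record
        is_undet = rng.random(n) < u_col[true_idx]
        # Gumbel top-k gives a without-replacement ordering whose first
        # element is distributed as the renormalised substantive row
        with np.errstate(divide="ignore", invalid="ignore"):
            logits = np.log(np.clip(rows, 0.0, None))
        gumbel = rng.gumbel(size=rows.shape)
        order = np.argsort(-(logits + gumbel), axis=1)
        depth = model.rank_depth
        ranked = np.array(sub, dtype=object)[order[:, :depth]]
        n_avail = (rows > 0).sum(axis=1)

        assigned = ranked[:, 0].copy()
        if undet is not None:
            assigned[is_undet] = undet
        assigned[n_avail == 0] = undet if undet is not None else ""

        top_p = np.take_along_axis(rows, order[:, :1], axis=1)[:, 0]
        score = np.clip(
            rng.normal(top_p, model.score_noise), 1e-4, 1.0
        )
        scores = [score]
        for k in range(1, depth):
            score = score * rng.uniform(0.4, 0.9, size=n)
            scores.append(score)
        if model.indeterminate_threshold > 0 and undet is not None:
            assigned[scores[0] < model.indeterminate_threshold] = undet

        data[f"{name}_cause"] = assigned
        for k in range(depth):
            col = ranked[:, k].astype(object)
            col[n_avail <= k] = ""
            data[f"{name}_rank{k + 1}"] = col
            data[f"{name}_score{k + 1}"] = np.round(scores[k], 6)

    frame = pd.DataFrame(data)
    return Cohort(frame, cl, list(spec.coders))


# ---------------------------------------------------------------------------
# Closed-form expectations (test oracle)
# ---------------------------------------------------------------------------


def expected_metrics(
    spec: SimulationSpec, strata: list[StratumKey] | None = None
) -> dict[str, dict[str, object]]:
    """Analytic expectations of the metric battery under the spec.

    Computed on the post-exclusion population (reference-undetermined mass
    removed): per-cause sensitivity is the confusion diagonal, the coder
    CSMF is ``p' M`` for true-cause distribution ``p``, overall agreement is
    ``sum_j p_j M_jj``, kappa follows from those marginals, and CSMF
    accuracy compares ``p' M`` (undetermined column included) with ``p``.
    Exact when ``indeterminate_threshold`` is 0 for every coder.
    """
    cl = spec.cause_list
    sub = list(cl.substantive_codes)
    undet = cl.undetermined_code
    keys = (
        [tuple(k) for k in spec.stratum_weights.index] if strata is None else list(strata)
    )
    # post-exclusion true-cause distribution: strata with higher undetermined
    # fractions contribute proportionally less
    mass = np.array(
        [spec.stratum_weights.get(k, 0.0) * (1 - spec.undetermined_prob(k)) for k in keys]
    )
    if mass.sum() <= 0:
        raise ValueError("no post-exclusion mass in the requested strata")
    w = mass / mass.sum()
    p = pd.Series(0.0, index=sub)
    for wk, key in zip(w, keys):
        p = p + wk * spec.csmf[key].reindex(sub, fill_value=0.0)

    out: dict[str, dict[str, object]] = {}
    for name, model in spec.coders.items():
        cols = sub + ([undet] if undet else [])
        M = model.M.reindex(index=sub, columns=cols, fill_value=0.0)
        q = p.to_numpy() @ M.to_numpy()  # coder category distribution
        q = pd.Series(q, index=cols)
        diag = pd.Series(np.diag(M.loc[sub, sub].to_numpy()), index=sub)
        p_o = float((p * diag).sum())
        ref_marg = p.reindex(cols, fill_value=0.0)  # undetermined mass is 0
        p_e = float((ref_marg * q).sum())
        kappa = (p_o - p_e) / (1 - p_e)
        t = ref_marg.to_numpy()
        acc = 1.0 - float(np.abs(t - q.to_numpy()).sum()) / (2 * (1 - t.min()))
        out[name] = {
            "sensitivity": diag,
            "coder_csmf": q,
            "overall_agreement": p_o,
            "kappa": kappa,
            "csmf_accuracy": acc,
            "true_csmf": p,
        }
    return out
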