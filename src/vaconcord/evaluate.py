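"""End-to-end agreement evaluation: map, filter, stratify, score, report.

The central objects follow the model/results convention of statistical
packages: :class:`AgreementEvaluation` is built from a cohort (or from the
cohort/cause-list/map files named in a :class:`RunConfig`), and its
:meth:`~AgreementEvaluation.fit` returns an :class:`AgreementResults`
carrying every metric for every coder in every stratum, with a
``summary()`` table and writers for wide CSV, tidy CSV and JSON.

Pipeline stages, in order: cause mapping (optional) → descriptive CSMFs
including undetermined → redistribution of the reference-undetermined
deaths → exclusion of those deaths → per-stratum, per-coder metric battery.
A stage-count ledger (rows in = rows excluded + per-age-stratum rows) is
asserted on every run.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import pandas as pd
import yaml

from .causes import CauseList, CauseMap, UnmappedCodeError, compose_maps, load_cause_list
from .cohort import STANDARD_STRATA, Cohort, StratumSpec, read_cohort
from .individual import (
    ConfusionTable,
    MetricResult,
    UnsupportedCoderError,
    build_confusion,
    ccc,
    cohens_kappa,
    interpret_kappa,
    mean_ccc,
    overall_agreement,
    ppv,
    sensitivity,
)
from .population import (
    chance_corrected_csmf_accuracy,
    csmf,
    csmf_accuracy,
    redistribution_matrix,
    spearman_rank_correlation,
)

logger = logging.getLogger(__name__)

__all__ = [
    "RunConfig",
    "AgreementEvaluation",
    "AgreementResults",
    "run_evaluation",
    "top3_supported",
    "write_report",
    "apply_cause_map",
]


@dataclass
class RunConfig:
    """Everything one evaluation run needs, loadable from YAML/JSON."""

    cohort: str
    cause_list: str
    cause_maps: tuple[str, ...] = ()
    coders: tuple[str, ...] | None = None
    ci_level: float = 0.95
    output_dir: str = "."
    seed: int = 0
    formats: tuple[str, ...] = ("wide", "tidy", "json")
    unmapped: str = "error"  # or "undetermined"
    map_columns: tuple[str, ...] = ("ref_cause",)

    def __post_init__(self) -> None:
        if not 0.0 < self.ci_level < 1.0:
            raise ValueError("ci_level must lie in (0, 1)")
        if self.unmapped not in {"error", "undetermined"}:
            raise ValueError("unmapped must be 'error' or 'undetermined'")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        for key in ("cause_maps", "coders", "formats", "map_columns"):
            if key in raw and raw[key] is not None:
                raw[key] = tuple(raw[key])
        return cls(**raw)


def apply_cause_map(
    frame: pd.DataFrame,
    cause_map: CauseMap,
    columns: Sequence[str],
    unmapped: str = "error",
) -> pd.DataFrame:
    """Map the cause codes in ``columns`` through ``cause_map``.

    Unmapped codes are a hard error by default; ``unmapped="undetermined"``
    routes them to the target list's undetermined category with a logged
    warning, so mapping-table gaps stay visible.
    """
    out = frame.copy()
    undet = cause_map.target_list.undetermined_code
    for col in columns:
        mapped = []
        misses: list[str] = []
        for code in out[col]:
            try:
                mapped.append(cause_map(code).code)
            except UnmappedCodeError:
                if unmapped == "undetermined" and undet is not None:
                    misses.append(code)
                    mapped.append(undet)
                else:
                    raise
        if misses:
            logger.warning(
                "column %s: %d codes not in map routed to undetermined (e.g. %s)",
                col, len(misses), sorted(set(misses))[:5],
            )
        out[col] = mapped
    return out


def top3_supported(cohort: Cohort, coder: str) -> bool:
    """Whether every record exposes at least 3 ranked causes for the coder
    (ignoring its indeterminate cutoff). Single-cause coders return False."""
    cols = [f"{coder}_rank{r}" for r in (1, 2, 3)]
    if any(c not in cohort.frame.columns for c in cols):
        return False
    incomplete = (cohort.frame[cols] == "").any(axis=1)
    if incomplete.any():
        logger.info(
            "coder %s: %d records carry fewer than 3 ranked causes",
            coder, int(incomplete.sum()),
        )
        return False
    return True


def _metric_dict(m: MetricResult) -> dict:
    return {
        "value": m.value,
        "ci_low": m.ci_low,
        "ci_high": m.ci_high,
        "n": m.n,
        "reason": m.reason,
    }


@dataclass
class AgreementResults:
    """Stratified report of every agreement metric for every coder.

    ``rows`` holds one dict per stratum x coder with full-precision values;
    the per-cause PPV/sensitivity/CCC battery and the CSMF tables are tidy
    DataFrames. Display rounding (percentages to 1 decimal, proportions to
    2) happens only in the wide table and ``summary()``.
    """

    strata: tuple[str, ...]
    coders: tuple[str, ...]
    rows: list[dict]
    per_cause: pd.DataFrame
    csmf_descriptive: pd.DataFrame
    csmf_agreement: pd.DataFrame
    redistribution: pd.DataFrame
    confusion: dict[str, ConfusionTable]
    counts: dict[str, int]
    metadata: dict = field(default_factory=dict)

    # -- views --------------------------------------------------------------------
    def to_wide_frame(self) -> pd.DataFrame:
        """Report-shaped wide table, one row per stratum x coder, display-rounded."""
        recs = []
        for r in self.rows:
            def pct(m):  # noqa: ANN001 - internal formatter
                return None if m["value"] is None else round(100 * m["value"], 1)

            def prop(m):  # noqa: ANN001
                return None if m["value"] is None else round(m["value"], 2)

            recs.append(
                {
                    "stratum": r["stratum"],
                    "coder": r["coder"],
                    "n": r["n"],
                    "overall_agreement_top1_pct": pct(r["overall_agreement_top1"]),
                    "oa_top1_ci": _ci_str(r["overall_agreement_top1"], scale=100),
                    "overall_agreement_top3_pct": pct(r["overall_agreement_top3"]),
                    "oa_top3_ci": _ci_str(r["overall_agreement_top3"], scale=100),
                    "kappa": prop(r["kappa"]),
                    "kappa_ci": _ci_str(r["kappa"]),
                    "kappa_band": r["kappa_band"],
                    "mean_ccc": prop(r["mean_ccc"]),
                    "csmf_accuracy": prop(r["csmf_accuracy"]),
                    "spearman_rho": prop(r["spearman_rho"]),
                    "rho_ci": _ci_str(r["spearman_rho"]),
                }
            )
        return pd.DataFrame(recs)

    def to_tidy_frame(self) -> pd.DataFrame:
        """Long format ``stratum,coder,metric,cause,value,ci_low,ci_high,n``
        at full precision, stratum-level and per-cause metrics together."""
        recs = []
        for r in self.rows:
            for metric in (
                "overall_agreement_top1",
                "overall_agreement_top3",
                "kappa",
                "mean_ccc",
                "spearman_rho",
            ):
                m = r[metric]
                recs.append(
                    {
                        "stratum": r["stratum"], "coder": r["coder"], "metric": metric,
                        "cause": "", "value": m["value"], "ci_low": m["ci_low"],
                        "ci_high": m["ci_high"], "n": m["n"],
                    }
                )
            for metric in ("csmf_accuracy", "chance_corrected_csmf_accuracy"):
                recs.append(
                    {
                        "stratum": r["stratum"], "coder": r["coder"], "metric": metric,
                        "cause": "", "value": r[metric]["value"], "ci_low": None,
                        "ci_high": None, "n": r["n"],
                    }
                )
        tidy = pd.DataFrame(recs)
        if not self.per_cause.empty:
            tidy = pd.concat([tidy, self.per_cause], ignore_index=True)
        return tidy

    def to_json_dict(self) -> dict:
        return {
            "counts": self.counts,
            "metadata": self.metadata,
            "rows": self.rows,
            "per_cause": self.per_cause.to_dict(orient="records"),
            "csmf_descriptive": self.csmf_descriptive.to_dict(orient="records"),
            "csmf_agreement": self.csmf_agreement.to_dict(orient="records"),
            "redistribution": self.redistribution.to_dict(orient="records"),
        }

    def summary(self) -> str:
        """Human-readable stratified summary table."""
        lines = [
            "Agreement evaluation (reference vs automated coders)",
            f"records in: {self.counts['rows_in']}   "
            f"reference-undetermined excluded: {self.counts['rows_excluded']}   "
            f"analysed: {self.counts['rows_retained']}",
            "",
            f"{'stratum':<16}{'coder':<12}{'n':>6}{'OA top1%':>10}{'OA top3%':>10}"
            f"{'kappa':>8}{'band':>15}{'CCC':>7}{'CSMFacc':>9}{'rho':>7}",
        ]
        for r in self.rows:
            def f(m, scale=1.0, nd=2):  # noqa: ANN001
                return "." if m["value"] is None else f"{scale * m['value']:.{nd}f}"

            lines.append(
                f"{r['stratum']:<16}{r['coder']:<12}{r['n']:>6}"
                f"{f(r['overall_agreement_top1'], 100, 1):>10}"
                f"{f(r['overall_agreement_top3'], 100, 1):>10}"
                f"{f(r['kappa']):>8}{(r['kappa_band'] or '.'):>15}"
                f"{f(r['mean_ccc']):>7}{f(r['csmf_accuracy']):>9}"
                f"{f(r['spearman_rho']):>7}"
            )
        return "\n".join(lines)

    def write(self, output_dir: str | Path, formats: Sequence[str] = ("wide", "tidy", "json")) -> list[Path]:
        return write_report(self, output_dir, formats)


def _ci_str(m: dict, scale: float = 1.0) -> str | None:
    if m["ci_low"] is None:
        return None
    nd = 1 if scale == 100 else 2
    return f"({scale * m['ci_low']:.{nd}f}-{scale * m['ci_high']:.{nd}f})"


class AgreementEvaluation:
    """Model object: one cohort, a stratum set, and a CI level.

    Parameters
    ----------
    cohort
        Validated cohort, already on the analysis cause list.
    strata
        Stratum specs to evaluate; defaults to total + four age groups +
        both sexes + in/out of facility.
    ci_level
        Two-sided confidence level for the proportion and kappa intervals.
    """

    def __init__(
        self,
        cohort: Cohort,
        strata: Sequence[StratumSpec] = STANDARD_STRATA,
        ci_level: float = 0.95,
    ):
        self.cohort = cohort
        self.strata = tuple(strata)
        self.ci_level = ci_level

    @classmethod
    def from_files(
        cls,
        cohort_path: str | Path,
        cause_list_path: str | Path,
        cause_map_paths: Sequence[str | Path] = (),
        coders: Sequence[str] | None = None,
        unmapped: str = "error",
        map_columns: Sequence[str] = ("ref_cause",),
        **kwargs,
    ) -> "AgreementEvaluation":
        cause_list = load_cause_list(cause_list_path)
        if cause_map_paths:
            maps = [CauseMap.read(p, cause_list) for p in cause_map_paths]
            # intermediate maps target the *next* map's source; only the last
            # must target the analysis list, so re-read accordingly
            if len(maps) > 1:
                raise NotImplementedError(
                    "chained map files: compose them with compose_maps() and "
                    "pass a single file"
                )
            frame = pd.read_csv(cohort_path, dtype={"id": str}, keep_default_na=False, na_values=[])
            frame = apply_cause_map(frame, maps[0], map_columns, unmapped)
            cohort = Cohort(frame, cause_list, coders)
        else:
            cohort = read_cohort(cohort_path, cause_list, coders)
        return cls(cohort, **kwargs)

    @classmethod
    def from_config(cls, config: RunConfig) -> "AgreementEvaluation":
        ev = cls.from_files(
            config.cohort,
            config.cause_list,
            config.cause_maps,
            coders=config.coders,
            unmapped=config.unmapped,
            map_columns=config.map_columns,
            ci_level=config.ci_level,
        )
        if config.coders:
            absent = [k for k in config.coders if k not in ev.cohort.coders]
            if absent:
                raise ValueError(f"configured coders absent from cohort: {absent}")
        return ev

    # -- fitting ------------------------------------------------------------------
    def fit(self) -> AgreementResults:
        cohort = self.cohort
        level = self.ci_level
        cl = cohort.cause_list
        C = cl.C

        # descriptive CSMFs (undetermined included) on the full cohort
        desc_recs = []
        for spec in self.strata:
            sub = cohort.stratify(spec)
            if len(sub) == 0:
                continue
            for who in ("reference", *cohort.coders):
                vec = csmf(sub, who, include_undetermined=True)
                for cause, frac in vec.fractions.items():
                    desc_recs.append(
                        {"stratum": spec.name, "coder": who, "cause": cause,
                         "csmf": float(frac)}
                    )
        csmf_descriptive = pd.DataFrame(desc_recs)

        # redistribution of the reference-undetermined deaths
        undet_subset = cohort.reference_undetermined_subset()
        redist_recs = []
        if len(undet_subset) > 0:
            for coder in cohort.coders:
                vec = redistribution_matrix(undet_subset, coder)
                for cause, frac in vec.fractions.items():
                    redist_recs.append(
                        {"coder": coder, "cause": cause, "fraction": float(frac)}
                    )
        redistribution = pd.DataFrame(redist_recs)

        # exclusion filter + conservation ledger
        excl, n_excluded = cohort.exclude_reference_undetermined()
        age_counts = {
            g: int((excl.frame["age_group"] == g).sum())
            for g in ("neonate", "child", "adult", "elder")
        }
        counts = {
            "rows_in": len(cohort),
            "rows_excluded": n_excluded,
            "rows_retained": len(excl),
            **{f"retained_{g}": c for g, c in age_counts.items()},
        }
        if len(cohort) != n_excluded + sum(age_counts.values()):
            raise AssertionError("stage-count ledger violated: rows lost in filtering")

        rows: list[dict] = []
        cause_recs: list[dict] = []
        confusion: dict[str, ConfusionTable] = {}
        agr_recs: list[dict] = []
        for spec in self.strata:
            sub = excl.stratify(spec)
            for coder in cohort.coders:
                row: dict = {"stratum": spec.name, "coder": coder, "n": len(sub)}
                if len(sub) == 0:
                    empty = {"value": None, "ci_low": None, "ci_high": None, "n": 0,
                             "reason": "empty stratum"}
                    for m in ("overall_agreement_top1", "overall_agreement_top3",
                              "kappa", "mean_ccc", "csmf_accuracy",
                              "chance_corrected_csmf_accuracy", "spearman_rho"):
                        row[m] = dict(empty)
                    row["kappa_band"] = None
                    rows.append(row)
                    continue
                table = build_confusion(sub, coder)
                if spec.name == "total":
                    confusion[coder] = table

                row["overall_agreement_top1"] = _metric_dict(
                    overall_agreement(sub, coder, 1, level)
                )
                try:
                    row["overall_agreement_top3"] = _metric_dict(
                        overall_agreement(sub, coder, 3, level)
                    )
                except UnsupportedCoderError as err:
                    row["overall_agreement_top3"] = {
                        "value": None, "ci_low": None, "ci_high": None, "n": 0,
                        "reason": str(err),
                    }
                kappa_res, breakdown = cohens_kappa(table, level)
                row["kappa"] = _metric_dict(kappa_res)
                row["kappa_p_o"] = breakdown.p_o
                row["kappa_p_e"] = breakdown.p_e
                row["kappa_band"] = (
                    interpret_kappa(kappa_res.value) if kappa_res.is_defined else None
                )
                row["mean_ccc"] = _metric_dict(mean_ccc(table, C))

                ref_vec = csmf(sub, "reference", include_undetermined=True)
                pred_vec = csmf(sub, coder, include_undetermined=True)
                acc = csmf_accuracy(ref_vec, pred_vec)
                row["csmf_accuracy"] = {"value": acc, "ci_low": None, "ci_high": None,
                                        "n": len(sub), "reason": None}
                row["chance_corrected_csmf_accuracy"] = {
                    "value": chance_corrected_csmf_accuracy(acc), "ci_low": None,
                    "ci_high": None, "n": len(sub), "reason": None,
                }
                row["spearman_rho"] = _metric_dict(
                    spearman_rank_correlation(ref_vec, pred_vec, level)
                )
                rows.append(row)

                for cause, frac in pred_vec.fractions.items():
                    agr_recs.append({"stratum": spec.name, "coder": coder,
                                     "cause": cause, "csmf": float(frac)})
                if spec.name == "total":
                    for cause, frac in ref_vec.fractions.items():
                        agr_recs.append({"stratum": spec.name, "coder": "reference",
                                         "cause": cause, "csmf": float(frac)})
                    for cause in cl.substantive_codes:
                        for name, fn in (("ppv", ppv), ("sensitivity", sensitivity)):
                            m = fn(table, cause, level)
                            cause_recs.append(
                                {"stratum": spec.name, "coder": coder, "metric": name,
                                 "cause": cause, "value": m.value, "ci_low": m.ci_low,
                                 "ci_high": m.ci_high, "n": m.n}
                            )
                        m = ccc(table, cause, C)
                        cause_recs.append(
                            {"stratum": spec.name, "coder": coder, "metric": "ccc",
                             "cause": cause, "value": m.value, "ci_low": None,
                             "ci_high": None, "n": m.n}
                        )

        # drop duplicated reference rows from repeated appends
        csmf_agreement = pd.DataFrame(agr_recs).drop_duplicates(ignore_index=True)
        return AgreementResults(
            strata=tuple(s.name for s in self.strata),
            coders=cohort.coders,
            rows=rows,
            per_cause=pd.DataFrame(cause_recs),
            csmf_descriptive=csmf_descriptive,
            csmf_agreement=csmf_agreement,
            redistribution=redistribution,
            confusion=confusion,
            counts=counts,
            metadata={
                "cause_list": cl.name,
                "C": C,
                "ci_level": level,
                "csmf_agreement_mode": "post-exclusion, coder-side undetermined retained",
                "kappa_bands": "half-open intervals at published gap midpoints",
            },
        )


def run_evaluation(config: RunConfig) -> AgreementResults:
    """Config-driven entry point: build the model from files, fit, and
    write the requested report formats to ``config.output_dir``."""
    results = AgreementEvaluation.from_config(config).fit()
    write_report(results, config.output_dir, config.formats)
    return results


def write_report(
    results: AgreementResults,
    output_dir: str | Path,
    formats: Sequence[str] = ("wide", "tidy", "json"),
) -> list[Path]:
    """Write the report files; byte-stable for identical inputs.

    ``wide`` → report_wide.csv (display-rounded, one row per stratum x
    coder); ``tidy`` → report_tidy.csv (full precision, long format) plus
    the CSMF and redistribution tables; ``json`` → report.json;
    ``figures`` → per-stratum CSMF bar charts (requires matplotlib).
    """
    outdir = Path(output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    if "wide" in formats:
        p = outdir / "report_wide.csv"
        results.to_wide_frame().to_csv(p, index=False)
        written.append(p)
    if "tidy" in formats:
        p = outdir / "report_tidy.csv"
        results.to_tidy_frame().to_csv(p, index=False)
        written.append(p)
        for name, frame in (
            ("csmf_descriptive", results.csmf_descriptive),
            ("csmf_agreement", results.csmf_agreement),
            ("redistribution", results.redistribution),
        ):
            p = outdir / f"{name}.csv"
            frame.to_csv(p, index=False)
            written.append(p)
        for coder, table in results.confusion.items():
            p = outdir / f"confusion_{coder}.csv"
            table.write(p)
            written.append(p)
    if "json" in formats:
        p = outdir / "report.json"
        with open(p, "w", encoding="utf-8") as fh:
            json.dump(results.to_json_dict(), fh, indent=1, sort_keys=True)
        written.append(p)
    if "figures" in formats:
        written.extend(_plot_csmf(results, outdir))
    return written


def _plot_csmf(results: AgreementResults, outdir: Path) -> list[Path]:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    written = []
    frame = results.csmf_descriptive
    for stratum in ("total", "male", "female"):
        sub = frame[frame["stratum"] == stratum]
        if sub.empty:
            continue
        pivot = sub.pivot(index="cause", columns="coder", values="csmf")
        ax = pivot.plot.barh(figsize=(8, 10))
        ax.set_xlabel("CSMF")
        ax.set_title(f"Cause-specific mortality fractions — {stratum}")
        p = outdir / f"csmf_{stratum}.png"
        ax.figure.tight_layout()
        ax.figure.savefig(p, dpi=120)
        plt.close(ax.figure)
        written.append(p)
    return written
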