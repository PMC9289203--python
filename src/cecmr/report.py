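"""One-call orchestration of the full MR analysis and report serialization.

:func:`run_analysis` runs the cross of outcomes × methods on either the
bundled tables (named by trait) or user-supplied summary files, adds the
per-outcome Cochran Q and the pairwise between-outcome comparisons, and
flags each result against the Bonferroni-corrected significance level of
0.05/6 = 0.0083 used when six outcomes are tested.  :func:`write_report`
renders the result as TSV, JSON (full precision) or a markdown grid using
the print conventions of the field: odds ratios to two decimals, Egger
intercepts to three, Q to one, I² as an integer percentage.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

from . import datasets
from .estimators import (
    DEFAULT_N_BOOT,
    EggerEstimate,
    MREstimate,
    ivw,
    mr_egger,
    simple_median,
    wald_ratio,
    weighted_median,
)
from .exceptions import CecmrError
from .heterogeneity import HeterogeneityResult, cochran_q, compare_estimates
from .summary import (
    DEFAULT_PALINDROMIC_EAF_WINDOW,
    HarmonizedInstrument,
    harmonize_tables,
    read_summary_table,
)

logger = logging.getLogger(__name__)

#: Bonferroni-corrected significance level for six outcomes (0.05/6).
BONFERRONI_ALPHA = 0.05 / 6

KNOWN_METHODS = ("wald", "ivw", "egger", "simple_median", "weighted_median")


@dataclass(frozen=True)
class AnalysisReport:
    """Full result set of one analysis run.

    ``estimates`` maps ``(outcome, method)`` to the causal estimate;
    ``egger`` holds the full Egger fits (slope + intercept);
    ``heterogeneity`` the per-outcome instrument Cochran Q (when k ≥ 2);
    ``comparisons`` the pairwise between-outcome heterogeneity tests on the
    primary estimates.  A result is flagged significant iff its p-value is
    below :data:`BONFERRONI_ALPHA`.
    """

    outcomes: tuple[str, ...]
    methods: tuple[str, ...]
    n_snps: int
    estimates: Mapping[tuple[str, str], MREstimate]
    egger: Mapping[str, EggerEstimate] = field(default_factory=dict)
    heterogeneity: Mapping[str, HeterogeneityResult] = field(default_factory=dict)
    comparisons: Mapping[tuple[str, str], HeterogeneityResult] = field(
        default_factory=dict)
    alpha: float = BONFERRONI_ALPHA

    def is_significant(self, outcome: str, method: str) -> bool:
        return self.estimates[(outcome, method)].pvalue < self.alpha


def _resolve_instruments(
    exposure: str | Path,
    outcome: str | Path,
    snps: Sequence[str] | None,
    palindromic_eaf_window: float,
) -> list[HarmonizedInstrument]:
    if isinstance(outcome, str) and outcome in datasets.OUTCOME_TRAITS:
        wanted = tuple(snps) if snps else datasets.FIVE_SNP_SET
        return datasets.instrument_for(outcome, wanted)
    exposure_table = read_summary_table(exposure)
    if snps:
        exposure_table = [r for r in exposure_table if r.snp_id in set(snps)]
    outcome_table = read_summary_table(outcome)
    return harmonize_tables(exposure_table, outcome_table,
                            palindromic_eaf_window)


def run_analysis(
    outcomes: Sequence[str | Path] = datasets.OUTCOME_TRAITS,
    methods: Sequence[str] = ("ivw", "egger", "simple_median", "weighted_median"),
    exposure: str | Path = "CEC",
    snps: Sequence[str] | None = None,
    variance_model: str = "fixed",
    n_boot: int = DEFAULT_N_BOOT,
    seed: int = 0,
    palindromic_eaf_window: float = DEFAULT_PALINDROMIC_EAF_WINDOW,
    compare_on: str | None = None,
) -> AnalysisReport:
    """Run every requested method against every outcome.

    ``outcomes`` are bundled trait labels (``"CAD"`` … ``"CES"``) or paths
    to summary files harmonized against ``exposure`` (a path when any
    outcome is one).  ``snps`` restricts the instrument (default: the
    bundled five-SNP set for bundled outcomes).  Between-outcome
    comparisons are computed pairwise on ``compare_on`` (defaults to
    ``"ivw"`` when present, else ``"wald"``).  Deterministic for fixed
    ``seed``: the bootstrap of the median methods is the only randomness.
    """
    methods = tuple(methods)
    if not methods:
        raise ValueError("methods must be a non-empty subset of "
                         f"{KNOWN_METHODS}")
    unknown = set(methods) - set(KNOWN_METHODS)
    if unknown:
        raise ValueError(f"unknown methods {sorted(unknown)}; "
                         f"choose from {KNOWN_METHODS}")

    estimates: dict[tuple[str, str], MREstimate] = {}
    egger_fits: dict[str, EggerEstimate] = {}
    heterogeneity: dict[str, HeterogeneityResult] = {}
    n_snps = 0

    for outcome in outcomes:
        label = str(outcome)
        try:
            instruments = _resolve_instruments(
                exposure, outcome, snps, palindromic_eaf_window)
            n_snps = max(n_snps, len(instruments))
            for method in methods:
                if method == "wald":
                    if len(instruments) != 1:
                        logger.warning(
                            "%s/wald: %d instruments, using the first",
                            label, len(instruments))
                    estimates[(label, method)] = wald_ratio(instruments[0])
                elif method == "ivw":
                    estimates[(label, method)] = ivw(
                        instruments, variance_model=variance_model)
                elif method == "egger":
                    fit = mr_egger(instruments)
                    egger_fits[label] = fit
                    estimates[(label, method)] = fit.slope
                elif method == "simple_median":
                    estimates[(label, method)] = simple_median(
                        instruments, n_boot=n_boot, seed=seed)
                elif method == "weighted_median":
                    estimates[(label, method)] = weighted_median(
                        instruments, n_boot=n_boot, seed=seed)
            if len(instruments) >= 2:
                heterogeneity[label] = cochran_q(instruments)
        except CecmrError as exc:
            raise type(exc)(f"outcome {label}: {exc}") from exc

    if compare_on is None:
        compare_on = "ivw" if "ivw" in methods else methods[0]
    comparisons: dict[tuple[str, str], HeterogeneityResult] = {}
    labels = [str(o) for o in outcomes]
    for i, a in enumerate(labels):
        for b in labels[i + 1:]:
            ea, eb = estimates.get((a, compare_on)), estimates.get((b, compare_on))
            if ea is not None and eb is not None:
                comparisons[(a, b)] = compare_estimates(
                    [(a, ea.theta, ea.se), (b, eb.theta, eb.se)])

    return AnalysisReport(
        outcomes=tuple(labels),
        methods=methods,
        n_snps=n_snps,
        estimates=estimates,
        egger=egger_fits,
        heterogeneity=heterogeneity,
        comparisons=comparisons,
    )


def _rows(report: AnalysisReport) -> list[dict]:
    rows = []
    for outcome in report.outcomes:
        for method in report.methods:
            est = report.estimates.get((outcome, method))
            if est is None:
                continue
            row: dict = {
                "outcome": outcome,
                "method": method,
                "n_snps": est.n_snps,
                "theta": est.theta,
                "se": est.se,
                "odds_ratio": est.odds_ratio,
                "or_ci_low": est.or_ci_low,
                "or_ci_high": est.or_ci_high,
                "pvalue": est.pvalue,
                "significant": report.is_significant(outcome, method),
            }
            if method == "egger" and outcome in report.egger:
                icept = report.egger[outcome].intercept
                row.update(intercept=icept.value, intercept_se=icept.se,
                           intercept_ci_low=icept.ci_low,
                           intercept_ci_high=icept.ci_high,
                           intercept_pvalue=icept.pvalue)
            rows.append(row)
    return rows


_COLUMNS = ("outcome", "method", "n_snps", "theta", "se", "odds_ratio",
            "or_ci_low", "or_ci_high", "pvalue", "significant",
            "intercept", "intercept_se", "intercept_ci_low",
            "intercept_ci_high", "intercept_pvalue")


def _fmt_p(p: float) -> str:
    return "<1e-300" if p < 1e-300 else f"{p:.3g}"


def write_report(report: AnalysisReport, format: str, path: str | Path) -> None:
    """Serialize a report; ``format`` is ``"tsv"``, ``"json"`` or
    ``"markdown"``.  TSV and JSON carry full precision in a stable column
    order; markdown applies the display rounding conventions."""
    path = Path(path)
    rows = _rows(report)
    if format == "tsv":
        lines = ["\t".join(_COLUMNS)]
        for row in rows:
            lines.append("\t".join(
                "" if row.get(c) is None else repr(row[c]) for c in _COLUMNS))
        path.write_text("\n".join(lines) + "\n")
    elif format == "json":
        payload = {
            "alpha": report.alpha,
            "estimates": rows,
            "heterogeneity": {
                outcome: {"Q": h.Q, "df": h.df, "pvalue": h.pvalue,
                          "i_squared": h.i_squared}
                for outcome, h in report.heterogeneity.items()
            },
            "comparisons": {
                f"{a} vs {b}": {"Q": h.Q, "df": h.df, "pvalue": h.pvalue,
                                "i_squared": h.i_squared}
                for (a, b), h in report.comparisons.items()
            },
        }
        path.write_text(json.dumps(payload, indent=2) + "\n")
    elif format == "markdown":
        lines = [
            "| Outcome | Method | OR (95% CI) | *p* | Intercept (95% CI) | *p* intercept |",
            "| --- | --- | --- | --- | --- | --- |",
        ]
        for row in rows:
            or_cell = (f"{row['odds_ratio']:.2f} "
                       f"({row['or_ci_low']:.2f}-{row['or_ci_high']:.2f})")
            if "intercept" in row:
                icept = (f"{row['intercept']:.3f} "
                         f"({row['intercept_ci_low']:.3f}, "
                         f"{row['intercept_ci_high']:.3f})")
                ip = _fmt_p(row["intercept_pvalue"])
            else:
                icept, ip = "", ""
            lines.append(f"| {row['outcome']} | {row['method']} | {or_cell} | "
                         f"{_fmt_p(row['pvalue'])} | {icept} | {ip} |")
        if report.heterogeneity:
            lines += ["", "| Outcome | Q | df | *p* | I² |",
                      "| --- | --- | --- | --- | --- |"]
            for outcome, h in report.heterogeneity.items():
                lines.append(f"| {outcome} | {h.Q:.1f} | {h.df} | "
                             f"{_fmt_p(h.pvalue)} | {h.i_squared_percent}% |")
        if report.comparisons:
            lines += ["", "| Comparison | Q | *p* | I² |",
                      "| --- | --- | --- | --- |"]
            for (a, b), h in report.comparisons.items():
                lines.append(f"| {a} vs {b} | {h.Q:.1f} | {_fmt_p(h.pvalue)} | "
                             f"{h.i_squared_percent}% |")
        path.write_text("\n".join(lines) + "\n")
    else:
        raise ValueError(f"unknown format {format!r}; use tsv, json or markdown")


def read_report_tsv(path: str | Path) -> list[dict]:
    """Read back a TSV report at full precision (inverse of the TSV writer)."""
    lines = Path(path).read_text().splitlines()
    header = lines[0].split("\t")
    out = []
    for line in lines[1:]:
        row = {}
        for key, cell in zip(header, line.split("\t")):
            if cell == "":
                continue
            if key in ("outcome", "method"):
                row[key] = cell
            elif key == "significant":
                row[key] = cell == "True"
            elif key == "n_snps":
                row[key] = int(cell)
            else:
                row[key] = float(cell)
        out.append(row)
    return out
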