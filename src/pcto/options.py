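"""Treatment-options analysis over a precision cohort.

Cohort members are grouped by observed treatment decision; each option is
compared with the "no change" baseline on the fraction of controlled
follow-up outcomes using a 2x2 chi-square test with Bonferroni
correction, and annotated with a medication-complexity delta
(fewer/same/more active medications than baseline).  The report
serializes to JSON/CSV and to a Sankey diagram structure.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional

import numpy as np
import pandas as pd
from scipy.stats import chi2_contingency

from pcto.decision_points import NO_CHANGE

ALPHA = 0.05


@dataclass
class OptionRow:
    decision_label: str
    n: int
    n_controlled: int
    pct_controlled: float
    diff_vs_baseline: Optional[float] = None
    chi2_stat: Optional[float] = None
    p_value: Optional[float] = None
    tested: bool = False
    significant: bool = False
    direction: str = "equal"  # better | worse | equal
    n_meds: Optional[int] = None
    med_delta: Optional[str] = None  # fewer | same | more


@dataclass
class OptionsReport:
    index_dp_id: str
    cohort_size: int
    baseline: Optional[OptionRow]
    options: list[OptionRow] = field(default_factory=list)
    m_tests: int = 0
    no_baseline: bool = False

    @property
    def alpha_per_test(self) -> float:
        return ALPHA / self.m_tests if self.m_tests else ALPHA

    def significant_better(self) -> list[OptionRow]:
        return [r for r in self.options if r.significant and r.direction == "better"]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for row in ([self.baseline] if self.baseline else []) + self.options:
            rows.append(
                {
                    "decision_label": row.decision_label,
                    "n": row.n,
                    "pct_controlled": row.pct_controlled,
                    "diff_vs_baseline": row.diff_vs_baseline,
                    "chi2_stat": row.chi2_stat,
                    "p_value": row.p_value,
                    "tested": row.tested,
                    "significant": row.significant,
                    "direction": row.direction,
                    "n_meds": row.n_meds,
                    "med_delta": row.med_delta,
                }
            )
        return pd.DataFrame(rows)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "index_dp_id": self.index_dp_id,
            "cohort_size": self.cohort_size,
            "m_tests": self.m_tests,
            "no_baseline": self.no_baseline,
            "rows": self.to_frame().replace({np.nan: None}).to_dict(orient="records"),
        }
        Path(path).write_text(json.dumps(payload, indent=2))


def group_by_decision(members: pd.DataFrame) -> dict[str, pd.DataFrame]:
    """Exact partition of cohort member DPs by decision label."""
    if len(members) == 0:
        raise ValueError("cohort is empty")
    return {label: grp for label, grp in members.groupby("decision_label", sort=True)}


def chi2_2x2(a: int, b: int, c: int, d: int, correction: bool = False) -> tuple[float, float]:
    """Pearson chi-square for the 2x2 table [[a, b], [c, d]].

    Returns (statistic, p-value); a table with an all-zero margin yields
    (0, 1) with a warning.
    """
    table = np.array([[a, b], [c, d]], dtype=float)
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        warnings.warn("chi-square table has an all-zero margin; p set to 1", stacklevel=2)
        return 0.0, 1.0
    stat, p, _, _ = chi2_contingency(table, correction=correction)
    return float(stat), float(p)


def _median_meds(group: pd.DataFrame) -> int:
    med = float(np.median(group["n_meds_after"].to_numpy(dtype=float)))
    return int(math.floor(med + 0.5)) if med >= 0 else -int(math.floor(-med + 0.5))


def compare_outcomes(
    groups: Mapping[str, pd.DataFrame],
    min_group_size: int = 30,
    index_dp_id: str = "",
    correction: bool = False,
) -> OptionsReport:
    """Per-option outcome statistics and Bonferroni-corrected tests.

    Each non-baseline group with at least ``min_group_size`` members is
    tested against the baseline with a 2x2 chi-square (option vs baseline
    x controlled vs not); m = the number of such tests and each is judged
    at 0.05/m (strict inequality).  Smaller groups are reported untested.
    """
    cohort_size = sum(len(g) for g in groups.values())
    baseline_df = groups.get(NO_CHANGE)

    def make_row(label: str, grp: pd.DataFrame) -> OptionRow:
        n = len(grp)
        n_ctrl = int((grp["outcome"] == "controlled").sum())
        return OptionRow(
            decision_label=label,
            n=n,
            n_controlled=n_ctrl,
            pct_controlled=100.0 * n_ctrl / n,
            n_meds=_median_meds(grp),
        )

    if baseline_df is None or len(baseline_df) == 0:
        report = OptionsReport(
            index_dp_id=index_dp_id,
            cohort_size=cohort_size,
            baseline=None,
            options=[make_row(lbl, g) for lbl, g in groups.items() if lbl != NO_CHANGE],
            no_baseline=True,
        )
        return report

    base = make_row(NO_CHANGE, baseline_df)
    option_rows = []
    testable = []
    for label in sorted(groups):
        if label == NO_CHANGE:
            continue
        row = make_row(label, groups[label])
        row.diff_vs_baseline = row.pct_controlled - base.pct_controlled
        if row.diff_vs_baseline > 0:
            row.direction = "better"
        elif row.diff_vs_baseline < 0:
            row.direction = "worse"
        if row.n_meds > base.n_meds:
            row.med_delta = "more"
        elif row.n_meds < base.n_meds:
            row.med_delta = "fewer"
        else:
            row.med_delta = "same"
        if row.n >= min_group_size:
            testable.append(row)
        option_rows.append(row)

    m = len(testable)
    for row in testable:
        stat, p = chi2_2x2(
            row.n_controlled,
            row.n - row.n_controlled,
            base.n_controlled,
            base.n - base.n_controlled,
            correction=correction,
        )
        row.chi2_stat = stat
        row.p_value = p
        row.tested = True
        row.significant = p < ALPHA / m  # strict: ties are not significant

    return OptionsReport(
        index_dp_id=index_dp_id,
        cohort_size=cohort_size,
        baseline=base,
        options=option_rows,
        m_tests=m,
    )


def analyze_cohort(
    members: pd.DataFrame,
    min_group_size: int = 30,
    index_dp_id: str = "",
    correction: bool = False,
) -> OptionsReport:
    """Group members by decision and compare outcomes (one-call wrapper)."""
    return compare_outcomes(
        group_by_decision(members),
        min_group_size=min_group_size,
        index_dp_id=index_dp_id,
        correction=correction,
    )


# ---------------------------------------------------------------------------
# Sankey serialization


def _color_class(row: OptionRow) -> str:
    if row.decision_label == NO_CHANGE:
        return "gray"
    if row.direction == "better":
        return "dark-green" if row.significant else "light-green"
    if row.direction == "worse":
        return "dark-red" if row.significant else "light-red"
    return "gray"


def to_sankey(report: OptionsReport) -> dict:
    """Sankey-serializable structure: initial node -> one node per option
    -> controlled / not_controlled terminals.  Link widths are DP counts,
    so widths leaving the initial node sum to the cohort size.
    """
    rows = ([report.baseline] if report.baseline else []) + report.options
    nodes = [{"id": "initial", "label": "precision cohort"}]
    links = []
    for row in rows:
        node_id = f"option:{row.decision_label}"
        nodes.append(
            {
                "id": node_id,
                "label": f"{row.decision_label} ({row.pct_controlled:.0f}%)",
                "color_class": _color_class(row),
            }
        )
        links.append({"source": "initial", "target": node_id, "value": row.n})
        links.append({"source": node_id, "target": "controlled", "value": row.n_controlled})
        links.append({"source": node_id, "target": "not_controlled", "value": row.n - row.n_controlled})
    nodes.append({"id": "controlled", "label": "controlled", "color_class": "green"})
    nodes.append({"id": "not_controlled", "label": "not controlled", "color_class": "red"})
    return {"nodes": nodes, "links": links, "cohort_size": report.cohort_size}
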