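"""Leave-one-out evaluation over the scoring set and per-filter-cohort
aggregation.

Each scoring decision point in turn plays the index patient: it is
removed from the scoring pool, a precision cohort is built from the
remainder, and the treatment-options analysis is run.  Records are then
aggregated by filter-variable cohort (the exact-match key), with a
cumulative-coverage column over cohorts sorted by size.

Medication-complexity flags come in two explicitly labelled variants:
``better_*`` counts significantly-better options with that med delta;
``comparable_*`` counts tested options that are not significantly worse.
"""

from __future__ import annotations

import logging
from typing import Optional, Sequence

import pandas as pd

from pcto.cohort import CohortConfig, score_candidates, select_threshold
from pcto.lsml import SimilarityModel
from pcto.options import OptionsReport, analyze_cohort

logger = logging.getLogger(__name__)

RECORD_COLUMNS = [
    "dp_id",
    "filter_key",
    "cohort_size",
    "insufficient",
    "reason",
    "has_better",
    "better_fewer",
    "better_same",
    "better_more",
    "comparable_fewer",
    "comparable_same",
    "comparable_more",
]


def _flags(report: OptionsReport) -> dict[str, bool]:
    better = report.significant_better()
    comparable = [
        r for r in report.options if r.tested and not (r.significant and r.direction == "worse")
    ]
    return {
        "has_better": len(better) > 0,
        "better_fewer": any(r.med_delta == "fewer" for r in better),
        "better_same": any(r.med_delta == "same" for r in better),
        "better_more": any(r.med_delta == "more" for r in better),
        "comparable_fewer": any(r.med_delta == "fewer" for r in comparable),
        "comparable_same": any(r.med_delta == "same" for r in comparable),
        "comparable_more": any(r.med_delta == "more" for r in comparable),
    }


def loocv_run(
    model: SimilarityModel,
    dps: pd.DataFrame,
    variable_matrix: pd.DataFrame,
    filter_matrix: pd.DataFrame,
    scoring_ids: Sequence[str],
    cohort_config: Optional[CohortConfig] = None,
    min_group_size: int = 30,
) -> pd.DataFrame:
    """One LOOCV record per scoring DP.

    ``dps`` must carry dp_id, decision_label, outcome, n_meds_after;
    ``variable_matrix``/``filter_matrix`` are indexed by dp_id.  Per-DP
    computations are independent; the result is sorted by dp_id, so it
    does not depend on processing order.
    """
    cohort_config = cohort_config or CohortConfig()
    dps = dps.set_index("dp_id", drop=False)
    scoring_ids = [i for i in scoring_ids]

    fm = filter_matrix.loc[scoring_ids]
    key_of = {dp_id: tuple(row) for dp_id, row in zip(fm.index, fm.to_numpy().tolist())}
    groups: dict[tuple, list[str]] = {}
    for dp_id in scoring_ids:
        groups.setdefault(key_of[dp_id], []).append(dp_id)

    decision_labels = dps["decision_label"]
    records = []
    for dp_id in scoring_ids:
        key = key_of[dp_id]
        candidates = [i for i in groups[key] if i != dp_id]
        rec = {
            "dp_id": dp_id,
            "filter_key": "|".join(str(v) for v in key),
            "cohort_size": 0,
            "insufficient": True,
            "reason": "",
            **{k: False for k in RECORD_COLUMNS[5:]},
        }
        if not candidates:
            rec["reason"] = "no candidate matches the filter variables"
            records.append(rec)
            continue
        scores = score_candidates(
            model,
            variable_matrix.loc[dp_id].to_numpy(dtype=float),
            variable_matrix.loc[candidates],
            percentile=cohort_config.score_percentile,
        )
        balance_cols = [c for c in variable_matrix.columns if c not in filter_matrix.columns]
        cohort = select_threshold(
            dp_id,
            scores,
            decision_labels,
            variable_matrix[balance_cols],
            cohort_config,
        )
        rec["cohort_size"] = len(cohort.member_ids)
        rec["insufficient"] = cohort.insufficient
        rec["reason"] = cohort.reason
        if not cohort.insufficient:
            report = analyze_cohort(
                dps.loc[cohort.member_ids],
                min_group_size=min_group_size,
                index_dp_id=dp_id,
            )
            rec.update(_flags(report))
        records.append(rec)

    out = pd.DataFrame(records, columns=RECORD_COLUMNS)
    return out.sort_values("dp_id", kind="stable").reset_index(drop=True)


def aggregate_by_filter_cohort(records: pd.DataFrame, pool_below: int = 5) -> pd.DataFrame:
    """Per-filter-cohort summary of the LOOCV records.

    Cohorts with fewer than ``pool_below`` DPs are pooled into an
    ``"other"`` row.  Rows are sorted by size (descending) with a
    cumulative-coverage column; a final ``"overall"`` row holds totals.
    """
    if len(records) == 0:
        raise ValueError("no records to aggregate")
    flag_cols = RECORD_COLUMNS[5:]

    counts = records.groupby("filter_key").size()
    small = set(counts.index[counts < pool_below])
    keyed = records.assign(
        cohort_key=records["filter_key"].map(lambda k: "other" if k in small else k)
    )

    rows = []
    for key, grp in keyed.groupby("cohort_key"):
        row = {"filter_cohort": key, "n_dps": len(grp)}
        for col in flag_cols:
            row[f"pct_{col}"] = 100.0 * grp[col].mean()
        rows.append(row)
    summary = pd.DataFrame(rows).sort_values(
        ["n_dps", "filter_cohort"], ascending=[False, True], kind="stable"
    )
    total = len(records)
    summary["cumulative_coverage_pct"] = 100.0 * summary["n_dps"].cumsum() / total

    overall = {"filter_cohort": "overall", "n_dps": total, "cumulative_coverage_pct": 100.0}
    for col in flag_cols:
        overall[f"pct_{col}"] = 100.0 * records[col].mean()
    summary = pd.concat([summary, pd.DataFrame([overall])], ignore_index=True)
    return summary.reset_index(drop=True)
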