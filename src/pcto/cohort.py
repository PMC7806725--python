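"""Precision-cohort construction: filter, score, threshold under a
covariate-balance constraint.

For an index decision point, candidates are the scoring-set DPs with
identical filter-variable values.  Candidates are scored by the learned
metric (distances normalized by their 99th percentile and capped at 1, so
scores live in [0, 1] with 0 = identical) and a similarity-score
threshold is chosen from a quantile grid: the largest threshold whose
cohort is both big enough and balanced enough.  Balance is the
standardized bias between the treatment-change and no-change groups.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from pcto.decision_points import NO_CHANGE
from pcto.lsml import SimilarityModel, pairwise_distances

logger = logging.getLogger(__name__)


@dataclass
class CohortConfig:
    score_quantile_grid: Sequence[float] = tuple(np.round(np.arange(0.05, 1.0001, 0.05), 2))
    min_cohort: int = 100
    balance_max: float = 0.1
    balance_agg: str = "max"  # max | mean
    score_percentile: float = 99.0

    def __post_init__(self) -> None:
        if self.balance_agg not in ("max", "mean"):
            raise ValueError("balance_agg must be 'max' or 'mean'")


@dataclass
class BalanceReport:
    per_covariate: pd.Series
    aggregate: float
    n_change: int
    n_no_change: int


@dataclass
class PrecisionCohort:
    index_dp_id: str
    candidate_ids: list[str]
    scores: pd.Series  # indexed by candidate dp_id, in [0, 1]
    threshold: Optional[float]
    member_ids: list[str]
    balance_profile: pd.DataFrame  # columns: threshold, size, balance
    final_balance: float = float("nan")
    insufficient: bool = False
    balance_violating: bool = False
    reason: str = ""

    def to_dict(self) -> dict:
        return {
            "index_dp_id": self.index_dp_id,
            "n_candidates": len(self.candidate_ids),
            "threshold": self.threshold,
            "n_members": len(self.member_ids),
            "final_balance": None if np.isnan(self.final_balance) else self.final_balance,
            "insufficient": self.insufficient,
            "balance_violating": self.balance_violating,
            "reason": self.reason,
            "member_ids": self.member_ids,
            "balance_profile": self.balance_profile.to_dict(orient="records"),
        }


def filter_candidates(index_dp_id: str, filter_matrix: pd.DataFrame) -> list[str]:
    """DP ids whose filter-variable vector equals the index DP's exactly;
    the index DP itself is excluded (leave-one-out contract)."""
    if index_dp_id not in filter_matrix.index:
        raise KeyError(f"index DP {index_dp_id!r} not in filter matrix")
    target = filter_matrix.loc[index_dp_id]
    mask = (filter_matrix == target).all(axis=1)
    ids = filter_matrix.index[mask].tolist()
    return [i for i in ids if i != index_dp_id]


def score_candidates(
    model: SimilarityModel,
    index_vector: np.ndarray,
    candidates: pd.DataFrame,
    percentile: float = 99.0,
) -> pd.Series:
    """Normalized similarity scores in [0, 1] (0 = most similar).

    Raw learned distances are divided by their ``percentile``-th
    percentile and capped at 1; the candidate ordering is preserved.
    """
    if len(candidates) < 1:
        raise ValueError("need at least one candidate to score")
    raw = pairwise_distances(model, np.asarray(index_vector, dtype=float), candidates.to_numpy(dtype=float))
    denom = float(np.percentile(raw, percentile))
    if denom <= 0.0:
        warnings.warn("all candidates identical to index; scores set to 0", stacklevel=2)
        scores = np.zeros_like(raw)
    else:
        scores = np.minimum(raw / denom, 1.0)
    return pd.Series(scores, index=candidates.index, name="score")


def standardized_bias(values: Sequence[float], is_change: Sequence[bool]) -> float:
    """Group-mean difference scaled by the treatment-change group's sd:
    (mean_no_change - mean_change) / sd_change.  NaN when the change
    group's sd is 0 (covariate skipped by aggregators)."""
    v = np.asarray(values, dtype=float)
    m = np.asarray(is_change, dtype=bool)
    if not m.any() or m.all():
        raise ValueError("both groups must be non-empty")
    sd = float(np.std(v[m], ddof=1)) if m.sum() > 1 else 0.0
    if sd == 0.0:
        return float("nan")
    return (float(v[~m].mean()) - float(v[m].mean())) / sd


def balance_report(covariates: pd.DataFrame, is_change: Sequence[bool], agg: str = "max") -> BalanceReport:
    """Per-covariate standardized bias plus the aggregate (max or mean of
    absolute values over covariates with defined bias)."""
    m = np.asarray(is_change, dtype=bool)
    per = {}
    for col in covariates.columns:
        try:
            per[col] = standardized_bias(covariates[col].to_numpy(), m)
        except ValueError:
            per[col] = float("nan")
    series = pd.Series(per, name="standardized_bias")
    abs_vals = series.abs().dropna()
    if len(abs_vals) == 0:
        aggregate = float("nan")
    else:
        aggregate = float(abs_vals.max() if agg == "max" else abs_vals.mean())
    return BalanceReport(
        per_covariate=series,
        aggregate=aggregate,
        n_change=int(m.sum()),
        n_no_change=int((~m).sum()),
    )


def select_threshold(
    index_dp_id: str,
    scores: pd.Series,
    decision_labels: pd.Series,
    balance_covariates: pd.DataFrame,
    config: Optional[CohortConfig] = None,
) -> PrecisionCohort:
    """Grid search over score-quantile thresholds.

    Evaluates cohort size and aggregate balance at each grid threshold
    (ascending) and selects the largest threshold whose cohort has at
    least ``min_cohort`` members and balance <= ``balance_max``.  If no
    threshold is balanced, the minimum-balance qualifying threshold is
    used and the cohort flagged ``balance_violating``.  If no threshold
    reaches ``min_cohort``, the cohort is flagged ``insufficient``.
    """
    config = config or CohortConfig()
    candidate_ids = list(scores.index)
    profile_rows = []
    feasible: list[tuple[float, int, float]] = []

    thresholds = np.quantile(scores.to_numpy(), list(config.score_quantile_grid))
    for thr in thresholds:
        member_mask = scores.to_numpy() <= thr
        size = int(member_mask.sum())
        ids = scores.index[member_mask]
        is_change = (decision_labels.loc[ids] != NO_CHANGE).to_numpy()
        if size > 0 and is_change.any() and (~is_change).any():
            rep = balance_report(balance_covariates.loc[ids], is_change, agg=config.balance_agg)
            bal = rep.aggregate
        else:
            bal = float("nan")
        profile_rows.append({"threshold": float(thr), "size": size, "balance": bal})
        if size >= config.min_cohort and np.isfinite(bal):
            feasible.append((float(thr), size, bal))

    profile = pd.DataFrame(profile_rows, columns=["threshold", "size", "balance"])

    def cohort_at(thr: float, bal: float, violating: bool) -> PrecisionCohort:
        member_ids = scores.index[scores.to_numpy() <= thr].tolist()
        return PrecisionCohort(
            index_dp_id=index_dp_id,
            candidate_ids=candidate_ids,
            scores=scores,
            threshold=thr,
            member_ids=member_ids,
            balance_profile=profile,
            final_balance=bal,
            balance_violating=violating,
        )

    balanced = [f for f in feasible if f[2] <= config.balance_max]
    if balanced:
        thr, _, bal = max(balanced, key=lambda f: f[0])
        return cohort_at(thr, bal, violating=False)
    if feasible:
        thr, _, bal = min(feasible, key=lambda f: (f[2], -f[0]))
        logger.info("no threshold meets balance_max=%g; using min-balance threshold", config.balance_max)
        return cohort_at(thr, bal, violating=True)
    return PrecisionCohort(
        index_dp_id=index_dp_id,
        candidate_ids=candidate_ids,
        scores=scores,
        threshold=None,
        member_ids=[],
        balance_profile=profile,
        insufficient=True,
        reason=f"no threshold yields >= {config.min_cohort} members with both decision groups",
    )


def build_precision_cohort(
    model: SimilarityModel,
    index_dp_id: str,
    variable_matrix: pd.DataFrame,
    filter_matrix: pd.DataFrame,
    decision_labels: pd.Series,
    scoring_ids: Sequence[str],
    config: Optional[CohortConfig] = None,
) -> PrecisionCohort:
    """Full funnel for one index DP: filter -> score -> threshold.

    ``variable_matrix`` holds the similarity/balance variables (model
    variable order), ``filter_matrix`` the exact-match variables; both are
    indexed by dp_id.  ``scoring_ids`` restricts the candidate pool.
    """
    config = config or CohortConfig()
    pool = filter_matrix.loc[[i for i in scoring_ids if i != index_dp_id]]
    candidates = filter_candidates(index_dp_id, pd.concat([filter_matrix.loc[[index_dp_id]], pool]))
    if len(candidates) == 0:
        return PrecisionCohort(
            index_dp_id=index_dp_id,
            candidate_ids=[],
            scores=pd.Series(dtype=float),
            threshold=None,
            member_ids=[],
            balance_profile=pd.DataFrame(columns=["threshold", "size", "balance"]),
            insufficient=True,
            reason="no candidate matches the filter variables",
        )
    scores = score_candidates(
        model,
        variable_matrix.loc[index_dp_id].to_numpy(dtype=float),
        variable_matrix.loc[candidates],
        percentile=config.score_percentile,
    )
    balance_cols = [c for c in variable_matrix.columns if c not in filter_matrix.columns]
    return select_threshold(
        index_dp_id,
        scores,
        decision_labels,
        variable_matrix[balance_cols],
        config,
    )
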