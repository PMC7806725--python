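"""Baseline-variable construction and salient-variable selection.

Variables are built over each decision point's baseline window from
constructor templates (active medication, diagnosis history, latest lab
value/flag, demographics).  Candidate variables are then ranked by
stability selection: many L1-penalized logistic regressions on random row
subsets, keeping variables selected by a large fraction of models.  A
correlation/cluster report links near-duplicate candidates for manual
review; an approved-variable list file, when supplied, overrides the
automatic selection.
"""

from __future__ import annotations

import datetime as dt
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression

from pcto.events import EventKind, PatientTimeline

logger = logging.getLogger(__name__)

WINDOW_DAYS = {"past_12m": 365, "past_14m": 425, "all_history": None}

SOURCES = (
    "medication_active",
    "diagnosis_ever",
    "diagnosis_recent",
    "lab_latest_value",
    "lab_latest_flag",
    "demographic",
)


@dataclass(frozen=True)
class VariableTemplate:
    """One baseline-variable constructor.

    ``codes`` lists the event codes the variable summarizes (or the
    attribute name for demographics).  ``flag_op``/``flag_value`` define
    the comparison for ``lab_latest_flag`` output.
    """

    name: str
    source: str
    codes: tuple[str, ...]
    window: Optional[str] = None
    flag_op: str = "ge"
    flag_value: float = 0.0

    def __post_init__(self) -> None:
        if self.source not in SOURCES:
            raise ValueError(f"unknown source {self.source!r}")
        if self.source != "demographic" and self.window is None:
            raise ValueError(f"template {self.name!r}: window required for source {self.source}")
        if self.window is not None and self.window not in WINDOW_DAYS:
            raise ValueError(f"unknown window {self.window!r}")
        if not self.codes:
            raise ValueError(f"template {self.name!r}: codes must be non-empty")


def _window_start(index_date: dt.date, window: str) -> Optional[dt.date]:
    days = WINDOW_DAYS[window]
    return None if days is None else index_date - dt.timedelta(days=days)


_FLAG_OPS = {"ge": np.greater_equal, "gt": np.greater, "le": np.less_equal, "lt": np.less}


def _eval_template(tpl: VariableTemplate, timeline: PatientTimeline, index_date: dt.date):
    if tpl.source == "demographic":
        key = tpl.codes[0]
        if key == "age":
            birth = timeline.attributes.get("birth_date")
            if birth is None:
                return None
            if isinstance(birth, str):
                birth = dt.date.fromisoformat(birth)
            return (index_date - birth).days / 365.25
        return timeline.attributes.get(key)

    if tpl.source == "medication_active":
        return float(any(code in timeline.active_ingredients(index_date) for code in tpl.codes))

    start = _window_start(index_date, tpl.window)
    if tpl.source in ("diagnosis_ever", "diagnosis_recent"):
        lo = start if tpl.source == "diagnosis_recent" else None
        for ev in timeline.events:
            if ev.event_kind is EventKind.DIAGNOSIS and ev.code in tpl.codes and ev.event_date <= index_date:
                if lo is None or ev.event_date >= lo:
                    return 1.0
        return 0.0

    # lab_latest_value / lab_latest_flag
    latest = None
    for ev in timeline.events:
        if (
            ev.event_kind is EventKind.MEASUREMENT
            and ev.code in tpl.codes
            and ev.event_date <= index_date
            and (start is None or ev.event_date >= start)
        ):
            if latest is None or ev.event_date >= latest[0]:
                latest = (ev.event_date, float(ev.value))
    if latest is None:
        return None
    if tpl.source == "lab_latest_value":
        return latest[1]
    return float(bool(_FLAG_OPS[tpl.flag_op](latest[1], tpl.flag_value)))


@dataclass
class ConstructionReport:
    n_dps: int = 0
    n_retained: int = 0
    n_dropped_missing: int = 0
    dropped_dp_ids: list[str] = field(default_factory=list)


def construct_variables(
    timelines: Mapping[str, PatientTimeline],
    dps: pd.DataFrame,
    templates: Sequence[VariableTemplate],
    report: Optional[ConstructionReport] = None,
) -> pd.DataFrame:
    """Build the DP-by-variable matrix.

    One row per decision point (indexed by ``dp_id``); rows with any
    missing value are dropped and counted in ``report``.
    """
    names = [t.name for t in templates]
    if len(set(names)) != len(names):
        raise ValueError("template names must be unique")
    if report is None:
        report = ConstructionReport()
    report.n_dps = len(dps)

    rows = {}
    for rec in dps.itertuples(index=False):
        timeline = timelines[rec.patient_id]
        index_date = rec.index_date
        if isinstance(index_date, pd.Timestamp):
            index_date = index_date.date()
        vals = [_eval_template(t, timeline, index_date) for t in templates]
        if any(v is None for v in vals):
            report.n_dropped_missing += 1
            report.dropped_dp_ids.append(rec.dp_id)
            continue
        rows[rec.dp_id] = [float(v) for v in vals]

    report.n_retained = len(rows)
    X = pd.DataFrame.from_dict(rows, orient="index", columns=names)
    X.index.name = "dp_id"
    return X


# ---------------------------------------------------------------------------
# stability selection


@dataclass
class StabilityResult:
    """Per-variable selection frequencies over resampled L1 models."""

    frequencies: pd.Series  # int, 0..n_models
    n_models: int
    threshold: int
    l1_strength: float
    clusters: Optional[pd.Series] = None

    @property
    def selected(self) -> pd.Series:
        return self.frequencies >= self.threshold

    @property
    def selected_names(self) -> list[str]:
        return list(self.frequencies.index[self.selected])

    def to_frame(self) -> pd.DataFrame:
        out = pd.DataFrame(
            {
                "frequency": self.frequencies,
                "selected": self.selected,
            }
        )
        if self.clusters is not None:
            out["cluster"] = self.clusters
        out.index.name = "variable"
        return out


def _zscore(A: np.ndarray) -> np.ndarray:
    mu = A.mean(axis=0)
    sd = A.std(axis=0, ddof=0)
    sd_safe = np.where(sd > 0, sd, 1.0)
    return (A - mu) / sd_safe


def choose_l1_strength(
    X: np.ndarray,
    y: np.ndarray,
    target_nonzero: int,
    grid: Optional[Sequence[float]] = None,
) -> float:
    """Pick the penalty whose full-data fit has the nonzero-coefficient
    count closest to ``target_nonzero`` (ties favor the stronger penalty)."""
    if grid is None:
        grid = np.logspace(-2.5, 1.5, 13)
    Z = _zscore(X)
    best: tuple[float, float] = (np.inf, np.inf)
    chosen = float(grid[0])
    for strength in sorted(grid, reverse=True):
        clf = LogisticRegression(l1_ratio=1.0, C=1.0 / strength, solver="liblinear", max_iter=2000)
        clf.fit(Z, y)
        nnz = int(np.sum(np.abs(clf.coef_[0]) > 1e-8))
        score = (abs(nnz - target_nonzero), strength)
        if score < best:
            best = score
            chosen = float(strength)
    logger.info("chose l1_strength=%g (target %d nonzero)", chosen, target_nonzero)
    return chosen


def stability_select(
    X: pd.DataFrame,
    y: Sequence[int],
    n_models: int = 200,
    subsample_frac: float = 0.75,
    threshold: int = 150,
    l1_strength: Optional[float] = None,
    target_nonzero: Optional[int] = None,
    seed: int = 0,
) -> StabilityResult:
    """Stability selection with L1-penalized logistic regression.

    Fits ``n_models`` models, each on an independent uniform subsample of
    ``floor(subsample_frac * n)`` rows (without replacement).  A variable
    is selected in one model iff its coefficient magnitude exceeds 1e-8;
    its frequency is the count over models.  Continuous columns are
    z-scored inside each resample so the penalty is scale-free.
    """
    y = np.asarray(y, dtype=int)
    if len(np.unique(y)) < 2:
        raise ValueError("outcome vector must contain both classes")
    if len(X) < 20:
        raise ValueError("need at least 20 rows for stability selection")
    A = X.to_numpy(dtype=float)
    n, p = A.shape

    constant = A.std(axis=0) == 0
    if constant.any():
        warnings.warn(
            f"constant columns never selectable: {list(X.columns[constant])}",
            stacklevel=2,
        )

    if l1_strength is None:
        if target_nonzero is None:
            target_nonzero = min(p, 2 * max(3, p // 10))
        l1_strength = choose_l1_strength(A, y, target_nonzero)

    rng = np.random.default_rng(seed)
    m = int(np.floor(subsample_frac * n))
    counts = np.zeros(p, dtype=int)
    clf = LogisticRegression(l1_ratio=1.0, C=1.0 / l1_strength, solver="liblinear", max_iter=2000)
    for _ in range(n_models):
        idx = rng.choice(n, size=m, replace=False)
        ys = y[idx]
        if len(np.unique(ys)) < 2:  # degenerate resample: nothing selected
            continue
        Z = _zscore(A[idx])
        clf.fit(Z, ys)
        counts += np.abs(clf.coef_[0]) > 1e-8
    freqs = pd.Series(counts, index=X.columns, name="frequency")
    return StabilityResult(
        frequencies=freqs,
        n_models=n_models,
        threshold=threshold,
        l1_strength=float(l1_strength),
    )


def correlate_and_cluster(X: pd.DataFrame, r_threshold: float = 0.8) -> pd.Series:
    """Single-linkage clusters of candidate variables with
    ``|Pearson r| >= r_threshold`` (transitive closure via union-find).

    Returned labels are integers, ordered by first appearance.
    """
    if X.shape[1] < 2:
        raise ValueError("need at least 2 candidate variables")
    corr = np.corrcoef(X.to_numpy(dtype=float), rowvar=False)
    p = corr.shape[0]

    parent = list(range(p))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(p):
        for j in range(i + 1, p):
            r = corr[i, j]
            if np.isfinite(r) and abs(r) >= r_threshold:
                parent[find(j)] = find(i)

    labels: dict[int, int] = {}
    out = []
    for i in range(p):
        root = find(i)
        if root not in labels:
            labels[root] = len(labels)
        out.append(labels[root])
    return pd.Series(out, index=X.columns, name="cluster")


def load_approved_variables(path: str | Path) -> list[str]:
    """One approved variable name per line; blank lines and ``#`` comments
    ignored (models the manual review pass)."""
    names = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if line and not line.startswith("#"):
            names.append(line)
    return names
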