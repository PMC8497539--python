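"""Two-arm longitudinal trial statistics for marker-distance endpoints.

The analysis mirrors a placebo-controlled design in which every subject
contributes a session distance (mm) at baseline (``pre``) and at three
follow-ups (``2wk``, ``3mo``, ``9mo``).  Inter-individual differences in
swallowing vigour are removed by baseline subtraction; arms are compared
per endpoint with independent two-sample t-tests, and covariate subgroups
(sex, age band, height band) with Mann-Whitney U tests.  Subjects with
statistically extreme values can be screened out per arm, either by an
iterative Grubbs test or by removing a fixed count of most-extreme values.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, asdict
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

log = logging.getLogger(__name__)

TIMEPOINTS = ("pre", "2wk", "3mo", "9mo")
FOLLOWUPS = ("2wk", "3mo", "9mo")
ARMS = ("AA+", "AA-")

#: canonical trial-table columns (one row per subject)
TRIAL_COLUMNS = [
    "id", "arm", "sex", "age_years", "height_cm",
    "distance_pre", "distance_2wk", "distance_3mo", "distance_9mo",
]


@dataclass
class SubjectRecord:
    """One subject: arm assignment, covariates and the four session distances."""

    id: str
    arm: str
    sex: str
    age_years: float
    height_cm: float
    distances: dict[str, float | None] = field(default_factory=dict)

    def validate(self, check_age: bool = True) -> None:
        if self.arm not in ARMS:
            raise ValueError(f"arm must be one of {ARMS}, got {self.arm!r}")
        if check_age and not (20 <= self.age_years <= 65):
            raise ValueError(f"age {self.age_years} outside eligible range 20-65")
        for tp, d in self.distances.items():
            if d is not None and not np.isnan(d) and d < 0:
                raise ValueError(f"negative distance {d} at {tp}")


class TrialTable:
    """Subject-level trial data plus an exclusion log.

    Wraps a :class:`pandas.DataFrame` with the :data:`TRIAL_COLUMNS` schema.
    Excluded subjects are removed from ``data`` and appended to
    ``exclusions`` (columns: id, arm, endpoint, reason, statistic).
    """

    def __init__(self, data: pd.DataFrame, exclusions: pd.DataFrame | None = None):
        missing = [c for c in TRIAL_COLUMNS if c not in data.columns]
        if missing:
            raise ValueError(f"trial table missing columns: {missing}")
        bad = set(data["arm"]) - set(ARMS)
        if bad:
            raise ValueError(f"unknown arm labels: {sorted(bad)}")
        self.data = data.reset_index(drop=True).copy()
        if exclusions is None:
            exclusions = pd.DataFrame(
                columns=["id", "arm", "endpoint", "reason", "statistic"])
        self.exclusions = exclusions.reset_index(drop=True).copy()
        overlap = set(self.data["id"]) & set(self.exclusions["id"])
        if overlap:
            raise ValueError(f"subjects both analyzed and excluded: {sorted(overlap)}")

    def __len__(self) -> int:
        return len(self.data)

    def arm(self, label: str) -> pd.DataFrame:
        return self.data[self.data["arm"] == label]

    @classmethod
    def from_records(cls, records: Iterable[SubjectRecord]) -> "TrialTable":
        rows = []
        for r in records:
            row = {"id": r.id, "arm": r.arm, "sex": r.sex,
                   "age_years": r.age_years, "height_cm": r.height_cm}
            for tp in TIMEPOINTS:
                row[f"distance_{tp}"] = r.distances.get(tp, np.nan)
            rows.append(row)
        return cls(pd.DataFrame(rows, columns=TRIAL_COLUMNS))

    @classmethod
    def read_csv(cls, path) -> "TrialTable":
        return cls(pd.read_csv(path))

    def to_csv(self, path) -> None:
        self.data.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# baseline subtraction


def baseline_subtract(table: pd.DataFrame | TrialTable) -> pd.DataFrame:
    """Per-subject change from baseline: change(t) = distance(t) - distance(pre).

    Subjects with a missing baseline get NaN changes everywhere (they are
    flagged in the log and drop out of change endpoints); changes may be
    negative.  Returns a frame with id, arm, covariates and ``change_*``
    columns.
    """
    df = table.data if isinstance(table, TrialTable) else table
    out = df[["id", "arm", "sex", "age_years", "height_cm"]].copy()
    pre = df["distance_pre"]
    n_missing = int(pre.isna().sum())
    if n_missing:
        log.warning("%d subject(s) lack a baseline distance; excluded from "
                    "change endpoints", n_missing)
    for tp in FOLLOWUPS:
        out[f"change_{tp}"] = df[f"distance_{tp}"] - pre
    return out


def subject_changes(record: SubjectRecord) -> dict[str, float]:
    """Baseline-subtracted changes for a single subject."""
    pre = record.distances.get("pre")
    if pre is None or (isinstance(pre, float) and math.isnan(pre)):
        raise ValueError(f"subject {record.id}: missing baseline distance")
    out = {}
    for tp in FOLLOWUPS:
        d = record.distances.get(tp)
        if d is not None and not (isinstance(d, float) and math.isnan(d)):
            out[tp] = d - pre
    return out


# ---------------------------------------------------------------------------
# outlier screening


def grubbs_critical(n: int, alpha: float) -> float:
    """Two-sided Grubbs critical value for sample size n at level alpha."""
    if n < 3:
        return np.inf
    t = stats.t.ppf(1 - alpha / (2 * n), n - 2)
    return (n - 1) / math.sqrt(n) * math.sqrt(t * t / (n - 2 + t * t))


def grubbs_screen(values: np.ndarray, alpha: float = 0.05
                  ) -> tuple[np.ndarray, list[tuple[int, float, float]]]:
    """Iteratively flag extreme values by the two-sided Grubbs test.

    Returns (boolean keep-mask, log of (index, G statistic, critical G))
    for each removal, in removal order.
    """
    values = np.asarray(values, dtype=float)
    keep = ~np.isnan(values)
    removals: list[tuple[int, float, float]] = []
    while keep.sum() >= 3:
        x = values[keep]
        sd = x.std(ddof=1)
        if sd == 0:
            break
        dev = np.abs(x - x.mean())
        g = dev.max() / sd
        crit = grubbs_critical(keep.sum(), alpha)
        if g <= crit:
            break
        idx_kept = np.flatnonzero(keep)
        worst = idx_kept[int(np.argmax(dev))]
        keep[worst] = False
        removals.append((int(worst), float(g), float(crit)))
    return keep, removals


def exclude_outliers(table: TrialTable, endpoint: str, alpha: float = 0.05,
                     mode: str = "grubbs", k: int | None = None) -> TrialTable:
    """Screen statistically extreme subjects per arm on one endpoint.

    ``endpoint`` is a distance column (``distance_pre`` ...) or a change
    label (``change_2wk`` ...).  ``mode="grubbs"`` applies the iterative
    Grubbs test at ``alpha``; ``mode="fixed_count"`` removes the ``k``
    most-extreme subjects (largest absolute deviation from the running arm
    mean) from each arm regardless of significance.
    """
    if not (0 < alpha < 1):
        raise ValueError("alpha must be in (0, 1)")
    if mode not in ("grubbs", "fixed_count"):
        raise ValueError(f"unknown outlier mode {mode!r}")
    if mode == "fixed_count" and (k is None or k < 0):
        raise ValueError("fixed_count mode requires k >= 0")

    df = table.data
    if endpoint.startswith("change_"):
        series = baseline_subtract(df)[endpoint]
    elif endpoint in df.columns:
        series = df[endpoint]
    else:
        raise ValueError(f"unknown endpoint {endpoint!r}")

    drop_rows = []
    for arm in ARMS:
        arm_idx = np.flatnonzero((df["arm"] == arm).to_numpy())
        if len(arm_idx) < 3:
            raise ValueError(f"need >= 3 subjects per arm, arm {arm} has {len(arm_idx)}")
        vals = series.to_numpy()[arm_idx].astype(float)
        if mode == "grubbs":
            keep, removals = grubbs_screen(vals, alpha)
            for local, g, crit in removals:
                drop_rows.append((arm_idx[local], f"Grubbs G={g:.3f} > {crit:.3f}", g))
        else:
            keep = ~np.isnan(vals)
            for _ in range(min(k, int(keep.sum()))):
                x = vals[keep]
                dev = np.abs(x - x.mean())
                local = np.flatnonzero(keep)[int(np.argmax(dev))]
                keep[local] = False
                drop_rows.append((arm_idx[local],
                                  f"fixed-count |dev|={dev.max():.3f}",
                                  float(dev.max())))

    drop_idx = [i for i, _, _ in drop_rows]
    new_excl = pd.DataFrame(
        [{"id": df.loc[i, "id"], "arm": df.loc[i, "arm"], "endpoint": endpoint,
          "reason": reason, "statistic": stat}
         for i, reason, stat in drop_rows],
        columns=["id", "arm", "endpoint", "reason", "statistic"])
    kept = df.drop(index=drop_idx)
    if table.exclusions.empty:
        combined = new_excl
    else:
        combined = pd.concat([table.exclusions, new_excl], ignore_index=True)
    return TrialTable(kept, combined)


# ---------------------------------------------------------------------------
# two-sample tests


@dataclass
class GroupComparisonResult:
    """One endpoint's arm comparison: summaries, test statistic, two-sided p."""

    endpoint: str
    test: str
    n1: int
    n2: int
    mean1: float
    mean2: float
    sd1: float
    sd2: float
    statistic: float
    p_value: float
    subject_ids: tuple[tuple[str, ...], tuple[str, ...]] | None = None

    def __post_init__(self):
        if not (0 <= self.p_value <= 1 or math.isnan(self.p_value)):
            raise ValueError(f"p-value {self.p_value} outside [0, 1]")

    def to_dict(self) -> dict:
        d = asdict(self)
        d.pop("subject_ids")
        return d


def ttest_independent(x: Sequence[float], y: Sequence[float],
                      variant: str = "welch", endpoint: str = "") -> GroupComparisonResult:
    """Two-sided independent two-sample t-test.

    ``variant`` is ``"pooled"`` (equal-variance Student) or ``"welch"``.
    Degenerate zero-variance samples with equal means return p = 1 by
    convention (logged).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    x, y = x[~np.isnan(x)], y[~np.isnan(y)]
    if len(x) < 2 or len(y) < 2:
        raise ValueError("need at least 2 values per sample")
    if variant not in ("pooled", "welch"):
        raise ValueError(f"unknown t-test variant {variant!r}")
    if x.std(ddof=1) == 0 and y.std(ddof=1) == 0 and x.mean() == y.mean():
        log.warning("both samples constant and equal; p = 1 by convention")
        t, p = 0.0, 1.0
    else:
        t, p = stats.ttest_ind(x, y, equal_var=(variant == "pooled"))
    return GroupComparisonResult(
        endpoint=endpoint, test=f"t-{variant}", n1=len(x), n2=len(y),
        mean1=float(x.mean()), mean2=float(y.mean()),
        sd1=float(x.std(ddof=1)), sd2=float(y.std(ddof=1)),
        statistic=float(t), p_value=float(p))


def ttest_from_summary(mean1: float, sd1: float, n1: int,
                       mean2: float, sd2: float, n2: int,
                       variant: str = "pooled", endpoint: str = "") -> GroupComparisonResult:
    """t-test from printed summary statistics (mean, SD, n per arm).

    Equals :func:`ttest_independent` on any raw samples realizing those
    summaries exactly (pooled variant).
    """
    if n1 < 2 or n2 < 2:
        raise ValueError("need n >= 2 per arm")
    if variant not in ("pooled", "welch"):
        raise ValueError(f"unknown t-test variant {variant!r}")
    t, p = stats.ttest_ind_from_stats(mean1, sd1, n1, mean2, sd2, n2,
                                      equal_var=(variant == "pooled"))
    return GroupComparisonResult(
        endpoint=endpoint, test=f"t-{variant}-summary", n1=n1, n2=n2,
        mean1=mean1, mean2=mean2, sd1=sd1, sd2=sd2,
        statistic=float(t), p_value=float(p))


def mann_whitney_u(x: Sequence[float], y: Sequence[float],
                   endpoint: str = "") -> GroupComparisonResult:
    """Two-sided Mann-Whitney U test with mid-rank tie handling.

    Exact p by enumeration of rank arrangements when the combined sample
    size is <= 20 and there are no ties; otherwise the normal approximation
    with tie and continuity corrections.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    x, y = x[~np.isnan(x)], y[~np.isnan(y)]
    if len(x) == 0 or len(y) == 0:
        raise ValueError("need at least 1 value per sample")
    combined = np.concatenate([x, y])
    has_ties = len(np.unique(combined)) < len(combined)
    if len(combined) <= 20 and not has_ties:
        method = "exact"
    else:
        method = "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method,
                             use_continuity=True)
    return GroupComparisonResult(
        endpoint=endpoint, test=f"mann-whitney-{method}", n1=len(x), n2=len(y),
        mean1=float(x.mean()), mean2=float(y.mean()),
        sd1=float(x.std(ddof=1)) if len(x) > 1 else 0.0,
        sd2=float(y.std(ddof=1)) if len(y) > 1 else 0.0,
        statistic=float(res.statistic), p_value=float(res.pvalue))


def holm_adjust(p_values: Sequence[float]) -> list[float]:
    """Holm step-down adjustment of a family of p-values."""
    p = np.asarray(p_values, dtype=float)
    order = np.argsort(p)
    m = len(p)
    adj = np.empty(m)
    running = 0.0
    for rank, idx in enumerate(order):
        running = max(running, (m - rank) * p[idx])
        adj[idx] = min(1.0, running)
    return adj.tolist()


# ---------------------------------------------------------------------------
# full analysis


@dataclass
class TrialAnalysisConfig:
    """Knobs of the arm-comparison analysis.

    ttest_variant: "welch" (default, robust to unequal variances) or "pooled".
    outlier_mode: "none", "grubbs" (iterative at outlier_alpha) or
        "fixed_count" (remove outlier_k most extreme per arm).
    outlier_endpoint: the endpoint screened for extremes.
    age_split_years / height_split_cm: subgroup strata boundaries.
    holm: apply Holm correction across each family of endpoint p-values.
    """

    ttest_variant: str = "welch"
    outlier_mode: str = "none"
    outlier_endpoint: str = "change_2wk"
    outlier_alpha: float = 0.05
    outlier_k: int = 5
    age_split_years: float = 50.0
    height_split_cm: float = 160.0
    holm: bool = False


def _strata(df: pd.DataFrame, cfg: TrialAnalysisConfig) -> dict[str, pd.Series]:
    return {
        "sex:male": df["sex"] == "M",
        "sex:female": df["sex"] == "F",
        f"age:{20:.0f}-{cfg.age_split_years - 1:.0f}": df["age_years"] < cfg.age_split_years,
        f"age:{cfg.age_split_years:.0f}+": df["age_years"] >= cfg.age_split_years,
        f"height:<{cfg.height_split_cm:.0f}cm": df["height_cm"] < cfg.height_split_cm,
        f"height:>={cfg.height_split_cm:.0f}cm": df["height_cm"] >= cfg.height_split_cm,
    }


def run_trial_analysis(table: TrialTable,
                       config: TrialAnalysisConfig | None = None) -> dict:
    """Arm summaries and tests for raw and baseline-subtracted distances.

    Produces, per timepoint, arm means/SDs and a t-test ("actual" and
    "change" sections), plus Mann-Whitney subgroup comparisons of the change
    endpoints within sex/age/height strata.  Every test records the subject
    ids that entered it; empty or too-small strata are reported as
    not-testable rather than aborting.
    """
    cfg = config or TrialAnalysisConfig()
    present_arms = sorted(set(table.data["arm"]))
    if len(present_arms) < 2:
        raise ValueError(f"need both arms for comparison, found {present_arms}")

    if cfg.outlier_mode != "none":
        table = exclude_outliers(table, cfg.outlier_endpoint,
                                 alpha=cfg.outlier_alpha, mode=cfg.outlier_mode,
                                 k=cfg.outlier_k)
    df = table.data
    changes = baseline_subtract(df)

    def arm_vals(frame: pd.DataFrame, col: str, arm: str) -> tuple[np.ndarray, list[str]]:
        sub = frame[frame["arm"] == arm]
        ok = sub[col].notna()
        return sub.loc[ok, col].to_numpy(dtype=float), sub.loc[ok, "id"].tolist()

    report: dict = {
        "config": asdict(cfg),
        "n_analyzed": {arm: int((df["arm"] == arm).sum()) for arm in ARMS},
        "exclusions": table.exclusions.to_dict(orient="records"),
        "actual": {}, "change": {}, "subgroups": {},
    }

    for section, frame, cols in (
            ("actual", df, [f"distance_{tp}" for tp in TIMEPOINTS]),
            ("change", changes, [f"change_{tp}" for tp in FOLLOWUPS])):
        for col in cols:
            x, ids_x = arm_vals(frame, col, "AA+")
            y, ids_y = arm_vals(frame, col, "AA-")
            if len(x) < 2 or len(y) < 2:
                report[section][col] = {"testable": False,
                                        "n1": len(x), "n2": len(y)}
                continue
            res = ttest_independent(x, y, variant=cfg.ttest_variant, endpoint=col)
            entry = res.to_dict()
            entry["testable"] = True
            entry["subject_ids"] = {"AA+": ids_x, "AA-": ids_y}
            report[section][col] = entry
        if cfg.holm:
            tested = [c for c in cols if report[section][c].get("testable")]
            adj = holm_adjust([report[section][c]["p_value"] for c in tested])
            for c, p in zip(tested, adj):
                report[section][c]["p_holm"] = p

    for name, mask in _strata(changes, cfg).items():
        stratum = changes[mask]
        block: dict = {"n": {arm: int((stratum["arm"] == arm).sum()) for arm in ARMS}}
        for tp in FOLLOWUPS:
            col = f"change_{tp}"
            x, ids_x = arm_vals(stratum, col, "AA+")
            y, ids_y = arm_vals(stratum, col, "AA-")
            if len(x) == 0 or len(y) == 0:
                block[col] = {"testable": False, "n1": len(x), "n2": len(y)}
                continue
            res = mann_whitney_u(x, y, endpoint=f"{name}/{col}")
            entry = res.to_dict()
            entry["testable"] = True
            entry["subject_ids"] = {"AA+": ids_x, "AA-": ids_y}
            block[col] = entry
        report["subgroups"][name] = block

    return report
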