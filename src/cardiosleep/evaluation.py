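"""Agreement metrics, sleep-architecture metrics and cohort statistics.

Agreement between expert and model hypnograms is summarized by a 4x4
confusion matrix (rows expert, columns model, class order WAKE/N1N2/N3/REM),
overall accuracy, and Cohen's Kappa. Epochs the expert marked ARTIFACT, and
synthetic PAD epochs, are excluded from all agreement statistics.

Sleep-architecture metrics per night: time in bed (TIB, the scored-window
duration — no lights-off marker exists for a self-applied home device),
total sleep time (TST), sleep efficiency (SE = 100*TST/TIB), sleep-onset
latency (SOL, recording start to first sleep epoch), and stage percentages
relative to TST. ARTIFACT epochs count toward TIB but never toward TST.

Cohort statistics follow the one-value-per-participant principle: paired,
two-tailed t-tests on per-participant means, and a consistency test applied
to squared deviations from the cohort mean.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .types import CLASS_STAGES, Hypnogram, Stage

__all__ = [
    "ConfusionMatrix",
    "SleepMetrics",
    "PairedTestResult",
    "confusion",
    "accuracy",
    "cohens_kappa",
    "sleep_metrics",
    "paired_metric_test",
    "variance_consistency_test",
    "longitudinal_trends",
    "class_distribution",
]


@dataclass
class ConfusionMatrix:
    """4x4 agreement counts; rows = expert stage, columns = predicted stage."""

    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.shape != (4, 4) or np.any(self.counts < 0):
            raise ValueError("confusion matrix must be 4x4 and non-negative")

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def row_percent(self) -> np.ndarray:
        """Row-normalized percentages (rows with zero support stay zero)."""
        sums = self.counts.sum(axis=1, keepdims=True).astype(float)
        out = np.zeros_like(self.counts, dtype=float)
        nz = sums[:, 0] > 0
        out[nz] = 100.0 * self.counts[nz] / sums[nz]
        return out

    def __add__(self, other: "ConfusionMatrix") -> "ConfusionMatrix":
        return ConfusionMatrix(self.counts + other.counts)


def _stage_array(hyp: Hypnogram | np.ndarray) -> np.ndarray:
    if isinstance(hyp, Hypnogram):
        return hyp.stages
    return np.asarray(hyp, dtype=np.int64)


def confusion(true: Hypnogram | np.ndarray, pred: Hypnogram | np.ndarray
              ) -> ConfusionMatrix:
    """Count stage agreement over scorable epochs.

    Pairs where either sequence is ARTIFACT or PAD are excluded.
    """
    t, p = _stage_array(true), _stage_array(pred)
    if t.size != p.size:
        raise ValueError(f"length mismatch: {t.size} vs {p.size}")
    keep = np.isin(t, CLASS_STAGES) & np.isin(p, CLASS_STAGES)
    t, p = t[keep], p[keep]
    counts = np.zeros((4, 4), dtype=np.int64)
    np.add.at(counts, (t, p), 1)
    return ConfusionMatrix(counts)


def accuracy(cm: ConfusionMatrix) -> float:
    """Overall percentage agreement (0-100)."""
    if cm.total == 0:
        raise ValueError("confusion matrix is empty; accuracy undefined")
    return 100.0 * float(np.trace(cm.counts)) / cm.total


def cohens_kappa(cm: ConfusionMatrix) -> float:
    """Chance-corrected agreement: kappa = (p_o - p_e) / (1 - p_e)."""
    n = cm.total
    if n == 0:
        raise ValueError("confusion matrix is empty; kappa undefined")
    p_o = float(np.trace(cm.counts)) / n
    row = cm.counts.sum(axis=1) / n
    col = cm.counts.sum(axis=0) / n
    p_e = float(row @ col)
    if p_e >= 1.0 - 1e-12:
        if p_o >= 1.0 - 1e-12:
            return 1.0
        raise ValueError("kappa undefined: chance agreement is 1 but observed < 1")
    return (p_o - p_e) / (1.0 - p_e)


def class_distribution(counts: dict[str, int] | list[int]) -> np.ndarray:
    """Percentages of labeled epochs per class, from raw counts."""
    vals = np.asarray(list(counts.values()) if isinstance(counts, dict) else counts,
                      dtype=float)
    total = vals.sum()
    if total <= 0:
        raise ValueError("no epochs")
    return 100.0 * vals / total


@dataclass
class SleepMetrics:
    """Per-night sleep-architecture summary (minutes and percentages)."""

    tib_min: float
    tst_min: float
    se_pct: float
    sol_min: float | None
    pct_n1n2: float | None
    pct_n3: float | None
    pct_rem: float | None


def sleep_metrics(hyp: Hypnogram | np.ndarray) -> SleepMetrics:
    """Compute TIB/TST/SE/SOL and stage percentages for one hypnogram.

    SOL is measured from the first scored epoch to the first sleep epoch;
    an all-wake night has undefined SOL and stage percentages (None).
    """
    stages = _stage_array(hyp)
    scored = stages != Stage.PAD
    if not scored.any():
        raise ValueError("no scored epochs")
    stages = stages[scored]
    epoch_min = 0.5
    tib = stages.size * epoch_min
    sleep = np.isin(stages, (Stage.N1N2, Stage.N3, Stage.REM))
    tst = float(sleep.sum()) * epoch_min
    se = 100.0 * tst / tib if tib > 0 else 0.0
    if sleep.any():
        sol = float(np.argmax(sleep)) * epoch_min
        n = sleep.sum()
        pct = {
            s: 100.0 * float(np.sum(stages == s)) / n
            for s in (Stage.N1N2, Stage.N3, Stage.REM)
        }
        return SleepMetrics(tib, tst, se, sol,
                            pct[Stage.N1N2], pct[Stage.N3], pct[Stage.REM])
    return SleepMetrics(tib, 0.0, 0.0, None, None, None, None)


@dataclass
class PairedTestResult:
    t_stat: float
    p_value: float
    degenerate: bool = False


def paired_metric_test(before: np.ndarray, after: np.ndarray) -> PairedTestResult:
    """Paired, two-tailed t-test on per-participant metric values."""
    before = np.asarray(before, dtype=float)
    after = np.asarray(after, dtype=float)
    if before.shape != after.shape:
        raise ValueError("before/after must cover the same participants")
    if before.size < 3:
        raise ValueError("need at least 3 participants")
    d = after - before
    if np.std(d, ddof=1) == 0:
        # constant difference: the t statistic is undefined
        return PairedTestResult(
            t_stat=0.0 if np.allclose(d, 0) else math.inf * np.sign(d.mean()),
            p_value=1.0 if np.allclose(d, 0) else 0.0,
            degenerate=True,
        )
    t, p = stats.ttest_rel(after, before)
    return PairedTestResult(float(t), float(p))


def variance_consistency_test(acc_a: np.ndarray, acc_b: np.ndarray
                              ) -> PairedTestResult:
    """Compare inter-participant spread of a metric between two conditions.

    Per condition, each participant contributes the squared deviation from
    that condition's cohort mean; the two sets of squared deviations are
    compared with a paired, two-tailed t-test. A negative t statistic means
    condition B is more consistent (smaller spread) than condition A.
    """
    a = np.asarray(acc_a, dtype=float)
    b = np.asarray(acc_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("conditions must cover the same participants")
    da = (a - a.mean()) ** 2
    db = (b - b.mean()) ** 2
    return paired_metric_test(da, db)


_METRIC_FIELDS = ("tst_min", "tib_min", "se_pct", "pct_n1n2", "pct_n3", "pct_rem")


def longitudinal_trends(
    nights: list[tuple[str, str, Hypnogram | np.ndarray, Hypnogram | np.ndarray | None]],
) -> pd.DataFrame:
    """Cohort mean +/- SEM of sleep metrics per night label and source.

    ``nights`` holds ``(participant_id, night_label, expert, model)`` tuples;
    ``model`` may be None when only expert labels exist. Returns a tidy frame
    with columns (metric, night_label, source, mean, sem, n); SEM is NaN for
    single-participant cells.
    """
    rows = []
    for pid, label, expert, model in nights:
        for source, hyp in (("expert", expert), ("model", model)):
            if hyp is None:
                continue
            m = sleep_metrics(hyp)
            for f in _METRIC_FIELDS:
                v = getattr(m, f)
                if v is not None:
                    rows.append((pid, label, source, f, v))
    df = pd.DataFrame(rows, columns=["participant", "night_label", "source",
                                     "metric", "value"])
    if df.empty:
        return pd.DataFrame(columns=["metric", "night_label", "source",
                                     "mean", "sem", "n"])
    g = df.groupby(["metric", "night_label", "source"])["value"]
    out = g.agg(mean="mean", sem=lambda v: stats.sem(v) if len(v) > 1 else np.nan,
                n="count").reset_index()
    return out
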