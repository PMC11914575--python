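"""Evaluation statistics and survival machinery.

Correlation and segmentation metrics used to validate the model, plus the
survival side: univariate Cox proportional hazards on a score-thresholded
grouping, Kaplan-Meier / log-rank comparison, Harrell's concordance index,
and the exploratory threshold scan that locates stratification cutoffs as
local minima of the log-rank p-value (the "two peaks" pattern that yields a
low and a high cutoff for three-class stratification).

Orientation convention: a higher angiogenesis score means longer expected
survival, so a well-oriented score has c-index > 0.5. Cox fitting uses the
partial likelihood with Efron tie handling (via lifelines).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import logrank_test, multivariate_logrank_test
from lifelines.utils import concordance_index as _lifelines_cindex
from scipy import stats
from scipy.signal import find_peaks

__all__ = [
    "SurvivalTable",
    "StratificationResult",
    "ThresholdScan",
    "spearman_corr",
    "seg_metrics",
    "aggregate_seg_metrics",
    "responder_auc",
    "cox_stratified",
    "median_stratified",
    "three_class_stratified",
    "concordance_index",
    "threshold_scan",
]


class SurvivalTable:
    """Per-patient time / event / score records.

    Backed by a DataFrame with columns patient_id, time, event, score and an
    optional group label. Times must be positive, events 0/1, patient ids
    unique.
    """

    COLUMNS = ("patient_id", "time", "event", "score")

    def __init__(self, df: pd.DataFrame):
        for col in self.COLUMNS:
            if col not in df.columns:
                raise ValueError(f"missing column {col!r}")
        if (df["time"] <= 0).any():
            raise ValueError("times must be positive")
        if not df["event"].isin([0, 1]).all():
            raise ValueError("event must be 0/1")
        if df["patient_id"].duplicated().any():
            raise ValueError("duplicate patient_id")
        self.df = df.reset_index(drop=True)

    @classmethod
    def from_arrays(cls, patient_id, time, event, score, group=None) -> "SurvivalTable":
        df = pd.DataFrame({
            "patient_id": list(patient_id),
            "time": np.asarray(time, dtype=float),
            "event": np.asarray(event, dtype=int),
            "score": np.asarray(score, dtype=float),
        })
        if group is not None:
            df["group"] = list(group)
        return cls(df)

    @classmethod
    def read_csv(cls, path: str | Path) -> "SurvivalTable":
        return cls(pd.read_csv(path))

    def to_csv(self, path: str | Path) -> None:
        self.df.to_csv(path, index=False)

    def __len__(self) -> int:
        return len(self.df)


@dataclass
class StratificationResult:
    thresholds: tuple[float, ...]
    groups: pd.Series                   # per-patient labels, index = patient_id
    hazard_ratio: float
    hr_ci: tuple[float, float]          # Wald 95% CI
    logrank_p: float
    c_index: float
    km_curves: dict = field(default_factory=dict)   # label -> DataFrame(time, survival)

    def to_json_dict(self) -> dict:
        return {
            "thresholds": list(self.thresholds),
            "hazard_ratio": self.hazard_ratio,
            "hr_ci": list(self.hr_ci),
            "logrank_p": self.logrank_p,
            "c_index": self.c_index,
            "group_sizes": self.groups.value_counts().to_dict(),
        }


@dataclass
class ThresholdScan:
    """Per-threshold log-rank p and HR over a sorted grid, with detected
    candidate cutoffs (local minima of p). The scan is exploratory: p-values
    are unadjusted for the multiplicity of thresholds tried."""

    thresholds: np.ndarray
    logrank_p: np.ndarray
    hazard_ratio: np.ndarray
    peak_indices: np.ndarray

    @property
    def peak_thresholds(self) -> np.ndarray:
        return self.thresholds[self.peak_indices]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({
            "threshold": self.thresholds,
            "logrank_p": self.logrank_p,
            "hazard_ratio": self.hazard_ratio,
        })
        df["is_peak"] = False
        df.loc[self.peak_indices, "is_peak"] = True
        return df


# ---------------------------------------------------------------------------
# plain statistics


def spearman_corr(x, y) -> tuple[float, float]:
    """Spearman rank correlation with a two-sided p-value (average ranks on
    ties). Constant input has no defined rank correlation and is refused."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 3:
        raise ValueError("x and y must be equal-length 1-D vectors, n >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("Spearman correlation undefined for constant input")
    rho, p = stats.spearmanr(x, y)
    return float(rho), float(p)


def seg_metrics(pred_mask, truth_mask) -> tuple[float, float, float]:
    """Pixel-level precision / recall / F1 on the positive class.

    A truth mask with no positive pixel leaves recall undefined; that case is
    an error here and is excluded (not zero-filled) by the aggregator.
    """
    pred = np.asarray(pred_mask).astype(bool)
    truth = np.asarray(truth_mask).astype(bool)
    if pred.shape != truth.shape:
        raise ValueError("mask shapes differ")
    if not truth.any():
        raise ValueError("truth mask has no positive pixels; recall undefined")
    tp = float(np.sum(pred & truth))
    fp = float(np.sum(pred & ~truth))
    fn = float(np.sum(~pred & truth))
    precision = tp / (tp + fp) if tp + fp > 0 else 0.0
    recall = tp / (tp + fn)
    f1 = 2 * tp / (2 * tp + fp + fn) if tp + fn + fp > 0 else 0.0
    return precision, recall, f1


def aggregate_seg_metrics(pred_masks, truth_masks) -> tuple[float, float, float]:
    """Micro-aggregated precision/recall/F1 over a patch set: pixel counts are
    pooled across patches; patches whose truth is all-negative contribute
    their false positives but cannot contribute recall terms."""
    tp = fp = fn = 0.0
    for pred, truth in zip(pred_masks, truth_masks, strict=True):
        pred = np.asarray(pred).astype(bool)
        truth = np.asarray(truth).astype(bool)
        tp += np.sum(pred & truth)
        fp += np.sum(pred & ~truth)
        fn += np.sum(~pred & truth)
    if tp + fn == 0:
        raise ValueError("no positive truth pixels in the whole set")
    precision = tp / (tp + fp) if tp + fp > 0 else 0.0
    recall = tp / (tp + fn)
    f1 = 2 * tp / (2 * tp + fp + fn)
    return float(precision), float(recall), float(f1)


def responder_auc(scores, responder_labels, n_boot: int = 2000,
                  seed: int = 0) -> tuple[float, tuple[float, float]]:
    """Rank-based ROC AUC of scores for separating responders (label 1) from
    non-responders, with a stratified-bootstrap 95% CI."""
    from sklearn.metrics import roc_auc_score

    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(responder_labels, dtype=int)
    if set(np.unique(labels)) != {0, 1}:
        raise ValueError("both responder classes must be present")
    auc = float(roc_auc_score(labels, scores))
    rng = np.random.default_rng(seed)
    pos = np.flatnonzero(labels == 1)
    neg = np.flatnonzero(labels == 0)
    boots = np.empty(n_boot)
    for i in range(n_boot):
        idx = np.concatenate([rng.choice(pos, len(pos)), rng.choice(neg, len(neg))])
        boots[i] = roc_auc_score(labels[idx], scores[idx])
    lo, hi = np.percentile(boots, [2.5, 97.5])
    return auc, (float(lo), float(hi))


# ---------------------------------------------------------------------------
# survival


def _km_curves(df: pd.DataFrame, label_col: str) -> dict:
    curves = {}
    for label, sub in df.groupby(label_col):
        km = KaplanMeierFitter()
        km.fit(sub["time"], sub["event"], label=str(label))
        sf = km.survival_function_
        curves[str(label)] = pd.DataFrame({
            "time": sf.index.to_numpy(),
            "survival": sf.iloc[:, 0].to_numpy(),
        })
    return curves


def _fit_cox_binary(df: pd.DataFrame) -> tuple[float, tuple[float, float]]:
    cph = CoxPHFitter()
    cph.fit(df[["time", "event", "high"]], duration_col="time", event_col="event")
    hr = float(np.exp(cph.params_["high"]))
    lo, hi = cph.confidence_intervals_.loc["high"]
    return hr, (float(np.exp(lo)), float(np.exp(hi)))


def cox_stratified(table: SurvivalTable, threshold: float) -> StratificationResult:
    """Stratify at ``score >= threshold`` and fit a univariate Cox PH model on
    the binary group. Returns the high-vs-low hazard ratio with its Wald 95%
    CI, the two-sided log-rank p, Harrell's c-index of the raw score, and the
    Kaplan-Meier curves of both groups."""
    df = table.df.copy()
    df["high"] = (df["score"] >= threshold).astype(int)
    sizes = df["high"].value_counts()
    if len(sizes) < 2 or (sizes < 2).any():
        raise ValueError(f"each group needs >= 2 patients at threshold {threshold}")
    if (df.groupby("high")["event"].sum() < 1).any():
        raise ValueError("each group needs at least one event")
    hr, ci = _fit_cox_binary(df)
    lr = logrank_test(
        df.loc[df.high == 1, "time"], df.loc[df.high == 0, "time"],
        df.loc[df.high == 1, "event"], df.loc[df.high == 0, "event"],
    )
    groups = pd.Series(np.where(df["high"] == 1, "high", "low"),
                       index=df["patient_id"], name="group")
    return StratificationResult(
        thresholds=(float(threshold),),
        groups=groups,
        hazard_ratio=hr,
        hr_ci=ci,
        logrank_p=float(lr.p_value),
        c_index=concordance_index(df["score"], table),
        km_curves=_km_curves(df.assign(label=groups.to_numpy()), "label"),
    )


def median_stratified(table: SurvivalTable) -> StratificationResult:
    """Median-split stratification (low/high at the cohort median score)."""
    return cox_stratified(table, float(table.df["score"].median()))


def three_class_stratified(table: SurvivalTable, low_threshold: float,
                           high_threshold: float) -> StratificationResult:
    """Three-class stratification at two externally supplied cutoffs (the
    low/high p-value peaks of a threshold scan on an independent cohort).
    The reported HR and CI are for high vs low; the log-rank p is the
    multivariate test over all three groups."""
    if not low_threshold < high_threshold:
        raise ValueError("low_threshold must be < high_threshold")
    df = table.df.copy()
    labels = np.where(df["score"] >= high_threshold, "high",
                      np.where(df["score"] >= low_threshold, "medium", "low"))
    df["label"] = labels
    if (pd.Series(labels).value_counts() < 1).any() or len(set(labels)) < 3:
        raise ValueError("a stratum is empty at the given thresholds")
    sub = df[df.label.isin(["high", "low"])].copy()
    sub["high"] = (sub.label == "high").astype(int)
    hr, ci = _fit_cox_binary(sub)
    lr = multivariate_logrank_test(df["time"], df["label"], df["event"])
    return StratificationResult(
        thresholds=(float(low_threshold), float(high_threshold)),
        groups=pd.Series(labels, index=df["patient_id"], name="group"),
        hazard_ratio=hr,
        hr_ci=ci,
        logrank_p=float(lr.p_value),
        c_index=concordance_index(df["score"], table),
        km_curves=_km_curves(df, "label"),
    )


def concordance_index(scores, table: SurvivalTable) -> float:
    """Harrell's c over usable (non-censoring-ambiguous) pairs. Higher score
    predicting longer survival gives c > 0.5."""
    scores = np.asarray(scores, dtype=float)
    df = table.df
    if len(scores) != len(df):
        raise ValueError("scores length must match table")
    if df["event"].sum() == 0:
        raise ValueError("no events: no comparable pairs")
    return float(_lifelines_cindex(df["time"], scores, df["event"]))


def threshold_scan(
    scores,
    table: SurvivalTable,
    n_grid: int = 25,
    quantile_range: tuple[float, float] = (0.10, 0.90),
    min_prominence: float = 0.25,
) -> ThresholdScan:
    """Sweep a score cutoff over the interior quantiles and record the
    log-rank p and Cox HR at each cutoff.

    Candidate stratification thresholds are local minima of p, detected with
    a minimum prominence of ``min_prominence`` decades on the -log10(p)
    trace. The endpoints of the grid are eligible as peaks. Exploratory:
    p-values are not multiplicity-adjusted.
    """
    scores = np.asarray(scores, dtype=float)
    if len(scores) != len(table):
        raise ValueError("scores length must match table")
    lo, hi = np.quantile(scores, quantile_range)
    if n_grid < 2 or not lo < hi:
        raise ValueError("degenerate threshold grid")
    grid = np.linspace(lo, hi, n_grid)
    work = table.df.copy()
    work["score"] = scores
    pvals = np.full(n_grid, np.nan)
    hrs = np.full(n_grid, np.nan)
    for i, th in enumerate(grid):
        high = work["score"] >= th
        sizes = high.value_counts()
        if len(sizes) < 2 or (sizes < 2).any():
            continue
        ev = work.groupby(high)["event"].sum()
        if (ev < 1).any():
            continue
        lr = logrank_test(work.loc[high, "time"], work.loc[~high, "time"],
                          work.loc[high, "event"], work.loc[~high, "event"])
        pvals[i] = lr.p_value
        try:
            # extreme cutoffs can completely separate events from censoring;
            # the HR is then unstable and lifelines warns — silence it here
            # and keep the (possibly huge) point estimate
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                hrs[i], _ = _fit_cox_binary(work.assign(high=high.astype(int)))
        except Exception:
            pass
    neglog = -np.log10(np.where(np.isnan(pvals), 1.0, np.clip(pvals, 1e-300, 1.0)))
    # pad so grid endpoints can be detected as local minima of p
    padded = np.concatenate([[-np.inf], neglog, [-np.inf]])
    peaks, _ = find_peaks(padded, prominence=min_prominence)
    peaks = peaks - 1
    return ThresholdScan(thresholds=grid, logrank_p=pvals, hazard_ratio=hrs,
                         peak_indices=peaks.astype(int))
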