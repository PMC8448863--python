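"""XIC peak-height quantification of identified phosphopeptides.

Given MS1 ion maps — (retention time, m/z, intensity) point lists per sample —
and a table of identified peptides with target m/z and expected elution apex,
an extracted ion chromatogram (XIC) is built for every peptide in every sample
inside a ppm-level m/z window and a retention-time window around the apex.
The peptide's abundance in a sample is the XIC peak height (maximum point
intensity), accepted only when the trace holds enough points to define a peak.
Heights are normalised to each sample's total intensity, and conditions are
compared by Student's t tests on log2 heights with Benjamini-Hochberg
correction.

Chromatographic peaks in the data this models are ~30 s wide at the base and
sampled with at least ten MS1 points, which motivates the default
retention-time half-window (30 s) and minimum point count (10).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .enrich import bh_adjust

__all__ = [
    "RawIonMap",
    "XICParams",
    "IntensityMatrix",
    "DiffResult",
    "read_ionmap_tsv",
    "read_peptides_tsv",
    "extract_xic",
    "peak_height",
    "quantify",
    "normalize_heights",
    "differential",
    "differential_table",
]

ION_COLUMNS = ["sample", "rt_s", "mz", "intensity"]
PEPTIDE_COLUMNS = ["peptide_id", "mz", "charge", "rt_apex_s", "site"]


@dataclass
class RawIonMap:
    """MS1 centroid point lists for one or more samples."""

    points: pd.DataFrame  # columns: sample, rt_s, mz, intensity

    def __post_init__(self) -> None:
        missing = [c for c in ION_COLUMNS if c not in self.points.columns]
        if missing:
            raise ValueError(f"ion map is missing columns: {missing}")
        pts = self.points
        if (pts["intensity"] < 0).any():
            raise ValueError("intensities must be non-negative")
        if not np.isfinite(pts[["rt_s", "mz"]].to_numpy(dtype=float)).all():
            raise ValueError("rt and m/z must be finite")

    def samples(self) -> list[str]:
        return sorted(self.points["sample"].unique())

    def sample_points(self, sample: str) -> pd.DataFrame:
        return self.points[self.points["sample"] == sample]


@dataclass
class XICParams:
    """Extraction window: m/z tolerance (ppm), RT half-window (s), minimum points."""

    ppm_tol: float = 10.0
    rt_half_window_s: float = 30.0
    min_points: int = 10
    smooth: bool = False  # 3-point moving average before taking the maximum

    def __post_init__(self) -> None:
        if self.ppm_tol <= 0:
            raise ValueError("ppm_tol must be positive")
        if self.rt_half_window_s <= 0:
            raise ValueError("rt_half_window_s must be positive")
        if self.min_points < 1:
            raise ValueError("min_points must be >= 1")


@dataclass
class IntensityMatrix:
    """Peptide x sample peak heights with per-sample condition labels."""

    heights: pd.DataFrame            # index: peptide_id, columns: samples
    conditions: pd.Series            # index: samples, values: condition labels

    def __post_init__(self) -> None:
        if not set(self.heights.columns) <= set(self.conditions.index):
            raise ValueError("every sample column needs a condition label")
        vals = self.heights.to_numpy(dtype=float)
        if np.nanmin(vals, initial=0.0) < 0:
            raise ValueError("peak heights must be non-negative where present")


@dataclass
class DiffResult:
    peptide_id: str
    log2fc: float
    p: float
    q: float
    n_a: int
    n_b: int


def read_ionmap_tsv(path: str | Path) -> RawIonMap:
    return RawIonMap(points=pd.read_csv(path, sep="\t", comment="#"))


def read_peptides_tsv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#")
    missing = [c for c in PEPTIDE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"peptide table is missing columns: {missing}")
    return df


def extract_xic(sample_points: pd.DataFrame, target_mz: float, rt_apex_s: float, params: XICParams) -> pd.DataFrame:
    """All points with |mz - target|/target <= ppm_tol ppm and |rt - apex| <= half-window.

    Returns the trace ordered by retention time; an empty trace is a valid
    result meaning the peptide was not observed in this sample.
    """
    if target_mz <= 0:
        raise ValueError("target m/z must be positive")
    mz = sample_points["mz"].to_numpy(dtype=float)
    rt = sample_points["rt_s"].to_numpy(dtype=float)
    keep = (np.abs(mz - target_mz) / target_mz <= params.ppm_tol * 1e-6) & (
        np.abs(rt - rt_apex_s) <= params.rt_half_window_s
    )
    return sample_points.loc[keep].sort_values("rt_s", kind="mergesort")


def peak_height(trace: pd.DataFrame, params: XICParams) -> float:
    """Maximum intensity over the trace, or NaN if it has fewer than min_points points."""
    if len(trace) < params.min_points:
        return float("nan")
    y = trace["intensity"].to_numpy(dtype=float)
    if params.smooth and len(y) >= 3:
        y = np.convolve(y, np.ones(3) / 3.0, mode="valid")
    return float(y.max())


def quantify(
    raw: RawIonMap,
    peptides: pd.DataFrame,
    params: XICParams | None = None,
    conditions: pd.Series | dict | None = None,
) -> IntensityMatrix:
    """Peak heights for every peptide in every sample.

    Vectorised equivalent of running :func:`extract_xic` + :func:`peak_height`
    per (peptide, sample) pair; sorts each sample's points by m/z once and
    locates each peptide's window by binary search.
    """
    params = params or XICParams()
    missing = [c for c in PEPTIDE_COLUMNS[:4] if c not in peptides.columns]
    if missing:
        raise ValueError(f"peptide table is missing columns: {missing}")
    samples = raw.samples()
    out = np.full((len(peptides), len(samples)), np.nan)
    tol = params.ppm_tol * 1e-6
    pep_mz = peptides["mz"].to_numpy(dtype=float)
    pep_rt = peptides["rt_apex_s"].to_numpy(dtype=float)
    for j, sample in enumerate(samples):
        pts = raw.sample_points(sample)
        order = np.argsort(pts["mz"].to_numpy(dtype=float), kind="mergesort")
        mz = pts["mz"].to_numpy(dtype=float)[order]
        rt = pts["rt_s"].to_numpy(dtype=float)[order]
        inten = pts["intensity"].to_numpy(dtype=float)[order]
        lo = np.searchsorted(mz, pep_mz * (1 - tol), side="left")
        hi = np.searchsorted(mz, pep_mz * (1 + tol), side="right")
        for i in range(len(peptides)):
            s = slice(lo[i], hi[i])
            in_rt = np.abs(rt[s] - pep_rt[i]) <= params.rt_half_window_s
            npts = int(in_rt.sum())
            if npts < params.min_points:
                continue
            y = inten[s][in_rt]
            if params.smooth and npts >= 3:
                # smoothing acts along the RT axis
                rt_order = np.argsort(rt[s][in_rt], kind="mergesort")
                y = np.convolve(y[rt_order], np.ones(3) / 3.0, mode="valid")
            out[i, j] = y.max()
    heights = pd.DataFrame(out, index=peptides["peptide_id"].to_numpy(), columns=samples)
    heights.index.name = "peptide_id"
    if conditions is None:
        conditions = pd.Series({s: "unknown" for s in samples})
    elif isinstance(conditions, dict):
        conditions = pd.Series(conditions)
    return IntensityMatrix(heights=heights, conditions=conditions)


def normalize_heights(m: IntensityMatrix) -> IntensityMatrix:
    """Divide each sample by its total intensity, rescaled by the mean of the totals.

    After normalisation every sample's total over present values is identical
    (the mean of the original totals), so per-sample global scale factors
    cancel exactly while magnitudes stay on the original intensity scale.
    """
    totals = m.heights.sum(axis=0, skipna=True)
    bad = totals[~(totals > 0)]
    if len(bad):
        raise ValueError(f"sample(s) with non-positive total intensity: {list(bad.index)}")
    scaled = m.heights.div(totals, axis=1) * float(totals.mean())
    return IntensityMatrix(heights=scaled, conditions=m.conditions)


def differential(
    m: IntensityMatrix,
    condition_a: str | None = None,
    condition_b: str | None = None,
    equal_var: bool = True,
) -> list[DiffResult]:
    """Per-peptide log2 fold change (B vs A), t test, and BH correction.

    Fold change is mean(log2 heights in B) - mean(log2 heights in A). The
    two-sided t test (equal-variance Student by default; Welch with
    ``equal_var=False``) runs only for peptides with at least two present
    values per condition; others are returned with NaN p/q. Missing values
    are never imputed.
    """
    labels = m.conditions.loc[m.heights.columns]
    uniq = list(pd.unique(labels))
    if condition_a is None or condition_b is None:
        if len(uniq) != 2:
            raise ValueError(f"need exactly two conditions, found {uniq}")
        condition_a, condition_b = uniq[0], uniq[1]
    cols_a = labels.index[labels == condition_a]
    cols_b = labels.index[labels == condition_b]
    if len(cols_a) < 2 or len(cols_b) < 2:
        raise ValueError("each condition needs at least two samples")
    with np.errstate(divide="ignore"):
        la = np.log2(m.heights[cols_a].to_numpy(dtype=float))
        lb = np.log2(m.heights[cols_b].to_numpy(dtype=float))
    n_a = np.isfinite(la).sum(axis=1)
    n_b = np.isfinite(lb).sum(axis=1)
    mean_a = np.where(n_a > 0, np.nanmean(np.where(np.isfinite(la), la, np.nan), axis=1), np.nan)
    mean_b = np.where(n_b > 0, np.nanmean(np.where(np.isfinite(lb), lb, np.nan), axis=1), np.nan)
    fc = mean_b - mean_a
    testable = (n_a >= 2) & (n_b >= 2)
    p = np.full(len(fc), np.nan)
    if testable.any():
        import warnings

        with np.errstate(invalid="ignore"), warnings.catch_warnings():
            # zero-variance rows (e.g. noiseless simulations) yield NaN p by design
            warnings.simplefilter("ignore", RuntimeWarning)
            res = stats.ttest_ind(
                np.where(np.isfinite(lb), lb, np.nan)[testable],
                np.where(np.isfinite(la), la, np.nan)[testable],
                axis=1,
                equal_var=equal_var,
                nan_policy="omit",
            )
        p[testable] = res.pvalue
    q = np.full(len(fc), np.nan)
    finite_p = np.isfinite(p)
    if finite_p.any():
        q[finite_p] = np.maximum(bh_adjust(p[finite_p]), p[finite_p])
    return [
        DiffResult(
            peptide_id=pep,
            log2fc=float(fc[i]),
            p=float(p[i]),
            q=float(q[i]),
            n_a=int(n_a[i]),
            n_b=int(n_b[i]),
        )
        for i, pep in enumerate(m.heights.index)
    ]


def differential_table(results: Sequence[DiffResult]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "peptide_id": [r.peptide_id for r in results],
            "log2fc": [r.log2fc for r in results],
            "p": [r.p for r in results],
            "q": [r.q for r in results],
            "n_a": [r.n_a for r in results],
            "n_b": [r.n_b for r in results],
        }
    )
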