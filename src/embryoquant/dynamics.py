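"""Temporal classification, profile clustering and time-course QC.

Genes in an early-embryo time course fall into four kinetic groups:
maternal-downregulated (deposited in the oocyte, destabilised after the
first hour), persistent (held steady through mid-sampling), transient
(a single sharp peak), and zygotic (absent early, detected only once the
zygotic genome activates).  The rules here quantify those verbal
definitions; precedence zygotic > maternal > transient > persistent
resolves overlaps, zygotic being the call with the strongest biological
commitment (detectability, not shape).
"""
from __future__ import annotations

import dataclasses
import warnings
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage

from .io import SampleMeta, ValidationError

LABELS = ("maternal_down", "persistent", "transient", "zygotic", "unclassified")

#: Cluster label reserved for zero-variance (flat) profiles.
FLAT_CLUSTER = 0


@dataclasses.dataclass(frozen=True)
class TemporalClassParams:
    """Thresholds quantifying the four kinetic groups.

    maternal_fold
        Minimum first/last abundance ratio for a maternal-downregulated call.
    persistent_log2_sd_max
        Maximum standard deviation of log2(m+1) across the 3-5 h samples for
        a persistent call.
    transient_peak_fold
        Minimum ratio of the unique peak to the mean of the remaining
        timepoints.
    zygotic_onset_hours
        Timepoint (h) at or after which zygotic transcription may first be
        detected; samples before it must be undetected.
    """

    maternal_fold: float = 2.0
    persistent_log2_sd_max: float = 0.25
    transient_peak_fold: float = 2.0
    zygotic_onset_hours: float = 4.0
    persistent_window: tuple[float, float] = (3.0, 5.0)

    def __post_init__(self) -> None:
        if self.maternal_fold <= 1 or self.transient_peak_fold <= 1:
            raise ValidationError("fold thresholds must exceed 1")
        if self.persistent_log2_sd_max <= 0:
            raise ValidationError("persistent_log2_sd_max must be positive")


def classify_temporal(
    abundance: pd.DataFrame,
    detected: pd.DataFrame,
    timepoints: Sequence[float],
    params: TemporalClassParams | None = None,
) -> pd.Series:
    """Assign each gene exactly one temporal label.

    Rules, in precedence order (samples must be time-ordered):

    1. zygotic: undetected at every sample before the onset index (first
       sample with timepoint >= ``zygotic_onset_hours``) and detected at
       least once from it onward.
    2. maternal_down: detected at the first sample, the trajectory maximum
       falls at the first sample or at the 3 h sample (allowing the global
       poly(A) rebound), and m(t1) >= maternal_fold * m(t_last).
    3. transient: detected somewhere, with a unique maximum at least
       transient_peak_fold times the mean of all other timepoints.
    4. persistent: detected at every sample and SD of log2(m+1) across the
       3-5 h samples <= persistent_log2_sd_max.
    5. otherwise unclassified.
    """
    params = params or TemporalClassParams()
    tps = np.asarray(list(timepoints), dtype=float)
    if len(tps) < 3:
        raise ValidationError("temporal classification needs >= 3 timepoints")
    if abundance.shape[1] != len(tps) or detected.shape[1] != len(tps):
        raise ValidationError("abundance/detected columns must match timepoints")

    onset_candidates = np.nonzero(tps >= params.zygotic_onset_hours)[0]
    onset_idx = int(onset_candidates[0]) if len(onset_candidates) else len(tps)
    rebound_candidates = np.nonzero(tps >= 3.0)[0]
    peak_allowed = {0}
    if len(rebound_candidates):
        peak_allowed.add(int(rebound_candidates[0]))
    lo, hi = params.persistent_window
    window_idx = np.nonzero((tps >= lo) & (tps <= hi))[0]

    m = abundance.to_numpy(dtype=float)
    det = detected.reindex(index=abundance.index).to_numpy(dtype=bool)
    labels = np.full(m.shape[0], "unclassified", dtype=object)

    for i in range(m.shape[0]):
        row, drow = m[i], det[i]
        if onset_idx > 0 and not drow[:onset_idx].any() and drow[onset_idx:].any():
            labels[i] = "zygotic"
            continue
        peak = int(np.argmax(row))
        if (
            drow[0]
            and peak in peak_allowed
            and row[0] > 0
            and (row[-1] == 0 or row[0] >= params.maternal_fold * row[-1])
        ):
            labels[i] = "maternal_down"
            continue
        if drow.any():
            mx = row.max()
            if (row == mx).sum() == 1 and mx > 0:
                rest = np.delete(row, peak).mean()
                if rest == 0 or mx >= params.transient_peak_fold * rest:
                    labels[i] = "transient"
                    continue
        if drow.all():
            win = np.log2(row[window_idx] + 1.0)
            sd = win.std(ddof=1) if len(win) > 1 else 0.0
            if sd <= params.persistent_log2_sd_max:
                labels[i] = "persistent"
    return pd.Series(labels, index=abundance.index, name="label")


def cluster_profiles(abundance: pd.DataFrame, k: int) -> pd.Series:
    """Cluster temporal profiles by shape.

    Rows are z-scored log2(m+1) profiles; distance is 1 - Pearson
    correlation with average linkage, cut to ``k`` clusters (labels 1..k).
    Zero-variance rows cannot be correlated and go to the dedicated flat
    cluster (label 0) before clustering.
    """
    if k < 1:
        raise ValidationError("k must be >= 1")
    logm = np.log2(abundance.to_numpy(dtype=float) + 1.0)
    sd = logm.std(axis=1)
    flat = sd < 1e-12
    n_active = int((~flat).sum())
    if k > n_active:
        raise ValidationError(
            f"k={k} exceeds the {n_active} non-flat profiles available"
        )
    out = np.zeros(len(abundance), dtype=int)
    active = logm[~flat]
    z = (active - active.mean(axis=1, keepdims=True)) / active.std(
        axis=1, keepdims=True
    )
    if n_active == 1:
        out[~flat] = 1
    else:
        link = linkage(z, method="average", metric="correlation")
        out[~flat] = fcluster(link, t=k, criterion="maxclust")
    return pd.Series(out, index=abundance.index, name="cluster")


def successive_correlation(abundance: pd.DataFrame) -> pd.Series:
    """Spearman rank correlation over genes for each adjacent sample pair.

    A time course sampled densely enough shows high correlation between
    neighbouring samples; a drop flags a batch problem or a too-sparse
    sampling grid.  Constant columns give an undefined correlation, reported
    as NaN with a warning.
    """
    cols = list(abundance.columns)
    if len(cols) < 2:
        raise ValidationError("need at least two samples")
    out = {}
    for a, b in zip(cols, cols[1:]):
        x = abundance[a].to_numpy(dtype=float)
        y = abundance[b].to_numpy(dtype=float)
        if np.all(x == x[0]) or np.all(y == y[0]):
            warnings.warn(f"constant column in pair ({a}, {b}); correlation NaN")
            rho = np.nan
        else:
            rho = float(stats.spearmanr(x, y).statistic)
        out[f"{a}|{b}"] = rho
    return pd.Series(out, name="spearman_rho")


def stability_ranking(
    abundance: pd.DataFrame,
    detected: pd.DataFrame,
    top_n: int = 10,
) -> pd.DataFrame:
    """Rank reference-gene candidates by a log-scale coefficient of variation.

    Only genes detected at every timepoint are eligible.  The variability
    score is SD(log2(m+1)) / mean(log2(m+1)) across timepoints; lower is
    more stable.  Ties break by gene ID.
    """
    eligible = detected.reindex(index=abundance.index).all(axis=1)
    if not eligible.any():
        raise ValidationError("no genes detected at all timepoints")
    sub = abundance.loc[eligible]
    logm = np.log2(sub.to_numpy(dtype=float) + 1.0)
    mean = logm.mean(axis=1)
    sd = logm.std(axis=1, ddof=1)
    score = np.divide(sd, mean, out=np.full_like(sd, np.inf), where=mean > 0)
    df = pd.DataFrame({"gene_id": sub.index, "score": score})
    df = df.sort_values(["score", "gene_id"], kind="mergesort").reset_index(drop=True)
    df["rank"] = np.arange(1, len(df) + 1)
    return df.head(top_n).set_index("gene_id")
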