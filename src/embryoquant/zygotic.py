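"""Zygotic-early gene identification and corroborating signals.

A gene undetected in the first two hourly samples but detected later must
have been transcribed from the zygotic genome (or polyadenylated after
fertilisation, which this assay cannot distinguish).  Two orthogonal
signals corroborate the call: zygotic genes carry a higher fraction of
intron-containing (nascent) reads, and they tend to be shorter with fewer
exons than the maternal background.
"""
from __future__ import annotations

import dataclasses
import itertools
import math
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io import GeneModelSet, SampleMeta, ValidationError

#: Latest timepoint (h) still considered "early" (pre-activation).
EARLY_CUTOFF_HOURS = 2.0


def identify_zygotic_early(
    detected: pd.DataFrame,
    samples: Sequence[SampleMeta],
    early_cutoff_hours: float = EARLY_CUTOFF_HOURS,
) -> list[str]:
    """Genes undetected at every sample <= 2 h but detected at one later.

    Raises
    ------
    ValidationError
        When there is no early (<= cutoff) or no late sample to compare.
    """
    tps = np.asarray([s.timepoint for s in samples], dtype=float)
    if list(detected.columns) != [s.sample_id for s in samples]:
        raise ValidationError("detected columns must match sample metadata")
    early = tps <= early_cutoff_hours
    late = ~early
    if not early.any():
        raise ValidationError(f"no samples at <= {early_cutoff_hours} h")
    if not late.any():
        raise ValidationError(f"no samples after {early_cutoff_hours} h")
    det = detected.to_numpy(dtype=bool)
    keep = (~det[:, early]).all(axis=1) & det[:, late].any(axis=1)
    return list(detected.index[keep])


def intron_read_fraction(
    exonic: pd.DataFrame,
    intronic: pd.DataFrame,
    detected: pd.DataFrame | None = None,
    models: GeneModelSet | None = None,
) -> pd.DataFrame:
    """Pooled intron-read fraction per gene.

    Counts are pooled over the samples where the gene is detected (all
    samples when no detection matrix is given); the fraction is
    intronic / (exonic + intronic), NaN when both pooled counts are zero.
    Genes without annotated introns are flagged not applicable.
    """
    if (exonic.to_numpy() < 0).any() or (intronic.to_numpy() < 0).any():
        raise ValidationError("negative read counts")
    intronic = intronic.reindex(index=exonic.index, columns=exonic.columns).fillna(0)
    if detected is not None:
        mask = detected.reindex(index=exonic.index, columns=exonic.columns)
        mask = mask.fillna(False).astype(bool)
        ex = (exonic * mask).sum(axis=1)
        intr = (intronic * mask).sum(axis=1)
    else:
        ex = exonic.sum(axis=1)
        intr = intronic.sum(axis=1)
    total = ex + intr
    frac = intr.astype(float).divide(total.astype(float))
    frac[total == 0] = np.nan
    applicable = pd.Series(True, index=exonic.index)
    if models is not None:
        applicable = pd.Series(
            [g in models and len(models[g].introns) > 0 for g in exonic.index],
            index=exonic.index,
        )
    return pd.DataFrame(
        {
            "exonic_reads": ex,
            "intronic_reads": intr,
            "intron_fraction": frac,
            "applicable": applicable,
        }
    )


# ---------------------------------------------------------------------------
# Rank-sum test
# ---------------------------------------------------------------------------

@dataclasses.dataclass(frozen=True)
class RankSumResult:
    """Mann-Whitney U with one- and two-sided p-values.

    ``u`` is the U statistic of group a; ``p_less``/``p_greater`` are the
    one-sided tails (a stochastically smaller / larger than b); ``p_one``
    is the smaller tail and ``p_two`` = min(1, 2 * p_one).
    """

    u: float
    u_other: float
    p_less: float
    p_greater: float
    p_one: float
    p_two: float
    method: str


def _exact_tail_p(u: float, n_a: int, n_b: int) -> tuple[float, float]:
    """Exact permutation tails of U by enumerating all rank assignments."""
    n = n_a + n_b
    offset = n_a * (n_a + 1) / 2.0
    us = np.fromiter(
        (sum(c) - offset for c in itertools.combinations(range(1, n + 1), n_a)),
        dtype=float,
        count=math.comb(n, n_a),
    )
    return float(np.mean(us <= u)), float(np.mean(us >= u))


def _normal_tail_p(
    u: float, n_a: int, n_b: int, pooled: np.ndarray
) -> tuple[float, float]:
    """Normal approximation with tie correction and continuity correction."""
    n = n_a + n_b
    mu = n_a * n_b / 2.0
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(tie_counts**3 - tie_counts))
    var = n_a * n_b / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    if var <= 0:
        return 0.5, 0.5
    sd = math.sqrt(var)
    p_less = stats.norm.cdf((u - mu + 0.5) / sd)
    p_greater = stats.norm.sf((u - mu - 0.5) / sd)
    return float(p_less), float(p_greater)


def rank_sum_compare(
    group_a: Sequence[float],
    group_b: Sequence[float],
    exact_max_n: int = 10,
) -> RankSumResult:
    """Mann-Whitney rank-sum comparison of two groups.

    Average ranks for ties.  p-values come from exact enumeration of all
    rank assignments when both groups have <= ``exact_max_n`` observations
    and no ties occur, otherwise from a normal approximation with tie and
    continuity corrections.
    """
    a = np.asarray(list(group_a), dtype=float)
    b = np.asarray(list(group_b), dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValidationError("both groups must be non-empty")
    pooled = np.concatenate([a, b])
    ranks = stats.rankdata(pooled)
    u_a = float(ranks[: len(a)].sum() - len(a) * (len(a) + 1) / 2.0)
    u_b = len(a) * len(b) - u_a
    has_ties = len(np.unique(pooled)) < len(pooled)
    if len(a) <= exact_max_n and len(b) <= exact_max_n and not has_ties:
        p_less, p_greater = _exact_tail_p(u_a, len(a), len(b))
        method = "exact"
    else:
        p_less, p_greater = _normal_tail_p(u_a, len(a), len(b), pooled)
        method = "normal"
    p_one = min(p_less, p_greater)
    return RankSumResult(
        u=u_a,
        u_other=u_b,
        p_less=p_less,
        p_greater=p_greater,
        p_one=p_one,
        p_two=min(1.0, 2.0 * p_one),
        method=method,
    )


def architecture_compare(
    models: GeneModelSet,
    zygotic_set: Sequence[str],
    background_set: Sequence[str],
) -> pd.DataFrame:
    """Rank-sum comparison of transcript length and exon count.

    Tests whether the zygotic set is built from shorter, exon-poorer genes
    than the background.  Returns one row per attribute with group medians,
    U and one-/two-sided p-values.
    """
    if len(zygotic_set) == 0 or len(background_set) == 0:
        raise ValidationError("both gene sets must be non-empty")
    rows = []
    for attr, getter in (
        ("length", models.lengths),
        ("exon_count", models.exon_counts),
    ):
        za = getter(list(zygotic_set))
        bg = getter(list(background_set))
        res = rank_sum_compare(za.to_numpy(), bg.to_numpy())
        rows.append(
            {
                "attribute": attr,
                "median_zygotic": float(za.median()),
                "median_background": float(bg.median()),
                "u": res.u,
                "p_less": res.p_less,
                "p_one": res.p_one,
                "p_two": res.p_two,
                "method": res.method,
            }
        )
    return pd.DataFrame(rows).set_index("attribute")
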