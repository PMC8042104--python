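"""Relative expression (RPG10K) and the detection rule.

RPG10K — reads per gene per 10,000 aligned reads — is the depth
normalisation used for long-read counts: rho_ij = c_ij / N_j * 1e4, where
N_j is the total number of aligned reads in sample j *including* spike-in
reads, so gene and spike relative scales share one denominator.
"""
from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from .io import CountMatrix, SampleMeta, ValidationError

#: Reads-per-10,000 scale of the relative unit.
RPG10K_SCALE = 1e4

#: Default sensitivity floor in RPG10K units (~2 reads at 2e6 aligned reads).
DEFAULT_DETECTION_THRESHOLD = 0.01


@dataclasses.dataclass
class RelativeExpressionMatrix:
    """RPG10K values for genes (rho_ij) and spike-ins (r_qj).

    ``values`` holds all features; per-sample totals N_j are kept for
    provenance.  Rows sum to exactly 10,000 in every sample.
    """

    values: pd.DataFrame
    totals: pd.Series
    spike_ids: tuple[str, ...]
    samples: tuple[SampleMeta, ...]

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def gene_ids(self) -> list[str]:
        spikes = set(self.spike_ids)
        return [f for f in self.values.index if f not in spikes]

    def genes(self) -> pd.DataFrame:
        return self.values.loc[self.gene_ids]

    def spikes(self) -> pd.DataFrame:
        return self.values.loc[list(self.spike_ids)]


def compute_rpg10k(counts: CountMatrix) -> RelativeExpressionMatrix:
    """Normalise counts to reads per gene per 10,000 aligned reads.

    Raises
    ------
    ValidationError
        If any sample has zero aligned reads (named in the message).
    """
    totals = counts.column_sums
    zero = totals.index[totals == 0].tolist()
    if zero:
        raise ValidationError(f"samples with zero total reads: {zero}")
    rho = counts.counts / totals.astype(float) * RPG10K_SCALE
    return RelativeExpressionMatrix(
        values=rho,
        totals=totals.astype(int),
        spike_ids=tuple(counts.spike_ids),
        samples=counts.samples,
    )


def detection_call(
    rel: RelativeExpressionMatrix,
    threshold_rpg10k: float = DEFAULT_DETECTION_THRESHOLD,
) -> pd.DataFrame:
    """Boolean gene x sample matrix: detected iff rho_ij >= threshold.

    The boundary is closed so a gene sitting exactly at the sensitivity
    floor counts as detected.  Spike-ins are excluded from the result.
    """
    if threshold_rpg10k <= 0:
        raise ValidationError("detection threshold must be positive")
    return rel.genes() >= threshold_rpg10k
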