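"""Run-level summary assembling the headline readouts of a full analysis."""
from __future__ import annotations

import dataclasses
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .calibration import AbsoluteQuantResults, round_sig
from .io import ValidationError
from .motif import SetEnrichment

MISSING = "missing"


@dataclasses.dataclass
class RunSummary:
    """Per-sample totals plus global group/zygotic/motif statistics."""

    per_sample: pd.DataFrame
    global_stats: dict

    def to_text(self) -> str:
        """Plain-text narrative; values rounded to 3 significant figures."""

        def fmt(x):
            if isinstance(x, (int, np.integer)):
                return str(int(x))
            if isinstance(x, float):
                return f"{round_sig(x, 3):g}"
            return str(x)

        lines = ["Run summary", "=" * 40]
        for sid, row in self.per_sample.iterrows():
            parts = [f"{sid}:"]
            for col in self.per_sample.columns:
                parts.append(f"{col}={fmt(row[col])}")
            lines.append("  " + " ".join(parts))
        lines.append("-" * 40)
        for key, val in self.global_stats.items():
            lines.append(f"{key}: {fmt(val)}")
        return "\n".join(lines)


def build_summary(
    results: AbsoluteQuantResults,
    labels: pd.Series | None = None,
    zygotic_genes: Sequence[str] | None = None,
    enrichment: SetEnrichment | None = None,
    spearman: pd.Series | None = None,
    mass_totals: pd.Series | None = None,
) -> RunSummary:
    """Aggregate stage outputs into one deterministic summary.

    Optional stages that were not run are reported as flagged gaps rather
    than errors; inconsistent sample universes are errors.
    """
    sample_ids = results.absolute.sample_ids
    per_sample = pd.DataFrame(index=pd.Index(sample_ids, name="sample_id"))
    per_sample["total_transcripts"] = results.total_transcripts_per_embryo()
    per_sample["detection_limit"] = results.detection_limits
    if mass_totals is not None:
        if list(mass_totals.index) != sample_ids:
            raise ValidationError("mass totals sample set mismatch")
        per_sample["total_ng"] = mass_totals
    else:
        per_sample["total_ng"] = np.nan

    gene_ids = list(results.absolute.genes.index)
    stats: dict = {"n_genes": len(gene_ids), "n_samples": len(sample_ids)}
    if labels is not None:
        if sorted(labels.index) != sorted(gene_ids):
            raise ValidationError("label gene set mismatch")
        counts = labels.value_counts().to_dict()
        stats["group_counts"] = counts
        if sum(counts.values()) != len(gene_ids):
            raise ValidationError("group counts do not sum to gene count")
    else:
        stats["group_counts"] = MISSING
    stats["zygotic_early_count"] = (
        len(zygotic_genes) if zygotic_genes is not None else MISSING
    )
    if enrichment is not None:
        stats["motif_odds_ratio"] = enrichment.odds_ratio
        stats["motif_p_value"] = enrichment.p_value
    else:
        stats["motif_odds_ratio"] = MISSING
        stats["motif_p_value"] = MISSING
    if spearman is not None:
        stats["successive_spearman_min"] = float(spearman.min())
    else:
        stats["successive_spearman_min"] = MISSING
    return RunSummary(per_sample=per_sample, global_stats=stats)
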