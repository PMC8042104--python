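"""Spike-in calibrated absolute quantification.

The calibration model regresses the relative abundance r_qj (RPG10K) of
each spike-in species q against its known molecule count per embryo S_q in
an intercept-only Poisson regression with log link and offset log(S_q):

    E[r_qj] = exp(beta_j + log S_q)

The maximum-likelihood intercept has the closed form

    beta_j = log( sum_q r_qj / sum_q S_q ),

the unique root of the score equation  sum_q r_qj - e^beta sum_q S_q = 0.
Zero-count spikes stay in both sums.  The conversion to transcripts per
embryo is  m_ij = rho_ij * e^(-beta_j);  e^(-beta_j) is therefore the number
of transcripts per embryo represented by one RPG10K unit.

:class:`AbsoluteQuantModel` wraps the full counts -> transcripts-per-embryo
pipeline in a model/results pair; the free functions below are the
individual steps.
"""
from __future__ import annotations

import dataclasses
import math
from typing import Sequence

import numpy as np
import pandas as pd

from .io import AVOGADRO, CountMatrix, GeneModelSet, SpikeInTable, ValidationError
from .relative import (
    DEFAULT_DETECTION_THRESHOLD,
    RelativeExpressionMatrix,
    compute_rpg10k,
    detection_call,
)

#: Average molar mass of one RNA nucleotide residue (g/mol), single-stranded
#: RNA convention, plus the 159 g/mol 5'-triphosphate terminal correction.
MW_PER_NT = 320.5
MW_TERMINAL = 159.0


@dataclasses.dataclass
class ConversionFactors:
    """Per-sample calibration: intercept beta_j and scale e^(-beta_j).

    ``scale`` is transcripts per embryo per RPG10K unit.
    """

    table: pd.DataFrame  # index: sample_id; columns: beta, scale, n_spikes_used

    @property
    def beta(self) -> pd.Series:
        return self.table["beta"]

    @property
    def scale(self) -> pd.Series:
        return self.table["scale"]

    @property
    def sample_ids(self) -> list[str]:
        return list(self.table.index)


@dataclasses.dataclass
class AbsoluteExpressionMatrix:
    """Transcripts per embryo, m_ij, for genes; spike rows kept for QC."""

    genes: pd.DataFrame
    spikes: pd.DataFrame
    factors: ConversionFactors
    detection_limits: pd.Series
    threshold_rpg10k: float

    @property
    def sample_ids(self) -> list[str]:
        return list(self.genes.columns)

    def total_per_sample(self) -> pd.Series:
        return self.genes.sum(axis=0)


def fit_conversion_factor(
    spike_rel: pd.DataFrame, spikes: SpikeInTable
) -> ConversionFactors:
    """Closed-form Poisson-offset MLE of the conversion factor per sample.

    Parameters
    ----------
    spike_rel
        Spike-in rows of an RPG10K matrix (spike x sample).
    spikes
        Known molecules per embryo-equivalent for each spike species.

    Raises
    ------
    ValidationError
        If a spike in the matrix is absent from the table, or a sample has
        no spike-in signal at all.
    """
    missing = [s for s in spike_rel.index if s not in spikes]
    if missing:
        raise ValidationError(f"spike IDs absent from spike-in table: {missing}")
    if spike_rel.shape[0] == 0:
        raise ValidationError("no spike-in rows in relative matrix")
    s_q = np.array([spikes[q] for q in spike_rel.index], dtype=float)
    total_s = s_q.sum()
    rows = {}
    for sample in spike_rel.columns:
        r = spike_rel[sample].to_numpy(dtype=float)
        total_r = r.sum()
        if total_r <= 0:
            raise ValidationError(f"no spike-in signal in sample {sample!r}")
        beta = math.log(total_r / total_s)
        rows[sample] = {
            "beta": beta,
            "scale": math.exp(-beta),
            "n_spikes_used": len(r),
        }
    table = pd.DataFrame.from_dict(rows, orient="index")
    table["n_spikes_used"] = table["n_spikes_used"].astype(int)
    table.index.name = "sample_id"
    return ConversionFactors(table)


def to_absolute(
    rel: RelativeExpressionMatrix,
    cf: ConversionFactors,
    threshold_rpg10k: float = DEFAULT_DETECTION_THRESHOLD,
) -> AbsoluteExpressionMatrix:
    """Convert RPG10K to transcripts per embryo: m_ij = rho_ij * e^(-beta_j)."""
    missing = [s for s in rel.sample_ids if s not in cf.table.index]
    if missing:
        raise ValidationError(f"no conversion factor for samples: {missing}")
    scale = cf.scale.reindex(rel.sample_ids)
    genes = rel.genes() * scale
    spikes = rel.spikes() * scale
    limits = detection_limit_transcripts(cf, threshold_rpg10k)[0].reindex(
        rel.sample_ids
    )
    return AbsoluteExpressionMatrix(
        genes=genes,
        spikes=spikes,
        factors=cf,
        detection_limits=limits,
        threshold_rpg10k=threshold_rpg10k,
    )


def detection_limit_transcripts(
    cf: ConversionFactors,
    threshold_rpg10k: float = DEFAULT_DETECTION_THRESHOLD,
) -> tuple[pd.Series, float]:
    """Per-sample detection limit in transcripts per embryo, and its mean.

    The limit is the absolute abundance at the RPG10K sensitivity floor:
    limit_j = threshold * e^(-beta_j).  The mean is unweighted over samples.
    """
    if threshold_rpg10k < 0:
        raise ValidationError("threshold must be nonnegative")
    limits = threshold_rpg10k * cf.scale
    return limits.rename("detection_limit"), float(limits.mean())


def rna_molecular_weight(length_nt: float | np.ndarray) -> float | np.ndarray:
    """Molar mass (g/mol) of a single-stranded RNA of the given length."""
    return MW_PER_NT * np.asarray(length_nt, dtype=float) + MW_TERMINAL


def transcripts_to_mass(
    abs_expr: AbsoluteExpressionMatrix,
    models: GeneModelSet,
    permissive: bool = False,
) -> tuple[pd.DataFrame, pd.Series]:
    """Convert transcript copies to nanograms per embryo.

    mass_ij [ng] = m_ij * MW(L_i) / N_A * 1e9 with MW(L) = 320.5 L + 159.

    Returns the per-gene mass matrix and the per-sample totals.  Genes
    missing from the models raise an error unless ``permissive`` is set, in
    which case they are skipped with a warning.
    """
    gene_ids = list(abs_expr.genes.index)
    missing = [g for g in gene_ids if g not in models]
    if missing and not permissive:
        raise ValidationError(f"genes missing from models: {missing}")
    if missing:
        import warnings

        warnings.warn(f"skipping {len(missing)} genes missing from models")
        gene_ids = [g for g in gene_ids if g not in set(missing)]
    lengths = models.lengths(gene_ids)
    mw = rna_molecular_weight(lengths.to_numpy())
    grams_per_molecule = mw / AVOGADRO
    mass = abs_expr.genes.loc[gene_ids].mul(grams_per_molecule * 1e9, axis=0)
    return mass, mass.sum(axis=0).rename("total_ng_per_embryo")


def round_sig(x: float, sig: int = 3) -> float:
    """Round to ``sig`` significant figures (0 stays 0)."""
    if x == 0 or not math.isfinite(x):
        return x
    return round(x, -int(math.floor(math.log10(abs(x)))) + (sig - 1))


@dataclasses.dataclass(frozen=True)
class VolumeScaledMass:
    scaled_mass_ng: float
    volume_ratio: float
    #: values rounded to 3 significant figures, for reporting
    scaled_mass_ng_3sig: float
    volume_ratio_3sig: float


def volume_scaled_mass(
    mass_ng: float, source_volume_mm3: float, target_volume_mm3: float
) -> VolumeScaledMass:
    """Scale a per-embryo mRNA mass between embryos of different volumes.

    Cell volume and RNA content scale together, so a per-embryo mass
    measured in an embryo of ``source_volume_mm3`` is compared with a
    larger/smaller species by multiplying with the volume ratio
    target/source.
    """
    if source_volume_mm3 <= 0 or target_volume_mm3 <= 0:
        raise ValidationError("volumes must be positive")
    ratio = target_volume_mm3 / source_volume_mm3
    scaled = mass_ng * ratio
    return VolumeScaledMass(
        scaled_mass_ng=scaled,
        volume_ratio=ratio,
        scaled_mass_ng_3sig=round_sig(scaled, 3),
        volume_ratio_3sig=round_sig(ratio, 3),
    )


# ---------------------------------------------------------------------------
# Model / Results surface
# ---------------------------------------------------------------------------

class AbsoluteQuantModel:
    """Spike-in calibration model for a count matrix.

    Parameters
    ----------
    counts
        Gene + spike-in read counts with ordered sample metadata.
    spikes
        Known molecules per embryo for every spike species in the counts.
    gene_models
        Optional gene models; enables the mass conversion in the results.
    threshold_rpg10k
        Sensitivity floor used for detection calls and detection limits.
    """

    def __init__(
        self,
        counts: CountMatrix,
        spikes: SpikeInTable,
        gene_models: GeneModelSet | None = None,
        threshold_rpg10k: float = DEFAULT_DETECTION_THRESHOLD,
    ) -> None:
        self.counts = counts
        self.spikes = spikes
        self.gene_models = gene_models
        self.threshold_rpg10k = threshold_rpg10k

    @classmethod
    def from_files(
        cls,
        counts_path,
        spikes_path,
        models_path=None,
        samples_path=None,
        threshold_rpg10k: float = DEFAULT_DETECTION_THRESHOLD,
    ) -> "AbsoluteQuantModel":
        from . import io as _io

        samples = (
            _io.read_sample_metadata(samples_path) if samples_path else None
        )
        counts = _io.read_count_matrix(counts_path, samples=samples)
        spikes = _io.read_spikein_table(spikes_path)
        models = _io.read_gene_models(models_path) if models_path else None
        return cls(counts, spikes, models, threshold_rpg10k)

    def fit(self) -> "AbsoluteQuantResults":
        rel = compute_rpg10k(self.counts)
        cf = fit_conversion_factor(rel.spikes(), self.spikes)
        absolute = to_absolute(rel, cf, self.threshold_rpg10k)
        detected = detection_call(rel, self.threshold_rpg10k)
        return AbsoluteQuantResults(self, rel, cf, absolute, detected)


class AbsoluteQuantResults:
    """Fitted calibration: factors, absolute abundances, detection calls."""

    def __init__(
        self,
        model: AbsoluteQuantModel,
        relative: RelativeExpressionMatrix,
        factors: ConversionFactors,
        absolute: AbsoluteExpressionMatrix,
        detected: pd.DataFrame,
    ) -> None:
        self.model = model
        self.relative = relative
        self.conversion_factors = factors
        self.absolute = absolute
        self.detected = detected

    @property
    def detection_limits(self) -> pd.Series:
        return self.absolute.detection_limits

    @property
    def mean_detection_limit(self) -> float:
        return float(self.absolute.detection_limits.mean())

    def total_transcripts_per_embryo(self) -> pd.Series:
        return self.absolute.total_per_sample().rename("total_transcripts")

    def mass_per_embryo(
        self, models: GeneModelSet | None = None, permissive: bool = False
    ) -> tuple[pd.DataFrame, pd.Series]:
        models = models or self.model.gene_models
        if models is None:
            raise ValidationError("gene models required for mass conversion")
        return transcripts_to_mass(self.absolute, models, permissive=permissive)

    def summary(self) -> str:
        """Per-sample calibration summary table as plain text."""
        cf = self.conversion_factors.table
        totals = self.total_transcripts_per_embryo()
        n_det = self.detected.sum(axis=0)
        lines = [
            "Spike-in calibrated absolute quantification",
            "=" * 68,
            f"{'sample':<10}{'t(h)':>6}{'beta':>10}{'scale':>12}"
            f"{'limit':>10}{'detected':>10}{'total':>12}",
            "-" * 68,
        ]
        for s in self.relative.samples:
            sid = s.sample_id
            lines.append(
                f"{sid:<10}{s.timepoint:>6.1f}{cf.loc[sid, 'beta']:>10.4f}"
                f"{cf.loc[sid, 'scale']:>12.4g}"
                f"{self.detection_limits[sid]:>10.4g}"
                f"{int(n_det[sid]):>10d}{totals[sid]:>12.4g}"
            )
        lines.append("-" * 68)
        lines.append(
            f"mean detection limit: {round_sig(self.mean_detection_limit, 4)}"
            " transcripts/embryo"
            f"   (threshold {self.model.threshold_rpg10k} RPG10K)"
        )
        return "\n".join(lines)
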