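"""Synthetic embryo time-course experiments with known ground truth.

The generator emulates the statistical structure of a spike-in calibrated
early-embryo RNA-seq time course: six hourly samples, a maternal transcript
pool whose global poly(A) content dips at 2 h and rebounds at 3 h, zygotic
genes first detectable at 4-6 h with shorter transcripts, fewer exons and a
higher intron-read fraction, 92 spike-in species spanning five orders of
magnitude added per embryo, Poisson read sampling at fixed depth, and
promoters in which the CAGGTAG heptamer is planted close to the TSS of a
fraction of zygotic genes.

Generative model (all randomness from a single seed):

1. baseline per-embryo abundance b_i ~ LogNormal(meanlog 7, sdlog 1.5);
2. trajectories over timepoints t with global scale g_t:
   maternal    m* = b * g_t * delta^t,   delta ~ U[0.6, 0.95]
   persistent  m* = b * g_t
   transient   m* = b * g_t * (1 + A exp(-(t - t_peak)^2 / 2 sigma^2)),
               A ~ U[4, 20], sigma = 0.5, t_peak in {2..5}
   zygotic     m* = 0 before onset, then b * (t - onset + 1),
               onset in {4, 5, 6}
3. spike molecules S_q ~ log-uniform over [1e2, 1e7], identical across
   samples (per-embryo spiking);
4. reads c_kj ~ Poisson(d_j * w_kj / sum_k w_kj) with sampling weight
   w = m* * L^bias over genes and spikes (bias 0 by default: full-length
   reads count molecules, not nucleotides);
5. intronic reads ~ Binomial(c, pi_group) for genes with >= 2 exons;
6. transcript lengths LogNormal(log 2000, 0.5) (x0.6 for zygotic genes),
   exon counts 1 + Poisson(5) (non-zygotic) vs 1 + Poisson(1) (zygotic);
7. promoters: i.i.d. bases at 40% GC, one CAGGTAG planted uniformly within
   the 300 bp proximal window for a configured fraction of zygotic genes.
"""
from __future__ import annotations

import dataclasses
import json
import math
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import io as eqio
from .io import (
    CountMatrix,
    GeneModel,
    GeneModelSet,
    SampleMeta,
    SpikeInTable,
    ValidationError,
)

GROUPS = ("maternal_down", "persistent", "transient", "zygotic")

#: Global per-timepoint scale of the maternal pool, a stylised rescaling of
#: the measured per-embryo mRNA-mass trajectory (dip at 2 h, rebound at 3 h,
#: slow decline to 6 h).  Not fitted.
DEFAULT_GLOBAL_SCALE = (1.00, 0.49, 1.18, 1.05, 0.95, 0.74)


def _as_mapping(obj) -> dict:
    return dict(obj) if not isinstance(obj, dict) else obj


@dataclasses.dataclass
class SimulationConfig:
    """Study-condition defaults for the synthetic experiment."""

    n_genes: int = 2000
    group_proportions: Mapping[str, float] = dataclasses.field(
        default_factory=lambda: {
            "maternal_down": 0.50,
            "persistent": 0.25,
            "transient": 0.15,
            "zygotic": 0.10,
        }
    )
    timepoints: tuple[float, ...] = (1.0, 2.0, 3.0, 4.0, 5.0, 6.0)
    global_scale: tuple[float, ...] = DEFAULT_GLOBAL_SCALE
    n_spikes: int = 92
    spike_range: tuple[float, float] = (1e2, 1e7)
    depth: float = 2e6
    zygotic_onsets: tuple[float, ...] = (4.0, 5.0, 6.0)
    intron_read_prob: Mapping[str, float] = dataclasses.field(
        default_factory=lambda: {
            "maternal_down": 0.02,
            "persistent": 0.02,
            "transient": 0.02,
            "zygotic": 0.15,
        }
    )
    motif_plant_rate: float = 0.5
    promoter_length: int = 1000
    proximal_window: int = 300
    background_gc: float = 0.40
    baseline_meanlog: float = 7.0
    baseline_sdlog: float = 1.5
    decay_range: tuple[float, float] = (0.6, 0.95)
    transient_amp_range: tuple[float, float] = (4.0, 20.0)
    transient_sigma: float = 0.5
    length_meanlog: float = math.log(2000.0)
    length_sdlog: float = 0.5
    zygotic_length_factor: float = 0.6
    exon_rate_nonzygotic: float = 5.0
    exon_rate_zygotic: float = 1.0
    intron_length: int = 200
    length_bias_exponent: float = 0.0
    spike_jitter_sdlog: float = 0.0  # per-sample lognormal misspecification
    embryos_pooled: int = 100
    seed: int = 0

    def validate(self) -> None:
        props = _as_mapping(self.group_proportions)
        if set(props) != set(GROUPS):
            raise ValidationError(f"group proportions must cover {GROUPS}")
        if abs(sum(props.values()) - 1.0) > 1e-9:
            raise ValidationError("group proportions must sum to 1")
        if len(self.global_scale) != len(self.timepoints):
            raise ValidationError("global_scale must match timepoints")
        if min(self.global_scale) <= 0 or self.depth <= 0:
            raise ValidationError("scales and depth must be positive")
        if not 0.0 <= self.motif_plant_rate <= 1.0:
            raise ValidationError("motif plant rate must lie in [0, 1]")
        if min(self.spike_range) <= 0:
            raise ValidationError("spike concentration range must be positive")
        if any(p < 0 or p > 1 for p in _as_mapping(self.intron_read_prob).values()):
            raise ValidationError("intron read probabilities must lie in [0, 1]")


@dataclasses.dataclass
class GroundTruth:
    """Per-gene truth labels and per-sample true calibration."""

    genes: pd.DataFrame  # group, baseline, length, exon_count, onset, motif_planted
    trajectories: pd.DataFrame  # true transcripts per embryo, gene x sample
    true_scale: pd.Series  # molecules per RPG10K unit, per sample
    spike_molecules: pd.Series


@dataclasses.dataclass
class SimulatedExperiment:
    counts: CountMatrix
    spikes: SpikeInTable
    models: GeneModelSet
    promoters: dict[str, str]
    intron_counts: pd.DataFrame  # intronic reads, gene x sample
    truth: GroundTruth
    config: SimulationConfig


def _group_sizes(n: int, proportions: Mapping[str, float]) -> dict[str, int]:
    """Largest-remainder apportionment of n genes over the groups."""
    exact = {g: proportions[g] * n for g in GROUPS}
    sizes = {g: int(math.floor(v)) for g, v in exact.items()}
    short = n - sum(sizes.values())
    order = sorted(GROUPS, key=lambda g: exact[g] - sizes[g], reverse=True)
    for g in order[:short]:
        sizes[g] += 1
    return sizes


def random_promoters(
    rng: np.random.Generator,
    n: int,
    length: int = 1000,
    gc: float = 0.40,
    plant_rate: float = 0.0,
    proximal_window: int = 300,
    motif: str = "CAGGTAG",
) -> tuple[list[str], np.ndarray]:
    """i.i.d. background promoters, optionally with one planted motif.

    The motif is planted, for a ``plant_rate`` fraction of promoters, at a
    start position uniform over the proximal window (the ``proximal_window``
    bases nearest the TSS, i.e. the end of the sequence), fully inside it.
    Returns the sequences and a boolean planted flag per promoter.
    """
    at = (1.0 - gc) / 2.0
    gcp = gc / 2.0
    bases = np.array(list("ACGT"))
    mat = rng.choice(4, size=(n, length), p=[at, gcp, gcp, at])
    planted = rng.random(n) < plant_rate
    lo = length - proximal_window  # 0-based start range [lo, length - len(motif)]
    hi = length - len(motif)
    if hi < lo:
        raise ValidationError("proximal window shorter than motif")
    motif_idx = np.array([("ACGT").index(c) for c in motif])
    for i in np.nonzero(planted)[0]:
        start = int(rng.integers(lo, hi + 1))
        mat[i, start : start + len(motif)] = motif_idx
    seqs = ["".join(row) for row in bases[mat]]
    return seqs, planted


def _build_gene_models(
    gene_ids: Sequence[str],
    lengths: np.ndarray,
    exon_counts: np.ndarray,
    strands: np.ndarray,
    intron_length: int,
    seqid: str = "chr1",
) -> GeneModelSet:
    models = []
    cursor = 1500  # leave room upstream of the first promoter
    for gid, L, E, strand in zip(gene_ids, lengths, exon_counts, strands):
        L, E = int(L), int(E)
        E = max(1, min(E, L))  # at least 1 bp per exon
        sizes = [L // E] * E
        sizes[0] += L - sum(sizes)
        exons = []
        pos = cursor
        for s in sizes:
            exons.append((pos, pos + s - 1))
            pos += s + intron_length
        span_end = exons[-1][1]
        tss = cursor if strand == "+" else span_end
        models.append(
            GeneModel(
                gene_id=gid,
                seqid=seqid,
                strand=str(strand),
                tss=tss,
                transcript_id=f"{gid}.t1",
                length=L,
                exon_count=E,
                exons=tuple(exons),
                introns=eqio._introns_from_exons(exons),
            )
        )
        cursor = span_end + 2500
    return GeneModelSet(models)


def simulate_experiment(config: SimulationConfig | None = None) -> SimulatedExperiment:
    """Draw one synthetic experiment under the configured study conditions."""
    config = config or SimulationConfig()
    config.validate()
    rng = np.random.default_rng(config.seed)
    tps = np.asarray(config.timepoints, dtype=float)
    g = np.asarray(config.global_scale, dtype=float)
    n_t = len(tps)

    sizes = _group_sizes(config.n_genes, _as_mapping(config.group_proportions))
    groups = np.concatenate([[grp] * sizes[grp] for grp in GROUPS])
    n = config.n_genes
    width = max(4, len(str(n)))
    gene_ids = [f"gene{i + 1:0{width}d}" for i in range(n)]

    b = rng.lognormal(config.baseline_meanlog, config.baseline_sdlog, n)
    traj = np.zeros((n, n_t))
    onset = np.full(n, np.nan)
    for grp in GROUPS:
        idx = np.nonzero(groups == grp)[0]
        if len(idx) == 0:
            continue
        if grp == "maternal_down":
            delta = rng.uniform(*config.decay_range, len(idx))
            traj[idx] = b[idx, None] * g[None, :] * delta[:, None] ** tps[None, :]
        elif grp == "persistent":
            traj[idx] = b[idx, None] * g[None, :]
        elif grp == "transient":
            amp = rng.uniform(*config.transient_amp_range, len(idx))
            interior = tps[1:-1] if n_t > 2 else tps
            t_peak = rng.choice(interior, len(idx))
            bump = 1.0 + amp[:, None] * np.exp(
                -((tps[None, :] - t_peak[:, None]) ** 2)
                / (2.0 * config.transient_sigma**2)
            )
            traj[idx] = b[idx, None] * g[None, :] * bump
        else:  # zygotic
            on = rng.choice(np.asarray(config.zygotic_onsets, float), len(idx))
            onset[idx] = on
            ramp = np.clip(tps[None, :] - on[:, None] + 1.0, 0.0, None)
            ramp[tps[None, :] < on[:, None]] = 0.0
            traj[idx] = b[idx, None] * ramp

    # spike-in molecules, identical across samples unless jittered
    lo, hi = config.spike_range
    s_q = np.exp(rng.uniform(math.log(lo), math.log(hi), config.n_spikes))
    spike_ids = [f"ERCC-SIM-{i + 1:03d}" for i in range(config.n_spikes)]
    spike_table = SpikeInTable(pd.Series(s_q, index=spike_ids))
    spike_per_sample = np.tile(s_q[:, None], (1, n_t))
    if config.spike_jitter_sdlog > 0:
        spike_per_sample = spike_per_sample * rng.lognormal(
            0.0, config.spike_jitter_sdlog, spike_per_sample.shape
        )

    # transcript architecture
    lengths = rng.lognormal(config.length_meanlog, config.length_sdlog, n)
    zyg = groups == "zygotic"
    lengths[zyg] *= config.zygotic_length_factor
    lengths = np.maximum(np.round(lengths), 50).astype(int)
    exon_counts = np.where(
        zyg,
        1 + rng.poisson(config.exon_rate_zygotic, n),
        1 + rng.poisson(config.exon_rate_nonzygotic, n),
    )

    # Poisson read sampling
    bias = config.length_bias_exponent
    gene_w = traj * (lengths[:, None].astype(float) ** bias)
    spike_w = spike_per_sample * (1000.0**bias)
    total_w = gene_w.sum(axis=0) + spike_w.sum(axis=0)
    depth = float(config.depth)
    gene_counts = rng.poisson(depth * gene_w / total_w[None, :])
    spike_counts = rng.poisson(depth * spike_w / total_w[None, :])

    # intronic reads only where introns exist
    pi = np.array([_as_mapping(config.intron_read_prob)[grp] for grp in groups])
    pi = np.where(exon_counts >= 2, pi, 0.0)
    intronic = rng.binomial(gene_counts, pi[:, None])

    # promoters: one pass for all genes, planting only in zygotic promoters
    plant = np.where(zyg, config.motif_plant_rate, 0.0)
    at = (1.0 - config.background_gc) / 2.0
    gcp = config.background_gc / 2.0
    bases = np.array(list("ACGT"))
    L = config.promoter_length
    mat = rng.choice(4, size=(n, L), p=[at, gcp, gcp, at])
    planted = rng.random(n) < plant
    motif_idx = np.array([("ACGT").index(c) for c in "CAGGTAG"])
    lo_pos = L - config.proximal_window
    hi_pos = L - len(motif_idx)
    for i in np.nonzero(planted)[0]:
        start = int(rng.integers(lo_pos, hi_pos + 1))
        mat[i, start : start + len(motif_idx)] = motif_idx
    promoters = {gid: "".join(row) for gid, row in zip(gene_ids, bases[mat])}

    strands = rng.choice(np.array(["+", "-"]), n)
    models = _build_gene_models(
        gene_ids, lengths, exon_counts, strands, config.intron_length
    )
    # models may clamp exon counts for very short transcripts
    exon_counts = np.array([models[gid].exon_count for gid in gene_ids])

    samples = [
        SampleMeta(f"t{tp:g}h", float(tp), config.embryos_pooled) for tp in tps
    ]
    sample_ids = [s.sample_id for s in samples]
    counts_df = pd.DataFrame(
        np.vstack([gene_counts, spike_counts]),
        index=gene_ids + spike_ids,
        columns=sample_ids,
    )
    counts = CountMatrix(counts_df, samples=samples)

    truth = GroundTruth(
        genes=pd.DataFrame(
            {
                "group": groups,
                "baseline": b,
                "length": lengths,
                "exon_count": exon_counts,
                "onset": onset,
                "motif_planted": planted,
            },
            index=pd.Index(gene_ids, name="gene_id"),
        ),
        trajectories=pd.DataFrame(traj, index=gene_ids, columns=sample_ids),
        true_scale=pd.Series(total_w / 1e4, index=sample_ids, name="true_scale"),
        spike_molecules=pd.Series(s_q, index=spike_ids),
    )
    intron_counts = pd.DataFrame(intronic, index=gene_ids, columns=sample_ids)
    return SimulatedExperiment(
        counts=counts,
        spikes=spike_table,
        models=models,
        promoters=promoters,
        intron_counts=intron_counts,
        truth=truth,
        config=config,
    )


def write_fixture(sim: SimulatedExperiment, directory: str | Path) -> dict[str, Path]:
    """Write a simulated experiment as a self-contained file fixture.

    Produces counts.tsv, spikes.tsv, models.gff3, promoters.fa, truth.tsv
    and config.json, plus intron_counts.tsv and samples.tsv so the zygotic
    stage and sample metadata round-trip without the Python objects.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {name: directory / name for name in (
        "counts.tsv",
        "spikes.tsv",
        "models.gff3",
        "promoters.fa",
        "truth.tsv",
        "config.json",
        "intron_counts.tsv",
        "samples.tsv",
    )}
    tag = [f"embryoquant simulate seed={sim.config.seed}"]
    eqio.write_count_matrix(sim.counts, paths["counts.tsv"], comments=tag)
    eqio.write_spikein_table(sim.spikes, paths["spikes.tsv"], comments=tag)
    eqio.write_gene_models(sim.models, paths["models.gff3"])
    with open(paths["promoters.fa"], "w") as fh:
        for gid, seq in sim.promoters.items():
            fh.write(f">{gid}\n")
            for i in range(0, len(seq), 80):
                fh.write(seq[i : i + 80] + "\n")
    truth = sim.truth.genes.join(
        sim.truth.trajectories.rename(columns=lambda c: f"true_{c}")
    )
    eqio.write_table(truth, paths["truth.tsv"], comments=tag)
    cfg = dataclasses.asdict(sim.config)
    cfg["group_proportions"] = _as_mapping(cfg["group_proportions"])
    cfg["intron_read_prob"] = _as_mapping(cfg["intron_read_prob"])
    with open(paths["config.json"], "w") as fh:
        json.dump(cfg, fh, indent=2, default=list)
    eqio.write_table(sim.intron_counts.rename_axis("gene_id"),
                     paths["intron_counts.tsv"], comments=tag)
    eqio.write_sample_metadata(sim.counts.samples, paths["samples.tsv"])
    return paths
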