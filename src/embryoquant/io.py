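"""Readers, writers and core containers.

Tabular data (count matrices, spike-in tables, sample metadata, result
tables) travel as TSV with ``#``-prefixed comment headers.  Gene models are
GFF3 (1-based, inclusive), parsed through :mod:`gffutils`.  Genomic and
promoter sequence is FASTA.

Feature IDs beginning with ``ERCC`` are treated as spike-in species;
everything else is a gene.
"""
from __future__ import annotations

import dataclasses
import logging
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import gffutils
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Avogadro's number (molecules per mole), 2019 SI exact value.
AVOGADRO = 6.02214076e23

#: Feature-ID prefix that marks spike-in species in a count matrix.
SPIKE_PREFIX = "ERCC"


class ValidationError(ValueError):
    """Input violates a structural invariant (duplicates, bounds, signs)."""


class ParseError(ValueError):
    """File content could not be interpreted."""


# ---------------------------------------------------------------------------
# Samples and counts
# ---------------------------------------------------------------------------

@dataclasses.dataclass(frozen=True)
class SampleMeta:
    """Metadata for one sequenced sample (one timepoint of pooled embryos)."""

    sample_id: str
    timepoint: float  # hours after egg laying
    embryos_pooled: int = 1
    total_aligned_reads: int = 0

    def __post_init__(self) -> None:
        if self.timepoint <= 0:
            raise ValidationError(
                f"sample {self.sample_id!r}: timepoint must be positive"
            )
        if self.embryos_pooled < 1:
            raise ValidationError(
                f"sample {self.sample_id!r}: embryos_pooled must be >= 1"
            )


class CountMatrix:
    """Raw aligned-read counts per feature (gene or spike-in) per sample.

    Parameters
    ----------
    counts
        Integer DataFrame, features in rows, samples in columns.
    samples
        Optional ordered sample metadata; when omitted, samples are assumed
        to be consecutive hourly timepoints.  ``total_aligned_reads`` is
        always (re)derived from the column sums.
    """

    def __init__(
        self,
        counts: pd.DataFrame,
        samples: Sequence[SampleMeta] | None = None,
        spike_prefix: str = SPIKE_PREFIX,
    ) -> None:
        if counts.shape[0] == 0:
            raise ParseError("no features")
        if counts.index.duplicated().any():
            dups = counts.index[counts.index.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate feature IDs: {dups}")
        arr = counts.to_numpy()
        if not np.issubdtype(arr.dtype, np.number):
            raise ParseError("counts must be numeric")
        if np.any(arr < 0) or np.any(arr != np.floor(arr)):
            raise ValidationError("counts must be nonnegative integers")
        self.counts = counts.astype(np.int64)
        self.counts.index = self.counts.index.astype(str)
        self.spike_prefix = spike_prefix

        totals = self.counts.sum(axis=0)
        if samples is None:
            samples = [
                SampleMeta(str(c), float(i + 1)) for i, c in enumerate(counts.columns)
            ]
        if [s.sample_id for s in samples] != [str(c) for c in counts.columns]:
            raise ValidationError("sample metadata does not match count columns")
        tps = [s.timepoint for s in samples]
        if any(b <= a for a, b in zip(tps, tps[1:])):
            raise ValidationError("sample timepoints must be strictly increasing")
        self.samples: tuple[SampleMeta, ...] = tuple(
            dataclasses.replace(s, total_aligned_reads=int(totals[s.sample_id]))
            for s in samples
        )

    # -- views --------------------------------------------------------------

    @property
    def features(self) -> list[str]:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> list[str]:
        return [s.sample_id for s in self.samples]

    @property
    def timepoints(self) -> np.ndarray:
        return np.asarray([s.timepoint for s in self.samples], dtype=float)

    @property
    def spike_ids(self) -> list[str]:
        return [f for f in self.counts.index if f.startswith(self.spike_prefix)]

    @property
    def gene_ids(self) -> list[str]:
        return [f for f in self.counts.index if not f.startswith(self.spike_prefix)]

    @property
    def column_sums(self) -> pd.Series:
        return self.counts.sum(axis=0)

    def gene_counts(self) -> pd.DataFrame:
        return self.counts.loc[self.gene_ids]

    def spike_counts(self) -> pd.DataFrame:
        return self.counts.loc[self.spike_ids]

    def __eq__(self, other: object) -> bool:
        return (
            isinstance(other, CountMatrix)
            and self.counts.equals(other.counts)
            and self.samples == other.samples
        )


def read_count_matrix(
    path: str | Path, samples: Sequence[SampleMeta] | None = None
) -> CountMatrix:
    """Read a feature x sample TSV of integer counts.

    The first column holds feature IDs, the header row sample IDs.  Comment
    lines starting with ``#`` are skipped.  Non-integer cells raise
    :class:`ParseError` naming the offending feature and sample.
    """
    raw = pd.read_csv(path, sep="\t", comment="#", index_col=0, dtype=str)
    if raw.shape[0] == 0:
        raise ParseError(f"{path}: no features")
    parsed = {}
    for col in raw.columns:
        num = pd.to_numeric(raw[col], errors="coerce")
        bad = num.isna() | (num % 1 != 0)
        if bad.any():
            feat = raw.index[bad.to_numpy().nonzero()[0][0]]
            raise ParseError(
                f"{path}: non-integer count at feature {feat!r}, sample {col!r}"
            )
        parsed[col] = num.astype(np.int64)
    df = pd.DataFrame(parsed, index=raw.index.astype(str))
    return CountMatrix(df, samples=samples)


def write_count_matrix(
    cm: CountMatrix, path: str | Path, comments: Iterable[str] = ()
) -> None:
    with open(path, "w") as fh:
        for line in comments:
            fh.write(f"# {line}\n")
        out = cm.counts.copy()
        out.index.name = "feature_id"
        out.to_csv(fh, sep="\t")


def read_sample_metadata(path: str | Path) -> list[SampleMeta]:
    df = pd.read_csv(path, sep="\t", comment="#")
    required = {"sample_id", "timepoint", "embryos_pooled"}
    if not required.issubset(df.columns):
        raise ParseError(f"{path}: expected columns {sorted(required)}")
    return [
        SampleMeta(str(r.sample_id), float(r.timepoint), int(r.embryos_pooled))
        for r in df.itertuples()
    ]


def write_sample_metadata(samples: Sequence[SampleMeta], path: str | Path) -> None:
    df = pd.DataFrame(
        {
            "sample_id": [s.sample_id for s in samples],
            "timepoint": [s.timepoint for s in samples],
            "embryos_pooled": [s.embryos_pooled for s in samples],
            "total_aligned_reads": [s.total_aligned_reads for s in samples],
        }
    )
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Spike-in table
# ---------------------------------------------------------------------------

class SpikeInTable:
    """Known absolute abundance (molecules per embryo-equivalent) per spike.

    The same molecule numbers apply to every sample because the mix is added
    per embryo.
    """

    def __init__(self, molecules: Mapping[str, float] | pd.Series) -> None:
        s = pd.Series(molecules, dtype=float)
        if len(s) == 0:
            raise ValidationError("spike-in table is empty")
        if s.index.duplicated().any():
            raise ValidationError("duplicate spike IDs")
        if (s <= 0).any():
            bad = s.index[s <= 0].tolist()
            raise ValidationError(f"nonpositive spike concentrations: {bad}")
        self.molecules = s
        self.molecules.index = self.molecules.index.astype(str)

    def __len__(self) -> int:
        return len(self.molecules)

    def __contains__(self, spike_id: str) -> bool:
        return spike_id in self.molecules.index

    def __getitem__(self, spike_id: str) -> float:
        return float(self.molecules[spike_id])

    @property
    def ids(self) -> list[str]:
        return list(self.molecules.index)

    def to_frame(self) -> pd.DataFrame:
        return self.molecules.rename("molecules_per_embryo").rename_axis(
            "spike_id"
        ).reset_index()

    @classmethod
    def default(cls) -> "SpikeInTable":
        """Bundled synthetic 92-species mix (log-spaced 1e2-1e7 ladder).

        A synthetic stand-in mirroring the species count and concentration
        span of a commercial 92-species spike-in mix; not vendor values.
        """
        ref = resources.files("embryoquant.data") / "spike_mix_synthetic.tsv"
        with resources.as_file(ref) as p:
            return read_spikein_table(p)


def read_spikein_table(path: str | Path) -> SpikeInTable:
    df = pd.read_csv(path, sep="\t", comment="#", float_precision="round_trip")
    if df.shape[1] < 2:
        raise ParseError(f"{path}: expected spike_id and molecules columns")
    ids = df.iloc[:, 0].astype(str)
    mols = pd.to_numeric(df.iloc[:, 1], errors="coerce")
    if mols.isna().any():
        raise ParseError(f"{path}: non-numeric concentration")
    return SpikeInTable(pd.Series(mols.to_numpy(), index=ids))


def write_spikein_table(
    table: SpikeInTable, path: str | Path, comments: Iterable[str] = ()
) -> None:
    with open(path, "w") as fh:
        for line in comments:
            fh.write(f"# {line}\n")
        # %.17g keeps molecule counts bit-exact through a write/read cycle
        table.to_frame().to_csv(fh, sep="\t", index=False, float_format="%.17g")


def molecules_from_attomoles(
    attomoles_per_ul: float,
    volume_ul: float = 1.0,
    dilution: float = 1.0,
    embryos: int = 1,
) -> float:
    """Convert a spike-in stock concentration to molecules per embryo.

    ``attomoles_per_ul * volume_ul / dilution`` attomoles are distributed
    over ``embryos`` embryos; one attomole is 1e-18 mol.
    """
    if volume_ul <= 0 or dilution <= 0 or embryos < 1:
        raise ValidationError("volume, dilution and embryos must be positive")
    return attomoles_per_ul * volume_ul / dilution * 1e-18 * AVOGADRO / embryos


# ---------------------------------------------------------------------------
# Gene models
# ---------------------------------------------------------------------------

@dataclasses.dataclass(frozen=True)
class GeneModel:
    """Representative-transcript view of one gene.

    The representative transcript is the longest isoform (sum of exon
    lengths); the TSS is its strand-aware 5' end.  Coordinates are 1-based
    inclusive; introns are the gaps between consecutive exons.
    """

    gene_id: str
    seqid: str
    strand: str
    tss: int
    transcript_id: str
    length: int
    exon_count: int
    exons: tuple[tuple[int, int], ...]
    introns: tuple[tuple[int, int], ...]


class GeneModelSet:
    """Per-gene TSS, representative length, exon count and intron intervals."""

    def __init__(self, models: Iterable[GeneModel]) -> None:
        self._models: dict[str, GeneModel] = {}
        for m in models:
            if m.gene_id in self._models:
                raise ValidationError(f"duplicate gene ID {m.gene_id!r}")
            self._models[m.gene_id] = m

    def __len__(self) -> int:
        return len(self._models)

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self._models

    def __getitem__(self, gene_id: str) -> GeneModel:
        return self._models[gene_id]

    def __iter__(self):
        return iter(self._models.values())

    @property
    def ids(self) -> list[str]:
        return list(self._models)

    def lengths(self, gene_ids: Sequence[str] | None = None) -> pd.Series:
        ids = self.ids if gene_ids is None else list(gene_ids)
        missing = [g for g in ids if g not in self._models]
        if missing:
            raise ValidationError(f"genes missing from models: {missing}")
        return pd.Series({g: self._models[g].length for g in ids}, dtype=float)

    def exon_counts(self, gene_ids: Sequence[str] | None = None) -> pd.Series:
        ids = self.ids if gene_ids is None else list(gene_ids)
        missing = [g for g in ids if g not in self._models]
        if missing:
            raise ValidationError(f"genes missing from models: {missing}")
        return pd.Series({g: self._models[g].exon_count for g in ids}, dtype=float)

    def table(self) -> pd.DataFrame:
        rows = [
            {
                "gene_id": m.gene_id,
                "seqid": m.seqid,
                "strand": m.strand,
                "tss": m.tss,
                "transcript_id": m.transcript_id,
                "length": m.length,
                "exon_count": m.exon_count,
            }
            for m in self._models.values()
        ]
        return pd.DataFrame(rows).set_index("gene_id")


def _introns_from_exons(exons: Sequence[tuple[int, int]]) -> tuple[tuple[int, int], ...]:
    out = []
    for (s1, e1), (s2, e2) in zip(exons, exons[1:]):
        if s2 <= e1:
            raise ValidationError("overlapping exons within one transcript")
        if s2 > e1 + 1:
            out.append((e1 + 1, s2 - 1))
    return tuple(out)


def read_gene_models(path: str | Path) -> GeneModelSet:
    """Parse gene/mRNA/exon features from GFF3 into a :class:`GeneModelSet`.

    For each gene the longest isoform (total exon length, ties broken by
    transcript ID) is the representative transcript.  Genes without explicit
    mRNA children are treated as single-transcript genes using their own
    exon children (or the gene span when no exons are annotated).
    """
    db = gffutils.create_db(
        str(path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
    )
    models = []
    for gene in db.features_of_type("gene"):
        candidates: list[tuple[int, str, str, list[tuple[int, int]]]] = []
        transcripts = list(
            db.children(gene, featuretype=("mRNA", "transcript"), level=1)
        )
        if not transcripts:
            transcripts = [gene]
        for t in transcripts:
            strand = t.strand if t.strand in "+-" else gene.strand
            if strand not in "+-":
                raise ValidationError(
                    f"gene {gene.id}: missing strand on {t.id}"
                )
            exons = sorted(
                (
                    (int(e.start), int(e.end))
                    for e in db.children(t, featuretype="exon")
                ),
            )
            if not exons:
                exons = [(int(t.start), int(t.end))]
            for s, e in exons:
                if s < t.start or e > t.end:
                    raise ValidationError(
                        f"gene {gene.id}: exon ({s},{e}) outside bounds of {t.id}"
                    )
            length = sum(e - s + 1 for s, e in exons)
            candidates.append((length, str(t.id), strand, exons))
        length, tid, strand, exons = max(
            candidates, key=lambda c: (c[0], [-ord(ch) for ch in c[1]])
        )
        tss = exons[0][0] if strand == "+" else exons[-1][1]
        models.append(
            GeneModel(
                gene_id=str(gene.id),
                seqid=str(gene.seqid),
                strand=strand,
                tss=tss,
                transcript_id=tid,
                length=length,
                exon_count=len(exons),
                exons=tuple(exons),
                introns=_introns_from_exons(exons),
            )
        )
    return GeneModelSet(models)


def write_gene_models(models: GeneModelSet, path: str | Path) -> None:
    """Write a minimal gene/mRNA/exon GFF3 for a :class:`GeneModelSet`."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for m in models:
            start = m.exons[0][0]
            end = m.exons[-1][1]
            fh.write(
                f"{m.seqid}\tembryoquant\tgene\t{start}\t{end}\t.\t{m.strand}\t.\t"
                f"ID={m.gene_id}\n"
            )
            fh.write(
                f"{m.seqid}\tembryoquant\tmRNA\t{start}\t{end}\t.\t{m.strand}\t.\t"
                f"ID={m.transcript_id};Parent={m.gene_id}\n"
            )
            for i, (s, e) in enumerate(m.exons, 1):
                fh.write(
                    f"{m.seqid}\tembryoquant\texon\t{s}\t{e}\t.\t{m.strand}\t.\t"
                    f"ID={m.transcript_id}.exon{i};Parent={m.transcript_id}\n"
                )


# ---------------------------------------------------------------------------
# Generic result tables
# ---------------------------------------------------------------------------

def read_table(path: str | Path, index_col: int | None = 0) -> pd.DataFrame:
    """Read a result TSV written by :func:`write_table`."""
    return pd.read_csv(
        path, sep="\t", comment="#", index_col=index_col,
        float_precision="round_trip",
    )


def write_table(
    df: pd.DataFrame,
    path: str | Path,
    comments: Iterable[str] = (),
    index: bool = True,
) -> None:
    with open(path, "w") as fh:
        for line in comments:
            fh.write(f"# {line}\n")
        df.to_csv(fh, sep="\t", index=index)
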