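"""Promoter extraction and TAGteam motif enrichment.

The TAGteam family of promoter elements (core CAGGTAG, degenerate
CAGGTAB with B = C/G/T) is bound by the maternal transcription factor
Zelda and times early zygotic transcription in drosophilids.  This module
extracts strand-aware promoter windows, scans them for IUPAC patterns on
both strands, and tests enrichment between gene sets (Fisher exact on
promoters with >= 1 hit) and positional enrichment near the TSS (binomial
tail against a uniform-placement null).
"""
from __future__ import annotations

import dataclasses
import logging
import re
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from Bio.Data.IUPACData import ambiguous_dna_values
from Bio.Seq import Seq
from scipy import stats

from .io import GeneModelSet, ValidationError

logger = logging.getLogger(__name__)

#: Core TAGteam heptamer and its degenerate form (B = C, G or T).
TAGTEAM_CORE = "CAGGTAG"
TAGTEAM_DEGENERATE = "CAGGTAB"

MIN_PROMOTER_LENGTH = 50
DEFAULT_PROMOTER_WINDOW = 1000
DEFAULT_PROXIMAL_WINDOW = 300


@dataclasses.dataclass(frozen=True)
class MotifPattern:
    """IUPAC nucleotide pattern, optionally scanned on both strands."""

    pattern: str
    both_strands: bool = True

    def __post_init__(self) -> None:
        pat = self.pattern.upper()
        bad = [c for c in pat if c not in ambiguous_dna_values]
        if bad:
            raise ValidationError(f"invalid IUPAC codes in motif: {bad}")
        if len(pat) < 4:
            raise ValidationError("motif must be at least 4 bases long")
        object.__setattr__(self, "pattern", pat)

    def regex(self) -> str:
        parts = []
        for c in self.pattern:
            vals = ambiguous_dna_values[c]
            parts.append(vals if len(vals) == 1 else f"[{vals}]")
        return "".join(parts)

    def reverse_complement(self) -> str:
        return str(Seq(self.pattern).reverse_complement())


def scan_motif(seq: str, motif: MotifPattern) -> list[tuple[int, str]]:
    """All (1-based start, strand) matches of the motif in ``seq``.

    Overlapping matches are all reported.  Reverse-strand sites are found by
    scanning the forward sequence with the reverse-complemented pattern, so
    positions stay in forward coordinates.  ``N`` in the sequence never
    matches (character classes contain only A/C/G/T).
    """
    s = seq.upper()
    fwd = re.compile(f"(?=({motif.regex()}))")
    hits = [(m.start() + 1, "+") for m in fwd.finditer(s)]
    if motif.both_strands:
        rc = motif.reverse_complement()
        if rc != motif.pattern:  # palindromes would double-count
            rc_re = re.compile(f"(?=({MotifPattern(rc, False).regex()}))")
            hits += [(m.start() + 1, "-") for m in rc_re.finditer(s)]
    return sorted(hits)


def extract_promoters(
    models: GeneModelSet,
    genome: Mapping[str, str] | str | Path,
    window: int = DEFAULT_PROMOTER_WINDOW,
    min_length: int = MIN_PROMOTER_LENGTH,
) -> dict[str, str]:
    """Strand-aware promoter windows immediately upstream of each TSS.

    For a + strand gene with TSS t the genomic interval is [t-window, t-1]
    (1-based inclusive); for a - strand gene it is [t+1, t+window],
    reverse-complemented.  Every returned sequence reads 5'->3' toward the
    TSS, so its last base abuts the TSS.  Windows are clipped at contig
    edges; promoters shorter than ``min_length`` are dropped with a warning.
    """
    if isinstance(genome, (str, Path)):
        from pyfaidx import Fasta

        fa = Fasta(str(genome), as_raw=True, sequence_always_upper=True)
        contigs: Mapping[str, str] = {name: str(fa[name][:]) for name in fa.keys()}
    else:
        contigs = {k: v.upper() for k, v in genome.items()}
    out: dict[str, str] = {}
    for m in models:
        if m.seqid not in contigs:
            raise ValidationError(f"contig {m.seqid!r} not in genome")
        contig = contigs[m.seqid]
        if not (1 <= m.tss <= len(contig)):
            raise ValidationError(
                f"gene {m.gene_id}: TSS {m.tss} outside contig {m.seqid}"
            )
        if m.strand == "+":
            start = max(1, m.tss - window)
            end = m.tss - 1
            seq = contig[start - 1 : end] if end >= start else ""
        else:
            start = m.tss + 1
            end = min(len(contig), m.tss + window)
            raw = contig[start - 1 : end] if end >= start else ""
            seq = str(Seq(raw).reverse_complement())
        if len(seq) < min_length:
            logger.warning(
                "gene %s: promoter clipped to %d bp (<%d), dropped",
                m.gene_id,
                len(seq),
                min_length,
            )
            continue
        out[m.gene_id] = seq
    return out


@dataclasses.dataclass(frozen=True)
class SetEnrichment:
    """2x2 promoter-with-motif table and Fisher exact enrichment."""

    a_with: int
    a_without: int
    b_with: int
    b_without: int
    odds_ratio: float
    p_value: float  # one-sided, enrichment in set a

    @property
    def table(self) -> np.ndarray:
        return np.array(
            [[self.a_with, self.a_without], [self.b_with, self.b_without]]
        )


def set_enrichment(
    set_a: Mapping[str, str],
    set_b: Mapping[str, str],
    motif: MotifPattern,
) -> SetEnrichment:
    """Fisher exact test for motif enrichment in promoter set a over set b.

    Promoters are dichotomised by >= 1 hit; the p-value is the one-sided
    hypergeometric tail for over-representation in set a.  The odds ratio
    uses the Haldane +0.5 correction when any cell is zero.
    """
    if len(set_a) == 0 or len(set_b) == 0:
        raise ValidationError("both promoter sets must be non-empty")
    a_with = sum(1 for s in set_a.values() if scan_motif(s, motif))
    b_with = sum(1 for s in set_b.values() if scan_motif(s, motif))
    a_wo = len(set_a) - a_with
    b_wo = len(set_b) - b_with
    table = [[a_with, a_wo], [b_with, b_wo]]
    _, p = stats.fisher_exact(table, alternative="greater")
    if min(a_with, a_wo, b_with, b_wo) == 0:
        orr = ((a_with + 0.5) * (b_wo + 0.5)) / ((a_wo + 0.5) * (b_with + 0.5))
    else:
        orr = (a_with * b_wo) / (a_wo * b_with)
    return SetEnrichment(a_with, a_wo, b_with, b_wo, float(orr), float(p))


@dataclasses.dataclass(frozen=True)
class PositionalEnrichment:
    """Proximal-window hit excess against a uniform placement null."""

    n_hits: int
    n_proximal: int
    expected_proximal: float
    p_value: float


def positional_enrichment(
    hits_per_promoter: Mapping[str, Sequence[int]],
    proximal_window: int = DEFAULT_PROXIMAL_WINDOW,
    promoter_length: int = DEFAULT_PROMOTER_WINDOW,
) -> PositionalEnrichment:
    """Binomial test for motif concentration in the TSS-proximal window.

    Hit start positions (1-based, promoter coordinates with position
    ``promoter_length`` immediately upstream of the TSS) are pooled across
    promoters.  A hit is proximal when its start lies within the
    ``proximal_window`` bases nearest the TSS.  Under the uniform null each
    hit is proximal with probability proximal_window / promoter_length; the
    p-value is the one-sided upper binomial tail (1.0 when there are no
    hits).
    """
    if proximal_window > promoter_length:
        raise ValidationError("proximal window exceeds promoter length")
    starts = [p for positions in hits_per_promoter.values() for p in positions]
    n = len(starts)
    cutoff = promoter_length - proximal_window  # proximal iff start > cutoff
    k = sum(1 for p in starts if p > cutoff)
    prob = proximal_window / promoter_length
    if n == 0:
        return PositionalEnrichment(0, 0, 0.0, 1.0)
    p = stats.binomtest(k, n, prob, alternative="greater").pvalue
    return PositionalEnrichment(n, k, n * prob, float(p))


def scan_promoter_set(
    promoters: Mapping[str, str], motif: MotifPattern
) -> dict[str, list[tuple[int, str]]]:
    """Hits per promoter for a whole set (convenience for the CLI/report)."""
    return {g: scan_motif(s, motif) for g, s in promoters.items()}
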