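"""Nucleotide-composition statistics for genes and intergenic flanks.

GC is computed over unambiguous bases only (A, C, G, T); gaps and ambiguity
codes are excluded from both numerator and denominator. Codon-position GC
(GC1/GC2/GC3) follows the alignment frame, so it requires an in-frame
alignment whose length is a multiple of three.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from .errors import FrameError, InputError
from .genome_io import GeneFamilyAlignment

_GC = frozenset("GC")
_VALID = frozenset("ACGT")


@dataclass(frozen=True)
class GeneCompositionRecord:
    """Per-family composition summary (means over member sequences)."""

    family_id: str
    gc: float
    gc1: float
    gc2: float
    gc3: float
    n_valid: int
    intergenic_gc: float = math.nan


@dataclass(frozen=True)
class GeneContext:
    """A gene with its up/downstream intergenic flanks (each <= 400 bp)."""

    gene_id: str
    genome: str
    strand: str
    start: int  # 0-based half-open
    end: int
    left_flank: str
    right_flank: str


def gc_content(seq: str) -> float:
    """(#G + #C) / (#A + #C + #G + #T); NaN when no unambiguous base remains."""
    if not seq:
        raise InputError("gc_content: empty sequence")
    s = seq.upper()
    gc = sum(1 for c in s if c in _GC)
    valid = sum(1 for c in s if c in _VALID)
    if valid == 0:
        return math.nan
    return gc / valid


def gc_by_codon_position(cds: str) -> tuple[float, float, float]:
    """GC at codon positions 1, 2 and 3 of an in-frame sequence."""
    if not cds or len(cds) % 3 != 0:
        raise FrameError(f"sequence length {len(cds)} is not a positive multiple of 3")
    return tuple(gc_content(cds[i::3]) for i in range(3))  # type: ignore[return-value]


def family_mean_gc(a: GeneFamilyAlignment) -> GeneCompositionRecord:
    """Average GC and GC1-3 over the family's sequences (equal weight each).

    Sequences contributing no unambiguous base (e.g. all-gap rows) are
    skipped with a warning; codon positions follow alignment columns.
    """
    if not a.in_frame:
        raise FrameError(f"family {a.family_id!r}: alignment length {a.length} not in frame")
    rows = []
    n_valid = 0
    for taxon, seq in zip(a.taxa, a.seqs):
        g = gc_content(seq)
        if math.isnan(g):
            warnings.warn(
                f"family {a.family_id!r}: sequence of {taxon!r} has no unambiguous base; skipped",
                stacklevel=2,
            )
            continue
        g1, g2, g3 = gc_by_codon_position(seq)
        rows.append((g, g1, g2, g3))
        n_valid += sum(1 for c in seq.upper() if c in _VALID)
    if not rows:
        return GeneCompositionRecord(a.family_id, math.nan, math.nan, math.nan, math.nan, 0)
    means = [sum(col) / len(rows) for col in zip(*rows)]
    return GeneCompositionRecord(a.family_id, *means, n_valid=n_valid)


def intergenic_gc(ctx: GeneContext, min_flank: int = 50) -> float:
    """Mean GC over the gene's intergenic flanks longer than *min_flank* bp.

    NaN (missing) when neither flank qualifies. GC is strand-symmetric, so
    the focal gene's strand is irrelevant.
    """
    vals = [
        gc_content(f)
        for f in (ctx.left_flank, ctx.right_flank)
        if len(f) > min_flank
    ]
    vals = [v for v in vals if not math.isnan(v)]
    if not vals:
        return math.nan
    return sum(vals) / len(vals)


def family_intergenic_gc(contexts: Sequence[GeneContext], min_flank: int = 50) -> float:
    """Per-family intergenic GC: mean over genomes with a non-missing value."""
    vals = [intergenic_gc(c, min_flank=min_flank) for c in contexts]
    vals = [v for v in vals if not math.isnan(v)]
    if not vals:
        return math.nan
    return sum(vals) / len(vals)


def extract_gene_contexts(
    coords: pd.DataFrame,
    genome_seqs: Mapping[str, str],
    max_flank: int = 400,
) -> dict[str, list[GeneContext]]:
    """Build flank contexts from a gene-coordinate table and genome sequences.

    *coords* needs columns gene_id, family_id, genome, seqid, start, end,
    strand with 0-based half-open coordinates. Flanks extend up to
    *max_flank* bp but are truncated at the nearest neighbouring gene
    boundary on the same sequence. Returns contexts grouped by family_id.
    """
    required = {"gene_id", "family_id", "genome", "seqid", "start", "end", "strand"}
    missing = required - set(coords.columns)
    if missing:
        raise InputError(f"coordinate table lacks columns: {sorted(missing)}")
    out: dict[str, list[GeneContext]] = {}
    for (genome, seqid), sub in coords.groupby(["genome", "seqid"], sort=True):
        if genome not in genome_seqs:
            raise InputError(f"no sequence for genome {genome!r}")
        seq = genome_seqs[genome]
        sub = sub.sort_values(["start", "gene_id"]).reset_index(drop=True)
        for i, row in sub.iterrows():
            left_bound = int(sub.loc[i - 1, "end"]) if i > 0 else 0
            right_bound = int(sub.loc[i + 1, "start"]) if i + 1 < len(sub) else len(seq)
            start, end = int(row.start), int(row.end)
            lf_start = max(left_bound, start - max_flank)
            rf_end = min(right_bound, end + max_flank)
            ctx = GeneContext(
                gene_id=str(row.gene_id),
                genome=str(genome),
                strand=str(row.strand),
                start=start,
                end=end,
                left_flank=seq[lf_start:start],
                right_flank=seq[end:rf_end],
            )
            out.setdefault(str(row.family_id), []).append(ctx)
    return out


def composition_table(records: Sequence[GeneCompositionRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "family_id": r.family_id,
                "gc": r.gc,
                "gc1": r.gc1,
                "gc2": r.gc2,
                "gc3": r.gc3,
                "intergenic_gc": r.intergenic_gc,
                "n_valid": r.n_valid,
            }
            for r in records
        ]
    )


def write_composition(records: Sequence[GeneCompositionRecord], path: str | Path) -> None:
    composition_table(records).to_csv(path, sep="\t", index=False)
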