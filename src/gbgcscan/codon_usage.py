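"""Optimal-codon determination and Fop/Fnop composition classes.

Two routes define the optimal codon of each amino acid:

* **RP method** — a codon is *optimal* when it is significantly enriched
  (2x2 chi-squared, default p < 0.001) in ribosomal-protein genes relative
  to all other coding sequences, the table contrasting the focal codon's
  count against its synonyms' counts in the two gene classes.
* **HCB method** — per-strain preferred-codon tables are combined by a
  consensus rule: an amino acid's optimal codon is accepted only when a
  strict majority (> 60%) of strains agree on it and every dissenting strain
  prefers a codon with the same third-base composition (A/U vs G/C).

Fop and Fnop are the fractions of a gene's codons that are optimal and
non-optimal, split by third-base class (AU-ending vs GC-ending); amino acids
without a defined optimal codon contribute to the denominator only.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio.Data import CodonTable
from scipy import stats

from .errors import InputError

_STANDARD = CodonTable.unambiguous_dna_by_id[1]

#: amino acid -> tuple of synonymous codons (DNA alphabet, 61 sense codons)
SYNONYM_FAMILIES: dict[str, tuple[str, ...]] = {}
for _codon, _aa in sorted(_STANDARD.forward_table.items()):
    SYNONYM_FAMILIES.setdefault(_aa, ())
    SYNONYM_FAMILIES[_aa] += (_codon,)

SENSE_CODONS: tuple[str, ...] = tuple(sorted(_STANDARD.forward_table))
STOP_CODONS: frozenset[str] = frozenset(_STANDARD.stop_codons)
AMINO_ACID_OF: dict[str, str] = dict(_STANDARD.forward_table)

#: single-codon amino acids (Met, Trp) — no synonymous choice, always excluded
ONE_FOLD_CODONS: frozenset[str] = frozenset(
    c for aa, cs in SYNONYM_FAMILIES.items() if len(cs) == 1 for c in cs
)


def third_base_class(codon: str) -> str:
    """'GC_ending' or 'AU_ending' by the codon's third base."""
    if len(codon) != 3:
        raise InputError(f"not a codon: {codon!r}")
    return "GC_ending" if codon[2].upper() in "GC" else "AU_ending"


@dataclass
class CodonCountTable:
    """Counts of the 61 sense codons for a gene or a gene class."""

    counts: Counter = field(default_factory=Counter)

    def __post_init__(self) -> None:
        bad = [c for c in self.counts if c not in AMINO_ACID_OF]
        if bad:
            raise InputError(f"non-sense codons in count table: {sorted(bad)[:5]}")
        if any(v < 0 for v in self.counts.values()):
            raise InputError("negative codon counts")

    @classmethod
    def from_seq(cls, seq: str) -> "CodonCountTable":
        """Count sense codons of an in-frame sequence.

        Codons containing gaps/ambiguity and stop codons are skipped (the
        sequence need not end at a stop; internal stops are ignored too).
        """
        s = seq.upper().replace("U", "T")
        counts: Counter = Counter()
        for i in range(0, len(s) - len(s) % 3, 3):
            codon = s[i : i + 3]
            if codon in AMINO_ACID_OF:
                counts[codon] += 1
        return cls(counts)

    @classmethod
    def from_seqs(cls, seqs: Iterable[str]) -> "CodonCountTable":
        total: Counter = Counter()
        for s in seqs:
            total += cls.from_seq(s).counts
        return cls(total)

    def __add__(self, other: "CodonCountTable") -> "CodonCountTable":
        return CodonCountTable(self.counts + other.counts)

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    def aa_total(self, aa: str) -> int:
        return sum(self.counts[c] for c in SYNONYM_FAMILIES[aa])


@dataclass(frozen=True)
class OptimalCodonSet:
    """Per-codon optimal / non_optimal / excluded labels."""

    labels: Mapping[str, str]
    method: str

    def __post_init__(self) -> None:
        bad = {v for v in self.labels.values()} - {"optimal", "non_optimal", "excluded"}
        if bad:
            raise InputError(f"unknown labels: {sorted(bad)}")

    def label(self, codon: str) -> str:
        return self.labels.get(codon, "excluded")

    @property
    def optimal(self) -> set[str]:
        return {c for c, v in self.labels.items() if v == "optimal"}

    @property
    def non_optimal(self) -> set[str]:
        return {c for c, v in self.labels.items() if v == "non_optimal"}

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "codon": c,
                "amino_acid": AMINO_ACID_OF[c],
                "label": self.label(c),
                "third_base_class": third_base_class(c),
            }
            for c in SENSE_CODONS
        ]
        return pd.DataFrame(rows)

    def write_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


@dataclass(frozen=True)
class CodonFrequencies:
    """Fop/Fnop split by third-base composition; fractions of all codons."""

    fop_gc: float
    fop_au: float
    fnop_gc: float
    fnop_au: float
    excluded: float
    n_codons: int


def rp_optimal_codons(
    rp: CodonCountTable,
    other: CodonCountTable,
    alpha: float = 0.001,
    continuity_correction: bool = False,
) -> OptimalCodonSet:
    """Define optimal codons by enrichment in ribosomal-protein genes.

    For each codon of a >= 2-fold amino acid, the 2x2 table is
    (focal count, synonym count) x (RP genes, other genes); the codon is
    optimal when the chi-squared p-value is below *alpha* AND its relative
    frequency among synonyms is higher in RP genes. Codons that cannot be
    tested (zero margin) are excluded.
    """
    if rp.total == 0:
        raise InputError("empty ribosomal-protein codon table")
    if other.total == 0:
        raise InputError("empty background codon table")
    labels: dict[str, str] = {}
    for aa, codons in SYNONYM_FAMILIES.items():
        if len(codons) == 1:
            labels[codons[0]] = "excluded"
            continue
        rp_aa = rp.aa_total(aa)
        other_aa = other.aa_total(aa)
        for codon in codons:
            a = rp.counts[codon]
            b = rp_aa - a
            c = other.counts[codon]
            d = other_aa - c
            table = [[a, b], [c, d]]
            # zero margin -> untestable
            if min(a + b, c + d, a + c, b + d) == 0:
                labels[codon] = "excluded"
                continue
            chi2, p, _, _ = stats.chi2_contingency(table, correction=continuity_correction)
            enriched = (a / rp_aa) > (c / other_aa)
            labels[codon] = "optimal" if (p < alpha and enriched) else "non_optimal"
    return OptimalCodonSet(labels=labels, method="RP")


def hcb_consensus(
    strain_preferences: Mapping[str, Sequence[str]],
    threshold: float = 0.60,
) -> OptimalCodonSet:
    """Combine per-strain preferred codons into a consensus optimal set.

    *strain_preferences* maps each amino acid to the preferred codon reported
    for every documented strain. The amino acid's modal codon is accepted as
    optimal iff its support is a strict majority above *threshold* and every
    dissenting strain prefers a codon of the same third-base class; otherwise
    the amino acid is excluded entirely.
    """
    labels: dict[str, str] = {}
    for aa, codons in SYNONYM_FAMILIES.items():
        prefs = [c.upper().replace("U", "T") for c in strain_preferences.get(aa, ())]
        if len(codons) == 1 or not prefs:
            for c in codons:
                labels[c] = "excluded"
            continue
        unknown = set(prefs) - set(codons)
        if unknown:
            raise InputError(f"{aa}: preferred codons not synonymous: {sorted(unknown)}")
        winner, n_win = Counter(prefs).most_common(1)[0]
        agree = n_win / len(prefs) > threshold
        same_class = all(third_base_class(c) == third_base_class(winner) for c in prefs)
        if agree and same_class:
            for c in codons:
                labels[c] = "optimal" if c == winner else "non_optimal"
        else:
            for c in codons:
                labels[c] = "excluded"
    return OptimalCodonSet(labels=labels, method="HCB")


def fop_fnop(gene: CodonCountTable, oset: OptimalCodonSet) -> CodonFrequencies:
    """Fractions of a gene's codons in each optimal x third-base class.

    The denominator is the gene's total sense-codon count, so excluded
    codons dilute all four fractions; fop_gc + fop_au + fnop_gc + fnop_au +
    excluded = 1.
    """
    n = gene.total
    if n == 0:
        raise InputError("gene has no sense codons")
    tallies = {"fop_gc": 0, "fop_au": 0, "fnop_gc": 0, "fnop_au": 0, "excluded": 0}
    for codon, count in gene.counts.items():
        lab = oset.label(codon)
        if lab == "excluded":
            tallies["excluded"] += count
            continue
        kind = "fop" if lab == "optimal" else "fnop"
        cls = "gc" if third_base_class(codon) == "GC_ending" else "au"
        tallies[f"{kind}_{cls}"] += count
    return CodonFrequencies(
        fop_gc=tallies["fop_gc"] / n,
        fop_au=tallies["fop_au"] / n,
        fnop_gc=tallies["fnop_gc"] / n,
        fnop_au=tallies["fnop_au"] / n,
        excluded=tallies["excluded"] / n,
        n_codons=n,
    )


def read_strain_preferences(path: str | Path) -> dict[str, list[str]]:
    """Read a TSV of per-strain preferred codons (amino_acid, strain, codon)."""
    df = pd.read_csv(path, sep="\t")
    need = {"amino_acid", "strain", "codon"}
    if not need <= set(df.columns):
        raise InputError(f"{path}: needs columns {sorted(need)}")
    out: dict[str, list[str]] = {}
    for _, row in df.iterrows():
        out.setdefault(str(row.amino_acid), []).append(str(row.codon))
    return out
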