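"""Gene-family alignment and genome-group input handling.

A *genome group* is a set of closely related genomes (>= 6 members, mean
pairwise nucleotide distance below 0.15) analysed together; its *single-copy
core* families are those with exactly one member per genome. Alignments are
in-frame nucleotide FASTA files, one per family, with record identifiers of
the form ``genome|gene`` (delimiter configurable).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from Bio import SeqIO

from .errors import FormatError, InputError, TooShortError

VALID_BASES = frozenset("ACGT")

# nucleotide -> integer code used by the numerical modules; anything else
# (gap, N, IUPAC ambiguity) is missing data
_BASE_CODE = {"A": 0, "C": 1, "G": 2, "T": 3}
MISSING = -1


@dataclass(frozen=True)
class GeneFamilyAlignment:
    """One gene family's aligned nucleotide sequences.

    ``taxa`` holds the genome identifier of each row (parsed from the FASTA
    header); duplicates are permitted here so that multi-copy families can be
    represented and then rejected by :func:`core_single_copy`.
    """

    family_id: str
    taxa: tuple[str, ...]
    seqs: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.seqs) < 2:
            raise InputError(
                f"family {self.family_id!r}: need >= 2 sequences, got {len(self.seqs)}"
            )
        if len(self.taxa) != len(self.seqs):
            raise InputError(f"family {self.family_id!r}: taxa/seqs length mismatch")
        lengths = {len(s) for s in self.seqs}
        if len(lengths) != 1:
            raise FormatError(
                f"family {self.family_id!r}: ragged alignment, lengths {sorted(lengths)}"
            )

    @property
    def length(self) -> int:
        return len(self.seqs[0])

    @property
    def n_seqs(self) -> int:
        return len(self.seqs)

    @property
    def in_frame(self) -> bool:
        return self.length % 3 == 0

    def to_codes(self) -> np.ndarray:
        """(n_seqs, length) int8 matrix; non-ACGT characters become MISSING."""
        out = np.full((self.n_seqs, self.length), MISSING, dtype=np.int8)
        for i, s in enumerate(self.seqs):
            a = np.frombuffer(s.upper().encode(), dtype="S1")
            for base, code in _BASE_CODE.items():
                out[i, a == base.encode()] = code
        return out


@dataclass(frozen=True)
class IdentityMatrix:
    """Symmetric matrix of mean best-hit identity scores *s* in [0, 1].

    The analysis works with the distance ``1 - s``.
    """

    genomes: tuple[str, ...]
    s: np.ndarray

    def __post_init__(self) -> None:
        s = np.asarray(self.s, dtype=float)
        n = len(self.genomes)
        if s.shape != (n, n):
            raise InputError(f"identity matrix shape {s.shape} != ({n}, {n})")
        if not np.allclose(s, s.T, atol=1e-9):
            raise InputError("identity matrix is not symmetric")
        if not np.allclose(np.diag(s), 1.0, atol=1e-9):
            raise InputError("identity matrix diagonal must be 1")
        if s.min() < -1e-9 or s.max() > 1 + 1e-9:
            raise InputError("identity scores must lie in [0, 1]")
        object.__setattr__(self, "s", s)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "IdentityMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        if list(df.index) != list(df.columns):
            raise InputError(f"{path}: row and column genome ids differ")
        return cls(tuple(str(g) for g in df.index), df.to_numpy(dtype=float))

    def distance(self, a: str, b: str) -> float:
        i, j = self.genomes.index(a), self.genomes.index(b)
        return 1.0 - float(self.s[i, j])


@dataclass
class GenomeGroup:
    """A set of genomes and the gene families observed in them."""

    group_id: str
    genomes: tuple[str, ...]
    families: list[GeneFamilyAlignment] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(set(self.genomes)) != len(self.genomes):
            raise InputError(f"group {self.group_id!r}: duplicate genome ids")

    @property
    def core_single_copy_ids(self) -> set[str]:
        return core_single_copy(self)


def read_family_fasta(
    path: str | Path, delimiter: str = "|", family_id: str | None = None
) -> GeneFamilyAlignment:
    """Read one family alignment from FASTA.

    The genome identifier is the part of the record id before ``delimiter``
    (the whole id when the delimiter is absent). The family id defaults to the
    file stem.
    """
    path = Path(path)
    records = list(SeqIO.parse(str(path), "fasta"))
    if len(records) == 0:
        raise InputError(f"{path}: empty FASTA file")
    if len(records) < 2:
        raise InputError(f"{path}: alignment needs >= 2 records")
    taxa = tuple(r.id.split(delimiter, 1)[0] for r in records)
    seqs = tuple(str(r.seq).upper() for r in records)
    fid = family_id if family_id is not None else path.stem
    return GeneFamilyAlignment(family_id=fid, taxa=taxa, seqs=seqs)


def read_family_directory(
    directory: str | Path, pattern: str = "*.fasta", delimiter: str = "|"
) -> list[GeneFamilyAlignment]:
    """Read every family FASTA under *directory* (sorted for reproducibility)."""
    directory = Path(directory)
    paths = sorted(directory.glob(pattern))
    if not paths:
        raise InputError(f"{directory}: no alignments matching {pattern!r}")
    return [read_family_fasta(p, delimiter=delimiter) for p in paths]


def select_groups(
    m: IdentityMatrix, min_size: int = 6, max_dist: float = 0.15
) -> list[set[str]]:
    """Delimit analysis groups from the identity matrix.

    Genomes are linked whenever their distance ``1 - s`` is below *max_dist*;
    groups are the connected components (single linkage) of that graph with at
    least *min_size* members. Components are returned sorted by their smallest
    genome id.
    """
    g = nx.Graph()
    g.add_nodes_from(m.genomes)
    d = 1.0 - m.s
    n = len(m.genomes)
    for i in range(n):
        for j in range(i + 1, n):
            if d[i, j] < max_dist:
                g.add_edge(m.genomes[i], m.genomes[j])
    comps = [set(c) for c in nx.connected_components(g) if len(c) >= min_size]
    return sorted(comps, key=lambda c: min(c))


def core_single_copy(group: GenomeGroup) -> set[str]:
    """Family ids with exactly one sequence per genome of the group."""
    want = set(group.genomes)
    out: set[str] = set()
    for fam in group.families:
        counts: dict[str, int] = {}
        for t in fam.taxa:
            counts[t] = counts.get(t, 0) + 1
        if set(counts) == want and all(v == 1 for v in counts.values()):
            out.add(fam.family_id)
    return out


def trim_central(a: GeneFamilyAlignment, target_len: int = 900) -> GeneFamilyAlignment:
    """Restrict the alignment to its *target_len* central columns.

    With an odd number of surplus columns the extra discarded column falls on
    the right (floor convention). Families shorter than *target_len* raise
    :class:`TooShortError` and are excluded from the recombination analysis.
    """
    if target_len <= 0:
        raise InputError("target_len must be positive")
    if a.length < target_len:
        raise TooShortError(
            f"family {a.family_id!r}: length {a.length} < {target_len}"
        )
    start = (a.length - target_len) // 2
    seqs = tuple(s[start : start + target_len] for s in a.seqs)
    return GeneFamilyAlignment(family_id=a.family_id, taxa=a.taxa, seqs=seqs)


def write_group_manifest(groups: Iterable[Sequence[str] | set[str]], path: str | Path) -> None:
    rows = [
        {"group_id": f"group{i + 1}", "genomes": ",".join(sorted(g))}
        for i, g in enumerate(groups)
    ]
    pd.DataFrame(rows, columns=["group_id", "genomes"]).to_csv(path, sep="\t", index=False)
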