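"""Shared fixtures and the brute-force minimum-homoplasy oracle.

The oracle enumerates every unrooted binary topology on the taxa present at
both sites, scores each character by Fitch parsimony, and reports the excess
of the best joint score over the per-character minima. It is deliberately
independent of the package's partition-intersection-graph computation.
"""

from __future__ import annotations

import numpy as np
import pytest

from gbgcscan.genome_io import GeneFamilyAlignment


@pytest.fixture
def make_alignment():
    def _make(seqs, taxa=None, family_id="fam"):
        taxa = taxa or tuple(f"g{i + 1:02d}" for i in range(len(seqs)))
        return GeneFamilyAlignment(family_id=family_id, taxa=tuple(taxa), seqs=tuple(seqs))

    return _make


@pytest.fixture
def rng():
    return np.random.default_rng(20_260_921)


# ---------------------------------------------------------------------------
# brute-force oracle


def _insertions(shape, leaf):
    """All ways to attach *leaf* onto an edge of *shape* (nested tuples)."""
    yield (shape, leaf)  # break the edge above this subtree
    if not isinstance(shape, int):
        left, right = shape
        for nl in _insertions(left, leaf):
            yield (nl, right)
        for nr in _insertions(right, leaf):
            yield (left, nr)


def _all_unrooted_trees(taxa: tuple[int, ...]):
    """Every unrooted binary topology, rooted at taxa[0] for scoring.

    Built by sequential edge insertion; yields (2n-5)!! distinct trees.
    """
    if len(taxa) < 3:
        yield (taxa[0], taxa[1])
        return
    shapes = [taxa[1]]
    for leaf in taxa[2:]:
        shapes = [s2 for s in shapes for s2 in _insertions(s, leaf)]
    for s in shapes:
        yield (taxa[0], s)


def _fitch_length(tree, states: dict[int, int]) -> int:
    """Fitch parsimony length of one character on a rooted shape."""

    def post(node):
        if isinstance(node, int):
            return frozenset([states[node]]), 0
        (ls, lc), (rs, rc) = post(node[0]), post(node[1])
        inter = ls & rs
        if inter:
            return inter, lc + rc
        return ls | rs, lc + rc + 1

    return post(tree)[1]


def brute_force_incompatibility(col_i, col_j) -> int:
    """Minimum extra changes for a site pair over all tree topologies."""
    missing = {None, "-", "N", -1}
    taxa = [
        t
        for t, (x, y) in enumerate(zip(col_i, col_j))
        if x not in missing and y not in missing
    ]
    if not taxa:
        return 0
    si = {t: col_i[t] for t in taxa}
    sj = {t: col_j[t] for t in taxa}
    ki = len(set(si.values()))
    kj = len(set(sj.values()))
    if len(taxa) == 1:
        return 0
    best = None
    for tree in _all_unrooted_trees(tuple(taxa)):
        total = _fitch_length(tree, si) + _fitch_length(tree, sj)
        best = total if best is None else min(best, total)
    return best - (ki - 1) - (kj - 1)
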