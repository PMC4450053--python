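"""Permutation tests for recombination in gene-family alignments.

Three site-pattern statistics are computed on the same alignment and share a
single site-permutation null:

* **PHI** — the mean *refined incompatibility* (minimum number of extra state
  changes, i.e. homoplasies, forced by a pair of sites on any tree) over all
  parsimony-informative site pairs closer than a window (default 100 bp) in
  original alignment coordinates. Recombination makes nearby sites more
  congruent than random pairs, so low observed values are significant.
* **NSS** — the neighbour similarity score of the site-compatibility
  matrix: for adjacent informative sites, the fraction of other sites with
  which both members of the pair have the same compatibility status,
  averaged along the sequence. Recombination makes neighbouring sites share
  compatibility patterns, so high observed values are significant. (The
  coarser variant — the plain fraction of adjacent pairs that are compatible
  — is available as ``formulation='adjacent'``.)
* **MaxChi2** — over all sequence pairs and all candidate breakpoints, the
  largest 2x2 chi-squared (no continuity correction) contrasting
  match/mismatch counts in windows of variable sites left versus right of
  the breakpoint; high values are significant. The default half-window is a
  quarter of the variable sites (matching the scale of conversion tracts
  relative to a gene); ``half_window='full'`` gives the classic whole
  sequence split.

P-values use the permutation estimator ``(1 + k) / (1 + n_perm)`` where *k*
counts permutations at least as extreme as the observation. Permuting site
order destroys the spatial signal while preserving the site patterns, so the
null is exact for exchangeable (clonal) alignments.

The refined incompatibility of two sites equals the cycle rank
``edges - vertices + components`` of their partition intersection graph
(vertices: observed states at either site; edges: observed joint states).
For two binary sites this reduces to the four-gamete test.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np

from .errors import InputError, NotComputableError
from .genome_io import MISSING, GeneFamilyAlignment

METHODS = ("PHI", "NSS", "MaxChi2")


# ---------------------------------------------------------------------------
# site matrices


@dataclass(frozen=True)
class InformativeSiteMatrix:
    """Parsimony-informative columns of an alignment.

    ``states`` is (n_taxa, n_sites) with compact per-site codes 0..k-1 and -1
    for missing data (gaps, N, ambiguity codes). ``positions`` are original
    alignment coordinates (0-based).
    """

    positions: np.ndarray
    states: np.ndarray
    n_states: np.ndarray

    @property
    def n_sites(self) -> int:
        return int(self.positions.size)

    @property
    def n_taxa(self) -> int:
        return int(self.states.shape[0])


def _compact_columns(codes: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Recode each column to 0..k-1 (missing stays -1); return codes, k per column."""
    n, m = codes.shape
    out = np.full_like(codes, MISSING)
    ks = np.zeros(m, dtype=np.int64)
    for j in range(m):
        col = codes[:, j]
        states = np.unique(col[col != MISSING])
        ks[j] = states.size
        for new, old in enumerate(states):
            out[col == old, j] = new
    return out, ks


def informative_sites(a: GeneFamilyAlignment | np.ndarray) -> InformativeSiteMatrix:
    """Retain columns with >= 2 states each carried by >= 2 sequences."""
    codes = a.to_codes() if isinstance(a, GeneFamilyAlignment) else np.asarray(a)
    n, L = codes.shape
    keep = []
    for j in range(L):
        col = codes[:, j]
        vals, counts = np.unique(col[col != MISSING], return_counts=True)
        if (counts >= 2).sum() >= 2:
            keep.append(j)
    keep_arr = np.asarray(keep, dtype=np.int64)
    sub, ks = _compact_columns(codes[:, keep_arr]) if keep else (
        np.empty((n, 0), dtype=codes.dtype),
        np.empty(0, dtype=np.int64),
    )
    return InformativeSiteMatrix(positions=keep_arr, states=sub, n_states=ks)


def variable_sites(codes: np.ndarray) -> np.ndarray:
    """Column indices with >= 2 observed states (missing ignored)."""
    keep = []
    for j in range(codes.shape[1]):
        col = codes[:, j]
        if np.unique(col[col != MISSING]).size >= 2:
            keep.append(j)
    return np.asarray(keep, dtype=np.int64)


# ---------------------------------------------------------------------------
# pairwise incompatibility


def pair_incompatibility(site_i: Sequence, site_j: Sequence) -> int:
    """Minimum number of extra state changes (homoplasies) forced by a site pair.

    Accepts two equal-length columns of hashable states; ``None``, ``'-'``,
    ``'N'`` and -1 are treated as missing, and a taxon missing at either site
    is dropped from the pair. Computed as the cycle rank of the partition
    intersection graph, which equals the brute-force minimum over all trees.
    """
    if len(site_i) != len(site_j):
        raise InputError("site columns must cover the same taxa")
    missing = {None, "-", "N", MISSING}
    pairs = {
        (x, y)
        for x, y in zip(site_i, site_j)
        if x not in missing and y not in missing
    }
    if not pairs:
        return 0
    verts: dict[tuple[int, object], int] = {}
    for x, y in pairs:
        verts.setdefault((0, x), len(verts))
        verts.setdefault((1, y), len(verts))
    parent = list(range(len(verts)))

    def find(u: int) -> int:
        while parent[u] != u:
            parent[u] = parent[parent[u]]
            u = parent[u]
        return u

    components = len(verts)
    for x, y in pairs:
        ru, rv = find(verts[(0, x)]), find(verts[(1, y)])
        if ru != rv:
            parent[ru] = rv
            components -= 1
    return len(pairs) - len(verts) + components


def incompatibility_matrix(m: InformativeSiteMatrix) -> np.ndarray:
    """Symmetric (n_sites, n_sites) matrix of refined incompatibility scores.

    Sites with at most two states (the overwhelmingly common case) go through
    a vectorised four-gamete path; pairs touching a multi-state site fall
    back to the general graph computation.
    """
    S, ks = m.states, m.n_states
    n, msites = S.shape
    out = np.zeros((msites, msites), dtype=np.int16)
    if msites == 0:
        return out
    binary = ks <= 2
    bidx = np.nonzero(binary)[0]
    if bidx.size:
        sub = S[:, bidx]
        valid = (sub != MISSING).astype(np.int32)
        one = ((sub == 1) & (sub != MISSING)).astype(np.int32)
        zero = ((sub == 0)).astype(np.int32)
        c11 = one.T @ one
        c10 = one.T @ zero
        c01 = zero.T @ one
        c00 = zero.T @ zero
        four = (c11 > 0) & (c10 > 0) & (c01 > 0) & (c00 > 0)
        out[np.ix_(bidx, bidx)] = four.astype(np.int16)
    multi = np.nonzero(~binary)[0]
    for i in multi:
        for j in range(msites):
            if i == j:
                continue
            v = pair_incompatibility(S[:, i], S[:, j])
            out[i, j] = v
            out[j, i] = v
    np.fill_diagonal(out, 0)
    return out


# ---------------------------------------------------------------------------
# statistics (observed values); prepared forms support fast permutation


def phi_statistic(
    m: InformativeSiteMatrix,
    window: int = 100,
    incompat: np.ndarray | None = None,
    window_unit: str = "bp",
) -> float:
    """Mean refined incompatibility over informative-site pairs within *window*.

    Distances are measured in original alignment coordinates when
    ``window_unit == 'bp'`` (the published parameterisation) or in ranks
    among informative sites when ``'sites'``.
    """
    ia, ib = _phi_pairs(m, window, window_unit)
    if ia.size == 0:
        raise NotComputableError("PHI: no informative-site pair within window")
    inc = incompat if incompat is not None else incompatibility_matrix(m)
    return float(inc[ia, ib].mean())


def _phi_pairs(
    m: InformativeSiteMatrix, window: int, window_unit: str
) -> tuple[np.ndarray, np.ndarray]:
    if window_unit not in ("bp", "sites"):
        raise InputError(f"unknown window unit {window_unit!r}")
    pos = m.positions if window_unit == "bp" else np.arange(m.n_sites)
    ia, ib = np.triu_indices(m.n_sites, k=1)
    dist = np.abs(pos[ib] - pos[ia])
    keep = dist <= window
    return ia[keep], ib[keep]


def compatibility_row_similarity(incompat: np.ndarray) -> np.ndarray:
    """(m, m) matrix of pairwise row agreement of the compatibility matrix.

    Entry (i, k) is the fraction of sites j for which sites i and k have the
    same compatibility status with j.
    """
    compat = (incompat == 0).astype(np.float32)
    m = compat.shape[0]
    agree = compat @ compat.T + (1.0 - compat) @ (1.0 - compat).T
    return agree / m


def nss_statistic(
    m: InformativeSiteMatrix,
    incompat: np.ndarray | None = None,
    formulation: str = "matrix",
) -> float:
    """Neighbour similarity score of adjacent informative sites.

    ``formulation='matrix'`` (default) averages, over adjacent site pairs,
    the agreement of their compatibility-matrix rows; ``'adjacent'`` is the
    plain fraction of adjacent pairs that are themselves compatible.
    """
    if m.n_sites < 2:
        raise NotComputableError("NSS: fewer than 2 informative sites")
    inc = incompat if incompat is not None else incompatibility_matrix(m)
    idx = np.arange(m.n_sites - 1)
    if formulation == "adjacent":
        return float((inc[idx, idx + 1] == 0).mean())
    if formulation != "matrix":
        raise InputError(f"unknown NSS formulation {formulation!r}")
    rowsim = compatibility_row_similarity(inc)
    return float(rowsim[idx, idx + 1].mean())


class _MaxChiPrepared:
    """Per-pair mismatch/validity over variable sites, for fast re-evaluation."""

    def __init__(self, codes: np.ndarray, half_window: int | str | None = None):
        var = variable_sites(codes)
        if var.size < 2:
            raise NotComputableError("MaxChi2: fewer than 2 variable sites")
        sub = codes[:, var]
        n = codes.shape[0]
        ii, jj = np.triu_indices(n, k=1)
        a, b = sub[ii, :], sub[jj, :]
        self.valid = (a != MISSING) & (b != MISSING)
        self.mismatch = (a != b) & self.valid
        if not self.mismatch.any():
            raise NotComputableError("MaxChi2: no mismatching sequence pair")
        v = var.size
        self.n_sites = v
        if half_window == "full":
            self.half_window = 0  # whole-sequence split
        elif half_window is None:
            self.half_window = min(max(10, v // 4), v // 2)
        else:
            if half_window < 1:
                raise InputError("half_window must be >= 1 or 'full'")
            self.half_window = min(int(half_window), v // 2)
        if self.half_window and self.half_window < 2:
            raise NotComputableError("MaxChi2: too few variable sites for the window")

    def value(self, order: np.ndarray | None = None) -> float:
        valid = self.valid if order is None else self.valid[:, order]
        mism = self.mismatch if order is None else self.mismatch[:, order]
        npair = valid.shape[0]
        zeros = np.zeros((npair, 1))
        cv = np.concatenate([zeros, valid.cumsum(axis=1)], axis=1).astype(float)
        cm = np.concatenate([zeros, mism.cumsum(axis=1)], axis=1).astype(float)
        v = self.n_sites
        h = self.half_window
        if h:
            ks = np.arange(h, v - h + 1)
            lv = cv[:, ks] - cv[:, ks - h]
            lm = cm[:, ks] - cm[:, ks - h]
            rv = cv[:, ks + h] - cv[:, ks]
            rm = cm[:, ks + h] - cm[:, ks]
        else:
            ks = np.arange(1, v)
            lv, lm = cv[:, ks], cm[:, ks]
            rv = cv[:, -1:] - lv
            rm = cm[:, -1:] - lm
        a = lm
        bl = lv - lm
        c = rm
        d = rv - rm
        denom = (a + bl) * (c + d) * (a + c) * (bl + d)
        num = (lv + rv) * (a * d - bl * c) ** 2
        with np.errstate(divide="ignore", invalid="ignore"):
            chi2 = np.where(denom > 0, num / denom, 0.0)
        return float(chi2.max())


def maxchi_statistic(
    a: GeneFamilyAlignment | np.ndarray, half_window: int | str | None = None
) -> float:
    """Maximum 2x2 breakpoint chi-squared over all sequence pairs.

    *half_window* counts variable sites on each side of the breakpoint;
    ``None`` adapts it to a quarter of the variable sites, ``'full'`` uses
    the whole sequence either side.
    """
    codes = a.to_codes() if isinstance(a, GeneFamilyAlignment) else np.asarray(a)
    return _MaxChiPrepared(codes, half_window=half_window).value()


# ---------------------------------------------------------------------------
# permutation machinery


@dataclass(frozen=True)
class RecombTestResult:
    method: str
    statistic: float | None
    p_value: float | None
    n_permutations: int
    computable: bool

    @classmethod
    def not_computable(cls, method: str) -> "RecombTestResult":
        return cls(method=method, statistic=None, p_value=None, n_permutations=0, computable=False)


@dataclass(frozen=True)
class RecombinationVerdict:
    family_id: str
    results: Mapping[str, RecombTestResult]
    status: str  # recombinant | non_recombinant | unclassified | discarded


class _PreparedPhi:
    def __init__(self, m: InformativeSiteMatrix, incompat: np.ndarray, window: int, unit: str):
        self.ia, self.ib = _phi_pairs(m, window, unit)
        if self.ia.size == 0:
            raise NotComputableError("PHI: no informative-site pair within window")
        self.incompat = incompat
        self.n_columns = m.n_sites

    def value(self, order: np.ndarray | None = None) -> float:
        if order is None:
            return float(self.incompat[self.ia, self.ib].mean())
        return float(self.incompat[order[self.ia], order[self.ib]].mean())


class _PreparedNss:
    def __init__(self, m: InformativeSiteMatrix, incompat: np.ndarray, formulation: str):
        if m.n_sites < 2:
            raise NotComputableError("NSS: fewer than 2 informative sites")
        if formulation == "matrix":
            self.score = compatibility_row_similarity(incompat)
        elif formulation == "adjacent":
            self.score = (incompat == 0).astype(np.float32)
        else:
            raise InputError(f"unknown NSS formulation {formulation!r}")
        self.idx = np.arange(m.n_sites - 1)
        self.n_columns = m.n_sites

    def value(self, order: np.ndarray | None = None) -> float:
        if order is None:
            return float(self.score[self.idx, self.idx + 1].mean())
        return float(self.score[order[self.idx], order[self.idx + 1]].mean())


class PhiTest:
    """PHI statistic with its permutation direction (low tail)."""

    name = "PHI"
    tail = "low"

    def __init__(self, window: int = 100, window_unit: str = "bp"):
        self.window = window
        self.window_unit = window_unit

    def prepare(self, a) -> _PreparedPhi:
        prep = a if isinstance(a, _SharedSiteData) else _SharedSiteData(a)
        return _PreparedPhi(prep.m, prep.incompat, self.window, self.window_unit)


class NssTest:
    name = "NSS"
    tail = "high"

    def __init__(self, formulation: str = "matrix"):
        self.formulation = formulation

    def prepare(self, a) -> _PreparedNss:
        prep = a if isinstance(a, _SharedSiteData) else _SharedSiteData(a)
        return _PreparedNss(prep.m, prep.incompat, self.formulation)


class MaxChiTest:
    name = "MaxChi2"
    tail = "high"

    def __init__(self, half_window: int | str | None = None):
        self.half_window = half_window

    def prepare(self, a) -> _MaxChiPrepared:
        prep = a if isinstance(a, _SharedSiteData) else _SharedSiteData(a)
        mc = _MaxChiPrepared(prep.codes, half_window=self.half_window)
        mc.n_columns = mc.n_sites
        return mc


_TESTS = {"PHI": PhiTest, "NSS": NssTest, "MaxChi2": MaxChiTest}


class _SharedSiteData:
    """Informative-site matrix and incompatibility scores shared by the tests."""

    def __init__(self, a: GeneFamilyAlignment | np.ndarray):
        self.codes = a.to_codes() if isinstance(a, GeneFamilyAlignment) else np.asarray(a)
        self.m = informative_sites(self.codes)
        self.incompat = incompatibility_matrix(self.m)


def permutation_test(
    stat,
    a,
    n_perm: int = 1000,
    tail: str | None = None,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> RecombTestResult:
    """Site-permutation test of one statistic on one alignment.

    *stat* is a :class:`PhiTest`, :class:`NssTest` or :class:`MaxChiTest`
    (anything with ``name``, ``tail`` and ``prepare``). The p-value is
    ``(1 + k) / (1 + n_perm)`` with *k* the number of permutations at least
    as extreme as the observation in the statistic's tail; ties count as
    extreme, keeping the estimator valid (conservative) for discrete nulls.
    """
    if n_perm < 1:
        raise InputError("n_perm must be >= 1")
    tail = tail or stat.tail
    if tail not in ("low", "high"):
        raise InputError(f"unknown tail {tail!r}")
    if rng is None:
        rng = np.random.default_rng(seed)
    try:
        prepared = stat.prepare(a)
    except NotComputableError:
        return RecombTestResult.not_computable(stat.name)
    observed = prepared.value(None)
    tol = 1e-12
    k = 0
    for _ in range(n_perm):
        order = rng.permutation(prepared.n_columns)
        val = prepared.value(order)
        k += (val <= observed + tol) if tail == "low" else (val >= observed - tol)
    return RecombTestResult(
        method=stat.name, statistic=float(observed),
        p_value=float((1 + k) / (1 + n_perm)),
        n_permutations=n_perm, computable=True,
    )


def run_family_tests(
    a: GeneFamilyAlignment,
    methods: Iterable[str] = METHODS,
    n_perm: int = 1000,
    window: int = 100,
    window_unit: str = "bp",
    seed: int | None = None,
) -> dict[str, RecombTestResult]:
    """Run the requested tests on one family with a shared permutation stream.

    All tests draw their permutations from a single generator seeded by
    *seed*, mirroring the use of the same permutations across statistics, and
    reuse one incompatibility matrix.
    """
    methods = tuple(methods)
    unknown = set(methods) - set(METHODS)
    if unknown:
        raise InputError(f"unknown methods: {sorted(unknown)}")
    rng = np.random.default_rng(seed)
    shared = _SharedSiteData(a)
    out: dict[str, RecombTestResult] = {}
    for name in methods:
        stat = _TESTS[name]() if name != "PHI" else PhiTest(window, window_unit)
        out[name] = permutation_test(stat, shared, n_perm=n_perm, rng=rng)
    return out


def classify_family(
    results: Mapping[str, RecombTestResult],
    alpha: float = 0.05,
    methods: Iterable[str] = ("PHI",),
    family_id: str = "",
) -> RecombinationVerdict:
    """Classify a family from its test results.

    Single-method mode: recombinant iff p < alpha; a not-computable test
    means unclassified. Consensus mode (several methods): recombinant when
    every method calls recombinant, non-recombinant when every method calls
    non-recombinant, discarded on disagreement; any not-computable test means
    unclassified.
    """
    methods = tuple(methods)
    missing = [m for m in methods if m not in results]
    if missing:
        raise InputError(f"missing results for methods: {missing}")
    calls = []
    for m in methods:
        r = results[m]
        if not r.computable:
            return RecombinationVerdict(family_id, dict(results), "unclassified")
        calls.append(r.p_value < alpha)
    if all(calls):
        status = "recombinant"
    elif not any(calls):
        status = "non_recombinant"
    else:
        status = "discarded"
    return RecombinationVerdict(family_id, dict(results), status)
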