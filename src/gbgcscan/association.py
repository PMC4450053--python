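"""Statistical comparisons linking recombination status to base composition.

Three analyses: (i) Student's t contrasts of a composition metric between
recombinant and non-recombinant families, reported as recombinant minus
non-recombinant so a positive difference means GC enrichment of
recombinants; (ii) a cross-dataset sign test (1-df chi-squared of the
positive/non-positive split against equal expectation); (iii) the binned
correlation: families sorted by GC3 are pooled into 20 equal-size classes
and the per-bin proportion of recombinant families (P_REC, a proxy for the
bin's average recombination rate) or an externally supplied mean rate is
regressed on the bin's mean GC3 by ordinary least squares.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import InputError


@dataclass(frozen=True)
class ContrastResult:
    metric: str
    mean_difference: float  # recombinant minus non-recombinant
    t_statistic: float
    p_value: float
    n_recomb: int
    n_nonrecomb: int


@dataclass(frozen=True)
class BinSummary:
    bin_index: int  # 1-based
    mean_gc3: float
    p_rec: float
    n_genes: int
    mean_external_rate: float = math.nan


@dataclass(frozen=True)
class RegressionResult:
    slope: float
    intercept: float
    r_squared: float
    p_value: float
    n_bins: int


def compare_groups(
    recomb: Sequence[float],
    nonrecomb: Sequence[float],
    metric: str = "",
    welch: bool = False,
) -> ContrastResult:
    """Two-sided Student's t-test (pooled variance unless *welch*).

    The difference is recombinant minus non-recombinant.
    """
    r = np.asarray([v for v in recomb if not math.isnan(v)], dtype=float)
    n = np.asarray([v for v in nonrecomb if not math.isnan(v)], dtype=float)
    if r.size < 2 or n.size < 2:
        raise InputError(
            f"compare_groups({metric!r}): need >= 2 values per group, got {r.size}/{n.size}"
        )
    diff = float(r.mean() - n.mean())
    if r.var(ddof=1) == 0 and n.var(ddof=1) == 0 and diff == 0:
        t, p = 0.0, 1.0  # identical constant groups: no evidence either way
    else:
        t, p = stats.ttest_ind(r, n, equal_var=not welch)
    return ContrastResult(
        metric=metric,
        mean_difference=float(r.mean() - n.mean()),
        t_statistic=float(t),
        p_value=float(p),
        n_recomb=int(r.size),
        n_nonrecomb=int(n.size),
    )


def sign_test_across_datasets(differences: Sequence[float]) -> tuple[float, float]:
    """Chi-squared (1 df, no continuity correction) of the sign split.

    Tests whether the number of positive differences across datasets departs
    from the equal split expected by chance. Exact zeros are dropped with a
    warning.
    """
    diffs = [d for d in differences if not math.isnan(d)]
    zeros = sum(1 for d in diffs if d == 0)
    if zeros:
        warnings.warn(f"sign test: dropping {zeros} zero difference(s)", stacklevel=2)
        diffs = [d for d in diffs if d != 0]
    if not diffs:
        raise InputError("sign test: no non-zero differences")
    n_pos = sum(1 for d in diffs if d > 0)
    n_neg = len(diffs) - n_pos
    chi2, p = stats.chisquare([n_pos, n_neg])
    return float(chi2), float(p)


def bin_by_gc3(
    genes: Iterable[tuple],
    n_bins: int = 20,
) -> list[BinSummary]:
    """Pool families sorted by GC3 into *n_bins* classes of (near-)equal size.

    *genes* yields ``(family_id, gc3, status)`` or
    ``(family_id, gc3, status, rate)`` tuples with status in
    {'recombinant', 'non_recombinant'}. The sort is stable with ties broken
    by family id; when n is not divisible by *n_bins*, the first
    ``n % n_bins`` bins take one extra gene.
    """
    rows = []
    for g in genes:
        if len(g) == 3:
            fid, gc3, status = g
            rate = math.nan
        elif len(g) == 4:
            fid, gc3, status, rate = g
            rate = math.nan if rate is None else float(rate)
        else:
            raise InputError("genes must be (family_id, gc3, status[, rate]) tuples")
        if status not in ("recombinant", "non_recombinant"):
            raise InputError(f"family {fid!r}: unexpected status {status!r}")
        rows.append((str(fid), float(gc3), status, rate))
    n = len(rows)
    if n < n_bins:
        raise InputError(f"need >= {n_bins} classified families, got {n}")
    rows.sort(key=lambda r: (r[1], r[0]))
    base, extra = divmod(n, n_bins)
    out: list[BinSummary] = []
    start = 0
    for b in range(n_bins):
        size = base + (1 if b < extra else 0)
        chunk = rows[start : start + size]
        start += size
        gc3s = [r[1] for r in chunk]
        rates = [r[3] for r in chunk if not math.isnan(r[3])]
        out.append(
            BinSummary(
                bin_index=b + 1,
                mean_gc3=sum(gc3s) / size,
                p_rec=sum(1 for r in chunk if r[2] == "recombinant") / size,
                n_genes=size,
                mean_external_rate=sum(rates) / len(rates) if rates else math.nan,
            )
        )
    return out


def bin_regression(bins: Sequence[BinSummary], y: str = "p_rec") -> RegressionResult:
    """OLS of a per-bin response (p_rec or mean_external_rate) on mean GC3.

    Returns NaN fields (undefined signal) when x or y is constant.
    """
    if y not in ("p_rec", "mean_external_rate"):
        raise InputError(f"unknown response {y!r}")
    pts = [
        (b.mean_gc3, getattr(b, y))
        for b in bins
        if not (math.isnan(b.mean_gc3) or math.isnan(getattr(b, y)))
    ]
    if len(pts) < 3:
        raise InputError(f"bin_regression: need >= 3 bins with defined {y}, got {len(pts)}")
    x = np.array([p[0] for p in pts])
    yy = np.array([p[1] for p in pts])
    if np.ptp(x) == 0 or np.ptp(yy) == 0:
        return RegressionResult(math.nan, math.nan, math.nan, math.nan, len(pts))
    res = stats.linregress(x, yy)
    return RegressionResult(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
        p_value=float(res.pvalue),
        n_bins=len(pts),
    )


def ingest_external_rates(
    path: str | Path, exclude: Iterable[str] = ()
) -> dict[str, float]:
    """Read a two-column TSV of per-family recombination rates.

    *exclude* lists family ids to drop (e.g. genes whose rate estimate did
    not converge). Duplicate ids or non-numeric rates are input errors.
    """
    df = pd.read_csv(path, sep="\t")
    if df.shape[1] < 2:
        raise InputError(f"{path}: expected two columns (family_id, rate)")
    fam_col, rate_col = df.columns[0], df.columns[1]
    fams = df[fam_col].astype(str)
    if fams.duplicated().any():
        dup = sorted(fams[fams.duplicated()].unique())
        raise InputError(f"{path}: duplicate family ids: {dup[:5]}")
    rates = pd.to_numeric(df[rate_col], errors="coerce")
    if rates.isna().any():
        bad = df.loc[rates.isna(), fam_col].tolist()
        raise InputError(f"{path}: non-numeric rates for {bad[:5]}")
    drop = set(exclude)
    return {f: float(r) for f, r in zip(fams, rates) if f not in drop}


def bins_table(bins: Sequence[BinSummary]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "bin": b.bin_index,
                "mean_gc3": b.mean_gc3,
                "p_rec": b.p_rec,
                "mean_external_rate": b.mean_external_rate,
                "n_genes": b.n_genes,
            }
            for b in bins
        ]
    )
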