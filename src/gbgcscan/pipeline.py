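"""Dataset-level orchestration: trim -> detect -> composition -> codons ->
contrasts -> bins, with TSV reports and a reproducibility manifest.

Input layout (as written by :mod:`gbgcscan.simulate` and documented in the
README)::

    dataset/
      families/<family_id>.fasta   in-frame nucleotide alignments
      genomes.tsv                  genome ids (one column 'genome')
      rp_families.txt              optional, ribosomal-protein family ids
      genomes/<genome>.fna         optional, genome sequences for intergenes
      coords.tsv                   optional, gene coordinates (0-based half-open)
      rates.tsv                    optional, per-family external recombination rates
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO

from . import __version__
from .association import (
    BinSummary,
    ContrastResult,
    RegressionResult,
    bin_by_gc3,
    bin_regression,
    bins_table,
    compare_groups,
    ingest_external_rates,
)
from .codon_usage import CodonCountTable, OptimalCodonSet, fop_fnop, rp_optimal_codons
from .composition import (
    GeneCompositionRecord,
    composition_table,
    extract_gene_contexts,
    family_intergenic_gc,
    family_mean_gc,
)
from .errors import InputError, TooShortError
from .genome_io import GeneFamilyAlignment, read_family_directory, trim_central
from .recombination import METHODS, RecombinationVerdict, classify_family, run_family_tests

log = logging.getLogger("gbgcscan")


@dataclass
class PipelineConfig:
    """Flat run parameters; every field maps to a CLI flag."""

    methods: str = "phi"        # 'phi' (single test) or 'consensus' (all three)
    n_perm: int = 1000
    window: int = 100
    window_unit: str = "bp"
    alpha: float = 0.05
    trim_length: int = 900
    seed: int = 0
    delimiter: str = "|"
    min_flank: int = 50
    max_flank: int = 400
    n_bins: int = 20
    rp_alpha: float = 0.001
    welch: bool = False

    def method_tuple(self) -> tuple[str, ...]:
        if self.methods == "phi":
            return ("PHI",)
        if self.methods == "consensus":
            return METHODS
        raise InputError(f"methods must be 'phi' or 'consensus', got {self.methods!r}")


@dataclass
class DatasetReport:
    """Per-dataset counts and statistics (the Table-1-style summary)."""

    dataset_id: str
    n_families: int
    n_tested: int            # families of length >= trim_length
    n_skipped_short: int
    n_recombinant: int
    n_non_recombinant: int
    n_unclassified: int
    n_discarded: int
    mean_gc: float
    mean_gc3: float
    contrasts: list[ContrastResult] = field(default_factory=list)
    bins: list[BinSummary] = field(default_factory=list)
    regression: RegressionResult | None = None
    rate_regression: RegressionResult | None = None

    def check_additivity(self) -> None:
        total = (
            self.n_recombinant
            + self.n_non_recombinant
            + self.n_unclassified
            + self.n_discarded
        )
        if total != self.n_tested:
            raise AssertionError(
                f"count invariant violated: {total} classified vs {self.n_tested} tested"
            )


def detect_families(
    families: Sequence[GeneFamilyAlignment], config: PipelineConfig
) -> dict[str, RecombinationVerdict]:
    """Run the recombination tests on every family.

    Each family gets an independent, reproducible permutation stream derived
    from the run seed and the family's rank in sorted id order, so results do
    not depend on file-system ordering.
    """
    verdicts: dict[str, RecombinationVerdict] = {}
    methods = config.method_tuple()
    ordered = sorted(families, key=lambda f: f.family_id)
    streams = np.random.SeedSequence(config.seed).spawn(len(ordered))
    for fam, ss in zip(ordered, streams):
        seed = int(np.random.default_rng(ss).integers(0, 2**31 - 1))
        results = run_family_tests(
            fam,
            methods=methods,
            n_perm=config.n_perm,
            window=config.window,
            window_unit=config.window_unit,
            seed=seed,
        )
        verdicts[fam.family_id] = classify_family(
            results, alpha=config.alpha, methods=methods, family_id=fam.family_id
        )
        log.debug("family %s -> %s", fam.family_id, verdicts[fam.family_id].status)
    return verdicts


def _read_genome_seqs(directory: Path) -> dict[str, str]:
    out: dict[str, str] = {}
    for p in sorted(directory.glob("*.fna")):
        for rec in SeqIO.parse(str(p), "fasta"):
            out[rec.id] = str(rec.seq).upper()
    return out


def _codon_contrasts(
    families: Sequence[GeneFamilyAlignment],
    status: dict[str, str],
    rp_ids: set[str],
    rp_alpha: float,
    welch: bool,
) -> tuple[OptimalCodonSet, list[ContrastResult]]:
    rp_tab = CodonCountTable.from_seqs(
        s for f in families if f.family_id in rp_ids for s in f.seqs
    )
    other_tab = CodonCountTable.from_seqs(
        s for f in families if f.family_id not in rp_ids for s in f.seqs
    )
    oset = rp_optimal_codons(rp_tab, other_tab, alpha=rp_alpha)
    per_class: dict[str, dict[str, list[float]]] = {
        k: {"recombinant": [], "non_recombinant": []}
        for k in ("fop_gc", "fop_au", "fnop_gc", "fnop_au")
    }
    for fam in families:
        st = status.get(fam.family_id)
        if st not in ("recombinant", "non_recombinant"):
            continue
        tab = CodonCountTable.from_seqs(fam.seqs)
        if tab.total == 0:
            continue
        freqs = fop_fnop(tab, oset)
        for k in per_class:
            per_class[k][st].append(getattr(freqs, k))
    contrasts = []
    for k, groups in per_class.items():
        try:
            contrasts.append(
                compare_groups(
                    groups["recombinant"], groups["non_recombinant"], metric=k, welch=welch
                )
            )
        except InputError:
            log.warning("codon contrast %s skipped: too few classified families", k)
    return oset, contrasts


def run_dataset(
    input_dir: str | Path,
    config: PipelineConfig | None = None,
    outdir: str | Path | None = None,
    dataset_id: str | None = None,
) -> DatasetReport:
    """Execute the full analysis on one dataset directory.

    Writes, when *outdir* is given: verdicts.tsv, composition.tsv,
    contrasts.tsv, bins.tsv, optimal_codons.tsv, skips.tsv and
    manifest.json.
    """
    config = config or PipelineConfig()
    input_dir = Path(input_dir)
    fam_dir = input_dir / "families"
    if not fam_dir.is_dir():
        raise InputError(f"missing input directory: {fam_dir}")
    families = read_family_directory(fam_dir, delimiter=config.delimiter)
    did = dataset_id or input_dir.name

    # trim; families shorter than the trim length are ignored downstream
    trimmed: list[GeneFamilyAlignment] = []
    skips: list[dict] = []
    for fam in families:
        try:
            trimmed.append(trim_central(fam, config.trim_length))
        except TooShortError:
            skips.append(
                {"family_id": fam.family_id, "reason": "shorter_than_trim_length",
                 "length": fam.length}
            )
    if not trimmed:
        log.warning("dataset %s: no family reaches %d bp", did, config.trim_length)

    verdicts = detect_families(trimmed, config)
    status = {fid: v.status for fid, v in verdicts.items()}

    comps: list[GeneCompositionRecord] = [family_mean_gc(f) for f in trimmed]

    # intergenic proxy (only when annotation is available)
    coords_path = input_dir / "coords.tsv"
    genome_dir = input_dir / "genomes"
    intergenic: dict[str, float] = {}
    if coords_path.is_file() and genome_dir.is_dir():
        coords = pd.read_csv(coords_path, sep="\t")
        contexts = extract_gene_contexts(
            coords, _read_genome_seqs(genome_dir), max_flank=config.max_flank
        )
        intergenic = {
            fid: family_intergenic_gc(ctxs, min_flank=config.min_flank)
            for fid, ctxs in contexts.items()
        }
        comps = [
            GeneCompositionRecord(
                c.family_id, c.gc, c.gc1, c.gc2, c.gc3, c.n_valid,
                intergenic_gc=intergenic.get(c.family_id, math.nan),
            )
            for c in comps
        ]

    by_id = {c.family_id: c for c in comps}

    def metric_groups(attr: str) -> tuple[list[float], list[float]]:
        rec, non = [], []
        for fid, st in status.items():
            v = getattr(by_id[fid], attr)
            if st == "recombinant":
                rec.append(v)
            elif st == "non_recombinant":
                non.append(v)
        return rec, non

    contrasts: list[ContrastResult] = []
    for attr in ("gc", "gc3", "intergenic_gc"):
        rec, non = metric_groups(attr)
        try:
            contrasts.append(compare_groups(rec, non, metric=attr, welch=config.welch))
        except InputError:
            log.warning("dataset %s: contrast %s not computable", did, attr)

    # codon usage (needs RP labels)
    oset: OptimalCodonSet | None = None
    rp_path = input_dir / "rp_families.txt"
    if rp_path.is_file():
        rp_ids = {line.strip() for line in rp_path.read_text().splitlines() if line.strip()}
        if rp_ids and any(f.family_id in rp_ids for f in trimmed):
            oset, codon_contrasts = _codon_contrasts(
                trimmed, status, rp_ids, config.rp_alpha, config.welch
            )
            contrasts.extend(codon_contrasts)
        else:
            log.warning("dataset %s: no tested ribosomal-protein family; codon step skipped", did)

    # GC3 bins and regression
    rates_path = input_dir / "rates.tsv"
    rates = ingest_external_rates(rates_path) if rates_path.is_file() else {}
    classified = [
        (fid, by_id[fid].gc3, st, rates.get(fid, math.nan))
        for fid, st in status.items()
        if st in ("recombinant", "non_recombinant") and not math.isnan(by_id[fid].gc3)
    ]
    bins: list[BinSummary] = []
    regression = rate_regression = None
    if len(classified) >= config.n_bins:
        bins = bin_by_gc3(classified, n_bins=config.n_bins)
        regression = bin_regression(bins, y="p_rec")
        if rates:
            rate_regression = bin_regression(bins, y="mean_external_rate")
    else:
        log.warning(
            "dataset %s: %d classified families < %d bins, skipping regression",
            did, len(classified), config.n_bins,
        )

    counts = {s: sum(1 for v in status.values() if v == s)
              for s in ("recombinant", "non_recombinant", "unclassified", "discarded")}
    gcs = [c.gc for c in comps if not math.isnan(c.gc)]
    gc3s = [c.gc3 for c in comps if not math.isnan(c.gc3)]
    report = DatasetReport(
        dataset_id=did,
        n_families=len(families),
        n_tested=len(trimmed),
        n_skipped_short=len(skips),
        n_recombinant=counts["recombinant"],
        n_non_recombinant=counts["non_recombinant"],
        n_unclassified=counts["unclassified"],
        n_discarded=counts["discarded"],
        mean_gc=sum(gcs) / len(gcs) if gcs else math.nan,
        mean_gc3=sum(gc3s) / len(gc3s) if gc3s else math.nan,
        contrasts=contrasts,
        bins=bins,
        regression=regression,
        rate_regression=rate_regression,
    )
    report.check_additivity()

    if outdir is not None:
        _write_outputs(Path(outdir), report, verdicts, comps, skips, oset, config)
    return report


def _write_outputs(outdir, report, verdicts, comps, skips, oset, config) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    rows = []
    for fid in sorted(verdicts):
        v = verdicts[fid]
        row = {"family_id": fid, "status": v.status}
        for m, r in v.results.items():
            row[f"{m}_stat"] = r.statistic
            row[f"{m}_p"] = r.p_value
        rows.append(row)
    pd.DataFrame(rows).to_csv(outdir / "verdicts.tsv", sep="\t", index=False)
    composition_table(comps).to_csv(outdir / "composition.tsv", sep="\t", index=False)
    pd.DataFrame([asdict(c) for c in report.contrasts]).to_csv(
        outdir / "contrasts.tsv", sep="\t", index=False
    )
    if report.bins:
        bins_table(report.bins).to_csv(outdir / "bins.tsv", sep="\t", index=False)
    if skips:
        pd.DataFrame(skips).to_csv(outdir / "skips.tsv", sep="\t", index=False)
    if oset is not None:
        oset.write_tsv(outdir / "optimal_codons.tsv")
    manifest = {
        "package": "gbgcscan",
        "version": __version__,
        "dataset_id": report.dataset_id,
        "parameters": asdict(config),
        "counts": {
            "families": report.n_families,
            "tested": report.n_tested,
            "skipped_short": report.n_skipped_short,
            "recombinant": report.n_recombinant,
            "non_recombinant": report.n_non_recombinant,
            "unclassified": report.n_unclassified,
            "discarded": report.n_discarded,
        },
        "regression": asdict(report.regression) if report.regression else None,
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
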