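"""Synthetic genome groups with clonal genealogies, AT-biased mutation,
gene-conversion tracts and a tunable GC-transmission bias.

The generator emulates the statistical structure the pipeline assumes in
closely related bacterial genomes:

* one neutral-coalescent **clonal genealogy** per group (msprime), shared by
  every gene family;
* a **two-state GC/AT substitution process** per site, layered onto a
  four-letter emission (each site is assigned one AT letter and one GC
  letter), with AT->GC rate proportional to kappa(B) and GC->AT to
  lambda * kappa(-B) so the stationary GC content is
  1 / (1 + lambda * exp(-B));
* **codon structure**: first and second codon positions evolve at a reduced
  rate and with a damped conversion bias (purifying selection on amino
  acids), so GC3 responds to gBGC more than GC1/GC2;
* **gene conversion** as unidirectional tract transfer between extant
  lineages; at GC/AT-heterozygous sites inside a tract the GC allele is
  retained with probability p_gc regardless of which lineage donates;
* two **per-gene conversion-rate classes** (low/high); high-rate genes both
  receive more tracts and, when p_gc > 0.5, evolve under a higher effective
  B (their long-term composition reflects the conversion bias);
* **ribosomal-protein labels** with an enriched optimal-codon profile at the
  root, giving the RP chi-squared method signal;
* **intergenes** between consecutive genes, evolving without codon structure
  under the mean bias of their flanking genes.

All randomness flows from a single seed through named per-family streams, so
identical configurations yield byte-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import msprime
import numpy as np
import pandas as pd
import yaml

from .codon_usage import SYNONYM_FAMILIES, third_base_class
from .errors import InputError
from .genome_io import GeneFamilyAlignment, GenomeGroup
from .popgen import b0_from_pgc, equilibrium_gc, fixation_bias_factor

#: planted "true" optimal codon per degenerate amino acid (synthetic profile,
#: a mixture of GC- and AU-ending choices loosely modelled on fast-growing
#: bacteria; configurable through SimulationConfig.optimal_codons)
DEFAULT_OPTIMAL_CODONS: dict[str, str] = {
    "F": "TTC", "L": "CTG", "I": "ATC", "V": "GTT", "S": "TCT", "P": "CCG",
    "T": "ACT", "A": "GCA", "Y": "TAC", "H": "CAC", "Q": "CAG", "N": "AAC",
    "K": "AAA", "D": "GAC", "E": "GAA", "C": "TGC", "R": "CGT", "G": "GGT",
}


# ---------------------------------------------------------------------------
# clonal genealogy


@dataclass(frozen=True)
class CoalescentTree:
    """A rooted genealogy in array form (times in coalescent units)."""

    n_leaves: int
    parent: np.ndarray        # parent[u] = -1 for the root
    time: np.ndarray          # node times, leaves at 0
    preorder: np.ndarray      # root first
    leaf_names: tuple[str, ...]
    newick: str

    @property
    def n_nodes(self) -> int:
        return int(self.parent.size)

    def branch_length(self, u: int) -> float:
        p = int(self.parent[u])
        if p < 0:
            return 0.0
        return float(self.time[p] - self.time[u])

    @property
    def total_branch_length(self) -> float:
        return sum(self.branch_length(u) for u in range(self.n_nodes))


def simulate_clonal_tree(n_genomes: int, seed: int) -> CoalescentTree:
    """Standard neutral coalescent genealogy for *n_genomes* haploid lineages.

    Deterministic under *seed*; leaf u is named ``g{u+1:02d}``.
    """
    if n_genomes < 2:
        raise InputError("need at least 2 genomes")
    ts = msprime.sim_ancestry(
        samples=n_genomes, ploidy=1, population_size=1.0, random_seed=int(seed)
    )
    t = ts.first()
    n_nodes = ts.num_nodes
    parent = np.array([t.parent(u) for u in range(n_nodes)], dtype=np.int64)
    parent[parent == -1] = -1
    names = tuple(f"g{u + 1:02d}" for u in range(n_genomes))
    return CoalescentTree(
        n_leaves=n_genomes,
        parent=parent,
        time=ts.nodes_time.copy(),
        preorder=np.asarray(t.preorder(), dtype=np.int64),
        leaf_names=names,
        newick=t.as_newick(precision=6),
    )


# ---------------------------------------------------------------------------
# sequence evolution


def _site_rates(
    theta: float | np.ndarray, lambda_mut: float, B: float | np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Per-site total rate q and stationary GC probability pi."""
    theta = np.asarray(theta, dtype=float)
    B = np.asarray(B, dtype=float)
    kap = np.vectorize(fixation_bias_factor)
    q01 = theta * kap(B) / (1.0 + lambda_mut)          # AT -> GC
    q10 = theta * lambda_mut * kap(-B) / (1.0 + lambda_mut)  # GC -> AT
    q = q01 + q10
    with np.errstate(invalid="ignore", divide="ignore"):
        pi = np.where(q > 0, q01 / np.where(q > 0, q, 1.0), 0.5)
    return q, pi


def _evolve_states(
    tree: CoalescentTree,
    q: np.ndarray,
    pi: np.ndarray,
    rng: np.random.Generator,
    root_states: np.ndarray | None = None,
) -> np.ndarray:
    """Simulate the two-state process down the tree; returns (n_leaves, L)."""
    L = q.size
    states = np.zeros((tree.n_nodes, L), dtype=np.int8)
    for u in tree.preorder:
        p = int(tree.parent[u])
        if p < 0:
            if root_states is not None:
                states[u] = root_states
            else:
                states[u] = rng.random(L) < pi
        else:
            t = tree.branch_length(u)
            decay = np.exp(-q * t)
            p1 = pi + decay * (states[p] - pi)
            states[u] = rng.random(L) < p1
    return states[: tree.n_leaves]


def _states_to_seqs(states: np.ndarray, at_letters: np.ndarray, gc_letters: np.ndarray) -> list[str]:
    letters = np.where(states.astype(bool), gc_letters, at_letters)
    return ["".join(row) for row in letters]


def evolve_sequences(
    tree: CoalescentTree,
    length: int,
    theta: float,
    lambda_mut: float,
    B: float,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
    rate_scale: np.ndarray | None = None,
    site_B: np.ndarray | None = None,
    root_seq: str | None = None,
    family_id: str = "sim",
) -> GeneFamilyAlignment:
    """Evolve an alignment of *length* sites along *tree*.

    The root is drawn from the stationary distribution unless *root_seq* is
    given. *rate_scale* (per-site multiplier of theta) and *site_B* (per-site
    B overriding the scalar) implement codon-position structure.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    theta_arr = np.full(length, float(theta))
    if rate_scale is not None:
        theta_arr = theta_arr * np.asarray(rate_scale, dtype=float)
    B_arr = np.full(length, float(B)) if site_B is None else np.asarray(site_B, dtype=float)
    q, pi = _site_rates(theta_arr, lambda_mut, B_arr)

    if root_seq is not None:
        if len(root_seq) != length:
            raise InputError("root_seq length mismatch")
        root = np.array(list(root_seq.upper()), dtype="U1")
        is_gc = np.isin(root, ["G", "C"])
        gc_letters = np.where(is_gc, root, rng.choice(np.array(["G", "C"]), size=length))
        at_letters = np.where(~is_gc, root, rng.choice(np.array(["A", "T"]), size=length))
        root_states = is_gc.astype(np.int8)
    else:
        gc_letters = rng.choice(np.array(["G", "C"]), size=length)
        at_letters = rng.choice(np.array(["A", "T"]), size=length)
        root_states = None

    states = _evolve_states(tree, q, pi, rng, root_states)
    seqs = _states_to_seqs(states, at_letters, gc_letters)
    return GeneFamilyAlignment(family_id=family_id, taxa=tree.leaf_names, seqs=tuple(seqs))


def sample_codon_root(
    n_codons: int,
    rng: np.random.Generator,
    pi3: float,
    optimal_codons: dict[str, str] | None = None,
    optimal_weight: float = 1.0,
) -> str:
    """Draw a root coding sequence codon by codon.

    Amino acids are uniform; within an amino acid, codon weights follow the
    third-base stationary composition (pi3 for GC-ending) times
    *optimal_weight* for the planted optimal codon (ribosomal-protein
    profile).
    """
    aas = sorted(SYNONYM_FAMILIES)
    chosen_aas = rng.choice(len(aas), size=n_codons)
    parts = []
    for ai in chosen_aas:
        codons = SYNONYM_FAMILIES[aas[ai]]
        w = np.array(
            [pi3 if third_base_class(c) == "GC_ending" else 1.0 - pi3 for c in codons]
        )
        if optimal_codons:
            opt = optimal_codons.get(aas[ai])
            if opt is not None:
                w = w * np.where(np.array(codons) == opt, optimal_weight, 1.0)
        w = w / w.sum()
        parts.append(codons[rng.choice(len(codons), p=w)])
    return "".join(parts)


# ---------------------------------------------------------------------------
# gene conversion


@dataclass(frozen=True)
class ConversionEvent:
    donor: str
    recipient: str
    start: int  # 0-based half-open tract
    end: int
    n_het: int       # GC/AT-heterozygous sites in the tract
    n_to_gc: int     # het sites resolved to the GC allele


def apply_gene_conversion(
    a: GeneFamilyAlignment,
    n_events: int,
    tract_length: int,
    p_gc: float,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[GeneFamilyAlignment, list[ConversionEvent]]:
    """Apply *n_events* conversion tracts between random extant lineages.

    Within a tract the recipient takes the donor's sites, except that at
    GC/AT-heterozygous sites the GC allele is retained with probability
    *p_gc* whichever lineage carries it. Alignment length and taxa are
    unchanged.
    """
    if n_events < 0:
        raise InputError("n_events must be >= 0")
    if tract_length > a.length:
        raise InputError(f"tract length {tract_length} exceeds alignment length {a.length}")
    if not 0.0 <= p_gc <= 1.0:
        raise InputError("p_gc must lie in [0, 1]")
    if rng is None:
        rng = np.random.default_rng(seed)
    mat = np.array([list(s) for s in a.seqs], dtype="U1")
    events: list[ConversionEvent] = []
    for _ in range(n_events):
        donor, recipient = rng.choice(a.n_seqs, size=2, replace=False)
        start = int(rng.integers(0, a.length - tract_length + 1))
        end = start + tract_length
        d = mat[donor, start:end]
        r = mat[recipient, start:end]
        d_gc = np.isin(d, ["G", "C"])
        r_gc = np.isin(r, ["G", "C"])
        differ = d != r
        het = differ & (d_gc != r_gc)
        same_class = differ & ~het
        new = r.copy()
        new[same_class] = d[same_class]  # plain conversion, no bias possible
        take_gc = rng.random(het.sum()) < p_gc
        gc_allele = np.where(d_gc[het], d[het], r[het])
        at_allele = np.where(d_gc[het], r[het], d[het])
        new[np.nonzero(het)[0]] = np.where(take_gc, gc_allele, at_allele)
        mat[recipient, start:end] = new
        events.append(
            ConversionEvent(
                donor=a.taxa[donor],
                recipient=a.taxa[recipient],
                start=start,
                end=end,
                n_het=int(het.sum()),
                n_to_gc=int(take_gc.sum()),
            )
        )
    seqs = tuple("".join(row) for row in mat)
    return GeneFamilyAlignment(family_id=a.family_id, taxa=a.taxa, seqs=seqs), events


# ---------------------------------------------------------------------------
# whole-dataset generation


@dataclass
class SimulationConfig:
    """Study conditions of the synthetic genome group.

    Defaults describe a group of 10 closely related genomes (pairwise
    diversity a few percent), AT-biased mutation (lambda = 2), 900-bp
    in-frame genes in two conversion-rate classes differing 4-fold, and
    200-bp conversion tracts. ``p_gc = 0.5`` is the unbiased null; the
    effective per-gene bias is B = b_scale * b0 * conv_rate * L / gene_length.
    """

    n_genomes: int = 10
    n_families: int = 200
    gene_length: int = 900
    theta: float = 0.05
    lambda_mut: float = 2.0
    conv_rate_low: float = 1.0     # expected conversion events per family
    conv_rate_high: float = 4.0
    high_rate_fraction: float = 0.5
    tract_length: int = 200
    p_gc: float = 0.5
    rp_fraction: float = 0.1
    intergene_length: int = 200
    pos12_factor: float = 0.25     # rate and bias damping at codon positions 1-2
    rp_codon_weight: float = 3.0
    b_scale: float = 2.0
    seed: int = 0
    optimal_codons: dict[str, str] = field(
        default_factory=lambda: dict(DEFAULT_OPTIMAL_CODONS)
    )

    def __post_init__(self) -> None:
        if self.n_genomes < 6:
            raise InputError("a genome group needs >= 6 members")
        if self.gene_length % 3 != 0:
            raise InputError("gene_length must be a multiple of 3")
        if min(self.theta, self.conv_rate_low, self.conv_rate_high) < 0:
            raise InputError("rates must be >= 0")
        if not 0.0 <= self.p_gc <= 1.0:
            raise InputError("p_gc must lie in [0, 1]")
        if self.tract_length > self.gene_length:
            raise InputError("tract_length exceeds gene_length")

    @property
    def b0(self) -> float:
        return b0_from_pgc(self.p_gc)

    def effective_b(self, conv_rate: float) -> float:
        """Per-gene population-scaled bias implied by its conversion rate."""
        return self.b_scale * self.b0 * conv_rate * self.tract_length / self.gene_length

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimulationConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise InputError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)


@dataclass
class SimulatedGroup:
    """A synthetic genome group plus its ground truth."""

    group: GenomeGroup
    intergenes: dict[str, GeneFamilyAlignment]
    truth: pd.DataFrame  # family_id, rate_class, conv_rate, n_events, b_eff, eq_gc3, is_rp
    tree: CoalescentTree
    config: SimulationConfig

    @property
    def rp_family_ids(self) -> list[str]:
        return sorted(self.truth.loc[self.truth.is_rp, "family_id"])


def simulate_family(
    tree: CoalescentTree,
    config: SimulationConfig,
    conv_rate: float,
    is_rp: bool,
    rng: np.random.Generator,
    family_id: str,
) -> tuple[GeneFamilyAlignment, GeneFamilyAlignment, int]:
    """One coding family plus its downstream intergene; returns event count."""
    L = config.gene_length
    b_eff = config.effective_b(conv_rate)
    pi3 = equilibrium_gc(config.lambda_mut, b_eff)
    root = sample_codon_root(
        L // 3,
        rng,
        pi3,
        optimal_codons=config.optimal_codons if is_rp else None,
        optimal_weight=config.rp_codon_weight if is_rp else 1.0,
    )
    rate_scale = np.where(np.arange(L) % 3 == 2, 1.0, config.pos12_factor)
    site_B = np.where(np.arange(L) % 3 == 2, b_eff, b_eff * config.pos12_factor)
    gene = evolve_sequences(
        tree, L, config.theta, config.lambda_mut, b_eff,
        rng=rng, rate_scale=rate_scale, site_B=site_B,
        root_seq=root, family_id=family_id,
    )
    n_events = int(rng.poisson(conv_rate))
    gene, _events = apply_gene_conversion(
        gene, n_events, config.tract_length, config.p_gc, rng=rng
    )
    intergene = evolve_sequences(
        tree, config.intergene_length, config.theta, config.lambda_mut, b_eff,
        rng=rng, family_id=f"{family_id}_ig",
    )
    return gene, intergene, n_events


def simulate_dataset(config: SimulationConfig) -> SimulatedGroup:
    """Generate a full genome group under *config* (deterministic in seed)."""
    master = np.random.SeedSequence(config.seed)
    tree_ss, assign_ss, *fam_ss = master.spawn(2 + config.n_families)
    tree_seed = int(np.random.default_rng(tree_ss).integers(1, 2**31 - 1))
    tree = simulate_clonal_tree(config.n_genomes, tree_seed)

    assign_rng = np.random.default_rng(assign_ss)
    n_high = round(config.high_rate_fraction * config.n_families)
    classes = np.array(["low"] * (config.n_families - n_high) + ["high"] * n_high)
    assign_rng.shuffle(classes)
    n_rp = round(config.rp_fraction * config.n_families)
    rp_flags = np.zeros(config.n_families, dtype=bool)
    rp_flags[assign_rng.choice(config.n_families, size=n_rp, replace=False)] = True

    families: list[GeneFamilyAlignment] = []
    intergenes: dict[str, GeneFamilyAlignment] = {}
    rows = []
    width = len(str(config.n_families))
    for i in range(config.n_families):
        fid = f"fam{i + 1:0{width}d}"
        conv_rate = config.conv_rate_high if classes[i] == "high" else config.conv_rate_low
        rng = np.random.default_rng(fam_ss[i])
        gene, intergene, n_events = simulate_family(
            tree, config, conv_rate, bool(rp_flags[i]), rng, fid
        )
        families.append(gene)
        intergenes[fid] = intergene
        rows.append(
            {
                "family_id": fid,
                "rate_class": classes[i],
                "conv_rate": conv_rate,
                "n_events": n_events,
                "b_eff": config.effective_b(conv_rate),
                "eq_gc3": equilibrium_gc(config.lambda_mut, config.effective_b(conv_rate)),
                "is_rp": bool(rp_flags[i]),
            }
        )
    group = GenomeGroup(group_id="sim", genomes=tree.leaf_names, families=families)
    return SimulatedGroup(
        group=group,
        intergenes=intergenes,
        truth=pd.DataFrame(rows),
        tree=tree,
        config=config,
    )


def write_dataset(sim: SimulatedGroup, outdir: str | Path) -> Path:
    """Write the directory layout the pipeline reads.

    families/<id>.fasta, genomes/<genome>.fna (genes and intergenes
    concatenated), coords.tsv (0-based half-open), genomes.tsv,
    rp_families.txt, truth.tsv, tree.nwk, config.yml.
    """
    outdir = Path(outdir)
    (outdir / "families").mkdir(parents=True, exist_ok=True)
    (outdir / "genomes").mkdir(exist_ok=True)
    for fam in sim.group.families:
        with open(outdir / "families" / f"{fam.family_id}.fasta", "w") as fh:
            for taxon, seq in zip(fam.taxa, fam.seqs):
                fh.write(f">{taxon}|{fam.family_id}_{taxon}\n{seq}\n")
    coords = []
    for gi, genome in enumerate(sim.group.genomes):
        parts = []
        pos = 0
        for fam in sim.group.families:
            gene_seq = fam.seqs[fam.taxa.index(genome)]
            ig_seq = sim.intergenes[fam.family_id].seqs[gi]
            coords.append(
                {
                    "gene_id": f"{fam.family_id}_{genome}",
                    "family_id": fam.family_id,
                    "genome": genome,
                    "seqid": genome,
                    "start": pos,
                    "end": pos + len(gene_seq),
                    "strand": "+",
                }
            )
            parts.append(gene_seq)
            parts.append(ig_seq)
            pos += len(gene_seq) + len(ig_seq)
        with open(outdir / "genomes" / f"{genome}.fna", "w") as fh:
            fh.write(f">{genome}\n{''.join(parts)}\n")
    pd.DataFrame(coords).to_csv(outdir / "coords.tsv", sep="\t", index=False)
    pd.DataFrame({"genome": sim.group.genomes}).to_csv(
        outdir / "genomes.tsv", sep="\t", index=False
    )
    with open(outdir / "rp_families.txt", "w") as fh:
        fh.writelines(f"{fid}\n" for fid in sim.rp_family_ids)
    sim.truth.to_csv(outdir / "truth.tsv", sep="\t", index=False)
    (outdir / "tree.nwk").write_text(sim.tree.newick + "\n")
    sim.config.to_yaml(outdir / "config.yml")
    return outdir
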