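"""Synthetic barcoded-library and pangenome data generators.

This module emulates the data a survival-fitness experiment with a randomly
barcoded transposon insertion (RB-TnSeq) library produces: a table of barcode
counts across reference and post-challenge outgrowth samples, with known
(planted) per-gene fitness effects so that the downstream estimators can be
validated by parameter recovery.  It also generates binary ortholog
presence/absence matrices emulating a multi-genome pangenome.

Randomness is driven by a single integer seed through
:class:`numpy.random.SeedSequence` spawning, so every sub-simulation is
independently reproducible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import CountTable

__all__ = [
    "LibraryDesign",
    "EffectModel",
    "SequencingModel",
    "simulate_library",
    "simulate_survival_experiment",
    "expected_abundances",
    "expected_strain_log_ratios",
    "simulate_pangenome",
    "simulate_nested_pangenome",
    "simulate_gene_context",
]

#: Default scaffold layout: a chromosome plus three plasmids of decreasing
#: size, mimicking an Enterobacteriaceae genome with a large accessory
#: plasmid complement.  Weights are relative gene allocations.
DEFAULT_SCAFFOLD_WEIGHTS = {
    "chromosome": 3558,
    "plasmid_1": 496,
    "plasmid_2": 110,
    "plasmid_3": 5,
}


@dataclass
class LibraryDesign:
    """Design of a barcoded transposon insertion library.

    Parameters
    ----------
    n_genes
        Number of genes with at least a chance of carrying insertions.
    strains_per_gene_mean
        Mean number of insertion strains per gene.
    strains_per_gene_dispersion
        Dispersion of the per-gene strain count.  Counts are drawn from a
        negative binomial with this mean/dispersion, then floored at 1 so
        every gene has at least one strain.  ``dispersion=0`` gives a
        Poisson draw; ``None`` makes the count deterministic (exactly the
        mean, which must then be an integer).
    central_fraction
        Fraction of strains whose insertion lands in the central 10-90% of
        the gene (the window retained by downstream quality control).
    n_scaffolds
        Number of replicons; genes are allocated proportionally to
        ``scaffold_weights`` (default: chromosome + 3 plasmids).
    """

    n_genes: int
    strains_per_gene_mean: float = 10.0
    strains_per_gene_dispersion: float | None = None
    central_fraction: float = 0.9
    n_scaffolds: int = 4
    scaffold_weights: dict[str, float] | None = None

    def __post_init__(self) -> None:
        if self.n_genes < 1:
            raise ValueError("n_genes must be >= 1")
        if self.strains_per_gene_mean < 1:
            raise ValueError("strains_per_gene_mean must be >= 1")
        if not 0.0 <= self.central_fraction <= 1.0:
            raise ValueError("central_fraction must be in [0, 1]")
        if self.n_scaffolds < 1:
            raise ValueError("n_scaffolds must be >= 1")


def _random_barcodes(n: int, rng: np.random.Generator, length: int = 20) -> list[str]:
    """Unique random DNA barcodes of fixed length."""
    alphabet = np.array(list("ACGT"))
    seen: set[str] = set()
    out: list[str] = []
    while len(out) < n:
        batch = rng.integers(0, 4, size=(n - len(out), length))
        for row in batch:
            bc = "".join(alphabet[row])
            if bc not in seen:
                seen.add(bc)
                out.append(bc)
    return out


def simulate_library(design: LibraryDesign, seed: int | np.random.SeedSequence = 0) -> pd.DataFrame:
    """Simulate a barcoded insertion library.

    Returns a strain table with one row per insertion mutant and columns
    ``barcode``, ``gene_id``, ``scaffold``, ``position_fraction`` (insertion
    position as a fraction of gene length).  Reproducible for a fixed seed.
    """
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    rng = np.random.default_rng(ss)

    weights = design.scaffold_weights
    if weights is None:
        names = list(DEFAULT_SCAFFOLD_WEIGHTS)[: design.n_scaffolds]
        if design.n_scaffolds > len(names):
            names += [f"scaffold_{i}" for i in range(len(names), design.n_scaffolds)]
        weights = {n: DEFAULT_SCAFFOLD_WEIGHTS.get(n, 100.0) for n in names}
    scaff_names = list(weights)
    p = np.asarray([weights[n] for n in scaff_names], dtype=float)
    p /= p.sum()
    gene_scaffold = rng.choice(len(scaff_names), size=design.n_genes, p=p)

    mean = design.strains_per_gene_mean
    disp = design.strains_per_gene_dispersion
    if disp is None:
        if abs(mean - round(mean)) > 1e-9:
            raise ValueError("deterministic strains_per_gene requires an integer mean")
        counts = np.full(design.n_genes, int(round(mean)))
    elif disp == 0:
        counts = np.maximum(rng.poisson(mean, size=design.n_genes), 1)
    else:
        # NB parameterized by mean m and dispersion k: var = m + m^2/k
        k = disp
        p_nb = k / (k + mean)
        counts = np.maximum(rng.negative_binomial(k, p_nb, size=design.n_genes), 1)

    gene_ids = [f"g{i:05d}" for i in range(design.n_genes)]
    rows_gene = np.repeat(np.arange(design.n_genes), counts)
    n_strains = int(counts.sum())

    central = rng.random(n_strains) < design.central_fraction
    pos = np.empty(n_strains)
    pos[central] = rng.uniform(0.1, 0.9, size=int(central.sum()))
    # edge insertions: uniform over the two 10% tails
    n_edge = int((~central).sum())
    tail = rng.uniform(0.0, 0.2, size=n_edge)
    pos[~central] = np.where(tail < 0.1, tail, tail + 0.8)

    table = pd.DataFrame(
        {
            "barcode": _random_barcodes(n_strains, rng),
            "gene_id": [gene_ids[i] for i in rows_gene],
            "scaffold": [scaff_names[gene_scaffold[i]] for i in rows_gene],
            "position_fraction": pos,
        }
    )
    return table


@dataclass
class EffectModel:
    """Planted per-gene fitness effects as quadratic functions of a gradient.

    The effect of a gene at gradient value ``x`` is ``a0 + a1*x + a2*x**2``
    (log2 relative-abundance change of its mutants during the challenge),
    clipped to ``max_effect`` in magnitude.  Null genes have all coefficients
    zero.
    """

    coefficients: pd.DataFrame  # index gene_id, columns a0, a1, a2
    max_effect: float = 8.0

    def __post_init__(self) -> None:
        missing = {"a0", "a1", "a2"} - set(self.coefficients.columns)
        if missing:
            raise ValueError(f"coefficient table missing columns: {sorted(missing)}")
        if self.max_effect <= 0:
            raise ValueError("max_effect must be positive")

    @classmethod
    def null(cls, gene_ids: list[str]) -> "EffectModel":
        coef = pd.DataFrame(0.0, index=pd.Index(gene_ids, name="gene_id"), columns=["a0", "a1", "a2"])
        return cls(coef)

    @classmethod
    def constant(cls, gene_ids: list[str], effects: dict[str, float], max_effect: float = 8.0) -> "EffectModel":
        """All-null model with constant (gradient-independent) effects planted
        for the genes in ``effects``."""
        model = cls.null(gene_ids)
        model.max_effect = max_effect
        for g, e in effects.items():
            if g not in model.coefficients.index:
                raise KeyError(f"unknown gene {g!r}")
            model.coefficients.loc[g, "a0"] = e
        return model

    @classmethod
    def quadratic(cls, gene_ids: list[str], coef: dict[str, tuple[float, float, float]],
                  max_effect: float = 8.0) -> "EffectModel":
        model = cls.null(gene_ids)
        model.max_effect = max_effect
        for g, (a0, a1, a2) in coef.items():
            model.coefficients.loc[g, ["a0", "a1", "a2"]] = [a0, a1, a2]
        return model

    def effect_at(self, x: float) -> pd.Series:
        """Per-gene effect (log2) at gradient value ``x``."""
        c = self.coefficients
        e = c["a0"] + c["a1"] * x + c["a2"] * x**2
        return e.clip(-self.max_effect, self.max_effect)

    @property
    def null_fraction(self) -> float:
        return float((self.coefficients == 0).all(axis=1).mean())


@dataclass
class SequencingModel:
    """Sampling model for barcode sequencing of reference and outgrowth pools.

    Each sample is an independent multinomial draw of ``depth`` reads over the
    strains' relative abundances, so column sums of simulated counts equal the
    configured depth exactly.  The challenge is run in five replicate vials
    per condition against six pooled reference samples, mirroring the
    quintuplet-vial / six-reference experimental design.
    """

    depth: int = 1_000_000
    replicates: int = 5
    reference_samples: int = 6
    baseline_sigma: float = 0.5  # lognormal sd of strain baseline abundances

    def __post_init__(self) -> None:
        if self.depth <= 0:
            raise ValueError("depth must be positive")
        if self.replicates < 1 or self.reference_samples < 1:
            raise ValueError("replicates and reference_samples must be >= 1")


def _baseline_abundances(n_strains: int, sigma: float, rng: np.random.Generator) -> np.ndarray:
    """Uneven (lognormal) baseline strain abundances, normalized to sum 1."""
    a = rng.lognormal(mean=0.0, sigma=sigma, size=n_strains)
    return a / a.sum()


def expected_abundances(
    library: pd.DataFrame,
    effects: EffectModel,
    gradient_value: float,
    baseline: np.ndarray,
) -> np.ndarray:
    """Exact post-challenge relative strain abundances (infinite-depth limit).

    Each strain's abundance is its baseline multiplied by ``2**effect`` of its
    gene at the gradient value, renormalized to sum to 1 — what sequencing of
    the survivor pool measures.
    """
    e = effects.effect_at(gradient_value)
    strain_effect = e.reindex(library["gene_id"]).to_numpy()
    post = baseline * np.exp2(strain_effect)
    return post / post.sum()


def expected_strain_log_ratios(
    library: pd.DataFrame,
    effects: EffectModel,
    gradient_value: float,
    baseline: np.ndarray,
) -> np.ndarray:
    """Analytic per-strain log2(post/baseline) abundance ratios.

    Equals the planted effect minus the compositional offset
    ``log2(sum_j baseline_j * 2**effect_j)`` induced by renormalization.
    """
    post = expected_abundances(library, effects, gradient_value, baseline)
    return np.log2(post) - np.log2(baseline)


def simulate_survival_experiment(
    library: pd.DataFrame,
    effects: EffectModel,
    gradient: list[float],
    seq: SequencingModel | None = None,
    axis: str = "time_h",
    seed: int | np.random.SeedSequence = 0,
) -> CountTable:
    """Simulate a survival challenge across a condition gradient.

    Reference samples are multinomial draws from the baseline abundances;
    for each condition value, post-challenge abundances are the baseline
    scaled by ``2**effect`` per strain and renormalized, and each replicate
    vial is an independent multinomial draw at the configured depth.

    Parameters
    ----------
    library
        Strain table from :func:`simulate_library`.
    effects
        Planted per-gene effects; every gene in the library must be covered.
    gradient
        Ordered condition values along ``axis`` (e.g. hours, pH, mM glucose).
    seq
        Depth/replication model (defaults: depth 1e6, 5 replicate vials,
        6 reference samples).
    axis
        Name of the gradient axis recorded in the sample metadata.

    Returns
    -------
    CountTable
        Counts plus sample metadata (role, condition axis/value, replicate).
    """
    if len(library) == 0:
        raise ValueError("library is empty")
    if len(gradient) == 0:
        raise ValueError("gradient is empty")
    seq = seq or SequencingModel()
    missing = set(library["gene_id"]) - set(effects.coefficients.index)
    if missing:
        raise ValueError(f"effects missing for genes: {sorted(missing)[:5]} ...")

    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    ss_base, ss_ref, ss_out = ss.spawn(3)
    rng_base = np.random.default_rng(ss_base)
    rng_ref = np.random.default_rng(ss_ref)
    rng_out = np.random.default_rng(ss_out)

    baseline = _baseline_abundances(len(library), seq.baseline_sigma, rng_base)

    counts: dict[str, np.ndarray] = {}
    meta_rows: list[dict] = []
    for i in range(seq.reference_samples):
        sid = f"ref_{i + 1}"
        counts[sid] = rng_ref.multinomial(seq.depth, baseline)
        meta_rows.append(
            {"sample_id": sid, "role": "reference", "condition_axis": "",
             "condition_value": np.nan, "replicate": i + 1}
        )
    for value in gradient:
        post = expected_abundances(library, effects, value, baseline)
        for r in range(seq.replicates):
            sid = f"{axis}_{value:g}_r{r + 1}"
            counts[sid] = rng_out.multinomial(seq.depth, post)
            meta_rows.append(
                {"sample_id": sid, "role": "outgrowth", "condition_axis": axis,
                 "condition_value": float(value), "replicate": r + 1}
            )

    strains = library.set_index("barcode")
    count_df = pd.DataFrame(counts, index=strains.index)
    samples = pd.DataFrame(meta_rows).set_index("sample_id")
    return CountTable(strains=strains, counts=count_df, samples=samples)


def simulate_gene_context(
    library: pd.DataFrame,
    matrix: pd.DataFrame,
    island_fraction: float = 0.06,
    unclustered_fraction: float = 0.01,
    seed: int | np.random.SeedSequence = 0,
) -> pd.DataFrame:
    """Synthetic gene-context table for the focal strain.

    Maps each gene to a genomic location derived from its scaffold
    (chromosomal genes fall inside a predicted genomic island with
    probability ``island_fraction``; plasmid scaffolds map to
    ``plasmid:<name>``) and assigns it an ortholog cluster drawn from the
    presence/absence matrix, leaving a small fraction unclustered
    (focal-strain singletons).  Higher-prevalence clusters are preferred for
    chromosomal genes and rarer clusters for island/plasmid genes, mimicking
    accessory genes travelling on mobile elements.
    """
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    rng = np.random.default_rng(ss)
    genes = library.drop_duplicates("gene_id")[["gene_id", "scaffold"]].reset_index(drop=True)

    location = []
    for scaff in genes["scaffold"]:
        if scaff == "chromosome":
            location.append(
                "genomic_island" if rng.random() < island_fraction else "chromosome"
            )
        else:
            location.append(f"plasmid:{scaff}")
    genes["location"] = location

    prev = matrix.sum(axis=1).to_numpy(dtype=float)
    n = matrix.shape[1]
    cluster_ids = matrix.index.to_numpy()
    cluster = []
    for loc in genes["location"]:
        if rng.random() < unclustered_fraction:
            cluster.append("")
            continue
        # conserved genes for the chromosome, accessory-biased elsewhere
        w = prev / n if loc == "chromosome" else (1.0 - prev / n) + 0.05
        w = w / w.sum()
        cluster.append(str(rng.choice(cluster_ids, p=w)))
    genes["cluster_id"] = cluster
    return genes[["gene_id", "location", "cluster_id"]]


# ---------------------------------------------------------------------------
# Pangenome simulation


def _zero_truncated_binomial(n: int, p: float, rng: np.random.Generator) -> int:
    """Draw from Binomial(n, p) conditioned on a non-zero outcome."""
    if p <= 0.0:
        return 1  # limiting conditional distribution as p -> 0
    k = np.arange(1, n + 1)
    log_pmf = (
        [math.lgamma(n + 1) - math.lgamma(ki + 1) - math.lgamma(n - ki + 1)
         for ki in k]
        + k * math.log(p)
        + (n - k) * math.log1p(-p)
    )
    pmf = np.exp(log_pmf - np.max(log_pmf))
    pmf /= pmf.sum()
    return int(rng.choice(k, p=pmf))


def simulate_pangenome(
    n_genomes: int,
    n_core: int,
    n_accessory: int = 0,
    presence_probs: np.ndarray | None = None,
    beta_params: tuple[float, float] = (0.3, 1.0),
    seed: int | np.random.SeedSequence = 0,
) -> pd.DataFrame:
    """Simulate a binary ortholog presence/absence matrix.

    Core clusters are present in every genome.  Accessory clusters are
    present independently per genome with per-cluster probabilities, either
    given explicitly (``presence_probs``) or drawn from a Beta distribution
    (default Beta(0.3, 1), a U-shaped-to-rare spectrum giving a large cloud
    with a thinner shell, as open bacterial pangenomes show).  Accessory
    presence is conditioned on each cluster appearing in at least one genome
    (an ortholog cluster observed nowhere does not exist), so the matrix has
    exactly ``n_core + n_accessory`` clusters, all with prevalence >= 1.

    Returns a DataFrame with cluster ids as rows, genome ids as columns and
    values in {0, 1}.
    """
    if n_genomes < 2:
        raise ValueError("n_genomes must be >= 2")
    if n_core < 0:
        raise ValueError("n_core must be >= 0")
    if presence_probs is not None:
        presence_probs = np.asarray(presence_probs, dtype=float)
        n_accessory = len(presence_probs)
    if n_core == 0 and n_accessory == 0:
        raise ValueError("empty pangenome spec: need core or accessory clusters")

    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    rng = np.random.default_rng(ss)

    blocks = []
    if n_core:
        blocks.append(np.ones((n_core, n_genomes), dtype=np.int8))
    if n_accessory:
        if presence_probs is None:
            presence_probs = rng.beta(*beta_params, size=n_accessory)
        acc = (rng.random((n_accessory, n_genomes)) < presence_probs[:, None]).astype(np.int8)
        # condition each cluster on presence in >= 1 genome: clusters that
        # drew empty get an exact zero-truncated binomial prevalence
        for i in np.flatnonzero(acc.sum(axis=1) == 0):
            k = _zero_truncated_binomial(n_genomes, float(presence_probs[i]), rng)
            acc[i, rng.choice(n_genomes, size=k, replace=False)] = 1
        blocks.append(acc)
    mat = np.vstack(blocks)
    clusters = [f"cluster_{i:05d}" for i in range(len(mat))]
    genomes = [f"genome_{j:03d}" for j in range(n_genomes)]
    return pd.DataFrame(mat, index=pd.Index(clusters, name="cluster_id"), columns=genomes)


def simulate_nested_pangenome(c: float, gamma: float, n_genomes: int) -> pd.DataFrame:
    """Deterministic nested matrix whose cumulative-union amplification curve
    is exactly ``round(c * n**gamma)``.

    Genome ``n`` carries clusters ``1..round(c * n**gamma)``, so adding
    genomes in index order grows the pangenome along the target power law
    while the running core stays at ``c`` (genome 1's set is contained in
    every later genome's set).
    """
    if c <= 0 or n_genomes < 1:
        raise ValueError("c must be positive and n_genomes >= 1")
    sizes = np.rint(c * np.arange(1, n_genomes + 1, dtype=float) ** gamma).astype(int)
    n_clusters = int(sizes[-1])
    mat = np.zeros((n_clusters, n_genomes), dtype=np.int8)
    for j, s in enumerate(sizes):
        mat[:s, j] = 1
    clusters = [f"cluster_{i:05d}" for i in range(n_clusters)]
    genomes = [f"genome_{j:03d}" for j in range(n_genomes)]
    return pd.DataFrame(mat, index=pd.Index(clusters, name="cluster_id"), columns=genomes)
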