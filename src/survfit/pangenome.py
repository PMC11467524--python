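"""Pangenome partition, accumulation curves, openness and size estimation.

Operates on a binary ortholog presence/absence matrix (clusters x genomes).
Clusters are partitioned into core (present in every genome), shell
(intermediate prevalence) and cloud (present in at most 15% of genomes).
Pangenome openness is the exponent gamma of the Heaps-type power law
``G = c * N**gamma`` relating pangenome size to genome count, with the
prefactor fixed at the core size; the full pangenome size is estimated from
singleton and doubleton cluster counts by the Chao1 lower bound
``N1 = Nobs + F1^2 / (2 * F2)``.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd

__all__ = [
    "validate_matrix",
    "classify_clusters",
    "accumulation_curves",
    "cumulative_sizes",
    "drop_empty_clusters",
    "fit_openness",
    "estimate_full_size",
    "summarize",
    "AccumulationCurve",
    "PangenomeSummary",
    "CLOUD_MAX_FRACTION",
]

#: Prevalence fraction at or below which a cluster belongs to the cloud.
CLOUD_MAX_FRACTION = 0.15

#: Genome count at or below which accumulation curves enumerate all
#: orderings exactly instead of sampling permutations.
EXHAUSTIVE_MAX_GENOMES = 7


def validate_matrix(matrix: pd.DataFrame) -> None:
    vals = matrix.to_numpy()
    if not np.isin(vals, (0, 1)).all():
        raise ValueError("presence/absence matrix must be binary")
    if matrix.index.has_duplicates or matrix.columns.has_duplicates:
        raise ValueError("duplicate cluster or genome ids")
    if (vals.sum(axis=1) == 0).any():
        raise ValueError("matrix contains empty clusters (prevalence 0)")
    if matrix.shape[1] < 1:
        raise ValueError("matrix has no genomes")


def drop_empty_clusters(matrix: pd.DataFrame) -> pd.DataFrame:
    """Remove clusters absent from every genome (after subsetting)."""
    return matrix.loc[matrix.sum(axis=1) > 0]


def classify_clusters(
    matrix: pd.DataFrame, cloud_max_fraction: float = CLOUD_MAX_FRACTION
) -> pd.Series:
    """Label each cluster ``core``, ``shell`` or ``cloud``.

    Core: present in all N genomes.  Cloud: prevalence/N <= the cloud
    fraction (no rounding of genome counts — at N=75 the boundary is 11
    genomes, since 11/75 = 14.7% <= 15% < 12/75).  Shell: everything
    between.
    """
    validate_matrix(matrix)
    n = matrix.shape[1]
    prev = matrix.sum(axis=1)
    labels = pd.Series("shell", index=matrix.index, name="class")
    labels[prev / n <= cloud_max_fraction] = "cloud"
    labels[prev == n] = "core"
    return labels


@dataclass
class AccumulationCurve:
    """Mean (and SD) core/pangenome size as genomes accumulate in random order."""

    n_genomes: np.ndarray
    mean: np.ndarray
    sd: np.ndarray
    kind: str  # "rarefaction" (running core) | "amplification" (running pangenome)
    n_orderings: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"n": self.n_genomes, "mean": self.mean, "sd": self.sd})


def _curves_for_orderings(presence: np.ndarray, orderings) -> tuple[np.ndarray, np.ndarray]:
    cores, pans = [], []
    for order in orderings:
        sub = presence[:, order]
        pans.append(np.logical_or.accumulate(sub, axis=1).sum(axis=0))
        cores.append(np.logical_and.accumulate(sub, axis=1).sum(axis=0))
    return np.asarray(cores, dtype=float), np.asarray(pans, dtype=float)


def accumulation_curves(
    matrix: pd.DataFrame,
    n_permutations: int = 100,
    seed: int | np.random.SeedSequence = 0,
    exhaustive_max: int = EXHAUSTIVE_MAX_GENOMES,
) -> tuple[AccumulationCurve, AccumulationCurve]:
    """Rarefaction (running core) and amplification (running pangenome) curves.

    For each genome ordering the running intersection and union sizes are
    tracked; curves are averaged across orderings.  When the genome count is
    small (<= ``exhaustive_max``) all N! orderings are enumerated exactly;
    otherwise ``n_permutations`` random orderings are drawn from the seeded
    generator.  The n = N endpoints equal the exact core size and observed
    pangenome size in every ordering.
    """
    validate_matrix(matrix)
    if n_permutations < 1:
        raise ValueError("n_permutations must be >= 1")
    presence = matrix.to_numpy(dtype=bool)
    n = presence.shape[1]
    if n <= exhaustive_max:
        orderings = list(itertools.permutations(range(n)))
    else:
        rng = np.random.default_rng(seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed))
        orderings = [rng.permutation(n) for _ in range(n_permutations)]
    cores, pans = _curves_for_orderings(presence, orderings)
    ns = np.arange(1, n + 1)
    rare = AccumulationCurve(ns, cores.mean(axis=0), cores.std(axis=0, ddof=0), "rarefaction", len(orderings))
    amp = AccumulationCurve(ns, pans.mean(axis=0), pans.std(axis=0, ddof=0), "amplification", len(orderings))
    return rare, amp


def cumulative_sizes(
    matrix: pd.DataFrame, order: list[int] | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Running core and pangenome sizes for one explicit genome ordering.

    Defaults to column order.  Useful for deterministic constructions (e.g.
    nested matrices built to follow an exact power law when genomes are
    added in index order).  Returns ``(core_sizes, pangenome_sizes)``.
    """
    validate_matrix(matrix)
    presence = matrix.to_numpy(dtype=bool)
    if order is None:
        order = list(range(presence.shape[1]))
    cores, pans = _curves_for_orderings(presence, [order])
    return cores[0], pans[0]


def fit_openness(curve, core_size: float) -> float:
    """Fit the openness exponent gamma of ``G(n) = c * n**gamma``.

    Least squares on ``log G(n) = log c + gamma * log n`` with the intercept
    fixed at the (given) core size, so
    ``gamma = sum(log(G/c) * log n) / sum((log n)^2)`` over n = 1..N.
    A closed pangenome (G constant at c) gives gamma = 0.
    """
    g = curve.mean if isinstance(curve, AccumulationCurve) else np.asarray(curve, dtype=float)
    if core_size <= 0:
        raise ValueError("core size must be positive")
    if (g <= 0).any():
        raise ValueError("amplification curve values must be positive")
    if len(g) < 2:
        raise ValueError("need at least 2 genome counts to fit openness")
    logn = np.log(np.arange(1, len(g) + 1, dtype=float))
    return float((np.log(g / core_size) * logn).sum() / (logn**2).sum())


def estimate_full_size(matrix: pd.DataFrame) -> tuple[float, int, int, int]:
    """Chao1-type estimate of the full pangenome size.

    ``N1 = Nobs + F1^2 / (2 * F2)`` where F1 and F2 are the singleton and
    doubleton cluster counts.  When F2 = 0 the bias-corrected form
    ``Nobs + F1*(F1 - 1)/2`` is used instead.  Returns
    ``(N1, F1, F2, Nobs)``.
    """
    validate_matrix(matrix)
    prev = matrix.sum(axis=1)
    n_obs = int(len(prev))
    f1 = int((prev == 1).sum())
    f2 = int((prev == 2).sum())
    if f2 > 0:
        n1 = n_obs + f1**2 / (2 * f2)
    else:
        n1 = n_obs + f1 * (f1 - 1) / 2
    return float(n1), f1, f2, n_obs


@dataclass
class PangenomeSummary:
    """Headline pangenome statistics for one genome set."""

    n_genomes: int
    n_obs: int  # observed pangenome size (cluster count)
    core: int
    shell: int
    cloud: int
    gamma: float  # openness exponent
    n1: float  # estimated full pangenome size
    f1: int  # singleton clusters
    f2: int  # doubleton clusters

    def to_dict(self) -> dict:
        return asdict(self)


def summarize(
    matrix: pd.DataFrame,
    n_permutations: int = 100,
    seed: int | np.random.SeedSequence = 0,
    cloud_max_fraction: float = CLOUD_MAX_FRACTION,
) -> PangenomeSummary:
    """Partition, openness and size-estimate summary of one matrix.

    The core/shell/cloud counts always sum to the observed pangenome size.
    Gamma is fit to the mean amplification curve with the prefactor fixed at
    the core size; an empty core makes gamma undefined (NaN).
    """
    matrix = drop_empty_clusters(matrix)
    labels = classify_clusters(matrix, cloud_max_fraction)
    counts = labels.value_counts()
    core = int(counts.get("core", 0))
    _, amp = accumulation_curves(matrix, n_permutations=n_permutations, seed=seed)
    gamma = fit_openness(amp, core) if core > 0 else math.nan
    n1, f1, f2, n_obs = estimate_full_size(matrix)
    return PangenomeSummary(
        n_genomes=int(matrix.shape[1]),
        n_obs=n_obs,
        core=core,
        shell=int(counts.get("shell", 0)),
        cloud=int(counts.get("cloud", 0)),
        gamma=gamma,
        n1=n1,
        f1=f1,
        f2=f2,
    )
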