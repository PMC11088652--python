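"""Pairwise moment relatedness on diploid females and kin-graph pruning.

The default estimator is the symmetrized Queller–Goodnight moment estimator.
For a focal individual X with alleles (a, b) and partner Y with alleles
(c, d) at locus l, with population allele frequencies p_.:

    r_{X->Y} = sum_l [ 0.5 (I_ac + I_ad + I_bc + I_bd) - p_a - p_b ]
             / sum_l [ 1 + I_ab - p_a - p_b ]

where I_xy are allele-identity indicators; the reported value averages the
two directions. For biallelic dosages g in {0,1,2} with ALT frequency p this
reduces to closed forms in (g_x, g_y, p). The estimator is unbiased for the
pedigree relatedness coefficient when frequencies are known: ~0 for
unrelated pairs, ~0.5 for diploid parent-offspring, and ~0.75 for
haplodiploid super-sisters (same mother, same haploid father).

Kin pruning removes a near-minimal set of samples so that no retained pair
exceeds a relatedness cutoff, via greedy highest-degree vertex deletion on
the "too related" graph (network-relationship removal as used for building
trees/PCAs from unrelated subsets).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import DataError, UndefinedStatisticError
from .genotypes import MISSING, GenotypeMatrix


@dataclass
class RelatednessResult:
    """Symmetric pairwise relatedness among females with per-population summaries."""

    sample_ids: list[str]
    r: np.ndarray  # symmetric, NaN diagonal
    per_population_mean: pd.DataFrame  # population, mean, se, n_pairs

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.r, index=self.sample_ids, columns=self.sample_ids)

    def write(self, path: str) -> str:
        self.to_frame().to_csv(path, sep="\t", index_label="sample_id")
        return str(path)


@dataclass
class UnrelatedSet:
    """Samples surviving kin pruning; no retained pair exceeds ``cutoff``."""

    retained: list[str]
    removed: list[str]  # in removal order
    cutoff: float

    def write(self, path: str) -> str:
        with open(path, "w") as fh:
            fh.writelines(s + "\n" for s in self.retained)
        return str(path)


def moment_relatedness(
    ga: np.ndarray,
    gb: np.ndarray,
    freqs: np.ndarray,
    min_sites: int = 30,
) -> float:
    """Symmetrized Queller–Goodnight relatedness from dosage vectors.

    Parameters
    ----------
    ga, gb:
        Dosage vectors for the pair (missing = -1).
    freqs:
        Per-site ALT frequency estimated from the full analysis panel.
    min_sites:
        Minimum number of pairwise-complete polymorphic sites required.
    """
    ga = np.asarray(ga, dtype=float)
    gb = np.asarray(gb, dtype=float)
    p = np.asarray(freqs, dtype=float)
    ok = (ga != MISSING) & (gb != MISSING) & (p > 0) & (p < 1) & ~np.isnan(p)
    if int(ok.sum()) < min_sites:
        raise UndefinedStatisticError(
            f"only {int(ok.sum())} informative sites (< {min_sites})"
        )
    x, y, p = ga[ok], gb[ok], p[ok]

    # matching ordered allele pairs among the 4 cross-comparisons
    m = x * y + (2 - x) * (2 - y)
    s = 0.5 * m

    def direction(gx: np.ndarray) -> tuple[float, float]:
        p_ab = gx * p + (2 - gx) * (1 - p)  # sum of the focal pair's allele freqs
        i_ab = (gx != 1).astype(float)
        num = float(np.sum(s - p_ab))
        den = float(np.sum(1.0 + i_ab - p_ab))
        return num, den

    num_x, den_x = direction(x)
    num_y, den_y = direction(y)
    if den_x == 0.0 or den_y == 0.0:
        raise UndefinedStatisticError("all loci uninformative (zero denominator)")
    return 0.5 * (num_x / den_x + num_y / den_y)


def relatedness_matrix(
    gm: GenotypeMatrix,
    meta: pd.DataFrame,
    estimator=moment_relatedness,
) -> RelatednessResult:
    """All female-female pairwise relatedness with per-population mean ± SE.

    Males in ``meta`` are excluded. Allele frequencies come from the female
    analysis panel (all populations pooled). The input matrix is expected to
    be quality-filtered, kb-window LD-pruned and locus-subsampled already.
    """
    meta = meta.set_index("sample_id", drop=False)
    females = [s for s in gm.sample_ids if meta.loc[s, "sex"] == "female"]
    if len(females) < 2:
        raise DataError("relatedness requires at least 2 female samples")
    sub = gm.take_samples([gm.sample_index(s) for s in females])
    freqs = sub.alt_freq()

    n = len(females)
    r = np.full((n, n), np.nan)
    for i, j in itertools.combinations(range(n), 2):
        val = estimator(sub.calls[i], sub.calls[j], freqs)
        r[i, j] = r[j, i] = val

    rows = []
    pops = meta.loc[females, "population"]
    for pop in pd.unique(pops):
        idx = [k for k, s in enumerate(females) if pops[s] == pop]
        vals = np.array([r[i, j] for i, j in itertools.combinations(idx, 2)])
        if vals.size == 0:
            continue
        se = float(vals.std(ddof=1) / np.sqrt(vals.size)) if vals.size > 1 else np.nan
        rows.append({"population": pop, "mean": float(vals.mean()), "se": se,
                     "n_pairs": int(vals.size)})
    summary = pd.DataFrame(rows, columns=["population", "mean", "se", "n_pairs"])
    return RelatednessResult(females, r, summary)


def prune_related(rel: RelatednessResult, cutoff: float = 0.33) -> UnrelatedSet:
    """Greedy highest-degree removal until no pair exceeds ``cutoff``.

    Ties in degree are broken toward the lexicographically smallest
    sample_id, making the result deterministic.
    """
    import networkx as nx

    g = nx.Graph()
    g.add_nodes_from(rel.sample_ids)
    n = len(rel.sample_ids)
    for i, j in itertools.combinations(range(n), 2):
        if np.isfinite(rel.r[i, j]) and rel.r[i, j] > cutoff:
            g.add_edge(rel.sample_ids[i], rel.sample_ids[j])

    removed: list[str] = []
    while g.number_of_edges() > 0:
        victim = min(g.nodes, key=lambda s: (-g.degree[s], s))
        removed.append(victim)
        g.remove_node(victim)
    retained = [s for s in rel.sample_ids if s not in set(removed)]

    # exact re-verification of the post-condition over all retained pairs
    idx = {s: k for k, s in enumerate(rel.sample_ids)}
    for a, b in itertools.combinations(retained, 2):
        v = rel.r[idx[a], idx[b]]
        if np.isfinite(v) and v > cutoff:
            raise DataError("kin pruning failed to clear all related pairs")
    return UnrelatedSet(retained, removed, cutoff)
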