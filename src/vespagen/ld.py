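"""Pairwise genotype r² and windowed LD pruning.

r² is the squared Pearson correlation of ALT-allele dosages over
pairwise-complete samples — the unphased-genotype analogue of haplotype LD.
Two pruning dialects are provided:

* :func:`prune_kb_window` — greedy left-to-right scan dropping any later site
  within a physical window (default 200 kb) whose r² with a kept site exceeds
  the threshold (default 0.1). This is the stringent pruning used upstream of
  relatedness estimation.
* :func:`prune_snp_window` — sliding windows of a fixed SNP count (default 50,
  advancing by 5) within which offending pairs (r² > 0.8) lose their later
  member. This is the conventional pruning used upstream of PCA.

Both are deterministic for a fixed input ordering: ties are broken by always
removing the site with the larger genome coordinate.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigError, UndefinedStatisticError
from .genotypes import MISSING, GenotypeMatrix


@dataclass
class PruneResult:
    """Kept/removed site indices (into the input matrix) plus the parameters used."""

    kept: list[int]
    removed: list[int]
    params: dict = field(default_factory=dict)

    def apply(self, gm: GenotypeMatrix) -> GenotypeMatrix:
        return gm.take_sites(self.kept)

    def write_sites(self, gm: GenotypeMatrix, path: str) -> str:
        """Write kept sites as 1-based ``chrom:pos`` lines."""
        with open(path, "w") as fh:
            for i in self.kept:
                fh.write(f"{gm.chrom[i]}:{gm.pos[i]}\n")
        return str(path)


def pairwise_r2(a: np.ndarray, b: np.ndarray) -> float:
    """Squared dosage correlation over pairwise-complete samples, in [0, 1].

    Raises
    ------
    UndefinedStatisticError
        Fewer than 2 complete pairs, or either vector monomorphic over the
        complete pairs (callers treat this as "not in LD").
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ConfigError("dosage vectors differ in length")
    ok = (a != MISSING) & (b != MISSING)
    if ok.sum() < 2:
        raise UndefinedStatisticError("fewer than 2 pairwise-complete samples")
    x, y = a[ok], b[ok]
    vx = x.var()
    vy = y.var()
    if vx == 0.0 or vy == 0.0:
        raise UndefinedStatisticError("monomorphic vector over complete pairs")
    cov = ((x - x.mean()) * (y - y.mean())).mean()
    r2 = (cov * cov) / (vx * vy)
    return min(float(r2), 1.0)


def _r2_or_zero(
    calls: np.ndarray, i: int, j: int, cache: dict | None = None
) -> float:
    """r² between site columns i and j; undefined r² counts as no LD.

    Overlapping windows revisit the same pairs, so results are memoized.
    """
    if cache is not None and (i, j) in cache:
        return cache[(i, j)]
    try:
        val = pairwise_r2(calls[:, i], calls[:, j])
    except UndefinedStatisticError:
        val = 0.0
    if cache is not None:
        cache[(i, j)] = val
    return val


def prune_kb_window(
    gm: GenotypeMatrix, window_kb: float = 200, r2_max: float = 0.1
) -> PruneResult:
    """Greedy physical-window pruning: one locus of each pair in LD is dropped.

    Scanning each chromosome left to right, a site is removed iff some
    already-kept site within ``window_kb`` upstream has r² > ``r2_max``
    against it; hence no kept pair within the window exceeds the threshold.
    """
    if window_kb <= 0:
        raise ConfigError("window_kb must be positive")
    window_bp = int(round(window_kb * 1000))
    kept: list[int] = []
    removed: list[int] = []
    for c in dict.fromkeys(gm.chrom.tolist()):
        sites = np.flatnonzero(gm.chrom == c)
        kept_here: list[int] = []
        for j in sites:
            in_ld = False
            for i in reversed(kept_here):
                if gm.pos[j] - gm.pos[i] > window_bp:
                    break
                if _r2_or_zero(gm.calls, i, j) > r2_max:
                    in_ld = True
                    break
            (removed if in_ld else kept_here).append(int(j))
        kept.extend(kept_here)
    kept.sort()
    removed.sort()
    return PruneResult(kept, removed, {"window_kb": window_kb, "r2_max": r2_max})


def prune_snp_window(
    gm: GenotypeMatrix,
    window_snps: int = 50,
    step_snps: int = 5,
    r2_max: float = 0.8,
) -> PruneResult:
    """SNP-count sliding-window pruning.

    Windows of ``window_snps`` consecutive sites advance by ``step_snps``
    along each chromosome (trailing partial windows included). Within each
    window, while any kept pair has r² > ``r2_max``, the later member of the
    first offending pair (in index order) is removed.
    """
    if window_snps < 1 or step_snps < 1:
        raise ConfigError("window_snps and step_snps must be >= 1")
    kept_mask = np.ones(gm.n_sites, dtype=bool)
    cache: dict = {}
    for c in dict.fromkeys(gm.chrom.tolist()):
        sites = np.flatnonzero(gm.chrom == c)
        for start in range(0, len(sites), step_snps):
            window = sites[start : start + window_snps]
            _prune_window(gm.calls, window, kept_mask, r2_max, cache)
            if start + window_snps >= len(sites):
                break
    kept = np.flatnonzero(kept_mask).tolist()
    removed = np.flatnonzero(~kept_mask).tolist()
    return PruneResult(
        kept,
        removed,
        {"window_snps": window_snps, "step_snps": step_snps, "r2_max": r2_max},
    )


def _prune_window(
    calls: np.ndarray,
    window: np.ndarray,
    kept_mask: np.ndarray,
    r2_max: float,
    cache: dict | None = None,
) -> None:
    """Remove later members of offending pairs until the window is clean."""
    while True:
        live = [int(s) for s in window if kept_mask[s]]
        offender = None
        for ai in range(len(live)):
            for bi in range(ai + 1, len(live)):
                if _r2_or_zero(calls, live[ai], live[bi], cache) > r2_max:
                    offender = live[bi]
                    break
            if offender is not None:
                break
        if offender is None:
            return
        kept_mask[offender] = False
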