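"""Principal component analysis of an LD-pruned genotype matrix.

Sites are standardized with the binomial (Patterson) scaling: dosage g at a
site with panel ALT frequency p becomes (g - 2p) / sqrt(2p(1-p)); missing
calls are mean-imputed (0 after centering) and monomorphic sites dropped.
Components come from an exact SVD of the standardized matrix, so results are
deterministic up to per-component sign; the sign is fixed by forcing each
component's largest-magnitude site loading positive.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ConfigError
from .genotypes import MISSING, GenotypeMatrix

logger = logging.getLogger(__name__)


@dataclass
class PCAResult:
    sample_ids: list[str]
    coords: np.ndarray  # samples x k component scores
    var_explained: np.ndarray  # per-component fraction of total variance

    def to_frame(self) -> pd.DataFrame:
        cols = [f"PC{i + 1}" for i in range(self.coords.shape[1])]
        return pd.DataFrame(self.coords, index=self.sample_ids, columns=cols)

    def write(self, path: str) -> str:
        df = self.to_frame()
        df.loc["__var_explained__"] = self.var_explained
        df.to_csv(path, sep="\t", index_label="sample_id")
        return str(path)


def standardize(gm: GenotypeMatrix) -> tuple[np.ndarray, np.ndarray]:
    """Binomially scaled, mean-imputed dosage matrix.

    Returns ``(X, kept)`` where ``X`` is samples x kept-sites and ``kept``
    holds the indices of sites that were polymorphic (others are dropped
    with a logged warning).
    """
    calls = gm.calls.astype(float)
    obs = calls != MISSING
    freq = gm.alt_freq()
    poly = obs.any(axis=0) & (freq > 0) & (freq < 1) & ~np.isnan(freq)
    if not poly.all():
        logger.warning("standardize: dropping %d monomorphic sites", int((~poly).sum()))
    kept = np.flatnonzero(poly)
    calls = calls[:, kept]
    obs = obs[:, kept]
    p = freq[kept]
    x = (calls - 2 * p) / np.sqrt(2 * p * (1 - p))
    x[~obs] = 0.0
    return x, kept


def run_pca(gm: GenotypeMatrix, k: int = 10) -> PCAResult:
    """Top-k PCA of the standardized genotype matrix."""
    x, _ = standardize(gm)
    n, m = x.shape
    if n < 2:
        raise ConfigError("PCA requires at least 2 samples")
    if not 1 <= k <= min(n - 1, m):
        raise ConfigError(f"k={k} out of range for {n} samples x {m} sites")
    x = x - x.mean(axis=0)  # re-center across samples (finite-panel correction)
    u, sv, vt = np.linalg.svd(x, full_matrices=False)
    total_var = float(np.sum(sv**2))
    coords = u[:, :k] * sv[:k]
    var_explained = (sv[:k] ** 2) / total_var if total_var > 0 else np.zeros(k)
    # deterministic sign: largest-magnitude loading positive per component
    for c in range(k):
        j = int(np.argmax(np.abs(vt[c])))
        if vt[c, j] < 0:
            coords[:, c] = -coords[:, c]
    return PCAResult(list(gm.sample_ids), coords, var_explained)


def plot_pca(
    result: PCAResult, meta: pd.DataFrame, path: str, components: tuple[int, int] = (1, 2)
) -> str:
    """Scatter of two components colored by population label."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    a, b = components
    meta = meta.set_index("sample_id")
    pops = [meta.loc[s, "population"] for s in result.sample_ids]
    fig, ax = plt.subplots(figsize=(6, 5))
    for pop in sorted(set(pops)):
        sel = [i for i, p in enumerate(pops) if p == pop]
        ax.scatter(result.coords[sel, a - 1], result.coords[sel, b - 1], label=pop, s=18)
    ax.set_xlabel(f"PC{a} ({result.var_explained[a - 1]:.1%})")
    ax.set_ylabel(f"PC{b} ({result.var_explained[b - 1]:.1%})")
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return str(path)
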