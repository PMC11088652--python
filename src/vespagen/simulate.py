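"""Synthetic haplodiploid, nest-structured genotype panels with ground truth.

The generator emulates the study design this package analyses: several
populations with tunable allele-frequency divergence, haplodiploid nests
(diploid females sharing one haploid father, so "super-sisters" have
relatedness 0.75), individuals with planted autozygous tracts of known total
fraction, per-call depth/quality/missingness for filter testing, and
mitogenome consensus panels with low-depth patches and a known haplotype
partition.

Population allele frequencies follow the Balding–Nichols construction: with
ancestral frequency p and differentiation F, each population's frequency is
Beta(p(1-F)/F, (1-p)(1-F)/F) (F = 0 copies p). Autozygosity is planted by
copying haplotype A over haplotype B inside disjoint tracts until a target
fraction of the SNP-covered genome is reached, giving exact per-individual
truth for fROH recovery tests. Inheritance is per-site independent apart
from the planted tracts, so the outbred background contains essentially no
long runs of homozygosity.

All outputs are a pure function of :class:`SimConfig` (including the seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigError
from .genotypes import MISSING, GenotypeMatrix
from .mito import MitoAlignment

_BASES = np.frombuffer(b"ACGT", dtype="S1")


@dataclass(frozen=True)
class SimConfig:
    """Study-condition parameters for the synthetic panels.

    The defaults define the bundled small fixture used throughout the test
    suite: 2 chromosomes x 10 Mb at ~4 kb SNP spacing (~5,000 SNPs), three
    populations at differentiation 0.1, two nests of four super-sister
    daughters plus a mother, three unrelated females and two haploid males
    per population. Depth/quality marginals mimic a ~19x short-read panel.
    """

    # genome / sites
    n_chrom: int = 2
    chrom_length: int = 10_000_000
    snp_spacing_mean: float = 4_000
    # population structure
    n_populations: int = 3
    divergence: float | Sequence[float] = 0.1
    nests_per_population: int = 2
    daughters_per_nest: int = 4
    include_mothers: bool = True
    n_unrelated_females: int = 3
    n_males: int = 2
    # planted autozygosity (extra females appended to population 1)
    autozygosity_targets: tuple[float, ...] = ()
    tract_length_kb: float = 1_000
    # per-call metadata
    depth_mean: float = 19.0
    depth_overdispersion: float = 5.0
    gq_mean: float = 60.0
    gq_sd: float = 15.0
    missing_rate: float = 0.02
    # mitogenome panel
    mito_length: int = 16_000
    mito_n_haplotypes: int = 5
    mito_samples_per_haplotype: int = 4
    mito_substitutions: int = 3
    mito_patch_rate: float = 0.3
    mito_patch_length: int = 30
    mito_high_n_samples: int = 2
    mito_high_n_patch: int = 200
    seed: int = 0

    def divergence_of(self, pop_index: int) -> float:
        if np.isscalar(self.divergence):
            return float(self.divergence)  # type: ignore[arg-type]
        return float(self.divergence[pop_index])  # type: ignore[index]


@dataclass
class SimTruth:
    """Machine-readable ground truth for a simulated panel."""

    population: dict[str, str] = field(default_factory=dict)
    sex: dict[str, str] = field(default_factory=dict)
    nest: dict[str, Optional[str]] = field(default_factory=dict)
    pedigree: dict[str, tuple[str, str]] = field(default_factory=dict)
    planted_fraction: dict[str, float] = field(default_factory=dict)
    tracts: dict[str, list[tuple[str, int, int]]] = field(default_factory=dict)
    mito_haplotype: dict[str, str] = field(default_factory=dict)

    def to_meta(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "sample_id": list(self.population),
                "population": [self.population[s] for s in self.population],
                "sex": [self.sex[s] for s in self.population],
                "nest": [self.nest.get(s) for s in self.population],
            }
        )


# ---------------------------------------------------------------------------
# genotype panel
# ---------------------------------------------------------------------------


def _site_positions(cfg: SimConfig, rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    chroms, pos = [], []
    for c in range(cfg.n_chrom):
        gaps = np.maximum(1, rng.exponential(cfg.snp_spacing_mean, size=int(
            3 * cfg.chrom_length / cfg.snp_spacing_mean) + 10).astype(np.int64))
        p = np.cumsum(gaps)
        p = p[p <= cfg.chrom_length]
        chroms.append(np.full(p.size, f"chr{c + 1}"))
        pos.append(p)
    return np.concatenate(chroms), np.concatenate(pos)


def _pop_freqs(cfg: SimConfig, rng: np.random.Generator, n_sites: int) -> np.ndarray:
    p_anc = np.clip(rng.beta(0.8, 0.8, size=n_sites), 0.05, 0.95)
    freqs = np.empty((cfg.n_populations, n_sites))
    for k in range(cfg.n_populations):
        f = cfg.divergence_of(k)
        if f <= 0:
            freqs[k] = p_anc
        else:
            freqs[k] = np.clip(
                rng.beta(p_anc * (1 - f) / f, (1 - p_anc) * (1 - f) / f), 0.0, 1.0
            )
    return freqs


def _plant_tracts(
    cfg: SimConfig,
    rng: np.random.Generator,
    chrom: np.ndarray,
    pos: np.ndarray,
    target: float,
) -> list[tuple[str, int, int]]:
    """Disjoint tract intervals covering ~``target`` of the SNP-covered span."""
    spans = {
        str(c): (int(pos[chrom == c].min()), int(pos[chrom == c].max()))
        for c in dict.fromkeys(chrom.tolist())
    }
    total_span = sum(b - a + 1 for a, b in spans.values())
    tract_bp = int(cfg.tract_length_kb * 1000)
    n_tracts = int(round(target * total_span / tract_bp))
    if n_tracts == 0:
        return []
    if n_tracts * tract_bp > 0.9 * total_span:
        raise ConfigError(
            f"autozygosity target {target} infeasible with {cfg.tract_length_kb} kb tracts"
        )
    # largest-remainder apportionment of tracts across chromosomes by span
    names = list(spans)
    weights = np.array([spans[c][1] - spans[c][0] + 1 for c in names], dtype=float)
    quota = n_tracts * weights / weights.sum()
    alloc = np.floor(quota).astype(int)
    for i in np.argsort(quota - alloc)[::-1][: n_tracts - alloc.sum()]:
        alloc[i] += 1
    tracts: list[tuple[str, int, int]] = []
    for c, n_c in zip(names, alloc):
        if n_c == 0:
            continue
        a, b = spans[c]
        slot = (b - a + 1) / n_c
        if slot < tract_bp:
            raise ConfigError(f"tracts do not fit on {c} for target {target}")
        for t in range(n_c):
            jitter = rng.uniform(0, slot - tract_bp)
            start = int(a + t * slot + jitter)
            tracts.append((c, start, start + tract_bp - 1))
    return tracts


def simulate_panel(config: SimConfig) -> tuple[GenotypeMatrix, pd.DataFrame, SimTruth]:
    """Generate the genotype panel, its metadata table and the ground truth."""
    rng = np.random.default_rng(config.seed)
    chrom, pos = _site_positions(config, rng)
    n_sites = pos.size
    if n_sites == 0:
        raise ConfigError("no SNP sites generated; check genome parameters")
    freqs = _pop_freqs(config, rng, n_sites)

    truth = SimTruth()
    sample_ids: list[str] = []
    calls_rows: list[np.ndarray] = []

    def hap(k: int) -> np.ndarray:
        return (rng.random(n_sites) < freqs[k]).astype(np.int8)

    def add(sid: str, dosage: np.ndarray, pop: str, sex: str, nest: Optional[str]) -> None:
        sample_ids.append(sid)
        calls_rows.append(dosage)
        truth.population[sid] = pop
        truth.sex[sid] = sex
        truth.nest[sid] = nest

    for k in range(config.n_populations):
        pop = f"pop{k + 1}"
        for j in range(config.nests_per_population):
            nest = f"{pop}_nest{j + 1}"
            father = hap(k)
            m1, m2 = hap(k), hap(k)
            mother_id = f"{nest}_mother"
            if config.include_mothers:
                add(mother_id, (m1 + m2).astype(np.int8), pop, "female", nest)
            for d in range(config.daughters_per_nest):
                pick = rng.random(n_sites) < 0.5
                dosage = (np.where(pick, m1, m2) + father).astype(np.int8)
                sid = f"{nest}_daughter{d + 1}"
                add(sid, dosage, pop, "female", nest)
                truth.pedigree[sid] = (mother_id, f"{nest}_father")
        for u in range(config.n_unrelated_females):
            add(f"{pop}_female{u + 1}", (hap(k) + hap(k)).astype(np.int8), pop, "female", None)
        for m in range(config.n_males):
            add(f"{pop}_male{m + 1}", (2 * hap(k)).astype(np.int8), pop, "male", None)

    spans_total = sum(
        int(pos[chrom == c].max()) - int(pos[chrom == c].min()) + 1
        for c in dict.fromkeys(chrom.tolist())
    )
    for t, target in enumerate(config.autozygosity_targets):
        sid = f"pop1_inbred{t + 1}"
        h1, h2 = hap(0), hap(0)
        tracts = _plant_tracts(config, rng, chrom, pos, target)
        planted_bp = 0
        for c, a, b in tracts:
            inside = (chrom == c) & (pos >= a) & (pos <= b)
            h2[inside] = h1[inside]
            planted_bp += b - a + 1
        add(sid, (h1 + h2).astype(np.int8), "pop1", "female", None)
        truth.tracts[sid] = tracts
        truth.planted_fraction[sid] = planted_bp / spans_total
    for sid in sample_ids:
        truth.planted_fraction.setdefault(sid, 0.0)

    calls = np.vstack(calls_rows)
    # per-call metadata overlays
    shape = calls.shape
    p_nb = config.depth_overdispersion / (config.depth_overdispersion + config.depth_mean)
    depth = rng.negative_binomial(config.depth_overdispersion, p_nb, size=shape).astype(np.int32)
    gq = np.rint(np.clip(rng.normal(config.gq_mean, config.gq_sd, size=shape), 0, 99)).astype(np.int32)
    if config.missing_rate > 0:
        calls = calls.copy()
        calls[rng.random(shape) < config.missing_rate] = MISSING

    gm = GenotypeMatrix(sample_ids, chrom, pos, calls, depth=depth, gq=gq)
    return gm, truth.to_meta(), truth


def simulate_relatedness_pairs(
    relationship: str,
    n_pairs: int = 200,
    n_loci: int = 5_000,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Dosage vectors for pairs of known pedigree relatedness.

    ``relationship`` is one of ``unrelated`` (r = 0), ``parent_offspring``
    (diploid, r = 0.5) or ``supersister`` (haplodiploid full sisters sharing
    their father's single haplotype, r = 0.75). Returns ``(ga, gb, freqs)``
    where ``freqs`` are ALT frequencies estimated from the whole simulated
    panel, as the estimator expects.
    """
    rng = np.random.default_rng(seed)
    p = np.clip(rng.beta(0.8, 0.8, size=n_loci), 0.05, 0.95)
    ga = np.empty((n_pairs, n_loci), dtype=np.int8)
    gb = np.empty((n_pairs, n_loci), dtype=np.int8)

    def bern(prob: np.ndarray) -> np.ndarray:
        return (rng.random(n_loci) < prob).astype(np.int8)

    for i in range(n_pairs):
        if relationship == "unrelated":
            ga[i] = bern(p) + bern(p)
            gb[i] = bern(p) + bern(p)
        elif relationship == "parent_offspring":
            a1, a2 = bern(p), bern(p)
            ga[i] = a1 + a2
            transmitted = np.where(rng.random(n_loci) < 0.5, a1, a2)
            gb[i] = (transmitted + bern(p)).astype(np.int8)
        elif relationship == "supersister":
            m1, m2 = bern(p), bern(p)
            father = bern(p)
            pick1 = rng.random(n_loci) < 0.5
            pick2 = rng.random(n_loci) < 0.5
            ga[i] = (np.where(pick1, m1, m2) + father).astype(np.int8)
            gb[i] = (np.where(pick2, m1, m2) + father).astype(np.int8)
        else:
            raise ConfigError(f"unknown relationship {relationship!r}")
    freqs = np.concatenate([ga, gb]).mean(axis=0) / 2.0
    return ga, gb, freqs


# ---------------------------------------------------------------------------
# mitogenome panel
# ---------------------------------------------------------------------------


def simulate_mito(config: SimConfig) -> tuple[MitoAlignment, SimTruth]:
    """Consensus-sequence panel with depth tracks and a known mitotype partition.

    Each of ``mito_n_haplotypes`` lineages carries private substitutions
    relative to a random root sequence; substitution sites are confined to
    the final 10% of the molecule while low-depth patches are placed in the
    first 85%, so depth masking never erases a haplotype-defining site. The
    first ``mito_high_n_samples`` samples receive a patch long enough to
    push them over the 0.4% N cap after masking.
    """
    rng = np.random.default_rng(config.seed + 1)
    length = config.mito_length
    root = rng.choice(_BASES, size=length)

    sub_region = np.arange(int(0.9 * length), length)
    n_subs_total = config.mito_n_haplotypes * config.mito_substitutions
    if n_subs_total > sub_region.size:
        raise ConfigError("too many substitutions for the mitogenome length")
    sub_sites = rng.choice(sub_region, size=n_subs_total, replace=False)

    haplotypes = []
    for h in range(config.mito_n_haplotypes):
        seq = root.copy()
        sites = sub_sites[h * config.mito_substitutions : (h + 1) * config.mito_substitutions]
        for s in sites:
            current = seq[s]
            seq[s] = rng.choice(_BASES[_BASES != current])
        haplotypes.append(seq)

    truth = SimTruth()
    ids: list[str] = []
    rows: list[np.ndarray] = []
    for h, seq in enumerate(haplotypes):
        for r in range(config.mito_samples_per_haplotype):
            sid = f"mt_h{h + 1}_s{r + 1}"
            ids.append(sid)
            rows.append(seq.copy())
            truth.mito_haplotype[sid] = f"hap{h + 1}"
    n = len(ids)

    depth = rng.integers(150, 250, size=(n, length)).astype(np.int32)
    patch_region_end = int(0.85 * length)
    for i in range(n):
        if i < config.mito_high_n_samples:
            patch_len = config.mito_high_n_patch
        elif rng.random() < config.mito_patch_rate:
            patch_len = config.mito_patch_length
        else:
            continue
        start = int(rng.integers(0, patch_region_end - patch_len))
        depth[i, start : start + patch_len] = rng.integers(5, 90)

    return MitoAlignment(ids, np.vstack(rows), depth), truth


# ---------------------------------------------------------------------------
# truth serialization
# ---------------------------------------------------------------------------


def write_truth(truth: SimTruth, prefix: str) -> list[str]:
    """Write the truth tables as TSVs next to ``prefix``; returns paths."""
    paths = []
    samples = list(truth.population) or list(truth.mito_haplotype)
    per_sample = pd.DataFrame({"sample_id": samples})
    for col, d in [
        ("population", truth.population),
        ("sex", truth.sex),
        ("nest", truth.nest),
        ("planted_fraction", truth.planted_fraction),
        ("mito_haplotype", truth.mito_haplotype),
    ]:
        per_sample[col] = [d.get(s) for s in samples]
    per_sample["mother"] = [
        truth.pedigree.get(s, (None, None))[0] for s in samples
    ]
    per_sample["father"] = [
        truth.pedigree.get(s, (None, None))[1] for s in samples
    ]
    p = f"{prefix}_truth_samples.tsv"
    per_sample.to_csv(p, sep="\t", index=False)
    paths.append(p)

    tract_rows = [
        {"sample_id": s, "chrom": c, "start": a, "end": b}
        for s, tracts in truth.tracts.items()
        for c, a, b in tracts
    ]
    p = f"{prefix}_truth_tracts.tsv"
    pd.DataFrame(tract_rows, columns=["sample_id", "chrom", "start", "end"]).to_csv(
        p, sep="\t", index=False
    )
    paths.append(p)
    return paths
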