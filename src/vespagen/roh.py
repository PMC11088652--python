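"""Sliding-window run-of-homozygosity (ROH) detection and the fROH statistic.

The detector reproduces the semantics of the classic sliding-window caller:

1. every contiguous window of ``window_snps`` sites on a chromosome is scored;
   a window passes iff it contains at most ``window_het_max`` heterozygous and
   at most ``window_missing_max`` missing calls;
2. a SNP is *flagged* iff the fraction of windows containing it that pass is
   at least ``hit_threshold`` (chromosomes with fewer than ``window_snps``
   sites yield no flags);
3. candidate segments are maximal runs of flagged SNPs, split wherever the
   distance between adjacent SNPs exceeds ``gap_kb``;
4. each candidate is trimmed so both terminal SNPs are homozygous and
   non-missing;
5. a candidate is accepted iff it spans at least ``min_snps`` SNPs, at least
   ``min_length_kb`` kb, has at most ``density_kb_per_snp`` kb per SNP, and at
   most ``segment_het_max`` heterozygous calls (unlimited by default).

fROH normalizes a sample's total accepted ROH length (ROH_true) by ROH_max,
the total obtained for a synthetic individual homozygous at every site of the
same SNP set with the same parameters — the theoretical upper bound given the
SNP density actually available. fROH is therefore in [0, 1], equals 1 exactly
for the fully homozygous individual, and is comparable across SNP sets of
different density.

Segment lengths are ``end - start + 1`` bp between the terminal SNP
coordinates; only SNP positions are observable, not physical chromosome ends.
Haploid (male) samples carry no heterozygosity signal and must be excluded by
the caller; :func:`froh_profile` does this from the sample metadata.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigError, DataError, UndefinedStatisticError
from .genotypes import MISSING, GenotypeMatrix, restrict_to_polymorphic

ROH_LENGTHS_KB = (500, 1000, 2000)


@dataclass(frozen=True)
class ROHParams:
    """Window/flag/segment parameters of the sliding-window ROH scan."""

    window_snps: int = 50
    window_het_max: int = 1
    window_missing_max: int = 5
    hit_threshold: float = 0.05
    min_snps: int = 50
    min_length_kb: float = 500
    density_kb_per_snp: float = 60
    gap_kb: float = 500
    segment_het_max: Optional[int] = None  # None = unlimited

    def __post_init__(self) -> None:
        if min(self.window_snps, self.min_snps) < 1:
            raise ConfigError("window_snps and min_snps must be >= 1")
        if self.min_length_kb <= 0 or self.density_kb_per_snp <= 0 or self.gap_kb <= 0:
            raise ConfigError("length/density/gap parameters must be positive")
        if self.window_het_max < 0 or self.window_missing_max < 0:
            raise ConfigError("window caps must be >= 0")


@dataclass
class ROHSegment:
    """One accepted homozygous segment (1-based inclusive SNP coordinates)."""

    chrom: str
    start: int
    end: int
    n_snps: int
    n_het: int

    @property
    def length(self) -> int:
        return self.end - self.start + 1


def detect_roh(
    calls: np.ndarray,
    chrom: np.ndarray,
    pos: np.ndarray,
    params: ROHParams = ROHParams(),
) -> list[ROHSegment]:
    """Run the window/flag/segment scan for one diploid sample.

    ``calls`` is the sample's dosage vector (missing = -1) over sites sorted
    by (chrom, pos); positions must be strictly increasing within chromosome.
    """
    calls = np.asarray(calls)
    chrom = np.asarray(chrom)
    pos = np.asarray(pos, dtype=np.int64)
    segments: list[ROHSegment] = []
    for c in dict.fromkeys(chrom.tolist()):
        sel = np.flatnonzero(chrom == c)
        p = pos[sel]
        if np.any(np.diff(p) <= 0):
            raise DataError(f"positions not sorted on {c!s}")
        segments.extend(_detect_one_chrom(calls[sel], p, str(c), params))
    return segments


def _detect_one_chrom(
    g: np.ndarray, pos: np.ndarray, chrom: str, params: ROHParams
) -> list[ROHSegment]:
    n = g.size
    w = params.window_snps
    if n < w:
        return []
    het = g == 1
    miss = g == MISSING

    # window pass flags via cumulative sums
    chet = np.concatenate([[0], np.cumsum(het)])
    cmiss = np.concatenate([[0], np.cumsum(miss)])
    n_win = n - w + 1
    starts = np.arange(n_win)
    passing = (chet[starts + w] - chet[starts] <= params.window_het_max) & (
        cmiss[starts + w] - cmiss[starts] <= params.window_missing_max
    )
    cpass = np.concatenate([[0], np.cumsum(passing)])

    # per-SNP hit rate over the windows that contain it
    i = np.arange(n)
    lo = np.maximum(0, i - w + 1)
    hi = np.minimum(i, n_win - 1)
    n_containing = hi - lo + 1
    n_passing = cpass[hi + 1] - cpass[lo]
    flagged = n_passing / n_containing >= params.hit_threshold

    # maximal flagged runs, split at large inter-SNP gaps
    gap_bp = params.gap_kb * 1000
    segs: list[ROHSegment] = []
    run_start = None
    for k in range(n + 1):
        in_run = k < n and flagged[k]
        if in_run and run_start is not None and pos[k] - pos[k - 1] > gap_bp:
            segs.extend(_finish(g, pos, chrom, run_start, k - 1, params))
            run_start = k
        elif in_run and run_start is None:
            run_start = k
        elif not in_run and run_start is not None:
            segs.extend(_finish(g, pos, chrom, run_start, k - 1, params))
            run_start = None
    return segs


def _finish(
    g: np.ndarray, pos: np.ndarray, chrom: str, a: int, b: int, params: ROHParams
) -> list[ROHSegment]:
    """Trim a candidate run to homozygous ends and apply acceptance rules."""
    hom = (g == 0) | (g == 2)
    while a <= b and not hom[a]:
        a += 1
    while b >= a and not hom[b]:
        b -= 1
    if a > b:
        return []
    n_snps = b - a + 1
    length = int(pos[b] - pos[a] + 1)
    n_het = int(np.count_nonzero(g[a : b + 1] == 1))
    if n_snps < params.min_snps:
        return []
    if length < params.min_length_kb * 1000:
        return []
    if length / n_snps > params.density_kb_per_snp * 1000:
        return []
    if params.segment_het_max is not None and n_het > params.segment_het_max:
        return []
    return [ROHSegment(chrom, int(pos[a]), int(pos[b]), n_snps, n_het)]


def roh_max(
    chrom: np.ndarray, pos: np.ndarray, params: ROHParams = ROHParams()
) -> int:
    """Total accepted ROH length for a synthetic fully homozygous individual.

    This is the theoretical upper bound of detectable ROH on the given SNP
    set with the given parameters (segments still split at gaps and must
    clear the length/count floors).
    """
    zeros = np.zeros(len(pos), dtype=np.int8)
    return sum(s.length for s in detect_roh(zeros, chrom, pos, params))


def froh(
    calls: np.ndarray,
    chrom: np.ndarray,
    pos: np.ndarray,
    params: ROHParams = ROHParams(),
) -> float:
    """ROH_true / ROH_max for one sample on one SNP set; in [0, 1]."""
    denom = roh_max(chrom, pos, params)
    if denom == 0:
        raise UndefinedStatisticError("ROH_max is 0: no detectable ROH on this SNP set")
    true_bp = sum(s.length for s in detect_roh(calls, chrom, pos, params))
    return true_bp / denom


def froh_profile(
    gm: GenotypeMatrix,
    meta: pd.DataFrame,
    lengths_kb: Sequence[float] = ROH_LENGTHS_KB,
    snp_set: str = "pooled",
    params: ROHParams = ROHParams(),
) -> pd.DataFrame:
    """fROH for every female at every length threshold on one SNP-set mode.

    ``snp_set='pooled'`` uses the full site set for everyone;
    ``'within_population'`` recomputes, per population, the subset of sites
    polymorphic within that population (and its own ROH_max) before scanning
    that population's females. The input should be the quality-filtered,
    LD-unpruned SNP set. Returns a long-format frame with columns sample,
    population, min_length_kb, snp_set, roh_true, roh_max, froh.
    """
    if snp_set not in ("pooled", "within_population"):
        raise ConfigError(f"unknown snp_set mode {snp_set!r}")
    meta = meta.set_index("sample_id", drop=False)
    rows = []
    pops = pd.unique(meta.loc[[s for s in gm.sample_ids], "population"])
    for pop in pops:
        females = [
            s for s in gm.sample_ids
            if meta.loc[s, "population"] == pop and meta.loc[s, "sex"] == "female"
        ]
        if not females:
            continue
        sub = gm if snp_set == "pooled" else restrict_to_polymorphic(
            gm, [s for s in gm.sample_ids if meta.loc[s, "population"] == pop]
        )
        for length in lengths_kb:
            p = replace_length(params, length)
            denom = roh_max(sub.chrom, sub.pos, p)
            for s in females:
                calls = sub.calls[sub.sample_index(s)]
                true_bp = sum(
                    seg.length for seg in detect_roh(calls, sub.chrom, sub.pos, p)
                )
                rows.append(
                    {
                        "sample": s,
                        "population": pop,
                        "min_length_kb": length,
                        "snp_set": snp_set,
                        "roh_true": true_bp,
                        "roh_max": denom,
                        "froh": true_bp / denom if denom else np.nan,
                    }
                )
    return pd.DataFrame(
        rows,
        columns=["sample", "population", "min_length_kb", "snp_set",
                 "roh_true", "roh_max", "froh"],
    )


def replace_length(params: ROHParams, min_length_kb: float) -> ROHParams:
    return replace(params, min_length_kb=min_length_kb)


def froh_group(value: float) -> str:
    """Bin an fROH value into the zero / intermediate / high groups."""
    if value == 0:
        return "zero"
    return "intermediate" if value <= 0.02 else "high"


def segments_frame(sample_id: str, segments: list[ROHSegment]) -> pd.DataFrame:
    """BED-like 1-based table (chrom, start, end, n_snps, n_het) for one sample."""
    return pd.DataFrame(
        [
            {"sample": sample_id, "chrom": s.chrom, "start": s.start,
             "end": s.end, "n_snps": s.n_snps, "n_het": s.n_het}
            for s in segments
        ],
        columns=["sample", "chrom", "start", "end", "n_snps", "n_het"],
    )
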