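"""Genotype matrix container, VCF and metadata I/O, and site/genotype filters.

The central object is :class:`GenotypeMatrix`: samples x biallelic-SNP sites
with ALT-allele dosage calls in {0, 1, 2, MISSING}, optional per-call read
depth (DP) and genotype quality (GQ), and optional per-site variant-calling
annotations (QUAL, QD, SOR, FS, MQ, MQRankSum, ReadPosRankSum) used by the
hard filter.

Coordinates are 1-based inclusive, as in VCF. Missing calls are encoded as a
distinct sentinel (:data:`MISSING` = -1), never as dosage 0.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigError, DataError, VCFParseError

logger = logging.getLogger(__name__)

#: Sentinel dosage for a missing genotype call.
MISSING: int = -1

#: INFO keys consulted by :func:`gatk_hard_filter` (QUAL comes from the QUAL column).
INFO_FIELDS = ("QUAL", "QD", "SOR", "FS", "MQ", "MQRankSum", "ReadPosRankSum")

METADATA_COLUMNS = ("sample_id", "population", "sex", "nest")


@dataclass
class GenotypeMatrix:
    """Samples x sites matrix of biallelic SNP dosages.

    Attributes
    ----------
    sample_ids:
        Ordered sample labels (rows of ``calls``).
    chrom:
        Per-site chromosome label.
    pos:
        Per-site 1-based coordinate (bp), strictly increasing within chrom.
    calls:
        ``(n_samples, n_sites)`` int8 array of ALT dosages; missing = -1.
    depth, gq:
        Optional per-call read depth / phred genotype quality, same shape.
    info:
        Optional per-site DataFrame with columns from :data:`INFO_FIELDS`
        (NaN where a field is absent for a site).
    ref, alt:
        Optional per-site REF/ALT alleles (single bases); synthesized as
        A/T on write when absent.
    """

    sample_ids: list[str]
    chrom: np.ndarray
    pos: np.ndarray
    calls: np.ndarray
    depth: Optional[np.ndarray] = None
    gq: Optional[np.ndarray] = None
    info: Optional[pd.DataFrame] = None
    ref: Optional[np.ndarray] = None
    alt: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.chrom = np.asarray(self.chrom)
        self.pos = np.asarray(self.pos, dtype=np.int64)
        self.calls = np.asarray(self.calls, dtype=np.int8)
        if self.calls.shape != (len(self.sample_ids), len(self.pos)):
            raise DataError(
                f"calls shape {self.calls.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.pos)} sites"
            )
        valid = np.isin(self.calls, (MISSING, 0, 1, 2))
        if not valid.all():
            raise DataError("calls must be in {0,1,2} or MISSING (-1)")
        for c in np.unique(self.chrom):
            p = self.pos[self.chrom == c]
            if np.any(np.diff(p) <= 0):
                raise DataError(f"positions not strictly increasing on {c!s}")

    # -- basic properties ------------------------------------------------
    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_sites(self) -> int:
        return len(self.pos)

    def sample_index(self, sample_id: str) -> int:
        try:
            return self.sample_ids.index(sample_id)
        except ValueError:
            raise DataError(f"unknown sample {sample_id!r}") from None

    # -- structural subsetting -------------------------------------------
    def take_sites(self, idx: Sequence[int] | np.ndarray) -> "GenotypeMatrix":
        idx = np.asarray(idx, dtype=np.intp)
        return GenotypeMatrix(
            sample_ids=list(self.sample_ids),
            chrom=self.chrom[idx],
            pos=self.pos[idx],
            calls=self.calls[:, idx],
            depth=None if self.depth is None else self.depth[:, idx],
            gq=None if self.gq is None else self.gq[:, idx],
            info=None if self.info is None else self.info.iloc[idx].reset_index(drop=True),
            ref=None if self.ref is None else self.ref[idx],
            alt=None if self.alt is None else self.alt[idx],
        )

    def take_samples(self, idx: Sequence[int] | np.ndarray) -> "GenotypeMatrix":
        idx = np.asarray(idx, dtype=np.intp)
        return GenotypeMatrix(
            sample_ids=[self.sample_ids[i] for i in idx],
            chrom=self.chrom,
            pos=self.pos,
            calls=self.calls[idx],
            depth=None if self.depth is None else self.depth[idx],
            gq=None if self.gq is None else self.gq[idx],
            info=self.info,
            ref=self.ref,
            alt=self.alt,
        )

    # -- summaries --------------------------------------------------------
    def alt_freq(self, sample_idx: Optional[np.ndarray] = None) -> np.ndarray:
        """Per-site ALT allele frequency over non-missing calls.

        Monomorphic-by-missingness sites yield NaN.
        """
        calls = self.calls if sample_idx is None else self.calls[np.asarray(sample_idx)]
        obs = calls != MISSING
        n_alleles = 2 * obs.sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(obs, calls, 0).sum(axis=0) / n_alleles

    def missing_fraction(self) -> np.ndarray:
        return (self.calls == MISSING).mean(axis=0)


# ---------------------------------------------------------------------------
# VCF I/O
# ---------------------------------------------------------------------------

_SNP_BASES = frozenset("ACGT")


def read_vcf(path: str) -> GenotypeMatrix:
    """Read a multi-sample VCF into a :class:`GenotypeMatrix`.

    Only biallelic SNP records are kept; multi-allelic or non-SNP records are
    skipped with a logged count. Dosage is the count of ALT alleles; ``./.``
    becomes :data:`MISSING`. DP and GQ are loaded when declared in the header.
    """
    from cyvcf2 import VCF

    try:
        vcf = VCF(str(path))
    except Exception as exc:  # cyvcf2 raises bare OSError/Exception on bad input
        raise VCFParseError(f"cannot open VCF {path}: {exc}") from exc

    has_dp = "##FORMAT=<ID=DP" in vcf.raw_header
    has_gq = "##FORMAT=<ID=GQ" in vcf.raw_header

    sample_ids = list(vcf.samples)
    chroms: list[str] = []
    pos: list[int] = []
    calls: list[np.ndarray] = []
    depth: list[np.ndarray] = []
    gq: list[np.ndarray] = []
    info_rows: list[list[float]] = []
    refs: list[str] = []
    alts: list[str] = []
    n_skipped = 0

    try:
        for v in vcf:
            if (
                len(v.ALT) != 1
                or v.REF is None
                or len(v.REF) != 1
                or len(v.ALT[0]) != 1
                or v.REF not in _SNP_BASES
                or v.ALT[0] not in _SNP_BASES
            ):
                n_skipped += 1
                continue
            # cyvcf2 gt_types: 0=hom-ref, 1=het, 2=unknown, 3=hom-alt
            gt = v.gt_types
            dosage = np.select([gt == 0, gt == 1, gt == 3], [0, 1, 2], default=MISSING)
            chroms.append(v.CHROM)
            pos.append(v.POS)
            calls.append(dosage.astype(np.int8))
            refs.append(v.REF)
            alts.append(v.ALT[0])
            if has_dp:
                depth.append(v.format("DP").reshape(-1))
            if has_gq:
                gq.append(v.format("GQ").reshape(-1))
            row = [np.nan if v.QUAL is None else float(v.QUAL)]
            for key in INFO_FIELDS[1:]:
                val = v.INFO.get(key)
                row.append(np.nan if val is None else float(val))
            info_rows.append(row)
    except VCFParseError:
        raise
    except Exception as exc:
        raise VCFParseError(
            f"malformed VCF {path} near record {len(pos) + n_skipped + 1}: {exc}"
        ) from exc

    if n_skipped:
        logger.info("read_vcf: skipped %d multi-allelic/non-SNP records", n_skipped)
    if not pos:
        raise DataError(f"no usable biallelic SNP records in {path}")

    info = pd.DataFrame(info_rows, columns=list(INFO_FIELDS))
    if info.drop(columns="QUAL").isna().all().all() and info["QUAL"].isna().all():
        info = None
    gm = GenotypeMatrix(
        sample_ids=sample_ids,
        chrom=np.array(chroms),
        pos=np.array(pos, dtype=np.int64),
        calls=np.vstack(calls).T if calls else np.empty((len(sample_ids), 0), np.int8),
        depth=np.vstack(depth).T.astype(np.int32) if depth else None,
        gq=np.vstack(gq).T.astype(np.int32) if gq else None,
        info=info,
        ref=np.array(refs),
        alt=np.array(alts),
    )
    logger.info("read_vcf: %d samples x %d sites from %s", gm.n_samples, gm.n_sites, path)
    return gm


def write_vcf(gm: GenotypeMatrix, path: str) -> str:
    """Write a VCF v4.2 with GT (+DP/GQ when present); inverse of read_vcf."""
    import pysam

    header = pysam.VariantHeader()
    for c in dict.fromkeys(gm.chrom.tolist()):  # preserve first-seen order
        maxpos = int(gm.pos[gm.chrom == c].max()) if gm.n_sites else 1
        header.contigs.add(str(c), length=maxpos + 1)
    header.formats.add("GT", 1, "String", "Genotype")
    if gm.depth is not None:
        header.formats.add("DP", 1, "Integer", "Read depth")
    if gm.gq is not None:
        header.formats.add("GQ", 1, "Integer", "Genotype quality")
    for key in INFO_FIELDS[1:]:
        header.info.add(key, 1, "Float", key)
    for s in gm.sample_ids:
        header.add_sample(s)

    ref = gm.ref if gm.ref is not None else np.full(gm.n_sites, "A")
    alt = gm.alt if gm.alt is not None else np.full(gm.n_sites, "T")
    gt_map = {0: (0, 0), 1: (0, 1), 2: (1, 1), MISSING: (None, None)}
    try:
        out = pysam.VariantFile(str(path), "w", header=header)
    except OSError as exc:
        raise DataError(f"cannot write VCF to {path}: {exc}") from exc
    with out:
        for j in range(gm.n_sites):
            rec = out.new_record(
                contig=str(gm.chrom[j]),
                start=int(gm.pos[j]) - 1,
                alleles=(str(ref[j]), str(alt[j])),
            )
            if gm.info is not None:
                qual = gm.info["QUAL"].iloc[j]
                if not np.isnan(qual):
                    rec.qual = float(qual)
                for key in INFO_FIELDS[1:]:
                    val = gm.info[key].iloc[j]
                    if not np.isnan(val):
                        rec.info[key] = float(val)
            for i, s in enumerate(gm.sample_ids):
                rec.samples[s]["GT"] = gt_map[int(gm.calls[i, j])]
                if gm.depth is not None:
                    rec.samples[s]["DP"] = int(gm.depth[i, j])
                if gm.gq is not None:
                    rec.samples[s]["GQ"] = int(round(float(gm.gq[i, j])))
            out.write(rec)
    return str(path)


# ---------------------------------------------------------------------------
# Sample metadata
# ---------------------------------------------------------------------------


def read_metadata(path: str) -> pd.DataFrame:
    """Read the sample-metadata TSV (sample_id, population, sex, nest)."""
    meta = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in METADATA_COLUMNS[:3] if c not in meta.columns]
    if missing:
        raise DataError(f"metadata {path} lacks required columns {missing}")
    if "nest" not in meta.columns:
        meta["nest"] = pd.NA
    if meta["sample_id"].duplicated().any():
        raise DataError("duplicate sample_id in metadata")
    bad_sex = set(meta["sex"]) - {"female", "male"}
    if bad_sex:
        raise DataError(f"sex must be female/male; found {sorted(bad_sex)}")
    return meta[list(METADATA_COLUMNS)]


def write_metadata(meta: pd.DataFrame, path: str) -> str:
    meta[list(METADATA_COLUMNS)].to_csv(path, sep="\t", index=False)
    return str(path)


def check_metadata(gm: GenotypeMatrix, meta: pd.DataFrame) -> None:
    """Every matrix sample must have exactly one metadata record."""
    ids = set(meta["sample_id"])
    absent = [s for s in gm.sample_ids if s not in ids]
    if absent:
        raise DataError(f"samples missing from metadata: {absent[:5]}")


# ---------------------------------------------------------------------------
# Filters
# ---------------------------------------------------------------------------


def filter_genotypes(
    gm: GenotypeMatrix,
    min_gq: float = 20,
    max_missing_frac: float = 0.10,
    min_depth: int = 3,
) -> GenotypeMatrix:
    """Genotype-level quality masking followed by site-level missingness drop.

    Calls with GQ < ``min_gq`` or depth <= ``min_depth`` - 1 are set missing
    first; sites whose missing fraction then exceeds ``max_missing_frac`` are
    dropped. Idempotent.
    """
    if min_gq < 0 or max_missing_frac < 0 or min_depth < 0:
        raise ConfigError("filter thresholds must be non-negative")
    calls = gm.calls.copy()
    n_masked = 0
    if min_gq > 0:
        if gm.gq is None:
            raise ConfigError("min_gq active but matrix has no GQ values")
        mask = (gm.gq < min_gq) & (calls != MISSING)
        n_masked += int(mask.sum())
        calls[mask] = MISSING
    if min_depth > 0:
        if gm.depth is None:
            raise ConfigError("min_depth active but matrix has no depth values")
        mask = (gm.depth <= min_depth - 1) & (calls != MISSING)
        n_masked += int(mask.sum())
        calls[mask] = MISSING
    masked = replace(gm, calls=calls)
    keep = np.flatnonzero(masked.missing_fraction() <= max_missing_frac)
    out = masked.take_sites(keep)
    logger.info(
        "filter_genotypes: masked %d calls; dropped %d/%d sites for missingness",
        n_masked, gm.n_sites - out.n_sites, gm.n_sites,
    )
    return out


def gatk_hard_filter(gm: GenotypeMatrix) -> GenotypeMatrix:
    """Drop sites failing any variant-calling hard-filter inequality.

    Failure conditions: QD < 2.0, QUAL < 30.0, SOR > 3.0, FS > 60.0,
    MQ < 40.0, MQRankSum < -12.5, ReadPosRankSum < -8.0. A site lacking a
    field is not tested on it. Idempotent.
    """
    if gm.info is None:
        return gm
    info = gm.info
    fail = np.zeros(gm.n_sites, dtype=bool)
    rules = [
        ("QD", "<", 2.0),
        ("QUAL", "<", 30.0),
        ("SOR", ">", 3.0),
        ("FS", ">", 60.0),
        ("MQ", "<", 40.0),
        ("MQRankSum", "<", -12.5),
        ("ReadPosRankSum", "<", -8.0),
    ]
    for key, op, thresh in rules:
        vals = info[key].to_numpy(dtype=float)
        with np.errstate(invalid="ignore"):
            bad = vals < thresh if op == "<" else vals > thresh
        fail |= np.nan_to_num(bad, nan=False).astype(bool) & ~np.isnan(vals)
    out = gm.take_sites(np.flatnonzero(~fail))
    logger.info("gatk_hard_filter: dropped %d/%d sites", int(fail.sum()), gm.n_sites)
    return out


def subset(
    gm: GenotypeMatrix,
    meta: pd.DataFrame,
    populations: Optional[Iterable[str]] = None,
    sexes: Optional[Iterable[str]] = None,
    sample_ids: Optional[Iterable[str]] = None,
) -> GenotypeMatrix:
    """Restrict to samples matching all given selectors; sites unchanged."""
    meta = meta.set_index("sample_id", drop=False)
    keep = pd.Series(True, index=[s for s in gm.sample_ids])
    if populations is not None:
        populations = set(populations)
        unknown = populations - set(meta["population"])
        if unknown:
            raise DataError(f"unknown population label(s) {sorted(unknown)}")
        keep &= pd.Series({s: meta.loc[s, "population"] in populations for s in gm.sample_ids})
    if sexes is not None:
        sexes = set(sexes)
        if not sexes <= {"female", "male"}:
            raise DataError(f"unknown sex label(s) {sorted(sexes - {'female', 'male'})}")
        keep &= pd.Series({s: meta.loc[s, "sex"] in sexes for s in gm.sample_ids})
    if sample_ids is not None:
        sample_ids = set(sample_ids)
        unknown = sample_ids - set(gm.sample_ids)
        if unknown:
            raise DataError(f"unknown sample id(s) {sorted(unknown)[:5]}")
        keep &= pd.Series({s: s in sample_ids for s in gm.sample_ids})
    idx = [i for i, s in enumerate(gm.sample_ids) if keep[s]]
    return gm.take_samples(idx)


def restrict_to_polymorphic(
    gm: GenotypeMatrix, samples: Optional[Iterable[str]] = None
) -> GenotypeMatrix:
    """Keep sites with >= 2 distinct non-missing alleles among ``samples``.

    All samples are retained in the output; only the site set shrinks.
    """
    if samples is None:
        idx = np.arange(gm.n_samples)
    else:
        idx = np.array([gm.sample_index(s) for s in samples])
        if idx.size == 0:
            raise DataError("restrict_to_polymorphic: empty sample subset")
    calls = gm.calls[idx]
    ref_present = ((calls == 0) | (calls == 1)).any(axis=0)
    alt_present = ((calls == 2) | (calls == 1)).any(axis=0)
    keep = np.flatnonzero(ref_present & alt_present)
    logger.info(
        "restrict_to_polymorphic: kept %d/%d sites over %d samples",
        keep.size, gm.n_sites, idx.size,
    )
    return gm.take_sites(keep)


def site_subsample(gm: GenotypeMatrix, step: int = 90) -> GenotypeMatrix:
    """Keep every ``step``-th site in genome order (indices 0, step, 2*step...)."""
    if step < 1:
        raise ConfigError(f"site_subsample step must be >= 1, got {step}")
    return gm.take_sites(np.arange(0, gm.n_sites, step))
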