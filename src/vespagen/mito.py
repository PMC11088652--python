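"""Mitochondrial super-barcode QC, site census and mitotype assignment.

Whole-mitogenome ("super-barcode") haplotyping from per-sample consensus
sequences called against a fixed reference. The QC pipeline is, in order:

1. :func:`mask_low_depth` — sites with read depth below a floor become N;
2. :func:`drop_high_n_samples` — samples whose N fraction exceeds a cap are
   removed (low individual coverage / poor template);
3. :func:`drop_n_columns` — alignment columns containing any N or IUPAC
   ambiguity code in any remaining sample are removed.

The trimmed alignment is then censused (parsimony-informative / singleton /
constant sites, which partition its length exactly) and partitioned into
mitotypes: equivalence classes of identical post-trim sequences. Re-running
the trim on trimmed output is the identity.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .errors import ConfigError, DataError

_STANDARD = np.frombuffer(b"ACGT", dtype="S1")


@dataclass
class MitoAlignment:
    """Equal-length consensus sequences with optional per-site read depth."""

    sample_ids: list[str]
    seqs: np.ndarray  # (n_samples, length) byte array, dtype 'S1'
    depth: Optional[np.ndarray] = None  # same shape, reads

    def __post_init__(self) -> None:
        self.seqs = np.asarray(self.seqs, dtype="S1")
        if self.seqs.ndim != 2 or self.seqs.shape[0] != len(self.sample_ids):
            raise DataError("seqs must be n_samples x length")
        if self.seqs.shape[1] == 0:
            raise DataError("empty alignment")
        if self.depth is not None and self.depth.shape != self.seqs.shape:
            raise DataError("depth shape must match seqs")

    @property
    def length(self) -> int:
        return self.seqs.shape[1]

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def sequence(self, sample_id: str) -> str:
        i = self.sample_ids.index(sample_id)
        return self.seqs[i].tobytes().decode()


@dataclass
class SiteCensus:
    """Counts of parsimony-informative, singleton and constant columns."""

    n_parsimony_informative: int
    n_singleton: int
    n_constant: int

    @property
    def total(self) -> int:
        return self.n_parsimony_informative + self.n_singleton + self.n_constant


@dataclass
class MitotypeTable:
    """Sample -> mitotype partition with one representative sequence per type."""

    assignments: dict[str, str]
    n_mitotypes: int
    representative: dict[str, str]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"sample": list(self.assignments), "mitotype": list(self.assignments.values())}
        )


# ---------------------------------------------------------------------------
# FASTA / depth I/O
# ---------------------------------------------------------------------------


def read_fasta(path: str) -> MitoAlignment:
    from Bio import SeqIO

    ids, rows = [], []
    for rec in SeqIO.parse(str(path), "fasta"):
        ids.append(rec.id)
        rows.append(np.frombuffer(str(rec.seq).upper().encode(), dtype="S1"))
    if not ids:
        raise DataError(f"no sequences in {path}")
    if len({r.size for r in rows}) != 1:
        raise DataError(f"sequences in {path} are not equal length")
    return MitoAlignment(ids, np.vstack(rows))


def write_fasta(aln: MitoAlignment, path: str) -> str:
    from Bio import SeqIO
    from Bio.Seq import Seq
    from Bio.SeqRecord import SeqRecord

    records = [
        SeqRecord(Seq(aln.seqs[i].tobytes().decode()), id=s, description="")
        for i, s in enumerate(aln.sample_ids)
    ]
    SeqIO.write(records, str(path), "fasta")
    return str(path)


def read_depth(path: str, aln: MitoAlignment) -> MitoAlignment:
    """Attach a positions x samples depth TSV (column per sample) to ``aln``."""
    df = pd.read_csv(path, sep="\t")
    missing = [s for s in aln.sample_ids if s not in df.columns]
    if missing:
        raise DataError(f"depth table lacks columns for samples {missing[:5]}")
    depth = df[aln.sample_ids].to_numpy().T
    if depth.shape != aln.seqs.shape:
        raise DataError("depth table length does not match alignment")
    return MitoAlignment(aln.sample_ids, aln.seqs, depth)


def write_depth(aln: MitoAlignment, path: str) -> str:
    if aln.depth is None:
        raise ConfigError("alignment has no depth track")
    df = pd.DataFrame(aln.depth.T, columns=aln.sample_ids)
    df.insert(0, "position", np.arange(1, aln.length + 1))
    df.to_csv(path, sep="\t", index=False)
    return str(path)


# ---------------------------------------------------------------------------
# QC / trimming
# ---------------------------------------------------------------------------


def mask_low_depth(aln: MitoAlignment, min_depth: float = 100) -> MitoAlignment:
    """Set sites with depth < ``min_depth`` to N, per sample."""
    if aln.depth is None:
        raise ConfigError("mask_low_depth requires a depth track")
    seqs = aln.seqs.copy()
    seqs[aln.depth < min_depth] = b"N"
    return MitoAlignment(list(aln.sample_ids), seqs, aln.depth)


def drop_high_n_samples(aln: MitoAlignment, max_n_frac: float = 0.004) -> MitoAlignment:
    """Remove samples whose fraction of N/ambiguous sites exceeds ``max_n_frac``."""
    ambiguous = ~np.isin(aln.seqs, _STANDARD)
    frac = ambiguous.mean(axis=1)
    keep = np.flatnonzero(frac <= max_n_frac)
    if keep.size == 0:
        raise DataError("all samples exceed the N-fraction cap")
    return MitoAlignment(
        [aln.sample_ids[i] for i in keep],
        aln.seqs[keep],
        None if aln.depth is None else aln.depth[keep],
    )


def drop_n_columns(aln: MitoAlignment) -> MitoAlignment:
    """Remove columns containing any N or IUPAC ambiguity in any sample."""
    clean = np.isin(aln.seqs, _STANDARD).all(axis=0)
    if not clean.any():
        raise DataError("no alignment columns survive N-column removal")
    return MitoAlignment(
        list(aln.sample_ids),
        aln.seqs[:, clean],
        None if aln.depth is None else aln.depth[:, clean],
    )


# ---------------------------------------------------------------------------
# Census and mitotypes
# ---------------------------------------------------------------------------


def classify_sites(aln: MitoAlignment) -> SiteCensus:
    """Partition columns into parsimony-informative / singleton / constant.

    Constant: one allele. Parsimony-informative: >= 2 alleles each carried by
    >= 2 samples. Singleton: variable but not informative (every minor allele
    occurs once; a three-allele column with two single-copy minors still
    counts as one singleton site — the census classifies sites, not alleles).
    """
    if not np.isin(aln.seqs, _STANDARD).all():
        raise DataError("classify_sites requires an N-free alignment")
    n_const = n_single = n_inform = 0
    for j in range(aln.length):
        col = aln.seqs[:, j]
        _, counts = np.unique(col, return_counts=True)
        if counts.size == 1:
            n_const += 1
        elif (counts >= 2).sum() >= 2:
            n_inform += 1
        else:
            n_single += 1
    return SiteCensus(n_inform, n_single, n_const)


def call_mitotypes(aln: MitoAlignment, label_prefix: str = "mt") -> MitotypeTable:
    """Group identical post-trim sequences; labels in first-occurrence order."""
    assignments: dict[str, str] = {}
    representative: dict[str, str] = {}
    seen: dict[bytes, str] = {}
    for i, s in enumerate(aln.sample_ids):
        key = aln.seqs[i].tobytes()
        if key not in seen:
            label = f"{label_prefix}-{len(seen) + 1}"
            seen[key] = label
            representative[label] = key.decode()
        assignments[s] = seen[key]
    return MitotypeTable(assignments, len(seen), representative)


def mitotype_pipeline(
    aln: MitoAlignment, min_depth: float = 100, max_n_frac: float = 0.004
) -> tuple[MitoAlignment, SiteCensus, MitotypeTable]:
    """Full QC + census + mitotype chain in the fixed order."""
    masked = mask_low_depth(aln, min_depth) if aln.depth is not None else aln
    trimmed = drop_n_columns(drop_high_n_samples(masked, max_n_frac))
    return trimmed, classify_sites(trimmed), call_mitotypes(trimmed)
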