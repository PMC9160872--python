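"""Count normalization (TPM / RPKM), expression filtering and sample QC.

The central container is :class:`ExpressionTable`: a transcripts × samples
matrix tagged with its unit (``count``, ``TPM`` or ``RPKM``) and carrying
transcript lengths and per-sample mapped-read totals.  Parental samples
are quantified against their own transcriptome; hybrid samples against
the concatenation of both parental transcriptomes, so the hybrid table
contains both homeologs of every pair.

TPM renormalizes length-corrected rates so every sample sums to one
million; RPKM divides by transcript length (kb) and mapped reads
(millions).  When no explicit mapped-read totals are supplied the column
sums of the count matrix stand in for them.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ExpressionTable",
    "compute_tpm",
    "compute_rpkm",
    "filter_expressed",
    "sample_correlation",
    "read_counts",
    "read_lengths",
    "read_metadata",
    "read_library_sizes",
    "validate_metadata",
    "TAXA",
]

#: Valid taxon labels: the two parents and the hybrid.
TAXA = ("P1", "P2", "F1")

_UNITS = ("count", "TPM", "RPKM")


@dataclass
class ExpressionTable:
    """Transcripts × samples expression matrix with a unit tag.

    Parameters
    ----------
    values
        Non-negative matrix; index = transcript ids, columns = sample ids.
    unit
        One of ``count``, ``TPM``, ``RPKM``.
    lengths
        Transcript lengths in bp, indexed like ``values`` (required for
        TPM/RPKM computation).
    library_sizes
        Mapped reads per sample.  Optional; column sums are the fallback.
    """

    values: pd.DataFrame
    unit: str = "count"
    lengths: pd.Series | None = None
    library_sizes: pd.Series | None = None

    def __post_init__(self) -> None:
        if self.unit not in _UNITS:
            raise ValueError(f"unit must be one of {_UNITS}, got {self.unit!r}")
        if (self.values.to_numpy() < 0).any():
            raise ValueError("expression values must be non-negative")
        if self.lengths is not None:
            missing = self.values.index.difference(self.lengths.index)
            if len(missing):
                raise ValueError(
                    f"{len(missing)} transcripts lack a length "
                    f"(e.g. {missing[0]!r})"
                )
            self.lengths = self.lengths.reindex(self.values.index)
            if (self.lengths < 1).any():
                raise ValueError("transcript lengths must be >= 1 bp")
        if self.library_sizes is not None:
            missing = self.values.columns.difference(self.library_sizes.index)
            if len(missing):
                raise ValueError(f"samples lack a library size: {list(missing)}")
            self.library_sizes = self.library_sizes.reindex(self.values.columns)
            if (self.library_sizes <= 0).any():
                raise ValueError("library sizes must be positive")

    @property
    def transcript_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    def effective_library_sizes(self) -> pd.Series:
        """Explicit mapped-read totals if supplied, else count column sums."""
        if self.library_sizes is not None:
            return self.library_sizes
        if self.unit != "count":
            raise ValueError(
                "library sizes can only be inferred from a count matrix"
            )
        return self.values.sum(axis=0)


def compute_tpm(counts: ExpressionTable) -> ExpressionTable:
    """Transcripts-per-million normalization.

    Per sample: ``rate_t = count_t / length_t``; ``TPM_t = 1e6 * rate_t /
    sum(rate)``.  Columns of the result sum to 1e6 except for all-zero
    samples, which stay all-zero (with a warning).
    """
    if counts.unit != "count":
        raise ValueError(f"compute_tpm needs counts, got unit {counts.unit!r}")
    if counts.lengths is None:
        raise ValueError("compute_tpm requires transcript lengths")
    rate = counts.values.div(counts.lengths, axis=0)
    totals = rate.sum(axis=0)
    zero_cols = totals == 0
    if zero_cols.any():
        warnings.warn(
            f"samples with all-zero counts left as zero TPM: "
            f"{list(totals.index[zero_cols])}",
            stacklevel=2,
        )
        totals = totals.replace(0, np.nan)
    tpm = rate.div(totals, axis=1).fillna(0.0) * 1e6
    return replace(counts, values=tpm, unit="TPM")


def compute_rpkm(
    counts: ExpressionTable, library_sizes: pd.Series | None = None
) -> ExpressionTable:
    """Reads per kilobase per million mapped reads.

    ``RPKM_ts = count_ts * 1e9 / (length_t * library_size_s)``.
    """
    if counts.unit != "count":
        raise ValueError(f"compute_rpkm needs counts, got unit {counts.unit!r}")
    if counts.lengths is None:
        raise ValueError("compute_rpkm requires transcript lengths")
    if library_sizes is None:
        library_sizes = counts.effective_library_sizes()
    library_sizes = library_sizes.reindex(counts.values.columns)
    if library_sizes.isna().any() or (library_sizes <= 0).any():
        raise ValueError("every sample needs a positive library size")
    rpkm = (
        counts.values.mul(1e9)
        .div(counts.lengths, axis=0)
        .div(library_sizes, axis=1)
    )
    return replace(counts, values=rpkm, unit="RPKM", library_sizes=library_sizes)


def filter_expressed(
    tpm: ExpressionTable, min_tpm: float = 1.0, min_samples: int = 1
) -> set[str]:
    """Transcripts with ``TPM >= min_tpm`` in at least ``min_samples`` samples."""
    if tpm.unit != "TPM":
        raise ValueError(f"filter_expressed needs TPM, got unit {tpm.unit!r}")
    n_ok = (tpm.values >= min_tpm).sum(axis=1)
    return set(tpm.values.index[n_ok >= min_samples])


def sample_correlation(expr: ExpressionTable) -> pd.DataFrame:
    """Pairwise Spearman rank correlation between samples (QC).

    Ties receive average ranks.  A sample whose column is constant has no
    defined rank correlation; its off-diagonal entries are NaN and a
    warning is emitted.  The diagonal is exactly 1.
    """
    vals = expr.values
    if vals.shape[1] < 2:
        raise ValueError("sample_correlation needs at least 2 samples")
    if vals.shape[0] < 3:
        raise ValueError("sample_correlation needs at least 3 transcripts")
    constant = vals.nunique(axis=0) <= 1
    if constant.any():
        warnings.warn(
            f"constant samples have undefined rank correlation: "
            f"{list(vals.columns[constant])}",
            stacklevel=2,
        )
    with warnings.catch_warnings():
        # our own warning above already covers the constant-sample case
        warnings.simplefilter("ignore", stats.ConstantInputWarning)
        rho = stats.spearmanr(vals.to_numpy(), axis=0).statistic
    if np.ndim(rho) == 0:  # scipy collapses the 2-sample case to a scalar
        rho = np.array([[1.0, float(rho)], [float(rho), 1.0]])
    out = pd.DataFrame(rho, index=vals.columns, columns=vals.columns)
    out.values[np.diag_indices_from(out.values)] = 1.0
    return out


# ---------------------------------------------------------------------------
# readers


def read_counts(
    path: str | Path,
    lengths: pd.Series | None = None,
    library_sizes: pd.Series | None = None,
) -> ExpressionTable:
    """Read a count matrix TSV: first column transcript id, header row of
    sample ids."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.has_duplicates:
        dup = df.index[df.index.duplicated()][0]
        raise ValueError(f"{path}: duplicated transcript id {dup!r}")
    return ExpressionTable(
        values=df.astype(float),
        unit="count",
        lengths=lengths,
        library_sizes=library_sizes,
    )


def read_lengths(path: str | Path) -> pd.Series:
    """Transcript lengths from a 2-column TSV (id, length) or a FASTA file."""
    path = Path(path)
    with path.open() as fh:
        first = fh.readline()
    if first.startswith(">"):
        from Bio import SeqIO

        lengths = {rec.id: len(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}
        return pd.Series(lengths, name="length", dtype=int)
    df = pd.read_csv(path, sep="\t")
    if df.shape[1] < 2:
        raise ValueError(f"{path}: expected 2 columns (id, length)")
    ser = df.set_index(df.columns[0])[df.columns[1]].astype(int)
    ser.name = "length"
    return ser


def read_library_sizes(path: str | Path) -> pd.Series:
    """Mapped-read totals from a 2-column TSV (sample_id, mapped_reads)."""
    df = pd.read_csv(path, sep="\t")
    if df.shape[1] < 2:
        raise ValueError(f"{path}: expected 2 columns (sample_id, mapped_reads)")
    ser = df.set_index(df.columns[0])[df.columns[1]].astype(float)
    ser.name = "mapped_reads"
    return ser


def validate_metadata(meta: pd.DataFrame) -> pd.DataFrame:
    """Validate a sample-metadata table (sample_id, taxon, condition, replicate)."""
    required = {"sample_id", "taxon", "condition", "replicate"}
    missing = required - set(meta.columns)
    if missing:
        raise ValueError(f"metadata missing columns: {sorted(missing)}")
    bad = set(meta["taxon"]) - set(TAXA)
    if bad:
        raise ValueError(f"unknown taxon labels {sorted(bad)}; expected {TAXA}")
    if meta["sample_id"].duplicated().any():
        raise ValueError("duplicate sample_id in metadata")
    key = meta[["taxon", "condition", "replicate"]]
    if key.duplicated().any():
        raise ValueError("duplicate (taxon, condition, replicate) in metadata")
    if (meta["replicate"].astype(int) < 1).any():
        raise ValueError("replicate numbers must be positive integers")
    return meta


def read_metadata(path: str | Path) -> pd.DataFrame:
    """Read and validate the sample-metadata TSV."""
    meta = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "condition": str})
    return validate_metadata(meta)
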