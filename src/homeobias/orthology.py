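"""Reciprocal-best-hit pairing of two parental transcript sets.

Homeolog pairs are built from two precomputed tabular alignment files
(the standard 12-column BLAST ``outfmt 6`` dialect), one per direction.
Hits are first filtered on percent identity and E-value to suppress
out-paralogs, then paired by strict reciprocal best hit: transcript *a*
and *b* are paired iff *b* is *a*'s top-scoring hit in the A→B table and
*a* is *b*'s top-scoring hit in the B→A table.  "Best" means highest
bitscore, with ties broken by lowest E-value and then lexicographically
smallest subject id, so the pairing is a deterministic function of the
hit set regardless of row order.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

from homeobias.errors import HitTableParseError, SelfHitError

__all__ = [
    "AlignmentHit",
    "HomeologPair",
    "parse_hit_table",
    "filter_hits",
    "reciprocal_best_hits",
    "write_pairs",
    "read_pairs",
    "DEFAULT_MIN_IDENTITY",
    "DEFAULT_MAX_EVALUE",
]

#: Stringent pre-filter defaults used to reduce out-paralog hits.
DEFAULT_MIN_IDENTITY = 90.0
DEFAULT_MAX_EVALUE = 1e-50


@dataclass(frozen=True)
class AlignmentHit:
    """One row of a tabular alignment file (query → subject)."""

    query_id: str
    subject_id: str
    percent_identity: float
    evalue: float
    bitscore: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.percent_identity <= 100.0:
            raise ValueError(
                f"percent_identity must be in [0, 100], got {self.percent_identity}"
            )
        if self.evalue < 0.0:
            raise ValueError(f"evalue must be non-negative, got {self.evalue}")


@dataclass(frozen=True)
class HomeologPair:
    """A P1 transcript paired 1:1 with a P2 transcript."""

    p1_id: str
    p2_id: str


def parse_hit_table(path: str | Path) -> list[AlignmentHit]:
    """Parse a 12-column tab-separated alignment table.

    Columns follow the standard tabular dialect (qseqid, sseqid, pident,
    length, mismatch, gapopen, qstart, qend, sstart, send, evalue,
    bitscore); only columns 1, 2, 3, 11 and 12 are retained.  Lines
    starting with ``#`` are ignored.  A row with fewer than 12 columns
    raises :class:`HitTableParseError` naming the offending line.
    """
    path = Path(path)
    hits: list[AlignmentHit] = []
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 12:
                raise HitTableParseError(
                    f"{path}:{lineno}: expected >=12 tab-separated columns, "
                    f"got {len(fields)}"
                )
            try:
                hit = AlignmentHit(
                    query_id=fields[0],
                    subject_id=fields[1],
                    percent_identity=float(fields[2]),
                    evalue=float(fields[10]),
                    bitscore=float(fields[11]),
                )
            except ValueError as exc:
                raise HitTableParseError(f"{path}:{lineno}: {exc}") from exc
            hits.append(hit)
    if not hits:
        warnings.warn(f"hit table {path} contains no alignment rows", stacklevel=2)
    return hits


def filter_hits(
    hits: Iterable[AlignmentHit],
    min_identity: float = DEFAULT_MIN_IDENTITY,
    max_evalue: float = DEFAULT_MAX_EVALUE,
) -> list[AlignmentHit]:
    """Keep hits with ``percent_identity >= min_identity`` and
    ``evalue <= max_evalue``, preserving input order."""
    if not 0.0 <= min_identity <= 100.0:
        raise ValueError(f"min_identity must be in [0, 100], got {min_identity}")
    if not max_evalue >= 0.0:
        raise ValueError("max_evalue must be non-negative")
    return [
        h
        for h in hits
        if h.percent_identity >= min_identity and h.evalue <= max_evalue
    ]


def _best_hits(hits: Iterable[AlignmentHit]) -> dict[str, AlignmentHit]:
    """Map each query to its single best hit.

    Best = highest bitscore; ties broken by lowest evalue, then by
    lexicographically smallest subject id (a total order, so the result is
    independent of input row order).
    """
    best: dict[str, AlignmentHit] = {}
    for h in hits:
        if h.query_id == h.subject_id:
            raise SelfHitError(
                f"transcript {h.query_id!r} hits itself; parental identifier "
                "namespaces must be disjoint"
            )
        cur = best.get(h.query_id)
        if cur is None:
            best[h.query_id] = h
            continue
        cand_key = (-h.bitscore, h.evalue, h.subject_id)
        cur_key = (-cur.bitscore, cur.evalue, cur.subject_id)
        if cand_key < cur_key:
            best[h.query_id] = h
    return best


def reciprocal_best_hits(
    hits_ab: Iterable[AlignmentHit], hits_ba: Iterable[AlignmentHit]
) -> list[HomeologPair]:
    """Strict 1:1 reciprocal-best-hit pairs from two directional hit sets.

    ``hits_ab`` holds P1→P2 alignments, ``hits_ba`` P2→P1.  Pair
    ``(a, b)`` is emitted iff ``b`` is ``a``'s best subject in ``hits_ab``
    and ``a`` is ``b``'s best subject in ``hits_ba``.  The output is
    sorted by ``p1_id`` and each transcript occurs in at most one pair.
    """
    best_ab = _best_hits(hits_ab)
    best_ba = _best_hits(hits_ba)
    pairs = [
        HomeologPair(p1_id=a, p2_id=hit.subject_id)
        for a, hit in best_ab.items()
        if best_ba.get(hit.subject_id) is not None
        and best_ba[hit.subject_id].subject_id == a
    ]
    pairs.sort(key=lambda p: p.p1_id)
    return pairs


def write_pairs(pairs: Sequence[HomeologPair], path: str | Path) -> None:
    """Write pairs as a 2-column TSV with a one-line header."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write("p1_id\tp2_id\n")
        for p in pairs:
            fh.write(f"{p.p1_id}\t{p.p2_id}\n")


def read_pairs(path: str | Path) -> list[HomeologPair]:
    """Read pairs written by :func:`write_pairs`."""
    path = Path(path)
    pairs: list[HomeologPair] = []
    with path.open() as fh:
        header = fh.readline()
        if not header.startswith("p1_id"):
            raise ValueError(f"{path}: missing 'p1_id\\tp2_id' header")
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) != 2:
                raise ValueError(f"{path}:{lineno}: expected 2 columns")
            pairs.append(HomeologPair(p1_id=fields[0], p2_id=fields[1]))
    return pairs
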