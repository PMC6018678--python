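"""From raw screen reads to normalized, filtered sgRNA count tables.

Reads carry the spacer inside a fixed ``GCAC + N20 + GTTT`` cassette.  The
processing chain is: quality filtering (length cap, end trimming, composite
Phred cutoffs), exact cassette extraction on either orientation, exact-match
counting against the designed library, per-library depth normalization,
low-count filtering on the reference (initial/control) library, and
geometric-mean replicate combination.
"""

from __future__ import annotations

import gzip
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio import SeqIO

from crispri_kit.genome import revcomp

logger = logging.getLogger(__name__)

MAX_READ_LENGTH = 194
TRIM_QUALITY = 25
CASSETTE_UP = "GCAC"
CASSETTE_DOWN = "GTTT"
CASSETTE_LEN = 28


@dataclass
class ReadRecord:
    """A sequencing read with per-base Phred qualities."""

    identifier: str
    bases: str
    qualities: list[int]

    def __post_init__(self) -> None:
        if len(self.bases) != len(self.qualities):
            raise ValueError(f"{self.identifier}: bases/qualities length mismatch")


def read_fastq(path):
    """Yield :class:`ReadRecord` from a (possibly gzipped) FASTQ file."""
    opener = gzip.open if str(path).endswith(".gz") else open
    with opener(path, "rt") as fh:
        try:
            for rec in SeqIO.parse(fh, "fastq"):
                yield ReadRecord(
                    rec.id, str(rec.seq).upper(), rec.letter_annotations["phred_quality"]
                )
        except ValueError as exc:
            raise ValueError(f"malformed FASTQ in {path}: {exc}") from exc


def quality_filter(reads, stats: dict | None = None):
    """Apply the read-level quality rules; yields surviving (trimmed) reads.

    Rules, in order: drop reads longer than 194 nt; trim leading/trailing
    bases with Phred < 25; keep the read only if it has no base below Q10,
    more than 85% of bases at Q>=20 and more than 60% at Q>=30.
    """
    counters = stats if stats is not None else {}
    counters.setdefault("input", 0)
    counters.setdefault("too_long", 0)
    counters.setdefault("failed_quality", 0)
    counters.setdefault("passed", 0)
    for read in reads:
        counters["input"] += 1
        if len(read.bases) > MAX_READ_LENGTH:
            counters["too_long"] += 1
            continue
        quals = np.asarray(read.qualities)
        keep = np.nonzero(quals >= TRIM_QUALITY)[0]
        if keep.size == 0:
            counters["failed_quality"] += 1
            continue
        lo, hi = keep[0], keep[-1] + 1
        bases, quals = read.bases[lo:hi], quals[lo:hi]
        n = len(quals)
        if (quals < 10).sum() >= 1 or (quals >= 20).sum() / n <= 0.85 or (quals >= 30).sum() / n <= 0.60:
            counters["failed_quality"] += 1
            continue
        counters["passed"] += 1
        yield ReadRecord(read.identifier, bases, list(quals))


def extract_spacer(read) -> str | None:
    """Extract the 20-mer from the first exact GCAC+N20+GTTT cassette.

    The forward sequence is searched first, then its reverse complement; a
    cassette with any substitution in either 4-bp flank does not match.
    Returns ``None`` when no intact cassette is present.
    """
    bases = read.bases if isinstance(read, ReadRecord) else str(read)
    for seq in (bases, revcomp(bases)):
        hits = []
        start = seq.find(CASSETTE_UP)
        while start != -1:
            end = start + CASSETTE_LEN
            if end <= len(seq) and seq[end - 4 : end] == CASSETTE_DOWN:
                hits.append(seq[start + 4 : end - 4])
            start = seq.find(CASSETTE_UP, start + 1)
        if hits:
            if len(hits) > 1:
                logger.warning("read contains %d cassettes; using the first", len(hits))
            return hits[0]
    return None


@dataclass
class CountColumn:
    """Counts for one sequencing library plus mapping statistics."""

    counts: pd.Series
    n_extracted: int
    n_mapped: int

    @property
    def mapping_ratio(self) -> float:
        if self.n_extracted == 0:
            return float("nan")
        return self.n_mapped / self.n_extracted


def count_spacers(spacers, library_spacers: pd.Series) -> CountColumn:
    """Exact-match counting of extracted spacers against the library.

    ``library_spacers`` maps sgRNA name -> 20-nt spacer and must be unique;
    unmapped spacers are tallied but not assigned.
    """
    if library_spacers.duplicated().any():
        raise ValueError("library spacers are not unique")
    lookup = {spacer: name for name, spacer in library_spacers.items()}
    counts = dict.fromkeys(library_spacers.index, 0)
    n_extracted = n_mapped = 0
    for spacer in spacers:
        if spacer is None:
            continue
        n_extracted += 1
        name = lookup.get(spacer)
        if name is not None:
            counts[name] += 1
            n_mapped += 1
    return CountColumn(
        counts=pd.Series(counts, name="count"),
        n_extracted=n_extracted,
        n_mapped=n_mapped,
    )


def normalize_counts(table: pd.DataFrame) -> pd.DataFrame:
    """Depth-normalize libraries to the mean total.

    Each library i is divided by ``factor_i = total_i / mean(totals)`` so all
    normalized totals equal the mean of the original totals.  Idempotent.
    """
    totals = table.sum(axis=0)
    if (totals <= 0).any():
        bad = totals.index[totals <= 0].tolist()
        raise ValueError(f"library with zero total reads: {bad}")
    factors = totals / totals.mean()
    return table / factors


def filter_low_count(
    table: pd.DataFrame, reference_library: str, min_reads: float = 20
) -> pd.DataFrame:
    """Drop sgRNAs with fewer than ``min_reads`` in the reference library
    (the initial or control library of the experiment); exactly ``min_reads``
    is kept."""
    if reference_library not in table.columns:
        raise KeyError(f"reference library {reference_library!r} not in table")
    return table.loc[table[reference_library] >= min_reads]


def combine_replicates(table_a: pd.DataFrame, table_b: pd.DataFrame) -> pd.DataFrame:
    """Geometric mean of two biological replicates, entrywise.

    A zero in either replicate yields zero (no pseudocount here; depletion is
    handled by the fitness pseudocount downstream).
    """
    if not table_a.index.equals(table_b.index) or not table_a.columns.equals(table_b.columns):
        raise ValueError("replicate tables have mismatched rows/columns")
    return np.sqrt(table_a * table_b)
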