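"""k-mer spectrum profiling and genome-size estimation.

The estimator is the classic spectrum formula G = (K_total - K_error) / D:
K_total is the total k-mer count of the read set, K_error the count of
low-multiplicity k-mers attributed to sequencing error, and D the depth of
the spectrum's main (homozygous) peak. Counting is numpy-vectorised over a
2-bit base encoding; windows containing N (or any non-ACGT base) are
skipped.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .core import SeqRecord, div_round_half_up, round_half_up
from .errors import NoPeakError, ValidationError

_ENC = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _ENC[_b] = _i
for _i, _b in enumerate(b"acgt"):
    _ENC[_b] = _i


def encode_bases(seq: str) -> np.ndarray:
    """2-bit encode a DNA string; non-ACGT bases become the sentinel 4."""
    return _ENC[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def kmer_codes(vals: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Forward k-mer codes and a validity mask for every window.

    Returns (codes, valid) of length len(vals)-k+1; windows touching a
    sentinel base are invalid (their codes are garbage and must be masked).
    """
    n = len(vals)
    m = n - k + 1
    if m <= 0:
        return np.empty(0, np.uint64), np.empty(0, bool)
    bad = np.concatenate(([0], np.cumsum(vals >= 4, dtype=np.int64)))
    valid = (bad[k:] - bad[:-k]) == 0
    v = vals.astype(np.uint64)
    v &= np.uint64(3)  # sentinel bases are masked out via `valid`
    codes = np.zeros(m, dtype=np.uint64)
    for j in range(k):  # in-place rolling pack: ~k cheap passes, no temporaries
        codes <<= np.uint64(2)
        codes |= v[j : j + m]
    return codes, valid


def revcomp_codes(codes: np.ndarray, k: int) -> np.ndarray:
    """Reverse-complement of 2-bit packed k-mer codes."""
    rc = np.zeros_like(codes)
    c = codes.copy()
    tmp = np.empty_like(codes)
    two, three = np.uint64(2), np.uint64(3)
    for _ in range(k):
        rc <<= two
        np.bitwise_and(c, three, out=tmp)
        tmp ^= three
        rc |= tmp
        c >>= two
    return rc


@dataclass
class KmerHistogram:
    """Distinct-k-mer counts by multiplicity."""

    k: int
    counts: dict[int, int]
    canonical: bool

    @property
    def k_total(self) -> int:
        """Total k-mer count: sum of multiplicity x distinct k-mers."""
        return sum(m * c for m, c in self.counts.items())

    def k_error(self, error_multiplicity_max: int = 1) -> int:
        return sum(m * c for m, c in self.counts.items() if m <= error_multiplicity_max)


def count_kmers(records: Sequence[SeqRecord], k: int, canonical: bool = True) -> KmerHistogram:
    """Count k-mers over a record set into a multiplicity histogram.

    Canonical counting (Jellyfish-style) pools each k-mer with its reverse
    complement under the lexicographically smaller representative; depth
    peaks are defined on such strand-collapsed spectra. Deterministic.
    """
    if k < 1:
        raise ValidationError(f"k must be >= 1, got {k}")
    if canonical and k % 2 == 0:
        # even k admits self-reverse-complement palindromes; allowed, just noted
        pass
    if not records:
        return KmerHistogram(k, {}, canonical)
    # one vectorised pass over all records; N separators invalidate
    # windows that would otherwise straddle record boundaries
    joined = "N".join(rec.sequence for rec in records)
    all_codes, valid = kmer_codes(encode_bases(joined), k)
    if all_codes.size == 0 or not valid.any():
        return KmerHistogram(k, {}, canonical)
    codes = all_codes[valid]
    if canonical:
        codes = np.minimum(codes, revcomp_codes(codes, k))
    _, mult = np.unique(codes, return_counts=True)
    ms, cs = np.unique(mult, return_counts=True)
    return KmerHistogram(k, {int(m): int(c) for m, c in zip(ms, cs)}, canonical)


def find_peak_depth(hist: KmerHistogram, min_valley_search: int = 2) -> int:
    """Depth of the coverage peak beyond the error valley.

    The valley is the first local minimum of counts[m] for
    m >= min_valley_search (on the dense spectrum, absent multiplicities
    counting as zero); the peak is the argmax strictly beyond it, ties
    broken toward smaller m. A spectrum that only decreases has no
    coverage peak and raises NoPeakError.
    """
    if not hist.counts:
        raise ValidationError("empty histogram")
    max_m = max(hist.counts)
    dense = np.zeros(max_m + 2, dtype=np.int64)  # index = multiplicity; +1 pad
    for m, c in hist.counts.items():
        dense[m] = c
    valley = None
    for m in range(max(min_valley_search, 1), max_m):
        left = dense[m - 1] if m >= 2 else np.iinfo(np.int64).max
        if dense[m] <= left and dense[m] <= dense[m + 1]:
            valley = m
            break
    if valley is None or valley >= max_m:
        raise NoPeakError("k-mer spectrum has no coverage peak beyond the error valley")
    tail = dense[valley + 1 : max_m + 1]
    if tail.max() == 0:
        raise NoPeakError("k-mer spectrum has no coverage peak beyond the error valley")
    return valley + 1 + int(np.argmax(tail))  # argmax returns first max (smaller m)


@dataclass
class GenomeSizeEstimate:
    """Genome size from the spectrum formula G = (K_total - K_error)/D."""

    G: int
    K_total: int
    K_error: int
    D: int
    error_multiplicity_max: int

    @property
    def mb(self) -> float:
        """Genome size in Mb, rounded half-up to 0 decimals."""
        return round_half_up(self.G / 1e6, 0)


def estimate_genome_size(
    hist: KmerHistogram, D: int, error_multiplicity_max: int = 1
) -> GenomeSizeEstimate:
    """Apply the spectrum formula to a histogram at peak depth D."""
    if D < 1:
        raise ValidationError(f"peak depth D must be >= 1, got {D}")
    k_total = hist.k_total
    k_error = hist.k_error(error_multiplicity_max)
    return estimate_from_totals(k_total, k_error, D, error_multiplicity_max)


def estimate_from_totals(
    K_total: int, K_error: int, D: int, error_multiplicity_max: int = 1
) -> GenomeSizeEstimate:
    """Spectrum formula from pre-tallied totals (e.g. a published count)."""
    if D < 1:
        raise ValidationError(f"peak depth D must be >= 1, got {D}")
    if K_error > K_total:
        raise ValidationError("K_error exceeds K_total")
    G = div_round_half_up(K_total - K_error, D)
    return GenomeSizeEstimate(G, K_total, K_error, D, error_multiplicity_max)


def write_histogram(hist: KmerHistogram, path) -> None:
    with open(path, "w") as fh:
        fh.write("multiplicity\tdistinct_kmers\n")
        for m in sorted(hist.counts):
            fh.write(f"{m}\t{hist.counts[m]}\n")


def read_histogram(path, k: int = 0, canonical: bool = True) -> KmerHistogram:
    counts: dict[int, int] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("multiplicity"):
                continue
            m, c = line.split("\t")
            counts[int(m)] = int(c)
    return KmerHistogram(k, counts, canonical)
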