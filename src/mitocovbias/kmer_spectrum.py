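"""k-mer spectrum error estimation and depth from the spectrum peak.

Counting all length-k substrings of the reads yields a bimodal multiplicity
histogram: genuine k-mers cluster in a peak near the mean k-mer coverage M,
while k-mers containing a sequencing error are essentially unique and pile
up at low multiplicity. The valley between the two modes separates error
k-mer instances from genuine ones; dividing the error fraction by k gives a
per-base error rate, and the peak multiplicity converts to base coverage via
the read-length correction N = M*L/(L-k+1).

Counting is exact and hash-based, sized for desk-scale synthetic read sets
(up to ~1e7 k-mer instances), not genome-scale data.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, TextIO, Union

import numpy as np
from Bio import SeqIO

logger = logging.getLogger("mitocovbias")

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


@dataclass
class KmerSpectrum:
    """Multiplicity histogram of k-mers: multiplicity -> number of distinct
    k-mers seen exactly that many times."""

    k: int
    histogram: dict[int, int]
    canonical: bool

    @property
    def total_kmer_instances(self) -> int:
        return sum(m * c for m, c in self.histogram.items())

    @property
    def n_distinct(self) -> int:
        return sum(self.histogram.values())


@dataclass
class SpectrumEstimates:
    error_threshold: int
    peak_multiplicity: float  # mean k-mer coverage M
    error_kmer_instances: int
    total_kmer_instances: int
    error_fraction: float
    per_base_error: float


def _revcomp(s: str) -> str:
    return s.translate(_COMPLEMENT)[::-1]


def _iter_read_sequences(source) -> Iterable[str]:
    if isinstance(source, (list, tuple)):
        yield from source
        return
    if isinstance(source, (str, Path)):
        path = Path(source)
        fmt = "fastq" if path.suffix.lower() in {".fq", ".fastq"} else "fasta"
        with open(path) as fh:
            for rec in SeqIO.parse(fh, fmt):
                yield str(rec.seq)
        return
    # open handle: sniff first character
    first = source.read(1)
    fmt = "fastq" if first == "@" else "fasta"
    source.seek(source.tell() - 1)
    for rec in SeqIO.parse(source, fmt):
        yield str(rec.seq)


def count_kmers(
    reads: Union[str, Path, TextIO, list],
    k: int,
    canonical: bool = True,
) -> KmerSpectrum:
    """Exact k-mer counting over a FASTQ/FASTA stream (or list of strings).

    k-mers spanning any non-ACGT base are dropped. Canonical mode maps each
    k-mer to the lexicographic minimum of itself and its reverse complement,
    so the spectrum is strand-independent.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    counts: Counter = Counter()
    longest = 0
    for seq in _iter_read_sequences(reads):
        seq = seq.upper()
        longest = max(longest, len(seq))
        for segment in _acgt_segments(seq):
            for i in range(len(segment) - k + 1):
                kmer = segment[i : i + k]
                if canonical:
                    kmer = min(kmer, _revcomp(kmer))
                counts[kmer] += 1
    if longest and k > longest:
        logger.warning("k=%d exceeds the longest read (%d bp); spectrum is empty", k, longest)
    histogram: dict[int, int] = {}
    for mult in counts.values():
        histogram[mult] = histogram.get(mult, 0) + 1
    return KmerSpectrum(k=k, histogram=histogram, canonical=canonical)


def _acgt_segments(seq: str) -> Iterable[str]:
    start = None
    for i, ch in enumerate(seq):
        if ch in "ACGT":
            if start is None:
                start = i
        elif start is not None:
            yield seq[start:i]
            start = None
    if start is not None:
        yield seq[start:]


def find_error_threshold(spectrum: KmerSpectrum, user_cutoff: int | None = None) -> int:
    """Multiplicity cutoff separating error k-mers from genuine ones.

    Auto-detection takes the multiplicity of the first local minimum of the
    log-counts (smoothed with a 3-bin moving median over occupied bins)
    between the low-multiplicity error mode and the main peak. An explicit
    ``user_cutoff`` is returned verbatim. A spectrum with no interior valley
    (e.g. strictly decreasing) raises, prompting a manual cutoff.
    """
    if user_cutoff is not None:
        return int(user_cutoff)
    if not spectrum.histogram:
        raise ValueError("empty spectrum")
    mults = np.array(sorted(spectrum.histogram), dtype=np.int64)
    counts = np.array([spectrum.histogram[m] for m in mults], dtype=float)
    if len(mults) < 3:
        raise ValueError("spectrum too sparse for valley detection; supply a cutoff")
    logc = np.log(counts)
    smooth = np.array(
        [np.median(logc[max(0, i - 1) : i + 2]) for i in range(len(logc))]
    )
    # first interior local minimum with higher smoothed counts on both sides:
    # the descent from the error mode meets the rise into the main peak
    for i in range(1, len(smooth) - 1):
        if (
            smooth[i] <= smooth[i - 1]
            and smooth[i] < smooth[i + 1]
            and smooth[:i].max() > smooth[i]
            and smooth[i + 1 :].max() > smooth[i]
        ):
            return int(mults[i])
    raise ValueError(
        "no valley between an error mode and a main peak; spectrum looks "
        "unimodal — supply an explicit cutoff"
    )


def kmer_error_rate(spectrum: KmerSpectrum, cutoff: int) -> tuple[float, float]:
    """(error_fraction, per_base_error) at a multiplicity cutoff.

    Error fraction is the share of k-mer instances with multiplicity below
    the cutoff; dividing by k converts to per-base error, since one miscalled
    base corrupts the k overlapping k-mers.
    """
    if cutoff < 1:
        raise ValueError("cutoff must be >= 1")
    total = spectrum.total_kmer_instances
    if total == 0:
        raise ValueError("empty spectrum")
    err = sum(m * c for m, c in spectrum.histogram.items() if m < cutoff)
    frac = err / total
    return frac, frac / spectrum.k


def error_rate_from_instance_counts(
    error_instances: float, total_instances: float, k: int
) -> float:
    """Per-base error rate from already-tallied instance counts."""
    if total_instances <= 0:
        raise ValueError("total_instances must be positive")
    return (error_instances / total_instances) / k


def depth_from_peak(peak_multiplicity: float, read_length: float, k: int) -> float:
    """Base coverage N from mean k-mer coverage M: N = M*L/(L-k+1).

    A read of length L contributes L-k+1 k-mers covering each of its bases,
    so k-mer coverage understates base coverage by the factor (L-k+1)/L;
    this inverts it.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if read_length <= k:
        raise ValueError("read length must exceed k")
    if peak_multiplicity <= 0:
        raise ValueError("peak multiplicity must be positive")
    return peak_multiplicity * read_length / (read_length - k + 1)


def find_peak_multiplicity(spectrum: KmerSpectrum, cutoff: int) -> float:
    """Mean k-mer coverage M of the genuine (multiplicity >= cutoff) part
    of the spectrum: the distinct-k-mer-weighted mean multiplicity, which
    estimates the spectrum's main-peak location far more stably than the
    modal histogram bin at desk scale."""
    genuine = {m: c for m, c in spectrum.histogram.items() if m >= cutoff}
    if not genuine:
        raise ValueError("no k-mers at or above the cutoff")
    total_distinct = sum(genuine.values())
    return float(sum(m * c for m, c in genuine.items()) / total_distinct)


def estimate_spectrum(
    spectrum: KmerSpectrum, user_cutoff: int | None = None
) -> SpectrumEstimates:
    """Threshold, peak, and error-rate estimates from one spectrum."""
    cutoff = find_error_threshold(spectrum, user_cutoff)
    frac, per_base = kmer_error_rate(spectrum, cutoff)
    total = spectrum.total_kmer_instances
    return SpectrumEstimates(
        error_threshold=cutoff,
        peak_multiplicity=find_peak_multiplicity(spectrum, cutoff),
        error_kmer_instances=int(round(frac * total)),
        total_kmer_instances=total,
        error_fraction=frac,
        per_base_error=per_base,
    )
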