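"""Genome-size and coverage arithmetic, and k-mer spectrum peak detection.

Two complementary routes to genome size from shotgun reads:

* read arithmetic — coverage = n_reads * read_len / genome_size, and its
  inverse. With ~400 million 150-bp reads, a 500-Mbp genome would sit at
  ~120x; if the observed k-mer peak is instead at coverage <= 2, the genome
  must be at least 400e6 * 150 / 2 = 30,000 Mbp.
* k-mer spectrum — total k-mer mass above the error peak divided by the
  multiplicity of the genome peak. Valid when k << read length, so k-mer
  coverage approximately equals read coverage.
"""

from __future__ import annotations

import warnings

from .types import KmerHistogram

__all__ = ["coverage_from_reads", "size_from_reads", "histogram_peak",
           "size_from_histogram"]


def coverage_from_reads(n_reads: float, read_len: float,
                        genome_size: float) -> float:
    """Fold coverage: n_reads * read_len / genome_size (all inputs > 0)."""
    for name, value in (("n_reads", n_reads), ("read_len", read_len),
                        ("genome_size", genome_size)):
        if value <= 0:
            raise ValueError(f"{name} must be positive, got {value}")
    return n_reads * read_len / genome_size


def size_from_reads(n_reads: float, read_len: float,
                    coverage: float) -> float:
    """Genome size in bp implied by a read count at a given coverage.

    Exact inverse of :func:`coverage_from_reads` in its third argument.
    """
    for name, value in (("n_reads", n_reads), ("read_len", read_len),
                        ("coverage", coverage)):
        if value <= 0:
            raise ValueError(f"{name} must be positive, got {value}")
    return n_reads * read_len / coverage


def histogram_peak(hist: KmerHistogram, error_cutoff: int = 3) -> int:
    """Multiplicity of the genome peak: the largest count above the cutoff.

    Bins at multiplicity <= ``error_cutoff`` are treated as sequencing-error
    k-mers and ignored. Ties are resolved to the lowest multiplicity with a
    warning. Raises if no bin lies above the cutoff (the peak is buried in
    the error region and only a size lower bound can be quoted).
    """
    above = hist.multiplicities > error_cutoff
    if not above.any() or hist.counts[above].max() == 0:
        raise ValueError(
            f"no k-mer counts above multiplicity {error_cutoff}: the genome "
            "peak is below the error cutoff; only a lower bound on genome "
            "size is available")
    mult = hist.multiplicities[above]
    cnt = hist.counts[above]
    top = cnt.max()
    winners = mult[cnt == top]
    if len(winners) > 1:
        warnings.warn(
            f"tied histogram peak at multiplicities {winners.tolist()}; "
            "using the lowest", stacklevel=2)
    return int(winners[0])


def size_from_histogram(hist: KmerHistogram, error_cutoff: int = 3) -> float:
    """Genome size estimate: above-cutoff k-mer mass over the peak coverage.

    Sum of multiplicity x count over bins above ``error_cutoff`` (total
    error-free k-mer occurrences) divided by the genome-peak multiplicity
    (the k-mer coverage).
    """
    peak = histogram_peak(hist, error_cutoff=error_cutoff)
    above = hist.multiplicities > error_cutoff
    mass = float((hist.multiplicities[above] * hist.counts[above]).sum())
    return mass / peak
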