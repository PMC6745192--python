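"""AT-content profiling, codon/amino-acid usage, and the stop-codon model.

The central quantity is the probability that a random codon is a stop under
a base-composition null. For a sequence with AT content alpha in which the
four bases occur independently with p(A) = p(T) = alpha/2 and
p(C) = p(G) = (1 - alpha)/2, the standard three-stop code gives

    P(stop) = P(TAA) + P(TGA) + P(TAG) = alpha^2/4 - alpha^3/8

so at alpha = 0.88 roughly one random codon in nine is a stop — which is
why intact reading frames in such a genome are evidence of ongoing
purifying selection.
"""

from __future__ import annotations

import math
import warnings
from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .types import (ALL_CODONS, AT_BASES, CODING_KINDS, FEATURE_KINDS,
                    UNAMBIGUOUS, BaseComposition, FeatureTable, GeneticCode,
                    SequenceRecord)

__all__ = [
    "at_content", "windowed_at", "weighted_at", "codon_usage", "aa_usage",
    "expected_codon_freq", "expected_aa_freq", "stop_probability",
    "stop_probability_closed_form", "expected_stop_spacing",
    "feature_weighted_at", "FeatureATSummary",
]


def _at_counts(seq: str) -> tuple[int, int]:
    """(A+T count, unambiguous base count) of an already-normalized string."""
    at = sum(seq.count(b) for b in AT_BASES)
    called = sum(seq.count(b) for b in UNAMBIGUOUS)
    return at, called


def at_content(seq: SequenceRecord | str) -> float:
    """Fraction of A+T among unambiguous bases.

    N, gaps and IUPAC ambiguity codes do not enter the denominator, so the
    value is a fraction of called bases.
    """
    s = seq.sequence if isinstance(seq, SequenceRecord) else \
        SequenceRecord("seq", seq).sequence
    at, called = _at_counts(s)
    if called == 0:
        raise ValueError("sequence has no unambiguous bases")
    return at / called


def windowed_at(seq: SequenceRecord, window: int = 200,
                step: int | None = None,
                include_partial: bool = False) -> pd.DataFrame:
    """AT content in fixed windows along a sequence.

    Parameters
    ----------
    window : window width in bp (default 200).
    step : distance between window starts; defaults to ``window``
        (non-overlapping).
    include_partial : also emit the trailing partial window. By default it
        is dropped so every value covers exactly ``window`` bases.

    Returns
    -------
    DataFrame with columns ``start`` (0-based window start) and
    ``at_fraction``. Windows without any unambiguous base get NaN.
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    step = window if step is None else step
    if step < 1:
        raise ValueError("step must be >= 1")
    s = seq.sequence
    if window > len(s):
        warnings.warn(
            f"window ({window} bp) exceeds sequence length ({len(s)} bp); "
            "empty profile", stacklevel=2)
        if not include_partial:
            return pd.DataFrame({"start": pd.Series(dtype=int),
                                 "at_fraction": pd.Series(dtype=float)})
    starts, values = [], []
    pos = 0
    while pos < len(s):
        chunk = s[pos:pos + window]
        if len(chunk) < window and not include_partial:
            break
        at, called = _at_counts(chunk)
        starts.append(pos)
        values.append(at / called if called else math.nan)
        pos += step
    return pd.DataFrame({"start": starts, "at_fraction": values})


def weighted_at(records: Sequence[SequenceRecord]) -> float:
    """Length-weighted average AT content of a set of sequences.

    Identical to the AT content of the concatenation of the records
    (lengths weight by called bases, so ambiguity codes stay excluded).
    """
    if not records:
        raise ValueError("at least one record required")
    at_total = called_total = 0
    for rec in records:
        at, called = _at_counts(rec.sequence)
        at_total += at
        called_total += called
    if called_total == 0:
        raise ValueError("records contain no unambiguous bases")
    return at_total / called_total


def _iter_codons(rec: SequenceRecord) -> Iterable[str]:
    if len(rec) % 3 != 0:
        raise ValueError(
            f"record {rec.id!r} has length {len(rec)}, not divisible by 3")
    s = rec.sequence
    return (s[i:i + 3] for i in range(0, len(s), 3))


def codon_usage(cds: Sequence[SequenceRecord],
                code: GeneticCode) -> pd.DataFrame:
    """Observed codon counts and frequencies over a set of coding sequences.

    Codons containing ambiguous bases are skipped (and tallied in the
    ``n_skipped`` attribute of the result).
    """
    if not cds:
        raise ValueError("at least one coding sequence required")
    counts: Counter[str] = Counter()
    skipped = 0
    for rec in cds:
        for codon in _iter_codons(rec):
            if set(codon) <= UNAMBIGUOUS:
                counts[codon] += 1
            else:
                skipped += 1
    total = sum(counts.values())
    if total == 0:
        raise ValueError("no unambiguous codons in input")
    table = pd.DataFrame({
        "codon": list(ALL_CODONS),
        "amino_acid": [code.codon_to_aa[c] for c in ALL_CODONS],
        "count": [counts.get(c, 0) for c in ALL_CODONS],
    })
    table["frequency"] = table["count"] / total
    table = table.set_index("codon")
    table.attrs["n_codons"] = total
    table.attrs["n_skipped"] = skipped
    return table


def aa_usage(cds: Sequence[SequenceRecord], code: GeneticCode) -> pd.Series:
    """Amino-acid frequencies over coding sequences; stops are excluded.

    Frequencies are over non-stop codons, so they sum to 1 across the
    amino acids the code encodes.
    """
    usage = codon_usage(cds, code)
    non_stop = usage[usage["amino_acid"] != "*"]
    total = non_stop["count"].sum()
    if total == 0:
        raise ValueError("no non-stop codons in input")
    freq = non_stop.groupby("amino_acid")["count"].sum() / total
    return freq.reindex(code.amino_acids(), fill_value=0.0).rename("frequency")


def expected_codon_freq(comp: BaseComposition,
                        code: GeneticCode) -> pd.Series:
    """Null codon distribution: product of per-position base probabilities.

    With a flat composition this is the zeroth-order null; with
    position-specific compositions it mirrors an F3x4-style null.
    ``code`` fixes the codon universe (all 64); it does not alter the
    probabilities.
    """
    base_index = {b: i for i, b in enumerate("ACGT")}
    pos_probs = [comp.position(i).as_array() for i in range(3)]
    probs = {
        codon: float(pos_probs[0][base_index[codon[0]]]
                     * pos_probs[1][base_index[codon[1]]]
                     * pos_probs[2][base_index[codon[2]]])
        for codon in ALL_CODONS
    }
    return pd.Series(probs, name="probability").reindex(list(ALL_CODONS))


def expected_aa_freq(comp: BaseComposition, code: GeneticCode) -> pd.Series:
    """Null amino-acid distribution under the composition model.

    Codon probabilities are aggregated by amino acid and renormalized over
    non-stop codons: observed proteins contain no internal stops, so the
    null conditions on the codon not being a stop.
    """
    codon_freq = expected_codon_freq(comp, code)
    agg: dict[str, float] = {aa: 0.0 for aa in code.amino_acids()}
    for codon, p in codon_freq.items():
        aa = code.codon_to_aa[codon]
        if aa != "*":
            agg[aa] += p
    non_stop_mass = sum(agg.values())
    if non_stop_mass == 0:
        raise ValueError("composition puts all probability on stop codons")
    freq = pd.Series(agg, name="probability") / non_stop_mass
    return freq.reindex(code.amino_acids())


def stop_probability(comp: BaseComposition, code: GeneticCode) -> float:
    """Probability that a random codon under the composition null is a stop."""
    codon_freq = expected_codon_freq(comp, code)
    return float(codon_freq[sorted(code.stop_codons)].sum())


def stop_probability_closed_form(alpha: float) -> float:
    """Closed form alpha^2/4 - alpha^3/8 for the standard three-stop code.

    Valid for a position-independent composition with p(A) = p(T) = alpha/2:
    the TAA, TGA and TAG terms collapse to this cubic. Equal to
    :func:`stop_probability` on ``BaseComposition.from_alpha(alpha)``.
    """
    if not 0.0 <= alpha <= 1.0:
        raise ValueError("alpha must lie in [0, 1]")
    return alpha ** 2 / 4 - alpha ** 3 / 8


def expected_stop_spacing(comp: BaseComposition, code: GeneticCode) -> int:
    """Expected number of codons per stop, floored to an integer.

    At alpha = 0.88 under the standard code this is 9: in a random
    open reading frame of that composition every 9th codon is a stop.
    """
    p = stop_probability(comp, code)
    if p == 0:
        raise ValueError("stop probability is zero; spacing undefined")
    return math.floor(1.0 / p)


@dataclass(frozen=True)
class FeatureATSummary:
    """Per-feature-kind weighted AT content plus the coding fraction."""

    per_kind_at: Mapping[str, float]
    per_kind_bp: Mapping[str, int]
    coding_fraction: float
    genome_length: int

    def to_dict(self) -> dict:
        return {
            "per_kind_at": dict(self.per_kind_at),
            "per_kind_bp": dict(self.per_kind_bp),
            "coding_fraction": self.coding_fraction,
            "genome_length": self.genome_length,
        }


def feature_weighted_at(genome: SequenceRecord,
                        features: FeatureTable) -> FeatureATSummary:
    """Length-weighted AT per feature kind and the genome coding fraction.

    The coding fraction counts protein-coding and ncRNA bases (everything
    that is neither intergenic nor intronic) over the genome length;
    overlapping coding features are merged so shared bases count once.
    """
    features.validate_against(genome)
    per_kind_at: dict[str, float] = {}
    per_kind_bp: dict[str, int] = {}
    for kind in FEATURE_KINDS:
        subset = features.of_kind(kind)
        if not subset:
            continue
        records = [SequenceRecord(f"{f.name or kind}_{i}",
                                  genome.sequence[f.start:f.end])
                   for i, f in enumerate(subset)]
        per_kind_at[kind] = weighted_at(records)
        per_kind_bp[kind] = sum(len(f) for f in subset)
    coding = np.zeros(len(genome), dtype=bool)
    for f in features:
        if f.kind in CODING_KINDS:
            coding[f.start:f.end] = True
    return FeatureATSummary(
        per_kind_at=per_kind_at,
        per_kind_bp=per_kind_bp,
        coding_fraction=float(coding.sum()) / len(genome),
        genome_length=len(genome),
    )
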