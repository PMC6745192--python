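"""Core value types shared across the pipeline.

The types here are deliberately thin: validated containers with a few
constructors, no analysis logic. Sequences are normalized to an uppercase
DNA alphabet (U -> T) on ingest so RNA genes and DNA are handled uniformly.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
from Bio.Data import CodonTable

BASES = ("A", "C", "G", "T")
AT_BASES = frozenset("AT")
UNAMBIGUOUS = frozenset(BASES)
GAP_CHARS = frozenset("-.")
#: IUPAC ambiguity codes (including N); excluded from composition denominators.
AMBIGUOUS = frozenset("RYSWKMBDHVN")
_VALID_SEQ = UNAMBIGUOUS | AMBIGUOUS
_VALID_ALN = _VALID_SEQ | GAP_CHARS


def normalize_sequence(seq: str, *, allow_gaps: bool = False) -> str:
    """Uppercase, map U->T, and validate against the IUPAC DNA alphabet."""
    s = seq.upper().replace("U", "T")
    valid = _VALID_ALN if allow_gaps else _VALID_SEQ
    bad = set(s) - valid
    if bad:
        raise ValueError(f"invalid sequence characters: {sorted(bad)!r}")
    return s


@dataclass(frozen=True)
class SequenceRecord:
    """A named DNA sequence (RNA is converted on construction)."""

    id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("sequence record id must be non-empty")
        if not self.sequence:
            raise ValueError(f"sequence of record {self.id!r} is empty")
        object.__setattr__(self, "sequence", normalize_sequence(self.sequence))

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class BaseComposition:
    """Base probabilities of a sequence model, optionally per codon position.

    ``positions``, when given, holds three position-specific compositions
    (codon positions 1..3); the flat probabilities then act as the average.
    The uniform-AT constructor :meth:`from_alpha` places ``alpha/2`` on each
    of A and T and ``(1-alpha)/2`` on each of C and G.
    """

    p_A: float
    p_C: float
    p_G: float
    p_T: float
    positions: tuple["BaseComposition", ...] | None = None

    def __post_init__(self) -> None:
        vec = self.as_array()
        if np.any(vec < -1e-12) or np.any(vec > 1 + 1e-12):
            raise ValueError("base probabilities must lie in [0, 1]")
        if abs(vec.sum() - 1.0) > 1e-9:
            raise ValueError(f"base probabilities sum to {vec.sum()}, not 1")
        if self.positions is not None:
            if len(self.positions) != 3:
                raise ValueError("positions must hold exactly 3 compositions")
            for comp in self.positions:
                if comp.positions is not None:
                    raise ValueError("per-position compositions cannot nest")

    def as_array(self) -> np.ndarray:
        """Probabilities in A, C, G, T order."""
        return np.array([self.p_A, self.p_C, self.p_G, self.p_T], dtype=float)

    def position(self, i: int) -> "BaseComposition":
        """Composition at codon position ``i`` (0-based); flat if not set."""
        if self.positions is None:
            return self
        return self.positions[i]

    @property
    def at(self) -> float:
        return self.p_A + self.p_T

    @classmethod
    def from_alpha(cls, alpha: float) -> "BaseComposition":
        """Uniform-AT composition with AT content ``alpha``."""
        if not 0.0 <= alpha <= 1.0:
            raise ValueError("alpha must lie in [0, 1]")
        return cls(p_A=alpha / 2, p_C=(1 - alpha) / 2,
                   p_G=(1 - alpha) / 2, p_T=alpha / 2)

    @classmethod
    def from_probs(cls, probs: Sequence[float]) -> "BaseComposition":
        a, c, g, t = (float(x) for x in probs)
        return cls(p_A=a, p_C=c, p_G=g, p_T=t)

    @classmethod
    def from_sequences(cls, records: Iterable[SequenceRecord],
                       by_codon_position: bool = False) -> "BaseComposition":
        """Empirical composition of one or more sequences.

        Ambiguous bases are excluded from the counts. With
        ``by_codon_position`` the records must be in-frame coding sequences.
        """
        records = list(records)
        if not records:
            raise ValueError("at least one record required")
        if not by_codon_position:
            counts = np.zeros(4)
            for rec in records:
                for i, b in enumerate(BASES):
                    counts[i] += rec.sequence.count(b)
            if counts.sum() == 0:
                raise ValueError("no unambiguous bases in input")
            return cls.from_probs(counts / counts.sum())
        pos_counts = np.zeros((3, 4))
        for rec in records:
            if len(rec) % 3 != 0:
                raise ValueError(
                    f"record {rec.id!r} length {len(rec)} not divisible by 3")
            arr = np.frombuffer(rec.sequence.encode(), dtype="S1")
            for p in range(3):
                col = arr[p::3]
                for i, b in enumerate(BASES):
                    pos_counts[p, i] += int((col == b.encode()).sum())
        if np.any(pos_counts.sum(axis=1) == 0):
            raise ValueError("a codon position has no unambiguous bases")
        per_pos = tuple(cls.from_probs(row / row.sum()) for row in pos_counts)
        mean = pos_counts.sum(axis=0) / pos_counts.sum()
        return cls(p_A=mean[0], p_C=mean[1], p_G=mean[2], p_T=mean[3],
                   positions=per_pos)


def _all_codons() -> list[str]:
    return [a + b + c for a in BASES for b in BASES for c in BASES]


ALL_CODONS: tuple[str, ...] = tuple(_all_codons())


@dataclass(frozen=True)
class GeneticCode:
    """Codon-to-amino-acid map with an explicit stop-codon set.

    Follows the NCBI translation-table convention. The default used across
    this package is table 11 (bacterial/plastid), whose stop set equals the
    standard {TAA, TAG, TGA}. Non-canonical codes (e.g. plastomes that
    read TAG as tryptophan) are expressed via :meth:`with_overrides`.
    """

    table_id: int
    codon_to_aa: Mapping[str, str]
    stop_codons: frozenset[str]

    def __post_init__(self) -> None:
        if set(self.codon_to_aa) != set(ALL_CODONS):
            raise ValueError("codon table must map exactly the 64 DNA codons")
        if not self.stop_codons:
            raise ValueError("stop-codon set must be non-empty")
        if not self.stop_codons <= set(ALL_CODONS):
            raise ValueError("stop codons must be valid codons")

    @classmethod
    def from_ncbi(cls, table_id: int = 11) -> "GeneticCode":
        table = CodonTable.unambiguous_dna_by_id[table_id]
        mapping = dict(table.forward_table)
        for stop in table.stop_codons:
            mapping[stop] = "*"
        return cls(table_id=table_id, codon_to_aa=mapping,
                   stop_codons=frozenset(table.stop_codons))

    def with_overrides(self, overrides: Mapping[str, str]) -> "GeneticCode":
        """A modified code; mapping a codon to ``*`` marks it as a stop."""
        mapping = dict(self.codon_to_aa)
        for codon, aa in overrides.items():
            codon = normalize_sequence(codon)
            if len(codon) != 3:
                raise ValueError(f"{codon!r} is not a codon")
            mapping[codon] = aa
        stops = frozenset(c for c, aa in mapping.items() if aa == "*")
        return GeneticCode(table_id=self.table_id, codon_to_aa=mapping,
                           stop_codons=stops)

    def amino_acids(self) -> tuple[str, ...]:
        return tuple(sorted({aa for aa in self.codon_to_aa.values()
                             if aa != "*"}))


FEATURE_KINDS = ("protein_coding", "ncRNA", "intron", "intergenic")
#: Kinds counted as coding in the coding-fraction summary
#: (everything that is neither intergenic nor intronic).
CODING_KINDS = frozenset({"protein_coding", "ncRNA"})


@dataclass(frozen=True)
class Feature:
    """A genome interval in 0-based half-open coordinates."""

    seq_id: str
    start: int
    end: int
    strand: str
    kind: str
    name: str

    def __post_init__(self) -> None:
        if not 0 <= self.start < self.end:
            raise ValueError(
                f"feature {self.name!r}: require 0 <= start < end, "
                f"got [{self.start}, {self.end})")
        if self.strand not in {"+", "-", "."}:
            raise ValueError(f"invalid strand {self.strand!r}")
        if self.kind not in FEATURE_KINDS:
            raise ValueError(
                f"feature {self.name!r}: unknown kind {self.kind!r}; "
                f"expected one of {FEATURE_KINDS}")

    def __len__(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class FeatureTable:
    features: tuple[Feature, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "features", tuple(self.features))

    def validate_against(self, genome: SequenceRecord) -> None:
        for f in self.features:
            if f.seq_id != genome.id:
                raise ValueError(
                    f"feature {f.name!r} references {f.seq_id!r}, "
                    f"not {genome.id!r}")
            if f.end > len(genome):
                raise ValueError(
                    f"feature {f.name!r} ends at {f.end}, beyond sequence "
                    f"length {len(genome)}")

    def of_kind(self, kind: str) -> tuple[Feature, ...]:
        return tuple(f for f in self.features if f.kind == kind)

    def __iter__(self):
        return iter(self.features)

    def __len__(self) -> int:
        return len(self.features)


class MultipleAlignment:
    """An equal-length set of aligned sequences keyed by taxon.

    Rows may contain gaps, N and IUPAC ambiguity codes in addition to
    A/C/G/T. Column operations are vectorized over a (taxa x columns)
    byte matrix.
    """

    def __init__(self, taxa: Sequence[str], rows: Sequence[str]) -> None:
        taxa = list(taxa)
        rows = [normalize_sequence(r, allow_gaps=True) for r in rows]
        if len(taxa) != len(rows):
            raise ValueError("taxa and rows must have equal length")
        if not taxa:
            raise ValueError("alignment must contain at least one taxon")
        if len(set(taxa)) != len(taxa):
            raise ValueError("taxon names must be unique")
        lengths = {len(r) for r in rows}
        if len(lengths) != 1:
            raise ValueError(f"rows have unequal lengths: {sorted(lengths)}")
        self.taxa: tuple[str, ...] = tuple(taxa)
        self._rows: tuple[str, ...] = tuple(rows)
        self._matrix = np.frombuffer(
            "".join(rows).encode(), dtype="S1").reshape(len(taxa), -1)

    @property
    def n_taxa(self) -> int:
        return len(self.taxa)

    @property
    def n_columns(self) -> int:
        return self._matrix.shape[1]

    @property
    def matrix(self) -> np.ndarray:
        """Read-only (taxa x columns) matrix of single-byte characters."""
        return self._matrix

    def row(self, taxon: str) -> str:
        return self._rows[self.index(taxon)]

    def index(self, taxon: str) -> int:
        try:
            return self.taxa.index(taxon)
        except ValueError:
            raise KeyError(f"taxon {taxon!r} not in alignment") from None

    def items(self):
        return zip(self.taxa, self._rows)

    def select_columns(self, mask: np.ndarray) -> "MultipleAlignment":
        """Order-preserving column subset; ``mask`` is boolean or indices."""
        sub = self._matrix[:, mask]
        rows = [sub[i].tobytes().decode() for i in range(sub.shape[0])]
        return MultipleAlignment(self.taxa, rows)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, MultipleAlignment):
            return NotImplemented
        return self.taxa == other.taxa and self._rows == other._rows

    def __repr__(self) -> str:
        return (f"MultipleAlignment({self.n_taxa} taxa x "
                f"{self.n_columns} columns)")


@dataclass(frozen=True)
class TaxonGroups:
    """Taxon -> group label map used by placement reports."""

    mapping: Mapping[str, str]

    def __getitem__(self, taxon: str) -> str:
        try:
            return self.mapping[taxon]
        except KeyError:
            raise KeyError(f"taxon {taxon!r} has no group label") from None

    def labels(self) -> tuple[str, ...]:
        return tuple(sorted(set(self.mapping.values())))

    def check_covers(self, taxa: Iterable[str]) -> None:
        missing = [t for t in taxa if t not in self.mapping]
        if missing:
            raise ValueError(f"taxa without group labels: {missing}")


@dataclass(frozen=True)
class DepthTrack:
    """Per-position sequencing depth over one reference sequence.

    Positions are 1-based in the on-disk TSV and 0-based internally.
    """

    reference: str
    depths: np.ndarray

    def __post_init__(self) -> None:
        arr = np.asarray(self.depths)
        if arr.ndim != 1:
            raise ValueError("depths must be one-dimensional")
        if not np.issubdtype(arr.dtype, np.integer):
            if not np.all(np.equal(np.mod(arr, 1), 0)):
                raise ValueError("depths must be integers")
            arr = arr.astype(np.int64)
        if np.any(arr < 0):
            raise ValueError("depths must be non-negative")
        object.__setattr__(self, "depths", arr.astype(np.int64))

    def __len__(self) -> int:
        return len(self.depths)


@dataclass(frozen=True)
class InsertTrack:
    """Read-pair insert sizes located by pair midpoint on the reference."""

    reference: str
    midpoints: np.ndarray
    sizes: np.ndarray

    def __post_init__(self) -> None:
        mid = np.asarray(self.midpoints, dtype=float)
        sz = np.asarray(self.sizes, dtype=float)
        if mid.shape != sz.shape or mid.ndim != 1:
            raise ValueError("midpoints and sizes must be equal-length 1-D")
        if np.any(sz <= 0):
            raise ValueError("insert sizes must be positive")
        object.__setattr__(self, "midpoints", mid)
        object.__setattr__(self, "sizes", sz)

    def __len__(self) -> int:
        return len(self.sizes)


@dataclass(frozen=True)
class KmerHistogram:
    """A k-mer spectrum: count of distinct k-mers per coverage multiplicity."""

    multiplicities: np.ndarray
    counts: np.ndarray
    k: int = 21

    def __post_init__(self) -> None:
        mult = np.asarray(self.multiplicities, dtype=np.int64)
        cnt = np.asarray(self.counts, dtype=np.int64)
        if mult.shape != cnt.shape or mult.ndim != 1 or len(mult) == 0:
            raise ValueError("histogram must be two equal non-empty columns")
        if np.any(mult < 1):
            raise ValueError("multiplicities must be >= 1")
        if np.any(np.diff(mult) <= 0):
            raise ValueError("multiplicities must be strictly increasing")
        if np.any(cnt < 0):
            raise ValueError("counts must be non-negative")
        if self.k < 1:
            raise ValueError("k must be positive")
        object.__setattr__(self, "multiplicities", mult)
        object.__setattr__(self, "counts", cnt)

    def total_kmers(self) -> int:
        """Total k-mer occurrences: sum of multiplicity x count."""
        return int((self.multiplicities * self.counts).sum())
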