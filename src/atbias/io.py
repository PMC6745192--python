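"""Readers and writers for the flat-text formats the pipeline exchanges.

FASTA goes through Biopython; trees through dendropy (newick, bootstrap
supports as internal-node labels). Tabular tracks are plain TSV:

* depth — ``reference  position(1-based)  depth`` (samtools-depth style)
* inserts — ``reference  midpoint  size``
* k-mer histogram — ``multiplicity  count`` per line (jellyfish histo)
* taxon groups — ``taxon<TAB>group``
* features — BED (0-based half-open) or a minimal GFF3 subset
  (1-based closed, converted on read)
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable

import dendropy
import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as BioSeqRecord

from .types import (DepthTrack, Feature, FeatureTable, InsertTrack,
                    KmerHistogram, MultipleAlignment, SequenceRecord,
                    TaxonGroups)

__all__ = [
    "read_fasta", "write_fasta", "read_alignment", "write_alignment",
    "read_groups", "read_depth_tsv", "write_depth_tsv", "read_insert_tsv",
    "write_insert_tsv", "read_kmer_histogram", "write_kmer_histogram",
    "read_bed", "read_gff3", "write_newick", "read_newick", "write_json",
]

_KIND_ALIASES = {
    "cds": "protein_coding", "gene": "protein_coding",
    "protein_coding": "protein_coding", "mrna": "protein_coding",
    "ncrna": "ncRNA", "rrna": "ncRNA", "trna": "ncRNA",
    "intron": "intron", "intergenic": "intergenic",
    "intergenic_region": "intergenic",
}


def _kind(raw: str) -> str:
    try:
        return _KIND_ALIASES[raw.lower()]
    except KeyError:
        raise ValueError(
            f"unknown feature kind {raw!r}; expected one of "
            f"{sorted(set(_KIND_ALIASES))}") from None


def read_fasta(path: str | Path) -> list[SequenceRecord]:
    records = [SequenceRecord(rec.id, str(rec.seq))
               for rec in SeqIO.parse(str(path), "fasta")]
    if not records:
        raise ValueError(f"no FASTA records in {path}")
    return records


def write_fasta(records: Iterable[SequenceRecord],
                path: str | Path) -> None:
    """Multi-record FASTA, wrapped at 60 columns."""
    bio = [BioSeqRecord(Seq(rec.sequence), id=rec.id, description="")
           for rec in records]
    SeqIO.write(bio, str(path), "fasta")


def read_alignment(path: str | Path) -> MultipleAlignment:
    """Aligned FASTA -> MultipleAlignment (gaps allowed)."""
    taxa, rows = [], []
    for rec in SeqIO.parse(str(path), "fasta"):
        taxa.append(rec.id)
        rows.append(str(rec.seq))
    if not taxa:
        raise ValueError(f"no FASTA records in {path}")
    return MultipleAlignment(taxa, rows)


def write_alignment(aln: MultipleAlignment, path: str | Path) -> None:
    bio = [BioSeqRecord(Seq(row), id=taxon, description="")
           for taxon, row in aln.items()]
    SeqIO.write(bio, str(path), "fasta")


def read_groups(path: str | Path) -> TaxonGroups:
    """Two-column TSV: taxon<TAB>group label."""
    frame = pd.read_csv(path, sep="\t", header=None, comment="#",
                        names=["taxon", "group"], dtype=str)
    if frame["taxon"].duplicated().any():
        dup = frame.loc[frame["taxon"].duplicated(), "taxon"].tolist()
        raise ValueError(f"duplicate taxa in group table: {dup}")
    return TaxonGroups(dict(zip(frame["taxon"], frame["group"])))


def read_depth_tsv(path: str | Path,
                   reference: str | None = None,
                   length: int | None = None) -> DepthTrack:
    """samtools-depth style TSV: reference, 1-based position, depth.

    Positions missing from the file get depth 0. ``length`` extends the
    track beyond the last reported position when given.
    """
    frame = pd.read_csv(path, sep="\t", header=None, comment="#",
                        names=["reference", "position", "depth"])
    if reference is not None:
        frame = frame[frame["reference"] == reference]
    refs = frame["reference"].unique()
    if len(refs) != 1:
        raise ValueError(
            f"depth file covers references {refs.tolist()}; pass "
            "`reference=` to select one")
    if (frame["position"] < 1).any():
        raise ValueError("depth positions must be 1-based (>= 1)")
    n = int(length if length is not None else frame["position"].max())
    depths = np.zeros(n, dtype=np.int64)
    depths[frame["position"].to_numpy() - 1] = frame["depth"].to_numpy()
    return DepthTrack(reference=str(refs[0]), depths=depths)


def write_depth_tsv(track: DepthTrack, path: str | Path) -> None:
    frame = pd.DataFrame({
        "reference": track.reference,
        "position": np.arange(1, len(track) + 1),
        "depth": track.depths,
    })
    frame.to_csv(path, sep="\t", header=False, index=False)


def read_insert_tsv(path: str | Path) -> InsertTrack:
    """TSV: reference, pair midpoint (bp), insert size (bp)."""
    frame = pd.read_csv(path, sep="\t", header=None, comment="#",
                        names=["reference", "midpoint", "size"])
    refs = frame["reference"].unique()
    if len(refs) != 1:
        raise ValueError(f"insert file covers references {refs.tolist()}")
    return InsertTrack(reference=str(refs[0]),
                       midpoints=frame["midpoint"].to_numpy(float),
                       sizes=frame["size"].to_numpy(float))


def write_insert_tsv(track: InsertTrack, path: str | Path) -> None:
    frame = pd.DataFrame({
        "reference": track.reference,
        "midpoint": track.midpoints,
        "size": track.sizes,
    })
    frame.to_csv(path, sep="\t", header=False, index=False)


def read_kmer_histogram(path: str | Path, k: int = 21) -> KmerHistogram:
    """jellyfish `histo` text: two whitespace-separated integers per line."""
    frame = pd.read_csv(path, sep=r"\s+", header=None, comment="#",
                        names=["multiplicity", "count"])
    return KmerHistogram(multiplicities=frame["multiplicity"].to_numpy(),
                         counts=frame["count"].to_numpy(), k=k)


def write_kmer_histogram(hist: KmerHistogram, path: str | Path) -> None:
    frame = pd.DataFrame({"multiplicity": hist.multiplicities,
                          "count": hist.counts})
    frame.to_csv(path, sep=" ", header=False, index=False)


def read_bed(path: str | Path) -> FeatureTable:
    """BED with >= 4 columns: chrom, start, end, name[, score, strand].

    The feature kind is taken from the name's prefix before the first
    ``:`` (e.g. ``CDS:rps14``); a bare name defaults to protein_coding.
    """
    features = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 4:
                raise ValueError(f"BED line has fewer than 4 columns: {line!r}")
            chrom, start, end, name = parts[:4]
            strand = parts[5] if len(parts) > 5 else "."
            kind, _, label = name.partition(":")
            if not label:
                kind, label = "protein_coding", name
            else:
                kind = _kind(kind)
            features.append(Feature(seq_id=chrom, start=int(start),
                                    end=int(end), strand=strand,
                                    kind=kind, name=label))
    return FeatureTable(tuple(features))


def read_gff3(path: str | Path) -> FeatureTable:
    """Minimal GFF3 subset: seqid, source, type, start, end, ., strand.

    Coordinates are converted from 1-based closed to 0-based half-open.
    Types map onto the four feature kinds (CDS/gene -> protein_coding,
    rRNA/tRNA/ncRNA -> ncRNA, intron, intergenic_region -> intergenic).
    """
    features = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 8:
                raise ValueError(f"GFF3 line has fewer than 8 columns: {line!r}")
            seqid, _source, ftype, start, end, _score, strand = parts[:7]
            attrs = parts[8] if len(parts) > 8 else ""
            name = ftype
            for field in attrs.split(";"):
                key, _, value = field.partition("=")
                if key in ("Name", "ID") and value:
                    name = value
                    if key == "Name":
                        break
            features.append(Feature(seq_id=seqid, start=int(start) - 1,
                                    end=int(end), strand=strand or ".",
                                    kind=_kind(ftype), name=name))
    return FeatureTable(tuple(features))


def write_newick(tree: dendropy.Tree, path: str | Path) -> None:
    """Newick with bootstrap supports as internal-node labels."""
    tree.write(path=str(path), schema="newick",
               suppress_rooting=True, unquoted_underscores=True)


def read_newick(path: str | Path) -> dendropy.Tree:
    return dendropy.Tree.get(path=str(path), schema="newick",
                             preserve_underscores=True)


def write_json(payload: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True)
                          + "\n")
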