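"""Reading and writing the pipeline's standard formats.

Coordinate convention: everything in memory is 0-based, half-open.  GenBank
I/O converts to/from the 1-based inclusive convention of the flat-file format.
Ambiguity codes other than N are mapped to N with a warning.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import dendropy
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqFeature import CompoundLocation, SeqFeature, SimpleLocation
from Bio.SeqRecord import SeqRecord

log = logging.getLogger(__name__)

FEATURE_KINDS = ("CDS", "tRNA", "rRNA", "intron", "spacer", "pseudogene", "other")


class GenBankParseError(ValueError):
    pass


class CoordinateError(ValueError):
    pass


@dataclass
class Feature:
    """A typed, stranded, possibly multi-interval gene feature.

    ``intervals`` are 0-based half-open and pairwise non-overlapping; a
    multi-interval feature models an intron-containing gene (introns are the
    gaps between consecutive intervals).
    """

    gene_name: str
    kind: str
    strand: str
    intervals: list[tuple[int, int]]
    qualifiers: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.kind not in FEATURE_KINDS:
            raise ValueError(f"unknown feature kind {self.kind!r}")
        if self.strand not in "+-":
            raise ValueError(f"strand must be + or -, got {self.strand!r}")
        if not self.intervals:
            raise ValueError("feature needs at least one interval")
        ivs = sorted(self.intervals)
        for s, e in ivs:
            if not s < e:
                raise ValueError(f"empty interval ({s},{e}) in {self.gene_name}")
        for (_s1, e1), (s2, _e2) in zip(ivs, ivs[1:]):
            if s2 < e1:
                raise ValueError(f"overlapping intervals in {self.gene_name}")
        self.intervals = ivs

    @property
    def start(self) -> int:
        return self.intervals[0][0]

    @property
    def end(self) -> int:
        return self.intervals[-1][1]

    @property
    def span(self) -> tuple[int, int]:
        return (self.start, self.end)

    @property
    def length(self) -> int:
        return sum(e - s for s, e in self.intervals)

    @property
    def n_introns(self) -> int:
        return len(self.intervals) - 1


@dataclass
class AnnotatedGenome:
    """A circular plastid genome: sequence over {A,C,G,T,N} plus gene features."""

    id: str
    sequence: str
    features: list[Feature] = field(default_factory=list)
    organism: str = ""
    species_label: str = ""
    is_circular: bool = True

    def __post_init__(self) -> None:
        if len(self.sequence) == 0:
            raise ValueError("empty genome sequence")
        seq = self.sequence.upper()
        if set(seq) - set("ACGTN"):
            bad = sorted(set(seq) - set("ACGTN"))
            warnings.warn(f"ambiguity codes {bad} mapped to N in {self.id}")
            seq = "".join(c if c in "ACGTN" else "N" for c in seq)
        self.sequence = seq
        n = len(seq)
        for f in self.features:
            if f.end > n or f.start < 0:
                if not self.is_circular:
                    raise CoordinateError(
                        f"feature {f.gene_name} [{f.start},{f.end}) outside "
                        f"non-circular genome of length {n}"
                    )
                f.intervals = [(s % n, ((e - 1) % n) + 1) for s, e in f.intervals]

    def __len__(self) -> int:
        return len(self.sequence)

    def features_of_kind(self, *kinds: str) -> list[Feature]:
        return [f for f in self.features if f.kind in kinds]


# ---------------------------------------------------------------------------
# GenBank

_GB_KINDS = {"CDS": "CDS", "tRNA": "tRNA", "rRNA": "rRNA"}


def _location_to_intervals(loc) -> list[tuple[int, int]]:
    return [(int(p.start), int(p.end)) for p in loc.parts]


def read_genbank(path: str | Path) -> AnnotatedGenome:
    """Read one GenBank flat-file record into an :class:`AnnotatedGenome`.

    ``join(...)`` locations become multi-interval features; coordinates are
    converted to 0-based half-open.  Feature types other than
    gene/CDS/tRNA/rRNA are kept with kind ``other`` and their original type
    recorded in the qualifiers.
    """
    path = Path(path)
    try:
        record = SeqIO.read(str(path), "genbank")
    except ValueError as exc:
        raise GenBankParseError(f"{path}: {exc}") from exc
    if len(record.seq) == 0:
        raise GenBankParseError(f"{path}: record has no ORIGIN sequence")

    topology = (record.annotations.get("topology") or "").lower()
    circular = topology != "linear"
    n = len(record.seq)

    features: list[Feature] = []
    for bf in record.features:
        if bf.type in ("source", "gene", "misc_feature"):
            if bf.type != "gene":
                continue
            # gene features are redundant with CDS/tRNA/rRNA in our own output;
            # keep them only when no typed sibling exists (checked below by name)
            continue
        name = (
            bf.qualifiers.get("gene", [None])[0]
            or bf.qualifiers.get("locus_tag", ["?"])[0]
        )
        kind = _GB_KINDS.get(bf.type)
        quals = {k: v[0] for k, v in bf.qualifiers.items() if v}
        if kind is None:
            if bf.type == "pseudogene" or "pseudo" in bf.qualifiers:
                kind = "pseudogene"
            else:
                kind = "other"
                quals["original_type"] = bf.type
        elif "pseudo" in bf.qualifiers:
            kind = "pseudogene"
        ivs = _location_to_intervals(bf.location)
        for s, e in ivs:
            if e > n and not circular:
                raise CoordinateError(
                    f"{path}: feature {name} end {e} beyond sequence length {n}"
                )
        strand = "-" if bf.location.strand == -1 else "+"
        features.append(Feature(name, kind, strand, ivs, quals))

    organism = record.annotations.get("organism", "")
    return AnnotatedGenome(
        id=record.id or record.name,
        sequence=str(record.seq),
        features=features,
        organism=organism,
        species_label=record.annotations.get("comment", "") or organism,
        is_circular=circular,
    )


def write_genbank(genome: AnnotatedGenome, path: str | Path) -> None:
    """Emit a GenBank flat file that :func:`read_genbank` reads back losslessly."""
    record = SeqRecord(
        Seq(genome.sequence),
        id=genome.id,
        name=genome.id[:16].replace(" ", "_"),
        description=genome.organism or genome.id,
        annotations={
            "molecule_type": "DNA",
            "topology": "circular" if genome.is_circular else "linear",
            "organism": genome.organism,
            "comment": genome.species_label,
        },
    )
    for f in genome.features:
        strand = -1 if f.strand == "-" else 1
        parts = [SimpleLocation(s, e, strand) for s, e in f.intervals]
        loc = parts[0] if len(parts) == 1 else CompoundLocation(parts)
        gb_type = f.kind if f.kind in _GB_KINDS else f.qualifiers.get("original_type", "misc_feature")
        quals = {"gene": [f.gene_name]}
        for k, v in f.qualifiers.items():
            if k not in ("gene", "original_type"):
                quals[k] = [v]
        if f.kind == "pseudogene":
            gb_type = "CDS"
            quals["pseudo"] = [""]
        record.features.append(SeqFeature(loc, type=gb_type, qualifiers=quals))
    with open(path, "w") as fh:
        SeqIO.write([record], fh, "genbank")


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    """Read FASTA into (first-token id, uppercase sequence) pairs."""
    out: list[tuple[str, str]] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"duplicate FASTA id {rec.id!r} in {path}")
        seen.add(rec.id)
        out.append((rec.id, str(rec.seq).upper()))
    return out


def write_fasta(records: Iterable[tuple[str, str]], path: str | Path, width: int = 70) -> None:
    seen: set[str] = set()
    with open(path, "w") as fh:
        for rid, seq in records:
            if rid in seen:
                raise ValueError(f"duplicate FASTA id {rid!r}")
            seen.add(rid)
            fh.write(f">{rid}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# Newick


def tree_to_newick(tree: "dendropy.Tree") -> str:
    """Serialize with internal-node support labels, no branch-length noise."""
    return tree.as_string(
        schema="newick",
        suppress_rooting=True,
        unquoted_underscores=True,
    ).strip()


def write_newick(tree: "dendropy.Tree", path: str | Path) -> None:
    for leaf in tree.leaf_node_iter():
        if leaf.taxon is None or not leaf.taxon.label:
            raise ValueError("unlabeled leaf in tree")
    with open(path, "w") as fh:
        fh.write(tree_to_newick(tree) + "\n")


def read_newick(path_or_text: str | Path) -> "dendropy.Tree":
    text = str(path_or_text)
    if "(" in text:
        return dendropy.Tree.get(data=text, schema="newick", preserve_underscores=True)
    return dendropy.Tree.get(
        path=str(path_or_text), schema="newick", preserve_underscores=True
    )


# ---------------------------------------------------------------------------
# TSV reports


def write_tsv_report(
    records: Sequence[Mapping[str, object]],
    path: str | Path,
    columns: Sequence[str] | None = None,
    sort_by: str | None = None,
    reverse: bool = False,
    header_comment: str | None = None,
) -> None:
    """Write tabular records as TSV: header row, deterministic row order.

    Raises on ragged records (keys differing from the header).
    """
    records = list(records)
    if columns is None:
        if not records:
            raise ValueError("need explicit columns for an empty record list")
        columns = list(records[0].keys())
    for r in records:
        if set(r.keys()) != set(columns):
            raise ValueError(f"ragged record keys {sorted(r)} vs header {sorted(columns)}")
    if sort_by is not None:
        records.sort(key=lambda r: r[sort_by], reverse=reverse)  # type: ignore[arg-type]
    with open(path, "w", encoding="utf-8") as fh:
        if header_comment:
            for line in header_comment.splitlines():
                fh.write(f"# {line}\n")
        fh.write("\t".join(columns) + "\n")
        for r in records:
            fh.write("\t".join(str(r[c]) for c in columns) + "\n")


def read_tsv_report(path: str | Path) -> list[dict[str, str]]:
    with open(path, encoding="utf-8") as fh:
        lines = [ln.rstrip("\n") for ln in fh if not ln.startswith("#")]
    header = lines[0].split("\t")
    return [dict(zip(header, ln.split("\t"), strict=True)) for ln in lines[1:] if ln]
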