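"""Annotated plastome parsing and adjacent gene-pair enumeration.

Plastomes are small (100--200 kb), gene-dense, usually circular genomes.
The operon-prediction pipeline views such a genome as an ordered list of
genes and works on *adjacent gene pairs*: on a circular genome with n genes
there are n pairs (including the pair that wraps the origin), on a linear
genome n - 1.

Coordinates are 0-based half-open internally; GenBank's 1-based inclusive
convention is converted on read and write.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqFeature import (
    CompoundLocation,
    SeqFeature,
    SimpleLocation,
)
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger("plastoperon")

GENE_TYPES = ("CDS", "tRNA", "rRNA", "other")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


class PlastomeError(ValueError):
    """Raised for unparseable or empty annotations."""


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def normalize_sequence(seq: str) -> str:
    """Uppercase, U->T; anything outside {A,C,G,T} becomes N."""
    seq = seq.upper().replace("U", "T")
    return "".join(c if c in "ACGT" else "N" for c in seq)


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GeneModel:
    """One annotated gene.

    ``start``/``end`` give the outermost genomic span (0-based half-open);
    ``exon_spans`` lists the individual exon intervals for spliced genes
    (``None`` for single-exon genes).  ``canonical`` is False for CDS
    features whose spliced length is not a multiple of three; such genes
    are kept but excluded from codon-based features.
    """

    gene_id: str
    gene_type: str
    strand: str
    start: int
    end: int
    genome_id: str = ""
    product: str | None = None
    exon_spans: tuple[tuple[int, int], ...] | None = None
    wraps_origin: bool = False
    canonical: bool = True

    def __post_init__(self) -> None:
        if self.gene_type not in GENE_TYPES:
            raise ValueError(f"unknown gene_type {self.gene_type!r}")
        if self.strand not in "+-":
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if not self.wraps_origin and self.end <= self.start:
            raise ValueError(f"{self.gene_id}: end must exceed start")

    @property
    def length(self) -> int:
        if self.exon_spans is not None:
            return sum(e - s for s, e in self.exon_spans)
        return self.end - self.start

    def sequence(self, genome_sequence: str) -> str:
        """Strand-corrected (spliced) nucleotide sequence of the gene."""
        spans = self.exon_spans or ((self.start, self.end),)
        n = len(genome_sequence)
        parts = []
        for s, e in spans:
            if e <= n and s >= 0:
                parts.append(genome_sequence[s:e])
            else:  # wrap-around span on a circular genome
                parts.append(genome_sequence[s % n :] + genome_sequence[: e % n])
        seq = "".join(parts)
        return reverse_complement(seq) if self.strand == "-" else seq

    def start_codon_position(self) -> int:
        """Genomic coordinate of the first transcribed base (5' end)."""
        return self.start if self.strand == "+" else self.end


@dataclass
class PlastomeAnnotation:
    """A parsed plastome: sequence plus genes sorted by start coordinate."""

    genome_id: str
    sequence: str
    circular: bool = True
    genes: list[GeneModel] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.sequence = normalize_sequence(self.sequence)
        self.genes = sorted(self.genes, key=lambda g: (g.start, g.end))
        seen: set[str] = set()
        for g in self.genes:
            if g.gene_id in seen:
                raise PlastomeError(f"duplicate gene_id {g.gene_id!r}")
            seen.add(g.gene_id)

    @property
    def length(self) -> int:
        return len(self.sequence)

    def gene(self, gene_id: str) -> GeneModel:
        for g in self.genes:
            if g.gene_id == gene_id:
                return g
        raise KeyError(gene_id)


@dataclass(frozen=True)
class GenePair:
    """An ordered pair of genomically adjacent genes and their spacer.

    The intergenic spacer (IGS) is the half-open interval between
    ``gene5.end`` and ``gene3.start``.  Overlapping genes give a negative
    IGS length and an empty spacer sequence.  ``pair_group`` is "CDS" iff
    both members are CDS, else "mixed".
    """

    gene5: GeneModel
    gene3: GeneModel
    igs_start: int
    igs_end: int
    same_strand: bool
    pair_group: str
    wraps_origin: bool = False
    genome_length: int = 0

    @property
    def pair_id(self) -> str:
        return f"{self.gene5.gene_id}|{self.gene3.gene_id}"

    @property
    def igs_length(self) -> int:
        if self.wraps_origin:
            return (self.gene3.start + self.genome_length) - self.gene5.end
        return self.gene3.start - self.gene5.end

    def igs_sequence(self, annotation: PlastomeAnnotation) -> str:
        if self.igs_length <= 0:
            return ""
        n = annotation.length
        if self.igs_end <= n and not self.wraps_origin:
            return annotation.sequence[self.igs_start : self.igs_end]
        return (
            annotation.sequence[self.igs_start :]
            + annotation.sequence[: self.igs_end % n]
        )


# ---------------------------------------------------------------------------
# Parsing
# ---------------------------------------------------------------------------

_FEATURE_KEYS = {"CDS": "CDS", "tRNA": "tRNA", "rRNA": "rRNA"}


def _feature_gene_id(feature: SeqFeature, index: int) -> str:
    for key in ("gene", "locus_tag", "label"):
        if key in feature.qualifiers:
            return str(feature.qualifiers[key][0])
    return f"feature_{index}"


def _gene_from_feature(
    feature: SeqFeature, genome_id: str, genome_length: int, index: int
) -> GeneModel | None:
    if feature.location is None:
        logger.warning("%s: feature without coordinates skipped", genome_id)
        return None
    if "pseudo" in feature.qualifiers or "pseudogene" in feature.qualifiers:
        logger.warning("%s: pseudogene %s skipped", genome_id, _feature_gene_id(feature, index))
        return None
    gene_type = _FEATURE_KEYS.get(feature.type, "other")
    strand = "-" if feature.location.strand == -1 else "+"
    parts = sorted(
        ((int(p.start), int(p.end)) for p in feature.location.parts),
        key=lambda se: se[0],
    )
    start = parts[0][0]
    end = parts[-1][1]
    exon_spans = tuple(parts) if len(parts) > 1 else None
    wraps = end > genome_length
    spliced_len = sum(e - s for s, e in parts)
    canonical = gene_type != "CDS" or spliced_len % 3 == 0
    if not canonical:
        logger.warning(
            "%s: CDS %s has length %d not divisible by 3; flagged non-canonical",
            genome_id,
            _feature_gene_id(feature, index),
            spliced_len,
        )
    product = feature.qualifiers.get("product", [None])[0]
    return GeneModel(
        gene_id=_feature_gene_id(feature, index),
        gene_type=gene_type,
        strand=strand,
        start=start,
        end=end,
        genome_id=genome_id,
        product=product,
        exon_spans=exon_spans,
        wraps_origin=wraps,
        canonical=canonical,
    )


def _disambiguate(genes: list[GeneModel]) -> list[GeneModel]:
    """Duplicate gene names (e.g. inverted-repeat copies) get a coordinate suffix."""
    counts: dict[str, int] = {}
    for g in genes:
        counts[g.gene_id] = counts.get(g.gene_id, 0) + 1
    out = []
    for g in genes:
        if counts[g.gene_id] > 1:
            out.append(replace(g, gene_id=f"{g.gene_id}_{g.start}"))
        else:
            out.append(g)
    return out


def parse_plastome(
    path: str | Path,
    format: str = "genbank",
    fasta: str | Path | None = None,
) -> PlastomeAnnotation:
    """Parse an annotated plastome from GenBank or GFF3 + FASTA.

    Gene-bearing feature keys (CDS, tRNA, rRNA; anything else becomes
    "other" except the redundant ``gene``/``source``/``exon`` keys) are
    turned into :class:`GeneModel` records.  Pseudogenes and features
    without coordinates are skipped with a logged warning.
    """
    path = Path(path)
    if format == "genbank":
        try:
            record = next(SeqIO.parse(str(path), "genbank"))
        except StopIteration:
            raise PlastomeError(f"{path}: no GenBank record found") from None
        except Exception as exc:  # noqa: BLE001 - surface parser message
            raise PlastomeError(f"{path}: GenBank parse error: {exc}") from exc
        genome_id = record.id or record.name or path.stem
        sequence = str(record.seq)
        circular = record.annotations.get("topology", "circular") == "circular"
        raw = []
        for i, feat in enumerate(record.features):
            if feat.type in ("gene", "source", "exon", "misc_feature"):
                continue
            if feat.type not in _FEATURE_KEYS and feat.type not in ("ncRNA", "tmRNA"):
                continue
            g = _gene_from_feature(feat, genome_id, len(sequence), i)
            if g is not None:
                raw.append(g)
    elif format in ("gff3+fasta", "gff3"):
        if fasta is None:
            raise PlastomeError("gff3 input requires a companion FASTA path")
        seq_record = next(SeqIO.parse(str(fasta), "fasta"))
        genome_id = seq_record.id
        sequence = str(seq_record.seq)
        circular = True
        raw = _parse_gff3(path, genome_id, len(sequence))
    else:
        raise PlastomeError(f"unknown format {format!r}")

    if not raw:
        raise PlastomeError(f"{path}: no gene features found")
    genes = _disambiguate(raw)
    return PlastomeAnnotation(
        genome_id=genome_id, sequence=sequence, circular=circular, genes=genes
    )


def _parse_gff3(path: Path, genome_id: str, genome_length: int) -> list[GeneModel]:
    genes: list[GeneModel] = []
    with open(path) as fh:
        for i, line in enumerate(fh):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) < 9:
                raise PlastomeError(f"{path}:{i + 1}: malformed GFF3 line")
            ftype = cols[2]
            if ftype not in ("CDS", "tRNA", "rRNA"):
                continue
            attrs = dict(
                kv.split("=", 1) for kv in cols[8].split(";") if "=" in kv
            )
            if attrs.get("pseudo") == "true":
                continue
            gene_id = attrs.get("gene") or attrs.get("Name") or attrs.get("ID") or f"feature_{i}"
            start = int(cols[3]) - 1  # GFF3 is 1-based inclusive
            end = int(cols[4])
            strand = cols[6] if cols[6] in "+-" else "+"
            length = end - start
            genes.append(
                GeneModel(
                    gene_id=gene_id,
                    gene_type=ftype,
                    strand=strand,
                    start=start,
                    end=end,
                    genome_id=genome_id,
                    product=attrs.get("product"),
                    canonical=ftype != "CDS" or length % 3 == 0,
                )
            )
    return genes


# ---------------------------------------------------------------------------
# Writing
# ---------------------------------------------------------------------------


def write_genbank(annotation: PlastomeAnnotation, path: str | Path) -> Path:
    """Write the annotation as a GenBank flat file (round-trip safe)."""
    record = SeqRecord(
        Seq(annotation.sequence),
        id=annotation.genome_id,
        name=annotation.genome_id[:16].replace("|", "_"),
        description="plastome annotation",
        annotations={
            "molecule_type": "DNA",
            "topology": "circular" if annotation.circular else "linear",
        },
    )
    for g in annotation.genes:
        spans = g.exon_spans or ((g.start, g.end),)
        strand = -1 if g.strand == "-" else 1
        locs = [SimpleLocation(s, e, strand) for s, e in spans]
        location = locs[0] if len(locs) == 1 else CompoundLocation(locs)
        ftype = g.gene_type if g.gene_type in _FEATURE_KEYS else "misc_RNA"
        qualifiers: dict[str, list[str]] = {"gene": [g.gene_id]}
        if g.product:
            qualifiers["product"] = [g.product]
        record.features.append(SeqFeature(location, type=ftype, qualifiers=qualifiers))
    path = Path(path)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        SeqIO.write([record], str(path), "genbank")
    return path


def write_gene_table(annotation: PlastomeAnnotation, path: str | Path) -> Path:
    """Normalized gene table as TSV."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("genome_id\tgene_id\ttype\tstrand\tstart\tend\n")
        for g in annotation.genes:
            fh.write(
                f"{annotation.genome_id}\t{g.gene_id}\t{g.gene_type}\t"
                f"{g.strand}\t{g.start}\t{g.end}\n"
            )
    return path


# ---------------------------------------------------------------------------
# Pair enumeration
# ---------------------------------------------------------------------------


def _make_pair(
    gene5: GeneModel, gene3: GeneModel, genome_length: int, wraps: bool
) -> GenePair:
    group = "CDS" if gene5.gene_type == "CDS" and gene3.gene_type == "CDS" else "mixed"
    return GenePair(
        gene5=gene5,
        gene3=gene3,
        igs_start=gene5.end,
        igs_end=gene3.start + (genome_length if wraps else 0),
        same_strand=gene5.strand == gene3.strand,
        pair_group=group,
        wraps_origin=wraps,
        genome_length=genome_length,
    )


def enumerate_adjacent_pairs(annotation: PlastomeAnnotation) -> list[GenePair]:
    """All adjacent gene pairs in genomic order.

    Circular genomes yield one pair per gene (the last->first wrap pair is
    emitted exactly once, flagged ``wraps_origin``); linear genomes yield
    one fewer.  Opposite-strand neighbours are enumerated too, with
    ``same_strand=False``.
    """
    genes = annotation.genes
    if len(genes) < 2:
        logger.warning("%s: fewer than 2 genes; no pairs", annotation.genome_id)
        return []
    n = annotation.length
    pairs = [
        _make_pair(genes[i], genes[i + 1], n, wraps=False)
        for i in range(len(genes) - 1)
    ]
    if annotation.circular:
        pairs.append(_make_pair(genes[-1], genes[0], n, wraps=True))
    return pairs
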