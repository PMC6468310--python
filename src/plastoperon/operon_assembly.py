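"""Concatenating classified gene pairs into full operon maps.

A pair labelled 1 means its two genes are co-transcribed; maximal runs of
1-labelled adjacent pairs therefore form multi-gene operons, and genes
with no 1-labelled neighbour are monocistrons.  On a circular genome a run
may cross the origin; a genome whose every pair is labelled 1 is a single
operon containing all genes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

from .classifier import PairPrediction
from .genome_io import GenePair, PlastomeAnnotation, enumerate_adjacent_pairs

logger = logging.getLogger("plastoperon")


@dataclass
class OperonMap:
    """Partition of a genome's genes into maximal co-transcribed runs."""

    genome_id: str
    operons: list[list[str]]
    pair_scores: dict[tuple[str, str], float] = field(default_factory=dict)
    wraps_origin: bool = False  # true when one operon crosses the origin

    @property
    def gene_count(self) -> int:
        return sum(len(op) for op in self.operons)

    def multi_gene_operons(self) -> list[list[str]]:
        return [op for op in self.operons if len(op) >= 2]

    def operon_of(self, gene_id: str) -> list[str]:
        for op in self.operons:
            if gene_id in op:
                return op
        raise KeyError(gene_id)

    def strand_inconsistent_operons(
        self, annotation: PlastomeAnnotation
    ) -> list[int]:
        """Indices of multi-gene operons mixing strands (flagged, not forbidden)."""
        strands = {g.gene_id: g.strand for g in annotation.genes}
        return [
            i
            for i, op in enumerate(self.operons)
            if len(op) >= 2 and len({strands[g] for g in op}) > 1
        ]


def assemble(
    predictions: Sequence[PairPrediction],
    annotation: PlastomeAnnotation,
) -> OperonMap:
    """Merge 1-labelled adjacent pairs into maximal operons.

    ``predictions`` are matched to the genome's enumerated pairs by
    pair_id; enumerated pairs without a prediction are treated as label 0
    with a warning.  The result partitions the gene list: every gene lands
    in exactly one operon (monocistrons included as length-1 operons).
    """
    pairs = enumerate_adjacent_pairs(annotation)
    known_ids = {p.pair_id for p in pairs}
    by_id: dict[str, PairPrediction] = {}
    for pred in predictions:
        if pred.pair_id not in known_ids:
            raise ValueError(f"prediction for unknown pair {pred.pair_id!r}")
        by_id[pred.pair_id] = pred
    labels: list[int] = []
    scores: dict[tuple[str, str], float] = {}
    for pair in pairs:
        pred = by_id.get(pair.pair_id)
        if pred is None:
            logger.warning("%s: no prediction; treated as non-operon", pair.pair_id)
            labels.append(0)
            scores[(pair.gene5.gene_id, pair.gene3.gene_id)] = 0.0
        else:
            labels.append(pred.label)
            scores[(pair.gene5.gene_id, pair.gene3.gene_id)] = pred.score
    genes = [g.gene_id for g in annotation.genes]
    n = len(genes)

    if not annotation.circular:
        operons = _runs_linear(genes, labels)
        wraps = False
    else:
        # pairs[i] joins genes[i] and genes[i+1]; pairs[n-1] is the wrap pair.
        if all(lab == 1 for lab in labels):
            operons = [list(genes)]
            wraps = True
        else:
            # rotate so position 0 starts just after a 0-labelled pair
            anchor = next(i for i, lab in enumerate(labels) if lab == 0)
            rot_genes = genes[anchor + 1 :] + genes[: anchor + 1]
            rot_labels = labels[anchor + 1 :] + labels[: anchor + 1]
            operons = _runs_linear(rot_genes, rot_labels[:-1])
            wraps = any(
                genes[0] in op and genes[-1] in op and len(op) >= 2 for op in operons
            )
    return OperonMap(
        genome_id=annotation.genome_id,
        operons=operons,
        pair_scores=scores,
        wraps_origin=wraps,
    )


def _runs_linear(genes: list[str], labels: list[int]) -> list[list[str]]:
    operons: list[list[str]] = []
    current = [genes[0]]
    for gene, lab in zip(genes[1:], labels):
        if lab == 1:
            current.append(gene)
        else:
            operons.append(current)
            current = [gene]
    operons.append(current)
    return operons


@dataclass(frozen=True)
class OperonSummary:
    genome_id: str
    n_genes: int
    n_operons: int
    n_multi_gene_operons: int
    cds_in_operons_fraction: float
    genes_in_operons_fraction: float
    class_counts: dict  # gene class -> (in multi-gene operons, total)


def summarize(operon_map: OperonMap, annotation: PlastomeAnnotation) -> OperonSummary:
    """Genome-level operon statistics.

    A gene counts as "in an operon" only when its operon has at least two
    genes; the per-class membership counts feed the enrichment index.
    """
    types = {g.gene_id: g.gene_type for g in annotation.genes}
    in_operon = {g for op in operon_map.multi_gene_operons() for g in op}
    all_genes = [g.gene_id for g in annotation.genes]
    cds = [g for g in all_genes if types[g] == "CDS"]
    class_counts: dict[str, tuple[int, int]] = {}
    for cls in sorted({t for t in types.values()}):
        members = [g for g in all_genes if types[g] == cls]
        class_counts[cls] = (sum(1 for g in members if g in in_operon), len(members))
    return OperonSummary(
        genome_id=operon_map.genome_id,
        n_genes=len(all_genes),
        n_operons=len(operon_map.operons),
        n_multi_gene_operons=len(operon_map.multi_gene_operons()),
        cds_in_operons_fraction=(
            sum(1 for g in cds if g in in_operon) / len(cds) if cds else 0.0
        ),
        genes_in_operons_fraction=len(in_operon) / len(all_genes) if all_genes else 0.0,
        class_counts=class_counts,
    )


# ---------------------------------------------------------------------------
# Writers
# ---------------------------------------------------------------------------


def write_operon_tsv(
    operon_map: OperonMap, annotation: PlastomeAnnotation, path: str | Path
) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(
            "genome_id\toperon_id\tgene_id\tposition_in_operon\tpair_score_upstream\n"
        )
        for oi, op in enumerate(operon_map.operons):
            for pos, gene in enumerate(op):
                score = ""
                if pos > 0:
                    score = f"{operon_map.pair_scores.get((op[pos - 1], gene), '')}"
                fh.write(
                    f"{operon_map.genome_id}\toperon_{oi:04d}\t{gene}\t{pos}\t{score}\n"
                )
    return path


def _operon_span(
    op: list[str], annotation: PlastomeAnnotation
) -> tuple[int, int, str]:
    genes = [annotation.gene(g) for g in op]
    start = min(g.start for g in genes)
    end = max(g.end for g in genes)
    strands = {g.strand for g in genes}
    strand = strands.pop() if len(strands) == 1 else "."
    return start, end, strand


def write_operon_gff3(
    operon_map: OperonMap, annotation: PlastomeAnnotation, path: str | Path
) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for oi, op in enumerate(operon_map.operons):
            start, end, strand = _operon_span(op, annotation)
            attrs = f"ID=operon_{oi:04d};genes={','.join(op)}"
            fh.write(
                f"{operon_map.genome_id}\tplastoperon\toperon\t{start + 1}\t{end}\t.\t"
                f"{strand}\t.\t{attrs}\n"
            )
    return path


def write_operon_bed12(
    operon_map: OperonMap, annotation: PlastomeAnnotation, path: str | Path
) -> Path:
    """BED12 with one block per member gene."""
    path = Path(path)
    with open(path, "w") as fh:
        for oi, op in enumerate(operon_map.operons):
            start, end, strand = _operon_span(op, annotation)
            genes = sorted((annotation.gene(g) for g in op), key=lambda g: g.start)
            sizes = ",".join(str(g.end - g.start) for g in genes)
            starts = ",".join(str(g.start - start) for g in genes)
            fh.write(
                f"{operon_map.genome_id}\t{start}\t{end}\toperon_{oi:04d}\t0\t"
                f"{strand if strand != '.' else '+'}\t{start}\t{end}\t0\t"
                f"{len(genes)}\t{sizes}\t{starts}\n"
            )
    return path
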