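"""Seeded synthetic plastomes with planted operon structure.

The generator emits a circular annotated genome whose genes are grouped
into operons with known truth labels, so every pipeline stage can be
exercised hermetically.  Planted contrasts mirror the sequence signatures
that separate operon pairs (OP) from non-operon pairs (NOP) in real
plastomes:

* OP spacers are shorter and AT-richer than NOP spacers;
* the folding-energy profile around the downstream gene's start codon is
  a mutated copy of its operon partner's start region, tuned by a
  rejection loop until the profile Pearson correlation reaches a target;
* tRNA and rRNA genes are biased toward the monocistronic form.

``effect_scale`` interpolates every contrast between the NOP baseline
(scale 0: OP and NOP indistinguishable) and the configured OP values
(scale 1).  All randomness flows from ``SimConfig.seed``.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import features as ft
from .genome_io import (
    GeneModel,
    PlastomeAnnotation,
    reverse_complement,
    write_genbank,
)
from .operon_assembly import OperonMap

logger = logging.getLogger("plastoperon")

_STOPS = ("TAA", "TAG", "TGA")


class SimulationError(ValueError):
    """Raised for unsatisfiable simulation configurations."""


@dataclass
class SimConfig:
    """Study conditions for one simulated plastome.

    IGS lengths are drawn from normals (mean, sd) in nt; GC values are
    per-site probabilities.  ``fold_profile_correlation_op`` is the target
    Pearson r between the start-anchored folding profiles of the two
    members of an OP pair (``None`` disables that planting).
    """

    n_genes: int = 60
    class_mix: dict = field(
        default_factory=lambda: {"CDS": 0.80, "tRNA": 0.15, "rRNA": 0.05}
    )
    operon_length_distribution: dict = field(
        default_factory=lambda: {1: 0.35, 2: 0.20, 3: 0.20, 4: 0.15, 5: 0.10}
    )
    op_igs_length: tuple[float, float] = (30.0, 12.0)
    nop_igs_length: tuple[float, float] = (150.0, 40.0)
    op_igs_gc: float = 0.22
    nop_igs_gc: float = 0.40
    rna_monocistron_bias: float = 0.7  # P(tRNA/rRNA gene placed monocistronic)
    fold_profile_correlation_op: float | None = 0.80
    effect_scale: float = 1.0
    genome_gc: float = 0.35
    cds_length_range: tuple[int, int] = (180, 600)
    trna_length: int = 75
    rrna_length: int = 400
    upstream: int = 100
    downstream: int = 50
    window: int = 40
    plant_step: int = 2
    max_plant_iter: int = 14
    seed: int = 0

    def __post_init__(self) -> None:
        for frac in (
            *self.class_mix.values(),
            self.op_igs_gc,
            self.nop_igs_gc,
            self.genome_gc,
            self.effect_scale,
            self.rna_monocistron_bias,
        ):
            if not 0.0 <= frac <= 1.0:
                raise SimulationError("fractions must lie in [0, 1]")
        if self.effect_scale > 0 and self.op_igs_length[0] >= self.nop_igs_length[0]:
            raise SimulationError(
                "OP spacers must be shorter than NOP spacers when an effect is planted"
            )
        if self.n_genes < 4:
            raise SimulationError("need at least 4 genes")

    @classmethod
    def realistic(cls, **overrides) -> "SimConfig":
        """Overlapping OP/NOP distributions, closer to real plastomes."""
        base = dict(
            op_igs_length=(60.0, 45.0),
            nop_igs_length=(130.0, 70.0),
            op_igs_gc=0.30,
            nop_igs_gc=0.37,
            fold_profile_correlation_op=0.50,
        )
        base.update(overrides)
        return cls(**base)

    # effective (effect_scale-interpolated) OP parameters -------------------

    def effective_op_igs_length(self) -> tuple[float, float]:
        s = self.effect_scale
        return (
            self.nop_igs_length[0] + s * (self.op_igs_length[0] - self.nop_igs_length[0]),
            self.nop_igs_length[1] + s * (self.op_igs_length[1] - self.nop_igs_length[1]),
        )

    def effective_op_igs_gc(self) -> float:
        s = self.effect_scale
        return self.nop_igs_gc + s * (self.op_igs_gc - self.nop_igs_gc)

    def effective_fold_target(self) -> float | None:
        if self.fold_profile_correlation_op is None or self.effect_scale == 0:
            return None
        return self.effect_scale * self.fold_profile_correlation_op


@dataclass
class SimulatedPlastome:
    annotation: PlastomeAnnotation
    truth_labels: pd.DataFrame  # gene5, gene3, pair_group, label per adjacent pair
    truth_map: OperonMap
    config: SimConfig

    def label_dict(self) -> dict[str, int]:
        return {
            f"{r.gene5}|{r.gene3}": int(r.label)
            for r in self.truth_labels.itertuples()
        }

    def write(self, outdir: str | Path) -> Path:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_genbank(self.annotation, outdir / f"{self.annotation.genome_id}.gb")
        self.truth_labels.to_csv(
            outdir / f"{self.annotation.genome_id}_truth_pairs.tsv",
            sep="\t",
            index=False,
        )
        cfg = dataclasses.asdict(self.config)
        with open(outdir / f"{self.annotation.genome_id}_simconfig.json", "w") as fh:
            json.dump(cfg, fh, indent=2, default=str)
        return outdir


# ---------------------------------------------------------------------------
# Sequence synthesis helpers
# ---------------------------------------------------------------------------


def _random_seq(rng: np.random.Generator, length: int, gc: float) -> str:
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return "".join(rng.choice(list("ACGT"), size=length, p=p))


def _random_cds(rng: np.random.Generator, length: int, gc: float) -> str:
    """ATG + stop-free GC-tuned codons + TAA; ``length`` is total nt (mult. of 3)."""
    n_codons = length // 3 - 2
    codons = []
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    while len(codons) < n_codons:
        c = "".join(rng.choice(list("ACGT"), size=3, p=p))
        if c not in _STOPS:
            codons.append(c)
    return "ATG" + "".join(codons) + "TAA"


def _fix_internal_stops(seq_list: list[str], gene: "_Gene", n: int) -> None:
    """Recode internal stop codons (third base -> C) and restore the final TAA."""
    if gene.gene_type != "CDS":
        return
    s = _read_region(seq_list, gene.start, gene.end, gene.strand, n)
    codons = [s[i : i + 3] for i in range(0, len(s) - 3, 3)]
    changed = False
    for i, c in enumerate(codons):
        if c in _STOPS:
            codons[i] = c[:2] + "C"
            changed = True
    tail = s[len(s) - 3 :]
    if tail != "TAA":
        tail = "TAA"
        changed = True
    if changed:
        _write_region(seq_list, gene.start, gene.end, gene.strand, "".join(codons) + tail, n)


def _read_region(seq_list: list[str], lo: int, hi: int, strand: str, n: int) -> str:
    s = "".join(seq_list[i % n] for i in range(lo, hi))
    return reverse_complement(s) if strand == "-" else s


def _write_region(
    seq_list: list[str], lo: int, hi: int, strand: str, content: str, n: int
) -> None:
    if strand == "-":
        content = reverse_complement(content)
    for k, i in enumerate(range(lo, hi)):
        seq_list[i % n] = content[k]


@dataclass
class _Gene:
    gene_id: str
    gene_type: str
    strand: str
    start: int = 0
    end: int = 0
    seq: str = ""
    operon: int = 0

    def utr_region(self, upstream: int, downstream: int) -> tuple[int, int]:
        """Genomic coordinates of the start-anchored region (strand space)."""
        if self.strand == "+":
            return self.start - upstream, self.start + downstream
        return self.end - downstream, self.end + upstream


# ---------------------------------------------------------------------------
# Folding-similarity planting
# ---------------------------------------------------------------------------


def _region_similarity(
    seq_list: list[str],
    u: _Gene,
    d: _Gene,
    cfg: SimConfig,
    n: int,
    engine,
    profile_u=None,
) -> float:
    lo_u, hi_u = u.utr_region(cfg.upstream, cfg.downstream)
    lo_d, hi_d = d.utr_region(cfg.upstream, cfg.downstream)
    if profile_u is None:
        r_u = _read_region(seq_list, lo_u, hi_u, u.strand, n)
        profile_u = ft.folding_profile(r_u, cfg.window, cfg.plant_step, engine)
    r_d = _read_region(seq_list, lo_d, hi_d, d.strand, n)
    profile_d = ft.folding_profile(r_d, cfg.window, cfg.plant_step, engine)
    try:
        r = ft.profile_similarity(profile_u, profile_d)
    except ft.FeatureUndefined:  # degenerate (constant) profile
        r = 0.0
    return r, profile_u


def _plant_pair_similarity(
    seq_list: list[str],
    genes: list[_Gene],
    owner: np.ndarray,
    u: _Gene,
    d: _Gene,
    cfg: SimConfig,
    target: float,
    rng: np.random.Generator,
    engine,
    tol: float = 0.05,
) -> bool | None:
    """Copy-and-mutate u's start region into d's until the profile r hits target.

    Writable positions in d's region: the pair's spacer, u's own body
    (frame-corrected afterwards) and d's coding body past the ATG; bases
    belonging to any other gene are left untouched.  Because coding frames
    constrain a few bases, the attainable correlation has a per-pair
    ceiling (the exact-copy r); when the target exceeds it the maximal
    attainable copy is kept and False is returned so the caller can judge
    whether the configured target is globally unreachable.  Returns None
    when the pair cannot be planted at all (overlapping anchor regions).
    """
    n = len(seq_list)
    lo_u, hi_u = u.utr_region(cfg.upstream, cfg.downstream)
    lo_d, hi_d = d.utr_region(cfg.upstream, cfg.downstream)
    span = hi_d - lo_d
    # strand-space index k of d's region -> genomic position
    if d.strand == "+":
        pos_d = [(lo_d + k) % n for k in range(span)]
    else:
        pos_d = [(hi_d - 1 - k) % n for k in range(span)]
    # regions overlapping each other cannot be planted independently
    pos_u = {i % n for i in range(lo_u, hi_u)}
    if pos_u & set(pos_d):
        logger.debug("%s|%s: anchor regions overlap; similarity not planted", u.gene_id, d.gene_id)
        return None
    uid, did = genes.index(u), genes.index(d)
    writable = np.zeros(span, dtype=bool)
    for k, p in enumerate(pos_d):
        own = owner[p]
        if own == -1 or own == uid:
            writable[k] = True
        elif own == did:
            # keep d's ATG; the rest of d's body may be rewritten
            offset_in_d = k - cfg.upstream  # strand-space offset from start codon
            writable[k] = offset_in_d >= 3
    if writable.sum() < span // 2:
        logger.debug("%s|%s: too few writable bases; similarity not planted", u.gene_id, d.gene_id)
        return None

    source = _read_region(seq_list, lo_u, hi_u, u.strand, n)
    original = _read_region(seq_list, lo_d, hi_d, d.strand, n)
    profile_u = None

    def apply(mutation_rate: float) -> float:
        nonlocal profile_u
        cand = list(original)
        for k in range(span):
            if writable[k]:
                if rng.random() < mutation_rate:
                    cand[k] = "ACGT"[rng.integers(4)]
                else:
                    cand[k] = source[k]
        _write_region(seq_list, lo_d, hi_d, d.strand, "".join(cand), n)
        _fix_internal_stops(seq_list, u, n)
        _fix_internal_stops(seq_list, d, n)
        r, pu = _region_similarity(seq_list, u, d, cfg, n, engine, profile_u)
        profile_u = pu
        return r

    r0 = apply(0.0)
    if r0 < target - tol:
        # the frame-constrained ceiling sits below the target: keep the copy
        logger.debug(
            "%s|%s: exact-copy ceiling r=%.2f below target %.2f",
            u.gene_id, d.gene_id, r0, target,
        )
        return False
    if r0 <= target + tol:
        return True
    lo_m, hi_m = 0.0, 0.9
    best = (abs(r0 - target), 0.0)
    for _ in range(cfg.max_plant_iter):
        m = (lo_m + hi_m) / 2
        r = apply(m)
        if abs(r - target) < best[0]:
            best = (abs(r - target), m)
        if r > target + tol:
            lo_m = m
        elif r < target - tol:
            hi_m = m
        else:
            return True
    apply(best[1])  # settle on the closest rate seen
    return True


# ---------------------------------------------------------------------------
# Main generator
# ---------------------------------------------------------------------------


def simulate_plastome(config: SimConfig) -> SimulatedPlastome:
    """Generate one circular annotated plastome with known operon truth.

    Deterministic per ``config.seed``; see the module docstring for the
    planted contrasts.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)

    # 1. operon sizes ------------------------------------------------------
    lengths = np.array(list(cfg.operon_length_distribution.keys()))
    probs = np.array(list(cfg.operon_length_distribution.values()), dtype=float)
    probs = probs / probs.sum()
    sizes: list[int] = []
    while sum(sizes) < cfg.n_genes:
        sizes.append(int(rng.choice(lengths, p=probs)))
    sizes[-1] -= sum(sizes) - cfg.n_genes
    if sizes[-1] == 0:
        sizes.pop()

    # 2. gene classes: tRNA/rRNA preferentially monocistronic --------------
    n = cfg.n_genes
    n_trna = int(round(cfg.class_mix.get("tRNA", 0.0) * n))
    n_rrna = int(round(cfg.class_mix.get("rRNA", 0.0) * n))
    gene_types = ["CDS"] * n
    positions = np.arange(n)
    operon_of = np.repeat(np.arange(len(sizes)), sizes)
    singles = list(
        positions[np.isin(operon_of, [i for i, s in enumerate(sizes) if s == 1])]
    )
    rng.shuffle(singles)
    multi = [p for p in positions if p not in set(singles)]
    rng.shuffle(multi)
    # each RNA gene prefers a monocistron slot (tRNA the strongest real-world
    # bias) but some land inside operons, so mixed operon pairs exist
    for kind, count in (("rRNA", n_rrna), ("tRNA", n_trna)):
        for _ in range(count):
            pick_single = rng.random() < cfg.rna_monocistron_bias
            pool = singles if (pick_single and singles) or not multi else multi
            gene_types[pool.pop()] = kind

    # 3. gene sequences and per-operon strands -----------------------------
    strands = [rng.choice(["+", "-"]) for _ in sizes]
    genes: list[_Gene] = []
    for idx in range(n):
        op = int(operon_of[idx])
        gtype = gene_types[idx]
        if gtype == "CDS":
            lo3, hi3 = cfg.cds_length_range[0] // 3, cfg.cds_length_range[1] // 3
            length = 3 * int(rng.integers(lo3, hi3 + 1))
            seq = _random_cds(rng, length, cfg.genome_gc)
        elif gtype == "tRNA":
            seq = _random_seq(rng, cfg.trna_length, cfg.genome_gc)
        else:
            seq = _random_seq(rng, cfg.rrna_length, cfg.genome_gc)
        genes.append(
            _Gene(
                gene_id=f"g{idx:04d}_{gtype.lower()}",
                gene_type=gtype,
                strand=strands[op],
                seq=seq,
                operon=op,
            )
        )

    # 4. spacers and layout ------------------------------------------------
    op_len_mean, op_len_sd = cfg.effective_op_igs_length()
    op_gc = cfg.effective_op_igs_gc()
    plant_fold = cfg.effective_fold_target() is not None
    chunks: list[str] = []
    pos = 0
    pair_is_op: list[bool] = []
    for idx, gene in enumerate(genes):
        # the spacer preceding gene idx belongs to pair (idx-1, idx); the
        # one preceding gene 0 is the wrap pair's spacer (always NOP here:
        # planted operons never cross the origin)
        prev = genes[idx - 1]
        is_op = idx > 0 and prev.operon == gene.operon
        pair_is_op.append(is_op)
        if is_op:
            igs_len = max(2, int(round(rng.normal(op_len_mean, op_len_sd))))
            igs = _random_seq(rng, igs_len, op_gc)
        else:
            igs_len = max(2, int(round(rng.normal(*cfg.nop_igs_length))))
            igs = _random_seq(rng, igs_len, cfg.nop_igs_gc)
            if plant_fold:
                # The similarity planting copies the region just upstream of
                # an operon's first start codon into the downstream member's
                # spacer; giving that source band OP-level GC keeps planted
                # operon spacers AT-rich all the way down the copy chain.
                band = min(igs_len, 60)
                if gene.strand == "+" and sizes[gene.operon] >= 2 and (
                    idx == 0 or genes[idx - 1].operon != gene.operon
                ):
                    igs = igs[:-band] + _random_seq(rng, band, op_gc)
                if prev.strand == "-" and sizes[prev.operon] >= 2 and (
                    prev.operon != gene.operon
                ):
                    igs = _random_seq(rng, band2 := min(igs_len, 60), op_gc) + igs[band2:]
        chunks.append(igs)
        pos += igs_len
        gene.start = pos
        gene.end = pos + len(gene.seq)
        chunks.append(gene.seq if gene.strand == "+" else reverse_complement(gene.seq))
        pos = gene.end
    seq_list = list("".join(chunks))
    genome_length = len(seq_list)
    owner = np.full(genome_length, -1, dtype=int)
    for gi, g in enumerate(genes):
        owner[g.start : g.end] = gi

    # 5. plant folding-profile similarity within operons -------------------
    target = cfg.effective_fold_target()
    if target is not None:
        engine = ft.default_engine()
        reached, attempted = 0, 0
        for op_idx, size in enumerate(sizes):
            if size < 2:
                continue
            members = [g for g in genes if g.operon == op_idx]
            if strands[op_idx] == "-":
                members = members[::-1]  # transcription order
            for u, d in zip(members, members[1:]):
                outcome = _plant_pair_similarity(
                    seq_list, genes, owner, u, d, cfg, target, rng, engine
                )
                if outcome is not None:
                    attempted += 1
                    reached += outcome
        if attempted and reached < attempted / 2:
            raise SimulationError(
                f"folding-profile correlation target {target:.2f} unreachable for "
                f"{attempted - reached}/{attempted} operon pairs; lower the target"
            )

    # 6. assemble outputs --------------------------------------------------
    models = [
        GeneModel(
            gene_id=g.gene_id,
            gene_type=g.gene_type,
            strand=g.strand,
            start=g.start,
            end=g.end,
            genome_id=f"sim{cfg.seed:06d}",
        )
        for g in genes
    ]
    annotation = PlastomeAnnotation(
        genome_id=f"sim{cfg.seed:06d}",
        sequence="".join(seq_list),
        circular=True,
        genes=models,
    )
    rows = []
    for idx in range(n):
        g5 = genes[idx]
        g3 = genes[(idx + 1) % n]
        is_op = pair_is_op[(idx + 1) % n]
        group = "CDS" if g5.gene_type == "CDS" and g3.gene_type == "CDS" else "mixed"
        rows.append(
            {
                "genome_id": annotation.genome_id,
                "gene5": g5.gene_id,
                "gene3": g3.gene_id,
                "pair_group": group,
                "label": int(is_op),
            }
        )
    truth_labels = pd.DataFrame(rows)
    operons = [
        [g.gene_id for g in genes if g.operon == op_idx] for op_idx in range(len(sizes))
    ]
    truth_map = OperonMap(genome_id=annotation.genome_id, operons=operons)
    return SimulatedPlastome(annotation, truth_labels, truth_map, cfg)


# ---------------------------------------------------------------------------
# Reference panels for the conservation feature
# ---------------------------------------------------------------------------


def make_reference_panel(
    base: PlastomeAnnotation,
    n_genomes: int,
    rearrangement_rate: float,
    seed: int = 0,
) -> list[PlastomeAnnotation]:
    """Shuffled-block variants of ``base`` with known adjacency retention.

    Each inter-gene adjacency is broken independently with probability
    ``rearrangement_rate``; the resulting blocks are shuffled and relaid as
    compact annotations (sequences are fresh random filler — conservation
    is a name-based notion).  rate 0 preserves every adjacency; rate 1
    reduces conservation to the chance level of random adjacency.
    """
    if not 0.0 <= rearrangement_rate <= 1.0:
        raise ValueError("rearrangement_rate must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    order = list(base.genes)
    k = len(order)
    panel = []
    for gi in range(n_genomes):
        breaks = [i for i in range(k) if rng.random() < rearrangement_rate]
        if not breaks:
            blocks = [list(range(k))]
        else:
            blocks = []
            start = breaks[-1] + 1  # circular: cut after the last break
            idx = [(start + j) % k for j in range(k)]
            current = []
            for j in idx:
                current.append(j)
                if j in breaks:
                    blocks.append(current)
                    current = []
            if current:
                blocks.append(current)
        rng.shuffle(blocks)
        flat = [order[j] for b in blocks for j in b]
        pos = 0
        models = []
        for g in flat:
            length = min(g.end - g.start, 60)
            pos += 20
            models.append(
                GeneModel(
                    gene_id=g.gene_id,
                    gene_type=g.gene_type,
                    strand=g.strand,
                    start=pos,
                    end=pos + length,
                    genome_id=f"{base.genome_id}_ref{gi}",
                )
            )
            pos += length
        sequence = _random_seq(rng, pos + 20, 0.4)
        panel.append(
            PlastomeAnnotation(
                genome_id=f"{base.genome_id}_ref{gi}",
                sequence=sequence,
                circular=True,
                genes=models,
            )
        )
    return panel
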