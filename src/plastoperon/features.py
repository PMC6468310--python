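"""Sequence-based features for adjacent gene pairs.

Operon pairs (OP) in plastomes differ from non-operon pairs (NOP) in a
handful of measurable sequence properties: they sit closer together, their
intergenic spacers are AT-richer, their gene order is conserved across
plastomes, and — a chloroplast-specific trait — the mRNA folding-energy
profiles around their translational starts are correlated.  This module
computes those features for a :class:`~plastoperon.genome_io.GenePair`.

An RNA folding-energy profile is the vector of minimum-free-energy (MFE)
values of a fixed-width window (default 40 nt) slid along a sequence.  The
MFE computation is pluggable behind a one-method engine contract; the
default engine binds the ViennaRNA thermodynamic folder when its Python
bindings are importable, otherwise a self-contained base-pair-maximisation
folder (Nussinov-style dynamic program with simple pair energies) keeps the
pipeline runnable.  Energies are in kcal/mol and never exceed 0.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio.Seq import Seq
from Bio.SeqUtils.ProtParam import ProteinAnalysis

from .genome_io import (
    GeneModel,
    GenePair,
    PlastomeAnnotation,
    reverse_complement,
)

logger = logging.getLogger("plastoperon")

PLASTID_CODON_TABLE = 11  # bacterial/plastid genetic code


class FeatureUndefined(ValueError):
    """A feature cannot be computed for this input; it is omitted, not zeroed."""


# ---------------------------------------------------------------------------
# Folding engines
# ---------------------------------------------------------------------------


class ViennaFoldingEngine:
    """Minimum free energy via the ViennaRNA package (RNAfold, 37 degC)."""

    name = "vienna"

    def __init__(self) -> None:
        import RNA  # deferred: optional at runtime

        self._rna = RNA

    def mfe(self, seq: str) -> float:
        _, energy = self._rna.fold(seq)
        return float(energy)


_PAIR_ENERGY = {
    ("G", "C"): -3.0, ("C", "G"): -3.0,
    ("A", "U"): -2.0, ("U", "A"): -2.0,
    ("G", "U"): -1.0, ("U", "G"): -1.0,
}


class NussinovFoldingEngine:
    """Base-pair-maximisation folder with simple stacking-free pair energies.

    A deliberately small model (GC -3, AU -2, GU -1 kcal/mol, minimum
    hairpin loop of 3 nt) used when ViennaRNA is unavailable.  It shares
    the properties the pipeline relies on: energies are <= 0, homopolymers
    score exactly 0, and similar sequences get similar profiles.
    """

    name = "nussinov"

    def __init__(self, min_loop: int = 3) -> None:
        self.min_loop = min_loop

    def mfe(self, seq: str) -> float:
        n = len(seq)
        if n < 2:
            return 0.0
        E = [[0.0] * n for _ in range(n)]
        for span in range(self.min_loop + 1, n):
            for i in range(n - span):
                j = i + span
                best = E[i][j - 1]
                for k in range(i, j - self.min_loop):
                    pe = _PAIR_ENERGY.get((seq[k], seq[j]))
                    if pe is not None:
                        left = E[i][k - 1] if k > i else 0.0
                        inner = E[k + 1][j - 1] if k + 1 <= j - 1 else 0.0
                        cand = left + inner + pe
                        if cand < best:
                            best = cand
                E[i][j] = best
        return E[0][n - 1]


@lru_cache(maxsize=1)
def default_engine():
    """ViennaRNA when importable, else the built-in simplified folder."""
    try:
        return ViennaFoldingEngine()
    except ImportError:
        logger.warning("ViennaRNA bindings not found; using simplified folding engine")
        return NussinovFoldingEngine()


# ---------------------------------------------------------------------------
# Folding profiles
# ---------------------------------------------------------------------------


@dataclass
class FoldingProfile:
    """Per-window MFE values of a sliding window over one region."""

    anchor: str
    window: int
    step: int
    energies: np.ndarray

    def __len__(self) -> int:
        return len(self.energies)


def expected_window_count(region_length: int, window: int, step: int) -> int:
    if region_length < window:
        return 0
    return (region_length - window) // step + 1


def folding_profile(
    seq: str,
    window: int = 40,
    step: int = 1,
    engine=None,
    anchor: str = "",
) -> FoldingProfile:
    """MFE of every window of ``seq`` (DNA input; T->U applied before folding)."""
    if engine is None:
        engine = default_engine()
    rna = seq.upper().replace("T", "U")
    n_windows = expected_window_count(len(rna), window, step)
    if n_windows == 0:
        logger.warning("sequence of length %d shorter than window %d", len(seq), window)
        return FoldingProfile(anchor, window, step, np.empty(0))
    energies = np.fromiter(
        (engine.mfe(rna[i * step : i * step + window]) for i in range(n_windows)),
        dtype=float,
        count=n_windows,
    )
    return FoldingProfile(anchor, window, step, np.minimum(energies, 0.0))


def extract_5utr_region(
    gene: GeneModel,
    annotation: PlastomeAnnotation,
    upstream: int = 100,
    downstream: int = 50,
) -> str:
    """Strand-corrected sequence around the translational start.

    Covers ``upstream`` nt before the first transcribed base through
    ``downstream`` nt into the gene.  On circular genomes the region may
    wrap the origin; on linear genomes it is truncated at the ends with a
    warning.
    """
    n = annotation.length
    if gene.strand == "+":
        lo, hi = gene.start - upstream, gene.start + downstream
    else:
        lo, hi = gene.end - downstream, gene.end + upstream
    if annotation.circular:
        seq = "".join(annotation.sequence[i % n] for i in range(lo, hi)) if (
            lo < 0 or hi > n
        ) else annotation.sequence[lo:hi]
    else:
        if lo < 0 or hi > n:
            logger.warning(
                "%s: 5'UTR region truncated at linear genome edge", gene.gene_id
            )
        seq = annotation.sequence[max(lo, 0) : min(hi, n)]
    return reverse_complement(seq) if gene.strand == "-" else seq


def profile_similarity(p1: FoldingProfile, p2: FoldingProfile) -> float:
    """Pearson correlation of two profiles truncated to the shorter length.

    Profiles are aligned at their anchor (index 0 = same position relative
    to the start codon).  Undefined (raises) when either profile has fewer
    than 3 windows or is constant.
    """
    m = min(len(p1), len(p2))
    if m < 3:
        raise FeatureUndefined("profiles have fewer than 3 aligned windows")
    a = p1.energies[:m]
    b = p2.energies[:m]
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise FeatureUndefined("constant folding profile")
    return float(np.corrcoef(a, b)[0, 1])


def position_margin_profile(
    profiles5: Sequence[FoldingProfile], profiles3: Sequence[FoldingProfile]
) -> list[tuple[int, float]]:
    """Mean |E5 - E3| at each aligned window position, averaged over pairs.

    Positions are window-start offsets (in steps) from the region anchor.
    Pairs whose profiles do not reach a position simply do not contribute
    there.
    """
    if not profiles5 or len(profiles5) != len(profiles3):
        raise ValueError("need equal, non-empty lists of 5' and 3' profiles")
    max_len = max(min(len(a), len(b)) for a, b in zip(profiles5, profiles3))
    if max_len == 0:
        raise ValueError("no aligned windows in any pair")
    out = []
    for pos in range(max_len):
        diffs = [
            abs(a.energies[pos] - b.energies[pos])
            for a, b in zip(profiles5, profiles3)
            if pos < min(len(a), len(b))
        ]
        out.append((pos, float(np.mean(diffs))))
    return out


# ---------------------------------------------------------------------------
# Composition / codon / protein features
# ---------------------------------------------------------------------------


def gc_content(seq: str) -> float:
    """GC fraction over A/C/G/T positions; N excluded from both counts."""
    counts = {c: seq.count(c) for c in "ACGT"}
    total = sum(counts.values())
    if total == 0:
        raise FeatureUndefined("empty or all-N sequence")
    return (counts["G"] + counts["C"]) / total


def intergenic_distance(pair: GenePair) -> int:
    """Signed spacer length; negative means the genes overlap."""
    return pair.igs_length


_STOP_CODONS = {"TAA", "TAG", "TGA"}


def _codon_families() -> dict[str, list[str]]:
    """Synonymous codon families of the plastid (bacterial) code, stops excluded."""
    families: dict[str, list[str]] = {}
    bases = "TCAG"
    for c1 in bases:
        for c2 in bases:
            for c3 in bases:
                codon = c1 + c2 + c3
                if codon in _STOP_CODONS:
                    continue
                aa = str(Seq(codon).translate(table=PLASTID_CODON_TABLE))
                families.setdefault(aa, []).append(codon)
    return families


_FAMILIES = _codon_families()
# 59 codons: 61 sense codons minus the single-codon families Met and Trp.
_RSCU_CODONS = [
    c for aa, codons in sorted(_FAMILIES.items()) if len(codons) > 1 for c in codons
]


def rscu_vector(cds: str) -> np.ndarray:
    """Relative synonymous codon usage over the 59 multi-codon-family codons.

    RSCU of codon c = observed count / (family total / family size); a
    family absent from the gene contributes zeros.
    """
    cds = cds.upper()
    if len(cds) % 3 != 0:
        raise ValueError("CDS length not divisible by 3")
    counts: dict[str, int] = {}
    for i in range(0, len(cds), 3):
        codon = cds[i : i + 3]
        counts[codon] = counts.get(codon, 0) + 1
    vec = np.zeros(len(_RSCU_CODONS))
    idx = {c: i for i, c in enumerate(_RSCU_CODONS)}
    for aa, codons in _FAMILIES.items():
        if len(codons) == 1:
            continue
        family_total = sum(counts.get(c, 0) for c in codons)
        if family_total == 0:
            continue
        expected = family_total / len(codons)
        for c in codons:
            vec[idx[c]] = counts.get(c, 0) / expected
    return vec


def codon_usage_distance(cds5: str, cds3: str) -> float:
    """Euclidean distance between the two genes' RSCU vectors (>= 0)."""
    return float(np.linalg.norm(rscu_vector(cds5) - rscu_vector(cds3)))


def _translate_checked(cds: str) -> str:
    protein = str(Seq(cds).translate(table=PLASTID_CODON_TABLE))
    if protein.endswith("*"):
        protein = protein[:-1]
    if "*" in protein:
        raise ValueError(f"internal stop codon at residue {protein.index('*') + 1}")
    return protein


def gravy(cds: str) -> float:
    """Grand average of hydropathy (Kyte-Doolittle) of the encoded protein."""
    protein = _translate_checked(cds)
    if not protein:
        raise FeatureUndefined("empty protein")
    return float(ProteinAnalysis(protein).gravy())


def gravy_margin(cds5: str, cds3: str) -> float:
    return abs(gravy(cds5) - gravy(cds3))


# ---------------------------------------------------------------------------
# Pair conservation
# ---------------------------------------------------------------------------


def normalize_gene_name(name: str) -> str:
    """Case-fold and strip the coordinate suffix added for duplicate names."""
    name = name.lower()
    parts = name.rsplit("_", 1)
    if len(parts) == 2 and parts[1].isdigit():
        return parts[0]
    return name


def pair_conservation(
    pair: GenePair, reference: Sequence[PlastomeAnnotation]
) -> float:
    """Fraction of reference genomes where the two gene names are adjacent.

    Adjacency requires the same relative order and orientation; a pair on
    the opposite strand of a reference (both order and strands flipped) is
    the same arrangement and counts as conserved.  Name matching is
    case-insensitive with locus suffixes stripped — a deliberate
    name-based (not homology-based) notion that leans on the strong
    standardisation of plastid gene names.
    """
    if not reference:
        raise ValueError("reference panel is empty")
    n5 = normalize_gene_name(pair.gene5.gene_id)
    n3 = normalize_gene_name(pair.gene3.gene_id)
    if not n5 or not n3:
        raise FeatureUndefined("unnamed gene")
    rel_strand = (pair.gene5.strand, pair.gene3.strand)
    hits = 0
    for ref in reference:
        genes = ref.genes
        order = [(normalize_gene_name(g.gene_id), g.strand) for g in genes]
        k = len(order)
        found = False
        rng = range(k) if ref.circular else range(k - 1)
        for i in rng:
            a, sa = order[i]
            b, sb = order[(i + 1) % k]
            if a == n5 and b == n3 and (sa, sb) == rel_strand:
                found = True
                break
            # same arrangement read from the other strand
            flip = {"+": "-", "-": "+"}
            if a == n3 and b == n5 and (sb, sa) == (
                flip[rel_strand[0]],
                flip[rel_strand[1]],
            ):
                found = True
                break
        hits += found
    return hits / len(reference)


# ---------------------------------------------------------------------------
# Assembled per-pair feature vectors
# ---------------------------------------------------------------------------


@dataclass
class FeatureConfig:
    """Knobs for feature computation.

    ``upstream``/``downstream`` bound the start-anchored region whose
    folding profile is computed (default -100..+50 nt around the start
    codon); ``window``/``step`` control the sliding window; ``margin
    positions`` are the window offsets exported as position-specific
    folding-margin features.
    """

    upstream: int = 100
    downstream: int = 50
    window: int = 40
    step: int = 1
    margin_positions: tuple[int, ...] = (0, 20, 40, 60, 80, 100)
    engine: object | None = None


@dataclass
class PairFeatureVector:
    pair_id: str
    pair_group: str
    features: dict[str, float]


CDS_ONLY_FEATURES = ("cub_distance", "gravy_margin")


class FeatureExtractor:
    """Computes feature vectors for all pairs of one annotated genome.

    Per-gene folding profiles are cached so each gene is folded once no
    matter how many pairs it participates in.
    """

    def __init__(
        self,
        annotation: PlastomeAnnotation,
        reference: Sequence[PlastomeAnnotation] | None = None,
        config: FeatureConfig | None = None,
    ) -> None:
        self.annotation = annotation
        self.reference = list(reference) if reference else []
        self.config = config or FeatureConfig()
        self._profiles: dict[str, FoldingProfile] = {}

    def gene_profile(self, gene: GeneModel) -> FoldingProfile:
        if gene.gene_id not in self._profiles:
            cfg = self.config
            region = extract_5utr_region(
                gene, self.annotation, cfg.upstream, cfg.downstream
            )
            self._profiles[gene.gene_id] = folding_profile(
                region,
                window=cfg.window,
                step=cfg.step,
                engine=cfg.engine,
                anchor=f"start-{cfg.upstream}..+{cfg.downstream} of {gene.gene_id}",
            )
        return self._profiles[gene.gene_id]

    def pair_features(self, pair: GenePair) -> PairFeatureVector:
        cfg = self.config
        feats: dict[str, float] = {}
        omitted: list[str] = []

        def attempt(name: str, fn) -> None:
            try:
                feats[name] = float(fn())
            except (FeatureUndefined, ValueError) as exc:
                omitted.append(name)
                logger.debug("%s: %s omitted (%s)", pair.pair_id, name, exc)

        seq = self.annotation.sequence
        feats["igs_length"] = float(intergenic_distance(pair))
        feats["same_strand"] = 1.0 if pair.same_strand else 0.0
        igs = pair.igs_sequence(self.annotation)
        if igs:
            attempt("igs_gc", lambda: gc_content(igs))
        else:
            omitted.append("igs_gc")  # no spacer exists for overlapping genes
        attempt("cds_gc_5", lambda: gc_content(pair.gene5.sequence(seq)))
        attempt("cds_gc_3", lambda: gc_content(pair.gene3.sequence(seq)))
        if "cds_gc_5" in feats and "cds_gc_3" in feats:
            feats["gc_margin"] = abs(feats["cds_gc_5"] - feats["cds_gc_3"])

        p5 = self.gene_profile(pair.gene5)
        p3 = self.gene_profile(pair.gene3)
        attempt("fold_profile_pearson", lambda: profile_similarity(p5, p3))
        m = min(len(p5), len(p3))
        if m > 0:
            margins = np.abs(p5.energies[:m] - p3.energies[:m])
            feats["fold_profile_mean_abs_margin"] = float(margins.mean())
            for pos in cfg.margin_positions:
                if pos < m:
                    feats[f"fold_margin_at_{pos}"] = float(margins[pos])
        if self.reference:
            attempt("pair_conservation", lambda: pair_conservation(pair, self.reference))

        if pair.pair_group == "CDS":
            if pair.gene5.canonical and pair.gene3.canonical:
                c5 = pair.gene5.sequence(seq)
                c3 = pair.gene3.sequence(seq)
                attempt("cub_distance", lambda: codon_usage_distance(c5, c3))
                attempt("gravy_margin", lambda: gravy_margin(c5, c3))
            else:
                omitted.extend(CDS_ONLY_FEATURES)

        applicable = len(feats) + len(omitted)
        if applicable and len(omitted) > applicable / 2:
            raise FeatureUndefined(
                f"{pair.pair_id}: {len(omitted)}/{applicable} features omitted"
            )
        return PairFeatureVector(pair.pair_id, pair.pair_group, feats)


def compute_pair_features(
    pair: GenePair,
    annotation: PlastomeAnnotation,
    reference: Sequence[PlastomeAnnotation] | None = None,
    config: FeatureConfig | None = None,
) -> PairFeatureVector:
    """One-shot convenience wrapper around :class:`FeatureExtractor`."""
    return FeatureExtractor(annotation, reference, config).pair_features(pair)


def feature_table(
    annotation: PlastomeAnnotation,
    pairs: Sequence[GenePair],
    reference: Sequence[PlastomeAnnotation] | None = None,
    config: FeatureConfig | None = None,
) -> pd.DataFrame:
    """Feature matrix for a list of pairs (rows indexed by pair_id).

    Missing features are NaN in memory and empty cells on disk — never 0.
    """
    extractor = FeatureExtractor(annotation, reference, config)
    rows = {}
    meta = {}
    for pair in pairs:
        vec = extractor.pair_features(pair)
        rows[vec.pair_id] = vec.features
        meta[vec.pair_id] = {
            "genome_id": annotation.genome_id,
            "gene5": pair.gene5.gene_id,
            "gene3": pair.gene3.gene_id,
            "pair_group": vec.pair_group,
        }
    df = pd.DataFrame.from_dict(rows, orient="index")
    meta_df = pd.DataFrame.from_dict(meta, orient="index")
    out = meta_df.join(df)
    out.index.name = "pair_id"
    return out


def write_feature_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", na_rep="")
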