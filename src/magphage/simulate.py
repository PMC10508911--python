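"""Synthetic gut-cohort generator with planted integrated prophages.

Emulates the data regime a MAG-based prophage census operates on: per-MAG
contig FASTA files with completeness-dependent contig loss, gene
annotations (viral / cellular / transposon / metabolic), viral-region
calls with boundary jitter and miss/false-call noise, and an infant
cohort abundance table (copies per million) with early/late timepoint
structure.  Every prophage planted is recorded in a ground-truth table so
recovery can be scored exactly.

Prophages are drawn from a cohort-level pool of phage genome templates.
Copies of a template planted into different MAGs carry a small per-copy
substitution load, so species-level clusters, multi-host vOTUs and
catalog overlap all have a known ground truth.  Some templates are
diverged variants of others (below the species ANI threshold but sharing
most protein content), which gives the gene-sharing genus graph
non-trivial structure.

All randomness flows from explicit integer seeds through
``numpy.random.default_rng``; identical inputs give identical outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import math
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .census import (
    GENE_COLUMNS,
    MAGRecord,
    REGION_CALL_COLUMNS,
    TAXONOMY_RANKS,
    ViralRegionCall,
    region_calls_to_frame,
)

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

INFANT_TIMEPOINTS = ("3w", "3m", "6m", "12m")

#: gut taxa the simulator samples MAG taxonomy from (weights sum to 1)
_TAXA: list[tuple[str, str, str, str, str, str, float]] = [
    ("Bacillota", "Clostridia", "Lachnospirales", "Lachnospiraceae", "Blautia", "Blautia wexlerae", 0.16),
    ("Bacillota", "Clostridia", "Oscillospirales", "Ruminococcaceae", "Faecalibacterium", "Faecalibacterium prausnitzii", 0.13),
    ("Bacillota", "Clostridia", "Oscillospirales", "Oscillospiraceae", "Oscillibacter", "Oscillibacter valericigenes", 0.09),
    ("Bacillota", "Bacilli", "Lactobacillales", "Enterococcaceae", "Enterococcus", "Enterococcus faecalis", 0.06),
    ("Bacillota", "Bacilli", "Lactobacillales", "Streptococcaceae", "Streptococcus", "Streptococcus salivarius", 0.06),
    ("Bacillota", "Negativicutes", "Veillonellales", "Veillonellaceae", "Veillonella", "Veillonella parvula", 0.06),
    ("Bacteroidota", "Bacteroidia", "Bacteroidales", "Bacteroidaceae", "Phocaeicola", "Phocaeicola vulgatus", 0.12),
    ("Bacteroidota", "Bacteroidia", "Bacteroidales", "Bacteroidaceae", "Bacteroides", "Bacteroides uniformis", 0.08),
    ("Bacteroidota", "Bacteroidia", "Bacteroidales", "Tannerellaceae", "Parabacteroides", "Parabacteroides distasonis", 0.05),
    ("Actinomycetota", "Actinomycetia", "Bifidobacteriales", "Bifidobacteriaceae", "Bifidobacterium", "Bifidobacterium longum", 0.09),
    ("Actinomycetota", "Coriobacteriia", "Coriobacteriales", "Coriobacteriaceae", "Collinsella", "Collinsella aerofaciens", 0.05),
    ("Pseudomonadota", "Gammaproteobacteria", "Enterobacterales", "Enterobacteriaceae", "Escherichia", "Escherichia coli", 0.05),
]

_KEGG_CATEGORIES = (
    "Amino acid metabolism", "Carbon metabolism", "Energy metabolism",
    "Galactose metabolism", "Fructose and mannose metabolism",
    "Starch and sucrose metabolism", "Pentose and glucuronate interconversions",
    "Transport", "Regulation",
)
_CAZY_FAMILIES = ("GT2", "GH13", "GH43", "GH5", "GH42", "PL1")


def sample_dist(spec: Sequence, rng: np.random.Generator) -> float:
    """Draw one value from a small distribution spec.

    Supported: ``("fixed", v)``, ``("poisson", mean)``,
    ``("uniform", lo, hi)``, ``("normal", mean, sd)``.
    """
    kind = spec[0]
    if kind == "fixed":
        return float(spec[1])
    if kind == "poisson":
        return float(rng.poisson(spec[1]))
    if kind == "uniform":
        return float(rng.uniform(spec[1], spec[2]))
    if kind == "normal":
        return float(rng.normal(spec[1], spec[2]))
    raise ValueError(f"unknown distribution spec {spec!r}")


@dataclass
class SimulationConfig:
    """Study conditions for one synthetic cohort.

    Defaults describe a desk-scale infant/parent gut cohort: each
    individual contributes a handful of MAGs with 70-100% completeness,
    prophages are planted at a Poisson rate with a GC composition shift
    against the host background, and region calls carry boundary jitter
    plus miss/false-call noise.  The per-genome prophage count and length
    distributions are simulator choices, not literature estimates; see
    docs/methods.md.
    """

    seed: int = 0
    n_individuals: int = 6
    timepoints: tuple[str, ...] = ("3w", "3m", "6m", "12m", "mother", "father")
    n_mags_per_individual: int = 5
    host_genome_length: int = 300_000
    host_gc: float = 0.45
    prophage_count_dist: tuple = ("poisson", 1.5)
    prophage_length_dist: tuple = ("uniform", 15_000, 40_000)
    composition_shift: float = 0.08
    gene_length_dist: tuple = ("uniform", 600, 1_200)
    intergenic_gap: int = 60
    viral_gene_density_inside: float = 0.85
    viral_gene_rate_outside: float = 0.02
    transposon_rate: float = 0.01
    metabolic_gene_rate_inside: float = 0.08
    completeness_range: tuple[float, float] = (70.0, 100.0)
    contamination_range: tuple[float, float] = (0.0, 2.0)
    fragment_length_dist: tuple = ("uniform", 30_000, 80_000)
    boundary_jitter_sd: float = 200.0
    region_fnr: float = 0.1
    region_fpr: float = 0.05
    n_phage_templates: int = 25
    template_mutation_rate: float = 0.02
    related_template_prob: float = 0.3
    related_template_divergence: float = 0.08
    # prophage loci concentrate in the poorly-recoverable portion of the
    # genome (mobile/repeat-rich regions), so incomplete bins lose them
    # preferentially -- the technical-limitation regime the census assumes
    prophage_loss_bias: float = 1.0
    prophage_loss_tail: float = 0.05

    def validate(self) -> None:
        fractions = {
            "composition_shift": self.composition_shift,
            "viral_gene_density_inside": self.viral_gene_density_inside,
            "viral_gene_rate_outside": self.viral_gene_rate_outside,
            "transposon_rate": self.transposon_rate,
            "metabolic_gene_rate_inside": self.metabolic_gene_rate_inside,
            "region_fnr": self.region_fnr,
            "template_mutation_rate": self.template_mutation_rate,
            "prophage_loss_bias": self.prophage_loss_bias,
            "prophage_loss_tail": self.prophage_loss_tail,
        }
        for name, value in fractions.items():
            if not 0.0 <= value <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {value}")
        if self.composition_shift > 0.5:
            raise ValueError("composition_shift must be in [0, 0.5]")
        lo, hi = self.completeness_range
        if not (0 < lo <= hi <= 100):
            raise ValueError(f"completeness_range must lie within (0, 100], got {self.completeness_range}")
        clo, chi = self.contamination_range
        if not (0 <= clo <= chi <= 5):
            raise ValueError(f"contamination_range must lie within [0, 5], got {self.contamination_range}")
        for name in ("host_genome_length", "n_individuals", "n_mags_per_individual"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        sum_inside = (
            self.transposon_rate + self.viral_gene_density_inside + self.metabolic_gene_rate_inside
        )
        if sum_inside > 1.0:
            raise ValueError("per-gene category probabilities inside prophages exceed 1")

    def hash(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()


@dataclass
class TruthRecord:
    """Ground truth for one planted prophage.

    ``genome_start``/``genome_end`` are coordinates on the modified
    (post-insertion) source genome; ``true_start``/``true_end`` are contig
    coordinates after fragmentation, set only when the whole interval
    survived on one retained contig.
    """

    prophage_id: str
    template_id: str
    genome_start: int
    genome_end: int
    mag_id: str = ""
    contig_id: str = ""
    true_start: int | None = None
    true_end: int | None = None
    survived_fragmentation: bool = False

    @property
    def length(self) -> int:
        return self.genome_end - self.genome_start


@dataclass
class PhageTemplate:
    """A phage genome shared across the cohort, with a fixed gene layout."""

    template_id: str
    sequence: str
    genes: list[dict]  # start/end/strand/category/amg_score/kegg_category/cazy_family (template coords)


def random_sequence(length: int, gc: float, rng: np.random.Generator) -> str:
    if length <= 0:
        raise ValueError(f"sequence length must be positive, got {length}")
    if not 0 < gc < 1:
        raise ValueError(f"GC fraction must be in (0, 1), got {gc}")
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    idx = rng.choice(4, size=length, p=p)
    return _BASES[idx].tobytes().decode("ascii")


def generate_host_genome(length: int, gc: float, seed: int) -> str:
    """Generate a random host chromosome with the requested GC content."""
    return random_sequence(length, gc, np.random.default_rng(seed))


def gc_content(sequence: str) -> float:
    if not sequence:
        return 0.0
    return (sequence.count("G") + sequence.count("C")) / len(sequence)


def mutate_sequence(sequence: str, rate: float, rng: np.random.Generator) -> str:
    """Apply random substitutions at the given per-base rate."""
    if rate <= 0:
        return sequence
    n = rng.binomial(len(sequence), rate)
    if n == 0:
        return sequence
    positions = rng.choice(len(sequence), size=n, replace=False)
    buf = bytearray(sequence, "ascii")
    alphabet = b"ACGT"
    for pos in positions:
        old = buf[pos]
        choices = [b for b in alphabet if b != old]
        buf[pos] = choices[rng.integers(0, len(choices))]
    return buf.decode("ascii")


def _tile_genes(
    seg_start: int,
    seg_end: int,
    inside_prophage: bool,
    config: SimulationConfig,
    rng: np.random.Generator,
) -> list[dict]:
    """Tile one genome segment with annotated genes (coords are absolute)."""
    genes: list[dict] = []
    pos = seg_start + config.intergenic_gap
    while True:
        glen = max(90, int(sample_dist(config.gene_length_dist, rng)))
        if pos + glen > seg_end:
            break
        genes.append(_draw_gene(pos, pos + glen, inside_prophage, config, rng))
        pos += glen + config.intergenic_gap
    return genes


def _draw_gene(
    start: int, end: int, inside_prophage: bool,
    config: SimulationConfig, rng: np.random.Generator,
) -> dict:
    u = rng.random()
    amg_score: float = math.nan
    kegg = ""
    cazy = ""
    if inside_prophage:
        if u < config.transposon_rate:
            category = "transposon"
        elif u < config.transposon_rate + config.viral_gene_density_inside:
            category = "viral"
        elif u < (config.transposon_rate + config.viral_gene_density_inside
                  + config.metabolic_gene_rate_inside):
            category = "metabolic"
            amg_score = int(rng.integers(1, 6))
            kegg = _KEGG_CATEGORIES[rng.integers(0, len(_KEGG_CATEGORIES))]
            if rng.random() < 0.25:
                cazy = _CAZY_FAMILIES[rng.integers(0, len(_CAZY_FAMILIES))]
        else:
            category = "cellular"
    else:
        if u < config.transposon_rate:
            category = "transposon"
        elif u < config.transposon_rate + config.viral_gene_rate_outside:
            category = "viral"
        else:
            category = "cellular"
    return {
        "start": start, "end": end,
        "strand": "+" if rng.random() < 0.5 else "-",
        "category": category, "amg_score": amg_score,
        "kegg_category": kegg, "cazy_family": cazy,
    }


def make_template_pool(config: SimulationConfig, rng: np.random.Generator) -> list[PhageTemplate]:
    """Build the cohort's shared phage templates with fixed gene layouts."""
    gc = min(0.95, max(0.05, config.host_gc + config.composition_shift))
    templates: list[PhageTemplate] = []
    for i in range(config.n_phage_templates):
        tid = f"T{i:03d}"
        if templates and rng.random() < config.related_template_prob:
            parent = templates[rng.integers(0, len(templates))]
            seq = mutate_sequence(parent.sequence, config.related_template_divergence, rng)
            genes = [dict(g) for g in parent.genes]
        else:
            length = int(np.clip(sample_dist(config.prophage_length_dist, rng), 5_000, 100_000))
            seq = random_sequence(length, gc, rng)
            genes = _tile_genes(0, length, True, config, rng)
        templates.append(PhageTemplate(tid, seq, genes))
    return templates


def plant_prophages(
    genome: str,
    config: SimulationConfig,
    seed: int,
    templates: Sequence[PhageTemplate] | None = None,
) -> tuple[str, list[TruthRecord], pd.DataFrame]:
    """Insert prophages into a host genome and annotate all genes.

    Each prophage is a contiguous insertion (never overlapping another)
    whose GC is shifted from the host background by
    ``config.composition_shift``.  When ``templates`` is given, prophages
    are mutated copies of pool templates and reuse the template gene
    layout; otherwise fresh random prophages are generated and tiled.
    Host segments are tiled with background genes.  Truth coordinates
    refer to the modified sequence; the returned gene table uses
    contig_id ``"genome"`` until fragmentation remaps it.
    """
    if not genome:
        raise ValueError("genome must be non-empty")
    rng = np.random.default_rng(seed)
    n = max(0, int(sample_dist(config.prophage_count_dist, rng)))

    inserts: list[tuple[str, str, list[dict]]] = []  # (template_id, seq, genes rel. to insert)
    for i in range(n):
        if templates:
            tpl = templates[rng.integers(0, len(templates))]
            seq = mutate_sequence(tpl.sequence, config.template_mutation_rate, rng)
            inserts.append((tpl.template_id, seq, [dict(g) for g in tpl.genes]))
        else:
            length = int(np.clip(sample_dist(config.prophage_length_dist, rng), 5_000, 100_000))
            gc = min(0.95, max(0.05, gc_content(genome) + config.composition_shift))
            seq = random_sequence(length, gc, rng)
            inserts.append((f"denovo{i}", seq, _tile_genes(0, length, True, config, rng)))

    total = sum(len(s) for _, s, _ in inserts)
    if total > len(genome):
        raise ValueError(
            f"requested total prophage length {total} exceeds genome length {len(genome)}"
        )
    if n == 0:
        genes = _tile_genes(0, len(genome), False, config, rng)
        return genome, [], _genes_frame(genes)

    # insertion points strictly inside the genome, so every prophage has
    # host sequence on both sides before fragmentation
    positions = np.sort(rng.choice(np.arange(1, len(genome)), size=n, replace=False))
    parts: list[str] = []
    truths: list[TruthRecord] = []
    all_genes: list[dict] = []
    prev = 0
    offset = 0
    for i, pos in enumerate(positions):
        host_seg = genome[prev:pos]
        all_genes.extend(_tile_genes(prev + offset, pos + offset, False, config, rng))
        parts.append(host_seg)
        template_id, seq, tgenes = inserts[i]
        start = pos + offset
        parts.append(seq)
        truths.append(TruthRecord(
            prophage_id=f"pp{i:03d}", template_id=template_id,
            genome_start=start, genome_end=start + len(seq),
        ))
        for g in tgenes:
            g = dict(g)
            g["start"] += start
            g["end"] += start
            all_genes.append(g)
        offset += len(seq)
        prev = pos
    all_genes.extend(_tile_genes(prev + offset, len(genome) + offset, False, config, rng))
    parts.append(genome[prev:])
    all_genes.sort(key=lambda g: g["start"])
    return "".join(parts), truths, _genes_frame(all_genes)


def _genes_frame(genes: list[dict], mag_id: str = "", contig_id: str = "genome") -> pd.DataFrame:
    frame = pd.DataFrame(genes, columns=[c for c in GENE_COLUMNS if c not in
                                         ("mag_id", "contig_id", "gene_id")])
    frame.insert(0, "mag_id", mag_id)
    frame.insert(1, "contig_id", contig_id)
    frame.insert(2, "gene_id", [f"g{i:05d}" for i in range(len(frame))])
    return frame[GENE_COLUMNS]


def _retention_order(
    contigs: Sequence[tuple[int, int]],
    prophage_intervals: Sequence[tuple[int, int]],
    rng: np.random.Generator,
    loss_bias: float,
    loss_tail: float,
) -> np.ndarray:
    """Priority order in which contigs enter the bin.

    Contigs are retained in descending-priority order until the
    completeness target is met.  Host contigs draw a uniform priority;
    a contig carrying a prophage draws, with probability ``loss_bias``,
    its priority from the bottom ``loss_tail`` of the range instead --
    prophage loci sit in the poorly-recoverable portion of the genome, so
    incomplete bins lose them preferentially and flanked-prophage
    recovery rises steeply with completeness.  Priorities are drawn once
    per contig from a stream that does not depend on the completeness
    target, so raising completeness always retains a superset.
    """
    u = rng.random(len(contigs))
    v = rng.random(len(contigs))
    keys = u.copy()
    for i, (gs, ge) in enumerate(contigs):
        has_prophage = any(gs <= s and e <= ge for s, e in prophage_intervals)
        if has_prophage and v[i] < loss_bias:
            keys[i] = u[i] * loss_tail
    return np.argsort(-keys, kind="stable")


def remap_truths_to_contigs(
    truths: Sequence[TruthRecord],
    pieces: Sequence[tuple[str, int, int]],
    mag_id: str,
) -> list[TruthRecord]:
    """Remap genome-coordinate truths onto retained contig pieces.

    ``pieces`` are ``(contig_id, genome_start, genome_end)`` intervals of
    the modified genome retained as contigs.  A prophage survives
    fragmentation only if its whole interval lies strictly within one
    piece, i.e. with at least 1 bp of host flank on each side — the
    flanked-prophage requirement the census applies.  A prophage split
    across pieces, partially lost, or touching a contig edge is
    non-surviving.
    """
    remapped: list[TruthRecord] = []
    for t in truths:
        hit = next(
            (p for p in pieces if p[1] < t.genome_start and t.genome_end < p[2]),
            None,
        )
        if hit is None:
            remapped.append(replace(t, mag_id=mag_id, contig_id="",
                                    true_start=None, true_end=None,
                                    survived_fragmentation=False))
        else:
            cid, gs, _ = hit
            remapped.append(replace(
                t, mag_id=mag_id, contig_id=cid,
                true_start=t.genome_start - gs, true_end=t.genome_end - gs,
                survived_fragmentation=True,
            ))
    return remapped


def fragment_to_mag(
    genome: str,
    truths: Sequence[TruthRecord],
    completeness: float,
    contamination: float,
    fragment_length_dist: tuple = ("uniform", 30_000, 80_000),
    seed: int = 0,
    genes: pd.DataFrame | None = None,
    mag_id: str = "MAG1",
    config: SimulationConfig | None = None,
) -> tuple[MAGRecord, list[TruthRecord], pd.DataFrame]:
    """Fragment a genome into a bin with completeness-dependent contig loss.

    The genome is cut into contigs (cut points are pushed off planted
    prophage intervals, emulating the contiguous assembly of an integrated
    prophage), contigs are retained in priority order until
    ``completeness``% of the bases are kept (the last contig is truncated
    to hit the target), and contamination is added as foreign contigs
    totalling ~``contamination``% of the retained bases.  Retention
    priorities are biased against prophage-bearing contigs (see
    :func:`_retention_order`), so flanked-prophage recovery rises steeply
    with completeness, as observed in real MAG collections.  Truths and
    genes are remapped to contig coordinates; genes cut by a boundary are
    dropped.  For a fixed seed the cut points and retention priorities do
    not depend on ``completeness``, so raising completeness never loses a
    surviving prophage.
    """
    if not 0 < completeness <= 100:
        raise ValueError(f"completeness must be in (0, 100], got {completeness}")
    if not 0 <= contamination <= 5:
        raise ValueError(f"contamination must be in [0, 5], got {contamination}")
    config = config or SimulationConfig()
    rng = np.random.default_rng(seed)
    L = len(genome)

    boundaries = [0]
    pos = 0
    intervals = sorted((t.genome_start, t.genome_end) for t in truths)
    while pos < L:
        pos += max(1_000, int(sample_dist(fragment_length_dist, rng)))
        for gs, ge in intervals:
            if gs - 1 < pos < ge + 1:
                pos = ge + 1  # never cut inside or at the edge of a prophage
        pos = min(pos, L)
        if pos > boundaries[-1]:
            boundaries.append(pos)
    contigs = [(boundaries[i], boundaries[i + 1]) for i in range(len(boundaries) - 1)]

    order = _retention_order(contigs, intervals, rng,
                             config.prophage_loss_bias, config.prophage_loss_tail)
    target = completeness / 100.0 * L
    kept: list[tuple[int, int]] = []
    total = 0.0
    for idx in order:
        gs, ge = contigs[idx]
        clen = ge - gs
        if total + clen <= target:
            kept.append((gs, ge))
            total += clen
        else:
            gap = int(round(target - total))
            if gap >= 1:
                kept.append((gs, gs + gap))
                total += gap
            break
    kept.sort()
    pieces = [(f"{mag_id}_c{i:03d}", gs, ge) for i, (gs, ge) in enumerate(kept)]
    contig_seqs = {cid: genome[gs:ge] for cid, gs, ge in pieces}

    # contamination: foreign-genome contigs appended to the bin
    retained_bp = sum(ge - gs for _, gs, ge in pieces)
    foreign_target = contamination / 100.0 * retained_bp
    foreign_genes: list[dict] = []
    acc = 0
    i = 0
    while acc < foreign_target - 1:
        flen = min(max(1_000, int(sample_dist(fragment_length_dist, rng))),
                   int(round(foreign_target)) - acc)
        if flen < 1:
            break
        cid = f"{mag_id}_f{i:03d}"
        contig_seqs[cid] = random_sequence(flen, 0.55, rng)
        for g in _tile_genes(0, flen, False, config, rng):
            g["contig_id"] = cid
            foreign_genes.append(g)
        acc += flen
        i += 1

    remapped_truths = remap_truths_to_contigs(truths, pieces, mag_id)

    gene_rows: list[dict] = []
    if genes is not None and not genes.empty:
        piece_starts = np.array([gs for _, gs, _ in pieces])
        piece_ends = np.array([ge for _, _, ge in pieces])
        piece_ids = [cid for cid, _, _ in pieces]
        for row in genes.itertuples(index=False):
            j = np.searchsorted(piece_starts, row.start, side="right") - 1
            if j >= 0 and row.start >= piece_starts[j] and row.end <= piece_ends[j]:
                g = row._asdict()
                g["contig_id"] = piece_ids[j]
                g["start"] = int(row.start - piece_starts[j])
                g["end"] = int(row.end - piece_starts[j])
                gene_rows.append(g)
    for g in foreign_genes:
        gene_rows.append({**g, "mag_id": mag_id, "gene_id": ""})
    genes_out = pd.DataFrame(gene_rows, columns=GENE_COLUMNS) if gene_rows else \
        pd.DataFrame(columns=GENE_COLUMNS)
    if not genes_out.empty:
        genes_out = genes_out.sort_values(["contig_id", "start"], kind="stable").reset_index(drop=True)
        genes_out["mag_id"] = mag_id
        genes_out["gene_id"] = [f"{mag_id}_g{i:05d}" for i in range(len(genes_out))]

    mag = MAGRecord(
        mag_id=mag_id, contigs=contig_seqs,
        completeness=completeness, contamination=contamination,
    )
    return mag, remapped_truths, genes_out


def emit_region_calls(
    truths: Sequence[TruthRecord],
    contig_lengths: Mapping[str, int],
    jitter_sd: float = 200.0,
    fnr: float = 0.1,
    fpr_per_mag: float = 0.05,
    seed: int = 0,
    mag_id: str = "",
) -> list[ViralRegionCall]:
    """Emit noisy viral-region calls for one MAG's surviving truths.

    Each surviving truth is reported with probability ``1 - fnr``, with
    boundaries perturbed by Gaussian jitter (clipped to the contig).
    False-positive calls are added at a Poisson rate of ``fpr_per_mag``
    on host intervals that do not overlap a planted prophage.  Host-flank
    flags are true exactly when >= 1 bp of contig remains on that side.
    """
    rng = np.random.default_rng(seed)
    calls: list[ViralRegionCall] = []
    survived = [t for t in truths if t.survived_fragmentation]
    occupied: dict[str, list[tuple[int, int]]] = {}
    for t in survived:
        occupied.setdefault(t.contig_id, []).append((t.true_start, t.true_end))
    for t in survived:
        if rng.random() < fnr:
            continue
        clen = contig_lengths[t.contig_id]
        start, end = t.true_start, t.true_end
        if jitter_sd > 0:
            start = int(round(start + rng.normal(0, jitter_sd)))
            end = int(round(end + rng.normal(0, jitter_sd)))
        start = int(np.clip(start, 0, clen - 1))
        end = int(np.clip(end, start + 1, clen))
        calls.append(ViralRegionCall(
            contig_id=t.contig_id, start=start, end=end,
            left_flank_present=start > 0, right_flank_present=end < clen,
            caller_label="prophage" if (start > 0 or end < clen) else "viral",
            mag_id=mag_id or t.mag_id,
        ))
    n_fp = rng.poisson(fpr_per_mag)
    contig_ids = sorted(contig_lengths)
    if contig_ids:
        weights = np.array([contig_lengths[c] for c in contig_ids], dtype=float)
        weights /= weights.sum()
        for _ in range(n_fp):
            for _attempt in range(20):
                cid = contig_ids[rng.choice(len(contig_ids), p=weights)]
                clen = contig_lengths[cid]
                flen = min(int(rng.uniform(8_000, 20_000)), max(2, clen - 1))
                start = int(rng.integers(0, max(1, clen - flen)))
                end = start + flen
                if all(end <= s or start >= e for s, e in occupied.get(cid, [])):
                    calls.append(ViralRegionCall(
                        contig_id=cid, start=start, end=end,
                        left_flank_present=start > 0,
                        right_flank_present=end < clen,
                        caller_label="prophage",
                        mag_id=mag_id,
                    ))
                    break
    return calls


@dataclass
class CohortData:
    """An in-memory synthetic cohort plus its ground truth."""

    config: SimulationConfig
    templates: list[PhageTemplate]
    mags: list[MAGRecord]
    truths: list[TruthRecord]
    genes: pd.DataFrame
    region_calls: pd.DataFrame
    metadata: pd.DataFrame
    abundance: pd.DataFrame
    confirmations: pd.DataFrame
    manifest: dict

    def write(self, out_dir: str | Path) -> Path:
        """Write the cohort dataset (FASTA + TSVs + manifest) to disk."""
        out = Path(out_dir)
        try:
            (out / "mags").mkdir(parents=True, exist_ok=True)
        except OSError as exc:
            raise OSError(f"cannot create output directory {out}: {exc}") from exc
        from .io import write_fasta

        for mag in self.mags:
            write_fasta(mag.contigs, out / "mags" / f"{mag.mag_id}.fasta")
        self.genes.to_csv(out / "genes.tsv", sep="\t", index=False)
        self.region_calls.to_csv(out / "region_calls.tsv", sep="\t", index=False)
        self.metadata.to_csv(out / "metadata.tsv", sep="\t", index=False)
        self.abundance.to_csv(out / "abundance.tsv", sep="\t", index=False)
        self.confirmations.to_csv(out / "confirmations.tsv", sep="\t", index=False)
        truth_frame = pd.DataFrame([dataclasses.asdict(t) for t in self.truths])
        truth_frame.to_csv(out / "truth_prophages.tsv", sep="\t", index=False)
        (out / "manifest.json").write_text(json.dumps(self.manifest, indent=2, sort_keys=True))
        return out


def simulate_cohort(config: SimulationConfig, out_dir: str | Path | None = None) -> CohortData:
    """Generate a full labelled cohort; optionally write it to disk."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    templates = make_template_pool(config, rng)
    taxa_weights = np.array([t[6] for t in _TAXA])
    taxa_weights /= taxa_weights.sum()

    mags: list[MAGRecord] = []
    truths: list[TruthRecord] = []
    gene_frames: list[pd.DataFrame] = []
    call_rows: list[pd.DataFrame] = []
    meta_rows: list[dict] = []
    abund_rows: list[dict] = []
    trend_by_mag: dict[str, str] = {}

    for i in range(config.n_individuals):
        ind = f"ind{i:02d}"
        for j in range(config.n_mags_per_individual):
            mag_id = f"{ind}_m{j:02d}"
            origin = ("infant", "mother", "father")[
                rng.choice(3, p=[2 / 3, 1 / 6, 1 / 6])
            ]
            taxon = _TAXA[rng.choice(len(_TAXA), p=taxa_weights)]
            gc = float(np.clip(rng.normal(config.host_gc, 0.02), 0.25, 0.7))
            genome = random_sequence(config.host_genome_length, gc, rng)
            modified, mag_truths, mag_genes = plant_prophages(
                genome, config, seed=int(rng.integers(0, 2**31)), templates=templates,
            )
            completeness = float(rng.uniform(*config.completeness_range))
            contamination = float(rng.uniform(*config.contamination_range))
            mag, mag_truths, mag_genes = fragment_to_mag(
                modified, mag_truths, completeness, contamination,
                config.fragment_length_dist, seed=int(rng.integers(0, 2**31)),
                genes=mag_genes, mag_id=mag_id, config=config,
            )
            mag.individual_id = ind
            mag.cohort_group = {"infant": "Unassigned", "mother": "Maternal",
                                "father": "Paternal"}[origin]
            mag.taxonomy = dict(zip(TAXONOMY_RANKS, ("Bacteria",) + taxon[:6]))
            calls = emit_region_calls(
                mag_truths, mag.contig_lengths,
                jitter_sd=config.boundary_jitter_sd, fnr=config.region_fnr,
                fpr_per_mag=config.region_fpr,
                seed=int(rng.integers(0, 2**31)), mag_id=mag_id,
            )
            mags.append(mag)
            truths.extend(mag_truths)
            gene_frames.append(mag_genes)
            call_rows.append(region_calls_to_frame(calls))
            meta_rows.append({
                "mag_id": mag_id, "individual_id": ind, "origin": origin,
                "cohort_group": mag.cohort_group,
                "completeness": round(completeness, 2),
                "contamination": round(contamination, 2),
                **mag.taxonomy,
                "n_contigs": len(mag.contigs), "total_bp": mag.total_bp,
            })

            # abundance structure: infant MAGs follow an early- or
            # late-dominant trajectory; parental MAGs appear in one sample
            base = float(rng.lognormal(math.log(500.0), 1.0))
            if origin == "infant":
                trend = "Early" if rng.random() < 0.5 else "Late"
                trend_by_mag[mag_id] = trend
                mult = (2.0, 1.4, 0.35, 0.2) if trend == "Early" else (0.2, 0.35, 1.4, 2.0)
                for tp, m in zip(INFANT_TIMEPOINTS, mult):
                    abund_rows.append({
                        "sample_id": f"{ind}_{tp}", "mag_id": mag_id,
                        "cpm": base * m * float(rng.lognormal(0, 0.25)),
                    })
            else:
                abund_rows.append({
                    "sample_id": f"{ind}_{origin}", "mag_id": mag_id,
                    "cpm": base * float(rng.lognormal(0, 0.25)),
                })

    genes = pd.concat(gene_frames, ignore_index=True) if gene_frames else \
        pd.DataFrame(columns=GENE_COLUMNS)
    region_calls = pd.concat(call_rows, ignore_index=True) if call_rows else \
        pd.DataFrame(columns=REGION_CALL_COLUMNS)
    metadata = pd.DataFrame(meta_rows)
    abundance = pd.DataFrame(abund_rows, columns=["sample_id", "mag_id", "cpm"])
    if not abundance.empty:
        totals = abundance.groupby("sample_id")["cpm"].transform("sum")
        abundance["cpm"] = abundance["cpm"] / totals * 1_000_000.0

    # external-confirmation stand-in for CAZy-annotated metabolic genes
    cazy = genes[(genes["category"] == "metabolic") & (genes["cazy_family"] != "")]
    confirmations = pd.DataFrame({
        "gene_id": cazy["gene_id"].to_numpy(),
        "confirmation_probability": np.round(rng.uniform(55, 100, size=len(cazy)), 1),
    })

    manifest = {
        "seed": config.seed,
        "config_hash": config.hash(),
        "n_individuals": config.n_individuals,
        "n_mags": len(mags),
        "n_planted_prophages": len(truths),
        "n_surviving_prophages": sum(t.survived_fragmentation for t in truths),
        "true_trend_by_mag": trend_by_mag,
    }
    cohort = CohortData(
        config=config, templates=templates, mags=mags, truths=truths,
        genes=genes, region_calls=region_calls, metadata=metadata,
        abundance=abundance, confirmations=confirmations, manifest=manifest,
    )
    if out_dir is not None:
        cohort.write(out_dir)
    return cohort


def simulate_detection_labels(
    n_mags: int, config: SimulationConfig, seed: int
) -> pd.DataFrame:
    """Fast interval-only cohort: completeness vs surviving-prophage counts.

    Replays the planting and fragmentation interval arithmetic without
    generating sequence, for statistical studies of the
    completeness-driven prophage-loss mechanism.  Returns one row per MAG
    with ``completeness`` and ``n_surviving`` (prophages whose whole
    interval lies on one retained contig); a MAG is a detected lysogen
    when ``n_surviving >= 1``.
    """
    rng = np.random.default_rng(seed)
    rows = []
    L = config.host_genome_length
    for i in range(n_mags):
        n = max(0, int(sample_dist(config.prophage_count_dist, rng)))
        lengths = [int(np.clip(sample_dist(config.prophage_length_dist, rng), 5_000, 100_000))
                   for _ in range(n)]
        positions = np.sort(rng.choice(np.arange(1, L), size=n, replace=False)) if n \
            else np.array([], dtype=int)
        offset = 0
        intervals = []
        for pos, plen in zip(positions, lengths):
            intervals.append((pos + offset, pos + offset + plen))
            offset += plen
        total_len = L + offset
        boundaries = [0]
        pos = 0
        while pos < total_len:
            pos += max(1_000, int(sample_dist(config.fragment_length_dist, rng)))
            for gs, ge in intervals:
                if gs - 1 < pos < ge + 1:
                    pos = ge + 1
            pos = min(pos, total_len)
            if pos > boundaries[-1]:
                boundaries.append(pos)
        contigs = [(boundaries[k], boundaries[k + 1]) for k in range(len(boundaries) - 1)]
        order = _retention_order(contigs, intervals, rng,
                                 config.prophage_loss_bias, config.prophage_loss_tail)
        completeness = float(rng.uniform(*config.completeness_range))
        target = completeness / 100.0 * total_len
        kept = []
        total = 0.0
        for idx in order:
            gs, ge = contigs[idx]
            if total + (ge - gs) <= target:
                kept.append((gs, ge))
                total += ge - gs
            else:
                gap = int(round(target - total))
                if gap >= 1:
                    kept.append((gs, gs + gap))
                break
        n_surv = sum(
            any(gs < s and e < ge for gs, ge in kept) for s, e in intervals
        )
        rows.append({"mag_id": f"m{i:04d}", "completeness": completeness,
                     "n_planted": n, "n_surviving": n_surv})
    return pd.DataFrame(rows)
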