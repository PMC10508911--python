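"""Extraction and quality screening of integrated prophages from MAG contigs.

A MAG (metagenome-assembled genome) is a bin of contigs representing one
bacterial genome, with CheckM-style completeness and contamination
estimates.  Viral-region calls on its contigs (from an external prophage
detector, or from :func:`detect_viral_regions`) are trimmed to remove host
flanks, scored with a transparent gene-content quality stand-in, and passed
through the retention rules used for census-grade prophage catalogs:
length above 10 kb, host sequence flanking the call on both sides, and
phage-gene evidence.  A MAG carrying at least one retained prophage is a
lysogen.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import pandas as pd

COHORT_GROUPS = ("Early", "Late", "Maternal", "Paternal", "Unassigned")
QUALITY_TIERS = ("Complete", "High", "Medium", "Low", "NotDetermined")
TAXONOMY_RANKS = ("domain", "phylum", "class", "order", "family", "genus", "species")

#: columns of the gene-annotation table used throughout the package
GENE_COLUMNS = [
    "mag_id", "contig_id", "gene_id", "start", "end", "strand",
    "category", "amg_score", "kegg_category", "cazy_family",
]
GENE_CATEGORIES = ("viral", "cellular", "transposon", "metabolic", "unknown")

REGION_CALL_COLUMNS = [
    "mag_id", "contig_id", "start", "end",
    "left_flank_present", "right_flank_present", "caller_label",
]


@dataclass
class MAGRecord:
    """One genome bin: contigs plus bin-level quality and taxonomy."""

    mag_id: str
    contigs: dict[str, str]
    completeness: float
    contamination: float
    individual_id: str = ""
    cohort_group: str = "Unassigned"
    taxonomy: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.cohort_group not in COHORT_GROUPS:
            raise ValueError(f"unknown cohort group {self.cohort_group!r}")
        if len(set(self.contigs)) != len(self.contigs):
            raise ValueError("contig ids must be unique within a MAG")

    @property
    def contig_lengths(self) -> dict[str, int]:
        return {cid: len(seq) for cid, seq in self.contigs.items()}

    @property
    def total_bp(self) -> int:
        return sum(len(s) for s in self.contigs.values())


@dataclass(frozen=True)
class ViralRegionCall:
    """A predicted integrated-prophage interval on a contig.

    Coordinates are 0-based half-open.  Flank flags record whether host
    sequence remains on each side of the interval (>= 1 bp of contig).
    """

    contig_id: str
    start: int
    end: int
    left_flank_present: bool
    right_flank_present: bool
    caller_label: str = "prophage"
    mag_id: str = ""

    def __post_init__(self) -> None:
        if not 0 <= self.start < self.end:
            raise ValueError(f"invalid region interval [{self.start}, {self.end})")
        if self.caller_label not in ("prophage", "viral", "none"):
            raise ValueError(f"unknown caller label {self.caller_label!r}")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class ProphageRecord:
    """A trimmed prophage with gene-content quality evidence."""

    prophage_id: str
    mag_id: str
    contig_id: str
    start: int
    end: int
    quality_tier: str = "NotDetermined"
    viral_gene_count: int = 0
    cellular_gene_count: int = 0
    total_gene_count: int = 0
    non_viral_score: float = 0.0
    left_flank_present: bool = True
    right_flank_present: bool = True
    caller_label: str = "prophage"

    @property
    def length(self) -> int:
        return self.end - self.start


def region_calls_to_frame(calls: Iterable[ViralRegionCall]) -> pd.DataFrame:
    rows = [
        (c.mag_id, c.contig_id, c.start, c.end,
         c.left_flank_present, c.right_flank_present, c.caller_label)
        for c in calls
    ]
    return pd.DataFrame(rows, columns=REGION_CALL_COLUMNS)


def frame_to_region_calls(frame: pd.DataFrame) -> list[ViralRegionCall]:
    return [
        ViralRegionCall(
            contig_id=row.contig_id, start=int(row.start), end=int(row.end),
            left_flank_present=bool(row.left_flank_present),
            right_flank_present=bool(row.right_flank_present),
            caller_label=str(row.caller_label), mag_id=str(row.mag_id),
        )
        for row in frame.itertuples(index=False)
    ]


def detect_viral_regions(
    genes: pd.DataFrame,
    contig_length: int,
    window_genes: int = 10,
    min_viral_density: float = 0.8,
    min_run_genes: int = 5,
) -> list[ViralRegionCall]:
    """Call candidate prophage regions from gene annotations on one contig.

    Sliding windows of ``window_genes`` consecutive genes are scored by
    their fraction of viral-annotated genes; genes covered by any window at
    or above ``min_viral_density`` form candidate runs, and maximal runs of
    at least ``min_run_genes`` genes are reported, trimmed to the first and
    last viral gene of the run.  Runs touching the first/last gene of the
    contig are extended to the contig end, so a fully viral contig yields a
    call with no host flanks.  This is a transparent stand-in for an
    external prophage detector, usable when only annotations are available.
    """
    if genes.empty:
        return []
    starts = genes["start"].to_numpy()
    if (starts[1:] < starts[:-1]).any():
        raise ValueError("gene annotations must be sorted by start coordinate")
    is_viral = (genes["category"] == "viral").to_numpy()
    n = len(genes)
    w = min(window_genes, n)
    marked = [False] * n
    for i in range(n - w + 1):
        if is_viral[i:i + w].mean() >= min_viral_density:
            for j in range(i, i + w):
                marked[j] = True
    calls: list[ViralRegionCall] = []
    ends = genes["end"].to_numpy()
    for flag, group in itertools.groupby(range(n), key=lambda i: marked[i]):
        idx = list(group)
        if not flag or len(idx) < min_run_genes:
            continue
        viral_idx = [i for i in idx if is_viral[i]]
        if not viral_idx:
            continue
        first, last = viral_idx[0], viral_idx[-1]
        start = 0 if idx[0] == 0 else int(starts[first])
        end = contig_length if idx[-1] == n - 1 else int(ends[last])
        calls.append(ViralRegionCall(
            contig_id=str(genes["contig_id"].iloc[0]),
            start=start, end=end,
            left_flank_present=start > 0,
            right_flank_present=end < contig_length,
            caller_label="prophage" if (start > 0 or end < contig_length) else "viral",
            mag_id=str(genes["mag_id"].iloc[0]) if "mag_id" in genes else "",
        ))
    return calls


def merge_overlapping_calls(
    calls: Sequence[ViralRegionCall], contig_lengths: Mapping[str, int]
) -> list[ViralRegionCall]:
    """Merge strictly overlapping calls on the same contig by interval union.

    Flank flags are recomputed from the merged coordinates; the merged call
    is labelled ``prophage`` unless every constituent was labelled ``none``.
    Prevents double-counting of bases in downstream prophage-content sums.
    """
    merged: list[ViralRegionCall] = []
    by_contig: dict[str, list[ViralRegionCall]] = {}
    for c in calls:
        by_contig.setdefault(c.contig_id, []).append(c)
    for contig_id in sorted(by_contig):
        clen = contig_lengths[contig_id]
        group = sorted(by_contig[contig_id], key=lambda c: (c.start, c.end))
        current: ViralRegionCall | None = None
        labels: set[str] = set()
        for c in group:
            if current is not None and c.start < current.end:
                labels.add(c.caller_label)
                if c.end > current.end:
                    current = replace(current, end=c.end)
                continue
            if current is not None:
                merged.append(_finalize_merged(current, labels, clen))
            current, labels = c, {c.caller_label}
        if current is not None:
            merged.append(_finalize_merged(current, labels, clen))
    return merged


def _finalize_merged(call: ViralRegionCall, labels: set[str], contig_length: int) -> ViralRegionCall:
    label = "none" if labels == {"none"} else ("prophage" if "prophage" in labels else "viral")
    return replace(
        call,
        left_flank_present=call.start > 0,
        right_flank_present=call.end < contig_length,
        caller_label=label,
    )


def trim_host_flanks(contig_sequence: str, call: ViralRegionCall) -> str:
    """Return the prophage sequence with up/downstream host bases removed."""
    if call.end > len(contig_sequence):
        raise ValueError(
            f"region [{call.start}, {call.end}) exceeds contig length {len(contig_sequence)}"
        )
    return contig_sequence[call.start:call.end]


@dataclass(frozen=True)
class QualityThresholds:
    """Viral-gene-fraction cutoffs for the gene-content quality stand-in."""

    complete: float = 0.95   # also requires both host flanks
    high: float = 0.90
    medium: float = 0.50


def assess_quality(
    prophage: ProphageRecord,
    genes: pd.DataFrame,
    thresholds: QualityThresholds = QualityThresholds(),
) -> ProphageRecord:
    """Fill gene counts, non-viral score and quality tier for one prophage.

    Only genes lying fully inside the region (on the same contig) count.
    ``cellular_gene_count`` is the number of genes *not* annotated viral
    (cellular, metabolic, transposon or unknown), so
    ``non_viral_score = cellular / max(1, total)`` is the fraction of
    non-viral genes -- the transparent analogue of a "possible non-viral"
    score.  Tier is assigned from the viral-gene fraction: Complete
    (>= ``thresholds.complete``, both flanks present), High, Medium, else
    Low; a region containing no genes is NotDetermined.
    """
    inside = genes[
        (genes["contig_id"] == prophage.contig_id)
        & (genes["start"] >= prophage.start)
        & (genes["end"] <= prophage.end)
    ]
    total = len(inside)
    viral = int((inside["category"] == "viral").sum())
    cellular = total - viral
    score = cellular / max(1, total)
    if total == 0:
        tier = "NotDetermined"
    else:
        viral_frac = viral / total
        both_flanks = prophage.left_flank_present and prophage.right_flank_present
        if viral_frac >= thresholds.complete and both_flanks:
            tier = "Complete"
        elif viral_frac >= thresholds.high:
            tier = "High"
        elif viral_frac >= thresholds.medium:
            tier = "Medium"
        else:
            tier = "Low"
    return replace(
        prophage,
        viral_gene_count=viral,
        cellular_gene_count=cellular,
        total_gene_count=total,
        non_viral_score=score,
        quality_tier=tier,
    )


def extract_prophages(
    mag: MAGRecord,
    calls: Sequence[ViralRegionCall],
    genes: pd.DataFrame,
    thresholds: QualityThresholds = QualityThresholds(),
    merge_overlaps: bool = True,
) -> tuple[list[ProphageRecord], dict[str, str]]:
    """Trim and quality-score all region calls on one MAG.

    Returns the scored records and a prophage_id -> sequence map.
    """
    if merge_overlaps:
        calls = merge_overlapping_calls(calls, mag.contig_lengths)
    records: list[ProphageRecord] = []
    sequences: dict[str, str] = {}
    for i, call in enumerate(sorted(calls, key=lambda c: (c.contig_id, c.start))):
        if call.contig_id not in mag.contigs:
            raise ValueError(f"region call on unknown contig {call.contig_id!r}")
        pid = f"{mag.mag_id}|pp{i:03d}"
        record = ProphageRecord(
            prophage_id=pid, mag_id=mag.mag_id, contig_id=call.contig_id,
            start=call.start, end=call.end,
            left_flank_present=call.left_flank_present,
            right_flank_present=call.right_flank_present,
            caller_label=call.caller_label,
        )
        records.append(assess_quality(record, genes, thresholds))
        sequences[pid] = trim_host_flanks(mag.contigs[call.contig_id], call)
    return records, sequences


# ordered retention rules; the first failing rule is the reported reason
FILTER_REASONS = ("min_length", "flanks", "gene_evidence", "no_caller")


def filter_prophages(
    records: Sequence[ProphageRecord],
    min_length_bp: int = 10_000,
    require_flanks: bool = True,
) -> tuple[list[ProphageRecord], dict[str, str | None]]:
    """Apply the census retention rules to scored prophage records.

    A record is retained iff its length is strictly greater than
    ``min_length_bp``, both host flanks are present (when
    ``require_flanks``), it shows phage-gene evidence (>= 1 viral gene OR
    zero non-viral genes), and the caller labelled it viral or prophage.
    Returns the retained records and a per-record reason map (None when
    retained; otherwise the first failing rule).
    """
    retained: list[ProphageRecord] = []
    reasons: dict[str, str | None] = {}
    for rec in records:
        if rec.length <= min_length_bp:
            reason = "min_length"
        elif require_flanks and not (rec.left_flank_present and rec.right_flank_present):
            reason = "flanks"
        elif not (rec.viral_gene_count >= 1 or rec.cellular_gene_count == 0):
            reason = "gene_evidence"
        elif rec.caller_label == "none":
            reason = "no_caller"
        else:
            reason = None
            retained.append(rec)
        reasons[rec.prophage_id] = reason
    return retained, reasons


def label_lysogens(
    mags: Iterable[MAGRecord | str], prophages: Sequence[ProphageRecord]
) -> dict[str, bool]:
    """Flag each MAG as lysogen iff >= 1 retained prophage maps to it."""
    mag_ids = [m.mag_id if isinstance(m, MAGRecord) else m for m in mags]
    flags = {mag_id: False for mag_id in mag_ids}
    for p in prophages:
        if p.mag_id not in flags:
            raise ValueError(f"prophage {p.prophage_id} references unknown MAG {p.mag_id}")
        flags[p.mag_id] = True
    return flags


def prophage_content(
    mag: MAGRecord, prophages: Sequence[ProphageRecord]
) -> tuple[int, float]:
    """Total retained-prophage bp in a MAG and their fraction of MAG bp."""
    bp = sum(p.length for p in prophages if p.mag_id == mag.mag_id)
    total = mag.total_bp
    return bp, (bp / total if total else 0.0)
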