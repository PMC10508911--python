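"""Screening of putative auxiliary metabolic genes (pAMGs) on prophages.

A pAMG is a host-metabolism gene carried on a phage genome.  Because
mis-drawn prophage boundaries and mobile elements generate false
positives, candidates must sit in convincingly viral context: low
non-viral score of the carrying prophage, a confident AMG score (1-3),
viral genes on both sides, a strictly greater than 5 kb distance from
either prophage end, and no transposon nearby.  A stricter
carbohydrate-active-enzyme (CAZy) subset additionally requires a
Complete/High-quality prophage and an external structure-search
confirmation probability of at least 90%.

The AMG score and the non-viral score are consumed as input columns with
defined semantics (1-3 confident, 4-5 weak; non-viral score in [0, 1]);
this module does not annotate genes itself.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import pandas as pd

from .census import ProphageRecord

# ordered screening rules; the first failing rule is the reported reason
SCREEN_REASONS = ("non_viral_score", "amg_score", "flanking", "end_margin", "transposon")


@dataclass
class PAMGRecord:
    """One candidate auxiliary metabolic gene with rule-by-rule evidence."""

    gene_id: str
    prophage_id: str
    start: int
    end: int
    amg_score: int
    non_viral_score: float
    distance_to_nearest_end: int
    n_viral_genes_upstream: int
    n_viral_genes_downstream: int
    transposon_within_window: bool
    kegg_category: str = ""
    cazy_family: str = ""
    confirmation_probability: float | None = None
    retained: bool = False
    reason: str | None = None


def screen_pamgs(
    genes: pd.DataFrame,
    prophages: Mapping[str, ProphageRecord] | Sequence[ProphageRecord],
    end_margin_bp: int = 5_000,
    transposon_window_bp: int = 5_000,
    max_non_viral_score: float = 0.25,
    allowed_scores: frozenset[int] | set[int] = frozenset({1, 2, 3}),
    confirmations: Mapping[str, float] | None = None,
) -> list[PAMGRecord]:
    """Screen metabolic genes on prophages with positional and score rules.

    ``genes`` carries one row per gene in *prophage-local* coordinates
    (columns ``prophage_id, gene_id, start, end, category, amg_score`` and
    optionally ``kegg_category, cazy_family``).  A metabolic gene is
    retained iff the prophage's non-viral score is strictly below
    ``max_non_viral_score``, its AMG score is in ``allowed_scores``, at
    least one viral gene lies on each side within the prophage, both
    prophage ends are strictly farther than ``end_margin_bp`` away, and no
    transposon-annotated gene lies within ``transposon_window_bp``.
    Rejected records carry the first failing rule as their reason.
    """
    if not isinstance(prophages, Mapping):
        prophages = {p.prophage_id: p for p in prophages}
    confirmations = confirmations or {}
    records: list[PAMGRecord] = []
    for prophage_id, group in genes.groupby("prophage_id", observed=True):
        prophage = prophages[prophage_id]
        plen = prophage.length
        if plen <= 0:
            raise ValueError(f"prophage {prophage_id} has non-positive length")
        if ((group["start"] < 0) | (group["end"] > plen)).any():
            raise ValueError(f"gene outside prophage interval on {prophage_id}")
        viral = group[group["category"] == "viral"]
        transposons = group[group["category"] == "transposon"]
        for row in group[group["category"] == "metabolic"].itertuples(index=False):
            distance = int(min(row.start, plen - row.end))
            upstream = int((viral["end"] <= row.start).sum())
            downstream = int((viral["start"] >= row.end).sum())
            near_transposon = bool((
                (transposons["start"] <= row.end + transposon_window_bp)
                & (transposons["end"] >= row.start - transposon_window_bp)
            ).any())
            score = int(row.amg_score) if not _is_na(row.amg_score) else 0
            rec = PAMGRecord(
                gene_id=row.gene_id, prophage_id=prophage_id,
                start=int(row.start), end=int(row.end),
                amg_score=score,
                non_viral_score=prophage.non_viral_score,
                distance_to_nearest_end=distance,
                n_viral_genes_upstream=upstream,
                n_viral_genes_downstream=downstream,
                transposon_within_window=near_transposon,
                kegg_category=str(getattr(row, "kegg_category", "") or ""),
                cazy_family=str(getattr(row, "cazy_family", "") or ""),
                confirmation_probability=confirmations.get(row.gene_id),
            )
            if not prophage.non_viral_score < max_non_viral_score:
                rec.reason = "non_viral_score"
            elif score not in allowed_scores:
                rec.reason = "amg_score"
            elif not (upstream >= 1 and downstream >= 1):
                rec.reason = "flanking"
            elif not distance > end_margin_bp:
                rec.reason = "end_margin"
            elif near_transposon:
                rec.reason = "transposon"
            else:
                rec.retained = True
            records.append(rec)
    return records


def _is_na(value) -> bool:
    try:
        return value is None or (isinstance(value, float) and math.isnan(value))
    except TypeError:
        return False


def cazy_strict_subset(
    pamgs: Sequence[PAMGRecord],
    prophage_tiers: Mapping[str, str],
    min_probability: float = 90.0,
) -> tuple[list[PAMGRecord], int]:
    """Confirmed CAZy pAMGs on Complete/High-quality prophages.

    Keeps retained pAMGs carrying a CAZy family label whose host prophage
    tier is Complete or High and whose external confirmation probability
    is at least ``min_probability`` (strictly lower values are excluded).
    Records lacking a confirmation value are excluded and counted
    separately; returns ``(kept, n_unconfirmed)``.
    """
    kept: list[PAMGRecord] = []
    n_unconfirmed = 0
    for rec in pamgs:
        if not (rec.retained and rec.cazy_family):
            continue
        if prophage_tiers.get(rec.prophage_id) not in ("Complete", "High"):
            continue
        if rec.confirmation_probability is None:
            n_unconfirmed += 1
            continue
        if rec.confirmation_probability >= min_probability:
            kept.append(rec)
    return kept, n_unconfirmed


CLASS_II_CATEGORIES = ("Transport", "Regulation")


def categorize_functions(pamgs: Sequence[PAMGRecord]) -> pd.DataFrame:
    """Tally retained pAMGs by primary functional category.

    Returns one row per category with ``count``, ``proportion`` (over all
    retained pAMGs, summing to 1) and a ``class_ii`` flag for transport
    and regulation functions, which are not part of central metabolism.
    """
    retained = [p for p in pamgs if p.retained]
    counts: dict[str, int] = {}
    for rec in retained:
        category = rec.kegg_category or "Unannotated"
        counts[category] = counts.get(category, 0) + 1
    total = sum(counts.values())
    rows = [
        {
            "category": category,
            "count": count,
            "proportion": count / total if total else 0.0,
            "class_ii": category in CLASS_II_CATEGORIES,
        }
        for category, count in sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    ]
    return pd.DataFrame(rows, columns=["category", "count", "proportion", "class_ii"])
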