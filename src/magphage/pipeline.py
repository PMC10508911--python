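"""End-to-end census pipeline: ingest -> detect -> extract -> filter ->
cluster -> analyze -> screen AMGs -> report.

The pipeline consumes a dataset directory (per-MAG contig FASTA, gene
annotations, optional region calls, MAG metadata, abundance table) or an
in-memory :class:`~magphage.simulate.CohortData`, and produces the census
tables plus a deterministic plain-text / JSON report.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .amg import PAMGRecord, cazy_strict_subset, categorize_functions, screen_pamgs
from .census import (
    GENE_COLUMNS,
    MAGRecord,
    ProphageRecord,
    QualityThresholds,
    TAXONOMY_RANKS,
    detect_viral_regions,
    extract_prophages,
    filter_prophages,
    frame_to_region_calls,
    label_lysogens,
    prophage_content,
)
from .clustering import (
    build_gene_sharing_graph,
    cluster_genus_votus,
    cluster_proteins,
    cluster_species_votus,
    compare_to_catalog,
    dereplicate,
    host_range_summary,
)
from .io import read_fasta, write_fasta
from .lysogeny import (
    DEFAULT_BINS,
    INFANT_TIMEPOINTS,
    abundance_comparison,
    bin_by_completeness,
    classify_early_late,
    completeness_bin_labels,
    prevalence_by_group,
    ranksum_test,
    spearman_correlation,
)
from .report import format_percent, render_report, summarize_mag_quality


@dataclass
class RunConfig:
    """All thresholds and paths for one pipeline run."""

    input_dir: str = ""
    output_dir: str = ""
    catalog_fasta: str = ""
    seed: int = 0
    # prophage census
    min_prophage_length_bp: int = 10_000
    require_flanks: bool = True
    detection_window_genes: int = 10
    detection_min_viral_density: float = 0.8
    detection_min_run_genes: int = 5
    tier_complete: float = 0.95
    tier_high: float = 0.90
    tier_medium: float = 0.50
    # vOTU clustering
    derep_ani: float = 0.99
    species_ani: float = 0.95
    cluster_coverage: float = 0.75
    ani_fragment_bp: int = 500
    min_fragment_identity: float = 0.7
    protein_identity: float = 0.5
    protein_coverage: float = 0.8
    genus_min_edge_weight: float = 1.3
    # lysogeny analytics
    completeness_bins: tuple = DEFAULT_BINS
    near_complete_min: float = 95.0
    family_min_n: int = 30
    group_min_n: int = 5
    abundance_min_per_arm: int = 5
    # pAMG screening
    amg_end_margin_bp: int = 5_000
    amg_transposon_window_bp: int = 5_000
    amg_max_non_viral_score: float = 0.25
    amg_allowed_scores: tuple = (1, 2, 3)
    cazy_min_probability: float = 90.0

    def validate(self) -> None:
        for name in ("derep_ani", "species_ani", "cluster_coverage",
                     "min_fragment_identity", "protein_identity", "protein_coverage",
                     "amg_max_non_viral_score", "detection_min_viral_density"):
            value = getattr(self, name)
            if not 0.0 <= value <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {value}")
        for name in ("min_prophage_length_bp", "ani_fragment_bp",
                     "amg_end_margin_bp", "amg_transposon_window_bp"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if not set(self.amg_allowed_scores) <= {1, 2, 3, 4, 5}:
            raise ValueError("amg_allowed_scores must be a subset of {1..5}")

    def hash(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("completeness_bins",):
            if key in raw:
                raw[key] = tuple(tuple(b) for b in raw[key])
        for key in ("amg_allowed_scores",):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)


@dataclass
class DatasetBundle:
    """The pipeline's in-memory view of one input dataset."""

    mags: list[MAGRecord]
    genes: pd.DataFrame
    region_calls: pd.DataFrame | None
    metadata: pd.DataFrame
    abundance: pd.DataFrame
    confirmations: pd.DataFrame | None = None


def load_dataset(input_dir: str | Path) -> DatasetBundle:
    """Load a dataset directory written by the simulator (or equivalent)."""
    root = Path(input_dir)

    def _require(name: str, stage: str) -> Path:
        path = root / name
        if not path.exists():
            raise FileNotFoundError(
                f"required input {path} is missing (needed by the {stage} stage)"
            )
        return path

    metadata = pd.read_csv(_require("metadata.tsv", "ingest"), sep="\t")
    genes = pd.read_csv(_require("genes.tsv", "detect"), sep="\t",
                        keep_default_na=False, na_values=[""],
                        dtype={"kegg_category": str, "cazy_family": str})
    genes["kegg_category"] = genes["kegg_category"].fillna("")
    genes["cazy_family"] = genes["cazy_family"].fillna("")
    abundance = pd.read_csv(_require("abundance.tsv", "analyze"), sep="\t")
    calls_path = root / "region_calls.tsv"
    region_calls = pd.read_csv(calls_path, sep="\t") if calls_path.exists() else None
    conf_path = root / "confirmations.tsv"
    confirmations = pd.read_csv(conf_path, sep="\t") if conf_path.exists() else None

    mags_dir = _require("mags", "ingest")
    mags: list[MAGRecord] = []
    for row in metadata.itertuples(index=False):
        fasta = mags_dir / f"{row.mag_id}.fasta"
        if not fasta.exists():
            raise FileNotFoundError(
                f"required input {fasta} is missing (needed by the extract stage)"
            )
        taxonomy = {rank: getattr(row, rank, "") for rank in TAXONOMY_RANKS
                    if hasattr(row, rank)}
        mags.append(MAGRecord(
            mag_id=str(row.mag_id), contigs=read_fasta(fasta),
            completeness=float(row.completeness),
            contamination=float(row.contamination),
            individual_id=str(getattr(row, "individual_id", "")),
            cohort_group=str(getattr(row, "cohort_group", "Unassigned")),
            taxonomy=taxonomy,
        ))
    return DatasetBundle(mags=mags, genes=genes, region_calls=region_calls,
                         metadata=metadata, abundance=abundance,
                         confirmations=confirmations)


@dataclass
class RunResult:
    """All pipeline outputs for one run."""

    config: RunConfig
    mag_table: pd.DataFrame
    prophage_table: pd.DataFrame
    prophage_seqs: dict[str, str]
    retained: list[ProphageRecord]
    votus: pd.DataFrame
    genus_edges: list[tuple[str, str, float]]
    prevalence_bins: pd.DataFrame
    prevalence_family: pd.DataFrame
    prevalence_group_family: pd.DataFrame
    stats: pd.DataFrame
    abundance_tests: pd.DataFrame
    pamgs: list[PAMGRecord]
    pamg_table: pd.DataFrame
    pamg_categories: pd.DataFrame
    cazy_confirmed: list[PAMGRecord]
    report: dict
    report_text: str


def _dataset_from_cohort(cohort) -> DatasetBundle:
    return DatasetBundle(
        mags=cohort.mags, genes=cohort.genes, region_calls=cohort.region_calls,
        metadata=cohort.metadata, abundance=cohort.abundance,
        confirmations=cohort.confirmations,
    )


def run_pipeline(config: RunConfig, cohort=None) -> RunResult:
    """Execute the full census pipeline and (optionally) write outputs."""
    config.validate()
    if cohort is not None:
        data = _dataset_from_cohort(cohort)
    else:
        if not config.input_dir:
            raise FileNotFoundError(
                "config.input_dir is empty (needed by the ingest stage)"
            )
        data = load_dataset(config.input_dir)

    admitted: list[MAGRecord] = []
    for mag in data.mags:
        if mag.completeness < 70 or mag.contamination > 5:
            warnings.warn(f"MAG {mag.mag_id} fails admission thresholds; skipped")
            continue
        admitted.append(mag)
    mag_by_id = {m.mag_id: m for m in admitted}

    genes_by_mag = dict(tuple(data.genes.groupby("mag_id"))) if not data.genes.empty else {}

    # detect: use supplied region calls, else call regions from annotations
    thresholds = QualityThresholds(
        complete=config.tier_complete, high=config.tier_high, medium=config.tier_medium
    )
    all_records: list[ProphageRecord] = []
    all_seqs: dict[str, str] = {}
    for mag in admitted:
        mag_genes = genes_by_mag.get(mag.mag_id, pd.DataFrame(columns=GENE_COLUMNS))
        if data.region_calls is not None and not data.region_calls.empty:
            calls = frame_to_region_calls(
                data.region_calls[data.region_calls["mag_id"] == mag.mag_id]
            )
        else:
            calls = []
            for contig_id, contig_genes in mag_genes.groupby("contig_id"):
                calls.extend(detect_viral_regions(
                    contig_genes.sort_values("start"), len(mag.contigs[contig_id]),
                    window_genes=config.detection_window_genes,
                    min_viral_density=config.detection_min_viral_density,
                    min_run_genes=config.detection_min_run_genes,
                ))
        records, seqs = extract_prophages(mag, calls, mag_genes, thresholds)
        all_records.extend(records)
        all_seqs.update(seqs)

    retained, reasons = filter_prophages(
        all_records, min_length_bp=config.min_prophage_length_bp,
        require_flanks=config.require_flanks,
    )
    retained_ids = {p.prophage_id for p in retained}
    prophage_table = pd.DataFrame([
        {
            "prophage_id": r.prophage_id, "mag_id": r.mag_id, "contig_id": r.contig_id,
            "start": r.start, "end": r.end, "length": r.length,
            "quality_tier": r.quality_tier,
            "viral_gene_count": r.viral_gene_count,
            "cellular_gene_count": r.cellular_gene_count,
            "non_viral_score": round(r.non_viral_score, 4),
            "left_flank_present": r.left_flank_present,
            "right_flank_present": r.right_flank_present,
            "caller_label": r.caller_label,
            "retained": r.prophage_id in retained_ids,
            "reject_reason": reasons[r.prophage_id] or "",
        }
        for r in all_records
    ])

    # analyze: per-MAG lysogeny, Early/Late categorization, prevalence
    lysogen_flags = label_lysogens(admitted, retained)
    mag_rows = []
    abund_wide = _infant_abundance_wide(data.abundance, admitted)
    early_late = classify_early_late(abund_wide) if not abund_wide.empty else pd.Series(dtype=object)
    mean_abund = data.abundance.groupby("mag_id")["cpm"].mean() if not data.abundance.empty \
        else pd.Series(dtype=float)
    for mag in admitted:
        group = mag.cohort_group
        if group == "Unassigned" and mag.mag_id in early_late.index:
            group = early_late[mag.mag_id]
        bp, fraction = prophage_content(mag, retained)
        mag_rows.append({
            "mag_id": mag.mag_id, "individual_id": mag.individual_id,
            "cohort_group": group,
            "completeness": mag.completeness, "contamination": mag.contamination,
            "family": mag.taxonomy.get("family", ""),
            "species": mag.taxonomy.get("species", ""),
            "total_bp": mag.total_bp,
            "is_lysogen": lysogen_flags[mag.mag_id],
            "prophage_bp": bp,
            "prophage_fraction": round(fraction, 6),
            "abundance": float(mean_abund.get(mag.mag_id, np.nan)),
        })
    mag_table = pd.DataFrame(mag_rows)
    mag_table["completeness_bin"] = bin_by_completeness(
        mag_table["completeness"].clip(upper=100), config.completeness_bins
    ).to_numpy()

    prevalence_bins = prevalence_by_group(mag_table, "completeness_bin", min_n=1)
    order = completeness_bin_labels(config.completeness_bins)
    prevalence_bins["completeness_bin"] = pd.Categorical(
        prevalence_bins["completeness_bin"], categories=order, ordered=True
    )
    prevalence_bins = prevalence_bins.sort_values("completeness_bin").reset_index(drop=True)

    near = mag_table[mag_table["completeness"] > config.near_complete_min]
    prevalence_family = prevalence_by_group(near, "family", min_n=config.family_min_n)
    prevalence_group_family = prevalence_by_group(
        mag_table, ["cohort_group", "family"], min_n=config.group_min_n
    )

    stats_rows = []
    if len(near) >= 3:
        rho, p = spearman_correlation(near["total_bp"], near["prophage_bp"])
        stats_rows.append({"test": "spearman_prophage_bp_vs_mag_bp",
                           "statistic": rho, "p_value": p, "n": len(near)})
        rho2, p2 = spearman_correlation(near["completeness"], near["prophage_bp"])
        stats_rows.append({"test": "spearman_prophage_bp_vs_completeness",
                           "statistic": rho2, "p_value": p2, "n": len(near)})
    lys_comp = mag_table.loc[mag_table["is_lysogen"], "completeness"]
    non_comp = mag_table.loc[~mag_table["is_lysogen"], "completeness"]
    if len(lys_comp) and len(non_comp):
        u, p = ranksum_test(lys_comp, non_comp)
        stats_rows.append({"test": "ranksum_completeness_lysogen_vs_non",
                           "statistic": u, "p_value": p, "n": len(mag_table)})
    stats = pd.DataFrame(stats_rows, columns=["test", "statistic", "p_value", "n"])

    abundance_tests = abundance_comparison(
        mag_table.dropna(subset=["abundance"]), min_per_arm=config.abundance_min_per_arm
    ) if not mag_table.empty else pd.DataFrame()

    # cluster: dereplicate -> species vOTUs -> gene-sharing genera
    retained_seqs = {pid: all_seqs[pid] for pid in sorted(retained_ids)}
    votus, genus_edges = _cluster_stage(retained_seqs, genes_by_mag, retained, config, mag_by_id)

    # pAMG screening on retained prophages
    conf_map: dict[str, float] = {}
    if data.confirmations is not None and not data.confirmations.empty:
        conf_map = dict(zip(data.confirmations["gene_id"],
                            data.confirmations["confirmation_probability"].astype(float)))
    local_genes = _genes_in_prophage_coords(retained, genes_by_mag)
    pamgs = screen_pamgs(
        local_genes, {p.prophage_id: p for p in retained},
        end_margin_bp=config.amg_end_margin_bp,
        transposon_window_bp=config.amg_transposon_window_bp,
        max_non_viral_score=config.amg_max_non_viral_score,
        allowed_scores=frozenset(config.amg_allowed_scores),
        confirmations=conf_map,
    ) if not local_genes.empty else []
    tiers = {p.prophage_id: p.quality_tier for p in retained}
    cazy_confirmed, n_unconfirmed = cazy_strict_subset(
        pamgs, tiers, min_probability=config.cazy_min_probability
    )
    pamg_categories = categorize_functions(pamgs)
    pamg_table = pd.DataFrame([dataclasses.asdict(p) for p in pamgs])

    report = _build_report(config, data, mag_table, prophage_table, retained, votus,
                           prevalence_bins, pamgs, pamg_categories, cazy_confirmed,
                           n_unconfirmed)
    result = RunResult(
        config=config, mag_table=mag_table, prophage_table=prophage_table,
        prophage_seqs=all_seqs, retained=retained, votus=votus,
        genus_edges=genus_edges, prevalence_bins=prevalence_bins,
        prevalence_family=prevalence_family,
        prevalence_group_family=prevalence_group_family, stats=stats,
        abundance_tests=abundance_tests, pamgs=pamgs, pamg_table=pamg_table,
        pamg_categories=pamg_categories, cazy_confirmed=cazy_confirmed,
        report=report, report_text=render_report(report),
    )
    if config.output_dir:
        write_outputs(result, config.output_dir)
    return result


def _infant_abundance_wide(abundance: pd.DataFrame, mags: list[MAGRecord]) -> pd.DataFrame:
    """Wide infant-timepoint abundance (rows: infant MAGs, cols: timepoints)."""
    if abundance.empty:
        return pd.DataFrame(columns=list(INFANT_TIMEPOINTS))
    frame = abundance.copy()
    frame["timepoint"] = frame["sample_id"].astype(str).str.rsplit("_", n=1).str[-1]
    frame = frame[frame["timepoint"].isin(INFANT_TIMEPOINTS)]
    if frame.empty:
        return pd.DataFrame(columns=list(INFANT_TIMEPOINTS))
    wide = frame.pivot_table(index="mag_id", columns="timepoint", values="cpm",
                             aggfunc="mean")
    return wide.reindex(columns=list(INFANT_TIMEPOINTS))


def _cluster_stage(retained_seqs, genes_by_mag, retained, config, mag_by_id):
    from Bio.Seq import Seq

    if not retained_seqs:
        return pd.DataFrame(columns=[
            "sequence_id", "mag_id", "species_votu_id", "genus_votu_id",
            "is_representative", "is_singleton", "novel_vs_catalog",
            "host_species", "host_family",
        ]), []
    derep_reps, derep_map = dereplicate(
        retained_seqs, ani_threshold=config.derep_ani,
        cov_threshold=config.cluster_coverage, fragment_bp=config.ani_fragment_bp,
        min_fragment_identity=config.min_fragment_identity,
    )
    rep_seqs = {r: retained_seqs[r] for r in derep_reps}
    species = cluster_species_votus(
        rep_seqs, ani_threshold=config.species_ani,
        cov_threshold=config.cluster_coverage, fragment_bp=config.ani_fragment_bp,
        min_fragment_identity=config.min_fragment_identity,
    )
    species_of = dict(zip(species["sequence_id"], species["species_votu_id"]))
    singleton_of = dict(zip(species["species_votu_id"], species["is_singleton"]))
    species_rep = dict(zip(
        species.loc[species["is_representative"], "species_votu_id"],
        species.loc[species["is_representative"], "sequence_id"],
    ))

    # genus stage operates on the species representatives
    by_id = {p.prophage_id: p for p in retained}
    proteins: dict[str, str] = {}
    profiles_members: dict[str, list[str]] = {}
    for votu, rep in species_rep.items():
        record = by_id[rep]
        mag_genes = genes_by_mag.get(record.mag_id)
        members = []
        if mag_genes is not None:
            inside = mag_genes[
                (mag_genes["contig_id"] == record.contig_id)
                & (mag_genes["start"] >= record.start)
                & (mag_genes["end"] <= record.end)
                & (mag_genes["category"] == "viral")
            ]
            seq = retained_seqs[rep]
            for row in inside.itertuples(index=False):
                nt = seq[row.start - record.start:row.end - record.start]
                nt = nt[: len(nt) // 3 * 3]
                if len(nt) >= 60:
                    pid = f"{rep}::{row.gene_id}"
                    proteins[pid] = str(Seq(nt).translate())
                    members.append(pid)
        profiles_members[votu] = members
    families = cluster_proteins(
        proteins, identity_threshold=config.protein_identity,
        coverage_threshold=config.protein_coverage,
    )
    profiles = {votu: {families[p] for p in members}
                for votu, members in profiles_members.items()}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # empty profiles become genus singletons
        edges = build_gene_sharing_graph(
            {v: f for v, f in profiles.items() if f},
            min_weight=config.genus_min_edge_weight,
        )
    genus_of_votu = cluster_genus_votus(edges, nodes=sorted(profiles))

    novelty: dict[str, bool] = {}
    if config.catalog_fasta:
        catalog = read_fasta(config.catalog_fasta)
        novelty = compare_to_catalog(
            {species_rep[v]: retained_seqs[species_rep[v]] for v in species_rep},
            catalog, ani_threshold=config.species_ani,
            cov_threshold=config.cluster_coverage,
            fragment_bp=config.ani_fragment_bp,
            min_fragment_identity=config.min_fragment_identity,
        )

    rows = []
    for pid in sorted(retained_seqs):
        rep = derep_map[pid]
        votu = species_of[rep]
        record = by_id[pid]
        mag = mag_by_id[record.mag_id]
        rows.append({
            "sequence_id": pid, "mag_id": record.mag_id,
            "species_votu_id": votu, "genus_votu_id": genus_of_votu[votu],
            "is_representative": species_rep[votu] == pid,
            "is_singleton": bool(singleton_of[votu]),
            "novel_vs_catalog": novelty.get(species_rep[votu], pd.NA),
            "host_species": mag.taxonomy.get("species", ""),
            "host_family": mag.taxonomy.get("family", ""),
        })
    return pd.DataFrame(rows), edges


def _genes_in_prophage_coords(retained, genes_by_mag) -> pd.DataFrame:
    """Map gene annotations into prophage-local coordinates."""
    frames = []
    for record in retained:
        mag_genes = genes_by_mag.get(record.mag_id)
        if mag_genes is None:
            continue
        inside = mag_genes[
            (mag_genes["contig_id"] == record.contig_id)
            & (mag_genes["start"] >= record.start)
            & (mag_genes["end"] <= record.end)
        ].copy()
        if inside.empty:
            continue
        inside["start"] = inside["start"] - record.start
        inside["end"] = inside["end"] - record.start
        inside["prophage_id"] = record.prophage_id
        frames.append(inside)
    if not frames:
        return pd.DataFrame(columns=GENE_COLUMNS + ["prophage_id"])
    return pd.concat(frames, ignore_index=True)


def _build_report(config, data, mag_table, prophage_table, retained, votus,
                  prevalence_bins, pamgs, pamg_categories, cazy_confirmed,
                  n_unconfirmed) -> dict:
    tier_counts = pd.Series([p.quality_tier for p in retained]).value_counts().to_dict() \
        if retained else {}
    reason_hist = prophage_table.loc[prophage_table["reject_reason"] != "",
                                     "reject_reason"].value_counts().to_dict() \
        if not prophage_table.empty else {}
    n_species = votus["species_votu_id"].nunique() if not votus.empty else 0
    n_genus = votus["genus_votu_id"].nunique() if not votus.empty else 0
    n_singleton = votus.drop_duplicates("species_votu_id")["is_singleton"].sum() \
        if not votus.empty else 0
    multi_species, multi_family = host_range_summary(votus) if not votus.empty else (0, 0)
    near = mag_table[mag_table["completeness"] > config.near_complete_min]
    novel_known = votus.drop_duplicates("species_votu_id")["novel_vs_catalog"].dropna() \
        if not votus.empty else pd.Series(dtype=object)
    retained_pamgs = [p for p in pamgs if p.retained]
    report = {
        "version": __version__,
        "seed": config.seed,
        "config_hash": config.hash(),
        "mags": {
            **summarize_mag_quality(data.metadata),
            "lysogens": int(mag_table["is_lysogen"].sum()) if not mag_table.empty else 0,
            "lysogen_prevalence_near_complete": format_percent(
                int(near["is_lysogen"].sum()), len(near), 0
            ),
            "median_prophage_fraction": float(
                mag_table.loc[mag_table["is_lysogen"], "prophage_fraction"].median()
            ) if not mag_table.empty and mag_table["is_lysogen"].any() else 0.0,
        },
        "prophages": {
            "candidate_regions": int(len(prophage_table)),
            "retained": len(retained),
            "tiers": {t: int(tier_counts.get(t, 0))
                      for t in ("Complete", "High", "Medium", "Low", "NotDetermined")},
            "reject_reasons": {k: int(v) for k, v in sorted(reason_hist.items())},
        },
        "votus": {
            "species": int(n_species),
            "genus": int(n_genus),
            "species_singletons": int(n_singleton),
            "species_singleton_percent": format_percent(int(n_singleton), int(n_species), 1),
            "multi_host_species": int(multi_species),
            "multi_host_family": int(multi_family),
            "novel_percent": format_percent(int(novel_known.sum()), len(novel_known), 0)
            if len(novel_known) else "NA",
        },
        "prevalence_by_completeness_bin": {
            str(row.completeness_bin): round(float(row.prevalence), 4)
            for row in prevalence_bins.itertuples(index=False)
        },
        "pamgs": {
            "candidates": len(pamgs),
            "retained": len(retained_pamgs),
            "prophages_with_pamg": len({p.prophage_id for p in retained_pamgs}),
            "cazy_confirmed": len(cazy_confirmed),
            "cazy_unconfirmed": int(n_unconfirmed),
            "top_categories": {
                str(row.category): int(row.count)
                for row in pamg_categories.head(5).itertuples(index=False)
            },
        },
    }
    return report


def write_outputs(result: RunResult, out_dir: str | Path) -> Path:
    """Write all census tables, FASTA, and the report twins."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    result.mag_table.to_csv(out / "mags.tsv", sep="\t", index=False)
    result.prophage_table.to_csv(out / "prophages.tsv", sep="\t", index=False)
    retained_ids = {p.prophage_id for p in result.retained}
    write_fasta({pid: seq for pid, seq in result.prophage_seqs.items()
                 if pid in retained_ids}, out / "prophages.fasta")
    result.votus.to_csv(out / "votus.tsv", sep="\t", index=False)
    pd.DataFrame(result.genus_edges, columns=["votu_a", "votu_b", "weight"]).to_csv(
        out / "genus_edges.tsv", sep="\t", index=False)
    result.prevalence_bins.to_csv(out / "prevalence_bins.tsv", sep="\t", index=False)
    result.prevalence_family.to_csv(out / "prevalence_family.tsv", sep="\t", index=False)
    result.prevalence_group_family.to_csv(out / "prevalence_group_family.tsv",
                                          sep="\t", index=False)
    result.stats.to_csv(out / "stats.tsv", sep="\t", index=False)
    result.abundance_tests.to_csv(out / "abundance_tests.tsv", sep="\t", index=False)
    result.pamg_table.to_csv(out / "pamgs.tsv", sep="\t", index=False)
    result.pamg_categories.to_csv(out / "pamg_categories.tsv", sep="\t", index=False)
    (out / "report.json").write_text(json.dumps(result.report, indent=2, sort_keys=True))
    (out / "report.txt").write_text(result.report_text)
    return out
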