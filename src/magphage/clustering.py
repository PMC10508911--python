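"""Dereplication and vOTU clustering of prophage sequences.

Species-like viral OTUs follow the community convention of 95% average
nucleotide identity (ANI) over at least 75% of the shorter sequence;
dereplication uses the same machinery at 99% ANI.  ANI is computed by a
fragment-mapping scheme: the shorter sequence is cut into non-overlapping
fragments, each fragment is aligned to the longer sequence by exact
edit-distance dynamic programming (edlib, infix mode), and ANI is the
length-weighted mean identity of the fragments that align above a minimum
identity.  Clustering is greedy centroid clustering with sequences
visited in decreasing-length order (ties broken by id), which makes the
result independent of input order.

Genus-like vOTUs use a simplified gene-sharing stand-in for
protein-cluster network tools: genomes are profiled by shared protein
families (greedy clustering on amino-acid identity), pairs are connected
when the hypergeometric tail probability of their shared-family count is
small, and connected components of the significant-edge graph are the
genera.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Collection, Mapping, Sequence

import edlib
import networkx as nx
import numpy as np
import pandas as pd
from scipy.stats import hypergeom


@dataclass(frozen=True)
class ANIResult:
    """Pairwise ANI over aligned fragments, with shorter-sequence coverage."""

    query_id: str
    target_id: str
    ani: float
    coverage_shorter: float


def _fragment_identity(fragment: str, target: str) -> float:
    """Identity of the best infix alignment of ``fragment`` in ``target``."""
    result = edlib.align(fragment, target, mode="HW", task="distance")
    return 1.0 - result["editDistance"] / len(fragment)


def pairwise_ani(
    seq_a: str,
    seq_b: str,
    fragment_bp: int = 500,
    min_fragment_identity: float = 0.7,
    id_a: str = "a",
    id_b: str = "b",
) -> ANIResult:
    """Fragment-mapping ANI between two nucleotide sequences.

    The shorter sequence is cut into non-overlapping ``fragment_bp``
    windows (a terminal remnant >= 100 bp is kept); each window is aligned
    to the longer sequence and counts as aligned when its identity is at
    least ``min_fragment_identity``.  ANI is the length-weighted mean
    identity of aligned fragments and coverage is aligned fragment bases
    over the shorter length.  The result is identical under argument
    swap.
    """
    if not seq_a or not seq_b:
        raise ValueError("sequences must be non-empty")
    # deterministic orientation so that the result is swap-invariant
    if (len(seq_a), seq_a) <= (len(seq_b), seq_b):
        shorter, longer = seq_a, seq_b
    else:
        shorter, longer = seq_b, seq_a
    aligned_bp = 0
    weighted = 0.0
    for off in range(0, len(shorter), fragment_bp):
        frag = shorter[off:off + fragment_bp]
        if len(frag) < min(100, len(shorter)):
            continue
        identity = _fragment_identity(frag, longer)
        if identity >= min_fragment_identity:
            aligned_bp += len(frag)
            weighted += identity * len(frag)
    ani = weighted / aligned_bp if aligned_bp else 0.0
    coverage = aligned_bp / len(shorter)
    return ANIResult(query_id=id_a, target_id=id_b, ani=ani, coverage_shorter=coverage)


def greedy_order(sequences: Mapping[str, str]) -> list[str]:
    """Centroid visiting order: length descending, ties by id ascending."""
    return sorted(sequences, key=lambda sid: (-len(sequences[sid]), sid))


_KMER_K = 16
#: minimum shared-16-mer fraction below which a pair cannot plausibly pass
#: a >= 90% ANI / >= 75% coverage gate (such pairs share >~ 10% of k-mers);
#: pairs below it are skipped without alignment.
KMER_PREFILTER_MIN_SHARE = 0.02


def _kmer_set(sequence: str, k: int = _KMER_K) -> frozenset[str]:
    return frozenset(sequence[i:i + k] for i in range(len(sequence) - k + 1))


def _kmer_share(kmers_a: frozenset[str], kmers_b: frozenset[str]) -> float:
    smaller = min(len(kmers_a), len(kmers_b))
    if smaller == 0:
        return 1.0  # too short to prefilter; fall through to alignment
    return len(kmers_a & kmers_b) / smaller


def _greedy_cluster(
    sequences: Mapping[str, str],
    ani_threshold: float,
    cov_threshold: float,
    fragment_bp: int,
    min_fragment_identity: float,
    prefilter_min_share: float | None = KMER_PREFILTER_MIN_SHARE,
) -> dict[str, str]:
    """Greedy centroid clustering; returns member -> representative."""
    kmers = {sid: _kmer_set(seq) for sid, seq in sequences.items()} \
        if prefilter_min_share else {}
    assignment: dict[str, str] = {}
    representatives: list[str] = []
    for sid in greedy_order(sequences):
        rep_found = None
        for rep in representatives:
            if prefilter_min_share and \
                    _kmer_share(kmers[sid], kmers[rep]) < prefilter_min_share:
                continue
            res = pairwise_ani(
                sequences[sid], sequences[rep],
                fragment_bp=fragment_bp, min_fragment_identity=min_fragment_identity,
            )
            if res.ani >= ani_threshold and res.coverage_shorter >= cov_threshold:
                rep_found = rep
                break
        if rep_found is None:
            representatives.append(sid)
            assignment[sid] = sid
        else:
            assignment[sid] = rep_found
    return assignment


def dereplicate(
    sequences: Mapping[str, str],
    ani_threshold: float = 0.99,
    cov_threshold: float = 0.75,
    fragment_bp: int = 500,
    min_fragment_identity: float = 0.7,
) -> tuple[list[str], dict[str, str]]:
    """Remove near-identical redundancy at 99% ANI.

    Returns the representative ids (in visiting order) and the
    member -> representative map.  Idempotent: re-running on the
    representatives changes nothing.
    """
    assignment = _greedy_cluster(
        sequences, ani_threshold, cov_threshold, fragment_bp, min_fragment_identity
    )
    reps = [sid for sid in greedy_order(sequences) if assignment[sid] == sid]
    return reps, assignment


def cluster_species_votus(
    sequences: Mapping[str, str],
    ani_threshold: float = 0.95,
    cov_threshold: float = 0.75,
    fragment_bp: int = 500,
    min_fragment_identity: float = 0.7,
) -> pd.DataFrame:
    """Cluster sequences into species-like vOTUs (95% ANI / 75% coverage).

    Returns a table with one row per sequence: ``sequence_id``,
    ``species_votu_id``, ``is_representative``, ``is_singleton``.
    """
    assignment = _greedy_cluster(
        sequences, ani_threshold, cov_threshold, fragment_bp, min_fragment_identity
    )
    reps = [sid for sid in greedy_order(sequences) if assignment[sid] == sid]
    votu_ids = {rep: f"sOTU_{i:04d}" for i, rep in enumerate(reps)}
    sizes: dict[str, int] = {}
    for rep in assignment.values():
        sizes[rep] = sizes.get(rep, 0) + 1
    rows = [
        {
            "sequence_id": sid,
            "species_votu_id": votu_ids[assignment[sid]],
            "is_representative": assignment[sid] == sid,
            "is_singleton": sizes[assignment[sid]] == 1,
        }
        for sid in greedy_order(sequences)
    ]
    return pd.DataFrame(rows)


def _protein_identity(prot_a: str, prot_b: str) -> tuple[float, float]:
    """Global amino-acid identity and mutual length coverage."""
    dist = edlib.align(prot_a, prot_b, mode="NW", task="distance")["editDistance"]
    longer = max(len(prot_a), len(prot_b))
    return 1.0 - dist / longer, min(len(prot_a), len(prot_b)) / longer


def cluster_proteins(
    proteins: Mapping[str, str],
    identity_threshold: float = 0.5,
    coverage_threshold: float = 0.8,
) -> dict[str, str]:
    """Greedy centroid clustering of proteins into families.

    Returns member -> family representative.  Deterministic under the
    length-then-id visiting order.
    """
    assignment: dict[str, str] = {}
    representatives: list[str] = []
    for pid in greedy_order(proteins):
        rep_found = None
        for rep in representatives:
            # length ratio bounds coverage, so skip hopeless pairs cheaply
            if min(len(proteins[pid]), len(proteins[rep])) < coverage_threshold * max(
                len(proteins[pid]), len(proteins[rep])
            ):
                continue
            identity, coverage = _protein_identity(proteins[pid], proteins[rep])
            if identity >= identity_threshold and coverage >= coverage_threshold:
                rep_found = rep
                break
        if rep_found is None:
            representatives.append(pid)
            assignment[pid] = pid
        else:
            assignment[pid] = rep_found
    return assignment


def build_gene_sharing_graph(
    profiles: Mapping[str, Collection[str]],
    min_weight: float = 1.3,
    universe_size: int | None = None,
) -> list[tuple[str, str, float]]:
    """Significant gene-sharing edges between genomes.

    Edge weight is ``-log10`` of the hypergeometric upper-tail probability
    of observing at least the shared-family count given the two genomes'
    family counts and the family universe; edges below ``min_weight``
    (default 1.3, i.e. p <= 0.05) are dropped.  Genomes with an empty
    profile are excluded with a warning.
    """
    kept: dict[str, frozenset[str]] = {}
    for gid, fams in profiles.items():
        fams = frozenset(fams)
        if not fams:
            warnings.warn(f"genome {gid!r} has no proteins; excluded from gene-sharing graph")
            continue
        kept[gid] = fams
    universe = universe_size if universe_size is not None else \
        len(set().union(*kept.values())) if kept else 0
    edges: list[tuple[str, str, float]] = []
    ids = sorted(kept)
    for i, a in enumerate(ids):
        for b in ids[i + 1:]:
            k = len(kept[a] & kept[b])
            if k == 0:
                continue
            p_tail = float(hypergeom.sf(k - 1, universe, len(kept[a]), len(kept[b])))
            weight = -np.log10(max(p_tail, 1e-300))
            if weight >= min_weight:
                edges.append((a, b, float(weight)))
    return edges


def cluster_genus_votus(
    edges: Sequence[tuple[str, str, float]],
    nodes: Collection[str],
) -> dict[str, str]:
    """Genus-like vOTUs as connected components of the significant graph.

    Isolated nodes become genus singletons.  Genus ids are assigned in
    order of each component's lexicographically smallest member, so the
    labelling is deterministic.
    """
    graph = nx.Graph()
    graph.add_nodes_from(nodes)
    graph.add_weighted_edges_from(edges)
    components = sorted(nx.connected_components(graph), key=lambda c: min(c))
    assignment: dict[str, str] = {}
    for i, component in enumerate(components):
        gid = f"gOTU_{i:04d}"
        for node in component:
            assignment[node] = gid
    return assignment


def compare_to_catalog(
    representatives: Mapping[str, str],
    references: Mapping[str, str],
    ani_threshold: float = 0.95,
    cov_threshold: float = 0.75,
    fragment_bp: int = 500,
    min_fragment_identity: float = 0.7,
) -> dict[str, bool]:
    """Novelty of each vOTU representative against a reference catalog.

    A vOTU is non-novel iff its representative clusters with at least one
    reference sequence under the species thresholds.
    """
    ref_kmers = {rid: _kmer_set(seq) for rid, seq in references.items()}
    novelty: dict[str, bool] = {}
    for rid, seq in representatives.items():
        rep_kmers = _kmer_set(seq)
        novel = True
        for ref_id, ref_seq in references.items():
            if _kmer_share(rep_kmers, ref_kmers[ref_id]) < KMER_PREFILTER_MIN_SHARE:
                continue
            res = pairwise_ani(
                seq, ref_seq, fragment_bp=fragment_bp,
                min_fragment_identity=min_fragment_identity,
            )
            if res.ani >= ani_threshold and res.coverage_shorter >= cov_threshold:
                novel = False
                break
        novelty[rid] = novel
    return novelty


def host_range_summary(
    assignments: pd.DataFrame,
    votu_col: str = "species_votu_id",
    species_col: str = "host_species",
    family_col: str = "host_family",
) -> tuple[int, int]:
    """Count multi-host vOTUs at species and family rank.

    Only vOTUs with >= 2 member sequences are considered; returns
    ``(n_votus_spanning_multiple_host_species, n_spanning_multiple_host_families)``.
    """
    multi_species = 0
    multi_family = 0
    for _, group in assignments.groupby(votu_col):
        if len(group) < 2:
            continue
        if group[species_col].nunique() > 1:
            multi_species += 1
        if group[family_col].nunique() > 1:
            multi_family += 1
    return multi_species, multi_family
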