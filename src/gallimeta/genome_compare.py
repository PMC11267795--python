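"""Genome quality filtering, ANI/AAI, dereplication and novelty calls.

The ANI estimator is fragment-mapping: the query genome is cut into
non-overlapping fragments which are placed on the reference by k-mer-seeded
gapless extension; ANI is the mean identity of fragments passing the
identity floor, undefined when too few fragments survive.  AAI is the mean
identity of reciprocal best protein hits.  Dereplication is greedy centroid
clustering by descending assembly quality (completeness - 5 x
contamination); genus clusters are single-linkage components over AAI
edges.  Novelty calls mirror the strain/species/genus decision rules:
a strain is known if some reference genome exceeds 99% ANI, a species at
95% ANI (strict inequalities), a genus cluster if it co-clusters with a
reference genome at 60% AAI or carries a reference genus label.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Mapping

import networkx as nx
import numpy as np
import pandas as pd

from ._align import best_gapless_match_indexed, kmer_index, seq_to_array


@dataclass
class GenomeRecord:
    genome_id: str
    sequence: str = ""
    completeness: float | None = None
    contamination: float | None = None

    @property
    def quality_score(self) -> float | None:
        if self.completeness is None or self.contamination is None:
            return None
        return self.completeness - 5.0 * self.contamination


@dataclass
class ANIResult:
    query_id: str
    reference_id: str
    ani: float | None  # percent, None when undefined
    aligned_fraction: float


@dataclass
class ClusterSet:
    """Clusters of genome ids, each with a representative, plus the threshold used."""

    clusters: list[tuple[str, list[str]]]
    threshold: float

    @property
    def representatives(self) -> list[str]:
        return [rep for rep, _ in self.clusters]

    def cluster_of(self, genome_id: str) -> tuple[str, list[str]] | None:
        for rep, members in self.clusters:
            if genome_id in members:
                return rep, members
        return None


@dataclass
class UniquenessCall:
    subject_id: str  # genome id, or representative id for genus clusters
    level: str  # strain | species | genus
    unique_vs_reference_db: bool | None  # None = indeterminate
    unique_vs_nsc: bool | None


def quality_filter(genomes: list[GenomeRecord], completeness_min: float = 80.0,
                   contamination_max: float = 5.0
                   ) -> tuple[list[GenomeRecord], list[tuple[str, str]]]:
    """Split genomes into passing and rejected (with a reason).

    Thresholds are inclusive: completeness >= 80 and contamination <= 5 pass.
    Genomes with a missing metric are rejected.
    """
    passing, rejected = [], []
    for g in genomes:
        if g.completeness is None or g.contamination is None:
            rejected.append((g.genome_id, "missing quality metric"))
        elif g.completeness < completeness_min:
            rejected.append((g.genome_id, f"completeness {g.completeness} < {completeness_min}"))
        elif g.contamination > contamination_max:
            rejected.append((g.genome_id, f"contamination {g.contamination} > {contamination_max}"))
        else:
            passing.append(g)
    return passing, rejected


def ani(query: str, reference: str, query_id: str = "query",
        reference_id: str = "reference", fragment_len: int = 1020,
        min_fragment_identity: float = 0.8, min_aligned_fraction: float = 0.5,
        k: int = 16) -> ANIResult:
    """Fragment-mapping average nucleotide identity of *query* against *reference*.

    The query is cut into non-overlapping *fragment_len* windows (a trailing
    partial window is dropped); each is placed at its best k-mer-anchored
    offset and scored gaplessly over the full fragment.  Fragments below
    *min_fragment_identity* (or unplaceable ones) do not count as aligned;
    ANI is undefined when fewer than *min_aligned_fraction* of fragments
    align.
    """
    if len(query) < 10_000 or len(reference) < 10_000:
        raise ValueError("genomes must be at least 10 kb")
    index = kmer_index(reference, k)
    ref_arr = seq_to_array(reference)
    n_fragments = len(query) // fragment_len
    identities = []
    for i in range(n_fragments):
        frag = query[i * fragment_len : (i + 1) * fragment_len]
        matches, overlap, _ = best_gapless_match_indexed(
            frag, ref_arr, index, k, step=k, top=3)
        if overlap < fragment_len:
            continue
        ident = matches / fragment_len
        if ident >= min_fragment_identity:
            identities.append(ident)
    fraction = len(identities) / n_fragments if n_fragments else 0.0
    if fraction < min_aligned_fraction:
        return ANIResult(query_id, reference_id, None, fraction)
    return ANIResult(query_id, reference_id, 100.0 * float(np.mean(identities)), fraction)


def symmetric_ani(a: str, b: str, **kwargs) -> float | None:
    """Directional ANI both ways, combined by maximum (percent, or None)."""
    fwd = ani(a, b, **kwargs).ani
    rev = ani(b, a, **kwargs).ani
    values = [v for v in (fwd, rev) if v is not None]
    return max(values) if values else None


def aai(proteome_a: Mapping[str, str], proteome_b: Mapping[str, str],
        k: int = 4, min_rbh: int = 5) -> float | None:
    """Average amino-acid identity over reciprocal best hits (percent).

    Best hits are found by k-mer-seeded gapless matching with identity
    computed over the shorter protein; AAI is undefined (None) with fewer
    than *min_rbh* reciprocal pairs.
    """
    if len(proteome_a) < 10 or len(proteome_b) < 10:
        raise ValueError("each proteome needs at least 10 proteins")

    def _best_hits(source, target):
        arrays = {pid: seq_to_array(s) for pid, s in target.items()}
        indexes = {pid: kmer_index(s, k) for pid, s in target.items()}
        hits = {}
        for qid, qseq in source.items():
            best = (0.0, None)
            for tid, tseq in target.items():
                matches, overlap, _ = best_gapless_match_indexed(
                    qseq, arrays[tid], indexes[tid], k, step=1, top=2)
                if overlap == 0:
                    continue
                ident = matches / min(len(qseq), len(tseq))
                if ident > best[0]:
                    best = (ident, tid)
            if best[1] is not None:
                hits[qid] = best
        return hits

    ab = _best_hits(proteome_a, proteome_b)
    ba = _best_hits(proteome_b, proteome_a)
    identities = [ident for qid, (ident, tid) in ab.items()
                  if tid in ba and ba[tid][1] == qid]
    if len(identities) < min_rbh:
        return None
    return 100.0 * float(np.mean(identities))


def dereplicate(genomes: list[GenomeRecord], ani_threshold: float = 0.99,
                **ani_kwargs) -> ClusterSet:
    """Greedy centroid dereplication at an ANI threshold (0.99 or 0.95).

    Genomes are visited by descending quality score (ties by genome_id);
    each joins the first representative whose symmetrised ANI reaches the
    threshold, else founds its own cluster.  Undefined ANI counts as below
    threshold, so unrelated genomes never merge.
    """
    ordered = sorted(genomes, key=lambda g: (-(g.quality_score or -np.inf), g.genome_id))
    clusters: list[tuple[GenomeRecord, list[str]]] = []
    for g in ordered:
        for rep, members in clusters:
            value = symmetric_ani(g.sequence, rep.sequence, **ani_kwargs)
            if value is not None and value / 100.0 >= ani_threshold:
                members.append(g.genome_id)
                break
        else:
            clusters.append((g, [g.genome_id]))
    return ClusterSet(clusters=[(rep.genome_id, members) for rep, members in clusters],
                      threshold=ani_threshold)


def genus_cluster(aai_matrix: pd.DataFrame, threshold: float = 0.60) -> ClusterSet:
    """Single-linkage genus clusters: components over AAI > threshold edges.

    *aai_matrix* is symmetric, in percent (NaN = undefined).  The
    representative of each component is its lexicographically first member.
    """
    graph = nx.Graph()
    graph.add_nodes_from(aai_matrix.index)
    for a, b in itertools.combinations(aai_matrix.index, 2):
        value = aai_matrix.loc[a, b]
        if pd.notna(value) and value / 100.0 > threshold:
            graph.add_edge(a, b)
    clusters = [(min(comp), sorted(comp)) for comp in nx.connected_components(graph)]
    clusters.sort()
    return ClusterSet(clusters=clusters, threshold=threshold)


def classify_uniqueness(level: str,
                        subjects: list[str],
                        best_reference_ani: Mapping[str, float | None] | None = None,
                        nsc_clusters: ClusterSet | None = None,
                        nsc_ids: set[str] | None = None,
                        genus_clusters: ClusterSet | None = None,
                        reference_genus_label: Mapping[str, str | None] | None = None
                        ) -> list[UniquenessCall]:
    """Uniqueness calls against a reference database and the NSC genome set.

    strain / species levels: a subject genome is *not* unique vs the
    reference database when its best reference ANI strictly exceeds 99%
    (strain) or 95% (species); it is not unique vs NSC when it co-clusters
    with an NSC genome at the level's ANI threshold (``nsc_clusters`` built
    over own + NSC genomes, ``nsc_ids`` naming the NSC members).

    genus level: a cluster (identified by its representative in
    ``genus_clusters``) is not unique vs the reference database when any
    member carries a reference genus label, and not unique vs NSC when any
    member is an NSC genome.

    A missing comparison yields ``None`` (indeterminate), never a silent
    "unique".
    """
    thresholds = {"strain": 99.0, "species": 95.0}
    calls: list[UniquenessCall] = []
    if level in thresholds:
        cutoff = thresholds[level]
        best_reference_ani = best_reference_ani or {}
        for gid in subjects:
            if gid not in best_reference_ani:
                ref_unique = None
            else:
                value = best_reference_ani[gid]
                ref_unique = True if value is None else not (value > cutoff)
            if nsc_clusters is None or nsc_ids is None:
                nsc_unique = None
            else:
                found = nsc_clusters.cluster_of(gid)
                if found is None:
                    nsc_unique = None
                else:
                    nsc_unique = not any(m in nsc_ids for m in found[1] if m != gid)
            calls.append(UniquenessCall(gid, level, ref_unique, nsc_unique))
    elif level == "genus":
        if genus_clusters is None:
            raise ValueError("genus level needs genus_clusters")
        reference_genus_label = reference_genus_label or {}
        nsc_ids = nsc_ids or set()
        for rep, members in genus_clusters.clusters:
            if rep not in subjects:
                continue
            labelled = [reference_genus_label.get(m) for m in members]
            if all(m not in reference_genus_label for m in members):
                ref_unique = None
            else:
                ref_unique = not any(bool(lbl) for lbl in labelled)
            nsc_unique = not any(m in nsc_ids for m in members)
            calls.append(UniquenessCall(rep, "genus", ref_unique, nsc_unique))
    else:
        raise ValueError(f"unknown level {level!r}")
    return calls


def cluster_frame(clusters: ClusterSet) -> pd.DataFrame:
    rows = [(rep, m) for rep, members in clusters.clusters for m in members]
    return pd.DataFrame(rows, columns=["representative", "member"])
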