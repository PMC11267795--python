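"""Non-redundant gene-catalogue construction.

ORFs are called with a naive six-frame maximal-ORF finder (ATG start,
TAA/TAG/TGA stop) rather than an HMM gene predictor; redundancy removal is
greedy longest-first clustering at 95% identity over 90% of the shorter
sequence, the CD-HIT contract.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._align import best_gapless_match

START = "ATG"
STOPS = {"TAA", "TAG", "TGA"}
_COMP = str.maketrans("ACGTN", "TGCAN")


@dataclass(frozen=True)
class GeneRecord:
    """A predicted ORF: 0-based half-open contig coordinates, stop included."""

    gene_id: str
    sequence: str
    contig: str
    start: int
    end: int
    strand: str

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass
class CatalogueCluster:
    representative: str
    members: list[str] = field(default_factory=list)
    representative_length: int = 0


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def _orfs_in_frame(seq: str, frame: int, min_len: int) -> list[tuple[int, int]]:
    """Maximal ORFs in one forward frame: first ATG after each stop, to the stop."""
    out = []
    start_candidate = None
    for i in range(frame, len(seq) - 2, 3):
        codon = seq[i : i + 3]
        if codon in STOPS:
            if start_candidate is not None and (i + 3 - start_candidate) >= min_len:
                out.append((start_candidate, i + 3))
            start_candidate = None
        elif codon == START and start_candidate is None:
            start_candidate = i
    return out


def predict_orfs(contig: str, min_len: int = 200, contig_id: str = "contig") -> list[GeneRecord]:
    """Call all maximal start-to-stop ORFs of length >= *min_len* on six frames.

    Coordinates are 0-based half-open on the input contig; reverse-strand
    ORFs report the coordinates of the region whose reverse complement is
    the gene.  Codons containing N never match a start or stop.
    """
    contig = contig.upper()
    if not set(contig) <= set("ACGTN"):
        raise ValueError("contig must be over the alphabet {A,C,G,T,N}")
    records = []
    n = len(contig)
    for strand, seq in (("+", contig), ("-", reverse_complement(contig))):
        for frame in range(3):
            for s, e in _orfs_in_frame(seq, frame, min_len):
                if strand == "+":
                    start, end = s, e
                else:
                    start, end = n - e, n - s
                records.append(GeneRecord(
                    gene_id=f"{contig_id}_{start}_{end}_{strand}",
                    sequence=seq[s:e], contig=contig_id,
                    start=start, end=end, strand=strand))
    records.sort(key=lambda r: (r.start, r.end, r.strand))
    return records


def _matches_cluster(gene: str, rep: str, identity: float, coverage: float,
                     k: int = 8) -> bool:
    """CD-HIT-style acceptance: identity over the shorter sequence, with
    the aligned overlap covering at least *coverage* of the shorter one."""
    shorter, longer = (gene, rep) if len(gene) <= len(rep) else (rep, gene)
    matches, overlap, _ = best_gapless_match(shorter, longer, k=k, top=5)
    if overlap < coverage * len(shorter):
        return False
    return matches >= identity * len(shorter)


def cluster_nonredundant(genes: list[GeneRecord], identity: float = 0.95,
                         coverage: float = 0.90) -> list[CatalogueCluster]:
    """Greedy longest-first clustering of genes into a non-redundant catalogue.

    Genes are visited longest first (ties by gene_id); each joins the first
    existing representative it matches at >= *identity* over >= *coverage*
    of the shorter sequence, otherwise it founds a new cluster.
    """
    if not 0 < identity <= 1 or not 0 < coverage <= 1:
        raise ValueError("identity and coverage must be in (0, 1]")
    ids = [g.gene_id for g in genes]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate gene_ids")

    ordered = sorted(genes, key=lambda g: (-g.length, g.gene_id))
    clusters: list[CatalogueCluster] = []
    reps: list[GeneRecord] = []
    for gene in ordered:
        for cluster, rep in zip(clusters, reps):
            if _matches_cluster(gene.sequence, rep.sequence, identity, coverage):
                cluster.members.append(gene.gene_id)
                break
        else:
            clusters.append(CatalogueCluster(
                representative=gene.gene_id, members=[gene.gene_id],
                representative_length=gene.length))
            reps.append(gene)
    return clusters


def gene_prevalence(counts: pd.DataFrame, core_fraction: float = 0.80) -> pd.DataFrame:
    """Label genes core/non-core by presence in >= *core_fraction* of samples.

    *counts* is genes x samples; presence means count > 0.  Returns a frame
    with ``prevalence`` (fraction of samples) and boolean ``core``.
    """
    if counts.shape[1] == 0:
        raise ValueError("no samples")
    if (counts.to_numpy() < 0).any():
        raise ValueError("counts must be nonnegative")
    prevalence = (counts > 0).mean(axis=1)
    out = pd.DataFrame({"prevalence": prevalence, "core": prevalence >= core_fraction})
    out.index.name = "gene_id"
    return out


def clusters_to_frame(clusters: list[CatalogueCluster]) -> pd.DataFrame:
    rows = [(c.representative, m) for c in clusters for m in c.members]
    return pd.DataFrame(rows, columns=["representative", "member"])
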