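"""Two-pass homolog-neighbourhood LCA taxonomy assignment and rank profiling.

A query gene is aligned against a protein reference twice.  Significant
first-pass hits (E-value < 1e-5) define, per query, a best E-value; the
second pass is then restricted to hits at E-values at or below that best
value — the homolog neighbourhood — and the query is assigned the lowest
common ancestor of the neighbourhood's lineages.  Abundance profiles at
each rank are length-normalised gene abundances summed over member genes,
with unassigned mass kept in an explicit ``unclassified`` bucket so that
per-sample totals are conserved.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Iterable, Mapping

import numpy as np
import pandas as pd

from .synthetic import RANKS

EVALUE_MAX = 1e-5
UNCLASSIFIED = "unclassified"


@dataclass
class TaxonomicAssignment:
    query_id: str
    lineage: tuple[str, ...]  # possibly truncated; empty tuple = unassigned
    neighbourhood_size: int

    @property
    def rank(self) -> str | None:
        return RANKS[len(self.lineage) - 1] if self.lineage else None


def filter_hits(hits: pd.DataFrame, evalue_max: float = EVALUE_MAX) -> pd.DataFrame:
    """Keep hits with E-value strictly below *evalue_max*; order preserved."""
    return hits[hits["evalue"] < evalue_max]


def best_first_pass_evalue(first_pass: pd.DataFrame) -> pd.Series:
    """Per-query minimum E-value over (already filtered) first-pass hits."""
    return first_pass.groupby("qseqid")["evalue"].min()


def neighbourhood(first_best: pd.Series, second_pass: pd.DataFrame
                  ) -> tuple[dict[str, pd.DataFrame], list[str]]:
    """Per-query second-pass hits at E-values <= the first-pass best.

    Queries present in the second pass but missing a first-pass best value
    are returned in the flagged list and skipped.
    """
    neighbourhoods: dict[str, pd.DataFrame] = {}
    flagged: list[str] = []
    for query, sub in second_pass.groupby("qseqid"):
        if query not in first_best.index:
            flagged.append(str(query))
            continue
        neighbourhoods[str(query)] = sub[sub["evalue"] <= first_best[query]]
    return neighbourhoods, flagged


def assign_lca(lineages: Iterable[tuple[str, ...]]) -> tuple[str, ...]:
    """Deepest rank prefix on which all lineages agree.

    An empty slot counts as disagreement at that rank, so the result is a
    (possibly empty) prefix of every input lineage.
    """
    lineages = list(lineages)
    if not lineages:
        raise ValueError("empty lineage set")
    prefix: list[str] = []
    for level in zip(*lineages):
        values = set(level)
        if len(values) != 1 or not next(iter(values)):
            break
        prefix.append(level[0])
    return tuple(prefix)


def assign_taxonomy(first_pass: pd.DataFrame, second_pass: pd.DataFrame,
                    lineage_lookup: Callable[[str], tuple[str, ...]],
                    evalue_max: float = EVALUE_MAX) -> list[TaxonomicAssignment]:
    """Full two-pass LCA pipeline.

    *lineage_lookup* maps a subject id to its 7-rank lineage.  Queries with
    an empty neighbourhood (all second-pass hits weaker than the first-pass
    best, or no significant hits at all) come back unassigned.
    """
    first = filter_hits(first_pass, evalue_max)
    second = filter_hits(second_pass, evalue_max)
    first_best = best_first_pass_evalue(first)
    neighbourhoods, _ = neighbourhood(first_best, second)

    assignments = []
    for query in first_best.index:
        hood = neighbourhoods.get(str(query))
        if hood is None or len(hood) == 0:
            assignments.append(TaxonomicAssignment(str(query), (), 0))
            continue
        lineages = {lineage_lookup(s) for s in hood["sseqid"]}
        assignments.append(TaxonomicAssignment(
            str(query), assign_lca(lineages), len(hood)))
    return assignments


def profile_taxa(counts: pd.DataFrame,
                 assignments: Iterable[TaxonomicAssignment],
                 gene_lengths: Mapping[str, float]) -> dict[str, pd.DataFrame]:
    """Per-rank relative abundance matrices from gene counts.

    Gene abundance in a sample is count/length normalised to sum to one
    over all genes; a taxon's abundance at a rank is the summed abundance
    of genes whose assignment reaches that rank, and the remainder goes to
    the ``unclassified`` row.  Zero-depth samples are dropped.

    Returns ``{rank: taxa x samples}``; each column sums to 1.
    """
    missing = [g for g in counts.index if g not in gene_lengths]
    if missing:
        raise ValueError(f"genes without lengths: {missing[:3]}")
    lengths = np.array([float(gene_lengths[g]) for g in counts.index])
    weights = counts.to_numpy(dtype=float) / lengths[:, None]
    depth = weights.sum(axis=0)
    keep = depth > 0
    weights = weights[:, keep] / depth[keep]
    samples = counts.columns[keep]

    by_query = {a.query_id: a.lineage for a in assignments}
    profiles: dict[str, pd.DataFrame] = {}
    for level, rank in enumerate(RANKS, start=1):
        labels = [
            ";".join(by_query.get(g, ())[:level])
            if len(by_query.get(g, ())) >= level else UNCLASSIFIED
            for g in counts.index
        ]
        frame = pd.DataFrame(weights, index=pd.Index(labels, name=rank), columns=samples)
        prof = frame.groupby(level=0, sort=True).sum()
        if UNCLASSIFIED not in prof.index:
            prof.loc[UNCLASSIFIED] = 0.0
        profiles[rank] = prof
    return profiles
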