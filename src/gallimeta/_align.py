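"""Gapless k-mer-seeded alignment primitives.

These back the gene-catalogue clustering and the ANI/AAI estimators.  All
comparisons are substitution-only: a shared k-mer proposes a relative offset
between the two sequences, and identity is counted position-wise over the
implied overlap.  Indels are out of scope (the synthetic genomes used for
testing mutate by substitution only), so no gapped extension is attempted.
"""

from __future__ import annotations

from collections import Counter, defaultdict

import numpy as np


def seq_to_array(seq: str) -> np.ndarray:
    return np.frombuffer(seq.encode("ascii"), dtype=np.uint8)


def kmer_index(seq: str, k: int) -> dict[str, list[int]]:
    """Map every k-mer of *seq* to the list of its start positions."""
    index: dict[str, list[int]] = defaultdict(list)
    for i in range(len(seq) - k + 1):
        index[seq[i : i + k]].append(i)
    return index


def candidate_offsets(query: str, index: dict[str, list[int]], k: int,
                      step: int = 1, top: int = 3) -> list[int]:
    """Offsets (target_start - query_start) voted by shared k-mers, best first."""
    votes: Counter[int] = Counter()
    for qpos in range(0, len(query) - k + 1, step):
        for tpos in index.get(query[qpos : qpos + k], ()):
            votes[tpos - qpos] += 1
    return [off for off, _ in votes.most_common(top)]


def overlap_identity(query_arr: np.ndarray, target_arr: np.ndarray,
                     offset: int) -> tuple[int, int]:
    """(matching positions, overlap length) when query is laid at *offset* on target."""
    qstart = max(0, -offset)
    qend = min(len(query_arr), len(target_arr) - offset)
    if qend <= qstart:
        return 0, 0
    q = query_arr[qstart:qend]
    t = target_arr[qstart + offset : qend + offset]
    return int((q == t).sum()), qend - qstart


def best_gapless_match(query: str, target: str, k: int,
                       step: int = 1, top: int = 3) -> tuple[int, int, int]:
    """Best (matches, overlap, offset) over k-mer-anchored offsets.

    Returns ``(0, 0, 0)`` when no k-mer is shared.  "Best" maximises the
    number of matching positions, which favours long well-conserved overlaps.
    """
    index = kmer_index(target, k)
    return best_gapless_match_indexed(query, seq_to_array(target), index, k, step, top)


def best_gapless_match_indexed(query: str, target_arr: np.ndarray,
                               index: dict[str, list[int]], k: int,
                               step: int = 1, top: int = 3) -> tuple[int, int, int]:
    offsets = candidate_offsets(query, index, k, step=step, top=top)
    if not offsets:
        return 0, 0, 0
    query_arr = seq_to_array(query)
    best = (0, 0, 0)
    for off in offsets:
        matches, overlap = overlap_identity(query_arr, target_arr, off)
        if matches > best[0]:
            best = (matches, overlap, off)
    return best
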