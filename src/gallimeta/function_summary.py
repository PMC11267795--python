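"""Per-genome functional summaries: CAZymes, pathways, SCFA sets, growth class."""

from __future__ import annotations

import re
from dataclasses import dataclass
from importlib import resources
from typing import Iterable, Mapping

import pandas as pd
import yaml

CAZY_PATTERN = re.compile(r"^(GH|GT|PL|CE|CBM|AA)[0-9]+$")
SCFA_VOCABULARY = frozenset({"acetate", "butyrate", "propionate", "lactate"})
HIGH_RICHNESS_CUTOFF = 250  # CAZy genes; genomes above this are flagged


@dataclass(frozen=True)
class PathwayDef:
    name: str
    steps: tuple[str, ...]
    key_gene: str | None = None

    def __post_init__(self):
        if len(set(self.steps)) != len(self.steps):
            raise ValueError("pathway steps must be unique")


def load_pathways(path=None) -> dict[str, PathwayDef]:
    """Load pathway definitions from YAML (packaged defaults when *path* is None)."""
    if path is None:
        text = resources.files("gallimeta").joinpath("data/pathways.yaml").read_text()
    else:
        text = open(path).read()
    raw = yaml.safe_load(text)
    out = {}
    for name, spec in raw.items():
        out[name] = PathwayDef(name=name, steps=tuple(spec["steps"]),
                               key_gene=spec.get("key_gene"))
    return out


def cazyme_counts(annotations: pd.DataFrame) -> pd.DataFrame:
    """CAZy richness per genome.

    Counts rows with ``annotation_class == "cazy"``: total CAZy genes,
    unique families, total glycoside-hydrolase (GH) genes and unique GH
    families.  A malformed CAZy label raises with its row position.
    Genomes above the 250-gene cutoff are flagged ``high_richness``.
    """
    cazy = annotations[annotations["annotation_class"] == "cazy"]
    bad = cazy[~cazy["label"].str.match(CAZY_PATTERN)]
    if len(bad):
        pos = bad.index[0]
        raise ValueError(f"malformed CAZy label {bad.loc[pos, 'label']!r} at row {pos}")
    rows = []
    for gid in annotations["genome_id"].unique():
        labels = cazy.loc[cazy["genome_id"] == gid, "label"]
        gh = labels[labels.str.startswith("GH")]
        rows.append({
            "genome_id": gid,
            "total_cazy_genes": len(labels),
            "unique_cazy_families": labels.nunique(),
            "total_gh_genes": len(gh),
            "unique_gh_families": gh.nunique(),
        })
    out = pd.DataFrame(rows).set_index("genome_id")
    out["high_richness"] = out["total_cazy_genes"] > HIGH_RICHNESS_CUTOFF
    return out


def pathway_completeness(annotations: pd.DataFrame, pathway: PathwayDef) -> pd.DataFrame:
    """Per-genome pathway step counts and completeness flags.

    ``complete``: all steps present; ``partial``: at least four steps.  When
    the pathway declares a key gene (methanogenesis: mcr) both flags
    additionally require it — the key gene is tracked separately from the
    steps, not counted as one of them.
    """
    steps = set(pathway.steps)
    prefix = f"{pathway.name}:"
    sub = annotations[(annotations["annotation_class"] == "pathway_step")
                      & annotations["label"].str.startswith(prefix)]
    rows = []
    for gid in annotations["genome_id"].unique():
        labels = {l[len(prefix):] for l in sub.loc[sub["genome_id"] == gid, "label"]}
        present = labels & steps
        has_key = pathway.key_gene is None or pathway.key_gene in labels
        rows.append({
            "genome_id": gid,
            "steps_present": len(present),
            "key_gene": pathway.key_gene in labels if pathway.key_gene else None,
            "complete": len(present) == len(pathway.steps) and has_key,
            "partial": len(present) >= 4 and has_key,
        })
    return pd.DataFrame(rows).set_index("genome_id")


def scfa_intersections(potentials: Mapping[str, Iterable[str]],
                       min_set: int = 10) -> pd.DataFrame:
    """Exclusive (UpSet-style) intersection counts of SCFA production sets.

    Every genome belongs to exactly one pattern (its full set, ``none`` when
    empty), so pattern counts partition the genome set; patterns below
    *min_set* are retained in the table but marked unreported.
    """
    counts: dict[frozenset, int] = {}
    for gid, labels in potentials.items():
        labels = frozenset(labels)
        unknown = labels - SCFA_VOCABULARY
        if unknown:
            raise ValueError(f"unknown SCFA label(s) {sorted(unknown)} for {gid!r}")
        counts[labels] = counts.get(labels, 0) + 1
    rows = [{"pattern": "+".join(sorted(p)) if p else "none",
             "size": len(p), "count": c, "reported": c >= min_set}
            for p, c in counts.items()]
    out = pd.DataFrame(rows, columns=["pattern", "size", "count", "reported"])
    return out.sort_values(["count", "pattern"], ascending=[False, True]).reset_index(drop=True)


def growth_class(doubling_time: float) -> str:
    """Copiotroph (< 5 h doubling time) vs oligotroph (> 5 h).

    Exactly 5 h is classed oligotroph by convention (the defining
    inequalities are strict on both sides and leave the boundary open).
    """
    if doubling_time <= 0:
        raise ValueError("doubling time must be positive")
    return "copiotroph" if doubling_time < 5.0 else "oligotroph"
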