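"""Synthetic inputs with known ground truth for the whole pipeline.

Every input the analysis consumes can be generated here: a balanced 7-rank
taxonomy, genome sets with controlled substitution divergence (and planted
protein-coding genes for proteome comparisons), Dirichlet-multinomial
sample x genus count matrices with latent enterotype structure tied to an
altitude gradient, two-pass protein-alignment hit tables with an optional
decoy fraction, and per-genome annotation/quality tables.

Divergence parameters are *pairwise*: two genomes generated at divergence
``d`` differ at a fraction ``d`` of their sites.  This is achieved by giving
each sibling its own disjoint set of mutated sites (each of size ``d/2``),
so the observed mismatch fraction of a pair is exact up to rounding rather
than a random variable.  Mutations are substitutions only; there are no
indels, which keeps alignment trivial for the estimators under test while
still exercising their identity arithmetic.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from Bio.Seq import Seq

RANKS = ("domain", "phylum", "class", "order", "family", "genus", "species")
RANK_PREFIXES = dict(zip(RANKS, ("d__", "p__", "c__", "o__", "f__", "g__", "s__")))

#: sense codons (no stop codons) used to fill planted genes
_STOPS = {"TAA", "TAG", "TGA"}
_SENSE_CODONS = [a + b + c for a in "ACGT" for b in "ACGT" for c in "ACGT"
                 if a + b + c not in _STOPS]

SCFA_VOCABULARY = ("acetate", "butyrate", "propionate", "lactate")

#: SCFA production-potential patterns and sampling weights; single acetate
#: production is by far the most common, followed by acetate+lactate and
#: acetate+butyrate co-production.
_SCFA_PATTERNS = [
    (("acetate",), 0.40),
    (("acetate", "lactate"), 0.20),
    (("acetate", "butyrate"), 0.15),
    (("acetate", "propionate"), 0.08),
    (("acetate", "butyrate", "lactate"), 0.05),
    (("butyrate",), 0.04),
    ((), 0.08),
]


@dataclass
class SyntheticTruth:
    """Ground-truth labels recorded by the generators.

    Fields are filled by whichever generator produced the object; the rest
    stay empty.  ``divergence`` keys are frozensets of two genome ids and the
    values are realised (counted, not nominal) pairwise mismatch fractions.
    """

    enterotype: dict[str, int] = field(default_factory=dict)
    climate_zone: dict[str, int] = field(default_factory=dict)
    divergence: dict[frozenset, float] = field(default_factory=dict)
    gene_taxon: dict[str, str] = field(default_factory=dict)
    #: genome -> list of (start, end) coordinates of planted genes (+ strand)
    gene_coords: dict[str, list[tuple[int, int]]] = field(default_factory=dict)
    site_of_sample: dict[str, str] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# taxonomy
# ---------------------------------------------------------------------------

_SYLLABLES = ["ba", "ce", "di", "fo", "ga", "hu", "ki", "lo", "mu", "ne",
              "pa", "ri", "so", "tu", "ve", "za"]


def _make_name(rng: np.random.Generator, n_syll: int = 3) -> str:
    return "".join(rng.choice(_SYLLABLES, size=n_syll)).capitalize()


def gen_taxonomy(n_per_rank: Sequence[int], seed: int) -> pd.DataFrame:
    """Generate a balanced 7-rank taxonomy.

    Parameters
    ----------
    n_per_rank
        Seven positive integers: the number of children each node has at
        domain, phylum, ..., species level (the first entry is the number of
        domains).  The number of leaf taxa is their product.
    seed
        Seed for the name generator; identical seeds give identical tables.

    Returns
    -------
    DataFrame indexed by ``taxon_id`` with one prefixed column per rank
    (``d__``/``p__``/.../``s__``).
    """
    n_per_rank = list(n_per_rank)
    if len(n_per_rank) != len(RANKS):
        raise ValueError(f"n_per_rank must have {len(RANKS)} entries")
    if any(int(n) < 1 for n in n_per_rank):
        raise ValueError("all rank counts must be positive")

    rng = np.random.default_rng(seed)
    lineages: list[list[str]] = [[]]
    for rank, n_children in zip(RANKS, n_per_rank):
        prefix = RANK_PREFIXES[rank]
        new: list[list[str]] = []
        for parent in lineages:
            for i in range(int(n_children)):
                name = f"{prefix}{_make_name(rng)}_{len(new):03d}"
                new.append(parent + [name])
        lineages = new

    table = pd.DataFrame(lineages, columns=list(RANKS))
    table.index = [f"T{i:05d}" for i in range(len(table))]
    table.index.name = "taxon_id"
    return table


def lineage_of(taxonomy: pd.DataFrame, taxon_id: str) -> tuple[str, ...]:
    return tuple(taxonomy.loc[taxon_id, list(RANKS)])


# ---------------------------------------------------------------------------
# genomes
# ---------------------------------------------------------------------------

def _random_genome_with_genes(rng: np.random.Generator, length: int,
                              n_genes: int, gene_length: int
                              ) -> tuple[str, list[tuple[int, int]]]:
    """Random genome with *n_genes* planted coding genes (ATG ... TAA, + strand)."""
    if gene_length % 3 or gene_length < 9:
        raise ValueError("gene_length must be a multiple of 3 and >= 9")
    spacing = length // n_genes
    if spacing <= gene_length:
        raise ValueError("genes do not fit: reduce n_genes or gene_length")
    seq = rng.choice(list("ACGT"), size=length)
    coords = []
    for i in range(n_genes):
        start = i * spacing
        codons = rng.choice(_SENSE_CODONS, size=gene_length // 3 - 2)
        gene = "ATG" + "".join(codons) + "TAA"
        seq[start : start + gene_length] = list(gene)
        coords.append((start, start + gene_length))
    return "".join(seq), coords


def _mutate(seq_arr: np.ndarray, sites: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Substitute every listed site with a uniformly chosen *different* base."""
    out = seq_arr.copy()
    bases = np.array(list("ACGT"))
    for pos in sites:
        choices = bases[bases != out[pos]]
        out[pos] = rng.choice(choices)
    return out


def gen_genomes(taxonomy: pd.DataFrame,
                strain_divergence: float = 0.02,
                species_divergence: float = 0.08,
                genome_length: int = 20_000,
                n_strains: int = 1,
                n_genes: int = 30,
                gene_length: int = 300,
                seed: int = 0) -> tuple[dict[str, str], SyntheticTruth]:
    """Generate genomes for every species in *taxonomy*, plus strains.

    Species within a genus share a genus ancestor and differ pairwise by
    ``species_divergence``; strains within a species differ pairwise by
    ``strain_divergence``.  Genomes from different genera are unrelated
    random sequences.  The defaults place strain pairs inside the
    (95%, 99%) ANI band and species pairs below 95% ANI, matching the usual
    strain/species ANI conventions.

    Returns ``({genome_id: sequence}, truth)`` where truth records realised
    pairwise divergences (within genera) and planted gene coordinates.
    """
    if not 0 <= strain_divergence < species_divergence < 0.5:
        raise ValueError("need 0 <= strain_divergence < species_divergence < 0.5")
    if genome_length < 10_000:
        raise ValueError("genome_length < 10 kb: too little material for fragment ANI")

    rng = np.random.default_rng(seed)
    truth = SyntheticTruth()
    genomes: dict[str, str] = {}
    genus_members: dict[str, list[str]] = {}

    by_genus = taxonomy.groupby("genus", sort=True)
    for genus, sub in by_genus:
        species_ids = sorted(sub.index)
        n_species = len(species_ids)
        half_sp = int(round(genome_length * species_divergence / 2))
        half_st = int(round(genome_length * strain_divergence / 2))
        if n_species * half_sp + n_strains * half_st > genome_length:
            raise ValueError("divergence tiers exceed available sites")

        ancestor, coords = _random_genome_with_genes(rng, genome_length, n_genes, gene_length)
        anc_arr = np.array(list(ancestor))

        # disjoint per-species mutation sets -> exact pairwise species divergence
        sp_sites = rng.choice(genome_length, size=n_species * half_sp, replace=False)
        members: list[str] = []
        for i, sp in enumerate(species_ids):
            sp_arr = _mutate(anc_arr, sp_sites[i * half_sp : (i + 1) * half_sp], rng)
            # disjoint per-strain sets within the species -> exact strain divergence
            st_sites = rng.choice(genome_length, size=n_strains * half_st, replace=False)
            for j in range(n_strains):
                gid = f"{sp}_s{j + 1}"
                arr = _mutate(sp_arr, st_sites[j * half_st : (j + 1) * half_st], rng)
                genomes[gid] = "".join(arr)
                truth.gene_coords[gid] = coords
                members.append(gid)
        genus_members[str(genus)] = members

    # realised divergences, counted directly on the sequences
    for members in genus_members.values():
        for a, b in itertools.combinations(members, 2):
            arr_a = np.frombuffer(genomes[a].encode(), dtype=np.uint8)
            arr_b = np.frombuffer(genomes[b].encode(), dtype=np.uint8)
            truth.divergence[frozenset((a, b))] = float((arr_a != arr_b).mean())

    return genomes, truth


def proteomes_from_genomes(genomes: Mapping[str, str],
                           truth: SyntheticTruth) -> dict[str, dict[str, str]]:
    """Translate the planted genes of each genome into its proteome.

    Substitutions may have created premature stops in mutated copies; the
    raw translation (with ``*``) is kept except for the terminal stop, so
    ortholog pairs remain position-comparable.
    """
    proteomes: dict[str, dict[str, str]] = {}
    for gid, seq in genomes.items():
        coords = truth.gene_coords.get(gid)
        if coords is None:
            raise KeyError(f"no planted gene coordinates for genome {gid!r}")
        prot = {}
        for i, (start, end) in enumerate(coords):
            aa = str(Seq(seq[start:end]).translate())
            prot[f"{gid}_p{i:03d}"] = aa.rstrip("*")
        proteomes[gid] = prot
    return proteomes


# ---------------------------------------------------------------------------
# community (counts + environment)
# ---------------------------------------------------------------------------

#: the three enterotype signatures: each enterotype is driven by one
#: discriminating genus and supported by four further signature genera
DEFAULT_DISCRIMINATING = {1: "Alistipes", 2: "Bacteroides", 3: "Prevotella"}
_SIGNATURES = {
    1: ["Treponema", "Brachyspira", "Mucispirillum", "Muribaculum"],
    2: ["Lachnoclostridium", "Clostridium", "Blautia", "Pseudoflavonifractor"],
    3: ["Megamonas", "Faecalibacterium", "Olsenella", "Lactobacillus"],
}

#: zone -> (mean altitude m, enterotype mixing weights); zone 1 is the
#: high-altitude zone and is strongly enriched for enterotype 3
DEFAULT_ZONES = {
    1: (3100.0, (0.19, 0.19, 0.62)),
    2: (2400.0, (0.40, 0.40, 0.20)),
    3: (1800.0, (0.40, 0.40, 0.20)),
    4: (1300.0, (0.45, 0.40, 0.15)),
    5: (1000.0, (0.45, 0.40, 0.15)),
}


def default_enterotype_profiles(discriminating_fold: float = 2.5,
                                signature_fold: float = 1.8,
                                off_signature_fold: float = 0.45,
                                n_genera: int = 40) -> pd.DataFrame:
    """Three genus mean-abundance profiles (columns 1..3, rows = genera).

    Each enterotype boosts its own discriminating genus by
    ``discriminating_fold`` and its supporting signature genera by
    ``signature_fold``, and carries the *other* enterotypes' signature
    genera at ``off_signature_fold`` of baseline — enterotypes of real
    communities differ across many genera, not one.  The structure is
    symmetric across the three groups, so the renormalisation constants are
    equal and a discriminating genus is exactly
    ``discriminating_fold / off_signature_fold`` times (in particular, at
    least ``discriminating_fold`` times) more abundant in its own
    enterotype than in any other.
    """
    if discriminating_fold < 1:
        raise ValueError("discriminating_fold must be >= 1")
    named = list(DEFAULT_DISCRIMINATING.values()) + sum(_SIGNATURES.values(), [])
    n_filler = n_genera - len(named)
    if n_filler < 0:
        raise ValueError(f"n_genera must be >= {len(named)}")
    genera = named + [f"Genus{i:02d}" for i in range(n_filler)]

    base = pd.Series(0.0, index=genera)
    base[list(DEFAULT_DISCRIMINATING.values())] = 8.0
    for sig in _SIGNATURES.values():
        base[sig] = 3.0
    base.iloc[len(named):] = np.exp(-np.arange(n_filler) / 8.0) * 4.0

    profiles = {}
    for et, disc in DEFAULT_DISCRIMINATING.items():
        p = base.copy()
        for other, other_disc in DEFAULT_DISCRIMINATING.items():
            if other != et:
                p[_SIGNATURES[other]] *= off_signature_fold
                p[other_disc] *= off_signature_fold
        p[_SIGNATURES[et]] *= signature_fold
        p[disc] *= discriminating_fold
        profiles[et] = p / p.sum()
    return pd.DataFrame(profiles)


def gen_community(n_samples: int = 90,
                  enterotype_profiles: pd.DataFrame | None = None,
                  discriminating_fold: float = 2.5,
                  dispersion: float = 100.0,
                  depth: int = 20_000,
                  env_link: Mapping[int, Sequence[float]] | None = None,
                  n_sites: int = 26,
                  seed: int = 0) -> tuple[pd.DataFrame, pd.DataFrame, SyntheticTruth]:
    """Simulate a sample x genus count matrix with latent enterotypes.

    Per sample: a site (hence climate zone) is assigned; an enterotype is
    drawn from the zone's mixing weights; the genus composition is drawn
    from a Dirichlet centred on the enterotype profile with concentration
    ``dispersion * profile``; counts are multinomial at exactly *depth*
    reads.  ``dispersion=inf`` collapses the Dirichlet to the profile.

    Returns ``(counts genera x samples, environment table, truth)``.
    """
    if enterotype_profiles is None:
        enterotype_profiles = default_enterotype_profiles(discriminating_fold)
    profiles = enterotype_profiles
    if not np.allclose(profiles.sum(axis=0), 1.0, atol=1e-8):
        raise ValueError("each enterotype profile must sum to 1")
    if discriminating_fold < 1:
        raise ValueError("discriminating_fold must be >= 1")
    n_genera = profiles.shape[0]
    if depth < n_genera:
        raise ValueError("depth must be at least the number of genera")

    rng = np.random.default_rng(seed)
    zone_table = DEFAULT_ZONES if env_link is None else {
        z: (DEFAULT_ZONES[z][0], tuple(env_link[z])) for z in DEFAULT_ZONES
    }
    enterotypes = list(profiles.columns)

    truth = SyntheticTruth()
    samples = [f"S{i:03d}" for i in range(n_samples)]
    counts = np.zeros((n_genera, n_samples), dtype=int)
    env_rows = []
    zones = sorted(zone_table)
    for i, sample in enumerate(samples):
        site = i % n_sites
        zone = zones[site % len(zones)]
        alt_mean, weights = zone_table[zone]
        weights = np.asarray(weights, dtype=float)
        et = enterotypes[rng.choice(len(enterotypes), p=weights / weights.sum())]
        p = profiles[et].to_numpy()
        comp = p if np.isinf(dispersion) else rng.dirichlet(dispersion * p)
        counts[:, i] = rng.multinomial(depth, comp)

        truth.enterotype[sample] = et
        truth.climate_zone[sample] = zone
        truth.site_of_sample[sample] = f"site{site:02d}"
        altitude = alt_mean + rng.normal(0, 100.0)
        env_rows.append({
            "sample": sample,
            "site": f"site{site:02d}",
            "altitude": altitude,
            "annual_mean_temperature": 28.0 - 0.006 * altitude + rng.normal(0, 0.5),
            "annual_precipitation": 600.0 + 0.2 * altitude + rng.normal(0, 50.0),
            "precip_driest_quarter": 10.0 + 0.01 * altitude + rng.normal(0, 3.0),
        })

    env = pd.DataFrame(env_rows).set_index("sample")
    # remaining covariates: uncorrelated with zone by default
    for col in ["bio2", "bio3", "bio13", "bio14", "bio15", "bio18", "bio19",
                "CULT", "FOR", "SNDPPT", "SLTPPT", "CRFVOL", "BLDFIE",
                "CECSOL", "ORCDRC", "PHIHOX", "WATCAP"]:
        env[col] = rng.normal(0, 1, size=n_samples)
    for col in ["Wheat", "Maize", "Barley", "Millet", "Teff", "Ingera"]:
        env[col] = rng.integers(0, 2, size=n_samples)

    count_df = pd.DataFrame(counts, index=profiles.index, columns=samples)
    return count_df, env, truth


# ---------------------------------------------------------------------------
# hit tables
# ---------------------------------------------------------------------------

def gen_hit_tables(gene_taxa: Mapping[str, str],
                   taxonomy: pd.DataFrame,
                   decoy_rate: float = 0.0,
                   n_neighbours: int = 4,
                   seed: int = 0) -> tuple[pd.DataFrame, pd.DataFrame, SyntheticTruth]:
    """Simulate first- and second-pass protein alignment hit tables.

    ``gene_taxa`` maps every query gene to its true source species (a
    ``taxon_id`` of *taxonomy*).  The first pass holds the true hit at the
    lowest E-value plus weaker same-genus neighbours; the second pass holds
    the homolog neighbourhood: same-genus hits at E-values at or below the
    first-pass best, weaker homologs above it, and (at ``decoy_rate`` per
    gene) an off-lineage decoy at an E-value of at least 1e-5, i.e. above
    the downstream significance cutoff.

    Subject ids are ``<taxon_id>|p<k>``, so the source taxon of any subject
    is recoverable from the id prefix.
    """
    if len(taxonomy) == 0:
        raise ValueError("reference taxonomy is empty")
    unknown = set(gene_taxa.values()) - set(taxonomy.index)
    if unknown:
        raise ValueError(f"gene source taxa missing from taxonomy: {sorted(unknown)[:3]}")

    # decoys draw from their own stream so the base tables are identical
    # for any decoy_rate given the same seed
    hit_seed, decoy_seed = np.random.SeedSequence(seed).spawn(2)
    rng = np.random.default_rng(hit_seed)
    rng_decoy = np.random.default_rng(decoy_seed)
    genus_of = taxonomy["genus"]
    by_genus = {g: sorted(sub.index) for g, sub in taxonomy.groupby("genus")}
    other_genera = sorted(taxonomy.index)

    def _row(query, subject, evalue, pident):
        return {"qseqid": query, "sseqid": subject, "pident": round(pident, 1),
                "length": 250, "mismatch": int(250 * (1 - pident / 100)),
                "gapopen": 0, "qstart": 1, "qend": 250, "sstart": 1, "send": 250,
                "evalue": evalue, "bitscore": round(500 * pident / 100, 1)}

    first_rows, second_rows = [], []
    truth = SyntheticTruth(gene_taxon=dict(gene_taxa))
    for gene, taxon in gene_taxa.items():
        genus = genus_of[taxon]
        siblings = by_genus[genus]
        best_e = 10.0 ** rng.uniform(-80, -40)
        first_rows.append(_row(gene, f"{taxon}|p{rng.integers(100):02d}", best_e, 98.0))
        for n in range(n_neighbours):
            sib = siblings[(siblings.index(taxon) + 1 + n) % len(siblings)]
            e = 10.0 ** rng.uniform(-35, -10)
            first_rows.append(_row(gene, f"{sib}|p{rng.integers(100):02d}", e, 85.0))

        # neighbourhood: same-genus hits at or below the first-pass best E-value
        second_rows.append(_row(gene, f"{taxon}|p00", best_e, 98.0))
        for n in range(n_neighbours):
            sib = siblings[(siblings.index(taxon) + 1 + n) % len(siblings)]
            e = 10.0 ** rng.uniform(-120, np.log10(best_e))
            second_rows.append(_row(gene, f"{sib}|p{rng.integers(100):02d}", e, 90.0))
        # weaker homologs, rejected by the neighbourhood rule
        far = other_genera[rng.integers(len(other_genera))]
        second_rows.append(_row(gene, f"{far}|p99", 10.0 ** rng.uniform(-30, -10), 60.0))
        # decoy above the 1e-5 significance cutoff
        if rng_decoy.random() < decoy_rate:
            decoy = other_genera[rng_decoy.integers(len(other_genera))]
            second_rows.append(_row(gene, f"{decoy}|decoy",
                                    10.0 ** rng_decoy.uniform(-4.9, -2), 40.0))

    first = pd.DataFrame(first_rows)
    second = pd.DataFrame(second_rows)
    return first, second, truth


def subject_taxon(subject_id: str) -> str:
    """Source taxon of a synthetic reference protein id (``taxon|pNN``)."""
    return subject_id.split("|", 1)[0]


# ---------------------------------------------------------------------------
# annotations + quality metrics
# ---------------------------------------------------------------------------

DEFAULT_CAZY_FAMILIES = [
    "GH2", "GH3", "GH13", "GH25", "GH31", "GH43", "GH51", "GH77", "GH86",
    "GT2", "GT4", "GT35", "GT51", "CE1", "CE4", "CE10", "PL1", "PL9",
    "CBM13", "CBM48", "CBM50", "AA3", "AA6",
]


def gen_annotations(genome_phyla: Mapping[str, str],
                    cazy_rates: Mapping[str, float] | float = 60.0,
                    pathway_spec: Mapping[str, Sequence[str]] | None = None,
                    pathway_key_genes: Mapping[str, str] | None = None,
                    designations: Mapping[str, Mapping[str, str]] | None = None,
                    seed: int = 0) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate per-genome annotations and assembly-quality metrics.

    ``genome_phyla`` maps genome id -> phylum (used to pick the CAZy rate).
    CAZy gene totals are Poisson with the phylum's mean, spread over the
    default family list.  ``designations`` may force a pathway status per
    genome (``"complete"``, ``"partial"``, ``"none"``); unforced genomes
    draw a status at 10% / 15% / 75%.  Completeness is drawn on [70, 100]
    and contamination on [0, 8], so the population straddles the 80%/5%
    quality filter.

    Returns ``(annotation table, quality table)``; annotation rows are
    (genome_id, gene_id, annotation_class, label) with classes ``cazy``,
    ``pathway_step`` and ``scfa_potential``.
    """
    if pathway_spec is None:
        pathway_spec = {"methanogenesis": [f"step{i}" for i in range(1, 9)]}
        pathway_key_genes = {"methanogenesis": "mcr"}
    pathway_key_genes = pathway_key_genes or {}
    if isinstance(cazy_rates, (int, float)):
        rates = {ph: float(cazy_rates) for ph in set(genome_phyla.values())}
    else:
        rates = dict(cazy_rates)
    if any(r < 0 for r in rates.values()):
        raise ValueError("CAZy rates must be >= 0")
    designations = designations or {}
    for gid, spec in designations.items():
        for pw in spec:
            if pw not in pathway_spec:
                raise ValueError(f"unknown pathway {pw!r} designated for {gid!r}")

    rng = np.random.default_rng(seed)
    fam_weights = rng.dirichlet(np.ones(len(DEFAULT_CAZY_FAMILIES)) * 2.0)
    rows, quality_rows = [], []
    patterns = [p for p, _ in _SCFA_PATTERNS]
    weights = np.array([w for _, w in _SCFA_PATTERNS])

    for gid, phylum in genome_phyla.items():
        counter = itertools.count()
        n_cazy = rng.poisson(rates[phylum]) if rates[phylum] > 0 else 0
        if n_cazy:
            fam_counts = rng.multinomial(n_cazy, fam_weights)
            for fam, c in zip(DEFAULT_CAZY_FAMILIES, fam_counts):
                for _ in range(c):
                    rows.append((gid, f"{gid}_g{next(counter):04d}", "cazy", fam))

        for pw, steps in pathway_spec.items():
            status = designations.get(gid, {}).get(pw)
            if status is None:
                status = rng.choice(["complete", "partial", "none"], p=[0.10, 0.15, 0.75])
            if status == "complete":
                chosen, key = list(steps), True
            elif status == "partial":
                k = int(rng.integers(4, len(steps)))
                chosen = list(rng.choice(steps, size=k, replace=False))
                key = True
            else:
                k = int(rng.integers(0, 4))
                chosen = list(rng.choice(steps, size=min(k, len(steps)), replace=False))
                key = False
            for step in chosen:
                rows.append((gid, f"{gid}_g{next(counter):04d}", "pathway_step", f"{pw}:{step}"))
            if key and pw in pathway_key_genes:
                rows.append((gid, f"{gid}_g{next(counter):04d}", "pathway_step",
                             f"{pw}:{pathway_key_genes[pw]}"))

        for scfa in patterns[rng.choice(len(patterns), p=weights / weights.sum())]:
            rows.append((gid, f"{gid}_g{next(counter):04d}", "scfa_potential", scfa))

        quality_rows.append({"genome_id": gid,
                             "completeness": float(rng.uniform(70, 100)),
                             "contamination": float(rng.uniform(0, 8))})

    annotations = pd.DataFrame(rows, columns=["genome_id", "gene_id",
                                              "annotation_class", "label"])
    quality = pd.DataFrame(quality_rows).set_index("genome_id")
    return annotations, quality
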