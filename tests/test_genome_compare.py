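"""Quality filter, ANI/AAI estimators, dereplication, genus clusters, novelty."""

import itertools

import numpy as np
import pandas as pd
import pytest

from gallimeta import genome_compare as gc
from gallimeta import synthetic as syn


class TestQualityFilter:
    @pytest.mark.parametrize("completeness,contamination,passes", [
        (80.0, 5.0, True),   # inclusive boundary
        (79.9, 1.0, False),
        (95.0, 6.0, False),
        (100.0, 0.0, True),
    ])
    def test_boundaries(self, completeness, contamination, passes):
        rec = gc.GenomeRecord("g", "", completeness, contamination)
        passing, rejected = gc.quality_filter([rec])
        assert (len(passing) == 1) is passes

    def test_missing_metric_rejected_with_reason(self):
        rec = gc.GenomeRecord("g", "", None, 1.0)
        passing, rejected = gc.quality_filter([rec])
        assert passing == []
        assert rejected[0] == ("g", "missing quality metric")

    def test_quality_score(self):
        assert gc.GenomeRecord("g", "", 90.0, 2.0).quality_score == 80.0


@pytest.fixture(scope="module")
def genus_genomes():
    """One genus, 2 species (8% apart), 2 strains each (2% apart)."""
    tax = syn.gen_taxonomy([1, 1, 1, 1, 1, 1, 2], seed=21)
    return syn.gen_genomes(tax, 0.02, 0.08, n_strains=2, seed=21)


class TestAni:
    def test_self_identity(self, genus_genomes):
        genomes, _ = genus_genomes
        seq = next(iter(genomes.values()))
        res = gc.ani(seq, seq)
        assert res.ani == pytest.approx(100.0)
        assert res.aligned_fraction == pytest.approx(1.0)

    def test_two_percent_divergence(self, genus_genomes):
        genomes, truth = genus_genomes
        ids = sorted(genomes)
        a, b = ids[0], ids[1]  # same species, pairwise 2%
        true_div = truth.divergence[frozenset((a, b))]
        res = gc.ani(genomes[a], genomes[b])
        assert abs(res.ani - 100 * (1 - true_div)) <= 0.4

    def test_unrelated_genomes_undefined(self, rng):
        a = "".join(rng.choice(list("ACGT"), 15000))
        b = "".join(rng.choice(list("ACGT"), 15000))
        res = gc.ani(a, b)
        assert res.ani is None
        assert res.aligned_fraction < 0.5

    def test_short_genome_rejected(self):
        with pytest.raises(ValueError, match="10 kb"):
            gc.ani("ACGT" * 100, "ACGT" * 10000)

    @pytest.mark.parametrize("divergence", [0.0, 0.01, 0.02, 0.05])
    def test_estimator_bias_bounded(self, divergence):
        """|ANI - (1 - d) * 100| <= 0.5 across the divergence ladder."""
        for seed in range(3):
            tax = syn.gen_taxonomy([1] * 7, seed=seed)
            genomes, truth = syn.gen_genomes(
                tax, divergence, max(0.1, 2 * divergence + 0.01),
                n_strains=2, seed=seed)
            a, b = sorted(genomes)
            value = gc.symmetric_ani(genomes[a], genomes[b])
            assert abs(value - (100 - 100 * divergence)) <= 0.5


class TestAai:
    def test_identical_proteomes(self, genus_genomes):
        genomes, truth = genus_genomes
        prot = syn.proteomes_from_genomes(genomes, truth)
        gid = sorted(prot)[0]
        assert gc.aai(prot[gid], prot[gid]) == pytest.approx(100.0)

    def test_matches_translate_and_count_oracle(self, genus_genomes):
        """AAI of two strain proteomes agrees with direct positionwise
        identity of the planted ortholog pairs."""
        genomes, truth = genus_genomes
        prot = syn.proteomes_from_genomes(genomes, truth)
        a, b = sorted(prot)[:2]
        oracle = []
        for i in range(len(prot[a])):
            pa, pb = prot[a][f"{a}_p{i:03d}"], prot[b][f"{b}_p{i:03d}"]
            n = min(len(pa), len(pb))
            oracle.append(sum(x == y for x, y in zip(pa, pb)) / n)
        expected = 100 * np.mean(oracle)
        value = gc.aai(prot[a], prot[b])
        assert value == pytest.approx(expected, abs=0.5)

    def test_no_homologs_undefined(self, rng):
        aas = list("ACDEFGHIKLMNPQRSTVWY")
        pa = {f"a{i}": "".join(rng.choice(aas, 60)) for i in range(12)}
        pb = {f"b{i}": "".join(rng.choice(aas, 60)) for i in range(12)}
        assert gc.aai(pa, pb) is None

    def test_empty_proteome_rejected(self):
        with pytest.raises(ValueError):
            gc.aai({}, {"p": "MKL"})


class TestDereplicate:
    def _records(self, genomes, qualities):
        return [gc.GenomeRecord(gid, genomes[gid], q, 0.0)
                for gid, q in qualities.items()]

    def test_trio_thresholds(self, rng):
        """A,B at ~99.5% ANI, C unrelated: {A,B},{C} at both thresholds,
        representative = higher quality."""
        base = "".join(rng.choice(list("ACGT"), 20000))
        b = list(base)
        alt = {"A": "C", "C": "G", "G": "T", "T": "A"}
        for p in rng.choice(20000, 100, replace=False):  # 0.5% divergence
            b[p] = alt[b[p]]
        genomes = {"A": base, "B": "".join(b),
                   "C": "".join(rng.choice(list("ACGT"), 20000))}
        recs = self._records(genomes, {"A": 85.0, "B": 95.0, "C": 90.0})
        for threshold in (0.99, 0.95):
            cs = gc.dereplicate(recs, ani_threshold=threshold)
            as_sets = sorted(frozenset(m) for _, m in cs.clusters)
            assert as_sets == sorted([frozenset({"A", "B"}), frozenset({"C"})])
            rep_of_ab = [rep for rep, m in cs.clusters if "A" in m][0]
            assert rep_of_ab == "B"  # quality 95 beats 85

    def test_species_and_strain_tiers(self):
        """5 species x 3 strains at 2%/8% pairwise tiers: 15 clusters at
        99% ANI, 5 at 95%."""
        tax = syn.gen_taxonomy([1, 1, 1, 1, 1, 1, 5], seed=7)
        genomes, _ = syn.gen_genomes(tax, 0.02, 0.08, n_strains=3, seed=7)
        recs = self._records(genomes, {g: 90.0 for g in genomes})
        assert len(gc.dereplicate(recs, 0.99).clusters) == 15
        assert len(gc.dereplicate(recs, 0.95).clusters) == 5

    def test_greedy_matches_bruteforce_contract(self):
        """Members reach their representative at >= threshold; representative
        pairs stay below it (symmetrised ANI oracle over all pairs)."""
        tax = syn.gen_taxonomy([1, 1, 1, 1, 1, 1, 4], seed=3)
        genomes, _ = syn.gen_genomes(tax, 0.02, 0.08, n_strains=3, seed=3)
        recs = self._records(genomes, {g: 90.0 for g in genomes})
        clusters = gc.dereplicate(recs, 0.99)
        ani_cache = {}

        def sym(a, b):
            key = frozenset((a, b))
            if key not in ani_cache:
                ani_cache[key] = gc.symmetric_ani(genomes[a], genomes[b])
            return ani_cache[key]

        for rep, members in clusters.clusters:
            for m in members:
                if m != rep:
                    assert sym(m, rep) / 100.0 >= 0.99
        for r1, r2 in itertools.combinations(clusters.representatives, 2):
            value = sym(r1, r2)
            assert value is None or value / 100.0 < 0.99


class TestGenusCluster:
    def _matrix(self, values):
        ids = sorted({i for pair in values for i in pair})
        m = pd.DataFrame(np.nan, index=ids, columns=ids)
        for (a, b), v in values.items():
            m.loc[a, b] = m.loc[b, a] = v
        np.fill_diagonal(m.values, 100.0)
        return m

    def test_single_linkage_chain(self):
        m = self._matrix({("A", "B"): 65.0, ("B", "C"): 62.0, ("A", "C"): 40.0})
        cs = gc.genus_cluster(m, threshold=0.60)
        assert [sorted(members) for _, members in cs.clusters] == [["A", "B", "C"]]

    def test_all_below_threshold_singletons(self):
        m = self._matrix({("A", "B"): 50.0, ("B", "C"): 55.0, ("A", "C"): 40.0})
        cs = gc.genus_cluster(m, threshold=0.60)
        assert len(cs.clusters) == 3

    def test_lower_threshold_coarsens(self):
        m = self._matrix({("A", "B"): 55.0, ("B", "C"): 45.0, ("A", "C"): 30.0})
        assert len(gc.genus_cluster(m, threshold=0.60).clusters) == 3
        assert len(gc.genus_cluster(m, threshold=0.40).clusters) == 1

    def test_boundary_strict(self):
        m = self._matrix({("A", "B"): 60.0})
        assert len(gc.genus_cluster(m, threshold=0.60).clusters) == 2


class TestClassifyUniqueness:
    def test_strain_level_reference_calls(self):
        calls = gc.classify_uniqueness(
            "strain", ["g1", "g2", "g3"],
            best_reference_ani={"g1": 99.5, "g2": 97.0, "g3": None})
        by_id = {c.subject_id: c for c in calls}
        assert by_id["g1"].unique_vs_reference_db is False  # 99.5 > 99
        assert by_id["g2"].unique_vs_reference_db is True   # 97 <= 99
        assert by_id["g3"].unique_vs_reference_db is True   # no hit at all

    def test_species_level_boundary_exact_95_unique(self):
        calls = gc.classify_uniqueness("species", ["g"],
                                       best_reference_ani={"g": 95.0})
        assert calls[0].unique_vs_reference_db is True  # strict >

    def test_missing_comparison_indeterminate(self):
        calls = gc.classify_uniqueness("strain", ["g"], best_reference_ani={})
        assert calls[0].unique_vs_reference_db is None

    def test_nsc_cocluster_not_unique(self):
        clusters = gc.ClusterSet([("g1", ["g1", "nscA"]), ("g2", ["g2"])], 0.99)
        calls = gc.classify_uniqueness(
            "strain", ["g1", "g2"], best_reference_ani={"g1": 90.0, "g2": 90.0},
            nsc_clusters=clusters, nsc_ids={"nscA"})
        by_id = {c.subject_id: c for c in calls}
        assert by_id["g1"].unique_vs_nsc is False
        assert by_id["g2"].unique_vs_nsc is True

    def test_genus_cluster_with_nsc_member_not_unique(self):
        clusters = gc.ClusterSet([("g1", ["g1", "g2", "nscA"]),
                                  ("g3", ["g3"])], 0.60)
        calls = gc.classify_uniqueness(
            "genus", ["g1", "g3"], genus_clusters=clusters, nsc_ids={"nscA"},
            reference_genus_label={"g1": None, "g2": None, "g3": "g__Known"})
        by_id = {c.subject_id: c for c in calls}
        assert by_id["g1"].unique_vs_nsc is False
        assert by_id["g1"].unique_vs_reference_db is True   # no member labelled
        assert by_id["g3"].unique_vs_reference_db is False  # labelled genus
        assert by_id["g3"].unique_vs_nsc is True
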