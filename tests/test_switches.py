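"""Closest-nonequal-neighbor switch detection, JC distances, NJ, bootstrap."""

import itertools
import math

import numpy as np
import pytest
from skbio import DistanceMatrix

from trnaswitch.genetics import TRNAGene
from trnaswitch.simulate import FamilySpec, PlantedSwitch, gen_trna_pool
from trnaswitch.switches import (
    NoNeighborError,
    bootstrap_support,
    closest_nonequal_neighbor,
    count_switches,
    edit_distance,
    jc_distance,
    jc_distance_matrix,
    nj_tree,
    p_distance,
    to_newick,
)


def dp_edit_distance(a: str, b: str) -> int:
    """Independent dynamic-programming oracle (no library)."""
    prev = list(range(len(b) + 1))
    for i, ca in enumerate(a, 1):
        cur = [i] + [0] * len(b)
        for j, cb in enumerate(b, 1):
            cur[j] = min(prev[j] + 1, cur[j - 1] + 1,
                         prev[j - 1] + (ca != cb))
        prev = cur
    return prev[-1]


class TestEditDistance:
    @pytest.mark.parametrize(
        "a,b,d",
        [("ACGU", "ACGU", 0), ("ACGU", "ACGA", 1), ("ACGU", "AGU", 1),
         ("", "ACG", 3), ("ACG", "", 3)],
    )
    def test_examples(self, a, b, d):
        assert edit_distance(a, b) == d

    def test_agrees_with_dp_oracle_on_random_strings(self):
        rng = np.random.default_rng(11)
        for _ in range(200):
            a = "".join(rng.choice(list("ACGU"), size=rng.integers(0, 15)))
            b = "".join(rng.choice(list("ACGU"), size=rng.integers(0, 15)))
            assert edit_distance(a, b) == dp_edit_distance(a, b)

    def test_metric_properties_on_small_pool(self):
        rng = np.random.default_rng(5)
        seqs = ["".join(rng.choice(list("ACGU"), size=20)) for _ in range(8)]
        for a, b, c in itertools.product(seqs, repeat=3):
            dab = edit_distance(a, b)
            assert dab == edit_distance(b, a)          # symmetry
            assert (dab == 0) == (a == b)              # identity
            assert dab <= edit_distance(a, c) + edit_distance(c, b)

    def test_band_preserves_small_distances(self):
        assert edit_distance("ACGUACGU", "ACGAACGU", band=3) == 1
        assert edit_distance("A" * 20, "C" * 20, band=3) == 4  # saturates


def _pool(seed=0, with_switches=True):
    fams = [FamilySpec("Lys", "CUU", 8), FamilySpec("Met", "CAU", 5),
            FamilySpec("Arg", "UCU", 6)]
    switches = [PlantedSwitch(0, 4, "CGU"),
                PlantedSwitch(1, 3, "CGU")] if with_switches else []
    return gen_trna_pool(fams, planted_switches=switches, seed=seed,
                         distinct_copies=True)


class TestClosestNonequalNeighbor:
    def test_identical_sequences_excluded(self, thr_gene, lys_gene):
        twin = TRNAGene("tRNA-Thr-CGT-1-2", thr_gene.sequence,
                        thr_gene.structure)
        ev = closest_nonequal_neighbor(
            thr_gene, [thr_gene, twin, lys_gene])
        assert ev.neighbor_id == lys_gene.gene_id
        assert ev.distance >= 1

    def test_tie_broken_lexicographically(self, thr_gene):
        a = TRNAGene("tRNA-Lys-CTT-1-1",
                     thr_gene.sequence[:32] + "CUU" + thr_gene.sequence[35:],
                     thr_gene.structure)
        seqs = list(thr_gene.sequence)
        seqs[0] = "A" if seqs[0] != "A" else "C"
        b = TRNAGene("tRNA-Thr-CGT-2-1", "".join(seqs), thr_gene.structure)
        # both at distance 1 from a CGU->CAU variant? build a distance-1 tie:
        mid = TRNAGene("tRNA-Thr-CGT-9-9", thr_gene.sequence,
                       thr_gene.structure)
        ev = closest_nonequal_neighbor(mid, [a, b, mid])
        assert ev.distance == 1
        assert ev.neighbor_id == min(a.gene_id, b.gene_id)

    def test_no_nonequal_neighbor(self, thr_gene):
        twin = TRNAGene("x", thr_gene.sequence, thr_gene.structure)
        with pytest.raises(NoNeighborError):
            closest_nonequal_neighbor(thr_gene, [thr_gene, twin])

    def test_equals_exhaustive_scan_with_band(self):
        """Banded nearest-neighbor search matches the full all-pairs argmin."""
        pool, _ = _pool(seed=3)
        for gene in pool:
            banded = closest_nonequal_neighbor(gene, pool, band=12)
            best = min(
                ((edit_distance(gene.sequence, o.sequence), o.gene_id)
                 for o in pool if o.sequence != gene.sequence),
            )
            assert (banded.distance, banded.neighbor_id) == best


class TestCountSwitches:
    def test_no_injected_switches(self):
        pool, _ = _pool(seed=1, with_switches=False)
        n, events = count_switches(pool)
        assert n == 0
        assert len(events) == len(pool)

    @pytest.mark.parametrize("seed", range(12))
    def test_recovers_planted_switch_set(self, seed):
        pool, truth = _pool(seed=seed)
        n, events = count_switches(pool)
        planted = {d["gene_id"] for d in truth.planted_switches}
        flagged = {e.gene_id for e in events if e.switched}
        assert flagged == planted

    def test_met_to_thr_switch_reported_as_met_thr(self):
        """A CAU->CGU copy inside a Met family reads Thr next to Met kin."""
        pool, truth = _pool(seed=2)
        _, events = count_switches(pool)
        met_event = next(e for e in events
                         if e.switched and e.gene_id.startswith("tRNA-Met"))
        assert met_event.decoded_aa == "T"
        assert met_event.neighbor_aa == "M"
        assert met_event.annotated_aa == "M"  # header still says Met


class TestDistances:
    def test_p_distance_basic(self):
        assert p_distance("ACGU", "ACGU") == 0
        assert p_distance("ACGU", "ACGA") == 0.25
        with pytest.raises(ValueError):
            p_distance("ACG", "AC")

    def test_jc_closed_form(self):
        assert jc_distance(0.0) == 0.0
        # independent high-precision evaluation of -(3/4) ln(1 - 4p/3)
        assert jc_distance(0.1) == pytest.approx(0.1073256, abs=1e-6)
        assert jc_distance(0.3) == pytest.approx(
            -0.75 * math.log(1 - 0.4), rel=1e-12)

    def test_jc_saturation(self):
        assert jc_distance(0.75) == 5.0
        assert jc_distance(0.9, cap=7.5) == 7.5


class TestNJTree:
    def test_three_taxon_branch_lengths(self):
        # x = (dAB + dAC - dBC)/2 and cyclic: solved by hand
        d_ab, d_ac, d_bc = 4.0, 6.0, 8.0
        dm = DistanceMatrix(
            np.array([[0, d_ab, d_ac], [d_ab, 0, d_bc], [d_ac, d_bc, 0]]),
            ["A", "B", "C"],
        )
        tree = nj_tree(dm)
        tips = {t.name: t for t in tree.tips()}
        dist = {}
        for x, y in itertools.combinations("ABC", 2):
            dist[x + y] = tips[x].distance(tips[y])
        assert dist["AB"] == pytest.approx(d_ab)
        assert dist["AC"] == pytest.approx(d_ac)
        assert dist["BC"] == pytest.approx(d_bc)

    def test_additive_matrix_recovered_exactly(self):
        # distances generated from a known 5-taxon tree (additive by
        # construction); NJ must reproduce the full path-length matrix
        d = np.array([
            [0, 5, 9, 9, 8],
            [5, 0, 10, 10, 9],
            [9, 10, 0, 8, 7],
            [9, 10, 8, 0, 3],
            [8, 9, 7, 3, 0],
        ], dtype=float)
        taxa = list("ABCDE")
        tree = nj_tree(DistanceMatrix(d, taxa))
        tt = tree.tip_tip_distances()
        for i, j in itertools.combinations(range(5), 2):
            assert tt[taxa[i], taxa[j]] == pytest.approx(d[i, j], abs=1e-9)

    def test_equidistant_matrix_star_like(self):
        n = 5
        d = np.full((n, n), 2.0)
        np.fill_diagonal(d, 0.0)
        tree = nj_tree(DistanceMatrix(d, [f"t{i}" for i in range(n)]))
        for node in tree.non_tips(include_self=False):
            assert node.length == pytest.approx(0.0, abs=1e-9)

    def test_too_few_taxa(self):
        dm = DistanceMatrix(np.array([[0, 1.0], [1.0, 0]]), ["A", "B"])
        with pytest.raises(ValueError):
            nj_tree(dm)

    def test_newick_serialization(self):
        dm = jc_distance_matrix(["A", "B", "C"],
                                ["ACGUACGUAA", "ACGUACGUCC", "AAAUACGUCC"])
        text = to_newick(nj_tree(dm))
        assert text.endswith(";")
        for taxon in "ABC":
            assert taxon in text


class TestBootstrap:
    @staticmethod
    def _clades(seed=0, n_diag=12):
        rng = np.random.default_rng(seed)
        base = "".join(rng.choice(list("ACGU"), size=60))

        def mutate(s, n):
            s = list(s)
            pos = rng.choice(len(s), size=n, replace=False)
            for p in pos:
                s[p] = "ACGU"[("ACGU".index(s[p]) + 1) % 4]
            return "".join(s)

        clade_a = [mutate(base, 2) for _ in range(3)]
        far = mutate(base, n_diag * 2)
        clade_b = [mutate(far, 2) for _ in range(3)]
        ids = [f"A{i}" for i in range(3)] + [f"B{i}" for i in range(3)]
        return ids, clade_a + clade_b

    def test_separating_edge_gets_full_support(self):
        ids, seqs = self._clades()
        sup = bootstrap_support(ids, seqs, n_replicates=100, seed=1)
        split = frozenset(["A0", "A1", "A2"])
        assert sup[split] >= 0.95

    def test_zero_replicates_empty(self):
        ids, seqs = self._clades()
        assert bootstrap_support(ids, seqs, n_replicates=0) == {}

    def test_deterministic_under_seed(self):
        ids, seqs = self._clades()
        a = bootstrap_support(ids, seqs, n_replicates=30, seed=42)
        b = bootstrap_support(ids, seqs, n_replicates=30, seed=42)
        assert a == b
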