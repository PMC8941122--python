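"""Chromosome counts, tandem-cluster detection, terminal-arm localization."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from crkscan.genome_distribution import (
    ClusterPolicy,
    chromosome_counts,
    detect_tandem_clusters,
    terminal_arm_fraction,
)
from crkscan.io_formats import GeneLocus


def locus(gene_id, chrom="chr1", start=1000, end=4000, species="sp"):
    return GeneLocus(gene_id=gene_id, chromosome=chrom, start=start, end=end,
                     species=species)


def spaced(n, chrom="chr1", start=10_000, gap=10_000, glen=3_000, prefix="g"):
    out, cursor = [], start
    for i in range(n):
        out.append(locus(f"{prefix}{i}", chrom, cursor, cursor + glen - 1))
        cursor += glen + gap
    return out


class TestChromosomeCounts:
    def test_counts_partition_loci(self):
        loci = [locus(f"g{i}", "chrA") for i in range(3)] + [
            locus(f"h{i}", "chrB") for i in range(2)
        ]
        assert chromosome_counts(loci) == {("sp", "chrA"): 3, ("sp", "chrB"): 2}

    def test_empty(self):
        assert chromosome_counts([]) == {}

    def test_scaffolds_pooled_as_unplaced(self):
        loci = [locus("g1", "scaffold_12"), locus("g2", "Contig99"), locus("g3", "chr1")]
        counts = chromosome_counts(loci)
        assert counts[("sp", "unplaced")] == 2 and counts[("sp", "chr1")] == 1


def brute_force_clusters(family, policy):
    """Independent oracle: connected components of the all-pairs
    within-distance graph between *adjacent* family genes, per chromosome."""
    by_chrom = {}
    for l in family:
        by_chrom.setdefault((l.species, l.chromosome), []).append(l)
    out = set()
    for members in by_chrom.values():
        members = sorted(members, key=lambda l: (l.start, l.end))
        parent = list(range(len(members)))

        def find(i):
            while parent[i] != i:
                parent[i] = parent[parent[i]]
                i = parent[i]
            return i

        for i, j in itertools.combinations(range(len(members)), 2):
            a, b = members[i], members[j]
            if j != i + 1:
                continue  # only physically adjacent family genes can chain
            if max(0, b.start - a.end - 1) <= policy.max_gap_bp:
                parent[find(i)] = find(j)
        groups = {}
        for i in range(len(members)):
            groups.setdefault(find(i), []).append(members[i].gene_id)
        out |= {frozenset(g) for g in groups.values() if len(g) > 1}
    return out


class TestTandemClusters:
    def test_three_genes_at_10kb_form_one_cluster(self):
        family = spaced(3, gap=10_000)
        (cluster,) = detect_tandem_clusters(family)
        assert cluster.members == ("g0", "g1", "g2")
        assert cluster.member_count == 3

    def test_genes_500kb_apart_do_not_cluster(self):
        family = spaced(2, gap=500_000)
        assert detect_tandem_clusters(family) == []

    def test_single_gene_never_a_cluster(self):
        assert detect_tandem_clusters(spaced(1)) == []

    def test_intervening_gene_criterion(self):
        family = spaced(2, gap=100_000)
        # plant 3 non-family genes between the two members
        others = [
            locus(f"x{i}", start=20_000 + i * 10_000, end=22_000 + i * 10_000)
            for i in range(3)
        ]
        all_loci = family + others
        strict = ClusterPolicy(max_intervening=2)
        lax = ClusterPolicy(max_intervening=3)
        assert detect_tandem_clusters(family, all_loci, strict) == []
        (cluster,) = detect_tandem_clusters(family, all_loci, lax)
        assert cluster.member_count == 2

    def test_missing_family_genes_in_full_set_is_an_error(self):
        family = spaced(2)
        with pytest.raises(ValueError, match="g0"):
            detect_tandem_clusters(family, all_loci=[locus("other")])

    def test_cluster_spans_never_overlap_and_membership_partitions(self):
        family = spaced(4, gap=10_000) + spaced(3, start=2_000_000, gap=5_000,
                                                prefix="h")
        clusters = detect_tandem_clusters(family)
        seen = [m for c in clusters for m in c.members]
        assert len(seen) == len(set(seen))
        spans = sorted((c.span_start, c.span_end) for c in clusters)
        for (s1, e1), (s2, e2) in zip(spans, spans[1:]):
            assert e1 < s2

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(
        starts=st.lists(st.integers(1, 2_000_000), min_size=2, max_size=10,
                        unique=True),
        max_gap=st.sampled_from([50_000, 250_000]),
    )
    def test_equals_brute_force_closure(self, starts, max_gap):
        family = [
            locus(f"g{i}", start=s, end=s + 2_999) for i, s in enumerate(sorted(starts))
        ]
        policy = ClusterPolicy(max_gap_bp=max_gap)
        found = {frozenset(c.members) for c in detect_tandem_clusters(family, policy=policy)}
        assert found == brute_force_clusters(family, policy)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        starts=st.lists(st.integers(1, 2_000_000), min_size=2, max_size=10,
                        unique=True),
        gap_small=st.sampled_from([20_000, 80_000]),
    )
    def test_raising_max_gap_never_splits_clusters(self, starts, gap_small):
        family = [
            locus(f"g{i}", start=s, end=s + 2_999) for i, s in enumerate(sorted(starts))
        ]
        small = {
            frozenset(c.members)
            for c in detect_tandem_clusters(
                family, policy=ClusterPolicy(max_gap_bp=gap_small)
            )
        }
        large = {
            frozenset(c.members)
            for c in detect_tandem_clusters(
                family, policy=ClusterPolicy(max_gap_bp=gap_small * 4)
            )
        }
        for cluster in small:
            assert any(cluster <= big for big in large)


class TestTerminalArms:
    LENGTHS = {"chr1": 1_000_000}

    def test_all_genes_near_origin(self):
        family = [locus(f"g{i}", start=100 + i, end=200 + i) for i in range(5)]
        frac, _ = terminal_arm_fraction(family, self.LENGTHS)
        assert frac == 1.0

    def test_gene_at_midpoint_not_terminal(self):
        family = [locus("g0", start=499_000, end=501_000)]
        frac, _ = terminal_arm_fraction(family, self.LENGTHS,
                                        ClusterPolicy(arm_fraction=0.25))
        assert frac == 0.0

    def test_missing_chromosome_length_is_an_error(self):
        with pytest.raises(ValueError, match="chrX"):
            terminal_arm_fraction([locus("g0", chrom="chrX")], self.LENGTHS)

    def test_mirror_invariance(self):
        rng = np.random.default_rng(11)
        length = self.LENGTHS["chr1"]
        family = []
        for i, s in enumerate(rng.integers(1, length - 5000, size=50)):
            family.append(locus(f"g{i}", start=int(s), end=int(s) + 4_999))
        mirrored = [
            locus(l.gene_id, start=length - l.end + 1, end=length - l.start + 1)
            for l in family
        ]
        f1, _ = terminal_arm_fraction(family, self.LENGTHS)
        f2, _ = terminal_arm_fraction(mirrored, self.LENGTHS)
        assert f1 == f2

    def test_uniform_placement_matches_binomial_expectation(self):
        """Uniform gene midpoints: terminal fraction ~ Binomial(n, 2f)/n,
        so it must land within 3 standard errors of 0.5 at f = 0.25."""
        rng = np.random.default_rng(2024)
        n, length = 10_000, self.LENGTHS["chr1"]
        family = [
            locus(f"g{i}", start=int(s), end=int(s))
            for i, s in enumerate(rng.integers(1, length, size=n))
        ]
        frac, _ = terminal_arm_fraction(family, self.LENGTHS,
                                        ClusterPolicy(arm_fraction=0.25))
        se = (0.5 * 0.5 / n) ** 0.5
        assert abs(frac - 0.5) < 3 * se
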