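import numpy as np
import pytest

from habprof import (
    AlignmentHit,
    HitScenario,
    RankGates,
    SequenceRead,
    gen_hit_table,
    lca_assign,
    merge_or_interleave,
    prefilter_hits,
    profile_sample,
)
from habprof.taxonomy import RANKS


def hit(query="r1", genus="Bacteria;p1;c1;o1;f1;g1", identity=97.0,
        evalue=1e-10, bitscore=200.0, length=100):
    return AlignmentHit(query, f"ref|{genus}", identity, length, evalue,
                        bitscore, annotation=genus)


def revcomp(seq):
    comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
    return "".join(comp[b] for b in reversed(seq))


class TestMergeOrInterleave:
    def setup_method(self):
        rng = np.random.default_rng(0)
        self.fwd = "".join(rng.choice(list("ACGT"), 60))

    def test_constructed_overlap_merges(self):
        r1 = SequenceRead("p/1", self.fwd, np.full(60, 35))
        # mate covers the 3' 30 bases of r1 plus 20 novel downstream bases
        rng = np.random.default_rng(1)
        downstream = "".join(rng.choice(list("ACGT"), 20))
        r2 = SequenceRead("p/2", revcomp(self.fwd[-30:] + downstream), np.full(50, 30))
        merged, mode = merge_or_interleave(r1, r2, min_overlap=10)
        assert mode == "merged"
        assert len(merged) == 60 + 50 - 30
        assert merged.bases == self.fwd + downstream

    def test_disjoint_reads_interleaved(self):
        r1 = SequenceRead("p/1", "AG" * 15, np.full(30, 35))
        r2 = SequenceRead("p/2", "G" * 30, np.full(30, 30))  # rc = C*30, no overlap
        combined, mode = merge_or_interleave(r1, r2, min_overlap=10)
        assert mode == "interleaved"
        assert len(combined) == 60

    def test_interleave_appends_reverse_complement_verbatim(self):
        r1 = SequenceRead("p/1", "ACGTACGTAC", np.full(10, 35))
        r2 = SequenceRead("p/2", "TTGGCCAATT", np.full(10, 30))
        combined, mode = merge_or_interleave(r1, r2, min_overlap=8)
        assert mode == "interleaved"
        assert combined.bases.endswith(revcomp(r2.bases))


class TestPrefilter:
    @pytest.mark.parametrize(
        "evalue,kept", [(1e-5, True), (1e-3, False), (1e-4, False)]
    )
    def test_evalue_boundary_strict(self, evalue, kept):
        hits = prefilter_hits([hit(evalue=evalue)])
        assert bool(hits) is kept

    def test_empty_input(self):
        assert prefilter_hits([]) == []


def oracle_lca(hits, tree, gates, score_margin):
    """Independent exhaustive oracle: enumerate the ancestors of every
    retained hit and walk ranks root-to-genus counting votes."""
    from collections import Counter

    if not hits:
        return {}
    best = max(h.identity for h in hits)
    retained = [h for h in hits if h.identity >= best - score_margin]
    ancestor_sets = []
    for h in retained:
        ancestor_sets.append({(n.rank, n.taxon_id) for n in tree.lineage(h.annotation)})
    assigned = {}
    for rank in RANKS:
        votes = Counter(
            t for s in ancestor_sets for r, t in s if r == rank
        )
        if not votes:
            break
        taxon, count = votes.most_common(1)[0]
        if count / len(retained) < gates.consensus_fraction:
            break
        if best < gates.gate(rank):
            break
        assigned[rank] = taxon
    return assigned


class TestLcaAssign:
    def test_class_gate_blocks_deeper_than_class(self, tree):
        # hits spread over genera of one class at 92%: class assigned,
        # nothing deeper (no genus consensus, genus gate unmet anyway)
        hits = [
            hit(genus="Bacteria;p1;c1;o1;f1;g1", identity=92.0),
            hit(genus="Bacteria;p1;c1;o2;f2;g2", identity=92.0),
        ]
        res = lca_assign(hits, tree)
        assert res.deepest_rank == "class"
        assert res.lineage["class"] == "Bacteria;p1;c1"

    def test_89_percent_single_hit_stops_at_phylum(self, tree):
        res = lca_assign([hit(identity=89.0)], tree)
        assert res.deepest_rank == "phylum"
        assert "class" not in res.lineage

    def test_85_percent_single_hit_unassigned_at_phylum(self, tree):
        res = lca_assign([hit(identity=85.0)], tree)
        assert "phylum" not in res.lineage
        assert res.deepest_rank == "domain"

    def test_split_phyla_break_consensus(self, tree):
        hits = [
            hit(genus="Bacteria;p1;c1;o1;f1;g1", identity=95.0),
            hit(genus="Bacteria;p2;c1;o1;f1;g1", identity=95.0),
        ]
        res = lca_assign(hits, tree, RankGates(consensus_fraction=0.9))
        assert "phylum" not in res.lineage
        assert res.deepest_rank == "domain"

    def test_empty_hit_set_fully_unassigned(self, tree):
        res = lca_assign([], tree)
        assert res.lineage == {} and res.deepest_rank is None

    def test_score_margin_drops_weak_hits(self, tree):
        hits = [
            hit(genus="Bacteria;p1;c1;o1;f1;g1", identity=97.0),
            hit(genus="Fungi;p1;c1;o1;f1;g1", identity=92.0),  # outside margin
        ]
        res = lca_assign(hits, tree, score_margin=1.0)
        assert res.lineage["domain"] == "Bacteria"
        assert res.n_retained == 1

    def test_matches_exhaustive_oracle_on_generated_hit_sets(self, tree):
        rng = np.random.default_rng(21)
        taxa = sorted(tree.nodes)
        gates = RankGates()
        for i in range(150):
            sc = HitScenario(
                f"r{i}",
                taxa[rng.integers(len(taxa))],
                n_hits=int(rng.integers(1, 6)),
                identity=float(rng.uniform(80, 100)),
                identity_spread=float(rng.uniform(0, 2)),
            )
            hits = gen_hit_table([sc], tree, seed=int(rng.integers(2**31)))
            got = lca_assign(hits, tree, gates).lineage
            assert got == oracle_lca(hits, tree, gates, 1.0)

    def test_gate_monotonicity(self, tree):
        hits = [hit(identity=93.0, genus="Bacteria;p1;c1;o1;f1;g1")] * 3
        depth = {None: -1, **{r: i for i, r in enumerate(RANKS)}}
        prev = None
        for genus_gate in (90.0, 93.5, 96.0):
            gates = RankGates(min_identity={**dict.fromkeys(RANKS, 0.0),
                                            "family": min(genus_gate, 93.0),
                                            "genus": genus_gate})
            d = depth[lca_assign(hits, tree, gates).deepest_rank]
            if prev is not None:
                assert d <= prev
            prev = d

    def test_assigned_lineage_is_root_path(self, tree):
        rng = np.random.default_rng(3)
        taxa = sorted(tree.nodes)
        for i in range(40):
            sc = HitScenario(f"q{i}", taxa[rng.integers(len(taxa))],
                             n_hits=3, identity=96.0, identity_spread=1.0)
            hits = gen_hit_table([sc], tree, seed=i)
            res = lca_assign(hits, tree)
            ranks = [r for r in RANKS if r in res.lineage]
            assert ranks == list(RANKS[: len(ranks)])  # contiguous from domain
            for shallow, deep in zip(ranks, ranks[1:]):
                node = tree.nodes[res.lineage[deep]]
                assert node.parent == res.lineage[shallow]


class TestProfileSample:
    def test_normalizes_by_total_reads(self, tree):
        hits = [hit(query=f"r{i}") for i in range(10)]
        assignments = [lca_assign([h], tree) for h in hits]
        counts, normalized = profile_sample(assignments, "genus", total_reads=1000)
        assert counts["Bacteria;p1;c1;o1;f1;g1"] == 10
        assert normalized["Bacteria;p1;c1;o1;f1;g1"] == pytest.approx(0.01)
        assert normalized.sum() <= 1.0

    def test_no_assignments_gives_empty_vector(self, tree):
        counts, normalized = profile_sample([], "genus", total_reads=100)
        assert counts.empty and normalized.empty
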