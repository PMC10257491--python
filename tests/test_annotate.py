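"""Library mapping, uniqueness filtering, composition, and polishing."""

import numpy as np
import pytest

from rdnascope import align
from rdnascope.annotate import (
    AlignmentHit,
    classify_cohort,
    compose_read,
    filter_and_merge_hits,
    map_library,
    polish_consensus,
)
from rdnascope.core import Interval, PipelineConfig, SequenceRecord, reverse_complement
from rdnascope.simulate import ReadSimParams, simulate_reads


def _rand(rng, n):
    return "".join(rng.choice(list("ACGT"), size=n))


class TestMapLibrary:
    def test_unique_exact_hit_is_mapq60_identity1(self, config, rng):
        elem = _rand(rng, 600)
        read = SequenceRecord("r", _rand(rng, 1000) + elem + _rand(rng, 1000))
        hits = map_library(read, {"E": elem}, config)
        assert len(hits) == 1
        h = hits[0]
        assert (h.query.start, h.query.end) == (1000, 1600)
        assert h.identity == pytest.approx(1.0)
        assert h.mapq == 60

    def test_identical_double_planting_forces_mapq0(self, config, rng):
        elem = _rand(rng, 500)
        read = SequenceRecord(
            "r", _rand(rng, 800) + elem + _rand(rng, 2000) + elem + _rand(rng, 800)
        )
        hits = map_library(read, {"E": elem}, config)
        assert len(hits) == 2
        assert all(h.mapq == 0 for h in hits)

    def test_minus_strand_reported_in_plus_coords(self, config, rng):
        elem = _rand(rng, 400)
        read = SequenceRecord(
            "r", _rand(rng, 500) + reverse_complement(elem) + _rand(rng, 500)
        )
        hits = map_library(read, {"E": elem}, config)
        assert len(hits) == 1
        assert hits[0].query.strand == "-"
        assert (hits[0].query.start, hits[0].query.end) == (500, 900)

    def test_truncated_fragment_found_with_subject_interval(self, config, rng):
        elem = _rand(rng, 1000)
        frag = elem[300:800]  # internal fragment
        read = SequenceRecord("r", _rand(rng, 400) + frag + _rand(rng, 400))
        hits = map_library(read, {"E": elem}, config)
        assert len(hits) == 1
        # flanks may extend the match by a base or two when the next random
        # base happens to agree with the consensus
        assert abs(hits[0].subject.start - 300) <= 2
        assert abs(hits[0].subject.end - 800) <= 2

    def test_empty_library_rejected(self, config):
        with pytest.raises(ValueError):
            map_library(SequenceRecord("r", "ACGT" * 50), {}, config)

    def test_truth_overlap_oracle_error_free(self, config, small_truth, small_reads):
        """Recovered hits match truth blocks (interval Jaccard >= 0.9).

        Raw placements are checked: the mini profile's units are shorter
        than some reads, so the uniqueness filter would (correctly) censor
        copies duplicated within one read.
        """
        reads, rtruth = small_reads
        library = dict(small_truth.repeat_library)
        library.update(small_truth.gene_refs)
        for read, rt in zip(reads[:15], rtruth[:15]):
            hits = map_library(read, library, config)
            s, e = rt.origin.start, rt.origin.end
            for b in small_truth.blocks_overlapping(s, e):
                if b.label == "IGS":
                    continue
                ov = min(b.end, e) - max(b.start, s)
                if ov < 200:
                    continue
                # map truth interval into read coordinates
                if rt.strand == "+":
                    t0, t1 = max(b.start, s) - s, min(b.end, e) - s
                else:
                    t0, t1 = e - min(b.end, e), e - max(b.start, s)
                same = [h for h in hits if h.label == b.label]
                best = 0.0
                for h in same:
                    inter = max(0, min(h.query.end, t1) - max(h.query.start, t0))
                    union = (t1 - t0) + h.q_len() - inter
                    best = max(best, inter / union)
                assert best >= 0.9, (b.label, rt.read_id)


class TestFilterAndMerge:
    def _hit(self, label, q0, q1, mapq=60, s0=0, s1=None):
        s1 = s1 if s1 is not None else q1 - q0
        return AlignmentHit(
            label, Interval("r", q0, q1), Interval(label, s0, s1), 0.99,
            q1 - q0, mapq,
        )

    def test_mapq19_removed_20_kept(self, config):
        hits = [self._hit("E", 0, 100, mapq=19), self._hit("E", 500, 800, mapq=20)]
        out = filter_and_merge_hits(hits, config)
        assert [h.query.start for h in out] == [500]

    def test_split_hits_within_gap_merged(self, config):
        hits = [
            self._hit("28S", 0, 1000, s0=0, s1=1000),
            self._hit("28S", 1050, 2000, s0=1060, s1=2010),
        ]
        out = filter_and_merge_hits(hits, config)
        assert len(out) == 1
        assert (out[0].query.start, out[0].query.end) == (0, 2000)
        assert out[0].score == 1000 + 950

    def test_matches_predicate_plus_merge_oracle(self, config, rng):
        labels = ["A", "B"]
        hits = []
        for _ in range(40):
            q0 = int(rng.integers(0, 5000))
            q1 = q0 + int(rng.integers(40, 400))
            hits.append(
                self._hit(str(rng.choice(labels)), q0, q1,
                          mapq=int(rng.integers(0, 61)))
            )
        out = filter_and_merge_hits(hits, config)
        # oracle: drop low mapq, then sweep-merge per label
        survivors = [h for h in hits if h.mapq >= config.min_mapq]
        expected_bp = {}
        for lab in labels:
            ivs = sorted(
                (h.query.start, h.query.end)
                for h in survivors
                if h.label == lab
            )
            merged = []
            for s, e in ivs:
                if merged and s <= merged[-1][1] + config.merge_gap:
                    merged[-1][1] = max(merged[-1][1], e)
                else:
                    merged.append([s, e])
            expected_bp[lab] = [(s, e) for s, e in merged]
        got = {}
        for h in out:
            got.setdefault(h.label, []).append((h.query.start, h.query.end))
        for lab in labels:
            assert sorted(got.get(lab, [])) == expected_bp[lab]

    def test_raising_min_mapq_never_adds_hits(self, config, rng):
        hits = [
            self._hit("A", int(i * 500), int(i * 500) + 200,
                      mapq=int(rng.integers(0, 61)))
            for i in range(10)
        ]
        prev = None
        for mq in (0, 10, 20, 30, 40, 50, 60):
            cfg = PipelineConfig(min_mapq=mq)
            ids = {(h.query.start, h.query.end) for h in
                   filter_and_merge_hits(hits, cfg)}
            if prev is not None:
                assert ids <= prev
            prev = ids


class TestComposeRead:
    def test_no_hits_empty_and_me_free(self):
        ann = compose_read([])
        assert ann.composition == [] and ann.me_free

    def test_r2_inside_split_28s_flagged(self):
        hits = [
            AlignmentHit("28S", Interval("r", 0, 2500), Interval("28S", 0, 2500),
                         1.0, 2500, 60),
            AlignmentHit("R2", Interval("r", 2500, 5500), Interval("R2", 0, 3000),
                         1.0, 3000, 60),
            AlignmentHit("28S", Interval("r", 5500, 6900), Interval("28S", 2500, 3900),
                         1.0, 1400, 60),
        ]
        ann = compose_read(hits)
        assert ann.has_r2_in_28S
        assert not ann.me_free

    def test_distant_r2_not_flagged(self):
        hits = [
            AlignmentHit("28S", Interval("r", 0, 3900), Interval("28S", 0, 3900),
                         1.0, 3900, 60),
            AlignmentHit("R2", Interval("r", 8000, 11000), Interval("R2", 0, 3000),
                         1.0, 3000, 60),
        ]
        assert not compose_read(hits).has_r2_in_28S

    def test_minus_orientation_flips_to_canonical(self):
        # gene hits on minus strand: labels must come out 18S -> 28S
        hits = [
            AlignmentHit("28S", Interval("r", 0, 1500, "-"), Interval("28S", 0, 1500),
                         1.0, 1500, 60),
            AlignmentHit("5.8S", Interval("r", 1700, 1850, "-"),
                         Interval("5.8S", 0, 150), 1.0, 150, 60),
            AlignmentHit("18S", Interval("r", 2000, 3800, "-"),
                         Interval("18S", 0, 1800), 1.0, 1800, 60),
        ]
        ann = compose_read(hits)
        assert ann.orientation == "-"
        assert ann.composition == ["18S", "5.8S", "28S"]


class TestClassifyCohort:
    def _ann_with_igs(self, rid, igs):
        from rdnascope.annotate import ReadAnnotation

        a = ReadAnnotation(read_id=rid)
        a.igs_composition = tuple(igs)
        a.element_bp = {l: 500 for l in igs}
        a.me_free = not igs
        return a

    def test_all_modal_means_zero_irregular(self, config):
        anns = [self._ann_with_igs(f"r{i}", ("A", "B")) for i in range(10)]
        s = classify_cohort(anns, config)
        assert s.n_irregular == 0 and s.n_canonical == 10

    def test_shuffled_reads_are_irregular(self, config):
        anns = [self._ann_with_igs(f"r{i}", ("A", "B")) for i in range(8)]
        anns += [self._ann_with_igs("x", ("B", "A"))]
        s = classify_cohort(anns, config)
        assert s.n_irregular == 1
        assert s.irregular_fraction == pytest.approx(1 / 9)

    def test_satellite_below_200bp_not_counted(self, config):
        from rdnascope.annotate import ReadAnnotation

        a = ReadAnnotation(read_id="r", element_bp={"satellite": 150},
                           satellite_bp=150)
        b = ReadAnnotation(read_id="s", element_bp={"satellite": 240},
                           satellite_bp=240)
        s = classify_cohort([a, b], config)
        assert s.reads_with_label["satellite"] == 1

    def test_empty_cohort_rejected(self, config):
        with pytest.raises(ValueError):
            classify_cohort([], config)


class TestPolishConsensus:
    def test_error_free_copies_reproduce_truth(self, config, rng):
        seed = _rand(rng, 2000)
        reads = [SequenceRecord(f"r{i}", seed) for i in range(20)]
        cons = polish_consensus(reads, seed, config)
        assert cons.residues == seed

    def test_tie_broken_by_fixed_base_order(self, config, rng):
        seed = _rand(rng, 1500)
        k = 700
        hap_a = seed[:k] + "A" + seed[k + 1 :]
        hap_c = seed[:k] + "C" + seed[k + 1 :]
        reads = [SequenceRecord(f"a{i}", hap_a) for i in range(10)]
        reads += [SequenceRecord(f"c{i}", hap_c) for i in range(10)]
        cons = polish_consensus(reads, seed, config)
        assert cons.residues[k] == "A"  # A < C in the fixed order

    def test_ont_error_polish_accuracy(self, config, small_truth):
        """Depth-20 ONT-like reads polish a region to >=99.5% identity."""
        start, end = small_truth.unit_bounds[1]
        seed_region = small_truth.genome.residues[start:end]
        params = ReadSimParams(
            mode="long", n_reads=40, median_len=4000, sigma=0.15,
            error_rate=0.07, mean_q=12,
        )
        reads, _ = simulate_reads(small_truth, params, seed=17)
        cons = polish_consensus(reads, seed_region, config)
        assert abs(len(cons) - len(seed_region)) <= 0.02 * len(seed_region)
        ident = align.global_identity(cons.residues, seed_region)
        assert ident >= 0.995

    def test_low_coverage_refused_with_gap_report(self, config, rng):
        seed = _rand(rng, 3000)
        # reads cover only the first half
        reads = [SequenceRecord(f"r{i}", seed[:1500]) for i in range(5)]
        with pytest.raises(ValueError, match="coverage below"):
            polish_consensus(reads, seed, config)

    def test_fewer_than_three_reads_rejected(self, config, rng):
        seed = _rand(rng, 500)
        with pytest.raises(ValueError):
            polish_consensus([SequenceRecord("r", seed)] * 2, seed, config)
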