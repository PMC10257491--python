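"""Depth computation, LOESS smoothing, block means, fraction estimators."""

import numpy as np
import pytest

from rdnascope.core import AnnotationBlock, Interval, SequenceRecord
from rdnascope.coverage import (
    CoverageProfile,
    block_means,
    compute_depth,
    genome_proportion,
    insertion_fraction,
    loess_smooth,
)
from rdnascope.simulate import _random_seq


@pytest.fixture
def consensus(rng):
    return SequenceRecord("unit", _random_seq(rng, 3000))


class TestComputeDepth:
    def test_no_reads_all_zero(self, config, consensus):
        depth = compute_depth([], consensus, config)
        assert depth.sum() == 0 and len(depth) == 3000

    def test_single_read_exact_interval(self, config, consensus):
        read = SequenceRecord("r", consensus.residues[100:220], [30] * 120)
        depth = compute_depth([read], consensus, config, circular=False)
        assert depth[100:220].tolist() == [1] * 120
        assert depth.sum() == 120

    def test_wrap_around_circular(self, config, consensus):
        read = SequenceRecord(
            "r", consensus.residues[-60:] + consensus.residues[:60], [30] * 120
        )
        depth = compute_depth([read], consensus, config, circular=True)
        assert depth[:60].sum() == 60 and depth[-60:].sum() == 60

    def test_low_identity_read_discarded(self, config, consensus, rng):
        junk = SequenceRecord("junk", _random_seq(rng, 120), [30] * 120)
        depth = compute_depth([junk], consensus, config)
        assert depth.sum() == 0

    def test_conservation_against_counting_oracle(self, config, consensus, rng):
        reads = []
        for i in range(200):
            s = int(rng.integers(0, 3000 - 120))
            reads.append(
                SequenceRecord(f"r{i}", consensus.residues[s : s + 120], [30] * 120)
            )
        depth, alignments = compute_depth(
            reads, consensus, config, circular=False, return_alignments=True
        )
        # per-position counting oracle from the alignment records
        oracle = np.zeros(3000, dtype=int)
        for _, _, start, alen in alignments:
            oracle[start : start + alen] += 1
        assert np.array_equal(depth, oracle)
        assert depth.sum() == sum(a[3] for a in alignments)

    def test_consensus_shorter_than_read_rejected(self, config, rng):
        tiny = SequenceRecord("t", _random_seq(rng, 50))
        read = SequenceRecord("r", _random_seq(rng, 120), [30] * 120)
        with pytest.raises(ValueError):
            compute_depth([read], tiny, config)


class TestLoessSmooth:
    def test_constant_reproduced(self):
        x = np.full(200, 30.0)
        assert np.abs(loess_smooth(x, 0.1) - 30).max() < 1e-9

    def test_line_reproduced(self):
        x = np.arange(300, dtype=float) * 2 + 5
        assert np.abs(loess_smooth(x, 0.1) - x).max() < 1e-6

    def test_step_function_against_wls_oracle(self, rng):
        """Per-position weighted-least-squares oracle reproduces the smoother."""
        y = np.concatenate([np.full(300, 10.0), np.full(300, 20.0)])
        y += rng.normal(0, 1, size=600)
        span = 0.08
        sm = loess_smooth(y, span)
        n = len(y)
        w = max(3, int(round(span * n)))
        half = w // 2
        for i in (50, 200, 299, 450, 580):  # spot-check positions
            left = min(max(0, i - half), n - w)
            xs = np.arange(left, left + w, dtype=float)
            ys = y[left : left + w]
            d = np.abs(xs - i)
            tw = (1 - (d / d.max()) ** 3) ** 3
            coef = np.polyfit(xs, ys, 1, w=np.sqrt(tw))
            assert sm[i] == pytest.approx(max(0.0, np.polyval(coef, i)), abs=1e-6)
        # far from the step the plateau levels are preserved within 5%
        assert abs(sm[100] - 10) < 0.5 + 0.05 * 10
        assert abs(sm[500] - 20) < 0.5 + 0.05 * 20

    def test_agrees_with_statsmodels_lowess(self, rng):
        """Independent cross-check against the reference LOESS implementation
        (interior positions; implementations differ at the edges)."""
        from statsmodels.nonparametric.smoothers_lowess import lowess

        y = rng.poisson(30, size=400).astype(float)
        span = 0.15
        ours = loess_smooth(y, span)
        ref = lowess(y, np.arange(400), frac=span, it=0, return_sorted=False)
        inner = slice(60, 340)
        assert np.abs(ours[inner] - ref[inner]).max() < 1.0

    def test_never_negative(self, rng):
        y = rng.normal(0, 1, size=300)
        assert (loess_smooth(y, 0.2) >= 0).all()

    def test_bad_span(self):
        with pytest.raises(ValueError):
            loess_smooth(np.ones(100), 0.0)


class TestBlockMeans:
    def _blocks(self, spec):
        return [
            AnnotationBlock(lab, Interval("unit", s, e)) for lab, s, e in spec
        ]

    def test_constant_depth(self):
        depth = np.full(200, 7.0)
        means = block_means(depth, self._blocks([("A", 0, 100), ("B", 100, 200)]))
        assert means == {"A": 7.0, "B": 7.0}

    def test_two_level_depth(self):
        depth = np.concatenate([np.full(100, 10.0), np.full(100, 20.0)])
        means = block_means(depth, self._blocks([("A", 0, 100), ("B", 100, 200)]))
        assert means == {"A": 10.0, "B": 20.0}

    def test_random_blocks_match_brute_force(self, rng):
        depth = rng.poisson(25, size=1000).astype(float)
        spec = []
        for i in range(12):
            s = int(rng.integers(0, 950))
            e = int(rng.integers(s + 1, 1000))
            spec.append((f"b{i}", s, e))
        means = block_means(depth, self._blocks(spec))
        for lab, s, e in spec:
            assert means[lab] == pytest.approx(float(depth[s:e].mean()), abs=1e-12)

    def test_split_label_uses_position_union(self):
        depth = np.concatenate([np.full(50, 10.0), np.full(50, 30.0)])
        means = block_means(depth, self._blocks([("28S", 0, 50), ("28S", 50, 100)]))
        assert means["28S"] == 20.0

    def test_out_of_bounds_rejected(self):
        with pytest.raises(ValueError):
            block_means(np.ones(10), self._blocks([("A", 5, 20)]))


class TestInsertionFraction:
    def test_ratio_and_missing_label(self):
        prof = CoverageProfile("u", np.ones(10), np.ones(10),
                               {"R2": 10.0, "28S": 30.0})
        est = insertion_fraction(prof, "R2", "28S")
        assert est.fraction == pytest.approx(1 / 3)
        with pytest.raises(ValueError):
            insertion_fraction(prof, "R1", "28S")

    def test_zero_host_rejected(self):
        prof = CoverageProfile("u", np.ones(10), np.ones(10),
                               {"R2": 1.0, "28S": 0.0})
        with pytest.raises(ValueError):
            insertion_fraction(prof, "R2", "28S")


class TestGenomeProportion:
    def test_all_reads_from_locus(self, config, consensus, rng):
        reads = [
            SequenceRecord(
                f"r{i}",
                consensus.residues[s : s + 120],
                [30] * 120,
            )
            for i, s in enumerate(rng.integers(0, 2880, size=50))
        ]
        assert genome_proportion(reads, consensus, config) == pytest.approx(
            1.0, abs=0.02
        )

    def test_no_reads_align(self, config, consensus, rng):
        reads = [
            SequenceRecord(f"r{i}", _random_seq(rng, 120), [30] * 120)
            for i in range(20)
        ]
        assert genome_proportion(reads, consensus, config) == 0.0

    def test_zero_bp_rejected(self, config, consensus):
        with pytest.raises(ValueError):
            genome_proportion([], consensus, config)
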