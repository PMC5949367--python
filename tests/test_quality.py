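"""Quality-stage predicates against brute-force oracles."""

import numpy as np
import pytest

from exomesieve import FilterConfig, RefWindow, VariantKey
from exomesieve.model import AnnotatedVariant, DataError, normalize_variant
from exomesieve.quality import flag_homopolymer, intersect_platforms, passes_quality


def _call(qd=5.0, fs=1.0, depth=50, vaf=0.5):
    return AnnotatedVariant(chrom="1", pos=100, ref="A", alt="G",
                            qd=qd, fs=fs, depth=depth, vaf=vaf)


class TestPassesQuality:
    def test_qd_threshold_is_strict(self, config):
        assert passes_quality(_call(qd=2.0), config).verdict == "fail"
        assert passes_quality(_call(qd=2.0 + 1e-9), config).verdict == "pass"

    def test_depth_threshold_is_inclusive(self, config):
        assert passes_quality(_call(depth=10), config).verdict == "pass"
        assert passes_quality(_call(depth=9), config).verdict == "fail"

    def test_vaf_and_fs_boundaries(self, config):
        assert passes_quality(_call(vaf=0.25), config).verdict == "fail"
        assert passes_quality(_call(fs=6.0), config).verdict == "fail"

    def test_missing_metric_fails_conservatively(self, config):
        d = passes_quality(_call(qd=None), config)
        assert d.verdict == "fail" and "missing_metric" in d.failed_criteria

    def test_thousand_random_calls_match_oracle_recount(self, config, rng):
        calls = [
            _call(qd=rng.uniform(0, 5), fs=rng.uniform(0, 12),
                  depth=int(rng.integers(1, 30)), vaf=rng.uniform(0, 1))
            for _ in range(1000)
        ]
        n_pass = sum(passes_quality(c, config).verdict == "pass" for c in calls)
        # independent recount applying the four predicates separately
        oracle = sum(
            1 for c in calls
            if c.qd > 2 and c.fs < 6 and c.depth >= 10 and c.vaf > 0.25
        )
        assert n_pass == oracle

    def test_relaxing_thresholds_never_shrinks_pass_set(self, config, rng):
        calls = [
            _call(qd=rng.uniform(0, 5), fs=rng.uniform(0, 12),
                  depth=int(rng.integers(1, 30)), vaf=rng.uniform(0, 1))
            for _ in range(300)
        ]
        relaxed = config.with_overrides(qd_min=1.0, vaf_min=0.1, fs_max=10.0,
                                        depth_min=5)
        strict_pass = {id(c) for c in calls
                       if passes_quality(c, config).verdict == "pass"}
        relaxed_pass = {id(c) for c in calls
                        if passes_quality(c, relaxed).verdict == "pass"}
        assert strict_pass <= relaxed_pass


class TestPlatformIntersection:
    def test_exact_intersection(self):
        a = {VariantKey("1", i, "A", "G") for i in (1, 2, 3)}
        b = {VariantKey("1", i, "A", "G") for i in (2, 3, 4)}
        assert intersect_platforms({"A": a, "B": b}) == a & b

    def test_disjoint_sets_give_empty(self):
        a = {VariantKey("1", 1, "A", "G")}
        b = {VariantKey("1", 2, "A", "G")}
        assert intersect_platforms({"A": a, "B": b}) == set()

    def test_single_platform_is_identity(self):
        a = {VariantKey("1", 1, "A", "G")}
        assert intersect_platforms({"B": a}) == a

    def test_divergent_indel_spellings_match_after_normalization(self):
        # one platform reports the deletion at the left edge of the run,
        # the other at the right edge; both collapse to one key
        ctx = RefWindow("1", 95, "GGGGCATTTTGC")
        left = normalize_variant("1", 100, "AT", "A", ctx)
        right = normalize_variant("1", 103, "TT", "T", ctx)
        assert intersect_platforms({"A": {left}, "B": {right}}) == {left}


def _oracle_homopolymer(seq: str, start: int, span: tuple[int, int],
                        min_run: int) -> bool:
    """Independent run-length scan with +/-1 adjacency."""
    lo, hi = span[0] - 1, span[1] + 1
    i = 0
    while i < len(seq):
        j = i
        while j < len(seq) and seq[j] == seq[i]:
            j += 1
        if j - i >= min_run and (start + i) <= hi and (start + j - 1) >= lo:
            return True
        i = j
    return False


class TestHomopolymer:
    def test_run_of_five_flags(self, config):
        ctx = RefWindow("1", 95, "GACGCACTTTTTCGACGCA")  # TTTTT at 103-107
        key = VariantKey("1", 104, "T", "A")
        assert flag_homopolymer(key, ctx, config) is True

    def test_run_of_four_does_not_flag(self, config):
        ctx = RefWindow("1", 95, "GACGCACTTTTCGACGCAG")  # TTTT only
        key = VariantKey("1", 104, "T", "A")
        assert flag_homopolymer(key, ctx, config) is False

    def test_window_too_short_is_error(self, config):
        ctx = RefWindow("1", 99, "ACGTT")
        with pytest.raises(DataError):
            flag_homopolymer(VariantKey("1", 100, "C", "T"), ctx, config)

    def test_500_random_loci_match_scan_oracle(self, config, rng):
        seq = "".join(rng.choice(list("ACGT"), 3000))
        # salt with explicit runs so the flag fires often
        seq = seq[:500] + "TTTTT" + seq[505:1500] + "AAAAAA" + seq[1506:]
        ctx = RefWindow("1", 1, seq)
        mismatches = 0
        for _ in range(500):
            pos = int(rng.integers(20, len(seq) - 20))
            ref = ctx.base(pos)
            alt = "A" if ref != "A" else "G"
            key = VariantKey("1", pos, ref, alt)
            got = flag_homopolymer(key, ctx, config)
            want = _oracle_homopolymer(seq, 1, (pos, pos),
                                       config.homopolymer_min_run)
            mismatches += got != want
        assert mismatches == 0
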