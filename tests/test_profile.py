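"""Quality-gated site calling, frequencies, isoform tables and recoding."""

import numpy as np
import pytest

from ampedit.align import AlignedRead, AmpliconAligner
from ampedit.profiling import (
    EDITED,
    MASKED,
    UNEDITED,
    ReadSiteCalls,
    build_recoding_table,
    call_sites,
    isoform_counts,
    profile_sample,
    site_frequencies,
    translate_pattern,
)
from ampedit.reference import all_patterns, pattern_index
from ampedit.simulate import SimulationConfig, generate_reads, marginalize


def _read(ref, bases=None, quals=None, start=0, length=None):
    length = length if length is not None else len(ref)
    seq = list(ref.sequence[start : start + length])
    q = np.full(length, 30, dtype=np.int16)
    for pos, b in (bases or {}).items():
        seq[pos - start] = b
    for pos, v in (quals or {}).items():
        q[pos - start] = v
    return AlignedRead("r", start, "".join(seq), q)


class TestCallSites:
    def test_reference_read_is_unedited_and_complete(self, ref):
        calls = call_sites(_read(ref), ref)
        assert calls.calls == (UNEDITED,) * 5 and calls.complete

    def test_low_quality_site_is_masked(self, ref):
        c_offset = ref.site_offsets[3]  # site C
        calls = call_sites(
            _read(ref, bases={c_offset: "G"}, quals={c_offset: 19}), ref
        )
        assert calls.calls[3] == MASKED and not calls.complete

    def test_quality_exactly_at_gate_is_called(self, ref):
        c_offset = ref.site_offsets[3]
        calls = call_sites(
            _read(ref, bases={c_offset: "G"}, quals={c_offset: 20}), ref
        )
        assert calls.calls[3] == EDITED

    def test_non_AG_base_is_masked(self, ref):
        a_offset = ref.site_offsets[0]
        calls = call_sites(_read(ref, bases={a_offset: "T"}), ref)
        assert calls.calls[0] == MASKED

    def test_uncovered_sites_are_masked(self, ref):
        calls = call_sites(_read(ref, length=50), ref)  # ends before the sites
        assert calls.calls == (MASKED,) * 5

    def test_raising_min_q_never_increases_coverage(self, ref, rng):
        reads = [
            _read(ref, quals={o: int(rng.integers(2, 41)) for o in ref.site_offsets})
            for _ in range(50)
        ]
        prev = np.full(5, len(reads) + 1)
        for min_q in (0, 10, 20, 30, 41):
            calls = [call_sites(r, ref, min_q=min_q) for r in reads]
            cov = site_frequencies(calls)["n_covered"].to_numpy()
            assert np.all(cov <= prev)
            prev = cov


class TestSiteFrequencies:
    def test_forty_percent(self):
        calls = [
            ReadSiteCalls(f"r{i}", ((EDITED if i < 4 else UNEDITED),) + (UNEDITED,) * 4)
            for i in range(10)
        ]
        df = site_frequencies(calls)
        assert df.loc["A", "pct"] == 40.0 and df.loc["A", "n_covered"] == 10

    def test_fully_masked_site_reported_missing_not_zero(self):
        calls = [
            ReadSiteCalls(f"r{i}", (UNEDITED, UNEDITED, MASKED, UNEDITED, UNEDITED))
            for i in range(5)
        ]
        df = site_frequencies(calls)
        assert np.isnan(df.loc["E", "pct"]) and df.loc["E", "n_covered"] == 0

    def test_empty_collection_is_an_error(self):
        with pytest.raises(ValueError):
            site_frequencies([])


class TestIsoformCounts:
    def test_trivial_tallies(self):
        empty = (UNEDITED,) * 5
        full = (EDITED,) * 5
        counts, n_inc = isoform_counts(
            [ReadSiteCalls("a", empty), ReadSiteCalls("b", empty),
             ReadSiteCalls("c", full)]
        )
        assert counts[0] == 2 and counts[31] == 1 and counts.sum() == 3
        assert n_inc == 0

    def test_incomplete_reads_counted_separately(self):
        calls = [
            ReadSiteCalls("a", (UNEDITED,) * 5),
            ReadSiteCalls("b", (MASKED,) + (UNEDITED,) * 4),
        ]
        counts, n_inc = isoform_counts(calls)
        assert counts.sum() == 1 and n_inc == 1


class TestRecoding:
    def test_fully_edited_is_VGV_and_unedited_is_INI(self, recoding):
        assert recoding[(1, 1, 1, 1, 1)] == "VGV"
        assert recoding[(0, 0, 0, 0, 0)] == "INI"

    def test_32_patterns_collapse_to_24_proteins(self, recoding):
        assert len(recoding) == 32
        assert len(set(recoding.values())) == 24

    def test_matches_hand_written_residue_rules(self, recoding):
        res156 = {(0, 0): "I", (1, 0): "V", (0, 1): "M", (1, 1): "V"}
        res158 = {(0, 0): "N", (1, 0): "D", (0, 1): "S", (1, 1): "G"}
        res160 = {0: "I", 1: "V"}
        for pattern in all_patterns():
            a, b, e, c, d = pattern
            expected = res156[(a, b)] + res158[(e, c)] + res160[d]
            assert translate_pattern(pattern, recoding) == expected

    def test_preimage_sizes_sum_to_32(self, recoding):
        sizes = {}
        for pep in recoding.values():
            sizes[pep] = sizes.get(pep, 0) + 1
        assert sum(sizes.values()) == 32


class TestProfileSample:
    def test_single_unedited_read(self, ref):
        prof = profile_sample([_read(ref)], ref, "s")
        assert (prof.site_table["pct"] == 0.0).all()
        assert prof.isoform_counts[0] == 1 and prof.n_complete == 1

    def test_zero_reads_is_an_error(self, ref):
        with pytest.raises(ValueError, match="zero accepted"):
            profile_sample([], ref, "empty_sample")

    def test_conservation_and_marginal_consistency(self, ref, tmp_path):
        cfg = SimulationConfig(n_reads=5000, seed=21)
        generate_reads(ref, cfg, tmp_path / "r.fq", "s")
        aligner = AmpliconAligner(ref)
        accepted = [r for r in aligner.align_fastq(tmp_path / "r.fq")]
        prof = profile_sample(accepted, ref, "s")
        # conservation: complete + incomplete = accepted
        assert prof.n_complete + prof.n_incomplete == len(accepted)
        # the complete-read site marginal is an exact identity
        marg = prof.complete_read_marginal()
        patterns = np.array(list(all_patterns()))
        expected = patterns.T @ prof.isoform_counts * 100.0 / prof.n_complete
        assert np.allclose(marg, expected)

    def test_recovery_within_three_binomial_se(self, ref, tmp_path):
        p = (0.6, 0.5, 0.3, 0.05, 0.35)
        cfg = SimulationConfig(
            per_site_probs=p, n_reads=20_000, base_error_rate=0.001, seed=23
        )
        generate_reads(ref, cfg, tmp_path / "r.fq", "s")
        aligner = AmpliconAligner(ref)
        prof = profile_sample(list(aligner.align_fastq(tmp_path / "r.fq")), ref, "s")
        for i, site in enumerate(("A", "B", "E", "C", "D")):
            est = prof.site_table.loc[site, "pct"] / 100
            n = prof.site_table.loc[site, "n_covered"]
            se = np.sqrt(p[i] * (1 - p[i]) / n)
            assert abs(est - p[i]) <= 3 * se + cfg.base_error_rate

    def test_tsv_round_trip(self, ref, tmp_path, recoding):
        prof = profile_sample([_read(ref)], ref, "s", genotype="WT", region="ctx")
        prof.write_tsv(tmp_path, recoding=recoding)
        back = type(prof).read_tsv(tmp_path, "s", "WT", "ctx")
        assert np.array_equal(back.isoform_counts, prof.isoform_counts)
        assert list(back.site_table["n_covered"]) == list(
            prof.site_table["n_covered"]
        )
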