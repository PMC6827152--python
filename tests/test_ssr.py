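"""Perfect-SSR detection: canonical motifs by exhaustive enumeration,
scanner equivalence with a brute-force oracle, and planted-locus recovery."""

from __future__ import annotations

import numpy as np
import pytest

from genomesurvey import canonical_motif, find_ssrs, summarize_ssrs
from genomesurvey._encode import revcomp
from genomesurvey.ssr import primitive_unit


def oracle_motif(unit):
    """Enumerate every rotation of the (primitive) unit and its revcomp."""
    n = len(unit)
    while True:
        reduced = next(
            (unit[:p] for p in range(1, n) if n % p == 0 and unit == unit[:p] * (n // p)),
            unit,
        )
        if reduced == unit:
            break
        unit, n = reduced, len(reduced)
    rc = revcomp(unit)
    cands = [unit[i:] + unit[:i] for i in range(n)] + [rc[i:] + rc[:i] for i in range(n)]
    return sorted(cands)[0]


def oracle_ssrs(seq, min_len=12):
    """Brute force: test every (segment, unit length, start) by direct string
    comparison; maximality = the period cannot be extended left by one base;
    complete copies counted from the start."""
    out = set()
    pos = 0
    for segment in seq.upper().split("N"):
        n = len(segment)
        for m in range(2, 7):
            for start in range(0, n - 2 * m + 1):
                if start > 0 and segment[start - 1] == segment[start + m - 1]:
                    continue  # left-extendable: not the run start
                unit = segment[start : start + m]
                if primitive_unit(unit) != unit:
                    continue
                copies = 1
                while segment[start + copies * m : start + (copies + 1) * m] == unit:
                    copies += 1
                span = copies * m
                if copies >= 2 and span >= min_len:
                    out.add((pos + start, pos + start + span, m, oracle_motif(unit), copies))
        pos += n + 1
    return out


def records_to_set(records):
    return {(r.start, r.end, r.unit_length, r.motif, r.copies) for r in records}


class TestCanonicalMotif:
    @pytest.mark.parametrize(
        "unit,expected",
        [
            ("TG", "AC"),  # rotations {TG,GT}; revcomp rotations {CA,AC} -> AC
            ("AC", "AC"),
            ("ACG", "ACG"),
            ("GAT", "ATC"),
            ("ATAT", "AT"),  # power of a shorter unit -> primitive root
            ("AGAGAG", "AG"),
        ],
    )
    def test_known_cases(self, unit, expected):
        assert canonical_motif(unit) == expected

    def test_matches_enumeration_oracle_on_all_dinucleotides(self):
        for a in "ACGT":
            for b in "ACGT":
                if a == b:
                    continue
                assert canonical_motif(a + b) == oracle_motif(a + b)

    def test_matches_enumeration_oracle_on_random_units(self, rng):
        for _ in range(300):
            ln = int(rng.integers(2, 7))
            unit = "".join(rng.choice(list("ACGT"), ln))
            if len(set(unit)) == 1:
                continue  # homopolymer: no di-hexa motif
            assert canonical_motif(unit) == oracle_motif(unit)

    def test_strand_equivalence(self, rng):
        for _ in range(100):
            ln = int(rng.integers(2, 7))
            unit = "".join(rng.choice(list("ACGT"), ln))
            if len(set(unit)) == 1:
                continue
            assert canonical_motif(unit) == canonical_motif(revcomp(unit))

    def test_invalid_units_rejected(self):
        with pytest.raises(ValueError):
            canonical_motif("ACGTACG")  # length 7
        with pytest.raises(ValueError):
            canonical_motif("AN")


class TestFindSsrs:
    def test_twelve_bp_dinucleotide_boundary(self):
        recs = find_ssrs("ACACACACACAC")  # AC x6 = 12 bp
        assert len(recs) == 1
        r = recs[0]
        assert (r.start, r.end, r.unit_length, r.copies, r.motif) == (0, 12, 2, 6, "AC")

    def test_ten_bp_run_below_threshold(self):
        assert find_ssrs("ACACACACAC") == []  # AC x5 = 10 bp

    def test_penta_needs_three_copies(self):
        assert find_ssrs("AACGT" * 2) == []  # 10 bp < 12
        recs = find_ssrs("AACGT" * 3)
        assert len(recs) == 1
        assert recs[0].copies == 3

    def test_partial_trailing_copy_not_counted(self):
        recs = find_ssrs("ACGACGACGACGAC")  # ACG x4 + "AC"
        assert len(recs) == 1
        assert recs[0].end - recs[0].start == 12

    def test_runs_split_at_n(self):
        seq = "ACACACACACAC" + "N" + "ACACACACACAC"
        recs = find_ssrs(seq)
        assert [(r.start, r.end) for r in recs] == [(0, 12), (13, 25)]

    def test_non_primitive_units_reported_once(self):
        recs = find_ssrs("AT" * 8)  # also matches ATAT x4
        assert len(recs) == 1
        assert recs[0].unit_length == 2

    def test_planted_ssrs_recovered_exactly(self, rng):
        rs = np.random.default_rng(99)
        plants = [("AC", 7), ("AGG", 5), ("ACGT", 4), ("AACGT", 3), ("ACGTAG", 3)]
        seq_parts = []
        expected = []
        pos = 0

        def random_gap(n):
            # SSR-free-ish gap; verified against the oracle anyway
            return "".join(rs.choice(list("ACGT"), n))

        def other_base(b):
            return "G" if b != "G" else "T"

        for unit, copies in plants:
            gap = random_gap(30)
            # guard bases so the gap cannot extend the planted period
            gap = gap[:-1] + other_base(unit[-1])
            seq_parts.append(gap)
            pos += len(gap)
            run = unit * copies
            expected.append((pos, pos + len(run)))
            seq_parts.append(run)
            pos += len(run)
            seq_parts.append(other_base(unit[0]))
            pos += 1
        seq_parts.append(random_gap(30))
        seq = "".join(seq_parts)
        recs = find_ssrs(seq)
        found = records_to_set(recs)
        oracle = oracle_ssrs(seq)
        assert found == oracle
        spans = {(r.start, r.end) for r in recs}
        for span in expected:
            assert span in spans

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_bruteforce_oracle_on_repeat_rich_random(self, seed):
        # low-entropy alphabet so runs actually occur
        rs = np.random.default_rng(seed)
        seq = "".join(rs.choice(list("AACCGT"), 3000))
        assert records_to_set(find_ssrs(seq)) == oracle_ssrs(seq)

    def test_same_unit_length_records_nearly_disjoint(self, rng):
        # maximal runs of the same period never share a complete copy;
        # adjacent runs may share at most unit_length-1 boundary bases
        rs = np.random.default_rng(7)
        seq = "".join(rs.choice(list("AC"), 5000))
        recs = find_ssrs(seq)
        by_m: dict[int, list] = {}
        for r in recs:
            by_m.setdefault(r.unit_length, []).append((r.start, r.end))
        for m, spans in by_m.items():
            spans.sort()
            for i in range(len(spans) - 1):
                overlap = spans[i][1] - spans[i + 1][0]
                assert overlap < m

    def test_strand_invariance_of_motif_classes(self, rng):
        rs = np.random.default_rng(11)
        seq = "".join(rs.choice(list("AACGT"), 4000))
        fwd = find_ssrs(seq)
        rev = find_ssrs(revcomp(seq))
        assert sorted((r.motif, r.unit_length) for r in fwd) == sorted(
            (r.motif, r.unit_length) for r in rev
        )
        n = len(seq)
        fwd_regions = sorted(r.start for r in fwd)
        rev_regions = sorted(n - r.end for r in rev)
        # mirrored coordinates up to a phase shift < unit length
        assert all(abs(a - b) < 6 for a, b in zip(fwd_regions, rev_regions))


class TestSummaries:
    def test_reference_class_counts(self):
        s = summarize_ssrs([84406, 50420, 11361, 2200, 870])
        assert s.total == 149257
        assert s.percentages == {
            "di": 56.55,
            "tri": 33.78,
            "tetra": 7.61,
            "penta": 1.47,
            "hexa": 0.58,
        }

    def test_single_class(self):
        s = summarize_ssrs([1, 0, 0, 0, 0])
        assert s.percentages["di"] == 100.0

    def test_empty_records(self):
        s = summarize_ssrs([])
        assert s.total == 0
        assert all(v == 0 for v in s.counts.values())

    def test_counts_from_records(self):
        recs = find_ssrs("ACACACACACAC" + "T" * 20 + "ACGACGACGACG")
        s = summarize_ssrs(recs)
        assert s.counts["di"] == 1
        assert s.counts["tri"] == 1
        assert s.total == 2
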