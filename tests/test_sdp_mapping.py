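"""SDP encoding, 3-way classification and candidate-interval scanning."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from xcemap import (
    GenotypeTable,
    StrainPanel,
    classify_sdp,
    classify_table,
    encode_sdp,
    refine_with_strains,
    scan_intervals,
)
from xcemap.io_tables import Variant
from xcemap.sdp_mapping import (
    CONSISTENT,
    INCONSISTENT,
    MISSING,
    PARTIAL,
    SDPRecord,
    brute_force_scan,
)


class TestEncode:
    def test_reference_anchored_coding(self, tiny_panel):
        sdp, mono, multi = encode_sdp(
            {"B6": "T", "A1": "C", "A2": "C", "A3": "T", "D1": "T", "D2": "T"},
            tiny_panel,
        )
        assert sdp == {"B6": 0, "A1": 1, "A2": 1, "A3": 0, "D1": 0, "D2": 0}
        assert not mono and not multi

    def test_monomorphic_flagged(self, tiny_panel):
        sdp, mono, multi = encode_sdp(
            {s: "T" for s in tiny_panel.strains()}, tiny_panel
        )
        assert all(v == 0 for v in sdp.values()) and mono

    def test_reference_missing_skips(self, tiny_panel):
        sdp, _, _ = encode_sdp({"B6": None, "A1": "C"}, tiny_panel)
        assert sdp is None

    def test_multi_allelic_flagged(self, tiny_panel):
        calls = {"B6": "T", "A1": "C", "A2": "G", "A3": "C", "D1": "T", "D2": "T"}
        _, _, multi = encode_sdp(calls, tiny_panel)
        assert multi


def _oracle_classify(sdp, group1, group0):
    """Set-logic restatement of the classification rule."""
    g1 = [sdp[s] for s in group1 if sdp[s] != MISSING]
    g0 = [sdp[s] for s in group0 if sdp[s] != MISSING]
    if any(v == 0 for v in g1) and any(v == 1 for v in g0):
        return INCONSISTENT
    if g1 and g0 and all(v == 1 for v in g1) and all(v == 0 for v in g0):
        return CONSISTENT
    return PARTIAL


class TestClassify:
    G1 = ["A1", "A2", "A3"]
    G0 = ["B6", "D1", "D2"]

    def test_classical_panel_perfect_partition_is_consistent(self, classical_panel):
        group0, group1 = classical_panel.phenotype_groups("a")
        sdp = {**{s: 1 for s in group1}, **{s: 0 for s in group0}, "C57L/J": 1}
        assert classify_sdp(sdp, group1, group0) == CONSISTENT

    def test_opposed_carriers_are_inconsistent(self, classical_panel):
        group0, group1 = classical_panel.phenotype_groups("a")
        sdp = {**{s: 1 for s in group1}, **{s: 0 for s in group0}}
        sdp["A/J"] = 0      # an Xce^a carrier sharing the reference allele
        sdp["DBA/1J"] = 1   # an Xce^b carrier with the alternative allele
        assert classify_sdp(sdp, group1, group0) == INCONSISTENT

    def test_exhaustive_enumeration_matches_oracle(self):
        strains = self.G0 + self.G1
        for bits in itertools.product([0, 1], repeat=6):
            sdp = dict(zip(strains, bits))
            assert classify_sdp(sdp, self.G1, self.G0) == _oracle_classify(
                sdp, self.G1, self.G0
            )

    @given(st.lists(st.sampled_from([0, 1, MISSING]), min_size=6, max_size=6))
    @settings(deadline=None)
    def test_partition_property_with_missingness(self, bits):
        """Every SDP lands in exactly one class; matches the set-logic oracle."""
        sdp = dict(zip(self.G0 + self.G1, bits))
        cls = classify_sdp(sdp, self.G1, self.G0)
        assert cls in (CONSISTENT, INCONSISTENT, PARTIAL)
        assert cls == _oracle_classify(sdp, self.G1, self.G0)

    @given(
        st.lists(st.sampled_from([0, 1]), min_size=6, max_size=6),
        st.integers(min_value=0, max_value=5),
    )
    @settings(deadline=None)
    def test_missingness_monotonicity(self, bits, drop):
        """Blanking one call never swaps consistent <-> inconsistent directly."""
        strains = self.G0 + self.G1
        sdp = dict(zip(strains, bits))
        before = classify_sdp(sdp, self.G1, self.G0)
        sdp[strains[drop]] = MISSING
        after = classify_sdp(sdp, self.G1, self.G0)
        if before == CONSISTENT:
            assert after != INCONSISTENT
        if before == INCONSISTENT:
            assert after != CONSISTENT

    def test_empty_group_fatal(self):
        with pytest.raises(ValueError):
            classify_sdp({"B6": 0}, [], ["B6"])


def _records(pattern, positions, chrom="X"):
    codes = {"C": CONSISTENT, "I": INCONSISTENT, "P": PARTIAL}
    return [
        SDPRecord(f"v{i}", pos, "array", chrom, {}, classification=codes[c])
        for i, (c, pos) in enumerate(zip(pattern, positions))
    ]


class TestScan:
    def test_flanked_run(self):
        recs = _records("ICCPCI", [5, 10, 20, 30, 50, 60])
        rep = scan_intervals(recs, min_count=3)
        assert (rep.min_interval.start_bp, rep.min_interval.end_bp) == (10, 50)
        assert (rep.max_interval.start_bp, rep.max_interval.end_bp) == (5, 60)
        assert rep.consistent_count == 3

    def test_all_inconsistent_yields_no_interval(self):
        rep = scan_intervals(_records("III", [1, 2, 3]), min_count=1)
        assert rep.status == "no-interval" and rep.min_interval is None

    def test_below_min_count_yields_no_interval(self):
        rep = scan_intervals(_records("CC", [1, 2]), min_count=3)
        assert rep.status == "no-interval"

    def test_tie_breaks_by_span_then_position(self):
        # two runs of 2 consistent each; second spans wider
        recs = _records("CCICPC", [10, 20, 30, 40, 50, 70])
        rep = scan_intervals(recs, min_count=2)
        assert (rep.min_interval.start_bp, rep.min_interval.end_bp) == (40, 70)

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_brute_force_on_random_tables(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(20, 120))
        pattern = rng.choice(list("CIP"), size=n, p=[0.35, 0.25, 0.40])
        positions = np.sort(rng.choice(10_000, size=n, replace=False))
        recs = _records("".join(pattern), positions)
        a = scan_intervals(recs, min_count=3)
        b = brute_force_scan(recs, min_count=3)
        assert a.status == ("no-interval" if b.min_interval is None else "ok")
        if a.min_interval is not None:
            assert (a.min_interval.start_bp, a.min_interval.end_bp) == (
                b.min_interval.start_bp, b.min_interval.end_bp)
            assert (a.max_interval.start_bp, a.max_interval.end_bp) == (
                b.max_interval.start_bp, b.max_interval.end_bp)
            assert a.consistent_count == b.consistent_count


def _table_from_bits(bits, strains, positions):
    variants = [Variant(f"v{i}", "X", int(p)) for i, p in enumerate(positions)]
    calls = np.empty((len(variants), len(strains)), dtype=object)
    for i in range(len(variants)):
        for j in range(len(strains)):
            calls[i, j] = "G" if bits[i][j] else "A"
    return GenotypeTable(variants, strains, calls)


class TestRefinement:
    def test_matching_added_strain_changes_nothing(self, tiny_panel):
        strains = ["B6", "D1", "D2", "A1", "A2", "A3", "NEW"]
        # NEW matches the a-group pattern everywhere
        bits = [[0, 0, 0, 1, 1, 1, 1]] * 6
        table = _table_from_bits(bits, strains, range(10, 70, 10))
        rep = refine_with_strains(table, tiny_panel, {"NEW": "a"}, min_count=3)
        assert rep.consistent_before == rep.consistent_after == 6
        assert rep.proximal_shift_kb == 0.0 and rep.distal_shift_kb == 0.0

    def test_breaking_strain_moves_proximal_boundary(self, tiny_panel):
        strains = ["B6", "D1", "D2", "A1", "A2", "A3", "NEW"]
        consistent = [0, 0, 0, 1, 1, 1]
        bits = [
            consistent + [0],  # pos 10_000: NEW (a-group) shares ref allele -> demoted
            consistent + [0],  # pos 20_000: demoted
            consistent + [1],  # pos 30_000
            consistent + [1],
            consistent + [1],
        ]
        table = _table_from_bits(bits, strains, [10_000, 20_000, 30_000, 40_000, 50_000])
        rep = refine_with_strains(table, tiny_panel, {"NEW": "a"}, min_count=3)
        assert rep.consistent_before == 5 and rep.consistent_after == 3
        assert rep.before.min_interval.start_bp == 10_000
        assert rep.after.min_interval.start_bp == 30_000
        assert rep.proximal_shift_kb == pytest.approx(20.0)

    def test_absent_strain_is_fatal(self, tiny_panel):
        table = _table_from_bits([[0, 0, 0, 1, 1, 1]], tiny_panel.strains()[:6],
                                 [100])
        with pytest.raises(KeyError):
            refine_with_strains(table, tiny_panel, {"GHOST": "a"})

    @pytest.mark.parametrize("seed", range(10))
    def test_consistent_count_never_increases(self, seed, tiny_panel):
        """Adding a strain can only demote classifications."""
        rng = np.random.default_rng(100 + seed)
        strains = tiny_panel.strains() + ["NEW"]
        n = 40
        bits = rng.integers(0, 2, size=(n, len(strains)))
        bits[:, list(strains).index("B6")] = 0
        table = _table_from_bits(bits.tolist(), strains, np.sort(
            rng.choice(100_000, size=n, replace=False)))
        before, _ = classify_table(table, tiny_panel)
        allele = "a" if seed % 2 else "b"
        after, _ = classify_table(table, tiny_panel.with_strains({"NEW": allele}))
        cons_before = {r.variant_id for r in before if r.classification == CONSISTENT}
        cons_after = {r.variant_id for r in after if r.classification == CONSISTENT}
        assert cons_after <= cons_before
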