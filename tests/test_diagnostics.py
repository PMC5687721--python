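"""Diagnostic-window discovery against a brute-force oracle."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ednamark import diagnostics, iupac, seqio
from oracles import brute_min_placement_mm, brute_windows, count_mm

# ------------------------------------------------------------- consensus

def aln(*seqs):
    return seqio.MultipleAlignment(
        records=[seqio.SequenceRecord(id=f"h{i}", seq=s) for i, s in enumerate(seqs)]
    )


class TestDegenerateConsensus:
    def test_union_codes(self):
        assert diagnostics.degenerate_consensus(aln("AAAA", "GAAA")) == "RAAA"
        assert diagnostics.degenerate_consensus(aln("A", "C", "G", "T")) == "N"

    def test_identity_when_conserved(self):
        assert diagnostics.degenerate_consensus(aln("ACGT", "ACGT")) == "ACGT"

    def test_gap_dominates(self):
        assert diagnostics.degenerate_consensus(aln("AC-T", "ACGT")) == "AC-T"

    def test_empty_interval(self):
        assert diagnostics.degenerate_consensus(aln("ACGT"), 2, 2) == ""


# ------------------------------------------------------------- mismatches

class TestMismatchKernel:
    @pytest.mark.parametrize(
        "a, b, n",
        [
            ("R", "A", 0), ("R", "C", 1), ("ACGT", "ACGT", 0),
            ("GGTCTRACGAAAGCAATACT", "GGTCTAACGAAAGCAATACT", 0),
            ("ACGT", "ANGT", 0),  # template N matches
        ],
    )
    def test_examples(self, a, b, n):
        assert diagnostics.mismatches(a, b) == n

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            diagnostics.mismatches("ACG", "AC")

    @given(
        st.text(alphabet="ACGTRYSWKMBDHVN", min_size=1, max_size=30),
        st.data(),
    )
    @settings(max_examples=150, deadline=None)
    def test_agrees_with_set_membership_oracle(self, a, data):
        b = data.draw(st.text(alphabet="ACGTN", min_size=len(a), max_size=len(a)))
        assert diagnostics.mismatches(a, b) == count_mm(a, b)


# ----------------------------------------------------------- window scan

def make_panel(targets, nontargets):
    return seqio.HaplotypePanel(
        target_haplotypes=aln(*targets),
        nontarget_seqs=[
            seqio.SequenceRecord(id=f"n{i}", seq=s, taxon=f"nt_{i}")
            for i, s in enumerate(nontargets)
        ],
        target_taxon="target",
    )


class TestScanDiagnosticWindows:
    def test_planted_region_is_recovered(self):
        """Targets share a 20-mer absent (3 mismatches) from the non-target."""
        rng = np.random.default_rng(5)
        bases = np.array(list("ACGT"))
        backbone = "".join(bases[rng.integers(0, 4, size=120)])
        planted = backbone[40:60]
        nt = backbone[:40] + _mutate(planted, (3, 9, 16)) + backbone[60:]
        panel = make_panel([backbone, backbone[:10] + _mutate(backbone[10:12], (0,)) + backbone[12:]],
                           [nt])
        wins = diagnostics.scan_diagnostic_windows(panel, window_len=20,
                                                   max_degeneracy=8, min_mm=2)
        assert wins, "planted diagnostic region not found"
        assert any(w.start == 40 and w.end == 60 for w in wins)
        # oracle agreement on the full scan
        expected = brute_windows(
            [r.seq for r in panel.target_haplotypes.records],
            [r.seq for r in panel.nontarget_seqs], 20, 8, 2,
        )
        got = sorted((w.start, w.end, w.consensus, w.min_mismatches_vs_nontargets)
                     for w in wins)
        assert got == sorted(expected)

    def test_empty_nontargets_vacuous_specificity(self):
        panel = make_panel(["ACGT" * 10], [])
        wins = diagnostics.scan_diagnostic_windows(panel, window_len=20,
                                                   max_degeneracy=8, min_mm=2)
        assert len(wins) == 40 - 20 + 1

    def test_all_variable_columns_blocked_by_degeneracy(self):
        targets = ["A" * 20, "C" * 20, "G" * 20, "T" * 20]
        panel = make_panel(targets, [])
        assert diagnostics.scan_diagnostic_windows(panel, window_len=20,
                                                   max_degeneracy=8, min_mm=1) == []

    def test_window_len_floor(self):
        panel = make_panel(["ACGT" * 10], [])
        with pytest.raises(diagnostics.ParameterError):
            diagnostics.scan_diagnostic_windows(panel, window_len=10)

    def test_gap_columns_rejected(self):
        panel = make_panel(["AAAAA" * 5 + "-" + "AAAA" * 5, "AAAAA" * 5 + "A" + "AAAA" * 5], [])
        wins = diagnostics.scan_diagnostic_windows(panel, window_len=20,
                                                   max_degeneracy=8, min_mm=1)
        assert all(not (w.start <= 25 < w.end) for w in wins)

    @given(st.integers(0, 10_000))
    @settings(max_examples=40, deadline=None)
    def test_oracle_equivalence_random_panels(self, seed):
        rng = np.random.default_rng(seed)
        bases = np.array(list("ACGT"))
        n = int(rng.integers(40, 120))
        ref = bases[rng.integers(0, 4, size=n)]
        targets = []
        for _ in range(int(rng.integers(1, 4))):
            h = ref.copy()
            for p in rng.choice(n, size=int(rng.integers(0, 3)), replace=False):
                h[p] = bases[rng.integers(0, 4)]
            targets.append("".join(h))
        targets = list(dict.fromkeys(targets))
        nontargets = []
        for _ in range(int(rng.integers(0, 3))):
            g = ref.copy()
            for p in rng.choice(n, size=int(rng.integers(0, 8)), replace=False):
                g[p] = bases[rng.integers(0, 4)]
            nontargets.append("".join(g))
        panel = make_panel(targets, nontargets)
        min_mm = int(rng.integers(1, 4))
        got = diagnostics.scan_diagnostic_windows(panel, window_len=18,
                                                  max_degeneracy=8, min_mm=min_mm)
        expected = brute_windows(targets, nontargets, 18, 8, min_mm)
        assert sorted((w.start, w.end, w.consensus, w.min_mismatches_vs_nontargets)
                      for w in got) == sorted(expected)

    def test_monotonicity_in_min_mm_and_degeneracy(self, small_panel):
        panel, _ = small_panel
        keys = lambda ws: {(w.start, w.end) for w in ws}
        loose = keys(diagnostics.scan_diagnostic_windows(panel, 20, 16, 1))
        tight = keys(diagnostics.scan_diagnostic_windows(panel, 20, 16, 3))
        assert tight <= loose
        small_deg = keys(diagnostics.scan_diagnostic_windows(panel, 20, 2, 1))
        assert small_deg <= loose

    def test_returned_windows_truly_divergent(self, small_panel):
        """Every window with min_mm >= 1 fails to match every non-target."""
        panel, _ = small_panel
        wins = diagnostics.scan_diagnostic_windows(panel, 20, 8, 2)
        for w in wins[:20]:
            for rec in panel.nontarget_seqs:
                assert brute_min_placement_mm(w.consensus, rec.seq) >= 2


def _mutate(seq, positions):
    rot = {"A": "C", "C": "G", "G": "T", "T": "A"}
    out = list(seq)
    for p in positions:
        out[p] = rot[out[p]]
    return "".join(out)


def test_window_report_is_one_based(tmp_path, small_panel):
    panel, _ = small_panel
    wins = diagnostics.scan_diagnostic_windows(panel, 20, 8, 2)
    out = tmp_path / "wins.tsv"
    diagnostics.write_window_report(wins, out)
    lines = out.read_text().splitlines()
    assert lines[0].startswith("window_start_1based")
    first = lines[1].split("\t")
    assert int(first[0]) == wins[0].start + 1
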