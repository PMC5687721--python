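"""Diagnostic-region discovery.

A diagnostic window is an interval of the target alignment that is conserved
across every target haplotype (summarised as a degenerate IUPAC consensus) yet
differs from every non-target panel sequence by at least ``min_mm`` mismatches
at the non-target's *best* ungapped placement, on either strand. Such windows
are where taxon-specific primers can anchor.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from . import iupac
from .seqio import HaplotypePanel, MultipleAlignment

#: shortest window we accept as a credible primer footprint
MIN_WINDOW_LEN = 15


class ParameterError(ValueError):
    pass


@dataclass(frozen=True)
class DiagnosticWindow:
    """One candidate primer-anchoring region on the target alignment.

    Coordinates are 0-based half-open alignment columns. ``consensus`` is the
    gap-free degenerate consensus over target haplotypes;
    ``min_mismatches_vs_nontargets`` is the worst case over the panel (the
    minimum over taxa of each taxon's best-placement mismatch count).
    """

    start: int
    end: int
    consensus: str
    min_mismatches_vs_nontargets: int
    per_nontarget_mismatches: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.end - self.start != len(self.consensus):
            raise ValueError("consensus length must equal end - start")
        if "-" in self.consensus:
            raise ValueError("diagnostic window consensus must be gap-free")
        if self.per_nontarget_mismatches:
            lo = min(self.per_nontarget_mismatches.values())
            if lo != self.min_mismatches_vs_nontargets:
                raise ValueError("min_mismatches_vs_nontargets inconsistent with map")

    @property
    def degeneracy(self) -> int:
        return iupac.degeneracy(self.consensus)

    def __len__(self) -> int:
        return self.end - self.start


def degenerate_consensus(alignment: MultipleAlignment, start: int = 0, end: int | None = None) -> str:
    """Per-column IUPAC union of observed bases over ``[start, end)``.

    A gap in any haplotype yields ``'-'`` for that column. An empty interval
    yields the empty string.
    """
    if end is None:
        end = alignment.length
    if not (0 <= start <= end <= alignment.length):
        raise IndexError(f"interval [{start}, {end}) outside alignment of length {alignment.length}")
    return "".join(iupac.union_code(alignment.column(i)) for i in range(start, end))


# re-exported comparison kernel (defined with the alphabet machinery)
mismatches = iupac.mismatches


def _window_lengths(window_len: int | Sequence[int]) -> list[int]:
    if isinstance(window_len, int):
        lens = [window_len]
    else:
        lo, hi = min(window_len), max(window_len)
        lens = list(range(lo, hi + 1))
    for L in lens:
        if L < MIN_WINDOW_LEN:
            raise ParameterError(
                f"window_len {L} below minimum credible primer length {MIN_WINDOW_LEN}"
            )
    return lens


def scan_diagnostic_windows(
    panel: HaplotypePanel,
    window_len: int | Sequence[int] = (18, 25),
    max_degeneracy: int = 8,
    min_mm: int = 2,
) -> list[DiagnosticWindow]:
    """Exhaustively scan the target alignment for diagnostic windows.

    ``window_len`` may be a single length or an inclusive ``(min, max)`` range
    scanned jointly. A window is returned iff

    * no target haplotype has a gap in it,
    * its consensus degeneracy (product of per-column set sizes) is at most
      ``max_degeneracy``, and
    * every non-target sequence mismatches the consensus at ``>= min_mm``
      positions at its best ungapped placement, on either strand.

    Per-taxon mismatch minima are recorded; results are sorted by descending
    ``min_mismatches_vs_nontargets``, then ascending start, then length.
    """
    aln = panel.target_haplotypes
    lens = _window_lengths(window_len)
    if aln.length < min(lens):
        raise ParameterError(
            f"alignment length {aln.length} shorter than window length {min(lens)}"
        )
    full_consensus = degenerate_consensus(aln)
    out: list[DiagnosticWindow] = []
    for L in lens:
        for start in range(aln.length - L + 1):
            cons = full_consensus[start:start + L]
            if "-" in cons:
                continue
            if iupac.degeneracy(cons) > max_degeneracy:
                continue
            per_taxon: dict[str, int] = {}
            ok = True
            for rec in panel.nontarget_seqs:
                best = iupac.min_mismatches_any_placement(cons, rec.ungapped)
                if best < min_mm:
                    ok = False
                    break
                prev = per_taxon.get(rec.taxon)
                per_taxon[rec.taxon] = best if prev is None else min(prev, best)
            if not ok:
                continue
            overall = min(per_taxon.values()) if per_taxon else min_mm
            out.append(
                DiagnosticWindow(
                    start=start,
                    end=start + L,
                    consensus=cons,
                    min_mismatches_vs_nontargets=overall,
                    per_nontarget_mismatches=per_taxon,
                )
            )
    out.sort(key=lambda w: (-w.min_mismatches_vs_nontargets, w.start, len(w)))
    return out


def write_window_report(windows: Iterable[DiagnosticWindow], path: str | Path) -> None:
    """TSV report; positions converted to 1-based inclusive for human readers."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(
            ["window_start_1based", "window_end_1based", "consensus",
             "degeneracy", "min_mismatch", "worst_nontarget_taxon"]
        )
        for win in windows:
            worst = ""
            if win.per_nontarget_mismatches:
                worst = min(win.per_nontarget_mismatches, key=win.per_nontarget_mismatches.get)
            w.writerow(
                [win.start + 1, win.end, win.consensus, win.degeneracy,
                 win.min_mismatches_vs_nontargets, worst]
            )
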