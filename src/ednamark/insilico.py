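"""Degenerate-aware, mismatch-tolerant in-silico PCR.

The computational stand-in for BLAST specificity checks and for wet-lab
cross-amplification panels: exhaustive binding-site search on both template
strands, convergent-pair amplicon prediction, and assay × taxon
cross-amplification matrices with per-assay specificity verdicts.

A primer position matches a template position by IUPAC set containment
(template ``N`` matches anything); a site is accepted iff its total mismatch
count is within policy and its 3'-terminal ``clamp3`` bases match perfectly —
mismatches at the extension end abort real PCR far more effectively than
internal ones.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from . import iupac
from .design import AssayDefinition
from .seqio import SequenceRecord


@dataclass(frozen=True)
class PcrPolicy:
    """Annealing tolerance for in-silico PCR."""

    max_mm: int = 2
    clamp3: int = 2
    size_window: tuple[int, int] = (50, 1500)


DEFAULT_POLICY = PcrPolicy()


@dataclass(frozen=True)
class BindingSite:
    """One accepted primer annealing site on a template.

    ``start``/``end`` are 0-based half-open template coordinates of the primer
    footprint; ``strand`` ``'+'`` means the primer sequence (5'→3') matches the
    template string directly, ``'-'`` that it matches the reverse complement.
    ``ambiguous`` counts template ``N`` positions under the footprint.
    """

    template_id: str
    strand: str
    start: int
    end: int
    mismatches: int
    ambiguous: int = 0

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError("strand must be '+' or '-'")


@dataclass(frozen=True)
class AmpliconPrediction:
    """A predicted PCR product: convergent forward/reverse sites on opposite strands."""

    template_id: str
    forward_site: BindingSite
    reverse_site: BindingSite
    product_bp: int

    def __post_init__(self) -> None:
        span = max(self.forward_site.end, self.reverse_site.end) - min(
            self.forward_site.start, self.reverse_site.start
        )
        if self.product_bp != span:
            raise ValueError("product_bp must equal the site span (both footprints included)")


def _scan_one_strand(
    primer_masks: np.ndarray,
    template_masks: np.ndarray,
    max_mm: int,
    clamp3: int,
    three_prime_at_end: bool,
) -> list[tuple[int, int, int]]:
    """Offsets where the primer anneals; returns (start, mismatches, n_ambiguous).

    ``three_prime_at_end`` states whether the primer's 3' terminus sits at the
    high-coordinate end of the footprint (true when the primer as written runs
    left-to-right along the scanned array).
    """
    n, k = len(template_masks), len(primer_masks)
    if n < k:
        return []
    win = np.lib.stride_tricks.sliding_window_view(template_masks, k)
    is_n = win == 15
    mism = ((win & ~primer_masks) != 0) & ~is_n
    counts = mism.sum(axis=1)
    if clamp3 > 0:
        clamp_cols = mism[:, -clamp3:] if three_prime_at_end else mism[:, :clamp3]
        clamp_ok = ~clamp_cols.any(axis=1)
    else:
        clamp_ok = np.ones(len(counts), dtype=bool)
    ok = (counts <= max_mm) & clamp_ok
    ambig = is_n.sum(axis=1)
    return [(int(i), int(counts[i]), int(ambig[i])) for i in np.nonzero(ok)[0]]


def find_binding_sites(
    primer: str,
    template: SequenceRecord | str,
    max_mm: int = DEFAULT_POLICY.max_mm,
    clamp3: int = DEFAULT_POLICY.clamp3,
) -> list[BindingSite]:
    """Exhaustively scan both strands of a gap-free template for annealing sites.

    A primer longer than the template simply yields no sites. Sites are sorted
    by start, '+' strand first.
    """
    if isinstance(template, str):
        template = SequenceRecord(id="template", seq=template)
    if "-" in template.seq:
        raise ValueError(f"template {template.id!r} contains gaps; ungap it first")
    if max_mm < 0 or clamp3 < 0:
        raise ValueError("max_mm and clamp3 must be non-negative")
    primer = iupac.validate(primer, label="primer")
    p = iupac.to_masks(primer)
    t = iupac.to_masks(template.seq)
    sites: list[BindingSite] = []
    # + strand: primer 5'->3' aligns with template left-to-right, 3' end at the right
    for start, mm, amb in _scan_one_strand(p, t, max_mm, clamp3, three_prime_at_end=True):
        sites.append(BindingSite(template.id, "+", start, start + len(primer), mm, amb))
    # - strand: revcomp(primer) appears in the template; the primer 3' end maps
    # to the low-coordinate end of the footprint
    prc = iupac.to_masks(iupac.reverse_complement(primer))
    for start, mm, amb in _scan_one_strand(prc, t, max_mm, clamp3, three_prime_at_end=False):
        sites.append(BindingSite(template.id, "-", start, start + len(primer), mm, amb))
    sites.sort(key=lambda s: (s.start, s.strand))
    return sites


def predict_amplicons(
    assay: AssayDefinition,
    template: SequenceRecord | str,
    size_window: tuple[int, int] = DEFAULT_POLICY.size_window,
    max_mm: int = DEFAULT_POLICY.max_mm,
    clamp3: int = DEFAULT_POLICY.clamp3,
) -> list[AmpliconPrediction]:
    """All convergent forward/reverse primer pairings within the size window.

    Both template orientations are considered: the forward primer may anneal to
    the '+' strand with the reverse primer downstream on '-', or (when the
    record is deposited on the opposite strand) the mirror arrangement. The
    product includes both primer footprints; overlapping footprints are
    rejected. Results are sorted by product size then position.
    """
    if isinstance(template, str):
        template = SequenceRecord(id="template", seq=template)
    f_sites = find_binding_sites(assay.forward, template, max_mm, clamp3)
    r_sites = find_binding_sites(assay.reverse, template, max_mm, clamp3)
    lo, hi = size_window
    out: list[AmpliconPrediction] = []
    for fs in f_sites:
        for rs in r_sites:
            if fs.strand == "+" and rs.strand == "-" and rs.start >= fs.end:
                product = rs.end - fs.start
            elif fs.strand == "-" and rs.strand == "+" and fs.start >= rs.end:
                product = fs.end - rs.start
            else:
                continue
            if lo <= product <= hi:
                out.append(AmpliconPrediction(template.id, fs, rs, product))
    out.sort(key=lambda a: (a.product_bp, min(a.forward_site.start, a.reverse_site.start)))
    return out


@dataclass
class CrossAmplificationMatrix:
    """Assay × taxon amplification outcomes with per-assay specificity verdicts."""

    assays: list[str]
    panel_taxa: list[str]
    cells: dict = field(default_factory=dict)  # (assay, taxon) -> list[AmpliconPrediction]
    verdicts: dict = field(default_factory=dict)  # assay -> "specific" | "non-specific"

    def amplifies(self, assay: str, taxon: str) -> bool:
        return bool(self.cells.get((assay, taxon)))

    def to_tsv(self, path: str | Path) -> None:
        """One row per assay, one column per taxon, cells '+'/'-'; the textual
        analogue of a cross-amplification gel panel."""
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh, delimiter="\t", lineterminator="\n")
            w.writerow(["assay", *self.panel_taxa, "verdict"])
            for a in self.assays:
                row = ["+" if self.amplifies(a, t) else "-" for t in self.panel_taxa]
                w.writerow([a, *row, self.verdicts.get(a, "")])


def cross_panel(
    assays: Sequence[AssayDefinition],
    panel: Sequence[SequenceRecord],
    policy: PcrPolicy = DEFAULT_POLICY,
) -> CrossAmplificationMatrix:
    """Run every assay against every panel taxon.

    A cell amplifies iff any record of that taxon yields at least one in-window
    product. An assay is *specific* iff the only amplified taxa are its own
    target taxon; a marker that also amplifies congeners is flagged
    non-specific (a genus-level marker).
    """
    taxa: list[str] = []
    for r in panel:
        if r.taxon not in taxa:
            taxa.append(r.taxon)
    mat = CrossAmplificationMatrix(assays=[a.name for a in assays], panel_taxa=taxa)
    for a in assays:
        amplified: set[str] = set()
        for r in panel:
            preds = predict_amplicons(
                a, r, size_window=policy.size_window,
                max_mm=policy.max_mm, clamp3=policy.clamp3,
            )
            if preds:
                mat.cells.setdefault((a.name, r.taxon), []).extend(preds)
                amplified.add(r.taxon)
        mat.verdicts[a.name] = (
            "specific" if amplified <= {a.target_taxon} else "non-specific"
        )
    return mat


def write_amplicon_tsv(preds: Iterable[AmpliconPrediction], path: str | Path) -> None:
    """Amplicon table with 1-based inclusive template positions."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(
            ["template", "fwd_strand", "fwd_start_1based", "fwd_end",
             "rev_strand", "rev_start_1based", "rev_end",
             "fwd_mismatches", "rev_mismatches", "product_bp"]
        )
        for p in preds:
            w.writerow(
                [p.template_id,
                 p.forward_site.strand, p.forward_site.start + 1, p.forward_site.end,
                 p.reverse_site.strand, p.reverse_site.start + 1, p.reverse_site.end,
                 p.forward_site.mismatches, p.reverse_site.mismatches, p.product_bp]
            )
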