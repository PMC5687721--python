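"""Primer-pair enumeration and ranking within diagnostic windows.

Candidate primers are sub-intervals of diagnostic windows; candidate assays
are ordered upstream/downstream pairs whose implied product lies in the
requested amplicon range. Each candidate runs a filter cascade (degeneracy,
GC, melting-temperature balance over worst-case expansions, hairpin,
self-dimer, cross-dimer); survivors are ranked by specificity margin, then Tm
balance, then product size, giving a deterministic total order.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable, Sequence

from . import iupac, thermo
from .diagnostics import DiagnosticWindow
from .seqio import HaplotypePanel, Locus

#: filter names, in cascade order, used as attrition-report keys
FILTERS = ("degeneracy", "gc", "tm_diff", "hairpin", "self_dimer", "cross_dimer")


@dataclass(frozen=True)
class AssayDefinition:
    """One PCR marker: a primer pair plus its assay conditions.

    ``forward`` is written 5'→3' on the sense strand; ``reverse`` is written
    5'→3' as synthesised, i.e. the reverse complement of the sense-strand
    region it covers. ``annealing_C`` is the empirical PCR annealing
    temperature (an optimised assay condition, not a computed Tm).
    """

    name: str
    target_taxon: str
    forward: str
    reverse: str
    locus: Locus = "other"
    annealing_C: float | None = None
    mg_mM: float | None = None
    expected_amplicon_bp: int | None = None
    detection_limit_ng_ml: float | None = None
    forward_name: str = ""
    reverse_name: str = ""

    def __post_init__(self) -> None:
        f = iupac.validate(self.forward, label=f"{self.name} forward")
        r = iupac.validate(self.reverse, label=f"{self.name} reverse")
        if "-" in f or "-" in r:
            raise ValueError(f"{self.name}: primers must be gap-free")
        object.__setattr__(self, "forward", f)
        object.__setattr__(self, "reverse", r)
        if self.expected_amplicon_bp is not None and self.expected_amplicon_bp < len(f) + len(r):
            raise ValueError(
                f"{self.name}: amplicon {self.expected_amplicon_bp} bp shorter than "
                "the two primer footprints"
            )


@dataclass(frozen=True)
class DesignConstraints:
    """Filter thresholds for assay design; all ranges are inclusive."""

    primer_len: tuple[int, int] = (18, 25)
    amplicon_bp: tuple[int, int] = (100, 400)
    max_tm_diff_C: float = 5.0
    max_degeneracy: int = 8
    gc: tuple[float, float] = (0.2, 0.8)
    forbid_hairpin: bool = True
    forbid_dimer: bool = True

    def __post_init__(self) -> None:
        for name in ("primer_len", "amplicon_bp", "gc"):
            lo, hi = getattr(self, name)
            if lo > hi:
                raise ValueError(f"{name}: min {lo} > max {hi}")


@dataclass
class RankedAssay:
    """A surviving candidate with the scores that ranked it."""

    assay: AssayDefinition
    specificity_margin: int  # sum over both primers of min non-target mismatches
    tm_diff_C: float
    fwd_interval: tuple[int, int]  # alignment columns
    rev_interval: tuple[int, int]


def _sub_primers(window: DiagnosticWindow, primer_len: tuple[int, int], max_deg: int):
    """All constraint-length sub-intervals of a window with bounded degeneracy."""
    lo, hi = primer_len
    for L in range(lo, hi + 1):
        if L > len(window):
            continue
        for off in range(len(window) - L + 1):
            sub = window.consensus[off:off + L]
            if iupac.degeneracy(sub) <= max_deg:
                yield (window.start + off, window.start + off + L, sub)


def _tm_range(seq: str) -> tuple[float, float]:
    tms = [thermo.melting_temperature(e) for e in iupac.expand(seq)]
    return min(tms), max(tms)


def _gc_range(seq: str) -> tuple[float, float]:
    gcs = [thermo.gc_content(e) for e in iupac.expand(seq)]
    return min(gcs), max(gcs)


def _ungapped_span_bp(panel: HaplotypePanel, start: int, end: int) -> int:
    """Product size implied by alignment columns [start, end): ungapped length
    of the first target haplotype over the span."""
    return len(panel.target_haplotypes.records[0].seq[start:end].replace("-", ""))


def _specificity(sub: str, panel: HaplotypePanel) -> int:
    if not panel.nontarget_seqs:
        return 0
    return min(
        iupac.min_mismatches_any_placement(sub, rec.ungapped)
        for rec in panel.nontarget_seqs
    )


def enumerate_pairs(
    windows: Sequence[DiagnosticWindow],
    panel: HaplotypePanel,
    constraints: DesignConstraints = DesignConstraints(),
    name_prefix: str = "assay",
) -> tuple[list[RankedAssay], dict[str, int]]:
    """Enumerate, filter and rank primer pairs from diagnostic windows.

    Returns ``(ranked_assays, attrition)`` where attrition counts, per filter,
    the candidates removed by that (first-failing) filter; the counts sum to
    candidates minus survivors. An empty window list yields an empty result
    with an all-zero report.
    """
    attrition = {k: 0 for k in FILTERS}
    candidates: list[tuple] = []
    subs: list[tuple[int, int, str]] = []
    seen = set()
    for w in windows:
        for sp in _sub_primers(w, constraints.primer_len, max_deg=10 ** 9):
            if sp not in seen:  # overlapping windows yield duplicate sub-primers
                seen.add(sp)
                subs.append(sp)
    lo_bp, hi_bp = constraints.amplicon_bp
    for a_start, a_end, a_sub in subs:
        for b_start, b_end, b_sub in subs:
            if b_start < a_end:
                continue
            product = _ungapped_span_bp(panel, a_start, b_end)
            if not (lo_bp <= product <= hi_bp):
                continue
            candidates.append((a_start, a_end, a_sub, b_start, b_end, b_sub, product))

    # per-oligo caches: the same sub-primer appears in many pairs
    tm_cache: dict[str, tuple[float, float]] = {}
    gc_cache: dict[str, tuple[float, float]] = {}
    hp_cache: dict[str, bool] = {}
    sd_cache: dict[str, bool] = {}
    spec_cache: dict[str, int] = {}

    survivors: list[RankedAssay] = []
    for a_start, a_end, a_sub, b_start, b_end, b_sub, product in candidates:
        fwd = a_sub
        rev = iupac.reverse_complement(b_sub)
        if iupac.degeneracy(fwd) > constraints.max_degeneracy or \
           iupac.degeneracy(rev) > constraints.max_degeneracy:
            attrition["degeneracy"] += 1
            continue
        ok = True
        for oligo in (fwd, rev):
            if oligo not in gc_cache:
                gc_cache[oligo] = _gc_range(oligo)
            g_lo, g_hi = gc_cache[oligo]
            if g_lo < constraints.gc[0] or g_hi > constraints.gc[1]:
                ok = False
                break
        if not ok:
            attrition["gc"] += 1
            continue
        for oligo in (fwd, rev):
            if oligo not in tm_cache:
                tm_cache[oligo] = _tm_range(oligo)
        (f_lo, f_hi), (r_lo, r_hi) = tm_cache[fwd], tm_cache[rev]
        tm_diff = max(abs(f_hi - r_lo), abs(r_hi - f_lo))
        if tm_diff > constraints.max_tm_diff_C:
            attrition["tm_diff"] += 1
            continue
        if constraints.forbid_hairpin:
            for oligo in (fwd, rev):
                if oligo not in hp_cache:
                    hp_cache[oligo] = thermo.hairpin_screen(oligo)[0]
            if hp_cache[fwd] or hp_cache[rev]:
                attrition["hairpin"] += 1
                continue
        if constraints.forbid_dimer:
            for oligo in (fwd, rev):
                if oligo not in sd_cache:
                    sd_cache[oligo] = thermo.dimer_screen(oligo)[0]
            if sd_cache[fwd] or sd_cache[rev]:
                attrition["self_dimer"] += 1
                continue
            if thermo.dimer_screen(fwd, rev)[0]:
                attrition["cross_dimer"] += 1
                continue
        for sub in (a_sub, b_sub):
            if sub not in spec_cache:
                spec_cache[sub] = _specificity(sub, panel)
        margin = spec_cache[a_sub] + spec_cache[b_sub]
        assay = AssayDefinition(
            name="",  # named after ranking
            target_taxon=panel.target_taxon,
            forward=fwd,
            reverse=rev,
            expected_amplicon_bp=product,
        )
        survivors.append(
            RankedAssay(assay, margin, round(tm_diff, 4), (a_start, a_end), (b_start, b_end))
        )

    survivors.sort(
        key=lambda s: (
            -s.specificity_margin,
            s.tm_diff_C,
            s.assay.expected_amplicon_bp,
            s.fwd_interval,
            s.rev_interval,
        )
    )
    ranked = []
    for i, s in enumerate(survivors, start=1):
        named = AssayDefinition(**{**asdict(s.assay), "name": f"{name_prefix}-{i:03d}"})
        ranked.append(
            RankedAssay(named, s.specificity_margin, s.tm_diff_C, s.fwd_interval, s.rev_interval)
        )
    return ranked, attrition


def attrition_report(attrition: dict[str, int]) -> str:
    """Human-readable per-filter attrition summary."""
    lines = [f"{k}\t{attrition.get(k, 0)}" for k in FILTERS]
    return "filter\tremoved\n" + "\n".join(lines) + "\n"


# --- assay table I/O -------------------------------------------------------

_TSV_COLUMNS = (
    "name", "target_taxon", "locus", "primer_label", "sequence_5to3",
    "annealing_C", "mg_mM", "amplicon_bp", "detection_limit_ng_ml",
)


def write_assay_tsv(assays: Iterable[AssayDefinition], path: str | Path) -> None:
    """Two rows per assay (forward then reverse), mirroring a published primer table."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(_TSV_COLUMNS)
        for a in assays:
            common = [a.annealing_C, a.mg_mM, a.expected_amplicon_bp, a.detection_limit_ng_ml]
            w.writerow([a.name, a.target_taxon, a.locus,
                        a.forward_name or f"{a.name}-F", a.forward, *common])
            w.writerow([a.name, a.target_taxon, a.locus,
                        a.reverse_name or f"{a.name}-R", a.reverse, *common])


def read_assay_tsv(path: str | Path) -> list[AssayDefinition]:
    """Read an assay table written by :func:`write_assay_tsv`."""
    rows: dict[str, dict] = {}
    order: list[str] = []
    with open(path, newline="") as fh:
        for rec in csv.DictReader(fh, delimiter="\t"):
            name = rec["name"]
            if name not in rows:
                rows[name] = {"labels": [], "seqs": [], "rec": rec}
                order.append(name)
            rows[name]["labels"].append(rec["primer_label"])
            rows[name]["seqs"].append(rec["sequence_5to3"])
    out = []
    for name in order:
        info = rows[name]
        if len(info["seqs"]) != 2:
            raise ValueError(f"assay {name!r}: expected 2 primer rows, got {len(info['seqs'])}")
        rec = info["rec"]

        def _num(key):
            v = rec.get(key, "")
            return float(v) if v not in ("", None, "None") else None

        amp = _num("amplicon_bp")
        out.append(
            AssayDefinition(
                name=name,
                target_taxon=rec["target_taxon"],
                locus=rec.get("locus", "other") or "other",
                forward=info["seqs"][0],
                reverse=info["seqs"][1],
                forward_name=info["labels"][0],
                reverse_name=info["labels"][1],
                annealing_C=_num("annealing_C"),
                mg_mM=_num("mg_mM"),
                expected_amplicon_bp=int(amp) if amp is not None else None,
                detection_limit_ng_ml=_num("detection_limit_ng_ml"),
            )
        )
    return out


def write_assay_json(assays: Iterable[AssayDefinition], path: str | Path) -> None:
    Path(path).write_text(json.dumps([asdict(a) for a in assays], indent=2) + "\n")
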