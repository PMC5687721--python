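"""Oligo property filters: degenerate expansion, GC, melting temperature,
hairpin and primer-dimer screening.

Melting temperatures use the unified nearest-neighbor duplex parameters
(Allawi & SantaLucia 1997) as implemented in Biopython, with the Owczarzy
(2004/2008) monovalent/divalent salt correction, so every reported value is
reproducible from a published model. Degenerate oligos are screened per
concrete expansion and pass/fail on the worst case.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

from Bio.SeqUtils import MeltingTemp as _mt

from . import iupac
from .iupac import expand as expand_degenerate  # re-export; cap default 64

#: identifier recorded in every oligo report
NN_PARAMETER_SET = "unified-NN-AllawiSantaLucia1997/Owczarzy-salt"

# screening defaults: hairpin stem >= 4 with loop >= 3; dimer run >= 8
# anywhere or >= 5 including a 3' terminus
HAIRPIN_STEM = 4
HAIRPIN_MIN_LOOP = 3
DIMER_RUN = 8
DIMER_3PRIME_RUN = 5


class DegenerateInputError(ValueError):
    """A concrete-only operation received a degenerate sequence."""


def _require_concrete(seq: str, op: str) -> str:
    seq = iupac.validate(seq)
    if any(c not in iupac.CONCRETE for c in seq):
        raise DegenerateInputError(
            f"{op} requires a concrete ACGT sequence; expand the degenerate "
            f"oligo first (got {seq!r})"
        )
    return seq


def gc_content(seq: str) -> float:
    """GC fraction of a concrete sequence."""
    seq = _require_concrete(seq, "gc_content")
    return (seq.count("G") + seq.count("C")) / len(seq)


def melting_temperature(
    seq: str,
    oligo_conc: float = 1e-6,
    monovalent: float = 0.05,
    divalent: float = 0.0,
) -> float:
    """Two-state nearest-neighbor melting temperature in °C.

    Parameters
    ----------
    seq
        Concrete ACGT sequence, length >= 8.
    oligo_conc
        Total oligo concentration in mol/L (default 1 µM, the standard PCR
        primer concentration).
    monovalent
        Monovalent cation concentration in mol/L (default 50 mM).
    divalent
        Mg²⁺ concentration in mol/L; corrected with the Owczarzy divalent
        model.
    """
    seq = _require_concrete(seq, "melting_temperature")
    if len(seq) < 8:
        raise ValueError("melting_temperature requires length >= 8")
    if oligo_conc <= 0 or monovalent <= 0 or divalent < 0:
        raise ValueError("concentrations must be positive (divalent may be 0)")
    return float(
        _mt.Tm_NN(
            seq,
            nn_table=_mt.DNA_NN3,
            dnac1=oligo_conc * 1e9,  # nM
            dnac2=0,
            Na=monovalent * 1e3,  # mM
            Mg=divalent * 1e3,
            saltcorr=7,
        )
    )


def _complementary(a: str, b: str) -> bool:
    # Watson-Crick only, degenerate codes resolved pessimistically upstream
    return iupac.COMPLEMENT.get(a) == b


def hairpin_screen(
    seq: str,
    stem: int = HAIRPIN_STEM,
    min_loop: int = HAIRPIN_MIN_LOOP,
) -> tuple[bool, tuple[int, int, int] | None]:
    """Flag self-complementary inverted repeats that can fold into a hairpin.

    Returns ``(flag, span)`` where span is ``(stem5_start, stem3_start, stem_len)``
    for the longest stem found (0-based), or ``None``. A hairpin needs a stem of
    at least ``stem`` perfectly complementary bases separated by a loop of at
    least ``min_loop`` bases. Degenerate oligos are screened per expansion and
    the worst case (any expansion folding) is reported.
    """
    if any(c not in iupac.CONCRETE for c in seq.upper()):
        worst: tuple[bool, tuple[int, int, int] | None] = (False, None)
        for ex in iupac.expand(seq):
            flag, span = hairpin_screen(ex, stem, min_loop)
            if flag:
                return flag, span
        return worst
    s = iupac.validate(seq)
    n = len(s)
    best: tuple[int, int, int] | None = None
    for i in range(n):
        for j in range(i + stem + min_loop, n):
            # extend a stem pairing s[i..] with s[j..] downward (j runs 3'->5')
            L = 0
            while (
                i + L < n
                and j - L > i + L
                and _complementary(s[i + L], s[j - L])
            ):
                L += 1
            # a shorter prefix of a maximal stem may leave a legal loop where
            # the full extension does not; the loop shrinks by 2 per base
            L = min(L, (j - i + 1 - min_loop) // 2)
            if L >= stem:
                if best is None or L > best[2]:
                    best = (i, j - L + 1, L)
    return (best is not None), best


def _best_duplex_run(a: str, b: str) -> tuple[int, int, bool]:
    """Longest ungapped complementary run between *a* and *b* in antiparallel
    orientation, over all offsets.

    Returns ``(run_len, best_3prime_run, any)`` where ``best_3prime_run`` is the
    longest run that includes the 3'-terminal base of either oligo.
    """
    br = b[::-1]  # antiparallel: align a 5'->3' against b 3'->5'
    na, nb = len(a), len(br)
    best = 0
    best3 = 0
    for off in range(-(nb - 1), na):
        match = [
            0 <= off + k < na and _complementary(a[off + k], br[k])
            for k in range(nb)
        ]
        k = 0
        while k < nb:
            if not match[k]:
                k += 1
                continue
            start = k
            while k < nb and match[k]:
                k += 1
            run = k - start  # maximal run over br indices [start, k)
            best = max(best, run)
            # b's 3'-terminal base sits at br index 0; a's at array index na-1
            includes_b3 = start == 0
            includes_a3 = start <= na - 1 - off < k
            if includes_a3 or includes_b3:
                best3 = max(best3, run)
    return best, best3, best > 0


def dimer_screen(
    a: str,
    b: str | None = None,
    run: int = DIMER_RUN,
    run3: int = DIMER_3PRIME_RUN,
) -> tuple[bool, dict]:
    """Flag primer-dimer risk between *a* and *b* (self-dimer when *b* omitted).

    Flagged when the best ungapped complementary run is at least ``run`` bases
    anywhere, or at least ``run3`` bases including either 3' terminus (3'-anchored
    duplexes prime extension). Degenerate oligos are screened per expansion;
    the worst case over expansion pairs is reported. Symmetric in a and b.
    """
    if b is None:
        b = a
    ea = iupac.expand(a)
    eb = iupac.expand(b)
    worst = {"run": 0, "run3": 0}
    for xa in ea:
        for xb in eb:
            r, r3, _ = _best_duplex_run(xa, xb)
            worst["run"] = max(worst["run"], r)
            worst["run3"] = max(worst["run3"], r3)
    flag = worst["run"] >= run or worst["run3"] >= run3
    return flag, worst


@dataclass(frozen=True)
class OligoReport:
    """Worst-case property summary of a (possibly degenerate) oligo."""

    seq: str
    length: int
    degeneracy: int
    gc_range: tuple[float, float]
    tm_range_C: tuple[float, float]
    hairpin_flag: bool
    selfdimer_flag: bool
    parameter_set: str = NN_PARAMETER_SET

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(asdict(self), indent=2)
        if path is not None:
            Path(path).write_text(text + "\n")
        return text


def oligo_report(
    seq: str,
    oligo_conc: float = 1e-6,
    monovalent: float = 0.05,
    divalent: float = 0.0,
    cap: int = 64,
) -> OligoReport:
    """Property report over all expansions of a degenerate oligo."""
    seq = iupac.validate(seq)
    exps = iupac.expand(seq, cap=cap)
    gcs = [gc_content(e) for e in exps]
    tms = [melting_temperature(e, oligo_conc, monovalent, divalent) for e in exps]
    hp, _ = hairpin_screen(seq)
    sd, _ = dimer_screen(seq)
    return OligoReport(
        seq=seq,
        length=len(seq),
        degeneracy=iupac.degeneracy(seq),
        gc_range=(min(gcs), max(gcs)),
        tm_range_C=(round(min(tms), 2), round(max(tms), 2)),
        hairpin_flag=hp,
        selfdimer_flag=sd,
    )
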