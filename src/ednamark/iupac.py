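"""IUPAC degenerate-nucleotide alphabet and the matching kernels built on it.

Every sequence in this package is a string over the 15 IUPAC nucleotide codes
plus the alignment gap ``'-'``. Internally each code is a 4-bit mask over
{A, C, G, T}, which makes set operations (union for consensus, subset tests
for primer/template matching) single integer ops and lets the binding-site
scanner vectorise over a whole template with numpy.

Matching convention used throughout: a *primer* (possibly degenerate) position
matches a *template* position iff the template's base set is contained in the
primer's base set, with the single exception that a template ``N`` matches any
primer base (low-quality template positions are given the benefit of the
doubt; callers may count them separately).
"""

from __future__ import annotations

import itertools

import numpy as np

# Bit per canonical base.
_A, _C, _G, _T = 1, 2, 4, 8

#: code -> 4-bit mask over {A, C, G, T}; '-' is the empty set.
CODE_TO_MASK: dict[str, int] = {
    "A": _A, "C": _C, "G": _G, "T": _T,
    "R": _A | _G, "Y": _C | _T, "S": _C | _G, "W": _A | _T,
    "K": _G | _T, "M": _A | _C,
    "B": _C | _G | _T, "D": _A | _G | _T, "H": _A | _C | _T, "V": _A | _C | _G,
    "N": _A | _C | _G | _T,
    "-": 0,
}

MASK_TO_CODE: dict[int, str] = {m: c for c, m in CODE_TO_MASK.items()}

ALPHABET = frozenset(CODE_TO_MASK)
CONCRETE = "ACGT"

# complement flips the A<->T and C<->G bits of a mask
_COMPLEMENT_MASK = {
    m: (( _T if m & _A else 0) | (_G if m & _C else 0) | (_C if m & _G else 0) | (_A if m & _T else 0))
    for m in range(16)
}
COMPLEMENT: dict[str, str] = {c: MASK_TO_CODE[_COMPLEMENT_MASK[m]] for c, m in CODE_TO_MASK.items()}

_MASK_LUT = np.zeros(128, dtype=np.uint8)
for _c, _m in CODE_TO_MASK.items():
    _MASK_LUT[ord(_c)] = _m
_VALID = np.zeros(128, dtype=bool)
for _c in CODE_TO_MASK:
    _VALID[ord(_c)] = True


class AlphabetError(ValueError):
    """A sequence contains a character outside the IUPAC-plus-gap alphabet."""


def validate(seq: str, label: str = "sequence") -> str:
    """Return *seq* uppercased, raising :class:`AlphabetError` at the first bad char.

    ``U`` is transliterated to ``T`` (RNA-gene records in public databases use
    either letter for the same locus).
    """
    up = seq.upper().replace("U", "T")
    for i, ch in enumerate(up):
        if ch not in ALPHABET:
            raise AlphabetError(f"{label}: invalid character {ch!r} at position {i + 1}")
    return up


def to_masks(seq: str) -> np.ndarray:
    """Encode a validated sequence as a uint8 mask array."""
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    return _MASK_LUT[arr]


def base_set(code: str) -> frozenset[str]:
    m = CODE_TO_MASK[code]
    return frozenset(b for b in CONCRETE if CODE_TO_MASK[b] & m)


def union_code(codes) -> str:
    """IUPAC code whose base set is the union of the given codes ('-' if any gap)."""
    mask = 0
    for c in codes:
        cm = CODE_TO_MASK[c]
        if cm == 0:
            return "-"
        mask |= cm
    return MASK_TO_CODE[mask]


def degeneracy(seq: str) -> int:
    """Product over positions of the IUPAC set size (gap counts as 1)."""
    d = 1
    for c in seq:
        d *= max(1, bin(CODE_TO_MASK[c]).count("1"))
    return d


def expand(seq: str, cap: int = 64) -> list[str]:
    """All concrete expansions of a degenerate sequence, lexicographically sorted.

    Raises ``ValueError`` when the degeneracy exceeds *cap* (oligo synthesis and
    downstream screens are exponential in the expansion count).
    """
    d = degeneracy(seq)
    if d > cap:
        raise ValueError(f"degeneracy {d} exceeds cap {cap}; refusing to expand")
    choices = [sorted(base_set(c)) if c != "-" else ["-"] for c in seq]
    return ["".join(p) for p in itertools.product(*choices)]


def reverse_complement(seq: str) -> str:
    return "".join(COMPLEMENT[c] for c in reversed(seq))


def matches(primer_code: str, template_code: str) -> bool:
    """Primer/template single-position match under the package convention."""
    t = CODE_TO_MASK[template_code]
    p = CODE_TO_MASK[primer_code]
    if t == 15:  # template N
        return True
    if t == 0:  # template gap
        return p == 0
    return (t & ~p) == 0


def mismatches(degenerate_a: str, plain_b: str) -> int:
    """Count positions of *plain_b* whose base is not within *degenerate_a*'s set.

    Template ``N`` counts as a match (conservative when screening specificity).
    Raises ``ValueError`` on length mismatch.
    """
    if len(degenerate_a) != len(plain_b):
        raise ValueError(
            f"length mismatch: {len(degenerate_a)} vs {len(plain_b)}"
        )
    return sum(0 if matches(a, b) else 1 for a, b in zip(degenerate_a, plain_b))


def mismatch_profile(primer: str, template: str) -> np.ndarray:
    """Mismatch count of *primer* at every ungapped offset of *template* (+ strand).

    Vectorised over offsets; returns an int array of length
    ``len(template) - len(primer) + 1`` (empty when the primer is longer).
    """
    p = to_masks(primer)
    t = to_masks(template)
    n, k = len(t), len(p)
    if n < k:
        return np.zeros(0, dtype=np.intp)
    win = np.lib.stride_tricks.sliding_window_view(t, k)
    is_n = win == 15
    mism = ((win & ~p) != 0) & ~is_n
    return mism.sum(axis=1)


def min_mismatches_any_placement(primer: str, template: str, both_strands: bool = True) -> int:
    """Best (minimum) mismatch count of *primer* over all ungapped placements.

    Scans the forward strand and, by default, the reverse complement. When the
    template is shorter than the primer there is no placement and the primer is
    treated as maximally divergent (``len(primer)``).
    """
    best = len(primer)
    prof = mismatch_profile(primer, template)
    if prof.size:
        best = min(best, int(prof.min()))
    if both_strands:
        prof = mismatch_profile(primer, reverse_complement(template))
        if prof.size:
            best = min(best, int(prof.min()))
    return best
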