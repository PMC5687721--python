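"""Independent brute-force oracles used by the test suite.

Everything here is written from first principles — plain dict/loop Python with
its own literal IUPAC tables — and deliberately shares no code with the
package paths it checks.
"""

IUPAC_SETS = {
    "A": {"A"}, "C": {"C"}, "G": {"G"}, "T": {"T"},
    "R": {"A", "G"}, "Y": {"C", "T"}, "S": {"C", "G"}, "W": {"A", "T"},
    "K": {"G", "T"}, "M": {"A", "C"},
    "B": {"C", "G", "T"}, "D": {"A", "G", "T"}, "H": {"A", "C", "T"},
    "V": {"A", "C", "G"}, "N": {"A", "C", "G", "T"},
}
COMP = {"A": "T", "T": "A", "C": "G", "G": "C", "N": "N",
        "R": "Y", "Y": "R", "S": "S", "W": "W", "K": "M", "M": "K",
        "B": "V", "V": "B", "D": "H", "H": "D", "-": "-"}


def revcomp(s):
    return "".join(COMP[c] for c in reversed(s))


def position_matches(primer_code, template_code):
    if template_code == "N":
        return True
    return IUPAC_SETS[template_code] <= IUPAC_SETS[primer_code]


def count_mm(primer, segment):
    return sum(0 if position_matches(p, t) else 1 for p, t in zip(primer, segment))


def brute_sites(primer, template, max_mm, clamp3):
    """All accepted binding sites as (strand, start, end, mismatches)."""
    k = len(primer)
    out = []
    for strand in "+-":
        probe = primer if strand == "+" else revcomp(primer)
        for i in range(len(template) - k + 1):
            seg = template[i:i + k]
            mm = count_mm(probe, seg)
            if mm > max_mm:
                continue
            # primer 3' end sits at the right end on '+', at the left on '-'
            clamp_seg = (
                list(zip(probe, seg))[-clamp3:] if strand == "+"
                else list(zip(probe, seg))[:clamp3]
            )
            if clamp3 and any(not position_matches(p, t) for p, t in clamp_seg):
                continue
            out.append((strand, i, i + k, mm))
    out.sort()
    return out


def brute_min_placement_mm(query, template):
    """Minimum mismatches of query over all ungapped placements, both strands."""
    k = len(query)
    best = k
    for tpl in (template, revcomp(template)):
        for i in range(len(tpl) - k + 1):
            best = min(best, count_mm(query, tpl[i:i + k]))
    return best


def brute_consensus(rows, start, end):
    out = []
    for i in range(start, end):
        col = {r[i] for r in rows}
        if "-" in col:
            out.append("-")
            continue
        union = set()
        for c in col:
            union |= IUPAC_SETS[c]
        code = next(k for k, v in IUPAC_SETS.items() if v == union)
        out.append(code)
    return "".join(out)


def brute_windows(target_rows, nontargets, window_len, max_degeneracy, min_mm):
    """All diagnostic windows as (start, end, consensus, overall_min_mm)."""
    n = len(target_rows[0])
    out = []
    for start in range(n - window_len + 1):
        cons = brute_consensus(target_rows, start, start + window_len)
        if "-" in cons:
            continue
        deg = 1
        for c in cons:
            deg *= len(IUPAC_SETS[c])
        if deg > max_degeneracy:
            continue
        mins = [brute_min_placement_mm(cons, nt) for nt in nontargets]
        if any(m < min_mm for m in mins):
            continue
        out.append((start, start + window_len, cons, min(mins) if mins else min_mm))
    return out


def brute_hairpin(seq, stem, min_loop):
    """Exhaustive inverted-repeat search: any two disjoint arms of length >= stem,
    separated by >= min_loop, complementary in antiparallel orientation."""
    n = len(seq)
    for L in range(stem, n // 2 + 1):
        for i in range(n - L + 1):
            for j in range(i + L + min_loop, n - L + 1):
                if all(COMP[seq[i + k]] == seq[j + L - 1 - k] for k in range(L)):
                    return True
    return False
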