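# Methods

This note documents the models, rules and numerical choices behind
`ednamark`, in the order data flows through the toolkit.

## Sequence model and matching kernel

Sequences are strings over the 15 IUPAC nucleotide codes plus the alignment
gap `-`. Each code is held internally as a 4-bit mask over {A, C, G, T};
consensus building is per-column mask union, degeneracy is the product of
per-position set sizes, and matching is a subset test. One asymmetric
convention is used everywhere: a *primer* position matches a *template*
position iff the template's base set is contained in the primer's, except
that a template `N` matches any primer base. The rationale: a degenerate
primer is a synthesised mixture, so its set enumerates oligos actually in the
tube, whereas template ambiguity is usually a sequencing-quality artefact —
treating `N` as a match is conservative for specificity screening (an `N`
never rescues a claimed mismatch). Binding-site scans report the number of
`N` positions under a footprint so callers can down-weight low-quality hits.

On ingestion sequences are uppercased and `U` is transliterated to `T`
(public rRNA-gene records use both letters); any other character outside the
alphabet is an error naming the record and 1-based position. Coordinates are
0-based half-open internally; TSV reports convert to 1-based inclusive and
say so in their headers.

Alignment is consumed, not computed: target haplotypes arrive pre-aligned
(any standard aligner), because multiple sequence alignment is not this
package's contribution and the loci involved are short and easy to align.

## Diagnostic-window scan

A window of the target alignment is diagnostic when (a) no haplotype has a
gap in it — indels break primer annealing geometry; (b) its consensus
degeneracy is within the synthesis budget (default 8, the highest degeneracy
among the bundled published primers); and (c) every non-target sequence
carries at least `min_mm` mismatches at its *best* ungapped placement of the
consensus, scanning both strands (primers bind either strand, and database
records are deposited in arbitrary orientation). Placement is ungapped by
design: gapped similarity would model recombination of the binding site, not
annealing. Window lengths 18–25 are scanned jointly by default (the range of
credible primer lengths; a hard floor of 15 guards against degenerate use).
`min_mm` defaults to 2 and is surfaced as a flag — published marker-design
practice picks divergent regions by eye, so the threshold is genuinely a
user choice. Windows are sorted by descending worst-case non-target
divergence, ties by position, giving a deterministic order.

The scanner is vectorised (numpy sliding windows over bitmasks); the test
suite holds it equal to a character-by-character brute-force oracle on
randomized panels.

## Oligo thermodynamics and structure screens

Melting temperatures use the unified nearest-neighbor duplex parameters
(Allawi & SantaLucia 1997) with the two-state formula
`Tm = 1000·ΔH / (ΔS + R·ln C) − 273.15` and the Owczarzy monovalent/Mg²⁺
correction, via Biopython's `Tm_NN` (table `DNA_NN3`, `saltcorr=7`). The
published web calculator used in marker-design papers is proprietary; fixing
a published parameter set makes every number reproducible, and the parameter
set identifier is recorded in each oligo report. Defaults: oligo 1 µM (the
standard PCR primer concentration), monovalent 50 mM, Mg²⁺ from the assay
definition. Values are deterministic; the suite pins them against an
independently hand-summed ΔH/ΔS oracle to 0.1 °C.

Degenerate oligos are screened per concrete expansion (capped at degeneracy
64) and pass/fail on the worst case; reports carry min/max ranges for GC and
Tm. Structure screens are exhaustive string searches, not partition
functions: a hairpin flag needs a perfectly complementary inverted repeat
with stem ≥ 4 and loop ≥ 3; a dimer flag needs an ungapped antiparallel
complementary run ≥ 8 anywhere or ≥ 5 touching either 3′ terminus
(3′-anchored duplexes prime extension). These mirror common oligo-screening
defaults and are configurable. Empirical annealing temperatures in assay
definitions are free user-set fields: they come from PCR optimisation, not
from the Tm model, and the two are deliberately not conflated.

## Pair enumeration and ranking

Candidate primers are all constraint-length sub-intervals of diagnostic
windows; candidate assays are ordered non-overlapping pairs whose implied
product (ungapped length of the first haplotype across the span, both
footprints included) lies in the amplicon range. The filter cascade runs
degeneracy → GC → Tm balance → hairpin → self-dimer → cross-dimer, each
candidate charged to its first failing filter, so the attrition report's
counts sum exactly to candidates minus survivors. Tm balance compares
worst-case expansion pairs (max |Tm_F − Tm_R| over the cross product) with a
5 °C default ceiling. Ranking is a total order: descending sum of the two
primers' minimum non-target mismatches, then ascending Tm difference, then
ascending product size, then coordinates — manual primer picking is replaced
by a fully specified tie-break so reruns are identical. The reverse primer is
stored 5′→3′ as synthesised (reverse complement of its sense-strand window),
the convention of published primer tables.

## In-silico PCR

Binding-site search is an exhaustive scan of both strands: a site is
accepted iff total mismatches ≤ `max_mm` (default 2) and the 3′-terminal
`clamp3` bases (default 2) match perfectly — polymerase extension tolerates
internal wobble far better than 3′ mismatches. Amplicons are convergent
forward/reverse sites on opposite strands, non-overlapping footprints, with
product size in a window defaulting to 50–1500 bp; both template
orientations are handled so records deposited on either strand predict the
same products. BLAST-style remote checks are replaced by this local search
against a user-supplied panel FASTA: it is exhaustive, reproducible and
needs no network. A cross-panel run marks an assay *specific* iff the only
amplified taxa match its target taxon exactly — a marker that also amplifies
congeners is reported non-specific (a genus-level marker, which may still be
useful and is left to the user to judge).

Internal consistency between design and validation requires the design-time
divergence floor to exceed the validation-time mismatch tolerance: with
`min_mm = 3` at design and `max_mm = 2` at validation, every emitted assay
is guaranteed specific on its own panel; the suite checks this end to end.

## Detection limits and presence calls

The detection limit of a dilution series is the concentration of the last
positive step before the first negative (`stock / dilutions[k−1]` where `k`
is the first negative index). An all-positive ladder yields a censored
result (`≤ stock/last_factor`), propagated as a flag rather than silently
rounded; a first-step negative is "undetected at stock"; a positive after
the first negative triggers a warning but the first-negative rule still
applies, as the rule is stated operationally. The rule is scale-equivariant
in the stock, which the suite checks as a property. The bundled ladders use
the standard 11 steps (1:5 … 1:100000); their stock values (3.75, 3, 3.8 and
2.02 µg/ml) are this package's reconstruction — each is the unique value in
the reported 1–5 µg/ml working range consistent with its marker's published
limit under the first-negative rule.

Presence calling gates first: any positive extraction- or PCR-negative
control invalidates the whole batch for that assay; a negative
universal-primer control invalidates the sample (its DNA cannot support PCR,
so a negative with the specific marker means nothing). After gating, a
species is present iff some extraction yields ≥ 2 positive PCRs or ≥ 2
distinct extractions each yield ≥ 1 positive. The second clause is read as
replication *across* extractions; the looser reading (any single positive
when two extractions were run) would make the first clause redundant, but is
available behind `require_two_extractions=False`. Calls are monotone in the
outcome pattern (upgrading a negative PCR never turns present into absent),
verified as a property test. Survey matrices print `X`/`-`/`!`; the `!`
(invalid) code is this package's extension for gated cells, and invalid
sites are excluded from positive-site counts rather than counted absent.

## Synthetic data

`synth.generate_panel` emulates the raw material of marker design: a random
reference locus (default 400 nt, uniform base composition), target
haplotypes differing by a few substitutions (default 5 haplotypes × 2
substitutions — haplotype counts per species are rarely reported, so this is
a deliberate, modest default), and non-target relatives that are
near-identical except at *planted* regions where each carries `min_mm + 1`
substitutions. The planted guarantee (every non-target at least `min_mm`
mismatches from each planted region at its best placement, both strands) is
verified post hoc and the panel redrawn on failure, so the truth record is
exact, not probabilistic. Substitutions are uniform outside planted regions;
transition/transversion bias is not modelled because no tested logic depends
on it. `generate_survey` draws per-PCR Bernoulli outcomes: detection
probability `p` at occupied sites, contamination probability (default 0)
elsewhere and for batch controls, over a default 2 extraction × 2 PCR
design. All generators are pure functions of their spec (PCG64 via
`numpy.random.default_rng`, no global state), hence byte-identical across
runs and platforms.

What the generators do *not* emulate — and hence what passing tests do not
show about field data: no indels or alignment error, no phylogenetic
structure among non-targets (real congeners are correlated, not
independently mutated), no PCR inhibition, no sequence-dependent
amplification efficiency, no spatial or temporal autocorrelation of eDNA,
and no cross-contamination structure beyond a single probability. Synthetic
amplification templates (`datasets.synthetic_template`) embed an assay's
primer sites at the expected spacing in random sequence; they validate
amplicon-size arithmetic and degenerate matching, not marker performance on
real mitochondrial records, and are labelled synthetic wherever they appear.

## Problem sizes in the validation suite

The test suite exercises the scanners against brute-force oracles at sizes
chosen to keep a full run around a quarter of a minute: 10⁴ randomized
binding-site cases (templates 30–120 nt with a 2 % admixture of 400–500 nt,
primers 15–24 nt), 30 randomized diagnostic-scan panels up to 300 nt × 6
sequences, and end-to-end design on 320 nt panels with two planted 22 nt
regions. The acceptance script re-runs scaled versions of the same checks
(1000 binding-site cases, 3 design panels) plus every bundled-data
computation.

## Known limitations

* No thermodynamic extension-efficiency model: a binding site within the
  mismatch policy is treated as amplifying, so faint off-target products
  from heavily mismatched annealing are invisible to the cross-panel.
* Ungapped placement means a non-target that differs from a window only by
  an indel scores as highly divergent even though a real duplex might
  bulge-loop around it.
* The Tm model targets standard PCR buffer; exotic additives (BSA, betaine)
  are outside the salt correction.
* Presence calling is deterministic gating, not occupancy modelling: it
  reports what the replicate rule says, with no detection-probability
  estimate attached.
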