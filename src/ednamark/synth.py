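"""Seeded generators for synthetic test panels and surveys.

These emulate the two kinds of input the toolkit consumes:

* **Haplotype panels**: a target species with a handful of closely related
  haplotypes, against non-target relatives that are near-identical except at
  *planted* diagnostic regions where they carry a guaranteed minimum number of
  mismatches. This mimics the situation where a barcoding locus is broadly
  conserved but carries short species-diagnostic stretches.
* **Surveys**: replicated per-site PCR outcomes (extractions × PCRs) where
  occupied sites amplify with a per-PCR detection probability and unoccupied
  sites amplify only through a (normally zero) contamination probability.

All generators are pure functions of their spec, seed included; no global
random state is touched.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np

from . import iupac
from .assaycall import SurveyObservation
from .seqio import HaplotypePanel, MultipleAlignment, SequenceRecord

_BASES = np.array(list("ACGT"))


class GenerationError(RuntimeError):
    """The spec could not be satisfied (e.g. region too short for its min_mm)."""


@dataclass(frozen=True)
class PlantedRegion:
    """A diagnostic region to plant: conserved in targets, divergent in non-targets."""

    position: int
    length: int
    min_mm: int = 2

    def __post_init__(self) -> None:
        if self.min_mm < 1:
            raise ValueError("planted regions need min_mm >= 1")
        if self.min_mm + 1 > self.length:
            raise GenerationError(
                f"region of length {self.length} cannot host min_mm={self.min_mm}"
            )


@dataclass(frozen=True)
class PanelSpec:
    """Recipe for a synthetic haplotype panel.

    Defaults give a small barcoding-locus panel: 5 target haplotypes differing
    by 2 substitutions each, 3 close non-target relatives, and two planted
    20 nt diagnostic regions far enough apart to host a realistic amplicon.
    """

    seed: int = 0
    locus_len: int = 400
    n_target_haps: int = 5
    intra_target_subs: int = 2
    n_nontargets: int = 3
    nontarget_subs: int = 6
    planted_regions: tuple[PlantedRegion, ...] = (
        PlantedRegion(60, 20, 3),
        PlantedRegion(260, 20, 3),
    )
    base_composition: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)
    target_taxon: str = "target_sp"

    def __post_init__(self) -> None:
        for r in self.planted_regions:
            if r.position + r.length > self.locus_len:
                raise ValueError("planted region extends past locus end")
        if abs(sum(self.base_composition) - 1.0) > 1e-9:
            raise ValueError("base_composition must sum to 1")


@dataclass(frozen=True)
class PanelTruth:
    """Ground truth accompanying a generated panel."""

    planted: tuple[tuple[int, int], ...]  # (start, end) per region
    min_mm: tuple[int, ...]

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2) + "\n")


def _random_seq(rng: np.random.Generator, n: int, comp) -> np.ndarray:
    return rng.choice(4, size=n, p=list(comp))


def _mutate(rng: np.random.Generator, codes: np.ndarray, positions: np.ndarray) -> None:
    """In-place substitution at *positions* to a uniformly chosen different base."""
    for p in positions:
        codes[p] = (codes[p] + rng.integers(1, 4)) % 4


def generate_panel(spec: PanelSpec, max_attempts: int = 25) -> tuple[HaplotypePanel, PanelTruth]:
    """Generate a haplotype panel with planted diagnostic regions.

    Guarantees, verified post-hoc and re-drawn on failure:

    * target haplotypes are distinct and identical within planted regions;
    * every non-target differs from each planted region by at least its
      ``min_mm`` at the best ungapped placement on either strand.
    """
    rng = np.random.default_rng(spec.seed)
    planted_cols = np.zeros(spec.locus_len, dtype=bool)
    for r in spec.planted_regions:
        planted_cols[r.position:r.position + r.length] = True
    free_cols = np.nonzero(~planted_cols)[0]
    if spec.intra_target_subs > len(free_cols):
        raise GenerationError("not enough non-planted columns for intra-target variation")

    for _ in range(max_attempts):
        ref = _random_seq(rng, spec.locus_len, spec.base_composition)
        haps = [ref.copy()]
        for _h in range(spec.n_target_haps - 1):
            h = ref.copy()
            pos = rng.choice(free_cols, size=spec.intra_target_subs, replace=False)
            _mutate(rng, h, pos)
            haps.append(h)
        seqs = ["".join(_BASES[h]) for h in haps]
        if len(set(seqs)) != len(seqs):
            continue

        nontargets = []
        for j in range(spec.n_nontargets):
            nt = ref.copy()
            for r in spec.planted_regions:
                k = min(r.length, r.min_mm + 1)  # margin of one extra substitution
                pos = r.position + rng.choice(r.length, size=k, replace=False)
                _mutate(rng, nt, pos)
            if spec.nontarget_subs:
                pos = rng.choice(free_cols, size=min(spec.nontarget_subs, len(free_cols)),
                                 replace=False)
                _mutate(rng, nt, pos)
            nontargets.append(nt)

        # post-hoc guarantee: best placement of every planted consensus on every
        # non-target (either strand) carries at least min_mm mismatches
        ok = True
        for r in spec.planted_regions:
            cons = "".join(_BASES[ref[r.position:r.position + r.length]])
            for nt in nontargets:
                nt_seq = "".join(_BASES[nt])
                if iupac.min_mismatches_any_placement(cons, nt_seq) < r.min_mm:
                    ok = False
                    break
            if not ok:
                break
        if not ok:
            continue

        records = [
            SequenceRecord(id=f"{spec.target_taxon}_hap{i + 1}", seq=s,
                           taxon=spec.target_taxon)
            for i, s in enumerate(seqs)
        ]
        nt_records = [
            SequenceRecord(id=f"nontarget_{j + 1:02d}", seq="".join(_BASES[nt]),
                           taxon=f"nontarget_sp_{j + 1:02d}")
            for j, nt in enumerate(nontargets)
        ]
        panel = HaplotypePanel(
            target_haplotypes=MultipleAlignment(records=records),
            nontarget_seqs=nt_records,
            target_taxon=spec.target_taxon,
        )
        truth = PanelTruth(
            planted=tuple((r.position, r.position + r.length) for r in spec.planted_regions),
            min_mm=tuple(r.min_mm for r in spec.planted_regions),
        )
        return panel, truth
    raise GenerationError(f"could not satisfy spec after {max_attempts} attempts")


@dataclass(frozen=True)
class SurveySpec:
    """Recipe for a replicated synthetic survey.

    The default replicate structure is the standard field design: two
    independent extractions per site, two PCRs per extraction.
    """

    seed: int = 0
    sites: int = 10
    occupied_sites: tuple[int, ...] = (0, 1, 2)
    per_pcr_detection_prob: float = 0.8
    extractions_per_site: int = 2
    pcrs_per_extraction: int = 2
    control_contamination_prob: float = 0.0
    assay: str = "assay-001"

    def __post_init__(self) -> None:
        if not (0.0 <= self.per_pcr_detection_prob <= 1.0):
            raise ValueError("per_pcr_detection_prob must be in [0, 1]")
        if not (0.0 <= self.control_contamination_prob <= 1.0):
            raise ValueError("control_contamination_prob must be in [0, 1]")
        if any(i < 0 or i >= self.sites for i in self.occupied_sites):
            raise ValueError("occupied_sites indices out of range")


def generate_survey(
    spec: SurveySpec,
    truth_occupancy: dict[str, bool] | None = None,
) -> tuple[list[SurveyObservation], dict[str, bool]]:
    """Generate replicated survey outcomes and return them with the truth.

    Occupied sites yield per-PCR positives as independent Bernoulli draws with
    the detection probability; unoccupied sites can only turn positive through
    ``control_contamination_prob`` (normally zero). Batch negative controls are
    drawn once per survey with the same contamination probability.
    """
    rng = np.random.default_rng(spec.seed)
    site_ids = [f"site_{i + 1:02d}" for i in range(spec.sites)]
    if truth_occupancy is None:
        truth_occupancy = {
            s: (i in spec.occupied_sites) for i, s in enumerate(site_ids)
        }
    ext_neg = bool(rng.random() < spec.control_contamination_prob)
    pcr_neg = bool(rng.random() < spec.control_contamination_prob)
    obs = []
    for s in site_ids:
        p = spec.per_pcr_detection_prob if truth_occupancy[s] else spec.control_contamination_prob
        extractions = tuple(
            tuple(bool(rng.random() < p) for _ in range(spec.pcrs_per_extraction))
            for _ in range(spec.extractions_per_site)
        )
        obs.append(
            SurveyObservation(
                site_id=s,
                assay=spec.assay,
                extractions=extractions,
                universal_control=True,
                extraction_negative=ext_neg,
                pcr_negative=pcr_neg,
            )
        )
    return obs, truth_occupancy


def panel_spec_from_json(path: str | Path) -> PanelSpec:
    d = json.loads(Path(path).read_text())
    if "planted_regions" in d:
        d["planted_regions"] = tuple(PlantedRegion(**r) for r in d["planted_regions"])
    if "base_composition" in d:
        d["base_composition"] = tuple(d["base_composition"])
    return PanelSpec(**d)


def survey_spec_from_json(path: str | Path) -> SurveySpec:
    d = json.loads(Path(path).read_text())
    if "occupied_sites" in d:
        d["occupied_sites"] = tuple(d["occupied_sites"])
    return SurveySpec(**d)
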