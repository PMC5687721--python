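"""From lab outcome tables to assay metadata and survey results.

Three pieces of logic live here:

* **Detection limits** from serial dilution series, by the first-negative
  rule: the limit is the concentration of the last positive dilution before
  the first negative one.
* **Presence/absence calls** from replicated PCR outcomes, gated by
  contamination and sample-quality controls. A species is called present in a
  sample when at least two PCRs from one extraction are positive, or at least
  one PCR from each of two different extractions is positive — a single
  unreplicated positive is never enough.
* **Survey tables**: per-site × per-assay matrices with per-assay
  positive-site counts.
"""

from __future__ import annotations

import csv
import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable, Literal, Sequence

import pandas as pd

Outcome = bool  # True = positive amplification

#: the standard 11-step serial dilution ladder used for sensitivity assays
STANDARD_DILUTIONS = (5, 10, 25, 50, 100, 500, 1000, 5000, 10000, 50000, 100000)


class NonMonotoneDilutionWarning(UserWarning):
    """A positive outcome occurred after the first negative dilution."""


@dataclass(frozen=True)
class DilutionSeries:
    """A serial dilution of a quantified DNA stock with per-step PCR outcomes."""

    stock_ng_ml: float
    dilutions: tuple[int, ...] = STANDARD_DILUTIONS
    outcomes: tuple[bool, ...] = ()
    assay: str = ""

    def __post_init__(self) -> None:
        if not self.dilutions:
            raise ValueError("empty dilution series")
        if any(b <= a for a, b in zip(self.dilutions, self.dilutions[1:])):
            raise ValueError("dilution factors must be strictly increasing")
        if len(self.outcomes) != len(self.dilutions):
            raise ValueError("one outcome required per dilution step")
        if self.stock_ng_ml <= 0:
            raise ValueError("stock concentration must be positive")


@dataclass(frozen=True)
class DetectionLimit:
    """Result of the first-negative rule on a dilution series.

    ``censored`` marks an all-positive series (the true limit is at or below
    the reported value); ``undetected`` marks a series negative from the first
    dilution. ``non_monotone`` flags positives observed after the first
    negative (the rule still uses the first negative, but the series merits a
    second look).
    """

    limit_ng_ml: float | None
    censored: bool = False
    undetected: bool = False
    non_monotone: bool = False

    def __str__(self) -> str:
        if self.undetected:
            return "undetected at stock"
        prefix = "<=" if self.censored else ""
        return f"{prefix}{self.limit_ng_ml:g} ng/ml"


def detection_limit(series: DilutionSeries) -> DetectionLimit:
    """Detection limit by the first-negative rule.

    The limit is the concentration at the last positive dilution preceding the
    first negative: ``stock / dilutions[k-1]`` where ``k`` indexes the first
    negative outcome. An all-positive series is censored at the last dilution;
    a first-step negative is reported as undetected.
    """
    outcomes = series.outcomes
    first_neg = next((i for i, o in enumerate(outcomes) if not o), None)
    if first_neg == 0:
        return DetectionLimit(limit_ng_ml=None, undetected=True)
    if first_neg is None:
        return DetectionLimit(
            limit_ng_ml=series.stock_ng_ml / series.dilutions[-1], censored=True
        )
    non_monotone = any(outcomes[first_neg:])
    if non_monotone:
        warnings.warn(
            f"positive outcome after the first negative (assay {series.assay or '?'}); "
            "applying the first-negative rule regardless",
            NonMonotoneDilutionWarning,
            stacklevel=2,
        )
    return DetectionLimit(
        limit_ng_ml=series.stock_ng_ml / series.dilutions[first_neg - 1],
        non_monotone=non_monotone,
    )


Call = Literal["present", "absent", "invalid_sample", "invalid_batch"]


@dataclass(frozen=True)
class SurveyObservation:
    """Replicated PCR outcomes for one site × assay.

    ``extractions`` holds one list of PCR outcomes per independent extraction
    replicate (structures may be ragged). ``universal_control`` is the
    sample-quality PCR with universal primers (a negative means the sample
    cannot support PCR at all); ``controls`` are batch-level negative controls
    (a positive means contamination somewhere in the pipeline).
    """

    site_id: str
    assay: str
    extractions: tuple[tuple[bool, ...], ...]
    universal_control: bool = True
    extraction_negative: bool = False
    pcr_negative: bool = False

    def __post_init__(self) -> None:
        if not self.extractions or not any(len(e) for e in self.extractions):
            raise ValueError(f"{self.site_id}/{self.assay}: at least one PCR outcome required")


@dataclass(frozen=True)
class PresenceCall:
    site_id: str
    assay: str
    call: Call
    reason: str


def call_presence(
    obs: SurveyObservation,
    require_two_extractions: bool = True,
) -> PresenceCall:
    """Replicate-based presence/absence call with control gating.

    Gating precedes everything: a positive batch negative control invalidates
    the batch; a negative universal (sample-quality) control invalidates the
    sample. Then the species is *present* iff some extraction has >= 2
    positive PCRs, or >= 2 distinct extractions each have >= 1 positive PCR.

    ``require_two_extractions=False`` switches the second clause to the looser
    literal reading "one positive result from two different extractions" = a
    single positive anywhere when two extractions were run; the default
    reading requires replication across extractions (the loose reading would
    make the first clause redundant).
    """
    if obs.extraction_negative or obs.pcr_negative:
        which = "extraction" if obs.extraction_negative else "PCR"
        return PresenceCall(obs.site_id, obs.assay, "invalid_batch",
                            f"{which} negative control amplified (batch contamination)")
    if not obs.universal_control:
        return PresenceCall(obs.site_id, obs.assay, "invalid_sample",
                            "universal-primer control negative (sample unfit for PCR)")
    pos_per_ext = [sum(e) for e in obs.extractions]
    if any(p >= 2 for p in pos_per_ext):
        return PresenceCall(obs.site_id, obs.assay, "present",
                            ">=2 positive PCRs within one extraction")
    ext_with_pos = sum(1 for p in pos_per_ext if p >= 1)
    if require_two_extractions:
        if ext_with_pos >= 2:
            return PresenceCall(obs.site_id, obs.assay, "present",
                                ">=1 positive PCR in each of two extractions")
    else:
        if ext_with_pos >= 1 and len(obs.extractions) >= 2:
            return PresenceCall(obs.site_id, obs.assay, "present",
                                "positive PCR with two extractions run (loose reading)")
    return PresenceCall(obs.site_id, obs.assay, "absent",
                        "no replicated positive amplification")


_CELL = {"present": "X", "absent": "-", "invalid_sample": "!", "invalid_batch": "!"}


@dataclass
class SurveyTable:
    """Site × assay presence matrix plus per-assay positive-site counts."""

    matrix: pd.DataFrame  # index = assay, columns = site, cells X / - / !
    counts: dict = field(default_factory=dict)

    def to_tsv(self, path: str | Path) -> None:
        self.matrix.to_csv(path, sep="\t", index_label="assay")


def build_survey_table(
    calls: Sequence[PresenceCall],
    site_order: Sequence[str] | None = None,
    assay_order: Sequence[str] | None = None,
) -> SurveyTable:
    """Assemble presence calls into a survey matrix.

    Cells are ``X`` (present), ``-`` (absent) or ``!`` (invalid); per-assay
    counts tally present sites only (invalid sites are excluded, not counted
    as absent). Duplicate (site, assay) pairs are an error.
    """
    seen = set()
    for c in calls:
        key = (c.site_id, c.assay)
        if key in seen:
            raise ValueError(f"duplicate call for site {c.site_id!r}, assay {c.assay!r}")
        seen.add(key)
    sites = list(site_order) if site_order is not None else \
        list(dict.fromkeys(c.site_id for c in calls))
    assays = list(assay_order) if assay_order is not None else \
        list(dict.fromkeys(c.assay for c in calls))
    mat = pd.DataFrame("", index=assays, columns=sites, dtype=object)
    counts = {a: 0 for a in assays}
    for c in calls:
        if c.assay in assays and c.site_id in sites:
            mat.loc[c.assay, c.site_id] = _CELL[c.call]
            if c.call == "present":
                counts[c.assay] += 1
    return SurveyTable(matrix=mat, counts=counts)


# --- replicate-level TSV I/O ----------------------------------------------

def read_survey_tsv(
    survey_path: str | Path,
    controls_path: str | Path | None = None,
) -> list[SurveyObservation]:
    """Read replicate-level survey outcomes (and optional controls) from TSV.

    The survey file has columns ``site_id, assay, extraction_index, pcr_index,
    outcome`` with outcomes ``positive``/``negative`` (or ``+``/``-``). The
    controls file has columns ``control_type, site_id, assay, outcome`` where
    ``control_type`` is ``universal`` (per site), ``extraction_negative`` or
    ``pcr_negative`` (per assay; blank site applies to every site).
    """
    groups: dict[tuple[str, str], dict[int, dict[int, bool]]] = {}
    site_seen: list[str] = []
    with open(survey_path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        _require_columns(reader, survey_path,
                         ("site_id", "assay", "extraction_index", "pcr_index", "outcome"))
        for rec in reader:
            key = (rec["site_id"], rec["assay"])
            if rec["site_id"] not in site_seen:
                site_seen.append(rec["site_id"])
            ext = int(rec["extraction_index"])
            pcr = int(rec["pcr_index"])
            groups.setdefault(key, {}).setdefault(ext, {})[pcr] = _parse_outcome(rec["outcome"])
    universal: dict[str, bool] = {}
    batch_neg: dict[tuple[str, str], bool] = {}  # (control_type, assay) -> positive?
    if controls_path is not None:
        with open(controls_path, newline="") as fh:
            for rec in csv.DictReader(fh, delimiter="\t"):
                ctype = rec["control_type"]
                pos = _parse_outcome(rec["outcome"])
                if ctype == "universal":
                    universal[rec["site_id"]] = pos
                elif ctype in ("extraction_negative", "pcr_negative"):
                    key = (ctype, rec.get("assay", "") or "")
                    batch_neg[key] = batch_neg.get(key, False) or pos
                else:
                    raise ValueError(f"unknown control_type {ctype!r}")
    out = []
    for (site, assay), exts in groups.items():
        extractions = tuple(
            tuple(exts[e][p] for p in sorted(exts[e])) for e in sorted(exts)
        )
        out.append(
            SurveyObservation(
                site_id=site,
                assay=assay,
                extractions=extractions,
                universal_control=universal.get(site, True),
                extraction_negative=batch_neg.get(("extraction_negative", assay),
                                                  batch_neg.get(("extraction_negative", ""), False)),
                pcr_negative=batch_neg.get(("pcr_negative", assay),
                                           batch_neg.get(("pcr_negative", ""), False)),
            )
        )
    return out


def _require_columns(reader: csv.DictReader, path, required: tuple[str, ...]) -> None:
    have = set(reader.fieldnames or ())
    missing = [c for c in required if c not in have]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")


def _parse_outcome(text: str) -> bool:
    t = text.strip().lower()
    if t in ("positive", "+", "1", "true", "x"):
        return True
    if t in ("negative", "-", "0", "false"):
        return False
    raise ValueError(f"unparseable outcome {text!r}")


def read_dilution_tsv(path: str | Path) -> list[DilutionSeries]:
    """Read dilution series from TSV with columns
    ``assay, stock_ng_ml, dilution_factor, outcome`` (one row per step)."""
    rows: dict[str, dict] = {}
    order: list[str] = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        _require_columns(reader, path, ("assay", "stock_ng_ml", "dilution_factor", "outcome"))
        for rec in reader:
            a = rec["assay"]
            if a not in rows:
                rows[a] = {"stock": float(rec["stock_ng_ml"]), "steps": []}
                order.append(a)
            rows[a]["steps"].append((int(rec["dilution_factor"]), _parse_outcome(rec["outcome"])))
    out = []
    for a in order:
        steps = sorted(rows[a]["steps"])
        out.append(
            DilutionSeries(
                stock_ng_ml=rows[a]["stock"],
                dilutions=tuple(d for d, _ in steps),
                outcomes=tuple(o for _, o in steps),
                assay=a,
            )
        )
    return out


def write_calls_json(calls: Iterable[PresenceCall], path: str | Path) -> None:
    Path(path).write_text(json.dumps([asdict(c) for c in calls], indent=2) + "\n")
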