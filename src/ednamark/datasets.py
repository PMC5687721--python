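"""Bundled example datasets.

The package ships a worked example built around four published taxon-specific
mitochondrial markers for invasive freshwater molluscs (*Corbicula* sp.,
*Melanoides tuberculata*, *Mytilopsis leucophaeata*, *Sinanodonta woodiana*;
16S rRNA and COI loci), together with:

* the standard 11-step serial-dilution ladder and per-assay outcome series
  whose stocks are reconstructed to be consistent with each marker's reported
  detection limit under the first-negative rule;
* a replicate-level transcription of the markers' Iberian river survey
  (11 sites across the Manzanares, Guadalquivir and Ebro basins);
* *synthetic* template builders that embed an assay's primer binding sites at
  the expected amplicon spacing, for exercising the in-silico PCR machinery
  without any sequence download. These are constructed stand-ins, not real
  mitochondrial records.
"""

from __future__ import annotations

from importlib import resources

import numpy as np

from . import iupac
from .assaycall import DilutionSeries, SurveyObservation, read_dilution_tsv, read_survey_tsv
from .design import AssayDefinition, read_assay_tsv
from .seqio import SequenceRecord

#: site labels of the bundled survey, upstream-to-downstream within each basin
SURVEY_SITES = ("MR", "M1", "M2", "M3", "S1", "S2", "S3", "EL", "Z1", "Z2", "Z3")


def _data_path(name: str):
    return resources.files("ednamark").joinpath("data", name)


def reference_assays() -> list[AssayDefinition]:
    """The four bundled mollusc marker assays."""
    with resources.as_file(_data_path("invasive_mollusc_assays.tsv")) as p:
        return read_assay_tsv(p)


def reference_dilution_series() -> list[DilutionSeries]:
    """Per-assay serial dilution outcomes on the standard 11-step ladder."""
    with resources.as_file(_data_path("dilution_series.tsv")) as p:
        return read_dilution_tsv(p)


def reference_survey() -> list[SurveyObservation]:
    """Replicate-level outcomes of the bundled 11-site field survey."""
    with resources.as_file(_data_path("iberian_survey.tsv")) as ps, \
            resources.as_file(_data_path("iberian_survey_controls.tsv")) as pc:
        return read_survey_tsv(ps, pc)


def synthetic_template(
    assay: AssayDefinition,
    seed: int = 0,
    pad: int = 40,
    taxon: str | None = None,
) -> SequenceRecord:
    """Build a synthetic template that the assay amplifies at its expected size.

    The template is random sequence with one concrete expansion of the forward
    primer and the reverse complement of one concrete expansion of the reverse
    primer planted ``expected_amplicon_bp`` apart (footprints included). It is
    a synthetic stand-in for a real mitochondrial record carrying the marker
    region, useful for validating amplicon-size arithmetic offline.
    """
    if assay.expected_amplicon_bp is None:
        raise ValueError(f"assay {assay.name!r} has no expected amplicon size")
    rng = np.random.default_rng(seed)
    bases = np.array(list("ACGT"))

    def rand(n: int) -> str:
        return "".join(bases[rng.integers(0, 4, size=n)])

    def concrete(primer: str) -> str:
        exps = iupac.expand(primer)
        return exps[int(rng.integers(0, len(exps)))]

    fwd = concrete(assay.forward)
    rev = concrete(assay.reverse)
    spacer = assay.expected_amplicon_bp - len(fwd) - len(rev)
    if spacer < 0:
        raise ValueError(f"assay {assay.name!r}: amplicon shorter than primer footprints")
    seq = rand(pad) + fwd + rand(spacer) + iupac.reverse_complement(rev) + rand(pad)
    return SequenceRecord(
        id=f"synthetic_{assay.name}_template",
        seq=seq,
        taxon=taxon if taxon is not None else assay.target_taxon,
        locus=assay.locus,
    )


def synthetic_cross_panel(
    assays: list[AssayDefinition] | None = None,
    n_offtarget: int = 9,
    seed: int = 0,
    length: int = 600,
) -> list[SequenceRecord]:
    """A synthetic cross-amplification panel: one template per assay target plus
    unrelated random sequences, emulating an in-vitro specificity test across a
    collection of non-target taxa."""
    if assays is None:
        assays = reference_assays()
    rng = np.random.default_rng(seed)
    bases = np.array(list("ACGT"))
    panel = [
        synthetic_template(a, seed=int(rng.integers(0, 2 ** 31))) for a in assays
    ]
    for j in range(n_offtarget):
        seq = "".join(bases[rng.integers(0, 4, size=length)])
        panel.append(
            SequenceRecord(id=f"synthetic_offtarget_{j + 1:02d}", seq=seq,
                           taxon=f"offtarget_sp_{j + 1:02d}")
        )
    return panel
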