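import pytest

from ednamark import datasets, synth


@pytest.fixture(scope="session")
def reference_assays():
    return datasets.reference_assays()


@pytest.fixture(scope="session")
def assay_by_name(reference_assays):
    return {a.name: a for a in reference_assays}


@pytest.fixture(scope="session")
def small_panel():
    """A small seeded panel with two planted diagnostic regions (min_mm=3)."""
    spec = synth.PanelSpec(
        seed=11, locus_len=320, n_target_haps=4, intra_target_subs=2,
        n_nontargets=3, nontarget_subs=5,
        planted_regions=(synth.PlantedRegion(50, 22, 3), synth.PlantedRegion(240, 22, 3)),
    )
    return synth.generate_panel(spec)
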