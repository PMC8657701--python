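"""Shared fixtures: a small edited family and its processed pipeline run.

Everything is generated programmatically from fixed seeds; nothing is read
from disk.
"""

import pytest

import amplindel as am
from amplindel.simulate import (EditSpec, FamilySpec, ReadSimSpec,
                                pcr_amplify, simulate_reads)

SMALL_EDITS = (("A01", -3, 0), ("B01", 2, -1), ("D02", -6, 1))


@pytest.fixture(scope="session")
def small_family():
    return am.simulate_family(FamilySpec(seed=7))


@pytest.fixture(scope="session")
def small_dataset(small_family):
    """WT and edited molecule sets plus their truth tables."""
    wt_mol, _ = am.apply_edits(small_family, EditSpec(edits=()))
    ed_mol, truth = am.apply_edits(
        small_family,
        EditSpec(edits=SMALL_EDITS, zygosity_fraction={"B01": 0.5}, seed=3))
    return {"family": small_family, "wt_molecules": wt_mol,
            "ed_molecules": ed_mol, "truth": truth}


@pytest.fixture(scope="session")
def small_reads(small_dataset):
    wt_amps = pcr_amplify(small_dataset["wt_molecules"])
    ed_amps = pcr_amplify(small_dataset["ed_molecules"])
    r1w, r2w = simulate_reads(wt_amps, ReadSimSpec(depth=150, seed=11))
    r1e, r2e = simulate_reads(ed_amps, ReadSimSpec(depth=150, seed=12))
    return {"WT": (r1w, r2w), "CR": (r1e, r2e),
            "wt_amplicons": wt_amps, "ed_amplicons": ed_amps}


@pytest.fixture(scope="session")
def small_chain(small_reads):
    samples = [("WT", *small_reads["WT"]), ("CR", *small_reads["CR"])]
    return am.run_chain(samples)


@pytest.fixture(scope="session")
def small_meta():
    return [am.LineMeta("WT", "BW", "WT"),
            am.LineMeta("CR", "BW", "T0", cas9="present")]
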