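import numpy as np
import pytest

from junglecoal import synth
from junglecoal.locus_io import IntronLocus, LocusCatalog, SampleRecord


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_catalog(loci_spec, samples):
    """Build an in-memory catalog.

    ``loci_spec``: {locus_id: [(individual, copy, seq), ...]};
    ``samples``: [(individual_id, group, ploidy), ...].
    """
    records = [SampleRecord(*s) for s in samples]
    loci = []
    for locus_id, seqs in loci_spec.items():
        length = len(seqs[0][2])
        loci.append(IntronLocus(locus_id, length, list(seqs)))
    catalog = LocusCatalog(records, loci)
    for rec in records:
        for locus in loci:
            if not locus.copies_of(rec.individual_id):
                catalog.missing.add((rec.individual_id, locus.locus_id))
    return catalog


@pytest.fixture
def small_catalog():
    """Two loci, four diploid individuals in two groups, fully sequenced."""
    samples = [("i1", "G1", 2), ("i2", "G1", 2), ("i3", "G2", 2), ("i4", "G2", 2)]
    loci = {
        "locA": [
            (ind, copy, seq)
            for ind, seqs in [
                ("i1", ("AACGT", "AACGT")),
                ("i2", ("AACGT", "AATGT")),
                ("i3", ("AATGT", "AATGT")),
                ("i4", ("AACGT", "AATGT")),
            ]
            for copy, seq in enumerate(seqs)
        ],
        "locB": [
            (ind, copy, seq)
            for ind, seqs in [
                ("i1", ("CCC", "CCC")),
                ("i2", ("CCC", "CCC")),
                ("i3", ("CCG", "CCG")),
                ("i4", ("CCC", "CCG")),
            ]
            for copy, seq in enumerate(seqs)
        ],
    }
    return make_catalog(loci, samples)


@pytest.fixture(scope="session")
def default_sim_catalog():
    """One study-design catalog (no introgression, no inbreeding)."""
    cat, truth = synth.simulate_catalog(
        synth.SimulationConfig(), np.random.default_rng(777)
    )
    return cat, truth


SPECIES_MAP = {"KOSHA": "C", "UKO": "C", "SHAMO": "C", "WL": "C",
               "RJF": "R", "GJF": "G"}


@pytest.fixture(scope="session")
def species_map():
    return dict(SPECIES_MAP)
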