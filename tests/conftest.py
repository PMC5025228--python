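"""Shared fixtures: printed study sequences and small simulated datasets."""

import pytest

import mitomodkit as mk

# The four template oligos assembled into the T7 transcription template for
# the helix-71 segment of human mitochondrial 16S rRNA (positions 866-979).
TEMPLATE_OLIGOS = [
    "gctaatacgactcactataggcaccgcctgcccagtgacacatgtttaacggc",
    "gtgacacatgtttaacggccgcggtaccctaaccgtgcaaaggtagcataatcac",
    "gtgcaaaggtagcataatcacttgttccttaaatagggacctgtatgaatggctccacgagggtt",
    "aaccctcgtggagccattc",
]

# The two published 90-nt lagging-strand MAGE oligos editing E. coli 23S
# rRNA position 1954 (G->A and G->T in gene-strand coordinates; the edited
# base sits at oligo offset 46).
MAGE_OLIGO_G_TO_A = ("GTGGAGACAGCCTGGCCATCATTACGCCATTCGTGCAGGTCGGAA" "T"
                     "TTACCCGACAAGGAATTTCGCTACCTTAGGACCGTTATAGTTAC")
MAGE_OLIGO_G_TO_T = ("GTGGAGACAGCCTGGCCATCATTACGCCATTCGTGCAGGTCGGAA" "A"
                     "TTACCCGACAAGGAATTTCGCTACCTTAGGACCGTTATAGTTAC")


@pytest.fixture(scope="session")
def template_oligos():
    return list(TEMPLATE_OLIGOS)


@pytest.fixture(scope="session")
def mage_oligos():
    return MAGE_OLIGO_G_TO_A, MAGE_OLIGO_G_TO_T


@pytest.fixture(scope="session")
def helix71_transcript(template_oligos):
    """The predicted 114-nt run-off transcript in 16S coordinates (866-979)."""
    template = mk.assemble_overlap(template_oligos)
    return mk.t7_runoff(template, start_pos=866, parent_name="human 16S rRNA")


@pytest.fixture(scope="session")
def sim_dataset(tmp_path_factory):
    """One seeded read simulation with its SAM on disk and truth record."""
    ref = mk.make_reference(400, seed=11, embed=("TTCCTTAAATAG", 193), name="simref")
    spec = mk.SiteSignatureSpec(pos=201, p_T=0.60, p_G=0.12, p_trunc=0.20,
                                coverage=2000, seed=5)
    sam_path = tmp_path_factory.mktemp("sim") / "reads.sam"
    _, truth = mk.simulate_reads(ref, spec, sam_path=sam_path)
    return {"reference": ref, "spec": spec, "sam_path": sam_path, "truth": truth,
            "site": 201}
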