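"""Shared fixtures: printed reference sequences and a small planted dataset."""

import numpy as np
import pytest

from cas9kit import synthetic_data as sd

# Guide/oligo pair from the published point-mutation edit (N209S, A626G):
# the guide matches the wild-type locus end-to-end; the repair oligo carries
# the single A->G substitution, so guide vs edited region has 19/20 matches.
CDT1_N209S_GUIDE = "TGCACTGGCTTCTACAACTG"
CDT1_N209S_OLIGO = "CGGCCGCTGCACTGGCTTCTACAGCTGCGGTTGGTTCGGAGGTTCATTCCTGCCGCCTG"
CDT1_N209S_EDIT_OFFSET = 23  # 0-based position of the edited base within the oligo

CDT1_F262Y_GUIDE = "CCTCGCTTCCTATTTGCCAA"
CDT1_F262Y_OLIGO = "AGAATCCCCTCGCTACCTATTTGCCAACGGCCGCGACGCTGAGGCTGTTGCCTTTCTTGT"
CDT1_F262Y_EDIT_OFFSET = 14


@pytest.fixture(scope="session")
def guide():
    return CDT1_N209S_GUIDE


@pytest.fixture(scope="session")
def offtarget_scene(guide):
    """Genome with planted decoy sites and variants at known distances.

    Decoy match counts straddle the 12-match threshold; the (5, SNP, 14) and
    (8, MNP, 12) specs are true positives, the rest true negatives.
    """
    specs = [(5, "SNP", 14), (8, "MNP", 12), (3, "INDEL", 10), (12, "SNP", 8)]
    plants = sd.plan_decoy_plants(guide, specs, 20_000, seed=11)
    genome, gtruth = sd.make_genome(lengths=(20_000,), planted=plants, seed=11)
    records, vtruth = sd.make_variants(
        genome, specs, guide, seed=11, planted_sites=gtruth.planted_sites
    )
    return dict(
        genome=genome, specs=specs, records=records,
        planted_sites=gtruth.planted_sites, offtargets=vtruth.planted_offtargets,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
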