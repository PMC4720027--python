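import numpy as np
import pytest

from clonegrid.design import SgRNADesign, PairedDeletionDesign, find_targets
from clonegrid.indels import AmpliconReference


def make_reference(seed: int = 7, length: int = 240, pam_at: int = 118) -> AmpliconReference:
    """Random amplicon with one + strand NGG target planted mid-sequence."""
    rng = np.random.default_rng(seed)
    core = "".join(rng.choice(list("ACGT"), length))
    seq = core[:pam_at] + "TGG" + core[pam_at + 3 :]
    cut = pam_at - 3
    designs = [
        d for d in find_targets(seq) if d.strand == "+" and d.cut_site == cut
    ]
    assert designs, "planted target not recovered"
    return AmpliconReference("amp", seq, (designs[0],), primer_lengths=(20, 20))


def _dummy_sg(cut_site: int, name: str) -> SgRNADesign:
    return SgRNADesign(
        spacer="ACGTACGTACGTACGTACGT",
        pam="AGG",
        strand="+",
        cut_site=cut_site,
        name=name,
    )


def make_paired_designs(cuts=(100, 400, 640), wt_bp: int = 1000):
    """All pairwise deletion designs for the given cut sites (shared amplicon)."""
    sgs = [_dummy_sg(c, f"sg{i+1}") for i, c in enumerate(cuts)]
    designs = []
    for i in range(len(sgs)):
        for j in range(i + 1, len(sgs)):
            d = abs(sgs[j].cut_site - sgs[i].cut_site)
            designs.append(
                PairedDeletionDesign(
                    sg_a=sgs[i],
                    sg_b=sgs[j],
                    expected_deletion_bp=d,
                    wt_amplicon_bp=wt_bp,
                    edited_amplicon_bp=wt_bp - d,
                    genotyping_primers=("ACGTACGTACGTACGTACGT", "ACGTACGTACGTACGTACGT"),
                    name=f"{sgs[i].name}+{sgs[j].name}",
                )
            )
    return designs


@pytest.fixture(scope="session")
def amplicon() -> AmpliconReference:
    return make_reference()


@pytest.fixture(scope="session")
def paired_designs():
    return make_paired_designs()
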