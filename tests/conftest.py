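import numpy as np
import pytest

from phosphopipe.tables_io import ProteinRecord, PsmRecord, SiteProb


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


def make_psm(
    peptide="AKSPR",
    accession="P1",
    start=0,
    charge=2,
    score=3.1,
    rank=1,
    fdr_pass=True,
    n_phospho=0,
    site_probs=(),
    cell_line="lineA",
    condition="vehicle",
    replicate="R1",
    fraction="cytosolic",
):
    return PsmRecord(
        peptide=peptide, accession=accession, start=start, charge=charge,
        score=score, rank=rank, fdr_pass=fdr_pass, n_phospho=n_phospho,
        site_probs=tuple(site_probs), cell_line=cell_line, condition=condition,
        replicate=replicate, fraction=fraction,
    )


def random_protein(rng, length, alphabet="ACDEFGHIKLMNPQRSTVWY"):
    return ProteinRecord(
        f"RND{rng.integers(1, 10**9)}",
        "".join(rng.choice(list(alphabet), size=length)),
    )


@pytest.fixture
def phospho_psm():
    return make_psm(
        peptide="AKSPRTY", n_phospho=2,
        site_probs=(SiteProb(3, "S", 0.995), SiteProb(6, "T", 0.90)),
    )
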