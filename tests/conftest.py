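import numpy as np
import pytest

from miredit.refset import (
    MatureAnnotation,
    PrecursorRecord,
    ReferenceSet,
    write_reference,
)


@pytest.fixture
def toy_refset():
    """Two hand-made precursors: one hairpin-capable, one with 5p+3p arms."""
    # 60 nt; mature 16-36 => seed = precursor 17-23
    seq_a = "GGGGCCCCAAUUAAGGUAGUAGACCGUAUAGCGUACGAAAACCCGGGGAAAACCCCGGGG"
    rec_a = PrecursorRecord(
        precursor_id="toy-mir-1",
        sequence=seq_a,
        matures=(MatureAnnotation("toy-miR-1-5p", "5p", 16, 36),),
        chromosome="1",
        cluster_id="cl1",
    )
    seq_b = (
        "AUGCAUGCAUGCAUGCAUGCA"  # 1-21: 5p arm 2-21
        "GAACGAAACGAAACG"        # 22-36 loop
        "UUACGUUACGUUACGUUACGUUAC"  # 37-60: 3p arm 38-59
    )
    rec_b = PrecursorRecord(
        precursor_id="toy-mir-2",
        sequence=seq_b,
        matures=(
            MatureAnnotation("toy-miR-2-5p", "5p", 2, 21),
            MatureAnnotation("toy-miR-2-3p", "3p", 38, 59),
        ),
        chromosome="2",
    )
    return ReferenceSet([rec_a, rec_b])


@pytest.fixture
def toy_reference_files(tmp_path, toy_refset):
    fasta = tmp_path / "precursors.fa"
    matures = tmp_path / "matures.tsv"
    clusters = tmp_path / "clusters.tsv"
    write_reference(toy_refset, fasta, matures, clusters)
    return fasta, matures, clusters


@pytest.fixture
def rng():
    return np.random.default_rng(20260929)
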