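import json
from pathlib import Path

import pytest

from hetinsul.genome_io import GeneModel, Interval
from hetinsul.simulate import SimConfig, simulate


@pytest.fixture(scope="session")
def bundle(tmp_path_factory) -> Path:
    """Default synthetic bundle (seed 1), shared across the session."""
    d = tmp_path_factory.mktemp("bundle")
    simulate(SimConfig(seed=1), d)
    return d


@pytest.fixture(scope="session")
def bundle_truth(bundle) -> dict:
    return json.loads((bundle / "truth.json").read_text())


def make_gene(gene_id="g1", chrom="chr2L", start=1000, end=3000, strand="+",
              biotype="protein_coding"):
    iv = Interval(chrom, start, end, strand)
    tss = start if strand == "+" else end - 1
    return GeneModel(gene_id, iv, tss, biotype)
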