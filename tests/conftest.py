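import numpy as np
import pandas as pd
import pytest

from hydroxyscape.genome_io import GenomeAssembly, TagCollection
from hydroxyscape.synthetic_data import SimulationConfig, generate_truth, simulate_tags


@pytest.fixture
def toy_assembly():
    return GenomeAssembly((("chr1", 1000), ("chrX", 500)))


def make_tags(rows, tag_length=38):
    """rows: iterable of (chrom, start, strand)."""
    frame = pd.DataFrame(rows, columns=["chrom", "start", "strand"])
    frame["start"] = frame["start"].astype(np.int64)
    return TagCollection(frame, tag_length=tag_length)


@pytest.fixture(scope="session")
def small_study():
    """One simulated 2 Mb study shared by read-only tests."""
    cfg = SimulationConfig(
        chrom_lengths=(2_000_000,),
        n_genes=40,
        n_enhancers=20,
        ip_tags=200_000,
        input_tags=200_000,
        seed=2,
    )
    assembly, sequences, genes, feats, meth, truth = generate_truth(cfg)
    ip, input_tags = simulate_tags(truth, genes, feats["enhancers"], assembly)
    return {
        "config": cfg,
        "assembly": assembly,
        "sequences": sequences,
        "genes": genes,
        "features": feats,
        "methylation": meth,
        "truth": truth,
        "ip": ip,
        "input": input_tags,
    }
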