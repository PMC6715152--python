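import numpy as np
import pytest

from mirclip.pipeline import run_simulation
from mirclip.seedscan import seed_from_mature
from mirclip.simulate import SimConfig

MIR16_MATURE = "UAGCAGCACGUAAAUAUUGGCG"


@pytest.fixture(scope="session")
def mir16():
    return seed_from_mature("miR-15/16", MIR16_MATURE, members=["miR-16-5p"])


def _genome(seed: int, length: int) -> str:
    rng = np.random.default_rng(seed)
    return "".join("ACGT"[k] for k in rng.integers(0, 4, size=length))


@pytest.fixture(scope="session")
def plus_gtf():
    """Two-exon plus-strand transcript: exons 1-100 and 201-300 (1-based
    inclusive), CDS 51-250; expected regions 5'UTR [0,50), CDS [50,150),
    3'UTR [150,200)."""
    attrs = 'gene_id "GP"; transcript_id "TP";'
    return "\n".join([
        f"c1\tx\texon\t1\t100\t.\t+\t.\t{attrs}",
        f"c1\tx\texon\t201\t300\t.\t+\t.\t{attrs}",
        f"c1\tx\tCDS\t51\t250\t.\t+\t.\t{attrs}",
    ]) + "\n"


@pytest.fixture(scope="session")
def minus_gtf():
    """Single-exon minus-strand transcript: exon 1-100, CDS 21-80; expected
    regions in transcript orientation 5'UTR [0,20), CDS [20,80), 3'UTR [80,100)."""
    attrs = 'gene_id "GM"; transcript_id "TM";'
    return "\n".join([
        f"c2\tx\texon\t1\t100\t.\t-\t.\t{attrs}",
        f"c2\tx\tCDS\t21\t80\t.\t-\t.\t{attrs}",
    ]) + "\n"


@pytest.fixture(scope="session")
def toy_fasta():
    return (f">c1\n{_genome(1, 300)}\n"
            f">c2\n{_genome(2, 100)}\n")


@pytest.fixture(scope="session")
def toy_ts(plus_gtf, minus_gtf, toy_fasta):
    from mirclip.transcriptome import load_annotation
    return load_annotation(plus_gtf + minus_gtf, toy_fasta, mode="genome")


@pytest.fixture(scope="session")
def small_sim():
    """One small full-pipeline run shared by read-only tests."""
    cfg = SimConfig(n_genes=60, n_target_genes=8, seed=11)
    result, sim, de_full = run_simulation(cfg)
    return cfg, result, sim, de_full
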