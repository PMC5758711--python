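import numpy as np
import pandas as pd
import pytest

from emtlink.config import SimConfig


@pytest.fixture
def small_cfg():
    """A fast simulation config for unit tests."""
    return SimConfig(
        seed=7,
        n_genes=200,
        chrom_sizes={"chr1": 500_000, "chr2": 400_000},
        n_peaks=150,
        img_n_cells=2,
        img_grid=32,
    )


@pytest.fixture
def zero_noise_cfg():
    """Noise-free, fixed-effect config: planted effects recoverable exactly."""
    return SimConfig(
        seed=11,
        n_genes=300,
        chrom_sizes={"chr1": 800_000, "chr2": 600_000},
        noise_sd=0.0,
        effect_log2fc_sd=0.0,
        effect_log2fc_mean=2.0,
        n_peaks=200,
        img_n_cells=2,
        img_grid=32,
    )


@pytest.fixture
def toy_genes():
    return pd.DataFrame(
        {
            "chrom": ["chr1", "chr1", "chr1", "chr2"],
            "tss": [1000, 3000, 10_000, 2000],
            "strand": ["+", "+", "-", "-"],
            "gene_id": ["g1", "g2", "g3", "g4"],
        }
    )


def regions_frame(rows):
    """rows: (chrom, start, end, region_id, tag_count)"""
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "region_id", "tag_count"])
    df["factor"] = "A"
    return df


@pytest.fixture
def rng():
    return np.random.default_rng(20260928)
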