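import numpy as np
import pandas as pd
import pytest

import ymcregulon as y
from ymcregulon.simulate import signal_peak_regions


@pytest.fixture(scope="session")
def default_sim() -> y.SimResult:
    """The default synthetic study (seed 42); shared read-only across tests."""
    return y.simulate_all(y.SimConfig())


@pytest.fixture(scope="session")
def scanned_sites(default_sim) -> pd.DataFrame:
    """All-TF motif sites from scanning within histone-signal peak regions."""
    regions = signal_peak_regions(default_sim.truth, default_sim.chrom_sizes)
    frames = [
        y.scan_motifs(default_sim.sequences, pwm, regions) for pwm in default_sim.pwms
    ]
    return pd.concat(frames, ignore_index=True)


@pytest.fixture()
def tiny_config() -> y.SimConfig:
    return y.SimConfig(
        n_chroms=1, chrom_len=80_000, n_genes=40, n_tf_motifs=3, pathway_size=5, seed=11
    )


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(0)


def make_annotation(records, chrom_sizes=None) -> y.GeneAnnotation:
    """records: (gene_id, chrom, start, end, strand, phase)."""
    df = pd.DataFrame(
        records, columns=["gene_id", "chrom", "start", "end", "strand", "phase"]
    )
    return y.GeneAnnotation(df, chrom_sizes or {})
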