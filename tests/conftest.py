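import numpy as np
import pandas as pd
import pytest

from polytail import (
    SimulationDesign,
    default_references,
    simulate_polya_table,
    write_sample_bams,
    write_synthetic_gtf,
)


@pytest.fixture
def tiny_polya() -> pd.DataFrame:
    """Hand-written five-read table over three transcripts and two groups."""
    return pd.DataFrame({
        "read_id": ["r1", "r2", "r3", "r4", "r5"],
        "transcript_id": ["t1", "t1", "t2", "t2", "t3"],
        "polyA_length": [40, 60, 55, 100, 12],
        "sample_name": ["s1", "s1", "s1", "s2", "s2"],
        "group": ["CTR", "CTR", "CTR", "HIGH", "HIGH"],
    })


@pytest.fixture
def small_design() -> SimulationDesign:
    return SimulationDesign.two_group(
        seed=11, n_genes=8, n_affected=2, shift_nt=-25.0,
        reads_per_gene_per_sample=12, n_samples_per_group=2,
    )


@pytest.fixture
def small_experiment(small_design, tmp_path):
    """Simulated table written to per-sample BAMs plus a matching GTF."""
    polya, truth = simulate_polya_table(small_design)
    refs = default_references(small_design)
    samples = write_sample_bams(polya, refs, str(tmp_path / "bams"))
    gtf = write_synthetic_gtf(small_design.transcript_gene_map(),
                              str(tmp_path / "annotation.gtf"))
    return {"design": small_design, "polya": polya, "truth": truth,
            "samples": samples, "gtf": gtf, "references": refs}


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260928)
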