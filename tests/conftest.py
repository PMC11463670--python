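import time
from pathlib import Path

import numpy as np
import pytest

from pgcmultiome.pipeline import run_pipeline
from pgcmultiome.simulate import SimulatedMultiome, SynthConfig, simulate_multiome


@pytest.fixture(scope="session")
def small_ds() -> SimulatedMultiome:
    """A reduced-scale simulated multiome shared across unit tests."""
    cfg = SynthConfig(
        n_pgc=40,
        n_supporting=40,
        n_somatic=30,
        n_genes=800,
        n_peaks=1200,
        frags_per_cell=120,
    )
    return simulate_multiome(cfg, seed=7)


@pytest.fixture(scope="session")
def pipeline_run(tmp_path_factory):
    """The full pipeline at the default synthetic scale, run twice with the
    same seed. Returns (outdir, data_dir, byte-mismatched files, elapsed)."""
    base = tmp_path_factory.mktemp("pipeline")
    t0 = time.time()
    out1 = run_pipeline(["all"], base / "data1", base / "out1", seed=11)
    out2 = run_pipeline(["all"], base / "data2", base / "out2", seed=11)
    elapsed = time.time() - t0
    mismatches = []
    files1 = sorted(p.relative_to(out1) for p in Path(out1).rglob("*") if p.is_file())
    files2 = sorted(p.relative_to(out2) for p in Path(out2).rglob("*") if p.is_file())
    if files1 != files2:
        mismatches.append("file lists differ")
    else:
        for rel in files1:
            if (out1 / rel).read_bytes() != (out2 / rel).read_bytes():
                mismatches.append(str(rel))
    return Path(out1), base / "data1", mismatches, elapsed


@pytest.fixture(scope="session")
def rng() -> np.random.Generator:
    return np.random.default_rng(123)
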