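import numpy as np
import pytest

import sexscan as sx
from sexscan import _seq
from sexscan import coverage as cov


@pytest.fixture(scope="session")
def tiny_cfg():
    """A small four-scaffold study: 2 autosomes, 1 X, 1 Y at 30 kb, 10x."""
    return sx.SimConfig(n_autosomal_scaffolds=2, n_x_scaffolds=1,
                        n_y_scaffolds=1, scaffold_length_range=(30_000, 30_000),
                        n_genes_per_scaffold=3, mean_depth=10.0, seed=7)


@pytest.fixture(scope="session")
def tiny_sim(tiny_cfg):
    assembly, truth = sx.simulate_assembly(tiny_cfg)
    reads_f = sx.simulate_reads(assembly, truth, "female", tiny_cfg)
    reads_m = sx.simulate_reads(assembly, truth, "male", tiny_cfg)
    return {"cfg": tiny_cfg, "assembly": assembly, "truth": truth,
            "female": reads_f, "male": reads_m}


@pytest.fixture(scope="session")
def tiny_tracks(tiny_sim):
    """Placements and RPKM tracks for the tiny study, both sexes."""
    assembly = tiny_sim["assembly"]
    windows = cov.tile_windows(assembly)
    out = {"windows": windows}
    for sex in ("female", "male"):
        pl = cov.place_reads(tiny_sim[sex], assembly)
        lib = int((pl["status"] == cov.UNIQUE).sum())
        out[sex] = {"placements": pl, "library_size": lib,
                    "track": cov.window_rpkm(pl, windows, lib, sex=sex)}
    return out


def make_readset(sequences, sex="male"):
    """Build a ReadSet from explicit uniform-length sequence strings."""
    n = len(sequences)
    if n == 0:
        return sx.ReadSet(sex, np.empty((0, 0), np.uint8),
                          np.empty(0, object), np.empty(0, np.int64),
                          np.empty(0, object))
    rl = len(sequences[0])
    assert all(len(s) == rl for s in sequences)
    codes = np.vstack([_seq.encode(s) for s in sequences])
    scaf = np.empty(n, object)
    scaf[:] = "manual"
    strands = np.empty(n, object)
    strands[:] = "+"
    return sx.ReadSet(sex, codes, scaf, np.zeros(n, np.int64), strands)
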