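import numpy as np
import pandas as pd
import pytest

from polysweep.panel import GenotypePanel


def make_panel(calls, pos=None, chrom="1A", cm=None, lines=None,
               metadata_groups=None, ref=None, alt=None):
    """Build a small GenotypePanel from a calls matrix (variants x lines)."""
    calls = np.asarray(calls, dtype=np.int8)
    m, n = calls.shape
    if pos is None:
        pos = np.arange(1, m + 1) * 1000
    pos = np.asarray(pos)
    if cm is None:
        cm = pos / 1e6
    if lines is None:
        lines = [f"L{i + 1:02d}" for i in range(n)]
    if isinstance(chrom, str):
        chrom = [chrom] * m
    sg = [c.rstrip()[-1] for c in chrom]
    variants = pd.DataFrame({
        "chrom": chrom, "pos": pos,
        "ref": ref if ref is not None else ["A"] * m,
        "alt": alt if alt is not None else ["G"] * m,
        "subgenome": sg, "cm": np.asarray(cm, dtype=float)})
    metadata = None
    if metadata_groups is not None:
        metadata = pd.DataFrame({
            "line": lines, "group": metadata_groups,
            "growth_habit": ["spring"] * n}).set_index("line")
    return GenotypePanel(variants, calls, list(lines), metadata)


@pytest.fixture(scope="session")
def small_sim():
    """One small simulated population shared across tests."""
    from polysweep.simulate import SimConfig, default_subgenomes, simulate_population

    cfg = SimConfig(seed=11, subgenomes=default_subgenomes(scale=0.25))
    return cfg, simulate_population(cfg)
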