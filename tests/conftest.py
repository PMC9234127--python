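import numpy as np
import pandas as pd
import pytest

from tepnorm import CountMatrix, CtPanel


def make_panel(ct: dict, groups=None, efficiency: float = 2.0) -> CtPanel:
    """Build a collapsed CtPanel from gene -> per-sample Ct lists."""
    n = len(next(iter(ct.values())))
    samples = [f"S{i + 1}" for i in range(n)]
    if groups is None:
        groups = ["g1"] * n
    gmap = pd.Series(list(groups), index=samples)
    wide = pd.DataFrame({s: {g: ct[g][i] for g in ct} for i, s in enumerate(samples)})
    wide = wide.reindex(index=list(ct), columns=samples)
    return CtPanel.from_wide(wide, gmap, efficiency=efficiency)


def random_ct_dict(rng, n_genes=5, n_samples=8):
    """Complete random panel as plain dict, suitable for the oracles."""
    return {
        f"G{i + 1}": list(np.round(rng.uniform(18.0, 30.0, n_samples), 4))
        for i in range(n_genes)
    }


@pytest.fixture
def panel_factory():
    return make_panel


@pytest.fixture
def abc_panel():
    """Three-gene, four-sample worked example panel."""
    return make_panel(
        {"A": [20, 21, 22, 23], "B": [20, 21, 22, 23], "C": [20, 22, 21, 25]}
    )


@pytest.fixture
def toy_count_matrix():
    counts = pd.DataFrame(
        {"s1": [1, 3, 5], "s2": [2, 4, 6]}, index=["g1", "g2", "g3"]
    )
    groups = pd.Series(["normal", "tumor"], index=["s1", "s2"])
    return CountMatrix(counts, groups)


@pytest.fixture
def count_files(tmp_path):
    """Write a small count matrix + sample sheet to disk, return the paths."""

    def _write(counts: pd.DataFrame, groups: dict, isr: dict | None = None):
        cpath = tmp_path / "counts.tsv"
        mpath = tmp_path / "samples.tsv"
        out = counts.copy()
        out.index.name = "gene_id"
        out.to_csv(cpath, sep="\t")
        meta = pd.DataFrame(
            {"sample_id": list(groups), "group": list(groups.values())}
        )
        if isr is not None:
            meta["intron_spanning_reads"] = [isr[s] for s in groups]
        meta.to_csv(mpath, sep="\t", index=False)
        return cpath, mpath

    return _write
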