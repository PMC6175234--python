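from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from necrosip.io import CountTable, SampleMetadata, SpectrumSet


@pytest.fixture
def small_counts() -> CountTable:
    rng = np.random.default_rng(42)
    df = pd.DataFrame(
        rng.integers(0, 50, size=(8, 4)),
        index=[f"p{i}" for i in range(8)],
        columns=["s1", "s2", "s3", "s4"],
    )
    df.iloc[0] += 1  # no all-zero sample
    return CountTable(df)


def make_metadata(rows: list[dict]) -> SampleMetadata:
    defaults = dict(
        day=0, substrate="none", isotope="none", dose="none",
        inhibitor="none", molecule="DNA", replicate=1,
    )
    return SampleMetadata(pd.DataFrame([{**defaults, **r} for r in rows]))


@pytest.fixture
def tiny_spectra() -> SpectrumSet:
    wn = np.arange(600.0, 1801.0)
    rng = np.random.default_rng(7)
    cells = []
    for _ in range(3):
        base = 0.2 + 0.1 * (wn - wn.mean()) ** 2 / (np.ptp(wn) / 2) ** 2
        peak = np.exp(-0.5 * ((wn - 1002.0) / 1.7) ** 2)
        cells.append(base + peak + rng.normal(0, 0.005, wn.size))
    return SpectrumSet(
        wn, np.clip(np.vstack(cells), 0, None),
        ["c1", "c2", "c3"], ["probe", "probe", "negative"],
    )
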