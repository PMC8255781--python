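import numpy as np
import pandas as pd
import pytest

from pharmaeeg import synth
from pharmaeeg.spectral import FS_ANALYSIS


@pytest.fixture(scope="session")
def small_design():
    return synth.default_design(n_wt=3, n_ko=3, treatments=("SAL",))


@pytest.fixture(scope="session")
def small_study(small_design):
    """3 WT + 3 KO subjects, SAL session + short baseline, reduced protocol."""
    return synth.make_study(small_design, seed=7, protocol=synth.reduced_protocol(),
                            include_baseline=True)


def make_tone_recording(freq, duration_s=24.0, amplitude=1.0, fs=FS_ANALYSIS):
    """Pure-sinusoid recording at the analysis rate (for spectral tests)."""
    t = np.arange(int(duration_s * fs)) / fs
    x = amplitude * np.sin(2 * np.pi * freq * t)
    return synth.RawRecording(channels={"eeg_frontal": x, "emg": np.zeros_like(x)},
                              fs=fs)


def fixture_datasets():
    """Five small complete datasets for the oracle cross-check.

    Each entry: (long DataFrame, factor columns, list of group matrices in
    lexicographic cell order, between-factor level counts).
    """
    out = []

    def from_groups(groups, factor_names, level_lists):
        rows = []
        if len(level_lists) == 1:
            cells = [(a,) for a in level_lists[0]]
        else:
            cells = [(a, b) for a in level_lists[0] for b in level_lists[1]]
        for cell, M in zip(cells, groups):
            M = np.asarray(M, dtype=float)
            for i in range(M.shape[0]):
                for j in range(M.shape[1]):
                    row = {"unit": f"{'_'.join(map(str, cell))}_{i}",
                           "time": j, "value": M[i, j]}
                    row.update(dict(zip(factor_names, cell)))
                    rows.append(row)
        return pd.DataFrame(rows)

    # 1: 2 groups x 2 times, integers
    g = [np.array([[1, 5], [2, 7], [3, 6], [4, 8]]),
         np.array([[9, 2], [10, 4], [11, 1], [12, 3]])]
    out.append((from_groups(g, ["group"], [["A", "B"]]), ("group",), g, [2]))

    # 2: 2 groups x 3 times with heavy ties
    g = [np.array([[1, 1, 2], [2, 2, 2], [1, 3, 3], [2, 1, 2]]),
         np.array([[3, 1, 1], [2, 2, 3], [3, 3, 1], [1, 2, 2]])]
    out.append((from_groups(g, ["group"], [["A", "B"]]), ("group",), g, [2]))

    # 3: 3 groups x 2 times
    g = [np.array([[0.5, 1.1], [0.7, 1.3], [0.6, 0.9]]),
         np.array([[1.5, 2.1], [1.7, 1.9], [1.4, 2.3]]),
         np.array([[2.5, 0.1], [2.7, 0.3], [2.6, 0.2]])]
    out.append((from_groups(g, ["group"], [["A", "B", "C"]]), ("group",), g, [3]))

    # 4: F2 layout, 2 x 2 groups x 2 times
    g = [np.array([[1.0, 2.0], [1.5, 2.5], [0.8, 1.9]]),
         np.array([[2.0, 3.0], [2.2, 3.1], [1.9, 2.8]]),
         np.array([[0.4, 0.6], [0.5, 0.7], [0.3, 0.8]]),
         np.array([[3.0, 1.0], [3.3, 1.2], [2.9, 0.9]])]
    out.append((from_groups(g, ["geno", "treat"],
                            [["WT", "KO"], ["SAL", "DRUG"]]),
                ("geno", "treat"), g, [2, 2]))

    # 5: 2 groups x 4 times, float values from a fixed stream
    rng = np.random.default_rng(42)
    g = [np.round(rng.lognormal(0, 0.4, (5, 4)), 6),
         np.round(rng.lognormal(0.2, 0.4, (4, 4)), 6)]
    out.append((from_groups(g, ["group"], [["A", "B"]]), ("group",), g, [2]))
    return out
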