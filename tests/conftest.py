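import numpy as np
import pandas as pd
import pytest

from metamed.simulate import RawPlateMatrix


def plates_from_blocks(blocks, met_names):
    """Assemble a RawPlateMatrix from explicit per-plate arrays.

    ``blocks``: iterable of (plate_id, zeros, refs, samples, nd) where
    zeros/refs/samples are 2-D arrays (rows x metabolites) and nd is a
    boolean array matching samples (or None). ND sample cells are NaN'd.
    """
    frames, nd_frames = [], []
    pid = 0
    for plate_id, zeros, refs, samples, nd in blocks:
        zeros = np.atleast_2d(np.asarray(zeros, dtype=float))
        refs = np.atleast_2d(np.asarray(refs, dtype=float))
        samples = np.atleast_2d(np.asarray(samples, dtype=float))
        if nd is None:
            nd = np.zeros(samples.shape, dtype=bool)
        nd = np.asarray(nd, dtype=bool)
        samples = samples.copy()
        samples[nd] = np.nan
        vals = np.vstack([zeros, refs, samples])
        block = pd.DataFrame(vals, columns=met_names)
        pids = [""] * (len(zeros) + len(refs)) + [
            f"P{pid + i + 1:05d}" for i in range(len(samples))
        ]
        pid += len(samples)
        block.insert(0, "participant_id", pids)
        block.insert(0, "role", ["zero"] * len(zeros) + ["reference"] * len(refs) + ["sample"] * len(samples))
        block.insert(0, "plate", plate_id)
        frames.append(block)
        nd_frames.append(
            np.vstack([np.zeros((len(zeros) + len(refs), len(met_names)), bool), nd])
        )
    data = pd.concat(frames, ignore_index=True)
    nondetect = pd.DataFrame(np.vstack(nd_frames), columns=met_names)
    return RawPlateMatrix(data=data, nondetect=nondetect)


@pytest.fixture
def make_plates():
    return plates_from_blocks


def printed_exclusion_roster_config(seed=11):
    """Simulation settings planting the published participant-class counts."""
    from metamed.simulate import SimulationConfig

    return SimulationConfig(
        n_participants=2216,
        n_metabolites=5,
        n_plates=2,
        seed=seed,
        class_counts={
            "underweight_missing": 23,
            "prediabetes": 390,
            "T1D": 6,
            "unclear": 82,
        },
    )
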