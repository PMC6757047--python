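import numpy as np
import pandas as pd
import pytest

import semioprofile as sp
import semioprofile.synthdata as sd


@pytest.fixture(scope="session")
def small_cfg():
    """6 females x 2 cycles, 40 animal samples, 4 blanks."""
    return sd.DesignConfig(
        n_females=6,
        cycles_per_female=(2,) * 6,
        state_quotas={"follicular": 12, "peri-ovulatory": 16, "luteal": 12},
        n_handling_blanks=2,
        n_air_blanks=2,
        n_parous=3,
    )


@pytest.fixture(scope="session")
def small_spec():
    """40 substances (8 cycle / 5 age / 5 parity planted) + 4 contaminants."""
    return sp.EffectSpec.random(
        n_substances=40,
        n_contaminants=4,
        n_cycle=8,
        n_age=5,
        n_parity=5,
        effect_size=1.2,
        seed=3,
    )


@pytest.fixture(scope="session")
def small_study(small_cfg, small_spec):
    design, peaklists, truth = sp.simulate_study(small_cfg, small_spec, seed=3)
    return design, peaklists, truth


@pytest.fixture(scope="session")
def aligned(small_study):
    _, peaklists, _ = small_study
    return sp.align_peak_lists(peaklists, min_occurrence=5)


@pytest.fixture(scope="session")
def rel_table(small_study, small_spec, aligned):
    design, _, _ = small_study
    return sp.preprocess(
        aligned, small_spec.contaminant_table(), list(design.blanks["sample_id"])
    )


def make_table(areas: pd.DataFrame, rts=None, mzs=None) -> sp.AlignedTable:
    """Hand-built AlignedTable from a raw area matrix (for filter tests)."""
    cols = list(areas.columns)
    ranges = pd.DataFrame(
        {
            "range_id": cols,
            "rt_low": rts if rts is not None else np.arange(len(cols), dtype=float),
            "rt_high": rts if rts is not None else np.arange(len(cols), dtype=float),
            "representative_rt": rts if rts is not None else np.arange(len(cols), dtype=float),
            "occurrence": areas.gt(0).sum().to_numpy(),
            "prominent_mz": mzs if mzs is not None else ["50"] * len(cols),
            "verified": True,
        }
    )
    return sp.AlignedTable(areas=areas, ranges=ranges)
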