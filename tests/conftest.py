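import numpy as np
import pandas as pd
import pytest

from thymoflux import FluxTraceSet, InjectionSchedule, assign_phases

#: suite-wide base seed for stochastic checks
SEED = 20260927 % 2**31


@pytest.fixture
def schedule() -> InjectionSchedule:
    return InjectionSchedule.default(3)


def make_trace(
    well: str,
    group: str,
    phase_ocr: tuple[float, float, float, float],
    ecar_baseline: float = 30.0,
    measurements_per_phase: int = 3,
) -> pd.DataFrame:
    """Piecewise-constant single-well trace: one OCR level per phase."""
    m = measurements_per_phase
    ocr = np.repeat(phase_ocr, m)
    n = 4 * m
    return pd.DataFrame(
        {
            "well": well,
            "group": group,
            "experiment": "e1",
            "measurement": np.arange(1, n + 1),
            "time_min": np.arange(n) * 6.5,
            "ocr": ocr,
            "ecar": np.full(n, float(ecar_baseline)),
        }
    )


def make_plate(wells: dict[str, tuple[str, tuple[float, float, float, float]]]) -> FluxTraceSet:
    """Plate from {well: (group, phase OCR levels)} with default schedule."""
    df = pd.concat(
        [make_trace(w, grp, levels) for w, (grp, levels) in wells.items()],
        ignore_index=True,
    )
    ts = FluxTraceSet(data=df, cell_counts={w: 1000 for w in wells})
    return assign_phases(ts, InjectionSchedule.default(3))
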