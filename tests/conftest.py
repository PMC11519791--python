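import numpy as np
import pytest

from atriamap import Region, RestitutionParams, TissueSpec

FRAME_PERIOD_MS = 1000.0 / 900.0  # 900 Hz acquisition


@pytest.fixture
def frame_period() -> float:
    return FRAME_PERIOD_MS


def uniform_tissue(
    rows: int = 8,
    cols: int = 8,
    params: RestitutionParams | None = None,
    **kw,
) -> TissueSpec:
    """Single-region tissue covering the whole grid."""
    params = params or RestitutionParams()
    mask = np.ones((rows, cols), dtype=bool)
    return TissueSpec(
        grid_rows=rows, grid_cols=cols,
        regions=(Region(mask=mask, params=params,
                        amp_from_di=kw.pop("amp_from_di", False),
                        amp_alternans=kw.pop("amp_alternans", 0.0)),),
        **kw,
    )


#: fast-kinetics parameters where every beat fully recovers between stimuli
#: at moderate cycle lengths (clean amplitude/duration measurement)
FAST_CAT = RestitutionParams(
    apd_max=30.0, tau_rest=10.0, cat_decay_tau=0.008,
    cat_amp_tau_refr=60.0, rise_time=10.0, cat90_offset=5.0,
)
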