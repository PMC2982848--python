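import numpy as np
import pytest

from luxtrace import photometry as ph
from luxtrace.synthetic import (
    CellPhenotype,
    ImagingModel,
    make_scene,
    render_stack,
)


def steady_phenotype(rate: float) -> CellPhenotype:
    """A cell emitting at a constant true rate (no onset, no fluctuation)."""
    return CellPhenotype(amplitude=rate, onset_center=0.0, onset_width=1.0,
                         init_level=rate, fluct_sd=0.0, fluct_tau=1.0)


@pytest.fixture(scope="session")
def small_run():
    """10 steady cells at known rates, 3 rendered frame pairs."""
    rates = np.linspace(30, 300, 10)
    imaging = ImagingModel(frame_shape=(320, 320))
    scene = make_scene(10, imaging, [steady_phenotype(r) for r in rates], seed=21)
    rate_matrix = np.tile(rates[:, None], (1, 3))
    dark, lum = render_stack(scene, rate_matrix, seed=21)
    dark_frames = [ph.Frame(d, "darkfield", 0.1, 10.0 * j) for j, d in enumerate(dark)]
    lum_frames = [ph.Frame(l, "luminescence", imaging.exposure, 10.0 * j)
                  for j, l in enumerate(lum)]
    return {"scene": scene, "rates": rates, "dark": dark_frames, "lum": lum_frames,
            "imaging": imaging}


@pytest.fixture(scope="session")
def empty_frames():
    """Pure-background luminescence frames at the default imaging model."""
    imaging = ImagingModel(frame_shape=(192, 192))
    scene = make_scene(0, imaging, [], seed=5)
    _, lum = render_stack(scene, np.zeros((0, 15)), seed=5)
    frames = [ph.Frame(l, "luminescence", imaging.exposure, 10.0 * j)
              for j, l in enumerate(lum)]
    return {"imaging": imaging, "frames": frames}
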