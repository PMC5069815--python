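import numpy as np
import pandas as pd
import pytest

import hccscreen as h
from hccscreen.simulate import OpticsConfig, render_field


@pytest.fixture(scope="session")
def populations():
    return h.default_populations()


@pytest.fixture(scope="session")
def library():
    return h.default_drug_library()


def make_field(n_cells: int, seed: int = 0, size: int = 512,
               optics: OpticsConfig | None = None,
               hcc_frac: float = 0.0):
    """Render one field of non-overlapping cells with known ground truth.

    Returns (cells_truth_df, images_dict) where the truth carries centroids,
    radii and the sampled marker intensities.
    """
    from hccscreen.simulate import _place_cells

    optics = optics or OpticsConfig(field_size_px=size)
    rng = np.random.default_rng(seed)
    pops = h.default_populations()
    n_hcc = int(round(hcc_frac * n_cells))
    names = np.array(["Huh7"] * n_hcc + ["Fa2N-4"] * (n_cells - n_hcc))
    pos = _place_cells(n_cells, size, min_sep=1.2 * 12, margin=12, rng=rng)
    cells = pd.DataFrame({"field": 0, "population": names,
                          "row": pos[:, 0], "col": pos[:, 1]})
    radii = np.empty(n_cells)
    hoechst = np.empty(n_cells)
    markers = {"chalv1": np.empty(n_cells), "afp": np.empty(n_cells)}
    for i, name in enumerate(names):
        p = pops[name]
        radii[i] = max(2.0, rng.normal(p.nucleus_radius_mean_px,
                                       p.nucleus_radius_sd_px))
        hoechst[i] = optics.hoechst.sample(rng, 1)[0]
        for m in markers:
            markers[m][i] = p.marker_intensity[m].sample(rng, 1)[0]
    cells["radius_px"] = radii
    cells["hoechst"] = hoechst
    for m, v in markers.items():
        cells[m] = v
    images = render_field(cells, optics, rng)
    return cells, images
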