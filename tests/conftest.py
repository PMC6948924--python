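import numpy as np
import pandas as pd
import pytest

from tilt3d.prior_estimation import TiltPrior, posterior_choice_probs
from tilt3d.stimulus_geometry import SurfacePose, ViewingGeometry


@pytest.fixture(scope="session")
def geom():
    return ViewingGeometry()


@pytest.fixture(scope="session")
def slant60_pose():
    """The largest tested slant at the fixation distance."""
    return SurfacePose(tilt=270.0, slant=60.0, distance=57.0)


def make_choice_table(prior: TiltPrior, kappas, n_per_condition, seed) -> pd.DataFrame:
    """Choice-proportion table sampled from the posterior model itself.

    One condition per (tilt, κ_L) pair; observed proportions are multinomial
    draws at the exact posterior bin masses.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for kl in kappas:
        for tilt in np.arange(0.0, 360.0, 45.0):
            p = posterior_choice_probs(tilt, kl, prior, method="exact")
            counts = rng.multinomial(n_per_condition, p)
            row = {"tilt": tilt, "n": n_per_condition}
            row.update(
                {f"p{int(c)}": counts[j] / n_per_condition
                 for j, c in enumerate(np.arange(0, 360, 45))}
            )
            rows.append(row)
    return pd.DataFrame(rows)
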