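import numpy as np
import pytest

from smtpipe.render import MovieSpec, render_movie
from smtpipe.simulate import ModeParams, PopulationSpec, simulate_population


@pytest.fixture(scope="session")
def field_movie():
    """A short movie at the study's labeling density with ground truth.

    131 Brownian emitters over a 25.6 × 25.6 µm field (0.2 spots/µm²),
    30 frames, no bleaching.
    """
    spec = PopulationSpec(
        fractions={"brownian": 1.0},
        mode_params={"brownian": ModeParams("brownian", 0.15)},
        n_traj=131,
        n_frames=30,
        sigma_log=0.3,
        seed=901,
        field_size=25.6,
    )
    trajs = simulate_population(spec)
    mspec = MovieSpec()
    stack, truth = render_movie(trajs, mspec, seed=902)
    return {"stack": stack, "truth": truth, "movie_spec": mspec,
            "trajectories": trajs, "pop_spec": spec}
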