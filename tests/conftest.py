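import numpy as np
import pytest
from hypothesis import settings

import seedshadow as ss
from seedshadow.synthetic import _stack_standardization

settings.register_profile("ci", deadline=None, derandomize=True,
                          max_examples=50)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def stack_truth():
    """Default synthetic landscape (3 x 3 km at 10 m) with ground truth."""
    return ss.gen_landscape(ss.SyntheticLandscapeConfig(seed=11))


@pytest.fixture(scope="session")
def stack(stack_truth):
    return stack_truth[0]


@pytest.fixture(scope="session")
def stack_std(stack):
    return _stack_standardization(stack)


@pytest.fixture(scope="session")
def tentative():
    return ss.TentativeKernel(2.0, 0.01, 0.0, 0.5)


@pytest.fixture(scope="session")
def tracks_truth(stack):
    cfg = ss.SyntheticTrackConfig(true_beta={"canopy_height": 0.3},
                                  n_animals=2, n_steps=400, seed=21)
    return ss.gen_tracks(cfg, stack)


@pytest.fixture(scope="session")
def strata_std(tracks_truth, stack, tentative):
    """Standardised strata for one synthetic animal (fitted tentative)."""
    fixes, truth = tracks_truth
    rs = ss.resample_track(fixes)
    steps = ss.steps_from_fixes(rs[rs.animal_id == "synth00"])
    tk = ss.fit_tentative(steps)
    strata = ss.build_strata(rs[rs.animal_id == "synth00"], 10, tk, stack,
                             rng_seed=31)
    out, _ = ss.standardize_covariates(
        strata, ("canopy_height", "vci", "dist_gap_small", "dist_gap_large"),
        fixed_params=truth["standardization"])
    return out


def flood_fill_regions(mask: np.ndarray) -> list[set]:
    """Brute-force 4-connected regions of a boolean mask (test oracle)."""
    seen = np.zeros_like(mask, dtype=bool)
    regions = []
    nr, nc = mask.shape
    for r0 in range(nr):
        for c0 in range(nc):
            if mask[r0, c0] and not seen[r0, c0]:
                stack_ = [(r0, c0)]
                region = set()
                seen[r0, c0] = True
                while stack_:
                    r, c = stack_.pop()
                    region.add((r, c))
                    for dr, dc in ((1, 0), (-1, 0), (0, 1), (0, -1)):
                        rr, cc = r + dr, c + dc
                        if (0 <= rr < nr and 0 <= cc < nc and mask[rr, cc]
                                and not seen[rr, cc]):
                            seen[rr, cc] = True
                            stack_.append((rr, cc))
                regions.append(region)
    return regions
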