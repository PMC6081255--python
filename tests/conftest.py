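import numpy as np
import pytest

import plaque_radiomics as pr


@pytest.fixture(scope="session")
def small_cohort():
    """A small but non-trivial cohort for pipeline-level tests."""
    spec = pr.CohortSpec(n_symptomatic=20, n_asymptomatic=12, seed=11)
    return pr.generate_cohort(spec)


@pytest.fixture(scope="session")
def small_table(small_cohort):
    return pr.build_feature_table(small_cohort)


@pytest.fixture(scope="session")
def large_cohort():
    """n = 200 per group: used for distributional checks on the generator."""
    spec = pr.CohortSpec(n_symptomatic=200, n_asymptomatic=200, seed=13)
    return pr.generate_cohort(spec)


def random_discretised(rng, max_side=8, max_bins=6):
    """Random small labelled ROI with at least one co-occurring pair."""
    from plaque_radiomics.features import DiscretisedRoi

    while True:
        nrow = int(rng.integers(2, max_side + 1))
        ncol = int(rng.integers(2, max_side + 1))
        n_bins = int(rng.integers(2, max_bins + 1))
        mask = rng.random((nrow, ncol)) < 0.7
        if mask.sum() < 2:
            continue
        grid = np.where(mask, rng.integers(1, n_bins + 1, size=(nrow, ncol)), 0)
        # Need one adjacent in-mask pair for the GLCM to be defined.
        ok = False
        for dr, dc in ((0, 1), (-1, 1), (-1, 0), (-1, -1)):
            a = np.zeros_like(mask)
            rs = slice(max(0, -dr), min(nrow, nrow - dr))
            cs = slice(max(0, -dc), min(ncol, ncol - dc))
            if mask[rs, cs].any():
                sub = mask[rs, cs] & mask[
                    slice(rs.start + dr, rs.stop + dr), slice(cs.start + dc, cs.stop + dc)
                ]
                if sub.any():
                    ok = True
                    break
        if ok:
            return DiscretisedRoi(
                grid=grid.astype(np.int32),
                mask=mask,
                n_bins=n_bins,
                bin_edges=np.arange(n_bins + 1, dtype=float),
            )
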