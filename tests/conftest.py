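import numpy as np
import pandas as pd
import pytest

from rhizotrace.geometry import TubeGeometry
from rhizotrace.root_traits import RootProfile


@pytest.fixture(scope="session")
def geom() -> TubeGeometry:
    return TubeGeometry()


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


def random_profile(rng: np.random.Generator, geom: TubeGeometry, scale: float = 1.0) -> RootProfile:
    """A random non-negative root profile on the full image grid."""
    depths = geom.image_depths_m()
    lengths = scale * rng.gamma(shape=1.5, scale=0.8, size=depths.size)
    return RootProfile("R1", "s", depths, lengths)


def logistic_profile(
    geom: TubeGeometry, A: float = 2.0, k: float = 0.05, m_cm: float = 120.0
) -> RootProfile:
    depths = geom.image_depths_m()
    y = A / (1.0 + np.exp(k * (depths * 100.0 - m_cm)))
    return RootProfile("R1", "s", depths, y)


def observations_frame(profile: RootProfile, geom: TubeGeometry, genotype="G01") -> pd.DataFrame:
    """Long-format observation rows matching the input schema."""
    from rhizotrace.geometry import position_at_depth

    return pd.DataFrame(
        {
            "row_id": profile.row_id,
            "genotype": genotype,
            "session": profile.session,
            "position_mm": position_at_depth(profile.depths_m, geom),
            "root_length_cm": profile.lengths_cm,
        }
    )
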