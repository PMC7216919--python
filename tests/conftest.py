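import numpy as np
import pytest

from scifidose import (
    DetectorGeometry,
    DiskGrid,
    PipelineConfig,
    build_system_matrix,
    default_cone_suite,
    default_half_profile_grid,
    run_pipeline,
)


def abel_projection(radial_fn, x, z_max=30.0, dz=0.01):
    """Numeric line-projection oracle for a radially symmetric 2D function.

    p(x) = integral of f(sqrt(x^2 + z^2)) over z, computed by dense trapezoid
    quadrature; independent of the package's projection code path.
    """
    x = np.atleast_1d(np.asarray(x, dtype=float))
    z = np.arange(0.0, z_max, dz)
    vals = radial_fn(np.hypot(x[:, None], z[None, :]))
    return 2.0 * np.trapezoid(vals, z, axis=1)


@pytest.fixture(scope="session")
def geometry():
    return DetectorGeometry()


@pytest.fixture(scope="session")
def default_system():
    """System matrix on the default measurement and disk grids (123 x 122)."""
    return build_system_matrix(default_half_profile_grid(), DiskGrid.default())


@pytest.fixture(scope="session")
def suite_report():
    """Full noiseless pipeline run over the seven-cone suite (shared)."""
    suite = default_cone_suite()
    report = run_pipeline(PipelineConfig(), suite)
    return suite, report
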