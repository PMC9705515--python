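import numpy as np
import pytest

from t1calib.models import CalibrationPair, PhantomScan, PhantomTube
from t1calib.reference import REFERENCE_CORRECTIONS


@pytest.fixture
def fn_a_native():
    return REFERENCE_CORRECTIONS[("A", "native")]


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


def make_phantom_scan(
    institution_id="A",
    contrast_state="native",
    tubes_gt=(250.0, 500.0, 800.0, 1100.0, 1500.0, 2000.0),
    gs_offset=0.0,
    ml_fn=None,
    rris=(600.0, 900.0, 1200.0),
):
    """Deterministic phantom scan; ml_fn maps (gt, rri) -> MOLLI T1."""
    if ml_fn is None:
        ml_fn = lambda gt, rri: gt  # identity scanner
    tubes = [
        PhantomTube(
            tube_id=f"T{i + 1}",
            t1_gt=gt,
            t1_gs=gt + gs_offset,
            t1_ml_by_rri={rri: ml_fn(gt, rri) for rri in rris},
        )
        for i, gt in enumerate(tubes_gt)
    ]
    return PhantomScan(
        institution_id=institution_id, contrast_state=contrast_state, tubes=tubes
    )


def pairs_from(points):
    return [CalibrationPair(s, t) for s, t in points]
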