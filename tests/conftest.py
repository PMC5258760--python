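import numpy as np
import pytest

from mirqtl.io_formats import CountMatrix, LibraryMeta, MarkerMap


@pytest.fixture
def tiny_meta():
    """Two libraries: one control/heat pair for GXN at 6 h."""
    return {
        "GXN-6hC": LibraryMeta("GXN", "control", 6),
        "GXN-6hT": LibraryMeta("GXN", "heat", 6),
    }


@pytest.fixture
def tiny_counts(tiny_meta):
    return CountMatrix(
        mirna_ids=["mir-a", "mir-b"],
        library_ids=["GXN-6hC", "GXN-6hT"],
        counts=np.array([[10, 0], [3, 7]], dtype=np.int64),
        library_meta=tiny_meta,
    )


@pytest.fixture
def four_marker_map():
    """One chromosome, markers at 0/1/2/3 Mb, chromosome end at 3 Mb."""
    return MarkerMap(
        marker_ids=["m1", "m2", "m3", "m4"],
        chromosomes=["1"] * 4,
        positions_mb=np.array([0.0, 1.0, 2.0, 3.0]),
        chromosome_end={"1": 3.0},
    )
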