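import numpy as np
import pytest
from hypothesis import settings

from mu8.aaindex import AAINDEX_RESIDUE_ORDER, IndexScale
from mu8.alignment import Alignment, crop_to_reference

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

# A handcrafted AAindex1 record: I rows are 0.1..1.0 / 1.1..2.0 in the
# canonical residue order, so value(A)=0.1 and value(V)=2.0.
RAMP_RECORD = """H TEST0001
D handcrafted ramp scale
R PMID:0000000
A Nobody, A.
T A ramp for parser tests
J Nowhere (2024)
C TEST0002    0.999
I    A/L     R/K     N/M     D/F     C/P     Q/S     E/T     G/W     H/Y     I/V
     0.1     0.2     0.3     0.4     0.5     0.6     0.7     0.8     0.9     1.0
     1.1     1.2     1.3     1.4     1.5     1.6     1.7     1.8     1.9     2.0
//
"""

NA_RECORD = """H TEST0002
D record with a missing proline value
I    A/L     R/K     N/M     D/F     C/P     Q/S     E/T     G/W     H/Y     I/V
     0.1     0.2     0.3     0.4     0.5     0.6     0.7     0.8     0.9     1.0
     1.1     1.2     1.3     1.4      NA     1.6     1.7     1.8     1.9     2.0
//
"""


def make_scale(values, accession="SC", char_class="other"):
    """IndexScale from a vector in canonical residue order."""
    return IndexScale(
        accession=accession,
        description="test scale",
        values={aa: float(v) for aa, v in zip(AAINDEX_RESIDUE_ORDER, values)},
        char_class=char_class,
    )


@pytest.fixture
def ramp_scale():
    return make_scale(np.arange(1, 21, dtype=float))


@pytest.fixture
def toy_alignment():
    """Reference 'A-CD' with two family rows; cropping keeps columns 0, 2, 3."""
    return Alignment(
        records=(("REF", "A-CD"), ("F1", "AXCD"), ("F2", "-YC-")),
        reference_id="REF",
    )


@pytest.fixture
def toy_cropped(toy_alignment):
    return crop_to_reference(toy_alignment)
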