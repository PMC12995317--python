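"""Built-in example models.

``three_party_model`` is the worked three-group questionnaire example: an
extremist party, a moderate mainstream party and the politically
disengaged remainder, coupled by

    J = [[ 0.7, -0.2,  0.2],
         [-0.2,  0.6,  0.1],
         [ 0.2,  0.1,  0.5]]

(high temperature; the extremist group has the strongest internal cohesion
and hence the largest limiting within-group correlation, which is what the
detection algorithm peels off first).

``polarised_pair_model`` is a low-temperature two-group model with strong
internal cohesion and a weak *antagonistic* cross-group coupling; its two
ordered phases are anti-aligned, the groups have distinct Z-vectors and
the model is identifiable (gamma > 0).  The same magnitudes with a
*positive* cross-coupling produce aligned phases with identical Z-vectors
— a standard example of a non-identifiable low-temperature model.
"""

from __future__ import annotations

import numpy as np

from .model import BlockSpinModel, build_model

__all__ = [
    "THREE_PARTY_J",
    "three_party_model",
    "polarised_pair_model",
    "aligned_pair_model",
]

THREE_PARTY_J = np.array(
    [
        [0.7, -0.2, 0.2],
        [-0.2, 0.6, 0.1],
        [0.2, 0.1, 0.5],
    ]
)


def three_party_model(sizes=(40, 30, 30)) -> BlockSpinModel:
    """The three-party questionnaire model (high temperature)."""
    return build_model(sizes, THREE_PARTY_J)


def polarised_pair_model(sizes=(10, 10), within: float = 1.5, cross: float = -0.1) -> BlockSpinModel:
    """Two antagonistic cohesive groups (low temperature, identifiable)."""
    J = np.array([[within, cross], [cross, within]])
    return build_model(sizes, J)


def aligned_pair_model(sizes=(10, 10), within: float = 1.5, cross: float = 0.1) -> BlockSpinModel:
    """Two cohesive groups with weak positive cross-coupling.

    Low temperature but *not identifiable*: both ordered phases magnetise
    the groups identically, so the groups share one Z-vector and all pair
    correlations converge to a common limit.
    """
    J = np.array([[within, cross], [cross, within]])
    return build_model(sizes, J)
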