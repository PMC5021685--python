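"""Shared helpers for the test suite."""

import numpy as np

from qconvert.metrics import TensorFit


def fit_from_eigenvalues(ev):
    """A TensorFit carrying only eigenvalues, for scalar-metric tests."""
    ev = np.asarray(ev, dtype=float)
    shape = ev.shape[:-1]
    return TensorFit(
        tensors=np.zeros(shape + (3, 3)),
        eigenvalues=ev,
        eigenvectors=np.broadcast_to(np.eye(3), shape + (3, 3)).copy(),
        S0=np.ones(shape),
        valid=np.ones(shape, dtype=bool),
    )
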