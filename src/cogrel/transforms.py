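"""Latent <-> bounded parameter transforms.

Hierarchical models in this package place group and subject-level
distributions on an unbounded latent (z) scale and map draws to each
parameter's native bounded scale with a probit transform,

    x = lo + (hi - lo) * Phi(z),

where Phi is the standard-normal CDF. The synthetic-data generator and the
fitting routines share these functions, so a population specified on the
latent scale is exactly the population the fitter assumes.
"""

from __future__ import annotations

import numpy as np
from scipy.special import ndtr, ndtri

__all__ = ["to_native", "to_latent"]


def to_native(z, lo, hi):
    """Map unbounded latent values to the bounded native scale.

    Parameters
    ----------
    z : array-like
        Latent values.
    lo, hi : float or array-like
        Parameter bounds, broadcast against ``z``.
    """
    z = np.asarray(z, dtype=float)
    return lo + (hi - lo) * ndtr(z)


def to_latent(x, lo, hi, eps=1e-12):
    """Inverse of :func:`to_native`; clips to the open interval first."""
    x = np.asarray(x, dtype=float)
    u = (x - lo) / (hi - lo)
    u = np.clip(u, eps, 1.0 - eps)
    return ndtri(u)
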