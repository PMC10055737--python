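"""Expression-tensor normalizations.

Two corrections are applied to the raw ISH intensity tensor before
deconvolution: a per-bin median scaling that removes bin-to-bin
labelling differences, and a depth rescaling that forces the mean
expression profile to follow the cell-density profile measured on
Nissl slices.
"""

from __future__ import annotations

import logging

import numpy as np

from .types import DensityMap, ExpressionTensor

logger = logging.getLogger(__name__)


def median_normalize(E: ExpressionTensor) -> ExpressionTensor:
    """Divide each (depth, area) bin by its median non-zero gene value.

    After normalization the non-zero median of every touched bin is
    exactly 1.  Bins that are entirely zero (or whose non-zero median
    is zero) are left unchanged and logged.  The operation is
    idempotent and keeps zeros at zero.
    """
    values = E.values.copy()
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN bins are expected
        masked = np.where(values > 0, values, np.nan)
        med = np.nanmedian(masked, axis=0)  # (depth, area)
    untouched = ~np.isfinite(med) | (med == 0)
    if untouched.any():
        logger.info("median_normalize: %d bins left unchanged (no non-zero median)",
                    int(untouched.sum()))
    med = np.where(untouched, 1.0, med)
    values /= med[None, :, :]
    return ExpressionTensor(values=values, gene_ids=list(E.gene_ids), bins=E.bins)


def depth_rescale(E: ExpressionTensor, nissl: DensityMap) -> ExpressionTensor:
    """Rescale each depth bin so the mean profile follows the Nissl shape.

    With ``m(j)`` the mean of E over genes and area bins at depth j and
    ``n(j)`` the Nissl density profile (summed over area bins), every
    value at depth j is multiplied by ``s(j) = c * n(j) / m(j)``, the
    constant c chosen so the global mean of E is unchanged.  Depth bins
    with ``m(j) = 0`` get ``s(j) = 0`` and a log entry; an all-zero
    mean profile is an error.
    """
    if nissl.bins.n_depth_bins != E.bins.n_depth_bins:
        raise ValueError("expression tensor and Nissl map use different depth binning")
    m = E.values.mean(axis=(0, 2))
    if not m.any():
        raise ValueError("depth_rescale: mean expression profile is all zero")
    n = nissl.depth_profile()

    s = np.zeros_like(m)
    nonzero = m > 0
    s[nonzero] = n[nonzero] / m[nonzero]
    dead = ~nonzero
    if dead.any():
        logger.info("depth_rescale: %d depth bins have zero mean expression", int(dead.sum()))

    scaled = E.values * s[None, :, None]
    scaled_mean = scaled.mean()
    c = E.values.mean() / scaled_mean if scaled_mean > 0 else 1.0
    return ExpressionTensor(values=c * scaled, gene_ids=list(E.gene_ids), bins=E.bins)
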