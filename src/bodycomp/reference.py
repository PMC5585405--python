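"""Naive reference implementation of the ILT filter.

Deliberately slow and literal: loops over every pixel and direction,
marching each ray sample-by-sample with hand-coded bilinear
interpolation (see :func:`bodycomp.ilt.accumulate_direction`), pooling
the smallest accumulations with a plain ``sorted``.  It shares no
array machinery with the vectorised production path in
:mod:`bodycomp.ilt` and exists to validate it.
"""

from __future__ import annotations

import math

import numpy as np

from .core import CTSlice
from .ilt import ILTParams, accumulate_direction, hu_to_lean_prob, ray_directions


def naive_ilt_response(ct: CTSlice, params: ILTParams) -> np.ndarray:
    """Per-pixel, per-direction ray-marching ILT response (normalised)."""
    prob = hu_to_lean_prob(ct.pixels, params.L1, params.L2)
    nrows, ncols = prob.shape
    step = params.step_mm if params.step_mm is not None else min(ct.spacing)
    dirs = ray_directions(params.n_dir)
    k = params.n_pooled
    response = np.zeros((nrows, ncols), dtype=np.float64)
    for r in range(nrows):
        for c in range(ncols):
            acc = [
                accumulate_direction(
                    prob,
                    (r, c),
                    (d[0], d[1]),
                    step,
                    ct.spacing,
                    max_range_mm=params.max_range_mm,
                    interp=params.interp,
                )
                for d in dirs
            ]
            response[r, c] = math.fsum(sorted(acc)[:k])
    peak = response.max()
    if peak > 0.0:
        response /= peak
    return response
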