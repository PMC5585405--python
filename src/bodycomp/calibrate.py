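"""Phantom-based calibration of the paper-silent thresholds.

The per-station pm_thresholds (and the morphological erosion depth) have
no published values; they are tuned here on seeded phantom training
ensembles — primarily for adipose-area agreement, secondarily for Dice —
mirroring how the original parameters were trained on held-out subjects.
The frozen results live in :mod:`bodycomp.config`.
"""

from __future__ import annotations

import numpy as np

from . import config as cfg
from .core import DEFAULT_BANDS, body_mask
from .ilt import ilt_response, inside_mask
from .metrics import overlap
from .phantom import (
    DEFAULT_ABDOMEN_JITTER,
    DEFAULT_THIGH_JITTER,
    AbdomenPhantomSpec,
    ThighPhantomSpec,
    make_ensemble,
)
from .thigh import segment_muscle_at, separate_thighs, sfat_imat_morph

__all__ = ["calibrate_abdomen_pm", "calibrate_thigh_pm", "calibrate_thigh_depth"]


def calibrate_abdomen_pm(
    thresholds=np.round(np.arange(0.01, 0.21, 0.01), 3),
    n: int = 10,
    seed: int = 0,
) -> tuple[float, dict[float, float]]:
    """Sweep the cavity threshold; score = mean of VAT and SAT Dice.

    The ILT response is computed once per phantom and re-thresholded, so
    the sweep is cheap.  Back AT is excluded from both sides of the Dice
    (its removal is calibrated separately via the atlas threshold).
    """
    ensemble = make_ensemble(AbdomenPhantomSpec(seed=seed), n, DEFAULT_ABDOMEN_JITTER, seed=seed)
    scores = {float(t): [] for t in thresholds}
    for p in ensemble:
        ct = p.slice
        body = body_mask(ct, DEFAULT_BANDS)
        response = ilt_response(ct, cfg.ABDOMEN_ILT.with_threshold(0.0), roi=body, support=body)
        adipose = DEFAULT_BANDS.adipose_mask(ct.pixels) & body & ~p.depot_mask("back_at")
        true_vat = p.depot_mask("vat")
        true_sat = p.depot_mask("sat")
        for t in thresholds:
            cavity = inside_mask(response, float(t), largest_component=True, fill_holes=True)
            vat = adipose & cavity
            sat = adipose & ~cavity
            scores[float(t)].append(
                0.5 * (overlap(vat, true_vat).dice + overlap(sat, true_sat).dice)
            )
    table = {t: float(np.mean(v)) for t, v in scores.items()}
    best = max(table, key=table.get)
    return best, table


def calibrate_thigh_pm(
    sat_thresholds=np.round(np.arange(0.005, 0.105, 0.005), 4),
    deep_thresholds=np.round(np.arange(0.05, 0.85, 0.05), 3),
    n: int = 5,
    seed: int = 0,
) -> tuple[float, float, dict]:
    """Sweep the SAT-pass and deep-pass thresholds; scores = SAT / IMAT Dice."""
    ensemble = make_ensemble(ThighPhantomSpec(seed=seed), n, DEFAULT_THIGH_JITTER, seed=seed)
    sat_scores = {float(t): [] for t in sat_thresholds}
    deep_scores = {float(t): [] for t in deep_thresholds}
    for p in ensemble:
        ct = p.slice
        left, right = separate_thighs(ct)
        for side, mask in (("left", left), ("right", right)):
            _, adipose, _ = segment_muscle_at(mask, ct)
            response = ilt_response(
                ct, cfg.THIGH_SAT_ILT.with_threshold(0.0), roi=mask, support=mask
            )
            true_sat = p.depot_mask("sat", side)
            true_imat = p.depot_mask("imat", side)
            true_inner = p.depot_mask("sfat", side) | true_imat
            for t in sat_thresholds:
                inside = inside_mask(response, float(t), largest_component=True, fill_holes=True)
                sat_scores[float(t)].append(overlap(adipose & ~inside, true_sat).dice)
            inner = adipose & true_inner  # isolate the deep-pass sweep from pass 1
            for t in deep_thresholds:
                deep = inside_mask(response, float(t), largest_component=True, fill_holes=True)
                deep_scores[float(t)].append(overlap(inner & deep, true_imat).dice)
    sat_table = {t: float(np.mean(v)) for t, v in sat_scores.items()}
    deep_table = {t: float(np.mean(v)) for t, v in deep_scores.items()}
    return (
        max(sat_table, key=sat_table.get),
        max(deep_table, key=deep_table.get),
        {"sat": sat_table, "deep": deep_table},
    )


def calibrate_thigh_depth(
    depths=np.round(np.arange(4.0, 10.5, 0.5), 2),
    n: int = 5,
    seed: int = 0,
) -> tuple[float, dict[float, float]]:
    """Sweep the morphological erosion depth; score = mean of SFAT and IMAT Dice."""
    ensemble = make_ensemble(ThighPhantomSpec(seed=seed), n, DEFAULT_THIGH_JITTER, seed=seed)
    scores = {float(d): [] for d in depths}
    for p in ensemble:
        ct = p.slice
        left, right = separate_thighs(ct)
        for side, mask in (("left", left), ("right", right)):
            muscle, adipose, _ = segment_muscle_at(mask, ct)
            true_sfat = p.depot_mask("sfat", side)
            true_imat = p.depot_mask("imat", side)
            inner = adipose & (true_sfat | true_imat)
            for d in depths:
                sfat, imat = sfat_imat_morph(inner, muscle, float(d), ct.spacing)
                scores[float(d)].append(
                    0.5 * (overlap(sfat, true_sfat).dice + overlap(imat, true_imat).dice)
                )
    table = {d: float(np.mean(v)) for d, v in scores.items()}
    best = max(table, key=table.get)
    return best, table
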