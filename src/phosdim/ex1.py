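"""Bimodal (EX1) exchange detection from isotopic-envelope time series.

Exchange in the EX2 regime shifts a single isotopic envelope gradually; in
the EX1 regime a whole segment exchanges in one cooperative opening event,
so the envelope is a two-component mixture whose heavy component grows with
time.  This module fits both descriptions — a single binomial deuteration
distribution and a two-binomial mixture, each convolved with the fixed
averagine natural envelope — and classifies a peptide as EX1 only when the
mixture is preferred reproducibly over time, the two modes are well
separated, and the light-population weight decays monotonically (one-way
population transfer).  The classifier is an independent re-implementation in
the spirit of the bimodal deconvolution tools used for this purpose.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
from scipy import optimize

from .envelopes import IsotopicEnvelope, binomial_envelope, convolve, natural_envelope
from .synthetic import Peptide

_RSS_FLOOR = 1e-12  # numerical floor so noiseless fits do not degenerate


@dataclass(frozen=True)
class Ex1Config:
    """Classifier settings.

    ``penalty`` is the per-parameter information-criterion penalty (an AIC
    uses 2); ``min_separation`` is the minimum distance between the two
    deuteration modes, in Da, for a mixture to count as bimodal;
    ``min_consecutive`` is how many consecutive timepoints must prefer the
    mixture; ``w_tolerance`` is the slack allowed on the monotone decay of
    the light-population weight.
    """

    penalty: float = 2.0
    min_separation: float = 2.0  # Da
    min_consecutive: int = 2
    w_tolerance: float = 0.05
    min_weight: float = 0.02  # mixture weights closer than this to 0/1 are unimodal


@dataclass
class BimodalFit:
    """Single- and two-mode least-squares fits of one envelope."""

    p_single: float
    loss_single: float
    p_low: float
    p_high: float
    w_low: float
    loss_two: float
    n_exchangeable: int
    score: float  # IC(single) - IC(mixture); > 0 prefers the mixture
    mode: Literal["single", "two", "ambiguous"]

    @property
    def separation(self) -> float:
        """Distance between the two deuteration modes in Da."""
        return (self.p_high - self.p_low) * self.n_exchangeable


def _predict(natural: np.ndarray, n: int, p: float, size: int) -> np.ndarray:
    env = convolve(natural, binomial_envelope(n, p))
    if env.size < size:
        env = np.pad(env, (0, size - env.size))
    return env[:size]


def _predict_mix(
    natural: np.ndarray, n: int, p_lo: float, p_hi: float, w: float, size: int
) -> np.ndarray:
    lo = _predict(natural, n, p_lo, size)
    hi = _predict(natural, n, p_hi, size)
    return w * lo + (1.0 - w) * hi


def fit_envelope(
    envelope: IsotopicEnvelope,
    n_exchangeable: int | None = None,
    config: Ex1Config = Ex1Config(),
) -> BimodalFit:
    """Fit single-binomial and two-binomial-mixture models to one envelope.

    Model selection uses the information criterion
    ``K * log(RSS/K) + penalty * k`` with k = 1 (single) or 3 (mixture)
    parameters.  A flat or degenerate envelope yields ``mode='ambiguous'``.
    """
    obs = envelope.intensities
    size = obs.size
    if size < 4:
        raise ValueError("need at least 4 isotope channels")
    pep = Peptide(envelope.start, envelope.end, envelope.peptide_sequence)
    n = pep.exchangeable_amides if n_exchangeable is None else n_exchangeable
    natural = natural_envelope(envelope.peptide_sequence)

    # degenerate: no usable shape
    if np.ptp(obs) < 1e-9:
        return BimodalFit(0.0, np.inf, 0.0, 0.0, 0.5, np.inf, n, 0.0, "ambiguous")

    def rss_single(p: float) -> float:
        return float(np.sum((obs - _predict(natural, n, p, size)) ** 2))

    grid = np.linspace(0.0, 1.0, 41)
    p0 = grid[int(np.argmin([rss_single(p) for p in grid]))]
    res1 = optimize.minimize_scalar(
        rss_single, bounds=(max(0.0, p0 - 0.05), min(1.0, p0 + 0.05)),
        method="bounded", options={"xatol": 1e-10},
    )
    p_single, rss1 = float(res1.x), float(res1.fun)

    def rss_two(params: np.ndarray) -> float:
        p_lo, p_hi, w = params
        return float(
            np.sum((obs - _predict_mix(natural, n, p_lo, p_hi, w, size)) ** 2)
        )

    starts = [
        (max(0.0, p_single - 0.3), min(1.0, p_single + 0.3), 0.5),
        (0.02, min(1.0, p_single + 0.5), 0.5),
        (max(0.0, p_single - 0.5), 0.95, 0.3),
        (0.05, 0.85, 0.7),
    ]
    best = None
    for s in starts:
        r = optimize.minimize(
            rss_two, np.asarray(s),
            bounds=[(0.0, 1.0), (0.0, 1.0), (0.0, 1.0)],
            method="L-BFGS-B",
        )
        if best is None or r.fun < best.fun:
            best = r
    p_lo, p_hi, w = best.x
    if p_lo > p_hi:  # canonical ordering
        p_lo, p_hi, w = p_hi, p_lo, 1.0 - w
    rss2 = float(best.fun)

    k_ch = float(size)
    ic1 = k_ch * np.log(max(rss1, _RSS_FLOOR) / k_ch) + config.penalty * 1
    ic2 = k_ch * np.log(max(rss2, _RSS_FLOOR) / k_ch) + config.penalty * 3
    score = float(ic1 - ic2)

    separation = (p_hi - p_lo) * n
    genuinely_bimodal = (
        score > 0
        and separation >= config.min_separation
        and config.min_weight <= w <= 1.0 - config.min_weight
    )
    mode = "two" if genuinely_bimodal else "single"
    return BimodalFit(
        p_single, rss1, float(p_lo), float(p_hi), float(w), rss2, n, score, mode
    )


def classify_kinetics(
    envelopes: Sequence[IsotopicEnvelope],
    n_exchangeable: int | None = None,
    config: Ex1Config = Ex1Config(),
) -> tuple[str, list[BimodalFit]]:
    """Classify a peptide's exchange regime from its envelope time series.

    Returns ``('EX1'|'EX2'|'ambiguous', fits)``.  EX1 requires the
    two-component mixture to be preferred at ``min_consecutive`` consecutive
    timepoints with mode separation at least ``min_separation`` Da and a
    light-population weight that never increases (beyond ``w_tolerance``)
    across those timepoints.  Undeuterated (exposure 0) envelopes are used
    as reference context but not classified.
    """
    series = sorted(envelopes, key=lambda e: e.exposure)
    labelled = [e for e in series if e.exposure > 0]
    if len(labelled) < 3:
        raise ValueError("need at least 3 labelled timepoints")
    fits = [fit_envelope(e, n_exchangeable, config) for e in labelled]
    if all(f.mode == "ambiguous" for f in fits):
        return "ambiguous", fits

    bimodal = [f.mode == "two" for f in fits]
    run = best_run = 0
    run_start = idx_start = 0
    for i, b in enumerate(bimodal):
        if b:
            run += 1
            if run == 1:
                run_start = i
            if run > best_run:
                best_run, idx_start = run, run_start
        else:
            run = 0
    if best_run < config.min_consecutive:
        return "EX2", fits

    ws = [fits[i].w_low for i in range(idx_start, idx_start + best_run)]
    monotone = all(w2 <= w1 + config.w_tolerance for w1, w2 in zip(ws, ws[1:]))
    return ("EX1" if monotone else "EX2"), fits
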