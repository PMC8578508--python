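"""Isotopic-envelope containers and distribution helpers.

Envelopes live on an integer isotope-index grid: channel ``k`` holds the
relative intensity of the species ``k`` mass units above the lightest
isotopologue.  For deuterium-uptake arithmetic the grid spacing is treated as
exactly 1 Da per channel, so envelope centroids and centroid-difference
uptake values share one unit without conversion constants.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .chem import AVERAGINE_NEUTRON_RATE, peptide_mass

_TAIL = 1e-12  # mass truncated from distribution tails


@dataclass
class IsotopicEnvelope:
    """Normalized isotope-index intensity profile for one peptide spectrum."""

    intensities: np.ndarray
    peptide_sequence: str
    start: int
    end: int
    exposure: float  # min
    replicate: int = 1
    state: str = ""

    def __post_init__(self):
        arr = np.asarray(self.intensities, dtype=float)
        if arr.ndim != 1 or arr.size < 1:
            raise ValueError("intensities must be a 1-D array")
        if np.any(arr < 0):
            raise ValueError("intensities must be non-negative")
        total = arr.sum()
        if not np.isclose(total, 1.0, atol=1e-9):
            if total <= 0:
                raise ValueError("envelope has zero total intensity")
            arr = arr / total
        self.intensities = arr

    @property
    def n_channels(self) -> int:
        return self.intensities.size

    def centroid(self) -> float:
        """Intensity-weighted mean isotope index (Da above the base channel)."""
        return float(np.dot(np.arange(self.n_channels), self.intensities))

    def rescaled(self, factor: float) -> "IsotopicEnvelope":
        """Same envelope with intensities multiplied by a positive constant
        (re-normalized on construction; classification must not change)."""
        return IsotopicEnvelope(
            self.intensities * factor,
            self.peptide_sequence,
            self.start,
            self.end,
            self.exposure,
            self.replicate,
            self.state,
        )


def poisson_envelope(lam: float) -> np.ndarray:
    """Poisson(+1 isotope) distribution truncated to negligible tail mass."""
    if lam < 0:
        raise ValueError("lambda must be >= 0")
    if lam == 0:
        return np.array([1.0])
    k_max = int(lam + 12 * np.sqrt(lam) + 15)
    k = np.arange(k_max + 1)
    pmf = stats.poisson.pmf(k, lam)
    pmf = pmf / pmf.sum()
    # drop trailing channels carrying < _TAIL mass
    keep = np.nonzero(pmf > _TAIL)[0]
    return pmf[: keep[-1] + 1] / pmf[: keep[-1] + 1].sum()


def natural_envelope(sequence: str) -> np.ndarray:
    """Averagine-style natural-abundance envelope for a peptide sequence.

    The number of one-neutron substitutions is modelled as Poisson with rate
    proportional to the monoisotopic mass (see
    :data:`phosdim.chem.AVERAGINE_NEUTRON_RATE`).
    """
    m = peptide_mass(sequence, average=False)
    return poisson_envelope(m * AVERAGINE_NEUTRON_RATE)


def binomial_envelope(n: int, p: float) -> np.ndarray:
    """Binomial(n, p) deuteration distribution on channels 0..n."""
    if n < 0:
        raise ValueError("n must be >= 0")
    if not 0.0 <= p <= 1.0:
        raise ValueError("p must be in [0, 1]")
    if n == 0:
        return np.array([1.0])
    return stats.binom.pmf(np.arange(n + 1), n, p)


def convolve(*dists: np.ndarray) -> np.ndarray:
    """Convolution of independent channel distributions."""
    out = np.array([1.0])
    for d in dists:
        out = np.convolve(out, np.asarray(d, dtype=float))
    return out / out.sum()
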