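"""Two-state Linderstrøm-Lang exchange simulator.

Generates everything the downstream analysis consumes — overlapping peptide
maps, replicated centroid-uptake tables, and isotopic-envelope time series —
from an explicit per-residue kinetic model, so the whole pipeline is testable
against known ground truth without any instrument data.

Model
-----
Each non-proline backbone amide ``j`` (the first residue of a peptide never
retains deuterium) exchanges with intrinsic rate ``k_int_j`` slowed by a
state-dependent protection factor ``P_j >= 1``:

    uptake_j(t) = (1 - b) * f_D * (1 - exp(-(k_int_j / P_j) * t))

EX1 segments open cooperatively and irreversibly with rate ``k_op``; their
residues exchange only via the opening event, which produces the
characteristic bimodal envelopes:

    uptake_seg(t) = (1 - b) * f_D * n_seg * (1 - exp(-k_op * t))

``f_D`` is the deuterium fraction of the labelling buffer and ``b`` the
back-exchange fraction.  Intrinsic rates are drawn from a seeded lognormal
around a configurable base rate — a deliberate simplification of the
sequence-dependent intrinsic-rate tables that is adequate for exercising the
analysis (documented in the methods note).
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .chem import peptide_mass
from .constructs import Construct
from .envelopes import IsotopicEnvelope, binomial_envelope, convolve, natural_envelope

UPTAKE_COLUMNS = [
    "Protein", "Start", "End", "Sequence", "State", "Exposure", "Replicate", "Center",
]


# ---------------------------------------------------------------------------
# Peptides
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Peptide:
    """A proteolytic peptide in construct numbering (1-based inclusive)."""

    start: int
    end: int
    sequence: str

    def __post_init__(self):
        if self.end - self.start + 1 != len(self.sequence):
            raise ValueError(
                f"peptide {self.start}-{self.end} length mismatch with sequence"
            )

    @property
    def key(self) -> tuple[int, int, str]:
        return (self.start, self.end, self.sequence)

    def exchanging_positions(self) -> list[int]:
        """Residue numbers that can retain deuterium: every position after
        the peptide's first residue, prolines excluded."""
        return [
            self.start + k
            for k in range(1, len(self.sequence))
            if self.sequence[k] != "P"
        ]

    @property
    def exchangeable_amides(self) -> int:
        return len(self.exchanging_positions())


@dataclass(frozen=True)
class PeptideMap:
    construct: Construct
    peptides: tuple[Peptide, ...]

    def __post_init__(self):
        lo, hi = self.construct.first_residue, self.construct.last_residue
        for p in self.peptides:
            if p.start < lo or p.end > hi:
                raise ValueError(f"peptide {p.start}-{p.end} outside construct")
            if self.construct.subsequence(p.start, p.end) != p.sequence:
                raise ValueError(f"peptide {p.start}-{p.end} sequence mismatch")
            if p.exchangeable_amides < 1:
                raise ValueError(f"peptide {p.start}-{p.end} has no exchangeable amide")
        object.__setattr__(self, "peptides", tuple(self.peptides))

    def __len__(self) -> int:
        return len(self.peptides)

    def coverage_counts(self) -> dict[int, int]:
        """Residue -> number of peptides in which it is an exchanging position."""
        counts: dict[int, int] = {}
        for p in self.peptides:
            for j in p.exchanging_positions():
                counts[j] = counts.get(j, 0) + 1
        return counts

    def coverable_residues(self) -> list[int]:
        """Residues that could in principle be exchanging positions: every
        non-proline residue after the construct's first."""
        c = self.construct
        return [
            j
            for j in range(c.first_residue + 1, c.last_residue + 1)
            if c.residue_at(j) != "P"
        ]

    def mean_coverage(self) -> float:
        coverable = self.coverable_residues()
        counts = self.coverage_counts()
        return sum(counts.get(j, 0) for j in coverable) / len(coverable)


def generate_peptide_map(
    construct: Construct,
    length_range: tuple[int, int] = (6, 20),
    target_redundancy: float = 3.0,
    seed: int = 0,
) -> PeptideMap:
    """Overlapping peptide map emulating pepsin-digest coverage.

    A deterministic tiling pass guarantees contiguous coverage, then random
    peptides are added until the mean per-residue coverage (counted over
    coverable residues, see :meth:`PeptideMap.mean_coverage`) reaches
    ``target_redundancy``.  Deterministic under a fixed seed.
    """
    min_len, max_len = length_range
    if not (4 <= min_len <= max_len <= 40):
        raise ValueError("length_range must satisfy 4 <= min <= max <= 40")
    lo, hi = construct.first_residue, construct.last_residue
    n_res = hi - lo + 1
    if min_len > n_res:
        raise ValueError(
            f"minimum peptide length {min_len} exceeds construct length {n_res}"
        )
    rng = np.random.default_rng(seed)
    chosen: dict[tuple[int, int], Peptide] = {}
    counts: dict[int, int] = {}
    coverable = [
        j
        for j in range(lo + 1, hi + 1)
        if construct.residue_at(j) != "P"
    ]
    if not coverable:
        raise ValueError("construct has no coverable (exchanging) residues")

    def add(start: int, end: int) -> None:
        start = max(lo, start)
        end = min(hi, end)
        if end - start + 1 < min_len:
            start = max(lo, end - min_len + 1)
        if (start, end) in chosen:
            return
        pep = Peptide(start, end, construct.subsequence(start, end))
        if pep.exchangeable_amides >= 1:
            chosen[(start, end)] = pep
            for j in pep.exchanging_positions():
                counts[j] = counts.get(j, 0) + 1

    def mean_cov() -> float:
        return sum(counts.get(j, 0) for j in coverable) / len(coverable)

    # tiling pass: overlap by 3 residues so peptide N-termini are covered
    pos = lo
    while pos <= hi - min_len + 1:
        length = int(rng.integers(min_len, max_len + 1))
        end = min(pos + length - 1, hi)
        add(pos, end)
        pos = end - 2
        if end == hi:
            break

    max_iter = int(10000 * max(target_redundancy, 1.0))
    it = 0
    while mean_cov() < target_redundancy:
        it += 1
        if it > max_iter:
            raise ValueError(
                f"could not reach redundancy {target_redundancy} for this construct"
            )
        start = int(rng.integers(lo, hi - min_len + 2))
        length = int(rng.integers(min_len, max_len + 1))
        add(start, start + length - 1)

    peptides = tuple(sorted(chosen.values(), key=lambda p: (p.start, p.end)))
    return PeptideMap(construct, peptides)


# ---------------------------------------------------------------------------
# Exchange model
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Ex1Segment:
    start: int
    end: int
    k_op: float  # opening rate, 1/min

    def __post_init__(self):
        if self.start > self.end:
            raise ValueError("EX1 segment start > end")
        if self.k_op <= 0:
            raise ValueError("EX1 opening rate must be > 0")


@dataclass(frozen=True)
class ExchangeModel:
    """Per-residue intrinsic rates plus per-state protection and EX1 segments.

    ``k_int`` is indexed like the construct sequence.  ``protection`` maps a
    state label to a per-residue protection-factor array (all >= 1); EX1
    segments are per state and must be disjoint within a state.
    """

    construct: Construct
    k_int: np.ndarray  # 1/min
    protection: dict[str, np.ndarray]
    ex1_segments: dict[str, tuple[Ex1Segment, ...]] = field(default_factory=dict)

    def __post_init__(self):
        k = np.asarray(self.k_int, dtype=float)
        if k.shape != (len(self.construct.sequence),):
            raise ValueError("k_int must have one entry per residue")
        if np.any(k <= 0):
            raise ValueError("intrinsic rates must be > 0")
        object.__setattr__(self, "k_int", k)
        prot = {}
        for state, arr in self.protection.items():
            arr = np.asarray(arr, dtype=float)
            if arr.shape != k.shape:
                raise ValueError(f"protection[{state}] has wrong length")
            if np.any(arr < 1):
                raise ValueError("protection factors must be >= 1")
            prot[state] = arr
        object.__setattr__(self, "protection", prot)
        segs = {}
        for state, seglist in self.ex1_segments.items():
            seglist = tuple(seglist)
            spans = sorted((s.start, s.end) for s in seglist)
            for (a1, b1), (a2, b2) in zip(spans, spans[1:]):
                if a2 <= b1:
                    raise ValueError(f"EX1 segments overlap in state {state!r}")
            segs[state] = seglist
        object.__setattr__(self, "ex1_segments", segs)

    @property
    def states(self) -> tuple[str, ...]:
        return tuple(self.protection)

    def _require_state(self, state: str) -> None:
        if state not in self.protection:
            raise KeyError(
                f"state {state!r} not in model (have {sorted(self.protection)})"
            )

    def _ex1_mask(self, state: str) -> np.ndarray:
        mask = np.zeros(len(self.construct.sequence), dtype=bool)
        for seg in self.ex1_segments.get(state, ()):
            a = self.construct.index_of(seg.start)
            b = self.construct.index_of(seg.end)
            mask[a: b + 1] = True
        return mask

    @classmethod
    def two_state(
        cls,
        construct: Construct,
        seed: int = 0,
        base_rate: float = 50.0,
        rate_sigma: float = 1.0,
        baseline_protection: float = 100.0,
        protected_interval: tuple[int, int] | None = None,
        protection_factor: float = 20.0,
        states: tuple[str, str] = ("unphos", "phos"),
        ex1_segments: dict[str, tuple[Ex1Segment, ...]] | None = None,
    ) -> "ExchangeModel":
        """Standard two-state model for pipeline studies.

        Both states share lognormal intrinsic rates (median ``base_rate``
        1/min, log-sd ``rate_sigma``) and a uniform baseline protection; the
        second state additionally multiplies protection by
        ``protection_factor`` inside ``protected_interval`` (a protected,
        motif-B-like segment).
        """
        rng = np.random.default_rng(seed)
        n = len(construct.sequence)
        k_int = base_rate * rng.lognormal(mean=0.0, sigma=rate_sigma, size=n)
        p_a = np.full(n, baseline_protection)
        p_b = p_a.copy()
        if protected_interval is not None:
            a = construct.index_of(protected_interval[0])
            b = construct.index_of(protected_interval[1])
            p_b[a: b + 1] *= protection_factor
        return cls(
            construct,
            k_int,
            {states[0]: p_a, states[1]: p_b},
            ex1_segments or {},
        )


@dataclass(frozen=True)
class LabelingProtocol:
    """Labelling conditions of the simulated experiment.

    Defaults follow the emulated protocol: exposures of 3 s and 0.5, 50 and
    180 min, triplicate measurements, a deuterium fraction of 0.862 (5 ul
    protein diluted into 50 ul of 94.8% D2O buffer: 50/55 x 0.948), no
    back-exchange correction, and 0.05 Da centroid noise.
    """

    f_d: float = 0.862
    times: tuple[float, ...] = (0.05, 0.5, 50.0, 180.0)  # min
    replicates: int = 3
    back_exchange: float = 0.0
    noise_sd: float = 0.05  # Da
    seed: int = 0

    def __post_init__(self):
        if not 0.0 <= self.f_d <= 1.0:
            raise ValueError("deuterium fraction must be in [0, 1]")
        if not 0.0 <= self.back_exchange < 1.0:
            raise ValueError("back-exchange fraction must be in [0, 1)")
        if self.replicates < 1:
            raise ValueError("need at least one replicate")
        times = tuple(float(t) for t in self.times)
        if any(t <= 0 for t in times) or any(
            t2 <= t1 for t1, t2 in zip(times, times[1:])
        ):
            raise ValueError("exposure times must be positive and strictly increasing")
        object.__setattr__(self, "times", times)


# ---------------------------------------------------------------------------
# Uptake simulation
# ---------------------------------------------------------------------------

def _site_probabilities(
    model: ExchangeModel, peptide: Peptide, protocol: LabelingProtocol,
    state: str, t: float,
) -> tuple[np.ndarray, list[tuple[int, float]]]:
    """(per-site EX2 exchange probabilities, [(n_seg, open_prob), ...])."""
    model._require_state(state)
    scale = (1.0 - protocol.back_exchange) * protocol.f_d
    ex1_mask = model._ex1_mask(state)
    probs = []
    for j in peptide.exchanging_positions():
        idx = model.construct.index_of(j)
        if ex1_mask[idx]:
            continue
        k_obs = model.k_int[idx] / model.protection[state][idx]
        probs.append(-np.expm1(-k_obs * t))
    segments = []
    ex_pos = set(peptide.exchanging_positions())
    for seg in model.ex1_segments.get(state, ()):
        n_seg = len(ex_pos & set(range(seg.start, seg.end + 1)))
        if n_seg:
            segments.append((n_seg, float(-np.expm1(-seg.k_op * t))))
    return scale * np.asarray(probs), segments


def noiseless_uptake(
    model: ExchangeModel, peptide: Peptide, protocol: LabelingProtocol,
    state: str, t: float,
) -> float:
    """Expected centroid uptake (Da) of a peptide at exposure ``t`` minutes."""
    if t < 0:
        raise ValueError("exposure must be >= 0")
    scale = (1.0 - protocol.back_exchange) * protocol.f_d
    ex2, segments = _site_probabilities(model, peptide, protocol, state, t)
    ex1 = sum(n * scale * p_open for n, p_open in segments)
    return float(ex2.sum() + ex1)


def simulate_uptake(
    model: ExchangeModel,
    peptide_map: PeptideMap,
    protocol: LabelingProtocol,
    state: str,
    include_t0: bool = True,
) -> pd.DataFrame:
    """Replicated centroid table for one state, in cluster-CSV layout.

    ``Center`` is the peptide's average mass plus the noiseless uptake plus
    i.i.d. Gaussian centroid noise per replicate; undeuterated (Exposure 0)
    rows are included so uptake can be recomputed downstream exactly as for
    real data.  The noise stream is seeded from ``protocol.seed`` and the
    state label, so states are reproducible and mutually independent.
    """
    model._require_state(state)
    rng = np.random.default_rng(
        [protocol.seed, zlib.crc32(state.encode("utf8"))]
    )
    times = ((0.0,) if include_t0 else ()) + protocol.times
    rows = []
    for pep in peptide_map.peptides:
        base = peptide_mass(pep.sequence, average=True)
        for t in times:
            truth = noiseless_uptake(model, pep, protocol, state, t)
            noise = rng.normal(0.0, protocol.noise_sd, size=protocol.replicates)
            for rep in range(1, protocol.replicates + 1):
                rows.append(
                    (
                        model.construct.name, pep.start, pep.end, pep.sequence,
                        state, t, rep, base + truth + noise[rep - 1],
                    )
                )
    return pd.DataFrame(rows, columns=UPTAKE_COLUMNS)


# ---------------------------------------------------------------------------
# Envelope simulation
# ---------------------------------------------------------------------------

def simulate_envelope(
    model: ExchangeModel, peptide: Peptide, protocol: LabelingProtocol,
    state: str, t: float, replicate: int = 1,
) -> IsotopicEnvelope:
    """Noiseless isotopic envelope of one peptide at one exposure.

    The deuteration distribution is a binomial over the EX2 amides at their
    mean site probability, convolved per EX1 segment with a two-component
    opening mixture (closed weight ``exp(-k_op t)``), convolved with the
    averagine natural envelope.
    """
    scale = (1.0 - protocol.back_exchange) * protocol.f_d
    ex2, segments = _site_probabilities(model, peptide, protocol, state, t)
    if len(ex2):
        dist = binomial_envelope(len(ex2), float(np.mean(ex2)))
    else:
        dist = np.array([1.0])
    for n_seg, p_open in segments:
        open_dist = binomial_envelope(n_seg, scale)
        closed = np.array([1.0])
        mix = (1.0 - p_open) * np.pad(
            closed, (0, len(open_dist) - 1)
        ) + p_open * open_dist
        dist = convolve(dist, mix)
    full = convolve(natural_envelope(peptide.sequence), dist)
    return IsotopicEnvelope(
        full, peptide.sequence, peptide.start, peptide.end, t, replicate, state
    )


def simulate_envelopes(
    model: ExchangeModel, peptide: Peptide, protocol: LabelingProtocol,
    state: str, times: tuple[float, ...] | None = None, include_t0: bool = True,
) -> list[IsotopicEnvelope]:
    """Envelope time series (undeuterated envelope first by default)."""
    ts = protocol.times if times is None else tuple(times)
    if include_t0:
        ts = (0.0,) + ts
    return [simulate_envelope(model, peptide, protocol, state, t) for t in ts]


# ---------------------------------------------------------------------------
# Ready-made study system
# ---------------------------------------------------------------------------

def demo_system(
    seed: int = 0,
    n_residues: int = 180,
    protected_interval: tuple[int, int] = (101, 122),
    ex1_interval: tuple[int, int] | None = (41, 52),
    ex1_k_op: float = 0.007,
) -> tuple[Construct, ExchangeModel]:
    """A self-contained two-state study system.

    A random-sequence construct (proline-depleted alphabet plus occasional
    prolines) carrying a 22-residue segment whose protection rises 20-fold in
    the ``phos`` state — the motif-B analogue — and, in the ``unphos`` state
    only, an EX1 segment with slow cooperative opening, mimicking a plastic
    bromodomain.
    """
    rng = np.random.default_rng(seed)
    alphabet = list("ACDEFGHIKLMNQRSTVWY")
    seq = [str(rng.choice(alphabet)) for _ in range(n_residues)]
    for i in range(9, n_residues, 23):  # sparse prolines, none in key segments
        if not (
            protected_interval[0] - 1 <= i + 1 <= protected_interval[1] + 1
            or (ex1_interval and ex1_interval[0] - 1 <= i + 1 <= ex1_interval[1] + 1)
        ):
            seq[i] = "P"
    construct = Construct(f"demo_{seed}", "".join(seq))
    ex1 = {}
    if ex1_interval is not None:
        ex1 = {"unphos": (Ex1Segment(ex1_interval[0], ex1_interval[1], ex1_k_op),)}
    model = ExchangeModel.two_state(
        construct,
        seed=seed,
        protected_interval=protected_interval,
        ex1_segments=ex1,
    )
    return construct, model
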