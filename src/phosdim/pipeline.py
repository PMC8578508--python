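"""Differential HDX-MS analysis.

From replicated peptide-centroid tables this module computes deuterium
uptake (centroid minus undeuterated centroid), state differences with the
two-part significance rule (absolute change above a Da threshold AND above a
multiple of the propagated replicate SD), the per-residue projection

    res_j = (1/N) * sum_i pep_i / amide_i

over the N peptides in which residue j is an exchanging position, protected-
region calling on the resulting profile, and per-region coverage summaries.

Conventions (documented in the methods note): non-significant and
EX1-flagged peptides contribute a difference of zero rather than being
dropped, so covered-but-unchanged regions read 0 instead of becoming gaps;
no back-exchange correction is applied; a residue is "contained" in a
peptide only when it is an exchanging position (first residue and prolines
excluded).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd

from .constructs import Construct, RegionAnnotation
from .synthetic import Peptide, PeptideMap, UPTAKE_COLUMNS

PeptideKey = tuple[int, int, str]

_TIME_TOL = 1e-9  # min; exposures closer than this are the same timepoint


class UptakeTableError(ValueError):
    """Malformed uptake table."""


@dataclass(frozen=True)
class SignificanceConfig:
    """The two-part significance rule for a state difference.

    A peptide/timepoint difference is significant when |delta| exceeds
    ``abs_threshold`` (Da) and ``sd_multiplier`` times the SD of the
    difference.  ``pooling`` selects how that SD is computed: per peptide and
    timepoint from the replicate SDs of the two states
    (``sqrt(sd_A**2 + sd_B**2)``), or pooled globally (RMS of the per-peptide
    values) when replicate counts are too low to trust individual SDs.
    """

    abs_threshold: float = 0.5
    sd_multiplier: float = 2.3
    pooling: Literal["per_peptide", "pooled"] = "per_peptide"

    def __post_init__(self):
        if self.abs_threshold <= 0 or self.sd_multiplier <= 0:
            raise ValueError("significance thresholds must be > 0")
        if self.pooling not in ("per_peptide", "pooled"):
            raise ValueError(f"unknown pooling mode {self.pooling!r}")


# ---------------------------------------------------------------------------
# Table IO
# ---------------------------------------------------------------------------

def read_uptake_table(path) -> pd.DataFrame:
    """Read and validate a cluster-style uptake CSV.

    Required columns: Protein, Start, End, Sequence, State, Exposure,
    Replicate, Center (an Uptake column is accepted and preserved).
    """
    df = pd.read_csv(path)
    return validate_uptake_table(df)


def write_uptake_table(records: pd.DataFrame, path) -> None:
    validate_uptake_table(records).to_csv(path, index=False)


def validate_uptake_table(df: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in UPTAKE_COLUMNS if c not in df.columns]
    if missing:
        raise UptakeTableError(f"missing column(s): {', '.join(missing)}")
    bad = df[df["Start"] > df["End"]]
    if len(bad):
        raise UptakeTableError(
            f"Start > End in row(s): {list(bad.index[:5])}"
        )
    if (df["Exposure"] < 0).any():
        raise UptakeTableError("negative exposure time")
    dup = df.duplicated(
        subset=["Start", "End", "Sequence", "State", "Exposure", "Replicate"]
    )
    if dup.any():
        raise UptakeTableError(
            f"duplicate (peptide, state, exposure, replicate) in row(s): "
            f"{list(df.index[dup][:5])}"
        )
    return df


# ---------------------------------------------------------------------------
# Uptake
# ---------------------------------------------------------------------------

def compute_uptake(centroid_t: float, centroid_0: float) -> float:
    """Deuterium uptake: deuterated centroid minus undeuterated centroid."""
    if not (np.isfinite(centroid_t) and np.isfinite(centroid_0)):
        raise ValueError("centroids must be finite")
    return centroid_t - centroid_0


def add_uptake(records: pd.DataFrame) -> pd.DataFrame:
    """Attach an Uptake column: Center minus the peptide/state mean
    undeuterated Center.  Peptides without an Exposure-0 record get NaN
    uptake and a warning."""
    df = validate_uptake_table(records).copy()
    t0 = df[np.isclose(df["Exposure"], 0.0, atol=_TIME_TOL)]
    ref = t0.groupby(["Start", "End", "Sequence", "State"])["Center"].mean()
    keys = pd.MultiIndex.from_frame(df[["Start", "End", "Sequence", "State"]])
    base = ref.reindex(keys).to_numpy()
    if np.isnan(base).any():
        n = df.loc[np.isnan(base), ["Start", "End", "State"]].drop_duplicates()
        warnings.warn(
            f"{len(n)} peptide/state group(s) lack an undeuterated record; "
            "their uptake is left undefined",
            stacklevel=2,
        )
    df["Uptake"] = df["Center"].to_numpy() - base
    return df


# ---------------------------------------------------------------------------
# Differential analysis
# ---------------------------------------------------------------------------

@dataclass
class DifferentialResult:
    """Output of :func:`differential`.

    ``per_timepoint`` has one row per peptide and exposure with the mean
    difference (state A minus state B), its SD, and the significance flag;
    ``per_peptide`` has one row per peptide with the across-timepoint summary
    difference (non-significant timepoints contributing zero, EX1-flagged
    peptides forced to zero).
    """

    state_a: str
    state_b: str
    config: SignificanceConfig
    per_timepoint: pd.DataFrame
    per_peptide: pd.DataFrame

    def peptides(self) -> list[Peptide]:
        return [
            Peptide(int(r.Start), int(r.End), r.Sequence)
            for r in self.per_peptide.itertuples()
        ]


def differential(
    records: pd.DataFrame,
    state_a: str,
    state_b: str,
    config: SignificanceConfig = SignificanceConfig(),
    ex1_peptides: Iterable[PeptideKey] = (),
) -> DifferentialResult:
    """Per-peptide state differences with the two-part significance rule.

    ``records`` must contain both states; uptake is (re)computed from the
    centroids if absent.  ``ex1_peptides`` identifies peptides whose exchange
    is bimodal — their centroid difference is not a meaningful EX2 quantity,
    so their summary difference is forced to zero and flagged.
    """
    df = records if "Uptake" in records.columns else add_uptake(records)
    for s in (state_a, state_b):
        if not (df["State"] == s).any():
            raise KeyError(f"state {s!r} absent from table")
    df = df[df["State"].isin([state_a, state_b])]
    df = df[~np.isclose(df["Exposure"], 0.0, atol=_TIME_TOL)]

    grouped = df.groupby(["Start", "End", "Sequence", "Exposure", "State"])["Uptake"]
    stats = grouped.agg(["mean", "std", "count"]).unstack("State")
    n_min = stats["count"].min().min()
    if n_min < 3:
        warnings.warn(
            f"fewer than 3 replicates in some group(s) (min {int(n_min)})",
            stacklevel=2,
        )
    delta = stats[("mean", state_a)] - stats[("mean", state_b)]
    sd = np.sqrt(
        stats[("std", state_a)].fillna(0.0) ** 2
        + stats[("std", state_b)].fillna(0.0) ** 2
    )
    if config.pooling == "pooled":
        sd = pd.Series(np.sqrt(np.mean(sd**2)), index=sd.index)

    ex1_set = {tuple(k) for k in ex1_peptides}
    out = delta.rename("DeltaUptake").reset_index()
    out["SDDiff"] = sd.to_numpy()
    out["Significant"] = (np.abs(out["DeltaUptake"]) > config.abs_threshold) & (
        np.abs(out["DeltaUptake"]) > config.sd_multiplier * out["SDDiff"]
    )
    out["EX1"] = [
        (s, e, q) in ex1_set
        for s, e, q in zip(out["Start"], out["End"], out["Sequence"])
    ]

    contrib = np.where(out["Significant"], out["DeltaUptake"], 0.0)
    out["Contribution"] = np.where(out["EX1"], 0.0, contrib)
    summary = (
        out.groupby(["Start", "End", "Sequence"])
        .agg(
            SummaryDelta=("Contribution", "mean"),
            AnySignificant=("Significant", "any"),
            EX1=("EX1", "any"),
        )
        .reset_index()
        .sort_values(["Start", "End"])
        .reset_index(drop=True)
    )
    summary.loc[summary["EX1"], "SummaryDelta"] = 0.0
    return DifferentialResult(state_a, state_b, config, out, summary)


# ---------------------------------------------------------------------------
# Residue projection
# ---------------------------------------------------------------------------

def residue_projection(
    diff: DifferentialResult | pd.DataFrame,
    construct: Construct | None = None,
    exposure: float | None = None,
) -> pd.DataFrame:
    """Project per-peptide summary differences onto residues.

    For each residue j covered (as an exchanging position) by N peptides,
    ``ResJ`` is the mean over those peptides of ``SummaryDelta / amide``.
    Returns a frame with one row per residue of the covered span: Residue,
    ResJ (NaN where uncovered — a gap), N, Covered.

    By default peptide differences are the across-timepoint summaries; pass
    ``exposure`` to project a single timepoint instead (its non-significant
    and EX1 contributions are likewise zero).
    """
    if exposure is not None:
        if not isinstance(diff, DifferentialResult):
            raise TypeError("per-timepoint projection needs a DifferentialResult")
        tp = diff.per_timepoint
        tp = tp[np.isclose(tp["Exposure"], exposure, atol=_TIME_TOL)]
        if tp.empty:
            raise KeyError(f"no records at exposure {exposure}")
        summary = tp.rename(columns={"Contribution": "SummaryDelta"})[
            ["Start", "End", "Sequence", "SummaryDelta"]
        ].reset_index(drop=True)
    else:
        summary = diff.per_peptide if isinstance(diff, DifferentialResult) else diff
    peptides = [
        Peptide(int(r.Start), int(r.End), r.Sequence) for r in summary.itertuples()
    ]
    if construct is not None:
        lo, hi = construct.first_residue, construct.last_residue
    elif peptides:
        lo = min(p.start for p in peptides)
        hi = max(p.end for p in peptides)
    else:
        return pd.DataFrame(columns=["Residue", "ResJ", "N", "Covered"])

    acc: dict[int, list[float]] = {}
    for pep, row in zip(peptides, summary.itertuples()):
        share = row.SummaryDelta / pep.exchangeable_amides
        for j in pep.exchanging_positions():
            acc.setdefault(j, []).append(share)
    rows = []
    for j in range(lo, hi + 1):
        vals = acc.get(j, [])
        rows.append(
            (j, float(np.mean(vals)) if vals else np.nan, len(vals), bool(vals))
        )
    return pd.DataFrame(rows, columns=["Residue", "ResJ", "N", "Covered"])


def call_protected_regions(
    profile: pd.DataFrame,
    min_abs: float = 0.05,
    min_run: int = 5,
) -> list[tuple[int, int, int]]:
    """Maximal runs of consistent differential protection.

    Returns ``(start, end, sign)`` intervals of at least ``min_run``
    consecutive covered residues with ``|ResJ| >= min_abs`` and uniform sign;
    coverage gaps break runs.
    """
    out = []
    run_start, run_sign, prev = None, 0, None
    def flush(last):
        if run_start is not None and last - run_start + 1 >= min_run:
            out.append((run_start, last, run_sign))
    for row in profile.itertuples():
        j, val, covered = int(row.Residue), row.ResJ, bool(row.Covered)
        sign = 0
        if covered and np.isfinite(val) and abs(val) >= min_abs:
            sign = 1 if val > 0 else -1
        contiguous = prev is not None and j == prev + 1
        if sign != 0 and contiguous and sign == run_sign:
            pass  # run continues
        else:
            flush(prev if prev is not None else j)
            run_start, run_sign = (j, sign) if sign != 0 else (None, 0)
        prev = j
    flush(prev if prev is not None else 0)
    return out


def coverage_summary(
    peptide_map: PeptideMap,
    construct: Construct,
    regions: Sequence[RegionAnnotation],
) -> dict[str, float]:
    """Fraction of each region's residues that are exchanging positions of at
    least one peptide."""
    counts = peptide_map.coverage_counts()
    out = {}
    for r in regions:
        residues = [
            j for j in range(r.start, r.end + 1)
            if construct.first_residue <= j <= construct.last_residue
        ]
        if not residues:
            out[r.label] = 0.0
            continue
        out[r.label] = sum(counts.get(j, 0) > 0 for j in residues) / len(residues)
    return out


def write_residue_profile(profile: pd.DataFrame, path) -> None:
    profile.to_csv(path, index=False)
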