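"""Sequence-level modelling of BET-protein constructs.

A :class:`Construct` is a named amino-acid sequence with its own residue
numbering (``numbering_offset`` is the residue number of the first position),
region annotations, and covalent modifications.  On top of it this module
provides intact-mass computation, CK2 consensus-motif scanning, point
substitutions and region/linker replacement, and heptad-repeat annotation for
coiled-coil candidate segments.

Coordinates are 1-based inclusive residue numbers throughout.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass
from typing import Iterable, Literal, Sequence

import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .chem import WATER_AVERAGE, WATER_MONO, peptide_mass, validate_sequence

#: UniMod mass shifts (monoisotopic, average) for the supported modifications.
MODIFICATION_SHIFTS = {
    "phospho": (79.9663, 79.98),
    "acetyl": (42.0106, 42.04),
}

#: Residues counted as hydrophobic at heptad a/d positions.
HEPTAD_HYDROPHOBIC = frozenset("AILMFVWY")


@dataclass(frozen=True)
class RegionAnnotation:
    label: str
    start: int
    end: int

    def __post_init__(self):
        if self.start > self.end:
            raise ValueError(f"region {self.label}: start {self.start} > end {self.end}")

    def __len__(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class Modification:
    """A covalent modification at a single residue.

    ``position`` of 0 denotes the free N-terminus (acetyl only).
    """

    kind: Literal["phospho", "acetyl"]
    position: int

    def __post_init__(self):
        if self.kind not in MODIFICATION_SHIFTS:
            raise ValueError(f"unsupported modification kind {self.kind!r}")

    def mass_shift(self, average: bool = True) -> float:
        mono, avg = MODIFICATION_SHIFTS[self.kind]
        return avg if average else mono


@dataclass(frozen=True)
class MassOptions:
    scale: Literal["average", "monoisotopic"] = "average"
    include_water: bool = True
    terminal_adduct: float = 0.0  # extra Da on top of free termini

    def __post_init__(self):
        if self.scale not in ("average", "monoisotopic"):
            raise ValueError(f"unknown mass scale {self.scale!r}")


@dataclass(frozen=True)
class Construct:
    name: str
    sequence: str
    numbering_offset: int = 1
    regions: tuple[RegionAnnotation, ...] = ()
    modifications: tuple[Modification, ...] = ()

    def __post_init__(self):
        if not self.sequence:
            raise ValueError("sequence must be non-empty")
        validate_sequence(self.sequence, self.numbering_offset)
        object.__setattr__(self, "regions", tuple(self.regions))
        object.__setattr__(self, "modifications", tuple(self.modifications))
        lo, hi = self.first_residue, self.last_residue
        for r in self.regions:
            if r.start < lo or r.end > hi:
                raise ValueError(f"region {r.label} [{r.start},{r.end}] outside [{lo},{hi}]")
        for m in self.modifications:
            if m.kind == "acetyl" and m.position == 0:
                continue  # N-terminal acetylation
            if m.position < lo or m.position > hi:
                raise ValueError(f"modification at {m.position} outside [{lo},{hi}]")
            aa = self.residue_at(m.position)
            if m.kind == "phospho" and aa not in "STY":
                raise ValueError(f"phospho at {m.position} requires S/T/Y, found {aa}")
            if m.kind == "acetyl" and aa != "K":
                raise ValueError(f"acetyl at {m.position} requires K, found {aa}")

    @property
    def first_residue(self) -> int:
        return self.numbering_offset

    @property
    def last_residue(self) -> int:
        return self.numbering_offset + len(self.sequence) - 1

    def index_of(self, position: int) -> int:
        """0-based string index of residue number ``position``."""
        if not self.first_residue <= position <= self.last_residue:
            raise IndexError(
                f"residue {position} outside [{self.first_residue},{self.last_residue}]"
            )
        return position - self.numbering_offset

    def residue_at(self, position: int) -> str:
        return self.sequence[self.index_of(position)]

    def subsequence(self, start: int, end: int) -> str:
        if start > end:
            raise ValueError(f"start {start} > end {end}")
        return self.sequence[self.index_of(start): self.index_of(end) + 1]

    def truncate(self, start: int, end: int, name: str | None = None) -> "Construct":
        """Sub-construct spanning residues ``start..end`` (numbering kept)."""
        seq = self.subsequence(start, end)
        regions = tuple(r for r in self.regions if r.start >= start and r.end <= end)
        mods = tuple(m for m in self.modifications if start <= m.position <= end)
        return Construct(
            name or f"{self.name}_{start}-{end}", seq, start, regions, mods
        )

    def region(self, label: str) -> RegionAnnotation:
        for r in self.regions:
            if r.label == label:
                return r
        raise KeyError(label)


# ---------------------------------------------------------------------------
# Mass
# ---------------------------------------------------------------------------

def compute_intact_mass(construct: Construct, opts: MassOptions = MassOptions()) -> float:
    """Intact neutral mass of a construct in Da.

    Sum of residue masses, one water for the free termini (unless
    ``include_water`` is off), any terminal adduct, and modification shifts.
    """
    average = opts.scale == "average"
    m = peptide_mass(construct.sequence, average=average)
    if not opts.include_water:
        m -= WATER_AVERAGE if average else WATER_MONO
    m += opts.terminal_adduct
    for mod in construct.modifications:
        m += mod.mass_shift(average=average)
    return m


# ---------------------------------------------------------------------------
# CK2 consensus
# ---------------------------------------------------------------------------

def find_ck2_consensus(sequence: str, offset: int = 1) -> list[tuple[int, str]]:
    """All CK2 consensus sites S/T-x-x-E/D in a sequence.

    Returns ``(residue_number, 'S'|'T')`` pairs sorted ascending; overlapping
    matches are all reported.  The acidic determinant at position +3 may be
    either D or E and the two intervening residues are unconstrained.
    """
    hits = []
    for i in range(len(sequence) - 3):
        if sequence[i] in "ST" and sequence[i + 3] in "DE":
            hits.append((offset + i, sequence[i]))
    return hits


def find_ck2_consensus_in_region(
    construct: Construct, region: RegionAnnotation | str
) -> list[tuple[int, str]]:
    """CK2 consensus sites whose S/T falls inside ``region``.

    The +3 determinant may lie outside the region (the scan runs over the
    full construct so sites at the region edge are not lost).
    """
    if isinstance(region, str):
        region = construct.region(region)
    hits = find_ck2_consensus(construct.sequence, construct.numbering_offset)
    return [h for h in hits if region.start <= h[0] <= region.end]


# ---------------------------------------------------------------------------
# Mutagenesis
# ---------------------------------------------------------------------------

def apply_substitutions(
    construct: Construct,
    substitutions: Iterable[tuple],
    name: str | None = None,
) -> Construct:
    """Point substitutions, keeping the numbering.

    Each substitution is ``(position, new_residue)`` or
    ``(position, expected_original, new_residue)``; when the original residue
    is supplied it is checked against the sequence.
    """
    seq = list(construct.sequence)
    for sub in substitutions:
        if len(sub) == 2:
            position, new = sub
            expected = None
        elif len(sub) == 3:
            position, expected, new = sub
        else:
            raise ValueError(f"substitution must have 2 or 3 fields, got {sub!r}")
        idx = construct.index_of(position)
        if expected is not None and seq[idx] != expected:
            raise ValueError(
                f"expected {expected} at residue {position}, found {seq[idx]}"
            )
        validate_sequence(new, position)
        seq[idx] = new
    return Construct(
        name or construct.name,
        "".join(seq),
        construct.numbering_offset,
        construct.regions,
        construct.modifications,
    )


def replace_region(
    construct: Construct,
    start: int,
    end: int,
    replacement: str,
    name: str | None = None,
) -> Construct:
    """Delete residues ``start..end`` and splice in ``replacement``.

    Used for deletion constructs where a segment is swapped for a flexible
    linker.  Numbering offset is kept; annotations and modifications inside
    or downstream of the edited window are dropped (their coordinates are no
    longer meaningful).
    """
    i, j = construct.index_of(start), construct.index_of(end)
    validate_sequence(replacement, start)
    seq = construct.sequence[:i] + replacement + construct.sequence[j + 1:]
    regions = tuple(r for r in construct.regions if r.end < start)
    mods = tuple(m for m in construct.modifications if 0 <= m.position < start)
    return Construct(
        name or f"{construct.name}_d{start}-{end}",
        seq,
        construct.numbering_offset,
        regions,
        mods,
    )


# ---------------------------------------------------------------------------
# Heptads
# ---------------------------------------------------------------------------

def count_complete_heptads(start: int, end: int) -> int:
    """Number of complete 7-residue repeats in a residue interval."""
    if start > end:
        raise ValueError(f"start {start} > end {end}")
    return (end - start + 1) // 7


def heptad_register_score(
    sequence: str, start: int, end: int, offset: int = 1
) -> tuple[int, float]:
    """Best heptad register for an interval and its hydrophobicity score.

    For each of the 7 register phases, the score is the fraction of ``a``/``d``
    positions occupied by hydrophobic residues (A, I, L, M, F, V, W, Y).
    Returns ``(best_phase, score)``; phase ``p`` means the first interval
    residue sits at heptad position ``p`` (0 = ``a``).  Ties break toward the
    smallest phase index.
    """
    lo, hi = offset, offset + len(sequence) - 1
    if start < lo or end > hi or start > end:
        raise ValueError(f"interval [{start},{end}] outside sequence [{lo},{hi}]")
    window = sequence[start - offset: end - offset + 1]
    best_phase, best_score = 0, -1.0
    for phase in range(7):
        ad = [
            aa
            for k, aa in enumerate(window)
            if (k + phase) % 7 in (0, 3)  # a and d positions
        ]
        if not ad:
            continue
        score = sum(aa in HEPTAD_HYDROPHOBIC for aa in ad) / len(ad)
        if score > best_score:
            best_phase, best_score = phase, score
    return best_phase, best_score


# ---------------------------------------------------------------------------
# FASTA and packaged data
# ---------------------------------------------------------------------------

def read_fasta(path) -> list[Construct]:
    """Read constructs from a FASTA file (one per record)."""
    out = []
    for rec in SeqIO.parse(str(path), "fasta"):
        out.append(Construct(rec.id, str(rec.seq).upper()))
    return out


def write_fasta(constructs: Sequence[Construct], path) -> None:
    records = [
        SeqRecord(Seq(c.sequence), id=c.name, description="")
        for c in constructs
    ]
    SeqIO.write(records, str(path), "fasta")


def _data_path(filename: str):
    return importlib.resources.files("phosdim.data").joinpath(filename)


def load_brd4(with_regions: bool = True) -> Construct:
    """The packaged BRD4 residues 1-722 reference construct.

    The packaged sequence is a literature-validated reconstruction of UniProt
    O60885 residues 1-722 (see the FASTA header), bundled so that every
    sequence-level computation runs without a network connection.
    """
    with importlib.resources.as_file(_data_path("brd4_1_722.synthetic.fasta")) as p:
        rec = next(SeqIO.parse(str(p), "fasta"))
    regions: tuple[RegionAnnotation, ...] = ()
    if with_regions:
        regions = tuple(load_brd4_regions()["domains"])
    return Construct("BRD4_1-722", str(rec.seq).upper(), 1, regions)


def load_brd4_regions() -> dict[str, list[RegionAnnotation]]:
    """Packaged BRD4 region tables: ``domains`` and ``hdx_protected``."""
    with importlib.resources.as_file(_data_path("brd4_regions.yaml")) as p:
        raw = yaml.safe_load(p.read_text())
    return {
        key: [RegionAnnotation(d["label"], d["start"], d["end"]) for d in entries]
        for key, entries in raw.items()
    }
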