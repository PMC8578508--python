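"""Cross-linking MS topology analysis.

Turns residue-pair cross-link lists from monomer- and dimer-enriched
fractions into intra-/inter-molecular classifications (links unique to the
monomer fraction are intra-molecular, links unique to the dimer fraction are
inter-molecular), region-by-region contact matrices, and a concordance score
against HDX-protected regions.  Link identity for all set operations is the
canonicalized position pair; scores are carried along but ignored for
identity.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd

from .constructs import RegionAnnotation

#: Residue pairs chemically allowed for the amine-reactive cross-linker.
LINKABLE_PAIRS = frozenset(
    {("K", "K"), ("K", "S"), ("K", "T"), ("K", "Y")}
)

XL_COLUMNS = ["pos1", "res1", "pos2", "res2", "sample", "score"]


@dataclass(frozen=True)
class CrossLink:
    """A residue-pair cross-link, canonicalized so position1 <= position2."""

    position1: int
    position2: int
    residue1: str = "K"
    residue2: str = "K"
    sample: str = ""
    score: float | None = None
    annotation: str = ""

    def __post_init__(self):
        if self.position1 > self.position2:
            p1, p2 = self.position2, self.position1
            r1, r2 = self.residue2, self.residue1
            object.__setattr__(self, "position1", p1)
            object.__setattr__(self, "position2", p2)
            object.__setattr__(self, "residue1", r1)
            object.__setattr__(self, "residue2", r2)

    @property
    def pair(self) -> tuple[int, int]:
        return (self.position1, self.position2)

    @property
    def is_self_link(self) -> bool:
        """Same residue number on both ends — only possible between two
        copies of the protein, hence necessarily inter-molecular."""
        return self.position1 == self.position2


def validate_linkable(link: CrossLink) -> bool:
    """True iff the unordered residue pair is chemically cross-linkable."""
    pair = tuple(sorted((link.residue1.upper(), link.residue2.upper())))
    return pair in LINKABLE_PAIRS


def classify_by_sample(
    monomer_links: Iterable[CrossLink],
    dimer_links: Iterable[CrossLink],
) -> dict[str, set[tuple[int, int]]]:
    """Partition position pairs by fraction of origin.

    ``intra``: unique to the monomer fraction; ``inter``: unique to the dimer
    fraction; ``shared``: observed in both.  The three sets are disjoint and
    cover the union.
    """
    mono = {l.pair for l in monomer_links}
    dim = {l.pair for l in dimer_links}
    return {
        "intra": mono - dim,
        "inter": dim - mono,
        "shared": mono & dim,
    }


def assert_self_links_inter(
    classified: dict[str, set[tuple[int, int]]],
) -> tuple[dict[str, set[tuple[int, int]]], list[str]]:
    """Enforce that self-links (x, x) are inter-molecular.

    A self-link in the monomer-unique (intra) set is logically impossible for
    a monomer and is reported as an inconsistency (and moved to ``inter``);
    consistent input is returned unchanged.
    """
    intra = set(classified["intra"])
    inter = set(classified["inter"])
    shared = set(classified["shared"])
    problems = []
    for pair in sorted(intra):
        if pair[0] == pair[1]:
            problems.append(
                f"self-link {pair} found in the monomer-unique set; "
                "a link between identical residue numbers requires two chains"
            )
            intra.discard(pair)
            inter.add(pair)
    return {"intra": intra, "inter": inter, "shared": shared}, problems


def contact_matrix(
    links: Iterable[CrossLink],
    regions: Sequence[RegionAnnotation],
) -> pd.DataFrame:
    """Symmetric region-by-region link-count matrix.

    Each link endpoint is assigned to the first region (by start, then input
    order) containing it; links with an unannotated endpoint are dropped.
    """
    ordered = sorted(regions, key=lambda r: r.start)

    def assign(pos: int) -> str | None:
        for r in ordered:
            if r.start <= pos <= r.end:
                return r.label
        return None

    labels = [r.label for r in ordered]
    mat = pd.DataFrame(0, index=labels, columns=labels, dtype=int)
    for link in links:
        a, b = assign(link.position1), assign(link.position2)
        if a is None or b is None:
            continue
        mat.loc[a, b] += 1
        if a != b:
            mat.loc[b, a] += 1
    return mat


def hdx_concordance(
    inter_links: Iterable[CrossLink],
    protected_regions: Sequence[RegionAnnotation | tuple[int, int]],
    window: int = 0,
) -> float:
    """Fraction of inter-molecular links near HDX-protected regions.

    A link agrees when at least one endpoint lies within ``window`` residues
    of any protected interval.  Returns 0.0 when there are no links or no
    regions.
    """
    if window < 0:
        raise ValueError("window must be >= 0")
    spans = [
        (r.start, r.end) if isinstance(r, RegionAnnotation) else tuple(r)
        for r in protected_regions
    ]
    links = list(inter_links)
    if not links or not spans:
        return 0.0
    def near(pos: int) -> bool:
        return any(a - window <= pos <= b + window for a, b in spans)
    hits = sum(near(l.position1) or near(l.position2) for l in links)
    return hits / len(links)


# ---------------------------------------------------------------------------
# CSV IO (columns: pos1,res1,pos2,res2,sample,score; header required)
# ---------------------------------------------------------------------------

def read_crosslinks(path) -> list[CrossLink]:
    df = pd.read_csv(path)
    missing = [c for c in XL_COLUMNS[:5] if c not in df.columns]
    if missing:
        raise ValueError(f"cross-link table missing column(s): {', '.join(missing)}")
    out = []
    for row in df.itertuples():
        score = getattr(row, "score", None)
        out.append(
            CrossLink(
                int(row.pos1), int(row.pos2), str(row.res1), str(row.res2),
                str(row.sample), None if pd.isna(score) else float(score),
            )
        )
    return out


def write_crosslinks(links: Sequence[CrossLink], path) -> None:
    pd.DataFrame(
        [
            (l.position1, l.residue1, l.position2, l.residue2, l.sample, l.score)
            for l in links
        ],
        columns=XL_COLUMNS,
    ).to_csv(path, index=False)
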