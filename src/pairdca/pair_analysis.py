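"""Post-processing of the all-pairs score table.

The raw DCA output scores every column pair of the concatenated alignment.
This module turns it into biology: remove trivially proximal pairs (close
residue numbers covary for structural reasons, not interaction), keep only
inter-protein pairs, translate concatenated column indices into per-protein
residue numbers, and rank the partners of an *anchor* residue (one
implicated by genetics, e.g. A147 of the PhoU-like protein) within a target
domain by MI or DI.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from pathlib import Path

from .dca import PairScoreTable
from .exceptions import FormatError, InconsistencyError, ParameterError
from .paired_msa import SEGMENT_A, SEGMENT_B, SEGMENT_SPACER, PositionMap

logger = logging.getLogger(__name__)

MISSING_DISTANCE = "NA"


@dataclass(frozen=True)
class AnnotatedPair:
    """An inter-protein residue pair in per-protein numbering.

    ``distance`` (Å) is filled in by the structure-annotation stage and is
    ``None`` until then (or when the residue is unresolved in the model).
    """

    protein_i: str
    res_i: int
    protein_j: str
    res_j: int
    mi: float
    di: float
    distance: float | None = None

    def __post_init__(self):
        for seg in (self.protein_i, self.protein_j):
            if seg not in (SEGMENT_A, SEGMENT_B):
                raise InconsistencyError(f"segment tag {seg!r} is not A or B")
        if self.res_i < 1 or self.res_j < 1:
            raise InconsistencyError("residue numbers must be >= 1")

    def key(self) -> frozenset:
        """Orientation-independent identity of the pair."""
        return frozenset(
            {(self.protein_i, self.res_i), (self.protein_j, self.res_j)}
        )


@dataclass(frozen=True)
class AnchorQuery:
    """Rank partners of one anchor residue within a target domain.

    ``target_range`` is an inclusive residue interval of the partner
    protein (e.g. the PAS domain span); ``sort_key`` is ``"mi"`` or
    ``"di"``.
    """

    anchor: tuple[str, int]
    target_segment: str
    target_range: tuple[int, int]
    sort_key: str = "mi"
    top_n: int = 10

    def __post_init__(self):
        seg, res = self.anchor
        if seg not in (SEGMENT_A, SEGMENT_B) or self.target_segment not in (
            SEGMENT_A,
            SEGMENT_B,
        ):
            raise ParameterError("anchor/target segments must be A or B")
        if seg == self.target_segment:
            raise ParameterError(
                "anchor and target segments must differ for an inter-protein query"
            )
        lo, hi = self.target_range
        if lo > hi or lo < 1:
            raise ParameterError(f"empty or invalid target range {self.target_range}")
        if self.sort_key not in ("mi", "di"):
            raise ParameterError(f"sort_key must be 'mi' or 'di', got {self.sort_key!r}")
        if self.top_n < 1:
            raise ParameterError(f"top_n must be >= 1, got {self.top_n}")
        if res < 1:
            raise ParameterError(f"anchor residue must be >= 1, got {res}")


def filter_proximal_pairs(table: PairScoreTable, min_sep: int = 5) -> PairScoreTable:
    """Remove rows with |i - j| <= min_sep (boundary included).

    Applied in concatenated coordinates *before* per-protein translation,
    so with a spacer at least ``min_sep`` wide it can only ever remove
    intra-protein neighbours.
    """
    if min_sep < 0:
        raise ParameterError(f"min_sep must be >= 0, got {min_sep}")
    frame = table.frame
    keep = (frame["i"] - frame["j"]).abs() > min_sep
    return PairScoreTable(frame.loc[keep].reset_index(drop=True))


def restrict_inter_protein(
    table: PairScoreTable, posmap: PositionMap
) -> list[AnnotatedPair]:
    """Keep only A-vs-B pairs and translate to per-protein numbering.

    Pairs touching a spacer column and intra-protein pairs are dropped.
    Because protein A columns precede protein B columns, the surviving
    pairs come out oriented (A residue, B residue).
    """
    out: list[AnnotatedPair] = []
    for row in table.frame.itertuples(index=False):
        seg_i, res_i = posmap.annotate(int(row.i))
        seg_j, res_j = posmap.annotate(int(row.j))
        if SEGMENT_SPACER in (seg_i, seg_j):
            continue
        if seg_i == seg_j:
            continue
        out.append(
            AnnotatedPair(seg_i, res_i, seg_j, res_j, float(row.mi), float(row.di))
        )
    return out


def rank_anchor_hits(
    pairs: list[AnnotatedPair], query: AnchorQuery
) -> list[AnnotatedPair]:
    """Top partners of the anchor within the target domain, best first.

    Returned pairs are re-oriented partner-first (partner residue in
    ``protein_i``/``res_i``, anchor in ``protein_j``/``res_j``), matching
    the layout of the ranking report.  Ties in the sort key break by
    ascending partner residue number, making the ranking deterministic and
    independent of input order.
    """
    aseg, ares = query.anchor
    lo, hi = query.target_range
    hits: list[AnnotatedPair] = []
    for p in pairs:
        if (p.protein_i, p.res_i) == (aseg, ares):
            partner_seg, partner_res = p.protein_j, p.res_j
        elif (p.protein_j, p.res_j) == (aseg, ares):
            partner_seg, partner_res = p.protein_i, p.res_i
        else:
            continue
        if partner_seg != query.target_segment or not lo <= partner_res <= hi:
            continue
        hits.append(
            AnnotatedPair(
                partner_seg, partner_res, aseg, ares, p.mi, p.di, p.distance
            )
        )
    if not hits:
        logger.warning(
            "anchor %s:%d has no scored partners in %s:%d-%d",
            aseg, ares, query.target_segment, lo, hi,
        )
        return []
    score = {"mi": lambda p: p.mi, "di": lambda p: p.di}[query.sort_key]
    hits.sort(key=lambda p: (-score(p), p.res_i))
    return hits[: query.top_n]


# ---------------------------------------------------------------------------
# Ranking reports
# ---------------------------------------------------------------------------

def write_ranking_report(rankings: list[AnnotatedPair], path) -> None:
    """Write a 5-column TSV: partner, anchor, MI, DI, distance (Å).

    MI/DI keep full precision so the report round-trips; a missing
    distance is written as ``NA``.
    """
    path = Path(path)
    with path.open("w") as fh:
        fh.write("partner\tanchor\tmi\tdi\tdistance\n")
        for p in rankings:
            dist = MISSING_DISTANCE if p.distance is None else f"{p.distance:.17g}"
            fh.write(
                f"{p.protein_i}:{p.res_i}\t{p.protein_j}:{p.res_j}\t"
                f"{p.mi:.17g}\t{p.di:.17g}\t{dist}\n"
            )


def _parse_residue(token: str) -> tuple[str, int]:
    try:
        seg, res = token.split(":")
        return seg, int(res)
    except ValueError:
        raise FormatError(f"malformed residue token {token!r}") from None


def read_ranking_report(path) -> list[AnnotatedPair]:
    """Read a report written by :func:`write_ranking_report`."""
    path = Path(path)
    lines = path.read_text().splitlines()
    if not lines or not lines[0].startswith("partner\t"):
        raise FormatError(f"{path} is not a ranking report (missing header)")
    out = []
    for ln in lines[1:]:
        if not ln.strip():
            continue
        fields = ln.split("\t")
        if len(fields) != 5:
            raise FormatError(f"{path}: expected 5 columns, got {len(fields)}: {ln!r}")
        (pseg, pres), (aseg, ares) = _parse_residue(fields[0]), _parse_residue(fields[1])
        dist = None if fields[4] == MISSING_DISTANCE else float(fields[4])
        out.append(
            AnnotatedPair(pseg, pres, aseg, ares, float(fields[2]), float(fields[3]), dist)
        )
    return out


def with_distance(pair: AnnotatedPair, distance: float | None) -> AnnotatedPair:
    """Return a copy of ``pair`` with the distance field set."""
    return replace(pair, distance=distance)
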