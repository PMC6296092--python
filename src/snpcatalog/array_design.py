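"""Genotyping-array candidate selection.

A fixed-size bead array can interrogate one SNP per probe, so candidates are
chosen one per gene, preferring the SNP the assay is most likely to convert.
A candidate must sit in locally "clean" sequence — no other polymorphism
(from either caller's raw call list, whatever its filter status) within 50 bp
on either side, since any underlying variant can disrupt probe annealing —
must lie at least 20 bp from both contig ends, and must carry an assay
functionality score of at least 0.60.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from .catalog import CallerVariant, ConsensusSNP
from .errors import ContigLookupError

__all__ = [
    "ArrayCandidate",
    "VariantIndex",
    "check_flank_cleanliness",
    "select_candidates",
]

DEFAULT_CLEAN_WINDOW = 50
DEFAULT_MIN_END_DISTANCE = 20
DEFAULT_MIN_SCORE = 0.60


@dataclass
class ArrayCandidate:
    contig_id: str
    pos: int
    gene_id: str | None
    functionality_score: float
    clean_flanks: bool
    end_distance_ok: bool
    score_ok: bool
    selected: bool = False

    @property
    def eligible(self) -> bool:
        return self.clean_flanks and self.end_distance_ok and self.score_ok


class VariantIndex:
    """Sorted per-contig position index over raw variant calls.

    Built from the union of both callers' variant lists (SNPs and indels
    alike), regardless of whether those calls later survived quality
    filtering.
    """

    def __init__(self, variants: Iterable[CallerVariant]) -> None:
        self._positions: dict[str, list[int]] = {}
        for v in variants:
            self._positions.setdefault(v.contig_id, []).append(v.pos)
        for contig_id, positions in self._positions.items():
            self._positions[contig_id] = sorted(set(positions))

    def contigs(self) -> set[str]:
        return set(self._positions)

    def neighbors_in_window(self, contig_id: str, pos: int, window: int) -> int:
        """Count variants within [pos - window, pos + window], excluding pos."""
        try:
            positions = self._positions[contig_id]
        except KeyError:
            raise ContigLookupError(
                f"contig {contig_id!r} absent from the variant index"
            ) from None
        lo = bisect.bisect_left(positions, pos - window)
        hi = bisect.bisect_right(positions, pos + window)
        in_window = hi - lo
        i = bisect.bisect_left(positions, pos)
        if i < len(positions) and positions[i] == pos:
            in_window -= 1
        return in_window


def check_flank_cleanliness(
    snp: ConsensusSNP, index: VariantIndex, window: int = DEFAULT_CLEAN_WINDOW
) -> bool:
    """True iff no other variant lies within ``window`` bp of the SNP.

    The window is closed on both sides: a neighbor exactly ``window`` bp away
    disqualifies the SNP (the stricter, probe-safe reading).
    """
    return index.neighbors_in_window(snp.contig_id, snp.pos, window) == 0


def _end_distance_ok(pos: int, contig_length: int, min_distance: int) -> bool:
    # distance to the nearer end: pos-1 bases before, L-pos after
    return min(pos - 1, contig_length - pos) >= min_distance


def select_candidates(
    snps: Sequence[ConsensusSNP],
    functionality_scores: Mapping[tuple[str, int], float],
    index: VariantIndex,
    contig_lengths: Mapping[str, int],
    *,
    per_gene: int = 1,
    clean_window: int = DEFAULT_CLEAN_WINDOW,
    min_end_distance: int = DEFAULT_MIN_END_DISTANCE,
    min_score: float = DEFAULT_MIN_SCORE,
) -> list[ArrayCandidate]:
    """Evaluate every catalog SNP and select at most ``per_gene`` per gene.

    Within a gene, eligible SNPs are preferred by highest functionality
    score, then highest MAF, then lowest position — a deterministic argmax
    independent of input order.  Returns one :class:`ArrayCandidate` per
    input SNP with its criteria flags; winners carry ``selected=True``.
    """
    candidates: list[ArrayCandidate] = []
    by_gene: dict[str, list[tuple[float, float, int, int]]] = {}
    for i, snp in enumerate(snps):
        score = functionality_scores.get((snp.contig_id, snp.pos), 0.0)
        cand = ArrayCandidate(
            contig_id=snp.contig_id,
            pos=snp.pos,
            gene_id=snp.gene_id,
            functionality_score=score,
            clean_flanks=check_flank_cleanliness(snp, index, clean_window),
            end_distance_ok=_end_distance_ok(
                snp.pos, contig_lengths[snp.contig_id], min_end_distance
            ),
            score_ok=score >= min_score,
        )
        candidates.append(cand)
        if cand.eligible and snp.gene_id is not None:
            by_gene.setdefault(snp.gene_id, []).append((-score, -snp.maf, snp.pos, i))
    for gene_id, entries in by_gene.items():
        for _, _, _, i in sorted(entries)[:per_gene]:
            candidates[i].selected = True
    return candidates
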