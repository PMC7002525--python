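"""Variant filtering and background copy-number assignment.

With typically ten-fold fewer SVs than SNVs in a tumour genome, each variant
carries more weight in clustering, so filtering is conservative: germline
support, too-small events, minimal read support and depth, and valid
copy-number states are all required before a breakpoint reaches the mixture
model.  Every rejection carries a machine-readable reason code so the filter
audit trail is reproducible.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

from .io_formats import (Breakend, Breakpoint, CNAnnotation, CNMap, Direction,
                         SampleMeta)
from .count import ReadCounts

log = logging.getLogger(__name__)

GERMLINE_WINDOW = 6  # bp tolerance for matching germline breakpoints


@dataclass(frozen=True)
class FilterParams:
    """Thresholds for the hard and optional filters.

    ``min_split``/``min_span`` are the minimum split and spanning reads per
    breakpoint; ``min_depth`` is the strict lower bound on supporting +
    normal reads per breakend; ``size_min`` (the fragment size) bounds
    intra-chromosomal event size; ``require_valid_cn`` rejects SVs with no
    valid copy-number state (major + minor >= 1) at either end when CN input
    is supplied.  ``neutral_only`` and ``exclude_subclonal_cn`` are the
    optional stricter criteria; ``blacklist`` is a list of half-open
    (chrom, start, end) regions any overlap with which rejects.
    """

    min_split: int = 1
    min_span: int = 1
    min_depth: float = 2.0
    germline_window: int = GERMLINE_WINDOW
    size_min: float | None = None  # defaults to insert_mean from SampleMeta
    require_valid_cn: bool = True
    neutral_only: bool = False
    exclude_subclonal_cn: bool = False
    blacklist: tuple = ()


def _ends_match(a: Breakpoint, b: Breakpoint, window: int) -> bool:
    """Same event: both breakends within window with matching directions."""
    def close(x: Breakend, y: Breakend) -> bool:
        return (x.chrom == y.chrom and abs(x.pos - y.pos) <= window
                and (x.direction == y.direction
                     or Direction.UNKNOWN in (x.direction, y.direction)))
    return close(a.lo, b.lo) and close(a.hi, b.hi)


def _in_blacklist(bp: Breakpoint, regions) -> bool:
    for chrom, start, end in regions:
        for e in bp.ends():
            if e.chrom == str(chrom) and start <= e.pos < end:
                return True
    return False


def _valid_state(ann: CNAnnotation) -> bool:
    """A copy-number state is valid when major + minor >= 1."""
    return any(s.total >= 1 for s in ann.states)


def assign_background_cn(bp: Breakpoint, cn_map: CNMap | None,
                         total_normal: float = 2.0
                         ) -> tuple[CNAnnotation, CNAnnotation, bool, bool]:
    """Background copy number (the state preceding the SV) for each breakend.

    Intra-chromosomal events take the segment upstream of the lower breakend
    and downstream of the upper breakend, so the interval between the
    breakends (the rearranged sequence itself) is never consulted.
    Inter-chromosomal breakends take the segment on the side opposite the
    breakend's direction, i.e. the side from which reference-supporting reads
    arrive.  Positions outside all segments fall back to the normal-ploidy
    default.  Returns (ann_lo, ann_hi, found_lo, found_hi).
    """
    if cn_map is None:
        default = CNAnnotation.default(total_normal)
        return default, default, False, False

    def query_side(end: Breakend, upstream: bool):
        pos = end.pos - 1 if upstream else end.pos + 1
        ann, found = cn_map.query_or_default(end.chrom, max(1, pos))
        if not found:
            log.warning("no CN segment at %s:%d; normal-ploidy default used",
                        end.chrom, pos)
        return ann, found

    if bp.intrachromosomal:
        ann_lo, found_lo = query_side(bp.lo, upstream=True)
        ann_hi, found_hi = query_side(bp.hi, upstream=False)
    else:
        # opposite the clip side: '+' clips right -> background is upstream
        ann_lo, found_lo = query_side(bp.lo, bp.lo.direction is not Direction.MINUS)
        ann_hi, found_hi = query_side(bp.hi, bp.hi.direction is not Direction.MINUS)
    return ann_lo, ann_hi, found_lo, found_hi


def apply_filters(svs: list[tuple[Breakpoint, ReadCounts]],
                  meta: SampleMeta,
                  germline: list[tuple[Breakpoint, ReadCounts]] | None = None,
                  cn_map: CNMap | None = None,
                  params: FilterParams | None = None,
                  total_normal: float = 2.0):
    """Split counted SVs into (kept, rejected) with reason codes.

    ``kept`` is a list of (Breakpoint, ReadCounts, CNAnnotation_lo,
    CNAnnotation_hi); ``rejected`` a list of (Breakpoint, reason).  Reasons:
    ``germline``, ``size``, ``min_support``, ``min_depth``, ``invalid_cn``,
    ``non_neutral_cn``, ``subclonal_cn``, ``blacklist``, ``high_depth``,
    ``complex``.  The kept set is independent of input order.
    """
    params = params or FilterParams()
    size_min = params.size_min if params.size_min is not None else meta.insert_mean
    germline_hits = [g for g, gc in (germline or []) if gc.support >= 1]

    kept, rejected = [], []
    for bp, counts in svs:
        reason = None
        ann_lo, ann_hi, found_lo, found_hi = assign_background_cn(
            bp, cn_map, total_normal)
        if bp.svclass.name == "COMPLEX":
            reason = "complex"
        elif counts.high_depth_flag:
            reason = "high_depth"
        elif _in_blacklist(bp, params.blacklist):
            reason = "blacklist"
        elif any(_ends_match(bp, g, params.germline_window) for g in germline_hits):
            reason = "germline"
        elif bp.intrachromosomal and bp.span <= size_min:
            reason = "size"
        elif (counts.split_lo + counts.split_hi < params.min_split
              or counts.spanning < params.min_span):
            reason = "min_support"
        elif (counts.depth_lo <= params.min_depth
              or counts.depth_hi <= params.min_depth):
            reason = "min_depth"
        elif cn_map is not None and params.require_valid_cn and not (
                (found_lo and _valid_state(ann_lo))
                or (found_hi and _valid_state(ann_hi))):
            reason = "invalid_cn"
        elif params.neutral_only and not all(
                len(a.states) == 1 and a.states[0].major == 1
                and a.states[0].minor == 1 for a in (ann_lo, ann_hi)):
            reason = "non_neutral_cn"
        elif params.exclude_subclonal_cn and (ann_lo.subclonal or ann_hi.subclonal):
            reason = "subclonal_cn"

        if reason is None:
            # an invalid end falls back to the default annotation, flagged
            if cn_map is not None and found_lo and not _valid_state(ann_lo):
                ann_lo = CNAnnotation.default(total_normal)
            if cn_map is not None and found_hi and not _valid_state(ann_hi):
                ann_hi = CNAnnotation.default(total_normal)
            kept.append((bp, counts, ann_lo, ann_hi))
        else:
            rejected.append((bp, reason))
    log.info("filter: %d kept, %d rejected", len(kept), len(rejected))
    return kept, rejected
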