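"""Read classification and counting at SV breakends.

Every fragment (read pair) near a breakend is placed in exactly one category
per breakend:

* **split** — one read's soft-clip boundary falls at the breakend (within a
  positional window absorbing micro-homology), the clip is longer than the
  soft-clip threshold, and the clip lies on the side named by the breakend's
  direction (``+`` = clip right of the locus, ``-`` = clip left);
* **spanning** — the mates flank the junction, each on the joined side of its
  breakend, both oriented toward the break, with an adjusted insert size
  (sum of each mate's outer-end distance to its breakend) under the insert
  cap ``mu_ins + 3 sigma_ins``;
* **normal** — the read or its insert crosses the locus with at least
  ``norm_overlap`` bases on each side, soft-clipped at most ``norm_clip_max``
  bases, in a proper orientation within the insert cap;
* **anomalous** — crosses the boundary but fits no category (oversized
  insert, mates not facing the break, double-clipped, sub-threshold clip, or
  support in the direction opposite the called breakend);
* **irrelevant** — does not cross the boundary region at all.

Split and spanning reads together form the supporting count ``b = s_l + s_u
+ c``, used as the binomial numerator at both ends with side-specific normal
counts as the remainder of the trials (``d_i = b + o_i``).  A ``per_side``
support mode (``b_i = s_i + c``) is available for sensitivity analyses.
"""
from __future__ import annotations

from dataclasses import dataclass, replace
from enum import Enum

from .io_formats import (GAIN_CLASSES, Breakend, Breakpoint, Direction,
                         SampleMeta, SVClass)

WINDOW = 6          # positional tolerance around a breakend (bp)
NORM_OVERLAP = 10   # min bases on each side of the locus for a normal read
NORM_CLIP_MAX = 6   # max soft-clip length tolerated on a normal read


class ReadCategory(str, Enum):
    SPLIT = "split"
    SPANNING = "spanning"
    NORMAL = "normal"
    ANOMALOUS = "anomalous"
    IRRELEVANT = "irrelevant"


@dataclass
class ReadCounts:
    """Per-breakpoint read tallies.

    ``split_lo``/``split_hi`` are split reads at each breakend, ``spanning``
    the discordant pairs bridging the junction, ``norm_lo``/``norm_hi`` the
    reference-supporting reads per end, and ``anomalous`` the boundary
    crossers in no category.  Normal counts are real-valued because the
    DNA-gain adjustment scales them.
    """

    split_lo: int = 0
    split_hi: int = 0
    spanning: int = 0
    norm_lo: float = 0.0
    norm_hi: float = 0.0
    anomalous: int = 0
    high_depth_flag: bool = False
    adjusted: bool = False
    support_mode: str = "total"

    @property
    def support(self) -> int:
        """Total supporting reads b = s_l + s_u + c."""
        return self.split_lo + self.split_hi + self.spanning

    def _support_at(self, side: str) -> float:
        if self.support_mode == "per_side":
            split = self.split_lo if side == "lo" else self.split_hi
            return split + self.spanning
        return self.support

    @property
    def depth_lo(self) -> float:
        return self._support_at("lo") + self.norm_lo

    @property
    def depth_hi(self) -> float:
        return self._support_at("hi") + self.norm_hi


@dataclass(frozen=True)
class SideEvidence:
    """Supporting reads and depth at one breakend."""

    b: float
    d: float
    adjusted: bool = False

    @property
    def vaf(self) -> float:
        if self.d <= 0:
            raise ValueError("VAF undefined at zero depth")
        return self.b / self.d


# ---------------------------------------------------------------------------
# fragment-level classification
# ---------------------------------------------------------------------------

def _clips(read) -> tuple[int, int]:
    """(left, right) soft-clip lengths of an aligned read."""
    cigar = read.cigartuples or []
    left = cigar[0][1] if cigar and cigar[0][0] == 4 else 0
    right = cigar[-1][1] if cigar and cigar[-1][0] == 4 else 0
    return left, right


def _is_split(read, be: Breakend, clip_min: int, window: int):
    """None, or True (direction-matching split) / False (opposite-direction
    support at this locus)."""
    if read.reference_name != be.chrom:
        return None
    left, right = _clips(read)
    p0 = be.pos - 1  # 0-based base index of the breakend
    if left > clip_min and right > clip_min:
        return None  # double-clipped: handled as anomalous by the caller
    # '+' breakend: read aligns up to the locus from the left, clip on right
    if right > 0 and abs(read.reference_end - (p0 + 1)) <= window:
        if right <= clip_min:
            return None
        return be.direction is Direction.PLUS
    if left > 0 and abs(read.reference_start - p0) <= window:
        if left <= clip_min:
            return None
        return be.direction is Direction.MINUS
    return None


def _has_subthreshold_clip_at(read, be: Breakend, clip_min: int, window: int) -> bool:
    left, right = _clips(read)
    p0 = be.pos - 1
    if 0 < right <= clip_min and abs(read.reference_end - (p0 + 1)) <= window:
        return True
    if 0 < left <= clip_min and abs(read.reference_start - p0) <= window:
        return True
    return False


def _faces_break(read, be: Breakend) -> bool:
    """True when the read sits on the joined side of the breakend and points
    toward the junction."""
    if read.reference_name != be.chrom:
        return False
    p0 = be.pos - 1
    if be.direction is Direction.PLUS:
        # joined sequence lies left of the locus; read on forward strand
        return (not read.is_reverse) and read.reference_end <= p0 + 1 + WINDOW
    if be.direction is Direction.MINUS:
        return read.is_reverse and read.reference_start >= p0 - WINDOW
    return False


def _distance_to_break(read, be: Breakend) -> int:
    """Outer-end distance of a break-facing read to its breakend."""
    p0 = be.pos - 1
    if be.direction is Direction.PLUS:
        return (p0 + 1) - read.reference_start
    return read.reference_end - p0


def _fragment_span(frag) -> tuple[str, int, int] | None:
    """Outer span of a same-chromosome fragment, or None."""
    chroms = {r.reference_name for r in frag}
    if len(chroms) != 1:
        return None
    start = min(r.reference_start for r in frag)
    end = max(r.reference_end for r in frag)
    return chroms.pop(), start, end


def _is_normal(frag, be: Breakend, meta: SampleMeta, norm_overlap: int,
               norm_clip_max: int) -> bool:
    span = _fragment_span(frag)
    if span is None or span[0] != be.chrom:
        return False
    _, start, end = span
    p0 = be.pos - 1
    if (p0 - start + 1) < norm_overlap or (end - p0) < norm_overlap:
        return False
    if any(max(_clips(r)) > norm_clip_max for r in frag):
        return False
    if end - start >= meta.max_insert:
        return False
    if len(frag) == 2:
        fwd = [r for r in frag if not r.is_reverse]
        rev = [r for r in frag if r.is_reverse]
        if len(fwd) != 1:  # must be a forward/reverse pair
            return False
        if fwd[0].reference_start > rev[0].reference_start:
            return False
    return True


def _crosses_boundary(frag, be: Breakend, window: int) -> bool:
    span = _fragment_span(frag)
    if span is not None and span[0] == be.chrom:
        _, start, end = span
        p0 = be.pos - 1
        if start - window <= p0 <= end - 1 + window:
            return True
    # clipped at or near the locus also counts as touching the boundary
    return any(r.reference_name == be.chrom
               and min(abs(r.reference_start - (be.pos - 1)),
                       abs(r.reference_end - be.pos)) <= window
               for r in frag)


def _is_spanning(frag, lo: Breakend, hi: Breakend, meta: SampleMeta) -> bool:
    if len(frag) != 2:
        return False
    for a, b in ((frag[0], frag[1]), (frag[1], frag[0])):
        if _faces_break(a, lo) and _faces_break(b, hi):
            adj_insert = _distance_to_break(a, lo) + _distance_to_break(b, hi)
            if 0 < adj_insert < meta.max_insert:
                return True
    return False


def classify_read(frag, be: Breakend, meta: SampleMeta,
                  partner: Breakend | None = None,
                  clip_min: int | None = None, window: int = WINDOW,
                  norm_overlap: int = NORM_OVERLAP,
                  norm_clip_max: int = NORM_CLIP_MAX) -> ReadCategory:
    """Classify one fragment (list of 1-2 aligned reads) at a breakend.

    ``partner`` is the other breakend of the breakpoint; it is required to
    recognise spanning pairs.
    """
    frag = list(frag)
    if clip_min is None:
        clip_min = meta.clip_min

    double_clipped = any(left > norm_clip_max and right > norm_clip_max
                         for left, right in map(_clips, frag))
    split_votes = [v for v in (_is_split(r, be, clip_min, window) for r in frag)
                   if v is not None]
    if split_votes and not double_clipped:
        if any(split_votes):
            return ReadCategory.SPLIT
        return ReadCategory.ANOMALOUS  # opposite-direction support

    if partner is not None and not double_clipped:
        in_order = (be, partner) if be.pos <= partner.pos or be.chrom != partner.chrom \
            else (partner, be)
        if _is_spanning(frag, *in_order, meta):
            return ReadCategory.SPANNING

    if not double_clipped and _is_normal(frag, be, meta, norm_overlap, norm_clip_max):
        return ReadCategory.NORMAL

    if _crosses_boundary(frag, be, window) or any(
            _has_subthreshold_clip_at(r, be, clip_min, window) for r in frag):
        return ReadCategory.ANOMALOUS
    return ReadCategory.IRRELEVANT


# ---------------------------------------------------------------------------
# per-SV counting
# ---------------------------------------------------------------------------

def _fetch_fragments(alignments, chrom: str, pos: int, meta: SampleMeta):
    pad = int(meta.max_insert)
    start = max(0, pos - 1 - pad)
    try:
        reads = list(alignments.fetch(chrom, start, pos + pad))
    except ValueError as exc:
        raise IOError(f"cannot fetch reads at {chrom}:{pos}: {exc}") from exc
    frags: dict[str, list] = {}
    for read in reads:
        if read.is_unmapped or read.is_secondary or read.is_supplementary:
            continue
        frags.setdefault(read.query_name, []).append(read)
    return frags


def _mean_depth(alignments, chrom: str, pos: int, width: int = 50) -> float:
    start = max(0, pos - 1 - width)
    try:
        n = alignments.count(chrom, start, pos + width)
    except ValueError:
        return 0.0
    return n * 1.0  # reads overlapping the window ~ depth at typical read len


def count_sv(bp: Breakpoint, alignments, meta: SampleMeta,
             clip_min: int | None = None, window: int = WINDOW,
             norm_overlap: int = NORM_OVERLAP, norm_clip_max: int = NORM_CLIP_MAX,
             support_mode: str = "total") -> ReadCounts:
    """Tally split/spanning/normal/anomalous reads for one breakpoint.

    Fragments are fetched around both breakends, merged by read name so that
    each fragment contributes to at most one category per breakend, and
    classified by :func:`classify_read`.  The ``high_depth_flag`` is set when
    the mean read depth at either end exceeds ``expected_depth * max_cn``
    (likely repeat regions, excluded downstream).
    """
    if bp.svclass is SVClass.COMPLEX:
        raise ValueError(f"{bp.id}: complex events are not counted")
    frags_lo = _fetch_fragments(alignments, bp.lo.chrom, bp.lo.pos, meta)
    frags_hi = _fetch_fragments(alignments, bp.hi.chrom, bp.hi.pos, meta)
    all_names = set(frags_lo) | set(frags_hi)

    counts = ReadCounts(support_mode=support_mode)
    for name in all_names:
        frag = {r.reference_start: r for r in
                frags_lo.get(name, []) + frags_hi.get(name, [])}
        frag = sorted(frag.values(), key=lambda r: (r.reference_name, r.reference_start))
        cat_lo = classify_read(frag, bp.lo, meta, partner=bp.hi, clip_min=clip_min,
                               window=window, norm_overlap=norm_overlap,
                               norm_clip_max=norm_clip_max)
        cat_hi = classify_read(frag, bp.hi, meta, partner=bp.lo, clip_min=clip_min,
                               window=window, norm_overlap=norm_overlap,
                               norm_clip_max=norm_clip_max)
        if ReadCategory.SPLIT in (cat_lo, cat_hi):
            if cat_lo is ReadCategory.SPLIT:
                counts.split_lo += 1
            else:
                counts.split_hi += 1
        elif ReadCategory.SPANNING in (cat_lo, cat_hi):
            counts.spanning += 1
        else:
            if cat_lo is ReadCategory.NORMAL:
                counts.norm_lo += 1
            if cat_hi is ReadCategory.NORMAL:
                counts.norm_hi += 1
            if ReadCategory.ANOMALOUS in (cat_lo, cat_hi) and \
                    cat_lo is not ReadCategory.NORMAL and \
                    cat_hi is not ReadCategory.NORMAL:
                counts.anomalous += 1

    cap = meta.expected_depth * meta.max_cn
    if (_mean_depth(alignments, bp.lo.chrom, bp.lo.pos) > cap
            or _mean_depth(alignments, bp.hi.chrom, bp.hi.pos) > cap):
        counts.high_depth_flag = True
    return counts


def softclip_evidence(alignments, be: Breakend, meta: SampleMeta,
                      window: int = WINDOW):
    """Count soft-clipped reads on each side of a locus (for direction
    inference): clips ending at the locus from the left leave their clipped
    portion on the right and vice versa."""
    from .annotate import SoftclipEvidence

    left = right = 0
    p0 = be.pos - 1
    for reads in _fetch_fragments(alignments, be.chrom, be.pos, meta).values():
        for r in reads:
            lcl, rcl = _clips(r)
            if rcl > 0 and abs(r.reference_end - (p0 + 1)) <= window:
                right += 1
            elif lcl > 0 and abs(r.reference_start - p0) <= window:
                left += 1
    return SoftclipEvidence(n_clip_left=left, n_clip_right=right)


def adjust_normals(counts: ReadCounts, svclass: SVClass,
                   meta: SampleMeta) -> ReadCounts:
    """Scale normal read counts of DNA-gain events by ``1 - t/n_p``.

    Duplication-class SVs retain normal reads on the duplicated allele, so
    their raw normal counts overestimate the reference-supporting depth; the
    adjustment factor removes the expected share of tumour-derived normal
    reads.  Non-gain classes are returned unchanged.
    """
    if svclass not in GAIN_CLASSES:
        return counts
    factor = 1.0 - meta.purity / meta.ploidy
    if factor < 0:
        factor = 0.0
    return replace(counts, norm_lo=counts.norm_lo * factor,
                   norm_hi=counts.norm_hi * factor, adjusted=True)


def compute_vaf(counts: ReadCounts) -> tuple[SideEvidence, SideEvidence]:
    """Per-end supporting evidence and VAF: ``vaf_i = b / (b + o_i)``."""
    out = []
    for side in ("lo", "hi"):
        b = counts._support_at(side)
        o = counts.norm_lo if side == "lo" else counts.norm_hi
        out.append(SideEvidence(b=b, d=b + o, adjusted=counts.adjusted))
    return tuple(out)
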