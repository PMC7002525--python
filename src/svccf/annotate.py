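"""Breakend directionality inference and SV classification.

Directionality of a breakend records which side of the locus connects to the
distant partner: reads supporting a ``+`` breakend align up to the position
from the left and carry their soft-clip on the right; ``-`` is the mirror.
When soft-clips pile up on both sides of a locus (at least 10% of clipped
reads on the minority side) the evidence is mixed and multiple breakend pairs
are involved; these events are resolved against the rest of the SV input or
flagged complex.  SVs are classified into six rearrangement categories from
directionality and partner geometry.
"""
from __future__ import annotations

from dataclasses import dataclass, replace

from .io_formats import Breakend, Breakpoint, Direction, SVClass

MIXED_MINORITY_FRAC = 0.10  # minority clip side must hold >= 10% of clips


@dataclass(frozen=True)
class SoftclipEvidence:
    """Soft-clip counts on each side of a locus.

    ``n_clip_left`` counts reads whose clipped portion lies to the left of
    the locus (supporting a ``-`` breakend); ``n_clip_right`` those clipped to
    the right (supporting ``+``).
    """

    n_clip_left: int = 0
    n_clip_right: int = 0

    def __post_init__(self):
        if self.n_clip_left < 0 or self.n_clip_right < 0:
            raise ValueError("clip counts must be non-negative")


def infer_direction(ev: SoftclipEvidence) -> Direction:
    """Infer a breakend's direction from soft-clip side counts.

    Unanimous evidence gives ``+`` (clips on the right) or ``-``; when the
    minority side holds at least 10% of all clipped reads the direction is
    ``MIXED``; no evidence gives ``UNKNOWN``.
    """
    total = ev.n_clip_left + ev.n_clip_right
    if total == 0:
        return Direction.UNKNOWN
    minority = min(ev.n_clip_left, ev.n_clip_right)
    if minority / total >= MIXED_MINORITY_FRAC:
        return Direction.MIXED
    return Direction.PLUS if ev.n_clip_right > ev.n_clip_left else Direction.MINUS


def _matches(a: Breakend, b: Breakend, window: int) -> bool:
    return a.chrom == b.chrom and abs(a.pos - b.pos) <= window


def _with_dirs(bp: Breakpoint, lo_dir: Direction, hi_dir: Direction,
               suffix: str = "") -> Breakpoint:
    return Breakpoint(id=bp.id + suffix,
                      lo=replace(bp.lo, direction=lo_dir),
                      hi=replace(bp.hi, direction=hi_dir),
                      svclass=bp.svclass)


def _match_partners(bp: Breakpoint, others: list[Breakpoint], window: int):
    """Partners sharing a breakend locus (within window) with bp."""
    hits = []
    for other in others:
        if other.id == bp.id:
            continue
        shared = sum(1 for e1 in bp.ends() for e2 in other.ends()
                     if _matches(e1, e2, window))
        if shared:
            hits.append(other)
    return hits


def _rank_pattern(group: list[Breakpoint], window: int):
    """Positional ranks of each breakpoint's loci among the group's distinct
    loci (1 = leftmost), merging loci that coincide within the window."""
    loci = sorted({e.pos for bp in group for e in bp.ends()})
    rank, current = {}, 0
    prev = None
    for p in loci:
        if prev is None or p - prev > window:
            current += 1
        rank[p] = current
        prev = p
    return [(rank[bp.lo.pos], rank[bp.hi.pos]) for bp in group]


def resolve_mixed(svs: list[Breakpoint], match_window: int = 6) -> list[Breakpoint]:
    """Resolve breakpoints whose breakends have mixed directionality.

    One mixed end only: the event is split into a ``(-,-)`` and a ``(+,+)``
    duplicate.  Both ends mixed: (i) no partner in the input matches either
    locus -> emit ``(-,-)`` plus a ``(+,+)`` duplicate; (ii) both loci match
    one partner -> first pair by input order becomes ``(-,-)``, the partner
    ``(+,+)``; (iii) three same-chromosome breakpoints whose positional ranks
    form [(1,2),(2,3),(1,3)] -> an intra-chromosomal translocation pattern
    with directions [(+,-),(+,-),(-,+)]; (iv) more than two matching partners
    -> all flagged COMPLEX (discarded at the count step).

    Loci are never changed, only directions, classes and ids; the SV count is
    conserved or increased.
    """
    out: list[Breakpoint] = []
    handled: set[str] = set()

    for bp in svs:
        if bp.id in handled:
            continue
        lo_mixed = bp.lo.direction is Direction.MIXED
        hi_mixed = bp.hi.direction is Direction.MIXED
        if not (lo_mixed or hi_mixed):
            out.append(bp)
            continue
        if lo_mixed != hi_mixed:
            # one mixed end: split into two events
            out.append(_with_dirs(bp, Direction.MINUS, Direction.MINUS, "_m"))
            out.append(_with_dirs(bp, Direction.PLUS, Direction.PLUS, "_p"))
            handled.add(bp.id)
            continue

        partners = _match_partners(bp, svs, match_window)
        if len(partners) == 0:  # scenario (i)
            out.append(_with_dirs(bp, Direction.MINUS, Direction.MINUS, "_m"))
            out.append(_with_dirs(bp, Direction.PLUS, Direction.PLUS, "_p"))
            handled.add(bp.id)
        elif len(partners) == 1 and all(
                any(_matches(e1, e2, match_window) for e2 in partners[0].ends())
                for e1 in bp.ends()):
            # scenario (ii): assignment by file order, first pair (-,-)
            out.append(_with_dirs(bp, Direction.MINUS, Direction.MINUS))
            out.append(_with_dirs(partners[0], Direction.PLUS, Direction.PLUS))
            handled.update({bp.id, partners[0].id})
        elif len(partners) == 2:
            group = sorted([bp, *partners], key=lambda b: (b.lo.pos, b.hi.pos))
            same_chrom = len({e.chrom for g in group for e in g.ends()}) == 1
            pattern = _rank_pattern(group, match_window)
            if same_chrom and sorted(pattern) == [(1, 2), (1, 3), (2, 3)]:
                # scenario (iii): translocation signature; the breakpoint
                # spanning the outer loci (1,3) takes (-,+), the others (+,-)
                dir_by_rank = {(1, 2): (Direction.PLUS, Direction.MINUS),
                               (2, 3): (Direction.PLUS, Direction.MINUS),
                               (1, 3): (Direction.MINUS, Direction.PLUS)}
                for g, ranks in zip(group, pattern):
                    dl, dh = dir_by_rank[ranks]
                    out.append(_with_dirs(g, dl, dh))
                    handled.add(g.id)
            else:
                for g in group:
                    out.append(replace(g, svclass=SVClass.COMPLEX))
                    handled.add(g.id)
        else:  # scenario (iv): > 2 matches
            out.append(replace(bp, svclass=SVClass.COMPLEX))
            handled.add(bp.id)
            for p in partners:
                out.append(replace(p, svclass=SVClass.COMPLEX))
                handled.add(p.id)
    return out


def classify_sv(bp: Breakpoint, partners: list[Breakpoint] | None = None,
                pos_tol: int = 100, del_tol: int = 6) -> SVClass:
    """Classify an SV from breakend directionality and partner geometry.

    Rules, in order: inter-chromosomal loci -> INTRX (no direction check);
    matching directions -> INV; ``(+,-)`` with l < u -> DEL; ``(-,+)`` with
    l < u -> DUP, promoted to INTDUP when a partner with a deletion signature
    shares the lower breakend within ``pos_tol`` but differs at the upper, and
    to TRX when a third deletion-signature breakpoint additionally spans the
    mobile element with both ends within ``del_tol``.  Anything else is
    UNKNOWN.  The result is invariant to the order of ``partners``.
    """
    if bp.svclass is SVClass.COMPLEX:
        return SVClass.COMPLEX
    partners = partners or []
    ld, ud = bp.lo.direction, bp.hi.direction
    if not bp.intrachromosomal:
        return SVClass.INTRX
    if ld is Direction.UNKNOWN or ud is Direction.UNKNOWN:
        return SVClass.UNKNOWN
    if ld == ud and ld in (Direction.PLUS, Direction.MINUS):
        return SVClass.INV

    sig = (ld, ud)
    dup_sig = (Direction.MINUS, Direction.PLUS)
    del_sig = (Direction.PLUS, Direction.MINUS)

    def _dup_partner_pair(a: Breakpoint, b: Breakpoint) -> bool:
        """a has the DUP signature, b the DEL signature, lower ends within
        pos_tol, upper ends distinct."""
        return (b.intrachromosomal and b.lo.chrom == a.lo.chrom
                and (b.lo.direction, b.hi.direction) == del_sig
                and abs(a.lo.pos - b.lo.pos) <= pos_tol
                and a.hi.pos != b.hi.pos)

    if sig == dup_sig:
        mates = [p for p in partners if _dup_partner_pair(bp, p)]
        if not mates:
            return SVClass.DUP
        # TRX needs a third deletion-signature breakpoint spanning the mobile
        # element: l3 ~ u2(del mate), u3 ~ u1, both within del_tol
        for mate in mates:
            for third in partners:
                if third.id in (bp.id, mate.id) or not third.intrachromosomal:
                    continue
                if ((third.lo.direction, third.hi.direction) == del_sig
                        and third.lo.chrom == bp.lo.chrom
                        and abs(third.lo.pos - mate.hi.pos) <= del_tol
                        and abs(third.hi.pos - bp.hi.pos) <= del_tol):
                    return SVClass.TRX
        return SVClass.INTDUP

    if sig == del_sig:
        # the deletion-signature member of an interspersed-duplication pair
        dup_mates = [p for p in partners
                     if p.intrachromosomal and p.lo.chrom == bp.lo.chrom
                     and (p.lo.direction, p.hi.direction) == dup_sig
                     and _dup_partner_pair(p, bp)]
        if not dup_mates:
            return SVClass.DEL
        for mate in dup_mates:
            for third in partners:
                if third.id in (bp.id, mate.id) or not third.intrachromosomal:
                    continue
                if ((third.lo.direction, third.hi.direction) == del_sig
                        and abs(third.lo.pos - bp.hi.pos) <= del_tol
                        and abs(third.hi.pos - mate.hi.pos) <= del_tol):
                    return SVClass.TRX
        return SVClass.INTDUP

    return SVClass.UNKNOWN


def annotate_all(svs: list[Breakpoint], match_window: int = 6,
                 pos_tol: int = 100, del_tol: int = 6,
                 trust_caller: bool = True) -> list[Breakpoint]:
    """Resolve mixed directions then classify every SV against its cohort.

    Caller-provided classifications are kept when ``trust_caller`` is set.
    """
    resolved = resolve_mixed(svs, match_window=match_window)
    out = []
    for bp in resolved:
        if trust_caller and bp.svclass not in (SVClass.UNKNOWN,):
            out.append(bp)
            continue
        cls = classify_sv(bp, [p for p in resolved if p.id != bp.id],
                          pos_tol=pos_tol, del_tol=del_tol)
        out.append(replace(bp, svclass=cls))
    return out
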