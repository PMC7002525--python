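"""Synthetic data with known truth: count-level SV datasets, two-sample
mixtures, alignment fixtures and copy-number perturbations.

The count-level generator draws read counts directly from the clustering
model's forward process: each SV belongs to a clone with CCF ``phi``, its
per-end success probability is ``f = w(m) phi + eps`` with the weight
computed from the (possibly subclonal) background copy number, depths are
Poisson around the target coverage and supporting counts binomial.
DNA-gain classes additionally receive inflated raw normal counts (the
duplicated allele keeps its reference-supporting reads), so the purity/
ploidy adjustment in the counting step can be exercised end to end.

Two-sample mixtures emulate combining two clonal samples at proportion
``pA``: shared variants stay clonal (CCF 1), sample-private variants drop
to CCF ``pA`` or ``1 - pA``, reproducing the branching three-cluster truth
of an in-silico tumour mix.

The alignment generator writes small sorted+indexed BAMs realising exact
split/spanning/normal/anomalous counts per the read-classification
contracts, closing the loop with the counting step without any external
read simulator.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .io_formats import (GAIN_CLASSES, Breakpoint, CNAnnotation, CNState,
                         Direction, SampleMeta, SVClass)
from .model import compute_weight, multiplicity_candidates

log = logging.getLogger(__name__)

#: default rearrangement class mix (equal over the four basic classes)
DEFAULT_CLASS_MIX = {"DEL": 0.25, "DUP": 0.25, "INV": 0.25, "INTRX": 0.25}


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for one synthetic sample.

    ``n_sv`` SVs per clone at the given ``clone_ccfs``; coverage ``depth``
    per breakend (Poisson unless ``fixed_depth``); ``subclonal_cn_frac`` of
    breakends receive a two-state subclonal background (primary state drawn
    from ``cn_states`` at fraction ``rho``, the remainder diploid).
    """

    n_sv: tuple[int, ...] = (100,)
    clone_ccfs: tuple[float, ...] = (1.0,)
    purity: float = 0.75
    ploidy: float = 2.0
    depth: float = 50.0
    error_rate: float = 1e-3
    class_mix: dict = field(default_factory=lambda: dict(DEFAULT_CLASS_MIX))
    cn_states: tuple[tuple[float, float], ...] = ((1, 1),)
    subclonal_cn_frac: float = 0.0
    rho: float = 0.7
    fixed_depth: bool = False
    seed: int = 0

    def __post_init__(self):
        if len(self.n_sv) != len(self.clone_ccfs):
            raise ValueError("n_sv and clone_ccfs must have equal length")
        if any(not (0 < c <= 1) for c in self.clone_ccfs):
            raise ValueError("clone CCFs must be in (0, 1]")
        if abs(sum(self.class_mix.values()) - 1.0) > 1e-9:
            raise ValueError("class mix proportions must sum to 1")

    def meta(self) -> SampleMeta:
        return SampleMeta(purity=self.purity, ploidy=self.ploidy,
                          error_rate=self.error_rate,
                          expected_depth=self.depth)


_CN_COLS = [f"{side}_{fld}{c}" for side in ("lo", "hi")
            for c in (1, 2) for fld in ("maj", "min", "frac")]


def _draw_cn(rng: np.random.Generator, cfg: SimConfig) -> CNAnnotation:
    maj, minor = cfg.cn_states[rng.integers(len(cfg.cn_states))]
    if rng.random() < cfg.subclonal_cn_frac:
        rho = cfg.rho
        return CNAnnotation((CNState(maj, minor, rho), CNState(1, 1, 1 - rho)))
    return CNAnnotation((CNState(maj, minor, 1.0),))


def _cn_to_row(ann: CNAnnotation, side: str) -> dict:
    row = {}
    for c, state in enumerate(ann.states, start=1):
        row[f"{side}_maj{c}"] = state.major
        row[f"{side}_min{c}"] = state.minor
        row[f"{side}_frac{c}"] = state.frac
    return row


def cn_from_row(row, side: str) -> CNAnnotation:
    """Rebuild a breakend's CNAnnotation from dataset columns."""
    states = [CNState(row[f"{side}_maj1"], row[f"{side}_min1"],
                      row[f"{side}_frac1"])]
    frac2 = row.get(f"{side}_frac2")
    if frac2 is not None and not pd.isna(frac2):
        states.append(CNState(row[f"{side}_maj2"], row[f"{side}_min2"], frac2))
    return CNAnnotation(tuple(states))


def annotations_from_dataset(df: pd.DataFrame):
    """(cn_lo, cn_hi) annotation lists for the clustering model."""
    cn_lo = [cn_from_row(row, "lo") for _, row in df.iterrows()]
    cn_hi = [cn_from_row(row, "hi") for _, row in df.iterrows()]
    return cn_lo, cn_hi


def _draw_counts(rng, cfg: SimConfig, meta: SampleMeta, phi: float,
                 ann: CNAnnotation, m: float):
    """(b, d_adjusted, o_raw) for one breakend."""
    w = compute_weight(m, ann, meta)
    f = np.clip(w * phi + cfg.error_rate, 0.0, 1.0)
    d = cfg.depth if cfg.fixed_depth else rng.poisson(cfg.depth)
    d = max(int(d), 1)
    b = rng.binomial(d, f)
    return b, d, d - b


def _simulate_variant(rng, cfg: SimConfig, meta: SampleMeta, vid: str,
                      phi: float, cluster: int, svclass: str,
                      ann_lo: CNAnnotation, ann_hi: CNAnnotation) -> dict:
    # multiplicity: uniform over positive candidates (shared by both ends
    # when the annotations coincide, else drawn per end)
    def draw_m(ann):
        cands = multiplicity_candidates(ann)
        pos = cands[cands > 0]
        return float(rng.choice(pos))

    m_lo = draw_m(ann_lo)
    m_hi = m_lo if ann_hi == ann_lo else draw_m(ann_hi)
    b1, d1, o1 = _draw_counts(rng, cfg, meta, phi, ann_lo, m_lo)
    b2, d2, o2 = _draw_counts(rng, cfg, meta, phi, ann_hi, m_hi)

    gain = SVClass(svclass) in GAIN_CLASSES
    af_norm = 1.0 - meta.purity / meta.ploidy
    if gain and af_norm > 0:
        # the duplicated allele keeps its normal reads: raw counts inflate
        o1_raw, o2_raw = round(o1 / af_norm), round(o2 / af_norm)
    else:
        o1_raw, o2_raw = o1, o2

    row = {"id": vid, "svclass": svclass,
           "b1": b1, "d1": d1, "b2": b2, "d2": d2,
           "norm1_raw": o1_raw, "norm2_raw": o2_raw,
           "m_lo_true": m_lo, "m_hi_true": m_hi}
    row.update(_cn_to_row(ann_lo, "lo"))
    row.update(_cn_to_row(ann_hi, "hi"))
    return row


def simulate_counts(cfg: SimConfig) -> tuple[pd.DataFrame, "TruthTable"]:
    """Generate a count-level SV dataset with its truth table.

    The dataset holds per-end supporting counts and adjusted depths
    (``b1, d1, b2, d2``), raw normal counts before the DNA-gain adjustment,
    background copy-number columns and the drawn class; the truth table
    records each SV's clone CCF, cluster index and clonality label (clonal
    iff its clone CCF is 1).
    """
    from .evaluate import TruthTable

    rng = np.random.default_rng(cfg.seed)
    meta = cfg.meta()
    classes = list(cfg.class_mix)
    probs = np.array([cfg.class_mix[c] for c in classes])

    rows, truth_rows = [], []
    idx = 0
    for cluster, (n, phi) in enumerate(zip(cfg.n_sv, cfg.clone_ccfs)):
        for _ in range(n):
            vid = f"sv{idx:04d}"
            idx += 1
            svclass = classes[rng.choice(len(classes), p=probs)]
            for _try in range(100):
                ann_lo = _draw_cn(rng, cfg)
                ann_hi = ann_lo
                try:
                    rows.append(_simulate_variant(
                        rng, cfg, meta, vid, phi, cluster, svclass,
                        ann_lo, ann_hi))
                    break
                except ValueError:
                    continue
            else:
                log.warning("no feasible CN/multiplicity combination for %s",
                            vid)
                continue
            truth_rows.append({"id": vid, "true_ccf": phi,
                               "true_cluster": cluster,
                               "clonal": bool(phi >= 1.0 - 1e-9)})
    dataset = pd.DataFrame(rows)
    truth = TruthTable(pd.DataFrame(truth_rows),
                       np.asarray(cfg.clone_ccfs, dtype=float))
    return dataset, truth


def make_mixture(dataset_a: pd.DataFrame, dataset_b: pd.DataFrame,
                 shared_ids, p_a: float, cfg: SimConfig
                 ) -> tuple[pd.DataFrame, "TruthTable"]:
    """Mix two clonal samples at proportion ``p_a``.

    Variants in ``shared_ids`` (present in both samples) are re-emitted at
    CCF 1; A-private variants at ``p_a``; B-private at ``1 - p_a``.  Read
    counts are re-drawn from the forward model at the new CCFs, keeping
    each variant's class, copy-number background and multiplicity.
    """
    from .evaluate import TruthTable

    if not (0 < p_a < 1):
        raise ValueError(f"mixture proportion must be in (0,1), got {p_a}")
    shared_ids = set(shared_ids)
    ids_a = set(dataset_a["id"])
    ids_b = set(dataset_b["id"])
    if not shared_ids <= (ids_a & ids_b):
        raise ValueError("shared_ids must be present in both datasets")

    rng = np.random.default_rng(cfg.seed + 1)
    meta = cfg.meta()
    ccfs = {1.0: 0}
    rows, truth_rows = [], []

    def emit(row, phi):
        ann_lo, ann_hi = cn_from_row(row, "lo"), cn_from_row(row, "hi")
        new = _simulate_variant(rng, cfg, meta, row["id"], phi, 0,
                                row["svclass"], ann_lo, ann_hi)
        new["m_lo_true"], new["m_hi_true"] = row["m_lo_true"], row["m_hi_true"]
        rows.append(new)
        truth_rows.append({"id": row["id"], "true_ccf": phi,
                           "true_cluster": None,
                           "clonal": bool(phi >= 1.0 - 1e-9)})

    p_b = round(1.0 - p_a, 12)
    for _, row in dataset_a.iterrows():
        emit(row, 1.0 if row["id"] in shared_ids else p_a)
    for _, row in dataset_b.iterrows():
        if row["id"] in shared_ids:
            continue  # shared variants already emitted from A
        emit(row, p_b)

    truth_df = pd.DataFrame(truth_rows)
    cluster_means = sorted(truth_df["true_ccf"].unique(), reverse=True)
    lookup = {c: k for k, c in enumerate(cluster_means)}
    truth_df["true_cluster"] = truth_df["true_ccf"].map(lookup)
    truth = TruthTable(truth_df, np.asarray(cluster_means))
    return pd.DataFrame(rows), truth


# ---------------------------------------------------------------------------
# copy-number perturbation
# ---------------------------------------------------------------------------

def simulate_cn_perturbation(dataset: pd.DataFrame, mode: str,
                             sides: str = "one", seed: int = 0) -> pd.DataFrame:
    """Perturb background copy-number annotations of a dataset.

    ``cn_minus_1``: subtract one from the primary clone's major allele
    (fall back to the minor allele when the major is 1; 1-0 states are left
    unchanged).  ``cn_plus_1``: add one to the primary clone's major allele.
    ``frac_pm_03``: add 0.3 to the subclonal fraction unless the result
    would exceed 0.9, in which case subtract 0.3; the second clone's
    fraction is the complement.  ``sides`` perturbs the lower end only
    (``one``) or both ends (``both``).
    """
    if mode not in ("cn_minus_1", "cn_plus_1", "frac_pm_03"):
        raise ValueError(f"unknown perturbation mode {mode!r}")
    if sides not in ("one", "both"):
        raise ValueError("sides must be 'one' or 'both'")
    out = dataset.copy()
    side_list = ("lo",) if sides == "one" else ("lo", "hi")

    for side in side_list:
        maj, mino, frac = (f"{side}_maj1", f"{side}_min1", f"{side}_frac1")
        if mode == "cn_minus_1":
            majs, mins = out[maj].to_numpy(float), out[mino].to_numpy(float)
            can_major = majs > 1
            can_minor = (majs == 1) & (mins >= 1)
            majs = np.where(can_major, majs - 1, majs)
            mins = np.where(can_minor, mins - 1, mins)  # 1-0 stays unchanged
            out[maj], out[mino] = majs, mins
        elif mode == "cn_plus_1":
            out[maj] = out[maj].to_numpy(float) + 1
        else:  # frac_pm_03
            fr = out[frac].to_numpy(float)
            subclonal = out[f"{side}_frac2"].notna().to_numpy()
            new = np.where(fr + 0.3 > 0.9, fr - 0.3, fr + 0.3)
            new = np.clip(new, 0.05, 1.0)
            fr = np.where(subclonal, new, fr)
            out[frac] = fr
            out.loc[subclonal, f"{side}_frac2"] = 1.0 - fr[subclonal]
    return out


# ---------------------------------------------------------------------------
# alignment fixtures
# ---------------------------------------------------------------------------

def _sam_header(bp: Breakpoint, meta: SampleMeta) -> dict:
    chroms = {}
    for e in bp.ends():
        chroms[e.chrom] = max(chroms.get(e.chrom, 0),
                              e.pos + int(meta.max_insert) + 1000)
    return {"HD": {"VN": "1.6", "SO": "coordinate"},
            "SQ": [{"SN": c, "LN": ln} for c, ln in sorted(chroms.items())]}


def _mk_read(header, name, chrom, start0, cigar, reverse=False,
             paired=False, mate=None):
    import pysam

    a = pysam.AlignedSegment(header=pysam.AlignmentHeader.from_dict(header)
                             if isinstance(header, dict) else header)
    a.query_name = name
    a.reference_name = chrom
    a.reference_start = start0
    a.cigarstring = cigar
    a.mapping_quality = 60
    a.is_reverse = reverse
    qlen = a.infer_query_length()
    a.query_sequence = "A" * qlen
    a.query_qualities = pysam.qualitystring_to_array("I" * qlen)
    if paired and mate is not None:
        a.is_paired = True
        a.is_proper_pair = False
        a.next_reference_name = mate[0]
        a.next_reference_start = mate[1]
        a.mate_is_reverse = mate[2]
        a.is_read1 = mate[3]
        a.is_read2 = not mate[3]
    return a


def _split_read(header, name, be, meta, clip_len):
    aligned = meta.read_len - clip_len
    p0 = be.pos - 1
    if be.direction is Direction.PLUS:
        start = p0 - aligned + 1
        cigar = f"{aligned}M{clip_len}S"
    else:
        start = p0
        cigar = f"{clip_len}S{aligned}M"
    return _mk_read(header, name, be.chrom, start, cigar)


def _normal_read(header, name, be, meta):
    half = meta.read_len // 2
    start = (be.pos - 1) - half + 1
    return _mk_read(header, name, be.chrom, start, f"{meta.read_len}M")


def _spanning_pair(header, name, lo, hi, meta, gap=20):
    reads = []
    R = meta.read_len
    for be, other, is_r1 in ((lo, hi, True), (hi, lo, False)):
        p0 = be.pos - 1
        if be.direction is Direction.PLUS:
            start, reverse = p0 - gap - R + 1, False
        else:
            start, reverse = p0 + gap, True
        reads.append((be.chrom, start, reverse, is_r1))
    a = _mk_read(header, name, reads[0][0], reads[0][1], f"{R}M",
                 reverse=reads[0][2], paired=True,
                 mate=(reads[1][0], reads[1][1], reads[1][2], True))
    b = _mk_read(header, name, reads[1][0], reads[1][1], f"{R}M",
                 reverse=reads[1][2], paired=True,
                 mate=(reads[0][0], reads[0][1], reads[0][2], False))
    return [a, b]


def _anomalous_read(header, name, be, meta):
    # double-clipped read crossing the locus: fits no counted category
    clip = 20
    aligned = meta.read_len - 2 * clip
    start = (be.pos - 1) - aligned // 2
    return _mk_read(header, name, be.chrom, start,
                    f"{clip}S{aligned}M{clip}S")


def generate_alignments(bp: Breakpoint, n_split_lo: int, n_split_hi: int,
                        n_span: int, n_norm_lo: int, n_norm_hi: int,
                        n_anom: int, meta: SampleMeta, seed: int,
                        out_path: str | Path) -> Path:
    """Write a sorted, indexed BAM realising exact category counts at ``bp``.

    Split reads carry a soft-clip longer than the threshold ending exactly
    at the breakend on the direction-matching side; spanning pairs flank the
    junction facing it within the insert bound; normal reads cleanly cross
    each locus; anomalous reads are double-clipped boundary crossers.
    Raises for geometrically impossible requests (breakends too close for
    the categories to stay distinct).
    """
    import pysam

    if any(n < 0 for n in (n_split_lo, n_split_hi, n_span, n_norm_lo,
                           n_norm_hi, n_anom)):
        raise ValueError("category counts must be non-negative")
    if bp.lo.direction not in (Direction.PLUS, Direction.MINUS) or \
            bp.hi.direction not in (Direction.PLUS, Direction.MINUS):
        raise ValueError("breakend directions must be resolved")
    if bp.intrachromosomal and bp.span < 3 * meta.max_insert:
        raise ValueError("breakends too close: categories would overlap")
    if bp.lo.pos < 2 * meta.max_insert or bp.hi.pos < 2 * meta.max_insert:
        raise ValueError("breakends too close to the contig start")

    rng = np.random.default_rng(seed)
    header = _sam_header(bp, meta)
    clip_len = meta.clip_min + 5
    reads = []
    n = 0

    def name():
        nonlocal n
        n += 1
        return f"frag{n:05d}"

    for _ in range(n_split_lo):
        reads.append(_split_read(header, name(), bp.lo, meta, clip_len))
    for _ in range(n_split_hi):
        reads.append(_split_read(header, name(), bp.hi, meta, clip_len))
    for _ in range(n_span):
        reads.extend(_spanning_pair(header, name(), bp.lo, bp.hi, meta,
                                    gap=int(rng.integers(10, 40))))
    for _ in range(n_norm_lo):
        reads.append(_normal_read(header, name(), bp.lo, meta))
    for _ in range(n_norm_hi):
        reads.append(_normal_read(header, name(), bp.hi, meta))
    for _ in range(n_anom):
        reads.append(_anomalous_read(header, name(), bp.lo, meta))

    out_path = Path(out_path)
    tmp = out_path.with_suffix(".unsorted.bam")
    with pysam.AlignmentFile(str(tmp), "wb", header=header) as fh:
        for read in reads:
            fh.write(read)
    pysam.sort("-o", str(out_path), str(tmp))
    tmp.unlink()
    pysam.index(str(out_path))
    return out_path
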