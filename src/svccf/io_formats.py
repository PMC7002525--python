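"""Input/output formats and canonical internal records.

Structural variants enter the pipeline as paired single-nucleotide-resolution
breakends, either as VCF 4.2 BND records or as a tab-delimited table of
breakend pairs.  Allele-specific copy-number segmentations may be supplied in
a Battenberg-style subclones table (up to two copy-number clones per segment),
an ASCAT-style table, or a consensus-style table.  All coordinates are 1-based
inclusive for breakends; copy-number segments are treated as 1-based half-open
``[start, end)`` intervals for queries, so a boundary base belongs to the
segment that starts at it.
"""
from __future__ import annotations

import logging
import re
from dataclasses import dataclass, replace
from enum import Enum
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

log = logging.getLogger(__name__)

FLOAT_FMT = "%.6f"
NA = "NA"


class Direction(str, Enum):
    """Which side of a locus connects to the distant partner locus.

    ``PLUS`` means the break lies on the right side of the locus: reads
    supporting the junction align up to the position from the left and are
    soft-clipped on the right.  ``MINUS`` is the mirror case.  ``MIXED``
    marks loci with substantial soft-clip evidence on both sides (multiple
    breakend pairs involved), ``UNKNOWN`` marks absent evidence.
    """

    PLUS = "+"
    MINUS = "-"
    MIXED = "mixed"
    UNKNOWN = "?"


class SVClass(str, Enum):
    DEL = "DEL"
    DUP = "DUP"
    INTDUP = "INTDUP"
    INV = "INV"
    TRX = "TRX"
    INTRX = "INTRX"
    UNKNOWN = "UNKNOWN"
    COMPLEX = "COMPLEX"


#: duplication classes whose normal read counts need the purity/ploidy correction
GAIN_CLASSES = frozenset({SVClass.DUP, SVClass.INTDUP})
#: copy-number balanced rearrangement classes
BALANCED_CLASSES = frozenset({SVClass.INV, SVClass.INTRX})


def _chrom_key(chrom: str):
    c = chrom.removeprefix("chr")
    return (0, int(c), "") if c.isdigit() else (1, 0, c)


@dataclass(frozen=True)
class Breakend:
    chrom: str
    pos: int  # 1-based
    direction: Direction = Direction.UNKNOWN

    def __post_init__(self):
        if self.pos < 1:
            raise ValueError(f"breakend position must be >= 1, got {self.pos}")


@dataclass(frozen=True)
class Breakpoint:
    """A paired breakend (l, u) with classification.

    ``lo`` is the lower-coordinate breakend when both loci share a chromosome,
    otherwise the breakend on the lexicographically/numerically lower
    chromosome.
    """

    id: str
    lo: Breakend
    hi: Breakend
    svclass: SVClass = SVClass.UNKNOWN

    def __post_init__(self):
        if self.lo.chrom == self.hi.chrom:
            if self.lo.pos > self.hi.pos:
                raise ValueError(f"{self.id}: lo.pos > hi.pos on same chromosome")
        elif _chrom_key(self.lo.chrom) > _chrom_key(self.hi.chrom):
            raise ValueError(f"{self.id}: lo must be on the lower chromosome")

    @property
    def intrachromosomal(self) -> bool:
        return self.lo.chrom == self.hi.chrom

    @property
    def span(self) -> int | None:
        """u - l, or None for inter-chromosomal events."""
        return self.hi.pos - self.lo.pos if self.intrachromosomal else None

    def ends(self) -> tuple[Breakend, Breakend]:
        return (self.lo, self.hi)


@dataclass(frozen=True)
class CNState:
    """One copy-number clone of a segment: major/minor alleles and fraction."""

    major: float
    minor: float
    frac: float = 1.0

    def __post_init__(self):
        if self.major < 0 or self.minor < 0:
            raise ValueError("copy numbers must be non-negative")
        if not (0 < self.frac <= 1):
            raise ValueError(f"clone fraction must be in (0,1], got {self.frac}")

    @property
    def total(self) -> float:
        return self.major + self.minor


@dataclass(frozen=True)
class CNAnnotation:
    """Background copy number at a breakend: one (clonal) or two (subclonal)
    copy-number states with fractions summing to one.

    ``total_tumour`` is the fraction-weighted total copy number over the
    states; ``total_normal`` is the normal-population copy number (2 for
    autosomes).
    """

    states: tuple[CNState, ...]
    total_normal: float = 2.0

    def __post_init__(self):
        if not 1 <= len(self.states) <= 2:
            raise ValueError("CNAnnotation needs 1 or 2 states")
        if abs(sum(s.frac for s in self.states) - 1.0) > 1e-6:
            raise ValueError("clone fractions must sum to 1")

    @property
    def total_tumour(self) -> float:
        return sum(s.frac * s.total for s in self.states)

    @property
    def subclonal(self) -> bool:
        return len(self.states) == 2

    @classmethod
    def default(cls, total_normal: float = 2.0) -> "CNAnnotation":
        """Normal-ploidy fallback when no copy-number input covers a locus:
        tumour total matches the normal total, no subclonality."""
        half = total_normal / 2.0
        return cls(states=(CNState(major=max(half, total_normal - half),
                                   minor=min(half, total_normal - half), frac=1.0),),
                   total_normal=total_normal)


@dataclass(frozen=True)
class SampleMeta:
    """Sample-level parameters used throughout counting and clustering."""

    purity: float = 1.0          # tumour content t in (0, 1]
    ploidy: float = 2.0          # tumour ploidy n_p
    error_rate: float = 1e-3     # sequencing error constant epsilon
    expected_depth: float = 50.0  # lambda, expected reads per locus
    max_cn: float = 10.0         # max expected copy number (high-depth filter)
    insert_mean: float = 300.0   # mean fragment size mu_ins
    insert_sd: float = 20.0      # fragment size s.d. sigma_ins
    read_len: int = 100

    def __post_init__(self):
        if not (0 < self.purity <= 1):
            raise ValueError(f"purity must be in (0,1], got {self.purity}")
        if self.ploidy <= 0:
            raise ValueError("ploidy must be positive")
        if not (0 <= self.error_rate < 1):
            raise ValueError("error rate must be in [0,1)")

    @property
    def max_insert(self) -> float:
        """Insert-size cap for counted reads: mu_ins + 3 sigma_ins."""
        return self.insert_mean + 3.0 * self.insert_sd

    @property
    def clip_min(self) -> int:
        """Minimum soft-clip length for a split read; 10 for 100 bp reads,
        scaled proportionally for other read lengths."""
        return max(1, round(0.1 * self.read_len))


# ---------------------------------------------------------------------------
# SV input
# ---------------------------------------------------------------------------

_DIR_MAP = {"+": Direction.PLUS, "-": Direction.MINUS, "−": Direction.MINUS,
            "?": Direction.UNKNOWN, "": Direction.UNKNOWN, "mixed": Direction.MIXED}

_BND_RE = re.compile(r"^(?P<head>[ACGTNacgtn.]*)"
                     r"(?P<br1>[\[\]])(?P<chrom>[^:\[\]]+):(?P<pos>\d+)(?P<br2>[\[\]])"
                     r"(?P<tail>[ACGTNacgtn.]*)$")


class SVParseError(ValueError):
    pass


def _parse_dir(token: str) -> Direction:
    token = token.strip()
    try:
        return _DIR_MAP[token]
    except KeyError:
        raise SVParseError(f"unknown direction token {token!r}") from None


def _ordered_pair(id_: str, end_a: Breakend, end_b: Breakend,
                  svclass: SVClass) -> Breakpoint:
    """Order two breakends into (lo, hi) canonical form."""
    if end_a.chrom == end_b.chrom:
        first = end_a.pos <= end_b.pos
    else:
        first = _chrom_key(end_a.chrom) <= _chrom_key(end_b.chrom)
    lo, hi = (end_a, end_b) if first else (end_b, end_a)
    return Breakpoint(id=id_, lo=lo, hi=hi, svclass=svclass)


def _read_sv_tsv(path: Path) -> list[Breakpoint]:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    required = ["chrom1", "pos1", "dir1", "chrom2", "pos2", "dir2"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SVParseError(f"{path}: missing columns {missing}")
    out = []
    for idx, row in df.iterrows():
        try:
            a = Breakend(row["chrom1"], int(row["pos1"]), _parse_dir(row["dir1"]))
            b = Breakend(row["chrom2"], int(row["pos2"]), _parse_dir(row["dir2"]))
        except ValueError as exc:
            raise SVParseError(f"{path} row {idx}: {exc}") from exc
        cls = SVClass.UNKNOWN
        if "classification" in df.columns and row["classification"]:
            try:
                cls = SVClass(row["classification"])
            except ValueError:
                log.warning("row %s: unknown classification %r kept as UNKNOWN",
                            idx, row["classification"])
        bp_id = row["id"] if "id" in df.columns and row["id"] else f"sv{idx}"
        out.append(_ordered_pair(bp_id, a, b, cls))
    if not out:
        log.warning("%s: no SV records found", path)
    return out


def _bnd_directions(alt: str):
    """VCF 4.2 BND bracket semantics -> (this end's direction, mate position,
    mate chrom, mate direction).

    ``t[p[``: piece right of p joins after t  -> this +, mate -.
    ``t]p]``: reverse-comp piece left of p joins after t -> this +, mate +.
    ``[p[t``: piece right of p joins before t (rev-comp) -> this -, mate -.
    ``]p]t``: piece left of p joins before t -> this -, mate +.
    """
    m = _BND_RE.match(alt)
    if m is None:
        raise SVParseError(f"unparseable BND ALT {alt!r}")
    head, br1 = m.group("head"), m.group("br1")
    this_dir = Direction.PLUS if head else Direction.MINUS
    mate_dir = Direction.MINUS if br1 == "[" else Direction.PLUS
    return this_dir, m.group("chrom"), int(m.group("pos")), mate_dir


def _read_sv_vcf(path: Path) -> list[Breakpoint]:
    import pysam

    records: dict[str, dict] = {}
    with pysam.VariantFile(str(path)) as vcf:
        for rec in vcf:
            alts = rec.alts or ()
            if not alts or "[" not in alts[0] and "]" not in alts[0]:
                continue  # not a breakend record
            this_dir, mchrom, mpos, mate_dir = _bnd_directions(alts[0])

            def _info(key):
                try:  # pysam raises on INFO keys absent from the header
                    val = rec.info.get(key)
                except (KeyError, ValueError):
                    return None
                return val[0] if isinstance(val, tuple) else val

            mateid = _info("MATEID")
            svclass = _info("SVCLASS")
            records[rec.id or f"{rec.chrom}:{rec.pos}"] = {
                "chrom": rec.chrom, "pos": rec.pos, "dir": this_dir,
                "mate_chrom": mchrom, "mate_pos": mpos, "mate_dir": mate_dir,
                "mateid": mateid, "svclass": svclass,
            }

    out, used = [], set()
    for rid, rec in records.items():
        if rid in used:
            continue
        mate_id, mate = None, None
        if rec["mateid"] is not None:
            mate_id = rec["mateid"]
            mate = records.get(mate_id)
            if mate is None:
                raise SVParseError(f"record {rid}: MATEID {mate_id} not found")
        else:  # resolve by ALT coordinates
            for oid, other in records.items():
                if oid == rid or oid in used:
                    continue
                if (other["chrom"] == rec["mate_chrom"]
                        and other["pos"] == rec["mate_pos"]
                        and other["mate_chrom"] == rec["chrom"]
                        and other["mate_pos"] == rec["pos"]):
                    mate_id, mate = oid, other
                    break
            if mate is None:
                raise SVParseError(f"record {rid}: no resolvable mate")
        used.update({rid, mate_id})
        # cross-check: the mate's record should place this end where we expect
        end_a = Breakend(rec["chrom"], rec["pos"], rec["dir"])
        end_b = Breakend(mate["chrom"], mate["pos"], mate["dir"])
        cls = SVClass.UNKNOWN
        if rec["svclass"]:
            try:
                cls = SVClass(str(rec["svclass"]))
            except ValueError:
                pass
        out.append(_ordered_pair(min(rid, mate_id), end_a, end_b, cls))
    if not out:
        log.warning("%s: no BND records found", path)
    return out


def read_sv_input(path: str | Path, dialect: str = "tsv_pairs") -> list[Breakpoint]:
    """Read paired SV breakends from ``tsv_pairs`` or ``vcf_bnd`` input."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if dialect == "tsv_pairs":
        return _read_sv_tsv(path)
    if dialect == "vcf_bnd":
        return _read_sv_vcf(path)
    raise ValueError(f"unknown SV dialect {dialect!r}")


# ---------------------------------------------------------------------------
# Copy-number input
# ---------------------------------------------------------------------------

class CNMap:
    """Interval map of copy-number annotations, queryable by (chrom, pos).

    Segments are half-open ``[start, end)`` in 1-based coordinates.
    """

    def __init__(self, default_total_normal: float = 2.0):
        self._trees: dict[str, IntervalTree] = {}
        self.default_total_normal = default_total_normal

    def add(self, chrom: str, start: int, end: int, ann: CNAnnotation) -> bool:
        chrom = str(chrom)
        tree = self._trees.setdefault(chrom, IntervalTree())
        if tree.overlap(start, end):
            log.warning("overlapping CN segment %s:%d-%d dropped (first kept)",
                        chrom, start, end)
            return False
        tree.addi(start, end, ann)
        return True

    def query(self, chrom: str, pos: int) -> CNAnnotation | None:
        """Annotation of the segment containing ``pos``, or None."""
        tree = self._trees.get(str(chrom))
        if tree is None:
            return None
        hits = tree[pos]
        return next(iter(hits)).data if hits else None

    def query_or_default(self, chrom: str, pos: int) -> tuple[CNAnnotation, bool]:
        ann = self.query(chrom, pos)
        if ann is None:
            return CNAnnotation.default(self.default_total_normal), False
        return ann, True

    def segments(self) -> Iterable[tuple[str, int, int, CNAnnotation]]:
        for chrom in sorted(self._trees, key=_chrom_key):
            for iv in sorted(self._trees[chrom]):
                yield chrom, iv.begin, iv.end, iv.data

    def __len__(self):
        return sum(len(t) for t in self._trees.values())


class CNFormatError(ValueError):
    pass


_CN_COLUMNS = {
    "battenberg": ["chr", "startpos", "endpos", "nMaj1_A", "nMin1_A", "frac1_A"],
    "ascat": ["chr", "start", "end", "nMajor", "nMinor"],
    "consensus": ["chromosome", "start", "end", "major_cn", "minor_cn",
                  "clonal_frequency"],
}


def _battenberg_states(row) -> tuple[CNState, ...] | None:
    frac1 = float(row["frac1_A"])
    if not (0 < frac1 <= 1):
        return None
    s1 = CNState(float(row["nMaj1_A"]), float(row["nMin1_A"]), frac1)
    # first segmentation solution only; frac1_A == 1 means the segment is clonal
    if frac1 >= 1.0 - 1e-9:
        return (replace(s1, frac=1.0),)
    if pd.isna(row.get("nMaj2_A")) or pd.isna(row.get("frac2_A")):
        return None
    frac2 = float(row["frac2_A"])
    if abs(frac1 + frac2 - 1.0) > 1e-6:
        return None
    s2 = CNState(float(row["nMaj2_A"]), float(row["nMin2_A"]), frac2)
    return (s1, s2)


def read_cn_input(path: str | Path, dialect: str = "battenberg",
                  total_normal: float = 2.0) -> CNMap:
    """Read an allele-specific copy-number segmentation into a ``CNMap``.

    Records with a clone fraction outside (0, 1] are rejected with a warning;
    overlapping segments keep the first by file order.
    """
    path = Path(path)
    if dialect not in _CN_COLUMNS:
        raise ValueError(f"unknown CN dialect {dialect!r}")
    chrom_col = _CN_COLUMNS[dialect][0]
    df = pd.read_csv(path, sep="\t", dtype={chrom_col: str})
    missing = [c for c in _CN_COLUMNS[dialect] if c not in df.columns]
    if missing:
        raise CNFormatError(f"{path}: missing columns {missing} for {dialect}")

    cn_map = CNMap(default_total_normal=total_normal)
    for _, row in df.iterrows():
        try:
            if dialect == "battenberg":
                chrom, start, end = row["chr"], int(row["startpos"]), int(row["endpos"])
                states = _battenberg_states(row)
            elif dialect == "ascat":
                chrom, start, end = row["chr"], int(row["start"]), int(row["end"])
                states = (CNState(float(row["nMajor"]), float(row["nMinor"]), 1.0),)
            else:  # consensus
                chrom, start, end = row["chromosome"], int(row["start"]), int(row["end"])
                frac = float(row["clonal_frequency"])
                if not (0 < frac <= 1):
                    states = None
                else:
                    states = (CNState(float(row["major_cn"]), float(row["minor_cn"]),
                                      1.0),)
        except (ValueError, TypeError):
            states = None
        if states is None:
            log.warning("CN segment %s rejected (bad fraction or copy number)",
                        dict(row))
            continue
        cn_map.add(str(chrom), start, end, CNAnnotation(states, total_normal))
    return cn_map


# ---------------------------------------------------------------------------
# Results output
# ---------------------------------------------------------------------------

def _fmt(x) -> str:
    if x is None or (isinstance(x, float) and np.isnan(x)):
        return NA
    if isinstance(x, (float, np.floating)):
        return FLOAT_FMT % x
    return str(x)


def _write_tsv(df: pd.DataFrame, path: Path) -> None:
    out = df.copy()
    for col in out.columns:
        if out[col].dtype.kind == "f":
            out[col] = out[col].map(_fmt)
    out.to_csv(path, sep="\t", index=False, na_rep=NA)


def write_results(fit, variants: pd.DataFrame, out_dir: str | Path) -> dict[str, Path]:
    """Persist a completed cluster fit as deterministic TSVs.

    Writes the filtered-SVs table, a cluster summary (id, mean CCF, size,
    weight), per-variant assignments with responsibility vectors, and a
    run-metadata record (seed, parameters, final ELBO).
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {}

    paths["variants"] = out_dir / "filtered_svs.tsv"
    _write_tsv(variants, paths["variants"])

    summary = fit.cluster_table()
    paths["clusters"] = out_dir / "cluster_summary.tsv"
    _write_tsv(summary, paths["clusters"])

    assign = fit.assignment_table()
    paths["assignments"] = out_dir / "assignments.tsv"
    _write_tsv(assign, paths["assignments"])

    meta = fit.run_metadata()
    paths["metadata"] = out_dir / "run_metadata.txt"
    with open(paths["metadata"], "w") as fh:
        for key, val in meta.items():
            fh.write(f"{key}\t{_fmt(val)}\n")
    return paths
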