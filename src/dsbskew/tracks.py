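"""Aligned fragments -> filtered, strand-assigned, TMM-scaled coverage.

Strand assignment follows the proper-pair SAM flag convention for a
stranded library: a pair with flags {99, 147} derives from the + template
strand, {83, 163} from the - strand; every other flag combination is
``unassigned``. Counting is fragment-level (template span), not per-read:
the span/skew logic downstream is molecule-centric.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pysam
from intervaltree import IntervalTree
from scipy.stats import rankdata

from .sites import GenomicSite

__all__ = [
    "FragmentRecord",
    "StrandedTrack",
    "assign_template_strand",
    "read_fragments",
    "filter_fragments",
    "compute_coverage",
    "tmm_norm_factors",
    "tmm_scale_factors",
    "skew_track",
    "normalized_skew",
    "combine_tracks",
    "write_bedgraph",
]

logger = logging.getLogger(__name__)

PLUS_FLAGS = frozenset({99, 147})
MINUS_FLAGS = frozenset({83, 163})

DEFAULT_MITO_NAMES = ("chrM", "MT")


def assign_template_strand(flags: Iterable[int]) -> str:
    """Map a read pair's SAM flags to the template strand."""
    s = frozenset(flags)
    if s == PLUS_FLAGS:
        return "+"
    if s == MINUS_FLAGS:
        return "-"
    return "unassigned"


@dataclass
class FragmentRecord:
    """One sequenced fragment reconstructed from a read pair."""

    chrom: str
    start: int
    end: int
    flags: tuple[int, int]
    template_strand: str = "unassigned"
    proper_pair: bool = True
    gap_blocks: tuple[tuple[int, int], ...] = ()
    duplicate: bool = False

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"empty fragment {self.chrom}:{self.start}-{self.end}")


def _deletion_blocks(read: pysam.AlignedSegment) -> list[tuple[int, int]]:
    blocks = []
    pos = read.reference_start
    for op, ln in read.cigartuples or ():
        if op in (0, 7, 8):  # M, =, X
            pos += ln
        elif op == 2:  # D
            blocks.append((pos, pos + ln))
            pos += ln
        elif op == 3:  # N
            pos += ln
        elif op in (1, 4, 5, 6):  # I, S, H, P: no reference advance
            continue
        else:
            raise ValueError(
                f"malformed/unsupported cigar op {op} in record {read.query_name}"
            )
    return blocks


def read_fragments(path: str | Path) -> list[FragmentRecord]:
    """Read a SAM/BAM file into one :class:`FragmentRecord` per read pair.

    Secondary, supplementary and unmapped records are dropped, as are reads
    whose mate never appears; drop counts are logged with fixed keys.
    """
    pairs: dict[str, pysam.AlignedSegment] = {}
    records: list[FragmentRecord] = []
    tally = {"secondary": 0, "supplementary": 0, "unmapped": 0, "mateless": 0}
    with pysam.AlignmentFile(str(path), check_sq=False) as fh:
        for read in fh:
            if read.is_secondary:
                tally["secondary"] += 1
                continue
            if read.is_supplementary:
                tally["supplementary"] += 1
                continue
            if read.is_unmapped:
                tally["unmapped"] += 1
                continue
            mate = pairs.pop(read.query_name, None)
            if mate is None:
                pairs[read.query_name] = read
                continue
            r1, r2 = (read, mate) if read.is_read1 else (mate, read)
            start = min(r1.reference_start, r2.reference_start)
            end = max(r1.reference_end, r2.reference_end)
            gaps = sorted(set(_deletion_blocks(r1)) | set(_deletion_blocks(r2)))
            flags = (r1.flag, r2.flag)
            records.append(
                FragmentRecord(
                    chrom=r1.reference_name,
                    start=start,
                    end=end,
                    flags=flags,
                    template_strand=assign_template_strand(flags),
                    proper_pair=r1.is_proper_pair and r2.is_proper_pair,
                    gap_blocks=tuple(gaps),
                )
            )
    tally["mateless"] = len(pairs)
    logger.info(
        "read_fragments pairs=%d secondary=%d supplementary=%d unmapped=%d mateless=%d",
        len(records), tally["secondary"], tally["supplementary"],
        tally["unmapped"], tally["mateless"],
    )
    records.sort(key=lambda r: (r.chrom, r.start, r.end, r.flags))
    return records


def filter_fragments(
    records: Sequence[FragmentRecord],
    blacklist: Sequence[GenomicSite] | None = None,
    mode: str = "chip",
    excluded_contigs: Sequence[str] | None = None,
) -> tuple[list[FragmentRecord], dict[str, int]]:
    """Blacklist, deduplicate and (in ATAC mode) pair/contig filter.

    * any >= 1 bp overlap with a blacklist interval removes the fragment;
    * duplicates are identical (chrom, start, end, template_strand), keep
      first in input order;
    * ``mode="atac"`` additionally removes non-proper pairs and fragments
      on excluded contigs (default: mitochondrial names chrM/MT).

    Returns the survivors and a per-rule removal tally.
    """
    if mode not in ("chip", "atac"):
        raise ValueError(f"mode must be 'chip' or 'atac' (got {mode!r})")
    if excluded_contigs is None:
        excluded_contigs = DEFAULT_MITO_NAMES if mode == "atac" else ()
    trees: dict[str, IntervalTree] = {}
    for iv in blacklist or ():
        trees.setdefault(iv.chrom, IntervalTree()).addi(iv.start, iv.end)

    tally = {
        "input": len(records),
        "blacklist": 0,
        "duplicate": 0,
        "improper_pair": 0,
        "excluded_contig": 0,
        "kept": 0,
    }
    seen: set[tuple] = set()
    kept: list[FragmentRecord] = []
    for rec in records:
        if mode == "atac" and rec.chrom in excluded_contigs:
            tally["excluded_contig"] += 1
            continue
        if mode == "atac" and not rec.proper_pair:
            tally["improper_pair"] += 1
            continue
        tree = trees.get(rec.chrom)
        if tree is not None and tree.overlaps(rec.start, rec.end):
            tally["blacklist"] += 1
            continue
        key = (rec.chrom, rec.start, rec.end, rec.template_strand)
        if key in seen:
            tally["duplicate"] += 1
            continue
        seen.add(key)
        kept.append(rec)
    tally["kept"] = len(kept)
    logger.info(
        "filter_fragments %s",
        " ".join(f"{k}={v}" for k, v in tally.items()),
    )
    return kept, tally


@dataclass
class StrandedTrack:
    """Binned per-strand coverage for one chromosome.

    Values are fragment-bp overlap per bin divided by ``bin_size`` (i.e. a
    mean per-bp fragment depth), already multiplied by ``scale_factor``.
    """

    chrom: str
    bin_size: int
    values_plus: np.ndarray
    values_minus: np.ndarray
    scale_factor: float = 1.0
    n_fragments_used: int = 0

    def __post_init__(self) -> None:
        self.values_plus = np.asarray(self.values_plus, dtype=float)
        self.values_minus = np.asarray(self.values_minus, dtype=float)
        if self.values_plus.shape != self.values_minus.shape:
            raise ValueError("plus/minus arrays differ in length")
        if self.bin_size <= 0:
            raise ValueError("bin_size must be positive")
        if self.scale_factor <= 0:
            raise ValueError("scale_factor must be positive")

    @property
    def n_bins(self) -> int:
        return len(self.values_plus)

    def values(self, strand: str = "both") -> np.ndarray:
        if strand == "+":
            return self.values_plus
        if strand == "-":
            return self.values_minus
        if strand == "both":
            return self.values_plus + self.values_minus
        raise ValueError(f"strand must be +, - or both (got {strand!r})")


def _binned(starts, ends, chrom_len: int, bin_size: int) -> np.ndarray:
    n_bins = math.ceil(chrom_len / bin_size)
    diff = np.zeros(n_bins * bin_size + 1)
    np.add.at(diff, starts, 1.0)
    np.add.at(diff, ends, -1.0)
    per_bp = np.cumsum(diff[:-1])
    return per_bp.reshape(n_bins, bin_size).sum(axis=1) / bin_size


def compute_coverage(
    records: Sequence[FragmentRecord],
    chrom_lengths: Mapping[str, int],
    bin_size: int,
    scale_factor: float = 1.0,
) -> dict[str, StrandedTrack]:
    """Fragment-level binned coverage per chromosome and strand.

    Each fragment contributes its bp overlap with each bin divided by
    ``bin_size``. Plus and minus template strands are binned separately
    (their sum is the unstranded track); ``unassigned``-strand fragments
    are excluded and counted in the log.
    """
    if bin_size <= 0:
        raise ValueError("bin_size must be positive")
    n_unassigned = 0
    by_chrom: dict[str, dict[str, list]] = {
        c: {"+": [], "-": []} for c in chrom_lengths
    }
    for rec in records:
        if rec.template_strand == "unassigned":
            n_unassigned += 1
            continue
        if rec.chrom not in by_chrom:
            continue
        by_chrom[rec.chrom][rec.template_strand].append((rec.start, rec.end))
    if n_unassigned:
        logger.info("compute_coverage unassigned_strand=%d", n_unassigned)
    out: dict[str, StrandedTrack] = {}
    for chrom, length in chrom_lengths.items():
        tracks = {}
        n_used = 0
        for strand in "+-":
            iv = by_chrom[chrom][strand]
            n_used += len(iv)
            if iv:
                arr = np.array(iv, dtype=np.int64)
                starts = np.clip(arr[:, 0], 0, length)
                ends = np.clip(arr[:, 1], 0, length)
                tracks[strand] = _binned(starts, ends, length, bin_size) * scale_factor
            else:
                tracks[strand] = np.zeros(math.ceil(length / bin_size))
        out[chrom] = StrandedTrack(
            chrom=chrom,
            bin_size=bin_size,
            values_plus=tracks["+"],
            values_minus=tracks["-"],
            scale_factor=scale_factor,
            n_fragments_used=n_used,
        )
    return out


# ---------------------------------------------------------------------------
# TMM normalization


def _tmm_pair_factor(
    obs: np.ndarray,
    ref: np.ndarray,
    lib_obs: float,
    lib_ref: float,
    logratio_trim: float = 0.3,
    sum_trim: float = 0.05,
) -> float:
    """Trimmed mean of M-values factor of one sample against the reference.

    Standard recipe: M and A over bins non-zero in both samples, double
    trim (30% by M, 5% by A), precision weighting by the inverse asymptotic
    binomial variance.
    """
    mask = (obs > 0) & (ref > 0)
    o, r = obs[mask], ref[mask]
    log_r = np.log2((o / lib_obs) / (r / lib_ref))
    abs_e = (np.log2(o / lib_obs) + np.log2(r / lib_ref)) / 2.0
    var = (lib_obs - o) / (lib_obs * o) + (lib_ref - r) / (lib_ref * r)
    if log_r.size == 0 or np.max(np.abs(log_r)) < 1e-6:
        return 1.0
    n = log_r.size
    lo_l = math.floor(n * logratio_trim) + 1
    hi_l = n + 1 - lo_l
    lo_s = math.floor(n * sum_trim) + 1
    hi_s = n + 1 - lo_s
    rank_m = rankdata(log_r)
    rank_a = rankdata(abs_e)
    keep = (rank_m >= lo_l) & (rank_m <= hi_l) & (rank_a >= lo_s) & (rank_a <= hi_s)
    if not keep.any():
        return 1.0
    f = np.sum(log_r[keep] / var[keep]) / np.sum(1.0 / var[keep])
    return float(2.0**f)


def _as_matrix(count_matrix, sample_names=None):
    try:  # DataFrame: rows = samples
        values = count_matrix.to_numpy(dtype=float)
        names = list(count_matrix.index)
    except AttributeError:
        values = np.asarray(count_matrix, dtype=float)
        names = sample_names or [f"sample{i}" for i in range(values.shape[0])]
    return values, names


def tmm_norm_factors(count_matrix, sample_names=None) -> np.ndarray:
    """Composition-robust TMM normalization factors (geometric mean 1).

    ``count_matrix`` is samples x bins. The reference sample is the one
    whose library-scaled 75th-percentile count is closest to the mean over
    samples. Factors multiply library sizes to give effective sizes.
    """
    y, names = _as_matrix(count_matrix, sample_names)
    if y.ndim != 2 or y.shape[0] < 2:
        raise ValueError("need a samples x bins matrix with >= 2 samples")
    if (y < 0).any():
        raise ValueError("counts must be non-negative")
    lib = y.sum(axis=1)
    for i, tot in enumerate(lib):
        if tot == 0:
            raise ValueError(f"sample {names[i]!r} has all-zero bins")
    if int((y.sum(axis=0) > 0).sum()) < 100:
        raise ValueError("need >= 100 non-zero bins for a stable TMM fit")
    f75 = np.quantile(y, 0.75, axis=1) / lib
    ref = int(np.argmin(np.abs(f75 - f75.mean())))
    f = np.array(
        [_tmm_pair_factor(y[i], y[ref], lib[i], lib[ref]) for i in range(y.shape[0])]
    )
    return f / np.exp(np.mean(np.log(f)))


def tmm_scale_factors(count_matrix, sample_names=None) -> np.ndarray:
    """Per-sample multiplicative coverage normalizers.

    The TMM factor is combined with the library-size ratio (scale
    proportional to 1 / effective library size) and the product rescaled to
    geometric mean 1, so scaled tracks are directly comparable.
    """
    y, _ = _as_matrix(count_matrix, sample_names)
    nf = tmm_norm_factors(count_matrix, sample_names)
    eff = y.sum(axis=1) * nf
    scale = 1.0 / eff
    return scale / np.exp(np.mean(np.log(scale)))


# ---------------------------------------------------------------------------
# track algebra


def skew_track(track: StrandedTrack) -> np.ndarray:
    """Per-bin raw strand skew: plus coverage minus minus coverage."""
    return track.values_plus - track.values_minus


def normalized_skew(track: StrandedTrack, epsilon: float = 1.0) -> np.ndarray:
    """Depth-normalized skew (plus-minus)/(plus+minus+eps), bounded on
    sparse bins by the epsilon pseudocount (one scaled count)."""
    both = track.values_plus + track.values_minus
    return (track.values_plus - track.values_minus) / (both + epsilon)


def _check_compatible(tracks: Sequence[StrandedTrack]) -> None:
    first = tracks[0]
    for t in tracks[1:]:
        if (
            t.chrom != first.chrom
            or t.bin_size != first.bin_size
            or t.n_bins != first.n_bins
        ):
            raise ValueError("tracks differ in chromosome or binning")


def combine_tracks(tracks: Sequence[StrandedTrack], op: str = "mean") -> StrandedTrack:
    """Bin-wise replicate mean, or treatment-control subtraction.

    ``op="mean"`` averages any number of tracks; ``op="subtract"`` takes
    exactly two (first minus second).
    """
    if not tracks:
        raise ValueError("no tracks to combine")
    _check_compatible(tracks)
    if op == "mean":
        plus = np.mean([t.values_plus for t in tracks], axis=0)
        minus = np.mean([t.values_minus for t in tracks], axis=0)
    elif op == "subtract":
        if len(tracks) != 2:
            raise ValueError("subtract takes exactly two tracks")
        plus = tracks[0].values_plus - tracks[1].values_plus
        minus = tracks[0].values_minus - tracks[1].values_minus
    else:
        raise ValueError(f"op must be 'mean' or 'subtract' (got {op!r})")
    return StrandedTrack(
        chrom=tracks[0].chrom,
        bin_size=tracks[0].bin_size,
        values_plus=plus,
        values_minus=minus,
        scale_factor=1.0,
        n_fragments_used=sum(t.n_fragments_used for t in tracks),
    )


def write_bedgraph(
    values: np.ndarray,
    chrom: str,
    bin_size: int,
    path: str | Path,
    chrom_length: int | None = None,
    mode: str = "w",
) -> None:
    """Write one binned value array as 0-based half-open bedGraph lines."""
    with open(path, mode) as fh:
        for i, v in enumerate(values):
            start = i * bin_size
            end = start + bin_size
            if chrom_length is not None:
                end = min(end, chrom_length)
            fh.write(f"{chrom}\t{start}\t{end}\t{v:.6g}\n")
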