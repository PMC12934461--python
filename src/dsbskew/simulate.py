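"""Synthetic stranded paired-end fragments around double-strand breaks.

The generator produces sequencing fragments from an explicit cut /
resection / occupancy model so that every downstream stage (strand
splitting, skew, span classification, deletion detection, normalization,
%ssDNA inversion) can be exercised against known ground truth.

Generative model, per fragment (each fragment is drawn from an
independently sampled molecule — fragments subsample a large molecule
population, so molecule states are i.i.d. across fragments):

1. each configured DSB site is cut with probability ``cut_efficiency``;
2. a cut is rejoined (repaired, possibly with a junction deletion) with
   probability ``rejoined_fraction``; an open cut undergoes 5'->3'
   resection with probability ``resected_fraction``, the resected length
   per end being geometric with mean ``resection_mean`` — memoryless
   per-base stopping;
3. a binding position is sampled from an occupancy mixture: uniform
   background, Gaussian kernels at pre-existing open-chromatin peaks
   (amplified when an adjacent DSB is cut), a Gaussian damage-induced
   footprint at each cut, and a uniform extra weight on resected
   single-stranded spans;
4. a uniform fragment length from ``fragment_len_range`` is laid over the
   binding position; fragments are truncated at open (unrejoined) cuts —
   a sequencing fragment cannot cross a physically broken molecule;
5. 5'->3' resection retains the 3'-terminated strand: fragments wholly
   inside a left resected span are template ``+``, wholly inside a right
   span template ``-``; everything else is double-stranded (``both``);
6. fragments from rejoined molecules may span the cut and carry the
   configured junction deletion as an alignment gap.

Induction folds are calibrated as fragment mass added relative to the
uniform background within +-``signal_window`` of the cut, so a window-mean
fold-change measurement recovers the configured fold.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import pysam

from .sites import ASISI_MOTIF, GenomicSite, ReferenceSequence

__all__ = [
    "OpenPeak",
    "FactorProfile",
    "SimulationConfig",
    "FragmentTruth",
    "simulate_genome",
    "simulate_fragments",
    "emit_sam",
    "simulate_qpcr",
    "resection_span_lengths",
    "FOOTPRINT_PRESETS",
    "INDUCTION_PRESETS",
]

# Narrow footprint emulates an end-processing nuclease held at the break;
# broad emulates a clamp spreading over surrounding chromatin.
FOOTPRINT_PRESETS = {"narrow": 150.0, "broad": 1000.0}

# Window-mean signal gain on cutting: damage-site loading in the
# ATM-proficient and ATM-inhibited regimes, and the overall gain seen at a
# cut open-chromatin locus.
INDUCTION_PRESETS = {"dsb": 25.0, "atmi": 5.0, "open_chromatin": 10.0}

ADJACENT_MIN_DIST = 1_500
ADJACENT_MAX_DIST = 50_000

CT_CENSOR = 40.0
QPCR_MAX_USABLE_CT = 35.0


@dataclass
class OpenPeak:
    """A pre-existing open-chromatin site: Gaussian occupancy kernel."""

    center: int
    width: float = 300.0  # Gaussian sigma, bp
    occupancy: float = 1.0  # relative pre-loading weight
    chrom: str = "chr1"


@dataclass
class FactorProfile:
    """Binding behaviour of the simulated chromatin factor."""

    footprint_sigma: float = FOOTPRINT_PRESETS["narrow"]
    preload_weight: float = 10.0  # window-mean fold over background at open peaks
    dsb_induction_fold: float = INDUCTION_PRESETS["open_chromatin"]
    adjacent_induction_fold: float = 3.0  # gain at open peaks 1.5-50 kb from a cut
    ssdna_affinity: float = 5.0  # extra per-bp weight on resected ssDNA


@dataclass
class SimulationConfig:
    """Full parameterization of one synthetic experiment.

    ``dsb_sites`` are motif-start anchors (the cut falls at the planted
    motif midpoint, anchor + len(motif)//2); entries may be plain ints
    (placed on the first chromosome) or ``(chrom, anchor)`` pairs.
    Defaults reflect the assayed chemistry: 200-600 bp shear, 150-bp
    paired-end reads.
    """

    seed: int
    genome_length: int = 100_000  # per chromosome, bp
    n_chroms: int = 1
    dsb_sites: Sequence = (30_000, 70_000)
    cut_efficiency: float = 0.8
    resected_fraction: float = 0.8
    resection_mean: float = 1_500.0  # geometric mean resected length per end, bp
    open_peaks: Sequence[OpenPeak] = ()
    factor_profile: FactorProfile = field(default_factory=FactorProfile)
    deletion_length: int = 0
    rejoined_fraction: float = 0.2
    fragment_len_range: tuple[int, int] = (200, 600)
    read_length: int = 150
    n_fragments: int = 50_000
    motif: str = ASISI_MOTIF
    signal_window: int = 1_000  # calibration half-window for induction folds, bp
    qpcr_distances: Sequence[int] = (335, 1_618, 3_500)
    qpcr_replicates: int = 3
    qpcr_ct_mock: float = 26.0
    qpcr_noise_sd: float = 0.1

    def __post_init__(self) -> None:
        for name in ("cut_efficiency", "resected_fraction", "rejoined_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1] (got {v})")
        lo, hi = self.fragment_len_range
        if not (50 <= lo <= hi <= 2000):
            raise ValueError(
                f"fragment_len_range must lie within [50, 2000] (got {lo}-{hi})"
            )
        if self.read_length > lo:
            raise ValueError(
                f"read_length {self.read_length} exceeds minimum fragment length {lo}"
            )
        if self.resection_mean < 1:
            raise ValueError("resection_mean must be >= 1 bp")
        if self.n_chroms < 1 or self.genome_length < 1_000:
            raise ValueError("need n_chroms >= 1 and genome_length >= 1000")
        if self.deletion_length < 0:
            raise ValueError("deletion_length must be >= 0")
        if self.seed is None:
            raise ValueError("seed is mandatory")

    # -- derived helpers ----------------------------------------------------

    def chrom_names(self) -> list[str]:
        return [f"chr{i + 1}" for i in range(self.n_chroms)]

    def site_anchors(self) -> list[tuple[str, int]]:
        out = []
        for entry in self.dsb_sites:
            if isinstance(entry, (tuple, list)):
                out.append((str(entry[0]), int(entry[1])))
            else:
                out.append((self.chrom_names()[0], int(entry)))
        return out


@dataclass
class FragmentTruth:
    """One simulated fragment with its ground-truth provenance.

    ``origin`` is one of ``dsDNA`` (uncut duplex), ``ssDNA_left`` /
    ``ssDNA_right`` (wholly inside a resected span; the retained
    3'-terminated strand is ``+`` left of the cut and ``-`` right of it),
    or ``rejoined`` (spans a repaired junction). ``deletion`` is the
    reference interval removed at a rejoined junction, or None.
    """

    chrom: str
    start: int
    end: int
    template_strand: str  # {+, -, both}
    origin: str  # {dsDNA, ssDNA_left, ssDNA_right, rejoined}
    deletion: tuple[int, int] | None = None

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"empty fragment {self.start}-{self.end}")
        if self.origin == "ssDNA_left" and self.template_strand != "+":
            raise ValueError("left resected span must retain the + strand")
        if self.origin == "ssDNA_right" and self.template_strand != "-":
            raise ValueError("right resected span must retain the - strand")


# ---------------------------------------------------------------------------
# genome


def _destroy_accidental_motifs(seq: np.ndarray, motif: str, planted: list[int]) -> None:
    """Mutate chance motif occurrences so planted sites are the only ones.

    ``seq`` is a mutable array of single-character strings. Occurrences of
    the motif or its reverse complement outside the planted anchors get one
    base (outside any planted span) substituted; rescans until clean.
    """
    from .sites import reverse_complement

    targets = {motif, reverse_complement(motif)}
    planted_spans = [(p, p + len(motif)) for p in planted]
    for _ in range(50):
        text = "".join(seq)
        dirty = []
        for t in targets:
            i = text.find(t)
            while i != -1:
                if i not in planted:
                    dirty.append(i)
                i = text.find(t, i + 1)
        if not dirty:
            return
        swap = {"A": "C", "C": "A", "G": "T", "T": "G"}
        for i in sorted(set(dirty)):
            for pos in range(i + len(motif) // 2, i + len(motif)):
                if not any(s <= pos < e for s, e in planted_spans):
                    seq[pos] = swap[str(seq[pos])]
                    break
            else:  # pragma: no cover - needs pathological overlap
                raise RuntimeError("cannot sanitize motif occurrence overlapping sites")
    raise RuntimeError("motif sanitization did not converge")  # pragma: no cover


def simulate_genome(
    config: SimulationConfig,
) -> tuple[list[ReferenceSequence], list[GenomicSite]]:
    """Random genome with the recognition motif planted at each DSB anchor.

    The planted occurrences are the *only* occurrences of the motif (chance
    hits in the random background are mutated away), so a motif scan of the
    emitted genome recovers exactly the configured site list. Deterministic
    under the config seed.
    """
    rng = np.random.default_rng([config.seed, 0])
    motif = config.motif.upper()
    max_len = config.fragment_len_range[1]
    anchors = config.site_anchors()
    names = config.chrom_names()
    margin = max_len + config.deletion_length
    by_chrom: dict[str, list[int]] = {n: [] for n in names}
    for chrom, anchor in anchors:
        if chrom not in by_chrom:
            raise ValueError(f"dsb_site on unknown chromosome {chrom!r}")
        if anchor < margin or anchor + len(motif) + margin > config.genome_length:
            raise ValueError(
                f"dsb_site {chrom}:{anchor} within {margin} bp of a sequence edge"
            )
        by_chrom[chrom].append(anchor)
    for chrom, pos_list in by_chrom.items():
        pos_sorted = sorted(pos_list)
        for a, b in zip(pos_sorted, pos_sorted[1:]):
            if b - a < 2 * max_len + len(motif):
                raise ValueError(
                    f"dsb_sites {chrom}:{a} and {chrom}:{b} closer than two "
                    "fragment lengths; truncation would be ambiguous"
                )

    bases = np.array(list("ACGT"))
    refs: list[ReferenceSequence] = []
    site_list: list[GenomicSite] = []
    for name in names:
        arr = rng.choice(bases, size=config.genome_length)
        for anchor in by_chrom[name]:
            arr[anchor : anchor + len(motif)] = list(motif)
        _destroy_accidental_motifs(arr, motif, by_chrom[name])
        refs.append(ReferenceSequence(name=name, seq="".join(arr)))
        for k, anchor in enumerate(sorted(by_chrom[name])):
            site_list.append(
                GenomicSite(
                    chrom=name,
                    start=anchor,
                    end=anchor + len(motif),
                    cut=anchor + len(motif) // 2,
                    orientation=".",
                    label=f"dsb_{name}_{k}",
                    site_class="DSB",
                )
            )
    return refs, site_list


# ---------------------------------------------------------------------------
# fragments


def _footprint_kept_fraction(sigma: float, len_lo: int, len_hi: int) -> float:
    """Expected surviving length fraction of a break-footprint fragment.

    Fragments anchored a Gaussian(0, sigma) distance from an open cut are
    truncated at the cut; the induced mass is divided by this factor so
    the *delivered* window-mean gain matches the configured induction
    fold. Deterministic numeric expectation over anchor distance t
    (|N(0, sigma)| via mid-quantiles), fragment length (uniform) and
    anchor offset (uniform, integrated in closed form).
    """
    from scipy.stats import norm

    z = norm.ppf((np.arange(200) + 0.5) / 200.0)
    t_grid = np.abs(z) * sigma
    l_grid = np.linspace(len_lo, len_hi, 41)
    tt = t_grid[:, None]
    ll = l_grid[None, :]
    # E_a[kept | t, l]: the fragment crosses the cut iff its anchor offset
    # a < l - t, keeping t + a of its length; otherwise it survives whole.
    c = np.clip(ll - tt, 0.0, None)
    kept = (tt * c + c**2 / 2.0 + ll * (ll - c)) / ll
    return float(kept.mean() / l_grid.mean())


def resection_span_lengths(
    config: SimulationConfig, n_ends: int, seed: int | None = None
) -> np.ndarray:
    """Sample resected span lengths under the simulator's geometric law."""
    rng = np.random.default_rng([config.seed if seed is None else seed, 4])
    return rng.geometric(1.0 / config.resection_mean, size=n_ends)


def simulate_fragments(
    config: SimulationConfig,
    genome: Sequence[ReferenceSequence],
    sites: Sequence[GenomicSite],
) -> list[FragmentTruth]:
    """Draw ``n_fragments`` fragments from the occupancy mixture model."""
    rng = np.random.default_rng([config.seed, 1])
    fp = config.factor_profile
    n = config.n_fragments
    S = len(sites)
    K = len(config.open_peaks)
    lo, hi = config.fragment_len_range

    chrom_len = {ref.name: len(ref.seq) for ref in genome}
    names = [ref.name for ref in genome]
    offsets = np.cumsum([0] + [chrom_len[c] for c in names])
    total_len = int(offsets[-1])
    chrom_index = {c: i for i, c in enumerate(names)}

    cut_global = np.array(
        [offsets[chrom_index[s.chrom]] + s.cut for s in sites], dtype=np.int64
    )
    peak_global = np.array(
        [offsets[chrom_index[p.chrom]] + p.center for p in config.open_peaks],
        dtype=np.int64,
    )
    peak_width = np.array([p.width for p in config.open_peaks])
    peak_occ = np.array([p.occupancy for p in config.open_peaks])

    # molecule state per fragment
    cut = rng.random((n, S)) < config.cut_efficiency if S else np.zeros((n, 0), bool)
    rejoined = cut & (rng.random((n, S)) < config.rejoined_fraction)
    open_end = cut & ~rejoined
    resected = open_end & (rng.random((n, S)) < config.resected_fraction)
    geo = rng.geometric(1.0 / config.resection_mean, size=(2, n, S))
    r_left = np.where(resected, geo[0], 0).astype(np.int64)
    r_right = np.where(resected, geo[1], 0).astype(np.int64)

    # occupancy mixture masses (bp-equivalents against unit background density)
    w2 = 2.0 * config.signal_window
    masses = [np.full((n, 1), float(total_len))]
    if K:
        adj = np.zeros((K, S), bool)
        for k in range(K):
            for j in range(S):
                if config.open_peaks[k].chrom == sites[j].chrom:
                    d = abs(config.open_peaks[k].center - sites[j].cut)
                    adj[k, j] = ADJACENT_MIN_DIST < d < ADJACENT_MAX_DIST
        adj_hit = cut @ adj.T.astype(float) > 0 if S else np.zeros((n, K), bool)
        peak_mass = fp.preload_weight * peak_occ * w2 * np.where(
            adj_hit, fp.adjacent_induction_fold, 1.0
        )
        masses.append(peak_mass)
    if S:
        # open (unrejoined) cuts truncate footprint fragments: divide their
        # mass by the expected surviving fraction so the delivered
        # window-mean gain matches the configured induction fold
        kappa = _footprint_kept_fraction(fp.footprint_sigma, lo, hi)
        dsb_weight = np.where(rejoined, 1.0, 1.0 / kappa) * cut
        masses.append(dsb_weight * (fp.dsb_induction_fold - 1.0) * w2)
        masses.append(fp.ssdna_affinity * r_left.astype(float))
        masses.append(fp.ssdna_affinity * r_right.astype(float))
    mass = np.concatenate(masses, axis=1)
    cum = np.cumsum(mass, axis=1)
    pick = rng.random(n) * cum[:, -1]
    comp = (cum < pick[:, None]).sum(axis=1)

    # binding position per component
    u_pos = rng.random(n)
    z = rng.standard_normal(n)
    x = np.empty(n, dtype=np.int64)
    m = comp == 0
    x[m] = (u_pos[m] * total_len).astype(np.int64)
    for k in range(K):
        m = comp == 1 + k
        x[m] = peak_global[k] + np.rint(z[m] * peak_width[k]).astype(np.int64)
    for j in range(S):
        m = comp == 1 + K + j
        x[m] = cut_global[j] + np.rint(z[m] * fp.footprint_sigma).astype(np.int64)
        m = comp == 1 + K + S + j
        x[m] = cut_global[j] - 1 - (u_pos[m] * r_left[m, j]).astype(np.int64)
        m = comp == 1 + K + 2 * S + j
        x[m] = cut_global[j] + (u_pos[m] * r_right[m, j]).astype(np.int64)

    # fragment placement
    frag_chrom = np.searchsorted(offsets, x, side="right") - 1
    frag_chrom = np.clip(frag_chrom, 0, len(names) - 1)
    c_lo = offsets[frag_chrom]
    c_hi = offsets[frag_chrom + 1]
    x = np.clip(x, c_lo, c_hi - 1)
    length = rng.integers(lo, hi + 1, size=n)
    anchor_off = rng.integers(0, length)
    start = x - anchor_off
    end = start + length
    start = np.maximum(start, c_lo)
    end = np.minimum(end, c_hi)

    # truncate at open breaks; record rejoined junction crossings
    origin = np.full(n, "dsDNA", dtype=object)
    strand = np.full(n, "both", dtype=object)
    gap_start = np.full(n, -1, dtype=np.int64)
    d_len = config.deletion_length
    for j in range(S):
        c = cut_global[j]
        straddle = (start < c) & (end > c)
        m = open_end[:, j] & straddle
        left_side = x < c
        end[m & left_side] = c
        start[m & ~left_side] = c
        mr = rejoined[:, j] & straddle
        origin[mr] = "rejoined"
        if d_len > 0:
            end[mr] = np.minimum(end[mr] + d_len, c_hi[mr])
            gap_start[mr] = c
    for j in range(S):
        c = cut_global[j]
        in_left = resected[:, j] & (end <= c) & (start >= c - r_left[:, j])
        origin[in_left] = "ssDNA_left"
        strand[in_left] = "+"
        in_right = resected[:, j] & (start >= c) & (end <= c + r_right[:, j])
        origin[in_right] = "ssDNA_right"
        strand[in_right] = "-"

    out: list[FragmentTruth] = []
    for i in range(n):
        ci = int(frag_chrom[i])
        off = int(offsets[ci])
        deletion = None
        if gap_start[i] >= 0 and end[i] > gap_start[i] + d_len:
            deletion = (int(gap_start[i]) - off, int(gap_start[i]) + d_len - off)
        out.append(
            FragmentTruth(
                chrom=names[ci],
                start=int(start[i]) - off,
                end=int(end[i]) - off,
                template_strand=str(strand[i]),
                origin=str(origin[i]),
                deletion=deletion,
            )
        )
    return out


def fragments_to_records(fragments: Sequence[FragmentTruth], config: SimulationConfig):
    """Convert truth fragments directly to track-ready fragment records.

    Bypasses SAM emission but uses the *same* random stream to assign
    double-stranded (``both``) fragments to a library strand, so coverage
    computed from these records is identical to coverage computed from
    :func:`emit_sam` output read back through ``tracks.read_fragments``.
    """
    from .tracks import FragmentRecord

    rng = np.random.default_rng([config.seed, 2])
    flip = rng.random(len(fragments)) < 0.5
    out = []
    for i, frag in enumerate(fragments):
        strand = frag.template_strand
        if strand == "both":
            strand = "+" if flip[i] else "-"
        flags = (99, 147) if strand == "+" else (83, 163)
        out.append(
            FragmentRecord(
                chrom=frag.chrom,
                start=frag.start,
                end=frag.end,
                flags=flags,
                template_strand=strand,
                proper_pair=True,
                gap_blocks=() if frag.deletion is None else (frag.deletion,),
            )
        )
    return out


# ---------------------------------------------------------------------------
# SAM / FASTQ emission


def _read_seq(ref_seq: str, ref_start: int, cigar: list[tuple[int, int]]) -> str:
    """Query sequence implied by an M/D cigar over the reference."""
    parts = []
    pos = ref_start
    for op, ln in cigar:
        if op == 0:  # M
            parts.append(ref_seq[pos : pos + ln])
            pos += ln
        elif op == 2:  # D
            pos += ln
        else:  # pragma: no cover
            raise ValueError(f"unsupported cigar op {op}")
    return "".join(parts)


def _split_read_cigars(
    frag: FragmentTruth, read_len: int
) -> tuple[list[tuple[int, int]], list[tuple[int, int]], int, int]:
    """Cigars and reference starts for the left and right reads of a pair."""
    d = 0 if frag.deletion is None else frag.deletion[1] - frag.deletion[0]
    qlen = (frag.end - frag.start) - d
    rl = min(read_len, qlen)
    qj = -1 if frag.deletion is None else frag.deletion[0] - frag.start
    # left read covers query [0, rl)
    if 0 < qj < rl:
        left = [(0, qj), (2, d), (0, rl - qj)]
    else:
        left = [(0, rl)]
    left_start = frag.start
    # right read covers query [qlen-rl, qlen)
    if qlen - rl < qj < qlen:
        right = [(0, qj - (qlen - rl)), (2, d), (0, qlen - qj)]
        right_start = frag.start + (qlen - rl)
    else:
        right = [(0, rl)]
        right_start = frag.start + (qlen - rl) + (d if 0 <= qj <= qlen - rl else 0)
    return left, right, left_start, right_start


def emit_sam(
    fragments: Sequence[FragmentTruth],
    genome: Sequence[ReferenceSequence],
    config: SimulationConfig,
    path: str | Path,
    fastq_prefix: str | Path | None = None,
) -> None:
    """Write one properly-paired read pair per fragment to a SAM file.

    Template ``+`` fragments are emitted with flags 99/147, template ``-``
    with 83/163; ``both`` fragments are assigned an orientation with
    probability 1/2 each. Junction deletions appear as D cigar operations.
    Records are coordinate sorted.
    """
    rng = np.random.default_rng([config.seed, 2])
    flip = rng.random(len(fragments)) < 0.5  # drawn for every fragment: reproducible
    seqs = {ref.name: ref.seq for ref in genome}
    header = {
        "HD": {"VN": "1.6", "SO": "coordinate"},
        "SQ": [{"SN": ref.name, "LN": len(ref.seq)} for ref in genome],
    }
    tid = {ref.name: i for i, ref in enumerate(genome)}

    reads = []
    fastq = {"1": [], "2": []}
    for i, frag in enumerate(fragments):
        strand = frag.template_strand
        if strand == "both":
            strand = "+" if flip[i] else "-"
        left_cig, right_cig, left_start, right_start = _split_read_cigars(
            frag, config.read_length
        )
        qname = f"frag{i:08d}"
        tlen = frag.end - frag.start
        left_seq = _read_seq(seqs[frag.chrom], left_start, left_cig)
        right_seq = _read_seq(seqs[frag.chrom], right_start, right_cig)
        if strand == "+":
            pairs = [
                (99, left_start, left_cig, left_seq, right_start, tlen, True),
                (147, right_start, right_cig, right_seq, left_start, -tlen, False),
            ]
        else:
            pairs = [
                (83, right_start, right_cig, right_seq, left_start, -tlen, True),
                (163, left_start, left_cig, left_seq, right_start, tlen, False),
            ]
        for flag, pos, cig, seq, mpos, tl, is_r1 in pairs:
            a = pysam.AlignedSegment()
            a.query_name = qname
            a.flag = flag
            a.reference_id = tid[frag.chrom]
            a.reference_start = pos
            a.mapping_quality = 60
            a.cigar = cig
            a.next_reference_id = tid[frag.chrom]
            a.next_reference_start = mpos
            a.template_length = tl
            a.query_sequence = seq
            a.query_qualities = pysam.qualitystring_to_array("I" * len(seq))
            reads.append(a)
            if fastq_prefix is not None:
                from .sites import reverse_complement

                raw = seq if flag & 16 == 0 else reverse_complement(seq)
                fastq["1" if is_r1 else "2"].append((qname, raw))

    reads.sort(key=lambda a: (a.reference_id, a.reference_start, a.flag))
    with pysam.AlignmentFile(str(path), "wh", header=header) as fh:
        for a in reads:
            fh.write(a)
    if fastq_prefix is not None:
        for mate, entries in fastq.items():
            with open(f"{fastq_prefix}_R{mate}.fastq", "w") as fh:
                for qname, seq in entries:
                    fh.write(f"@{qname}/{mate}\n{seq}\n+\n{'I' * len(seq)}\n")


# ---------------------------------------------------------------------------
# qPCR


def true_ssdna_fraction(config: SimulationConfig, distance: int) -> float:
    """Model probability that a molecule is single-stranded ``distance`` bp
    from a cut: cut x resected x P(geometric span > distance)."""
    q, r, L = config.cut_efficiency, config.resected_fraction, config.resection_mean
    return q * r * (1.0 - 1.0 / L) ** distance


def simulate_qpcr(
    config: SimulationConfig, path: str | Path | None = None
) -> pd.DataFrame:
    """Ct table for the restriction-protection %ssDNA assay.

    For each configured amplicon distance the model ssDNA fraction ``f`` is
    converted to a (mock, digested) Ct pair by the exact inverse of the
    %ssDNA formula, dCt = 1 + log2(1/f - 0.5), then Gaussian Ct noise is
    added. ``f = 0`` (or any Ct beyond 40 cycles) is censored at 40.
    """
    rng = np.random.default_rng([config.seed, 3])
    rows = []
    for dist in config.qpcr_distances:
        f = true_ssdna_fraction(config, dist)
        dct = math.inf if f <= 0 else 1.0 + math.log2(1.0 / f - 0.5)
        for rep in range(1, config.qpcr_replicates + 1):
            noise = rng.normal(0.0, 1.0, size=2) * config.qpcr_noise_sd
            ct_mock = config.qpcr_ct_mock + noise[0]
            ct_dig = CT_CENSOR if not math.isfinite(dct) else ct_mock + dct + noise[1]
            rows.append(
                {
                    "amplicon": f"d{dist}",
                    "distance": dist,
                    "ct_mock": ct_mock,
                    "ct_digested": min(ct_dig, CT_CENSOR),
                    "replicate": rep,
                }
            )
    df = pd.DataFrame(rows)
    if path is not None:
        df.to_csv(path, sep="\t", index=False)
    return df
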