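"""Cut-site prediction and genomic-interval bookkeeping.

Coordinates are 0-based half-open throughout (BED convention); the ``cut``
attribute of a :class:`GenomicSite` is a single inter-base coordinate, i.e.
the break falls between base ``cut - 1`` and base ``cut``.

Two nucleases are modelled:

* a restriction endonuclease with a fixed recognition motif (the default
  workflow uses the rare-cutting AsiSI site ``GCGATCGC``, which is
  palindromic), cut placed bluntly at the motif midpoint;
* Cas9 guided by a 20-nt protospacer next to an NGG PAM, cut placed bluntly
  between protospacer positions 17 and 18 (3 bp 5' of the PAM).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO

__all__ = [
    "GenomicSite",
    "ReferenceSequence",
    "reverse_complement",
    "scan_recognition_sites",
    "cas9_cut_site",
    "read_sites",
    "write_sites",
    "read_fasta",
    "write_fasta",
    "ASISI_MOTIF",
]

ASISI_MOTIF = "GCGATCGC"

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

SITE_CLASSES = ("DSB", "open_chromatin", "adjacent_open", "other")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class GenomicSite:
    """A cut site or chromatin interval with orientation and class label.

    ``orientation`` is ``"+"``, ``"-"`` or ``"."`` (unoriented; used for
    palindromic recognition sites, which read identically on both strands).
    """

    chrom: str
    start: int
    end: int
    cut: int | None = None
    orientation: str = "."
    label: str = ""
    site_class: str = "other"

    def __post_init__(self) -> None:
        if not 0 <= self.start < self.end:
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end} "
                "(need 0 <= start < end)"
            )
        if self.orientation not in ("+", "-", "."):
            raise ValueError(f"orientation must be +, - or . (got {self.orientation!r})")
        if self.site_class not in SITE_CLASSES:
            raise ValueError(f"unknown site_class {self.site_class!r}")
        if self.site_class == "DSB" and self.cut is not None:
            if not self.start <= self.cut <= self.end:
                raise ValueError(
                    f"cut {self.cut} outside interval {self.start}-{self.end}"
                )

    @property
    def center(self) -> int:
        return (self.start + self.end) // 2


@dataclass
class ReferenceSequence:
    """A named nucleotide sequence, normalized to uppercase {A,C,G,T,N}."""

    name: str
    seq: str

    def __post_init__(self) -> None:
        self.seq = self.seq.upper()
        if len(self.seq) < 1:
            raise ValueError(f"reference {self.name!r} is empty")
        bad = set(self.seq) - set("ACGTN")
        if bad:
            raise ValueError(f"reference {self.name!r} has non-ACGTN characters {bad}")

    def __len__(self) -> int:
        return len(self.seq)


def _validate_motif(motif: str) -> str:
    motif = motif.upper()
    if len(motif) < 4:
        raise ValueError(f"motif must be at least 4 nt (got {len(motif)})")
    bad = set(motif) - set("ACGT")
    if bad:
        raise ValueError(
            f"motif contains ambiguity or invalid codes {sorted(bad)}; "
            "only literal A/C/G/T motifs are supported"
        )
    return motif


def _find_all(haystack: str, needle: str) -> Iterable[int]:
    """Yield every (possibly overlapping) occurrence offset."""
    i = haystack.find(needle)
    while i != -1:
        yield i
        i = haystack.find(needle, i + 1)


def scan_recognition_sites(
    refs: Iterable[ReferenceSequence], motif: str
) -> list[GenomicSite]:
    """Locate every occurrence of a recognition motif.

    Palindromic motifs (equal to their reverse complement) are scanned on the
    forward strand only — each duplex occurrence reads identically on both
    strands, so a double-strand scan would double count. Non-palindromic
    motifs are scanned on both strands and reported with orientation.

    The cut coordinate is placed bluntly at ``start + len(motif)//2``
    (mirrored for minus-strand occurrences).
    """
    motif = _validate_motif(motif)
    rc = reverse_complement(motif)
    palindromic = motif == rc
    half = len(motif) // 2
    out: list[GenomicSite] = []
    for ref in refs:
        for p in _find_all(ref.seq, motif):
            out.append(
                GenomicSite(
                    chrom=ref.name,
                    start=p,
                    end=p + len(motif),
                    cut=p + half,
                    orientation="." if palindromic else "+",
                    label=f"{ref.name}:{p}",
                    site_class="DSB",
                )
            )
        if not palindromic:
            for p in _find_all(ref.seq, rc):
                out.append(
                    GenomicSite(
                        chrom=ref.name,
                        start=p,
                        end=p + len(motif),
                        cut=p + (len(motif) - half),
                        orientation="-",
                        label=f"{ref.name}:{p}",
                        site_class="DSB",
                    )
                )
    out.sort(key=lambda s: (s.chrom, s.start, s.orientation))
    return out


def cas9_cut_site(
    protospacer: str, ref: ReferenceSequence, pam: str = "NGG"
) -> list[GenomicSite]:
    """Predict blunt Cas9 cut coordinates for a 20-nt protospacer.

    Exact-match search only. A plus-strand target has the protospacer at
    ``[p, p+20)`` followed immediately by an NGG PAM; the cut is 3 bp 5' of
    the PAM, between protospacer positions 17 and 18, i.e. ``cut = p + 17``.
    Minus-strand targets are found as the reverse complement (``CCN`` PAM
    immediately 5' of the reverse-complemented protospacer) with mirrored
    arithmetic: ``cut = p + 3``. The reported interval spans protospacer+PAM.
    """
    protospacer = protospacer.upper()
    if len(protospacer) != 20:
        raise ValueError(f"protospacer must be 20 nt (got {len(protospacer)})")
    if pam.upper() != "NGG":
        raise ValueError("only the NGG PAM is supported")
    seq = ref.seq
    n = len(protospacer)
    out: list[GenomicSite] = []
    for p in _find_all(seq, protospacer):
        pam_seq = seq[p + n : p + n + 3]
        if len(pam_seq) == 3 and pam_seq[1:] == "GG":
            out.append(
                GenomicSite(
                    chrom=ref.name,
                    start=p,
                    end=p + n + 3,
                    cut=p + 17,
                    orientation="+",
                    label=f"{ref.name}:{p}:+",
                    site_class="DSB",
                )
            )
    rc = reverse_complement(protospacer)
    for p in _find_all(seq, rc):
        pam_seq = seq[p - 3 : p]
        if len(pam_seq) == 3 and pam_seq[:2] == "CC":
            out.append(
                GenomicSite(
                    chrom=ref.name,
                    start=p - 3,
                    end=p + n,
                    cut=p + 3,
                    orientation="-",
                    label=f"{ref.name}:{p}:-",
                    site_class="DSB",
                )
            )
    out.sort(key=lambda s: (s.chrom, s.start, s.orientation))
    return out


# ---------------------------------------------------------------------------
# BED6 / FASTA I/O


def write_sites(sites: Sequence[GenomicSite], path: str | Path) -> None:
    """Write sites as BED6: name carries the label, strand the orientation."""
    with open(path, "w") as fh:
        for s in sites:
            name = s.label if s.label else "."
            fh.write(f"{s.chrom}\t{s.start}\t{s.end}\t{name}\t0\t{s.orientation}\n")


def read_sites(path: str | Path, site_class: str = "other") -> list[GenomicSite]:
    """Read a BED(6) file into :class:`GenomicSite` records.

    For ``site_class="DSB"`` the cut coordinate is reconstructed as the
    interval midpoint (exact for motif-scan output, where the cut is defined
    as the midpoint). Malformed lines raise with their line number.
    """
    out: list[GenomicSite] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}:{lineno}: expected >=3 BED columns")
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-integer coordinates") from exc
            if start >= end or start < 0:
                raise ValueError(
                    f"{path}:{lineno}: invalid interval {start}-{end} (start >= end)"
                )
            label = parts[3] if len(parts) > 3 and parts[3] != "." else ""
            orientation = parts[5] if len(parts) > 5 else "."
            if orientation not in ("+", "-", "."):
                raise ValueError(f"{path}:{lineno}: bad strand field {orientation!r}")
            cut = (start + end) // 2 if site_class == "DSB" else None
            out.append(
                GenomicSite(
                    chrom=parts[0],
                    start=start,
                    end=end,
                    cut=cut,
                    orientation=orientation,
                    label=label,
                    site_class=site_class,
                )
            )
    return out


def read_fasta(path: str | Path) -> list[ReferenceSequence]:
    """Read a (multi-record, possibly wrapped, any-case) FASTA file."""
    return [
        ReferenceSequence(name=rec.id, seq=str(rec.seq))
        for rec in SeqIO.parse(str(path), "fasta")
    ]


def write_fasta(refs: Sequence[ReferenceSequence], path: str | Path, width: int = 80) -> None:
    with open(path, "w") as fh:
        for ref in refs:
            fh.write(f">{ref.name}\n")
            for i in range(0, len(ref.seq), width):
                fh.write(ref.seq[i : i + width] + "\n")
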