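"""%ssDNA from qPCR Ct pairs (restriction-protection resection assay).

Genomic DNA is digested with a restriction enzyme whose site sits at a
known distance from an inducible DSB. Double-stranded templates are cut
and fail to amplify across the site; single-stranded (resected) templates
are protected. Comparing the quantification cycle of digested vs
mock-digested aliquots therefore measures the single-stranded fraction:

    dCt    = Ct_digested - Ct_mock
    %ssDNA = 100 / (2^(dCt - 1) + 0.5)

Derivation: let f be the single-stranded molecule fraction at the
amplicon. A double-stranded molecule denatures into two amplifiable
template strands, a single-stranded one into one, and digestion destroys
only the double-stranded molecules. So the digested aliquot starts from f
templates per input molecule and the mock from f + 2(1 - f), giving
2^(-dCt) = f / (2 - f) under perfect doubling, i.e.
f = 2 / (2^dCt + 1) = 1 / (2^(dCt - 1) + 0.5). The map is exactly 100% at
dCt = 0 and strictly decreasing in dCt with limit 0.

Usability QC: any record whose mock or digested reaction amplified above
35 cycles is excluded as non-usable; a digested Ct more than 0.5 cycles
*below* the mock Ct indicates assay inversion and is an error (smaller
negative differences are tolerated as technical noise and clamped to 0).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "CtRecord",
    "NonUsableError",
    "percent_ssdna",
    "read_ct_table",
    "resection_profile",
    "MAX_USABLE_CT",
    "NEGATIVE_DCT_TOLERANCE",
]

MAX_USABLE_CT = 35.0
NEGATIVE_DCT_TOLERANCE = 0.5


class NonUsableError(ValueError):
    """Raised for records failing the 35-cycle usability QC."""


@dataclass
class CtRecord:
    amplicon: str
    distance_from_cut: int
    ct_mock: float
    ct_digested: float
    replicate: int = 1

    def __post_init__(self) -> None:
        for name in ("ct_mock", "ct_digested"):
            v = getattr(self, name)
            if not 0 < v <= 45:
                raise ValueError(f"{name}={v} outside (0, 45] cycles")
        if self.distance_from_cut < 0:
            raise ValueError("distance_from_cut must be >= 0")


def percent_ssdna(ct_digested: float, ct_mock: float) -> float:
    """Percent single-stranded DNA from a (digested, mock) Ct pair.

    Returns a value in (0, 100]; dCt = 0 maps to exactly 100%.
    Raises :class:`NonUsableError` if either Ct exceeds 35 cycles and
    ``ValueError`` if dCt < -0.5 (assay inversion).
    """
    if ct_digested > MAX_USABLE_CT or ct_mock > MAX_USABLE_CT:
        raise NonUsableError(
            f"non-usable: Ct above {MAX_USABLE_CT} cycles "
            f"(mock={ct_mock}, digested={ct_digested})"
        )
    dct = ct_digested - ct_mock
    if dct < -NEGATIVE_DCT_TOLERANCE:
        raise ValueError(
            f"assay inversion: digested Ct {abs(dct):.2f} cycles below mock"
        )
    dct = max(dct, 0.0)
    return 100.0 / (2.0 ** (dct - 1.0) + 0.5)


def read_ct_table(path: str | Path) -> pd.DataFrame:
    """Read a TSV with columns amplicon, distance, ct_mock, ct_digested,
    replicate (extra columns are preserved)."""
    df = pd.read_csv(path, sep="\t")
    required = {"amplicon", "distance", "ct_mock", "ct_digested", "replicate"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"Ct table missing columns {sorted(missing)}")
    return df


def resection_profile(
    ct_table: pd.DataFrame,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Aggregate replicate %ssDNA per amplicon distance.

    Returns ``(profile, exclusions)``: the profile has one row per
    distance, ordered by distance, with mean, sd (ddof=1, NaN for a single
    replicate) and n of the usable replicates; amplicons with zero usable
    replicates appear with n=0 and no mean. Excluded records are returned
    with their reason.
    """
    rows, excluded = [], []
    for _, rec in ct_table.iterrows():
        try:
            pct = percent_ssdna(float(rec["ct_digested"]), float(rec["ct_mock"]))
        except (NonUsableError, ValueError) as exc:
            excluded.append({**rec.to_dict(), "reason": str(exc)})
            continue
        rows.append(
            {
                "amplicon": rec["amplicon"],
                "distance": int(rec["distance"]),
                "percent_ssdna": pct,
            }
        )
    usable = pd.DataFrame(rows, columns=["amplicon", "distance", "percent_ssdna"])
    all_amps = ct_table[["amplicon", "distance"]].drop_duplicates()
    out = []
    for _, amp in all_amps.iterrows():
        sel = usable[usable["amplicon"] == amp["amplicon"]]
        n = len(sel)
        out.append(
            {
                "amplicon": amp["amplicon"],
                "distance": int(amp["distance"]),
                "mean_percent_ssdna": float(sel["percent_ssdna"].mean()) if n else None,
                "sd_percent_ssdna": float(sel["percent_ssdna"].std(ddof=1))
                if n > 1
                else (0.0 if n == 1 else None),
                "n": n,
            }
        )
    profile = pd.DataFrame(out).sort_values("distance").reset_index(drop=True)
    exclusions = pd.DataFrame(excluded)
    return profile, exclusions
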