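"""Bivalency statistics: positive-part filter, angle phi, binarization,
bivalent-state calls, and H3.3 co-localization fractions.

The bivalency angle maps the balance of the two promoter marks onto a
half-circle:

    phi = 2 * arctan[ +(SI_H3K27me3) / +(SI_H3K4me3) ]    (degrees)

where +(x) = max(x, 0) treats negative SI as no signal. phi = 0 deg is
pure H3K4me3, 180 deg pure H3K27me3, 90 deg a perfectly balanced
bivalent unit. Units where both filtered SIs are zero carry no signal
for either mark and are excluded (phi = NaN).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd


def positive_part(x: float) -> float:
    """+(x): x if x > 0 else 0. Non-finite input is rejected."""
    if not math.isfinite(x):
        raise ValueError(f"non-finite SI: {x!r}")
    return x if x > 0 else 0.0


def bivalency_angle(si_k4: float, si_k27: float) -> float:
    """Bivalency angle in degrees, or NaN when both filtered SIs are zero.

    By convention a unit with no H3K4me3 signal but positive H3K27me3 is
    fully repressed: phi = 180 deg.
    """
    a = positive_part(si_k4)
    b = positive_part(si_k27)
    if a == 0 and b == 0:
        return float("nan")
    if a == 0:
        return 180.0
    return math.degrees(2.0 * math.atan(b / a))


def bivalency_angles(si_k4, si_k27) -> np.ndarray:
    """Vectorized :func:`bivalency_angle`; NaN marks excluded units."""
    a = np.maximum(np.asarray(si_k4, dtype=float), 0.0)
    b = np.maximum(np.asarray(si_k27, dtype=float), 0.0)
    if not (np.isfinite(a).all() and np.isfinite(b).all()):
        raise ValueError("non-finite SI values")
    with np.errstate(divide="ignore", invalid="ignore"):
        phi = np.degrees(2.0 * np.arctan(b / a))
    phi = np.where(a == 0, 180.0, phi)
    return np.where((a == 0) & (b == 0), np.nan, phi)


def call_enrichment(si_values, mode: str = "si") -> np.ndarray:
    """Binarize per-window SI into enriched (True) / depleted (False).

    A window is enriched iff its IP density exceeds the input density.
    ``mode="si"`` tests SI > 0; ``mode="log_ratio"`` tests
    log(RPKM_ip/RPKM_input) > 0 — the two rules agree everywhere both
    are defined (same sign), so both route to the SI sign. SI exactly 0
    is scored depleted (no evidence of enrichment).
    """
    if mode not in ("si", "log_ratio"):
        raise ValueError(f"unknown binarization mode {mode!r}")
    return np.asarray(si_values, dtype=float) > 0


def bivalent_state(calls_k4: np.ndarray, calls_k27: np.ndarray) -> np.ndarray:
    """Per-window bivalent flag: both marks enriched."""
    calls_k4 = np.asarray(calls_k4, dtype=bool)
    calls_k27 = np.asarray(calls_k27, dtype=bool)
    if calls_k4.shape != calls_k27.shape:
        raise ValueError("enrichment call lists are on different grids")
    return calls_k4 & calls_k27


@dataclass
class ColocalizationSummary:
    """Genome-wide co-localization of bivalency with H3.3 enrichment.

    Conditional fractions are NaN when their stratum is empty. The full
    2x2x2 (H3.3 x K4 x K27) count table is kept for export/recomputation.
    """

    n_windows: int
    n_h33_enriched: int
    n_bivalent_given_h33_enriched: int
    n_bivalent_given_h33_depleted: int
    counts: pd.DataFrame  # columns: h33, k4, k27 (bool), count

    @property
    def frac_h33_enriched(self) -> float:
        return self.n_h33_enriched / self.n_windows

    @property
    def frac_bivalent_given_h33_enriched(self) -> float:
        if self.n_h33_enriched == 0:
            return float("nan")
        return self.n_bivalent_given_h33_enriched / self.n_h33_enriched

    @property
    def frac_bivalent_given_h33_depleted(self) -> float:
        n_dep = self.n_windows - self.n_h33_enriched
        if n_dep == 0:
            return float("nan")
        return self.n_bivalent_given_h33_depleted / n_dep

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "n_windows": [self.n_windows],
                "frac_h33_enriched": [self.frac_h33_enriched],
                "frac_bivalent_given_h33_enriched": [self.frac_bivalent_given_h33_enriched],
                "frac_bivalent_given_h33_depleted": [self.frac_bivalent_given_h33_depleted],
            }
        )


def colocalization_summary(calls_h33, calls_k4, calls_k27) -> ColocalizationSummary:
    """Fractions of bivalent windows within H3.3-enriched vs -depleted strata."""
    h33 = np.asarray(calls_h33, dtype=bool)
    k4 = np.asarray(calls_k4, dtype=bool)
    k27 = np.asarray(calls_k27, dtype=bool)
    if not (h33.shape == k4.shape == k27.shape):
        raise ValueError("call lists are on different grids")
    n = len(h33)
    biv = k4 & k27
    cells = []
    for a in (True, False):
        for b in (True, False):
            for c in (True, False):
                cells.append(
                    {"h33": a, "k4": b, "k27": c,
                     "count": int(((h33 == a) & (k4 == b) & (k27 == c)).sum())}
                )
    return ColocalizationSummary(
        n_windows=n,
        n_h33_enriched=int(h33.sum()),
        n_bivalent_given_h33_enriched=int((biv & h33).sum()),
        n_bivalent_given_h33_depleted=int((biv & ~h33).sum()),
        counts=pd.DataFrame(cells),
    )


def angle_scatter_table(si_k4: pd.Series, si_k27: pd.Series,
                        si_h33: pd.Series) -> pd.DataFrame:
    """Per-gene (phi, SI_H3.3) table for the angle-vs-incorporation scatter.

    All three series must cover exactly the same genes (a gene scored for
    only some marks is an incomplete record and is rejected). Genes whose
    phi is undefined (no signal for either mark) are flagged
    ``included=False`` and should be dropped from exported scatters.
    """
    idx = si_k4.index
    if not (idx.equals(si_k27.index) and idx.equals(si_h33.index)):
        raise ValueError("marks scored on different gene lists (incomplete records)")
    phi = bivalency_angles(si_k4.to_numpy(), si_k27.to_numpy())
    df = pd.DataFrame(
        {
            "gene_id": idx.astype(str),
            "phi_degrees": phi,
            "si_h33": si_h33.to_numpy(dtype=float),
            "si_k4": si_k4.to_numpy(dtype=float),
            "si_k27": si_k27.to_numpy(dtype=float),
        }
    )
    df["included"] = ~np.isnan(phi)
    return df
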