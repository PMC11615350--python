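"""Flow-cytometry derived scores.

SCENITH metabolic dependences from puromycin gMFI under metabolic
inhibitors, background-subtracted relative MFI, and the per-batch
top-percentile intensity-ratio statistic used to compare a chromatin mark
against MYC in the highest-MYC cells.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class ScenithSample:
    """Puromycin gMFI per inhibitor condition for one sample.

    DMSO is the vehicle control; 2-DG blocks glycolysis; oligomycin blocks
    oxidative phosphorylation; the double treatment bounds total
    translation-coupled metabolism.
    """

    gmfi_dmso: float
    gmfi_2dg: float
    gmfi_oligo: float
    gmfi_2dg_oligo: float

    def __post_init__(self) -> None:
        for name in ("gmfi_dmso", "gmfi_2dg", "gmfi_oligo", "gmfi_2dg_oligo"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.gmfi_2dg_oligo > self.gmfi_dmso:
            warnings.warn(
                "double-inhibitor gMFI exceeds DMSO control; check staining",
                stacklevel=2,
            )


def scenith_scores(s: ScenithSample) -> Tuple[float, float]:
    """Glucose dependence and FAO/AAO capacity, in percent.

    Glucose dependence (%) = 100 x (DMSO - 2DG) / (DMSO - 2DG&Oligo);
    FAO/AAO capacity (%) = 100 - glucose dependence.  Values outside
    [0, 100] are reported raw with a warning rather than clamped.
    """
    denom = s.gmfi_dmso - s.gmfi_2dg_oligo
    if denom == 0:
        raise ZeroDivisionError(
            "DMSO and 2-DG+oligomycin gMFI are equal; dependence undefined"
        )
    gd = 100.0 * (s.gmfi_dmso - s.gmfi_2dg) / denom
    faoaao = 100.0 - gd
    if not (0.0 <= gd <= 100.0):
        warnings.warn(f"glucose dependence {gd:.1f}% outside [0, 100]", stacklevel=2)
    return gd, faoaao


def relative_mfi(
    sample_mfi: float,
    background_mfi: float,
    reference_mfi: Optional[float] = None,
) -> float:
    """Background-subtracted (and optionally reference-normalized) MFI.

    The no-primary-antibody background is subtracted from the sample MFI;
    when a reference population is supplied the result is the ratio of
    background-subtracted values.
    """
    if sample_mfi < 0 or background_mfi < 0:
        raise ValueError("MFI values must be non-negative")
    value = sample_mfi - background_mfi
    if reference_mfi is not None:
        ref = reference_mfi - background_mfi
        if ref == 0:
            raise ZeroDivisionError("reference MFI equals background")
        value = value / ref
    if value < 0 and reference_mfi is None:
        warnings.warn("sample MFI below background", stacklevel=2)
    return value


def top_percentile_ratio(table: pd.DataFrame, pct: float = 5.0) -> pd.DataFrame:
    """Mark/MYC intensity ratios for the top-MYC cells of each batch.

    Within each batch independently, the ``ceil(n * pct/100)`` cells with
    the highest ``myc_mi`` are selected (ties at the cutoff resolved by
    higher ``myc_mi`` first, then ``cell_id`` order) and the per-cell
    ``mark_mi / myc_mi`` ratio is returned.  Batches are never pooled.
    """
    if not (0 < pct < 100):
        raise ValueError("pct must lie in (0, 100)")
    required = {"cell_id", "batch", "myc_mi", "mark_mi"}
    if not required.issubset(table.columns):
        raise ValueError(f"table must have columns {sorted(required)}")
    if (table["myc_mi"] < 0).any() or (table["mark_mi"] < 0).any():
        raise ValueError("intensities must be non-negative")
    out = []
    for batch, grp in table.groupby("batch", sort=True):
        n = len(grp)
        k = math.ceil(n * pct / 100.0)
        if n < math.ceil(100.0 / pct):
            raise ValueError(
                f"batch {batch!r} has {n} cells; need >= {math.ceil(100.0 / pct)}"
            )
        sel = grp.sort_values(
            ["myc_mi", "cell_id"], ascending=[False, True], kind="mergesort"
        ).head(k)
        ratios = sel["mark_mi"] / sel["myc_mi"]
        out.append(
            pd.DataFrame(
                {
                    "cell_id": sel["cell_id"].to_numpy(),
                    "batch": batch,
                    "myc_mi": sel["myc_mi"].to_numpy(),
                    "mark_mi": sel["mark_mi"].to_numpy(),
                    "ratio": ratios.to_numpy(),
                }
            )
        )
    return pd.concat(out, ignore_index=True) if out else pd.DataFrame(
        columns=["cell_id", "batch", "myc_mi", "mark_mi", "ratio"]
    )
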