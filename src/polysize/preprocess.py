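"""DLS data cleaning: invalid-sample removal and replicate-outlier rejection.

Raw tables carry one row per DLS measurement: each formulation is prepared in
three replicates and each replicate measured three times, so a formulation
contributes up to nine rows.  Cleaning proceeds in two stages:

1. :func:`filter_invalid` drops rows that cannot be trusted on their own —
   missing size (no particles formed / measurement aborted), polydispersity
   index above threshold (broad or multimodal distribution), or a z-average
   outside physically sensible bounds (instrument artifacts).
2. :func:`remove_replicate_outliers` compares each surviving row against the
   median of its formulation group and rejects strong deviators; formulations
   left with too few measurements are dropped entirely.

Every rejection carries a machine-readable reason code and the two stages
conserve rows: kept ∪ rejected = input at each step.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ValidationError

__all__ = [
    "FilterConfig",
    "filter_invalid",
    "remove_replicate_outliers",
    "assemble_dataset",
    "preprocess",
    "RAW_COLUMNS",
    "FORMULATION_KEYS",
]

#: schema of a raw measurement table (sizes in nm, concentrations in g/L)
RAW_COLUMNS = (
    "row_id",
    "polymer",
    "name",
    "smiles",
    "dp",
    "conc_gL",
    "surf_gL",
    "replicate",
    "measurement",
    "size_nm",
    "pdi",
)

#: columns identifying one formulation (shared by its up-to-9 measurements)
FORMULATION_KEYS = ("polymer", "dp", "conc_gL", "surf_gL")

REASON_MISSING = "missing_size"
REASON_PDI = "high_dispersity"
REASON_BOUNDS = "size_out_of_bounds"
REASON_OUTLIER = "replicate_outlier"
REASON_TOO_FEW = "insufficient_replicates"


@dataclass(frozen=True)
class FilterConfig:
    """Cleaning thresholds.

    Defaults follow common DLS practice: PDI ≤ 0.3 for a trustworthy
    monomodal distribution, sizes within [10, 1000] nm for nanoprecipitation,
    replicate outlier = deviation from the formulation median by more than
    30 % of the median, and at least 3 surviving measurements per formulation.
    All are configurable stand-ins.
    """

    pdi_max: float = 0.3
    size_min_nm: float = 10.0
    size_max_nm: float = 1000.0
    outlier_tol: float = 0.30
    min_survivors: int = 3

    def __post_init__(self):
        if self.pdi_max <= 0:
            raise ValidationError("pdi_max must be positive")
        if not self.size_min_nm < self.size_max_nm:
            raise ValidationError(
                f"size bounds out of order: [{self.size_min_nm}, {self.size_max_nm}]"
            )
        if self.outlier_tol <= 0:
            raise ValidationError("outlier_tol must be positive")


def _require_columns(df: pd.DataFrame, cols):
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ValidationError(f"raw table is missing columns {missing}")


def filter_invalid(raw: pd.DataFrame, cfg: FilterConfig | None = None):
    """Stage 1: drop individually invalid rows.

    Returns ``(kept, rejected)``; ``rejected`` gains a ``reason`` column with
    one code per row (first matching rule wins: missing size, then high
    dispersity, then size out of bounds).
    """
    cfg = cfg or FilterConfig()
    if len(raw) == 0:
        raise ValidationError("raw table is empty")
    _require_columns(raw, ("size_nm", "pdi"))
    size = raw["size_nm"].to_numpy(dtype=float)
    pdi = raw["pdi"].to_numpy(dtype=float)
    reason = np.full(len(raw), "", dtype=object)
    missing = ~np.isfinite(size)
    reason[missing] = REASON_MISSING
    high_pdi = ~missing & np.isfinite(pdi) & (pdi > cfg.pdi_max)
    reason[high_pdi] = REASON_PDI
    bad_size = (
        ~missing
        & ~high_pdi
        & ((size < cfg.size_min_nm) | (size > cfg.size_max_nm))
    )
    reason[bad_size] = REASON_BOUNDS
    bad = reason != ""
    rejected = raw.loc[bad].copy()
    rejected["reason"] = reason[bad]
    return raw.loc[~bad].copy(), rejected


def remove_replicate_outliers(kept: pd.DataFrame, cfg: FilterConfig | None = None):
    """Stage 2: robust within-formulation outlier rejection.

    Rows deviating from their formulation's median size by more than
    ``outlier_tol × median`` are rejected; formulations retaining fewer than
    ``min_survivors`` measurements are dropped entirely.  Decisions depend
    only on group membership, never on row order.
    """
    cfg = cfg or FilterConfig()
    if len(kept) == 0:
        return kept.copy(), kept.iloc[0:0].copy().assign(reason=pd.Series(dtype=object))
    _require_columns(kept, FORMULATION_KEYS + ("size_nm",))
    size = kept["size_nm"].to_numpy(dtype=float)
    med = (
        kept.groupby(list(FORMULATION_KEYS))["size_nm"]
        .transform("median")
        .to_numpy(dtype=float)
    )
    outlier = np.abs(size - med) > cfg.outlier_tol * med
    reason = np.full(len(kept), "", dtype=object)
    reason[outlier] = REASON_OUTLIER
    surv = kept.loc[~outlier]
    counts = surv.groupby(list(FORMULATION_KEYS))["size_nm"].transform("size")
    too_few = counts < cfg.min_survivors
    reason[np.nonzero(~outlier)[0][too_few.to_numpy()]] = REASON_TOO_FEW
    bad = reason != ""
    rejected = kept.loc[bad].copy()
    rejected["reason"] = reason[bad]
    return kept.loc[~bad].copy(), rejected


def assemble_dataset(surviving: pd.DataFrame) -> pd.DataFrame:
    """Turn cleaned measurements into the modeling dataset.

    One record per surviving measurement (measurements are deliberately not
    averaged: the study's surviving unit is the measurement).  Adds the group
    labels used by the worst-group decomposition; the additive label is
    derived from the surfactant concentration (0 → "none", else "PVA").
    """
    if len(surviving) == 0:
        raise ValidationError("no measurements survived preprocessing")
    _require_columns(
        surviving, ("polymer", "smiles", "dp", "conc_gL", "surf_gL", "size_nm")
    )
    ds = surviving.copy().reset_index(drop=True)
    ds["additive"] = np.where(ds["surf_gL"].to_numpy(dtype=float) > 0, "PVA", "none")
    if (ds["size_nm"] <= 0).any():
        raise ValidationError("assembled dataset contains non-positive sizes")
    return ds


def preprocess(raw: pd.DataFrame, cfg: FilterConfig | None = None):
    """Full pipeline; returns ``(dataset, rejects)``.

    ``rejects`` concatenates both stages' rejections with their reason codes,
    so ``len(dataset) + len(rejects) == len(raw)``.
    """
    cfg = cfg or FilterConfig()
    kept, rej1 = filter_invalid(raw, cfg)
    surv, rej2 = remove_replicate_outliers(kept, cfg)
    rejects = pd.concat([rej1, rej2], ignore_index=True)
    return assemble_dataset(surv), rejects
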