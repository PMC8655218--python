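"""Synthetic nanoprecipitation study generator with known ground truth.

Emulates the structure of the training study: ten methacrylate repeat units
with carbon-only ester side chains, several degrees of polymerization per
unit, stock concentrations of 1–30 g/L, surfactant (PVA) either absent or at
0.0025 g/L, each formulation prepared in three replicates and measured three
times.  Sizes follow an invented closed-form law (the real law is what the
model is meant to learn):

    s = a · Dp^alpha · c^beta · (k_heavy / 7)^delta · (1 − gamma·[surfactant])

which is monotone in concentration and degree of polymerization and depends
on structure only through a graph-computable descriptor (heavy atoms per
repeat unit), so a graph network can in principle recover it.  Measurement
noise is multiplicative lognormal, since DLS size errors scale with size.
Outliers (3× size) and invalid rows (high PDI or missing size) are planted at
configurable rates with full bookkeeping.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigError
from .graphs import RepeatUnit, parse_repeat_unit
from .preprocess import assemble_dataset

__all__ = [
    "METHACRYLATE_BATTERY",
    "GroundTruthCoeffs",
    "SynthConfig",
    "ground_truth_size",
    "generate_raw_table",
    "generate_clean_dataset",
    "battery_units",
]

#: the ten methacrylate repeat units of the study (name → SMILES, two markers)
METHACRYLATE_BATTERY = {
    "methyl methacrylate": "*CC(*)(C)C(=O)OC",
    "ethyl methacrylate": "*CC(*)(C)C(=O)OCC",
    "propyl methacrylate": "*CC(*)(C)C(=O)OCCC",
    "butyl methacrylate": "*CC(*)(C)C(=O)OCCCC",
    "iso-butyl methacrylate": "*CC(*)(C)C(=O)OCC(C)C",
    "tert-butyl methacrylate": "*CC(*)(C)C(=O)OC(C)(C)C",
    "hexyl methacrylate": "*CC(*)(C)C(=O)OCCCCCC",
    "phenyl methacrylate": "*CC(*)(C)C(=O)Oc1ccccc1",
    "benzyl methacrylate": "*CC(*)(C)C(=O)OCc1ccccc1",
    "isobornyl methacrylate": "*CC(*)(C)C(=O)OC1CC2CCC1(C)C2(C)C",
}


def battery_units(battery: dict | None = None) -> dict[str, RepeatUnit]:
    battery = battery or METHACRYLATE_BATTERY
    return {name: parse_repeat_unit(smi, name=name) for name, smi in battery.items()}


@dataclass(frozen=True)
class GroundTruthCoeffs:
    """Coefficients of the invented size law (sizes land in ~35–850 nm)."""

    a: float = 6.0
    alpha: float = 0.5  # Dp exponent
    beta: float = 1.0 / 3.0  # concentration exponent
    delta: float = 0.4  # structure-descriptor exponent
    gamma: float = 0.2  # fractional shrinkage with surfactant


@dataclass(frozen=True)
class SynthConfig:
    """Study layout and corruption rates.

    Defaults reproduce the study's combinatorics: 10 units × 3 Dp levels ×
    5 concentrations × surfactant on/off × (3 replicates × 3 measurements)
    = 2700 raw rows.  ``extreme_dp_unit`` optionally adds one far-outside
    Dp level (default 1013) for a single unit, emulating a
    highest-polymerization batch; it is off by default.  Sizes of that batch
    deviate from the smooth law by ``extreme_dp_anomaly`` (default 1.6×,
    standing in for aggregation effects beyond the power-law regime), so the
    batch is a genuinely anomalous group a trained model cannot extrapolate
    to — the planted target of the worst-group decomposition.
    """

    battery: dict = field(default_factory=lambda: dict(METHACRYLATE_BATTERY))
    dp_levels: tuple = (53.0, 150.0, 420.0)
    conc_levels_gL: tuple = (1.0, 3.0, 10.0, 20.0, 30.0)
    surf_levels_gL: tuple = (0.0, 0.0025)
    coeffs: GroundTruthCoeffs = field(default_factory=GroundTruthCoeffs)
    noise_sigma_log: float = 0.05
    outlier_rate: float = 0.02
    invalid_rate: float = 0.02
    extreme_dp_unit: str | None = None
    extreme_dp: float = 1013.0
    extreme_dp_anomaly: float = 1.6
    seed: int = 0

    def __post_init__(self):
        if not self.battery:
            raise ConfigError("repeat-unit battery is empty")
        if self.outlier_rate < 0 or self.invalid_rate < 0:
            raise ConfigError("planting rates must be non-negative")
        if self.outlier_rate + self.invalid_rate > 1:
            raise ConfigError("planting rates sum to more than 1")
        if any(d <= 0 for d in self.dp_levels):
            raise ConfigError("Dp levels must be positive")
        if any(not 0 < c <= 30 for c in self.conc_levels_gL):
            raise ConfigError("concentrations must lie in (0, 30] g/L")
        if self.extreme_dp_unit is not None and self.extreme_dp_unit not in self.battery:
            raise ConfigError(f"unknown extreme-Dp unit {self.extreme_dp_unit!r}")


def ground_truth_size(
    unit: RepeatUnit, dp: float, conc_gL: float, surf_gL: float, coeffs=None
) -> float:
    """Closed-form deterministic size in nm for one formulation."""
    c = coeffs or GroundTruthCoeffs()
    if dp <= 0 or conc_gL <= 0 or surf_gL < 0:
        raise ConfigError("formulation parameters out of range")
    s = (
        c.a
        * dp**c.alpha
        * conc_gL**c.beta
        * (unit.n_heavy / 7.0) ** c.delta
        * (1.0 - c.gamma * (surf_gL > 0))
    )
    if s <= 0:
        raise ConfigError("ground-truth coefficients produce a non-positive size")
    return float(s)


def _formulations(cfg: SynthConfig, units: dict):
    for name, unit in units.items():
        dps = list(cfg.dp_levels)
        if cfg.extreme_dp_unit == name:
            dps.append(cfg.extreme_dp)
        for dp in dps:
            for conc in cfg.conc_levels_gL:
                for surf in cfg.surf_levels_gL:
                    yield name, unit, dp, conc, surf


def generate_raw_table(cfg: SynthConfig | None = None):
    """Generate a raw measurement table plus planting bookkeeping.

    Returns ``(raw, bookkeeping)``: ``raw`` follows the preprocessing schema
    (one row per measurement, ``row_id`` unique); ``bookkeeping`` lists every
    planted anomaly as (row_id, kind) with kind ∈ {outlier, high_pdi,
    missing_size}.  Byte-identical for identical configs (seed included).
    """
    cfg = cfg or SynthConfig()
    rng = np.random.default_rng(cfg.seed)
    units = battery_units(cfg.battery)
    rows = []
    rid = 0
    for name, unit, dp, conc, surf in _formulations(cfg, units):
        truth = ground_truth_size(unit, dp, conc, surf, cfg.coeffs)
        if cfg.extreme_dp_unit == name and dp == cfg.extreme_dp:
            truth *= cfg.extreme_dp_anomaly
        for rep in (1, 2, 3):
            for meas in (1, 2, 3):
                noise = (
                    np.exp(rng.normal(0.0, cfg.noise_sigma_log))
                    if cfg.noise_sigma_log > 0
                    else 1.0
                )
                rows.append(
                    {
                        "row_id": rid,
                        "polymer": f"poly({name})",
                        "name": name,
                        "smiles": unit.smiles,
                        "dp": dp,
                        "conc_gL": conc,
                        "surf_gL": surf,
                        "replicate": rep,
                        "measurement": meas,
                        "size_nm": truth * noise,
                        "pdi": rng.uniform(0.05, 0.25),
                    }
                )
                rid += 1
    raw = pd.DataFrame(rows)
    n = len(raw)
    n_outlier = int(round(cfg.outlier_rate * n))
    n_invalid = int(round(cfg.invalid_rate * n))
    planted = rng.choice(n, size=n_outlier + n_invalid, replace=False)
    book = []
    for i in planted[:n_outlier]:
        raw.loc[i, "size_nm"] *= 3.0
        book.append({"row_id": int(raw.loc[i, "row_id"]), "kind": "outlier"})
    for j, i in enumerate(planted[n_outlier:]):
        if j % 2 == 0:
            raw.loc[i, "pdi"] = rng.uniform(0.45, 0.95)
            book.append({"row_id": int(raw.loc[i, "row_id"]), "kind": "high_pdi"})
        else:
            raw.loc[i, "size_nm"] = np.nan
            book.append({"row_id": int(raw.loc[i, "row_id"]), "kind": "missing_size"})
    bookkeeping = pd.DataFrame(book, columns=["row_id", "kind"])
    return raw, bookkeeping


def generate_clean_dataset(cfg: SynthConfig | None = None) -> pd.DataFrame:
    """Noisy but anomaly-free modeling dataset (no planting, no filtering)."""
    cfg = cfg or SynthConfig()
    clean_cfg = SynthConfig(
        battery=cfg.battery,
        dp_levels=cfg.dp_levels,
        conc_levels_gL=cfg.conc_levels_gL,
        surf_levels_gL=cfg.surf_levels_gL,
        coeffs=cfg.coeffs,
        noise_sigma_log=cfg.noise_sigma_log,
        outlier_rate=0.0,
        invalid_rate=0.0,
        extreme_dp_unit=cfg.extreme_dp_unit,
        extreme_dp=cfg.extreme_dp,
        extreme_dp_anomaly=cfg.extreme_dp_anomaly,
        seed=cfg.seed,
    )
    raw, _ = generate_raw_table(clean_cfg)
    return assemble_dataset(raw)
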