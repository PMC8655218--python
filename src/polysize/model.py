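"""The fused particle-size regressor and its training/evaluation protocols.

:class:`ParticleSizeModel` binds a cleaned formulation dataset (one row per
DLS measurement) to the architecture: a graph-convolutional encoder turns the
cyclic repeat-unit graph into a fixed-length fingerprint, which is
concatenated with the scaled formulation numerics (degree of polymerization,
polymer concentration, surfactant concentration) and passed through a fully
connected network to a single predicted z-average diameter in nm.  ``fit``
minimizes the mean absolute percentage error with Adam and returns a
:class:`ParticleSizeResults` carrying the fitted parameters, the training
history, diagnostics, and prediction/plotting methods.

Numeric inputs are log-transformed (Dp, concentration — both span decades and
act multiplicatively) then standardized with training-set statistics stored in
the results; the surfactant level is standardized raw.  The output head is
linear: the relative loss with positive targets keeps predictions positive in
practice, and a non-positive prediction logs a warning rather than being
clamped, so pathologies stay visible.
"""

from __future__ import annotations

import copy
import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import (
    NotFittedError,
    TrainingError,
    ValidationError,
)
from .graphs import (
    AtomFeatureSpec,
    MolecularGraph,
    RepeatUnit,
    build_cyclic_polymer,
    default_feature_spec,
    normalized_adjacency,
    parse_repeat_unit,
)
from .metrics import mape, rmse, split_dataset, worst_group_analysis
from .nn import MLP, Adam, GCNEncoder

logger = logging.getLogger("polysize")

__all__ = [
    "ModelConfig",
    "FormulationInput",
    "InputScaler",
    "ParticleSizeModel",
    "ParticleSizeResults",
    "TrainReport",
    "LOPOReport",
    "train",
    "leave_one_polymer_out",
]

BUNDLE_FORMAT_VERSION = 1

DATA_COLUMNS = ("polymer", "smiles", "dp", "conc_gL", "surf_gL", "size_nm")


@dataclass(frozen=True)
class FormulationInput:
    """Numeric formulation inputs for one prediction."""

    dp: float
    conc_gL: float
    surf_gL: float = 0.0

    def __post_init__(self):
        if self.dp <= 0:
            raise ValidationError(f"degree of polymerization must be > 0, got {self.dp}")
        if self.conc_gL <= 0:
            raise ValidationError(
                f"polymer concentration must be > 0 g/L, got {self.conc_gL}"
            )
        if self.surf_gL < 0:
            raise ValidationError(
                f"surfactant concentration must be >= 0 g/L, got {self.surf_gL}"
            )


@dataclass(frozen=True)
class ModelConfig:
    """Architecture and optimization settings.

    Defaults: 4 convolutional layers of width 64 (fingerprint length 128),
    FC head 128→64→32→1, cyclic ring of 10 units, dropout 0.1 on every
    convolutional and fully connected hidden layer, Adam at 1e-3, batch 64,
    up to 300 epochs with best-validation checkpointing and early stopping.
    """

    feature_spec: AtomFeatureSpec = field(default_factory=default_feature_spec)
    conv_dims: tuple = (64, 64, 64, 64)
    fc_dims: tuple = (128, 64, 32)
    ring_size: int = 10
    dropout: float = 0.1
    sum_mode: str = "gated"
    lr: float = 1e-3
    batch_size: int = 64
    max_epochs: int = 300
    patience: int = 40
    val_ratio: float = 0.2
    seed: int = 0

    def __post_init__(self):
        if self.ring_size < 3:
            raise ValidationError("ring_size must be >= 3")
        if not 0 <= self.dropout < 1:
            raise ValidationError("dropout must be in [0, 1)")


class InputScaler:
    """Log/linear transform + standardization of the numeric inputs.

    Column order is (dp, conc_gL, surf_gL) with transforms (log, log,
    linear); statistics come from the training split only.
    """

    transforms = ("log", "log", "linear")
    columns = ("dp", "conc_gL", "surf_gL")

    def __init__(self, mean=None, std=None):
        self.mean = None if mean is None else np.asarray(mean, dtype=float)
        self.std = None if std is None else np.asarray(std, dtype=float)

    def _raw(self, df: pd.DataFrame) -> np.ndarray:
        X = df.loc[:, list(self.columns)].to_numpy(dtype=float)
        out = X.copy()
        for j, t in enumerate(self.transforms):
            if t == "log":
                if (X[:, j] <= 0).any():
                    raise ValidationError(
                        f"column {self.columns[j]} must be positive for log scaling"
                    )
                out[:, j] = np.log(X[:, j])
        return out

    def fit(self, df: pd.DataFrame) -> "InputScaler":
        Z = self._raw(df)
        self.mean = Z.mean(axis=0)
        self.std = Z.std(axis=0)
        self.std[self.std == 0] = 1.0
        return self

    def transform(self, df: pd.DataFrame) -> np.ndarray:
        if self.mean is None:
            raise NotFittedError("scaler statistics unavailable; fit the model first")
        return (self._raw(df) - self.mean) / self.std

    def inverse_transform(self, Z: np.ndarray) -> np.ndarray:
        X = np.asarray(Z, dtype=float) * self.std + self.mean
        out = X.copy()
        for j, t in enumerate(self.transforms):
            if t == "log":
                out[:, j] = np.exp(X[:, j])
        return out

    def to_dict(self):
        return {"mean": self.mean.tolist(), "std": self.std.tolist()}


@dataclass
class TrainReport:
    """Per-epoch curves plus final-split metrics and error decomposition."""

    history: pd.DataFrame
    best_epoch: int
    mape_train: float
    rmse_train: float
    mape_val: float
    rmse_val: float
    worst_group: str | None
    mape_val_excl_worst: float | None
    group_table: pd.DataFrame | None

    def to_json(self, path=None):
        payload = {
            "best_epoch": self.best_epoch,
            "mape_train_pct": self.mape_train,
            "rmse_train_nm": self.rmse_train,
            "mape_val_pct": self.mape_val,
            "rmse_val_nm": self.rmse_val,
            "worst_group": self.worst_group,
            "mape_val_excl_worst_pct": self.mape_val_excl_worst,
        }
        if path is None:
            return json.dumps(payload, indent=2)
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)


def _parse_units(data: pd.DataFrame) -> dict[str, RepeatUnit]:
    units = {}
    names = data["name"] if "name" in data.columns else data["polymer"]
    for smi, name in zip(data["smiles"], names):
        if smi not in units:
            units[smi] = parse_repeat_unit(smi, name=str(name))
    return units


class ParticleSizeModel:
    """Particle-size regression model bound to a formulation dataset.

    ``data`` needs the columns polymer, smiles, dp, conc_gL, surf_gL,
    size_nm (an ``additive`` group label is derived if absent).  ``fit``
    splits 8:2 into training and validation unless an explicit split is
    passed, and is fully reproducible given the seed.
    """

    def __init__(self, data: pd.DataFrame, config: ModelConfig | None = None):
        missing = [c for c in DATA_COLUMNS if c not in data.columns]
        if missing:
            raise ValidationError(f"dataset is missing columns {missing}")
        if len(data) == 0:
            raise ValidationError("dataset is empty")
        df = data.copy().reset_index(drop=True)
        if (df["size_nm"] <= 0).any() or not np.isfinite(df["size_nm"]).all():
            raise ValidationError("measured sizes must be positive and finite")
        if (df["dp"] <= 0).any():
            raise ValidationError("degrees of polymerization must be positive")
        if "additive" not in df.columns:
            df["additive"] = np.where(df["surf_gL"].astype(float) > 0, "PVA", "none")
        self.data = df
        self.config = config or ModelConfig()
        self.units = _parse_units(df)

    @classmethod
    def from_dataframe(cls, data, config=None) -> "ParticleSizeModel":
        return cls(data, config=config)

    # ------------------------------------------------------------------

    def _graphs(self) -> dict[str, tuple[MolecularGraph, np.ndarray]]:
        cfg = self.config
        out = {}
        for smi, unit in self.units.items():
            g = build_cyclic_polymer(
                unit, cfg.ring_size, cfg.feature_spec, n_conv_layers=len(cfg.conv_dims)
            )
            out[smi] = (g, normalized_adjacency(g))
        return out

    def fit(self, seed: int | None = None, split=None, verbose: int = 0):
        cfg = self.config
        seed = cfg.seed if seed is None else int(seed)
        rng = np.random.default_rng(seed)
        df = self.data
        if split is None:
            train_df, val_df = split_dataset(df, 1.0 - cfg.val_ratio, seed)
            train_idx = train_df.index.to_numpy()
            val_idx = val_df.index.to_numpy()
        else:
            train_idx = np.asarray(split[0], dtype=int)
            val_idx = np.asarray(split[1], dtype=int)
            if np.intersect1d(train_idx, val_idx).size:
                raise ValidationError("train and validation indices overlap")
        if len(train_idx) == 0 or len(val_idx) == 0:
            raise ValidationError("empty training or validation split")

        graphs = self._graphs()
        scaler = InputScaler().fit(df.iloc[train_idx])
        Xnum = scaler.transform(df)
        y = df["size_nm"].to_numpy(dtype=float)
        smiles = df["smiles"].to_numpy()

        encoder = GCNEncoder(
            cfg.feature_spec.total_dim,
            cfg.conv_dims,
            dropout=cfg.dropout,
            sum_mode=cfg.sum_mode,
            rng=rng,
        )
        mlp = MLP(
            encoder.fingerprint_dim + Xnum.shape[1],
            cfg.fc_dims,
            dropout=cfg.dropout,
            rng=rng,
        )
        opt_params = {f"enc.{k}": v for k, v in encoder.params.items()}
        opt_params.update({f"mlp.{k}": v for k, v in mlp.params.items()})
        opt = Adam(opt_params, lr=cfg.lr)

        fp_dim = encoder.fingerprint_dim
        # rows of the training set grouped by repeat unit, for fingerprint reuse
        batch_order = np.arange(len(train_idx))
        history = []
        best = {"val_mape": np.inf, "epoch": -1, "enc": None, "mlp": None}
        stale = 0
        for epoch in range(cfg.max_epochs):
            rng.shuffle(batch_order)
            loss_num, sq_num, n_seen = 0.0, 0.0, 0
            for start in range(0, len(batch_order), cfg.batch_size):
                rows = train_idx[batch_order[start : start + cfg.batch_size]]
                batch_smiles = smiles[rows]
                uniq = pd.unique(batch_smiles)
                fps, caches = {}, {}
                for smi in uniq:
                    g, A = graphs[smi]
                    fps[smi], caches[smi] = encoder.forward(
                        g.H0, A, training=True, rng=rng
                    )
                X = np.empty((len(rows), fp_dim + Xnum.shape[1]))
                for i, (r, smi) in enumerate(zip(rows, batch_smiles)):
                    X[i, :fp_dim] = fps[smi]
                    X[i, fp_dim:] = Xnum[r]
                y_b = y[rows]
                y_hat, fc_caches = mlp.forward(X, training=True, rng=rng)
                resid = y_hat - y_b
                loss = float(np.mean(np.abs(resid) / y_b))
                if not np.isfinite(loss):
                    raise TrainingError(
                        f"training diverged (non-finite loss) at epoch {epoch}",
                        epoch=epoch,
                    )
                loss_num += loss * len(rows)
                sq_num += float(np.sum(resid**2))
                n_seen += len(rows)
                dy = np.sign(resid) / (y_b * len(rows))
                mlp_grads, dX = mlp.backward(fc_caches, dy)
                grads = {f"mlp.{k}": v for k, v in mlp_grads.items()}
                enc_grads = None
                for smi in uniq:
                    mask = batch_smiles == smi
                    d_fp = dX[mask, :fp_dim].sum(axis=0)
                    g_u = encoder.backward(caches[smi], d_fp)
                    if enc_grads is None:
                        enc_grads = g_u
                    else:
                        for k in enc_grads:
                            enc_grads[k] += g_u[k]
                grads.update({f"enc.{k}": v for k, v in enc_grads.items()})
                opt.step(grads)
            val_hat = _predict_rows(encoder, mlp, graphs, smiles[val_idx], Xnum[val_idx])
            rec = {
                "epoch": epoch,
                "train_mape": 100.0 * loss_num / n_seen,
                "train_rmse": float(np.sqrt(sq_num / n_seen)),
                "val_mape": mape(val_hat, y[val_idx]),
                "val_rmse": rmse(val_hat, y[val_idx]),
            }
            history.append(rec)
            if verbose:
                logger.info(
                    "epoch %d: train MAPE %.2f%%, val MAPE %.2f%%",
                    epoch,
                    rec["train_mape"],
                    rec["val_mape"],
                )
            if rec["val_mape"] < best["val_mape"]:
                best.update(
                    val_mape=rec["val_mape"],
                    epoch=epoch,
                    enc=copy.deepcopy(encoder.params),
                    mlp=copy.deepcopy(mlp.params),
                )
                stale = 0
            else:
                stale += 1
                if stale > cfg.patience:
                    break
        encoder.params = best["enc"]
        mlp.params = best["mlp"]
        return ParticleSizeResults(
            model=self,
            config=cfg,
            scaler=scaler,
            encoder=encoder,
            mlp=mlp,
            units=dict(self.units),
            history=pd.DataFrame(history),
            best_epoch=best["epoch"],
            train_idx=train_idx,
            val_idx=val_idx,
        )


def _predict_rows(encoder, mlp, graphs, row_smiles, Xnum_rows):
    """Evaluation-mode predictions for rows (smiles + scaled numerics)."""
    fp_dim = encoder.fingerprint_dim
    fps = {}
    for smi in pd.unique(row_smiles):
        g, A = graphs[smi]
        fps[smi], _ = encoder.forward(g.H0, A)
    X = np.empty((len(row_smiles), fp_dim + Xnum_rows.shape[1]))
    for i, smi in enumerate(row_smiles):
        X[i, :fp_dim] = fps[smi]
        X[i, fp_dim:] = Xnum_rows[i]
    y_hat, _ = mlp.forward(X)
    return y_hat


class ParticleSizeResults:
    """Fitted model state: parameters, history, diagnostics, predictions."""

    def __init__(
        self,
        model,
        config: ModelConfig,
        scaler: InputScaler,
        encoder: GCNEncoder,
        mlp: MLP,
        units: dict,
        history: pd.DataFrame,
        best_epoch: int,
        train_idx=None,
        val_idx=None,
    ):
        self.model = model
        self.config = config
        self.scaler = scaler
        self.encoder = encoder
        self.mlp = mlp
        self.units = units
        self.history = history
        self.best_epoch = best_epoch
        self.train_idx = train_idx
        self.val_idx = val_idx
        self._graph_cache: dict[str, tuple] = {}
        self._fp_cache: dict[str, np.ndarray] = {}

    # -- prediction ----------------------------------------------------

    def _unit(self, unit) -> RepeatUnit:
        if isinstance(unit, RepeatUnit):
            return unit
        if isinstance(unit, str):
            if unit in self.units:
                return self.units[unit]
            return parse_repeat_unit(unit)
        raise ValidationError(f"cannot interpret repeat unit {unit!r}")

    def _fingerprint(self, unit: RepeatUnit) -> np.ndarray:
        key = unit.smiles
        if key not in self._fp_cache:
            g = build_cyclic_polymer(
                unit,
                self.config.ring_size,
                self.config.feature_spec,
                n_conv_layers=len(self.config.conv_dims),
            )
            fp, _ = self.encoder.forward(g.H0, normalized_adjacency(g))
            self._fp_cache[key] = fp
        return self._fp_cache[key]

    def predict(self, unit, dp: float, conc_gL: float, surf_gL: float = 0.0) -> float:
        """Predicted z-average diameter in nm; deterministic in eval mode."""
        form = FormulationInput(dp=dp, conc_gL=conc_gL, surf_gL=surf_gL)
        ru = self._unit(unit)
        fp = self._fingerprint(ru)
        Xnum = self.scaler.transform(
            pd.DataFrame(
                {"dp": [form.dp], "conc_gL": [form.conc_gL], "surf_gL": [form.surf_gL]}
            )
        )
        X = np.concatenate([fp, Xnum[0]])[None, :]
        y_hat, _ = self.mlp.forward(X)
        val = float(y_hat[0])
        if val <= 0:
            logger.warning(
                "non-positive size prediction (%.3g nm) for %s at Dp=%g, c=%g g/L",
                val,
                ru.name or ru.smiles,
                dp,
                conc_gL,
            )
        return val

    def predict_df(self, df: pd.DataFrame) -> np.ndarray:
        """Vectorized predictions for a dataset-schema frame."""
        units = {smi: self._unit(smi) for smi in pd.unique(df["smiles"])}
        fps = {smi: self._fingerprint(u) for smi, u in units.items()}
        Xnum = self.scaler.transform(df)
        fp_dim = self.encoder.fingerprint_dim
        X = np.empty((len(df), fp_dim + Xnum.shape[1]))
        for i, smi in enumerate(df["smiles"]):
            X[i, :fp_dim] = fps[smi]
            X[i, fp_dim:] = Xnum[i]
        y_hat, _ = self.mlp.forward(X)
        return y_hat

    def evaluate(self, df: pd.DataFrame) -> dict:
        y_hat = self.predict_df(df)
        y = df["size_nm"].to_numpy(dtype=float)
        return {"mape": mape(y_hat, y), "rmse": rmse(y_hat, y)}

    # -- diagnostics ---------------------------------------------------

    def _split_frame(self, idx):
        if self.model is None or idx is None:
            raise NotFittedError("split data unavailable on a loaded bundle")
        return self.model.data.iloc[idx]

    @property
    def mape_train(self) -> float:
        return self.evaluate(self._split_frame(self.train_idx))["mape"]

    @property
    def mape_val(self) -> float:
        return self.evaluate(self._split_frame(self.val_idx))["mape"]

    def train_report(self) -> TrainReport:
        train_df = self._split_frame(self.train_idx)
        val_df = self._split_frame(self.val_idx)
        ev_train = self.evaluate(train_df)
        ev_val = self.evaluate(val_df)
        wg = worst_group_analysis(self.predict_df(val_df), val_df)
        return TrainReport(
            history=self.history,
            best_epoch=self.best_epoch,
            mape_train=ev_train["mape"],
            rmse_train=ev_train["rmse"],
            mape_val=ev_val["mape"],
            rmse_val=ev_val["rmse"],
            worst_group=None if wg is None else wg.label,
            mape_val_excl_worst=None if wg is None else wg.mape_excluding,
            group_table=None if wg is None else wg.table,
        )

    def summary(self) -> str:
        cfg = self.config
        lines = [
            "Particle-size GCN regression results",
            "=" * 52,
            f"repeat units:        {len(self.units)}",
            f"conv layers:         {len(cfg.conv_dims)} x {cfg.conv_dims[-1]} "
            f"(fingerprint {self.encoder.fingerprint_dim})",
            f"fc layers:           {' -> '.join(map(str, cfg.fc_dims))} -> 1",
            f"cyclic ring size:    {cfg.ring_size}",
            f"dropout:             {cfg.dropout}",
            f"epochs run:          {len(self.history)} (best: {self.best_epoch})",
        ]
        if self.model is not None and self.train_idx is not None:
            lines += [
                f"n train / val:       {len(self.train_idx)} / {len(self.val_idx)}",
                f"train MAPE / RMSE:   {self.mape_train:.2f} % / "
                f"{self.evaluate(self._split_frame(self.train_idx))['rmse']:.1f} nm",
                f"val   MAPE / RMSE:   {self.mape_val:.2f} % / "
                f"{self.evaluate(self._split_frame(self.val_idx))['rmse']:.1f} nm",
            ]
        lines.append("=" * 52)
        return "\n".join(lines)

    # -- prediction surface -------------------------------------------

    def prediction_surface(
        self,
        unit,
        dp_range=(10.0, 300.0),
        conc_range=(1.0, 30.0),
        grid_steps: int = 30,
        surf_gL: float = 0.0,
    ) -> pd.DataFrame:
        """Predicted size over a (Dp, concentration) grid, long format.

        Rows are emitted row-major (Dp outer, concentration inner) with
        columns dp, conc_gL, predicted_size_nm.
        """
        if grid_steps < 1:
            raise ValidationError("grid_steps must be positive")
        if not (dp_range[0] < dp_range[1] and conc_range[0] < conc_range[1]):
            raise ValidationError("empty parameter range")
        if dp_range[0] <= 0 or conc_range[0] <= 0:
            raise ValidationError("grid must stay within Dp > 0 and c > 0")
        ru = self._unit(unit)
        dps = np.linspace(dp_range[0], dp_range[1], grid_steps)
        concs = np.linspace(conc_range[0], conc_range[1], grid_steps)
        grid = pd.DataFrame(
            {
                "dp": np.repeat(dps, grid_steps),
                "conc_gL": np.tile(concs, grid_steps),
            }
        )
        # point-wise evaluation keeps grid values bit-identical to predict()
        grid["predicted_size_nm"] = [
            self.predict(ru, dp=row.dp, conc_gL=row.conc_gL, surf_gL=surf_gL)
            for row in grid.itertuples()
        ]
        return grid

    # -- plotting ------------------------------------------------------

    def plot_training(self, ax=None):
        """Training/validation MAPE curves over epochs."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.plot(self.history["epoch"], self.history["train_mape"], label="train")
        ax.plot(self.history["epoch"], self.history["val_mape"], label="validation")
        ax.set_xlabel("epoch")
        ax.set_ylabel("MAPE [%]")
        ax.legend()
        return ax

    def plot_surface(self, unit, ax=None, **kwargs):
        """Filled-contour prediction surface for one repeat unit."""
        import matplotlib.pyplot as plt

        surface = self.prediction_surface(unit, **kwargs)
        n = int(np.sqrt(len(surface)))
        if ax is None:
            _, ax = plt.subplots()
        cs = ax.contourf(
            surface["conc_gL"].to_numpy().reshape(n, n),
            surface["dp"].to_numpy().reshape(n, n),
            surface["predicted_size_nm"].to_numpy().reshape(n, n),
            levels=20,
        )
        ax.figure.colorbar(cs, ax=ax, label="predicted size [nm]")
        ax.set_xlabel("polymer concentration [g/L]")
        ax.set_ylabel("degree of polymerization")
        return ax

    # -- persistence ---------------------------------------------------

    def save(self, path):
        """Single JSON bundle: config, scaling stats, all layer weights."""
        cfg = self.config
        payload = {
            "format_version": BUNDLE_FORMAT_VERSION,
            "kind": "particle_size_model",
            "config": {
                "conv_dims": list(cfg.conv_dims),
                "fc_dims": list(cfg.fc_dims),
                "ring_size": cfg.ring_size,
                "dropout": cfg.dropout,
                "sum_mode": cfg.sum_mode,
                "feature_spec": {
                    "featurizers": list(cfg.feature_spec.featurizers),
                    "elements": list(cfg.feature_spec.elements),
                    "degrees": list(cfg.feature_spec.degrees),
                    "hybridizations": list(cfg.feature_spec.hybridizations),
                    "h_counts": list(cfg.feature_spec.h_counts),
                },
            },
            "scaler": self.scaler.to_dict(),
            "encoder": {"config": self.encoder.config(), "params": self.encoder.state_dict()},
            "mlp": {"config": self.mlp.config(), "params": self.mlp.state_dict()},
            "units": {smi: u.name for smi, u in self.units.items()},
            "best_epoch": self.best_epoch,
            "history": self.history.to_dict(orient="list"),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)

    @classmethod
    def load(cls, path) -> "ParticleSizeResults":
        with open(path) as fh:
            payload = json.load(fh)
        if payload.get("kind") != "particle_size_model":
            raise ValidationError(f"{path} is not a particle-size model bundle")
        fs = payload["config"]["feature_spec"]
        spec = AtomFeatureSpec(
            featurizers=tuple(fs["featurizers"]),
            elements=tuple(fs["elements"]),
            degrees=tuple(fs["degrees"]),
            hybridizations=tuple(fs["hybridizations"]),
            h_counts=tuple(fs["h_counts"]),
        )
        config = ModelConfig(
            feature_spec=spec,
            conv_dims=tuple(payload["config"]["conv_dims"]),
            fc_dims=tuple(payload["config"]["fc_dims"]),
            ring_size=payload["config"]["ring_size"],
            dropout=payload["config"]["dropout"],
            sum_mode=payload["config"]["sum_mode"],
        )
        encoder = GCNEncoder(**payload["encoder"]["config"])
        encoder.load_state_dict(payload["encoder"]["params"])
        mlp = MLP(**payload["mlp"]["config"])
        mlp.load_state_dict(payload["mlp"]["params"])
        scaler = InputScaler(**payload["scaler"])
        units = {
            smi: parse_repeat_unit(smi, name=name)
            for smi, name in payload["units"].items()
        }
        return cls(
            model=None,
            config=config,
            scaler=scaler,
            encoder=encoder,
            mlp=mlp,
            units=units,
            history=pd.DataFrame(payload.get("history", {})),
            best_epoch=payload.get("best_epoch", -1),
        )


def train(train_df: pd.DataFrame, val_df: pd.DataFrame, config: ModelConfig | None = None):
    """Train on an explicit (train, validation) pair.

    Returns ``(results, report)``; raises :class:`TrainingError` on
    divergence.
    """
    if len(train_df) == 0 or len(val_df) == 0:
        raise ValidationError("training and validation sets must be non-empty")
    config = config or ModelConfig()
    data = pd.concat([train_df, val_df], ignore_index=True)
    model = ParticleSizeModel(data, config)
    split = (np.arange(len(train_df)), np.arange(len(train_df), len(data)))
    results = model.fit(split=split)
    return results, results.train_report()


@dataclass
class LOPOReport:
    """One leave-one-polymer-out row, mirroring the study's report table.

    ``mape_test`` is the error on the held-out polymer's complete dataset;
    ``mape_all`` on the union of the held-out data and the standard test
    split.  The ``*_excl_worst`` variants remove the worst-performing group
    identified on that union.
    """

    held_out: tuple
    n_train: int
    n_val: int
    n_heldout: int
    mape_train: float
    mape_test: float
    mape_test_excl_worst: float
    mape_all: float
    mape_all_excl_worst: float
    worst_group: str | None
    group_table: pd.DataFrame | None
    results: ParticleSizeResults | None = None

    def to_dict(self) -> dict:
        return {
            "held_out": list(self.held_out),
            "n_train": self.n_train,
            "n_val": self.n_val,
            "n_heldout": self.n_heldout,
            "mape_train_pct": self.mape_train,
            "mape_test_pct": self.mape_test,
            "mape_test_excl_worst_pct": self.mape_test_excl_worst,
            "mape_all_pct": self.mape_all,
            "mape_all_excl_worst_pct": self.mape_all_excl_worst,
            "worst_group": self.worst_group,
        }


def leave_one_polymer_out(
    data: pd.DataFrame,
    holdouts,
    config: ModelConfig | None = None,
    seed: int | None = None,
    keep_results: bool = False,
) -> list[LOPOReport]:
    """Generalization protocol: retrain with each polymer (or pair) held out.

    For every entry of ``holdouts`` (a polymer id or a sequence of ids) all
    of its records are removed, the remainder is split 8:2 and trained, and
    the model is evaluated on the held-out records and on their union with
    the test split.  A leakage audit asserts that no held-out record enters
    training.
    """
    config = config or ModelConfig()
    if "additive" not in data.columns:
        data = data.copy()
        data["additive"] = np.where(data["surf_gL"].astype(float) > 0, "PVA", "none")
    all_polymers = set(data["polymer"])
    reports = []
    for entry in holdouts:
        ids = (entry,) if isinstance(entry, str) else tuple(entry)
        unknown = [p for p in ids if p not in all_polymers]
        if unknown:
            raise ValidationError(f"held-out polymer(s) with no records: {unknown}")
        if set(ids) >= all_polymers:
            raise ValidationError("cannot hold out every polymer")
        held = data[data["polymer"].isin(ids)]
        rest = data[~data["polymer"].isin(ids)]
        model = ParticleSizeModel(rest, config)
        results = model.fit(seed=seed)
        train_part = model.data.iloc[results.train_idx]
        assert not set(train_part["polymer"]) & set(ids), "held-out leakage"
        val_part = model.data.iloc[results.val_idx]
        y_held = results.predict_df(held)
        all_df = pd.concat([val_part, held], ignore_index=True)
        y_all = results.predict_df(all_df)
        wg = worst_group_analysis(y_all, all_df)
        if wg is None:
            test_excl = all_excl = float("nan")
            label = None
            table = None
        else:
            label, table = wg.label, wg.table
            mask_all = (all_df[wg.key] == wg.value).to_numpy()
            all_excl = mape(y_all[~mask_all], all_df["size_nm"].to_numpy()[~mask_all])
            mask_held = (held[wg.key] == wg.value).to_numpy()
            if mask_held.all():
                test_excl = float("nan")
            else:
                test_excl = mape(
                    y_held[~mask_held], held["size_nm"].to_numpy()[~mask_held]
                )
        reports.append(
            LOPOReport(
                held_out=ids,
                n_train=len(results.train_idx),
                n_val=len(results.val_idx),
                n_heldout=len(held),
                mape_train=results.mape_train,
                mape_test=mape(y_held, held["size_nm"].to_numpy()),
                mape_test_excl_worst=test_excl,
                mape_all=mape(y_all, all_df["size_nm"].to_numpy()),
                mape_all_excl_worst=all_excl,
                worst_group=label,
                group_table=table,
                results=results if keep_results else None,
            )
        )
    return reports
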