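"""Shallow feed-forward regression from 25 pulse-wave features to (SBP, DBP).

The network family is deliberately small: 25 inputs, two hidden layers (first
30–60 nodes in steps of 5, second 5/10/15), two outputs, ReLU activations on
hidden *and* output layers (blood pressure is positive), mean-squared-error
loss minimised with Adam, 50 epochs at batch size 10 with a 15% validation
split.  Every topology is trained twice — with and without an L1 penalty on
the first-layer weights — giving a grid of 42 models per correlation
threshold (126 over the three thresholds).

The trainer is a compact NumPy implementation (He-initialised weights, Adam
updates, optional L1 subgradient on the input layer).  The output-layer bias
is initialised to the training-target mean so the ReLU outputs start in the
active regime at mmHg scale.

Evaluation reports the pooled RMSE over both outputs, mean +- SD of the
absolute errors per output, r^2 per output, cumulative error percentages at
5/10/15 mmHg, the BHS grade (A requires >=60/85/95% of absolute errors below
5/10/15 mmHg; B >=50/75/90; C >=40/65/85; else D) and the AAMI rule (mean
error <= 5 mmHg and SD <= 8 mmHg).
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from radarbp.synthetic import FEATURE_COLUMNS, TARGET_COLUMNS

__all__ = [
    "TopologySpec",
    "TrainConfig",
    "EvalReport",
    "HIDDEN1_GRID",
    "HIDDEN2_GRID",
    "normalize_features",
    "apply_normalization",
    "denormalize_features",
    "split_dataset",
    "build_grid",
    "FeedForwardNet",
    "train_model",
    "train_grid",
    "cumulative_error_pct",
    "bhs_grade",
    "aami_check",
    "evaluate_model",
    "feature_target_correlations",
]

HIDDEN1_GRID = (30, 35, 40, 45, 50, 55, 60)
HIDDEN2_GRID = (5, 10, 15)

BHS_BOUNDS = {"A": (60.0, 85.0, 95.0), "B": (50.0, 75.0, 90.0), "C": (40.0, 65.0, 85.0)}
AAMI_MEAN_MMHG = 5.0
AAMI_SD_MMHG = 8.0


@dataclass(frozen=True)
class TopologySpec:
    """One network architecture of the grid."""

    hidden1: int
    hidden2: int
    l1_on_input: bool = False
    n_inputs: int = 25
    n_outputs: int = 2

    def __post_init__(self) -> None:
        for size in (self.n_inputs, self.hidden1, self.hidden2, self.n_outputs):
            if size <= 0:
                raise ValueError("layer sizes must be positive")

    @property
    def name(self) -> str:
        return f"{self.n_inputs}-{self.hidden1}-{self.hidden2}-{self.n_outputs}"

    @property
    def label(self) -> str:
        return self.name + ("-L1" if self.l1_on_input else "")


@dataclass
class TrainConfig:
    """Training protocol shared across the grid."""

    epochs: int = 50
    batch_size: int = 10
    validation_split: float = 0.15
    test_fraction: float = 0.2
    split_seed: int = 42
    learning_rate: float = 1e-3
    adam_beta1: float = 0.9
    adam_beta2: float = 0.999
    adam_eps: float = 1e-8
    l1_coeff: float = 1e-3
    init_seed: int = 0
    output_relu: bool = True

    def __post_init__(self) -> None:
        if not (0.0 < self.validation_split < 1.0):
            raise ValueError("validation_split must lie in (0, 1)")
        if not (0.0 < self.test_fraction < 1.0):
            raise ValueError("test_fraction must lie in (0, 1)")


@dataclass
class EvalReport:
    """Regression metrics plus AAMI/BHS grading for one trained model."""

    rmse: float
    rmse_sys: float
    rmse_dia: float
    sys_mean_abs_err: float
    sys_err_sd: float
    dia_mean_abs_err: float
    dia_err_sd: float
    sys_signed_mean: float
    dia_signed_mean: float
    r2_sys: float
    r2_dia: float
    sys_cum: tuple[float, float, float]
    dia_cum: tuple[float, float, float]
    bhs_grade_sys: str
    bhs_grade_dia: str
    aami_pass_sys: bool
    aami_pass_dia: bool
    n_test: int

    def to_dict(self) -> dict:
        return asdict(self)


def normalize_features(
    table: pd.DataFrame, columns: list[str] | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Column-wise min-max scaling to [0, 1]; returns (scaled, bounds).

    Constant columns map to zero with a warning.  The returned bounds frame
    (rows ``min``/``max``) reapplies the identical scaling to new data.
    """
    if len(table) < 2:
        raise ValueError("need at least 2 rows to normalize")
    columns = list(columns) if columns is not None else list(table.columns)
    out = table.copy()
    mins, maxs = {}, {}
    for col in columns:
        lo, hi = table[col].min(), table[col].max()
        mins[col], maxs[col] = float(lo), float(hi)
        if hi > lo:
            out[col] = (table[col] - lo) / (hi - lo)
        else:
            warnings.warn(f"constant feature column '{col}' mapped to 0", stacklevel=2)
            out[col] = 0.0
    bounds = pd.DataFrame([mins, maxs], index=["min", "max"])
    return out, bounds


def apply_normalization(table: pd.DataFrame, bounds: pd.DataFrame) -> pd.DataFrame:
    out = table.copy()
    for col in bounds.columns:
        lo, hi = bounds.loc["min", col], bounds.loc["max", col]
        out[col] = (table[col] - lo) / (hi - lo) if hi > lo else 0.0
    return out


def denormalize_features(table: pd.DataFrame, bounds: pd.DataFrame) -> pd.DataFrame:
    out = table.copy()
    for col in bounds.columns:
        lo, hi = bounds.loc["min", col], bounds.loc["max", col]
        out[col] = table[col] * (hi - lo) + lo
    return out


def split_dataset(
    table: pd.DataFrame, cfg: TrainConfig
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Deterministic shuffled train/test split (default 80/20, seed 42)."""
    n = len(table)
    if n < 5:
        raise ValueError("need at least 5 rows to split")
    rng = np.random.default_rng(cfg.split_seed)
    perm = rng.permutation(n)
    n_train = math.ceil((1.0 - cfg.test_fraction) * n)
    return (
        table.iloc[perm[:n_train]].reset_index(drop=True),
        table.iloc[perm[n_train:]].reset_index(drop=True),
    )


def build_grid(
    hidden1_sizes=HIDDEN1_GRID,
    hidden2_sizes=HIDDEN2_GRID,
    regularization=(False, True),
) -> list[TopologySpec]:
    """Full architecture grid: h1 ascending, h2 ascending, L1 off then on."""
    return [
        TopologySpec(hidden1=h1, hidden2=h2, l1_on_input=reg)
        for h1 in hidden1_sizes
        for h2 in hidden2_sizes
        for reg in regularization
    ]


def _relu(x: np.ndarray) -> np.ndarray:
    return np.maximum(x, 0.0)


class FeedForwardNet:
    """25-h1-h2-2 fully connected network with ReLU activations."""

    def __init__(self, spec: TopologySpec, seed: int = 0, output_relu: bool = True):
        self.spec = spec
        self.output_relu = output_relu
        rng = np.random.default_rng(seed)
        sizes = [spec.n_inputs, spec.hidden1, spec.hidden2, spec.n_outputs]
        self.weights = [
            rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(fan_in, fan_out))
            for fan_in, fan_out in zip(sizes[:-1], sizes[1:])
        ]
        self.biases = [np.zeros(fan_out) for fan_out in sizes[1:]]

    def _forward(self, x: np.ndarray):
        pre, post = [], [x]
        h = x
        for layer, (w, b) in enumerate(zip(self.weights, self.biases)):
            z = h @ w + b
            pre.append(z)
            last = layer == len(self.weights) - 1
            h = _relu(z) if (not last or self.output_relu) else z
            post.append(h)
        return pre, post

    def predict(self, x: np.ndarray) -> np.ndarray:
        return self._forward(np.asarray(x, dtype=float))[1][-1]

    # -- persistence ---------------------------------------------------
    def save(self, path: str | Path, bounds: pd.DataFrame | None = None) -> None:
        path = Path(path)
        arrays = {f"w{i}": w for i, w in enumerate(self.weights)}
        arrays.update({f"b{i}": b for i, b in enumerate(self.biases)})
        np.savez(path.with_suffix(".npz"), **arrays)
        meta = {
            "name": self.spec.name,
            "hidden1": self.spec.hidden1,
            "hidden2": self.spec.hidden2,
            "l1_on_input": self.spec.l1_on_input,
            "n_inputs": self.spec.n_inputs,
            "n_outputs": self.spec.n_outputs,
            "output_relu": self.output_relu,
        }
        if bounds is not None:
            meta["normalization"] = bounds.to_dict()
        path.with_suffix(".json").write_text(json.dumps(meta, indent=2))

    @classmethod
    def load(cls, path: str | Path) -> tuple["FeedForwardNet", pd.DataFrame | None]:
        path = Path(path)
        meta = json.loads(path.with_suffix(".json").read_text())
        spec = TopologySpec(
            hidden1=meta["hidden1"], hidden2=meta["hidden2"],
            l1_on_input=meta["l1_on_input"], n_inputs=meta["n_inputs"],
            n_outputs=meta["n_outputs"],
        )
        net = cls(spec, seed=0, output_relu=meta["output_relu"])
        data = np.load(path.with_suffix(".npz"))
        net.weights = [data[f"w{i}"] for i in range(3)]
        net.biases = [data[f"b{i}"] for i in range(3)]
        bounds = None
        if "normalization" in meta:
            bounds = pd.DataFrame(meta["normalization"]).loc[["min", "max"]]
        return net, bounds


def _split_xy(table: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    x = table[FEATURE_COLUMNS].to_numpy(dtype=float)
    y = table[TARGET_COLUMNS].to_numpy(dtype=float)
    return x, y


def train_model(
    spec: TopologySpec,
    train_table: pd.DataFrame,
    cfg: TrainConfig,
) -> tuple[FeedForwardNet, pd.DataFrame]:
    """Train one network on a normalized feature table (targets in mmHg).

    Returns the network and a per-epoch history frame (train/validation MSE
    loss and RMSE).  The validation rows are split off deterministically from
    ``init_seed`` before training.
    """
    x, y = _split_xy(train_table)
    net = FeedForwardNet(spec, seed=cfg.init_seed, output_relu=cfg.output_relu)
    history = pd.DataFrame(columns=["epoch", "loss", "val_loss", "rmse", "val_rmse"])
    if cfg.epochs == 0:
        return net, history

    rng = np.random.default_rng(cfg.init_seed)
    n = x.shape[0]
    perm = rng.permutation(n)
    n_val = max(1, int(round(cfg.validation_split * n)))
    if n_val >= n:
        raise ValueError("validation split leaves no training rows")
    val_idx, tr_idx = perm[:n_val], perm[n_val:]
    x_tr, y_tr = x[tr_idx], y[tr_idx]
    x_val, y_val = x[val_idx], y[val_idx]

    # start the ReLU output in its active regime at mmHg scale
    net.biases[-1] = y_tr.mean(axis=0).copy()

    params = net.weights + net.biases
    m_t = [np.zeros_like(p) for p in params]
    v_t = [np.zeros_like(p) for p in params]
    b1, b2, eps_a = cfg.adam_beta1, cfg.adam_beta2, cfg.adam_eps
    step = 0
    records = []
    n_tr = x_tr.shape[0]
    for epoch in range(cfg.epochs):
        order = rng.permutation(n_tr)
        for start in range(0, n_tr, cfg.batch_size):
            batch = order[start : start + cfg.batch_size]
            xb, yb = x_tr[batch], y_tr[batch]
            pre, post = net._forward(xb)
            pred = post[-1]
            if not np.all(np.isfinite(pred)):
                raise FloatingPointError(
                    f"non-finite prediction at epoch {epoch}, step {step}"
                )
            # dL/dpred for L = mean over batch and outputs of squared error
            grad = 2.0 * (pred - yb) / yb.size
            grads_w, grads_b = [], []
            delta = grad
            for layer in reversed(range(3)):
                last = layer == 2
                if not last or net.output_relu:
                    delta = delta * (pre[layer] > 0)
                grads_w.insert(0, post[layer].T @ delta)
                grads_b.insert(0, delta.sum(axis=0))
                if layer > 0:
                    delta = delta @ net.weights[layer].T
            if spec.l1_on_input:
                grads_w[0] = grads_w[0] + cfg.l1_coeff * np.sign(net.weights[0])

            step += 1
            grads = grads_w + grads_b
            for i, (p, g) in enumerate(zip(params, grads)):
                m_t[i] = b1 * m_t[i] + (1 - b1) * g
                v_t[i] = b2 * v_t[i] + (1 - b2) * g * g
                m_hat = m_t[i] / (1 - b1**step)
                v_hat = v_t[i] / (1 - b2**step)
                p -= cfg.learning_rate * m_hat / (np.sqrt(v_hat) + eps_a)

        tr_mse = float(np.mean((net.predict(x_tr) - y_tr) ** 2))
        val_mse = float(np.mean((net.predict(x_val) - y_val) ** 2))
        records.append(
            {"epoch": epoch, "loss": tr_mse, "val_loss": val_mse,
             "rmse": math.sqrt(tr_mse), "val_rmse": math.sqrt(val_mse)}
        )
    return net, pd.DataFrame.from_records(records)


def evaluate_model(model: FeedForwardNet, test_table: pd.DataFrame) -> EvalReport:
    """Apply a trained model to unseen rows and grade the errors."""
    x, y = _split_xy(test_table)
    if x.shape[0] == 0:
        raise ValueError("empty test set")
    pred = model.predict(x)
    err = pred - y  # signed, columns (sys, dia)
    abs_err = np.abs(err)
    sq = err**2

    def _r2(col: int) -> float:
        ss_res = sq[:, col].sum()
        ss_tot = ((y[:, col] - y[:, col].mean()) ** 2).sum()
        return float(1.0 - ss_res / ss_tot) if ss_tot > 0 else float("nan")

    sys_cum = cumulative_error_pct(abs_err[:, 0])
    dia_cum = cumulative_error_pct(abs_err[:, 1])
    sys_mean, sys_sd = float(abs_err[:, 0].mean()), float(abs_err[:, 0].std())
    dia_mean, dia_sd = float(abs_err[:, 1].mean()), float(abs_err[:, 1].std())
    return EvalReport(
        rmse=float(np.sqrt(sq.mean())),
        rmse_sys=float(np.sqrt(sq[:, 0].mean())),
        rmse_dia=float(np.sqrt(sq[:, 1].mean())),
        sys_mean_abs_err=sys_mean,
        sys_err_sd=sys_sd,
        dia_mean_abs_err=dia_mean,
        dia_err_sd=dia_sd,
        sys_signed_mean=float(err[:, 0].mean()),
        dia_signed_mean=float(err[:, 1].mean()),
        r2_sys=_r2(0),
        r2_dia=_r2(1),
        sys_cum=sys_cum,
        dia_cum=dia_cum,
        bhs_grade_sys=bhs_grade(*sys_cum),
        bhs_grade_dia=bhs_grade(*dia_cum),
        aami_pass_sys=aami_check(sys_mean, sys_sd),
        aami_pass_dia=aami_check(dia_mean, dia_sd),
        n_test=x.shape[0],
    )


def train_grid(
    table: pd.DataFrame,
    cfg: TrainConfig | None = None,
    grid: list[TopologySpec] | None = None,
) -> pd.DataFrame:
    """Train and evaluate every grid architecture on one table.

    The table's feature columns are min-max normalized (targets stay in
    mmHg), split 80/20, and each architecture trained on the same split.
    Returns one row per model with its evaluation report, sorted by the grid
    order; the best model is the RMSE argmin.
    """
    cfg = cfg or TrainConfig()
    grid = grid or build_grid()
    normed, _bounds = normalize_features(table, columns=FEATURE_COLUMNS)
    train_tbl, test_tbl = split_dataset(normed, cfg)
    rows = []
    for spec in grid:
        model, _history = train_model(spec, train_tbl, cfg)
        report = evaluate_model(model, test_tbl)
        row = {"name": spec.name, "label": spec.label,
               "hidden1": spec.hidden1, "hidden2": spec.hidden2,
               "l1_on_input": spec.l1_on_input}
        row.update(report.to_dict())
        rows.append(row)
    return pd.DataFrame.from_records(rows)


def cumulative_error_pct(
    abs_errors: np.ndarray, thresholds: tuple[float, ...] = (5.0, 10.0, 15.0)
) -> tuple[float, ...]:
    """Percentage of absolute errors at or below each threshold."""
    e = np.asarray(abs_errors, dtype=float)
    if e.size == 0:
        raise ValueError("empty error sequence")
    return tuple(float(100.0 * np.mean(e <= th)) for th in thresholds)


def bhs_grade(cum5: float, cum10: float, cum15: float) -> str:
    """Best BHS grade whose three cumulative-percentage bounds are all met."""
    for grade, bounds in BHS_BOUNDS.items():
        if cum5 >= bounds[0] and cum10 >= bounds[1] and cum15 >= bounds[2]:
            return grade
    return "D"


def aami_check(mean_abs_err: float, err_sd: float) -> bool:
    """AAMI rule: mean error <= 5.0 mmHg and standard deviation <= 8.0 mmHg."""
    if mean_abs_err < 0 or err_sd < 0:
        raise ValueError("error statistics must be non-negative")
    return mean_abs_err <= AAMI_MEAN_MMHG and err_sd <= AAMI_SD_MMHG


def feature_target_correlations(table: pd.DataFrame) -> dict[str, pd.DataFrame]:
    """Pearson correlation of every feature with each target, ranked by |r|."""
    if len(table) < 3:
        raise ValueError("need at least 3 rows")
    out = {}
    for target in TARGET_COLUMNS:
        y = table[target].to_numpy(dtype=float)
        rows = []
        for col in FEATURE_COLUMNS:
            xcol = table[col].to_numpy(dtype=float)
            if np.std(xcol) == 0 or np.std(y) == 0:
                r = float("nan")
            else:
                r = float(np.corrcoef(xcol, y)[0, 1])
            rows.append({"feature": col, "correlation": r})
        df = pd.DataFrame(rows)
        df["abs_correlation"] = df["correlation"].abs()
        df = (df.sort_values("abs_correlation", ascending=False, na_position="last")
                .drop(columns="abs_correlation").reset_index(drop=True))
        out[target] = df
    return out
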