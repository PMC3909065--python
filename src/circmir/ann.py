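"""Single-probe ANN ranking with Monte Carlo cross-validation.

Each array probe is scored by training a tiny feed-forward network
(1 input → 2 sigmoid hidden → 1 sigmoid output) by classical online
back-propagation with momentum, minimising squared error, with early
stopping on a held-out validation split. Classification performance is
measured only on a blind test split never touched during training, and the
whole procedure is repeated over many stratified random train/validation/
test splits (Monte Carlo cross-validation). Probes are ranked by mean blind
accuracy; repeated random blind splits keep single-probe over-fitting from
inflating the rank order.
"""

from __future__ import annotations

import math
import zlib
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .synthetic import UNDETERMINED

__all__ = [
    "TrainConfig",
    "SplitScheme",
    "ProbeScore",
    "ScreenMatrix",
    "TrainedNetwork",
    "prepare_screen_matrix",
    "train_ann",
    "mccv_score_probe",
    "rank_probes",
    "select_top_k",
]


@dataclass(frozen=True)
class TrainConfig:
    """Back-propagation hyper-parameters for the 1-2-1 sigmoid network."""

    hidden_nodes: int = 2
    learning_rate: float = 0.1
    momentum: float = 0.5
    max_epochs: int = 3000
    patience: int = 100
    weight_init_range: float = 0.5
    loss: str = "squared_error"  # or "cross_entropy"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.hidden_nodes < 1:
            raise ValueError("hidden_nodes must be >= 1")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if not 0 <= self.momentum < 1:
            raise ValueError("momentum must be in [0, 1)")
        if self.patience >= self.max_epochs:
            raise ValueError("patience must be smaller than max_epochs")
        if self.loss not in ("squared_error", "cross_entropy"):
            raise ValueError("loss must be squared_error or cross_entropy")


@dataclass(frozen=True)
class SplitScheme:
    """Stratified Monte Carlo train/validation/blind-test splitting."""

    train_frac: float = 0.6
    val_frac: float = 0.2
    test_frac: float = 0.2
    n_repeats: int = 50
    stratified: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        total = self.train_frac + self.val_frac + self.test_frac
        if abs(total - 1.0) > 1e-9:
            raise ValueError("split fractions must sum to 1")
        if min(self.train_frac, self.val_frac, self.test_frac) <= 0:
            raise ValueError("all split fractions must be positive")
        if self.n_repeats < 1:
            raise ValueError("n_repeats must be >= 1")


@dataclass(frozen=True)
class ProbeScore:
    probe_id: str
    mean_test_accuracy: float
    sd_test_accuracy: float
    mean_test_auc: float
    mean_val_mse: float
    n_repeats: int

    def sort_key(self):
        """Descending accuracy, then AUC, then ascending val MSE, then id."""
        return (-round(self.mean_test_accuracy, 12),
                -round(self.mean_test_auc, 12),
                round(self.mean_val_mse, 12),
                self.probe_id)


@dataclass
class ScreenMatrix:
    """Prepared screen: samples × probes in [0, 1], no missing cells."""

    values: np.ndarray
    labels: np.ndarray  # 1 = case, 0 = control
    probe_ids: list[str]
    sample_ids: list[str]
    detect_fraction: pd.DataFrame  # probes × {case, control}

    def column(self, probe_id: str) -> np.ndarray:
        return self.values[:, self.probe_ids.index(probe_id)]


def prepare_screen_matrix(ct_table: pd.DataFrame, sample_sheet: pd.DataFrame,
                          max_cycles: float = 40.0,
                          min_detect_fraction: float = 0.5) -> ScreenMatrix:
    """Build the ANN input matrix from a single-replicate C_T screen.

    Non-detected wells are capped at ``max_cycles`` (C_T 40). Probes whose
    detection fraction (numeric C_T strictly below the cap) is under 50% in
    BOTH groups are excluded — a probe detectable in either group alone is
    informative and kept. Retained C_T values are converted to an expression
    scale (40 − C_T) and min-max scaled to [0, 1] per probe over the full
    screen; zero-range columns map to 0.
    """
    groups = sample_sheet.set_index("sample_id")["group"]
    keep = groups.isin(["case", "control"])
    groups = groups[keep]
    labels_by_sample = (groups == "case").astype(int)
    if labels_by_sample.sum() == 0 or (1 - labels_by_sample).sum() == 0:
        raise ValueError("screen requires samples from both groups")

    tab = ct_table[ct_table["sample_id"].isin(groups.index)].copy()
    ct_num = pd.to_numeric(tab["ct"], errors="coerce")
    tab["ct_capped"] = ct_num.clip(upper=max_cycles).fillna(max_cycles)
    tab["detected"] = ct_num.notna() & (ct_num < max_cycles)

    wide = tab.pivot_table(index="sample_id", columns="mirna_id",
                           values="ct_capped", aggfunc="mean")
    wide = wide.reindex(groups.index)
    det = tab.pivot_table(index="sample_id", columns="mirna_id",
                          values="detected", aggfunc="mean").reindex(groups.index)
    grp = groups.map({"case": "case", "control": "control"})
    detect_fraction = det.groupby(grp).mean().T  # probes × groups
    kept = detect_fraction.max(axis=1) >= min_detect_fraction
    probe_ids = sorted(detect_fraction.index[kept])
    if not probe_ids:
        raise ValueError("no probe passes the detectability filter")

    expr = (max_cycles - wide[probe_ids]).to_numpy(dtype=float)
    lo, hi = expr.min(axis=0), expr.max(axis=0)
    span = hi - lo
    scaled = np.where(span > 0, (expr - lo) / np.where(span > 0, span, 1.0), 0.0)
    return ScreenMatrix(values=scaled,
                        labels=labels_by_sample.to_numpy(),
                        probe_ids=probe_ids,
                        sample_ids=list(groups.index),
                        detect_fraction=detect_fraction.loc[probe_ids])


# ---------------------------------------------------------------------------
# the network


@dataclass
class TrainedNetwork:
    """Weights of the best-validation epoch plus the validation trace."""

    w1: np.ndarray  # hidden weights (hidden,)
    b1: np.ndarray
    w2: np.ndarray  # output weights (hidden,)
    b2: float
    best_val_mse: float
    best_epoch: int
    val_trace: list[float]

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        h = 1.0 / (1.0 + np.exp(-(np.outer(x, self.w1) + self.b1)))
        z = h @ self.w2 + self.b2
        return 1.0 / (1.0 + np.exp(-z))


def _train_loop(xt, yt, xv, yv, perms, w1, b1, w2, b2, lr, mom,
                patience, xent):
    """Online back-propagation with momentum; early stopping on val MSE.

    Pure-numerics inner loop (JIT-compiled when numba is available). Visits
    the training patterns in the pre-drawn per-epoch orders ``perms``;
    records validation MSE after every epoch; returns the weights of the
    best validation epoch, its MSE/epoch and the recorded trace.
    """
    nh = w1.shape[0]
    max_epochs = perms.shape[0]
    n_tr = xt.shape[0]
    dw1 = np.zeros(nh)
    db1 = np.zeros(nh)
    dw2 = np.zeros(nh)
    db2 = 0.0
    trace = np.empty(max_epochs + 1)

    # validation MSE of the initial weights
    mse = 0.0
    for i in range(xv.shape[0]):
        z = 0.0
        for j in range(nh):
            z += w2[j] / (1.0 + math.exp(-(xv[i] * w1[j] + b1[j])))
        o = 1.0 / (1.0 + math.exp(-(z + b2)))
        mse += (o - yv[i]) ** 2
    mse /= xv.shape[0]
    trace[0] = mse

    best_w1 = w1.copy()
    best_b1 = b1.copy()
    best_w2 = w2.copy()
    best_b2 = b2
    best_mse = mse
    best_epoch = 0
    since_improve = 0
    n_epochs = 0

    h = np.empty(nh)
    for epoch in range(1, max_epochs + 1):
        n_epochs = epoch
        for k in range(n_tr):
            i = perms[epoch - 1, k]
            xi = xt[i]
            yi = yt[i]
            z = 0.0
            for j in range(nh):
                h[j] = 1.0 / (1.0 + math.exp(-(xi * w1[j] + b1[j])))
                z += h[j] * w2[j]
            o = 1.0 / (1.0 + math.exp(-(z + b2)))
            if xent:
                delta_o = o - yi
            else:
                delta_o = (o - yi) * o * (1.0 - o)
            for j in range(nh):
                delta_h = delta_o * w2[j] * h[j] * (1.0 - h[j])
                dw2[j] = -lr * delta_o * h[j] + mom * dw2[j]
                w2[j] += dw2[j]
                dw1[j] = -lr * delta_h * xi + mom * dw1[j]
                w1[j] += dw1[j]
                db1[j] = -lr * delta_h + mom * db1[j]
                b1[j] += db1[j]
            db2 = -lr * delta_o + mom * db2
            b2 += db2
        mse = 0.0
        for i in range(xv.shape[0]):
            z = 0.0
            for j in range(nh):
                z += w2[j] / (1.0 + math.exp(-(xv[i] * w1[j] + b1[j])))
            o = 1.0 / (1.0 + math.exp(-(z + b2)))
            mse += (o - yv[i]) ** 2
        mse /= xv.shape[0]
        trace[epoch] = mse
        if mse < best_mse - 1e-12:
            best_mse = mse
            best_w1 = w1.copy()
            best_b1 = b1.copy()
            best_w2 = w2.copy()
            best_b2 = b2
            best_epoch = epoch
            since_improve = 0
        else:
            since_improve += 1
            if since_improve >= patience:
                break
    return best_w1, best_b1, best_w2, best_b2, best_mse, best_epoch, trace, n_epochs


try:  # JIT-compile the hot loop when numba is present
    from numba import njit

    _train_loop_fast = njit(cache=True)(_train_loop)
except ImportError:  # pragma: no cover
    _train_loop_fast = _train_loop


def train_ann(x: np.ndarray, y: np.ndarray, config: TrainConfig,
              train_idx: np.ndarray, val_idx: np.ndarray,
              rng: np.random.Generator) -> TrainedNetwork:
    """Train the 1-2-1 sigmoid network by online back-propagation.

    Patterns are visited in a freshly shuffled order each epoch; weight
    updates use gradient descent with momentum on the squared error
    (optionally cross-entropy). After every epoch the validation MSE is
    recorded; training stops at ``max_epochs`` or once validation MSE has
    not improved for ``patience`` epochs, and the weights of the best
    validation epoch are returned — so the blind test split is never seen.
    """
    for idx, name in ((train_idx, "training"), (val_idx, "validation")):
        if len(np.unique(y[idx])) < 2:
            raise ValueError(f"degenerate {name} partition (single class); re-split")

    nh = config.hidden_nodes
    r = config.weight_init_range
    w1 = rng.uniform(-r, r, nh)
    b1 = rng.uniform(-r, r, nh)
    w2 = rng.uniform(-r, r, nh)
    b2 = float(rng.uniform(-r, r))

    xt = np.ascontiguousarray(x[train_idx], dtype=float)
    yt = np.ascontiguousarray(y[train_idx], dtype=float)
    xv = np.ascontiguousarray(x[val_idx], dtype=float)
    yv = np.ascontiguousarray(y[val_idx], dtype=float)
    # pre-draw all epoch orders so the compiled loop stays deterministic
    perms = rng.permuted(
        np.tile(np.arange(len(xt)), (config.max_epochs, 1)), axis=1)

    bw1, bb1, bw2, bb2, best_mse, best_epoch, trace, n_epochs = _train_loop_fast(
        xt, yt, xv, yv, perms, w1, b1, w2, b2,
        config.learning_rate, config.momentum, config.patience,
        config.loss == "cross_entropy")
    return TrainedNetwork(bw1, bb1, bw2, float(bb2), float(best_mse),
                          int(best_epoch), trace[:n_epochs + 1].tolist())


# ---------------------------------------------------------------------------
# Monte Carlo cross-validation


def _stratified_split(y: np.ndarray, scheme: SplitScheme,
                      rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """One stratified train/val/test split; every partition keeps both classes."""
    train, val, test = [], [], []
    for cls in np.unique(y):
        idx = np.where(y == cls)[0]
        idx = rng.permutation(idx)
        n = len(idx)
        n_tr = max(1, int(round(scheme.train_frac * n)))
        n_va = max(1, int(round(scheme.val_frac * n)))
        n_tr = min(n_tr, n - 2)  # leave room for val and test
        n_va = min(n_va, n - n_tr - 1)
        train.extend(idx[:n_tr])
        val.extend(idx[n_tr:n_tr + n_va])
        test.extend(idx[n_tr + n_va:])
    return (np.array(sorted(train)), np.array(sorted(val)), np.array(sorted(test)))


def _blind_auc(scores: np.ndarray, labels: np.ndarray) -> float:
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    if len(pos) == 0 or len(neg) == 0:
        return math.nan
    greater = (pos[:, None] > neg[None, :]).sum()
    ties = (pos[:, None] == neg[None, :]).sum()
    return (greater + 0.5 * ties) / (len(pos) * len(neg))


def mccv_score_probe(x: np.ndarray, y: np.ndarray, config: TrainConfig,
                     scheme: SplitScheme, probe_id: str = "probe",
                     rng: np.random.Generator | None = None) -> ProbeScore:
    """Score one probe over repeated stratified splits.

    Accuracy (probability threshold 0.5) and AUC are computed on the blind
    test partition only; the summary reports means and SD over repeats.
    """
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence(
            [config.seed & 0x7FFFFFFF, zlib.crc32(probe_id.encode())]))
    accs, aucs, val_mses = [], [], []
    for _ in range(scheme.n_repeats):
        tr, va, te = _stratified_split(y, scheme, rng)
        net = train_ann(x, y, config, tr, va, rng)
        p = net.predict_proba(x[te])
        accs.append(float(np.mean((p >= 0.5).astype(int) == y[te])))
        aucs.append(_blind_auc(p, y[te]))
        val_mses.append(net.best_val_mse)
    aucs = [a for a in aucs if not math.isnan(a)]
    return ProbeScore(
        probe_id=probe_id,
        mean_test_accuracy=float(np.mean(accs)),
        sd_test_accuracy=float(np.std(accs, ddof=1)) if len(accs) > 1 else 0.0,
        mean_test_auc=float(np.mean(aucs)) if aucs else math.nan,
        mean_val_mse=float(np.mean(val_mses)),
        n_repeats=scheme.n_repeats,
    )


def rank_probes(matrix: ScreenMatrix, config: TrainConfig,
                scheme: SplitScheme) -> list[ProbeScore]:
    """Score every probe and sort by blind performance.

    Each probe draws its own RNG stream from (seed, probe_id), so the rank
    order is reproducible and invariant to probe column order. Ties break by
    higher blind AUC, then lower validation MSE, then probe id.
    """
    scores = []
    for pid in matrix.probe_ids:
        x = matrix.column(pid)
        rng = np.random.default_rng(np.random.SeedSequence(
            [config.seed & 0x7FFFFFFF, zlib.crc32(pid.encode())]))
        scores.append(mccv_score_probe(x, matrix.labels, config, scheme, pid, rng))
    return sorted(scores, key=ProbeScore.sort_key)


def select_top_k(ranked: Sequence[ProbeScore], k: int) -> list[str]:
    """First k probe ids of the ranked list (k may be 0)."""
    if k > len(ranked):
        raise ValueError(f"k={k} exceeds ranked-list length {len(ranked)}")
    return [s.probe_id for s in ranked[:k]]


def ranked_list_frame(ranked: Sequence[ProbeScore]) -> pd.DataFrame:
    return pd.DataFrame([{
        "rank": i + 1, "probe_id": s.probe_id,
        "mean_test_accuracy": s.mean_test_accuracy,
        "sd_test_accuracy": s.sd_test_accuracy,
        "mean_test_auc": s.mean_test_auc,
        "mean_val_mse": s.mean_val_mse,
        "n_repeats": s.n_repeats,
    } for i, s in enumerate(ranked)])
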