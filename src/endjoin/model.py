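"""Three-component logistic predictor of end-joining repair outcomes.

The predictor decomposes the outcome distribution of a target into

* an **indel ratio** component: a binary logistic regression on the 384
  one-hot protospacer features giving the overall insertion fraction
  ``p_ins`` (microhomology features do not help here);
* a **deletion** component: a softmax regression over the deletion-class
  catalog on sequence + microhomology features (3100 features with the
  default 550-class catalog);
* an **insertion** component: a softmax regression over the 21 insertion
  classes on the 104 cut-proximal hexamer features.

Each component is trained independently on *soft labels* -- the observed
class frequencies -- with categorical cross-entropy, an Adam optimizer
(learning rate 0.001, full batch), at most 100 epochs and early stopping
with patience 1, scanning L1/L2 penalty strengths over a 1e-10..1e-1 grid
and selecting by validation MSE.  Prediction intersects the components:
``P(del c) = (1 - p_ins) softmax_del(c)``, ``P(ins j) = p_ins
softmax_ins(j)``, with redundant deletion classes collapsed onto their
sequence-specific canonicals.

Usage follows the model/results idiom::

    model = RepairOutcomeModel(targets, distributions)
    res = model.fit(l2_grid=[1e-6, 1e-4, 1e-2])
    dist = res.predict(targets[0])
    print(res.summary())
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, replace

import numpy as np

from .catalog import (CatalogConfig, DEFAULT_CONFIG, DeletionClass,
                      TargetContext, collapse_redundant,
                      enumerate_deletion_classes, enumerate_insertion_classes,
                      parse_event_id)
from .distributions import OutcomeDistribution, evaluate_mse
from .features import (assemble_features, encode_hexamer,
                       encode_target_onehot, SCHEMA_VERSION)
from .microhomology import annotate_mh

MODEL_FORMAT = "endjoin-model-1"

#: the canonical penalty-strength scan
DEFAULT_LAMBDA_GRID = tuple(10.0 ** e for e in range(-10, 0))


class ModelError(ValueError):
    pass


@dataclass(frozen=True)
class ModelConfig:
    """Optimisation settings for one component."""

    penalty: str = "l2"          # "l1" | "l2"
    lam: float = 1e-5
    learning_rate: float = 0.001
    max_epochs: int = 100
    patience: int = 1
    batch_size: int | None = 32  # None = full batch
    seed: int = 0

    def __post_init__(self) -> None:
        if self.penalty not in ("l1", "l2"):
            raise ModelError(f"penalty must be l1 or l2, got {self.penalty!r}")
        if self.lam < 0:
            raise ModelError("lam must be >= 0")
        if self.patience < 0:
            raise ModelError("patience must be >= 0")


def _softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def _add_bias(X: np.ndarray) -> np.ndarray:
    return np.hstack([X, np.ones((X.shape[0], 1))])


def predict_probs(X: np.ndarray, W: np.ndarray) -> np.ndarray:
    """Softmax probabilities for a weight matrix with trailing bias row."""
    return _softmax(_add_bias(np.atleast_2d(X)) @ W)


def _cross_entropy(P: np.ndarray, Y: np.ndarray) -> float:
    return float(-(Y * np.log(np.clip(P, 1e-12, None))).sum(axis=1).mean())


def train_component(X: np.ndarray, Y: np.ndarray, cfg: ModelConfig,
                    X_val: np.ndarray | None = None,
                    Y_val: np.ndarray | None = None
                    ) -> tuple[np.ndarray, list[dict]]:
    """Fit one softmax component on soft labels.

    Mini-batch Adam (beta1 0.9, beta2 0.999, eps 1e-7) from zero-initialised
    weights, with a seeded shuffle per epoch; the penalty is applied to
    everything except the bias row.  With a validation set, training stops
    once the validation cross-entropy has not improved for ``patience + 1``
    consecutive epochs and the best-epoch weights are restored.  Returns
    ``(weights, history)`` where weights has shape
    ``(n_features + 1, n_classes)``.
    """
    X = np.asarray(X, dtype=np.float64)
    Y = np.asarray(Y, dtype=np.float64)
    if X.ndim != 2 or Y.ndim != 2 or X.shape[0] != Y.shape[0]:
        raise ModelError("X and Y must be 2-D with matching row counts")
    if X.shape[0] == 0:
        raise ModelError("empty training set")
    if not np.allclose(Y.sum(axis=1), 1.0, atol=1e-6):
        raise ModelError("soft-label rows must sum to 1")
    n, d = X.shape
    k = Y.shape[1]
    Xb = _add_bias(X)
    Xvb = _add_bias(np.asarray(X_val, dtype=np.float64)) if X_val is not None else None

    W = np.zeros((d + 1, k))
    m = np.zeros_like(W)
    v = np.zeros_like(W)
    beta1, beta2, eps = 0.9, 0.999, 1e-7
    rng = np.random.default_rng(cfg.seed)
    bs = n if cfg.batch_size is None else min(cfg.batch_size, n)

    best_val = math.inf
    best_W = W.copy()
    stale = 0
    step = 0
    history: list[dict] = []
    for epoch in range(1, cfg.max_epochs + 1):
        order = rng.permutation(n) if bs < n else np.arange(n)
        for lo in range(0, n, bs):
            idx = order[lo:lo + bs]
            Xbatch, Ybatch = Xb[idx], Y[idx]
            P = _softmax(Xbatch @ W)
            grad = Xbatch.T @ (P - Ybatch) / len(idx)
            if cfg.lam > 0:
                if cfg.penalty == "l2":
                    grad[:-1] += 2.0 * cfg.lam * W[:-1]
                else:
                    grad[:-1] += cfg.lam * np.sign(W[:-1])
            step += 1
            m = beta1 * m + (1 - beta1) * grad
            v = beta2 * v + (1 - beta2) * grad ** 2
            mh = m / (1 - beta1 ** step)
            vh = v / (1 - beta2 ** step)
            W = W - cfg.learning_rate * mh / (np.sqrt(vh) + eps)
        if not np.all(np.isfinite(W)):
            raise ModelError(f"non-finite weights at epoch {epoch}")

        train_loss = _cross_entropy(_softmax(Xb @ W), Y)
        entry = {"epoch": epoch, "train_loss": train_loss}
        if Xvb is not None:
            val_loss = _cross_entropy(_softmax(Xvb @ W), Y_val)
            entry["val_loss"] = val_loss
            if val_loss < best_val - 1e-12:
                best_val = val_loss
                best_W = W.copy()
                stale = 0
            else:
                stale += 1
            history.append(entry)
            if stale > cfg.patience:
                break
        else:
            history.append(entry)
    if Xvb is not None:
        W = best_W
    return W, history


def _val_mse(W: np.ndarray, X_val: np.ndarray, Y_val: np.ndarray) -> float:
    P = predict_probs(X_val, W)
    return float(((P - Y_val) ** 2).mean())


def grid_search(X_tr: np.ndarray, Y_tr: np.ndarray,
                X_val: np.ndarray, Y_val: np.ndarray,
                configs: list[ModelConfig]
                ) -> tuple[ModelConfig, np.ndarray, list[dict]]:
    """Train one component under each config; keep the lowest validation MSE.

    Ties go to the larger penalty (the simpler model).  The full search
    log -- one entry per config with its validation MSE and epoch count --
    is returned alongside the winner.
    """
    if not configs:
        raise ModelError("empty hyperparameter grid")
    log: list[dict] = []
    best: tuple[float, float, ModelConfig, np.ndarray] | None = None
    for cfg in configs:
        W, hist = train_component(X_tr, Y_tr, cfg, X_val, Y_val)
        mse = _val_mse(W, X_val, Y_val)
        log.append({"penalty": cfg.penalty, "lam": cfg.lam,
                    "val_mse": mse, "epochs": len(hist)})
        if best is None or (mse, -cfg.lam) < (best[0], -best[1]):
            best = (mse, cfg.lam, cfg, W)
    return best[2], best[3], log


def _lambda_configs(base: ModelConfig, l2_grid, l1_grid) -> list[ModelConfig]:
    out = [replace(base, penalty="l2", lam=l) for l in (l2_grid or [])]
    out += [replace(base, penalty="l1", lam=l) for l in (l1_grid or [])]
    return out


class RepairOutcomeModel:
    """End-joining outcome model built from targets and observed outcomes.

    Parameters
    ----------
    targets
        One :class:`TargetContext` per training sequence.
    distributions
        Matching observed :class:`OutcomeDistribution` objects (frequencies
        over event-class ids; deletions already collapsed onto canonical
        classes, as produced by the calling pipeline or the simulator).
    deletion_classes
        The deletion-class universe the deletion component predicts over;
        defaults to the full 550-class catalog.
    """

    def __init__(self, targets: list[TargetContext],
                 distributions: list[OutcomeDistribution],
                 deletion_classes: list[DeletionClass] | None = None,
                 catalog_config: CatalogConfig = DEFAULT_CONFIG):
        if len(targets) != len(distributions):
            raise ModelError("targets and distributions must align")
        if not targets:
            raise ModelError("empty training set")
        self.targets = list(targets)
        self.distributions = list(distributions)
        self.catalog_config = catalog_config
        self.deletion_classes = (list(deletion_classes) if deletion_classes
                                 else enumerate_deletion_classes(catalog_config))
        self.insertion_ids = [c.event_id() for c in enumerate_insertion_classes()]
        cut = catalog_config.cut_index
        self.deletion_ids = [c.event_id(cut) for c in self.deletion_classes]
        self._del_index = {e: i for i, e in enumerate(self.deletion_ids)}
        self._ins_index = {e: i for i, e in enumerate(self.insertion_ids)}

    @classmethod
    def from_counts(cls, targets: list[TargetContext],
                    counts: "dict[str, dict[str, int]] | object",
                    **kwargs) -> "RepairOutcomeModel":
        """Build from a per-target ``{event_id: umi_count}`` mapping or a
        tidy DataFrame with target_id / event_id / umi_count columns."""
        if hasattr(counts, "groupby"):  # DataFrame without importing pandas here
            counts = {tid: dict(zip(g["event_id"], g["umi_count"]))
                      for tid, g in counts.groupby("target_id")}
        dists = []
        for t in targets:
            if t.target_id not in counts:
                raise ModelError(f"no counts for target {t.target_id!r}")
            dists.append(OutcomeDistribution.from_counts(counts[t.target_id]))
        return cls(targets, dists, **kwargs)

    # -- design matrices -------------------------------------------------
    def _matrices(self) -> dict[str, np.ndarray]:
        X_seq, X_full, X_hex = [], [], []
        for t in self.targets:
            ann = annotate_mh(t, self.deletion_classes)
            X_seq.append(encode_target_onehot(t.protospacer))
            X_full.append(assemble_features(t, self.deletion_classes, ann))
            X_hex.append(encode_hexamer(t.hexamer()))
        n = len(self.targets)
        Y_ratio = np.zeros((n, 2))
        Y_del = np.zeros((n, len(self.deletion_ids)))
        Y_ins = np.zeros((n, len(self.insertion_ids)))
        for i, dist in enumerate(self.distributions):
            for eid, p in dist.probs.items():
                if eid.startswith("I:"):
                    Y_ins[i, self._ins_index[eid]] += p
                elif eid in self._del_index:
                    Y_del[i, self._del_index[eid]] += p
            p_ins = Y_ins[i].sum()
            p_del = Y_del[i].sum()
            Y_ratio[i] = [p_del, p_ins]
        return {"X_seq": np.array(X_seq), "X_full": np.array(X_full),
                "X_hex": np.array(X_hex), "Y_ratio": Y_ratio,
                "Y_del": Y_del, "Y_ins": Y_ins}

    @staticmethod
    def _conditional(Y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Rows renormalised to sum 1; mask of rows with any mass."""
        mass = Y.sum(axis=1)
        keep = mass > 0
        Yc = Y[keep] / mass[keep, None]
        return Yc, keep

    def fit(self, l2_grid=DEFAULT_LAMBDA_GRID, l1_grid=(),
            val_fraction: float = 0.15, seed: int = 0,
            base_config: ModelConfig | None = None) -> "RepairOutcomeResults":
        """Train all three components with a shared train/validation split.

        ``l2_grid``/``l1_grid`` are the penalty strengths scanned per
        component (defaults: the canonical ten-point L2 scan).
        """
        base = base_config or ModelConfig(seed=seed)
        mats = self._matrices()
        n = len(self.targets)
        rng = np.random.default_rng(seed)
        order = rng.permutation(n)
        n_val = max(1, int(round(val_fraction * n)))
        if n_val >= n:
            raise ModelError("validation split leaves no training rows")
        val_idx = np.zeros(n, dtype=bool)
        val_idx[order[:n_val]] = True

        configs = _lambda_configs(base, l2_grid, l1_grid)
        components = {}
        logs = {}
        for name, Xname, Y in (("ratio", "X_seq", mats["Y_ratio"]),
                               ("deletion", "X_full", mats["Y_del"]),
                               ("insertion", "X_hex", mats["Y_ins"])):
            X = mats[Xname]
            Yn, keep = self._conditional(Y)
            Xk = X[keep]
            vk = val_idx[keep]
            if vk.sum() == 0 or (~vk).sum() == 0:
                raise ModelError(f"{name}: degenerate train/validation split")
            cfg, W, log = grid_search(Xk[~vk], Yn[~vk], Xk[vk], Yn[vk], configs)
            components[name] = (cfg, W)
            logs[name] = log
        return RepairOutcomeResults(
            ratio_weights=components["ratio"][1],
            deletion_weights=components["deletion"][1],
            insertion_weights=components["insertion"][1],
            configs={k: components[k][0] for k in components},
            search_logs=logs,
            deletion_ids=list(self.deletion_ids),
            insertion_ids=list(self.insertion_ids),
            catalog_config=self.catalog_config,
            n_train=int(n - n_val), n_val=int(n_val))


@dataclass
class RepairOutcomeResults:
    """Fitted weights of the three components plus the class catalog they
    index; supports prediction, summary and lossless JSON round-trip."""

    ratio_weights: np.ndarray
    deletion_weights: np.ndarray
    insertion_weights: np.ndarray
    configs: dict[str, ModelConfig]
    search_logs: dict[str, list[dict]]
    deletion_ids: list[str]
    insertion_ids: list[str]
    catalog_config: CatalogConfig = DEFAULT_CONFIG
    n_train: int = 0
    n_val: int = 0
    schema_version: str = SCHEMA_VERSION
    format: str = MODEL_FORMAT

    def __post_init__(self) -> None:
        cut = self.catalog_config.cut_index
        self._classes = [parse_event_id(e, cut) for e in self.deletion_ids]
        if self.deletion_weights.shape[1] != len(self.deletion_ids):
            raise ModelError("deletion weights do not match the class list")
        if self.insertion_weights.shape[1] != len(self.insertion_ids):
            raise ModelError("insertion weights do not match the class list")

    # -- prediction ------------------------------------------------------
    def predict_components(self, target: TargetContext
                           ) -> tuple[float, np.ndarray, np.ndarray]:
        """(p_insertion, deletion-class probs, insertion-class probs)."""
        ann = annotate_mh(target, self._classes)
        x_seq = encode_target_onehot(target.protospacer)
        x_full = assemble_features(target, self._classes, ann)
        x_hex = encode_hexamer(target.hexamer())
        if x_full.shape[0] + 1 != self.deletion_weights.shape[0]:
            raise ModelError("feature schema does not match the model weights")
        p_ins = float(predict_probs(x_seq, self.ratio_weights)[0, 1])
        p_del = predict_probs(x_full, self.deletion_weights)[0]
        p_iclass = predict_probs(x_hex, self.insertion_weights)[0]
        return p_ins, p_del, p_iclass

    def predict(self, target: TargetContext) -> OutcomeDistribution:
        """Full predicted outcome distribution, collapsed and normalized."""
        p_ins, p_del, p_iclass = self.predict_components(target)
        cut = self.catalog_config.cut_index
        canon = collapse_redundant(target, self._classes)
        probs: dict[str, float] = {}
        for dc, p in zip(self._classes, p_del):
            eid = canon[dc].event_id(cut)
            probs[eid] = probs.get(eid, 0.0) + (1.0 - p_ins) * float(p)
        for eid, p in zip(self.insertion_ids, p_iclass):
            probs[eid] = p_ins * float(p)
        return OutcomeDistribution(probs)

    # -- reporting -------------------------------------------------------
    def summary(self) -> str:
        lines = ["End-joining repair outcome model",
                 "=" * 48,
                 f"training targets:   {self.n_train} (+{self.n_val} validation)",
                 f"deletion classes:   {len(self.deletion_ids)}",
                 f"insertion classes:  {len(self.insertion_ids)}",
                 f"feature schema:     {self.schema_version}",
                 "-" * 48,
                 f"{'component':<11}{'features':>9}{'classes':>9}"
                 f"{'penalty':>9}{'lambda':>10}{'val MSE':>10}"]
        for name, W in (("ratio", self.ratio_weights),
                        ("deletion", self.deletion_weights),
                        ("insertion", self.insertion_weights)):
            cfg = self.configs[name]
            best = min(e["val_mse"] for e in self.search_logs[name])
            lines.append(f"{name:<11}{W.shape[0] - 1:>9}{W.shape[1]:>9}"
                         f"{cfg.penalty:>9}{cfg.lam:>10.1e}{best:>10.2e}")
        return "\n".join(lines)

    # -- serialization ---------------------------------------------------
    def save(self, path) -> None:
        doc = {
            "format": self.format,
            "schema_version": self.schema_version,
            "catalog_config": {
                "context_length": self.catalog_config.context_length,
                "max_deletion_length": self.catalog_config.max_deletion_length,
                "window_upstream": self.catalog_config.window_upstream,
                "window_downstream": self.catalog_config.window_downstream,
            },
            "deletion_ids": self.deletion_ids,
            "insertion_ids": self.insertion_ids,
            "configs": {k: vars(c) for k, c in self.configs.items()},
            "search_logs": self.search_logs,
            "n_train": self.n_train, "n_val": self.n_val,
            "weights": {
                "ratio": self.ratio_weights.tolist(),
                "deletion": self.deletion_weights.tolist(),
                "insertion": self.insertion_weights.tolist(),
            },
        }
        with open(path, "w") as fh:
            json.dump(doc, fh)

    @classmethod
    def load(cls, path) -> "RepairOutcomeResults":
        with open(path) as fh:
            doc = json.load(fh)
        if doc.get("format") != MODEL_FORMAT:
            raise ModelError(f"unsupported model format {doc.get('format')!r}")
        if doc.get("schema_version") != SCHEMA_VERSION:
            raise ModelError(
                f"feature schema {doc.get('schema_version')!r} does not match "
                f"this build ({SCHEMA_VERSION})")
        cc = doc["catalog_config"]
        return cls(
            ratio_weights=np.array(doc["weights"]["ratio"]),
            deletion_weights=np.array(doc["weights"]["deletion"]),
            insertion_weights=np.array(doc["weights"]["insertion"]),
            configs={k: ModelConfig(**v) for k, v in doc["configs"].items()},
            search_logs=doc["search_logs"],
            deletion_ids=doc["deletion_ids"],
            insertion_ids=doc["insertion_ids"],
            catalog_config=CatalogConfig(**cc),
            n_train=doc["n_train"], n_val=doc["n_val"],
            schema_version=doc["schema_version"])


def predict_full(target: TargetContext,
                 results: RepairOutcomeResults) -> OutcomeDistribution:
    """Functional alias for :meth:`RepairOutcomeResults.predict`."""
    return results.predict(target)


# -- evaluation ----------------------------------------------------------

def canonical_support(target: TargetContext,
                      deletion_classes: list[DeletionClass],
                      insertion_ids: list[str]) -> list[str]:
    """The per-target evaluation class set: canonical (collapsed) deletion
    ids plus all insertion ids (~450-560 classes depending on repeats)."""
    cut = target.cut_index
    canon = collapse_redundant(target, deletion_classes)
    dels = sorted({c.event_id(cut) for c in canon.values()})
    return dels + list(insertion_ids)


def mse_on_support(pred: OutcomeDistribution, obs: OutcomeDistribution,
                   support: list[str]) -> float:
    """Per-target MSE over a fixed class set (absent classes count as 0)."""
    p = OutcomeDistribution({e: pred.probs.get(e, 0.0) for e in support})
    o = OutcomeDistribution({e: obs.probs.get(e, 0.0) for e in support})
    return evaluate_mse(p, o)


def aggregate_baseline(distributions: list[OutcomeDistribution]
                       ) -> OutcomeDistribution:
    """Pooled-frequency baseline: every class predicted at the aggregate
    frequency at which it was observed across the training targets."""
    pooled: dict[str, float] = {}
    total = 0.0
    for dist in distributions:
        w = dist.total_support or 1
        total += w
        for eid, p in dist.probs.items():
            pooled[eid] = pooled.get(eid, 0.0) + w * p
    return OutcomeDistribution({e: v / total for e, v in pooled.items()})


# -- hexamer insertion-proportion regression ------------------------------

def fit_insertion_proportion(hexamers: list[str], proportions: np.ndarray,
                             alpha: float = 1e-6) -> np.ndarray:
    """Least-squares linear fit of insertion proportion on the 104 hexamer
    features (plus intercept).  Returns the length-105 weight vector.

    A small ridge term on the non-intercept weights resolves the exact
    collinearity of the one-hot blocks (so a constant signal is carried by
    the intercept alone).
    """
    X = _add_bias(np.array([encode_hexamer(h) for h in hexamers]))
    y = np.asarray(proportions, dtype=np.float64)
    d = X.shape[1]
    reg = math.sqrt(alpha) * np.eye(d)
    reg[-1, -1] = 0.0  # intercept unpenalised
    Xa = np.vstack([X, reg])
    ya = np.concatenate([y, np.zeros(d)])
    w, *_ = np.linalg.lstsq(Xa, ya, rcond=None)
    return w


def insertion_proportion_hexamer(hexamer: str, weights: np.ndarray) -> float:
    """Predicted insertion proportion for one hexamer, clipped to [0, 1]."""
    x = np.append(encode_hexamer(hexamer), 1.0)
    return float(np.clip(x @ weights, 0.0, 1.0))
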