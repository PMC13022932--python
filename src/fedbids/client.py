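"""Per-round local training: receive global weights, train over bootstraps,
report validated weights and statistics.

Each federation round a client re-partitions its fixed 80% training pool
into ``n_bootstraps`` (default 5) random 75/25 train/validation splits.  For
every bootstrap it loads the incoming global weights into a fresh model,
applies the plan's freeze policy, trains with an L1 objective and Adam, and
records the validation MAE.  By default the weights of the best (lowest
validation MAE) bootstrap become the client's update; a plain average of the
bootstrap weight sets is the configurable alternative.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import stats as _stats

from .bids_io import (
    BootstrapSplit,
    Split,
    SubjectRecord,
    bootstrap_splits,
    derive_seed,
    discover_subjects,
    subject_split,
)
from .model_zoo import (
    DenseNetSpec,
    WeightSet,
    apply_freeze_policy,
    build_densenet,
    load_weight_set,
    save_weight_set,
)
from .nn import Adam, l1_loss
from .preprocess import PreprocessConfig, preprocess_pipeline
from . import protocol

logger = logging.getLogger(__name__)

__all__ = ["ClientUpdate", "VolumeLoader", "run_round", "evaluate_on_test",
           "client_loop"]


@dataclass(frozen=True)
class ClientUpdate:
    client_name: str
    round_index: int
    weights: WeightSet
    n_train_samples: int
    val_mae_per_bootstrap: tuple[float, ...]
    val_mae_mean: float
    val_mae_ci95: tuple[float, float]

    def __post_init__(self):
        if self.n_train_samples <= 0:
            raise ValueError("n_train_samples must be positive")
        if abs(self.val_mae_mean
               - float(np.mean(self.val_mae_per_bootstrap))) > 1e-9:
            raise ValueError("val_mae_mean must equal the bootstrap mean")
        lo, hi = self.val_mae_ci95
        if not (lo <= self.val_mae_mean <= hi):
            raise ValueError("CI95 must bracket the mean")

    def stats_dict(self) -> dict:
        return {
            "client_name": self.client_name,
            "round_index": self.round_index,
            "n_train_samples": self.n_train_samples,
            "val_mae_per_bootstrap": list(self.val_mae_per_bootstrap),
            "val_mae_mean": self.val_mae_mean,
            "val_mae_ci95": list(self.val_mae_ci95),
        }


def _ci95(values: np.ndarray) -> tuple[float, float]:
    m = float(values.mean())
    if values.size < 2 or np.ptp(values) == 0:
        return (m, m)
    half = float(_stats.t.ppf(0.975, values.size - 1)
                 * values.std(ddof=1) / np.sqrt(values.size))
    return (m - half, m + half)


class VolumeLoader:
    """Maps subjects to model-ready (image, target) arrays with caching."""

    def __init__(self, records: list[SubjectRecord],
                 preprocess_config: PreprocessConfig,
                 cache_dir: Path | None = None):
        self.records = {r.subject_id: r for r in records}
        self.config = preprocess_config
        self.cache_dir = cache_dir
        self._memory: dict[str, list[np.ndarray]] = {}

    def images(self, subject_id: str) -> list[np.ndarray]:
        if subject_id not in self._memory:
            rec = self.records[subject_id]
            self._memory[subject_id] = [
                preprocess_pipeline(p, self.config, self.cache_dir)
                for p in rec.image_paths]
        return self._memory[subject_id]

    def target(self, subject_id: str) -> float:
        return self.records[subject_id].target

    def pairs(self, subject_ids) -> list[tuple[np.ndarray, float, str]]:
        out = []
        for sid in sorted(subject_ids):
            for img in self.images(sid):
                out.append((img, self.target(sid), sid))
        return out


def _train_items(global_weights: WeightSet, plan, spec: DenseNetSpec,
                 train_items: list, val_items: list,
                 rng_seed: int) -> tuple[WeightSet, float]:
    """Train one model copy on item lists; return (weights, val MAE)."""
    model = build_densenet(spec, seed=0)
    global_weights.apply_to(model)
    if plan.freeze_mode != "none":
        apply_freeze_policy(model, plan.freeze_mode)
    opt = Adam(model, lr=plan.learning_rate)
    rng = np.random.default_rng(rng_seed)
    model.set_training(True)
    for _ in range(plan.epochs_per_round):
        order = rng.permutation(len(train_items))
        for start in range(0, len(order), plan.batch_size):
            idx = order[start:start + plan.batch_size]
            x = np.stack([train_items[i][0] for i in idx])
            y = np.array([train_items[i][1] for i in idx], dtype=np.float32)
            pred = model(x).reshape(-1)
            _, grad = l1_loss(pred, y)
            model.zero_grad()
            model.backward(grad.reshape(-1, 1))
            opt.step()
    preds = _predict(model, [it[0] for it in val_items], plan.batch_size)
    truths = np.array([it[1] for it in val_items])
    val_mae = float(np.mean(np.abs(preds - truths)))
    return WeightSet.from_model(model), val_mae


def _predict(model, images: list[np.ndarray], batch_size: int) -> np.ndarray:
    preds = []
    for start in range(0, len(images), batch_size):
        x = np.stack(images[start:start + batch_size])
        preds.append(model.predict(x))
    return np.concatenate(preds) if preds else np.array([])


def _average_weight_sets(sets: list[WeightSet]) -> WeightSet:
    out = WeightSet()
    for key in sets[0]:
        acc = np.mean([ws[key].astype(np.float64) for ws in sets], axis=0)
        out[key] = acc.astype(sets[0][key].dtype)
    return out


def run_round(global_weights: WeightSet, plan, dataset: list[SubjectRecord],
              split: Split, round_index: int, spec: DenseNetSpec,
              loader: VolumeLoader, client_name: str) -> ClientUpdate:
    """Train one federation round and return the client's update.

    The train/test split is computed once at federation start and reused
    every round; only the training pool is re-bootstrapped here.
    """
    if not split.train_subjects:
        raise ValueError("training pool is empty")
    bsplits = bootstrap_splits(split.train_subjects, plan.n_bootstraps,
                               plan.val_fraction, round_index,
                               base_seed=derive_seed(plan.seed, client_name))
    results = []
    for b in bsplits:
        # shuffle seed shared across clients (and the centralised benchmark):
        # client identity enters through the data, not the batch order
        seed = derive_seed(plan.seed, "train", round_index,
                           b.bootstrap_index)
        results.append(_train_items(
            global_weights, plan, spec, loader.pairs(b.train_subjects),
            loader.pairs(b.val_subjects), seed))
    val_maes = np.array([r[1] for r in results])
    if plan.bootstrap_selection == "best":
        weights = results[int(np.argmin(val_maes))][0]
    else:
        weights = _average_weight_sets([r[0] for r in results])
    n_train = sum(len(loader.records[s].image_paths)
                  for s in split.train_subjects)
    return ClientUpdate(
        client_name=client_name, round_index=round_index, weights=weights,
        n_train_samples=n_train,
        val_mae_per_bootstrap=tuple(float(v) for v in val_maes),
        val_mae_mean=float(val_maes.mean()), val_mae_ci95=_ci95(val_maes))


def evaluate_on_test(weights: WeightSet, dataset: list[SubjectRecord],
                     split: Split, spec: DenseNetSpec, loader: VolumeLoader,
                     batch_size: int = 10) -> list[tuple[str, float, float]]:
    """Deterministic (subject_id, true, predicted) per test image, ordered
    by (subject_id, image index)."""
    if not split.test_subjects:
        raise ValueError("test set is empty")
    model = build_densenet(spec, seed=0)
    weights.apply_to(model)
    items = loader.pairs(split.test_subjects)
    preds = _predict(model, [it[0] for it in items], batch_size)
    return [(sid, float(t), float(p))
            for (_, t, sid), p in zip(items, preds)]


# ---------------------------------------------------------------------------
# protocol-driven client loop
# ---------------------------------------------------------------------------

def client_loop(settings: protocol.ClientSettings, timeout_s: float = 3600.0,
                poll_s: float = 0.05) -> Path:
    """Run a full client session against a server over the file protocol.

    Waits for the FL plan, then per round: receive global weights → train →
    send the client update; exits when the final model arrives.  Returns the
    path of the stored final model.
    """
    ws = protocol.init_workspace(settings.workspace_root, "client")
    name = settings.client_name
    plan_msg = protocol.receive(ws.inbox, "plan", 0, "server",
                                timeout_s=timeout_s, poll_s=poll_s)
    plan = protocol.FLPlan.from_json(plan_msg.payload_path)
    spec = DenseNetSpec.from_dict(plan.model) if plan.model \
        else DenseNetSpec()
    pconf = PreprocessConfig.from_dict(settings.preprocess) \
        if settings.preprocess else PreprocessConfig()
    records = discover_subjects(settings.dataset_root, settings.target_column)
    split = subject_split(records, plan.test_fraction,
                          seed=derive_seed(plan.seed, name, "split"))
    loader = VolumeLoader(records, pconf, cache_dir=ws.preproc_cache)
    server_inbox = Path(settings.server) / "inbox"
    transport = protocol.LocalTransport(server_inbox)
    r = 1
    while True:
        msg = protocol.receive_any(
            ws.inbox, [("global_model", r, "server"),
                       ("final_model", 0, "server")],
            timeout_s=timeout_s, poll_s=poll_s)
        if msg.kind == "final_model":
            final_path = ws.state / "final_model.fcp"
            final_path.write_bytes(Path(msg.payload_path).read_bytes())
            protocol.receive(ws.inbox, "stop", 0, "server",
                             timeout_s=timeout_s, poll_s=poll_s)
            logger.info("%s: received final model, stopping", name)
            return final_path
        global_weights, _ = load_weight_set(msg.payload_path)
        update = run_round(global_weights, plan, records, split, r, spec,
                           loader, name)
        payload = ws.outbox / f"client_update_round{r}_{name}.fcp"
        save_weight_set(update.weights, payload, meta=update.stats_dict())
        (ws.logs / f"round{r}_stats.json").write_text(
            json.dumps(update.stats_dict(), indent=2, sort_keys=True))
        protocol.send(protocol.Message("client_update", r, payload, name),
                      transport)
        r += 1
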