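"""Server orchestration: broadcast, collect, sample, aggregate, early-stop.

Each round the server broadcasts the current global weights, collects an
update from every client, draws a uniform random sample of
``clients_per_round`` of them and aggregates the sampled weight sets by
federated averaging with weights n_i / Σ_j n_j (client training-pool sample
sizes).  The server tracks the mean validation MAE across the sampled
clients; training stops early after ``patience`` consecutive rounds without
a new minimum, and the final model is the aggregate of the round with the
*minimum* server-side validation MAE, not the last round run.

A centralised benchmark trains one model on the union of the clients'
training pools while reusing the identical per-client bootstrap splits, so
the two regimes differ only in where gradient steps happen.
"""

from __future__ import annotations

import json
import logging
import threading
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .bids_io import Split, derive_seed
from .client import VolumeLoader, _train_items as _train_items_fn
from .model_zoo import (
    CheckpointError,
    DenseNetSpec,
    WeightSet,
    build_densenet,
    load_weight_set,
    save_weight_set,
)
from . import protocol

logger = logging.getLogger(__name__)

__all__ = ["RoundRecord", "FederationError", "EarlyStopper", "sample_clients",
           "fedavg", "run_federation", "run_centralized",
           "simulate_federation"]


class FederationError(RuntimeError):
    """The federation aborted (e.g. a client went silent)."""


class EarlyStopper:
    """Stop after ``patience`` consecutive rounds without a new minimum;
    separately remembers the round of the minimum (the final-model round)."""

    def __init__(self, patience: int):
        self.patience = patience
        self.best_mae = np.inf
        self.best_round = 0
        self.since_best = 0

    def update(self, round_index: int, avg_val_mae: float) -> bool:
        """Record one round; returns True when training should stop."""
        if avg_val_mae < self.best_mae:
            self.best_mae = avg_val_mae
            self.best_round = round_index
            self.since_best = 0
            return False
        self.since_best += 1
        return self.since_best >= self.patience


@dataclass(frozen=True)
class RoundRecord:
    round_index: int
    sampled_client_names: tuple[str, ...]
    aggregate_weights_ref: Path | None
    avg_val_mae: float
    per_client_val_mae: dict

    def to_dict(self) -> dict:
        return {
            "round_index": self.round_index,
            "sampled_client_names": list(self.sampled_client_names),
            "aggregate_weights_ref": str(self.aggregate_weights_ref)
            if self.aggregate_weights_ref else None,
            "avg_val_mae": self.avg_val_mae,
            "per_client_val_mae": self.per_client_val_mae,
        }


def sample_clients(client_names: list[str], k: int,
                   round_rng: np.random.Generator) -> list[str]:
    """Uniform random subset of k clients, returned in sorted order."""
    names = sorted(client_names)
    if not (1 <= k <= len(names)):
        raise ValueError(f"cannot sample {k} of {len(names)} clients")
    picked = round_rng.choice(len(names), size=k, replace=False)
    return sorted(names[i] for i in picked)


def fedavg(updates: list[tuple[WeightSet, int]]) -> WeightSet:
    """Sample-size-weighted federated average of client weight sets.

    out[p] = Σ_i (n_i / Σ_j n_j) · w_i[p], computed in double precision as
    an anchored sum w_0[p] + Σ_i λ_i (w_i[p] − w_0[p]) so that identical
    updates aggregate bit-exactly to themselves.
    """
    if not updates:
        raise ValueError("fedavg needs at least one update")
    for ws, n in updates:
        if n <= 0:
            raise ValueError("client sample sizes must be positive")
    keys = list(updates[0][0])
    for ws, _ in updates[1:]:
        if list(ws) != keys:
            extra = set(ws).symmetric_difference(keys)
            raise CheckpointError(
                "weight sets disagree on keys: " + ", ".join(sorted(extra)[:5]))
    total = float(sum(n for _, n in updates))
    lams = [n / total for _, n in updates]
    out = WeightSet()
    base = updates[0][0]
    for key in keys:
        anchor = base[key].astype(np.float64)
        acc = anchor.copy()
        for (ws, _), lam in zip(updates[1:], lams[1:]):
            arr = ws[key]
            if arr.shape != anchor.shape:
                raise CheckpointError(
                    f"shape mismatch for {key!r}: {arr.shape} vs "
                    f"{anchor.shape}")
            acc += lam * (arr.astype(np.float64) - anchor)
        out[key] = acc.astype(base[key].dtype)
    return out


def _initial_weights(plan: protocol.FLPlan,
                     settings: protocol.ServerSettings) -> WeightSet:
    if settings.model_definition is not None:
        import importlib.util
        spec_ = importlib.util.spec_from_file_location(
            "fedbids_model_definition", settings.model_definition)
        mod = importlib.util.module_from_spec(spec_)
        spec_.loader.exec_module(mod)
        model = mod.build_model(seed=plan.seed)
    else:
        arch = DenseNetSpec.from_dict(plan.model) if plan.model \
            else DenseNetSpec()
        model = build_densenet(arch, seed=plan.seed)
    return WeightSet.from_model(model)


def run_federation(plan: protocol.FLPlan,
                   settings: protocol.ServerSettings,
                   transports: dict | None = None,
                   timeout_s: float = 3600.0,
                   poll_s: float = 0.05
                   ) -> tuple[WeightSet, list[RoundRecord], int]:
    """Drive a full federation; returns (final weights, history, best round).

    ``transports`` maps client name → transport; defaults to local-directory
    transports into each client's workspace inbox.
    """
    ws = protocol.init_workspace(settings.workspace_root, "server")
    names = sorted(c["name"] for c in settings.clients)
    if plan.clients_per_round > len(names):
        raise ValueError("clients_per_round exceeds the number of clients")
    if transports is None:
        transports = {
            c["name"]: protocol.LocalTransport(
                Path(c["workspace_root"]) / "inbox")
            for c in settings.clients}

    plan_path = ws.state / "plan.json"
    plan.to_json(plan_path)
    for name in names:
        protocol.send(protocol.Message("plan", 0, plan_path, "server"),
                      transports[name])

    global_weights = _initial_weights(plan, settings)
    history: list[RoundRecord] = []
    stopper = EarlyStopper(plan.patience)
    log_path = ws.logs / "rounds.jsonl"

    for r in range(1, plan.n_rounds_max + 1):
        gpath = ws.outbox / f"global_model_round{r}_server.fcp"
        save_weight_set(global_weights, gpath, meta={"round": r})
        for name in names:
            protocol.send(protocol.Message("global_model", r, gpath,
                                           "server"), transports[name])
        updates = {}
        for name in names:
            try:
                msg = protocol.receive(ws.inbox, "client_update", r, name,
                                       timeout_s=timeout_s, poll_s=poll_s)
            except TimeoutError as exc:
                raise FederationError(
                    f"client {name!r} did not report an update for round "
                    f"{r}; aborting federation") from exc
            weights, meta = load_weight_set(msg.payload_path)
            updates[name] = (weights, meta)

        rng = np.random.default_rng(derive_seed(plan.seed, "sample", r))
        sampled = sample_clients(names, plan.clients_per_round, rng)
        agg = fedavg([(updates[n][0], int(updates[n][1]["n_train_samples"]))
                      for n in sampled])
        apath = ws.state / f"aggregate_round{r}.fcp"
        save_weight_set(agg, apath, meta={"round": r, "sampled": sampled})
        avg_val = float(np.mean([updates[n][1]["val_mae_mean"]
                                 for n in sampled]))
        rec = RoundRecord(
            round_index=r, sampled_client_names=tuple(sampled),
            aggregate_weights_ref=apath, avg_val_mae=avg_val,
            per_client_val_mae={n: float(updates[n][1]["val_mae_mean"])
                                for n in names})
        history.append(rec)
        with open(log_path, "a") as fh:
            fh.write(json.dumps(rec.to_dict(), sort_keys=True) + "\n")
        logger.info("round %d: sampled %s, avg val MAE %.4f", r, sampled,
                    avg_val)

        global_weights = agg
        if stopper.update(r, avg_val):
            logger.info("early stop after round %d (best round %d)",
                        r, stopper.best_round)
            break

    best_round = stopper.best_round
    final_weights, _ = load_weight_set(
        ws.state / f"aggregate_round{best_round}.fcp")
    fpath = ws.state / "final_model.fcp"
    save_weight_set(final_weights, fpath, meta={"best_round": best_round})
    stop_path = ws.state / "stop.json"
    stop_path.write_text(json.dumps({"best_round": best_round}))
    for name in names:
        protocol.send(protocol.Message("final_model", 0, fpath, "server"),
                      transports[name])
        protocol.send(protocol.Message("stop", 0, stop_path, "server"),
                      transports[name])

    summary = ["round\tsampled_clients\tavg_val_mae"]
    summary += [f"{rec.round_index}\t{','.join(rec.sampled_client_names)}\t"
                f"{rec.avg_val_mae:.6g}" for rec in history]
    (ws.logs / "rounds.tsv").write_text("\n".join(summary) + "\n")
    return final_weights, history, best_round


def run_centralized(plan: protocol.FLPlan, spec: DenseNetSpec,
                    loaders: dict[str, VolumeLoader],
                    splits: dict[str, Split],
                    out_dir: str | Path | None = None
                    ) -> tuple[WeightSet, list[RoundRecord], int]:
    """Hyperparameter-synced centralised benchmark.

    One training process over the union of the client training pools; each
    "round" re-uses the per-client bootstrap splits (identical seeds to the
    federated run) merged by bootstrap index, with validation MAE over the
    merged validation set, the same early stopping and best-round selection.
    """
    from .bids_io import bootstrap_splits

    names = sorted(loaders)
    model = build_densenet(spec, seed=plan.seed)
    global_weights = WeightSet.from_model(model)
    history: list[RoundRecord] = []
    round_weights: dict[int, WeightSet] = {}
    stopper = EarlyStopper(plan.patience)

    for r in range(1, plan.n_rounds_max + 1):
        per_client = {
            name: bootstrap_splits(
                splits[name].train_subjects, plan.n_bootstraps,
                plan.val_fraction, r,
                base_seed=derive_seed(plan.seed, name))
            for name in names}
        boot_results = []
        for b in range(plan.n_bootstraps):
            train_items, val_items = [], []
            for name in names:
                bs = per_client[name][b]
                train_items += loaders[name].pairs(bs.train_subjects)
                val_items += loaders[name].pairs(bs.val_subjects)
            seed = derive_seed(plan.seed, "train", r, b)
            boot_results.append(_train_items_fn(
                global_weights, plan, spec, train_items, val_items, seed))
        val_maes = np.array([v for _, v in boot_results])
        if plan.bootstrap_selection == "best":
            global_weights = boot_results[int(np.argmin(val_maes))][0]
        else:
            from .client import _average_weight_sets
            global_weights = _average_weight_sets(
                [w for w, _ in boot_results])
        avg_val = float(val_maes.mean())
        round_weights[r] = global_weights
        history.append(RoundRecord(
            round_index=r, sampled_client_names=tuple(names),
            aggregate_weights_ref=None, avg_val_mae=avg_val,
            per_client_val_mae={"merged": avg_val}))
        if stopper.update(r, avg_val):
            break

    best_round = stopper.best_round
    final = round_weights[best_round]
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        save_weight_set(final, out_dir / "final_model.fcp",
                        meta={"best_round": best_round})
        with open(out_dir / "rounds.jsonl", "w") as fh:
            for rec in history:
                fh.write(json.dumps(rec.to_dict(), sort_keys=True) + "\n")
    return final, history, best_round


# ---------------------------------------------------------------------------
# one-process simulation over the local transport
# ---------------------------------------------------------------------------

def simulate_federation(workdir: str | Path, plan: protocol.FLPlan,
                        phantom_configs: list, target_column: str = "age",
                        preprocess_config: dict | None = None,
                        timeout_s: float = 3600.0,
                        emit_reports: bool = True) -> dict:
    """Run server + clients over the local transport in one process tree.

    ``phantom_configs`` is one :class:`~fedbids.synthetic.PhantomConfig` per
    client; datasets and workspaces are created under ``workdir``.  Returns
    the final weights, round history, best round and per-client test
    evaluation.
    """
    from .bids_io import discover_subjects, subject_split
    from .client import client_loop, evaluate_on_test
    from .evaluation import evaluate_client, emit_report
    from .synthetic import generate_dataset

    workdir = Path(workdir)
    spec = DenseNetSpec.from_dict(plan.model) if plan.model else DenseNetSpec()
    pconf = preprocess_config or {}
    server_root = workdir / "server"
    clients = []
    for i, cfg in enumerate(phantom_configs):
        name = f"client{i + 1}"
        droot = workdir / f"data_{name}"
        generate_dataset(cfg, droot)
        croot = workdir / name
        settings = protocol.ClientSettings(
            workspace_root=croot, dataset_root=droot,
            target_column=target_column, server=str(server_root),
            client_name=name, preprocess=pconf)
        clients.append(settings)

    server_settings = protocol.ServerSettings(
        workspace_root=server_root,
        clients=tuple({"name": c.client_name, "address": "local",
                       "workspace_root": str(c.workspace_root)}
                      for c in clients))

    threads, errors = [], []

    def _client(settings):
        try:
            client_loop(settings, timeout_s=timeout_s)
        except Exception as exc:  # surfaced after join
            errors.append((settings.client_name, exc))

    for settings in clients:
        protocol.init_workspace(settings.workspace_root, "client")
        t = threading.Thread(target=_client, args=(settings,), daemon=True)
        t.start()
        threads.append(t)

    final, history, best_round = run_federation(
        plan, server_settings, timeout_s=timeout_s)
    for t in threads:
        t.join(timeout=timeout_s)
    if errors:
        name, exc = errors[0]
        raise FederationError(f"client {name} failed: {exc}") from exc

    results, scatter = [], {}
    from .preprocess import PreprocessConfig
    pconf_obj = PreprocessConfig.from_dict(pconf) if pconf \
        else PreprocessConfig()
    for settings in clients:
        records = discover_subjects(settings.dataset_root,
                                    settings.target_column)
        split = subject_split(records, plan.test_fraction,
                              seed=derive_seed(plan.seed,
                                               settings.client_name, "split"))
        loader = VolumeLoader(records, pconf_obj,
                              cache_dir=Path(settings.workspace_root)
                              / "preproc_cache")
        triples = evaluate_on_test(final, records, split, spec, loader,
                                   plan.batch_size)
        pairs = [(t, p) for _, t, p in triples]
        results.append(evaluate_client(settings.client_name, pairs,
                                       brain_age=target_column == "age"))
        scatter[settings.client_name] = pairs
    report_paths = {}
    if emit_reports:
        report_paths = emit_report(results, history,
                                   workdir / "report", scatter_pairs=scatter)
    return {"final_weights": final, "history": history,
            "best_round": best_round, "results": results,
            "report_paths": report_paths}
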