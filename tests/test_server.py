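"""Sampling, federated averaging, early stopping, centralised merging."""

from itertools import combinations

import numpy as np
import pytest

from fedbids.model_zoo import CheckpointError, WeightSet
from fedbids.server import EarlyStopper, fedavg, sample_clients


def _ws(**arrays):
    ws = WeightSet()
    for k, v in arrays.items():
        ws[k] = np.asarray(v, dtype=np.float64)
    return ws


def test_fedavg_worked_example():
    out = fedavg([(_ws(w=[1.0]), 100), (_ws(w=[2.0]), 300)])
    np.testing.assert_allclose(out["w"], [1.75])


def test_fedavg_equal_sizes_is_plain_mean():
    a = _ws(w=np.arange(5.0))
    b = _ws(w=np.arange(5.0) * 3)
    out = fedavg([(a, 7), (b, 7)])
    np.testing.assert_allclose(out["w"], np.arange(5.0) * 2)


def test_fedavg_single_update_is_bit_identical():
    rng = np.random.default_rng(0)
    a = _ws(w=rng.normal(size=20), b=rng.normal(size=(3, 4)))
    out = fedavg([(a, 13)])
    for k in a:
        np.testing.assert_array_equal(out[k], a[k])


def test_fedavg_identical_updates_conserve_bit_exactly():
    rng = np.random.default_rng(1)
    base = WeightSet(
        (k, rng.normal(size=s).astype(np.float32))
        for k, s in [("conv", (4, 3, 3)), ("bias", (7,))])
    copies = [(WeightSet((k, v.copy()) for k, v in base.items()), n)
              for n in (3, 17, 113)]
    out = fedavg(copies)
    for k in base:
        np.testing.assert_array_equal(out[k], base[k])


def test_fedavg_matches_bruteforce_weighted_mean():
    """Oracle: per-entry weighted mean on random 3-client toy weight sets."""
    rng = np.random.default_rng(42)
    for _ in range(10):
        keys = [f"p{i}" for i in range(rng.integers(1, 5))]
        shapes = [tuple(rng.integers(1, 5, size=2)) for _ in keys]
        updates = []
        for _ in range(3):
            ws = WeightSet((k, rng.normal(size=s))
                           for k, s in zip(keys, shapes))
            updates.append((ws, int(rng.integers(1, 500))))
        out = fedavg(updates)
        total = sum(n for _, n in updates)
        for k in keys:
            expected = sum(ws[k] * (n / total) for ws, n in updates)
            np.testing.assert_allclose(out[k], expected, atol=1e-12, rtol=0)


def test_fedavg_errors():
    with pytest.raises(ValueError):
        fedavg([])
    with pytest.raises(ValueError):
        fedavg([(_ws(w=[1.0]), 0)])
    with pytest.raises(CheckpointError, match="other"):
        fedavg([(_ws(w=[1.0]), 1), (_ws(other=[1.0]), 1)])


def test_sample_clients_uniform_over_pairs():
    """3 choose 2: each pair appears with frequency 1/3 ± 2%."""
    names = ["brussels", "greifswald", "prague"]
    pairs = {tuple(sorted(c)): 0 for c in combinations(names, 2)}
    for seed in range(10_000):
        picked = sample_clients(names, 2, np.random.default_rng(seed))
        pairs[tuple(picked)] += 1
    assert set(pairs) == set(tuple(sorted(c))
                             for c in combinations(names, 2))
    for count in pairs.values():
        assert abs(count / 10_000 - 1 / 3) < 0.02


def test_sample_clients_k_equals_n_and_determinism():
    names = ["c2", "c1", "c3"]
    assert sample_clients(names, 3, np.random.default_rng(0)) \
        == ["c1", "c2", "c3"]
    a = sample_clients(names, 2, np.random.default_rng(99))
    b = sample_clients(names, 2, np.random.default_rng(99))
    assert a == b
    with pytest.raises(ValueError):
        sample_clients(names, 4, np.random.default_rng(0))


def test_early_stopping_hand_trace():
    """MAE sequence 5, 4, 4.5, 4.6, 4.7 with patience 3: stop after round 5,
    final model from round 2."""
    stopper = EarlyStopper(patience=3)
    stops = [stopper.update(r, mae)
             for r, mae in enumerate([5, 4, 4.5, 4.6, 4.7], start=1)]
    assert stops == [False, False, False, False, True]
    assert stopper.best_round == 2


def test_early_stopping_never_fires_on_monotone_descent():
    stopper = EarlyStopper(patience=2)
    maes = [10 - r for r in range(8)]
    assert not any(stopper.update(r + 1, m) for r, m in enumerate(maes))
    assert stopper.best_round == 8


def test_centralized_merges_per_client_bootstraps():
    """Merged bootstrap b trains on the union of each client's bootstrap-b
    training subjects (identical seeds to the federated clients)."""
    from fedbids.bids_io import bootstrap_splits, derive_seed

    pools = {"c1": frozenset(f"c1s{i}" for i in range(8)),
             "c2": frozenset(f"c2s{i}" for i in range(12))}
    per_client = {
        name: bootstrap_splits(pool, 5, 0.25, round_index=3,
                               base_seed=derive_seed(0, name))
        for name, pool in pools.items()}
    for b in range(5):
        merged_train = set().union(*(per_client[n][b].train_subjects
                                     for n in pools))
        merged_val = set().union(*(per_client[n][b].val_subjects
                                   for n in pools))
        assert merged_train | merged_val == pools["c1"] | pools["c2"]
        assert not merged_train & merged_val


def test_one_client_centralized_equals_standalone_loop(tmp_path):
    """With a single client the centralised benchmark is that client's own
    training loop: identical per-round validation MAEs and final weights."""
    from fedbids.client import VolumeLoader, run_round
    from fedbids.model_zoo import DenseNetSpec, WeightSet, build_densenet
    from fedbids.preprocess import PreprocessConfig
    from fedbids.protocol import FLPlan
    from fedbids.bids_io import discover_subjects, subject_split, derive_seed
    from fedbids.server import run_centralized
    from fedbids.synthetic import PhantomConfig, generate_dataset

    spec = DenseNetSpec.small()
    plan = FLPlan(n_rounds_max=2, clients_per_round=1, epochs_per_round=1,
                  learning_rate=3e-3, batch_size=10, patience=20, seed=9,
                  model=spec.to_dict())
    generate_dataset(PhantomConfig(n_subjects=8, seed=31), tmp_path / "ds")
    records = discover_subjects(tmp_path / "ds", "age")
    split = subject_split(records, plan.test_fraction,
                          seed=derive_seed(plan.seed, "c1", "split"))
    pconf = PreprocessConfig(target_spacing=1.0, window=32,
                             normalize="zscore")
    loader = VolumeLoader(records, pconf)

    final_c, history_c, best_c = run_centralized(
        plan, spec, {"c1": loader}, {"c1": split})

    gw = WeightSet.from_model(build_densenet(spec, seed=plan.seed))
    standalone_vals = []
    per_round_weights = {}
    for r in (1, 2):
        update = run_round(gw, plan, records, split, r, spec, loader, "c1")
        gw = update.weights
        standalone_vals.append(update.val_mae_mean)
        per_round_weights[r] = gw

    assert [rec.avg_val_mae for rec in history_c] \
        == pytest.approx(standalone_vals)
    for key in final_c:
        np.testing.assert_array_equal(final_c[key],
                                      per_round_weights[best_c][key],
                                      err_msg=key)


def test_centralized_runs_with_two_clients_and_persists(tmp_path):
    from fedbids.client import VolumeLoader
    from fedbids.model_zoo import DenseNetSpec
    from fedbids.preprocess import PreprocessConfig
    from fedbids.protocol import FLPlan
    from fedbids.bids_io import discover_subjects, subject_split, derive_seed
    from fedbids.server import run_centralized
    from fedbids.synthetic import PhantomConfig, generate_dataset

    spec = DenseNetSpec.small()
    plan = FLPlan(n_rounds_max=2, clients_per_round=1, learning_rate=3e-3,
                  seed=3, model=spec.to_dict())
    loaders, splits = {}, {}
    pconf = PreprocessConfig(target_spacing=1.0, window=32,
                             normalize="zscore")
    for i, n in enumerate((6, 8)):
        name = f"c{i + 1}"
        generate_dataset(PhantomConfig(n_subjects=n, seed=40 + i),
                         tmp_path / name)
        records = discover_subjects(tmp_path / name, "age")
        splits[name] = subject_split(records, plan.test_fraction,
                                     seed=derive_seed(plan.seed, name,
                                                      "split"))
        loaders[name] = VolumeLoader(records, pconf)
    final, history, best = run_centralized(plan, spec, loaders, splits,
                                           out_dir=tmp_path / "out")
    assert len(history) == 2 and best in (1, 2)
    assert (tmp_path / "out" / "final_model.fcp").is_file()
    assert (tmp_path / "out" / "rounds.jsonl").read_text().count("\n") == 2


def test_model_definition_file_builds_initial_weights(tmp_path):
    """The server can source its architecture from a plain Python file
    exporting build_model()."""
    from fedbids.protocol import FLPlan, ServerSettings
    from fedbids.server import _initial_weights
    from fedbids.model_zoo import WeightSet, build_densenet, DenseNetSpec

    definition = tmp_path / "model_definition.py"
    definition.write_text(
        "from fedbids.model_zoo import DenseNetSpec, build_densenet\n\n\n"
        "def build_model(seed=0):\n"
        "    return build_densenet(DenseNetSpec.small(), seed=seed)\n")
    settings = ServerSettings(
        workspace_root=tmp_path / "ws",
        clients=({"name": "c1", "address": "local",
                  "workspace_root": str(tmp_path / "c1")},),
        model_definition=definition)
    plan = FLPlan(n_rounds_max=1, clients_per_round=1, seed=13)
    ws = _initial_weights(plan, settings)
    direct = WeightSet.from_model(build_densenet(DenseNetSpec.small(),
                                                 seed=13))
    assert list(ws) == list(direct)
    for key in ws:
        np.testing.assert_array_equal(ws[key], direct[key])
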