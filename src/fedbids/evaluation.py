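"""Reported metrics: MAE, sample-size-weighted overall MAE, Pearson
correlations and brain-age-difference (BAD) bias diagnostics.

The overall MAE across clients is the sample-size-weighted mean

    MAE_overall = Σ_i MAE_i · n_i / N,   N = Σ_i n_i,

which is algebraically identical to pooling all test pairs first.  BAD is
predicted minus true age; its correlation with true age diagnoses the usual
regression-to-the-mean bias of brain-age models (over-prediction for young,
under-prediction for old subjects).  No bias correction is applied — the
diagnostics are reported, nothing more.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import stats

__all__ = [
    "EvaluationResult", "UndefinedCorrelationError", "BadDiagnostics",
    "mae", "overall_mae", "pearson", "bad_diagnostics", "emit_report",
]


class UndefinedCorrelationError(ValueError):
    """Pearson correlation is undefined (constant margin or too few pairs)."""


@dataclass(frozen=True)
class EvaluationResult:
    client_name: str
    n_test: int
    mae: float
    pearson_r: float | None
    pearson_p: float | None
    bad_r: float | None = None
    bad_p: float | None = None


@dataclass(frozen=True)
class BadDiagnostics:
    bad: np.ndarray
    r: float | None
    p: float | None
    defined: bool


def _as_pairs(pairs) -> tuple[np.ndarray, np.ndarray]:
    arr = np.asarray(pairs, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise ValueError("expected a sequence of (true, predicted) pairs")
    return arr[:, 0], arr[:, 1]


def mae(pairs) -> float:
    """Mean absolute error over (true, predicted) pairs."""
    true, pred = _as_pairs(pairs)
    if true.size == 0:
        raise ValueError("mae of an empty set of pairs is undefined")
    return float(np.mean(np.abs(true - pred)))


def overall_mae(per_client) -> float:
    """Sample-size-weighted overall MAE from per-client (mae_i, n_i)."""
    arr = np.asarray(per_client, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2 or arr.shape[0] == 0:
        raise ValueError("expected a non-empty sequence of (mae, n) pairs")
    maes, ns = arr[:, 0], arr[:, 1]
    if np.any(ns <= 0):
        raise ValueError("client sample sizes must be positive")
    return float(np.sum(maes * ns) / np.sum(ns))


def pearson(pairs) -> tuple[float, float]:
    """Sample Pearson r and two-sided p (t-distribution, n-2 df)."""
    true, pred = _as_pairs(pairs)
    if true.size < 3:
        raise UndefinedCorrelationError("need at least 3 pairs")
    if np.ptp(true) == 0 or np.ptp(pred) == 0:
        raise UndefinedCorrelationError(
            "correlation undefined: one margin is constant")
    res = stats.pearsonr(true, pred)
    return float(res.statistic), float(res.pvalue)


def bad_diagnostics(pairs) -> BadDiagnostics:
    """Brain-age difference (predicted − true) and its correlation with age.

    When BAD is constant (e.g. a perfectly unbiased or uniformly offset
    predictor) the correlation is flagged as undefined rather than reported
    as a number.
    """
    true, pred = _as_pairs(pairs)
    bad = pred - true
    try:
        r, p = pearson(np.column_stack([true, bad]))
    except UndefinedCorrelationError:
        return BadDiagnostics(bad=bad, r=None, p=None, defined=False)
    return BadDiagnostics(bad=bad, r=r, p=p, defined=True)


def evaluate_client(client_name: str, pairs, brain_age: bool = False
                    ) -> EvaluationResult:
    """Convenience: all per-client metrics from (true, predicted) pairs."""
    true, pred = _as_pairs(pairs)
    try:
        r, p = pearson(pairs)
    except UndefinedCorrelationError:
        r = p = None
    bad_r = bad_p = None
    if brain_age:
        diag = bad_diagnostics(pairs)
        bad_r, bad_p = diag.r, diag.p
    return EvaluationResult(client_name=client_name, n_test=int(true.size),
                            mae=mae(pairs), pearson_r=r, pearson_p=p,
                            bad_r=bad_r, bad_p=bad_p)


def _fmt(x) -> str:
    return "NA" if x is None else f"{x:.6g}"


def emit_report(results: list[EvaluationResult], history=None,
                out_dir: str | Path = ".", scatter_pairs: dict | None = None,
                plots: bool = False) -> dict:
    """Write the metrics table, JSON summary and plot-ready curve data.

    ``history`` may be a server RoundHistory (or None); ``scatter_pairs``
    optionally maps client name → (true, predicted) pairs for scatter data.
    Returns a dict of written paths.
    """
    if not results:
        raise ValueError("no evaluation results to report")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = {}

    ov = overall_mae([(r.mae, r.n_test) for r in results])
    lines = ["client\tn_test\tmae\tpearson_r\tpearson_p\tbad_r\tbad_p"]
    for r in results:
        lines.append("\t".join([
            r.client_name, str(r.n_test), _fmt(r.mae), _fmt(r.pearson_r),
            _fmt(r.pearson_p), _fmt(r.bad_r), _fmt(r.bad_p)]))
    lines.append("\t".join(["overall", str(sum(r.n_test for r in results)),
                            _fmt(ov), "NA", "NA", "NA", "NA"]))
    table = out_dir / "metrics.tsv"
    table.write_text("\n".join(lines) + "\n")
    written["metrics"] = table

    summary = {
        "overall_mae": ov,
        "per_client": [{
            "client": r.client_name, "n_test": r.n_test, "mae": r.mae,
            "pearson_r": r.pearson_r, "pearson_p": r.pearson_p,
            "bad_r": r.bad_r, "bad_p": r.bad_p} for r in results],
    }
    summary_path = out_dir / "summary.json"
    summary_path.write_text(json.dumps(summary, indent=2, sort_keys=True))
    written["summary"] = summary_path

    if history is not None:
        rows = ["round\tsampled_clients\tavg_val_mae\tper_client_val_mae"]
        for rec in history:
            rows.append("\t".join([
                str(rec.round_index), ",".join(rec.sampled_client_names),
                f"{rec.avg_val_mae:.6g}",
                json.dumps(rec.per_client_val_mae, sort_keys=True)]))
        curve = out_dir / "loss_curve.tsv"
        curve.write_text("\n".join(rows) + "\n")
        written["loss_curve"] = curve

    if scatter_pairs:
        for name, pairs in scatter_pairs.items():
            true, pred = _as_pairs(pairs)
            p = out_dir / f"scatter_{name}.tsv"
            p.write_text("true\tpredicted\n" + "\n".join(
                f"{t:.6g}\t{y:.6g}" for t, y in zip(true, pred)) + "\n")
            written[f"scatter_{name}"] = p

    if plots:
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt
        if scatter_pairs:
            fig, axes = plt.subplots(1, len(scatter_pairs),
                                     figsize=(4 * len(scatter_pairs), 4),
                                     squeeze=False)
            for ax, (name, pairs) in zip(axes[0], scatter_pairs.items()):
                true, pred = _as_pairs(pairs)
                ax.scatter(true, pred, s=12)
                lim = [min(true.min(), pred.min()), max(true.max(), pred.max())]
                ax.plot(lim, lim, "--", color="grey")
                ax.set_title(name)
                ax.set_xlabel("true")
                ax.set_ylabel("predicted")
            fig.tight_layout()
            fig.savefig(out_dir / "scatter.png", dpi=100)
            plt.close(fig)
            written["scatter_png"] = out_dir / "scatter.png"
        if history is not None:
            fig, ax = plt.subplots(figsize=(5, 4))
            ax.plot([rec.round_index for rec in history],
                    [rec.avg_val_mae for rec in history], marker="o")
            ax.set_xlabel("FL round")
            ax.set_ylabel("avg validation MAE (sampled clients)")
            fig.tight_layout()
            fig.savefig(out_dir / "loss_curve.png", dpi=100)
            plt.close(fig)
            written["loss_curve_png"] = out_dir / "loss_curve.png"
    return written
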