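"""Per-slice accuracy and Jaccard evaluation of label volumes.

Metrics are computed pixel-by-pixel on a binary mask per slice — by default
the nucleus class versus everything else, the envelope excluded from the
positive set.  For each slice the confusion counts are tallied and

    accuracy = (TP + TN) / (TP + TN + FP + FN)
    jaccard  = TP / (TP + FP + FN)        (intersection over union)

A slice where both ground truth and prediction are empty has no defined
Jaccard (TP+FP+FN = 0); such slices carry accuracy 1, a flagged-undefined
Jaccard, and are excluded from range averages.  A slice with non-empty ground
truth but an empty prediction scores Jaccard 0 — exactly the regime seen at
the top and bottom of a stack where a nucleus is present but missed.

Range summaries are unweighted means of the per-slice values over 1-based
slice ranges ("a:s:b"); per-slice curves and CSV export mirror the usual way
such results are reported.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .volume_io import NUCLEUS, ENVELOPE, LabelVolume, parse_slice_range


class EvaluationError(Exception):
    pass


@dataclass
class SliceMetrics:
    slice: int                    # 1-based, as printed in slice-range notation
    tp: int
    tn: int
    fp: int
    fn: int
    accuracy: float
    jaccard: float
    jaccard_defined: bool


def confusion_counts(pred: np.ndarray, gt: np.ndarray) -> tuple[int, int, int, int]:
    """(TP, TN, FP, FN) over two congruent binary masks."""
    pred = np.asarray(pred, bool)
    gt = np.asarray(gt, bool)
    if pred.shape != gt.shape:
        raise EvaluationError(f"shape mismatch: pred {pred.shape} vs gt {gt.shape}")
    tp = int(np.count_nonzero(pred & gt))
    tn = int(np.count_nonzero(~pred & ~gt))
    fp = int(np.count_nonzero(pred & ~gt))
    fn = int(np.count_nonzero(~pred & gt))
    return tp, tn, fp, fn


def metrics_from_counts(slice_index: int, tp: int, tn: int, fp: int, fn: int) -> SliceMetrics:
    total = tp + tn + fp + fn
    acc = (tp + tn) / total if total else 1.0
    denom = tp + fp + fn
    defined = denom > 0
    jac = tp / denom if defined else 0.0
    return SliceMetrics(slice_index, tp, tn, fp, fn, acc, jac, defined)


def _positive_mask(labels: np.ndarray, positive_class: int,
                   include_envelope: bool) -> np.ndarray:
    m = labels == positive_class
    if include_envelope and positive_class == NUCLEUS:
        m |= labels == ENVELOPE
    return m


def evaluate_volume(pred: LabelVolume | np.ndarray, gt: LabelVolume | np.ndarray,
                    positive_class: int = NUCLEUS,
                    include_envelope: bool = False,
                    range_specs: list[str] | None = None) -> pd.DataFrame:
    """Per-slice metrics of a predicted label volume against ground truth.

    Returns a DataFrame with columns slice, TP, TN, FP, FN, accuracy,
    jaccard, jaccard_defined (slice is 1-based).  Use
    :func:`summarize_ranges` for the range averages.
    """
    p = pred.data if isinstance(pred, LabelVolume) else np.asarray(pred)
    g = gt.data if isinstance(gt, LabelVolume) else np.asarray(gt)
    if p.shape != g.shape:
        raise EvaluationError(f"volume shapes differ: {p.shape} vs {g.shape}")
    rows = []
    for z in range(p.shape[0]):
        pm = _positive_mask(p[z], positive_class, include_envelope)
        gm = _positive_mask(g[z], positive_class, include_envelope)
        m = metrics_from_counts(z + 1, *confusion_counts(pm, gm))
        rows.append(dict(slice=m.slice, TP=m.tp, TN=m.tn, FP=m.fp, FN=m.fn,
                         accuracy=m.accuracy, jaccard=m.jaccard,
                         jaccard_defined=m.jaccard_defined))
    return pd.DataFrame(rows)


def evaluate_per_class(pred, gt, classes: tuple[int, ...] = (0, 1, 2, 3)
                       ) -> dict[int, pd.DataFrame]:
    """One-vs-rest metrics for each requested class code."""
    return {c: evaluate_volume(pred, gt, positive_class=c) for c in classes}


def summarize_ranges(df: pd.DataFrame,
                     range_specs: list[str] | None = None) -> pd.DataFrame:
    """Unweighted mean accuracy/Jaccard over 1-based slice ranges.

    Defaults to the whole stack plus its central third.  Slices with
    undefined Jaccard are excluded from the Jaccard mean (their accuracy
    still counts).
    """
    n = int(df["slice"].max())
    if range_specs is None:
        third = max(1, n // 3)
        range_specs = [f"1:1:{n}", f"{third + 1}:1:{min(n, 2 * third)}"]
    rows = []
    for spec in range_specs:
        idx = [i for i in parse_slice_range(spec) if i <= n]
        sub = df[df["slice"].isin(idx)]
        jac = sub[sub["jaccard_defined"]]["jaccard"]
        rows.append(dict(range=spec,
                         n_slices=len(sub),
                         mean_accuracy=float(sub["accuracy"].mean()) if len(sub) else np.nan,
                         mean_jaccard=float(jac.mean()) if len(jac) else np.nan,
                         n_jaccard_defined=int(sub["jaccard_defined"].sum())))
    return pd.DataFrame(rows)


def write_metrics_csv(df: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)
    return path


def plot_metrics(curves: dict[str, pd.DataFrame], path: str | Path) -> Path:
    """Accuracy and Jaccard versus slice for one or more methods, as a PNG."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, (ax_acc, ax_jac) = plt.subplots(1, 2, figsize=(11, 4))
    for name, df in curves.items():
        ax_acc.plot(df["slice"], df["accuracy"], label=name)
        d = df[df["jaccard_defined"]]
        ax_jac.plot(d["slice"], d["jaccard"], label=name)
    ax_acc.set(xlabel="slice", ylabel="accuracy", ylim=(0, 1.02))
    ax_jac.set(xlabel="slice", ylabel="Jaccard index", ylim=(0, 1.02))
    ax_jac.legend(fontsize=8)
    fig.tight_layout()
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return path
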