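"""metrics.tsv emission, condition comparison, and overview plots.

A metrics file is tab-separated: scalar key/value rows (the run summary and
parameter echo) followed by a per-cluster table. The "wrangler" collects
metrics files from two condition directories and compares each shared
scalar metric by unpaired two-tailed t-test, both pooling clusters across
files and averaging per file first.
"""

from __future__ import annotations

import math
from pathlib import Path
from typing import Sequence

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd
from scipy.stats import ttest_ind

from .core import NasticResult

CLUSTER_COLUMNS = (
    "cluster_id",
    "n_members",
    "radius_um",
    "lifetime_s",
    "mean_time_s",
    "centroid_x_um",
    "centroid_y_um",
)


def write_metrics_tsv(result: NasticResult, path: str | Path, seed: int | None = None) -> None:
    """Scalar summary rows, then a per-cluster table, all tab-separated."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("key\tvalue\n")
        for key, value in result.summary.items():
            fh.write(f"{key}\t{value}\n")
        if seed is not None:
            fh.write(f"seed\t{seed}\n")
        fh.write("\n")
        fh.write("\t".join(CLUSTER_COLUMNS) + "\n")
        for cl in result.clusters:
            fh.write(
                f"{cl.cluster_id}\t{cl.n_members}\t{cl.radius:.6f}\t{cl.lifetime:.4f}"
                f"\t{cl.mean_time:.4f}\t{cl.centroid_x:.5f}\t{cl.centroid_y:.5f}\n"
            )


def read_metrics_tsv(path: str | Path) -> tuple[dict[str, float | str], pd.DataFrame]:
    """Inverse of :func:`write_metrics_tsv`: (scalar dict, cluster table)."""
    text = Path(path).read_text().split("\n\n")
    scalars: dict[str, float | str] = {}
    for line in text[0].splitlines()[1:]:
        key, value = line.split("\t", 1)
        try:
            scalars[key] = float(value)
        except ValueError:
            scalars[key] = value
    if len(text) > 1 and text[1].strip():
        from io import StringIO

        table = pd.read_csv(StringIO(text[1]), sep="\t")
    else:
        table = pd.DataFrame(columns=CLUSTER_COLUMNS)
    return scalars, table


def _collect(directory: str | Path) -> list[Path]:
    return sorted(Path(directory).rglob("metrics.tsv"))


def wrangler_compare(
    condition_a: str | Path | Sequence[Path],
    condition_b: str | Path | Sequence[Path],
    equal_var: bool = True,
) -> pd.DataFrame:
    """Compare scalar metrics between two conditions of metrics.tsv files.

    Each condition is a directory (searched recursively) or an explicit list
    of files. For every metric present in all files, the per-file values are
    compared by unpaired two-tailed t-test (Student's by default,
    ``equal_var=False`` for Welch); per-cluster columns are additionally
    compared pooled across files. Returns a tidy frame with one row per
    (metric, mode).
    """
    files_a = _collect(condition_a) if isinstance(condition_a, (str, Path)) else list(condition_a)
    files_b = _collect(condition_b) if isinstance(condition_b, (str, Path)) else list(condition_b)
    if len(files_a) < 2 or len(files_b) < 2:
        raise ValueError("need >= 2 metrics files per condition")
    parsed_a = [read_metrics_tsv(f) for f in files_a]
    parsed_b = [read_metrics_tsv(f) for f in files_b]

    rows = []

    def add_row(metric: str, mode: str, va: np.ndarray, vb: np.ndarray) -> None:
        stat = ttest_ind(va, vb, equal_var=equal_var)
        rows.append(
            {
                "metric": metric,
                "mode": mode,
                "mean_a": float(np.mean(va)),
                "sem_a": float(np.std(va, ddof=1) / math.sqrt(len(va))) if len(va) > 1 else 0.0,
                "mean_b": float(np.mean(vb)),
                "sem_b": float(np.std(vb, ddof=1) / math.sqrt(len(vb))) if len(vb) > 1 else 0.0,
                "n_a": len(va),
                "n_b": len(vb),
                "t": float(stat.statistic),
                "p": float(stat.pvalue),
            }
        )

    scalar_keys = set.intersection(
        *[set(s) for s, _ in parsed_a], *[set(s) for s, _ in parsed_b]
    )
    for key in sorted(scalar_keys):
        va = [s[key] for s, _ in parsed_a]
        vb = [s[key] for s, _ in parsed_b]
        if not all(isinstance(v, float) for v in va + vb):
            continue
        add_row(key, "per_cell", np.array(va, dtype=float), np.array(vb, dtype=float))

    tables_a = [t[1] for t in parsed_a if len(t[1])]
    tables_b = [t[1] for t in parsed_b if len(t[1])]
    if tables_a and tables_b:
        for col in ("n_members", "radius_um", "lifetime_s"):
            pooled_a = np.concatenate([t[col].to_numpy(float) for t in tables_a])
            pooled_b = np.concatenate([t[col].to_numpy(float) for t in tables_b])
            if len(pooled_a) > 1 and len(pooled_b) > 1:
                add_row(col, "pooled_clusters", pooled_a, pooled_b)
    return pd.DataFrame(rows)


def plot_overview(
    result: NasticResult,
    trajectories: Sequence,
    path: str | Path,
    dpi: int = 300,
) -> None:
    """Deterministic overview PNG: trajectories in gray, cluster hulls
    coloured by mean detection time on a fixed colormap."""
    fig, ax = plt.subplots(figsize=(6, 6))
    for tr in trajectories:
        ax.plot(tr.xy[:, 0], tr.xy[:, 1], color="0.8", linewidth=0.3, zorder=1)
    if result.clusters:
        times = [cl.mean_time for cl in result.clusters]
        t_lo, t_hi = min(times), max(times)
        cmap = plt.get_cmap("viridis")
        for cl in result.clusters:
            if cl.hull is None:
                continue
            frac = 0.5 if t_hi == t_lo else (cl.mean_time - t_lo) / (t_hi - t_lo)
            ax.fill(cl.hull[:, 0], cl.hull[:, 1], color=cmap(frac), alpha=0.7, zorder=2)
        sm = plt.cm.ScalarMappable(cmap=cmap, norm=plt.Normalize(t_lo, t_hi))
        fig.colorbar(sm, ax=ax, label="cluster mean time (s)")
    ax.set_xlabel("x (µm)")
    ax.set_ylabel("y (µm)")
    ax.set_aspect("equal")
    fig.savefig(path, dpi=dpi, metadata={"Software": None})
    plt.close(fig)
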