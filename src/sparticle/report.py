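"""Population-level summaries of measured particles.

Splits the population into mycelial fragments and pellets at a maximal
length (default 150 µm), tabulates per-metric summary statistics for each
subpopulation, draws diameter-versus-polar-circularity scatter plots with
95% confidence ellipses, and compares populations with Welch's two-sample
t-test.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "EllipseParams", "PopulationSummary", "split_population",
    "confidence_ellipse", "compare_populations", "summarize", "write_report",
]

DEFAULT_SPLIT_UM = 150.0


@dataclass(frozen=True)
class EllipseParams:
    """Confidence ellipse of a 2-D sample: centre, semi-axes (major first),
    orientation of the major axis (radians, CCW from +x) and level."""

    center: tuple[float, float]
    semi_axes: tuple[float, float]
    orientation: float
    level: float


@dataclass(frozen=True)
class PopulationSummary:
    n_particles: int
    n_fragments: int
    n_pellets: int
    split_um: float
    stats: pd.DataFrame  # rows: metric; columns: group mean/SD

    def __post_init__(self) -> None:
        assert self.n_fragments + self.n_pellets == self.n_particles


def split_population(metrics: pd.DataFrame, cutoff_um: float = DEFAULT_SPLIT_UM
                     ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """(fragments, pellets): fragments have feret_um strictly below the
    cutoff, pellets are the remainder."""
    if "feret_um" not in metrics.columns:
        raise KeyError("metrics table lacks a feret_um column")
    frag = metrics[metrics["feret_um"] < cutoff_um].reset_index(drop=True)
    pel = metrics[~(metrics["feret_um"] < cutoff_um)].reset_index(drop=True)
    return frag, pel


def confidence_ellipse(x, y, level: float = 0.95) -> EllipseParams:
    """Covariance confidence ellipse of a 2-D sample.

    Eigen-decomposition of the 2×2 sample covariance; semi-axis i is
    √(q·λᵢ) where q is the chi-square quantile with 2 degrees of freedom at
    ``level`` (q = 5.991 at 0.95).  The orientation is the angle of the
    principal eigenvector.
    """
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if len(x) != len(y):
        raise ValueError("x and y must have equal length")
    if len(x) < 3:
        raise ValueError("need at least 3 points for a confidence ellipse")
    if not (0.0 < level < 1.0):
        raise ValueError("confidence level must lie in (0, 1)")
    cov = np.cov(x, y)
    if not np.isfinite(cov).all() or np.allclose(cov, 0.0):
        raise ValueError("sample has no variance in either axis")
    eigvals, eigvecs = np.linalg.eigh(cov)
    order = np.argsort(eigvals)[::-1]
    eigvals = np.clip(eigvals[order], 0.0, None)
    eigvecs = eigvecs[:, order]
    q = stats.chi2.ppf(level, df=2)
    semi = tuple(float(math.sqrt(q * lam)) for lam in eigvals)
    orientation = float(math.atan2(eigvecs[1, 0], eigvecs[0, 0]))
    if orientation < -math.pi / 2:
        orientation += math.pi
    elif orientation > math.pi / 2:
        orientation -= math.pi
    return EllipseParams(
        center=(float(x.mean()), float(y.mean())),
        semi_axes=semi, orientation=orientation, level=level,
    )


def compare_populations(a, b) -> tuple[float, float]:
    """Welch two-sample t-test (unequal variances), two-sided p value."""
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each sample needs at least 2 values")
    if a.std(ddof=1) == 0 and b.std(ddof=1) == 0:
        raise ValueError("degenerate samples: both have zero variance")
    t, p = stats.ttest_ind(a, b, equal_var=False)
    return float(t), float(p)


def summarize(metrics: pd.DataFrame, split_um: float = DEFAULT_SPLIT_UM
              ) -> PopulationSummary:
    """Per-metric mean/SD for the fragment and pellet subpopulations."""
    frag, pel = split_population(metrics, split_um)
    numeric = [c for c in metrics.columns
               if pd.api.types.is_numeric_dtype(metrics[c]) and c != "label"]
    rows = []
    for col in numeric:
        rows.append({
            "metric": col,
            "fragments_mean": frag[col].mean() if len(frag) else np.nan,
            "fragments_sd": frag[col].std(ddof=1) if len(frag) > 1 else np.nan,
            "pellets_mean": pel[col].mean() if len(pel) else np.nan,
            "pellets_sd": pel[col].std(ddof=1) if len(pel) > 1 else np.nan,
        })
    table = pd.DataFrame(rows, columns=[
        "metric", "fragments_mean", "fragments_sd", "pellets_mean", "pellets_sd",
    ])
    return PopulationSummary(
        n_particles=len(metrics), n_fragments=len(frag), n_pellets=len(pel),
        split_um=split_um, stats=table,
    )


def _plot_scatter(frag: pd.DataFrame, pel: pd.DataFrame, path) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from matplotlib.patches import Ellipse

    fig, ax = plt.subplots(figsize=(6, 5))
    for df, color, name in ((frag, "tab:orange", "fragments"),
                            (pel, "tab:blue", "pellets")):
        if len(df) == 0:
            continue
        x = df["feret_um"].to_numpy()
        y = df["polar_circularity"].to_numpy()
        ax.scatter(x, y, s=8, alpha=0.6, color=color, label=f"{name} (n={len(df)})")
        try:
            ell = confidence_ellipse(x, y)
            ax.add_patch(Ellipse(
                ell.center, 2 * ell.semi_axes[0], 2 * ell.semi_axes[1],
                angle=math.degrees(ell.orientation),
                fill=False, color=color, lw=1.5))
        except ValueError:
            pass
    ax.set_xlabel("maximum Feret diameter (µm)")
    ax.set_ylabel("polar circularity")
    if ax.get_legend_handles_labels()[0]:
        ax.legend(loc="best", fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def write_report(metrics: pd.DataFrame, out_dir,
                 split_um: float = DEFAULT_SPLIT_UM,
                 config: dict | None = None) -> dict:
    """Write population CSVs, the diameter-vs-circularity scatter with 95%
    confidence ellipses, and a run log carrying a hash of the configuration.

    Re-running on identical inputs reproduces the CSVs byte-identically.
    Returns the paths written.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    summary = summarize(metrics, split_um)
    frag, pel = split_population(metrics, split_um)

    paths = {
        "summary": out / "summary.csv",
        "fragments": out / "fragments.csv",
        "pellets": out / "pellets.csv",
        "scatter": out / "diameter_vs_polar_circularity.png",
        "run_log": out / "run_log.json",
    }
    summary.stats.to_csv(paths["summary"], index=False)
    frag.to_csv(paths["fragments"], index=False)
    pel.to_csv(paths["pellets"], index=False)
    _plot_scatter(frag, pel, paths["scatter"])

    cfg = dict(config or {})
    cfg["split_um"] = split_um
    cfg_json = json.dumps(cfg, sort_keys=True)
    with open(paths["run_log"], "w") as fh:
        json.dump({
            "n_particles": summary.n_particles,
            "n_fragments": summary.n_fragments,
            "n_pellets": summary.n_pellets,
            "config": cfg,
            "config_sha256": hashlib.sha256(cfg_json.encode()).hexdigest(),
        }, fh, indent=2, sort_keys=True)
    return {k: str(v) for k, v in paths.items()}
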