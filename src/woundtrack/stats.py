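"""Group comparison and report generation.

Scalar per-track metrics are compared between groups (e.g. genotypes) with
the classical unpaired two-tailed Student t-test (pooled variance; Welch's
correction available behind a flag), starred at the conventional
0.05 / 0.01 / 0.001 / 0.0001 thresholds.  No multiple-testing correction
is applied; the report carries raw p-values and says so.  Scalars are
reported as mean ± SD, cohort curves (MSD, axial velocity) with SEM
shading.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = ["GroupComparison", "significance_stars", "compare", "compare_groups", "render_report"]

logger = logging.getLogger(__name__)

STAR_THRESHOLDS = ((1e-4, "****"), (1e-3, "***"), (1e-2, "**"), (5e-2, "*"))


def significance_stars(p: float) -> str:
    """Map a p-value to the conventional star annotation ('ns' if ≥ 0.05)."""
    for cut, stars in STAR_THRESHOLDS:
        if p < cut:
            return stars
    return "ns"


@dataclass(frozen=True)
class GroupComparison:
    group_a: str
    group_b: str
    metric: str
    mean_a: float
    mean_b: float
    sd_a: float
    sd_b: float
    n_a: int
    n_b: int
    t: float
    p: float
    stars: str


def compare(
    values_a: Sequence[float],
    values_b: Sequence[float],
    *,
    group_a: str = "A",
    group_b: str = "B",
    metric: str = "",
    welch: bool = False,
) -> GroupComparison:
    """Unpaired two-tailed t-test between two metric samples.

    Non-finite values (e.g. the undefined meandering index of a stationary
    cell) are dropped before testing.  Both groups must retain n ≥ 2.  When
    both groups are constant and equal, t = 0 and p = 1 by convention
    (logged); swapping the groups negates t and preserves p.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    a = a[np.isfinite(a)]
    b = b[np.isfinite(b)]
    if a.size < 2 or b.size < 2:
        raise ValueError(f"need n >= 2 finite values per group, got {a.size} and {b.size}")
    if a.std(ddof=1) == 0.0 and b.std(ddof=1) == 0.0 and a.mean() == b.mean():
        logger.warning("both groups constant and equal for %r; p = 1 by convention", metric)
        t_stat, p_val = 0.0, 1.0
    else:
        t_stat, p_val = sps.ttest_ind(a, b, equal_var=not welch)
        t_stat, p_val = float(t_stat), float(p_val)
    return GroupComparison(
        group_a=group_a,
        group_b=group_b,
        metric=metric,
        mean_a=float(a.mean()),
        mean_b=float(b.mean()),
        sd_a=float(a.std(ddof=1)),
        sd_b=float(b.std(ddof=1)),
        n_a=int(a.size),
        n_b=int(b.size),
        t=t_stat,
        p=p_val,
        stars=significance_stars(p_val),
    )


def compare_groups(
    summaries: pd.DataFrame,
    metrics: Sequence[str],
    *,
    group_col: str = "group",
    welch: bool = False,
) -> list[GroupComparison]:
    """All pairwise group comparisons for each listed metric column."""
    groups = sorted(summaries[group_col].unique())
    out = []
    for metric in metrics:
        for i, ga in enumerate(groups):
            for gb in groups[i + 1 :]:
                out.append(
                    compare(
                        summaries.loc[summaries[group_col] == ga, metric],
                        summaries.loc[summaries[group_col] == gb, metric],
                        group_a=ga,
                        group_b=gb,
                        metric=metric,
                        welch=welch,
                    )
                )
    return out


def comparisons_frame(comparisons: Sequence[GroupComparison]) -> pd.DataFrame:
    cols = [
        "metric", "group_a", "group_b", "mean_a", "sd_a", "n_a",
        "mean_b", "sd_b", "n_b", "t", "p", "stars",
    ]
    if not comparisons:
        return pd.DataFrame(columns=cols)
    return pd.DataFrame([asdict(c) for c in comparisons])[cols]


def _curve_figure(curves: Mapping[str, pd.DataFrame], ylabel: str, path: Path) -> None:
    # Figure + Agg canvas directly: no global pyplot state, deterministic
    from matplotlib.backends.backend_agg import FigureCanvasAgg
    from matplotlib.figure import Figure

    fig = Figure(figsize=(5, 4))
    FigureCanvasAgg(fig)
    ax = fig.add_subplot(111)
    for label, curve in sorted(curves.items()):
        t = curve["lag_or_time"].to_numpy()
        m = curve["mean"].to_numpy()
        s = curve["sem"].to_numpy()
        ax.plot(t, m, label=label)
        ok = np.isfinite(s)
        ax.fill_between(t[ok], (m - s)[ok], (m + s)[ok], alpha=0.3)
    ax.set_xlabel("time or lag (min)")
    ax.set_ylabel(ylabel)
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)


def render_report(
    comparisons: Sequence[GroupComparison],
    curves: Mapping[str, Mapping[str, pd.DataFrame]] | None = None,
    summaries: pd.DataFrame | None = None,
    outdir: str | Path = ".",
) -> list[Path]:
    """Write deterministic CSV tables and SEM-shaded curve plots.

    ``curves`` maps a quantity name (e.g. ``"msd"``, ``"v_ap"``) to a
    mapping of group label → curve table with columns
    ``(lag_or_time, mean, sem, n)``.  Scalar comparisons are tabulated as
    mean ± SD per group with raw (uncorrected) p-values.  Re-running on the
    same inputs yields byte-identical tables.  Returns the written paths.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    cmp_path = outdir / "comparisons.csv"
    comparisons_frame(comparisons).to_csv(cmp_path, index=False)
    written.append(cmp_path)

    if summaries is not None:
        from .io import write_summary

        sum_path = outdir / "track_summaries.csv"
        write_summary(summaries, sum_path)
        written.append(sum_path)

    for name, per_group in (curves or {}).items():
        for label, curve in sorted(per_group.items()):
            csv_path = outdir / f"{name}_{label}.csv"
            from .io import write_curve

            write_curve(curve, csv_path)
            written.append(csv_path)
        ylabel = "MSD (μm²)" if name.lower().startswith("msd") else f"{name} (μm/min)"
        png_path = outdir / f"{name}.png"
        _curve_figure(per_group, ylabel, png_path)
        written.append(png_path)

    note = outdir / "README.txt"
    note.write_text(
        "Scalar tables report mean ± SD per group; curve tables carry the\n"
        "across-cell SEM used for shading. p-values are raw two-tailed\n"
        "Student t-test values; no multiple-testing correction is applied.\n",
        encoding="utf-8",
    )
    written.append(note)
    return written
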