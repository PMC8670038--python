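"""Per-site sensitivity estimates and funnel-plot control limits.

Institutional comparison follows standard funnel-plot practice: per-site
sensitivities are scattered against site size, with control limits drawn
around the pooled proportion at p ± z·sqrt(p(1−p)/n).  Exact binomial
limits are available behind a flag.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .accuracy import (
    ProportionEstimate,
    average_readers,
    classify_gastric,
    proportion_ci,
)
from .records import PatientDataset, TubeLocation

__all__ = ["SiteEstimate", "FunnelSeries", "per_site_estimates", "funnel_limits", "plot_funnel"]


@dataclass(frozen=True)
class SiteEstimate:
    site_id: str
    n: int
    sens_standard: ProportionEstimate
    sens_novel: ProportionEstimate

    @property
    def margin(self) -> float:
        """Sensitivity margin of the novel over the standard strip."""
        return self.sens_novel.point - self.sens_standard.point


def per_site_estimates(
    dataset: PatientDataset, cutoff: float, level: float = 0.95
) -> list[SiteEstimate]:
    """One sensitivity estimate per site, ordered by site id.

    Sites without gastric records are skipped with a warning.
    """
    gastric = dataset.gastric
    if not gastric:
        raise ValueError("dataset contains no gastric records")
    by_site: dict[str, list] = {}
    for rec in gastric:
        by_site.setdefault(rec.site_id, []).append(rec)
    out = []
    for site_id in sorted(by_site):
        recs = by_site[site_id]
        if not recs:  # defensive; empty groups cannot arise from the dict build
            warnings.warn(f"site {site_id!r} has no gastric records; skipped")
            continue
        n = len(recs)
        k_std = sum(
            classify_gastric(average_readers(r.std_r1, r.std_r2), cutoff) for r in recs
        )
        k_nov = sum(
            classify_gastric(average_readers(r.novel_r1, r.novel_r2), cutoff) for r in recs
        )
        out.append(
            SiteEstimate(
                site_id=site_id,
                n=n,
                sens_standard=proportion_ci(k_std, n, level),
                sens_novel=proportion_ci(k_nov, n, level),
            )
        )
    return out


@dataclass(frozen=True)
class FunnelSeries:
    """Control limits around a pooled proportion over a grid of sizes."""

    pooled_p: float
    n_grid: tuple[int, ...]
    lower: tuple[float, ...]
    upper: tuple[float, ...]
    level: float = 0.95

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "n": self.n_grid,
                "lower": self.lower,
                "pooled": [self.pooled_p] * len(self.n_grid),
                "upper": self.upper,
            }
        )


def funnel_limits(
    pooled_p: float,
    n_grid: Sequence[int],
    level: float = 0.95,
    method: str = "normal",
) -> FunnelSeries:
    """Control limits for a funnel plot, clipped to [0, 1].

    ``method="normal"`` (default) uses pooled_p ± z·sqrt(p(1−p)/n);
    ``method="exact"`` uses binomial quantiles.  A degenerate pooled
    proportion (0 or 1) collapses both limits onto it.
    """
    if not (0.0 <= pooled_p <= 1.0):
        raise ValueError("pooled_p outside [0, 1]")
    grid = tuple(int(n) for n in n_grid)
    if not grid or any(n <= 0 for n in grid):
        raise ValueError("n_grid must be non-empty and positive")
    if pooled_p in (0.0, 1.0):
        flat = tuple(pooled_p for _ in grid)
        return FunnelSeries(pooled_p, grid, flat, flat, level)
    lower, upper = [], []
    if method == "normal":
        z = float(stats.norm.ppf(0.5 + level / 2.0))
        for n in grid:
            half = z * np.sqrt(pooled_p * (1.0 - pooled_p) / n)
            lower.append(max(0.0, pooled_p - half))
            upper.append(min(1.0, pooled_p + half))
    elif method == "exact":
        alpha = 1.0 - level
        for n in grid:
            lower.append(float(stats.binom.ppf(alpha / 2.0, n, pooled_p)) / n)
            upper.append(float(stats.binom.ppf(1.0 - alpha / 2.0, n, pooled_p)) / n)
    else:
        raise ValueError("method must be 'normal' or 'exact'")
    return FunnelSeries(pooled_p, grid, tuple(lower), tuple(upper), level)


def plot_funnel(
    sites: Sequence[SiteEstimate],
    series: FunnelSeries,
    strip: str = "novel",
    path: Optional[str] = None,
):
    """Render the funnel plot (optional output; numeric series are the API)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    xs = [s.n for s in sites]
    ys = [
        (s.sens_novel if strip == "novel" else s.sens_standard).point for s in sites
    ]
    ax.scatter(xs, ys, zorder=3)
    ax.plot(series.n_grid, series.lower, "k--", lw=0.8)
    ax.plot(series.n_grid, series.upper, "k--", lw=0.8)
    ax.axhline(series.pooled_p, color="k", lw=0.8)
    ax.set_xlabel("site size (gastric samples)")
    ax.set_ylabel(f"{strip} strip sensitivity")
    ax.set_ylim(0, 1)
    if path is not None:
        fig.savefig(path, dpi=150, bbox_inches="tight")
        plt.close(fig)
    return fig
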