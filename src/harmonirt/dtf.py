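"""Differential item and test functioning (DIF/DTF) summaries.

Item-level DIF is summarized as posterior differences of group-specific item
parameters between a focal and a reference group.  Scale-level DTF follows
the expected-score method of Stark and colleagues: for every focal-group
person, two expected total test scores are computed from the same trait
value — one under the focal group's item parameters and one under the
reference group's — and

``DTFR = E[TCC_F(theta) - TCC_R(theta)]`` over the focal group's traits,

so a positive DTFR means the focal parameters yield systematically higher
expected scores at equal trait level.  ``d_DTF = DTFR / SD_F`` expresses this
as an effect size against the focal group's observed sum-score SD, and the
observed mean difference decomposes as ``OMD = DTFR + IMPACT``, where IMPACT
is the part attributable to a true latent-mean difference.
"""

from __future__ import annotations

import dataclasses
import warnings
from typing import Sequence

import numpy as np
import pandas as pd

from .gpcm import ParamSet, tcc
from .response_data import ResponseDataset


@dataclasses.dataclass
class SumScoreStats:
    """Observed sum-score statistics for one group on an item subset."""

    group: int
    items: tuple[int, ...]
    mean: float
    sd: float
    n: int


@dataclasses.dataclass
class DTFResult:
    """One focal-vs-reference DTF comparison (a report-table row plus the
    TCC grids).  Satisfies ``IMPACT == OMD - DTFR`` exactly."""

    focal: str
    reference: str
    items: tuple[int, ...]
    TS: int
    M_F: float
    SD_F: float
    M_R: float
    SD_R: float
    OMD: float
    DTFR: float
    d_DTF: float
    IMPACT: float
    theta_grid: np.ndarray
    tcc_F: np.ndarray
    tcc_R: np.ndarray


def observed_sum_stats(ds: ResponseDataset, group: int, items: Sequence) -> SumScoreStats:
    """Mean and SD (denominator n-1) of observed sum scores over ``items``
    for complete cases within ``group``."""
    idx = ds.item_index(items)
    rows = np.where(ds.group_idx == group)[0]
    sub = ds.responses[np.ix_(rows, idx)]
    complete = ~np.isnan(sub).any(axis=1)
    scores = sub[complete].sum(axis=1)
    n = scores.size
    if n < 2:
        raise ValueError(f"need at least 2 complete cases for an SD, got {n}")
    return SumScoreStats(
        group=group,
        items=tuple(int(k) for k in idx),
        mean=float(scores.mean()),
        sd=float(scores.std(ddof=1)),
        n=n,
    )


def compute_omd(m_f: float, m_r: float) -> float:
    """Observed mean difference, focal minus reference."""
    return m_f - m_r


def effect_size(dtfr: float, sd_f: float) -> float:
    """DTF effect size ``d_DTF = DTFR / SD_F``."""
    if sd_f <= 0:
        raise ValueError("SD_F must be > 0")
    return dtfr / sd_f


def compute_impact(omd: float, dtfr: float) -> float:
    """True latent-mean component of the observed difference:
    ``IMPACT = OMD - DTFR``."""
    return omd - dtfr


def compute_dtfr(
    thetas_f: np.ndarray,
    params: ParamSet,
    focal: int,
    reference: int,
    items: Sequence,
) -> float:
    """Average focal-minus-reference TCC difference over the focal group's
    trait values.  ``items`` must be administered in both groups."""
    thetas_f = np.asarray(thetas_f, dtype=float)
    if thetas_f.size == 0:
        raise ValueError("focal group has no trait values")
    items = list(items)
    for k in items:
        if not (params.admin_mask[focal, k] and params.admin_mask[reference, k]):
            raise ValueError(
                f"item {params.item_labels[k]!r} is not shared by both groups"
            )
    diff = tcc(thetas_f, params, focal, items) - tcc(thetas_f, params, reference, items)
    return float(np.mean(diff))


def tcc_curve(
    params: ParamSet,
    group: int,
    items: Sequence,
    theta_min: float,
    theta_max: float,
    n_points: int = 101,
) -> tuple[np.ndarray, np.ndarray]:
    """Expected-sum-score grid over ``[theta_min, theta_max]``."""
    if not theta_min < theta_max:
        raise ValueError("theta_min must be strictly below theta_max")
    if n_points < 2:
        raise ValueError("n_points must be >= 2")
    grid = np.linspace(theta_min, theta_max, n_points)
    return grid, tcc(grid, params, group, list(items))


def dif_table(posterior, focal, reference) -> pd.DataFrame:
    """Per-item, per-parameter posterior differences between two groups.

    For every item administered in both groups and each parameter (alpha and
    each threshold): posterior mean difference focal-minus-reference, central
    95% interval, and a flag when the interval excludes 0.  Items not shared
    are excluded (with a warning naming them).
    """
    fi = _group_index(posterior, focal)
    ri = _group_index(posterior, reference)
    alpha = posterior.stacked("alpha")
    beta = posterior.stacked("beta")
    shared = posterior.admin_mask[fi] & posterior.admin_mask[ri]
    skipped = [
        posterior.item_labels[k]
        for k in range(len(posterior.item_labels))
        if (posterior.admin_mask[fi, k] or posterior.admin_mask[ri, k]) and not shared[k]
    ]
    if skipped:
        warnings.warn(
            f"items not administered in both groups excluded from DIF table: {skipped}"
        )
    rows = []
    for k in np.where(shared)[0]:
        blocks = {"alpha": alpha[:, fi, k] - alpha[:, ri, k]}
        for c in range(posterior.C):
            blocks[f"beta{c + 1}"] = beta[:, fi, k, c] - beta[:, ri, k, c]
        for pname, d in blocks.items():
            lo, hi = np.percentile(d, [2.5, 97.5])
            rows.append(
                {
                    "item": posterior.item_labels[k],
                    "parameter": pname,
                    "diff_mean": float(d.mean()),
                    "q2.5": float(lo),
                    "q97.5": float(hi),
                    "flagged": bool(lo > 0 or hi < 0),
                }
            )
    if not rows:
        warnings.warn(
            f"no items shared between {posterior.group_labels[fi]!r} and "
            f"{posterior.group_labels[ri]!r}; DIF table is empty"
        )
    return pd.DataFrame(rows, columns=["item", "parameter", "diff_mean", "q2.5", "q97.5", "flagged"])


def _group_index(posterior, group) -> int:
    if isinstance(group, (int, np.integer)):
        return int(group)
    return posterior.group_labels.index(group)


def dtf_result(
    ds: ResponseDataset,
    posterior,
    focal,
    reference,
    items: Sequence | None = None,
    n_grid: int = 101,
) -> DTFResult:
    """Full DTF comparison from a fitted posterior.

    Uses posterior-mean item parameters and posterior-mean focal traits
    (``use_draws=True`` averaging is available via
    :func:`compute_dtfr_draws`).  ``items`` defaults to all items shared by
    the two groups.  Observed sum-score statistics come from complete cases
    on those items within each group.
    """
    fi = _group_index(posterior, focal)
    ri = _group_index(posterior, reference)
    if items is None:
        idx = np.where(posterior.admin_mask[fi] & posterior.admin_mask[ri])[0]
    else:
        idx = ds.item_index(items)
    idx = [int(k) for k in idx]
    params = posterior.mean_paramset()
    theta_mean = posterior.theta_mean
    thetas_f = theta_mean[ds.group_idx == fi]
    stats_f = observed_sum_stats(ds, fi, idx)
    stats_r = observed_sum_stats(ds, ri, idx)
    omd = compute_omd(stats_f.mean, stats_r.mean)
    dtfr = compute_dtfr(thetas_f, params, fi, ri, idx)
    both = theta_mean[(ds.group_idx == fi) | (ds.group_idx == ri)]
    grid, curve_f = tcc_curve(params, fi, idx, both.min(), both.max(), n_grid)
    _, curve_r = tcc_curve(params, ri, idx, both.min(), both.max(), n_grid)
    return DTFResult(
        focal=posterior.group_labels[fi],
        reference=posterior.group_labels[ri],
        items=tuple(idx),
        TS=ds.C * len(idx),
        M_F=stats_f.mean,
        SD_F=stats_f.sd,
        M_R=stats_r.mean,
        SD_R=stats_r.sd,
        OMD=omd,
        DTFR=dtfr,
        d_DTF=effect_size(dtfr, stats_f.sd),
        IMPACT=compute_impact(omd, dtfr),
        theta_grid=grid,
        tcc_F=curve_f,
        tcc_R=curve_r,
    )


def compute_dtfr_draws(ds: ResponseDataset, posterior, focal, reference, items) -> float:
    """DTFR averaged over posterior draws of the item parameters (the
    draws-averaging alternative to posterior-mean parameters)."""
    fi = _group_index(posterior, focal)
    ri = _group_index(posterior, reference)
    idx = [int(k) for k in ds.item_index(items)]
    thetas_f = posterior.theta_mean[ds.group_idx == fi]
    alpha = posterior.stacked("alpha")
    beta = posterior.stacked("beta")
    vals = []
    for s in range(alpha.shape[0]):
        p = ParamSet(alpha[s], beta[s], posterior.admin_mask,
                     posterior.group_labels, posterior.item_labels)
        vals.append(compute_dtfr(thetas_f, p, fi, ri, idx))
    return float(np.mean(vals))


def dtf_report(ds: ResponseDataset, posterior, pairs: Sequence[tuple], n_grid: int = 101):
    """DTF table with one row per (focal, reference) pair, mirroring the
    standard report columns; values rounded to two decimals in the table,
    with the full-precision results returned alongside."""
    results = [dtf_result(ds, posterior, f, r, n_grid=n_grid) for f, r in pairs]
    rows = []
    for res in results:
        rows.append(
            {
                "comparison": f"{res.focal}-{res.reference}",
                "TS": res.TS,
                "M_F": round(res.M_F, 2),
                "SD_F": round(res.SD_F, 2),
                "M_R": round(res.M_R, 2),
                "SD_R": round(res.SD_R, 2),
                "OMD": round(res.OMD, 2),
                "DTFR": round(res.DTFR, 2),
                "d_DTF": round(res.d_DTF, 2),
                "IMPACT": round(res.IMPACT, 2),
            }
        )
    return pd.DataFrame(rows), results


def plot_tcc_comparison(curves: dict, TS: int, out_path=None, title: str | None = None):
    """Plot test characteristic curves for several groups on a common grid.

    ``curves`` maps a group label to a ``(theta_grid, expected_scores)``
    pair; all grids must coincide.  The y-axis is fixed to the full
    theoretical score range ``[0, TS]`` so small DTF reads as small.
    Returns ``(fig, ax)`` and writes ``out_path`` if given (PNG/SVG by
    extension).
    """
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    if len(curves) < 2:
        raise ValueError("need at least two curves to compare")
    grids = [np.asarray(gv[0]) for gv in curves.values()]
    for other in grids[1:]:
        if other.shape != grids[0].shape or not np.allclose(other, grids[0]):
            raise ValueError("all curves must share a common theta grid")
    fig, ax = plt.subplots(figsize=(6, 4))
    for label, (grid, values) in curves.items():
        ax.plot(grid, values, label=label)
    ax.set_ylim(0, TS)
    ax.set_xlabel(r"latent trait $\theta$")
    ax.set_ylabel("expected test score")
    if title:
        ax.set_title(title)
    ax.legend()
    fig.tight_layout()
    if out_path is not None:
        fig.savefig(out_path, dpi=150)
    return fig, ax
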