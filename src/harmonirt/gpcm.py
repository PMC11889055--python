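"""Generalized partial credit model (GPCM) mathematics.

The GPCM models an ordered polytomous response with codes ``0..C`` through a
person trait ``theta``, an item discrimination ``alpha`` and ``C`` category
thresholds ``beta_1..beta_C``.  Category probabilities use the standard
divide-by-total form

.. math::

    P(Y = c \\mid \\theta) =
        \\frac{\\exp\\big(\\sum_{v=1}^{c} \\alpha(\\theta - \\beta_v)\\big)}
             {\\sum_{r=0}^{C} \\exp\\big(\\sum_{v=1}^{r}
              \\alpha(\\theta - \\beta_v)\\big)},

with the empty sum for ``c = 0`` equal to zero.  All likelihood work is done
in log space (log-sum-exp), so probabilities never underflow to exact zeros
for finite parameters.

The module also provides the expected item score, the test characteristic
curve (TCC, the expected sum score as a function of the trait) and the
observed-data log-likelihood used by the sampler, plus the ``ParamSet``
container that holds group-specific item parameters aligned to an
administration mask.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import softmax


@dataclasses.dataclass(frozen=True)
class GroupItemParams:
    """Item parameters for one item in one group.

    Parameters
    ----------
    alpha
        Discrimination; must be strictly positive.
    betas
        The ``C`` category thresholds, in latent-trait units.
    """

    alpha: float
    betas: tuple[float, ...]

    def __post_init__(self) -> None:
        if not np.isfinite(self.alpha) or self.alpha <= 0:
            raise ValueError(f"discrimination must be finite and > 0, got {self.alpha}")
        betas = tuple(float(b) for b in self.betas)
        if len(betas) == 0 or not np.all(np.isfinite(betas)):
            raise ValueError(f"thresholds must be a non-empty finite sequence, got {self.betas}")
        object.__setattr__(self, "betas", betas)

    @property
    def n_categories(self) -> int:
        return len(self.betas) + 1


def _cumulative_logits(theta: np.ndarray, alpha: np.ndarray, beta: np.ndarray) -> np.ndarray:
    """Cumulative GPCM logits s_c = sum_{v<=c} alpha*(theta - beta_v), s_0 = 0.

    ``theta`` and ``alpha`` broadcast against ``beta[..., C]``; returns an
    array with a trailing axis of length C+1.
    """
    d = np.asarray(alpha, float)[..., None] * (
        np.asarray(theta, float)[..., None] - np.asarray(beta, float)
    )
    s = np.cumsum(d, axis=-1)
    zero = np.zeros(s.shape[:-1] + (1,), dtype=float)
    return np.concatenate([zero, s], axis=-1)


def category_probabilities(theta, item: GroupItemParams) -> np.ndarray:
    """Probabilities of each response category ``0..C`` at trait ``theta``.

    ``theta`` may be a scalar or an array; the category axis is appended
    last.  Probabilities are strictly positive and sum to one.
    """
    theta = np.asarray(theta, dtype=float)
    if not np.all(np.isfinite(theta)):
        raise ValueError("theta must be finite")
    s = _cumulative_logits(theta, item.alpha, np.asarray(item.betas))
    return softmax(s, axis=-1)


def expected_item_score(theta, item: GroupItemParams):
    """Expected score ``sum_c c * P(Y=c)``; lies in ``[0, C]`` and is strictly
    increasing in ``theta`` for ``alpha > 0``."""
    p = category_probabilities(theta, item)
    c = np.arange(p.shape[-1], dtype=float)
    out = p @ c
    return float(out) if np.isscalar(theta) or np.ndim(theta) == 0 else out


class ParamSet:
    """Group-specific GPCM item parameters aligned to an administration mask.

    Internally stores ``alpha`` with shape (J, K) and ``beta`` with shape
    (J, K, C); entries are NaN exactly where ``admin_mask`` is False.
    """

    def __init__(
        self,
        alpha: np.ndarray,
        beta: np.ndarray,
        admin_mask: np.ndarray,
        group_labels: Sequence[str] | None = None,
        item_labels: Sequence[str] | None = None,
    ) -> None:
        alpha = np.array(alpha, dtype=float)
        beta = np.array(beta, dtype=float)
        admin_mask = np.array(admin_mask, dtype=bool)
        if alpha.ndim != 2 or beta.ndim != 3 or admin_mask.shape != alpha.shape:
            raise ValueError("alpha (J,K), beta (J,K,C) and admin_mask (J,K) required")
        if beta.shape[:2] != alpha.shape:
            raise ValueError("beta leading dims must match alpha")
        J, K = alpha.shape
        if np.any(~np.isfinite(alpha[admin_mask])) or np.any(alpha[admin_mask] <= 0):
            raise ValueError("administered discriminations must be finite and > 0")
        if np.any(~np.isfinite(beta[admin_mask])):
            raise ValueError("administered thresholds must be finite")
        alpha[~admin_mask] = np.nan
        beta[~admin_mask] = np.nan
        self.alpha = alpha
        self.beta = beta
        self.admin_mask = admin_mask
        self.group_labels = list(group_labels) if group_labels is not None else [
            f"group{j + 1}" for j in range(J)
        ]
        self.item_labels = list(item_labels) if item_labels is not None else [
            f"item{k + 1}" for k in range(K)
        ]

    @property
    def n_groups(self) -> int:
        return self.alpha.shape[0]

    @property
    def n_items(self) -> int:
        return self.alpha.shape[1]

    @property
    def C(self) -> int:
        return self.beta.shape[2]

    def get(self, group: int, item: int) -> GroupItemParams:
        if not self.admin_mask[group, item]:
            raise KeyError(f"item {item} is not administered in group {group}")
        return GroupItemParams(float(self.alpha[group, item]), tuple(self.beta[group, item]))

    def to_long_frame(self) -> pd.DataFrame:
        rows = []
        for j in range(self.n_groups):
            for k in range(self.n_items):
                if not self.admin_mask[j, k]:
                    continue
                row = {
                    "group": self.group_labels[j],
                    "item": self.item_labels[k],
                    "alpha": self.alpha[j, k],
                }
                for c in range(self.C):
                    row[f"beta{c + 1}"] = self.beta[j, k, c]
                rows.append(row)
        return pd.DataFrame(rows)

    @classmethod
    def from_long_frame(cls, df: pd.DataFrame) -> "ParamSet":
        group_labels = list(dict.fromkeys(df["group"]))
        item_labels = list(dict.fromkeys(df["item"]))
        beta_cols = sorted(c for c in df.columns if c.startswith("beta"))
        J, K, C = len(group_labels), len(item_labels), len(beta_cols)
        alpha = np.full((J, K), np.nan)
        beta = np.full((J, K, C), np.nan)
        admin = np.zeros((J, K), dtype=bool)
        gi = {g: j for j, g in enumerate(group_labels)}
        ii = {it: k for k, it in enumerate(item_labels)}
        for _, r in df.iterrows():
            j, k = gi[r["group"]], ii[r["item"]]
            alpha[j, k] = r["alpha"]
            beta[j, k] = [r[c] for c in beta_cols]
            admin[j, k] = True
        return cls(alpha, beta, admin, group_labels, item_labels)

    def to_csv(self, path) -> None:
        self.to_long_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "ParamSet":
        return cls.from_long_frame(pd.read_csv(path))

    def to_json(self, path=None) -> str:
        payload = {
            "group_labels": self.group_labels,
            "item_labels": self.item_labels,
            "C": self.C,
            "entries": [
                {
                    "group": self.group_labels[j],
                    "item": self.item_labels[k],
                    "alpha": self.alpha[j, k],
                    "betas": list(self.beta[j, k]),
                }
                for j in range(self.n_groups)
                for k in range(self.n_items)
                if self.admin_mask[j, k]
            ],
        }
        text = json.dumps(payload, indent=1)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source) -> "ParamSet":
        if isinstance(source, (str, Path)) and Path(str(source)).exists():
            payload = json.loads(Path(source).read_text())
        else:
            payload = json.loads(source)
        J, K, C = len(payload["group_labels"]), len(payload["item_labels"]), payload["C"]
        alpha = np.full((J, K), np.nan)
        beta = np.full((J, K, C), np.nan)
        admin = np.zeros((J, K), dtype=bool)
        gi = {g: j for j, g in enumerate(payload["group_labels"])}
        ii = {it: k for k, it in enumerate(payload["item_labels"])}
        for e in payload["entries"]:
            j, k = gi[e["group"]], ii[e["item"]]
            alpha[j, k] = e["alpha"]
            beta[j, k] = e["betas"]
            admin[j, k] = True
        return cls(alpha, beta, admin, payload["group_labels"], payload["item_labels"])

    def equals(self, other: "ParamSet") -> bool:
        return (
            np.array_equal(self.admin_mask, other.admin_mask)
            and np.array_equal(self.alpha, other.alpha, equal_nan=True)
            and np.array_equal(self.beta, other.beta, equal_nan=True)
            and self.group_labels == other.group_labels
            and self.item_labels == other.item_labels
        )


def tcc(theta, params: ParamSet, group: int, items: Sequence[int]):
    """Test characteristic curve: expected sum score over ``items`` for the
    item parameters of ``group`` at trait value(s) ``theta``.

    Empty item sets give 0.  Raises if any item is not administered in the
    group.
    """
    items = list(items)
    scalar = np.isscalar(theta) or np.ndim(theta) == 0
    theta_arr = np.atleast_1d(np.asarray(theta, dtype=float))
    if not np.all(np.isfinite(theta_arr)):
        raise ValueError("theta must be finite")
    total = np.zeros(theta_arr.shape, dtype=float)
    for k in items:
        if not params.admin_mask[group, k]:
            raise ValueError(
                f"item {params.item_labels[k]!r} is not administered in group "
                f"{params.group_labels[group]!r}"
            )
        total += expected_item_score(theta_arr, params.get(group, k))
    return float(total[0]) if scalar else total


def loglik_cells(
    y: np.ndarray,
    obs: np.ndarray,
    alpha_pi: np.ndarray,
    beta_pi: np.ndarray,
    theta: np.ndarray,
) -> np.ndarray:
    """Per-(person, item) log-likelihood contributions.

    ``y`` (N, K) int response codes (any value where not observed), ``obs``
    (N, K) bool, ``alpha_pi``/``beta_pi`` the person-aligned parameter
    matrices (N, K) and (N, K, C), ``theta`` (N,).  Non-observed cells
    contribute exactly 0.
    """
    C = beta_pi.shape[-1]
    with np.errstate(invalid="ignore"):
        d = alpha_pi[:, :, None] * (theta[:, None, None] - beta_pi)
        s = np.cumsum(d, axis=-1)  # (N, K, C): cumulative logits for c >= 1
        m = np.maximum(s.max(axis=-1), 0.0)  # include the c = 0 logit of 0
        logZ = m + np.log(np.exp(-m) + np.exp(s - m[..., None]).sum(axis=-1))
        idx = (np.clip(y, 1, C) - 1)[..., None]
        s_y = np.take_along_axis(s, idx, axis=-1)[..., 0]
        s_y = np.where(y > 0, s_y, 0.0)
    return np.where(obs, s_y - logZ, 0.0)


def log_likelihood(ds, params: ParamSet, thetas) -> float:
    """Observed-data log-likelihood of a :class:`ResponseDataset`.

    Additive over persons and items; MISSING and non-administered cells
    contribute zero.  Never returns -inf for finite parameters.
    """
    thetas = np.asarray(thetas, dtype=float)
    if thetas.shape != (ds.n_persons,):
        raise ValueError("thetas must align one-to-one with persons")
    if ds.n_persons == 0:
        return 0.0
    obs = ~np.isnan(ds.responses)
    y = np.nan_to_num(ds.responses, nan=0.0).astype(int)
    alpha_pi = params.alpha[ds.group_idx]
    beta_pi = params.beta[ds.group_idx]
    cells = loglik_cells(y, obs, alpha_pi, beta_pi, thetas)
    total = float(cells.sum())
    if not np.isfinite(total):
        raise FloatingPointError("non-finite log-likelihood for finite parameters")
    return total
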