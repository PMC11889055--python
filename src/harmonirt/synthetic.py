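"""Synthetic multi-cohort GPCM response data with known truth.

The real cohort data behind harmonization studies of this kind are typically
restricted, so this module generates stand-in cohorts from the same
generative model the sampler estimates: persons draw a latent trait from a
group-specific normal distribution, and each administered item produces an
ordinal code from GPCM category probabilities with (possibly group-varying)
item parameters.  A DIF ledger plants known threshold shifts or
discrimination factors in chosen (item, group) cells, and an optional twin
layer duplicates a fraction of persons as correlated pairs so the
one-per-family filter has realistic input.

The stored :class:`SyntheticTruth` is expressed *after* the per-group
identification transform (mean threshold 0, product of discriminations 1),
so parameter-recovery comparisons against a fitted model are well-posed.
"""

from __future__ import annotations

import dataclasses
import io
from typing import Sequence

import numpy as np
import yaml

from .gpcm import ParamSet, _cumulative_logits
from .response_data import ResponseDataset
from scipy.special import softmax


@dataclasses.dataclass
class DifEntry:
    """A planted deviation: add ``delta_beta`` to the thresholds and multiply
    the discrimination by ``alpha_factor`` for one (item, group) cell."""

    item: int
    group: int
    delta_beta: tuple[float, ...]
    alpha_factor: float = 1.0


@dataclasses.dataclass
class TruthConfig:
    """Complete description of a synthetic multi-cohort study."""

    group_sizes: tuple[int, ...]
    group_means: tuple[float, ...]
    group_sds: tuple[float, ...]
    alpha: np.ndarray  # (K,) base discriminations
    beta: np.ndarray  # (K, C) base thresholds
    admin_mask: np.ndarray  # (J, K) bool
    item_labels: list[str] = dataclasses.field(default_factory=list)
    group_labels: list[str] = dataclasses.field(default_factory=list)
    C: int = 2
    dif: list[DifEntry] = dataclasses.field(default_factory=list)
    twin_fraction: float = 0.0  # fraction of persons who are one of a twin pair
    twin_corr: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        self.alpha = np.asarray(self.alpha, dtype=float)
        self.beta = np.asarray(self.beta, dtype=float)
        self.admin_mask = np.asarray(self.admin_mask, dtype=bool)
        J, K = self.admin_mask.shape
        if len(self.group_sizes) != J or len(self.group_means) != J or len(self.group_sds) != J:
            raise ValueError("group_sizes/means/sds must all have length J")
        if any(n < 1 for n in self.group_sizes):
            raise ValueError("group sizes must be >= 1")
        if any(s <= 0 for s in self.group_sds):
            raise ValueError("group trait SDs must be > 0")
        if self.alpha.shape != (K,) or self.beta.shape != (K, self.C):
            raise ValueError("alpha must be (K,), beta (K,C), aligned to admin_mask")
        if np.any(self.alpha <= 0):
            raise ValueError("base discriminations must be > 0")
        if not self.item_labels:
            self.item_labels = [f"item{k + 1}" for k in range(K)]
        if not self.group_labels:
            self.group_labels = [f"group{j + 1}" for j in range(J)]
        for d in self.dif:
            if not self.admin_mask[d.group, d.item]:
                raise ValueError(
                    f"DIF target item {d.item} is not administered in group {d.group}"
                )
            if self.alpha[d.item] * d.alpha_factor <= 0:
                raise ValueError("alpha_factor must keep the discrimination positive")
        if not 0.0 <= self.twin_fraction <= 1.0:
            raise ValueError("twin_fraction must lie in [0, 1]")

    # -- group-specific true parameters (before identification) ---------------
    def group_params(self) -> tuple[np.ndarray, np.ndarray]:
        J, K = self.admin_mask.shape
        alpha = np.tile(self.alpha, (J, 1))
        beta = np.tile(self.beta, (J, 1, 1))
        for d in self.dif:
            alpha[d.group, d.item] *= d.alpha_factor
            beta[d.group, d.item] += np.asarray(d.delta_beta, dtype=float)
        alpha[~self.admin_mask] = np.nan
        beta[~self.admin_mask] = np.nan
        return alpha, beta

    def to_yaml(self, path=None) -> str:
        payload = dataclasses.asdict(self)
        payload["alpha"] = self.alpha.tolist()
        payload["beta"] = self.beta.tolist()
        payload["admin_mask"] = self.admin_mask.astype(int).tolist()
        payload["group_sizes"] = list(self.group_sizes)
        payload["group_means"] = list(self.group_means)
        payload["group_sds"] = list(self.group_sds)
        payload["dif"] = [dataclasses.asdict(d) for d in self.dif]
        text = yaml.safe_dump(payload, sort_keys=False)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_yaml(cls, source) -> "TruthConfig":
        if isinstance(source, str) and "\n" not in source:
            with open(source) as fh:
                payload = yaml.safe_load(fh)
        elif isinstance(source, io.IOBase):
            payload = yaml.safe_load(source)
        else:
            payload = yaml.safe_load(source)
        payload["dif"] = [
            DifEntry(item=d["item"], group=d["group"],
                     delta_beta=tuple(d["delta_beta"]),
                     alpha_factor=d.get("alpha_factor", 1.0))
            for d in payload.get("dif", [])
        ]
        for key in ("group_sizes", "group_means", "group_sds"):
            payload[key] = tuple(payload[key])
        return cls(**payload)


@dataclasses.dataclass
class SyntheticTruth:
    """Ground truth after the per-group identification transform."""

    theta: np.ndarray  # (N,) identified person traits
    params: ParamSet  # identified group-specific item parameters
    group_means: np.ndarray  # identified group trait means
    group_sds: np.ndarray  # identified group trait SDs


def _identify_truth(alpha, beta, theta, mu, sd, admin, group_idx):
    """Per-group transform to mean-threshold-0 / product-of-alpha-1 scale."""
    J = admin.shape[0]
    alpha = alpha.copy()
    beta = beta.copy()
    theta = theta.copy()
    mu = np.asarray(mu, dtype=float).copy()
    sd = np.asarray(sd, dtype=float).copy()
    for j in range(J):
        k = admin[j]
        g = float(np.exp(np.mean(np.log(alpha[j, k]))))
        scaled = beta[j, k] * g
        m = float(scaled.mean())
        alpha[j, k] = alpha[j, k] / g
        beta[j, k] = scaled - m
        rows = group_idx == j
        theta[rows] = g * theta[rows] - m
        mu[j] = g * mu[j] - m
        sd[j] = g * sd[j]
    return alpha, beta, theta, mu, sd


def generate(cfg: TruthConfig, seed: int | None = None) -> tuple[ResponseDataset, SyntheticTruth]:
    """Draw a dataset and its ground truth from ``cfg``.

    Reproducible: the same config and seed give byte-identical data.  The
    responses are category draws from the GPCM probabilities; cells outside
    the administration mask are missing.
    """
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    J, K = cfg.admin_mask.shape
    alpha_g, beta_g = cfg.group_params()

    thetas: list[np.ndarray] = []
    groups: list[np.ndarray] = []
    families: list = []
    fam_counter = 0
    for j in range(J):
        n = cfg.group_sizes[j]
        mu, sd = cfg.group_means[j], cfg.group_sds[j]
        n_pairs = int(round(n * cfg.twin_fraction / 2.0))
        n_pairs = min(n_pairs, n // 2)
        n_single = n - 2 * n_pairs
        th = np.empty(n)
        fam = np.empty(n, dtype=object)
        if n_pairs:
            cov = np.array([[1.0, cfg.twin_corr], [cfg.twin_corr, 1.0]]) * sd**2
            pair = rng.multivariate_normal([mu, mu], cov, size=n_pairs)
            th[: 2 * n_pairs] = pair.ravel()
            for p in range(n_pairs):
                fam_counter += 1
                fam[2 * p] = fam[2 * p + 1] = f"fam{fam_counter}"
        th[2 * n_pairs:] = rng.normal(mu, sd, size=n_single)
        for s in range(n_single):
            fam_counter += 1
            fam[2 * n_pairs + s] = f"fam{fam_counter}"
        thetas.append(th)
        groups.append(np.full(n, j, dtype=int))
        families.append(fam)

    theta = np.concatenate(thetas)
    group_idx = np.concatenate(groups)
    family = np.concatenate(families) if cfg.twin_fraction > 0 else None
    N = theta.size

    # category draws: P (N, K, C+1) from the person's group parameters
    A = alpha_g[group_idx]
    B = beta_g[group_idx]
    theta_b = np.broadcast_to(theta[:, None], A.shape)
    with np.errstate(invalid="ignore"):
        s = _cumulative_logits(theta_b, A, B)
        p = softmax(s, axis=-1)
    u = rng.uniform(size=(N, K))
    cum = np.cumsum(p, axis=-1)
    y = (u[..., None] > cum[..., :-1]).sum(axis=-1).astype(float)
    y[~cfg.admin_mask[group_idx]] = np.nan

    ds = ResponseDataset(
        responses=y,
        group_idx=group_idx,
        admin_mask=cfg.admin_mask.copy(),
        item_labels=list(cfg.item_labels),
        group_labels=list(cfg.group_labels),
        C=cfg.C,
        family_id=family,
    )

    ia, ib, itheta, imu, isd = _identify_truth(
        alpha_g, beta_g, theta, cfg.group_means, cfg.group_sds, cfg.admin_mask, group_idx
    )
    truth = SyntheticTruth(
        theta=itheta,
        params=ParamSet(ia, ib, cfg.admin_mask, cfg.group_labels, cfg.item_labels),
        group_means=imu,
        group_sds=isd,
    )
    return ds, truth


def inject_dif(
    cfg: TruthConfig,
    item: int,
    group: int,
    delta_beta1: float = 0.0,
    delta_beta2: float = 0.0,
    alpha_factor: float = 1.0,
) -> TruthConfig:
    """Return a copy of ``cfg`` with one extra DIF ledger entry; base
    parameters and other groups are untouched."""
    entry = DifEntry(item=item, group=group,
                     delta_beta=(delta_beta1, delta_beta2),
                     alpha_factor=alpha_factor)
    new = dataclasses.replace(cfg, dif=list(cfg.dif) + [entry])
    return new


def _base_items(K: int) -> tuple[np.ndarray, np.ndarray]:
    """Deterministic, realistic base item parameters: discriminations spread
    around 1 with geometric mean 1, ordered thresholds centered at 0."""
    alpha = np.exp(np.linspace(-0.3, 0.3, K))
    alpha /= np.exp(np.mean(np.log(alpha)))  # product exactly 1
    b1 = np.linspace(-1.4, 0.6, K)
    b2 = b1 + 1.2
    beta = np.column_stack([b1, b2])
    beta -= beta.mean()  # overall threshold mean exactly 0
    return alpha, beta


def default_paper_scenario(scale: str, seed: int = 0) -> TruthConfig:
    """Default 3-cohort study designs.

    ``"adhd"``: 16 three-point items (11 long-form + 5 short-form); cohort
    sizes (1551, 878, 4501); the third cohort is administered only the 5
    short-form items.  ``"anxdep"``: 36 items (31 long-form + 5 short-form);
    sizes (1507, 866, 4504); the third cohort answers only 4 of the 5
    short-form items.  Group trait means are ordered third > first >= second,
    with gaps echoing typical cross-cohort latent-mean contrasts (about
    0.4-0.6 SD); these defaults are illustrative, not estimates.
    """
    if scale == "adhd":
        K, n_long = 16, 11
        sizes = (1551, 878, 4501)
        means = (0.0, -0.40, 0.54)
        labels = [f"CBCL_adhd_{i + 1:02d}" for i in range(n_long)] + [
            f"SDQ_hyper_{i + 1:02d}" for i in range(5)
        ]
        short_admin = np.arange(n_long, K)
    elif scale == "anxdep":
        K, n_long = 36, 31
        sizes = (1507, 866, 4504)
        means = (0.0, 0.0, 0.58)
        labels = [f"CBCL_anxdep_{i + 1:02d}" for i in range(n_long)] + [
            f"SDQ_emot_{i + 1:02d}" for i in range(5)
        ]
        # the third cohort lacks one short-form item (the "often unhappy,
        # tearful" emotional item), leaving 4 administered items
        short_admin = np.array([n_long, n_long + 1, n_long + 3, n_long + 4])
    else:
        raise ValueError(f"unknown scale {scale!r}; expected 'adhd' or 'anxdep'")

    alpha, beta = _base_items(K)
    admin = np.zeros((3, K), dtype=bool)
    admin[0] = admin[1] = True
    admin[2, short_admin] = True
    return TruthConfig(
        group_sizes=sizes,
        group_means=means,
        group_sds=(1.0, 1.0, 1.0),
        alpha=alpha,
        beta=beta,
        admin_mask=admin,
        item_labels=labels,
        group_labels=["Raine", "ABCD", "TEDS"],
        C=2,
        seed=seed,
    )


def write_truth_bundle(ds: ResponseDataset, truth: SyntheticTruth, cfg: TruthConfig, outdir) -> dict:
    """Emit the canonical responses CSV, admin-mask CSV, truth JSON and config
    YAML; returns the paths."""
    import json
    from pathlib import Path

    from .response_data import ResponseSchema, write_responses
    import pandas as pd

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "responses": outdir / "responses.csv",
        "admin_mask": outdir / "admin_mask.csv",
        "truth": outdir / "truth.json",
        "config": outdir / "truth_config.yaml",
    }
    schema = ResponseSchema(family_col="family" if ds.family_id is not None else None)
    write_responses(ds, paths["responses"], schema)
    pd.DataFrame(
        ds.admin_mask.astype(int), index=ds.group_labels, columns=ds.item_labels
    ).to_csv(paths["admin_mask"])
    payload = {
        "theta": truth.theta.tolist(),
        "group_means": truth.group_means.tolist(),
        "group_sds": truth.group_sds.tolist(),
        "params": json.loads(truth.params.to_json()),
    }
    paths["truth"].write_text(json.dumps(payload))
    cfg.to_yaml(paths["config"])
    return {k: str(v) for k, v in paths.items()}
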