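"""Shared fixtures.

The expensive session fixtures run the full simulate-and-fit study twice
over 20 replicates each — once with a planted DIF item (parameter recovery)
and once fully invariant (the DTF null) — and distil each replicate into the
metrics the tests assert on, so the posteriors themselves do not pile up in
memory.  The study conditions (3 groups of 300 persons, 16 three-point
items, latent means 0 / 0.4 / 1.0, one +0.5 first-threshold shift in group 2
on item 4) are fixed here and shared by every consumer.
"""

import numpy as np
import pandas as pd
import pytest

import harmonirt as h
from harmonirt.synthetic import _base_items

N_REPLICATES = 20
GROUP_MEANS = (0.0, 0.4, 1.0)
DIF_ITEM = 3
DIF_GROUP = 1
DIF_SHIFT = 0.5
REDUCED_MCMC = dict(n_burn=200, n_keep=800)


def study_config(with_dif: bool) -> h.TruthConfig:
    alpha, beta = _base_items(16)
    cfg = h.TruthConfig(
        group_sizes=(300, 300, 300),
        group_means=GROUP_MEANS,
        group_sds=(1.0, 1.0, 1.0),
        alpha=alpha,
        beta=beta,
        admin_mask=np.ones((3, 16), dtype=bool),
        seed=0,
    )
    if with_dif:
        cfg = h.inject_dif(cfg, item=DIF_ITEM, group=DIF_GROUP, delta_beta1=DIF_SHIFT)
    return cfg


def _fit_replicate(cfg, data_seed, chain_seed):
    ds, truth = h.generate(cfg, seed=data_seed)
    post = h.fit(ds, h.McmcConfig(seed=chain_seed, **REDUCED_MCMC))
    return ds, truth, post


@pytest.fixture(scope="session")
def recovery_replicates():
    """20 reduced fits to data with planted group-mean gaps and one DIF item;
    returns per-replicate recovery metrics plus the first replicate's full
    (dataset, truth, posterior) triple for reuse."""
    cfg = study_config(with_dif=True)
    metrics = []
    first = None
    for rep in range(N_REPLICATES):
        ds, truth, post = _fit_replicate(cfg, data_seed=1000 + rep, chain_seed=rep)
        mu = post.stacked("mu")
        c21 = mu[:, 1] - mu[:, 0]
        c31 = mu[:, 2] - mu[:, 0]
        beta_d = post.stacked("beta")
        dif_dev = beta_d[:, DIF_GROUP, DIF_ITEM, 0] - beta_d[:, 0, DIF_ITEM, 0]
        table = h.dif_table(post, DIF_GROUP, 0)
        planted = table[
            (table["item"] == post.item_labels[DIF_ITEM]) & (table["parameter"] == "beta1")
        ].iloc[0]
        metrics.append(
            {
                "c21_mean": float(c21.mean()),
                "c21_sd": float(c21.std(ddof=1)),
                "c31_mean": float(c31.mean()),
                "c31_sd": float(c31.std(ddof=1)),
                "truth_c21": float(truth.group_means[1] - truth.group_means[0]),
                "truth_c31": float(truth.group_means[2] - truth.group_means[0]),
                "dif_dev_mean": float(dif_dev.mean()),
                "dif_flagged": bool(planted["flagged"]),
                "theta_corr": float(np.corrcoef(post.theta_mean, truth.theta)[0, 1]),
            }
        )
        if first is None:
            first = (ds, truth, post)
    return {"metrics": metrics, "first": first}


@pytest.fixture(scope="session")
def nodif_replicates():
    """20 reduced fits to fully invariant data; per-replicate DTFR and focal
    sum-score SD, plus the first replicate's full triple."""
    cfg = study_config(with_dif=False)
    metrics = []
    first = None
    for rep in range(N_REPLICATES):
        ds, truth, post = _fit_replicate(cfg, data_seed=5000 + rep, chain_seed=100 + rep)
        res = h.dtf_result(ds, post, 0, 1)
        metrics.append({"dtfr": res.DTFR, "sd_f": res.SD_F})
        if first is None:
            first = (ds, truth, post)
    return {"metrics": metrics, "first": first}


@pytest.fixture()
def tiny_dataset():
    """Small 2-group dataset with hand-placed patterns for scoring tests."""
    rng = np.random.default_rng(77)
    alpha = np.exp(np.linspace(-0.2, 0.2, 6))
    alpha /= np.exp(np.mean(np.log(alpha)))
    b1 = np.linspace(-0.8, 0.4, 6)
    beta = np.column_stack([b1, b1 + 1.0])
    beta -= beta.mean()
    cfg = h.TruthConfig(
        group_sizes=(60, 60),
        group_means=(0.0, 0.5),
        group_sds=(1.0, 1.0),
        alpha=alpha,
        beta=beta,
        admin_mask=np.ones((2, 6), dtype=bool),
        seed=int(rng.integers(1 << 20)),
    )
    ds, truth = h.generate(cfg, seed=11)
    return ds, truth
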