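"""Multi-cohort item-response datasets: container, CSV I/O and sample filters.

A :class:`ResponseDataset` is a persons x items matrix of ordinal codes
``0..C`` (NaN for missing), a group index per person, an optional family
identifier and a group x item administration mask.  The mask encodes
missingness *by design* (a cohort never received an item); a NaN on an
administered item is ordinary missing data and makes the person incomplete
for that scale.

The filters implement the sample-construction rules for multi-cohort
questionnaire studies: complete-case filtering on the administered items of a
scale, and random selection of one child per family to break the dependence
between twins.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

MISSING = np.nan


class ValidationError(ValueError):
    """Raised when a dataset or input file violates the data contract."""


@dataclasses.dataclass
class ResponseDataset:
    """Persons x items ordinal responses with cohort structure.

    Attributes
    ----------
    responses
        (N, K) float array of codes in ``{0..C}``; NaN marks a missing value.
    group_idx
        (N,) int array of 0-based group indices (contiguous ``0..J-1``).
    admin_mask
        (J, K) bool; False means the item was never administered in that
        group, and all its responses there must be NaN.
    item_labels, group_labels
        Column / cohort names.
    C
        Highest category code (2 for 3-point scales).
    family_id
        Optional (N,) object array of family identifiers (may contain None).
    """

    responses: np.ndarray
    group_idx: np.ndarray
    admin_mask: np.ndarray
    item_labels: list[str]
    group_labels: list[str]
    C: int = 2
    family_id: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.responses = np.asarray(self.responses, dtype=float)
        if self.responses.ndim != 2:
            raise ValidationError("responses must be a 2-D persons x items array")
        self.group_idx = np.asarray(self.group_idx, dtype=int)
        self.admin_mask = np.asarray(self.admin_mask, dtype=bool)
        self.item_labels = list(self.item_labels)
        self.group_labels = list(self.group_labels)
        if self.family_id is not None:
            self.family_id = np.asarray(self.family_id, dtype=object)
        self.validate()

    # -- basic shape accessors -------------------------------------------------
    @property
    def n_persons(self) -> int:
        return self.responses.shape[0]

    @property
    def n_items(self) -> int:
        return self.responses.shape[1]

    @property
    def n_groups(self) -> int:
        return len(self.group_labels)

    def validate(self) -> None:
        N, K = self.responses.shape
        J = len(self.group_labels)
        if len(self.item_labels) != K:
            raise ValidationError("item_labels must match the number of columns")
        if self.group_idx.shape != (N,):
            raise ValidationError("group_idx must have one entry per person")
        if N and (self.group_idx.min() < 0 or self.group_idx.max() >= J):
            raise ValidationError("group indices must lie in 0..J-1")
        if self.admin_mask.shape != (J, K):
            raise ValidationError("admin_mask must be J x K")
        if self.family_id is not None and self.family_id.shape != (N,):
            raise ValidationError("family_id must have one entry per person")
        obs = ~np.isnan(self.responses)
        vals = self.responses[obs]
        if vals.size:
            if np.any(vals != np.round(vals)):
                i, k = np.argwhere(obs & (self.responses != np.round(self.responses)))[0]
                raise ValidationError(
                    f"non-integer code {self.responses[i, k]} at row {i}, "
                    f"column {self.item_labels[k]!r}"
                )
            if vals.min() < 0 or vals.max() > self.C:
                bad = np.argwhere(obs & ((self.responses < 0) | (self.responses > self.C)))[0]
                i, k = bad
                raise ValidationError(
                    f"code {self.responses[i, k]:g} out of range 0..{self.C} at row {i}, "
                    f"column {self.item_labels[k]!r}"
                )
        # design missingness: no observed response where the mask is off
        for j in range(J):
            rows = self.group_idx == j
            if not rows.any():
                continue
            off = ~self.admin_mask[j]
            if off.any() and obs[np.ix_(rows, off)].any():
                k = int(np.where(off)[0][np.argmax(obs[np.ix_(rows, off)].any(axis=0))])
                raise ValidationError(
                    f"group {self.group_labels[j]!r} has responses on item "
                    f"{self.item_labels[k]!r} which admin_mask marks as not administered"
                )

    def subset_persons(self, keep: np.ndarray) -> "ResponseDataset":
        """Dataset restricted to the persons selected by ``keep`` (bool or index)."""
        return ResponseDataset(
            responses=self.responses[keep].copy(),
            group_idx=self.group_idx[keep].copy(),
            admin_mask=self.admin_mask.copy(),
            item_labels=list(self.item_labels),
            group_labels=list(self.group_labels),
            C=self.C,
            family_id=None if self.family_id is None else self.family_id[keep].copy(),
        )

    def item_index(self, items: Sequence) -> np.ndarray:
        """Resolve item labels or integer positions to integer positions."""
        out = []
        for it in items:
            if isinstance(it, (int, np.integer)):
                if not 0 <= it < self.n_items:
                    raise ValidationError(f"item index {it} out of range")
                out.append(int(it))
            else:
                try:
                    out.append(self.item_labels.index(it))
                except ValueError:
                    raise ValidationError(f"unknown item label {it!r}") from None
        return np.asarray(out, dtype=int)


@dataclasses.dataclass
class ResponseSchema:
    """Column naming for the canonical responses CSV.

    ``item_cols=None`` means every column other than group/family is an item.
    """

    group_col: str = "group"
    family_col: str | None = None
    item_cols: list[str] | None = None
    missing_token: str = "NA"
    C: int = 2


def read_responses(path, schema: ResponseSchema | None = None, admin_mask=None) -> ResponseDataset:
    """Read a wide-format responses CSV into a validated dataset.

    One row per person; a group column, an optional family column, and one
    column per item with integer codes or the missing token.  Unless given
    explicitly, ``admin_mask`` is inferred as "administered iff any person of
    the group has a non-missing code on the item".
    """
    schema = schema or ResponseSchema()
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    if schema.group_col not in df.columns:
        raise ValidationError(f"missing group column {schema.group_col!r}")
    item_cols = schema.item_cols
    if item_cols is None:
        skip = {schema.group_col, schema.family_col}
        item_cols = [c for c in df.columns if c not in skip]
    for c in item_cols:
        if c not in df.columns:
            raise ValidationError(f"missing item column {c!r}")

    group_labels = list(dict.fromkeys(df[schema.group_col]))
    gi = {g: j for j, g in enumerate(group_labels)}
    group_idx = df[schema.group_col].map(gi).to_numpy()

    N, K = len(df), len(item_cols)
    responses = np.full((N, K), np.nan)
    for k, col in enumerate(item_cols):
        raw = df[col].str.strip()
        miss = (raw == schema.missing_token) | (raw == "")
        for i in np.where(~miss)[0]:
            try:
                v = int(raw.iat[i])
            except ValueError:
                raise ValidationError(
                    f"non-integer code {raw.iat[i]!r} at row {i}, column {col!r}"
                ) from None
            if not 0 <= v <= schema.C:
                raise ValidationError(
                    f"code {v} out of range 0..{schema.C} at row {i}, column {col!r}"
                )
            responses[i, k] = v

    family = None
    if schema.family_col is not None:
        if schema.family_col not in df.columns:
            raise ValidationError(f"missing family column {schema.family_col!r}")
        fam = df[schema.family_col].str.strip()
        family = np.array([None if f in ("", schema.missing_token) else f for f in fam], dtype=object)

    if admin_mask is None:
        J = len(group_labels)
        mask = np.zeros((J, K), dtype=bool)
        obs = ~np.isnan(responses)
        for j in range(J):
            rows = group_idx == j
            mask[j] = obs[rows].any(axis=0)
    else:
        mask = np.asarray(admin_mask, dtype=bool)

    return ResponseDataset(
        responses=responses,
        group_idx=group_idx,
        admin_mask=mask,
        item_labels=item_cols,
        group_labels=group_labels,
        C=schema.C,
        family_id=family,
    )


def read_admin_mask(path, group_labels: Sequence[str], item_labels: Sequence[str]) -> np.ndarray:
    """Read a groups x items 0/1 CSV (first column = group label) into a bool mask."""
    df = pd.read_csv(path, index_col=0)
    df = df.loc[list(group_labels), list(item_labels)]
    return df.to_numpy().astype(bool)


def write_responses(ds: ResponseDataset, path, schema: ResponseSchema | None = None) -> None:
    """Write the canonical responses CSV (round-trips bit-exactly with
    :func:`read_responses` for the same schema)."""
    schema = schema or ResponseSchema(
        family_col="family" if ds.family_id is not None else None
    )
    cols: dict[str, list] = {schema.group_col: [ds.group_labels[j] for j in ds.group_idx]}
    if ds.family_id is not None:
        fam_col = schema.family_col or "family"
        cols[fam_col] = [schema.missing_token if f is None else f for f in ds.family_id]
    for k, label in enumerate(ds.item_labels):
        col = ds.responses[:, k]
        cols[label] = [schema.missing_token if np.isnan(v) else str(int(v)) for v in col]
    pd.DataFrame(cols).to_csv(path, index=False)


def complete_case_filter(
    ds: ResponseDataset, item_subset: Sequence | None = None
) -> tuple[ResponseDataset, int]:
    """Keep persons with no missing value among the *administered* items of
    ``item_subset`` (default: all items).

    Items not administered to a person's group do not count against them.
    Returns the filtered dataset and the number of persons removed; raises if
    nothing survives.  Idempotent.
    """
    items = (
        np.arange(ds.n_items) if item_subset is None else ds.item_index(item_subset)
    )
    obs = ~np.isnan(ds.responses[:, items])
    required = ds.admin_mask[np.ix_(ds.group_idx, items)]  # (N, |items|)
    complete = (obs | ~required).all(axis=1)
    n_removed = int((~complete).sum())
    if not complete.any():
        raise ValidationError("no complete cases remain after filtering")
    return ds.subset_persons(complete), n_removed


def select_one_per_family(
    ds: ResponseDataset, seed: int, allow_singletons: bool = False
) -> ResponseDataset:
    """Retain exactly one person per family, chosen uniformly at random.

    Reproducible for a fixed ``seed``.  Persons without a family identifier
    raise unless ``allow_singletons`` is set, in which case each is kept as
    their own one-person family.
    """
    if ds.family_id is None:
        raise ValidationError("dataset has no family identifiers")
    fam = ds.family_id
    if any(f is None for f in fam) and not allow_singletons:
        raise ValidationError(
            "missing family IDs; pass allow_singletons=True to keep such persons"
        )
    rng = np.random.default_rng(seed)
    keep = np.zeros(ds.n_persons, dtype=bool)
    members: dict = {}
    for i, f in enumerate(fam):
        if f is None:
            keep[i] = True
        else:
            members.setdefault(f, []).append(i)
    # iterate in first-appearance order for seed-stable selection
    for f, idx in members.items():
        keep[idx[rng.integers(len(idx))]] = True
    return ds.subset_persons(keep)


def sample_report(original: ResponseDataset, filtered: ResponseDataset, n_removed: int) -> dict:
    """JSON-ready summary of the sample-construction step: N per group before
    and after, and the number removed."""
    def per_group(d: ResponseDataset) -> dict:
        return {
            g: int((d.group_idx == j).sum()) for j, g in enumerate(d.group_labels)
        }

    return {
        "n_before": original.n_persons,
        "n_after": filtered.n_persons,
        "n_removed": n_removed,
        "per_group_before": per_group(original),
        "per_group_after": per_group(filtered),
    }
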