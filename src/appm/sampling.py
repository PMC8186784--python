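"""Class rebalancing and train/validation/test splitting.

Per-allele datasets are rebalanced by removing 0-labeled records at random
(under-sampling) and duplicating 1-labeled records (over-sampling).
Rebalancing is meant for the TRAIN partition only — evaluating on
rebalanced data would bias PPV — so the intended order is split first,
then rebalance the training table.

A fixture with the 20 per-allele training summaries (positive/negative
counts, train/test sizes, and the under/over-sampling proportions) ships
with the package; see :func:`load_table1`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from importlib import resources
from typing import Dict, Tuple

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger(__name__)


class DegenerateClassError(ValueError):
    """Dataset is missing one of the two label classes."""


class SplitSizeError(ValueError):
    """Requested test partition does not fit in the dataset."""


@dataclass(frozen=True)
class SamplingPlan:
    """Per-allele rebalancing plan.

    ``under_fraction`` in (0, 1] is the fraction of 0-labeled records kept;
    ``over_factor`` ≥ 1 is the total multiplicity of each 1-labeled record.
    """

    allele: str
    under_fraction: float = 1.0
    over_factor: int = 1

    def __post_init__(self) -> None:
        if not 0.0 < self.under_fraction <= 1.0:
            raise ValueError(f"under_fraction must be in (0, 1], got {self.under_fraction}")
        if self.over_factor < 1 or int(self.over_factor) != self.over_factor:
            raise ValueError(f"over_factor must be an integer >= 1, got {self.over_factor}")


@dataclass(frozen=True)
class SplitSpec:
    """Stratified split sizes: an exact test count plus a validation fraction
    of the non-test remainder."""

    test_count: int
    validation_fraction: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.test_count < 0:
            raise ValueError("test_count must be >= 0")
        if not 0.0 <= self.validation_fraction < 1.0:
            raise ValueError("validation_fraction must be in [0, 1)")


def rebalance(dataset: pd.DataFrame, plan: SamplingPlan, seed: int) -> pd.DataFrame:
    """Rebalance a labeled peptide table according to ``plan``.

    Negatives: ``floor(under_fraction × N)`` kept, chosen uniformly without
    replacement under ``seed``. Positives: each duplicated ``over_factor − 1``
    extra times; replicas carry a ``replica`` column (0-based) so partition
    disjointness stays well defined. Over-sampling never fabricates
    sequences.
    """
    if "label" not in dataset.columns:
        raise ValueError("dataset must have a 'label' column")
    pos = dataset[dataset["label"] == 1]
    neg = dataset[dataset["label"] == 0]
    if len(pos) == 0 or len(neg) == 0:
        raise DegenerateClassError(
            f"need both classes present, got {len(pos)} positives and {len(neg)} negatives"
        )
    rng = np.random.default_rng(seed)
    n_keep = int(np.floor(plan.under_fraction * len(neg)))
    keep_idx = rng.choice(len(neg), size=n_keep, replace=False)
    keep_idx.sort()
    neg_out = neg.iloc[keep_idx].copy()
    neg_out["replica"] = 0

    pos_parts = []
    for r in range(plan.over_factor):
        part = pos.copy()
        part["replica"] = r
        pos_parts.append(part)
    pos_out = pd.concat(pos_parts, ignore_index=False)

    out = pd.concat([pos_out, neg_out], ignore_index=True)
    logger.info(
        "rebalance[%s]: positives %d -> %d (over=%d), negatives %d -> %d (under=%g); "
        "positive fraction %.4f",
        plan.allele, len(pos), len(pos_out), plan.over_factor,
        len(neg), len(neg_out), plan.under_fraction,
        len(pos_out) / max(len(out), 1),
    )
    return out


def _allocate_stratified(group_sizes: Dict[int, int], total: int) -> Dict[int, int]:
    """Largest-remainder allocation of ``total`` across strata, proportional to
    group size. Keeps every partition's per-stratum share within one record of
    the exact proportion."""
    n = sum(group_sizes.values())
    if total > n:
        raise SplitSizeError(f"cannot allocate {total} records from {n}")
    if n == 0:
        return {k: 0 for k in group_sizes}
    quotas = {k: total * size / n for k, size in group_sizes.items()}
    alloc = {k: int(np.floor(q)) for k, q in quotas.items()}
    shortfall = total - sum(alloc.values())
    # hand the remainder to the largest fractional parts, deterministically
    order = sorted(group_sizes, key=lambda k: (-(quotas[k] - alloc[k]), k))
    for k in order[:shortfall]:
        alloc[k] += 1
    for k, size in group_sizes.items():
        alloc[k] = min(alloc[k], size)
    return alloc


def split(
    dataset: pd.DataFrame, spec: SplitSpec
) -> Tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Stratified (train, validation, test) split.

    Test gets exactly ``spec.test_count`` records; validation gets
    ``round(validation_fraction × remainder)``; train gets the rest. The
    three partitions are pairwise disjoint by record identity and their
    union is the input. Per-partition label proportions stay within one
    record of the global proportions per stratum.
    """
    if spec.test_count >= len(dataset):
        raise SplitSizeError(
            f"test_count {spec.test_count} >= dataset size {len(dataset)}"
        )
    rng = np.random.default_rng(spec.seed)
    groups = {lab: df for lab, df in dataset.groupby("label", sort=True)}
    sizes = {lab: len(df) for lab, df in groups.items()}

    test_alloc = _allocate_stratified(sizes, spec.test_count)
    remainder_sizes = {lab: sizes[lab] - test_alloc[lab] for lab in sizes}
    n_val = int(round(spec.validation_fraction * sum(remainder_sizes.values())))
    val_alloc = _allocate_stratified(remainder_sizes, n_val)

    train_parts, val_parts, test_parts = [], [], []
    for lab, df in groups.items():
        perm = rng.permutation(len(df))
        t, v = test_alloc[lab], val_alloc[lab]
        test_parts.append(df.iloc[perm[:t]])
        val_parts.append(df.iloc[perm[t:t + v]])
        train_parts.append(df.iloc[perm[t + v:]])

    def _cat(parts):
        out = pd.concat(parts) if parts else dataset.iloc[:0]
        return out.sort_index()

    return _cat(train_parts), _cat(val_parts), _cat(test_parts)


def load_table1() -> pd.DataFrame:
    """Load the packaged 20-allele training-summary fixture.

    Columns: ``allele, label1, label0, train, test, under, over``.
    """
    with resources.files("appm.data").joinpath("table1.csv").open("r") as fh:
        return pd.read_csv(fh)


def plans_from_table1(table: pd.DataFrame | None = None) -> Dict[str, SamplingPlan]:
    """Build a per-allele :class:`SamplingPlan` map from the fixture table."""
    if table is None:
        table = load_table1()
    return {
        row.allele: SamplingPlan(
            allele=row.allele,
            under_fraction=float(row.under),
            over_factor=int(row.over),
        )
        for row in table.itertuples()
    }


def load_plan_yaml(path) -> Dict[str, SamplingPlan]:
    """Read a YAML sampling-plan file: a list of ``{allele, under, over}`` maps
    (an optional ``test_count`` per entry is preserved by the CLI, not here)."""
    with open(path) as fh:
        entries = yaml.safe_load(fh)
    plans = {}
    for e in entries:
        plans[e["allele"]] = SamplingPlan(
            allele=e["allele"],
            under_fraction=float(e.get("under", 1.0)),
            over_factor=int(e.get("over", 1)),
        )
    return plans
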